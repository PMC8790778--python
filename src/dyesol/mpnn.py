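"""Directed message passing encoder (NumPy, with hand-written backprop).

The encoder operates on directed-bond hidden states. With atom features
``x_u`` and bond features ``e_uv``:

* initialisation: ``z0_uv = [x_u ; e_uv] W_i`` and ``h0_uv = relu(z0_uv)``;
* message step (repeated ``depth`` times): each directed bond ``u -> v``
  sums the hidden states of bonds *incoming at u*, excluding its own
  reverse ``v -> u``; the sum passes through a shared linear map ``W_h``,
  is added to the initial pre-activation (residual), and goes through the
  rectifier (and dropout when training);
* readout: each atom sums its incoming bond states, concatenates its own
  features, passes through ``W_o`` + rectifier, and the molecule embedding
  is the sum (or mean) over atoms.

All linear maps are bias-free. Weights are Xavier-uniform initialised from
a seeded generator, so a given (params, seed) pair is fully reproducible.
Gradients for ``W_i``, ``W_h``, ``W_o`` are computed by reversing the exact
forward graph; the exclude-reverse sum is evaluated as (sum of all incoming
at u) minus (state of the reverse bond), which keeps both passes O(bonds).

The module also houses the generic pieces the regressors share: a small
fully-connected network (:class:`FFNN`), the Adam optimiser, and a
warmup/decay learning-rate schedule.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .featurize import ATOM_FEATURE_DIM, BOND_FEATURE_DIM, MolGraph


@dataclass
class EncoderParams:
    hidden_size: int = 64
    depth: int = 2
    dropout: float = 0.0
    aggregation: str = "mean"  # "mean" | "sum"
    seed: int = 0

    def __post_init__(self):
        if self.hidden_size < 1 or self.depth < 1:
            raise ValueError("hidden_size and depth must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.aggregation not in ("sum", "mean"):
            raise ValueError("aggregation must be 'sum' or 'mean'")


class _SegmentSum:
    """Segment sum of row vectors by an integer index, via sort + reduceat.

    Deterministic and much faster than ``np.add.at`` for the sizes used
    here. ``sum(values)`` returns shape ``(n_segments, dim)``.
    """

    def __init__(self, index: np.ndarray, n_segments: int):
        self.n_segments = n_segments
        self.order = np.argsort(index, kind="stable")
        sorted_idx = index[self.order]
        if len(sorted_idx):
            boundaries = np.flatnonzero(np.diff(sorted_idx)) + 1
            self.starts = np.concatenate(([0], boundaries))
            self.present = sorted_idx[self.starts]
        else:
            self.starts = np.zeros(0, dtype=np.int64)
            self.present = np.zeros(0, dtype=np.int64)

    def sum(self, values: np.ndarray) -> np.ndarray:
        out = np.zeros((self.n_segments, values.shape[1]))
        if len(self.starts):
            out[self.present] = np.add.reduceat(values[self.order], self.starts, axis=0)
        return out


class BatchMolGraph:
    """Disjoint union of molecular graphs with precomputed scatter plans."""

    def __init__(self, graphs: Sequence[MolGraph]):
        if not graphs:
            raise ValueError("empty batch")
        a_off = 0
        b_off = 0
        atom_f, bond_f, src, dst, rev, mol_of_atom = [], [], [], [], [], []
        for gi, g in enumerate(graphs):
            if g.n_atoms == 0:
                raise ValueError("graph with no atoms")
            atom_f.append(g.atom_features)
            bond_f.append(g.bond_features)
            src.append(g.src + a_off)
            dst.append(g.dst + a_off)
            rev.append(g.rev + b_off)
            mol_of_atom.append(np.full(g.n_atoms, gi, dtype=np.int64))
            a_off += g.n_atoms
            b_off += g.n_bonds
        self.n_mols = len(graphs)
        self.atom_features = np.concatenate(atom_f, axis=0)
        self.bond_features = (
            np.concatenate(bond_f, axis=0)
            if b_off
            else np.zeros((0, BOND_FEATURE_DIM))
        )
        self.src = np.concatenate(src) if b_off else np.zeros(0, dtype=np.int64)
        self.dst = np.concatenate(dst) if b_off else np.zeros(0, dtype=np.int64)
        self.rev = np.concatenate(rev) if b_off else np.zeros(0, dtype=np.int64)
        self.mol_of_atom = np.concatenate(mol_of_atom)
        self.n_atoms = a_off
        self.n_bonds = b_off
        self.atoms_per_mol = np.bincount(self.mol_of_atom, minlength=self.n_mols)
        self._by_dst = _SegmentSum(self.dst, self.n_atoms)
        self._by_src = _SegmentSum(self.src, self.n_atoms)
        self._by_mol = _SegmentSum(self.mol_of_atom, self.n_mols)


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


class DMPNNEncoder:
    """Bond-level message passing encoder. Weights: Wi, Wh, Wo (bias-free)."""

    def __init__(
        self,
        params: EncoderParams,
        n_atom_features: int = ATOM_FEATURE_DIM,
        n_bond_features: int = BOND_FEATURE_DIM,
    ):
        self.params = params
        self.n_atom_features = n_atom_features
        self.n_bond_features = n_bond_features
        h = params.hidden_size
        rng = np.random.default_rng(params.seed)
        self.Wi = _xavier(rng, n_atom_features + n_bond_features, h)
        self.Wh = _xavier(rng, h, h)
        self.Wo = _xavier(rng, n_atom_features + h, h)

    @property
    def weights(self) -> list[np.ndarray]:
        return [self.Wi, self.Wh, self.Wo]

    def set_weights(self, ws: Sequence[np.ndarray]) -> None:
        self.Wi, self.Wh, self.Wo = [np.array(w) for w in ws]

    def forward(
        self,
        batch: BatchMolGraph,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Return (embeddings (n_mols, hidden), cache for backward)."""
        p = self.params
        keep = 1.0 - p.dropout
        X = np.concatenate(
            [batch.atom_features[batch.src], batch.bond_features], axis=1
        ) if batch.n_bonds else np.zeros((0, self.Wi.shape[0]))
        z0 = X @ self.Wi
        h = np.maximum(z0, 0.0)
        masks, hs, ms = [], [h], []
        for _ in range(p.depth):
            s = batch._by_dst.sum(h)  # s[u] = sum of states of bonds arriving at u
            m = s[batch.src] - h[batch.rev]  # exclude the reverse bond
            z = z0 + m @ self.Wh
            h = np.maximum(z, 0.0)
            if training and p.dropout > 0.0:
                mask = (rng.random(h.shape) < keep) / keep
                h = h * mask
            else:
                mask = None
            masks.append(mask)
            ms.append(m)
            hs.append(h)
        a = batch._by_dst.sum(h)  # per-atom sum of incoming bond states
        Xa = np.concatenate([batch.atom_features, a], axis=1)
        za = Xa @ self.Wo
        ha = np.maximum(za, 0.0)
        if training and p.dropout > 0.0:
            amask = (rng.random(ha.shape) < keep) / keep
            ha = ha * amask
        else:
            amask = None
        emb = batch._by_mol.sum(ha)
        if p.aggregation == "mean":
            emb = emb / batch.atoms_per_mol[:, None]
        cache = (batch, X, z0, hs, ms, masks, Xa, za, amask)
        return emb, cache

    def backward(self, cache, d_emb: np.ndarray) -> list[np.ndarray]:
        """Gradients [dWi, dWh, dWo] for a given d(loss)/d(embedding)."""
        batch, X, z0, hs, ms, masks, Xa, za, amask = cache
        p = self.params
        if p.aggregation == "mean":
            d_emb = d_emb / batch.atoms_per_mol[:, None]
        d_ha = d_emb[batch.mol_of_atom]
        if amask is not None:
            d_ha = d_ha * amask
        d_za = d_ha * (za > 0.0)
        dWo = Xa.T @ d_za
        d_a = d_za @ self.Wo[self.n_atom_features :, :].T
        # a[v] = sum_{dst==v} h  =>  d_h += d_a[dst]
        d_h = d_a[batch.dst]
        dWh = np.zeros_like(self.Wh)
        d_z0 = np.zeros_like(z0)
        for t in range(p.depth, 0, -1):
            if masks[t - 1] is not None:
                d_h = d_h * masks[t - 1]
            z_t = z0 + ms[t - 1] @ self.Wh
            d_z = d_h * (z_t > 0.0)
            d_z0 += d_z
            dWh += ms[t - 1].T @ d_z
            d_m = d_z @ self.Wh.T
            # m = s[src] - h_rev with s = segsum of h_prev by dst
            d_s = batch._by_src.sum(d_m)
            d_h = d_s[batch.dst]
            d_h[batch.rev] -= d_m
        d_z0 += d_h * (z0 > 0.0)
        dWi = X.T @ d_z0
        return [dWi, dWh, dWo]


class FFNN:
    """Fully connected regressor head: (layers-1) hidden ReLU layers + linear
    output, biases everywhere."""

    def __init__(self, n_in: int, hidden: int, layers: int, n_out: int, seed: int):
        rng = np.random.default_rng(seed)
        dims = [n_in] + [hidden] * max(layers - 1, 0) + [n_out]
        self.Ws = [_xavier(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]
        self.bs = [np.zeros(b) for b in dims[1:]]

    @property
    def weights(self) -> list[np.ndarray]:
        out = []
        for W, b in zip(self.Ws, self.bs):
            out.extend([W, b])
        return out

    def set_weights(self, ws: Sequence[np.ndarray]) -> None:
        ws = [np.array(w) for w in ws]
        self.Ws = ws[0::2]
        self.bs = ws[1::2]

    def forward(self, x: np.ndarray):
        acts = [x]
        pre = []
        h = x
        for i, (W, b) in enumerate(zip(self.Ws, self.bs)):
            z = h @ W + b
            pre.append(z)
            h = np.maximum(z, 0.0) if i < len(self.Ws) - 1 else z
            acts.append(h)
        return h, (acts, pre)

    def backward(self, cache, d_out: np.ndarray):
        """Returns (grads aligned with :attr:`weights`, d_input)."""
        acts, pre = cache
        grads: list[np.ndarray] = []
        d = d_out
        for i in range(len(self.Ws) - 1, -1, -1):
            if i < len(self.Ws) - 1:
                d = d * (pre[i] > 0.0)
            grads.append(np.sum(d, axis=0))  # bias
            grads.append(acts[i].T @ d)  # weight
            d = d @ self.Ws[i].T
        return grads[::-1], d


class Adam:
    """Adam optimiser over a flat list of parameter arrays (in-place)."""

    def __init__(self, params: list[np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


def lr_schedule(
    step: int,
    steps_per_epoch: int,
    epochs: int,
    warmup_epochs: float,
    init_lr: float,
    max_lr: float,
    final_lr: float,
) -> float:
    """Linear warmup from ``init_lr`` to ``max_lr`` over ``warmup_epochs``,
    then exponential decay reaching ``final_lr`` at the last step."""
    warm = max(int(warmup_epochs * steps_per_epoch), 1)
    total = max(epochs * steps_per_epoch, warm + 1)
    if step < warm:
        return init_lr + (max_lr - init_lr) * step / warm
    frac = (step - warm) / (total - warm)
    return max_lr * (final_lr / max_lr) ** frac


def save_checkpoint(path: str, arrays: dict[str, np.ndarray], meta: dict) -> None:
    """Single-file checkpoint: npz payload with the JSON header embedded."""
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    return arrays, meta
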