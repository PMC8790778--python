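"""Single- and multi-fidelity absorption regressors.

The single-fidelity model encodes the dye with a directed message passing
network, represents the solvent either with its own (non-weight-shared)
message passing network, a 256-bit Morgan fingerprint, or a tabulated
descriptor vector, concatenates the two representations and regresses the
peak absorption wavelength with a feed-forward head.

The multi-fidelity model adds a frozen auxiliary network -- a dye-only
regressor trained on cheap computed excitation energies (a vacuum TD-DFT
surrogate). Its scalar prediction is standardized with training-fold
statistics and concatenated to the representation before the head, so the
main model learns to correct the surrogate rather than predict from
structure alone. No gradient flows into the auxiliary model.

Targets are z-scored with training-fold statistics; predictions are
un-scaled before any metric is computed. Ensembles are independent
retrainings from consecutive seeds; the ensemble mean is the prediction and
the population variance across members is the epistemic-uncertainty
estimate.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .curation import SpectralRecord, canonicalize_smiles
from .featurize import (
    MolGraph,
    SolventDescriptorTable,
    mol_to_graph,
    morgan_fingerprint,
)
from .mpnn import (
    Adam,
    BatchMolGraph,
    DMPNNEncoder,
    EncoderParams,
    FFNN,
    lr_schedule,
)
from .splitting import SplitAssignment
from .tddft import nm_to_ev

_EPS = 1e-8

# module-level graph cache: canonical SMILES -> MolGraph
_GRAPH_CACHE: dict[str, MolGraph] = {}


def _graph(smiles: str) -> MolGraph:
    key = canonicalize_smiles(smiles)
    g = _GRAPH_CACHE.get(key)
    if g is None:
        g = mol_to_graph(key)
        _GRAPH_CACHE[key] = g
    return g


@dataclass
class ModelConfig:
    dye_encoder: EncoderParams = field(default_factory=EncoderParams)
    solvent_mode: str = "mpnn"  # mpnn | morgan | cgsd | minnesota | none
    solvent_encoder: EncoderParams | None = None
    ffn_layers: int = 2
    ffn_hidden: int = 64
    target_units: str = "nm"  # nm | ev
    epochs: int = 30
    batch_size: int = 64
    warmup_epochs: float = 2.0
    init_lr: float = 1e-4
    max_lr: float = 1e-3
    final_lr: float = 1e-4
    ensemble_size: int = 5
    seed: int = 0
    n_extra_features: int = 0

    def __post_init__(self):
        if self.solvent_mode not in ("mpnn", "morgan", "cgsd", "minnesota", "none"):
            raise ValueError(f"unknown solvent_mode {self.solvent_mode!r}")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.solvent_mode == "mpnn" and self.solvent_encoder is None:
            self.solvent_encoder = EncoderParams(
                hidden_size=32, depth=2, aggregation="mean", seed=self.seed + 1
            )
        if self.solvent_mode != "mpnn":
            self.solvent_encoder = None

    def with_seed(self, seed: int) -> "ModelConfig":
        cfg = copy.deepcopy(self)
        cfg.seed = seed
        cfg.dye_encoder.seed = seed
        if cfg.solvent_encoder is not None:
            cfg.solvent_encoder.seed = seed + 1
        return cfg


@dataclass
class EnsemblePrediction:
    """Mean and population variance of an ensemble's predictions (nm)."""

    mean_nm: float
    variance_nm2: float
    member_values: tuple[float, ...]
    uncertainty_available: bool = True

    @classmethod
    def from_members(cls, values: Sequence[float]) -> "EnsemblePrediction":
        arr = np.asarray(values, dtype=float)
        return cls(
            mean_nm=float(arr.mean()),
            variance_nm2=float(arr.var()),  # population variance
            member_values=tuple(float(v) for v in arr),
            uncertainty_available=len(arr) > 1,
        )

    @property
    def uncertainty_nm(self) -> float:
        return float(np.sqrt(self.variance_nm2))


class MissingSolventDescriptorError(KeyError):
    """Solvent not present in the descriptor table; drop the pair
    (reason ``missing_descriptor``) or switch to a computable representation."""


class ChempropModel:
    """One dye/solvent regressor (a single ensemble member)."""

    def __init__(self, config: ModelConfig, solvent_table: SolventDescriptorTable | None = None):
        if config.solvent_mode in ("cgsd", "minnesota") and solvent_table is None:
            raise ValueError("descriptor solvent modes need a solvent_table")
        self.config = config
        self.solvent_table = solvent_table
        self.dye_encoder = DMPNNEncoder(config.dye_encoder)
        self.solvent_encoder = (
            DMPNNEncoder(config.solvent_encoder) if config.solvent_mode == "mpnn" else None
        )
        if config.solvent_mode == "mpnn":
            solv_dim = config.solvent_encoder.hidden_size
        elif config.solvent_mode == "morgan":
            solv_dim = 256
        elif config.solvent_mode == "none":
            solv_dim = 0
        else:
            solv_dim = solvent_table.dim
        self.solv_dim = solv_dim
        n_in = config.dye_encoder.hidden_size + solv_dim + config.n_extra_features
        self.ffn = FFNN(n_in, config.ffn_hidden, config.ffn_layers, 1, seed=config.seed + 2)
        # standardization statistics (set by fit)
        self.t_mean, self.t_std = 0.0, 1.0
        self.s_mean = np.zeros(solv_dim)
        self.s_std = np.ones(solv_dim)
        self.x_mean = np.zeros(config.n_extra_features)
        self.x_std = np.ones(config.n_extra_features)

    # --- representation plumbing -------------------------------------------------
    def _solvent_matrix(self, solvents: Sequence[str]) -> np.ndarray:
        mode = self.config.solvent_mode
        rows = []
        for s in solvents:
            if mode == "morgan":
                rows.append(morgan_fingerprint(s).bits.astype(float))
            else:
                vec = self.solvent_table.lookup(s)
                if vec is None:
                    raise MissingSolventDescriptorError(
                        f"no {self.solvent_table.scheme} descriptors for solvent "
                        f"{s!r}; drop this pair (missing_descriptor)"
                    )
                rows.append(vec)
        return np.asarray(rows, dtype=float)

    def _all_params(self) -> list[np.ndarray]:
        params = list(self.dye_encoder.weights)
        if self.solvent_encoder is not None:
            params += self.solvent_encoder.weights
        params += self.ffn.weights
        return params

    def _forward(self, dyes, solvents, extra_std, training=False, rngs=None):
        batch_d = BatchMolGraph([_graph(s) for s in dyes])
        emb_d, cache_d = self.dye_encoder.forward(
            batch_d, training=training, rng=rngs[0] if rngs else None
        )
        parts = [emb_d]
        cache_s = batch_s = None
        if self.config.solvent_mode == "mpnn":
            batch_s = BatchMolGraph([_graph(s) for s in solvents])
            emb_s, cache_s = self.solvent_encoder.forward(
                batch_s, training=training, rng=rngs[1] if rngs else None
            )
            parts.append(emb_s)
        elif self.config.solvent_mode != "none":
            S = (self._solvent_matrix(solvents) - self.s_mean) / self.s_std
            parts.append(S)
        if extra_std is not None and extra_std.shape[1]:
            parts.append(extra_std)
        x = np.concatenate(parts, axis=1)
        out, cache_f = self.ffn.forward(x)
        return out[:, 0], (cache_d, cache_s, cache_f)

    def _backward(self, caches, d_out: np.ndarray) -> list[np.ndarray]:
        cache_d, cache_s, cache_f = caches
        ffn_grads, d_x = self.ffn.backward(cache_f, d_out[:, None])
        h_d = self.config.dye_encoder.hidden_size
        grads = list(self.dye_encoder.backward(cache_d, d_x[:, :h_d]))
        if self.solvent_encoder is not None:
            h_s = self.config.solvent_encoder.hidden_size
            grads += self.solvent_encoder.backward(cache_s, d_x[:, h_d : h_d + h_s])
        grads += ffn_grads
        return grads

    # --- training ----------------------------------------------------------------
    def fit(
        self,
        dyes: Sequence[str],
        solvents: Sequence[str],
        targets: np.ndarray,
        train_idx: np.ndarray,
        valid_idx: np.ndarray,
        extra: np.ndarray | None = None,
    ) -> list[dict]:
        cfg = self.config
        targets = np.asarray(targets, dtype=float)
        tr = np.asarray(train_idx, dtype=int)
        va = np.asarray(valid_idx, dtype=int)
        if len(tr) == 0:
            raise ValueError("empty training fold")
        self.t_mean = float(targets[tr].mean())
        self.t_std = float(targets[tr].std())
        if self.t_std < _EPS:
            self.t_std = 1.0
        if cfg.solvent_mode in ("morgan", "cgsd", "minnesota"):
            S = self._solvent_matrix([solvents[i] for i in tr])
            self.s_mean = S.mean(axis=0)
            self.s_std = np.where(S.std(axis=0) < _EPS, 1.0, S.std(axis=0))
        if extra is not None:
            extra = np.asarray(extra, dtype=float)
            if extra.ndim == 1:
                extra = extra[:, None]
            self.x_mean = extra[tr].mean(axis=0)
            xs = extra[tr].std(axis=0)
            self.x_std = np.where(xs < _EPS, 1.0, xs)
            extra_std = (extra - self.x_mean) / self.x_std
        else:
            extra_std = None

        tz = (targets - self.t_mean) / self.t_std
        params = self._all_params()
        opt = Adam(params)
        rng_shuffle = np.random.default_rng(cfg.seed + 1001)
        rngs = (
            np.random.default_rng(cfg.seed + 2001),
            np.random.default_rng(cfg.seed + 3001),
        )
        n_batches = max(1, int(np.ceil(len(tr) / cfg.batch_size)))
        log: list[dict] = []
        best_mae = np.inf
        best_weights = [p.copy() for p in params]
        step = 0

        def eval_mae(idx):
            if len(idx) == 0:
                return float("nan")
            preds = self._predict_std(dyes, solvents, extra_std, idx)
            return float(np.mean(np.abs(preds - tz[idx]))) * self.t_std

        for epoch in range(cfg.epochs):
            perm = rng_shuffle.permutation(tr)
            losses = []
            for b in range(n_batches):
                idx = perm[b * cfg.batch_size : (b + 1) * cfg.batch_size]
                if len(idx) == 0:
                    continue
                ex = extra_std[idx] if extra_std is not None else None
                pred, caches = self._forward(
                    [dyes[i] for i in idx],
                    [solvents[i] for i in idx],
                    ex,
                    training=True,
                    rngs=rngs,
                )
                err = pred - tz[idx]
                losses.append(float(np.mean(err**2)))
                grads = self._backward(caches, 2.0 * err / len(idx))
                lr = lr_schedule(
                    step,
                    n_batches,
                    cfg.epochs,
                    cfg.warmup_epochs,
                    cfg.init_lr,
                    cfg.max_lr,
                    cfg.final_lr,
                )
                opt.step(grads, lr)
                step += 1
            val_mae = eval_mae(va)
            log.append(
                {
                    "epoch": epoch,
                    "train_loss": float(np.mean(losses)) if losses else float("nan"),
                    "valid_mae": val_mae,
                }
            )
            if np.isfinite(val_mae) and val_mae < best_mae:
                best_mae = val_mae
                best_weights = [p.copy() for p in params]
        if cfg.epochs > 0 and np.isfinite(best_mae):
            for p, w in zip(params, best_weights):
                p[...] = w
        if cfg.epochs == 0:
            log.append({"epoch": -1, "train_loss": float("nan"), "valid_mae": eval_mae(va)})
        return log

    def _predict_std(self, dyes, solvents, extra_std, idx, chunk=512):
        out = np.empty(len(idx))
        idx = np.asarray(idx, dtype=int)
        for s in range(0, len(idx), chunk):
            sel = idx[s : s + chunk]
            ex = extra_std[sel] if extra_std is not None else None
            out[s : s + len(sel)], _ = self._forward(
                [dyes[i] for i in sel], [solvents[i] for i in sel], ex
            )
        return out

    def predict(
        self,
        dyes: Sequence[str],
        solvents: Sequence[str] | None = None,
        extra: np.ndarray | None = None,
    ) -> np.ndarray:
        """Predict in the model's target units (inference mode, deterministic)."""
        if solvents is None:
            solvents = [""] * len(dyes)
        if extra is not None:
            extra = np.asarray(extra, dtype=float)
            if extra.ndim == 1:
                extra = extra[:, None]
            extra = (extra - self.x_mean) / self.x_std
        idx = np.arange(len(dyes))
        z = self._predict_std(list(dyes), list(solvents), extra, idx)
        return z * self.t_std + self.t_mean

    def embed_dye(self, smiles: str) -> np.ndarray:
        """Dye encoder output (pre-head), e.g. for UMAP/t-SNE export."""
        emb, _ = self.dye_encoder.forward(BatchMolGraph([_graph(smiles)]))
        return emb[0]


def extract_embedding(model: ChempropModel, dye_smiles: str) -> np.ndarray:
    return model.embed_dye(dye_smiles)


# --- checkpointing ------------------------------------------------------------

def save_model(model: ChempropModel, path: str) -> None:
    """Serialize one model to a single-file checkpoint (npz payload with an
    embedded JSON header carrying the configuration and seed)."""
    from dataclasses import asdict

    from .mpnn import save_checkpoint

    cfg = model.config
    meta = {
        "config": {
            **{
                k: v
                for k, v in asdict(cfg).items()
                if k not in ("dye_encoder", "solvent_encoder")
            },
            "dye_encoder": asdict(cfg.dye_encoder),
            "solvent_encoder": asdict(cfg.solvent_encoder)
            if cfg.solvent_encoder is not None
            else None,
        },
        "scheme": model.solvent_table.scheme if model.solvent_table else None,
        "solvent_keys": sorted(model.solvent_table.entries)
        if model.solvent_table
        else None,
    }
    arrays = {
        "t_stats": np.array([model.t_mean, model.t_std]),
        "s_mean": model.s_mean,
        "s_std": model.s_std,
        "x_mean": model.x_mean,
        "x_std": model.x_std,
    }
    for i, w in enumerate(model.dye_encoder.weights):
        arrays[f"dye_{i}"] = w
    if model.solvent_encoder is not None:
        for i, w in enumerate(model.solvent_encoder.weights):
            arrays[f"solv_{i}"] = w
    for i, w in enumerate(model.ffn.weights):
        arrays[f"ffn_{i}"] = w
    if model.solvent_table is not None:
        arrays["solvent_matrix"] = np.stack(
            [model.solvent_table.entries[k] for k in meta["solvent_keys"]]
        )
    save_checkpoint(path, arrays, meta)


def load_model(path: str) -> ChempropModel:
    from .featurize import SolventDescriptorTable
    from .mpnn import load_checkpoint

    arrays, meta = load_checkpoint(path)
    cfg_d = dict(meta["config"])
    cfg_d["dye_encoder"] = EncoderParams(**cfg_d["dye_encoder"])
    if cfg_d.get("solvent_encoder"):
        cfg_d["solvent_encoder"] = EncoderParams(**cfg_d["solvent_encoder"])
    else:
        cfg_d["solvent_encoder"] = None
    cfg = ModelConfig(**cfg_d)
    table = None
    if meta.get("scheme"):
        table = SolventDescriptorTable(
            scheme=meta["scheme"],
            entries={
                k: arrays["solvent_matrix"][i]
                for i, k in enumerate(meta["solvent_keys"])
            },
        )
    model = ChempropModel(cfg, solvent_table=table)
    model.dye_encoder.set_weights(
        [arrays[f"dye_{i}"] for i in range(len(model.dye_encoder.weights))]
    )
    if model.solvent_encoder is not None:
        model.solvent_encoder.set_weights(
            [arrays[f"solv_{i}"] for i in range(len(model.solvent_encoder.weights))]
        )
    model.ffn.set_weights(
        [arrays[f"ffn_{i}"] for i in range(len(model.ffn.weights))]
    )
    model.t_mean, model.t_std = map(float, arrays["t_stats"])
    model.s_mean, model.s_std = arrays["s_mean"], arrays["s_std"]
    model.x_mean, model.x_std = arrays["x_mean"], arrays["x_std"]
    return model


def save_ensemble(
    models: Sequence[ChempropModel],
    run_dir: str,
    aux: AuxModel | None = None,
    logs: Sequence[Sequence[dict]] | None = None,
) -> None:
    """Write an ensemble (plus optional frozen aux model and training logs)
    into a run directory."""
    import json
    import os

    os.makedirs(run_dir, exist_ok=True)
    for i, m in enumerate(models):
        save_model(m, os.path.join(run_dir, f"member_{i}.npz"))
    if aux is not None:
        save_model(aux.model, os.path.join(run_dir, "aux.npz"))
    manifest = {"n_members": len(models), "has_aux": aux is not None}
    with open(os.path.join(run_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    if logs is not None:
        with open(os.path.join(run_dir, "training_log.jsonl"), "w") as fh:
            for i, log in enumerate(logs):
                for entry in log:
                    fh.write(json.dumps({"member": i, **entry}) + "\n")


def load_ensemble(run_dir: str) -> tuple[list[ChempropModel], AuxModel | None]:
    import json
    import os

    with open(os.path.join(run_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    models = [
        load_model(os.path.join(run_dir, f"member_{i}.npz"))
        for i in range(manifest["n_members"])
    ]
    aux = None
    if manifest["has_aux"]:
        aux = AuxModel(load_model(os.path.join(run_dir, "aux.npz")))
    return models, aux


def forward_single(model: ChempropModel, dye_smiles: str, solvent_input: str) -> float:
    """Single prediction from one trained (or initialised) model."""
    return float(model.predict([dye_smiles], [solvent_input])[0])


class AuxModel:
    """Frozen dye-only surrogate regressor (predicts the low-fidelity
    vertical excitation energy, eV, from structure alone)."""

    def __init__(self, model: ChempropModel):
        if model.config.solvent_mode != "none":
            raise ValueError("aux model must be dye-only (solvent_mode='none')")
        self.model = model

    def predict_dye(self, dyes: Sequence[str]) -> np.ndarray:
        return self.model.predict(list(dyes))


def forward_multifidelity(
    aux: AuxModel, model: ChempropModel, dye_smiles: str, solvent_input: str
) -> float:
    """Prediction with the frozen surrogate's scalar injected as an extra
    feature. The same dye gives the same aux scalar in every solvent."""
    extra = aux.predict_dye([dye_smiles])
    return float(model.predict([dye_smiles], [solvent_input], extra=extra)[0])


def _targets_from_records(records: Sequence[SpectralRecord], units: str) -> np.ndarray:
    lam = np.array([r.lambda_max_nm for r in records], dtype=float)
    return nm_to_ev(lam) if units == "ev" else lam


def train(
    records: Sequence[SpectralRecord],
    split: SplitAssignment,
    config: ModelConfig,
    solvent_table: SolventDescriptorTable | None = None,
    aux_model: AuxModel | None = None,
    extra_features: np.ndarray | None = None,
) -> tuple[list[ChempropModel], list[list[dict]]]:
    """Train an ensemble on the split's train fold, selecting each member's
    best epoch by validation MAE. Member ``i`` is seeded ``config.seed + i``.

    If ``aux_model`` is given the ensemble is trained multi-fidelity style:
    the frozen surrogate's per-dye prediction becomes an extra standardized
    input feature. ``extra_features`` allows injecting arbitrary
    per-record extra inputs instead (used for equivalence checks).
    """
    dyes = [r.dye_smiles for r in records]
    solvents = [r.solvent_smiles for r in records]
    targets = _targets_from_records(records, config.target_units)
    tr = np.asarray(split.indices("train"), dtype=int)
    va = np.asarray(split.indices("valid"), dtype=int)
    if len(tr) == 0:
        raise ValueError("empty training fold")
    if aux_model is not None and extra_features is not None:
        raise ValueError("pass aux_model or extra_features, not both")
    extra = extra_features
    if aux_model is not None:
        extra = aux_model.predict_dye(dyes)
    if extra is not None:
        extra = np.asarray(extra, dtype=float)
        if extra.ndim == 1:
            extra = extra[:, None]
        if config.n_extra_features != extra.shape[1]:
            config = copy.deepcopy(config)
            config.n_extra_features = extra.shape[1]
    models: list[ChempropModel] = []
    logs: list[list[dict]] = []
    for i in range(config.ensemble_size):
        member_cfg = config.with_seed(config.seed + i)
        model = ChempropModel(member_cfg, solvent_table=solvent_table)
        logs.append(model.fit(dyes, solvents, targets, tr, va, extra=extra))
        models.append(model)
    return models, logs


def train_aux(
    records: Sequence[SpectralRecord],
    config: ModelConfig | None = None,
    valid_fraction: float = 0.1,
) -> tuple[AuxModel, list[dict]]:
    """Train the dye-only surrogate on every record carrying a low-fidelity
    value (eV), under its own random split for epoch selection.

    The surrogate is deliberately trained on the full low-fidelity table --
    computed values exist for all dyes regardless of which experimental fold
    they later occupy, exactly as a cheap physics code could be run on any
    candidate structure.
    """
    cfg = copy.deepcopy(config) if config is not None else ModelConfig()
    cfg.solvent_mode = "none"
    cfg.target_units = "ev"
    cfg.ensemble_size = 1
    cfg.n_extra_features = 0
    cfg.__post_init__()
    usable = [(r.dye_smiles, r.low_fidelity_ev) for r in records if r.low_fidelity_ev is not None]
    if not usable:
        raise ValueError("no records carry a low-fidelity value")
    # one value per unique dye (the surrogate is solvent-independent)
    seen: dict[str, float] = {}
    for smi, v in usable:
        seen.setdefault(canonicalize_smiles(smi), v)
    dyes = list(seen.keys())
    targets = np.array([seen[d] for d in dyes])
    rng = np.random.default_rng(cfg.seed + 7001)
    perm = rng.permutation(len(dyes))
    n_valid = max(1, int(round(valid_fraction * len(dyes))))
    va, tr = perm[:n_valid], perm[n_valid:]
    model = ChempropModel(cfg)
    log = model.fit(dyes, [""] * len(dyes), targets, tr, va)
    return AuxModel(model), log


def predict_ensemble(
    models: Sequence[ChempropModel],
    dyes: Sequence[str],
    solvents: Sequence[str],
    aux_model: AuxModel | None = None,
) -> list[EnsemblePrediction]:
    """Ensemble mean + population variance per input pair."""
    if not models:
        raise ValueError("empty ensemble")
    extra = aux_model.predict_dye(dyes) if aux_model is not None else None
    member_preds = np.stack(
        [m.predict(dyes, solvents, extra=extra) for m in models], axis=0
    )
    return [EnsemblePrediction.from_members(member_preds[:, j]) for j in range(member_preds.shape[1])]
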