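"""Leakage-aware train/validation/test splitting.

Three strategies of increasing rigor:

* ``pair`` -- uniform random split of dye--solvent pairs (assumes the
  dataset is deduplicated, so no pair can leak across folds);
* ``dye`` -- all measurements of one dye (any solvent) stay in one fold,
  removing the correlation between a dye's peaks in different solvents;
* ``scaffold`` -- all dyes sharing a Bemis--Murcko scaffold (ring systems
  plus linkers, side chains stripped) stay in one fold, probing
  generalization to unseen chemotypes.

Fractions default to 80-10-10. Whole groups are indivisible, so achieved
fold sizes can deviate from the targets by at most (largest group - 1).
For the scaffold strategy groups are assigned largest-first, which pushes
big scaffold families into training and keeps validation/test diverse.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .curation import InvalidSmilesError, SpectralRecord, canonicalize_smiles

FOLDS = ("train", "valid", "test")


@dataclass
class SplitAssignment:
    strategy: str
    fractions: tuple[float, float, float]
    folds: dict[int, str]  # record index -> fold name
    seed: int

    def indices(self, fold: str) -> list[int]:
        return sorted(i for i, f in self.folds.items() if f == fold)

    def sizes(self) -> dict[str, int]:
        return {f: len(self.indices(f)) for f in FOLDS}

    def to_json(self, path: str | None = None) -> str:
        payload = json.dumps(
            {
                "strategy": self.strategy,
                "seed": self.seed,
                "fractions": list(self.fractions),
                "folds": {f: self.indices(f) for f in FOLDS},
            },
            indent=1,
        )
        if path:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source: str) -> "SplitAssignment":
        try:
            data = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                data = json.load(fh)
        folds = {int(i): f for f in FOLDS for i in data["folds"][f]}
        return cls(
            strategy=data["strategy"],
            fractions=tuple(data["fractions"]),
            folds=folds,
            seed=int(data["seed"]),
        )


def _targets(n: int, fractions: tuple[float, float, float]) -> dict[str, int]:
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_train = int(np.floor(n * fractions[0]))
    n_test = int(np.floor(n * fractions[2]))
    return {"train": n_train, "valid": n - n_train - n_test, "test": n_test}


def bemis_murcko_scaffold(smiles: str) -> str:
    """Canonical Bemis--Murcko scaffold SMILES; empty string for acyclic
    molecules (which therefore share one scaffold group by default)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"unparsable SMILES: {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold)


def split_by_pair(
    records: Sequence[SpectralRecord],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Uniform random split of records (assumed unique dye--solvent pairs)."""
    n = len(records)
    if n < len(FOLDS):
        raise ValueError("fewer records than folds")
    tgt = _targets(n, fractions)
    perm = np.random.default_rng(seed).permutation(n)
    folds: dict[int, str] = {}
    a, b = tgt["train"], tgt["train"] + tgt["valid"]
    for pos, idx in enumerate(perm):
        folds[int(idx)] = "train" if pos < a else ("valid" if pos < b else "test")
    return SplitAssignment("pair", tuple(fractions), folds, seed)


def _group_split(
    groups: list[list[int]],
    fractions: tuple[float, float, float],
    seed: int,
    strategy: str,
    largest_first: bool,
) -> SplitAssignment:
    n = sum(len(g) for g in groups)
    if n < len(FOLDS):
        raise ValueError("fewer records than folds")
    tgt = _targets(n, fractions)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(groups))
    ordered = [groups[i] for i in order]
    if largest_first:
        ordered.sort(key=len, reverse=True)  # stable: ties keep shuffled order
    if ordered and len(ordered[0]) > tgt["train"]:
        warnings.warn(
            f"a single {strategy} group ({len(ordered[0])} records) exceeds the "
            "training-fold target; it is assigned to train"
        )
    folds: dict[int, str] = {}
    filled = {f: 0 for f in FOLDS}
    for grp in ordered:
        deficits = {f: tgt[f] - filled[f] for f in FOLDS}
        fold = max(FOLDS, key=lambda f: deficits[f])  # ties: train > valid > test
        for idx in grp:
            folds[idx] = fold
        filled[fold] += len(grp)
    return SplitAssignment(strategy, tuple(fractions), folds, seed)


def split_by_dye(
    records: Sequence[SpectralRecord],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Group records by canonical dye; whole groups are assigned to folds."""
    groups: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        groups.setdefault(canonicalize_smiles(r.dye_smiles), []).append(i)
    return _group_split(
        list(groups.values()), fractions, seed, "dye", largest_first=False
    )


def split_by_scaffold(
    records: Sequence[SpectralRecord],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Group records by the dye's Bemis--Murcko scaffold; larger scaffold
    families are assigned first (hence into training), which keeps the small
    validation/test folds maximally diverse. Solvents never constrain
    splits. All acyclic dyes share the empty-scaffold group."""
    groups: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        groups.setdefault(bemis_murcko_scaffold(r.dye_smiles), []).append(i)
    if len(groups) == 1:
        warnings.warn("all dyes share one scaffold group; everything lands in train")
    return _group_split(
        list(groups.values()), fractions, seed, "scaffold", largest_first=True
    )


def make_split(
    records: Sequence[SpectralRecord],
    strategy: str,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    fn = {"pair": split_by_pair, "dye": split_by_dye, "scaffold": split_by_scaffold}
    if strategy not in fn:
        raise ValueError(f"unknown strategy {strategy!r}")
    return fn[strategy](records, fractions, seed)
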