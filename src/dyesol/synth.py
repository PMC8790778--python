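"""Synthetic dye--solvent datasets with a known ground truth.

The generator emulates the statistical shape of a curated solvatochromism
dataset without any downloads: dye structures are built from a grammar of
aromatic scaffolds (benzene through anthracene, plus common heteroaromatics
and linked systems) decorated with small substituents (halogens, alkyl,
methoxy, nitro, cyano, ...), every structure valence-checked by RDKit at
build time.

The structure -> wavelength law is deliberately simple and learnable:

    lambda_true(dye, solvent) = base + coeff * n_aromatic_rings(dye)
                                + shift(solvent) + N(0, noise_sd)

with the aromatic-ring count as a conjugation proxy (more fused/linked
rings -> red shift, as in real chromophores at caricature scale). The
correlated low-fidelity channel mimics a vacuum excited-state calculation:

    lowfi_nm = (lambda_vac - intercept) / slope + N(0, lowfi_noise_sd)

reported in eV, where ``lambda_vac`` is the noiseless, solvent-free part of
the law. An ordinary least-squares fit of experiment against the
low-fidelity wavelength therefore recovers (slope, intercept) -- the same
affine vacuum-to-solution calibration structure seen in real TD-DFT data.

A configurable fraction of dyes is "measured" in several solvents, giving
the replicate structure that distinguishes pair, dye and scaffold splits.
Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .curation import CuratedDataset, SpectralRecord, canonicalize_smiles
from .tddft import nm_to_ev

# scaffold cores: (single-substituent template, double-substituent template)
_SCAFFOLD_TEMPLATES: list[tuple[str, str]] = [
    ("{a}c1ccccc1", "{a}c1ccc({b})cc1"),  # benzene
    ("{a}c1ccc2ccccc2c1", "{a}c1ccc2ccc({b})cc2c1"),  # naphthalene
    ("{a}c1ccc2cc3ccccc3cc2c1", "{a}c1ccc2cc3ccc({b})cc3cc2c1"),  # anthracene
    ("{a}c1ccncc1", "{a}c1cc({b})ncc1"),  # pyridine
    ("{a}c1cccs1", "{a}c1ccc({b})s1"),  # thiophene
    ("{a}c1ccco1", "{a}c1ccc({b})o1"),  # furan
    ("{a}c1ccc2[nH]ccc2c1", "{a}c1ccc2[nH]cc({b})c2c1"),  # indole
    ("{a}c1ccc2ncccc2c1", "{a}c1ccc2nc({b})ccc2c1"),  # quinoline
    ("{a}c1ccc(-c2ccccc2)cc1", "{a}c1ccc(-c2ccc({b})cc2)cc1"),  # biphenyl
    ("{a}C(=Cc1ccccc1)c1ccccc1", "{a}C(=Cc1ccccc1)c1ccc({b})cc1"),  # stilbenoid
    ("{a}c1ccc2sccc2c1", "{a}c1ccc2scc({b})c2c1"),  # benzothiophene
    ("{a}c1ccc2occc2c1", "{a}c1ccc2occ({b})c2c1"),  # benzofuran
]

# substituent fragments in two spellings: attachment atom written last for
# the prefix position ("CO" + benzene -> anisole) and first for the branch
# position inside parentheses ("(OC)")
_SUBSTITUENTS = [
    ("F", "F"),
    ("Cl", "Cl"),
    ("Br", "Br"),
    ("C", "C"),
    ("CC", "CC"),
    ("CCC", "CCC"),
    ("CC(C)", "C(C)C"),
    ("CO", "OC"),
    ("CCO", "OCC"),
    ("O=[N+]([O-])", "[N+](=O)[O-]"),
    ("N#C", "C#N"),
    ("FC(F)(F)", "C(F)(F)F"),
    ("N", "N"),
    ("CN(C)", "N(C)C"),
    ("O", "O"),
    ("S", "S"),
]

DEFAULT_SOLVENTS: tuple[tuple[str, float], ...] = (
    ("O", 30.0),
    ("CC#N", 18.0),
    ("CCO", 12.0),
    ("C1CCOC1", 8.0),
    ("Cc1ccccc1", 0.0),
)


@dataclass
class GeneratorSpec:
    """All knobs of the synthetic study, with a full parameter record kept
    alongside the generated data (the "truth")."""

    n_scaffolds: int = 10
    substituents_per_scaffold: int = 30
    solvents: tuple[tuple[str, float], ...] = DEFAULT_SOLVENTS
    base_lambda_nm: float = 300.0
    conjugation_coeff_nm: float = 60.0
    noise_sd_nm: float = 5.0
    lowfi_slope: float = 1.8
    lowfi_intercept_nm: float = -220.0
    lowfi_noise_sd_nm: float = 3.0
    replicate_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.n_scaffolds <= len(_SCAFFOLD_TEMPLATES):
            raise ValueError(
                f"n_scaffolds must be in [1, {len(_SCAFFOLD_TEMPLATES)}]"
            )
        if self.noise_sd_nm < 0 or self.lowfi_noise_sd_nm < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0.0 <= self.replicate_fraction <= 1.0:
            raise ValueError("replicate_fraction must lie in [0, 1]")
        for smi, _ in self.solvents:
            if Chem.MolFromSmiles(smi) is None:
                raise ValueError(f"invalid solvent SMILES {smi!r}")


def _build_dyes(n_scaffolds: int, per_scaffold: int) -> list[list[str]]:
    """Enumerate valence-checked dye SMILES per scaffold family:
    single-substituent variants first, then substituent pairs."""
    families: list[list[str]] = []
    for tmpl1, tmpl2 in _SCAFFOLD_TEMPLATES[:n_scaffolds]:
        seen: set[str] = set()
        dyes: list[str] = []
        candidates = [tmpl1.format(a=a) for a, _ in _SUBSTITUENTS]
        candidates += [
            tmpl2.format(a=a, b=b)
            for (a, _), (_, b) in product(_SUBSTITUENTS, _SUBSTITUENTS)
        ]
        for smi in candidates:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise ValueError(f"fragment grammar produced invalid SMILES {smi!r}")
            can = Chem.MolToSmiles(mol)
            if can not in seen:
                seen.add(can)
                dyes.append(can)
            if len(dyes) == per_scaffold:
                break
        if len(dyes) < per_scaffold:
            raise ValueError(
                f"grammar exhausted: only {len(dyes)} distinct dyes for scaffold"
            )
        families.append(dyes)
    return families


def _aromatic_rings(smiles: str) -> int:
    return rdMolDescriptors.CalcNumAromaticRings(Chem.MolFromSmiles(smiles))


def generate(spec: GeneratorSpec) -> tuple[CuratedDataset, dict]:
    """Generate a curated-format dataset plus the ground-truth record.

    Returns ``(dataset, truth)`` where ``truth`` holds the generator
    parameters and, per record, the noiseless wavelength, the noiseless
    vacuum wavelength and the solvent shift.
    """
    rng = np.random.default_rng(spec.seed)
    families = _build_dyes(spec.n_scaffolds, spec.substituents_per_scaffold)
    solvent_smiles = [canonicalize_smiles(s) for s, _ in spec.solvents]
    shifts = {s: sh for s, (_, sh) in zip(solvent_smiles, spec.solvents)}

    records: list[SpectralRecord] = []
    truth_rows: list[dict] = []
    row = 0
    for fam in families:
        for dye in fam:
            rings = _aromatic_rings(dye)
            lam_vac = spec.base_lambda_nm + spec.conjugation_coeff_nm * rings
            lowfi_nm = (lam_vac - spec.lowfi_intercept_nm) / spec.lowfi_slope
            lowfi_nm += rng.normal(0.0, spec.lowfi_noise_sd_nm) if spec.lowfi_noise_sd_nm else 0.0
            lowfi_ev = float(nm_to_ev(lowfi_nm))
            replicated = rng.random() < spec.replicate_fraction
            if replicated:
                chosen = solvent_smiles
            else:
                chosen = [solvent_smiles[rng.integers(len(solvent_smiles))]]
            for solv in chosen:
                lam = lam_vac + shifts[solv]
                if spec.noise_sd_nm:
                    lam += rng.normal(0.0, spec.noise_sd_nm)
                records.append(
                    SpectralRecord(
                        dye_smiles=dye,
                        solvent_smiles=solv,
                        lambda_max_nm=float(lam),
                        source="synthetic",
                        low_fidelity_ev=lowfi_ev,
                        row=row,
                    )
                )
                truth_rows.append(
                    {
                        "row": row,
                        "dye_smiles": dye,
                        "solvent_smiles": solv,
                        "lambda_noiseless_nm": float(lam_vac + shifts[solv]),
                        "lambda_vacuum_nm": float(lam_vac),
                        "solvent_shift_nm": float(shifts[solv]),
                        "n_aromatic_rings": rings,
                    }
                )
                row += 1
    truth = {
        "params": {
            "n_scaffolds": spec.n_scaffolds,
            "substituents_per_scaffold": spec.substituents_per_scaffold,
            "solvents": [[s, float(shifts[s])] for s in solvent_smiles],
            "base_lambda_nm": spec.base_lambda_nm,
            "conjugation_coeff_nm": spec.conjugation_coeff_nm,
            "noise_sd_nm": spec.noise_sd_nm,
            "lowfi_slope": spec.lowfi_slope,
            "lowfi_intercept_nm": spec.lowfi_intercept_nm,
            "lowfi_noise_sd_nm": spec.lowfi_noise_sd_nm,
            "replicate_fraction": spec.replicate_fraction,
            "seed": spec.seed,
        },
        "records": truth_rows,
    }
    dataset = CuratedDataset(
        records=records,
        provenance=[(r.row,) for r in records],
        drop_log=[],
    )
    return dataset, truth


def inject_duplicates(
    dataset: CuratedDataset, n_pairs: int, spread_nm: float, seed: int = 0
) -> CuratedDataset:
    """Plant duplicate measurements for ``n_pairs`` randomly chosen records:
    each chosen record is replaced by two copies at lambda +- spread/2, so a
    deduplication pass with tolerance t merges them iff spread <= t."""
    if spread_nm < 0:
        raise ValueError("spread must be non-negative")
    if n_pairs > len(dataset.records):
        raise ValueError("n_pairs exceeds dataset size")
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(len(dataset.records), size=n_pairs, replace=False).tolist())
    out: list[SpectralRecord] = []
    for i, rec in enumerate(dataset.records):
        if i in chosen:
            out.append(replace(rec, lambda_max_nm=rec.lambda_max_nm - spread_nm / 2))
            out.append(replace(rec, lambda_max_nm=rec.lambda_max_nm + spread_nm / 2))
        else:
            out.append(rec)
    return CuratedDataset(
        records=out, provenance=[(r.row,) for r in out], drop_log=[]
    )


def write_synthetic(dataset: CuratedDataset, truth: dict, csv_path: str, truth_path: str | None = None) -> None:
    """Write the generated dataset as curated-format CSV (plus the
    low-fidelity column) and optionally the truth record as JSON."""
    import json

    import pandas as pd

    df = dataset.to_frame()
    df["low_fidelity_ev"] = [r.low_fidelity_ev for r in dataset.records]
    df.to_csv(csv_path, index=False)
    if truth_path:
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=1)
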