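"""Curation of experimental absorption measurements.

Raw tables of dye UV/Vis measurements come from heterogeneous sources: dyes
are given as SMILES, solvents either as SMILES or as free-text names and
abbreviations, and the same dye--solvent pair is often measured more than
once. This module parses such tables into :class:`SpectralRecord` objects,
resolves solvent names through a user-supplied dictionary, drops structures
that do not survive RDKit sanitization or that encode multi-component
species (a ``.`` in the SMILES), and aggregates duplicate measurements: a
group of measurements for one (dye, solvent) key is merged to its arithmetic
mean when the group's spread (max - min) is within a tolerance (default
5 nm), and discarded entirely when it disagrees by more than that.

Every dropped row is logged with a reason drawn from a fixed enumeration so
that curation is fully auditable: ``invalid_smiles``, ``multi_component``,
``duplicate_conflict``, ``missing_field``, ``missing_descriptor``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

DROP_REASONS = frozenset(
    {
        "invalid_smiles",
        "multi_component",
        "duplicate_conflict",
        "missing_field",
        "missing_descriptor",
    }
)

#: default column names expected in input tables
DEFAULT_COLUMNS = {
    "smiles": "smiles",
    "solvent": "solvent",
    "wavelength": "peak_wavelength_nm",
    "source": "source",
}


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed and sanitized."""


@dataclass(frozen=True)
class SpectralRecord:
    """One absorption measurement of a dye in a solvent.

    ``lambda_max_nm`` is the peak wavelength of maximum absorption in nm.
    ``low_fidelity_ev`` optionally carries a cheap computed surrogate for the
    transition (a vacuum vertical excitation energy, eV).
    ``row`` is the 0-based row index in the originating table (-1 if none).
    """

    dye_smiles: str
    solvent_smiles: str
    lambda_max_nm: float
    source: str
    low_fidelity_ev: float | None = None
    row: int = -1


@dataclass
class CuratedDataset:
    """Deduplicated measurement set plus a full audit trail.

    ``provenance[i]`` lists the original row indices merged into
    ``records[i]``; ``drop_log`` is a list of ``(row, reason)`` pairs.
    """

    records: list[SpectralRecord]
    provenance: list[tuple[int, ...]] = field(default_factory=list)
    drop_log: list[tuple[int, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dye_smiles": [r.dye_smiles for r in self.records],
                "solvent_smiles": [r.solvent_smiles for r in self.records],
                "lambda_max_nm": [r.lambda_max_nm for r in self.records],
                "source": [r.source for r in self.records],
            }
        )


def canonicalize_smiles(smiles: str) -> str:
    """Return RDKit's canonical form; raise :class:`InvalidSmilesError` if the
    string does not parse and sanitize (valence check included)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def _is_valid_smiles(smiles: str) -> bool:
    return Chem.MolFromSmiles(smiles) is not None


def load_name_map(path_or_frame) -> dict[str, str]:
    """Load a solvent name -> SMILES dictionary from a two-column CSV
    (``name,smiles``). Keys are lowercased and stripped."""
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame
    else:
        df = pd.read_csv(path_or_frame)
    cols = list(df.columns)
    return {
        str(n).strip().lower(): str(s)
        for n, s in zip(df[cols[0]], df[cols[1]])
    }


def parse_records(
    table: pd.DataFrame | str,
    name_map: Mapping[str, str] | None = None,
    columns: Mapping[str, str] | None = None,
) -> tuple[list[SpectralRecord], list[tuple[int, str]]]:
    """Parse a raw measurement table into records.

    The solvent column may hold SMILES or names/abbreviations; names are
    resolved through ``name_map`` (case-insensitive, whitespace-stripped).
    Rows with an unmappable solvent, a missing field, or a non-positive
    wavelength are dropped with reason ``missing_field``. Structure validity
    is *not* checked here -- that is :func:`filter_structures`' job.
    """
    if isinstance(table, str):
        try:
            table = pd.read_csv(table)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ValueError(f"malformed input file: {exc}") from exc
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    # accept the canonical curated header as an alias for the raw one
    aliases = {
        "smiles": ["dye_smiles"],
        "solvent": ["solvent_smiles"],
        "wavelength": ["lambda_max_nm"],
        "source": [],
    }
    for role in ("smiles", "solvent", "wavelength", "source"):
        if cols[role] not in table.columns:
            alt = next((a for a in aliases[role] if a in table.columns), None)
            if alt is None:
                raise KeyError(
                    f"missing mandatory column {cols[role]!r} (role: {role})"
                )
            cols[role] = alt
    if "low_fidelity" not in cols and "low_fidelity_ev" in table.columns:
        cols["low_fidelity"] = "low_fidelity_ev"

    records: list[SpectralRecord] = []
    drops: list[tuple[int, str]] = []
    lowfi_col = cols.get("low_fidelity")
    for i, row in enumerate(table.itertuples(index=False)):
        row = row._asdict()
        dye = row[cols["smiles"]]
        solvent = row[cols["solvent"]]
        wav = row[cols["wavelength"]]
        source = row[cols["source"]]
        if any(
            v is None or (isinstance(v, float) and math.isnan(v)) or str(v) == ""
            for v in (dye, solvent, wav, source)
        ):
            drops.append((i, "missing_field"))
            continue
        try:
            lam = float(wav)
        except (TypeError, ValueError):
            drops.append((i, "missing_field"))
            continue
        if not math.isfinite(lam) or lam <= 0:
            drops.append((i, "missing_field"))
            continue
        solvent = str(solvent).strip()
        key = solvent.lower()
        if name_map is not None and key in name_map:
            solvent_smiles = name_map[key]
        elif _is_valid_smiles(solvent):
            solvent_smiles = solvent
        else:
            drops.append((i, "missing_field"))
            continue
        lowfi = None
        if lowfi_col and lowfi_col in row:
            v = row[lowfi_col]
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                lowfi = float(v)
        records.append(
            SpectralRecord(
                dye_smiles=str(dye).strip(),
                solvent_smiles=solvent_smiles,
                lambda_max_nm=lam,
                source=str(source),
                low_fidelity_ev=lowfi,
                row=i,
            )
        )
    return records, drops


def filter_structures(
    records: Sequence[SpectralRecord],
) -> tuple[list[SpectralRecord], list[tuple[int, str]]]:
    """Drop records whose dye or solvent is multi-component (contains ``.``)
    or fails RDKit parsing/sanitization; canonicalize survivors' SMILES."""
    kept: list[SpectralRecord] = []
    drops: list[tuple[int, str]] = []
    for rec in records:
        if "." in rec.dye_smiles or "." in rec.solvent_smiles:
            drops.append((rec.row, "multi_component"))
            continue
        try:
            dye = canonicalize_smiles(rec.dye_smiles)
            solv = canonicalize_smiles(rec.solvent_smiles)
        except InvalidSmilesError:
            drops.append((rec.row, "invalid_smiles"))
            continue
        kept.append(replace(rec, dye_smiles=dye, solvent_smiles=solv))
    return kept, drops


def _merge_groups(
    groups: dict,
    tolerance_nm: float,
) -> tuple[list[SpectralRecord], list[tuple[int, str]], list[tuple[int, ...]]]:
    merged: list[SpectralRecord] = []
    drops: list[tuple[int, str]] = []
    provenance: list[tuple[int, ...]] = []
    for recs in groups.values():
        lams = [r.lambda_max_nm for r in recs]
        rows = tuple(r.row for r in recs)
        if len(recs) == 1:
            merged.append(recs[0])
            provenance.append(rows)
        elif max(lams) - min(lams) <= tolerance_nm:
            lowfis = [r.low_fidelity_ev for r in recs if r.low_fidelity_ev is not None]
            merged.append(
                replace(
                    recs[0],
                    lambda_max_nm=sum(lams) / len(lams),
                    low_fidelity_ev=sum(lowfis) / len(lowfis) if lowfis else None,
                )
            )
            provenance.append(rows)
        else:
            drops.extend((r.row, "duplicate_conflict") for r in recs)
    return merged, drops, provenance


def deduplicate(
    records: Sequence[SpectralRecord],
    tolerance_nm: float = 5.0,
) -> tuple[list[SpectralRecord], list[tuple[int, str]], list[tuple[int, ...]]]:
    """Aggregate duplicate (dye, solvent) measurements.

    The rule is applied twice with the same tolerance: first within each
    source, then across sources on the merged survivors. A group whose
    spread (max - min) is <= ``tolerance_nm`` collapses to its unweighted
    arithmetic mean; otherwise the whole group is dropped with reason
    ``duplicate_conflict``. Records are assumed structure-filtered, i.e.
    SMILES already canonical. Idempotent.
    """
    # within-source pass
    by_src: dict[tuple[str, str, str], list[SpectralRecord]] = {}
    for rec in records:
        by_src.setdefault(
            (rec.source, rec.dye_smiles, rec.solvent_smiles), []
        ).append(rec)
    stage1, drops1, prov1 = _merge_groups(by_src, tolerance_nm)

    # cross-source pass on the per-source representatives
    prov_of = {id(r): p for r, p in zip(stage1, prov1)}
    by_pair: dict[tuple[str, str], list[SpectralRecord]] = {}
    for rec in stage1:
        by_pair.setdefault((rec.dye_smiles, rec.solvent_smiles), []).append(rec)
    out: list[SpectralRecord] = []
    drops = list(drops1)
    provenance: list[tuple[int, ...]] = []
    for recs in by_pair.values():
        lams = [r.lambda_max_nm for r in recs]
        rows = tuple(i for r in recs for i in prov_of[id(r)])
        if len(recs) == 1:
            out.append(recs[0])
            provenance.append(rows)
        elif max(lams) - min(lams) <= tolerance_nm:
            lowfis = [r.low_fidelity_ev for r in recs if r.low_fidelity_ev is not None]
            srcs = sorted({r.source for r in recs})
            out.append(
                replace(
                    recs[0],
                    lambda_max_nm=sum(lams) / len(lams),
                    low_fidelity_ev=sum(lowfis) / len(lowfis) if lowfis else None,
                    source="+".join(srcs),
                )
            )
            provenance.append(rows)
        else:
            for r in recs:
                drops.extend((i, "duplicate_conflict") for i in prov_of[id(r)])
    return out, drops, provenance


def curate(
    table: pd.DataFrame | str,
    name_map: Mapping[str, str] | None = None,
    tolerance_nm: float = 5.0,
    columns: Mapping[str, str] | None = None,
) -> CuratedDataset:
    """Full curation pipeline: parse -> structure filter -> deduplicate."""
    parsed, d1 = parse_records(table, name_map=name_map, columns=columns)
    filtered, d2 = filter_structures(parsed)
    deduped, d3, provenance = deduplicate(filtered, tolerance_nm=tolerance_nm)
    return CuratedDataset(
        records=deduped, provenance=provenance, drop_log=d1 + d2 + d3
    )


def write_curated(dataset: CuratedDataset, path: str, log_path: str | None = None) -> None:
    """Write the canonical curated CSV (fixed header) and optionally the drop log."""
    dataset.to_frame().to_csv(path, index=False)
    if log_path:
        pd.DataFrame(dataset.drop_log, columns=["row", "reason"]).to_csv(
            log_path, index=False
        )


def read_curated(path: str) -> list[SpectralRecord]:
    """Read a curated CSV back into records (inverse of :func:`write_curated`).

    A ``low_fidelity_ev`` column is honoured if present.
    """
    df = pd.read_csv(path)
    has_lowfi = "low_fidelity_ev" in df.columns
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        lowfi = None
        if has_lowfi:
            v = getattr(row, "low_fidelity_ev")
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                lowfi = float(v)
        records.append(
            SpectralRecord(
                dye_smiles=row.dye_smiles,
                solvent_smiles=row.solvent_smiles,
                lambda_max_nm=float(row.lambda_max_nm),
                source=str(row.source),
                low_fidelity_ev=lowfi,
                row=i,
            )
        )
    return records
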