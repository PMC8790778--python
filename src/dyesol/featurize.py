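"""Molecular featurization: graphs, fingerprints, solvent descriptors.

Three families of representation feed the models downstream:

* :class:`MolGraph` -- an explicit directed-bond graph with per-atom and
  per-bond feature vectors, the input to the message-passing encoder. Each
  chemical bond contributes two directed bonds; ``rev[i]`` is the index of
  the bond opposite to bond ``i``.
* Bit fingerprints -- 256-bit radius-4 Morgan fingerprints used as a fixed
  solvent representation, and the RDKit path fingerprint (default 2048 bits)
  used for dataset-similarity analyses (Tanimoto nearest neighbours).
* Tabulated solvent descriptors -- the 5-component CGSD scheme
  (E_T(30), SA, SB, SdP, SP) and the 7-component Minnesota scheme
  (n, alpha, beta, gamma, epsilon, phi, psi), looked up by canonical solvent
  SMILES. A missing entry is a value (``None``), not an exception: the
  caller drops the pair with reason ``missing_descriptor``.

Atom features: one-hot element over the organic subset (plus "other"),
one-hot degree 0-5, formal charge, aromaticity flag, one-hot total hydrogen
count 0-4. Bond features: one-hot bond order (single/double/triple/
aromatic), conjugation flag, ring-membership flag. Hydrogens are implicit.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .curation import InvalidSmilesError, canonicalize_smiles

_ELEMENTS = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "Si", "B"]
_MAX_DEGREE = 5
_MAX_H = 4

ATOM_FEATURE_DIM = len(_ELEMENTS) + 1 + (_MAX_DEGREE + 1) + 1 + 1 + (_MAX_H + 1)
BOND_FEATURE_DIM = 4 + 1 + 1

_BOND_ORDER_INDEX = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}


@dataclass
class MolGraph:
    """Directed-bond molecular graph.

    ``src[i] -> dst[i]`` is directed bond ``i``; ``rev[i]`` indexes the
    opposite direction of the same chemical bond (an involution).
    """

    atom_features: np.ndarray  # (n_atoms, ATOM_FEATURE_DIM)
    bond_features: np.ndarray  # (n_bonds, BOND_FEATURE_DIM)
    src: np.ndarray  # (n_bonds,) int
    dst: np.ndarray  # (n_bonds,) int
    rev: np.ndarray  # (n_bonds,) int

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.bond_features.shape[0]


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    v = np.zeros(ATOM_FEATURE_DIM)
    sym = atom.GetSymbol()
    idx = _ELEMENTS.index(sym) if sym in _ELEMENTS else len(_ELEMENTS)
    v[idx] = 1.0
    off = len(_ELEMENTS) + 1
    v[off + min(atom.GetDegree(), _MAX_DEGREE)] = 1.0
    off += _MAX_DEGREE + 1
    v[off] = float(atom.GetFormalCharge())
    v[off + 1] = 1.0 if atom.GetIsAromatic() else 0.0
    off += 2
    v[off + min(atom.GetTotalNumHs(), _MAX_H)] = 1.0
    return v


def _bond_features(bond: Chem.Bond) -> np.ndarray:
    v = np.zeros(BOND_FEATURE_DIM)
    v[_BOND_ORDER_INDEX.get(bond.GetBondType(), 0)] = 1.0
    v[4] = 1.0 if bond.GetIsConjugated() else 0.0
    v[5] = 1.0 if bond.IsInRing() else 0.0
    return v


def mol_to_graph(smiles: str) -> MolGraph:
    """Build a :class:`MolGraph` from SMILES (canonicalized first, so the
    graph is deterministic for any spelling of the same molecule)."""
    mol = Chem.MolFromSmiles(canonicalize_smiles(smiles))
    n_atoms = mol.GetNumAtoms()
    atom_feats = np.array([_atom_features(a) for a in mol.GetAtoms()]).reshape(
        n_atoms, ATOM_FEATURE_DIM
    )
    src, dst, bond_feats, rev = [], [], [], []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = _bond_features(bond)
        i = len(src)
        src.extend([u, v])
        dst.extend([v, u])
        bond_feats.extend([f, f])
        rev.extend([i + 1, i])
    return MolGraph(
        atom_features=atom_feats,
        bond_features=np.array(bond_feats).reshape(len(src), BOND_FEATURE_DIM),
        src=np.array(src, dtype=np.int64),
        dst=np.array(dst, dtype=np.int64),
        rev=np.array(rev, dtype=np.int64),
    )


@dataclass(frozen=True)
class BitFingerprint:
    bits: np.ndarray  # uint8 0/1 vector
    nbits: int
    radius: int

    def popcount(self) -> int:
        return int(self.bits.sum())


def morgan_fingerprint(smiles: str, radius: int = 4, nbits: int = 256) -> BitFingerprint:
    """Binary Morgan (ECFP-style) fingerprint; default radius 4, 256 bits."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    arr = np.zeros(nbits, dtype=np.uint8)
    fp = gen.GetFingerprint(mol)
    for b in fp.GetOnBits():
        arr[b] = 1
    return BitFingerprint(bits=arr, nbits=nbits, radius=radius)


def rdkit_fingerprint(smiles: str, nbits: int = 2048) -> BitFingerprint:
    """RDKit path-based (Daylight-like) fingerprint, used for the
    dataset-similarity (nearest-neighbour Tanimoto) analysis."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=nbits)
    arr = np.zeros(nbits, dtype=np.uint8)
    for b in gen.GetFingerprint(mol).GetOnBits():
        arr[b] = 1
    return BitFingerprint(bits=arr, nbits=nbits, radius=-1)


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Jaccard similarity of two bit vectors; defined as 1.0 when both are
    empty (two identical null objects)."""
    if a.nbits != b.nbits:
        raise ValueError("fingerprint lengths differ")
    inter = int(np.sum(a.bits & b.bits))
    union = int(np.sum(a.bits | b.bits))
    if union == 0:
        return 1.0
    return inter / union


def _fp_matrix(fps: Sequence[BitFingerprint]) -> np.ndarray:
    return np.stack([f.bits for f in fps]).astype(np.float64)


def nearest_neighbor_similarity(
    query_fps: Sequence[BitFingerprint],
    reference_fps: Sequence[BitFingerprint] | None = None,
) -> tuple[np.ndarray, float]:
    """Per-query max Tanimoto over the references, plus the mean.

    With ``reference_fps=None`` the comparison is within the query set and
    self-matches are excluded (a singleton set is an error). Vectorized:
    intersection = A B^T, union = |a| + |b| - intersection.
    """
    within = reference_fps is None
    if len(query_fps) == 0 or (not within and len(reference_fps) == 0):
        raise ValueError("empty molecule set")
    if within and len(query_fps) < 2:
        raise ValueError("within-set mode needs at least two molecules")
    A = _fp_matrix(query_fps)
    B = A if within else _fp_matrix(reference_fps)
    if A.shape[1] != B.shape[1]:
        raise ValueError("fingerprint lengths differ")
    inter = A @ B.T
    pa = A.sum(axis=1)[:, None]
    pb = B.sum(axis=1)[None, :]
    union = pa + pb - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
    if within:
        np.fill_diagonal(sim, -np.inf)
    best = sim.max(axis=1)
    return best, float(best.mean())


CGSD_COLUMNS = ["et30", "sa", "sb", "sdp", "sp"]
MINNESOTA_COLUMNS = ["n", "alpha", "beta", "gamma", "epsilon", "phi", "psi"]


@dataclass
class SolventDescriptorTable:
    """Canonical-SMILES-keyed table of empirical solvent descriptors."""

    scheme: str  # "cgsd" | "minnesota"
    entries: dict[str, np.ndarray]

    @property
    def dim(self) -> int:
        return 5 if self.scheme == "cgsd" else 7

    def lookup(self, smiles: str) -> np.ndarray | None:
        """Descriptor vector for the solvent, or ``None`` if not tabulated
        (the caller must then drop the pair, reason ``missing_descriptor``)."""
        try:
            key = canonicalize_smiles(smiles)
        except InvalidSmilesError:
            return None
        return self.entries.get(key)


def load_descriptor_table(source, scheme: str) -> SolventDescriptorTable:
    """Load a descriptor CSV (``solvent_smiles`` + scheme columns).

    ``source`` may be a path, a DataFrame, or ``None`` to load the packaged
    example table (approximate literature values for a dozen common
    solvents, intended for tests and demonstration)."""
    scheme = scheme.lower()
    cols = {"cgsd": CGSD_COLUMNS, "minnesota": MINNESOTA_COLUMNS}[scheme]
    if source is None:
        ref = resources.files("dyesol.data") / f"{scheme}.csv"
        df = pd.read_csv(ref)
    elif isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"{scheme} table missing columns: {missing}")
    entries = {}
    for row in df.itertuples(index=False):
        vec = np.array([float(getattr(row, c)) for c in cols])
        if not np.all(np.isfinite(vec)):
            raise ValueError(f"incomplete descriptor entry for {row.solvent_smiles}")
        entries[canonicalize_smiles(row.solvent_smiles)] = vec
    return SolventDescriptorTable(scheme=scheme, entries=entries)


def lookup_solvent(smiles: str, table: SolventDescriptorTable) -> np.ndarray | None:
    """Convenience wrapper around :meth:`SolventDescriptorTable.lookup`."""
    return table.lookup(smiles)


def export_fingerprints(
    smiles_list: Sequence[str],
    path: str,
    kind: str = "morgan",
    **kwargs,
) -> pd.DataFrame:
    """Write fingerprints as a CSV of bitstrings (``smiles,bits``)."""
    fn = {"morgan": morgan_fingerprint, "rdkit": rdkit_fingerprint}[kind]
    rows = [
        {"smiles": s, "bits": "".join(map(str, fn(s, **kwargs).bits.tolist()))}
        for s in smiles_list
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
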