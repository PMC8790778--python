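"""Regression metrics, uncertainty diagnostics, similarity-binned errors.

Accuracy is summarised as MAE, RMSE and R^2 (all in nm for wavelength
targets). The usefulness of the ensemble-variance uncertainty estimate is
probed with the Spearman rank correlation between sqrt(ensemble variance)
and absolute error -- a perfectly informative uncertainty would rank errors
exactly (rho = 1). Error is also stratified by how similar each test dye is
to its nearest training-set neighbour (Tanimoto over path fingerprints),
binned in steps of 0.1: under a leakage-free split the largest errors
should concentrate in the low-similarity bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .featurize import BitFingerprint, nearest_neighbor_similarity, rdkit_fingerprint
from .models import EnsemblePrediction


@dataclass(frozen=True)
class MetricsReport:
    mae: float
    rmse: float
    r2: float | None
    n: int


@dataclass(frozen=True)
class UncertaintyReport:
    spearman_rho: float | None
    pairs: tuple[tuple[float, float], ...]  # (sqrt variance, abs error)


@dataclass(frozen=True)
class SimilarityBin:
    lo: float
    hi: float
    count: int
    max_abs_error: float | None
    mean_abs_error: float | None


def compute_metrics(y_true, y_pred) -> MetricsReport:
    """MAE, RMSE and R^2 = 1 - SSE/SST. R^2 is ``None`` (undefined) when the
    truth has zero variance."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between truth and predictions")
    if y_true.size == 0:
        raise ValueError("no points to score")
    err = y_pred - y_true
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = None if sst == 0.0 else float(1.0 - np.sum(err**2) / sst)
    return MetricsReport(mae=mae, rmse=rmse, r2=r2, n=len(y_true))


def spearman_uncertainty(
    preds: Sequence[EnsemblePrediction], y_true
) -> UncertaintyReport:
    """Rank correlation between ensemble spread and realised error
    (average-rank ties). ``None`` when either vector is constant."""
    y_true = np.asarray(y_true, dtype=float)
    if len(preds) != len(y_true):
        raise ValueError("length mismatch")
    if len(preds) < 3:
        raise ValueError("need at least 3 points")
    unc = np.array([p.uncertainty_nm for p in preds])
    err = np.abs(np.array([p.mean_nm for p in preds]) - y_true)
    if np.ptp(unc) == 0 or np.ptp(err) == 0:
        rho = None
    else:
        rho = float(stats.spearmanr(unc, err).statistic)
        if math.isnan(rho):  # pragma: no cover - defensive
            rho = None
    return UncertaintyReport(
        spearman_rho=rho, pairs=tuple(zip(unc.tolist(), err.tolist()))
    )


def similarity_binned_errors(
    test_smiles: Sequence[str],
    train_smiles: Sequence[str],
    abs_errors,
    bin_width: float = 0.1,
    fingerprints: Sequence[BitFingerprint] | None = None,
    train_fingerprints: Sequence[BitFingerprint] | None = None,
) -> list[SimilarityBin]:
    """Bin test-set absolute errors by nearest-training-neighbour Tanimoto.

    Bins are half-open ``[a, a + w)`` except the last, which is closed so a
    similarity of exactly 1.0 (test molecule present in train) is counted.
    """
    if len(train_smiles) == 0:
        raise ValueError("empty training set")
    abs_errors = np.asarray(abs_errors, dtype=float)
    if len(abs_errors) != len(test_smiles):
        raise ValueError("length mismatch")
    if fingerprints is None:
        fingerprints = [rdkit_fingerprint(s) for s in test_smiles]
    if train_fingerprints is None:
        train_fingerprints = [rdkit_fingerprint(s) for s in train_smiles]
    best, _ = nearest_neighbor_similarity(fingerprints, train_fingerprints)
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    bins: list[SimilarityBin] = []
    for k in range(len(edges) - 1):
        lo, hi = float(edges[k]), float(edges[k + 1])
        last = k == len(edges) - 2
        mask = (best >= lo) & ((best <= hi) if last else (best < hi))
        sel = abs_errors[mask]
        bins.append(
            SimilarityBin(
                lo=lo,
                hi=hi,
                count=int(mask.sum()),
                max_abs_error=float(sel.max()) if len(sel) else None,
                mean_abs_error=float(sel.mean()) if len(sel) else None,
            )
        )
    return bins


def cv_summary(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error (sample SD / sqrt(k)) over cross-validation
    folds, the convention used to report repeated-split results."""
    arr = np.asarray(values, dtype=float)
    if len(arr) < 2:
        return float(arr.mean()), 0.0
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(len(arr)))
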