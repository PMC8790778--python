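"""Peak selection from computed excitation spectra and linear calibration.

A quantum-chemistry excited-state calculation yields a ladder of vertical
excitation energies with oscillator strengths. The reference "peak" state is
chosen by three rules: (1) if no state falls inside the visible window
(default 1-4 eV), take the lowest-energy state; (2) if exactly one state is
in the window, take it; (3) if several are, take the one with the largest
oscillator strength.

Computed vacuum energies systematically deviate from solution-phase
experiment; an ordinary-least-squares line fitted in wavelength space
(experimental nm vs computed nm) quantifies and removes the systematic part
of that error. The calibration object reports the raw MAE (identity mapping)
and the regression-adjusted MAE on the fitted data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

#: hc in eV*nm (CODATA), the photon energy-wavelength conversion constant
PLANCK_EVNM = 1239.84193


@dataclass(frozen=True)
class ExcitationState:
    energy_ev: float
    oscillator_strength: float

    def __post_init__(self):
        if self.energy_ev <= 0:
            raise ValueError("excitation energy must be positive")
        if self.oscillator_strength < 0:
            raise ValueError("oscillator strength must be non-negative")


@dataclass(frozen=True)
class ExcitationSpectrum:
    """Non-empty list of excited states, stored sorted ascending by energy."""

    states: tuple[ExcitationState, ...]

    def __init__(self, states: Iterable[ExcitationState]):
        states = tuple(sorted(states, key=lambda s: s.energy_ev))
        if not states:
            raise ValueError("spectrum must contain at least one state")
        object.__setattr__(self, "states", states)


@dataclass(frozen=True)
class LinearCalibration:
    """y = slope * x + intercept fitted by OLS, with MAE before/after."""

    slope: float
    intercept: float
    mae_raw: float
    mae_reg: float

    def apply(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def ev_to_nm(energy_ev: float):
    """Convert photon energy (eV) to wavelength (nm)."""
    e = np.asarray(energy_ev, dtype=float)
    if np.any(e <= 0):
        raise ValueError("energy must be positive")
    out = PLANCK_EVNM / e
    return float(out) if out.ndim == 0 else out


def nm_to_ev(wavelength_nm: float):
    """Convert wavelength (nm) to photon energy (eV)."""
    l = np.asarray(wavelength_nm, dtype=float)
    if np.any(l <= 0):
        raise ValueError("wavelength must be positive")
    out = PLANCK_EVNM / l
    return float(out) if out.ndim == 0 else out


def select_peak(
    spectrum: ExcitationSpectrum,
    window_ev: tuple[float, float] = (1.0, 4.0),
) -> ExcitationState:
    """Pick the reference excited state.

    Rule precedence: no state in the window -> lowest energy; one state in
    the window -> that state; several -> highest oscillator strength, ties
    broken by lower energy (states are pre-sorted ascending in energy so the
    first maximum wins).
    """
    lo, hi = window_ev
    in_window = [s for s in spectrum.states if lo <= s.energy_ev <= hi]
    if not in_window:
        return spectrum.states[0]
    if len(in_window) == 1:
        return in_window[0]
    return max(in_window, key=lambda s: s.oscillator_strength)


def select_peak_bruteforce(
    states: Sequence[ExcitationState],
    window_ev: tuple[float, float] = (1.0, 4.0),
) -> ExcitationState:
    """Literal re-statement of the three rules by exhaustive scan; oracle for
    property tests, independent of :class:`ExcitationSpectrum` sorting."""
    lo, hi = window_ev
    inside = [s for s in states if lo <= s.energy_ev <= hi]
    if len(inside) == 0:
        best = states[0]
        for s in states:
            if s.energy_ev < best.energy_ev:
                best = s
        return best
    if len(inside) == 1:
        return inside[0]
    best = inside[0]
    for s in inside:
        if s.oscillator_strength > best.oscillator_strength or (
            s.oscillator_strength == best.oscillator_strength
            and s.energy_ev < best.energy_ev
        ):
            best = s
    return best


def fit_linear_calibration(pairs: Sequence[tuple[float, float]]) -> LinearCalibration:
    """OLS fit of experimental vs computed wavelength (both nm).

    ``pairs`` holds (x = computed, y = experimental). Raises on fewer than
    two pairs or degenerate (constant) x.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
        raise ValueError("need at least two (x, y) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all x values identical")
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    mae_raw = float(np.mean(np.abs(y - x)))
    mae_reg = float(np.mean(np.abs(y - (slope * x + intercept))))
    return LinearCalibration(slope=slope, intercept=intercept, mae_raw=mae_raw, mae_reg=mae_reg)


def pick_peaks_table(df, window_ev: tuple[float, float] = (1.0, 4.0)):
    """Apply :func:`select_peak` per molecule to a long-format excited-state
    table with columns ``molecule_id, state, energy_ev, osc_strength``;
    returns a frame ``molecule_id, peak_energy_ev, peak_osc_strength,
    peak_lambda_nm``."""
    import pandas as pd

    rows = []
    for mol_id, grp in df.groupby("molecule_id", sort=False):
        spec = ExcitationSpectrum(
            ExcitationState(float(e), float(f))
            for e, f in zip(grp["energy_ev"], grp["osc_strength"])
        )
        peak = select_peak(spec, window_ev)
        rows.append(
            {
                "molecule_id": mol_id,
                "peak_energy_ev": peak.energy_ev,
                "peak_osc_strength": peak.oscillator_strength,
                "peak_lambda_nm": ev_to_nm(peak.energy_ev),
            }
        )
    return pd.DataFrame(rows)
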