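"""Interpretive quantities: encounter-rate ratio, phage burden, Ct differences,
and one-at-a-time parameter sensitivity sweeps.

The encounter-rate ratio compares the instantaneous conjugation flux
``gamma(r) n_D n_R`` with the infection flux ``beta(r) n_D n_P``. The donor
density and the shared hyperbolic resource factor cancel, leaving

    (gamma_max / beta_max) * (n_R / n_P),

so the competition between plasmid transfer and phage capture of a donor is
set entirely by the rate-constant ratio and the recipient:phage abundance
ratio at mixing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import KineticParameters
from .qpcr import DEFAULT_CALIBRATION, CtCalibration, abundance_to_ct, marker_abundance
from .simulate import ExperimentCondition, Trajectory, integrate

__all__ = [
    "RatioReport",
    "conjugation_infection_ratio",
    "phages_per_cell",
    "CtDifferenceSeries",
    "ct_difference_series",
    "saturation_summary",
    "sensitivity_sweep",
]


@dataclass(frozen=True)
class RatioReport:
    """Conjugation-to-infection encounter-rate ratio and its two factors."""

    gamma_over_beta: float
    nR_over_nP: float
    rate_ratio: float
    gamma_max: float
    beta_max: float
    n_R: float
    n_P: float


def conjugation_infection_ratio(gamma_max: float, beta_max: float,
                                n_R: float, n_P: float) -> RatioReport:
    """Ratio of conjugation rate to phage infection rate at given densities.

    Donor density cancels between the two bilinear fluxes, as does the shared
    hyperbolic resource dependence.
    """
    if beta_max <= 0:
        raise ValueError("beta_max must be > 0")
    if n_P <= 0:
        raise ValueError("n_P must be > 0")
    gob = gamma_max / beta_max
    pop = n_R / n_P
    return RatioReport(gamma_over_beta=gob, nR_over_nP=pop, rate_ratio=gob * pop,
                       gamma_max=gamma_max, beta_max=beta_max, n_R=n_R, n_P=n_P)


def phages_per_cell(traj: Trajectory, t: float) -> float:
    """Free phage per cell, n_P(t) / total_cells(t), at a sampled time.

    Returns NaN (undefined) when no cells are present at ``t``.
    """
    state = traj.state_at(t)
    total = state.total_cells()
    if total <= 0:
        return float("nan")
    return state.n_P / total


@dataclass
class CtDifferenceSeries:
    """Per-time Ct(locus_a) - Ct(locus_b); censored points are omitted."""

    locus_a: str
    locus_b: str
    times: np.ndarray
    delta_ct: np.ndarray
    n_censored: int


def ct_difference_series(traj: Trajectory, locus_a: str, locus_b: str,
                         calib: CtCalibration = DEFAULT_CALIBRATION) -> CtDifferenceSeries:
    """Ideal-Ct difference between two loci along a trajectory.

    Equals log2(N_b / N_a) at each time; with a shared calibration the
    reference constants cancel exactly. Points where either locus is censored
    (zero abundance) are omitted and counted.
    """
    ct_a = abundance_to_ct(marker_abundance(traj, locus_a).abundance, calib)
    ct_b = abundance_to_ct(marker_abundance(traj, locus_b).abundance, calib)
    delta = ct_a - ct_b
    ok = np.isfinite(delta)
    return CtDifferenceSeries(locus_a=locus_a, locus_b=locus_b,
                              times=traj.times[ok], delta_ct=delta[ok],
                              n_censored=int((~ok).sum()))


def saturation_summary(traj: Trajectory) -> dict:
    """Operational saturation report for a trajectory.

    ``t_end`` is the last sampling time (the operational "saturation" point);
    ``t_growth_stopped`` is the first sample time at which the total-cell
    growth rate falls below 1e-3 * psi_max * K per minute (NaN if never).
    """
    total = traj.total_cells()
    rate = np.gradient(total, traj.times)
    thresh = 1e-3 * traj.params.psi_max * traj.params.K
    below = np.nonzero(rate < thresh)[0]
    # ignore the initial lag: look for the first drop *after* the rate peak
    peak = int(np.argmax(rate))
    below = below[below >= peak]
    return {
        "t_end": float(traj.times[-1]),
        "t_growth_stopped": float(traj.times[below[0]]) if below.size else float("nan"),
    }


def _initial_log_slope(times: np.ndarray, abundance: np.ndarray,
                       window: float = 100.0) -> float:
    """Least-squares slope of log10 abundance over the first ``window`` minutes."""
    mask = (times <= window) & (abundance > 0)
    if mask.sum() < 2:
        return float("nan")
    return float(np.polyfit(times[mask], np.log10(abundance[mask]), 1)[0])


def _time_to_half_saturation(times: np.ndarray, abundance: np.ndarray) -> float:
    """First (interpolated) time the curve reaches half its final value."""
    half = abundance[-1] / 2.0
    above = np.nonzero(abundance >= half)[0]
    if above.size == 0:
        return float("nan")
    i = above[0]
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    a0, a1 = abundance[i - 1], abundance[i]
    return float(t0 + (half - a0) / (a1 - a0) * (t1 - t0))


def sensitivity_sweep(param_name: str, multipliers, condition: ExperimentCondition,
                      params: KineticParameters, locus: str,
                      system: str = "full", slope_window: float = 100.0) -> pd.DataFrame:
    """One-at-a-time sweep of a parameter, summarising one locus's curve.

    For each multiplier, the condition is re-simulated at the scaled parameter
    and two summaries of the locus curve are reported: the initial log10 slope
    (first ``slope_window`` minutes) and the time to half of the final value.
    """
    base = getattr(params, param_name)
    multipliers = np.asarray(multipliers, dtype=float)
    if np.any(multipliers <= 0):
        raise ValueError("multipliers must be > 0")
    rows = []
    for m in multipliers:
        p = params.replace(**{param_name: base * m})
        traj = integrate(condition, p, system=system)
        ab = marker_abundance(traj, locus).abundance
        rows.append({
            "param": param_name,
            "multiplier": float(m),
            "value": base * float(m),
            "initial_log_slope": _initial_log_slope(traj.times, ab, slope_window),
            "t_half_saturation": _time_to_half_saturation(traj.times, ab),
            "final_abundance": float(ab[-1]),
        })
    return pd.DataFrame(rows)
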