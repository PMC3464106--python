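"""Staged least-squares calibration of the conjugation/infection model.

The full model has too many free parameters to fit at once, so calibration is
staged: each stage uses the experimental condition in which only a subset of
parameters is identifiable, fixes everything established earlier, and fits the
new subset by pooled least squares on log10 abundance (equivalently, linearly
in ideal Ct — one qPCR cycle is one factor of 2):

1. **growth** (pure-donor culture, conjugation-only system): ``psi_max``, ``e``
2. **conjugation** (donor:recipient ratio series): ``gamma_max``
3. **infection** (COND2A + COND2B phage series, infection-only system):
   ``beta_max``, ``psiP_max``, ``P_psi``
4. **competition** (COND3 mixtures plus phage, full system): ``P_gamma``

Stages are exposed statsmodels-style: a ``*StageModel`` is constructed from
data (a list of :class:`Experiment`), ``fit()`` returns a
:class:`StageFitResults` carrying estimates, residual diagnostics and a
``summary()`` table; :class:`StagedCalibration` threads the stages together.

Optimisation is trust-region least squares (`scipy.optimize.least_squares`)
over log10-transformed parameters within documented bounds, multi-started from
five points (the initial guess plus four log-spaced quantiles of the bound
box) with best-residual selection. Zero or censored abundances are excluded
from the residuals, never log-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .kinetics import KineticParameters
from .qpcr import (
    DEFAULT_CALIBRATION,
    CtCalibration,
    MarkerSeries,
    marker_abundance,
)
from .simulate import ExperimentCondition, IntegrationError, integrate

__all__ = [
    "PARAMETER_BOUNDS",
    "STAGE_ORDER",
    "Experiment",
    "StageFitResults",
    "CalibrationResults",
    "GrowthStageModel",
    "ConjugationStageModel",
    "InfectionStageModel",
    "CompetitionStageModel",
    "StagedCalibration",
    "fit_growth",
    "fit_conjugation",
    "fit_infection",
    "fit_competition",
    "run_full_calibration",
]

#: fitting bounds (natural scale); optimisation runs in log10 space
PARAMETER_BOUNDS = {
    "psi_max": (1e-4, 1.0),
    "e": (1e-10, 1e-5),
    "gamma_max": (1e-14, 1e-7),
    "beta_max": (1e-15, 1e-8),
    "psiP_max": (1e-2, 1e2),
    "P_psi": (1e-4, 1.0),
    "P_gamma": (1e-4, 1.0),
}

STAGE_ORDER = ("growth", "conjugation", "infection", "competition")

_LOG_FLOOR = 1e-30  # model abundance floor before log10 (keeps residuals finite)


@dataclass
class Experiment:
    """One flask: its inoculation condition plus the measured marker series."""

    condition: ExperimentCondition
    series: list[MarkerSeries]

    def loci(self) -> set[str]:
        return {s.locus for s in self.series}


@dataclass
class StageFitResults:
    """Estimates and diagnostics from one calibration stage.

    Attributes
    ----------
    estimates : dict
        Fitted parameter values (natural scale, model units).
    fixed : dict
        Parameters held constant during this stage.
    residual_norm : float
        Sum of squared log10-abundance residuals at the optimum.
    converged : bool
        Optimizer termination status; a failed stage is reported, never
        silently accepted.
    diagnostics : dict
        Iteration counts, termination reason, identifiability warnings,
        at-bound flags and the decreasing trace of accepted objective values.
    """

    stage: str
    estimates: dict
    fixed: dict
    residual_norm: float
    n_observations: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)
    params: KineticParameters | None = None

    def summary(self) -> str:
        lines = [f"Stage: {self.stage}",
                 f"  converged: {self.converged}"
                 f"   n_obs: {self.n_observations}"
                 f"   SSR(log10): {self.residual_norm:.6g}"]
        lines.append("  estimates:")
        for k, v in self.estimates.items():
            lo, hi = PARAMETER_BOUNDS[k]
            lines.append(f"    {k:<10} = {v:.6g}   (bounds [{lo:g}, {hi:g}])")
        if self.diagnostics.get("warnings"):
            for w in self.diagnostics["warnings"]:
                lines.append(f"  warning: {w}")
        lines.append(f"  termination: {self.diagnostics.get('termination', '?')}"
                     f" after {self.diagnostics.get('nfev', '?')} evaluations")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "estimates": self.estimates,
            "fixed": self.fixed,
            "residual_norm": self.residual_norm,
            "n_observations": self.n_observations,
            "converged": self.converged,
            "diagnostics": {k: v for k, v in self.diagnostics.items()
                            if k != "objective_trace"},
        }


class _StageModel:
    """Shared machinery: pooled log10-abundance residuals and multi-start TRF."""

    stage: str = ""
    free: tuple = ()
    loci: tuple = ()
    system: str = "full"

    def __init__(self, experiments: list[Experiment],
                 params0: KineticParameters | None = None,
                 calib: CtCalibration = DEFAULT_CALIBRATION,
                 rtol: float = 1e-8, atol: float = 1e-2):
        if not experiments:
            raise ValueError(f"{self.stage} stage needs at least one experiment")
        self.experiments = list(experiments)
        self.params0 = params0 or KineticParameters()
        self.calib = calib
        self.rtol = rtol
        self.atol = atol
        self._data = self._prepare_data()
        self._check_data()

    # -- data ---------------------------------------------------------------
    def _prepare_data(self):
        prepared = []
        for exp in self.experiments:
            per_locus = []
            for s in exp.series:
                if s.locus not in self.loci:
                    continue
                ab = s.get_abundance(self.calib)
                mask = np.isfinite(ab) & (ab > 0)
                if mask.sum() == 0:
                    continue
                per_locus.append((s.locus, s.times[mask], np.log10(ab[mask])))
            if per_locus:
                t_eval = np.unique(np.concatenate([t for _, t, _ in per_locus]))
                prepared.append((exp.condition, t_eval, per_locus))
        if not prepared:
            raise ValueError(
                f"{self.stage} stage: no usable observations at loci {self.loci}")
        return prepared

    def _check_data(self):
        """Stage-specific identifiability checks; collected into warnings."""
        self._warnings: list[str] = []

    # -- objective ----------------------------------------------------------
    def _params_at(self, theta_log: np.ndarray) -> KineticParameters:
        return self.params0.replace(
            **{name: 10.0 ** v for name, v in zip(self.free, theta_log)})

    def _residuals(self, theta_log: np.ndarray) -> np.ndarray:
        p = self._params_at(theta_log)
        res = []
        for condition, t_eval, per_locus in self._data:
            try:
                traj = integrate(condition, p, system=self.system,
                                 rtol=self.rtol, atol=self.atol, t_eval=t_eval)
            except IntegrationError:
                # a parameter vector the solver cannot handle is simply a bad fit
                return np.full(self._n_obs(), 1e3)
            for locus, times, log_obs in per_locus:
                model = marker_abundance(traj, locus).abundance
                pos = np.searchsorted(t_eval, times)
                res.append(np.log10(np.clip(model[pos], _LOG_FLOOR, None)) - log_obs)
        return np.concatenate(res)

    def _n_obs(self) -> int:
        return sum(t.size for _, _, per_locus in self._data for _, t, _ in per_locus)

    # -- fitting ------------------------------------------------------------
    def _starts(self, n_starts: int) -> list[np.ndarray]:
        lo = np.array([np.log10(PARAMETER_BOUNDS[f][0]) for f in self.free])
        hi = np.array([np.log10(PARAMETER_BOUNDS[f][1]) for f in self.free])
        x0 = np.array([np.log10(np.clip(getattr(self.params0, f),
                                        PARAMETER_BOUNDS[f][0],
                                        PARAMETER_BOUNDS[f][1]))
                       for f in self.free])
        starts = [x0]
        for q in np.linspace(0.125, 0.875, n_starts - 1):
            starts.append(lo + q * (hi - lo))
        return starts

    def fit(self, n_starts: int = 5, max_nfev: int = 500,
            ftol: float = 1e-10) -> StageFitResults:
        """Multi-start bounded least squares over the stage's free parameters."""
        lo = np.array([np.log10(PARAMETER_BOUNDS[f][0]) for f in self.free])
        hi = np.array([np.log10(PARAMETER_BOUNDS[f][1]) for f in self.free])

        trace: list[float] = []

        def residuals(theta):
            r = self._residuals(theta)
            cost = float(r @ r)
            if not trace or cost < trace[-1]:
                trace.append(cost)
            return r

        best = None
        total_nfev = 0
        for x0 in self._starts(n_starts):
            sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                ftol=ftol, xtol=1e-12, gtol=1e-12,
                                max_nfev=max_nfev)
            total_nfev += sol.nfev
            if best is None or sol.cost < best.cost:
                best = sol

        theta = best.x
        estimates = {name: 10.0 ** v for name, v in zip(self.free, theta)}
        at_bound = [name for name, v, l, h in zip(self.free, theta, lo, hi)
                    if v - l < 1e-6 or h - v < 1e-6]
        warnings = list(self._warnings)
        if at_bound:
            warnings.append(f"estimate(s) at a bound: {at_bound}")
        fitted_params = self._params_at(theta)
        diagnostics = {
            "termination": best.message,
            "status": int(best.status),
            "nfev": total_nfev,
            "n_starts": n_starts,
            "at_bound": at_bound,
            "warnings": warnings,
            "objective_trace": trace,
        }
        fixed = {k: v for k, v in self.params0.to_dict().items()
                 if k not in self.free}
        return StageFitResults(
            stage=self.stage, estimates=estimates, fixed=fixed,
            residual_norm=2.0 * float(best.cost),  # scipy cost is 0.5*SSR
            n_observations=self._n_obs(),
            converged=bool(best.success),
            diagnostics=diagnostics, params=fitted_params)


class GrowthStageModel(_StageModel):
    """Fit ``psi_max`` and ``e`` to the tolC curve of a pure-donor culture.

    The early log-slope pins the maximum growth rate; the saturation plateau
    (final density ~ r0/e for r0/e below the carrying capacity) pins the
    resource consumed per division.
    """

    stage = "growth"
    free = ("psi_max", "e")
    loci = ("tolC",)
    system = "conjugation_only"

    def _check_data(self):
        super()._check_data()
        for exp in self.experiments:
            if exp.condition.initial_state.n_R > 0:
                raise ValueError("growth stage requires donor-only cultures "
                                 f"(condition {exp.condition.label} has recipients)")


class ConjugationStageModel(_StageModel):
    """Fit ``gamma_max`` jointly to tolC+traI across donor:recipient ratios."""

    stage = "conjugation"
    free = ("gamma_max",)
    loci = ("tolC", "traI")
    system = "conjugation_only"

    def _check_data(self):
        super()._check_data()
        if len(self._data) < 2:
            self._warnings.append(
                "insufficient identifiability: fewer than 2 ratio datasets")
        if all(exp.condition.initial_state.n_R == 0 for exp in self.experiments):
            self._warnings.append(
                "gamma_max unidentifiable: no recipients in any dataset "
                "(traI == tolC carries no transfer signal)")


class InfectionStageModel(_StageModel):
    """Fit ``beta_max``, ``psiP_max`` and ``P_psi`` jointly to tolC+M13 series
    from the two phage-infection experiment families (COND2A and COND2B)."""

    stage = "infection"
    free = ("beta_max", "psiP_max", "P_psi")
    loci = ("tolC", "M13")
    system = "infection_only"

    def _check_data(self):
        super()._check_data()
        if all(exp.condition.initial_state.n_P == 0 for exp in self.experiments):
            self._warnings.append(
                "beta_max unidentifiable: all datasets are phage-free")


class CompetitionStageModel(_StageModel):
    """Fit the conjugation penalty ``P_gamma`` on the full three-marker system."""

    stage = "competition"
    free = ("P_gamma",)
    loci = ("tolC", "traI", "M13")
    system = "full"


_STAGE_CLASSES = {
    "growth": GrowthStageModel,
    "conjugation": ConjugationStageModel,
    "infection": InfectionStageModel,
    "competition": CompetitionStageModel,
}


@dataclass
class CalibrationResults:
    """Ordered stage results plus the consolidated parameter set."""

    stage_results: dict
    params: KineticParameters
    missing_stages: list = field(default_factory=list)
    aborted_at: str | None = None

    @property
    def converged(self) -> bool:
        return self.aborted_at is None and all(
            r.converged for r in self.stage_results.values())

    def parameter_table(self) -> pd.DataFrame:
        """Consolidated table of every model parameter and its provenance."""
        fitted_in = {}
        for stage, res in self.stage_results.items():
            for name in res.estimates:
                fitted_in[name] = stage
        rows = []
        for name, value in self.params.to_dict().items():
            rows.append({"parameter": name, "value": value,
                         "source": fitted_in.get(name, "fixed")})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        parts = ["Staged calibration"]
        for stage in STAGE_ORDER:
            if stage in self.stage_results:
                parts.append(self.stage_results[stage].summary())
            elif stage in self.missing_stages:
                parts.append(f"Stage: {stage}\n  absent: no data supplied")
            elif self.aborted_at is not None:
                parts.append(f"Stage: {stage}\n  skipped: aborted at {self.aborted_at}")
        parts.append("Consolidated parameters:\n"
                     + self.parameter_table().to_string(index=False))
        return "\n".join(parts)

    def simulate(self, condition: ExperimentCondition, system: str = "full"):
        """Forward-simulate a condition at the calibrated parameter set."""
        return integrate(condition, self.params, system=system)

    def to_dict(self) -> dict:
        return {
            "stages": {k: v.to_dict() for k, v in self.stage_results.items()},
            "missing_stages": self.missing_stages,
            "aborted_at": self.aborted_at,
            "parameters": self.params.to_dict(),
        }


class StagedCalibration:
    """Run the four stages in order, threading each stage's estimates forward.

    ``bundle`` maps stage name -> list of :class:`Experiment`. A missing stage
    is reported as absent and skipped; a non-convergent stage aborts all
    downstream stages (their parameters would inherit a bad fix).
    """

    def __init__(self, bundle: dict, params0: KineticParameters | None = None,
                 calib: CtCalibration = DEFAULT_CALIBRATION):
        unknown = set(bundle) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stage(s) in bundle: {sorted(unknown)}")
        self.bundle = bundle
        self.params0 = params0 or KineticParameters()
        self.calib = calib

    def fit(self, n_starts: int = 5, max_nfev: int = 500) -> CalibrationResults:
        params = self.params0
        results: dict[str, StageFitResults] = {}
        missing: list[str] = []
        aborted_at = None
        for stage in STAGE_ORDER:
            exps = self.bundle.get(stage)
            if not exps:
                missing.append(stage)
                continue
            model = _STAGE_CLASSES[stage](exps, params0=params, calib=self.calib)
            res = model.fit(n_starts=n_starts, max_nfev=max_nfev)
            results[stage] = res
            if not res.converged:
                aborted_at = stage
                break
            params = res.params
        return CalibrationResults(stage_results=results, params=params,
                                  missing_stages=missing, aborted_at=aborted_at)


# -- functional wrappers ----------------------------------------------------

def fit_growth(experiments, params0=None, **kw) -> StageFitResults:
    return GrowthStageModel(experiments, params0=params0).fit(**kw)


def fit_conjugation(experiments, params0=None, **kw) -> StageFitResults:
    return ConjugationStageModel(experiments, params0=params0).fit(**kw)


def fit_infection(experiments, params0=None, **kw) -> StageFitResults:
    return InfectionStageModel(experiments, params0=params0).fit(**kw)


def fit_competition(experiments, params0=None, **kw) -> StageFitResults:
    return CompetitionStageModel(experiments, params0=params0).fit(**kw)


def run_full_calibration(bundle, params0=None, **kw) -> CalibrationResults:
    return StagedCalibration(bundle, params0=params0).fit(**kw)
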