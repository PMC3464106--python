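"""Batch-culture integration and the five experimental inoculation presets.

The presets translate the bench protocol (volumes pipetted from saturated
overnight cultures and phage stocks into 50 mL of fresh broth) into initial
densities, taking the saturated culture density to be the cell carrying
capacity K = 3e9 cells/mL and the phage stock titer to be 1e11 phages/mL:

* ``COND1``  — conjugation only: donor/recipient mixtures at a total of
  1e6 cells/mL, D:R ratios 1:0, 1:1, 1:10, 1:100, 1:1000.
* ``COND2A`` — infection, variable cells: phage fixed at 1e7/mL, donors at
  3e7 * 10^{0,-1,-2} cells/mL.
* ``COND2B`` — infection, variable phage: donors fixed at 3e6 cells/mL,
  phage at 1e8 * 10^{0..-4}/mL.
* ``COND2C`` — pre-infected overnight culture diluted into fresh broth:
  producers n_I = 1.2e7 * 10^{0,-1,-2} cells/mL with free phage
  n_P = 1.6e9 * 10^{0,-1,-2}/mL (the saturated ratio K_P/K is preserved).
* ``COND3``  — competition: the COND1 mixtures plus phage at 1e7/mL at t=0.

All presets start with a fresh resource pool r0 = 100 a.u. The simulation
clock starts at inoculation (phage-inoculation time for COND2/COND3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import io
import math

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from .kinetics import (
    CONJUGATION_ONLY_FIELDS,
    INFECTION_ONLY_FIELDS,
    STATE_FIELDS,
    KineticParameters,
    PopulationState,
    _rhs_array,
    params_vector,
)

__all__ = [
    "SYSTEMS",
    "ExperimentCondition",
    "Trajectory",
    "IntegrationError",
    "integrate",
    "euler_oracle",
    "preset_condition",
    "preset_variants",
    "trajectory_deviation",
]

#: named ODE systems -> indices of the retained coordinates in STATE_FIELDS
SYSTEMS = {
    "full": tuple(range(9)),
    "conjugation_only": tuple(STATE_FIELDS.index(f) for f in CONJUGATION_ONLY_FIELDS),
    "infection_only": tuple(STATE_FIELDS.index(f) for f in INFECTION_ONLY_FIELDS),
}

DEFAULT_R0 = 100.0          # initial resource, a.u.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-2         # cells (or phages) per mL

PRESET_LABELS = ("COND1", "COND2A", "COND2B", "COND2C", "COND3")

#: donor:recipient mixing ratios used by COND1 and COND3
MIX_RATIOS = (0, 1, 10, 100, 1000)


class IntegrationError(RuntimeError):
    pass


@dataclass
class ExperimentCondition:
    """Inoculation densities, initial resource and sampling schedule for one flask."""

    label: str
    initial_state: PopulationState
    duration: float = 700.0          # min
    sampling_interval: float = 20.0  # min
    variant: object = None           # preset dilution/ratio index, informational

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")
        self.initial_state.validate()

    def sampling_times(self) -> np.ndarray:
        n = int(math.floor(self.duration / self.sampling_interval + 1e-9))
        return np.arange(n + 1) * self.sampling_interval

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "variant": self.variant,
            "duration": self.duration,
            "sampling_interval": self.sampling_interval,
            "initial_state": {f: getattr(self.initial_state, f) for f in STATE_FIELDS},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentCondition":
        return cls(
            label=d["label"],
            initial_state=PopulationState(**d["initial_state"]),
            duration=float(d["duration"]),
            sampling_interval=float(d["sampling_interval"]),
            variant=d.get("variant"),
        )


@dataclass
class Trajectory:
    """Time grid plus the population state at each sample time.

    ``y`` is an (n_times, 9) array in STATE_FIELDS order, clamped to >= 0.
    """

    times: np.ndarray
    y: np.ndarray
    params: KineticParameters
    condition: ExperimentCondition | None = None
    system: str = "full"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (self.times.size, len(STATE_FIELDS)):
            raise ValueError("trajectory shape mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def states(self) -> list[PopulationState]:
        return [PopulationState.from_array(row) for row in self.y]

    def column(self, name: str) -> np.ndarray:
        return self.y[:, STATE_FIELDS.index(name)]

    def total_cells(self) -> np.ndarray:
        return self.y[:, 1:8].sum(axis=1)

    def state_at(self, t: float) -> PopulationState:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-6:
            raise KeyError(f"time {t} not on the sampling grid")
        return PopulationState.from_array(self.y[i])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(STATE_FIELDS))
        df.insert(0, "time_min", self.times)
        return df

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, params: KineticParameters | None = None) -> "Trajectory":
        df = pd.read_csv(path, sep="\t")
        return cls(times=df["time_min"].to_numpy(),
                   y=df[list(STATE_FIELDS)].to_numpy(),
                   params=params or KineticParameters())


def _clamp(times, y, atol, system):
    """Clamp tiny negative overshoots to zero; reject genuinely negative runs."""
    floor = -1e6 * atol
    if y.min() < floor:
        i, j = np.unravel_index(np.argmin(y), y.shape)
        raise IntegrationError(
            f"state {STATE_FIELDS[j]} fell to {y[i, j]:.3g} at t={times[i]:g} min "
            f"(below the overshoot floor {floor:.3g})")
    return np.clip(y, 0.0, None)


def integrate(condition: ExperimentCondition,
              params: KineticParameters,
              system: str = "full",
              rtol: float = DEFAULT_RTOL,
              atol: float = DEFAULT_ATOL,
              t_eval: np.ndarray | None = None) -> Trajectory:
    """Integrate one flask with an adaptive stiff-capable solver (LSODA).

    States are reported on the condition's sampling grid (or ``t_eval``).
    Eliminated coordinates of a reduced system must be zero initially and are
    held at exactly zero throughout.
    """
    if system not in SYSTEMS:
        raise ValueError(f"unknown system {system!r}; choose from {sorted(SYSTEMS)}")
    idx = np.array(SYSTEMS[system])
    y0 = condition.initial_state.to_array()
    dropped = np.setdiff1d(np.arange(9), idx)
    if np.any(y0[dropped] != 0.0):
        bad = [STATE_FIELDS[i] for i in dropped if y0[i] != 0.0]
        raise ValueError(f"system {system!r} requires zero initial {bad}")

    if t_eval is None:
        t_eval = condition.sampling_times()
    t_eval = np.asarray(t_eval, dtype=float)

    pv = params_vector(params)
    if system == "full":
        def rhs(y, t):
            return _rhs_array(y, pv)
    else:
        full = np.zeros(9)

        def rhs(yr, t):
            full[idx] = yr
            return _rhs_array(full, pv)[idx]

    # LSODA: adaptive, switches to BDF automatically on stiffness
    yr, info = odeint(rhs, y0[idx], t_eval, rtol=rtol, atol=atol,
                      full_output=True, printmessg=False)
    if info["message"] != "Integration successful.":
        t_fail = float(info["tcur"][-1]) if len(info.get("tcur", [])) else t_eval[0]
        raise IntegrationError(
            f"integration of {condition.label} ({system}) failed near t={t_fail:g} min: "
            f"{info['message']}")
    y = np.zeros((t_eval.size, 9))
    y[:, idx] = yr
    y = _clamp(t_eval, y, atol, system)
    return Trajectory(times=t_eval, y=y, params=params, condition=condition,
                      system=system)


def euler_oracle(condition: ExperimentCondition,
                 params: KineticParameters,
                 system: str = "full",
                 dt: float = 0.01) -> Trajectory:
    """Fixed-step forward-Euler integration, for cross-validating `integrate`.

    Steps are chosen so each sampling interval is an integer number of steps of
    size <= dt (the effective step never exceeds the requested one).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    idx = np.array(SYSTEMS[system])
    y0 = condition.initial_state.to_array()
    times = condition.sampling_times()
    pv = params_vector(params)
    mask = np.zeros(9)
    mask[idx] = 1.0
    full = y0 * mask
    out = np.zeros((times.size, 9))
    out[0] = full
    for k in range(1, times.size):
        span = times[k] - times[k - 1]
        nsub = max(1, int(math.ceil(span / dt - 1e-12)))
        h = span / nsub
        for _ in range(nsub):
            full = full + (h * mask) * _rhs_array(full, pv)
        out[k] = full
    out = np.clip(out, 0.0, None)
    return Trajectory(times=times, y=out, params=params, condition=condition,
                      system=system)


def trajectory_deviation(a: Trajectory, b: Trajectory, floor: float = 1.0) -> float:
    """Maximum per-compartment deviation between two trajectories.

    For each compartment the deviation is max_t |a - b| divided by the
    compartment's dynamic range max_t max(|a|, |b|), floored at ``floor``
    (1 cell, phage or resource unit per mL by default). Pointwise-relative
    error is ill-posed for compartments that collapse to ~0, so deviations are
    measured against each compartment's scale, as in a mixed error norm.
    """
    if a.times.shape != b.times.shape or not np.allclose(a.times, b.times):
        raise ValueError("trajectories must share the same time grid")
    scale = np.maximum(np.max(np.abs(a.y), axis=0), np.max(np.abs(b.y), axis=0))
    scale = np.maximum(scale, floor)
    return float(np.max(np.abs(a.y - b.y).max(axis=0) / scale))


def preset_variants(label: str) -> int:
    """Number of documented variants (ratio or dilution indices) of a preset."""
    return {"COND1": 5, "COND2A": 3, "COND2B": 5, "COND2C": 3, "COND3": 5}[label]


def _ratio_variant(variant) -> int:
    """Normalise a COND1/COND3 variant given as index, int ratio or 'D:R' string."""
    if isinstance(variant, str):
        d, _, rpart = variant.partition(":")
        if d.strip() != "1":
            raise ValueError(f"unknown mixing-ratio variant {variant!r}")
        ratio = int(float(rpart))
        return MIX_RATIOS.index(ratio)
    variant = int(variant)
    if variant in range(5):
        return variant
    if variant in MIX_RATIOS:
        return MIX_RATIOS.index(variant)
    raise ValueError(f"unknown mixing-ratio variant {variant!r}")


def preset_condition(label: str, variant=0,
                     params: KineticParameters | None = None) -> ExperimentCondition:
    """Documented inoculation preset for one of the five experimental conditions.

    ``variant`` indexes the dilution series (COND2*) or the donor:recipient
    mixing ratio (COND1/COND3; accepts an index 0-4, the recipient multiple
    0/1/10/100/1000, or a string like ``"1:10"``). Pure function: the same
    label and variant always yield the identical condition.
    """
    p = params or KineticParameters()
    label = label.upper()
    if label not in PRESET_LABELS:
        raise ValueError(f"unknown condition label {label!r}; choose from {PRESET_LABELS}")

    if label in ("COND1", "COND3"):
        i = _ratio_variant(variant)
        ratio = MIX_RATIOS[i]
        total = 1e6
        n_D = total / (1.0 + ratio)
        n_R = total * ratio / (1.0 + ratio)
        state = PopulationState(r=DEFAULT_R0, n_D=n_D, n_R=n_R,
                                n_P=1e7 if label == "COND3" else 0.0)
        return ExperimentCondition(label=label, initial_state=state, duration=700.0,
                                   sampling_interval=20.0, variant=f"1:{ratio}")

    i = int(variant)
    if label == "COND2A":
        if i not in range(3):
            raise ValueError("COND2A dilution index must be 0, 1 or 2")
        state = PopulationState(r=DEFAULT_R0, n_D=p.K * (0.5 / 50.0) * 10.0 ** (-i),
                                n_P=1e7)
    elif label == "COND2B":
        if i not in range(5):
            raise ValueError("COND2B dilution index must be 0..4")
        state = PopulationState(r=DEFAULT_R0, n_D=3e6, n_P=1e8 * 10.0 ** (-i))
    else:  # COND2C — overnight pre-infected culture, all cells already producing
        if i not in range(3):
            raise ValueError("COND2C dilution index must be 0, 1 or 2")
        state = PopulationState(r=DEFAULT_R0,
                                n_I=p.K * (0.2 / 50.0) * 10.0 ** (-i),
                                n_P=p.K_P * (0.2 / 50.0) * 10.0 ** (-i))
    return ExperimentCondition(label=label, initial_state=state, duration=500.0,
                               sampling_interval=20.0, variant=10.0 ** (-i))
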