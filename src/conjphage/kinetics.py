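"""Resource-limited kinetic model of conjugation and M13 infection in batch culture.

State space, rate laws and right-hand sides for a nine-variable compartmental
model of an *E. coli* batch culture in which an F plasmid spreads by
conjugation while the F-pilus-specific filamentous phage M13 spreads by
infection. The culture is closed: a single resource pool ``r`` (arbitrary
units) is consumed as cells divide, and growth saturates both through resource
exhaustion and through a logistic factor ``(1 - total_cells/K)``.

Cell compartments
-----------------
``n_D``   active donors (F+, uninfected)
``n_R``   recipients (F-)
``n_T``   transconjugants — recipients that just received the plasmid and
          mature into donors at rate ``lambda_T``
``n_X``   exhausted donors — donors recovering after transfer at rate
          ``lambda_X``
``n_N``   newly infected cells — not yet producing phage, become producers at
          rate ``lambda_N``
``n_I``   actively phage-producing infected cells (can still conjugate, at a
          penalty ``P_gamma``)
``n_XI``  exhausted infected donors recovering at rate ``lambda_X``
``n_P``   free phage

All kinetic rates share a hyperbolic (Monod / Michaelis-Menten-like) dependence
on the resource, ``rate(r) = rate_max * r / (Q + r)``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
import math

import numpy as np

__all__ = [
    "STATE_FIELDS",
    "PopulationState",
    "KineticParameters",
    "hyperbolic_rate",
    "derivatives_full",
    "derivatives_conjugation_only",
    "derivatives_infection_only",
    "CONJUGATION_ONLY_FIELDS",
    "INFECTION_ONLY_FIELDS",
]

STATE_FIELDS = ("r", "n_D", "n_R", "n_T", "n_X", "n_N", "n_I", "n_XI", "n_P")

#: coordinates retained by the conjugation-only reduction
CONJUGATION_ONLY_FIELDS = ("r", "n_D", "n_R", "n_T", "n_X")
#: coordinates retained by the infection-only reduction
INFECTION_ONLY_FIELDS = ("r", "n_D", "n_N", "n_I", "n_P")

_CELL_FIELDS = ("n_D", "n_R", "n_T", "n_X", "n_N", "n_I", "n_XI")


@dataclass
class PopulationState:
    """Densities of all compartments at one instant.

    ``r`` is in arbitrary resource units; cell compartments are in cells/mL and
    ``n_P`` in phages/mL. Also used as the container for time-derivatives of
    the same shape (in which case entries may be negative and ``validate`` is
    not called).
    """

    r: float = 0.0
    n_D: float = 0.0
    n_R: float = 0.0
    n_T: float = 0.0
    n_X: float = 0.0
    n_N: float = 0.0
    n_I: float = 0.0
    n_XI: float = 0.0
    n_P: float = 0.0

    def total_cells(self) -> float:
        """Total cell density Σn over the seven cellular compartments."""
        return sum(getattr(self, f) for f in _CELL_FIELDS)

    def plasmid_bearing(self) -> float:
        """Density of all F-plasmid-carrying compartments (everything but n_R)."""
        return self.total_cells() - self.n_R

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "PopulationState":
        return cls(**dict(zip(STATE_FIELDS, map(float, y))))

    def validate(self) -> "PopulationState":
        """Raise ``ValueError`` unless all coordinates are finite and >= 0."""
        for f in STATE_FIELDS:
            v = getattr(self, f)
            if not math.isfinite(v):
                raise ValueError(f"non-finite state coordinate {f}={v!r}")
            if v < 0:
                raise ValueError(f"negative state coordinate {f}={v!r}")
        return self

    def replace(self, **kw) -> "PopulationState":
        return replace(self, **kw)


# Table of default rate constants (the published simulation parameter set).
@dataclass
class KineticParameters:
    """Rate constants, capacities, lags and infection penalties.

    Units: rates in min^-1 (bilinear rates in mL cell^-1 min^-1 or
    mL phage^-1 min^-1), densities per mL, resource in arbitrary units (a.u.).

    ``P_gamma`` is the conjugation-rate penalty applied to infected donors;
    the alias ``P_lambda`` is accepted by :meth:`from_dict` for configs.
    """

    psi_max: float = 0.035          # max cell growth rate, min^-1
    gamma_max: float = 3e-10        # max conjugation rate, mL cell^-1 min^-1
    beta_max: float = 3e-11         # max phage infection rate, mL phage^-1 min^-1
    psiP_max: float = 6.0           # max phage production, phages cell^-1 min^-1
    Q: float = 1.0                  # resource at half-maximum rate, a.u.
    e: float = 3.5e-8               # resource per cell division, a.u. mL cell^-1
    K: float = 3e9                  # cell carrying capacity, cells mL^-1
    K_P: float = 4e11               # phage carrying capacity, phages mL^-1
    lambda_T: float = 1.0 / 90.0    # transconjugant -> donor maturation, min^-1
    lambda_X: float = 1.0 / 30.0    # exhausted -> active donor recovery, min^-1
    lambda_N: float = 1.0 / 30.0    # newly infected -> producer, min^-1
    P_psi: float = 0.6              # growth penalty on infected cells, (0,1]
    P_gamma: float = 0.1            # conjugation penalty on infected cells, (0,1]

    # capacities, the half-saturation constant and penalties must be strictly
    # positive; pure rates may be zero (switching a process off is meaningful,
    # e.g. growth-free conservation checks)
    _STRICT = ("Q", "e", "K", "K_P", "P_psi", "P_gamma")

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name} must be finite and >= 0, got {v!r}")
            if f.name in self._STRICT and v == 0:
                raise ValueError(f"parameter {f.name} must be > 0, got {v!r}")
        for name in ("P_psi", "P_gamma"):
            v = getattr(self, name)
            if v > 1:
                raise ValueError(f"penalty {name} must lie in (0, 1], got {v!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        d = dict(d)
        if "P_lambda" in d:
            if "P_gamma" in d and d["P_gamma"] != d["P_lambda"]:
                raise ValueError("P_lambda is an alias of P_gamma; got conflicting values")
            d["P_gamma"] = d.pop("P_lambda")
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown kinetic parameter(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def replace(self, **kw) -> "KineticParameters":
        if "P_lambda" in kw:
            kw["P_gamma"] = kw.pop("P_lambda")
        return replace(self, **kw)


def hyperbolic_rate(r: float, rate_max: float, Q: float):
    """Monod-type rate law ``rate_max * r / (Q + r)``.

    Monotone non-decreasing in ``r``, equal to ``rate_max/2`` at ``r == Q`` and
    bounded above by ``rate_max``. Accepts scalars or arrays for ``r``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("resource concentration r must be >= 0")
    if Q <= 0:
        raise ValueError("half-saturation constant Q must be > 0")
    if rate_max < 0:
        raise ValueError("rate_max must be >= 0")
    out = rate_max * r / (Q + r)
    return float(out) if out.ndim == 0 else out


def _rhs_full(y, p: KineticParameters):
    """Full nine-variable right-hand side on a raw coordinate array.

    Hot path for the integrators: no validation, no dataclass construction.
    The hyperbolic factor is evaluated at max(r, 0) so that tiny negative
    overshoots of the resource during stiff steps cannot flip rate signs.
    """
    r, nD, nR, nT, nX, nN, nI, nXI, nP = y
    total = nD + nR + nT + nX + nN + nI + nXI
    lg = 1.0 - total / p.K
    rr = r if r > 0.0 else 0.0
    f = rr / (p.Q + rr)
    psi = p.psi_max * f
    gam = p.gamma_max * f
    bet = p.beta_max * f
    psiP = p.psiP_max * f

    conjDR = gam * nD * nR
    conjIR = p.P_gamma * gam * nI * nR
    infect = bet * nD * nP

    dr = (-p.e * psi * (nD + nR + nT + nX) * lg
          - p.e * p.P_psi * psi * (nN + nI + nXI) * lg)
    dnD = psi * nD * lg - conjDR + p.lambda_X * nX + p.lambda_T * nT - infect
    dnR = psi * nR * lg - conjDR - conjIR
    dnT = psi * nT * lg + conjDR - p.lambda_T * nT + conjIR
    dnX = psi * nX * lg + conjDR - p.lambda_X * nX
    dnN = p.P_psi * psi * nN * lg + infect - p.lambda_N * nN
    dnI = p.P_psi * psi * nI * lg + p.lambda_N * nN - conjIR + p.lambda_X * nXI
    dnXI = p.P_psi * psi * nXI * lg + conjIR - p.lambda_X * nXI
    dnP = psiP * (nI + nXI) * (1.0 - nP / p.K_P)
    return (dr, dnD, dnR, dnT, dnX, dnN, dnI, dnXI, dnP)


#: parameter order of the packed vector consumed by the array RHS
_PARAM_ORDER = ("psi_max", "gamma_max", "beta_max", "psiP_max", "Q", "e", "K",
                "K_P", "lambda_T", "lambda_X", "lambda_N", "P_psi", "P_gamma")


def params_vector(p: KineticParameters) -> np.ndarray:
    return np.array([getattr(p, name) for name in _PARAM_ORDER])


def _rhs_array(y, pv):
    """Array form of the full RHS (same formulas/op order as `_rhs_full`)."""
    psi_max, gamma_max, beta_max, psiP_max, Q, e, K, K_P, \
        lambda_T, lambda_X, lambda_N, P_psi, P_gamma = pv
    r, nD, nR, nT, nX, nN, nI, nXI, nP = y
    total = nD + nR + nT + nX + nN + nI + nXI
    lg = 1.0 - total / K
    rr = r if r > 0.0 else 0.0
    f = rr / (Q + rr)
    psi = psi_max * f
    gam = gamma_max * f
    bet = beta_max * f
    psiP = psiP_max * f
    conjDR = gam * nD * nR
    conjIR = P_gamma * gam * nI * nR
    infect = bet * nD * nP
    out = np.empty(9)
    out[0] = (-e * psi * (nD + nR + nT + nX) * lg
              - e * P_psi * psi * (nN + nI + nXI) * lg)
    out[1] = psi * nD * lg - conjDR + lambda_X * nX + lambda_T * nT - infect
    out[2] = psi * nR * lg - conjDR - conjIR
    out[3] = psi * nT * lg + conjDR - lambda_T * nT + conjIR
    out[4] = psi * nX * lg + conjDR - lambda_X * nX
    out[5] = P_psi * psi * nN * lg + infect - lambda_N * nN
    out[6] = P_psi * psi * nI * lg + lambda_N * nN - conjIR + lambda_X * nXI
    out[7] = P_psi * psi * nXI * lg + conjIR - lambda_X * nXI
    out[8] = psiP * (nI + nXI) * (1.0 - nP / K_P)
    return out


try:  # optional acceleration; identical formulas either way
    from numba import njit

    _rhs_array = njit(cache=True)(_rhs_array)
except ImportError:  # pragma: no cover - numba is an optional extra
    pass


def derivatives_full(state: PopulationState, params: KineticParameters) -> PopulationState:
    """Time-derivatives of the full nine-variable system.

    Returns a :class:`PopulationState`-shaped container holding dr/dt and the
    eight compartment derivatives (entries may be negative).
    """
    y = state.to_array()
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state coordinates")
    return PopulationState(*_rhs_full(tuple(y), params))


def _reduced_derivatives(state_fields, state: PopulationState, params: KineticParameters,
                         must_be_zero) -> PopulationState:
    y = state.to_array()
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state coordinates")
    for f in must_be_zero:
        if getattr(state, f) != 0.0:
            raise ValueError(f"reduced system requires {f} == 0, got {getattr(state, f)!r}")
    d = _rhs_full(tuple(y), params)
    full = PopulationState(*d)
    # zero out the eliminated coordinates explicitly: the reduction carries
    # only `state_fields`, everything else is identically zero by construction
    kept = {f: getattr(full, f) for f in state_fields}
    return PopulationState(**kept)


def derivatives_conjugation_only(state: PopulationState,
                                 params: KineticParameters) -> PopulationState:
    """Derivatives of the phage-free five-variable reduction (r, n_D, n_R, n_T, n_X).

    Bitwise-consistent with :func:`derivatives_full` evaluated at
    ``n_N = n_I = n_XI = n_P = 0`` (it is computed exactly that way).
    """
    return _reduced_derivatives(CONJUGATION_ONLY_FIELDS, state, params,
                                must_be_zero=("n_N", "n_I", "n_XI", "n_P"))


def derivatives_infection_only(state: PopulationState,
                               params: KineticParameters) -> PopulationState:
    """Derivatives of the conjugation-free five-variable reduction (r, n_D, n_N, n_I, n_P).

    With no recipients present, no cell ever enters n_T/n_X/n_XI, so phage
    production comes from n_I only — identical to the full system restricted
    to these coordinates.
    """
    return _reduced_derivatives(INFECTION_ONLY_FIELDS, state, params,
                                must_be_zero=("n_R", "n_T", "n_X", "n_XI"))
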