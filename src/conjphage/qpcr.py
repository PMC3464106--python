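"""Marker mapping and synthetic qPCR time series.

Three genomic loci are assayed: ``tolC`` (one copy per chromosome — counts all
cells), ``traI`` (one copy per F plasmid — counts plasmid-bearing cells) and
``M13`` (the phage genome — counts free phage). Threshold-cycle values follow
an idealized log-linear calibration with perfect doubling efficiency,

    Ct = ct_ref - log2(N / N_ref),

so one cycle is exactly one doubling and calibration offsets cancel in Ct
differences between loci. Measurement noise is applied in Ct (log) space only:
Gaussian cycle noise of sd ``noise_sd`` (default 0.5 cycles, giving replicate
ranges of about one cycle), which corresponds to multiplicative log-normal
noise on abundance and can never produce a negative abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Trajectory

__all__ = [
    "LOCI",
    "CtCalibration",
    "MarkerSeries",
    "marker_abundance",
    "abundance_to_ct",
    "ct_to_abundance",
    "synthesize_dataset",
    "write_marker_series",
    "read_marker_series",
]

LOCI = ("tolC", "traI", "M13")

#: plasmid-bearing compartments counted by the traI assay
_TRAI_FIELDS = ("n_D", "n_T", "n_X", "n_N", "n_I", "n_XI")
_CELL_FIELDS = ("n_D", "n_R", "n_T", "n_X", "n_N", "n_I", "n_XI")


@dataclass(frozen=True)
class CtCalibration:
    """Reference point of the idealized Ct <-> abundance map."""

    ct_ref: float = 35.0   # cycles
    N_ref: float = 1e3     # copies per mL

    def to_dict(self) -> dict:
        return {"ct_ref": self.ct_ref, "N_ref": self.N_ref}


DEFAULT_CALIBRATION = CtCalibration()


@dataclass
class MarkerSeries:
    """Per-locus abundance and/or Ct time series — the unit of fitting.

    At least one of ``abundance`` (copies/mL) and ``ct`` (cycles) is present;
    censored points (abundance 0 or undefined Ct) are carried as NaN in ``ct``.
    """

    locus: str
    times: np.ndarray
    abundance: np.ndarray | None = None
    ct: np.ndarray | None = None
    replicate_id: int = 0

    def __post_init__(self):
        if self.locus not in LOCI:
            raise ValueError(f"unknown locus {self.locus!r}; choose from {LOCI}")
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.abundance is None and self.ct is None:
            raise ValueError("at least one of abundance/ct must be present")
        for name in ("abundance", "ct"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.times.shape:
                    raise ValueError(f"{name} and times must have the same length")
                setattr(self, name, v)
        if self.abundance is not None and np.any(self.abundance < 0):
            raise ValueError("abundances must be >= 0")

    def get_abundance(self, calib: CtCalibration = DEFAULT_CALIBRATION) -> np.ndarray:
        """Abundance values, derived from Ct if not stored directly."""
        if self.abundance is not None:
            return self.abundance
        return ct_to_abundance(self.ct, calib)

    def get_ct(self, calib: CtCalibration = DEFAULT_CALIBRATION) -> np.ndarray:
        if self.ct is not None:
            return self.ct
        return abundance_to_ct(self.abundance, calib)


def marker_abundance(traj: Trajectory, locus: str) -> MarkerSeries:
    """Map a trajectory onto the copies/mL counted by one qPCR locus.

    tolC -> all seven cell compartments; traI -> every plasmid-bearing
    compartment (all cells except recipients); M13 -> free phage.
    """
    if locus == "tolC":
        ab = sum(traj.column(f) for f in _CELL_FIELDS)
    elif locus == "traI":
        ab = sum(traj.column(f) for f in _TRAI_FIELDS)
    elif locus == "M13":
        ab = traj.column("n_P")
    else:
        raise ValueError(f"unknown locus {locus!r}; choose from {LOCI}")
    return MarkerSeries(locus=locus, times=traj.times.copy(), abundance=np.asarray(ab))


def abundance_to_ct(N, calib: CtCalibration = DEFAULT_CALIBRATION):
    """Ideal threshold cycle for abundance ``N`` copies/mL.

    Non-positive abundances have no defined Ct and map to NaN (censored),
    not an exception.
    """
    if calib.N_ref <= 0:
        raise ValueError("N_ref must be > 0")
    N = np.asarray(N, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ct = np.where(N > 0, calib.ct_ref - np.log2(N / calib.N_ref), np.nan)
    return float(ct) if ct.ndim == 0 else ct


def ct_to_abundance(ct, calib: CtCalibration = DEFAULT_CALIBRATION):
    """Exact inverse of :func:`abundance_to_ct` (NaN Ct stays NaN)."""
    ct = np.asarray(ct, dtype=float)
    N = calib.N_ref * np.exp2(calib.ct_ref - ct)
    return float(N) if N.ndim == 0 else N


def _replicate_rng(seed: int, locus: str, replicate: int) -> np.random.Generator:
    # per-(locus, replicate) substream: reruns of any subset are reproducible
    ss = np.random.SeedSequence(entropy=int(seed),
                                spawn_key=(LOCI.index(locus), int(replicate)))
    return np.random.default_rng(ss)


def synthesize_dataset(traj: Trajectory,
                       loci=LOCI,
                       noise_sd: float = 0.5,
                       n_replicates: int = 3,
                       seed: int = 0,
                       calib: CtCalibration = DEFAULT_CALIBRATION) -> list[MarkerSeries]:
    """Synthetic replicate Ct series for each locus on the trajectory's grid.

    i.i.d. Gaussian cycle noise of sd ``noise_sd`` is added to the ideal Ct of
    each point; ``noise_sd=0`` reproduces the ideal Ct exactly. Deterministic
    under a fixed ``seed`` (each locus/replicate draws from its own substream).
    """
    loci = tuple(loci)
    if not loci:
        raise ValueError("loci set must be non-empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    out = []
    for locus in loci:
        ideal = abundance_to_ct(marker_abundance(traj, locus).abundance, calib)
        for rep in range(n_replicates):
            ct = np.array(ideal, dtype=float)
            if noise_sd > 0:
                rng = _replicate_rng(seed, locus, rep)
                ct = ct + rng.normal(0.0, noise_sd, size=ct.shape)
            out.append(MarkerSeries(locus=locus, times=traj.times.copy(),
                                    ct=ct, replicate_id=rep))
    return out


def write_marker_series(series: list[MarkerSeries], path) -> None:
    """Write a dataset as tidy TSV: locus, replicate_id, time_min, ct, abundance."""
    rows = []
    for s in series:
        ct = s.ct if s.ct is not None else np.full(s.times.shape, np.nan)
        ab = s.abundance if s.abundance is not None else np.full(s.times.shape, np.nan)
        for t, c, a in zip(s.times, ct, ab):
            rows.append({"locus": s.locus, "replicate_id": s.replicate_id,
                         "time_min": t, "ct": c, "abundance": a})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="")


def read_marker_series(path) -> list[MarkerSeries]:
    """Read a dataset written by :func:`write_marker_series`.

    ``path`` may be one file or a directory of per-locus files.
    """
    path = Path(path)
    files = sorted(path.glob("*.tsv")) if path.is_dir() else [path]
    out = []
    for f in files:
        df = pd.read_csv(f, sep="\t")
        for (locus, rep), g in df.groupby(["locus", "replicate_id"], sort=True):
            g = g.sort_values("time_min")
            ct = g["ct"].to_numpy(dtype=float)
            ab = g["abundance"].to_numpy(dtype=float)
            has_ab = not np.all(np.isnan(ab))
            # a fully censored locus keeps its all-NaN Ct column
            has_ct = not np.all(np.isnan(ct)) or not has_ab
            out.append(MarkerSeries(
                locus=str(locus), times=g["time_min"].to_numpy(dtype=float),
                ct=ct if has_ct else None,
                abundance=np.nan_to_num(ab, nan=0.0) if has_ab else None,
                replicate_id=int(rep)))
    return out
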