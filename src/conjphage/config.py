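"""Run configuration: YAML/JSON blocks for parameters, condition, integration,
synthesis and fitting, with strict key checking."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import yaml

from .kinetics import KineticParameters, PopulationState
from .qpcr import LOCI, CtCalibration
from .simulate import SYSTEMS, ExperimentCondition, preset_condition

__all__ = ["ConfigError", "RunConfig", "load_config"]

_TOP_KEYS = {"parameters", "condition", "integration", "synthesis", "fit", "output"}
_CONDITION_KEYS = {"label", "variant", "duration", "sampling_interval", "initial_state"}
_INTEGRATION_KEYS = {"system", "rtol", "atol"}
_SYNTH_KEYS = {"loci", "noise_sd", "seed", "replicates", "calibration"}
_FIT_KEYS = {"stage", "n_starts", "max_nfev"}


class ConfigError(ValueError):
    pass


def _check_keys(block: dict, allowed: set, where: str):
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Resolved configuration for a simulate/synth/fit/recover run."""

    params: KineticParameters
    condition: ExperimentCondition | None
    system: str = "full"
    rtol: float = 1e-8
    atol: float = 1e-2
    loci: tuple = LOCI
    noise_sd: float = 0.0
    seed: int | None = None
    replicates: int = 3
    calibration: CtCalibration = field(default_factory=CtCalibration)
    fit_stage: str = "all"
    n_starts: int = 5
    max_nfev: int = 500
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        if not isinstance(doc, dict):
            raise ConfigError("config root must be a mapping")
        _check_keys(doc, _TOP_KEYS, "config root")

        try:
            params = KineticParameters.from_dict(doc.get("parameters", {}))
        except ValueError as exc:
            raise ConfigError(f"parameters block: {exc}") from exc

        condition = None
        cond = doc.get("condition")
        if cond is not None:
            _check_keys(cond, _CONDITION_KEYS, "condition block")
            if "label" in cond and cond.get("label", "CUSTOM") != "CUSTOM" \
                    and "initial_state" not in cond:
                condition = preset_condition(cond["label"], cond.get("variant", 0),
                                             params=params)
                if "duration" in cond:
                    condition.duration = float(cond["duration"])
                if "sampling_interval" in cond:
                    condition.sampling_interval = float(cond["sampling_interval"])
            else:
                state = cond.get("initial_state")
                if state is None:
                    raise ConfigError("custom condition needs an initial_state block")
                try:
                    init = PopulationState(**{k: float(v) for k, v in state.items()})
                    init.validate()
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"initial_state block: {exc}") from exc
                condition = ExperimentCondition(
                    label=cond.get("label", "CUSTOM"), initial_state=init,
                    duration=float(cond.get("duration", 700.0)),
                    sampling_interval=float(cond.get("sampling_interval", 20.0)))

        integ = doc.get("integration", {})
        _check_keys(integ, _INTEGRATION_KEYS, "integration block")
        system = integ.get("system", "full")
        if system not in SYSTEMS:
            raise ConfigError(f"unknown system {system!r}")

        synth = doc.get("synthesis", {})
        _check_keys(synth, _SYNTH_KEYS, "synthesis block")
        loci = tuple(synth.get("loci", LOCI))
        bad = set(loci) - set(LOCI)
        if bad:
            raise ConfigError(f"unknown loci {sorted(bad)}")
        noise_sd = float(synth.get("noise_sd", 0.0))
        seed = synth.get("seed")
        if noise_sd > 0 and seed is None:
            raise ConfigError("synthesis.seed is mandatory when noise_sd > 0")
        calib_block = synth.get("calibration", {})
        _check_keys(calib_block, {"ct_ref", "N_ref"}, "calibration block")
        calib = CtCalibration(ct_ref=float(calib_block.get("ct_ref", 35.0)),
                              N_ref=float(calib_block.get("N_ref", 1e3)))

        fit = doc.get("fit", {})
        _check_keys(fit, _FIT_KEYS, "fit block")

        return cls(params=params, condition=condition, system=system,
                   rtol=float(integ.get("rtol", 1e-8)),
                   atol=float(integ.get("atol", 1e-2)),
                   loci=loci, noise_sd=noise_sd,
                   seed=None if seed is None else int(seed),
                   replicates=int(synth.get("replicates", 3)),
                   calibration=calib,
                   fit_stage=fit.get("stage", "all"),
                   n_starts=int(fit.get("n_starts", 5)),
                   max_nfev=int(fit.get("max_nfev", 500)),
                   raw=doc)


def load_config(path) -> RunConfig:
    """Load a YAML (or JSON, a YAML subset) config file."""
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if doc is None:
        doc = {}
    return RunConfig.from_dict(doc)
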