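"""Study configuration: one YAML file governing all pipeline stages.

The schema is validated before any stage runs; unknown keys are rejected
with the offending path named.  Every entry has a default, so an empty
config is valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from perfquant.perfusion import FermiBounds
from perfquant.signal_model import (
    AIF_SEQ,
    IMAGING_SEQ,
    PD_SEQ,
    RelaxationContext,
    SequenceParams,
)

__all__ = ["StudyConfig", "load_config"]

_SEQ_KEYS = {"sr_time", "tr", "flip_angle", "n_pulses_to_center",
             "readout_duration"}

_SCHEMA: dict = {
    "seed": None,
    "sequences": {"imaging": _SEQ_KEYS, "aif": _SEQ_KEYS, "pd": _SEQ_KEYS},
    "relaxation": {"t10_tissue", "t10_blood", "relaxivity_r1"},
    "fitting": {"amplitude", "decay_k", "width_w", "delay_td", "n_starts",
                "dt", "baseline_frames", "pd_floor_fraction"},
    "simulation": {"n_frames", "rr_s", "snr", "grid_size", "n_pd",
                   "aif_peak", "t_arrival"},
    "stats": {"alpha_normality", "welch", "covariates"},
}


@dataclass
class StudyConfig:
    seed: int = 0
    seq_imaging: SequenceParams = IMAGING_SEQ
    seq_aif: SequenceParams = AIF_SEQ
    seq_pd: SequenceParams = PD_SEQ
    relaxation: RelaxationContext = field(default_factory=RelaxationContext)
    bounds: FermiBounds = field(default_factory=FermiBounds)
    n_starts: int = 5
    dt: float = 0.5
    baseline_frames: int = 3
    pd_floor_fraction: float = 0.05
    # simulation defaults
    n_frames: int = 50
    rr_s: float = 1.0
    snr: float = 20.0
    grid_size: int = 8
    n_pd: int = 2
    aif_peak: float = 5.0
    t_arrival: float = 6.0
    # stats
    alpha_normality: float = 0.05
    welch: bool = False
    covariates: tuple = ("age", "lv_mass", "bmi", "female")


def _validate_keys(data: dict, schema: dict, path: str = "") -> None:
    for key, value in data.items():
        where = f"{path}.{key}" if path else key
        if key not in schema:
            raise ValueError(f"unknown config key: {where!r}")
        sub = schema[key]
        if isinstance(sub, dict):
            if not isinstance(value, dict):
                raise ValueError(f"config key {where!r} must be a mapping")
            _validate_keys(value, sub, where)
        elif isinstance(sub, set):
            if not isinstance(value, dict):
                raise ValueError(f"config key {where!r} must be a mapping")
            for k in value:
                if k not in sub:
                    raise ValueError(f"unknown config key: {where}.{k!r}")


def _seq_from(data: dict, default: SequenceParams) -> SequenceParams:
    kwargs = {
        "sr_time": default.sr_time, "tr": default.tr,
        "flip_angle": default.flip_angle,
        "n_pulses_to_center": default.n_pulses_to_center,
        "readout_duration": default.readout_duration,
    }
    kwargs.update(data)
    return SequenceParams(**kwargs)


def load_config(path_or_dict=None) -> StudyConfig:
    """Build a :class:`StudyConfig` from a YAML file, dict, or defaults."""
    if path_or_dict is None:
        data = {}
    elif isinstance(path_or_dict, dict):
        data = path_or_dict
    else:
        data = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    _validate_keys(data, _SCHEMA)

    cfg = StudyConfig()
    if "seed" in data:
        cfg.seed = int(data["seed"])
    seqs = data.get("sequences", {})
    cfg.seq_imaging = _seq_from(seqs.get("imaging", {}), IMAGING_SEQ)
    cfg.seq_aif = _seq_from(seqs.get("aif", {}), AIF_SEQ)
    cfg.seq_pd = _seq_from(seqs.get("pd", {}), PD_SEQ)
    relax = data.get("relaxation", {})
    cfg.relaxation = RelaxationContext(
        t10_tissue=relax.get("t10_tissue", 1100.0),
        t10_blood=relax.get("t10_blood", 1650.0),
        relaxivity_r1=relax.get("relaxivity_r1", 4.3),
    )
    fit = data.get("fitting", {})
    cfg.bounds = FermiBounds(
        amplitude=tuple(fit.get("amplitude", (0.05, 8.0))),
        decay_k=tuple(fit.get("decay_k", (0.0, 5.0))),
        width_w=tuple(fit.get("width_w", (0.0, 30.0))),
        delay_td=tuple(fit.get("delay_td", (0.0, 5.0))),
    )
    cfg.n_starts = int(fit.get("n_starts", cfg.n_starts))
    cfg.dt = float(fit.get("dt", cfg.dt))
    cfg.baseline_frames = int(fit.get("baseline_frames", cfg.baseline_frames))
    cfg.pd_floor_fraction = float(fit.get("pd_floor_fraction",
                                          cfg.pd_floor_fraction))
    sim = data.get("simulation", {})
    cfg.n_frames = int(sim.get("n_frames", cfg.n_frames))
    cfg.rr_s = float(sim.get("rr_s", cfg.rr_s))
    snr = sim.get("snr", cfg.snr)
    cfg.snr = float("inf") if snr in ("inf", None) else float(snr)
    cfg.grid_size = int(sim.get("grid_size", cfg.grid_size))
    cfg.n_pd = int(sim.get("n_pd", cfg.n_pd))
    cfg.aif_peak = float(sim.get("aif_peak", cfg.aif_peak))
    cfg.t_arrival = float(sim.get("t_arrival", cfg.t_arrival))
    st = data.get("stats", {})
    cfg.alpha_normality = float(st.get("alpha_normality", cfg.alpha_normality))
    cfg.welch = bool(st.get("welch", cfg.welch))
    cfg.covariates = tuple(st.get("covariates", cfg.covariates))
    return cfg
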