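"""Saturation-recovery signal model and gadolinium concentration conversion.

Forward model: an ideally spoiled gradient-echo pulse train following a
saturation preparation.  Longitudinal magnetization obeys the recurrence

    Mz <- (Mz * cos(alpha)) * E1 + M0 * (1 - E1),      E1 = exp(-TR / T1)

between RF pulses; the measured signal is the transverse magnetization at
the pulse that acquires the k-space centre, ``Mz * sin(alpha)``.  The
proton-density (PD) reference acquisition uses the same recurrence but
starts from thermal equilibrium (no saturation) at a low flip angle, so the
PD-normalized ratio SR/PD cancels M0 and receiver scaling and depends on T1
only.  Inverting that ratio on a precomputed lookup yields T1, and the
relaxivity relation 1/T1 = 1/T10 + r1*[Gd] yields concentration.

Units: sequence timing in milliseconds, relaxivity in L mmol^-1 s^-1,
concentrations in mmol/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SequenceParams",
    "RelaxationContext",
    "NormalizedFrame",
    "ConcentrationLookup",
    "sr_signal",
    "pd_signal",
    "normalize_series",
    "signal_to_concentration",
    "IMAGING_SEQ",
    "AIF_SEQ",
    "PD_SEQ",
    "DEFAULT_CONTEXT",
]


@dataclass(frozen=True)
class SequenceParams:
    """Timing and flip-angle description of one acquisition.

    Parameters
    ----------
    sr_time : float or None
        Delay in ms from saturation to the first readout RF pulse; ``None``
        for the unsaturated PD acquisition.
    tr : float
        Repetition time of the readout train, ms.
    flip_angle : float
        Readout flip angle, degrees, in (0, 90).
    n_pulses_to_center : int
        Number of RF pulses up to and including the one acquiring the
        k-space centre (>= 1).
    readout_duration : float
        Duration of a single readout, ms (informational).
    """

    sr_time: float | None
    tr: float
    flip_angle: float
    n_pulses_to_center: int = 1
    readout_duration: float = 6.1

    def __post_init__(self) -> None:
        if self.sr_time is not None and self.sr_time < 0:
            raise ValueError(f"sr_time must be >= 0, got {self.sr_time}")
        if self.tr <= 0:
            raise ValueError(f"tr must be > 0, got {self.tr}")
        if not 0.0 < self.flip_angle < 90.0:
            raise ValueError(
                f"flip_angle must be in (0, 90) degrees, got {self.flip_angle}"
            )
        if self.n_pulses_to_center < 1:
            raise ValueError(
                f"n_pulses_to_center must be >= 1, got {self.n_pulses_to_center}"
            )


# Default sequences: high-resolution imaging readout (8 interleaves, centre
# at interleave 4 under linear ordering), single-shot AIF, unsaturated PD.
IMAGING_SEQ = SequenceParams(sr_time=80.0, tr=9.0, flip_angle=30.0,
                             n_pulses_to_center=4, readout_duration=6.1)
AIF_SEQ = SequenceParams(sr_time=20.0, tr=9.0, flip_angle=45.0,
                         n_pulses_to_center=1, readout_duration=6.1)
PD_SEQ = SequenceParams(sr_time=None, tr=9.0, flip_angle=10.0,
                        n_pulses_to_center=4, readout_duration=6.1)


@dataclass(frozen=True)
class RelaxationContext:
    """Pre-contrast relaxation times and contrast-agent relaxivity.

    Defaults are literature-typical 1.5 T values for a gadopentetate agent
    and are configuration, not ground truth.
    """

    t10_tissue: float = 1100.0  # ms
    t10_blood: float = 1650.0   # ms
    relaxivity_r1: float = 4.3  # L mmol^-1 s^-1

    def __post_init__(self) -> None:
        for name in ("t10_tissue", "t10_blood", "relaxivity_r1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def t1_of_concentration(self, conc: np.ndarray | float, t10: float) -> np.ndarray:
        """Effective T1 (ms) at gadolinium concentration ``conc`` (mmol/L)."""
        conc = np.asarray(conc, dtype=float)
        if np.any(conc < 0):
            raise ValueError("concentration must be >= 0")
        r1_per_s = 1000.0 / t10 + self.relaxivity_r1 * conc  # 1/s
        return 1000.0 / r1_per_s

    def concentration_of_t1(self, t1: np.ndarray | float, t10: float) -> np.ndarray:
        """Concentration (mmol/L) from effective T1 (ms); clipped at 0."""
        t1 = np.asarray(t1, dtype=float)
        conc = (1000.0 / t1 - 1000.0 / t10) / self.relaxivity_r1
        return np.clip(conc, 0.0, None)


DEFAULT_CONTEXT = RelaxationContext()


@dataclass(frozen=True)
class NormalizedFrame:
    """A PD-normalized frame: dimensionless intensity ratio plus its time (s)."""

    values: np.ndarray
    time: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.valid is None:
            object.__setattr__(self, "valid", np.ones(self.values.shape, dtype=bool))


def _check_t1(t1: float) -> None:
    if not np.all(np.asarray(t1) > 0):
        raise ValueError("t1 must be > 0 ms")


def sr_signal(t1, seq: SequenceParams, m0: float = 1.0):
    """Signal of the saturation-prepared spoiled-GRE train at the centre pulse.

    Starts from Mz = 0 at saturation, recovers for ``seq.sr_time``, then
    applies ``seq.n_pulses_to_center`` pulses; returns Mz at the centre
    pulse times sin(flip angle).  Accepts scalar or array ``t1`` (ms).
    """
    if seq.sr_time is None:
        raise ValueError("sr_signal requires a sequence with sr_time set")
    _check_t1(t1)
    t1 = np.asarray(t1, dtype=float)
    alpha = np.deg2rad(seq.flip_angle)
    e1 = np.exp(-seq.tr / t1)
    mz = m0 * (1.0 - np.exp(-seq.sr_time / t1))
    for _ in range(seq.n_pulses_to_center - 1):
        mz = mz * np.cos(alpha) * e1 + m0 * (1.0 - e1)
    return mz * np.sin(alpha)


def pd_signal(t1, seq: SequenceParams, m0: float = 1.0):
    """Signal of the unsaturated proton-density reference acquisition.

    Same recurrence as :func:`sr_signal` but starting from Mz = M0.  At a
    10-degree flip angle the result is nearly T1 independent by design.
    """
    if seq.sr_time is not None:
        raise ValueError("pd_signal requires a sequence without sr_time")
    _check_t1(t1)
    t1 = np.asarray(t1, dtype=float)
    alpha = np.deg2rad(seq.flip_angle)
    e1 = np.exp(-seq.tr / t1)
    mz = np.full_like(t1, m0, dtype=float) if t1.ndim else m0
    for _ in range(seq.n_pulses_to_center - 1):
        mz = mz * np.cos(alpha) * e1 + m0 * (1.0 - e1)
    return mz * np.sin(alpha)


def normalize_series(sr_frames, pd_frames, pd_floor_fraction: float = 0.05,
                     times=None):
    """PD-normalize a dynamic SR series.

    Parameters
    ----------
    sr_frames : array, shape (n_frames, ...)
        Saturation-recovery frames.
    pd_frames : array, shape (n_pd, ...)
        Proton-density reference frames; averaged pixel-wise.
    pd_floor_fraction : float
        Pixels whose mean PD falls below this fraction of the PD series
        median are flagged invalid (guards against division blow-ups).
    times : sequence of float, optional
        Frame times in seconds; attached to the returned frames.

    Returns
    -------
    list of NormalizedFrame
    """
    sr_frames = np.asarray(sr_frames, dtype=float)
    pd_frames = np.asarray(pd_frames, dtype=float)
    if pd_frames.size == 0:
        raise ValueError("pd_frames is empty")
    if sr_frames.shape[1:] != pd_frames.shape[1:]:
        raise ValueError(
            f"spatial shape mismatch: SR {sr_frames.shape[1:]} vs PD {pd_frames.shape[1:]}"
        )
    pd_mean = pd_frames.mean(axis=0)
    if not np.any(pd_mean > 0):
        raise ValueError("all-zero PD frames")
    floor = pd_floor_fraction * np.median(pd_mean)
    valid = pd_mean > floor
    safe_pd = np.where(valid, pd_mean, 1.0)
    if times is None:
        times = np.arange(len(sr_frames), dtype=float)
    frames = []
    for i, frame in enumerate(sr_frames):
        ratio = np.where(valid, frame / safe_pd, 0.0)
        frames.append(NormalizedFrame(values=ratio, time=float(times[i]),
                                      valid=valid.copy()))
    return frames


class ConcentrationLookup:
    """Monotone lookup inverting the SR/PD signal ratio to T1 and [Gd].

    The grid runs from 20 to 4000 ms in 1 ms steps (configurable); the ratio
    sr_signal(T1, seq_sr) / pd_signal(T10, seq_pd) is strictly decreasing in
    T1 over this range for the sequences of interest, so linear
    interpolation on the reversed grid inverts it.
    """

    def __init__(self, seq_sr: SequenceParams, seq_pd: SequenceParams,
                 ctx: RelaxationContext, t10: float,
                 t1_min: float = 20.0, t1_max: float = 4000.0,
                 t1_step: float = 1.0):
        self.seq_sr = seq_sr
        self.seq_pd = seq_pd
        self.ctx = ctx
        self.t10 = float(t10)
        self._t1_grid = np.arange(t1_min, t1_max + t1_step / 2, t1_step)
        pd_ref = pd_signal(np.asarray([t10]), seq_pd)[0]
        self._ratio_grid = sr_signal(self._t1_grid, seq_sr) / pd_ref
        diffs = np.diff(self._ratio_grid)
        if not np.all(diffs < 0):
            raise ValueError("signal ratio is not strictly decreasing in T1 "
                             "over the lookup grid; cannot invert")
        # np.interp needs ascending x
        self._x = self._ratio_grid[::-1]
        self._y = self._t1_grid[::-1]

    @property
    def max_ratio(self) -> float:
        """Largest invertible ratio (at the shortest grid T1)."""
        return float(self._ratio_grid[0])

    def ratio_at_t1(self, t1) -> np.ndarray:
        """Forward model: SR/PD ratio at effective T1 (ms)."""
        pd_ref = pd_signal(np.asarray([self.t10]), self.seq_pd)[0]
        return sr_signal(t1, self.seq_sr) / pd_ref

    def ratio_at_concentration(self, conc, t10: float | None = None) -> np.ndarray:
        """Forward model: SR/PD ratio at gadolinium concentration (mmol/L)."""
        t10 = self.t10 if t10 is None else t10
        t1 = self.ctx.t1_of_concentration(conc, t10)
        return self.ratio_at_t1(t1)

    def t1_of_ratio(self, ratio) -> np.ndarray:
        ratio = np.asarray(ratio, dtype=float)
        if np.any(ratio < 0):
            raise ValueError("ratio must be >= 0")
        if np.any(ratio > self.max_ratio):
            bad = np.argwhere(ratio > self.max_ratio)
            raise ValueError(
                f"ratio exceeds the invertible maximum {self.max_ratio:.4f} "
                f"(saturated signal) at index {bad[0].tolist()}"
            )
        return np.interp(ratio, self._x, self._y)

    def concentration_of_ratio(self, ratio, clip: bool = True) -> np.ndarray:
        """Invert ratio -> T1 -> [Gd]; T1 >= T10 maps to 0 (clip at zero).

        ``clip=False`` returns signed concentrations (negative where the
        inverted T1 exceeds T10), which keeps noise zero-mean around the
        pre-contrast baseline — the decoding pipeline uses this internally
        to avoid rectification bias in the deconvolution.
        """
        t1 = self.t1_of_ratio(ratio)
        conc = (1000.0 / t1 - 1000.0 / self.t10) / self.ctx.relaxivity_r1
        return np.clip(conc, 0.0, None) if clip else conc

    def max_invertible_concentration(self) -> float:
        """Largest [Gd] whose forward ratio is still on the monotone grid."""
        return float(self.ctx.concentration_of_t1(self._t1_grid[0], self.t10))


def signal_to_concentration(ratio, seq_sr: SequenceParams, seq_pd: SequenceParams,
                            ctx: RelaxationContext, t10: float | None = None,
                            lookup: ConcentrationLookup | None = None):
    """Convert PD-normalized ratio(s) to gadolinium concentration (mmol/L).

    Builds (or reuses) a :class:`ConcentrationLookup` with the blood or
    tissue pre-contrast T1 and inverts by monotone interpolation.  Ratios
    whose inverted T1 exceeds T10 give concentration 0.
    """
    if lookup is None:
        t10 = ctx.t10_tissue if t10 is None else t10
        lookup = ConcentrationLookup(seq_sr, seq_pd, ctx, t10)
    return lookup.concentration_of_ratio(ratio)


def linear_aif_concentration(ratio, baseline_ratio, ctx: RelaxationContext,
                             t10: float, seq_sr: SequenceParams,
                             seq_pd: SequenceParams) -> np.ndarray:
    """First-order (linear) signal-to-concentration conversion for the AIF.

    Alternative to the Bloch lookup: linearizes the ratio around the
    pre-contrast baseline, using the analytic derivative of the forward
    model at T10.  Adequate at short SR times where the signal is nearly
    linear in 1/T1; the lookup path is the default.
    """
    lookup = ConcentrationLookup(seq_sr, seq_pd, ctx, t10)
    eps = 0.01  # mmol/L step for the numerical slope at baseline
    slope = (lookup.ratio_at_concentration(eps) - lookup.ratio_at_concentration(0.0)) / eps
    conc = (np.asarray(ratio, dtype=float) - baseline_ratio) / slope
    return np.clip(conc, 0.0, None)
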