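"""Synthetic ground-truth generators for every pipeline input.

Gamma-variate arterial input functions, Fermi-convolved tissue curves
encoded through the saturation-recovery forward model, MOLLI relaxation
samples, CT calcium phantoms, and two-group cohort tables with
configurable group means/SDs.  Every generator takes an explicit seed and
is deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from perfquant.perfusion import ConcentrationCurve, FermiParams, model_tissue_curve
from perfquant.signal_model import (
    AIF_SEQ,
    DEFAULT_CONTEXT,
    IMAGING_SEQ,
    PD_SEQ,
    RelaxationContext,
    SequenceParams,
    pd_signal,
    sr_signal,
)
from perfquant.t1_ecv import MolliSampleSet

__all__ = [
    "gen_aif",
    "gen_tissue_curve",
    "DynamicSeries",
    "gen_dynamic_series",
    "GroupSpec",
    "CohortSpec",
    "gen_cohort",
    "gen_molli_samples",
    "gen_ct_phantom",
    "MVD_GROUP",
    "CONTROL_GROUP",
    "default_cohort_spec",
]

# Default Fermi impulse-response shape (decay, width, delay); amplitude is
# set per pixel from the true MBF.
DEFAULT_FERMI_SHAPE = {"decay_k": 0.3, "width_w": 8.0, "delay_td": 1.0}


def gen_aif(peak: float = 5.0, t_arrival: float = 6.0, alpha: float = 2.5,
            beta: float = 1.5, times: np.ndarray | None = None,
            recirculation: float = 0.0, recirc_delay: float = 20.0,
            noise_sd: float = 0.0, seed: int = 0) -> ConcentrationCurve:
    """Gamma-variate first-pass bolus, normalized so its maximum is ``peak``.

    c(t) = peak * (tau/(alpha*beta))**alpha * exp(alpha - tau/beta) with
    tau = t - t_arrival, zero before arrival; the analytic maximum sits at
    tau = alpha*beta.  An optional recirculation bump adds a delayed,
    dispersed copy scaled by ``recirculation``.
    """
    if peak <= 0:
        raise ValueError("peak must be > 0")
    if times is None:
        times = np.arange(0.0, 50.0, 0.5)
    times = np.asarray(times, dtype=float)

    def gamma_variate(tau, a, b):
        out = np.zeros_like(tau)
        pos = tau > 0
        out[pos] = (tau[pos] / (a * b)) ** a * np.exp(a - tau[pos] / b)
        return out

    vals = peak * gamma_variate(times - t_arrival, alpha, beta)
    if recirculation > 0:
        vals = vals + recirculation * peak * gamma_variate(
            times - t_arrival - recirc_delay, alpha, 2.0 * beta)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = np.clip(vals + rng.normal(0.0, noise_sd, vals.shape), 0.0, None)
    return ConcentrationCurve(times=times, values=vals, kind="aif")


def gen_tissue_curve(aif: ConcentrationCurve, mbf: float,
                     shape: dict | None = None) -> ConcentrationCurve:
    """Tissue concentration = AIF convolved with a Fermi IRF at flow ``mbf``."""
    shape = dict(DEFAULT_FERMI_SHAPE if shape is None else shape)
    p = FermiParams.from_mbf(mbf, **shape)
    return model_tissue_curve(aif, p)


@dataclass
class DynamicSeries:
    """A simulated dual-sequence dynamic perfusion acquisition.

    ``frames`` holds the imaging-resolution series (PD frames first),
    ``aif_signals`` the low-resolution blood-pool series acquired in the
    same heartbeats (its own PD values first).  ``truth`` carries the
    ground-truth concentrations and MBF map used for generation.
    """

    frames: np.ndarray        # (n_frames, ny, nx)
    times_s: np.ndarray       # (n_frames,)
    n_pd: int
    aif_signals: np.ndarray   # (n_frames,)
    truth: dict = field(default_factory=dict)

    @property
    def pd_frames(self) -> np.ndarray:
        return self.frames[: self.n_pd]

    @property
    def dynamic_frames(self) -> np.ndarray:
        return self.frames[self.n_pd:]

    @property
    def dynamic_times(self) -> np.ndarray:
        return self.times_s[self.n_pd:]


def gen_dynamic_series(mbf_map: np.ndarray, aif: ConcentrationCurve | None = None,
                       seq_imaging: SequenceParams = IMAGING_SEQ,
                       seq_aif: SequenceParams = AIF_SEQ,
                       seq_pd: SequenceParams = PD_SEQ,
                       ctx: RelaxationContext = DEFAULT_CONTEXT,
                       snr: float = np.inf, seed: int = 0,
                       n_frames: int = 50, rr_s: float = 1.0, n_pd: int = 2,
                       fermi_shape: dict | None = None,
                       m0: float = 1.0, fine_dt: float = 0.02,
                       aif_roi_pixels: int = 64) -> DynamicSeries:
    """Forward-encode a dynamic series from a true MBF map.

    Per pixel, the tissue concentration curve is the AIF convolved with the
    Fermi impulse response at that pixel's true MBF (computed on a fine
    uniform grid, then sampled at the frame times).  Concentrations map to
    effective T1 through the relaxivity relation and to signal through the
    saturation-recovery model; the first ``n_pd`` heartbeats are
    proton-density frames.  Gaussian noise is added at the stated SNR
    (reference level = mean PD signal); ``snr=inf`` disables noise.
    """
    mbf_map = np.asarray(mbf_map, dtype=float)
    if mbf_map.ndim != 2:
        raise ValueError("mbf_map must be 2-D")
    times = rr_s * np.arange(n_frames)
    dyn_times = times[n_pd:]
    fine_times = np.arange(0.0, times[-1] + fine_dt, fine_dt)
    if aif is None:
        aif = gen_aif(times=fine_times)
    else:
        aif = ConcentrationCurve(times=fine_times,
                                 values=np.interp(fine_times, aif.times, aif.values),
                                 kind="aif")

    shape = dict(DEFAULT_FERMI_SHAPE if fermi_shape is None else fermi_shape)
    ny, nx = mbf_map.shape
    tissue_conc = np.zeros((dyn_times.size, ny, nx))
    for val in np.unique(mbf_map):
        sel = mbf_map == val
        if val <= 0:
            continue
        fine_ct = gen_tissue_curve(aif, float(val), shape)
        ct = np.interp(dyn_times, fine_ct.times, fine_ct.values)
        tissue_conc[:, sel] = ct[:, None]

    aif_conc = np.interp(dyn_times, aif.times, aif.values)

    # encode: concentration -> T1 -> signal
    t1_tissue = ctx.t1_of_concentration(tissue_conc, ctx.t10_tissue)
    sr_frames = sr_signal(t1_tissue, seq_imaging, m0=m0)
    pd_level = float(pd_signal(np.asarray([ctx.t10_tissue]), seq_pd, m0=m0)[0])
    pd_frames = np.full((n_pd, ny, nx), pd_level)

    t1_blood = ctx.t1_of_concentration(aif_conc, ctx.t10_blood)
    aif_sr = sr_signal(t1_blood, seq_aif, m0=m0)
    aif_pd = float(pd_signal(np.asarray([ctx.t10_blood]), seq_pd, m0=m0)[0])

    frames = np.concatenate([pd_frames, sr_frames], axis=0)
    aif_signals = np.concatenate([np.full(n_pd, aif_pd), aif_sr])

    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        # SNR is referenced to the peak-enhancement tissue signal (the
        # conventional image-SNR definition for first-pass perfusion).
        sigma = float(np.max(sr_frames)) / snr if np.max(sr_frames) > 0 \
            else pd_level / snr
        frames = frames + rng.normal(0.0, sigma, frames.shape)
        # The AIF curve is an ROI mean over the blood pool, so its noise is
        # reduced by sqrt(ROI size) relative to a single pixel.
        aif_sigma = float(np.max(aif_sr)) / snr / np.sqrt(max(aif_roi_pixels, 1))
        aif_signals = aif_signals + rng.normal(0.0, aif_sigma, aif_signals.shape)
        frames = np.abs(frames)
        aif_signals = np.abs(aif_signals)

    truth = {
        "mbf_map": mbf_map.copy(),
        "tissue_conc": tissue_conc,
        "aif_conc": ConcentrationCurve(times=dyn_times, values=aif_conc, kind="aif"),
        "fermi_shape": shape,
        "snr": snr,
    }
    return DynamicSeries(frames=frames, times_s=times, n_pd=n_pd,
                         aif_signals=aif_signals, truth=truth)


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class GroupSpec:
    """Distributional description of one study group.

    Continuous variables are (mean, sd) normal draws truncated at
    physiologic floors; flags are Bernoulli fractions.  CAC is a mixture of
    a point mass at zero and a lognormal tail; set ``acquire_cac=False``
    for groups that did not undergo CT.
    """

    name: str
    n: int
    rest_mbf: tuple[float, float] = (1.15, 0.28)
    stress_mbf: tuple[float, float] = (2.65, 0.62)
    age: tuple[float, float] = (57.5, 11.2)
    bmi: tuple[float, float] = (31.3, 6.0)
    lv_mass: tuple[float, float] = (78.0, 23.0)
    lvef: tuple[float, float] = (61.2, 6.7)
    ecv: tuple[float, float] = (0.266, 0.029)
    native_t1: tuple[float, float] = (988.0, 42.0)
    hct: tuple[float, float] = (0.41, 0.04)
    # within-subject correlation of rest and stress flow draws; keeps the
    # implied MPR dispersion near the observed interquartile ranges
    rest_stress_corr: float = 0.7
    female_fraction: float = 0.74
    diabetes_fraction: float = 0.80
    htn_fraction: float = 0.80
    hld_fraction: float = 0.87
    smoking_fraction: float = 0.54
    acquire_cac: bool = True
    cac_zero_fraction: float = 0.57
    # lognormal tail kept essentially above 1 so the zero-mass fraction is
    # also the fraction of scores below 1
    cac_lognormal: tuple[float, float] = (2.5, 1.2)  # (mu, sigma) of log score

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for fname in ("female_fraction", "diabetes_fraction", "htn_fraction",
                      "hld_fraction", "smoking_fraction", "cac_zero_fraction"):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{fname} must be in [0, 1]")
        for fname in ("rest_mbf", "stress_mbf", "age", "bmi", "lv_mass",
                      "lvef", "ecv", "native_t1", "hct"):
            if getattr(self, fname)[1] < 0:
                raise ValueError(f"{fname} SD must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    seed: int = 0


# Defaults shaped after the study design: a risk-factor group of 46 and 20
# healthy controls, with group-level flow/tissue parameters as configured
# values (not code constants used for validation).
MVD_GROUP = GroupSpec(name="mvd_risk", n=46)
CONTROL_GROUP = GroupSpec(
    name="control", n=20,
    rest_mbf=(1.11, 0.23), stress_mbf=(3.17, 0.49),
    age=(53.4, 11.9), bmi=(24.3, 3.6), lv_mass=(70.0, 23.0),
    lvef=(59.7, 4.3), ecv=(0.271, 0.022), native_t1=(987.0, 35.0),
    female_fraction=0.60, diabetes_fraction=0.0, htn_fraction=0.05,
    hld_fraction=0.05, smoking_fraction=0.05, acquire_cac=False,
)


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    return CohortSpec(groups=(MVD_GROUP, CONTROL_GROUP), seed=seed)


_FLOORS = {
    "rest_mbf": 0.2, "stress_mbf": 0.3, "age": 18.0, "bmi": 14.0,
    "lv_mass": 30.0, "lvef": 20.0, "ecv": 0.05, "native_t1": 500.0,
    "hct": 0.15,
}


def _truncated_normal(rng, mean, sd, n, floor):
    vals = rng.normal(mean, sd, n)
    return np.maximum(vals, floor)


def gen_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort table and its ground truth from a :class:`CohortSpec`.

    Returns ``(table, truth)``: the observable cohort table (one row per
    subject) and a ground-truth frame with the true per-subject flows and
    MPR.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for g in spec.groups:
        n = g.n
        draws = {var: _truncated_normal(rng, *getattr(g, var), n=n,
                                        floor=_FLOORS[var])
                 for var in ("age", "bmi", "lv_mass",
                             "lvef", "ecv", "native_t1", "hct")}
        # correlated rest/stress flows (shared vasomotor factor)
        rho = float(np.clip(g.rest_stress_corr, -1.0, 1.0))
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + np.sqrt(1.0 - rho ** 2) * rng.standard_normal(n)
        draws["rest_mbf"] = np.maximum(
            g.rest_mbf[0] + g.rest_mbf[1] * z1, _FLOORS["rest_mbf"])
        draws["stress_mbf"] = np.maximum(
            g.stress_mbf[0] + g.stress_mbf[1] * z2, _FLOORS["stress_mbf"])
        female = rng.random(n) < g.female_fraction
        diabetes = rng.random(n) < g.diabetes_fraction
        htn = rng.random(n) < g.htn_fraction
        hld = rng.random(n) < g.hld_fraction
        smoking = rng.random(n) < g.smoking_fraction
        if g.acquire_cac:
            zero = rng.random(n) < g.cac_zero_fraction
            tail = np.exp(rng.normal(*g.cac_lognormal, n))
            cac = np.where(zero, 0.0, tail)
        else:
            cac = np.full(n, np.nan)
        for i in range(n):
            rows.append({
                "subject_id": f"{g.name}_{i:03d}",
                "group": g.name,
                "age": draws["age"][i],
                "female": bool(female[i]),
                "bmi": draws["bmi"][i],
                "diabetes": bool(diabetes[i]),
                "htn": bool(htn[i]),
                "hld": bool(hld[i]),
                "smoking": bool(smoking[i]),
                "lv_mass": draws["lv_mass"][i],
                "lvef": draws["lvef"][i],
                "rest_mbf": draws["rest_mbf"][i],
                "stress_mbf": draws["stress_mbf"][i],
                "mpr": draws["stress_mbf"][i] / draws["rest_mbf"][i],
                "native_t1": draws["native_t1"][i],
                "ecv": draws["ecv"][i],
                "hct": draws["hct"][i],
                "cac": cac[i],
            })
    table = pd.DataFrame(rows)
    truth_cols = ["subject_id", "group", "rest_mbf", "stress_mbf", "mpr",
                  "native_t1", "ecv", "cac"]
    truth = table[truth_cols].copy() if len(table) else pd.DataFrame(
        columns=truth_cols)
    truth = truth.rename(columns={c: f"true_{c}" for c in truth_cols
                                  if c not in ("subject_id", "group")})
    return table, truth


# ---------------------------------------------------------------------------
# MOLLI and CT generators


def molli_543_inversion_times(rr_ms: float = 1000.0, ti1_ms: float = 100.0,
                              ti2_ms: float = 180.0) -> np.ndarray:
    """Inversion times of the 5(4)3 scheme: 5 beats sampled, 4 recovery,
    3 sampled in a second inversion experiment."""
    first = ti1_ms + rr_ms * np.arange(5)
    second = ti2_ms + rr_ms * np.arange(3)
    return np.concatenate([first, second])


def gen_molli_samples(t1: float, a: float = 1.0, b_over_a: float = 1.9,
                      rr_ms: float = 1000.0, noise_sd: float = 0.0,
                      seed: int = 0) -> MolliSampleSet:
    """Simulate magnitude MOLLI samples at true (Look-Locker-corrected) T1.

    Uses the apparent-relaxation model s(TI) = |A - B exp(-TI/T1*)| with
    T1* = T1 / (B/A - 1), so the fit's corrected T1 equals the requested
    value.  ``b_over_a`` encodes inversion efficiency and readout-driven
    apparent shortening.
    """
    if t1 <= 0:
        raise ValueError("t1 must be > 0")
    if b_over_a <= 1.0:
        raise ValueError("b_over_a must be > 1")
    ti = molli_543_inversion_times(rr_ms=rr_ms)
    t1_star = t1 / (b_over_a - 1.0)
    signed = a - (b_over_a * a) * np.exp(-ti / t1_star)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signed = signed + rng.normal(0.0, noise_sd, signed.shape)
    return MolliSampleSet(inversion_times=ti, signals=np.abs(signed))


def gen_ct_phantom(lesions: list[tuple[int, float, float]],
                   shape: tuple[int, int, int] = (3, 64, 64),
                   pixel_spacing: tuple[float, float] = (1.0, 1.0),
                   slice_thickness: float = 3.0,
                   background_hu: float = 0.0,
                   noise_sd: float = 0.0, seed: int = 0):
    """CT phantom with rectangular calcium lesions of known area and HU.

    ``lesions`` is a list of (slice_index, area_mm2, peak_hu); each lesion
    is painted as a compact 4-connected block whose pixel count best
    matches the requested area.  Lesions are laid out on a grid with
    generous separation so they never merge.
    """
    from perfquant.calcium import CtVolume

    vol = np.full(shape, background_hu, dtype=float)
    pix_area = pixel_spacing[0] * pixel_spacing[1]
    per_slice_count: dict[int, int] = {}
    for z, area_mm2, peak_hu in lesions:
        n_pix = max(1, int(round(area_mm2 / pix_area)))
        width = int(np.ceil(np.sqrt(n_pix)))
        k = per_slice_count.get(z, 0)
        per_slice_count[z] = k + 1
        stride = width + 6
        ncols = max((shape[2] - 8) // stride, 1)
        row0 = 4 + (k // ncols) * stride
        col0 = 4 + (k % ncols) * stride
        if row0 + width >= shape[1] or col0 + width >= shape[2]:
            raise ValueError("phantom too small for requested lesions")
        placed = 0
        for r in range(width):
            for c in range(width):
                if placed >= n_pix:
                    break
                vol[z, row0 + r, col0 + c] = peak_hu
                placed += 1
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, noise_sd, vol.shape)
    return CtVolume(voxels=vol, pixel_spacing=pixel_spacing,
                    slice_thickness=slice_thickness)
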