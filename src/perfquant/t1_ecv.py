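"""MOLLI T1 estimation, gadolinium partition coefficient, and ECV.

Magnitude inversion-recovery samples are fitted with the three-parameter
apparent-relaxation model |A - B exp(-TI/T1*)| with exhaustive polarity
restoration, followed by the Look-Locker correction T1 = T1* (B/A - 1).
The partition coefficient lambda is the ordinary least-squares slope of
1/T1(myocardium) on 1/T1(blood) across serial pre/post-contrast pairs, and
ECV = lambda * (1 - hematocrit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

__all__ = [
    "MolliSampleSet",
    "MolliFit",
    "T1Pair",
    "EcvResult",
    "fit_molli",
    "partition_coefficient",
    "compute_ecv",
]


@dataclass(frozen=True)
class MolliSampleSet:
    """Inversion-time / magnitude-signal samples from one MOLLI acquisition."""

    inversion_times: np.ndarray  # ms
    signals: np.ndarray          # magnitude intensities
    scheme: str = "5(4)3"

    def __post_init__(self) -> None:
        ti = np.asarray(self.inversion_times, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        order = np.argsort(ti)
        object.__setattr__(self, "inversion_times", ti[order])
        object.__setattr__(self, "signals", s[order])
        if ti.size < 6:
            raise ValueError("need at least 6 MOLLI samples")
        if np.any(ti <= 0):
            raise ValueError("inversion times must be positive")
        if ti.shape != s.shape:
            raise ValueError("inversion_times and signals must match in length")


@dataclass(frozen=True)
class MolliFit:
    t1: float        # ms, Look-Locker corrected
    t1_star: float   # ms, apparent
    a: float
    b: float
    residual_norm: float
    valid: bool


@dataclass(frozen=True)
class T1Pair:
    """Matched myocardial / blood T1 at one contrast timepoint."""

    t1_myo: float
    t1_blood: float
    timepoint: str = "native"

    def __post_init__(self) -> None:
        if self.t1_myo <= 0 or self.t1_blood <= 0:
            raise ValueError("T1 values must be positive")


@dataclass(frozen=True)
class EcvResult:
    lam: float
    hematocrit: float
    ecv: float
    fit_r2: float


def _three_param_fit(ti: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, float]:
    """Fit s ~ A - B exp(-TI/T1*) by least squares; returns (A, B, T1*), cost."""
    a0 = float(np.max(np.abs(s)))
    b0 = 2.0 * a0 if a0 > 0 else 1.0
    t0 = float(np.median(ti))

    def resid(theta):
        a, b, t1s = theta
        return a - b * np.exp(-ti / t1s) - s

    res = least_squares(resid, x0=[a0 if a0 > 0 else 1.0, b0, max(t0, 1.0)],
                        bounds=([-np.inf, -np.inf, 1.0], [np.inf, np.inf, 1e5]),
                        xtol=1e-14, ftol=1e-14, max_nfev=2000)
    return res.x, float(np.linalg.norm(res.fun))


def fit_molli(samples: MolliSampleSet) -> MolliFit:
    """Estimate T1 from magnitude MOLLI samples.

    Tries every polarity-restoration candidate (negating the first ``i``
    samples in inversion-time order), keeps the best-residual fit, and
    applies the Look-Locker correction.  Degenerate inputs (constant
    signal, A <= 0, or non-positive corrected T1) are flagged invalid.
    """
    ti = samples.inversion_times
    s = samples.signals
    if np.allclose(s, s[0]):
        return MolliFit(t1=np.nan, t1_star=np.nan, a=np.nan, b=np.nan,
                        residual_norm=np.inf, valid=False)
    best: tuple[np.ndarray, float] | None = None
    for flip in range(ti.size + 1):
        signed = s.copy()
        signed[:flip] = -signed[:flip]
        try:
            theta, cost = _three_param_fit(ti, signed)
        except Exception:
            continue
        if best is None or cost < best[1]:
            best = (theta, cost)
    if best is None:
        return MolliFit(t1=np.nan, t1_star=np.nan, a=np.nan, b=np.nan,
                        residual_norm=np.inf, valid=False)
    (a, b, t1_star), cost = best
    if a <= 0 or b / a <= 1.0:
        return MolliFit(t1=np.nan, t1_star=float(t1_star), a=float(a),
                        b=float(b), residual_norm=cost, valid=False)
    t1 = t1_star * (b / a - 1.0)
    return MolliFit(t1=float(t1), t1_star=float(t1_star), a=float(a),
                    b=float(b), residual_norm=cost, valid=True)


def partition_coefficient(pairs: list[T1Pair]) -> tuple[float, float]:
    """OLS slope of 1/T1(myo) on 1/T1(blood) across timepoints.

    Returns (lambda, R^2).  At exactly two pairs this reduces to the
    two-point difference quotient.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 T1 pairs")
    x = np.array([1.0 / p.t1_blood for p in pairs])
    y = np.array([1.0 / p.t1_myo for p in pairs])
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct blood T1 values")
    if len(pairs) == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        return float(slope), 1.0
    fit = linregress(x, y)
    return float(fit.slope), float(fit.rvalue ** 2)


def compute_ecv(lam: float, hct: float) -> float:
    """Extracellular volume fraction: lambda * (1 - hematocrit)."""
    if not 0.0 < hct < 1.0:
        raise ValueError(f"hematocrit must be in (0, 1), got {hct}")
    if lam <= 0:
        raise ValueError(f"lambda must be > 0, got {lam}")
    return lam * (1.0 - hct)
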