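"""Agatston coronary calcium scoring and CAC-based cohort stratification."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["CtVolume", "LesionScore", "agatston_score", "cac_stratify"]

HU_THRESHOLD = 130.0

# classic density weights keyed by peak-HU band lower edges
_WEIGHT_EDGES = np.array([130.0, 200.0, 300.0, 400.0])


@dataclass(frozen=True)
class CtVolume:
    """Non-contrast CT volume in Hounsfield units.

    ``voxels`` is (n_slices, rows, cols); spacings in mm.
    """

    voxels: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_thickness: float = 3.0

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        object.__setattr__(self, "voxels", vox)
        if vox.ndim != 3:
            raise ValueError("voxels must be a 3-D (slice, row, col) array")
        if any(s <= 0 for s in self.pixel_spacing) or self.slice_thickness <= 0:
            raise ValueError("spacings must be positive")

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.pixel_spacing[0] * self.pixel_spacing[1])


@dataclass(frozen=True)
class LesionScore:
    slice_index: int
    area_mm2: float
    peak_hu: float
    weight: int
    score: float


def _density_weight(peak_hu: float) -> int:
    """1 for 130-199 HU, 2 for 200-299, 3 for 300-399, 4 for >= 400."""
    return int(np.searchsorted(_WEIGHT_EDGES, peak_hu, side="right"))


def agatston_score(vol: CtVolume, min_area_mm2: float = 1.0
                   ) -> tuple[float, list[LesionScore]]:
    """Total Agatston score and the per-lesion breakdown.

    Per slice: threshold at 130 HU, extract 4-connected components, drop
    lesions smaller than ``min_area_mm2``, and score each as
    area (mm^2) x density weight.  No 3-D merging across slices.
    """
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    area = vol.pixel_area_mm2
    lesions: list[LesionScore] = []
    for z in range(vol.voxels.shape[0]):
        sl = vol.voxels[z]
        mask = sl >= HU_THRESHOLD
        if not mask.any():
            continue
        labels, n = ndimage.label(mask, structure=structure)
        for comp in range(1, n + 1):
            comp_mask = labels == comp
            lesion_area = float(comp_mask.sum()) * area
            if lesion_area < min_area_mm2:
                continue
            peak = float(sl[comp_mask].max())
            w = _density_weight(peak)
            lesions.append(LesionScore(slice_index=z, area_mm2=lesion_area,
                                       peak_hu=peak, weight=w,
                                       score=lesion_area * w))
    total = float(sum(l.score for l in lesions))
    return total, lesions


def cac_stratify(table: pd.DataFrame, threshold: float | None = None,
                 cac_column: str = "cac") -> pd.Series:
    """Label subjects ``low``/``high`` around a CAC threshold.

    Uses the cohort median when ``threshold`` is None; subjects with CAC
    <= threshold are "low", the rest "high".
    """
    if cac_column not in table.columns:
        raise ValueError(f"missing column {cac_column!r}")
    cac = pd.to_numeric(table[cac_column], errors="coerce")
    if cac.isna().all():
        raise ValueError("all CAC values missing")
    if threshold is None:
        threshold = float(cac.median())
    labels = pd.Series(np.where(cac <= threshold, "low", "high"),
                       index=table.index, name="cac_stratum")
    labels[cac.isna()] = pd.NA
    return labels
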