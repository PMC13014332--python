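"""ROI statistics and contrast metrics (CNR, LBR, agent fold ratios).

The contrast-to-noise ratio between tumor and contralateral brain ROIs,

    CNR = (m_tumor - m_brain) / sqrt(sd_tumor^2 + sd_brain^2),

is computed identically on post-injection T1w signal and on post-
injection CEST ST% maps.  The lesion-to-brain ratio is the ratio of ROI
means: SI_tumor/SI_brain on post-injection T1w, dST_tumor/dST_brain on
the difference contrast map.  Agent comparisons report the fold ratios
oriented so both exceed 1 for the gadolinium-vs-iodine comparison
(gadolinium wins on CNR, the iodinated agent on LBR).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

from .zspec import ContrastMap, MapKind

__all__ = [
    "Modality",
    "ROISet",
    "ROIStats",
    "ContrastComparison",
    "roi_stats",
    "compute_cnr",
    "compute_lbr",
    "compare_agents",
]

#: LBR denominators below this (percent dST or signal units) are unstable
LBR_FLOOR = 0.05


class Modality(str, enum.Enum):
    T1W_POST = "T1W_POST"
    CEST_DELTA = "CEST_DELTA"


@dataclass
class ROISet:
    """Named binary ROI masks on a shared grid; requires tumor and brain."""

    masks: dict

    def __post_init__(self) -> None:
        for name in ("tumor", "brain"):
            if name not in self.masks:
                raise ValueError(f"ROISet is missing required mask {name!r}")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) != 1:
            raise ValueError("ROI masks are not on a shared grid")
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}
        for name, m in self.masks.items():
            if not m.any():
                raise ValueError(f"ROI {name!r} is empty")
        if (self.masks["tumor"] & self.masks["brain"]).any():
            raise ValueError("tumor and brain ROIs overlap")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]


@dataclass(frozen=True)
class ROIStats:
    """Mean and sample standard deviation of a map over one ROI."""

    roi_name: str
    map_kind: str
    n_voxels: int
    mean: float
    sd: float


def _values_and_mask(map_or_volume):
    if isinstance(map_or_volume, ContrastMap):
        return map_or_volume.values, map_or_volume.valid_mask, map_or_volume.kind.value
    vol = np.asarray(map_or_volume, dtype=float)
    return vol, np.isfinite(vol), "volume"


def roi_stats(map_or_volume, roi: np.ndarray, roi_name: str = "roi") -> ROIStats:
    """Summary statistics over the ROI, restricted to valid voxels.

    Uses the sample (n-1) standard deviation.  Raises when the ROI has
    no valid voxel.
    """
    values, valid, kind = _values_and_mask(map_or_volume)
    sel = np.asarray(roi, dtype=bool) & valid
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"ROI {roi_name!r} contains no valid voxels")
    v = values[sel]
    sd = float(np.std(v, ddof=1)) if n > 1 else 0.0
    return ROIStats(roi_name, kind, n, float(np.mean(v)), sd)


def compute_cnr(tumor: ROIStats, brain: ROIStats) -> float:
    """Tumor-vs-brain contrast-to-noise ratio.

    (mean_tumor - mean_brain) / sqrt(sd_tumor^2 + sd_brain^2); an error
    when both spreads are zero (no noise scale to compare against).
    """
    if tumor.map_kind != brain.map_kind:
        raise ValueError(
            f"CNR inputs from different maps: {tumor.map_kind} vs {brain.map_kind}"
        )
    denom = float(np.hypot(tumor.sd, brain.sd))
    if denom == 0.0:
        raise ValueError("degenerate CNR: both ROI standard deviations are zero")
    return (tumor.mean - brain.mean) / denom


def compute_lbr(map_: ContrastMap, rois: ROISet, modality: Modality) -> float:
    """Lesion-to-brain ratio of ROI means for the stated modality.

    CEST_DELTA requires a dST map; T1W_POST takes a raw post-injection
    signal volume (pass it wrapped or use roi means directly).  Returns
    NaN with a warning when the brain-ROI mean is below the positivity
    floor (0.05), where the ratio is numerically meaningless.
    """
    modality = Modality(modality)
    if isinstance(map_, ContrastMap):
        if modality is Modality.CEST_DELTA and map_.kind is not MapKind.DELTA_ST:
            raise ValueError(f"CEST_DELTA LBR requires a DELTA_ST map, got {map_.kind}")
        if modality is Modality.T1W_POST and map_.kind is MapKind.DELTA_ST:
            raise ValueError("T1W_POST LBR cannot use a DELTA_ST map")
    t = roi_stats(map_, rois["tumor"], "tumor")
    b = roi_stats(map_, rois["brain"], "brain")
    if b.mean <= LBR_FLOOR:
        warnings.warn(
            f"brain-ROI mean {b.mean:.4g} at or below positivity floor "
            f"{LBR_FLOOR}; LBR reported as NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return t.mean / b.mean


def _round_half_even(x: float, decimals: int) -> float:
    return float(np.round(x, decimals))


@dataclass(frozen=True)
class ContrastComparison:
    """Head-to-head agent comparison via CNR and LBR fold ratios."""

    cnr_iop: float
    cnr_gd: float
    lbr_iop: float
    lbr_gd: float
    cnr_fold: float
    lbr_fold: float
    rounding: int = 1

    @property
    def cnr_fold_rounded(self) -> float:
        return _round_half_even(self.cnr_fold, self.rounding)

    @property
    def lbr_fold_rounded(self) -> float:
        return _round_half_even(self.lbr_fold, self.rounding)


def compare_agents(
    cnr_iop: float, cnr_gd: float, lbr_iop: float, lbr_gd: float
) -> ContrastComparison:
    """Fold ratios between agents: CNR as Gd/iodine, LBR as iodine/Gd.

    The orientation puts the stronger agent in the numerator for each
    metric (gadolinium dominates CNR, the iodinated agent dominates
    LBR), so the reported folds are > 1 in the regime of interest.
    """
    vals = (cnr_iop, cnr_gd, lbr_iop, lbr_gd)
    if not all(np.isfinite(v) and v > 0 for v in vals):
        raise ValueError("compare_agents requires finite positive inputs")
    return ContrastComparison(
        cnr_iop=cnr_iop,
        cnr_gd=cnr_gd,
        lbr_iop=lbr_iop,
        lbr_gd=lbr_gd,
        cnr_fold=cnr_gd / cnr_iop,
        lbr_fold=lbr_iop / lbr_gd,
    )
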