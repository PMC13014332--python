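"""Segmentation-overlap metrics and reader-agreement ICC.

Overlap between two tumor segmentations (e.g. one drawn on the
post-injection CEST contrast, one on the post-injection T1w image) is
summarized by the Tanimoto coefficient (intersection over union, as a
percentage), the Dice similarity coefficient 2|A&B|/(|A|+|B|), and the
volume similarity min(|A|,|B|)/max(|A|,|B|).  Tanimoto and Dice obey
D = 2T/(1+T) with T as a fraction.

Reader agreement on numeric measurements (subjects x raters tables) is
quantified by the two-way random-effects, absolute-agreement,
single-measurement intraclass correlation ICC(2,1) and bucketed as
poor (<=0.2), fair (0.2-0.4], moderate (0.4-0.6], good (0.6-0.8] or
excellent (>0.8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MaskPair",
    "OverlapReport",
    "AgreementReport",
    "tanimoto",
    "dice",
    "volume_ratio",
    "overlap_report",
    "icc",
    "categorize_icc",
]

ICC_CATEGORIES = (
    (0.2, "poor"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "good"),
)


@dataclass
class MaskPair:
    """Two binary segmentations on a shared voxel grid."""

    mask_a: np.ndarray
    mask_b: np.ndarray
    label_a: str = "a"
    label_b: str = "b"

    def __post_init__(self) -> None:
        self.mask_a = np.asarray(self.mask_a, dtype=bool)
        self.mask_b = np.asarray(self.mask_b, dtype=bool)
        if self.mask_a.shape != self.mask_b.shape:
            raise ValueError(
                f"mask grids differ: {self.mask_a.shape} vs {self.mask_b.shape}"
            )

    @property
    def counts(self) -> tuple[int, int, int]:
        """(|A|, |B|, |A & B|)."""
        return (
            int(self.mask_a.sum()),
            int(self.mask_b.sum()),
            int((self.mask_a & self.mask_b).sum()),
        )


@dataclass(frozen=True)
class OverlapReport:
    tanimoto_pct: float
    dice: float
    volume_ratio: float
    label_a: str = "a"
    label_b: str = "b"


def tanimoto(pair: MaskPair) -> float:
    """Overlapping percentage: |A & B| / |A | B| * 100."""
    a, b, inter = pair.counts
    union = a + b - inter
    if union == 0:
        raise ValueError("tanimoto undefined: both masks are empty")
    return inter / union * 100.0


def dice(pair: MaskPair) -> float:
    """Dice similarity coefficient 2|A & B| / (|A| + |B|), in [0, 1]."""
    a, b, inter = pair.counts
    if a + b == 0:
        raise ValueError("dice undefined: both masks are empty")
    return 2.0 * inter / (a + b)


def volume_ratio(pair: MaskPair, signed: bool = False) -> float:
    """Volume similarity min(|A|, |B|) / max(|A|, |B|), in (0, 1].

    ``signed=True`` instead returns 1 - |VA - VB|/(VA + VB), an
    alternative volume-similarity convention.
    """
    a, b, _ = pair.counts
    if a == 0 or b == 0:
        raise ValueError("volume_ratio undefined: a mask is empty")
    if signed:
        return 1.0 - abs(a - b) / (a + b)
    return min(a, b) / max(a, b)


def overlap_report(pair: MaskPair) -> OverlapReport:
    return OverlapReport(
        tanimoto_pct=tanimoto(pair),
        dice=dice(pair),
        volume_ratio=volume_ratio(pair),
        label_a=pair.label_a,
        label_b=pair.label_b,
    )


@dataclass(frozen=True)
class AgreementReport:
    icc: float
    category: str
    n_subjects: int
    n_raters: int
    form: str = "ICC(2,1) two-way random, absolute agreement, single measurement"


def categorize_icc(value: float) -> str:
    """Agreement category for an ICC value (right-closed intervals)."""
    if not (-1.0 <= value <= 1.0):
        raise ValueError(f"ICC must lie in [-1, 1], got {value}")
    for upper, label in ICC_CATEGORIES:
        if value <= upper:
            return label
    return "excellent"


def _validate_table(table) -> pd.DataFrame:
    df = pd.DataFrame(table)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("rating table needs >= 2 subjects and >= 2 raters")
    if df.isna().any().any():
        raise ValueError("rating table has missing cells")
    return df.astype(float)


def icc(table) -> AgreementReport:
    """ICC(2,1) agreement for a subjects-by-raters measurement table.

    Rows are subjects, columns raters (or repeated analyses by one
    reader).  Computed through the two-way ANOVA decomposition
    (pingouin's ICC2); degenerate tables with zero total variance are
    rejected.
    """
    import pingouin as pg

    df = _validate_table(table)
    n, k = df.shape
    if float(df.to_numpy().std()) == 0.0:
        raise ValueError("degenerate rating table: zero total variance")
    long = df.reset_index(drop=True).reset_index(names="subject").melt(
        id_vars="subject", var_name="rater", value_name="score"
    )
    res = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
    by_type = res.set_index("Type")["ICC"]
    # two-way random, absolute agreement, single measurement; label varies
    # across pingouin versions ("ICC2" vs "ICC(A,1)")
    key = "ICC(A,1)" if "ICC(A,1)" in by_type.index else "ICC2"
    value = float(by_type[key])
    value = float(np.clip(value, -1.0, 1.0))
    return AgreementReport(
        icc=value, category=categorize_icc(value), n_subjects=n, n_raters=k
    )
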