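"""Saturation-offset schedules and their TSV sidecars.

An acquisition schedule is an ordered list of saturation offsets in ppm
plus exactly one unsaturated reference entry used for normalization.
The default schedule mimics a preclinical iodinated-CEST protocol:
46 saturation offsets unevenly spaced within +/-10 ppm, sampled densely
around the water resonance and across the amide band (3.4-6.0 ppm, both
signs, so the asymmetry at 4.2 ppm is interpolable), coarsely elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["OffsetSchedule", "default_schedule"]

#: Sentinel offset for the unsaturated reference acquisition (far off-resonance).
REFERENCE_OFFSET = 300.0


@dataclass(frozen=True)
class OffsetSchedule:
    """Ordered saturation offsets with a single reference entry.

    ``offsets`` and ``is_reference`` have equal length and acquisition
    order.  Non-reference offsets must lie within [-10, +10] ppm.
    """

    offsets: np.ndarray
    is_reference: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "offsets", np.asarray(self.offsets, dtype=float))
        object.__setattr__(self, "is_reference", np.asarray(self.is_reference, dtype=bool))
        if self.offsets.shape != self.is_reference.shape or self.offsets.ndim != 1:
            raise ValueError("offsets and is_reference must be 1-D and equal length")
        if int(self.is_reference.sum()) != 1:
            raise ValueError("schedule must contain exactly one reference entry")
        sat = self.saturation_offsets
        if sat.size and (np.abs(sat) > 10.0 + 1e-9).any():
            raise ValueError("saturation offsets must lie within [-10, +10] ppm")

    @property
    def saturation_offsets(self) -> np.ndarray:
        """Offsets of the saturated acquisitions, acquisition order."""
        return self.offsets[~self.is_reference]

    @property
    def n_saturated(self) -> int:
        return int((~self.is_reference).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset_ppm": self.offsets, "is_reference": self.is_reference.astype(int)}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "OffsetSchedule":
        df = pd.read_csv(path, sep="\t")
        return cls(df["offset_ppm"].to_numpy(), df["is_reference"].to_numpy().astype(bool))


def default_schedule() -> OffsetSchedule:
    """46 unevenly spaced saturation offsets in +/-10 ppm plus one reference.

    Dense 0.25 ppm sampling in [-1, 1] (water line, B0 estimation),
    0.2 ppm across +/-(3.4-6.0) ppm (amide band and its mirror), coarse
    points out to +/-10 ppm.  The reference is acquired first.
    """
    inner = np.array([0.125, 0.25, 0.5, 0.75, 1.0])         # 10 with mirror
    band = np.arange(3.4, 6.0 + 1e-9, 0.2)                  # 14 each sign
    coarse = np.array([1.5, 2.5, 7.0, 10.0])                # 8 with mirror
    half = np.concatenate([inner, band, coarse])
    sat = np.round(np.sort(np.concatenate([-half, half])), 6)
    assert sat.size == 46
    offsets = np.concatenate([[REFERENCE_OFFSET], sat])
    is_ref = np.zeros(offsets.size, dtype=bool)
    is_ref[0] = True
    return OffsetSchedule(offsets, is_ref)
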