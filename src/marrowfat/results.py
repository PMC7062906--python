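"""Result container shared by the two quantification procedures."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True)
class MarrowFatResult:
    """Aggregate bone-marrow-fat estimate from one procedure.

    Attributes
    ----------
    method : str
        ``"T1"`` or ``"IDEAL"``.
    per_slice : DataFrame
        One row per analyzed slice; columns carry units in their names.
    bmff : float
        Bone marrow fat fraction in percent (aggregate over slices).
    bmfv : float
        Bone marrow fat volume in cm³.
    slice_range : tuple
        Half-open (start, stop) of the analyzed slices.
    slice_extent_cm : float
        Axial extent per slice (thickness + gap) used for volumes.
    aggregation : str
        ``"slice-mean"`` (default) or ``"area-weighted"`` BMFF rule.
    excluded_slices : tuple
        Slices in range that were skipped (empty marrow mask).
    """

    method: str
    per_slice: pd.DataFrame
    bmff: float
    bmfv: float
    slice_range: tuple[int, int]
    slice_extent_cm: float
    aggregation: str = "slice-mean"
    excluded_slices: tuple[int, ...] = field(default_factory=tuple)

    @property
    def n_slices(self) -> int:
        return len(self.per_slice)

    def summary(self) -> str:
        """Plain-text summary table."""
        lines = [
            f"Bone marrow fat quantification ({self.method})",
            "=" * 46,
            f"slices analyzed          {self.n_slices}"
            f"  (range {self.slice_range[0]}..{self.slice_range[1] - 1})",
            f"axial extent per slice   {self.slice_extent_cm:.3f} cm",
            f"BMFF ({self.aggregation:>13s})  {self.bmff:8.2f} %",
            f"BMFV                     {self.bmfv:8.3f} cm3",
            f"mean marrow area         "
            f"{self.per_slice['marrow_area_cm2'].mean():8.3f} cm2/slice",
        ]
        if self.excluded_slices:
            lines.append(f"excluded slices          {list(self.excluded_slices)}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<MarrowFatResult method={self.method} bmff={self.bmff:.2f}% "
                f"bmfv={self.bmfv:.3f}cm3 n_slices={self.n_slices}>")
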