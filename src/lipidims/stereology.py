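"""Cavalieri volume estimation from point-count grids.

With systematic sections a known distance apart and a point grid of known
area per point superimposed on each section, the unbiased volume estimate is

    V = (sum of points over sections) x area_per_point x section_spacing.

The default grid assigns 9000 um^2 per point; spacing is the distance between
analysed sections (sampling interval x 5 um section thickness) and is an
input, not a constant.  PCNA-positive percentages are plain count ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "SectionGrid",
    "cavalieri_volume",
    "pcna_positive_fraction",
    "relative_volume",
    "volumes_from_table",
]

UM3_PER_MM3 = 1e9


@dataclass(frozen=True)
class SectionGrid:
    """Point counts for one analysed section of one region."""

    section_index: int
    point_count: int
    area_per_point_um2: float = 9000.0
    spacing_um: float = 50.0

    def __post_init__(self):
        if self.point_count < 0:
            raise ValueError("point counts must be non-negative")
        if self.area_per_point_um2 <= 0 or self.spacing_um <= 0:
            raise ValueError("area per point and spacing must be positive")


def cavalieri_volume(grids: list[SectionGrid]) -> dict[str, float]:
    """Volume of a region from its ordered section grids.

    Returns both um^3 and mm^3.  All sections must share the same grid area
    and spacing (one systematic sample per specimen).
    """
    if not grids:
        raise ValueError("at least one section is required")
    a_p = grids[0].area_per_point_um2
    spacing = grids[0].spacing_um
    for g in grids:
        if g.area_per_point_um2 != a_p or g.spacing_um != spacing:
            raise ValueError("inconsistent grid parameters across sections")
    total_points = sum(g.point_count for g in grids)
    volume_um3 = total_points * a_p * spacing
    return {"points": total_points, "volume_um3": volume_um3,
            "volume_mm3": volume_um3 / UM3_PER_MM3}


def pcna_positive_fraction(positive_nuclei: int, total_nuclei: int) -> float:
    """Percentage of PCNA-positive nuclei."""
    if total_nuclei <= 0:
        raise ValueError("total nuclei must be positive")
    if positive_nuclei < 0 or positive_nuclei > total_nuclei:
        raise ValueError("positive count must be within [0, total]")
    return 100.0 * positive_nuclei / total_nuclei


def relative_volume(volume_mm3: float, body_weight_g: float) -> float:
    """Volume normalised to body weight, mm^3/g."""
    if body_weight_g <= 0:
        raise ValueError("body weight must be positive")
    return volume_mm3 / body_weight_g


def volumes_from_table(df: pd.DataFrame) -> pd.DataFrame:
    """Cavalieri volumes per (animal_id, region) from a long point-count table.

    Expected columns: animal_id, section_index, region, point_count,
    area_per_point_um2, spacing_um.
    """
    required = {"animal_id", "section_index", "region", "point_count",
                "area_per_point_um2", "spacing_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"point-count table missing columns: {sorted(missing)}")
    rows = []
    for (animal, region), grp in df.groupby(["animal_id", "region"]):
        grids = [
            SectionGrid(int(r.section_index), int(r.point_count),
                        float(r.area_per_point_um2), float(r.spacing_um))
            for r in grp.itertuples()
        ]
        vol = cavalieri_volume(grids)
        rows.append({"animal_id": animal, "region": region, **vol})
    return pd.DataFrame(rows)
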