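"""Targeted LC-MS acyl-carnitine quantification.

The rule chain, applied per analyte and sample, is:

1. retention-time acceptance: drift beyond +/-0.1 min from the expected RT
   excludes the peak ("Not Found", concentration 0);
2. blank correction: a peak area below 3x the blank area is zeroed;
3. quantification: concentration = (area / internal-standard area) x the
   internal-standard concentration (5 uM), divided by tissue mass (mg) for
   tissue samples, giving uM/mg.

Class totals group analytes into small/medium/long-chain, hydroxylated,
odd-chain and dicarboxylic pools with configurable chain-length boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import PROTON_MASS
from .library import make_species

__all__ = [
    "CarnitineTarget",
    "CarnitineMeasurement",
    "CarnitineResult",
    "ChainClassConfig",
    "assign_rt_peak",
    "blank_correct",
    "quantify_concentration",
    "quantify_measurement",
    "quantify_table",
    "classify_target",
    "carnitine_class_totals",
    "default_panel",
    "INTERNAL_STANDARDS",
]

#: Deuterated internal standards spiked at 5 uM; chain <= C12 analytes are
#: normalised to butyryl-d7, chain >= C14 to hexadecanoyl-d3 (configurable
#: per target via ``is_name``).
INTERNAL_STANDARDS = {
    "butyryl-d7": {"formula": "C11H14D7NO4", "rt_min": 1.20},
    "hexadecanoyl-d3": {"formula": "C23H42D3NO4", "rt_min": 4.20},
}

SCAN_RANGE_MZ = (150.0, 800.0)


@dataclass(frozen=True)
class CarnitineTarget:
    """A targeted acyl-carnitine analyte measured as [M+H]+."""

    name: str  # e.g. "C4-OH", "C16:0"
    chain_carbons: int
    double_bonds: int = 0
    hydroxyl: bool = False
    dicarboxylic: bool = False
    expected_rt: float = 1.0  # min
    expected_mz: float | None = None
    is_name: str = ""

    def __post_init__(self):
        if self.expected_rt <= 0:
            raise ValueError(f"{self.name}: expected_rt must be positive")
        if self.expected_mz is None:
            # the second acid group of a dicarboxylic acyl is +O2 plus one
            # double-bond equivalent relative to the plain acyl chain
            species = make_species(
                "CAR", self.chain_carbons,
                self.double_bonds + int(self.dicarboxylic),
                int(self.hydroxyl) + 2 * int(self.dicarboxylic),
            )
            object.__setattr__(self, "expected_mz", species.formula.mass + PROTON_MASS)
        if not (SCAN_RANGE_MZ[0] <= self.expected_mz <= SCAN_RANGE_MZ[1]):
            raise ValueError(
                f"{self.name}: expected m/z {self.expected_mz:.4f} outside the "
                f"{SCAN_RANGE_MZ[0]:.0f}-{SCAN_RANGE_MZ[1]:.0f} scan range"
            )
        if not self.is_name:
            object.__setattr__(
                self, "is_name",
                "butyryl-d7" if self.chain_carbons <= 12 else "hexadecanoyl-d3",
            )


@dataclass(frozen=True)
class CarnitineMeasurement:
    """One integrated chromatographic peak for one target in one sample."""

    sample_id: str
    target: CarnitineTarget
    observed_rt: float  # min
    area: float
    is_area: float
    blank_area: float = 0.0
    tissue_mg: float | None = None

    def __post_init__(self):
        if min(self.area, self.is_area, self.blank_area) < 0:
            raise ValueError("areas must be non-negative")
        if self.tissue_mg is not None and self.tissue_mg <= 0:
            raise ValueError("tissue_mg must be positive for tissue samples")


@dataclass(frozen=True)
class CarnitineResult:
    sample_id: str
    target_name: str
    concentration: float  # uM/mg for tissue, uM otherwise; 0 = "Not Found"
    status: str  # quantified | rt_fail | blank_fail


def assign_rt_peak(observed_rt: float, expected_rt: float, drift_max: float = 0.1) -> bool:
    """Accept a peak iff |observed - expected| <= drift_max (boundary kept:
    only drift strictly greater than the window excludes)."""
    if observed_rt <= 0 or expected_rt <= 0:
        raise ValueError("retention times must be positive")
    # tiny tolerance so a drift exactly at the window (0.10 min) is kept
    # despite binary float representation of the minute values
    return abs(observed_rt - expected_rt) <= drift_max + 1e-9


def blank_correct(area: float, blank_area: float, factor: float = 3.0) -> float | None:
    """Return the area unchanged if it is at least ``factor`` x blank, else
    None ("Not Found"; strictly-less-than zeroes, the boundary passes)."""
    if area < 0 or blank_area < 0:
        raise ValueError("areas must be non-negative")
    return None if area < factor * blank_area else area


def quantify_concentration(
    area: float, is_area: float, is_conc: float = 5.0, tissue_mg: float | None = None
) -> float:
    """(area / is_area) x is_conc, / tissue_mg for tissue samples."""
    if is_area <= 0:
        raise ValueError("internal-standard area must be positive (missing IS voids the run)")
    conc = area / is_area * is_conc
    if tissue_mg is not None:
        conc /= tissue_mg
    return conc


def quantify_measurement(
    m: CarnitineMeasurement,
    drift_max: float = 0.1,
    blank_factor: float = 3.0,
    is_conc: float = 5.0,
) -> CarnitineResult:
    """RT rule -> blank rule -> quantification, in that fixed order."""
    if not assign_rt_peak(m.observed_rt, m.target.expected_rt, drift_max):
        return CarnitineResult(m.sample_id, m.target.name, 0.0, "rt_fail")
    area = blank_correct(m.area, m.blank_area, blank_factor)
    if area is None:
        return CarnitineResult(m.sample_id, m.target.name, 0.0, "blank_fail")
    conc = quantify_concentration(area, m.is_area, is_conc, m.tissue_mg)
    return CarnitineResult(m.sample_id, m.target.name, conc, "quantified")


def quantify_table(
    measurements: list[CarnitineMeasurement] | pd.DataFrame,
    targets: dict[str, CarnitineTarget] | None = None,
    drift_max: float = 0.1,
    blank_factor: float = 3.0,
    is_conc: float = 5.0,
) -> pd.DataFrame:
    """Quantify a batch; accepts CarnitineMeasurement objects or a DataFrame
    with columns (sample_id, target, observed_rt, area, is_area, blank_area,
    tissue_mg), in which case ``targets`` maps target names to specs."""
    if isinstance(measurements, pd.DataFrame):
        if targets is None:
            raise ValueError("a target panel is required with DataFrame input")
        objs = []
        for _, row in measurements.iterrows():
            name = row["target"]
            if name not in targets:
                raise ValueError(f"measurement references unknown target {name!r}")
            mg = row.get("tissue_mg")
            objs.append(CarnitineMeasurement(
                str(row["sample_id"]), targets[name], float(row["observed_rt"]),
                float(row["area"]), float(row["is_area"]),
                float(row.get("blank_area", 0.0) or 0.0),
                None if pd.isna(mg) else float(mg),
            ))
        measurements = objs
    rows = [quantify_measurement(m, drift_max, blank_factor, is_conc)
            for m in measurements]
    return pd.DataFrame(
        [{"sample_id": r.sample_id, "target": r.target_name,
          "concentration": r.concentration, "status": r.status} for r in rows]
    )


@dataclass(frozen=True)
class ChainClassConfig:
    """Chain-length boundaries for the acyl-carnitine class totals."""

    small: tuple[int, int] = (2, 5)
    medium: tuple[int, int] = (6, 12)
    long_min: int = 14


def classify_target(target: CarnitineTarget, config: ChainClassConfig = ChainClassConfig()) -> str:
    """Assign a target to exactly one class pool.

    Priority: dicarboxylic (DCAC) > hydroxylated (LCAC-OH for chain >=
    ``long_min``, S/MCAC-OH below) > odd chain > chain-length class
    (SCAC/MCAC/LCAC).  The pools therefore partition the panel.
    """
    c = target.chain_carbons
    if target.dicarboxylic:
        return "DCAC"
    if target.hydroxyl:
        return "LCAC-OH" if c >= config.long_min else "S/MCAC-OH"
    if c % 2 == 1:
        return "OddChain"
    if config.small[0] <= c <= config.small[1]:
        return "SCAC"
    if config.medium[0] <= c <= config.medium[1]:
        return "MCAC"
    if c >= config.long_min:
        return "LCAC"
    raise ValueError(f"target {target.name} (C{c}) fits no chain-length class")


def carnitine_class_totals(
    results: pd.DataFrame,
    targets: dict[str, CarnitineTarget],
    config: ChainClassConfig = ChainClassConfig(),
) -> pd.DataFrame:
    """Per-sample summed concentration per class pool.

    ``results`` is the :func:`quantify_table` output; every target named
    there must be classifiable, otherwise the offending name is reported.
    """
    classes = {}
    for name in results["target"].unique():
        if name not in targets:
            raise ValueError(f"result references unknown target {name!r}")
        classes[name] = classify_target(targets[name], config)
    tagged = results.assign(pool=results["target"].map(classes))
    totals = tagged.pivot_table(index="sample_id", columns="pool",
                                values="concentration", aggfunc="sum", fill_value=0.0)
    for pool in ["SCAC", "MCAC", "LCAC", "S/MCAC-OH", "LCAC-OH", "OddChain", "DCAC"]:
        if pool not in totals.columns:
            totals[pool] = 0.0
    return totals[["SCAC", "MCAC", "LCAC", "S/MCAC-OH", "LCAC-OH", "OddChain", "DCAC"]]


def default_panel() -> dict[str, CarnitineTarget]:
    """An editable default acyl-carnitine panel.

    Expected RTs follow the reversed-phase elution order (longer, more
    saturated chains elute later) anchored at the two internal standards
    (C4-d7 at 1.20 min, C16-d3 at 4.20 min); they are panel configuration,
    not constants of the method.
    """
    def rt(c: int) -> float:
        return round(min(5.4, max(0.6, 1.2 + (c - 4) * 0.25)), 2)

    specs = []
    for c in range(2, 23):
        specs.append((f"C{c}:0", c, 0, False, False))
    for name, c, db in [("C12:1", 12, 1), ("C14:1", 14, 1), ("C16:1", 16, 1),
                        ("C18:1", 18, 1), ("C18:2", 18, 2), ("C20:4", 20, 4),
                        ("C22:5", 22, 5), ("C22:6", 22, 6)]:
        specs.append((name, c, db, False, False))
    for name, c in [("C4-OH", 4), ("C5-OH", 5), ("C14-OH", 14), ("C16-OH", 16)]:
        specs.append((name, c, 0, True, False))
    for name, c in [("C6-DC", 6), ("C8-DC", 8)]:
        specs.append((name, c, 0, False, True))
    panel = {}
    for name, c, db, oh, dc in specs:
        panel[name] = CarnitineTarget(name, c, db, oh, dc, expected_rt=rt(c))
    return panel


def load_panel_csv(path) -> dict[str, CarnitineTarget]:
    """Target panel CSV: name, chain, db, oh, dcac, expected_rt[, expected_mz, is_name]."""
    df = pd.read_csv(path)
    panel = {}
    for _, row in df.iterrows():
        mz = row.get("expected_mz")
        panel[row["name"]] = CarnitineTarget(
            row["name"], int(row["chain"]), int(row.get("db", 0) or 0),
            bool(row.get("oh", False)), bool(row.get("dcac", False)),
            float(row["expected_rt"]),
            None if pd.isna(mz) else float(mz),
            str(row.get("is_name", "") or ""),
        )
    return panel


__all__.append("load_panel_csv")
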