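"""Theoretical ion libraries for direct-infusion lipidomics.

A library is an m/z-sorted list of :class:`TheoreticalIon` objects, each a
lipid (or fatty-acid) species plus an adduct.  Species formulas are generated
from per-class composition rules written as functions of total acyl carbons,
double bonds and hydroxyl count.  Because direct infusion resolves ions by
m/z only, ions closer than the instrument tolerance are isobaric and are
grouped; each group carries a ranked annotation list and the top-ranked
annotation is the group representative used for class aggregation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import pandas as pd

from .chem import PROTON_MASS, ELECTRON_MASS, MONOISOTOPIC_MASS, ElementalFormula

__all__ = [
    "AdductSpec",
    "ADDUCTS",
    "LipidSpecies",
    "TheoreticalIon",
    "IonLibrary",
    "COMPOSITION_RULES",
    "make_species",
    "parse_label",
    "ion_mz",
    "enumerate_fatty_acids",
    "build_intact_library",
    "group_isobars",
    "default_intact_specs",
    "DEFAULT_CLASS_PRIORITY",
]


@dataclass(frozen=True)
class AdductSpec:
    """An ionisation adduct: m/z = (neutral mass + mass_shift) / |charge|."""

    name: str
    mass_shift: float  # Da, signed; includes proton/electron bookkeeping
    charge: int

    def __post_init__(self):
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")

    @property
    def polarity(self) -> str:
        return "positive" if self.charge > 0 else "negative"


def _normalise_adduct_name(name: str) -> str:
    return name.replace("−", "-").replace("–", "-")


_NH4 = MONOISOTOPIC_MASS["N"] + 4 * MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", PROTON_MASS, +1),
    "[M-H]-": AdductSpec("[M-H]-", -PROTON_MASS, -1),
    "[M+Na]+": AdductSpec("[M+Na]+", MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS, +1),
    "[M+NH4]+": AdductSpec("[M+NH4]+", _NH4, +1),
}


def get_adduct(name: str | AdductSpec) -> AdductSpec:
    if isinstance(name, AdductSpec):
        return name
    key = _normalise_adduct_name(name)
    try:
        return ADDUCTS[key]
    except KeyError:
        raise ValueError(f"unknown adduct: {name!r}") from None


# ---------------------------------------------------------------------------
# Species composition rules
# ---------------------------------------------------------------------------

# Each rule maps (carbons, double_bonds) -> element counts for the neutral
# species with no hydroxylation; a hydroxyl substitutes H -> OH, i.e. adds one
# oxygen and leaves the H count unchanged.  Rules are the standard neutral
# formulas of diacyl glycerophospholipids (PA scaffold + head group),
# glycerides, d18:1 sphingolipids, cholesteryl esters, sterols, free fatty
# acids and acyl-carnitines, with c = total acyl/backbone carbons per the
# "class C:DB" shorthand.
COMPOSITION_RULES: dict[str, Callable[[int, int], dict[str, int]]] = {
    "FA": lambda c, db: {"C": c, "H": 2 * c - 2 * db, "O": 2},
    "CAR": lambda c, db: {"C": c + 7, "H": 2 * c - 2 * db + 13, "N": 1, "O": 4},
    "PA": lambda c, db: {"C": c + 3, "H": 2 * c - 2 * db + 5, "O": 8, "P": 1},
    "PC": lambda c, db: {"C": c + 8, "H": 2 * c - 2 * db + 16, "N": 1, "O": 8, "P": 1},
    "PE": lambda c, db: {"C": c + 5, "H": 2 * c - 2 * db + 10, "N": 1, "O": 8, "P": 1},
    "PG": lambda c, db: {"C": c + 6, "H": 2 * c - 2 * db + 11, "O": 10, "P": 1},
    "PS": lambda c, db: {"C": c + 6, "H": 2 * c - 2 * db + 10, "N": 1, "O": 10, "P": 1},
    "PI": lambda c, db: {"C": c + 9, "H": 2 * c - 2 * db + 15, "O": 13, "P": 1},
    "LPC": lambda c, db: {"C": c + 8, "H": 2 * c - 2 * db + 18, "N": 1, "O": 7, "P": 1},
    "LPE": lambda c, db: {"C": c + 5, "H": 2 * c - 2 * db + 12, "N": 1, "O": 7, "P": 1},
    "TG": lambda c, db: {"C": c + 3, "H": 2 * c - 2 * db + 2, "O": 6},
    "DG": lambda c, db: {"C": c + 3, "H": 2 * c - 2 * db + 4, "O": 5},
    "MG": lambda c, db: {"C": c + 3, "H": 2 * c - 2 * db + 6, "O": 4},
    "SM": lambda c, db: {"C": c + 5, "H": 2 * c - 2 * db + 13, "N": 2, "O": 6, "P": 1},
    "CE": lambda c, db: {"C": c + 27, "H": 2 * c - 2 * db + 44, "O": 2},
    "Cer": lambda c, db: {"C": c, "H": 2 * c - 2 * db + 1, "N": 1, "O": 3},
    # Sterols: the double-bond count excludes the four rings (campesterol
    # ST 28:1;O = C28H48O); the ;O oxygen comes from the hydroxyl term.
    "ST": lambda c, db: {"C": c, "H": 2 * c - 6 - 2 * db},
}

#: Version tag for the built-in composition table (bumped when rules change).
COMPOSITION_RULES_VERSION = "1"

#: Ranking used to pick a representative among isobaric annotations when no
#: other evidence is available; configurable in :func:`group_isobars`.
DEFAULT_CLASS_PRIORITY: tuple[str, ...] = ("PC", "PE", "TG", "SM", "CE", "Cer")


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid species in ``CLASS carbons:double_bonds[;O]`` shorthand."""

    class_code: str
    total_carbons: int
    double_bonds: int
    hydroxyls: int
    formula: ElementalFormula
    label: str


def make_species(class_code: str, carbons: int, double_bonds: int, hydroxyls: int = 0) -> LipidSpecies:
    """Build a species (label + formula) from the class composition rule."""
    if class_code not in COMPOSITION_RULES:
        raise ValueError(f"no composition rule for class code {class_code!r}")
    if carbons <= 0 or double_bonds < 0 or hydroxyls < 0:
        raise ValueError("carbons must be positive; double bonds/hydroxyls non-negative")
    counts = dict(COMPOSITION_RULES[class_code](carbons, double_bonds))
    if counts.get("H", 0) < 0:
        raise ValueError(
            f"{class_code} {carbons}:{double_bonds} has a negative hydrogen count"
        )
    counts["O"] = counts.get("O", 0) + hydroxyls
    label = f"{class_code} {carbons}:{double_bonds}"
    if hydroxyls == 1:
        label += ";O"
    elif hydroxyls > 1:
        label += f";O{hydroxyls}"
    return LipidSpecies(
        class_code, carbons, double_bonds, hydroxyls, ElementalFormula(counts), label
    )


def parse_label(label: str) -> LipidSpecies:
    """Inverse of the ``make_species`` label (round-trips exactly)."""
    try:
        class_code, rest = label.split(" ", 1)
        if ";O" in rest:
            cd, osuf = rest.split(";O", 1)
            hydroxyls = int(osuf) if osuf else 1
        else:
            cd, hydroxyls = rest, 0
        carbons, double_bonds = (int(v) for v in cd.split(":"))
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"cannot parse species label {label!r}") from exc
    return make_species(class_code, carbons, double_bonds, hydroxyls)


def ion_mz(species: LipidSpecies, adduct: str | AdductSpec) -> float:
    """m/z of ``species`` under ``adduct``: (M + shift)/|z|."""
    adduct = get_adduct(adduct)
    mz = (species.formula.mass + adduct.mass_shift) / abs(adduct.charge)
    if mz <= 0:
        raise ValueError(f"non-positive m/z for {species.label} {adduct.name}")
    return mz


@dataclass
class TheoreticalIon:
    species: LipidSpecies
    adduct: AdductSpec
    mz: float
    polarity: str
    isobar_group: int | None = None
    #: Labels of all species in this ion's isobar group, ranked by priority
    #: (filled in by :func:`group_isobars`); first entry = representative.
    annotations: tuple[str, ...] = ()

    @property
    def feature_id(self) -> str:
        return f"{self.species.label} {self.adduct.name}"


@dataclass
class IonLibrary:
    """An m/z-sorted collection of theoretical ions within a mass window."""

    ions: list[TheoreticalIon]
    polarity: str
    mz_window: tuple[float, float] = (50.0, 1000.0)

    def __post_init__(self):
        lo, hi = self.mz_window
        self.ions = sorted(
            (i for i in self.ions if lo <= i.mz <= hi), key=lambda i: (i.mz, i.feature_id)
        )
        for ion in self.ions:
            if ion.polarity != self.polarity:
                raise ValueError(
                    f"ion {ion.feature_id} polarity {ion.polarity} != library {self.polarity}"
                )

    def __len__(self) -> int:
        return len(self.ions)

    def __iter__(self) -> Iterator[TheoreticalIon]:
        return iter(self.ions)

    def mz_values(self) -> list[float]:
        return [ion.mz for ion in self.ions]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ion in self.ions:
            s = ion.species
            rows.append(
                {
                    "label": s.label,
                    "class_code": s.class_code,
                    "carbons": s.total_carbons,
                    "double_bonds": s.double_bonds,
                    "hydroxyls": s.hydroxyls,
                    "formula": str(s.formula),
                    "adduct": ion.adduct.name,
                    "polarity": ion.polarity,
                    "mz": ion.mz,
                    "isobar_group": ion.isobar_group,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, mz_window: tuple[float, float] = (50.0, 1000.0)) -> "IonLibrary":
        df = pd.read_csv(path)
        ions = []
        polarity = None
        for _, row in df.iterrows():
            species = make_species(
                row["class_code"], int(row["carbons"]), int(row["double_bonds"]),
                int(row.get("hydroxyls", 0) or 0),
            )
            adduct = get_adduct(row["adduct"])
            group = row.get("isobar_group")
            ions.append(
                TheoreticalIon(
                    species, adduct, ion_mz(species, adduct), adduct.polarity,
                    None if pd.isna(group) else int(group),
                )
            )
            polarity = adduct.polarity
        if polarity is None:
            raise ValueError("empty library CSV")
        return cls(ions, polarity, mz_window)


def enumerate_fatty_acids(
    min_c: int = 14,
    max_c: int = 36,
    max_db: int = 6,
    max_oh: int = 1,
    mz_window: tuple[float, float] = (50.0, 1000.0),
) -> IonLibrary:
    """[M-H]- library of fatty acids C(min_c)-C(max_c), 0..max_db double
    bonds, 0..max_oh hydroxyls (formula C_c H_(2c-2db) O_(2+oh))."""
    if min_c > max_c:
        raise ValueError("min_c must be <= max_c")
    if max_db < 0 or max_oh not in (0, 1):
        raise ValueError("max_db must be >= 0 and max_oh in {0, 1}")
    adduct = ADDUCTS["[M-H]-"]
    ions = []
    for c in range(min_c, max_c + 1):
        for db in range(max_db + 1):
            if 2 * c - 2 * db < 0:
                continue
            for oh in range(max_oh + 1):
                species = make_species("FA", c, db, oh)
                ions.append(
                    TheoreticalIon(species, adduct, ion_mz(species, adduct), "negative")
                )
    return IonLibrary(ions, "negative", mz_window)


ClassSpec = tuple  # (class_code, (c_min, c_max), (db_min, db_max)[, (oh_min, oh_max)])


def build_intact_library(
    class_specs: Iterable[ClassSpec],
    adducts: Sequence[str | AdductSpec],
    mz_window: tuple[float, float] = (50.0, 1000.0),
) -> IonLibrary:
    """Cartesian enumeration of intact-lipid ions, deduplicated and sorted."""
    adduct_objs = [get_adduct(a) for a in adducts]
    if not adduct_objs:
        raise ValueError("at least one adduct is required")
    polarity = adduct_objs[0].polarity
    if any(a.polarity != polarity for a in adduct_objs):
        raise ValueError("all adducts in one library must share a polarity")
    seen: set[tuple[str, str]] = set()
    ions = []
    for spec in class_specs:
        class_code, (c_min, c_max), (db_min, db_max), *rest = spec
        if class_code not in COMPOSITION_RULES:
            raise ValueError(f"no composition rule for class code {class_code!r}")
        oh_min, oh_max = rest[0] if rest else (0, 0)
        for c in range(c_min, c_max + 1):
            for db in range(db_min, db_max + 1):
                for oh in range(oh_min, oh_max + 1):
                    try:
                        species = make_species(class_code, c, db, oh)
                    except ValueError:
                        continue  # negative H count: combination never emitted
                    for adduct in adduct_objs:
                        key = (species.label, adduct.name)
                        if key in seen:
                            continue
                        seen.add(key)
                        ions.append(
                            TheoreticalIon(
                                species, adduct, ion_mz(species, adduct), polarity
                            )
                        )
    return IonLibrary(ions, polarity, mz_window)


def default_intact_specs(polarity: str = "positive") -> list[ClassSpec]:
    """Built-in positive/negative-mode intact-lipid enumeration ranges.

    A reconstruction of a typical shotgun-lipidomics target list (the classes
    quantified in mammalian serum/heart extracts); ranges cover the commonly
    observed acyl-carbon and double-bond space.
    """
    if polarity == "positive":
        return [
            ("PC", (26, 44), (0, 8)),
            ("LPC", (14, 26), (0, 6)),
            ("PE", (26, 44), (0, 8)),
            ("LPE", (14, 26), (0, 6)),
            ("SM", (28, 44), (0, 4)),
            ("TG", (40, 62), (0, 10)),
            ("DG", (26, 44), (0, 8)),
            ("MG", (14, 24), (0, 4)),
            ("CE", (12, 24), (0, 6)),
            ("Cer", (30, 44), (0, 3)),
            ("ST", (27, 29), (1, 2), (0, 1)),
        ]
    return [
        ("PA", (26, 44), (0, 8)),
        ("PG", (26, 44), (0, 8)),
        ("PS", (26, 44), (0, 8)),
        ("PI", (26, 44), (0, 8)),
        ("PE", (26, 44), (0, 8)),
        ("FA", (14, 36), (0, 6), (0, 1)),
    ]


def group_isobars(
    library: IonLibrary,
    tol_ppm: float = 9.0,
    priority: Sequence[str] = DEFAULT_CLASS_PRIORITY,
) -> IonLibrary:
    """Assign isobar groups by single-linkage clustering at ``tol_ppm``.

    Walking the m/z-sorted ions, consecutive ions whose relative gap is
    <= ``tol_ppm`` join the same group.  Each ion receives the group's
    annotation list ranked by the class-priority table (classes missing from
    the table rank after listed ones, ties broken by m/z then label); the
    first annotation is the group representative.
    """
    rank = {code: i for i, code in enumerate(priority)}

    def class_rank(ion: TheoreticalIon) -> tuple:
        return (
            rank.get(ion.species.class_code, len(priority)),
            ion.mz,
            ion.species.label,
        )

    grouped: list[TheoreticalIon] = []
    group_id = -1
    prev_mz = None
    current: list[TheoreticalIon] = []

    def flush():
        if not current:
            return
        ranked = sorted(current, key=class_rank)
        labels = tuple(ion.species.label for ion in ranked)
        for ion in current:
            grouped.append(dataclasses.replace(ion, isobar_group=group_id, annotations=labels))

    for ion in library:
        if prev_mz is None or (ion.mz - prev_mz) / prev_mz * 1e6 > tol_ppm:
            flush()
            current = []
            group_id += 1
        current.append(ion)
        prev_mz = ion.mz
    flush()
    return IonLibrary(grouped, library.polarity, library.mz_window)


def isobar_representatives(library: IonLibrary) -> IonLibrary:
    """Reduce a grouped library to one top-ranked ion per isobar group."""
    best: dict[int, TheoreticalIon] = {}
    for ion in library:
        if ion.isobar_group is None:
            raise ValueError("library has no isobar groups; run group_isobars first")
        if ion.isobar_group not in best and ion.species.label == ion.annotations[0]:
            best[ion.isobar_group] = ion
    return IonLibrary(list(best.values()), library.polarity, library.mz_window)


__all__.append("isobar_representatives")
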