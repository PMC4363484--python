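"""Domain types, validation and CSV readers/writers for raw field tables.

The measurement campaign behind this package fells a canopy tree and records,
per tree: two polished stem discs (three radii each, bark thickness, annual
ring widths, sapwood/heartwood radial lengths, pith diameter), radial wood
samples for wood density, four to five branches for the basal-area :
leaf-area ratio, a pooled leaf sample, and leaf/sapwood nitrogen assays.
Everything downstream (disc derivations, tree-level traits, inference)
consumes the types defined here.

Units are fixed per column: disc geometry in cm, heights in m, branch basal
area in cm^2, leaf areas in cm^2, masses in g. Conversions happen only inside
derivation code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError

__all__ = [
    "Guild",
    "SpeciesInfo",
    "DEFAULT_SPECIES",
    "species_lookup",
    "DiscMeasurement",
    "WoodSample",
    "BranchMeasurement",
    "TreeRecord",
    "TraitRecord",
    "TRAIT_COLUMNS",
    "Violation",
    "validate_tree",
    "read_field_tables",
    "write_field_tables",
    "FIELD_TABLE_NAMES",
]


class Guild(str, Enum):
    """Ecological guild: long-lived pioneer vs partially shade tolerant."""

    LLP = "LLP"
    PST = "PST"


@dataclass(frozen=True)
class SpeciesInfo:
    """Species-level attributes of one of the four study species.

    ``ce_juv`` is the average juvenile crown-exposure index (ordinal 1-5,
    increasing access to direct light); ``wd_breast_height`` the average
    wood density (g cm^-3) at breast height.
    """

    name: str
    family: str
    guild: Guild
    max_height_m: float
    ce_juv: float
    wd_breast_height: float

    def __post_init__(self) -> None:
        if self.max_height_m <= 0:
            raise ValueError(f"max_height_m must be positive, got {self.max_height_m}")
        if not 1.0 <= self.ce_juv <= 5.0:
            raise ValueError(f"ce_juv must lie in [1, 5], got {self.ce_juv}")
        if not 0.1 < self.wd_breast_height < 1.5:
            raise ValueError(
                f"wd_breast_height must lie in (0.1, 1.5), got {self.wd_breast_height}"
            )

    @property
    def genus(self) -> str:
        return self.name.split()[0]


#: The four Bolivian study species with guild, maximum height, juvenile
#: crown exposure and breast-height wood density.
DEFAULT_SPECIES: tuple[SpeciesInfo, ...] = (
    SpeciesInfo("Hura crepitans", "Euphorbiaceae", Guild.PST, 44.0, 1.62, 0.37),
    SpeciesInfo("Schizolobium parahyba", "Fabaceae/Caesalpiniaceae", Guild.LLP, 35.0, 2.39, 0.45),
    SpeciesInfo("Cariniana ianeirensis", "Lecythidaceae", Guild.PST, 45.0, 1.74, 0.36),
    SpeciesInfo("Sweetia fruticosa", "Fabaceae/Papillionaceae", Guild.LLP, 30.0, 1.91, 0.82),
)


def species_lookup(
    name: str, table: Sequence[SpeciesInfo] = DEFAULT_SPECIES
) -> SpeciesInfo:
    """Resolve a species name case-insensitively, accepting the bare genus."""
    key = name.strip().lower()
    for sp in table:
        if key in (sp.name.lower(), sp.genus.lower()):
            return sp
    raise IntegrityError(f"unknown species {name!r}")


@dataclass
class DiscMeasurement:
    """One polished stem disc.

    ``radii_cm`` holds the longest, shortest and one intermediate radius,
    measured inside bark from the pith.  Ring widths are measured on the same
    three radii for the last five years (``ring_widths_5yr_cm``, shape 3x5)
    and as a 15-year mean per radius (``mean_ring_width_15yr_cm``).  Sapwood
    and heartwood radial lengths are per radius and are ``None`` when the
    sapwood boundary is not distinguishable (the *Cariniana* case).
    """

    disc_id: str
    height_above_soil_m: float
    radii_cm: tuple[float, float, float]
    bark_thickness_cm: tuple[float, float, float, float]
    ring_widths_5yr_cm: np.ndarray  # shape (3 radii, 5 years)
    mean_ring_width_15yr_cm: tuple[float, float, float]
    sapwood_radial_length_cm: tuple[float, float, float] | None
    heartwood_radial_length_cm: tuple[float, float, float] | None
    pith_diameter_cm: float

    def __post_init__(self) -> None:
        self.ring_widths_5yr_cm = np.asarray(self.ring_widths_5yr_cm, dtype=float)
        if self.ring_widths_5yr_cm.shape != (3, 5):
            raise SchemaError(
                f"disc {self.disc_id}: ring widths must be 3 radii x 5 years, "
                f"got shape {self.ring_widths_5yr_cm.shape}"
            )

    @property
    def has_sapwood_boundary(self) -> bool:
        return self.sapwood_radial_length_cm is not None


@dataclass
class WoodSample:
    """A radial wood sample: fresh volume by water displacement, oven-dry mass."""

    position_index: int  # 1 = outermost (youngest sapwood), increasing inward
    fresh_volume_cm3: float
    dry_mass_g: float
    is_youngest_sapwood: bool = False


@dataclass
class BranchMeasurement:
    """One crown branch: shoot census plus basal area excluding bark."""

    branch_id: str
    basal_area_excl_bark_cm2: float
    n_shoot_apices: int
    leaves_per_shoot: tuple[int, ...]  # up to 5 censused apices
    harvested_leaf_area_cm2: float | None = None


@dataclass
class TreeRecord:
    """One felled tree with all raw measurements cross-linked."""

    tree_id: str
    species: SpeciesInfo
    total_height_m: float
    stem_height_m: float  # height to the first major branch
    discs: list[DiscMeasurement]
    wood_samples: dict[str, list[WoodSample]]  # disc_id -> samples
    branches: list[BranchMeasurement]
    pooled_leaf_area_cm2: float
    pooled_leaf_dry_mass_g: float
    n_leaf_pct: float
    n_sapw_pct: float

    @property
    def lower_disc(self) -> DiscMeasurement:
        return min(self.discs, key=lambda d: d.height_above_soil_m)

    @property
    def upper_disc(self) -> DiscMeasurement:
        return max(self.discs, key=lambda d: d.height_above_soil_m)


#: Column order of the derived trait table (one row per tree).
TRAIT_COLUMNS = [
    "tree_id",
    "species",
    "agr",               # kg yr^-1
    "height",            # m
    "tla",               # m^2
    "sa",                # m^2, may be NaN
    "sla",               # cm^2 g^-1
    "n_leaf",            # %
    "n_sapw",            # %
    "ba",                # m^2 (stem basal area, lower disc)
    "sapwood_lifespan",  # yr, may be NaN
    "sapwood_growth",    # cm^2 yr^-1
    "sa_imputed",        # bool
]


@dataclass
class TraitRecord:
    """One row of the derived tree-level trait table."""

    tree_id: str
    species: str
    agr: float
    height: float
    tla: float
    sa: float | None
    sla: float
    n_leaf: float
    n_sapw: float
    ba: float
    sapwood_lifespan: float | None
    sapwood_growth: float
    sa_imputed: bool = False

    def as_dict(self) -> dict:
        return {
            "tree_id": self.tree_id,
            "species": self.species,
            "agr": self.agr,
            "height": self.height,
            "tla": self.tla,
            "sa": np.nan if self.sa is None else self.sa,
            "sla": self.sla,
            "n_leaf": self.n_leaf,
            "n_sapw": self.n_sapw,
            "ba": self.ba,
            "sapwood_lifespan": (
                np.nan if self.sapwood_lifespan is None else self.sapwood_lifespan
            ),
            "sapwood_growth": self.sapwood_growth,
            "sa_imputed": self.sa_imputed,
        }


def traits_to_frame(records: Iterable[TraitRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.as_dict() for r in records])
    return df[TRAIT_COLUMNS]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    """A single invariant violation; violations are data, not exceptions."""

    tree_id: str
    field: str
    rule: str
    message: str


def _check(cond: bool, out: list[Violation], tree_id: str, field_: str, rule: str, msg: str):
    if not cond:
        out.append(Violation(tree_id, field_, rule, msg))


def validate_tree(t: TreeRecord, radial_tolerance: float = 0.02) -> list[Violation]:
    """Check every type invariant of a :class:`TreeRecord`.

    Returns an empty list iff the record is internally consistent.  The
    radial-consistency rule requires, per radius, that
    sapwood + heartwood + pith_diameter/2 matches the measured radius within
    ``radial_tolerance`` (a fraction of the radius; default 2 %, the scale of
    caliper/ruler error in the field).
    """
    v: list[Violation] = []
    tid = t.tree_id

    _check(0 < t.stem_height_m < t.total_height_m, v, tid, "stem_height_m",
           "height_ordering",
           f"stem height {t.stem_height_m} must lie in (0, total height {t.total_height_m})")
    _check(len(t.discs) == 2, v, tid, "discs", "disc_count",
           f"expected exactly 2 discs, got {len(t.discs)}")
    if len(t.discs) == 2:
        lo, hi = sorted(d.height_above_soil_m for d in t.discs)
        _check(lo < hi <= t.stem_height_m, v, tid, "discs", "disc_heights",
               f"disc heights ({lo}, {hi}) must be ordered and <= stem height "
               f"{t.stem_height_m}")
    _check(4 <= len(t.branches) <= 5, v, tid, "branches", "branch_count",
           f"expected 4-5 branches, got {len(t.branches)}")

    for d in t.discs:
        fld = f"discs[{d.disc_id}]"
        _check(all(r > 0 for r in d.radii_cm), v, tid, fld, "positive_radius",
               f"radii must be positive, got {d.radii_cm}")
        _check(all(b >= 0 for b in d.bark_thickness_cm), v, tid, fld,
               "nonnegative_length", "bark thickness must be >= 0")
        _check(d.pith_diameter_cm >= 0, v, tid, fld, "nonnegative_length",
               "pith diameter must be >= 0")
        _check(bool(np.all(d.ring_widths_5yr_cm >= 0)), v, tid, fld,
               "nonnegative_ring_width", "ring widths must be >= 0")
        _check(all(w >= 0 for w in d.mean_ring_width_15yr_cm), v, tid, fld,
               "nonnegative_ring_width", "15-yr mean ring widths must be >= 0")
        if d.has_sapwood_boundary:
            sap = d.sapwood_radial_length_cm
            heart = d.heartwood_radial_length_cm
            if heart is None:
                v.append(Violation(tid, fld, "sapwood_pairing",
                                   "sapwood lengths present without heartwood lengths"))
            else:
                _check(all(s >= 0 for s in sap) and all(h >= 0 for h in heart),
                       v, tid, fld, "nonnegative_length",
                       "sapwood/heartwood lengths must be >= 0")
                for i, (s, h, r) in enumerate(zip(sap, heart, d.radii_cm)):
                    total = s + h + d.pith_diameter_cm / 2.0
                    if abs(total - r) > radial_tolerance * r:
                        v.append(Violation(
                            tid, fld, "radial_consistency",
                            f"radius {i + 1}: sapwood+heartwood+pith/2 = {total:.3f} "
                            f"differs from radius {r:.3f} by more than "
                            f"{radial_tolerance:.0%}"))

        samples = t.wood_samples.get(d.disc_id, [])
        _check(len(samples) >= 1, v, tid, fld, "wood_sample_count",
               "each disc needs at least one wood sample")
        for s in samples:
            _check(s.fresh_volume_cm3 > 0, v, tid, fld, "positive_volume",
                   f"sample {s.position_index}: fresh volume must be > 0")
            _check(s.dry_mass_g > 0, v, tid, fld, "positive_mass",
                   f"sample {s.position_index}: dry mass must be > 0")
            if s.fresh_volume_cm3 > 0:
                _check(s.dry_mass_g / s.fresh_volume_cm3 < 1.5, v, tid, fld,
                       "wood_density_bound",
                       f"sample {s.position_index}: dry mass / fresh volume = "
                       f"{s.dry_mass_g / s.fresh_volume_cm3:.2f} >= 1.5 g cm^-3")

    for b in t.branches:
        fld = f"branches[{b.branch_id}]"
        _check(b.n_shoot_apices >= 1, v, tid, fld, "positive_shoots",
               "branch must carry at least one leaf-bearing shoot apex")
        _check(b.basal_area_excl_bark_cm2 > 0, v, tid, fld, "positive_ba",
               "branch basal area must be > 0")
        _check(1 <= len(b.leaves_per_shoot) <= 5, v, tid, fld,
               "leaves_per_shoot_count",
               f"expected 1-5 leaves-per-shoot counts, got {len(b.leaves_per_shoot)}")

    _check(t.pooled_leaf_area_cm2 > 0, v, tid, "pooled_leaf_area_cm2",
           "positive_area", "pooled leaf area must be > 0")
    _check(t.pooled_leaf_dry_mass_g > 0, v, tid, "pooled_leaf_dry_mass_g",
           "positive_mass", "pooled leaf dry mass must be > 0")
    return v


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

FIELD_TABLE_NAMES = ("trees", "discs", "rings", "ring15", "wood_samples", "branches")

_SCHEMAS: dict[str, list[str]] = {
    "trees": ["tree_id", "species", "total_height_m", "stem_height_m",
              "pooled_leaf_area_cm2", "pooled_leaf_dry_mass_g",
              "n_leaf_pct", "n_sapw_pct"],
    "discs": ["tree_id", "disc_id", "height_m",
              "radius_long_cm", "radius_short_cm", "radius_mid_cm",
              "bark1_cm", "bark2_cm", "bark3_cm", "bark4_cm",
              "sapwood1_cm", "sapwood2_cm", "sapwood3_cm",
              "heartwood1_cm", "heartwood2_cm", "heartwood3_cm",
              "pith_diameter_cm"],
    "rings": ["tree_id", "disc_id", "radius_index", "year_index", "width_cm"],
    "ring15": ["tree_id", "disc_id", "radius_index", "mean_width_15yr_cm"],
    "wood_samples": ["tree_id", "disc_id", "position_index",
                     "fresh_volume_cm3", "dry_mass_g", "is_youngest_sapwood"],
    "branches": ["tree_id", "branch_id", "ba_cm2", "n_shoots",
                 "leaves_per_shoot_1", "leaves_per_shoot_2", "leaves_per_shoot_3",
                 "leaves_per_shoot_4", "leaves_per_shoot_5", "leaf_area_cm2"],
}


def _require_columns(df: pd.DataFrame, table: str) -> None:
    missing = [c for c in _SCHEMAS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}.csv: missing required column(s) {missing}")


def _resolve_paths(source: Mapping[str, Path] | str | Path) -> dict[str, Path]:
    if isinstance(source, (str, Path)):
        base = Path(source)
        return {name: base / f"{name}.csv" for name in FIELD_TABLE_NAMES}
    return {name: Path(p) for name, p in source.items()}


def read_field_tables(
    source: Mapping[str, Path] | str | Path,
    species_table: Sequence[SpeciesInfo] = DEFAULT_SPECIES,
    outside_bark_radii: bool = False,
) -> list[TreeRecord]:
    """Read the six raw CSV tables and assemble cross-linked tree records.

    ``source`` is either a directory containing ``trees.csv`` .. ``branches.csv``
    or an explicit name -> path mapping.  When ``outside_bark_radii`` is set,
    the mean of the four bark thicknesses is subtracted from each radius
    (radii are stored inside bark).

    Raises :class:`SchemaError` for missing columns and :class:`IntegrityError`
    for orphan disc/branch/ring rows.
    """
    paths = _resolve_paths(source)
    frames: dict[str, pd.DataFrame] = {}
    for name in FIELD_TABLE_NAMES:
        p = paths[name]
        if not p.exists():
            raise SchemaError(f"missing input table {name}.csv at {p}")
        frames[name] = pd.read_csv(p)
        _require_columns(frames[name], name)

    trees_df = frames["trees"]
    known = set(trees_df["tree_id"].astype(str))
    for name in ("discs", "rings", "ring15", "wood_samples", "branches"):
        ids = set(frames[name]["tree_id"].astype(str))
        orphans = sorted(ids - known)
        if orphans:
            raise IntegrityError(
                f"{name}.csv references unknown tree_id(s): {orphans}")

    disc_keys = set(zip(frames["discs"]["tree_id"].astype(str),
                        frames["discs"]["disc_id"].astype(str)))
    for name in ("rings", "ring15", "wood_samples"):
        keys = set(zip(frames[name]["tree_id"].astype(str),
                       frames[name]["disc_id"].astype(str)))
        orphans = sorted(keys - disc_keys)
        if orphans:
            raise IntegrityError(
                f"{name}.csv references unknown (tree_id, disc_id) pair(s): {orphans}")

    records: list[TreeRecord] = []
    for _, trow in trees_df.iterrows():
        tid = str(trow["tree_id"])
        sp = species_lookup(str(trow["species"]), species_table)

        discs: list[DiscMeasurement] = []
        wood: dict[str, list[WoodSample]] = {}
        dsub = frames["discs"][frames["discs"]["tree_id"].astype(str) == tid]
        for _, drow in dsub.iterrows():
            did = str(drow["disc_id"])
            radii = [float(drow["radius_long_cm"]), float(drow["radius_short_cm"]),
                     float(drow["radius_mid_cm"])]
            bark = tuple(float(drow[f"bark{i}_cm"]) for i in range(1, 5))
            if outside_bark_radii:
                radii = [r - float(np.mean(bark)) for r in radii]

            rsub = frames["rings"][
                (frames["rings"]["tree_id"].astype(str) == tid)
                & (frames["rings"]["disc_id"].astype(str) == did)]
            widths = np.full((3, 5), np.nan)
            for _, rrow in rsub.iterrows():
                widths[int(rrow["radius_index"]) - 1, int(rrow["year_index"]) - 1] = \
                    float(rrow["width_cm"])

            r15sub = frames["ring15"][
                (frames["ring15"]["tree_id"].astype(str) == tid)
                & (frames["ring15"]["disc_id"].astype(str) == did)]
            r15 = [np.nan] * 3
            for _, rrow in r15sub.iterrows():
                r15[int(rrow["radius_index"]) - 1] = float(rrow["mean_width_15yr_cm"])

            sap = tuple(float(drow[f"sapwood{i}_cm"]) for i in range(1, 4))
            heart = tuple(float(drow[f"heartwood{i}_cm"]) for i in range(1, 4))
            if any(math.isnan(s) for s in sap):
                sap, heart = None, None

            discs.append(DiscMeasurement(
                disc_id=did,
                height_above_soil_m=float(drow["height_m"]),
                radii_cm=tuple(radii),
                bark_thickness_cm=bark,
                ring_widths_5yr_cm=widths,
                mean_ring_width_15yr_cm=tuple(r15),
                sapwood_radial_length_cm=sap,
                heartwood_radial_length_cm=heart,
                pith_diameter_cm=float(drow["pith_diameter_cm"]),
            ))

            wsub = frames["wood_samples"][
                (frames["wood_samples"]["tree_id"].astype(str) == tid)
                & (frames["wood_samples"]["disc_id"].astype(str) == did)]
            wood[did] = [
                WoodSample(
                    position_index=int(w["position_index"]),
                    fresh_volume_cm3=float(w["fresh_volume_cm3"]),
                    dry_mass_g=float(w["dry_mass_g"]),
                    is_youngest_sapwood=bool(w["is_youngest_sapwood"]),
                )
                for _, w in wsub.iterrows()
            ]

        bsub = frames["branches"][frames["branches"]["tree_id"].astype(str) == tid]
        branches = []
        for _, brow in bsub.iterrows():
            counts = tuple(
                int(brow[f"leaves_per_shoot_{i}"])
                for i in range(1, 6)
                if not pd.isna(brow[f"leaves_per_shoot_{i}"])
            )
            la = brow["leaf_area_cm2"]
            branches.append(BranchMeasurement(
                branch_id=str(brow["branch_id"]),
                basal_area_excl_bark_cm2=float(brow["ba_cm2"]),
                n_shoot_apices=int(brow["n_shoots"]),
                leaves_per_shoot=counts,
                harvested_leaf_area_cm2=None if pd.isna(la) else float(la),
            ))

        records.append(TreeRecord(
            tree_id=tid,
            species=sp,
            total_height_m=float(trow["total_height_m"]),
            stem_height_m=float(trow["stem_height_m"]),
            discs=discs,
            wood_samples=wood,
            branches=branches,
            pooled_leaf_area_cm2=float(trow["pooled_leaf_area_cm2"]),
            pooled_leaf_dry_mass_g=float(trow["pooled_leaf_dry_mass_g"]),
            n_leaf_pct=float(trow["n_leaf_pct"]),
            n_sapw_pct=float(trow["n_sapw_pct"]),
        ))
    return records


def write_field_tables(trees: Iterable[TreeRecord], outdir: str | Path) -> dict[str, Path]:
    """Write tree records back to the six CSV schemas (inverse of the reader)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows: dict[str, list[dict]] = {name: [] for name in FIELD_TABLE_NAMES}
    for t in trees:
        rows["trees"].append({
            "tree_id": t.tree_id, "species": t.species.name,
            "total_height_m": t.total_height_m, "stem_height_m": t.stem_height_m,
            "pooled_leaf_area_cm2": t.pooled_leaf_area_cm2,
            "pooled_leaf_dry_mass_g": t.pooled_leaf_dry_mass_g,
            "n_leaf_pct": t.n_leaf_pct, "n_sapw_pct": t.n_sapw_pct,
        })
        for d in t.discs:
            sap = d.sapwood_radial_length_cm or (np.nan,) * 3
            heart = d.heartwood_radial_length_cm or (np.nan,) * 3
            row = {
                "tree_id": t.tree_id, "disc_id": d.disc_id,
                "height_m": d.height_above_soil_m,
                "radius_long_cm": d.radii_cm[0], "radius_short_cm": d.radii_cm[1],
                "radius_mid_cm": d.radii_cm[2],
                "pith_diameter_cm": d.pith_diameter_cm,
            }
            row.update({f"bark{i+1}_cm": b for i, b in enumerate(d.bark_thickness_cm)})
            row.update({f"sapwood{i+1}_cm": s for i, s in enumerate(sap)})
            row.update({f"heartwood{i+1}_cm": h for i, h in enumerate(heart)})
            rows["discs"].append(row)
            for ri in range(3):
                for yi in range(5):
                    rows["rings"].append({
                        "tree_id": t.tree_id, "disc_id": d.disc_id,
                        "radius_index": ri + 1, "year_index": yi + 1,
                        "width_cm": d.ring_widths_5yr_cm[ri, yi],
                    })
                rows["ring15"].append({
                    "tree_id": t.tree_id, "disc_id": d.disc_id,
                    "radius_index": ri + 1,
                    "mean_width_15yr_cm": d.mean_ring_width_15yr_cm[ri],
                })
            for s in t.wood_samples.get(d.disc_id, []):
                rows["wood_samples"].append({
                    "tree_id": t.tree_id, "disc_id": d.disc_id,
                    "position_index": s.position_index,
                    "fresh_volume_cm3": s.fresh_volume_cm3,
                    "dry_mass_g": s.dry_mass_g,
                    "is_youngest_sapwood": s.is_youngest_sapwood,
                })
        for b in t.branches:
            row = {"tree_id": t.tree_id, "branch_id": b.branch_id,
                   "ba_cm2": b.basal_area_excl_bark_cm2, "n_shoots": b.n_shoot_apices,
                   "leaf_area_cm2": (np.nan if b.harvested_leaf_area_cm2 is None
                                     else b.harvested_leaf_area_cm2)}
            for i in range(5):
                row[f"leaves_per_shoot_{i+1}"] = (
                    b.leaves_per_shoot[i] if i < len(b.leaves_per_shoot) else np.nan)
            rows["branches"].append(row)

    paths = {}
    for name in FIELD_TABLE_NAMES:
        df = pd.DataFrame(rows[name], columns=_SCHEMAS[name])
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths
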