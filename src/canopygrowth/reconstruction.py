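"""Tree-level trait reconstruction.

Aboveground biomass growth (AGR, kg yr^-1) is rebuilt from the two discs:
wood density of the youngest sapwood times annual basal-area growth gives a
biomass growth rate per unit tree height for each disc; the stem contributes
the disc average times stem height, the crown contributes the upper-disc rate
times crown length (total height minus stem height).  Leaf mass is excluded
because it covaries with total leaf area, one of the explanatory traits.

Total leaf area (TLA) follows the constant basal-area : leaf-area ratio
assumption: the ratio measured on 4-5 branches, averaged per tree, divides
the stem basal area just below the first branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    BranchMeasurement,
    TraitRecord,
    TreeRecord,
    traits_to_frame,
)
from .dendro import DiscDerived, derive_disc
from .errors import DomainError

__all__ = [
    "BranchDerived",
    "biomass_growth_per_height",
    "tree_biomass_growth",
    "branch_leaf_area",
    "tree_ba_la_ratio",
    "total_leaf_area",
    "specific_leaf_area",
    "mean_leaf_area",
    "assemble_trait_record",
    "derive_traits",
]

SapwoodStat = Literal["mean", "lower", "upper"]


@dataclass
class BranchDerived:
    """Leaf area and BA:LA ratio of one branch (both from the shoot census)."""

    branch_id: str
    leaf_area_cm2: float
    ba_la_ratio: float  # cm^2 basal area per cm^2 leaf area


def biomass_growth_per_height(wd_g_cm3: float, ba_growth_cm2_yr: float) -> float:
    """Biomass growth per unit tree height (kg m^-1 yr^-1).

    WD [g cm^-3] x BA growth [cm^2 yr^-1] gives g cm^-1 yr^-1; the factor
    0.1 converts to kg m^-1 yr^-1.
    """
    if wd_g_cm3 is None or not np.isfinite(wd_g_cm3):
        raise DomainError("wood density missing for biomass growth")
    return wd_g_cm3 * ba_growth_cm2_yr * 0.1


def tree_biomass_growth(
    t: TreeRecord, lower: DiscDerived, upper: DiscDerived
) -> float:
    """Absolute aboveground biomass growth AGR (kg yr^-1), stem + crown."""
    if not t.stem_height_m < t.total_height_m:
        raise DomainError(
            f"tree {t.tree_id}: stem height {t.stem_height_m} must be below "
            f"total height {t.total_height_m}")
    if not (lower.height_above_soil_m < upper.height_above_soil_m
            <= t.stem_height_m):
        raise DomainError(
            f"tree {t.tree_id}: disc heights ({lower.height_above_soil_m}, "
            f"{upper.height_above_soil_m}) inconsistent with stem height "
            f"{t.stem_height_m}")
    r_lo = lower.biomass_growth_per_height_kg_m_yr
    r_up = upper.biomass_growth_per_height_kg_m_yr
    stem = 0.5 * (r_lo + r_up) * t.stem_height_m
    crown = r_up * (t.total_height_m - t.stem_height_m)
    return stem + crown


def mean_leaf_area(t: TreeRecord, n_leaves: int = 22) -> float:
    """Tree-level mean leaf area (cm^2) from the pooled 20-25 leaf sample."""
    return t.pooled_leaf_area_cm2 / n_leaves


def branch_leaf_area(b: BranchMeasurement, mean_leaf_area_cm2: float) -> float:
    """Branch leaf area: shoots x mean leaves/shoot x tree mean leaf area."""
    if b.n_shoot_apices <= 0:
        raise DomainError(f"branch {b.branch_id}: shoot count must be positive")
    if not b.leaves_per_shoot:
        raise DomainError(f"branch {b.branch_id}: no leaves-per-shoot counts")
    return b.n_shoot_apices * float(np.mean(b.leaves_per_shoot)) * mean_leaf_area_cm2


def tree_ba_la_ratio(branches: Sequence[BranchDerived]) -> float:
    """Arithmetic mean of per-branch BA:LA ratios (one value per tree)."""
    if not branches:
        raise DomainError("no branches to average")
    return float(np.mean([b.ba_la_ratio for b in branches]))


def total_leaf_area(ba_below_first_branch_m2: float, ratio: float) -> float:
    """TLA (m^2) = stem BA just below the first branch / BA:LA ratio."""
    if ratio <= 0:
        raise DomainError(f"BA:LA ratio must be positive, got {ratio}")
    return ba_below_first_branch_m2 / ratio


def specific_leaf_area(pooled_area_cm2: float, pooled_dry_mass_g: float) -> float:
    """SLA (cm^2 g^-1) of the pooled leaf sample."""
    if pooled_dry_mass_g <= 0:
        raise DomainError("pooled leaf dry mass must be positive")
    return pooled_area_cm2 / pooled_dry_mass_g


def _sapwood_stat(lo: float | None, up: float | None, stat: SapwoodStat) -> float | None:
    if lo is None or up is None:
        return None
    if stat == "lower":
        return lo
    if stat == "upper":
        return up
    return 0.5 * (lo + up)


def assemble_trait_record(
    t: TreeRecord,
    lower: DiscDerived,
    upper: DiscDerived,
    n_pooled_leaves: int = 22,
    sapwood_stat: SapwoodStat = "mean",
) -> TraitRecord:
    """Build the tree's row of the trait table from its derived discs.

    Tree-level sapwood area is the mean of the two disc values (converted to
    m^2; null when either disc lacks a sapwood boundary).  Stem basal area is
    the lower disc (the basal sample, nearest breast height).  Sapwood growth
    and lifespan average the two discs by default (``sapwood_stat`` switches
    to a single disc).
    """
    mla = mean_leaf_area(t, n_pooled_leaves)
    derived_branches = [
        BranchDerived(
            branch_id=b.branch_id,
            leaf_area_cm2=branch_leaf_area(b, mla),
            ba_la_ratio=b.basal_area_excl_bark_cm2 / branch_leaf_area(b, mla),
        )
        for b in t.branches
    ]
    ratio = tree_ba_la_ratio(derived_branches)
    ba_upper_m2 = upper.basal_area_cm2 * 1e-4
    tla = total_leaf_area(ba_upper_m2, ratio)

    sa = _sapwood_stat(lower.sapwood_area_cm2, upper.sapwood_area_cm2, "mean")
    lifespan = _sapwood_stat(lower.sapwood_lifespan_yr, upper.sapwood_lifespan_yr,
                             sapwood_stat)
    growth = _sapwood_stat(lower.ba_growth_cm2_yr, upper.ba_growth_cm2_yr,
                           sapwood_stat)

    return TraitRecord(
        tree_id=t.tree_id,
        species=t.species.name,
        agr=tree_biomass_growth(t, lower, upper),
        height=t.total_height_m,
        tla=tla,
        sa=None if sa is None else sa * 1e-4,
        sla=specific_leaf_area(t.pooled_leaf_area_cm2, t.pooled_leaf_dry_mass_g),
        n_leaf=t.n_leaf_pct,
        n_sapw=t.n_sapw_pct,
        ba=lower.basal_area_cm2 * 1e-4,
        sapwood_lifespan=lifespan,
        sapwood_growth=growth,
        sa_imputed=False,
    )


def derive_traits(
    trees: Sequence[TreeRecord],
    n_pooled_leaves: int = 22,
    sapwood_stat: SapwoodStat = "mean",
    convention: str = "mean_radius",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive the full trait table plus the per-disc derived table.

    Returns ``(traits, derived_discs)`` as DataFrames; ``traits`` has one row
    per tree in trait-table column order, ``derived_discs`` one row per disc.
    """
    records = []
    disc_rows = []
    for t in trees:
        lo = derive_disc(t.lower_disc, t.wood_samples[t.lower_disc.disc_id],
                         convention)
        up = derive_disc(t.upper_disc, t.wood_samples[t.upper_disc.disc_id],
                         convention)
        records.append(assemble_trait_record(t, lo, up, n_pooled_leaves,
                                             sapwood_stat))
        for d in (lo, up):
            row = {"tree_id": t.tree_id}
            row.update({k: (np.nan if v is None else v)
                        for k, v in d.__dict__.items()})
            disc_rows.append(row)
    return traits_to_frame(records), pd.DataFrame(disc_rows)
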