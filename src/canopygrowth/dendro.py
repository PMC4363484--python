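"""Disc-level derivations: ring widths, basal area, growth, density, sapwood.

A stem disc is treated as a circle on the mean of its three measured radii
(discs are never perfectly circular, so three radii are measured and
averaged).  Annual basal-area growth is the outermost annulus whose width is
the 5-year mean ring width; sapwood, heartwood and pith partition the disc
under a concentric-circle model on the mean radial lengths, which keeps the
partition identity exact.  The alternative convention (mean of per-radius
areas) is available through ``convention="mean_area"`` for sensitivity
analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .data_model import DiscMeasurement, WoodSample
from .errors import DomainError

__all__ = [
    "DiscDerived",
    "mean_ring_width",
    "disc_basal_area",
    "annual_ba_growth",
    "wood_density",
    "sapwood_geometry",
    "sapwood_width",
    "sapwood_lifespan",
    "youngest_sapwood_density",
    "derive_disc",
]

logger = logging.getLogger(__name__)

Convention = Literal["mean_radius", "mean_area"]


@dataclass
class DiscDerived:
    """Derived quantities for one stem disc (areas cm^2, widths cm)."""

    disc_id: str
    height_above_soil_m: float
    mean_radius_cm: float
    basal_area_cm2: float
    mean_ring_width_cm: float
    ba_growth_cm2_yr: float
    sapwood_area_cm2: float | None
    heartwood_area_cm2: float | None
    pith_area_cm2: float
    sapwood_width_cm: float | None
    sapwood_lifespan_yr: float | None
    wd_youngest_sapwood_g_cm3: float
    biomass_growth_per_height_kg_m_yr: float


def _mean_radius(d: DiscMeasurement) -> float:
    r = float(np.mean(d.radii_cm))
    if any(x <= 0 for x in d.radii_cm):
        raise DomainError(f"disc {d.disc_id}: all radii must be positive, got {d.radii_cm}")
    return r


def mean_ring_width(d: DiscMeasurement) -> float:
    """Arithmetic mean ring width over 3 radii x 5 years (cm yr^-1)."""
    w = d.ring_widths_5yr_cm
    if np.isnan(w).any():
        ri, yi = map(int, np.argwhere(np.isnan(w))[0])
        raise DomainError(
            f"disc {d.disc_id}: missing ring width at radius {ri + 1}, year {yi + 1}")
    if (w < 0).any():
        raise DomainError(f"disc {d.disc_id}: negative ring width")
    return float(w.mean())


def disc_basal_area(d: DiscMeasurement, convention: Convention = "mean_radius") -> float:
    """Disc basal area (cm^2) from the three inside-bark radii."""
    if convention == "mean_area":
        return float(np.mean([math.pi * r * r for r in d.radii_cm]))
    r = _mean_radius(d)
    return math.pi * r * r


def annual_ba_growth(d: DiscMeasurement, convention: Convention = "mean_radius") -> float:
    """Annual basal-area growth (cm^2 yr^-1): the outermost annulus of one
    mean ring width, pi*r^2 - pi*(r - w)^2."""
    w = mean_ring_width(d)
    if convention == "mean_area":
        areas = []
        for r in d.radii_cm:
            if w >= r:
                raise DomainError(
                    f"disc {d.disc_id}: mean ring width {w} >= radius {r}")
            areas.append(math.pi * (r * r - (r - w) ** 2))
        return float(np.mean(areas))
    r = _mean_radius(d)
    if w >= r:
        raise DomainError(
            f"disc {d.disc_id}: mean ring width {w} >= mean radius {r}")
    return math.pi * (r * r - (r - w) ** 2)


def wood_density(s: WoodSample) -> float:
    """Wood density (g cm^-3) = oven-dry mass / fresh volume."""
    if s.fresh_volume_cm3 <= 0:
        raise DomainError(
            f"wood sample {s.position_index}: fresh volume must be positive")
    return s.dry_mass_g / s.fresh_volume_cm3


def sapwood_geometry(
    d: DiscMeasurement, convention: Convention = "mean_radius"
) -> tuple[float, float, float] | None:
    """(sapwood, heartwood, pith) areas in cm^2 under the concentric model.

    Mean radial lengths define concentric circles: pith radius q, heartwood
    outer radius q + h, sapwood outer radius q + h + s.  Returns ``None``
    when the sapwood boundary was not distinguishable.  The three areas sum
    to pi*(q+h+s)^2 exactly.
    """
    if not d.has_sapwood_boundary:
        return None
    s_len = d.sapwood_radial_length_cm
    h_len = d.heartwood_radial_length_cm
    if any(x < 0 for x in s_len) or any(x < 0 for x in h_len) or d.pith_diameter_cm < 0:
        raise DomainError(f"disc {d.disc_id}: negative radial lengths")
    q = d.pith_diameter_cm / 2.0
    s_bar = float(np.mean(s_len))
    h_bar = float(np.mean(h_len))
    pith = math.pi * q * q
    heart = math.pi * ((q + h_bar) ** 2 - q * q)
    sap = math.pi * ((q + h_bar + s_bar) ** 2 - (q + h_bar) ** 2)
    return sap, heart, pith


def sapwood_width(d: DiscMeasurement) -> float | None:
    """Mean sapwood radial length (cm), or None without a sapwood boundary."""
    if not d.has_sapwood_boundary:
        return None
    return float(np.mean(d.sapwood_radial_length_cm))


def sapwood_lifespan(d: DiscMeasurement) -> float | None:
    """Sapwood age (yr): sapwood width / 15-year mean ring width.

    The 15-year mean ring width is averaged arithmetically over the three
    radii, mirroring the 3-radius averaging used elsewhere.
    """
    s_bar = sapwood_width(d)
    if s_bar is None:
        return None
    w15 = float(np.mean(d.mean_ring_width_15yr_cm))
    if not w15 > 0:
        raise DomainError(
            f"disc {d.disc_id}: 15-yr mean ring width must be positive, got {w15}")
    return s_bar / w15


def youngest_sapwood_density(samples: Sequence[WoodSample]) -> float:
    """Wood density of the youngest (cambium-side) sapwood sample.

    A sample flagged ``is_youngest_sapwood`` wins; otherwise the sample with
    the lowest position index (outermost) is used.  A flag that disagrees
    with the position ordering is honoured with a logged warning.
    """
    if not samples:
        raise DomainError("no wood samples available")
    flagged = [s for s in samples if s.is_youngest_sapwood]
    outermost = min(samples, key=lambda s: s.position_index)
    if flagged:
        chosen = flagged[0]
        if chosen.position_index != outermost.position_index:
            logger.warning(
                "youngest-sapwood flag (position %d) disagrees with outermost "
                "position %d; using the flagged sample",
                chosen.position_index, outermost.position_index)
        return wood_density(chosen)
    return wood_density(outermost)


def derive_disc(
    d: DiscMeasurement,
    samples: Sequence[WoodSample],
    convention: Convention = "mean_radius",
) -> DiscDerived:
    """Run every disc-level derivation and bundle the results."""
    r_bar = _mean_radius(d)
    ba = disc_basal_area(d, convention)
    w_bar = mean_ring_width(d)
    dba = annual_ba_growth(d, convention)
    geom = sapwood_geometry(d, convention)
    q = d.pith_diameter_cm / 2.0
    wd = youngest_sapwood_density(samples)
    rate = wd * dba * 0.1  # g cm^-1 yr^-1 -> kg m^-1 yr^-1
    return DiscDerived(
        disc_id=d.disc_id,
        height_above_soil_m=d.height_above_soil_m,
        mean_radius_cm=r_bar,
        basal_area_cm2=ba,
        mean_ring_width_cm=w_bar,
        ba_growth_cm2_yr=dba,
        sapwood_area_cm2=None if geom is None else geom[0],
        heartwood_area_cm2=None if geom is None else geom[1],
        pith_area_cm2=math.pi * q * q,
        sapwood_width_cm=sapwood_width(d),
        sapwood_lifespan_yr=sapwood_lifespan(d),
        wd_youngest_sapwood_g_cm3=wd,
        biomass_growth_per_height_kg_m_yr=rate,
    )
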