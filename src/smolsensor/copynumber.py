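"""Copy-number arithmetic: from membrane spot densities to per-cell copies,
ploidy-corrected totals, proteome fractions, and optical crowding limits.

All operations are pure and exact; the "about" figures quoted for such
estimates are reproduced deterministically by explicit rounding conventions
(2 significant figures for areas, 1 for crowding densities, nearest integer
percent), with raw values always available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CellGeometry",
    "cell_count_from_density",
    "ploidy_scale",
    "proteome_fraction",
    "airy_area",
    "crowding_density",
    "round_sig",
    "copy_number_report",
]


@dataclass(frozen=True)
class CellGeometry:
    """Cell footprint area (um^2), ploidy, and total proteome copy number.

    Defaults describe a HEK293 cell: ~1500 um^2 membrane footprint,
    pseudotriploid genome, ~23,000 total copies of the protein of interest.
    """

    surface_area: float = 1500.0
    ploidy: int = 3
    total_copies: int = 23000

    def __post_init__(self) -> None:
        if self.surface_area <= 0:
            raise ValueError("surface_area must be positive")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        if self.total_copies <= 0:
            raise ValueError("total_copies must be positive")


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def cell_count_from_density(density: float, geometry: CellGeometry) -> float:
    """Molecules per cell = (density per 100 um^2) / 100 * surface area."""
    if density < 0:
        raise ValueError("density must be non-negative")
    return density / 100.0 * geometry.surface_area


def ploidy_scale(count: float, ploidy: int) -> float:
    """Scale a per-allele count by ploidy (single-allele tagging)."""
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    return count * ploidy


def proteome_fraction(count: float, total_copies: float) -> tuple[float, int]:
    """Percentage of the total copy number; returns (raw_pct, rounded_pct)."""
    if total_copies <= 0:
        raise ValueError("total_copies must be positive")
    pct = 100.0 * count / total_copies
    return pct, int(round(pct))


def airy_area(diameter_nm: float) -> tuple[float, float]:
    """Area of a diffraction-limited disc of given diameter (nm) in um^2.

    Returns (raw, rounded-to-2-significant-figures).
    """
    if diameter_nm <= 0:
        raise ValueError("diameter must be positive")
    r_um = diameter_nm / 2.0 / 1000.0
    raw = math.pi * r_um**2
    return raw, round_sig(raw, 2)


def crowding_density(airy_area_um2: float) -> tuple[float, float]:
    """Density (per 100 um^2) at which diffraction discs tile the membrane
    and single molecules can no longer be resolved.

    Returns (raw, rounded-to-1-significant-figure).
    """
    if airy_area_um2 <= 0:
        raise ValueError("airy_area must be positive")
    raw = 100.0 / airy_area_um2
    return raw, round_sig(raw, 1)


def copy_number_report(density: float, geometry: CellGeometry = CellGeometry(),
                       airy_diameter_nm: float = 210.0) -> dict:
    """Full worked-example chain from a measured density to a crowding limit."""
    per_cell = cell_count_from_density(density, geometry)
    total = ploidy_scale(per_cell, geometry.ploidy)
    pct_raw, pct_round = proteome_fraction(total, geometry.total_copies)
    a_raw, a_round = airy_area(airy_diameter_nm)
    d_raw, d_round = crowding_density(a_round)
    return {
        "density_per_100um2": density,
        "surface_area_um2": geometry.surface_area,
        "molecules_per_cell": per_cell,
        "ploidy": geometry.ploidy,
        "ploidy_scaled_copies": total,
        "total_copies": geometry.total_copies,
        "proteome_fraction_pct": pct_raw,
        "proteome_fraction_pct_rounded": pct_round,
        "airy_diameter_nm": airy_diameter_nm,
        "airy_area_um2": a_raw,
        "airy_area_um2_2sf": a_round,
        "crowding_density_per_100um2": d_raw,
        "crowding_density_per_100um2_1sf": d_round,
    }
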