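"""Land-use class conventions shared across the pipeline."""

from __future__ import annotations

from .grid import CategoricalGrid, Grid

#: Integer codes for the land-use legend.
PADDY, DRY_LAND, FOREST, WATER, ARTIFICIAL, OTHER = 1, 2, 3, 4, 5, 6

LAND_CLASSES: dict[int, str] = {
    PADDY: "paddy",
    DRY_LAND: "dry_land",
    FOREST: "forest",
    WATER: "water",
    ARTIFICIAL: "artificial",
    OTHER: "other",
}

#: Farmland = paddy + dry land (the mask over which fertilizer and
#: pesticide intensities are dispersed).
FARMLAND_CODES = (PADDY, DRY_LAND)

#: Default "suitable breeding area" for the livestock indicator: dry land
#: and other (unused) land; configurable where scenes differ.
BREEDING_CODES = (DRY_LAND, OTHER)


def farmland_mask(land_use: CategoricalGrid) -> Grid:
    return land_use.mask_of(*FARMLAND_CODES)


def water_mask(land_use: CategoricalGrid) -> Grid:
    return land_use.mask_of(WATER)


def paddy_mask(land_use: CategoricalGrid) -> Grid:
    return land_use.mask_of(PADDY)
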