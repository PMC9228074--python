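"""Controlled vocabularies shared across the pipeline.

Land use is classified into five types (managed forest, plantation,
pasture, cropland, urban), each at three management intensities
(minimal, light, intense), giving 15 land-use categories.  Species
loss is accounted for five taxa; the four vertebrate classes are
additionally reported as a single aggregate.
"""

from __future__ import annotations

LAND_USE_TYPES: tuple[str, ...] = (
    "managed_forest",
    "plantation",
    "pasture",
    "cropland",
    "urban",
)

INTENSITIES: tuple[str, ...] = ("minimal", "light", "intense")

#: The 15 land-use categories, ordered type-major then intensity.
CATEGORIES: tuple[str, ...] = tuple(
    f"{t}_{i}" for t in LAND_USE_TYPES for i in INTENSITIES
)

TAXA: tuple[str, ...] = ("mammals", "amphibians", "reptiles", "birds", "plants")

#: Taxa summed into the "vertebrates" headline aggregate.
VERTEBRATE_TAXA: tuple[str, ...] = ("mammals", "amphibians", "reptiles", "birds")

#: Global species richness per taxon (species counts used to express
#: absolute species-equivalent losses as a share of the global pool).
GLOBAL_SPECIES_TOTALS: dict[str, int] = {
    "mammals": 5490,
    "amphibians": 6433,
    "reptiles": 9084,
    "birds": 10104,
    "plants": 321212,
}


def split_category(category: str) -> tuple[str, str]:
    """Split ``"pasture_light"`` into ``("pasture", "light")``."""
    land_type, _, intensity = category.rpartition("_")
    if land_type not in LAND_USE_TYPES or intensity not in INTENSITIES:
        raise ValueError(f"unknown land-use category: {category!r}")
    return land_type, intensity
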