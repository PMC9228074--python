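"""Proportional spatial allocation of land-use footprints.

Consumption-based land use computed at country resolution is spread
onto grid cells proportionally to the observed production pattern: the
land a consumer drives in producing region ``r`` for product ``i`` and
category ``m`` is distributed over ``r``'s cells with weights taken
from the (r, i, m) land-use layer — an equal-preference assumption with
no competition between consumers (the model stays linear).

Products without a dedicated map fall back to the producing country's
aggregate category-``m`` map.  Every cell is then flagged by key
biodiversity area (KBA) membership, splitting each allocation into an
inside/outside partition that is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .errors import AllocationGapError, StructuralError, ValidationError
from .mrio import FootprintTensor, LandExtension
from .rasters import GridGeometry

__all__ = [
    "CellMasks",
    "LandUseGrid",
    "SpatialShares",
    "AllocatedLandGrid",
    "normalize_distribution",
    "allocate",
    "allocate_production",
    "split_by_kba",
    "country_marginals",
]


@dataclass
class CellMasks:
    """Country, ecoregion and KBA rasters on one shared grid.

    ``country_id`` / ``ecoregion_id`` are integer rasters (−1 = no
    data); ``country_id`` indexes into ``regions``.  ``kba`` is a
    boolean raster; membership is binary per cell.
    """

    country_id: np.ndarray
    ecoregion_id: np.ndarray
    kba: np.ndarray
    geometry: GridGeometry
    regions: list[str]

    def __post_init__(self):
        self.country_id = np.asarray(self.country_id, dtype=np.int64)
        self.ecoregion_id = np.asarray(self.ecoregion_id, dtype=np.int64)
        self.kba = np.asarray(self.kba, dtype=bool)
        for name, arr in (
            ("country_id", self.country_id),
            ("ecoregion_id", self.ecoregion_id),
            ("kba", self.kba),
        ):
            if arr.shape != self.geometry.shape:
                raise StructuralError(f"{name} does not match the grid geometry")
        if self.country_id.max(initial=-1) >= len(self.regions):
            raise ValidationError("country_id exceeds the region list")

    def country_mask(self, region: str) -> np.ndarray:
        return self.country_id == self.regions.index(region)

    def kba_area_m2(self, region: str) -> float:
        """Total KBA area within a country (binary cell membership)."""
        inside = self.country_mask(region) & self.kba
        return float(inside.sum()) * self.geometry.cell_area_m2


@dataclass
class LandUseGrid:
    """Stack of absolute land-use layers (m² per cell).

    Layers are keyed ``(region, product, category)``; a key with
    ``product=None`` is the country's aggregate map for that category
    and serves as the fallback for products without a dedicated map.
    """

    layers: dict[tuple[str, str | None, str], np.ndarray]
    geometry: GridGeometry

    def __post_init__(self):
        for key, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.geometry.shape:
                raise StructuralError(f"layer {key} does not match the grid geometry")
            if np.any(arr < 0):
                raise ValidationError(f"layer {key} contains negative cells")
            self.layers[key] = arr

    def layer_for(self, region: str, product: str, category: str) -> np.ndarray | None:
        """Dedicated (r, i, m) layer, else the (r, m) fallback map."""
        layer = self.layers.get((region, product, category))
        if layer is None:
            layer = self.layers.get((region, None, category))
        return layer


@dataclass
class SpatialShares:
    """Normalized per-layer cell shares; each resolved (r, i, m) layer
    sums to one."""

    shares: dict[tuple[str, str, str], np.ndarray]
    geometry: GridGeometry


def normalize_distribution(
    land_grid: LandUseGrid, extension: LandExtension
) -> SpatialShares:
    """Turn absolute land-use layers into allocation shares.

    For every (region, product, category) with land in the extension,
    the resolved layer is normalized to sum to one.  A land-using entry
    whose resolved layer is missing or all-zero is an allocation gap
    and raises :class:`AllocationGapError` listing the offenders.
    """
    shares: dict[tuple[str, str, str], np.ndarray] = {}
    missing: list[tuple[str, str, str]] = []
    cache: dict[int, np.ndarray] = {}
    for ir, region in enumerate(extension.regions):
        for ip, product in enumerate(extension.products):
            for im, category in enumerate(extension.categories):
                if extension.d[ir, ip, im] <= 0:
                    continue
                layer = land_grid.layer_for(region, product, category)
                if layer is None or not np.any(layer > 0):
                    missing.append((region, product, category))
                    continue
                key = id(layer)
                if key not in cache:
                    cache[key] = layer / layer.sum()
                shares[(region, product, category)] = cache[key]
    if missing:
        raise AllocationGapError(missing)
    return SpatialShares(shares=shares, geometry=land_grid.geometry)


@dataclass
class AllocatedLandGrid:
    """Per-cell land allocation: dims (consumer, category, row, col).

    The producing country of each cell is implicit through the country
    mask.
    """

    data: np.ndarray
    consumers: list[str]
    categories: list[str]
    geometry: GridGeometry

    def __post_init__(self):
        expected = (len(self.consumers), len(self.categories)) + self.geometry.shape
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != expected:
            raise StructuralError(
                f"allocated grid must have shape {expected}, got {self.data.shape}"
            )

    def total_by_cell(self) -> np.ndarray:
        return self.data.sum(axis=(0, 1))


def allocate(
    footprint: FootprintTensor | xr.DataArray,
    shares: SpatialShares,
    masks: CellMasks,
) -> AllocatedLandGrid:
    """Spread the footprint tensor onto grid cells.

    ``cell[s, m, n] = Σ_{r,i} F[s, r, i, m] · share[n | r, i, m]``.
    Conservation holds per (consumer, producer country, category)
    because each share layer sums to one within its country.
    """
    F = footprint.total if isinstance(footprint, FootprintTensor) else footprint
    masks.geometry.require_same_grid(shares.geometry, "share layers")
    consumers = [str(v) for v in F.coords["consumer"].values]
    producers = [str(v) for v in F.coords["producer"].values]
    products = [str(v) for v in F.coords["product"].values]
    categories = [str(v) for v in F.coords["category"].values]
    values = F.transpose("consumer", "producer", "product", "category").values
    out = np.zeros((len(consumers), len(categories)) + masks.geometry.shape)
    gaps = []
    for ir, region in enumerate(producers):
        for ip, product in enumerate(products):
            for im, category in enumerate(categories):
                amounts = values[:, ir, ip, im]
                if not np.any(amounts > 0):
                    continue
                layer = shares.shares.get((region, product, category))
                if layer is None:
                    gaps.append((region, product, category))
                    continue
                out[:, im] += amounts[:, np.newaxis, np.newaxis] * layer
    if gaps:
        raise AllocationGapError(gaps)
    return AllocatedLandGrid(
        data=out, consumers=consumers, categories=categories, geometry=masks.geometry
    )


def allocate_production(
    extension: LandExtension, shares: SpatialShares, masks: CellMasks
) -> AllocatedLandGrid:
    """Spread production-based land (the extension itself) onto cells.

    Returns a single-consumer grid labelled ``__production__``; used for
    territorial aggregates such as land inside KBAs per country.
    """
    masks.geometry.require_same_grid(shares.geometry, "share layers")
    out = np.zeros((1, len(extension.categories)) + masks.geometry.shape)
    gaps = []
    for ir, region in enumerate(extension.regions):
        for ip, product in enumerate(extension.products):
            for im, category in enumerate(extension.categories):
                amount = extension.d[ir, ip, im]
                if amount <= 0:
                    continue
                layer = shares.shares.get((region, product, category))
                if layer is None:
                    gaps.append((region, product, category))
                    continue
                out[0, im] += amount * layer
    if gaps:
        raise AllocationGapError(gaps)
    return AllocatedLandGrid(
        data=out,
        consumers=["__production__"],
        categories=list(extension.categories),
        geometry=masks.geometry,
    )


def split_by_kba(
    grid: AllocatedLandGrid, masks: CellMasks
) -> tuple[AllocatedLandGrid, AllocatedLandGrid]:
    """Exact cellwise partition of an allocation by KBA membership."""
    grid.geometry.require_same_grid(masks.geometry, "KBA mask")
    inside = grid.data * masks.kba[np.newaxis, np.newaxis]
    outside = grid.data * (~masks.kba)[np.newaxis, np.newaxis]
    mk = lambda data: AllocatedLandGrid(
        data=data,
        consumers=list(grid.consumers),
        categories=list(grid.categories),
        geometry=grid.geometry,
    )
    return mk(inside), mk(outside)


def country_marginals(grid: AllocatedLandGrid, masks: CellMasks) -> xr.DataArray:
    """Sum cells by producing country: dims (consumer, producer, category).

    Used by conservation checks against the footprint tensor's
    producer-country marginals.
    """
    grid.geometry.require_same_grid(masks.geometry, "country mask")
    flat = grid.data.reshape(grid.data.shape[0], grid.data.shape[1], -1)
    country = masks.country_id.ravel()
    n_regions = len(masks.regions)
    out = np.zeros((flat.shape[0], n_regions, flat.shape[1]))
    valid = country >= 0
    for s in range(flat.shape[0]):
        for m in range(flat.shape[1]):
            out[s, :, m] = np.bincount(
                country[valid], weights=flat[s, m, valid], minlength=n_regions
            )
    return xr.DataArray(
        out,
        dims=("consumer", "producer", "category"),
        coords={
            "consumer": grid.consumers,
            "producer": masks.regions,
            "category": grid.categories,
        },
        name="allocated_land_m2",
    )
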