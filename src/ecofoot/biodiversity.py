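"""Species-loss accounting from allocated land use.

Land occupation is converted into *potential global species loss*
(species-equivalents committed to extinction, including extinction
debt) with characterization factors (CFs): species lost per m² of a
land-use category in an ecoregion, per taxon.  CFs are average (not
marginal) factors and are consumed as data; every cell of an ecoregion
carries that ecoregion's CF.

The cell-level product ``SL = CF · land`` is then aggregated into every
reported account: production- vs consumption-based country totals,
per-capita values, embodied trade flows between region groups, and the
attribution of losses to final products (food via the physical demand
product, nonfood via the monetary demand product).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .categories import GLOBAL_SPECIES_TOTALS, TAXA, VERTEBRATE_TAXA
from .errors import CoverageError, StructuralError, ValidationError
from .mrio import HybridEconomy, LandExtension, block_leontief, disaggregate_rest_of_world
from .spatial import AllocatedLandGrid, CellMasks, SpatialShares

__all__ = [
    "CFTable",
    "SpeciesLossAccount",
    "FlowMatrix",
    "species_loss",
    "production_vs_consumption",
    "per_capita",
    "trade_flows",
    "loss_factors",
    "product_attribution",
]

KBA_FLAGS = ("inside", "outside")


@dataclass
class CFTable:
    """Characterization factors and richness metadata per ecoregion.

    ``cf[g, m, eco]`` is the potential global species loss per m² for
    taxon ``g`` under land-use category ``m`` in an ecoregion;
    ``richness_per_m2[g, eco]`` is the species richness density used by
    the country-level decomposition (richness per unit area is assumed
    uniform within an ecoregion); ``taxon_totals`` is global richness
    per taxon for relative-loss reporting.
    """

    taxa: list[str]
    categories: list[str]
    ecoregions: list[int]
    cf: np.ndarray  # (n_taxa, n_categories, n_ecoregions)
    richness_per_m2: np.ndarray  # (n_taxa, n_ecoregions)
    taxon_totals: pd.Series = None

    def __post_init__(self):
        shape = (len(self.taxa), len(self.categories), len(self.ecoregions))
        self.cf = np.asarray(self.cf, dtype=float)
        if self.cf.shape != shape:
            raise StructuralError(f"cf must have shape {shape}, got {self.cf.shape}")
        if np.any(self.cf < 0):
            raise ValidationError("characterization factors must be non-negative")
        self.richness_per_m2 = np.asarray(self.richness_per_m2, dtype=float)
        if self.richness_per_m2.shape != (len(self.taxa), len(self.ecoregions)):
            raise StructuralError("richness_per_m2 must be (taxa, ecoregions)")
        if self.taxon_totals is None:
            self.taxon_totals = pd.Series(
                {g: GLOBAL_SPECIES_TOTALS.get(g, np.nan) for g in self.taxa}
            )
        else:
            self.taxon_totals = pd.Series(self.taxon_totals, dtype=float)

    def cell_view(self, masks: CellMasks, *, strict: bool = True) -> np.ndarray:
        """CF raster view, shape (n_taxa, n_categories, n_rows, n_cols).

        Every cell gets its ecoregion's CF.  Cells whose ecoregion is
        missing from the table raise :class:`CoverageError` in strict
        mode and are zero-filled otherwise.
        """
        eco = masks.ecoregion_id
        index = np.full(eco.shape, -1, dtype=np.int64)
        pos = {e: k for k, e in enumerate(self.ecoregions)}
        known = np.zeros(eco.shape, dtype=bool)
        for e, k in pos.items():
            hit = eco == e
            index[hit] = k
            known |= hit
        uncovered = (~known) & (eco >= 0)
        if np.any(uncovered):
            missing = sorted(set(eco[uncovered].tolist()))
            if strict:
                raise CoverageError(
                    f"no characterization factors for ecoregions {missing}"
                )
        safe = np.where(index >= 0, index, 0)
        view = self.cf[:, :, safe]
        view[:, :, index < 0] = 0.0
        return view

    def richness_cell_view(self, masks: CellMasks) -> np.ndarray:
        """Richness density raster view (n_taxa, n_rows, n_cols)."""
        eco = masks.ecoregion_id
        pos = {e: k for k, e in enumerate(self.ecoregions)}
        index = np.full(eco.shape, -1, dtype=np.int64)
        for e, k in pos.items():
            index[eco == e] = k
        safe = np.where(index >= 0, index, 0)
        view = self.richness_per_m2[:, safe]
        view[:, index < 0] = 0.0
        return view


@dataclass
class SpeciesLossAccount:
    """Potential global species loss by taxon, consumer, producer,
    land-use category and KBA flag (species-equivalents)."""

    sl: xr.DataArray  # dims taxon, consumer, producer, category, kba

    @property
    def taxa(self) -> list[str]:
        return [str(v) for v in self.sl.coords["taxon"].values]

    def total(self) -> float:
        return float(self.sl.sum())

    def by_kba(self) -> xr.DataArray:
        return self.sl.sum(["consumer", "producer", "category"])

    def vertebrates(self) -> xr.DataArray:
        """Vertebrate aggregate: plain sum of the four class losses."""
        present = [g for g in VERTEBRATE_TAXA if g in self.taxa]
        return self.sl.sel(taxon=present).sum("taxon")

    def headline(self) -> xr.DataArray:
        """Two headline groups: plants and the vertebrate aggregate."""
        vert = self.vertebrates().expand_dims(taxon=["vertebrates"])
        plants = self.sl.sel(taxon=["plants"])
        return xr.concat([plants, vert], dim="taxon")

    def relative_loss(self, taxon_totals: pd.Series) -> xr.DataArray:
        """Loss as a share of each taxon's global species richness."""
        totals = xr.DataArray(
            [float(taxon_totals[g]) for g in self.taxa],
            dims=("taxon",),
            coords={"taxon": self.taxa},
        )
        return self.sl / totals


def species_loss(
    grid: AllocatedLandGrid,
    cfs: CFTable,
    masks: CellMasks,
    *,
    strict: bool = True,
) -> SpeciesLossAccount:
    """Convert allocated land into species loss and aggregate.

    Cell-level: ``SL[g, s, m, n] = CF[g, m, eco(n)] · land[s, m, n]``,
    then summed by the cell's country (producer) and KBA flag.  With
    ``strict`` (default) a missing CF for a land-bearing cell's
    ecoregion is a coverage error; otherwise it contributes zero.
    """
    grid.geometry.require_same_grid(masks.geometry, "ecoregion raster")
    land = grid.data  # (S, M, H, W)
    if not strict:
        cf_cells = cfs.cell_view(masks, strict=False)
    else:
        # strict coverage applies only where land is actually present
        has_land = land.sum(axis=(0, 1)) > 0
        eco = masks.ecoregion_id
        missing = sorted(
            set(eco[has_land & (eco >= 0)].tolist()) - set(cfs.ecoregions)
        )
        if missing:
            raise CoverageError(
                f"no characterization factors for land-bearing ecoregions {missing}"
            )
        cf_cells = cfs.cell_view(masks, strict=False)
    n_taxa = len(cfs.taxa)
    n_s, n_m = land.shape[0], land.shape[1]
    country = masks.country_id.ravel()
    kba = masks.kba.ravel().astype(np.int64)
    valid = country >= 0
    n_regions = len(masks.regions)
    # composite key: country * 2 + kba flag (1 = inside)
    key = country[valid] * 2 + kba[valid]
    out = np.zeros((n_taxa, n_s, n_regions, n_m, 2))
    land_flat = land.reshape(n_s, n_m, -1)[:, :, valid]
    cf_flat = cf_cells.reshape(n_taxa, n_m, -1)[:, :, valid]
    for g in range(n_taxa):
        for m in range(n_m):
            weights = land_flat[:, m, :] * cf_flat[g, m, np.newaxis, :]
            for s in range(n_s):
                counts = np.bincount(
                    key, weights=weights[s], minlength=n_regions * 2
                ).reshape(n_regions, 2)
                out[g, s, :, m, 1] = counts[:, 1]
                out[g, s, :, m, 0] = counts[:, 0]
    sl = xr.DataArray(
        out[..., ::-1],  # order kba flags (inside, outside)
        dims=("taxon", "consumer", "producer", "category", "kba"),
        coords={
            "taxon": cfs.taxa,
            "consumer": grid.consumers,
            "producer": masks.regions,
            "category": grid.categories,
            "kba": list(KBA_FLAGS),
        },
        name="species_loss",
    )
    return SpeciesLossAccount(sl=sl)


def production_vs_consumption(account: SpeciesLossAccount) -> pd.DataFrame:
    """Paired country accounts per taxon.

    Production-based loss is the marginal over consumers (where the
    land lies); consumption-based is the marginal over producers (who
    finally consumes).  Their global totals coincide.
    """
    production = account.sl.sum(["consumer", "category", "kba"]).rename(
        producer="region"
    )
    consumption = account.sl.sum(["producer", "category", "kba"]).rename(
        consumer="region"
    )
    df = pd.DataFrame(
        {
            "production_based": production.to_series(),
            "consumption_based": consumption.to_series(),
        }
    )
    df.index.names = ["taxon", "region"]
    return df.reset_index()


def per_capita(table: pd.DataFrame, population: pd.Series) -> pd.DataFrame:
    """Divide every numeric column by each row's country population."""
    population = pd.Series(population, dtype=float)
    if (population <= 0).any():
        raise ValidationError("population must be positive")
    missing = set(table["region"]) - set(population.index)
    if missing:
        raise ValidationError(f"population missing for regions: {sorted(missing)}")
    out = table.copy()
    pop = table["region"].map(population)
    for col in out.columns:
        if col not in ("taxon", "region") and pd.api.types.is_numeric_dtype(out[col]):
            out[col] = out[col] / pop
    return out


@dataclass
class FlowMatrix:
    """Embodied species-loss flows between region groups.

    ``flows[g, G_r, G_s]`` sums loss occurring in producer group
    ``G_r`` over consumers in group ``G_s``; the diagonal is domestic
    loss and ``trade_share`` (percent) is ``1 − trace/total``.
    """

    flows: xr.DataArray  # dims taxon, producer_group, consumer_group
    trade_share_pct: pd.Series  # per taxon


def trade_flows(account: SpeciesLossAccount, grouping: dict[str, str]) -> FlowMatrix:
    """Aggregate the account into a producer-group × consumer-group
    flow matrix (e.g. seven world regions)."""
    sl = account.sl.sum(["category", "kba"])
    regions = [str(v) for v in sl.coords["producer"].values]
    ungrouped = [r for r in regions if r not in grouping]
    if ungrouped:
        raise ValidationError(f"regions missing from grouping: {ungrouped}")
    groups = sorted(set(grouping.values()))
    pos = {g: k for k, g in enumerate(groups)}
    row = np.array([pos[grouping[r]] for r in regions])
    values = sl.transpose("taxon", "producer", "consumer").values
    n_taxa = values.shape[0]
    out = np.zeros((n_taxa, len(groups), len(groups)))
    for gr in range(len(groups)):
        sel_r = row == gr
        for gs in range(len(groups)):
            sel_s = row == gs
            out[:, gr, gs] = values[:, sel_r][:, :, sel_s].sum(axis=(1, 2))
    flows = xr.DataArray(
        out,
        dims=("taxon", "producer_group", "consumer_group"),
        coords={
            "taxon": account.taxa,
            "producer_group": groups,
            "consumer_group": groups,
        },
        name="species_loss_flow",
    )
    totals = out.sum(axis=(1, 2))
    domestic = np.trace(out, axis1=1, axis2=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(totals > 0, 100.0 * (1.0 - domestic / totals), 0.0)
    return FlowMatrix(
        flows=flows,
        trade_share_pct=pd.Series(share, index=account.taxa, name="trade_share_pct"),
    )


# ---------------------------------------------------------------------------
# Loss factors and final-product attribution


def loss_factors(
    shares: SpatialShares, cfs: CFTable, masks: CellMasks, *, strict: bool = True
) -> xr.DataArray:
    """Species loss per m² of (producer, product, category) land.

    ``lf[g, r, i, m, kba] = Σ_n share[n | r, i, m] · CF[g, m, eco(n)]``
    restricted to cells with the given KBA flag.  Contracting the
    footprint tensor with these factors reproduces the grid-route
    species loss exactly (the allocation is linear), which is how
    final-product attribution avoids re-rasterizing per product.
    """
    cf_cells = cfs.cell_view(masks, strict=strict)
    n_taxa = len(cfs.taxa)
    cats = {m: k for k, m in enumerate(cfs.categories)}
    keys = sorted(shares.shares.keys())
    regions = sorted({k[0] for k in keys})
    products = sorted({k[1] for k in keys})
    rpos = {r: k for k, r in enumerate(regions)}
    ppos = {p: k for k, p in enumerate(products)}
    out = np.zeros((n_taxa, len(regions), len(products), len(cfs.categories), 2))
    kba = masks.kba
    for (region, product, category), layer in shares.shares.items():
        m = cats[category]
        inside = layer * kba
        outside = layer * ~kba
        for g in range(n_taxa):
            out[g, rpos[region], ppos[product], m, 0] = float(
                (cf_cells[g, m] * inside).sum()
            )
            out[g, rpos[region], ppos[product], m, 1] = float(
                (cf_cells[g, m] * outside).sum()
            )
    return xr.DataArray(
        out,
        dims=("taxon", "producer", "product", "category", "kba"),
        coords={
            "taxon": cfs.taxa,
            "producer": regions,
            "product": products,
            "category": cfs.categories,
            "kba": list(KBA_FLAGS),
        },
        name="loss_per_m2_weighted",
    )


def product_attribution(
    economy: HybridEconomy,
    extension: LandExtension,
    y_phys: np.ndarray,
    y_mon: np.ndarray,
    lossfac: xr.DataArray,
    *,
    kba: str = "total",
    food_groups: dict[str, str] | None = None,
    nonfood_groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Attribute species loss to the final-demand product.

    Food loss is attributed to the physical final-demand product
    (summing over last-exporter origins); nonfood loss to the monetary
    final-demand product.  The per-final-sector loss weight is the
    land intensity contracted with per-land loss factors propagated
    through the Leontief blocks, so the groups partition total loss
    exactly.  ``kba`` selects inside/outside/total loss.
    """
    if kba not in ("inside", "outside", "total"):
        raise ValidationError("kba must be inside, outside or total")
    lf = lossfac.sum("kba") if kba == "total" else lossfac.sel(kba=kba)
    lf = lf.reindex(
        producer=economy.phys_regions, product=economy.phys_products, fill_value=0.0
    )
    # loss per unit of gross output of each physical sector:
    # w[g, (r,i)] = Σ_m lf[g,r,i,m] · e[(r,i),m]
    lf_vals = lf.transpose("taxon", "producer", "product", "category").values
    n_taxa = lf_vals.shape[0]
    e = extension.e  # (R, I, M)
    w = (lf_vals * e[np.newaxis]).sum(axis=3).reshape(n_taxa, -1)
    blocks = block_leontief(economy)
    y_mon_s = disaggregate_rest_of_world(
        np.asarray(y_mon, dtype=float),
        economy.mon_regions,
        economy.concordance,
        economy.population,
    )
    taxa = [str(v) for v in lf.coords["taxon"].values]
    records = []
    for provenance, L, y, products, n_reg in (
        ("food", blocks.L_phys, np.asarray(y_phys, float), economy.phys_products,
         len(economy.phys_regions)),
        ("nonfood", blocks.L_cross, y_mon_s, economy.mon_products,
         len(economy.mon_regions)),
    ):
        # loss embodied per unit delivery of final sector (t, j)
        weight = w @ L  # (n_taxa, n_final_sectors)
        loss = weight[:, :, np.newaxis] * y[np.newaxis]  # (taxa, sector, consumer)
        per_product = loss.reshape(n_taxa, n_reg, len(products), -1).sum(axis=(1, 3))
        groups = (food_groups if provenance == "food" else nonfood_groups) or {}
        unknown = [p for p in groups if p not in products]
        if unknown:
            raise ValidationError(f"grouped products not in the table: {unknown}")
        for g_idx, g in enumerate(taxa):
            for p_idx, p in enumerate(products):
                records.append(
                    {
                        "taxon": g,
                        "provenance": provenance,
                        "product": p,
                        "group": groups.get(p, p),
                        "species_loss": float(per_product[g_idx, p_idx]),
                    }
                )
    df = pd.DataFrame.from_records(records)
    if food_groups is not None or nonfood_groups is not None:
        gap = set()
        for prov, groups, products in (
            ("food", food_groups, economy.phys_products),
            ("nonfood", nonfood_groups, economy.mon_products),
        ):
            if groups is not None:
                gap |= set(products) - set(groups)
        if gap:
            raise ValidationError(f"products missing from grouping: {sorted(gap)}")
    return df
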