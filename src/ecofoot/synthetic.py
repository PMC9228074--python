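"""Synthetic toy worlds with known ground truth.

Generates complete, internally consistent datasets — a hybrid
physical/monetary economy, a land-use extension, per-country land-use
rasters, ecoregion/country/KBA masks, characterization factors and
populations — with the statistical structure the accounting pipeline
assumes: a productive economy (block coefficient matrix rescaled to an
exact target spectral radius), non-negative flows, mixed physical
units, configurable trade topology, and balanced tables (final demand
is drawn first and gross output derived from it, so the production/
consumption conservation identity is exact by construction).

Planted scenarios additionally carry closed-form expected results
(species losses, trade shares, CTV vectors) so every pipeline stage can
be checked against an analytic answer.

Real-world counterparts at full scale are a 192-region × 128-product
physical system and a 49-region × 200-product monetary system; the
generator scales to any configured size but defaults to toy dimensions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .biodiversity import CFTable
from .categories import CATEGORIES, GLOBAL_SPECIES_TOTALS, TAXA
from .ctv import CountryDecomposition
from .errors import ConfigError
from .mrio import (
    HybridEconomy,
    LandExtension,
    LinkTable,
    MonetaryIOTable,
    PhysicalIOTable,
    assemble_hybrid,
    technical_coefficients,
)
from .rasters import GridGeometry
from .spatial import CellMasks, LandUseGrid

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "PlantedScenario",
    "BalanceReport",
    "CheckResult",
    "generate",
    "planted_scenario",
    "balance_check",
    "SCENARIOS",
]

_UNITS_CYCLE = ("t", "head", "m3")

#: Default per-taxon CF magnitude ranges (species lost per m²),
#: log-uniform; plants are roughly two orders of magnitude above the
#: vertebrate classes, matching the relative scale of global richness.
DEFAULT_CF_RANGES: dict[str, tuple[float, float]] = {
    "plants": (1e-12, 1e-10),
    "mammals": (1e-13, 1e-11),
    "amphibians": (1e-13, 1e-11),
    "reptiles": (1e-13, 1e-11),
    "birds": (1e-13, 1e-11),
}

#: Default richness-density ranges (species per m² of ecoregion).
DEFAULT_RICHNESS_RANGES: dict[str, tuple[float, float]] = {
    "plants": (1e-9, 1e-7),
    "mammals": (1e-11, 1e-9),
    "amphibians": (1e-11, 1e-9),
    "reptiles": (1e-11, 1e-9),
    "birds": (1e-11, 1e-9),
}

TRADE_TOPOLOGIES = ("autarky", "single-exporter", "random")
SCENARIOS = (
    "no-trade",
    "single-chain",
    "uniform-cf",
    "one-driver-ctv",
    "four-driver-ctv",
)


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of the synthetic world generator.

    All randomness flows from the single ``seed``.  Defaults are toy
    sized so that a full pipeline run stays interactive.
    """

    seed: int = 0
    n_phys_regions: int = 6
    n_mon_regions: int = 3
    n_phys_products: int = 4
    n_mon_products: int = 3
    n_rows: int = 20
    n_cols: int = 30
    resolution_arcmin: float = 5.0
    cell_area_m2: float = 8.6e7
    n_ecoregions: int = 5
    #: scalar = same KBA share for every country; (lo, hi) = per-country
    #: shares drawn uniformly, reflecting real cross-country spread
    kba_fraction: float | tuple = (0.1, 0.4)
    occupied_fraction: float = 0.5
    trade_topology: str = "random"
    trade_density: float = 0.5
    #: fraction of each product's final demand served domestically
    #: before the rest is split across trade partners (home bias)
    home_bias: float = 0.7
    target_spectral_radius: float = 0.6
    link_density: float = 0.5
    #: total biomass absorbed by monetary sectors relative to physical
    #: final demand; 0.35 puts the food route near three quarters of
    #: land demand, the structure observed in real food systems
    nonfood_food_ratio: float = 0.35
    extension_density: float = 0.4
    dedicated_layer_products: int = 1
    cf_ranges: dict = field(default_factory=lambda: dict(DEFAULT_CF_RANGES))
    richness_ranges: dict = field(
        default_factory=lambda: dict(DEFAULT_RICHNESS_RANGES)
    )
    population_range: tuple[float, float] = (1e5, 1e8)
    concordance: dict | None = None

    def __post_init__(self):
        for name in (
            "n_phys_regions",
            "n_mon_regions",
            "n_phys_products",
            "n_mon_products",
            "n_rows",
            "n_cols",
            "n_ecoregions",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0 < self.target_spectral_radius < 1:
            raise ConfigError("target_spectral_radius must lie in (0, 1)")
        kf = self.kba_fraction
        bounds = kf if isinstance(kf, (tuple, list)) else (kf,)
        if not all(0 <= f <= 1 for f in bounds):
            raise ConfigError("kba_fraction must lie in [0, 1]")
        if not 0 < self.occupied_fraction <= 1:
            raise ConfigError("occupied_fraction must lie in (0, 1]")
        if not 0 <= self.home_bias <= 1:
            raise ConfigError("home_bias must lie in [0, 1]")
        if self.nonfood_food_ratio < 0:
            raise ConfigError("nonfood_food_ratio must be non-negative")
        if self.trade_topology not in TRADE_TOPOLOGIES:
            raise ConfigError(f"trade_topology must be one of {TRADE_TOPOLOGIES}")
        if self.n_mon_regions > self.n_phys_regions:
            raise ConfigError("need at least as many physical as monetary regions")
        if self.n_cols < self.n_phys_regions:
            raise ConfigError("grid too narrow: need one column strip per region")
        if self.n_rows < self.n_ecoregions:
            raise ConfigError("grid too short: need one row band per ecoregion")

    @property
    def phys_regions(self) -> list[str]:
        return [f"P{i:02d}" for i in range(self.n_phys_regions)]

    @property
    def mon_regions(self) -> list[str]:
        return [f"M{i:02d}" for i in range(self.n_mon_regions)]

    @property
    def phys_products(self) -> list[str]:
        return [f"crop_{i:02d}" for i in range(self.n_phys_products)]

    @property
    def mon_products(self) -> list[str]:
        return [f"sector_{i:02d}" for i in range(self.n_mon_products)]

    @property
    def units(self) -> dict[str, str]:
        return {
            p: _UNITS_CYCLE[i % len(_UNITS_CYCLE)]
            for i, p in enumerate(self.phys_products)
        }

    def resolved_concordance(self) -> dict[str, str]:
        """Physical → monetary region map; the last monetary region is
        the composite rest-of-world absorbing all remaining physical
        regions."""
        if self.concordance is not None:
            missing = set(self.phys_regions) - set(self.concordance)
            if missing:
                raise ConfigError(f"concordance misses regions {sorted(missing)}")
            return dict(self.concordance)
        mapping = {}
        for i, r in enumerate(self.phys_regions):
            j = min(i, self.n_mon_regions - 1)
            mapping[r] = self.mon_regions[j]
        return mapping

    def geometry(self) -> GridGeometry:
        return GridGeometry(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            resolution_arcmin=self.resolution_arcmin,
            cell_area_m2=self.cell_area_m2,
        )


@dataclass
class SyntheticWorld:
    """A complete generated dataset plus its ground-truth ledger."""

    config: WorldConfig
    phys: PhysicalIOTable
    mon: MonetaryIOTable
    link: LinkTable
    extension: LandExtension
    land_grid: LandUseGrid
    masks: CellMasks
    cfs: CFTable
    population: pd.Series
    concordance: dict[str, str]
    ground_truth: dict = field(default_factory=dict)

    def economy(self) -> HybridEconomy:
        """Assemble the hybrid coefficient system from the tables."""
        A_phys = technical_coefficients(self.phys.Z, self.phys.x)
        A_mon = technical_coefficients(self.mon.Z, self.mon.x)
        A_link = technical_coefficients(self.link.Z, self.mon.x)
        return assemble_hybrid(
            A_phys,
            A_link,
            A_mon,
            phys_regions=self.phys.regions,
            phys_products=self.phys.products,
            mon_regions=self.mon.regions,
            mon_products=self.mon.products,
            concordance=self.concordance,
            population=self.population,
        )


# ---------------------------------------------------------------------------
# Generation helpers


def _trade_mask(n: int, topology: str, density: float, rng) -> np.ndarray:
    allowed = np.eye(n, dtype=bool)
    if topology == "single-exporter" and n > 1:
        allowed[0, :] = True
    elif topology == "random":
        off = rng.random((n, n)) < density
        allowed |= off
    return allowed


def _expand_region_mask(mask: np.ndarray, n_products_row: int, n_products_col: int):
    return np.kron(mask, np.ones((n_products_row, n_products_col), dtype=bool))


def _log_uniform(rng, lo: float, hi: float, size) -> np.ndarray:
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=size))


def _country_strips(config: WorldConfig) -> np.ndarray:
    """Country-ID raster: contiguous column strips, one per region."""
    country = np.zeros((config.n_rows, config.n_cols), dtype=np.int64)
    splits = np.array_split(np.arange(config.n_cols), config.n_phys_regions)
    for idx, cols in enumerate(splits):
        country[:, cols] = idx
    return country


def _ecoregion_bands(config: WorldConfig) -> np.ndarray:
    eco = np.zeros((config.n_rows, config.n_cols), dtype=np.int64)
    splits = np.array_split(np.arange(config.n_rows), config.n_ecoregions)
    for idx, rows in enumerate(splits):
        eco[rows, :] = idx
    return eco


def _make_cfs(config: WorldConfig, rng) -> CFTable:
    """CFs log-uniform within per-taxon ranges, monotone in intensity
    (intense ≥ light ≥ minimal within a type/ecoregion)."""
    n_eco = config.n_ecoregions
    cf = np.zeros((len(TAXA), len(CATEGORIES), n_eco))
    for g, taxon in enumerate(TAXA):
        lo, hi = config.cf_ranges[taxon]
        for t in range(len(CATEGORIES) // 3):
            draws = np.sort(_log_uniform(rng, lo, hi, (3, n_eco)), axis=0)
            cf[g, 3 * t : 3 * t + 3, :] = draws  # minimal, light, intense
    rho = np.zeros((len(TAXA), n_eco))
    for g, taxon in enumerate(TAXA):
        lo, hi = config.richness_ranges[taxon]
        rho[g] = _log_uniform(rng, lo, hi, n_eco)
    return CFTable(
        taxa=list(TAXA),
        categories=list(CATEGORIES),
        ecoregions=list(range(n_eco)),
        cf=cf,
        richness_per_m2=rho,
        taxon_totals=pd.Series(GLOBAL_SPECIES_TOTALS),
    )


def generate(config: WorldConfig) -> SyntheticWorld:
    """Generate a balanced synthetic world (deterministic per seed).

    Construction order guarantees the conservation contracts: the block
    coefficient matrix is rescaled to the exact target spectral radius,
    total final demand is drawn positive, gross output solves the
    Leontief system, and flows are ``Z = A·x̂`` — so per-sector balance
    ``x = Z·1 (+ Z_link·1) + y·1`` holds to machine precision.
    """
    rng = np.random.default_rng(config.seed)
    n_pr, n_pp = config.n_phys_regions, config.n_phys_products
    n_mr, n_mp = config.n_mon_regions, config.n_mon_products
    n_phys, n_mon = n_pr * n_pp, n_mr * n_mp
    concordance = config.resolved_concordance()

    trade_phys = _trade_mask(n_pr, config.trade_topology, config.trade_density, rng)
    trade_mon = _trade_mask(n_mr, config.trade_topology, config.trade_density, rng)
    members: dict[str, list[int]] = {m: [] for m in config.mon_regions}
    for i, r in enumerate(config.phys_regions):
        members[concordance[r]].append(i)
    trade_link = np.zeros((n_pr, n_mr), dtype=bool)
    for j, m in enumerate(config.mon_regions):
        for i in range(n_pr):
            trade_link[i, j] = bool(trade_phys[i, members[m]].any())

    # home bias damps imported intermediate inputs the same way it
    # damps imported final demand; the foreign share is split across
    # potential partners so the aggregate import intensity stays at
    # (1 − home_bias) of a domestic coefficient
    damp_phys = np.where(
        _expand_region_mask(np.eye(n_pr, dtype=bool), n_pp, n_pp),
        1.0,
        (1.0 - config.home_bias) / max(1, n_pr - 1),
    )
    damp_mon = np.where(
        _expand_region_mask(np.eye(n_mr, dtype=bool), n_mp, n_mp),
        1.0,
        (1.0 - config.home_bias) / max(1, n_mr - 1),
    )
    A_phys = rng.random((n_phys, n_phys)) * (rng.random((n_phys, n_phys)) < 0.7)
    A_phys *= _expand_region_mask(trade_phys, n_pp, n_pp) * damp_phys
    np.fill_diagonal(A_phys, rng.uniform(0.5, 1.0, n_phys))
    A_mon = rng.random((n_mon, n_mon)) * (rng.random((n_mon, n_mon)) < 0.7)
    A_mon *= _expand_region_mask(trade_mon, n_mp, n_mp) * damp_mon
    np.fill_diagonal(A_mon, rng.uniform(0.5, 1.0, n_mon))
    A_link = rng.random((n_phys, n_mon)) * (
        rng.random((n_phys, n_mon)) < config.link_density
    )
    A_link *= _expand_region_mask(trade_link, n_pp, n_mp)

    # eigenvalues of the block-triangular system come from the diagonal
    # blocks; one global rescale hits the target radius exactly
    rho_raw = max(
        np.max(np.abs(np.linalg.eigvals(A_phys))),
        np.max(np.abs(np.linalg.eigvals(A_mon))),
    )
    scale = config.target_spectral_radius / rho_raw
    A_phys *= scale
    A_mon *= scale
    A_link *= scale

    # close the tables: demand first, output by Leontief solve
    y_phys_total = rng.uniform(100.0, 1000.0, n_phys)
    y_mon_total = rng.uniform(1e5, 1e6, n_mon)
    x_mon = np.linalg.solve(np.eye(n_mon) - A_mon, y_mon_total)
    # pin the biomass drawn through the monetary route relative to
    # physical final demand (off-diagonal block: spectrum unaffected)
    biomass_to_mon = float((A_link @ x_mon).sum())
    if biomass_to_mon > 0:
        A_link *= config.nonfood_food_ratio * y_phys_total.sum() / biomass_to_mon
    x_phys = np.linalg.solve(
        np.eye(n_phys) - A_phys, y_phys_total + A_link @ x_mon
    )
    Z_phys = A_phys * x_phys[np.newaxis, :]
    Z_mon = A_mon * x_mon[np.newaxis, :]
    Z_link = A_link * x_mon[np.newaxis, :]

    def split_demand(total, n_reg, n_prod, allowed):
        out = np.zeros((n_reg * n_prod, n_reg))
        for t in range(n_reg):
            partners = np.flatnonzero(allowed[t] & (np.arange(n_reg) != t))
            for j in range(n_prod):
                row = t * n_prod + j
                if partners.size == 0:
                    out[row, t] = total[row]
                    continue
                out[row, t] = total[row] * config.home_bias
                sh = rng.dirichlet(np.ones(partners.size))
                out[row, partners] = total[row] * (1.0 - config.home_bias) * sh
        return out

    y_phys = split_demand(y_phys_total, n_pr, n_pp, trade_phys)
    y_mon = split_demand(y_mon_total, n_mr, n_mp, trade_mon)

    phys = PhysicalIOTable(
        regions=config.phys_regions,
        products=config.phys_products,
        Z=Z_phys,
        x=x_phys,
        y=y_phys,
        units=config.units,
    )
    mon = MonetaryIOTable(
        regions=config.mon_regions,
        products=config.mon_products,
        Z=Z_mon,
        x=x_mon,
        y=y_mon,
    )
    link = LinkTable(Z=Z_link)

    # land-use extension: intensities drawn, land areas derived from
    # output so the footprint conservation identity is meaningful
    e = _log_uniform(rng, 1e2, 1e4, (n_pr, n_pp, len(CATEGORIES)))
    e *= rng.random((n_pr, n_pp, len(CATEGORIES))) < config.extension_density
    for r in range(n_pr):  # every region uses some land
        if not np.any(e[r] > 0):
            e[r, 0, rng.integers(len(CATEGORIES))] = _log_uniform(rng, 1e2, 1e4, ())
    d = e * x_phys.reshape(n_pr, n_pp)[:, :, np.newaxis]
    extension = LandExtension(
        regions=config.phys_regions,
        products=config.phys_products,
        categories=list(CATEGORIES),
        d=d,
        e=e,
    )

    geometry = config.geometry()
    country = _country_strips(config)
    eco = _ecoregion_bands(config)
    kba = np.zeros(geometry.shape, dtype=bool)
    flat_country = country.ravel()
    kf = config.kba_fraction
    if isinstance(kf, (tuple, list)):
        fractions = rng.uniform(kf[0], kf[1], n_pr)
    else:
        fractions = np.full(n_pr, float(kf))
    for r in range(n_pr):
        cells = np.flatnonzero(flat_country == r)
        if fractions[r] > 0:
            if cells.size == 0:
                raise ConfigError(f"region {r} has no grid cells for its KBAs")
            k = max(1, round(fractions[r] * cells.size))
            chosen = rng.choice(cells, size=min(k, cells.size), replace=False)
            kba.ravel()[chosen] = True
    masks = CellMasks(
        country_id=country,
        ecoregion_id=eco,
        kba=kba,
        geometry=geometry,
        regions=config.phys_regions,
    )

    def random_layer(region_idx: int, total: float) -> np.ndarray:
        cells = np.flatnonzero(flat_country == region_idx)
        k = max(1, round(config.occupied_fraction * cells.size))
        chosen = rng.choice(cells, size=min(k, cells.size), replace=False)
        layer = np.zeros(geometry.shape)
        layer.ravel()[chosen] = rng.uniform(0.2, 1.0, size=chosen.size)
        layer *= total / layer.sum()
        return layer

    layers: dict[tuple[str, str | None, str], np.ndarray] = {}
    for r, region in enumerate(config.phys_regions):
        for m, category in enumerate(CATEGORIES):
            total = float(d[r, :, m].sum())
            if total > 0:
                layers[(region, None, category)] = random_layer(r, total)
            for ip in range(min(config.dedicated_layer_products, n_pp)):
                amount = float(d[r, ip, m])
                if amount > 0:
                    layers[(region, config.phys_products[ip], category)] = (
                        random_layer(r, amount)
                    )
    land_grid = LandUseGrid(layers=layers, geometry=geometry)

    cfs = _make_cfs(config, rng)
    lo, hi = config.population_range
    population = pd.Series(
        np.round(_log_uniform(rng, lo, hi, n_pr)), index=config.phys_regions
    )

    ground_truth = {
        "target_spectral_radius": config.target_spectral_radius,
        "total_land_m2": float(d.sum()),
        "global_final_demand_phys": float(y_phys_total.sum()),
        "global_final_demand_mon": float(y_mon_total.sum()),
    }
    return SyntheticWorld(
        config=config,
        phys=phys,
        mon=mon,
        link=link,
        extension=extension,
        land_grid=land_grid,
        masks=masks,
        cfs=cfs,
        population=population,
        concordance=concordance,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# Planted scenarios


@dataclass
class PlantedScenario:
    """A generated scenario plus its closed-form expectations.

    ``world`` is None for factor-level scenarios (four-driver CTV),
    which instead carry a ready :class:`CountryDecomposition`.
    """

    name: str
    expected: dict
    world: SyntheticWorld | None = None
    decomposition: CountryDecomposition | None = None


def _constant_cf_table(n_ecoregions: int, cf_by_taxon=None, rho_by_taxon=None):
    cf_by_taxon = cf_by_taxon or {
        g: (1e-10 if g == "plants" else 1e-12) for g in TAXA
    }
    rho_by_taxon = rho_by_taxon or {
        g: (1e-8 if g == "plants" else 1e-10) for g in TAXA
    }
    cf = np.zeros((len(TAXA), len(CATEGORIES), n_ecoregions))
    rho = np.zeros((len(TAXA), n_ecoregions))
    for g, taxon in enumerate(TAXA):
        cf[g, :, :] = cf_by_taxon[taxon]
        rho[g, :] = rho_by_taxon[taxon]
    return CFTable(
        taxa=list(TAXA),
        categories=list(CATEGORIES),
        ecoregions=list(range(n_ecoregions)),
        cf=cf,
        richness_per_m2=rho,
        taxon_totals=pd.Series(GLOBAL_SPECIES_TOTALS),
    )


def _single_chain_world(config: WorldConfig | None) -> PlantedScenario:
    """One consumer country, one producer country, one product grown
    exclusively on the producer's KBA cells; zero intermediate inputs."""
    base = config or WorldConfig()
    cfg = replace(
        base,
        n_phys_regions=2,
        n_mon_regions=1,
        n_phys_products=1,
        n_mon_products=1,
        n_ecoregions=1,
        trade_topology="single-exporter",
    )
    geometry = cfg.geometry()
    consumer, producer = cfg.phys_regions
    product = cfg.phys_products[0]
    category = "cropland_light"
    q = 10.0  # tonnes of final demand
    land = 1e6  # m²
    country = _country_strips(cfg)
    eco = np.zeros(geometry.shape, dtype=np.int64)
    rng = np.random.default_rng(cfg.seed)
    kba = np.zeros(geometry.shape, dtype=bool)
    prod_cells = np.flatnonzero(country.ravel() == 1)
    chosen = rng.choice(
        prod_cells, size=max(1, round(0.5 * prod_cells.size)), replace=False
    )
    kba.ravel()[chosen] = True
    masks = CellMasks(
        country_id=country,
        ecoregion_id=eco,
        kba=kba,
        geometry=geometry,
        regions=cfg.phys_regions,
    )
    layer = np.zeros(geometry.shape)
    layer.ravel()[chosen] = 1.0
    land_grid = LandUseGrid(
        layers={(producer, None, category): layer * (land / layer.sum())},
        geometry=geometry,
    )
    y_phys = np.zeros((2, 2))
    y_phys[1, 0] = q  # sector (producer, product) consumed by the consumer
    phys = PhysicalIOTable(
        regions=cfg.phys_regions,
        products=[product],
        Z=np.zeros((2, 2)),
        x=np.array([0.0, q]),
        y=y_phys,
        units={product: "t"},
    )
    mon = MonetaryIOTable(
        regions=cfg.mon_regions,
        products=cfg.mon_products,
        Z=np.zeros((1, 1)),
        x=np.zeros(1),
        y=np.zeros((1, 1)),
    )
    link = LinkTable(Z=np.zeros((2, 1)))
    d = np.zeros((2, 1, len(CATEGORIES)))
    d[1, 0, CATEGORIES.index(category)] = land
    extension = LandExtension.from_land_areas(
        cfg.phys_regions, [product], list(CATEGORIES), d, phys.x
    )
    cfs = _constant_cf_table(1)
    population = pd.Series([1e6, 1e6], index=cfg.phys_regions)
    world = SyntheticWorld(
        config=cfg,
        phys=phys,
        mon=mon,
        link=link,
        extension=extension,
        land_grid=land_grid,
        masks=masks,
        cfs=cfs,
        population=population,
        concordance=cfg.resolved_concordance(),
        ground_truth={"land_m2": land, "demand": q},
    )
    cf_by_taxon = {g: float(cfs.cf[i, 0, 0]) for i, g in enumerate(TAXA)}
    expected = {
        "consumer": consumer,
        "producer": producer,
        "product": product,
        "category": category,
        "land_m2": land,
        "species_loss": {g: land * cf_by_taxon[g] for g in TAXA},
        "all_inside_kba": True,
        "trade_share_pct": 100.0,
        "food_share_pct": 100.0,
    }
    return PlantedScenario(name="single-chain", expected=expected, world=world)


def _one_driver_world(config: WorldConfig | None) -> PlantedScenario:
    """30 autarkic countries whose within-KBA loss varies only through
    KBA area: occupied share, richness density and relative loss are
    constant across countries, so the area factor is the sole driver."""
    base = config or WorldConfig()
    n = 30
    cfg = replace(
        base,
        n_phys_regions=n,
        n_mon_regions=1,
        n_phys_products=1,
        n_mon_products=1,
        n_rows=20,
        n_cols=2 * n,
        n_ecoregions=1,
        trade_topology="autarky",
    )
    geometry = cfg.geometry()
    country = _country_strips(cfg)
    eco = np.zeros(geometry.shape, dtype=np.int64)
    rng = np.random.default_rng(cfg.seed)
    kba = np.zeros(geometry.shape, dtype=bool)
    used_share = 0.5
    kba_counts = {}
    layers = {}
    d = np.zeros((n, 1, len(CATEGORIES)))
    category = "pasture_light"
    m_idx = CATEGORIES.index(category)
    q = 100.0
    for r, region in enumerate(cfg.phys_regions):
        cells = np.flatnonzero(country.ravel() == r)
        k = 5 + r  # strictly increasing KBA area across countries
        chosen = rng.choice(cells, size=k, replace=False)
        kba.ravel()[chosen] = True
        kba_counts[region] = k
        d[r, 0, m_idx] = used_share * k * cfg.cell_area_m2
        layer = np.zeros(geometry.shape)
        layer.ravel()[chosen] = 1.0
        layers[(region, None, category)] = layer * (d[r, 0, m_idx] / k)
    masks = CellMasks(
        country_id=country,
        ecoregion_id=eco,
        kba=kba,
        geometry=geometry,
        regions=cfg.phys_regions,
    )
    x = np.full(n, q)
    y = np.diag(x)
    phys = PhysicalIOTable(
        regions=cfg.phys_regions,
        products=cfg.phys_products,
        Z=np.zeros((n, n)),
        x=x,
        y=y,
        units={cfg.phys_products[0]: "t"},
    )
    mon = MonetaryIOTable(
        regions=cfg.mon_regions,
        products=["sector_00"],
        Z=np.zeros((1, 1)),
        x=np.zeros(1),
        y=np.zeros((1, 1)),
    )
    link = LinkTable(Z=np.zeros((n, 1)))
    extension = LandExtension.from_land_areas(
        cfg.phys_regions, cfg.phys_products, list(CATEGORIES), d, x
    )
    cfs = _constant_cf_table(1)
    population = pd.Series(np.full(n, 1e6), index=cfg.phys_regions)
    world = SyntheticWorld(
        config=cfg,
        phys=phys,
        mon=mon,
        link=link,
        extension=extension,
        land_grid=LandUseGrid(layers=layers, geometry=geometry),
        masks=masks,
        cfs=cfs,
        population=population,
        concordance=cfg.resolved_concordance(),
        ground_truth={"kba_cells": kba_counts, "used_share": used_share},
    )
    cf_by_taxon = {g: float(cfs.cf[i, 0, 0]) for i, g in enumerate(TAXA)}
    expected = {
        "ctv": (100.0, 0.0, 0.0, 0.0),
        "species_loss_by_region": {
            g: {
                region: cf_by_taxon[g] * float(d[r, 0, m_idx])
                for r, region in enumerate(cfg.phys_regions)
            }
            for g in TAXA
        },
        "used_share": used_share,
    }
    return PlantedScenario(name="one-driver-ctv", expected=expected, world=world)


def _four_driver_decomposition(config: WorldConfig | None) -> PlantedScenario:
    """Factor-level scenario: four monotone co-drivers with exactly
    equal rank-correlation strength.

    One uniform log-factor vector is reused as four cyclic shifts by
    n/4; since the log-loss (the shifts' sum) is invariant under the
    shift, the four factor-vs-loss rank scatter sets coincide and the
    four sample Spearman coefficients are exactly equal, planting a CTV
    of 25% per factor by construction.
    """
    base = config or WorldConfig()
    n = 200
    k = n // 4
    rng = np.random.default_rng(base.seed)
    mu = {
        "kba_area": math.log(1e9),
        "used_share": math.log(0.3),
        "richness_per_area": math.log(1e-8),
        "relative_loss": math.log(1e-3),
    }
    records = []
    factors = list(mu)
    idx = np.arange(n)
    for taxon in TAXA:
        u = rng.uniform(-1.0, 1.0, n)
        cols = {
            f: np.exp(mu[f] + 0.5 * u[(idx + d * k) % n])
            for d, f in enumerate(factors)
        }
        # the log-loss Σ_d u[(i+dk) mod n] is invariant under shifts by
        # k; evaluating it once per orbit keeps the 4-way ties exact, so
        # the four factor-vs-loss rank scatters coincide exactly
        core = sum(u[(idx[:k] + j * k) % n] for j in range(4))
        sl = np.exp(sum(mu.values()) + 0.5 * core[idx % k])
        for i in range(n):
            records.append(
                {
                    "region": f"C{i:03d}",
                    "taxon": taxon,
                    "species_loss": sl[i],
                    "kba_area_m2": cols["kba_area"][i],
                    "landuse_area_m2": cols["kba_area"][i] * cols["used_share"][i],
                    "richness_species": cols["kba_area"][i]
                    * cols["used_share"][i]
                    * cols["richness_per_area"][i],
                    "kba_area": cols["kba_area"][i],
                    "used_share": cols["used_share"][i],
                    "richness_per_area": cols["richness_per_area"][i],
                    "relative_loss": cols["relative_loss"][i],
                    "included": True,
                }
            )
    decomposition = CountryDecomposition(table=pd.DataFrame.from_records(records))
    expected = {"ctv": (25.0, 25.0, 25.0, 25.0), "n_countries": n}
    return PlantedScenario(
        name="four-driver-ctv", expected=expected, decomposition=decomposition
    )


def planted_scenario(name: str, config: WorldConfig | None = None) -> PlantedScenario:
    """Build a named scenario with closed-form expected results."""
    if name == "no-trade":
        base = config or WorldConfig()
        # identity concordance: a composite rest-of-world region would
        # reintroduce flows between its members via the per-capita split
        world = generate(
            replace(
                base,
                trade_topology="autarky",
                n_mon_regions=base.n_phys_regions,
                concordance=None,
            )
        )
        return PlantedScenario(
            name=name, expected={"trade_share_pct": 0.0}, world=world
        )
    if name == "single-chain":
        return _single_chain_world(config)
    if name == "uniform-cf":
        base = config or WorldConfig()
        world = generate(base)
        cf_by_taxon = {
            g: math.sqrt(lo * hi) for g, (lo, hi) in base.cf_ranges.items()
        }
        for i, g in enumerate(world.cfs.taxa):
            world.cfs.cf[i, :, :] = cf_by_taxon[g]
        land_by_region = {
            r: float(world.extension.d[ir].sum())
            for ir, r in enumerate(world.extension.regions)
        }
        return PlantedScenario(
            name=name,
            expected={"cf": cf_by_taxon, "land_by_region_m2": land_by_region},
            world=world,
        )
    if name == "one-driver-ctv":
        return _one_driver_world(config)
    if name == "four-driver-ctv":
        return _four_driver_decomposition(config)
    raise ConfigError(f"unknown scenario {name!r}; valid names: {SCENARIOS}")


# ---------------------------------------------------------------------------
# Balance checking


@dataclass
class CheckResult:
    name: str
    passed: bool
    detail: str = ""

    def to_dict(self) -> dict:
        return {"name": self.name, "passed": self.passed, "detail": self.detail}


@dataclass
class BalanceReport:
    checks: list[CheckResult]

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks)

    def to_dict(self) -> dict:
        return {"ok": self.ok, "checks": [c.to_dict() for c in self.checks]}

    def __getitem__(self, name: str) -> CheckResult:
        for c in self.checks:
            if c.name == name:
                return c
        raise KeyError(name)


def _balance_residuals(x, Z_rows, y_rows, sectors, rel_tol):
    supply = Z_rows + y_rows
    scale = np.maximum(np.abs(x), np.abs(supply))
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(scale > 0, np.abs(x - supply) / scale, 0.0)
    bad = np.flatnonzero(rel > rel_tol)
    names = [str(tuple(sectors[i])) for i in bad[:5]]
    return rel, bad, names


def balance_check(world: SyntheticWorld, rel_tol: float = 1e-9) -> BalanceReport:
    """Verify the accounting identities of a world.

    Checks per-sector balance of both tables, productiveness of the
    assembled economy, non-negativity of all flows, that every
    land-using (region, product, category) entry resolves to a nonzero
    raster layer, and that land-bearing cells carry country and
    ecoregion IDs.  Returns a machine-readable report; never raises.
    """
    checks: list[CheckResult] = []

    z_rows = world.phys.Z.sum(axis=1) + world.link.Z.sum(axis=1)
    y_rows = world.phys.y.sum(axis=1)
    rel, bad, names = _balance_residuals(
        world.phys.x, z_rows, y_rows, list(world.phys.sectors), rel_tol
    )
    checks.append(
        CheckResult(
            "physical_balance",
            bad.size == 0,
            f"max rel residual {rel.max():.3e}"
            + (f"; unbalanced sectors: {names}" if bad.size else ""),
        )
    )
    rel, bad, names = _balance_residuals(
        world.mon.x,
        world.mon.Z.sum(axis=1),
        world.mon.y.sum(axis=1),
        list(world.mon.sectors),
        rel_tol,
    )
    checks.append(
        CheckResult(
            "monetary_balance",
            bad.size == 0,
            f"max rel residual {rel.max():.3e}"
            + (f"; unbalanced sectors: {names}" if bad.size else ""),
        )
    )

    neg = any(
        np.any(arr < 0)
        for arr in (
            world.phys.Z,
            world.phys.x,
            world.phys.y,
            world.mon.Z,
            world.mon.x,
            world.mon.y,
            world.link.Z,
            world.extension.d,
        )
    )
    checks.append(CheckResult("non_negative_flows", not neg))

    try:
        economy = world.economy()
        checks.append(
            CheckResult(
                "productive_economy",
                True,
                f"spectral radius {economy.spectral_radius:.6f}",
            )
        )
    except Exception as exc:
        checks.append(CheckResult("productive_economy", False, str(exc)))

    gaps = []
    for ir, region in enumerate(world.extension.regions):
        for ip, product in enumerate(world.extension.products):
            for im, category in enumerate(world.extension.categories):
                if world.extension.d[ir, ip, im] <= 0:
                    continue
                layer = world.land_grid.layer_for(region, product, category)
                if layer is None or not np.any(layer > 0):
                    gaps.append((region, product, category))
    checks.append(
        CheckResult(
            "extension_raster_consistency",
            not gaps,
            f"{len(gaps)} land-using entries without a raster layer" if gaps else "",
        )
    )

    has_land = np.zeros(world.masks.geometry.shape, dtype=bool)
    for layer in world.land_grid.layers.values():
        has_land |= layer > 0
    orphan = has_land & (
        (world.masks.country_id < 0) | (world.masks.ecoregion_id < 0)
    )
    checks.append(
        CheckResult(
            "mask_consistency",
            not np.any(orphan),
            f"{int(orphan.sum())} land cells without country/ecoregion IDs"
            if np.any(orphan)
            else "",
        )
    )
    return BalanceReport(checks=checks)
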