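"""Hybrid physical/monetary multiregional input-output (MRIO) core.

The model couples two square inter-industry systems — a *physical*
table covering agriculture, food and forestry products in mixed natural
units (tonnes, heads, m³) and a *monetary* table covering the whole
economy in currency units — through a rectangular *link* matrix giving
the physical biomass inputs absorbed per unit of monetary sector
output.  The coupled technical-coefficient matrix is upper block
triangular::

    A = [[A_phys, A_link],
         [0,      A_mon ]]

because monetary sectors deliver no inputs back into the physical
system.  Its Leontief inverse therefore factorizes into blocks

    L = [[L_A, L_A · A_link · L_B],
         [0,   L_B             ]]

with ``L_A = (I − A_phys)⁻¹`` and ``L_B = (I − A_mon)⁻¹``, so the full
dense inversion is never required.

A consumer's land-use footprint is the land-use extension applied to
the gross output its final demand drives through both routes::

    F[s] = ê · (L_A · y_phys[s]  +  L_A · A_link · L_B · y_mon[s])

where ``ê`` is the diagonal of land-use intensities (m² per unit
output, per land-use category).  Final demand carries a *last-exporter*
origin dimension: ``y[(t, j), s]`` is consumption in region ``s`` of
product ``j`` whose last exporting region is ``t``; deeper supply-chain
links follow the Leontief structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .errors import NonProductiveEconomyError, StructuralError, ValidationError

__all__ = [
    "PhysicalIOTable",
    "MonetaryIOTable",
    "LinkTable",
    "HybridEconomy",
    "LeontiefBlocks",
    "LandExtension",
    "FootprintTensor",
    "technical_coefficients",
    "assemble_hybrid",
    "block_leontief",
    "leontief_apply",
    "disaggregate_rest_of_world",
    "consumption_footprint",
    "spectral_radius",
]

#: Side length above which Leontief application solves linear systems
#: per demand column instead of forming explicit inverses.
DEFAULT_SOLVE_THRESHOLD = 512


def sector_index(regions, products) -> pd.MultiIndex:
    """Region-major MultiIndex over (region, product) sectors."""
    return pd.MultiIndex.from_product(
        [list(regions), list(products)], names=["region", "product"]
    )


def _check_nonneg(name: str, arr: np.ndarray) -> None:
    if np.any(np.asarray(arr) < 0):
        raise ValidationError(f"{name} contains negative entries")


def spectral_radius(matrix: np.ndarray) -> float:
    """Largest eigenvalue modulus of a square matrix."""
    if matrix.size == 0:
        return 0.0
    return float(np.max(np.abs(np.linalg.eigvals(matrix))))


# ---------------------------------------------------------------------------
# Tables


@dataclass
class PhysicalIOTable:
    """Physical inter-industry system (agriculture/food/forestry).

    ``Z`` and ``x`` are in natural units per product (the ``units``
    mapping records which); ``y`` is final demand with a last-exporter
    origin on the rows and one column per consuming region.
    """

    regions: list[str]
    products: list[str]
    Z: np.ndarray
    x: np.ndarray
    y: np.ndarray
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.regions) * len(self.products)
        self.Z = np.asarray(self.Z, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.Z.shape != (n, n):
            raise StructuralError(f"Z must be {n}x{n}, got {self.Z.shape}")
        if self.x.shape != (n,):
            raise StructuralError(f"x must have length {n}")
        if self.y.shape[0] != n:
            raise StructuralError("y rows must match the sector index")
        for name, arr in (("Z", self.Z), ("x", self.x), ("y", self.y)):
            _check_nonneg(name, arr)

    @property
    def sectors(self) -> pd.MultiIndex:
        return sector_index(self.regions, self.products)

    @property
    def n_sectors(self) -> int:
        return len(self.regions) * len(self.products)


@dataclass
class MonetaryIOTable:
    """Monetary economy-wide inter-industry system (currency units)."""

    regions: list[str]
    products: list[str]
    Z: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        n = len(self.regions) * len(self.products)
        self.Z = np.asarray(self.Z, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.Z.shape != (n, n):
            raise StructuralError(f"Z must be {n}x{n}, got {self.Z.shape}")
        if self.x.shape != (n,):
            raise StructuralError(f"x must have length {n}")
        if self.y.shape[0] != n:
            raise StructuralError("y rows must match the sector index")
        for name, arr in (("Z", self.Z), ("x", self.x), ("y", self.y)):
            _check_nonneg(name, arr)

    @property
    def sectors(self) -> pd.MultiIndex:
        return sector_index(self.regions, self.products)

    @property
    def n_sectors(self) -> int:
        return len(self.regions) * len(self.products)


@dataclass
class LinkTable:
    """Physical biomass inputs (physical units) to monetary sectors."""

    Z: np.ndarray

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        _check_nonneg("Z_link", self.Z)


# ---------------------------------------------------------------------------
# Coefficients and assembly


def technical_coefficients(Z: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Input requirements per unit of output: ``A = Z · x̂⁻¹``.

    Columns belonging to zero-output sectors are set to zero (the sector
    is inert) instead of being dropped, preserving indexing.
    """
    Z = np.asarray(Z, dtype=float)
    x = np.asarray(x, dtype=float)
    if Z.ndim != 2 or x.ndim != 1 or Z.shape[1] != x.shape[0]:
        raise StructuralError(
            f"Z columns ({Z.shape}) must match output vector length ({x.shape})"
        )
    _check_nonneg("Z", Z)
    _check_nonneg("x", x)
    inv_x = np.zeros_like(x)
    nonzero = x > 0
    inv_x[nonzero] = 1.0 / x[nonzero]
    return Z * inv_x[np.newaxis, :]


@dataclass
class HybridEconomy:
    """Assembled block coefficient system plus region metadata.

    ``concordance`` maps every physical region onto its monetary region
    (many-to-one for composite rest-of-world regions); ``population``
    (persons) is indexed by physical region and drives the per-capita
    disaggregation of composite-region demand.
    """

    A_phys: np.ndarray
    A_link: np.ndarray
    A_mon: np.ndarray
    phys_regions: list[str]
    phys_products: list[str]
    mon_regions: list[str]
    mon_products: list[str]
    concordance: dict[str, str]
    population: pd.Series
    spectral_radius: float = 0.0

    @property
    def n_phys(self) -> int:
        return len(self.phys_regions) * len(self.phys_products)

    @property
    def n_mon(self) -> int:
        return len(self.mon_regions) * len(self.mon_products)

    @property
    def phys_sectors(self) -> pd.MultiIndex:
        return sector_index(self.phys_regions, self.phys_products)

    @property
    def mon_sectors(self) -> pd.MultiIndex:
        return sector_index(self.mon_regions, self.mon_products)

    def full_matrix(self) -> np.ndarray:
        """Dense block coefficient matrix (for oracles and checks)."""
        top = np.hstack([self.A_phys, self.A_link])
        bottom = np.hstack([np.zeros((self.n_mon, self.n_phys)), self.A_mon])
        return np.vstack([top, bottom])


def assemble_hybrid(
    A_phys: np.ndarray,
    A_link: np.ndarray,
    A_mon: np.ndarray,
    *,
    phys_regions,
    phys_products,
    mon_regions,
    mon_products,
    concordance: dict[str, str],
    population: pd.Series | dict,
) -> HybridEconomy:
    """Assemble and validate the upper-block-triangular hybrid system.

    Raises :class:`NonProductiveEconomyError` when the spectral radius
    of the block coefficient matrix is >= 1, and
    :class:`ValidationError` on a concordance that does not cover every
    physical region.
    """
    A_phys = np.asarray(A_phys, dtype=float)
    A_link = np.asarray(A_link, dtype=float)
    A_mon = np.asarray(A_mon, dtype=float)
    n_phys = len(phys_regions) * len(phys_products)
    n_mon = len(mon_regions) * len(mon_products)
    if A_phys.shape != (n_phys, n_phys):
        raise StructuralError(f"A_phys must be {n_phys}x{n_phys}")
    if A_mon.shape != (n_mon, n_mon):
        raise StructuralError(f"A_mon must be {n_mon}x{n_mon}")
    if A_link.shape != (n_phys, n_mon):
        raise StructuralError(
            f"A_link must be {n_phys}x{n_mon}, got {A_link.shape}"
        )
    for name, arr in (("A_phys", A_phys), ("A_link", A_link), ("A_mon", A_mon)):
        _check_nonneg(name, arr)
    missing = [r for r in phys_regions if r not in concordance]
    if missing:
        raise ValidationError(f"concordance misses physical regions: {missing}")
    bad = [r for r, m in concordance.items() if m not in list(mon_regions)]
    if bad:
        raise ValidationError(f"concordance targets unknown monetary regions: {bad}")
    population = pd.Series(population, dtype=float).reindex(list(phys_regions))
    if population.isna().any() or (population <= 0).any():
        raise ValidationError("population must be positive for every physical region")
    # upper-triangular block structure => eigenvalues are those of the
    # diagonal blocks
    rho = max(spectral_radius(A_phys), spectral_radius(A_mon))
    if rho >= 1.0:
        raise NonProductiveEconomyError(
            f"spectral radius {rho:.6f} >= 1: economy is not productive"
        )
    return HybridEconomy(
        A_phys=A_phys,
        A_link=A_link,
        A_mon=A_mon,
        phys_regions=list(phys_regions),
        phys_products=list(phys_products),
        mon_regions=list(mon_regions),
        mon_products=list(mon_products),
        concordance=dict(concordance),
        population=population,
        spectral_radius=rho,
    )


# ---------------------------------------------------------------------------
# Leontief inversion


@dataclass
class LeontiefBlocks:
    """Blocks of the Leontief inverse of the hybrid system."""

    L_phys: np.ndarray  # (I − A_phys)⁻¹
    L_cross: np.ndarray  # L_phys · A_link · L_mon
    L_mon: np.ndarray  # (I − A_mon)⁻¹

    def full(self) -> np.ndarray:
        n_phys, n_mon = self.L_cross.shape
        top = np.hstack([self.L_phys, self.L_cross])
        bottom = np.hstack([np.zeros((n_mon, n_phys)), self.L_mon])
        return np.vstack([top, bottom])


def _inv_leontief(A: np.ndarray, label: str) -> np.ndarray:
    try:
        return np.linalg.inv(np.eye(A.shape[0]) - A)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by radius
        raise NonProductiveEconomyError(f"(I − {label}) is singular") from exc


def block_leontief(economy: HybridEconomy) -> LeontiefBlocks:
    """Explicit block Leontief inverse of the hybrid system.

    Equals the dense inverse of ``I − A`` of the full block matrix; the
    lower-left block is identically zero.
    """
    L_phys = _inv_leontief(economy.A_phys, "A_phys")
    L_mon = _inv_leontief(economy.A_mon, "A_mon")
    L_cross = L_phys @ economy.A_link @ L_mon
    return LeontiefBlocks(L_phys=L_phys, L_cross=L_cross, L_mon=L_mon)


def leontief_apply(
    economy: HybridEconomy,
    y_phys: np.ndarray,
    y_mon: np.ndarray,
    *,
    solve_threshold: int = DEFAULT_SOLVE_THRESHOLD,
) -> np.ndarray:
    """Physical gross output driven by final demand, per demand column.

    Returns ``L_phys · y_phys + L_phys · A_link · L_mon · y_mon`` with
    shape ``(n_phys, n_columns)``.  Above ``solve_threshold`` sectors
    the computation solves linear systems per demand column instead of
    forming explicit inverses; the two paths agree to 1e-10.
    """
    y_phys = np.atleast_2d(np.asarray(y_phys, dtype=float).T).T
    y_mon = np.atleast_2d(np.asarray(y_mon, dtype=float).T).T
    if y_phys.shape[0] != economy.n_phys:
        raise StructuralError("y_phys rows must match physical sectors")
    if y_mon.shape[0] != economy.n_mon:
        raise StructuralError("y_mon rows must match monetary sectors")
    side = economy.n_phys + economy.n_mon
    if side > solve_threshold:
        I_mon = np.eye(economy.n_mon)
        x_mon = np.linalg.solve(I_mon - economy.A_mon, y_mon)
        I_phys = np.eye(economy.n_phys)
        rhs = y_phys + economy.A_link @ x_mon
        return np.linalg.solve(I_phys - economy.A_phys, rhs)
    blocks = block_leontief(economy)
    return blocks.L_phys @ y_phys + blocks.L_cross @ y_mon


# ---------------------------------------------------------------------------
# Land-use extension


@dataclass
class LandExtension:
    """Land areas and land-use intensities of the physical sectors.

    ``d[r, i, m]`` is the land area (m²) occupied by production of
    product ``i`` in region ``r`` under land-use category ``m``;
    ``e = d / x`` is the land-use intensity (m² per unit of output),
    zero for zero-output sectors.
    """

    regions: list[str]
    products: list[str]
    categories: list[str]
    d: np.ndarray  # (n_regions, n_products, n_categories)
    e: np.ndarray = None  # same shape; derived if not given

    def __post_init__(self):
        shape = (len(self.regions), len(self.products), len(self.categories))
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != shape:
            raise StructuralError(f"d must have shape {shape}, got {self.d.shape}")
        _check_nonneg("d", self.d)
        if self.e is not None:
            self.e = np.asarray(self.e, dtype=float)
            if self.e.shape != shape:
                raise StructuralError(f"e must have shape {shape}")
            _check_nonneg("e", self.e)

    @classmethod
    def from_land_areas(
        cls, regions, products, categories, d: np.ndarray, x: np.ndarray
    ) -> "LandExtension":
        """Derive intensities from land areas and sector gross output.

        ``x`` is the physical output vector over the region-major
        (region, product) sector index.  Zero-output sectors get zero
        intensity regardless of ``d`` (inert sector, no division).
        """
        d = np.asarray(d, dtype=float)
        x = np.asarray(x, dtype=float).reshape(len(regions), len(products))
        e = np.zeros_like(d)
        nz = x > 0
        e[nz, :] = d[nz, :] / x[nz][:, np.newaxis]
        return cls(list(regions), list(products), list(categories), d=d, e=e)

    @property
    def e_matrix(self) -> np.ndarray:
        """Intensities as (n_phys_sectors, n_categories)."""
        return self.e.reshape(-1, len(self.categories))

    @property
    def d_matrix(self) -> np.ndarray:
        return self.d.reshape(-1, len(self.categories))

    def d_xr(self) -> xr.DataArray:
        return xr.DataArray(
            self.d,
            dims=("producer", "product", "category"),
            coords={
                "producer": self.regions,
                "product": self.products,
                "category": self.categories,
            },
            name="land_area_m2",
        )


# ---------------------------------------------------------------------------
# Demand disaggregation and footprints


def disaggregate_rest_of_world(
    y_mon: np.ndarray,
    mon_regions: list[str],
    concordance: dict[str, str],
    population: pd.Series,
) -> np.ndarray:
    """Split monetary-region final demand onto physical regions.

    Composite (rest-of-world) monetary regions are split across their
    member physical regions proportionally to population — the same
    per-capita consumption is assumed for all members.  Totals are
    conserved exactly; single-member regions pass through unchanged.

    ``y_mon`` has one column per monetary region; the result has one
    column per physical region, ordered like ``population.index``.
    """
    y_mon = np.asarray(y_mon, dtype=float)
    if y_mon.shape[1] != len(mon_regions):
        raise StructuralError("y_mon must have one column per monetary region")
    population = pd.Series(population, dtype=float)
    phys_regions = list(population.index)
    if set(concordance) != set(phys_regions):
        raise ValidationError("concordance and population must cover the same regions")
    mon_pop = {m: 0.0 for m in mon_regions}
    for r in phys_regions:
        pop = population[r]
        if not pop > 0:
            raise ValidationError(f"population of {r} must be positive")
        mon_pop[concordance[r]] += pop
    out = np.zeros((y_mon.shape[0], len(phys_regions)))
    mon_pos = {m: j for j, m in enumerate(mon_regions)}
    for s, r in enumerate(phys_regions):
        m = concordance[r]
        total = mon_pop[m]
        if total <= 0:
            raise ValidationError(f"composite region {m} has zero total population")
        out[:, s] = y_mon[:, mon_pos[m]] * (population[r] / total)
    return out


@dataclass
class FootprintTensor:
    """Consumption-based land use, resolved along the supply chain.

    ``F[provenance, s, r, i, m]`` is the land (m²) in producer region
    ``r`` under product ``i`` and category ``m`` attributable to final
    consumption in region ``s``.  Provenance separates land driven by
    physical final demand (``food``) from land embodied in monetary
    final demand via the link matrix (``nonfood``); the two partitions
    are disjoint and exhaustive.
    """

    F: xr.DataArray

    @property
    def total(self) -> xr.DataArray:
        return self.F.sum("provenance")

    @property
    def consumers(self) -> list[str]:
        return list(self.F.coords["consumer"].values)

    def conservation_residual(self, extension: LandExtension) -> float:
        """Max relative gap between Σ_s F and the land extension d."""
        produced = self.total.sum("consumer").values
        d = extension.d
        scale = np.maximum(np.abs(d), np.abs(produced))
        diff = np.abs(produced - d)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(scale > 0, diff / scale, 0.0)
        return float(rel.max()) if rel.size else 0.0


def consumption_footprint(
    economy: HybridEconomy,
    extension: LandExtension,
    y_phys: np.ndarray,
    y_mon: np.ndarray,
    *,
    solve_threshold: int = DEFAULT_SOLVE_THRESHOLD,
) -> FootprintTensor:
    """Land-use footprint of each consuming region.

    ``y_phys`` carries one column per physical (consumer) region;
    ``y_mon`` one column per monetary region and is first disaggregated
    onto physical regions per capita.  Negative demand is rejected; a
    demand that exceeds the recorded output balance is permitted (the
    model is linear).
    """
    y_phys = np.asarray(y_phys, dtype=float)
    y_mon = np.asarray(y_mon, dtype=float)
    _check_nonneg("y_phys", y_phys)
    _check_nonneg("y_mon", y_mon)
    if extension.regions != economy.phys_regions or (
        extension.products != economy.phys_products
    ):
        raise StructuralError("extension index does not match the physical system")
    if y_phys.shape != (economy.n_phys, len(economy.phys_regions)):
        raise StructuralError("y_phys must be (n_phys_sectors, n_phys_regions)")
    y_mon_s = disaggregate_rest_of_world(
        y_mon, economy.mon_regions, economy.concordance, economy.population
    )
    zero_mon = np.zeros_like(y_mon_s)
    zero_phys = np.zeros_like(y_phys)
    x_food = leontief_apply(
        economy, y_phys, zero_mon, solve_threshold=solve_threshold
    )
    x_nonfood = leontief_apply(
        economy, zero_phys, y_mon_s, solve_threshold=solve_threshold
    )
    e = extension.e_matrix  # (n_phys, M)
    n_r = len(economy.phys_regions)
    n_i = len(economy.phys_products)
    n_m = len(extension.categories)
    # F[prov, s, sector, m] = e[sector, m] * x_driven[sector, s]
    stacked = np.stack([x_food, x_nonfood])  # (2, n_phys, S)
    F = stacked[:, :, :, np.newaxis].transpose(0, 2, 1, 3) * e[np.newaxis, np.newaxis]
    F = F.reshape(2, n_r, n_r, n_i, n_m)
    da = xr.DataArray(
        F,
        dims=("provenance", "consumer", "producer", "product", "category"),
        coords={
            "provenance": ["food", "nonfood"],
            "consumer": economy.phys_regions,
            "producer": economy.phys_regions,
            "product": economy.phys_products,
            "category": extension.categories,
        },
        name="land_footprint_m2",
    )
    return FootprintTensor(F=da)
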