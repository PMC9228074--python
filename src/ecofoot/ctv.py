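"""Country-level decomposition of KBA species loss and its
contribution-to-variance (CTV) analysis.

Per country ``r`` and taxon ``g``, the potential species loss from land
use within key biodiversity areas factorizes identically into four
multiplicative drivers::

    SL = A · (L/A) · (S/L) · (SL/S)

with ``A`` the country's KBA area, ``L`` the anthropogenic land-use
area within its KBAs, and ``S`` the species richness of the occupied
land (richness density is uniform within an ecoregion, so ``S`` is the
area-weighted sum of ecoregion densities over occupied KBA cells).

The share of cross-country variability each factor explains is
quantified with squared Spearman rank correlations between factor and
loss, normalized to 100%:  ``CTV_d = R_d² / Σ_d' R_d'² × 100``.  Rank
correlations are used because species loss and its drivers are far
from normal; the rank basis also makes CTV invariant to monotone
transformations of any factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .biodiversity import CFTable, SpeciesLossAccount
from .errors import AnalysisError, ValidationError
from .spatial import AllocatedLandGrid, CellMasks

__all__ = [
    "FACTORS",
    "CountryDecomposition",
    "CTVResult",
    "decompose",
    "spearman",
    "ctv",
]

#: The four factors, in reporting order.
FACTORS: tuple[str, ...] = (
    "kba_area",  # A
    "used_share",  # L / A
    "richness_per_area",  # S / L
    "relative_loss",  # SL / S
)


@dataclass
class CountryDecomposition:
    """Long table of per-(region, taxon) quantities and factors.

    Columns: region, taxon, species_loss (SL), kba_area (A),
    landuse_area (L), richness (S), the four factor columns named as in
    :data:`FACTORS`, and ``included`` — False where a zero denominator
    breaks the multiplicative chain (such countries are listwise
    excluded from CTV and reported).
    """

    table: pd.DataFrame

    def included(self, taxon: str) -> pd.DataFrame:
        sub = self.table[(self.table["taxon"] == taxon) & self.table["included"]]
        return sub.reset_index(drop=True)

    def excluded_regions(self) -> list[str]:
        bad = self.table.loc[~self.table["included"], "region"]
        return sorted(set(bad))

    def reconstruction_residual(self) -> float:
        """Max relative gap between the factor product and SL over
        included rows (identity check)."""
        sub = self.table[self.table["included"]]
        if sub.empty:
            return 0.0
        product = (
            sub["kba_area"]
            * sub["used_share"]
            * sub["richness_per_area"]
            * sub["relative_loss"]
        )
        scale = np.maximum(np.abs(sub["species_loss"]), np.abs(product))
        rel = np.where(scale > 0, np.abs(product - sub["species_loss"]) / scale, 0.0)
        return float(np.max(rel)) if len(rel) else 0.0


def decompose(
    account: SpeciesLossAccount,
    masks: CellMasks,
    cfs: CFTable,
    production_grid: AllocatedLandGrid,
) -> CountryDecomposition:
    """Aggregate the within-KBA loss of each country into the four
    factors.

    ``production_grid`` is the production-based cell allocation of the
    land extension (see :func:`ecofoot.spatial.allocate_production`);
    its within-KBA portion gives ``L`` and, weighted by ecoregion
    richness densities, ``S``.  ``SL`` is the production-based (summed
    over consumers and categories) within-KBA loss from the account.
    """
    production_grid.geometry.require_same_grid(masks.geometry, "production grid")
    land_cells = production_grid.data.sum(axis=(0, 1))  # (H, W), all categories
    kba_land = land_cells * masks.kba
    rho = cfs.richness_cell_view(masks)  # (G, H, W)
    sl_prod = account.sl.sel(kba="inside").sum(["consumer", "category"])
    records = []
    for region in masks.regions:
        in_country = masks.country_mask(region)
        A = masks.kba_area_m2(region)
        L = float(kba_land[in_country].sum())
        for g_idx, taxon in enumerate(cfs.taxa):
            S = float((kba_land * rho[g_idx])[in_country].sum())
            SL = float(sl_prod.sel(taxon=taxon, producer=region))
            ok = A > 0 and L > 0 and S > 0
            records.append(
                {
                    "region": region,
                    "taxon": taxon,
                    "species_loss": SL,
                    "kba_area_m2": A,
                    "landuse_area_m2": L,
                    "richness_species": S,
                    "kba_area": A,
                    "used_share": L / A if A > 0 else np.nan,
                    "richness_per_area": S / L if L > 0 else np.nan,
                    "relative_loss": SL / S if S > 0 else np.nan,
                    "included": bool(ok),
                }
            )
    return CountryDecomposition(table=pd.DataFrame.from_records(records))


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks for ties).

    Returns NaN when either sample has (numerically) zero variance —
    the correlation is undefined, and ranking the floating-point
    jitter of a constant would manufacture a spurious signal, so
    variation below 1e-12 relative to the sample magnitude counts as
    zero.  Requires at least three pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("spearman expects two equally long 1-D samples")
    if x.size < 3:
        raise ValidationError("spearman needs at least 3 pairs")

    def degenerate(v: np.ndarray) -> bool:
        return np.ptp(v) <= 1e-12 * np.max(np.abs(v), initial=0.0)

    if degenerate(x) or degenerate(y):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = stats.spearmanr(x, y).statistic
    return float(r)


@dataclass
class CTVResult:
    """Per-taxon CTV shares and the rank correlations behind them.

    ``table`` columns: taxon, factor, spearman_r, ctv_pct, n.  CTV
    sums to 100% per taxon; factors with undefined correlations
    contribute 0.
    """

    table: pd.DataFrame

    def ctv_vector(self, taxon: str) -> np.ndarray:
        sub = self.table[self.table["taxon"] == taxon].set_index("factor")
        return sub.loc[list(FACTORS), "ctv_pct"].to_numpy()


def ctv(decomposition: CountryDecomposition) -> CTVResult:
    """Contribution-to-variance shares of the four factors per taxon.

    For each taxon, the Spearman correlation ``R_d`` between each
    factor and SL is computed over countries with all factors defined;
    ``CTV_d = R_d²/ΣR²·100``.  A factor with zero variance has an
    undefined correlation and contributes 0 (with a warning); if all
    four are undefined the analysis fails.
    """
    records = []
    taxa = sorted(set(decomposition.table["taxon"]))
    for taxon in taxa:
        sub = decomposition.included(taxon)
        if len(sub) < 3:
            raise AnalysisError(
                f"fewer than 3 countries with defined factors for {taxon}"
            )
        r2 = {}
        rs = {}
        for factor in FACTORS:
            r = spearman(sub[factor].to_numpy(), sub["species_loss"].to_numpy())
            rs[factor] = r
            r2[factor] = 0.0 if np.isnan(r) else r * r
        total = sum(r2.values())
        if total == 0:
            raise AnalysisError(
                f"all rank correlations undefined or zero for {taxon}"
            )
        undefined = [f for f in FACTORS if np.isnan(rs[f])]
        if undefined:
            warnings.warn(
                f"zero-variance factors for {taxon}: {undefined}; CTV set to 0",
                stacklevel=2,
            )
        for factor in FACTORS:
            records.append(
                {
                    "taxon": taxon,
                    "factor": factor,
                    "spearman_r": rs[factor],
                    "ctv_pct": 100.0 * r2[factor] / total,
                    "n": len(sub),
                }
            )
    return CTVResult(table=pd.DataFrame.from_records(records))
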