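# Methods

## The accounting problem

Land use is the leading terrestrial driver of biodiversity loss, and
much of it is ultimately driven by consumers far from the land itself.
`ecofoot` implements a complete accounting chain that attributes
*potential global species loss* — species-equivalents committed to
extinction if current land use persists, including extinction debt —
to the countries and final products whose consumption drives the land
use, with special attention to losses inside key biodiversity areas
(KBAs: sites meeting standardized criteria for significant
contribution to the global persistence of biodiversity).

The chain has four stages, each a module:

1. **Hybrid MRIO** (`mrio`) — trace land use to final consumers;
2. **Spatial allocation** (`spatial`) — place that land on grid cells;
3. **Biodiversity accounting** (`biodiversity`) — convert land to
   species loss with ecoregion characterization factors and aggregate;
4. **CTV analysis** (`ctv`) — decompose country-level KBA losses into
   four drivers and rank them by contribution to variance.

A fifth module (`synthetic`) generates complete toy datasets with
known ground truth, and `pipeline`/`cli` orchestrate file-based runs.

## Hybrid physical/monetary MRIO model

Two multiregional input–output systems are coupled: a *physical*
table of agriculture, food and forestry products in natural units
(tonnes, heads, m³ — at real-world scale 192 regions × 128 products)
and a *monetary* economy-wide table (49 regions × 200 products at real
scale, in euros).  A rectangular *link* matrix records the physical
biomass absorbed per unit of monetary sector output.  Technical
coefficients are `A = Z·x̂⁻¹` per system; the coupled matrix is upper
block triangular,

```
A = [[A_phys, A_link],
     [0,      A_mon ]],
```

because monetary sectors deliver no inputs back to the physical
system.  The Leontief inverse then factorizes into blocks

```
L = [[L_A, L_A·A_link·L_B],
     [0,   L_B           ]],   L_A = (I − A_phys)⁻¹,  L_B = (I − A_mon)⁻¹,
```

so a dense inversion of the full system is never needed.  The land-use
footprint of consumer *s* is

```
F[s] = ê · (L_A·y_phys[s] + L_A·A_link·L_B·y_mon[s]),
```

with `ê` the diagonal land-use intensity (m² per unit output, per
producing sector and land-use category, `e = d/x`).  The two demand
routes are kept separate as *food* (physical final demand) and
*nonfood* (monetary final demand) provenances.

Modelling conventions:

- **Final-demand origin.** Demand `y[(t,j), s]` carries the *last
  exporter* `t` of product `j` to consumer `s`; attribution of the
  first supply-chain link honours this origin, deeper links follow the
  Leontief structure.
- **Rest-of-world disaggregation.** Where the monetary system is more
  aggregated than the physical one, composite-region final demand is
  split across member countries proportionally to population (equal
  per-capita consumption); totals are conserved exactly.
- **Zero-output sectors** keep their index with all-zero coefficient
  columns (inert) rather than being dropped — physical tables have
  many empty country–product cells — and never produce division
  artifacts.
- **Units** are never converted: each product carries a unit label and
  the intensities absorb units (m² per tonne/head/m³/euro).
- **Inversion strategy.** Explicit inverses below 512 sectors;
  per-column linear solves above.  The two paths agree to 1e-10 and
  are tested against a dense inversion of the full block matrix.

## Spatial allocation

Footprints computed at country resolution are downscaled with a
*proportional* assumption: the land a consumer drives in producing
country *r*, product *i*, category *m* is spread over *r*'s cells with
weights from the observed (r, i, m) land-use map.  There is no
competition between consumers (the model stays linear), and products
without a dedicated map fall back to the country's aggregate
category-*m* map.  Cells live on a regular geographic grid (5 arcmin
by default), identified by (row, col) from the north-west corner; cell
area is carried explicitly.  KBA membership is binary per cell; the
inside/outside split is an exact cellwise partition, so every
downstream account satisfies inside + outside = total identically.
Country attribution comes solely from the country raster.

Land use is classified into five types (managed forest, plantation,
pasture, cropland, urban) × three intensities (minimal, light,
intense) — 15 categories.

## Species-loss conversion

Characterization factors (CFs) give potential global species lost per
m² of a land-use category in an ecoregion, per taxon (mammals,
amphibians, reptiles, birds, plants).  They are *average* (not
marginal) factors, consumed as data, derived upstream from the
countryside species–area relationship with IUCN-based vulnerability
weighting; every cell of an ecoregion carries that ecoregion's CF.
Cell-level loss is simply `SL = CF · land`, summed into accounts
indexed by taxon × consumer × producer × category × KBA flag.

Reported aggregations mirror standard footprint practice:
production-based (where the land lies) vs consumption-based (who
finally consumes) country tables — their global totals coincide by
construction; per-capita values; embodied flows between region groups
with the trade share `1 − trace/total`; and final-product attribution.
Attribution contracts per-land loss factors
`lf[g,r,i,m] = Σ_n share[n|r,i,m]·CF[g,m,eco(n)]` through the Leontief
blocks, which reproduces the grid-route loss exactly (the allocation
is linear) without re-rasterizing per product.  Food losses attach to
the physical final-demand product, nonfood losses to the monetary
final-demand product (consumer-facing categories), summing over
last-exporter origins.

The vertebrate headline aggregate is the plain sum of the four class
losses (species-equivalents are additive); plants are reported
separately.  Relative losses divide by global taxon richness (defaults
5490 mammals, 6433 amphibians, 9084 reptiles, 10,104 birds, 321,212
plants).  Missing CFs for land-bearing ecoregions are an error by
default (`strict`); a permissive mode zero-fills with a report.

## Four-factor decomposition and CTV

Within-KBA loss of country *r* for taxon *g* factorizes identically:

```
SL = A · (L/A) · (S/L) · (SL/S)
```

- `A` — KBA area (m², binary cell membership × cell area);
- `L/A` — share of KBA area under anthropogenic land use;
- `S/L` — species richness per m² of occupied KBA land (richness
  density is uniform within an ecoregion, so `S` is the area-weighted
  sum of ecoregion densities over occupied cells);
- `SL/S` — relative loss on the occupied land.

Countries with a zero denominator anywhere in the chain are flagged
and listwise-excluded from the CTV step, with a report.  The
contribution to variance of factor *d* is

```
CTV_d = R_d² / Σ_d' R_d'² × 100,
```

where `R_d` is the Spearman rank correlation between the factor and
the loss across countries — rank-based because neither losses nor
drivers are anywhere near normal, which also makes CTV invariant to
monotone transformations of any factor.  The R²-share normalization is
our reading of the CTV convention in the sensitivity-analysis
literature, adopted as a documented interpretation.  Ties take average
ranks (delegated to `scipy.stats.spearmanr`).  A factor whose sample
variation is below 1e-12 relative is treated as constant: its
correlation is undefined and its CTV is 0 with a warning — ranking the
floating-point jitter of a constant would manufacture signal.  If all
four correlations are undefined the analysis errors out.

## Synthetic worlds

The generator emulates the full data stack at toy scale with exact
internal consistency.  Construction order is chosen so the
conservation contracts hold *by construction* rather than
approximately:

1. Coefficient blocks are drawn non-negative with a configurable trade
   topology (autarky / single-exporter / random density) and rescaled
   so the block matrix hits the target spectral radius exactly
   (default 0.6; eigenvalues come from the diagonal blocks, so one
   global rescale suffices and the link rescale below cannot move it).
2. Total final demand is drawn positive first; gross output solves the
   Leontief system; flows are `Z = A·x̂`.  Per-sector balance
   `x = Z·1 (+ Z_link·1) + y·1` is then exact, final demand is
   non-negative, and residual closure is never needed.
3. Demand is split across consumers with a home bias (default 70%
   domestic) applied to both final demand and imported intermediate
   coefficients (foreign share split across partners); the biomass
   drawn through the monetary route is pinned to 0.35× physical final
   demand, putting the food route near three quarters of land demand —
   the qualitative structure of real food systems.
4. Land-use intensities are drawn log-uniform (1e2–1e4 m² per unit)
   and the extension is `d = e·x`, so footprint conservation is a
   meaningful test, not a tautology.
5. Rasters: countries are contiguous column strips, ecoregions row
   bands, KBA shares per country drawn from a range (default 10–40% of
   cells) so KBA area genuinely varies across countries; land-use
   layers are random fields on a configurable occupied fraction of
   each country, scaled to the extension totals, with optional
   dedicated per-product layers exercising the fallback logic.
6. CFs are log-uniform within per-taxon ranges (plants 1e-12–1e-10,
   vertebrate classes 1e-13–1e-11 species/m²) and made
   intensity-monotone (intense ≥ light ≥ minimal) by sorting — the
   qualitative structure of intensity-dependent CFs without copying
   any published values.  Richness densities are log-uniform per
   ecoregion.  Populations are log-uniform between 1e5 and 1e8.

All randomness flows from one seed; generation is bit-reproducible.
`balance_check` verifies every identity and returns a machine-readable
report naming any unbalanced sector.

### Planted scenarios

- **no-trade** — autarky with a 1:1 region concordance (a composite
  rest-of-world region would reintroduce flows between its members
  through the per-capita split); expected trade share exactly 0%.
- **single-chain** — one consumer, one producer, one product grown
  exclusively on the producer's KBA cells, no intermediate inputs;
  expected loss is exactly land × CF, 100% trade share, 100%
  single-product food attribution.
- **uniform-cf** — CFs flattened per taxon; country loss ratios must
  equal land-use ratios.
- **one-driver-ctv** — 30 autarkic countries whose KBA area increases
  strictly while occupied share (0.5), richness density and relative
  loss are constant; expected CTV (100, 0, 0, 0).  Cell values are
  chosen so the constant factors are *exactly* constant in floating
  point.
- **four-driver-ctv** — a factor-level scenario (it returns the
  decomposition table directly; rank correlations cannot be controlled
  through the full spatial pipeline): one uniform log-factor vector
  reused as four cyclic shifts by n/4, per-factor scale constants,
  loss = product.  The shifted sum is invariant under the shift, so
  the four factor-vs-loss rank scatters coincide and the four sample
  Spearman coefficients are exactly equal — CTV is 25% per factor by
  construction at n = 200 countries.

## Numerical choices

- Conservation checks at 1e-9 relative (configurable); block-inverse
  and solve-path equivalence at 1e-10; planted-scenario recovery at
  1e-12 relative; decomposition reconstruction at 1e-12 relative.
- Relative residuals are measured against the larger of the two
  compared magnitudes; 0/0 counts as zero residual.
- Spearman degeneracy threshold 1e-12 relative sample variation (see
  above).
- Demand splits use Dirichlet(1) shares; ties in CF intensity sorting
  are resolved by the sort order.

## Problem sizes

Default worlds are deliberately small — 6 physical regions × 4
products, 3 monetary regions × 3 products, a 20 × 30 grid, 5
ecoregions — which keeps every property test and the full pipeline
interactive while exercising all structural features (composite
regions, mixed units, dedicated and fallback maps, both demand
routes).  The generator scales to the real systems' 192 × 128 and
49 × 200 shapes if asked.

## What the synthetic worlds do and do not show

Passing tests demonstrate that the accounting machinery is *exact*:
balances, conservation identities, partitions and planted recoveries
hold to stated tolerances.  The toy worlds do **not** emulate the
statistical realism of real IO databases (sparsity patterns, sectoral
correlations, price structures), real geography (country shapes,
ecoregion boundaries, spatial autocorrelation of land use), partial
KBA cell coverage, or empirical CF magnitudes beyond order-of-
magnitude ranges.  Headline numbers from a toy run (absolute losses,
trade shares, CTV rankings) characterize the synthetic world only and
are not estimates of any real-world quantity.

## Known limitations

- Proportional spatial allocation ignores that export production may
  concentrate near infrastructure; nonproportional allocation is out
  of scope.
- KBA membership is binary at cell level; fractional coverage is not
  modelled.
- CFs are consumed as given; no uncertainty propagation, no marginal
  CF mode, no aquatic taxa, single-snapshot semantics (no land-use
  change over time).
- The block-triangular coupling forbids re-export of physical products
  through monetary sectors back into physical ones.
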