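"""Species-loss conversion and the reported aggregations."""

import numpy as np
import pandas as pd
import pytest

import ecofoot as ef
from ecofoot.biodiversity import KBA_FLAGS
from ecofoot.errors import CoverageError, ValidationError
from ecofoot.rasters import GridGeometry


def small_grid_setup(land, eco_ids, cf_by_eco, kba=None, consumers=("S0",)):
    """Hand-built allocated grid + masks + CF table on a 1×N strip.

    ``land``: per-consumer cell land for the first category.
    ``cf_by_eco``: taxon-independent CF value per ecoregion id.
    """
    land = np.asarray(land, dtype=float)
    if land.ndim == 1:
        land = land[np.newaxis]
    n = land.shape[1]
    geometry = GridGeometry(n_rows=1, n_cols=n, cell_area_m2=1.0)
    masks = ef.CellMasks(
        country_id=np.zeros((1, n), dtype=int),
        ecoregion_id=np.asarray(eco_ids, dtype=int).reshape(1, n),
        kba=(np.zeros((1, n), dtype=bool) if kba is None
             else np.asarray(kba).reshape(1, n)),
        geometry=geometry,
        regions=["P00"],
    )
    data = np.zeros((land.shape[0], len(ef.CATEGORIES), 1, n))
    data[:, 0, 0, :] = land
    grid = ef.AllocatedLandGrid(
        data=data,
        consumers=list(consumers),
        categories=list(ef.CATEGORIES),
        geometry=geometry,
    )
    ecoregions = sorted(cf_by_eco)
    cf = np.zeros((len(ef.TAXA), len(ef.CATEGORIES), len(ecoregions)))
    for k, e in enumerate(ecoregions):
        cf[:, :, k] = cf_by_eco[e]
    cfs = ef.CFTable(
        taxa=list(ef.TAXA),
        categories=list(ef.CATEGORIES),
        ecoregions=ecoregions,
        cf=cf,
        richness_per_m2=np.full((len(ef.TAXA), len(ecoregions)), 1e-9),
    )
    return grid, masks, cfs


class TestSpeciesLoss:
    def test_single_cell_product(self):
        grid, masks, cfs = small_grid_setup([10.0], [0], {0: 1e-3})
        account = ef.species_loss(grid, cfs, masks)
        assert float(
            account.sl.sel(taxon="plants").sum()
        ) == pytest.approx(0.01)

    def test_zero_cfs_mean_zero_loss(self):
        grid, masks, cfs = small_grid_setup([5.0, 7.0], [0, 0], {0: 0.0})
        assert ef.species_loss(grid, cfs, masks).total() == 0.0

    def test_two_ecoregions_weighted_sum(self):
        grid, masks, cfs = small_grid_setup(
            [4.0, 6.0], [0, 1], {0: 1e-3, 1: 1e-2}
        )
        account = ef.species_loss(grid, cfs, masks)
        expected = 4.0 * 1e-3 + 6.0 * 1e-2
        assert float(account.sl.sel(taxon="plants").sum()) == pytest.approx(
            expected
        )

    def test_brute_force_cell_loop_oracle(self, world, analysis):
        """The vectorized aggregation must match an explicit per-cell,
        per-taxon loop bit for bit."""
        grid, masks, cfs = analysis.grid, world.masks, world.cfs
        cf_cells = cfs.cell_view(masks, strict=False)
        n_taxa = len(cfs.taxa)
        n_s, n_m = grid.data.shape[0], grid.data.shape[1]
        out = np.zeros(
            (n_taxa, n_s, len(masks.regions), n_m, 2)
        )
        for g in range(n_taxa):
            for m in range(n_m):
                for s in range(n_s):
                    for r_idx, c_idx in np.ndindex(masks.geometry.shape):
                        country = masks.country_id[r_idx, c_idx]
                        if country < 0:
                            continue
                        flag = 0 if masks.kba[r_idx, c_idx] else 1
                        out[g, s, country, m, flag] += (
                            grid.data[s, m, r_idx, c_idx]
                            * cf_cells[g, m, r_idx, c_idx]
                        )
        vectorized = analysis.account.sl.transpose(
            "taxon", "consumer", "producer", "category", "kba"
        ).values
        assert np.array_equal(out, vectorized)

    def test_missing_cf_strict_errors(self):
        grid, masks, cfs = small_grid_setup([1.0, 1.0], [0, 1], {0: 1e-3})
        masks.ecoregion_id[0, 1] = 7  # land-bearing cell, unknown ecoregion
        with pytest.raises(CoverageError):
            ef.species_loss(grid, cfs, masks, strict=True)

    def test_missing_cf_permissive_zero_fills(self):
        grid, masks, cfs = small_grid_setup([1.0, 1.0], [0, 7], {0: 1e-3})
        account = ef.species_loss(grid, cfs, masks, strict=False)
        assert float(account.sl.sel(taxon="plants").sum()) == pytest.approx(
            1e-3
        )

    def test_kba_partition_identity(self, analysis):
        sl = analysis.account.sl
        total = sl.sum("kba")
        parts = sl.sel(kba="inside") + sl.sel(kba="outside")
        assert np.allclose(parts.values, total.values, rtol=0, atol=0)

    def test_linear_in_cfs(self):
        grid, masks, cfs = small_grid_setup([2.0, 3.0], [0, 0], {0: 1e-3})
        base = ef.species_loss(grid, cfs, masks).total()
        cfs.cf *= 3.0
        assert ef.species_loss(grid, cfs, masks).total() == pytest.approx(
            3.0 * base
        )

    def test_aggregation_order_invariance(self, analysis):
        sl = analysis.account.sl
        producer_first = float(sl.sum("producer").sum())
        consumer_first = float(sl.sum("consumer").sum())
        assert producer_first == pytest.approx(consumer_first, rel=1e-12)


class TestAccounts:
    def test_autarky_production_equals_consumption(self):
        world = ef.planted_scenario("no-trade").world
        from ecofoot.pipeline import analyze_world

        analysis = analyze_world(world, with_ctv=False)
        pvc = ef.production_vs_consumption(analysis.account)
        assert np.allclose(
            pvc["production_based"], pvc["consumption_based"], rtol=1e-9
        )

    def test_single_exporter_sign_of_net_trade(self):
        scenario = ef.planted_scenario("single-chain")
        from ecofoot.pipeline import analyze_world

        analysis = analyze_world(scenario.world, with_ctv=False)
        pvc = ef.production_vs_consumption(analysis.account).set_index(
            ["taxon", "region"]
        )
        row = pvc.loc[("plants", scenario.expected["producer"])]
        assert row["production_based"] > row["consumption_based"]

    def test_global_totals_agree(self, analysis):
        pvc = ef.production_vs_consumption(analysis.account)
        assert pvc["production_based"].sum() == pytest.approx(
            pvc["consumption_based"].sum(), rel=1e-9
        )

    def test_per_capita_division(self):
        table = pd.DataFrame(
            {"taxon": ["plants"], "region": ["P00"], "loss": [2e-4]}
        )
        out = ef.per_capita(table, pd.Series({"P00": 100.0}))
        assert out.loc[0, "loss"] == pytest.approx(2e-6)

    def test_per_capita_ratio(self):
        table = pd.DataFrame(
            {"taxon": ["plants"] * 2, "region": ["A", "B"], "loss": [1.0, 1.0]}
        )
        out = ef.per_capita(table, pd.Series({"A": 10.0, "B": 100.0}))
        assert out.loc[1, "loss"] / out.loc[0, "loss"] == pytest.approx(0.1)

    def test_per_capita_zero_population_rejected(self):
        table = pd.DataFrame({"region": ["A"], "loss": [1.0]})
        with pytest.raises(ValidationError):
            ef.per_capita(table, pd.Series({"A": 0.0}))


class TestTradeFlows:
    def test_single_import_chain_is_pure_trade(self):
        scenario = ef.planted_scenario("single-chain")
        from ecofoot.pipeline import analyze_world

        analysis = analyze_world(scenario.world, with_ctv=False)
        flows = analysis.flows
        assert np.allclose(flows.trade_share_pct, 100.0)
        off = flows.flows.sel(
            producer_group=scenario.expected["producer"],
            consumer_group=scenario.expected["consumer"],
        )
        assert float(off.sum()) == pytest.approx(
            analysis.account.total(), rel=1e-12
        )

    def test_autarky_is_diagonal(self):
        world = ef.planted_scenario("no-trade").world
        from ecofoot.pipeline import analyze_world

        analysis = analyze_world(world, with_ctv=False)
        assert np.allclose(analysis.flows.trade_share_pct, 0.0)
        values = analysis.flows.flows.values
        off_diag = values - np.einsum("gij,ij->gij", values, np.eye(values.shape[1]))
        assert np.max(np.abs(off_diag)) == 0.0

    def test_matrix_total_matches_account(self, analysis):
        assert float(analysis.flows.flows.sum()) == pytest.approx(
            analysis.account.total(), rel=1e-9
        )

    def test_grouped_regions(self, world, analysis):
        grouping = {
            r: ("north" if i < 3 else "south")
            for i, r in enumerate(world.phys.regions)
        }
        flows = ef.trade_flows(analysis.account, grouping)
        assert list(flows.flows.coords["producer_group"].values) == [
            "north",
            "south",
        ]
        assert float(flows.flows.sum()) == pytest.approx(
            analysis.account.total(), rel=1e-9
        )

    def test_ungrouped_region_rejected(self, analysis):
        with pytest.raises(ValidationError):
            ef.trade_flows(analysis.account, {"P00": "g"})


class TestProductAttribution:
    def test_partition_matches_total(self, analysis):
        assert analysis.attribution["species_loss"].sum() == pytest.approx(
            analysis.account.total(), rel=1e-9
        )

    def test_single_product_demand(self):
        scenario = ef.planted_scenario("single-chain")
        from ecofoot.pipeline import analyze_world

        analysis = analyze_world(scenario.world, with_ctv=False)
        attr = analysis.attribution
        nonzero = attr[attr["species_loss"] > 0]
        assert set(nonzero["product"]) == {scenario.expected["product"]}
        assert set(nonzero["provenance"]) == {"food"}

    def test_food_nonfood_partition(self, analysis):
        by_prov = analysis.attribution.groupby("provenance")[
            "species_loss"
        ].sum()
        assert set(by_prov.index) == {"food", "nonfood"}
        assert by_prov.sum() == pytest.approx(
            analysis.account.total(), rel=1e-9
        )

    def test_incomplete_grouping_rejected(self, world, analysis):
        from ecofoot.biodiversity import product_attribution

        lossfac = ef.loss_factors(analysis.shares, world.cfs, world.masks)
        with pytest.raises(ValidationError):
            product_attribution(
                analysis.economy,
                world.extension,
                world.phys.y,
                world.mon.y,
                lossfac,
                food_groups={world.phys.products[0]: "cereals"},
            )


class TestUniformCfScaling:
    def test_country_loss_ratios_follow_land_ratios(self):
        scenario = ef.planted_scenario("uniform-cf")
        from ecofoot.pipeline import analyze_world

        analysis = analyze_world(scenario.world, with_ctv=False)
        production = analysis.account.sl.sum(["consumer", "category", "kba"])
        for taxon, cf_value in scenario.expected["cf"].items():
            got = production.sel(taxon=taxon).to_series()
            expected = {
                r: cf_value * land
                for r, land in scenario.expected["land_by_region_m2"].items()
            }
            for region, value in expected.items():
                assert got[region] == pytest.approx(value, rel=1e-9)


def test_vertebrate_aggregate_is_class_sum(analysis):
    vert = analysis.account.vertebrates()
    by_class = sum(
        analysis.account.sl.sel(taxon=g)
        for g in ("mammals", "amphibians", "reptiles", "birds")
    )
    assert np.allclose(vert.values, by_class.values, rtol=0, atol=0)


def test_relative_loss_uses_taxon_totals(analysis, world):
    rel = analysis.account.relative_loss(world.cfs.taxon_totals)
    plants_total = float(analysis.account.sl.sel(taxon="plants").sum())
    assert float(rel.sel(taxon="plants").sum()) == pytest.approx(
        plants_total / float(world.cfs.taxon_totals["plants"]), rel=1e-12
    )
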