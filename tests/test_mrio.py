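"""Hybrid MRIO core: coefficients, block inversion, footprints."""

import numpy as np
import pandas as pd
import pytest

import ecofoot as ef
from ecofoot.errors import (
    NonProductiveEconomyError,
    StructuralError,
    ValidationError,
)
from ecofoot.mrio import leontief_apply


def toy_economy(A_phys, A_link, A_mon, populations=None):
    """Wrap raw coefficient blocks as a one-product-per-sector economy."""
    n_phys, n_mon = np.shape(A_link)
    phys_regions = [f"P{i:02d}" for i in range(n_phys)]
    mon_regions = [f"M{i:02d}" for i in range(n_mon)]
    return ef.assemble_hybrid(
        A_phys,
        A_link,
        A_mon,
        phys_regions=phys_regions,
        phys_products=["p"],
        mon_regions=mon_regions,
        mon_products=["q"],
        concordance={r: mon_regions[0] for r in phys_regions},
        population=pd.Series(
            populations if populations is not None else np.ones(n_phys),
            index=phys_regions,
        ),
    )


def random_blocks(rng, n_phys, n_mon, radius):
    """Random non-negative blocks rescaled to an exact spectral radius."""
    A_phys = rng.random((n_phys, n_phys)) * (rng.random((n_phys, n_phys)) < 0.6)
    A_mon = rng.random((n_mon, n_mon)) * (rng.random((n_mon, n_mon)) < 0.6)
    A_link = rng.random((n_phys, n_mon)) * (rng.random((n_phys, n_mon)) < 0.6)
    rho = max(
        np.max(np.abs(np.linalg.eigvals(A_phys))),
        np.max(np.abs(np.linalg.eigvals(A_mon))),
    )
    if rho == 0:
        A_phys = A_phys + np.eye(n_phys) * 0.1
        rho = 0.1
    scale = radius / rho
    return A_phys * scale, A_link * scale, A_mon * scale


class TestTechnicalCoefficients:
    def test_single_division(self):
        assert ef.technical_coefficients(np.array([[4.0]]), np.array([8.0])) == (
            np.array([[0.5]])
        )

    def test_zero_output_column_zeroed(self):
        A = ef.technical_coefficients(
            np.array([[1.0, 0.0], [0.0, 2.0]]), np.array([2.0, 0.0])
        )
        assert np.array_equal(A, np.array([[0.5, 0.0], [0.0, 0.0]]))

    def test_reconstructs_flows(self):
        rng = np.random.default_rng(1)
        Z = rng.random((6, 6))
        x = rng.uniform(1.0, 5.0, 6)
        A = ef.technical_coefficients(Z, x)
        assert np.max(np.abs(A * x[np.newaxis, :] - Z)) < 1e-12

    def test_dimension_mismatch_is_structural(self):
        with pytest.raises(StructuralError):
            ef.technical_coefficients(np.ones((2, 3)), np.ones(2))

    def test_negative_entries_rejected(self):
        with pytest.raises(ValidationError):
            ef.technical_coefficients(np.array([[-1.0]]), np.array([1.0]))


class TestAssembleHybrid:
    def test_all_zero_blocks_valid(self):
        economy = toy_economy(np.zeros((2, 2)), np.zeros((2, 1)), np.zeros((1, 1)))
        assert economy.spectral_radius == 0.0
        assert np.array_equal(economy.full_matrix(), np.zeros((3, 3)))

    def test_wrong_link_rows_is_structural(self):
        with pytest.raises(StructuralError):
            toy_economy(np.zeros((2, 2)), np.zeros((3, 1)), np.zeros((1, 1)))

    def test_nonproductive_economy_rejected(self):
        with pytest.raises(NonProductiveEconomyError):
            toy_economy(np.array([[1.2]]), np.zeros((1, 1)), np.zeros((1, 1)))

    def test_concordance_gap_rejected(self):
        with pytest.raises(ValidationError):
            ef.assemble_hybrid(
                np.zeros((1, 1)),
                np.zeros((1, 1)),
                np.zeros((1, 1)),
                phys_regions=["P00"],
                phys_products=["p"],
                mon_regions=["M00"],
                mon_products=["q"],
                concordance={},
                population=pd.Series([1.0], index=["P00"]),
            )


class TestBlockLeontief:
    def test_zero_coefficients_give_identity(self):
        economy = toy_economy(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((2, 2)))
        blocks = ef.block_leontief(economy)
        assert np.array_equal(blocks.full(), np.eye(4))

    def test_two_by_two_closed_form(self):
        # (I-0.2)^-1 = 1.25, (I-0.5)^-1 = 2, cross = 1.25*0.1*2 = 0.25
        economy = toy_economy(
            np.array([[0.2]]), np.array([[0.1]]), np.array([[0.5]])
        )
        blocks = ef.block_leontief(economy)
        assert np.allclose(
            blocks.full(), np.array([[1.25, 0.25], [0.0, 2.0]]), atol=1e-14
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_inverse(self, seed):
        rng = np.random.default_rng(seed)
        A_phys, A_link, A_mon = random_blocks(rng, 8, 6, 0.7)
        economy = toy_economy(A_phys, A_link, A_mon)
        dense = np.linalg.inv(np.eye(14) - economy.full_matrix())
        assert np.max(np.abs(ef.block_leontief(economy).full() - dense)) < 1e-10

    def test_blocks_nonnegative(self):
        rng = np.random.default_rng(3)
        economy = toy_economy(*random_blocks(rng, 5, 4, 0.9))
        assert np.all(ef.block_leontief(economy).full() >= 0)

    def test_solve_path_matches_inverse_path(self):
        rng = np.random.default_rng(4)
        economy = toy_economy(*random_blocks(rng, 7, 5, 0.8))
        y_phys = rng.random((7, 3))
        y_mon = rng.random((5, 3))
        via_inverse = leontief_apply(
            economy, y_phys, y_mon, solve_threshold=10_000
        )
        via_solve = leontief_apply(economy, y_phys, y_mon, solve_threshold=0)
        assert np.max(np.abs(via_inverse - via_solve)) < 1e-10

    @pytest.mark.parametrize("seed", [0, 5])
    def test_neumann_series_converges_monotonically(self, seed):
        rng = np.random.default_rng(seed)
        economy = toy_economy(*random_blocks(rng, 4, 3, 0.6))
        A = economy.full_matrix()
        L = np.linalg.inv(np.eye(7) - A)
        partial = np.eye(7)
        power = np.eye(7)
        previous = partial.copy()
        for _ in range(200):
            power = power @ A
            partial = partial + power
            assert np.all(partial >= previous - 1e-15)
            previous = partial.copy()
        assert np.max(np.abs(partial - L)) < 1e-9


class TestDisaggregation:
    def test_population_proportional_split(self):
        y = np.array([[100.0]])
        out = ef.disaggregate_rest_of_world(
            y,
            ["M00"],
            {"P00": "M00", "P01": "M00"},
            pd.Series([1.0, 3.0], index=["P00", "P01"]),
        )
        assert np.allclose(out, [[25.0, 75.0]])

    def test_single_member_passthrough(self):
        y = np.array([[42.0], [7.0]])
        out = ef.disaggregate_rest_of_world(
            y, ["M00"], {"P00": "M00"}, pd.Series([123.0], index=["P00"])
        )
        assert np.array_equal(out, y)

    def test_totals_conserved(self):
        rng = np.random.default_rng(0)
        y = rng.random((6, 2)) * 100
        concordance = {"P00": "M00", "P01": "M01", "P02": "M01", "P03": "M01"}
        pop = pd.Series(rng.uniform(1, 9, 4), index=list(concordance))
        out = ef.disaggregate_rest_of_world(y, ["M00", "M01"], concordance, pop)
        assert np.allclose(out.sum(axis=1), y.sum(axis=1), rtol=1e-12)

    def test_zero_population_rejected(self):
        with pytest.raises(ValidationError):
            ef.disaggregate_rest_of_world(
                np.ones((1, 1)),
                ["M00"],
                {"P00": "M00"},
                pd.Series([0.0], index=["P00"]),
            )


class TestConsumptionFootprint:
    def _bare_economy_extension(self, intensity=5.0):
        economy = toy_economy(np.zeros((2, 2)), np.zeros((2, 1)), np.zeros((1, 1)))
        d = np.zeros((2, 1, len(ef.CATEGORIES)))
        d[1, 0, 0] = intensity  # producer P01, one unit of output
        extension = ef.LandExtension(
            regions=economy.phys_regions,
            products=["p"],
            categories=list(ef.CATEGORIES),
            d=d,
            e=d.copy(),
        )
        return economy, extension

    def test_direct_demand_no_intermediates(self):
        economy, extension = self._bare_economy_extension(intensity=5.0)
        y_phys = np.zeros((2, 2))
        y_phys[1, 0] = 1.0  # consumer P00 buys one unit from P01
        fp = ef.consumption_footprint(
            economy, extension, y_phys, np.zeros((1, 1))
        )
        assert fp.total.sel(
            consumer="P00", producer="P01", product="p", category=ef.CATEGORIES[0]
        ) == pytest.approx(5.0)
        assert float(fp.total.sum()) == pytest.approx(5.0)

    def test_monetary_demand_without_link_leaves_no_land(self):
        economy, extension = self._bare_economy_extension()
        fp = ef.consumption_footprint(
            economy, extension, np.zeros((2, 2)), np.array([[9.9]])
        )
        assert float(fp.F.sum()) == 0.0

    def test_negative_demand_rejected(self):
        economy, extension = self._bare_economy_extension()
        with pytest.raises(ValidationError):
            ef.consumption_footprint(
                economy, extension, -np.ones((2, 2)), np.zeros((1, 1))
            )

    def test_global_conservation(self, world, analysis):
        assert (
            analysis.footprint.conservation_residual(world.extension) < 1e-9
        )

    def test_consumer_scaling_linearity(self, world):
        economy = world.economy()
        fp1 = ef.consumption_footprint(
            economy, world.extension, world.phys.y, world.mon.y
        )
        y_phys = world.phys.y.copy()
        y_phys[:, 0] *= 2.0
        # the monetary route is left unchanged: doubling applies to the
        # physical demand column of the first consumer only
        fp2 = ef.consumption_footprint(
            economy, world.extension, y_phys, world.mon.y
        )
        food1 = fp1.F.sel(provenance="food")
        food2 = fp2.F.sel(provenance="food")
        target = [str(v) for v in food1.coords["consumer"].values][0]
        assert np.allclose(
            food2.sel(consumer=target), 2.0 * food1.sel(consumer=target), rtol=1e-12
        )
        others = [
            c for c in food1.coords["consumer"].values if str(c) != target
        ]
        assert np.allclose(
            food2.sel(consumer=others), food1.sel(consumer=others), rtol=0
        )

    def test_zero_output_sectors_stay_inert(self):
        # a sector with zero output, zero intensity: no NaN, no land
        economy, extension = self._bare_economy_extension()
        fp = ef.consumption_footprint(
            economy, extension, np.zeros((2, 2)), np.zeros((1, 1))
        )
        assert np.all(np.isfinite(fp.F.values))
        assert float(fp.F.sum()) == 0.0
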