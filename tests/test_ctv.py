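"""Four-factor decomposition and contribution-to-variance analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecofoot as ef
from ecofoot.ctv import FACTORS, CountryDecomposition
from ecofoot.errors import AnalysisError, ValidationError


def brute_force_spearman(x, y):
    """Independent oracle: Pearson correlation of average ranks."""

    def average_ranks(v):
        v = np.asarray(v, dtype=float)
        ranks = np.empty(len(v))
        order = np.argsort(v, kind="stable")
        i = 0
        sorted_v = v[order]
        position = 1.0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            mean_rank = (position + position + (j - i)) / 2.0
            for k in range(i, j + 1):
                ranks[order[k]] = mean_rank
            position += j - i + 1
            i = j + 1
        return ranks

    rx, ry = average_ranks(x), average_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def make_table(factors: dict, sl=None, taxon="plants"):
    """Assemble a decomposition table from factor columns."""
    n = len(next(iter(factors.values())))
    if sl is None:
        sl = np.ones(n)
        for values in factors.values():
            sl = sl * np.asarray(values, dtype=float)
    rows = []
    for i in range(n):
        rows.append(
            {
                "region": f"C{i:03d}",
                "taxon": taxon,
                "species_loss": sl[i],
                **{f: factors[f][i] for f in FACTORS},
                "included": True,
            }
        )
    return CountryDecomposition(table=pd.DataFrame(rows))


class TestSpearman:
    def test_perfectly_increasing(self):
        assert ef.spearman([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)

    def test_perfectly_reversed(self):
        assert ef.spearman([1, 2, 3], [9, 5, 1]) == pytest.approx(-1.0)

    def test_matches_brute_force_on_swapped_pairs(self):
        x = [1, 2, 3, 4]
        y = [2, 1, 4, 3]
        assert ef.spearman(x, y) == pytest.approx(brute_force_spearman(x, y))
        assert ef.spearman(x, y) == pytest.approx(0.6)

    @settings(derandomize=True, max_examples=50)
    @given(
        data=st.lists(
            st.tuples(
                st.integers(min_value=-50, max_value=50),
                st.integers(min_value=-50, max_value=50),
            ),
            min_size=3,
            max_size=30,
        )
    )
    def test_matches_brute_force_with_ties(self, data):
        x = [p[0] for p in data]
        y = [p[1] for p in data]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            assert np.isnan(ef.spearman(x, y))
        else:
            got = ef.spearman(x, y)
            assert got == pytest.approx(brute_force_spearman(x, y), abs=1e-12)
            assert -1.0 <= got <= 1.0

    def test_zero_variance_is_undefined(self):
        assert np.isnan(ef.spearman([1.0, 1.0, 1.0], [1, 2, 3]))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            ef.spearman([1, 2], [3, 4])


class TestDecompose:
    def test_reconstruction_identity_on_generated_world(self, analysis):
        assert analysis.decomposition.reconstruction_residual() < 1e-12

    def test_factor_values_identity(self):
        # A=100, L=50, S=10, SL=0.2 -> factors (100, 0.5, 0.2, 0.02)
        table = make_table(
            {
                "kba_area": [100.0],
                "used_share": [0.5],
                "richness_per_area": [0.2],
                "relative_loss": [0.02],
            }
        )
        row = table.table.iloc[0]
        assert row["species_loss"] == pytest.approx(0.2)
        product = (
            row["kba_area"]
            * row["used_share"]
            * row["richness_per_area"]
            * row["relative_loss"]
        )
        assert product == pytest.approx(row["species_loss"], rel=1e-12)

    def test_zero_land_use_excludes_country(self, world, analysis):
        # erase one country's land from the production grid: factors
        # downstream of L become undefined and the country is flagged
        import copy

        grid = copy.deepcopy(analysis.production_grid)
        victim = world.phys.regions[0]
        grid.data[:, :, world.masks.country_mask(victim)] = 0.0
        decomposition = ef.decompose(
            analysis.account, world.masks, world.cfs, grid
        )
        assert victim in decomposition.excluded_regions()
        sub = decomposition.table[decomposition.table["region"] == victim]
        assert (~sub["included"]).all()
        assert (sub["used_share"] == 0.0).all()
        assert sub["richness_per_area"].isna().all()


class TestCtv:
    def test_single_driver_gets_everything(self):
        n = 10
        table = make_table(
            {
                "kba_area": np.arange(1.0, n + 1.0),
                "used_share": np.full(n, 0.5),
                "richness_per_area": np.full(n, 2.0),
                "relative_loss": np.full(n, 0.1),
            }
        )
        with pytest.warns(UserWarning):
            result = ef.ctv(table)
        assert np.allclose(
            result.ctv_vector("plants"), [100.0, 0.0, 0.0, 0.0]
        )

    def test_equal_strength_drivers_split_evenly(self):
        scenario = ef.planted_scenario("four-driver-ctv")
        result = ef.ctv(scenario.decomposition)
        for taxon in ef.TAXA:
            assert np.allclose(result.ctv_vector(taxon), 25.0, atol=1e-9)

    def test_ctv_sums_to_hundred(self, analysis):
        sums = analysis.ctv.table.groupby("taxon")["ctv_pct"].sum()
        assert np.allclose(sums, 100.0, atol=1e-9)
        assert (analysis.ctv.table["ctv_pct"] >= 0).all()

    def test_monotone_transform_invariance(self):
        scenario = ef.planted_scenario("four-driver-ctv")
        base = ef.ctv(scenario.decomposition).ctv_vector("plants")
        warped = CountryDecomposition(table=scenario.decomposition.table.copy())
        warped.table["kba_area"] = warped.table["kba_area"] ** 3
        warped.table["used_share"] = np.log(warped.table["used_share"])
        got = ef.ctv(warped).ctv_vector("plants")
        assert np.allclose(got, base, atol=1e-9)

    def test_permutation_invariance(self):
        scenario = ef.planted_scenario("four-driver-ctv")
        base = ef.ctv(scenario.decomposition).ctv_vector("birds")
        rng = np.random.default_rng(0)
        shuffled = CountryDecomposition(
            table=scenario.decomposition.table.sample(
                frac=1.0, random_state=rng.integers(2**31)
            ).reset_index(drop=True)
        )
        assert np.allclose(ef.ctv(shuffled).ctv_vector("birds"), base, atol=1e-9)

    def test_all_undefined_correlations_fail(self):
        n = 5
        table = make_table({f: np.full(n, 1.0) for f in FACTORS})
        with pytest.raises(AnalysisError):
            ef.ctv(table)

    def test_too_few_countries_fail(self):
        table = make_table({f: [1.0, 2.0] for f in FACTORS})
        with pytest.raises(AnalysisError):
            ef.ctv(table)


class TestOneDriverScenario:
    def test_pipeline_recovers_planted_ctv(self):
        scenario = ef.planted_scenario("one-driver-ctv")
        from ecofoot.pipeline import analyze_world

        with pytest.warns(UserWarning):
            analysis = analyze_world(scenario.world)
        for taxon in ef.TAXA:
            assert np.allclose(
                analysis.ctv.ctv_vector(taxon),
                scenario.expected["ctv"],
                atol=1e-9,
            )

    def test_planted_species_losses_recovered(self):
        scenario = ef.planted_scenario("one-driver-ctv")
        from ecofoot.pipeline import analyze_world

        analysis = analyze_world(scenario.world, with_ctv=False)
        production = analysis.account.sl.sel(kba="inside").sum(
            ["consumer", "category"]
        )
        for taxon, by_region in scenario.expected[
            "species_loss_by_region"
        ].items():
            for region, expected in by_region.items():
                got = float(production.sel(taxon=taxon, producer=region))
                assert got == pytest.approx(expected, rel=1e-9)
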