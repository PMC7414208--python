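"""Study simulation, embedded fixtures, and the subgroup table back-solver."""

import numpy as np
import pytest

from watertaste import (
    ContingencyTable2x2,
    SimulationConfig,
    aggregate,
    estimate,
    paper_dataset,
    paper_fixture,
    reconstruct_subgroup_table,
    simulate_study,
    simulate_tables,
)
from watertaste.tables_io import COVARIATES


class TestSimulateStudy:
    def test_identical_config_gives_identical_dataset(self):
        cfg = SimulationConfig(n_total=100, seed=77)
        assert simulate_study(cfg).records == simulate_study(cfg).records
        other = simulate_study(SimulationConfig(n_total=100, seed=78))
        assert other.records != simulate_study(cfg).records

    def test_bernoulli_allocation_splits_arms_binomially(self):
        cfg = SimulationConfig(n_total=278, allocation="bernoulli_half", seed=5)
        table = aggregate(simulate_study(cfg))["all"]
        assert abs(table.n1 / 278 - 0.5) < 0.1  # within ~3 binomial SDs
        rng = np.random.default_rng(5)
        a, b, c, d = simulate_tables(278, 0.76, 0.21, "bernoulli_half", 5000, rng)
        n1 = a + b
        assert n1.mean() == pytest.approx(139, abs=1.0)
        assert n1.std() == pytest.approx(np.sqrt(278 * 0.25), rel=0.1)

    def test_fixed_equal_allocation_is_exactly_balanced(self):
        cfg = SimulationConfig(n_total=278, allocation="fixed_equal", seed=5)
        table = aggregate(simulate_study(cfg))["all"]
        assert (table.n1, table.n2) == (139, 139)

    def test_default_parameters_reproduce_marginal_tap_reply_bias(self):
        # Se=0.76, Sp=0.21 imply ~77.5% of replies are "tap" overall.
        rng = np.random.default_rng(13)
        a, b, c, d = simulate_tables(278, 0.76, 0.21, "bernoulli_half", 2000, rng)
        frac = (a + c).sum() / (a + b + c + d).sum()
        assert frac == pytest.approx(0.775, abs=0.005)

    def test_null_world_estimates_near_no_ability(self):
        cfg = SimulationConfig(n_total=5000, true_se=0.5, true_sp=0.5, seed=3)
        est = estimate(aggregate(simulate_study(cfg))["all"])
        assert est.auc == pytest.approx(0.5, abs=0.03)
        assert est.odds_ratio == pytest.approx(1.0, abs=0.25)

    def test_large_n_consistency_of_se_sp(self):
        cfg = SimulationConfig(n_total=27_800, seed=9)
        est = estimate(aggregate(simulate_study(cfg))["all"])
        assert est.se == pytest.approx(0.76, abs=0.01)
        assert est.sp == pytest.approx(0.21, abs=0.01)

    def test_covariate_margins_respected(self):
        cfg = SimulationConfig(n_total=27_800, seed=21)
        ds = simulate_study(cfg)
        frac_male = sum(r.gender == "male" for r in ds.records) / len(ds)
        assert frac_male == pytest.approx(118 / 278, abs=0.01)

    def test_table_sampler_matches_participant_sampler_in_mean(self):
        # The vectorized table sampler is distributionally identical to
        # aggregating participant-level studies.
        cells = np.zeros(4)
        reps = 40
        for seed in range(reps):
            t = aggregate(
                simulate_study(SimulationConfig(n_total=278, seed=seed))
            )["all"]
            cells += np.array(t.cells())
        cells /= reps
        rng = np.random.default_rng(0)
        a, b, c, d = simulate_tables(278, 0.76, 0.21, "bernoulli_half", 20_000, rng)
        expected = np.array([a.mean(), b.mean(), c.mean(), d.mean()])
        # Mean cell counts are ~100; allow 3 SEs of the 40-rep average.
        assert np.allclose(cells, expected, atol=3 * 7.0 / np.sqrt(reps))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_total=1)
        with pytest.raises(ValueError):
            SimulationConfig(true_se=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(covariate_margins={"age": 0.5})


class TestPaperFixture:
    def test_overall_table(self, fixture):
        assert fixture["table"] == ContingencyTable2x2(106, 33, 110, 29)

    def test_gender_arm_sizes(self, fixture):
        assert fixture["arm_sizes"]["gender"]["male"] == (52, 66)
        assert fixture["arm_sizes"]["gender"]["female"] == (87, 73)

    @pytest.mark.parametrize("covariate", sorted(COVARIATES))
    def test_subgroup_arm_sizes_conserve_totals(self, fixture, covariate):
        sizes = fixture["arm_sizes"][covariate].values()
        assert tuple(map(sum, zip(*sizes))) == (139, 139)

    def test_fixture_expansion_matches_fixture_margins(self, fixture):
        ds = paper_dataset()
        assert len(ds) == 278
        assert aggregate(ds)["all"] == fixture["table"]
        for cov, labels in COVARIATES.items():
            for arm_i, arm in enumerate(("tap", "filtered")):
                count = sum(
                    1
                    for r in ds.records
                    if r.arm == arm and getattr(r, cov) == labels[0]
                )
                assert count == fixture["arm_sizes"][cov][labels[0]][arm_i]


class TestReconstructSubgroupTable:
    def test_dispenser_no_subgroup_candidates(self):
        candidates = reconstruct_subgroup_table(46, 43, 0.52, 0.42)
        assert ContingencyTable2x2(25, 21, 30, 13) in candidates

    def test_trivial_balanced_case(self):
        assert ContingencyTable2x2(1, 1, 1, 1) in reconstruct_subgroup_table(
            2, 2, 1.00, 0.50
        )

    def test_inconsistent_targets_give_empty_set(self):
        # OR < 1 with AUC > 0.5 violates the side-of-null invariant.
        assert reconstruct_subgroup_table(10, 10, 0.10, 0.90) == []

    def test_candidates_sorted_and_satisfy_side_of_null(self):
        candidates = reconstruct_subgroup_table(46, 43, 0.52, 0.42)
        keys = [(t.a, t.d) for t in candidates]
        assert keys == sorted(keys)
        for t in candidates:
            est = estimate(t, correction="none")
            assert (est.odds_ratio - 1) * (est.auc - 0.5) >= 0 or (
                est.odds_ratio == 1 and est.auc == 0.5
            )
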