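"""Non-parametric battery vs exact-enumeration and scipy oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hirukit import reference
from hirukit.expression_stats import (
    friedman,
    ks_normality,
    mann_whitney,
    run_battery,
    wilcoxon_signed_rank,
)

small_sample = st.lists(
    st.floats(-50, 50, allow_nan=False).map(lambda v: round(v, 1)),
    min_size=3,
    max_size=7,
)

# tie-free material for the exact-enumeration comparisons: the normal
# approximation converges to the enumeration oracle as ties vanish
unique_values = st.lists(
    st.floats(0.5, 50, allow_nan=False).map(lambda v: round(v, 1)),
    min_size=10,
    max_size=15,
    unique=True,
)


class TestKSNormality:
    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0])

    def test_constant_sample_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            ks_normality([3.0] * 10)

    def test_d_matches_scipy_with_fitted_normal(self):
        rng = np.random.default_rng(42)
        x = rng.normal(10, 3, size=40)
        r = ks_normality(x)
        scipy_stat = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).statistic
        assert r.statistic == pytest.approx(scipy_stat)

    def test_null_calibration(self):
        # drawn from a normal, the Lilliefors-corrected screen should be
        # calibrated: empirical size near the nominal 5%
        rng = np.random.default_rng(0)
        rejections = sum(
            ks_normality(rng.normal(0, 1, size=50)).p_value < 0.05 for _ in range(500)
        )
        assert 0.01 <= rejections / 500 <= 0.09

    def test_classical_p_is_conservative_under_fitted_null(self):
        # the uncorrected asymptotic Kolmogorov p with fitted parameters
        # almost never rejects a truly normal sample
        rng = np.random.default_rng(0)
        rejections = sum(
            ks_normality(rng.normal(0, 1, size=50), method="classical").p_value < 0.05
            for _ in range(500)
        )
        assert rejections < 0.02 * 500

    def test_power_against_skewed_lognormal(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            ks_normality(rng.lognormal(0, 1.5, size=12)).p_value < 0.05
            for _ in range(400)
        )
        assert rejections / 400 > 0.5


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0

    def test_identical_groups_give_zero_z_and_p_one(self):
        r = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.z_value == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_u_statistics_sum_to_product_of_sizes(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=6), rng.normal(size=9)
        r_xy = mann_whitney(x, y)
        r_yx = mann_whitney(y, x)
        # reported U is min(U1, U2), identical either way; U1 + U2 = n1*n2
        assert r_xy.statistic == r_yx.statistic
        assert r_xy.statistic <= 6 * 9 / 2

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=10), rng.normal(1.0, 1, size=12)
        r = mann_whitney(x, y)
        scipy_r = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert r.p_value == pytest.approx(scipy_r.pvalue)

    @given(unique_values, st.integers(4, 8))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_normal_approximation_close_to_exact_enumeration(self, pooled, n1):
        # the continuity-corrected z is the normal approximation that
        # converges to the enumeration p across the whole range; the
        # uncorrected default deviates by up to ~0.09 mid-range at these n
        n1 = min(n1, len(pooled) - 4)
        x, y = pooled[:n1], pooled[n1:]
        approx = mann_whitney(x, y, continuity_correction=True)
        exact = mann_whitney(x, y, exact=True)
        assert abs(approx.p_value - exact.p_value) < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestFriedman:
    def test_tabulated_activity_matrix(self):
        # blocks = assay repeats, treatments = the three proteins of one species
        for genes in (("Hnip1", "Hnip2", "Hnip3"), ("Htia1", "Htia2", "Htia3")):
            table = np.array([reference.ACTIVITY_REPLICATES[g] for g in genes]).T
            r = friedman(table)
            assert r.statistic == pytest.approx(6.000)
            assert r.df == 2
            assert r.p_value < 0.05

    def test_identical_treatments_give_zero(self):
        r = friedman([[1.0, 1.0, 1.0]] * 4)
        assert r.statistic == pytest.approx(0.0)

    @pytest.mark.parametrize("n,k", [(3, 3), (5, 4), (12, 3)])
    def test_perfect_concordance_closed_form(self, n, k):
        table = [[j + 0.1 * i for j in range(k)] for i in range(n)]
        r = friedman(table)
        assert r.statistic == pytest.approx(n * (k - 1))

    def test_rank_sums_identity_and_scipy_agreement(self):
        rng = np.random.default_rng(5)
        table = rng.normal(size=(8, 4))
        r = friedman(table)
        scipy_r = stats.friedmanchisquare(*table.T)
        assert r.statistic == pytest.approx(scipy_r.statistic)
        assert r.p_value == pytest.approx(scipy_r.pvalue)

    def test_ragged_blocks_rejected(self):
        with pytest.raises(ValueError):
            friedman([[1, 2], [1, 2, 3]])


class TestWilcoxon:
    def test_all_positive_differences(self):
        x = np.array([10, 20, 30, 40, 50, 60], dtype=float)
        y = x - np.array([1, 2, 3, 4, 5, 6], dtype=float)
        r = wilcoxon_signed_rank(x, y)
        assert r.statistic == 0.0  # W- = 0
        assert r.z_value == pytest.approx(10.5 / np.sqrt(6 * 7 * 13 / 24))

    def test_swapping_inputs_negates_z(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=10), rng.normal(0.5, 1, size=10)
        assert wilcoxon_signed_rank(x, y).z_value == pytest.approx(
            -wilcoxon_signed_rank(y, x).z_value
        )

    def test_zero_differences_dropped(self):
        r = wilcoxon_signed_rank([1.0, 2.0, 3.0, 9.0], [1.0, 2.0, 5.0, 3.0])
        assert r.n_effective == 2

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_three_pairs_cannot_reach_significance(self):
        # with n=3 untied differences the most extreme |Z| under the
        # zero-drop normal approximation is 6/sqrt(3*4*7/24) ~ 1.604; fully
        # tied differences reach sqrt(3) ~ 1.732 after the tie correction.
        # Either way |Z| < 1.96, so three pairs can never reach p < 0.05.
        r = wilcoxon_signed_rank([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert abs(r.z_value) == pytest.approx(1.604, abs=0.001)
        assert r.p_value > 0.05
        r_tied = wilcoxon_signed_rank([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
        assert abs(r_tied.z_value) == pytest.approx(np.sqrt(3.0), abs=0.001)
        assert r_tied.p_value > 0.05

    @given(unique_values, st.integers(0, 2**12 - 1))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_normal_approximation_close_to_sign_flip_enumeration(self, mags, signbits):
        # unique magnitudes (no rank ties), random signs, n in [5, 12]
        mags = mags[:12]
        x = np.array(
            [m if signbits >> i & 1 else -m for i, m in enumerate(mags)]
        )
        y = np.zeros_like(x)
        approx = wilcoxon_signed_rank(x, y)
        exact = wilcoxon_signed_rank(x, y, exact=True)
        assert abs(approx.p_value - exact.p_value) < 0.05


class TestBattery:
    @staticmethod
    def _null_matrix(rng):
        mat = pd.DataFrame(
            rng.lognormal(5, 1, size=(6, 12)),
            index=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        species = {g: ("A" if g.startswith("a") else "B") for g in mat.index}
        return mat, species

    def test_structure_and_order_on_study_shaped_matrix(self, study_bundle):
        report = run_battery(study_bundle.expression, study_bundle.species_of())
        assert len(report.normality) == 6
        assert report.species_total is not None
        assert len(report.cross_species_pairs) == 9
        assert set(report.within_species) == set(reference.SPECIES)
        frame = report.to_frame()
        assert set(frame["test"]).issubset(
            {"ks_normality", "mann_whitney", "friedman", "wilcoxon_signed_rank"}
        )
        assert ((frame["p"] >= 0) & (frame["p"] <= 1)).all()

    def test_type_I_control_under_global_null(self):
        triggered = 0
        for ss in np.random.SeedSequence(12345).spawn(200):
            mat, species = self._null_matrix(np.random.default_rng(ss))
            report = run_battery(mat, species)
            triggered += bool(report.pairwise_within)
        assert triggered <= 0.10 * 200

    def test_power_against_planted_twenty_fold_shift(self):
        detected = 0
        n_seeds = 200
        for ss in np.random.SeedSequence(999).spawn(n_seeds):
            rng = np.random.default_rng(ss)
            mat, species = self._null_matrix(rng)
            mat.loc["a1"] = rng.lognormal(5 + np.log(20), 1, size=12)
            report = run_battery(mat, species)
            hits = report.pairwise_within.get("A", [])
            detected += any("a1" in r.label and r.p_value < 0.05 for r in hits)
        assert detected / n_seeds > 0.8

    def test_within_species_heterogeneity_flagged_on_study_conditions(self):
        # the study-scale expression contrasts (40-fold within one species)
        # should be detected by the Friedman stage in most synthetic studies
        from hirukit.synthetic import default_config, generate_study

        flagged = 0
        n_seeds = 25
        for seed in range(n_seeds):
            bundle = generate_study(default_config(master_seed=seed))
            report = run_battery(bundle.expression, bundle.species_of())
            flagged += all(r.p_value < 0.05 for r in report.within_species.values())
        assert flagged / n_seeds > 0.8

    def test_tabulated_activity_matrix_through_battery_friedman(self):
        genes = ("Hnip1", "Hnip2", "Hnip3")
        table = np.array([reference.ACTIVITY_REPLICATES[g] for g in genes]).T
        r = friedman(table)
        assert (round(r.statistic, 3), r.df) == (6.000, 2)

    def test_missing_species_tag_rejected(self, study_bundle):
        with pytest.raises(ValueError, match="species tag"):
            run_battery(study_bundle.expression, {"Hnip1": "H_nipponia"})
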