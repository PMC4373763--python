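import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st
from scipy import stats

from twodedd import (
    BootstrapSettings,
    PowerSettings,
    SimulationConfig,
    adjust_fdr,
    compute_variability_profile,
    fold_change,
    generate_spot_table,
    normalize_total_volume,
    sample_size_profile,
    select_differential,
    spot_power,
    validate_against_reference,
    welch_test,
)


class TestWelch:
    def test_identical_groups(self):
        res = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == 1.0

    def test_shifted_groups_scipy_oracle(self):
        a = np.array([11.0, 12.0, 13.0])
        b = np.array([1.0, 2.0, 3.0])
        res = welch_test(a, b)
        oracle = stats.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(oracle.statistic)
        assert res.p == pytest.approx(oracle.pvalue)
        assert res.p < 0.01
        assert res.t > 0  # first argument larger -> positive t
        assert welch_test(b, a).t == pytest.approx(-res.t)

    def test_df_welch_satterthwaite_hand_formula(self):
        a = np.array([1.0, 4.0, 2.0, 8.0])
        b = np.array([3.0, 3.1, 2.9])
        res = welch_test(a, b)
        sa = a.var(ddof=1) / 4
        sb = b.var(ddof=1) / 3
        df = (sa + sb) ** 2 / (sa**2 / 3 + sb**2 / 2)
        assert res.df == pytest.approx(df)

    def test_one_tailed_is_half_two_tailed(self):
        a = [5.0, 6.0, 7.0]
        b = [1.0, 2.0, 3.0]
        assert welch_test(a, b, tails="one").p == pytest.approx(
            welch_test(a, b, tails="two").p / 2
        )

    def test_zero_variance_equal_means_p_one(self):
        res = welch_test([2.0, 2.0], [2.0, 2.0])
        assert res.p == 1.0

    def test_zero_variance_different_means(self):
        res = welch_test([3.0, 3.0], [1.0, 1.0])
        assert res.p == 0.0
        assert res.t == np.inf

    def test_too_small_group(self):
        with pytest.raises(ValueError, match="at least 2"):
            welch_test([1.0], [1.0, 2.0])

    def test_bad_tails(self):
        with pytest.raises(ValueError, match="tails"):
            welch_test([1.0, 2.0], [1.0, 2.0], tails="both")

    def test_null_pvalues_uniform(self):
        # super-uniformity of Welch p under the Gaussian null (KS check)
        rng = np.random.default_rng(77)
        a = rng.normal(0, 1, size=(4000, 7))
        b = rng.normal(0, 1, size=(4000, 7))
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        assert stats.kstest(p, "uniform").pvalue > 0.01


def brute_force_bh(p):
    """Direct step-up definition: min over j >= rank of p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj = np.empty(m)
    for i in range(m):
        adj[i] = min(min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


class TestFDR:
    def test_single_p_unchanged(self):
        assert adjust_fdr([0.03])[0] == pytest.approx(0.03)

    def test_all_equal(self):
        assert np.allclose(adjust_fdr([0.2] * 5), 0.2)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(15)
        p = rng.uniform(size=100)
        assert np.allclose(adjust_fdr(p), brute_force_bh(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @hyp_settings(max_examples=50, deadline=None)
    def test_properties(self, p):
        adj = adjust_fdr(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.2])


class TestFoldChange:
    @pytest.mark.parametrize(
        "ctrl,kd,expected", [(100.0, 50.0, 0.5), (10.0, 26.0, 2.6), (7.0, 7.0, 1.0)]
    )
    def test_values(self, ctrl, kd, expected):
        assert fold_change(ctrl, kd) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 1.0)
        with pytest.raises(ValueError):
            fold_change(1.0, -2.0)


def _run_selection(cfg, n_boot=300, alpha=0.05, boot_seed=1):
    table, truth = generate_spot_table(cfg)
    table, _ = normalize_total_volume(table)
    prof = compute_variability_profile(table, BootstrapSettings(n_boot=n_boot, seed=boot_seed))
    return table, truth, prof, select_differential(table, prof, alpha=alpha)


class TestSelectDifferential:
    def test_flags_consistent(self):
        cfg = SimulationConfig(n_spots=150, spiked_spots=((0, 2.5), (1, 2.5, "down")), seed=31)
        _, _, _, de = _run_selection(cfg)
        t = de.table
        assert (t["selected"] == (t["passes_fdr"] & t["passes_threshold"])).all()
        assert ((t["direction"] == "up") == (t["fold"] > 1)).all()
        assert (t["p_fdr"] >= t["p_raw"] - 1e-15).all()

    def test_selected_subset_of_fdr_only(self):
        cfg = SimulationConfig(n_spots=300, seed=32)
        _, _, _, de = _run_selection(cfg)
        assert set(de.selected_ids) <= set(de.table.index[de.table["passes_fdr"]])

    def test_fold_exactly_one_never_selected(self, small_table, boot_settings):
        table, _ = small_table
        table = table.copy()
        # knockdown volumes = permutation of control volumes -> fold exactly 1
        ctrl = table.gels_in_group("control")
        kd = table.gels_in_group("knockdown")
        perm = list(ctrl[1:]) + [ctrl[0]]
        table.volumes[kd] = table.volumes[perm].to_numpy()
        prof = compute_variability_profile(table, boot_settings)
        de = select_differential(table, prof)
        assert np.allclose(de.table["fold"], 1.0)
        assert not de.table["selected"].any()
        assert not de.table["passes_threshold"].any()

    def test_strong_spike_recovered(self):
        cfg = SimulationConfig(
            n_spots=200, cv_intercept=0.2, cv_slope_logvolume=0.0,
            cv_coeff_x=0.0, cv_coeff_y=0.0, spiked_spots=((5, 4.0),), seed=33,
        )
        _, truth, _, de = _run_selection(cfg)
        assert de.table.loc[truth.spiked_ids, "selected"].all()
        assert (de.table.loc[truth.spiked_ids, "direction"] == "up").all()

    def test_zero_volume_spot_excluded_and_reported(self, small_table, boot_settings):
        table, _ = small_table
        prof = compute_variability_profile(table, boot_settings)
        table = table.copy()
        table.volumes.iloc[3, 0] = 0.0
        de = select_differential(table, prof)
        assert table.spot_ids[3] in de.excluded
        assert table.spot_ids[3] not in de.table.index

    def test_missing_threshold_errors_with_ids(self, small_table, boot_settings):
        table, _ = small_table
        prof = compute_variability_profile(table, boot_settings)
        prof.table = prof.table.iloc[5:]
        with pytest.raises(ValueError, match="threshold"):
            select_differential(table, prof)

    def test_scale_raw_runs(self, small_table, boot_settings):
        table, _ = small_table
        prof = compute_variability_profile(table, boot_settings)
        de_log = select_differential(table, prof, scale="log")
        de_raw = select_differential(table, prof, scale="raw")
        # fold column identical (raw means either way); p-values differ
        assert np.allclose(de_log.table["fold"], de_raw.table["fold"])
        assert not np.allclose(de_log.table["p_raw"], de_raw.table["p_raw"])


class TestValidation:
    def _selected_setup(self, seed=41):
        cfg = SimulationConfig(
            n_spots=120, cv_intercept=0.25, cv_slope_logvolume=0.0,
            cv_coeff_x=0.0, cv_coeff_y=0.0,
            groups=("control", "knockdown", "wildtype"),
            spiked_spots=((0, 3.0), (1, 3.0, "down")), seed=seed,
        )
        table, truth = generate_spot_table(cfg)
        table, _ = normalize_total_volume(table)
        prof = compute_variability_profile(table, BootstrapSettings(n_boot=300, seed=2))
        de = select_differential(table, prof)
        return table, truth, de

    def test_reference_like_control_validates(self):
        table, truth, de = self._selected_setup()
        assert de.table.loc[truth.spiked_ids, "selected"].all()
        out = validate_against_reference(de, table)
        assert out.table.loc[truth.spiked_ids, "validated"].all()
        # oracle recomputation for one spiked spot
        spot = truth.spiked_ids[0]
        k = np.log(table.group_volumes("knockdown").loc[spot])
        r = np.log(table.group_volumes("wildtype").loc[spot])
        res = stats.ttest_ind(k, r, equal_var=False)
        assert out.table.at[spot, "p_reference"] == pytest.approx(res.pvalue / 2)

    def test_reversed_reference_not_validated(self):
        table, truth, de = self._selected_setup()
        table = table.copy()
        spot = truth.spiked_ids[0]  # up-regulated spot
        # move the reference mean to the knockdown side: direction vs
        # reference reverses, so validation must fail
        wt = table.gels_in_group("wildtype")
        table.volumes.loc[spot, wt] = table.volumes.loc[spot, wt] * 100.0
        out = validate_against_reference(de, table)
        assert not out.table.at[spot, "validated"]

    def test_nonselected_never_validated(self):
        table, _, de = self._selected_setup()
        out = validate_against_reference(de, table)
        assert not out.table.loc[~out.table["selected"], "validated"].any()

    def test_empty_selection_empty_validation(self, small_table, boot_settings):
        table, _ = small_table
        prof = compute_variability_profile(table, boot_settings)
        de = select_differential(table, prof, alpha=1e-12)
        out = validate_against_reference(de, table)
        assert len(out.validated_ids) == 0

    def test_missing_reference_warns_not_errors(self):
        table, truth, de = self._selected_setup()
        table = table.copy()
        spot = truth.spiked_ids[0]
        wt = table.gels_in_group("wildtype")
        table.volumes.loc[spot, wt] = 0.0
        out = validate_against_reference(de, table)
        assert not out.table.at[spot, "validated"]


class TestSpotPower:
    def test_null_effect_limit_is_alpha(self):
        assert spot_power(0.3, 7, 1.0 + 1e-12, alpha=0.05) == pytest.approx(0.05, abs=1e-6)

    def test_monotone_in_n_fold_sd(self):
        base = spot_power(0.35, 7, 2.0)
        assert spot_power(0.35, 8, 2.0) > base
        assert spot_power(0.35, 7, 2.5) > base
        assert spot_power(0.5, 7, 2.0) < base

    @pytest.mark.parametrize("test_kind", ["student", "welch"])
    def test_down_fold_symmetric(self, test_kind):
        assert spot_power(0.3, 6, 2.0, test=test_kind) == pytest.approx(
            spot_power(0.3, 6, 0.5, test=test_kind)
        )

    def test_student_matches_student_mc(self):
        # Monte-Carlo oracle with pooled-variance t-tests (scaled down;
        # the 100k Welch version runs in the acceptance suite)
        log_sd, n, fold, alpha = 0.35, 7, 2.0, 0.05
        rng = np.random.default_rng(50)
        nsim = 40000
        a = rng.normal(0, log_sd, (nsim, n))
        b = rng.normal(np.log(fold), log_sd, (nsim, n))
        p = stats.ttest_ind(b, a, axis=1, equal_var=True).pvalue
        mc = (p <= alpha).mean()
        assert spot_power(log_sd, n, fold, alpha) == pytest.approx(mc, abs=0.01)

    def test_welch_variant_below_student_at_small_n(self):
        assert spot_power(0.35, 4, 1.5, test="welch") < spot_power(0.35, 4, 1.5)

    def test_bad_args(self):
        with pytest.raises(ValueError):
            spot_power(0.3, 1, 2.0)
        with pytest.raises(ValueError):
            spot_power(0.0, 7, 2.0)
        with pytest.raises(ValueError):
            spot_power(0.3, 7, -1.0)


class TestSampleSizeProfile:
    def test_identical_sds_step_function(self):
        settings = PowerSettings(n_grid=tuple(range(2, 13)))
        prof = sample_size_profile([0.35] * 50, settings)
        for fold in settings.folds:
            frac = prof.table[prof.table["fold"] == fold]["fraction"].to_numpy()
            assert set(frac) <= {0.0, 1.0}
            assert (np.diff(frac) >= 0).all()

    def test_monotone_in_n_and_fold(self):
        rng = np.random.default_rng(60)
        sds = rng.lognormal(np.log(0.3), 0.4, 200)
        prof = sample_size_profile(sds, PowerSettings())
        for fold in (2.0, 1.5):
            frac = prof.table[prof.table["fold"] == fold].sort_values("n")["fraction"]
            assert (np.diff(frac) >= 0).all()
        pivot = prof.table.pivot(index="n", columns="fold", values="fraction")
        assert (pivot[2.0] >= pivot[1.5]).all()

    def test_recommended_n(self):
        prof = sample_size_profile([0.35] * 10, PowerSettings(), coverage_goal=0.9)
        n_rec = prof.recommended_n[2.0]
        assert prof.fraction(n_rec, 2.0) == 1.0
        assert spot_power(0.35, n_rec, 2.0) >= 0.8
        assert spot_power(0.35, n_rec - 1, 2.0) < 0.8

    def test_empty_sds_rejected(self):
        with pytest.raises(ValueError):
            sample_size_profile([], PowerSettings())

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            PowerSettings(alpha=0.0)
        with pytest.raises(ValueError):
            PowerSettings(folds=(1.0,))
        with pytest.raises(ValueError):
            PowerSettings(n_grid=())
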