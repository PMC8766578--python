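"""ATT estimation, matched-pair bootstrap, t-test cross-check, experiments."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dietscape.inference import (
    OUTCOMES,
    ExperimentSpec,
    att_relative,
    bootstrap_pairs,
    correlate_reference,
    null_experiment,
    paired_ttest,
    run_experiment,
)
from dietscape.synthetic import SimConfig, gen_null_covariate, gen_zip_table


class TestATTRelative:
    def test_definition(self):
        assert att_relative([1.03, 1.03], [1.0, 1.0]) == pytest.approx(3.0)

    def test_null_effect(self):
        assert att_relative([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_sign_convention(self):
        assert att_relative([0.9], [1.0]) == pytest.approx(-10.0)

    def test_zero_control_mean(self):
        with pytest.raises(ZeroDivisionError):
            att_relative([1.0], [0.0])


class TestBootstrap:
    def test_deterministic(self):
        rng = np.random.default_rng(0)
        t, c = rng.random(50) + 1, rng.random(50) + 1
        assert bootstrap_pairs(t, c, seed=3) == bootstrap_pairs(t, c, seed=3)

    def test_degenerate_pairs(self):
        # identical positive pair differences: point-mass CI, floored p
        t = np.full(10, 1.1)
        c = np.full(10, 1.0)
        lo, hi, p = bootstrap_pairs(t, c, reps=400, seed=0)
        est = att_relative(t, c)
        assert lo == pytest.approx(est) and hi == pytest.approx(est)
        assert p == pytest.approx(1 / 400)

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            bootstrap_pairs([1.0], [1.0])

    def test_distinct_controls_reduce_to_plain_pair_bootstrap(self):
        rng = np.random.default_rng(1)
        t, c = rng.random(40) + 1, rng.random(40) + 1
        plain = bootstrap_pairs(t, c, seed=5)
        clustered = bootstrap_pairs(t, c, seed=5, control_ids=[f"u{i}" for i in range(40)])
        assert plain == clustered

    def test_ci_contains_point_estimate_typically(self):
        rng = np.random.default_rng(2)
        t = rng.normal(1.05, 0.1, 120)
        c = rng.normal(1.0, 0.1, 120)
        lo, hi, p = bootstrap_pairs(t, c, seed=0)
        est = att_relative(t, c)
        assert lo <= est <= hi


class TestPairedTTest:
    def test_hand_computed_example(self):
        # differences {+1,+1,+1,-1}: mean 0.5, sd 1 -> t = 0.5/(1/2) = 1.0, df 3
        t_out = np.array([2.0, 2.0, 2.0, 0.0])
        c_out = np.array([1.0, 1.0, 1.0, 1.0])
        t_stat, p = paired_ttest(t_out, c_out)
        assert t_stat == pytest.approx(1.0)
        assert p == pytest.approx(2 * stats.t.sf(1.0, df=3))

    def test_zero_variance_flagged(self):
        t_stat, p = paired_ttest([2.0, 2.0], [1.0, 1.0])
        assert np.isnan(p)

    def test_sign_agrees_with_relative_difference(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            t = rng.normal(1.0, 0.2, 30)
            c = rng.normal(1.0, 0.2, 30)
            t_stat, _ = paired_ttest(t, c)
            assert np.sign(t_stat) == np.sign(att_relative(t, c))


class TestCorrelateReference:
    def test_exact_linear(self):
        x = pd.Series([0.0, 1, 2, 3])
        r, p, n = correlate_reference(x, 2 * x + 1)
        assert r == pytest.approx(1.0) and n == 4
        r, _, _ = correlate_reference(x, -x)
        assert r == pytest.approx(-1.0)

    def test_three_point_zero_correlation(self):
        r, p, n = correlate_reference([0, 1, 2], [0, 1, 0])
        assert r == pytest.approx(0.0)

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            correlate_reference([1, 2], [1, 2])
        with pytest.raises(ValueError, match="variance"):
            correlate_reference([1, 1, 1], [1, 2, 3])

    def test_drops_missing_pairs(self):
        a = pd.Series([1.0, 2.0, np.nan, 4.0, 5.0])
        b = pd.Series([1.1, 2.2, 3.0, np.nan, 5.1])
        r, p, n = correlate_reference(a, b)
        assert n == 3


def _sim_tables(seed, n_zips=500, **kw):
    cfg = SimConfig(n_zips=n_zips, seed=seed, **kw)
    cov, out, truth = gen_zip_table(cfg)
    return cov, out, truth


def test_experiment_reports_subgroup_specific_medians():
    cov, out, _ = _sim_tables(0, majority_fractions={"white": 0.4, "black": 0.4, "hispanic": 0.1})
    res_all = run_experiment(ExperimentSpec(factor="income", seed=0), cov, out)
    res_sub = run_experiment(
        ExperimentSpec(factor="income", subgroup="black_majority", seed=0), cov, out
    )
    assert res_sub.n_treated < res_all.n_treated
    assert res_sub.cut != res_all.cut  # median computed inside the subgroup


def test_subgroup_effect_recovery():
    """An extra treatment effect confined to Black-majority zips is found there."""
    cov, out, truth = _sim_tables(
        2,
        n_zips=600,
        majority_fractions={"white": 0.45, "black": 0.40, "hispanic": 0.1},
        effects={"grocery_access": {"mean_fv": 3.0}},
        subgroup_effects={("black", "grocery_access"): {"mean_fv": 7.0}},
    )
    res = run_experiment(
        ExperimentSpec(factor="grocery_access", subgroup="black_majority", seed=2), cov, out
    )
    est = res.by_outcome("mean_fv").relative_diff_pct
    expected = truth.effect("grocery_access", "mean_fv", "black_majority")
    assert expected == 10.0
    assert est == pytest.approx(expected, abs=2.5)


def test_subgroup_too_small_errors():
    cov, out, _ = _sim_tables(1, n_zips=60, majority_fractions={"white": 0.95})
    with pytest.raises(ValueError, match="too small"):
        run_experiment(
            ExperimentSpec(factor="income", subgroup="hispanic_majority", seed=1), cov, out
        )


def test_quartile_split_amplifies_dose_response():
    """Top-vs-bottom-quartile contrasts exceed median splits under a dose response."""
    amp = []
    for seed in range(3):
        cov, out, _ = _sim_tables(
            seed, dose_response=True, effects={"grocery_access": {"mean_fv": 10.0}}
        )
        med = run_experiment(ExperimentSpec(factor="grocery_access", seed=seed), cov, out)
        qrt = run_experiment(
            ExperimentSpec(factor="grocery_access", split="quartile", seed=seed), cov, out
        )
        amp.append(
            abs(qrt.by_outcome("mean_fv").relative_diff_pct)
            - abs(med.by_outcome("mean_fv").relative_diff_pct)
        )
    assert np.mean(amp) > 0


def test_null_experiment_reports_correlations():
    cov, out, _ = _sim_tables(3)
    nv = gen_null_covariate(cov, seed=3)
    res, corrs = null_experiment(nv, ExperimentSpec(factor="ignored", seed=3), cov, out)
    assert set(corrs) == {"income", "college_frac", "grocery_access", "fastfood_access"}
    assert all(abs(r) < 0.3 for r in corrs.values())
    assert len(res.results) == len(OUTCOMES)


def test_null_of_a_real_factor_shows_effect():
    """Using a genuine factor as the 'null' treatment must NOT read as null."""
    cov, out, _ = _sim_tables(4)  # default effects active
    fake_null = cov.set_index("zip")["grocery_access"].rename("fake")
    res, corrs = null_experiment(fake_null, ExperimentSpec(factor="ignored", seed=4), cov, out)
    assert corrs["grocery_access"] == pytest.approx(1.0)
    r = res.by_outcome("mean_fastfood")
    assert not (r.ci_low_pct <= 0 <= r.ci_high_pct)  # strong injected effect


def test_ci_width_shrinks_like_root_n():
    """Bootstrap CI width scales roughly as 1/sqrt(n_pairs) (100 vs 400 pairs)."""
    widths = {200: [], 800: []}
    for n_zips in widths:
        for seed in range(6):
            cov, out, _ = _sim_tables(seed + 10, n_zips=n_zips, effects={})
            res = run_experiment(ExperimentSpec(factor="grocery_access", seed=seed), cov, out)
            r = res.by_outcome("mean_fv")
            widths[n_zips].append(r.ci_high_pct - r.ci_low_pct)
    ratio = np.mean(widths[200]) / np.mean(widths[800])
    assert ratio == pytest.approx(2.0, rel=0.25)


def test_bootstrap_and_ttest_agree_on_rejection():
    """Bootstrap and paired-t rejection decisions at alpha=0.05 mostly agree."""
    agree = total = 0
    for seed in range(5):
        cov, out, _ = _sim_tables(seed + 20)  # default (large) effects
        res = run_experiment(ExperimentSpec(factor="college_frac", seed=seed), cov, out)
        for r in res.results:
            total += 1
            agree += (r.p_value < 0.05) == (r.t_test_p < 0.05)
    assert agree / total >= 0.9
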