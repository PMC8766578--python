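"""Median splits, SMD, genetic matching, adaptive caliper."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dietscape.matching import (
    BalanceUnattainableError,
    MatchConfig,
    _MatchProblem,
    adaptive_caliper_match,
    balance_report,
    compute_smd,
    genetic_match,
    split_treatment,
)


def series(values, prefix="z"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


class TestSplit:
    def test_median_high(self):
        s = series([50_000, 60_000, 80_000, 90_000])
        sp = split_treatment(s, "high_is_treated")
        assert set(sp.treated) == {"z2", "z3"}
        assert sp.cut == pytest.approx(70_000)

    def test_boundary_value_is_treated(self):
        # a zip exactly at the cut lands on the treated side
        s = series([1.0, 2.0, 3.0])
        sp = split_treatment(s, "high_is_treated")
        assert "z1" in sp.treated and sp.cut == 2.0
        sp_low = split_treatment(s, "low_is_treated")
        assert "z1" in sp_low.treated

    def test_low_is_treated(self):
        s = series([0.02, 0.08])
        sp = split_treatment(s, "low_is_treated")
        assert sp.treated == ("z0",)

    def test_quartile_discards_middle(self):
        s = series(np.arange(8, dtype=float))
        sp = split_treatment(s, "high_is_treated", split="quartile")
        assert set(sp.treated) == {"z6", "z7"}
        assert set(sp.control) == {"z0", "z1"}
        assert len(sp.treated) + len(sp.control) < len(s)

    def test_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            split_treatment(series([5.0, 5.0, 5.0]))


class TestSMD:
    def test_identical_groups(self):
        assert compute_smd([1, 2, 3], [1, 2, 3]) == 0.0

    def test_unit_case(self):
        assert compute_smd([0.5, 1.5], [-0.5, 0.5]) == pytest.approx(
            1.0 / np.std([-0.5, 0.5], ddof=1)
        )
        # mean_T 1, mean_C 0, sd_C 1
        assert compute_smd([2, 0], [1, -1]) == pytest.approx(1.0 / np.sqrt(2))

    def test_equal_means_unequal_spread(self):
        assert compute_smd([2, 2], [1, 3]) == pytest.approx(0.0)

    def test_zero_sd_sentinels(self):
        assert compute_smd([5, 5], [5, 5]) == 0.0
        assert compute_smd([6, 6], [5, 5]) == np.inf
        assert compute_smd([4, 4], [5, 5]) == -np.inf

    def test_numerator_antisymmetry(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=20)
        t = rng.normal(size=15)
        sd = c.std(ddof=1)
        assert compute_smd(t, c) == pytest.approx((t.mean() - c.mean()) / sd)
        assert compute_smd(t, c) == pytest.approx(
            -((c.mean() - t.mean()) / sd)
        )

    def test_empty_group(self):
        with pytest.raises(ValueError):
            compute_smd([], [1.0])


def random_deck(seed, n_t=5, n_c=7, k=3):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n_t + n_c, k)),
        columns=[f"c{j}" for j in range(k)],
        index=[f"z{i}" for i in range(n_t + n_c)],
    )
    return X, list(X.index[:n_t]), list(X.index[n_t:])


class TestGeneticMatch:
    def test_single_covariate_equals_nearest_neighbour(self):
        X, tr, ct = random_deck(0, k=1)
        mc = MatchConfig(covariates=("c0",), seed=0)
        mp = genetic_match(X, tr, ct, mc)
        for t_zip, c_zip in zip(mp.treated, mp.controls):
            dists = (X.loc[ct, "c0"] - X.loc[t_zip, "c0"]).abs()
            assert dists[c_zip] == pytest.approx(dists.min())

    def test_determinism(self):
        X, tr, ct = random_deck(4)
        mc = MatchConfig(covariates=("c0", "c1", "c2"), seed=9)
        assert genetic_match(X, tr, ct, mc) == genetic_match(X, tr, ct, mc)

    def test_fitness_not_worse_than_identity_weights(self):
        for seed in range(4):
            X, tr, ct = random_deck(seed)
            mc = MatchConfig(covariates=("c0", "c1", "c2"), seed=seed)
            mp = genetic_match(X, tr, ct, mc)
            prob = _MatchProblem(X, tr, ct)
            ga = prob.fitness(*prob.match(np.array(mp.weights), None)[:2])
            ident = prob.fitness(*prob.match(np.ones(3), None)[:2])
            assert ga <= ident + 1e-12

    def test_no_controls_errors(self):
        X, tr, _ = random_deck(0)
        mc = MatchConfig(covariates=("c0",), seed=0)
        with pytest.raises(ValueError):
            genetic_match(X, tr, [], mc)

    def test_removing_unmatched_control_is_noop(self):
        # with a single covariate the weight search is irrelevant, so the
        # with-replacement property is exact: dropping a control nobody
        # matched to leaves every pair unchanged
        X, tr, ct = random_deck(7, n_t=4, n_c=8, k=1)
        mc = MatchConfig(covariates=("c0",), seed=3)
        mp = genetic_match(X, tr, ct, mc)
        unused = sorted(set(ct) - set(mp.controls))
        assert unused, "fixture should leave at least one control unmatched"
        ct2 = [c for c in ct if c != unused[0]]
        mp2 = genetic_match(X.drop(index=unused[0]), tr, ct2, mc)
        assert mp.treated == mp2.treated and mp.controls == mp2.controls


def test_ga_beats_grid_search_on_small_decks():
    """GA fitness is never worse than a dense weight grid (resolution 0.1).

    Nearest-neighbour assignment is invariant to rescaling the weight
    vector, so a grid over [0.1, 1]^3 covers every direction a grid over
    [0.1, weight_max]^3 can express at that resolution.
    """
    grid = [np.array(w) for w in itertools.product(np.arange(0.1, 1.01, 0.1), repeat=3)]
    for seed in range(6):
        rng = np.random.default_rng(seed)
        X, tr, ct = random_deck(seed + 100, n_t=int(rng.integers(3, 7)), n_c=int(rng.integers(4, 9)))
        mc = MatchConfig(covariates=("c0", "c1", "c2"), seed=seed)
        mp = genetic_match(X, tr, ct, mc)
        prob = _MatchProblem(X, tr, ct)
        ga = prob.fitness(*prob.match(np.array(mp.weights), None)[:2])
        best = min(prob.fitness(*prob.match(w, None)[:2]) for w in grid)
        assert ga <= best + 1e-9


class TestAdaptiveCaliper:
    def test_already_balanced_first_pass(self):
        rng = np.random.default_rng(0)
        n = 60
        X = pd.DataFrame(
            rng.normal(size=(n, 2)), columns=["a", "b"], index=[f"z{i}" for i in range(n)]
        )
        tr, ct = list(X.index[:30]), list(X.index[30:])
        mc = MatchConfig(covariates=("a", "b"), seed=0)
        pairs, rep = adaptive_caliper_match(X, tr, ct, mc)
        assert rep.balanced and pairs.caliper_used is None
        assert rep.max_abs_smd < 0.25

    def test_outlier_dropped_once_caliper_binds(self):
        vals = {"t0": 0.1, "t1": 0.2, "t2": 0.3, "t3": 10.0,
                "c0": 0.0, "c1": 0.1, "c2": 0.2, "c3": 0.3, "c4": 0.4}
        X = pd.DataFrame({"a": pd.Series(vals)})
        mc = MatchConfig(covariates=("a",), seed=0)
        pairs, rep = adaptive_caliper_match(
            X, ["t0", "t1", "t2", "t3"], ["c0", "c1", "c2", "c3", "c4"], mc
        )
        assert "t3" in pairs.dropped_treated
        assert pairs.caliper_used is not None
        assert rep.balanced and rep.max_abs_smd < 0.25

    def test_unattainable_raises(self):
        # treated and controls fully separated: no caliper can balance
        X = pd.DataFrame(
            {"a": [0.0, 0.1, 0.2, 10.0, 10.1, 10.2]},
            index=["t0", "t1", "t2", "c0", "c1", "c2"],
        )
        mc = MatchConfig(covariates=("a",), seed=0)
        with pytest.raises(BalanceUnattainableError):
            adaptive_caliper_match(X, ["t0", "t1", "t2"], ["c0", "c1", "c2"], mc)

    def test_balance_report_mean_smd_nonnegative(self):
        X, tr, ct = random_deck(5)
        mc = MatchConfig(covariates=("c0", "c1", "c2"), seed=5)
        mp = genetic_match(X, tr, ct, mc)
        rep = balance_report(X, mp)
        assert rep.mean_smd >= 0
        assert rep.max_abs_smd >= rep.median_smd >= 0
        assert rep.balanced == (rep.max_abs_smd < rep.threshold)
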