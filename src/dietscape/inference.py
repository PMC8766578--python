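"""ATT estimation over matched pairs with matched-pair bootstrap inference.

The effect of a binary zip-level treatment on each outcome is reported
as the relative difference (in percent) of the treated pair-mean over
the control pair-mean:

    ATT% = 100 · (mean_T − mean_C) / mean_C,

with means taken over matched pairs (a control matched to several
treated zips is counted once per pair). Confidence intervals and
p-values come from a nonparametric bootstrap that resamples whole
matched pairs — never individual zips — so the resampling respects the
matching structure; a paired t-test serves as a parametric cross-check.

Experiment runners reproduce the study designs: for each treatment
factor, match on the remaining factors; optionally restrict to zip
codes where one ethnic group holds a ≥50% majority; and run
null-treatment (discriminant-validity) checks with a covariate that
should not move any outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matching import (
    BalanceReport,
    MatchConfig,
    MatchedPairs,
    adaptive_caliper_match,
    split_treatment,
)

__all__ = [
    "OUTCOMES",
    "DEFAULT_FACTORS",
    "FACTOR_DIRECTIONS",
    "ATTResult",
    "ExperimentSpec",
    "ExperimentResult",
    "att_relative",
    "bootstrap_pairs",
    "paired_ttest",
    "run_experiment",
    "null_experiment",
    "correlate_reference",
]

log = logging.getLogger(__name__)

OUTCOMES = ("mean_fv", "mean_fastfood", "mean_soda", "overweight_fraction")
DEFAULT_FACTORS = ("income", "college_frac", "grocery_access", "fastfood_access")
#: Treated side per factor: high income/education/grocery access, LOW fast-food access.
FACTOR_DIRECTIONS = {
    "income": "high_is_treated",
    "college_frac": "high_is_treated",
    "grocery_access": "high_is_treated",
    "fastfood_access": "low_is_treated",
}
SUBGROUP_COLUMNS = {
    "black_majority": "frac_black",
    "hispanic_majority": "frac_hispanic",
    "white_majority": "frac_white",
}


@dataclass(frozen=True)
class ATTResult:
    outcome: str
    relative_diff_pct: float
    ci_low_pct: float
    ci_high_pct: float
    p_value: float
    n_pairs: int
    bootstrap_reps: int
    t_test_p: float | None = None


@dataclass(frozen=True)
class ExperimentSpec:
    """One matching experiment: a treatment factor plus design knobs."""

    factor: str
    direction: str | None = None  # default: FACTOR_DIRECTIONS[factor]
    covariates: tuple[str, ...] | None = None  # default: other study factors
    subgroup: str = "all"
    split: str = "median"
    bootstrap_reps: int = 1000
    balance_threshold: float = 0.25
    seed: int = 0

    def resolved_direction(self) -> str:
        if self.direction is not None:
            return self.direction
        return FACTOR_DIRECTIONS.get(self.factor, "high_is_treated")

    def resolved_covariates(self) -> tuple[str, ...]:
        if self.covariates is not None:
            return tuple(self.covariates)
        return tuple(f for f in DEFAULT_FACTORS if f != self.factor)


@dataclass(frozen=True)
class ExperimentResult:
    spec: ExperimentSpec
    results: tuple[ATTResult, ...]
    balance: BalanceReport
    pairs: MatchedPairs
    cut: float | tuple[float, float]
    n_treated: int
    n_control: int

    def by_outcome(self, outcome: str) -> ATTResult:
        for r in self.results:
            if r.outcome == outcome:
                return r
        raise KeyError(outcome)


def att_relative(treated_outcomes, control_outcomes) -> float:
    """Relative treated-vs-control difference in percent over matched pairs."""
    t = np.asarray(treated_outcomes, dtype=float)
    c = np.asarray(control_outcomes, dtype=float)
    if t.shape != c.shape or t.size == 0:
        raise ValueError("treated and control outcome vectors must align")
    mc = c.mean()
    if mc == 0:
        raise ZeroDivisionError("relative difference undefined: control mean is 0")
    return float(100.0 * (t.mean() - mc) / mc)


def bootstrap_pairs(
    treated_outcomes,
    control_outcomes,
    reps: int = 1000,
    seed: int = 0,
    control_ids=None,
) -> tuple[float, float, float]:
    """Matched-pair bootstrap CI and p-value for the relative difference.

    Resamples whole matched pairs with replacement *reps* times,
    recomputing the relative difference per replicate; never resamples
    individual zips. CI is the 2.5/97.5 percentile interval; the
    two-sided p-value is twice the smaller sign-crossing tail fraction,
    floored at 1/reps. Replicates whose control mean is zero are redrawn
    (and counted in the log).

    When matching is done *with replacement* a control zip can enter
    several pairs, making those pairs statistically dependent; treating
    them as independent resampling units underestimates the sampling
    variance of the ATT (the interval under-covers). Pass *control_ids*
    (the matched control zip per pair) to resample pairs in clusters
    that share a control — the clusters are the independent units, so
    the interval regains nominal coverage. With all-distinct controls
    this reduces exactly to the plain pair bootstrap.
    """
    t = np.asarray(treated_outcomes, dtype=float)
    c = np.asarray(control_outcomes, dtype=float)
    n = t.size
    if n < 2:
        raise ValueError("need at least 2 matched pairs to bootstrap")
    rng = np.random.default_rng(seed)

    if control_ids is None:
        cluster_of = np.arange(n)
    else:
        arr = np.asarray(control_ids, dtype=object)
        _, first, inv = np.unique(arr, return_index=True, return_inverse=True)
        # relabel clusters in first-appearance order so that all-distinct
        # controls reduce exactly to the plain pair bootstrap
        rank = np.empty(len(first), dtype=int)
        rank[np.argsort(first)] = np.arange(len(first))
        cluster_of = rank[inv]
    n_clusters = int(cluster_of.max()) + 1
    # per-cluster sufficient statistics: pair count and outcome sums
    sizes = np.bincount(cluster_of, minlength=n_clusters).astype(float)
    sum_t = np.bincount(cluster_of, weights=t, minlength=n_clusters)
    sum_c = np.bincount(cluster_of, weights=c, minlength=n_clusters)

    def draw(k: int):
        idx = rng.integers(0, n_clusters, size=(k, n_clusters))
        npairs = sizes[idx].sum(axis=1)
        tm = sum_t[idx].sum(axis=1) / npairs
        cm = sum_c[idx].sum(axis=1) / npairs
        return tm, cm

    tm, cm = draw(reps)
    bad = cm == 0
    n_redrawn = 0
    while bad.any():
        n_redrawn += int(bad.sum())
        tm[bad], cm[bad] = draw(int(bad.sum()))
        bad = cm == 0
    if n_redrawn:
        log.info("redrew %d bootstrap replicates with zero control mean", n_redrawn)
    est = 100.0 * (tm - cm) / cm
    ci_low, ci_high = np.percentile(est, [2.5, 97.5])
    frac_le = float(np.mean(est <= 0))
    frac_ge = float(np.mean(est >= 0))
    p = max(2.0 * min(frac_le, frac_ge), 1.0 / reps)
    return float(ci_low), float(ci_high), float(min(p, 1.0))


def paired_ttest(treated_outcomes, control_outcomes) -> tuple[float, float]:
    """Two-sided paired t-test on treated-minus-control pair differences.

    Returns (t statistic, p-value). Zero-variance differences are
    degenerate: p is undefined and returned as NaN.
    """
    t = np.asarray(treated_outcomes, dtype=float)
    c = np.asarray(control_outcomes, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 matched pairs")
    d = t - c
    if np.allclose(d.std(ddof=1), 0.0):
        log.warning("paired t-test degenerate: zero variance of pair differences")
        return float("nan"), float("nan")
    res = stats.ttest_rel(t, c)
    return float(res.statistic), float(res.pvalue)


def _subgroup_mask(covariates: pd.DataFrame, subgroup: str) -> pd.Series:
    if subgroup == "all":
        return pd.Series(True, index=covariates.index)
    try:
        col = SUBGROUP_COLUMNS[subgroup]
    except KeyError:
        raise ValueError(f"unknown subgroup {subgroup!r}") from None
    return covariates[col] >= 0.5


def run_experiment(
    spec: ExperimentSpec,
    covariates: pd.DataFrame,
    outcomes: pd.DataFrame,
    match_config: MatchConfig | None = None,
) -> ExperimentResult:
    """Run one full matching experiment.

    *covariates* and *outcomes* are indexed by zip (or carry a ``zip``
    column). The subgroup filter applies before the split, so cut
    points are subgroup-specific. Matching controls for all study
    factors except the treatment factor; each outcome then gets a
    relative-difference estimate with matched-pair bootstrap CI and
    p-value plus the paired t-test cross-check.
    """
    cov = covariates.set_index("zip") if "zip" in covariates.columns else covariates
    out = outcomes.set_index("zip") if "zip" in outcomes.columns else outcomes
    cov = cov.loc[_subgroup_mask(cov, spec.subgroup)]
    common = cov.index.intersection(out.index)
    cov = cov.loc[common]
    out = out.loc[common]
    if len(cov) < 4:
        raise ValueError(
            f"subgroup {spec.subgroup!r} too small to match: {len(cov)} zips"
        )

    split = split_treatment(cov[spec.factor], spec.resolved_direction(), spec.split)
    if len(split.treated) < 2 or len(split.control) < 2:
        raise ValueError(
            f"subgroup {spec.subgroup!r} too small to match: "
            f"{len(split.treated)} treated, {len(split.control)} control"
        )
    if match_config is None:
        match_config = MatchConfig(
            covariates=spec.resolved_covariates(),
            balance_threshold=spec.balance_threshold,
            seed=spec.seed,
        )
    pairs, report = adaptive_caliper_match(
        cov, split.treated, split.control, match_config
    )

    seeds = np.random.SeedSequence(spec.seed).generate_state(len(OUTCOMES))
    results = []
    for outcome, boot_seed in zip(OUTCOMES, seeds):
        t_out = out.loc[list(pairs.treated), outcome].to_numpy(dtype=float)
        c_out = out.loc[list(pairs.controls), outcome].to_numpy(dtype=float)
        est = att_relative(t_out, c_out)
        ci_low, ci_high, p = bootstrap_pairs(
            t_out,
            c_out,
            reps=spec.bootstrap_reps,
            seed=int(boot_seed % (2**31 - 1)),
            control_ids=pairs.controls,
        )
        _, p_t = paired_ttest(t_out, c_out)
        results.append(
            ATTResult(
                outcome=outcome,
                relative_diff_pct=est,
                ci_low_pct=ci_low,
                ci_high_pct=ci_high,
                p_value=p,
                n_pairs=pairs.n_pairs,
                bootstrap_reps=spec.bootstrap_reps,
                t_test_p=p_t,
            )
        )
    return ExperimentResult(
        spec=spec,
        results=tuple(results),
        balance=report,
        pairs=pairs,
        cut=split.cut,
        n_treated=len(split.treated),
        n_control=len(split.control),
    )


def null_experiment(
    null_values: pd.Series,
    spec: ExperimentSpec,
    covariates: pd.DataFrame,
    outcomes: pd.DataFrame,
) -> tuple[ExperimentResult, dict[str, float]]:
    """Discriminant-validity run with a covariate unrelated to the outcomes.

    The null covariate becomes the treatment factor while matching
    controls for *all* study factors; a sound pipeline yields CIs
    covering zero. Also reports the Pearson correlation of the null
    covariate with each study factor (it should be small for the check
    to be meaningful).
    """
    cov = covariates.set_index("zip") if "zip" in covariates.columns else covariates
    cov = cov.copy()
    name = null_values.name or "null_factor"
    cov[name] = null_values
    correlations = {
        f: float(stats.pearsonr(cov[name], cov[f])[0]) for f in DEFAULT_FACTORS
    }
    big = {f: r for f, r in correlations.items() if abs(r) > 0.3}
    if big:
        log.warning("null covariate correlates with study factors: %s", big)
    # a factor (near-)identical to the null covariate cannot be balanced
    # across its own median split, so it is excluded from matching
    match_factors = tuple(f for f in DEFAULT_FACTORS if abs(correlations[f]) < 0.95)
    if len(match_factors) < len(DEFAULT_FACTORS):
        log.warning(
            "null covariate duplicates a study factor; matching on %s only",
            match_factors,
        )
    null_spec = ExperimentSpec(
        factor=name,
        direction=spec.direction or "high_is_treated",
        covariates=match_factors,
        subgroup=spec.subgroup,
        split=spec.split,
        bootstrap_reps=spec.bootstrap_reps,
        balance_threshold=spec.balance_threshold,
        seed=spec.seed,
    )
    result = run_experiment(null_spec, cov, outcomes)
    return result, correlations


def correlate_reference(series_a, series_b) -> tuple[float, float, int]:
    """Pearson correlation of two per-region series against a reference.

    Pairs with a missing value on either side are dropped; returns
    (r, two-sided t-test p-value, n used).
    """
    df = pd.DataFrame({"a": series_a, "b": series_b}).dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 paired non-missing regions")
    if df["a"].nunique() == 1 or df["b"].nunique() == 1:
        raise ValueError("zero variance in one series")
    r, p = stats.pearsonr(df["a"], df["b"])
    return float(r), float(p), len(df)
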