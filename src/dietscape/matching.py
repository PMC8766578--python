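"""Median-split treatment assignment and genetic matching with balance diagnostics.

Zip codes are split into treatment and control groups at the sample
median of the treatment factor (boundary values fall on the treated
side). Each treated zip is then matched one-to-one *with replacement*
to the control zip nearest under a weighted Euclidean distance on
standardized covariates,

    d_w(i, j) = sqrt( Σ_k  w_k (z_ik − z_jk)² ),

where the weights ``w`` are tuned by a small genetic algorithm to
minimize the mean absolute standardized mean difference (SMD) across
covariates of the resulting matched sample. This estimates the average
treatment effect on the treated (ATT).

Balance is diagnosed per covariate with the conservative SMD convention
(mean difference divided by the *post-matching control-group* standard
deviation); a match is balanced when every |SMD| is below 0.25. When the
unrestricted match is unbalanced, a per-covariate caliper starting at
2.5 standardized units and shrinking by 0.1 is applied until balance is
reached; treated units with no admissible control are dropped (and
reported — the estimand then narrows to a caliper-restricted ATT).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MatchConfig",
    "MatchedPairs",
    "BalanceReport",
    "TreatmentSplit",
    "BalanceUnattainableError",
    "split_treatment",
    "compute_smd",
    "genetic_match",
    "balance_report",
    "adaptive_caliper_match",
]

log = logging.getLogger(__name__)


class BalanceUnattainableError(RuntimeError):
    """Raised when the adaptive caliper loop exhausts calipers without balance."""


@dataclass(frozen=True)
class MatchConfig:
    """Tunable parameters of the matching stage.

    ``covariates`` are the zip-table columns matched on (never the
    treatment factor itself). GA defaults are small because balance
    surfaces on a handful of covariates are benign; all overridable.
    """

    covariates: tuple[str, ...]
    balance_threshold: float = 0.25
    caliper_start: float = 2.5
    caliper_step: float = 0.1
    ga_pop_size: int = 50
    ga_generations: int = 30
    ga_patience: int = 8
    weight_max: float = 10.0
    weight_min: float = 1e-2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.covariates:
            raise ValueError("at least one matching covariate required")
        if self.balance_threshold <= 0:
            raise ValueError("balance_threshold must be > 0")
        if not (self.caliper_start > self.caliper_step > 0):
            raise ValueError("need caliper_start > caliper_step > 0")
        if not (0 < self.weight_min < self.weight_max):
            raise ValueError("need 0 < weight_min < weight_max")


@dataclass(frozen=True)
class TreatmentSplit:
    treated: tuple[str, ...]
    control: tuple[str, ...]
    cut: float | tuple[float, float]
    direction: str
    split: str


@dataclass(frozen=True)
class MatchedPairs:
    """One-to-one treated→control assignment (controls may repeat)."""

    treated: tuple[str, ...]
    controls: tuple[str, ...]
    distances: tuple[float, ...]
    dropped_treated: tuple[str, ...]
    weights: tuple[float, ...]
    covariates: tuple[str, ...]
    caliper_used: float | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.treated)


@dataclass(frozen=True)
class BalanceReport:
    smd_per_covariate: dict[str, float] = field(default_factory=dict)
    mean_smd: float = float("nan")
    median_smd: float = float("nan")
    max_abs_smd: float = float("nan")
    balanced: bool = False
    threshold: float = 0.25


def split_treatment(
    values: pd.Series,
    direction: str = "high_is_treated",
    split: str = "median",
) -> TreatmentSplit:
    """Dichotomize a zip-level factor into treatment and control groups.

    Median split: treated are the zips at or beyond the sample median in
    the treated direction (boundary inclusive), control the rest.
    Quartile split: treated are the top quartile in the treated
    direction, control the bottom quartile; the middle half is
    discarded.
    """
    if direction not in ("high_is_treated", "low_is_treated"):
        raise ValueError(f"unknown direction {direction!r}")
    if split not in ("median", "quartile"):
        raise ValueError(f"unknown split {split!r}")
    v = values.dropna()
    if len(v) < 2:
        raise ValueError("need at least 2 zips with non-missing values")
    if v.nunique() == 1:
        raise ValueError("degenerate split: all values identical")
    high = direction == "high_is_treated"
    if split == "median":
        cut = float(v.median())
        mask = v >= cut if high else v <= cut
        return TreatmentSplit(
            treated=tuple(v.index[mask].astype(str)),
            control=tuple(v.index[~mask].astype(str)),
            cut=cut,
            direction=direction,
            split=split,
        )
    q1, q3 = float(v.quantile(0.25)), float(v.quantile(0.75))
    t_mask = v >= q3 if high else v <= q1
    c_mask = v <= q1 if high else v >= q3
    return TreatmentSplit(
        treated=tuple(v.index[t_mask].astype(str)),
        control=tuple(v.index[c_mask & ~t_mask].astype(str)),
        cut=(q1, q3),
        direction=direction,
        split=split,
    )


def compute_smd(treated_values, control_values) -> float:
    """Standardized mean difference with the control-group SD convention.

    (mean_T − mean_C) / sd_C, sd_C the post-matching control sample
    standard deviation (ddof=1). When sd_C = 0: 0 if the means agree,
    +/−inf sentinel otherwise.
    """
    t = np.asarray(treated_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("both groups must be non-empty")
    diff = t.mean() - c.mean()
    sd = c.std(ddof=1) if c.size > 1 else 0.0
    if sd == 0 or np.isnan(sd):
        if np.isclose(diff, 0.0):
            return 0.0
        return float(np.sign(diff) * np.inf)
    return float(diff / sd)


class _MatchProblem:
    """Precomputed structures for fast repeated nearest-control matching.

    Covariates are standardized by the full pre-matching sample SD
    (distances); SMD diagnostics use the post-matching control SD and
    are scale-invariant, so they are computed on the same z-scores.
    """

    def __init__(self, covariates: pd.DataFrame, treated_ids, control_ids):
        self.covariate_names = tuple(covariates.columns)
        self.treated_ids = np.asarray(list(treated_ids), dtype=object)
        self.control_ids = np.asarray(list(control_ids), dtype=object)
        X = covariates.astype(float)
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any() or sd.isna().any():
            bad = list(sd.index[(sd == 0) | sd.isna()])
            raise ValueError(f"degenerate matching covariates: {bad}")
        Z = (X - mu) / sd
        self.Zt = Z.loc[list(self.treated_ids)].to_numpy()
        self.Zc = Z.loc[list(self.control_ids)].to_numpy()
        diff = self.Zt[:, None, :] - self.Zc[None, :, :]
        self.sq = diff**2  # (n_t, n_c, k)
        self.absdiff = np.abs(diff)
        self.n_t, self.n_c, self.k = self.sq.shape
        self._flat_sq = self.sq.reshape(self.n_t * self.n_c, self.k)

    def admissible(self, caliper: float | None) -> np.ndarray | None:
        if caliper is None:
            return None
        return (self.absdiff <= caliper).all(axis=2)

    def match(self, w: np.ndarray, ok: np.ndarray | None):
        """Nearest admissible control per treated unit under weights *w*.

        Returns (control index per treated, kept mask, squared distance).
        """
        d2 = (self._flat_sq @ w).reshape(self.n_t, self.n_c)
        if ok is not None:
            d2 = np.where(ok, d2, np.inf)
            keep = ok.any(axis=1)
        else:
            keep = np.ones(self.n_t, dtype=bool)
        j = np.argmin(d2, axis=1)
        return j, keep, d2[np.arange(self.n_t), j]

    def fitness(self, j: np.ndarray, keep: np.ndarray) -> float:
        """Mean |SMD| across covariates of the matched sample."""
        if not keep.any():
            return np.inf
        Zt = self.Zt[keep]
        Zc = self.Zc[j[keep]]
        diff = Zt.mean(axis=0) - Zc.mean(axis=0)
        sd = Zc.std(axis=0, ddof=1) if Zc.shape[0] > 1 else np.zeros(self.k)
        smd = np.empty(self.k)
        for i in range(self.k):
            if sd[i] == 0 or np.isnan(sd[i]):
                smd[i] = 0.0 if np.isclose(diff[i], 0.0) else np.inf
            else:
                smd[i] = diff[i] / sd[i]
        return float(np.mean(np.abs(smd)))


def genetic_match(
    covariates: pd.DataFrame,
    treated_ids,
    control_ids,
    config: MatchConfig,
    caliper: float | None = None,
) -> MatchedPairs:
    """One-to-one matching with replacement under GA-tuned distance weights.

    *covariates* is indexed by zip and restricted to the matching
    covariates. The genetic algorithm (tournament selection, uniform
    crossover, log-scale mutation, elitism, early stopping) searches
    weight vectors in ``(0, weight_max]^k``; fitness is the mean |SMD|
    of the induced match. Fully reproducible from ``config.seed``; the
    identity weight vector is always in the initial population, so the
    result is never worse than plain equal-weight nearest-neighbour
    matching.
    """
    treated_ids = list(treated_ids)
    control_ids = list(control_ids)
    if not treated_ids or not control_ids:
        raise ValueError("need at least one treated and one control unit")
    prob = _MatchProblem(covariates[list(config.covariates)], treated_ids, control_ids)
    ok = prob.admissible(caliper)
    rng = np.random.default_rng(config.seed)
    k = prob.k
    lo, hi = np.log(config.weight_min), np.log(config.weight_max)

    def sample(m: int) -> np.ndarray:
        # the induced match only depends on the weight *direction*, so sample
        # log-normal around identity rather than uniformly over magnitudes
        return np.exp(np.clip(rng.normal(0.0, 1.2, size=(m, k)), lo, hi))

    pop = sample(config.ga_pop_size)
    pop[0] = 1.0  # identity weights baseline
    fit = np.array([prob.fitness(*prob.match(w, ok)[:2]) for w in pop])

    # On small instances an exhaustive coarse direction scan is cheap, so
    # seed the population with the best lattice direction; the evolutionary
    # stage and the final polish then refine it.
    if prob.n_t * prob.n_c <= 1000 and 10**k <= 1500:
        axes = [np.arange(0.1, 1.01, 0.1)] * k
        lattice = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, k)
        lat_fit = np.array([prob.fitness(*prob.match(w, ok)[:2]) for w in lattice])
        li = int(np.argmin(lat_fit))
        pop[1] = lattice[li]
        fit[1] = lat_fit[li]

    best_i = int(np.argmin(fit))
    best_w, best_f = pop[best_i].copy(), float(fit[best_i])
    stall = 0
    n_imm = max(2, config.ga_pop_size // 10)  # fresh random immigrants per generation
    for _ in range(config.ga_generations):
        order = np.argsort(fit)
        elite = pop[order[:2]]
        n_children = config.ga_pop_size - 2 - n_imm
        # tournament selection (size 3)
        idx = rng.integers(0, len(pop), size=(2 * n_children, 3))
        winners = idx[np.arange(len(idx)), np.argmin(fit[idx], axis=1)]
        parents = pop[winners].reshape(-1, 2, k)
        mask = rng.random(parents.shape[:1] + (k,)) < 0.5
        children = np.where(mask, parents[:, 0, :], parents[:, 1, :])
        # log-scale mutation
        mut = rng.random(children.shape) < 0.4
        children = np.where(
            mut, np.exp(np.clip(np.log(children) + rng.normal(0, 1.0, children.shape), lo, hi)), children
        )
        pop = np.vstack([elite, children, sample(n_imm)])
        fit = np.array([prob.fitness(*prob.match(w, ok)[:2]) for w in pop])
        gen_best = int(np.argmin(fit))
        if fit[gen_best] < best_f - 1e-12:
            best_w, best_f = pop[gen_best].copy(), float(fit[gen_best])
            stall = 0
        else:
            stall += 1
            if stall >= config.ga_patience:
                break

    # memetic polish: coordinate-wise multiplicative hill climb from the best
    improved = True
    while improved:
        improved = False
        for dim in range(k):
            for step in (0.5, 0.75, 1.33, 2.0):
                w = best_w.copy()
                w[dim] = float(np.clip(w[dim] * step, config.weight_min, config.weight_max))
                f = prob.fitness(*prob.match(w, ok)[:2])
                if f < best_f - 1e-12:
                    best_w, best_f = w, f
                    improved = True

    j, keep, d2 = prob.match(best_w, ok)
    kept_idx = np.flatnonzero(keep)
    if kept_idx.size == 0:
        raise BalanceUnattainableError("caliper excluded every treated unit")
    return MatchedPairs(
        treated=tuple(str(z) for z in prob.treated_ids[kept_idx]),
        controls=tuple(str(z) for z in prob.control_ids[j[kept_idx]]),
        distances=tuple(float(np.sqrt(d2[i])) for i in kept_idx),
        dropped_treated=tuple(str(z) for z in prob.treated_ids[~keep]),
        weights=tuple(float(x) for x in best_w),
        covariates=prob.covariate_names,
        caliper_used=caliper,
    )


def balance_report(
    covariates: pd.DataFrame, pairs: MatchedPairs, threshold: float = 0.25
) -> BalanceReport:
    """Per-covariate SMD diagnostics of a matched sample.

    Controls entering several pairs are counted once per pair, so the
    diagnostic reflects the weighted control sample actually compared.
    """
    t = covariates.loc[list(pairs.treated), list(pairs.covariates)]
    c = covariates.loc[list(pairs.controls), list(pairs.covariates)]
    smds = {
        name: compute_smd(t[name].to_numpy(), c[name].to_numpy())
        for name in pairs.covariates
    }
    abs_vals = np.abs(list(smds.values()))
    max_abs = float(np.max(abs_vals))
    return BalanceReport(
        smd_per_covariate=smds,
        mean_smd=float(np.mean(abs_vals)),
        median_smd=float(np.median(abs_vals)),
        max_abs_smd=max_abs,
        balanced=bool(max_abs < threshold),
        threshold=threshold,
    )


def adaptive_caliper_match(
    covariates: pd.DataFrame,
    treated_ids,
    control_ids,
    config: MatchConfig,
) -> tuple[MatchedPairs, BalanceReport]:
    """Genetic matching with the adaptive caliper fallback.

    First matches without a caliper. If any covariate |SMD| reaches the
    balance threshold, re-matches under a per-covariate caliper starting
    at ``caliper_start`` standardized units and shrinking by
    ``caliper_step`` until balanced. Raises
    :class:`BalanceUnattainableError` when the caliper reaches zero
    without achieving balance.
    """
    cov = covariates[list(config.covariates)]
    pairs = genetic_match(cov, treated_ids, control_ids, config)
    report = balance_report(cov, pairs, config.balance_threshold)
    if report.balanced:
        return pairs, report
    c = config.caliper_start
    while c > 1e-9:
        log.info("balance not reached (max |SMD| %.3f); retrying with caliper %.1f",
                 report.max_abs_smd, c)
        try:
            pairs = genetic_match(cov, treated_ids, control_ids, config, caliper=c)
        except BalanceUnattainableError:
            break
        report = balance_report(cov, pairs, config.balance_threshold)
        if report.balanced:
            if pairs.dropped_treated:
                log.warning(
                    "caliper %.1f dropped %d treated units; estimand is caliper-restricted ATT",
                    c, len(pairs.dropped_treated),
                )
            return pairs, report
        c = round(c - config.caliper_step, 10)
    raise BalanceUnattainableError(
        f"balance unattainable: max |SMD| {report.max_abs_smd:.3f} "
        f">= {config.balance_threshold} at smallest caliper"
    )
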