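"""Synthetic study inputs with known ground-truth treatment effects.

Generates every table the pipeline consumes — zip-level covariates with
configurable cross-correlations, zip-level outcomes with injected
relative treatment effects, participant food-log streams rendered as
free text, census-tract/crosswalk geometry and business point patterns —
all reproducible from a single seed.

The covariate generator draws a Gaussian copula with the configured
correlation matrix and maps it to realistic marginals (log-normal
income, logistic-transformed fractions). Outcomes follow

    outcome_z = baseline · (1 + Σ_f δ_f·T_f(z) + Σ_{g,f} δ_{g,f}·T_f(z)·1[majority g]) · exp(ε),

with ε ~ Normal(0, noise_sd), treatment indicators T_f from median
splits of the generated covariates, and δ given in percent. The default
effect map mirrors the magnitudes the pipeline is designed to detect;
recovery tests typically inject a single effect with the rest zeroed.

Food-log rendering samples brand/description strings from the category
vocabularies plus distractors that deliberately stress the classifier's
excluder logic (diet/zero sodas, juices, near-miss snack names).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .inference import DEFAULT_FACTORS, OUTCOMES
from .matching import split_treatment

__all__ = [
    "SimConfig",
    "GroundTruth",
    "DEFAULT_EFFECTS",
    "gen_zip_table",
    "gen_food_logs",
    "gen_geography",
    "gen_null_covariate",
]

#: Default injected relative effects (percent) per factor and outcome,
#: matching the effect magnitudes the full study design targets.
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "grocery_access": {
        "mean_fv": 3.4, "mean_fastfood": -7.6, "mean_soda": -6.4,
        "overweight_fraction": -2.4,
    },
    "fastfood_access": {  # treated side is LOW fast-food access
        "mean_fv": 5.3, "mean_fastfood": -6.2, "mean_soda": -13.3,
        "overweight_fraction": -1.5,
    },
    "college_frac": {
        "mean_fv": 9.2, "mean_fastfood": -8.5, "mean_soda": -13.8,
        "overweight_fraction": -13.1,
    },
    "income": {
        "mean_fv": 3.3, "mean_fastfood": -6.8, "mean_soda": -8.6,
        "overweight_fraction": 0.6,
    },
}

#: Baseline zip-level outcomes: mean daily entries per category and the
#: overweight/obesity fraction.
BASELINE_OUTCOMES = {
    "mean_fv": 0.90,
    "mean_fastfood": 0.35,
    "mean_soda": 0.25,
    "overweight_fraction": 0.55,
}

_DEFAULT_CORR = np.array(
    [
        #  income college grocery fastfood
        [1.00, 0.60, 0.15, -0.10],
        [0.60, 1.00, 0.20, -0.10],
        [0.15, 0.20, 1.00, 0.30],
        [-0.10, -0.10, 0.30, 1.00],
    ]
)


def _default_majorities() -> dict[str, float]:
    # Composition skew of the emulated cohort: most zips white-majority.
    return {"white": 0.78, "hispanic": 0.06, "black": 0.04}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator. The defaults are the study conditions."""

    n_zips: int = 500
    participants_per_zip: int = 119
    entries_per_day_mean: float = 9.30
    active_days_mean: float = 197.0
    active_days_min: int = 10
    covariate_correlation: np.ndarray = field(
        default_factory=lambda: _DEFAULT_CORR.copy()
    )
    effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {f: dict(v) for f, v in DEFAULT_EFFECTS.items()}
    )
    subgroup_effects: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=dict
    )
    noise_sd: float = 0.05
    majority_fractions: dict[str, float] = field(default_factory=_default_majorities)
    dose_response: bool = False  # effects scale with covariate rank, not the median indicator
    rate_shape: float = 10.0  # participant-level gamma heterogeneity of rates
    bmi_sd: float = 4.0
    missing_bmi_frac: float = 0.0008
    businesses_per_zip: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        C = np.asarray(self.covariate_correlation, dtype=float)
        if C.shape != (4, 4) or not np.allclose(C, C.T):
            raise ValueError("covariate_correlation must be a symmetric 4x4 matrix")
        eig = np.linalg.eigvalsh(C)
        if eig.min() < -1e-10:
            i, j = np.unravel_index(np.argmax(np.abs(C - np.eye(4))), C.shape)
            raise ValueError(
                f"covariate_correlation is not positive semidefinite "
                f"(largest off-diagonal involves factors {DEFAULT_FACTORS[i]!r}, "
                f"{DEFAULT_FACTORS[j]!r})"
            )
        for f in self.effects:
            if f not in DEFAULT_FACTORS:
                raise ValueError(f"unknown effect factor {f!r}")
        if sum(self.majority_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("majority fractions sum to more than 1")


@dataclass(frozen=True)
class GroundTruth:
    """True injected relative effects (percent) for recovery checks."""

    effects: dict[str, dict[str, float]]
    subgroup_effects: dict[tuple[str, str], dict[str, float]]

    def effect(self, factor: str, outcome: str, subgroup: str = "all") -> float:
        base = self.effects.get(factor, {}).get(outcome, 0.0)
        if subgroup == "all":
            return base
        group = subgroup.replace("_majority", "")
        extra = self.subgroup_effects.get((group, factor), {}).get(outcome, 0.0)
        return base + extra


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, config.seed])


def _ethnicity_fractions(n: int, config: SimConfig, rng: np.random.Generator):
    groups = list(config.majority_fractions)
    probs = [config.majority_fractions[g] for g in groups]
    probs.append(max(0.0, 1.0 - sum(probs)))
    choice = rng.choice(len(groups) + 1, size=n, p=np.array(probs) / sum(probs))
    frac = {g: np.empty(n) for g in ("white", "black", "hispanic")}
    for i in range(n):
        if choice[i] < len(groups):
            g = groups[choice[i]]
            major = rng.uniform(0.55, 0.90)
            rest = rng.dirichlet(np.ones(2)) * (1.0 - major) * rng.uniform(0.5, 0.9)
            others = [x for x in ("white", "black", "hispanic") if x != g]
            frac[g][i] = major
            frac[others[0]][i], frac[others[1]][i] = rest
        else:  # no majority group
            w = rng.uniform(0.20, 0.49)
            b = rng.uniform(0.05, min(0.45, 0.95 - w))
            h = rng.uniform(0.05, min(0.45, max(0.06, 0.98 - w - b)))
            frac["white"][i], frac["black"][i], frac["hispanic"][i] = w, b, h
    return frac, choice, groups


def gen_zip_table(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate zip covariates, zip outcomes and the ground truth.

    Returns (covariates, outcomes, truth); both tables carry a ``zip``
    column of 5-character codes and are index-aligned.
    """
    rng = _rng(config, 1)
    n = config.n_zips
    zips = np.array([f"{i:05d}" for i in range(10000, 10000 + n)])

    L = np.linalg.cholesky(
        np.asarray(config.covariate_correlation, dtype=float) + 1e-12 * np.eye(4)
    )
    z = rng.standard_normal((n, 4)) @ L.T
    income = np.exp(np.log(65_000) + 0.45 * z[:, 0])
    college = expit(logit(0.28) + 0.80 * z[:, 1])
    grocery = expit(logit(0.30) + 1.00 * z[:, 2])
    fastfood = expit(logit(0.05) + 0.50 * z[:, 3])

    frac, majority_idx, groups = _ethnicity_fractions(n, config, rng)
    ruca = rng.choice(
        np.arange(1, 11),
        size=n,
        p=np.array([0.40, 0.12, 0.10, 0.08, 0.08, 0.07, 0.05, 0.04, 0.03, 0.03]),
    )
    population = np.round(np.exp(rng.normal(np.log(7800), 0.6, size=n))).astype(int)
    lat = 25.0 + (np.arange(n) // 200) * 0.5
    lon = -160.0 + (np.arange(n) % 200) * 0.8
    food_desert_frac = expit(logit(0.10) - 0.8 * z[:, 2] + rng.normal(0, 0.3, n))

    covariates = pd.DataFrame(
        {
            "zip": zips,
            "income": income,
            "college_frac": college,
            "grocery_access": grocery,
            "fastfood_access": fastfood,
            "food_desert_frac": food_desert_frac,
            "frac_white": frac["white"],
            "frac_black": frac["black"],
            "frac_hispanic": frac["hispanic"],
            "ruca": ruca,
            "population": population,
            "centroid_lat": lat,
            "centroid_lon": lon,
        }
    )

    from .inference import FACTOR_DIRECTIONS  # avoid cycle at import time

    indexed = covariates.set_index("zip")
    treat = {}
    for f in DEFAULT_FACTORS:
        if config.dose_response:
            # signed exposure in [-1, 1]: rank percentile toward the treated
            # direction, so a median split sees a mean exposure contrast of 1
            # and a top-vs-bottom-quartile split a contrast of 1.5
            pct = indexed[f].rank(pct=True).to_numpy()
            sign = 1.0 if FACTOR_DIRECTIONS[f] == "high_is_treated" else -1.0
            treat[f] = sign * (2.0 * pct - 1.0)
        else:
            split = split_treatment(indexed[f], FACTOR_DIRECTIONS[f], "median")
            t = np.zeros(n)
            t[indexed.index.get_indexer(list(split.treated))] = 1.0
            treat[f] = t

    majority_of = np.array(
        [groups[i] if i < len(groups) else "" for i in majority_idx], dtype=object
    )
    eps = rng.normal(0.0, config.noise_sd, size=(n, len(OUTCOMES)))
    out = {}
    for k, outcome in enumerate(OUTCOMES):
        mult = np.ones(n)
        for f in DEFAULT_FACTORS:
            delta = config.effects.get(f, {}).get(outcome, 0.0) / 100.0
            mult += delta * treat[f]
            for (g, gf), effs in config.subgroup_effects.items():
                if gf == f and outcome in effs:
                    mult += (effs[outcome] / 100.0) * treat[f] * (majority_of == g)
        vals = BASELINE_OUTCOMES[outcome] * mult * np.exp(eps[:, k])
        if outcome == "overweight_fraction":
            vals = np.clip(vals, 0.01, 0.99)
        out[outcome] = vals

    outcomes = pd.DataFrame({"zip": zips, "n_participants": config.participants_per_zip, **out})
    truth = GroundTruth(
        effects={f: dict(v) for f, v in config.effects.items()},
        subgroup_effects={k: dict(v) for k, v in config.subgroup_effects.items()},
    )
    return covariates, outcomes, truth


# --------------------------------------------------------------------------
# Food-log rendering vocabularies. Distractors include near-miss strings
# (diet/zero sodas, juices, "light" snacks) that must classify as none.

FV_ITEMS = [
    ("", "Banana"),
    ("", "Fuji Apple, medium"),
    ("Dole", "Romaine Lettuce salad"),
    ("", "Baby Spinach, 2 cups"),
    ("Fresh Market", "Strawberries"),
    ("", "Carrots, raw"),
    ("Green Giant", "Broccoli florets"),
    ("", "Roma Tomato"),
    ("", "Blueberries, 1 cup"),
    ("", "Cucumber slices"),
]
FASTFOOD_ITEMS = [
    ("McDonald's", "Big Mac"),
    ("Burger King", "Whopper with cheese"),
    ("Taco Bell", "Crunchwrap Supreme"),
    ("KFC", "Fried chicken, 2 pc"),
    ("Wendy's", "Baconator"),
    ("Subway", "Turkey sub, footlong"),
    ("Chipotle", "Chicken burrito bowl"),
]
SODA_ITEMS = [
    ("Coca-Cola", "12 oz can"),
    ("Pepsi", "Fountain drink, large"),
    ("Sprite", "20 oz bottle"),
    ("Mountain Dew", "12oz"),
    ("Dr Pepper", "2 liter, 1 glass"),
]
DISTRACTOR_ITEMS = [
    ("Chobani", "Greek Yogurt, plain"),
    ("Quaker", "Oatmeal with brown sugar"),
    ("", "Apple Juice"),
    ("Tropicana", "Orange Juice, 8 oz"),
    ("Coca-Cola", "Diet Coke, 12 oz"),
    ("Pepsi", "Pepsi Zero Sugar"),
    ("", "Light string cheese"),
    ("Kraft", "Mac and cheese"),
    ("Starbucks", "Caffe Latte, grande"),
    ("Tyson", "Grilled chicken breast"),
    ("Barilla", "Spaghetti with marinara"),
    ("", "Scrambled eggs"),
    ("Nature Valley", "Granola bar"),
]
_CATEGORY_ITEMS = {
    "mean_fv": FV_ITEMS,
    "mean_fastfood": FASTFOOD_ITEMS,
    "mean_soda": SODA_ITEMS,
}


def gen_food_logs(
    zip_outcomes: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render participant food-log streams consistent with zip outcomes.

    Per participant: active days from a shifted negative binomial with
    floor ``active_days_min``; per active day, category entry counts are
    Poisson with a participant-specific rate (gamma-heterogeneous around
    the zip mean) plus Poisson distractor entries filling the overall
    logging rate; BMI is normal around a zip mean calibrated so the
    overweight fraction is recoverable.

    Returns (entries, participants): entries with columns
    participant_id, log_date, brand, description, serving_unit,
    n_servings; participants with participant_id, zip, bmi.
    """
    rng = _rng(config, 2)
    base_date = np.datetime64("2015-01-01")
    mean_extra = max(config.active_days_mean - config.active_days_min, 0.0)

    entry_rows: list[pd.DataFrame] = []
    part_rows = []
    for row in zip_outcomes.itertuples():
        zcode = str(row.zip).zfill(5)
        n_part = int(getattr(row, "n_participants", config.participants_per_zip))
        zip_means = {c: getattr(row, c) for c in _CATEGORY_ITEMS}
        distractor_rate = max(
            config.entries_per_day_mean - sum(zip_means.values()), 0.3
        )
        ow = float(np.clip(row.overweight_fraction, 0.01, 0.99))
        bmi_mu = 25.0 + config.bmi_sd * norm.ppf(ow)
        for p in range(n_part):
            pid = f"{zcode}-p{p:04d}"
            if mean_extra > 0:
                days = config.active_days_min + rng.negative_binomial(
                    2, 2.0 / (2.0 + mean_extra)
                )
            else:
                days = config.active_days_min
            start = base_date + rng.integers(0, 365)
            dates = start + np.arange(days)
            pid_brands, pid_descs, pid_dates = [], [], []
            for cat, items in _CATEGORY_ITEMS.items():
                rate = zip_means[cat] * rng.gamma(config.rate_shape, 1.0 / config.rate_shape)
                counts = rng.poisson(rate, size=days)
                total = int(counts.sum())
                if total == 0:
                    continue
                pick = rng.integers(0, len(items), size=total)
                pid_dates.append(np.repeat(dates, counts))
                pid_brands.extend(items[i][0] for i in pick)
                pid_descs.extend(items[i][1] for i in pick)
            counts = rng.poisson(distractor_rate, size=days)
            counts[0] = max(counts[0], 1)  # every active day stream is non-empty
            total = int(counts.sum())
            pick = rng.integers(0, len(DISTRACTOR_ITEMS), size=total)
            pid_dates.append(np.repeat(dates, counts))
            pid_brands.extend(DISTRACTOR_ITEMS[i][0] for i in pick)
            pid_descs.extend(DISTRACTOR_ITEMS[i][1] for i in pick)

            all_dates = np.concatenate(pid_dates)
            entry_rows.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "log_date": all_dates.astype("datetime64[D]").astype(str),
                        "brand": pid_brands,
                        "description": pid_descs,
                        "serving_unit": "serving",
                        "n_servings": 1.0,
                    }
                )
            )
            bmi = rng.normal(bmi_mu, config.bmi_sd)
            if rng.random() < config.missing_bmi_frac:
                bmi = np.nan
            part_rows.append((pid, zcode, bmi))

    entries = pd.concat(entry_rows, ignore_index=True)
    participants = pd.DataFrame(part_rows, columns=["participant_id", "zip", "bmi"])
    return entries, participants


def gen_geography(
    covariates: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate tract, crosswalk, business-point and centroid tables.

    Tract "beyond 0.5 miles" fractions are jittered around each zip's
    1 − grocery_access so the population-weighted crosswalk reproduces
    the configured access values; business points are scattered within
    a few km of each centroid with the zip's chain fraction, and
    centroids are spaced widely enough that 40 km queries stay
    zip-local.
    """
    rng = _rng(config, 3)
    tracts, xwalk, biz = [], [], []
    for row in covariates.itertuples():
        zcode = str(row.zip).zfill(5)
        target_beyond = 1.0 - row.grocery_access
        n_tracts = int(rng.integers(1, 9))
        pops = np.round(np.exp(rng.normal(np.log(2000), 0.5, n_tracts))).astype(int)
        pops = np.maximum(pops, 50)
        vals = np.clip(target_beyond + rng.normal(0, 0.05, n_tracts), 0.0, 1.0)
        # re-centre the weighted mean on the target, then clip
        vals = np.clip(vals + (target_beyond - np.average(vals, weights=pops)), 0.0, 1.0)
        desert = (rng.random(n_tracts) < row.food_desert_frac).astype(int)
        for t in range(n_tracts):
            tid = f"{zcode}T{t}"
            tracts.append(
                (tid, int(pops[t]), float(vals[t]), int(rng.random() < 0.3), int(desert[t]))
            )
            xwalk.append((zcode, tid))
        n_rest = int(rng.poisson(config.businesses_per_zip))
        n_other = int(rng.poisson(config.businesses_per_zip * 0.2))
        n_pts = n_rest + n_other
        lat = row.centroid_lat + rng.uniform(-0.04, 0.04, n_pts)
        lon = row.centroid_lon + rng.uniform(-0.04, 0.04, n_pts)
        is_rest = np.zeros(n_pts, dtype=bool)
        is_rest[:n_rest] = True
        is_chain = is_rest & (rng.random(n_pts) < row.fastfood_access)
        for i in range(n_pts):
            biz.append((float(lat[i]), float(lon[i]), bool(is_rest[i]), bool(is_chain[i])))

    tracts_df = pd.DataFrame(
        tracts,
        columns=["tract_id", "population", "beyond_half_mile_frac", "low_income", "food_desert"],
    )
    xwalk_df = pd.DataFrame(xwalk, columns=["zip", "tract_id"])
    biz_df = pd.DataFrame(
        biz, columns=["latitude", "longitude", "is_restaurant", "is_fastfood_chain"]
    )
    centroids = covariates[["zip", "centroid_lat", "centroid_lon"]].rename(
        columns={"centroid_lat": "latitude", "centroid_lon": "longitude"}
    )
    return tracts_df, xwalk_df, biz_df, centroids


def gen_null_covariate(
    covariates: pd.DataFrame, seed: int = 0, name: str = "null_service_frac"
) -> pd.Series:
    """A zip-level covariate independent of everything in the study.

    Emulates e.g. the local fraction of waterproofing services — a
    quantity with no plausible link to diet — for discriminant-validity
    (null-treatment) experiments.
    """
    rng = np.random.default_rng([4, seed])
    vals = rng.beta(2.0, 18.0, size=len(covariates))
    idx = (
        covariates["zip"].astype(str).str.zfill(5)
        if "zip" in covariates.columns
        else covariates.index
    )
    return pd.Series(vals, index=pd.Index(idx, name="zip"), name=name)
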