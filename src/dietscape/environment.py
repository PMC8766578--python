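"""Zip-level food-environment covariates.

Census-tract measures (fraction of residents beyond 0.5 miles from a
grocery store; food-desert status) are carried to the zip level through
a tract→zip crosswalk as a population-weighted average. Grocery access
is stored with the "fraction *within* 0.5 miles" sign convention so that
high access is above-median. Fast-food access is the fraction of the
(up to) 1000 restaurants nearest the zip centroid within 40 km that are
fast-food chains, with great-circle distances.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "haversine_km",
    "tract_to_zip",
    "grocery_access",
    "food_desert_flag",
    "fastfood_access",
    "build_zip_covariates",
]

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between points given in degrees."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def tract_to_zip(
    tracts: pd.DataFrame, crosswalk: pd.DataFrame, value_col: str
) -> pd.Series:
    """Population-weighted average of a tract measure per zip code.

    ``zip value = Σ(tract value × tract population) / Σ(tract population)``
    over the tracts the crosswalk lists as overlapping the zip. Zips
    whose overlapping tracts have zero total population get NaN.

    *tracts* needs ``tract_id``, ``population`` and *value_col*;
    *crosswalk* needs ``zip`` and ``tract_id`` (pairs unique).
    """
    if crosswalk.duplicated(["zip", "tract_id"]).any():
        raise ValueError("crosswalk (zip, tract_id) pairs must be unique")
    merged = crosswalk.merge(tracts, on="tract_id", how="left", validate="m:1")
    if merged["population"].isna().any():
        bad = merged.loc[merged["population"].isna(), "tract_id"].tolist()[:5]
        raise ValueError(f"crosswalk references unknown tracts, e.g. {bad}")
    merged["_w"] = merged["population"].astype(float)
    merged["_wv"] = merged["_w"] * merged[value_col].astype(float)
    g = merged.groupby("zip", sort=True)
    wsum = g["_w"].sum()
    out = g["_wv"].sum() / wsum.where(wsum > 0)
    n_missing = int(out.isna().sum())
    if n_missing:
        log.warning("%d zips have zero overlapping population; value missing", n_missing)
    out.name = value_col
    return out


def grocery_access(beyond_half_mile_frac):
    """Convert "fraction beyond 0.5 miles" to "fraction within 0.5 miles"."""
    arr = np.asarray(beyond_half_mile_frac, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("beyond_half_mile_frac must lie in [0, 1]")
    out = 1.0 - arr
    if np.isscalar(beyond_half_mile_frac) or arr.ndim == 0:
        return float(out)
    if isinstance(beyond_half_mile_frac, pd.Series):
        return pd.Series(out, index=beyond_half_mile_frac.index, name="grocery_access")
    return out


def food_desert_flag(food_desert_frac, threshold: float = 0.5):
    """Binary food-desert status: weighted tract fraction >= threshold."""
    arr = np.asarray(food_desert_frac, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("food_desert_frac must lie in [0, 1]")
    out = arr >= threshold
    if np.isscalar(food_desert_frac) or arr.ndim == 0:
        return bool(out)
    return out


def fastfood_access(
    centroid: tuple[float, float],
    businesses: pd.DataFrame,
    max_n: int = 1000,
    max_km: float = 40.0,
) -> float:
    """Fraction of nearby restaurants that are fast-food chains.

    Restaurants within *max_km* of the zip centroid are ranked by
    great-circle distance; among the nearest *max_n* (emulating a
    capped point-of-interest API query) the chain fraction is returned.
    Distance ties keep stable input order. NaN when no restaurant lies
    within the radius.
    """
    rest = businesses[businesses["is_restaurant"].astype(bool)]
    if rest.empty:
        return float("nan")
    d = haversine_km(
        centroid[0], centroid[1], rest["latitude"].to_numpy(), rest["longitude"].to_numpy()
    )
    within = d <= max_km
    if not within.any():
        return float("nan")
    d_in = d[within]
    chains = rest["is_fastfood_chain"].to_numpy(dtype=bool)[within]
    order = np.argsort(d_in, kind="stable")[:max_n]
    return float(chains[order].mean())


def build_zip_covariates(
    tracts: pd.DataFrame,
    crosswalk: pd.DataFrame,
    businesses: pd.DataFrame,
    centroids: pd.DataFrame,
    demographics: pd.DataFrame,
    max_n: int = 1000,
    max_km: float = 40.0,
) -> pd.DataFrame:
    """Assemble the per-zip covariate table used by matching.

    *centroids* has ``zip``, ``latitude``, ``longitude``; *demographics*
    is keyed by ``zip`` with income, college_frac, ethnicity fractions,
    ruca and population. Grocery access and food-desert fraction come
    from the tract crosswalk, fast-food access from the business points.
    """
    cent = centroids.copy()
    cent["zip"] = cent["zip"].astype(str).str.zfill(5)
    demo = demographics.copy()
    demo["zip"] = demo["zip"].astype(str).str.zfill(5)
    xwalk = crosswalk.copy()
    xwalk["zip"] = xwalk["zip"].astype(str).str.zfill(5)

    beyond = tract_to_zip(tracts, xwalk, "beyond_half_mile_frac")
    desert = tract_to_zip(tracts, xwalk, "food_desert")
    env = pd.DataFrame(
        {
            "grocery_access": grocery_access(beyond),
            "food_desert_frac": desert,
        }
    )
    ff = [
        fastfood_access((row.latitude, row.longitude), businesses, max_n, max_km)
        for row in cent.itertuples()
    ]
    env = env.join(pd.Series(ff, index=cent["zip"], name="fastfood_access"), how="outer")
    out = demo.merge(env.reset_index(), on="zip", how="left").merge(
        cent.rename(columns={"latitude": "centroid_lat", "longitude": "centroid_lon"}),
        on="zip",
        how="left",
    )
    return out
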