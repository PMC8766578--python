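"""Rule-based classification of free-text food-log entries.

Each logged entry carries a free-text brand and description. Three
independent binary classifiers label an entry as fresh fruit/vegetable
(F&V), fast food, and/or sugary non-diet soda:

* **fast food** — the normalized brand contains a known chain name as a
  substring;
* **soda** — the normalized brand contains a soda drink name as a
  substring *and* the normalized description contains none of the diet
  excluder tokens (``diet``, ``lite``, ``light``, ``zero``);
* **F&V** — the normalized brand or description contains a fruit or
  vegetable term as a whole token sequence and no excluder token
  (juices and processed preparations are excluded by design).

The three labels are independent (multi-label); an entry matching none
of them is excluded from downstream consumption outcomes but still
counts toward logging activity.

Keyword inventories are configuration, not code: they live in editable
plain-text files (one keyword per line, ``#`` comments allowed) loaded
into a :class:`RuleSet`.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass
from datetime import date
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FoodEntry",
    "CategoryLabel",
    "RuleSet",
    "RuleSetError",
    "normalize_text",
    "classify_entry",
    "classify_entries",
    "estimate_precision",
]

REQUIRED_SODA_EXCLUDERS = frozenset({"diet", "lite", "light", "zero"})

# ASCII punctuation plus the common unicode quotes/dashes seen in app logs.
_PUNCT = string.punctuation + "‘’“”–—"
_PUNCT_TABLE = str.maketrans("", "", _PUNCT)
_WS = re.compile(r"\s+")


def normalize_text(raw: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace.

    Punctuation characters are deleted (not replaced by a space), so
    ``"Coca-Cola"`` and ``"CocaCola"`` normalize to the same string.
    Idempotent; empty input maps to the empty string.
    """
    return _WS.sub(" ", raw.translate(_PUNCT_TABLE).lower()).strip()


class RuleSetError(ValueError):
    """Raised when a keyword rule set violates its contract."""


@dataclass(frozen=True)
class FoodEntry:
    """One logged food event."""

    participant_id: str
    log_date: date
    brand: str
    description: str
    serving_unit: str = ""
    n_servings: float = 1.0

    def __post_init__(self) -> None:
        if self.brand is None or self.description is None:
            raise ValueError("brand/description may be empty but not absent")
        if self.n_servings < 0:
            raise ValueError("n_servings must be nonnegative")


@dataclass(frozen=True)
class CategoryLabel:
    is_fv: bool
    is_fastfood: bool
    is_soda: bool

    @property
    def excluded(self) -> bool:
        """True when the entry falls in none of the study categories."""
        return not (self.is_fv or self.is_fastfood or self.is_soda)


@dataclass(frozen=True)
class RuleSet:
    """Keyword inventories for the three binary classifiers.

    All keywords must already be normalized (see :func:`normalize_text`).
    Chain and soda names match as substrings of the normalized brand;
    excluders and F&V terms match as whole token (sequences), so that
    e.g. ``lite`` does not fire inside ``politely``.
    """

    fastfood_chains: tuple[str, ...]
    soda_names: tuple[str, ...]
    soda_excluders: tuple[str, ...]
    fv_keywords: tuple[str, ...]
    fv_excluders: tuple[str, ...]

    def __post_init__(self) -> None:
        for name in (
            "fastfood_chains",
            "soda_names",
            "soda_excluders",
            "fv_keywords",
            "fv_excluders",
        ):
            words = getattr(self, name)
            if not words:
                raise RuleSetError(f"rule list {name!r} is empty")
            for w in words:
                if w != normalize_text(w):
                    raise RuleSetError(
                        f"keyword {w!r} in {name!r} is not normalized"
                    )
        missing = REQUIRED_SODA_EXCLUDERS - set(self.soda_excluders)
        if missing:
            raise RuleSetError(f"soda_excluders must include {sorted(missing)}")

    # -- construction -----------------------------------------------------

    @staticmethod
    def _read_list(path: Path) -> tuple[str, ...]:
        out = []
        for line in path.read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
        return tuple(out)

    @classmethod
    def from_dir(cls, directory: str | Path) -> "RuleSet":
        """Load the five keyword files from *directory*."""
        d = Path(directory)
        return cls(
            fastfood_chains=cls._read_list(d / "fastfood_chains.txt"),
            soda_names=cls._read_list(d / "soda_names.txt"),
            soda_excluders=cls._read_list(d / "soda_excluders.txt"),
            fv_keywords=cls._read_list(d / "fv_keywords.txt"),
            fv_excluders=cls._read_list(d / "fv_excluders.txt"),
        )

    @classmethod
    def default(cls) -> "RuleSet":
        """The rule set shipped with the package."""
        with resources.as_file(resources.files("dietscape") / "data") as d:
            return cls.from_dir(d)


def _substring_regex(words: Iterable[str]) -> re.Pattern:
    return re.compile("|".join(re.escape(w) for w in words))


def _token_regex(words: Iterable[str]) -> re.Pattern:
    # Normalized text is space-separated tokens, so \b delimits tokens;
    # multi-word phrases match as consecutive tokens.
    return re.compile(r"\b(?:" + "|".join(re.escape(w) for w in words) + r")\b")


@lru_cache(maxsize=8)
def _compiled(rules: RuleSet) -> dict[str, re.Pattern]:
    return {
        "fastfood": _substring_regex(rules.fastfood_chains),
        "soda": _substring_regex(rules.soda_names),
        "soda_excl": _token_regex(rules.soda_excluders),
        "fv": _token_regex(rules.fv_keywords),
        "fv_excl": _token_regex(rules.fv_excluders),
    }


def classify_entry(entry: FoodEntry, rules: RuleSet) -> CategoryLabel:
    """Apply the three binary classifiers to a single entry."""
    rx = _compiled(rules)
    brand = normalize_text(entry.brand)
    desc = normalize_text(entry.description)
    both = f"{brand} {desc}".strip()
    is_fastfood = bool(rx["fastfood"].search(brand))
    is_soda = bool(rx["soda"].search(brand)) and not rx["soda_excl"].search(desc)
    is_fv = bool(rx["fv"].search(both)) and not rx["fv_excl"].search(both)
    return CategoryLabel(is_fv=is_fv, is_fastfood=is_fastfood, is_soda=is_soda)


def classify_entries(entries: pd.DataFrame, rules: RuleSet) -> pd.DataFrame:
    """Vectorized classification of a food-log table.

    Parameters
    ----------
    entries
        Food-log table with at least ``brand`` and ``description``
        columns (free text, missing values treated as empty).
    rules
        Keyword rule set.

    Returns
    -------
    Copy of *entries* with boolean ``is_fv``, ``is_fastfood``,
    ``is_soda`` columns appended.
    """
    rx = _compiled(rules)
    brand = entries["brand"].fillna("").map(normalize_text)
    desc = entries["description"].fillna("").map(normalize_text)
    both = (brand + " " + desc).str.strip()
    out = entries.copy()
    out["is_fastfood"] = brand.str.contains(rx["fastfood"], regex=True)
    out["is_soda"] = brand.str.contains(rx["soda"], regex=True) & ~desc.str.contains(
        rx["soda_excl"], regex=True
    )
    out["is_fv"] = both.str.contains(rx["fv"], regex=True) & ~both.str.contains(
        rx["fv_excl"], regex=True
    )
    return out


def estimate_precision(
    predicted_positive: Sequence | pd.DataFrame,
    manual_labels: Sequence[bool],
    sample_size: int = 50,
    seed: int = 0,
) -> float:
    """Audit classifier precision on a random sample of predicted positives.

    Precision = (# true positive) / (# predicted positive) estimated on a
    without-replacement random sample of *sample_size* entries (all
    entries when fewer are available). *manual_labels* is aligned with
    *predicted_positive* and records the manual audit verdict per entry.
    """
    n = len(predicted_positive)
    if n == 0:
        raise ValueError("no predicted positives to audit")
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    labels = np.asarray(manual_labels, dtype=bool)
    if len(labels) != n:
        raise ValueError("manual_labels must align with predicted_positive")
    rng = np.random.default_rng(seed)
    take = min(sample_size, n)
    idx = rng.choice(n, size=take, replace=False)
    return float(labels[idx].mean())
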