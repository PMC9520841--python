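"""Descriptive statistics for the dog-flea infestation survey.

Prevalence of infestation with Wald normal-approximation confidence
intervals, species composition of the collected fleas, female:male sex
ratios, and contingency analysis comparing a morphological identification
against the cox1 reference identification.

Rounding follows field reporting conventions: percentages to whole percent
(half away from zero), ratios to two decimals (round half to even).
Wilson and Clopper-Pearson intervals are available behind a flag; Wald is
the default because it is what normal-approximation spreadsheet workflows
produce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurveyTable",
    "prevalence_ci",
    "species_composition",
    "sex_ratio",
    "agreement_table",
    "infestation_by_group",
    "read_survey_tsv",
]

_Z95 = 1.959964


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass
class SurveyTable:
    """Per-dog infestation records plus a long-format flea table.

    ``dogs`` columns: dog_id, region, age_months, dog_sex, infested.
    ``fleas`` columns: dog_id, species, flea_sex, morphology_id, cox1_id.
    """

    dogs: pd.DataFrame
    fleas: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"dog_id", "region", "age_months", "dog_sex", "infested"}
        missing = need - set(self.dogs.columns)
        if missing:
            raise ValueError(f"dogs table missing columns: {sorted(missing)}")
        need_f = {"dog_id", "species", "flea_sex", "morphology_id", "cox1_id"}
        missing_f = need_f - set(self.fleas.columns)
        if missing_f:
            raise ValueError(f"fleas table missing columns: {sorted(missing_f)}")
        if (self.dogs["age_months"] <= 0).any():
            raise ValueError("age_months must be positive")
        with_fleas = set(self.fleas["dog_id"])
        flagged = set(self.dogs.loc[self.dogs["infested"], "dog_id"])
        if flagged != with_fleas:
            raise ValueError("infested flag must match presence of flea records")

    @property
    def n_dogs(self) -> int:
        return len(self.dogs)

    def write_tsv(self, path: str | Path) -> None:
        """One row per flea; uninfested dogs appear once with empty flea fields."""
        merged = self.dogs.merge(self.fleas, on="dog_id", how="left")
        merged.to_csv(path, sep="\t", index=False)


def read_survey_tsv(path: str | Path) -> SurveyTable:
    df = pd.read_csv(path, sep="\t", dtype={"dog_id": str})
    dog_cols = ["dog_id", "region", "age_months", "dog_sex", "infested"]
    dogs = df[dog_cols].drop_duplicates("dog_id").reset_index(drop=True)
    flea_cols = ["dog_id", "species", "flea_sex", "morphology_id", "cox1_id"]
    fleas = df.loc[df["species"].notna(), flea_cols].reset_index(drop=True)
    return SurveyTable(dogs=dogs, fleas=fleas)


def prevalence_ci(
    k: int, n: int, confidence: float = 0.95, method: str = "wald"
) -> dict[str, float | int]:
    """Binomial proportion with its confidence interval, as percentages.

    Default is the Wald interval ``p +/- z sqrt(p(1-p)/n)`` clamped to
    [0, 100]; ``method`` may also be ``wilson`` or ``clopper-pearson``.
    Returns both whole-percent values (half away from zero) and the
    unrounded percentages.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    p = k / n
    z = _Z95 if confidence == 0.95 else float(stats.norm.ppf(0.5 + confidence / 2.0))
    if method == "wald":
        half = z * math.sqrt(p * (1.0 - p) / n)
        lo, hi = p - half, p + half
    elif method == "wilson":
        centre = (p + z**2 / (2 * n)) / (1 + z**2 / n)
        half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
        lo, hi = centre - half, centre + half
    elif method == "clopper-pearson":
        alpha = 1.0 - confidence
        lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
        hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    lo_pct = min(max(100.0 * lo, 0.0), 100.0)
    hi_pct = min(max(100.0 * hi, 0.0), 100.0)
    return {
        "percent": _round_half_away(100.0 * p),
        "lower": _round_half_away(lo_pct),
        "upper": _round_half_away(hi_pct),
        "percent_raw": 100.0 * p,
        "lower_raw": lo_pct,
        "upper_raw": hi_pct,
        "k": k,
        "n": n,
    }


def species_composition(counts: dict[str, int]) -> dict[str, int]:
    """Percent of total per species, whole-percent rounding (half away from zero)."""
    total = sum(counts.values())
    if total < 1:
        raise ValueError("total count must be >= 1")
    return {sp: _round_half_away(100.0 * c / total) for sp, c in counts.items()}


def sex_ratio(females: int, males: int) -> float:
    """Female:male ratio to two decimals, round half to even (5.625 -> 5.62)."""
    if males < 1:
        raise ValueError("sex ratio undefined with zero males")
    ratio = Decimal(females) / Decimal(males)
    return float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def agreement_table(
    truth: "pd.Series | list[str]",
    assigned: "pd.Series | list[str]",
    indeterminate: str = "indeterminate",
) -> tuple[pd.DataFrame, pd.Series]:
    """Cross-tabulate a reference identification against an assigned one.

    Rows are the truth (cox1) classes, columns the assigned classes.  The
    per-true-class misclassification percentage excludes specimens the
    assigner left ``indeterminate`` from its denominator, so it reflects
    only specimens fully identified by both methods.
    """
    t = pd.Series(list(truth), name="true")
    a = pd.Series(list(assigned), name="assigned")
    if len(t) != len(a):
        raise ValueError("truth and assigned label lists differ in length")
    table = pd.crosstab(t, a)
    rates = {}
    for cls in table.index:
        cols = [c for c in table.columns if c != indeterminate]
        total = int(table.loc[cls, cols].sum())
        right = int(table.loc[cls, cls]) if cls in cols else 0
        rates[cls] = math.nan if total == 0 else _round_half_away(
            100.0 * (total - right) / total
        )
    return table, pd.Series(rates, name="misclassification_pct")


def infestation_by_group(
    table: SurveyTable, grouping: str, age_threshold_months: float = 12.0
) -> pd.DataFrame:
    """Per-group infestation prevalence with confidence intervals.

    ``grouping`` is ``age`` (juvenile <= threshold vs adult), ``sex`` or
    ``region``.  Empty groups are reported with n=0 and a skip flag.
    """
    dogs = table.dogs
    if grouping == "age":
        keys = np.where(dogs["age_months"] <= age_threshold_months, "juvenile", "adult")
    elif grouping == "sex":
        keys = dogs["dog_sex"].to_numpy()
    elif grouping == "region":
        keys = dogs["region"].to_numpy()
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    rows = []
    for g in dict.fromkeys(keys):
        sub = dogs[keys == g]
        n = len(sub)
        if n == 0:
            rows.append({"group": g, "k": 0, "n": 0, "skipped": True})
            continue
        k = int(sub["infested"].sum())
        ci = prevalence_ci(k, n)
        rows.append(
            {
                "group": g,
                "k": k,
                "n": n,
                "percent": ci["percent"],
                "lower": ci["lower"],
                "upper": ci["upper"],
                "skipped": False,
            }
        )
    return pd.DataFrame(rows).set_index("group")
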