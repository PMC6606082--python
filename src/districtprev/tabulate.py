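"""Survey-weighted cross-tabulation of first births by age bracket.

Reproduces the descriptive-table logic of adolescent first-birth reporting:
for women aged 20-29 at survey, the share whose first birth fell at <16,
16-17, 18-19 and <20 completed years, weighted by the sampling weight and
stratified by residence, education or wealth quintile.  The three
sub-brackets partition <20, so their shares are additive within every
stratum.  Point estimates only; no design-based variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

BRACKETS = ("lt16", "16to17", "18to19", "lt20")
_BOUNDS = {"lt16": (0, 16), "16to17": (16, 18), "18to19": (18, 20), "lt20": (0, 20)}
SUB_BRACKETS = ("lt16", "16to17", "18to19")

STRATIFIERS = {
    "total": None,
    "residence": "urban",
    "education": "education",
    "wealth_quintile": "wealth_quintile",
}


class UndefinedRatioError(ZeroDivisionError):
    pass


def classify_age_group(age_first_birth: float | None) -> str | None:
    """Map a completed-years age at first birth to its bracket label.

    Returns ``None`` for women with no birth or a first birth at >= 20 years.
    The fine brackets partition <20: 15 -> lt16, 16 -> 16to17, 19 -> 18to19.
    """
    if age_first_birth is None or (isinstance(age_first_birth, float) and np.isnan(age_first_birth)):
        return None
    if age_first_birth < 0:
        raise ValueError(f"negative age at first birth: {age_first_birth}")
    for label in SUB_BRACKETS:
        lo, hi = _BOUNDS[label]
        if lo <= age_first_birth < hi:
            return label
    return None


@dataclass
class PrevalenceTable:
    """Weighted proportions per (stratum level, bracket) with denominators."""

    stratifier: str
    proportions: pd.DataFrame  # index: level, columns: BRACKETS
    denominators: pd.Series  # weighted count per level
    empty_strata: list = field(default_factory=list)

    def proportion(self, level, bracket: str) -> float:
        return float(self.proportions.loc[level, bracket])

    def as_percent(self, decimals: int = 1) -> pd.DataFrame:
        return (self.proportions * 100).round(decimals)

    def to_csv(self, path) -> None:
        out = self.proportions.copy()
        out["weighted_n"] = self.denominators
        out.to_csv(path, lineterminator="\n")


def weighted_prevalence(dataset, stratifier: str = "total") -> PrevalenceTable:
    """Weighted share of women in each first-birth bracket, by stratum.

    For stratum s and bracket b the estimate is
    sum(w_i * 1[i in s, bracket_i = b]) / sum(w_i * 1[i in s]).
    Accepts a SurveyDataset or a records DataFrame.  Empty strata are
    reported as NaN and flagged, never as zero.
    """
    if stratifier not in STRATIFIERS:
        raise KeyError(f"unknown stratifier {stratifier!r}; one of {sorted(STRATIFIERS)}")
    df = dataset if isinstance(dataset, pd.DataFrame) else dataset.records_frame()
    if (df["weight"] <= 0).any():
        raise ValueError("sampling weights must be strictly positive")
    df = df.copy()
    df["bracket"] = [classify_age_group(a) for a in df["age_first_birth"]]

    if stratifier == "total":
        df["_stratum"] = "total"
        levels = ["total"]
    else:
        col = STRATIFIERS[stratifier]
        if stratifier == "residence":
            df["_stratum"] = np.where(df[col], "urban", "rural")
            levels = ["urban", "rural"]
        else:
            df["_stratum"] = df[col]
            levels = sorted(df["_stratum"].unique().tolist())

    rows, denoms, empty = {}, {}, []
    for level in levels:
        sub = df[df["_stratum"] == level]
        denom = sub["weight"].sum()
        denoms[level] = denom
        if denom == 0 or len(sub) == 0:
            empty.append(level)
            rows[level] = {b: np.nan for b in BRACKETS}
            continue
        shares = {}
        for b in SUB_BRACKETS:
            shares[b] = sub.loc[sub["bracket"] == b, "weight"].sum() / denom
        shares["lt20"] = shares["lt16"] + shares["16to17"] + shares["18to19"]
        rows[level] = shares
    props = pd.DataFrame.from_dict(rows, orient="index")[list(BRACKETS)].loc[levels]
    return PrevalenceTable(
        stratifier=stratifier,
        proportions=props,
        denominators=pd.Series(denoms).loc[levels],
        empty_strata=empty,
    )


def round_half_up(x: float, decimals: int = 1) -> float:
    """Display rounding with ties away from zero (2.25 -> 2.3)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def group_ratio(table: PrevalenceTable, numerator_level, denominator_level, bracket: str) -> float:
    """Prevalence ratio between two strata for one bracket, rounded half-up
    to one decimal for reporting (computed from unrounded proportions)."""
    if bracket not in BRACKETS:
        raise KeyError(f"unknown bracket {bracket!r}")
    num = table.proportion(numerator_level, bracket)
    den = table.proportion(denominator_level, bracket)
    if not np.isfinite(num) or not np.isfinite(den):
        raise UndefinedRatioError("ratio over an empty stratum is undefined")
    if den == 0:
        raise UndefinedRatioError(f"zero denominator prevalence in {denominator_level!r}/{bracket}")
    return round_half_up(num / den, 1)


def ratio_from_percentages(numerator_pct: float, denominator_pct: float) -> float:
    """Ratio of two printed percentage cells, reporting-rounded to 1 decimal."""
    if denominator_pct == 0:
        raise UndefinedRatioError("zero denominator percentage")
    return round_half_up(numerator_pct / denominator_pct, 1)
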