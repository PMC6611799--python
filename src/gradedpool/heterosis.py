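"""Heterosis-contribution arithmetic from per-line trait summaries.

A mapped locus's share of hybrid vigour is expressed by introgressing its
high allele into the inbred parent (a near-isogenic line, NIL) and asking
what fraction of the F1-minus-parent yield gap the NIL recovers:

    contribution rate = (Y_NIL - Y_parent) / (Y_F1 - Y_parent).

The rate is affine-invariant in the trait scale.  Line comparisons are
computed from summary statistics (mean, SD, n per line) under the one-way
layout: the pooled mean-squared error across all groups gives the standard
error of any pairwise mean difference, sqrt(MSE * (1/n_I + 1/n_J)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = ["TraitSummary", "ContributionResult", "contribution_rate",
           "pairwise_differences", "percent_change", "round_half_away"]


@dataclass(frozen=True)
class TraitSummary:
    """Per-line trait summary: name, sample size, mean, SD (trait units)."""

    line: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"{self.line}: need n >= 2")
        if self.sd < 0:
            raise ValueError(f"{self.line}: sd must be >= 0")


@dataclass(frozen=True)
class ContributionResult:
    rate: float          # dimensionless fraction
    y_f1: float
    y_parent: float
    y_nil: float

    @property
    def percent(self) -> float:
        """Rate as a percentage rounded to 1 decimal, half away from zero."""
        return round_half_away(100.0 * self.rate, 1)


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (not banker's rounding)."""
    factor = 10 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def contribution_rate(y_f1: float, y_parent: float, y_nil: float) -> ContributionResult:
    """Share of the F1-parent gap recovered by the NIL carrying the locus."""
    gap = y_f1 - y_parent
    if gap == 0:
        raise ZeroDivisionError(
            "contribution rate undefined: F1 and parent means are equal")
    return ContributionResult(rate=(y_nil - y_parent) / gap,
                              y_f1=y_f1, y_parent=y_parent, y_nil=y_nil)


def percent_change(mean_a: float, mean_b: float) -> float:
    """Percent change of a relative to baseline b: 100 (a - b) / b."""
    if mean_b == 0:
        raise ZeroDivisionError("percent change undefined for zero baseline")
    return 100.0 * (mean_a - mean_b) / mean_b


def pooled_mse(summaries: Sequence[TraitSummary]) -> float:
    """One-way-layout pooled error variance: sum (n_g - 1) sd_g^2 / sum (n_g - 1)."""
    num = sum((s.n - 1) * s.sd ** 2 for s in summaries)
    den = sum(s.n - 1 for s in summaries)
    return num / den


def pairwise_differences(summaries: Sequence[TraitSummary],
                         tukey_p: bool = False) -> pd.DataFrame:
    """All ordered pairwise mean differences with pooled-MSE standard errors.

    One row per ordered pair (I, J): difference mean_I - mean_J and
    SE = sqrt(MSE (1/n_I + 1/n_J)) with MSE pooled over all groups.  With
    ``tukey_p`` a studentized-range p-value is added; it is approximate for
    unequal n and is computed from summary statistics only.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two lines to compare")
    mse = pooled_mse(summaries)
    df_err = sum(s.n - 1 for s in summaries)
    k = len(summaries)
    rows = []
    for si in summaries:
        for sj in summaries:
            if si.line == sj.line:
                continue
            diff = si.mean - sj.mean
            se = math.sqrt(mse * (1.0 / si.n + 1.0 / sj.n))
            row = {"I": si.line, "J": sj.line, "difference": diff, "se": se}
            if tukey_p:
                from scipy.stats import studentized_range
                q = abs(diff) / (se / math.sqrt(2.0))
                row["tukey_p_approx"] = float(studentized_range.sf(q, k, df_err))
            rows.append(row)
    return pd.DataFrame(rows)


def read_summaries(path) -> list:
    """Read a line-summary TSV with columns line, n, mean, sd."""
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"line", "n", "mean", "sd"}
    if not needed.issubset(df.columns):
        raise ValueError(f"summary table must have columns {sorted(needed)}")
    return [TraitSummary(line=str(r.line), n=int(r.n), mean=float(r.mean), sd=float(r.sd))
            for r in df.itertuples(index=False)]
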