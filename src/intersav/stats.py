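"""Enrichment statistics over structural regions and energy classes.

The central quantity is the region odds ratio

    OR_ij = (x_i / (1 - x_i)) / (x_j / (1 - x_j)),

where ``x_i`` is the probability of observing a variant in region *i*
(observed count over residue count).  Confidence intervals use the
Woolf log-OR normal approximation with standard error
``sqrt(1/a + 1/b + 1/c + 1/d)``; p-values come from the Pearson chi-square
2x2 test without continuity correction; multiple comparisons over the
six region pairs are Bonferroni-corrected.  Observed-versus-expected
comparisons distribute the grand variant count proportionally to the
regions' residue counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

#: the six pairwise region contrasts reported per variant category
REGION_PAIRS = (
    ("buried", "surface"),
    ("core", "buried"),
    ("core", "rim"),
    ("core", "surface"),
    ("rim", "surface"),
    ("rim", "buried"),
)


@dataclass
class ContingencyTable:
    """Residue totals and observed variant counts per group (region or
    energy class) for one variant category."""

    category: str
    totals: dict[str, int]
    observed: dict[str, int]

    def __post_init__(self) -> None:
        if set(self.totals) != set(self.observed):
            raise ValueError("totals and observed must cover the same groups")
        for g in self.totals:
            if self.observed[g] > self.totals[g]:
                raise ValueError(f"observed > total in group {g!r}")

    @property
    def grand_total(self) -> int:
        return sum(self.totals.values())

    @property
    def grand_observed(self) -> int:
        return sum(self.observed.values())


@dataclass(frozen=True)
class OddsRatioResult:
    comparison: str
    or_value: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_adjusted: float | None = None
    zero_cell_corrected: bool = False


def odds_ratio(
    obs_i: int, n_i: int, obs_j: int, n_j: int,
    comparison: str = "",
    conf_level: float = 0.95,
) -> OddsRatioResult:
    """Odds ratio of observing a variant in region *i* versus region *j*.

    Zero cells trigger the Haldane-Anscombe 0.5 correction (flagged in
    the result); the p-value is always computed on the uncorrected
    table.
    """
    if min(obs_i, obs_j) < 0 or min(n_i, n_j) <= 0:
        raise ValueError("counts must be non-negative with positive totals")
    a, b = obs_i, n_i - obs_i
    c, d = obs_j, n_j - obs_j
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (v + 0.5 for v in (a, b, c, d)) if corrected else (a, b, c, d)
    or_value = (aa / bb) / (cc / dd)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = sps.norm.ppf(0.5 + conf_level / 2)
    log_or = math.log(or_value)
    ci_low = math.exp(log_or - z * se)
    ci_high = math.exp(log_or + z * se)
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum(axis=0).min() > 0 and table.sum(axis=1).min() > 0:
        _, p_raw, _, _ = sps.chi2_contingency(table, correction=False)
    else:
        p_raw = 1.0
    return OddsRatioResult(
        comparison=comparison,
        or_value=or_value,
        ci_low=ci_low,
        ci_high=ci_high,
        p_raw=float(p_raw),
        zero_cell_corrected=corrected,
    )


def woolf_se(obs_i: int, n_i: int, obs_j: int, n_j: int) -> float:
    """Standard error of the log odds ratio."""
    a, b, c, d = obs_i, n_i - obs_i, obs_j, n_j - obs_j
    return math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)


def expected_counts(table: ContingencyTable) -> pd.DataFrame:
    """Expected counts if variants followed the residue composition.

    expected_g = grand_observed * total_g / grand_total; one row per
    group with observed, expected and O/E.
    """
    if table.grand_total <= 0:
        raise ValueError("grand total must be positive")
    rows = []
    for g in table.totals:
        exp = table.grand_observed * table.totals[g] / table.grand_total
        rows.append({
            "group": g,
            "total_residues": table.totals[g],
            "observed": table.observed[g],
            "expected": exp,
            "o_over_e": table.observed[g] / exp if exp > 0 else float("nan"),
        })
    return pd.DataFrame(rows)


def chisq_obs_vs_expected(observed, expected) -> tuple[float, float]:
    """Pearson goodness-of-fit statistic sum (O-E)^2/E with
    df = len - 1 and its upper-tail p-value."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("length mismatch between observed and expected")
    if (expected <= 0).any():
        raise ValueError("expected counts must be positive")
    stat = float(((observed - expected) ** 2 / expected).sum())
    df = observed.size - 1
    p = float(sps.chi2.sf(stat, df)) if df > 0 else 1.0
    return stat, p


def bonferroni(p_values, m: int) -> list[float]:
    """min(1, p * m) for each raw p-value; ``m`` >= number of tests."""
    p_values = list(p_values)
    if m < len(p_values):
        raise ValueError("m must be at least the number of tests")
    out = []
    for p in p_values:
        if not 0 <= p <= 1:
            raise ValueError(f"p-value outside [0, 1]: {p}")
        out.append(min(1.0, p * m))
    return out


def region_pair_report(
    table: ContingencyTable,
    pairs: tuple = REGION_PAIRS,
    m: int | None = None,
) -> pd.DataFrame:
    """Odds ratios with CIs and Bonferroni-adjusted p-values for the
    standard region contrasts of one variant category."""
    m = len(pairs) if m is None else m
    results = [
        odds_ratio(
            table.observed[i], table.totals[i],
            table.observed[j], table.totals[j],
            comparison=f"{i} vs {j}",
        )
        for i, j in pairs
    ]
    adj = bonferroni([r.p_raw for r in results], m)
    return pd.DataFrame([
        {
            "comparison": r.comparison,
            "odds_ratio": r.or_value,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p_raw": r.p_raw,
            "p_adjusted": a,
            "zero_cell_corrected": r.zero_cell_corrected,
        }
        for r, a in zip(results, adj)
    ])


def per_aa_mutability(
    sav_frame: pd.DataFrame,
    composition: pd.DataFrame,
) -> pd.DataFrame:
    """Variant frequency per amino acid and region, per category.

    ``sav_frame`` needs columns wt_aa, region, category; ``composition``
    needs columns aa, region, n_residues.  The frequency is the variant
    count divided by the residue count of that amino acid in that
    region; zero-residue denominators yield NaN.
    """
    required = {"wt_aa", "region", "category"}
    if not required <= set(sav_frame.columns):
        raise ValueError(f"sav_frame needs columns {sorted(required)}")
    counts = (
        sav_frame.groupby(["wt_aa", "region", "category"])
        .size().rename("n_savs").reset_index()
    )
    comp = composition.rename(columns={"aa": "wt_aa"})
    out = counts.merge(comp, on=["wt_aa", "region"], how="left")
    out["frequency"] = np.where(
        out["n_residues"] > 0, out["n_savs"] / out["n_residues"], np.nan
    )
    return out


def roc_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties get
    half credit.  Labels are binary with 1 = positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc)
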