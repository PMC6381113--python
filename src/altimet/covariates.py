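"""Physiological covariate statistics: paired tests and normality-gated
correlation of metabolite changes against covariate changes.

Per-subject deltas (top minus baseline location) of a feature are
correlated with deltas of SpO2 or body weight: Pearson when both delta
distributions pass the D'Agostino-Pearson normality test, Spearman
otherwise; correlations significant at ``alpha`` are followed up with an
ordinary least-squares regression.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedDelta",
    "CorrelationResult",
    "paired_deltas",
    "dagostino_pearson",
    "wilcoxon_matched_pairs",
    "correlate_deltas",
    "followup_regression",
]

MIN_N = 20  # smallest sample for the normality test / correlation gate


@dataclass
class PairedDelta:
    """Per-subject delta (top - baseline) for one variable."""

    name: str
    deltas: pd.Series  # indexed by subject

    @property
    def n(self) -> int:
        return len(self.deltas)


def paired_deltas(values: pd.DataFrame, name: str, baseline: str = "LDN",
                  top: str = "EBC", value_col: str | None = None) -> PairedDelta:
    """Build a :class:`PairedDelta` from a long table.

    ``values`` needs columns subject, location and the value column
    (default: ``name``).  Only subjects observed at both locations
    contribute.
    """
    col = value_col or name
    wide = values.pivot_table(index="subject", columns="location", values=col,
                              aggfunc="first")
    for loc in (baseline, top):
        if loc not in wide.columns:
            raise ValueError(f"location {loc!r} absent")
    ok = wide[[baseline, top]].notna().all(axis=1)
    return PairedDelta(name, wide.loc[ok, top] - wide.loc[ok, baseline])


def dagostino_pearson(sample: np.ndarray) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus K2 normality test.

    Combines the z-scores of sample skewness and kurtosis into a
    statistic referred to chi-square with 2 df.  Undefined at small n;
    requires n >= 20.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size < MIN_N:
        raise ValueError(f"D'Agostino-Pearson needs n >= {MIN_N}")
    k2, p = stats.normaltest(sample)
    return float(k2), float(p)


def wilcoxon_matched_pairs(before: np.ndarray, after: np.ndarray,
                           alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped (Wilcoxon convention).  The null
    distribution is exact (full enumeration) for n <= 25 without ties,
    otherwise a normal approximation with continuity correction.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired vectors must have equal length")
    d = after - before
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, alternative=alternative, method=method,
                         correction=(method == "approx"))
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationResult:
    feature: str
    covariate: str
    method: str          # "pearson" | "spearman"
    coefficient: float
    p_value: float
    n: int


def correlate_deltas(delta_feature: PairedDelta, delta_covariate: PairedDelta,
                     normality_alpha: float = 0.05) -> CorrelationResult:
    """Correlate two per-subject delta series with a normality gate.

    Subjects are intersected; Pearson is used when both delta
    distributions pass the D'Agostino-Pearson test at
    ``normality_alpha``, Spearman rank correlation (two-tailed)
    otherwise.
    """
    common = delta_feature.deltas.index.intersection(delta_covariate.deltas.index)
    if len(common) < MIN_N:
        raise ValueError(f"need >= {MIN_N} paired subjects, got {len(common)}")
    a = delta_feature.deltas.loc[common].to_numpy(dtype=float)
    b = delta_covariate.deltas.loc[common].to_numpy(dtype=float)
    _, pa = dagostino_pearson(a)
    _, pb = dagostino_pearson(b)
    if pa > normality_alpha and pb > normality_alpha:
        coef, p = stats.pearsonr(a, b)
        method = "pearson"
    else:
        coef, p = stats.spearmanr(a, b)
        method = "spearman"
    return CorrelationResult(delta_feature.name, delta_covariate.name, method,
                             float(coef), float(p), len(common))


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_value: float
    p_value: float


def followup_regression(delta_feature: PairedDelta, delta_covariate: PairedDelta,
                        correlation: CorrelationResult, alpha: float = 0.01
                        ) -> LinearFit | None:
    """OLS fit of feature delta on covariate delta, only for significant
    correlations (p < ``alpha``); returns None otherwise."""
    if correlation.p_value >= alpha:
        return None
    common = delta_feature.deltas.index.intersection(delta_covariate.deltas.index)
    res = stats.linregress(delta_covariate.deltas.loc[common].to_numpy(dtype=float),
                           delta_feature.deltas.loc[common].to_numpy(dtype=float))
    return LinearFit(float(res.slope), float(res.intercept), float(res.rvalue),
                     float(res.pvalue))
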