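"""Absolute-change summaries: % changes, baseline-corrected ratios and
the final results table.

Spectral intensities carry no absolute concentration, so changes are
expressed in arbitrary units (AU): the paired per-subject % change
between the baseline (LDN) and top (EBC) locations, its median, and the
per-subject top/baseline ratio (1 = no change).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import LongitudinalDataset

__all__ = [
    "pct_change",
    "median_pct_change",
    "ldn_ratio",
    "assemble_results",
    "PairedChange",
    "RatioSummary",
]


def pct_change(from_value: float, to_value: float) -> float:
    """Percent change 100*(to-from)/from, reported to one decimal."""
    if from_value == 0:
        raise ValueError("zero baseline value")
    return round(100.0 * (to_value - from_value) / from_value, 1)


@dataclass
class PairedChange:
    median_pct: float
    n_pairs: int
    n_excluded: int


def _paired_values(data: LongitudinalDataset, feature: str,
                   baseline: str, top: str) -> pd.DataFrame:
    meta = data.metadata
    vals = data.values[feature]
    frame = pd.DataFrame({"subject": meta["subject"].to_numpy(),
                          "location": meta["location"].to_numpy(),
                          "value": vals.to_numpy(dtype=float)})
    wide = frame.pivot_table(index="subject", columns="location", values="value",
                             aggfunc="first")
    for loc in (baseline, top):
        if loc not in wide.columns:
            raise ValueError(f"location {loc!r} absent from dataset")
    return wide[[baseline, top]]


def median_pct_change(data: LongitudinalDataset, feature: str,
                      baseline: str = "LDN", top: str = "EBC") -> PairedChange:
    """Median over subjects of the paired % change baseline -> top.

    Subjects missing either visit (or with a zero baseline) are excluded
    and counted.
    """
    wide = _paired_values(data, feature, baseline, top)
    ok = wide.notna().all(axis=1) & (wide[baseline] != 0)
    if not ok.any():
        raise ValueError(f"{feature}: no subjects with both visits observed")
    pct = 100.0 * (wide.loc[ok, top] - wide.loc[ok, baseline]) / wide.loc[ok, baseline]
    return PairedChange(round(float(pct.median()), 1), int(ok.sum()),
                        int((~ok).sum()))


@dataclass
class RatioSummary:
    ratios: pd.Series      # per-subject top/baseline
    median: float
    iqr: tuple[float, float]
    n_excluded: int


def ldn_ratio(data: LongitudinalDataset, feature: str, baseline: str = "LDN",
              top: str = "EBC") -> RatioSummary:
    """Per-subject top/baseline abundance ratios (1 = no change).

    Summarized as the median and interquartile range; subjects with a
    missing visit or zero baseline are excluded and counted.
    """
    wide = _paired_values(data, feature, baseline, top)
    ok = wide.notna().all(axis=1) & (wide[baseline] != 0)
    if not ok.any():
        raise ValueError(f"{feature}: no subjects with both visits observed")
    ratios = wide.loc[ok, top] / wide.loc[ok, baseline]
    q1, q3 = np.percentile(ratios, [25, 75])
    return RatioSummary(ratios, float(ratios.median()), (float(q1), float(q3)),
                        int((~ok).sum()))


def assemble_results(decisions: pd.DataFrame, data: LongitudinalDataset,
                     baseline: str = "LDN", top: str = "EBC") -> pd.DataFrame:
    """One row per changer: abundances, % change (both conventions), slope.

    ``median_pct_change`` is the median of per-subject paired changes;
    ``pct_change_of_medians`` is the % change between the printed
    baseline/top abundance columns (which are per-location medians).
    The two generally differ on noisy data and both are reported.  Rows
    are sorted by |median % change| descending within direction
    (increasing first).
    """
    changers = decisions[decisions["changer"] == True]  # noqa: E712 (NA-safe)
    rows = []
    meta = data.metadata
    for _, dec in changers.iterrows():
        feat = dec["feature"]
        if feat not in data.values.columns:
            raise ValueError(f"changer {feat!r} missing from abundance data")
        vals = data.values[feat]
        base_med = float(vals[meta["location"].to_numpy() == baseline].median())
        top_med = float(vals[meta["location"].to_numpy() == top].median())
        paired = median_pct_change(data, feat, baseline, top)
        rows.append({
            "feature": feat,
            "direction": dec["direction"],
            f"{baseline}_abundance": base_med,
            f"{top}_abundance": top_med,
            "median_pct_change": paired.median_pct,
            "pct_change_of_medians": pct_change(base_med, top_med)
            if base_med != 0 else np.nan,
            "slope_au_per_km": dec["slope_au_per_km"],
            "n_pairs": paired.n_pairs,
        })
    table = pd.DataFrame(rows, columns=[
        "feature", "direction", f"{baseline}_abundance", f"{top}_abundance",
        "median_pct_change", "pct_change_of_medians", "slope_au_per_km",
        "n_pairs"])
    if len(table):
        table["_dir_order"] = (table["direction"] != "Increasing").astype(int)
        table = table.sort_values(
            ["_dir_order", "median_pct_change"],
            key=lambda c: c.abs() if c.name == "median_pct_change" else c,
            ascending=[True, False]).drop(columns="_dir_order")
    return table.reset_index(drop=True)
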