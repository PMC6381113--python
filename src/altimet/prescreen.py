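"""Stage-1 frequentist screen: cheap hierarchical slope estimates.

Full Bayesian fits are computationally expensive, so candidate features
are first selected with a two-stage estimator: an ordinary
least-squares slope per subject, averaged (unweighted) into a
per-feature mean slope.  Features whose mean slope sits more than 1.96
population SDs from the across-feature mean are carried forward.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import LongitudinalDataset

__all__ = ["SlopeScreen", "simple_hier_fit", "select_candidates"]


@dataclass
class SlopeScreen:
    """Selection outcome: per-feature slope, z-score and flag."""

    table: pd.DataFrame        # feature, mean_slope, n_subjects, z_score, selected
    population_mean: float
    population_sd: float
    threshold: float

    @property
    def selected(self) -> list[str]:
        return self.table.loc[self.table["selected"], "feature"].tolist()


def simple_hier_fit(data: LongitudinalDataset, min_subjects: int = 3
                    ) -> pd.DataFrame:
    """Per-feature mean of per-subject OLS slopes (abundance on altitude km).

    Subjects with fewer than two distinct altitudes for a feature are
    skipped (counted in ``n_skipped``); features with fewer than
    ``min_subjects`` contributing subjects are flagged unestimable.
    """
    meta = data.metadata
    subjects = meta["subject"].to_numpy()
    x = meta["altitude_km"].to_numpy(dtype=float)
    Y = data.values.to_numpy(dtype=float)

    uniq, codes = np.unique(subjects, return_inverse=True)
    order = np.argsort(codes, kind="stable")
    xs = x[order]
    Ys = Y[order]
    cs = codes[order]
    starts = np.searchsorted(cs, np.arange(uniq.size))
    counts = np.diff(np.append(starts, xs.size)).astype(float)

    obs = ~np.isnan(Ys)
    Y0 = np.where(obs, Ys, 0.0)
    n = np.add.reduceat(obs.astype(float), starts, axis=0)
    sx = np.add.reduceat(np.where(obs, xs[:, None], 0.0), starts, axis=0)
    sxx = np.add.reduceat(np.where(obs, xs[:, None] ** 2, 0.0), starts, axis=0)
    sy = np.add.reduceat(Y0, starts, axis=0)
    sxy = np.add.reduceat(Y0 * xs[:, None], starts, axis=0)
    del counts
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = sxx - sx * sx / np.where(n > 0, n, 1.0)
        slopes = (sxy - sx * sy / np.where(n > 0, n, 1.0)) / denom
    # a subject contributes only with >= 2 observations at distinct altitudes
    usable = (n >= 2) & (denom > 1e-12)
    slopes = np.where(usable, slopes, np.nan)

    n_sub = usable.sum(axis=0)
    mean_slope = np.nanmean(np.where(usable, slopes, np.nan), axis=0)
    return pd.DataFrame({
        "feature": data.features,
        "mean_slope": mean_slope,
        "n_subjects": n_sub,
        "n_skipped": uniq.size - n_sub,
        "estimable": n_sub >= min_subjects,
    })


def select_candidates(slopes: pd.DataFrame, threshold: float = 1.96,
                      mode: str = "population") -> SlopeScreen:
    """Flag features whose mean slope is an outlier across the population.

    ``mode='population'`` (default): selected iff
    ``|slope - mean(slopes)| > threshold * SD(slopes)`` over estimable
    features.  ``mode='se'`` is the alternative reading where each slope
    is compared with ``threshold`` times its own standard error across
    subjects (requires a ``slope_se`` column).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    est = slopes[slopes["estimable"]]
    if len(est) < 3:
        raise ValueError("need at least 3 estimable features to screen")
    values = est["mean_slope"].to_numpy(dtype=float)
    pop_mean = float(values.mean())
    pop_sd = float(values.std(ddof=1))
    table = slopes.copy()
    if mode == "population":
        if pop_sd == 0:
            z = np.zeros(len(table))
        else:
            z = (table["mean_slope"].to_numpy(dtype=float) - pop_mean) / pop_sd
        table["z_score"] = z
        table["selected"] = table["estimable"] & (np.abs(z) > threshold) \
            & (pop_sd > 0)
    elif mode == "se":
        if "slope_se" not in table.columns:
            raise ValueError("mode='se' requires a slope_se column")
        z = table["mean_slope"] / table["slope_se"]
        table["z_score"] = z
        table["selected"] = table["estimable"] & (np.abs(z) > threshold)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SlopeScreen(table, pop_mean, pop_sd, threshold)
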