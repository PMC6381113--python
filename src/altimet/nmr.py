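"""NMR spectral preprocessing: region exclusion, binning, normalization,
scaling and batch-bias removal.

The chain mirrors standard 1H-NMR metabolomics practice for binned
spectra: keep the aliphatic region, reduce full-resolution points to 10:1
bins, remove per-sample dilution with probabilistic quotient
normalization (PQN), Pareto-scale the bins, and strip residual
acquisition-batch structure with an SVD-based bias filter.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.linalg import svds

__all__ = [
    "SpectrumSet",
    "BinnedMatrix",
    "exclude_region",
    "bin_spectra",
    "pqn_normalize",
    "pareto_scale",
    "remove_batch_bias",
]


@dataclass
class SpectrumSet:
    """Full-resolution spectra on a shared, decreasing ppm axis."""

    ppm_axis: np.ndarray
    intensities: np.ndarray  # samples x points
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.sample_ids), self.ppm_axis.size):
            raise ValueError("intensity matrix shape does not match axis/sample ids")
        if np.isnan(self.intensities).any():
            raise ValueError("missing intensities are not allowed")


@dataclass
class BinnedMatrix:
    """Binned sample x feature matrix with ppm bin centers."""

    bin_centers: np.ndarray
    values: pd.DataFrame  # samples x bins, index = sample ids
    bin_ratio: int = 1

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


def exclude_region(spectra: SpectrumSet, window: tuple[float, float]) -> SpectrumSet:
    """Retain only points inside ``window`` (ppm interval), order preserved.

    Used to drop the noisy aromatic region and keep the aliphatic one.
    """
    lo, hi = min(window), max(window)
    keep = (spectra.ppm_axis >= lo) & (spectra.ppm_axis <= hi)
    if not keep.any():
        raise ValueError(f"retained window {window} does not overlap the ppm axis")
    return SpectrumSet(spectra.ppm_axis[keep], spectra.intensities[:, keep],
                       list(spectra.sample_ids))


def bin_spectra(spectra: SpectrumSet, ratio: int = 10) -> BinnedMatrix:
    """Reduce consecutive non-overlapping blocks of ``ratio`` points to their mean.

    A trailing remainder shorter than ``ratio`` is dropped.  Bin center =
    mean ppm of the block.  The default 10:1 ratio turns a 12,030-point
    aliphatic region into 1203 bins.
    """
    if ratio < 1:
        raise ValueError("bin ratio must be >= 1")
    n_points = spectra.ppm_axis.size
    if n_points < ratio:
        raise ValueError("fewer points than the bin ratio")
    n_bins = n_points // ratio
    used = n_bins * ratio
    vals = spectra.intensities[:, :used].reshape(len(spectra.sample_ids), n_bins, ratio)
    centers = spectra.ppm_axis[:used].reshape(n_bins, ratio).mean(axis=1)
    frame = pd.DataFrame(vals.mean(axis=2), index=pd.Index(spectra.sample_ids,
                                                           name="sample"),
                         columns=[f"ppm_{c:.4f}" for c in centers])
    return BinnedMatrix(centers, frame, ratio)


def pqn_normalize(binned: BinnedMatrix, target_total: float | None = None
                  ) -> tuple[BinnedMatrix, pd.Series]:
    """Probabilistic quotient normalization against the median spectrum.

    Each sample is first integral-normalized (scaled to a common total:
    ``target_total`` if given, otherwise the median of the input sample
    totals), then divided by the median of its pointwise ratios to the
    median spectrum of the integral-normalized data.  Returns the
    normalized matrix and the composite per-sample factor (integral x
    quotient) that was divided out.

    With a fixed ``target_total`` the output is exactly invariant to
    per-sample positive dilution; with the data-driven default the
    output additionally preserves the input scale when samples are
    homogeneous.
    """
    X = binned.values.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PQN needs at least 2 samples")
    totals = X.sum(axis=1)
    zero = np.where(totals == 0)[0]
    if zero.size:
        raise ValueError(f"all-zero sample(s): {[binned.sample_ids[i] for i in zero]}")
    anchor = float(np.median(totals)) if target_total is None else float(target_total)
    integral = totals / anchor
    X1 = X / integral[:, None]
    reference = np.median(X1, axis=0)
    usable = reference > 0
    if not usable.any():
        raise ValueError("reference spectrum has no strictly positive points")
    quotients = np.median(X1[:, usable] / reference[usable], axis=1)
    X2 = X1 / quotients[:, None]
    factors = pd.Series(integral * quotients, index=binned.values.index,
                        name="pqn_factor")
    frame = pd.DataFrame(X2, index=binned.values.index, columns=binned.values.columns)
    return BinnedMatrix(binned.bin_centers, frame, binned.bin_ratio), factors


def pareto_scale(binned: BinnedMatrix) -> BinnedMatrix:
    """Mean-center each bin and divide by the square root of its SD.

    A compromise between unit-variance and no scaling; zero-variance bins
    map to all-zero columns rather than dividing by zero.
    """
    X = binned.values.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("Pareto scaling needs at least 2 samples")
    centered = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    scale = np.sqrt(sd, out=np.ones_like(sd), where=sd > 0)
    out = np.where(sd > 0, centered / scale, 0.0)
    frame = pd.DataFrame(out, index=binned.values.index, columns=binned.values.columns)
    return BinnedMatrix(binned.bin_centers, frame, binned.bin_ratio)


def _known_effects_residuals(X: np.ndarray, altitude: np.ndarray,
                             subjects: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Residuals of every bin after projecting out the preserved signal.

    The preserved design is intercept + altitude (optionally + subject
    indicators).  Subject indicators are *not* preserved by default:
    batch membership is constant within subject, so preserving subject
    effects would shield the batch bias from removal.
    """
    cols = [np.ones_like(altitude), altitude]
    if subjects is not None:
        uniq, idx = np.unique(subjects, return_inverse=True)
        dummies = np.zeros((altitude.size, uniq.size))
        dummies[np.arange(altitude.size), idx] = 1.0
        cols = [dummies, altitude[:, None]]
        design = np.hstack(cols)
    else:
        design = np.column_stack(cols)
    q, _ = np.linalg.qr(design)
    fitted = q @ (q.T @ X)
    return fitted, X - fitted


def remove_batch_bias(binned: BinnedMatrix, metadata: pd.DataFrame,
                      alpha: float = 0.05, n_permutations: int = 24,
                      preserve_subjects: bool = False, seed: int = 0
                      ) -> tuple[BinnedMatrix, dict]:
    """SVD-based removal of systematic (batch) bias trends.

    Per bin, the known-effects model (altitude trend) is fitted and
    residuals formed; the residual matrix is decomposed by SVD and the
    leading components whose singular values exceed a permutation-null
    threshold (entries of each residual column independently shuffled
    across samples, significance level ``alpha``) are subtracted.  The
    report carries each retained component's residual-variance fraction.
    """
    meta = metadata.set_index("sample").loc[binned.sample_ids]
    batches = meta["batch"].to_numpy()
    uniq_batches, batch_counts = np.unique(batches, return_counts=True)
    if uniq_batches.size < 2 or batch_counts.min() < 2:
        warnings.warn("fewer than 2 batches with 2 samples each; "
                      "bias removal is a no-op", stacklevel=2)
        return binned, {"n_components": 0, "variance_fractions": [],
                        "threshold": np.nan}

    X = binned.values.to_numpy(dtype=float)
    altitude = meta["altitude_km"].to_numpy(dtype=float)
    subjects = meta["subject"].to_numpy() if preserve_subjects else None
    fitted, resid = _known_effects_residuals(X, altitude, subjects)

    u, s, vt = np.linalg.svd(resid, full_matrices=False)
    total_ss = float(np.sum(s**2))

    rng = np.random.default_rng(seed)
    null_top = np.empty(n_permutations)
    for p in range(n_permutations):
        perm = rng.permuted(resid, axis=0)  # break row structure per column
        k = 1 if min(perm.shape) > 2 else min(perm.shape) - 1
        null_top[p] = svds(perm, k=max(k, 1), return_singular_vectors=False).max()
    threshold = float(np.quantile(null_top, 1.0 - alpha))

    n_keep = 0
    while n_keep < s.size and s[n_keep] > threshold:
        n_keep += 1
    cleaned = resid.copy()
    if n_keep:
        cleaned -= (u[:, :n_keep] * s[:n_keep]) @ vt[:n_keep]
    out = fitted + cleaned
    report = {
        "n_components": n_keep,
        "variance_fractions": [float(s[k] ** 2 / total_ss) for k in range(n_keep)],
        "singular_values": s[: max(n_keep, 3)].tolist(),
        "threshold": threshold,
    }
    frame = pd.DataFrame(out, index=binned.values.index, columns=binned.values.columns)
    return BinnedMatrix(binned.bin_centers, frame, binned.bin_ratio), report
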