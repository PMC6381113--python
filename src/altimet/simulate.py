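"""Synthetic cohorts, spectra, lipid scans and covariates.

The generators emulate the statistical structure of a longitudinal
high-altitude plasma study: ~198 subjects sampled at five altitude
locations (75 m baseline up to 5,300 m), per-subject linear altitude
responses with normally distributed random intercepts/slopes,
t-distributed residuals, a two-batch spectral acquisition bias, and
missing visits.  Every generated dataset carries its true parameters so
downstream stages can be tested by parameter recovery.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import LongitudinalDataset

__all__ = [
    "StudyDesign",
    "FeatureSpec",
    "BatchDesign",
    "PeakLayout",
    "LipidSpecies",
    "generate_cohort",
    "generate_feature_matrix",
    "generate_spectra",
    "generate_lipid_scans",
    "generate_covariates",
]

#: (name, altitude in km, attendance) for the five study locations.  The
#: per-location attendance split keeps every count in the observed 182-198
#: range and sums to the 965 samples of the full study.
DEFAULT_LOCATIONS = (
    ("LDN", 0.075, 198),
    ("KTM", 1.300, 198),
    ("NAM", 3.500, 197),
    ("PHE", 4.250, 190),
    ("EBC", 5.300, 182),
)


class InvalidDesignError(ValueError):
    """A study design violates its invariants."""


@dataclass(frozen=True)
class StudyDesign:
    """Cohort layout: locations with altitudes and attendance counts.

    The first location is the baseline; its visit is never dropped unless
    ``allow_baseline_dropout`` is set.
    """

    locations: tuple[tuple[str, float, int], ...] = DEFAULT_LOCATIONS
    n_subjects: int = 198
    seed: int = 0
    allow_baseline_dropout: bool = False

    def __post_init__(self) -> None:
        alts = [a for _, a, _ in self.locations]
        if any(b <= a for a, b in zip(alts, alts[1:])):
            raise InvalidDesignError("altitudes must be strictly increasing")
        for name, _, count in self.locations:
            if count > self.n_subjects:
                raise InvalidDesignError(
                    f"attendance at {name} ({count}) exceeds n_subjects ({self.n_subjects})"
                )


@dataclass(frozen=True)
class FeatureSpec:
    """Generative counterpart of one feature's hierarchical parameters.

    ``mu0``/``sigma0`` are the group mean and SD of per-subject intercepts,
    ``mu1``/``sigma1`` the same for slopes (z-units per standardized
    altitude), ``sigma`` the residual scale and ``nu`` the t-distribution
    normality parameter (larger = closer to Gaussian residuals).
    """

    name: str
    mu0: float = 0.0
    sigma0: float = 0.3
    mu1: float = 0.0
    sigma1: float = 0.15
    sigma: float = 0.3
    nu: float = 5.0

    def __post_init__(self) -> None:
        if min(self.sigma0, self.sigma1, self.sigma) <= 0:
            raise InvalidDesignError(f"{self.name}: scale parameters must be positive")
        if self.nu <= 1:
            raise InvalidDesignError(f"{self.name}: nu must exceed 1")


@dataclass(frozen=True)
class BatchDesign:
    """Two-batch acquisition bias: additive smooth trend, constant within subject."""

    n_batches: int = 2
    bias_amplitude: float = 0.0
    bias_profile: np.ndarray | None = None  # over spectral points; default smooth sinusoid

    def profile(self, n_points: int) -> np.ndarray:
        if self.bias_profile is not None:
            prof = np.asarray(self.bias_profile, dtype=float)
            if prof.size != n_points:
                raise InvalidDesignError("bias_profile length does not match spectral axis")
            return prof
        t = np.linspace(0.0, 1.0, n_points)
        return np.sin(2 * np.pi * t) * np.exp(-((t - 0.35) ** 2) / 0.08)


def generate_cohort(design: StudyDesign = StudyDesign()) -> pd.DataFrame:
    """Generate per-sample metadata: one row per attended (subject, location).

    Attendance shortfalls are drawn without replacement among subjects,
    uniformly per location; baseline visits are kept complete by default.
    Each subject is assigned to one of two acquisition batches (all of a
    subject's samples were run together), balanced across the cohort.
    """
    rng = np.random.default_rng(design.seed)
    subjects = np.array([f"sub{idx:03d}" for idx in range(design.n_subjects)])
    batch_of = dict(zip(subjects, rng.permuted(
        np.where(np.arange(design.n_subjects) % 2 == 0, "B1", "B2"))))

    rows = []
    for loc_idx, (name, altitude, count) in enumerate(design.locations):
        if loc_idx == 0 and not design.allow_baseline_dropout:
            attending = subjects if count == design.n_subjects else subjects[
                np.sort(rng.choice(design.n_subjects, size=count, replace=False))]
        else:
            attending = subjects[np.sort(rng.choice(design.n_subjects, size=count,
                                                    replace=False))]
        for sub in attending:
            rows.append((f"{sub}_{name}", sub, name, altitude, batch_of[sub]))
    return pd.DataFrame(rows, columns=["sample", "subject", "location",
                                       "altitude_km", "batch"])


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def generate_feature_matrix(metadata: pd.DataFrame, specs: list[FeatureSpec],
                            seed: int = 0) -> LongitudinalDataset:
    """Simulate abundances: y = b0_s + b1_s * x* + sigma * t(nu) per feature.

    x* is the standardized altitude over samples.  The per-subject
    intercepts/slopes are drawn from the group normals of each
    :class:`FeatureSpec`.  True parameters are attached as ``.truth`` for
    recovery tests.
    """
    if metadata.groupby("subject").size().min() < 1:
        raise InvalidDesignError("every subject needs at least one row")
    rng = np.random.default_rng(seed)
    subjects = metadata["subject"].to_numpy()
    uniq, subj_idx = np.unique(subjects, return_inverse=True)
    n_sub = uniq.size
    x_star = _standardize(metadata["altitude_km"].to_numpy(dtype=float))

    values = {}
    truth: dict = {"x_mean": metadata["altitude_km"].mean(),
                   "x_sd": metadata["altitude_km"].std(ddof=1)}
    for spec in specs:
        b0 = rng.normal(spec.mu0, spec.sigma0, size=n_sub)
        b1 = rng.normal(spec.mu1, spec.sigma1, size=n_sub)
        resid = rng.standard_t(spec.nu, size=len(metadata)) * spec.sigma
        values[spec.name] = b0[subj_idx] + b1[subj_idx] * x_star[:] + resid
        truth[spec.name] = {"spec": spec, "beta0": dict(zip(uniq, b0)),
                            "beta1": dict(zip(uniq, b1))}
    frame = pd.DataFrame(values, index=pd.Index(metadata["sample"], name="sample"))
    return LongitudinalDataset(metadata.reset_index(drop=True), frame, truth)


@dataclass(frozen=True)
class PeakLayout:
    """Peak positions/shapes for the synthetic NMR-like spectra.

    Amplitude of peak ``p`` for a sample at altitude ``a`` is
    ``base_amplitudes[p] + altitude_slopes[p] * a`` (clipped at 0).
    """

    centers: np.ndarray
    widths: np.ndarray
    base_amplitudes: np.ndarray
    altitude_slopes: np.ndarray
    shape: str = "lorentzian"
    ppm_window: tuple[float, float] = (0.5, 4.51)
    n_points: int = 12030

    @staticmethod
    def default(n_peaks: int = 24, seed: int = 7, n_points: int = 12030,
                ppm_window: tuple[float, float] = (0.5, 4.51)) -> "PeakLayout":
        rng = np.random.default_rng(seed)
        lo, hi = ppm_window
        centers = rng.uniform(lo + 0.1, hi - 0.1, size=n_peaks)
        widths = rng.uniform(0.004, 0.02, size=n_peaks)
        base = rng.uniform(0.4, 2.0, size=n_peaks)
        # a handful of altitude-responsive peaks, the rest flat
        slopes = np.zeros(n_peaks)
        responsive = rng.choice(n_peaks, size=max(2, n_peaks // 4), replace=False)
        slopes[responsive] = rng.uniform(-0.15, 0.15, size=responsive.size)
        return PeakLayout(centers, widths, base, slopes, "lorentzian",
                          ppm_window, n_points)


def generate_spectra(metadata: pd.DataFrame, layout: PeakLayout,
                     batch: BatchDesign = BatchDesign(), seed: int = 0,
                     dilution: np.ndarray | None = None,
                     noise_sd: float = 0.002):
    """Full-resolution spectra on a decreasing ppm axis.

    Additive batch bias (profile x amplitude x batch indicator) and
    multiplicative per-sample dilution factors are applied so that the
    batch-correction and PQN stages have something real to remove.
    Returns a :class:`altimet.nmr.SpectrumSet`.
    """
    from .nmr import SpectrumSet  # local import to avoid a cycle

    if layout.n_points < 1:
        raise InvalidDesignError("empty ppm axis")
    rng = np.random.default_rng(seed)
    lo, hi = layout.ppm_window
    ppm = np.linspace(hi, lo, layout.n_points)  # decreasing, NMR convention

    alt = metadata["altitude_km"].to_numpy(dtype=float)
    amps = np.clip(layout.base_amplitudes[None, :]
                   + layout.altitude_slopes[None, :] * alt[:, None], 0.0, None)
    delta = ppm[None, :] - layout.centers[:, None]
    if layout.shape == "gaussian":
        profiles = np.exp(-0.5 * (delta / layout.widths[:, None]) ** 2)
    else:
        profiles = 1.0 / (1.0 + (delta / layout.widths[:, None]) ** 2)
    spectra = amps @ profiles

    if batch.bias_amplitude > 0:
        prof = batch.profile(layout.n_points)
        is_b2 = (metadata["batch"].to_numpy() == "B2").astype(float)
        spectra = spectra + batch.bias_amplitude * is_b2[:, None] * prof[None, :]
    if noise_sd > 0:
        spectra = spectra + rng.normal(0.0, noise_sd, size=spectra.shape)
    if dilution is not None:
        dilution = np.asarray(dilution, dtype=float)
        spectra = spectra * dilution[:, None]
    return SpectrumSet(ppm, spectra, list(metadata["sample"]))


@dataclass(frozen=True)
class LipidSpecies:
    """One synthetic lipid: true m/z, baseline intensity and altitude trend.

    ``rel_slope_per_km`` is the fractional intensity change per km of
    altitude (0 = flat species).
    """

    name: str
    mz: float
    base_intensity: float = 20000.0
    rel_slope_per_km: float = 0.0


def generate_lipid_scans(metadata: pd.DataFrame, species: list[LipidSpecies],
                         seed: int = 0, n_scans: int = 72,
                         jitter_ppm: float = 3.0, dropout: float = 0.0,
                         intensity_cv: float = 0.2, ion_mode: str = "positive"):
    """Per-sample direct-infusion scan lists.

    Each sample gets ``n_scans`` scans of (m/z, intensity) pairs (72 by
    default, one per second of a 72 s acquisition, so that the standard
    scan-20-to-70 averaging window is fully covered).  m/z
    jitter is uniform within +/-``jitter_ppm`` (<= 10 ppm) around the true
    mass; a ``dropout`` fraction of species is removed per sample to
    exercise the coverage filter downstream.  Masses outside the 200-2000
    acquisition window are clipped with a warning.  Returns
    ``{sample_id: ScanSet}``.
    """
    from .lipids import ScanSet

    if jitter_ppm > 10:
        raise InvalidDesignError("m/z jitter must stay within 10 ppm of truth")
    masses = np.array([s.mz for s in species], dtype=float)
    if (masses < 200).any() or (masses > 2000).any():
        warnings.warn("species masses outside the 200-2000 m/z acquisition window "
                      "were clipped", stacklevel=2)
        masses = np.clip(masses, 200.0, 2000.0)

    rng = np.random.default_rng(seed)
    out = {}
    for _, row in metadata.iterrows():
        present = rng.random(len(species)) >= dropout
        if not present.any():
            present[rng.integers(len(species))] = True
        base = np.array([
            max(sp.base_intensity * (1.0 + sp.rel_slope_per_km * row["altitude_km"]), 0.0)
            for sp in species])
        scans = []
        for _ in range(n_scans):
            jit = rng.uniform(-jitter_ppm, jitter_ppm, size=len(species)) * 1e-6
            mz = np.clip(masses * (1.0 + jit), 200.0, 2000.0)
            inten = base * np.exp(rng.normal(0.0, intensity_cv, size=len(species)))
            scans.append(np.column_stack([mz[present], inten[present]]))
        out[row["sample"]] = ScanSet(sample_id=row["sample"], ion_mode=ion_mode,
                                     scans=scans)
    return out


def generate_covariates(metadata: pd.DataFrame, seed: int = 0,
                        spo2_range: tuple[float, float] = (98.0, 78.0),
                        weight_baseline: float = 81.1, weight_loss: float = 3.0,
                        subject_sd: tuple[float, float] = (1.0, 10.0),
                        noise_sd: tuple[float, float] = (0.8, 0.4)) -> pd.DataFrame:
    """Per-sample SpO2 (%) and body weight (kg).

    Location medians interpolate linearly in altitude from the baseline
    SpO2 (98%) down to the summit-camp value (78%); body weight declines
    by ``weight_loss`` kg (about 3.7% of an 81 kg baseline) over the same
    span.  Subject-level offsets and visit noise are added on top.
    """
    rng = np.random.default_rng(seed)
    alt = metadata["altitude_km"].to_numpy(dtype=float)
    a_lo, a_hi = alt.min(), alt.max()
    frac = (alt - a_lo) / (a_hi - a_lo) if a_hi > a_lo else np.zeros_like(alt)
    spo2_med = spo2_range[0] + (spo2_range[1] - spo2_range[0]) * frac
    weight_med = weight_baseline - weight_loss * frac

    uniq, idx = np.unique(metadata["subject"].to_numpy(), return_inverse=True)
    off_spo2 = rng.normal(0.0, subject_sd[0], size=uniq.size)
    off_w = rng.normal(0.0, subject_sd[1], size=uniq.size)
    spo2 = spo2_med + off_spo2[idx] + rng.normal(0.0, noise_sd[0], size=alt.size)
    weight = weight_med + off_w[idx] + rng.normal(0.0, noise_sd[1], size=alt.size)
    return pd.DataFrame({"sample": metadata["sample"].to_numpy(),
                         "subject": metadata["subject"].to_numpy(),
                         "location": metadata["location"].to_numpy(),
                         "spo2_pct": np.clip(spo2, 50.0, 100.0),
                         "weight_kg": weight})
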