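"""Direct-infusion MS lipidomics: scan averaging, feature grouping,
normalization and annotation.

Features are m/z peaks grouped across samples (no chromatography).  The
grouping step re-expresses the mzClust behaviour at a 22 ppm window as
greedy centroid-gap clustering on sorted m/z; annotation combines an
exact-mass search against a small bundled lipid library with the
Kendrick mass-defect transform for homologous-series assignment.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics.mass import calculate_mass

__all__ = [
    "ScanSet",
    "LipidFeatureTable",
    "average_scans",
    "group_features",
    "tic_normalize",
    "annotate_exact_mass",
    "kendrick",
    "default_library",
    "KENDRICK_FACTOR",
    "C13_SPACING",
    "PROTON",
]

#: CH2-referenced Kendrick rescaling: nominal/exact mass of the CH2 unit.
KENDRICK_FACTOR = 14.00000 / 14.01565
#: 13C-12C isotope spacing used for isotopologue flagging.
C13_SPACING = 1.00336
PROTON = 1.00727646677
NH4 = 18.03382555

ACQUISITION_WINDOW = (200.0, 2000.0)


@dataclass
class ScanSet:
    """Raw per-sample scans: a list of (m/z, intensity) arrays."""

    sample_id: str
    ion_mode: str
    scans: list[np.ndarray]

    def __post_init__(self) -> None:
        self.scans = [np.asarray(s, dtype=float).reshape(-1, 2) for s in self.scans]
        for s in self.scans:
            if s.size and ((s[:, 0] < ACQUISITION_WINDOW[0]).any()
                           or (s[:, 0] > ACQUISITION_WINDOW[1]).any()):
                raise ValueError("m/z outside the 200-2000 acquisition window")
            if s.size and (s[:, 1] < 0).any():
                raise ValueError("negative intensities")


@dataclass
class LipidFeatureTable:
    """Grouped features: per-feature metadata plus feature x sample intensities.

    ``features`` columns: mz (consensus, intensity-weighted), ion_mode,
    coverage, and after annotation: annotation, lipid_class, mass_error_ppm,
    is_isotope, kendrick_mass, kendrick_mass_defect, series_id.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame  # features x samples

    def copy(self) -> "LipidFeatureTable":
        return LipidFeatureTable(self.features.copy(), self.intensities.copy())


def _greedy_group(order_mz: np.ndarray, order_inten: np.ndarray,
                  ppm_window: float) -> np.ndarray:
    """Cut sorted peaks into groups where the relative gap to the running
    intensity-weighted centroid exceeds ``ppm_window`` (in ppm)."""
    labels = np.empty(order_mz.size, dtype=int)
    group = -1
    centroid = wsum = 0.0
    for i, (mz, inten) in enumerate(zip(order_mz, order_inten)):
        if group < 0 or (mz - centroid) / centroid * 1e6 > ppm_window:
            group += 1
            centroid, wsum = mz, max(inten, 1e-30)
        else:
            wsum_new = wsum + max(inten, 1e-30)
            centroid = (centroid * wsum + mz * max(inten, 1e-30)) / wsum_new
            wsum = wsum_new
        labels[i] = group
    return labels


def average_scans(scanset: ScanSet, window: tuple[int, int] = (20, 70),
                  cutoff: float = 2000.0, ppm_tol: float = 22.0) -> pd.DataFrame:
    """Average one sample's scans over a scan-index window.

    Peaks are matched across scans within ``ppm_tol``; matched peaks are
    averaged (mean intensity over the scans in which the peak appears,
    intensity-weighted mean m/z) and averaged peaks below ``cutoff`` are
    discarded.  Scan indices are 0-based, the window half-open, so the
    default (20, 70) averages 50 spectra.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty scan window")
    selected = scanset.scans[lo:hi]
    if len(selected) < hi - lo:
        warnings.warn(f"{scanset.sample_id}: only {len(selected)} scans available "
                      f"in window {window}; averaging over what exists", stacklevel=2)
    if not selected or all(s.size == 0 for s in selected):
        return pd.DataFrame(columns=["mz", "intensity"])
    peaks = np.vstack([s for s in selected if s.size])
    order = np.argsort(peaks[:, 0], kind="stable")
    mz_s, in_s = peaks[order, 0], peaks[order, 1]
    labels = _greedy_group(mz_s, in_s, ppm_tol)
    n_groups = labels[-1] + 1
    w = np.bincount(labels, weights=in_s, minlength=n_groups)
    counts = np.bincount(labels, minlength=n_groups)
    mz_mean = np.bincount(labels, weights=mz_s * in_s, minlength=n_groups) / np.where(
        w > 0, w, 1.0)
    inten_mean = w / counts
    keep = inten_mean >= cutoff
    return pd.DataFrame({"mz": mz_mean[keep], "intensity": inten_mean[keep]}
                        ).sort_values("mz", ignore_index=True)


def group_features(samples: dict[str, pd.DataFrame], ppm_window: float = 22.0,
                   min_coverage: float = 0.60, ion_mode: str = "positive"
                   ) -> LipidFeatureTable:
    """Align averaged peak lists across samples into a feature table.

    Peaks from all samples are pooled, sorted by m/z and cut greedily
    into groups wherever the relative gap to the running group centroid
    exceeds ``ppm_window``.  Groups observed in fewer than
    ``min_coverage`` of samples are removed; when a sample contributes
    several peaks to one group, the most intense is kept.
    """
    if len(samples) < 2:
        raise ValueError("feature grouping needs at least 2 samples")
    sample_ids = sorted(samples)
    mz_all, in_all, sample_idx = [], [], []
    for si, sid in enumerate(sample_ids):
        plist = samples[sid]
        if len(plist):
            mz_all.append(plist["mz"].to_numpy(dtype=float))
            in_all.append(plist["intensity"].to_numpy(dtype=float))
            sample_idx.append(np.full(len(plist), si))
    if not mz_all:
        return LipidFeatureTable(
            pd.DataFrame(columns=["mz", "ion_mode", "coverage"]),
            pd.DataFrame(columns=sample_ids))
    mz = np.concatenate(mz_all)
    inten = np.concatenate(in_all)
    sidx = np.concatenate(sample_idx)
    order = np.argsort(mz, kind="stable")
    labels = _greedy_group(mz[order], inten[order], ppm_window)

    n_groups = labels[-1] + 1
    n_samples = len(sample_ids)
    matrix = np.zeros((n_groups, n_samples))
    # most intense member wins per (group, sample)
    np.maximum.at(matrix, (labels, sidx[order]), inten[order])
    member_w = np.where(matrix > 0, matrix, 0.0)
    kept_mask = matrix > 0
    # consensus m/z: intensity-weighted mean over the kept members
    mz_sorted, in_sorted = mz[order], inten[order]
    num = np.zeros(n_groups)
    den = np.zeros(n_groups)
    is_kept = in_sorted == matrix[labels, sidx[order]]
    np.add.at(num, labels[is_kept], mz_sorted[is_kept] * in_sorted[is_kept])
    np.add.at(den, labels[is_kept], in_sorted[is_kept])
    consensus = num / np.where(den > 0, den, 1.0)
    coverage = kept_mask.sum(axis=1) / n_samples

    keep = coverage >= min_coverage
    features = pd.DataFrame({
        "mz": consensus[keep],
        "ion_mode": ion_mode,
        "coverage": coverage[keep],
    }).reset_index(drop=True)
    features.index.name = "feature"
    intens = pd.DataFrame(member_w[keep], columns=sample_ids)
    intens.index.name = "feature"
    return LipidFeatureTable(features, intens)


def tic_normalize(table: LipidFeatureTable, target_sum: float = 10_000.0
                  ) -> LipidFeatureTable:
    """Scale each sample so its summed feature intensity equals ``target_sum``.

    Corrects for per-sample ionisation efficiency.
    """
    totals = table.intensities.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"zero-total sample(s): {zero}")
    out = table.copy()
    out.intensities = table.intensities * (target_sum / totals)
    return out


def default_library() -> pd.DataFrame:
    """Bundled exact-mass library of the named plasma lipids.

    Monoisotopic masses are computed from molecular formulas; the adduct
    column states the ionisation assumed per species (ammoniated
    triglycerides and protonated phospho/sphingolipids in positive mode,
    deprotonated free fatty acids in negative mode).
    """
    entries = [
        # name, class, formula, adduct, mode
        ("Palmitic acid 16:0", "FFA", "C16H32O2", "[M-H]-", "negative"),
        ("Oleic acid 18:1", "FFA", "C18H34O2", "[M-H]-", "negative"),
        ("Linoleic acid 18:2", "FFA", "C18H32O2", "[M-H]-", "negative"),
        ("TG 48:1", "TG", "C51H96O6", "[M+NH4]+", "positive"),
        ("TG 50:1", "TG", "C53H100O6", "[M+NH4]+", "positive"),
        ("TG 52:3", "TG", "C55H100O6", "[M+NH4]+", "positive"),
        ("TG 52:4", "TG", "C55H98O6", "[M+NH4]+", "positive"),
        ("PC 46:2", "PC", "C54H102NO8P", "[M+H]+", "positive"),
        ("SM 34:1", "SM", "C39H79N2O6P", "[M+H]+", "positive"),
    ]
    rows = []
    for name, cls, formula, adduct, mode in entries:
        m = calculate_mass(formula=formula)
        if adduct == "[M-H]-":
            mz = m - PROTON
        elif adduct == "[M+H]+":
            mz = m + PROTON
        elif adduct == "[M+NH4]+":
            mz = m + NH4
        else:
            raise ValueError(f"unsupported adduct {adduct}")
        rows.append((name, cls, formula, adduct, mode, mz))
    return pd.DataFrame(rows, columns=["name", "lipid_class", "formula",
                                       "adduct", "ion_mode", "mz"])


def annotate_exact_mass(table: LipidFeatureTable, library: pd.DataFrame | None = None,
                        tol_ppm: float = 10.0) -> LipidFeatureTable:
    """Annotate features by exact-mass match against a lipid library.

    Each feature gets the library entry with the smallest absolute ppm
    error within ``tol_ppm`` (restricted to matching ion mode).  A
    feature sitting one 13C spacing (+1.00336) above a more intense
    annotated feature is flagged as an isotopologue and left
    unannotated.  Unmatched features are retained unlabeled.  The
    operation is idempotent.
    """
    if library is None:
        library = default_library()
    if library.empty or tol_ppm <= 0:
        raise ValueError("library must be nonempty and tol_ppm positive")
    out = table.copy()
    feats = out.features
    mz = feats["mz"].to_numpy(dtype=float)
    mean_inten = out.intensities.mean(axis=1).to_numpy() if len(out.intensities.columns) \
        else np.zeros(len(feats))

    annotation = np.array([None] * len(feats), dtype=object)
    lipid_class = np.array([None] * len(feats), dtype=object)
    err_ppm = np.full(len(feats), np.nan)
    for i, (m, mode) in enumerate(zip(mz, feats["ion_mode"])):
        lib = library[library["ion_mode"] == mode]
        if lib.empty:
            continue
        errors = (m - lib["mz"].to_numpy()) / lib["mz"].to_numpy() * 1e6
        j = int(np.argmin(np.abs(errors)))
        if abs(errors[j]) <= tol_ppm:
            annotation[i] = lib["name"].iloc[j]
            lipid_class[i] = lib["lipid_class"].iloc[j]
            err_ppm[i] = errors[j]

    is_isotope = np.zeros(len(feats), dtype=bool)
    for i, m in enumerate(mz):
        parent = m - C13_SPACING
        rel = np.abs(mz - parent) / parent * 1e6
        cand = np.where((rel <= tol_ppm) & (mean_inten > mean_inten[i])
                        & (annotation != None))[0]  # noqa: E711
        if cand.size:
            is_isotope[i] = True
            annotation[i] = None
            lipid_class[i] = None
            err_ppm[i] = np.nan

    feats = feats.drop(columns=[c for c in ("annotation", "lipid_class",
                                            "mass_error_ppm", "is_isotope")
                                if c in feats.columns])
    feats["annotation"] = annotation
    feats["lipid_class"] = lipid_class
    feats["mass_error_ppm"] = err_ppm
    feats["is_isotope"] = is_isotope
    out.features = feats
    return out


def kendrick(table: LipidFeatureTable, series_tol: float = 1e-3
             ) -> LipidFeatureTable:
    """Attach the CH2-based Kendrick mass and mass defect to each feature.

    ``kendrick_mass = m/z * 14.00000/14.01565``;
    ``defect = round(kendrick_mass) - kendrick_mass``.  Features whose
    defects agree within ``series_tol`` share a homologous ``series_id``.
    """
    out = table.copy()
    mz = out.features["mz"].to_numpy(dtype=float)
    if (mz <= 0).any():
        raise ValueError("m/z must be positive")
    km = mz * KENDRICK_FACTOR
    kmd = np.round(km) - km
    series = np.full(mz.size, -1, dtype=int)
    if mz.size:
        order = np.argsort(kmd, kind="stable")
        sid = 0
        prev = kmd[order[0]]
        for k in order:
            if kmd[k] - prev > series_tol:
                sid += 1
            series[k] = sid
            prev = kmd[k]
    out.features = out.features.assign(kendrick_mass=km, kendrick_mass_defect=kmd,
                                       series_id=series)
    return out
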