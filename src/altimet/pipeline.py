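"""End-to-end orchestration: configuration, stage execution, manifest.

The pipeline chains the package's stages on synthetic (or previously
written) data::

    generate -> preprocess (NMR + lipids) -> prescreen -> bayes
             -> summaries -> correlate

Every tunable that the analysis depends on is surfaced in
:class:`PipelineConfig` with the study value as default (10:1 binning,
22 ppm grouping window, 60% coverage, 2000 signal cutoff, 1.96 screen
threshold, 95% HDI, the non-informative priors, 0.01 correlation
alpha).  A run directory receives all stage outputs plus a JSON
manifest; identical configs produce byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import MCMCConfig, PriorSpec, decide_changers, fit_feature
from .covariates import correlate_deltas, followup_regression, paired_deltas
from .datasets import LongitudinalDataset, read_dataset, write_dataset
from .lipids import (LipidFeatureTable, annotate_exact_mass, average_scans,
                     default_library, group_features, kendrick, tic_normalize)
from .nmr import (SpectrumSet, bin_spectra, exclude_region, pareto_scale,
                  pqn_normalize, remove_batch_bias)
from .prescreen import select_candidates, simple_hier_fit
from .simulate import (BatchDesign, LipidSpecies, PeakLayout, StudyDesign,
                       generate_cohort, generate_covariates,
                       generate_feature_matrix, generate_lipid_scans,
                       generate_spectra)
from .summaries import assemble_results

__all__ = ["PipelineConfig", "run_pipeline", "write_spectra", "read_spectra",
           "write_scanset", "read_scanset", "read_dataset", "write_dataset"]

log = logging.getLogger("altimet")


class _StopRun(Exception):
    """Internal: truncate the run after the requested stage."""

STAGES = ("generate", "preprocess", "prescreen", "bayes", "summaries",
          "correlate")


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; round-trips losslessly through YAML."""

    outdir: str = "runs/demo"
    seed: int = 0
    # cohort
    n_subjects: int = 30
    attendance_fractions: list = field(
        default_factory=lambda: [1.0, 1.0, 197 / 198, 190 / 198, 182 / 198])
    # NMR simulation + preprocessing
    nmr_points: int = 1000
    nmr_peaks: int = 18
    retain_low: float = 0.5
    retain_high: float = 4.51
    bin_ratio: int = 10
    batch_bias_amplitude: float = 0.3
    spectrum_noise_sd: float = 0.01
    dilution_log_sd: float = 0.15
    eigen_alpha: float = 0.05
    eigen_permutations: int = 12
    # lipid simulation + preprocessing
    n_extra_lipids: int = 11
    lipid_dropout: float = 0.05
    lipid_jitter_ppm: float = 3.0
    scan_lo: int = 20
    scan_hi: int = 70
    signal_cutoff: float = 2000.0
    group_ppm: float = 22.0
    min_coverage: float = 0.60
    tic_target: float = 10_000.0
    annotation_tol_ppm: float = 10.0
    # screening
    prescreen_enabled: bool = True
    screen_threshold: float = 1.96
    # Bayesian stage
    n_chains: int = 3
    n_draws: int = 2000
    n_burn: int = 500
    thin: int = 1
    hdi_mass: float = 0.95
    prior_mu_scale: float = 10.0
    prior_sigma_low: float = 1e-3
    prior_sigma_high: float = 1e3
    prior_nu_mean: float = 30.0
    max_bayes_features: int = 40
    # summaries / correlations
    baseline_location: str = "LDN"
    top_location: str = "EBC"
    corr_alpha: float = 0.01

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------- text I/O

def write_spectra(spectra: SpectrumSet, path: str | Path) -> None:
    """Spectral matrix as TSV: ppm axis in the header row, one row per sample."""
    frame = pd.DataFrame(spectra.intensities,
                         index=pd.Index(spectra.sample_ids, name="sample"),
                         columns=[f"{p:.6f}" for p in spectra.ppm_axis])
    frame.to_csv(path, sep="\t", float_format="%.8g")


def read_spectra(path: str | Path) -> SpectrumSet:
    frame = pd.read_csv(path, sep="\t", index_col="sample")
    ppm = np.array([float(c) for c in frame.columns])
    return SpectrumSet(ppm, frame.to_numpy(dtype=float), list(frame.index))


def write_scanset(scanset, outdir: str | Path) -> None:
    """One two-column (m/z, intensity) text file per scan."""
    d = Path(outdir) / scanset.sample_id
    d.mkdir(parents=True, exist_ok=True)
    for i, scan in enumerate(scanset.scans):
        np.savetxt(d / f"scan_{i:03d}.tsv", scan, fmt="%.8g", delimiter="\t",
                   header="mz\tintensity")


def read_scanset(sample_dir: str | Path, ion_mode: str = "positive"):
    from .lipids import ScanSet

    d = Path(sample_dir)
    scans = [np.loadtxt(f, delimiter="\t", ndmin=2)
             for f in sorted(d.glob("scan_*.tsv"))]
    return ScanSet(sample_id=d.name, ion_mode=ion_mode, scans=scans)


# ------------------------------------------------------------- simulation

def _demo_lipid_species(config: PipelineConfig, rng: np.random.Generator
                        ) -> list[LipidSpecies]:
    """Library species with altitude trends plus unannotated fillers."""
    lib = default_library()
    lib = lib[lib["ion_mode"] == "positive"]
    trends = {"TG 48:1": -0.09, "TG 50:1": -0.02, "TG 52:3": 0.10,
              "TG 52:4": 0.10, "PC 46:2": -0.05, "SM 34:1": 0.03}
    species = [LipidSpecies(row["name"], row["mz"],
                            base_intensity=rng.uniform(8000, 40000),
                            rel_slope_per_km=trends.get(row["name"], 0.0))
               for _, row in lib.iterrows()]
    for i in range(config.n_extra_lipids):
        species.append(LipidSpecies(f"unknown_{i:02d}",
                                    float(rng.uniform(300, 950)),
                                    base_intensity=float(rng.uniform(5000, 30000)),
                                    rel_slope_per_km=0.0))
    return species


def _lipid_dataset(table: LipidFeatureTable) -> pd.DataFrame:
    """Feature x sample intensities -> sample x feature with readable names."""
    names = []
    for idx, row in table.features.iterrows():
        label = row.get("annotation") or f"mz_{row['mz']:.4f}"
        names.append(f"lipid:{label}")
    frame = table.intensities.T
    frame.columns = names
    return frame


# ---------------------------------------------------------------- stages

def run_pipeline(config: PipelineConfig, stop_after: str | None = None) -> Path:
    """Execute the stages in order; returns the run directory.

    ``stop_after`` truncates the run after the named stage (used by the
    per-stage CLI subcommands).  Any stage failure aborts with the stage
    name in the exception; outputs of completed stages are retained.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": []}
    config.to_yaml(outdir / "config.yaml")

    stage = "generate"
    try:
        rng = np.random.default_rng(config.seed)
        locs = tuple(
            (name, alt, max(3, int(round(frac * config.n_subjects))))
            for (name, alt, _), frac in zip(
                StudyDesign().locations, config.attendance_fractions))
        design = StudyDesign(locations=locs, n_subjects=config.n_subjects,
                             seed=config.seed)
        metadata = generate_cohort(design)
        covars = generate_covariates(metadata, seed=config.seed + 1)
        layout = PeakLayout.default(n_peaks=config.nmr_peaks,
                                    seed=7, n_points=config.nmr_points,
                                    ppm_window=(config.retain_low,
                                                config.retain_high))
        dil = np.exp(rng.normal(0.0, config.dilution_log_sd, size=len(metadata)))
        spectra = generate_spectra(
            metadata, layout,
            BatchDesign(bias_amplitude=config.batch_bias_amplitude),
            seed=config.seed + 2, dilution=dil,
            noise_sd=config.spectrum_noise_sd)
        species = _demo_lipid_species(config, np.random.default_rng(config.seed + 3))
        scans = generate_lipid_scans(metadata, species, seed=config.seed + 4,
                                     jitter_ppm=config.lipid_jitter_ppm,
                                     dropout=config.lipid_dropout)
        metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False,
                        float_format="%.10g")
        covars.to_csv(outdir / "covariates.tsv", sep="\t", index=False,
                      float_format="%.10g")
        write_spectra(spectra, outdir / "spectra.tsv")
        manifest["stages"].append({"stage": stage, "n_samples": len(metadata),
                                   "n_subjects": config.n_subjects})
        log.info("generate: %d samples", len(metadata))
        if stop_after == "generate":
            raise _StopRun

        stage = "preprocess"
        kept = exclude_region(spectra, (config.retain_low, config.retain_high))
        binned = bin_spectra(kept, config.bin_ratio)
        binned, _pqn = pqn_normalize(binned)
        scaled = pareto_scale(binned)
        corrected, bias_report = remove_batch_bias(
            scaled, metadata, alpha=config.eigen_alpha,
            n_permutations=config.eigen_permutations, seed=config.seed + 5)
        nmr_frame = corrected.values.copy()
        nmr_frame.columns = [f"nmr:{c}" for c in nmr_frame.columns]

        averaged = {sid: average_scans(ss, (config.scan_lo, config.scan_hi),
                                       config.signal_cutoff, config.group_ppm)
                    for sid, ss in scans.items()}
        table = group_features(averaged, config.group_ppm, config.min_coverage)
        table = tic_normalize(table, config.tic_target)
        table = annotate_exact_mass(table, tol_ppm=config.annotation_tol_ppm)
        table = kendrick(table)
        lipid_frame = _lipid_dataset(table).reindex(metadata["sample"]).fillna(0.0)

        values = pd.concat([nmr_frame, lipid_frame], axis=1)
        data = LongitudinalDataset(metadata, values)
        write_dataset(data, outdir / "features.tsv", outdir / "metadata.tsv")
        feat_out = table.features.copy()
        feat_out.to_csv(outdir / "lipid_features.tsv", sep="\t",
                        float_format="%.8g")
        manifest["stages"].append({
            "stage": stage, "n_nmr_bins": nmr_frame.shape[1],
            "n_lipid_features": lipid_frame.shape[1],
            "batch_components_removed": bias_report["n_components"]})
        log.info("preprocess: %d NMR bins, %d lipid features",
                 nmr_frame.shape[1], lipid_frame.shape[1])
        if stop_after == "preprocess":
            raise _StopRun

        stage = "prescreen"
        slopes = simple_hier_fit(data)
        if config.prescreen_enabled:
            screen = select_candidates(slopes, config.screen_threshold)
            screen.table.to_csv(outdir / "prescreen.tsv", sep="\t", index=False,
                                float_format="%.8g")
            candidates = screen.selected
        else:
            slopes.to_csv(outdir / "prescreen.tsv", sep="\t", index=False,
                          float_format="%.8g")
            candidates = slopes.loc[slopes["estimable"], "feature"].tolist()
        manifest["stages"].append({"stage": stage, "n_features": len(slopes),
                                   "n_candidates": len(candidates)})
        candidates = candidates[: config.max_bayes_features]
        log.info("prescreen: %d candidates of %d features", len(candidates),
                 len(slopes))
        if stop_after == "prescreen":
            raise _StopRun

        stage = "bayes"
        priors = PriorSpec(mu_scale=config.prior_mu_scale,
                           sigma_low=config.prior_sigma_low,
                           sigma_high=config.prior_sigma_high,
                           nu_mean=config.prior_nu_mean)
        draws_dir = outdir / "posterior_draws"
        draws_dir.mkdir(exist_ok=True)
        summaries = []
        for i, feat in enumerate(candidates):
            mcmc = MCMCConfig(n_chains=config.n_chains, n_draws=config.n_draws,
                              n_burn=config.n_burn, thin=config.thin,
                              hdi_mass=config.hdi_mass,
                              seed=config.seed + 100 + i)
            s = fit_feature(data, feat, priors, mcmc)
            summaries.append(s)
            archive = pd.DataFrame({k: s.flat(k)[::10] for k in s.draws})
            safe = feat.replace("/", "_").replace(":", "_").replace(" ", "_")
            archive.to_csv(draws_dir / f"{safe}.tsv", sep="\t", index=False,
                           float_format="%.6g")
        decisions = decide_changers(summaries)
        decisions.to_csv(outdir / "decisions.tsv", sep="\t", index=False,
                         float_format="%.8g")
        manifest["stages"].append({
            "stage": stage, "n_fitted": len(summaries),
            "n_changers": int((decisions["changer"] == True).sum()),  # noqa: E712
            "n_unconverged": int((~decisions["converged"]).sum())})
        log.info("bayes: %d fitted, %d changers", len(summaries),
                 int((decisions["changer"] == True).sum()))  # noqa: E712
        if stop_after == "bayes":
            raise _StopRun

        stage = "summaries"
        results = assemble_results(decisions, data, config.baseline_location,
                                   config.top_location)
        results.to_csv(outdir / "results_table.tsv", sep="\t", index=False,
                       float_format="%.8g")
        manifest["stages"].append({"stage": stage, "n_rows": len(results)})
        if stop_after == "summaries":
            raise _StopRun

        stage = "correlate"
        corr_rows = []
        covar_deltas = {
            name: paired_deltas(covars, name, config.baseline_location,
                                config.top_location, value_col=col)
            for name, col in (("SpO2", "spo2_pct"), ("weight", "weight_kg"))}
        for feat in results["feature"]:
            vals = data.metadata[["subject", "location"]].copy()
            vals[feat] = data.values[feat].to_numpy()
            try:
                dfeat = paired_deltas(vals, feat, config.baseline_location,
                                      config.top_location)
            except ValueError:
                continue
            for cname, dcov in covar_deltas.items():
                try:
                    corr = correlate_deltas(dfeat, dcov)
                except ValueError:
                    continue
                fit = followup_regression(dfeat, dcov, corr, config.corr_alpha)
                corr_rows.append({
                    "feature": feat, "covariate": cname, "method": corr.method,
                    "coefficient": corr.coefficient, "p_value": corr.p_value,
                    "n": corr.n,
                    "regression_slope": fit.slope if fit else np.nan})
        pd.DataFrame(corr_rows, columns=["feature", "covariate", "method",
                                         "coefficient", "p_value", "n",
                                         "regression_slope"]
                     ).to_csv(outdir / "correlations.tsv", sep="\t", index=False,
                              float_format="%.8g")
        manifest["stages"].append({"stage": stage, "n_tests": len(corr_rows)})
    except _StopRun:
        pass
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return outdir
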