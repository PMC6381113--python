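"""NMR preprocessing chain: exclusion -> 10:1 binning -> PQN -> Pareto ->
batch-bias removal.

Simulates full-resolution aliphatic-region spectra with per-sample
dilution and a two-batch acquisition bias, then removes both.
"""
import numpy as np

from altimet import (BatchDesign, PeakLayout, StudyDesign, bin_spectra,
                     exclude_region, generate_cohort, generate_spectra,
                     pareto_scale, pqn_normalize, remove_batch_bias)

design = StudyDesign(locations=tuple((n, a, 40) for n, a, _ in
                                     StudyDesign().locations),
                     n_subjects=40, seed=3)
md = generate_cohort(design)
rng = np.random.default_rng(4)
dilution = np.exp(rng.normal(0, 0.2, size=len(md)))
spectra = generate_spectra(md, PeakLayout.default(),
                           BatchDesign(bias_amplitude=0.4), seed=5,
                           dilution=dilution)
print(f"full-resolution points: {spectra.ppm_axis.size}")

kept = exclude_region(spectra, (0.5, 4.51))
binned = bin_spectra(kept, ratio=10)
print(f"bins after 10:1 binning: {binned.values.shape[1]}")

normalized, factors = pqn_normalize(binned)
print("PQN factors track the injected dilution (correlation "
      f"{np.corrcoef(factors, dilution)[0, 1]:.3f})")

scaled = pareto_scale(normalized)
corrected, report = remove_batch_bias(scaled, md, seed=6)
print(f"batch components removed: {report['n_components']}, leading component "
      f"carried {100 * report['variance_fractions'][0]:.1f}% of residual "
      "variance")
print("Each bin is now a dilution-free, batch-corrected feature ready for "
      "the altitude screen.")
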