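"""Robust Bayesian hierarchical regression: transforms, priors, HDI,
sampler correctness (oracle cross-checks), shrinkage and robustness."""
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from altimet import (
    FeatureSpec,
    MCMCConfig,
    PriorSpec,
    back_transform_slope,
    decide_changers,
    fit_feature,
    fit_robust_hier,
    generate_cohort,
    generate_feature_matrix,
    hdi,
    sample_priors,
    simple_hier_fit,
    ztransform,
)
from altimet.bayes import TransformRecord

from conftest import scaled_design

FAST = MCMCConfig(n_chains=2, n_draws=2000, n_burn=600, seed=5)


class TestZTransform:
    def test_standardized_input_unchanged(self, rng):
        y = rng.normal(size=50)
        y = (y - y.mean()) / y.std(ddof=1)
        x = rng.normal(size=50)
        x = (x - x.mean()) / x.std(ddof=1)
        yz, xz, _ = ztransform(y, x)
        np.testing.assert_allclose(yz, y, atol=1e-12)
        np.testing.assert_allclose(xz, x, atol=1e-12)

    def test_three_point_vector(self):
        yz, _, _ = ztransform(np.array([1.0, 2.0, 3.0]), np.array([0.0, 1.0, 2.0]))
        assert yz.mean() == pytest.approx(0.0, abs=1e-12)
        assert yz.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_round_trip_is_exact(self, rng):
        y = rng.normal(3.0, 2.5, size=30)
        x = rng.normal(2.0, 1.5, size=30)
        yz, xz, rec = ztransform(y, x)
        np.testing.assert_allclose(yz * rec.y_sd + rec.y_mean, y, rtol=1e-12)
        np.testing.assert_allclose(xz * rec.x_sd + rec.x_mean, x, rtol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ztransform(np.ones(5), np.arange(5.0))


class TestPriors:
    def test_nu_prior_mean_is_thirty(self):
        draws = sample_priors(n_draws=10**6, seed=1)["nu"]
        se = draws.std(ddof=1) / 1000
        assert draws.mean() == pytest.approx(30.0, abs=3 * se)
        assert draws.min() >= 1.0

    def test_mu_prior_sd_is_ten(self):
        draws = sample_priors(n_draws=10**6, seed=2)["mu"]
        assert draws.std(ddof=1) == pytest.approx(10.0, abs=0.05)
        assert draws.mean() == pytest.approx(0.0, abs=0.05)

    def test_sigma_prior_respects_bounds(self):
        draws = sample_priors(n_draws=10**5, seed=3)["sigma"]
        assert draws.min() > 1e-3 and draws.max() < 1e3

    def test_invalid_prior_spec_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(sigma_low=1.0, sigma_high=0.1)


class TestHDI:
    def test_degenerate_draws(self):
        lo, hi = hdi(np.full(500, 3.14))
        assert lo == hi == pytest.approx(3.14)

    def test_standard_normal_endpoints(self):
        draws = np.random.default_rng(7).standard_normal(10**6)
        lo, hi = hdi(draws, 0.95)
        assert lo == pytest.approx(-1.960, abs=0.02)
        assert hi == pytest.approx(1.960, abs=0.02)

    def test_shortest_window_property(self, rng):
        draws = rng.gamma(2.0, 1.0, size=400)
        lo, hi = hdi(draws, 0.9)
        inside = ((draws >= lo) & (draws <= hi)).mean()
        assert inside >= 0.9
        # exhaustive scan: no shorter window holds ceil(0.9 n) sorted draws
        s = np.sort(draws)
        k = int(np.ceil(0.9 * s.size))
        widths = s[k - 1:] - s[: s.size - k + 1]
        assert hi - lo == pytest.approx(widths.min())

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            hdi(np.arange(50.0))


class TestBackTransform:
    def test_identity_when_unit_scales(self):
        rec = TransformRecord(0.0, 1.0, 0.0, 1.0)
        np.testing.assert_allclose(back_transform_slope(np.array([0.3]), rec),
                                   [0.3])

    def test_arithmetic_example(self):
        rec = TransformRecord(0.0, 0.002, 0.0, 2.0)
        assert back_transform_slope(np.array([1.0]), rec)[0] == pytest.approx(
            0.001)

    def test_round_trip_recovers_generating_slope(self):
        md = generate_cohort(scaled_design(40, seed=51))
        spec = FeatureSpec("f", mu1=0.3, sigma1=0.1, sigma=0.2, nu=10)
        data = generate_feature_matrix(md, [spec], seed=52)
        s = fit_feature(data, "f", mcmc=FAST)
        x_sd = md["altitude_km"].std(ddof=1)
        # slope per km back to slope per z-altitude, in generated units
        slope_per_zx = s.slope_au_per_km * x_sd
        lo, hi = s.slope_hdi_au[0] * x_sd, s.slope_hdi_au[1] * x_sd
        assert lo <= 0.3 <= hi
        assert slope_per_zx == pytest.approx(0.3, abs=0.1)


def _toy_dataset(n_subjects=30, mu1=-0.4, seed=61, **spec_kw):
    md = generate_cohort(scaled_design(n_subjects, seed=seed))
    spec = FeatureSpec("f", mu1=mu1, **spec_kw)
    return generate_feature_matrix(md, [spec], seed=seed + 1), spec


class TestFitRobustHier:
    def test_recovery_of_negative_slope(self):
        md = generate_cohort(scaled_design(60, seed=71))
        spec = FeatureSpec("f", mu1=-0.4, sigma1=0.15, sigma=0.3, nu=5)
        data = generate_feature_matrix(md, [spec], seed=72)
        s = fit_feature(data, "f",
                        mcmc=MCMCConfig(n_chains=3, n_draws=4000, n_burn=1000,
                                        seed=73))
        rec = s.transform
        post_mean = s.flat("mu1").mean() * rec.y_sd
        assert post_mean == pytest.approx(-0.4, abs=0.1)
        assert s.hdi_low * rec.y_sd <= -0.4 <= s.hdi_high * rec.y_sd
        assert s.converged

    def test_normal_limit_matches_mean_of_ols_slopes(self):
        # large nu, low noise: posterior mean of mu1 ~ mean per-subject OLS
        data, _ = _toy_dataset(n_subjects=40, mu1=0.5, seed=81,
                               sigma1=0.2, sigma=0.05, nu=500)
        s = fit_feature(data, "f", mcmc=FAST)
        assert s.flat("mu1").mean() == pytest.approx(
            s.subject_slope_ols.mean(), abs=0.02)

    def test_insufficient_subjects_rejected(self):
        y = np.array([1.0, 2, 3, 4])
        x = np.array([0.0, 1, 0, 1])
        subj = np.array(["a", "a", "b", "b"])
        with pytest.raises(ValueError):
            fit_robust_hier(y, x, subj, mcmc=FAST)

    def test_shrinkage_of_subject_slopes(self):
        data, _ = _toy_dataset(n_subjects=40, mu1=0.2, seed=91,
                               sigma1=0.1, sigma=0.5, nu=5)
        s = fit_feature(data, "f", mcmc=FAST)
        assert s.subject_slope_means.std() < s.subject_slope_ols.std()

    def test_robustness_to_contamination_vs_ols(self):
        data, _ = _toy_dataset(n_subjects=30, mu1=0.0, seed=101,
                               sigma1=0.1, sigma=0.3, nu=30)
        y = data.values["f"].to_numpy().copy()
        sd = y.std(ddof=1)
        clean_bayes = fit_feature(data, "f", mcmc=FAST).flat("mu1").mean()
        clean_ols = simple_hier_fit(data)["mean_slope"].iloc[0]

        # contaminate one subject's top-altitude observation with a 10-SD spike
        md = data.metadata
        victim = md["subject"].iloc[0]
        idx = np.where((md["subject"] == victim)
                       & (md["location"] == "EBC"))[0][0]
        y2 = y.copy()
        y2[idx] += 10 * sd
        dirty = data.values.copy()
        dirty["f"] = y2
        from altimet.datasets import LongitudinalDataset
        dirty_data = LongitudinalDataset(md, dirty)
        dirty_bayes = fit_feature(dirty_data, "f", mcmc=FAST).flat("mu1").mean()
        dirty_ols = simple_hier_fit(dirty_data)["mean_slope"].iloc[0]

        x_sd = md["altitude_km"].std(ddof=1)
        y_sd_clean = fit_feature(data, "f", mcmc=FAST).transform.y_sd
        # compare both shifts on the common data scale (per z-altitude)
        bayes_shift = abs(dirty_bayes * dirty_data.values["f"].std(ddof=1)
                          - clean_bayes * y_sd_clean)
        ols_shift = abs(dirty_ols - clean_ols) * x_sd
        assert bayes_shift < ols_shift

    def test_group_posterior_stable_under_subject_relabeling(self):
        data, _ = _toy_dataset(n_subjects=30, mu1=0.3, seed=111,
                               sigma1=0.1, sigma=0.3, nu=10)
        y, x, subj = data.feature_arrays("f")
        s1 = fit_robust_hier(y, x, subj, mcmc=FAST)
        mapping = {s: f"relabel_{i:03d}" for i, s in
                   enumerate(np.random.default_rng(1).permutation(
                       np.unique(subj)))}
        subj2 = np.array([mapping[s] for s in subj])
        s2 = fit_robust_hier(y, x, subj2,
                             mcmc=MCMCConfig(n_chains=2, n_draws=2000,
                                             n_burn=600, seed=6))
        mcse = s1.flat("mu1").std() / np.sqrt(min(s1.ess["mu1"], s2.ess["mu1"]))
        assert abs(s1.flat("mu1").mean() - s2.flat("mu1").mean()) < 6 * mcse + 0.01


class TestDecisions:
    def _summary(self, lo, hi, converged=True):
        med = (lo + hi) / 2
        from altimet.bayes import PosteriorSummary
        return PosteriorSummary(
            feature="f", draws={}, hdi_low=lo, hdi_high=hi,
            changer=not (lo <= 0 <= hi),
            direction="Increasing" if med > 0 else "Decreasing",
            mu1_median=med, slope_au_per_km=med, slope_hdi_au=(lo, hi),
            rhat={}, ess={}, converged=converged, n_subjects=10,
            transform=TransformRecord(0, 1, 0, 1),
            subject_slope_means=pd.Series(dtype=float),
            subject_slope_ols=pd.Series(dtype=float))

    def test_positive_interval_is_increasing_changer(self):
        t = decide_changers([self._summary(0.2, 0.9)])
        assert bool(t["changer"].iloc[0]) and t["direction"].iloc[0] == "Increasing"

    def test_interval_containing_zero_is_not_changer(self):
        t = decide_changers([self._summary(-0.3, 0.4)])
        assert t["changer"].iloc[0] == False  # noqa: E712

    def test_unconverged_decision_withheld(self):
        t = decide_changers([self._summary(0.2, 0.9, converged=False)])
        assert pd.isna(t["changer"].iloc[0])
        assert not t["converged"].iloc[0]


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available for the JAGS cross-check")
def test_posterior_matches_jags_reference(tmp_path):
    """Dual-route check: the in-package sampler against JAGS on one fixture."""
    md = generate_cohort(scaled_design(25, seed=5))
    data = generate_feature_matrix(
        md, [FeatureSpec("f", mu1=-0.3, sigma1=0.15, sigma=0.3, nu=5)], seed=6)
    y, x, subj = data.feature_arrays("f")
    s = fit_robust_hier(y, x, subj,
                        mcmc=MCMCConfig(n_chains=3, n_draws=6000, n_burn=1500,
                                        seed=7))
    yz, xz, _ = ztransform(y, x)
    codes = pd.Categorical(subj).codes + 1
    fixture = tmp_path / "fixture.csv"
    pd.DataFrame({"y": yz, "x": xz, "s": codes}).to_csv(fixture, index=False)
    script = tmp_path / "check.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(rjags))
        d <- read.csv("{fixture}")
        model <- "model {{
          for (i in 1:N) {{
            y[i] ~ dt(b0[s[i]] + b1[s[i]] * x[i], 1/sigma^2, nu)
          }}
          for (j in 1:S) {{
            b0[j] ~ dnorm(mu0, 1/sigma0^2)
            b1[j] ~ dnorm(mu1, 1/sigma1^2)
          }}
          mu0 ~ dnorm(0, 1/100); mu1 ~ dnorm(0, 1/100)
          sigma ~ dunif(0.001, 1000); sigma0 ~ dunif(0.001, 1000)
          sigma1 ~ dunif(0.001, 1000)
          nuMinusOne ~ dexp(1/29); nu <- nuMinusOne + 1
        }}"
        jm <- jags.model(textConnection(model),
                         data=list(y=d$y, x=d$x, s=d$s, N=nrow(d), S=max(d$s)),
                         n.chains=3, n.adapt=1500, quiet=TRUE)
        update(jm, 1500)
        samp <- coda.samples(jm, c("mu1"), n.iter=6000)
        m <- as.matrix(samp)
        cat(mean(m[,"mu1"]), sd(m[,"mu1"]), sep="\\n")
    """))
    res = subprocess.run(["Rscript", str(script)], capture_output=True,
                         text=True, timeout=300)
    assert res.returncode == 0, res.stderr
    jags_mean, jags_sd = (float(v) for v in res.stdout.strip().split("\n")[-2:])
    ours = s.flat("mu1")
    assert ours.mean() == pytest.approx(jags_mean, abs=0.5 * jags_sd)
    assert ours.std() == pytest.approx(jags_sd, rel=0.25)
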