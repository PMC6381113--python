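"""NMR preprocessing: exclusion, binning, PQN, Pareto, batch-bias removal."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from altimet import (
    BatchDesign,
    PeakLayout,
    SpectrumSet,
    bin_spectra,
    exclude_region,
    generate_spectra,
    pareto_scale,
    pqn_normalize,
    remove_batch_bias,
)
from altimet.nmr import BinnedMatrix

from conftest import scaled_design
from altimet import generate_cohort


def make_spectra(intensities, lo=0.0, hi=10.0):
    intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
    axis = np.linspace(hi, lo, intensities.shape[1])  # decreasing
    ids = [f"s{i}" for i in range(intensities.shape[0])]
    return SpectrumSet(axis, intensities, ids)


def make_binned(values):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    frame = pd.DataFrame(values, index=[f"s{i}" for i in range(values.shape[0])],
                         columns=[f"b{j}" for j in range(values.shape[1])])
    return BinnedMatrix(np.arange(values.shape[1], dtype=float), frame)


class TestExcludeRegion:
    def test_retained_points_inside_window(self):
        spec = make_spectra(np.random.default_rng(0).random((3, 500)), -0.5, 10)
        out = exclude_region(spec, (0.5, 4.5))
        assert out.ppm_axis.min() >= 0.5 and out.ppm_axis.max() <= 4.5
        assert (np.diff(out.ppm_axis) < 0).all()  # order preserved

    def test_full_window_is_identity(self):
        spec = make_spectra(np.random.default_rng(1).random((2, 100)))
        out = exclude_region(spec, (-1, 11))
        np.testing.assert_array_equal(out.intensities, spec.intensities)

    def test_disjoint_window_rejected(self):
        spec = make_spectra(np.ones((2, 10)))
        with pytest.raises(ValueError):
            exclude_region(spec, (100, 200))


class TestBinning:
    def test_12030_points_give_1203_bins(self):
        spec = make_spectra(np.zeros((2, 12030)), 0.5, 4.51)
        assert bin_spectra(spec, 10).values.shape[1] == 1203

    def test_single_block_of_constant_value(self):
        out = bin_spectra(make_spectra(np.full((1, 10), 7.5)), 10)
        assert out.values.shape == (1, 1)
        assert out.values.iloc[0, 0] == pytest.approx(7.5)

    def test_matches_block_mean_loop_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.random((3, 101))
        out = bin_spectra(make_spectra(x), 10)
        # independent oracle: explicit loop over non-overlapping blocks
        expected = np.array([[row[10 * k:10 * (k + 1)].mean() for k in range(10)]
                             for row in x])
        np.testing.assert_allclose(out.values.to_numpy(), expected)
        assert out.values.shape[1] == 10  # trailing point dropped

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValueError):
            bin_spectra(make_spectra(np.ones((1, 10))), 0)


class TestPQN:
    def test_scaled_sample_factor_and_restoration(self):
        rng = np.random.default_rng(7)
        ref = rng.random(50) + 0.5
        X = np.vstack([ref, ref, ref, ref, 3 * ref])
        out, factors = pqn_normalize(make_binned(X))
        assert factors.iloc[-1] == pytest.approx(3.0)
        np.testing.assert_allclose(out.values.iloc[-1].to_numpy(), ref, rtol=1e-12)

    def test_identical_samples_are_left_untouched(self):
        X = np.tile(np.linspace(1, 2, 30), (4, 1))
        out, factors = pqn_normalize(make_binned(X))
        np.testing.assert_allclose(factors.to_numpy(), 1.0)
        np.testing.assert_allclose(out.values.to_numpy(), X)

    def test_factors_match_median_of_ratios_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.random((6, 40)) + 0.1
        binned = make_binned(X)
        out, factors = pqn_normalize(binned)
        # independent oracle: integral step then median of pointwise ratios
        totals = X.sum(axis=1)
        X1 = X / (totals / np.median(totals))[:, None]
        ref = np.median(X1, axis=0)
        expected = []
        for i in range(X.shape[0]):
            ratios = [X1[i, j] / ref[j] for j in range(X.shape[1]) if ref[j] > 0]
            expected.append((totals[i] / np.median(totals)) * np.median(ratios))
        np.testing.assert_allclose(factors.to_numpy(), expected, rtol=1e-12)

    def test_fixed_target_gives_exact_dilution_invariance(self):
        rng = np.random.default_rng(9)
        X = rng.random((5, 30)) + 0.1
        base, _ = pqn_normalize(make_binned(X), target_total=100.0)
        for i, c in [(0, 17.0), (2, 0.03), (4, 2.5)]:
            Y = X.copy()
            Y[i] *= c
            out, _ = pqn_normalize(make_binned(Y), target_total=100.0)
            np.testing.assert_allclose(out.values.to_numpy(),
                                       base.values.to_numpy(), atol=1e-9)

    def test_zero_sample_named_in_error(self):
        X = np.vstack([np.ones(10), np.zeros(10)])
        with pytest.raises(ValueError, match="s1"):
            pqn_normalize(make_binned(X))

    def test_permutation_equivariance_with_binning(self):
        rng = np.random.default_rng(11)
        X = rng.random((5, 60)) + 0.2
        spec = make_spectra(X)
        out, _ = pqn_normalize(bin_spectra(spec, 10), target_total=50.0)
        perm = [3, 1, 4, 0, 2]
        spec_p = SpectrumSet(spec.ppm_axis, X[perm],
                             [spec.sample_ids[i] for i in perm])
        out_p, _ = pqn_normalize(bin_spectra(spec_p, 10), target_total=50.0)
        np.testing.assert_allclose(out_p.values.to_numpy(),
                                   out.values.to_numpy()[perm], rtol=1e-12)


class TestPareto:
    def test_sd_nine_column_scales_to_sd_three(self, rng):
        x = rng.normal(0, 1, size=200)
        x = (x - x.mean()) / x.std(ddof=1) * 9.0  # exact SD 9
        out = pareto_scale(make_binned(x[:, None]))
        assert out.values.iloc[:, 0].std(ddof=1) == pytest.approx(3.0)

    def test_constant_column_maps_to_zero(self):
        out = pareto_scale(make_binned(np.full((5, 1), 4.2)))
        np.testing.assert_array_equal(out.values.to_numpy(), 0.0)

    def test_centered_unit_sd_column_unchanged(self, rng):
        x = rng.normal(size=100)
        x = (x - x.mean()) / x.std(ddof=1)
        out = pareto_scale(make_binned(x[:, None]))
        np.testing.assert_allclose(out.values.iloc[:, 0].to_numpy(), x, rtol=1e-9)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_column_means_are_zero(self, seed):
        X = np.random.default_rng(seed).random((6, 8))
        out = pareto_scale(make_binned(X))
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-9)


def _planted_bias_setup(bias_amplitude, seed=0, n_subjects=30, n_points=600):
    md = generate_cohort(scaled_design(n_subjects, seed=seed))
    layout = PeakLayout.default(n_peaks=10, seed=3, n_points=n_points)
    spec = generate_spectra(md, layout,
                            BatchDesign(bias_amplitude=bias_amplitude),
                            seed=seed + 1, noise_sd=0.01)
    return md, bin_spectra(spec, 10)


def _explained_ss(X, z):
    """Sum of squares of X explained by the centered regressor z."""
    z = z - z.mean()
    coef = z @ X / (z @ z)
    return float(np.sum((np.outer(z, coef)) ** 2))


class TestBatchBiasRemoval:
    def test_planted_bias_is_removed(self):
        md, binned = _planted_bias_setup(bias_amplitude=0.5, seed=5)
        out, report = remove_batch_bias(binned, md, seed=6)
        z = (md["batch"].to_numpy() == "B2").astype(float)
        pre = _explained_ss(binned.values.to_numpy(), z)
        post = _explained_ss(out.values.to_numpy(), z)
        assert report["n_components"] >= 1
        assert post < 0.05 * pre

    def test_altitude_signal_preserved(self):
        md, binned = _planted_bias_setup(bias_amplitude=0.5, seed=7)
        out, _ = remove_batch_bias(binned, md, seed=8)
        a = md["altitude_km"].to_numpy(dtype=float)
        pre = _explained_ss(binned.values.to_numpy(), a)
        post = _explained_ss(out.values.to_numpy(), a)
        assert post > 0.90 * pre

    def test_no_bias_is_near_identity(self):
        md, binned = _planted_bias_setup(bias_amplitude=0.0, seed=9)
        out, report = remove_batch_bias(binned, md, seed=10)
        assert report["n_components"] == 0
        np.testing.assert_allclose(out.values.to_numpy(),
                                   binned.values.to_numpy(), atol=1e-8)

    def test_reported_variance_fraction_matches_construction(self, rng):
        # rank-1 structure planted directly into iid noise residuals
        n, p = 80, 120
        noise = rng.normal(0, 1.0, size=(n, p))
        u = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        v = rng.normal(0, 1.0, size=p)
        bias = np.outer(u, v) * 0.6
        X = noise + bias
        md = pd.DataFrame({
            "sample": [f"s{i}" for i in range(n)],
            "subject": [f"sub{i}" for i in range(n)],
            "location": "LDN",
            "altitude_km": rng.normal(2.0, 1.0, size=n),
            "batch": np.where(np.arange(n) % 2 == 0, "B1", "B2"),
        })
        frame = pd.DataFrame(X, index=md["sample"])
        binned = BinnedMatrix(np.arange(p, dtype=float), frame)
        out, report = remove_batch_bias(binned, md, seed=12)
        # construction oracle for the planted leading-component fraction
        resid = X - np.outer(np.ones(n), X.mean(axis=0))  # approx known-effects
        planted_frac = np.sum(bias**2) / np.sum(resid**2)
        assert report["n_components"] >= 1
        assert report["variance_fractions"][0] == pytest.approx(
            planted_frac, abs=0.05)

    def test_single_batch_is_noop_with_warning(self):
        md, binned = _planted_bias_setup(bias_amplitude=0.0, seed=13)
        md = md.assign(batch="B1")
        with pytest.warns(UserWarning):
            out, report = remove_batch_bias(binned, md)
        assert report["n_components"] == 0
        pd.testing.assert_frame_equal(out.values, binned.values)

    def test_sample_and_bin_counts_preserved(self):
        md, binned = _planted_bias_setup(bias_amplitude=0.4, seed=14)
        out, _ = remove_batch_bias(binned, md, seed=15)
        assert out.values.shape == binned.values.shape
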