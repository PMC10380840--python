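"""Inversion pipeline: normalisation, spectra, background tuning, MC fit."""

import numpy as np
import pytest
from dataclasses import replace

from deerkin.errors import FitFailureError, InvalidInputError
from deerkin.forward import (
    BackgroundParams,
    DeerTrace,
    DistanceDistribution,
    GaussianComponent,
    compose_trace,
    distribution_kernel,
    inter_signal,
)
from deerkin.inverse import (
    FitResult,
    NormalizedTrace,
    classify_artifact_components,
    cosine_ft,
    fit_multigauss_mc,
    invert_trace,
    normalize,
    scan_chi2_dispersion,
    tune_background,
    zero_frequency_artifact,
)
from deerkin.synthetic import NoiseSpec, gen_deer


class TestNormalize:
    def test_noiseless_forward_trace_maps_to_kernel(self, bimodal_truth, t_grid):
        # after background division, normalisation maps 1 - lam*<cos>
        # exactly onto <cos>
        tr = compose_trace(bimodal_truth, 0.3, BackgroundParams(0.0, 1.0), 1.0, t_grid)
        norm = normalize(tr.t_us, tr.signal)
        kern = distribution_kernel(bimodal_truth, t_grid)
        # the tail-plateau estimate differs from the exact V(inf) by the
        # residual kernel oscillation in the averaging window
        assert np.max(np.abs(norm.v_n - kern)) < 5e-3
        assert norm.v_n[0] == 1.0

    def test_lambda_cancels(self, bimodal_truth, t_grid):
        norms = []
        for lam in (0.2, 0.4):
            tr = compose_trace(
                bimodal_truth, lam, BackgroundParams(0.0, 1.0), 1.0, t_grid
            )
            norms.append(normalize(tr.t_us, tr.signal).v_n)
        assert np.max(np.abs(norms[0] - norms[1])) < 1e-6

    def test_flat_trace_rejected(self, t_grid):
        with pytest.raises(FitFailureError):
            normalize(t_grid, np.ones_like(t_grid))


class TestCosineFT:
    def test_pure_cosine_peaks_at_its_frequency(self, t_grid):
        vn = np.cos(2 * np.pi * 0.5 * t_grid)
        spec = cosine_ft(NormalizedTrace(t_grid, vn))
        peak = spec.freq_mhz[np.argmax(spec.amplitude)]
        df = spec.freq_mhz[1] - spec.freq_mhz[0]
        assert abs(peak - 0.5) <= df

    def test_zero_signal_gives_zero_spectrum(self, t_grid):
        spec = cosine_ft(NormalizedTrace(t_grid, np.zeros_like(t_grid)))
        assert np.allclose(spec.amplitude, 0.0)

    def test_resolution_follows_padded_span(self, t_grid):
        spec = cosine_ft(NormalizedTrace(t_grid, np.zeros_like(t_grid)))
        dt = t_grid[1] - t_grid[0]
        m = 4 * t_grid.size
        assert spec.freq_mhz[1] == pytest.approx(1.0 / (2 * (m - 1) * dt))

    def test_nonuniform_grid_rejected(self):
        t = np.array([0.0, 0.01, 0.05, 0.2])
        with pytest.raises(InvalidInputError):
            cosine_ft(NormalizedTrace(t, np.zeros(4)))


class TestZeroFrequencyArtifact:
    def test_definition(self):
        amp = np.array([2.0, 9.0, 0.5, 0.5, 0.5, 0.5, 0.5, 0.0])
        spec = type("S", (), {})()
        from deerkin.inverse import PakeSpectrum

        spec = PakeSpectrum(np.arange(8.0), amp)
        assert zero_frequency_artifact(spec) == pytest.approx(1.5)
        amp2 = amp.copy()
        amp2[0] = 0.5
        assert zero_frequency_artifact(PakeSpectrum(np.arange(8.0), amp2)) == 0.0

    def test_too_short_spectrum_rejected(self):
        from deerkin.inverse import PakeSpectrum

        with pytest.raises(InvalidInputError):
            zero_frequency_artifact(PakeSpectrum(np.arange(4.0), np.zeros(4)))

    def test_correct_background_beats_misset_exponent(
        self, bimodal_truth, t_grid
    ):
        trace = gen_deer(bimodal_truth, noise=NoiseSpec.from_snr(100, seed=3))
        metrics = {}
        for xi in (1.03, 1.33):
            from deerkin.inverse import _fit_tail_background

            alpha, c = _fit_tail_background(trace.t_us, trace.signal, xi)
            v_intra = trace.signal * np.exp(alpha * trace.t_us**xi - c)
            spec = cosine_ft(normalize(trace.t_us, v_intra))
            metrics[xi] = zero_frequency_artifact(spec)
        assert metrics[1.03] < metrics[1.33]


class TestTuneBackground:
    def test_recovers_zero_alpha(self, bimodal_truth, t_grid):
        tr = compose_trace(bimodal_truth, 0.3, BackgroundParams(0.0, 1.0), 1.0, t_grid)
        alpha, xi, _ = tune_background(tr)
        assert alpha < 5e-3

    def test_removes_tail_slope(self, bimodal_truth, t_grid):
        trace = gen_deer(
            bimodal_truth,
            bg=BackgroundParams(alpha=0.1, xi=1.0),
            noise=NoiseSpec.from_snr(100, seed=5),
        )
        alpha, xi, v_intra = tune_background(trace)
        n_tail = len(trace) // 4
        before = np.polyfit(trace.t_us[-n_tail:], trace.signal[-n_tail:], 1)[0]
        after = np.polyfit(trace.t_us[-n_tail:], v_intra[-n_tail:], 1)[0]
        # relative tail slope: background removal should kill >= 99% of it
        assert abs(after / np.mean(v_intra[-n_tail:])) < 0.01 * abs(
            before / np.mean(trace.signal[-n_tail:])
        ) + 1e-4

    def test_short_trace_rejected(self):
        t = np.arange(32) * 0.012
        with pytest.raises(InvalidInputError):
            tune_background(DeerTrace(t, np.ones(32)))


class TestMultiGaussFit:
    def test_input_validation(self, t_grid):
        norm = NormalizedTrace(t_grid, np.zeros_like(t_grid))
        with pytest.raises(InvalidInputError):
            fit_multigauss_mc(norm, n_components=4)
        with pytest.raises(InvalidInputError):
            fit_multigauss_mc(norm, n_iter=50)
        with pytest.raises(InvalidInputError):
            fit_multigauss_mc(norm, snr=0.0)

    def test_noiseless_delta_like_component(self, t_grid):
        # near-delta distribution: mean recovered to +-0.02 nm and the
        # spurious third component stays below 4%
        p = DistanceDistribution.from_arrays([1.0], [4.2], [0.05])
        vn = distribution_kernel(p, t_grid)
        fit = fit_multigauss_mc(
            NormalizedTrace(t_grid, vn), n_components=3, seed=2, n_iter=50_000
        )
        dom = fit.distribution.components[0]
        assert dom.r_mean == pytest.approx(4.2, abs=0.02)
        assert min(c.fraction for c in fit.distribution.components) < 0.04

    def test_fractions_sum_to_one_and_sorted(self, bimodal_truth, t_grid):
        vn = distribution_kernel(bimodal_truth, t_grid)
        fit = fit_multigauss_mc(
            NormalizedTrace(t_grid, vn), n_components=3, seed=4, n_iter=50_000
        )
        fr = [c.fraction for c in fit.distribution.components]
        assert sum(fr) == pytest.approx(1.0, abs=1e-9)
        assert fr == sorted(fr, reverse=True)

    def test_deterministic_under_seed(self, t_grid):
        p = DistanceDistribution.from_arrays([1.0], [4.0], [0.3])
        vn = distribution_kernel(p, t_grid)
        norm = NormalizedTrace(t_grid, vn)
        f1 = fit_multigauss_mc(norm, seed=9, n_iter=5_000)
        f2 = fit_multigauss_mc(norm, seed=9, n_iter=5_000)
        assert f1.distribution == f2.distribution


class TestChi2Surface:
    def test_truth_beats_displaced_mean(self, bimodal_truth, t_grid):
        # chi2 of the generating parameters is below chi2 with one mean
        # displaced by +0.3 nm, for 10 noise realisations
        displaced = DistanceDistribution.from_arrays(
            [0.25, 0.75], [3.94, 4.90], [0.36, 0.34]
        )
        bg = BackgroundParams(0.1, 1.03)
        vinter = inter_signal(bg, t_grid)
        base = compose_trace(bimodal_truth, 0.3, bg, 1.0, t_grid).signal
        kern_truth = distribution_kernel(bimodal_truth, t_grid)
        kern_disp = distribution_kernel(displaced, t_grid)
        spec_truth = cosine_ft(NormalizedTrace(t_grid, kern_truth)).amplitude
        spec_disp = cosine_ft(NormalizedTrace(t_grid, kern_disp)).amplitude
        for seed in range(10):
            rng = np.random.default_rng(seed)
            noisy = base + rng.normal(0, 1, t_grid.size) * (0.3 * vinter / 100)
            vn = normalize(t_grid, noisy / vinter).v_n
            spec = cosine_ft(NormalizedTrace(t_grid, vn)).amplitude
            chi_truth = np.sum((spec - spec_truth) ** 2)
            chi_disp = np.sum((spec - spec_disp) ** 2)
            assert chi_truth < chi_disp

    def test_dispersion_uncertainty_small_at_high_snr(self, t_grid):
        p = DistanceDistribution.from_arrays([1.0], [4.2], [0.35])
        vn = distribution_kernel(p, t_grid)
        norm = NormalizedTrace(t_grid, vn)
        fit = fit_multigauss_mc(norm, n_components=1, seed=3, n_iter=20_000)
        unc100 = scan_chi2_dispersion(norm, fit, snr=100.0)
        assert unc100[0] <= 0.05
        # halving the SNR (doubling noise std) widens the interval
        unc50 = scan_chi2_dispersion(norm, fit, snr=50.0)
        assert unc50[0] > unc100[0]

    def test_scan_requires_converged_fit(self, t_grid):
        p = DistanceDistribution.from_arrays([1.0], [4.2], [0.35])
        norm = NormalizedTrace(t_grid, distribution_kernel(p, t_grid))
        bad = FitResult(
            distribution=p, chi2=1e9, converged=False, seed=0, n_iter=100
        )
        with pytest.raises(InvalidInputError):
            scan_chi2_dispersion(norm, bad, snr=100.0)


class TestArtifactClassification:
    def _fit_with(self, comps):
        dist = DistanceDistribution(tuple(comps))
        return FitResult(distribution=dist, chi2=0.0, converged=True, seed=0,
                         n_iter=100)

    def test_small_fraction_and_window_flagged(self):
        fit = self._fit_with([
            GaussianComponent(0.73, 4.60, 0.34),
            GaussianComponent(0.24, 3.94, 0.36),
            GaussianComponent(0.03, 2.70, 0.10),
        ])
        out = classify_artifact_components(fit)
        assert out.artifact_flags == (False, False, True)
        head = out.headline_distribution
        assert sum(c.fraction for c in head.components) == pytest.approx(1.0, abs=1e-9)
        assert len(head.components) == 2

    def test_window_overrides_large_fraction(self):
        fit = self._fit_with([
            GaussianComponent(0.9, 4.5, 0.3),
            GaussianComponent(0.1, 2.65, 0.1),
        ])
        assert classify_artifact_components(fit).artifact_flags == (False, True)

    def test_clean_fit_unchanged(self):
        fit = self._fit_with([
            GaussianComponent(0.76, 4.60, 0.34),
            GaussianComponent(0.24, 3.94, 0.36),
        ])
        out = classify_artifact_components(fit)
        assert out.artifact_flags == (False, False)
        assert out.headline_distribution == fit.distribution


class TestFullPipeline:
    def test_noiseless_round_trip_exact(self, bimodal_truth, noiseless_trace):
        fit = invert_trace(noiseless_trace, seed=1, n_iter=50_000)
        assert fit.xi_best == pytest.approx(1.03, abs=0.005)
        assert fit.alpha_best == pytest.approx(0.1, abs=0.002)
        assert fit.lam_best == pytest.approx(0.3, abs=0.005)
        head = sorted(fit.headline_distribution.components, key=lambda c: c.r_mean)
        assert head[0].r_mean == pytest.approx(3.94, abs=0.02)
        assert head[1].r_mean == pytest.approx(4.60, abs=0.02)
        assert head[1].fraction == pytest.approx(0.75, abs=0.02)

    def test_lambda_invariance_of_recovered_distribution(
        self, bimodal_truth, t_grid, default_bg
    ):
        doms = []
        for lam in (0.2, 0.5):
            tr = compose_trace(bimodal_truth, lam, default_bg, 1.0, t_grid)
            fit = invert_trace(tr, seed=1, n_iter=30_000)
            doms.append(
                max(fit.headline_distribution.components, key=lambda c: c.fraction)
            )
        assert doms[0].r_mean == pytest.approx(doms[1].r_mean, abs=0.02)
        assert doms[0].fraction == pytest.approx(doms[1].fraction, abs=0.02)
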