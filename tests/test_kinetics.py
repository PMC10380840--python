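"""Mass-action simulation and the kinetic fitting routines."""

import numpy as np
import pytest

from deerkin.errors import FitFailureError, InvalidInputError
from deerkin.kinetics import (
    EP_KOFF_DEFAULT,
    ExpFitResult,
    FretTrace,
    MstModelParams,
    ObservableCoefficients,
    ProductCurveParams,
    Scheme1Params,
    SpeciesTrajectory,
    fit_mst_eq8,
    fit_multiexp,
    fit_product_eq6,
    fret_observable,
    global_fit_scheme1,
    simulate_scheme1,
)
from deerkin.presets import RATE_CONSTANTS, WT_STOPPED_FLOW_PHASES
from deerkin.synthetic import NoiseSpec, gen_fret_traces


class TestScheme1Params:
    def test_ka_consistency(self):
        p = Scheme1Params(k1=29.0, k_minus1=12.0, kcat=13.0, kp=4.0)
        assert p.ka == pytest.approx(29.0 / 12.0, rel=1e-12)
        q = Scheme1Params.from_ka(k1=29.0, ka=p.ka, kcat=13.0, kp=4.0)
        assert q.k_minus1 == pytest.approx(12.0, rel=1e-9)

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidInputError):
            Scheme1Params(k1=-1.0, k_minus1=1.0, kcat=1.0, kp=1.0)


class TestSimulate:
    def test_binding_equilibrium_matches_ka(self):
        # kcat = 0: detailed balance gives [ES]/([E][S]) = Ka
        p = Scheme1Params.from_ka(k1=0.9, ka=0.9, kcat=0.0, kp=10.0)
        traj = simulate_scheme1(p, 2.0, 1.0, np.linspace(1e-3, 200.0, 100))
        ratio = traj.es[-1] / (traj.e[-1] * traj.s[-1])
        assert ratio == pytest.approx(0.9, rel=0.01)

    def test_irreversible_catalysis_exhausts_substrate(self):
        traj = simulate_scheme1(
            RATE_CONSTANTS["E260A"], 2.0, 1.0, np.geomspace(1e-3, 500.0, 200)
        )
        assert traj.ep[-1] + traj.p[-1] == pytest.approx(1.0, abs=1e-3)

    def test_no_enzyme_means_no_reaction(self):
        traj = simulate_scheme1(
            RATE_CONSTANTS["E260A"], 0.0, 1.0, np.linspace(1e-3, 10.0, 50)
        )
        assert np.allclose(traj.p, 0.0, atol=1e-12)
        assert np.allclose(traj.s, 1.0, atol=1e-9)

    @pytest.mark.parametrize("mutant", sorted(RATE_CONSTANTS))
    def test_mass_conservation(self, mutant):
        traj = simulate_scheme1(
            RATE_CONSTANTS[mutant], 1.5, 1.0, np.geomspace(1e-3, 200.0, 150)
        )
        assert np.max(np.abs(traj.e + traj.es + traj.ep - 1.5)) < 1e-6
        assert np.max(np.abs(traj.s + traj.es + traj.ep + traj.p - 1.0)) < 1e-6

    def test_preequilibrium_limit_product_rate(self):
        # fast binding at fixed Ka: product forms single-exponentially with
        # rate ~ kcat * Ka E0 / (1 + Ka E0)
        ka, kcat, e0 = 0.9, 1.0, 2.0
        p = Scheme1Params.from_ka(k1=500.0, ka=ka, kcat=kcat, kp=1e6)
        t = np.geomspace(1e-3, 20.0, 200)
        traj = simulate_scheme1(p, e0, 0.02, t)
        frac = (traj.ep + traj.p) / 0.02
        expected = kcat * ka * e0 / (1.0 + ka * e0)
        # fit single exponential to the product curve
        fit = fit_multiexp(
            FretTrace(time_s=t, signal=1.0 - frac, e0=e0, s0=0.02), n_phases=1
        )
        assert fit.rates[0] == pytest.approx(expected, rel=0.05)

    def test_ep_offrate_sensitivity_documented(self):
        # only the EP equilibrium Kp is constrained by the data, so the
        # off-rate is a modelling assumption.  In the fast-release regime
        # (>= 50 1/s, i.e. >> kcat) the observable is insensitive to it;
        # at 10 1/s (only ~2.5 x kcat) transient deviations grow to the
        # ten-percent level, which bounds how slow an off-rate the default
        # can tolerate.
        truth = RATE_CONSTANTS["E260A"]
        t = np.geomspace(1e-3, 200.0, 200)
        coeff = ObservableCoefficients()
        sigs = {}
        for koff in (10.0, 50.0, 200.0):
            traj = simulate_scheme1(truth, 2.0, 1.0, t, ep_koff=koff)
            sigs[koff] = fret_observable(traj, coeff).signal
        amp = sigs[50.0].max() - sigs[50.0].min()
        assert np.max(np.abs(sigs[50.0] - sigs[200.0])) < 0.05 * amp
        assert np.max(np.abs(sigs[10.0] - sigs[200.0])) < 0.20 * amp

    def test_conservation_validator(self):
        t = np.linspace(0.0, 1.0, 5)
        with pytest.raises(InvalidInputError):
            SpeciesTrajectory(
                time_s=t, e=np.ones(5), s=np.ones(5), es=np.zeros(5),
                ep=np.zeros(5), p=np.zeros(5), e0=2.0, s0=1.0,
            )


class TestFretObservable:
    def test_equal_coefficients_give_constant_signal(self):
        traj = simulate_scheme1(
            RATE_CONSTANTS["N253G"], 1.0, 1.0, np.geomspace(1e-3, 50.0, 100)
        )
        c = ObservableCoefficients(f_s=2.0, f_es=2.0, f_ep=2.0, f_p=2.0)
        tr = fret_observable(traj, c, offset=0.5)
        assert np.max(np.abs(tr.signal - (0.5 + 2.0 * 1.0))) < 1e-6

    def test_default_coefficients_dip_then_rise(self):
        traj = simulate_scheme1(
            RATE_CONSTANTS["N253G"], 2.0, 1.0, np.geomspace(1e-4, 100.0, 300)
        )
        tr = fret_observable(traj, ObservableCoefficients(), offset=0.0)
        i_min = int(np.argmin(tr.signal))
        assert 0 < i_min < tr.signal.size - 1
        assert tr.signal[-1] > tr.signal[0] > tr.signal[i_min]


class TestMultiExp:
    def test_wild_type_phases_recovered_exactly(self):
        t = np.geomspace(1e-3, 5.0, 200)
        y = sum(a * np.exp(-k * t) for a, k in WT_STOPPED_FLOW_PHASES)
        fit = fit_multiexp(FretTrace(t, y, 2.0, 1.0), n_phases=2)
        (a1, k1), (a2, k2) = fit.phases
        assert k1 == pytest.approx(91.0, rel=1e-4)
        assert a1 == pytest.approx(-0.42, rel=1e-4)
        assert k2 == pytest.approx(20.0, rel=1e-4)
        assert a2 == pytest.approx(1.63, rel=1e-4)

    def test_single_phase_residual_near_machine_noise(self):
        t = np.geomspace(1e-3, 5.0, 120)
        y = 0.8 * np.exp(-3.0 * t) + 0.1
        fit = fit_multiexp(FretTrace(t, y, 1.0, 1.0), n_phases=1)
        assert fit.rss < 1e-16

    def test_constant_data_gives_zero_amplitudes(self):
        t = np.geomspace(1e-3, 5.0, 60)
        fit = fit_multiexp(FretTrace(t, np.full(60, 2.5), 1.0, 1.0), n_phases=1)
        assert abs(fit.amplitudes[0]) < 1e-6
        assert fit.baseline == pytest.approx(2.5, abs=1e-6)

    def test_invariant_to_phase_ordering(self):
        t = np.geomspace(1e-3, 5.0, 200)
        for order in ((0, 1), (1, 0)):
            phases = [WT_STOPPED_FLOW_PHASES[i] for i in order]
            y = sum(a * np.exp(-k * t) for a, k in phases)
            fit = fit_multiexp(FretTrace(t, y, 1.0, 1.0), n_phases=2)
            assert fit.rates[0] == pytest.approx(91.0, rel=1e-4)

    def test_input_validation(self):
        t = np.geomspace(1e-3, 5.0, 15)
        tr = FretTrace(t, np.ones(15), 1.0, 1.0)
        with pytest.raises(InvalidInputError):
            fit_multiexp(tr, n_phases=2)  # needs >= 20 points
        with pytest.raises(InvalidInputError):
            fit_multiexp(tr, n_phases=0)


class TestGlobalFit:
    def test_noiseless_recovery_at_truth(self):
        truth = RATE_CONSTANTS["E260A"]
        traces = gen_fret_traces(truth, noise=None)
        params, info = global_fit_scheme1(
            traces, ka_fixed=truth.ka, seed=0, n_starts=4
        )
        assert params.kcat == pytest.approx(truth.kcat, rel=0.02)
        assert params.k1 == pytest.approx(truth.k1, rel=0.05)
        assert info["rss"] < 1e-6

    def test_requires_three_distinct_concentrations(self):
        truth = RATE_CONSTANTS["E260A"]
        traces = gen_fret_traces(truth, e0_list=(1.0, 1.0, 1.0), noise=None)
        with pytest.raises(InvalidInputError):
            global_fit_scheme1(traces, ka_fixed=0.9)

    def test_kcat_recovery_stable_over_noise_seeds(self):
        # median relative error of kcat across seeds stays below 10%
        truth = RATE_CONSTANTS["E260A"]
        errs = []
        for seed in range(3):
            traces = gen_fret_traces(truth, noise=NoiseSpec(0.01, seed=seed))
            p, _ = global_fit_scheme1(traces, ka_fixed=0.9, seed=1, n_starts=2)
            errs.append(abs(p.kcat - truth.kcat) / truth.kcat)
        assert np.median(errs) <= 0.10


class TestProductCurve:
    def test_noiseless_exact_recovery(self):
        truth = ProductCurveParams(amplitude=80.0, k_obs=0.09, k_lin=0.0)
        t = np.linspace(1.0, 120.0, 25)
        fit = fit_product_eq6(t, truth(t))
        assert fit.amplitude == pytest.approx(80.0, rel=1e-6)
        assert fit.k_obs == pytest.approx(0.09, rel=1e-6)

    def test_plateau_equals_amplitude(self):
        truth = ProductCurveParams(amplitude=60.0, k_obs=0.5, k_lin=0.0)
        assert truth(1e3) == pytest.approx(60.0)

    def test_pure_linear_data(self):
        t = np.linspace(0.0, 100.0, 20)
        fit = fit_product_eq6(t, 0.3 * t)
        assert fit.k_lin == pytest.approx(0.3, rel=1e-3)
        assert fit.amplitude * (1 - np.exp(-fit.k_obs * 100.0)) < 0.5

    def test_validation(self):
        with pytest.raises(InvalidInputError):
            fit_product_eq6(np.arange(4), np.arange(4.0))
        with pytest.raises(InvalidInputError):
            ProductCurveParams(amplitude=120.0, k_obs=0.1)


class TestMstIsotherm:
    def test_half_amplitude_at_inverse_ka(self):
        m = MstModelParams(f_backgr=10.0, f_ampl=40.0, ka=2.0)
        assert m(0.5) == pytest.approx(10.0 + 20.0)

    def test_saturation_limit(self):
        m = MstModelParams(f_backgr=10.0, f_ampl=40.0, ka=2.0)
        assert m(1e6) == pytest.approx(50.0, rel=1e-4)

    def test_noiseless_recovery_three_significant_digits(self):
        truth = MstModelParams(f_backgr=100.0, f_ampl=50.0, ka=0.9)
        c = np.geomspace(0.1, 10.0, 12)
        fit = fit_mst_eq8(c, truth(c))
        assert fit.ka == pytest.approx(0.9, rel=1e-3)

    def test_validation(self):
        with pytest.raises(InvalidInputError):
            fit_mst_eq8(np.array([1, 2, 3.0]), np.array([1, 2, 3.0]))
        with pytest.raises(InvalidInputError):
            fit_mst_eq8(np.linspace(1.0, 2.0, 8), np.ones(8))  # < 1 decade
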