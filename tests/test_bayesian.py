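"""Base-function set, phase derivatives, windowed Bayesian inference and
coupling-strength reduction."""

import numpy as np
import pytest

from ecpipe import (
    BaseFunctionSet, CouplingSpec, InferenceConfig, OscillatorSpec,
    all_pairs, coupling_strength, infer_pair, phase_derivative,
    simulate_phases,
)
from ecpipe.bayesian import CouplingEstimate
from ecpipe.errors import ConfigError, LengthError
from ecpipe.wavelet import BAND_I, PhaseSeries

FS = 10.0


class TestBaseFunctionSet:
    @pytest.mark.parametrize("order,count", [(1, 9), (2, 25), (3, 49)])
    def test_term_count_is_square(self, order, count):
        assert BaseFunctionSet(order).n_terms == count

    def test_design_shape_and_constant(self):
        base = BaseFunctionSet(2)
        phi = np.linspace(0, 10, 100)
        P = base.design(phi, 2 * phi)
        assert P.shape == (100, 25)
        np.testing.assert_array_equal(P[:, 0], 1.0)

    def test_derivative_matches_finite_difference(self):
        base = BaseFunctionSet(2)
        rng = np.random.default_rng(0)
        phi1, phi2 = rng.uniform(0, 2 * np.pi, (2, 50))
        eps = 1e-6
        for wrt in (0, 1):
            D = base.derivative(phi1, phi2, wrt)
            d1 = (phi1 + eps, phi1)[wrt], (phi1, phi1)[0]
            if wrt == 0:
                num = (base.design(phi1 + eps, phi2)
                       - base.design(phi1 - eps, phi2)) / (2 * eps)
            else:
                num = (base.design(phi1, phi2 + eps)
                       - base.design(phi1, phi2 - eps)) / (2 * eps)
            np.testing.assert_allclose(D, num, atol=1e-6)

    def test_shared_trig_path_matches_separate(self):
        base = BaseFunctionSet(2)
        rng = np.random.default_rng(1)
        phi1, phi2 = rng.uniform(0, 20, (2, 64))
        P, vsum = base.design_and_derivative_sums(phi1, phi2)
        np.testing.assert_allclose(P, base.design(phi1, phi2))
        np.testing.assert_allclose(
            vsum[0], base.derivative(phi1, phi2, 0).sum(axis=0)
        )
        np.testing.assert_allclose(
            vsum[1], base.derivative(phi1, phi2, 1).sum(axis=0)
        )

    def test_involvement_masks(self):
        base = BaseFunctionSet(2)
        m0, m1 = base.involves(0), base.involves(1)
        assert not m0[0] and not m1[0]  # constant never involved
        # pure-self terms of phi_1 (k2 == 0) not in phi_2's mask
        labels = base.term_labels()
        i = labels.index("sin(1*phi1+0*phi2)")
        assert m0[i] and not m1[i]
        # joint terms count for both
        j = labels.index("sin(1*phi1+1*phi2)")
        assert m0[j] and m1[j]


class TestPhaseDerivative:
    def test_linear_phase_exact(self):
        t = np.arange(0, 100, 1 / FS)
        dphi, mid = phase_derivative(0.6 * t, FS)
        np.testing.assert_allclose(dphi, 0.6, atol=1e-9)
        assert mid.size == t.size - 1

    def test_quadratic_phase_midpoint_exact(self):
        # for a quadratic, the forward difference IS the midpoint slope
        t = np.arange(0, 100, 1 / FS)
        phi = 0.3 * t**2
        dphi, mid = phase_derivative(phi, FS)
        t_mid = (t[1:] + t[:-1]) / 2
        np.testing.assert_allclose(dphi, 0.6 * t_mid, atol=1e-9)

    def test_single_sample_rejected(self):
        with pytest.raises(LengthError):
            phase_derivative(np.array([1.0]), FS)


class TestCouplingStrength:
    def _estimate(self, c):
        base = BaseFunctionSet(2)
        return CouplingEstimate(
            c=c, E=np.eye(2), windows=c[None], base=base, fs=FS
        )

    def test_single_cross_coefficient(self):
        base = BaseFunctionSet(2)
        c = np.zeros((2, base.n_terms))
        i = base.term_labels().index("sin(1*phi1-1*phi2)")
        c[1, i] = 0.3  # phi_1's influence on phi_2
        assert coupling_strength(self._estimate(c), "1->2") == 0.3
        assert coupling_strength(self._estimate(c), "2->1") == 0.0

    def test_pythagorean_norm(self):
        base = BaseFunctionSet(2)
        labels = base.term_labels()
        c = np.zeros((2, base.n_terms))
        c[0, labels.index("sin(0*phi1+1*phi2)")] = 0.3
        c[0, labels.index("cos(1*phi1+2*phi2)")] = 0.4
        assert coupling_strength(self._estimate(c), "2->1") == pytest.approx(
            0.5
        )

    def test_zero_coefficients_zero_strength(self):
        c = np.zeros((2, 25))
        est = self._estimate(c)
        assert coupling_strength(est, "1->2") == 0.0

    def test_constant_and_self_terms_excluded(self):
        base = BaseFunctionSet(2)
        labels = base.term_labels()
        c = np.zeros((2, base.n_terms))
        c[1, 0] = 0.8  # constant (omega)
        c[1, labels.index("sin(0*phi1+1*phi2)")] = 0.7  # phi_2 self term
        assert coupling_strength(self._estimate(c), "1->2") == 0.0


class TestInferPair:
    def test_noiseless_uncoupled_recovers_omegas(self):
        specs = [OscillatorSpec(0.06, noise_sd=0.0),
                 OscillatorSpec(0.13, noise_sd=0.0)]
        ph = simulate_phases(specs, [], 600, FS, seed=0)
        est = infer_pair(ph[0], ph[1], FS)
        np.testing.assert_allclose(
            est.omega, 2 * np.pi * np.array([0.06, 0.13]), atol=1e-3
        )
        assert est.strength_12 < 1e-6 and est.strength_21 < 1e-6

    def test_directed_coupling_recovered(self):
        specs = [OscillatorSpec(0.06, noise_sd=0.05),
                 OscillatorSpec(0.13, noise_sd=0.05)]
        ph = simulate_phases(
            specs, [CouplingSpec(2, 1, 0.3)], 600, FS, seed=1
        )
        est = infer_pair(ph[0], ph[1], FS)
        labels = est.base.term_labels()
        coef = est.c[0, labels.index("sin(1*phi1-1*phi2)")]
        # injected 0.3*sin(phi2 - phi1) == -0.3*sin(phi1 - phi2)
        assert coef == pytest.approx(-0.3, rel=0.2)
        assert est.strength_21 > est.strength_12
        assert est.strength_12 < 0.05

    def test_relabelling_swaps_strengths(self):
        specs = [OscillatorSpec(0.07, noise_sd=0.1),
                 OscillatorSpec(0.12, noise_sd=0.1)]
        ph = simulate_phases(
            specs, [CouplingSpec(1, 2, 0.2)], 400, FS, seed=2
        )
        a = infer_pair(ph[0], ph[1], FS)
        b = infer_pair(ph[1], ph[0], FS)
        assert a.strength_12 == pytest.approx(b.strength_21, rel=1e-9)
        assert a.strength_21 == pytest.approx(b.strength_12, rel=1e-9)

    def test_null_strength_shrinks_with_record_length(self):
        meds = {}
        for dur in (300, 1200):
            vals = []
            for seed in range(8):
                specs = [OscillatorSpec(0.07, noise_sd=0.1),
                         OscillatorSpec(0.12, noise_sd=0.1)]
                ph = simulate_phases(specs, [], dur, FS, seed=100 + seed)
                est = infer_pair(ph[0], ph[1], FS)
                vals.append(max(est.strength_12, est.strength_21))
            meds[dur] = np.median(vals)
        assert meds[1200] < meds[300]

    def test_unequal_lengths_rejected(self):
        with pytest.raises(LengthError):
            infer_pair(np.zeros(100), np.zeros(99), FS)

    def test_window_identifiability_guard(self):
        with pytest.raises(ConfigError):
            InferenceConfig(window_s=10.0).validate(FS)


class TestAllPairs:
    def _phases(self, n_ch, duration=150):
        rng = np.random.default_rng(5)
        freqs = rng.uniform(0.06, 0.13, n_ch)
        specs = [OscillatorSpec(float(f), noise_sd=0.05) for f in freqs]
        ph = simulate_phases(specs, [], duration, FS, seed=6)
        return PhaseSeries(phases=ph, band=BAND_I, fs=FS)

    @pytest.mark.parametrize("n_ch,expected", [(2, 2), (6, 30)])
    def test_directed_pair_count(self, n_ch, expected):
        cm = all_pairs(self._phases(n_ch))
        assert cm.n_directed == expected

    def test_diagonal_undefined(self):
        cm = all_pairs(self._phases(3))
        assert np.all(np.isnan(np.diag(cm.strengths)))
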