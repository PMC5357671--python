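"""Surrogate auditory-nerve-fiber generator: rates, phase locking, refractoriness."""

import math

import numpy as np
import pytest
from scipy import integrate, special

from gbcsim import (ANFParams, ToneProtocol, generate_anf_train,
                    generate_population, rate_envelope, vector_strength,
                    vs_to_concentration)
from gbcsim.metrics import pooled_metrics


# ----------------------------------------------------------------------
class TestRateEnvelope:
    def test_silence_is_spontaneous_rate(self, anf, silence_protocol):
        env = rate_envelope(silence_protocol, anf)
        t = np.linspace(0, 1.0, 100)
        assert np.allclose(env(t), anf.spont_rate)

    def test_long_tone_converges_to_driven_steady_state(self, anf):
        proto = ToneProtocol(cf=500.0, level_db=60.0, tone_duration=1.0,
                             repetition_period=1.2, n_repetitions=1)
        env = rate_envelope(proto, anf)
        r_mid = env(np.array([0.9]))[0]
        assert r_mid == pytest.approx(anf.driven_rate(60.0), rel=0.01)

    def test_cycle_integral_matches_quadrature_oracle(self, anf):
        """Spike count per cycle agrees with quadrature of the piecewise form."""
        proto = ToneProtocol.fitting_train(650.0)
        env = rate_envelope(proto, anf)

        def oracle(t):
            # independent scalar transcription of the envelope pieces
            d, rd = proto.tone_duration, proto.ramp_duration
            r_ss = anf.driven_rate(proto.level_db)
            peak = anf.onset_peak_rate
            if t <= d:
                if t < rd:
                    gate = math.sin(0.5 * math.pi * t / rd) ** 2
                elif t > d - rd:
                    gate = math.sin(0.5 * math.pi * (d - t) / rd) ** 2
                else:
                    gate = 1.0
                a = anf.adapt_rapid_fraction
                adapted = r_ss + (peak - r_ss) * (
                    a * math.exp(-t / anf.adapt_tau_rapid)
                    + (1 - a) * math.exp(-t / anf.adapt_tau_short))
                return anf.spont_rate + gate * (adapted - anf.spont_rate)
            s = t - d
            return anf.spont_rate * (
                1 - anf.offset_suppression * math.exp(-s / anf.offset_tau))

        expected, _ = integrate.quad(oracle, 0.0, proto.repetition_period,
                                     limit=500)
        t = np.linspace(0, proto.repetition_period, 200001)
        got = np.trapezoid(env(t), t)
        assert got == pytest.approx(expected, rel=1e-3)

    def test_envelope_nonnegative_and_spont_before_zero(self, anf):
        proto = ToneProtocol.sweep_train(500.0, 3)
        env = rate_envelope(proto, anf)
        t = np.linspace(-0.05, proto.duration + 0.05, 5000)
        r = env(t)
        assert np.all(r >= 0)
        assert np.allclose(r[t < 0], anf.spont_rate)

    def test_rejects_invalid_params(self):
        with pytest.raises(ValueError):
            ANFParams(spont_rate=-5.0)
        with pytest.raises(ValueError):
            ANFParams(adapt_tau_rapid=math.nan)


# ----------------------------------------------------------------------
class TestVsToConcentration:
    def test_zero_target_gives_uniform_phase(self):
        assert vs_to_concentration(0.0) == 0.0

    def test_monotone_in_target(self):
        assert vs_to_concentration(0.8) > vs_to_concentration(0.5)

    def test_target_rejected_at_one(self):
        with pytest.raises(ValueError):
            vs_to_concentration(1.0)

    def test_quadrature_oracle(self):
        """Resultant length of the von Mises density at kappa equals the target."""
        kappa = vs_to_concentration(0.7)
        num, _ = integrate.quad(
            lambda th: math.cos(th) * math.exp(kappa * math.cos(th)),
            -math.pi, math.pi)
        den, _ = integrate.quad(
            lambda th: math.exp(kappa * math.cos(th)), -math.pi, math.pi)
        assert num / den == pytest.approx(0.7, abs=1e-9)


# ----------------------------------------------------------------------
class TestGenerateTrain:
    def test_spontaneous_rate_matches(self, anf, silence_protocol):
        st = generate_anf_train(silence_protocol, anf, seed=11, duration=100.0)
        assert st.rate == pytest.approx(50.0, abs=3.0)

    def test_no_modulation_gives_unlocked_train(self):
        anf = ANFParams(vs_curve={500.0: 0.0})
        proto = ToneProtocol.sweep_train(500.0, 50)
        st = generate_anf_train(proto, anf, seed=5)
        vs = vector_strength(st.times, 500.0, proto.tone_windows())
        n = np.count_nonzero(st.times < proto.duration)
        # Rayleigh statistic 2 n VS^2 ~ chi2(2) under no locking
        assert 2 * n * vs**2 < 12.0

    def test_vs_hits_target_monte_carlo(self):
        """Measured VS within +/-0.05 of the 0.8 target (>=10 seeds)."""
        anf = ANFParams(vs_curve={500.0: 0.8})
        proto = ToneProtocol.sweep_train(500.0, 100)
        vss = []
        for seed in range(10):
            st = generate_anf_train(proto, anf, seed=seed)
            vss.append(vector_strength(st.times, 500.0, proto.tone_windows()))
        assert np.mean(vss) == pytest.approx(0.8, abs=0.05)

    @pytest.mark.parametrize("seed", [0, 7])
    def test_refractoriness_never_violated(self, anf, seed):
        proto = ToneProtocol.sweep_train(1000.0, 20)
        st = generate_anf_train(proto, anf, seed=seed)
        assert np.diff(st.times).min() >= anf.abs_refractory

    def test_fixed_seed_is_bit_identical(self, anf):
        proto = ToneProtocol.fitting_train(650.0, 10)
        a = generate_anf_train(proto, anf, seed=42)
        b = generate_anf_train(proto, anf, seed=42)
        assert np.array_equal(a.times, b.times)

    def test_silence_requires_duration(self, anf, silence_protocol):
        with pytest.raises(ValueError):
            generate_anf_train(silence_protocol, anf, seed=0)


class TestGeneratePopulation:
    def test_singleton_equals_spawned_train(self, anf):
        proto = ToneProtocol.fitting_train(500.0, 5)
        ss = np.random.SeedSequence(3)
        pop = generate_population(proto, anf, 1, np.random.SeedSequence(3))
        direct = generate_anf_train(proto, anf, ss.spawn(1)[0])
        assert np.array_equal(pop[0].times, direct.times)

    def test_fibers_are_distinct(self, anf):
        proto = ToneProtocol.fitting_train(500.0, 5)
        pop = generate_population(proto, anf, 40, seed=1)
        assert len(pop) == 40
        assert len({tuple(np.round(p.times, 9)) for p in pop}) == 40

    def test_pooled_spontaneous_rate_superposition(self, anf, silence_protocol):
        """40 independent 50 sp/s fibers pool to 2000 +/- 90 sp/s over 10 s."""
        pop = generate_population(silence_protocol, anf, 40, seed=9,
                                  duration=10.0)
        total = sum(len(p) for p in pop) / 10.0
        assert total == pytest.approx(2000.0, abs=90.0)

    def test_rejects_empty_population(self, anf, silence_protocol):
        with pytest.raises(ValueError):
            generate_population(silence_protocol, anf, 0, seed=0)
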