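import numpy as np
import pytest

import avfpulse as ap
from avfpulse.spectral import BandConfig, PixelTrace, power_spectrum

FPS = 40.0
NFFT = 256
T = np.arange(NFFT) / FPS  # bin width 40/256 = 0.15625 Hz


def tone(freq, amp=1.0, phase=0.0, n=NFFT):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / FPS + phase)


def trace(samples):
    return PixelTrace(samples, FPS)


class TestBandPass:
    def test_in_band_on_grid_tone_unchanged(self):
        x = tone(2.5)  # bin 16, inside 1-5 Hz
        out = ap.band_pass(trace(x), (1.0, 5.0))
        np.testing.assert_allclose(out.samples, x, atol=1e-9)

    def test_out_of_band_tone_blocked(self):
        x = tone(12.5)  # bin 80, outside 1-5 Hz
        out = ap.band_pass(trace(x), (1.0, 5.0))
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-9)

    def test_mixture_keeps_only_in_band_component(self):
        out = ap.band_pass(trace(tone(2.5) + tone(12.5, amp=3.0)), (1.0, 5.0))
        np.testing.assert_allclose(out.samples, tone(2.5), atol=1e-9)

    def test_band_plus_complement_reconstructs(self, rng):
        x = rng.normal(size=NFFT)
        lo = ap.band_pass(trace(x), (0.0, 5.0)).samples
        hi = ap.band_pass(trace(x), (5.0 + 1e-9, FPS / 2)).samples
        np.testing.assert_allclose(lo + hi, x, atol=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            ap.band_pass(trace(np.zeros(100)), (1.0, 5.0))
        with pytest.raises(ValueError, match="Nyquist"):
            ap.band_pass(trace(np.zeros(NFFT)), (1.0, 25.0))


class TestPowers:
    def test_parseval_consistency(self, rng):
        for _ in range(20):
            x = rng.normal(size=NFFT)
            _, p = power_spectrum(x, FPS, demean=False)
            assert p.sum() == pytest.approx(np.mean(x**2), abs=1e-9)

    def test_zero_trace_gives_zero_powers(self):
        z = trace(np.zeros(NFFT))
        assert ap.signal_power(z) == 0.0
        assert ap.noise_power(z) == 0.0

    def test_pure_tone_signal_power_is_half_amplitude_squared(self):
        # one-sided power of an on-grid tone of amplitude a is a^2/2
        a = 3.0
        avfs = ap.signal_power(trace(tone(2.5, amp=a)))
        assert avfs == pytest.approx(a**2 / 2, rel=1e-9)

    def test_out_of_band_tone_contributes_no_signal_power(self):
        assert ap.signal_power(trace(tone(12.5))) == pytest.approx(0.0, abs=1e-12)

    def test_second_harmonic_counted_even_above_band_edge(self):
        # fundamental at 3.125 Hz (bin 20); 2nd harmonic 6.25 Hz (bin 40)
        # lies above the 5 Hz band edge but still belongs to the pulse
        x = tone(3.125, amp=2.0) + tone(6.25, amp=1.0)
        avfs, f0 = ap.signal_power(trace(x), return_freq=True)
        assert f0 == pytest.approx(3.125)
        assert avfs == pytest.approx(2.0**2 / 2 + 1.0**2 / 2, rel=1e-9)

    def test_noise_power_sums_two_largest_bins(self):
        x = tone(12.5, amp=2.0) + tone(15.0, amp=1.0)  # bins 80 and 96
        avfn = ap.noise_power(trace(x))
        assert avfn == pytest.approx(2.0**2 / 2 + 1.0**2 / 2, rel=1e-9)

    def test_single_noise_tone(self):
        avfn = ap.noise_power(trace(tone(12.5, amp=2.0)))
        assert avfn == pytest.approx(2.0, rel=1e-6)

    def test_dc_offset_ignored(self):
        x = tone(2.5, amp=1.0) + 120.0
        assert ap.signal_power(trace(x)) == pytest.approx(0.5, rel=1e-9)

    def test_band_config_validation(self):
        with pytest.raises(ValueError, match="Nyquist"):
            BandConfig(noise_band=(10.0, 21.0)).validate(FPS)
        with pytest.raises(ValueError, match="disjoint"):
            BandConfig(signal_band=(1.0, 12.0)).validate(FPS)


class TestSweep:
    def _uniform_stack(self, x, h=9, w=9):
        return ap.ScalarStack(np.tile(x[:, None, None], (1, h, w)),
                              "luminance", FPS)

    def test_spatially_uniform_stack_ratio_independent_of_n(self):
        x = tone(2.5) + tone(12.5, amp=0.5) + tone(15.0, amp=0.25)
        stack = self._uniform_stack(x)
        res = ap.snavf_sweep(stack, (4, 4), sizes=[1, 3, 5, 7, 9])
        np.testing.assert_allclose(res.ratio, res.ratio[0], rtol=1e-9)
        assert res.optimal_n == 1  # tie broken toward the smallest kernel

    def test_sweep_matches_filter_then_extract_route(self, rng):
        stack = ap.ScalarStack(rng.normal(120, 5, size=(NFFT, 11, 11)),
                               "luminance", FPS)
        sizes = [1, 3, 5, 7]
        res = ap.snavf_sweep(stack, (5, 5), sizes=sizes)
        for i, n in enumerate(sizes):
            tr = ap.extract_trace(stack, 5, 5, n)
            avfs = ap.signal_power(tr)
            avfn = ap.noise_power(tr)
            assert res.avfs[i] == pytest.approx(avfs, rel=1e-9)
            assert res.avfn[i] == pytest.approx(avfn, rel=1e-9)
            assert res.ratio[i] == pytest.approx(avfs / avfn, rel=1e-9)

    def test_snavf_is_max_and_optimal_n_attains_it(self, rng):
        stack = ap.ScalarStack(rng.normal(120, 5, size=(NFFT, 15, 15)),
                               "luminance", FPS)
        res = ap.snavf_sweep(stack, (7, 7), sizes=[1, 3, 5, 7, 9, 11])
        assert res.snavf == res.ratio.max()
        assert res.ratio[list(res.sizes).index(res.optimal_n)] == res.snavf

    def test_scale_invariance_of_ratio(self, rng):
        vals = rng.normal(120, 5, size=(NFFT, 7, 7))
        a = ap.snavf_sweep(ap.ScalarStack(vals, "luminance", FPS), (3, 3),
                           sizes=[1, 3])
        b = ap.snavf_sweep(ap.ScalarStack(vals * 7.5, "luminance", FPS), (3, 3),
                           sizes=[1, 3])
        np.testing.assert_allclose(a.ratio, b.ratio, rtol=1e-9)

    def test_noise_free_input_yields_infinite_sentinel(self):
        stack = self._uniform_stack(tone(2.5))
        with pytest.warns(UserWarning, match="infinite"):
            res = ap.snavf_sweep(stack, (4, 4), sizes=[1])
        assert np.isinf(res.ratio[0])

    def test_roi_outside_valid_region(self):
        stack = self._uniform_stack(tone(2.5))
        with pytest.raises(ValueError, match="valid region"):
            ap.snavf_sweep(stack, (0, 0), sizes=[1, 5])

    def test_result_export(self, tmp_path, rng):
        import json

        import pandas as pd

        stack = ap.ScalarStack(rng.normal(120, 5, size=(NFFT, 7, 7)),
                               "luminance", FPS)
        res = ap.snavf_sweep(stack, (3, 3), sizes=[1, 3, 5])
        df = pd.read_csv(res.to_csv(tmp_path / "sweep.csv"))
        assert list(df.columns)[:4] == ["N", "AVFs", "AVFn", "ratio"]
        summary = json.loads((res.to_json(tmp_path / "s.json")).read_text())
        assert {"optimal_N", "SNAVF"} <= set(summary)


class TestPhaseOpposition:
    def test_self_and_negation(self):
        x = tone(2.5) + tone(3.125, amp=0.5)
        assert ap.phase_opposition(trace(x), trace(x)) == pytest.approx(1.0)
        assert ap.phase_opposition(trace(x), trace(-x)) == pytest.approx(-1.0)

    def test_out_of_band_noise_does_not_mask_opposition(self, rng):
        x = tone(2.5)
        noisy_a = x + tone(12.5, amp=5.0)
        noisy_b = -x + tone(15.0, amp=5.0)
        r = ap.phase_opposition(trace(noisy_a), trace(noisy_b))
        assert r == pytest.approx(-1.0, abs=1e-6)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            ap.phase_opposition(trace(np.zeros(NFFT)), trace(tone(2.5)))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            ap.phase_opposition(trace(tone(2.5)), trace(tone(2.5, n=300)))
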