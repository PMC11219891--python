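import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgkit import (
    FirDesignSpec,
    LinearFilter,
    NoiseSpec,
    add_noise,
    apply_filter,
    baseline_highpass,
    baseline_lowpass,
    comb_lowpass,
    convolve,
    denoise,
    equiripple_fir,
    freq_response,
    generate_record,
    make_rhythm,
    weighted_error,
    window_fir,
)
from ecgkit.filters import amplitude_response


def dirichlet_mag(N, f, fs):
    """Independent closed form |sin(N w/2) / sin(w/2)| for the N-tap moving sum."""
    w = 2 * np.pi * f / fs
    if abs(np.sin(w / 2)) < 1e-15:
        return float(N)
    return abs(np.sin(N * w / 2) / np.sin(w / 2))


class TestConvolve:
    def test_impulse_sifting(self, rng):
        h = rng.normal(size=7)
        np.testing.assert_allclose(convolve([1, 0, 0], h)[:7], h)

    def test_direct_arithmetic(self):
        np.testing.assert_allclose(convolve([1, 2], [3, 4]), [3, 10, 8])

    def test_commutative(self, rng):
        for _ in range(5):
            x, h = rng.normal(size=9), rng.normal(size=4)
            np.testing.assert_allclose(convolve(x, h), convolve(h, x))


class TestFreqResponse:
    def test_identity_filter(self):
        f = LinearFilter(b=[1.0], a=[1.0], fs=100.0)
        fr = freq_response(f, np.linspace(0, 50, 11))
        np.testing.assert_allclose(fr.H, 1.0)

    def test_moving_sum_zero_at_fs_over_10(self):
        c = comb_lowpass(10, 1, fs=480.0)
        assert abs(freq_response(c, [48.0]).H[0]) < 1e-10

    def test_moving_sum_matches_dirichlet_closed_form(self, rng):
        c = comb_lowpass(10, 1, fs=480.0)
        freqs = rng.uniform(0.0, 240.0, size=500)
        mags = freq_response(c, freqs).magnitude()
        expect = [dirichlet_mag(10, f, 480.0) for f in freqs]
        np.testing.assert_allclose(mags, expect, atol=1e-8)

    def test_removable_dc_pole_evaluates_to_dc_gain(self):
        c = comb_lowpass(10, 1, fs=480.0)
        fr = freq_response(c, [0.0])
        assert not fr.singular[0]
        assert fr.H[0] == pytest.approx(10.0)

    def test_true_singularity_flagged(self):
        # pole at z = 1 with no cancelling zero
        f = LinearFilter(b=[1.0], a=[1.0, -1.0], fs=100.0)
        fr = freq_response(f, [0.0, 25.0])
        assert fr.singular[0] and not fr.singular[1]


class TestCombFamily:
    @pytest.mark.parametrize("order,gain", [(1, 10.0), (2, 100.0)])
    def test_dc_gain(self, order, gain):
        c = comb_lowpass(10, order, fs=480.0)
        assert freq_response(c, [0.0]).H[0] == pytest.approx(gain)

    def test_integer_coefficients(self):
        for filt in (comb_lowpass(10, 2, 480.0), baseline_lowpass(240, 480.0),
                     baseline_highpass(240, fs=480.0)):
            assert np.all(filt.b == np.round(filt.b))
            assert np.all(filt.a == np.round(filt.a))

    def test_baseline_lowpass_impulse_response_is_ones(self):
        lp = baseline_lowpass(240, fs=480.0)
        imp = np.zeros(300)
        imp[0] = 1.0
        y = apply_filter(lp, imp)
        np.testing.assert_allclose(y[:240], 1.0)
        np.testing.assert_allclose(y[240:], 0.0, atol=1e-12)

    def test_baseline_lowpass_null_at_2hz(self):
        lp = baseline_lowpass(240, fs=480.0)
        assert abs(freq_response(lp, [2.0]).H[0]) < 1e-9


class TestBaselineHighpass:
    def test_dc_gain_exactly_zero(self):
        hp = baseline_highpass(240, fs=480.0)
        assert abs(freq_response(hp, [0.0]).H[0]) < 1e-12
        assert hp.as_fir().sum() == pytest.approx(0.0, abs=1e-12)

    def test_impulse_coefficient_at_delay_by_polynomial_expansion(self):
        # oracle: expand z^-120 - (1/240)(1 - z^-240)/(1 - z^-1) by explicit
        # polynomial long division of the comb term
        comb_fir = np.ones(240) / 240.0  # (1 - z^-240)/(1 - z^-1) / 240
        expect = -comb_fir
        expect[120] += 1.0
        hp = baseline_highpass(240, fs=480.0)
        np.testing.assert_allclose(hp.as_fir(), expect, atol=1e-15)
        assert hp.as_fir()[120] == pytest.approx(1 - 1 / 240)

    def test_passband_gain_near_one_at_50hz(self):
        # comb sidelobe magnitude at 50 Hz is 1/(240 sin(pi 50/480)); the
        # high-pass is within that of unity
        hp = baseline_highpass(240, fs=480.0)
        mag = abs(freq_response(hp, [50.0]).H[0])
        assert mag == pytest.approx(1.0, rel=0.02)

    def test_constant_input_rejected_after_transient(self):
        hp = baseline_highpass(240, fs=480.0)
        y = apply_filter(hp, np.ones(1000))
        np.testing.assert_allclose(y[300:], 0.0, atol=1e-10)

    def test_odd_m_rejected(self):
        with pytest.raises(ValueError, match="even"):
            baseline_highpass(241, fs=480.0)


class TestApply:
    def test_identity(self, rng):
        x = rng.normal(size=64)
        ident = LinearFilter(b=[1.0], a=[1.0], fs=100.0)
        np.testing.assert_array_equal(apply_filter(ident, x), x)

    def test_comb_impulse_response_equals_squared_polynomial(self):
        # oracle: coefficients of (1 + z^-1 + ... + z^-9)^2 by polynomial
        # multiplication
        expect = np.convolve(np.ones(10), np.ones(10))
        imp = np.zeros(40)
        imp[0] = 1.0
        y = apply_filter(comb_lowpass(10, 2, 480.0), imp)
        np.testing.assert_allclose(y[:19], expect, atol=1e-10)
        np.testing.assert_allclose(y[19:], 0.0, atol=1e-10)

    @pytest.mark.parametrize("f_hz", [5.0, 20.0, 60.0])
    def test_sinusoid_steady_state_gain_matches_response(self, f_hz):
        filt = comb_lowpass(7, 1, fs=360.0)
        t = np.arange(8000) / 360.0
        x = np.sin(2 * np.pi * f_hz * t)
        y = apply_filter(filt, x)[4000:]
        # amplitude via complex demodulation (robust to peak sampling)
        ph = np.exp(-2j * np.pi * f_hz * t[4000:])
        ss = 2 * abs(np.mean(y * ph))
        expect = abs(freq_response(filt, [f_hz]).H[0])
        assert ss == pytest.approx(expect, rel=0.01)

    def test_fir_and_rational_forms_agree(self, rng):
        for filt in (comb_lowpass(10, 1, 480.0), comb_lowpass(10, 2, 480.0),
                     baseline_highpass(48, fs=480.0)):
            x = rng.normal(size=2000)
            y_iir = apply_filter(filt, x)
            fir = LinearFilter(b=filt.as_fir(), a=[1.0], fs=filt.fs)
            y_fir = apply_filter(fir, x)
            np.testing.assert_allclose(y_iir[100:], y_fir[100:], atol=1e-9)


class TestWindowFir:
    def test_symmetric_taps(self):
        spec = FirDesignSpec.lowpass(20, 40, 360, 31)
        h = window_fir(spec, "hamming").b
        np.testing.assert_allclose(h, h[::-1], atol=1e-15)

    def test_rectangular_lowpass_equals_sampled_sinc(self):
        # ideal LPF at cutoff fc: h[k] = 2 fc/fs sinc(2 fc (k - alpha)/fs);
        # with a single passband [0, fc] the design reduces to exactly that
        fc, fs, M = 30.0, 360.0, 41
        spec = FirDesignSpec(bands=[(0.0, fc, 1.0, 1.0)], numtaps=M, fs=fs)
        h = window_fir(spec, "rectangular").b
        k = np.arange(M) - (M - 1) / 2
        expect = 2 * fc / fs * np.sinc(2 * fc * k / fs)
        np.testing.assert_allclose(h, expect, atol=1e-12)

    def test_dc_gain_near_one_for_long_lowpass(self):
        spec = FirDesignSpec.lowpass(30, 50, 360, 51)
        filt = window_fir(spec, "hamming")
        assert abs(freq_response(filt, [0.0]).H[0]) == pytest.approx(1.0, rel=0.01)

    def test_unsupported_window_listed(self):
        spec = FirDesignSpec.lowpass(20, 40, 360, 31)
        with pytest.raises(ValueError, match="supported"):
            window_fir(spec, "kaiser-nope")


class TestWeightedError:
    def test_zero_when_candidate_matches_desired(self):
        spec = FirDesignSpec(bands=[(0.0, 180.0, 1.0, 1.0)], numtaps=1, fs=360)
        ident = LinearFilter(b=[1.0], a=[1.0], fs=360)
        E, emax = weighted_error(ident, spec)
        assert emax < 1e-12

    def test_hand_arithmetic_on_three_point_grid(self):
        # E = W (Hd - H*): [1*(1-0.9), 1*(1-1.1), 10*(0-0.2)] -> max 2.0
        W = np.array([1.0, 1.0, 10.0])
        Hd = np.array([1.0, 1.0, 0.0])
        Hstar = np.array([0.9, 1.1, 0.2])
        E = W * (Hd - Hstar)
        assert np.max(np.abs(E)) == pytest.approx(2.0)

    def test_amplitude_response_is_real_zero_phase(self):
        spec = FirDesignSpec.lowpass(20, 40, 360, 31)
        filt = window_fir(spec, "hamming")
        f = np.linspace(0, 180, 50)
        amp = amplitude_response(filt, f)
        fr = freq_response(filt, f)
        np.testing.assert_allclose(np.abs(amp), fr.magnitude(), atol=1e-9)


class TestEquiripple:
    def test_full_band_unity_gives_unit_impulse(self):
        spec = FirDesignSpec(bands=[(0.0, 180.0, 1.0, 1.0)], numtaps=21, fs=360)
        h = equiripple_fir(spec).b
        expect = np.zeros(21)
        expect[10] = 1.0
        np.testing.assert_allclose(h, expect, atol=1e-6)

    def test_beats_window_design_and_alternates(self):
        specs = [
            FirDesignSpec.lowpass(40, 60, 360, 31),
            FirDesignSpec.lowpass(50, 70, 500, 41),
            FirDesignSpec.lowpass(1, 5, 360, 51, w_pass=1, w_stop=10),
            FirDesignSpec(bands=[(0, 30, 1.0, 1.0), (45, 100, 0.0, 2.0)], numtaps=33, fs=250),
            FirDesignSpec(bands=[(0, 20, 0.0, 1.0), (35, 80, 1.0, 1.0), (95, 125, 0.0, 1.0)],
                          numtaps=41, fs=250),
        ]
        for spec in specs:
            eq = equiripple_fir(spec)
            wd = window_fir(spec, "hamming")
            _, e_eq = weighted_error(eq, spec)
            _, e_wd = weighted_error(wd, spec)
            assert e_eq <= e_wd + 1e-12
            E, delta = weighted_error(eq, spec)
            assert count_alternations(E, delta) >= (spec.numtaps - 1) // 2 + 2

    def test_coefficients_symmetric(self):
        spec = FirDesignSpec.lowpass(40, 60, 360, 31)
        h = equiripple_fir(spec).b
        np.testing.assert_allclose(h, h[::-1], atol=1e-12)


def count_alternations(E, delta):
    """Count sign-alternating error extrema reaching ~the ripple level."""
    idx = []
    for i in range(len(E)):
        if abs(E[i]) >= 0.95 * delta:
            if not idx or np.sign(E[i]) != np.sign(E[idx[-1]]):
                idx.append(i)
            elif abs(E[i]) > abs(E[idx[-1]]):
                idx[-1] = i
    return len(idx)


class TestDenoise:
    @staticmethod
    def _bin_power(x, fs, f):
        from scipy.signal import periodogram

        fr, P = periodogram(x, fs)
        return P[np.argmin(np.abs(fr - f))]

    def test_powerline_bin_reduced_40db(self):
        rec = generate_record(20.0, 500.0, make_rhythm(20.0, seed=3), seed=3)
        noisy = add_noise(rec, NoiseSpec(powerline=(50.0, 0.5, 1), seed=3))
        den = denoise(noisy, mode="iir", powerline_hz=50.0)
        before = self._bin_power(noisy.lead(), 500.0, 50.0)
        after = self._bin_power(den.lead(), 500.0, 50.0)
        assert 10 * np.log10(before / max(after, 1e-300)) >= 40.0

    def test_baseline_drift_reduced_20db(self):
        rec = generate_record(20.0, 500.0, make_rhythm(20.0, seed=3), seed=3)
        noisy = add_noise(rec, NoiseSpec(baseline=(0.5, 0.3), seed=3))
        den = denoise(noisy, mode="iir", powerline_hz=50.0)
        before = self._bin_power(noisy.lead(), 500.0, 0.3)
        after = self._bin_power(den.lead(), 500.0, 0.3)
        assert 10 * np.log10(before / max(after, 1e-300)) >= 20.0

    def test_annotations_stay_aligned(self):
        rec = generate_record(20.0, 500.0, make_rhythm(20.0, seed=4), seed=4)
        noisy = add_noise(rec, NoiseSpec(baseline=(0.5, 0.3), powerline=(50.0, 0.5, 1), seed=4))
        den = denoise(noisy, mode="iir", powerline_hz=50.0)
        x = den.lead()
        for idx, _ in den.annotations:
            lo = max(0, idx - 30)
            assert abs(lo + int(np.argmax(np.abs(x[lo:idx + 30]))) - idx) <= 1

    def test_clean_record_preserved_in_qrs_band(self):
        from scipy.signal import butter, filtfilt

        rec = generate_record(20.0, 500.0, make_rhythm(20.0, seed=5), seed=5)
        den = denoise(rec, mode="iir", powerline_hz=50.0)
        b, a = butter(4, [5 / 250, 40 / 250], btype="band")
        cb = filtfilt(b, a, rec.lead())
        db = filtfilt(b, a, den.lead())
        assert np.corrcoef(cb, db)[0, 1] >= 0.99

    def test_fir_and_iir_modes_agree(self):
        rec = generate_record(10.0, 500.0, make_rhythm(10.0, seed=6), seed=6)
        d_fir = denoise(rec, mode="fir", powerline_hz=50.0)
        d_iir = denoise(rec, mode="iir", powerline_hz=50.0)
        np.testing.assert_allclose(d_fir.samples, d_iir.samples, atol=1e-8)

    def test_notch_above_nyquist_rejected(self):
        rec = generate_record(2.0, 80.0, [], seed=0)
        with pytest.raises(ValueError, match="fs/2"):
            denoise(rec, powerline_hz=50.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=2, max_value=30), st.integers(min_value=1, max_value=2))
def test_comb_dc_gain_property(N, order):
    """DC gain of the running-sum comb is always N^order."""
    c = comb_lowpass(N, order, fs=10.0 * N)
    assert freq_response(c, [0.0]).H[0].real == pytest.approx(float(N) ** order)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_linear_phase_group_delay_constant(seed):
    """Window designs have exactly linear phase: group delay (M-1)/2 across
    the passband."""
    rng = np.random.default_rng(seed)
    M = int(rng.integers(11, 61)) | 1
    spec = FirDesignSpec.lowpass(40, 60, 360, M)
    filt = window_fir(spec, "hamming")
    f = np.linspace(1.0, 35.0, 40)
    fr = freq_response(filt, f)
    phase = np.unwrap(np.angle(fr.H))
    gd = -np.diff(phase) / np.diff(fr.omega)
    np.testing.assert_allclose(gd, (M - 1) / 2, atol=1e-6)
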