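"""FIR/IIR denoising filters: integer-coefficient combs, window and
equiripple FIR design, and the baseline/power-line denoise cascade.

The comb family is built from the running-sum kernel

    H(z) = (1 - z^-N) / (1 - z^-1)

whose zeros sit at multiples of fs/N (the pole at z = 1 cancels the DC
zero, so DC is passed with gain N).  A first-null-at-2-Hz instance of the
same kernel, subtracted from a pure delay, yields the baseline-wander
high-pass with exactly zero DC gain.  All comb coefficients are integers;
the 1/M normalisations are carried symbolically in a scale factor and
applied once at the output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "LinearFilter",
    "FirDesignSpec",
    "FrequencyResponse",
    "convolve",
    "freq_response",
    "comb_lowpass",
    "baseline_lowpass",
    "baseline_highpass",
    "apply_filter",
    "window_fir",
    "weighted_error",
    "equiripple_fir",
    "denoise",
]


@dataclass
class LinearFilter:
    """Rational transfer function scale * B(z)/A(z) at sampling rate fs.

    ``b``/``a`` are coefficient arrays ordered by increasing delay with
    a[0] = 1 after normalisation.  For the comb family the stored
    coefficients are integers and ``scale`` carries the 1/M gain
    normalisation.  ``group_delay`` is the nominal integer-or-half-integer
    delay in samples used for zero-phase compensation.
    """

    b: np.ndarray
    a: np.ndarray
    fs: float
    label: str = ""
    scale: float = 1.0
    group_delay: float = 0.0
    fir_equivalent: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        if self.b.size == 0:
            raise ValueError("numerator must be non-empty")
        if not (np.all(np.isfinite(self.b)) and np.all(np.isfinite(self.a))):
            raise ValueError("coefficients must be finite")
        if self.a[0] == 0:
            raise ValueError("a[0] must be nonzero")

    @property
    def is_fir(self) -> bool:
        return self.a.size == 1

    def as_fir(self) -> np.ndarray:
        """Expanded FIR impulse response (including scale), when one exists."""
        if self.fir_equivalent is not None:
            return self.fir_equivalent * self.scale
        if self.is_fir:
            return self.b * (self.scale / self.a[0])
        raise ValueError(f"filter {self.label!r} has no exact FIR expansion")

    def to_text(self) -> str:
        """Two-line plain-text export: b-line then a-line (scale folded into b)."""
        b = self.b * self.scale / self.a[0]
        a = self.a / self.a[0]
        return (" ".join(f"{v:.12g}" for v in b) + "\n"
                + " ".join(f"{v:.12g}" for v in a) + "\n")

    @classmethod
    def from_text(cls, text: str, fs: float, label: str = "") -> "LinearFilter":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        if len(lines) != 2:
            raise ValueError("expected two coefficient lines (b, a)")
        b = np.array([float(v) for v in lines[0].split()])
        a = np.array([float(v) for v in lines[1].split()])
        return cls(b=b, a=a, fs=fs, label=label)


@dataclass
class FirDesignSpec:
    """Piecewise-constant FIR design target.

    ``bands`` is a list of ``(f_lo, f_hi, desired, weight)`` tuples in Hz
    covering the regions where the response matters; gaps between bands are
    transition regions.  ``numtaps`` is the filter length M (odd for
    type-I linear phase).
    """

    bands: list[tuple[float, float, float, float]]
    numtaps: int
    fs: float

    def __post_init__(self) -> None:
        if self.numtaps < 1:
            raise ValueError("numtaps must be >= 1")
        prev_hi = -1.0
        for f_lo, f_hi, _, w in self.bands:
            if not (0 <= f_lo < f_hi <= self.fs / 2):
                raise ValueError("band edges must satisfy 0 <= lo < hi <= fs/2")
            if f_lo < prev_hi:
                raise ValueError("bands must be non-overlapping and sorted")
            if w <= 0:
                raise ValueError("weights must be positive")
            prev_hi = f_hi

    @classmethod
    def lowpass(cls, f_pass: float, f_stop: float, fs: float, numtaps: int,
                w_pass: float = 1.0, w_stop: float = 1.0) -> "FirDesignSpec":
        if not 0 < f_pass < f_stop < fs / 2:
            raise ValueError("need 0 < f_pass < f_stop < fs/2")
        return cls(bands=[(0.0, f_pass, 1.0, w_pass), (f_stop, fs / 2, 0.0, w_stop)],
                   numtaps=numtaps, fs=fs)

    def grid(self, points_per_band: int = 256):
        """Dense evaluation grid (Hz) excluding transition bands, plus the
        desired response and weight at each grid point."""
        freqs, desired, weights = [], [], []
        for f_lo, f_hi, d, w in self.bands:
            f = np.linspace(f_lo, f_hi, points_per_band)
            freqs.append(f)
            desired.append(np.full_like(f, d))
            weights.append(np.full_like(f, w))
        return np.concatenate(freqs), np.concatenate(desired), np.concatenate(weights)


@dataclass
class FrequencyResponse:
    """Complex response on a frequency grid, with singular points flagged."""

    freqs: np.ndarray
    H: np.ndarray
    omega: np.ndarray
    singular: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.singular is None:
            self.singular = np.zeros(len(self.freqs), dtype=bool)

    def magnitude(self) -> np.ndarray:
        return np.abs(self.H)

    def phase(self) -> np.ndarray:
        return np.angle(self.H)


def convolve(x, h) -> np.ndarray:
    """Full linear convolution, length len(x) + len(h) - 1."""
    x = np.asarray(x, dtype=float)
    h = np.asarray(h, dtype=float)
    if x.size == 0 or h.size == 0:
        raise ValueError("convolve requires non-empty inputs")
    return np.convolve(x, h)


def freq_response(filt: LinearFilter, freqs_hz) -> FrequencyResponse:
    """Evaluate scale * B/A at z = e^{j Omega}, Omega = 2 pi f / fs.

    Points where the denominator vanishes are handled by polynomial
    division: if A divides B exactly (a removable pole, as at DC for the
    combs) the quotient is evaluated instead; otherwise the point is
    flagged singular and reported as NaN.
    """
    freqs = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    if np.any(freqs < 0) or np.any(freqs > filt.fs / 2 + 1e-9):
        raise ValueError("frequencies must lie in [0, fs/2]")
    omega = 2 * np.pi * freqs / filt.fs
    z_inv = np.exp(-1j * omega)
    # polynomials in z^-1, coefficients ordered by increasing delay
    B = np.polyval(filt.b[::-1], z_inv)
    A = np.polyval(filt.a[::-1], z_inv)
    H = np.empty_like(B)
    singular = np.zeros(len(freqs), dtype=bool)
    tol = 1e-9 * max(1.0, np.abs(filt.a).sum())
    bad = np.abs(A) < tol
    H[~bad] = B[~bad] / A[~bad]
    if np.any(bad):
        q, r = np.polydiv(filt.b[::-1], filt.a[::-1])
        if np.allclose(r, 0, atol=1e-9 * max(1.0, np.abs(filt.b).max())):
            H[bad] = np.polyval(q, z_inv[bad])
        else:
            H[bad] = np.nan
            singular[bad] = True
    return FrequencyResponse(freqs=freqs, H=filt.scale * H, omega=omega, singular=singular)


def comb_lowpass(N: int, order: int = 1, fs: float = 480.0) -> LinearFilter:
    """Running-sum comb low-pass (1 - z^-N)^order / (1 - z^-1)^order.

    Integer coefficients; zeros at k*fs/N for k = 1..N-1 (each of
    multiplicity ``order``), DC gain N^order.  The exact FIR expansion is
    the length-N all-ones kernel convolved with itself ``order`` times.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    num = np.zeros(N + 1)
    num[0], num[N] = 1.0, -1.0
    den = np.array([1.0, -1.0])
    b, a = num.copy(), den.copy()
    for _ in range(order - 1):
        b = np.convolve(b, num)
        a = np.convolve(a, den)
    fir = np.ones(N)
    for _ in range(order - 1):
        fir = np.convolve(fir, np.ones(N))
    return LinearFilter(
        b=b, a=a, fs=fs, label=f"comb_lowpass(N={N}, order={order})",
        scale=1.0, group_delay=(N - 1) / 2 * order, fir_equivalent=fir,
    )


def baseline_lowpass(M: int = 240, fs: float = 480.0) -> LinearFilter:
    """Long running-sum (1 - z^-M)/(1 - z^-1): first null at fs/M (2 Hz for
    the 480 Hz / M = 240 design), DC gain M."""
    if M < 2:
        raise ValueError("M must be >= 2")
    return comb_lowpass(M, order=1, fs=fs)


def baseline_highpass(M: int = 240, delay: int | None = None, fs: float = 480.0) -> LinearFilter:
    """Baseline-wander high-pass: delay minus normalised running sum,

        H(z) = z^-delay - (1/M) (1 - z^-M)/(1 - z^-1)

    with delay = M/2.  DC gain is exactly zero; frequencies above the
    running sum's main lobe pass with gain ~1.  Stored as integer
    coefficients over (1 - z^-1) with symbolic scale 1/M:

        H(z) = [ -1 + M z^-delay - M z^-(delay+1) + z^-M ] / [ M (1 - z^-1) ]

    The exact FIR expansion has h[k] = -1/M except h[delay] = 1 - 1/M.
    """
    if M < 2:
        raise ValueError("M must be >= 2")
    if delay is None:
        if M % 2:
            raise ValueError("M must be even for the default delay M/2")
        delay = M // 2
    elif delay != M // 2:
        warnings.warn("delay != M/2 gives a non-centred high-pass", stacklevel=2)
    b = np.zeros(M + 1)
    b[0] = -1.0
    b[delay] += M
    b[delay + 1] += -M
    b[M] += 1.0
    a = np.array([1.0, -1.0])
    fir = np.full(M, -1.0 / M)
    fir[delay] += 1.0
    return LinearFilter(
        b=b, a=a, fs=fs, label=f"baseline_highpass(M={M})",
        scale=1.0 / M, group_delay=float(delay),
        fir_equivalent=fir * M,  # fir_equivalent is pre-scale
    )


def apply_filter(filt: LinearFilter, x, zero_phase: bool = False) -> np.ndarray:
    """Run the difference equation with zero initial conditions.

    Output length equals input length.  ``zero_phase=True`` advances the
    output by the filter's nominal group delay (integer-rounded), padding
    the tail with zeros, so that filtered features stay aligned with the
    input's sample indices.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("signal must be non-empty")
    _warn_if_unstable(filt)
    y = filt.scale * sps.lfilter(filt.b, filt.a, x)
    if np.any(~np.isfinite(y)):
        raise FloatingPointError(f"filter {filt.label!r} produced non-finite output")
    if zero_phase:
        d = int(round(filt.group_delay))
        if d > 0:
            y = np.concatenate([y[d:], np.zeros(d)])
    return y


def _warn_if_unstable(filt: LinearFilter) -> None:
    if filt.is_fir:
        return
    # If A divides B exactly the recursion is FIR in disguise (the comb
    # case: the on-circle pole is removable) and therefore stable.
    _, rem = np.polydiv(filt.b[::-1], filt.a[::-1])
    if np.allclose(rem, 0, atol=1e-9 * max(1.0, np.abs(filt.b).max())):
        return
    roots_a = np.roots(filt.a)
    if np.any(np.abs(roots_a) > 1 - 1e-8):
        warnings.warn(
            f"{filt.label or 'filter'}: pole on or outside the unit circle; "
            "explicit recursion may be unstable", stacklevel=3,
        )


# ---------------------------------------------------------------------------
# FIR design
# ---------------------------------------------------------------------------

_SUPPORTED_WINDOWS = ("boxcar", "rectangular", "hamming", "hann", "blackman", "bartlett")


def _ideal_impulse(spec: FirDesignSpec) -> np.ndarray:
    """Inverse DTFT of the piecewise-constant desired amplitude, sampled at
    the M tap positions centred on (M-1)/2.  Closed form: each band
    [f1, f2] with desired d contributes d * (2 f2/fs sinc(2 f2 t/fs) -
    2 f1/fs sinc(2 f1 t/fs))."""
    M = spec.numtaps
    alpha = (M - 1) / 2
    t = np.arange(M) - alpha
    h = np.zeros(M)
    for f_lo, f_hi, d, _ in spec.bands:
        if d == 0:
            continue
        h += d * (2 * f_hi / spec.fs * np.sinc(2 * f_hi * t / spec.fs)
                  - 2 * f_lo / spec.fs * np.sinc(2 * f_lo * t / spec.fs))
    return h


def window_fir(spec: FirDesignSpec, window: str = "hamming") -> LinearFilter:
    """Window-method FIR: ideal impulse response truncated to M taps and
    tapered.  Type-I linear phase (M odd enforced), symmetric taps."""
    if spec.numtaps % 2 == 0:
        raise ValueError("numtaps must be odd for type-I linear phase")
    wname = window.lower()
    if wname not in _SUPPORTED_WINDOWS:
        raise ValueError(f"unsupported window {window!r}; supported: {_SUPPORTED_WINDOWS}")
    if wname == "rectangular":
        wname = "boxcar"
    taps = _ideal_impulse(spec) * sps.get_window(wname, spec.numtaps, fftbins=False)
    return LinearFilter(b=taps, a=np.array([1.0]), fs=spec.fs,
                        label=f"window_fir({window}, M={spec.numtaps})",
                        group_delay=(spec.numtaps - 1) / 2)


def amplitude_response(filt: LinearFilter, freqs_hz) -> np.ndarray:
    """Zero-phase (real) amplitude H*(w) of a linear-phase FIR: the complex
    response with the e^{-jw(M-1)/2} carrier removed."""
    fr = freq_response(filt, freqs_hz)
    alpha = (len(filt.b) - 1) / 2
    return np.real(fr.H * np.exp(1j * fr.omega * alpha))


def weighted_error(candidate: LinearFilter, spec: FirDesignSpec,
                   grid_hz=None) -> tuple[np.ndarray, float]:
    """Weighted approximation error E(w) = W(w)[H_d(w) - H*(w)] on the
    design grid (transition bands excluded) and its maximum magnitude."""
    if grid_hz is None:
        freqs, desired, weights = spec.grid()
    else:
        freqs = np.asarray(grid_hz, dtype=float)
        desired = np.empty_like(freqs)
        weights = np.empty_like(freqs)
        desired[:] = np.nan
        for f_lo, f_hi, d, w in spec.bands:
            m = (freqs >= f_lo) & (freqs <= f_hi)
            desired[m], weights[m] = d, w
        if np.any(np.isnan(desired)):
            raise ValueError("grid contains transition-band frequencies")
    E = weights * (desired - amplitude_response(candidate, freqs))
    return E, float(np.max(np.abs(E)))


def equiripple_fir(spec: FirDesignSpec) -> LinearFilter:
    """Minimax (equiripple) linear-phase FIR via Remez exchange.

    Minimises max |W(w)(H_d(w) - H*(w))| over the spec's bands; the optimal
    error alternates in sign at >= (free coefficients + 2) extremal
    frequencies.
    """
    if spec.numtaps % 2 == 0:
        raise ValueError("numtaps must be odd for type-I linear phase")
    if (len(spec.bands) == 1 and spec.bands[0][0] == 0.0
            and spec.bands[0][1] >= spec.fs / 2 - 1e-12):
        # constant desired over the full band is represented exactly by a
        # scaled, centred impulse (zero minimax error); the exchange
        # iteration has no extremal set to work with in this degenerate case
        taps = np.zeros(spec.numtaps)
        taps[(spec.numtaps - 1) // 2] = spec.bands[0][2]
        return LinearFilter(b=taps, a=np.array([1.0]), fs=spec.fs,
                            label=f"equiripple_fir(M={spec.numtaps})",
                            group_delay=(spec.numtaps - 1) / 2)
    bands_flat: list[float] = []
    desired: list[float] = []
    weights: list[float] = []
    for f_lo, f_hi, d, w in spec.bands:
        bands_flat.extend([f_lo, f_hi])
        desired.append(d)
        weights.append(w)
    try:
        taps = sps.remez(spec.numtaps, bands_flat, desired, weight=weights,
                         fs=spec.fs, maxiter=50)
    except Exception as exc:  # pragma: no cover - scipy raises on hard specs
        raise RuntimeError(f"equiripple design did not converge: {exc}") from exc
    if np.any(~np.isfinite(taps)):
        raise RuntimeError("equiripple design did not converge (non-finite taps)")
    taps = 0.5 * (taps + taps[::-1])  # enforce exact symmetry
    return LinearFilter(b=taps, a=np.array([1.0]), fs=spec.fs,
                        label=f"equiripple_fir(M={spec.numtaps})",
                        group_delay=(spec.numtaps - 1) / 2)


# ---------------------------------------------------------------------------
# Denoise cascade
# ---------------------------------------------------------------------------

def design_denoise_cascade(fs: float, powerline_hz: float = 50.0,
                           baseline_null_hz: float = 2.0,
                           comb_order: int = 1) -> list[LinearFilter]:
    """Build the two-stage cascade: baseline high-pass then power-line comb.

    M = round(fs / baseline_null_hz) (evened) puts the running sum's first
    null at ~baseline_null_hz; N = round(fs / powerline_hz) puts a comb
    zero at fs/N, nearest the mains frequency.  When fs/powerline is not an
    integer the zero misses the mains line and a warning is logged.
    """
    if powerline_hz >= fs / 2:
        raise ValueError("power-line frequency must be below fs/2")
    M = int(round(fs / baseline_null_hz))
    M += M % 2  # even, so delay M/2 is an integer
    hp = baseline_highpass(M=M, fs=fs)
    N = int(round(fs / powerline_hz))
    if abs(fs / N - powerline_hz) > 1e-6:
        logger.warning(
            "comb zero lands at %.2f Hz, not %.2f Hz (fs/notch non-integer)",
            fs / N, powerline_hz,
        )
    comb = comb_lowpass(N, order=comb_order, fs=fs)
    comb.scale = 1.0 / N ** comb_order  # unit DC gain
    return [hp, comb]


def denoise(record, mode: str = "iir", powerline_hz: float = 50.0,
            baseline_null_hz: float = 2.0, comb_order: int = 1):
    """Denoise an ECG record: remove baseline wander and mains interference.

    ``mode`` selects the realisation of the same combs: "iir" runs the
    rational (integer-coefficient recursive) form, "fir" the expanded
    moving-sum form; outputs agree to within accumulation round-off.  The
    total cascade delay is compensated by an integer-sample shift, so beat
    annotations remain aligned.
    """
    from dataclasses import replace

    if mode not in ("fir", "iir"):
        raise ValueError("mode must be 'fir' or 'iir'")
    cascade = design_denoise_cascade(record.fs, powerline_hz, baseline_null_hz, comb_order)
    out = np.empty_like(record.samples)
    for j in range(record.samples.shape[1]):
        y = record.samples[:, j]
        for filt in cascade:
            if mode == "fir":
                fir = filt.as_fir()
                ff = LinearFilter(b=fir, a=np.array([1.0]), fs=filt.fs,
                                  label=filt.label + "[fir]", group_delay=filt.group_delay)
                y = apply_filter(ff, y, zero_phase=True)
            else:
                y = apply_filter(filt, y, zero_phase=True)
        out[:, j] = y
    meta = dict(record.meta, denoise_mode=mode, powerline_hz=powerline_hz)
    return replace(record, samples=out, annotations=list(record.annotations), meta=meta)
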