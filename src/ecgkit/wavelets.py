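"""Multiresolution wavelet decomposition and the four beat-feature families.

The discrete wavelet transform is the two-channel pyramid: at each level
the signal is split by a conjugate low/high-pass pair and dyadically
downsampled, giving detail coefficients T_m and a final approximation
S_M.  With an orthogonal basis and periodic boundary handling the
transform conserves energy and inverts exactly, and the reconstructed
band signals obey the telescoping identities

    x_{m-1} = x_m + d_m        and        x_0 = x_M + sum_m d_m.

Feature families extracted per beat window:

* DW — per-band energies, energy fractions, mean |coeff| and coeff std;
* CC — sum-of-products autocorrelation at chosen lags, plus cross-
  correlation utilities;
* S  — eleven summary statistics of the raw window;
* F  — fiducial interval features (QRS duration, PR, QT, R amplitude,
  preceding RR) located by threshold crossings on a smoothed derivative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "WaveletBasis",
    "WaveletDecomposition",
    "FeatureVector",
    "dwt",
    "reconstruct",
    "band_signals",
    "wavelet_feature_vector",
    "autocorr_features",
    "cross_correlation",
    "statistical_features",
    "fiducial_features",
    "feature_matrix",
]

_DWT_MODE = "periodization"  # keeps orthogonal bases energy-conserving


@dataclass
class WaveletBasis:
    """Analysis/synthesis filter bank of a named wavelet."""

    name: str
    dec_lo: np.ndarray = field(init=False)
    dec_hi: np.ndarray = field(init=False)
    rec_lo: np.ndarray = field(init=False)
    rec_hi: np.ndarray = field(init=False)
    orthogonal: bool = field(init=False)

    def __post_init__(self) -> None:
        w = pywt.Wavelet(self.name)
        self.dec_lo = np.asarray(w.dec_lo)
        self.dec_hi = np.asarray(w.dec_hi)
        self.rec_lo = np.asarray(w.rec_lo)
        self.rec_hi = np.asarray(w.rec_hi)
        self.orthogonal = bool(w.orthogonal)

    @property
    def filter_length(self) -> int:
        return len(self.dec_lo)


@dataclass
class WaveletDecomposition:
    """Approximation S_M plus per-level details T_m (m = 1 shallowest)."""

    approx: np.ndarray
    details: list[np.ndarray]  # details[0] = level-1 (finest) T_1
    basis: WaveletBasis
    original_length: int

    @property
    def levels(self) -> int:
        return len(self.details)

    def coeff_list(self) -> list[np.ndarray]:
        """pywt-ordered coefficient list [S_M, T_M, ..., T_1]."""
        return [self.approx] + list(self.details[::-1])

    def energy(self) -> float:
        return float(sum(np.sum(c ** 2) for c in self.coeff_list()))


def dwt(signal: np.ndarray, basis: WaveletBasis | str = "db4", levels: int = 4) -> WaveletDecomposition:
    """Pyramid decomposition: ``levels`` rounds of filter + dyadic
    downsample with periodic boundary handling.

    Raises when the signal is too short for the requested depth (the
    error names the maximum feasible depth).
    """
    x = np.asarray(signal, dtype=float)
    if isinstance(basis, str):
        basis = WaveletBasis(basis)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if len(x) < basis.filter_length:
        raise ValueError("signal shorter than the wavelet filter")
    max_levels = pywt.dwt_max_level(len(x), basis.filter_length)
    if levels > max_levels:
        raise ValueError(
            f"requested {levels} levels but signal of length {len(x)} "
            f"supports at most {max_levels}"
        )
    coeffs = pywt.wavedec(x, basis.name, mode=_DWT_MODE, level=levels)
    approx, details_deep_first = coeffs[0], coeffs[1:]
    return WaveletDecomposition(
        approx=approx, details=list(details_deep_first[::-1]),
        basis=basis, original_length=len(x),
    )


def reconstruct(decomp: WaveletDecomposition) -> np.ndarray:
    """Invert the pyramid back to the original-length signal."""
    coeffs = decomp.coeff_list()
    expected = pywt.wavedec(np.zeros(decomp.original_length), decomp.basis.name,
                            mode=_DWT_MODE, level=decomp.levels)
    for c, e in zip(coeffs, expected):
        if c.shape != e.shape:
            raise ValueError("coefficient shapes inconsistent with the decomposition")
    y = pywt.waverec(coeffs, decomp.basis.name, mode=_DWT_MODE)
    return y[: decomp.original_length]


def band_signals(decomp: WaveletDecomposition) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Reconstructed band signals (x_m for m = 0..M, d_m for m = 1..M).

    d_m is the reconstruction from detail level m alone; x_m is the
    reconstruction from the approximation plus all details deeper than m,
    so x_{m-1} = x_m + d_m by linearity and x_0 is the original signal.
    """
    M = decomp.levels
    ds: list[np.ndarray] = []
    for m in range(1, M + 1):
        coeffs = [np.zeros_like(c) for c in decomp.coeff_list()]
        # coeff_list order: [S_M, T_M, ..., T_1]; T_m sits at index M - m + 1
        coeffs[M - m + 1] = decomp.details[m - 1]
        ds.append(pywt.waverec(coeffs, decomp.basis.name, mode=_DWT_MODE)[: decomp.original_length])
    coeffs = [np.zeros_like(c) for c in decomp.coeff_list()]
    coeffs[0] = decomp.approx
    x_M = pywt.waverec(coeffs, decomp.basis.name, mode=_DWT_MODE)[: decomp.original_length]
    xs = [x_M]
    for m in range(M, 0, -1):  # x_{m-1} = x_m + d_m
        xs.append(xs[-1] + ds[m - 1])
    xs.reverse()  # xs[m] = x_m, xs[0] = full reconstruction
    return xs, ds


@dataclass
class FeatureVector:
    """Named scalar features grouped by family (DW, CC, S, F)."""

    values: dict[str, float]
    family: str
    beat_id: int | None = None

    def names(self) -> list[str]:
        return list(self.values)

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)


def wavelet_feature_vector(decomp: WaveletDecomposition, beat_id: int | None = None) -> FeatureVector:
    """Family DW: per band (each detail level + final approximation) the
    energy, fraction of total energy, mean absolute coefficient and
    coefficient standard deviation."""
    bands = [(f"L{m}", decomp.details[m - 1]) for m in range(1, decomp.levels + 1)]
    bands.append((f"A{decomp.levels}", decomp.approx))
    total = sum(float(np.sum(c ** 2)) for _, c in bands)
    values: dict[str, float] = {}
    for name, c in bands:
        e = float(np.sum(c ** 2))
        values[f"DW.{name}.energy"] = e
        values[f"DW.{name}.frac"] = e / total if total > 0 else 0.0
        values[f"DW.{name}.mean_abs"] = float(np.mean(np.abs(c)))
        values[f"DW.{name}.std"] = float(np.std(c))
    return FeatureVector(values=values, family="DW", beat_id=beat_id)


def autocorr_features(signal: np.ndarray, lags, normalized: bool = True,
                      beat_id: int | None = None) -> FeatureVector:
    """Family CC: sum-of-products of the signal with its lag-shifted copy,

        r(l) = sum_{n >= l} x[n] x[n - l].

    The normalised variant uses the unbiased scaling
    r(l) * N / ((N - l) * r(0)), so a periodic signal scores ~1 at its
    period regardless of how many terms the shifted overlap loses."""
    x = np.asarray(signal, dtype=float)
    n = len(x)
    values: dict[str, float] = {}
    r0 = float(np.dot(x, x))
    for lag in lags:
        lag = int(lag)
        if lag >= n:
            raise ValueError(f"lag {lag} >= signal length {n}")
        r = float(np.dot(x[lag:], x[: n - lag])) if lag > 0 else r0
        if normalized:
            r = r * n / ((n - lag) * r0) if r0 > 0 else 0.0
        values[f"CC.lag{lag}"] = r
    return FeatureVector(values=values, family="CC", beat_id=beat_id)


def cross_correlation(a: np.ndarray, b: np.ndarray, normalized: bool = True):
    """Per-lag cross-correlation of equal-length signals.

    Returns (lags, values, peak_lag).  The normalised variant removes each
    signal's mean and scales by the norm product, so values lie in
    [-1, 1]; zero-variance input yields all-NaN values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("signals must have equal length")
    lags = np.arange(-len(a) + 1, len(a))
    if normalized:
        a0, b0 = a - a.mean(), b - b.mean()
        denom = np.linalg.norm(a0) * np.linalg.norm(b0)
        if denom == 0:
            return lags, np.full(len(lags), np.nan), 0
        c = np.correlate(a0, b0, mode="full") / denom
    else:
        c = np.correlate(a, b, mode="full")
    peak_lag = int(lags[np.argmax(np.abs(c))])
    return lags, c, peak_lag


def statistical_features(window: np.ndarray, beat_id: int | None = None) -> FeatureVector:
    """Family S: the eleven summary parameters of the beat window.

    mean, median, std, variance, RMS, skewness, kurtosis (Pearson,
    normal = 3), min, max, peak-to-peak, energy — population conventions
    throughout.  A constant window gets skewness/kurtosis of 0 with the
    degenerate flag set in the feature names' companion "S.degenerate".
    """
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise ValueError("window must be non-empty")
    mu = float(np.mean(x))
    var = float(np.var(x))
    sd = float(np.sqrt(var))
    degenerate = sd == 0
    if degenerate:
        skew = kurt = 0.0
    else:
        z = (x - mu) / sd
        skew = float(np.mean(z ** 3))
        kurt = float(np.mean(z ** 4))
    values = {
        "S.mean": mu,
        "S.median": float(np.median(x)),
        "S.std": sd,
        "S.variance": var,
        "S.rms": float(np.sqrt(np.mean(x ** 2))),
        "S.skewness": skew,
        "S.kurtosis": kurt,
        "S.min": float(np.min(x)),
        "S.max": float(np.max(x)),
        "S.ptp": float(np.ptp(x)),
        "S.energy": float(np.sum(x ** 2)),
    }
    values["S.degenerate"] = 1.0 if degenerate else 0.0
    return FeatureVector(values=values, family="S", beat_id=beat_id)


def _smooth_derivative(x: np.ndarray, fs: float) -> np.ndarray:
    win = max(1, int(round(0.01 * fs)))
    kernel = np.ones(win) / win
    return np.convolve(np.gradient(x) * fs, kernel, mode="same")


def _crossing(deriv_abs: np.ndarray, lo: int, hi: int, frac: float,
              direction: int) -> int | None:
    """First (direction=+1) or last (-1) index in [lo, hi) where the smoothed
    |derivative| exceeds frac of its local maximum."""
    seg = deriv_abs[lo:hi]
    if seg.size == 0:
        return None
    peak = float(np.max(seg))
    if peak <= 0:
        return None
    above = np.flatnonzero(seg >= frac * peak)
    if above.size == 0:
        return None
    return lo + int(above[0] if direction > 0 else above[-1])


def fiducial_features(window: np.ndarray, fs: float, rr_prev: float,
                      pre_s: float = 0.25, frac: float = 0.10,
                      beat_id: int | None = None) -> FeatureVector:
    """Family F: interval features from landmark estimates in one window.

    The window is assumed R-centred at sample floor(pre_s*fs).  QRS onset/
    offset are the first/last crossings of ``frac`` of the local smoothed-
    derivative extremum inside physiologic search regions around R; the P
    and T peaks are amplitude extrema in their own regions, from which the
    PR and QT intervals follow.  Undetectable landmarks (flat segments)
    yield NaN markers for the affected intervals.
    """
    x = np.asarray(window, dtype=float)
    n = len(x)
    r = int(np.floor(pre_s * fs))
    r = min(max(r, 0), n - 1)
    dabs = np.abs(_smooth_derivative(x, fs))

    def s(sec: float) -> int:
        return int(round(sec * fs))

    values: dict[str, float] = {"F.r_amp": float(x[r]), "F.rr_prev": float(rr_prev)}

    # QRS: steep-slope region within +-60 ms of R
    on = _crossing(dabs, max(0, r - s(0.06)), r + 1, frac, +1)
    off = _crossing(dabs, r, min(n, r + s(0.08)), frac, -1)
    flat = float(np.ptp(x)) == 0.0
    if flat or on is None or off is None or off <= on:
        values["F.qrs_dur"] = np.nan
        on = off = None
    else:
        values["F.qrs_dur"] = (off - on) / fs

    # P peak: largest amplitude 80-280 ms before R; T peak: 120-420 ms after
    p_lo, p_hi = max(0, r - s(0.28)), max(0, r - s(0.08))
    t_lo, t_hi = min(n, r + s(0.12)), min(n, r + s(0.42))
    p_seg = x[p_lo:p_hi]
    t_seg = x[t_lo:t_hi]
    p_idx = p_lo + int(np.argmax(np.abs(p_seg - np.median(p_seg)))) if p_seg.size else None
    t_idx = t_lo + int(np.argmax(np.abs(t_seg - np.median(t_seg)))) if t_seg.size else None
    p_ok = (p_idx is not None and not flat
            and abs(x[p_idx] - float(np.median(p_seg))) > 0.02 * max(abs(values["F.r_amp"]), 1e-12))
    t_ok = (t_idx is not None and not flat
            and abs(x[t_idx] - float(np.median(t_seg))) > 0.02 * max(abs(values["F.r_amp"]), 1e-12))

    values["F.pr_interval"] = (on - p_idx) / fs if (p_ok and on is not None) else np.nan
    values["F.qt_interval"] = (t_idx - on) / fs if (t_ok and on is not None) else np.nan
    values["F.p_amp"] = float(x[p_idx]) if p_ok else np.nan
    values["F.t_amp"] = float(x[t_idx]) if t_ok else np.nan
    return FeatureVector(values=values, family="F", beat_id=beat_id)


def feature_matrix(beat_set, families=("DW", "CC", "S", "F"),
                   wavelet: str = "db4", levels: int = 4,
                   cc_lags=(2, 4, 8, 16, 32)) -> tuple[np.ndarray, list[str]]:
    """Concatenate the requested feature families for every beat window.

    Families compose by plain concatenation, so hybrid sets like DW+CC and
    S+F are unions of the single-family columns with no recomputation.
    NaN interval features are imputed with the column median (the missing-
    landmark case), and an indicator column marks imputation per feature.
    Returns (matrix, column names).
    """
    rows: list[dict[str, float]] = []
    max_levels = pywt.dwt_max_level(beat_set.windows.shape[1],
                                    pywt.Wavelet(wavelet).dec_len)
    levels = min(levels, max(1, max_levels))
    for i, w in enumerate(beat_set.windows):
        feats: dict[str, float] = {}
        if "DW" in families:
            feats.update(wavelet_feature_vector(dwt(w, wavelet, levels), beat_id=i).values)
        if "CC" in families:
            feats.update(autocorr_features(w, cc_lags, beat_id=i).values)
        if "S" in families:
            feats.update(statistical_features(w, beat_id=i).values)
        if "F" in families:
            feats.update(fiducial_features(w, beat_set.fs, beat_set.rr_prev[i],
                                           pre_s=beat_set.pre_s, beat_id=i).values)
        rows.append(feats)
    if not rows:
        return np.empty((0, 0)), []
    names = list(rows[0])
    M = np.array([[row[c] for c in names] for row in rows], dtype=float)
    # median-impute NaNs (undefined fiducials / missing first-beat RR)
    for j in range(M.shape[1]):
        col = M[:, j]
        bad = ~np.isfinite(col)
        if np.any(bad):
            finite = col[~bad]
            col[bad] = float(np.median(finite)) if finite.size else 0.0
    return M, names
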