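"""R-peak detection, physiologic RR-interval filtering and beat segmentation.

Detection follows the Pan-Tompkins recipe: band-limit, differentiate,
square, integrate over a moving window, then pick peaks above an adaptive
(relative) threshold with a 200 ms refractory period.  The RR filter drops
beats whose coupling interval to the previous retained beat is shorter
than a physiologic minimum (default 400 ms), treating the later beat of
the offending pair as the spurious one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .filters import apply_filter, baseline_highpass, comb_lowpass
from .signal_model import EcgRecord

logger = logging.getLogger(__name__)

__all__ = ["BeatSet", "bandpass_preprocess", "detect_r_peaks", "filter_rr", "segment_beats"]

#: rr_prev marker for the first beat, whose preceding interval is unknown
RR_MISSING = float("nan")


@dataclass
class BeatSet:
    """Segmented beats: R indices, preceding RR intervals, fixed windows.

    ``windows`` has shape (n_beats, window_len); ``rr_prev[i]`` is
    (r_indices[i] - r_indices[i-1]) / fs for i >= 1 and NaN for the first
    beat.  ``labels`` holds class symbols when ground truth (or a
    classifier output) is attached.
    """

    r_indices: np.ndarray
    rr_prev: np.ndarray
    windows: np.ndarray
    fs: float
    labels: list[str] | None = None
    pre_s: float = 0.25
    post_s: float = 0.40
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r_indices = np.asarray(self.r_indices, dtype=int)
        self.rr_prev = np.asarray(self.rr_prev, dtype=float)
        if np.any(np.diff(self.r_indices) <= 0):
            raise ValueError("r_indices must be strictly increasing")
        if self.windows.ndim != 2 or self.windows.shape[0] != len(self.r_indices):
            raise ValueError("windows must be one equal-length row per beat")

    def __len__(self) -> int:
        return len(self.r_indices)

    def subset(self, keep: np.ndarray) -> "BeatSet":
        """New BeatSet with only the given beat positions (boolean or index
        array); rr_prev is recomputed against each beat's new predecessor."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        r = self.r_indices[keep]
        rr = np.empty(len(r))
        rr[0] = RR_MISSING
        if len(r) > 1:
            rr[1:] = np.diff(r) / self.fs
        labels = [self.labels[i] for i in keep] if self.labels is not None else None
        return replace(self, r_indices=r, rr_prev=rr,
                       windows=self.windows[keep], labels=labels)


def bandpass_preprocess(record: EcgRecord, low: float = 1.0, high: float = 50.0) -> EcgRecord:
    """Band-limit each lead to roughly [low, high] Hz with the integer combs.

    The low edge is realised by the subtraction high-pass with its running
    sum's first null at 2*low; the high edge by a unit-DC-gain comb
    low-pass with its first zero just above ``high``.  Output is
    delay-compensated so annotations stay aligned.
    """
    if not 0 < low < high < record.fs / 2:
        raise ValueError("need 0 < low < high < fs/2")
    M = int(round(record.fs / (2.0 * low)))
    M += M % 2
    hp = baseline_highpass(M=M, fs=record.fs)
    N = max(2, int(round(record.fs / high)))
    lp = comb_lowpass(N, order=1, fs=record.fs)
    lp.scale = 1.0 / N
    out = np.empty_like(record.samples)
    for j in range(record.samples.shape[1]):
        y = apply_filter(hp, record.samples[:, j], zero_phase=True)
        y = apply_filter(lp, y, zero_phase=True)
        out[:, j] = y
    return replace(record, samples=out, annotations=list(record.annotations))


def detect_r_peaks(
    record: EcgRecord,
    lead: int = 0,
    integration_window_s: float = 0.15,
    refractory_s: float = 0.2,
    threshold_frac: float = 0.25,
    search_back_s: float = 0.08,
) -> np.ndarray:
    """Pan-Tompkins-style R-peak detection on one lead.

    The derivative-squared signal is integrated over
    ``integration_window_s``; candidate peaks must exceed
    ``threshold_frac`` of the integrated signal's maximum (a relative
    threshold, so detection is invariant to amplitude scaling) and respect
    the refractory period.  Each candidate is then refined to the sample
    of largest absolute amplitude within +-``search_back_s`` on the raw
    lead.
    """
    x = record.lead(lead)
    fs = record.fs
    win = max(1, int(round(integration_window_s * fs)))
    if len(x) <= win + 2:
        warnings.warn("record shorter than one integration window; no detection", stacklevel=2)
        return np.array([], dtype=int)

    deriv = np.gradient(x)
    sq = deriv ** 2
    integ = np.convolve(sq, np.ones(win) / win, mode="same")
    peak = float(np.max(integ))
    if peak <= 0:
        return np.array([], dtype=int)
    thr = threshold_frac * peak

    refractory = int(round(refractory_s * fs))
    above = integ >= thr
    candidates: list[int] = []
    i = 0
    n = len(x)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            candidates.append(i + int(np.argmax(integ[i:j])))
            i = j + refractory
        else:
            i += 1

    # refine each candidate to the raw-signal extremum nearby
    half = max(1, int(round(search_back_s * fs)))
    refined: list[int] = []
    for c in candidates:
        lo, hi = max(0, c - half), min(n, c + half + 1)
        r = lo + int(np.argmax(np.abs(x[lo:hi])))
        if not refined or r - refined[-1] >= refractory:
            refined.append(r)
    return np.array(sorted(set(refined)), dtype=int)


def filter_rr(r_indices, fs: float, min_rr_s: float = 0.4) -> np.ndarray:
    """Drop beats closer than ``min_rr_s`` to the previous retained beat.

    Intervals below 400 ms correspond to implausibly fast rates for the
    targeted rhythms, so the later beat of a short pair is treated as the
    false or premature detection and removed.  Idempotent; all surviving
    intervals are >= min_rr_s.
    """
    r = np.asarray(r_indices, dtype=int)
    if len(r) == 0:
        return r.copy()
    if np.any(np.diff(r) <= 0):
        raise ValueError("r_indices must be strictly increasing")
    kept = [int(r[0])]
    for idx in r[1:]:
        if (idx - kept[-1]) / fs >= min_rr_s:
            kept.append(int(idx))
    return np.array(kept, dtype=int)


def segment_beats(
    record: EcgRecord,
    r_indices,
    pre_s: float = 0.25,
    post_s: float = 0.40,
    lead: int = 0,
    attach_labels: bool = False,
    label_tolerance_s: float = 0.05,
) -> BeatSet:
    """Cut fixed windows [R - pre_s, R + post_s) around each detected R.

    Window length is floor(pre_s*fs) + floor(post_s*fs) samples.  Beats
    whose window would run off either record edge are dropped with a
    warning.  With ``attach_labels`` the record's annotations are matched
    to detections within ``label_tolerance_s`` and the class symbols
    attached (unmatched beats get "?").
    """
    fs = record.fs
    n_pre = int(np.floor(pre_s * fs))
    n_post = int(np.floor(post_s * fs))
    if n_pre + n_post >= len(record):
        raise ValueError("window longer than the record")
    x = record.lead(lead)
    r = np.asarray(r_indices, dtype=int)
    inside = (r >= n_pre) & (r + n_post <= len(record))
    if np.any(~inside):
        warnings.warn(f"{int(np.sum(~inside))} edge beat(s) dropped", stacklevel=2)
    r = r[inside]
    windows = np.stack([x[i - n_pre : i + n_post] for i in r]) if len(r) else \
        np.empty((0, n_pre + n_post))
    rr = np.empty(len(r))
    if len(r):
        rr[0] = RR_MISSING
        rr[1:] = np.diff(r) / fs

    labels = None
    if attach_labels:
        tol = int(round(label_tolerance_s * fs))
        ann_idx = np.array([i for i, _ in record.annotations], dtype=int)
        ann_lab = [lab for _, lab in record.annotations]
        labels = []
        for idx in r:
            if len(ann_idx):
                k = int(np.argmin(np.abs(ann_idx - idx)))
                labels.append(ann_lab[k] if abs(int(ann_idx[k]) - int(idx)) <= tol else "?")
            else:
                labels.append("?")
    return BeatSet(r_indices=r, rr_prev=rr, windows=windows, fs=fs,
                   labels=labels, pre_s=pre_s, post_s=post_s)
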