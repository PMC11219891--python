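"""Synthetic ECG generation, noise injection, quantization and CSV I/O.

The generator produces beats as sums of five Gaussian bumps (P, Q, R, S, T),
which is enough morphology for exercising denoising, R detection, clustering
and classification downstream.  Two beat classes ship by default: "N"
(normal) and "V" (ventricular-ectopic: wide QRS, absent P wave, shortened
coupling interval).  Noise components model the three contaminants that
matter for ambulatory ECG: baseline wander (below 1 Hz), power-line
interference at 50/60 Hz with harmonics, and broadband white noise.
Amplitudes are millivolts throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EcgRecord",
    "BeatTemplate",
    "NoiseSpec",
    "default_templates",
    "make_rhythm",
    "generate_record",
    "add_noise",
    "quantize",
    "read_record",
    "write_record",
]


@dataclass
class BeatTemplate:
    """Beat morphology as five named Gaussian bumps.

    Each component maps a wave name to ``(amplitude_mV, center_s, width_s)``
    where ``center_s`` is the offset from the R peak (negative = earlier)
    and ``width_s`` is the Gaussian sigma.  Component centers must be
    ordered P < Q < R < S < T and widths positive.
    """

    components: dict[str, tuple[float, float, float]]

    ORDER = ("P", "Q", "R", "S", "T")

    def __post_init__(self) -> None:
        centers = [self.components[w][1] for w in self.ORDER if w in self.components]
        if any(c2 <= c1 for c1, c2 in zip(centers, centers[1:])):
            raise ValueError("component centers must be ordered P < Q < R < S < T")
        for name, (_, _, width) in self.components.items():
            if width <= 0:
                raise ValueError(f"width of wave {name!r} must be positive")

    def waveform(self, t: np.ndarray, r_time: float) -> np.ndarray:
        """Evaluate the beat on time grid ``t`` (s) with its R peak at ``r_time``."""
        y = np.zeros_like(t, dtype=float)
        for amp, center, width in self.components.values():
            y += amp * np.exp(-0.5 * ((t - r_time - center) / width) ** 2)
        return y


@dataclass
class NoiseSpec:
    """Additive contamination: baseline wander, power-line, white noise.

    ``baseline`` is ``(amplitude_mV, frequency_Hz)`` with frequency in
    [0, 1] Hz; ``powerline`` is ``(frequency_Hz, amplitude_mV, n_harmonics)``
    with frequency 50 or 60; ``white_sd`` is the white-noise standard
    deviation in mV.  The top-level ``seed`` deterministically derives one
    sub-stream per component, so enabling one component never perturbs
    another's draw.
    """

    baseline: tuple[float, float] = (0.0, 0.5)
    powerline: tuple[float, float, int] = (50.0, 0.0, 1)
    white_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline[0] < 0 or self.powerline[1] < 0 or self.white_sd < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if not 0.0 <= self.baseline[1] <= 1.0:
            raise ValueError("baseline wander frequency must lie in [0, 1] Hz")


@dataclass
class EcgRecord:
    """Multi-lead sampled ECG in mV with annotations and acquisition metadata.

    ``samples`` has shape (n_samples, n_leads).  ``annotations`` is a list of
    ``(sample_index, label)`` pairs with strictly increasing indices inside
    the record.  ``meta`` carries resolution bits / amplitude range when the
    record has been quantized.
    """

    samples: np.ndarray
    fs: float
    lead_names: list[str] = field(default_factory=lambda: ["I"])
    annotations: list[tuple[int, str]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] == 1 and self.samples.shape[1] > 1 and len(self.lead_names) == 1:
            self.samples = self.samples.T
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.shape[1] != len(self.lead_names):
            raise ValueError("lead_names must match the number of sample columns")
        idx = [i for i, _ in self.annotations]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("annotation indices must be strictly increasing")
        if idx and (idx[0] < 0 or idx[-1] >= len(self)):
            raise ValueError("annotation indices must lie within the record")

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    def lead(self, name_or_idx: int | str = 0) -> np.ndarray:
        """Return one lead as a 1-D array."""
        if isinstance(name_or_idx, str):
            name_or_idx = self.lead_names.index(name_or_idx)
        return self.samples[:, name_or_idx]

    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.fs


def default_templates() -> dict[str, BeatTemplate]:
    """Shipped beat classes: "N" normal, "V" ventricular ectopic.

    The ectopic beat has a broad, tall R deflection, a deep slurred S, no
    P wave and a discordant T — the textbook PVC silhouette.
    """
    normal = BeatTemplate({
        "P": (0.15, -0.200, 0.022),
        "Q": (-0.10, -0.038, 0.010),
        "R": (1.00, 0.000, 0.011),
        "S": (-0.22, 0.035, 0.011),
        "T": (0.32, 0.250, 0.060),
    })
    ectopic = BeatTemplate({
        "P": (0.00, -0.200, 0.022),
        "Q": (-0.05, -0.060, 0.020),
        "R": (1.25, 0.000, 0.034),
        "S": (-0.45, 0.075, 0.030),
        "T": (-0.35, 0.300, 0.070),
    })
    return {"N": normal, "V": ectopic}


def make_rhythm(
    duration_s: float,
    mean_rr_s: float = 0.8,
    ectopic_rate: float = 0.0,
    rr_jitter_s: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, str]]:
    """Draw a beat schedule: mostly "N" beats at ``mean_rr_s`` spacing,
    with "V" ectopics inserted at probability ``ectopic_rate`` per beat.

    An ectopic is premature: its coupling interval to the preceding beat is
    drawn uniformly in 0.3–0.5 s, and the next normal beat resumes the
    regular grid (a compensatory-pause-like pattern).
    """
    rng = np.random.default_rng([int(seed) % 2**31, 101])
    beats: list[tuple[float, str]] = []
    t = 0.35  # leave room for the first beat's P wave
    while t < duration_s - 0.45:
        jitter = rng.normal(0.0, rr_jitter_s) if rr_jitter_s > 0 else 0.0
        if beats and ectopic_rate > 0 and rng.random() < ectopic_rate:
            coupling = rng.uniform(0.3, 0.5)
            t_ect = beats[-1][0] + coupling
            if t_ect < duration_s - 0.45 and t_ect < t - 0.15:
                beats.append((t_ect, "V"))
        beats.append((t, "N"))
        t += max(0.3, mean_rr_s + jitter)
    beats.sort(key=lambda b: b[0])
    return beats


def generate_record(
    duration_s: float,
    fs: float,
    rhythm: list[tuple[float, str]],
    templates: dict[str, BeatTemplate] | None = None,
    seed: int = 0,
    lead_names: list[str] | None = None,
) -> EcgRecord:
    """Render a clean ECG record from a beat schedule.

    Annotations carry the ground-truth R sample index (the rounded beat
    time) and class label for every beat.  Deterministic for a fixed seed;
    the clean waveform itself involves no randomness.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    templates = default_templates() if templates is None else templates
    unknown = {c for _, c in rhythm if c not in templates}
    if unknown:
        raise ValueError(f"no template for beat class(es): {sorted(unknown)}")
    for bt, _ in rhythm:
        if not 0 <= bt < duration_s:
            raise ValueError(f"beat time {bt} outside record duration")

    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    annotations: list[tuple[int, str]] = []
    for beat_time, cls in sorted(rhythm, key=lambda b: b[0]):
        x += templates[cls].waveform(t, beat_time)
        r_idx = int(round(beat_time * fs))
        if 0 <= r_idx < n:
            annotations.append((r_idx, cls))
    lead_names = lead_names or ["I"]
    samples = np.tile(x[:, None], (1, len(lead_names)))
    return EcgRecord(samples=samples, fs=fs, lead_names=lead_names,
                     annotations=annotations, meta={"seed": int(seed)})


def _component_rng(seed: int, component: int) -> np.random.Generator:
    # Independent sub-stream per noise component from the one top-level seed.
    return np.random.default_rng([int(seed) % 2**31, 7919, component])


def add_noise(record: EcgRecord, spec: NoiseSpec) -> EcgRecord:
    """Add baseline wander + power-line interference + white noise.

    Purely additive; annotations and metadata are untouched.  A spec with
    all amplitudes zero returns an identical copy.
    """
    t = record.times()
    noise = np.zeros(len(record))

    amp_b, f_b = spec.baseline
    if amp_b > 0:
        noise += amp_b * np.sin(2 * np.pi * f_b * t)

    f_p, amp_p, n_h = spec.powerline
    if amp_p > 0:
        for h in range(1, int(n_h) + 1):
            # harmonics roll off 1/h, matching mains interference in practice
            noise += (amp_p / h) * np.sin(2 * np.pi * f_p * h * t)

    if spec.white_sd > 0:
        rng = _component_rng(spec.seed, 3)
        noise += rng.normal(0.0, spec.white_sd, size=len(record))

    samples = record.samples + noise[:, None]
    return replace(record, samples=samples, annotations=list(record.annotations))


def quantize(record: EcgRecord, bits: int = 11, range_mv: float = 10.0) -> EcgRecord:
    """Mid-tread uniform quantization over +-range_mv/2, mapped back to mV.

    Step size is ``range_mv / 2**bits``; amplitudes outside the range are
    clipped (with a logged warning).  Idempotent.
    """
    if bits < 2:
        raise ValueError("need at least 2 bits")
    if range_mv <= 0:
        raise ValueError("range must be positive")
    step = range_mv / (2 ** bits)
    lo_level = -(2 ** (bits - 1))
    hi_level = 2 ** (bits - 1) - 1
    levels = np.round(record.samples / step)
    if np.any(levels < lo_level) or np.any(levels > hi_level):
        logger.warning("quantize: samples outside +-%.3g mV clipped", range_mv / 2)
        warnings.warn("samples outside quantizer range were clipped", stacklevel=2)
    levels = np.clip(levels, lo_level, hi_level)
    meta = dict(record.meta, resolution_bits=int(bits), range_mv=float(range_mv))
    return replace(record, samples=levels * step, annotations=list(record.annotations), meta=meta)


# ---------------------------------------------------------------------------
# CSV I/O.  Record file: first line "# fs=<Hz> leads=<comma names>", then one
# comma-separated row per sample.  Annotation sidecar (same path + ".ann"):
# two columns "sample_index,label", one row per beat.
# ---------------------------------------------------------------------------

def write_record(record: EcgRecord, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs={record.fs:g} leads={','.join(record.lead_names)}\n")
        for row in record.samples:
            fh.write(",".join(f"{v:.6f}" for v in row) + "\n")
    with open(str(path) + ".ann", "w", encoding="utf-8") as fh:
        for idx, label in record.annotations:
            fh.write(f"{idx},{label}\n")


def read_record(path: str) -> EcgRecord:
    import os

    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}:1: missing '# fs=... leads=...' header")
        fields = dict(
            part.split("=", 1) for part in header.lstrip("#").split() if "=" in part
        )
        if "fs" not in fields:
            raise ValueError(f"{path}:1: header does not declare fs")
        fs = float(fields["fs"])
        lead_names = fields.get("leads", "I").split(",")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                rows.append([float(v) for v in line.split(",")])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell") from exc
    samples = np.asarray(rows, dtype=float)

    annotations: list[tuple[int, str]] = []
    ann_path = str(path) + ".ann"
    if os.path.exists(ann_path):
        with open(ann_path, "r", encoding="utf-8") as fh:
            prev = -1
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    idx_s, label = line.split(",", 1)
                    idx = int(idx_s)
                except ValueError as exc:
                    raise ValueError(f"{ann_path}:{lineno}: malformed annotation row") from exc
                if idx <= prev:
                    raise ValueError(f"{ann_path}:{lineno}: annotation indices not sorted")
                prev = idx
                annotations.append((idx, label))
    return EcgRecord(samples=samples, fs=fs, lead_names=lead_names, annotations=annotations)
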