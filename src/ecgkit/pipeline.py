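"""End-to-end orchestration: simulate -> denoise -> beats -> cluster ->
features -> train -> evaluate, reproducible from (config, seed).

The configuration is a flat dataclass of per-stage parameter blocks; a
YAML file with the same keys can be loaded with ``PipelineConfig.from_yaml``.
Feature-set selection supports the single families DW, CC, S, F and the
hybrid pairings DW+CC and S+F; hybrid sets are plain column unions of the
single families.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from . import beats as beats_mod
from . import clustering, evaluation
from .classifiers import KernelSpec, TrainingSet, train_hybrid
from .filters import denoise
from .signal_model import NoiseSpec, add_noise, generate_record, make_rhythm, quantize, read_record
from .wavelets import feature_matrix

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "split", "run"]

FEATURE_SETS = {
    "DW": ("DW",), "CC": ("CC",), "S": ("S",), "F": ("F",),
    "DW+CC": ("DW", "CC"), "S+F": ("S", "F"),
}


@dataclass
class PipelineConfig:
    # simulation
    duration_s: float = 180.0
    fs: float = 360.0
    mean_rr_s: float = 0.8
    ectopic_rate: float = 0.18
    rr_jitter_s: float = 0.02
    baseline_amp_mv: float = 0.3
    baseline_hz: float = 0.3
    powerline_hz: float = 50.0
    powerline_amp_mv: float = 0.15
    white_sd_mv: float = 0.03
    quantize_bits: int = 11
    quantize_range_mv: float = 10.0
    # denoise
    denoise_mode: str = "iir"
    # beats
    band_low_hz: float = 1.0
    band_high_hz: float = 50.0
    min_rr_s: float = 0.4
    pre_s: float = 0.25
    post_s: float = 0.40
    # clustering
    pca_k: int = 5
    eps: float | None = None
    min_pts: int = 4
    cbcr_k: float = 3.0
    ncc_threshold: float = 0.6
    # features / model
    feature_set: str = "DW+CC"
    kernel: str = "rbf"
    kernel_sigma: float | None = None
    P: float = 10.0
    eps_loss: float = 0.0
    max_depth: int = 4
    min_leaf: int = 2
    # split
    train_fraction: float = 0.6
    stratified: bool = True
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"feature_set must be one of {sorted(FEATURE_SETS)}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def split(labels, fraction: float, stratified: bool = True, seed: int = 0):
    """Disjoint, exhaustive train/test index split over beats.

    Stratified mode splits each class separately so the train-set class mix
    matches the full set to within one beat; a class with fewer than two
    members triggers a fallback to a plain split (with a warning).
    """
    import warnings

    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    labels = list(labels)
    n = len(labels)
    rng = np.random.default_rng([int(seed) % 2**31, 271])
    if stratified:
        by_class: dict = {}
        for i, c in enumerate(labels):
            by_class.setdefault(c, []).append(i)
        if any(len(v) < 2 for v in by_class.values()):
            warnings.warn("a class has < 2 members; falling back to a plain split",
                          stacklevel=2)
            stratified = False
        else:
            train: list[int] = []
            test: list[int] = []
            for c in sorted(by_class, key=str):
                idx = np.array(by_class[c])
                rng.shuffle(idx)
                k = int(round(fraction * len(idx)))
                k = min(max(k, 1), len(idx) - 1)
                train.extend(idx[:k].tolist())
                test.extend(idx[k:].tolist())
            return np.array(sorted(train)), np.array(sorted(test))
    perm = rng.permutation(n)
    k = int(round(fraction * n))
    return np.sort(perm[:k]), np.sort(perm[k:])


def simulate_record(config: PipelineConfig):
    """Generate the default noisy, quantized two-class study record."""
    rhythm = make_rhythm(config.duration_s, config.mean_rr_s, config.ectopic_rate,
                         config.rr_jitter_s, seed=config.seed)
    rec = generate_record(config.duration_s, config.fs, rhythm, seed=config.seed)
    spec = NoiseSpec(
        baseline=(config.baseline_amp_mv, config.baseline_hz),
        powerline=(config.powerline_hz, config.powerline_amp_mv, 2),
        white_sd=config.white_sd_mv,
        seed=config.seed,
    )
    rec = add_noise(rec, spec)
    return quantize(rec, config.quantize_bits, config.quantize_range_mv)


def _prepare_beats(config: PipelineConfig, record):
    rec_dn = denoise(record, mode=config.denoise_mode, powerline_hz=config.powerline_hz)
    rec_bp = beats_mod.bandpass_preprocess(rec_dn, config.band_low_hz, config.band_high_hz)
    r = beats_mod.detect_r_peaks(rec_bp)
    r = beats_mod.filter_rr(r, record.fs, config.min_rr_s)
    beat_set = beats_mod.segment_beats(rec_bp, r, config.pre_s, config.post_s,
                                       attach_labels=True)
    return beat_set


def _cluster_retain(config: PipelineConfig, beat_set):
    if len(beat_set) < max(config.min_pts + 1, 4):
        return beat_set, {"clusters": 0, "discarded": 0}
    F = clustering.standardize(beat_set.windows)
    k = min(config.pca_k, F.shape[1], max(1, F.shape[0] - 1))
    proj, _, _ = clustering.pca_project(F, k)
    eps = config.eps if config.eps is not None else clustering.auto_eps(proj)
    result = clustering.dbscm(proj, eps=eps, min_pts=config.min_pts)
    retained, discarded = clustering.cbcr_filter(proj, result, k_max=config.cbcr_k)
    refs = {c: beat_set.windows[st.medoid] for c, st in result.stats.items()}
    labels_r = result.labels[retained]
    keep_rel = clustering.ncc_prune(beat_set.windows[retained], labels_r, refs,
                                    threshold=config.ncc_threshold)
    keep = retained[keep_rel] if len(keep_rel) else retained
    info = {"clusters": len(result.stats), "discarded": int(len(beat_set) - len(keep)),
            "eps": float(eps)}
    return beat_set.subset(np.sort(keep)), info


def _encode_labels(labels: list[str]) -> np.ndarray:
    # ectopic ("V") is the positive class
    return np.array([1.0 if lab == "V" else -1.0 for lab in labels])


def run(config: PipelineConfig, input_path: str | None = None,
        out_path: str | None = None) -> dict:
    """Execute the full pipeline and return (optionally write) the report.

    ``input_path`` loads a CSV record instead of simulating.  The report
    is a plain dict: configuration echo, per-stage tallies, and the
    evaluation metrics of the hybrid classifier and of its members on the
    held-out beats.  Deterministic for a fixed (config, seed): two runs
    produce byte-identical JSON.
    """
    stage = "simulate"
    try:
        record = read_record(input_path) if input_path else simulate_record(config)
        stage = "beats"
        beat_set = _prepare_beats(config, record)
        if len(beat_set) < 10:
            raise RuntimeError(f"only {len(beat_set)} beats detected; record too short")
        stage = "cluster"
        beat_set, cluster_info = _cluster_retain(config, beat_set)
        stage = "features"
        families = FEATURE_SETS[config.feature_set]
        F, feature_names = feature_matrix(beat_set, families=families)
        F = clustering.standardize(F)
        y = _encode_labels(beat_set.labels)
        stage = "train"
        tr, te = split(beat_set.labels, config.train_fraction,
                       config.stratified, seed=config.seed)
        sigma = config.kernel_sigma or float(np.sqrt(F.shape[1]))
        model = train_hybrid(
            TrainingSet(F[tr], y[tr]),
            kernel=KernelSpec(config.kernel, sigma=sigma),
            P=config.P, eps=config.eps_loss,
            max_depth=config.max_depth, min_leaf=config.min_leaf,
        )
        stage = "evaluate"
        y_pred = model.predict(F[te])
        k_cls, _, t_cls, _ = model.member_predictions(F[te])
        rep = {
            "config": asdict(config),
            "n_beats": int(len(beat_set)),
            "n_train": int(len(tr)),
            "n_test": int(len(te)),
            "clustering": cluster_info,
            "feature_columns": feature_names,
            "hybrid": evaluation.report(y[te].tolist(), y_pred.tolist(), 1.0),
            "kernel_member": evaluation.report(y[te].tolist(), k_cls.tolist(), 1.0),
            "tree_member": evaluation.report(y[te].tolist(), t_cls.tolist(), 1.0),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    if out_path:
        with open(out_path, "w", encoding="utf-8") as fh:
            json.dump(rep, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return rep
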