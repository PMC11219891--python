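"""Group beats by morphology and discard stragglers.

Pipeline: standardize beat windows -> PCA -> density clustering (DBSCM)
-> concentration-based retention (CBCR: drop beats beyond mean + 3 std of
medoid distance) -> normalized cross-correlation pruning against each
cluster's medoid waveform.
"""

import numpy as np

from ecgkit import (
    bandpass_preprocess, cbcr_filter, dbscm, detect_r_peaks, filter_rr,
    generate_record, make_rhythm, ncc_prune, pca_project, segment_beats,
    standardize, auto_eps,
)

fs = 360.0
rec = generate_record(60.0, fs, make_rhythm(60.0, 0.8, ectopic_rate=0.15, seed=8), seed=8)
bp = bandpass_preprocess(rec)
r = filter_rr(detect_r_peaks(bp), fs)
beats = segment_beats(bp, r, attach_labels=True)

F = standardize(beats.windows)
proj, _, var = pca_project(F, 5)
print(f"PCA: top-5 axes explain {var.sum() / np.var(F, axis=0).sum() * 100:.1f}% "
      "of window variance")

eps = auto_eps(proj)
res = dbscm(proj, eps=eps, min_pts=4)
print(f"DBSCM (eps={eps:.2f}): {len(res.stats)} clusters, "
      f"{int(np.sum(res.labels == -1))} sparse-region beats marked noise")

retained, discarded = cbcr_filter(proj, res, k_max=3.0)
refs = {c: beats.windows[st.medoid] for c, st in res.stats.items()}
kept = ncc_prune(beats.windows[retained], res.labels[retained], refs, threshold=0.6)
print(f"CBCR retained {len(retained)}/{len(beats)}; "
      f"NCC pruning keeps {len(kept)} of those")
# clusters separate normal from ectopic morphology; discarded beats are the
# ones too far from any cluster's typical waveform to trust.
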