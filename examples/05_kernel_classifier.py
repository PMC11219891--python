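"""Train the squared-eps-insensitive kernel machine and the hybrid pair.

Targets are +-1 class codes; the kernel model is fit in the dual (the sum
of dual coefficients is constrained to zero), and the hybrid model fuses
it with a CART tree by OR on positive calls.
"""

import numpy as np

from ecgkit.classifiers import (
    KernelSpec, TrainingSet, predict_kernel, train_hybrid, train_kernel,
)
from ecgkit.evaluation import confusion, recall

rng = np.random.default_rng(0)
X = rng.normal(size=(120, 4))
y = np.where(X[:, 0] - 0.5 * X[:, 1] + 0.3 * rng.normal(size=120) > 0, 1.0, -1.0)
train, test = slice(0, 80), slice(80, None)

km = train_kernel(TrainingSet(X[train], y[train]), KernelSpec("rbf", 2.0),
                  P=10.0, eps=0.0)
print(f"dual constraint |sum beta| = {abs(km.beta.sum()):.2e}")
print(f"support vectors: {len(km.beta)} of 80")
acc = np.mean(np.sign(predict_kernel(km, X[test])) == y[test])
print(f"kernel model test accuracy: {acc:.3f}")

hybrid = train_hybrid(TrainingSet(X[train], y[train]), KernelSpec("rbf", 2.0))
fused = hybrid.predict(X[test])
k_cls, _, t_cls, _ = hybrid.member_predictions(X[test])
for name, pred in (("kernel", k_cls), ("tree", t_cls), ("hybrid", fused)):
    r = recall(confusion(y[test], pred, 1.0))
    print(f"{name:>6} positive-class recall: {r:.3f}")
# OR fusion on positive calls means the hybrid's recall can never fall
# below the better member's.
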