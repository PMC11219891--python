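"""Learning stack: threshold-unit neurons, a kernel machine with squared
epsilon-insensitive loss trained in the dual, a CART decision tree, and
two-member hybrid fusion.

Kernel machine
--------------
Given training pairs (a_s, b_s), s = 1..N, the primal problem is

    min_{w,c,xi}  1/2 ||w||^2 + P * sum_s xi_s^2
    s.t.          |b_s - w^T phi(a_s) - c| <= eps + xi_s,   xi_s >= 0,

i.e. residuals inside the eps-tube are free and the excess is penalised
quadratically.  Writing beta_s = alpha_s - alpha'_s for the two dual
multipliers of the tube constraints, the dual reduces to the strongly
concave problem

    max_beta  -1/2 beta^T K beta + b^T beta - eps ||beta||_1
              - 1/(2P) ||beta||^2        s.t.  sum_s beta_s = 0,

(the quadratic-slack term makes the box unbounded above: no upper cap on
the multipliers).  For eps = 0 the l1 term vanishes and the optimum is the
solution of one linear KKT system (a least-squares kernel machine) — the
default fast path.  For eps > 0 the solver is pairwise coordinate ascent:
each update moves mass between two coordinates, which preserves the
sum-zero constraint exactly and has a closed-form piecewise-quadratic
maximiser.  The predictor never materialises w:

    f(a) = sum_{s in SV} beta_s k(a_s, a) + c.

Classification uses regression on +-1 targets with sign thresholding;
|f(a)| doubles as the confidence score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronLayer",
    "neuron_forward",
    "mlp_forward",
    "KernelSpec",
    "kernel_eval",
    "gram",
    "TrainingSet",
    "KernelModel",
    "train_kernel",
    "predict_kernel",
    "DecisionTreeModel",
    "train_tree",
    "predict_tree",
    "HybridModel",
    "hybrid_fuse",
    "train_hybrid",
]


# ---------------------------------------------------------------------------
# Threshold-unit neural layer
# ---------------------------------------------------------------------------

@dataclass
class NeuronLayer:
    """One layer of linear-combination units: weights (n_out, n_in),
    per-unit threshold theta, and an activation in
    {"threshold", "logistic", "identity"}.

    The threshold activation outputs 1 iff the net input A^T B >= theta."""

    weights: np.ndarray
    theta: np.ndarray | float = 0.0
    activation: str = "threshold"

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if self.activation not in ("threshold", "logistic", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")


def neuron_forward(layer: NeuronLayer, B) -> np.ndarray:
    B = np.asarray(B, dtype=float)
    if B.shape[0] != layer.weights.shape[1]:
        raise ValueError(
            f"input dimension {B.shape[0]} != weight columns {layer.weights.shape[1]}"
        )
    net = layer.weights @ B
    if layer.activation == "threshold":
        return (net >= layer.theta).astype(float)
    if layer.activation == "logistic":
        return 1.0 / (1.0 + np.exp(-(net - layer.theta)))
    return net - layer.theta


def mlp_forward(layers: list[NeuronLayer], B) -> np.ndarray:
    """Composition of neuron_forward over a chain of layers."""
    y = np.asarray(B, dtype=float)
    for k, layer in enumerate(layers):
        if y.shape[0] != layer.weights.shape[1]:
            raise ValueError(f"layer {k}: expects {layer.weights.shape[1]} inputs, got {y.shape[0]}")
        y = neuron_forward(layer, y)
    return y


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelSpec:
    """Kernel family: "linear" (a.b) or "rbf" (exp(-||a-b||^2 / 2 sigma^2))."""

    name: str = "rbf"
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel {self.name!r}")
        if self.name == "rbf" and self.sigma <= 0:
            raise ValueError("rbf width sigma must be positive")


def kernel_eval(spec: KernelSpec, a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("kernel arguments must have equal dimension")
    if spec.name == "linear":
        return float(a @ b)
    return float(np.exp(-np.sum((a - b) ** 2) / (2 * spec.sigma ** 2)))


def gram(spec: KernelSpec, A: np.ndarray, B: np.ndarray | None = None) -> np.ndarray:
    """Kernel matrix K[s, r] = k(A[s], B[r]); symmetric PSD for B = A."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = A if B is None else np.atleast_2d(np.asarray(B, dtype=float))
    if spec.name == "linear":
        return A @ B.T
    sq = (np.sum(A ** 2, axis=1)[:, None] + np.sum(B ** 2, axis=1)[None, :]
          - 2 * A @ B.T)
    return np.exp(-np.maximum(sq, 0.0) / (2 * spec.sigma ** 2))


# ---------------------------------------------------------------------------
# Kernel machine with squared epsilon-insensitive loss
# ---------------------------------------------------------------------------

@dataclass
class TrainingSet:
    """N pairs (a_s, b_s); class targets are encoded +-1."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y must have matching first dimension")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("targets must be finite")

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class KernelModel:
    """Dual solution: coefficients beta per retained sample, bias c."""

    beta: np.ndarray
    bias: float
    kernel: KernelSpec
    support_vectors: np.ndarray
    eps: float
    P: float
    sv_tol: float = 1e-10

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "bias": self.bias,
            "kernel": {"name": self.kernel.name, "sigma": self.kernel.sigma},
            "support_vectors": self.support_vectors.tolist(),
            "eps": self.eps,
            "P": self.P,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KernelModel":
        return cls(beta=np.array(d["beta"]), bias=float(d["bias"]),
                   kernel=KernelSpec(**d["kernel"]),
                   support_vectors=np.array(d["support_vectors"]),
                   eps=float(d["eps"]), P=float(d["P"]))


def _dual_objective(beta: np.ndarray, K: np.ndarray, y: np.ndarray,
                    eps: float, P: float) -> float:
    return float(-0.5 * beta @ K @ beta + y @ beta
                 - eps * np.sum(np.abs(beta)) - np.sum(beta ** 2) / (2 * P))


def _solve_eps0(K: np.ndarray, y: np.ndarray, P: float) -> tuple[np.ndarray, float]:
    """eps = 0 fast path: equality-constrained strongly concave quadratic,
    solved via its KKT linear system

        [K + I/P  1] [beta]   [y]
        [1^T      0] [  c ] = [0].
    """
    n = len(y)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = K + np.eye(n) / P
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    rhs = np.concatenate([y, [0.0]])
    sol = np.linalg.solve(A, rhs)
    return sol[:n], float(sol[n])


def _pair_update(beta: np.ndarray, i: int, j: int, K: np.ndarray, y: np.ndarray,
                 eps: float, P: float) -> float:
    """Exact maximisation along beta_i += t, beta_j -= t (constraint-
    preserving direction).  The objective restricted to t is concave and
    piecewise quadratic with kinks where beta_i + t or beta_j - t crosses
    zero; the best of the per-segment stationary points (clipped to the
    segment) is taken.  Returns the achieved objective increase."""
    bi, bj = beta[i], beta[j]
    # smooth part: J(t) = -1/2 q t^2 + g t  + (l1 term handled per segment)
    q = K[i, i] + K[j, j] - 2 * K[i, j] + 2.0 / P
    Kb_i = K[i] @ beta
    Kb_j = K[j] @ beta
    g0 = (y[i] - y[j]) - (Kb_i - Kb_j) - (bi - bj) / P
    kinks = sorted({-bi, bj})
    segments = []
    lo = -np.inf
    for kink in kinks:
        segments.append((lo, kink))
        lo = kink
    segments.append((lo, np.inf))
    best_t, best_gain = 0.0, 0.0

    def seg_gain(t: float) -> float:
        # objective change: smooth quadratic part plus exact l1 change
        d_smooth = g0 * t - 0.5 * q * t * t
        d_l1 = -eps * (abs(bi + t) - abs(bi) + abs(bj - t) - abs(bj))
        return d_smooth + d_l1

    for lo, hi in segments:
        mid = (max(lo, -1.0) + min(hi, 1.0)) / 2 if np.isfinite(lo) or np.isfinite(hi) else 0.0
        si = np.sign(bi + mid) if bi + mid != 0 else np.sign(bi + (hi if np.isfinite(hi) else 1))
        sj = np.sign(bj - mid) if bj - mid != 0 else np.sign(bj - (lo if np.isfinite(lo) else -1))
        g = g0 - eps * (si - sj)  # d/dt of the l1 term inside the segment
        if q <= 0:
            continue
        t_star = g / q
        t_star = min(max(t_star, lo), hi)
        if not np.isfinite(t_star):
            continue
        gain = seg_gain(t_star)
        if gain > best_gain:
            best_gain, best_t = gain, t_star
    if best_gain > 0:
        beta[i] += best_t
        beta[j] -= best_t
    return best_gain


def train_kernel(D: TrainingSet, kernel: KernelSpec | None = None,
                 P: float = 10.0, eps: float = 0.0,
                 tol: float = 1e-8, max_sweeps: int = 10_000) -> KernelModel:
    """Fit the squared-eps-insensitive kernel machine in the dual.

    eps = 0 uses the linear KKT solve; eps > 0 runs pairwise coordinate
    ascent until the best objective gain in a sweep falls below ``tol``
    (relative to 1 + |J|) or ``max_sweeps`` is reached.  The sum-zero dual
    constraint holds exactly by construction of the updates.
    """
    if len(D) < 2:
        raise ValueError("need at least two training samples")
    if P <= 0:
        raise ValueError("regularization P must be positive")
    if eps < 0:
        raise ValueError("eps must be non-negative")
    kernel = kernel or KernelSpec("rbf", sigma=np.sqrt(D.X.shape[1]))
    K = gram(kernel, D.X)
    y = D.y
    n = len(y)

    if eps == 0:
        beta, c = _solve_eps0(K, y, P)
    else:
        beta = np.zeros(n)
        converged = False
        # Gauss-Southwell pair selection: the feasible directions are
        # (+e_i, -e_j); pick the pair with the largest directional
        # derivative and maximise along it exactly.  At the optimum every
        # such derivative is <= 0 (KKT), which is the stopping rule.
        for _ in range(max_sweeps * n):
            grad = y - K @ beta - beta / P
            up = grad + np.where(beta >= 0, -eps, eps)
            down = -grad + np.where(beta <= 0, -eps, eps)
            i = int(np.argmax(up))
            j = int(np.argmax(down))
            if j == i:
                down_masked = down.copy()
                down_masked[i] = -np.inf
                j = int(np.argmax(down_masked))
            if up[i] + down[j] <= tol:
                converged = True
                break
            gain = _pair_update(beta, i, j, K, y, eps, P)
            if gain <= 1e-15 * (1.0 + float(np.abs(y).max())):
                converged = True  # stalled at numerical precision
                break
        if not converged:
            raise RuntimeError(
                "dual coordinate ascent did not converge "
                f"(max KKT violation {up[i] + down[j]:.3g})"
            )
        # bias from stationarity: for active beta_s,
        # b_s - (K beta)_s - eps sign(beta_s) - beta_s / P = c
        active = np.abs(beta) > 1e-8 * max(1.0, np.max(np.abs(beta)))
        if np.any(active):
            vals = (y - K @ beta - eps * np.sign(beta) - beta / P)[active]
            c = float(np.mean(vals))
        else:
            c = float(np.mean(y))

    keep = np.abs(beta) > 1e-10 * max(1.0, float(np.max(np.abs(beta))) if n else 1.0)
    return KernelModel(beta=beta[keep], bias=c, kernel=kernel,
                       support_vectors=D.X[keep], eps=eps, P=P)


def predict_kernel(model: KernelModel, A) -> np.ndarray | float:
    """f(a) = sum_SV beta_s k(a_s, a) + c; w is never materialised."""
    A = np.asarray(A, dtype=float)
    single = A.ndim == 1
    A2 = np.atleast_2d(A)
    if model.support_vectors.size == 0:
        out = np.full(A2.shape[0], model.bias)
    else:
        Kx = gram(model.kernel, A2, model.support_vectors)
        out = Kx @ model.beta + model.bias
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# CART decision tree
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    feature: int = -1
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None
    distribution: dict = field(default_factory=dict)  # leaf class -> fraction

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class DecisionTreeModel:
    """Greedy binary CART tree: (feature, threshold) splits minimising
    Gini impurity; leaves store class frequency distributions."""

    root: _Node
    max_depth: int
    classes: list

    def to_dict(self) -> dict:
        def enc(node: _Node) -> dict:
            if node.is_leaf:
                return {"leaf": {str(k): v for k, v in node.distribution.items()}}
            return {"feature": node.feature, "threshold": node.threshold,
                    "left": enc(node.left), "right": enc(node.right)}
        return {"tree": enc(self.root), "max_depth": self.max_depth,
                "classes": list(self.classes)}


def gini(labels: np.ndarray) -> float:
    """Gini impurity 1 - sum_c p_c^2 of a label multiset."""
    if len(labels) == 0:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(1.0 - np.sum(p ** 2))


def _best_split(X: np.ndarray, y: np.ndarray, min_leaf: int):
    n, p = X.shape
    best = None  # (weighted_gini, feature, threshold)
    for j in range(p):
        order = np.argsort(X[:, j], kind="stable")
        xs, ys = X[order, j], y[order]
        for i in range(min_leaf, n - min_leaf + 1):
            if i >= n or xs[i - 1] == xs[i]:
                continue
            thr = 0.5 * (xs[i - 1] + xs[i])
            g = (i * gini(ys[:i]) + (n - i) * gini(ys[i:])) / n
            if best is None or g < best[0] - 1e-12:
                best = (g, j, thr)
    return best


def _grow(X: np.ndarray, y: np.ndarray, depth: int, max_depth: int, min_leaf: int) -> _Node:
    classes, counts = np.unique(y, return_counts=True)
    dist = {c: float(k) / len(y) for c, k in zip(classes.tolist(), counts)}
    node = _Node(distribution=dist)
    if depth >= max_depth or len(classes) == 1 or len(y) < 2 * min_leaf:
        return node
    split = _best_split(X, y, min_leaf)
    # zero-gain splits are allowed (XOR-style targets need two levels
    # before any impurity decrease appears); only strictly worse splits stop
    if split is None or split[0] > gini(y) + 1e-12:
        return node
    _, j, thr = split
    mask = X[:, j] <= thr
    node.feature, node.threshold = j, thr
    node.left = _grow(X[mask], y[mask], depth + 1, max_depth, min_leaf)
    node.right = _grow(X[~mask], y[~mask], depth + 1, max_depth, min_leaf)
    return node


def train_tree(D: TrainingSet, max_depth: int = 5, min_leaf: int = 1) -> DecisionTreeModel:
    if len(D) < 1:
        raise ValueError("need at least one sample")
    y = D.y
    root = _grow(D.X, y, 0, max_depth, min_leaf)
    return DecisionTreeModel(root=root, max_depth=max_depth,
                             classes=sorted(set(y.tolist())))


def predict_tree(model: DecisionTreeModel, a) -> tuple[float, float]:
    """Traverse to a leaf; returns (majority class, its probability)."""
    a = np.asarray(a, dtype=float)
    node = model.root
    while not node.is_leaf:
        node = node.left if a[node.feature] <= node.threshold else node.right
    cls = max(node.distribution, key=lambda c: (node.distribution[c], c))
    return cls, node.distribution[cls]


# ---------------------------------------------------------------------------
# Hybrid fusion
# ---------------------------------------------------------------------------

def hybrid_fuse(pred_1: bool, pred_2: bool) -> bool:
    """Two-model fusion truth table: the pair classifies correctly when
    either member does (logical OR); only a double failure fails."""
    return bool(pred_1) or bool(pred_2)


@dataclass
class HybridModel:
    """Exactly two member models of *different* types with OR fusion.

    For binary +-1 problems the default rule flags a beat positive when
    either member calls it positive, so positive-class recall can never
    fall below the better member's.  The "confidence" rule instead takes
    the more confident member when they disagree.
    """

    kernel_model: KernelModel
    tree_model: DecisionTreeModel
    fusion_rule: str = "or_positive"
    positive_class: float = 1.0

    def __post_init__(self) -> None:
        if type(self.kernel_model) is type(self.tree_model):
            raise TypeError("hybrid members must be of different model types")
        if self.fusion_rule not in ("or_positive", "confidence"):
            raise ValueError(f"unknown fusion rule {self.fusion_rule!r}")

    def member_predictions(self, A) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        A = np.atleast_2d(np.asarray(A, dtype=float))
        f = predict_kernel(self.kernel_model, A)
        k_cls = np.where(f >= 0, 1.0, -1.0)
        k_conf = np.abs(f)
        t_cls = np.empty(A.shape[0])
        t_conf = np.empty(A.shape[0])
        for i, a in enumerate(A):
            c, prob = predict_tree(self.tree_model, a)
            t_cls[i], t_conf[i] = c, prob
        return k_cls, k_conf, t_cls, t_conf

    def predict(self, A) -> np.ndarray:
        k_cls, k_conf, t_cls, t_conf = self.member_predictions(A)
        if self.fusion_rule == "or_positive":
            pos = self.positive_class
            return np.where((k_cls == pos) | (t_cls == pos), pos, -pos)
        return np.where(k_conf >= t_conf, k_cls, t_cls)


def train_hybrid(D: TrainingSet, kernel: KernelSpec | None = None,
                 P: float = 10.0, eps: float = 0.0, max_depth: int = 5,
                 min_leaf: int = 1, fusion_rule: str = "or_positive") -> HybridModel:
    """Train the default member pair (kernel machine + decision tree) on
    the same +-1-encoded data."""
    km = train_kernel(D, kernel=kernel, P=P, eps=eps)
    tm = train_tree(D, max_depth=max_depth, min_leaf=min_leaf)
    return HybridModel(kernel_model=km, tree_model=tm, fusion_rule=fusion_rule)
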