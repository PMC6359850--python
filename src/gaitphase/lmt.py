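"""Logistic Model Tree (LMT) induction and inference.

A binary decision tree grown with the C4.5-style information-gain
criterion on numeric features, holding an additive logistic-regression
model (fitted by multiclass LogitBoost with one-feature simple linear
regression base learners) at every node.  Prediction routes an instance
to a leaf, evaluates the leaf's per-class linear scores
``F_i(x) = gamma_i . [1, x]`` and returns the class of greatest
probability ``P_i = exp(F_i) / sum_j exp(F_j)`` (the multinomial
normalization; with two classes this reduces to the familiar sigmoid
``e^F / (1 + e^F)``).

Training follows the standard LMT scheme:

* the LogitBoost iteration count is selected once, at the root, by
  internal stratified cross-validation (the "fast regression"
  heuristic); explicit counts may be given instead;
* each child node warm-starts from its parent's committee and performs
  the selected number of additional boosting iterations on its own
  instances, so deep leaves refine rather than refit;
* splitting stops on purity, on fewer than ``min_instances`` instances,
  or when no candidate split has positive information gain; candidate
  thresholds are midpoints between consecutive distinct sorted feature
  values;
* the grown tree is pruned by CART-style cost-complexity pruning with
  the one-standard-error rule on cross-validated misclassification
  error.

Numeric safeguards: LogitBoost working responses are capped at |z| <= 3
and weights floored at 1e-12 (the usual stabilization); a boosting step
that fails to decrease the training deviance is step-halved, so the
training negative log-likelihood is non-increasing in the iteration
count; leaf scores are clipped to +-500 before exponentiation, which
cannot change the argmax.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .features import FEATURE_NAMES
from .preprocess import PHASE_ORDER, ConfigurationError, InputError

__all__ = [
    "LMTTrainConfig",
    "LMTNode",
    "LMTModel",
    "train_lmt",
    "fit_logitboost",
    "leaf_probabilities",
    "predict_phase",
    "predict_batch",
    "serialize_model",
    "deserialize_model",
]

SCORE_CLIP = 500.0
Z_MAX = 3.0
_W_FLOOR = 1e-12
_GAIN_TOL = 1e-12


@dataclasses.dataclass(frozen=True)
class LMTTrainConfig:
    """Training parameters (defaults follow common LMT practice)."""

    min_instances: int = 15
    num_boosting_iterations: int = -1  # -1 = select automatically
    fast_regression: bool = True
    seed: int = 0
    cv_folds_for_iterations: int = 5
    max_boost_iterations: int = 200
    prune: bool = True
    prune_folds: int = 5

    def __post_init__(self) -> None:
        if self.min_instances < 2:
            raise ConfigurationError("min_instances must be >= 2")
        if self.max_boost_iterations < 1:
            raise ConfigurationError("max_boost_iterations must be >= 1")


class LMTNode:
    """Internal split (feature <= threshold goes left) or leaf.

    Every node carries the per-class coefficient vectors ``gamma``
    (shape K x (d+1), column 0 the intercept) of its boosted logistic
    model; after pruning only leaf models are used for prediction.
    """

    __slots__ = (
        "feature", "threshold", "left", "right",
        "gamma", "n_train", "resub_error", "collapse_alpha",
    )

    def __init__(self) -> None:
        self.feature: int | None = None
        self.threshold: float = 0.0
        self.left: "LMTNode | None" = None
        self.right: "LMTNode | None" = None
        self.gamma: np.ndarray | None = None
        self.n_train: int = 0
        self.resub_error: int = 0
        self.collapse_alpha: float = np.inf

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def make_leaf(self) -> None:
        self.feature = None
        self.left = None
        self.right = None


@dataclasses.dataclass
class LMTModel:
    """A trained logistic model tree."""

    root: LMTNode
    class_order: tuple[str, ...] = PHASE_ORDER
    feature_names: tuple[str, ...] = FEATURE_NAMES
    n_boost_iterations: int = 0
    pruning_info: dict | None = None

    @property
    def tree_size(self) -> int:
        return _count_nodes(self.root)

    @property
    def n_leaves(self) -> int:
        return _count_leaves(self.root)


def _count_nodes(node: LMTNode) -> int:
    if node.is_leaf:
        return 1
    return 1 + _count_nodes(node.left) + _count_nodes(node.right)


def _count_leaves(node: LMTNode) -> int:
    if node.is_leaf:
        return 1
    return _count_leaves(node.left) + _count_leaves(node.right)


# ---------------------------------------------------------------------------
# LogitBoost with simple (one-feature) linear regression base learners
# ---------------------------------------------------------------------------


def _softmax(F: np.ndarray) -> np.ndarray:
    F = np.clip(F, -SCORE_CLIP, SCORE_CLIP)
    F = F - F.max(axis=1, keepdims=True)
    e = np.exp(F)
    return e / e.sum(axis=1, keepdims=True)


def _nll(F: np.ndarray, y_codes: np.ndarray) -> float:
    Fc = np.clip(F, -SCORE_CLIP, SCORE_CLIP)
    m = Fc.max(axis=1)
    lse = m + np.log(np.exp(Fc - m[:, None]).sum(axis=1))
    return float((lse - Fc[np.arange(len(y_codes)), y_codes]).sum())


def _boost(
    X: np.ndarray,
    X2: np.ndarray,
    y_codes: np.ndarray,
    Y1h: np.ndarray,
    F: np.ndarray,
    gamma: np.ndarray,
    n_iter: int,
    X_val: np.ndarray | None = None,
    F_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    val_errors: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Run up to ``n_iter`` LogitBoost iterations in place.

    ``F`` (n x K) holds current committee scores for the training rows
    and ``gamma`` (K x (d+1)) the equivalent collapsed linear model;
    both are updated together.  When validation arrays are supplied the
    held-out misclassification count is accumulated into ``val_errors``
    after every iteration (used by the iteration-count search).
    """
    n, K = Y1h.shape
    c = (K - 1.0) / K
    rows = np.arange(K)
    nll_path: list[float] = []
    cur = _nll(F, y_codes)
    for m in range(n_iter):
        P = _softmax(F)
        W = np.maximum(P * (1.0 - P), _W_FLOOR)
        Z = np.where(
            Y1h > 0,
            np.minimum(1.0 / np.maximum(P, _W_FLOOR), Z_MAX),
            np.maximum(-1.0 / np.maximum(1.0 - P, _W_FLOOR), -Z_MAX),
        )
        WZ = W * Z
        SW = W.sum(axis=0)  # (K,)
        SWX = W.T @ X  # (K, d)
        SWXX = W.T @ X2
        SWZ = WZ.sum(axis=0)
        SWXZ = WZ.T @ X
        SZZ = (WZ * Z).sum(axis=0)

        denom = SWXX - SWX * SWX / SW[:, None]
        ok = denom > 1e-12
        b = np.where(ok, (SWXZ - SWX * SWZ[:, None] / SW[:, None]) / np.where(ok, denom, 1.0), 0.0)
        a = (SWZ[:, None] - b * SWX) / SW[:, None]
        sse = (
            SZZ[:, None]
            - 2.0 * (a * SWZ[:, None] + b * SWXZ)
            + (a * a * SW[:, None] + 2.0 * a * b * SWX + b * b * SWXX)
        )
        j_feat = np.argmin(sse, axis=1)  # (K,)
        a_sel = a[rows, j_feat]
        b_sel = b[rows, j_feat]

        G_raw = a_sel[None, :] + X[:, j_feat] * b_sel[None, :]  # (n, K)
        G = c * (G_raw - G_raw.mean(axis=1, keepdims=True))

        # step-halving keeps the training deviance non-increasing
        scale = 1.0
        accepted = False
        for _ in range(10):
            new = _nll(F + scale * G, y_codes)
            if new <= cur + 1e-10:
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            if val_errors is not None and F_val is not None:
                # pad remaining iterations with the current error level
                err = int((np.argmax(F_val, axis=1) != y_val).sum())
                val_errors[m:n_iter] += err
            break

        F += scale * G
        cur = new
        nll_path.append(cur)

        cc = scale * c
        gamma[:, 0] += cc * (a_sel - a_sel.mean())
        B = np.zeros_like(gamma[:, 1:])
        B[rows, j_feat] = b_sel
        gamma[:, 1:] += cc * (B - B.sum(axis=0) / K)

        if F_val is not None:
            G_raw_v = a_sel[None, :] + X_val[:, j_feat] * b_sel[None, :]
            F_val += scale * c * (G_raw_v - G_raw_v.mean(axis=1, keepdims=True))
            if val_errors is not None:
                val_errors[m] += int((np.argmax(F_val, axis=1) != y_val).sum())
    return gamma, F, nll_path


def fit_logitboost(
    X: np.ndarray,
    y_codes: np.ndarray,
    n_classes: int,
    n_iter: int,
    gamma0: np.ndarray | None = None,
    F0: np.ndarray | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Standalone LogitBoost fit; returns (gamma, per-iteration NLL).

    Equivalent to an LMT forced to a single leaf.  Exposed for direct
    inspection of the boosting objective.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    y_codes = np.asarray(y_codes, dtype=int)
    Y1h = np.zeros((n, n_classes))
    Y1h[np.arange(n), y_codes] = 1.0
    gamma = np.zeros((n_classes, d + 1)) if gamma0 is None else gamma0.copy()
    F = np.zeros((n, n_classes)) if F0 is None else F0.copy()
    gamma, _, nll_path = _boost(X, X * X, y_codes, Y1h, F, gamma, n_iter)
    return gamma, nll_path


def _select_n_iter(
    X: np.ndarray, X2: np.ndarray, y_codes: np.ndarray, K: int, cfg: LMTTrainConfig
) -> int:
    """Root-level iteration-count search by stratified inner CV."""
    n = len(y_codes)
    counts = np.bincount(y_codes, minlength=K)
    folds = min(cfg.cv_folds_for_iterations, int(counts[counts > 0].min()))
    if folds < 2:
        return min(10, cfg.max_boost_iterations)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed % (2**31))
    max_iter = cfg.max_boost_iterations
    val_errors = np.zeros(max_iter)
    for tr, va in skf.split(np.zeros(n), y_codes):
        Y1h = np.zeros((len(tr), K))
        Y1h[np.arange(len(tr)), y_codes[tr]] = 1.0
        _boost(
            X[tr], X2[tr], y_codes[tr], Y1h,
            np.zeros((len(tr), K)), np.zeros((K, X.shape[1] + 1)),
            max_iter,
            X_val=X[va], F_val=np.zeros((len(va), K)),
            y_val=y_codes[va], val_errors=val_errors,
        )
    return int(np.argmin(val_errors)) + 1


# ---------------------------------------------------------------------------
# Split search: information gain over midpoint thresholds
# ---------------------------------------------------------------------------


def _entropy_rows(counts: np.ndarray) -> np.ndarray:
    """Entropy (nats) of each row of class counts."""
    n = counts.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(counts > 0, counts * np.log(counts), 0.0).sum(axis=-1)
        h = np.where(n > 0, np.log(np.maximum(n, 1)) - term / np.maximum(n, 1), 0.0)
    return h


def _best_split(
    Xn: np.ndarray, y_codes: np.ndarray, K: int
) -> tuple[int, float, float] | None:
    """Best (feature, midpoint threshold, gain); None if no positive gain.

    Ties in gain break toward the lower feature index, then the lower
    threshold (argmax picks the first boundary).  Each child must
    receive at least 2 instances.
    """
    n, d = Xn.shape
    total = np.bincount(y_codes, minlength=K).astype(float)
    h_parent = float(_entropy_rows(total))
    best: tuple[int, float, float] | None = None
    best_gain = _GAIN_TOL
    onehot = np.zeros((n, K))
    onehot[np.arange(n), y_codes] = 1.0
    for f in range(d):
        xs = Xn[:, f]
        order = np.argsort(xs, kind="mergesort")
        xv = xs[order]
        cum = onehot[order].cumsum(axis=0)
        # boundary after position i: left has i+1 instances
        i = np.arange(n - 1)
        valid = (xv[:-1] < xv[1:]) & (i + 1 >= 2) & (n - i - 1 >= 2)
        if not valid.any():
            continue
        cl = cum[:-1][valid]
        nl = cl.sum(axis=1)
        cr = total[None, :] - cl
        nr = n - nl
        gain = h_parent - (nl * _entropy_rows(cl) + nr * _entropy_rows(cr)) / n
        j = int(np.argmax(gain))
        if gain[j] > best_gain:
            best_gain = float(gain[j])
            pos = i[valid][j]
            thr = 0.5 * (xv[pos] + xv[pos + 1])
            best = (f, float(thr), best_gain)
    return best


# ---------------------------------------------------------------------------
# Tree growth
# ---------------------------------------------------------------------------


def _grow(
    X: np.ndarray,
    X2: np.ndarray,
    y_codes: np.ndarray,
    idx: np.ndarray,
    F_rows: np.ndarray,
    gamma_parent: np.ndarray,
    n_iter: int,
    cfg: LMTTrainConfig,
    K: int,
) -> LMTNode:
    node = LMTNode()
    Xn, X2n, yn = X[idx], X2[idx], y_codes[idx]
    n = len(idx)
    Y1h = np.zeros((n, K))
    Y1h[np.arange(n), yn] = 1.0
    gamma, F, _ = _boost(Xn, X2n, yn, Y1h, F_rows, gamma_parent.copy(), n_iter)
    node.gamma = gamma
    node.n_train = n
    scores = np.hstack([np.ones((n, 1)), Xn]) @ gamma.T
    node.resub_error = int((np.argmax(scores, axis=1) != yn).sum())

    pure = len(np.unique(yn)) < 2
    if n < cfg.min_instances or pure:
        return node
    split = _best_split(Xn, yn, K)
    if split is None:
        return node
    f, thr, _gain = split
    mask = Xn[:, f] <= thr
    node.feature = f
    node.threshold = thr
    node.left = _grow(X, X2, y_codes, idx[mask], F[mask], gamma, n_iter, cfg, K)
    node.right = _grow(X, X2, y_codes, idx[~mask], F[~mask], gamma, n_iter, cfg, K)
    return node


# ---------------------------------------------------------------------------
# Cost-complexity pruning (CART weakest-link, 1-SE rule on CV error)
# ---------------------------------------------------------------------------


def _label_collapse_alphas(root: LMTNode) -> list[float]:
    """Assign each internal node the alpha at which weakest-link pruning
    collapses it; returns the increasing sequence of distinct alphas."""
    collapsed: set[int] = set()
    alphas: list[float] = []
    prev_alpha = 0.0
    while True:
        stats: dict[int, tuple[float, int]] = {}

        def walk(nd: LMTNode) -> tuple[float, int]:
            if nd.is_leaf or id(nd) in collapsed:
                return float(nd.resub_error), 1
            rl, ll = walk(nd.left)
            rr, lr = walk(nd.right)
            stats[id(nd)] = (rl + rr, ll + lr)
            return rl + rr, ll + lr

        walk(root)
        if not stats:
            break
        internal = {}
        def collect(nd: LMTNode) -> None:
            if nd.is_leaf or id(nd) in collapsed:
                return
            r_sub, leaves = stats[id(nd)]
            g = (nd.resub_error - r_sub) / max(leaves - 1, 1)
            internal[id(nd)] = (g, nd)
            collect(nd.left)
            collect(nd.right)
        collect(root)
        if not internal:
            break
        g_min = min(g for g, _ in internal.values())
        alpha = max(g_min, prev_alpha)  # enforce monotone alpha sequence
        for g, nd in internal.values():
            if g <= g_min + 1e-12:
                nd.collapse_alpha = alpha
                collapsed.add(id(nd))
        if not alphas or alpha > alphas[-1] + 1e-15:
            alphas.append(alpha)
        prev_alpha = alpha
    return alphas


def _pruned_errors(
    root: LMTNode, X: np.ndarray, y_codes: np.ndarray, alphas: Sequence[float]
) -> np.ndarray:
    """Held-out misclassification counts of the tree pruned at each alpha."""
    errs = np.zeros(len(alphas))
    ones = np.ones((len(y_codes), 1))
    Xa = np.hstack([ones, X])
    for ai, alpha in enumerate(alphas):
        def route(nd: LMTNode, rows: np.ndarray) -> int:
            if rows.size == 0:
                return 0
            if nd.is_leaf or nd.collapse_alpha <= alpha + 1e-15:
                pred = np.argmax(Xa[rows] @ nd.gamma.T, axis=1)
                return int((pred != y_codes[rows]).sum())
            mask = X[rows, nd.feature] <= nd.threshold
            return route(nd.left, rows[mask]) + route(nd.right, rows[~mask])

        errs[ai] = route(root, np.arange(len(y_codes)))
    return errs


def _prune_at(node: LMTNode, alpha: float) -> None:
    if node.is_leaf:
        return
    if node.collapse_alpha <= alpha + 1e-15:
        node.make_leaf()
        return
    _prune_at(node.left, alpha)
    _prune_at(node.right, alpha)


def _prune_tree(
    root: LMTNode,
    X: np.ndarray,
    X2: np.ndarray,
    y_codes: np.ndarray,
    n_iter: int,
    cfg: LMTTrainConfig,
    K: int,
) -> dict:
    """Cost-complexity pruning of ``root`` in place; returns diagnostics."""
    main_alphas = _label_collapse_alphas(root)
    if not main_alphas:
        return {"alphas": [0.0], "cv_errors": [float("nan")], "chosen_alpha": 0.0}

    candidates = [0.0]
    seq = [0.0] + main_alphas
    for a0, a1 in zip(seq, seq[1:]):
        candidates.append(float(np.sqrt(a0 * a1)) if a0 > 0 else a1 / 2.0)
    candidates.append(main_alphas[-1] * 2.0)

    n = len(y_codes)
    counts = np.bincount(y_codes, minlength=K)
    folds = min(cfg.prune_folds, int(counts[counts > 0].min()))
    if folds < 2:
        return {"alphas": candidates, "cv_errors": None, "chosen_alpha": 0.0}
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=(cfg.seed + 17) % (2**31))
    cv_err = np.zeros(len(candidates))
    for tr, va in skf.split(np.zeros(n), y_codes):
        sub = _grow(
            X, X2, y_codes, tr,
            np.zeros((len(tr), K)), np.zeros((K, X.shape[1] + 1)),
            n_iter, cfg, K,
        )
        _label_collapse_alphas(sub)
        cv_err += _pruned_errors(sub, X[va], y_codes[va], candidates)

    rates = cv_err / n
    i_min = int(np.argmin(rates))
    se = float(np.sqrt(max(rates[i_min] * (1 - rates[i_min]), 0.0) / n))
    within = [i for i, r in enumerate(rates) if r <= rates[i_min] + se]
    chosen = candidates[max(within)]  # largest alpha within 1 SE -> simplest tree
    _prune_at(root, chosen)
    return {
        "alphas": [float(a) for a in candidates],
        "cv_errors": [float(e) for e in cv_err],
        "cv_error_rates": [float(r) for r in rates],
        "chosen_alpha": float(chosen),
        "one_se": se,
        "n_val_total": n,
    }


# ---------------------------------------------------------------------------
# Public training / inference API
# ---------------------------------------------------------------------------


def train_lmt(
    X,
    y=None,
    config: LMTTrainConfig | None = None,
    class_order: tuple[str, ...] = PHASE_ORDER,
) -> LMTModel:
    """Train a logistic model tree on labelled feature vectors.

    ``X`` may be an (n, d) array with ``y`` a label vector, or a
    DataFrame carrying the 20 feature columns plus ``label``.
    """
    if y is None:
        df = X
        X = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
        y = df["label"].to_numpy(dtype=object)
    cfg = config or LMTTrainConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise InputError("training data must be a nonempty 2-D feature matrix")
    if not np.all(np.isfinite(X)):
        raise InputError("non-finite feature value in training data")
    index = {c: i for i, c in enumerate(class_order)}
    try:
        y_codes = np.asarray([index[str(lab)] for lab in y], dtype=int)
    except KeyError as exc:
        raise InputError(f"unknown class label {exc.args[0]!r}") from exc
    if len(y_codes) != X.shape[0]:
        raise InputError("X and y differ in length")
    K = len(class_order)
    d = X.shape[1]

    present = np.unique(y_codes)
    if present.size == 1:
        leaf = LMTNode()
        gamma = np.zeros((K, d + 1))
        gamma[present[0], 0] = SCORE_CLIP
        leaf.gamma = gamma
        leaf.n_train = len(y_codes)
        return LMTModel(root=leaf, class_order=class_order,
                        feature_names=tuple(f"f{i}" for i in range(d)) if d != len(FEATURE_NAMES) else FEATURE_NAMES,
                        n_boost_iterations=0)

    X2 = X * X
    if cfg.num_boosting_iterations and cfg.num_boosting_iterations > 0:
        n_iter = cfg.num_boosting_iterations
    else:
        n_iter = _select_n_iter(X, X2, y_codes, K, cfg)

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10000))
    try:
        root = _grow(
            X, X2, y_codes, np.arange(X.shape[0]),
            np.zeros((X.shape[0], K)), np.zeros((K, d + 1)),
            n_iter, cfg, K,
        )
        pruning_info = None
        if cfg.prune and not root.is_leaf:
            pruning_info = _prune_tree(root, X, X2, y_codes, n_iter, cfg, K)
    finally:
        sys.setrecursionlimit(old_limit)

    names = FEATURE_NAMES if d == len(FEATURE_NAMES) else tuple(f"f{i}" for i in range(d))
    return LMTModel(
        root=root,
        class_order=class_order,
        feature_names=names,
        n_boost_iterations=n_iter,
        pruning_info=pruning_info,
    )


def _route(node: LMTNode, x: np.ndarray) -> LMTNode:
    while not node.is_leaf:
        node = node.left if x[node.feature] <= node.threshold else node.right
    return node


def leaf_probabilities(model: LMTModel, x) -> np.ndarray:
    """Per-class probabilities of one feature vector (sum to 1)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InputError("non-finite feature value")
    leaf = _route(model.root, x)
    scores = leaf.gamma @ np.concatenate([[1.0], x])
    scores = np.clip(scores, -SCORE_CLIP, SCORE_CLIP)
    scores -= scores.max()
    e = np.exp(scores)
    p = e / e.sum()
    # keep probabilities strictly positive under extreme score spreads
    p = np.maximum(p, 1e-300)
    return p / p.sum()


def predict_phase(model: LMTModel, x) -> str:
    """Class of greatest probability; ties break by class order."""
    p = leaf_probabilities(model, x)
    return model.class_order[int(np.argmax(p))]


def predict_batch(model: LMTModel, X) -> np.ndarray:
    """Vectorized prediction for an (n, d) feature matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InputError("predict_batch expects a 2-D feature matrix")
    if not np.all(np.isfinite(X)):
        raise InputError("non-finite feature value")
    out = np.empty(X.shape[0], dtype=object)
    Xa = np.hstack([np.ones((X.shape[0], 1)), X])
    order = np.asarray(model.class_order, dtype=object)

    def route(nd: LMTNode, rows: np.ndarray) -> None:
        if rows.size == 0:
            return
        if nd.is_leaf:
            pred = np.argmax(Xa[rows] @ nd.gamma.T, axis=1)
            out[rows] = order[pred]
            return
        mask = X[rows, nd.feature] <= nd.threshold
        route(nd.left, rows[mask])
        route(nd.right, rows[~mask])

    route(model.root, np.arange(X.shape[0]))
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1


def _node_to_doc(node: LMTNode) -> dict:
    if node.is_leaf:
        return {"type": "leaf", "gamma": node.gamma.tolist(), "n_train": node.n_train}
    return {
        "type": "split",
        "feature": int(node.feature),
        "threshold": float(node.threshold),
        "left": _node_to_doc(node.left),
        "right": _node_to_doc(node.right),
        "n_train": node.n_train,
    }


def _node_from_doc(doc: dict, path: str) -> LMTNode:
    node = LMTNode()
    kind = doc.get("type")
    if kind == "leaf":
        if "gamma" not in doc:
            raise InputError(f"leaf at {path} missing gamma")
        node.gamma = np.asarray(doc["gamma"], dtype=float)
        node.n_train = int(doc.get("n_train", 0))
        return node
    if kind != "split":
        raise InputError(f"node at {path}: unknown type {kind!r}")
    for key in ("feature", "threshold", "left", "right"):
        if key not in doc:
            raise InputError(f"split at {path} missing {key!r}")
    node.feature = int(doc["feature"])
    node.threshold = float(doc["threshold"])
    node.left = _node_from_doc(doc["left"], path + ".left")
    node.right = _node_from_doc(doc["right"], path + ".right")
    node.n_train = int(doc.get("n_train", 0))
    return node


def serialize_model(model: LMTModel) -> str:
    """Portable JSON document for a trained model (lossless round-trip)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "class_order": list(model.class_order),
        "feature_names": list(model.feature_names),
        "n_boost_iterations": model.n_boost_iterations,
        "tree": _node_to_doc(model.root),
    }
    return json.dumps(doc, indent=1)


def deserialize_model(text: str) -> LMTModel:
    """Parse a model document; raises :class:`InputError` with location."""
    if not text.strip():
        raise InputError("empty model document")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise InputError(
            f"malformed model document at line {exc.lineno}, column {exc.colno}: {exc.msg}"
        ) from exc
    for key in ("schema_version", "class_order", "feature_names", "tree"):
        if key not in doc:
            raise InputError(f"model document missing {key!r}")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise InputError(f"unsupported schema version {doc['schema_version']!r}")
    root = _node_from_doc(doc["tree"], "tree")
    return LMTModel(
        root=root,
        class_order=tuple(doc["class_order"]),
        feature_names=tuple(doc["feature_names"]),
        n_boost_iterations=int(doc.get("n_boost_iterations", 0)),
    )
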