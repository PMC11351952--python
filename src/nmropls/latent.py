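"""From-scratch PCA and two-class OPLS-DA with VIP scores.

OPLS-DA separates class-predictive variation from orthogonal (class-
uncorrelated) variation: each orthogonal component is built from the part of
the loading vector that is orthogonal to the predictive weight and removed
from X by deflation, after which a single predictive PLS component carries
the discrimination.  With zero orthogonal components the model reduces
exactly to one-component PLS1.

The class decision uses the midpoint of the class-mean predicted training
scores as threshold, which stays sensible when cross-validation folds leave
the classes unbalanced.  VIP (variable importance in projection) is computed
on the predictive component only: ``VIP_j = sqrt(J) * |w_j| / ||w||``, so the
squared VIPs always average to 1 over the J features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PcaModel", "OplsModel", "fit_pca", "fit_oplsda", "predict", "vip", "opls_path"]

_EPS = 1e-12


@dataclass
class PcaModel:
    loadings: np.ndarray  # (bins, k), orthonormal columns
    scores: np.ndarray  # (samples, k)
    explained_variance_fraction: np.ndarray  # (k,)


@dataclass
class OplsModel:
    """One fitted two-class OPLS-DA model.

    ``class_labels`` is the ordered pair (positive, negative); the positive
    class is coded +1 and sits above ``decision_threshold`` in predicted
    score.  ``train_column_means``/``train_column_scale`` record the scaling
    statistics of the training split so held-out rows can be projected
    without leakage.
    """

    w_pred: np.ndarray
    p_pred: np.ndarray
    b: float
    w_orth: list[np.ndarray]
    p_orth: list[np.ndarray]
    n_orth: int
    class_labels: tuple[str, str]
    decision_threshold: float
    train_column_means: np.ndarray | None = None
    train_column_scale: np.ndarray | None = None


def fit_pca(X: np.ndarray, k: int) -> PcaModel:
    """PCA by SVD of the (already column-centered) matrix.

    Loadings are right singular vectors ordered by singular value; the sign
    convention makes each loading's largest-magnitude element positive.
    Explained fractions are σᵢ²/Σσ² over all singular values of X.
    """
    X = np.asarray(X, dtype=float)
    n, j = X.shape
    if k > min(n - 1, j):
        raise ValueError(f"k={k} exceeds min(samples-1, bins)={min(n - 1, j)}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(s**2))
    loadings = Vt[:k].T.copy()
    for c in range(k):
        imax = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[imax, c] < 0:
            loadings[:, c] *= -1.0
    scores = X @ loadings
    frac = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PcaModel(loadings=loadings, scores=scores, explained_variance_fraction=frac)


def _pls1_component(X: np.ndarray, yc: np.ndarray):
    """One PLS1 component on centered y: returns (w, t, p, b)."""
    w = X.T @ yc
    nw = float(np.linalg.norm(w))
    if nw < _EPS:
        raise ValueError("degenerate fit: X carries no covariance with y")
    w = w / nw
    t = X @ w
    tt = float(t @ t)
    p = X.T @ t / tt
    b = float(t @ yc) / tt
    return w, t, p, b


def opls_path(X: np.ndarray, yc: np.ndarray, max_orth: int):
    """Fit OPLS models for every orthogonal-component count 0..max_orth.

    One deflation pass yields the whole path, since the model with k
    orthogonal components is the predictive fit on X after k deflations.
    Returns a list of dicts with keys ``w_orth, p_orth, w, p, b, t`` —
    the list is truncated early if no orthogonal variation remains.
    """
    Xd = np.array(X, dtype=float)
    w_os: list[np.ndarray] = []
    p_os: list[np.ndarray] = []
    out = []
    for k in range(max_orth + 1):
        w, t, p, b = _pls1_component(Xd, yc)
        out.append({"w_orth": list(w_os), "p_orth": list(p_os), "w": w, "p": p, "b": b, "t": t})
        if k == max_orth:
            break
        w_o = p - float(w @ p) * w
        n_o = float(np.linalg.norm(w_o))
        if n_o < 1e-10:
            break  # rank exhausted: no orthogonal variation left
        w_o = w_o / n_o
        t_o = Xd @ w_o
        tt_o = float(t_o @ t_o)
        if tt_o < _EPS:
            break
        p_o = Xd.T @ t_o / tt_o
        Xd = Xd - np.outer(t_o, p_o)
        w_os = w_os + [w_o]
        p_os = p_os + [p_o]
    return out


def _threshold(scores: np.ndarray, ypos: np.ndarray) -> float:
    """Midpoint of the class-mean predicted scores."""
    return 0.5 * (float(scores[ypos].mean()) + float(scores[~ypos].mean()))


def fit_oplsda(
    X: np.ndarray,
    y,
    n_orth: int = 1,
    class_labels: tuple[str, str] | None = None,
) -> OplsModel:
    """Fit a two-class OPLS-DA model on a scaled matrix.

    ``y`` may be ±1 or a label vector; with labels, ``class_labels`` fixes
    which is the positive class (default: first label in order of
    appearance).  X is assumed centered/Pareto-scaled already.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if n_orth < 0:
        raise ValueError("n_orth must be >= 0")
    if class_labels is None:
        if y.dtype.kind in "if" and set(np.unique(y)) <= {-1.0, 1.0}:
            class_labels = ("+1", "-1")
            ypm = y.astype(float)
        else:
            uniq = list(dict.fromkeys(y.tolist()))
            if len(uniq) != 2:
                raise ValueError(f"need exactly two classes, got {uniq}")
            class_labels = (str(uniq[0]), str(uniq[1]))
            ypm = np.where(y == uniq[0], 1.0, -1.0)
    else:
        ypm = np.where(y.astype(str) == class_labels[0], 1.0, -1.0)
    if len(set(ypm.tolist())) < 2:
        raise ValueError("both classes must be present")
    if n_orth >= min(X.shape[0] - 1, X.shape[1]):
        raise ValueError(f"n_orth={n_orth} too large for matrix of shape {X.shape}")

    yc = ypm - ypm.mean()
    path = opls_path(X, yc, n_orth)
    if len(path) <= n_orth:
        raise ValueError(f"n_orth={n_orth} exceeds the rank of X")
    m = path[n_orth]
    scores = m["b"] * m["t"]
    return OplsModel(
        w_pred=m["w"],
        p_pred=m["p"],
        b=m["b"],
        w_orth=m["w_orth"],
        p_orth=m["p_orth"],
        n_orth=n_orth,
        class_labels=class_labels,
        decision_threshold=_threshold(scores, ypm > 0),
    )


def predict(m: OplsModel, Xnew: np.ndarray):
    """Predicted scores and class labels for new (already scaled) rows.

    Orthogonal variation is removed with the stored weights/loadings, then
    score = b · (X_deflated · w_pred); rows at or above the threshold get the
    positive (first-listed) class, so an exact tie resolves to it.
    """
    Xd = np.atleast_2d(np.asarray(Xnew, dtype=float)).copy()
    if Xd.shape[1] != m.w_pred.size:
        raise ValueError(f"bin mismatch: model has {m.w_pred.size}, got {Xd.shape[1]}")
    for w_o, p_o in zip(m.w_orth, m.p_orth):
        t_o = Xd @ w_o
        Xd -= np.outer(t_o, p_o)
    scores = m.b * (Xd @ m.w_pred)
    labels = np.where(scores >= m.decision_threshold, m.class_labels[0], m.class_labels[1])
    return scores, labels


def vip(m: OplsModel) -> np.ndarray:
    """VIP on the predictive component: sqrt(J)·|w_j|/‖w‖ (so Σ VIP² = J)."""
    w = m.w_pred
    return np.sqrt(w.size) * np.abs(w) / float(np.linalg.norm(w))
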