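"""Latent-variable models: PCA with Q-residual screening, orthogonal signal
correction (OSC), NIPALS PLS-DA, and the multilevel between/within-subject
decomposition.

The supervised chain is OSC followed by PLS-DA ("o-PLS-DA"): centering and
OSC are fitted on training data only and re-applied, via stored means and
weights, to held-out rows.  Multilevel PLS-DA is ordinary PLS-DA fitted on
the within-subject part of the paired-sample variance decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .preprocess import mean_center

__all__ = [
    "PcaModel", "fit_pca", "q_residual_screen",
    "OscComponents", "osc_filter", "apply_osc",
    "PlsdaModel", "fit_plsda", "predict", "save_model", "load_model",
    "MultilevelSplit", "multilevel_split", "encode_classes",
]


# --------------------------------------------------------------------------
# PCA

@dataclass
class PcaModel:
    n_components: int
    scores: np.ndarray                    # samples x components
    loadings: np.ndarray                  # points x components, orthonormal
    explained_variance_fraction: np.ndarray
    eigenvalues: np.ndarray               # all eigenvalues of X'X/(n-1)
    q_limit: float                        # Jackson-Mudholkar 95% limit


def _fix_signs(U: np.ndarray, Vt: np.ndarray):
    """Deterministic sign convention: largest-|.| loading element positive."""
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    return U, Vt


def _jackson_mudholkar(residual_eigs: np.ndarray, alpha: float = 0.05) -> float:
    """95% Q-residual control limit from the residual eigenvalues."""
    lam = residual_eigs[residual_eigs > 1e-30]
    if lam.size == 0:
        return 0.0
    t1, t2, t3 = lam.sum(), (lam**2).sum(), (lam**3).sum()
    h0 = 1.0 - 2.0 * t1 * t3 / (3.0 * t2**2)
    if h0 <= 0:
        h0 = 1e-3
    z = norm.ppf(1.0 - alpha)
    inner = (z * np.sqrt(2.0 * t2 * h0**2) / t1
             + 1.0 + t2 * h0 * (h0 - 1.0) / t1**2)
    return float(t1 * inner ** (1.0 / h0))


def fit_pca(X: np.ndarray, n_components: int) -> PcaModel:
    """PCA of a centered matrix via SVD.

    Explained-variance fractions are relative to the total variance of X;
    the Q-residual limit is computed from the eigenvalues left out of the
    model (Jackson-Mudholkar approximation, alpha = 0.05).
    """
    X = np.asarray(X, dtype=float)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_rank:
        raise ValueError(
            f"n_components {n_components} exceeds min(rows-1, cols) = {max_rank}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    U, Vt = _fix_signs(U, Vt)
    eigs = s**2 / (X.shape[0] - 1)
    total = float((s**2).sum())
    k = n_components
    return PcaModel(
        n_components=k,
        scores=U[:, :k] * s[:k],
        loadings=Vt[:k].T.copy(),
        explained_variance_fraction=s[:k] ** 2 / (total if total > 0 else 1.0),
        eigenvalues=eigs,
        q_limit=_jackson_mudholkar(eigs[k:]),
    )


def q_residual_screen(model: PcaModel, X: np.ndarray):
    """Per-sample squared reconstruction residuals and the excluded indices.

    q_i = ||x_i - x_i P P'||^2; samples with q above the model's
    Jackson-Mudholkar limit are flagged for exclusion (never silently
    dropped: callers decide and log).
    """
    X = np.asarray(X, dtype=float)
    P = model.loadings
    resid = X - (X @ P) @ P.T
    q = np.einsum("ij,ij->i", resid, resid)
    excluded = np.flatnonzero(q > model.q_limit)
    return q, excluded


# --------------------------------------------------------------------------
# class encoding

def encode_classes(y, classes=None):
    """Encode labels for PLS: two classes -> one ±1 column (sorted order,
    first class = -1); more -> one-hot columns in sorted class order.

    Returns (Y, classes, targets) where targets[i] is the code row of
    classes[i]."""
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist()) if classes is None else list(classes)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if len(classes) == 2:
        Y = np.where(y == classes[1], 1.0, -1.0)[:, None]
        targets = np.array([[-1.0], [1.0]])
    else:
        Y = np.zeros((y.size, len(classes)))
        for j, c in enumerate(classes):
            Y[y == c, j] = 1.0
        targets = np.eye(len(classes))
    return Y, classes, targets


# --------------------------------------------------------------------------
# OSC

@dataclass
class OscComponents:
    """Weights/loadings of the removed y-orthogonal components.

    For each component, score t = X @ weights[:, k] and the deflation is
    X <- X - t @ loadings[:, k].T."""
    weights: np.ndarray                    # p x k
    loadings: np.ndarray                   # p x k

    @property
    def n_components(self) -> int:
        return self.weights.shape[1] if self.weights.size else 0


def osc_filter(X: np.ndarray, y, n_osc: int, classes=None):
    """Wold-style NIPALS orthogonal signal correction.

    Removes ``n_osc`` components of X-variation orthogonal to the class
    targets by alternating projection between the row space of X and the
    orthogonal complement of Y; each converged score lies (numerically) in
    both, so corr(t, y) ~ 0.  Returns (X_filtered, OscComponents).
    """
    X = np.asarray(X, dtype=float)
    if n_osc < 0:
        raise ValueError("n_osc must be >= 0")
    if n_osc == 0:
        return X.copy(), OscComponents(np.zeros((X.shape[1], 0)),
                                       np.zeros((X.shape[1], 0)))
    Y, _, _ = encode_classes(y, classes)
    Yc = Y - Y.mean(axis=0)
    # projector onto the complement of span(Yc)
    Q, _ = np.linalg.qr(Yc)

    Xd = X.copy()
    W = np.zeros((X.shape[1], n_osc))
    P = np.zeros((X.shape[1], n_osc))
    for k in range(n_osc):
        # all heavy algebra on the n x n Gram matrix
        G = Xd @ Xd.T
        evals, evecs = np.linalg.eigh(G)
        tol = max(G.shape[0], Xd.shape[1]) * np.finfo(float).eps * \
            max(evals[-1], 0.0)
        live = evals > tol
        rank = int(live.sum())
        if n_osc >= rank + k:
            raise ValueError(
                f"n_osc = {n_osc} must be < rank(X) = {rank + k}")
        V = evecs[:, live]
        d = evals[live]
        t = V[:, -1] * np.sqrt(d[-1])          # first principal score
        if t[np.argmax(np.abs(t))] < 0:
            t = -t
        # alternating projection: row space of X <-> orthogonal complement
        # of Y; the limit lies in both, so corr(t, y) -> 0
        for _ in range(500):
            t_orth = t - Q @ (Q.T @ t)
            t_new = V @ (V.T @ t_orth)
            if np.linalg.norm(t_new - t) <= 1e-13 * max(
                    np.linalg.norm(t), 1e-30):
                t = t_new
                break
            t = t_new
        w = Xd.T @ (V @ ((V.T @ t) / d))       # min-norm solve X w = t
        nrm = np.linalg.norm(w)
        if nrm < 1e-30:
            raise ValueError("OSC component collapsed; reduce n_osc")
        w = w / nrm
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        Xd = Xd - np.outer(t, p)
        W[:, k], P[:, k] = w, p
    return Xd, OscComponents(W, P)


def apply_osc(osc: OscComponents, X: np.ndarray) -> np.ndarray:
    """Filter new (already centered) rows with stored OSC weights/loadings."""
    X = np.asarray(X, dtype=float).copy()
    for k in range(osc.n_components):
        t = X @ osc.weights[:, k]
        X -= np.outer(t, osc.loadings[:, k])
    return X


# --------------------------------------------------------------------------
# PLS-DA

@dataclass
class PlsdaModel:
    """OSC + NIPALS PLS-DA model.

    x_weights/x_loadings/y_loadings hold one column per latent variable;
    ``regression_vector`` is the full-LV coefficient matrix (p x m) and
    ``regression_per_lv[a]`` the coefficients using latent variables 1..a+1.
    """
    n_latent_variables: int
    classes: list
    class_targets: np.ndarray             # encoded target row per class
    training_column_means: np.ndarray
    y_means: np.ndarray
    osc: OscComponents
    x_weights: np.ndarray                 # p x A
    x_scores: np.ndarray                  # n x A
    x_loadings: np.ndarray                # p x A
    y_loadings: np.ndarray                # m x A
    regression_vector: np.ndarray         # p x m
    regression_per_lv: list = field(default_factory=list)

    @property
    def n_osc_components(self) -> int:
        return self.osc.n_components

    @property
    def class_encoding(self) -> dict:
        return {c: self.class_targets[i].tolist()
                for i, c in enumerate(self.classes)}


def fit_plsda(X: np.ndarray, y, n_lv: int, n_osc: int = 0,
              center: bool = True, classes=None) -> PlsdaModel:
    """NIPALS PLS-DA (PLS1 for two classes, PLS2 one-hot otherwise).

    X is column-centered (means stored), OSC-filtered with ``n_osc``
    components, then decomposed into at most ``n_lv`` latent variables.
    X is deflated per LV and Y is deflated through the X-scores (PLS2), so
    the regression vector reproduces the training fit exactly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    if np.unique(y).size < 2:
        raise ValueError("PLS-DA needs at least two classes in y")
    Y, cls, targets = encode_classes(y, classes)

    if center:
        Xc, means = mean_center(X)
    else:
        Xc, means = X.copy(), np.zeros(X.shape[1])
    y_means = Y.mean(axis=0)
    Yc = Y - y_means

    Xf, osc = osc_filter(Xc, y, n_osc, classes=cls) if n_osc else (
        Xc.copy(), OscComponents(np.zeros((X.shape[1], 0)),
                                 np.zeros((X.shape[1], 0))))

    n, p = Xf.shape
    m = Yc.shape[1]
    A = min(n_lv, n - (1 if center else 0), p)
    W = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    C = np.zeros((m, A))
    Xd, Yd = Xf.copy(), Yc.copy()
    actual = 0
    for a in range(A):
        u = Yd[:, int(np.argmax(Yd.var(axis=0)))]
        if np.linalg.norm(u) < 1e-12:
            break
        t_old = None
        for _ in range(500):
            w = Xd.T @ u
            wn = np.linalg.norm(w)
            if wn < 1e-14:
                break
            w = w / wn
            t = Xd @ w
            tt = t @ t
            if tt < 1e-28:
                break
            c = Yd.T @ t / tt
            u = Yd @ c / (c @ c)
            if t_old is not None and \
                    np.linalg.norm(t - t_old) <= 1e-12 * np.linalg.norm(t):
                break
            t_old = t
        else:
            pass
        if np.linalg.norm(w) < 1e-14 or (t @ t) < 1e-28:
            break
        p_vec = Xd.T @ t / (t @ t)
        Xd = Xd - np.outer(t, p_vec)
        Yd = Yd - np.outer(t, c)
        W[:, a], T[:, a], P[:, a], C[:, a] = w, t, p_vec, c
        actual = a + 1
    if actual == 0:
        raise ValueError("no latent variable could be extracted (X ~ 0)")
    W, T, P, C = W[:, :actual], T[:, :actual], P[:, :actual], C[:, :actual]

    per_lv = []
    for a in range(1, actual + 1):
        Wa, Pa, Ca = W[:, :a], P[:, :a], C[:, :a]
        Ba = Wa @ np.linalg.solve(Pa.T @ Wa, Ca.T)
        per_lv.append(Ba)
    return PlsdaModel(
        n_latent_variables=actual, classes=cls, class_targets=targets,
        training_column_means=means, y_means=y_means, osc=osc,
        x_weights=W, x_scores=T, x_loadings=P, y_loadings=C,
        regression_vector=per_lv[-1], regression_per_lv=per_lv)


def predict(model: PlsdaModel, X_new: np.ndarray, n_lv: int | None = None):
    """Continuous predictions and class assignments for new rows.

    New rows are centered with the *training* means, OSC-filtered with the
    training weights, and pushed through the regression vector for the first
    ``n_lv`` latent variables (default: all fitted).  The class is the
    nearest encoded target; exact ties go to the lexicographically first
    class.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.training_column_means.size:
        raise ValueError(
            f"column count {X_new.shape[1]} does not match training "
            f"({model.training_column_means.size})")
    a = model.n_latent_variables if n_lv is None else \
        min(n_lv, model.n_latent_variables)
    if a < 1:
        raise ValueError("n_lv must be >= 1")
    Xc = X_new - model.training_column_means
    Xc = apply_osc(model.osc, Xc)
    yhat = Xc @ model.regression_per_lv[a - 1] + model.y_means
    d2 = ((yhat[:, None, :] - model.class_targets[None, :, :]) ** 2).sum(-1)
    assign = np.array([model.classes[j] for j in np.argmin(d2, axis=1)])
    return yhat, assign


def save_model(model: PlsdaModel, path) -> None:
    """Serialize a fitted PLS-DA model (weights, means, encodings) to JSON
    so it can be reapplied to new matrices."""
    import json
    doc = {
        "format": "nmrfield-plsda-v1",
        "n_latent_variables": model.n_latent_variables,
        "classes": list(model.classes),
        "class_targets": model.class_targets.tolist(),
        "training_column_means": model.training_column_means.tolist(),
        "y_means": model.y_means.tolist(),
        "osc_weights": model.osc.weights.tolist(),
        "osc_loadings": model.osc.loadings.tolist(),
        "x_weights": model.x_weights.tolist(),
        "x_scores": model.x_scores.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "regression_per_lv": [b.tolist() for b in model.regression_per_lv],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True)


def load_model(path) -> PlsdaModel:
    """Inverse of :func:`save_model`."""
    import json
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "nmrfield-plsda-v1":
        raise ValueError(f"{path}: not an nmrfield PLS-DA model file")
    arr = lambda k: np.asarray(doc[k], dtype=float)  # noqa: E731
    per_lv = [np.asarray(b, dtype=float) for b in doc["regression_per_lv"]]
    return PlsdaModel(
        n_latent_variables=int(doc["n_latent_variables"]),
        classes=doc["classes"], class_targets=arr("class_targets"),
        training_column_means=arr("training_column_means"),
        y_means=arr("y_means"),
        osc=OscComponents(arr("osc_weights"), arr("osc_loadings")),
        x_weights=arr("x_weights"), x_scores=arr("x_scores"),
        x_loadings=arr("x_loadings"), y_loadings=arr("y_loadings"),
        regression_vector=per_lv[-1], regression_per_lv=per_lv)


# --------------------------------------------------------------------------
# multilevel decomposition

@dataclass
class MultilevelSplit:
    """Between/within-subject variance decomposition of a paired design.

    X = grand_mean + between + within row-wise; each subject's within rows
    sum to the zero vector."""
    grand_mean: np.ndarray
    between_matrix: np.ndarray
    within_matrix: np.ndarray
    subject_ids: np.ndarray


def multilevel_split(X: np.ndarray, subject_ids) -> MultilevelSplit:
    """Split X into subject means (between) and deviations (within).

    Every subject must contribute at least two samples; multilevel PLS-DA is
    ordinary PLS-DA fitted on ``within_matrix``.
    """
    X = np.asarray(X, dtype=float)
    subject_ids = np.asarray(subject_ids)
    if subject_ids.size != X.shape[0]:
        raise ValueError("subject_ids length must match row count")
    grand = X.mean(axis=0)
    between = np.empty_like(X)
    within = np.empty_like(X)
    for s in np.unique(subject_ids):
        rows = np.flatnonzero(subject_ids == s)
        if rows.size < 2:
            raise ValueError(
                f"subject {s!r} has a single sample; paired design required")
        sm = X[rows].mean(axis=0)
        between[rows] = sm - grand
        within[rows] = X[rows] - sm
    return MultilevelSplit(grand, between, within, subject_ids)
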