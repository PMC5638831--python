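"""Multivariate modelling: PCA, orthogonal signal correction (OSC),
NIPALS PLS-DA, repeated two-fold cross-validated Q2Y, permutation testing,
S-plots and correlation-coded loading pseudo-spectra.

Model conventions
-----------------
* ``Y`` is the dummy-coded class-membership matrix (one column per class,
  entries 0/1, columns summing to group sizes); it is centered internally.
* ``X`` is expected column-centered for full-data fits. Inside
  cross-validation, centering (and OSC, when enabled) is re-fit on each
  training fold and applied to the held-out fold, so Q2Y is leakage-free;
  the leaky variant (filter once on all data) is available via
  ``refit_osc=False`` for comparison with tools that filter up front.
* Every score/weight/loading vector carries a deterministic sign
  (largest-magnitude loading element positive) so outputs are reproducible.

Validation follows common chemometric practice for small-n metabolomics:
R2Y for goodness of fit, Q2Y from repeated stratified two-fold
cross-validation (Q2Y > 0.5 conventionally indicates group separation),
and an empirical p-value from permuting class labels, with
p = (1 + #{null >= observed}) / (n_perm + 1) so 2000 permutations floor at
1/2001 ~ 5e-04.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError
from .spectra import FeatureMatrix

# ---------------------------------------------------------------------------
# helpers


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, FeatureMatrix):
        return np.asarray(x.X, float)
    return np.asarray(x, float)


def dummy_code(labels) -> tuple[np.ndarray, list[str]]:
    """Class-membership matrix (samples x classes, 0/1) and class order."""
    labels = np.asarray(labels)
    classes = sorted(pd.unique(labels).tolist())
    Y = np.zeros((labels.size, len(classes)))
    for j, c in enumerate(classes):
        Y[labels == c, j] = 1.0
    return Y, classes


def _fix_sign(loading_like: np.ndarray, *followers: np.ndarray) -> None:
    """In-place column sign convention: largest-|element| positive."""
    for j in range(loading_like.shape[1]):
        i = int(np.argmax(np.abs(loading_like[:, j])))
        if loading_like[i, j] < 0:
            loading_like[:, j] *= -1
            for f in followers:
                f[:, j] *= -1


def _check_centered(X: np.ndarray, what: str) -> None:
    scale = np.abs(X).max() or 1.0
    if np.abs(X.mean(axis=0)).max() > 1e-6 * scale:
        raise InputError(f"{what}: X must be column-centered")


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaModel:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray


def pca(fm, k: int) -> PcaModel:
    """SVD-based PCA of a centered matrix; scores = X @ loadings."""
    X = _as_matrix(fm)
    if isinstance(fm, FeatureMatrix) and not fm.centered:
        raise InputError("pca: FeatureMatrix must be mean-centered first")
    _check_centered(X, "pca")
    n, p = X.shape
    if not 1 <= k <= min(n - 1, p):
        raise InputError(f"pca: k={k} outside [1, {min(n - 1, p)}]")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    loadings = Vt[:k].T.copy()
    scores = U[:, :k] * S[:k]
    _fix_sign(loadings, scores)
    ratio = (S**2 / (S**2).sum())[:k]
    return PcaModel(scores, loadings, ratio)


# ---------------------------------------------------------------------------
# OSC


@dataclass
class OscFilter:
    n_removed: int
    removed_scores: np.ndarray  # samples x n
    removed_loadings: np.ndarray  # features x n
    removed_weights: np.ndarray  # features x n
    r2x_removed: float
    converged: bool = True
    n_iter: list[int] | None = None

    def apply(self, X_new: np.ndarray) -> np.ndarray:
        """Filter new (already centered with training means) data."""
        X = np.asarray(X_new, float).copy()
        for j in range(self.n_removed):
            t = X @ self.removed_weights[:, j]
            X -= np.outer(t, self.removed_loadings[:, j])
        return X


def osc_filter(
    X, Y: np.ndarray, n_osc: int = 1, tol: float = 1e-8, max_iter: int = 100
) -> tuple[np.ndarray, OscFilter]:
    """Remove ``n_osc`` components of X-variation orthogonal to class
    membership before PLS-DA.

    Per component: start from the first PC score, orthogonalize it to the
    class space (t <- t - Y (Y'Y)^-1 Y' t), regress X on t for normalized
    weights, recompute t = Xw, iterate to convergence; deflate
    X <- X - t p' with p = X't / t't. Removed scores are exactly orthogonal
    to Y by a final projection. Non-convergence is flagged, not fatal.
    """
    X = _as_matrix(X).copy()
    Y = np.asarray(Y, float)
    _check_centered(X, "osc_filter")
    if n_osc < 1:
        raise InputError("osc_filter: n_osc must be >= 1")
    ss_total = (X**2).sum()
    proj = np.linalg.pinv(Y.T @ Y) @ Y.T  # (Y'Y)^-1 Y'

    def orth(t):
        return t - Y @ (proj @ t)

    scores, loadings, weights, iters = [], [], [], []
    removed_ss = 0.0
    converged = True
    for _ in range(n_osc):
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        t = U[:, 0] * S[0]
        it = 0
        for it in range(1, max_iter + 1):
            t_old = t
            to = orth(t)
            w = X.T @ to / (to @ to)
            w /= np.linalg.norm(w)
            t = X @ w
            if np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
        else:
            converged = False
        t = orth(X @ w)
        p = X.T @ t / (t @ t)
        X -= np.outer(t, p)
        removed_ss += (t @ t) * (p @ p)
        scores.append(t)
        loadings.append(p)
        weights.append(w)
        iters.append(it)
    W = np.column_stack(weights)
    P = np.column_stack(loadings)
    T = np.column_stack(scores)
    _fix_sign(P, W, T)
    filt = OscFilter(
        n_removed=n_osc,
        removed_scores=T,
        removed_loadings=P,
        removed_weights=W,
        r2x_removed=float(removed_ss / ss_total) if ss_total > 0 else 0.0,
        converged=converged,
        n_iter=iters,
    )
    if not converged:
        warnings.warn(
            f"OSC did not converge within {max_iter} iterations {iters}",
            RuntimeWarning,
        )
    return X, filt


# ---------------------------------------------------------------------------
# PLS-DA (NIPALS, X-deflation only)


@dataclass
class PlsdaModel:
    n_components: int
    x_weights: np.ndarray  # features x k
    x_loadings: np.ndarray  # features x k
    y_loadings: np.ndarray  # classes x k
    scores: np.ndarray  # samples x k
    coefficients: np.ndarray  # features x classes
    y_mean: np.ndarray
    classes: list[str] | None = None
    r2y: float = np.nan

    def predict(self, X_centered: np.ndarray) -> np.ndarray:
        return np.asarray(X_centered, float) @ self.coefficients + self.y_mean


def plsda_fit(X, Y: np.ndarray, k: int, max_iter: int = 500, tol: float = 1e-10) -> PlsdaModel:
    """NIPALS PLS2 against a dummy-coded class matrix.

    X is deflated per component, Y is not; predictions use
    B = W (P'W)^-1 Q'. R2Y = 1 - ||Yc - XB||^2 / ||Yc||^2 is
    non-decreasing in k.
    """
    X = _as_matrix(X)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    _check_centered(X, "plsda_fit")
    if not (X**2).sum() > 0:
        raise InputError("plsda_fit: X has zero variance")
    n, p = X.shape
    if not 1 <= k <= min(n - 1, p):
        raise InputError(f"plsda_fit: k={k} outside [1, {min(n - 1, p)}]")
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean
    Xd = X.copy()
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    Q = np.zeros((Y.shape[1], k))
    T = np.zeros((n, k))
    for a in range(k):
        u = Yc[:, int(np.argmax(Yc.var(axis=0)))]
        t = np.zeros(n)
        for _ in range(max_iter):
            w = Xd.T @ u / (u @ u)
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t_new = Xd @ w
            q = Yc.T @ t_new / (t_new @ t_new)
            u = Yc @ q / (q @ q)
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-30):
                t = t_new
                break
            t = t_new
        pl = Xd.T @ t / (t @ t)
        Xd -= np.outer(t, pl)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, pl, q, t
    # deterministic signs: flip (w, p, q, t) together per component
    for a in range(k):
        i = int(np.argmax(np.abs(W[:, a])))
        if W[i, a] < 0:
            W[:, a] *= -1
            P[:, a] *= -1
            Q[:, a] *= -1
            T[:, a] *= -1
    B = W @ np.linalg.solve(P.T @ W, Q.T)
    resid = Yc - X @ B
    r2y = 1.0 - (resid**2).sum() / (Yc**2).sum()
    return PlsdaModel(
        n_components=k, x_weights=W, x_loadings=P, y_loadings=Q,
        scores=T, coefficients=B, y_mean=y_mean, r2y=float(r2y),
    )


# ---------------------------------------------------------------------------
# cross-validation and permutation testing


def _stratified_folds(labels: np.ndarray, folds: int, rng: np.random.Generator):
    """Fold index per sample; each class dealt round-robin after shuffling."""
    assign = np.empty(labels.size, int)
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        rng.shuffle(idx)
        assign[idx] = np.arange(idx.size) % folds
    return assign


def cross_validate_q2(
    X,
    Y: np.ndarray,
    k: int,
    repeats: int = 50,
    folds: int = 2,
    seed: int = 0,
    n_osc: int = 0,
    refit_osc: bool = True,
    osc_prefit: OscFilter | None = None,
) -> float:
    """Q2Y from repeated stratified ``folds``-fold cross-validation.

    PRESS and the total sum of squares (against training-fold Y means) are
    pooled over all repeats and folds: Q2Y = 1 - PRESS / SS_total.
    Centering, and OSC when ``n_osc > 0`` and ``refit_osc``, are re-fit on
    each training fold only.
    """
    X = _as_matrix(X)
    Y = np.asarray(Y, float)
    labels = Y.argmax(axis=1)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        raise InputError(
            f"every group needs >= {folds} samples for {folds}-fold CV "
            f"(smallest has {counts.min()})"
        )
    rng = np.random.default_rng(seed)
    press = 0.0
    ss_tot = 0.0
    for _ in range(repeats):
        assign = _stratified_folds(labels, folds, rng)
        for f in range(folds):
            test = assign == f
            train = ~test
            x_mean = X[train].mean(axis=0)
            Xtr, Xte = X[train] - x_mean, X[test] - x_mean
            if n_osc > 0:
                if refit_osc:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        Xtr, filt = osc_filter(Xtr, Y[train], n_osc=n_osc)
                    Xte = filt.apply(Xte)
                elif osc_prefit is not None:
                    Xtr = osc_prefit.apply(Xtr)
                    Xte = osc_prefit.apply(Xte)
            kk = min(k, Xtr.shape[0] - 1, Xtr.shape[1])
            model = plsda_fit(Xtr, Y[train], kk)
            pred = model.predict(Xte)
            press += ((Y[test] - pred) ** 2).sum()
            ss_tot += ((Y[test] - model.y_mean) ** 2).sum()
    return float(1.0 - press / ss_tot)


@dataclass
class ModelValidation:
    r2y: float
    q2y: float
    p_perm: float
    null_stats: np.ndarray
    n_perm: int
    cv_repeats: int
    folds: int = 2
    observed_stat: float = np.nan

    def to_dict(self) -> dict:
        return {
            "r2y": self.r2y, "q2y": self.q2y, "p_perm": self.p_perm,
            "n_perm": self.n_perm, "cv_repeats": self.cv_repeats,
            "folds": self.folds, "observed_stat": self.observed_stat,
        }


def permutation_test(
    X,
    Y: np.ndarray,
    k: int,
    n_perm: int = 2000,
    seed: int = 0,
    cv_repeats: int = 50,
    perm_repeats: int = 7,
    folds: int = 2,
    n_osc: int = 0,
    refit_osc: bool = True,
) -> ModelValidation:
    """Label-permutation significance of an (OSC-)PLS-DA model.

    The test statistic is Q2Y from reduced-repeat CV (``perm_repeats``,
    default 7) evaluated identically for the observed and each permuted
    labeling with a shared fold-assignment stream, so the permutation test
    is exact. The reported ``q2y`` uses the full ``cv_repeats``; ``r2y``
    comes from a full-data fit (after OSC on all data when ``n_osc > 0``).
    """
    if n_perm < 1:
        raise InputError("permutation_test: n_perm must be >= 1")
    X = _as_matrix(X)
    Y = np.asarray(Y, float)
    master = np.random.SeedSequence(seed)
    fold_seed, perm_seed, cv_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(3)
    )
    stat = lambda Yp: cross_validate_q2(
        X, Yp, k, repeats=perm_repeats, folds=folds, seed=fold_seed,
        n_osc=n_osc, refit_osc=refit_osc,
    )
    observed = stat(Y)
    rng = np.random.default_rng(perm_seed)
    null = np.empty(n_perm)
    n = X.shape[0]
    for b in range(n_perm):
        null[b] = stat(Y[rng.permutation(n)])
    p = (1.0 + np.count_nonzero(null >= observed)) / (n_perm + 1.0)

    q2y = cross_validate_q2(
        X, Y, k, repeats=cv_repeats, folds=folds, seed=cv_seed,
        n_osc=n_osc, refit_osc=refit_osc,
    )
    Xc = X - X.mean(axis=0)
    if n_osc > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            Xc, _ = osc_filter(Xc, Y, n_osc=n_osc)
    kk = min(k, Xc.shape[0] - 1, Xc.shape[1])
    r2y = plsda_fit(Xc, Y, kk).r2y
    return ModelValidation(
        r2y=float(r2y), q2y=float(q2y), p_perm=float(p), null_stats=null,
        n_perm=n_perm, cv_repeats=cv_repeats, folds=folds,
        observed_stat=float(observed),
    )


def choose_n_components(X, Y, k_max: int = 3, repeats: int = 20, seed: int = 0,
                        n_osc: int = 0) -> int:
    """Pick the component count (<= k_max) maximizing cross-validated Q2Y."""
    best_k, best_q = 1, -np.inf
    for k in range(1, k_max + 1):
        try:
            q = cross_validate_q2(X, Y, k, repeats=repeats, seed=seed, n_osc=n_osc)
        except InputError:
            break
        if q > best_q + 1e-12:
            best_k, best_q = k, q
    return best_k


# ---------------------------------------------------------------------------
# S-plot and correlation-coded loading pseudo-spectrum


def splot(model: PlsdaModel, X) -> pd.DataFrame:
    """Per-feature (covariance, correlation) against the first predictive
    score: the S-plot coordinates. Zero-variance features get correlation 0
    with a warning."""
    X = _as_matrix(X)
    t = model.scores[:, 0]
    n = t.size
    Xc = X - X.mean(axis=0)
    tc = t - t.mean()
    cov = Xc.T @ tc / (n - 1)
    sx = Xc.std(axis=0, ddof=1)
    st = tc.std(ddof=1)
    corr = np.zeros_like(cov)
    nz = sx > 0
    if (~nz).any():
        warnings.warn(
            f"{int((~nz).sum())} zero-variance feature(s): correlation set to 0",
            RuntimeWarning,
        )
    corr[nz] = cov[nz] / (sx[nz] * st)
    return pd.DataFrame({"covariance": cov, "correlation": corr})


def pearson_critical_r(n: int, alpha: float = 0.05) -> float:
    """Two-sided critical |r| for Pearson correlation with n-2 df."""
    if n < 4:
        raise InputError("need n >= 4 for a meaningful critical value")
    df = n - 2
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(tcrit / np.sqrt(tcrit**2 + df))


DEFAULT_LOADING_WINDOWS = ((0.4, 4.3), (5.7, 9.4))


def correlation_loading_plot(
    model: PlsdaModel,
    X,
    feature_ppm: np.ndarray,
    alpha: float = 0.05,
    windows: tuple[tuple[float, float], ...] = DEFAULT_LOADING_WINDOWS,
) -> pd.DataFrame:
    """Covariance pseudo-spectrum colored by |correlation|.

    Height is the covariance of each bin with the first predictive score
    (back-scaled, i.e. in the bins' own intensity units under mean-centered
    scaling); color is |r|; a feature is flagged significant when |r|
    exceeds the Pearson critical value at ``alpha``. Rendering is
    restricted to the configured ppm windows.
    """
    X = _as_matrix(X)
    n = X.shape[0]
    rcrit = pearson_critical_r(n, alpha)
    sp = splot(model, X)
    feature_ppm = np.asarray(feature_ppm, float)
    inwin = np.zeros(feature_ppm.size, bool)
    for lo, hi in windows:
        inwin |= (feature_ppm >= lo) & (feature_ppm <= hi)
    df = pd.DataFrame({
        "ppm": feature_ppm,
        "covariance": sp["covariance"],
        "correlation": sp["correlation"],
        "abs_correlation": sp["correlation"].abs(),
        "significant": sp["correlation"].abs() > rcrit,
    })[inwin]
    df.attrs["critical_r"] = rcrit
    return df.reset_index(drop=True)


def hotelling_ellipse(scores2: np.ndarray, alpha: float = 0.05, n_points: int = 200):
    """95% (by default) Hotelling T2 ellipse for a 2-column score matrix;
    returns (x, y) outline coordinates for plotting."""
    S = np.cov(scores2.T)
    n = scores2.shape[0]
    f = sps.f.ppf(1 - alpha, 2, n - 2) * 2 * (n - 1) / (n - 2)
    vals, vecs = np.linalg.eigh(S)
    theta = np.linspace(0, 2 * np.pi, n_points)
    circ = np.column_stack([np.cos(theta), np.sin(theta)])
    ell = circ * np.sqrt(vals * f) @ vecs.T + scores2.mean(axis=0)
    return ell[:, 0], ell[:, 1]
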