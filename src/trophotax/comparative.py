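"""Phylogenetically informed statistics.

Implements the comparative toolkit the diet proxies feed into: the
Brownian-motion covariance of a tree (optionally Pagel-lambda scaled),
Blomberg's K and its multivariate extension with permutation tests,
pairwise group-mean comparisons under residual-randomisation (the
"phylogenetic HSD"), PCA with a deterministic sign convention, linear
flexible discriminant analysis (FDA; with a linear basis this is LDA),
and phylogenetic FDA in which predictors are whitened by the inverse
Cholesky factor of the lambda-scaled covariance and lambda is chosen by
leave-one-out misclassification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .trees import Phylogeny

__all__ = [
    "PhyloCov",
    "SignalResult",
    "DAModel",
    "DAPrediction",
    "phylo_cov",
    "blomberg_k",
    "kmult",
    "phylo_pairwise_hsd",
    "compact_letters",
    "pca_transform",
    "PCAResult",
    "fda_fit_predict",
    "pfda_fit_predict",
]


# ----------------------------------------------------------------------
# covariance
# ----------------------------------------------------------------------

@dataclass
class PhyloCov:
    """Shared-path-length covariance (Ma) with its Pagel's lambda."""

    matrix: pd.DataFrame
    lam: float

    @property
    def taxa(self) -> list[str]:
        return list(self.matrix.index)


def phylo_cov(tree: Phylogeny, lam: float = 1.0, labels=None) -> PhyloCov:
    """Build C[i, j] = root-to-MRCA path length, off-diagonals scaled by lambda."""
    return PhyloCov(matrix=tree.vcv(lam=lam, labels=labels), lam=lam)


def _gls_quadratics(Cinv: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column GLS mean and phylogenetically corrected error.

    Returns (ahat, err) where ``err[j] = (y_j - ahat_j)' Cinv (y_j - ahat_j)``.
    """
    one = np.ones(Cinv.shape[0])
    ci1 = Cinv @ one
    s = one @ ci1
    ciy = Cinv @ Y
    ahat = (one @ ciy) / s
    err = np.einsum("ij,ij->j", Y, ciy) - (one @ ciy) ** 2 / s
    return ahat, err


# ----------------------------------------------------------------------
# phylogenetic signal
# ----------------------------------------------------------------------

@dataclass
class SignalResult:
    """Blomberg's K (or its multivariate analogue) with a permutation p."""

    K: float
    p_value: float
    n_perm: int

    def __post_init__(self):
        if self.K <= 0:
            raise ValueError("K must be positive")
        if self.n_perm > 0 and self.p_value < 1.0 / (self.n_perm + 1) - 1e-12:
            raise ValueError("p-value below the permutation floor")


def _as_matrix(x, tree: Phylogeny) -> tuple[np.ndarray, list[str]]:
    if isinstance(x, pd.Series):
        x = x.to_frame()
    if isinstance(x, pd.DataFrame):
        labels = list(x.index)
        return x.to_numpy(dtype=float), labels
    arr = np.atleast_2d(np.asarray(x, dtype=float))
    if arr.shape[0] == 1:
        arr = arr.T
    return arr, tree.tip_labels


def _k_statistic(C: np.ndarray, Cinv: np.ndarray, Y: np.ndarray) -> tuple[float, float]:
    """(K, phylogenetically corrected error) for a trait matrix.

    For one column this is Blomberg's K; for several, sums of squares
    become traces over the GLS-centred matrix.
    """
    n = C.shape[0]
    one = np.ones(n)
    ci1 = Cinv @ one
    s = one @ ci1
    ahat, err = _gls_quadratics(Cinv, Y)
    R = Y - ahat  # GLS-centred
    mse0 = float(np.sum(R * R))
    mse = float(np.sum(err))
    expected = (np.trace(C) - n / s) / (n - 1)
    return (mse0 / mse) / expected, mse

def blomberg_k(tree: Phylogeny, x, n_perm: int = 999, seed: int = 0) -> SignalResult:
    """Blomberg's K for one trait, with a tip-permutation test.

    K compares the observed ratio of ordinary to phylogenetically
    corrected mean squared error to its Brownian-motion expectation
    (K near 1 under BM, below 1 when relatives resemble each other less
    than BM predicts).  The p-value is the fraction of tip-label
    permutations (observed included) whose phylogenetically corrected
    error is at most the observed one.
    """
    Y, labels = _as_matrix(x, tree)
    if Y.shape[1] != 1:
        raise ValueError("blomberg_k takes a single trait; use kmult")
    return _signal(tree, Y, labels, n_perm, seed)


def kmult(tree: Phylogeny, X, n_perm: int = 999, seed: int = 0) -> SignalResult:
    """Multivariate phylogenetic signal (K with traces over all traits)."""
    Y, labels = _as_matrix(X, tree)
    return _signal(tree, Y, labels, n_perm, seed)


def _signal(tree, Y, labels, n_perm, seed) -> SignalResult:
    n = Y.shape[0]
    if n < 4:
        raise ValueError("need at least 4 tips")
    if np.allclose(Y.var(axis=0), 0):
        raise ValueError("trait has zero variance")
    C = tree.vcv(labels=labels).to_numpy()
    try:
        cf = cho_factor(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("phylogenetic covariance is singular") from exc
    Cinv = cho_solve(cf, np.eye(n))
    K, err_obs = _k_statistic(C, Cinv, Y)
    rng = np.random.default_rng(seed)
    hits = 1  # the observed ordering counts
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, err = _gls_quadratics(Cinv, Y[perm])
        if float(np.sum(err)) <= err_obs:
            hits += 1
    return SignalResult(K=K, p_value=hits / (n_perm + 1), n_perm=n_perm)


# ----------------------------------------------------------------------
# pairwise group comparison under residual randomisation
# ----------------------------------------------------------------------

def compact_letters(p_matrix: pd.DataFrame, means: pd.Series, alpha: float = 0.05) -> dict:
    """Compact letter display from a pairwise p-value matrix.

    Groups that are not significantly different share at least one
    letter; significantly different groups share none.  Letters follow
    ascending group means.
    """
    groups = list(means.sort_values().index)
    nonsig = {
        g: {
            h
            for h in groups
            if h != g and p_matrix.loc[g, h] > alpha
        } | {g}
        for g in groups
    }
    # maximal cliques of the non-significance graph (few groups: recursion fine)
    cliques: list[set] = []

    def extend(clique: set, candidates: list):
        added = False
        for i, g in enumerate(candidates):
            if all(g in nonsig[h] for h in clique):
                extend(clique | {g}, candidates[i + 1:])
                added = True
        if not added and not any(clique < c for c in cliques) and clique:
            if clique not in cliques:
                cliques.append(clique)

    extend(set(), groups)
    cliques = [c for c in cliques if not any(c < d for d in cliques)]
    cliques.sort(key=lambda c: min(means[g] for g in c))
    letters = {g: "" for g in groups}
    for i, clique in enumerate(cliques):
        ch = chr(ord("a") + i)
        for g in clique:
            letters[g] += ch
    return letters


def phylo_pairwise_hsd(
    tree: Phylogeny,
    x: pd.Series,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Pairwise GLS group-mean comparisons via residual randomisation.

    The trait is regressed on group under the tree's covariance; the
    pairwise statistic is the absolute distance between GLS group means,
    and its p-value the fraction of null-model residual permutations
    (observed included) with a distance at least as large.  Returns the
    p-value matrix and a compact letter display at ``alpha``.
    """
    x = pd.Series(x)
    groups = pd.Series(groups).loc[x.index]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    counts = groups.value_counts()
    if (counts < 2).any():
        small = sorted(counts[counts < 2].index)
        raise ValueError(f"groups with fewer than 2 members: {small}")
    C = tree.vcv(labels=list(x.index)).to_numpy()
    L = cholesky(C, lower=True)
    y = solve_triangular(L, x.to_numpy(dtype=float), lower=True)
    G = pd.get_dummies(groups)[levels].to_numpy(dtype=float)
    Xw = solve_triangular(L, G, lower=True)
    X0 = solve_triangular(L, np.ones((len(x), 1)), lower=True)
    # null (intercept-only) fit and its residuals
    beta0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    fit0 = (X0 @ beta0).ravel()
    resid = y - fit0
    P = np.linalg.pinv(Xw)
    means_obs = P @ y
    k = len(levels)
    iu = np.triu_indices(k, 1)
    d_obs = np.abs(means_obs[iu[0]] - means_obs[iu[1]])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(len(y)) for _ in range(n_perm)])
    Ystar = fit0[None, :] + resid[perms]  # n_perm x n
    means_star = Ystar @ P.T  # n_perm x k
    d_star = np.abs(means_star[:, iu[0]] - means_star[:, iu[1]])
    counts_ge = (d_star >= d_obs[None, :] - 1e-12).sum(axis=0)
    pvals = (counts_ge + 1) / (n_perm + 1)
    pmat = pd.DataFrame(np.ones((k, k)), index=levels, columns=levels)
    for idx, (i, j) in enumerate(zip(*iu)):
        pmat.iloc[i, j] = pmat.iloc[j, i] = pvals[idx]
    letters = compact_letters(pmat, pd.Series(means_obs, index=levels), alpha=alpha)
    return pmat, letters


# ----------------------------------------------------------------------
# ordination
# ----------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained_pct: np.ndarray


def pca_transform(X, standardize: bool = False) -> PCAResult:
    """Centered (optionally z-scored) PCA with a fixed sign convention.

    Each component's largest-magnitude loading is made positive so the
    decomposition is deterministic.
    """
    X = pd.DataFrame(X)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    M = X.to_numpy(dtype=float)
    M = M - M.mean(axis=0)
    if standardize:
        sd = M.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = list(X.columns[sd == 0])
            raise ValueError(f"constant columns cannot be standardised: {bad}")
        M = M / sd
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    scores = U * S
    var = S**2
    pcs = [f"PC{i + 1}" for i in range(len(S))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=pcs),
        loadings=pd.DataFrame(Vt.T, index=X.columns, columns=pcs),
        variance_explained_pct=100.0 * var / var.sum(),
    )


# ----------------------------------------------------------------------
# (phylogenetic) flexible discriminant analysis
# ----------------------------------------------------------------------

@dataclass
class DAModel:
    """A fitted linear discriminant model (optionally phylogenetic)."""

    classes: list
    loadings: pd.DataFrame | None
    class_means: pd.DataFrame
    priors: pd.Series
    train_misclassification: float
    lam: float | None = None
    loo_errors: dict = field(default_factory=dict)
    _clf: LinearDiscriminantAnalysis | None = None


@dataclass
class DAPrediction:
    """Per-taxon class posterior probabilities; rows sum to one."""

    posterior: pd.DataFrame
    predicted: pd.Series

    def __post_init__(self):
        p = self.posterior.to_numpy()
        if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
            raise ValueError("posterior entries outside [0, 1]")
        if np.max(np.abs(p.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("posterior rows must sum to 1")


def _prior_vector(labels: pd.Series, priors: str) -> np.ndarray | None:
    classes = np.unique(labels)
    if priors == "proportional":
        return None  # sklearn default: empirical class frequencies
    if priors == "equal":
        return np.full(len(classes), 1.0 / len(classes))
    raise ValueError("priors must be 'proportional' or 'equal'")


def _fit_lda(M: np.ndarray, y: np.ndarray, priors_vec) -> LinearDiscriminantAnalysis:
    # rank check of the pooled within-class scatter; ridge-regularise if singular
    classes = np.unique(y)
    R = np.vstack([M[y == c] - M[y == c].mean(axis=0) for c in classes])
    rank = np.linalg.matrix_rank(R)
    if rank < M.shape[1]:
        warnings.warn(
            "singular within-class covariance; applying ridge regularisation",
            stacklevel=3,
        )
        clf = LinearDiscriminantAnalysis(
            solver="eigen", shrinkage=1e-6, priors=priors_vec
        )
    else:
        clf = LinearDiscriminantAnalysis(solver="svd", priors=priors_vec)
    clf.fit(M, y)
    return clf


def _package_model(clf, X_cols, y, lam=None, loo_errors=None) -> DAModel:
    classes = list(clf.classes_)
    n_axes = min(len(classes) - 1, len(X_cols))
    axes = [f"DA{i + 1}" for i in range(n_axes)]
    loadings = None
    if hasattr(clf, "scalings_"):
        loadings = pd.DataFrame(
            clf.scalings_[:, :n_axes], index=X_cols, columns=axes
        )
    means_da = pd.DataFrame(
        clf.transform(clf.means_)[:, :n_axes], index=classes, columns=axes
    )
    train_err = float(np.mean(clf.predict(clf._trophotax_X) != y))
    return DAModel(
        classes=classes,
        loadings=loadings,
        class_means=means_da,
        priors=pd.Series(clf.priors_, index=classes),
        train_misclassification=train_err,
        lam=lam,
        loo_errors=loo_errors or {},
        _clf=clf,
    )


def _predict(clf, M: np.ndarray, index, classes) -> DAPrediction:
    post = clf.predict_proba(M)
    df = pd.DataFrame(post, index=index, columns=clf.classes_)
    return DAPrediction(posterior=df, predicted=df.idxmax(axis=1))


def fda_fit_predict(
    X_train, labels, X_new=None, priors: str = "proportional"
) -> tuple[DAModel, DAPrediction | None]:
    """Linear-basis flexible discriminant analysis with Gaussian posteriors.

    With a linear basis, optimal scoring FDA is equivalent to LDA, so
    the model is fitted as LDA with the configured priors
    ('proportional' to class frequency, or 'equal').  New observations
    receive per-class posterior probabilities summing to one.
    """
    X_train = pd.DataFrame(X_train)
    labels = pd.Series(labels).loc[X_train.index]
    y = labels.to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if len(X_train) <= len(classes):
        raise ValueError("need more training rows than classes")
    M = X_train.to_numpy(dtype=float)
    clf = _fit_lda(M, y, _prior_vector(labels, priors))
    clf._trophotax_X = M
    model = _package_model(clf, list(X_train.columns), y)
    pred = None
    if X_new is not None:
        X_new = pd.DataFrame(X_new)
        pred = _predict(clf, X_new.to_numpy(dtype=float), X_new.index, classes)
    return model, pred


def _whiten(C: np.ndarray, lam: float) -> np.ndarray:
    try:
        return cholesky(C, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"covariance not positive definite at lambda={lam}"
        ) from exc


def pfda_fit_predict(
    tree: Phylogeny,
    X_train,
    labels,
    X_new=None,
    lambda_grid=None,
    priors: str = "proportional",
    mode: str = "combined",
) -> tuple[DAModel, DAPrediction | None]:
    """Phylogenetic FDA: whiten by chol(C(lambda))^-1, pick lambda by LOO.

    For each lambda on the grid the predictors are whitened by the
    inverse Cholesky factor of the lambda-scaled covariance of the
    training tips, a linear discriminant is fitted, and the
    leave-one-out misclassification rate scored; the smallest lambda
    achieving the minimum is selected.  New taxa (rows of ``X_new``
    named for tips of ``tree``) are whitened consistently: jointly with
    the training tips when ``mode='combined'`` (the default), or by
    their own root-to-tip depth only when ``mode='extant_only'``.
    """
    if lambda_grid is None:
        lambda_grid = np.round(np.arange(0.0, 1.0001, 0.01), 2)
    X_train = pd.DataFrame(X_train)
    labels = pd.Series(labels).loc[X_train.index]
    y = labels.to_numpy()
    train_tips = list(X_train.index)
    M = X_train.to_numpy(dtype=float)
    priors_vec = _prior_vector(labels, priors)

    loo_errors: dict = {}
    best_lam, best_err = None, np.inf
    for lam in lambda_grid:
        C = tree.vcv(lam=float(lam), labels=train_tips).to_numpy()
        L = _whiten(C, lam)
        Mw = solve_triangular(L, M, lower=True)
        wrong = 0
        idx = np.arange(len(y))
        for i in idx:
            keep = idx != i
            clf = _fit_lda(Mw[keep], y[keep], priors_vec)
            if clf.predict(Mw[[i]])[0] != y[i]:
                wrong += 1
        err = wrong / len(y)
        loo_errors[float(lam)] = err
        if err < best_err - 1e-12:
            best_lam, best_err = float(lam), err
    # final fit at the selected lambda
    C = tree.vcv(lam=best_lam, labels=train_tips).to_numpy()
    L = _whiten(C, best_lam)
    Mw = solve_triangular(L, M, lower=True)
    clf = _fit_lda(Mw, y, priors_vec)
    clf._trophotax_X = Mw
    model = _package_model(clf, list(X_train.columns), y, lam=best_lam,
                           loo_errors=loo_errors)
    pred = None
    if X_new is not None:
        X_new = pd.DataFrame(X_new)
        new_tips = list(X_new.index)
        if mode == "combined":
            overlap = set(new_tips) & set(train_tips)
            if overlap:
                raise ValueError(
                    "combined-tree whitening needs new taxa distinct from the "
                    f"training tips (overlap: {sorted(overlap)}); use "
                    "mode='extant_only' to re-score training taxa"
                )
            all_tips = train_tips + new_tips
            C_all = tree.vcv(lam=best_lam, labels=all_tips).to_numpy()
            L_all = _whiten(C_all, best_lam)
            stacked = np.vstack([M, X_new.to_numpy(dtype=float)])
            W = solve_triangular(L_all, stacked, lower=True)
            clf2 = _fit_lda(W[: len(train_tips)], y, priors_vec)
            pred = _predict(clf2, W[len(train_tips):], X_new.index, model.classes)
        elif mode == "extant_only":
            depths = np.diag(tree.vcv(lam=best_lam, labels=new_tips).to_numpy())
            Wn = X_new.to_numpy(dtype=float) / np.sqrt(depths)[:, None]
            pred = _predict(clf, Wn, X_new.index, model.classes)
        else:
            raise ValueError("mode must be 'combined' or 'extant_only'")
    return model, pred
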