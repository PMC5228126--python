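"""Phylogenetic generalized least squares with Pagel's lambda.

The regression model is y = X b + e with e ~ N(0, sigma^2 * V(lambda)),
where V is the Brownian-motion covariance of the tips — V[i, j] equals the
shared root-to-MRCA path length of species i and j, V[i, i] the root-to-tip
depth — and Pagel's lambda multiplies the off-diagonal entries.  lambda = 0
reduces to ordinary least squares, lambda = 1 to full Brownian covariance.
lambda is estimated by maximizing the (profile) log-likelihood over [0, 1],
by ML or REML; boundary optima are returned exactly as 0 or 1.

The GLS solve whitens through a Cholesky factor of V(lambda) rather than
forming an explicit inverse; an explicit normal-equations oracle lives in
the test suite as an independent cross-check.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
import dendropy
from scipy import optimize, stats
from scipy.linalg import solve_triangular
from sklearn.base import BaseEstimator, RegressorMixin


# ---------------------------------------------------------------------------
# Trees


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a newick string into a rooted tree with branch lengths.

    Rejects malformed newick (with the parser's position information),
    duplicate tip labels, missing or negative branch lengths.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as err:
        raise ValueError(f"malformed newick: {err}") from err
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        bl = node.edge.length
        if bl is None:
            where = node.taxon.label if node.taxon else "an internal node"
            raise ValueError(f"missing branch length above {where}")
        if bl < 0:
            raise ValueError(f"negative branch length {bl}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to newick preserving branch lengths at full precision."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".17g",
    ).strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def bm_vcv(tree: dendropy.Tree, tips: list[str] | None = None) -> pd.DataFrame:
    """Brownian-motion variance-covariance matrix of the tree's tips.

    V[i, j] is the path length from the root to the most recent common
    ancestor of tips i and j; the diagonal holds root-to-tip depths.  A
    root edge length, if present, is shared by all tips.
    """
    depth = {}
    tipsets = {}
    order = list(tree.preorder_node_iter())
    for node in order:
        if node.parent_node is None:
            depth[node] = node.edge.length or 0.0
        else:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    all_tips = tip_labels(tree)
    if tips is None:
        tips = all_tips
    else:
        unknown = sorted(set(tips) - set(all_tips))
        if unknown:
            raise ValueError(f"tips not present in tree: {unknown}")
    idx = {label: i for i, label in enumerate(tips)}
    n = len(tips)
    V = np.zeros((n, n))
    for node in reversed(order):  # postorder
        if node.is_leaf():
            label = node.taxon.label
            tipsets[node] = [idx[label]] if label in idx else []
            if label in idx:
                V[idx[label], idx[label]] = depth[node]
        else:
            child_sets = [tipsets.pop(ch) for ch in node.child_nodes()]
            d = depth[node]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    for i in child_sets[a]:
                        for j in child_sets[b]:
                            V[i, j] = V[j, i] = d
            tipsets[node] = [i for s in child_sets for i in s]
    return pd.DataFrame(V, index=tips, columns=tips)


def lambda_transform(V, lam: float):
    """Scale the off-diagonal entries of a BM covariance by Pagel's lambda."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    arr = np.asarray(V, dtype=float)
    out = lam * arr
    np.fill_diagonal(out, np.diag(arr))
    if isinstance(V, pd.DataFrame):
        return pd.DataFrame(out, index=V.index, columns=V.columns)
    return out


def log_transform_rate(rate):
    """Natural log of a positive rate (e.g. head movements/min).

    The log transform is how strictly positive, right-skewed rates are
    brought in line with the linear-model normality assumption.
    """
    arr = np.asarray(rate, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("rates must be > 0 to log-transform")
    out = np.log(arr)
    return float(out) if np.isscalar(rate) or out.ndim == 0 else out


# ---------------------------------------------------------------------------
# GLS core


def _gls_solve(y: np.ndarray, X: np.ndarray, C: np.ndarray):
    """Whitened least squares: returns (beta, rss, logdet_C, Xw)."""
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "transformed covariance matrix is not positive definite"
        ) from err
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("singular design matrix")
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return beta, rss, logdet, Xw


def _loglik(y, X, C, reml: bool):
    n, p = X.shape
    beta, rss, logdet, Xw = _gls_solve(y, X, C)
    if reml:
        df = n - p
        sigma2 = rss / df
        sign, logdet_xx = np.linalg.slogdet(Xw.T @ Xw)
        ll = -0.5 * (df * (np.log(2 * np.pi * sigma2) + 1) + logdet + logdet_xx)
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1) + logdet)
    return ll, beta, rss


def profile_lambda(
    y,
    X,
    V,
    reml: bool = False,
    grid_size: int = 101,
    tol: float = 1e-6,
):
    """Profile the log-likelihood over Pagel's lambda in [0, 1].

    A coarse grid scan is followed by bounded golden-section refinement
    around the grid optimum; optima at the boundaries are returned exactly
    as 0.0 or 1.0 (the values a comparative analysis reports as
    "lambda = 0" or "lambda = 1").

    Returns
    -------
    lambda_hat : float
    grid : ndarray of the lambda values evaluated
    loglik : ndarray of the corresponding log-likelihoods
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    V = np.asarray(V, dtype=float)

    def nll(lam):
        ll, _, _ = _loglik(y, X, lambda_transform(V, lam), reml)
        return -ll

    grid = np.linspace(0.0, 1.0, grid_size)
    lls = np.empty(grid_size)
    for i, lam in enumerate(grid):
        lls[i] = -nll(lam)
        if not np.isfinite(lls[i]):
            raise ValueError(f"non-finite log-likelihood at lambda = {lam}")
    best = int(np.argmax(lls))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_size - 1)]
    if lo == hi:
        return float(grid[best]), grid, lls
    res = optimize.minimize_scalar(
        nll, bounds=(lo, hi), method="bounded", options={"xatol": tol}
    )
    lam_hat = float(res.x)
    ll_hat = -float(res.fun)
    # prefer an exact boundary when it is at least as good
    for boundary in (0.0, 1.0):
        if abs(lam_hat - boundary) < 10 * tol or -nll(boundary) >= ll_hat:
            if -nll(boundary) >= ll_hat - 1e-12:
                lam_hat, ll_hat = boundary, -nll(boundary)
    if lls[best] > ll_hat:
        lam_hat = float(grid[best])
    return lam_hat, grid, lls


@dataclass(frozen=True)
class PGLSFit:
    """Result of one phylogenetic generalized least-squares regression."""

    coefficients: dict
    lambda_hat: float
    sigma2_hat: float
    F: float
    df: tuple
    p: float
    r2: float
    r2_adj: float
    loglik: float
    n: int

    @property
    def df_label(self) -> str:
        """Degrees-of-freedom label in the (parameters, residual) style some
        comparative analyses print (e.g. F_2,27 for one predictor, n = 29)."""
        q, den = self.df
        return f"F_{q + 1},{den}"


class PGLSRegression(BaseEstimator, RegressorMixin):
    """Phylogenetic generalized least squares, sklearn estimator style.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted phylogeny with branch lengths covering every species in the
        data.
    lam : "ml" or float
        Pagel's lambda: estimated by maximum likelihood over [0, 1], or
        held fixed at the given value.
    reml : bool
        Use restricted rather than ordinary maximum likelihood for the
        lambda profile (default ML).
    grid_size, tol : int, float
        Resolution of the lambda profile grid and of the bounded
        refinement.

    Attributes
    ----------
    coef_ : ndarray
        Fitted predictor coefficients (excluding the intercept).
    intercept_ : float
    lambda_ : float
        Estimated (or fixed) Pagel's lambda.
    sigma2_ : float
        Residual rate estimate, rss_gls / (n - p).
    fstat_, df_, pvalue_ : F test of the predictors against the
        intercept-only model under the same lambda.
    r2_, r2_adj_ : GLS coefficient of determination and its adjusted form
        (the adjusted value may be negative).
    loglik_ : float
        Log-likelihood at the optimum.
    taxa_ : list of str
        Species order used for the covariance.
    """

    def __init__(self, tree=None, lam="ml", reml=False, grid_size=101, tol=1e-6):
        self.tree = tree
        self.lam = lam
        self.reml = reml
        self.grid_size = grid_size
        self.tol = tol

    # -- data marshalling ---------------------------------------------------
    def _marshal(self, X, y, taxa):
        if isinstance(X, pd.DataFrame):
            taxa = list(X.index)
            names = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            if Xa.ndim == 1:
                Xa = Xa[:, None]
            names = [f"x{i}" for i in range(Xa.shape[1])]
        if isinstance(y, pd.Series):
            if taxa is None:
                taxa = list(y.index)
            ya = y.loc[taxa].to_numpy(dtype=float) if isinstance(
                y.index, pd.Index
            ) else y.to_numpy(dtype=float)
        else:
            ya = np.asarray(y, dtype=float)
        if taxa is None:
            raise ValueError(
                "species identities are required: pass a DataFrame/Series "
                "indexed by species or the taxa= argument"
            )
        if len(taxa) != len(set(taxa)):
            raise ValueError("duplicate species in data")
        if not (np.all(np.isfinite(Xa)) and np.all(np.isfinite(ya))):
            raise ValueError("non-finite values in y or X (complete cases only)")
        return Xa, ya, list(taxa), names

    def fit(self, X, y, taxa=None):
        """Fit the comparative regression.

        ``X`` may be a DataFrame indexed by species (preferred), ``y`` a
        Series; otherwise arrays plus an explicit ``taxa`` list aligned to
        the rows.
        """
        Xa, ya, taxa, names = self._marshal(X, y, taxa)
        n, q = Xa.shape
        if n <= q + 1:
            raise ValueError(f"need n > predictors + 1, got n={n}, q={q}")
        tree_tips = set(tip_labels(self.tree))
        absent = sorted(set(taxa) - tree_tips)
        if absent:
            raise ValueError(f"species absent from the tree: {absent}")
        V = bm_vcv(self.tree, taxa).to_numpy()
        Xd = np.column_stack([np.ones(n), Xa])

        if self.lam == "ml":
            lam_hat, grid, lls = profile_lambda(
                ya, Xd, V, reml=self.reml, grid_size=self.grid_size, tol=self.tol
            )
            self.lambda_profile_ = (grid, lls)
        else:
            lam_hat = float(self.lam)
            if not (0.0 <= lam_hat <= 1.0):
                raise ValueError("fixed lambda must be in [0, 1]")
        C = lambda_transform(V, lam_hat)
        ll, beta, rss = _loglik(ya, Xd, C, self.reml)
        # intercept-only comparison model under the same lambda
        _, rss0, _, _ = _gls_solve(ya, np.ones((n, 1)), C)
        # whitened residuals, standardized by the residual rate
        L = np.linalg.cholesky(C)
        rw = solve_triangular(L, ya - Xd @ beta, lower=True)

        p = q + 1
        self.taxa_ = taxa
        self.feature_names_in_ = names
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.lambda_ = lam_hat
        self.sigma2_ = rss / (n - p)
        self.loglik_ = float(ll)
        self.n_ = n
        self.df_ = (q, n - p)
        scale = np.sqrt(rss / (n - p)) if rss > 0 else 1.0
        self.resid_standardized_ = pd.Series(rw / scale, index=taxa)
        if q >= 1 and rss > 0:
            F = ((rss0 - rss) / q) / (rss / (n - p))
            self.fstat_ = float(F)
            self.pvalue_ = float(stats.f.sf(F, q, n - p))
        else:
            self.fstat_ = np.nan
            self.pvalue_ = np.nan
        self.r2_ = 1.0 - rss / rss0 if rss0 > 0 else np.nan
        self.r2_adj_ = 1.0 - (1.0 - self.r2_) * (n - 1) / (n - p)
        return self

    def predict(self, X):
        Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(
            X, dtype=float
        )
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        return self.intercept_ + Xa @ self.coef_

    def to_fit(self) -> PGLSFit:
        coeffs = {"intercept": self.intercept_}
        coeffs.update(dict(zip(self.feature_names_in_, self.coef_)))
        return PGLSFit(
            coefficients=coeffs,
            lambda_hat=self.lambda_,
            sigma2_hat=self.sigma2_,
            F=self.fstat_,
            df=self.df_,
            p=self.pvalue_,
            r2=self.r2_,
            r2_adj=self.r2_adj_,
            loglik=self.loglik_,
            n=self.n_,
        )


def pgls_fit(y, X, tree, lam="ml", reml: bool = False) -> PGLSFit:
    """Functional wrapper around :class:`PGLSRegression`.

    ``y`` a Series and ``X`` a DataFrame, both indexed by species matching
    the tree's tip labels; ``lam`` either "ml" or a fixed value in [0, 1].
    """
    if isinstance(X, pd.DataFrame) and isinstance(y, pd.Series):
        y = y.loc[X.index]
    model = PGLSRegression(tree=tree, lam=lam, reml=reml).fit(X, y)
    return model.to_fit()
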