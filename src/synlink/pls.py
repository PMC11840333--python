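"""Two-block partial least squares with permutation inference and power utilities.

PLS-CA (canonical mode) finds, per component i, unit weight vectors
(w_i, c_i) whose block projections t_i = X w_i and u_i = Y c_i have
maximal covariance; both blocks are deflated by their own scores so that
within-block scores stay orthogonal across components.  Each component is
summarised by its canonical correlation r_i = corr(t_i, u_i) and score
covariance Cov_i.  Significance is assessed by permuting the rows of the
Y block while holding X fixed, refitting, and taking the two-tailed
p-value as the proportion of permuted |r_i| exceeding the observed |r_i|.

PLS-R regresses a single behavioural outcome on the (multicollinear)
predictor block via orthogonal score components, summarised by in-sample
R^2 and RMSE, with a one-sided permutation test on R^2.

Power utilities use the Fisher z approximation for the distribution of
the sample correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PLSCAResult",
    "PLSRResult",
    "PermutationResult",
    "pls_canonical_fit",
    "permutation_test_pls_ca",
    "pls_regression",
    "permutation_test_plsr",
    "pearson_with_p",
    "correlation_power",
    "required_sample_size",
]

POWER_ITER_TOL = 1e-6
POWER_ITER_MAX = 500


@dataclass(frozen=True)
class PLSCAResult:
    x_weights: np.ndarray  # p_x x k, unit columns
    y_weights: np.ndarray  # p_y x k, unit columns
    x_scores: np.ndarray  # n x k
    y_scores: np.ndarray  # n x k
    correlations: np.ndarray  # r_i per component
    covariances: np.ndarray  # Cov_i per component (n-1 denominator)
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    n_iterations: tuple[int, ...]

    @property
    def n_components(self) -> int:
        return self.x_weights.shape[1]


@dataclass(frozen=True)
class PLSRResult:
    n_components: int
    predictions: np.ndarray
    r_squared: float
    rmse: float
    x_weights: np.ndarray
    coefficients: np.ndarray  # on standardized X, centred y scale


@dataclass(frozen=True)
class PermutationResult:
    observed: np.ndarray
    null_distribution: np.ndarray  # n_permutations (x k)
    p_values: np.ndarray
    n_permutations: int
    seed: int | None
    statistic: str
    smoothed: bool = False


def _standardize(M: np.ndarray, scale: bool, block: str):
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError(f"{block} block must be 2-D (subjects x features)")
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    if scale:
        zero = np.where(sd == 0)[0]
        if zero.size:
            raise ValueError(f"zero-variance column(s) in {block} block: {zero.tolist()}")
        return (M - mean) / sd, mean, sd
    return M - mean, mean, np.ones_like(sd)


def _dominant_pair(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Leading singular pair of the cross-product matrix by power iteration."""
    p, q = M.shape
    w = np.full(p, 1.0 / math.sqrt(p))
    A = M @ M.T
    n_iter = 0
    sigma_prev = math.inf
    for n_iter in range(1, POWER_ITER_MAX + 1):
        w_new = A @ w
        norm = np.linalg.norm(w_new)
        if norm <= 1e-300:
            # degenerate (zero cross-covariance): any direction is optimal
            w_new = np.zeros(p)
            w_new[0] = 1.0
            w = w_new
            break
        w_new /= norm
        # converged when either the direction or the maximised objective
        # (leading eigenvalue of M M') is stable; the latter covers
        # near-degenerate spectra where the direction wanders inside an
        # eigenspace whose objective value has already converged
        if (
            np.linalg.norm(w_new - w) < POWER_ITER_TOL
            or abs(norm - sigma_prev) < POWER_ITER_TOL * norm
        ):
            w = w_new
            break
        sigma_prev = norm
        w = w_new
    else:
        # near-degenerate spectrum (eigenvalue ratio ~1): the iteration's
        # fixed point is the dominant eigenvector of M M', so compute it
        # directly rather than failing
        eigvals, eigvecs = np.linalg.eigh(A)
        w = eigvecs[:, -1]
    c = M.T @ w
    cn = np.linalg.norm(c)
    if cn <= 1e-300:
        c = np.zeros(q)
        c[0] = 1.0
    else:
        c = c / cn
    return w, c, n_iter


def _fit_ca_core(Xs: np.ndarray, Ys: np.ndarray, n_components: int):
    """Canonical-mode NIPALS on pre-standardized blocks (internal fast path)."""
    n = Xs.shape[0]
    Xd, Yd = Xs.copy(), Ys.copy()
    W = np.empty((Xs.shape[1], n_components))
    C = np.empty((Ys.shape[1], n_components))
    T = np.empty((n, n_components))
    U = np.empty((n, n_components))
    rs = np.empty(n_components)
    covs = np.empty(n_components)
    iters = []
    for i in range(n_components):
        M = Xd.T @ Yd
        w, c, it = _dominant_pair(M)
        # deterministic sign: largest-|weight| X element positive
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w = -w
        t = Xd @ w
        u = Yd @ c
        cov = float(t @ u) / (n - 1)
        if cov < 0:
            c, u, cov = -c, -u, -cov
        tn = float(t @ t)
        un = float(u @ u)
        denom = math.sqrt(tn * un)
        rs[i] = (t @ u) / denom if denom > 0 else 0.0
        covs[i] = cov
        W[:, i], C[:, i], T[:, i], U[:, i] = w, c, t, u
        iters.append(it)
        # canonical deflation: each block by its own scores
        if tn > 0:
            Xd = Xd - np.outer(t, (t @ Xd) / tn)
        if un > 0:
            Yd = Yd - np.outer(u, (u @ Yd) / un)
    return W, C, T, U, rs, covs, iters


def pls_canonical_fit(
    X: np.ndarray | pd.DataFrame,
    Y: np.ndarray | pd.DataFrame,
    n_components: int = 2,
    scale: bool = True,
) -> PLSCAResult:
    """Two-block PLS in canonical (symmetric) mode.

    Columns are centred and, by default, scaled to unit variance.
    Components are extracted by power iteration on the cross-covariance
    (tolerance 1e-6, max 500 iterations) with canonical deflation.  Sign
    convention: the largest-|weight| X element is positive and the Y sign
    makes the score covariance non-negative.
    """
    Xa = np.asarray(X, dtype=float)
    Ya = np.asarray(Y, dtype=float)
    if Xa.shape[0] != Ya.shape[0]:
        raise ValueError("X and Y must have the same number of rows (subjects)")
    if Xa.shape[0] <= n_components:
        raise ValueError("need more subjects than components")
    if n_components > min(Xa.shape[1], Ya.shape[1]):
        raise ValueError("more components than the smaller block's column count")
    Xs, xm, xs = _standardize(Xa, scale, "X")
    Ys, ym, ys = _standardize(Ya, scale, "Y")
    W, C, T, U, rs, covs, iters = _fit_ca_core(Xs, Ys, n_components)
    return PLSCAResult(
        x_weights=W, y_weights=C, x_scores=T, y_scores=U,
        correlations=rs, covariances=covs,
        x_mean=xm, x_scale=xs, y_mean=ym, y_scale=ys,
        n_iterations=tuple(iters),
    )


def permutation_test_pls_ca(
    X: np.ndarray | pd.DataFrame,
    Y: np.ndarray | pd.DataFrame,
    n_components: int = 2,
    n_permutations: int = 1000,
    seed: int | None = None,
    scale: bool = True,
    smoothed: bool = False,
) -> PermutationResult:
    """Permutation test on PLS-CA canonical correlations.

    Rows of Y are shuffled while X is held fixed; the full fit is redone
    per permutation and the two-tailed p-value per component is the
    proportion of permuted |r_i| strictly greater than the observed
    |r_i|.  ``smoothed=True`` uses (b+1)/(m+1) instead, which cannot
    return exactly zero.  Standardisation is row-permutation invariant,
    so the refits operate on the standardized blocks directly.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    Xa = np.asarray(X, dtype=float)
    Ya = np.asarray(Y, dtype=float)
    Xs, *_ = _standardize(Xa, scale, "X")
    Ys, *_ = _standardize(Ya, scale, "Y")
    observed = np.abs(_fit_ca_core(Xs, Ys, n_components)[4])
    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, n_components))
    n = Xs.shape[0]
    for b in range(n_permutations):
        perm = rng.permutation(n)
        null[b] = np.abs(_fit_ca_core(Xs, Ys[perm], n_components)[4])
    exceed = (null > observed).sum(axis=0)
    if smoothed:
        p = (exceed + 1) / (n_permutations + 1)
    else:
        p = exceed / n_permutations
    return PermutationResult(
        observed=observed, null_distribution=null, p_values=p,
        n_permutations=n_permutations, seed=seed,
        statistic="abs_canonical_correlation", smoothed=smoothed,
    )


def _fit_plsr_core(Xs: np.ndarray, yc: np.ndarray, n_components: int):
    """PLS1 regression on standardized X and centred y; returns coefs, weights."""
    Xd = Xs.copy()
    yd = yc.copy()
    p = Xs.shape[1]
    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    q = np.empty(n_components)
    for i in range(n_components):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= 1e-300:
            w = np.zeros(p)
            w[0] = 1.0
        else:
            w = w / nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 0:
            W[:, i], P[:, i], q[i] = w, 0.0, 0.0
            continue
        pl = (Xd.T @ t) / tt
        qi = float(yd @ t) / tt
        Xd = Xd - np.outer(t, pl)
        yd = yd - qi * t
        W[:, i], P[:, i], q[i] = w, pl, qi
    coefs = W @ np.linalg.solve(P.T @ W, q)
    return coefs, W


def pls_regression(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    n_components: int = 2,
    scale: bool = True,
) -> PLSRResult:
    """PLS regression of a single outcome on a predictor block.

    In-sample fit quality: R^2 = 1 − SS_res/SS_tot and RMSE =
    sqrt(mean squared residual), both on the outcome's original units.
    """
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float).ravel()
    if Xa.shape[0] != ya.size:
        raise ValueError("X rows and y length differ")
    if Xa.shape[0] <= n_components:
        raise ValueError("need more subjects than components")
    ss_tot = float(((ya - ya.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("outcome is constant (SS_tot = 0)")
    Xs, *_ = _standardize(Xa, scale, "X")
    ym = ya.mean()
    coefs, W = _fit_plsr_core(Xs, ya - ym, n_components)
    pred = Xs @ coefs + ym
    resid = ya - pred
    ss_res = float((resid**2).sum())
    return PLSRResult(
        n_components=n_components,
        predictions=pred,
        r_squared=1.0 - ss_res / ss_tot,
        rmse=float(np.sqrt(np.mean(resid**2))),
        x_weights=W,
        coefficients=coefs,
    )


def permutation_test_plsr(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    n_components: int = 2,
    n_permutations: int = 1000,
    seed: int | None = None,
    scale: bool = True,
    smoothed: bool = False,
) -> PermutationResult:
    """One-sided permutation test on the PLS-R in-sample R^2 (large values)."""
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float).ravel()
    Xs, *_ = _standardize(Xa, scale, "X")
    ym = ya.mean()
    yc = ya - ym
    ss_tot = float((yc**2).sum())
    if ss_tot == 0:
        raise ValueError("outcome is constant (SS_tot = 0)")

    def r2_of(yvec):
        coefs, _ = _fit_plsr_core(Xs, yvec - yvec.mean(), n_components)
        resid = (yvec - yvec.mean()) - Xs @ coefs
        return 1.0 - float((resid**2).sum()) / float(((yvec - yvec.mean()) ** 2).sum())

    observed = r2_of(ya)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        null[b] = r2_of(ya[rng.permutation(ya.size)])
    exceed = int((null > observed).sum())
    p = (exceed + 1) / (n_permutations + 1) if smoothed else exceed / n_permutations
    return PermutationResult(
        observed=np.array([observed]), null_distribution=null,
        p_values=np.array([p]), n_permutations=n_permutations, seed=seed,
        statistic="r_squared", smoothed=smoothed,
    )


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> dict:
    """Pearson r with the two-sided t-based p-value (n−2 dof)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input to correlation")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p_two_sided": float(p)}


def correlation_power(
    true_r: float,
    n: int,
    alpha: float = 0.05,
    tails: int = 2,
) -> float:
    """Power to detect a correlation via the Fisher z approximation.

    power = Phi(sqrt(n−3)|atanh r| − z_{1−alpha/tails})
          + Phi(−sqrt(n−3)|atanh r| − z_{1−alpha/tails})
    (the second, far-tail term is negligible except near r = 0; at r = 0
    the two terms sum to alpha).
    """
    if not -1 < true_r < 1:
        raise ValueError("true_r must lie in (−1, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    lam = abs(math.atanh(true_r)) * math.sqrt(n - 3)
    zc = stats.norm.ppf(1.0 - alpha / tails)
    power = stats.norm.cdf(lam - zc)
    if tails == 2:
        power += stats.norm.cdf(-lam - zc)
    else:
        # one-tailed: at r=0 this reduces to alpha as well
        power += 0.0
    return float(power)


def required_sample_size(
    true_r: float,
    power: float = 0.80,
    alpha: float = 0.05,
    tails: int = 2,
) -> int:
    """Smallest n reaching the target power for a correlation test.

    n = ceil(((z_{1−alpha/tails} + z_{power}) / atanh|r|)^2 + 3), floored
    at 4 observations.
    """
    if not 0 < abs(true_r) < 1:
        raise ValueError("true_r must be nonzero and inside (−1, 1)")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    zc = stats.norm.ppf(1.0 - alpha / tails)
    zp = stats.norm.ppf(power)
    n = math.ceil(((zc + zp) / abs(math.atanh(true_r))) ** 2 + 3)
    return max(int(n), 4)
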