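"""Statistical primitives: normalization, NB regression, and tests.

The negative-binomial (NB2) regression with a per-gene interaction Wald test
is the workhorse of the differential translation-efficiency analysis. The
parameterization throughout is Var(Y) = mu + alpha * mu^2 with alpha > 0 the
dispersion. Coefficients are on the natural-log scale; callers convert to
log2 where needed.
"""

from __future__ import annotations

import itertools
import math
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

from .datatypes import CountTable, GlmFit

DISPERSION_FLOOR = 1e-8


def size_factors(counts) -> np.ndarray:
    """Median-of-ratios library-size factors.

    For every gene with strictly positive counts in all samples, the ratio of
    each sample's count to the gene's geometric mean is formed; the factor of
    a sample is the median of these ratios. Genes containing any zero are
    excluded from the reference set.
    """
    if isinstance(counts, CountTable):
        counts = counts.counts
    mat = np.asarray(counts, dtype=float)
    if mat.ndim != 2 or mat.shape[0] == 0 or mat.shape[1] == 0:
        raise ValueError("counts must be a non-empty 2-D matrix")
    reference = np.all(mat > 0, axis=1)
    if not np.any(reference):
        raise ValueError("no reference gene: every gene contains a zero count")
    ref = mat[reference]
    log_geo_mean = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_geo_mean)
    return np.median(ratios, axis=0)


def estimate_dispersion(
    row: np.ndarray,
    groups: Sequence,
    size_factors: np.ndarray,
    floor: float = DISPERSION_FLOOR,
) -> float:
    """Method-of-moments NB dispersion for one gene.

    Counts are size-factor-normalized; the variance is the within-cell
    residual sum of squares pooled across design cells (so real effects
    between cells never contaminate the estimate), scaled by the
    inverse-chi-square correction df/(df-2) that removes the upward bias
    of 1/s2 in the downstream Wald denominator at small replicate numbers.
    Then alpha = max(floor, (s2 - mbar) / mbar^2) with mbar the overall
    normalized mean. One estimate per gene, shared by every cell of the
    design, with no information borrowed across genes. Degenerate rows
    return the floor.
    """
    row = np.asarray(row, dtype=float)
    sf = np.asarray(size_factors, dtype=float)
    groups = np.asarray(groups)
    normalized = row / sf
    ss, df = 0.0, 0
    for lab in np.unique(groups):
        vals = normalized[groups == lab]
        if len(vals) >= 2:
            ss += np.sum((vals - vals.mean()) ** 2)
            df += len(vals) - 1
    if df == 0:
        raise ValueError("need at least one design cell with >= 2 samples")
    mbar = normalized.mean()
    if mbar <= 0:
        return floor
    s2 = ss / df
    if df > 2:
        s2 *= df / (df - 2.0)
    return max(floor, (s2 - mbar) / mbar**2)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood with known dispersion (constant terms included)."""
    r = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def nb_glm_fit(
    y: np.ndarray,
    design: np.ndarray,
    offsets: Optional[np.ndarray],
    alpha: float,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GlmFit:
    """Fit an NB2 GLM with log link and known dispersion by IRLS.

    Standard errors come from the Fisher information X' W X with working
    weights w_i = mu_i / (1 + alpha * mu_i). Convergence is declared when the
    largest absolute coefficient change falls below ``tol``; otherwise the
    fit is flagged ``converged=False`` (never silently).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    n, k = X.shape
    if offsets is None:
        offsets = np.zeros(n)
    offsets = np.asarray(offsets, dtype=float)
    if alpha <= 0:
        raise ValueError("dispersion alpha must be > 0")
    if np.any(y < 0) or np.any(np.mod(y, 1) != 0):
        raise ValueError("y must be non-negative integers")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank-deficient")

    nan = np.full(k, np.nan)
    if np.all(y == 0):
        return GlmFit(nan, nan, converged=False, iterations=0, dispersion_used=alpha)

    # start from OLS on the shifted log response
    beta = np.linalg.lstsq(X, np.log(y + 0.5) - offsets, rcond=None)[0]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta + offsets, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offsets) + (y - mu) / mu
        xtw = X.T * w
        try:
            beta_new = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError:
            return GlmFit(nan, nan, False, it, alpha)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            converged = True
            break

    if not converged or not np.all(np.isfinite(beta)):
        return GlmFit(nan, nan, False, it, alpha)
    mu = np.exp(np.clip(X @ beta + offsets, -30.0, 30.0))
    w = mu / (1.0 + alpha * mu)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return GlmFit(beta, nan, False, it, alpha)
    se = np.sqrt(np.diag(cov))
    if not np.all(np.isfinite(se)) or np.any(se <= 0):
        return GlmFit(beta, nan, False, it, alpha)
    return GlmFit(beta, se, True, it, alpha)


def wald_test(fit: GlmFit, index: int) -> tuple[float, float]:
    """Wald z and two-sided p for one coefficient of a converged fit.

    Non-converged fits yield missing values (NaN, NaN).
    """
    if not fit.converged:
        return (float("nan"), float("nan"))
    se = fit.standard_errors[index]
    if not np.isfinite(se) or se <= 0:
        raise ValueError(f"standard error at index {index} is not positive")
    z = fit.coefficients[index] / se
    p = 2.0 * norm.sf(abs(z))
    return (float(z), float(p))


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, preserving input order.

    Missing p-values (NaN) propagate to missing q-values and are excluded
    from the number of tests m.
    """
    p = np.asarray(p, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    m = int(finite.sum())
    if m == 0:
        return q
    pv = p[finite]
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # step-up: running minimum from the largest p downward
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.clip(ranked, 0.0, 1.0)
    q[finite] = qv
    return q


def _rank_sum_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic of x (midranks for ties)."""
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    r1 = ranks[: len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2.0


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    mode: str = "auto",
) -> tuple[float, float]:
    """Mann-Whitney U test.

    In exact mode (or auto with n1+n2 <= 12) the p-value is computed by
    enumerating every assignment of the pooled values to the two groups,
    which remains valid under ties. Otherwise the normal approximation with
    midrank tie correction and a 0.5 continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    n1, n2 = len(x), len(y)
    u_obs = _rank_sum_u(x, y)
    use_exact = mode == "exact" or (mode == "auto" and n1 + n2 <= 12)

    if use_exact:
        pooled = np.concatenate([x, y])
        n = n1 + n2
        mean_u = n1 * n2 / 2.0
        total = math.comb(n, n1)
        hits = 0
        for idx in itertools.combinations(range(n), n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            u = _rank_sum_u(pooled[mask], pooled[~mask])
            if alternative == "two-sided":
                if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
                    hits += 1
            elif alternative == "greater":
                if u >= u_obs - 1e-12:
                    hits += 1
            else:
                if u <= u_obs + 1e-12:
                    hits += 1
        return (float(u_obs), hits / total)

    # normal approximation with tie correction
    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1.0))
    sigma2 = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
    if sigma2 <= 0:
        return (float(u_obs), 1.0)
    sigma = math.sqrt(sigma2)
    mean_u = n1 * n2 / 2.0
    if alternative == "two-sided":
        z = (abs(u_obs - mean_u) - 0.5) / sigma
        p = 2.0 * norm.sf(max(z, 0.0))
    elif alternative == "greater":
        z = (u_obs - mean_u - 0.5) / sigma
        p = norm.sf(z)
    else:
        z = (u_obs - mean_u + 0.5) / sigma
        p = norm.cdf(z)
    return (float(u_obs), float(min(p, 1.0)))


def hypergeom_overlap_p(k: int, n_a: int, n_b: int, n_universe: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    X is the overlap of a fixed set of size n_a with a uniformly random set
    of size n_b drawn from a universe of size n_universe. The tail is summed
    in log space so p-values down to ~1e-300 do not underflow.
    """
    if not (0 <= k <= min(n_a, n_b)):
        raise ValueError(f"need 0 <= k <= min(n_a, n_b); got k={k}, n_a={n_a}, n_b={n_b}")
    if max(n_a, n_b) > n_universe:
        raise ValueError("set sizes cannot exceed the universe size")
    if k == 0:
        return 1.0
    i = np.arange(k, min(n_a, n_b) + 1)
    logpmf = (
        gammaln(n_a + 1)
        - gammaln(i + 1)
        - gammaln(n_a - i + 1)
        + gammaln(n_universe - n_a + 1)
        - gammaln(n_b - i + 1)
        - gammaln(n_universe - n_a - n_b + i + 1)
        - (gammaln(n_universe + 1) - gammaln(n_b + 1) - gammaln(n_universe - n_b + 1))
    )
    return float(min(1.0, math.exp(logsumexp(logpmf))))


def relative_enrichment(a: int, b: int, c: int, d: int) -> float:
    """Ratio of proportions (a/(a+b)) / (c/(c+d)).

    a, b partition the focal group; c, d partition the comparison group.
    """
    if a + b <= 0 or c + d <= 0:
        raise ValueError("both groups must be non-empty")
    if c <= 0:
        raise ValueError("comparison numerator c must be > 0")
    return (a / (a + b)) / (c / (c + d))
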