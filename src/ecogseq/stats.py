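"""Self-contained statistical primitives used throughout the pipeline.

Welch's two-sample t-test, Benjamini-Yekutieli FDR adjustment (valid under
arbitrary dependence), Tukey-bisquare robust regression by IRLS, the scaled
median absolute deviation, and McNemar's chi-square with Yates continuity
correction. All tests are two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "RobustFit",
    "welch_t",
    "fdr_by",
    "bisquare_regress",
    "mad_scaled",
    "mcnemar_yates",
]

#: Tukey bisquare tuning constant giving 95% efficiency at the gaussian model.
BISQUARE_C = 4.685

#: Consistency constant making the MAD unbiased for sigma at the gaussian model.
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its degrees of freedom and two-tailed p-value."""

    statistic: float
    df: float
    p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must lie in [0, 1], got {self.p}")
        if self.df <= 0:
            raise ValueError(f"df must be positive, got {self.df}")


@dataclass
class RobustFit:
    """Result of an iteratively reweighted bisquare regression."""

    coefficients: np.ndarray
    se: np.ndarray
    p: np.ndarray
    residuals: np.ndarray
    scale: float
    weights: np.ndarray
    converged: bool
    n_iter: int
    df: float = field(default=np.nan)


def welch_t(x, y) -> TestResult:
    """Welch's unequal-variance two-sample t-test.

    Uses the Welch-Satterthwaite approximation for the effective degrees of
    freedom. Raises ``ValueError`` when both samples are degenerate (zero
    variance), where the statistic is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t requires at least two observations per sample")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            # Identical constants: no evidence of difference.
            return TestResult(statistic=0.0, df=float(x.size + y.size - 2), p=1.0)
        raise ValueError("welch_t undefined: both samples have zero variance")
    sx = vx / x.size
    sy = vy / y.size
    t = (x.mean() - y.mean()) / np.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (
        (sx**2 / (x.size - 1)) + (sy**2 / (y.size - 1))
    )
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p=float(min(p, 1.0)))


def welch_t_arrays(mx, vx, nx, my, vy, ny):
    """Vectorised Welch statistic from precomputed means/variances/counts.

    Returns ``(t, df, p)`` arrays; entries where both variances are zero or a
    count is below 2 get ``t=0, p=1``. Used by the sliding-window detector
    where millions of tests are needed.
    """
    mx, vx, my, vy = (np.asarray(a, dtype=float) for a in (mx, vx, my, vy))
    nx = np.asarray(nx, dtype=float)
    ny = np.asarray(ny, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sx = vx / nx
        sy = vy / ny
        denom = np.sqrt(sx + sy)
        t = (mx - my) / denom
        df = (sx + sy) ** 2 / (sx**2 / (nx - 1) + sy**2 / (ny - 1))
    bad = ~np.isfinite(t) | (nx < 2) | (ny < 2)
    t = np.where(bad, 0.0, t)
    df = np.where(bad | ~np.isfinite(df), 1.0, df)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(bad, 1.0, np.minimum(p, 1.0))
    return t, df, p


def fdr_by(pvals) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values.

    Adjusted p_(i) = min over j >= i of min(1, p_(j) * m * c(m) / j) with
    c(m) = sum_{k=1..m} 1/k, valid under any dependence structure. Input order
    is preserved.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def mad_scaled(values) -> float:
    """Scaled median absolute deviation: 1.4826 * median(|v - median(v)|)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("mad_scaled requires at least one value")
    return float(MAD_SCALE * np.median(np.abs(v - np.median(v))))


def _bisquare_weights(r: np.ndarray, scale: float) -> np.ndarray:
    if scale <= 0:
        # Degenerate (e.g. exact fit): all points agree, keep full weight.
        return np.ones_like(r)
    u = r / (BISQUARE_C * scale)
    w = (1.0 - u**2) ** 2
    w[np.abs(u) >= 1.0] = 0.0
    return w


def bisquare_regress(design, y, tol: float = 1e-8, max_iter: int = 50) -> RobustFit:
    """Tukey-bisquare robust regression via iteratively reweighted least squares.

    The scale is re-estimated each iteration as the scaled MAD of the current
    residuals. Standard errors use the weighted least-squares covariance at the
    converged weights with a robust variance estimate; p-values are two-tailed
    from a t distribution on n - k degrees of freedom (asymptotic choice; the
    field has no single convention).
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} rows for {k} coefficients, got {n}")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    converged = False
    it = 0
    w = np.ones(n)
    scale = mad_scaled(resid)
    for it in range(1, max_iter + 1):
        scale = mad_scaled(resid)
        w = _bisquare_weights(resid, scale)
        if w.sum() < k + 1:  # pathological: nearly all points rejected
            w = np.ones(n)
        Xw = X * w[:, None]
        try:
            beta_new = np.linalg.solve(Xw.T @ X, Xw.T @ y)
        except np.linalg.LinAlgError:
            break
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        resid = y - X @ beta
        if step < tol:
            converged = True
            break

    # Robust covariance: Huber's correction with psi residuals (as used by
    # standard IRLS implementations).
    dof = max(n - k, 1)
    if scale > 0:
        u = resid / (BISQUARE_C * scale)
        psi = np.where(np.abs(u) < 1.0, resid * (1.0 - u**2) ** 2, 0.0)
        psi_deriv = np.where(
            np.abs(u) < 1.0, (1.0 - u**2) * (1.0 - 5.0 * u**2), 0.0
        )
        mean_dpsi = psi_deriv.mean()
        if abs(mean_dpsi) < 1e-12:
            mean_dpsi = 1e-12
        s2 = (n / dof) * np.sum(psi**2) / n / mean_dpsi**2
        kappa = 1.0 + k * psi_deriv.var() / (n * mean_dpsi**2)
        cov = kappa**2 * s2 * np.linalg.inv(X.T @ X)
    else:
        cov = np.zeros((k, k))
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * sps.t.sf(np.abs(tvals), dof)
    p = np.where(np.isfinite(tvals) | (beta == 0), p, 0.0)
    p = np.where((se == 0) & (beta == 0), 1.0, p)
    return RobustFit(
        coefficients=beta,
        se=se,
        p=np.minimum(p, 1.0),
        residuals=resid,
        scale=float(scale),
        weights=w,
        converged=converged,
        n_iter=it,
        df=float(dof),
    )


def mcnemar_yates(n01: int, n10: int) -> TestResult:
    """McNemar's chi-square with Yates continuity correction (df = 1).

    The continuity-corrected numerator is clamped at zero,
    chi2 = max(|n01 - n10| - 1, 0)^2 / (n01 + n10), so equal discordant counts
    give chi2 = 0 rather than a spurious positive value; chi2 = 0 likewise when
    there are no discordant pairs.
    """
    if n01 < 0 or n10 < 0:
        raise ValueError("discordant counts must be non-negative")
    total = n01 + n10
    if total == 0:
        return TestResult(statistic=0.0, df=1.0, p=1.0)
    num = max(abs(n01 - n10) - 1.0, 0.0)
    chi2 = num**2 / total
    p = float(sps.chi2.sf(chi2, 1))
    return TestResult(statistic=float(chi2), df=1.0, p=min(p, 1.0))
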