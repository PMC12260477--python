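"""Segmented regression for habitat-amount threshold detection.

Connectivity (IIC) is modeled against the minimum habitat amount retained
in the landscape.  Under the extinction-threshold hypothesis the response
is not a single line but two segments joined at a breakpoint ψ — the
habitat amount below which regional connectivity erodes.  The model is

    y = β₀ + β₁·x + β₂·(x − ψ)₊ ,

continuous at ψ, with left slope β₁ and right slope β₁ + β₂.  ψ is
estimated by iterative linearization: at a working value ψ⁽ᵗ⁾, regress y on
{1, x, (x − ψ)₊, −I(x > ψ)} and update ψ ← ψ + γ̂/β̂₂, where γ̂ is the
coefficient of the indicator ("gap") term and β̂₂ the slope change; at the
solution the gap vanishes and the fitted curve is continuous.  If the
iteration diverges, a deterministic grid search over interior x-quantiles
restarts it.

The linear model is the null against which the breakpoint is judged, via
AIC (convention AIC = n·ln(2π·RSS/n) + n + 2·(k+1), with k regression
coefficients and +1 for the error variance) and via a parametric bootstrap
test that simulates from the fitted linear model.

Least-squares solves use plain normal-equation-free ``numpy.linalg.lstsq``;
the Monte-Carlo test refits the segmented model hundreds of times, so the
inner loop stays allocation-light.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "LinearFit",
    "SegmentedFit",
    "fit_linear",
    "fit_segmented",
    "breakpoint_ci",
    "breakpoint_test",
    "compare_aic",
]


def _aic(n: int, rss: float, k: int) -> float:
    """Gaussian-likelihood AIC; k regression coefficients, +1 for σ²."""
    if rss <= 0:
        return -np.inf
    return n * np.log(2.0 * np.pi * rss / n) + n + 2.0 * (k + 1)


def _lstsq(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


@dataclass
class LinearFit:
    intercept: float
    slope: float
    rss: float
    aic: float
    r2: float
    n_obs: int
    fitted: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)


@dataclass
class SegmentedFit:
    """One-breakpoint piecewise-linear fit, with the linear fit on the same
    data as baseline.  ``psi`` is on the scale of the supplied x (percent
    habitat in the standard pipeline).  ``p_value`` is populated by
    :func:`breakpoint_test`, ``psi_ci`` by :func:`breakpoint_ci`."""

    psi: float
    psi_se: float
    intercept: float
    slope_left: float
    slope_right: float
    r2: float
    rss: float
    aic_segmented: float
    aic_linear: float
    delta_aic: float
    n_obs: int
    converged: bool
    gap: float
    psi_ci: tuple[float, float] | None = None
    p_value: float | None = None
    x: np.ndarray = field(default=None, repr=False)
    y: np.ndarray = field(default=None, repr=False)

    def predict(self, x_new) -> np.ndarray:
        x_new = np.asarray(x_new, dtype=float)
        return (
            self.intercept
            + self.slope_left * x_new
            + (self.slope_right - self.slope_left) * np.maximum(0.0, x_new - self.psi)
        )


def _check_xy(x, y, n_min: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < n_min:
        raise ValueError(f"at least {n_min} observations are required")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    return x, y


def fit_linear(x, y) -> LinearFit:
    """Ordinary least squares y = a + b·x."""
    x, y = _check_xy(x, y, 3)
    X = np.column_stack([np.ones_like(x), x])
    beta, rss = _lstsq(X, y)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    fitted = X @ beta
    return LinearFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        rss=rss,
        aic=_aic(x.size, rss, k=2),
        r2=r2,
        n_obs=x.size,
        fitted=fitted,
        residuals=y - fitted,
    )


def _profiled_rss(x: np.ndarray, y: np.ndarray, psi: float) -> tuple[np.ndarray, float]:
    X = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - psi)])
    return _lstsq(X, y)


def _iterate(
    x: np.ndarray,
    y: np.ndarray,
    psi: float,
    lo: float,
    hi: float,
    tol: float,
    max_iter: int,
) -> tuple[float, float, float, bool]:
    """Muggeo linearization from a starting ψ; returns (ψ, γ̂, se(γ̂)/|β̂₂|, ok)."""
    gamma = np.inf
    se_ratio = np.nan
    for _ in range(max_iter):
        U = np.maximum(0.0, x - psi)
        V = -(x > psi).astype(float)
        X = np.column_stack([np.ones_like(x), x, U, V])
        beta, rss = _lstsq(X, y)
        b2, gamma = float(beta[2]), float(beta[3])
        if b2 == 0.0 or not np.isfinite(gamma):
            return psi, gamma, se_ratio, False
        df = x.size - 4
        xtx = X.T @ X
        try:
            cov = np.linalg.inv(xtx)
        except np.linalg.LinAlgError:
            return psi, gamma, se_ratio, False
        sigma2 = rss / df if df > 0 else 0.0
        se_gamma = float(np.sqrt(max(sigma2 * cov[3, 3], 0.0)))
        se_ratio = se_gamma / abs(b2)
        step = gamma / b2
        new_psi = psi + step
        if not np.isfinite(new_psi) or new_psi <= lo or new_psi >= hi:
            return psi, gamma, se_ratio, False
        if abs(gamma) < tol or abs(new_psi - psi) < 1e-12 * (hi - lo):
            return new_psi, gamma, se_ratio, True
        psi = new_psi
    return psi, gamma, se_ratio, False


def fit_segmented(x, y, psi0: float | None = None, max_iter: int = 50) -> SegmentedFit:
    """Fit the one-breakpoint model, restarting from interior quantiles if
    the iteration diverges.

    The fit is deterministic given (x, y, psi0).  If no interior breakpoint
    improves on the plain line (degenerate y, or β₂ ≈ 0), the result has
    ``converged=False`` and carries the linear coefficients — no exception.
    """
    x, y = _check_xy(x, y, 5)
    lin = fit_linear(x, y)
    sdy = float(np.std(y))
    xs = np.sort(x)
    lo, hi = xs[0], xs[-1]
    tol = 1e-8 * sdy if sdy > 0 else 1e-12

    def degenerate() -> SegmentedFit:
        return SegmentedFit(
            psi=float(np.median(x)), psi_se=np.nan,
            intercept=lin.intercept, slope_left=lin.slope, slope_right=lin.slope,
            r2=lin.r2, rss=lin.rss,
            aic_segmented=_aic(x.size, lin.rss, k=4), aic_linear=lin.aic,
            delta_aic=_aic(x.size, lin.rss, k=4) - lin.aic,
            n_obs=x.size, converged=False, gap=0.0, x=x, y=y,
        )

    if sdy == 0:
        return degenerate()

    psi_start = float(np.median(x)) if psi0 is None else float(psi0)
    if not lo < psi_start < hi:
        raise ValueError("psi0 must lie strictly inside the x-range")

    # Multi-start: the linearization can stall in a local optimum of the
    # profiled RSS (the profile is only piecewise smooth in ψ), so the
    # iteration from psi0 always competes against restarts from interior
    # x-quantiles; the candidate with the lowest profiled RSS wins.
    candidates: list[tuple[float, float, float, bool]] = []
    res = _iterate(x, y, psi_start, lo, hi, tol, max_iter)
    if res[3]:
        candidates.append(res)
    qs = np.unique(np.quantile(x, np.linspace(0.05, 0.95, 19)))
    qs = qs[(qs > lo) & (qs < hi)]
    if qs.size:
        rss_q = np.array([_profiled_rss(x, y, q)[1] for q in qs])
        best_q = float(qs[int(np.argmin(rss_q))])
        res2 = _iterate(x, y, best_q, lo, hi, tol, max_iter)
        candidates.append(res2 if res2[3] else (best_q, 0.0, np.nan, False))
    if not candidates:
        return degenerate()
    psi, gamma, se_psi, iter_ok = min(
        candidates, key=lambda c: _profiled_rss(x, y, c[0])[1]
    )
    beta, rss = _profiled_rss(x, y, psi)
    improves = rss < lin.rss * (1.0 - 1e-12) and abs(beta[2]) > 0
    tss = float(np.sum((y - y.mean()) ** 2))
    aic_seg = _aic(x.size, rss, k=4)
    return SegmentedFit(
        psi=float(psi),
        psi_se=float(se_psi),
        intercept=float(beta[0]),
        slope_left=float(beta[1]),
        slope_right=float(beta[1] + beta[2]),
        r2=1.0 - rss / tss if tss > 0 else 0.0,
        rss=rss,
        aic_segmented=aic_seg,
        aic_linear=lin.aic,
        delta_aic=aic_seg - lin.aic,
        n_obs=x.size,
        converged=bool(iter_ok and improves),
        gap=float(gamma),
        x=x,
        y=y,
    )


def breakpoint_ci(
    fit: SegmentedFit,
    level: float = 0.95,
    method: str = "delta",
    n_boot: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Confidence interval for the breakpoint.

    ``delta``: ψ̂ ± t_{n−4} · SE(ψ̂), with SE(ψ̂) = SE(γ̂)/|β̂₂| propagated
    from the last linearization step.  ``bootstrap``: resample the
    segmented-fit residuals, refit, take the percentile interval.  The
    interval is stored on the fit and returned.
    """
    if not fit.converged:
        raise ValueError("confidence interval requires a converged fit")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if method == "delta":
        if not np.isfinite(fit.psi_se):
            raise ValueError("breakpoint CI undefined: slope change is ~0")
        tq = stats.t.ppf(0.5 + level / 2.0, df=max(fit.n_obs - 4, 1))
        ci = (fit.psi - tq * fit.psi_se, fit.psi + tq * fit.psi_se)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        resid = fit.y - fit.predict(fit.x)
        resid = resid - resid.mean()
        psis = []
        for _ in range(n_boot):
            y_star = fit.predict(fit.x) + rng.choice(resid, size=resid.size, replace=True)
            bfit = fit_segmented(fit.x, y_star, psi0=fit.psi)
            if bfit.converged:
                psis.append(bfit.psi)
        if len(psis) < max(20, n_boot // 10):
            raise ValueError("too few converged bootstrap refits for a CI")
        alpha = 1.0 - level
        ci = tuple(np.quantile(psis, [alpha / 2.0, 1.0 - alpha / 2.0]))
    else:
        raise ValueError("method must be 'delta' or 'bootstrap'")
    fit.psi_ci = (float(ci[0]), float(ci[1]))
    return fit.psi_ci


def breakpoint_test(x, y, fit: SegmentedFit, n_sim: int = 199, seed: int = 0) -> float:
    """Parametric bootstrap test of H₀: no slope change.

    Pseudo-data are simulated from the fitted *linear* model by resampling
    its residuals; for each replicate the RSS improvement of the segmented
    over the linear fit is compared with the observed improvement, and
    p = (1 + #{simulated ≥ observed}) / (n_sim + 1).  Degenerate constant y
    gives p = 1 by convention.  The p-value is stored on the fit.
    """
    x, y = _check_xy(x, y, 5)
    if np.ptp(y) == 0:
        fit.p_value = 1.0
        return 1.0
    lin = fit_linear(x, y)
    observed = lin.rss - fit.rss
    rng = np.random.default_rng(seed)
    resid = lin.residuals - lin.residuals.mean()
    exceed = 0
    for _ in range(n_sim):
        y_star = lin.fitted + rng.choice(resid, size=resid.size, replace=True)
        lin_star = fit_linear(x, y_star)
        seg_star = fit_segmented(x, y_star)
        if (lin_star.rss - seg_star.rss) >= observed:
            exceed += 1
    p = (1.0 + exceed) / (n_sim + 1.0)
    fit.p_value = float(p)
    return fit.p_value


def compare_aic(linear: LinearFit, segmented: SegmentedFit) -> float:
    """ΔAIC = AIC(segmented) − AIC(linear); negative favors the breakpoint
    model.  Both fits must be on the same observations."""
    if linear.n_obs != segmented.n_obs:
        raise ValueError("fits were not computed on the same data")
    return segmented.aic_segmented - linear.aic
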