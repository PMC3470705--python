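"""L1-penalized logistic regression paths.

The objective minimized at each penalty ``lam`` on the grid is

    f(mu, beta) = (1/n) * sum_i [ log(1 + exp(eta_i)) - y_i * eta_i ]
                  + lam * sum_j |beta_j|,          eta = mu + Xc @ beta

with an unpenalized intercept ``mu`` and a column-centered design ``Xc``.
The 1/n normalization gives the zeroing penalty the closed form

    lambda_max = (1/n) * max_j | <x_j, y - ybar * 1> |

so that any ``lam >= lambda_max`` produces the all-zero coefficient vector.

The solver is coordinate descent inside an IRLS (iteratively reweighted
least squares) outer loop with warm starts along the grid and an
active-set strategy, i.e. the algorithm popularized by glmnet. Convergence
is certified by the KKT conditions of the convex objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .containers import CaseControlResponse, GenotypeMatrix

ACTIVE_TOL = 1e-8  # |coefficient| above this counts as selected
KKT_TOL = 1e-8  # solver stationarity tolerance
_PMIN = 1e-5  # probability clip inside IRLS working weights


def center_columns(X: GenotypeMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-center a complete genotype matrix.

    Returns the centered matrix and the column means (retained so that
    out-of-sample rows can be centered in the same frame).
    """
    values = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X, dtype=float)
    if np.isnan(values).any():
        raise ValueError(
            "genotype matrix has missing entries; impute before centering "
            "(see llarrma.impute)"
        )
    means = values.mean(axis=0)
    return values - means, means


def lambda_max(Xc: np.ndarray, y_vec: np.ndarray) -> float:
    """Smallest penalty that zeroes out every coefficient.

    ``(1/n) * max_j |<x_j, y - ybar>|`` on the column-centered design. A
    constant response returns 0.
    """
    y = np.asarray(y_vec, dtype=float)
    n = y.size
    resid = y - y.mean()
    return float(np.abs(Xc.T @ resid).max() / n)


def default_grid(lam_max: float, n_points: int = 100, min_ratio: float = 0.001) -> np.ndarray:
    """Log-spaced decreasing penalty grid from lam_max down to min_ratio * lam_max."""
    if lam_max <= 0:
        raise ValueError("lambda_max must be positive to build a grid")
    return np.geomspace(lam_max, min_ratio * lam_max, n_points)


@njit(cache=True)
def _cd_path(Xf, X2f, y, lambdas, kkt_tol, inner_tol, max_outer, n_fit, sat_ratio, max_sweeps):  # pragma: no cover - numba
    """Coordinate-descent path kernel.

    Xf and X2f are Fortran-ordered so column slices are contiguous; X2f is
    the elementwise square of Xf. Sequential strong-rule screening restricts
    the working set per grid point, with a full KKT pass certifying (and,
    when violated, repairing) each solution.
    """
    n, m = Xf.shape
    L = lambdas.shape[0]
    coefs = np.zeros((L, m))
    intercepts = np.zeros(L)

    ybar = y.sum() / n
    null_dev = -2.0 * n * (ybar * np.log(ybar) + (1.0 - ybar) * np.log(1.0 - ybar))
    tol_base = inner_tol * null_dev / n
    mu = np.log(ybar / (1.0 - ybar))
    beta = np.zeros(m)
    eta = np.full(n, mu)
    r = np.empty(n)
    w = np.empty(n)
    a = np.empty(m)  # (1/n) sum_i w_i x_ij^2, per outer iteration
    g = np.empty(m)  # (1/n) X^T (y - p), carried across grid points
    resid = np.empty(n)
    cand = np.zeros(m, dtype=np.bool_)
    ever_active = np.zeros(m, dtype=np.bool_)

    # gradient at the all-zero warm start (p = ybar everywhere)
    for i in range(n):
        resid[i] = y[i] - ybar
    for j in range(m):
        g[j] = np.dot(resid, Xf[:, j]) / n

    for l in range(n_fit):
        lam = lambdas[l]
        lam_prev = lambdas[l - 1] if l > 0 else lam
        thr = 2.0 * lam - lam_prev
        for j in range(m):
            cand[j] = ever_active[j] or beta[j] != 0.0 or abs(g[j]) >= thr

        tol_cur = tol_base
        tighten_budget = 2
        sweep_budget = max_sweeps
        while True:  # strong-rule repair loop
            converged = False
            for _outer in range(max_outer):
                # IRLS working weights and residual at current eta
                wsum = 0.0
                for i in range(n):
                    p = 1.0 / (1.0 + np.exp(-eta[i]))
                    if p < _PMIN:
                        p = _PMIN
                    elif p > 1.0 - _PMIN:
                        p = 1.0 - _PMIN
                    w[i] = p * (1.0 - p)
                    r[i] = (y[i] - p) / w[i]  # working residual z - eta
                    wsum += w[i]
                for j in range(m):
                    if cand[j]:
                        a[j] = np.dot(w, X2f[:, j]) / n

                # coordinate descent over the candidate set
                first_sweep_delta = -1.0
                for _sweep in range(1000):
                    if sweep_budget <= 0:
                        break
                    sweep_budget -= 1
                    max_delta = 0.0
                    active_only = _sweep > 0
                    for j in range(m):
                        if not cand[j] or a[j] <= 0.0:
                            continue
                        if active_only and beta[j] == 0.0:
                            continue
                        colj = Xf[:, j]
                        uj = 0.0
                        for i in range(n):
                            uj += w[i] * colj[i] * r[i]
                        uj = uj / n + a[j] * beta[j]
                        if uj > lam:
                            newb = (uj - lam) / a[j]
                        elif uj < -lam:
                            newb = (uj + lam) / a[j]
                        else:
                            newb = 0.0
                        d = newb - beta[j]
                        if d != 0.0:
                            for i in range(n):
                                r[i] -= d * colj[i]
                            beta[j] = newb
                            if a[j] * d * d > max_delta:
                                max_delta = a[j] * d * d
                    # unpenalized intercept
                    dm = 0.0
                    for i in range(n):
                        dm += w[i] * r[i]
                    dm /= wsum
                    if dm != 0.0:
                        mu += dm
                        for i in range(n):
                            r[i] -= dm
                        if 0.25 * dm * dm > max_delta:
                            max_delta = 0.25 * dm * dm
                    if first_sweep_delta < 0.0:
                        first_sweep_delta = max_delta
                    if max_delta < tol_cur:
                        if active_only:
                            # confirming pass over the full candidate set
                            chg = 0.0
                            for j in range(m):
                                if not cand[j] or beta[j] != 0.0 or a[j] <= 0.0:
                                    continue
                                colj = Xf[:, j]
                                uj = 0.0
                                for i in range(n):
                                    uj += w[i] * colj[i] * r[i]
                                uj /= n
                                if uj > lam:
                                    newb = (uj - lam) / a[j]
                                elif uj < -lam:
                                    newb = (uj + lam) / a[j]
                                else:
                                    continue
                                for i in range(n):
                                    r[i] -= newb * colj[i]
                                beta[j] = newb
                                if a[j] * newb * newb > chg:
                                    chg = a[j] * newb * newb
                            if chg < tol_cur:
                                break
                        else:
                            break

                # eta = mu + X beta, via active columns only
                for i in range(n):
                    eta[i] = mu
                for j in range(m):
                    bj = beta[j]
                    if bj != 0.0:
                        colj = Xf[:, j]
                        for i in range(n):
                            eta[i] += bj * colj[i]

                # KKT certificate over the candidate set
                gsum = 0.0
                for i in range(n):
                    p = 1.0 / (1.0 + np.exp(-eta[i]))
                    resid[i] = y[i] - p
                    gsum += resid[i]
                gsum /= n
                viol = abs(gsum)
                for j in range(m):
                    if not cand[j]:
                        continue
                    g[j] = np.dot(resid, Xf[:, j]) / n
                    if beta[j] != 0.0:
                        s = 1.0 if beta[j] > 0 else -1.0
                        v = abs(g[j] - lam * s)
                    else:
                        v = abs(g[j]) - lam
                        if v < 0.0:
                            v = 0.0
                    if v > viol:
                        viol = v
                if viol < kkt_tol:
                    converged = True
                    break
                if sweep_budget <= 0:
                    break
                if first_sweep_delta < tol_cur:
                    # IRLS stalled at this surrogate tolerance. Tighten it (at
                    # most twice) so further outer iterations can reduce the
                    # KKT gap; past that, extra accuracy is unaffordable in
                    # ill-conditioned dense regimes and we accept the fit.
                    if tighten_budget == 0:
                        break
                    tighten_budget -= 1
                    tol_cur *= 0.01

            # full-gradient pass: admit strong-rule survivors that violate KKT
            new_violation = False
            for j in range(m):
                g[j] = np.dot(resid, Xf[:, j]) / n
                if not cand[j] and abs(g[j]) > lam + kkt_tol:
                    cand[j] = True
                    new_violation = True
            if not new_violation or not converged:
                break

        for j in range(m):
            if abs(beta[j]) < 1e-12:  # snap float residue to an exact zero
                beta[j] = 0.0
            coefs[l, j] = beta[j]
            if beta[j] != 0.0:
                ever_active[j] = True
        intercepts[l] = mu

        # saturation stop (standard path convention): once the fit explains
        # essentially all deviance, carry the solution forward
        dev = 0.0
        for i in range(n):
            p = 1.0 / (1.0 + np.exp(-eta[i]))
            if p < 1e-12:
                p = 1e-12
            elif p > 1.0 - 1e-12:
                p = 1.0 - 1e-12
            dev -= 2.0 * (y[i] * np.log(p) + (1.0 - y[i]) * np.log(1.0 - p))
        if 1.0 - dev / null_dev > sat_ratio:
            for l2 in range(l + 1, n_fit):
                for j in range(m):
                    coefs[l2, j] = beta[j]
                intercepts[l2] = mu
            break

    return intercepts, coefs


@dataclass
class LassoPath:
    """A fitted L1 logistic path over a decreasing penalty grid."""

    lambda_grid: np.ndarray
    coefficients: np.ndarray  # grid_length x m
    intercepts: np.ndarray
    column_means: np.ndarray | None = None
    n_fitted: int | None = None  # grid points actually solved (early stop)

    def linear_predictor(self, Xc: np.ndarray) -> np.ndarray:
        """Linear predictors at every fitted grid point: grid_length x n_new."""
        return self.intercepts[:, None] + self.coefficients @ Xc.T

    def predicted_probabilities(self, Xc: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        return expit(self.linear_predictor(Xc))


def fit_lasso_path(
    Xc: np.ndarray,
    y: CaseControlResponse | np.ndarray,
    lambda_grid: np.ndarray,
    column_means: np.ndarray | None = None,
    stop_index: int | None = None,
    max_outer: int = 50,
    inner_tol: float = 1e-7,
    saturation_ratio: float = 0.999,
    max_sweeps: int = 100,
) -> LassoPath:
    """Fit the L1 logistic path on a decreasing positive penalty grid.

    Parameters
    ----------
    Xc : column-centered complete design matrix.
    y : binary response with at least one case and one control.
    lambda_grid : strictly decreasing positive penalties.
    stop_index : solve only grid points 0..stop_index (warm-started); later
        grid points keep zero placeholders and ``n_fitted`` records the cut.
    """
    y_vec = y.y if isinstance(y, CaseControlResponse) else np.asarray(y)
    y_vec = np.ascontiguousarray(y_vec, dtype=np.float64)
    Xf = np.asfortranarray(Xc, dtype=np.float64)
    grid = np.ascontiguousarray(lambda_grid, dtype=np.float64)
    if not np.all(np.isfinite(Xf)) or not np.all(np.isfinite(y_vec)):
        raise ValueError("design and response must be finite")
    if (grid <= 0).any() or (grid.size > 1 and (np.diff(grid) >= 0).any()):
        raise ValueError("lambda grid must be positive and strictly decreasing")
    if y_vec.min() == y_vec.max():
        raise ValueError("response is constant: no cases or no controls")
    n_fit = grid.size if stop_index is None else stop_index + 1
    if not 1 <= n_fit <= grid.size:
        raise ValueError("stop_index outside grid")
    intercepts, coefs = _cd_path(
        Xf, Xf * Xf, y_vec, grid, KKT_TOL, inner_tol, max_outer, n_fit,
        saturation_ratio, max_sweeps
    )
    return LassoPath(grid, coefs, intercepts, column_means, n_fitted=n_fit)


def snap_to_grid(lambda_grid: np.ndarray, lam: float) -> int:
    """Index of the grid value nearest lam; ties go to the larger penalty."""
    grid = np.asarray(lambda_grid, dtype=float)
    lo, hi = grid.min(), grid.max()
    if not lo <= lam <= hi:
        raise ValueError(f"penalty {lam:g} outside the grid range [{lo:g}, {hi:g}]")
    # grid is decreasing, so the first argmin is the larger-lambda tie
    return int(np.argmin(np.abs(grid - lam)))


def active_set(path: LassoPath, lam: float) -> np.ndarray:
    """Binary inclusion vector at the grid point nearest lam.

    Element j is 1 iff |coefficient_j| exceeds the active-set tolerance at
    the snapped grid point.
    """
    idx = snap_to_grid(path.lambda_grid, lam)
    if path.n_fitted is not None and idx >= path.n_fitted:
        raise ValueError("requested penalty beyond the fitted part of the path")
    return (np.abs(path.coefficients[idx]) > ACTIVE_TOL).astype(np.int8)
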