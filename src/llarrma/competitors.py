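"""Benchmark methods: single-locus regression and Stability Selection.

Single-locus regression scores each SNP by the -log10 P-value of a
likelihood ratio test of a one-predictor logistic model against the
intercept-only model -- the standard GWAS scan statistic.

Stability Selection is subagging with a single global penalty shared by
all K subsamples, giving a stability path of RMIPs as a function of the
penalty. Because its penalty is a free parameter, the comparison here uses
"oracle" calibration: the penalty maximizing a truth-dependent criterion
(by default the initial AUC), an unfairly advantageous choice that gives
the competitor its best possible showing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .containers import CaseControlResponse, GenotypeMatrix, ScoreTable
from .evaluation import INITIAL_WINDOW, TrialResult, trial_auc
from .lasso import ACTIVE_TOL, center_columns, default_grid, fit_lasso_path, lambda_max
from .resampling import child_rng, draw_subsample

logger = logging.getLogger("llarrma")

MAX_LOGP = 300.0  # cap on -log10 P under (near-)separation


def _newton_single_snp(x: np.ndarray, y: np.ndarray, obs: np.ndarray,
                       max_iter: int = 60, tol: float = 1e-10) -> tuple[float, float]:
    """Deviance of the one-predictor and intercept-only logistic fits.

    Vectorized 2-parameter Newton-Raphson on the observed entries. Returns
    (null_deviance, model_deviance). Diverging fits (separation) are capped
    by clipping the linear predictor; the LRT is then capped downstream.
    """
    xo, yo = x[obs], y[obs]
    n = yo.size
    ybar = yo.mean()
    null_dev = -2.0 * n * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar))
    if xo.min() == xo.max():
        return null_dev, null_dev  # constant SNP carries no information
    a = float(np.log(ybar / (1 - ybar)))
    b = 0.0
    for _ in range(max_iter):
        eta = np.clip(a + b * xo, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        g0 = np.sum(yo - p)
        g1 = np.sum(xo * (yo - p))
        h00 = np.sum(w)
        h01 = np.sum(w * xo)
        h11 = np.sum(w * xo * xo)
        det = h00 * h11 - h01 * h01
        if det <= 1e-12:
            break
        da = (h11 * g0 - h01 * g1) / det
        db = (h00 * g1 - h01 * g0) / det
        a += da
        b += db
        if abs(da) < tol and abs(db) < tol:
            break
    eta = np.clip(a + b * xo, -30, 30)
    p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    model_dev = -2.0 * float(np.sum(yo * np.log(p) + (1 - yo) * np.log(1 - p)))
    return null_dev, model_dev


def single_locus_scores(
    X: GenotypeMatrix | np.ndarray, y: CaseControlResponse | np.ndarray
) -> np.ndarray:
    """-log10 LRT P-values (chi-squared, 1 df) for each SNP separately.

    Missing genotypes are handled per SNP by complete cases. Scores are
    capped at 300 (separation gives numerically zero P-values).
    """
    values = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X, dtype=float)
    y_vec = (y.y if isinstance(y, CaseControlResponse) else np.asarray(y)).astype(float)
    m = values.shape[1]
    scores = np.empty(m)
    for j in range(m):
        x = values[:, j]
        obs = ~np.isnan(x)
        null_dev, model_dev = _newton_single_snp(x, y_vec, obs)
        stat = max(0.0, null_dev - model_dev)
        # -log10 P via the log survival function; stable for huge statistics
        logp = -chi2.logsf(stat, df=1) / np.log(10.0) if stat > 0 else 0.0
        if logp > MAX_LOGP:
            logger.debug("SNP %d: separation-capped score", j)
            logp = MAX_LOGP
        scores[j] = logp
    return scores


class SingleLocus:
    """One-SNP-at-a-time logistic regression model for a hit region."""

    def __init__(self, X: GenotypeMatrix | np.ndarray, y) -> None:
        self.X = X
        self.y = y if isinstance(y, CaseControlResponse) else CaseControlResponse(y)

    def fit(self) -> "SingleLocusResults":
        return SingleLocusResults(model=self, logp=single_locus_scores(self.X, self.y))


@dataclass
class SingleLocusResults:
    model: SingleLocus
    logp: np.ndarray

    def to_score_table(self) -> ScoreTable:
        X = self.model.X
        snp_ids = X.snp_ids if isinstance(X, GenotypeMatrix) else [
            f"snp{j}" for j in range(self.logp.size)
        ]
        positions = X.positions if isinstance(X, GenotypeMatrix) else None
        return ScoreTable(snp_ids, self.logp, "single-locus", positions)

    def summary(self, top: int | None = 20) -> str:
        df = self.to_score_table().to_dataframe().sort_values("rank")
        if top is not None:
            df = df.head(top)
        lines = [f"{r.snp_id:<16}{r.score:>10.3f}{r.rank:>6d}" for r in df.itertuples()]
        return f"Single-locus logistic LRT\n{'snp_id':<16}{'-log10P':>10}{'rank':>6}\n" + \
            "\n".join(lines)


@dataclass
class StabilityPath:
    """RMIP as a function of a global penalty shared by all subsamples."""

    lambda_grid: np.ndarray
    rmip_matrix: np.ndarray  # grid_length x m, entries in {0, 1/K, ..., 1}
    K: int
    phi: float
    seed: int | None = None

    def rmip_at(self, lam: float) -> np.ndarray:
        from .lasso import snap_to_grid

        return self.rmip_matrix[snap_to_grid(self.lambda_grid, lam)]


def stability_selection(
    X: GenotypeMatrix | np.ndarray | None,
    y: CaseControlResponse,
    K: int = 100,
    phi: float = 0.5,
    grid: np.ndarray | None = None,
    seed=None,
    imputations=None,
    grid_size: int = 100,
    grid_min_ratio: float = 0.001,
    n_jobs: int = 1,
) -> StabilityPath:
    """Stability path over a single global grid anchored at the full-data
    lambda_max.

    Each subsample's path is fit on the shared grid (subsample-centered
    design); entry (l, j) of the result is the fraction of subsamples in
    which SNP j is active at grid point l. Subsample k is drawn from the
    stream keyed (k, 0) of ``seed``, matching the LLARRMA convention, and
    in multiple-imputation mode analyses the k-th sampled matrix.
    """
    from .engine import _resolve_matrix_for_k

    if grid is None:
        values0 = _resolve_matrix_for_k(X, imputations, 0, K)
        Xc0, _ = center_columns(values0)
        grid = default_grid(lambda_max(Xc0, y.y), grid_size, grid_min_ratio)

    def work(k: int):
        values = _resolve_matrix_for_k(X, imputations, k, K)
        sub = draw_subsample(y, phi, child_rng(seed, k, 0), k=k)
        Xc, means = center_columns(values[sub.indices])
        path = fit_lasso_path(Xc, y.y[sub.indices], grid, column_means=means)
        return (np.abs(path.coefficients) > ACTIVE_TOL).astype(np.int8)

    if n_jobs != 1:
        from joblib import Parallel, delayed

        actives = Parallel(n_jobs=n_jobs, prefer="threads")(
            delayed(work)(k) for k in range(K)
        )
    else:
        actives = [work(k) for k in range(K)]
    rmip_matrix = np.mean(actives, axis=0)
    return StabilityPath(lambda_grid=np.asarray(grid), rmip_matrix=rmip_matrix,
                         K=K, phi=phi, seed=seed if isinstance(seed, int) else None)


def oracle_lambda(
    path: StabilityPath,
    truth: np.ndarray,
    window: tuple[float, float] = INITIAL_WINDOW,
) -> tuple[float, np.ndarray]:
    """Truth-informed choice of the global penalty.

    Scores every grid row's RMIPs against the truth by the windowed AUC
    (default: initial AUC, FPR in [0, 0.05]) and returns the maximizing
    penalty with its RMIP vector. Ties go to the largest penalty. Constant
    RMIP rows score 0 by convention.
    """
    truth = np.asarray(truth).astype(bool)
    if not truth.any() or truth.all():
        raise ValueError("truth needs at least one signal and one background SNP")
    crit = np.empty(path.lambda_grid.size)
    for l, row in enumerate(path.rmip_matrix):
        if row.min() == row.max():
            crit[l] = 0.0
        else:
            crit[l] = trial_auc(TrialResult(row, truth), *window)
    best = int(np.argmax(crit))  # first max = largest penalty on ties
    return float(path.lambda_grid[best]), path.rmip_matrix[best]


class StabilitySelection:
    """Model object for Stability Selection on one hit region."""

    def __init__(self, X, y, imputations=None, grid_size: int = 100,
                 grid_min_ratio: float = 0.001) -> None:
        self.X = X
        self.y = y if isinstance(y, CaseControlResponse) else CaseControlResponse(y)
        self.imputations = imputations
        self.grid_size = grid_size
        self.grid_min_ratio = grid_min_ratio

    def fit(self, K: int = 100, phi: float = 0.5, seed=None,
            grid: np.ndarray | None = None, n_jobs: int = 1) -> "StabilityResults":
        path = stability_selection(
            self.X, self.y, K=K, phi=phi, grid=grid, seed=seed,
            imputations=self.imputations, grid_size=self.grid_size,
            grid_min_ratio=self.grid_min_ratio, n_jobs=n_jobs,
        )
        return StabilityResults(model=self, path=path)


@dataclass
class StabilityResults:
    model: StabilitySelection
    path: StabilityPath

    def oracle(self, truth: np.ndarray,
               window: tuple[float, float] = INITIAL_WINDOW) -> "OracleSelection":
        lam, rmip = oracle_lambda(self.path, truth, window)
        return OracleSelection(lam=lam, rmip=rmip, window=window)


@dataclass
class OracleSelection:
    lam: float
    rmip: np.ndarray
    window: tuple[float, float] = field(default=INITIAL_WINDOW)
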