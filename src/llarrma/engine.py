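"""LLARRMA: LASSO local automatic regularization resample model averaging.

For each of K stratified subsamples of a case-control study, an L1
logistic path is fit to the subsample and a subsample-specific ("local")
penalty is chosen automatically, by one of two criteria:

``perm``
    Permutation selection: the median over S response permutations of the
    smallest penalty that zeroes out every coefficient on the subsample's
    centered design. A discovery-calibrated choice -- under the null it
    tends to select no SNPs.
``cdev``
    Complement deviance selection: the penalty minimizing the binomial
    deviance of the subsample-fit model on the individuals left out of the
    subsample (out-of-sample prediction).

The binary inclusion vectors from the K subsamples are stacked into the
inclusion matrix Gamma, and each SNP's resample model inclusion
probability (RMIP) is its column mean. Uncertainty from genotype
imputation is folded in by supplying an ensemble of sampled imputations:
subsample k is then drawn from the k-th imputed matrix (multiple
imputation).

Usage follows the model/results convention::

    model = LLARRMA(X, y)
    res = model.fit(K=100, phi=0.5, criterion="perm", S=25, seed=1)
    res.summary()
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .containers import CaseControlResponse, GenotypeMatrix, ScoreTable
from .lasso import (
    LassoPath,
    active_set,
    center_columns,
    default_grid,
    fit_lasso_path,
    lambda_max,
    snap_to_grid,
)
from .resampling import Subsample, child_rng, draw_subsample, permute_response

logger = logging.getLogger("llarrma")

MAX_SUBSAMPLE_RETRIES = 10


@dataclass
class PermSelection:
    """Outcome of permutation selection for one subsample."""

    lam: float
    samples: np.ndarray  # the S permutation lambda_max values


@dataclass
class CdevSelection:
    """Outcome of complement deviance selection for one subsample."""

    lam: float
    deviance_curve: np.ndarray
    grid: np.ndarray
    path: LassoPath  # the subsample path, reusable for the active set


def _subsample_design(X_values: np.ndarray, sub: Subsample) -> tuple[np.ndarray, np.ndarray]:
    Xs = X_values[sub.indices]
    Xc, means = center_columns(Xs)
    return Xc, means


def select_lambda_perm(
    sub: Subsample,
    X: GenotypeMatrix | np.ndarray,
    y: CaseControlResponse,
    S: int,
    rng: np.random.Generator,
) -> PermSelection:
    """Permutation selection of the local penalty for subsample ``sub``.

    For each of S permutations of the subsample's response, computes the
    zeroing penalty lambda_max on the subsample's centered design; the
    selected penalty is the median (even S: mean of the central pair).
    """
    if S < 1:
        raise ValueError("permutation count S must be >= 1")
    values = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X, dtype=float)
    Xc, _ = _subsample_design(values, sub)
    y_sub = y.y[sub.indices]
    samples = np.empty(S)
    for s in range(S):
        y_perm = permute_response(y_sub, rng)
        samples[s] = lambda_max(Xc, y_perm)
    return PermSelection(lam=float(np.median(samples)), samples=samples)


def binomial_deviance(y_vec: np.ndarray, p_hat: np.ndarray) -> float:
    """-2 * Bernoulli log-likelihood, with probabilities clipped at 1e-12."""
    p = np.clip(p_hat, 1e-12, 1 - 1e-12)
    y_vec = np.asarray(y_vec, dtype=float)
    return float(-2.0 * np.sum(y_vec * np.log(p) + (1 - y_vec) * np.log(1 - p)))


def select_lambda_cdev(
    sub: Subsample,
    X: GenotypeMatrix | np.ndarray,
    y: CaseControlResponse,
    grid: np.ndarray | None = None,
    grid_size: int = 100,
    grid_min_ratio: float = 0.001,
) -> CdevSelection:
    """Complement deviance selection of the local penalty.

    The path is fit on the subsample rows, centered by the subsample column
    means; the complement rows are centered in the same frame before the
    fitted model predicts their case probabilities. Ties in the deviance
    curve go to the largest penalty (the sparser model).
    """
    if sub.complement.size == 0:
        raise ValueError(
            "complement deviance selection requires a nonempty complement; "
            "use phi < 1"
        )
    values = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X, dtype=float)
    Xc, means = _subsample_design(values, sub)
    y_sub = y.y[sub.indices]
    if grid is None:
        grid = default_grid(lambda_max(Xc, y_sub), grid_size, grid_min_ratio)
    path = fit_lasso_path(Xc, y_sub, grid, column_means=means)
    Xc_comp = values[sub.complement] - means
    y_comp = y.y[sub.complement].astype(float)
    probs = path.predicted_probabilities(Xc_comp)  # grid_length x n_comp
    p = np.clip(probs, 1e-12, 1 - 1e-12)
    curve = -2.0 * (y_comp * np.log(p) + (1 - y_comp) * np.log(1 - p)).sum(axis=1)
    best = int(np.argmin(curve))  # first minimum = largest lambda on ties
    return CdevSelection(lam=float(grid[best]), deviance_curve=curve, grid=grid, path=path)


def _resolve_matrix_for_k(
    X: GenotypeMatrix | np.ndarray | None,
    imputations: Sequence[GenotypeMatrix] | Callable[[int], GenotypeMatrix] | None,
    k: int,
    K: int,
) -> np.ndarray:
    if imputations is not None:
        if callable(imputations):
            Xk = imputations(k)
        else:
            if len(imputations) < K:
                raise ValueError(
                    f"multiple-imputation mode needs >= K={K} sampled matrices, "
                    f"got {len(imputations)}"
                )
            Xk = imputations[k]
        return Xk.values if isinstance(Xk, GenotypeMatrix) else np.asarray(Xk, dtype=float)
    values = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X, dtype=float)
    return values


def _one_subsample(
    values: np.ndarray,
    y: CaseControlResponse,
    k: int,
    phi: float,
    criterion: str,
    S: int,
    seed,
    grid_size: int,
    grid_min_ratio: float,
) -> tuple[np.ndarray, float, object]:
    """Inclusion vector for subsample k. Deterministic given (seed, k)."""
    for attempt in range(MAX_SUBSAMPLE_RETRIES + 1):
        sub = draw_subsample(y, phi, child_rng(seed, k, attempt), k=k)
        y_sub = y.y[sub.indices]
        if y_sub.min() != y_sub.max():
            break
        logger.warning("subsample %d draw %d has constant response; retrying", k, attempt)
    else:
        raise RuntimeError(f"subsample {k}: constant response after retries")

    if criterion == "perm":
        sel = select_lambda_perm(sub, values, y, S, child_rng(seed, k, 0, 1))
        Xc, means = _subsample_design(values, sub)
        grid = default_grid(lambda_max(Xc, y_sub), grid_size, grid_min_ratio)
        if sel.lam > grid[0]:
            # permutation penalty exceeds the subsample's own lambda_max:
            # nothing can be selected
            logger.debug("subsample %d: permutation lambda above lambda_max", k)
            return np.zeros(values.shape[1], dtype=np.int8), sel.lam, sel
        lam_eval = max(sel.lam, grid[-1])  # clamp below the grid floor
        idx = snap_to_grid(grid, lam_eval)
        path = fit_lasso_path(Xc, y_sub, grid, column_means=means, stop_index=idx)
        return active_set(path, lam_eval), sel.lam, sel
    elif criterion == "cdev":
        sel = select_lambda_cdev(
            sub, values, y, grid_size=grid_size, grid_min_ratio=grid_min_ratio
        )
        return active_set(sel.path, sel.lam), sel.lam, sel
    raise ValueError(f"unknown criterion {criterion!r}; use 'perm' or 'cdev'")


def run_llarrma(
    X: GenotypeMatrix | np.ndarray | None,
    y: CaseControlResponse,
    K: int = 100,
    phi: float = 0.5,
    criterion: str = "perm",
    S: int = 25,
    seed: int | np.random.SeedSequence | None = None,
    imputations: Sequence[GenotypeMatrix] | Callable[[int], GenotypeMatrix] | None = None,
    grid_size: int = 100,
    grid_min_ratio: float = 0.001,
    n_jobs: int = 1,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Run the full LLARRMA procedure.

    Returns ``(rmip, gamma, diagnostics)`` where ``gamma`` is the K x m
    binary inclusion matrix and ``rmip`` its column mean. In multiple
    imputation mode, subsample k analyses the k-th sampled imputation.

    Per-subsample randomness comes from counter-based child streams of
    ``seed``: subsample draw k uses key (k, attempt) and its permutations
    key (k, 0, 1), so results are reproducible and the first k subsamples
    do not change when K grows.
    """
    if K < 1:
        raise ValueError("K must be >= 1")

    def work(k: int):
        values = _resolve_matrix_for_k(X, imputations, k, K)
        if np.isnan(values).any():
            raise ValueError("genotype matrix has missing entries; impute first")
        return _one_subsample(
            values, y, k, phi, criterion, S, seed, grid_size, grid_min_ratio
        )

    if n_jobs != 1:
        from joblib import Parallel, delayed

        out = Parallel(n_jobs=n_jobs, prefer="threads")(delayed(work)(k) for k in range(K))
    else:
        out = [work(k) for k in range(K)]

    gamma = np.vstack([row for row, _, _ in out])
    lambdas = np.array([lam for _, lam, _ in out])
    diagnostics = [d for _, _, d in out]
    rmip = gamma.mean(axis=0)
    return rmip, gamma, (lambdas, diagnostics)


class LLARRMA:
    """Model object for LLARRMA on one hit region.

    Parameters
    ----------
    X : GenotypeMatrix or array
        Complete genotypes (raw or dosage), or None when ``imputations``
        supplies the matrices.
    y : CaseControlResponse or binary array
    imputations : sequence of complete GenotypeMatrix, or callable k -> matrix
        Sampled imputations for multiple-imputation mode.
    """

    def __init__(
        self,
        X: GenotypeMatrix | np.ndarray | None,
        y: CaseControlResponse | np.ndarray,
        imputations=None,
        grid_size: int = 100,
        grid_min_ratio: float = 0.001,
    ) -> None:
        self.X = X
        self.y = y if isinstance(y, CaseControlResponse) else CaseControlResponse(y)
        self.imputations = imputations
        self.grid_size = grid_size
        self.grid_min_ratio = grid_min_ratio
        if X is None and imputations is None:
            raise ValueError("supply a genotype matrix or an imputation ensemble")

    @classmethod
    def from_dataframe(cls, genotypes: pd.DataFrame, status: pd.Series, **kwargs) -> "LLARRMA":
        """Build from a samples-by-SNPs DataFrame and a 0/1 status Series."""
        gm = GenotypeMatrix(
            genotypes.to_numpy(dtype=float),
            [str(c) for c in genotypes.columns],
            [str(i) for i in genotypes.index],
        )
        return cls(gm, status.to_numpy(), **kwargs)

    @property
    def snp_ids(self) -> list[str]:
        if isinstance(self.X, GenotypeMatrix):
            return self.X.snp_ids
        if self.imputations is not None and not callable(self.imputations):
            first = self.imputations[0]
            if isinstance(first, GenotypeMatrix):
                return first.snp_ids
        m = self._m()
        return [f"snp{j}" for j in range(m)]

    def _m(self) -> int:
        if self.X is not None:
            v = self.X.values if isinstance(self.X, GenotypeMatrix) else self.X
            return v.shape[1]
        first = self.imputations(0) if callable(self.imputations) else self.imputations[0]
        v = first.values if isinstance(first, GenotypeMatrix) else first
        return v.shape[1]

    def fit(
        self,
        K: int = 100,
        phi: float = 0.5,
        criterion: str = "perm",
        S: int = 25,
        seed: int | None = None,
        n_jobs: int = 1,
    ) -> "LLARRMAResults":
        rmip, gamma, (lambdas, diagnostics) = run_llarrma(
            self.X,
            self.y,
            K=K,
            phi=phi,
            criterion=criterion,
            S=S,
            seed=seed,
            imputations=self.imputations,
            grid_size=self.grid_size,
            grid_min_ratio=self.grid_min_ratio,
            n_jobs=n_jobs,
        )
        return LLARRMAResults(
            model=self,
            rmip=rmip,
            inclusion_matrix=gamma,
            selected_lambdas=lambdas,
            diagnostics=diagnostics,
            K=K,
            phi=phi,
            criterion=criterion,
            S=S,
            seed=seed,
        )


@dataclass
class LLARRMAResults:
    """Fitted LLARRMA run: RMIPs with their resampling provenance."""

    model: LLARRMA
    rmip: np.ndarray
    inclusion_matrix: np.ndarray  # K x m binary Gamma
    selected_lambdas: np.ndarray
    diagnostics: list = field(repr=False, default_factory=list)
    K: int = 0
    phi: float = 0.5
    criterion: str = "perm"
    S: int = 25
    seed: int | None = None

    def to_score_table(self) -> ScoreTable:
        positions = None
        if isinstance(self.model.X, GenotypeMatrix):
            positions = self.model.X.positions
        return ScoreTable(
            snp_ids=self.model.snp_ids,
            score=self.rmip,
            method=f"llarrma-{self.criterion}",
            positions=positions,
            metadata={
                "K": self.K,
                "phi": self.phi,
                "criterion": self.criterion,
                "S": self.S,
                "seed": self.seed,
            },
        )

    def summary(self, top: int | None = 20) -> str:
        """Plain-text summary table of the top-ranked SNPs by RMIP."""
        df = self.to_score_table().to_dataframe().sort_values("rank")
        if top is not None:
            df = df.head(top)
        header = (
            f"LLARRMA ({self.criterion} selection)  "
            f"K={self.K} phi={self.phi} S={self.S} seed={self.seed}\n"
            f"{'snp_id':<16}{'RMIP':>8}{'rank':>6}\n"
        )
        lines = [
            f"{row.snp_id:<16}{row.score:>8.3f}{row.rank:>6d}"
            for row in df.itertuples()
        ]
        return header + "\n".join(lines)

    def plot(self, ax=None, truth: np.ndarray | None = None):
        """RMIP against SNP index; true signals highlighted when given."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.rmip.size
        ax.scatter(np.arange(m), self.rmip, s=12, color="0.5", label="background")
        if truth is not None:
            tr = np.asarray(truth, dtype=bool)
            ax.scatter(np.flatnonzero(tr), self.rmip[tr], s=28, marker="x", color="k",
                       label="true signal")
            ax.legend(frameon=False)
        ax.set_xlabel("SNP index")
        ax.set_ylabel("RMIP")
        ax.set_ylim(-0.02, 1.02)
        return ax
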