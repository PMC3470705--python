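"""ROC-based evaluation of SNP reprioritization methods.

Each simulation trial scores m SNPs of which q are true signals. Power at
threshold t is the fraction of true signals scoring >= t; the false
positive rate (FPR) is the fraction of background SNPs scoring >= t.
Sweeping t over the distinct scores traces an ROC curve, integrated with
the trapezium rule. The "initial AUC" restricts the FPR to [0, 0.05] --
enrichment among the top-ranked SNPs, the quantity that matters when only
a handful of SNPs can be followed up -- and the "full AUC" uses [0, 1].
Windowed AUCs are normalized by the window width so both live on [0, 1].

Curves averaged over trials use threshold averaging: at each threshold the
mean FPR and mean power across trials are plotted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CaseControlResponse, GenotypeMatrix

logger = logging.getLogger("llarrma")

INITIAL_WINDOW = (0.0, 0.05)
FULL_WINDOW = (0.0, 1.0)


@dataclass
class TrialResult:
    """Scores and ground truth for one simulated trial of one method."""

    scores: np.ndarray
    truth: np.ndarray
    method: str = ""
    trial_id: int = 0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.truth = np.asarray(self.truth).astype(bool)
        if self.scores.shape != self.truth.shape:
            raise ValueError("scores and truth must have the same length")
        if not self.truth.any() or self.truth.all():
            raise ValueError("truth needs at least one signal and one background SNP")


def power_fpr(trial: TrialResult, t: float) -> tuple[float, float]:
    """(power, FPR) when declaring SNPs with score >= t."""
    q = trial.truth.sum()
    hits = trial.scores >= t
    power = float(hits[trial.truth].sum() / q)
    fpr = float(hits[~trial.truth].sum() / (trial.truth.size - q))
    return power, fpr


def roc_points(trial: TrialResult) -> tuple[np.ndarray, np.ndarray]:
    """ROC step-curve vertices (fpr, power), from (0,0) to (1,1).

    Thresholds sweep the distinct scores in descending order; tied scores
    enter the curve together, producing diagonal segments; runs of equal
    FPR are vertical segments (zero width under the trapezium rule).
    """
    thresholds = np.unique(trial.scores)[::-1]
    q = int(trial.truth.sum())
    bg = trial.truth.size - q
    sig_scores = trial.scores[trial.truth]
    bg_scores = trial.scores[~trial.truth]
    power = np.array([(sig_scores >= t).sum() / q for t in thresholds])
    fpr = np.array([(bg_scores >= t).sum() / bg for t in thresholds])
    fpr = np.concatenate([[0.0], fpr])
    power = np.concatenate([[0.0], power])
    if fpr[-1] != 1.0 or power[-1] != 1.0:
        fpr = np.concatenate([fpr, [1.0]])
        power = np.concatenate([power, [1.0]])
    return fpr, power


def _power_at(fpr: np.ndarray, power: np.ndarray, x: float, side: str) -> float:
    """Power of the ROC polyline at FPR = x.

    At a vertex with a vertical segment the curve is set-valued: the left
    edge of a window uses the value leaving the vertex (top), the right
    edge the value entering it (bottom).
    """
    exact = fpr == x
    if exact.any():
        return float(power[exact].max() if side == "left" else power[exact].min())
    # strictly inside a segment: interpolate between the last point at the
    # lower vertex and the first point at the upper vertex
    hi = int(np.searchsorted(fpr, x))  # first index with fpr > x
    lo = hi - 1
    x0, x1 = fpr[lo], fpr[hi]
    y0, y1 = power[lo], power[hi]
    return float(y0 + (y1 - y0) * (x - x0) / (x1 - x0))


def trial_auc(trial: TrialResult, a: float = 0.0, b: float = 1.0) -> float:
    """Trapezium-rule AUC over the FPR window [a, b], normalized by b - a.

    Power at the window edges is linearly interpolated on the ROC polyline.
    Over [0, 1] this equals the tie-corrected Mann-Whitney statistic
    divided by q * (m - q).
    """
    if not 0 <= a < b <= 1:
        raise ValueError("need 0 <= a < b <= 1")
    fpr, power = roc_points(trial)
    inside = (fpr > a) & (fpr < b)
    xs = np.concatenate([[a], fpr[inside], [b]])
    ys = np.concatenate(
        [[_power_at(fpr, power, a, "left")], power[inside], [_power_at(fpr, power, b, "right")]]
    )
    return float(np.trapezoid(ys, xs) / (b - a))


@dataclass
class ROCSummary:
    """Cross-trial AUC aggregate for one method on one FPR window."""

    method: str
    window: tuple[float, float]
    per_trial_auc: np.ndarray
    mean_auc: float = field(init=False)
    variance_of_mean: float = field(init=False)

    def __post_init__(self) -> None:
        self.per_trial_auc = np.asarray(self.per_trial_auc, dtype=float)
        if self.per_trial_auc.size < 2:
            raise ValueError("need at least 2 trials to estimate a variance")
        self.mean_auc = float(self.per_trial_auc.mean())
        # cross-trial variance / trial count (normal approximation)
        self.variance_of_mean = float(
            self.per_trial_auc.var() / self.per_trial_auc.size
        )

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        """Normal-approximation confidence interval for the mean AUC."""
        from scipy.stats import norm

        half = norm.ppf(0.5 + level / 2) * np.sqrt(self.variance_of_mean)
        return self.mean_auc - half, self.mean_auc + half


def summarize(trials: list[TrialResult], a: float = 0.0, b: float = 1.0) -> ROCSummary:
    """Mean windowed AUC across trials, with variance of the mean."""
    if len(trials) < 2:
        raise ValueError("need at least 2 trials")
    aucs = np.array([trial_auc(tr, a, b) for tr in trials])
    method = trials[0].method
    return ROCSummary(method=method, window=(a, b), per_trial_auc=aucs)


def threshold_average(trials: list[TrialResult], thresholds: np.ndarray) -> np.ndarray:
    """Threshold-averaged ROC curve: rows of (mean FPR, mean power) per t."""
    pts = np.empty((len(thresholds), 2))
    for i, t in enumerate(thresholds):
        pf = np.array([power_fpr(tr, t) for tr in trials])
        pts[i] = pf[:, 1].mean(), pf[:, 0].mean()
    return pts


@dataclass
class StudyConfig:
    """Configuration of a simulation study comparing scoring methods."""

    scenario: str = "study2"  # study1A | study1B | study2
    q: int = 5  # number of true signals (study2 only)
    methods: tuple = ("single-locus", "llarrma-perm")
    replicates: int = 10
    K: int = 100
    phi: float = 0.5
    S: int = 25
    grid_size: int = 100
    grid_min_ratio: float = 0.001
    imputation: str = "complete"  # complete | hard | dosage | multiple
    seed: int | None = None
    n: int | None = None  # dataset size overrides, mainly for quick runs
    m: int | None = None
    n_jobs: int = 1


def _method_scores(
    method: str,
    X: GenotypeMatrix,
    y: CaseControlResponse,
    truth: np.ndarray,
    cfg: StudyConfig,
    seed,
    imputations=None,
) -> np.ndarray:
    from .competitors import SingleLocus, StabilitySelection
    from .engine import LLARRMA

    if method == "single-locus":
        return SingleLocus(X, y).fit().logp
    if method in ("llarrma-perm", "llarrma-cdev"):
        criterion = method.split("-")[1]
        res = LLARRMA(X if imputations is None else None, y, imputations=imputations,
                      grid_size=cfg.grid_size, grid_min_ratio=cfg.grid_min_ratio).fit(
            K=cfg.K, phi=cfg.phi, criterion=criterion, S=cfg.S, seed=seed,
            n_jobs=cfg.n_jobs,
        )
        return res.rmip
    if method == "ss-oracle":
        res = StabilitySelection(X if imputations is None else None, y,
                                 imputations=imputations, grid_size=cfg.grid_size,
                                 grid_min_ratio=cfg.grid_min_ratio).fit(
            K=cfg.K, phi=cfg.phi, seed=seed, n_jobs=cfg.n_jobs,
        )
        return res.oracle(truth).rmip
    raise ValueError(f"unknown method {method!r}")


def run_study(config: StudyConfig) -> tuple[pd.DataFrame, dict[str, list[TrialResult]]]:
    """Simulate, analyze and score `replicates` trials for each method.

    Returns a tidy summary table (method, window, mean AUC, variance of the
    mean, replicate count, seed) and the per-method trial results. Failed
    trials are logged and skipped; more than 10% failures aborts the study.
    """
    from . import simulate as sim
    from .impute import dosage_impute, hard_impute, naive_posterior, sample_imputation
    from .resampling import child_rng

    trials: dict[str, list[TrialResult]] = {meth: [] for meth in config.methods}
    failures = 0
    for s in range(config.replicates):
        trial_seed = np.random.SeedSequence(config.seed, spawn_key=(1000 + s,))
        try:
            ds = sim.simulate_study(
                config.scenario, q=config.q, seed=trial_seed, n=config.n, m=config.m
            )
            X_analysis = ds.genotypes
            imputations = None
            if config.imputation != "complete":
                rng = child_rng(trial_seed, 77)
                incomplete, _ = sim.generate_missingness(
                    ds.genotypes, sim.MissingnessSpec(), rng
                )
                post = naive_posterior(incomplete)
                if config.imputation == "hard":
                    X_analysis = hard_impute(incomplete, post)
                elif config.imputation == "dosage":
                    X_analysis = dosage_impute(incomplete, post)
                elif config.imputation == "multiple":
                    X_analysis = hard_impute(incomplete, post)  # for single-locus
                    imputations = [
                        sample_imputation(incomplete, post, child_rng(trial_seed, 78, k))
                        for k in range(config.K)
                    ]
                else:
                    raise ValueError(f"unknown imputation mode {config.imputation!r}")
            for meth in config.methods:
                scores = _method_scores(
                    meth, X_analysis, ds.response, ds.truth, config,
                    seed=np.random.SeedSequence(config.seed, spawn_key=(2000 + s,)),
                    imputations=imputations if meth != "single-locus" else None,
                )
                trials[meth].append(
                    TrialResult(scores=scores, truth=ds.truth, method=meth, trial_id=s)
                )
        except Exception:  # noqa: BLE001 - a bad draw must not kill the study
            failures += 1
            logger.exception("trial %d failed (seed %s)", s, config.seed)
            if failures > 0.1 * config.replicates:
                raise RuntimeError(
                    f"{failures} of {config.replicates} trials failed; aborting"
                )

    rows = []
    for meth, trs in trials.items():
        for window in (INITIAL_WINDOW, FULL_WINDOW):
            summ = summarize(trs, *window)
            rows.append(
                {
                    "method": meth,
                    "imputation": config.imputation,
                    "window": "initial" if window == INITIAL_WINDOW else "full",
                    "mean_auc": summ.mean_auc,
                    "variance_of_mean": summ.variance_of_mean,
                    "replicates": len(trs),
                    "seed": config.seed,
                }
            )
    return pd.DataFrame(rows), trials
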