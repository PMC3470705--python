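"""Core data containers for hit-region case-control analysis.

The central objects are a :class:`GenotypeMatrix` (an ``n x m`` additive-coded
SNP matrix with an explicit missingness mask), a :class:`CaseControlResponse`
(binary phenotype), and a :class:`ScoreTable` (per-SNP scores produced by any
of the scoring methods, e.g. RMIPs or -log10 P-values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GenotypeMatrix:
    """Additive-coded SNP genotypes for one hit region.

    Parameters
    ----------
    values : ndarray, shape (n, m)
        Allele counts. Raw genotypes are in {0, 1, 2}; dosage (expected
        allele count) matrices may hold fractional values in [0, 2].
        Missing entries are ``np.nan``.
    snp_ids : sequence of str
        Unique SNP labels, one per column, in file/physical order.
    sample_ids : sequence of str
        Unique individual labels, one per row.
    positions : ndarray or None
        Optional 1-based base-pair coordinates, one per SNP.
    """

    values: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D array")
        n, m = self.values.shape
        if n < 2 or m < 1:
            raise ValueError(f"need at least 2 samples and 1 SNP, got {n} x {m}")
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.snp_ids) != m:
            raise ValueError("snp_ids length does not match number of columns")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")
        if len(set(self.snp_ids)) != m:
            raise ValueError("snp_ids must be unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("non-missing genotype values must lie in [0, 2]")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=np.int64)
            if self.positions.shape != (m,):
                raise ValueError("positions length does not match number of SNPs")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean n x m array, True where the genotype is missing."""
        return np.isnan(self.values)

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.values.copy(),
            list(self.snp_ids),
            list(self.sample_ids),
            None if self.positions is None else self.positions.copy(),
        )


@dataclass
class CaseControlResponse:
    """Binary phenotype vector: cases coded 1, controls coded 0."""

    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if self.y.ndim != 1:
            raise ValueError("response must be a 1-D vector")
        uniq = set(np.unique(self.y).tolist())
        if not uniq <= {0, 1}:
            raise ValueError(f"response values must be 0/1, got {sorted(uniq)}")
        self.y = self.y.astype(np.int8)
        if self.n1 < 1 or self.n0 < 1:
            raise ValueError("need at least one case and one control")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def n1(self) -> int:
        return int(self.y.sum())

    @property
    def n0(self) -> int:
        return int(self.y.size - self.y.sum())


@dataclass
class ScoreTable:
    """Per-SNP scores from one method on one dataset.

    ``score`` is either an RMIP in [0, 1] or a -log10 P-value in [0, inf).
    ``metadata`` records the run configuration (K, phi, criterion, seed, ...).
    """

    snp_ids: list[str]
    score: np.ndarray
    method: str
    positions: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if len(self.snp_ids) != self.score.size:
            raise ValueError("one score per SNP required")

    def ranks(self) -> np.ndarray:
        """Rank 1 = best (highest) score; ties share the minimum rank."""
        s = pd.Series(self.score)
        return s.rank(ascending=False, method="min").to_numpy(dtype=np.int64)

    def to_dataframe(self) -> pd.DataFrame:
        pos = self.positions if self.positions is not None else np.full(len(self.snp_ids), -1)
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "position": pos,
                "score": self.score,
                "method": self.method,
                "rank": self.ranks(),
            }
        )


@dataclass
class GenotypePosterior:
    """Posterior genotype probabilities for the missing entries of a matrix.

    For each missing entry (i, j) a probability triple (p0, p1, p2) over the
    genotypes {0, 1, 2}. Triples are renormalized to sum to one.
    """

    rows: np.ndarray
    cols: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int64)
        self.cols = np.asarray(self.cols, dtype=np.int64)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 3:
            raise ValueError("probs must have shape (k, 3)")
        if not (self.rows.size == self.cols.size == self.probs.shape[0]):
            raise ValueError("rows, cols and probs must have matching lengths")
        if (self.probs < 0).any():
            bad = np.argwhere(self.probs < 0)[0]
            raise ValueError(f"negative posterior probability at entry {bad[0]}")
        totals = self.probs.sum(axis=1)
        if (totals <= 0).any():
            bad = int(np.argmin(totals))
            raise ValueError(
                f"posterior triple sums to zero for entry ({self.rows[bad]}, {self.cols[bad]})"
            )
        self.probs = self.probs / totals[:, None]

    def __len__(self) -> int:
        return self.probs.shape[0]

    def index_lookup(self) -> dict[tuple[int, int], int]:
        return {(int(r), int(c)): k for k, (r, c) in enumerate(zip(self.rows, self.cols))}
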