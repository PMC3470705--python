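"""Stratified subsampling and response permutation.

Subsamples are drawn without replacement, separately from cases and
controls, so every subsample preserves the case-control balance of the full
data up to ceiling rounding. Per-subsample random streams are derived from
one master seed by counter-based splitting, so subsample k is reproducible
and independent of how many subsamples are drawn in total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .containers import CaseControlResponse


def child_rng(seed: int | np.random.SeedSequence | None, *key: int) -> np.random.Generator:
    """Independent stream keyed by (seed, *key); stable under changes of K."""
    if isinstance(seed, np.random.SeedSequence):
        base_key = tuple(seed.spawn_key) + key
        ss = np.random.SeedSequence(seed.entropy, spawn_key=base_key)
    else:
        ss = np.random.SeedSequence(seed, spawn_key=key)
    return np.random.default_rng(ss)


@dataclass
class Subsample:
    """One stratified subsample of a case-control study."""

    indices: np.ndarray  # selected rows, cases then controls
    complement: np.ndarray  # all remaining rows
    k: int  # subsample number

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.complement = np.asarray(self.complement, dtype=np.int64)


def draw_subsample(
    y: CaseControlResponse, phi: float, rng: np.random.Generator, k: int = 0
) -> Subsample:
    """Draw ceil(phi*n1) cases and ceil(phi*n0) controls without replacement.

    The complement holds every individual not selected; it is empty when
    phi = 1.
    """
    if not 0 < phi <= 1:
        raise ValueError(f"subsampling proportion must be in (0, 1], got {phi}")
    case_idx = np.flatnonzero(y.y == 1)
    ctrl_idx = np.flatnonzero(y.y == 0)
    k1 = math.ceil(phi * y.n1)
    k0 = math.ceil(phi * y.n0)
    chosen = np.concatenate(
        [
            rng.choice(case_idx, size=k1, replace=False),
            rng.choice(ctrl_idx, size=k0, replace=False),
        ]
    )
    in_sub = np.zeros(y.n, dtype=bool)
    in_sub[chosen] = True
    return Subsample(indices=chosen, complement=np.flatnonzero(~in_sub), k=k)


def permute_response(y_vec: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of the response vector."""
    return rng.permutation(np.asarray(y_vec))
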