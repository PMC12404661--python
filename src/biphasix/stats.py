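"""Exact small-sample nonparametric tests and FDR correction.

The assay comparisons in this design have 4–6 replicates per group, where
asymptotic rank tests are unreliable; the tests here enumerate the full
permutation (or sign-assignment) distribution conditional on the observed
tie pattern and report exact two-sided p-values.

Conventions match the small printed statistics of the field:

* Mann–Whitney U is reported as ``min(U_x, U_y)`` with mid-ranks for ties;
  the two-sided p-value is the exact probability, over all C(n1+n2, n1)
  group labelings of the pooled sample, of a U at least as extreme (as
  small) as observed.
* The paired comparison is the exact Wilcoxon signed-rank test — the
  standard paired analogue of the U test — whose statistic V is the smaller
  signed-rank sum over nonzero differences, with the two-sided p from all
  2^n sign assignments.  (Six uniformly signed pairs give V = 0,
  p = 2/64 ≈ .03.)
* Benjamini–Hochberg step-up adjustment for multiplicity.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from functools import lru_cache
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "mann_whitney_exact",
    "wilcoxon_signed_rank_exact",
    "bh_fdr",
]

logger = logging.getLogger(__name__)

#: largest combined sample size for exact enumeration
EXACT_LIMIT = 20


@dataclasses.dataclass
class TestResult:
    comparison_id: str
    statistic_name: str  # "U" or "V"
    statistic: float
    p_value: float
    n1: int
    n2: int
    p_adjusted: Optional[float] = None
    exact: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must lie in (0, 1], got {self.p_value}")
        if self.p_adjusted is not None and self.p_adjusted < self.p_value:
            raise ValueError("adjusted p cannot be below the raw p")


@lru_cache(maxsize=4096)
def _u_min_distribution(ranks: Tuple[float, ...], n1: int) -> Tuple[np.ndarray, int]:
    """Sorted values of min(U_x, U_y) over all labelings of the pooled
    mid-ranks; cached per tie pattern."""
    n = len(ranks)
    n2 = n - n1
    arr = np.asarray(ranks)
    offset = n1 * (n1 + 1) / 2.0
    us = []
    for idx in itertools.combinations(range(n), n1):
        u1 = arr[list(idx)].sum() - offset
        us.append(min(u1, n1 * n2 - u1))
    out = np.sort(np.asarray(us))
    return out, len(us)


def mann_whitney_exact(
    x: Sequence[float], y: Sequence[float], comparison_id: str = ""
) -> TestResult:
    """Exact two-sided Mann–Whitney U test.

    U = min(U_x, U_y) with mid-rank tie handling; the p-value enumerates the
    permutation distribution conditional on the observed (possibly tied)
    pooled sample.  Combined sizes above 20 fall back to the normal
    approximation with tie correction (logged).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    u = min(u1, n1 * n2 - u1)
    if n1 + n2 <= EXACT_LIMIT:
        dist, total = _u_min_distribution(tuple(ranks.tolist()), n1)
        p = float(np.searchsorted(dist, u + 1e-9, side="left")) / total
        exact = True
    else:
        logger.info(
            "combined size %d > %d: normal approximation for Mann-Whitney",
            n1 + n2,
            EXACT_LIMIT,
        )
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts**3 - counts).sum() / ((n * (n - 1)) if n > 1 else 1.0)
        var = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if var == 0:
            p = 1.0
        else:
            z = (u - mu + 0.5) / math.sqrt(var)  # continuity-corrected
            p = min(1.0, 2.0 * norm.cdf(z))
        exact = False
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return TestResult(
        comparison_id=comparison_id,
        statistic_name="U",
        statistic=float(u),
        p_value=p,
        n1=n1,
        n2=n2,
        exact=exact,
    )


def _signed_rank_min_sums(ranks: np.ndarray) -> np.ndarray:
    """min(S, total-S) over all sign assignments, enumerated in chunks."""
    n = len(ranks)
    total = ranks.sum()
    out = np.empty(2**n)
    chunk_bits = min(n, 16)
    base = np.arange(2**chunk_bits, dtype=np.int64)
    bit_matrix = ((base[:, None] >> np.arange(chunk_bits)) & 1).astype(float)
    lo_sums = bit_matrix @ ranks[:chunk_bits]
    if n <= 16:
        sums = lo_sums
        out = np.minimum(sums, total - sums)
    else:
        hi_bits = n - chunk_bits
        hi_base = np.arange(2**hi_bits, dtype=np.int64)
        hi_matrix = ((hi_base[:, None] >> np.arange(hi_bits)) & 1).astype(float)
        hi_sums = hi_matrix @ ranks[chunk_bits:]
        for j, hs in enumerate(hi_sums):
            sums = lo_sums + hs
            out[j * 2**chunk_bits : (j + 1) * 2**chunk_bits] = np.minimum(
                sums, total - sums
            )
    return out


def wilcoxon_signed_rank_exact(
    paired_x: Sequence[float], paired_y: Sequence[float], comparison_id: str = ""
) -> TestResult:
    """Exact two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; V is the smaller of the positive and
    negative mid-rank sums; the p-value enumerates all 2^n sign patterns of
    the remaining differences (normal approximation beyond n = 20, logged).
    All-zero differences give V = 0, p = 1 (no evidence either way).
    """
    x = np.asarray(list(paired_x), dtype=float)
    y = np.asarray(list(paired_y), dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal lengths")
    if len(x) == 0:
        raise ValueError("paired samples must be nonempty")
    n_pairs = len(x)
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult(
            comparison_id=comparison_id,
            statistic_name="V",
            statistic=0.0,
            p_value=1.0,
            n1=n_pairs,
            n2=n_pairs,
        )
    ranks = rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    total = ranks.sum()
    v = min(w_pos, total - w_pos)
    if n <= EXACT_LIMIT:
        dist = _signed_rank_min_sums(ranks)
        p = float((dist <= v + 1e-9).mean())
        exact = True
    else:
        logger.info("n = %d > %d: normal approximation for signed-rank", n, EXACT_LIMIT)
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
        z = (v - mu + 0.5) / math.sqrt(var)
        p = min(1.0, 2.0 * norm.cdf(z))
        exact = False
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return TestResult(
        comparison_id=comparison_id,
        statistic_name="V",
        statistic=float(v),
        p_value=p,
        n1=n_pairs,
        n2=n_pairs,
        exact=exact,
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
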