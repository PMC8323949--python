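"""Shared-gene tabulation and exact intersection statistics.

Overlaps between ranked gene lists are scored against the null in which each
list is an independent uniform draw of its size from a finite universe.  For
two lists that null is hypergeometric; for n lists the distribution of the
size of the common intersection is built by chaining hypergeometric
conditionals (the intersection of the first i sets is itself a uniform random
subset given its size).  All tail sums run in log space so P-values far below
the double-precision underflow threshold remain meaningful.

Universe-size conventions: within one expression matrix, use the number of
genes analyzed in that matrix; when the lists come from different studies, a
generic transcriptome universe of 20,000 genes is conventional.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

__all__ = [
    "IntersectionProblem",
    "IntersectionResult",
    "shared_genes",
    "hypergeometric_overlap",
    "multiset_intersection_pvalue",
    "multiset_mc_oracle",
]


@dataclass(frozen=True)
class IntersectionProblem:
    """Universe size N, set sizes m_1..m_n, observed n-way overlap x."""

    universe: int
    sizes: tuple[int, ...]
    overlap: int

    def __post_init__(self) -> None:
        if self.universe < 1:
            raise ValueError("universe must be >= 1")
        if len(self.sizes) < 2:
            raise ValueError("need at least two sets")
        for m in self.sizes:
            if not 0 <= m <= self.universe:
                raise ValueError(f"set size {m} outside [0, {self.universe}]")
        if not 0 <= self.overlap <= min(self.sizes):
            raise ValueError("overlap must lie in [0, min set size]")


@dataclass(frozen=True)
class IntersectionResult:
    problem: IntersectionProblem
    p_value: float
    log10_p: float
    method: str
    std_error: float | None = None


def shared_genes(
    lists: list[list[str]], k_top: int, min_count: int
) -> dict[str, int]:
    """Genes present in at least ``min_count`` of the truncated lists.

    Each list is truncated to its top ``k_top`` entries, occurrences counted
    (at most once per list), and genes with count >= ``min_count`` returned
    with their counts.
    """
    if k_top < 1:
        raise ValueError("k_top must be >= 1")
    if not lists or any(len(lst) == 0 for lst in lists):
        raise ValueError("lists must be non-empty")
    counts: Counter[str] = Counter()
    for lst in lists:
        counts.update(set(lst[:k_top]))
    return {g: c for g, c in counts.items() if c >= min_count}


def _log_tail(logpmf: np.ndarray, x: int) -> float:
    """log of sum of pmf over support indices >= x (indices align with values)."""
    if x >= len(logpmf):
        return -np.inf
    return float(logsumexp(logpmf[x:]))


def hypergeometric_overlap(
    m1: int, m2: int, x: int, N: int
) -> IntersectionResult:
    """Upper-tail hypergeometric P(X >= x) for the overlap of two random sets.

    Computed by summing log-pmf terms, not via the survival function, so the
    extreme tails (P ~ 1e-33 and far below) keep full relative accuracy.
    """
    problem = IntersectionProblem(universe=N, sizes=(m1, m2), overlap=x)
    support = np.arange(0, min(m1, m2) + 1)
    logpmf = hypergeom.logpmf(support, N, m1, m2)
    logp = min(_log_tail(logpmf, x), 0.0)
    p = float(np.exp(logp))
    return IntersectionResult(
        problem=problem,
        p_value=p,
        log10_p=float(logp / np.log(10)),
        method="hypergeometric",
    )


def multiset_intersection_pvalue(problem: IntersectionProblem) -> IntersectionResult:
    """Exact P(X_n >= x) for the n-way intersection of uniform random sets.

    Dynamic programming over the intersection size: X_2 ~ Hypergeom(N, m1, m2)
    and, given the first i-1 sets intersect in j elements, intersecting with
    the i-th set gives X_i | X_{i-1}=j ~ Hypergeom(N, j, m_i).  All
    convolutions are performed on log probabilities.
    """
    N = problem.universe
    sizes = problem.sizes
    max_j = min(sizes[0], sizes[1])
    support = np.arange(0, max_j + 1)
    log_dist = hypergeom.logpmf(support, N, sizes[0], sizes[1])
    for m in sizes[2:]:
        new_max = min(max_j, m)
        new = np.full(new_max + 1, -np.inf)
        for j in range(max_j + 1):
            if log_dist[j] == -np.inf:
                continue
            ks = np.arange(0, min(j, m) + 1)
            terms = hypergeom.logpmf(ks, N, j, m) + log_dist[j]
            new[ks] = np.logaddexp(new[ks], terms)
        log_dist = new
        max_j = new_max
    logp = min(_log_tail(log_dist, problem.overlap), 0.0)
    return IntersectionResult(
        problem=problem,
        p_value=float(np.exp(logp)),
        log10_p=float(logp / np.log(10)),
        method="exact-dp",
    )


def multiset_mc_oracle(
    problem: IntersectionProblem, reps: int, seed: int
) -> IntersectionResult:
    """Monte-Carlo estimate of the same tail probability, with standard error.

    Draws ``reps`` tuples of uniform random subsets of the stated sizes and
    counts how often their common intersection reaches the observed overlap.
    """
    if reps < 1000:
        raise ValueError("reps must be >= 1000")
    rng = np.random.default_rng(seed)
    N = problem.universe
    common = np.ones((reps, N), dtype=bool)
    for m in problem.sizes:
        if m == 0:
            common[:] = False
            continue
        # uniform m-subsets: take the m smallest of N iid uniforms per rep
        keys = rng.random((reps, N))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        member = np.zeros((reps, N), dtype=bool)
        np.put_along_axis(member, idx, True, axis=1)
        common &= member
    hits = int((common.sum(axis=1) >= problem.overlap).sum())
    p = hits / reps
    se = float(np.sqrt(max(p * (1 - p), 1e-300) / reps))
    return IntersectionResult(
        problem=problem,
        p_value=p,
        log10_p=float(np.log10(p)) if p > 0 else -np.inf,
        method="monte-carlo",
        std_error=se,
    )
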