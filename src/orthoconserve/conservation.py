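"""Conservation-level comparisons against a reference and random sets.

The focal set's conservation proportion is compared two ways: against a
published genome-wide reference count (with the focal genes removed from
the reference so the two samples are independent), and against seeded
random gene sets of the same size drawn from the gene universe.  Both
comparisons run through the expected-count dispatch rule of
:mod:`orthoconserve.contingency`.  A z-score places the focal count
within the pooled distribution of all counts (random sets plus focal,
sample standard deviation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .contingency import ContingencyResult, select_test
from .exceptions import DegenerateDistributionError, ValidationError

__all__ = [
    "RandomSetConfig",
    "sample_random_sets",
    "pairwise_set_comparison",
    "zscore_outlier",
    "reference_comparison",
]


@dataclass(frozen=True)
class RandomSetConfig:
    universe: tuple[str, ...]
    seed: int
    n_sets: int = 10
    set_size: int = 69
    exclude: frozenset[str] = frozenset()

    def __post_init__(self):
        pool = len(set(self.universe) - self.exclude)
        if self.set_size > pool:
            raise ValidationError(
                f"set_size {self.set_size} exceeds available pool of {pool} genes"
            )


def sample_random_sets(config: RandomSetConfig) -> list[frozenset[str]]:
    """Draw ``n_sets`` gene sets of ``set_size`` without replacement.

    Sampling is uniform over universe minus exclusions; sets are drawn
    independently of one another (a gene may recur across sets, mirroring
    independent generator runs) and reproducibly for a fixed seed.
    """
    pool = np.array(sorted(set(config.universe) - config.exclude))
    rng = np.random.default_rng(config.seed)
    return [
        frozenset(rng.choice(pool, size=config.set_size, replace=False))
        for _ in range(config.n_sets)
    ]


def _check_counts(k: int, n: int, label: str) -> None:
    if not 0 <= k <= n:
        raise ValidationError(f"{label}: conserved count {k} outside [0, {n}]")


def pairwise_set_comparison(
    focal: tuple[int, int],
    randoms: Sequence[tuple[int, int]],
    threshold: float = 10.0,
) -> list[ContingencyResult]:
    """Compare the focal conservation count against each random set.

    Per random set i the table [[k_i, n_i - k_i], [k, n - k]] (random set
    as the reference row, focal second) goes through the dispatch rule.
    """
    k, n = focal
    _check_counts(k, n, "focal")
    results = []
    for i, (ki, ni) in enumerate(randoms):
        _check_counts(ki, ni, f"random set {i + 1}")
        results.append(select_test([[ki, ni - ki], [k, n - k]], threshold=threshold))
    return results


def zscore_outlier(all_counts: Sequence[float], focal_count: float) -> float:
    """z-score of the focal count within the pooled count distribution.

    ``all_counts`` must already include the focal count; the denominator
    is the sample (n-1) standard deviation.
    """
    counts = np.asarray(all_counts, dtype=float)
    if counts.size < 3:
        raise ValidationError("z-score needs at least 3 counts")
    sd = counts.std(ddof=1)
    if sd == 0:
        raise DegenerateDistributionError("zero variance in count distribution")
    return float((focal_count - counts.mean()) / sd)


def reference_comparison(
    focal: tuple[int, int],
    reference: tuple[int, int],
    remove_overlap: bool = True,
    threshold: float = 10.0,
) -> ContingencyResult:
    """Compare focal conservation against a genome-wide reference count.

    With ``remove_overlap`` the focal genes are subtracted from the
    reference before testing, all focal-conserved genes being assumed to
    lie in the reference's conserved stratum: the adjusted reference is
    (K - k conserved, (N - n) - (K - k) non-conserved).
    """
    k, n = focal
    K, N = reference
    _check_counts(k, n, "focal")
    _check_counts(K, N, "reference")
    if remove_overlap:
        K_adj, N_adj = K - k, N - n
        if K_adj < 0 or N_adj - K_adj < 0:
            raise ValidationError("overlap removal produced negative reference counts")
    else:
        K_adj, N_adj = K, N
    return select_test([[K_adj, N_adj - K_adj], [k, n - k]], threshold=threshold)
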