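"""Permutation test for tissue differences in mean circular-to-linear ratio.

The test works on ratio lists pooled across a tissue's biological
replicates.  To adjust for unequal dataset sizes the larger group is
randomly subsampled (without replacement) to the smaller group's size; a
Monte-Carlo permutation test on the group labels is run for each
subsample, and the procedure is repeated over many subsamples.  P-values
use the add-one smoothing (1 + #{extreme}) / (n_permutations + 1) so a
finite run never reports zero, and the subsample p-values are aggregated
by their median (the full distribution is also returned).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class PermutationConfig:
    n_permutations: int = 1000
    n_subsamples: int = 1000
    seed: Optional[int] = None
    alternative: str = "two_sided"  # or 'greater' (mean(a) > mean(b))
    use_log: bool = False           # compare means of log-ratios instead

    def __post_init__(self) -> None:
        if self.n_permutations < 1 or self.n_subsamples < 1:
            raise ValueError("n_permutations and n_subsamples must be ≥ 1")
        if self.alternative not in ("two_sided", "greater"):
            raise ValueError("alternative must be 'two_sided' or 'greater'")


@dataclass
class PermutationResult:
    observed_stat: float            # mean(a) − mean(b) on the full pooled data
    p_per_subsample: list[float] = field(default_factory=list)
    p_aggregate: float = 1.0        # median of p_per_subsample
    n_a: int = 0                    # group sizes after subsampling
    n_b: int = 0


def _mc_pvalue(
    a: np.ndarray, b: np.ndarray, n_perm: int, alternative: str,
    rng: np.random.Generator,
) -> float:
    pooled = np.concatenate([a, b])
    n = len(a)
    obs = a.mean() - b.mean()
    mat = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    null = mat[:, :n].mean(axis=1) - mat[:, n:].mean(axis=1)
    eps = 1e-12 * max(1.0, abs(obs))
    if alternative == "two_sided":
        hits = int(np.count_nonzero(np.abs(null) >= abs(obs) - eps))
    else:
        hits = int(np.count_nonzero(null >= obs - eps))
    return (1 + hits) / (n_perm + 1)


def permutation_test(
    ratios_a: Sequence[float],
    ratios_b: Sequence[float],
    cfg: Optional[PermutationConfig] = None,
) -> PermutationResult:
    """Subsampled Monte-Carlo permutation test on the difference of means.

    For each subsample the larger group is downsampled without replacement
    to the smaller group's size, the statistic T = mean(a) − mean(b) is
    computed, and a permutation null is built by relabeling the pooled
    values ``n_permutations`` times.  The aggregate p-value is the median
    over subsamples.
    """
    cfg = cfg or PermutationConfig()
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both ratio lists must be non-empty")
    if cfg.use_log:
        a, b = np.log(a), np.log(b)
    rng = np.random.default_rng(cfg.seed)
    n = min(a.size, b.size)
    ps = []
    for _ in range(cfg.n_subsamples):
        a_s = a if a.size == n else rng.choice(a, size=n, replace=False)
        b_s = b if b.size == n else rng.choice(b, size=n, replace=False)
        ps.append(_mc_pvalue(a_s, b_s, cfg.n_permutations, cfg.alternative, rng))
    return PermutationResult(
        observed_stat=float(a.mean() - b.mean()),
        p_per_subsample=ps,
        p_aggregate=float(np.median(ps)),
        n_a=n,
        n_b=n,
    )


def exhaustive_permutation_p(
    ratios_a: Sequence[float],
    ratios_b: Sequence[float],
    alternative: str = "two_sided",
) -> float:
    """Exact permutation p by complete enumeration (small groups only).

    Enumerates all C(n_a+n_b, n_a) label assignments; no smoothing, so the
    identity assignment contributes 1/C and the Monte-Carlo estimate
    converges to this value as the number of permutations grows.
    """
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    pooled = np.concatenate([a, b])
    n_a, total = len(a), len(pooled)
    if comb(total, n_a) > 200_000:
        raise ValueError("group sizes too large for exhaustive enumeration")
    obs = a.mean() - b.mean()
    eps = 1e-12 * max(1.0, abs(obs))
    idx = set(range(total))
    hits = 0
    count = 0
    for pick in combinations(range(total), n_a):
        rest = list(idx - set(pick))
        stat = pooled[list(pick)].mean() - pooled[rest].mean()
        if alternative == "two_sided":
            hits += abs(stat) >= abs(obs) - eps
        else:
            hits += stat >= obs - eps
        count += 1
    return hits / count


def standard_error(values: Sequence[float]) -> float:
    """Standard error of the mean (the error bar used for group means)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        return float("nan")
    return float(arr.std(ddof=1) / np.sqrt(arr.size))
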