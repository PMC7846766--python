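"""Same-chromosome shuffling and overlap-percentage significance testing.

Used to ask whether a region set (e.g. MRRs) overlaps an external element
list (e.g. a silencer screen's hits) more often than position-matched
chance: the query set is re-placed uniformly at random on its own
chromosomes many times, the percentage of target elements overlapped is
recorded per shuffle, and the actual percentage is compared against that
null both with a one-sided one-sample t-test (mean expected < actual) and
with the empirical permutation rank.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome import GenomeTable, GenomicInterval, overlaps_any

__all__ = [
    "ShuffleResult",
    "shuffle_same_chromosome",
    "overlap_percentage",
    "permutation_overlap_test",
]

DEFAULT_N_SHUFFLES = 1000


@dataclass
class ShuffleResult:
    actual_pct: float
    expected_pcts: np.ndarray
    p_value: float  # one-sided one-sample t-test, mean(expected) < actual
    empirical_p: float  # (1 + #{expected >= actual}) / (n_shuffles + 1)
    n_shuffles: int


def shuffle_same_chromosome(
    regions: Sequence[GenomicInterval],
    genome: GenomeTable,
    rng: np.random.Generator | int,
) -> list[GenomicInterval]:
    """Re-place each region uniformly at random on its own chromosome.

    Chromosome and length are preserved; placements are independent, so
    shuffled regions may overlap each other or the original position.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = []
    for region in regions:
        chrom_len = genome[region.chrom]
        length = len(region)
        if length > chrom_len:
            raise ValueError(
                f"region {region.chrom}:{region.start}-{region.end} longer than "
                f"chromosome ({chrom_len} bp)"
            )
        start = int(rng.integers(0, chrom_len - length + 1))
        out.append(GenomicInterval(region.chrom, start, start + length))
    return out


def overlap_percentage(
    target: Sequence[GenomicInterval], query: Sequence[GenomicInterval]
) -> float:
    """Percent of target elements sharing ≥1 bp with any query element."""
    if not target:
        raise ValueError("target must be non-empty")
    hit = overlaps_any(target, query)
    return 100.0 * float(hit.sum()) / len(target)


def permutation_overlap_test(
    target: Sequence[GenomicInterval],
    query: Sequence[GenomicInterval],
    genome: GenomeTable,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
) -> ShuffleResult:
    """Is the actual target-overlap percentage higher than the shuffle null?

    The t-test p-value tests H1: mean(expected) < actual over the shuffle
    distribution. The empirical permutation p, (1 + #{expected ≥ actual}) /
    (n_shuffles + 1), is the statistically safer headline number and is
    always reported alongside.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be ≥ 2")
    rng = np.random.default_rng(seed)
    actual = overlap_percentage(target, query)
    expected = np.empty(n_shuffles)
    for i in range(n_shuffles):
        expected[i] = overlap_percentage(
            target, shuffle_same_chromosome(query, genome, rng)
        )
    empirical_p = (1 + int((expected >= actual).sum())) / (n_shuffles + 1)
    if np.ptp(expected) == 0:
        warnings.warn(
            "zero variance in shuffled overlap percentages: t-test undefined, "
            "reporting empirical p only",
            stacklevel=2,
        )
        t_p = float("nan")
    else:
        t_p = float(stats.ttest_1samp(expected, actual, alternative="less").pvalue)
    return ShuffleResult(
        actual_pct=actual,
        expected_pcts=expected,
        p_value=t_p,
        empirical_p=empirical_p,
        n_shuffles=n_shuffles,
    )
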