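"""Chromatin-state labelling of interaction anchors and pair enrichment.

Anchors are labelled A (active, H3K27ac only), R (repressive, H3K27me3
only), B (both marks) or Q (quiescent, neither); an alternative repressive
mode labels anchors MRR vs T (typical H3K27me3). State-pair proportions
among loops are compared with the proportions expected under a homogeneous
pairing model built from the anchor-state marginals: each interaction
contributes two anchor slots, and the expected proportion of an unordered
pair (s, t) is 2·p_s·p_t for s ≠ t and p_s² for s = t.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeTable, GenomicInterval, IntervalIndex

logger = logging.getLogger(__name__)

__all__ = [
    "STATE_ALPHABET",
    "REPRESSIVE_ALPHABET",
    "StateLabeledInteraction",
    "StatePairEnrichment",
    "assign_anchor_state",
    "assign_repressive_class",
    "label_interactions",
    "pair_enrichment",
    "constituent_interaction_density",
    "dedupe_interactions",
]

STATE_ALPHABET = ("A", "R", "B", "Q")
REPRESSIVE_ALPHABET = ("T", "MRR")


@dataclass(frozen=True)
class StateLabeledInteraction:
    anchor1: GenomicInterval
    anchor2: GenomicInterval
    state1: str
    state2: str

    @property
    def pair(self) -> tuple[str, str]:
        """Unordered state pair (AR ≡ RA)."""
        return tuple(sorted((self.state1, self.state2)))


@dataclass
class StatePairEnrichment:
    """Observed vs expected state-pair proportions with log2 ratios."""

    table: pd.DataFrame  # pair, observed_count, observed_prop, expected_prop, log2_ratio
    marginals: dict[str, float]
    n_interactions: int

    def log2_ratio(self, s: str, t: str) -> float:
        key = "/".join(sorted((s, t)))
        row = self.table.loc[self.table["pair"] == key]
        if row.empty:
            raise KeyError(key)
        return float(row["log2_ratio"].iloc[0])


def assign_anchor_state(
    anchor: GenomicInterval,
    k27ac_index: IntervalIndex,
    k27me3_index: IntervalIndex,
) -> str:
    ac = k27ac_index.any_overlap(anchor)
    me3 = k27me3_index.any_overlap(anchor)
    if ac and me3:
        return "B"
    if ac:
        return "A"
    if me3:
        return "R"
    return "Q"


def assign_repressive_class(
    anchor: GenomicInterval,
    mrr_index: IntervalIndex,
    typical_index: IntervalIndex,
) -> str | None:
    """MRR (precedence) > T > None (excluded from the T/MRR analysis)."""
    if mrr_index.any_overlap(anchor):
        return "MRR"
    if typical_index.any_overlap(anchor):
        return "T"
    return None


def label_interactions(
    loops: Sequence[tuple[GenomicInterval, GenomicInterval]],
    k27ac_peaks: Iterable[GenomicInterval] | None = None,
    k27me3_peaks: Iterable[GenomicInterval] | None = None,
    mrr_regions: Iterable[GenomicInterval] | None = None,
    typical_regions: Iterable[GenomicInterval] | None = None,
    mode: str = "marks",
) -> list[StateLabeledInteraction]:
    """Label both anchors of every loop.

    mode="marks": A/R/B/Q from H3K27ac and H3K27me3 peak sets.
    mode="repressive": T/MRR from stitched-region sets; loops with an anchor
    in neither set are dropped (their count is logged).
    """
    out: list[StateLabeledInteraction] = []
    if mode == "marks":
        ac = IntervalIndex(k27ac_peaks or [])
        me3 = IntervalIndex(k27me3_peaks or [])
        for a1, a2 in loops:
            out.append(
                StateLabeledInteraction(
                    a1, a2, assign_anchor_state(a1, ac, me3), assign_anchor_state(a2, ac, me3)
                )
            )
    elif mode == "repressive":
        mrr = IntervalIndex(mrr_regions or [])
        typ = IntervalIndex(typical_regions or [])
        dropped = 0
        for a1, a2 in loops:
            s1 = assign_repressive_class(a1, mrr, typ)
            s2 = assign_repressive_class(a2, mrr, typ)
            if s1 is None or s2 is None:
                dropped += 1
                continue
            out.append(StateLabeledInteraction(a1, a2, s1, s2))
        if dropped:
            logger.info(
                "repressive mode: dropped %d loops with an unclassified anchor",
                dropped,
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def dedupe_interactions(
    loops: Sequence[tuple[GenomicInterval, GenomicInterval]],
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """Drop exact-coordinate duplicate loop records (orientation-insensitive)."""
    seen = set()
    out = []
    for a1, a2 in loops:
        key = tuple(
            sorted(
                [(a1.chrom, a1.start, a1.end), (a2.chrom, a2.start, a2.end)]
            )
        )
        if key in seen:
            continue
        seen.add(key)
        out.append((a1, a2))
    removed = len(loops) - len(out)
    if removed:
        logger.info("deduplicated %d exact-coordinate loop records", removed)
    return out


def pair_enrichment(
    interactions: Sequence[StateLabeledInteraction],
    alphabet: Sequence[str] | None = None,
) -> StatePairEnrichment:
    """Observed and expected unordered state-pair proportions with log2(Obs/Exp).

    Marginals are counted over anchor slots (each interaction contributes 2).
    Zero-observed pairs get log2_ratio = NaN (no pseudocount); pairs with
    expected 0 (state absent from the marginals) are reported only if an
    alphabet listing them is passed explicitly.
    """
    if not interactions:
        raise ValueError("pair_enrichment requires ≥1 interaction")
    n = len(interactions)
    slot_counts: dict[str, int] = {}
    pair_counts: dict[tuple[str, str], int] = {}
    for itx in interactions:
        for s in (itx.state1, itx.state2):
            slot_counts[s] = slot_counts.get(s, 0) + 1
        pair_counts[itx.pair] = pair_counts.get(itx.pair, 0) + 1
    marginals = {s: c / (2 * n) for s, c in slot_counts.items()}
    states = list(alphabet) if alphabet is not None else sorted(slot_counts)
    rows = []
    for i, s in enumerate(states):
        for t in states[i:]:
            pair = tuple(sorted((s, t)))
            obs_count = pair_counts.get(pair, 0)
            obs_prop = obs_count / n
            p_s = marginals.get(s, 0.0)
            p_t = marginals.get(t, 0.0)
            exp_prop = p_s * p_t if s == t else 2 * p_s * p_t
            if obs_count > 0 and exp_prop > 0:
                log2_ratio = float(np.log2(obs_prop / exp_prop))
            else:
                log2_ratio = float("nan")
            rows.append(
                {
                    "pair": "/".join(pair),
                    "observed_count": obs_count,
                    "observed_prop": obs_prop,
                    "expected_prop": exp_prop,
                    "log2_ratio": log2_ratio,
                }
            )
    table = pd.DataFrame(rows)
    return StatePairEnrichment(table=table, marginals=marginals, n_interactions=n)


def constituent_interaction_density(
    constituents: Sequence[GenomicInterval],
    interactions: Sequence[tuple[GenomicInterval, GenomicInterval]],
    genome: GenomeTable,
    shuffles: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Interaction counts at constituent peaks vs length-matched shuffled controls.

    Observed: per constituent, the number of loops with ≥1 anchor overlapping
    it. Controls: each constituent's midpoint is expanded to the global
    median constituent length, then the expanded region is placed uniformly
    at random on its own chromosome; this is repeated ``shuffles`` times.

    Returns ``(observed, control)`` with shapes (n,) and (shuffles, n).
    """
    if not constituents:
        raise ValueError("constituents must be non-empty")
    if shuffles < 1:
        raise ValueError("shuffles must be ≥ 1")
    anchors = [a for pair in interactions for a in pair]
    index = IntervalIndex(anchors)
    # count loops (not anchors): a loop hits a region if either anchor overlaps
    def loop_count(region: GenomicInterval) -> int:
        if not index.any_overlap(region):
            return 0
        return sum(
            1
            for a1, a2 in interactions
            if region.overlaps(a1) or region.overlaps(a2)
        )

    observed = np.array([loop_count(c) for c in constituents], dtype=np.int64)

    rng = np.random.default_rng(seed)
    control = np.empty((shuffles, len(constituents)), dtype=np.int64)
    for i in range(shuffles):
        for j, region in enumerate(expanded_shuffled_controls(constituents, genome, rng)):
            control[i, j] = loop_count(region)
    return observed, control


def expanded_shuffled_controls(
    constituents: Sequence[GenomicInterval],
    genome: GenomeTable,
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    """One control draw: midpoints expanded to the median constituent length,
    then each expanded region placed uniformly at random on its chromosome."""
    median_len = int(np.median([len(c) for c in constituents]))
    out = []
    for c in constituents:
        length = min(median_len, genome[c.chrom])
        start = int(rng.integers(0, genome[c.chrom] - length + 1))
        out.append(GenomicInterval(c.chrom, start, start + length))
    return out
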