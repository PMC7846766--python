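"""Expression specificity and cross-cell-line state-change analysis.

Specificity follows the entropy definition used for CAGE facet atlases:
a gene's expression vector x over N facets is normalized to a probability
distribution p, and

    specificity(x) = 1 − H(p) / log2(N),   H in bits.

A uniformly expressed gene scores 0, a single-facet gene scores 1. A cell
line of interest is appended to the reference facets as one extra facet
(69 reference facets + 1 cell line = 70) before scoring.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomicInterval, IntervalIndex

__all__ = [
    "SpecificityScore",
    "facet_average",
    "specificity",
    "specificity_frame",
    "specificity_bins",
    "assign_gene_state",
    "state_change_table",
]

#: Precedence when a gene overlaps several peak classes: rich regions
#: subsume their constituent marks.
STATE_PRECEDENCE = ("SE", "MRR", "H3K27ac", "H3K27me3")

FOLD_CHANGE_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class SpecificityScore:
    gene_id: str
    entropy_bits: float
    specificity: float  # NaN when total expression is 0
    bin: str | None = None  # low | mid | high | undefined


def facet_average(
    sample_matrix: pd.DataFrame, facet_map: Mapping[str, str]
) -> pd.DataFrame:
    """Average a genes × samples matrix into genes × facets.

    Every sample column must be mapped to a facet; facets inherit the
    arithmetic mean of their samples.
    """
    unmapped = [c for c in sample_matrix.columns if c not in facet_map]
    if unmapped:
        raise ValueError(f"samples with no facet assignment: {unmapped}")
    facets = pd.Index(sorted(set(facet_map[c] for c in sample_matrix.columns)))
    out = pd.DataFrame(index=sample_matrix.index, columns=facets, dtype=float)
    for facet in facets:
        cols = [c for c in sample_matrix.columns if facet_map[c] == facet]
        out[facet] = sample_matrix[cols].mean(axis=1)
    return out


def specificity(values: Sequence[float], gene_id: str = "") -> SpecificityScore:
    """Entropy-based specificity of one expression vector (see module docs)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need ≥2 facets")
    if np.any(x < 0):
        raise ValueError("negative expression value")
    total = x.sum()
    if total == 0:
        return SpecificityScore(gene_id, float("nan"), float("nan"), "undefined")
    p = x / total
    nz = p[p > 0]  # 0·log(0) = 0 convention
    entropy = float(-(nz * np.log2(nz)).sum())
    return SpecificityScore(gene_id, entropy, 1.0 - entropy / np.log2(x.size))


def specificity_frame(facet_matrix: pd.DataFrame) -> pd.DataFrame:
    """Specificity per row of a genes × facets matrix, with Q1/Q3 bins."""
    scores = [
        specificity(row.to_numpy(), gene_id=str(gene))
        for gene, row in facet_matrix.iterrows()
    ]
    binned = specificity_bins(scores)
    return pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in binned],
            "entropy_bits": [s.entropy_bits for s in binned],
            "specificity": [s.specificity for s in binned],
            "bin": [s.bin for s in binned],
        }
    )


def specificity_bins(scores: Sequence[SpecificityScore]) -> list[SpecificityScore]:
    """Bin scores at the quartiles: ≤ Q1 → low, ≥ Q3 → high, else mid.

    Quartiles are computed by linear interpolation over the defined scores;
    undefined scores (zero total expression) keep the "undefined" bin. A
    score satisfying both cutoffs at once (possible only when Q1 = Q3,
    e.g. all-equal scores) is neither distinctly low nor high and lands
    in mid.
    """
    defined = [s.specificity for s in scores if not np.isnan(s.specificity)]
    if len(defined) < 4:
        raise ValueError("need ≥4 defined specificity scores to bin")
    q1, q3 = np.quantile(defined, [0.25, 0.75])
    out = []
    for s in scores:
        if np.isnan(s.specificity):
            bin_ = "undefined"
        elif s.specificity <= q1 and not s.specificity >= q3:
            bin_ = "low"
        elif s.specificity >= q3 and not s.specificity <= q1:
            bin_ = "high"
        else:
            bin_ = "mid"
        out.append(SpecificityScore(s.gene_id, s.entropy_bits, s.specificity, bin_))
    return out


def assign_gene_state(
    body: GenomicInterval,
    promoter: GenomicInterval,
    se_index: IntervalIndex,
    mrr_index: IntervalIndex,
    k27ac_index: IntervalIndex,
    k27me3_index: IntervalIndex,
) -> str:
    """One chromatin-state label per gene per cell line.

    Overlap of body ∪ promoter against each region set, with precedence
    SE > MRR > H3K27ac > H3K27me3; no overlap → Others.
    """
    indexes = {
        "SE": se_index,
        "MRR": mrr_index,
        "H3K27ac": k27ac_index,
        "H3K27me3": k27me3_index,
    }
    for state in STATE_PRECEDENCE:
        idx = indexes[state]
        if idx.any_overlap(body) or idx.any_overlap(promoter):
            return state
    return "Others"


def state_change_table(
    labels_a: Mapping[str, str],
    labels_b: Mapping[str, str],
    expr_a: Mapping[str, float],
    expr_b: Mapping[str, float],
    pseudocount: float = FOLD_CHANGE_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene state-change categories with log2 fold changes (B over A).

    Category strings read "stateA vs stateB"; fold changes use a
    pseudocount on the expression unit, log2((b + ε)/(a + ε)).
    """
    genes = sorted(set(labels_a) & set(labels_b) & set(expr_a) & set(expr_b))
    rows = []
    for g in genes:
        a, b = float(expr_a[g]), float(expr_b[g])
        rows.append(
            {
                "gene_id": g,
                "state_a": labels_a[g],
                "state_b": labels_b[g],
                "category": f"{labels_a[g]} vs {labels_b[g]}",
                "log2_fc": float(np.log2((b + pseudocount) / (a + pseudocount))),
            }
        )
    return pd.DataFrame(rows)
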