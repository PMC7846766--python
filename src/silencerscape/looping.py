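"""Gene–MRR looping classification and control-gene construction.

A gene and an MRR can be related three ways, decided from Hi-C loops:

* proximal — the MRR overlaps the gene promoter, or the promoter and the
  MRR sit on the same interaction anchor;
* distal — a loop connects the MRR (one anchor) to the promoter (other
  anchor), with the MRR not touching the promoter's anchor;
* internal — the MRR overlaps the promoter AND part of the same MRR loops
  over to the promoter (a supporting loop with both anchors inside the MRR).

Precedence: internal > proximal > distal.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomicInterval, IntervalIndex

__all__ = [
    "GeneModel",
    "GeneMRRAssociation",
    "make_gene_model",
    "classify_gene_mrr",
    "build_control_genes",
]

DEFAULT_PROMOTER_HALFWIDTH = 2000


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    body: GenomicInterval
    promoter: GenomicInterval


def make_gene_model(
    gene_id: str,
    chrom: str,
    start: int,
    end: int,
    strand: str = "+",
    promoter_halfwidth: int = DEFAULT_PROMOTER_HALFWIDTH,
) -> GeneModel:
    """Build a gene model with a symmetric promoter window around the TSS."""
    tss = start if strand == "+" else end - 1
    promoter = GenomicInterval(
        chrom, max(0, tss - promoter_halfwidth), tss + promoter_halfwidth
    )
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        tss=tss,
        body=GenomicInterval(chrom, start, end, name=gene_id),
        promoter=promoter,
    )


@dataclass
class GeneMRRAssociation:
    gene_id: str
    mrr_id: str
    category: str  # proximal | distal | internal
    proximal_by_overlap: bool
    proximal_by_shared_anchor: bool
    supporting_loops: list[int] = field(default_factory=list)


def classify_gene_mrr(
    genes: Sequence[GeneModel],
    mrrs: Sequence[GenomicInterval],
    interactions: Sequence[tuple[GenomicInterval, GenomicInterval]],
) -> list[GeneMRRAssociation]:
    """Assign one category per (gene, MRR) pair with evidence recorded.

    Evidence per pair:
      * overlap: promoter overlaps the MRR directly;
      * shared anchor: one loop anchor overlaps both promoter and MRR;
      * loop: a loop joins an MRR-overlapping anchor to a
        promoter-overlapping anchor.

    internal = (overlap or shared anchor) and a supporting loop with both
    anchors overlapping the same MRR; proximal = overlap/shared-anchor
    evidence only; distal = loop evidence where the MRR stays off the
    promoter's anchor. Pairs with no evidence are omitted.
    """
    out: list[GeneMRRAssociation] = []
    for gene in genes:
        for m_idx, mrr in enumerate(mrrs):
            mrr_id = mrr.name or f"MRR_{m_idx}"
            prox_overlap = gene.promoter.overlaps(mrr)
            prox_shared = False
            loop_support: list[int] = []  # loops joining MRR and promoter
            internal_support: list[int] = []
            distal_support: list[int] = []
            for l_idx, (a1, a2) in enumerate(interactions):
                for prom_anchor, mrr_anchor in ((a1, a2), (a2, a1)):
                    if prom_anchor.overlaps(gene.promoter) and prom_anchor.overlaps(mrr):
                        prox_shared = True
                    if prom_anchor.overlaps(gene.promoter) and mrr_anchor.overlaps(mrr):
                        loop_support.append(l_idx)
                        if mrr.overlaps(a1) and mrr.overlaps(a2):
                            internal_support.append(l_idx)
                        if not mrr.overlaps(prom_anchor):
                            distal_support.append(l_idx)
            proximal_evidence = prox_overlap or prox_shared
            if proximal_evidence and internal_support:
                category, support = "internal", internal_support
            elif proximal_evidence:
                category, support = "proximal", loop_support
            elif distal_support:
                category, support = "distal", distal_support
            else:
                continue
            out.append(
                GeneMRRAssociation(
                    gene_id=gene.gene_id,
                    mrr_id=mrr_id,
                    category=category,
                    proximal_by_overlap=prox_overlap,
                    proximal_by_shared_anchor=prox_shared,
                    supporting_loops=sorted(set(support)),
                )
            )
    return out


def build_control_genes(
    genes: Sequence[GeneModel],
    blacklist: Iterable[GenomicInterval],
    h3k9me3_peaks: Iterable[GenomicInterval],
    interactions: Sequence[tuple[GenomicInterval, GenomicInterval]],
    n_per_category: Sequence[int],
    seed: int,
    promoter_counts: bool = False,
) -> list[str]:
    """Sample the expression-control gene set.

    Filters out genes whose body overlaps ENCODE-blacklist or H3K9me3
    regions (constitutive heterochromatin), keeps genes whose body or
    promoter overlaps a loop anchor, then samples
    floor(mean(n_per_category)) genes uniformly without replacement.
    """
    bad = IntervalIndex(list(blacklist) + list(h3k9me3_peaks))
    anchors = IntervalIndex([a for pair in interactions for a in pair])
    eligible = []
    for gene in genes:
        if bad.any_overlap(gene.body):
            continue
        hit = anchors.any_overlap(gene.promoter) if promoter_counts else (
            anchors.any_overlap(gene.body) or anchors.any_overlap(gene.promoter)
        )
        if hit:
            eligible.append(gene.gene_id)
    n_sample = int(np.floor(np.mean(list(n_per_category))))
    if len(eligible) < n_sample:
        raise ValueError(
            f"only {len(eligible)} eligible control genes, need {n_sample}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n_sample, replace=False)
    return [eligible[i] for i in sorted(chosen)]
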