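"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates one class of real input — clustered ChIP-seq peaks
with enriched coverage, state-labelled loop lists with a like-like
preference, facet expression matrices with graded specificity, and
distance-dependent differential 4C call tables — and records the planted
truth alongside, so recovery can be checked without any downloads.

Reproducibility: one global seed fans out to independent per-generator
substreams (``SeedSequence((seed, stream))``), so adding a generator never
perturbs the draws of another, and identical (parameters, seed) give
byte-identical output files.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import (
    GenomeTable,
    GenomicInterval,
    SignalTrack,
    write_bed,
    write_bedpe,
    write_signal,
)

__all__ = [
    "make_genome",
    "make_peaks_and_signal",
    "make_interactions",
    "make_expression",
    "make_fourc_pair",
    "make_genes_for_mrrs",
    "make_external_regions",
    "mark_peaks_for_anchors",
    "homogeneous_pair_distribution",
    "boost_diagonal",
    "planted_log2_ratios",
    "simulate_full",
]

#: substream ids, fixed forever so streams stay independent of call order
_STREAMS = {
    "peaks": 1,
    "interactions": 2,
    "expression": 3,
    "fourc": 4,
    "genes": 5,
    "external": 6,
}

SIGNAL_RESOLUTION = 10  # bp per coverage bin in emitted bedGraphs


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, _STREAMS[stream])))


def make_genome(
    n_chrom: int = 1, lengths: Sequence[int] | int = 10_000_000, seed: int = 0
) -> GenomeTable:
    """Deterministic toy genome: chrS1..chrSn with the given lengths."""
    if np.isscalar(lengths):
        lengths = [int(lengths)] * n_chrom
    if len(lengths) != n_chrom:
        raise ValueError("lengths must match n_chrom")
    return GenomeTable({f"chrS{i + 1}": int(l) for i, l in enumerate(lengths)})


# ---------------------------------------------------------------------------
# ChIP-seq peaks + coverage with planted rich clusters


@dataclass
class PeakSignalTruth:
    mrr_intervals: list[GenomicInterval]
    cluster_peaks: list[GenomicInterval]
    isolated_peaks: list[GenomicInterval]
    params: dict = field(default_factory=dict)


def make_peaks_and_signal(
    genome: GenomeTable,
    n_clusters: int = 20,
    peaks_per_cluster: int = 8,
    intra_gap: tuple[int, int] = (500, 3000),
    n_isolated: int = 500,
    signal_fold: float = 10.0,
    background: float = 1.0,
    noise: bool = True,
    seed: int = 0,
    stitch_window: int = 4000,
) -> tuple[list[GenomicInterval], SignalTrack, SignalTrack, PeakSignalTruth]:
    """Plant high-signal peak clusters among isolated low-signal peaks.

    Clusters of ``peaks_per_cluster`` peaks with intra-cluster gaps drawn
    below the stitch window are the planted rich regions; isolated peaks
    sit ≥ 2× window from anything else. Treatment coverage is Poisson with
    mean ``background`` outside peaks, ``background×signal_fold`` inside
    cluster peaks and ``background×signal_fold/3`` inside isolated peaks
    (exact means when ``noise=False``); control is flat ``background``.

    Returns (peaks, treatment, control, truth).
    """
    rng = _rng(seed, "peaks")
    if intra_gap[1] >= stitch_window:
        raise ValueError("intra-cluster gaps must stay below the stitch window")
    chroms = list(genome)
    sep = 2 * stitch_window  # guaranteed separation between planted units

    # build unit templates: lists of (offset, length, kind)
    units = []
    for _ in range(n_clusters):
        offs, lengths = [], []
        pos = 0
        for p in range(peaks_per_cluster):
            length = int(rng.integers(200, 601))
            offs.append(pos)
            lengths.append(length)
            pos += length + int(rng.integers(intra_gap[0], intra_gap[1] + 1))
        units.append(("cluster", list(zip(offs, lengths))))
    for _ in range(n_isolated):
        units.append(("isolated", [(0, int(rng.integers(200, 601)))]))

    order = rng.permutation(len(units))
    spans = [
        max(o + l for o, l in peaks) for _, peaks in (units[i] for i in order)
    ]
    total_needed = sum(spans) + sep * (len(units) + 1)
    total_len = sum(genome.values())
    if total_needed > total_len:
        raise ValueError(
            f"infeasible packing: need {total_needed} bp, genome has {total_len}"
        )

    # distribute units over chromosomes proportionally, then lay out with
    # random extra slack between consecutive units
    peaks: list[GenomicInterval] = []
    truth = PeakSignalTruth(
        mrr_intervals=[],
        cluster_peaks=[],
        isolated_peaks=[],
        params={
            "n_clusters": n_clusters,
            "peaks_per_cluster": peaks_per_cluster,
            "n_isolated": n_isolated,
            "signal_fold": signal_fold,
            "background": background,
            "seed": seed,
        },
    )
    unit_seq = [units[i] for i in order]
    # assign units to chromosomes by capacity
    per_chrom: dict[str, list] = {c: [] for c in chroms}
    cap = {c: genome[c] - sep for c in chroms}
    ci = 0
    for unit, span in zip(unit_seq, spans):
        placed = False
        for _ in range(len(chroms)):
            c = chroms[ci % len(chroms)]
            ci += 1
            if cap[c] >= span + sep:
                per_chrom[c].append(unit)
                cap[c] -= span + sep
                placed = True
                break
        if not placed:
            raise ValueError("infeasible packing across chromosomes")

    for chrom in chroms:
        chrom_units = per_chrom[chrom]
        if not chrom_units:
            continue
        chrom_spans = [max(o + l for o, l in u[1]) for u in chrom_units]
        slack = genome[chrom] - sum(chrom_spans) - sep * (len(chrom_units) + 1)
        extra = rng.multinomial(max(0, slack), np.ones(len(chrom_units)) / len(chrom_units))
        pos = sep
        for (kind, unit_peaks), span, pad in zip(chrom_units, chrom_spans, extra):
            pos += int(pad)
            ivs = [
                GenomicInterval(chrom, pos + o, pos + o + l) for o, l in unit_peaks
            ]
            peaks.extend(ivs)
            if kind == "cluster":
                truth.cluster_peaks.extend(ivs)
                truth.mrr_intervals.append(
                    GenomicInterval(chrom, ivs[0].start, ivs[-1].end)
                )
            else:
                truth.isolated_peaks.extend(ivs)
            pos += span + sep

    treatment = _coverage(
        genome,
        truth.cluster_peaks,
        truth.isolated_peaks,
        background,
        signal_fold,
        noise,
        rng,
    )
    control = SignalTrack.constant(genome, background)
    peaks.sort(key=lambda iv: (iv.chrom, iv.start))
    return peaks, treatment, control, truth


def _coverage(genome, cluster_peaks, isolated_peaks, background, fold, noise, rng):
    runs = {}
    res = SIGNAL_RESOLUTION
    for chrom, length in genome.items():
        n_bins = int(np.ceil(length / res))
        mean = np.full(n_bins, background)
        for peaks, level in (
            (cluster_peaks, background * fold),
            (isolated_peaks, background * fold / 3),
        ):
            for iv in peaks:
                if iv.chrom != chrom:
                    continue
                b0, b1 = iv.start // res, int(np.ceil(iv.end / res))
                mean[b0:b1] = level
        values = rng.poisson(mean).astype(float) if noise else mean
        starts = np.arange(n_bins, dtype=np.int64) * res
        ends = np.minimum(starts + res, length)
        # run-length encode equal neighbours to keep tracks compact
        keep = np.ones(n_bins, dtype=bool)
        keep[1:] = values[1:] != values[:-1]
        idx = np.flatnonzero(keep)
        run_starts = starts[idx]
        run_ends = np.append(run_starts[1:], ends[-1])
        runs[chrom] = (run_starts, run_ends, values[idx])
    return SignalTrack(runs)


# ---------------------------------------------------------------------------
# State-labelled loop lists


def homogeneous_pair_distribution(marginals: Mapping[str, float]) -> dict[tuple[str, str], float]:
    """Unordered-pair distribution implied by independent anchor pairing."""
    states = sorted(marginals)
    q = {}
    for i, s in enumerate(states):
        for t in states[i:]:
            q[(s, t)] = (
                marginals[s] ** 2 if s == t else 2 * marginals[s] * marginals[t]
            )
    return q


def boost_diagonal(
    q: Mapping[tuple[str, str], float], boost: float
) -> dict[tuple[str, str], float]:
    """Multiply like-like pairs by ``boost`` and renormalize."""
    out = {k: (v * boost if k[0] == k[1] else v) for k, v in q.items()}
    z = sum(out.values())
    return {k: v / z for k, v in out.items()}


def planted_log2_ratios(q: Mapping[tuple[str, str], float]) -> dict[tuple[str, str], float]:
    """log2(q / homogeneous-expected) from q's own slot marginals."""
    states = sorted({s for pair in q for s in pair})
    marg = {
        s: q.get((s, s), 0.0)
        + 0.5 * sum(v for (a, b), v in q.items() if a != b and s in (a, b))
        for s in states
    }
    out = {}
    for pair, prob in q.items():
        s, t = pair
        exp = marg[s] ** 2 if s == t else 2 * marg[s] * marg[t]
        out[pair] = float(np.log2(prob / exp)) if prob > 0 and exp > 0 else float("nan")
    return out


@dataclass
class InteractionTruth:
    anchors: list[GenomicInterval]
    anchor_states: list[str]
    pair_distribution: dict[tuple[str, str], float]
    log2_ratios: dict[tuple[str, str], float]


def make_interactions(
    genome: GenomeTable,
    state_probs: Mapping[str, float] | None = None,
    pair_preference: Mapping[tuple[str, str], float] | None = None,
    n_interactions: int = 5000,
    n_anchors: int = 400,
    anchor_length: int = 5000,
    seed: int = 0,
    sampling: str = "exact",
) -> tuple[list[tuple[GenomicInterval, GenomicInterval]], list[str], InteractionTruth]:
    """Sample loops between labelled anchors from a planted pair distribution.

    Anchors are placed non-overlapping and labelled i.i.d. from
    ``state_probs``; each loop carries an unordered state pair from
    ``pair_preference`` (default: like-like pairs boosted 3× over the
    homogeneous product of the marginals) and picks distinct anchors with
    those states. With ``sampling="exact"`` (default) the pair composition
    is allocated by largest-remainder rounding of n×preference, so the
    realized pair distribution matches the planted matrix up to rounding
    and randomness lives only in which anchors carry each loop;
    ``sampling="multinomial"`` draws the composition stochastically
    instead. The truth carries the planted log2(Obs/Exp).

    Returns (loops, per-loop anchor-state pairs, truth).
    """
    rng = _rng(seed, "interactions")
    if state_probs is None:
        state_probs = {"A": 0.35, "R": 0.25, "B": 0.15, "Q": 0.25}
    if pair_preference is None:
        pair_preference = boost_diagonal(
            homogeneous_pair_distribution(state_probs), 3.0
        )
    states = sorted(state_probs)
    probs = np.array([state_probs[s] for s in states])
    probs = probs / probs.sum()

    # non-overlapping anchor placement on a coarse lattice
    chroms = list(genome)
    anchors: list[GenomicInterval] = []
    labels: list[str] = []
    pitch = anchor_length * 2
    slots = [
        (c, s)
        for c in chroms
        for s in range(0, genome[c] - anchor_length, pitch)
    ]
    if len(slots) < n_anchors:
        raise ValueError("genome too small for requested anchor count")
    chosen = rng.choice(len(slots), size=n_anchors, replace=False)
    for idx in sorted(chosen):
        c, s = slots[idx]
        jitter = int(rng.integers(0, pitch - anchor_length))
        anchors.append(GenomicInterval(c, s + jitter, s + jitter + anchor_length))
        labels.append(states[rng.choice(len(states), p=probs)])
    by_state = {s: [i for i, l in enumerate(labels) if l == s] for s in states}
    for s in states:
        if len(by_state[s]) < 2:
            raise ValueError(f"too few anchors with state {s!r}; raise n_anchors")

    pairs = sorted(pair_preference)
    pair_probs = np.array([pair_preference[p] for p in pairs])
    pair_probs = pair_probs / pair_probs.sum()
    if sampling == "exact":
        ideal = pair_probs * n_interactions
        counts = np.floor(ideal).astype(int)
        remainder = n_interactions - counts.sum()
        if remainder:
            top = np.argsort(-(ideal - counts), kind="stable")[:remainder]
            counts[top] += 1
        pair_idx = rng.permutation(np.repeat(np.arange(len(pairs)), counts))
    elif sampling == "multinomial":
        pair_idx = rng.choice(len(pairs), size=n_interactions, p=pair_probs)
    else:
        raise ValueError(f"unknown sampling mode {sampling!r}")
    loops = []
    loop_states = []
    for k in pair_idx:
        s, t = pairs[k]
        if s == t:
            i, j = rng.choice(by_state[s], size=2, replace=False)
        else:
            i = by_state[s][rng.integers(len(by_state[s]))]
            j = by_state[t][rng.integers(len(by_state[t]))]
        loops.append((anchors[i], anchors[j]))
        loop_states.append((labels[i], labels[j]))
    truth = InteractionTruth(
        anchors=anchors,
        anchor_states=labels,
        pair_distribution=dict(pair_preference),
        log2_ratios=planted_log2_ratios(pair_preference),
    )
    return loops, loop_states, truth


def mark_peaks_for_anchors(
    anchors: Sequence[GenomicInterval],
    states: Sequence[str],
    seed: int = 0,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Emit H3K27ac/H3K27me3 peaks consistent with planted anchor states.

    Each A anchor gets a H3K27ac peak inside it, each R anchor a H3K27me3
    peak, B both, Q none; because anchors are non-overlapping, labelling
    anchors from these peak files reproduces the planted states exactly.
    """
    rng = _rng(seed, "interactions")
    k27ac, k27me3 = [], []
    for anchor, state in zip(anchors, states):
        width = max(200, len(anchor) // 4)
        lo = anchor.start
        hi = anchor.end - width
        if state in ("A", "B"):
            s = int(rng.integers(lo, hi + 1))
            k27ac.append(GenomicInterval(anchor.chrom, s, s + width))
        if state in ("R", "B"):
            s = int(rng.integers(lo, hi + 1))
            k27me3.append(GenomicInterval(anchor.chrom, s, s + width))
    return k27ac, k27me3


# ---------------------------------------------------------------------------
# Expression matrices with graded specificity


def make_expression(
    n_genes: int = 500,
    n_facets: int = 70,
    concentration: float | Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene facet profiles ~ Dirichlet(α) × lognormal total expression.

    Small α concentrates mass in few facets (high specificity); large α
    approaches uniform (specificity → 0). Default: per-gene α log-uniform
    in [10⁻², 10¹] for a broad specificity spread. Truth is the
    specificity computed from the drawn profile itself.
    """
    from .expression import specificity

    rng = _rng(seed, "expression")
    if concentration is None:
        alphas = 10 ** rng.uniform(-2, 1, size=n_genes)
    elif np.isscalar(concentration):
        alphas = np.full(n_genes, float(concentration))
    else:
        alphas = np.asarray(concentration, dtype=float)
        if alphas.size != n_genes:
            raise ValueError("per-gene concentrations must have length n_genes")
    if np.any(alphas <= 0):
        raise ValueError("concentrations must be > 0")
    rows = []
    for alpha in alphas:
        profile = rng.dirichlet(np.full(n_facets, alpha))
        total = rng.lognormal(mean=3.0, sigma=1.0)
        rows.append(profile * total)
    matrix = pd.DataFrame(
        rows,
        index=[f"gene_{i}" for i in range(n_genes)],
        columns=[f"facet_{j}" for j in range(n_facets)],
    )
    truth = pd.Series(
        [specificity(row).specificity for row in rows],
        index=matrix.index,
        name="true_specificity",
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Differential 4C call tables


@dataclass
class FourCTruth:
    status: dict[tuple[str, int, int], str]  # fragment key → gained/lost/unchanged
    bait: GenomicInterval
    params: dict = field(default_factory=dict)


def make_fourc_pair(
    bait: GenomicInterval,
    genome: GenomeTable,
    n_fragments: int = 300,
    cis_span: int = 3_000_000,
    sig_base: float = 0.85,
    sig_decay: float = 1_500_000.0,
    sig_floor: float = 0.15,
    change_min: float = 0.05,
    change_max: float = 0.75,
    change_midpoint: float | None = None,
    change_scale: float | None = None,
    rep_agreement: float = 0.8,
    n_trans: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[dict[str, dict[str, pd.DataFrame]], FourCTruth]:
    """Two-condition, two-replicate 4C call tables with a planted distance effect.

    A HindIII-like fragment grid (exponential sizes, mean ≈ 4 kb) tiles
    ``cis_span`` on each side of the bait. Control significance is
    Bernoulli with probability declining in bait distance d; the
    experiment flips each fragment's significance with a logistic
    change probability rising in d, so distant loops change more often.
    p-values land below ``alpha`` for significant calls and above
    otherwise; RPM is lognormal with mean declining in d. Replicate 1
    carries the full condition-level call set; replicate 2 reproduces each
    call with probability ``rep_agreement`` (pooling by union recovers the
    planted set exactly).

    Returns ({"control": {"rep1": df, "rep2": df}, "experiment": …}, truth);
    each table has columns chrom, start, end, rpm, p_value.
    """
    rng = _rng(seed, "fourc")
    if change_midpoint is None:
        change_midpoint = cis_span / 3
    if change_scale is None:
        change_scale = cis_span / 10

    # contiguous fragment grid around the bait
    sizes = np.clip(rng.exponential(4000, size=2 * n_fragments), 500, 20000).astype(int)
    frags: list[GenomicInterval] = []
    chrom_len = genome[bait.chrom]
    pos = int(bait.midpoint)
    for size in sizes[:n_fragments]:  # rightward
        if pos + size > chrom_len or pos - bait.midpoint > cis_span:
            break
        frags.append(GenomicInterval(bait.chrom, pos, pos + int(size)))
        pos += int(size)
    pos = int(bait.midpoint)
    for size in sizes[n_fragments:]:  # leftward
        if pos - size < 0 or bait.midpoint - pos > cis_span:
            break
        frags.append(GenomicInterval(bait.chrom, pos - int(size), pos))
        pos -= int(size)
    trans_chroms = [c for c in genome if c != bait.chrom]
    for _ in range(n_trans if trans_chroms else 0):
        c = trans_chroms[rng.integers(len(trans_chroms))]
        size = int(np.clip(rng.exponential(4000), 500, 20000))
        start = int(rng.integers(0, genome[c] - size))
        frags.append(GenomicInterval(c, start, start + size))

    status: dict[tuple[str, int, int], str] = {}
    control_sig: list[GenomicInterval] = []
    experiment_sig: list[GenomicInterval] = []
    dists: dict[tuple[str, int, int], float] = {}
    for f in frags:
        if f.chrom == bait.chrom:
            d = abs(f.midpoint - bait.midpoint)
            p_sig = sig_floor + (sig_base - sig_floor) * np.exp(-d / sig_decay)
            p_change = change_min + (change_max - change_min) / (
                1 + np.exp(-(d - change_midpoint) / change_scale)
            )
        else:
            d = np.inf
            p_sig, p_change = 0.3, 0.4
        dists[f.chrom, f.start, f.end] = d
        sig_c = rng.random() < p_sig
        flip = rng.random() < p_change
        sig_e = sig_c ^ flip
        if sig_c:
            control_sig.append(f)
        if sig_e:
            experiment_sig.append(f)
        if sig_c and sig_e:
            status[f.chrom, f.start, f.end] = "unchanged"
        elif sig_c:
            status[f.chrom, f.start, f.end] = "lost"
        elif sig_e:
            status[f.chrom, f.start, f.end] = "gained"

    def _table(sig_set: list[GenomicInterval], full_replicate: bool) -> pd.DataFrame:
        rows = []
        for f in sig_set:
            if not full_replicate and rng.random() > rep_agreement:
                continue
            d = dists[f.chrom, f.start, f.end]
            rpm_mean = 3.0 if not np.isfinite(d) else 6.0 - 2.0 * d / cis_span
            rows.append(
                {
                    "chrom": f.chrom,
                    "start": f.start,
                    "end": f.end,
                    "rpm": float(rng.lognormal(rpm_mean, 0.5)),
                    "p_value": float(rng.uniform(0, alpha)),
                }
            )
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "rpm", "p_value"])

    tables = {
        "control": {
            "rep1": _table(control_sig, True),
            "rep2": _table(control_sig, False),
        },
        "experiment": {
            "rep1": _table(experiment_sig, True),
            "rep2": _table(experiment_sig, False),
        },
    }
    truth = FourCTruth(
        status=status,
        bait=bait,
        params={
            "n_fragments": n_fragments,
            "cis_span": cis_span,
            "change_min": change_min,
            "change_max": change_max,
            "seed": seed,
        },
    )
    return tables, truth


# ---------------------------------------------------------------------------
# Genes planted around MRRs, and external element lists


@dataclass
class GeneTruth:
    categories: dict[str, str]  # gene_id → proximal/distal/internal
    genes: list  # GeneModel
    extra_loops: list[tuple[GenomicInterval, GenomicInterval]]


def make_genes_for_mrrs(
    mrrs: Sequence[GenomicInterval],
    genome: GenomeTable,
    seed: int = 0,
    promoter_halfwidth: int = 2000,
) -> GeneTruth:
    """Plant one proximal, distal, or internal gene per MRR (round-robin).

    proximal — promoter inside the MRR, no loop; distal — gene 0.5–1 Mb
    away, joined to the MRR by a dedicated loop; internal — promoter
    inside the MRR plus a loop whose two anchors both sit inside the MRR,
    one over the promoter.
    """
    from .looping import make_gene_model

    rng = _rng(seed, "genes")
    categories = {}
    genes = []
    loops = []
    kinds = ["proximal", "distal", "internal"]
    for i, mrr in enumerate(mrrs):
        kind = kinds[i % 3]
        gid = f"gene_{kind}_{i}"
        chrom_len = genome[mrr.chrom]
        if kind == "proximal":
            tss = int(mrr.start + len(mrr) // 2)
            genes.append(
                make_gene_model(gid, mrr.chrom, tss, min(tss + 20000, chrom_len),
                                "+", promoter_halfwidth)
            )
        elif kind == "distal":
            offset = int(rng.integers(500_000, 1_000_000))
            tss = (
                mrr.end + offset
                if mrr.end + offset + 20000 < chrom_len
                else max(0, mrr.start - offset - 20000)
            )
            genes.append(
                make_gene_model(gid, mrr.chrom, tss, tss + 20000, "+",
                                promoter_halfwidth)
            )
            loops.append(
                (
                    GenomicInterval(mrr.chrom, mrr.start, min(mrr.start + 5000, mrr.end)),
                    GenomicInterval(mrr.chrom, max(0, tss - 2500), tss + 2500),
                )
            )
        else:  # internal: promoter near the MRR start, loop to the MRR end
            tss = int(mrr.start + 1000)
            genes.append(
                make_gene_model(gid, mrr.chrom, tss, tss + 20000, "+",
                                promoter_halfwidth)
            )
            a_len = max(2000, min(5000, len(mrr) // 4))
            loops.append(
                (
                    GenomicInterval(mrr.chrom, mrr.start, mrr.start + a_len),
                    GenomicInterval(mrr.chrom, max(mrr.start + a_len, mrr.end - a_len), mrr.end),
                )
            )
        categories[gid] = kind
    return GeneTruth(categories=categories, genes=genes, extra_loops=loops)


def make_external_regions(
    truth: PeakSignalTruth,
    genome: GenomeTable,
    n: int = 150,
    frac_in_mrr: float = 0.3,
    length: int = 500,
    seed: int = 0,
) -> list[GenomicInterval]:
    """An external element list (screen-hit-like) enriched inside planted MRRs."""
    rng = _rng(seed, "external")
    out = []
    mrrs = truth.mrr_intervals
    for i in range(n):
        if mrrs and rng.random() < frac_in_mrr:
            m = mrrs[rng.integers(len(mrrs))]
            start = int(rng.integers(m.start, max(m.start + 1, m.end - length)))
            out.append(GenomicInterval(m.chrom, start, start + length))
        else:
            chrom = list(genome)[rng.integers(len(genome))]
            start = int(rng.integers(0, genome[chrom] - length))
            out.append(GenomicInterval(chrom, start, start + length))
    return out


# ---------------------------------------------------------------------------
# Full-scenario writer


def simulate_full(outdir, seed: int = 0, scale: float = 1.0) -> dict:
    """Write every input the pipeline consumes, plus a truth manifest.

    ``scale`` < 1 shrinks the scenario proportionally (used to keep smoke
    runs fast); the default is the full study condition. Returns the
    manifest dict (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_clusters = max(3, int(round(20 * scale)))
    n_isolated = max(20, int(round(500 * scale)))
    genome = make_genome(2, [int(10_000_000 * scale), int(5_000_000 * scale)], seed)
    chr_peaks, chr_loops = list(genome)
    # peaks live on one chromosome, Hi-C-like anchors on the other, so each
    # stage's planted truth stays uncontaminated by the other's features
    peak_genome = GenomeTable({chr_peaks: genome[chr_peaks]})
    loop_genome = GenomeTable({chr_loops: genome[chr_loops]})

    peaks, treatment, control, peak_truth = make_peaks_and_signal(
        peak_genome, n_clusters=n_clusters, n_isolated=n_isolated, seed=seed
    )
    write_bed(peaks, outdir / "h3k27me3_peaks.bed")
    write_signal(treatment, outdir / "h3k27me3_treatment.bedgraph")
    write_signal(control, outdir / "h3k27me3_control.bedgraph")
    write_bed(peak_truth.mrr_intervals, outdir / "truth_mrr.bed")

    loops, loop_states, itx_truth = make_interactions(
        loop_genome,
        n_interactions=int(5000 * max(scale, 0.2)),
        n_anchors=max(60, int(400 * scale)),
        seed=seed,
    )
    anchor_k27ac, anchor_k27me3 = mark_peaks_for_anchors(
        itx_truth.anchors, itx_truth.anchor_states, seed
    )
    write_bed(anchor_k27ac, outdir / "anchor_h3k27ac_peaks.bed")
    write_bed(anchor_k27me3, outdir / "anchor_h3k27me3_peaks.bed")
    gene_truth = make_genes_for_mrrs(peak_truth.mrr_intervals, genome, seed)
    write_bedpe(loops + gene_truth.extra_loops, outdir / "loops.bedpe")
    with open(outdir / "genes.bed", "w") as fh:
        for g in gene_truth.genes:
            fh.write(
                f"{g.chrom}\t{g.body.start}\t{g.body.end}\t{g.gene_id}\t.\t{g.strand}\n"
            )

    external = make_external_regions(peak_truth, genome, seed=seed)
    write_bed(external, outdir / "external_elements.bed")

    expr, spec_truth = make_expression(
        n_genes=int(500 * max(scale, 0.2)), seed=seed
    )
    expr.to_csv(outdir / "expression.tsv", sep="\t")
    spec_truth.to_csv(outdir / "truth_specificity.tsv", sep="\t")

    bait_chrom = list(genome)[0]
    mid = genome[bait_chrom] // 2
    bait = GenomicInterval(bait_chrom, mid - 2000, mid + 2000)
    tables, fourc_truth = make_fourc_pair(
        bait, genome, cis_span=min(3_000_000, genome[bait_chrom] // 3), seed=seed
    )
    for cond, reps in tables.items():
        for rep, df in reps.items():
            df.to_csv(outdir / f"fourc_{cond}_{rep}.tsv", sep="\t", index=False)

    with open(outdir / "chrom.sizes", "w") as fh:
        for c, l in genome.items():
            fh.write(f"{c}\t{l}\n")

    manifest = {
        "seed": seed,
        "scale": scale,
        "genome": dict(genome.items()),
        "n_planted_mrrs": len(peak_truth.mrr_intervals),
        "planted_log2_ratios": {
            "/".join(k): v for k, v in itx_truth.log2_ratios.items()
        },
        "gene_categories": gene_truth.categories,
        "fourc_bait": [bait.chrom, bait.start, bait.end],
        "fourc_status_counts": {
            s: sum(1 for v in fourc_truth.status.values() if v == s)
            for s in ("gained", "lost", "unchanged")
        },
        "files": sorted(p.name for p in outdir.iterdir()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
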