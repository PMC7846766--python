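"""End-to-end orchestration of the synthetic-data analysis.

Runs every stage against a directory of simulated inputs (as written by
:func:`silencerscape.simulate.simulate_full`) and writes one tidy table
per stage. Exists so the numbered analysis drivers, the end-to-end test
and the acceptance script all execute the same code path, including the
text-format round-trips (BED/bedGraph/BEDPE/TSV in, TSV out).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import fourc as fourc_mod
from . import mrr as mrr_mod
from . import shuffle as shuffle_mod
from . import signals as signals_mod
from . import states as states_mod
from .expression import specificity_frame
from .genome import (
    GenomicInterval,
    overlaps_any,
    read_bedpe,
    read_chrom_sizes,
    read_intervals,
    read_signal,
)
from .looping import classify_gene_mrr, make_gene_model

__all__ = ["run_pipeline"]


def run_pipeline(
    input_dir,
    output_dir,
    seed: int = 0,
    n_shuffles: int = 200,
) -> dict:
    """Run MRR calling → enrichment → looping → shuffle test → specificity →
    4C comparison → signal integration on a simulated input directory.

    Writes mrr_regions.tsv, mrr.bed, enrichment.tsv, associations.tsv,
    shuffle_report.tsv, specificity.tsv, fourc_comparison.tsv,
    fourc_proportions.tsv, integration_records.tsv, integration_tests.tsv
    and summary.json under ``output_dir``; returns the summary dict.
    """
    input_dir = Path(input_dir)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    genome = read_chrom_sizes(input_dir / "chrom.sizes")
    summary: dict = {"seed": seed}

    # --- MRR calling -------------------------------------------------------
    peaks = read_intervals(input_dir / "h3k27me3_peaks.bed", genome)
    treatment = read_signal(input_dir / "h3k27me3_treatment.bedgraph")
    control = read_signal(input_dir / "h3k27me3_control.bedgraph")
    regions, curve = mrr_mod.call_regions(peaks, treatment, control, mark="H3K27me3")
    mrr_intervals = [
        GenomicInterval(
            r.interval.chrom, r.interval.start, r.interval.end, name=f"MRR_{r.rank}"
        )
        for r in regions
        if r.is_rich
    ]
    region_table = pd.DataFrame(
        {
            "chrom": [r.interval.chrom for r in regions],
            "start": [r.interval.start for r in regions],
            "end": [r.interval.end for r in regions],
            "label": [r.label for r in regions],
            "score": [r.score for r in regions],
            "rank": [r.rank for r in regions],
            "n_constituents": [r.n_constituents for r in regions],
        }
    )
    region_table.to_csv(output_dir / "mrr_regions.tsv", sep="\t", index=False)
    from .genome import write_bed

    write_bed(mrr_intervals, output_dir / "mrr.bed")
    summary["n_stitched_regions"] = len(regions)
    summary["n_mrr"] = len(mrr_intervals)
    summary["cutoff_value"] = curve.cutoff_value

    # --- state-pair enrichment --------------------------------------------
    loops = states_mod.dedupe_interactions(read_bedpe(input_dir / "loops.bedpe"))
    labelled = states_mod.label_interactions(
        loops,
        k27ac_peaks=read_intervals(input_dir / "anchor_h3k27ac_peaks.bed"),
        k27me3_peaks=read_intervals(input_dir / "anchor_h3k27me3_peaks.bed"),
        mode="marks",
    )
    enrichment = states_mod.pair_enrichment(labelled)
    enrichment.table.to_csv(output_dir / "enrichment.tsv", sep="\t", index=False)
    summary["log2_obs_exp"] = {
        row.pair: None if np.isnan(row.log2_ratio) else row.log2_ratio
        for row in enrichment.table.itertuples()
    }

    # --- gene–MRR looping classes -----------------------------------------
    gene_models = []
    with open(input_dir / "genes.bed") as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            gene_models.append(
                make_gene_model(f[3], f[0], int(f[1]), int(f[2]),
                                f[5] if len(f) > 5 else "+")
            )
    assoc = classify_gene_mrr(gene_models, mrr_intervals, loops)
    assoc_table = pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in assoc],
            "mrr_id": [a.mrr_id for a in assoc],
            "category": [a.category for a in assoc],
        }
    )
    assoc_table.to_csv(output_dir / "associations.tsv", sep="\t", index=False)
    summary["n_associations"] = len(assoc)

    # --- external-list shuffle test ---------------------------------------
    external = read_intervals(input_dir / "external_elements.bed", genome)
    shuffle_result = shuffle_mod.permutation_overlap_test(
        external, mrr_intervals, genome, n_shuffles=n_shuffles, seed=seed
    )
    pd.DataFrame(
        {
            "actual_pct": [shuffle_result.actual_pct],
            "expected_pct_mean": [shuffle_result.expected_pcts.mean()],
            "expected_pct_sd": [shuffle_result.expected_pcts.std(ddof=1)],
            "t_test_p": [shuffle_result.p_value],
            "empirical_p": [shuffle_result.empirical_p],
            "n_shuffles": [shuffle_result.n_shuffles],
        }
    ).to_csv(output_dir / "shuffle_report.tsv", sep="\t", index=False)
    summary["overlap_actual_pct"] = shuffle_result.actual_pct
    summary["overlap_expected_pct_mean"] = float(shuffle_result.expected_pcts.mean())
    summary["overlap_empirical_p"] = shuffle_result.empirical_p
    summary["overlap_t_test_p"] = shuffle_result.p_value

    # --- expression specificity -------------------------------------------
    expr = pd.read_csv(input_dir / "expression.tsv", sep="\t", index_col=0)
    spec = specificity_frame(expr)
    spec.to_csv(output_dir / "specificity.tsv", sep="\t", index=False)
    summary["specificity_mean"] = float(spec["specificity"].mean())

    # --- differential 4C ---------------------------------------------------
    manifest = json.loads((input_dir / "manifest.json").read_text())
    bait = GenomicInterval(*manifest["fourc_bait"])
    pooled = {}
    for cond in ("control", "experiment"):
        reps = [
            fourc_mod.read_fourc_calls(
                input_dir / f"fourc_{cond}_rep{i}.tsv", f"rep{i}", cond
            )
            for i in (1, 2)
        ]
        pooled[cond] = fourc_mod.pool_replicates(reps)
    comparisons = fourc_mod.bait_distance(
        fourc_mod.compare_conditions(pooled["control"], pooled["experiment"]), bait
    )
    fourc_mod.comparisons_to_frame(comparisons).to_csv(
        output_dir / "fourc_comparison.tsv", sep="\t", index=False
    )
    proportions = fourc_mod.proportion_unchanged(comparisons)
    proportions.to_csv(output_dir / "fourc_proportions.tsv", sep="\t", index=False)
    dist = fourc_mod.distance_summary(comparisons)
    summary["fourc_counts"] = {
        s: sum(1 for c in comparisons if c.status == s)
        for s in ("gained", "lost", "unchanged")
    }
    summary["fourc_proportion_unchanged"] = {
        row.category: None if np.isnan(row.proportion_unchanged) else row.proportion_unchanged
        for row in proportions.itertuples()
    }
    summary["fourc_distance"] = dist

    # --- 4C × ChIP signal integration -------------------------------------
    # experiment-condition H3K27me3 = flat background: emulates global mark
    # depletion, so regions with planted peaks show negative deltas
    records, tests = signals_mod.integrate_fourc_chip(
        [c for c in comparisons if c.fragment.chrom in treatment.chroms],
        k27me3_tracks={"control": treatment, "experiment": control},
        k27ac_tracks={"control": control, "experiment": control},
        control_condition="control",
        experiment_condition="experiment",
    )
    records.to_csv(output_dir / "integration_records.tsv", sep="\t", index=False)
    tests.to_csv(output_dir / "integration_tests.tsv", sep="\t", index=False)

    # --- recovery vs planted truth ----------------------------------------
    truth_mrr = read_intervals(input_dir / "truth_mrr.bed")
    hit = overlaps_any(truth_mrr, mrr_intervals)
    fp = (~overlaps_any(mrr_intervals, truth_mrr)).sum() if mrr_intervals else 0
    summary["mrr_planted"] = len(truth_mrr)
    summary["mrr_recovered"] = int(hit.sum())
    summary["mrr_false_positives"] = int(fp)
    truth_spec = pd.read_csv(
        input_dir / "truth_specificity.tsv", sep="\t", index_col=0
    ).iloc[:, 0]
    summary["specificity_mean_abs_error"] = float(
        (spec.set_index("gene_id")["specificity"] - truth_spec).abs().mean()
    )

    with open(output_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
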