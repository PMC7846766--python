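"""Integrate 4C loop status with ChIP-seq signal areas at 4C regions.

Computes binned total signal areas (Σ Sig × BS) per 4C region per
condition, tertiles the regions on control-condition H3K27me3, and runs
paired Wilcoxon tests of control vs experiment areas per status group.
The experiment-condition H3K27me3 track is the flat background, so the
tests should flag a mark decrease wherever planted peaks coincide with
4C regions.
"""

import argparse
import json

from _common import ensure_inputs, results_dir
from silencerscape.fourc import bait_distance, compare_conditions, pool_replicates, read_fourc_calls
from silencerscape.genome import GenomicInterval, read_signal
from silencerscape.signals import integrate_fourc_chip


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    inputs = ensure_inputs(args.seed)
    manifest = json.loads((inputs / "manifest.json").read_text())
    bait = GenomicInterval(*manifest["fourc_bait"])
    pooled = {
        cond: pool_replicates(
            [
                read_fourc_calls(inputs / f"fourc_{cond}_rep{i}.tsv", f"rep{i}", cond)
                for i in (1, 2)
            ]
        )
        for cond in ("control", "experiment")
    }
    comparisons = bait_distance(
        compare_conditions(pooled["control"], pooled["experiment"]), bait
    )
    treatment = read_signal(inputs / "h3k27me3_treatment.bedgraph")
    flat = read_signal(inputs / "h3k27me3_control.bedgraph")
    records, tests = integrate_fourc_chip(
        [c for c in comparisons if c.fragment.chrom in treatment.chroms],
        k27me3_tracks={"control": treatment, "experiment": flat},
        k27ac_tracks={"control": flat, "experiment": flat},
        control_condition="control",
        experiment_condition="experiment",
    )
    print(f"{len(records)} 4C regions integrated")
    print(records["k27me3_tertile"].value_counts().to_string())
    print(tests.to_string(index=False))
    out = results_dir() / "integration_tests.tsv"
    tests.to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
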