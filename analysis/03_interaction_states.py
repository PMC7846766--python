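"""Chromatin-state pair enrichment of the synthetic loop list.

Labels loop anchors A/R/B/Q from the anchor-matched H3K27ac/H3K27me3
peak files, computes observed vs marginal-expected pair proportions, and
compares the log2(Obs/Exp) values with the planted ones: like-like pairs
(AA/RR/BB/QQ) were boosted 3× at generation, so their ratios should come
out positive and mixed pairs negative.
"""

import argparse
import json

from _common import ensure_inputs, results_dir
from silencerscape.genome import read_bedpe, read_intervals
from silencerscape.states import dedupe_interactions, label_interactions, pair_enrichment


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    inputs = ensure_inputs(args.seed)
    loops = dedupe_interactions(read_bedpe(inputs / "loops.bedpe"))
    labelled = label_interactions(
        loops,
        k27ac_peaks=read_intervals(inputs / "anchor_h3k27ac_peaks.bed"),
        k27me3_peaks=read_intervals(inputs / "anchor_h3k27me3_peaks.bed"),
        mode="marks",
    )
    result = pair_enrichment(labelled)
    planted = json.loads((inputs / "manifest.json").read_text())["planted_log2_ratios"]
    table = result.table.assign(
        planted_log2_ratio=[planted.get(p) for p in result.table["pair"]]
    )
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    diag = table[table.pair.str.split("/").str[0] == table.pair.str.split("/").str[1]]
    print(f"\nlike-like ratios all positive: {bool((diag.log2_ratio > 0).all())}")
    out = results_dir() / "state_pair_enrichment.tsv"
    table.to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
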