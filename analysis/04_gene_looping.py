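"""Classify gene–MRR looping relationships and build the control gene set.

Each planted gene sits in one of three configurations relative to an
MRR — promoter inside it (proximal), joined only by a long-range loop
(distal), or promoter inside with a loop between two parts of the same
MRR (internal) — and the classifier should recover all three from the
called MRRs and the loop list alone.
"""

import argparse
import json

import pandas as pd

from _common import ensure_inputs, results_dir
from silencerscape.genome import GenomicInterval, read_bedpe, read_intervals
from silencerscape.looping import build_control_genes, classify_gene_mrr, make_gene_model


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    inputs = ensure_inputs(args.seed)
    mrrs = read_intervals(inputs / "truth_mrr.bed")
    mrrs = [
        GenomicInterval(m.chrom, m.start, m.end, name=f"MRR_{i}")
        for i, m in enumerate(mrrs)
    ]
    loops = read_bedpe(inputs / "loops.bedpe")
    genes = []
    with open(inputs / "genes.bed") as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            genes.append(make_gene_model(f[3], f[0], int(f[1]), int(f[2]), f[5]))
    assoc = classify_gene_mrr(genes, mrrs, loops)
    truth = json.loads((inputs / "manifest.json").read_text())["gene_categories"]
    frame = pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in assoc],
            "mrr_id": [a.mrr_id for a in assoc],
            "category": [a.category for a in assoc],
            "planted": [truth.get(a.gene_id) for a in assoc],
        }
    )
    matched = sum(
        1 for g, cat in truth.items()
        if cat in set(frame.loc[frame.gene_id == g, "category"])
    )
    print(frame.to_string(index=False))
    print(f"\nplanted categories recovered: {matched}/{len(truth)}")

    counts = frame.groupby("gene_id")["category"].first().value_counts()
    n_per_cat = [int(counts.get(c, 0)) for c in ("proximal", "distal", "internal")]
    controls = build_control_genes(
        genes, [], [], loops, n_per_cat, seed=args.seed
    )
    print(f"control set: {len(controls)} genes "
          f"(floor of mean of category sizes {n_per_cat})")
    out = results_dir() / "gene_mrr_associations.tsv"
    frame.to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
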