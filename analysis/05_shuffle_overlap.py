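"""Permutation overlap test of the external element list against MRRs.

30% of the external elements were planted inside MRR clusters, so the
actual overlap percentage should sit far above the same-chromosome
shuffle null; both the one-sided one-sample t-test and the empirical
permutation p-value are reported.
"""

import argparse

import pandas as pd

from _common import ensure_inputs, results_dir
from silencerscape.genome import read_chrom_sizes, read_intervals
from silencerscape.shuffle import permutation_overlap_test


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-shuffles", type=int, default=1000)
    args = parser.parse_args()
    inputs = ensure_inputs(args.seed)
    genome = read_chrom_sizes(inputs / "chrom.sizes")
    target = read_intervals(inputs / "external_elements.bed", genome)
    query = read_intervals(inputs / "truth_mrr.bed", genome)
    result = permutation_overlap_test(
        target, query, genome, n_shuffles=args.n_shuffles, seed=args.seed
    )
    print(f"actual overlap: {result.actual_pct:.2f}% of {len(target)} elements")
    print(f"shuffle null  : {result.expected_pcts.mean():.2f}% "
          f"± {result.expected_pcts.std(ddof=1):.2f}% ({result.n_shuffles} shuffles)")
    print(f"one-sided t-test p = {result.p_value:.3g}, "
          f"empirical p = {result.empirical_p:.3g}")
    out = results_dir() / "shuffle_overlap.tsv"
    pd.DataFrame(
        {
            "actual_pct": [result.actual_pct],
            "expected_pct_mean": [result.expected_pcts.mean()],
            "expected_pct_sd": [result.expected_pcts.std(ddof=1)],
            "t_test_p": [result.p_value],
            "empirical_p": [result.empirical_p],
            "n_shuffles": [result.n_shuffles],
        }
    ).to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
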