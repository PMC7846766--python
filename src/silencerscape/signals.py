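"""ChIP-seq signal areas over regions and the 4C-status × histone-state tables.

Regions are tiled in fixed-size bins (the final bin truncated to the
region edge); the bin value Sig is the mean coverage over the bin, and

    Total Signal Area = Σ Sig_i × BS_i

with BS the bin width, so at bin size 1 the area equals the plain
value-bp sum over the region. 4C regions are additionally stratified into
high/medium/low tertiles of their control-condition signal.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomicInterval, IntervalIndex, SignalTrack
from .fourc import FourCComparison

__all__ = [
    "BinnedSignal",
    "signal_area",
    "tertile_labels",
    "tf_zscore_matrix",
    "integrate_fourc_chip",
]

DEFAULT_BIN_SIZE = 50


@dataclass
class BinnedSignal:
    region: GenomicInterval
    bin_size: int
    bin_starts: np.ndarray
    bin_widths: np.ndarray
    values: np.ndarray  # mean coverage per bin

    @property
    def total_area(self) -> float:
        return float((self.values * self.bin_widths).sum())


def signal_area(
    track: SignalTrack, region: GenomicInterval, bin_size: int = DEFAULT_BIN_SIZE
) -> BinnedSignal:
    """Tile a region left-to-right in ``bin_size`` bp bins and bin the signal.

    The final bin is truncated at the region end and its true width enters
    the area product, so total_area is exactly the value-bp mass of the
    region regardless of bin size.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be ≥ 1")
    starts = np.arange(region.start, region.end, bin_size, dtype=np.int64)
    ends = np.minimum(starts + bin_size, region.end)
    values = np.array(
        [track.mean_in(region.chrom, int(s), int(e)) for s, e in zip(starts, ends)]
    )
    return BinnedSignal(
        region=region,
        bin_size=bin_size,
        bin_starts=starts,
        bin_widths=(ends - starts).astype(float),
        values=values,
    )


def tertile_labels(values: Sequence[float]) -> list[str]:
    """high/medium/low by the 1/3 and 2/3 quantiles (linear interpolation).

    Assignment checks low (≤ q1/3) before high (≥ q2/3), so when the
    boundaries coincide (e.g. all values equal) everything lands in low,
    with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need ≥3 values for tertiles")
    q1, q2 = np.quantile(x, [1 / 3, 2 / 3])
    if q1 == q2:
        warnings.warn(
            "degenerate tertile boundaries (q1/3 = q2/3); low-before-high "
            "precedence applies",
            stacklevel=2,
        )
    labels = []
    for v in x:
        if v <= q1:
            labels.append("low")
        elif v >= q2:
            labels.append("high")
        else:
            labels.append("medium")
    return labels


def tf_zscore_matrix(
    regions: Sequence[GenomicInterval],
    tf_peaksets: Mapping[str, Sequence[GenomicInterval]],
) -> pd.DataFrame:
    """Regions × TF matrix of Z-scored overlapping-peak counts.

    Per TF, the count of its peaks overlapping each region is standardized
    across regions: z = (count − mean)/sd, with z = 0 everywhere when the
    counts are constant (sd = 0).
    """
    if len(regions) < 2:
        raise ValueError("need ≥2 regions to standardize")
    data = {}
    for tf, peaks in tf_peaksets.items():
        index = IntervalIndex(peaks)
        counts = np.array([index.count(r) for r in regions], dtype=float)
        sd = counts.std()  # population sd across regions
        data[tf] = (counts - counts.mean()) / sd if sd > 0 else np.zeros_like(counts)
    names = [r.name or f"region_{i}" for i, r in enumerate(regions)]
    return pd.DataFrame(data, index=names)


def integrate_fourc_chip(
    comparisons: Sequence[FourCComparison],
    k27me3_tracks: Mapping[str, SignalTrack],
    k27ac_tracks: Mapping[str, SignalTrack],
    control_condition: str,
    experiment_condition: str,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join 4C status with per-condition histone signal at each 4C region.

    Per region: total signal area per mark per condition, tertile labels
    computed on the control condition within the comparison cohort, and a
    log10(RPM) column per condition. Also runs a paired Wilcoxon
    signed-rank test of control vs experiment areas per mark within each
    status group (and in the pooled "changed" group).

    Returns (per-region records, per-group paired-test table).
    """
    for cond in (control_condition, experiment_condition):
        if cond not in k27me3_tracks or cond not in k27ac_tracks:
            raise ValueError(f"missing signal track for condition {cond!r}")
    rows = []
    for c in comparisons:
        record = {
            "chrom": c.fragment.chrom,
            "start": c.fragment.start,
            "end": c.fragment.end,
            "fourc_status": c.status,
        }
        for mark, tracks in (("k27me3", k27me3_tracks), ("k27ac", k27ac_tracks)):
            for label, cond in (
                ("control", control_condition),
                ("experiment", experiment_condition),
            ):
                record[f"{mark}_area_{label}"] = signal_area(
                    tracks[cond], c.fragment, bin_size
                ).total_area
        for label, rpms in (
            ("control", c.rpm_control),
            ("experiment", c.rpm_experiment),
        ):
            mean_rpm = np.mean(list(rpms.values())) if rpms else np.nan
            record[f"rpm_log10_{label}"] = (
                float(np.log10(mean_rpm)) if mean_rpm and mean_rpm > 0 else float("nan")
            )
        rows.append(record)
    records = pd.DataFrame(rows)
    records["k27me3_tertile"] = tertile_labels(records["k27me3_area_control"])
    records["k27ac_tertile"] = tertile_labels(records["k27ac_area_control"])
    records["k27me3_delta"] = (
        records["k27me3_area_experiment"] - records["k27me3_area_control"]
    )
    records["k27ac_delta"] = (
        records["k27ac_area_experiment"] - records["k27ac_area_control"]
    )

    groups = {
        "gained": records["fourc_status"] == "gained",
        "lost": records["fourc_status"] == "lost",
        "unchanged": records["fourc_status"] == "unchanged",
        "changed": records["fourc_status"].isin(["gained", "lost"]),
    }
    test_rows = []
    for mark in ("k27me3", "k27ac"):
        for group, mask in groups.items():
            sub = records.loc[mask]
            n = len(sub)
            deltas = sub[f"{mark}_delta"].to_numpy()
            if n >= 2 and np.any(deltas != 0):
                p = float(
                    stats.wilcoxon(
                        sub[f"{mark}_area_control"],
                        sub[f"{mark}_area_experiment"],
                    ).pvalue
                )
            else:
                p = float("nan")
            test_rows.append(
                {
                    "mark": mark,
                    "group": group,
                    "n": n,
                    "median_delta": float(np.median(deltas)) if n else float("nan"),
                    "wilcoxon_paired_p": p,
                }
            )
    return records, pd.DataFrame(test_rows)
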