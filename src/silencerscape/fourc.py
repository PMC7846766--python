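"""Differential 4C-seq loop analysis between two conditions.

Significant bait–fragment interactions (called upstream against a
restriction-digested genome background) are pooled across replicates per
condition at p < 0.05, then compared by exact fragment identity:

* gained — present only in the experimental condition,
* lost — present only in the control condition,
* unchanged — present in both.

Cis fragments are summarized by distance to the bait (midpoint to
midpoint) and split into distance tertiles (short/intermediate/long)
computed over the comparison's union set; trans fragments keep their
status but are excluded from all distance analytics.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomicInterval

__all__ = [
    "FourCCall",
    "FourCComparison",
    "DEFAULT_ALPHA",
    "pool_replicates",
    "compare_conditions",
    "bait_distance",
    "proportion_unchanged",
    "distance_summary",
    "read_fourc_calls",
]

DEFAULT_ALPHA = 0.05

FragmentKey = tuple[str, int, int]


@dataclass(frozen=True)
class FourCCall:
    fragment: GenomicInterval
    rpm: float
    p_value: float
    replicate_id: str
    condition: str | None = None
    bait: GenomicInterval | None = None

    def __post_init__(self):
        if not (0 <= self.p_value <= 1):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if self.rpm < 0:
            raise ValueError("rpm must be ≥ 0")

    @property
    def key(self) -> FragmentKey:
        f = self.fragment
        return (f.chrom, f.start, f.end)


@dataclass
class FourCComparison:
    fragment: GenomicInterval
    status: str  # gained | lost | unchanged
    rpm_control: dict[str, float] = field(default_factory=dict)
    rpm_experiment: dict[str, float] = field(default_factory=dict)
    distance_bp: float | None = None  # None until bait_distance; trans stays None
    is_trans: bool = False
    distance_category: str | None = None  # short | intermediate | long | trans


def read_fourc_calls(path, replicate_id: str, condition: str | None = None) -> list[FourCCall]:
    """Read a per-replicate call table: chrom, start, end, rpm, p_value (TSV)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "rpm", "p_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        FourCCall(
            fragment=GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            rpm=float(r.rpm),
            p_value=float(r.p_value),
            replicate_id=replicate_id,
            condition=condition,
        )
        for r in df.itertuples()
    ]


def pool_replicates(
    replicates: Sequence[Sequence[FourCCall]], alpha: float = DEFAULT_ALPHA
) -> dict[FragmentKey, dict[str, float]]:
    """Union of per-replicate significant fragments (p < alpha).

    Returns fragment key → {replicate_id: rpm} for every fragment
    significant in at least one replicate; per-replicate RPMs of the
    significant calls are carried along.
    """
    if not replicates:
        raise ValueError("need ≥1 replicate")
    baits = {
        (c.bait.chrom, c.bait.start, c.bait.end)
        for calls in replicates
        for c in calls
        if c.bait is not None
    }
    if len(baits) > 1:
        raise ValueError(f"inconsistent baits across replicates: {sorted(baits)}")
    pooled: dict[FragmentKey, dict[str, float]] = {}
    for calls in replicates:
        for call in calls:
            if call.p_value < alpha:
                pooled.setdefault(call.key, {})[call.replicate_id] = call.rpm
    return pooled


def compare_conditions(
    control_set: Mapping[FragmentKey, Mapping[str, float]],
    experiment_set: Mapping[FragmentKey, Mapping[str, float]],
) -> list[FourCComparison]:
    """Exact set algebra on fragment keys; statuses partition the union."""
    out = []
    for key in sorted(set(control_set) | set(experiment_set)):
        in_c, in_e = key in control_set, key in experiment_set
        status = "unchanged" if (in_c and in_e) else ("lost" if in_c else "gained")
        out.append(
            FourCComparison(
                fragment=GenomicInterval(*key),
                status=status,
                rpm_control=dict(control_set.get(key, {})),
                rpm_experiment=dict(experiment_set.get(key, {})),
            )
        )
    return out


def bait_distance(
    comparisons: Sequence[FourCComparison], bait: GenomicInterval
) -> list[FourCComparison]:
    """Attach bait distances and tertile categories (in place; returns input).

    Distance = |fragment midpoint − bait midpoint| for fragments on the
    bait's chromosome; tertile breakpoints are the 1/3 and 2/3 quantiles
    (linear interpolation) of cis distances over the union set. Trans
    fragments are flagged and excluded from the tertiles.
    """
    cis = []
    for cmp_ in comparisons:
        if cmp_.fragment.chrom != bait.chrom:
            cmp_.is_trans = True
            cmp_.distance_bp = None
            cmp_.distance_category = "trans"
        else:
            cmp_.is_trans = False
            cmp_.distance_bp = abs(cmp_.fragment.midpoint - bait.midpoint)
            cis.append(cmp_)
    if cis:
        dists = np.array([c.distance_bp for c in cis])
        q1, q2 = np.quantile(dists, [1 / 3, 2 / 3])
        for c in cis:
            if c.distance_bp <= q1:
                c.distance_category = "short"
            elif c.distance_bp >= q2:
                c.distance_category = "long"
            else:
                c.distance_category = "intermediate"
    return list(comparisons)


def proportion_unchanged(
    comparisons: Sequence[FourCComparison], min_category_size: int = 3
) -> pd.DataFrame:
    """Unchanged/total per distance category; small categories are dropped.

    Categories with fewer than ``min_category_size`` interactions are
    excluded (reported with proportion NaN and excluded=True).
    """
    rows = []
    for cat in ("short", "intermediate", "long"):
        members = [c for c in comparisons if c.distance_category == cat]
        total = len(members)
        unchanged = sum(1 for c in members if c.status == "unchanged")
        rows.append(
            {
                "category": cat,
                "n_total": total,
                "n_unchanged": unchanged,
                "proportion_unchanged": (
                    unchanged / total if total >= min_category_size else float("nan")
                ),
                "excluded": total < min_category_size,
            }
        )
    return pd.DataFrame(rows)


def distance_summary(comparisons: Sequence[FourCComparison]) -> dict:
    """Mean/median bait distance for changed (gained ∪ lost) vs unchanged.

    Cis fragments only. Includes a rank-based two-sample comparison
    (Mann–Whitney U, changed > unchanged) when both groups are non-empty.
    """
    cis = [c for c in comparisons if not c.is_trans and c.distance_bp is not None]
    if not cis:
        raise ValueError("no cis comparisons with distances")
    changed = np.array([c.distance_bp for c in cis if c.status in ("gained", "lost")])
    unchanged = np.array([c.distance_bp for c in cis if c.status == "unchanged"])

    def _stats(arr):
        if arr.size == 0:
            return {"n": 0, "mean": float("nan"), "median": float("nan")}
        return {"n": int(arr.size), "mean": float(arr.mean()), "median": float(np.median(arr))}

    result = {"changed": _stats(changed), "unchanged": _stats(unchanged)}
    if changed.size and unchanged.size:
        u = stats.mannwhitneyu(changed, unchanged, alternative="greater")
        result["mannwhitney_p_changed_greater"] = float(u.pvalue)
    else:
        result["mannwhitney_p_changed_greater"] = float("nan")
    return result


def comparisons_to_frame(comparisons: Sequence[FourCComparison]) -> pd.DataFrame:
    """Flat table for export: one row per fragment with status and distance."""
    rows = []
    for c in comparisons:
        rpms_c = list(c.rpm_control.values())
        rpms_e = list(c.rpm_experiment.values())
        rows.append(
            {
                "chrom": c.fragment.chrom,
                "start": c.fragment.start,
                "end": c.fragment.end,
                "status": c.status,
                "distance_bp": c.distance_bp if c.distance_bp is not None else "",
                "distance_category": c.distance_category or "",
                "rpm_control_mean": float(np.mean(rpms_c)) if rpms_c else float("nan"),
                "rpm_experiment_mean": float(np.mean(rpms_e)) if rpms_e else float("nan"),
            }
        )
    return pd.DataFrame(rows)
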