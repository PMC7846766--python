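"""Genomic interval data model, format I/O, and the overlap engine.

All coordinates are 0-based half-open (BED convention). Any 1-based input
must be converted at parse time; nothing downstream ever reasons about
inclusive ends. Chromosome names are matched by exact string comparison —
there is no ``chr`` aliasing.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeTable",
    "GenomicInterval",
    "SignalTrack",
    "IntervalIndex",
    "read_chrom_sizes",
    "read_intervals",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "read_signal",
    "overlaps_any",
    "count_overlaps",
    "overlap_fraction_of_shorter",
]


class GenomeTable(Mapping):
    """Chromosome name → length (bp). Names unique, lengths positive."""

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = list(sizes.items()) if isinstance(sizes, Mapping) else list(sizes)
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome table")
        for name, length in items:
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self._sizes = {str(n): int(l) for n, l in items}

    def __getitem__(self, key: str) -> int:
        return self._sizes[key]

    def __iter__(self):
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __repr__(self) -> str:
        return f"GenomeTable({self._sizes!r})"


@dataclass(frozen=True)
class GenomicInterval:
    """A located feature: ``chrom:[start, end)`` with optional name/score."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and max(self.start, other.start) < min(self.end, other.end)
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def validate_against(self, genome: GenomeTable) -> None:
        if self.chrom not in genome:
            raise ValueError(f"chromosome {self.chrom!r} not in genome table")
        if self.end > genome[self.chrom]:
            raise ValueError(
                f"{self.chrom}:{self.start}-{self.end} exceeds chromosome "
                f"length {genome[self.chrom]}"
            )


def _sort_key(iv: GenomicInterval):
    return (iv.chrom, iv.start, iv.end)


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=_sort_key)


class IntervalIndex:
    """Per-chromosome sorted-array index answering membership and count queries.

    Built once per subject set; queries are vectorized with ``searchsorted``.
    Counting uses the line-sweep identity #overlaps = #(start < qend) −
    #(end ≤ qstart), valid because intervals live on a line.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends_sorted: dict[str, np.ndarray] = {}
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            starts = np.sort(np.array([iv.start for iv in ivs], dtype=np.int64))
            ends = np.sort(np.array([iv.end for iv in ivs], dtype=np.int64))
            self._starts[chrom] = starts
            self._ends_sorted[chrom] = ends
            # merged runs for fast any-overlap tests
            order = sorted(ivs, key=lambda iv: iv.start)
            m_starts, m_ends = [], []
            for iv in order:
                if m_ends and iv.start <= m_ends[-1]:
                    m_ends[-1] = max(m_ends[-1], iv.end)
                else:
                    m_starts.append(iv.start)
                    m_ends.append(iv.end)
            self._merged[chrom] = (
                np.array(m_starts, dtype=np.int64),
                np.array(m_ends, dtype=np.int64),
            )

    def any_overlap(self, iv: GenomicInterval) -> bool:
        merged = self._merged.get(iv.chrom)
        if merged is None:
            return False
        m_starts, m_ends = merged
        idx = int(np.searchsorted(m_starts, iv.end, side="left"))
        return idx > 0 and m_ends[idx - 1] > iv.start

    def count(self, iv: GenomicInterval) -> int:
        starts = self._starts.get(iv.chrom)
        if starts is None:
            return 0
        n_start_before = int(np.searchsorted(starts, iv.end, side="left"))
        n_end_before = int(
            np.searchsorted(self._ends_sorted[iv.chrom], iv.start, side="right")
        )
        return n_start_before - n_end_before


def overlaps_any(
    query: Iterable[GenomicInterval], subject: Iterable[GenomicInterval]
) -> np.ndarray:
    """Boolean per query interval: does it share ≥1 bp with any subject interval?"""
    index = IntervalIndex(subject)
    return np.array([index.any_overlap(iv) for iv in query], dtype=bool)


def count_overlaps(
    query: Iterable[GenomicInterval], subject: Iterable[GenomicInterval]
) -> np.ndarray:
    """Number of subject intervals overlapping each query interval (≥1 bp)."""
    index = IntervalIndex(subject)
    return np.array([index.count(iv) for iv in query], dtype=np.int64)


def overlap_fraction_of_shorter(a: GenomicInterval, b: GenomicInterval) -> float:
    """Overlap in bp divided by the length of the shorter interval."""
    return a.overlap_bp(b) / min(len(a), len(b))


# ---------------------------------------------------------------------------
# Signal tracks


class SignalTrack:
    """Sparse nonnegative coverage: sorted, non-overlapping runs per chromosome.

    Absent coverage reads as 0. Values are taken as already depth-normalized
    (RPM/RPKM-style); no library-size scaling happens here.
    """

    def __init__(self, runs: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in runs.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise ValueError(f"empty run on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(
                    f"overlapping runs on {chrom}: ambiguous coverage"
                )
            if np.any(values < 0):
                raise ValueError(f"negative signal value on {chrom}")
            self._runs[chrom] = (starts, ends, values)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SignalTrack":
        runs = {}
        for chrom, sub in df.groupby(df.columns[0], sort=False):
            runs[str(chrom)] = (
                sub.iloc[:, 1].to_numpy(np.int64),
                sub.iloc[:, 2].to_numpy(np.int64),
                sub.iloc[:, 3].to_numpy(float),
            )
        return cls(runs)

    @classmethod
    def constant(cls, genome: GenomeTable, value: float) -> "SignalTrack":
        return cls(
            {
                chrom: (np.array([0]), np.array([length]), np.array([value]))
                for chrom, length in genome.items()
            }
        )

    @property
    def chroms(self) -> list[str]:
        return list(self._runs)

    def total_mass(self) -> float:
        return float(
            sum(((e - s) * v).sum() for s, e, v in self._runs.values())
        )

    def region_signal(self, region: GenomicInterval) -> float:
        """Σ over overlapped runs of value × overlapped bp (value-bp units)."""
        runs = self._runs.get(region.chrom)
        if runs is None:
            return 0.0
        starts, ends, values = runs
        i0 = int(np.searchsorted(ends, region.start, side="right"))
        i1 = int(np.searchsorted(starts, region.end, side="left"))
        if i0 >= i1:
            return 0.0
        s = np.maximum(starts[i0:i1], region.start)
        e = np.minimum(ends[i0:i1], region.end)
        return float(((e - s) * values[i0:i1]).sum())

    def mean_in(self, chrom: str, start: int, end: int) -> float:
        """Mean per-bp value over [start, end), counting uncovered bp as 0."""
        return self.region_signal(GenomicInterval(chrom, start, end)) / (end - start)

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for chrom, (starts, ends, values) in self._runs.items():
            frames.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": ends, "value": values}
                )
            )
        if not frames:
            return pd.DataFrame(columns=["chrom", "start", "end", "value"])
        return pd.concat(frames, ignore_index=True)


def region_signal(track: SignalTrack, region: GenomicInterval) -> float:
    return track.region_signal(region)


# ---------------------------------------------------------------------------
# File formats


def read_chrom_sizes(path) -> GenomeTable:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return GenomeTable(zip(df["chrom"].astype(str), df["length"].astype(int)))


def read_intervals(path, genome: GenomeTable | None = None) -> list[GenomicInterval]:
    """Read BED3+ / ENCODE broadPeak into validated, sorted intervals.

    broadPeak column 7 (signalValue) is kept as ``score``; BED column 5
    is used otherwise. Column 4 is kept as ``name`` when present.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected ≥3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            name = fields[3] if len(fields) >= 4 and fields[3] != "." else None
            score: float | None = None
            if len(fields) >= 9:  # broadPeak: signalValue in column 7
                score = float(fields[6])
            elif len(fields) >= 5 and fields[4] != ".":
                score = float(fields[4])
            try:
                iv = GenomicInterval(chrom, start, end, name=name, score=score)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            intervals.append(iv)
    if genome is not None:
        unmatched = sorted({iv.chrom for iv in intervals} - set(genome))
        if unmatched:
            warnings.warn(
                f"{path}: chromosomes not in genome table: {unmatched}",
                stacklevel=2,
            )
        for iv in intervals:
            if iv.chrom in genome:
                iv.validate_against(genome)
    return sort_intervals(intervals)


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\n")


def read_signal(path) -> SignalTrack:
    """Read a 4-column bedGraph into a SignalTrack (overlapping runs rejected)."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    if df.empty:
        return SignalTrack({})
    return SignalTrack.from_dataframe(df)


def write_signal(track: SignalTrack, path) -> None:
    track.to_dataframe().to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """Read two-anchor loop records: chrom1 start1 end1 chrom2 start2 end2 [score]."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected ≥6 columns")
            a1 = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            a2 = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
            pairs.append((a1, a2))
    return pairs


def write_bedpe(
    pairs: Iterable[tuple[GenomicInterval, GenomicInterval]], path
) -> None:
    with open(path, "w") as fh:
        for a1, a2 in pairs:
            fh.write(
                f"{a1.chrom}\t{a1.start}\t{a1.end}\t"
                f"{a2.chrom}\t{a2.start}\t{a2.end}\n"
            )
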