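import numpy as np
import pytest

from silencerscape.genome import GenomeTable, GenomicInterval, SignalTrack


@pytest.fixture
def toy_genome():
    return GenomeTable({"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_intervals(rng, n, chrom="chr1", chrom_len=100_000, max_len=500):
    out = []
    for _ in range(n):
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, chrom_len - length))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def dense_signal(track: SignalTrack, chrom: str, length: int) -> np.ndarray:
    """Per-bp expansion of a track — the brute-force oracle for signal sums."""
    dense = np.zeros(length)
    df = track.to_dataframe()
    for row in df[df["chrom"] == chrom].itertuples():
        dense[row.start : row.end] = row.value
    return dense
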