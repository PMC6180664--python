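import numpy as np
import pytest

from lnckit import SimulationConfig, simulate
from lnckit.intervals import GenomicInterval, TranscriptModel, make_transcript


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Default simulated dataset with expression noise disabled, so planted
    differential effects are exact."""
    return simulate(SimulationConfig(seed=1, fpkm_noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default simulated dataset (lognormal expression noise on)."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture()
def table1_path(tmp_path):
    from lnckit import write_fixture_table1

    path = tmp_path / "del_table.tsv"
    write_fixture_table1(path)
    return path


def random_transcript(
    rng: np.random.Generator,
    tid: str,
    chroms=("chr1", "chr2"),
    span=50_000,
) -> TranscriptModel:
    """A random small multi-exon transcript for property tests."""
    chrom = chroms[int(rng.integers(len(chroms)))]
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(1, 5))
    pos = int(rng.integers(0, span))
    coords = []
    for _ in range(n_exons):
        length = int(rng.integers(50, 400))
        coords.append((pos, pos + length))
        pos += length + int(rng.integers(30, 500))
    return make_transcript(tid, f"LOC_{tid}", chrom, strand, coords)


def brute_force_overlap(query: TranscriptModel, features, strand_mode, level):
    """Exhaustive all-pairs reimplementation of overlap_query."""
    if query.strand == "." and strand_mode != "any":
        return []
    out = []
    for f in features:
        if f.chrom != query.chrom:
            continue
        if strand_mode == "same" and f.strand != query.strand:
            continue
        if strand_mode == "opposite" and (
            f.strand == "." or f.strand == query.strand
        ):
            continue
        if level == "exon":
            a_ivs, b_ivs = query.exons, f.exons
        else:
            a_ivs, b_ivs = (query.interval,), (f.interval,)
        bp = sum(
            max(0, min(a.end, b.end) - max(a.start, b.start))
            for a in a_ivs
            for b in b_ivs
        )
        if bp >= 1:
            out.append((f.transcript_id, bp))
    return sorted(out)
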