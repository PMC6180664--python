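"""Transcript sequences: FASTA I/O, ORF finding and hexamer-usage scoring.

The ORF and hexamer scorers form the built-in coding-potential panel used
when no external score tables are supplied. They follow the classic
hexamer log-likelihood-ratio idea (coding vs noncoding hexamer usage) and
are deliberately simple; external tool scores can always be ingested
through a ScorePanel instead.
"""

from __future__ import annotations

import itertools
import math
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
HEXAMERS = tuple(
    "".join(p) for p in itertools.product(NUCLEOTIDES, repeat=6)
)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by record id (transcript_id)."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=tid, description="")
        for tid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def _check_nucleotides(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return seq


def longest_orf(seq: str) -> int:
    """Length in nt of the longest ATG-to-stop ORF over the three forward
    frames, stop codon included; 0 if no complete ORF exists.

    Codons containing N are treated as neither start nor stop.
    """
    seq = _check_nucleotides(seq)
    best = 0
    for frame in range(3):
        open_start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if open_start is not None:
                    best = max(best, i + 3 - open_start)
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = i
    return best


def longest_orf_span(seq: str) -> tuple[int, int] | None:
    """(start, end) of the longest complete ORF, or None."""
    seq = _check_nucleotides(seq)
    best: tuple[int, int] | None = None
    for frame in range(3):
        open_start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if open_start is not None:
                    if best is None or i + 3 - open_start > best[1] - best[0]:
                        best = (open_start, i + 3)
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = i
    return best


def hexamer_score(
    seq: str,
    coding_table: Mapping[str, float],
    noncoding_table: Mapping[str, float],
) -> float:
    """Mean log(p_coding / p_noncoding) over sliding hexamers.

    Within the longest complete ORF the window advances by 3 (in-frame
    hexamers); if the sequence has no ORF the full sequence is scanned with
    step 1. Positive scores are coding-like. Hexamers containing N are
    skipped; sequences shorter than 6 nt score 0 with a warning.
    """
    seq = _check_nucleotides(seq)
    if len(seq) < 6:
        warnings.warn("sequence shorter than 6 nt; hexamer score is 0")
        return 0.0
    span = longest_orf_span(seq)
    if span is not None and span[1] - span[0] >= 6:
        lo, hi = span
        step = 3
    else:
        lo, hi, step = 0, len(seq), 1
    ratios = []
    for i in range(lo, hi - 5, step):
        hexamer = seq[i : i + 6]
        if "N" in hexamer:
            continue
        ratios.append(
            math.log(coding_table[hexamer] / noncoding_table[hexamer])
        )
    if not ratios:
        return 0.0
    return float(np.mean(ratios))


def default_hexamer_tables() -> tuple[dict[str, float], dict[str, float]]:
    """A deterministic (coding, noncoding) hexamer-frequency pair.

    Both tables are product measures over per-nucleotide compositions: the
    coding model is GC-rich (as coding exons tend to be), the noncoding
    model AT-rich. Each sums to 1 over the 4096 hexamers, and because the
    bias is compositional the log-likelihood-ratio score is robust to the
    reading frame of the scanning window. These are synthetic defaults for
    the built-in scorer, not trained on any genome.
    """
    f_coding = {"A": 0.16, "C": 0.34, "G": 0.34, "T": 0.16}
    f_noncoding = {"A": 0.30, "C": 0.20, "G": 0.20, "T": 0.30}
    coding = {h: math.prod(f_coding[x] for x in h) for h in HEXAMERS}
    noncoding = {h: math.prod(f_noncoding[x] for x in h) for h in HEXAMERS}
    return coding, noncoding


def sample_from_hexamer_table(
    table: Mapping[str, float], length: int, rng: np.random.Generator
) -> str:
    """Concatenate hexamers drawn from a hexamer-frequency table until the
    requested length is reached (truncated to length)."""
    probs = np.array([table[h] for h in HEXAMERS])
    probs = probs / probs.sum()
    n = length // 6 + 1
    idx = rng.choice(4096, size=n, p=probs)
    return "".join(HEXAMERS[i] for i in idx)[:length]
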