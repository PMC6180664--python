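"""Fully labelled miniature datasets for exercising the whole pipeline.

The generator plants every transcript class the identification cascade
distinguishes (sense-overlapping, single-exon, short, coding-like,
small-RNA hits, known lncRNAs, intergenic and antisense lncRNAs), builds a
2-condition x 3-timepoint x 2-replicate FPKM matrix with planted
differential effects (including treatment-only "Inf" cases) and plants
cis-proximal and trans-correlated protein-coding targets — all with ground
truth attached, deterministic given the seed.

Placement keeps unrelated loci separated by more than the cis window, so
planted target sets are exactly recoverable. Expression noise is
multiplicative lognormal on the planted means; an unexpressed transcript
has FPKM exactly 0, so the Inf fold-change sentinel is exercised.

The module also packages a 22-row reference table of differentially
expressed lncRNAs (id, locus, per-timepoint log2 fold changes with "Inf"
tokens) used as an in-package worked example and fixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, write_gtf
from .expression import ExpressionMatrix
from .intervals import GenomicInterval, TranscriptModel, make_transcript
from .sequences import (
    default_hexamer_tables,
    hexamer_score,
    longest_orf,
    longest_orf_span,
    sample_from_hexamer_table,
    write_fasta,
)


class ConfigurationError(ValueError):
    """Raised when a simulation request cannot be laid out."""


# ---------------------------------------------------------------------------
# Packaged 22-row DEL reference table (id, XLOC, locus, log2FC at 3/12/24 h;
# empty = not called at that timepoint, Inf = silent in control).

TABLE1_COLUMNS = (
    "No.", "lncRNA", "XLOC", "locus", "log2FC_3h", "log2FC_12h", "log2FC_24h"
)

TABLE1_ROWS: tuple[tuple[str, ...], ...] = (
    ("1", "TCONS_00005658", "XLOC_002986", "10:777270-897286", "Inf", "", ""),
    ("2", "TCONS_00006290", "XLOC_003288", "7:63840034-63853541", "3.34", "", ""),
    ("3", "TCONS_00006291", "XLOC_003288", "10:78713507-78719836", "3.32", "", ""),
    ("4", "TCONS_00016901", "XLOC_008756", "14:120019330-120022623", "Inf", "", "Inf"),
    ("5", "TCONS_00034713", "XLOC_017807", "3:108221745-108230820", "1.76", "1.64", "2.32"),
    ("6", "TCONS_00034978", "XLOC_017941", "3:138550166-138568232", "1.16", "", ""),
    ("7", "TCONS_00038918", "XLOC_019982", "5:6915996-7133894", "1.34", "", ""),
    ("8", "TCONS_00040607", "XLOC_020835", "5:23100502-23101339", "2.07", "", ""),
    ("9", "TCONS_00041714", "XLOC_021448", "6:3237107-3238658", "3.77", "", ""),
    ("10", "TCONS_00048979", "XLOC_024965", "7:3272029-3276056", "Inf", "", ""),
    ("11", "TCONS_00053619", "XLOC_027505", "9:32511923-32566577", "1.51", "", ""),
    ("12", "TCONS_00056190", "XLOC_028876", "9:146755972-146762016", "2.08", "", ""),
    ("13", "TCONS_00060223", "XLOC_031885", "GL895718.2:3829-4611", "Inf", "", ""),
    ("14", "TCONS_00064401", "XLOC_034330", "X:123166327-123167560", "Inf", "", ""),
    ("15", "TCONS_00064964", "XLOC_034502", "X:14951320-15305754", "3.40", "", ""),
    ("16", "TCONS_00007818", "XLOC_004159", "11:18740477-18860373", "", "1.09", ""),
    ("17", "TCONS_00020891", "XLOC_010641", "15:71337144-71348412", "", "0.99", ""),
    ("18", "TCONS_00031035", "XLOC_015924", "2:160084074-160102520", "", "1.34", "2.68"),
    ("19", "TCONS_00008517", "XLOC_004581", "12:6857198-6863409", "", "", "2.06"),
    ("20", "TCONS_00030731", "XLOC_015756", "2:143856229-143907415", "", "", "-0.99"),
    ("21", "TCONS_00031038", "XLOC_015924", "2:160084074-160102520", "", "", "2.31"),
    ("22", "TCONS_00048132", "XLOC_024540", "7:63840034-63853541", "", "", "-1.01"),
)


def write_fixture_table1(path: str | Path) -> None:
    """Write the packaged 22-row DEL reference table as TSV."""
    df = pd.DataFrame(list(TABLE1_ROWS), columns=list(TABLE1_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Configuration and ground truth

SMALL_RNA_DEFAULTS = {
    "snoRNA": 4,
    "snRNA": 3,
    "miRNA": 3,
    "processed_transcript": 2,
    "pseudogene": 2,
}

PLANTED_DEFAULTS = {
    "sense_overlapping": 20,
    "single_exon": 15,
    "short": 15,
    "coding_like": 15,
    "rfam_hit": 5,
    "known_lnc": 5,
    "intergenic_lnc": 25,
    "antisense:protein_coding": 8,
    "antisense:snoRNA": 3,
    "antisense:snRNA": 2,
    "antisense:miRNA": 2,
    "antisense:processed_transcript": 1,
    "antisense:pseudogene": 1,
}

DE_DEFAULTS: tuple[tuple[str, int, float], ...] = (
    ("TCONS_LINC_0001", 3, 2.0),
    ("TCONS_LINC_0002", 3, 3.3),
    ("TCONS_LINC_0003", 3, math.inf),
    ("TCONS_LINC_0004", 12, 1.5),
    ("TCONS_LINC_0005", 24, 2.0),
    ("TCONS_LINC_0006", 24, -1.2),
    ("TCONS_LINC_0007", 3, 1.8),
    ("TCONS_LINC_0007", 12, 1.6),
    ("TCONS_LINC_0007", 24, 2.3),
    ("TCONS_LINC_0008", 3, math.inf),
    ("TCONS_LINC_0008", 24, math.inf),
)

CIS_DEFAULTS: tuple[tuple[str, str, int], ...] = (
    ("TCONS_LINC_0001", "PCG_0001", 500),
    ("TCONS_LINC_0004", "PCG_0002", 2500),
    ("TCONS_LINC_0005", "PCG_0003", 10_000),
    ("TCONS_LINC_0007", "PCG_0004", 7500),
)

TRANS_DEFAULTS: tuple[tuple[str, str, int], ...] = (
    ("TCONS_LINC_0001", "PCG_0005", +1),
    ("TCONS_LINC_0002", "PCG_0006", -1),
    ("TCONS_LINC_0003", "PCG_0007", +1),
    ("TCONS_LINC_0005", "PCG_0008", -1),
    ("TCONS_LINC_0007", "PCG_0009", +1),
    ("TCONS_LINC_0008", "PCG_0010", -1),
)

RFAM_FAMILIES = ("tRNA", "rRNA", "snoRNA", "miRNA", "snRNA")


@dataclass
class SimulationConfig:
    """Generator settings; defaults give ~60 reference genes and ~120
    assembled transcripts on 3 x 1 Mb chromosomes, seconds to build."""

    seed: int = 1
    n_chromosomes: int = 3
    chrom_length: int = 1_000_000
    n_protein_coding: int = 40
    n_known_lncrna: int = 5
    n_small_rna: Mapping[str, int] = field(
        default_factory=lambda: dict(SMALL_RNA_DEFAULTS)
    )
    n_planted: Mapping[str, int] = field(
        default_factory=lambda: dict(PLANTED_DEFAULTS)
    )
    timepoints: tuple[int, ...] = (3, 12, 24)
    n_replicates: int = 2
    de_effects: Sequence[tuple[str, int, float]] = DE_DEFAULTS
    cis_targets: Sequence[tuple[str, str, int]] = CIS_DEFAULTS
    trans_targets: Sequence[tuple[str, str, int]] = TRANS_DEFAULTS
    fpkm_noise_sd: float = 0.1
    isolation_gap: int = 15_000  # > cis window, keeps unrelated loci apart

    def __post_init__(self) -> None:
        counts = [self.n_protein_coding, self.n_known_lncrna]
        counts += list(self.n_small_rna.values())
        counts += list(self.n_planted.values())
        if any(c < 0 for c in counts):
            raise ConfigurationError("all counts must be >= 0")
        if any(d < 0 for _, _, d in self.cis_targets):
            raise ConfigurationError("cis distances must be >= 0")
        if self.fpkm_noise_sd < 0:
            raise ConfigurationError("fpkm_noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Planted fate of every assembled transcript plus the expected DEL and
    target sets the downstream stages should recover."""

    labels: dict[str, str]
    expected_dels: dict[int, set[str]]
    expected_cis: set[tuple[str, str, int]]
    expected_trans: set[tuple[str, str, int]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["transcript_id", "label"]
        )


@dataclass
class SimulatedDataset:
    reference: AnnotationSet
    assembled: list[TranscriptModel]
    sequences: dict[str, str]
    expression: ExpressionMatrix
    truth: GroundTruth
    rfam_hits: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        """Write reference.gtf, assembled.gtf, transcripts.fa, fpkm.tsv,
        rfam_hits.tsv and ground_truth.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gtf(self.reference, outdir / "reference.gtf")
        write_gtf(self.assembled, outdir / "assembled.gtf")
        write_fasta(self.sequences, outdir / "transcripts.fa")
        self.expression.to_tsv(outdir / "fpkm.tsv")
        self.rfam_hits.to_csv(outdir / "rfam_hits.tsv", sep="\t", index=False)
        self.truth.to_frame().to_csv(
            outdir / "ground_truth.tsv", sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Internal helpers


class _Placer:
    """Round-robin locus allocator keeping groups isolated by a fixed gap."""

    def __init__(self, n_chrom: int, length: int, gap: int) -> None:
        self.chroms = [f"chr{i + 1}" for i in range(n_chrom)]
        self.cursor = {c: 1000 for c in self.chroms}
        self.length = length
        self.gap = gap
        self._next = 0

    def place(self, extent: int) -> tuple[str, int]:
        for _ in range(len(self.chroms)):
            chrom = self.chroms[self._next % len(self.chroms)]
            self._next += 1
            start = self.cursor[chrom]
            if start + extent <= self.length:
                self.cursor[chrom] = start + extent + self.gap
                return chrom, start
        raise ConfigurationError(
            f"chromosomes too small to place a locus of {extent} bp"
        )


def _exon_chain(
    rng: np.random.Generator,
    n_exons: int,
    exon_range: tuple[int, int],
    intron_range: tuple[int, int],
    start: int = 0,
) -> list[tuple[int, int]]:
    coords = []
    pos = start
    for i in range(n_exons):
        ln = int(rng.integers(exon_range[0], exon_range[1] + 1))
        coords.append((pos, pos + ln))
        pos += ln + int(rng.integers(intron_range[0], intron_range[1] + 1))
    return coords


def _shift(coords: Sequence[tuple[int, int]], offset: int):
    return [(s + offset, e + offset) for s, e in coords]


_OPP = {"+": "-", "-": "+"}


def _noncoding_sequence(
    rng: np.random.Generator,
    length: int,
    coding_tbl: Mapping[str, float],
    noncoding_tbl: Mapping[str, float],
) -> str:
    """A sequence with max ORF < 100 nt and negative hexamer score, drawn
    from the noncoding hexamer model.

    Stop-codon blocks covering all three reading frames are stamped in
    every 75 nt, so no frame can hold an ORF reaching 100 nt."""
    for _ in range(1000):
        seq = list(sample_from_hexamer_table(noncoding_tbl, length, rng))
        for p in range(70, length - 10, 75):
            for off in (0, 4, 8):  # TAA in frames p, p+1, p+2
                seq[p + off : p + off + 3] = "TAA"
        seq = "".join(seq)
        if (
            longest_orf(seq) < 100
            and hexamer_score(seq, coding_tbl, noncoding_tbl) < 0
        ):
            return seq
    raise ConfigurationError("could not draw a noncoding sequence")


def _coding_sequence(
    rng: np.random.Generator,
    length: int,
    coding_tbl: Mapping[str, float],
    noncoding_tbl: Mapping[str, float],
) -> str:
    """A sequence carrying an in-frame ORF >= 300 nt built from the coding
    hexamer model, with a positive hexamer score."""
    if length < 330:
        raise ConfigurationError("coding-like transcripts need >= 330 nt")
    hexes = [h for h in coding_tbl if h[:3] not in ("TAA", "TAG", "TGA")
             and h[3:] not in ("TAA", "TAG", "TGA")]
    probs = np.array([coding_tbl[h] for h in hexes])
    probs /= probs.sum()
    orf_len = max(300, length - 48)
    orf_len -= orf_len % 3
    n_hex = (orf_len - 6) // 6 + 1
    for _ in range(1000):
        idx = rng.choice(len(hexes), size=n_hex, p=probs)
        body = "".join(hexes[i] for i in idx)[: orf_len - 6]
        orf = "ATG" + body + "TAA"
        pad = length - len(orf)
        prefix = sample_from_hexamer_table(noncoding_tbl, pad // 2, rng)
        suffix = sample_from_hexamer_table(noncoding_tbl, pad - pad // 2, rng)
        seq = (prefix + orf + suffix)[:length]
        if (
            longest_orf(seq) >= 300
            and hexamer_score(seq, coding_tbl, noncoding_tbl) > 0
        ):
            return seq
    raise ConfigurationError("could not draw a coding-like sequence")


# ---------------------------------------------------------------------------
# The generator


def simulate(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate a labelled dataset; deterministic given ``config.seed``."""
    cfg = config or SimulationConfig()
    ss = np.random.SeedSequence(cfg.seed)
    rng_place, rng_seq, rng_expr = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    placer = _Placer(cfg.n_chromosomes, cfg.chrom_length, cfg.isolation_gap)
    coding_tbl, noncoding_tbl = default_hexamer_tables()

    reference: list[TranscriptModel] = []
    assembled: list[TranscriptModel] = []
    labels: dict[str, str] = {}
    rfam_rows: list[tuple[str, str, str]] = []
    xloc = iter(range(1, 10_000))

    def new_xloc() -> str:
        return f"XLOC_{next(xloc):06d}"

    def rand_strand() -> str:
        return "+" if rng_place.random() < 0.5 else "-"

    planted = dict(cfg.n_planted)
    n_sense = planted.get("sense_overlapping", 0)
    n_sense_biotype = min(3, n_sense)  # marked protein_coding, no overlap
    n_sense_overlap = n_sense - n_sense_biotype

    # --- assign companion roles to the protein-coding genes -------------
    cis_genes = {g for _, g, _ in cfg.cis_targets}
    pcg_ids = [f"PCG_{i:04d}" for i in range(1, cfg.n_protein_coding + 1)]
    unknown = cis_genes - set(pcg_ids)
    if unknown:
        raise ConfigurationError(f"cis target genes not in reference: {unknown}")
    n_anti_pc = planted.get("antisense:protein_coding", 0)
    free = [g for g in pcg_ids if g not in cis_genes]
    if len(free) < n_anti_pc + n_sense_overlap:
        raise ConfigurationError(
            "not enough protein-coding genes for the requested companions"
        )
    anti_pc_hosts = free[:n_anti_pc]
    sense_hosts = [
        free[n_anti_pc + (i % (len(free) - n_anti_pc))]
        for i in range(n_sense_overlap)
    ]
    cis_by_gene: dict[str, list[tuple[str, int]]] = {}
    for lnc, gene, dist in cfg.cis_targets:
        cis_by_gene.setdefault(gene, []).append((lnc, dist))

    anti_counters: dict[str, int] = {}

    def antisense_id(biotype: str) -> str:
        anti_counters[biotype] = anti_counters.get(biotype, 0) + 1
        short = {
            "protein_coding": "PC",
            "snoRNA": "SNO",
            "snRNA": "SNR",
            "miRNA": "MIR",
            "processed_transcript": "PT",
            "pseudogene": "PSG",
        }[biotype]
        return f"TCONS_AS_{short}_{anti_counters[biotype]:04d}"

    def build_antisense(
        partner_coords: list[tuple[int, int]], offset: int
    ) -> list[tuple[int, int]]:
        """Two-exon lncRNA on the opposite strand overlapping the partner's
        first exon by >= 1 bp, in local coordinates."""
        ps, pe = partner_coords[0]
        overlap = min(60, pe - ps)
        exon1 = (ps, ps + max(overlap, 1))
        last_end = partner_coords[-1][1]
        exon2 = (last_end + 120, last_end + 320)
        # pad exon1 leftwards so the transcript is comfortably > 200 nt
        pad = max(0, 160 - (exon1[1] - exon1[0]))
        exon1 = (max(0, exon1[0] - pad), exon1[1])
        return _shift([exon1, exon2], offset)

    # --- reference protein-coding genes (+ companions) -------------------
    sense_by_host: dict[str, int] = {}
    for host in sense_hosts:
        sense_by_host[host] = sense_by_host.get(host, 0) + 1
    sense_counter = 0

    for gid in pcg_ids:
        strand = rand_strand()
        n_exons = int(rng_place.integers(2, 6))
        local_gene = _exon_chain(
            rng_place, n_exons, (150, 400), (200, 600), start=250
        )
        extent = local_gene[-1][1] + 400
        cis_here = cis_by_gene.get(gid, [])
        cis_specs = []
        lead = 0
        for lnc_id, dist in cis_here:
            # the cis lncRNA sits upstream; the gene follows at exactly dist
            lnc_coords = _exon_chain(rng_place, 2, (150, 300), (150, 400))
            lead = lnc_coords[-1][1] + dist
            cis_specs.append((lnc_id, lnc_coords))
        if cis_specs:
            local_gene = _shift(
                _exon_chain(rng_place, n_exons, (150, 400), (200, 600)), lead
            )
            extent = local_gene[-1][1] + 400
        chrom, off = placer.place(extent)
        gene_coords = _shift(local_gene, off)
        reference.append(
            make_transcript(gid, gid, chrom, strand, gene_coords, "protein_coding")
        )
        for lnc_id, lnc_coords in cis_specs:
            assembled.append(
                make_transcript(
                    lnc_id, new_xloc(), chrom, rand_strand(), _shift(lnc_coords, off)
                )
            )
            labels[lnc_id] = "novel_intergenic"
        if gid in anti_pc_hosts:
            tid = antisense_id("protein_coding")
            coords = build_antisense(gene_coords, 0)
            assembled.append(
                make_transcript(tid, new_xloc(), chrom, _OPP[strand], coords)
            )
            labels[tid] = "novel_antisense:protein_coding"
        for _ in range(sense_by_host.get(gid, 0)):
            sense_counter += 1
            tid = f"TCONS_SENSE_{sense_counter:04d}"
            # reuse the gene's first two exons: guaranteed sense overlap
            assembled.append(
                make_transcript(tid, new_xloc(), chrom, strand, gene_coords[:2])
            )
            labels[tid] = "removed_step1"

    # --- biotype-marked protein-coding assemblies (no overlap needed) ----
    for i in range(n_sense_biotype):
        sense_counter += 1
        tid = f"TCONS_SENSE_{sense_counter:04d}"
        coords = _exon_chain(rng_place, 2, (150, 300), (150, 400))
        chrom, off = placer.place(coords[-1][1])
        assembled.append(
            make_transcript(
                tid, new_xloc(), chrom, rand_strand(), _shift(coords, off),
                biotype="protein_coding",
            )
        )
        labels[tid] = "removed_step1"

    # --- reference known lncRNAs (+ assembled copies) ---------------------
    n_copies = planted.get("known_lnc", 0)
    if n_copies > cfg.n_known_lncrna:
        raise ConfigurationError(
            "more known_lnc copies requested than reference lncRNAs"
        )
    for i in range(1, cfg.n_known_lncrna + 1):
        strand = rand_strand()
        coords = _exon_chain(
            rng_place, int(rng_place.integers(2, 4)), (150, 400), (200, 500), start=100
        )
        chrom, off = placer.place(coords[-1][1] + 100)
        coords = _shift(coords, off)
        rid = f"LNC_REF_{i:04d}"
        reference.append(
            make_transcript(rid, rid, chrom, strand, coords, "lncRNA")
        )
        if i <= n_copies:
            tid = f"TCONS_KNOWN_{i:04d}"
            ext = [list(c) for c in coords]
            ext[0][0] = max(off - 40, ext[0][0] - int(rng_place.integers(0, 41)))
            ext[-1][1] += int(rng_place.integers(0, 41))
            assembled.append(
                make_transcript(
                    tid, new_xloc(), chrom, strand, [tuple(c) for c in ext]
                )
            )
            labels[tid] = "known_lnc"

    # --- reference small RNAs etc. (+ antisense companions) ---------------
    for biotype, count in cfg.n_small_rna.items():
        n_anti = planted.get(f"antisense:{biotype}", 0)
        if n_anti > count:
            raise ConfigurationError(
                f"more antisense:{biotype} lncRNAs than {biotype} features"
            )
        short_tag = {
            "snoRNA": "SNO",
            "snRNA": "SNR",
            "miRNA": "MIR",
            "processed_transcript": "PT",
            "pseudogene": "PSG",
        }.get(biotype, biotype.upper()[:3])
        for i in range(1, count + 1):
            strand = rand_strand()
            if biotype == "processed_transcript":
                coords = _exon_chain(rng_place, 2, (150, 300), (150, 300), start=250)
            elif biotype == "pseudogene":
                coords = [(250, 250 + int(rng_place.integers(400, 700)))]
            else:
                coords = [(250, 250 + int(rng_place.integers(70, 150)))]
            chrom, off = placer.place(coords[-1][1] + 450)
            coords = _shift(coords, off)
            rid = f"{short_tag}_{i:04d}"
            reference.append(
                make_transcript(rid, rid, chrom, strand, coords, biotype)
            )
            if i <= n_anti:
                tid = antisense_id(biotype)
                acoords = build_antisense(coords, 0)
                assembled.append(
                    make_transcript(tid, new_xloc(), chrom, _OPP[strand], acoords)
                )
                labels[tid] = f"novel_antisense:{biotype}"

    # --- standalone assembled classes --------------------------------------
    def place_standalone(tid: str, coords: list[tuple[int, int]], label: str) -> None:
        chrom, off = placer.place(coords[-1][1])
        assembled.append(
            make_transcript(tid, new_xloc(), chrom, rand_strand(), _shift(coords, off))
        )
        labels[tid] = label

    for i in range(1, planted.get("single_exon", 0) + 1):
        ln = int(rng_place.integers(300, 801))
        place_standalone(f"TCONS_SE_{i:04d}", [(0, ln)], "removed_step2")
    for i in range(1, planted.get("short", 0) + 1):
        coords = _exon_chain(rng_place, 2, (60, 95), (100, 300))
        place_standalone(f"TCONS_SHORT_{i:04d}", coords, "removed_step3")
    for i in range(1, planted.get("coding_like", 0) + 1):
        coords = _exon_chain(rng_place, 2, (220, 450), (150, 400))
        place_standalone(f"TCONS_CODE_{i:04d}", coords, "removed_step4")
    for i in range(1, planted.get("rfam_hit", 0) + 1):
        tid = f"TCONS_RFAM_{i:04d}"
        coords = _exon_chain(rng_place, 2, (130, 300), (150, 400))
        place_standalone(tid, coords, "removed_step5")
        family = RFAM_FAMILIES[(i - 1) % len(RFAM_FAMILIES)]
        rfam_rows.append((tid, f"RF{i:05d}", family))
    for i in range(1, planted.get("intergenic_lnc", 0) + 1):
        tid = f"TCONS_LINC_{i:04d}"
        if tid in labels:  # already placed as a cis companion
            continue
        coords = _exon_chain(
            rng_place, int(rng_place.integers(2, 5)), (100, 400), (150, 500)
        )
        place_standalone(tid, coords, "novel_intergenic")

    ref_set = AnnotationSet(reference)

    # --- sequences ---------------------------------------------------------
    sequences: dict[str, str] = {}
    for t in assembled:
        if labels[t.transcript_id] == "removed_step4":
            sequences[t.transcript_id] = _coding_sequence(
                rng_seq, t.spliced_length, coding_tbl, noncoding_tbl
            )
        else:
            sequences[t.transcript_id] = _noncoding_sequence(
                rng_seq, t.spliced_length, coding_tbl, noncoding_tbl
            )

    # --- expression --------------------------------------------------------
    samples = [
        f"{tag}_{tp}h_r{r}"
        for tag in ("C", "TCDD")
        for tp in cfg.timepoints
        for r in range(1, cfg.n_replicates + 1)
    ]
    feature_ids = [t.transcript_id for t in assembled] + pcg_ids
    for tid, _, _ in cfg.de_effects:
        if tid not in labels:
            raise ConfigurationError(f"de_effects names unknown transcript {tid}")
    for lnc, gene, _ in cfg.trans_targets:
        if lnc not in labels or gene not in pcg_ids:
            raise ConfigurationError(f"trans pair ({lnc}, {gene}) not in dataset")

    inf_lncs = {t for t, _, fc in cfg.de_effects if math.isinf(fc)}
    base = {}
    for fid in feature_ids:
        if fid in pcg_ids:
            base[fid] = rng_expr.uniform(1.0, 5.0)
        elif fid in inf_lncs:
            base[fid] = rng_expr.uniform(1.5, 3.0)
        else:
            base[fid] = rng_expr.uniform(-0.5, 3.0)

    effects: dict[tuple[str, int], float] = {}
    for tid, tp, fc in cfg.de_effects:
        effects[(tid, tp)] = fc

    means = pd.DataFrame(0.0, index=feature_ids, columns=samples)
    for fid in feature_ids:
        for s in samples:
            cond = "control" if s.startswith("C_") else "treated"
            tp = int(s.split("_")[1].rstrip("h"))
            fc = effects.get((fid, tp))
            mu = 2.0 ** base[fid]
            if fc is None:
                value = mu
            elif math.isinf(fc):
                value = 0.0 if (fc > 0) == (cond == "control") else mu
            else:
                value = mu * 2.0**fc if cond == "treated" else mu
            means.loc[fid, s] = value

    # trans-target genes mirror their lncRNA's log profile (sign-flipped
    # for negative pairs), giving |population r| ~ 1 on the log scale
    for lnc, gene, sign in cfg.trans_targets:
        prof = np.log2(means.loc[lnc].to_numpy(dtype=float) + 0.1)
        centered = prof - prof.mean()
        means.loc[gene] = 2.0 ** (base[gene] + np.sign(sign) * centered)

    noise = (
        rng_expr.lognormal(0.0, cfg.fpkm_noise_sd, size=means.shape)
        if cfg.fpkm_noise_sd > 0
        else 1.0
    )
    values = means * noise
    design = pd.DataFrame(
        {
            "condition": [
                "control" if s.startswith("C_") else "treated" for s in samples
            ],
            "timepoint": [int(s.split("_")[1].rstrip("h")) for s in samples],
            "replicate": [int(s.rsplit("_r", 1)[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    expr = ExpressionMatrix(values, design)

    truth = GroundTruth(
        labels=labels,
        expected_dels={
            tp: {tid for tid, t, _ in cfg.de_effects if t == tp}
            for tp in cfg.timepoints
        },
        expected_cis={(l, g, d) for l, g, d in cfg.cis_targets},
        expected_trans={(l, g, int(np.sign(s))) for l, g, s in cfg.trans_targets},
    )
    rfam = pd.DataFrame(
        rfam_rows, columns=["transcript_id", "family_accession", "family_class"]
    )
    return SimulatedDataset(ref_set, assembled, sequences, expr, truth, rfam)
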