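"""GTF reading/writing and strand-aware overlap queries.

GTF parsing is backed by gffutils (in-memory sqlite database); a light
validation pass runs first so malformed lines are reported with their line
number. Interval indexing uses one interval tree per chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

import gffutils
from intervaltree import IntervalTree

from .intervals import GenomicInterval, TranscriptModel

BIOTYPES = (
    "protein_coding",
    "lncRNA",
    "snoRNA",
    "snRNA",
    "miRNA",
    "processed_transcript",
    "pseudogene",
    "other",
)

StrandMode = Literal["same", "opposite", "any"]
OverlapLevel = Literal["exon", "span"]


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; message names the line number."""


def _validate_gtf(path: str | Path) -> int:
    n_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise GtfParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if end < start:
                raise GtfParseError(
                    f"{path}: line {lineno}: rejected record with end < start"
                )
            if "transcript_id" not in fields[8]:
                raise GtfParseError(
                    f"{path}: line {lineno}: missing transcript_id attribute"
                )
            n_records += 1
    return n_records


def read_gtf(
    path: str | Path,
    feature_kinds: set[str] = frozenset({"exon"}),
    biotype_attribute: str | None = None,
    chrom_aliases: dict[str, str] | None = None,
) -> "AnnotationSet":
    """Read a GTF 2.2 file into an AnnotationSet.

    Exon rows are grouped by transcript_id; 1-based inclusive coordinates
    become 0-based half-open. Biotype is taken from ``biotype_attribute`` if
    given, else from transcript_biotype then gene_biotype. Chromosome names
    are matched verbatim unless an alias map is supplied.
    """
    if _validate_gtf(path) == 0:
        return AnnotationSet([])
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in feature_kinds:
            continue
        attrs = feat.attributes
        tid = attrs["transcript_id"][0]
        gid = attrs.get("gene_id", [tid])[0]
        if biotype_attribute is not None:
            biotype = attrs.get(biotype_attribute, [""])[0]
        else:
            biotype = attrs.get(
                "transcript_biotype", attrs.get("gene_biotype", [""])
            )[0]
        chrom = feat.seqid
        if chrom_aliases:
            chrom = chrom_aliases.get(chrom, chrom)
        strand = feat.strand if feat.strand in ("+", "-") else "."
        rec = per_tx.setdefault(
            tid, {"gene_id": gid, "biotype": biotype, "exons": []}
        )
        rec["exons"].append(
            GenomicInterval(chrom, feat.start - 1, feat.end, strand)
        )
        if biotype and not rec["biotype"]:
            rec["biotype"] = biotype
    models = []
    for tid, rec in per_tx.items():
        exons = tuple(sorted(rec["exons"], key=lambda e: e.start))
        models.append(
            TranscriptModel(tid, rec["gene_id"], exons, rec["biotype"])
        )
    return AnnotationSet(models)


def write_gtf(
    models: Iterable[TranscriptModel],
    path: str | Path,
    source: str = "lnckit",
) -> None:
    """Write transcript models as GTF 2.2 exon rows (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        for t in models:
            attrs = f'gene_id "{t.locus_id}"; transcript_id "{t.transcript_id}";'
            if t.biotype:
                attrs += f' transcript_biotype "{t.biotype}";'
            for e in t.exons:
                fh.write(
                    "\t".join(
                        (
                            e.chrom,
                            source,
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            e.strand,
                            ".",
                            attrs,
                        )
                    )
                    + "\n"
                )


@dataclass
class AnnotationSet:
    """Indexed collection of transcript models with biotypes.

    Supports strand-aware overlap queries at exon or span level; results are
    identical to an exhaustive pairwise comparison.
    """

    features: list[TranscriptModel]

    def __post_init__(self) -> None:
        ids = [t.transcript_id for t in self.features]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate transcript ids: {dup[:5]}")
        self._by_id = {t.transcript_id: t for t in self.features}
        self._exon_trees: dict[str, IntervalTree] = {}
        self._span_trees: dict[str, IntervalTree] = {}
        for t in self.features:
            for e in t.exons:
                self._exon_trees.setdefault(e.chrom, IntervalTree()).addi(
                    e.start, e.end, t.transcript_id
                )
            sp = t.interval
            self._span_trees.setdefault(sp.chrom, IntervalTree()).addi(
                sp.start, sp.end, t.transcript_id
            )

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.features)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_id

    def get(self, transcript_id: str) -> TranscriptModel:
        return self._by_id[transcript_id]

    def subset(self, biotypes: Iterable[str]) -> "AnnotationSet":
        wanted = set(biotypes)
        return AnnotationSet([t for t in self.features if t.biotype in wanted])

    @property
    def biotypes(self) -> set[str]:
        return {t.biotype for t in self.features}

    def query(
        self,
        chrom: str,
        start: int,
        end: int,
        level: OverlapLevel = "exon",
    ) -> set[str]:
        """Transcript ids whose exons (or span) intersect [start, end)."""
        trees = self._exon_trees if level == "exon" else self._span_trees
        tree = trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}


def overlap_query(
    ann: AnnotationSet,
    t: TranscriptModel,
    strand_mode: StrandMode = "any",
    level: OverlapLevel = "exon",
) -> list[tuple[TranscriptModel, int]]:
    """Features of ``ann`` with >= 1 bp intersection with ``t`` at the
    requested level and strand relation, with total intersected bases.

    A transcript of unknown strand cannot satisfy a same/opposite relation:
    the result is empty and a warning is emitted.
    """
    if t.strand == "." and strand_mode != "any":
        warnings.warn(
            f"{t.transcript_id}: strand unknown; {strand_mode}-strand query "
            "returns no features",
            stacklevel=2,
        )
        return []
    query_ivs = t.exons if level == "exon" else (t.interval,)
    candidates: set[str] = set()
    for iv in query_ivs:
        candidates |= ann.query(iv.chrom, iv.start, iv.end, level=level)
    out = []
    for fid in sorted(candidates):
        feat = ann.get(fid)
        if strand_mode == "same" and feat.strand != t.strand:
            continue
        if strand_mode == "opposite":
            if feat.strand == "." or feat.strand == t.strand:
                continue
        target_ivs = feat.exons if level == "exon" else (feat.interval,)
        bp = sum(a.overlap_bp(b) for a in query_ivs for b in target_ivs)
        if bp >= 1:
            out.append((feat, bp))
    return out
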