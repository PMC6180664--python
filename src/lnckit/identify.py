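"""The lncRNA identification cascade.

Five successive filters reduce an assembled transcriptome to candidate
lncRNAs: (1) drop protein-coding transcripts and anything with >= 1 bp
same-strand exonic overlap with an annotated protein-coding feature;
(2) drop single-exon transcripts; (3) drop transcripts with spliced length
below 200 nt; (4) keep only transcripts every coding-potential scorer calls
non-coding (Venn intersection); (5) drop transcripts hitting small-RNA
(Rfam-style) families. Survivors are split into known lncRNAs (intron-chain
match to an annotated lncRNA) and novel ones, and novel lncRNAs are
classified as intergenic or antisense-to-<biotype> by position.

Each filter is a pure predicate, so the final kept set is the intersection
of the standalone filter survivors and is order-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .annotation import AnnotationSet, OverlapLevel, overlap_query
from .intervals import TranscriptModel
from .sequences import default_hexamer_tables, hexamer_score, longest_orf

Polarity = Literal["noncoding_below", "noncoding_above", "coding_if_hit_below"]
MissingPolicy = Literal["treat_noncoding", "treat_coding", "error"]

#: Tie-break priority when an antisense lncRNA overlaps several biotypes.
ANTISENSE_PRIORITY = (
    "protein_coding",
    "miRNA",
    "snoRNA",
    "snRNA",
    "processed_transcript",
    "pseudogene",
)


@dataclass(frozen=True)
class ScoreRule:
    """Threshold + polarity turning one tool's score into a coding verdict.

    ``noncoding_below``: score < threshold is non-coding (CPC/CNCI/PLEK
    score < 0; FEELnc coding potential below its cutoff).
    ``noncoding_above``: score > threshold is non-coding.
    ``coding_if_hit_below``: a present score below threshold is a coding
    call (Pfam E-value semantics); a present score at/above threshold is
    non-coding. Missing scores are resolved by ``missing_policy``.
    """

    tool_name: str
    threshold: float
    polarity: Polarity
    missing_policy: MissingPolicy = "treat_coding"

    def __post_init__(self) -> None:
        if not (self.threshold == self.threshold and abs(self.threshold) < float("inf")):
            raise ValueError("threshold must be finite")

    def verdict(self, score: float | None) -> str:
        """'noncoding' or 'coding' for one transcript's score."""
        if score is None:
            if self.missing_policy == "error":
                raise ValueError(f"missing score for tool {self.tool_name}")
            return (
                "noncoding"
                if self.missing_policy == "treat_noncoding"
                else "coding"
            )
        if self.polarity == "noncoding_below":
            return "noncoding" if score < self.threshold else "coding"
        if self.polarity == "noncoding_above":
            return "noncoding" if score > self.threshold else "coding"
        # coding_if_hit_below: Pfam-style, a strong (small) hit means coding
        return "coding" if score < self.threshold else "noncoding"


def paper_style_rules() -> list[ScoreRule]:
    """The five-tool rule set used in the source study's screen: CPC < 0,
    CNCI < 0 and PLEK < 0 call non-coding; FEELnc coding potential above
    0.558 calls coding; a Pfam domain hit with E-value < 0.001 calls coding
    (no hit is non-coding)."""
    return [
        ScoreRule("CPC", 0.0, "noncoding_below"),
        ScoreRule("CNCI", 0.0, "noncoding_below"),
        ScoreRule("PLEK", 0.0, "noncoding_below"),
        ScoreRule("FEELnc", 0.558, "noncoding_below"),
        ScoreRule("Pfam", 0.001, "coding_if_hit_below", "treat_noncoding"),
    ]


def internal_rules() -> list[ScoreRule]:
    """Rules for the built-in stand-in panel: coding if the longest ORF is
    >= 300 nt or the hexamer log-likelihood ratio is positive. These are
    NOT the external tools; they exist so the cascade runs self-contained."""
    return [
        ScoreRule("orf_length", 300.0, "noncoding_below"),
        ScoreRule("hexamer", 0.0, "noncoding_below"),
    ]


@dataclass
class ScorePanel:
    """Per-transcript scores from the coding-potential tools."""

    scores: dict[str, dict[str, float]]  # transcript_id -> tool -> score

    def tools(self) -> set[str]:
        out: set[str] = set()
        for row in self.scores.values():
            out |= row.keys()
        return out

    def get(self, transcript_id: str, tool: str) -> float | None:
        return self.scores.get(transcript_id, {}).get(tool)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScorePanel":
        """Read a long-format score table: transcript_id, tool, score."""
        df = pd.read_csv(path, sep="\t")
        scores: dict[str, dict[str, float]] = {}
        for row in df.itertuples(index=False):
            scores.setdefault(str(row.transcript_id), {})[str(row.tool)] = float(
                row.score
            )
        return cls(scores)


def build_internal_panel(sequences: Mapping[str, str]) -> ScorePanel:
    """Score every sequence with the built-in ORF and hexamer scorers."""
    coding_tbl, noncoding_tbl = default_hexamer_tables()
    scores = {
        tid: {
            "orf_length": float(longest_orf(seq)),
            "hexamer": hexamer_score(seq, coding_tbl, noncoding_tbl),
        }
        for tid, seq in sequences.items()
    }
    return ScorePanel(scores)


# ---------------------------------------------------------------------------
# The five filters


def filter_sense_overlap(
    assembled: Sequence[TranscriptModel],
    ref: AnnotationSet,
    level: OverlapLevel = "exon",
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Step 1: remove transcripts annotated protein-coding and transcripts
    with >= 1 bp same-strand overlap with a protein-coding feature."""
    coding = ref.subset(["protein_coding"])
    kept, removed = [], []
    for t in assembled:
        if t.biotype == "protein_coding" or overlap_query(
            coding, t, strand_mode="same", level=level
        ):
            removed.append(t)
        else:
            kept.append(t)
    return kept, removed


def filter_single_exon(
    transcripts: Sequence[TranscriptModel],
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Step 2: keep multi-exon transcripts only."""
    kept = [t for t in transcripts if t.exon_count >= 2]
    removed = [t for t in transcripts if t.exon_count < 2]
    return kept, removed


def filter_short(
    transcripts: Sequence[TranscriptModel], min_length: int = 200
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Step 3: keep transcripts with spliced length >= min_length nt."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    kept = [t for t in transcripts if t.spliced_length >= min_length]
    removed = [t for t in transcripts if t.spliced_length < min_length]
    return kept, removed


def consensus_noncoding(
    panel: ScorePanel,
    rules: Sequence[ScoreRule],
    transcript_ids: Iterable[str] | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Step 4: keep a transcript iff EVERY rule calls it non-coding.

    Returns the kept ids and the per-tool verdict matrix (rows transcripts,
    columns tools, values 'noncoding'/'coding'); the kept set is the Venn
    intersection of the per-tool non-coding sets.
    """
    names = [r.tool_name for r in rules]
    if len(set(names)) != len(names):
        raise ValueError("every rule must name a distinct tool")
    unknown = panel.tools() - set(names)
    if unknown:
        raise ValueError(f"panel contains tools with no rule: {sorted(unknown)}")
    ids = list(transcript_ids) if transcript_ids is not None else sorted(panel.scores)
    verdicts = pd.DataFrame(
        {
            r.tool_name: [r.verdict(panel.get(tid, r.tool_name)) for tid in ids]
            for r in rules
        },
        index=ids,
    )
    kept = {tid for tid in ids if (verdicts.loc[tid] == "noncoding").all()}
    return kept, verdicts


def filter_small_rna(
    transcripts: Sequence[TranscriptModel],
    hits: Mapping[str, str] | pd.DataFrame | None,
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Step 5: remove transcripts with >= 1 hit to a small-RNA family
    (rRNA, tRNA, snRNA, snoRNA, miRNA, ...). ``hits`` maps transcript_id to
    family class, or is a table with transcript_id / family_class columns."""
    if hits is None:
        hit_ids: set[str] = set()
    elif isinstance(hits, pd.DataFrame):
        hit_ids = set(hits["transcript_id"].astype(str))
    else:
        hit_ids = set(hits)
    kept = [t for t in transcripts if t.transcript_id not in hit_ids]
    removed = [t for t in transcripts if t.transcript_id in hit_ids]
    return kept, removed


# ---------------------------------------------------------------------------
# Known/novel split and positional classification


def split_known_novel(
    lncs: Sequence[TranscriptModel], ref: AnnotationSet
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Split candidates into known (intron-chain identity with an annotated
    lncRNA, same strand; terminal ends may differ) and novel.

    Single-exon candidates — which the cascade normally removes — are
    matched by same-strand exonic overlap with a single-exon reference
    lncRNA.
    """
    ref_lnc = ref.subset(["lncRNA"])
    chains: dict[tuple, list[str]] = {}
    for r in ref_lnc:
        if r.exon_count >= 2:
            chains.setdefault((r.chrom, r.strand, r.intron_chain), []).append(
                r.transcript_id
            )
    known, novel = [], []
    for t in lncs:
        if t.exon_count >= 2:
            is_known = (t.chrom, t.strand, t.intron_chain) in chains
        else:
            is_known = any(
                f.exon_count == 1
                for f, _ in overlap_query(ref_lnc, t, "same", "exon")
            )
        (known if is_known else novel).append(t)
    return known, novel


def classify_position(
    lnc: TranscriptModel,
    ref: AnnotationSet,
    level: OverlapLevel = "exon",
) -> str:
    """'intergenic' or 'antisense:<biotype>' for a cascade survivor.

    Antisense: >= 1 bp opposite-strand overlap with an annotated feature;
    the biotype is that of the feature with maximal overlap (ties broken by
    a fixed priority, protein_coding first). Intergenic: no overlap with
    any annotated feature.
    """
    anti = overlap_query(ref, lnc, strand_mode="opposite", level=level)
    if anti:
        prio = {b: i for i, b in enumerate(ANTISENSE_PRIORITY)}
        best = max(
            anti,
            key=lambda pair: (
                pair[1],
                -prio.get(pair[0].biotype, len(prio)),
            ),
        )
        return f"antisense:{best[0].biotype}"
    return "intergenic"


# ---------------------------------------------------------------------------
# The full cascade


@dataclass
class PipelineReport:
    """Stage counts and per-transcript fates of one identification run."""

    stage_counts: dict[str, int]
    fates: dict[str, str]  # transcript_id -> fate label
    known: list[TranscriptModel] = field(default_factory=list)
    novel_intergenic: list[TranscriptModel] = field(default_factory=list)
    novel_antisense: dict[str, list[TranscriptModel]] = field(
        default_factory=dict
    )
    verdicts: pd.DataFrame | None = None

    @property
    def lncrnas(self) -> list[TranscriptModel]:
        out = list(self.known) + list(self.novel_intergenic)
        for group in self.novel_antisense.values():
            out.extend(group)
        return out

    def fate_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.fates.items()), columns=["transcript_id", "fate"]
        )

    def summary(self) -> pd.DataFrame:
        rows = list(self.stage_counts.items())
        rows += [
            ("known_lncRNA", len(self.known)),
            ("novel_intergenic", len(self.novel_intergenic)),
        ]
        for biotype, group in sorted(self.novel_antisense.items()):
            rows.append((f"novel_antisense:{biotype}", len(group)))
        return pd.DataFrame(rows, columns=["stage", "count"])


def run_identification(
    assembled: Sequence[TranscriptModel],
    ref: AnnotationSet,
    sequences: Mapping[str, str] | None = None,
    panel: ScorePanel | None = None,
    rules: Sequence[ScoreRule] | None = None,
    hits: Mapping[str, str] | pd.DataFrame | None = None,
    min_length: int = 200,
    overlap_level: OverlapLevel = "exon",
) -> PipelineReport:
    """Run the five-step cascade, then split known/novel and classify.

    If no external score ``panel`` is given, the built-in ORF/hexamer panel
    is computed from ``sequences`` (with the matching ``internal_rules``).
    Transcripts of unknown strand are excluded at entry with a warning,
    since sense/antisense logic is undefined for them.
    """
    fates: dict[str, str] = {}
    entered = []
    for t in assembled:
        if t.strand == ".":
            fates[t.transcript_id] = "excluded_unknown_strand"
        else:
            entered.append(t)
    if len(entered) < len(assembled):
        warnings.warn(
            f"excluded {len(assembled) - len(entered)} unknown-strand "
            "transcripts at pipeline entry"
        )
    counts = {"input": len(assembled), "entered": len(entered)}

    s1, removed = filter_sense_overlap(entered, ref, level=overlap_level)
    fates.update({t.transcript_id: "removed_step1" for t in removed})
    counts["after_step1_sense_overlap"] = len(s1)

    s2, removed = filter_single_exon(s1)
    fates.update({t.transcript_id: "removed_step2" for t in removed})
    counts["after_step2_single_exon"] = len(s2)

    s3, removed = filter_short(s2, min_length=min_length)
    fates.update({t.transcript_id: "removed_step3" for t in removed})
    counts["after_step3_short"] = len(s3)

    if panel is None:
        if sequences is None:
            raise ValueError("need either a ScorePanel or sequences")
        panel = build_internal_panel(
            {t.transcript_id: sequences[t.transcript_id] for t in s3}
        )
        if rules is None:
            rules = internal_rules()
    elif rules is None:
        rules = paper_style_rules()
    kept_ids, verdicts = consensus_noncoding(
        panel, rules, [t.transcript_id for t in s3]
    )
    s4 = [t for t in s3 if t.transcript_id in kept_ids]
    fates.update(
        {
            t.transcript_id: "removed_step4"
            for t in s3
            if t.transcript_id not in kept_ids
        }
    )
    counts["after_step4_coding_potential"] = len(s4)

    s5, removed = filter_small_rna(s4, hits)
    fates.update({t.transcript_id: "removed_step5" for t in removed})
    counts["after_step5_small_rna"] = len(s5)

    known, novel = split_known_novel(s5, ref)
    fates.update({t.transcript_id: "known_lnc" for t in known})
    novel_intergenic: list[TranscriptModel] = []
    novel_antisense: dict[str, list[TranscriptModel]] = {}
    for t in novel:
        label = classify_position(t, ref, level=overlap_level)
        if label == "intergenic":
            novel_intergenic.append(t)
            fates[t.transcript_id] = "novel_intergenic"
        else:
            biotype = label.split(":", 1)[1]
            novel_antisense.setdefault(biotype, []).append(t)
            fates[t.transcript_id] = f"novel_antisense:{biotype}"
    return PipelineReport(
        stage_counts=counts,
        fates=fates,
        known=known,
        novel_intergenic=novel_intergenic,
        novel_antisense=novel_antisense,
        verdicts=verdicts,
    )
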