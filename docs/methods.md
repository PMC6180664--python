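# Methods

This note documents the models and procedures lnckit implements, the
defaults it ships, and what the synthetic-data tests do and do not show.

## Coordinates and annotation model

GTF files are 1-based inclusive on disk; internally every interval is
0-based half-open, so `length = end − start` with no off-by-one in length
arithmetic. Transcripts are exon chains (sorted, non-overlapping, one
chromosome and strand); the genomic span runs from the first exon start to
the last exon end, and the spliced length is the exon-length sum.
Chromosome names are matched verbatim (no `chr` normalization) unless an
alias map is passed to `read_gtf`. Parsing is backed by gffutils with a
pre-validation pass so malformed lines are reported by line number.

Overlap queries are strand-aware (`same`/`opposite`/`any`) and run at exon
or span level through per-chromosome interval trees; results are defined
as — and property-tested against — the exhaustive all-pairs intersection.
Transcripts of unknown strand cannot satisfy a stranded query and are
excluded from the identification cascade at entry with a warning, because
sense/antisense logic is undefined for them.

## The identification cascade

The five filters are pure predicates, so the final kept set is the
intersection of the standalone survivor sets and is order-independent
(tested). Step 1 removes transcripts annotated protein-coding and
transcripts with ≥ 1 bp same-strand overlap with protein-coding features.
The overlap is computed on **exons** by default: "coding sequences" are
exonic. Span-level overlap remains available (`overlap_level="span"`) as a
sensitivity check, since screens of this kind do not always state which
anchor they used.

Step 4 is a consensus: a transcript survives only if every configured
scorer calls it non-coding. Rule polarities encode each tool's score
semantics: CPC, CNCI and PLEK scores below 0 are non-coding calls; a
FEELnc coding potential above its cutoff (0.558) is a coding call; a Pfam
domain hit with E-value < 0.001 is a coding call and the absence of a hit
is non-coding. A score exactly at the FEELnc cutoff is treated as coding
by the `noncoding_below` rule — a measure-zero boundary. A missing score
defaults to a coding verdict (ambiguous transcripts are dropped;
configurable per rule), except for hit-based rules where absence is the
normal non-coding state.

When no external score tables are supplied, a built-in two-scorer panel is
used: coding if the longest ATG-to-stop ORF (three forward frames, stop
included) is ≥ 300 nt, or if the hexamer log-likelihood-ratio score is
positive. The default hexamer tables are **synthetic** product measures —
a GC-rich "coding" composition against an AT-rich "noncoding" one — not
trained on any genome; the compositional form makes the score robust to
the scanning frame. This panel is a self-contained stand-in, not a
re-implementation of the published tools; real screens should ingest real
score tables.

"Known" lncRNAs are candidates whose intron chain exactly matches an
annotated lncRNA on the same strand (terminal ends may differ) — the
transcript-comparison "complete match" convention. Novel survivors are
classified antisense:⟨biotype⟩ if they have ≥ 1 bp opposite-strand overlap
with an annotated feature (biotype of the feature with maximal overlap,
ties broken protein_coding > miRNA > snoRNA > snRNA > processed_transcript
> pseudogene), else intergenic. A survivor whose only overlap is
same-strand with a non-coding feature has no separate category and is
grouped with intergenic; the generator does not produce this case.

## Characterization

Transcript-level metrics use one transcript as the statistical unit; the
exon-length metric pools all exons of the group (its *n* is the exon
count). FPKM per transcript is the mean over all samples — the least
surprising choice where the convention is unstated. Default distribution
bins (all configurable): transcript length 200–1000/1000–2000/…/≥5000 nt;
exon length <50/50–200/200–500/≥500 nt; exon number 1…9/≥10; FPKM
<2/2–10/≥10. Welch's *t* uses the Welch–Satterthwaite df; two
zero-variance samples degenerate to t = 0, p = 1 (equal means) or p = 0
with a flag (unequal).

## Differential expression

Fold changes are computed on raw FPKM condition means, no pseudocount:
`log2(treated/control)` when both sides are expressed, `+Inf` when the
transcript is silent in every control replicate but expressed under
treatment, `−Inf` for the reverse, and no value when silent in both. This
keeps the "expressed only under treatment" sentinel semantics of typical
screen tables intact.

The significance test is a deliberate stand-in for count-model tools
(which need the read-level data): a Welch-style *t* on log₂(FPKM + 0.1)
whose per-group variances are shrunk 50/50 toward the across-transcript
mean within-group variance. Shrinkage weight 0 recovers the ordinary
Welch test exactly (tested). With *n* = 2 per group no test is robust;
the module therefore also accepts precomputed p-values
(`p_source="provided"`). Sentinel transcripts have no finite statistic
and use a presence/absence rule: p = 0 when the silent side is exactly 0
in every replicate and the expressed side reaches the expression floor
(default 0.5 FPKM, guarding against one-read noise), else p = 1.
Adjustment is Benjamini–Hochberg per timepoint. A DEL at a timepoint
requires adjusted p < α (0.05) and |log₂FC| ≥ 1 on the unrounded value, or
a sentinel; the threshold is two-sided because down-regulated entries
(−0.99, −1.01 after rounding) appear in this kind of table. The packaged
22-row DEL table retains one 0.99 entry verbatim — values that round to
two decimals can sit just under the nominal cutoff.

Heatmap matrices are z-scores per row on log₁₀(FPKM + 0.1),
(x − mean)/sd; constant rows get zero rows and a flag.

## Target prediction

Cis: the gap between the DEL span and the gene span (0 when overlapping),
either strand, either side, boundary-inclusive at the 10 kb window. The
window anchor is the span, not the TSS (configurable in principle; the
convention is rarely stated). Trans: Pearson correlation on
log₂(FPKM + 0.1) across all samples pooled — pooling maximizes *n* and the
log scale matches how FPKM heatmaps are drawn; thresholds are strict
(r > 0.7, r < −0.7). Zero-variance profiles are skipped with a warning.
Enrichment is a one-sided hypergeometric test per term against a
background of expressed protein-coding genes, BH within each namespace;
annotations are taken as already propagated up the GO graph (no DAG
handling). BH is used instead of g:Profiler's g:SCS correction — a
documented divergence.

## Splicing usage

For each exon/junction the counts are summed per condition and compared
against the rest of the locus in a 2×2 Fisher exact test, BH across all
features of all loci. This replaces a per-feature negative-binomial GLM:
it flags the same kind of events (shifts in a feature's share of its
locus) but does not model biological overdispersion, so its event counts
are comparable in kind, not numerically, to GLM output. Loci with one
feature are skipped (usage is undefined). Usage profiles scale each
sample to the median library total, then average per condition.

## qPCR

Technical replicates are averaged per (sample, gene); each gene's relative
quantity is E^(Ctmin − Ct) with the per-gene minimum Ct across samples as
calibrator (qBase convention — the calibrator cancels from group ratios);
the per-sample normalization factor is the geometric mean of the
reference-gene quantities; NRQ = RQ/factor. Amplification efficiency
defaults to 2.0 (perfect doubling) and is configurable per run. NRQs are
invariant to per-sample Ct shifts, and with a single reference gene the
method reduces to classical 2^−ΔΔCt up to the calibrator convention
(both tested). Group comparison is a pooled-variance Student's *t*.

## The synthetic-data generator

`simulate()` emulates the screen's study design: 2 conditions × 3
timepoints (3/12/24 h) × 2 replicates, a multi-biotype reference
annotation (~60 genes: protein-coding, lncRNA, snoRNA, snRNA, miRNA,
processed transcript, pseudogene) and ~120 assembled transcripts on
3 × 1 Mb chromosomes — seconds to generate. Every assembled transcript
carries exactly one planted fate: one class per cascade step
(sense-overlapping, single-exon, short < 200 nt, coding-like with an
in-frame ORF ≥ 300 nt, small-RNA hit) plus known copies (identical intron
chains with jittered ends), intergenic lncRNAs and antisense lncRNAs per
partner biotype. Noncoding sequences are drawn from the AT-rich model
with stop codons stamped into all three frames every 75 nt, so the
maximum ORF stays below 100 nt and both built-in scorers vote non-coding
deterministically.

Loci are laid out round-robin with a 15 kb isolation gap — larger than
the 10 kb cis window — so the only DEL-gene proximities are the planted
ones and the cis target set is exactly recoverable. Expression is built
from per-feature baseline means (lognormal-scale uniforms; coding genes
higher than lncRNAs) with planted per-timepoint log₂ effects; `+Inf`
effects set the control mean to exactly 0 (an unexpressed transcript has
FPKM exactly 0, never a small positive, so the sentinel path is
exercised). Trans-target genes mirror their lncRNA's centered log profile
(sign-flipped for negative pairs), giving population |r| ≈ 1 before
noise. Noise is multiplicative lognormal, default σ = 0.1; a single seed
drives all randomness through spawned child streams, so outputs are
byte-identical across runs.

What passing tests show — and what they do not: exact ground-truth
recovery on noiseless data demonstrates that the *logic* of every filter,
threshold and sentinel is implemented correctly, not that the pipeline's
statistical performance transfers to real data. The generator has no
read-level error, no isoform ambiguity, no overdispersion beyond
lognormal noise, and its planted effects are far cleaner than biology; at
n = 2 per group, real-data operating characteristics are dominated by
factors the generator deliberately omits.

## Numerical choices

Welch/Student/Pearson/Fisher/hypergeometric statistics are computed with
scipy, BH with statsmodels; tests verify each against independent
closed-form or enumeration oracles (1e-8–1e-12 agreement). Degenerate
inputs are handled explicitly: zero-variance Welch (above), constant
heatmap rows (zeros + flag, with a 1e-9 relative tolerance on the sd),
zero-variance correlation profiles (skipped), single-feature loci
(skipped), samples missing a reference gene (excluded with a warning).

## Known limitations

Counts from a real screen (tens of thousands of transcripts, thousands of
lncRNAs) are not reproducible at this scale and are out of scope, as are
the external tools themselves (their scores are ingested), read
processing, assembly, count-model differential expression and GO DAG
propagation.
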