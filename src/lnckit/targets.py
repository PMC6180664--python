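"""Cis/trans target prediction for DELs and GO over-representation.

Cis targets are protein-coding genes whose span lies within a fixed window
(default 10 kb, boundary inclusive, strand-blind) of a DEL locus. Trans
targets are genes whose expression correlates with a DEL beyond a Pearson
threshold (default |r| > 0.7, strict) across all samples jointly, computed
on log2(FPKM + 0.1). Enrichment is a one-sided hypergeometric test per GO
term with BH adjustment within each namespace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotationSet
from .diffexpr import DELRecord
from .intervals import GenomicInterval

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


@dataclass(frozen=True)
class TargetAssociation:
    lnc_id: str
    gene_id: str
    mode: str  # cis | trans_positive | trans_negative
    distance: int | None = None  # bp, cis only
    r: float | None = None  # Pearson, trans only


def cis_targets(
    dels: Sequence[DELRecord],
    coding_genes: AnnotationSet,
    window: int = 10_000,
) -> list[TargetAssociation]:
    """Protein-coding genes within ``window`` bp of each DEL locus.

    The gap is measured between genomic spans on either strand and either
    side; overlapping features are at distance 0 and the window boundary is
    inclusive.
    """
    coding = coding_genes.subset(["protein_coding"])
    out = []
    for rec in dels:
        if rec.locus is None:
            continue
        loc = rec.locus
        # pad by 1 so spans touching the window boundary are candidates
        lo, hi = max(0, loc.start - window - 1), loc.end + window + 1
        for gid in sorted(coding.query(loc.chrom, lo, hi, level="span")):
            gene = coding.get(gid)
            gap = loc.gap_to(gene.interval)
            if gap is not None and gap <= window:
                out.append(
                    TargetAssociation(rec.lnc_id, gid, "cis", distance=gap)
                )
    return out


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Pearson product-moment correlation; None (with a warning) when
    either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("vectors must have equal length >= 3")
    if x.var() == 0 or y.var() == 0:
        warnings.warn("zero-variance vector; correlation undefined")
        return None
    return float(stats.pearsonr(x, y).statistic)


def trans_targets(
    dels_expr: pd.DataFrame,
    genes_expr: pd.DataFrame,
    r_threshold: float = 0.7,
    log_transform: bool = True,
    pseudocount: float = 0.1,
) -> tuple[list[TargetAssociation], list[TargetAssociation]]:
    """Screen all DEL x gene pairs for co-expression across all samples.

    Returns (positive, negative) association lists partitioned at the
    strict thresholds r > r_threshold and r < -r_threshold. Pairs where
    either profile has zero variance are skipped.
    """
    if list(dels_expr.columns) != list(genes_expr.columns):
        raise ValueError("DEL and gene matrices must share the same samples")
    d = dels_expr.to_numpy(dtype=float)
    g = genes_expr.to_numpy(dtype=float)
    if log_transform:
        d = np.log2(d + pseudocount)
        g = np.log2(g + pseudocount)
    dsd = d.std(axis=1)
    gsd = g.std(axis=1)
    dz = (d - d.mean(axis=1, keepdims=True))
    gz = (g - g.mean(axis=1, keepdims=True))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (dz @ gz.T) / (d.shape[1] * np.outer(dsd, gsd))
    positive, negative = [], []
    for i, lnc in enumerate(dels_expr.index):
        if dsd[i] == 0:
            continue
        for j, gene in enumerate(genes_expr.index):
            if gsd[j] == 0:
                continue
            rij = float(r[i, j])
            if rij > r_threshold:
                positive.append(
                    TargetAssociation(lnc, gene, "trans_positive", r=rij)
                )
            elif rij < -r_threshold:
                negative.append(
                    TargetAssociation(lnc, gene, "trans_negative", r=rij)
                )
    return positive, negative


def associations_table(assocs: Iterable[TargetAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lnc_id": a.lnc_id,
                "gene_id": a.gene_id,
                "mode": a.mode,
                "distance": a.distance,
                "r": a.r,
            }
            for a in assocs
        ]
    )


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    namespace: str
    k: int  # term hits in target set
    K: int  # term hits in background
    n: int  # target set size
    N: int  # background size
    p_raw: float
    p_adjusted: float


def go_enrichment(
    target_genes: Iterable[str],
    background_genes: Iterable[str],
    gene2term: pd.DataFrame | Mapping[str, Iterable[tuple[str, str]]],
    alpha: float = 0.05,
    term_names: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation test per GO term.

    ``gene2term`` is a table with gene_id / term_id / namespace columns (an
    optional term_name column is carried through) or an equivalent mapping.
    Terms with no target hit are skipped; BH adjustment runs within each
    namespace. Annotations are taken as already propagated up the ontology.
    """
    target = set(target_genes)
    background = set(background_genes)
    if not target <= background:
        raise ValueError("target genes must be a subset of the background")
    if isinstance(gene2term, pd.DataFrame):
        df = gene2term
        names = term_names or {}
        if "term_name" in df.columns:
            names = {**dict(zip(df["term_id"], df["term_name"])), **names}
        pairs = [
            (str(r.gene_id), str(r.term_id), str(r.namespace))
            for r in df.itertuples(index=False)
        ]
    else:
        names = dict(term_names or {})
        pairs = [
            (g, t, ns)
            for g, terms in gene2term.items()
            for t, ns in terms
        ]
    term_genes: dict[tuple[str, str], set[str]] = {}
    for g, t, ns in pairs:
        if g in background:
            term_genes.setdefault((t, ns), set()).add(g)
    N, n = len(background), len(target)
    by_ns: dict[str, list[EnrichmentResult]] = {}
    for (term, ns), genes in sorted(term_genes.items()):
        K = len(genes)
        k = len(genes & target)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        by_ns.setdefault(ns, []).append(
            EnrichmentResult(term, names.get(term, ""), ns, k, K, n, N, p, p)
        )
    out: list[EnrichmentResult] = []
    for ns, results in by_ns.items():
        from .diffexpr import adjust_bh

        adj = adjust_bh([r.p_raw for r in results])
        for r, pa in zip(results, adj):
            r.p_adjusted = float(pa)
        out.extend(results)
    out.sort(key=lambda r: (r.p_adjusted, r.term_id))
    return out
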