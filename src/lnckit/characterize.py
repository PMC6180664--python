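"""Genomic-feature summaries of lncRNAs vs mRNAs and Welch's t comparisons.

Transcript-level metrics (spliced length, exon count, mean FPKM) use one
transcript as the unit; the exon-length metric pools every exon of the
group, so its n is the exon total. Summaries report mean +- SE and a binned
percentage distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .expression import ExpressionMatrix
from .intervals import TranscriptModel

#: Default bin edges; the first/last bins are open-ended.
DEFAULT_BINS: dict[str, list[float]] = {
    "transcript_length": [200, 1000, 2000, 3000, 4000, 5000],
    "exon_length": [50, 200, 500],
    "exon_count": [2, 3, 4, 5, 6, 7, 8, 9, 10],
    "fpkm": [2, 10],
}

METRICS = ("transcript_length", "exon_length", "exon_count", "fpkm")


@dataclass
class FeatureSummary:
    group: str
    metric: str
    mean: float
    se: float
    n: int
    bin_percentages: list[tuple[str, float]]


@dataclass
class WelchResult:
    """Welch's unequal-variance t-test: statistic, Welch-Satterthwaite df
    (non-integer) and two-sided p."""

    t: float
    df: float
    p: float
    degenerate: bool = False


def welch_t(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Two-sided Welch's t-test between two samples (each n >= 2).

    If both samples have zero variance the test degenerates: equal means
    give t = 0, p = 1; unequal means give p = 0 with the degenerate flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(len(a) + len(b) - 2), 1.0, True)
        t = math.inf if a.mean() > b.mean() else -math.inf
        return WelchResult(t, float(len(a) + len(b) - 2), 0.0, True)
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return WelchResult(float(res.statistic), float(df), float(res.pvalue))


def _bin_label(edges: list[float], i: int, integer: bool) -> str:
    fmt = (lambda x: f"{int(x)}") if integer else (lambda x: f"{x:g}")
    if i == 0:
        return f"<{fmt(edges[0])}"
    if i == len(edges):
        return f">={fmt(edges[-1])}"
    return f"{fmt(edges[i - 1])}-{fmt(edges[i])}"


def _bin_percentages(
    values: np.ndarray, edges: list[float], integer: bool = False
) -> list[tuple[str, float]]:
    idx = np.searchsorted(edges, values, side="right")
    out = []
    for i in range(len(edges) + 1):
        pct = 100.0 * float((idx == i).sum()) / len(values)
        out.append((_bin_label(edges, i, integer), pct))
    return out


def summarize_features(
    transcripts: Sequence[TranscriptModel],
    expr: ExpressionMatrix | None = None,
    group: str = "lncRNA",
    bins: Mapping[str, list[float]] | None = None,
) -> dict[str, FeatureSummary]:
    """Mean +- SE and binned percentage distribution of transcript length,
    exon length, exon number and FPKM for one transcript group.

    FPKM per transcript is its mean over all samples; the fpkm metric is
    skipped when ``expr`` is None or covers none of the group.
    """
    if not transcripts:
        raise ValueError("empty transcript group")
    bins = dict(DEFAULT_BINS) | dict(bins or {})
    data: dict[str, np.ndarray] = {
        "transcript_length": np.array(
            [t.spliced_length for t in transcripts], dtype=float
        ),
        "exon_length": np.array(
            [e.length for t in transcripts for e in t.exons], dtype=float
        ),
        "exon_count": np.array([t.exon_count for t in transcripts], dtype=float),
    }
    if expr is not None:
        ids = [
            t.transcript_id
            for t in transcripts
            if t.transcript_id in expr.values.index
        ]
        if ids:
            data["fpkm"] = expr.values.loc[ids].mean(axis=1).to_numpy()
    out = {}
    for metric, vals in data.items():
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out[metric] = FeatureSummary(
            group=group,
            metric=metric,
            mean=float(vals.mean()),
            se=sd / math.sqrt(len(vals)),
            n=len(vals),
            bin_percentages=_bin_percentages(
                vals, list(bins[metric]), integer=(metric == "exon_count")
            ),
        )
    return out


def compare_groups_welch(
    a: Sequence[TranscriptModel],
    b: Sequence[TranscriptModel],
    expr: ExpressionMatrix | None = None,
) -> dict[str, WelchResult]:
    """Welch's t between two transcript groups for each feature metric."""
    out = {}
    for metric in ("transcript_length", "exon_length", "exon_count", "fpkm"):
        if metric == "transcript_length":
            xa = [t.spliced_length for t in a]
            xb = [t.spliced_length for t in b]
        elif metric == "exon_length":
            xa = [e.length for t in a for e in t.exons]
            xb = [e.length for t in b for e in t.exons]
        elif metric == "exon_count":
            xa = [t.exon_count for t in a]
            xb = [t.exon_count for t in b]
        else:
            if expr is None:
                continue
            xa = [
                float(expr.values.loc[t.transcript_id].mean())
                for t in a
                if t.transcript_id in expr.values.index
            ]
            xb = [
                float(expr.values.loc[t.transcript_id].mean())
                for t in b
                if t.transcript_id in expr.values.index
            ]
            if len(xa) < 2 or len(xb) < 2:
                continue
        out[metric] = welch_t(xa, xb)
    return out
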