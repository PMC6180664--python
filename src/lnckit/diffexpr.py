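"""Differential expression of lncRNAs with fold-change sentinels.

Fold changes are computed on raw FPKM condition means: when the transcript
is silent in control but expressed under treatment the log2 fold change is
the +Inf sentinel (reported as the token "Inf" in tables); silent under
treatment gives -Inf; silent in both gives no value. The significance test
is a variance-moderated two-sample t on log2(FPKM + c) — a documented
stand-in for count-model tools, suited to the tiny replicate numbers the
screen design uses — with Benjamini-Hochberg adjustment per timepoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix
from .intervals import GenomicInterval, parse_locus

INF_TOKEN = "Inf"


def log2fc(treated_mean: float, control_mean: float) -> float | None:
    """log2(treated/control) with zero-expression sentinels.

    control > 0 and treated > 0 -> finite ratio; control == 0 < treated ->
    +inf; treated == 0 < control -> -inf; both zero -> None (no value).
    """
    if treated_mean < 0 or control_mean < 0:
        raise ValueError("FPKM means must be non-negative")
    if treated_mean == 0 and control_mean == 0:
        return None
    if control_mean == 0:
        return math.inf
    if treated_mean == 0:
        return -math.inf
    return math.log2(treated_mean / control_mean)


def moderated_test(
    expr: ExpressionMatrix,
    timepoint: int,
    pseudocount: float = 0.1,
    shrink: float = 0.5,
    floor: float = 0.5,
) -> pd.Series:
    """Per-transcript two-sided raw p at one timepoint.

    A Welch-style t on log2(FPKM + pseudocount) whose per-group variances
    are shrunk toward the across-transcript mean within-group variance with
    weight ``shrink`` (0 recovers the ordinary Welch t exactly). Transcripts
    silent in one condition have no finite statistic and fall back to a
    presence/absence rule: p = 0 when every replicate on the silent side is
    exactly 0 and every replicate on the expressed side reaches ``floor``
    FPKM, else p = 1.
    """
    ctrl = expr.samples_for("control", timepoint)
    trt = expr.samples_for("treated", timepoint)
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError(
            "need >= 2 replicates per condition; supply precomputed p-values "
            "(p_source='provided') for unreplicated designs"
        )
    c = expr.values[ctrl].to_numpy(dtype=float)
    t = expr.values[trt].to_numpy(dtype=float)
    silent_ctrl = (c == 0).all(axis=1)
    silent_trt = (t == 0).all(axis=1)
    sentinel = silent_ctrl ^ silent_trt

    lc = np.log2(c + pseudocount)
    lt = np.log2(t + pseudocount)
    vc = lc.var(axis=1, ddof=1)
    vt = lt.var(axis=1, ddof=1)
    regular = ~sentinel
    if regular.any():
        vbar = 0.5 * (vc[regular].mean() + vt[regular].mean())
    else:
        vbar = 0.0
    svc = (1 - shrink) * vc + shrink * vbar
    svt = (1 - shrink) * vt + shrink * vbar
    nc, nt = c.shape[1], t.shape[1]
    sea, seb = svt / nt, svc / nc
    denom = np.sqrt(sea + seb)
    diff = lt.mean(axis=1) - lc.mean(axis=1)
    p = np.ones(len(diff))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = diff / denom
        df = (sea + seb) ** 2 / (sea**2 / (nt - 1) + seb**2 / (nc - 1))
    ok = regular & (denom > 0)
    p[ok] = 2 * stats.t.sf(np.abs(tstat[ok]), df[ok])
    # zero variance, nonzero difference: perfectly separated -> p ~ 0
    degen = regular & (denom == 0) & (diff != 0)
    p[degen] = 0.0

    # presence/absence rule for one-sided-silent transcripts
    present_trt = silent_ctrl & (t >= floor).all(axis=1)
    present_ctrl = silent_trt & (c >= floor).all(axis=1)
    p[sentinel] = 1.0
    p[sentinel & (present_trt | present_ctrl)] = 0.0
    return pd.Series(p, index=expr.values.index, name=f"p_{timepoint}h")


def adjust_bh(pvalues: Sequence[float] | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (same order as input)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class TimepointCall:
    """One timepoint's entry of a DEL record."""

    log2fc: float  # may be +-inf
    p_adjusted: float | None = None

    @property
    def direction(self) -> str:
        if math.isinf(self.log2fc):
            return "treated_only" if self.log2fc > 0 else "control_only"
        return "up" if self.log2fc > 0 else "down"


@dataclass
class DELRecord:
    """A differentially expressed lncRNA with per-timepoint calls."""

    lnc_id: str
    locus_id: str = ""
    locus: GenomicInterval | None = None
    calls: dict[int, TimepointCall] = field(default_factory=dict)

    @property
    def treated_only(self) -> bool:
        return any(
            math.isinf(c.log2fc) and c.log2fc > 0 for c in self.calls.values()
        )

    def finite_fcs(self) -> list[float]:
        return [c.log2fc for c in self.calls.values() if math.isfinite(c.log2fc)]


def call_dels(
    expr: ExpressionMatrix,
    alpha: float = 0.05,
    lfc: float = 1.0,
    p_source: str = "internal",
    p_table: pd.DataFrame | None = None,
    loci: Mapping[str, GenomicInterval] | None = None,
    locus_ids: Mapping[str, str] | None = None,
    floor: float = 0.5,
) -> list[DELRecord]:
    """Call DELs per timepoint and merge records across timepoints.

    A transcript is a DEL at a timepoint iff its BH-adjusted p < ``alpha``
    and either |log2FC| >= ``lfc`` (finite case) or the fold change is a
    +-Inf sentinel. ``p_source='provided'`` takes raw p-values from
    ``p_table`` (transcripts x timepoint columns named like '3').
    """
    records: dict[str, DELRecord] = {}
    for tp in expr.timepoints:
        ctrl = expr.samples_for("control", tp)
        trt = expr.samples_for("treated", tp)
        cmean = expr.values[ctrl].mean(axis=1)
        tmean = expr.values[trt].mean(axis=1)
        if p_source == "provided":
            if p_table is None:
                raise ValueError("p_source='provided' needs p_table")
            praw = p_table[str(tp)].reindex(expr.values.index)
        else:
            praw = moderated_test(expr, tp, floor=floor)
        padj = pd.Series(adjust_bh(praw.to_numpy()), index=praw.index)
        for tid in expr.values.index:
            fc = log2fc(float(tmean[tid]), float(cmean[tid]))
            if fc is None:
                continue
            pa = float(padj[tid])
            passes_fc = math.isinf(fc) or abs(fc) >= lfc
            if pa < alpha and passes_fc:
                rec = records.setdefault(
                    tid,
                    DELRecord(
                        lnc_id=tid,
                        locus_id=(locus_ids or {}).get(tid, ""),
                        locus=(loci or {}).get(tid),
                    ),
                )
                rec.calls[tp] = TimepointCall(fc, pa)
    return [records[tid] for tid in sorted(records)]


# ---------------------------------------------------------------------------
# Table-shaped output, tallies, z-score heatmap


def _fc_token(value: float | None) -> str:
    if value is None:
        return ""
    if math.isinf(value):
        return INF_TOKEN if value > 0 else f"-{INF_TOKEN}"
    return f"{value:.2f}"


@dataclass
class DELTabulation:
    table: pd.DataFrame
    n_records: int
    tallies: dict[int, int]  # records with a reported value per timepoint
    n_treated_only: int
    n_down: dict[int, int]
    n_all_timepoints: int
    finite_fc_max: float | None
    finite_fc_min: float | None
    heatmap_z: pd.DataFrame | None = None
    constant_rows: list[str] = field(default_factory=list)


def tabulate_dels(
    dels: Sequence[DELRecord],
    expr: ExpressionMatrix | None = None,
    timepoints: Sequence[int] = (3, 12, 24),
    pseudocount: float = 0.1,
) -> DELTabulation:
    """Summarize DEL records into a report table with per-timepoint
    tallies, the finite fold-change range and (optionally) a per-row
    z-scored log-FPKM heatmap matrix, z = (x - mean(x)) / sd(x)."""
    if not dels:
        raise ValueError("no DEL records to tabulate")
    rows = []
    for i, rec in enumerate(dels, start=1):
        row: dict[str, object] = {
            "No.": i,
            "lncRNA": rec.lnc_id,
            "XLOC": rec.locus_id,
            "locus": str(rec.locus) if rec.locus else "",
        }
        for tp in timepoints:
            call = rec.calls.get(tp)
            row[f"log2FC_{tp}h"] = _fc_token(call.log2fc if call else None)
        rows.append(row)
    table = pd.DataFrame(rows)

    tallies = {
        tp: sum(1 for r in dels if tp in r.calls) for tp in timepoints
    }
    n_down = {
        tp: sum(
            1
            for r in dels
            if tp in r.calls
            and math.isfinite(r.calls[tp].log2fc)
            and r.calls[tp].log2fc < 0
        )
        for tp in timepoints
    }
    finite = [fc for r in dels for fc in r.finite_fcs()]
    heatmap = None
    constant_rows: list[str] = []
    if expr is not None:
        ids = [r.lnc_id for r in dels if r.lnc_id in expr.values.index]
        logf = np.log10(expr.values.loc[ids].to_numpy(dtype=float) + pseudocount)
        mu = logf.mean(axis=1, keepdims=True)
        sd = logf.std(axis=1, ddof=0, keepdims=True)
        z = np.zeros_like(logf)
        # tolerance absorbs float jitter in the std of a constant row
        nonconst = (sd > 1e-9 * np.maximum(1.0, np.abs(mu))).ravel()
        z[nonconst] = (logf[nonconst] - mu[nonconst]) / sd[nonconst]
        constant_rows = [tid for tid, ok in zip(ids, nonconst) if not ok]
        heatmap = pd.DataFrame(z, index=ids, columns=expr.values.columns)
    return DELTabulation(
        table=table,
        n_records=len(dels),
        tallies=tallies,
        n_treated_only=sum(1 for r in dels if r.treated_only),
        n_down=n_down,
        n_all_timepoints=sum(
            1 for r in dels if all(tp in r.calls for tp in timepoints)
        ),
        finite_fc_max=max(finite) if finite else None,
        finite_fc_min=min(finite) if finite else None,
        heatmap_z=heatmap,
        constant_rows=constant_rows,
    )


def write_del_table(dels: Sequence[DELRecord], path: str | Path) -> None:
    tabulate_dels(dels).table.to_csv(path, sep="\t", index=False)


def read_del_table(path: str | Path) -> list[DELRecord]:
    """Parse a DEL table TSV (columns No., lncRNA, XLOC, locus,
    log2FC_<tp>h with "Inf" tokens and empty cells) into DELRecords."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    tp_cols = [c for c in df.columns if c.startswith("log2FC_")]
    out = []
    for row in df.itertuples(index=False):
        rec = DELRecord(
            lnc_id=getattr(row, "lncRNA"),
            locus_id=getattr(row, "XLOC", ""),
            locus=parse_locus(row.locus) if getattr(row, "locus", "") else None,
        )
        for col in tp_cols:
            raw = getattr(row, col).strip()
            if not raw:
                continue
            tp = int(col.removeprefix("log2FC_").removesuffix("h"))
            if raw.replace("−", "-").lstrip("+-") == INF_TOKEN:
                value = math.inf if not raw.startswith(("-", "−")) else -math.inf
            else:
                value = float(raw.replace("−", "-"))
            rec.calls[tp] = TimepointCall(value)
        out.append(rec)
    return out
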