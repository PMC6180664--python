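"""Differential usage of exons and splice junctions within lncRNA loci.

A simplified usage statistic: for each exon/junction feature the counts are
summed per condition and compared against the rest of its locus in a 2x2
Fisher exact test (two-sided), with BH adjustment across all features of
all loci. This flags the same kind of events a per-feature GLM would —
shifts in the share of a locus's reads attributed to one feature — without
modelling overdispersion.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_bh

META_COLS = ("locus_id", "feature_id", "kind")


def _sample_columns(counts: pd.DataFrame) -> list[str]:
    return [c for c in counts.columns if c not in META_COLS]


def _validate_counts(counts: pd.DataFrame) -> None:
    for col in META_COLS:
        if col not in counts.columns:
            raise ValueError(f"counts table needs a {col!r} column")
    dup = counts.duplicated(subset=["locus_id", "feature_id"])
    if dup.any():
        raise ValueError("feature ids must be unique within a locus")
    arr = counts[_sample_columns(counts)].to_numpy()
    if (arr < 0).any() or not np.equal(np.mod(arr, 1), 0).all():
        raise ValueError("counts must be non-negative integers")


def differential_usage(
    counts: pd.DataFrame,
    design: Mapping[str, str] | pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature usage test between conditions.

    ``counts``: one row per feature with locus_id, feature_id, kind and one
    column per sample. ``design`` maps sample id -> 'control'/'treated'.
    Returns a table with the usage statistic (odds ratio of the pooled 2x2
    table), raw and BH-adjusted p, and a flag at ``alpha``. Loci with a
    single feature are skipped with a warning — usage is undefined there.
    """
    _validate_counts(counts)
    design = pd.Series(dict(design))
    samples = _sample_columns(counts)
    ctrl = [s for s in samples if design.get(s) == "control"]
    trt = [s for s in samples if design.get(s) == "treated"]
    if not ctrl or not trt:
        raise ValueError("need >= 1 sample per condition")
    rows = []
    for locus, sub in counts.groupby("locus_id", sort=True):
        if len(sub) < 2:
            warnings.warn(f"locus {locus} has a single feature; skipped")
            continue
        trt_tot = sub[trt].to_numpy().sum()
        ctrl_tot = sub[ctrl].to_numpy().sum()
        for _, feat in sub.iterrows():
            a = int(feat[trt].sum())  # feature, treated
            b = int(trt_tot - a)      # rest of locus, treated
            c = int(feat[ctrl].sum())
            d = int(ctrl_tot - c)
            odds, p = stats.fisher_exact([[a, b], [c, d]], "two-sided")
            rows.append(
                {
                    "locus_id": locus,
                    "feature_id": feat["feature_id"],
                    "kind": feat["kind"],
                    "usage_odds_ratio": float(odds),
                    "p_raw": float(p),
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(p_adjusted=[], flagged=[])
    out["p_adjusted"] = adjust_bh(out["p_raw"].to_numpy())
    out["flagged"] = out["p_adjusted"] < alpha
    return out


def usage_profile(
    counts: pd.DataFrame,
    locus_id: str,
    design: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Mean normalized counts per feature and condition for one locus.

    Samples are scaled so each library total equals the median library
    total (computed over all loci), then counts are averaged per condition.
    """
    _validate_counts(counts)
    design = pd.Series(dict(design))
    samples = _sample_columns(counts)
    sub = counts[counts["locus_id"] == locus_id]
    if sub.empty:
        raise KeyError(f"unknown locus {locus_id!r}")
    libsize = counts[samples].sum(axis=0).astype(float)
    scale = libsize.median() / libsize
    scaled = sub[samples].astype(float) * scale
    out = pd.DataFrame(index=sub["feature_id"])
    for cond in sorted(set(design.values)):
        cols = [s for s in samples if design.get(s) == cond]
        out[cond] = scaled[cols].mean(axis=1).to_numpy()
    return out
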