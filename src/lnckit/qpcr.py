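"""qPCR relative quantification against multiple reference genes.

Implements the qBase-style workflow: technical replicates are averaged,
each gene's quantities are expressed relative to its minimum Ct across
samples (RQ = E^(Ct_min - Ct)), per-sample normalization factors are the
geometric mean of the reference-gene RQs, and target NRQ = RQ / factor.
With perfect efficiency (E = 2) and one reference gene this reduces to the
classical 2^-ddCt up to the calibrator convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CtTable:
    """Long-format Ct measurements with gene roles and a sample design.

    ``data`` columns: sample, gene, replicate, ct. ``roles`` maps gene ->
    'target'/'reference' (>= 2 reference genes expected, e.g. GAPDH and
    beta-actin). ``design`` maps sample -> condition.
    """

    data: pd.DataFrame
    roles: Mapping[str, str]
    design: Mapping[str, str]

    def __post_init__(self) -> None:
        need = {"sample", "gene", "replicate", "ct"}
        if not need <= set(self.data.columns):
            raise ValueError(f"Ct table needs columns {sorted(need)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        refs = [g for g, r in self.roles.items() if r == "reference"]
        if len(refs) < 2:
            warnings.warn(
                "fewer than 2 reference genes; normalization is fragile"
            )

    @classmethod
    def from_tsv(
        cls, path: str | Path, design: Mapping[str, str]
    ) -> "CtTable":
        df = pd.read_csv(path, sep="\t")
        roles = dict(zip(df["gene"], df["role"]))
        return cls(df.drop(columns=["role"]), roles, design)

    @property
    def reference_genes(self) -> list[str]:
        return sorted(g for g, r in self.roles.items() if r == "reference")

    @property
    def target_genes(self) -> list[str]:
        return sorted(g for g, r in self.roles.items() if r == "target")


def relative_expression(
    ct: CtTable, efficiency: float = 2.0
) -> pd.DataFrame:
    """Normalized relative quantities (samples x target genes).

    Samples missing any reference gene are excluded with a warning.
    ``efficiency`` is the per-cycle amplification factor, in (1, 2].
    """
    if not (1.0 < efficiency <= 2.0):
        raise ValueError("efficiency must be in (1, 2]")
    mean_ct = (
        ct.data.groupby(["sample", "gene"])["ct"].mean().unstack("gene")
    )
    refs = ct.reference_genes
    ok = mean_ct[refs].notna().all(axis=1)
    if not ok.all():
        dropped = list(mean_ct.index[~ok])
        warnings.warn(f"samples missing a reference gene, excluded: {dropped}")
        mean_ct = mean_ct.loc[ok]
    rq = efficiency ** (mean_ct.min(axis=0) - mean_ct)
    norm = np.exp(np.log(rq[refs]).mean(axis=1))  # geometric mean
    nrq = rq[ct.target_genes].div(norm, axis=0)
    nrq.columns.name = None
    return nrq


@dataclass
class GroupComparison:
    means: dict[str, float]
    sems: dict[str, float]
    n: dict[str, int]
    t: float
    p: float


def compare_groups(
    nrq: pd.Series, labels: Mapping[str, str]
) -> GroupComparison:
    """Pooled-variance two-sample Student's t on per-sample NRQs.

    ``labels`` maps sample id -> group name (two groups, each n >= 2).
    Returns mean +- SEM per group and the two-sided p.
    """
    groups = sorted(set(labels.values()))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    vals = {
        g: nrq[[s for s in nrq.index if labels.get(s) == g]].to_numpy(float)
        for g in groups
    }
    for g, v in vals.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    a, b = vals[groups[0]], vals[groups[1]]
    res = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        means={g: float(v.mean()) for g, v in vals.items()},
        sems={g: float(stats.sem(v)) for g, v in vals.items()},
        n={g: len(v) for g, v in vals.items()},
        t=float(res.statistic),
        p=float(res.pvalue),
    )
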