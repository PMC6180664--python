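"""FPKM expression matrices with a condition x timepoint x replicate design."""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("control", "treated")

#: Sample-name pattern "C_3h_r1" / "TCDD_24h_r2" used by the generator.
_SAMPLE_RE = re.compile(r"^(?P<cond>[A-Za-z0-9]+)_(?P<tp>\d+)h_r(?P<rep>\d+)$")

_COND_ALIASES = {"c": "control", "ctrl": "control", "control": "control"}


def parse_sample_name(name: str) -> tuple[str, int, int]:
    """(condition, timepoint h, replicate) from a "C_3h_r1"-style id; any
    non-control condition token (e.g. "TCDD") maps to 'treated'."""
    m = _SAMPLE_RE.match(name)
    if m is None:
        raise ValueError(f"cannot parse sample name {name!r}")
    cond = _COND_ALIASES.get(m.group("cond").lower(), "treated")
    return cond, int(m.group("tp")), int(m.group("rep"))


def design_from_sample_names(samples: list[str]) -> pd.DataFrame:
    rows = []
    for s in samples:
        cond, tp, rep = parse_sample_name(s)
        rows.append((s, cond, tp, rep))
    return pd.DataFrame(
        rows, columns=["sample", "condition", "timepoint", "replicate"]
    ).set_index("sample")


@dataclass
class ExpressionMatrix:
    """Transcript/gene x sample FPKM table plus the sample design.

    ``values``: DataFrame, rows = feature ids, columns = sample ids.
    ``design``: DataFrame indexed by sample id with columns condition
    ('control'/'treated'), timepoint (hours, int) and replicate (int).
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        bad = set(self.design["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("FPKM values must be finite")
        if (arr < 0).any():
            raise ValueError("FPKM values must be non-negative")
        self.design = self.design.loc[list(self.values.columns)]

    @classmethod
    def from_tsv(
        cls, path: str | Path, design_path: str | Path | None = None
    ) -> "ExpressionMatrix":
        """Read an FPKM TSV (first column = feature id). If no design table
        is given, the design is parsed from the sample names."""
        values = pd.read_csv(path, sep="\t", index_col=0)
        if design_path is not None:
            design = pd.read_csv(design_path, sep="\t", index_col=0)
        else:
            design = design_from_sample_names(list(values.columns))
        return cls(values, design)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="id")

    @property
    def timepoints(self) -> list[int]:
        return sorted(self.design["timepoint"].unique())

    def samples_for(self, condition: str, timepoint: int) -> list[str]:
        mask = (self.design["condition"] == condition) & (
            self.design["timepoint"] == timepoint
        )
        return list(self.design.index[mask])

    def subset(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(feature_ids)], self.design)

    def mean_fpkm(self) -> pd.Series:
        """Per-feature mean FPKM over all samples."""
        return self.values.mean(axis=1)
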