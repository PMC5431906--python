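"""siRNA-screen CG expression analysis.

Supporting-read count tables (CGs x libraries, with flagged non-targeting
control libraries) are upper-quartile normalized, CGs are grouped by how
many control libraries detect them (nonzero raw count), and treatment values
are retained by the control-based expression threshold: for CGs detected in
at least three controls, a value must exceed the control mean plus two
sample standard deviations; CGs undetected in every control are assumed
unexpressed under control conditions and all their treatment values are
retained; everything else is discarded.  Retained CGs are counted per siRNA
treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SirnaCountTable",
    "upper_quartile_normalize",
    "group_cg_by_control_detection",
    "filter_cg_expression",
    "count_cg_per_treatment",
    "SirnaScreen",
    "SirnaScreenResult",
]


@dataclass
class SirnaCountTable:
    """Counts (rows = CG ids, columns = libraries) plus control flags."""

    counts: pd.DataFrame
    control_libraries: list[str]

    def __post_init__(self) -> None:
        missing = set(self.control_libraries) - set(self.counts.columns)
        if missing:
            raise ValueError(f"control libraries not in table: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def treatment_libraries(self) -> list[str]:
        return [c for c in self.counts.columns if c not in self.control_libraries]

    def to_tsv(self, path) -> None:
        long = self.counts.stack().rename("count").reset_index()
        long.columns = ["cg_id", "library", "count"]
        long["is_control"] = long["library"].isin(self.control_libraries).astype(int)
        long.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SirnaCountTable":
        long = pd.read_csv(path, sep="\t")
        counts = long.pivot(index="cg_id", columns="library", values="count")
        counts.columns.name = None
        counts.index.name = None
        controls = sorted(long.loc[long["is_control"] == 1, "library"].unique())
        # preserve a deterministic column order: controls first, then treatments
        order = controls + sorted(c for c in counts.columns if c not in controls)
        return cls(counts[order], controls)


def upper_quartile_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Upper-quartile library normalization to a common reference.

    Each library's values are divided by the 75th percentile of its nonzero
    counts and multiplied by the mean of those percentiles across libraries,
    so the transform is idempotent.  An all-zero library is an error.
    """
    quartiles = {}
    for lib in counts.columns:
        nz = counts[lib][counts[lib] > 0]
        if nz.empty:
            raise ValueError(f"library {lib!r} has no nonzero counts")
        quartiles[lib] = float(np.percentile(nz, 75))
    reference = float(np.mean(list(quartiles.values())))
    out = counts.astype(float).copy()
    for lib in counts.columns:
        out[lib] = out[lib] / quartiles[lib] * reference
    return out


def group_cg_by_control_detection(table: SirnaCountTable) -> dict[str, list]:
    """Partition CGs by the number of control libraries detecting them."""
    controls = table.counts[table.control_libraries]
    detected = (controls > 0).sum(axis=1)
    return {
        "in_ge3_controls": list(table.counts.index[detected >= 3]),
        "in_zero_controls": list(table.counts.index[detected == 0]),
        "other": list(table.counts.index[(detected > 0) & (detected < 3)]),
    }


def filter_cg_expression(
    normalized: pd.DataFrame,
    groups: dict[str, list],
    control_libraries: Sequence[str],
) -> pd.DataFrame:
    """Apply the control-based expression threshold to treatment values.

    Returns retained (cg_id, treatment, value) records: group-1 CG values
    must exceed the per-CG control mean + 2 sample SD; group-2 (never
    detected in controls) values are retained whenever positive; others are
    discarded.
    """
    control_libraries = list(control_libraries)
    treatments = [c for c in normalized.columns if c not in control_libraries]
    records = []
    ge3 = set(groups.get("in_ge3_controls", []))
    zero = set(groups.get("in_zero_controls", []))
    for cg in normalized.index:
        row = normalized.loc[cg]
        if cg in ge3:
            ctrl = row[control_libraries].to_numpy(dtype=float)
            threshold = ctrl.mean() + 2.0 * ctrl.std(ddof=1)
            for t in treatments:
                v = float(row[t])
                if v > threshold:
                    records.append({"cg_id": cg, "treatment": t, "value": v})
        elif cg in zero:
            for t in treatments:
                v = float(row[t])
                if v > 0:
                    records.append({"cg_id": cg, "treatment": t, "value": v})
    return pd.DataFrame(records, columns=["cg_id", "treatment", "value"])


def count_cg_per_treatment(records: pd.DataFrame, treatments: Sequence[str] | None = None) -> pd.Series:
    """Distinct retained CG ids per siRNA treatment."""
    if records.empty:
        counts = pd.Series(dtype=int)
    else:
        counts = records.groupby("treatment")["cg_id"].nunique()
    if treatments is not None:
        counts = counts.reindex(list(treatments), fill_value=0)
    return counts.astype(int)


@dataclass
class SirnaScreenResult:
    normalized: pd.DataFrame
    groups: dict[str, list]
    retained: pd.DataFrame
    counts_per_treatment: pd.Series

    def summary(self) -> str:
        g = self.groups
        lines = [
            "siRNA CG expression screen",
            f"  CGs: {len(self.normalized)}  "
            f"(>=3 controls: {len(g['in_ge3_controls'])}, "
            f"zero controls: {len(g['in_zero_controls'])}, "
            f"other: {len(g['other'])})",
            f"  retained records: {len(self.retained)}",
            "  CGs above threshold per treatment:",
        ]
        for t, n in self.counts_per_treatment.items():
            lines.append(f"    {t}: {n}")
        return "\n".join(lines)

    def plot_counts(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        self.counts_per_treatment.plot.bar(ax=ax)
        ax.set_ylabel("CGs above control threshold")
        return ax


class SirnaScreen:
    """Model object for the control-thresholded CG knockdown screen."""

    def __init__(self, table: SirnaCountTable):
        if len(table.control_libraries) < 3:
            raise ValueError("the screen needs >= 3 control libraries")
        self.table = table

    def fit(self) -> SirnaScreenResult:
        normalized = upper_quartile_normalize(self.table.counts)
        groups = group_cg_by_control_detection(self.table)
        retained = filter_cg_expression(
            normalized, groups, self.table.control_libraries
        )
        counts = count_cg_per_treatment(retained, self.table.treatment_libraries)
        return SirnaScreenResult(
            normalized=normalized,
            groups=groups,
            retained=retained,
            counts_per_treatment=counts,
        )
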