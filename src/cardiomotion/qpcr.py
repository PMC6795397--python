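"""Relative-quantification arithmetic for qPCR and group comparisons.

Implements the 2^-ΔΔCt method (target Cq normalized per sample to an
endogenous control such as U6 or miR-103, then referenced to a control
group), fold changes computed directly from printed per-group mean Cq
values, percent differences between group means, and unpaired t-tests
(pooled-variance Student by default, Welch behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CqTable",
    "GroupComparison",
    "normalize_dct",
    "fold_change_ddct",
    "fold_from_mean_cq",
    "percent_difference",
    "group_summary",
    "unpaired_t_test",
]


@dataclass(frozen=True)
class CqTable:
    """Long-format Cq table: one row per (sample, assay) measurement.

    ``data`` has columns ``sample``, ``group``, ``assay``, ``cq``;
    ``target_assay`` and ``control_assay`` name the assay of interest and
    the endogenous control.  Cq values may be negative: pre-normalized
    exported values commonly are.
    """

    data: pd.DataFrame
    target_assay: str
    control_assay: str

    def __post_init__(self) -> None:
        missing = {"sample", "group", "assay", "cq"} - set(self.data.columns)
        if missing:
            raise ValueError(f"CqTable missing columns: {sorted(missing)}")
        if len(self.data) == 0:
            raise ValueError("CqTable is empty")
        if not np.isfinite(self.data["cq"].to_numpy(dtype=float)).all():
            raise ValueError("Cq values must be finite")

    @classmethod
    def from_csv(cls, path: str | Path, target_assay: str, control_assay: str) -> "CqTable":
        return cls(pd.read_csv(path), target_assay, control_assay)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def normalize_dct(table: CqTable) -> pd.DataFrame:
    """Per-sample ΔCt = Cq(target) − Cq(control).

    Returns a frame with columns ``sample``, ``group``, ``dct`` in the
    target rows' order.  A sample with a target Cq but no control Cq is an
    error naming the sample.
    """
    df = table.data
    target = df[df["assay"] == table.target_assay]
    control = df[df["assay"] == table.control_assay].set_index("sample")["cq"]
    if len(target) == 0:
        raise ValueError(f"no rows for target assay {table.target_assay!r}")
    rows = []
    for _, row in target.iterrows():
        if row["sample"] not in control.index:
            raise ValueError(
                f"sample {row['sample']!r} has no Cq for control assay {table.control_assay!r}"
            )
        rows.append((row["sample"], row["group"], row["cq"] - control[row["sample"]]))
    return pd.DataFrame(rows, columns=["sample", "group", "dct"])


def fold_change_ddct(dct_treated, dct_control) -> float:
    """Fold change 2^(−ΔΔCt) with ΔΔCt = mean(ΔCt treated) − mean(ΔCt control)."""
    dct_treated = np.asarray(dct_treated, dtype=float)
    dct_control = np.asarray(dct_control, dtype=float)
    if dct_treated.size == 0 or dct_control.size == 0:
        raise ValueError("both groups must be nonempty")
    ddct = dct_treated.mean() - dct_control.mean()
    return float(2.0 ** (-ddct))


def fold_from_mean_cq(mean_cq_control: float, mean_cq_treated: float) -> float:
    """Fold change from already-normalized per-group mean Cq values.

    fold = 2^(Cq_control − Cq_treated); lower Cq means more template, so a
    treated mean below the control mean gives a fold above 1.
    """
    if not (np.isfinite(mean_cq_control) and np.isfinite(mean_cq_treated)):
        raise ValueError("mean Cq values must be finite")
    return float(2.0 ** (mean_cq_control - mean_cq_treated))


def percent_difference(mean_reference: float, mean_alternative: float) -> float:
    """Percent difference of the alternative group relative to the reference."""
    if mean_reference == 0:
        raise ValueError("reference mean must be nonzero")
    return 100.0 * (mean_alternative - mean_reference) / mean_reference


def group_summary(values) -> tuple[float, float | None, int]:
    """(mean, SEM, n); SEM uses the n−1 denominator and is None for n = 1."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be nonempty")
    n = values.size
    sem = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else None
    return float(values.mean()), sem, int(n)


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison: summaries, difference statistic, and t-test."""

    mean_a: float
    sem_a: float | None
    n_a: int
    mean_b: float
    sem_b: float | None
    n_b: int
    statistic: float  # fold change, ratio, or percent difference of b vs a
    statistic_kind: str  # "fold" (2^(a-b), Cq-scale inputs) | "ratio" | "percent"
    t: float
    df: float
    p: float
    tails: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def unpaired_t_test(
    group_a,
    group_b,
    tails: int = 2,
    variance: str = "pooled",
    statistic_kind: str = "percent",
) -> GroupComparison:
    """Unpaired two-sample t-test between group_a (reference) and group_b.

    ``variance='pooled'`` is the classic Student test; ``'welch'`` drops the
    equal-variance assumption.  ``tails=1`` reports the one-sided p for the
    observed direction (half the two-sided p).  Groups in which every value
    is identical (and equal across groups zero-variance) make the statistic
    undefined; both groups having zero variance raises.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values for a t-test")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if variance not in ("pooled", "welch"):
        raise ValueError("variance must be 'pooled' or 'welch'")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            # identical constant groups: no evidence of difference
            t_stat, p_two = 0.0, 1.0
            df = a.size + b.size - 2
            res = None
        else:
            raise ValueError("zero within-group variance in both groups; t undefined")
    else:
        res = stats.ttest_ind(b, a, equal_var=(variance == "pooled"))
        t_stat = float(res.statistic)
        p_two = float(res.pvalue)
        df = float(res.df)
    p = p_two / 2.0 if tails == 1 else p_two
    mean_a, sem_a, n_a = group_summary(a)
    mean_b, sem_b, n_b = group_summary(b)
    if statistic_kind == "fold":
        # Cq-scale inputs (e.g. per-sample dCt): fold = 2^(mean_a - mean_b)
        statistic = fold_from_mean_cq(mean_a, mean_b)
    elif statistic_kind == "ratio":
        if mean_a == 0:
            raise ValueError("reference mean must be nonzero for a ratio")
        statistic = mean_b / mean_a
    elif statistic_kind == "percent":
        statistic = percent_difference(mean_a, mean_b)
    else:
        raise ValueError("statistic_kind must be 'fold', 'ratio', or 'percent'")
    return GroupComparison(
        mean_a=mean_a,
        sem_a=sem_a,
        n_a=n_a,
        mean_b=mean_b,
        sem_b=sem_b,
        n_b=n_b,
        statistic=float(statistic),
        statistic_kind=statistic_kind,
        t=t_stat,
        df=float(df),
        p=float(p),
        tails=tails,
    )
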