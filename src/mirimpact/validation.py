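"""Verification-arm statistics: qPCR relative quantification and group tests.

Implements the comparative cycle-threshold (2^-ddCt) method: per sample,
dCt = Ct(target) - Ct(reference gene); ddCt = dCt - mean dCt of the
reference group; relative quantity RQ = 2^-ddCt.  Reference-group centering
uses the arithmetic mean of dCt, i.e. the geometric mean on the linear
scale, so the geometric mean of reference-group RQ is exactly 1.  Group
summaries are mean +/- SEM; group differences use the pooled two-sample
t-test shared with the array analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = [
    "PcrSampleRecord",
    "GroupComparison",
    "read_ct_table",
    "delta_delta_ct",
    "group_compare",
]


@dataclass(frozen=True)
class PcrSampleRecord:
    sample_id: str
    group: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not np.isfinite(v) or v <= 0:
                raise InputError(f"Ct values must be finite and positive, got {v}")


def read_ct_table(path: str | Path) -> list[PcrSampleRecord]:
    df = pd.read_csv(path)
    required = {"sample_id", "group", "ct_target", "ct_reference"}
    if not required.issubset(df.columns):
        raise InputError(f"Ct table needs columns {sorted(required)}")
    return [
        PcrSampleRecord(str(r.sample_id), str(r.group), float(r.ct_target), float(r.ct_reference))
        for r in df.itertuples()
    ]


def delta_delta_ct(
    records: Sequence[PcrSampleRecord],
    reference_group: str = "control",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample RQ = 2^-ddCt plus a per-group mean +/- SEM summary.

    RQ is invariant to adding a constant to both Ct values of a sample (the
    reference-gene subtraction cancels it), which is what makes the measure
    robust to per-sample input amounts.
    """
    ref = [r for r in records if r.group == reference_group]
    if not ref:
        raise InputError(f"no samples in reference group {reference_group!r}")
    ref_mean_dct = float(np.mean([r.ct_target - r.ct_reference for r in ref]))
    rows = []
    for r in records:
        dct = r.ct_target - r.ct_reference
        ddct = dct - ref_mean_dct
        rows.append(
            {
                "sample_id": r.sample_id,
                "group": r.group,
                "delta_ct": dct,
                "delta_delta_ct": ddct,
                "rq": 2.0 ** (-ddct),
            }
        )
    per_sample = pd.DataFrame(rows)
    summary = (
        per_sample.groupby("group")["rq"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan, n="count")
        .reset_index()
    )
    return per_sample, summary


@dataclass(frozen=True)
class GroupComparison:
    t: float
    p_value: float
    summary: pd.DataFrame  # per group: mean, sem, n


def group_compare(values: Sequence[float], groups: Mapping[str, str] | Sequence[str]) -> GroupComparison:
    """Two-sided pooled-variance t-test of case vs control values.

    ``groups`` is a sequence of group labels aligned with ``values`` (or a
    mapping used positionally by sorted key).  Zero variance in both groups
    with equal means yields t = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    if isinstance(groups, Mapping):
        labels = np.array([groups[k] for k in groups])
    else:
        labels = np.asarray(list(groups))
    if labels.shape[0] != values.shape[0]:
        raise InputError("values and group labels differ in length")
    case = values[labels == "case"]
    control = values[labels == "control"]
    if case.size < 2 or control.size < 2:
        raise InputError("need at least two samples per group")
    if case.var(ddof=1) == 0 and control.var(ddof=1) == 0 and case.mean() == control.mean():
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(case, control, equal_var=True)
        t, p = float(t), float(max(p, np.finfo(float).tiny))
    summary = pd.DataFrame(
        {
            "group": ["case", "control"],
            "mean": [case.mean(), control.mean()],
            "sem": [case.std(ddof=1) / np.sqrt(case.size), control.std(ddof=1) / np.sqrt(control.size)],
            "n": [case.size, control.size],
        }
    )
    return GroupComparison(t=t, p_value=p, summary=summary)
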