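"""Relative expression by the 2^-ddCt (Livak) method.

Each sample's target Ct is normalised to its reference-gene Ct
(dCt = target - reference); dCt is then centred on the control-group
mean (ddCt = dCt - mean control dCt) and exponentiated
(fold = 2^-ddCt), so the control group has geometric-mean fold 1.
Group comparison uses Welch's t on dCt.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CtRecord", "delta_delta_ct"]


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: target and reference Ct for one sample."""

    sample_id: str
    group: str
    target_ct: float
    reference_ct: float


def _to_frame(records: Union[pd.DataFrame, Sequence[CtRecord]]) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    required = {"sample_id", "group", "target_ct", "reference_ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    if not np.isfinite(df[["target_ct", "reference_ct"]].to_numpy()).all():
        raise ValueError("non-finite Ct values")
    return df


def delta_delta_ct(
    records: Union[pd.DataFrame, Sequence[CtRecord]],
    control_group_label: str = "control",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample fold changes and a per-group summary.

    Returns ``(per_sample, summary)``:

    * per_sample: sample_id, group, delta_ct, delta_delta_ct, fold
      (``fold = 2**-ddCt``; ``log2(fold) == -ddCt`` exactly).
    * summary: per group, n, mean_fold, sem_fold, mean ddCt and a
      two-sided Welch t p-value on dCt versus the control group (NaN
      for the control itself or when a group has a single sample).
    """
    df = _to_frame(records)
    if control_group_label not in set(df["group"]):
        raise ValueError(f"control group {control_group_label!r} absent")
    df["delta_ct"] = df["target_ct"] - df["reference_ct"]
    control_mean = df.loc[df["group"] == control_group_label, "delta_ct"].mean()
    df["delta_delta_ct"] = df["delta_ct"] - control_mean
    df["fold"] = 2.0 ** (-df["delta_delta_ct"])

    control_dct = df.loc[df["group"] == control_group_label, "delta_ct"]
    rows = []
    for group, sub in df.groupby("group", sort=True):
        if group == control_group_label or len(sub) < 2 or len(control_dct) < 2:
            pval = np.nan
        else:
            pval = stats.ttest_ind(
                sub["delta_ct"], control_dct, equal_var=False
            ).pvalue
        rows.append(
            {"group": group, "n": len(sub),
             "mean_fold": sub["fold"].mean(),
             "sem_fold": sub["fold"].sem() if len(sub) > 1 else np.nan,
             "mean_delta_delta_ct": sub["delta_delta_ct"].mean(),
             "welch_p_vs_control": pval}
        )
    per_sample = df[["sample_id", "group", "delta_ct",
                     "delta_delta_ct", "fold"]].reset_index(drop=True)
    return per_sample, pd.DataFrame(rows)
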