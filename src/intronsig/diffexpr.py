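"""Filtering and paired differential expression of probe-set intensities.

Operates on normalized log2 intensity matrices with Present/Absent detection
calls (both produced upstream by standard array-processing software and
consumed here as inputs).  Technical replicates are averaged first; probe
sets are then filtered on detection, minimum intensity and interquartile
range; finally a two-sided paired Student t-test with a fold-change cut-off
selects differentially expressed probe sets between two genotype groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionMatrix:
    """Probe sets x samples log2 intensities with calls and sample metadata.

    ``samples`` is indexed by column name and carries ``biosample`` (the
    biological sample a technical replicate belongs to), ``group`` (genotype
    or cell type), ``pair`` (pair id linking matched samples across genotype
    groups; empty string when unpaired) and ``replicate``.
    """

    values: pd.DataFrame
    calls: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape != self.calls.shape:
            raise ValueError("values and calls must share dimensions")
        if not self.values.columns.equals(self.calls.columns):
            raise ValueError("values and calls must share columns")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples metadata missing for columns: {sorted(missing)}")
        if (self.samples.loc[list(self.values.columns), "group"] == "").any():
            raise ValueError("every sample needs a group label")

    def write(self, values_path, calls_path, samples_path) -> None:
        self.values.to_csv(values_path, sep="\t")
        self.calls.to_csv(calls_path, sep="\t")
        self.samples.to_csv(samples_path, sep="\t")

    @classmethod
    def read(cls, values_path, calls_path, samples_path) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        calls = pd.read_csv(calls_path, sep="\t", index_col=0)
        samples = pd.read_csv(
            samples_path, sep="\t", index_col=0, keep_default_na=False, dtype=str
        )
        return cls(values, calls, samples)


@dataclass
class FilterConfig:
    """Cut-offs for probe-set filtering and differential-expression calls."""

    min_log2_intensity: float = math.log2(100)
    min_iqr: float = 0.5
    p_threshold: float = 0.05
    fc_threshold: float = 1.5

    def __post_init__(self) -> None:
        for name in ("min_log2_intensity", "min_iqr", "p_threshold", "fc_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def average_technical_replicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse technical replicates to one column per biological sample.

    Log2 intensities are averaged arithmetically.  The collapsed call is
    Absent only when every replicate is Absent; otherwise Marginal when no
    replicate is Present; otherwise Present.
    """
    meta = matrix.samples.loc[list(matrix.values.columns)]
    for bios, grp in meta.groupby("biosample"):
        if grp[["group", "pair"]].drop_duplicates().shape[0] > 1:
            raise ValueError(
                f"replicates of biosample {bios!r} span multiple biological samples"
            )

    order = meta["biosample"].drop_duplicates().tolist()
    values = matrix.values.T.groupby(meta["biosample"]).mean().T[order]

    def collapse(calls: pd.Series) -> str:
        if (calls == "Absent").all():
            return "Absent"
        if not (calls == "Present").any():
            return "Marginal"
        return "Present"

    calls = (
        matrix.calls.T.groupby(meta["biosample"]).agg(collapse).T[order]
    )
    samples = (
        meta.drop_duplicates("biosample").set_index("biosample")
        [["group", "pair"]]
        .assign(biosample=lambda d: d.index, replicate="")
        .loc[order, ["biosample", "group", "pair", "replicate"]]
    )
    return ExpressionMatrix(values, calls, samples)


def filter_probe_sets(matrix: ExpressionMatrix, config: FilterConfig) -> list[str]:
    """Return probe sets surviving the detection/intensity/variation filters.

    A probe set is excluded when all samples of some group are called Absent,
    when every sample's intensity is below the minimum, or when the
    interquartile range across all samples is below ``min_iqr`` (strict
    comparisons throughout; IQR uses linear-interpolation quantiles).
    """
    if matrix.values.empty:
        raise ValueError("empty expression matrix")
    vals = matrix.values
    calls = matrix.calls
    groups = matrix.samples.loc[list(vals.columns), "group"]

    absent_in_a_group = pd.Series(False, index=vals.index)
    for g, cols in groups.groupby(groups).groups.items():
        absent_in_a_group |= (calls[list(cols)] == "Absent").all(axis=1)

    all_dim = (vals < config.min_log2_intensity).all(axis=1)
    q75, q25 = np.percentile(vals.to_numpy(), [75, 25], axis=1)
    low_iqr = pd.Series(q75 - q25, index=vals.index) < config.min_iqr

    keep = ~(absent_in_a_group | all_dim | low_iqr)
    return vals.index[keep].tolist()


def paired_differential_expression(
    matrix: ExpressionMatrix,
    retained: Sequence[str],
    group_a: str,
    group_b: str,
    config: FilterConfig | None = None,
) -> pd.DataFrame:
    """Paired t-test of ``group_b`` against ``group_a`` on log2 intensities.

    Samples are matched by pair id.  Fold change is ``2**|mean paired log2
    difference|``; direction is the sign of the mean difference of group_b
    relative to group_a.  Records are emitted only when both the p-value and
    fold-change criteria are met.  Probe sets whose paired differences have
    zero variance (p undefined) are emitted on the fold-change criterion
    alone, flagged degenerate.
    """
    config = config or FilterConfig()
    meta = matrix.samples.loc[list(matrix.values.columns)]
    a = meta[meta["group"] == group_a].sort_values("pair")
    b = meta[meta["group"] == group_b].sort_values("pair")
    if list(a["pair"]) != list(b["pair"]):
        raise ValueError(
            f"groups {group_a!r}/{group_b!r} have mismatched pair ids"
        )
    if len(a) < 2:
        raise ValueError("need at least 2 pairs for a paired t-test")

    va = matrix.values.loc[list(retained), list(a.index)].to_numpy()
    vb = matrix.values.loc[list(retained), list(b.index)].to_numpy()
    diff = vb - va  # group_b relative to group_a
    mean_diff = diff.mean(axis=1)
    sd = diff.std(axis=1, ddof=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_rel(vb, va, axis=1)

    fc = 2.0 ** np.abs(mean_diff)
    degenerate = sd == 0
    significant = np.where(degenerate, fc > config.fc_threshold,
                           (p < config.p_threshold) & (fc > config.fc_threshold))

    out = pd.DataFrame(
        {
            "probeset_id": list(retained),
            "direction": np.where(mean_diff > 0, "up", "down"),
            "p_value": p,
            "fold_change": fc,
            f"mean_log2_{group_a}": va.mean(axis=1),
            f"mean_log2_{group_b}": vb.mean(axis=1),
            "degenerate_p": degenerate,
        }
    )
    return out[significant].reset_index(drop=True)
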