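"""Relative quantification of spliced vs unspliced transcript by qRT-PCR.

Ct tables for exonic (total mRNA) and intronic (unspliced pre-mRNA)
amplicons are quantified with the 2^-ddCt method against a reference gene
and a calibrator group.  Per-gene genotype ratios (e.g. WT over mutant) are
summarized across independent experiments by median and median absolute
deviation, then classified against a symmetric 1.5-fold band: genes whose
total mRNA is unchanged but whose unspliced signal drops are the selective
splicing-change pattern of interest.

The protein-prediction model assumes only fully spliced mRNA is translated:
with total transcript T and unspliced transcript U, the translatable pool is
T - c*U (c calibrates intronic onto total-signal units), so the expected
protein ratio between two conditions follows the spliced-estimate ratio
rather than the naive full-length ratio F.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

AMPLICON_TYPES = ("exonic", "intronic", "exon_intron", "intron_spanning")
SPLICING_CLASSES = ("no_change", "selective_intronic", "proportional", "mRNA_only")

QRT_COLUMNS = ["gene", "amplicon_type", "sample", "group", "experiment", "ct"]


@dataclass
class ProteinPrediction:
    full_length_ratio: float       # F: total mRNA ratio A/B
    full_over_unspliced_ratio: float  # F/U ratio
    spliced_estimate_ratio: float  # (T - c*U) ratio, the protein predictor
    observed_protein_ratio: float | None = None


def load_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(QRT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def ddct_quantify(
    records: pd.DataFrame, reference_gene: str, calibrator_group: str
) -> pd.DataFrame:
    """2^-ddCt relative quantity per (gene, amplicon_type, sample).

    dCt = Ct_target - Ct_reference within the same sample and experiment;
    ddCt subtracts the mean dCt of the calibrator group for that gene,
    amplicon type and experiment; quantity = 2^-ddCt (ideal doubling per
    cycle assumed).  The reference gene's exonic amplicon must be measured
    in every sample.
    """
    df = records.copy()
    if not np.isfinite(df["ct"]).all():
        raise ValueError("non-finite Ct values")
    ref = df[df["gene"] == reference_gene]
    if ref.empty:
        raise ValueError(f"no records for reference gene {reference_gene!r}")
    ref_ct = ref.set_index(["experiment", "sample"])["ct"]
    if ref_ct.index.has_duplicates:
        ref_ct = ref_ct.groupby(level=[0, 1]).mean()

    targets = df[df["gene"] != reference_gene].copy()
    key = pd.MultiIndex.from_frame(targets[["experiment", "sample"]])
    missing = set(key) - set(ref_ct.index)
    if missing:
        raise KeyError(
            f"reference gene {reference_gene!r} not measured for: {sorted(missing)}"
        )
    targets["dct"] = targets["ct"].to_numpy() - ref_ct.loc[key].to_numpy()

    calib = targets[targets["group"] == calibrator_group]
    if calib.empty:
        raise ValueError(f"no records in calibrator group {calibrator_group!r}")
    calib_mean = calib.groupby(["gene", "amplicon_type", "experiment"])["dct"].mean()
    ckey = pd.MultiIndex.from_frame(targets[["gene", "amplicon_type", "experiment"]])
    targets["ddct"] = targets["dct"].to_numpy() - calib_mean.loc[ckey].to_numpy()
    targets["quantity"] = 2.0 ** (-targets["ddct"])
    return targets.reset_index(drop=True)


def genotype_ratio_summary(
    quantities: pd.DataFrame, group_a: str, group_b: str
) -> pd.DataFrame:
    """Per-gene group_a/group_b ratios of exonic and intronic quantities.

    The per-experiment ratio divides mean quantities of the two groups; the
    gene summary is the median across experiments with the median absolute
    deviation as dispersion, separately for each amplicon type.
    """
    rows = []
    for (gene, amp), grp in quantities.groupby(["gene", "amplicon_type"]):
        ratios = []
        for _, exp_grp in grp.groupby("experiment"):
            qa = exp_grp.loc[exp_grp["group"] == group_a, "quantity"]
            qb = exp_grp.loc[exp_grp["group"] == group_b, "quantity"]
            if qa.empty or qb.empty:
                continue
            if (qa <= 0).any() or (qb <= 0).any():
                raise ValueError(f"nonpositive quantity for gene {gene!r}")
            ratios.append(qa.mean() / qb.mean())
        if not ratios:
            continue
        r = np.asarray(ratios)
        med = float(np.median(r))
        mad = float(np.median(np.abs(r - med)))
        rows.append(
            {"gene": gene, "amplicon_type": amp, "ratio": med, "mad": mad,
             "n_experiments": len(r)}
        )
    long = pd.DataFrame(rows)
    wide = long.pivot(index="gene", columns="amplicon_type", values=["ratio", "mad"])
    out = pd.DataFrame(index=wide.index)
    for amp, name in (("exonic", "mRNA"), ("intronic", "intronic")):
        if ("ratio", amp) in wide.columns:
            out[f"{name}_ratio"] = wide[("ratio", amp)]
            out[f"{name}_mad"] = wide[("mad", amp)]
    return out.reset_index()


def classify_splicing_change(
    mrna_ratio: float, intronic_ratio: float, cutoff: float = 1.5
) -> str:
    """Place a gene in the fold-change plane split by the symmetric cut-off.

    A ratio is "within" the band when 1/cutoff <= ratio <= cutoff.  mRNA
    within and intronic outside is the selective pattern: little change in
    total message but a shifted unspliced fraction.
    """
    if mrna_ratio <= 0 or intronic_ratio <= 0:
        raise ValueError("ratios must be positive")
    within = lambda r: (1.0 / cutoff) <= r <= cutoff
    m, i = within(mrna_ratio), within(intronic_ratio)
    if m and i:
        return "no_change"
    if m and not i:
        return "selective_intronic"
    if not m and not i:
        return "proportional"
    return "mRNA_only"


def classify_ratio_table(summary: pd.DataFrame, cutoff: float = 1.5) -> pd.DataFrame:
    out = summary.copy()
    out["splicing_class"] = [
        classify_splicing_change(r.mRNA_ratio, r.intronic_ratio, cutoff)
        if np.isfinite(r.mRNA_ratio) and np.isfinite(r.intronic_ratio)
        else "unclassified"
        for r in out.itertuples()
    ]
    return out


def predicted_protein_ratio(
    total_a: float,
    unspliced_a: float,
    total_b: float,
    unspliced_b: float,
    c: float = 1.0,
    observed_protein_ratio: float | None = None,
) -> ProteinPrediction:
    """Predict the protein ratio of condition A over B from transcript pools.

    F is the naive full-length (total mRNA) ratio; F/U the full-length over
    unspliced ratio; the spliced estimate (T - c*U ratio) is the model's
    protein predictor, since only the spliced pool is translated.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    if unspliced_a < 0 or unspliced_b < 0:
        raise ValueError("unspliced quantities must be >= 0")
    spliced_a = total_a - c * unspliced_a
    spliced_b = total_b - c * unspliced_b
    if spliced_a <= 0 or spliced_b <= 0:
        raise ValueError(
            "unspliced exceeds total under calibration "
            f"(c={c}: spliced pools {spliced_a:.4g}, {spliced_b:.4g}); "
            "lower c or check units"
        )
    f = total_a / total_b
    if unspliced_a == 0 or unspliced_b == 0:
        fu = float("nan")  # F/U undefined without unspliced signal
    else:
        fu = (total_a / unspliced_a) / (total_b / unspliced_b)
    return ProteinPrediction(
        full_length_ratio=f,
        full_over_unspliced_ratio=fu,
        spliced_estimate_ratio=spliced_a / spliced_b,
        observed_protein_ratio=observed_protein_ratio,
    )


def write_ratios(
    summary: pd.DataFrame,
    classified: pd.DataFrame,
    ratio_path,
    class_path,
    prediction: ProteinPrediction | None = None,
    json_path=None,
) -> None:
    summary.to_csv(ratio_path, sep="\t", index=False)
    classified.to_csv(class_path, sep="\t", index=False)
    if json_path is not None and prediction is not None:
        with open(json_path, "w") as fh:
            json.dump(prediction.__dict__, fh, indent=2)
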