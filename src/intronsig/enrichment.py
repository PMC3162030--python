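"""Category tallies and intronic-enrichment statistics.

Differentially expressed probe sets are tabulated by annotation category
(mRNA, intronic, repeat, ambiguous) and direction (up/down in the mutant
relative to matched wild-type).  The intronic count is then compared with
the array-wide background fraction of intronic probe sets using a 2x2
Pearson chi-square test with Yates continuity correction, and an expected
intronic count per direction is derived from the background fraction for
display next to the observed counts.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

DIRECTIONS = ("up", "down")
TALLY_CATEGORIES = ("mRNA", "intronic", "repeat", "ambiguous")


@dataclass
class CategoryTally:
    counts: pd.DataFrame  # categories x directions
    total_de: int
    expected_intronic_per_direction: int
    background_intronic: int
    background_total: int

    @property
    def background_fraction(self) -> float:
        return self.background_intronic / self.background_total


@dataclass
class EnrichmentResult:
    chi2: float
    p_value: float
    observed_fraction: float
    background_fraction: float
    continuity_correction: bool
    low_expected_warning: bool = False


def tally_categories(
    de_records: pd.DataFrame,
    annotation: Mapping[str, str] | pd.DataFrame,
    background_intronic: int,
    background_total: int,
    background_fraction: float | None = None,
    strict: bool = False,
) -> CategoryTally:
    """Cross-tabulate DE probe sets by category and direction.

    ``annotation`` maps probeset_id -> category (a DataFrame with those two
    columns is also accepted).  DE probe sets without an annotation are
    counted as ambiguous with a warning, or raise in strict mode.
    """
    if isinstance(annotation, pd.DataFrame):
        annotation = dict(zip(annotation["probeset_id"], annotation["category"]))

    counts = pd.DataFrame(0, index=list(TALLY_CATEGORIES), columns=list(DIRECTIONS))
    for _, rec in de_records.iterrows():
        cat = annotation.get(rec["probeset_id"])
        if cat is None:
            if strict:
                raise KeyError(f"no annotation for DE probe set {rec['probeset_id']!r}")
            warnings.warn(
                f"probe set {rec['probeset_id']!r} lacks annotation; counted ambiguous"
            )
            cat = "ambiguous"
        if cat not in TALLY_CATEGORIES:  # unmapped etc. absorbed into ambiguous
            cat = "ambiguous"
        counts.loc[cat, rec["direction"]] += 1

    total = int(counts.to_numpy().sum())
    if background_fraction is None:
        background_fraction = background_intronic / background_total
    expected = expected_intronic_count(total, background_fraction)
    return CategoryTally(counts, total, expected, background_intronic, background_total)


def expected_intronic_count(total_de: int, background_fraction: float = 0.15) -> int:
    """Expected intronic probe sets per direction under the background rate.

    The background fraction of the whole array is applied to the DE total and
    split evenly between the up and down directions; the result is rounded
    half away from zero.
    """
    if total_de < 0:
        raise ValueError("total_de must be >= 0")
    if not 0.0 <= background_fraction <= 1.0:
        raise ValueError("background_fraction must lie in [0, 1]")
    x = background_fraction * total_de / 2.0
    return int(math.floor(x + 0.5))


def intronic_enrichment_test(
    observed_intronic: int,
    n_tested: int,
    background_intronic: int,
    background_total: int,
    continuity: bool = True,
) -> EnrichmentResult:
    """2x2 chi-square test of the intronic rate among DE probe sets vs array.

    The table contrasts the tested probe sets with the rest of the array:
    ``[[obs, n-obs], [bg_intronic-obs, (bg_total-bg_intronic)-(n-obs)]]``,
    one degree of freedom, two-sided p, Yates correction by default.
    """
    if not 0 <= observed_intronic <= n_tested:
        raise ValueError("need 0 <= observed_intronic <= n_tested")
    if background_intronic <= 0 or background_total <= background_intronic:
        raise ValueError("background counts must be positive with total > intronic")

    table = [
        [observed_intronic, n_tested - observed_intronic],
        [
            background_intronic - observed_intronic,
            (background_total - background_intronic) - (n_tested - observed_intronic),
        ],
    ]
    res = stats.chi2_contingency(table, correction=continuity)
    low_expected = bool((res.expected_freq < 1).any())
    if low_expected:
        warnings.warn("chi-square expected cell count below 1; p-value unreliable")
    return EnrichmentResult(
        chi2=float(res.statistic),
        p_value=float(res.pvalue),
        observed_fraction=observed_intronic / n_tested if n_tested else 0.0,
        background_fraction=background_intronic / background_total,
        continuity_correction=continuity,
        low_expected_warning=low_expected,
    )


def tally_table(tally: CategoryTally) -> pd.DataFrame:
    """Publication-style table with the expected intronic count parenthesized."""
    df = tally.counts.astype(object).copy()
    for d in DIRECTIONS:
        df.loc["intronic", d] = (
            f"{tally.counts.loc['intronic', d]} ({tally.expected_intronic_per_direction})"
        )
    df.loc["total"] = [int(tally.counts[d].sum()) for d in DIRECTIONS]
    return df


def write_enrichment(
    tally: CategoryTally, result: EnrichmentResult, tsv_path, json_path
) -> None:
    tally_table(tally).to_csv(tsv_path, sep="\t")
    payload = {
        "total_de": tally.total_de,
        "expected_intronic_per_direction": tally.expected_intronic_per_direction,
        "background": {
            "intronic": tally.background_intronic,
            "total": tally.background_total,
            "fraction": tally.background_fraction,
        },
        "chi2": result.chi2,
        "p_value": result.p_value,
        "observed_fraction": result.observed_fraction,
        "continuity_correction": result.continuity_correction,
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)
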