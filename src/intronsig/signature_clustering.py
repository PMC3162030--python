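"""Signature-based hierarchical clustering with a randomization null.

A probe-set signature (e.g. the intronic probe sets down-regulated in a
mutant) is used to cluster samples by 1 - Pearson correlation.  The question
asked of each dendrogram is whether a designated sample population (e.g. the
HSCs of a published hematopoietic data set) separates cleanly, i.e. forms a
clade — equivalently, whether some cut of the tree yields exactly that sample
set as one cluster.  Specificity is calibrated by redrawing random probe-set
signatures of the same size from an eligible pool and recording how often a
random signature achieves the same clean separation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class SignatureSelection:
    mode: str
    chosen: dict[str, str]  # gene/transcript id -> probeset_id

    @property
    def probesets(self) -> list[str]:
        return list(self.chosen.values())


@dataclass
class Dendrogram:
    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:.6g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return fmt(tree, tree.dist).rsplit(":", 1)[0] + ";"


@dataclass
class RandomizationResult:
    n_draws: int
    n_clean: int
    seed: int
    pool_size: int

    @property
    def fraction_clean(self) -> float:
        return self.n_clean / self.n_draws


def select_signature(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    mode: str,
    reference_contrast: tuple[Sequence[str], Sequence[str]] | None = None,
    category: str | None = None,
) -> SignatureSelection:
    """Pick one probe set per gene for clustering.

    ``intronic_top_expressed``: per gene, the intronic probe set with the
    highest mean expression (avoids over-weighting genes detected by several
    intronic probe sets).  ``mrna_most_different``: per gene, the mRNA probe
    set with the largest absolute mean difference between the two column
    groups of ``reference_contrast``.
    """
    if mode not in ("intronic_top_expressed", "mrna_most_different"):
        raise ValueError(f"unknown mode {mode!r}")
    if category is None:
        category = "intronic" if mode == "intronic_top_expressed" else "mRNA"
    ann = annotation[annotation["category"] == category]
    ann = ann[ann["probeset_id"].isin(matrix.index)]

    if mode == "mrna_most_different":
        if reference_contrast is None:
            raise ValueError("mrna_most_different requires a reference contrast")
        cols_a, cols_b = (list(c) for c in reference_contrast)
        score = (
            matrix[cols_a].mean(axis=1) - matrix[cols_b].mean(axis=1)
        ).abs()
    else:
        score = matrix.mean(axis=1)

    chosen: dict[str, str] = {}
    for gene, grp in ann.groupby("gene_id", sort=True):
        ids = grp["probeset_id"].tolist()
        if not ids:
            continue
        chosen[gene] = max(ids, key=lambda p: (score[p], p))
    omitted = set(ann["gene_id"].dropna()) - set(chosen)
    if omitted:
        warnings.warn(f"genes without an eligible probe set omitted: {sorted(omitted)}")
    return SignatureSelection(mode, chosen)


def row_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-scores (mean 0, sd 1); constant rows map to zeros."""
    if matrix.shape[1] < 2:
        raise ValueError("row normalization needs >=2 samples")
    mu = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant rows mapped to zeros")
    sd = sd.mask(const, 1.0)
    out = matrix.sub(mu, axis=0).div(sd, axis=0)
    out[const] = 0.0
    return out


def correlation_dendrogram(
    matrix: pd.DataFrame, linkage: str = "complete", normalize_rows: bool = False
) -> Dendrogram:
    """Agglomerative clustering of samples at distance 1 - Pearson r.

    Distances are computed over the signature rows between sample columns on
    the values as given: per-gene magnitudes are part of the signal sample
    correlations should see (row z-scores are used only for heat-map export;
    z-scoring first flattens two-level rows into near-identical patterns and
    destroys the separation the statistic is meant to detect).  The result is
    deterministic given the column order (scipy's linkage resolves
    equal-distance merges by its fixed internal order).
    """
    if matrix.shape[1] < 3:
        raise ValueError("need >=3 samples to cluster")
    data = row_normalize(matrix) if normalize_rows else matrix
    sds = data.std(axis=0, ddof=0)
    zero_var = sds[sds == 0]
    if len(zero_var):
        raise ValueError(f"zero-variance sample(s): {list(zero_var.index)}")
    corr = np.corrcoef(data.to_numpy().T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    return Dendrogram(Z, list(matrix.columns))


def clean_separation(dendrogram: Dendrogram, target_labels: Sequence[str]) -> bool:
    """True iff the target samples form a clade of the dendrogram.

    Equivalent to: some horizontal cut of the tree yields exactly the target
    set as one cluster.  Invariant under rotation of the leaf order.
    """
    labels = dendrogram.labels
    targets = set(target_labels)
    unknown = targets - set(labels)
    if unknown:
        raise ValueError(f"target labels not in dendrogram: {sorted(unknown)}")
    if not targets or targets == set(labels):
        raise ValueError("targets must be a non-empty proper subset of the leaves")

    target_ids = {i for i, lab in enumerate(labels) if lab in targets}
    if len(target_ids) == 1:
        return True  # a single leaf is trivially a clade

    n = len(labels)
    leafsets: list[set[int]] = [{i} for i in range(n)]
    for merge_idx, (a, b, _, _) in enumerate(dendrogram.linkage):
        merged = leafsets[int(a)] | leafsets[int(b)]
        if merged == target_ids:
            return True
        leafsets.append(merged)
    return False


def randomization_null(
    matrix: pd.DataFrame,
    eligible_pool: Sequence[str],
    k: int,
    n_draws: int,
    target_labels: Sequence[str],
    seed: int,
    linkage: str = "complete",
) -> RandomizationResult:
    """Fraction of random size-k signatures that cleanly separate the targets.

    Draws are without replacement from ``eligible_pool`` (e.g. all probe sets
    annotated intronic and expressed); each draw is clustered exactly like
    the real signature.
    """
    pool = list(eligible_pool)
    if len(pool) < k:
        raise ValueError(f"pool of {len(pool)} smaller than signature size {k}")
    rng = np.random.default_rng(seed)
    n_clean = 0
    for _ in range(n_draws):
        draw = rng.choice(len(pool), size=k, replace=False)
        sub = matrix.loc[[pool[i] for i in draw]]
        dend = correlation_dendrogram(sub, linkage=linkage)
        if clean_separation(dend, target_labels):
            n_clean += 1
    return RandomizationResult(n_draws, n_clean, seed, len(pool))


def write_clustering(
    dendrogram: Dendrogram,
    matrix: pd.DataFrame,
    newick_path,
    matrix_path,
    result: RandomizationResult | None = None,
    json_path=None,
    separation: bool | None = None,
) -> None:
    with open(newick_path, "w") as fh:
        fh.write(dendrogram.to_newick() + "\n")
    order = hierarchy.leaves_list(dendrogram.linkage)
    matrix[[dendrogram.labels[i] for i in order]].to_csv(matrix_path, sep="\t")
    if json_path is not None:
        payload = {"clean_separation": separation}
        if result is not None:
            payload.update(
                n_draws=result.n_draws,
                n_clean=result.n_clean,
                fraction_clean=result.fraction_clean,
                seed=result.seed,
                pool_size=result.pool_size,
            )
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)
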