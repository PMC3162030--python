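"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's index/cascade/linkage code paths:
probe matching is a naive sliding-window scan, clustering is a direct
O(n^3) agglomeration, and clade detection enumerates tree cuts.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def scan_occurrences(seq: str, probe: str) -> list[tuple[int, str]]:
    """All perfect occurrences of probe (either strand) by sliding window."""
    hits = []
    rprobe = rc(probe)
    k = len(probe)
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if window == probe:
            hits.append((i, "+"))
        if window == rprobe:
            hits.append((i, "-"))
    return hits


def find_occurrences(seq: str, probe: str) -> list[tuple[int, str]]:
    """Like scan_occurrences but via str.find (fast path for big fixtures)."""
    hits = []
    for pat, strand in ((probe, "+"), (rc(probe), "-")):
        i = seq.find(pat)
        while i != -1:
            hits.append((i, strand))
            i = seq.find(pat, i + 1)
    return sorted(hits)


def brute_force_classify(probeset, models, genome, min_probes=8, repeat_threshold=10):
    """Literal re-implementation of the annotation rules by exhaustive scan."""
    k = len(probeset.probes[0])

    # stage 1: spliced reference transcripts, sense strand only
    for m in models:
        if not m.refseq:
            continue
        tx = m.spliced_sequence(genome)
        n = sum(
            1 for p in probeset.probes
            if any(s == "+" for _, s in find_occurrences(tx, p))
        )
        if n >= min_probes:
            return "mRNA"

    # genomic occurrences per probe
    occ = {
        i: [
            (chrom, pos, strand)
            for chrom, seq in genome.items()
            for pos, strand in find_occurrences(seq, p)
        ]
        for i, p in enumerate(probeset.probes)
    }
    if any(len(v) > repeat_threshold for v in occ.values()):
        return "repeat"

    gene_hits = {}
    for m in models:
        lo, hi = m.span
        hits = [
            (i, pos, strand)
            for i, v in occ.items()
            for chrom, pos, strand in v
            if chrom == m.chrom and lo <= pos and pos + k <= hi
        ]
        if len({i for i, _, _ in hits}) >= min_probes:
            gene_hits[m.gene_id] = (m, hits)
    if not gene_hits:
        return "unmapped"
    if len(gene_hits) > 1:
        return "ambiguous"

    (m, hits), = gene_hits.values()
    introns = m.introns
    for _, pos, strand in hits:
        if strand != m.strand:
            return "ambiguous"
        if not any(s <= pos and pos + k <= e for s, e in introns):
            return "ambiguous"
    return "intronic"


def naive_complete_linkage(dist: np.ndarray) -> list[tuple[frozenset, frozenset]]:
    """O(n^3) agglomeration; returns the merge sequence as leaf-set pairs."""
    clusters = [frozenset([i]) for i in range(len(dist))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(dist[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        _, i, j = best
        merges.append((clusters[i], clusters[j]))
        merged = clusters[i] | clusters[j]
        clusters = [c for q, c in enumerate(clusters) if q not in (i, j)] + [merged]
    return merges


def clade_by_cut_enumeration(linkage_matrix, labels, targets) -> bool:
    """Does some flat cut of the tree yield exactly the target set?"""
    from scipy.cluster import hierarchy

    target = {labels.index(t) for t in targets}
    n = len(labels)
    for k in range(1, n + 1):
        assign = hierarchy.fcluster(linkage_matrix, t=k, criterion="maxclust")
        groups = {}
        for leaf, c in enumerate(assign):
            groups.setdefault(c, set()).add(leaf)
        if target in groups.values():
            return True
    return False
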