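"""Re-annotation of microarray probe sets by exact 25-mer matching.

Affymetrix-style expression arrays interrogate each transcript with a probe
set of (typically) eleven 25-nt oligonucleotides.  The vendor annotation maps
probe sets to mRNAs, but a sizeable minority of probe sets in fact lie on the
coding strand entirely within introns of their host gene, so they report
unspliced pre-mRNA rather than mature message.  This module re-derives the
category of every probe set from sequence alone, in two stages:

1. match probes against spliced reference (RefSeq-like) mRNA sequences;
2. probe sets that fail stage 1 are matched against the genomic span of each
   gene (all bases from the 5'-most transcription start to the 3'-most end).

A probe "matches" a target only on 25/25 identity; a probe set matches a
target when at least ``min_probes`` (default 8) of its 11 probes match.  The
final category is one of ``mRNA``, ``intronic``, ``repeat``, ``ambiguous`` or
``unmapped``:

* ``mRNA``      — stage 1 match to a reference transcript;
* ``repeat``    — any probe occurs at more than ``repeat_threshold`` genomic
                  loci (checked before intronic/ambiguous);
* ``intronic``  — stage 2 match to exactly one gene span with every matching
                  probe on the coding (sense) strand and entirely inside
                  intron intervals;
* ``ambiguous`` — stage 2 match that touches exons/junctions, is antisense
                  only, or hits more than one gene span;
* ``unmapped``  — nothing above fires.
"""

from __future__ import annotations

import json
import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
from Bio import SeqIO

PROBE_LEN = 25
PROBES_PER_SET = 11

CATEGORIES = ("mRNA", "intronic", "repeat", "ambiguous", "unmapped")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptModel:
    """A transcript: ordered exon intervals on a chromosome strand.

    Coordinates are 0-based half-open.  Introns are the gaps between
    consecutive exons; the gene span runs from the first exon start to the
    last exon end.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    refseq: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if not (s0 < e0 <= s1 < e1):
                raise ValueError(
                    f"{self.transcript_id}: exons must be sorted and non-overlapping"
                )
        if self.exons[0][0] < 0:
            raise ValueError(f"{self.transcript_id}: negative coordinate")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]) if e0 < s1
        )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        chrom = genome[self.chrom]
        seq = "".join(chrom[s:e] for s, e in self.exons)
        return reverse_complement(seq) if self.strand == "-" else seq

    def span_sequence(self, genome: Mapping[str, str]) -> str:
        s, e = self.span
        return genome[self.chrom][s:e]


@dataclass(frozen=True)
class ProbeSet:
    """A probe set: identifier plus its 25-mer probe sequences."""

    probeset_id: str
    probes: tuple[str, ...]

    def __post_init__(self) -> None:
        for p in self.probes:
            if len(p) != PROBE_LEN:
                raise ValueError(
                    f"{self.probeset_id}: probe length {len(p)} != {PROBE_LEN}"
                )
        object.__setattr__(self, "probes", tuple(p.upper() for p in self.probes))


class ProbeMatch(NamedTuple):
    probe_index: int
    target: str
    offset: int
    strand: str  # match strand relative to the indexed target sequence


@dataclass
class AnnotationRecord:
    probeset_id: str
    category: str
    gene_id: str | None
    n_matched: int
    notes: str = ""


# ---------------------------------------------------------------------------
# Exact-match index
# ---------------------------------------------------------------------------

class KmerIndex:
    """Hash index of every k-mer occurrence in a set of sequences.

    Replaces alignment for the perfect-match criterion: querying a k-mer
    returns every occurrence on either strand of every indexed sequence.
    Sequences shorter than k contribute nothing.  Letters outside A/C/G/T are
    indexed verbatim but can never equal an A/C/G/T query.
    """

    def __init__(self, sequences: Mapping[str, str], k: int = PROBE_LEN):
        self.k = k
        idx: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in sequences.items():
            s = seq.upper()
            for i in range(len(s) - k + 1):
                idx[s[i : i + k]].append((name, i))
        self._idx = dict(idx)

    def query(self, kmer: str, probe_index: int = 0) -> list[ProbeMatch]:
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != k={self.k}")
        q = kmer.upper()
        hits = [
            ProbeMatch(probe_index, t, off, "+") for t, off in self._idx.get(q, ())
        ]
        hits += [
            ProbeMatch(probe_index, t, off, "-")
            for t, off in self._idx.get(reverse_complement(q), ())
        ]
        return hits


def build_match_index(sequences: Mapping[str, str], k: int = PROBE_LEN) -> KmerIndex:
    return KmerIndex(sequences, k=k)


def match_probe_set(
    probeset: ProbeSet, index: KmerIndex
) -> tuple[dict[str, int], list[ProbeMatch]]:
    """Count, per target, how many *distinct* probes match perfectly.

    A probe occurring several times in one target still counts once toward
    that target's probe count.
    """
    matches: list[ProbeMatch] = []
    per_target: dict[str, set[int]] = defaultdict(set)
    for i, probe in enumerate(probeset.probes):
        for hit in index.query(probe, probe_index=i):
            matches.append(hit)
            per_target[hit.target].add(i)
    counts = {t: len(s) for t, s in per_target.items()}
    return counts, matches


def call_probeset_target(
    counts: Mapping[str, int], min_probes: int = 8
) -> set[str]:
    """Targets hit by at least ``min_probes`` distinct probes."""
    return {t for t, n in counts.items() if n >= min_probes}


# ---------------------------------------------------------------------------
# Classification cascade
# ---------------------------------------------------------------------------

def _interval_contains(iv: tuple[int, int], start: int, end: int) -> bool:
    return iv[0] <= start and end <= iv[1]


def _gene_exons(models: Sequence[TranscriptModel]) -> list[tuple[int, int]]:
    ivs = sorted({iv for m in models for iv in m.exons})
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def classify_probe_set(
    probeset: ProbeSet,
    mrna_counts: Mapping[str, int],
    genome_matches: Sequence[ProbeMatch],
    models: Sequence[TranscriptModel],
    min_probes: int = 8,
    repeat_threshold: int = 10,
) -> AnnotationRecord:
    """Assign one category via the two-stage decision cascade.

    ``mrna_counts`` are distinct-probe counts against spliced reference
    transcripts (sense-strand matches only).  ``genome_matches`` are all
    perfect genomic occurrences of the probes (both strands).  ``models``
    supplies gene spans, strands and intron intervals.
    """
    by_transcript = {}
    by_gene: dict[str, list[TranscriptModel]] = defaultdict(list)
    for m in models:
        by_transcript[m.transcript_id] = m
        by_gene[m.gene_id].append(m)

    # Stage 1: reference mRNA.
    mrna_hits = call_probeset_target(mrna_counts, min_probes)
    ref_hits = set()
    for t in mrna_hits:
        if t not in by_transcript:
            raise KeyError(f"matched transcript {t!r} has no model")
        if by_transcript[t].refseq:
            ref_hits.add(t)
    if ref_hits:
        best = max(ref_hits, key=lambda t: (mrna_counts[t], t))
        genes = sorted({by_transcript[t].gene_id for t in ref_hits})
        note = "" if len(genes) == 1 else f"multiple genes matched: {','.join(genes)}"
        return AnnotationRecord(
            probeset.probeset_id, "mRNA", by_transcript[best].gene_id,
            mrna_counts[best], note,
        )

    # Repeat check: any probe at more genomic loci than the threshold.
    per_probe_loci: dict[int, int] = defaultdict(int)
    for hit in genome_matches:
        per_probe_loci[hit.probe_index] += 1
    worst = max(per_probe_loci.values(), default=0)
    if worst > repeat_threshold:
        return AnnotationRecord(
            probeset.probeset_id, "repeat", None, len(per_probe_loci),
            f"max genomic occurrences {worst} > {repeat_threshold}",
        )

    # Stage 2: gene spans. A genomic hit belongs to a gene when the 25-mer
    # interval lies fully inside the gene's span on its chromosome.
    k = PROBE_LEN
    span_probes: dict[str, set[int]] = defaultdict(set)
    span_hits: dict[str, list[ProbeMatch]] = defaultdict(list)
    for hit in genome_matches:
        for gene_id, gms in by_gene.items():
            gm = gms[0]
            if gm.chrom != hit.target:
                continue
            lo = min(m.span[0] for m in gms)
            hi = max(m.span[1] for m in gms)
            if lo <= hit.offset and hit.offset + k <= hi:
                span_probes[gene_id].add(hit.probe_index)
                span_hits[gene_id].append(hit)

    matched_genes = sorted(
        g for g, probes in span_probes.items() if len(probes) >= min_probes
    )
    if not matched_genes:
        n = len({h.probe_index for h in genome_matches})
        return AnnotationRecord(probeset.probeset_id, "unmapped", None, n)
    if len(matched_genes) > 1:
        return AnnotationRecord(
            probeset.probeset_id, "ambiguous", None,
            max(len(span_probes[g]) for g in matched_genes),
            f"matches {len(matched_genes)} gene spans: {','.join(matched_genes)}",
        )

    gene_id = matched_genes[0]
    gms = by_gene[gene_id]
    strand = gms[0].strand
    exons = _gene_exons(gms)
    introns = [
        (e0, s1) for (_, e0), (s1, _) in zip(exons, exons[1:]) if e0 < s1
    ]

    all_sense_intronic = True
    note = ""
    for hit in span_hits[gene_id]:
        sense = hit.strand == strand
        inside_intron = any(
            _interval_contains(iv, hit.offset, hit.offset + k) for iv in introns
        )
        if not sense:
            all_sense_intronic = False
            note = "antisense or mixed-strand genomic matches"
        elif not inside_intron:
            all_sense_intronic = False
            note = "probe overlaps an exon or exon/intron junction"
    category = "intronic" if all_sense_intronic else "ambiguous"
    return AnnotationRecord(
        probeset.probeset_id, category, gene_id, len(span_probes[gene_id]), note
    )


def annotate_array(
    probesets: Sequence[ProbeSet],
    refseq_sequences: Mapping[str, str],
    genome: Mapping[str, str],
    models: Sequence[TranscriptModel],
    exclude: Iterable[str] = (),
    min_probes: int = 8,
    repeat_threshold: int = 10,
) -> tuple[pd.DataFrame, float]:
    """Annotate every probe set; return the table and the background fraction.

    The background fraction is the share of probe sets annotated intronic
    among all probe sets not in ``exclude`` (the exclusion list plays the role
    of the array's control probe sets).
    """
    ids = [ps.probeset_id for ps in probesets]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate probeset ids: {dupes}")

    mrna_index = build_match_index(refseq_sequences)
    genome_index = build_match_index(genome)

    records = []
    for ps in probesets:
        mrna_counts_all, mrna_matches = match_probe_set(ps, mrna_index)
        # Only sense-strand transcript matches indicate the probe set reads
        # that mRNA; antisense transcript hits fall through to the genomic
        # stage where strand is assessed against the gene model.
        sense: dict[str, set[int]] = defaultdict(set)
        for hit in mrna_matches:
            if hit.strand == "+":
                sense[hit.target].add(hit.probe_index)
        mrna_counts = {t: len(s) for t, s in sense.items()}
        _, genome_matches = match_probe_set(ps, genome_index)
        records.append(
            classify_probe_set(
                ps, mrna_counts, genome_matches, models,
                min_probes=min_probes, repeat_threshold=repeat_threshold,
            )
        )

    table = pd.DataFrame(
        {
            "probeset_id": [r.probeset_id for r in records],
            "category": [r.category for r in records],
            "gene_id": [r.gene_id for r in records],
            "n_matched": [r.n_matched for r in records],
            "notes": [r.notes for r in records],
        }
    )
    excluded = set(exclude)
    retained = table[~table["probeset_id"].isin(excluded)]
    if len(retained) == 0:
        raise ValueError("exclusion list removes every probe set")
    background = float((retained["category"] == "intronic").mean())
    return table, background


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def load_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def load_probes_tsv(path) -> list[ProbeSet]:
    """Probe TSV with columns probeset_id, probe_index, sequence."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for pid, grp in df.groupby("probeset_id", sort=False):
        grp = grp.sort_values("probe_index", key=lambda s: s.astype(int))
        out.append(ProbeSet(pid, tuple(grp["sequence"])))
    return out


def load_probes_fasta(path) -> list[ProbeSet]:
    """Probe FASTA with headers ``<probesetID>_<probeindex>``."""
    groups: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for rec in SeqIO.parse(str(path), "fasta"):
        pid, idx = rec.id.rsplit("_", 1)
        groups[pid].append((int(idx), str(rec.seq)))
    return [
        ProbeSet(pid, tuple(seq for _, seq in sorted(pairs)))
        for pid, pairs in groups.items()
    ]


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def load_models_gtf(path) -> list[TranscriptModel]:
    """Read transcript models from a GTF of exon features."""
    exons: dict[tuple[str, str, str, str], list[tuple[int, int]]] = defaultdict(list)
    flags: dict[str, bool] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "exon":
                continue
            attrs = dict(_GTF_ATTR.findall(f[8]))
            key = (attrs["gene_id"], attrs["transcript_id"], f[0], f[6])
            exons[key].append((int(f[3]) - 1, int(f[4])))  # GTF is 1-based closed
            flags[attrs["transcript_id"]] = attrs.get("refseq", "1") not in ("0", "false")
    return [
        TranscriptModel(g, t, c, s, tuple(sorted(ivs)), refseq=flags[t])
        for (g, t, c, s), ivs in exons.items()
    ]


def load_models_bed12(path) -> list[TranscriptModel]:
    """Read transcript models from BED12 (name = gene_id|transcript_id)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (start + s, start + s + sz) for s, sz in zip(starts, sizes)
            )
            gene_id, _, transcript_id = name.partition("|")
            out.append(
                TranscriptModel(gene_id, transcript_id or name, chrom, strand, exons)
            )
    return out


def write_annotation(table: pd.DataFrame, background: float, tsv_path, json_path=None):
    table.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        summary = {
            "n_probesets": int(len(table)),
            "category_counts": table["category"].value_counts().to_dict(),
            "background_intronic_fraction": background,
        }
        with open(json_path, "w") as fh:
            json.dump(summary, fh, indent=2)


def transcript_sequences(
    models: Sequence[TranscriptModel], genome: Mapping[str, str]
) -> dict[str, str]:
    return {m.transcript_id: m.spliced_sequence(genome) for m in models}
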