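"""Synthetic genomes, probe sets, expression matrices and Ct tables.

The generator builds a miniature transcriptome with known ground truth that
mirrors the statistical structure the downstream analysis assumes:

* genes with exon/intron structure laid out non-overlapping on one
  chromosome (plus a dedicated repeat chromosome when repeat-class probe
  sets are requested);
* probe sets of five classes — exonic (substrings of the spliced mRNA),
  intronic (sense strand, fully inside introns), boundary (straddling an
  exon/intron junction), repeat (sequence present at many genomic loci) and
  antisense (reverse complement of intronic sequence);
* expression matrices in which exonic probe sets report total transcript
  and intronic/boundary probe sets report total x unspliced fraction, so a
  gene can lose unspliced signal without any change in total mRNA — the
  selective pattern the analysis is designed to detect;
* Ct tables following the log2 single-copy-per-cycle model with a constant
  reference gene.

Everything is drawn from one :class:`numpy.random.Generator` seeded from
``config.seed``; a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix
from .probe_annotation import (
    ProbeSet,
    TranscriptModel,
    reverse_complement,
)

PROBE_CLASSES = ("exonic", "intronic", "boundary", "repeat", "antisense")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults give a small two-genotype
    paired design with a minority of genes losing unspliced signal only."""

    n_genes: int = 30
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_len: tuple[int, int] = (150, 400)
    intron_len: tuple[int, int] = (300, 900)
    intergenic_len: tuple[int, int] = (200, 500)
    n_probesets_per_class: dict[str, int] = field(
        default_factory=lambda: {
            "exonic": 30, "intronic": 10, "boundary": 3, "repeat": 3, "antisense": 3,
        }
    )
    # Paired genotype design: [(genotype, n_pairs), (genotype, n_pairs)].
    # Cell-type design: list of (cell_type, n_samples) with design="celltype".
    groups: tuple = (("WT", 4), ("het", 4))
    design: str = "paired"
    baseline_unspliced: float = 0.2
    selective_unspliced: tuple[float, float] = (0.4, 0.1)  # (first, second) group
    n_selective: int = 4
    total_expression_range: tuple[float, float] = (2000.0, 20000.0)
    noise_sd: float = 0.25
    pair_effect_sd: float = 0.2
    n_tech_replicates: int = 1
    present_threshold: float = math.log2(100)
    background_intensity: float = 60.0
    repeat_copies: int = 12
    probes_per_set: int = 11
    probe_len: int = 25
    # celltype design: unspliced fraction of selective genes in the target
    # cell type vs all others (totals stay equal across cell types);
    # celltype_effect_sd is the per-gene, per-cell-type log2 jitter of the
    # unspliced fraction that gives each cell type its own expression
    # pattern (without it, sample correlations would be noise-only)
    target_group: str | None = None
    signature_unspliced: tuple[float, float] = (0.5, 0.1)
    celltype_effect_sd: float = 0.8
    # qRT simulation
    n_experiments: int = 3
    ct_intercept: float = 35.0
    qrt_noise_sd: float = 0.15
    reference_quantity: float = 5000.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("exons_per_gene", "exon_len", "intron_len", "intergenic_len"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (lo, hi) range")
        for f in (self.baseline_unspliced, *self.selective_unspliced,
                  *self.signature_unspliced):
            if not 0.0 <= f <= 1.0:
                raise ValueError("unspliced fractions must lie in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.noise_sd < 0 or self.pair_effect_sd < 0 or self.qrt_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.design not in ("paired", "celltype"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.design == "paired" and len(self.groups) != 2:
            raise ValueError("paired design needs exactly two genotype groups")
        unknown = set(self.n_probesets_per_class) - set(PROBE_CLASSES)
        if unknown:
            raise ValueError(f"unknown probe classes: {sorted(unknown)}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    probeset_class: dict[str, str]
    probeset_gene: dict[str, str | None]
    gene_total: dict[str, float]
    unspliced: dict[str, dict[str, float]]  # gene -> group -> fraction
    selective_genes: list[str]
    signature_probesets: list[str]

    def annotation_frame(self) -> pd.DataFrame:
        """Truth rendered in the shape of an annotation table (exonic and
        boundary map onto the array categories mRNA and ambiguous)."""
        to_cat = {
            "exonic": "mRNA", "intronic": "intronic", "boundary": "ambiguous",
            "repeat": "repeat", "antisense": "ambiguous",
        }
        return pd.DataFrame(
            {
                "probeset_id": list(self.probeset_class),
                "category": [to_cat[c] for c in self.probeset_class.values()],
                "gene_id": [self.probeset_gene[p] for p in self.probeset_class],
            }
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "probeset_class": self.probeset_class,
                    "probeset_gene": self.probeset_gene,
                    "gene_total": self.gene_total,
                    "unspliced": self.unspliced,
                    "selective_genes": self.selective_genes,
                    "signature_probesets": self.signature_probesets,
                },
                fh,
                indent=2,
            )


# ---------------------------------------------------------------------------
# Gene models and genome
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def generate_gene_models(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[TranscriptModel]]:
    """Lay out non-overlapping genes on one chromosome of random sequence.

    Exon counts and lengths are drawn uniformly from the configured ranges;
    strands alternate deterministically so both are always exercised.  When
    repeat probe sets are requested, a second chromosome carrying tandem
    copies of a repeat unit is added.
    """
    config.validate()
    rng = config.rng()
    models: list[TranscriptModel] = []
    cursor = 0
    for gi in range(config.n_genes):
        cursor += int(rng.integers(*config.intergenic_len, endpoint=True))
        n_exons = int(rng.integers(*config.exons_per_gene, endpoint=True))
        exons = []
        pos = cursor
        for ei in range(n_exons):
            elen = int(rng.integers(*config.exon_len, endpoint=True))
            exons.append((pos, pos + elen))
            pos += elen
            if ei < n_exons - 1:
                pos += int(rng.integers(*config.intron_len, endpoint=True))
        cursor = pos
        strand = "+" if gi % 2 == 0 else "-"
        models.append(
            TranscriptModel(
                gene_id=f"g{gi:04d}",
                transcript_id=f"t{gi:04d}",
                chrom="chr1",
                strand=strand,
                exons=tuple(exons),
            )
        )
    total_len = cursor + int(rng.integers(*config.intergenic_len, endpoint=True))
    genome = {"chr1": _random_seq(rng, total_len)}

    n_repeat_ps = config.n_probesets_per_class.get("repeat", 0)
    if n_repeat_ps > 0:
        unit = _random_seq(
            rng, config.probe_len + config.probes_per_set * n_repeat_ps + 10
        )
        parts = []
        for _ in range(config.repeat_copies):
            parts.append(unit)
            parts.append(_random_seq(rng, 40))
        genome["chrR"] = "".join(parts)
    return genome, models


def _repeat_unit_len(config: SimulationConfig) -> int:
    n = config.n_probesets_per_class.get("repeat", 0)
    return config.probe_len + config.probes_per_set * n + 10


# ---------------------------------------------------------------------------
# Probe-set design
# ---------------------------------------------------------------------------

def _sense(seq: str, strand: str) -> str:
    return reverse_complement(seq) if strand == "-" else seq


def _sample_distinct(rng, candidates: Sequence[int], n: int, what: str) -> list[int]:
    if len(candidates) < n:
        raise ValueError(f"too few candidate positions for {what}")
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in sorted(idx)]


def design_probe_sets(
    models: Sequence[TranscriptModel],
    genome: Mapping[str, str],
    config: SimulationConfig,
) -> tuple[list[ProbeSet], GroundTruth]:
    """Draw probe sets of each requested class and record the ground truth.

    Genes are used round-robin within each class, so with enough probe sets
    most genes end up carrying both an exonic and an intronic probe set —
    the pairing the selective-splicing analysis relies on.  Selective genes
    (those whose unspliced fraction will differ between groups) are the
    first ``n_selective`` genes that received an intronic probe set.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    k = config.probe_len
    npp = config.probes_per_set
    probesets: list[ProbeSet] = []
    ps_class: dict[str, str] = {}
    ps_gene: dict[str, str | None] = {}

    with_introns = [m for m in models if m.introns]
    counter = 0

    def take_probes(m: TranscriptModel, cls: str) -> tuple[str, ...]:
        chrom = genome[m.chrom]
        if cls == "exonic":
            tx = m.spliced_sequence(genome)
            cands = list(range(len(tx) - k + 1))
            starts = _sample_distinct(rng, cands, npp, f"exonic probes in {m.gene_id}")
            return tuple(tx[s : s + k] for s in starts)
        if cls in ("intronic", "antisense"):
            cands = [
                p
                for s, e in m.introns
                for p in range(s, e - k + 1)
            ]
            starts = _sample_distinct(
                rng, cands, npp, f"{cls} probes in {m.gene_id} (introns too short)"
            )
            seqs = [_sense(chrom[s : s + k], m.strand) for s in starts]
            if cls == "antisense":
                seqs = [reverse_complement(s) for s in seqs]
            return tuple(seqs)
        if cls == "boundary":
            cands = []
            for (es, ee), (ns, ne) in zip(m.exons, m.exons[1:]):
                # windows straddling the exon-end junction with >=5 nt each side
                cands.extend(range(ee - k + 5, ee - 5 + 1))
                # and the intron-end/next-exon-start junction
                cands.extend(range(ns - k + 5, ns - 5 + 1))
            cands = sorted(set(c for c in cands if 0 <= c <= len(chrom) - k))
            starts = _sample_distinct(rng, cands, npp, f"boundary probes in {m.gene_id}")
            return tuple(_sense(chrom[s : s + k], m.strand) for s in starts)
        raise AssertionError(cls)

    for cls in ("exonic", "intronic", "boundary", "antisense"):
        n_sets = config.n_probesets_per_class.get(cls, 0)
        pool = models if cls == "exonic" else with_introns
        if n_sets > 0 and not pool:
            raise ValueError(f"no gene can host {cls} probe sets")
        for j in range(n_sets):
            m = pool[j % len(pool)]
            pid = f"ps{counter:05d}_{cls[:2]}"
            counter += 1
            probes = take_probes(m, cls)
            if len(set(probes)) < npp:
                # overlapping draws can coincide in tiny genes; redraw once
                probes = take_probes(m, cls)
            probesets.append(ProbeSet(pid, probes))
            ps_class[pid] = cls
            ps_gene[pid] = m.gene_id

    n_repeat = config.n_probesets_per_class.get("repeat", 0)
    if n_repeat > 0:
        if "chrR" not in genome:
            raise ValueError("genome lacks the repeat chromosome (chrR)")
        unit_len = _repeat_unit_len(config)
        unit = genome["chrR"][:unit_len]
        for j in range(n_repeat):
            pid = f"ps{counter:05d}_re"
            counter += 1
            offs = range(j * npp, (j + 1) * npp)
            probesets.append(ProbeSet(pid, tuple(unit[o : o + k] for o in offs)))
            ps_class[pid] = "repeat"
            ps_gene[pid] = None

    # Expression ground truth.
    lo, hi = config.total_expression_range
    totals = {
        m.gene_id: float(2 ** rng.uniform(math.log2(lo), math.log2(hi)))
        for m in models
    }
    intronic_genes = [
        ps_gene[p] for p in ps_class if ps_class[p] == "intronic"
    ]
    seen: list[str] = []
    for g in intronic_genes:
        if g not in seen:
            seen.append(g)
    if len(seen) < config.n_selective:
        raise ValueError(
            f"only {len(seen)} genes host intronic probe sets; "
            f"cannot plant {config.n_selective} selective genes"
        )
    selective = seen[: config.n_selective]

    group_names = [g for g, _ in config.groups]
    if config.design == "celltype":
        # Each signature gene is strongly unspliced in the target population
        # and weakly (with gene- and cell-type-specific variation) elsewhere;
        # non-signature genes get mild per-cell-type jitter around baseline.
        # The jitter gives every cell type its own correlated expression
        # pattern, so samples of a type cluster together while only the
        # signature makes the target population stand apart.
        target = config.target_group or group_names[0]
        hi_u, lo_u = config.signature_unspliced
        sd = config.celltype_effect_sd
        unspliced = {}
        for m in models:
            per_group = {}
            for g in group_names:
                if m.gene_id in selective:
                    base = hi_u if g == target else lo_u
                    u = base * 2.0 ** rng.normal(0.0, sd)
                else:
                    u = config.baseline_unspliced  # uninformative across types
                per_group[g] = float(np.clip(u, 0.01, 0.95))
            unspliced[m.gene_id] = per_group
    else:
        u_first, u_second = config.selective_unspliced
        unspliced = {
            m.gene_id: {
                g: (
                    (u_first if gi == 0 else u_second)
                    if m.gene_id in selective
                    else config.baseline_unspliced
                )
                for gi, g in enumerate(group_names)
            }
            for m in models
        }

    signature = [
        p for p, c in ps_class.items()
        if c == "intronic" and ps_gene[p] in selective
    ]
    truth = GroundTruth(
        probeset_class=ps_class,
        probeset_gene=ps_gene,
        gene_total=totals,
        unspliced=unspliced,
        selective_genes=list(selective),
        signature_probesets=signature,
    )
    return probesets, truth


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(
    models: Sequence[TranscriptModel],
    truth: GroundTruth,
    config: SimulationConfig,
) -> ExpressionMatrix:
    """Log2 intensities per probe set and sample from the generative model.

    exonic:            log2(total) + effects + noise
    intronic/boundary: log2(total x unspliced fraction) + effects + noise
    repeat/antisense:  log2(background intensity) + noise

    In the paired design each pair contributes a shared Gaussian offset to
    both genotypes (biological pairing); technical replicates of a sample
    differ only in measurement noise.  Detection calls threshold the
    intensity at ``present_threshold``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)

    cols: list[str] = []
    meta_rows = []
    if config.design == "paired":
        (ga, na), (gb, nb) = config.groups
        if na != nb:
            raise ValueError("paired design needs equal pair counts")
        for p in range(na):
            for g in (ga, gb):
                bios = f"{g}_p{p + 1}"
                for r in range(config.n_tech_replicates):
                    col = bios if config.n_tech_replicates == 1 else f"{bios}_r{r + 1}"
                    cols.append(col)
                    meta_rows.append((col, bios, g, f"p{p + 1}", f"r{r + 1}"))
    else:
        for g, n in config.groups:
            for s in range(n):
                bios = f"{g}_s{s + 1}"
                cols.append(bios)
                meta_rows.append((bios, bios, g, "", "r1"))
    samples = pd.DataFrame(
        meta_rows, columns=["column", "biosample", "group", "pair", "replicate"]
    ).set_index("column")

    pair_ids = sorted(samples["pair"].unique())
    pair_offset = {
        p: (float(rng.normal(0.0, config.pair_effect_sd)) if p else 0.0)
        for p in pair_ids
    }

    pids = list(truth.probeset_class)
    mean = np.empty((len(pids), len(cols)))
    bg = math.log2(config.background_intensity)
    col_group = samples["group"].tolist()
    col_offset = [pair_offset[p] for p in samples["pair"]]
    for i, pid in enumerate(pids):
        cls = truth.probeset_class[pid]
        gene = truth.probeset_gene[pid]
        for j in range(len(cols)):
            if cls in ("repeat", "antisense") or gene is None:
                mu = bg
            elif cls == "exonic":
                mu = math.log2(truth.gene_total[gene])
            else:  # intronic, boundary
                u = truth.unspliced[gene][col_group[j]]
                mu = math.log2(max(truth.gene_total[gene] * u, 1e-12))
            mean[i, j] = mu + col_offset[j]

    noise = rng.normal(0.0, config.noise_sd, size=mean.shape) if config.noise_sd else 0.0
    values = pd.DataFrame(mean + noise, index=pids, columns=cols)
    calls = pd.DataFrame(
        np.where(values.to_numpy() >= config.present_threshold, "Present", "Absent"),
        index=pids,
        columns=cols,
    )
    return ExpressionMatrix(values, calls, samples)


# ---------------------------------------------------------------------------
# qRT simulation
# ---------------------------------------------------------------------------

def simulate_qrt(
    truth: GroundTruth,
    config: SimulationConfig,
    genes: Sequence[str] | None = None,
    reference_gene: str = "Ref",
) -> pd.DataFrame:
    """Ct table for exonic and intronic amplicons of the chosen genes.

    Ct = intercept - log2(quantity) + Gaussian noise.  Exonic amplicons
    measure total transcript; intronic amplicons measure total x unspliced
    fraction.  The reference gene has a constant quantity in every sample.
    One sample per group per independent experiment.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 3)
    if genes is None:
        genes = truth.selective_genes + [
            g for g in truth.gene_total if g not in truth.selective_genes
        ][:2]
    group_names = [g for g, _ in config.groups]

    rows = []
    for exp in range(1, config.n_experiments + 1):
        for grp in group_names:
            sample = f"{grp}_e{exp}"
            for gene in genes:
                total = truth.gene_total[gene]
                u = truth.unspliced[gene][grp]
                for amp, q in (("exonic", total), ("intronic", total * u)):
                    if q <= 0:
                        raise ValueError(
                            f"nonpositive quantity for {gene}/{amp} in {grp}"
                        )
                    ct = config.ct_intercept - math.log2(q)
                    if config.qrt_noise_sd:
                        ct += float(rng.normal(0.0, config.qrt_noise_sd))
                    rows.append((gene, amp, sample, grp, f"e{exp}", ct))
            ct = config.ct_intercept - math.log2(config.reference_quantity)
            if config.qrt_noise_sd:
                ct += float(rng.normal(0.0, config.qrt_noise_sd))
            rows.append((reference_gene, "exonic", sample, grp, f"e{exp}", ct))
    return pd.DataFrame(
        rows, columns=["gene", "amplicon_type", "sample", "group", "experiment", "ct"]
    )


# ---------------------------------------------------------------------------
# File export
# ---------------------------------------------------------------------------

def write_genome_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_models_gtf(models: Sequence[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            for s, e in m.exons:  # GTF is 1-based closed
                attrs = (
                    f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                    f'refseq "{int(m.refseq)}";'
                )
                fh.write(
                    f"{m.chrom}\tintronsig\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def write_models_bed12(models: Sequence[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            start, end = m.span
            sizes = ",".join(str(e - s) for s, e in m.exons) + ","
            starts = ",".join(str(s - start) for s, _ in m.exons) + ","
            name = f"{m.gene_id}|{m.transcript_id}"
            fh.write(
                f"{m.chrom}\t{start}\t{end}\t{name}\t0\t{m.strand}\t{start}\t{end}\t0\t"
                f"{len(m.exons)}\t{sizes}\t{starts}\n"
            )


def write_probes_fasta(probesets: Sequence[ProbeSet], path) -> None:
    with open(path, "w") as fh:
        for ps in probesets:
            for i, p in enumerate(ps.probes):
                fh.write(f">{ps.probeset_id}_{i}\n{p}\n")


def write_probes_tsv(probesets: Sequence[ProbeSet], path) -> None:
    rows = [
        (ps.probeset_id, i, p)
        for ps in probesets
        for i, p in enumerate(ps.probes)
    ]
    pd.DataFrame(rows, columns=["probeset_id", "probe_index", "sequence"]).to_csv(
        path, sep="\t", index=False
    )


def write_ct_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
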