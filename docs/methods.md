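# Methods

## The problem and the model

Short-oligo 3′ expression arrays interrogate each transcript with a probe set
of eleven 25-nt probes. When all the probes of a set fall, on the coding
strand, entirely inside introns of a gene, the set measures unspliced
pre-mRNA rather than mature message. The package's central quantitative idea
is that a cell can regulate the *unspliced fraction* u of a gene's transcript
pool independently of its total output T: the exonic signal tracks T, the
intronic signal tracks T·u, so a drop in u with T constant appears as an
intronic-only loss of signal. The downstream statistics ask three questions:

1. Are intronic probe sets over-represented among differentially expressed
   probe sets, relative to their share of the whole array?
2. Does the intronic signature carry cell-state information — does it group a
   designated population into its own clade more often than random probe-set
   draws of the same size do?
3. At single-gene resolution (qRT-PCR), does the exonic/intronic ratio pair
   classify genes into selective-splicing versus proportional changes, and
   does the spliced pool T − c·U predict protein better than total mRNA?

## Probe-set re-annotation

Matching is exact: a probe matches a target only at 25/25 identity, found by
hashing every 25-mer of the target sequences (both query orientations are
looked up; occurrences are labeled with the strand of the match). A probe set
matches a target when at least `min_probes` (default 8 of 11) distinct probes
match. The decision cascade is:

1. ≥ 8/11 sense-strand matches to a spliced reference transcript → `mRNA`;
2. otherwise, any probe with more than `repeat_threshold` (default 10)
   perfect genomic occurrences → `repeat`;
3. otherwise ≥ 8/11 probes inside exactly one gene span (first exon start to
   last exon end): `intronic` if every matching probe is on the gene's coding
   strand and wholly inside intron intervals, else `ambiguous` (this absorbs
   junction-straddling, exon-overlapping and antisense-only matches);
   more than one gene span → `ambiguous`;
4. nothing above → `unmapped`.

The cascade order encodes two priorities: a probe set that reads a mature
mRNA is `mRNA` no matter what else it hits, and promiscuous (repeat) probes
are disqualified from the intronic class because their signal cannot be
attributed to one locus. Exact matching was chosen over alignment because the
match criterion is perfect identity; there is no mismatch tolerance to
parameterize, and the index is byte-for-byte reproducible. Equivalence with a
brute-force sliding-window classifier is asserted in the test suite.

`repeat_threshold = 10` is a configurable convention (a cut between
single-locus and multi-locus probes); results are insensitive to it on
synthetic data because repeat probes are planted at 12 loci.

## Filtering and paired differential expression

Technical replicates are averaged (arithmetic mean of log₂ intensities;
a collapsed detection call is Absent only when every replicate is Absent).
A probe set is excluded when all samples of some group are called Absent,
when every intensity is below log₂(100) ≈ 6.644, or when the interquartile
range across samples is below 0.5 (strict comparisons; IQR from
linear-interpolation quantiles, the default of mainstream statistics
software). Differential expression is a two-sided paired Student *t*-test on
log₂ values with cut-offs *p* < 0.05 (raw, no multiplicity correction — the
enrichment statistic downstream is robust to the false-positive background,
which is shared between categories) and fold change > 1.5, where fold change
is 2^|mean paired log₂ difference| — the paired variant, consistent with the
paired test. Zero-variance differences leave *p* undefined; such records are
emitted on the fold-change criterion alone and flagged.

## Enrichment statistics

The tally crosses annotation categories with direction (up/down in the
mutant). The expected intronic count per direction is
round(background_fraction × total_DE / 2), rounded half away from zero and
split evenly between directions. The enrichment test is a 2×2 Pearson χ²
with Yates continuity correction (one degree of freedom, two-sided) on

```
[[observed_intronic,            n_tested − observed_intronic],
 [background_intronic − obs.,   background_rest − (n_tested − obs.)]]
```

With the published background 6780/45037 and counts 15/35, the corrected χ²
is ≈ 19.05 (p ≈ 1.3×10⁻⁵); without correction p ≈ 4×10⁻⁶. The correction is
on by default and exposed as a flag. Expected cell counts below 1 attach a
warning to the result rather than suppressing it.

## Signature clustering and the randomization null

Samples are clustered agglomeratively at distance 1 − Pearson *r*, computed
over the signature rows between sample columns, with complete linkage by
default (average and single selectable). Distances are computed on the
intensities **as given**: per-gene magnitudes are part of the signal. An
early design draft z-scored rows before the distance, but Pearson
correlation between samples is not invariant to per-row scaling, and
z-scoring collapses two-level rows (high in the target population, low
elsewhere) into nearly identical patterns — numerically this destroyed clade
separation that is perfectly robust on raw values. Row z-scores are still
used for the exported heat-map matrix, where relative-per-gene display is
the point.

"Clean separation" of a target population is the clade criterion: the
target samples form a subtree — equivalently, some flat cut of the
dendrogram yields exactly the target set as one cluster (the test suite
checks this equivalence by enumerating cuts). The randomization null redraws
`k` probe sets uniformly without replacement from an eligible pool (e.g.
expressed intronic probe sets), re-clusters, and reports the fraction of
draws achieving clean separation; it is fully reproducible from its seed.
Equal-distance merges are resolved by scipy's deterministic internal order,
so results are stable given the input column order.

## qRT quantification and the protein model

Relative quantities follow 2^−ΔΔCt with ideal per-cycle doubling:
ΔCt = Ct_target − Ct_reference within a sample and experiment;
ΔΔCt subtracts the calibrator group's mean ΔCt per gene, amplicon type and
experiment. Per-gene genotype ratios divide group-mean quantities within
each independent experiment and are summarized by the median across
experiments with the (unscaled) median absolute deviation — robust summaries
appropriate for the small number (3) of qRT experiments. Classification uses
a symmetric 1.5-fold band: a ratio r is "within" when 1/1.5 ≤ r ≤ 1.5; mRNA
within with intronic outside is the selective class. Exon–intron and
intron-spanning amplicon types are ingested and quantified but do not enter
the two-axis classification, which is defined on the exonic/intronic pair.

The protein predictor assumes only fully spliced message is translated. With
totals T and unspliced signals U in two conditions, it reports the naive
full-length ratio F = T_A/T_B, the full-over-unspliced ratio
(T_A/U_A)/(T_B/U_B), and the spliced-estimate ratio
(T_A − c·U_A)/(T_B − c·U_B). The constant c maps intronic-amplicon units
onto total-mRNA units; absolute calibration between two different amplicons
is not identifiable from ΔΔCt data alone, so c defaults to 1 and is exposed
for users with calibration curves. A spliced pool that goes non-positive
under the chosen c is an error with a diagnostic, not a silent clamp.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
array physics. Genes (default 30; 2–5 exons of 150–400 bp, introns
300–900 bp) are laid out without overlap on one chromosome of uniform-random
A/C/G/T sequence, strands alternating; coordinates are 0-based half-open
throughout. Probe sets (11 distinct 25-mers each) are drawn per class:
exonic from the spliced transcript, intronic fully inside introns in sense
orientation, boundary straddling a junction with ≥ 5 nt on each side,
antisense as reverse complements of intronic sequence, and repeat from a
dedicated chromosome carrying 12 tandem copies of a unit — one more than the
default repeat threshold.

Expression follows the generative model: exonic signal log₂(T_g), intronic
and boundary signal log₂(T_g·u_g), repeat/antisense a low constant
background (linear 60, below the Present threshold of log₂ 100), all plus
Gaussian noise on the log₂ scale (default sd 0.25) — matching the
log-intensity analysis downstream. Totals T_g are log-uniform in
2000–20000 so that even a gene at u = 0.1 stays above the detection
threshold. In the paired design each pair contributes a shared Gaussian
offset (sd 0.2) to both genotypes, giving the paired *t*-test a real pairing
structure; selective genes differ between genotypes only through u
(default 0.4 vs 0.1, totals equal — a 4-fold intronic-only shift).
Present/Absent calls are synthesized by thresholding because detection-call
software is an input to the real analysis, not part of it.

In the cell-type design, signature genes take a high unspliced fraction in
the target population (0.5) and a low one elsewhere (0.1), each multiplied
by per-(gene, cell type) log₂ jitter (sd 0.8) so that every cell type has
its own correlated pattern over the signature while the target is
consistently extreme; non-signature genes keep a constant unspliced fraction
across cell types and therefore form the uninformative pool for the
randomization null. Ct tables follow Ct = intercept − log₂(quantity) +
noise (intercept 35, sd 0.15 by default, 3 independent experiments, one
sample per group and experiment) with a constant-quantity reference gene.

What the generator does **not** emulate — and hence what passing tests do
not show about real arrays: cross-hybridization and GC-dependent background,
probe-affinity differences within a set, normalization artifacts, correlated
biological variation between genes, partial intron retention gradients
along a transcript, and poly(A)-priming artifacts in qRT (the latter are
carried only as a data-quality flag on input). Recovery rates on synthetic
data are upper bounds on real-data behavior.

## Problem sizes and determinism

Default study sizes (30–350 genes, 49–1000 probe sets, 4–6 pairs, 12
cell-type samples, 200 null draws) were chosen so the entire suite and the
acceptance script run in seconds while keeping every statistic in its
asymptotically meaningful regime (e.g. the planted-recovery study uses 1000
probe sets with a 15% intronic background, mirroring the array's category
proportions). All randomness flows from a single integer seed through
`numpy.random.default_rng`; a fixed seed yields byte-identical files, and
stage outputs of the CLI are reproducible end to end (verified by the test
suite comparing two runs byte for byte).

## Known limitations

* The mRNA stage does not distinguish the finer sub-categories (non-RefSeq,
  ncRNA, alternative 3′ UTR); model metadata can carry such labels but no
  sequence-based criterion is implemented for them.
* Probe sets matching several gene spans, or only antisense, are labeled
  `ambiguous` as a single class.
* The linkage method of the original clustering tool chain is not published;
  clade outcomes at small sample counts can depend on the linkage chosen,
  so the null fractions are comparable only within a linkage setting.
* The ΔΔCt model fixes amplification efficiency at 2 per cycle; efficiency
  calibration per primer pair is out of scope.
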