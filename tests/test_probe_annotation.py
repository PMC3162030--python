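"""Exact-match index, probe-set matching and the classification cascade."""

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_classify, rc, scan_occurrences
from intronsig import (
    ProbeSet,
    SimulationConfig,
    TranscriptModel,
    annotate_array,
    build_match_index,
    call_probeset_target,
    classify_probe_set,
    design_probe_sets,
    generate_gene_models,
    match_probe_set,
    reverse_complement,
)
from intronsig.probe_annotation import (
    load_models_bed12,
    load_models_gtf,
    load_probes_fasta,
    load_probes_tsv,
    transcript_sequences,
)
from intronsig.synthetic_data import (
    write_models_bed12,
    write_models_gtf,
    write_probes_fasta,
    write_probes_tsv,
)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestKmerIndex:
    def test_single_occurrence_and_reverse_complement(self):
        rng = np.random.default_rng(0)
        probe = _random_seq(rng, 25)
        seq = _random_seq(rng, 500) + probe + _random_seq(rng, 500)
        idx = build_match_index({"s": seq})
        hits = idx.query(probe)
        assert len(hits) == 1 and hits[0].strand == "+" and hits[0].offset == 500
        rhits = idx.query(reverse_complement(probe))
        assert len(rhits) == 1 and rhits[0].strand == "-" and rhits[0].offset == 500

    def test_equivalence_with_sliding_window_scan(self):
        rng = np.random.default_rng(42)
        seq = _random_seq(rng, 10_000)
        idx = build_match_index({"s": seq})
        queries = [seq[i : i + 25] for i in rng.integers(0, 9_975, size=100)]
        queries += [_random_seq(rng, 25) for _ in range(50)]
        queries += [rc(q) for q in queries[:50]]
        for q in queries:
            expect = {(pos, strand) for pos, strand in scan_occurrences(seq, q)}
            got = {(h.offset, h.strand) for h in idx.query(q)}
            assert got == expect

    def test_short_sequences_never_match(self):
        idx = build_match_index({"tiny": "ACGT" * 5})  # 20 nt < 25
        assert idx.query("A" * 25) == []


class TestMatching:
    def test_counts_are_distinct_probes_per_target(self):
        rng = np.random.default_rng(1)
        probes = [_random_seq(rng, 25) for _ in range(11)]
        t1 = "".join(probes)  # all 11 inside target 1
        t2 = "".join(probes[:5])
        idx = build_match_index({"t1": t1, "t2": t2})
        counts, _ = match_probe_set(ProbeSet("ps", tuple(probes)), idx)
        assert counts == {"t1": 11, "t2": 5}

    def test_duplicate_occurrences_count_once(self):
        rng = np.random.default_rng(2)
        probes = [_random_seq(rng, 25) for _ in range(11)]
        doubled = "".join(probes) + "NNNN" + "".join(probes)
        idx = build_match_index({"t": doubled})
        counts, matches = match_probe_set(ProbeSet("ps", tuple(probes)), idx)
        assert counts == {"t": 11}
        assert len(matches) == 22  # every occurrence still reported

    @pytest.mark.parametrize("n,expected", [(8, True), (7, False), (11, True)])
    def test_eight_of_eleven_threshold(self, n, expected):
        assert (("t" in call_probeset_target({"t": n})) is expected)

    def test_multiple_targets_above_threshold_all_returned(self):
        assert call_probeset_target({"a": 11, "b": 9, "c": 7}) == {"a", "b"}


def _toy_locus(rng, strand="+"):
    """One two-exon gene in 3 kb of sequence; returns (genome, model)."""
    seq = _random_seq(rng, 3000)
    model = TranscriptModel("gA", "tA", "chr1", strand,
                            exons=((500, 900), (1900, 2400)))
    return {"chr1": seq}, model


class TestClassifyCascade:
    def _annotate_one(self, ps, genome, models):
        table, _ = annotate_array(
            [ps], transcript_sequences(models, genome), genome, models
        )
        return table.iloc[0]["category"]

    def test_all_probes_in_intron_sense_is_intronic(self):
        rng = np.random.default_rng(3)
        genome, m = _toy_locus(rng)
        chrom = genome["chr1"]
        probes = tuple(chrom[1000 + 30 * i : 1025 + 30 * i] for i in range(11))
        assert self._annotate_one(ProbeSet("p", probes), genome, [m]) == "intronic"

    def test_minus_strand_gene_intronic_uses_sense_orientation(self):
        rng = np.random.default_rng(4)
        genome, m = _toy_locus(rng, strand="-")
        chrom = genome["chr1"]
        probes = tuple(
            reverse_complement(chrom[1000 + 30 * i : 1025 + 30 * i])
            for i in range(11)
        )
        assert self._annotate_one(ProbeSet("p", probes), genome, [m]) == "intronic"

    def test_nine_probes_on_spliced_transcript_is_mrna(self):
        rng = np.random.default_rng(5)
        genome, m = _toy_locus(rng)
        tx = m.spliced_sequence(genome)
        probes = tuple(tx[10 * i : 10 * i + 25] for i in range(9)) + tuple(
            _random_seq(rng, 25) for _ in range(2)
        )
        assert self._annotate_one(ProbeSet("p", probes), genome, [m]) == "mRNA"

    def test_junction_straddling_probe_breaks_intronic(self):
        rng = np.random.default_rng(6)
        genome, m = _toy_locus(rng)
        chrom = genome["chr1"]
        intronic = [chrom[1000 + 30 * i : 1025 + 30 * i] for i in range(10)]
        straddle = chrom[890:915]  # 10 nt exon, 15 nt intron
        probes = tuple(intronic + [straddle])
        assert self._annotate_one(ProbeSet("p", probes), genome, [m]) == "ambiguous"

    def test_antisense_only_matches_are_ambiguous(self):
        rng = np.random.default_rng(7)
        genome, m = _toy_locus(rng)
        chrom = genome["chr1"]
        probes = tuple(
            reverse_complement(chrom[1000 + 30 * i : 1025 + 30 * i])
            for i in range(11)
        )
        assert self._annotate_one(ProbeSet("p", probes), genome, [m]) == "ambiguous"

    def test_two_gene_spans_matched_is_ambiguous(self):
        rng = np.random.default_rng(8)
        seq = _random_seq(rng, 3000)
        # second gene's span covers the same intronic window via overlap on
        # a second chromosome copy
        genome = {"chr1": seq, "chr2": seq}
        m1 = TranscriptModel("gA", "tA", "chr1", "+", ((500, 900), (1900, 2400)))
        m2 = TranscriptModel("gB", "tB", "chr2", "+", ((500, 900), (1900, 2400)))
        probes = tuple(seq[1000 + 30 * i : 1025 + 30 * i] for i in range(11))
        assert self._annotate_one(ProbeSet("p", probes), genome, [m1, m2]) == "ambiguous"

    def test_repeat_precedence_over_intronic(self):
        rng = np.random.default_rng(9)
        genome, m = _toy_locus(rng)
        unit = genome["chr1"][1000:1330]
        genome["chr2"] = "".join(unit + _random_seq(rng, 20) for _ in range(12))
        probes = tuple(genome["chr1"][1000 + 30 * i : 1025 + 30 * i] for i in range(11))
        assert self._annotate_one(ProbeSet("p", probes), genome, [m]) == "repeat"

    def test_no_match_is_unmapped(self):
        rng = np.random.default_rng(10)
        genome, m = _toy_locus(rng)
        probes = tuple(_random_seq(rng, 25) for _ in range(11))
        assert self._annotate_one(ProbeSet("p", probes), genome, [m]) == "unmapped"

    def test_probe_order_permutation_never_changes_category(self):
        rng = np.random.default_rng(11)
        genome, m = _toy_locus(rng)
        chrom = genome["chr1"]
        probes = [chrom[1000 + 30 * i : 1025 + 30 * i] for i in range(11)]
        base = self._annotate_one(ProbeSet("p", tuple(probes)), genome, [m])
        rng.shuffle(probes)
        assert self._annotate_one(ProbeSet("p", tuple(probes)), genome, [m]) == base


class TestAnnotateArray:
    def test_generator_truth_recovered_exactly(self, small_sim):
        genome, models = small_sim["genome"], small_sim["models"]
        table, background = annotate_array(
            small_sim["probesets"],
            transcript_sequences(models, genome),
            genome,
            models,
        )
        expect = small_sim["truth"].annotation_frame().set_index("probeset_id")
        got = table.set_index("probeset_id")
        assert (got["category"] == expect.loc[got.index, "category"]).all()
        n_intronic = (expect["category"] == "intronic").sum()
        assert background == pytest.approx(n_intronic / len(expect))

    def test_brute_force_oracle_agreement(self, small_sim):
        genome, models = small_sim["genome"], small_sim["models"]
        table, _ = annotate_array(
            small_sim["probesets"],
            transcript_sequences(models, genome),
            genome,
            models,
        )
        got = table.set_index("probeset_id")["category"]
        for ps in small_sim["probesets"][::3]:  # subsample for speed
            assert got[ps.probeset_id] == brute_force_classify(ps, models, genome)

    def test_exclusion_list_changes_denominator(self, small_sim):
        genome, models = small_sim["genome"], small_sim["models"]
        refseq = transcript_sequences(models, genome)
        table, bg_all = annotate_array(
            small_sim["probesets"], refseq, genome, models
        )
        mrna_ids = table.loc[table["category"] == "mRNA", "probeset_id"]
        _, bg_excl = annotate_array(
            small_sim["probesets"], refseq, genome, models, exclude=list(mrna_ids)
        )
        retained = len(table) - len(mrna_ids)
        n_intronic = (table["category"] == "intronic").sum()
        assert bg_excl == pytest.approx(n_intronic / retained)
        assert bg_excl > bg_all

    def test_duplicate_probeset_ids_rejected(self, small_sim):
        genome, models = small_sim["genome"], small_sim["models"]
        ps = small_sim["probesets"][0]
        with pytest.raises(ValueError, match="duplicate"):
            annotate_array(
                [ps, ps], transcript_sequences(models, genome), genome, models
            )

    def test_strand_flip_invariance(self):
        """Reverse-complementing the genome and flipping every model leaves
        all categories unchanged."""
        cfg = SimulationConfig(seed=17, n_genes=12, n_probesets_per_class={
            "exonic": 6, "intronic": 6, "boundary": 2, "antisense": 2,
        })
        genome, models = generate_gene_models(cfg)
        probesets, _ = design_probe_sets(models, genome, cfg)
        table, _ = annotate_array(
            probesets, transcript_sequences(models, genome), genome, models
        )

        L = len(genome["chr1"])
        flipped_genome = {"chr1": reverse_complement(genome["chr1"])}
        flipped_models = [
            TranscriptModel(
                m.gene_id, m.transcript_id, m.chrom,
                "-" if m.strand == "+" else "+",
                tuple(sorted((L - e, L - s) for s, e in m.exons)),
                refseq=m.refseq,
            )
            for m in models
        ]
        table2, _ = annotate_array(
            probesets,
            transcript_sequences(flipped_models, flipped_genome),
            flipped_genome,
            flipped_models,
        )
        merged = table.merge(table2, on="probeset_id", suffixes=("", "_flipped"))
        assert (merged["category"] == merged["category_flipped"]).all()


class TestModelIO:
    def test_gtf_and_bed12_round_trip(self, small_sim, tmp_path):
        models = small_sim["models"]
        write_models_gtf(models, tmp_path / "m.gtf")
        write_models_bed12(models, tmp_path / "m.bed")
        for loaded in (
            load_models_gtf(tmp_path / "m.gtf"),
            load_models_bed12(tmp_path / "m.bed"),
        ):
            by_id = {m.transcript_id: m for m in loaded}
            assert len(by_id) == len(models)
            for m in models:
                got = by_id[m.transcript_id]
                assert got.exons == m.exons
                assert got.strand == m.strand and got.chrom == m.chrom

    def test_probe_fasta_and_tsv_round_trip(self, small_sim, tmp_path):
        probesets = small_sim["probesets"]
        write_probes_fasta(probesets, tmp_path / "p.fa")
        write_probes_tsv(probesets, tmp_path / "p.tsv")
        for loaded in (
            load_probes_fasta(tmp_path / "p.fa"),
            load_probes_tsv(tmp_path / "p.tsv"),
        ):
            assert sorted(loaded, key=lambda p: p.probeset_id) == sorted(
                probesets, key=lambda p: p.probeset_id
            )


def test_probe_length_enforced():
    with pytest.raises(ValueError, match="length"):
        ProbeSet("p", ("ACGT",))
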