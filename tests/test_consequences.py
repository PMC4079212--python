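import dataclasses
import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from plastedit.calling import EditingSite
from plastedit.consequences import (
    ConsistencyError,
    GeneEditingSummary,
    UndefinedCorrelationError,
    aggregate,
    annotate_codon_effects,
    apply_edits,
    hydropathy_mw_shift,
    identity_to_homolog,
    read_summary_tsv,
    sites_from_truth,
    spearman_rank,
    summaries_from_fixture,
    summarize_gene,
    write_summary_tsv,
)
from plastedit.core import (
    GeneRecord,
    LengthError,
    MoleculeClass,
    classify_edit,
    translate,
)
from plastedit.simulate import (
    SimulationConfig,
    homolog_restoration_scenario,
    make_gene,
    plant_edits,
    stop_restoration_scenario,
)


def _site(gene, pos, rna_base):
    etype = classify_edit(gene.seq[pos], rna_base)
    return EditingSite(
        gene_id=gene.gene_id,
        position=pos,
        dna_base=gene.seq[pos],
        rna_base=etype.rna_base,
        type=etype,
        depth=100,
        edited_reads=100,
        edited_fraction=1.0,
    )


class TestApplyEdits:
    def test_no_sites_identity(self):
        gene = GeneRecord("g", "g", "ATGAAA")
        assert apply_edits(gene, []) == gene.seq

    def test_single_substitution(self):
        gene = GeneRecord("g", "g", "AAAAAA")
        assert apply_edits(gene, [_site(gene, 0, "G")]) == "GAAAAA"

    def test_reference_mismatch_raises(self):
        gene = GeneRecord("g", "g", "ATGAAA")
        bad = _site(gene, 3, "G")
        bad = dataclasses.replace(bad, dna_base="C")
        with pytest.raises(ConsistencyError):
            apply_edits(gene, [bad])

    def test_roundtrip_against_simulator_transcript(self, small_config):
        gene = make_gene(small_config)
        transcript, truth = plant_edits(gene, small_config)
        assert apply_edits(gene, truth.planted_edits) == transcript
        assert apply_edits(gene, sites_from_truth(gene, truth)) == transcript


class TestAnnotateCodonEffects:
    def test_double_substitution_met_to_ala(self):
        # joint application inside one codon: ATG with A->G and T->C
        gene = GeneRecord("g", "g", "AAAATGAAA")
        sites = [_site(gene, 3, "G"), _site(gene, 4, "C")]
        annotated = annotate_codon_effects(gene, sites)
        assert [s.codon_position for s in annotated] == [1, 2]
        for site in annotated:
            assert site.ref_codon == "ATG"
            assert site.alt_codon == "GCG"
            assert site.ref_aa == "M"
            assert site.alt_aa == "A"
            assert site.synonymous is False

    def test_stop_restoration_tga_to_tgg(self):
        gene = GeneRecord("g", "g", "ATGTGAAAA")
        (site,) = annotate_codon_effects(gene, [_site(gene, 5, "G")])
        assert site.ref_codon == "TGA"
        assert site.alt_codon == "TGG"
        assert site.ref_aa == "*"
        assert site.alt_aa == "W"
        assert site.stop_restoration is True
        assert site.codon_position == 3

    def test_synonymous_third_position(self):
        gene = GeneRecord("g", "g", "ATGCCAAAA")
        (site,) = annotate_codon_effects(gene, [_site(gene, 5, "G")])
        assert site.ref_codon == "CCA"
        assert site.alt_codon == "CCG"
        assert site.synonymous is True
        assert site.stop_restoration is False

    def test_rrna_gets_no_codon_annotation(self):
        gene = GeneRecord("r", "r", "ACGTACGT", molecule_class=MoleculeClass.rRNA)
        (site,) = annotate_codon_effects(gene, [_site(gene, 2, "T")])
        assert site.codon_position is None
        assert site.synonymous is None

    def test_position_beyond_cds_raises(self):
        gene = GeneRecord("g", "g", "ATGAAA")
        site = _site(gene, 3, "G")
        site = dataclasses.replace(site, position=12)
        with pytest.raises(IndexError):
            annotate_codon_effects(gene, [site])

    def test_codon_position_invariant(self, small_config):
        gene = make_gene(small_config)
        _, truth = plant_edits(gene, small_config)
        annotated = annotate_codon_effects(gene, sites_from_truth(gene, truth))
        for site in annotated:
            assert site.codon_position == site.position % 3 + 1

    def test_brute_force_codon_oracle(self, rng):
        # exhaustive per-codon re-derivation on small random genes
        from Bio.Seq import Seq

        config = SimulationConfig(seed=11, gene_length_nt=90, n_edits=12)
        for trial in range(25):
            sub_rng = np.random.default_rng([trial, 5])
            gene = make_gene(config, sub_rng, gene_id=f"g{trial}")
            transcript, truth = plant_edits(gene, config, rng=sub_rng)
            annotated = annotate_codon_effects(gene, sites_from_truth(gene, truth))
            for site in annotated:
                ci = site.position // 3
                ref_codon = gene.seq[3 * ci: 3 * ci + 3]
                alt_codon = transcript[3 * ci: 3 * ci + 3]
                assert site.ref_codon == ref_codon
                assert site.alt_codon == alt_codon
                assert site.ref_aa == str(Seq(ref_codon).translate(table=11))
                assert site.alt_aa == str(Seq(alt_codon).translate(table=11))
                assert site.synonymous == (site.ref_aa == site.alt_aa)


class TestSummarizeGene:
    def test_petd_like_frequency(self):
        config = SimulationConfig(seed=3, gene_length_nt=477, n_edits=33)
        gene = make_gene(config)
        _, truth = plant_edits(gene, config)
        summary = summarize_gene(gene, sites_from_truth(gene, truth))
        assert summary.n_edits == 33
        assert summary.edit_frequency_pct == 6.9

    def test_psba_like_frequency(self):
        config = SimulationConfig(seed=3, gene_length_nt=1029, n_edits=4)
        gene = make_gene(config)
        _, truth = plant_edits(gene, config)
        summary = summarize_gene(gene, sites_from_truth(gene, truth))
        assert summary.edit_frequency_pct == 0.4

    def test_zero_sites(self):
        gene = GeneRecord("g", "g", "ATGAAACCC")
        summary = summarize_gene(gene, [])
        assert summary.n_edits == 0
        assert summary.edit_frequency_pct == 0.0
        assert summary.n_aa_substitutions == 0
        assert summary.type_counts == {}

    def test_type_counts_sum_to_n_edits(self, small_config):
        gene = make_gene(small_config)
        _, truth = plant_edits(gene, small_config)
        summary = summarize_gene(gene, sites_from_truth(gene, truth))
        assert sum(summary.type_counts.values()) == summary.n_edits
        assert summary.n_aa_substitutions <= summary.n_edits

    def test_per_codon_counting_switch(self):
        gene = GeneRecord("g", "g", "AAAATGAAA")
        sites = [_site(gene, 3, "G"), _site(gene, 4, "C")]
        per_site = summarize_gene(gene, sites)
        per_codon = summarize_gene(gene, sites, count_per_codon=True)
        assert per_site.n_aa_substitutions == 2
        assert per_codon.n_aa_substitutions == 1

    def test_foreign_site_rejected(self):
        gene = GeneRecord("g", "g", "ATGAAA")
        other = GeneRecord("h", "h", "ATGAAA")
        with pytest.raises(ValueError):
            summarize_gene(gene, [_site(other, 3, "G")])


class TestAggregateFixture:
    @pytest.fixture
    def stats(self, table1):
        return aggregate(summaries_from_fixture(table1))

    def test_total_edits(self, stats):
        assert stats.total_edits == 471

    def test_mrna_and_substitution_totals(self, stats):
        assert stats.total_mrna_edits == 413
        assert stats.total_aa_substitutions == 364
        assert stats.pct_aa_changing == 88

    def test_petb_gc_share(self, table1):
        summaries = {s.gene_id: s for s in summaries_from_fixture(table1)}
        assert summaries["petB"].type_share_pct("G/C") == 39
        assert summaries["petD"].type_share_pct("G/C") == 24

    def test_nine_observed_types(self, stats):
        assert len(stats.observed_types) == 9
        assert set(stats.observed_types) == {
            "A/G", "C/U", "U/C", "G/C", "A/C", "G/A", "U/G", "G/U", "A/U"
        }

    def test_spectrum_sums_to_100(self, stats):
        assert sum(stats.type_spectrum_pct.values()) == pytest.approx(100, abs=0.5)


class TestAggregateSimulation:
    def test_single_gene_gc_shift(self):
        gene = GeneRecord("g", "g", "A" * 99)
        sites = [_site(gene, 30, "G")]
        annotated = annotate_codon_effects(gene, sites)
        stats = aggregate([summarize_gene(gene, annotated)], annotated, [gene])
        assert stats.gc_pre_pct == 0.0
        assert stats.gc_post_pct == pytest.approx(100 / 99, abs=0.01)

    def test_codon_position_distribution(self):
        gene = GeneRecord("g", "g", "AAA" * 10)
        sites = [_site(gene, p, "G") for p in (3, 6, 9, 12, 4, 7, 5)]
        annotated = annotate_codon_effects(gene, sites)
        stats = aggregate([summarize_gene(gene, annotated)], annotated, [gene])
        assert stats.codon_position_counts == {1: 4, 2: 2, 3: 1}
        assert sum(stats.codon_position_pcts.values()) == pytest.approx(100, abs=0.2)

    def test_double_substitution_pct(self):
        gene = GeneRecord("g", "g", "ATGATGATG")
        sites = [_site(gene, 3, "G"), _site(gene, 4, "C"), _site(gene, 6, "G")]
        annotated = annotate_codon_effects(gene, sites)
        stats = aggregate([summarize_gene(gene, annotated)], annotated, [gene])
        # one doubly-edited codon among three mRNA edits
        assert stats.double_substitution_pct == pytest.approx(33.3)

    def test_requires_at_least_one_summary(self):
        with pytest.raises(ValueError):
            aggregate([])


class TestIdentityToHomolog:
    def test_identical_sequences(self):
        protein = "MKWVTFISLLFLFSSAYS"
        assert identity_to_homolog(protein, protein, protein) == (100, 100)

    def test_constructed_identity_counts(self, rng):
        aa = "ACDEFGHIKLMNPQRSTVWY"
        homolog = "".join(rng.choice(list(aa)) for _ in range(100))

        def mutate(seq, positions):
            out = list(seq)
            for p in positions:
                choices = [a for a in aa if a != out[p]]
                out[p] = choices[int(rng.integers(len(choices)))]
            return "".join(out)

        pre = mutate(homolog, range(5))
        post = mutate(homolog, range(2))
        assert identity_to_homolog(pre, post, homolog) == (95, 98)

    def test_empty_raises(self):
        with pytest.raises(LengthError):
            identity_to_homolog("", "MK", "MK")

    def test_restoration_scenario_direction(self, small_config):
        gene, transcript, truth = homolog_restoration_scenario(small_config)
        shift = hydropathy_mw_shift(gene, sites_from_truth(gene, truth))
        pre, post = identity_to_homolog(
            shift.protein_pre, shift.protein_post, gene.homolog_protein
        )
        assert post == 100
        assert post > pre


class TestHydropathyMwShift:
    def test_no_edits_identical(self):
        gene = GeneRecord("g", "g", "ATGAAACCCGGG")
        shift = hydropathy_mw_shift(gene, [])
        assert shift.mw_pre == shift.mw_post
        assert shift.gravy_pre == shift.gravy_post

    def test_ile_to_val_decreases_gravy_and_mw(self):
        # ATA (Ile) -> GTA (Val) via A/G at codon position 1
        gene = GeneRecord("g", "g", "ATGATAAAA")
        shift = hydropathy_mw_shift(gene, [_site(gene, 3, "G")])
        assert shift.gravy_post - shift.gravy_pre == pytest.approx(
            (4.2 - 4.5) / 3, abs=1e-9
        )
        assert shift.mw_post < shift.mw_pre

    def test_thr_to_ala_increases_gravy(self):
        # ACA (Thr) -> GCA (Ala)
        gene = GeneRecord("g", "g", "ATGACAAAA")
        shift = hydropathy_mw_shift(gene, [_site(gene, 3, "G")])
        assert shift.gravy_post - shift.gravy_pre == pytest.approx(
            (1.8 - (-0.7)) / 3, abs=1e-9
        )

    def test_premature_stops_excluded_and_flagged(self, small_config):
        gene, transcript, truth = stop_restoration_scenario(small_config, n_stops=2)
        shift = hydropathy_mw_shift(gene, sites_from_truth(gene, truth))
        assert shift.pre_internal_stops == 2
        assert shift.post_internal_stops == 0
        assert len(shift.protein_post) == len(gene.seq) // 3
        assert len(shift.protein_pre) == len(shift.protein_post) - 2


class TestSpearman:
    def test_perfect_inverse(self):
        rho, p = spearman_rank([1, 2, 3], [3, 2, 1])
        assert rho == -1.0
        assert p == 0.0

    def test_perfect_direct(self):
        rho, _ = spearman_rank([1, 2, 3], [10, 20, 30])
        assert rho == 1.0

    def test_constant_vector_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_rank([1, 1, 1], [1, 2, 3])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            spearman_rank([1, 2], [1, 2, 3])

    def test_scipy_oracle_with_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            xs = rng.integers(0, 8, size=n).astype(float)  # frequent ties
            ys = rng.normal(size=n)
            if len(set(xs)) < 2:
                continue
            rho, p = spearman_rank(xs, ys)
            expected_rho, expected_p = spearmanr(xs, ys)
            assert rho == pytest.approx(expected_rho, abs=1e-12)
            assert p == pytest.approx(expected_p, abs=1e-9)


class TestDirectionalProperties:
    def test_gc_nondecreasing_spectrum_over_seeds(self):
        from plastedit.core import gc_content

        spectrum = {"A/G": 0.7, "U/C": 0.15, "A/C": 0.1, "U/G": 0.05}
        for seed in range(50):
            config = SimulationConfig(
                seed=seed, gene_length_nt=300, n_edits=12, type_spectrum=spectrum
            )
            gene = make_gene(config)
            transcript, _ = plant_edits(gene, config)
            assert gc_content(transcript) >= gc_content(gene.seq)

    def test_stop_restoration_removes_all_internal_stops(self, small_config):
        gene, transcript, truth = stop_restoration_scenario(small_config, n_stops=4)
        assert "*" in gene.translate()
        assert "*" not in translate(transcript)
        annotated = annotate_codon_effects(gene, sites_from_truth(gene, truth))
        assert sum(s.stop_restoration for s in annotated) == 4
        summary = summarize_gene(gene, annotated)
        assert summary.n_stop_restorations == 4


class TestSummarySerialization:
    def test_roundtrip(self, table1, tmp_path):
        summaries = summaries_from_fixture(table1)
        path = tmp_path / "summary.tsv"
        write_summary_tsv(summaries, path, ["source=fixture"])
        back = read_summary_tsv(path)
        assert len(back) == len(summaries)
        for a, b in zip(back, summaries):
            assert a.gene_id == b.gene_id
            assert a.n_edits == b.n_edits
            assert a.type_counts == b.type_counts
            assert a.edit_frequency_pct == b.edit_frequency_pct
            assert a.n_aa_substitutions == b.n_aa_substitutions
            assert a.identity_post_pct == b.identity_post_pct

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene_id\tmolecule_class\nonly\ttwo\tcolumns\n")
        with pytest.raises(ValueError, match="bad.tsv:2"):
            read_summary_tsv(path)
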