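"""Genetic-code tables, codon counting and the sequence-intrinsic indices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import codonlens as cl
from codonlens.code_core import (
    CODONS,
    CodonCounts,
    codon_ids,
    gc3_content,
    gc_content,
)
from codonlens.exceptions import (
    DomainError,
    EmptyInputError,
    FrameError,
    MissingFamilyError,
)


def counts_of(**kw) -> CodonCounts:
    vec = np.zeros(64, dtype=np.int64)
    for codon, n in kw.items():
        vec[CODONS.index(codon)] = n
    return CodonCounts.from_vector(vec)


class TestCodeTable:
    def test_sense_stop_partition(self):
        code = cl.STANDARD_CODE
        assert len(code.sense_codons) == 61
        assert set(code.stop_codons) == {"TAA", "TAG", "TGA"}

    def test_family_degeneracy_structure(self):
        code = cl.STANDARD_CODE
        assert len(code.degenerate_sense_families) == 18
        assert len(code.twofold_families) == 9
        assert len(code.families["M"]) == 1 and len(code.families["W"]) == 1


class TestCountCodons:
    def test_direct_readoff(self):
        cc = cl.count_codons(cl.GeneRecord("g", "ATGGGTTAA"))
        assert cc.counts == {"ATG": 1, "GGT": 1, "TAA": 1}
        assert (cc.n_sense, cc.n_stop) == (2, 1)

    def test_frame_error(self):
        with pytest.raises(FrameError):
            cl.count_codons(cl.GeneRecord("g", "ATGGG"))

    def test_ambiguous_codons_skipped(self):
        cc = cl.count_codons(cl.GeneRecord("g", "ATGNNNTAA"))
        assert cc.counts == {"ATG": 1, "TAA": 1}
        assert cc.n_skipped == 1

    def test_internal_stop_warns_but_counts(self):
        with pytest.warns(UserWarning, match="internal stop"):
            cc = cl.count_codons(cl.GeneRecord("g", "ATGTAAGGTTAA"))
        assert cc.counts["TAA"] == 2


class TestSynonymousFractions:
    def test_two_codon_family(self):
        fr = cl.synonymous_fractions(counts_of(GCA=1, GCT=3))
        assert fr.family("A") == {"GCA": 0.25, "GCC": 0.0, "GCG": 0.0, "GCT": 0.75}

    def test_single_codon_family(self):
        fr = cl.synonymous_fractions(counts_of(ATG=5))
        assert fr.family("M") == {"ATG": 1.0}
        assert "A" in fr.absent

    def test_family_fractions_sum_to_one(self, small_genome):
        fr = cl.synonymous_fractions(cl.pool_counts(small_genome.genes))
        for aa, fam in fr.fractions.items():
            assert sum(fam.values()) == pytest.approx(1.0, abs=1e-12)

    def test_generator_truth_recovered(self, small_null_genome):
        """Pooled fractions of a selection-free genome match the generating
        GC-model probabilities within binomial sampling error."""
        pooled = cl.pool_counts(small_null_genome.genes)
        obs = cl.synonymous_fractions(pooled)
        expected = small_null_genome.truth.mutational_fractions
        for aa, fam in expected.fractions.items():
            total = sum(pooled.counts.get(c, 0) for c in fam)
            if total < 100:
                continue
            for codon, p in fam.items():
                se = max(np.sqrt(p * (1 - p) / total), 1e-9)
                assert abs(obs.fractions[aa][codon] - p) < 4 * se


class TestComplementarity:
    def test_worked_example(self):
        cc = counts_of(AAT=10, ATT=20, CGA=100)
        assert cl.complementarity_index(cc) == pytest.approx(10 / 130, abs=1e-9)

    def test_unpaired_codon_scores_zero(self):
        assert cl.complementarity_index(counts_of(AAA=5)) == 0.0

    def test_min_rule(self):
        assert cl.complementarity_index(counts_of(GAC=4, GTC=6)) == pytest.approx(0.4)

    def test_empty_counts_rejected(self):
        with pytest.raises(EmptyInputError):
            cl.complementarity_index(CodonCounts({}, 0, 0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 200), st.integers(0, 200), st.integers(1, 50))
    def test_invariant_under_partner_swap(self, a, b, c):
        """Swapping the counts of a codon and its reverse complement leaves
        the index unchanged."""
        x = cl.complementarity_index(counts_of(AAT=a, ATT=b, CGA=c))
        y = cl.complementarity_index(counts_of(AAT=b, ATT=a, CGA=c))
        assert x == pytest.approx(y, abs=1e-12)


class TestPeriodicity:
    def test_homopolymer_is_aperiodic(self):
        assert cl.periodicity_index(counts_of(AAA=7)) == pytest.approx(0.0)

    def test_forced_arithmetic_single_codon(self):
        assert cl.periodicity_index(counts_of(GAT=3)) == pytest.approx(2 / 3)

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_nonnegative_and_order_free(self, small_genome):
        from codonlens.null_models import shuffle_codons_within_cds

        gene = small_genome.genes[0]
        pi_native = cl.periodicity_index(cl.count_codons(gene))
        pi_shuffled = cl.periodicity_index(
            cl.count_codons(shuffle_codons_within_cds(gene, 5))
        )
        assert pi_native >= 0
        assert pi_shuffled == pytest.approx(pi_native, abs=1e-12)


class TestBiasIndices:
    @staticmethod
    def reference():
        # a reference pool that prefers GCT (Ala) and AAG (Lys), etc.
        return cl.synonymous_fractions(
            counts_of(GCT=90, GCA=5, GCC=3, GCG=2, AAG=80, AAA=20, TTT=10, TTC=90,
                      CTG=50, CTA=10, CTC=10, CTT=10, TTA=10, TTG=10,
                      ATT=60, ATC=30, ATA=10, GTT=70, GTA=10, GTC=10, GTG=10,
                      TCT=50, TCA=10, TCC=10, TCG=10, AGT=10, AGC=10,
                      CCA=70, CCC=10, CCG=10, CCT=10, ACT=60, ACA=10, ACC=20, ACG=10,
                      TAT=20, TAC=80, CAT=20, CAC=80, CAA=80, CAG=20,
                      AAT=20, AAC=80, GAT=30, GAC=70, GAA=80, GAG=20,
                      TGT=70, TGC=30, CGT=40, CGA=10, CGC=10, CGG=10, AGA=20, AGG=10,
                      GGT=70, GGA=10, GGC=10, GGG=10)
        )

    def test_all_major_gene_maxes_cai_and_fop(self):
        gene = counts_of(GCT=30, AAG=20, TTC=10)
        idx = cl.bias_indices(gene, self.reference())
        assert idx.cai == pytest.approx(1.0)
        assert idx.fop == pytest.approx(1.0)
        assert idx.cbi == pytest.approx(1.0)

    def test_nc_uniform_usage_near_61(self):
        """Wright's closed form: F_k = 1/k under uniform synonymous usage,
        so Nc → 61; a 10,000-codon draw stays in [55, 61]."""
        rng = np.random.default_rng(0)
        sense = [c for c in CODONS if cl.STANDARD_CODE.codon_to_aa[c] != "*"]
        draw = rng.choice(sense, size=10_000)
        vec = np.zeros(64, dtype=np.int64)
        for c in draw:
            vec[CODONS.index(c)] += 1
        nc = cl.effective_number_of_codons(CodonCounts.from_vector(vec))
        assert 55 <= nc <= 61

    def test_nc_single_codon_per_amino_acid_is_20(self):
        one_per_aa = {fam[0]: 50 for aa, fam in cl.STANDARD_CODE.families.items() if aa != "*"}
        assert cl.effective_number_of_codons(counts_of(**one_per_aa)) == pytest.approx(20.0)

    def test_empty_gene_rejected(self):
        with pytest.raises(EmptyInputError):
            cl.bias_indices(counts_of(ATG=3), self.reference())


class TestExpectedFractionsFromGC:
    def test_symmetric_at_half(self):
        fr = cl.expected_fractions_from_gc(0.5)
        for aa, fam in fr.fractions.items():
            vals = list(fam.values())
            assert all(v == pytest.approx(vals[0]) for v in vals)

    def test_glu_family_at_gc_06(self):
        fam = cl.expected_fractions_from_gc(0.6).family("E")
        assert fam["GAA"] == pytest.approx(0.4)
        assert fam["GAG"] == pytest.approx(0.6)

    @pytest.mark.parametrize("gc", [0.0, 1.0, -0.2, 1.5])
    def test_domain_error(self, gc):
        with pytest.raises(DomainError):
            cl.expected_fractions_from_gc(gc)

    def test_simulation_oracle_gc_035(self):
        """Empirical synonymous fractions of codons drawn from independent
        bases at GC = 0.35 match the closed form within sampling error."""
        rng = np.random.default_rng(42)
        gc = 0.35
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        n = 300_000
        bases = rng.choice(4, size=(n, 3), p=p)
        ids = bases[:, 0] * 16 + bases[:, 1] * 4 + bases[:, 2]
        vec = np.bincount(ids, minlength=64)
        obs = cl.synonymous_fractions(CodonCounts.from_vector(vec))
        exp = cl.expected_fractions_from_gc(gc)
        for aa, fam in exp.fractions.items():
            total = sum(vec[CODONS.index(c)] for c in fam)
            for codon, pexp in fam.items():
                se = max(np.sqrt(pexp * (1 - pexp) / total), 1e-9)
                assert abs(obs.fractions[aa][codon] - pexp) < 3.5 * se


class TestPairing:
    def test_watson_crick(self):
        assert cl.classify_pairing("GGC", "GCC") is cl.PairingClass.WATSON_CRICK

    def test_wobble_ug(self):
        assert cl.classify_pairing("GGT", "GCC") is cl.PairingClass.WOBBLE

    def test_no_pairing(self):
        assert cl.classify_pairing("GGA", "GCC") is cl.PairingClass.NONE

    def test_rna_alphabet_accepted(self):
        assert cl.classify_pairing("GGU", "GCC") is cl.PairingClass.WOBBLE

    def test_malformed_rejected(self):
        with pytest.raises(DomainError):
            cl.classify_pairing("GG", "GCC")

    def test_exactly_one_wc_anticodon_per_codon(self):
        from itertools import product

        for codon in CODONS:
            wc = [
                "".join(ac)
                for ac in product("ACGT", repeat=3)
                if cl.classify_pairing(codon, "".join(ac)) is cl.PairingClass.WATSON_CRICK
            ]
            assert wc == [cl.revcomp(codon)]


class TestMajorCodonTable:
    def test_alanine_major(self):
        table = cl.major_codon_table(
            counts_of(GCT=90, GCA=5, GCC=3, GCG=2, **{c: 1 for c in CODONS
                      if cl.STANDARD_CODE.codon_to_aa[c] not in ("A",)})
        )
        assert table.majors["A"] == "GCT"

    def test_stop_major(self):
        table = cl.major_codon_table(
            counts_of(TAA=98, TAG=1, TGA=1, **{c: 1 for c in CODONS
                      if cl.STANDARD_CODE.codon_to_aa[c] != "*"})
        )
        assert table.majors["*"] == "TAA"

    def test_tie_breaks_alphabetically_and_flags(self):
        table = cl.major_codon_table(
            counts_of(GCT=5, GCA=5, **{c: 1 for c in CODONS
                      if cl.STANDARD_CODE.codon_to_aa[c] != "A"})
        )
        assert table.majors["A"] == "GCA"
        assert "A" in table.ties

    def test_missing_family_raises(self):
        with pytest.raises(MissingFamilyError):
            cl.major_codon_table(counts_of(GCT=5))


def test_gc_contents():
    cc = counts_of(GCG=10)  # G,C,G at the three positions
    assert gc_content(cc) == pytest.approx(1.0)
    assert gc3_content(cc) == pytest.approx(1.0)
    cc = counts_of(GAT=10)
    assert gc3_content(cc) == pytest.approx(0.0)


def test_codon_ids_roundtrip():
    from codonlens.code_core import ids_to_cds

    cds = "ATGGCTTGGTAA"
    assert ids_to_cds(codon_ids(cds)) == cds
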