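"""The four sequence randomizers, the Z-score machinery and the
random-major-codon complementarity test."""

import numpy as np
import pytest
from Bio.Seq import Seq

import codonlens as cl
from codonlens.code_core import CODONS, CodonCounts
from codonlens.exceptions import DegenerateNullError, DomainError, MissingFamilyError
from codonlens.null_models import (
    enumerate_major_codon_null,
    equalize_synonymous_frequencies,
    exchange_synonymous_identities,
    gene_rng,
    pars_spread_null,
    random_major_codon_null,
    shuffle_codons_within_cds,
    simulate_neutral_genome,
    zscore_vs_null,
)


def protein(gene):
    return str(Seq(gene.cds).translate())


def fractions_of(**kw):
    vec = np.zeros(64, dtype=np.int64)
    for codon, n in kw.items():
        vec[CODONS.index(codon)] = n
    return cl.synonymous_fractions(CodonCounts.from_vector(vec))


class TestNeutralGenome:
    def test_deterministic_family_fraction(self):
        genes = [cl.GeneRecord("g", "GCAGCCGCGGCT" * 3 + "ATGTAA")]
        fr = fractions_of(GCT=10, ATG=1, TAA=1)
        sim = simulate_neutral_genome(genes, fr, seed=1)
        assert sim[0].cds == "GCT" * 12 + "ATGTAA"

    def test_met_trp_sites_fixed(self):
        genes = [cl.GeneRecord("g", "ATGTGGATGTAA")]
        fr = fractions_of(ATG=1, TGG=1, TAA=1)
        sim = simulate_neutral_genome(genes, fr, seed=9)
        assert sim[0].cds == genes[0].cds

    def test_missing_family_rejected(self):
        genes = [cl.GeneRecord("g", "GCTTAA")]
        with pytest.raises(MissingFamilyError):
            simulate_neutral_genome(genes, fractions_of(ATG=1, TAA=1), seed=0)

    def test_preserves_protein_and_is_order_independent(self, small_genome):
        g = small_genome
        fr = cl.synonymous_fractions(cl.pool_counts(g.genes))
        subset = g.genes[:15]
        sim = simulate_neutral_genome(subset, fr, seed=4)
        assert [protein(a) for a in subset] == [protein(b) for b in sim]
        sim_rev = simulate_neutral_genome(list(reversed(subset)), fr, seed=4)
        assert {x.id: x.cds for x in sim} == {x.id: x.cds for x in sim_rev}

    def test_sampling_matches_global_fractions(self, small_null_genome):
        """Pooled codon fractions of a large simulated genome match the
        generating fractions within binomial sampling error."""
        g = small_null_genome
        fr = cl.synonymous_fractions(cl.pool_counts(g.genes))
        sim = simulate_neutral_genome(g.genes[:200], fr, seed=8)
        pooled = cl.pool_counts(sim)
        obs = cl.synonymous_fractions(pooled)
        for aa, fam in fr.fractions.items():
            total = sum(pooled.counts.get(c, 0) for c in fam)
            if total < 200:
                continue
            for codon, p in fam.items():
                se = max(np.sqrt(p * (1 - p) / total), 1e-9)
                assert abs(obs.fractions[aa][codon] - p) < 4 * se


class TestZScore:
    def test_native_at_null_mean(self):
        assert zscore_vs_null(5.0, [4.0, 5.0, 6.0]) == pytest.approx(0.0)

    def test_two_sd_above(self):
        reps = np.array([1.0, 2.0, 3.0])
        native = reps.mean() + 2 * reps.std(ddof=1)
        assert zscore_vs_null(native, reps) == pytest.approx(2.0)

    def test_degenerate_null_rejected(self):
        with pytest.raises(DegenerateNullError):
            zscore_vs_null(1.0, [2.0, 2.0, 2.0])
        with pytest.raises(DegenerateNullError):
            zscore_vs_null(1.0, [2.0])

    def test_null_draw_rarely_extreme(self):
        """A statistic that is itself one more draw from the null should
        almost always fall within |Z| < 4."""
        rng = np.random.default_rng(17)
        extreme = 0
        trials = 400
        for _ in range(trials):
            draws = rng.normal(size=41)
            z = zscore_vs_null(draws[0], draws[1:])
            extreme += abs(z) >= 4
        assert extreme / trials < 0.01


class TestShuffle:
    def test_single_codon_type_unchanged(self):
        gene = cl.GeneRecord("g", "GCT" * 10)
        assert shuffle_codons_within_cds(gene, 3).cds == gene.cds

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_counts_preserved(self, small_genome):
        gene = small_genome.genes[0]
        before = cl.count_codons(gene).counts
        after = cl.count_codons(shuffle_codons_within_cds(gene, 21)).counts
        assert before == after

    def test_reproducible(self):
        gene = cl.GeneRecord("g", "GCTAAATTGCCC")
        assert (
            shuffle_codons_within_cds(gene, 5).cds
            == shuffle_codons_within_cds(gene, 5).cds
        )

    def test_permutation_uniformity(self):
        """All 6 orders of a 3-codon gene appear with frequency 1/6."""
        gene = cl.GeneRecord("g", "GCTAAATTG")
        from collections import Counter

        tally = Counter(
            shuffle_codons_within_cds(gene, seed).cds for seed in range(10_000)
        )
        assert len(tally) == 6
        se = np.sqrt((1 / 6) * (5 / 6) / 10_000)
        for count in tally.values():
            assert abs(count / 10_000 - 1 / 6) < 3.5 * se


class TestEqualize:
    def test_divisible_counts_become_uniform(self):
        gene = cl.GeneRecord("g", "GCT" * 4)
        out = equalize_synonymous_frequencies(gene, 2)
        counts = cl.count_codons(out).counts
        assert counts == {"GCA": 1, "GCC": 1, "GCG": 1, "GCT": 1}

    def test_remainder_rule_flagged(self):
        gene = cl.GeneRecord("g", "AAA" * 5)  # Lys: AAA/AAG, 5 sites
        out, flags = equalize_synonymous_frequencies(gene, 7, with_flags=True)
        counts = cl.count_codons(out).counts
        assert sorted(counts.values()) == [2, 3]
        assert "K" in flags

    def test_preserves_protein(self, small_genome):
        for gene in small_genome.genes[:10]:
            assert protein(equalize_synonymous_frequencies(gene, 13)) == protein(gene)


class TestExchange:
    def test_fraction_multisets_preserved_per_gene(self, small_genome):
        genes = small_genome.genes[:10]
        result = exchange_synonymous_identities(genes, 3, n_draws=2, keep_genomes=True)
        for genome in result.genomes:
            for native, exchanged in zip(genes, genome):
                f0 = cl.synonymous_fractions(cl.count_codons(native))
                f1 = cl.synonymous_fractions(cl.count_codons(exchanged))
                for aa in f0.fractions:
                    assert sorted(f0.fractions[aa].values()) == pytest.approx(
                        sorted(f1.fractions[aa].values())
                    )

    def test_nc_invariant_under_exchange(self, small_genome):
        genes = small_genome.genes[:5]
        result = exchange_synonymous_identities(genes, 3, n_draws=1, keep_genomes=True)
        for native, exchanged in zip(genes, result.genomes[0]):
            assert cl.effective_number_of_codons(
                cl.count_codons(exchanged)
            ) == pytest.approx(
                cl.effective_number_of_codons(cl.count_codons(native)), abs=1e-9
            )

    def test_protein_preserved(self, small_genome):
        genes = small_genome.genes[:5]
        result = exchange_synonymous_identities(genes, 5, n_draws=2, keep_genomes=True)
        for genome in result.genomes:
            assert [protein(a) for a in genes] == [protein(b) for b in genome]

    def test_native_majors_raise_complementarity_vs_exchange(self, small_genome):
        """The generator's major set contains five complementary pairs, so
        the native complementarity of highly biased genes exceeds the
        identity-exchange average."""
        g = small_genome
        biased = [
            gene for gene in g.genes if g.truth.selection_weight[gene.id] > 0.6
        ][:40]
        assert len(biased) >= 5
        result = exchange_synonymous_identities(biased, 11, n_draws=20)
        native = np.array(
            [cl.complementarity_index(cl.count_codons(x)) for x in biased]
        )
        exchanged = result.per_gene_stats["complementarity"].to_numpy()
        assert native.mean() > exchanged.mean()


class TestMajorCodonNull:
    def test_observed_zero_gives_p_one(self):
        assert random_major_codon_null(0, n_reps=100, seed=1).p_value == 1.0

    def test_counts_always_even(self):
        res = random_major_codon_null(10, n_reps=5000, seed=2)
        assert np.all(res.null_counts % 2 == 0)

    def test_reproducible(self):
        a = random_major_codon_null(10, n_reps=2000, seed=3)
        b = random_major_codon_null(10, n_reps=2000, seed=3)
        assert a.p_value == b.p_value

    def test_invalid_inputs(self):
        with pytest.raises(DomainError):
            random_major_codon_null(10, n_reps=0, seed=1)
        with pytest.raises(DomainError):
            random_major_codon_null(19, n_reps=10, seed=1)

    def test_monte_carlo_matches_enumeration_on_toy_code(self):
        """On a 3-family toy code (Lys, Phe, Glu — whose codons can pair
        AAA/TTT and AAG/CTT is absent, GAA/TTC) Monte-Carlo tail
        probabilities match exact enumeration within sampling error."""
        families = [
            cl.STANDARD_CODE.families["K"],  # AAA, AAG
            cl.STANDARD_CODE.families["F"],  # TTT, TTC
            cl.STANDARD_CODE.families["E"],  # GAA, GAG
        ]
        exact = enumerate_major_codon_null(families)
        for observed in (1, 2, 3):
            p_exact = float(exact[observed:].sum())
            res = random_major_codon_null(
                observed, n_reps=20_000, seed=5, families=families
            )
            se = np.sqrt(max(p_exact * (1 - p_exact), 1e-6) / 20_000)
            assert abs(res.p_value - p_exact) < 3 * se


class TestParsSpreadNull:
    def test_shuffle_null_collapses_spread(self, small_genome):
        g = small_genome
        result = pars_spread_null(g.genes, g.pars_profiles, n_reps=50, seed=6)
        assert result.native > result.replicates.mean()
        assert result.z_score > 5

    def test_reproducible(self, small_genome):
        g = small_genome
        a = pars_spread_null(g.genes, g.pars_profiles[:40], n_reps=10, seed=7)
        b = pars_spread_null(g.genes, g.pars_profiles[:40], n_reps=10, seed=7)
        np.testing.assert_array_equal(a.replicates, b.replicates)


def test_gene_rng_streams_differ_by_gene_and_seed():
    a = gene_rng(1, "geneA").integers(0, 2**31)
    b = gene_rng(1, "geneB").integers(0, 2**31)
    c = gene_rng(2, "geneA").integers(0, 2**31)
    assert len({a, b, c}) == 3
    assert gene_rng(1, "geneA").integers(0, 2**31) == a
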