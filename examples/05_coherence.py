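"""Coherence of codon-fraction trajectories across gene properties.

Genes are binned (20 equal-width bins, 0.25% trimmed per tail) along two
properties; per codon, the two 20-point fraction trajectories are
correlated.  Expression and PARS mean move codon usage the same way
(positively coherent); complementarity moves it the opposite way.
"""

import codonlens as cl

genome = cl.generate_genome(cl.SyntheticGenomeConfig(), seed=1)

pars_mean = {p.gene_id: float(p.scores.mean()) for p in genome.pars_profiles}
rep = cl.coherence(genome.genes, genome.expression, pars_mean, "mrna", "pars")
print(f"mrna vs pars: {rep.call} ({int(rep.table.significant.sum())} significant codons)")

compl = {g.id: cl.complementarity_index(cl.count_codons(g)) for g in genome.genes}
rep2 = cl.coherence(genome.genes, genome.expression, compl, "mrna", "complementarity")
print(
    f"mrna vs complementarity: {rep2.call} "
    f"({int(rep2.table.significant.sum())} significant codons)"
)

print("\nper-codon R for a few codons (mrna vs pars):")
print(rep.table.dropna(subset=["r"]).head(6)[["r", "p", "n_bins"]].round(3).to_string())
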