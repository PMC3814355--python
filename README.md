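# codonlens

Dissecting codon usage bias into its mutational and
transcriptional/structural components.

Synonymous codons encoding the same amino acid are used unequally ("codon
bias"). In budding yeast, part of this bias is neutral — set by the
mutational GC content of the genome — and part follows the expression level
of each gene, with the preferred ("major") codons of highly transcribed
genes tracking mRNA secondary structure rather than tRNA availability
alone. `codonlens` is a library (plus a thin CLI) for taking that question
apart quantitatively:

- **Sequence-intrinsic indices** — codon counting, within-family synonymous
  fractions, the codon **complementarity index** (fraction of codons in
  reverse-complement couples, min-count pairing rule), the **three-base
  periodicity index** Pi = ⅓ Σ_b Σ_p (f(b,p) − f̄(b))², and the standard
  bias indices CAI, Fop, CBI and Wright's N_c.
- **Expression linkage** — per-codon mean log2 transcript level,
  back-calculation of gene levels from codon composition, the three
  expression classes (breakpoints 0.5 and 32 mRNA/cell), stop-codon usage
  trajectories, and the mutational-contribution estimator
  x_i = (1 − fw_i)/(1 − fl_i) over the nine 2-fold degenerate families
  (fw, fl = major-codon fractions genome-wide and in lowly transcribed
  genes).
- **Structure linkage** — PARS-gene / PARS-nucleotide codon scores from
  per-nucleotide double-strandedness profiles, base-composition PARS
  prediction, predicted transcript PARS, and intron folding-ΔG correlation
  analysis (ΔG consumed as precomputed input).
- **Null models** — four seeded randomizers (neutral genomes drawn from
  genome-wide synonymous fractions, within-CDS codon shuffling, synonymous
  frequency equalization, genome-wide synonymous identity exchange), the
  Z-score machinery, and the random-major-codon complementarity test.
- **Binning / coherence** — 0.25%-per-tail trimming, 20 equal-width bins
  over any per-gene scalar, pooled per-bin synonymous fractions, and
  per-codon Pearson correlation of trajectories between two properties
  ("positively/negatively coherent" calls).
- **Synthetic genomes** — a ground-truth generator emulating a yeast-like
  genome (log-normal expression, GC-driven usage shifting linearly toward
  majors between the two breakpoints, structure scores rising with
  expression, expression-linked intron lengths and ΔG, wobble-aware tRNA
  copies), so every estimator can be scored against what the generator did.

## Worked example

```python
import codonlens as cl

genome = cl.generate_genome(cl.SyntheticGenomeConfig(), seed=1)

profile = cl.codon_expression_profile(genome.genes, genome.expression)
back = cl.back_calculate_expression(genome.genes, profile, genome.expression)
print(f"back-calculation R = {back.r_pearson:.2f}")

est = cl.estimate_mutational_contribution(
    genome.genes, genome.expression, genome.truth.major_table
)
print(f"mutational share = {est.mean_x:.3f} (truth {genome.truth.mutational_share:.3f})")
```

prints

```
back-calculation R = 0.85
mutational share = 0.855 (truth 0.855)
```

meaning: gene expression levels re-estimated purely from each gene's codon
composition correlate at R = 0.85 with the true levels, and the 2-fold-family
estimator recovers the generator's mutational share of codon bias to three
decimals. The `examples/` directory has one short narrative script per
capability (indices, expression link, PARS structure, null models,
coherence); each prints the numbers it computes and a line on what they
mean. The same operations are exposed as `codonlens` CLI subcommands
(`indices`, `profile`, `backcalc`, `classes`, `contribution`, `pars`,
`introns`, `simulate …`, `coherence`, `windows`, `synth`), each emitting a
JSON run manifest.

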