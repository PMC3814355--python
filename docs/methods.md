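# Methods

## The question the package operationalizes

Codon usage bias in a compact eukaryotic genome can be decomposed into a
neutral component — shared by all genes and set by mutational GC pressure —
and a selective component that scales with transcription and tracks mRNA
secondary structure. `codonlens` implements the statistics and simulations
needed to make that decomposition measurable: sequence-intrinsic codon
indices, codon-level expression and structure profiles, randomization null
models, and a binning/coherence framework, all exercisable end to end on
synthetic genomes with known ground truth.

## Statistics and their definitions

**Codon counting.** Frame 0 only, no internal-stop scanning: an annotated
CDS is taken as given, and an internal stop is counted as-is with a
warning. Codons containing any non-ACGT letter are skipped and tallied
separately, never silently counted. The terminal stop belongs to the stop
family {TAA, TAG, TGA} and is excluded from all sense-family statistics and
bias indices; stop codons are analyzed as their own 3-member family.

**Complementarity index.** For each unordered codon pair {c, revcomp(c)},
min(count(c), count(revcomp(c))) couples form; the index is the couple
count divided by the total codon count. No trinucleotide is its own reverse
complement, so there is no self-pair case. The index depends only on
counts, is invariant under swapping a codon's count with its partner's, and
{AAT:10, ATT:20, CGA:100} → 10/130 ≈ 0.077.

**Three-base periodicity (Pi).** With f(b,p) the frequency of base b at
codon position p (computed from codon frequencies, hence order-invariant)
and f̄(b) its mean over the three positions,
Pi = ⅓ Σ_b Σ_p (f(b,p) − f̄(b))². Pi = 0 iff positional base composition is
identical across positions. The original literature formula for Pi is not
printed in full anywhere we could consume it; this positional-deviation
form satisfies the same qualitative contract and is isolated behind a
single function so it can be swapped without touching anything else.

**Bias indices.** CAI is the geometric mean of relative-adaptiveness
weights w = f/f_max (from a highly expressed reference pool) over the
codons of degenerate sense families; Met, Trp and stops are excluded, and w
is floored at 0.01 when a reference fraction is zero (standard practice,
avoids log 0). Fop is the fraction of those codons that are the family
major; CBI is the Bennetzen–Hall excess of majors over random expectation
(it can go slightly negative for genes avoiding majors; it is reported
unclamped). N_c is Wright's estimator: per family with n ≥ 2,
F = (nΣp² − 1)/(n − 1); class means over the 2-/3-/4-/6-fold families enter
N_c = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, capped at 61. An unobservable
3-fold class borrows (F̄₂ + F̄₄)/2 (Wright's rule); any other missing class
borrows the mean of observable class means. Uniform synonymous usage gives
N_c → 61, one codon per amino acid gives exactly 20.

**GC-expected fractions.** Under independent nucleotides with
P(G) = P(C) = gc/2, each codon's probability is the product of its three
base probabilities, renormalized within its family. This is both the
neutral reference for real analyses and the mutational component of the
synthetic generator, which is why the selection-off recovery test can
demand agreement at binomial precision.

**Codon–anticodon pairing.** Watson–Crick iff the anticodon equals the
reverse complement of the codon; wobble iff codon positions 1–2 pair WC
with anticodon positions 3–2 and the codon-3:anticodon-1 pair is U:G or
G:U. Inosine and modified bases are not modeled; the analyses only reason
from G:U/U:G.

**Expression linkage.** Each codon occurrence inherits the log2 mRNA level
of its host gene; per-codon means over all occurrences form the profile,
and a gene's back-calculated level is the mean profile value of its codons
(a convex combination of profile means, which is itself a useful
invariant). Classes: level ≤ 0.5 mRNA/cell is "low" (the boundary is read
low-inclusive), ≤ 32 "moderate", above "high". The mutational-contribution
estimator uses the nine 2-fold families: x_i = (1 − fw_i)/(1 − fl_i), the
unique linear form with x = 1 when genome-wide major-codon fraction equals
the lowly transcribed baseline and x = 0 when the major has fixed. The
major codon is fixed once from the highly expressed pool so fw and fl refer
to the same codon; x outside [0, 1] (selection opposing mutation) is
clamped and flagged. On the generator's mixture model the estimator's
expectation is exactly 1 − s̄ (the codon-weighted mean selection weight),
which is what the recovery test asserts.

**Structure linkage.** PARS-gene assigns every codon occurrence its host
transcript's mean score; PARS-nucleotide assigns the mean of its own three
nucleotides. Spread is the population s.d. over codon types observed at
least once, unweighted by occurrence count (the weighting convention is not
externally fixed; unweighted-over-codons is adopted and documented).
Profiles must match CDS length exactly — UTR-trimmed data are rejected, not
padded, because alignment is the caller's responsibility. Intron ΔG values
are consumed as precomputed inputs (any folder can produce them); the
package only correlates them (Pearson and Spearman, two-sided p, pairwise
intersection of ids).

**Null models.** All four randomizers draw per-gene random streams from
(run seed, CRC32(gene id)), so results are bit-reproducible and independent
of gene order. Neutral genomes redraw every synonymous site from
genome-wide fractions; equalization makes within-family counts differ by at
most one, assigning remainder sites to random family members (flagged);
identity exchange applies one random permutation per family uniformly to
all genes and averages requested statistics over 20 draws. Codon shuffling
permutes codon order within each CDS (Fisher–Yates); it preserves the codon
and residue multisets but, by construction, not the residue order — the
other three preserve the translated sequence exactly, and the tests assert
exactly that split. The random-major-codon test draws one codon per
degenerate family uniformly and counts chosen codons whose reverse
complement is also chosen (always even); the Monte-Carlo tail is
cross-checked against exact enumeration on a 3-family toy code.

**Binning and coherence.** Outlier trimming removes floor(0.0025·n) items
per tail (the trim convention is per-tail with floor). Bins are 20
equal-width intervals over the retained range — equal-width, not
equal-count, and the right edge of the last bin is inclusive. Fractions are
pooled per bin (not averaged per gene). Coherence correlates, per codon,
the two 20-point fraction trajectories; significance is a two-sided t-test
on R at α = 0.05, codons with fewer than 50 pooled occurrences under either
property are excluded, and the call is "positively (negatively) coherent"
only when every significant codon agrees in sign. Windowed intragene bias
splits a gene's codons into contiguous near-equal blocks (remainders to the
earliest windows); the equal-block scheme is a documented stand-in, as no
external windowing protocol was available to match.

## The synthetic generator

The generator produces the conditions the analyses assume, with every
hidden parameter recorded:

- **Expression**: log2 level ~ N(−0.8, 2.2) (mRNA/cell log-normal). With
  these defaults ≈46% of genes sit at ≤0.5 mRNA/cell and ≈0.5% above 32,
  a yeast-like partition.
- **Selection weight** s: 0 up to 0.5 mRNA/cell, linear in log2 level to
  s_max = 0.9 at 32, saturating above — the simplest form matching a
  three-regime description (flat / linear-in-log / saturated).
- **Codon choice**: at each synonymous site, the family major with
  probability s, otherwise a draw from the GC(0.38)-expected fractions.
  Stops use the same mixture with TAA as major.
- **Majors**: yeast-like preferences in which exactly ten of the eighteen
  majors form five reverse-complement pairs, so complementarity-of-majors
  analyses are exercisable.
- **Structure**: per-nucleotide PARS = base mean (A 0.034, C 0.844,
  G 0.026, T 0.540) + 0.05·log2(level) + N(0, 0.3), for a random ≈47%
  subset of genes (≈3000 at default size, matching the scale of real
  transcriptome structure-probing sets).
- **Introns**: ≈5% of genes; length = 150 + 20·log2(level) + N(0, 20)
  (min 30 nt); ΔG = −0.30·length + N(0, 5) kcal/mol.
- **Protein**: level^1.3 with log-normal noise, so protein/mRNA rises with
  expression.
- **tRNA**: one anticodon per family decoding its major (Watson–Crick, or
  wobble for TGT and GGT, whose WC anticodons are absent from the pool),
  copies proportional to amino-acid usage.
- **Sizes**: 6400 genes, mean 300 codons (log-normal, min 40). Default
  gene count and the PARS/intron subset sizes mirror the genome scale the
  analyses are meant for while keeping the full property suite (three
  seeds) in a few minutes on one CPU.

What the generator does **not** emulate: amino-acid composition variation
across genes (composition is drawn from one fixed pool, uniform over the 18
degenerate families with Met/Trp down-weighted), sequence homology and gene
families, UTRs, measurement error in expression data, real RNA folding
(PARS noise is i.i.d. Gaussian, not thermodynamic), and any
mutation–selection population dynamics. Passing recovery tests therefore
shows the estimators are correct under the stated statistical model, not
that real data satisfy that model.

## Numerical and edge-case conventions

- Families with zero counts are marked absent rather than given fractions;
  per-family fractions sum to 1 within 1e-12 otherwise.
- Major-codon ties break alphabetically and are flagged.
- Correlations on constant vectors are flagged undefined (or raise, where
  the operation's contract requires variation) instead of returning NaN
  silently.
- Z-scores use the sample s.d. (ddof = 1) of the replicate statistics and
  refuse degenerate nulls.
- The neutral-model Z-score check at genome scale uses a pooled vectorized
  sampler (`neutral_profile_replicates`) that draws from the identical
  site-wise null as the per-gene-stream simulator; the per-gene-stream
  version remains the reference implementation for reproducibility and
  order-independence guarantees.
- Seeds: every stochastic entry point takes an explicit integer seed;
  per-gene streams derive from (seed, CRC32 of the gene id).

## Known limitations

- CAI/Fop/CBI depend on the reference pool; with very small highly
  expressed pools many weights hit the 0.01 floor and CAI compresses
  downward. Supply a pooled reference from enough genes.
- The Pi formula is a documented reconstruction (see above); absolute Pi
  values are not comparable to other software without checking conventions.
- N_c for very short windows relies on Wright's missing-class fallbacks and
  is reported as NaN when no family is observable.
- The coherence call uses a strict all-significant-signs-agree rule; a
  single discordant codon with a significant trend flips the call to
  "incoherent", which is conservative by design.
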