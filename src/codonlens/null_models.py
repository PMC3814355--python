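"""Seedable sequence-randomization null models.

Four randomizations, all preserving the translated amino-acid sequence of
every gene: (1) neutral genomes that redraw each synonymous site from
genome-wide fractions, (2) codon shuffling within each CDS, (3) equalization
of synonymous frequencies within each CDS, and (4) genome-wide exchange of
synonymous codon identities.  A fifth simulator tests whether the observed
number of complementary major codons could arise from random major-codon
choice.  Per-gene random streams are derived from (run seed, gene id), so
every result is independent of gene order and bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .code_core import (
    CODON_INDEX,
    CODONS,
    REVCOMP_IDS,
    STANDARD_CODE,
    STOP,
    CodonCounts,
    GeneRecord,
    UsageFractions,
    codon_ids,
)
from .exceptions import DegenerateNullError, DomainError, MissingFamilyError
from .structure import ParsProfile, codon_slots


def gene_rng(seed: int, gene_id: str) -> np.random.Generator:
    """Random stream for one gene, reproducible and order-independent."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(gene_id.encode())])
    )


@dataclass
class SimulationResult:
    """A native statistic against its null replicate distribution."""

    native: float
    replicates: np.ndarray
    z_score: float
    n_reps: int
    seed: int


def zscore_vs_null(native: float, replicates) -> float:
    """Standard score of the native statistic against null replicates:
    (native − mean) / s.d. (sample s.d., ddof = 1)."""
    reps = np.asarray(replicates, dtype=float)
    if reps.size < 2:
        raise DegenerateNullError("need at least two null replicates")
    sd = reps.std(ddof=1)
    if sd == 0:
        raise DegenerateNullError("null distribution has zero spread")
    return float((native - reps.mean()) / sd)


def _family_site_map(ids: np.ndarray) -> dict[str, np.ndarray]:
    """Positions of each synonymous family's sites within a codon-id array."""
    out = {}
    for aa, codons in STANDARD_CODE.families.items():
        member_ids = np.array([CODON_INDEX[c] for c in codons])
        mask = np.isin(ids, member_ids)
        if mask.any():
            out[aa] = np.flatnonzero(mask)
    return out


def _rebuild_cds(original: str, new_ids: np.ndarray) -> str:
    """Reassemble a CDS, keeping the original text of skipped (non-ACGT) codons."""
    parts = []
    for k, cid in enumerate(new_ids):
        parts.append(CODONS[cid] if cid >= 0 else original[3 * k : 3 * k + 3])
    return "".join(parts)


def simulate_neutral_genome(
    genes: list[GeneRecord],
    global_fractions: UsageFractions,
    seed: int,
) -> list[GeneRecord]:
    """Redraw every synonymous site from genome-wide synonymous fractions.

    The amino-acid sequence (including the stop) of every gene is preserved;
    expression and other properties are untouched.  A family present in the
    genes but absent from the fractions raises :class:`MissingFamilyError`.
    """
    out = []
    for gene in genes:
        rng = gene_rng(seed, gene.id)
        ids = codon_ids(gene.cds, gene.id)
        new_ids = ids.copy()
        for aa, sites in _family_site_map(ids).items():
            codons = STANDARD_CODE.families[aa]
            if aa not in global_fractions.fractions:
                raise MissingFamilyError([aa])
            probs = np.array([global_fractions.fractions[aa][c] for c in codons])
            member_ids = np.array([CODON_INDEX[c] for c in codons])
            new_ids[sites] = rng.choice(member_ids, size=sites.size, p=probs)
        out.append(GeneRecord(gene.id, _rebuild_cds(gene.cds, new_ids), dict(gene.properties)))
    return out


def shuffle_codons_within_cds(gene: GeneRecord, seed: int) -> GeneRecord:
    """Uniformly permute the order of a gene's codons (Fisher–Yates)."""
    ids = codon_ids(gene.cds, gene.id)
    rng = gene_rng(seed, gene.id)
    perm = rng.permutation(len(ids))
    original_codons = [gene.cds[3 * k : 3 * k + 3] for k in range(len(ids))]
    return GeneRecord(
        gene.id, "".join(original_codons[p] for p in perm), dict(gene.properties)
    )


def equalize_synonymous_frequencies(
    gene: GeneRecord, seed: int, with_flags: bool = False
):
    """Equalize synonymous codon counts within each family of one CDS.

    Within each family the new counts differ by at most one; sites that the
    remainder cannot fill evenly go to family members chosen at random
    (seeded), and the affected families are reported when ``with_flags``.
    Codon-to-site assignment is a seeded shuffle, so the gene keeps its
    amino-acid sequence but loses within-family bias.
    """
    ids = codon_ids(gene.cds, gene.id)
    rng = gene_rng(seed, gene.id)
    new_ids = ids.copy()
    flagged = []
    for aa, sites in _family_site_map(ids).items():
        codons = STANDARD_CODE.families[aa]
        member_ids = np.array([CODON_INDEX[c] for c in codons])
        base, remainder = divmod(sites.size, len(codons))
        assigned = np.repeat(member_ids, base)
        if remainder:
            assigned = np.concatenate(
                [assigned, rng.choice(member_ids, size=remainder, replace=False)]
            )
            flagged.append(aa)
        rng.shuffle(assigned)
        new_ids[sites] = assigned
    result = GeneRecord(gene.id, _rebuild_cds(gene.cds, new_ids), dict(gene.properties))
    if with_flags:
        return result, tuple(sorted(flagged))
    return result


def _random_family_permutation(
    rng: np.random.Generator, include_stop: bool
) -> np.ndarray:
    """A codon-id permutation acting independently within each synonymous family."""
    perm = np.arange(64)
    families = list(STANDARD_CODE.degenerate_sense_families)
    if include_stop:
        families.append(STOP)
    for aa in families:
        member_ids = np.array([CODON_INDEX[c] for c in STANDARD_CODE.families[aa]])
        perm[member_ids] = rng.permutation(member_ids)
    return perm


@dataclass
class ExchangeResult:
    """Genome-wide synonymous identity exchange, averaged over draws."""

    per_gene_stats: pd.DataFrame  # index gene id; one column per statistic (draw-averaged)
    n_draws: int
    seed: int
    genomes: list[list[GeneRecord]] | None = None


def exchange_synonymous_identities(
    genes: list[GeneRecord],
    seed: int,
    n_draws: int = 20,
    statistics: dict[str, Callable[[CodonCounts], float]] | None = None,
    include_stop: bool = False,
    keep_genomes: bool = False,
) -> ExchangeResult:
    """Randomly exchange synonymous codon identities uniformly across genes.

    Per draw, one uniform random permutation per family is applied
    identically to every gene (e.g. all GGA→GGG, GGC→GGT, ...), preserving
    each gene's within-family fraction multiset.  Requested per-gene count
    statistics are averaged over the draws.
    """
    if statistics is None:
        from .code_core import complementarity_index, periodicity_index

        statistics = {
            "complementarity": complementarity_index,
            "pi": periodicity_index,
        }
    rng = np.random.default_rng(int(seed))
    id_arrays = [codon_ids(g.cds, g.id) for g in genes]
    count_matrix = np.stack(
        [np.bincount(ids[ids >= 0], minlength=64) for ids in id_arrays]
    )
    acc = {name: np.zeros(len(genes)) for name in statistics}
    genomes = [] if keep_genomes else None
    for _ in range(n_draws):
        perm = _random_family_permutation(rng, include_stop)
        permuted = np.zeros_like(count_matrix)
        permuted[:, perm] = count_matrix
        for gi in range(len(genes)):
            cc = CodonCounts.from_vector(permuted[gi], n_skipped=int((id_arrays[gi] < 0).sum()))
            for name, fn in statistics.items():
                acc[name][gi] += fn(cc)
        if keep_genomes:
            genome = []
            for gene, ids in zip(genes, id_arrays):
                new_ids = np.where(ids >= 0, perm[np.maximum(ids, 0)], -1)
                genome.append(
                    GeneRecord(gene.id, _rebuild_cds(gene.cds, new_ids), dict(gene.properties))
                )
            genomes.append(genome)
    table = pd.DataFrame(
        {name: acc[name] / n_draws for name in statistics},
        index=[g.id for g in genes],
    )
    return ExchangeResult(table, n_draws, seed, genomes)


@dataclass
class MajorCodonNullResult:
    """Null distribution of the number of complementary major codons."""

    p_value: float
    null_counts: np.ndarray
    observed: int
    n_reps: int
    seed: int


def random_major_codon_null(
    observed_complementary: int,
    n_reps: int = 100_000,
    seed: int = 0,
    families: Iterable[tuple[str, ...]] | None = None,
) -> MajorCodonNullResult:
    """Monte-Carlo tail probability of the complementary-major-codon count.

    Per replicate, one codon is chosen uniformly from each degenerate sense
    family (the 18 families of the standard code by default); the statistic
    counts chosen codons whose reverse complement is also chosen — it is
    always even, since complementary codons pair up.  The p-value is the
    fraction of replicates with count ≥ observed.
    """
    if n_reps < 1:
        raise DomainError(f"n_reps must be >= 1, got {n_reps}")
    if families is None:
        families = [
            STANDARD_CODE.families[aa] for aa in STANDARD_CODE.degenerate_sense_families
        ]
    fam_ids = [np.array([CODON_INDEX[c] for c in fam]) for fam in families]
    n_fam = len(fam_ids)
    if not 0 <= observed_complementary <= n_fam:
        raise DomainError(
            f"observed count must be in [0, {n_fam}], got {observed_complementary}"
        )
    rng = np.random.default_rng(int(seed))
    chosen = np.empty((n_reps, n_fam), dtype=np.int64)
    for j, ids in enumerate(fam_ids):
        chosen[:, j] = ids[rng.integers(0, len(ids), size=n_reps)]
    present = np.zeros((n_reps, 64), dtype=bool)
    rows = np.repeat(np.arange(n_reps), n_fam)
    present[rows, chosen.ravel()] = True
    partner_present = present[rows, REVCOMP_IDS[chosen.ravel()]].reshape(n_reps, n_fam)
    counts = partner_present.sum(axis=1)
    p = float((counts >= observed_complementary).mean())
    return MajorCodonNullResult(p, counts, observed_complementary, n_reps, int(seed))


def enumerate_major_codon_null(
    families: Iterable[tuple[str, ...]],
) -> np.ndarray:
    """Exact null distribution of the complementary count by brute-force
    enumeration over every combination of one codon per family.  Intended
    for small toy codes; returns P(count = k) for k = 0..n_families."""
    import itertools

    fam_ids = [[CODON_INDEX[c] for c in fam] for fam in families]
    n_fam = len(fam_ids)
    dist = np.zeros(n_fam + 1)
    total = 0
    for combo in itertools.product(*fam_ids):
        chosen = set(combo)
        k = sum(1 for c in combo if int(REVCOMP_IDS[c]) in chosen)
        dist[k] += 1
        total += 1
    return dist / total


def pars_spread_null(
    genes: list[GeneRecord],
    profiles: list[ParsProfile],
    n_reps: int = 1000,
    seed: int = 0,
) -> SimulationResult:
    """Codon-shuffle null for the PARS-nucleotide codon-spread statistic.

    Per replicate, codon order is shuffled independently within each CDS
    (profiles stay fixed) and the population s.d. of the 64 per-codon mean
    PARS-nucleotide scores is recomputed.  Returns the native spread, the
    replicate spreads and the Z-score of native against the null.
    """
    ids, nt_means, _, seg = codon_slots(genes, profiles)
    occ = np.bincount(ids, minlength=64)
    observed = occ > 0
    rng = np.random.default_rng(int(seed))
    reps = np.empty(n_reps)
    for r in range(n_reps):
        # shuffling codons within a CDS == permuting the slot scores within
        # each segment; a single argsort of (segment + U[0,1)) does all genes
        perm = np.argsort(seg + rng.random(seg.size))
        sums = np.bincount(ids, weights=nt_means[perm], minlength=64)
        reps[r] = (sums[observed] / occ[observed]).std()
    native_sums = np.bincount(ids, weights=nt_means, minlength=64)
    native = float((native_sums[observed] / occ[observed]).std())
    return SimulationResult(
        native=native,
        replicates=reps,
        z_score=zscore_vs_null(native, reps),
        n_reps=n_reps,
        seed=int(seed),
    )


def neutral_profile_replicates(
    genes: list[GeneRecord],
    expr: dict[str, float],
    global_fractions: UsageFractions,
    n_reps: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-codon expression-profile means under the neutral model, vectorized.

    Draws every synonymous site from genome-wide fractions (the same null as
    :func:`simulate_neutral_genome`, pooled across genes for speed) and
    recomputes the 64 per-codon mean log2 levels per replicate.  Returns
    (native means, replicate means of shape (n_reps, 64)); codons never
    drawn in a replicate carry NaN.
    """
    site_levels = []
    site_family = []
    native_ids = []
    for gene in genes:
        if gene.id not in expr:
            continue
        ids = codon_ids(gene.cds, gene.id)
        ids = ids[ids >= 0]
        native_ids.append(ids)
        site_levels.append(np.full(ids.size, np.log2(expr[gene.id])))
        site_family.append(ids)
    ids_all = np.concatenate(native_ids)
    levels_all = np.concatenate(site_levels)
    occ = np.bincount(ids_all, minlength=64)
    with np.errstate(invalid="ignore"):
        native = np.where(
            occ > 0, np.bincount(ids_all, weights=levels_all, minlength=64) / np.maximum(occ, 1), np.nan
        )
    rng = np.random.default_rng(int(seed))
    reps = np.full((n_reps, 64), np.nan)
    fam_sites = _family_site_map(ids_all)
    for r in range(n_reps):
        new_ids = ids_all.copy()
        for aa, sites in fam_sites.items():
            codons = STANDARD_CODE.families[aa]
            if aa not in global_fractions.fractions:
                raise MissingFamilyError([aa])
            probs = np.array([global_fractions.fractions[aa][c] for c in codons])
            member_ids = np.array([CODON_INDEX[c] for c in codons])
            new_ids[sites] = member_ids[
                np.searchsorted(np.cumsum(probs), rng.random(sites.size), side="right").clip(0, len(codons) - 1)
            ]
        occ_r = np.bincount(new_ids, minlength=64)
        sums_r = np.bincount(new_ids, weights=levels_all, minlength=64)
        with np.errstate(invalid="ignore"):
            reps[r] = np.where(occ_r > 0, sums_r / np.maximum(occ_r, 1), np.nan)
    return native, reps
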