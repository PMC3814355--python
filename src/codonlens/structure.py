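"""PARS-based structural scoring of codons and intron folding-energy analysis.

PARS assigns every transcript nucleotide a score for its propensity to be
double-stranded.  Two codon-level summaries are derived: PARS-gene (each
codon occurrence inherits the mean score of its host transcript) and
PARS-nucleotide (each occurrence inherits the mean of its own three
nucleotides).  The spread of the 64 per-codon means over codon types is the
statistic of interest — a wide PARS-nucleotide spread relative to a
codon-shuffle null indicates that codon placement tracks local folding
structure.  Intron minimum folding free energies (ΔG, kcal/mol) are consumed
as precomputed inputs and only correlated against gene properties here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .code_core import BASES, CODONS, GeneRecord, codon_ids
from .exceptions import (
    AlignmentError,
    InsufficientDataError,
    MissingScoreError,
)


@dataclass
class ParsProfile:
    """Per-nucleotide double-strandedness scores for one CDS (0-based)."""

    gene_id: str
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)


@dataclass
class CodonParsScores:
    """Per-codon PARS-gene / PARS-nucleotide means and their spreads.

    ``spread_sd_*`` is the population standard deviation over the codon
    types observed at least once (unweighted by occurrence count); codons
    never observed are listed in ``unobserved``.
    """

    pars_gene: np.ndarray  # shape (64,), NaN where unobserved
    pars_nucleotide: np.ndarray
    occurrences: np.ndarray
    spread_sd_gene: float
    spread_sd_nucleotide: float
    unobserved: tuple[str, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "codon": CODONS,
                "pars_gene": self.pars_gene,
                "pars_nucleotide": self.pars_nucleotide,
                "occurrences": self.occurrences,
            }
        )


def codon_slots(
    genes: list[GeneRecord], profiles: list[ParsProfile]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Align profiles to CDSs and flatten to per-codon-slot arrays.

    Returns (codon ids, per-slot 3-nt mean score, per-slot host-gene mean
    score, per-slot gene index).  Slots whose codon contains a non-ACGT
    letter are dropped.  A profile whose length differs from its CDS raises
    :class:`AlignmentError`; profiles without a matching gene are ignored.
    """
    by_id = {g.id: g for g in genes}
    ids_parts, nt_parts, gene_parts, seg_parts = [], [], [], []
    for seg, prof in enumerate(profiles):
        gene = by_id.get(prof.gene_id)
        if gene is None:
            continue
        if len(prof.scores) != len(gene.cds):
            raise AlignmentError(
                f"gene {gene.id!r}: profile length {len(prof.scores)} != CDS length "
                f"{len(gene.cds)}"
            )
        ids = codon_ids(gene.cds, gene.id)
        nt_means = prof.scores.reshape(-1, 3).mean(axis=1)
        keep = ids >= 0
        ids_parts.append(ids[keep])
        nt_parts.append(nt_means[keep])
        gene_parts.append(np.full(keep.sum(), float(prof.scores.mean())))
        seg_parts.append(np.full(keep.sum(), seg, dtype=np.int64))
    if not ids_parts:
        raise InsufficientDataError("no profile matches any supplied gene")
    return (
        np.concatenate(ids_parts),
        np.concatenate(nt_parts),
        np.concatenate(gene_parts),
        np.concatenate(seg_parts),
    )


def _per_codon_means(ids: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    occ = np.bincount(ids, minlength=64)
    sums = np.bincount(ids, weights=values, minlength=64)
    with np.errstate(invalid="ignore"):
        means = np.where(occ > 0, sums / np.maximum(occ, 1), np.nan)
    return means, occ


def spread_sd(per_codon_means: np.ndarray) -> float:
    """Population s.d. of per-codon means over observed codon types."""
    observed = per_codon_means[np.isfinite(per_codon_means)]
    return float(observed.std())


def pars_codon_scores(
    genes: list[GeneRecord], profiles: list[ParsProfile]
) -> CodonParsScores:
    """PARS-gene and PARS-nucleotide means of the 64 codons over a gene set."""
    ids, nt_means, gene_means, _ = codon_slots(genes, profiles)
    pg, occ = _per_codon_means(ids, gene_means)
    pn, _ = _per_codon_means(ids, nt_means)
    unobserved = tuple(CODONS[i] for i in range(64) if occ[i] == 0)
    return CodonParsScores(
        pars_gene=pg,
        pars_nucleotide=pn,
        occurrences=occ,
        spread_sd_gene=spread_sd(pg),
        spread_sd_nucleotide=spread_sd(pn),
        unobserved=unobserved,
    )


@dataclass
class NucleotideParsMeans:
    """Average PARS score of A/C/G/T over all profiled positions, and the
    per-codon score estimated as the mean of its three base means."""

    base_means: dict[str, float]
    estimated_codon_scores: np.ndarray  # shape (64,)
    missing_bases: tuple[str, ...]


def nucleotide_pars_means(
    genes: list[GeneRecord], profiles: list[ParsProfile]
) -> NucleotideParsMeans:
    """Base-composition summary of PARS: per-base mean scores plus the
    composition-only estimate of each codon's PARS-nucleotide score."""
    by_id = {g.id: g for g in genes}
    sums = np.zeros(4)
    counts = np.zeros(4, dtype=np.int64)
    byte_to_base = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(BASES):
        byte_to_base[ord(b)] = i
    matched = False
    for prof in profiles:
        gene = by_id.get(prof.gene_id)
        if gene is None:
            continue
        if len(prof.scores) != len(gene.cds):
            raise AlignmentError(
                f"gene {gene.id!r}: profile length {len(prof.scores)} != CDS length "
                f"{len(gene.cds)}"
            )
        matched = True
        bases = byte_to_base[np.frombuffer(gene.cds.encode("ascii"), dtype=np.uint8)]
        keep = bases < 4
        sums += np.bincount(bases[keep], weights=prof.scores[keep], minlength=4)
        counts += np.bincount(bases[keep], minlength=4)
    if not matched:
        raise InsufficientDataError("no profile matches any supplied gene")
    missing = tuple(BASES[i] for i in range(4) if counts[i] == 0)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    est = np.array(
        [np.mean([means[BASES.index(b)] for b in codon]) for codon in CODONS]
    )
    return NucleotideParsMeans(
        base_means={b: float(means[i]) for i, b in enumerate(BASES)},
        estimated_codon_scores=est,
        missing_bases=missing,
    )


def estimate_codon_pars_from_base_means(base_means: dict[str, float]) -> np.ndarray:
    """Per-codon PARS estimate from externally supplied base means."""
    return np.array(
        [np.mean([base_means[b] for b in codon]) for codon in CODONS]
    )


def predict_transcript_pars(gene: GeneRecord, scores: CodonParsScores) -> float:
    """Expected transcript PARS: mean PARS-nucleotide score of the gene's codons."""
    ids = codon_ids(gene.cds, gene.id)
    ids = ids[ids >= 0]
    uncovered = {CODONS[i] for i in np.unique(ids) if not np.isfinite(scores.pars_nucleotide[i])}
    if uncovered:
        raise MissingScoreError(uncovered)
    return float(scores.pars_nucleotide[ids].mean())


@dataclass
class IntronRecord:
    """One intron: length in nucleotides and precomputed minimum folding
    free energy (kcal/mol, typically ≤ 0)."""

    gene_id: str
    length: int
    delta_g: float
    sequence: str | None = None

    def __post_init__(self):
        if self.sequence is not None and len(self.sequence) != self.length:
            raise AlignmentError(
                f"intron {self.gene_id!r}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )
        if not np.isfinite(self.delta_g):
            raise AlignmentError(f"intron {self.gene_id!r}: non-finite delta_g")


def _paired_correlation(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {
            "pearson_r": np.nan,
            "pearson_p": np.nan,
            "spearman_r": np.nan,
            "spearman_p": np.nan,
            "undefined": True,
        }
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return {
        "pearson_r": float(pr.statistic),
        "pearson_p": float(pr.pvalue),
        "spearman_r": float(sr.statistic),
        "spearman_p": float(sr.pvalue),
        "undefined": False,
    }


def intron_structure_association(
    introns: list[IntronRecord],
    gene_properties: dict[str, dict[str, float]],
) -> pd.DataFrame:
    """Correlate intron ΔG with intron length and with per-gene properties
    (mRNA level, bias indices, CDS length, ...).

    One row per comparison with Pearson and Spearman coefficients, two-sided
    p-values and n, computed on the intersection of gene ids.  Fewer than
    three paired introns raise :class:`InsufficientDataError`; constant
    variables are flagged ``undefined`` rather than raising.
    """
    if len(introns) < 3:
        raise InsufficientDataError(f"need >= 3 introns, got {len(introns)}")
    dg = {i.gene_id: i.delta_g for i in introns}
    length = {i.gene_id: float(i.length) for i in introns}
    comparisons = {"intron_length": length, **gene_properties}
    rows = []
    for name, table in comparisons.items():
        shared = sorted(set(dg) & set(table))
        if len(shared) < 3:
            raise InsufficientDataError(
                f"only {len(shared)} introns share gene ids with property {name!r}"
            )
        x = np.array([dg[g] for g in shared])
        y = np.array([table[g] for g in shared])
        rows.append({"property": name, "n": len(shared), **_paired_correlation(x, y)})
    return pd.DataFrame(rows).set_index("property")
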