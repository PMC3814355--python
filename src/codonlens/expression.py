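"""Linking codon usage to transcript level.

Each codon occurrence inherits the (log2-transformed) mRNA level of its host
gene; averaging over occurrences yields a per-codon transcriptional profile
from which gene levels can be back-calculated.  Genes are partitioned into
lowly / moderately / highly transcribed classes at 0.5 and 32 mRNA molecules
per cell, and the nine 2-fold degenerate families provide a simple estimator
of the mutational share of genome-wide codon bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .code_core import (
    CODONS,
    STANDARD_CODE,
    CodonCounts,
    GeneRecord,
    MajorCodonTable,
    codon_ids,
    pool_counts,
    synonymous_fractions,
)
from .exceptions import (
    CorrelationUndefinedError,
    DomainError,
    EmptyJoinError,
    MissingScoreError,
)

ExpressionTable = dict[str, float]


@dataclass(frozen=True)
class ExpressionClassScheme:
    """Breakpoints separating lowly, moderately and highly transcribed genes
    (mRNA molecules per cell).  A level equal to ``low_max`` is low; a level
    equal to ``high_min`` is moderate."""

    low_max: float = 0.5
    high_min: float = 32.0

    def __post_init__(self):
        if not 0 < self.low_max < self.high_min:
            raise DomainError("need 0 < low_max < high_min")

    def label(self, level: float) -> str:
        if level <= self.low_max:
            return "low"
        if level <= self.high_min:
            return "moderate"
        return "high"


@dataclass
class CodonExpressionProfile:
    """Mean log2 transcript level per codon, over all genomic occurrences."""

    mean_log2: np.ndarray  # shape (64,), NaN where a codon never occurs
    occurrences: np.ndarray  # shape (64,), int
    n_genes_used: int
    n_genes_missing: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "codon": CODONS,
                "mean_log2_level": self.mean_log2,
                "occurrences": self.occurrences,
            }
        )


def codon_expression_profile(
    genes: list[GeneRecord], expr: ExpressionTable
) -> CodonExpressionProfile:
    """Average log2 transcript level carried by each of the 64 codons.

    Genes absent from the expression table are excluded and counted in
    ``n_genes_missing``; an empty join raises :class:`EmptyJoinError`.
    """
    level_sum = np.zeros(64)
    occ = np.zeros(64, dtype=np.int64)
    n_used = n_missing = 0
    for gene in genes:
        if gene.id not in expr:
            n_missing += 1
            continue
        log2_level = np.log2(expr[gene.id])
        ids = codon_ids(gene.cds, gene.id)
        vec = np.bincount(ids[ids >= 0], minlength=64)
        level_sum += vec * log2_level
        occ += vec
        n_used += 1
    if n_used == 0:
        raise EmptyJoinError("no gene id shared between gene set and expression table")
    with np.errstate(invalid="ignore"):
        mean = np.where(occ > 0, level_sum / np.maximum(occ, 1), np.nan)
    return CodonExpressionProfile(mean, occ, n_used, n_missing)


@dataclass
class BackCalculation:
    """Gene levels re-estimated from the per-codon expression profile."""

    predicted_log2: dict[str, float]
    r_pearson: float
    n: int


def back_calculate_expression(
    genes: list[GeneRecord],
    profile: CodonExpressionProfile,
    expr: ExpressionTable,
) -> BackCalculation:
    """Predict each gene's log2 level as the mean profile value of its codons
    and correlate the predictions with the measured levels (Pearson, log2)."""
    predicted: dict[str, float] = {}
    for gene in genes:
        ids = codon_ids(gene.cds, gene.id)
        ids = ids[ids >= 0]
        uncovered = {CODONS[i] for i in np.unique(ids) if not np.isfinite(profile.mean_log2[i])}
        if uncovered:
            raise MissingScoreError(uncovered)
        predicted[gene.id] = float(profile.mean_log2[ids].mean())
    shared = [g for g in predicted if g in expr]
    x = np.array([predicted[g] for g in shared])
    y = np.log2([expr[g] for g in shared])
    if len(shared) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CorrelationUndefinedError(
            "back-calculated or measured levels carry no variation"
        )
    r = float(stats.pearsonr(x, y).statistic)
    return BackCalculation(predicted, r, len(shared))


@dataclass
class ExpressionClasses:
    labels: dict[str, str]
    summary: pd.DataFrame  # rows low/moderate/high; shares of codons/genes/transcripts


def classify_genes_by_expression(
    expr: ExpressionTable,
    scheme: ExpressionClassScheme = ExpressionClassScheme(),
    genes: list[GeneRecord] | None = None,
) -> ExpressionClasses:
    """Partition genes into the three transcription classes and summarize
    each class's share of genes, cellular transcripts and (when the gene
    sequences are supplied) codons."""
    labels = {g: scheme.label(level) for g, level in expr.items()}
    order = ["low", "moderate", "high"]
    n_genes = {c: 0 for c in order}
    transcripts = {c: 0.0 for c in order}
    for g, c in labels.items():
        n_genes[c] += 1
        transcripts[c] += expr[g]
    codons = {c: 0 for c in order}
    if genes is not None:
        for gene in genes:
            if gene.id in labels:
                codons[labels[gene.id]] += len(gene.cds) // 3
    total_codons = sum(codons.values())
    summary = pd.DataFrame(
        {
            "share_genes": [100 * n_genes[c] / max(len(labels), 1) for c in order],
            "share_transcripts": [
                100 * transcripts[c] / max(sum(transcripts.values()), 1e-300) for c in order
            ],
            "share_codons": [
                100 * codons[c] / total_codons if total_codons else np.nan for c in order
            ],
        },
        index=order,
    )
    return ExpressionClasses(labels, summary)


@dataclass
class MutationalContributionEstimate:
    """Per 2-fold-family mutational fractions x_i and their mean.

    x_i = (1 − fw_i)/(1 − fl_i) with fw_i, fl_i the major-codon fractions in
    the whole genome and in lowly transcribed genes; x_i = 1 when the
    genome-wide bias equals the lowly-transcribed (mutational) baseline and
    0 when the major codon has taken over completely."""

    table: pd.DataFrame  # index: family aa; columns fw, fl, x, clamped
    mean_x: float


def mutational_contribution(
    fw: dict[str, float], fl: dict[str, float]
) -> MutationalContributionEstimate:
    """Estimate the mutational share of genome-wide codon bias from the nine
    2-fold degenerate families.  Values of x outside [0, 1] (selection
    opposing mutation) are clamped and flagged."""
    families = STANDARD_CODE.twofold_families
    missing = [aa for aa in families if aa not in fw or aa not in fl]
    if missing:
        raise DomainError(f"major-codon fractions missing for families: {missing}")
    rows = []
    for aa in families:
        if fl[aa] >= 1.0:
            raise DomainError(
                f"family {aa}: lowly transcribed genes use only the major codon "
                "(fl = 1); the mutational baseline is degenerate"
            )
        raw = (1.0 - fw[aa]) / (1.0 - fl[aa])
        x = min(max(raw, 0.0), 1.0)
        rows.append({"family": aa, "fw": fw[aa], "fl": fl[aa], "x": x, "clamped": raw != x})
    table = pd.DataFrame(rows).set_index("family")
    return MutationalContributionEstimate(table, float(table["x"].mean()))


def twofold_major_fractions(
    pooled: CodonCounts, majors: MajorCodonTable
) -> dict[str, float]:
    """Major-codon fraction per 2-fold family from pooled codon counts."""
    fractions = synonymous_fractions(pooled)
    out = {}
    for aa in STANDARD_CODE.twofold_families:
        if aa in fractions.fractions:
            out[aa] = fractions.fractions[aa][majors.majors[aa]]
    return out


def estimate_mutational_contribution(
    genes: list[GeneRecord],
    expr: ExpressionTable,
    majors: MajorCodonTable,
    scheme: ExpressionClassScheme = ExpressionClassScheme(),
) -> MutationalContributionEstimate:
    """End-to-end mutational-share estimate: fw from the whole genome, fl
    from the lowly transcribed class, majors fixed by the supplied table so
    both refer to the same codon."""
    whole = pool_counts(genes)
    low_genes = [g for g in genes if g.id in expr and scheme.label(expr[g.id]) == "low"]
    if not low_genes:
        raise EmptyJoinError("no lowly transcribed genes with expression data")
    low = pool_counts(low_genes)
    return mutational_contribution(
        twofold_major_fractions(whole, majors), twofold_major_fractions(low, majors)
    )


def terminal_stop_codon(gene: GeneRecord) -> str | None:
    """The gene's final codon if it is a stop codon, else None."""
    last = gene.cds[-3:].upper()
    return last if last in STANDARD_CODE.stop_codons else None


def stop_codon_usage_by_class(
    genes: list[GeneRecord],
    expr: ExpressionTable,
    scheme: ExpressionClassScheme = ExpressionClassScheme(),
    n_bins: int | None = None,
) -> pd.DataFrame:
    """Fractions of TAA/TAG/TGA among terminal stop codons, per expression
    class (default) or per equal-width log2-level bin (``n_bins``).

    Rows with zero stop codons carry NaN fractions and are flagged by their
    ``n_stops`` column.  Within each populated row the fractions sum to 1.
    """
    stops = STANDARD_CODE.stop_codons
    records = []
    for gene in genes:
        if gene.id not in expr:
            continue
        stop = terminal_stop_codon(gene)
        if stop is None:
            continue
        records.append((np.log2(expr[gene.id]), stop))
    if not records:
        raise EmptyJoinError("no gene with both expression data and a terminal stop")
    levels = np.array([r[0] for r in records])
    stop_arr = np.array([r[1] for r in records])
    if n_bins is None:
        group_labels = np.array([scheme.label(2.0**lv) for lv in levels])
        groups = ["low", "moderate", "high"]
    else:
        edges = np.linspace(levels.min(), levels.max(), n_bins + 1)
        idx = np.clip(np.digitize(levels, edges[1:-1]), 0, n_bins - 1)
        group_labels = idx.astype(str)
        groups = [str(i) for i in range(n_bins)]
    rows = []
    for gname in groups:
        mask = group_labels == gname
        n = int(mask.sum())
        row = {"group": gname, "n_stops": n}
        for s in stops:
            row[s] = float((stop_arr[mask] == s).sum() / n) if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
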