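"""Binned synonymous-fraction trajectories and property-to-property coherence.

Any per-gene scalar (mRNA level, GC-content, PARS mean, complementarity, ...)
can order the genome; after trimming 0.25% of genes per tail, the retained
range is split into 20 equal-width bins and codon counts are pooled per bin.
Two properties are "coherent" when the per-codon fraction trajectories along
the two binnings correlate with a consistent sign across all codons showing
a significant trend.  Windowed intragene bias indices live here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .code_core import (
    CODON_FAMILY_IDS,
    CODON_INDEX,
    CODONS,
    FAMILY_INDEX,
    CodonCounts,
    GeneRecord,
    UsageFractions,
    bias_indices,
    codon_ids,
    complementarity_index,
    periodicity_index,
)
from .exceptions import DegenerateRangeError, DomainError, EmptyJoinError


def trim_outliers(values, fraction: float = 0.0025) -> np.ndarray:
    """Indices of values retained after removing floor(fraction·n) items
    from each tail.  Order of the input does not affect the retained set."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        raise DomainError("cannot trim an empty list")
    k = math.floor(fraction * n)
    if k == 0:
        return np.arange(n)
    order = np.argsort(values, kind="stable")
    return np.sort(order[k : n - k])


def equal_width_bins(values, k: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Assign each value to one of k equal-width bins spanning [min, max].

    The right edge of the last bin is inclusive, so the maximum lands in bin
    k−1.  Constant input raises :class:`DegenerateRangeError`.  Returns
    (assignments, bin centers).
    """
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi <= lo:
        raise DegenerateRangeError("all values identical; equal-width bins undefined")
    edges = np.linspace(lo, hi, k + 1)
    assignment = np.clip(np.digitize(values, edges[1:-1], right=False), 0, k - 1)
    centers = (edges[:-1] + edges[1:]) / 2
    return assignment, centers


@dataclass
class BinnedFractions:
    """Pooled within-family codon fractions along one binned gene property."""

    property_name: str
    bin_centers: np.ndarray  # shape (k,)
    fractions: np.ndarray  # shape (k, 64); NaN where the family has no data
    counts: np.ndarray  # shape (k, 64) pooled codon counts
    gene_count: np.ndarray  # shape (k,)

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)

    def codon_trajectory(self, codon: str) -> np.ndarray:
        return self.fractions[:, CODON_INDEX[codon]]

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fractions, columns=list(CODONS))
        df.insert(0, "bin_center", self.bin_centers)
        df.insert(1, "n_genes", self.gene_count)
        return df


_N_FAMILIES = len(FAMILY_INDEX)


def _family_fractions(counts: np.ndarray) -> np.ndarray:
    """Within-family fractions for a (k, 64) pooled count matrix."""
    fam_totals = np.zeros((counts.shape[0], _N_FAMILIES))
    np.add.at(fam_totals.T, CODON_FAMILY_IDS, counts.T)
    denom = fam_totals[:, CODON_FAMILY_IDS]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, counts / np.maximum(denom, 1), np.nan)


def binned_synonymous_fractions(
    genes: list[GeneRecord],
    prop: dict[str, float],
    property_name: str = "property",
    k: int = 20,
    trim: float = 0.0025,
) -> BinnedFractions:
    """Pool codon counts into k equal-width bins of a gene property and
    convert to within-family fractions per bin."""
    shared = [g for g in genes if g.id in prop]
    if not shared:
        raise EmptyJoinError(f"no gene id shared with property {property_name!r}")
    values = np.array([prop[g.id] for g in shared])
    keep = trim_outliers(values, trim)
    shared = [shared[i] for i in keep]
    values = values[keep]
    assignment, centers = equal_width_bins(values, k)
    counts = np.zeros((k, 64), dtype=np.int64)
    gene_count = np.zeros(k, dtype=np.int64)
    for gene, b in zip(shared, assignment):
        ids = codon_ids(gene.cds, gene.id)
        counts[b] += np.bincount(ids[ids >= 0], minlength=64)
        gene_count[b] += 1
    return BinnedFractions(property_name, centers, _family_fractions(counts), counts, gene_count)


@dataclass
class CoherenceReport:
    """Per-codon correlation of fraction trajectories along two properties.

    ``call`` is "positively coherent" when every codon with a significant
    correlation correlates positively, "negatively coherent" when every one
    correlates negatively, and "incoherent" otherwise (or when nothing is
    significant)."""

    table: pd.DataFrame  # index codon; r, p, n_bins, significant, excluded
    call: str
    property_a: str
    property_b: str


def coherence(
    genes: list[GeneRecord],
    property_a: dict[str, float],
    property_b: dict[str, float],
    name_a: str = "A",
    name_b: str = "B",
    k: int = 20,
    min_count: int = 50,
    alpha: float = 0.05,
) -> CoherenceReport:
    """Compare synonymous-fraction trajectories along two gene properties.

    For each codon, Pearson's R between its 20-bin fraction vector under
    property A and under property B (bins lacking data dropped pairwise);
    codons with fewer than ``min_count`` pooled occurrences under either
    property, or fewer than 3 shared informative bins, are excluded.
    Significance of R is a two-sided t-test at ``alpha``.
    """
    binned_a = binned_synonymous_fractions(genes, property_a, name_a, k)
    binned_b = binned_synonymous_fractions(genes, property_b, name_b, k)
    rows = []
    for ci, codon in enumerate(CODONS):
        total_a = binned_a.counts[:, ci].sum()
        total_b = binned_b.counts[:, ci].sum()
        fa = binned_a.fractions[:, ci]
        fb = binned_b.fractions[:, ci]
        ok = np.isfinite(fa) & np.isfinite(fb)
        excluded = None
        if min(total_a, total_b) < min_count:
            excluded = "low_count"
        elif ok.sum() < 3:
            excluded = "few_bins"
        elif np.ptp(fa[ok]) == 0 or np.ptp(fb[ok]) == 0:
            excluded = "constant"
        if excluded:
            rows.append(
                {"codon": codon, "r": np.nan, "p": np.nan, "n_bins": int(ok.sum()),
                 "significant": False, "excluded": excluded}
            )
            continue
        res = stats.pearsonr(fa[ok], fb[ok])
        rows.append(
            {
                "codon": codon,
                "r": float(res.statistic),
                "p": float(res.pvalue),
                "n_bins": int(ok.sum()),
                "significant": bool(res.pvalue < alpha),
                "excluded": None,
            }
        )
    table = pd.DataFrame(rows).set_index("codon")
    sig = table[table["significant"]]
    if len(sig) == 0:
        call = "incoherent"
    elif (sig["r"] > 0).all():
        call = "positively coherent"
    elif (sig["r"] < 0).all():
        call = "negatively coherent"
    else:
        call = "incoherent"
    return CoherenceReport(table, call, name_a, name_b)


def windowed_codon_bias(
    gene: GeneRecord,
    reference: UsageFractions,
    n_windows: int = 5,
) -> pd.DataFrame:
    """Codon-bias indices of contiguous intragene windows.

    The gene's codons are split into ``n_windows`` near-equal contiguous
    blocks (remainder codons go to the earliest windows); per window the
    standard indices plus complementarity and periodicity are computed.
    """
    ids = codon_ids(gene.cds, gene.id)
    n = len(ids)
    if n < n_windows:
        raise DomainError(f"gene {gene.id!r}: {n} codons < {n_windows} windows")
    base, rem = divmod(n, n_windows)
    sizes = [base + (1 if w < rem else 0) for w in range(n_windows)]
    rows = []
    start = 0
    for w, size in enumerate(sizes):
        chunk = ids[start : start + size]
        start += size
        valid = chunk[chunk >= 0]
        cc = CodonCounts.from_vector(
            np.bincount(valid, minlength=64), n_skipped=int((chunk < 0).sum())
        )
        row = {"window": w, "n_codons": size, "n_sense": cc.n_sense}
        try:
            idx = bias_indices(cc, reference)
            row.update(cai=idx.cai, fop=idx.fop, cbi=idx.cbi, nc=idx.nc)
        except Exception:
            row.update(cai=np.nan, fop=np.nan, cbi=np.nan, nc=np.nan)
        row["complementarity"] = complementarity_index(cc) if cc.total else np.nan
        row["pi"] = periodicity_index(cc) if cc.total else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("window")
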