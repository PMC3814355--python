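"""Genetic-code tables, codon counting and sequence-intrinsic codon-bias indices.

The standard nuclear genetic code partitions the 64 trinucleotides into 61
sense codons (20 amino acids) and 3 stop codons.  Eighteen amino acids are
encoded by two to six synonymous codons ("degenerate sense families"); nine
of them by exactly two.  All statistics in this module are functions of codon
counts only — they never look at expression or structural data, which is what
makes them usable both on native genes and on the randomized genomes produced
by :mod:`codonlens.null_models`.
"""

from __future__ import annotations

import enum
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable as _BioCodonTable

from .exceptions import (
    DomainError,
    EmptyInputError,
    FrameError,
    MissingFamilyError,
)

BASES = "ACGT"
#: the 64 codons in lexicographic (A < C < G < T) order; codon id = index here
CODONS = tuple("".join(p) for p in itertools.product(BASES, repeat=3))
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
STOP = "*"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (uppercase ACGT)."""
    return seq.translate(_COMPLEMENT)[::-1]


#: partner codon id for each codon id under reverse complementation
REVCOMP_IDS = np.array([CODON_INDEX[revcomp(c)] for c in CODONS], dtype=np.int64)

# base identity of each codon at each of the three positions, as integers 0..3
_POSITION_BASE = np.array(
    [[BASES.index(c[p]) for p in range(3)] for c in CODONS], dtype=np.int64
)


@dataclass(frozen=True)
class GeneticCodeTable:
    """The codon → amino-acid map and its synonymous families.

    ``families`` maps each amino acid (one-letter code, ``"*"`` for stop) to
    the lexicographically ordered tuple of its codons.
    """

    codon_to_aa: dict[str, str]
    families: dict[str, tuple[str, ...]]

    @classmethod
    def standard(cls) -> "GeneticCodeTable":
        bio = _BioCodonTable.unambiguous_dna_by_id[1]
        codon_to_aa = {c: bio.forward_table.get(c, STOP) for c in CODONS}
        families: dict[str, list[str]] = {}
        for codon in CODONS:
            families.setdefault(codon_to_aa[codon], []).append(codon)
        return cls(codon_to_aa, {aa: tuple(sorted(cs)) for aa, cs in families.items()})

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(sorted(a for a in self.families if a != STOP))

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if self.codon_to_aa[c] != STOP)

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return self.families[STOP]

    @property
    def degenerate_sense_families(self) -> tuple[str, ...]:
        """Amino acids with at least two synonymous codons (18 in the standard code)."""
        return tuple(
            sorted(a for a, cs in self.families.items() if a != STOP and len(cs) >= 2)
        )

    @property
    def twofold_families(self) -> tuple[str, ...]:
        """The nine amino acids encoded by exactly two codons."""
        return tuple(
            sorted(a for a, cs in self.families.items() if a != STOP and len(cs) == 2)
        )

    def family_of(self, codon: str) -> str:
        return self.codon_to_aa[codon]


STANDARD_CODE = GeneticCodeTable.standard()

#: amino-acid family id (as index into a fixed ordering) per codon id
_FAMILY_ORDER = tuple(sorted(STANDARD_CODE.families))  # includes "*"
FAMILY_INDEX = {aa: i for i, aa in enumerate(_FAMILY_ORDER)}
CODON_FAMILY_IDS = np.array(
    [FAMILY_INDEX[STANDARD_CODE.codon_to_aa[c]] for c in CODONS], dtype=np.int64
)
_IS_STOP = np.array([STANDARD_CODE.codon_to_aa[c] == STOP for c in CODONS])


@dataclass
class GeneRecord:
    """One coding sequence plus optional per-gene scalar properties."""

    id: str
    cds: str
    properties: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.cds = self.cds.upper()


# fast byte-level encoder: ASCII code -> base index, 255 for anything else
_BYTE_TO_BASE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BYTE_TO_BASE[ord(_b)] = _i


def codon_ids(cds: str, gene_id: str = "<anonymous>") -> np.ndarray:
    """Encode a CDS into frame-0 codon ids (0..63); codons containing a
    non-ACGT letter are returned as -1.

    Raises :class:`FrameError` when the length is not a multiple of three.
    """
    if len(cds) % 3 != 0 or len(cds) == 0:
        raise FrameError(gene_id, len(cds))
    raw = np.frombuffer(cds.upper().encode("ascii"), dtype=np.uint8)
    bases = _BYTE_TO_BASE[raw].astype(np.int64).reshape(-1, 3)
    ids = bases[:, 0] * 16 + bases[:, 1] * 4 + bases[:, 2]
    ids[(bases >= 4).any(axis=1)] = -1
    return ids


def ids_to_cds(ids: np.ndarray) -> str:
    """Decode codon ids back into a DNA string (inverse of :func:`codon_ids`)."""
    return "".join(CODONS[i] for i in ids)


@dataclass
class CodonCounts:
    """Codon occurrence counts for one gene or a pooled gene set."""

    counts: dict[str, int]
    n_sense: int
    n_stop: int
    n_skipped: int = 0

    @classmethod
    def from_vector(cls, vec: np.ndarray, n_skipped: int = 0) -> "CodonCounts":
        vec = np.asarray(vec, dtype=np.int64)
        counts = {CODONS[i]: int(v) for i, v in enumerate(vec) if v > 0}
        n_stop = int(vec[_IS_STOP].sum())
        return cls(counts, int(vec.sum()) - n_stop, n_stop, n_skipped)

    def vector(self) -> np.ndarray:
        vec = np.zeros(64, dtype=np.int64)
        for codon, n in self.counts.items():
            vec[CODON_INDEX[codon]] = n
        return vec

    @property
    def total(self) -> int:
        return self.n_sense + self.n_stop

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        merged = dict(self.counts)
        for codon, n in other.counts.items():
            merged[codon] = merged.get(codon, 0) + n
        return CodonCounts(
            merged,
            self.n_sense + other.n_sense,
            self.n_stop + other.n_stop,
            self.n_skipped + other.n_skipped,
        )


def count_codons(gene: GeneRecord) -> CodonCounts:
    """Count frame-0 codons of a CDS.

    Codons containing a non-ACGT letter only increment ``n_skipped``.  The
    terminal stop (when present) is counted in the stop family; internal stop
    codons are counted as-is with a warning, since annotated CDSs are taken
    at face value.
    """
    ids = codon_ids(gene.cds, gene.id)
    valid = ids[ids >= 0]
    vec = np.bincount(valid, minlength=64)
    n_internal_stop = int(_IS_STOP[valid[:-1]].sum()) if valid.size > 1 else 0
    if n_internal_stop:
        warnings.warn(
            f"gene {gene.id!r}: {n_internal_stop} internal stop codon(s) counted as-is",
            stacklevel=2,
        )
    return CodonCounts.from_vector(vec, n_skipped=int((ids < 0).sum()))


def pool_counts(counts_list) -> CodonCounts:
    """Sum codon counts over a collection of genes or CodonCounts."""
    vec = np.zeros(64, dtype=np.int64)
    n_skipped = 0
    for item in counts_list:
        cc = item if isinstance(item, CodonCounts) else count_codons(item)
        vec += cc.vector()
        n_skipped += cc.n_skipped
    return CodonCounts.from_vector(vec, n_skipped=n_skipped)


@dataclass
class UsageFractions:
    """Within-family synonymous codon fractions; families with zero counts
    are listed in ``absent`` instead of carrying fractions."""

    fractions: dict[str, dict[str, float]]
    absent: tuple[str, ...] = ()

    def get(self, codon: str) -> float:
        aa = STANDARD_CODE.codon_to_aa[codon]
        return self.fractions[aa][codon]

    def family(self, aa: str) -> dict[str, float]:
        return self.fractions[aa]


def synonymous_fractions(counts: CodonCounts) -> UsageFractions:
    """Per-family relative synonymous codon frequencies."""
    fractions: dict[str, dict[str, float]] = {}
    absent = []
    for aa, codons in STANDARD_CODE.families.items():
        total = sum(counts.counts.get(c, 0) for c in codons)
        if total == 0:
            absent.append(aa)
            continue
        fractions[aa] = {c: counts.counts.get(c, 0) / total for c in codons}
    return UsageFractions(fractions, tuple(sorted(absent)))


def complementarity_index(counts: CodonCounts) -> float:
    """Fraction of codons participating in reverse-complement codon couples.

    Each unordered pair {c, revcomp(c)} contributes min(count(c),
    count(revcomp(c))) couples; a couple involves two codons but is counted
    once, following the convention of the worked example
    ({AAT:10, ATT:20, CGA:100} → 10/130).  No trinucleotide is its own
    reverse complement, so there is no self-pair case.
    """
    if counts.total == 0:
        raise EmptyInputError("complementarity index of empty counts")
    vec = counts.vector()
    pair_min = np.minimum(vec, vec[REVCOMP_IDS])
    mask = np.arange(64) < REVCOMP_IDS  # visit each unordered pair once
    return float(pair_min[mask].sum()) / counts.total


def positional_base_frequencies(counts: CodonCounts) -> np.ndarray:
    """4×3 matrix: frequency of base b at codon position p, from codon counts."""
    vec = counts.vector().astype(float)
    total = vec.sum()
    if total == 0:
        raise EmptyInputError("positional base frequencies of empty counts")
    freq = np.zeros((4, 3))
    for p in range(3):
        freq[:, p] = np.bincount(_POSITION_BASE[:, p], weights=vec, minlength=4) / total
    return freq


def periodicity_index(counts: CodonCounts) -> float:
    """Three-base periodicity index Pi.

    Measures how strongly nucleotide composition differs across the three
    codon positions, as expected from the codon frequencies alone:
    Pi = (1/3) Σ_b Σ_p (f(b,p) − f̄(b))², where f(b,p) is the frequency of
    base b at position p and f̄(b) its mean over positions.  Zero iff the
    positional compositions are identical; order-invariant by construction.
    """
    freq = positional_base_frequencies(counts)
    dev = freq - freq.mean(axis=1, keepdims=True)
    return float((dev**2).sum() / 3.0)


def gc_content(counts: CodonCounts) -> float:
    """GC fraction over all counted codon positions."""
    freq = positional_base_frequencies(counts)
    return float(freq[1].mean() + freq[2].mean())  # C and G rows


def gc3_content(counts: CodonCounts) -> float:
    """GC fraction at the third codon position."""
    freq = positional_base_frequencies(counts)
    return float(freq[1, 2] + freq[2, 2])


@dataclass
class MajorCodonTable:
    """Most frequent codon per synonymous family (in a highly expressed pool)."""

    majors: dict[str, str]
    ties: tuple[str, ...] = ()

    def codon_id_set(self) -> np.ndarray:
        return np.array(sorted(CODON_INDEX[c] for c in self.majors.values()))


def major_codon_table(pooled: CodonCounts, include_stop: bool = True) -> MajorCodonTable:
    """Identify the major codon of each degenerate family from pooled counts.

    Ties are broken alphabetically and flagged.  Families with zero total
    count raise :class:`MissingFamilyError`.
    """
    majors: dict[str, str] = {}
    ties = []
    missing = []
    families = list(STANDARD_CODE.degenerate_sense_families)
    if include_stop:
        families.append(STOP)
    for aa in families:
        codons = STANDARD_CODE.families[aa]
        fam_counts = {c: pooled.counts.get(c, 0) for c in codons}
        best = max(fam_counts.values())
        if best == 0:
            missing.append(aa)
            continue
        winners = sorted(c for c, n in fam_counts.items() if n == best)
        majors[aa] = winners[0]
        if len(winners) > 1:
            ties.append(aa)
    if missing:
        raise MissingFamilyError(missing)
    return MajorCodonTable(majors, tuple(ties))


def expected_fractions_from_gc(gc: float) -> UsageFractions:
    """Synonymous fractions expected under independent nucleotides with the
    given GC content (P(G) = P(C) = gc/2, P(A) = P(T) = (1−gc)/2)."""
    if not 0.0 < gc < 1.0:
        raise DomainError(f"gc must be in (0, 1), got {gc}")
    p_base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codon_p = p_base[_POSITION_BASE].prod(axis=1)
    fractions = {}
    for aa, codons in STANDARD_CODE.families.items():
        ids = [CODON_INDEX[c] for c in codons]
        fam = codon_p[ids] / codon_p[ids].sum()
        fractions[aa] = {c: float(f) for c, f in zip(codons, fam)}
    return UsageFractions(fractions)


class PairingClass(enum.Enum):
    """How a codon pairs with an anticodon at the ribosome."""

    WATSON_CRICK = "watson_crick"
    WOBBLE = "wobble"
    NONE = "none"


_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
#: codon position 3 : anticodon position 1 pairs tolerated by wobble rules
_WOBBLE = {("T", "G"), ("G", "T")}


def classify_pairing(codon: str, anticodon: str) -> PairingClass:
    """Classify a codon–anticodon pair (both given 5'→3', DNA alphabet).

    Watson–Crick iff the anticodon is the reverse complement of the codon.
    Wobble iff codon positions 1–2 pair Watson–Crick with anticodon
    positions 3–2 and the codon-3 : anticodon-1 pair is U:G or G:U.
    Inosine and other modified anticodon bases are not modeled.
    """
    codon = codon.upper().replace("U", "T")
    anticodon = anticodon.upper().replace("U", "T")
    for s in (codon, anticodon):
        if len(s) != 3 or any(b not in BASES for b in s):
            raise DomainError(f"malformed trinucleotide: {s!r}")
    if anticodon == revcomp(codon):
        return PairingClass.WATSON_CRICK
    stem_ok = (codon[0], anticodon[2]) in _WC and (codon[1], anticodon[1]) in _WC
    if stem_ok and (codon[2], anticodon[0]) in _WOBBLE:
        return PairingClass.WOBBLE
    return PairingClass.NONE


# ---------------------------------------------------------------------------
# Bias indices (CAI, Fop, CBI, Nc)
# ---------------------------------------------------------------------------

@dataclass
class BiasIndices:
    cai: float
    fop: float
    cbi: float
    nc: float


_FAMILY_SIZES = {aa: len(cs) for aa, cs in STANDARD_CODE.families.items() if aa != STOP}
# number of families per degeneracy class in the standard code
_CLASS_COUNTS = {2: 9, 3: 1, 4: 5, 6: 3}


def _reference_weights(reference: UsageFractions) -> tuple[dict[str, float], dict[str, str]]:
    """CAI relative-adaptiveness weights and major codons from reference fractions."""
    weights: dict[str, float] = {}
    majors: dict[str, str] = {}
    missing = []
    for aa in STANDARD_CODE.degenerate_sense_families:
        if aa not in reference.fractions:
            missing.append(aa)
            continue
        fam = reference.fractions[aa]
        fmax = max(fam.values())
        if fmax == 0:
            missing.append(aa)
            continue
        majors[aa] = sorted(c for c, f in fam.items() if f == fmax)[0]
        for codon, f in fam.items():
            weights[codon] = max(f / fmax, 0.01)  # floor avoids log(0)
    if missing:
        raise MissingFamilyError(missing)
    return weights, majors


def effective_number_of_codons(counts: CodonCounts) -> float:
    """Wright's effective number of codons (Nc).

    Per sense family with n ≥ 2, the homozygosity F = (n·Σp² − 1)/(n − 1);
    class means of F over the 2-, 3-, 4- and 6-fold families enter
    Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, capped at 61.  When the single
    3-fold family (Ile) is unobservable, F̄₃ is replaced by the mean of F̄₂
    and F̄₄ (Wright's rule); any other unobservable class borrows the mean
    of the observable class means.
    """
    if counts.n_sense == 0:
        raise EmptyInputError("Nc of empty counts")
    f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in STANDARD_CODE.families.items():
        if aa == STOP or len(codons) < 2:
            continue
        ns = np.array([counts.counts.get(c, 0) for c in codons], dtype=float)
        n = ns.sum()
        if n < 2:
            continue
        p = ns / n
        f = (n * (p**2).sum() - 1) / (n - 1)
        if f > 0:
            f_by_class[len(codons)].append(f)
    means = {k: float(np.mean(v)) for k, v in f_by_class.items() if v}
    if not means:
        raise EmptyInputError("no synonymous family observed at n >= 2")
    if 3 not in means:
        if 2 in means and 4 in means:
            means[3] = (means[2] + means[4]) / 2
        else:
            means[3] = float(np.mean(list(means.values())))
    for k in (2, 4, 6):
        if k not in means:
            means[k] = float(np.mean([means[j] for j in means if j != k]))
    nc = 2.0 + sum(_CLASS_COUNTS[k] / means[k] for k in (2, 3, 4, 6))
    return float(min(nc, 61.0))


def bias_indices(counts: CodonCounts, reference: UsageFractions) -> BiasIndices:
    """CAI, Fop, CBI and Nc of one gene against a highly expressed reference.

    CAI is the geometric mean of relative-adaptiveness weights over the
    codons of degenerate sense families (Met, Trp and stops excluded); Fop
    the fraction of those codons that are optimal; CBI the Bennetzen–Hall
    excess of optimal codons over random expectation.
    """
    weights, majors = _reference_weights(reference)
    log_w_sum = 0.0
    n_scored = 0
    n_opt = 0
    n_random = 0.0
    for aa in STANDARD_CODE.degenerate_sense_families:
        codons = STANDARD_CODE.families[aa]
        for codon in codons:
            n = counts.counts.get(codon, 0)
            if n == 0:
                continue
            log_w_sum += n * np.log(weights[codon])
            n_scored += n
            if codon == majors[aa]:
                n_opt += n
        fam_total = sum(counts.counts.get(c, 0) for c in codons)
        n_random += fam_total / len(codons)
    if n_scored == 0:
        raise EmptyInputError("gene has no codons in degenerate sense families")
    cai = float(np.exp(log_w_sum / n_scored))
    fop = n_opt / n_scored
    cbi = (n_opt - n_random) / (n_scored - n_random) if n_scored > n_random else 0.0
    return BiasIndices(cai=cai, fop=fop, cbi=float(cbi), nc=effective_number_of_codons(counts))


def gene_index_table(genes, reference: UsageFractions) -> pd.DataFrame:
    """Per-gene codon-bias index table (one row per gene).

    Columns: gene_id, n_sense, gc, gc3, cai, fop, cbi, nc, complementarity, pi.
    """
    rows = []
    for gene in genes:
        cc = count_codons(gene)
        idx = bias_indices(cc, reference)
        rows.append(
            {
                "gene_id": gene.id,
                "n_sense": cc.n_sense,
                "gc": gc_content(cc),
                "gc3": gc3_content(cc),
                "cai": idx.cai,
                "fop": idx.fop,
                "cbi": idx.cbi,
                "nc": idx.nc,
                "complementarity": complementarity_index(cc),
                "pi": periodicity_index(cc),
            }
        )
    return pd.DataFrame(rows)
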