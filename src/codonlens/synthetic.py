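"""Synthetic genomes with known ground truth.

The generator emulates the statistical structure the analysis modules assume
in a budding-yeast-like genome: a few thousand genes with log-normal mRNA
levels; codon usage that is purely GC-driven in lowly transcribed genes and
shifts linearly (in log2 level) toward a fixed major-codon set between 0.5
and 32 mRNA/cell; per-nucleotide structure scores whose gene averages rise
with expression; introns whose length — and hence folding ΔG — grows with
expression; a tRNA gene-copy table adapted to the major codons under wobble
rules; and protein levels rising super-linearly with mRNA.  Every hidden
parameter is recorded in a :class:`SyntheticTruth` so estimators can be
scored against what the generator actually did.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .code_core import (
    CODON_INDEX,
    CODONS,
    STANDARD_CODE,
    STOP,
    GeneRecord,
    MajorCodonTable,
    PairingClass,
    UsageFractions,
    classify_pairing,
    expected_fractions_from_gc,
    revcomp,
)
from .exceptions import DomainError
from .structure import IntronRecord, ParsProfile

#: default major-codon set: yeast-like preferences in which exactly ten
#: codons form five reverse-complement pairs (TTC/GAA, TTG/CAA, GTT/AAC,
#: GGT/ACC, AGA/TCT), so complementarity-of-majors analyses are exercisable
DEFAULT_MAJOR_CODONS: dict[str, str] = {
    "F": "TTC", "L": "TTG", "I": "ATT", "V": "GTT", "S": "TCT",
    "P": "CCA", "T": "ACC", "A": "GCT", "Y": "TAC", "H": "CAC",
    "Q": "CAA", "N": "AAC", "K": "AAG", "D": "GAC", "E": "GAA",
    "C": "TGT", "R": "AGA", "G": "GGT", STOP: "TAA",
}

#: average PARS score per base, matching the magnitudes seen in yeast
#: transcriptome-wide structure probing (C and T positions far more often
#: paired than A and G)
DEFAULT_PARS_BASE_MEANS = {"A": 0.034, "C": 0.844, "G": 0.026, "T": 0.540}


@dataclass(frozen=True)
class SyntheticGenomeConfig:
    """Generator parameters; the defaults are the study conditions.

    Expression is log-normal in mRNA molecules per cell; the selection
    weight s of a gene is 0 up to ``low_break`` mRNA/cell, rises linearly in
    log2(level) to ``s_max`` at ``high_break``, and saturates above.  At each
    synonymous site the codon is the family major with probability s and a
    draw from the GC-driven mutational fractions otherwise.
    """

    n_genes: int = 6400
    log2_level_mean: float = -0.8
    log2_level_sd: float = 2.2
    mutational_gc: float = 0.38
    major_codons: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_MAJOR_CODONS)
    )
    low_break: float = 0.5
    high_break: float = 32.0
    s_max: float = 0.9
    mean_codons: int = 300
    length_log_sd: float = 0.45
    min_codons: int = 40
    aa_rare_weight: float = 0.2  # relative weight of Met/Trp vs degenerate families
    pars_fraction: float = 0.47
    pars_base_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PARS_BASE_MEANS)
    )
    pars_level_slope: float = 0.05
    pars_noise_sd: float = 0.30
    intron_fraction: float = 0.05
    intron_length_base: float = 150.0
    intron_length_slope: float = 20.0
    intron_length_noise_sd: float = 20.0
    intron_min_length: int = 30
    delta_g_per_nt: float = 0.30
    delta_g_noise_sd: float = 5.0
    protein_exponent: float = 1.3
    protein_noise_log2_sd: float = 1.0
    trna_total_copies: int = 275
    #: major codons decoded only through wobble (their Watson–Crick
    #: anticodon is absent from the tRNA pool)
    wobble_decoded_majors: tuple[str, ...] = ("TGT", "GGT")

    def validate(self) -> None:
        if self.n_genes < 1:
            raise DomainError("n_genes must be positive")
        if not 0.0 < self.mutational_gc < 1.0:
            raise DomainError("mutational_gc must be in (0, 1)")
        if not 0.0 <= self.s_max <= 1.0:
            raise DomainError("s_max must be in [0, 1]")
        if not 0 < self.low_break < self.high_break:
            raise DomainError("breakpoints must satisfy 0 < low < high")
        missing = [
            aa
            for aa in (*STANDARD_CODE.degenerate_sense_families, STOP)
            if aa not in self.major_codons
        ]
        if missing:
            raise DomainError(f"major_codons missing families: {missing}")
        for aa, codon in self.major_codons.items():
            if codon not in STANDARD_CODE.families[aa]:
                raise DomainError(f"{codon} is not a codon of family {aa}")
        if not 0.0 <= self.intron_fraction <= 1.0:
            raise DomainError("intron_fraction must be in [0, 1]")
        if not 0.0 <= self.pars_fraction <= 1.0:
            raise DomainError("pars_fraction must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """The generator's hidden parameters, for recovery tests."""

    config: SyntheticGenomeConfig
    seed: int
    selection_weight: dict[str, float]  # per gene
    mutational_fractions: UsageFractions
    major_table: MajorCodonTable
    mutational_share: float  # codon-weighted 1 − s over degenerate sites

    def per_gene_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(self.selection_weight),
                "selection_weight": list(self.selection_weight.values()),
            }
        )

    def global_params(self) -> dict:
        cfg = dataclasses.asdict(self.config)
        cfg["wobble_decoded_majors"] = list(cfg["wobble_decoded_majors"])
        return {
            "seed": self.seed,
            "mutational_share": self.mutational_share,
            "config": cfg,
        }


@dataclass
class SyntheticGenome:
    """Everything one run of the generator produces."""

    genes: list[GeneRecord]
    expression: dict[str, float]
    pars_profiles: list[ParsProfile]
    introns: list[IntronRecord]
    trna_table: pd.DataFrame
    protein: dict[str, float]
    truth: SyntheticTruth


def selection_weight(level: float, config: SyntheticGenomeConfig) -> float:
    """Piecewise-linear (in log2 level) selection weight of one gene."""
    lo, hi = np.log2(config.low_break), np.log2(config.high_break)
    x = np.log2(level)
    if x <= lo:
        return 0.0
    if x >= hi:
        return config.s_max
    return float(config.s_max * (x - lo) / (hi - lo))


def _amino_acid_pool(config: SyntheticGenomeConfig):
    aas = list(STANDARD_CODE.degenerate_sense_families) + ["M", "W"]
    w = np.array([1.0] * 18 + [config.aa_rare_weight] * 2)
    return aas, w / w.sum()


def generate_genome(config: SyntheticGenomeConfig, seed: int) -> SyntheticGenome:
    """Draw a complete synthetic genome (bit-reproducible from (config, seed))."""
    config.validate()
    rng = np.random.default_rng(int(seed))
    n = config.n_genes
    gene_names = [f"syn{g:05d}" for g in range(n)]

    log2_levels = rng.normal(config.log2_level_mean, config.log2_level_sd, size=n)
    levels = 2.0**log2_levels
    s = np.array([selection_weight(lv, config) for lv in levels])

    lengths = np.maximum(
        config.min_codons,
        np.round(config.mean_codons * rng.lognormal(0.0, config.length_log_sd, size=n)
                 / np.exp(config.length_log_sd**2 / 2)).astype(int),
    )

    aas, aa_probs = _amino_acid_pool(config)
    mut_fracs = expected_fractions_from_gc(config.mutational_gc)

    # flatten all sense sites genome-wide; stop codons are appended per gene
    total_sense = int(lengths.sum())
    gene_of_site = np.repeat(np.arange(n), lengths)
    aa_ids = rng.choice(len(aas), size=total_sense, p=aa_probs)
    codon_arr = np.empty(total_sense, dtype=np.int64)
    site_s = s[gene_of_site]
    use_major = rng.random(total_sense) < site_s
    for ai, aa in enumerate(aas):
        sites = np.flatnonzero(aa_ids == ai)
        if sites.size == 0:
            continue
        codons = STANDARD_CODE.families[aa]
        member_ids = np.array([CODON_INDEX[c] for c in codons])
        if len(codons) == 1:
            codon_arr[sites] = member_ids[0]
            continue
        probs = np.array([mut_fracs.fractions[aa][c] for c in codons])
        draws = member_ids[
            np.searchsorted(np.cumsum(probs), rng.random(sites.size)).clip(
                0, len(codons) - 1
            )
        ]
        major_id = CODON_INDEX[config.major_codons[aa]]
        codon_arr[sites] = np.where(use_major[sites], major_id, draws)

    # terminal stop codons under the same mutation/selection mixture
    stop_codons = STANDARD_CODE.families[STOP]
    stop_ids = np.array([CODON_INDEX[c] for c in stop_codons])
    stop_probs = np.array([mut_fracs.fractions[STOP][c] for c in stop_codons])
    stop_draws = stop_ids[
        np.searchsorted(np.cumsum(stop_probs), rng.random(n)).clip(0, 2)
    ]
    stop_major = CODON_INDEX[config.major_codons[STOP]]
    stops = np.where(rng.random(n) < s, stop_major, stop_draws)

    genes = []
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    for g in range(n):
        body = codon_arr[offsets[g] : offsets[g + 1]]
        cds = "".join(CODONS[c] for c in body) + CODONS[stops[g]]
        genes.append(GeneRecord(gene_names[g], cds))

    expression = dict(zip(gene_names, levels.tolist()))

    # PARS profiles for a random subset of genes
    n_pars = int(round(config.pars_fraction * n))
    pars_genes = rng.choice(n, size=n_pars, replace=False)
    base_mean_arr = np.array([config.pars_base_means[b] for b in "ACGT"])
    byte_to_base = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        byte_to_base[ord(b)] = i
    pars_profiles = []
    for g in sorted(pars_genes):
        cds = genes[g].cds
        bases = byte_to_base[np.frombuffer(cds.encode("ascii"), dtype=np.uint8)]
        scores = (
            base_mean_arr[bases]
            + config.pars_level_slope * log2_levels[g]
            + rng.normal(0.0, config.pars_noise_sd, size=len(cds))
        )
        pars_profiles.append(ParsProfile(gene_names[g], scores))

    # introns: length rises with expression, folding ΔG scales with length
    n_intron = int(round(config.intron_fraction * n))
    intron_genes = rng.choice(n, size=n_intron, replace=False)
    introns = []
    for g in sorted(intron_genes):
        length = int(
            max(
                config.intron_min_length,
                round(
                    config.intron_length_base
                    + config.intron_length_slope * log2_levels[g]
                    + rng.normal(0.0, config.intron_length_noise_sd)
                ),
            )
        )
        delta_g = -config.delta_g_per_nt * length + rng.normal(
            0.0, config.delta_g_noise_sd
        )
        introns.append(IntronRecord(gene_names[g], length, float(delta_g)))

    protein = {
        gene_names[g]: float(
            levels[g] ** config.protein_exponent
            * 2.0 ** rng.normal(0.0, config.protein_noise_log2_sd)
        )
        for g in range(n)
    }

    trna_table = _trna_table(config, s, lengths)

    major_table = MajorCodonTable(
        {aa: c for aa, c in config.major_codons.items()}, ()
    )
    # degenerate-family site counts weight the per-gene mutational share
    degenerate_aas = set(STANDARD_CODE.degenerate_sense_families)
    deg_mask = np.isin(aa_ids, [aas.index(a) for a in degenerate_aas])
    deg_per_gene = np.bincount(gene_of_site[deg_mask], minlength=n)
    mutational_share = float(1.0 - np.average(s, weights=deg_per_gene))
    truth = SyntheticTruth(
        config=config,
        seed=int(seed),
        selection_weight=dict(zip(gene_names, s.tolist())),
        mutational_fractions=mut_fracs,
        major_table=major_table,
        mutational_share=mutational_share,
    )
    return SyntheticGenome(
        genes, expression, pars_profiles, introns, trna_table, protein, truth
    )


def _trna_table(
    config: SyntheticGenomeConfig, s: np.ndarray, lengths: np.ndarray
) -> pd.DataFrame:
    """tRNA gene copies adapted to the major codons.

    Each degenerate family (plus Met and Trp) receives one anticodon
    decoding its major codon — the Watson–Crick partner, or the wobble
    partner for majors listed in ``wobble_decoded_majors`` — with copies
    proportional to the family's share of amino-acid usage."""
    aas, aa_probs = _amino_acid_pool(config)
    rows = []
    for aa, p in zip(aas, aa_probs):
        major = (
            config.major_codons[aa]
            if aa in config.major_codons
            else STANDARD_CODE.families[aa][0]
        )
        if major in config.wobble_decoded_majors:
            anticodon = "G" + revcomp(major)[1:]
        else:
            anticodon = revcomp(major)
        pairing = classify_pairing(major, anticodon)
        assert pairing is not PairingClass.NONE
        rows.append(
            {
                "anticodon": anticodon,
                "amino_acid": aa,
                "decoded_major": major,
                "pairing": pairing.value,
                "gene_copies": max(1, round(config.trna_total_copies * p)),
            }
        )
    return pd.DataFrame(rows)


def truth_report(truth: SyntheticTruth) -> pd.DataFrame:
    """Tabular form of the hidden parameters: one row per gene plus the
    global mutational share (gene_id ``__global__``)."""
    df = truth.per_gene_frame()
    global_row = pd.DataFrame(
        {"gene_id": ["__global__"], "selection_weight": [np.nan]}
    )
    out = pd.concat([df, global_row], ignore_index=True)
    out["mutational_share"] = truth.mutational_share
    out["seed"] = truth.seed
    return out
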