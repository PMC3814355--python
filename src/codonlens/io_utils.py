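"""File formats: FASTA gene sets, per-gene property TSVs, per-nucleotide
PARS profiles, intron tables, generator configs and run manifests.

All positional outputs are 0-based half-open.  Gene ids are joined across
files by exact string match.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .code_core import GeneRecord
from .exceptions import DuplicateIdError, EmptyInputError, SchemaError
from .structure import IntronRecord, ParsProfile
from .synthetic import SyntheticGenomeConfig

log = logging.getLogger("codonlens")

_IUPAC = set("ACGTUNRYSWKMBDHV")


def read_fasta(path) -> list[GeneRecord]:
    """Read a multi-record FASTA of CDSs.

    The gene id is the header token before the first whitespace; sequences
    are uppercased with U mapped to T.  Empty files, duplicate ids and
    non-IUPAC characters raise explicit errors.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - _IUPAC
        if bad:
            raise SchemaError(
                f"record {rec.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        records.append(GeneRecord(rec.id, seq))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    return records


def write_fasta(genes: list[GeneRecord], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(g.cds), id=g.id, description="") for g in genes),
        str(path),
        "fasta",
    )


def read_property_table(path, value_column: str | None = None) -> dict[str, float]:
    """Read a per-gene scalar property from a TSV with a header row.

    The first column is the gene id; ``value_column`` defaults to the second
    column.  Non-numeric and missing values are dropped (count logged);
    duplicate gene rows keep the last value, with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: property table needs >= 2 columns")
    id_col = df.columns[0]
    if value_column is None:
        value_column = df.columns[1]
    if value_column not in df.columns:
        raise SchemaError(f"{path}: no column named {value_column!r}")
    values = pd.to_numeric(df[value_column], errors="coerce")
    dropped = int(values.isna().sum())
    if dropped:
        log.info("%s: dropped %d non-numeric/missing values", path, dropped)
    keep = values.notna()
    ids = df[id_col][keep]
    if ids.duplicated().any():
        log.warning(
            "%s: %d duplicate gene ids; keeping the last value of each",
            path,
            int(ids.duplicated().sum()),
        )
    return dict(zip(ids, values[keep].astype(float)))


def write_property_table(
    table: dict[str, float], path, value_column: str = "value"
) -> None:
    pd.DataFrame(
        {"gene_id": list(table), value_column: list(table.values())}
    ).to_csv(path, sep="\t", index=False)


def read_pars_profiles(path) -> list[ParsProfile]:
    """Read per-nucleotide PARS profiles from TSV.

    Two dialects: long format with columns (gene_id, position, score),
    position 0-based and contiguous from 0; or wide format with columns
    (gene_id, scores) where scores is comma-joined.
    """
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if {"gene_id", "position", "score"} <= set(cols):
        profiles = []
        for gene_id, grp in df.groupby("gene_id", sort=False):
            grp = grp.sort_values("position")
            pos = grp["position"].to_numpy()
            if pos[0] != 0 or not np.array_equal(pos, np.arange(len(pos))):
                raise SchemaError(
                    f"{path}: positions of {gene_id!r} are not contiguous from 0"
                )
            profiles.append(ParsProfile(str(gene_id), grp["score"].to_numpy(float)))
        return profiles
    if {"gene_id", "scores"} <= set(cols):
        return [
            ParsProfile(
                str(r.gene_id),
                np.array([float(x) for x in str(r.scores).split(",")]),
            )
            for r in df.itertuples()
        ]
    raise SchemaError(
        f"{path}: expected columns (gene_id, position, score) or (gene_id, scores)"
    )


def write_pars_profiles(profiles: list[ParsProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tscores\n")
        for prof in profiles:
            fh.write(
                prof.gene_id + "\t" + ",".join(f"{s:.6g}" for s in prof.scores) + "\n"
            )


def read_intron_table(path) -> list[IntronRecord]:
    """Read an intron table TSV with columns gene_id, length, delta_g."""
    df = pd.read_csv(path, sep="\t")
    needed = {"gene_id", "length", "delta_g"}
    if not needed <= set(df.columns):
        raise SchemaError(f"{path}: intron table needs columns {sorted(needed)}")
    return [
        IntronRecord(str(r.gene_id), int(r.length), float(r.delta_g))
        for r in df.itertuples()
    ]


def write_intron_table(introns: list[IntronRecord], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [i.gene_id for i in introns],
            "length": [i.length for i in introns],
            "delta_g": [i.delta_g for i in introns],
        }
    ).to_csv(path, sep="\t", index=False)


def load_synthetic_config(path) -> SyntheticGenomeConfig:
    """Build a generator config from a YAML/JSON mapping of overrides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    valid = {f.name for f in dataclasses.fields(SyntheticGenomeConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    if "wobble_decoded_majors" in raw:
        raw["wobble_decoded_majors"] = tuple(raw["wobble_decoded_majors"])
    return SyntheticGenomeConfig(**raw)


@dataclass
class RunManifest:
    """Provenance record emitted once per CLI run."""

    command: str
    seed: int | None
    inputs: dict[str, str]  # path -> sha256
    package_version: str
    started: str
    finished: str
    parameters: dict


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(
    command: str,
    seed: int | None,
    input_paths: list,
    parameters: dict,
    started: float,
) -> RunManifest:
    from . import __version__

    return RunManifest(
        command=command,
        seed=seed,
        inputs={str(p): _sha256(p) for p in input_paths if p is not None},
        package_version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime(started)),
        finished=time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
        parameters=parameters,
    )


def write_manifest(manifest: RunManifest, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(manifest), indent=2) + "\n")
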