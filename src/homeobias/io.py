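"""Readers and writers for the tabular dialects of the pipeline.

Canonical dialect: tab-separated UTF-8 text, ``#`` comment lines, header
row required (except the samtools-depth track, which is headerless).
Expression tables are genes x replicate-samples in FPKM; the polyploid
table carries a ``subgenome`` column assigning each gene row to the A or
C subgenome.  Floats are written at 12 significant digits so that
write -> read round-trips are lossless for practical purposes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, InvalidInputError

FLOAT_FORMAT = "%.12g"

SPECIES = ("parentA", "parentC", "polyploid")


@dataclass
class ExpressionTable:
    """Replicate-by-gene FPKM table for one species.

    ``data`` is genes x replicate columns (float, finite, >= 0);
    ``subgenome`` maps gene -> {'A', 'C'} for polyploid tables.
    """

    data: pd.DataFrame
    species: str
    subgenome: pd.Series | None = None

    def __post_init__(self):
        if self.species not in SPECIES:
            raise InvalidInputError(f"unknown species tag {self.species!r}")
        if self.data.shape[1] < 2:
            raise FormatError(
                f"{self.species}: need >= 2 replicate columns, got {self.data.shape[1]}"
            )
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()][:5].tolist()
            raise FormatError(f"{self.species}: duplicate gene ids {dups}")
        values = self.data.to_numpy()
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise FormatError(f"{self.species}: expression values must be finite and >= 0")
        if self.subgenome is not None:
            bad = set(self.subgenome.unique()) - {"A", "C"}
            if bad:
                raise FormatError(f"subgenome tags must be 'A'/'C', got {sorted(bad)}")
            if not self.subgenome.index.equals(self.data.index):
                raise FormatError("subgenome series must align with gene index")

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def means(self) -> pd.Series:
        return self.data.mean(axis=1)

    def subset(self, gene_ids) -> "ExpressionTable":
        sub = self.subgenome.loc[gene_ids] if self.subgenome is not None else None
        return ExpressionTable(self.data.loc[gene_ids], self.species, sub)


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(
            path,
            sep="\t",
            comment="#",
            keep_default_na=False,
            na_values=[],
            **kwargs,
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file is empty") from exc


def read_expression(
    path,
    species: str,
    sample_sheet: pd.DataFrame | None = None,
    subgenome_column: str = "subgenome",
    id_prefix_subgenomes: dict[str, str] | None = None,
) -> ExpressionTable:
    """Read an expression TSV (first column gene_id, one column per sample).

    Polyploid tables declare subgenomes either via a ``subgenome`` column
    or, as a fallback, via ``id_prefix_subgenomes`` mapping gene-id
    prefixes to 'A'/'C'.  With a ``sample_sheet`` (columns sample,
    species, replicate) every numeric column must be declared.
    """
    df = _read_tsv(path, dtype=str)
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise FormatError(f"{path}: expected gene_id plus >= 1 sample column with data rows")
    gene_col = df.columns[0]
    genes = df[gene_col]
    if genes.duplicated().any():
        dups = genes[genes.duplicated()].head(5).tolist()
        raise FormatError(f"{path}: duplicate gene_id {dups}")
    df = df.set_index(gene_col)
    df.index.name = "gene_id"

    subgenome = None
    if subgenome_column in df.columns:
        subgenome = df.pop(subgenome_column)
    elif species == "polyploid" and id_prefix_subgenomes:
        tags = pd.Series("?", index=df.index)
        for prefix, tag in id_prefix_subgenomes.items():
            tags[df.index.str.startswith(prefix)] = tag
        if (tags == "?").any():
            bad = df.index[tags == "?"][:5].tolist()
            raise FormatError(f"{path}: gene ids with no subgenome prefix: {bad}")
        subgenome = tags

    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            gene = df.index[converted.isna()][0]
            value = df.loc[gene, col]
            raise FormatError(
                f"{path}: non-numeric value {value!r} at gene {gene!r}, column {col!r}"
            )
        numeric[col] = converted.astype(float)

    if sample_sheet is not None:
        declared = set(sample_sheet["sample"])
        undeclared = [c for c in numeric.columns if c not in declared]
        if undeclared:
            raise FormatError(f"{path}: undeclared sample columns {undeclared}")
    return ExpressionTable(numeric, species, subgenome)


def write_expression(table: ExpressionTable, path) -> None:
    out = table.data.copy()
    if table.subgenome is not None:
        out.insert(0, "subgenome", table.subgenome)
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_pair_map(path) -> pd.DataFrame:
    """Read a homoeolog pair map (2 or 3 tab-separated columns).

    Three columns: pair_id, gene_id_A, gene_id_C.  Two columns: gene_id_A,
    gene_id_C, with pair ids autogenerated from the A-gene id.
    """
    df = _read_tsv(path, dtype=str)
    if df.shape[1] == 3:
        df.columns = ["pair_id", "gene_id_A", "gene_id_C"]
    elif df.shape[1] == 2:
        df.columns = ["gene_id_A", "gene_id_C"]
        df.insert(0, "pair_id", df["gene_id_A"])
    else:
        raise FormatError(f"{path}: pair map must have 2 or 3 columns, got {df.shape[1]}")
    validate_pair_map(df, source=str(path))
    return df.reset_index(drop=True)


def validate_pair_map(df: pd.DataFrame, source: str = "pair map") -> None:
    for col in ("gene_id_A", "gene_id_C"):
        if df[col].duplicated().any():
            dups = df[col][df[col].duplicated()].head(5).tolist()
            raise FormatError(f"{source}: gene listed in more than one pair: {dups}")
    if df["pair_id"].duplicated().any():
        dups = df["pair_id"][df["pair_id"].duplicated()].head(5).tolist()
        raise FormatError(f"{source}: duplicate pair_id {dups}")


def write_pair_map(df: pd.DataFrame, path) -> None:
    df[["pair_id", "gene_id_A", "gene_id_C"]].to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV: columns sample, species, replicate."""
    df = _read_tsv(path)
    required = {"sample", "species", "replicate"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: sample sheet needs columns {sorted(required)}")
    counts = df.groupby("species")["sample"].count()
    if (counts < 2).any():
        raise FormatError(f"{path}: every species needs >= 2 replicates")
    return df


def read_depth(path) -> pd.DataFrame:
    """Read a per-base depth track (samtools-depth dialect, headerless).

    Columns: chrom, 1-based position, integer depth.
    """
    df = _read_tsv(path, header=None, names=["chrom", "pos", "depth"])
    try:
        df["pos"] = df["pos"].astype(np.int64)
        df["depth"] = pd.to_numeric(df["depth"]).astype(float)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: depth track columns must be numeric") from exc
    if (df["pos"] < 1).any():
        raise FormatError(f"{path}: positions are 1-based, found pos < 1")
    if (df["depth"] < 0).any():
        raise FormatError(f"{path}: negative depth values")
    return df


def write_depth(df: pd.DataFrame, path) -> None:
    df[["chrom", "pos", "depth"]].to_csv(path, sep="\t", index=False, header=False)


def read_gmt(path) -> dict[str, tuple[str, frozenset]]:
    """Read a GMT term map: term_id <tab> description <tab> gene ids..."""
    terms: dict[str, tuple[str, frozenset]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            term, desc, genes = fields[0], fields[1], fields[2:]
            if term in terms:
                raise FormatError(f"{path}:{lineno}: duplicate term {term!r}")
            terms[term] = (desc, frozenset(g for g in genes if g))
    if not terms:
        raise FormatError(f"{path}: no terms found")
    return terms


def write_gmt(terms: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, (desc, genes) in terms.items():
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def read_config(path) -> dict:
    """YAML (or JSON; JSON is a YAML subset) configuration file."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def write_manifest(manifest: dict, path) -> None:
    """Run manifest: every threshold, seed and i/o path of a CLI run."""
    Path(path).write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )
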