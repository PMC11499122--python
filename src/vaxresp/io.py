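"""Readers and writers for the tabular formats the pipeline touches.

Expression matrices travel as TSV/CSV with gene ids in the first
column and sample ids in the header (delimiter sniffed from the
header line); gene sets as GMT; graphs as GraphML/SIF; summaries as
JSON.  Writers emit a sidecar manifest carrying the run seed and a
hash of the configuration so outputs are traceable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import pandas as pd
import yaml

from .data import ExpressionMatrix, GeneSetCollection, RAW_COUNTS, validate_sample_table


def _sniff_delimiter(header: str) -> str:
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_expression(path, scale: str = RAW_COUNTS) -> ExpressionMatrix:
    """Genes x samples matrix from TSV/CSV (first column = gene ids)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = _sniff_delimiter(header)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene id(s) in {path.name}: {dup}")
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        row = bad.index[0] if len(bad) else "?"
        raise ValueError(
            f"non-numeric value in {path.name} at gene {row!r}, sample {col!r}"
        )
    return ExpressionMatrix(df, scale)


def write_expression(expr: ExpressionMatrix, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    expr.values.to_csv(path, sep=sep)


def read_sample_table(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    samples = pd.read_csv(path, sep=_sniff_delimiter(header))
    return validate_sample_table(samples)


def read_gmt(path) -> GeneSetCollection:
    """GMT: name<TAB>description<TAB>gene... per line."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "expected name, description, and at least one gene"
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                warnings.warn(f"{path}: dropping empty set {name!r} (line {lineno})")
                continue
            sets[name] = genes
    if not sets:
        warnings.warn(f"{path}: no gene sets read")
    return GeneSetCollection(sets, source_tag=str(path))


def write_gmt(sets: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.sets.items():
            fh.write("\t".join([name, sets.source_tag or "na", *genes]) + "\n")


def read_annotations(path) -> dict[str, str]:
    """Two-column gene id -> biotype table (TSV/CSV with header)."""
    with open(path) as fh:
        header = fh.readline()
    df = pd.read_csv(path, sep=_sniff_delimiter(header))
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def config_hash(config: dict) -> str:
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(outdir, config: dict, seed: int, extra: dict | None = None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
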