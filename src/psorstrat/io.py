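"""Readers and writers for the plain-text interchange formats.

Expression matrices travel as TSV (probes as rows) or GCT 1.2; signature
sets as two-column ``.sig.tsv`` files or GMT; genotypes as subjects x loci
TSV with ``NA`` for missing calls.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GenotypeTable, SignatureSet

LOG2_RANGE = (0.0, 25.0)


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="probe_id")


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    _validate_matrix(df, path)
    return df


def write_gct(expr: pd.DataFrame, path) -> None:
    """GCT 1.2: version line, dimension line, then Name/Description + samples."""
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{expr.shape[0]}\t{expr.shape[1]}\n")
        cols = "\t".join(str(c) for c in expr.columns)
        fh.write(f"Name\tDescription\t{cols}\n")
        for probe, row in expr.iterrows():
            vals = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{probe}\tna\t{vals}\n")


def read_gct(path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"{path}: expected GCT version '#1.2', got {version!r}")
        nrow, ncol = (int(x) for x in fh.readline().split("\t")[:2])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=["Description"])
    if df.shape != (nrow, ncol):
        raise ValueError(
            f"{path}: dimension line says {(nrow, ncol)}, data is {df.shape}"
        )
    df.index.name = "probe_id"
    _validate_matrix(df, path)
    return df


def _validate_matrix(df: pd.DataFrame, path) -> None:
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][:3].tolist()
        raise ValueError(f"{path}: duplicate probe ids, e.g. {dup}")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    vals = df.to_numpy()
    if np.nanmin(vals) < LOG2_RANGE[0] or np.nanmax(vals) > LOG2_RANGE[1]:
        warnings.warn(
            f"{path}: values outside [0, 25]; input may not be log2 scale",
            stacklevel=2,
        )


def read_expression(path, format: str | None = None,
                    metadata_path=None) -> ExpressionMatrix | pd.DataFrame:
    """Read an expression matrix; with metadata, return an ExpressionMatrix."""
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    df = read_gct(path) if format == "gct" else read_expression_tsv(path)
    if metadata_path is None:
        return df
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return ExpressionMatrix(df, meta)


def write_signature(sig: SignatureSet, directory) -> Path:
    path = Path(directory) / f"{sig.name}.{sig.direction}.sig.tsv"
    ranks = [sig.stage2_rank.get(p, i + 1) for i, p in enumerate(sig.probes)]
    pd.DataFrame({"probe_id": sig.probes, "rank": ranks}).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_signature(path) -> SignatureSet:
    path = Path(path)
    name, direction = path.name[: -len(".sig.tsv")].rsplit(".", 1)
    df = pd.read_csv(path, sep="\t")
    probes = df["probe_id"].tolist()
    ranks = dict(zip(probes, df["rank"]))
    return SignatureSet(name, direction, probes, stage2_rank=ranks)


def write_gmt(sets: list, path) -> None:
    with open(path, "w") as fh:
        for sig in sets:
            probes = "\t".join(str(p) for p in sig.probes)
            fh.write(f"{sig.label}\t{sig.direction}\t{probes}\n")


def read_gmt(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            label, direction, probes = fields[0], fields[1], fields[2:]
            name = label[: -len(direction) - 1] if label.endswith("." + direction) else label
            out.append(SignatureSet(name, direction, probes))
    return out


def write_genotypes(table: GenotypeTable, path) -> None:
    out = table.counts.copy()
    out.to_csv(path, sep="\t", index_label="subject", na_rep="NA",
               float_format="%.0f")


def read_genotypes(path, labels_path=None) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df = df.astype(float)  # uniform dtype whether or not NAs are present
    labels = None
    if labels_path is not None:
        labels = pd.read_csv(labels_path, sep="\t", index_col=0).iloc[:, 0]
    return GenotypeTable(df, labels)
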