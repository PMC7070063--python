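"""Readers and writers for the plain-text interchange formats.

All tables are TSV; matrices are square TSVs with an id header row and
column; trees are Newick.  Writers use stable orderings so that repeated
runs with the same seed are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import pandas as pd


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Square matrix with ids in the first column and header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column ids differ")
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_quality_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"mag_id": str})
    required = {"mag_id", "completeness", "contamination"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    """Long annotation table: mag_id, gene_id, comma-separated labels.

    Malformed rows are reported with their 1-based line numbers.
    """
    path = Path(path)
    bad: list[int] = []
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["mag_id", "gene_id", "labels"]:
            raise ValueError(f"{path}: expected header mag_id\tgene_id\tlabels")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0] or not parts[1]:
                bad.append(lineno)
                continue
            records.append(parts[:3])
    if bad:
        shown = ", ".join(map(str, bad[:10]))
        raise ValueError(f"{path}: malformed rows at lines {shown}")
    return pd.DataFrame(records, columns=["mag_id", "gene_id", "labels"])


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.index = df.index.astype(str)
    if "mapped_read_pairs" in df.columns and (df["mapped_read_pairs"] <= 0).any():
        raise ValueError(f"{path}: mapped_read_pairs must be positive")
    return df


def read_contig_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str})
    required = {"contig_id", "length", "est_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


def read_contig_mags(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return df.set_index("contig_id")["mag_id"]
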