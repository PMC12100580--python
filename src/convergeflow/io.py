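"""Shared readers and writers for the pipeline's on-disk formats.

Everything travels as UTF-8 TSV with ``NA`` for missing values, plain
multi-FASTA for alignment clusters, and Newick for the species tree.
Writers use a fixed float format (6 significant digits) so output is
byte-stable under a fixed configuration and seed.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import pandas as pd
import yaml
from Bio import SeqIO

NA_TOKEN = "NA"
FLOAT_FMT = "%.6g"


class SchemaError(ValueError):
    """A table is missing a required column or a cell fails to parse."""


class FormatError(ValueError):
    """A FASTA/Newick/config file violates its format contract."""


def read_table(path: str | Path, schema: Mapping[str, type]) -> pd.DataFrame:
    """Read a TSV into a typed DataFrame.

    ``schema`` maps required column names to types (str, int, float).
    Header order is irrelevant and extra columns pass through untouched.
    Blank lines and ``#`` comments are skipped; ``NA`` reads as missing.

    Raises
    ------
    SchemaError
        If a required column is absent or a cell cannot be coerced.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", skip_blank_lines=True,
            na_values=[NA_TOKEN], keep_default_na=False, dtype=str,
        )
    except Exception as exc:  # noqa: BLE001 - rewrap with path context
        raise SchemaError(f"{path}: cannot parse TSV: {exc}") from exc
    missing = set(schema) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {sorted(missing)}")
    for col, typ in schema.items():
        if typ is str:
            continue
        try:
            if typ is int:
                # int column with no missing values; NaN here is an error
                df[col] = df[col].astype("int64")
            else:
                df[col] = df[col].astype(float)
        except (ValueError, TypeError) as exc:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            line = bad.index[0] + 2 if len(bad) else "?"
            raise SchemaError(
                f"{path}: column {col!r} not coercible to {typ.__name__} (line {line})"
            ) from exc
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as TSV with NA for missing and stable float format."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN, float_format=FLOAT_FMT)


def read_alignment_fasta(path: str | Path) -> dict[str, str]:
    """Read one aligned multi-FASTA; returns an ordered label -> sequence map.

    Enforces >=2 records, unique labels, and equal sequence lengths.
    CRLF and wrapped lines are handled by the underlying parser.
    """
    path = Path(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence label {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if len(seqs) < 2:
        raise FormatError(f"{path}: alignment needs >=2 sequences, got {len(seqs)}")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise FormatError(f"{path}: ragged alignment, sequence lengths {sorted(lengths)}")
    return seqs


def write_alignment_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for label, seq in seqs.items():
            fh.write(f">{label}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    """Read a single rooted Newick tree with branch lengths.

    Tip labels must be unique; polytomies and unlabelled internal nodes are
    allowed. Missing branch lengths on non-root edges are an error because
    the downstream Brownian-motion covariance needs them.
    """
    text = str(path_or_string)
    if not text.lstrip().startswith("(") and Path(text).exists():
        text = Path(text).read_text(encoding="utf-8")
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse Newick: {exc}") from exc
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise FormatError("duplicate tip labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise FormatError(
                f"branch leading to {edge.head_node.taxon.label if edge.head_node.taxon else 'an internal node'} "
                "has no length; branch lengths are required"
            )
    return tree


def read_config(path: str | Path) -> dict:
    """Parse a flat key-value config file (YAML mapping, one level deep)."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a flat key-value mapping")
    for key, val in raw.items():
        if isinstance(val, (dict, list)):
            raise FormatError(f"{path}: config key {key!r} is nested; flat values only")
    return raw


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blanks and # comments skipped."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")
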