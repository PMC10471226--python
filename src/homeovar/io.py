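"""Readers and writers for the tabular formats used throughout the pipeline.

All tables are plain tab-separated text with a single header row; lines
starting with ``#`` are treated as comments. Genomic interval output (HE
segments) is BED6-style, 0-based half-open, expressed in *pair-order*
coordinates (order_index units along a homoeologous chromosome pair), not
base pairs: the dosage caller operates on gene windows, so gene rank is
the natural coordinate system.

Tables
------
pair table        pair_id, gene_C, gene_A, chrom_C, chrom_A, order_index
depth table       sample_id, pair_id, depth_C, depth_A
expression table  sample_id, pair_id, tpm_C, tpm_A
parental table    pair_id, tpm_oleracea, tpm_rapa  (replicate rows averaged)
sample meta       sample_id, line_id, generation
GO gene map       gene_id, go_id
GO class map      go_id, go_class  (I = dosage-insensitive, II = sensitive)
ortholog map      thaliana_gene, oleracea_gene
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

PAIR_COLUMNS = ["pair_id", "gene_C", "gene_A", "chrom_C", "chrom_A", "order_index"]
DEPTH_COLUMNS = ["sample_id", "pair_id", "depth_C", "depth_A"]
EXPRESSION_COLUMNS = ["sample_id", "pair_id", "tpm_C", "tpm_A"]
PARENTAL_COLUMNS = ["pair_id", "tpm_oleracea", "tpm_rapa"]
META_COLUMNS = ["sample_id", "line_id", "generation"]
VALID_GENERATIONS = (1, 5, 10)
GO_CLASSES = ("I", "II")
BED_COLUMNS = ["chrom_pair", "start_index", "end_index", "name", "score", "strand"]


def _read_tsv(path, required: list[str], what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {what} {path!r}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} {path!r} is missing column(s) {missing}")
    return df


def _write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# homoeolog pair map


def read_pair_table(path) -> pd.DataFrame:
    """Read the syntenic homoeolog pair map.

    Returns a frame sorted by (chrom_C, chrom_A, order_index) with an
    added ``chrom_pair`` column ("chrom_C/chrom_A"). Duplicated pair ids,
    or duplicated order_index within one chromosome pair, are rejected.
    """
    df = _read_tsv(path, PAIR_COLUMNS, "pair table")
    if df["pair_id"].duplicated().any():
        dups = df.loc[df["pair_id"].duplicated(), "pair_id"].head().tolist()
        raise ValidationError(f"duplicate pair_id(s) in pair table: {dups}")
    if df[["pair_id", "gene_C", "gene_A"]].isna().any().any():
        raise ValidationError("pair table has missing gene or pair ids")
    try:
        df["order_index"] = df["order_index"].astype(int)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"order_index must be integer: {exc}") from exc
    dup_order = df.duplicated(subset=["chrom_C", "chrom_A", "order_index"])
    if dup_order.any():
        bad = df.loc[dup_order, ["chrom_C", "chrom_A", "order_index"]].head()
        raise ValidationError(
            f"duplicate order_index within a chromosome pair:\n{bad}"
        )
    df = df.sort_values(["chrom_C", "chrom_A", "order_index"], kind="mergesort")
    df = df.reset_index(drop=True)
    df["chrom_pair"] = df["chrom_C"].astype(str) + "/" + df["chrom_A"].astype(str)
    return df


def write_pair_table(pairs: pd.DataFrame, path) -> None:
    _write_tsv(pairs[PAIR_COLUMNS], path)


# ---------------------------------------------------------------------------
# depth / expression / parental / meta


def read_depth_table(path) -> pd.DataFrame:
    """Read per-gene WGS read depths (one row per sample x pair)."""
    df = _read_tsv(path, DEPTH_COLUMNS, "depth table")
    depths = df[["depth_C", "depth_A"]].to_numpy(dtype=float)
    if (depths < 0).any():
        raise ValidationError("negative read depth in depth table")
    return df


def write_depth_table(depths: pd.DataFrame, path) -> None:
    _write_tsv(depths[DEPTH_COLUMNS], path)


def read_expression_table(path) -> pd.DataFrame:
    """Read polyploid homoeolog expression (TPM) per sample and pair."""
    df = _read_tsv(path, EXPRESSION_COLUMNS, "expression table")
    if (df[["tpm_C", "tpm_A"]].to_numpy(dtype=float) < 0).any():
        raise ValidationError("negative TPM in expression table")
    return df


def write_expression_table(expr: pd.DataFrame, path) -> None:
    _write_tsv(expr[EXPRESSION_COLUMNS], path)


def read_parental_table(path) -> pd.DataFrame:
    """Read progenitor ortholog expression (TPM per pair).

    Multiple rows per pair_id are interpreted as replicate libraries and
    averaged, giving a single stable parental baseline per pair.
    """
    df = _read_tsv(path, PARENTAL_COLUMNS, "parental table")
    if (df[["tpm_oleracea", "tpm_rapa"]].to_numpy(dtype=float) < 0).any():
        raise ValidationError("negative TPM in parental table")
    n_dup = int(df["pair_id"].duplicated().sum())
    if n_dup:
        log.info("parental table: averaging replicate rows for %d pair ids", n_dup)
        df = df.groupby("pair_id", as_index=False)[["tpm_oleracea", "tpm_rapa"]].mean()
    return df[PARENTAL_COLUMNS]


def write_parental_table(parental: pd.DataFrame, path) -> None:
    _write_tsv(parental[PARENTAL_COLUMNS], path)


def read_sample_meta(path) -> pd.DataFrame:
    df = _read_tsv(path, META_COLUMNS, "sample metadata")
    if df["generation"].isna().any():
        raise ValidationError("sample metadata: generation missing for some samples")
    df["generation"] = df["generation"].astype(int)
    bad = ~df["generation"].isin(VALID_GENERATIONS)
    if bad.any():
        raise ValidationError(
            f"generation must be one of {VALID_GENERATIONS}; "
            f"got {sorted(df.loc[bad, 'generation'].unique())}"
        )
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in sample metadata")
    return df


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    _write_tsv(meta[META_COLUMNS], path)


# ---------------------------------------------------------------------------
# GO annotation

def read_go_tables(go_path, class_path) -> pd.DataFrame:
    """Read gene-to-GO assignments joined with GO dosage classes.

    ``go_path`` maps gene ids to GO terms (columns gene_id, go_id);
    ``class_path`` maps GO terms to dosage classes (go_id, go_class with
    values I = dosage-insensitive, II = dosage-sensitive). GO terms absent
    from the class table are dropped with a warning, since they cannot be
    placed in either class downstream. A class label outside {I, II} is a
    validation error.
    """
    genes = _read_tsv(go_path, ["gene_id", "go_id"], "GO gene map")
    classes = _read_tsv(class_path, ["go_id", "go_class"], "GO class map")
    bad = ~classes["go_class"].isin(GO_CLASSES)
    if bad.any():
        raise ValidationError(
            f"GO class labels must be in {GO_CLASSES}; "
            f"got {sorted(classes.loc[bad, 'go_class'].unique())}"
        )
    classes = classes.drop_duplicates(subset="go_id")
    merged = genes.merge(classes, on="go_id", how="left")
    unclassed = merged["go_class"].isna()
    if unclassed.any():
        dropped = sorted(merged.loc[unclassed, "go_id"].unique())
        log.warning(
            "dropping %d GO term(s) with no dosage class: %s%s",
            len(dropped), dropped[:5], "..." if len(dropped) > 5 else "",
        )
        merged = merged[~unclassed]
    return merged.reset_index(drop=True)


def read_ortholog_map(path) -> pd.DataFrame:
    """Read the A. thaliana -> B. oleracea ortholog edges used to chain
    thaliana GO annotations onto Brassica homoeolog pairs."""
    return _read_tsv(path, ["thaliana_gene", "oleracea_gene"], "ortholog map")


# ---------------------------------------------------------------------------
# HE segments (BED)


def write_segments_bed(segments: Iterable, path) -> None:
    """Write HE segments as BED6 in pair-order coordinates.

    Intervals are 0-based half-open over order_index; the name field is
    ``sample_id|dosage_class`` and the score is the gene count. Segments
    may be any objects exposing sample_id, chrom_pair, start_index,
    end_index and dosage_class attributes.
    """
    rows = []
    for seg in segments:
        start, end = int(seg.start_index), int(seg.end_index)
        if end <= start:
            raise ValidationError(
                f"segment end ({end}) must exceed start ({start})"
            )
        rows.append(
            (seg.chrom_pair, start, end,
             f"{seg.sample_id}|{seg.dosage_class}", end - start, ".")
        )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_segments_bed(path) -> pd.DataFrame:
    """Read a BED file written by :func:`write_segments_bed` back into a
    frame with columns chrom_pair, start_index, end_index, sample_id,
    dosage_class, n_genes."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path!r}:{line_no}: expected 6 BED columns")
            chrom, start, end, name, score, _strand = fields[:6]
            sample_id, _, dosage_class = name.rpartition("|")
            rows.append(
                (chrom, int(start), int(end), sample_id, dosage_class,
                 int(end) - int(start))
            )
    return pd.DataFrame(
        rows,
        columns=["chrom_pair", "start_index", "end_index", "sample_id",
                 "dosage_class", "n_genes"],
    )
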