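"""TSV readers and writers for every table the pipeline exchanges.

All interchange formats are plain tab-separated text (gzip accepted on
read via pandas' transparent decompression):

* count matrix — first column ``gene_id``, one column per sample;
* sample metadata — ``sample_id``, genotype, maternal/paternal strain,
  diet, replicate, optional ``body_weight_g``;
* allelic SNP table — ``snp_id``, ``gene_id``, ``chrom``, ``pos`` (1-based),
  ``exonic``, then per-sample paired columns ``<sample>_b6`` / ``<sample>_pwk``;
* imprint annotation — ``gene_id``, ``status`` (PEG or MEG).

Readers validate and raise :class:`~poeseq.datatypes.ValidationError` with
the offending identifier; writers and readers are mutual inverses on valid
data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    AllelicSnpTable,
    ValidationError,
    validate_counts,
    validate_meta,
)

ALLELIC_FIXED_COLS = ["gene_id", "chrom", "pos", "exonic"]


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kw)
    except pd.errors.ParserError as err:
        raise ValidationError(f"{path}: malformed TSV ({err})") from err


def read_count_matrix(path) -> pd.DataFrame:
    df = _read_tsv(path, index_col=0)
    df.index.name = "gene_id"
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValidationError(f"{path}: non-numeric counts in column {col!r}")
    return validate_counts(df).astype(np.int64)


def write_count_matrix(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_sample_meta(path) -> pd.DataFrame:
    df = _read_tsv(path, index_col=0)
    df.index.name = "sample_id"
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate sample ids: {dup[:5]}")
    return validate_meta(df)


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta.rename_axis("sample_id").to_csv(path, sep="\t")


def read_allelic_table(path, meta: pd.DataFrame) -> AllelicSnpTable:
    """Read the wide allelic TSV; cross directions come from the metadata."""
    df = _read_tsv(path, index_col=0)
    df.index.name = "snp_id"
    missing = [c for c in ALLELIC_FIXED_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    count_cols = [c for c in df.columns if c not in ALLELIC_FIXED_COLS]
    if len(count_cols) % 2:
        raise ValidationError(f"{path}: odd number of allele-count columns")
    samples, b6_cols, pwk_cols = [], [], []
    for col in count_cols:
        if col.endswith("_b6"):
            sample = col[:-3]
            pair = f"{sample}_pwk"
            if pair not in df.columns:
                raise ValidationError(f"{path}: column {col!r} lacks its pair {pair!r}")
            samples.append(sample)
            b6_cols.append(col)
            pwk_cols.append(pair)
        elif not col.endswith("_pwk"):
            raise ValidationError(f"{path}: unrecognized column {col!r}")
    b6 = df[b6_cols].astype(np.int64)
    b6.columns = samples
    pwk = df[pwk_cols].astype(np.int64)
    pwk.columns = samples
    unknown = [s for s in samples if s not in meta.index]
    if unknown:
        raise ValidationError(f"{path}: samples absent from metadata: {unknown[:5]}")
    snps = df[ALLELIC_FIXED_COLS].copy()
    snps["exonic"] = snps["exonic"].astype(bool)
    return AllelicSnpTable(
        snps=snps, b6=b6, pwk=pwk, cross=meta.loc[samples, "genotype"]
    )


def write_allelic_table(table: AllelicSnpTable, path) -> None:
    out = table.snps.copy()
    for s in table.samples:
        out[f"{s}_b6"] = table.b6[s]
        out[f"{s}_pwk"] = table.pwk[s]
    out.rename_axis("snp_id").to_csv(path, sep="\t")


def read_annotation(path) -> pd.Series:
    df = _read_tsv(path, index_col=0)
    df.index.name = "gene_id"
    if "status" not in df.columns:
        raise ValidationError(f"{path}: annotation needs a 'status' column")
    if df.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate gene ids in annotation")
    bad = set(df["status"]) - {"PEG", "MEG"}
    if bad:
        raise ValidationError(f"{path}: unknown status labels {sorted(bad)}")
    return df["status"]


def write_annotation(status: pd.Series, path) -> None:
    status.rename("status").rename_axis("gene_id").to_csv(path, sep="\t")


def write_de_table(result, path) -> None:
    """Write a DEResult table (gene_id, means, fold, log2fc, p, direction)."""
    result.table.rename_axis("gene_id").to_csv(path, sep="\t")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.rename_axis("gene_id").to_csv(path, sep="\t")


def read_truth(path) -> pd.DataFrame:
    return _read_tsv(path, index_col=0)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
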