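"""Imprinted-gene expression vs body weight, and diet-shift asymmetry.

Paternally expressed genes (PEGs) are predicted to act as anti-obesity
genes and maternally expressed genes (MEGs) as pro-obesity genes; this
module computes the per-gene Pearson correlation between normalized
expression and body weight, the within-genotype high-fat-diet expression
shift of each imprinted gene, and a 1-df chi-square goodness-of-fit test
of whether significantly shifted genes of one class are predominantly
down- (PEG) or up- (MEG) regulated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import NormalizedExpression, ValidationError

__all__ = [
    "load_annotation",
    "expressed_imprinted",
    "weight_correlation",
    "hfd_shift",
    "direction_chisq",
]


def load_annotation(ann: pd.DataFrame) -> pd.Series:
    """Validate a gene -> PEG/MEG annotation (index gene_id, column status)."""
    status = ann["status"] if isinstance(ann, pd.DataFrame) else ann
    if status.index.has_duplicates:
        raise ValidationError("duplicate gene ids in imprint annotation")
    bad = set(status) - {"PEG", "MEG"}
    if bad:
        raise ValidationError(f"unknown imprint status labels: {sorted(bad)}")
    return status


def expressed_imprinted(
    counts: pd.DataFrame,
    annotation: pd.Series | pd.DataFrame,
    min_mean_count: float = 5.0,
) -> tuple[pd.Series, list[str]]:
    """Annotated imprinted genes passing the expression floor.

    Returns (status Series over expressed imprinted genes, list of
    annotation genes absent from the matrix).  A gene counts as expressed
    when its mean raw count across all samples is >= ``min_mean_count``.
    """
    status = load_annotation(annotation)
    if status.empty:
        raise ValidationError("empty imprint annotation")
    present = status.index.intersection(counts.index)
    missing = [g for g in status.index if g not in counts.index]
    expressed = present[counts.loc[present].mean(axis=1) >= min_mean_count]
    return status.loc[expressed], missing


def weight_correlation(
    norm: NormalizedExpression,
    weights: pd.Series,
    status: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r between each imprinted gene's expression and body weight.

    Computed across all samples; genes with constant expression get a
    missing r.  Returns (per-gene table, per-status summary with median and
    quartiles of r).
    """
    samples = norm.values.columns
    w = weights.reindex(samples)
    if w.isna().any():
        missing = list(samples[w.isna()])
        raise ValidationError(f"body weight missing for samples: {missing[:5]}")
    if len(samples) < 3:
        raise ValidationError("need at least 3 samples for correlation")
    wv = w.to_numpy(dtype=float)
    rows = []
    for gene in status.index:
        x = norm.values.loc[gene].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(wv) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(x, wv)[0, 1])
        rows.append(
            {"gene_id": gene, "status": status[gene], "r": r, "n": len(samples)}
        )
    table = pd.DataFrame(rows).set_index("gene_id")
    summary = (
        table.dropna(subset=["r"])
        .groupby("status")["r"]
        .agg(
            n="count",
            median_r="median",
            q1_r=lambda s: s.quantile(0.25),
            q3_r=lambda s: s.quantile(0.75),
        )
        .reset_index()
    )
    return table, summary


def hfd_shift(
    norm: NormalizedExpression,
    meta: pd.DataFrame,
    genotype: str,
    status: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mean normalized-expression difference (HFD - Con) per imprinted gene
    within one genotype, with a two-sided Student's t p-value.

    Zero-variance degenerate case: p = 0 when the group means differ and 1
    when they are equal.
    """
    sub = meta[meta["genotype"] == genotype]
    hfd = list(sub.index[sub["diet"] == "HFD"])
    con = list(sub.index[sub["diet"] == "Con"])
    if len(hfd) < 2 or len(con) < 2:
        raise ValidationError(
            f"genotype {genotype} needs >= 2 replicates in both diet groups"
        )
    rows = []
    for gene in status.index:
        a = norm.values.loc[gene, hfd].to_numpy(dtype=float)
        b = norm.values.loc[gene, con].to_numpy(dtype=float)
        diff = float(a.mean() - b.mean())
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            p = 0.0 if diff != 0 else 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        rows.append(
            {
                "gene_id": gene,
                "status": status[gene],
                "shift": diff,
                "p": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def direction_chisq(shifts: pd.DataFrame, status: str) -> dict[str, float]:
    """Test whether significant shifts of one imprint class are one-sided.

    Among genes of the given status with a significant diet shift, performs
    a 1-df chi-square goodness-of-fit of the observed down/up split against
    a 50:50 expectation.  Rejects when no gene of the status shifted
    significantly.
    """
    sub = shifts[(shifts["status"] == status) & shifts["significant"]]
    n_down = int((sub["shift"] < 0).sum())
    n_up = int((sub["shift"] > 0).sum())
    n = n_down + n_up
    if n == 0:
        raise ValidationError(f"no significant shifts for status {status}")
    chi2 = (n_down - n / 2) ** 2 / (n / 2) + (n_up - n / 2) ** 2 / (n / 2)
    p = float(stats.chi2.sf(chi2, df=1))
    return {
        "status": status,
        "n_down": n_down,
        "n_up": n_up,
        "chi2": float(chi2),
        "df": 1,
        "p": p,
    }
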