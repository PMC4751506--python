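"""SNP-based screen for imprinted genes from reciprocal F1 hybrids.

In an F1 from a B6 mother and PWK father (BxP_F1) the PWK allele is
paternal; in the reciprocal cross (PxB_F1) it is maternal.  Comparing the
PWK-allele expression fraction between the two cross directions therefore
separates parent-of-origin effects (mirror-image fractions) from
strain/cis effects (equal fractions in both crosses).

Filtering: SNPs on the Y chromosome, SNPs outside annotated exons, SNPs
with mean total depth below 10 across the F1 mice, and SNPs with any mouse
at zero depth are excluded (each rule's removals are tallied).

Strict screen: a SNP qualifies for a PEG call when the mean paternal-allele
fraction exceeds 0.99 in both crosses (a per-mouse variant is selectable);
one qualifying SNP calls the gene.  MEGs use the maternal fraction
symmetrically.

Mild screen (for partially imprinted genes): a SNP qualifies for a PEG
call when (1) per-mouse PWK-allele fractions are significantly higher in
BxP_F1 than PxB_F1 (Student's t, p < 0.05, one direction), (2) the
cross-mean PWK fraction is over 0.50 in BxP_F1 and under 0.50 in PxB_F1,
and (3) the cross means differ by at least 0.20; a gene is called with at
least four qualifying SNPs.  MEG criteria are the same on B6-allele
fractions (equivalently, all inequalities mirrored).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AllelicSnpTable, ScreenThresholds, ValidationError

__all__ = [
    "compute_fractions",
    "filter_snps",
    "screen_strict",
    "screen_mild",
    "run_screen",
    "annotate_known",
]

log = logging.getLogger(__name__)

FILTER_RULES = ("chrY", "non_exonic", "low_depth", "zero_read_mouse")


def compute_fractions(table: AllelicSnpTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP, per-sample PWK-allele fraction and total depth.

    Samples with zero depth at a SNP yield a missing (NaN) fraction.
    """
    if len(table.snps) == 0:
        raise ValidationError("empty allelic table")
    total = table.total()
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = table.pwk / total
    return frac.where(total > 0), total


def filter_snps(
    table: AllelicSnpTable, thresholds: ScreenThresholds | None = None
) -> tuple[AllelicSnpTable, dict[str, int]]:
    """Apply the SNP exclusion rules; return the kept table and per-rule tallies.

    Rules are applied in order (Y chromosome, non-exonic, mean depth
    strictly below ``min_avg_depth``, any mouse with zero reads); each SNP
    is attributed to the first rule that removes it, so
    input = retained + sum of tallies.
    """
    thresholds = thresholds or ScreenThresholds()
    total = table.total()
    excl: dict[str, int] = {}
    alive = pd.Series(True, index=table.snps.index)

    is_y = table.snps["chrom"].astype(str).str.lower() == "chry"
    excl["chrY"] = int((alive & is_y).sum())
    alive &= ~is_y

    non_exonic = ~table.snps["exonic"].astype(bool)
    excl["non_exonic"] = int((alive & non_exonic).sum())
    alive &= ~non_exonic

    low = total.mean(axis=1) < thresholds.min_avg_depth
    excl["low_depth"] = int((alive & low).sum())
    alive &= ~low

    zero = (total == 0).any(axis=1)
    excl["zero_read_mouse"] = int((alive & zero).sum())
    alive &= ~zero

    return table.subset(table.snps.index[alive]), excl


def _cross_split(table: AllelicSnpTable) -> tuple[list[str], list[str]]:
    bxp = table.samples_of("BxP_F1")
    pxb = table.samples_of("PxB_F1")
    return bxp, pxb


@dataclass
class ScreenResult:
    """Candidate calls plus per-SNP qualification diagnostics."""

    mode: str
    candidates: pd.DataFrame
    snp_calls: pd.DataFrame
    n_qualifying_snps: dict[str, int] = field(default_factory=dict)


def _gene_summary(
    table: AllelicSnpTable,
    frac: pd.DataFrame,
    qual: pd.DataFrame,
    mode: str,
    min_snps: int,
    bxp: list[str],
    pxb: list[str],
) -> ScreenResult:
    """Aggregate per-SNP PEG/MEG qualification flags into gene calls."""
    gene_of = table.snps["gene_id"]
    rows = []
    for call in ("PEG", "MEG"):
        n_by_gene = qual[call].groupby(gene_of).sum()
        for gene, n in n_by_gene[n_by_gene >= min_snps].items():
            snp_ids = table.snps.index[(gene_of == gene).to_numpy()]
            rows.append(
                {
                    "gene_id": gene,
                    "call": call,
                    "mode": mode,
                    "n_qualifying_snps": int(n),
                    "mean_pwk_fraction_BxP": float(
                        np.nanmean(frac.loc[snp_ids, bxp].to_numpy())
                    ),
                    "mean_pwk_fraction_PxB": float(
                        np.nanmean(frac.loc[snp_ids, pxb].to_numpy())
                    ),
                }
            )
    candidates = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "call",
            "mode",
            "n_qualifying_snps",
            "mean_pwk_fraction_BxP",
            "mean_pwk_fraction_PxB",
        ],
    ).sort_values(["call", "gene_id"]).reset_index(drop=True)
    snp_calls = pd.concat([table.snps[["gene_id"]], qual], axis=1)
    return ScreenResult(mode=mode, candidates=candidates, snp_calls=snp_calls)


def screen_strict(
    table: AllelicSnpTable, thresholds: ScreenThresholds | None = None
) -> ScreenResult:
    """Strict screen: near-exclusive monoallelic expression in both crosses."""
    thresholds = thresholds or ScreenThresholds()
    frac, _ = compute_fractions(table)
    bxp, pxb = _cross_split(table)
    if not bxp or not pxb:
        raise ValidationError("strict screen requires samples from both cross directions")

    # paternal fraction: PWK fraction in BxP_F1 mice, B6 (=1-PWK) in PxB_F1 mice
    pat_bxp = frac[bxp]
    pat_pxb = 1.0 - frac[pxb]
    cut = thresholds.strict_fraction
    if thresholds.strict_per_sample:
        peg = (pat_bxp > cut).all(axis=1) & (pat_pxb > cut).all(axis=1)
        peg &= pat_bxp.notna().all(axis=1) & pat_pxb.notna().all(axis=1)
        meg = ((1 - pat_bxp) > cut).all(axis=1) & ((1 - pat_pxb) > cut).all(axis=1)
        meg &= pat_bxp.notna().all(axis=1) & pat_pxb.notna().all(axis=1)
    else:
        mb, mp = pat_bxp.mean(axis=1), pat_pxb.mean(axis=1)
        peg = (mb > cut) & (mp > cut)
        meg = ((1 - mb) > cut) & ((1 - mp) > cut)
    qual = pd.DataFrame({"PEG": peg, "MEG": meg})
    return _gene_summary(
        table, frac, qual, "strict", thresholds.min_snps_strict, bxp, pxb
    )


def screen_mild(
    table: AllelicSnpTable, thresholds: ScreenThresholds | None = None
) -> ScreenResult:
    """Mild screen: significant, majority-switching, well-separated allelic bias."""
    thresholds = thresholds or ScreenThresholds()
    frac, _ = compute_fractions(table)
    bxp, pxb = _cross_split(table)
    if not bxp or not pxb:
        raise ValidationError("mild screen requires samples from both cross directions")

    fb = frac[bxp].to_numpy()
    fp = frac[pxb].to_numpy()
    nx = np.sum(~np.isnan(fb), axis=1)
    ny = np.sum(~np.isnan(fp), axis=1)
    usable = (nx >= 2) & (ny >= 2)  # else too few informative mice: SNP skipped
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mx = np.nanmean(np.where(usable[:, None], fb, np.nan), axis=1)
        my = np.nanmean(np.where(usable[:, None], fp, np.nan), axis=1)
        vx = np.nanvar(fb, axis=1, ddof=1)
        vy = np.nanvar(fp, axis=1, ddof=1)
        if thresholds.t_variant == "student":
            dfree = nx + ny - 2
            s2 = ((nx - 1) * vx + (ny - 1) * vy) / dfree
            tstat = (mx - my) / np.sqrt(s2 * (1.0 / nx + 1.0 / ny))
        elif thresholds.t_variant == "welch":
            se2 = vx / nx + vy / ny
            tstat = (mx - my) / np.sqrt(se2)
            dfree = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        else:
            raise ValidationError(f"unknown t-test variant: {thresholds.t_variant!r}")
        p = 2.0 * stats.t.sf(np.abs(tstat), np.maximum(dfree, 1e-300))
    # zero-variance degenerate case: p = 0 when means differ, 1 when equal
    degen = (vx == 0) & (vy == 0)
    p = np.where(degen, np.where(mx != my, 0.0, 1.0), p)
    sig = usable & (p < thresholds.alpha)

    # PEG: PWK (paternal in BxP) fraction higher in BxP, majority switch, gap;
    # MEG: B6 (maternal in BxP) fraction higher in BxP — mirrored inequalities
    maj, gap = thresholds.majority, thresholds.min_gap
    with np.errstate(invalid="ignore"):
        peg = sig & (mx > my) & (mx > maj) & (my < maj) & ((mx - my) >= gap)
        meg = sig & (my > mx) & (mx < maj) & (my > maj) & ((my - mx) >= gap)
    qual = pd.DataFrame({"PEG": peg, "MEG": meg}, index=frac.index)
    return _gene_summary(table, frac, qual, "mild", thresholds.min_snps_mild, bxp, pxb)


def run_screen(
    table: AllelicSnpTable,
    thresholds: ScreenThresholds | None = None,
    mode: str = "mild",
) -> tuple[ScreenResult, dict[str, int]]:
    """Filter SNPs then run the requested screen; returns result + exclusion tallies."""
    thresholds = thresholds or ScreenThresholds()
    filtered, excl = filter_snps(table, thresholds)
    if mode == "strict":
        res = screen_strict(filtered, thresholds)
    elif mode == "mild":
        res = screen_mild(filtered, thresholds)
    else:
        raise ValidationError(f"unknown screen mode: {mode!r}")
    return res, excl


def annotate_known(
    candidates: pd.DataFrame, known: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Mark candidates as known imprinted genes or novel.

    ``known``: DataFrame with a ``status`` column (PEG/MEG) indexed by
    gene_id.  A candidate whose called parental origin contradicts the
    annotation is flagged as a conflict.  Returns the annotated table and a
    summary {n_known, n_novel, n_conflict}.
    """
    out = candidates.copy()
    status = known["status"]
    known_status = []
    for _, row in out.iterrows():
        if row["gene_id"] not in status.index:
            known_status.append("novel")
        elif status[row["gene_id"]] == row["call"]:
            known_status.append("known")
        else:
            known_status.append("conflict")
    out["known_status"] = known_status
    summary = {
        "n_known": known_status.count("known"),
        "n_novel": known_status.count("novel"),
        "n_conflict": known_status.count("conflict"),
    }
    return out, summary
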