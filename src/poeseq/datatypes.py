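"""Shared containers and validation for the reciprocal-cross expression pipeline.

The pipeline works on three tables:

* a count matrix — genes x samples, nonnegative integers (a DataFrame with
  gene ids as index and sample ids as columns);
* sample metadata — one row per sample (genotype, parental strains, diet,
  replicate, body weight);
* an allele-specific SNP table — per-SNP B6/PWK read counts in the two
  reciprocal F1 hybrids.

Genotype labels: ``B6`` and ``PWK`` are the parental inbred strains;
``BxP_F1`` is the offspring of a B6 mother and PWK father, ``PxB_F1`` the
reverse cross.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("B6", "PWK", "BxP_F1", "PxB_F1")
DIETS = ("Con", "HFD")
F1_GENOTYPES = ("BxP_F1", "PxB_F1")

#: maternal/paternal strain for each genotype label
PARENTAGE: dict[str, tuple[str, str]] = {
    "B6": ("B6", "B6"),
    "PWK": ("PWK", "PWK"),
    "BxP_F1": ("B6", "PWK"),   # B6 mother x PWK father
    "PxB_F1": ("PWK", "B6"),   # PWK mother x B6 father
}

META_COLUMNS = (
    "genotype",
    "maternal_strain",
    "paternal_strain",
    "diet",
    "replicate",
    "body_weight_g",
)


class ValidationError(ValueError):
    """Raised when an input table violates its documented contract."""


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check a gene x sample count matrix: unique ids, integral, nonnegative."""
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids: {dup[:5]}")
    if counts.columns.has_duplicates:
        dup = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dup[:5]}")
    if counts.shape[1] < 2:
        raise ValidationError("count matrix needs at least 2 samples")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError("count matrix contains non-numeric cells")
    if np.any(values < 0):
        raise ValidationError("count matrix contains negative values")
    if not np.allclose(values, np.round(values)):
        raise ValidationError("count matrix contains non-integer values")
    return counts


def validate_meta(meta: pd.DataFrame, samples=None) -> pd.DataFrame:
    """Check sample metadata; optionally that it covers ``samples`` exactly."""
    missing = [c for c in META_COLUMNS if c not in meta.columns and c != "body_weight_g"]
    if missing:
        raise ValidationError(f"sample metadata missing columns: {missing}")
    bad = set(meta["genotype"]) - set(GENOTYPES)
    if bad:
        raise ValidationError(f"unknown genotype labels: {sorted(bad)}")
    bad = set(meta["diet"]) - set(DIETS)
    if bad:
        raise ValidationError(f"unknown diet labels: {sorted(bad)}")
    for geno, grp in meta.groupby("genotype"):
        mat, pat = PARENTAGE[str(geno)]
        if not ((grp["maternal_strain"] == mat) & (grp["paternal_strain"] == pat)).all():
            raise ValidationError(f"inconsistent parentage for genotype {geno}")
    if samples is not None:
        want = list(samples)
        have = set(meta.index)
        lost = [s for s in want if s not in have]
        if lost:
            raise ValidationError(f"metadata missing samples: {lost[:5]}")
    return meta


@dataclass
class NormalizedExpression:
    """Log2 normalized, per-gene median-baselined expression.

    ``values`` holds ``log2(CPM + 1)`` minus the per-gene median over all
    samples; ``cpm`` the TMM-scaled counts-per-million before the log;
    ``factors`` the TMM normalization factors (geometric mean 1) and
    ``library_sizes`` the raw column totals.
    """

    values: pd.DataFrame
    cpm: pd.DataFrame
    factors: pd.Series
    library_sizes: pd.Series


@dataclass
class DEThresholds:
    """Cutoffs for calling a gene differentially expressed.

    Both comparisons are strict: ``p < p_max`` and linear fold ``> fold_min``
    (or ``< 1/fold_min`` for down-regulation).
    """

    p_max: float = 0.05
    fold_min: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.p_max < 1:
            raise ValidationError(f"p_max must be in (0, 1), got {self.p_max}")
        if not self.fold_min > 1:
            raise ValidationError(f"fold_min must exceed 1, got {self.fold_min}")


@dataclass
class DEResult:
    """Per-gene differential expression for one named contrast.

    ``table`` columns: ``mean_a``, ``mean_b`` (linear normalized group means,
    pseudo-count included), ``fold`` (a/b), ``log2fc``, ``t``, ``p``,
    ``direction`` in {``up``, ``down``, ``ns``}.
    """

    contrast: str
    table: pd.DataFrame
    thresholds: DEThresholds = field(default_factory=DEThresholds)

    @property
    def up(self) -> pd.Index:
        return self.table.index[self.table["direction"] == "up"]

    @property
    def down(self) -> pd.Index:
        return self.table.index[self.table["direction"] == "down"]

    def directions(self) -> pd.Series:
        return self.table["direction"]


@dataclass
class AllelicSnpTable:
    """Allele-specific read counts at B6/PWK-discriminating SNPs in F1 mice.

    ``snps``: one row per SNP (index snp_id) with gene_id, chrom, pos
    (1-based), exonic flag. ``b6`` / ``pwk``: SNP x F1-sample count matrices
    sharing the snp index. ``cross``: sample -> cross direction
    (``BxP_F1`` or ``PxB_F1``).
    """

    snps: pd.DataFrame
    b6: pd.DataFrame
    pwk: pd.DataFrame
    cross: pd.Series

    def __post_init__(self) -> None:
        if self.snps.index.has_duplicates:
            raise ValidationError("duplicate snp ids")
        for name, mat in (("b6", self.b6), ("pwk", self.pwk)):
            if not mat.index.equals(self.snps.index):
                raise ValidationError(f"{name} counts not aligned with snp table")
            if (mat.to_numpy() < 0).any():
                raise ValidationError(f"negative {name} counts")
        if not self.b6.columns.equals(self.pwk.columns):
            raise ValidationError("b6/pwk sample columns differ")
        bad = set(self.cross.loc[self.b6.columns]) - set(F1_GENOTYPES)
        if bad:
            raise ValidationError(f"unknown cross-direction labels: {sorted(bad)}")

    @property
    def samples(self) -> pd.Index:
        return self.b6.columns

    def samples_of(self, direction: str) -> list[str]:
        return [s for s in self.samples if self.cross[s] == direction]

    def total(self) -> pd.DataFrame:
        """Total depth per SNP x sample."""
        return self.b6 + self.pwk

    def subset(self, snp_ids) -> "AllelicSnpTable":
        return AllelicSnpTable(
            snps=self.snps.loc[snp_ids],
            b6=self.b6.loc[snp_ids],
            pwk=self.pwk.loc[snp_ids],
            cross=self.cross,
        )


@dataclass
class ScreenThresholds:
    """Filters and cutoffs of the SNP-based imprinting screen.

    ``min_avg_depth``: SNPs whose mean total depth across all F1 mice is
    strictly below this are dropped. ``strict_fraction``: the parental
    allele fraction must strictly exceed this in both cross directions in
    the strict screen — evaluated on the per-cross mean of per-mouse
    fractions by default (``strict_per_sample`` demands it of every mouse
    instead, a much harsher rule at finite depth: at depth 50 a single
    opposite-allele read drops a mouse to 98%).
    ``majority`` / ``min_gap``: cross-mean criteria of the mild screen (the
    gap is inclusive, "at least 20%" read as 0.20 absolute allele fraction).
    """

    min_avg_depth: float = 10.0
    strict_fraction: float = 0.99
    majority: float = 0.50
    min_gap: float = 0.20
    alpha: float = 0.05
    min_snps_mild: int = 4
    min_snps_strict: int = 1
    t_variant: str = "student"        # or "welch"
    strict_per_sample: bool = False   # True: apply 99% rule to every mouse

    def __post_init__(self) -> None:
        if not 0.5 < self.strict_fraction < 1:
            raise ValidationError("strict_fraction must be in (0.5, 1)")
        if not 0 < self.min_gap < 1:
            raise ValidationError("min_gap must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
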