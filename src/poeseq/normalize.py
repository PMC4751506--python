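"""Between-sample normalization and QC.

TMM (trimmed mean of M-values) estimates a scaling factor for each library
from precision-weighted, doubly trimmed log-ratios of counts against a
reference library, on the assumption that most genes are not differentially
expressed.  The implementation follows the reference method's conventions:
the reference is the sample whose 75th-percentile count-per-library-size is
closest to the mean of those quantiles; per gene, M = log2 ratio of relative
abundances and A = average log2 relative abundance; the top and bottom 30%
of M and 5% of A are trimmed (by ranks); the remaining M values are averaged
with inverse asymptotic-variance (delta-method binomial) weights; factors
are rescaled to geometric mean 1.

One deliberate difference from the Bioconductor implementation: the
precision weights are computed on relative abundances, (1-p)/p per library
summed over the two libraries, i.e. the asymptotic variance of M per
sequenced read.  Using raw depths instead makes the factors depend on the
absolute sequencing depth, so multiplying one library by a constant would
perturb every factor; with per-read weights the whole algorithm is exactly
scale-invariant (the two weightings agree closely when depths are similar,
and the factors track the Bioconductor ones to a few parts in 10^4 on
typical data — see the cross-check test).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import NormalizedExpression, ValidationError, validate_counts

__all__ = ["tmm_factors", "normalize_log_baseline", "normalize", "replicate_correlation"]

MIN_USABLE_GENES = 10


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    trim_m: float,
    trim_a: float,
    min_usable: int,
) -> float:
    """TMM factor of one library against the reference (linear scale)."""
    p_obs = obs / obs.sum()
    p_ref = ref / ref.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2(p_obs / p_ref)
        abs_e = (np.log2(p_obs) + np.log2(p_ref)) / 2.0
        v = (1.0 - p_obs) / p_obs + (1.0 - p_ref) / p_ref
    keep = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[keep], abs_e[keep], v[keep]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    trimmed = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if trimmed.sum() < min_usable:
        warnings.warn(
            f"only {int(trimmed.sum())} genes left after trimming; falling back to factor 1",
            stacklevel=3,
        )
        return 1.0
    f = np.sum(log_r[trimmed] / v[trimmed]) / np.sum(1.0 / v[trimmed])
    return float(2.0**f) if np.isfinite(f) else 1.0


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    min_usable: int = MIN_USABLE_GENES,
) -> pd.Series:
    """Per-sample TMM normalization factors, rescaled to geometric mean 1.

    Samples with fewer than ``min_usable`` genes surviving the double trim
    fall back to factor 1 with a warning.
    """
    validate_counts(counts)
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        bad = counts.columns[lib <= 0].tolist()
        raise ValidationError(f"samples with zero total count: {bad}")
    # reference: library whose upper-quartile relative count is most typical
    q75 = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    ref = x[:, ref_idx]
    factors = np.array(
        [_tmm_pair(x[:, j], ref, trim_m, trim_a, min_usable) for j in range(x.shape[1])]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def normalize_log_baseline(
    counts: pd.DataFrame, factors: pd.Series
) -> NormalizedExpression:
    """log2(TMM-scaled CPM + 1), median-baselined per gene.

    value = log2(count / (library_size x factor) x 1e6 + 1) minus the
    per-gene median across all samples, so each gene's profile is centred
    on its own typical level.
    """
    validate_counts(counts)
    factors = factors.reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValidationError("normalization factors must be positive, one per sample")
    lib = counts.sum(axis=0)
    cpm = counts / (lib * factors) * 1e6
    logx = np.log2(cpm + 1.0)
    values = logx.sub(logx.median(axis=1), axis=0)
    return NormalizedExpression(
        values=values, cpm=cpm, factors=factors, library_sizes=lib
    )


def normalize(counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05) -> NormalizedExpression:
    """TMM factors + log/median-baseline in one call."""
    return normalize_log_baseline(counts, tmm_factors(counts, trim_m, trim_a))


def replicate_correlation(
    norm: NormalizedExpression,
    meta: pd.DataFrame,
    group_cols: tuple[str, ...] = ("genotype", "diet"),
) -> pd.DataFrame:
    """Pairwise Pearson correlation of replicates within each experimental group.

    Returns one row per within-group sample pair (group, sample_a, sample_b, r)
    plus the group means under sample_a = sample_b = "<mean>".  Constant
    expression vectors give r = NaN.
    """
    rows = []
    for key, grp in meta.groupby(list(group_cols), sort=False):
        samples = list(grp.index)
        if len(samples) < 2:
            raise ValidationError(f"group {key} has fewer than 2 samples")
        label = "/".join(map(str, key if isinstance(key, tuple) else (key,)))
        rs = []
        for i, a in enumerate(samples):
            for b in samples[i + 1:]:
                va = norm.values[a].to_numpy()
                vb = norm.values[b].to_numpy()
                if va.std() == 0 or vb.std() == 0:
                    r = np.nan
                else:
                    r = float(np.corrcoef(va, vb)[0, 1])
                rows.append({"group": label, "sample_a": a, "sample_b": b, "r": r})
                rs.append(r)
        rows.append(
            {
                "group": label,
                "sample_a": "<mean>",
                "sample_b": "<mean>",
                "r": float(np.nanmean(rs))
                if rs and not np.all(np.isnan(rs))
                else np.nan,
            }
        )
    return pd.DataFrame(rows)
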