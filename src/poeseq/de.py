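"""Differential expression: empirical-Bayes moderated t-test and DE calling.

With n = 3 mice per group, gene-wise variance estimates are unstable; the
moderated t-test shrinks each gene's pooled variance toward a common prior
value, with the prior variance s0^2 and prior degrees of freedom d0
estimated from the across-gene distribution of sample variances by matching
the moments of log s^2 under a scaled-F model.  The moderated statistic

    t_g = (mean_a - mean_b) / sqrt(s2_post_g * (1/n_a + 1/n_b)),
    s2_post_g = (d_g * s2_g + d0 * s0^2) / (d_g + d0)

is referred to a t distribution on d_g + d0 degrees of freedom.  Forcing
d0 = 0 recovers the ordinary pooled-variance t-test exactly; a Welch
t-test is selectable as an alternative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import DEResult, DEThresholds, NormalizedExpression, ValidationError

__all__ = ["fit_f_dist", "moderated_t", "call_de", "diet_contrasts", "select_samples"]


def _trigamma(x):
    return special.polygamma(1, x)


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = _trigamma(y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if -dif / y < 1e-8:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df1: float) -> tuple[float, float]:
    """Fit a scaled F distribution to sample variances.

    Models s2 ~ s0^2 * F(df1, df0) and returns (df0, s0^2), matching the
    mean and variance of log s2 (df0 may be ``inf`` when the variances are
    underdispersed relative to pure chi-square noise).
    """
    x = np.asarray(s2, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValidationError("need at least 2 finite variances to fit a prior")
    x = np.maximum(x, 0.0)
    m = np.median(x)
    if m == 0:
        m = 1.0
    x = np.maximum(x, 1e-5 * m)
    z = np.log(x)
    e = z - special.digamma(df1 / 2.0) + np.log(df1 / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - _trigamma(df1 / 2.0)
    if evar > 0:
        df0 = 2.0 * trigamma_inverse(evar)
        s20 = np.exp(emean + special.digamma(df0 / 2.0) - np.log(df0 / 2.0))
    else:
        # log-variances underdispersed relative to pure chi-square noise:
        # infinite prior df, common variance estimated by the plain mean
        # (exact when all gene variances coincide)
        df0 = np.inf
        s20 = np.mean(x)
    return float(df0), float(s20)


def moderated_t(
    values: pd.DataFrame,
    samples_a,
    samples_b,
    variant: str = "moderated",
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Per-gene two-sample test between two disjoint sample sets.

    ``variant``: "moderated" (default), "student" (ordinary pooled t) or
    "welch".  ``prior_df``/``prior_var`` override the fitted prior (0 gives
    the ordinary pooled t; useful for calibration checks).

    Returns a DataFrame indexed by gene with columns mean_a, mean_b, diff,
    s2 (pooled), s2_post, t, df_total, p; the prior used is stored in
    ``.attrs``.
    """
    samples_a = list(samples_a)
    samples_b = list(samples_b)
    if set(samples_a) & set(samples_b):
        raise ValidationError("sample groups overlap")
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValidationError("each group needs at least 2 samples")
    a = values[samples_a].to_numpy(dtype=float)
    b = values[samples_b].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    diff = mean_a - mean_b
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)

    if variant == "welch":
        with np.errstate(divide="ignore", invalid="ignore"):
            se2 = va / na + vb / nb
            t = diff / np.sqrt(se2)
            dfw = se2**2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        t, p = _degenerate(t, diff, dfw)
        out = _frame(values.index, mean_a, mean_b, diff, va, va, t, dfw, p)
        out.attrs.update(variant=variant, prior_df=0.0, prior_var=np.nan)
        return out

    df_resid = float(na + nb - 2)
    s2 = ((na - 1) * va + (nb - 1) * vb) / df_resid
    if variant == "student" or (prior_df is not None and prior_df == 0):
        d0, s20 = 0.0, np.nan
        s2_post = s2
    elif variant == "moderated":
        if prior_df is None:
            d0, s20 = fit_f_dist(s2, df_resid)
        else:
            d0 = float(prior_df)
            s20 = float(prior_var) if prior_var is not None else fit_f_dist(s2, df_resid)[1]
        if np.isinf(d0):
            s2_post = np.full_like(s2, s20)
        else:
            s2_post = (df_resid * s2 + d0 * s20) / (df_resid + d0)
    else:
        raise ValidationError(f"unknown test variant: {variant!r}")

    # total df for the reference t distribution, capped at the pooled df
    # across all genes (the information actually available)
    df_total = min(df_resid + d0, df_resid * len(values))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    t, p = _degenerate(t, diff, df_total)
    out = _frame(values.index, mean_a, mean_b, diff, s2, s2_post, t, df_total, p)
    out.attrs.update(variant=variant, prior_df=d0, prior_var=s20)
    return out


def _degenerate(t: np.ndarray, diff: np.ndarray, df) -> tuple[np.ndarray, np.ndarray]:
    """Zero-variance genes: p = 0 when the means differ, p = 1 when equal."""
    with np.errstate(invalid="ignore"):
        t = np.where(np.isnan(t) & (diff == 0), 0.0, t)
        t = np.where(np.isnan(t), np.sign(diff) * np.inf, t)
    if np.isscalar(df) and np.isinf(df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    return t, p


def _frame(index, mean_a, mean_b, diff, s2, s2_post, t, df_total, p) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "diff": diff,
            "s2": s2,
            "s2_post": s2_post,
            "t": t,
            "df_total": df_total,
            "p": p,
        },
        index=index,
    )


def select_samples(meta: pd.DataFrame, condition: dict) -> list[str]:
    """Samples matching a {column: value} condition; unknown values reject."""
    mask = pd.Series(True, index=meta.index)
    for col, val in condition.items():
        if col not in meta.columns:
            raise ValidationError(f"unknown metadata column: {col!r}")
        if val not in set(meta[col]):
            raise ValidationError(f"condition label {val!r} not present in column {col!r}")
        mask &= meta[col] == val
    if not mask.any():
        raise ValidationError(f"no samples match condition {condition}")
    return list(meta.index[mask])


def call_de(
    norm: NormalizedExpression,
    meta: pd.DataFrame,
    condition_a: dict,
    condition_b: dict,
    thresholds: DEThresholds | None = None,
    label: str | None = None,
    test: str = "moderated",
    bh_correct: bool = False,
    fold_basis: str = "linear",
) -> DEResult:
    """Call per-gene differential expression for condition_a vs condition_b.

    Fold change is the ratio of linear normalized group means with a
    pseudo-count of 1 (fold = (mean CPM_a + 1) / (mean CPM_b + 1), numerator
    the first-named condition).  A gene is ``up`` iff p < p_max and fold >
    fold_min, ``down`` iff p < p_max and fold < 1/fold_min (all strict),
    else ``ns``.  ``bh_correct`` applies Benjamini-Hochberg to the p-values
    before thresholding (off by default: the method screens on raw p).
    """
    thresholds = thresholds or DEThresholds()
    samples_a = select_samples(meta, condition_a)
    samples_b = select_samples(meta, condition_b)
    stats_df = moderated_t(norm.values, samples_a, samples_b, variant=test)
    lin_a = norm.cpm[samples_a].mean(axis=1) + 1.0
    lin_b = norm.cpm[samples_b].mean(axis=1) + 1.0
    if fold_basis == "linear":
        fold = lin_a / lin_b
    elif fold_basis == "log":
        logx = np.log2(norm.cpm + 1.0)
        fold = np.exp2(logx[samples_a].mean(axis=1) - logx[samples_b].mean(axis=1))
    else:
        raise ValidationError(f"unknown fold_basis: {fold_basis!r}")
    p = stats_df["p"].to_numpy()
    if bh_correct:
        p = _bh(p)
    table = pd.DataFrame(
        {
            "mean_a": lin_a,
            "mean_b": lin_b,
            "fold": fold,
            "log2fc": np.log2(fold),
            "t": stats_df["t"],
            "p": p,
        },
        index=norm.values.index,
    )
    up = (table["p"] < thresholds.p_max) & (table["fold"] > thresholds.fold_min)
    down = (table["p"] < thresholds.p_max) & (table["fold"] < 1.0 / thresholds.fold_min)
    table["direction"] = np.where(up, "up", np.where(down, "down", "ns"))
    if label is None:
        fmt = lambda c: ",".join(f"{v}" for v in c.values())  # noqa: E731
        label = f"{fmt(condition_a)}-vs-{fmt(condition_b)}"
    return DEResult(contrast=label, table=table, thresholds=thresholds)


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def diet_contrasts(
    norm: NormalizedExpression,
    meta: pd.DataFrame,
    thresholds: DEThresholds | None = None,
    genotypes=None,
    test: str = "moderated",
) -> dict[str, DEResult]:
    """HFD-vs-Con contrast within each genotype (the four diet contrasts)."""
    genotypes = genotypes or list(dict.fromkeys(meta["genotype"]))
    return {
        g: call_de(
            norm,
            meta,
            {"genotype": g, "diet": "HFD"},
            {"genotype": g, "diet": "Con"},
            thresholds=thresholds,
            label=f"{g}:HFD-vs-Con",
            test=test,
        )
        for g in genotypes
    }
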