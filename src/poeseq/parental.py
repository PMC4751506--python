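"""Parent-of-origin classification of diet-response genes, and the
cross-strain comparison.

A gene is *B6 paternal allele-dependent up-regulated* when it is
significantly up-regulated by the high-fat diet in both genotypes that
carry a paternal B6 allele (B6 itself and the PWK-mother cross PxB_F1) but
in neither genotype without one (PWK and BxP_F1).  "Not up-regulated" means
failing the joint p/fold criterion for that direction, regardless of trend.
The maternal categories swap the roles of the two F1s; down-regulation is
the mirror image.  The four categories are mutually exclusive by
construction: each requires the other category's qualifying F1 to be
non-significant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import DEResult, DEThresholds, NormalizedExpression, ValidationError
from .de import call_de, moderated_t

__all__ = ["classify_parental", "strain_comparison", "marker_report", "CATEGORIES"]

CATEGORIES = ("paternal_up", "paternal_down", "maternal_up", "maternal_down", "none")

#: genotype direction pattern defining each category:
#: (B6, PWK, PxB_F1, BxP_F1) calls that must hold / must fail
_RULES = {
    "paternal_up": ("up", ("B6", "PxB_F1"), ("PWK", "BxP_F1")),
    "paternal_down": ("down", ("B6", "PxB_F1"), ("PWK", "BxP_F1")),
    "maternal_up": ("up", ("B6", "BxP_F1"), ("PWK", "PxB_F1")),
    "maternal_down": ("down", ("B6", "BxP_F1"), ("PWK", "PxB_F1")),
}


def classify_parental(contrasts: dict[str, DEResult]) -> pd.Series:
    """Assign each gene a parental-dependence category from the four
    genotype-wise HFD-vs-Con contrasts.

    ``contrasts`` maps genotype label -> DEResult; all four genotypes are
    required and must share the gene universe.  Genes missing a call are
    assigned ``none``.
    """
    required = {"B6", "PWK", "PxB_F1", "BxP_F1"}
    missing = required - set(contrasts)
    if missing:
        raise ValidationError(f"missing contrasts for genotypes: {sorted(missing)}")
    genes = contrasts["B6"].table.index
    for g, res in contrasts.items():
        if not res.table.index.equals(genes):
            if set(res.table.index) != set(genes):
                raise ValidationError(f"gene universe of {g} differs from B6")
            contrasts[g] = DEResult(res.contrast, res.table.loc[genes], res.thresholds)
    direction = {g: contrasts[g].table["direction"] for g in required}

    out = pd.Series("none", index=genes, name="category")
    for category, (call, must, must_not) in _RULES.items():
        mask = pd.Series(True, index=genes)
        for g in must:
            mask &= direction[g] == call
        for g in must_not:
            mask &= direction[g] != call
        out[mask] = category
    return out


def classify_from_directions(directions: pd.DataFrame) -> pd.Series:
    """Classify from a genes x genotype table of 'up'/'down'/'ns' calls.

    Convenience used by the enumeration tests and the manifest; same rules
    as :func:`classify_parental`.
    """
    out = pd.Series("none", index=directions.index, name="category")
    for category, (call, must, must_not) in _RULES.items():
        mask = pd.Series(True, index=directions.index)
        for g in must:
            mask &= directions[g] == call
        for g in must_not:
            mask &= directions[g] != call
        out[mask] = category
    return out


def strain_comparison(de_con: DEResult, de_hfd: DEResult) -> dict[str, pd.Index]:
    """Five-fold comparison of PWK vs B6 expression under either diet.

    ``de_con``: PWK-Con vs B6-Con; ``de_hfd``: PWK-HFD vs B6-Con (both
    typically at the 5-fold threshold).  Returns the per-contrast up/down
    sets and their intersections — genes altered in PWK relative to B6 fed
    either diet.
    """
    if set(de_con.table.index) != set(de_hfd.table.index):
        raise ValidationError("strain comparison requires a shared gene universe")
    up_con, up_hfd = de_con.up, de_hfd.up
    down_con, down_hfd = de_con.down, de_hfd.down
    return {
        "up_con": up_con,
        "up_hfd": up_hfd,
        "up_both": up_con.intersection(up_hfd),
        "down_con": down_con,
        "down_hfd": down_hfd,
        "down_both": down_con.intersection(down_hfd),
    }


def marker_report(
    norm: NormalizedExpression,
    meta: pd.DataFrame,
    markers,
    diet: str = "Con",
    alpha: float = 0.05,
    test: str = "moderated",
) -> pd.DataFrame:
    """Fold change of selected marker genes in PWK relative to B6.

    Reports the linear fold change of group means (PWK / B6, same diet) per
    marker with a significance flag: ``flag`` is "" when p < alpha and "(-)"
    otherwise (no significant difference).  Markers absent from the matrix
    get status "missing".
    """
    markers = list(markers)
    if not markers:
        raise ValidationError("empty marker list")
    res = call_de(
        norm,
        meta,
        {"genotype": "PWK", "diet": diet},
        {"genotype": "B6", "diet": diet},
        thresholds=DEThresholds(),
        label=f"PWK-{diet}-vs-B6-{diet}",
        test=test,
    )
    rows = []
    for m in markers:
        if m not in res.table.index:
            rows.append({"gene_id": m, "fold": np.nan, "p": np.nan, "flag": "missing"})
            continue
        r = res.table.loc[m]
        rows.append(
            {
                "gene_id": m,
                "fold": float(r["fold"]),
                "p": float(r["p"]),
                "flag": "" if r["p"] < alpha else "(-)",
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
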