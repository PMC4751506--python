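"""Allelic imprinting screen: filters, strict/mild criteria, oracle equivalence."""

import math

import numpy as np
import pandas as pd
import pytest

from poeseq.datatypes import AllelicSnpTable, ScreenThresholds, ValidationError
from poeseq.screen import (
    annotate_known,
    compute_fractions,
    filter_snps,
    screen_mild,
    screen_strict,
)

from conftest import make_allelic

# ---------------------------------------------------------------------------
# Brute-force oracle: plain loops over SNPs and mice, no shared code with the
# pipeline.  Implements the documented filter + strict + mild rules directly.
# ---------------------------------------------------------------------------


def _student_t_p(x, y):
    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    if vx == 0 and vy == 0:
        return 0.0 if mx != my else 1.0
    df = nx + ny - 2
    s2 = ((nx - 1) * vx + (ny - 1) * vy) / df
    t = (mx - my) / math.sqrt(s2 * (1 / nx + 1 / ny))
    from scipy.stats import t as tdist

    return 2 * tdist.sf(abs(t), df)


def oracle_screen(table: AllelicSnpTable, thr: ScreenThresholds):
    """Returns (exclusions, strict calls, mild calls) as dicts gene -> {call: n}."""
    samples = list(table.samples)
    bxp = [s for s in samples if table.cross[s] == "BxP_F1"]
    pxb = [s for s in samples if table.cross[s] == "PxB_F1"]
    excl = {"chrY": 0, "non_exonic": 0, "low_depth": 0, "zero_read_mouse": 0}
    kept = []
    for snp in table.snps.index:
        tot = {s: table.b6.loc[snp, s] + table.pwk.loc[snp, s] for s in samples}
        if str(table.snps.loc[snp, "chrom"]).lower() == "chry":
            excl["chrY"] += 1
        elif not table.snps.loc[snp, "exonic"]:
            excl["non_exonic"] += 1
        elif sum(tot.values()) / len(samples) < thr.min_avg_depth:
            excl["low_depth"] += 1
        elif any(v == 0 for v in tot.values()):
            excl["zero_read_mouse"] += 1
        else:
            kept.append(snp)

    strict: dict = {}
    mild: dict = {}
    for snp in kept:
        gene = table.snps.loc[snp, "gene_id"]
        f_bxp = [table.pwk.loc[snp, s] / (table.pwk.loc[snp, s] + table.b6.loc[snp, s]) for s in bxp]
        f_pxb = [table.pwk.loc[snp, s] / (table.pwk.loc[snp, s] + table.b6.loc[snp, s]) for s in pxb]
        # strict (cross-mean rule): mean paternal fraction > cut in both crosses
        pat_bxp = sum(f_bxp) / len(f_bxp)
        pat_pxb = 1 - sum(f_pxb) / len(f_pxb)
        if pat_bxp > thr.strict_fraction and pat_pxb > thr.strict_fraction:
            strict.setdefault(gene, {}).setdefault("PEG", 0)
            strict[gene]["PEG"] += 1
        if (1 - pat_bxp) > thr.strict_fraction and (1 - pat_pxb) > thr.strict_fraction:
            strict.setdefault(gene, {}).setdefault("MEG", 0)
            strict[gene]["MEG"] += 1
        # mild
        if len(f_bxp) >= 2 and len(f_pxb) >= 2:
            mb = sum(f_bxp) / len(f_bxp)
            mp = sum(f_pxb) / len(f_pxb)
            p = _student_t_p(f_bxp, f_pxb)
            if (
                p < thr.alpha and mb > mp and mb > thr.majority and mp < thr.majority
                and (mb - mp) >= thr.min_gap
            ):
                mild.setdefault(gene, {}).setdefault("PEG", 0)
                mild[gene]["PEG"] += 1
            if (
                p < thr.alpha and mp > mb and mb < thr.majority and mp > thr.majority
                and (mp - mb) >= thr.min_gap
            ):
                mild.setdefault(gene, {}).setdefault("MEG", 0)
                mild[gene]["MEG"] += 1

    def gene_calls(per_snp, min_snps):
        return {
            (g, call): n
            for g, d in per_snp.items()
            for call, n in d.items()
            if n >= min_snps
        }

    return (
        excl,
        gene_calls(strict, thr.min_snps_strict),
        gene_calls(mild, thr.min_snps_mild),
    )


def random_table(rng, n_genes=10, max_snps=8, n_samples=12) -> AllelicSnpTable:
    rows_b6, rows_pwk, genes, chroms, exonic = [], [], [], [], []
    cross = ["BxP_F1"] * (n_samples // 2) + ["PxB_F1"] * (n_samples - n_samples // 2)
    for g in range(n_genes):
        # mix imprint-like, biased and noisy genes so both screens can fire
        kind = rng.integers(0, 4)
        p_bxp, p_pxb = {
            0: (0.997, 0.003),
            1: (rng.uniform(0.7, 0.95), rng.uniform(0.05, 0.3)),
            2: (0.5, 0.5),
            3: (0.8, 0.8),
        }[int(kind)]
        for _ in range(int(rng.integers(1, max_snps + 1))):
            depth = rng.poisson(rng.choice([4, 15, 40]), n_samples)
            p = np.array([p_bxp if c == "BxP_F1" else p_pxb for c in cross])
            pwk = rng.binomial(depth, p)
            rows_pwk.append(pwk)
            rows_b6.append(depth - pwk)
            genes.append(f"gene{g}")
            chroms.append(str(rng.choice(["chr1", "chrX", "chrY"], p=[0.8, 0.1, 0.1])))
            exonic.append(bool(rng.random() < 0.9))
    return make_allelic(
        np.array(rows_b6), np.array(rows_pwk), cross, gene_ids=genes,
        chrom=chroms, exonic=exonic,
    )


def pipeline_calls(table, thr):
    filtered, excl = filter_snps(table, thr)
    out = {}
    for mode, fn in (("strict", screen_strict), ("mild", screen_mild)):
        res = fn(filtered, thr)
        out[mode] = {
            (r["gene_id"], r["call"]): r["n_qualifying_snps"]
            for _, r in res.candidates.iterrows()
        }
    return excl, out["strict"], out["mild"]


def test_pipeline_agrees_with_brute_force_oracle():
    thr = ScreenThresholds()
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        table = random_table(rng, n_genes=12)
        excl_o, strict_o, mild_o = oracle_screen(table, thr)
        excl_p, strict_p, mild_p = pipeline_calls(table, thr)
        assert excl_p == excl_o
        assert strict_p == strict_o
        assert mild_p == mild_o


class TestFractions:
    def test_fraction_values(self, six_mouse_cross):
        table = make_allelic(
            [[0, 25, 0, 10, 10, 10]], [[50, 25, 0, 10, 10, 10]], six_mouse_cross
        )
        frac, total = compute_fractions(table)
        row = frac.iloc[0]
        assert row.iloc[0] == 1.0
        assert row.iloc[1] == 0.5
        assert np.isnan(row.iloc[2])  # zero depth -> missing
        assert total.iloc[0, 0] == 50

    def test_negative_counts_rejected(self, six_mouse_cross):
        with pytest.raises(ValidationError):
            make_allelic([[-1, 1, 1, 1, 1, 1]], [[1, 1, 1, 1, 1, 1]], six_mouse_cross)


class TestFilters:
    def test_y_chromosome_excluded_despite_depth(self, six_mouse_cross):
        table = make_allelic(
            [[500] * 6], [[500] * 6], six_mouse_cross, chrom="chrY"
        )
        kept, excl = filter_snps(table)
        assert len(kept.snps) == 0 and excl["chrY"] == 1

    def test_zero_read_mouse_excluded(self, six_mouse_cross):
        table = make_allelic(
            [[6, 7, 0, 10, 5, 6]], [[6, 8, 0, 10, 6, 7]], six_mouse_cross
        )
        # depths (12, 15, 0, 20, 11, 13): mean 11.83 >= 10, but one mouse empty
        kept, excl = filter_snps(table)
        assert len(kept.snps) == 0 and excl["zero_read_mouse"] == 1

    def test_mean_depth_exactly_ten_retained(self, six_mouse_cross):
        table = make_allelic(
            [[5, 5, 5, 5, 5, 5]], [[5, 5, 5, 5, 5, 5]], six_mouse_cross
        )
        kept, excl = filter_snps(table)  # mean depth exactly 10.0: strict "<10"
        assert len(kept.snps) == 1 and excl["low_depth"] == 0

    def test_non_exonic_excluded_and_tallies_reconcile(self, six_mouse_cross):
        table = make_allelic(
            np.tile([[10, 10, 10, 10, 10, 10]], (3, 1)),
            np.tile([[10, 10, 10, 10, 10, 10]], (3, 1)),
            six_mouse_cross,
            exonic=[True, False, True],
        )
        kept, excl = filter_snps(table)
        assert excl["non_exonic"] == 1
        assert len(table.snps) == len(kept.snps) + sum(excl.values())


class TestStrict:
    def test_fraction_0995_everywhere_is_peg(self, six_mouse_cross):
        pwk = [[199, 199, 199, 1, 1, 1]]
        b6 = [[1, 1, 1, 199, 199, 199]]
        res = screen_strict(make_allelic(b6, pwk, six_mouse_cross))
        assert list(res.candidates["call"]) == ["PEG"]
        assert res.candidates["n_qualifying_snps"].iloc[0] == 1

    def test_fraction_exactly_099_not_called(self, six_mouse_cross):
        pwk = [[99, 99, 99, 1, 1, 1]]
        b6 = [[1, 1, 1, 99, 99, 99]]
        res = screen_strict(make_allelic(b6, pwk, six_mouse_cross))
        assert len(res.candidates) == 0  # "over 99%" is strict

    def test_meg_is_mirror_image(self, six_mouse_cross):
        pwk = [[1, 1, 1, 199, 199, 199]]
        b6 = [[199, 199, 199, 1, 1, 1]]
        res = screen_strict(make_allelic(b6, pwk, six_mouse_cross))
        assert list(res.candidates["call"]) == ["MEG"]

    def test_single_cross_direction_rejected(self):
        table = make_allelic([[1, 1, 1]], [[9, 9, 9]], ["BxP_F1"] * 3)
        with pytest.raises(ValidationError):
            screen_strict(table)


class TestMild:
    BXP = [0.80, 0.78, 0.82, 0.81, 0.79, 0.80]
    PXB = [0.30, 0.28, 0.32, 0.31, 0.29, 0.30]

    def _table_from_fractions(self, f_bxp, f_pxb, n_snps=1, depth=100):
        rows_pwk = [
            [round(f * depth) for f in f_bxp] + [round(f * depth) for f in f_pxb]
        ] * n_snps
        rows_b6 = [[depth - v for v in row] for row in rows_pwk]
        return make_allelic(
            np.array(rows_b6), np.array(rows_pwk),
            ["BxP_F1"] * len(f_bxp) + ["PxB_F1"] * len(f_pxb),
        )

    def test_clear_separation_qualifies_for_peg(self):
        thr = ScreenThresholds(min_snps_mild=1)
        table = self._table_from_fractions(self.BXP, self.PXB)
        res = screen_mild(table, thr)
        assert list(res.candidates["call"]) == ["PEG"]
        # independent oracle p-value on the same 12 per-mouse fractions
        assert _student_t_p(self.BXP, self.PXB) < 0.05

    def test_gap_below_020_fails_even_if_significant(self):
        thr = ScreenThresholds(min_snps_mild=1)
        bxp = [0.60, 0.59, 0.61, 0.60, 0.60, 0.60]
        pxb = [0.45, 0.44, 0.46, 0.45, 0.45, 0.45]
        assert _student_t_p(bxp, pxb) < 0.05  # significant...
        res = screen_mild(self._table_from_fractions(bxp, pxb), thr)
        assert len(res.candidates) == 0  # ...but the 0.15 gap fails criterion 3

    def test_four_snps_required_for_gene_call(self):
        thr = ScreenThresholds()
        res3 = screen_mild(self._table_from_fractions(self.BXP, self.PXB, n_snps=3), thr)
        res4 = screen_mild(self._table_from_fractions(self.BXP, self.PXB, n_snps=4), thr)
        assert len(res3.candidates) == 0
        assert list(res4.candidates["call"]) == ["PEG"]
        assert res4.candidates["n_qualifying_snps"].iloc[0] == 4


def test_allele_or_cross_swap_symmetry():
    """Swapping the two allele columns flips PEG<->MEG; so does relabelling
    the cross directions; doing both restores the original calls."""
    rng = np.random.default_rng(77)
    table = random_table(rng, n_genes=15)
    thr = ScreenThresholds()
    _, strict_a, mild_a = pipeline_calls(table, thr)
    swap = {"PEG": "MEG", "MEG": "PEG"}
    cross_flip = {"BxP_F1": "PxB_F1", "PxB_F1": "BxP_F1"}

    allele_swapped = AllelicSnpTable(
        snps=table.snps, b6=table.pwk, pwk=table.b6, cross=table.cross
    )
    label_swapped = AllelicSnpTable(
        snps=table.snps, b6=table.b6, pwk=table.pwk, cross=table.cross.map(cross_flip)
    )
    both_swapped = AllelicSnpTable(
        snps=table.snps, b6=table.pwk, pwk=table.b6, cross=table.cross.map(cross_flip)
    )
    for flipped in (allele_swapped, label_swapped):
        _, strict_b, mild_b = pipeline_calls(flipped, thr)
        assert {(g, swap[c]): n for (g, c), n in strict_a.items()} == strict_b
        assert {(g, swap[c]): n for (g, c), n in mild_a.items()} == mild_b
    _, strict_c, mild_c = pipeline_calls(both_swapped, thr)
    assert strict_c == strict_a and mild_c == mild_a


def test_screen_invariant_to_snp_and_sample_order():
    rng = np.random.default_rng(78)
    table = random_table(rng, n_genes=10)
    thr = ScreenThresholds()
    _, strict_a, mild_a = pipeline_calls(table, thr)
    snp_perm = rng.permutation(table.snps.index)
    samp_perm = list(rng.permutation(table.samples))
    shuffled = AllelicSnpTable(
        snps=table.snps.loc[snp_perm],
        b6=table.b6.loc[snp_perm, samp_perm],
        pwk=table.pwk.loc[snp_perm, samp_perm],
        cross=table.cross,
    )
    _, strict_b, mild_b = pipeline_calls(shuffled, thr)
    assert strict_a == strict_b and mild_a == mild_b


def test_complete_noise_free_gene_called_by_both_modes(six_mouse_cross):
    pwk = np.tile([100, 100, 100, 0, 0, 0], (4, 1))
    b6 = np.tile([0, 0, 0, 100, 100, 100], (4, 1))
    table = make_allelic(b6, pwk, six_mouse_cross)
    assert list(screen_strict(table).candidates["call"]) == ["PEG"]
    assert list(screen_mild(table).candidates["call"]) == ["PEG"]


def test_strain_biased_gene_never_called_at_high_depth(six_mouse_cross):
    # 80% PWK-allele expression in BOTH crosses: cis bias, not imprinting
    pwk = np.tile([8000] * 6, (4, 1))
    b6 = np.tile([2000] * 6, (4, 1))
    table = make_allelic(b6, pwk, six_mouse_cross)
    assert len(screen_strict(table).candidates) == 0
    assert len(screen_mild(table).candidates) == 0


def test_annotate_known_statuses():
    candidates = pd.DataFrame(
        {
            "gene_id": ["Igf2", "Nnat", "H13"],
            "call": ["PEG", "PEG", "PEG"],
            "mode": ["mild"] * 3,
            "n_qualifying_snps": [5, 4, 6],
        }
    )
    known = pd.DataFrame(
        {"status": ["PEG", "MEG"]}, index=pd.Index(["Igf2", "H13"], name="gene_id")
    )
    annotated, summary = annotate_known(candidates, known)
    assert list(annotated["known_status"]) == ["known", "novel", "conflict"]
    assert summary == {"n_known": 1, "n_novel": 1, "n_conflict": 1}
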