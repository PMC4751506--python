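"""Shared fixtures: small synthetic studies and hand-built allelic tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from poeseq.datatypes import AllelicSnpTable
from poeseq.simulate import StudyDesign, TruthConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """An 800-gene full study with every planted effect class."""
    design = StudyDesign(n_genes=800)
    cfg = TruthConfig(
        n_complete_peg=25,
        n_complete_meg=25,
        n_partial_peg=25,
        n_strain_biased=25,
        n_b6_paternal_response=50,
        n_b6_maternal_response=25,
        n_shared_response=25,
    )
    return simulate_study(design, config=cfg, seed=42)


def make_allelic(
    b6: np.ndarray,
    pwk: np.ndarray,
    cross: list[str],
    gene_ids: list[str] | None = None,
    chrom: str | list[str] = "chr1",
    exonic: bool | list[bool] = True,
) -> AllelicSnpTable:
    """Build an allelic table from raw count arrays (snps x samples)."""
    b6 = np.atleast_2d(np.asarray(b6))
    pwk = np.atleast_2d(np.asarray(pwk))
    n_snps, n_samples = b6.shape
    samples = [f"m{j}" for j in range(n_samples)]
    snp_ids = pd.Index([f"s{i}" for i in range(n_snps)], name="snp_id")
    gene_ids = gene_ids or ["geneA"] * n_snps
    snps = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": chrom if isinstance(chrom, list) else [chrom] * n_snps,
            "pos": np.arange(1, n_snps + 1) * 100,
            "exonic": exonic if isinstance(exonic, list) else [exonic] * n_snps,
        },
        index=snp_ids,
    )
    return AllelicSnpTable(
        snps=snps,
        b6=pd.DataFrame(b6, index=snp_ids, columns=samples),
        pwk=pd.DataFrame(pwk, index=snp_ids, columns=samples),
        cross=pd.Series(cross, index=samples),
    )


@pytest.fixture
def six_mouse_cross():
    """3 BxP_F1 + 3 PxB_F1 sample labels."""
    return ["BxP_F1"] * 3 + ["PxB_F1"] * 3
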