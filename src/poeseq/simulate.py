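"""Synthetic reciprocal-cross diet studies with known ground truth.

Emulates the design of the study the pipeline targets: 4 genotypes
(B6, PWK and the two reciprocal F1 hybrids) x 2 diets (control, high-fat)
x replicates, gene-level negative-binomial read counts, allele-specific
beta-binomial SNP counts in the F1 mice, and body weights coupled to diet,
strain and imprinted-gene expression.  Every planted effect is recorded in
a truth table so downstream stages can be scored for recovery.

Planted effect classes
----------------------
* imprint_state: ``PEG_complete`` / ``PEG_partial`` (paternal-allele
  fraction near 1 / around 0.75), ``MEG_complete`` / ``MEG_partial``
  (mirrored), ``strain_biased`` (a fixed PWK-allele fraction in *both*
  cross directions — a cis effect that must not be called imprinted), or
  ``biallelic`` (0.5).
* diet response: a "B6-paternal" response gene responds to the high-fat
  diet wherever the B6 allele came from the father, i.e. in B6 and
  PxB_F1 only; "B6-maternal" in B6 and BxP_F1 only; "shared" in all four
  genotypes.
* weight coupling: a signed per-gene contribution of standardized
  log-expression to body weight (negative for PEGs, positive for MEGs by
  default, mirroring the anti-/pro-obesity pattern under test).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    DIETS,
    F1_GENOTYPES,
    GENOTYPES,
    PARENTAGE,
    AllelicSnpTable,
    ValidationError,
)

IMPRINT_STATES = (
    "PEG_complete",
    "PEG_partial",
    "MEG_complete",
    "MEG_partial",
    "strain_biased",
    "biallelic",
)
DIET_RESPONSE_CLASSES = ("none", "B6_paternal", "B6_maternal", "shared")


@dataclass
class StudyDesign:
    """Which genotype/diet cells exist and how many mice sit in each."""

    genotypes: tuple[str, ...] = GENOTYPES
    diets: tuple[str, ...] = DIETS
    replicates_per_cell: int = 3
    n_genes: int = 2000

    def __post_init__(self) -> None:
        bad = set(self.genotypes) - set(GENOTYPES)
        if bad:
            raise ValidationError(f"unknown genotypes: {sorted(bad)}")
        if self.replicates_per_cell < 2:
            raise ValidationError("replicates_per_cell must be >= 2")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")

    @property
    def n_samples(self) -> int:
        return len(self.genotypes) * len(self.diets) * self.replicates_per_cell

    def sample_frame(self) -> pd.DataFrame:
        rows = []
        for geno, diet in itertools.product(self.genotypes, self.diets):
            mat, pat = PARENTAGE[geno]
            for rep in range(1, self.replicates_per_cell + 1):
                rows.append(
                    {
                        "sample_id": f"{geno}_{diet}_{rep}",
                        "genotype": geno,
                        "maternal_strain": mat,
                        "paternal_strain": pat,
                        "diet": diet,
                        "replicate": rep,
                    }
                )
        return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class TruthConfig:
    """Generative parameters for the planted gene effects.

    Defaults describe a compact but realistic bulk RNA-seq study: log-normal
    baseline means around ~100 counts, gene-wise negative-binomial
    dispersions log-normal in roughly 0.05-0.2, and imprint-state blocks
    sized so each downstream screen has enough positives to score.
    """

    n_complete_peg: int = 50
    n_complete_meg: int = 50
    n_partial_peg: int = 50
    n_partial_meg: int = 0
    n_strain_biased: int = 50
    n_b6_paternal_response: int = 100
    n_b6_maternal_response: int = 50
    n_shared_response: int = 50
    diet_log2fc: float = 2.0               # 4-fold diet effect
    complete_fraction_range: tuple[float, float] = (0.99, 1.0)
    partial_fraction_range: tuple[float, float] = (0.70, 0.90)
    strain_bias_range: tuple[float, float] = (0.70, 0.90)
    baseline_log_mean: float = np.log(100.0)
    baseline_log_sd: float = 1.2
    dispersion_log_mean: float = np.log(0.1)
    dispersion_log_sd: float = 0.35
    weight_coupling_g: float = 0.5         # grams per SD of log-expression
    imprint_hfd_log2fc: float = 1.0        # PEGs -x, MEGs +x under HFD
    n_strain_up: int = 0                   # genes cis-up in PWK vs B6
    n_strain_down: int = 0
    strain_log2fc: float = 3.0             # 8-fold between the parental strains


def make_truth(design: StudyDesign, config: TruthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the per-gene ground truth table for a study.

    Imprint states and diet-response classes are assigned to disjoint leading
    blocks of genes (imprinted first, then diet responders among the
    remainder); all other genes are biallelic non-responders.
    """
    n = design.n_genes
    n_imprint = (
        config.n_complete_peg
        + config.n_complete_meg
        + config.n_partial_peg
        + config.n_partial_meg
        + config.n_strain_biased
    )
    n_response = (
        config.n_b6_paternal_response + config.n_b6_maternal_response + config.n_shared_response
    )
    n_strain = config.n_strain_up + config.n_strain_down
    if n_imprint + n_response + n_strain > n:
        raise ValidationError(
            f"planted effects ({n_imprint}+{n_response}+{n_strain}) exceed n_genes ({n})"
        )

    gene_ids = [f"g{i:05d}" for i in range(n)]
    truth = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    truth["baseline_mean"] = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, n)
    )
    truth["dispersion"] = np.exp(
        rng.normal(config.dispersion_log_mean, config.dispersion_log_sd, n)
    )

    states = ["biallelic"] * n
    pf = np.full(n, 0.5)
    pwk_bias = np.full(n, np.nan)
    i = 0
    for state, count in (
        ("PEG_complete", config.n_complete_peg),
        ("MEG_complete", config.n_complete_meg),
        ("PEG_partial", config.n_partial_peg),
        ("MEG_partial", config.n_partial_meg),
        ("strain_biased", config.n_strain_biased),
    ):
        for _ in range(count):
            states[i] = state
            if state == "strain_biased":
                pwk_bias[i] = rng.uniform(*config.strain_bias_range)
            else:
                rng_range = (
                    config.complete_fraction_range
                    if state.endswith("complete")
                    else config.partial_fraction_range
                )
                frac = rng.uniform(*rng_range)
                pf[i] = frac if state.startswith("PEG") else 1.0 - frac
            i += 1
    truth["imprint_state"] = states
    truth["paternal_fraction"] = pf
    truth["pwk_bias_fraction"] = pwk_bias

    response = ["none"] * n
    for cls, count in (
        ("B6_paternal", config.n_b6_paternal_response),
        ("B6_maternal", config.n_b6_maternal_response),
        ("shared", config.n_shared_response),
    ):
        for _ in range(count):
            response[i] = cls
            i += 1
    truth["diet_response"] = response
    sign = rng.choice([-1.0, 1.0], n)
    truth["diet_log2fc"] = np.where(
        truth["diet_response"] != "none", sign * config.diet_log2fc, 0.0
    )

    # imprinted genes respond to the diet in every genotype: PEGs down, MEGs
    # up under HFD (the anti-/pro-obesity pattern the phenotype stage probes)
    if config.imprint_hfd_log2fc:
        is_peg_state = truth["imprint_state"].str.startswith("PEG")
        is_meg_state = truth["imprint_state"].str.startswith("MEG")
        truth.loc[is_peg_state | is_meg_state, "diet_response"] = "shared"
        truth.loc[is_peg_state, "diet_log2fc"] = -config.imprint_hfd_log2fc
        truth.loc[is_meg_state, "diet_log2fc"] = config.imprint_hfd_log2fc

    # cis strain effects: expression scales with the number of PWK alleles
    strain_fc = np.zeros(n)
    for fc, count in (
        (config.strain_log2fc, config.n_strain_up),
        (-config.strain_log2fc, config.n_strain_down),
    ):
        for _ in range(count):
            strain_fc[i] = fc
            i += 1
    truth["strain_log2fc"] = strain_fc

    coupling = np.zeros(n)
    is_peg = truth["imprint_state"].str.startswith("PEG")
    is_meg = truth["imprint_state"].str.startswith("MEG")
    coupling[is_peg.to_numpy()] = -config.weight_coupling_g
    coupling[is_meg.to_numpy()] = config.weight_coupling_g
    truth["weight_coupling"] = coupling
    return truth


#: genotypes in which each diet-response class responds to the HFD
RESPONSIVE_GENOTYPES = {
    "none": (),
    "B6_paternal": ("B6", "PxB_F1"),
    "B6_maternal": ("B6", "BxP_F1"),
    "shared": GENOTYPES,
}


def diet_log2fc_by_genotype(truth: pd.DataFrame) -> pd.DataFrame:
    """Expand the response class into an explicit per-genotype log2 diet effect."""
    out = pd.DataFrame(0.0, index=truth.index, columns=list(GENOTYPES))
    for cls, genos in RESPONSIVE_GENOTYPES.items():
        mask = truth["diet_response"] == cls
        for g in genos:
            out.loc[mask, g] = truth.loc[mask, "diet_log2fc"]
    return out


@dataclass
class SimulatedStudy:
    """A complete synthetic study: counts, metadata, allelic table, truth."""

    counts: pd.DataFrame
    meta: pd.DataFrame
    truth: pd.DataFrame
    seed: int
    allelic: AllelicSnpTable | None = None
    library_factors: pd.Series | None = None


def simulate_expression(
    design: StudyDesign,
    truth: pd.DataFrame | None = None,
    seed: int = 0,
    config: TruthConfig | None = None,
    library_factor_range: tuple[float, float] = (0.7, 1.4),
) -> SimulatedStudy:
    """Draw the gene x sample count matrix.

    Counts are negative-binomial with mean
    ``baseline x library_factor x 2^(diet effect if HFD and responsive)``
    and gene-wise dispersion phi (phi = 0 degenerates to Poisson).
    Per-sample library factors are log-uniform so normalization has real
    work to do.
    """
    rng = np.random.default_rng(seed)
    config = config or TruthConfig()
    if truth is None:
        truth = make_truth(design, config, rng)
    meta = design.sample_frame()
    lo, hi = library_factor_range
    lib = pd.Series(
        np.exp(rng.uniform(np.log(lo), np.log(hi), len(meta))), index=meta.index
    )
    per_geno_fc = diet_log2fc_by_genotype(truth)

    base = truth["baseline_mean"].to_numpy()
    phi = truth["dispersion"].to_numpy()
    strain_fc = (
        truth["strain_log2fc"].to_numpy()
        if "strain_log2fc" in truth.columns
        else np.zeros(len(truth))
    )
    counts = np.empty((len(truth), len(meta)), dtype=np.int64)
    for j, (sample, row) in enumerate(meta.iterrows()):
        mu = base * lib.iloc[j]
        if row["diet"] == "HFD":
            mu = mu * np.exp2(per_geno_fc[row["genotype"]].to_numpy())
        # cis effect: additive in PWK allele dose (0 in B6, 1 in F1s, 2 in PWK)
        dose = (row["maternal_strain"] == "PWK") + (row["paternal_strain"] == "PWK")
        if dose:
            mu = mu * np.exp2(strain_fc * dose / 2.0)
        counts[:, j] = _rnbinom(rng, mu, phi)
    counts_df = pd.DataFrame(counts, index=truth.index, columns=meta.index.rename(None))
    return SimulatedStudy(
        counts=counts_df, meta=meta, truth=truth, seed=seed, library_factors=lib
    )


def _rnbinom(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Negative binomial with mean mu, variance mu + phi*mu^2; phi=0 -> Poisson."""
    out = np.empty_like(mu, dtype=np.int64)
    pois = phi <= 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    nb = ~pois
    if nb.any():
        size = 1.0 / phi[nb]
        p = size / (size + mu[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def _rbetabinom(
    rng: np.random.Generator, depth: np.ndarray, p: np.ndarray, rho: float
) -> np.ndarray:
    """Beta-binomial counts; rho=0 is plain binomial, p in {0,1} deterministic."""
    if rho == 0:
        return rng.binomial(depth, p)
    out = np.zeros_like(depth)
    fixed = (p <= 0) | (p >= 1)
    out[fixed] = depth[fixed] * (p[fixed] >= 1)
    free = ~fixed
    if free.any():
        a = p[free] * (1 - rho) / rho
        b = (1 - p[free]) * (1 - rho) / rho
        out[free] = rng.binomial(depth[free], rng.beta(a, b))
    return out


def simulate_allelic_counts(
    study: SimulatedStudy,
    snps_per_gene: int = 5,
    depth: float = 50.0,
    overdispersion_rho: float = 0.02,
    seed: int | None = None,
    chrom_pool: tuple[str, ...] | None = None,
) -> AllelicSnpTable:
    """Draw the allele-specific SNP table for the F1 samples of a study.

    Per SNP x F1 mouse: total depth is Poisson(``depth``); the PWK-allele
    count is beta-binomial(depth, p, rho) with p = the gene's paternal-allele
    fraction when the PWK allele is paternal (BxP_F1 mice) and 1 - that
    fraction when maternal (PxB_F1).  Strain-biased genes use their fixed
    PWK-allele fraction in both cross directions.  SNP positions are spread
    over autosomes; all SNPs are exonic (the filter stages are exercised
    with hand-built tables in tests).
    """
    if not 0 <= overdispersion_rho < 1:
        raise ValidationError(f"overdispersion rho must be in [0, 1), got {overdispersion_rho}")
    f1_samples = study.meta.index[study.meta["genotype"].isin(F1_GENOTYPES)]
    crosses = set(study.meta.loc[f1_samples, "genotype"])
    if crosses != set(F1_GENOTYPES):
        raise ValidationError("study must contain both reciprocal F1 genotypes")
    rng = np.random.default_rng(study.seed + 1 if seed is None else seed)
    chrom_pool = chrom_pool or tuple(f"chr{i}" for i in range(1, 20))

    truth = study.truth
    n_genes = len(truth)
    n_snps = n_genes * snps_per_gene
    snps = pd.DataFrame(
        {
            "gene_id": np.repeat(truth.index.to_numpy(), snps_per_gene),
            "chrom": rng.choice(chrom_pool, n_snps),
            "pos": rng.integers(1, 100_000_000, n_snps),
            "exonic": True,
        },
        index=pd.Index([f"snp{i:06d}" for i in range(n_snps)], name="snp_id"),
    )

    # generative PWK-allele fraction per gene and cross direction
    pf = truth["paternal_fraction"].to_numpy()
    bias = truth["pwk_bias_fraction"].to_numpy()
    strain = truth["imprint_state"].to_numpy() == "strain_biased"
    p_by_cross = {
        "BxP_F1": np.where(strain, bias, pf),        # PWK allele is paternal
        "PxB_F1": np.where(strain, bias, 1.0 - pf),  # PWK allele is maternal
    }

    b6 = np.empty((n_snps, len(f1_samples)), dtype=np.int64)
    pwk = np.empty_like(b6)
    for j, sample in enumerate(f1_samples):
        cross = study.meta.loc[sample, "genotype"]
        p = np.repeat(p_by_cross[cross], snps_per_gene)
        total = rng.poisson(depth, n_snps)
        pwk[:, j] = _rbetabinom(rng, total, p, overdispersion_rho)
        b6[:, j] = total - pwk[:, j]

    cols = pd.Index(list(f1_samples))
    table = AllelicSnpTable(
        snps=snps,
        b6=pd.DataFrame(b6, index=snps.index, columns=cols),
        pwk=pd.DataFrame(pwk, index=snps.index, columns=cols),
        cross=study.meta.loc[f1_samples, "genotype"],
    )
    study.allelic = table
    return table


def simulate_body_weights(
    study: SimulatedStudy,
    base_weight: float = 30.0,
    diet_effect: float = 12.0,
    strain_effects: dict[str, float] | None = None,
    coupling_scale: float = 1.0,
    noise_sd: float = 1.5,
    seed: int | None = None,
) -> pd.Series:
    """Body weight per mouse, in grams, written into ``study.meta``.

    weight = base + diet term + genotype term
             + coupling_scale * sum_g coupling_g * z_g + Gaussian noise,
    where z_g is the gene's standardized log2(count+1) across samples.
    Default genotype terms make B6 (and the B6-father cross PxB_F1) obesity
    prone and PWK resistant, matching the phenotype the design probes.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be nonnegative")
    strain_effects = strain_effects or {"B6": 0.0, "PWK": -8.0, "BxP_F1": -5.0, "PxB_F1": -2.0}
    rng = np.random.default_rng(study.seed + 2 if seed is None else seed)
    meta = study.meta

    w = pd.Series(base_weight, index=meta.index, dtype=float)
    w += np.where(meta["diet"] == "HFD", diet_effect, 0.0)
    w += meta["genotype"].map(strain_effects).fillna(0.0).to_numpy()

    coupled = study.truth.index[study.truth["weight_coupling"] != 0]
    if coupling_scale != 0 and len(coupled):
        logx = np.log2(study.counts.loc[coupled] + 1.0)
        sd = logx.std(axis=1, ddof=1).replace(0, np.nan)
        z = logx.sub(logx.mean(axis=1), axis=0).div(sd, axis=0).fillna(0.0)
        contrib = z.mul(study.truth.loc[coupled, "weight_coupling"], axis=0).sum(axis=0)
        w += coupling_scale * contrib
    w += rng.normal(0.0, noise_sd, len(w)) if noise_sd > 0 else 0.0
    w = w.clip(lower=1.0)
    study.meta = meta.assign(body_weight_g=w)
    return w


def simulate_study(
    design: StudyDesign | None = None,
    config: TruthConfig | None = None,
    seed: int = 0,
    snps_per_gene: int = 5,
    depth: float = 50.0,
    overdispersion_rho: float = 0.02,
    weight_kwargs: dict | None = None,
) -> SimulatedStudy:
    """One-call generator: expression + allelic counts + body weights."""
    design = design or StudyDesign()
    study = simulate_expression(design, seed=seed, config=config)
    if set(F1_GENOTYPES) <= set(design.genotypes):
        simulate_allelic_counts(
            study, snps_per_gene=snps_per_gene, depth=depth,
            overdispersion_rho=overdispersion_rho,
        )
    simulate_body_weights(study, **(weight_kwargs or {}))
    return study
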