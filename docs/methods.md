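# Methods

This note documents the statistical models behind `poeseq`, the choices
made where the analysis design was genuinely open, and what the synthetic
studies do and do not establish about real data.

## Study design and notation

Four genotypes — the inbred strains B6 and PWK and their reciprocal F1
hybrids — under two diets with `r` mice per genotype × diet cell (default
r = 3, i.e. 24 mice). `BxP_F1` denotes a B6 mother × PWK father, so its
PWK allele is paternal; `PxB_F1` is the reverse. Allele-specific counts are
observed at transcribed SNPs that distinguish the strains, in the F1 mice
only (the parents are uninformative for parent-of-origin effects).

## Normalization

Between-sample scaling uses the trimmed mean of M-values. For library *k*
against reference *r* (the sample whose 75th-percentile
count-per-library-size is closest to the mean of those quantiles), with
relative abundances p = y/N:

* M_g = log2(p_gk / p_gr), A_g = ½(log2 p_gk + log2 p_gr), genes with a
  zero in either library dropped;
* the top and bottom 30% of M ranks and 5% of A ranks are trimmed
  (rank bounds ⌊n·t⌋+1 … n−⌊n·t⌋, average ranks for ties);
* the factor is 2 to the precision-weighted mean of the surviving M, with
  weights 1/v_g, v_g = (1−p_gk)/p_gk + (1−p_gr)/p_gr;
* factors are rescaled to geometric mean 1. If |M| < 1e-6 throughout, the
  factor is 1; if fewer than `min_usable` (default 10) genes survive the
  trim, the sample falls back to factor 1 with a warning.

The weights are computed **per read** (on relative abundances) rather than
from raw depths. This is the one deliberate departure from the
Bioconductor formulation: raw-depth weights make the factors depend on
absolute sequencing depth, so multiplying one library by a constant
perturbs every factor (~3×10⁻² in practice), whereas the analysis treats
depth as a nuisance handled by library size. With per-read weights the
whole algorithm is exactly scale-invariant; for libraries of similar
depth the two weightings agree to a few parts in 10⁴ (cross-checked
against edgeR in the test suite).

Expression values are log2(TMM-scaled CPM + 1), then baselined by
subtracting each gene's median across all samples. The pseudo-count of 1
CPM bounds the log at low counts; the median baseline makes values
comparable across genes in heat-map/box-plot style summaries and is
idempotent.

## Moderated t-test

With r = 3 per group, per-gene variances are unstable. The pooled variance
s²_g (d_g = n_a + n_b − 2 df) is modelled as s²_g ~ s₀² F(d_g, d₀); the
prior (d₀, s₀²) is fitted by matching the mean and variance of log s²_g
(digamma/trigamma moment equations, trigamma inverted by Newton
iteration). When the observed log-variances are *under*-dispersed relative
to pure chi-square noise the prior df is infinite and s₀² is the plain
mean of the variances — this makes shrinkage an exact identity when all
gene variances coincide. The posterior variance is

    s²_post = (d_g s²_g + d₀ s₀²) / (d_g + d₀)

and t_g = Δmean / √(s²_post (1/n_a + 1/n_b)) is referred to a t
distribution on d_g + d₀ df, capped at the pooled df across genes.
Forcing d₀ = 0 recovers the ordinary pooled t exactly; a Welch variant is
selectable. Zero-variance degenerate genes: p = 0 when the means differ,
p = 1 when equal. The implementation is cross-checked against limma's
eBayes to ~1e-9 on shared inputs, and its global-null type-I error at
n = 3 vs 3 sits in [0.04, 0.06] at the 0.05 level.

No multiple-testing correction is applied by default because the calling
rule screens on raw p < 0.05 combined with a fold threshold;
Benjamini–Hochberg is available behind a flag.

## Differential-expression calling

Fold change is the ratio of linear normalized group means with the
pseudo-count included: fold = (mean CPM_a + 1)/(mean CPM_b + 1), numerator
the first-named condition (a log-mean basis is selectable). Calls are
strict: `up` iff p < p_max and fold > fold_min; `down` iff p < p_max and
fold < 1/fold_min; else `ns`. Defaults p_max = 0.05, fold_min = 2
(fold_min = 5 for the PWK-vs-B6 strain comparison). A fold of exactly 2
is therefore not called.

## Parental-dependence classification

From the four genotype-wise HFD-vs-Con contrasts (shared gene universe):

* `paternal_up`: up in B6 **and** PxB_F1, not-up in PWK **and** BxP_F1;
* `maternal_up`: up in B6 **and** BxP_F1, not-up in PWK **and** PxB_F1;
* `*_down` mirror these with down calls.

"Not up" means failing the joint p/fold criterion for that direction —
the only reading under which the four categories are disjoint by
construction (each requires the other category's qualifying F1 to be
non-significant). No same-direction trend is demanded of the
non-significant genotypes. Genes lacking a call in any genotype are
`none`. Because "not up" admits both `down` and `ns` in the two excluded
genotypes, each category corresponds to exactly 4 of the 3⁴ = 81 possible
direction patterns.

## Imprinting screen

Per-SNP PWK-allele fraction f = pwk/(pwk + b6); zero-depth mice yield a
missing fraction. SNP filters, applied in order with per-rule tallies:
Y chromosome (case-insensitive), non-exonic, mean total depth across all
F1 mice strictly below 10, any mouse with zero reads. A mean depth of
exactly 10 is retained.

**Strict screen** (complete imprints): a SNP qualifies for PEG when the
mean paternal-allele fraction — f averaged over BxP_F1 mice and (1 − f)
over PxB_F1 mice — strictly exceeds 0.99 in *both* cross directions; one
qualifying SNP calls the gene; MEG mirrors with maternal fractions. The
99% rule is applied to cross means because the per-mouse alternative
(also available, `strict_per_sample`) is confounded with depth: at 50×
a single opposite-allele read drops a mouse to 98%, so the per-mouse rule
degenerates into "zero opposite reads in every mouse" and loses half of
genuinely complete imprints at realistic depths.

**Mild screen** (partial imprints): a SNP qualifies for PEG when
(1) per-mouse PWK fractions are significantly higher in BxP_F1 than
PxB_F1 (Student's equal-variance t by default, Welch selectable,
two-sided p < 0.05, direction checked separately; when both groups have
zero variance, p = 0 if the means differ and 1 otherwise), (2) the
cross-mean PWK fraction is strictly over 0.50 in BxP_F1 and strictly
under 0.50 in PxB_F1, and (3) the cross means differ by at least 0.20
(inclusive; "20% higher" read as 20 percentage points of allele
fraction). A gene is called with at least 4 qualifying SNPs. MEG criteria
are the identical conditions on B6-allele fractions.

All F1 mice from both diet groups enter the screen (6 per cross direction
by default): imprinting status is not expected to depend on diet, and
pooling maximizes t-test power. Criteria (2)–(3) act on cross-direction
means of per-mouse fractions; criterion (1) on the per-mouse replicates.
Strain-biased genes — equal allelic fractions in both crosses — fail the
mirror-image requirement of both screens by construction; the test suite
verifies they are never called as depth grows.

Candidates are matched against a known-imprint annotation by exact gene
id; a known PEG called MEG (or vice versa) is flagged as a conflict.

## Phenotype statistics

Imprinted genes are restricted to those expressed in the tissue (mean raw
count ≥ 5 across all samples; the floor is configurable). Per gene,
Pearson r between median-baselined log2 expression and body weight is
computed across all 24 mice, with per-status (PEG/MEG) medians and
quartiles; per-strain correlations are also emitted for inspection since
a per-strain reading of the analysis is equally defensible. The
HFD-induced shift of each imprinted gene within one genotype (default B6,
the obesity-prone strain) is the difference of group means with a
two-sided Student's t. The directional asymmetry test takes the
significantly shifted genes of one status and performs a 1-df chi-square
goodness-of-fit of the down/up split against 50:50 — the chi-square
construction is an interpretation choice (the test is named in the
analysis tradition this follows but the table is not), and the output
metadata flags it as such.

## Synthetic studies

The generator emulates the full design with recorded ground truth:

* **Counts**: negative-binomial, mean = baseline × library factor ×
  2^(effects), gene-wise dispersion φ log-normal (median 0.1, log-sd
  0.35; φ = 0 degenerates to Poisson). Baselines log-normal (median 100
  counts, log-sd 1.2). Library factors log-uniform in [0.7, 1.4] so TMM
  has real work to do.
* **Effects**: diet responses (default 4-fold) planted as B6-paternal
  (respond in B6 and PxB_F1 only), B6-maternal, or shared classes; cis
  strain effects scale expression with PWK-allele dose (0/1/2); imprinted
  genes additionally respond to diet in every genotype (PEGs −1 log2,
  MEGs +1 log2 under HFD), reproducing the anti-/pro-obesity coupling the
  phenotype stage is designed to detect.
* **Allelic counts**: per SNP × F1 mouse, depth ~ Poisson(50), PWK-allele
  count beta-binomial(depth, p, ρ = 0.02) with p the paternal fraction
  when the PWK allele is paternal and its complement otherwise; complete
  imprints draw paternal fractions in [0.99, 1], partial in [0.70, 0.90],
  strain-biased genes use one fixed PWK fraction in both crosses.
* **Body weights**: base 30 g + 12 g HFD effect + genotype terms (PWK
  −8 g, BxP_F1 −5 g, PxB_F1 −2 g: obesity risk follows the paternal B6
  allele) + Σ coupling × standardized log-expression (−0.5 g/SD for PEGs,
  +0.5 g/SD for MEGs) + Gaussian noise (sd 1.5 g), clipped positive.

All randomness flows from one mandatory integer seed; identical seeds
give byte-identical outputs.

**What the synthetic studies do not model**: read-level artifacts
(mapping bias toward the reference allele, PCR duplicates), correlated
SNPs within a read, annotation errors, batch structure, and biological
co-expression between genes. Passing recovery tests therefore certifies
the *logic and calibration* of each stage under the assumed noise
families, not robustness to alignment-level artifacts — on real data the
screen's input must already be allele-resolved counts of reasonable
quality.

## Recovery scenarios and problem sizes

Test and acceptance runs use 2,000-gene studies (24 mice, 5 SNPs/gene,
depth 50) — large enough for stable rate estimates while keeping the
whole suite under a minute of compute. Scored scenarios: strict-screen
sensitivity on 50 + 50 complete PEGs/MEGs with 50 strain-biased and
~1,800 biallelic negatives; mild-screen sensitivity on 50 partial PEGs at
paternal fraction 0.75; parental classification of 200 planted
B6-paternal 4-fold responders at dispersion exactly 0.1; a 10,000-gene
global-null calibration of the moderated t. The strain-comparison (5-fold
Venn) scenario draws planted genes with a narrower baseline spread
(log-sd 0.6): with the full spread the lowest-count genes are
structurally undetectable at a 5-fold threshold with a 1-CPM pseudo-count,
and the scenario is meant to measure the set logic, not count-depth
detectability. The 378-fold marker-recovery scenario uses near-zero
dispersion (φ = 0.001) for the same reason.

## Numerical details and edge cases

* Thresholds are strict everywhere the rule is printed as a strict
  inequality (p < 0.05, fold > 2, > 99%, over/under 50%) and inclusive
  where stated as "at least" (0.20 gap, ≥ 4 SNPs).
* Ties in TMM trimming use average ranks; trimming bounds follow the
  floor convention above.
* The trigamma inverse uses Newton iteration from y = 0.5 + 1/x with
  closed-form guards for very large/small arguments.
* Constant expression vectors yield missing correlations, not errors;
  missing weights or diet groups are hard errors naming the sample/stage.
* The pipeline manifest omits wall-clock timestamps by default so reruns
  of the same config and seed are byte-identical; `record_timestamp`
  turns them back on.

## Known limitations

* The moderated t approximates the original analysis product's
  unpublished "moderate t-test"; exact gene lists can differ from that
  tool even on identical inputs (a plain Student/Welch t is available).
* Fold changes use linear CPM means with a +1 pseudo-count; very
  low-expressed genes are conservatively shrunk toward fold 1.
* The screen operates per gene id as given in the SNP table; no
  annotation lifting, deduplication of SNPs within a read pair, or
  haplotype phasing is attempted.
* Multi-SNP evidence is counted per SNP; linkage between SNPs of the same
  gene (shared reads) would make the effective SNP count smaller than the
  nominal one on real data.
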