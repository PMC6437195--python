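# Methods

## The model

A CpG methylation phenotype (residualised M values in real data; simulated
directly here) over n family-structured individuals is modelled as

    y = Xb + Σ_i u_i + e,     u_i ~ N(0, σ²_i A_i),   e ~ N(0, σ²_e I)

with relationship matrices A_i drawn from seven kinds:

| kind | meaning | construction |
|------|---------|--------------|
| G | common-SNP additive relationships | VanRaden GRM: G_ij = m⁻¹ Σ_s (x_is − 2p_s)(x_js − 2p_s)/(2p_s(1−p_s)); monomorphic SNPs dropped |
| K | close-relative (pedigree-associated) additive | G with off-diagonal entries < 0.05 zeroed (threshold configurable) |
| F | nuclear family | indicator: couple, parent-offspring or full-sib pair |
| S | full siblings | indicator: both parents shared |
| C | couples | indicator: share ≥ 1 common offspring |
| S_M | maternal-imprinting signature | indicator: full sibs OR father-offspring |
| S_P | paternal-imprinting signature | indicator: full sibs OR mother-offspring |

Fitting G and K jointly separates variance tagged by common SNPs in
nominally unrelated pairs from the residual close-relative resemblance; the
indicator matrices capture shared-environment layers.  The GKFSC
decomposition fits all five (G, K, F, S, C) simultaneously and reports each
component's proportion of phenotypic variance with a one-sided Wald test
p = 1 − Φ(σ̂²/SE).

Why S, S_M and S_P detect imprinting: under additive inheritance
parent-offspring and full-sib covariances are comparable, but when one
parental allele is silenced, the phenotype tracks the expressed allele,
which full sibs share more often than the silenced-side parent shares with
the offspring.  Complex (bipolar) imprinting — reciprocal heterozygotes aA
and Aa differ while homozygotes agree — inflates only the sib covariance
(matrix S); maternal imprinting (maternal allele silenced) inflates sib and
father-offspring covariance (S_M); paternal imprinting the mirror (S_P).
The scan compares the base model y ~ G + K against each alternative adding
one of S/S_M/S_P, by a one-sided LRT.

## REML

Average-information (AI) REML on the full dense covariance:

- restricted log-likelihood (constant dropped)
  l_R = −½[log|V| + log|X'V⁻¹X| + y'Py], P the usual REML projection;
- first iteration EM, then AI steps δ = AI⁻¹ s with
  s_i = ½(y'PA_iPy − tr(PA_i)) and AI_ij = ½ y'PA_iPA_jPy;
- components an AI step would drive negative are truncated at the boundary
  and the system re-solved for the remainder; components sitting at the
  boundary with a negative score are pinned (active set) and released when
  their score turns positive; EM remains the fallback when the AI system is
  singular or would force the residual negative;
- step-halving toward the previous iterate keeps l_R non-decreasing;
- convergence: |Δl_R| < 1e-6 and max|Δσ²| < 1e-8·max(1, var(y)) (the
  variance scaling makes the parameter criterion scale-invariant), at most
  100 iterations; non-convergence is flagged on the result, not raised;
- standard errors from the inverse AI matrix (flagged untrustworthy for
  boundary components);
- starting values: phenotypic variance split equally across components,
  unless warm starts are supplied (the scan warm-starts alternatives from
  the base fit).

Boundary tests: adding one variance component tests σ² = 0 on the edge of
the parameter space, so the LRT reference distribution is the equal mixture
½χ²₀ + ½χ²₁ — p = ½P(χ²₁ ≥ LRT) for a positive statistic, ½ at zero (the
statistic is floored at zero against numerical noise).  Whether one halves
a χ²₁ p-value or uses the mixture only differs at a statistic of exactly 0,
which never affects significant sites; the mixture is implemented as the
statistically correct form.

Scan selection rule: per CpG the alternative with the largest
log-likelihood is the candidate (ties broken complex > maternal > paternal,
since the sib pattern nests inside both one-parent patterns); its LRT
p-value enters one Benjamini–Hochberg pass across CpGs and the CpG is
labelled with the candidate model iff q ≤ 0.05.  Because all three
alternatives share the base log-likelihood, the max-log-likelihood
candidate is automatically the min-p candidate, so "select the significant
alternative with the largest gain" and "select the best, then gate on FDR"
coincide.  Applying FDR to best-of-three p-values is mildly
anti-conservative; the null-calibration test bounds the realised type-I
rate instead of assuming uniformity.  CpGs whose base model does not
converge are excluded; non-converged alternatives are skipped per CpG and
recorded.

## Origin assignment

Offspring phase is taken as known within a chromosome but with arbitrary
haplotype-to-parent orientation.  For each chromosome both orientations are
scored against the available parents; a locus votes when the offspring is
heterozygous and exactly one orientation is Mendelian-compatible (e.g. an
opposite-homozygous parent, or in duos a parent that cannot supply one of
the alleles).  The majority orientation (winning margin ≥ 1, configurable)
labels every locus on the chromosome; homozygous loci are labelled
trivially.  Loci incompatible with both orientations, or with the chosen
one, are flagged `inconsistent` rather than assigned — assignment never
silently contradicts Mendelian inheritance.  Whole-chromosome voting is
robust to isolated genotype errors; per-locus phase-switch errors from
statistical phasing are out of scope here because simulated haplotypes are
transmitted whole (no recombination model).

## POE regression

Ordered genotypes (paternal allele first) map to three codings —
additive (0,1,1,2), dominance (0,1,1,0), POE (0,−1,+1,0) for
(AA, Aa, aA, aa) — fitted jointly by OLS with intercept against
pre-corrected phenotypes; two-sided t-tests per coefficient.  With balanced
classes the centred codings are orthogonal.  β_poe equals half the
reciprocal-heterozygote mean difference; flipping the paternal-first
convention flips only its sign.  Columns collinear after class dropout
(e.g. dominance without minor homozygotes) are dropped and flagged.
Pre-correction (`scan.pre_correct`) removes fixed-effect predictions and
the summed BLUPs of fitted random effects (G for mQTL; G + K for traits),
so the per-SNP regressions need no mixed model.

Supporting rules: cis = same chromosome < 1 Mb, trans = > 5 Mb or different
chromosome, 1–5 Mb excluded as ambiguous; permutation FDR threshold
t* = largest observed p with (mean permuted count ≤ t)/(observed count ≤ t)
≤ q, permutations shuffling individual identity jointly across phenotypes
(10 replicates by default); greedy clumping around the smallest-p index
within ±250 kb at r² ≥ 0.1, applied to SNPs (genotype r²) and CpGs
(squared methylation correlation) alike.

## Trait analyses

The effective number of independently tested traits N_eff is the smallest k
whose leading correlation-matrix eigenvalues reach 95% of the variance,
verified by Kaiser's rule (all later eigenvalues < 0.5); when the two
criteria disagree the conservative max(k, #eigenvalues ≥ 0.5) is used with
a warning — for exactly independent traits this correctly returns the full
trait count rather than the 95%-rounding artefact.  Bonferroni tiers:
multi-trait α/(N_eff·n_CpGs) and per-trait α/n_CpGs for EWAS;
α/(n_independent_SNPs·N_eff) phenome-wide for PheWAS.  POE-by-sex
interactions add moderator and poe×moderator terms to the joint regression;
the age profile runs the plain POE test within sample-quantile age deciles
(ties to the lower decile).

## Enrichment

Sites are classified by distance to a merged reference region set:
`replication` strictly within 2 kb (distance 0 inside), `overlap` 2 kb–2 Mb,
`not_identified` beyond 2 Mb — the criterion for calling a hit previously
unidentified.  Enrichment uses the two-sided Fisher exact test with the
conditional-MLE odds ratio and 95% CI (sample odds ratio reported
alongside, with explicit 0/∞ bounds at zero cells) and Bonferroni
correction across annotations.  BED input is 0-based half-open and
converted to 1-based inclusive internally; distances are measured from the
single-base site to the nearest region edge.

## Synthetic data

The generator emulates a family cohort: nuclear families (founder couple +
offspring), optional masking of parents into father-/mother-duos or
fully ungenotyped, biallelic SNPs with per-SNP MAF uniform on a
configurable range (≥ 0.01, default 0.05–0.5), founder haplotypes drawn at
the allele frequency and offspring receiving one complete parental
haplotype per chromosome.  Phenotypes sum a polygenic term with covariance
σ²_g·G (realised GRM, eigenvalue-clipped factorisation so thresholded or
numerically indefinite matrices still simulate), a σ²_k·K term, shared
deviations per family/sibship/couple (exactly equivalent to the indicator
covariances because the groups partition a two-generation pedigree, and
O(n) instead of an eigendecomposition), a parent-of-origin term at the
causal SNP — complex: β(x_pat − x_mat); maternal imprinting: 2β·x_pat;
paternal: 2β·x_mat, so maternal/paternal patterns imply
|β_add| = |β_poe| in the regression coding and the complex pattern aligns
exactly with it — and iid residual taking the remaining variance (an
explicit σ²_e = 0 gives noise-free phenotypes for exact tests).  Default
variance fractions (σ²_g = 0.095, σ²_k = 0.072, σ²_f = 0.012, σ²_s = 0.014,
σ²_c = 0.021) reflect realistic genome-wide averages for blood methylation
in a family cohort.  Traits are multivariate normal with a configurable
cross-trait correlation and optional planted dependence on a CpG or SNP.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: linkage disequilibrium and recombination
(haplotypes transmit whole), imputation uncertainty and genotype error,
phase-switch errors from statistical phasing, array normalisation/batch
structure, cell-composition effects, X-chromosome inheritance, and
multi-generation pedigrees.  Conclusions about calibration and power
therefore apply to idealised family data; real-data deployments need the
usual upstream QC.

## Problem sizes in the validation suite

Chosen as the package's own benchmark scales: origin accuracy on 500 trios
× 500 SNPs; REML parameter recovery on 500 two-offspring families
(n = 2000, 20 replicates); scan calibration on 200 two-offspring families
(n = 800) over 500 null CpGs and 50 planted-imprinting replicates; small
exhaustive oracles (≤ 15 records, 10-vectors, n ≤ 200 tables) for
clumping, BH-FDR and Fisher tests.

## Known limitations

- Dense O(n³) REML per iteration: comfortable to a few thousand
  individuals, not biobank scale.
- The scan's FDR-after-selection inherits mild anti-conservativeness from
  best-of-three selection (documented above).
- Permutation FDR averages counts across replicates (pooled alternative
  estimators exist); 10 replicates bound the resolution of the estimated
  threshold.
- Couples are defined through shared offspring; childless couples are not
  representable from a pedigree alone.
- Standard errors at the variance boundary are reported but unreliable;
  downstream code should respect the boundary flags.
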