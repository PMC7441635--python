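# Methods

## The model

`xkin` implements the additive-genetic relationship algebra of the
X-chromosome for species with XX/XY sex determination (mammalian
convention; swap sexes for birds). All matrices refer to the scale on which
the gene-content variance of an ideal female population is 1, i.e.

    Var(m) = K * 2pq

for the relationship matrix `K` at a biallelic locus with allele
frequencies p, q, gene content coded {0,1} in hemizygous males and {0,1,2}
in females. Allelic effects are expressed as expected differences among
female descendants, with no imprinting: under this convention no assumption
about dosage compensation enters the relationship matrices themselves, and
compensation appears only as an explicit, estimable scaling factor k on
male effects.

### Expected relationships

* **A** (`build_A`): standard tabular recursion, `a_ii = 1 + 0.5 a_sd`,
  `a_ij = 0.5 (a_js + a_jd)`.
* **S** (`build_S`): the X-specific recursion. A male carries a single
  copy, inherited from the dam with Mendelian sampling; his diagonal is
  exactly 0.5 and he is unrelated to his sire. A female receives her
  sire's copy deterministically (no sampling, no recombination) plus one
  sampled dam gamete:

      male i:   S(i,x) = 0.5 S(d,x);             S(i,i) = 0.5
      female i: S(i,x) = S(s,x) + 0.5 S(d,x);    S(i,i) = 1 + S(s,d)

  The sparse inverse (`build_S_inverse`) accumulates per-individual
  contributions with regressions b = {0.5 dam} (males) and {1 sire,
  0.5 dam} (females) and Mendelian-sampling variance
  `v_i = S_ii - b' S_PP b` (= 0.5 - 0.25 S_dd for both sexes when both
  parents are known). Unknown parents contribute nothing and are dropped
  from the regression, which encodes the base-population convention.
* **S with metafounders** (`build_S_metafounders`): unknown parent slots
  are assigned to sexed metafounder pseudo-parents (one male-line and one
  female-line per genetic group) and the same recursion runs with the
  metafounder block seeded from the user-supplied gamma matrix. We derived
  the seeding from the gametic model in which two base gametes from lines
  a and b are IBD with probability gamma_ab/2 under the p = 0.5 reference:
  the founder-block entry is `gamma_ab * w_a * w_b` with w = 0.5 for a
  male-line and 1 for a female-line metafounder. With gamma = 0 the result
  is identical to S; the construction is validated against a constructive
  gene-dropping oracle with shared line alleles (gamma = 2 s s'). Gamma is
  taken as given — estimating it is out of scope.
* **P^r** (`build_P_par`): pseudo-autosomal expected relationships at
  recombination fraction r from the pseudo-autosomal boundary (PAB). Male
  meiosis exhibits a sex-gradient: a son receives the sire's paternal
  (Y-side) gamete with probability 1 - r, a daughter the sire's maternal
  (X-side) gamete with probability 1 - r; dams transmit evenly. The matrix
  is built by the conditional-expectation recursion on the 2n x 2n gametic
  relationship matrix and collapsed to individuals. At r = 0.5 it equals A
  exactly. Map distances are converted to recombination fractions with
  Haldane's function c(d) = (1 - e^(-2d/100))/2 (distances in cM, no
  interference) — the simplest closure consistent with the probabilistic
  transmission model used throughout.

A note on the daughter transmission probability: we model daughters as
receiving the sire's X-side haplotype with probability 1 - r. Formulations
that assign the same (1 - r, r) weights to sons and daughters break the
complementarity of the two sire haplotypes and contradict the mechanism
that links PAR inheritance to offspring sex; the gene-dropping oracle
confirms the complementary version.

### Realized relationships

`build_GX` computes

    G^X = Z Z' / (2 sum p_j q_j),   Z = [k (M_males - 1p') ; M_females - 2p']

Males are centered by p (not 2p) and may be scaled by the
dosage-compensation factor k. Under this construction the expected
diagonal is 0.5 for males and 1 for females and the expected mean of any
population block is 0 — but only when the *generating* (base) allele
frequencies are used for centering; with sample frequencies relationships
are biased slightly downward relative to S (asserted as a sign test).
The `weighted=True` variant standardizes each locus by its own 2pq before
an unweighted cross-product, up-weighting rare alleles. `build_G_auto` is
the ordinary VanRaden-type autosomal GRM and is also the correct
construction for PAR loci (both sexes diploid there). Monomorphic loci are
dropped with a logged count; missing genotypes are imputed to the
per-locus mean of the same sex, which keeps E[Z] = 0 per sex. The same
frequency vector is always used for centering and for the denominator.

### Single step

Gene content is a quantitative trait with heritability 1 and covariance
S * 2pq, so ungenotyped individuals (block 1) are merged with genotyped
ones (block 2) by the regression `z1_hat = S12 S22^-1 z2` with conditional
variance `(S11 - S12 S22^-1 S21) * 2pq`. Propagating G^X through the same
regression yields H^X with blocks

    [ S11 - S12 S22^-1 S21 + S12 S22^-1 G^X S22^-1 S21   S12 S22^-1 G^X ]
    [ G^X S22^-1 S21                                      G^X            ]

and inverse `S^-1 + [[0,0],[0, G^X^-1 - S22^-1]]`. Because male X copies
are frequently shared intact, G^X is often singular; `blend` first rescales
G^X by the exact two-equation linear adjustment that matches its mean
diagonal and overall mean to S (computed on the variance-equalized scale —
male axes times sqrt(2) — and mapped back), then returns
`alpha S + (1 - alpha) G^X`. The moment match is an exact two-point solve,
not a least-squares fit over entries, so it is deterministic. G^X is
declared numerically singular above condition number 1e10.

### Heritability of gene content

`reml_single_kinship` fits y = 1 mu + u + e with Var(u) = sigma2_u K,
Var(e) = sigma2_e I by restricted maximum likelihood. For one kinship plus
an identity residual the REML problem is exactly one-dimensional after an
eigendecomposition of K, so the package profiles the variance ratio on a
log scale over [1e-6, 1e6] (Brent search; estimates at the ends are flagged
`boundary`, capping reportable h2 at ~0.999999). This replaces iterative
AI-REML for this model class: same maximum, no convergence tuning. A
brute-force 2-D grid search over (sigma2_u, sigma2_e) is kept as a test
oracle. `h2_scan` applies the fit per locus to raw gene content, with the
MAF filter computed on the analyzed subset — this matters for males-only
runs, where a locus common overall can be rare among males. When males are
coded {0,k} instead of {0,1}, S must be rescaled (`rescale_S`: male-male
block times k^2, male-female blocks times k) for h2 to return to 1.

### Dosage compensation

For a trait recorded in both sexes, male and female phenotypes are treated
as two traits with genetic covariance `Sigma (x) G~`, where `G~` is the
variance-equalized kernel (male axes of G^X scaled by sqrt(2); unit
expected diagonal for both sexes). On that scale, a genetic correlation of
1 implies

    Sigma = sigma2_u [[k^2/2, k/sqrt(2)], [k/sqrt(2), 1]]

so k is solvable two ways — `k_var = sqrt(2 sigma2_m / sigma2_f)` and
`k_cov = sqrt(2) sigma_mf / sigma2_f` — and their agreement (plus r_g ~ 1)
is the model check reported by `solve_k`. The equalized kernel is
essential: with the raw G^X (male diagonal 0.5) the male multiplier would
absorb an extra factor 2 and k_var would recover sqrt(2) k.

The restricted likelihood is maximized directly by L-BFGS-B on
(log sigma2_e_m, log sigma2_e_f, Cholesky of Sigma), with the deviance
evaluated through a low-rank square root of G^X (the centered-genotype
factor when available, else a truncated eigendecomposition) and the
Woodbury identity, so each evaluation costs O(r^3) with r = rank(G^X).
Parameterizing through the Cholesky factor keeps the deviance finite and
smooth at the r_g = 1 boundary, where EM-style updates stall; the fit is
deterministic given data and the neutral start (half the phenotypic
variance per component, zero covariance). Sex-specific traits are refused
with an explanatory error: k is irrelevant when only one sex is
phenotyped. `snp_blup` provides the equivalent marker-effect (ridge)
formulation with male design rows scaled by k; its predictions match
GBLUP with the matching k-scaled G^X to numerical precision, which is
asserted as a test.

## The simulator

`xsimulate`-style gene dropping is the package's Monte-Carlo oracle, not a
fixture: every expected-relationship formula is validated against it.

* Discrete generations, fixed numbers of males and females per generation,
  random sire/dam assignment from the previous generation.
* X-specific dropping: founder alleles Bernoulli(p); males carry one
  haplotype; daughters receive the sire haplotype intact (zero crossovers
  by construction); maternal gametes recombine along the female map under
  a Haldane (no-interference) Markov chain over adjacent intervals.
* PAR dropping: male meiosis is anchored at the PAB on the haplotype
  matching the offspring sex and switches at Haldane crossovers; female
  meiosis is autosomal-like. Anchoring on the offspring-sex-matched
  haplotype is the conditional view of the mechanistic statement that the
  transmitted sire gamete (X- or Y-bearing) determines offspring sex.
* `independent_loci=True` drops every locus independently while keeping
  the correct per-locus marginals (for anchored male PAR meiosis the
  switch probability at distance d is c(d)); this is the regime of the
  covariance oracles, where linkage is irrelevant.
* Phenotypes: female-trait marker effects iid normal; male-trait effects
  correlate r_g and are scaled by k; residual variance calibrated to the
  female-trait heritability target.

Defaults: base frequency 0.5, female X map length 1 Morgan (at which about
e^-1 ~ 37% of female gametes carry no crossover — a realistic mammalian
scale), PAR map 0-50 cM. All randomness flows from a single mandatory
seed; runs are bit-reproducible.

What the simulator does *not* emulate: mutation, selection, assortative or
litter-structured mating, genotyping error, array ascertainment, crossover
interference, and linkage disequilibrium among founders. Passing tests
therefore certify the transmission algebra and the estimators under the
stated model, not robustness to real-data artifacts such as pedigree
errors or array QC issues.

## Statistical testing conventions

Monte-Carlo checks compare empirical moments to theory in units of the
Monte-Carlo standard error estimated from the per-locus spread of
cross-products (no Gaussianity assumed beyond the CLT over loci).
Entrywise covariance oracles over ~500 unique entries necessarily show
~0.3% chance exceedances of 3 SE — and more in clusters, because entries
of one pedigree share meioses — so those tests allow a small fraction of
3-SE exceedances while requiring every entry within 4.5 SE; a genuine
formula error sits tens of SEs away at 2e5 loci, so the hard cap is the
discriminating bound.

Per-locus REML estimates of a heritability that is truly 1 are
noise-limited from below at moderate sample sizes and capped at 0.999999
by the profile bound, so per-locus orderings between two kinship matrices
are asserted strictly only in the high-contrast males-only design and as a
>= 90% majority (plus a strict mean ordering) in the mixed-sex design.

## Problem sizes

Test and reproduction runs use: 30-individual pedigrees with 2e5
independently dropped loci for the covariance oracles; 1200-individual
pedigrees (25 males, 175 females per generation — a livestock-like sex
ratio) for the heritability-of-gene-content scan; ~400 individuals for the
reported mean h2; 5000 + 5000 unrelated individuals at 1000 loci for the
GRM diagonal moments; and 50 replicates of 1000 + 1000 individuals at 300
loci for dosage-compensation recovery. These sizes give Monte-Carlo
standard errors comfortably inside the assertions' tolerances.

## Known limitations

* The PAR matrix P^r is exact for a single locus at a given r; a
  chromosome-wide PAR analysis needs one matrix per position (or an
  average), which the CLI supports only one position at a time.
* The bivariate REML assumes one phenotype per individual and per-sex
  intercepts as the only fixed effects.
* Metafounder gamma matrices are user-supplied, never estimated.
* `read_genotypes` infers the {0,2} male coding from the file format
  (PLINK .raw) or the presence of male 2s; an all-{0,1} file that was
  *intended* as {0,2} cannot be detected.
* No support for binary PLINK or VCF input; no phasing or imputation
  beyond per-sex mean fill.
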