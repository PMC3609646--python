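# Methods

## The model

Carriers are followed on a yearly age grid from 18 to 80. For one disease,
a carrier with modifier genotype `g` (copies of allele 2) has discrete
yearly hazard `λ0(t)·r_g`, with `r_g = exp(βg)` under the per-allele
(multiplicative) model or `(1, exp(β1), exp(β2))` under the
genotype-specific model.

`λ0(t)` is never a free parameter. The average age-specific incidence for
carriers, `λ̄(t)`, is taken as known (an input CSV; published penetrance
estimates in practice), and the baseline is solved at every age from the
constraint that the genotype-weighted hazard among unaffected survivors
equals `λ̄(t)`:

```
λ0(t) = λ̄(t) / Σ_g π_g(t) r_g,
π_g(t+1) ∝ π_g(t) · (1 − λ0(t) r_g),      π(18) = HWE(p).
```

The survivor update matters: risk genotypes are depleted from the
unaffected pool with age, and it is exactly this depletion that makes the
probability-weighted average of the per-genotype cumulative risks equal the
population risk at every age (tested to 1e-8). The constraint is re-solved
inside every likelihood evaluation rather than profiled once; at the
problem sizes this package targets the exact version is cheap.

### Retrospective likelihood

Because carrier cohorts are sampled through clinics with a strong bias
toward affected women, the likelihood conditions on phenotype:

```
log L = Σ_i log [ P(d_i, t_i | g_i) P(g_i) ] − log [ Σ_g P(d_i, t_i | g) P(g) ]
```

with `P(d, t | g)` the discrete-time survival likelihood above (censored at
age t: survival through year t; event at age t: survival through t−1 times
the hazard in year t; within-year ties broken breast < ovarian < surgery <
censoring) and `P(g)` HWE at the per-stratum allele-2 frequency. Missing
genotypes contribute nothing. Imputed dosages enter as soft genotype
weights (the nearest three-point distribution with the dosage as its mean),
which reduces to the hard-call likelihood at integer dosages and makes the
null score exactly linear in the expected allele count, matching the usual
posterior-probability score test for imputed markers.

### Score test

Differentiating at β = 0 gives the 1-df score

```
U = Σ_i w̃_i (g_i − 2 p̂_s(i)),    w_i = δ_i − Σ_{u ∈ risk years} λ̄_s(u) / (1 − λ̄_s(u)),
```

a discrete-time martingale-residual weight, centred within stratum
(`w̃ = w − w̄_s`). Two design choices here deserve a note:

* **Allele frequency in the test.** The score plugs the per-stratum allele
  frequency of the analysis samples. With that choice, centring changes
  nothing algebraically (`Σ_s (g − 2p̂_s) = 0`) and `U` is the *exact*
  derivative of the plug-in log-likelihood — verified against a central
  finite difference to ~1e-12 relative error. It also makes the score
  invariant to the frequency estimate entirely, which keeps the null
  distribution calibrated no matter how distorted the sample frequency is
  by ascertainment. The conventional *reported* `freq2` remains the
  frequency among unaffected carriers.
* **Variances.** The kinship-adjusted variance uses
  `cov(g_i, g_j) = 2φ_ij σ_i σ_j` with the genotype variance estimated
  empirically with score-weighted residuals
  (`σ̂² = Σ w̃²(g−2p̂)² / Σ w̃²`) rather than the binomial `2p(1−p)`. With
  an identity kinship this makes the kinship variance coincide *exactly*
  with the family-cluster sandwich at singleton clusters, so the two
  variance routes agree whenever they should. The robust variance is the
  usual cluster sandwich over reported families. The headline P-value uses
  the kinship variance.

Calibration was checked by simulation: 2,000 null cohorts of 1,000
proband-ascertained carriers give a 5%-level rejection rate of 0.043
(binomial band [0.040, 0.060]) and a mean null chi-square of ~1.00.

### Maximum likelihood

`fit()` maximises the stratified retrospective log-likelihood by
Newton–Raphson with central-finite-difference derivatives, step-halving on
any likelihood decrease, convergence at |Δβ| < 1e-8 or 50 iterations, and
CIs from the observed information. The grid-search oracle (β over ±0.7 in
steps of 1e-3) agrees with the Newton optimum within 2e-3.

By default the per-stratum allele frequencies are plugged in
(`freq_mode='sample'`; `'unaffected'` is available for the conventional
choice). Under *random* sampling the plug-in is unbiased and the MLE
recovers simulated HRs with negligible bias. Under strong affected-biased
sampling the sample frequency itself is inflated by the ascertainment and
the plug-in MLE is biased downward; `fit(profile_freq=True)` therefore
estimates the frequencies jointly with β on the logit scale, restoring
near-zero bias (measured: −0.0005 on the log scale at HR 1.3, n = 5,000
all-affected carriers, with 93.5% CI coverage). The joint fit is the
recommended route for heavily ascertained cohorts; plug-in remains the
default because it is the cheaper, conventional choice and is exact for
the score test either way.

### Competing risks

Breast and ovarian cancer are modelled as independent cause-specific
processes given genotype. Follow-up for events ends at the first cancer;
mastectomy censors only the breast horizon and RRSO only the ovarian one,
so the two at-risk horizons are encoded separately per carrier. The joint
per-genotype likelihood is the product of the two cause-specific survival
likelihoods; both baselines are constrained to their own incidence curves
with a *shared* survivor pool depleted by both diseases. `(β_BC, β_OC)` is
maximised jointly (2-d Newton); CIs come from the joint information with no
a-priori covariance restriction. If one disease has no events (or a zero
incidence curve) its log-HR is reported unidentifiable and fixed at 0, and
the other disease's estimate reduces exactly to the single-disease fit.

## Quality control

Filters run in a fixed order: sample call rate → sample heterozygosity
(mean ± 4 SD; the band is a convention, chosen because only "low or high
heterozygosity" is specified in this field's pipelines) → declared-
duplicate resolution (keep the higher call rate) → SNP call rate →
monomorphic SNPs → country-stratified HWE (P < 1e-7) → SNPs discordant
among declared duplicates (pair concordance < 98%, computed on
pre-resolution calls). Inferred-gender exclusion needs sex-chromosome data
outside this data model and is replaced by an optional user exclusion
list.

The stratified HWE statistic combines per-stratum disequilibrium
coefficients `f̂_s = 1 − h_obs/h_exp` with inverse-variance weights (null
variance 1/n_s): `χ² = (Σ n_s f̂_s)² / Σ n_s`. With one stratum this *is*
the classic Pearson HWE chi-square (`n f̂²`), which fixes the convention;
the published construction it stands in for is cited but not reproduced in
the source literature, so agreement with historical counts at the
boundary is not claimed. Stratification removes the Wahlund effect: two
strata in perfect internal HWE at frequencies 0.1 and 0.9 give P ≈ 1
stratified versus P ≈ 1e-19 pooled.

## Kinship and ancestry

Kinship uses the allele-frequency-standardised estimator
`φ̂_ij = mean_k (g_ik − 2p_k)(g_jk − 2p_k) / (4 p_k (1 − p_k))` on greedily
r²-pruned SNPs (r² < 0.10), pairwise-deleting missing cells; the diagonal
uses the same form (~0.5 for non-inbred samples). Two small-sample caveats
are documented rather than hidden: in-sample frequencies attenuate
estimates by O(1/n), and greedy pruning against *sample* correlations in
small cohorts selects against chance correlation and deflates kinship —
`prune_r2=None` skips pruning for panels pruned upstream.

Ancestry: kinship is mapped to distances `max(0, 0.5 − φ̂)` (duplicates at
distance 0), classically scaled, and the first two components oriented so
the European reference centroid is non-negative. The European fraction of
a sample is its orthogonal projection onto the segment from the nearest
non-European reference centroid to the European centroid, clamped to
[0, 1]; samples with > 22% non-European fraction are excluded. The
projection geometry is this package's construction (the original method's
formulas are not public); it reproduces the required behaviour — reference
panels at 0/1, 50/50 admixture near 0.5 — and the exclusion boundary is
exact by construction (0.75 excluded, 0.80 retained at the default
threshold).

## Staged selection and stage pooling

Selection quotas follow the nominal proportions (61.5, 20, 2.5, 2.5, 2.5,
0.5, 0.5, 10%) with floor-then-largest-remainder rounding (ties to the
lower analysis index). Quotas fill in ascending analysis order by P-value
rank; a SNP already selected is skipped (dedup during fill, so provenance
goes to the earlier-filled analysis); a SNP with r² ≥ 0.90 to a
higher-ranking selected SNP is admitted only below the analysis gate
(1e-4 for the two main analyses, 1e-5 otherwise) and at most twice per LD
group. Unused quota spills back proportionally in a second pass — overflow
handling is unspecified in the source design, so this is a package
decision. Design-score-driven SNP replacement is reduced to an optional
user-supplied replacement map.

Combining stages is pure stratification (stage × country strata, or the
three super-strata Europe/Australia/USA+Canada for small stage-3 cohorts):
scores and information add across strata, and a single stage is bitwise
identical to the plain stratified analysis.

## Combined-SNP profiles

All 3^K multilocus genotypes (K ≤ 20) are enumerated with HWE product
probabilities and multiplicative combined HRs, renormalised so the
lowest-risk category is 1 (protective alleles anchor at their homozygous
state — no re-orientation needed). Percentiles use the lower-step
convention: the smallest category HR whose cumulative probability reaches
q. Absolute-risk curves generalise the constrained baseline to the
enumerated categories with survivor depletion; the non-depleting variant is
selectable for comparison but demonstrably violates conservation. The
bundled ovarian table holds the top SNP per region among the seven known
ovarian-risk modifier loci for BRCA1 carriers; the breast-profile analogue
requires effect estimates and incidence curves published outside this
package's bundled inputs, so the breast table is user-suppliable rather
than shipped.

## Synthetic cohorts

The generator emulates clinic ascertainment: families are two founder
parents (genotypes HWE at the configured MAFs) plus a sibship of carriers
by Mendelian transmission; a family is retained only if a designated
proband — the eldest affected member — exists. Onset ages are inverse-CDF
draws from the yearly genotype-specific hazards under the same constrained
baseline the estimators assume (enumerated over loci with non-zero
effects); breast and ovarian onsets are independent given genotype.
Prophylactic surgery uptake is a constant per-year probability (mastectomy
0.5%/yr from 30, RRSO 1%/yr from 35 — free parameters, since no published
uptake model exists); administrative censoring is uniform on 25-80 years;
missingness, duplicate samples (genotype-identical before missingness) and
ancestry outliers (all MAFs shifted by a constant, a deliberately crude
two-population model sufficient to exercise the MDS exclusion) are planted
as configured and recorded in the truth record together with every latent
parameter.

The default incidence curves are synthetic, penetrance-consistent
piecewise-constant hazards (~64% breast and ~42% ovarian cumulative risk by
80 — in line with published carrier penetrance). What the simulator does
*not* emulate: linkage disequilibrium beyond family transmission,
multi-generation pedigrees, genotyping error beyond missingness,
calendar-cohort incidence variation, left truncation at genetic testing
(follow-up starts at 18 with no delayed entry — a documented default where
practice varies), and ER-subtype structure. Passing tests therefore
demonstrate correctness of the estimators under the stated sampling and
hazard model, not robustness to those additional features of real cohorts.

## Numerical conventions and limitations

* Ages floor to whole years for hazard lookup; the grid is 18-80.
* A per-genotype yearly hazard reaching 1 raises an explicit error (the
  grid cannot represent the requested HR at that incidence).
* Monomorphic SNPs raise a distinct error in the score test and HWE test,
  separate from ordinary failures.
* Newton derivatives are finite differences (gradient step 1e-5, Hessian
  1e-4); adequate because log-likelihoods here are smooth and the score
  test, not the MLE, carries the multiple-testing burden.
* Simulation problem sizes in the test suite (2,000 × 1,000 calibration,
  200 × 5,000 recovery) were chosen to give binomial/Monte-Carlo precision
  comfortably inside the asserted bands while keeping the suite a
  few-minute run.
* The individual-level retrospective product is exact for sampling on a
  carrier's *own* phenotype. When retention depends on *relatives'*
  phenotypes (family-proband designs with sibships analysed jointly) it is
  a composite likelihood and mildly biased; the original analyses used
  full pedigree likelihoods for this reason, which are out of scope here.
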