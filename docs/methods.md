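# Methods

## The population model

Two biallelic loci are modelled jointly: a causal locus A with risk-allele
frequency `p_a` and a marker locus B with associated-allele frequency `p_b`,
linked by the squared allelic correlation `r2`. The haplotype frequencies are
fully determined by `(p_a, p_b, r2)` and the sign of the disequilibrium
coefficient D:

    h_AB = p_a p_b + D,   D = ± sqrt(r2 · p_a(1−p_a) p_b(1−p_b)),

with the other three haplotypes fixed by marginal consistency. By default D
is positive — the risk allele is positively correlated with the allele we
call "associated" at the marker; the negative sign is equivalent to
relabelling the marker alleles and is exposed as `d_sign` for completeness.

Not every `(p_a, p_b, r2)` is realisable: all four haplotype frequencies must
stay in [0, 1] (the Lewontin bounds on D). For positive D the feasible marker
frequencies form the closed interval

    r2·p_a / (1 − p_a + r2·p_a)  ≤  p_b  ≤  p_a / (p_a + r2·(1 − p_a)),

which always contains `p_a` and collapses to the point {p_a} at r2 = 1.
Requests within 1e-9 of the boundary are clipped onto it; anything beyond
raises a feasibility error naming the maximal achievable r2.

Random mating is assumed, so genotypes are the convolution of two
independent haplotype draws; each locus is marginally in Hardy–Weinberg
proportions. Disease risk depends only on the genotype at A through a
penetrance vector f(g):

| mode of inheritance | f(0) | f(1) | f(2) |
|---|---|---|---|
| dominant        | b | γb  | γb  |
| recessive       | b | b   | γb  |
| multiplicative  | b | γb  | γ²b |
| general         | b | γ₁b | γ₂b |

with baseline risk b = 0.05 by default and genotype relative risk γ. All
penetrances must lie strictly in (0, 1) and be non-decreasing in the risk
allele count.

The observable object is the expected marker-genotype distribution in cases
and in controls of an infinite population:

    P(G_B = j | case) ∝ Σ_i P(G_A = i, G_B = j) · f(i),
    P(G_B = j | control) ∝ Σ_i P(G_A = i, G_B = j) · (1 − f(i)).

## Fitting genotype codings to the expected data

The study design is retrospective with equal numbers of cases and controls,
so models are fitted by maximising the *expected* per-individual Bernoulli
log-likelihood with weights ½·case and ½·control on each genotype class.
Four codings are supported (trend/multiplicative `[g]`, dominant `[g ≥ 1]`,
recessive `[g = 2]`, and the saturated two-parameter general coding). The
intercept-only null always attains ℓ₀ = −log 2 under equal weighting.

Numerics: codings whose populated genotype classes collapse to as many
distinct covariate levels as there are parameters (the binary codings, the
saturated coding, and the trend coding when a class is empty) are solved in
closed form from the per-level logits; otherwise Newton iteration is used
with a gradient-norm tolerance of 1e-12 and at most 100 iterations. Genotype
classes with zero probability in both groups are dropped from the design; a
covariate level populated only by cases or only by controls is complete
separation and raises an explicit error rather than returning a divergent
estimate. Fitted heterozygote/homozygote odds ratios are read off the linear
predictor differences, so they are invariant to affine reparameterisations of
the design.

Model fit is summarised by pseudo-r² against the common null. The default is
McFadden's 1 − ℓ/ℓ₀; Cox–Snell 1 − exp(2(ℓ₀ − ℓ)) is selectable. The exact
definition matters little here: the *ratio* of two codings' pseudo-r² — the
quantity of interest throughout — agrees between the two definitions to
within 1% for GRR ≤ 1.3 (verified in the test suite). The fit ratio
pseudo-r²(true coding)/pseudo-r²(trend coding) is ≥ 1 by nesting whenever the
true mode is dominant or recessive at complete LD, and empirically ≥ 1 across
the whole scenario grid. When both pseudo-r² values fall below 1e-14 (no
association) the 0/0 ratio is reported as undefined (NaN with a flag), never
silently as 1.

## Power and sample size

The association test is the likelihood-ratio chi-square of a coding against
the intercept-only null (1 df for trend/dominant/recessive, 2 df for
general). For n cases and n controls the LRT statistic is asymptotically
noncentral chi-square with noncentrality

    λ = 2 · (2n) · (ℓ_coding − ℓ₀),

linear in n by construction. Power is the upper tail of that distribution
beyond the central (1 − α) quantile; the default α = 5e-7 approximates
genome-wide significance and the default target power is 0.8. A Wald-based
power formula was deliberately not used: the LRT noncentrality is the
standard infinite-population construction and reuses the fitting machinery
unchanged. Minimal sample sizes are solved by doubling then integer
bisection, exact at integer resolution (power(n) ≥ target, power(n−1) <
target). Detectable-frequency ranges scan the 0.01-step grid with the marker
frequency matched to the causal one and refine each boundary by bisection to
1e-3; an empty result is valid, not an error. The multi-locus helper solves
1 − (1 − p)^k = overall power under independence.

## Scenario sweeps

The matched-frequency sweep covers modes {dominant, recessive} × GRR
{1.1, 1.3, 2} × r² {1, 0.8, 0.5} × frequencies 0.01–0.99 (step 0.01, the
reported grids' resolution; the underlying functions accept any grid). Every
grid point yields a row — fit ratio, both pseudo-r² values, both heterozygote
odds ratios, the complete-LD sample size, optional power at a reference n —
with infeasible or degenerate points flagged in a status column rather than
dropped. Summaries over "detectable" frequencies restrict this grid to
points with ≥ 80% power at the stated sample size; averages are unweighted
grid means (the original averaging scheme is unstated, so tolerance on
average-based checks is generous).

The frequency-mismatch sweep fixes `p_a` ∈ {0.3, 0.5, 0.7} and lets `p_b`
run over its feasible interval (step 0.005, endpoints and the matched point
included) at r² ∈ {0.3, 0.5, 0.8}, reporting both the maximum relative
deviation and the mean relative change of the fit ratio against the matched
value. The two statistics behave very differently: at r² = 0.8 the mean
change stays within ±0.15% in every parameter combination while the
pointwise deviation can reach a few percent near the interval ends — both
are reported so the reader need not guess which is meant by "little
variation".

## The synthetic-data generator

Finite samples are drawn retrospectively: genotype counts for cases and for
controls are independent multinomials from the expected distributions,
matching the equal-cases-and-controls design (prospective sampling from the
population with its implied prevalence is not the default and not needed for
any reported quantity). One top-level integer seed is split into
per-replicate streams via `numpy.random.SeedSequence.spawn`, so every
stochastic result is bit-reproducible. The Cochran–Armitage trend test uses
the classic score form with scores (0, 1, 2) and no continuity correction;
finite-sample logistic fits reuse the weighted-likelihood machinery (the
score equations coincide when the weights are the observed counts).

What the generator emulates is exactly the structure the analytics assume —
two loci, random mating, penetrance at the causal locus, genotypes observed
at the marker only. What it does not emulate: genotyping error, population
stratification, covariates, multi-locus architectures, or ascertainment
beyond the case-control split. Passing Monte Carlo validation therefore
shows the analytics are internally correct, not that real studies behave
this way.

Monte Carlo validation of power uses a reduced significance level (5e-4) so
that a few thousand replicates can resolve power near 0.8; the genome-wide
threshold itself is exercised analytically only — desk-scale replicate
counts cannot resolve tail probabilities of 5e-7.

## Numerical and design choices

- Probability conservation is enforced to 1e-12 at every stage (haplotypes,
  joint genotypes, case/control distributions).
- Genotypes are coded as risk/associated allele counts g ∈ {0, 1, 2}
  everywhere, matching the trend-test convention.
- Odds ratios, not risk ratios, are reported: with a baseline risk of 0.05 a
  dominant GRR of 1.3 corresponds to a heterozygote odds ratio of
  (0.065/0.935)/(0.05/0.95) ≈ 1.3209.
- Reported sample sizes denote cases, with controls equal.
- Sweep grids: frequency step 0.01 for figure-style grids, 0.005 for the
  mismatch sweep within the feasible interval. These match the resolution at
  which the summary quantities are quoted; finer grids change the reported
  maxima/minima only below that resolution.
- The detectable-range boundary is refined by bisection to 1e-3; note that
  the widely quoted lower endpoint 0.12 for (dominant, GRR 1.3, n = 5000) is
  the smallest 0.01-grid frequency with ≥ 80% power, while the continuous
  boundary sits near 0.112.

## Known limitations

- The power model assumes the correct coding is fitted at a marker in
  complete LD, so it overstates what a real scan achieves; everything is
  asymptotic (expected-likelihood noncentrality), accurate for the sample
  sizes involved here but not for very small studies or very rare genotype
  classes.
- Dominant and recessive modes are the extreme non-multiplicative cases;
  intermediate dominance would show smaller fit ratios than reported by the
  sweeps.
- Exactly two loci; no haplotype-level selection, mutation or drift; marker
  and causal locus are assumed biallelic with known phase at the population
  (not individual) level.
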