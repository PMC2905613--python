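# markerfit

**Genetic-model misspecification, power and risk estimation at marker loci in
incomplete linkage disequilibrium with a causal locus.**

In a genome-wide association study the genotyped marker is usually not the
causal variant but a tag in linkage disequilibrium (LD) with it. As LD decays
(r² < 1), the association signal observed at the marker weakens — and the
*non-multiplicative* component of the genetic risk decays faster than the
multiplicative one. The practical consequences: the Cochran–Armitage trend
test (which assumes a multiplicative model) loses little power against tests
that model the true mode of inheritance; and a multiplicative risk model will
tend to fit well at the marker even when the causal locus is dominant or
recessive, biasing heterozygote risk estimates downward.

`markerfit` quantifies these effects analytically for an infinite population
sampled with equal numbers of cases and controls. It is aimed at
statistical geneticists designing or interpreting case-control association
studies.

## Model

Two biallelic loci: causal locus **A** (risk-allele frequency *p*ₐ) and marker
locus **B** (associated-allele frequency *p*ᵦ), with LD measured by the
squared allelic correlation r² built from the disequilibrium coefficient
D = h_AB − *p*ₐ*p*ᵦ. Under random mating, genotypes arise from two
independent haplotype draws. Disease risk is assigned at locus A by a
penetrance model f(g) with baseline risk f(0) (default 0.05) and genotype
relative risk (GRR): dominant f = (b, γb, γb), recessive (b, b, γb),
multiplicative (b, γb, γ²b), or general (b, γ₁b, γ₂b).

The expected marker-genotype distribution among cases and controls follows
from Bayes' rule. Genotype codings (trend/multiplicative, dominant,
recessive, general) are fitted by maximising the expected per-individual
log-likelihood

ℓ(β) = Σ_g [ ½·P(g|case)·log π(g) + ½·P(g|control)·log(1−π(g)) ],  π(g) = expit(xᵍᵀβ),

and model fit is summarised by McFadden's pseudo-r² against the
intercept-only null (ℓ₀ = −log 2). The **fit ratio** is
pseudo-r²(true coding) / pseudo-r²(trend coding) ≥ 1. Power for the
likelihood-ratio test uses the noncentral chi-square with noncentrality
λ = 2·(2n)·(ℓ_coding − ℓ₀) at genome-wide significance α = 5×10⁻⁷.

## Worked example

A dominant causal variant with GRR 1.3, baseline risk 0.05, risk-allele
frequency 0.3, marker at the same frequency:

```python
import markerfit as mf

pen = mf.PenetranceModel("dominant", grr=1.3, baseline=0.05)

for r2 in (1.0, 0.8, 0.5):
    dist = mf.expected_marker_distribution(mf.TwoLocusScenario(0.3, 0.3, r2), pen)
    cmp = mf.fit_ratio(dist, pen)
    print(f"r2={r2:<4} fit ratio={cmp.ratio:.3f}  "
          f"het OR true={cmp.fit_true.or_het:.3f}  trend={cmp.fit_mult.or_het:.3f}")

res = mf.min_sample_size(mf.PowerQuery(mf.TwoLocusScenario(0.3, 0.3, 1.0), pen))
print(f"cases (and controls) for 80% power at alpha=5e-7, r2=1: {res.n_required}")
intervals = mf.detectable_freq_range(5000, pen)
print(f"detectable risk-allele frequencies at n=5000: {intervals[0][0]:.3f}-{intervals[0][1]:.3f}")
```

prints

```
r2=1.0  fit ratio=1.228  het OR true=1.321  trend=1.213
r2=0.8  fit ratio=1.184  het OR true=1.276  trend=1.188
r2=0.5  fit ratio=1.106  het OR true=1.204  trend=1.145
cases (and controls) for 80% power at alpha=5e-7, r2=1: 3590
detectable risk-allele frequencies at n=5000: 0.112-0.495
```

Reading this: at complete LD the true dominant coding captures 22.8% more of
the variation than the trend coding; at r² = 0.5 the advantage shrinks to
10.6%. The heterozygote odds ratio is 1.321 under the true coding (above the
GRR of 1.3 because it is an odds ratio, not a risk ratio) but decays toward
the null both with LD breakdown and under the multiplicative coding. A study
of 3,590 cases and 3,590 controls reaches 80% power at genome-wide
significance for this scenario, and with 5,000 cases only risk-allele
frequencies between roughly 0.11 and 0.50 are detectable.

The same queries are available from a shell:

```sh
markerfit samplesize --p-a 0.27 --moi dominant --grr 1.25
# {"n_cases": 4940, "power": 0.80016, "noncentrality": 34.439, "df": 1}
markerfit sweep fit --moi dominant --grr 1.3 --out fit.csv
markerfit simulate --p-a 0.3 --moi dominant --grr 1.3 --n-cases 1000 --seed 7
```

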