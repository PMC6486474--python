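# Methods

This note documents the statistical models, the defaults and the design
choices behind `omicsim`, in the order the pipeline runs them.

## Reference panel and profiles (fixtures)

Real uses of a simulator like this start from a haplotype panel produced by
a population-genetic sequence generator and from profiles compiled out of
large consortium datasets. The fixture module generates synthetic
equivalents with *known* parameters so that every downstream check has a
ground truth:

* **Haplotype panel.** Each variant v has a target alternative-allele
  frequency p_v drawn from a user spectrum (point mass, uniform, or a fixed
  per-variant vector). Within an LD block every haplotype carries a shared
  latent ancestry u ~ U(0,1); the allele is 1[u < p_v], except that with
  probability 0.05 (the mutation analogue) it is resampled independently as
  Bernoulli(p_v). This is an infinite-founder limit of founder-copying: it
  keeps each allele marginally exactly Bernoulli(p_v) — so empirical MAFs
  track the spectrum at binomial precision, which a small founder set
  cannot do — while giving positive within-block and zero between-block
  correlation. Coalescent realism is not attempted; only sampling
  correctness matters downstream. Scenario panels default to block length
  1 (unlinked variants): the causal roles represent variants in different
  genes, and keeping them unlinked makes the penetrance terms separately
  identifiable when the model is refit.
* **Methylation profile.** Per CpG: a status drawn from the configured
  (methylated, unmethylated, fuzzy) mixture; a rate uniform within the
  status band ([0.7, 1], [0, 0.3], (0.3, 0.7) — the within-band shape is a
  free choice); a geometric spacing (mean 100 bp); and a negative-binomial
  depth model (mean 30 reads, dispersion 0.1 — typical WGBS coverage). A
  parametric depth model stands in for empirical per-status read-count
  tables so fixtures need no downloads.
* **RNA profile.** Per-gene (λ, ω) pairs: λ log-normal (log-mean 5.3, so a
  median around 200 counts, log-sd 1 — the heavy right tail of real RNA-seq
  means), ω gamma (mean 0.2 — typical bulk dispersions). Reference
  normalization factors c are log-normal centred at 1 (sd 0.15 on the log
  scale, modest technical variation). λ and ω are resampled *as pairs* so
  the mean–dispersion relationship is preserved.
* **Protein profile.** τ log-normal with median ≈ 0.2 on the normalized
  scale; κ_s = κ_d = 1, 10 kinetic steps.
* **CNV profile.** Non-overlapping regions with state-frequency vectors
  (f_D, f_N, f_U, f_UU) on the simplex, background Dirichlet(2, 30, 2, 1)
  (mostly normal, occasional deletions/duplications).

## Genome simulation

Unrelated individuals: two virtual parents per individual, each a haplotype
pair sampled with replacement from the panel, each transmitting one
recombinant gamete (start haplotype uniform, switch between variants t and
t+1 with probability θ_t). The pairing scheme for virtual parents is a
design choice; any exchangeable pairing conserves allele frequencies.
Pedigrees: founders drawn as above, non-founders get one gamete from each
listed parent into the (paternal, maternal) slots — the order is preserved
end-to-end because allele-specific methylation needs parental origin.
Coordinates are 1-based inclusive everywhere except BED output (0-based
half-open).

CNV regions are transmitted independently of SNP haplotypes and of each
other (single-copy crossover model: a region's state is never split).
Whether CNV transmission should be linked to flanking SNP haplotypes is
left open deliberately; the layers are coupled only through the allelic
coding in the penetrance function.

## Disease model

The penetrance function is logistic in the coded terms (see README). Coding
details that are package conventions rather than forced choices:

* **Allelic CNV coding of G_j**: when a SNP lies in a CNV region, each
  chromosome's allele is weighted by that chromosome's copy count (D=0,
  N=1, U=2, UU=3); additive coding is the weighted count, dominant/
  recessive threshold it at ≥1 / ≥2.
* **Interaction codings**: product of additive codings (the default used
  throughout), joint-dominant, joint-recessive, and XOR (exactly one
  carrier).
* β₀ is found by bisection on the Monte-Carlo mean penetrance over 20,000
  population genomes (tolerance 0.002); with a null model the closed form
  logit(prevalence) is used. Default prevalence 0.1 — a common figure for
  the complex diseases these architectures represent.
* Ascertainment rejection-samples batches of 2,000 until both quotas fill;
  surplus individuals are discarded (not banked), so retained draws are
  i.i.d. given their label. `max_draws` defaults to 1,000 × (cases +
  controls). Penetrance values are clamped to [1e-12, 1−1e-12]: the model
  is strictly inside (0, 1) mathematically, and the clamp keeps the float
  there when interaction scores saturate the logistic.

## Methylation

Per-individual rate at a CpG: profile rate × ratio^(alt-allele count at the
meQTL SNP), + delta for cases at differential CpGs, clamped to [0, 1] last.
Two conventions are documented choices: the meQTL ratio applies **once per
alternative allele** (ratio² for homozygotes), and the case-control delta is
**additive on the rate scale**. Differential CpGs are either named
explicitly or drawn per status band at configured proportions (seeded).
ASM splits each total Binomial(t, 0.5) between parental alleles and draws
methylated counts at allele-specific rates; a DMR re-simulates named CpGs
from an alternate cell-type profile for a designated group. One
chromosome's CpGs are simulated per call; multi-chromosome runs are a loop.

## Expression

NB convention: variance = μ + ω μ² (ω = 0 degenerates to Poisson). This is
stated prominently because profile ω values are only meaningful relative to
a convention. The eQTM mean is α_ij + β_i x_ij with α_ij = λ_i c_j and
β_i ~ Normal(user mean, sd), floored at 10⁻³ when a steep negative slope
would make the mean non-positive. A gene may carry both a DE fold change
and an eQTL (the multipliers compose; order is immaterial), but not both an
eQTL and an eQTM — those disagree about the functional form of the mean, so
the combination is rejected.

Allele-specific reads: n_as = round(0.005 t) (round-half-to-even), split
beta-binomial with mean p = 2ᵉ/(1+2ᵉ) and overdispersion ρ = 0.1,
parameterised α = p(1−ρ)/ρ, β = (1−p)(1−ρ)/ρ. The default effect size of a
cis-eQTL with fold change h is e = log₂(2h−1): the genotype means μ, hμ,
(2h−1)μ imply allele-level means μ/2 (reference) and (h−½)μ (alternative),
whose log₂ ratio is log₂(2h−1); e = 0 for homozygotes. The smoothed
bootstrap for normalization factors uses a Gaussian kernel at Silverman's
bandwidth, reflected at zero, and only when the cohort exceeds the
reference count (plain resampling otherwise).

## Protein

x is the MAD-normalized expression of the encoding gene (median/MAD across
individuals within gene, consistency constant 1.4826, so the scale is
comparable to normalized RPPA data; constant genes raise `ZeroMADError`).
η starts at x (no initial condition is canonical; at κ_d = 1 the recurrence
reaches its fixed point x κ_s/κ_d in one step regardless) and is iterated
`n_steps` = 10 times — the iteration matters only for user-set rates, where
the error contracts by |1 − κ_d| per step. The observed level is
Normal(η, τ_k) with τ_k resampled from the profile. Only the final time
point is emitted.

## Shipped scenarios

The breast-cancer configuration defaults to fixture scale (28 role SNPs +
10 filler, 688 CpGs, 100 genes/proteins, 1 CNV region); the paper-scale SNP
counts per gene derive from external reference sequences and reproducing
them has no verification value, so they are left as parameters. The
case-control methylation difference of 0.10 is configured directly as the
differential-methylation delta at the meQTL CpG (the meQTL ratio 1.2
additionally links genotype to methylation; under ascertainment the
realized difference can slightly exceed 0.10 because cases are enriched for
the interacting meQTL allele). The ovarian-scale scenario assigns survival
groups directly (no genetic penetrance): its effects are retrospective,
conditional on the label. Its eQTM CpG stores the long-term (control) rate
2.3% in the profile with a case delta of −0.3 percentage points giving the
2.0% short-term rate; the 0.6 fold changes of the three eQTM genes are
imposed directly (multiplying the eQTM mean for cases) rather than left to
emerge from the methylation difference, whose expression effect
(β ≈ 50 × Δx ≈ 0.003) is negligible against gene means of hundreds of
counts.

## Randomness and reproducibility

One master seed drives everything. Each layer draws from an independent
stream derived via `SeedSequence(seed, spawn_key=(layer,))`, so adding or
removing a layer never perturbs another layer's draws; reruns with the same
config and seed are bit-identical (the run manifest checksums every output
file). Validation/training cohorts use distinct derived seeds.

## Recovery harness and problem sizes

`omicsim validate` refits every generating term: logistic regression with
the generating codings on 2,000 + 2,000 ascertained samples (the
identifiability condition for case-control data; the intercept absorbs the
ascertainment and is not compared), group-mean differences for methylation,
c-adjusted group-mean ratios for fold changes, per-gene OLS slopes for the
eQTM law, and bounded-L-BFGS beta-binomial MLE (Wald CI from a
finite-difference Hessian) for the ASE overdispersion. Default tolerances:
3 estimated SEs, or 10% relative error for fold changes where an SE is
awkward. The acceptance script runs the ovarian scenario at 1/10 layer
dimensions with the full 500 + 500 samples — the per-gene estimators are
independent across genes, so scaling the gene count does not change any
per-parameter distribution — and uses 10,000 individuals for population
frequencies and 5,000 observations for the beta-binomial fit.

## Known limitations

No coalescent realism or recombination-map inference in the synthetic
panel; no read-level bisulphite conversion errors or FASTQ simulation; no
isoform quantification or library-size modeling beyond c_j; no batch
effects in the protein layer; no de-novo CNVs, multi-region CNV crossovers
or sex chromosomes; pairwise interactions only; dichotomous traits only.
Passing recovery tests shows the simulator realizes its own generative
model — not that the generative model captures any particular real
dataset.
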