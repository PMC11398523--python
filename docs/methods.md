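# Methods note

This note records the statistical models implemented by `bgeeval`, the
parameter defaults and why they were chosen, the numerical conventions,
and the known limitations. Nothing here claims empirical results beyond
what the package's own code computes on its own synthetic data.

## Synthetic cohort model

### Allele frequencies: Balding–Nichols divergence

Each site draws an ancestral frequency `p` uniformly from
`ancestral_af_range` (default (0.01, 0.99)), then each ancestry `k` draws
its frequency from

```
AF_k ~ Beta(p (1 − F_k) / F_k, (1 − p)(1 − F_k) / F_k)
```

which has mean `p` and variance `F_k · p(1 − p)`. `F` is the per-ancestry
drift/divergence parameter (default 0.1 for each of AFR/EUR/AMR — a
deliberately strong divergence so ancestry-dependent behaviour is visible
at desk scale). The closed-form mean and variance serve as test oracles.

### Admixed haplotypes: exponential tracts

Each haplotype is a sequence of ancestry tracts on one chromosome
(default length 1e8 bp at the fixed map 1 cM/Mb, i.e. one Morgan).
Breakpoints are Poisson with rate `g` per Morgan (`g` = generations since
admixture, default 10) and tract labels are drawn iid from the admixture
simplex (default 0.45/0.35/0.2). Consecutive same-label windows merge, so
the *observed* tract count follows the label-collapsed thinned rate
`1 + g(1 − Σπ_k²)` in expectation — tested against that formula. Truth
haplotype alleles are drawn per-site from the tract ancestry's AF.

### Alternate-allele polarisation

After genotypes are drawn, each site is polarised so that ALT is the
cohort **minor** allele (haplotypes, genotypes and AF complemented when
cohort AF > 0.5). This emulates allele-conforming preprocessing
(conform-gt-style) and is load-bearing: without it, folded MAF bins mix
sites with AF near 0 and near 1, and between-site AF spread alone
manufactures within-bin correlation even for information-free dosages.
With polarisation, zero-coverage dosages give aggregate R² < 0.02 in
every bin, as an information-free baseline must.

### Low-pass dosages: read-resampling posterior

Per genotype: depth `c ~ Poisson(mean_coverage)`; alternate reads
`~ Binomial(c, μ_g)` with `μ_0 = ε`, `μ_1 = 0.5`, `μ_2 = 1 − ε`
(`ε = base_error`, default 0.01); the posterior over {0, 1, 2} is
computed against a Hardy–Weinberg prior at the site's cohort AF. GP is
the posterior triple and dosage `= GP1 + 2·GP2`. Two exact consequences
anchor the tests: at `c = 0` the posterior equals the prior, so dosage
`= 2·AF` exactly; and as coverage grows the posterior concentrates on the
truth (>99% hard-call accuracy at 30×). Monomorphic sites (cohort AF 0
or 1) get prior-only dosages with a logged warning.

This model was chosen over additive Gaussian noise because it produces
valid GPs on the simplex, an exact no-data identity, and
coverage-monotone accuracy — all directly testable.

### Array truth, batches, CNV quartets

Array genotypes flip each called genotype to a random different value
with probability `array_error_rate` (default 0.002) and mask with
probability `array_missing_rate` (default 0.01). Batch assignment is
round-robin (default 2 batches). CNV planting places non-overlapping
events on runs of consecutive exons in quartet families: by default 20
transmitted deletions, 20 transmitted duplications (parent plus both
children carry them, 2 carrier families each) and 6 + 5 de novo
single-child events, QS drawn uniformly from (250, 1000). Drop-out on
the *test* copy of the callset has two modes: `carrier` (each carrier's
call drops independently with probability d) and `site` (all carriers of
an event drop together). Site mode makes the expected site-level recall
exactly `1 − d`; carrier mode makes it `P(Binomial(n_carriers, 1−d) ≥
⌈n_carriers/2⌉)`, which for 4 carriers at d = 0.2 is ≈ 0.973 — the two
modes answer different planted-recovery questions and both are tested
against their own oracle.

## Evaluation definitions

- **Aggregate R²**: per MAF bin, the squared Pearson correlation between
  the stacked (genotype-level) truth and dosage vectors; missing pairs
  are dropped. Bin edges default to
  (0, 0.005, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5], half-open `(lo, hi]`
  with the first bin closed at 0.
- **Non-reference concordance**: TP/(TP+FP+FN) with TP = same non-ref
  genotype, FN = truth non-ref not matched (a 1↔2 mismatch is FN by
  default; a `fp_fn` mode counts it as both FP and FN), FP = truth ref
  but test non-ref. Aggregate (pooled-count) and per-SNP variants are
  both provided; the pooled form is the headline because per-SNP averages
  are deflated for rare SNPs.
- **INFO**: ratio-of-variances score
  `1 − Σ(f − e²) / (2n θ(1 − θ))` with `e = P(1) + 2P(2)`,
  `f = P(1) + 4P(2)`, `θ` the posterior AF. Site filtering keeps
  INFO ≥ 0.8 (inclusive).
- **Batch merge**: `AF_c = Σ N_i AF_i / Σ N_i` and
  `INFO_c = 1 − [Σ (1 − I_i) · 2N_i AF_i(1 − AF_i)] /
  [2 Σ N_i · AF_c(1 − AF_c)]`; a monomorphic batch contributes zero
  numerator (its INFO may be absent); a cohort-monomorphic site has
  undefined INFO. Both formulas are exactly associative, verified by a
  two-stage-merge test. The identity against pooled computation holds
  exactly only when each batch's AF and INFO derive from the same
  posteriors.
- **Local-ancestry stratification**: per-genotype diploid background from
  half-open tracts; strata partition the compared genotypes exactly.
- **CNV benchmark**: sites are single-linkage clusters of same-type calls
  with reciprocal overlap ≥ 0.5; a truth site is recalled when ≥ 50% of
  its carriers have a same-type test call covering ≥ 50% of the truth
  call's exons; PPV is the same computation with roles swapped (so
  swapping callsets swaps the metrics exactly). De novo: a child call
  with no same-type parental call at reciprocal overlap ≥ 0.5.

## QC conventions

Genotype: drop when DP < 10, GQ < 20, het allele balance outside
[0.2, 0.8], or hom-alt allele balance < 0.8 (AB rules unevaluated when AD
is missing). Sample coverage: fail when exome fraction at ≥10× < 0.90,
WGS coverage < 1×, or chimera/contamination > 0.05 (boundary values
pass). Metric outliers: |x − mean| > 4·MAD within each stratum (MAD about
the median; median-centred variant available); zero-MAD metrics and
strata under 10 samples are skipped with a warning. Sex: X inbreeding
coefficient F < 0.6 female, > 0.6 male, exactly 0.6 or under 20 sites
undetermined. Array QC stages, in order: SNP call rate ≥ 95%; sample
call rate ≥ 98%, |FHET| < 0.2, reported/inferred sex concordance; SNP
call rate ≥ 98%; differential case/control missingness ≤ 2%; exact HWE
(Wigginton-style two-sided recurrence, validated against a gammaln
enumeration oracle) at p < 1e-6 in controls and p < 1e-10 in cases. CNV
calls: QS > 200 strict, carrier frequency < 1% strict within ancestry
group, samples with > 10 rare high-quality CNVs removed.

## Numerical choices

- **Seeding**: all randomness flows from
  `np.random.SeedSequence((seed, stream))` with a fixed stream id per
  operation (AFs, tracts, truth, dosages, array, CNV), so regenerating
  one artifact never perturbs another and runs are byte-reproducible.
- **Dosage/GP storage**: float32 (a 2,000 × 20,000 cohort keeps dosage +
  GP under 1 GiB); all statistics accumulate in float64.
- **Binned Pearson**: single-pass `bincount` sufficient statistics per
  bin (n, Σx, Σy, Σx², Σy², Σxy) rather than materialising per-bin
  stacks.
- **PCA**: SVD on HWE-normalised genotypes `(g − 2p)/√(2p(1−p))` with
  missing entries zeroed after centring; component signs fixed by the
  largest-magnitude loading so scores are deterministic.
- **VCF rounding**: GP triples are written with the third component as
  `1 − GP0 − GP1` so 3-decimal triples sum to exactly 1.000 and survive
  the reader's simplex check.
- **Exact HWE**: recurrence from the distribution mode with a
  `(1 + 1e-12)` slack when summing probabilities ≤ the observed one, to
  keep ties stable across platforms.

## Generator limitations

- **No linkage disequilibrium / no reference panel.** Sites are
  independent given ancestry, and the dosage posterior is single-site.
  Consequently absolute accuracy at 1–4× is far below what an LD-informed
  imputer achieves, and — more subtly — **GP-confidence filtering does
  not improve rare-bin aggregate R²** here: GP confidence is read-depth
  driven, so filtering is depth selection; in rare bins it retains mostly
  prior-dominated hom-ref genotypes, collapsing dosage variance faster
  than posterior uncertainty and *lowering* within-bin R². (For a
  calibrated posterior, within-stack R² = 1/(1 + E[Var(g|DS)]/Var(DS));
  the selection shrinks the denominator faster than the numerator.) The
  corresponding acceptance assertion is intentionally left failing rather
  than tuned around. Real imputers draw confidence from haplotype
  context, which restores the benefit of GP filtering.
- Tract labels are iid at breakpoints (no Markov ancestry switching), the
  recombination map is uniform, and tract structure is independent of
  allele frequencies given ancestry.
- The HWE prior uses the cohort AF even though the cohort is admixed;
  this mirrors a panel-free caller and slightly miscalibrates posteriors
  for strongly differentiated sites.
- CNV planting uses disjoint exon runs, so clustering is unambiguous by
  construction; boundary jitter (`jitter_exons`) is available but
  defaults to 0.
- Array error is symmetric across genotypes rather than cluster-based,
  and QC metric distributions are user-supplied rather than simulated
  from reads.
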