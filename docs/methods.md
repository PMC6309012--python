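# Methods

`cochise` reimplements, as a tested pipeline, the two analyses used to ask
whether song discrimination accompanies genomic isolation in Northern
Cardinals (*Cardinalis cardinalis*) across the Cochise Filter Barrier: (1)
coalescent demographic inference from the unfolded three-population joint
site-frequency spectrum (SFS), and (2) playback-experiment aggression
scoring compared across song treatments with linear mixed models. A
synthetic-data layer generates SNP matrices and playback trial tables with
the statistical structure the analyses assume, so every stage is validated
by parameter recovery rather than by re-reading published numbers.

## Demographic model

Three demes — Sonoran (S), Chihuahuan (C), and the outgroup subspecies
*C. c. carneus* (O) — evolve under a piecewise-constant structured
coalescent. Backwards in time, lineages in a deme of haploid size `N`
coalesce pairwise at rate `1/N` per generation; at the divergence time
`T_D` the two desert demes merge into an ancestral-desert deme of size
`N_eD`; at the calibration split `T_A = 2,000,000` years all lineages merge
into a root deme of size `N_eA`. Generation time is 1 year and the mutation
rate is `2.21e-9` per site per year, so times in years equal times in
generations. Six topologies are compared: pure isolation (ISO, 6 free
parameters), isolation with symmetric (SYM, 7), asymmetric (ASYM, 8), or
one-way migration (SON2CHI / CHI2SON, 7 each), and secondary contact
(SECCONTACT, 9), in which migration is allowed only more recently than
`T_SC` (at most the current interglacial, 21,000 years).

Migration is parameterized canonically as the backward per-lineage
per-generation probability that a lineage's ancestry jumps to the other
desert; `m_S` moves Chihuahuan lineages into Sonoran ancestry (forward
Sonoran-to-Chihuahuan migration) and `m_C` the reverse. Priors can be
expressed either directly on those rates or — as published for this system
— as forward migrant counts per generation, log-uniform on 0.001–20,
converted at evaluation time by dividing by the receiving deme's haploid
size. The reference (best-supported) parameter set reads the published
ASYM estimates with migration as migrants per generation, i.e. effectively
isolated populations (about one migrant per 10^5 generations). We verified
the alternative per-lineage-probability reading empirically: at
`m ≈ 1e-5` per lineage the desert demes exchange ~10 migrants per lineage
history, the joint SFS loses essentially all information about `T_D`
(likelihood slice flat to ~3 log units over ±20%), and no estimator can
reproduce the published ±8% divergence-time interval — which, together
with the published "minute gene flow" interpretation, fixes the
migrant-count reading as the operating point. Both conventions remain
available (`PriorSet.migration_unit`).

## Expected SFS by branch accumulation

The expected unfolded joint SFS is computed by Monte-Carlo genealogy
simulation: entry `(i, j, k)` is the mean, over simulated genealogies, of
the total branch length subtending exactly `i`/`j`/`k` sampled chromosomes
per deme, times the per-generation mutation rate. Two variance-reduction
choices matter:

- **Rao-Blackwellized mutation placement.** Mutations are never sampled;
  branch lengths are accumulated directly (unbiased for the same
  expectation as SNP sampling, at much lower variance).
- **Rao-Blackwellized sojourn times.** Within each inter-event interval the
  accumulator adds the conditional expectation
  `E[min(Exp(rate), boundary)]` of the interval length given the jump
  chain, not the realized exponential draw. This removes the holding-time
  variance (about a five-fold reduction in likelihood noise at equal cost
  in our measurements). The realized draws still drive the process and the
  per-genealogy quantities (TMRCA, total length, sampled branches), which
  must describe a single realization.

Observed datasets are sampled at the SNP level: a genealogy is accepted
with probability proportional to its total branch length (a random
segregating site falls on a length-biased genealogy) and one branch is
chosen proportional to length within it, one site per genealogy. This
makes the generator exactly model-consistent with the normalized expected
SFS, which parameter recovery depends on. The engine is cross-checked
entrywise against msprime (branch-mode allele-frequency spectra, ploidy 1)
under both an isolation and a migration setting, against the neutral
single-deme `1/i` spectrum, against closed-form pairwise coalescence times
and total tree lengths, and against an independent pure-Python reference
simulator kept in the package for that purpose.

## Composite likelihood and model selection

The observed SFS is treated as multinomial over unmasked entries (the two
monomorphic corners are always masked), with cell probabilities given by
the normalized expected SFS — the standard SFS composite likelihood, sites
independent; any overall scale (e.g. the mutation rate) cancels. Because a
finite-replicate expected SFS leaves genuinely small cells empty, and a
hard probability floor would penalize candidate parameters by how widely
they spread mass (we measured a ~50-log-unit parameter-dependent
distortion at 3,000 replicates that systematically favored spurious
migration), zero cells are handled by mixing in a uniform distribution
with weight `1e-3` over unmasked cells: every unresolved cell costs the
same under every candidate.

Maximization is a three-stage search in log-parameter space with common
random numbers (one simulation seed per fit, so Monte-Carlo error is a
frozen landscape rather than per-evaluation jitter): (1) screening of
prior draws at reduced replicates; (2) downhill-simplex (Nelder–Mead) runs
from the best-scoring draws, chosen greedily under a minimum log-distance
separation because the surface has well-separated secondary modes
(migration trading off against divergence time); (3) a long high-replicate
simplex polish of the leader, which is what pins the soft ridge directions
(notably `T_D` against `N_eD`). Optional warm starts let a nested model
begin from a simpler model's optimum. We initially implemented
coordinate-wise log-scale hill climbing for stage 2; it reliably stalled
60–180 log units short of the optimum on the ridge structure of this
likelihood and was replaced by the simplex scheme. The final
log-likelihood is re-evaluated at elevated replicates with a seed shared
across models fitted with the same user seed, keeping AIC differences
between models on common ground.

Model choice uses `AIC = 2k − 2ℓ` with ΔAIC support thresholds of 2
(significant) and 10 (highly significant). Upper prior bounds are soft
(refinement may exceed them, up to 10× and below `0.95 T_A`); lower bounds
are hard. Uncertainty comes from a parametric bootstrap: simulate
replicate SFS datasets at the fitted parameters, refit, and report means
with order-statistic 2.5/97.5 percentiles (so two replicates give their
min/max exactly); replicates whose refit fails are excluded, with more
than 20% failures an error.

Search-effort defaults (300 prior draws screened at 500 replicates, 4
simplex starts × 100 evaluations at 2,000 replicates, 600 polish
evaluations at 12,000 replicates) are the desk-scale counterpart of the
published scheme of 25 iterations × 100,000 simulations × 100 parameter
sets; the recovery harness (below) is the evidence that they suffice at
the reference point.

## SFS construction from genotypes

VCF genotypes (biallelic, GT-only; multi-allelic records skipped and
counted) are polarized against a designated outgroup: the ancestral allele
is the allele carried homozygously by the outgroup consensus, and sites
with a heterozygous, polymorphic, or entirely missing outgroup are dropped
and counted. Per-site derived counts are projected down to the analysis
sample sizes — 10 Sonoran × 10 Chihuahuan × 2 *carneus* haploid
chromosomes, giving an 11×11×3 array — by hypergeometric averaging, which
absorbs missing data; sites with fewer observed chromosomes than the
target in any population are dropped rather than up-weighted. The
projection is tested exactly against exhaustive subsample enumeration for
all configurations with n ≤ 8, and mass conservation (total SFS mass =
number of polarized sites) is asserted exactly for complete data. The
target sizes are interpreted as haploid chromosome counts, the convention
of the SFS tools this format comes from; linkage thinning keeps one
seeded-uniform SNP per locus.

## Differentiation statistics and ΔK

Per locus, allele frequencies are averaged over populations without
sample-size weights (Nei's original formulation; a flag enables weighted
averaging): `H_S` is the mean within-population expected heterozygosity,
`H_T` the heterozygosity of the mean frequency, `G_ST = (H_T − H_S)/H_T`
(zero where `H_T = 0`), and Hedrick's standardization
`G'_ST = G_ST (k − 1 + H_S) / ((k − 1)(1 − H_S))`. Multilocus values use
the ratio of mean components. The Evanno ΔK statistic consumes an
externally produced (K, replicate, log-likelihood) table —
`ΔK = |L(K+1) − 2 L(K) + L(K−1)| / sd(L(K))` on replicate means, interior
K only; the clustering program itself is out of scope.

## Playback analysis

Each site receives four treatments (Local, Distant same-desert,
Across-Barrier, heterospecific Control), observed over Pre-Playback,
Playback, and Post-Playback periods; Playback and Post-Playback are pooled
a posteriori into a Response period (counts summed, call presence OR-ed,
distance series concatenated). Five measures enter the composite: flybys,
alarm-call presence (0/1), close songs, far songs, and the mean of the
distance series with bins mapped to midpoints (0.5, 1.5, 3, 6, 12, 20 m)
and the open-ended >24 m bin coded as 28 m (configurable); the closest
distance is carried for reporting only. The composite is the first
principal component of the correlation matrix of Response vectors (the
measures mix counts, flags, and meters); Pre-Playback vectors are
standardized with the Response means and scales and projected on the same
loadings to give the pre-treatment covariate. The raw orientation of the
component is preserved — its sign is arbitrary and differed between the
two field experiments — and an `orientation_sign` (sign of the correlation
between the score and negated mean distance) is reported for analyses that
need a direction. Zero-variance measures are dropped with a warning and
re-padded with zero loadings.

Treatment effects are assessed with Gaussian linear mixed models fitted by
full maximum likelihood (so fixed-effect structures are comparable):
`score ~ treatment + pre_score` with crossed random intercepts for site
and stimulus set, against the null without treatment. Comparison uses
`AICc = AIC + 2k(k+1)/(n−k−1)` with `k` counting fixed effects, the two
variance components, and the residual variance; Wald chi-square tests
cover Treatment (3 df) and the pre-treatment slope (1 df); all six
pairwise treatment contrasts are reported from the fixed-effect
covariance, without multiplicity correction.

## Synthetic data

The genotype generator wraps the coalescent SNP sampler: diploids pair
consecutive haploid lineages (exchangeability makes fixed pairing
equivalent in distribution to random pairing), each site's REF allele is
the ancestral base only with probability 0.5 (so polarization is actually
exercised), genotypes go missing i.i.d. at a configurable rate, and two
perfect-outgroup individuals homozygous for the ancestral allele are
appended so the polarization step runs end to end. Defaults are the
reference ASYM parameters and the study's sample sizes (54 + 31 + 3
diploids).

The playback generator draws per-trial latent aggression as treatment
effect + `pre_effect ×` baseline + site intercept + stimulus-set intercept
+ residual, then produces the five measures as noisy monotone transforms
(counts rounded at zero, call presence thresholded, the distance series
binned from a jittered linear map of the latent, thresholds chosen so the
marginal bin distribution is non-degenerate at defaults). Site counts
default to the study design (67 + 61 sites × 4 treatments = 512 trials;
removing 16 + 25 undetected sites leaves 348). Defaults are calibrated to
the field study's scale: residual SD 0.6 against site/stimulus SDs 0.2/0.3
(the published variance components), and measurement noise 1.4 so the
first component explains ≈55% of Response variance, as the field PCA did.

What the generators deliberately do not emulate: linkage between SNPs
(sites are exchangeable draws), genotyping error and allele dropout,
outgroup polymorphism (the appended outgroup is perfect unless configured
otherwise), temporal or observer effects in playback trials, and the
study's single Control stimulus set (all four treatments get 5–7 sets, as
the design intended for the song treatments). Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to these field realities.

## Validation harnesses and calibration

- **Demographic recovery** (the headline check): simulate ~20,000
  segregating sites at the reference ASYM parameters (10×10×2 haploid),
  refit with the published priors over ten derived seeds, and compare the
  divergence-time and Chihuahuan-size estimates with the published 95%
  intervals. With default settings the estimates carry a small (~5%)
  upward finite-search bias in `T_D` that shrinks as the polish budget
  grows; the default budget places the large majority of seeds inside the
  published interval in our runs.
- **Model selection**: under isolation truth, all six models are fitted
  with symmetric search effort (every model, including isolation,
  warm-started from a first isolation fit; if a migration model still wins,
  isolation is refitted from the winner's shared parameters — nesting
  guarantees it can match). Without this symmetry the comparison penalizes
  the simpler model for optimizer shortfall, not for fit. Under strong
  asymmetric migration (one direction 10× the other, of order one migrant
  per generation) only isolation and the asymmetric model are compared;
  the asymmetric model wins by hundreds of AIC units.
- **Behavioral power**: a Local-only effect of one residual SD at 200
  trials (50 sites × 4 treatments) must be detected (ΔAICc > 2, significant
  Wald test and Local-vs-Control contrast, Local most aggressive after
  orienting the composite). **Null calibration**: with no treatment effect
  the null model should win on AICc. The null harness runs at zero
  stimulus-set variance: with only 5–7 stimulus sets nested in each
  treatment, stimulus-level noise is partially confounded with treatment
  and maximum-likelihood mixed models are anticonservative (variance
  components are often estimated at zero) — at the power-harness stimulus
  SD of 0.3 the null wins only ~70% of the time for that structural
  reason. The zero-variance null isolates the behavior of the information
  criterion itself; the confounding phenomenon is real and worth knowing
  about when interpreting field results.

## Numerical notes and limitations

- All stochastic operations take explicit integer seeds; per-replicate
  seeds are derived inside the kernel so results are independent of
  batching. Fits are bit-reproducible given (data, settings, seed).
- The composite likelihood ignores linkage; its absolute scale is not a
  true log-likelihood, so AIC differences are composite-likelihood AICs,
  as in the tool this pipeline mirrors.
- `T_SC` is clamped to `[0, T_D]` and `T_D` to below `0.95 T_A` during
  search; migration-to-rate conversion caps backward rates at 0.5.
- Percentile bootstrap intervals at B = 100 have sizable Monte-Carlo width
  themselves; the coverage test runs at reduced B and checks containment,
  not calibrated coverage.
- The mixed models use `statsmodels` MixedLM with variance components for
  the crossed random intercepts; near-singular fits (variance components
  at zero) are accepted and reported as zeros, matching standard practice.
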