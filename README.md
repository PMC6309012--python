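# cochise

Population-genomic and behavioral analyses of divergence across the
Cochise Filter Barrier — the habitat gap separating the Sonoran and
Chihuahuan deserts that filters gene flow between Northern Cardinal
(*Cardinalis cardinalis*) populations.

The package implements, as a tested pipeline:

- **Joint-SFS demographic inference.** Build an unfolded three-population
  joint site-frequency spectrum from VCF genotypes (outgroup polarization,
  hypergeometric projection over missing data), simulate expected spectra
  under six isolation / isolation-with-migration / secondary-contact
  coalescent models with a fast structured-coalescent engine, fit by
  multinomial composite likelihood, select models by AIC (ΔAIC thresholds
  2 and 10), and get 95% intervals by parametric bootstrap.
- **Differentiation statistics.** Nei's G_ST and Hedrick's G'_ST per locus
  and multilocus, and the Evanno ΔK statistic on clustering
  log-likelihood tables.
- **Playback-experiment analysis.** Reduce five field aggression measures
  to a PCA composite (PC1) on Response-period data, project Pre-Playback
  data with the same loadings, and compare treatment effects (Local /
  Distant / Across-Barrier / Control song) with linear mixed models under
  small-sample-corrected AIC, Wald tests, and pairwise contrasts.
- **Synthetic data.** Generators for SNP matrices (VCF + popmap) under the
  demographic models and for playback trial tables under the mixed-model
  structure, so every stage is validated by parameter recovery.

The scientific core is the demographic model: Sonoran and Chihuahuan demes
of haploid sizes N_eS, N_eC split from an ancestral deme (N_eD) at time
T_D, with the *C. c. carneus* outgroup (N_eO) splitting from their common
ancestor (N_eA) at a fixed calibration T_A = 2 My; generation time 1 year,
mutation rate μ = 2.21 × 10⁻⁹ per site per year. Migration, where a model
allows it, is a backward per-lineage probability m (equivalently, forward
migrant counts per generation — both conventions are supported). Expected
spectra are computed by Rao-Blackwellized branch-length accumulation:
entry (i, j, k) is μ times the mean total branch length subtending exactly
i/j/k sampled chromosomes per deme. See `docs/methods.md` for the full
model description, numerical choices, and validation design.

## Worked example

Simulate a SNP dataset at the best-supported parameter estimates for this
system, build the projected SFS, and fit two models:

```sh
cochise simulate genotypes --out demo --seed 7 --n-snps 2000 --individuals 12,12,2
cochise sfs --vcf demo/genotypes.vcf --popmap demo/popmap.tsv \
        --out demo/obs.sfs --project 10,10,2
cochise fit --sfs demo/obs.sfs --model ISO  --seed 7 --out demo/fit_iso.tsv \
        --draws 60 --starts 2 --refine 60 --reps 800 --polish 60
cochise fit --sfs demo/obs.sfs --model ASYM --seed 7 --out demo/fit_asym.tsv \
        --draws 60 --starts 2 --refine 60 --reps 800 --polish 60
cochise select demo/fit_iso.tsv demo/fit_asym.tsv --out demo/selection.tsv
```

The selection table (tab-delimited) from one run of the above:

```
model_id  k  loglik               aic                delta_aic           support
ISO       6  -4606.8930817484015  9225.786163496805  0.0                 best
ASYM      8  -4610.59130790384    9237.18261580768   11.396452310875247  highly_significant
```

Read: at 2,000 SNPs the asymmetric-migration model buys no composite
log-likelihood over isolation (its two extra parameters even trap the
reduced search slightly short), so isolation wins with ΔAIC > 10. At this
reference point the generating migration is about one migrant per 10⁵
generations, so preferring isolation is the correct call. With larger SNP
counts (the study scale of ~20,000) the same workflow recovers the
generating divergence time and effective sizes; that is exactly what the
reproduction script below measures.

The playback side, end to end:

```sh
cochise simulate playback --out demo/trials.tsv --seed 7 --sites 50,0
cochise behavior --trials demo/trials.tsv --desert SON --out demo/behavior.tsv
```

The output table starts:

```
quantity               value
AICc_null              687.8382270571359
AICc_full              653.1998907539964
delta_AICc             34.638336303139454
PC1_var_explained      0.5540129152634317
orientation_sign       -1.0
wald_treatment_chi2    107.91053913232417
wald_treatment_p       3.0900551034705595e-23
```

Read: the first principal component carries 55% of the Response-period
variance (here oriented so that more negative = more aggressive); adding
Treatment improves AICc by 34.6, and the Wald test confirms the treatment
effect (the generator's default puts a Local-song effect of 1.5 latent SD
into these trials). The remaining rows give the pre-treatment slope,
variance components, and all six pairwise treatment contrasts.

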