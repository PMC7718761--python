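# Methods

`rohscan` analyses runs of homozygosity (ROH) in diploid biallelic SNP
cohorts: quality control, diversity and inbreeding metrics, sliding-window
ROH detection, length-class and chromosome summaries, and ROH-island
scans. This note documents the models, parameter choices and numerical
conventions, and what the synthetic cohorts used for validation do and do
not establish about real data.

## Genotype model and containers

Genotypes are dense `int8` matrices (individuals × variants) coded as the
number of ALT alleles (0/1/2) with −1 for missing. Only biallelic SNPs
are handled; multiallelic and non-SNP records are skipped on VCF import
and counted. Variant positions are 1-based and strictly increasing
within each chromosome. Interchange coordinates (BED output, interval
intersection) are 0-based half-open; detection-internal segment
coordinates are 1-based inclusive SNP positions with
`length = end − start + 1`.

## Quality control

Three variant filters run in cheap-to-expensive order, each variant
counted once under the first rule that removes it:

1. **Polymorphism** — fewer than one copy of the minor allele among
   non-missing calls, cohort-wide.
2. **Call rate** — fraction of non-missing calls below `min_callrate`
   (default 0.1). The low default is deliberate: it is a permissive floor
   appropriate for sequence-derived panels with millions of sites; it is
   applied per variant, not per individual.
3. **Hardy–Weinberg** — exact-test p-value below `hwe_alpha` (default
   1e-6) in *any single population*. Testing within populations rather
   than on the pooled cohort is a deliberate choice: pooling diverged
   populations produces a Wahlund heterozygote deficit that would reject
   en masse at well-behaved sites.

The HWE test is the standard two-sided exact test conditional on allele
counts: the probability of `h` heterozygotes among `N` diploids given the
minor-allele count is proportional to the multinomial weight
`N!/(n1! h! n2!)·2^h` over heterozygote counts of matching parity, and
the p-value sums all configurations whose probability does not exceed the
observed one (no mid-p correction). The implementation uses exact integer
arithmetic (`math.comb` and `Fraction`), so tie comparisons are resolved
exactly rather than at floating-point precision; results are memoized on
`(N, minor count, het count)`, which makes per-variant testing cheap
because only a few hundred distinct triples occur per population.

## Diversity and inbreeding

* **Ho** — per-individual heterozygous fraction of non-missing calls.
* **He** — per-variant `2p(1−p)` from within-population allele
  frequencies, without small-sample correction (reported as a population
  summary; a corrected variant would multiply by `2n/(2n−1)`).
* **PN** — the "polymorphic marker ratio" is implemented operationally as
  the mean over individuals of the proportion of non-missing calls at the
  sites polymorphic within the population, × 100. The name suggests a
  fraction of polymorphic loci; the operational definition is what the
  quantity actually measures here and is the one implemented.
* **F_is** — per individual, `(O − E)/(L − E)` with `O` the observed
  homozygote count over the `L` non-missing sites and `E` the summed
  expected homozygosity `1 − 2p(1−p)·2n/(2n−1)`. The `2n/(2n−1)` factor
  is the conventional method-of-moments small-sample correction; without
  it, `E` is biased low and F_is biased high at small `n`. With it, the
  population mean F_is is centred at zero under Hardy–Weinberg sampling
  (verified to within 3 SE at n = 200 in the test suite). `F_is` is NaN
  with a warning when `L = E`.

## ROH detection

A window of `window_snps` = 50 consecutive SNPs is *homozygous* when it
contains at most `window_max_het` = 3 heterozygous and
`window_max_missing` = 5 missing calls. Each SNP's hit rate is the
fraction of containing windows that are homozygous; edge SNPs use only
the windows that exist, and a chromosome shorter than one window is a
single whole-chromosome window. A SNP is flagged when its hit rate is at
least `hit_proportion` = 0.05 (inclusive — "set to 0.05" is read as a
floor) *and* its own call is not heterozygous; missing calls may be
flagged because a missing call is not evidence against homozygosity.
Maximal runs of flagged SNPs are split at physical gaps above
`max_gap_kb` = 1000 and kept when they have ≥ `min_snps` = 50 SNPs, span
≥ `min_length_kb` = 300, and average ≤ `min_density_kb_per_snp` = 50 kb
per SNP. The het/missing allowances are window properties only and are
not re-imposed on the final segment.

Two interpretive points are worth making explicit. First, excluding a
SNP whose own call is heterozygous prevents het sites from sitting
inside reported runs beyond the window allowance; it also means a single
heterozygous call splits a run in two, which is exactly how long ROH
"break" into shorter tracts when genotyping error is present. Second,
the window allowance has a boundary consequence: any window containing
at most three SNPs outside a long homozygous tract passes regardless of
those SNPs' calls, so SNPs just beyond a tract are flagged whenever they
are themselves homozygous. A detected segment therefore extends past a
planted tract by the run of flanking SNPs that are homozygous *by
chance* — a geometric-length run with mean `(1−h)/h` SNPs per side at
background heterozygosity `h` (≈ 2.6 SNPs ≈ 13 kb per side at h = 0.28
and 5-kb spacing). This is not an implementation artifact: the flanking
homozygous SNPs are genuinely part of the homozygous run, and no
genotype-based caller can tell chance flanking homozygosity from
autozygosity. Consequences for validation: recovery of planted tracts
is complete in the one-sided sense (the detected run always spans every
SNP of an error-free tract ≥ 400 kb), but *reciprocal* overlap ≥ 95%
fails for roughly 15% of 400-kb-scale tracts on the desk cohort, and
boundary agreement to within one inter-SNP spacing fails for most. The
test suite asserts the one-sided property; the stricter two-sided bound
is exercised in the acceptance suite and fails for the reason above,
with the realized recovery rate reported by `scripts/acceptance.py`.

The caller is validated by set-equality against a brute-force oracle
(explicit per-window counting and run enumeration in pure Python) on
hundreds of random chromosomes, and post-filter monotonicity (raising
`min_snps` or `min_length_kb` never adds segments) is property-tested.

## Summaries and F_ROH

Segments are binned into seven length classes (0.3–1, 1–2, 2–4, 4–8,
8–10, 10–16, >16 Mb), left-closed right-open, so a segment of exactly
1.0 Mb falls in the 1–2 class; the classes are contiguous and
exhaustive above the 0.3 Mb reporting floor, and a segment below it is a
caller-contract violation, not data. `F_ROH = L_ROH / L_total` uses a
fixed genome size as denominator (default 931,000,000 bp, the chicken
autosomal assembly scale); per-class values use only that class's
segments and sum to the total exactly. Chromosome coverage averages the
covered fraction over *all* individuals of a population, including
non-carriers. Pearson correlation (for F_is vs F_ROH) delegates to
`scipy.stats.pearsonr` after validating length and variance.

## ROH islands

Per-SNP incidence is the fraction of a population's individuals with a
segment covering the SNP. The island threshold is the incidence of the
`ceil(top_fraction · n)`-th most-covered SNP (nearest-rank order
statistic, default `top_fraction` = 0.01): incidence takes at most N+1
discrete values for N individuals, so interpolation would be spurious.
This makes thresholds population-specific by construction — strongly
inbred populations produce high thresholds, diverse ones low — which is
the behaviour that motivates a quantile definition over a fixed
incidence cut-off. Islands are maximal runs of ≥ 2 adjacent qualifying
SNPs, broken at gaps > 1 Mb (the same gap scale as the caller, for
consistency). Interval intersection is half-open and returns all pairs
with ≥ 1 bp overlap; it is validated against a quadratic all-pairs
oracle and is symmetric up to column order.

## Synthetic cohorts

The generator emulates a five-population cohort: two layer-like lines
(WL, BL), two broiler-like lines (BRA, BRB) and a wild-reference
population (RJF), with target heterozygosities 0.278/0.282/0.296/0.309/
0.240 and n = 25/25/20/20/25. Per-SNP allele frequencies are drawn from
a symmetric Beta(a, a) with `a = h/(1−2h)` so that mean heterozygosity
`E[2p(1−p)]` equals the target `h`; genotypes are sampled independently
per site under Hardy–Weinberg proportions. Autozygosity is planted as
uniform-placed intervals homozygous for one founder haplotype, with
Poisson per-class counts per individual; overlapping tracts of one
individual are merged (with a warning) and the merged intervals are the
returned ground truth. Inside tracts, heterozygous calls are injected at
`within_tract_het_rate` (default 0.005) and missing calls at
`missing_rate` (default 0.02, matching a 0.97–0.99 genotyping rate).

The default desk-scale genome is three chromosomes of 50, 20 and 5 Mb
(macro/intermediate/micro contrast) at 1 SNP / 5 kb, ≈ 15,000 SNPs.
Tract burdens are scaled to this 75 Mb genome — e.g. the WL-like profile
plants ≈ 18 Mb per bird, mostly in the 0.3–1 Mb class, the RJF-like
profile ≈ 5 Mb weighted toward longer classes — chosen so that the
populations preserve the qualitative ordering of ROH burden and class
composition while keeping tract merging rare; the absolute per-bird ROH
counts and F_ROH of a full-genome cohort are not reproduced at desk
scale, and the default pipeline config therefore uses the 75 Mb layout
size as the F_ROH denominator.

What the simulator does *not* model: linkage disequilibrium and
recombination-driven haplotype structure, allele-frequency correlation
between populations (each population draws frequencies independently),
site-frequency-spectrum realism, genotyping error outside planted
tracts, and sex chromosomes. Passing recovery and calibration tests on
these cohorts therefore establishes the correctness of the scan
arithmetic and threshold logic, not the biological calibration of the
parameters on real sequence data.

## Determinism and problem sizes

All randomness flows through `numpy.random.default_rng(seed)`; seeds are
mandatory arguments and never global state. The same seed yields
byte-identical VCF and report output (asserted in tests). Test and
acceptance problem sizes — ≈ 15,000-SNP cohorts of 115 individuals, 100
random chromosomes of up to 2,000 SNPs for oracle equivalence, all
genotype-count triples with total ≤ 50 for the HWE exact test — were
chosen as the smallest scales at which every property they check is
informative.
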