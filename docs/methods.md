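# Methods

This note records the statistical model behind `mutmapkit`, the default
parameter values and why they were chosen, and the numerical decisions that
are not obvious from the code.

## 1. Genetic model

**Genome.** Ten chromosomes with physical lengths approximating a maize
assembly (151–307 Mb) and genetic lengths of 1.2–2.0 Morgans (~15 M total,
in line with consensus maize maps). Physical and genetic coordinates are
related by a constant rate per chromosome; the mapping statistics only ever
need the genetic distance between markers, so finer map structure would add
parameters without changing what is being tested.

**Meiosis.** Gametes are simulated with Poisson-distributed crossover counts
(mean = genetic length in Morgans) at uniform physical positions and no
interference. Evaluated at marker positions this is exactly a two-state
Markov chain whose switch probability between adjacent markers at genetic
distance *d* is Haldane's recombination fraction
`r(d) = (1 − e^(−2d))/2`; the implementation samples that chain directly
(vectorised switch draws + cumulative XOR), which is equivalent in
distribution at marker resolution and orders of magnitude faster. The unit
suite checks both the marginal switch frequencies and the pairwise genotype
correlation `corr = 1 − 2r` against this model.

**F2 and bulk.** F2 genotypes are the sum of two independent gametes.
The mutant bulk takes the first `pool_size` individuals homozygous for the
mutant allele at the causal site (a random subset under `causal=None`, the
null model); an optional phenotyping error rate replaces bulk slots with
random non-mutant individuals. With perfect selection the expected pooled
mutant-allele frequency at recombination fraction *r* from the causal locus
is `1 − r` — verified against brute-force enumeration of the two-locus F2
distribution, and end-to-end as an acceptance criterion.

**Reads.** Per-marker pool depth is Poisson (mean 60× for the pool, 15×/20×
for the wild-type/mutant parents); alternate read counts are binomial with
success probability `f(1−e) + (1−f)e` at sequencing error rate `e = 0.001`.
Reads are independent across markers given the bulk — no mapping bias, GC
bias or depth autocorrelation is modelled (see Limitations).

**EMS spectrum.** Variant classes are drawn from fixed probabilities
matching observed induced-marker counts: 2730 G>A, 2465 C>T, 169 other SNPs,
290 indels out of 5654 (91.9% G:C→A:T transitions). Positions are uniform
over the genome in proportion to physical length.

## 2. Marker selection rules

A site is *supported* only if `ref + alt > 2`. Zygosity calls from allele
depths: homozygous-alternate iff `alt ≥ 4 and ref ≤ 1`; homozygous-reference
mirrored; heterozygous iff both alleles have ≥ 2 reads (and the site is
supported); anything else is ambiguous. A mapping marker must be
homozygous-alternate in the mutant parent and *clean* in the wild-type
parent (homozygous-reference, or at most one alternate read). These exact
thresholds are pinned by an enumeration test over all read-count pairs in
[0, 20]².

## 3. Genome scan

**Index track.** `index = alt/(ref+alt)` in the pool at every marker;
zero-depth markers are excluded, duplicate positions merged by summing
counts.

**Smoothing.** Cleveland's LOWESS (tricube weights, local linear fits,
3 bisquare robustness iterations), implemented in-house as a batch routine:
the per-point weighted sums needed for all local fits are obtained from five
matrix products against a shared abscissa weight matrix, so 100 replicate
tracks smooth in ~60 ms where a looped reference implementation takes
seconds. The routine is held to ≤1e−10 agreement with
`statsmodels.nonparametric.lowess` in the test suite; statsmodels remains
the oracle, not the production path, purely for speed at
100-replicate scale. A degenerate robustness case (median absolute residual
of ~0 makes all bisquare weights collapse) is handled with a 1e−12 weight
floor.

**Span.** The smoothing window is 5% of each chromosome's markers
(~28 markers, ~12 Mb at default density). The classical 2/3 default is far
too wide here: it flattens the linkage peak into the chromosome-wide trend
and displaced the summit by ~51 Mb in calibration runs, versus a maximum
error of 2.8 Mb over 60 seeded replicates at 5%. The window must sit between
the read-noise scale (a few markers) and the linkage decay scale (tens of
Mb); 5% is in the middle of the plateau of spans that work.

**Null threshold.** The 95% threshold is the 0.95-quantile of the
genome-wide *maximum* smoothed index over 100 simulated null tracks at the
observed marker positions and depths. The null has two components:
binomial read noise at frequency 0.5, **plus** the sampling drift of a
finite bulk — even unlinked markers share a random 200-plant draw, giving
each marker frequency variance `1/(8·pool_size)` with inter-marker
correlation `e^(−2d)` (the first two moments of the gamete Markov chain),
simulated as a Gaussian AR(1) along each chromosome. A binomial-only null
ignores this drift, under-estimates the threshold and produces spurious
regions on non-causal chromosomes; with the drift term included, scans with
no causal locus report zero regions in ~95% of replicates, matching the
nominal quantile (an acceptance criterion).

**Regions.** Candidate regions are maximal runs of consecutive markers with
smoothed index ≥ threshold. Runs on the *same chromosome* are merged into
one region (merge gap = the chromosome's full marker span, the default):
linkage elevates the entire causal chromosome, so its separate
threshold crossings are one dependent signal, and treating flank excursions
15–70 Mb from the peak as independent candidates double-counts the same
locus. The summit is the (leftmost) maximum of the smoothed track; the
global summit is the highest region summit.

## 4. Assays

- Anthocyanin: `[(OD530 − OD620) − 0.1·(OD650 − OD620)] × volume_ml / mass_g`.
- Relative expression: `2^(−ΔΔCt)` with
  `ΔΔCt = (Ct_target − Ct_ref)_test − (Ct_target − Ct_ref)_control`.
- Segregation: Pearson chi-square against an expected ratio (default 3:1),
  df = 1, optional Yates continuity correction. The p-values are discrete
  (largest null atom ~0.065 at n = 200), so the calibration test applies a
  randomised probability integral transform before the KS uniformity check —
  raw discrete p-values cannot pass a KS < 0.05 bound and the randomised
  PIT is the standard fix.

## 5. Default parameters

| Parameter | Default | Rationale |
|---|---|---|
| `n_variants` | 5654 | observed induced-marker count the spectrum is calibrated to |
| `n_f2` | 1000 | large enough that a 200-plant recessive bulk (expected 250 mutants) almost always fills |
| `pool_size` | 200 | >200 mutant F2 pooled in the motivating experimental design |
| `mean_depth_pool` | 60 | pooled sequencing depth of that design (~62×) |
| `mean_depth_wt/mut` | 15 / 20 | parental depths of that design (14.2× / 19.4×) |
| `sequencing_error_rate` | 0.001 | typical post-filter short-read error |
| `span_fraction` | 0.05 | see Smoothing above |
| `q`, `n_sims` | 0.95, 100 | nominal genome-wide 5% false-positive rate; 100 maxima give a stable 0.95 quantile |
| `merge_gap_fraction` | 1.0 | per-chromosome merging, see Regions above |
| causal locus | chr4:195678521 | planted recessive locus used throughout the worked example |

## 6. Limitations

- Read sampling is independent across markers given the bulk: no alignment
  bias toward the reference allele, no GC/coverage waves, no shared-fragment
  correlation between nearby markers. Real pooled data would push the null
  threshold higher than this generator suggests.
- Constant recombination rate per chromosome — no centromeric suppression,
  so resolution near centromeres is optimistic.
- No interference in meiosis (Haldane, not Kosambi); at the distances that
  matter for the index decay the difference is small.
- The phenotype is fully penetrant and monogenic by construction; the
  `phenotyping_error_rate` knob only models random misclassification.
- Variant positions are uniform; real EMS variants cluster with chromatin
  and gene density.
- The scan assumes a recessive causal allele in a mutant-pool-only design;
  dominant traits or two-bulk (ΔSNP-index) designs are out of scope.
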