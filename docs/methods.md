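# Methods

## Problem setting

`poolscan` analyses Pool-Seq data: whole-genome sequencing of pooled DNA from
tens of individuals per population, genotyped as population allele frequencies
rather than individual genotypes. Each pool is assigned a fixed ploidy
C (default 20 allele copies per locus), so pool frequencies live on a 1/C grid
(increments of 0.05) and per-pool reference-allele counts sum to C. The
pipeline scans two groups of pools ("superpools") for localized regions of
elevated relative divergence — islands of differentiation — and characterises
them with absolute divergence and within-population diversity statistics.

## Estimators

Let p_X, p_Y be superpool reference-allele frequencies (unweighted arithmetic
means of member pool frequencies) and q = 1 − p.

* **Nei F_ST** = (Ĥ_T − Ĥ_S)/Ĥ_T with Ĥ_T = 2 p̄ (1 − p̄), p̄ the unweighted
  mean of group frequencies, and Ĥ_S the mean of within-group expected
  heterozygosities 2 p_i q_i. For two equally weighted groups this reduces
  algebraically to (p_X − p_Y)² / (4 p̄ q̄), which is the identity the test
  suite fuzzes. Sites with Ĥ_T = 0 are undefined (NaN) and excluded from all
  averages. The estimator is upwardly biased for pooled data because binomial
  pool sampling inflates between-group variance; the bias is consistent across
  pools of similar depth and pool size, so relative comparisons are
  meaningful. A bias-corrected estimator is deliberately out of scope.
  Group weighting is equal by default; ploidy weighting (e.g. 120:60 for a
  6-pool vs 3-pool comparison) is available via `weights="ploidy"` because the
  convention is genuinely ambiguous for superpools of unequal size.
* **d_XY** (unphased) = p_X q_Y + q_X p_Y. Symmetric, equal to 2p(1−p) when
  both groups share frequency p, and independent of within-group diversity.
* **Lin's concordance ρ_c** = 2ρσ_Xσ_Y / (σ²_X + σ²_Y + (μ_X − μ_Y)²), with
  population (n-denominator) moments so that ρ_c = 1 exactly iff the two
  frequency vectors are identical. Used to quantify replicate-pool agreement.
* **Global pairwise F_ST**: one whole-genome window per pool pair — the
  unweighted mean of per-SNP Nei F_ST over sites with Ĥ_T > 0 for that pair.

## SNP filters

Two steps, in order: (1) depth — drop any SNP whose depth in any pool is below
20× or above 2% of that pool's total reads summed over all input SNPs (the
per-pool cap); (2) completeness/variance — drop SNPs missing in any pool,
flagged multi-allelic, or monomorphic across all pools (every pool fixed for
the same allele). Both filters are idempotent on realistic inputs; the depth
cap is recomputed from the current matrix, so pathological inputs where
removal shifts totals across the 2% boundary could in principle differ on
reapplication.

## Kernel-smoothed scan

Window centers advance by a 20 kb step along each linkage group; a window is
the interval c ± 3σ with σ = 30 kb, i.e. a 180 kb span (the kernel is
truncated at 3σ — the only truncation consistent with that span). A SNP at
position p contributes weight exp(−(p−c)²/2σ²).

* Weighted F_ST is Σ wᵢ fᵢ / Σ wᵢ over SNPs with defined per-SNP F_ST; a
  window with none gets NaN and S_n = 0.
* Weighted d_XY is Σ wᵢ dᵢ / W with W the kernel weight summed over **every
  integer bp** of the span (W ≈ 74,995 at the defaults). Monomorphic sites
  contribute zero to the numerator, so d_XY is a per-bp quantity (order
  10⁻⁴–10⁻³ at realistic SNP densities), not a per-SNP mean.
* π per superpool: Σ 2j(C−j)/(C(C−1)) over sites in the span, divided by the
  window length n = 6σ; j is the reference-allele count at the superpool
  ploidy C (C = 20 × number of member pools). 2j(C−j) is symmetric in j, so
  the reference/derived labelling does not matter.
* Watterson's θ_W = S_n / Σ_{i=1}^{C−1} 1/i. The upper summation limit is
  configurable (`theta_sum_upper ∈ {"C-1", "C"}`) because both conventions
  appear in applied work; the default is the standard Watterson form, which is
  also what the Tajima variance constants assume.
* Tajima's D = (π_sum − θ_W)/√(e₁S + e₂S(S−1)) with the Tajima (1989)
  constants at sample size C. D uses the **per-window π total** (not the
  per-bp value) so π and θ_W are on the same scale; mixing scales would let
  θ_W dominate the numerator. S_n = 0 windows are undefined (NaN).

S_n is the number of SNPs in the window with defined per-SNP F_ST. For π and
D every SNP in the span contributes (a site monomorphic in one superpool adds
zero), so the same S_n serves both the significance lookup and θ_W.

## Bootstrap significance and FDR

Window significance is judged against bootstrap distributions of the
kernel-weighted mean built from the genome-wide pool of per-SNP F_ST values
for the same comparison. For each window size n (up to n_max, default 2000):
B replicates, each drawing n values with replacement and attaching them to n
positions drawn uniformly in [c−3σ, c+3σ]. Uniform random positions are the
least-informative way to attach kernel weights to an unordered draw; the
choice is recorded in the reference-file header. A window with S_n SNPs uses
the distribution for n = min(S_n, n_max); p = (#replicates ≥ observed)/B,
with resolution floor 1/B. The study-scale default is B = 10⁶; the test suite
and acceptance script use B = 10⁴, which resolves p-values to 10⁻⁴ and leaves
the uniformity of null p-values intact (KS distance < 0.05 against U(0,1) at
500 windows). Benjamini–Hochberg step-up adjustment (own implementation,
cross-checked against statsmodels) yields q-values; windows with S_n = 0 are
excluded from the adjustment. The significance threshold for "outlier
windows" defaults to q < 0.05 and is configurable.

## Islands of differentiation

An island is a maximal run of ≥ 4 consecutive windows (centers exactly one
step apart — a gap at a linkage-group end breaks the run) with weighted F_ST
strictly above 0.03. The interval is [first_center − step/2,
last_center + step/2], so island length = n_windows × step and may be smaller
than one full window span. The 0.03 default reflects an upper-decile choice
on the window distribution; `fst_threshold_from_quantile` offers the
quantile-based alternative, and `min_run` is configurable. Summaries report
mean weighted F_ST/d_XY over member windows, counts of windows with d_XY
above the genome-wide upper 5% quantile and above the genome-wide mean, and
per-superpool mean π and Tajima's D with counts below the genome-wide 5%
quantile. The dispersion of outlier windows across linkage groups is
summarised by the coefficient of variation (sample SD / mean) of per-LG
outlier counts.

## Gene overlap and covariates

A gene is "in" an island if gene body and island interval overlap by ≥ 1 bp;
its SNP count and mean per-SNP F_ST are taken over the **gene body**, not
clipped to the island. GFF3 (1-based inclusive) and BED (0-based half-open)
are normalised to half-open internally; parsing is strict with line-number
diagnostics, which is why the two tabular formats are read with pandas plus
explicit validation rather than a database-building annotation library.
Overlap uses an interval tree and is verified against a quadratic brute-force
oracle.

The environmental-association model itself is an external tool; `covariates`
only prepares its inputs (z-scored covariate tables, scalar current velocity
w = √(u²+v²)) and consumes its outputs: replicate-run convergence is checked
with pairwise Pearson correlations (averaging across runs is sanctioned only
when all pairs exceed 0.9), and SNPs with run-averaged log10 Bayes factor
above 30 dB are counted per island and covariate. Optical depth converts to
light transmission as exp(−od): 2.303 (= ln 10) units per decade.

## Synthetic data generator

The generator emulates the structure the analysis assumes: 11 pools (6 + 3 +
2 across three superpools, with two same-individual replicate pairs and one
temporally perturbed pair), ploidy 20, Poisson read depths with per-pool means
60–98, a truncated-Beta ancestral frequency spectrum (Beta(0.7, 0.7) clipped
to [0.05, 0.95] so grid quantization rarely fixes SNPs), Poisson SNP counts at
density 10⁻³/bp on five 2-Mb linkage groups, and a small fraction (0.2%) of
SNPs with depth zero in one pool to exercise the missing-data filter.

Population frequencies follow the Balding–Nichols model: given ancestral p
and divergence parameter c, a population's frequency is
Beta(p(1−c)/c, (1−p)(1−c)/c), with mean p and variance c·p(1−p). Replicate
pools share their population's frequencies exactly (independent binomial pool
draws) or, for the temporal pair, after a small Balding–Nichols perturbation
(c = 0.002).

**Calibration.** The dials `background_fst` and island `fst` are expressed on
the scale the pipeline reports: the expected pairwise Nei F_ST measured
between the two compared superpools. Two effects separate that scale from the
raw per-population parameter c: (i) Nei pairwise F_ST between two populations
each at parameter c is ≈ c/2, and (ii) binomial(C) pool sampling adds
τ = 1/(C·k_X) + 1/(C·k_Y) to the between-superpool variance (k pools per
superpool). Solving the expectation N/(4−N) = F with N = 2c + (1−c)τ gives
c = (N − τ)/(2 − τ), N = 4F/(1+F). Dials at or below the sampling floor
τ/(4−τ) (≈ 0.0063 for the 6-vs-3 default) map to c = 0. Island intervals
raise the designated diverged population to c_isl = 2·c(F_isl) − c_bg. The
residual gap between dial and measurement (Jensen's inequality on the per-SNP
ratio) is about −6% at F = 0.02, well inside the 20% recovery band the tests
assert. Without this calibration an absolute island threshold of 0.03 would
sit 1.5 standard errors above a nominal 0.02 background and null scans would
call spurious islands.

**What the generator does not emulate:** linkage disequilibrium and haplotype
structure (SNPs are independent), read-level error, a realistic site-frequency
spectrum (the symmetric Beta ancestral spectrum lacks the excess of rare
alleles real data show, so synthetic Tajima's D is positive rather than
negative), alignment artefacts, and within-superpool substructure. Passing
recovery tests therefore demonstrate that the scan machinery detects
frequency-shift islands of the configured size and strength under independent
SNPs — not that it would behave identically under linked selection or
demographic confounding.

## Numerical choices

* Undefined statistics (F_ST at Ĥ_T = 0, D at S_n = 0, p-values for empty
  windows, CV at zero mean) are NaN sentinels, excluded from averages and
  from the FDR adjustment — never silently zeroed.
* p-value ties count as extreme (#replicates **≥** observed), so p = 0 only
  above the null maximum; the floor 1/B is documented in the null header.
* Island threshold comparison is strict (> 0.03); quantiles use linear
  interpolation (`numpy.quantile` default).
* The sync reader keeps the sync reference base as the reference allele when
  it is among the two most frequent alleles genome-wide at that site, and
  rounds depth-based frequencies to the nearest 1/C; this is a stand-in for
  upstream maximum-likelihood allele-frequency estimation, which is not
  reproducible from count data.
* Determinism: every stochastic routine takes an explicit seed or
  `numpy.random.Generator`; identical seeds give bit-identical datasets and
  null references.

## Problem sizes

Default test and acceptance runs use five 2-Mb linkage groups at SNP density
10⁻³ (≈10⁴ SNPs, 460 windows), bootstrap B = 10⁴ over the ~60 distinct window
SNP counts that occur, and 10 seeds for the recovery/type-I/ordering suites.
These sizes were chosen so the full suite completes in well under a minute
per seeded scenario while keeping Monte-Carlo error far below the asserted
tolerances; the scan and bootstrap code paths are identical at study scale
(23 linkage groups, ~1.9 M SNPs, B = 10⁶), only slower.

## Known limitations

* The Nei/heterozygosity F_ST carries the Pool-Seq upward bias described
  above; absolute F_ST levels should not be compared across designs with
  different pool counts or ploidies.
* Windows with S_n larger than n_max reuse the n_max null distribution.
* The per-window significance treats windows as exchangeable with the
  genome-wide SNP pool; heavy autocorrelation between overlapping windows is
  handled only through the FDR adjustment, not through an explicit dependence
  model.
* BED/GFF3 parsing covers the tabular core of those formats (the fields the
  overlap analysis uses), not the full attribute ontology.
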