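# Methods

This note documents the models, estimators and numerical choices behind
metaboflow, what the synthetic generators do and do not emulate, and the
design decisions taken where the problem was genuinely open.

## Spectra model and I/O

A run is an RT-ordered list of centroided MS1 scans; retention time is
always stored in seconds (minute-denominated inputs are converted at parse
time).  mzXML is read through pyteomics; mzML is read and written by a
compact reader/writer pair (64-bit float arrays, zlib-compressed, base64)
validated by exact round-trip.  Profile-mode spectra are not rejected but
reduced to their local intensity maxima, with a flag in the run metadata;
whole-run inspection applies no intensity threshold before computing the
TIC.

## Synthetic data

`simulate_run` plants Gaussian-in-time peaks
`h·exp(−(t−apex)²/(2σ²))` on a regular RT grid, jitters each centroid's m/z
by N(0, ppm), adds isotopologue traces at +1.003355/z Th with relative
abundance drawn uniformly from 0.05–0.3 (enough to exercise isotope
detection without modeling elemental composition), and sprinkles noise
points uniform in m/z — the sparse background that makes ROI selection
informative.  Centroids below a detection floor (1 count) are not recorded,
as on a real instrument.  Every generator is a pure function of its
arguments and a seed, and ground truth (planted peaks, the clean matrix,
truth labels) is always returned next to the data.

`simulate_batched_table` separates three variance sources deliberately:
per-feature biological variation across study samples (log-sd 0.3),
technical noise on every injection (log-sd 0.05), and the batch effect
itself.  Pooled QC samples are the all-sample mean profile plus technical
noise only — this asymmetry (tight QCs, spread samples) is exactly what
makes QC dispersion an informative evaluation signal, and real pooled QCs
behave this way.  Batch shifts are feature-specific (log-normal around the
nominal factor, spread 0.3): a uniform multiplicative shift is row-sum
invariant, hence invisible to correspondence-analysis ordinations, and is
normalization's job rather than batch correction's.

What the generators do **not** emulate: chromatographic tailing, matrix
effects, mass-calibration drift, missing-value mechanisms beyond absence
from a sample, and correlated feature blocks.  Passing tests therefore
demonstrate correct recovery of planted structure under idealized peak
shapes and noise, not performance on vendor data.

## Peak detection

Centroids are chained into m/z traces by splitting the m/z-sorted point
cloud at gaps exceeding the ppm tolerance.  Traces must contain
`prefilter_k` consecutive scans above `prefilter_i` and reach the `noise`
floor.  Apexes are located on a lightly smoothed EIC (Gaussian filter,
σ ≈ 1.5 s — fixed, so the measured width does not depend on the width
filter being applied); bounds extend to the first valley or to 5% of the
apex height, whichever comes first.  For an isolated Gaussian this gives a
full width of ≈4.9σ, so planted peaks with σ ∈ [3, 6] s measure ≈15–29 s.
Signal-to-noise is (apex − boundary baseline) over the median positive
off-peak EIC intensity.  Peaks closer than `mzdiff` in m/z with overlapping
RT ranges are merged.  Areas are trapezoidal over the delimited bounds and
therefore clip ~2.5% of the theoretical Gaussian mass; the area test
accounts for this.

Peak shape is scored by nonlinear least squares of a Gaussian (moment-based
start, capped iterations); the score is the Pearson correlation between
fitted and observed intensities with a correlation-test p-value at n − 1
degrees of freedom.  A non-convergent or degenerate fit scores (0, 1).
Features are Gaussian at cor ≥ 0.9 and p ≤ 0.05 — both thresholds
inclusive.

## Grouping, alignment and quality scores

Peaks are grouped across samples within m/z slices of width
max(`mzdiff`, 2·ppm·m/z) by kernel density over RT (bandwidth `bw`);
density maxima claim their nearest peaks, at most one per sample (the most
intense wins).  Well-behaved groups — spanning at least `minfrac` of
samples, at least two samples when several exist, without duplicates —
anchor a per-sample LOESS of RT deviation against RT used to align all
peaks.  The retention-time correction score is
`RCS = 1/(1 + mean |post-alignment residual|)` and the grouping score
`GS = good²/(bad + 1)`; both are only ever used after min–max
normalization, so only their orderings matter, and both are monotone in
alignment/grouping quality by construction.

Isotope annotation flags feature A when a feature sits at
A.mz + 1.003355/z (z ∈ {1, 2}) within the ppm tolerance, co-elutes within
3 s, and has an intensity ratio in (0, 0.6] — bounds chosen loose to favor
recall, since reliable-peak inflation is penalized elsewhere by the Quality
Score.  The low-intensity threshold is the mean of the lowest 3% of feature
intensities, computed over grouped features (the "lowest 3% peak intensity"
could also be read over raw centroids; features were chosen as the unit the
rest of the score operates on).

## Parameter optimization

The Quality Score is

    QS = RP^1.5 / (all peaks − LIP) · GR² · QcoE

with QcoE = 0.4·normRCS + 0.4·normGS + 0.2·norm(1 − CV).  CV enters
inverted because a low coefficient of variation across replicates is the
desirable direction.  Normalization ("unit-based") is min–max over the
current design round's evaluations — normalization needs a cohort and the
round is the natural one — and the weighted combination is itself rescaled
to [0, 1] over the round.  When a component's span is degenerate it
contributes neutrally (0.5).  QS is defined as 0 when no peaks are found or
when all peaks ≤ LIP (the formula's denominator would otherwise be
non-positive).

Noise, prefilter and ppm are fixed first from the data: the noise floor at
the density antimode between the two dominant modes of the log₁₀-intensity
kernel density (fallback 3× median with a warning when unimodal), the
prefilter length as the modal consecutive-scan run of above-noise traces
(clamped to [2, 10]), and ppm as the 95th percentile of within-trace
deviations from the intensity-weighted trace mean (floor 1 ppm).

The five remaining factors are searched with a standard five-factor
Box–Behnken design: 40 edge runs (each factor pair at (±1, ±1), all others
at center) plus 6 center replicates.  Decoded points with
peakwidth_min ≥ peakwidth_max are repaired by swapping, with a logged note.
A full quadratic surface (intercept, linear, two-way interactions, squares)
is fitted by least squares; its maximum over the coded cube is located by a
3-level grid (ties broken toward the center, so flat factors stay put)
polished by L-BFGS-B.  The next round recenters on the surface optimum;
factors whose optimum sits on the coded boundary (|coded| > 0.95) have
their range widened by 50%.  The loop stops when the best evaluated QS
improves by less than 5% or after `max_rounds` (default 6; the examples and
acceptance experiments use 2–3 rounds, which is where the synthetic
problems converge).  The returned parameters are the best **evaluated**
point, never the surface prediction, which is robust to a poor quadratic
fit; the starting point is itself evaluated in round 1 so the result can
never fall below it in-round.  Platform starting parameters are this
package's own documented values (Orbitraps tight ppm, TOFs intermediate,
ion traps loose; UPLC peaks narrower than HPLC).

## Batch correction and selection

*ComBat* is the standard parametric empirical-Bayes location/scale
adjustment on the natural-log scale (zeros imputed to half the feature
minimum), with biological groups preserved through covariates.
*EigenMS* removes per-feature group means, standardizes the residual
columns — so per-sample dispersion differences (tight QCs vs spread study
samples) are not mistaken for bias — and removes the leading SVD trends
whose singular values exceed the 95th percentile of 99 row-wise
permutations (seeded), stopping at the first non-significant rank; group
effects are then restored.  *QC-RLSC* fits a LOESS (span 0.75) of each
feature's QC intensities against injection order, interpolates to all
samples with constant extrapolation, and divides by the fitted curve over
the median QC intensity (factors floored at 0.05; features with fewer than
3 finite QC values are left uncorrected and counted).

The **gradient length** that chooses the ordination is the first
correspondence-analysis axis in Hill-style SD units: sample positions are
weighted averages of species scores (which carries the eigenvalue
shrinkage) and the SD unit is the mean within-sample dispersion of species
scores.  This reproduces the reference DCA implementation closely on test
constructions (compact data ≈0.14 vs 0.13; unimodal turnover ≈8.6 vs 8.9)
without the segment-wise nonlinear rescaling, which only matters for axes
beyond the first.  Above 3 SD the evaluation uses PCA on the standardized
log matrix; otherwise CCA constrained on batch membership.

The **evaluation score** (lower is better) is a batch term plus a QC term,
both in units of the pooled within-batch score dispersion — normalizing by
total dispersion would let the batch effect inflate the denominator and
mask its own term.  The batch term is measured *above its no-effect
expectation*: for PCA, the standard-error floor of centroid separation; for
CCA, the mean constrained-inertia fraction over 20 batch-label permutations
(a constrained ordination separates any labels it is given, so the raw
fraction is meaningless without its null).  The QC term is the mean
distance of QC samples to their centroid.  A corrective method must beat
the uncorrected score by 25% to displace "none": an evaluation computed on
the same QC injections a QC-anchored smoother was fitted to concedes that
smoother a structural advantage of roughly its effective degrees of freedom
over the QC count (~20% apparent dispersion reduction for a handful of
QCs), while genuinely planted effects improve the score several-fold.
Ties among corrective methods follow the order eigenms, combat, qc_rlsc.

Only these three correctors are implemented — one per assumption class
(location/scale EB, SVD bias, QC smoothing); other published methods are
external contributions that plug into the same candidate interface.

## Empirical compounds and pathway activity

Ion forms are defined by (multiplier·M + mass shift)/|charge| over a table
of common positive- and negative-mode species; the primary set is M+H,
M+Na, M−H₂O+H, M−H, M−2H, M−H₂O−H, with whitespace/unicode spelling
variants normalized to one canonical name each.  Matching accepts a feature
when its relative m/z deviation from the theoretical value is within the
instrument ppm.

EC construction is three staged lists, all returned for inspection:
(1) per compound, single-linkage clustering over RT with the window as
linkage threshold — the most permissive reading of "within an expected RT
window", appropriate since an EC may contain unresolved isomers; the window
is `rt_tol` if given, else max RT × `rt_frac` (default 0.02);
(2) union–find merging of ECs sharing an identical (m/z, ion form) member
— m/z equality within the ppm tolerance and RT equality within the window,
since exact float equality would never fire;
(3) when primary ions are enforced (default), only ECs containing one are
kept.  Containment |final| ≤ |merged| ≤ |initial| is a tested invariant.

Enrichment maps significant features (p ≤ cutoff) to significant ECs — by
default any member feature suffices; a primary-ion-member-only rule is
available as a flag.  Per pathway the raw p-value is the one-sided
hypergeometric tail with EASE correction (observed hits minus one) on the
EC 2×2 table.  The permutation null redraws the significant feature count
from all features (100 draws by default, seeded), recomputes all per-pathway
EASE scores, and pools −ln p across pathways and permutations.  Because the
null has an atom at score 0 (pathways with ≤1 hit score p = 1), the Gamma
is fitted by maximum likelihood to the positive scores only and the
adjusted p-value is the mixture tail `frac_positive · Γ-sf(score)` (1 at
score 0); fitting through the atom is ill-posed and mis-calibrates.
Per-pathway Gamma fits were rejected as unstable at 100 permutations.

The pooled Gamma smooths the discreteness of the hypergeometric statistic
well only when hit counts are not tiny: the null-calibration check
therefore uses libraries whose pathways map to ≈10–15 ECs each with a ~25%
EC significance rate, where the statistic's support is fine enough for the
continuous approximation.  With very small pathways or sparse significance
the adjusted p-values remain valid but conservative and visibly discrete —
a property of Fisher-type tests, not of the implementation.

## Benchmark metrics

True-peak matching is greedy one-to-one assignment ordered by ppm distance
then RT distance, within 10 ppm and 18 s (0.3 min) tolerances — the
tolerances are fixed by convention, the assignment rule (one feature per
reference, no double counting) is this package's choice and is verified
against brute-force optimal assignment on toys.  Consensus quantification
counts matched references whose observed group-intensity ratio is within
50% relative error of the expected ratio.  Dilution linearity is an OLS
slope test of intensity (areas, not apex heights) against the dilution
factor at α = 0.001, counting positive slopes only; its false-positive rate
is checked against α on null data.  A reliability *index* in the style of
dilution-series benchmarks is not computed (its exact formula lives in
external work); the linear-peak count and fraction are the reported
surrogate.

## Problem sizes

The test and acceptance workloads are sized for a single CPU: synthetic
runs of ~240 one-second scans with 12–25 planted peaks, two runs per
optimization, up to three design rounds; batch tables of 80–150 features by
40–60 samples; enrichment calibration at 200 replicates of ~300-feature
peak lists with 100 permutations each.  These sizes are where the recovery
and calibration behavior stabilizes on the synthetic conditions; all scale
linearly for larger inputs.

## Known limitations

The picker is a centWave-style detector sharing the parameter vector, not a
bit-exact clone of any existing implementation; acceptance is via
planted-truth recovery.  Wavelet multi-scale detection, deconvolution of
co-eluting isomers, and adduct annotation beyond the isotope flag are out
of scope.  RT-free (no-retention-time) enrichment is rejected with an
error rather than emulated.  Vendor raw formats and ion mobility are not
read.  The optimizer's convergence rules (round limit, 5% relative
improvement, 50% boundary expansion) are documented choices; nothing in
the underlying design prescribes them.
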