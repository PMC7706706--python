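# Methods

## Coordinate conventions and formats

Internal coordinates are 1-based closed intervals, the SGD convention
for yeast assemblies; per-base arrays hold position *p* at index
*p* − 1. BED output converts on write (start − 1, end) and back on
read. The wiggle reader accepts variableStep (span = 1) and fixedStep
dialects plus 4-column bedGraph; the writer emits variableStep with
full float precision (`%.17g`), so write→read round-trips are
bit-exact. A `#spo11map-state=` header comment records whether a file
holds raw counts, RPM, or copy-corrected nRPM; files without it are
treated as raw. Maps are strand-collapsed single tracks.

The packaged default assembly is sacCer2 (16 nuclear chromosomes, SGD
lengths and centromere midpoints, rDNA locus chrXII:451,418–468,993).
Mitochondrial and 2-micron sequences are simply absent from the
nuclear assembly; readers skip them silently.

## Normalization model

RPM scales a raw map so its total over nuclear chromosomes is exactly
10⁶, with the rDNA interval zeroed both before totaling and in the
output (repetitive rDNA coverage is not meaningfully mappable).
Copy-number correction multiplies listed chromosomes by a factor —
2/copy_number against the diploid baseline, so a trisomic chromosome
gets 2/3 — and marks the map nRPM. For a chromosome whose homolog is a
diverged (homeologous) partner sequence, two modes exist: SUM adds the
partner chromosome's reads to the native copy and is appropriate for
per-chromosome totals; DOUBLE multiplies the native copy by two and is
the right choice for within-chromosome profiles, where partner
coordinates do not correspond base-by-base.

RPM is zero-sum: if one chromosome genuinely gains breaks, every other
chromosome's RPM drops. Cross-scaling therefore multiplies each of two
maps by one scalar so both totals over the *non-focal* chromosomes
equal their mean ("standard") total; focal-chromosome totals are then
directly comparable. Cross-scaling is symmetric in its arguments and
changes each map only by a single scalar.

A global scale factor (e.g. 1.8 for a synapsis-mutant map whose cells
make globally more Spo11-oligo complexes) is available to move a
relative map onto an absolute-DSB scale before ratio analyses.

Per-chromosome summary densities divide by the full assembly length of
each chromosome (not length minus masked rDNA); totals are reported
both in map units and as thousandths (kRPM).

## Hot-spot calling

The map is smoothed with a normalized Hann window
w_k ∝ (1 − cos(2πk/(W−1)))/2, default W = 201 bp. At chromosome ends
the window is truncated to in-bounds positions and re-normalized, so a
constant map is preserved exactly everywhere. (W = 3 degenerates to
the identity, which the tests exploit for exact boundary reasoning.)

Candidates are maximal runs of bases whose smoothed density is
*strictly greater* than the threshold: by default 2.3× the map's
included total divided by the included genome length, or a fixed
density (0.193 RPM/bp reproduces the published sacCer2 threshold; the
effective genome length behind that constant is not recoverable
exactly, so the fold rule is the default). Runs separated by ≤ 200 bp
merge, transitively — a chain of sub-threshold gaps each ≤ 200 bp
collapses into one call. Calls narrower than 25 bp **or** containing
less than 10 units of summed *unsmoothed* signal are then removed (the
stricter of the two readings of the width/total filter; hot-spot
strength is always the raw within-boundary sum, not the smoothed one).
The caller is fully deterministic and is verified against a per-base
brute-force oracle (scan, label runs, merge pairwise to fixed point,
filter) on a thousand random maps.

Two hot-spot sets are compared by ≥ 1-bp interval intersection;
because intersections can be many-to-one, shared counts are reported
from each side. Per-hotspot fold changes between two comparably scaled
maps are ratios of within-boundary sums; hot spots with a zero
denominator are flagged rather than silently dropped. The trend line
is a tricube-weighted local regression (lowess) over hotspot midpoints
per chromosome, span 0.5 by default (the published analyses do not
state a span).

## Chromosomal domains

Intervals are classified by midpoint — hot spots are far narrower than
any domain, so straddling is immaterial. Tel is within 20 kb of a
chromosome end; Cen within 10 kb of the centromere midpoint; rDNA from
60 kb left of the annotated rDNA locus to 30 kb right of it; EAR (only
under the EAR scheme) is (20 kb, 110 kb] from the nearer telomere, so
the 20-kb boundary itself belongs to Tel and Tel/EAR are disjoint.
Precedence is Tel > EAR > Cen > rDNA > interstitial; the Tel/Cen
collision can only occur on very short arms. Domain-level fold-change
summaries use linear-interpolation quartiles and Tukey whiskers (most
extreme points within 1.5 × IQR of the box). The size–density
relationship is a plain Pearson correlation of chromosome length
against break density, with optional exclusion of named (e.g. focal
aneuploid) chromosomes; constant input is an error, not r = 0.

## Kinetics

The observed broken fraction f = broken/(broken + parental) from gel
quantification understates break numbers when a chromatid breaks more
than once; under a Poisson model the mean break count is
λ = −ln(1 − f), the rate whose zero class has probability 1 − f
(implemented with log1p/expm1, round-trip exact to 1e−12).

DSB timing is fitted with y = a + b·exp{−[log(x+1) − c]²/d²} (natural
log), a pinned to the 0-h measurement, (b, c, d) by bounded least
squares from a deterministic start grid (b₀ = max − a, c₀ centered on
the argmax, d₀ ∈ {0.3, 0.6, 1.2}, small c perturbations); the lowest
residual sum wins, no randomness. The curve peaks at x = e^c − 1.
Note the model's value at x = 0 is a plus the Gaussian tail, so
pinning a to the 0-h datum leaves a small (≪ 1%) bias on noiseless
model data; recovery tolerances account for it. Time-averaged DSBs are
the trapezoidal integral of the *observed* points (no fitted-curve
integration), optionally after subtracting the 0-h background.

ChIP binding windows are estimated in three stages: (1) the same
log-normal form locates the signal peak — used here purely as a peak
locator, with the background pinned to the earliest sample rather than
requiring a 0-h point, so time-shifted series behave equivariantly;
(2) a 3-parameter logistic L/(1 + e^(−k(t−t₀))) is fitted to the
points up to the peak (always including the sample nearest the peak),
and the association time is its half-maximum time t₀ on the *fitted*
plateau L, not the observed maximum; (3) the mirror fit on the falling
side gives the dissociation time. Binding duration is their
difference; a slope with fewer than three samples is an error naming
the slope, and a half-maximum landing beyond the peak (degenerate
slope) is clipped to the peak so the window always brackets it.

## Multivariate map comparison

Each map reduces to its 16-vector (or toy-genome vector) of
per-chromosome included totals. PCA is computed on the column-centered
matrix **without** unit-variance scaling (covariance PCA, matching
R's `princomp` convention); this matters — correlation PCA would
change variance fractions. Signs are fixed by making each component's
largest-magnitude loading positive. Clustering is agglomerative on
Euclidean distances under the Ward D2 criterion (SciPy's `ward`
linkage on observations), with SciPy's deterministic lowest-index tie
breaking; a Newick serializer is provided for the dendrogram.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline assumes,
not the sequencing process: no reads, no mappability, no replication
of fine-scale chromatin structure. Defaults are chosen as study-like
conditions: 0.3 hot spots per kb (the genome-wide rate of called hot
spots in S. cerevisiae, ~3,600 over 12 Mb), widths uniform on
50–500 bp placed without overlap, intensities i.i.d. gamma with shape
0.6 (a heavy right tail like observed hot-spot strength spectra), 15%
of reads as uniform background, 10⁶ reads per time point.

Reads are drawn multinomially from a per-base weight vector: the
background share spread uniformly, and the hot-spot share split across
chromosomes **proportional to chromosome length**, then within each
chromosome proportional to intensity with a triangular within-hotspot
profile. The per-chromosome split is a deliberate design choice: with
a single global intensity normalization, heavy-tailed intensity draws
make equal-length chromosomes receive visibly unequal expected totals,
which would confound copy-number and focal-boost recovery; with the
split, expected chromosome totals are exactly proportional to
length × (copy_number/2) × focal fold, so scheduled effects are exact
in expectation and deviations are pure multinomial noise. A
chromosome that happens to receive no hot spots spreads its hot-spot
share uniformly. Domain modulation factors multiply individual
hot-spot weights after the split.

Everything is a pure function of (scenario, seed): generators derive
independent streams from the seed plus fixed stream tags, and repeat
calls are bit-identical. Time courses add Gaussian noise to the exact
kinetic forms (log-normal for PFGE; product of rising and falling
logistics for ChIP) and floor at zero to respect the measurement
domain.

What passing tests on synthetic data do and do not show: they
establish that the *pipeline* recovers planted structure (folds,
domains, timing, windows) at realistic noise and sampling depth; they
do not validate assumptions about real chromatin (mappability bias,
non-uniform background, inter-replicate variability), which enter real
analyses upstream of this package.

## Problem sizes and numerical choices

The test suite and acceptance script run the synthetic experiments at
10⁶ reads per time point on a 3.1-Mb four-chromosome toy genome, 200
replicates for noisy-fit recovery, and 300–1,000 random maps for
oracle agreement — sizes chosen so the whole suite completes in a
couple of minutes while leaving multinomial standard errors far below
the effects being recovered. Curve fits use `scipy.optimize.
least_squares` (trust-region reflective) with bounds b ≥ 0,
d ∈ (10⁻⁶, 50], k ∈ [10⁻³, 10³]; degenerate flat series fit cleanly
to b ≈ 0. All acceptance-style recovery checks use fixed seeds and
3-standard-error bands derived from the sampling model, not tuned
constants.

## Known limitations

- No mappability, GC, or chromatin covariate correction; maps are
  taken as curated.
- The fixed 0.193 RPM/bp threshold is provided for parity but the
  fold-over-mean rule is the default; the two differ when a map's
  average density differs from the original calibration.
- SUM-mode homeolog correction assumes the partner map is already on
  the same read scale; it adds per-base values up to the shorter
  chromosome length and is only meaningful for totals.
- The ChIP peak locator assumes a unimodal profile; bimodal binding
  profiles will produce a single compromise window.
- Loess trend lines near chromosome ends have one-sided windows and
  inherit the usual edge variance of local regression.
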