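# Methods

## The copy-number model

An HU-arrested S-phase sample has copy number ~2 in the replicated
neighborhood of each fired origin and ~1 elsewhere.  With both samples
normalized to genome mean 1, the mean-1 S track underestimates true copy
number by the factor (1 + *n*), where *n* is the replicated fraction of the
genome; the combination

R = S × (1 + n) − G2 + 1

restores S to copy-number scale, subtracts the library/mappability bias shared
with G2, and re-centers the baseline at 1.  *n* is interpreted as a fraction
(0.10 for 10%): this is the only reading under which mean-1 inputs give a
baseline-1 profile, i.e. under which the formula is dimensionally coherent.
On synthetic data *n* is computed from the planted intensity (its genome mean
minus 1), playing the role flow cytometry plays for real samples; a measured
value can be supplied instead.

Binning uses a 200-bp window stepped every 20 bp after extending each read
100 bp in the 3′ direction (sequenced fragments average ~200 bp, so the
extended read approximates the fragment).  A bin counts every extended read
whose interval overlaps its window — the overlap-count reading of a "sliding
window", robust at window edges, rather than midpoint assignment.  Exclusion
intervals (assembly artifacts, collapsed repeats) are masked *before*
normalization, so anomalous regions cannot distort the genome mean; masked
bins keep their raw values but are ignored by every statistic.

LOESS smoothing is degree-1 locally weighted regression with tricube weights
(statsmodels `lowess`, no robustness iterations).  The span is a per-dataset
choice; because the natural smoothing scale is physical, the default is
expressed as a 3,000-bp local window and converted to a per-chromosome
fraction.  An interpolation `delta` of 2% of the local window keeps the cost
near-linear without visibly quantizing peak apexes (at 10% the apex snaps to
interpolation anchors, which measurably degrades peak localization).

## Peak calling

The initial scan finds downward zero crossings of the moving-average-smoothed
first difference (smoothing width `SmoothW` bins; per-species presets 58/50/10
with amplitude threshold 1 and slope threshold 0), localizing each candidate
with a least-squares quadratic over `FitW` bins.  `SmoothW`/`FitW` are read as
bin counts, since the scan operates on sampled profile points.  Candidates are
refined to the maximum of R within ±500 bp, candidates above the anomaly
cutoff (3, or 10 for the GC-rich-genome preset; presumed unannotated repeats)
are discarded, and duplicates collapse.

The template is a unit-height Gaussian fitted (amplitude/sigma/baseline
nonlinear least squares) to the central half of the candidate-averaged peak
profile.  Only confident candidates (height above the 1.30 peak threshold)
enter the average, and their quadratic-fit positions are used for alignment:
apex-aligned (argmax) averaging superimposes a sharp selection spike at offset
zero that a Gaussian fit will otherwise latch onto.

Template fitting is greedy subtract-and-iterate.  At each step the candidate
with the greatest residual height at its apex is taken; the template is scaled
to that height, anchored at the apex, slid within ±250 bp for maximal Pearson
correlation with the residual, then its height is grid-searched in 0.01 steps
over [0.5×, 1.5×] the anchor height for minimal RMSD.  Correlation and RMSD
are evaluated only over bins where the residual is within 60% of the data
peak's maximum, which keeps baseline noise and neighboring-peak flanks out of
the fit; the height range is a package choice (the grid step is the published
constant, the range is not).  The fitted template (the RMSD-optimal one) is
subtracted from the residual and the iteration ends when no candidate's
residual height exceeds the 1.30 threshold — a value derived on real data as
~2 SD of the G2-vs-G2 difference noise, exposed as configuration here.
Tie-breaks: equal correlations resolve to the smaller slide magnitude, then
leftmost; equal RMSDs to the smaller height.  An iteration cap of 10× the
candidate count guarantees halting on adversarial input.  By construction the
original profile equals the final residual plus the sum of subtracted
templates, exactly.

The symmetric template is what makes the caller robust to "notched" peaks
(bubble-shaped replication intermediates lost during library preparation
hollow out the apex): the correlation step re-centers the template even when
the refined candidate sits on a notch shoulder.  The residual positional error
is bounded by the shoulder offset minus the 250-bp slide range, which on the
default synthetic conditions leaves template fitting ~150–200 bp more accurate
than a naive local argmax.

## Validation

Distance buckets for validated origins are: interval overlap (or distance 0),
under 1 kb, 1–2.5 kb, and none (≥2.5 kb).  Overlap enrichment uses a
Monte-Carlo permutation: the test peaks are re-placed uniformly (chromosome
chosen proportional to length) and the count of validation loci within the
matching distance is recomputed; p = (1 + #{null ≥ observed})/(1 + N).  The
+1 correction makes the p-value valid at any N; its floor is 1/(N+1).  The
resolution scan evaluates this p on a grid of matching distances and reports
the most significant; where several distances sit at the attainable floor the
permutation z-score (observed − null mean)/null SD breaks the tie, then the
smaller distance.  Peak-set comparison matches two point sets within a
distance by the sorted two-pointer sweep, which is maximum-cardinality for
threshold matching on a line; ties resolve leftmost.

## Sequence features and SVM

Positive loci are the intergenic portions of peak ± 1 kb windows, with
windows of peaks closer than 2 kb merged and counted once.  Backgrounds are
equally many random windows with identical intergenic masking, rejected if
within 8 kb of any sub-threshold peak so that weak origins below the calling
threshold do not contaminate the negatives.  Loci whose intergenic portion is
under 100 bp are dropped and counted.

The k-mer space collapses each k-mer with its reverse complement
(canonical = lexicographically smaller), giving 4^k/2 classes for odd k and
(4^k + 4^{k/2})/2 for even k: {2, 10, 32, 136, 512, 2080} for k = 1..6,
2,772 classes total.  Frequencies are counts over the L − k + 1 windows
(windows containing N are skipped; the denominator is not adjusted) and the
full vector is scaled to unit Euclidean norm per sequence — the per-sequence
reading of "2-norm normalized"; the per-feature alternative would be absorbed
by the SVM anyway for all but the motif columns, whose rescaling (below)
pins down the intended coupling.

Motif features are cumulative PWM scores: the sum over both strands and all
positions of the positive part of the log2 odds of the window under the motif
versus the background — a transparent cumulative scoring rule in place of a
full motif-enrichment program, which is outside this package's scope.  Each
motif column is affine-rescaled to the pooled mean and SD of the k-mer
entries so both feature kinds are commensurate under a linear kernel.

The SVM is a linear-kernel SVC with C = 1 (exposed), evaluated by stratified
5-fold cross-validation with held-out decision scores pooled before the auROC
is computed.  auROC is computed in rank form with midranks, equal to
P(score⁺ > score⁻) + ½P(tie).  Single-feature auROCs are reported as-is:
values below 0.5 mark features depleted at origins (auROC(x) + auROC(−x) = 1).

## Nucleosome analysis

Mononucleosome reads are extended to 147 bp (nucleosomal DNA) from the 5′
end, binned like the replication data, and normalized to genome mean exactly
1.  NFRs are maximal runs of bins below 0.5× the mean, merged across gaps of
at most one bin, kept at width ≥ 125 bp; threshold, gap, and width are
configuration since the upstream protocol's exact criteria are external to
this package.  Origin-proximal NFRs are the NFRs nearest each peak
(point-to-interval distance, leftmost on ties).  The depletion statistic is
the mean occupancy within ±200 bp of the NFR centers of the aggregate
profile — "average occupancy" needs a window, and ±200 bp covers the NFR body
at promoter scale.  The permutation draws an equal number of uniform
coordinates per iteration, takes their nearest NFRs, and reports p = n/N with
n the iterations at least as depleted; p = 0 is reported with a floor note of
< 1/N.  Motif-occupancy profiles aggregate log2 occupancy over
instance-centered windows, strand-oriented when strands are supplied, split
at 1 kb from the nearest peak into proximal and distal sets.

## The synthetic-data generator

The generator emulates the data-generating process the analysis assumes, not
any particular genome.  Chromosomes alternate intergenes (0.8–2.5 kb) and
genes sized to a target genic fraction (default 0.6).  Background composition
is 60% AT in polyA mode and 45% AT in GC-motif mode — fixture parameters
loosely mirroring AT-rich vs GC-rich genomes, not measurements.  Origins
occupy intergene centers, evenly spread, pairwise ≥ 4σ apart (well-posed
recovery); each origin core (±500 bp) is overwritten with species-style
content: six 8–15-bp polyA/polyT tracts in polyA mode; a polyG/polyC run, two
Sap1-like sites (a synthetic 10-bp GC-rich consensus), and a tandem CTCGCT
repeat in GC-motif mode — every GC-mode origin carries all three kinds, the
generator's deliberately clean version of "most origins carry at least one".

S-phase read starts follow 1 + Σᵢ hᵢ exp(−(x−μᵢ)²/2σ²), with σ = 2 kb
(~10-kb peaks at the base) and heights h ∈ [0.5, 1.5] (R-scale peaks
1.5–2.5).  The notch artifact is a multiplicative central Gaussian dip
(depth 0.3, width 2 kb by default): only "a centered dip" is constrained by
the phenomenon, and a Gaussian is smooth and differentiable.  Note the dip
depresses the apex relative to the notch shoulders at ±width/2, not relative
to ±σ — no depth below 1 − e^{−1/2} ≈ 0.39 can do the latter.  G2 starts are
uniform.  Default depth is 2.5 M reads per 3-Mb sample: ~290 reads per 200-bp
window, the same per-window sampling as >200-fold-coverage real experiments.
Read counts are exact (multinomial across chromosomes, inverse-CDF within).

Nucleosome intensity is a phased cosine (165-bp repeat, amplitude 0.4)
multiplied by near-zero dips at NFRs: origin NFRs 300 bp wide at depth 0.95,
non-origin NFRs 200 bp at 0.80 — deeper and broader at origins, as observed
in vivo.  Non-origin NFRs occupy 25% of non-origin intergenes, making origin
NFRs a small minority genome-wide (the regime in which "nearest NFR to a
random coordinate" is a meaningful null).

One global seed drives named substreams per stage, so a fixed seed reproduces
FASTA/BED output byte-for-byte.

What the generator does **not** model: sequencing error, mappability and
GC-bias, paired ends, fragment-length variation, replication-timing gradients,
heterogeneous arrest, or correlated noise.  Passing tests therefore
demonstrate the correctness and calibration of the algorithms under the
stated statistical assumptions — not performance on real libraries, where
bias correction and masking carry more weight.

## Problem sizes and calibration checks

The shipped tests and the acceptance script use desk-scale conditions chosen
as the package's defaults: a 3-Mb chromosome with 20 notched origins for peak
recovery; 200 positive + 200 background loci for sequence models; a 1-Mb
genome with 8 origins and ~60 NFRs for nucleosome analysis; 100–200 trials
with 199–999 permutations for p-value calibration.  The permutation
uniformity check uses a matching distance near 50% hit probability, where the
discrete count statistic has maximal spread — at much smaller distances the
statistic's ties make any exact-uniformity test fail by discreteness alone,
which is a property of count-based permutation p-values, not a defect.

## Known limitations

* Strongly overlapping origins (closer than ~2σ) merge into one candidate;
  the greedy subtraction cannot split a unimodal sum.
* The ±250-bp slide bounds how far a notch-displaced anchor can be corrected;
  very wide, deep notches leave a residual positional bias.
* The CLOVER-style cumulative motif score is a documented stand-in for the
  original enrichment score; absolute motif-column values are not comparable
  to other implementations, though rankings are stable.
* NFR calling on shallow nucleosome coverage (< ~30× fragments) is noisy;
  the 0.5× threshold assumes the occupancy track's Poisson CV is well below
  0.5.
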