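# Methods

## Selection model

One round of selection is modeled as multinomial resampling of the pool.
A molecule of unique sequence s is captured with probability proportional
to a linear mixture of a specific and a nonspecific term,

    p(s) ∝ (1 − β)·c(s)·w(s)/Σ c·w + β·c(s)/Σ c,

with c(s) the current abundance, β ∈ [0, 1] the nonspecific carry-over
fraction, and w(s) the ground-truth affinity of the random region. This is
the per-molecule reading of affinity capture: each copy competes with
weight (1 − β)·w/W̄ + β, W̄ the abundance-weighted mean affinity. β = 1
reduces to pure resampling (frequencies preserved in expectation); β = 0 is
deterministic relative selection. PCR amplification bias, sequencing error
and RNA secondary structure are deliberately not modeled: they are not
needed to exercise any downstream analysis, and a structure model would add
parameters that nothing in the pipeline could check.

`AffinityModel` assigns a nonnegative weight to every k-mer window and
aggregates over the sliding windows of the random region with either the
best window (`max_window`, default — occupancy dominated by the single best
site) or the window sum (`sum_windows`, multi-site binding). The default
ground truth is w(m) = 10^(#A in m) over 10-mer windows. The factor of 10
per adenosine is intentionally steep: the modeled protein requires on the
order of 11–12 consecutive adenosines for high-affinity binding, so the
affinity gap between an 8-A and a 12-A site spans orders of magnitude. A
shallower ground truth (e.g. 3× per A) makes the desk-scale experiment
unidentifiable — near-homopolymer jackpot clones overtake the true optimum
within five rounds.

### Study conditions

Defaults of `SelectionSimConfig`: randomized 20-mer, five rounds, pool of
10^6 molecules, 10^5 reads sequenced per round, β = 0.2, fixed constant
flanks, constant FASTQ quality (qualities are never used downstream). The
pool is intentionally an order of magnitude deeper than the sequencing
depth: a random 20-mer library of 10^6 molecules contains ~8 distinct
clones with a perfect A10 run, enough for several to survive round-1
sampling so that the homopolymer 10-mer accumulates counts across clones.
At 5×10^5 and below, selection regularly fixates on a single A10 clone,
whose homopolymer window count then ties with its clone-specific flank
k-mers — a finite-library artifact, not a property of the analysis. Real
selections start from ~10^13–10^14 molecules and do not sit in this regime;
the pool size is the smallest that escapes it at desk scale.

## Enrichment landscapes

Counts: every overlapping k-mer window of every retained random region,
stored densely (vector indexed by base-4 code; A=0 < C < G < U, so code
order is lexicographic order). Enrichment is the pseudocounted frequency
ratio of a selected round over a reference, pseudocount 0.5 (Jeffreys-style
stabilization of unobserved k-mers). Ranking is by descending enrichment
with lexicographic tie-break, a deterministic total order.

Reference choice: the sequenced round-0 library is the natural reference,
but it only estimates input frequencies when its depth covers the 4^k
universe. `selection_landscape` uses round 0 when the table holds at least
ten windows per k-mer on average, and otherwise substitutes the analytically
uniform input frequency 4^-k — the randomized library is uniform by
construction, and a 10^5-read sample of a 10^6-strong 10-mer universe
(expected count ≈ 1) contributes only shot noise to the denominator. For
k ≤ 8 at the default depth the round-0 reference is used.

Replicate reproducibility is Pearson's r on log10 enrichment restricted to
the union of each replicate's `top_n` most abundant k-mers (`top_n` caps at
120,000). The package measures it on single-round landscapes at k = 6:
after one round the pool is still diverse and the landscape reflects the
systematic affinity signal, which is the regime in which quantitative
enrichment is comparable across replicates (single-round protocols are
standard for quantitative specificity mapping for the same reason). By
round five, desk-scale pools are clone-dominated and the landscape beyond
the planted signal is jackpot-specific, which genuinely lowers replicate
correlation. At k ≤ 8 the default `top_n` covers the whole k-mer universe,
which matters for the no-selection control: restricting to the union of
top-abundance sets of two *independent* sparse samples conditions on
"present in at least one replicate" and produces a strong negative
correlation by construction; covering the universe removes that selection
effect, and the control then sits near r = 0 as it should.

## Motif model and logo

The position frequency matrix is the weight-normalized per-position base
tally of the top k-mers; log-odds are log2(PFM/background) with a tiny
additive pseudocount (1e-9) so single-k-mer models stay finite. Background
defaults to uniform. The logo weights the top 300 k-mers equally
(enrichment-weighting is available); per-position information content is
(2 − H) bits, without small-sample correction (negligible at n = 300).

Two scoring modes: `max_window_logodds` (continuous, for ROC work) and
`hit_count` (number of windows matching a top k-mer, for positional
analyses). The occupancy classifier is a pair of pseudocounted
class-conditional k-mer frequency models; a sequence's score is its mean
per-window log-likelihood ratio, which is length-invariant and antisymmetric
under class swap.

## Occupancy validation

Positives are windows of length 50 centered on a nominal crosslink site
with a planted motif (default A12, jitter ±5 around the center); negatives
are per-sequence composition-matched shuffles of the positives
(mononucleotide order-0 by default; an Eulerian-path dinucleotide shuffle,
Altschul–Erickson construction, preserves dinucleotide multisets exactly
for order-1 controls). Matching on composition is the point: it forces the
classifier to read the *arrangement* of the planted site, not raw base
content.

Cross-validation is stratified 10-fold; each fold's ROC is interpolated
onto a fixed 101-point FPR grid as a step function and the fold TPRs are
vertically averaged; the summary AUC is the trapezoid of the mean curve.
Mann–Whitney uses midranks; exact p-values are computed by the classic
count recursion when both groups have ≤ 8 tie-free observations (≤ 12,870
arrangements) and the normal approximation with tie and continuity
corrections otherwise. Two-sided exact p is twice the smaller tail, capped
at 1.

The positional-density profile counts, per offset from the center, the
fraction of sequences with a top-k-mer hit starting there. Note that a
self-overlapping motif (such as A12 against an A-containing background)
produces hits at small negative offsets whenever flanking background bases
extend the run; a delta profile at offset 0 is expected only for motifs
whose shifts cannot match.

## Curve fitting

Binding: hyperbolic single-site saturation with fitted floor and ceiling,
valid in the no-depletion regime (probe ≪ K_d; the default probe context is
0.5 nM against hundreds of nM). Multi-start nonlinear least squares over a
geometric K_d grid spanning the concentration range; stderr from the local
curvature, with an optional residual bootstrap. A quadratic
ligand-depletion variant is available (`depletion=True`). Concentrations
are nanomolar throughout.

Decay: y = y0·2^(−t/t½), seeded by log-linear regression and refined by
nonlinear least squares; the seed solution is kept if refinement does not
reduce the residual sum, so the fit never does worse than the seed. If no
observation falls below 90% of the initial intensity, the half-life is not
identifiable inside the observation window and the result is a censored
lower bound (t½ > max t) rather than an estimate — the "stabilized oligo"
case where decay is too slow to measure on a 24 h grid.

Simulated noise is Gaussian, either additive (default) or proportional
(noise_sd as coefficient of variation). The decay-recovery protocol uses
proportional 5% noise with triplicates on the 7-point 0–24 h grid:
intensity readouts from gel quantification scale their error with signal,
and on this short grid relative to an 18 h half-life the additive reading
of "5% noise" makes the half-life unidentifiable below ~5% median error for
any estimator (the Cramér–Rao bound for the design is ≈8% sd). The
K_d-recovery protocol uses additive noise at 2% of the anisotropy dynamic
range, 12 concentrations from 10 to 3000 nM, triplicate.

## Imaging

M1 = Σ A over pixels where both channels exceed their thresholds / Σ A over
pixels above the A threshold, in [0, 1]. CTCF = integrated ROI density −
ROI area × mean of background-ROI means (multiple background ROIs are
averaged). ICA = Σ over the ROI of (A − Ā)(B − B̄); the per-ROI percentage
summary reports the share of ROIs with positive score — one defensible
reading of an ambiguous convention, flagged here. Thresholds are explicit
arguments; an Otsu automatic option is provided rather than deferring to a
GUI plugin. The synthetic two-channel fixture places objects with an exact
constructed overlap fraction, so M1 has a pixel-count ground truth.

## What the generators do and do not emulate

Generators reproduce the *structure* of each assay — round-over-round
enrichment with nonspecific background, composition-confounded occupancy
windows, saturation and decay curves with realistic noise, thresholdable
two-channel images — with known ground truth, which is what the downstream
analyses consume. They do not emulate sequencing error, PCR duplicates,
RNA structure, CLIP-specific biases (crosslink-site nucleotide preference,
read truncation), instrument G-factors, or optical point-spread: passing
tests demonstrate that the analysis chain is correct and well-calibrated on
its own assumptions, not that those assumptions hold for any particular
real dataset.

## Numerical and interface conventions

Alphabet ACGU; T maps to U on input; no reverse-complement scanning
(single-stranded RNA). Coordinates 0-based, half-open; window centers at
floor(L/2). All generators are pure functions of their configuration
including the seed. Ranking ties break lexicographically. ROC curves start
at (0,0) and end at (1,1); tied scores collapse to single (diagonal)
segments, which is what makes the trapezoidal AUC equal the normalized
Mann–Whitney U. The analysis scripts and library functions are the
interface; the package ships no separate command-line executable.

## Known limitations

- Desk-scale pools drift: quantitative landscape statistics beyond the
  planted signal are clone-dominated after a few rounds, which is why
  reproducibility is assessed on single-round landscapes.
- The likelihood classifier is bag-of-k-mers; it cannot represent gapped or
  bipartite motifs, and cross-validation partitions sequences, not genomic
  regions, so it does not guard against region-level leakage in real CLIP
  data.
- The binding fit assumes equilibrium, a single site class, and no
  depletion unless the quadratic variant is requested; the decay fit is
  single-exponential.
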