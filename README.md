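# seqrs-kit

Specificity landscapes for RNA-binding proteins, end to end on synthetic
ground truth: simulation of iterative in vitro selection of a randomized RNA
library, k-mer enrichment analysis and replicate reproducibility, motif
models and sequence logos, cross-validated ROC evaluation of predicted
occupancy, equilibrium binding and RNA-stability curve fits, and the three
standard imaging quantification formulas.

The motivating biology is the poly(A)-binding protein (PABP), which binds
adenosine-rich RNA and couples the poly(A) tail to the cap-bound initiation
machinery. A selection experiment (SELEX-style: bind, wash, amplify,
sequence each round) against such a protein should recover an
adenosine-homopolymer-preferring landscape; a motif model built from the top
enriched k-mers should discriminate genuine occupancy windows from
composition-matched controls; and a candidate high-affinity ligand is
characterized by its dissociation constant and serum stability. The package
lets you run that entire analysis chain at desk scale, with every input
simulated under known ground truth so each stage's answer can be checked.

Intended users: computational biologists building or sanity-checking
in-vitro-selection analysis pipelines, and method developers who need a
fully controlled synthetic benchmark for motif-recovery and
occupancy-classification code.

## Models and statistics

**Selection.** A pool of molecules (randomized region of length 20 between
constant primer flanks) is resampled each round by a multinomial whose
probabilities mix affinity and nonspecific carry-over:

    p(s) ∝ (1 − β) · c(s)·w(s) / Σ c·w  +  β · c(s) / Σ c

where c(s) is the molecule's abundance, w(s) aggregates a ground-truth
window affinity over the random region (best window by default), and β is
the nonspecific fraction. The default ground truth is steeply
adenosine-preferring: w(m) = 10^(#A in m) per 10-mer window.

**Enrichment.** For k-mer m with counts c_sel, c_ref and total windows
T_sel, T_ref, the pseudocounted frequency ratio is

    E(m) = [(c_sel(m)+p)/(T_sel+p·4^k)] / [(c_ref(m)+p)/(T_ref+p·4^k)],  p = 0.5.

Against the analytically uniform input library the reference frequency is
4^-k. Replicate agreement is Pearson's r on log10 enrichment over the union
of each replicate's most abundant k-mers.

**Motif model.** From the top-ranked k-mers: a weighted position frequency
matrix, log2 odds against background, and an information-content logo
(IC_j = 2 − H_j bits). Occupancy scoring uses a class-conditional k-mer
likelihood model; a sequence's score is its mean per-window log-likelihood
ratio.

**Validation.** Mann–Whitney U with exact enumeration for small tie-free
groups (normal approximation with tie and continuity corrections
otherwise); ROC curves swept over unique scores with tied scores
contributing diagonal segments, so the trapezoidal AUC equals
(concordant + 0.5·tied)/(n1·n2); stratified 10-fold cross-validation with
fold ROC curves vertically averaged on a fixed 101-point FPR grid.

**Curves.** Binding: y = A_free + (A_bound − A_free)·P/(K_d + P) by
nonlinear least squares with multi-start initialization (quadratic
ligand-depletion variant behind a flag). Stability: y = y0·2^(−t/t½) with a
log-linear seed; series that never drop below 90% of the initial intensity
are reported as censored lower bounds (t½ > max t), not point estimates.

**Imaging.** Manders' M1 (thresholded overlap), corrected total cell
fluorescence (integrated ROI density − area × mean background), intensity
correlation analysis (sum of centered cross-channel products), and
percent-of-control normalization.

## Worked example

```sh
python analysis/01_simulate_selection.py 1     # writes results/selection/
python analysis/02_enrichment_landscape.py
python analysis/03_motif_and_logo.py
```

prints

```
round 0: 100000 reads retained, 0 discarded
round 5: 100000 reads retained, 0 discarded
top enriched 10-mer: AAAAAAAAAA (enrichment 88371.1)
per-position dominant base: AAAAAAAAAA
per-position information content (bits): 0.40 0.52 0.60 0.66 0.67 0.68 0.57 0.57 0.50 0.35
```

Five rounds of selection against the A-preferring ground truth drive the
adenosine homopolymer to the top of the 10-mer enrichment landscape
(enrichment is the frequency ratio over the uniform input library), and the
logo built from the top 300 10-mers is A-dominated at every position, with
the information content highest in the middle of the motif where the
planted preference is least diluted by window overlap. The remaining
drivers follow the same pattern:

```sh
python analysis/04_occupancy_validation.py 1   # CV-ROC, rank-sum, positional density
python analysis/05_binding_and_decay.py 1      # K_d and half-life recovery
python analysis/06_replicate_reproducibility.py 1
python analysis/07_image_quantification.py 1
```

typical output lines:

```
10-fold CV mean AUC = 0.998 (fold AUCs 0.990-1.000)
label-permutation null mean AUC = 0.509 over 20 seeds
K_d recovery (true 300 nM): noiseless rel. err 1.16e-14; median rel. err over 100 noisy curves 2.9%
half-life recovery (true 18 h): median rel. err over 100 noisy curves 3.1%
selection replicates: Pearson r mean 0.815 (range 0.793-0.845, 20 pairs)
no-selection controls: |r| mean 0.021 (max 0.055)
```

The motif model trained on planted-motif windows separates them almost
perfectly from their own mononucleotide-shuffled controls (AUC 0.998),
while permuting labels collapses performance to chance — the classifier is
reading the planted signal, not an artifact. Parameter recovery for the
binding and decay fits is well inside the simulated noise level, and the
landscape is reproducible across independent selection replicates but not
across no-selection controls.

## Layout

- `src/seqrs_kit/` — library: `simulate` (generators), `enrichment`
  (k-mer landscapes), `motif` (PFM/logo/likelihood), `validation`
  (rank-sum, ROC, cross-validation, positional density), `curves`
  (binding/decay fits), `imaging` (M1/CTCF/ICA), `protocols` (the study
  protocols the scripts run).
- `analysis/` — numbered narrative drivers writing tables under `results/`.
- `tests/` — pytest suite, including end-to-end property checks.
- `docs/methods.md` — modeling assumptions, parameter choices, limitations.
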