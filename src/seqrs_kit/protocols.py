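"""End-to-end study protocols: the experiments the analysis scripts run.

Each function simulates its inputs with known ground truth, runs the
corresponding pipeline stage, and returns the summary quantities. Problem
sizes are the package's standard desk-scale study conditions (see
docs/methods.md for the rationale behind each choice).
"""

from __future__ import annotations

import numpy as np

from .curves import BindingCurve, DecayCurve, fit_half_life, fit_kd
from .enrichment import (
    count_kmers,
    pool_regions,
    rank_kmers,
    replicate_correlation,
    selection_landscape,
    uniform_enrichment,
)
from .imaging import ctcf, ica_score, manders_m1
from .motif import build_logo
from .simulate import (
    AffinityModel,
    CurveSimConfig,
    LabeledSequenceSet,
    OccupancySimConfig,
    SelectionSimConfig,
    make_matched_negatives,
    run_selection,
    simulate_binding_curve,
    simulate_colocalization_image,
    simulate_decay,
    simulate_occupancy_sites,
)
from .validation import cross_validated_auc, likelihood_trainer, mann_whitney

# ---------------------------------------------------------------------------
# SEQRS landscape

LANDSCAPE_K = 10
LOGO_TOP_N = 300
AFFINITY_FACTOR = 10.0


def default_affinity_model() -> AffinityModel:
    """Ground-truth specificity: steeply adenosine-preferring, w = 10^(#A)
    per 10-mer window, best window per molecule."""
    return AffinityModel.a_preferring(k=LANDSCAPE_K, factor=AFFINITY_FACTOR)


def landscape_recovery(seed: int) -> dict:
    """Full five-round selection at sequencing depth 10^5; rank the 10-mer
    enrichment landscape of the final round and build the top-300 logo."""
    cfg = SelectionSimConfig(seed=seed)
    model = default_affinity_model()
    pools = run_selection(cfg, model)
    t0 = count_kmers(pool_regions(pools[0], cfg.primer_5, cfg.primer_3), LANDSCAPE_K, "round0")
    t5 = count_kmers(pool_regions(pools[-1], cfg.primer_5, cfg.primer_3), LANDSCAPE_K, "round5")
    landscape = selection_landscape(t0, t5)
    ranked = rank_kmers(landscape, LOGO_TOP_N)
    logo = build_logo([m for m, _ in ranked])
    return {
        "config": cfg,
        "landscape": landscape,
        "ranked": ranked,
        "top_kmer": ranked[0][0],
        "logo": logo,
        "dominant_bases": logo.dominant_bases(),
    }


# ---------------------------------------------------------------------------
# replicate reproducibility

REPCORR_K = 6
REPCORR_TOP_N = 120_000


def _single_round_landscape(seed: int, beta: float):
    cfg = SelectionSimConfig(seed=seed, n_rounds=1, nonspecific_fraction=beta)
    pools = run_selection(cfg, default_affinity_model())
    table = count_kmers(
        pool_regions(pools[-1], cfg.primer_5, cfg.primer_3), REPCORR_K, f"r1s{seed}"
    )
    return uniform_enrichment(table)


def replicate_correlation_experiment(seed: int, n_pairs: int = 20) -> dict:
    """Landscape reproducibility after one round of selection.

    Signal arm: pairs of same-model, different-seed selections (β = 0.2).
    Null arm: β = 1 (pure resampling, no selection) pairs. Pearson r on
    log10 enrichment over the top-N most abundant k-mers of either replicate.
    """
    rng = np.random.default_rng(seed)
    base = int(rng.integers(0, 2**28))
    signal, null = [], []
    for i in range(n_pairs):
        a = _single_round_landscape(base + 2 * i, 0.2)
        b = _single_round_landscape(base + 2 * i + 1, 0.2)
        signal.append(replicate_correlation(a, b, top_n=REPCORR_TOP_N))
        a = _single_round_landscape(base + 10_000 + 2 * i, 1.0)
        b = _single_round_landscape(base + 10_001 + 2 * i, 1.0)
        null.append(replicate_correlation(a, b, top_n=REPCORR_TOP_N))
    return {"signal_r": np.array(signal), "null_r": np.array(null)}


# ---------------------------------------------------------------------------
# occupancy validation

OCC_N = 200
OCC_WINDOW = 50
OCC_MOTIF = "A" * 12
OCC_JITTER = 5
OCC_CLASSIFIER_K = 5


def occupancy_set(seed: int, n: int = OCC_N) -> LabeledSequenceSet:
    """Planted-motif positives with per-sequence mononucleotide-matched
    shuffled negatives (exact composition control)."""
    cfg = OccupancySimConfig(
        n_positive=n, n_negative=0, window_len=OCC_WINDOW,
        motif=OCC_MOTIF, plant_offset_jitter=OCC_JITTER, seed=seed,
    )
    pos = simulate_occupancy_sites(cfg)
    negs = make_matched_negatives(pos.sequences, order=0, seed=seed + 7_001)
    seqs = list(pos.sequences) + list(negs)
    labels = np.r_[np.ones(n, int), np.zeros(n, int)]
    centers = np.full(2 * n, OCC_WINDOW // 2, dtype=int)
    return LabeledSequenceSet(seqs, labels, centers)


def occupancy_cv_experiment(seed: int, n_permutations: int = 20) -> dict:
    """10-fold cross-validated ROC on the planted-motif occupancy set, plus
    a label-permutation null over independent seeds."""
    ls = occupancy_set(seed)
    trainer = likelihood_trainer(OCC_CLASSIFIER_K)
    roc = cross_validated_auc(ls, trainer, n_folds=10, seed=seed)
    permuted = []
    for i in range(n_permutations):
        ls_i = occupancy_set(seed + 100 + i)
        rng = np.random.default_rng(seed + 900 + i)
        perm = LabeledSequenceSet(
            ls_i.sequences, rng.permutation(ls_i.labels), ls_i.centers
        )
        permuted.append(cross_validated_auc(perm, trainer, n_folds=10, seed=seed + i).auc)
    return {"roc": roc, "auc": roc.auc, "permuted_aucs": np.array(permuted)}


def occupancy_mann_whitney(seed: int) -> dict:
    """Held-out LLR scores of positives vs matched negatives under the
    rank-sum test (the enrichment-contrast analysis)."""
    train = occupancy_set(seed)
    test = occupancy_set(seed + 50_000)
    scorer = likelihood_trainer(OCC_CLASSIFIER_K)(
        [s for s, l in zip(train.sequences, train.labels) if l == 1],
        [s for s, l in zip(train.sequences, train.labels) if l == 0],
    )
    pos = [scorer(s) for s, l in zip(test.sequences, test.labels) if l == 1]
    neg = [scorer(s) for s, l in zip(test.sequences, test.labels) if l == 0]
    return {"result": mann_whitney(pos, neg, alternative="greater")}


# ---------------------------------------------------------------------------
# curve recovery

KD_TRUE = 300.0  # nM
KD_CONCS = tuple(np.geomspace(10.0, 3000.0, 12))
KD_FLOOR, KD_CEILING = 0.05, 0.25
KD_NOISE_SD = 0.02 * (KD_CEILING - KD_FLOOR)  # 2% of the dynamic range
CURVE_REPLICATES = 3

HALF_LIFE_TRUE = 18.0  # hours
DECAY_GRID = (0.0, 0.5, 1.0, 2.0, 3.0, 6.0, 24.0)
DECAY_CV = 0.05  # 5% proportional intensity noise


def kd_recovery(seed: int, n_curves: int = 100) -> dict:
    noiseless_cfg = CurveSimConfig(
        true_param=KD_TRUE, x_values=KD_CONCS, y_floor=KD_FLOOR,
        y_ceiling=KD_CEILING, noise_sd=0.0, seed=seed,
    )
    x, y = simulate_binding_curve(noiseless_cfg)
    exact = fit_kd(BindingCurve(x, y))
    errs = []
    rng = np.random.default_rng(seed)
    for _ in range(n_curves):
        cfg = CurveSimConfig(
            true_param=KD_TRUE, x_values=KD_CONCS, y_floor=KD_FLOOR,
            y_ceiling=KD_CEILING, noise_sd=KD_NOISE_SD,
            n_replicates=CURVE_REPLICATES, seed=int(rng.integers(0, 2**31)),
        )
        x, y = simulate_binding_curve(cfg)
        fit = fit_kd(BindingCurve(x, y))
        errs.append(abs(fit.param - KD_TRUE) / KD_TRUE)
    return {
        "noiseless_rel_err": abs(exact.param - KD_TRUE) / KD_TRUE,
        "median_rel_err": float(np.median(errs)),
        "rel_errs": np.array(errs),
    }


def half_life_recovery(seed: int, n_curves: int = 100) -> dict:
    errs = []
    rng = np.random.default_rng(seed)
    for _ in range(n_curves):
        cfg = CurveSimConfig(
            true_param=HALF_LIFE_TRUE, x_values=DECAY_GRID, y_ceiling=100.0,
            noise_sd=DECAY_CV, n_replicates=CURVE_REPLICATES,
            noise_model="proportional", seed=int(rng.integers(0, 2**31)),
        )
        t, y = simulate_decay(cfg)
        order = np.argsort(t, kind="stable")
        fit = fit_half_life(DecayCurve(t[order], y[order]))
        errs.append(abs(fit.param - HALF_LIFE_TRUE) / HALF_LIFE_TRUE)
    flat = fit_half_life(
        DecayCurve(np.asarray(DECAY_GRID), np.full(len(DECAY_GRID), 100.0))
    )
    return {
        "median_rel_err": float(np.median(errs)),
        "rel_errs": np.array(errs),
        "flat_fit": flat,
    }


# ---------------------------------------------------------------------------
# composition preservation

def composition_check(seed: int, n: int = 500, length: int = 50) -> dict:
    """Exact mono- and di-nucleotide preservation on random 50-mers."""
    from collections import Counter

    rng = np.random.default_rng(seed)
    seqs = ["".join(rng.choice(list("ACGU"), length)) for _ in range(n)]
    mono = make_matched_negatives(seqs, order=0, seed=seed + 1)
    di = make_matched_negatives(seqs, order=1, seed=seed + 2)
    mono_bad = sum(Counter(a) != Counter(b) for a, b in zip(seqs, mono))
    di_bad = sum(
        Counter(zip(a, a[1:])) != Counter(zip(b, b[1:])) for a, b in zip(seqs, di)
    )
    return {"mono_mismatches": mono_bad, "di_mismatches": di_bad, "n": n}


# ---------------------------------------------------------------------------
# imaging fixtures

def imaging_checks(seed: int, overlap_fraction: float = 0.37) -> dict:
    A, B, _, truth = simulate_colocalization_image(
        overlap_fraction=overlap_fraction, seed=seed
    )
    thr = truth["threshold"]
    m1 = manders_m1(A, B, thr, thr)
    img = np.full((10, 10), 10.0)
    img[0, :10] = 50.0
    roi = np.zeros((10, 10), bool)
    roi[0, :10] = True
    bg = np.zeros((10, 10), bool)
    bg[5, :] = True
    ctcf_val = ctcf(img, roi, [bg])
    a3 = np.array([[1.0, 2, 3], [4, 5, 6], [7, 8, 9]])
    b3 = np.array([[2.0, 1, 4], [3, 6, 5], [9, 7, 8]])
    manual = float(((a3 - a3.mean()) * (b3 - b3.mean())).sum())
    return {
        "m1": m1,
        "m1_truth": truth["m1"],
        "m1_abs_err": abs(m1 - truth["m1"]),
        "ctcf": ctcf_val,
        "ica": ica_score(a3, b3),
        "ica_manual": manual,
    }
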