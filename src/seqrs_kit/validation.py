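"""Model validation against labeled occupancy sequences.

Mann–Whitney rank-sum comparison of positive vs matched-negative scores,
hand-rolled ROC curves with trapezoidal AUC (ties contribute diagonal
segments, so the AUC equals the normalized U statistic), 10-fold
cross-validated ROC averaging on a fixed FPR grid, and positional k-mer
density around crosslink centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from .motif import MotifModel, score_llr, score_sequence, train_likelihood
from .sequences import normalize_rna

EXACT_MW_LIMIT = 8  # exact enumeration when both groups are at most this size


@dataclass
class MannWhitneyResult:
    u_statistic: float
    n1: int
    n2: int
    p_value: float
    method: str  # "exact" | "normal_tie_corrected"
    alternative: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.u_statistic <= self.n1 * self.n2:
            raise ValueError("U outside [0, n1*n2]")


def _exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """counts[u] = number of rank arrangements of n1 vs n2 tie-free values
    with U statistic u.

    Classic recursion on the largest pooled value: f(a,b,u) =
    f(a-1,b,u-b) + f(a,b-1,u) — a group-1 maximum beats all b group-2 values.
    """
    max_u = n1 * n2
    f = np.zeros((n1 + 1, max_u + 1))
    f[:, 0] = 1.0  # b = 0 layer
    for b in range(1, n2 + 1):
        g = np.zeros_like(f)
        g[0, 0] = 1.0
        for a in range(1, n1 + 1):
            g[a] = f[a]
            g[a, b:] += g[a - 1, : max_u + 1 - b]
        f = g
    return f[n1]


def _exact_p(u: float, n1: int, n2: int, alternative: str) -> float:
    counts = _exact_u_counts(n1, n2)
    total = comb(n1 + n2, n1)
    us = np.arange(len(counts))
    p_ge = counts[us >= u - 1e-12].sum() / total
    p_le = counts[us <= u + 1e-12].sum() / total
    if alternative == "greater":
        return float(p_ge)
    if alternative == "less":
        return float(p_le)
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def mann_whitney(scores_pos, scores_neg, alternative: str = "two_sided") -> MannWhitneyResult:
    """Mann–Whitney U with midranks for ties.

    Exact p by enumeration of all C(n1+n2, n1) arrangements when both groups
    have at most 8 values and the pooled data are tie-free; otherwise the
    normal approximation with tie and continuity corrections.
    `alternative="greater"` tests whether the positive group tends larger.
    """
    x = np.asarray(scores_pos, dtype=float)
    y = np.asarray(scores_neg, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    if alternative not in ("two_sided", "greater", "less"):
        raise ValueError("unknown alternative")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = (tie_counts > 1).any()
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical in both groups; p = 1")
        return MannWhitneyResult(u, n1, n2, 1.0, "normal_tie_corrected", alternative)
    if n1 <= EXACT_MW_LIMIT and n2 <= EXACT_MW_LIMIT and not has_ties:
        p = _exact_p(u, n1, n2, alternative)
        return MannWhitneyResult(u, n1, n2, p, "exact", alternative)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
    if alternative == "greater":
        p = stats.norm.sf((u - mu - 0.5) / sigma)
    elif alternative == "less":
        p = stats.norm.cdf((u - mu + 0.5) / sigma)
    else:
        p = 2.0 * stats.norm.sf((abs(u - mu) - 0.5) / sigma)
    return MannWhitneyResult(u, n1, n2, float(min(1.0, max(p, np.nextafter(0, 1)))), "normal_tie_corrected", alternative)


# ---------------------------------------------------------------------------
# folds


def kfold_partition(labels_or_n, n_folds: int = 10, stratified: bool = True, seed: int = 0) -> np.ndarray:
    """Fold assignment (0..n_folds-1) per item; folds are disjoint, exhaustive
    and balanced within one item (and within-class balanced when stratified)."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if np.isscalar(labels_or_n):
        n = int(labels_or_n)
        labels = np.zeros(n, dtype=int)
        stratified = False
    else:
        labels = np.asarray(labels_or_n)
        n = len(labels)
    if n < n_folds:
        raise ValueError("fewer items than folds")
    assign = np.empty(n, dtype=int)
    if stratified:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(n), labels)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(n))
    for fold, (_, test_idx) in enumerate(split):
        assign[test_idx] = fold
    return assign


# ---------------------------------------------------------------------------
# ROC


def roc_curve(scores, labels):
    """(fpr, tpr) swept over unique scores descending; tied scores collapse
    into single segments, i.e. diagonal steps. Curves start at (0,0) and end
    at (1,1)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels length mismatch")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for a ROC curve")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted == 1)
    fp = np.cumsum(y_sorted == 0)
    # keep only the last index of each tied-score block
    last = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    fpr = np.r_[0.0, fp[last] / n_neg]
    tpr = np.r_[0.0, tp[last] / n_pos]
    return fpr, tpr


def trapezoid_auc(fpr, tpr) -> float:
    """Trapezoidal area under a ROC curve."""
    return float(np.trapezoid(np.asarray(tpr, float), np.asarray(fpr, float)))


@dataclass
class RocResult:
    fold_curves: list  # (fpr, tpr) per fold
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    auc: float
    n_folds: int
    seed: int
    fold_aucs: list = field(default_factory=list)
    fold_tprs_on_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC outside [0, 1]")


def _step_interp(fpr, tpr, grid):
    """TPR of the step ROC curve at each grid FPR (last point with fpr <= g)."""
    idx = np.searchsorted(fpr, grid, side="right") - 1
    return tpr[np.clip(idx, 0, len(tpr) - 1)]


def likelihood_trainer(k: int, pseudocount: float = 0.5):
    """Trainer factory for `cross_validated_auc`: class-conditional k-mer
    likelihood models scored by mean log-likelihood ratio."""

    def train(pos_seqs, neg_seqs):
        clf = train_likelihood(pos_seqs, neg_seqs, k, pseudocount)
        return lambda seq: score_llr(clf, seq)

    return train


def cross_validated_auc(
    labeled_set,
    model_trainer,
    n_folds: int = 10,
    fpr_grid=None,
    seed: int = 0,
    stratified: bool = True,
) -> RocResult:
    """K-fold cross-validated ROC: train on 9/10, score the held-out 1/10,
    vertically average fold TPRs on a fixed FPR grid, and integrate the mean
    curve by trapezoids.

    `model_trainer` is either a callable (pos_seqs, neg_seqs) -> scorer, or a
    fixed `MotifModel` (no training; folds then differ only in test points).
    """
    labels = np.asarray(labeled_set.labels, dtype=int)
    if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
        raise ValueError("labeled set must contain both classes")
    grid = np.linspace(0.0, 1.0, 101) if fpr_grid is None else np.asarray(fpr_grid, float)
    assign = kfold_partition(labels, n_folds=n_folds, stratified=stratified, seed=seed)
    if not stratified:
        for fold in range(n_folds):
            if len(np.unique(labels[assign == fold])) < 2:
                warnings.warn("a fold lost a class; falling back to stratified folds")
                assign = kfold_partition(labels, n_folds=n_folds, stratified=True, seed=seed)
                break
    fixed_scorer = None
    if isinstance(model_trainer, MotifModel):
        model = model_trainer
        fixed_scorer = lambda seq: score_sequence(model, seq)  # noqa: E731
    fold_curves, fold_aucs, fold_tprs = [], [], []
    for fold in range(n_folds):
        test = assign == fold
        if fixed_scorer is None:
            train_idx = np.nonzero(~test)[0]
            pos = [labeled_set.sequences[i] for i in train_idx if labels[i] == 1]
            neg = [labeled_set.sequences[i] for i in train_idx if labels[i] == 0]
            scorer = model_trainer(pos, neg)
        else:
            scorer = fixed_scorer
        test_idx = np.nonzero(test)[0]
        scores = np.array([scorer(labeled_set.sequences[i]) for i in test_idx])
        fpr, tpr = roc_curve(scores, labels[test_idx])
        fold_curves.append((fpr, tpr))
        fold_aucs.append(trapezoid_auc(fpr, tpr))
        fold_tprs.append(_step_interp(fpr, tpr, grid))
    fold_tprs = np.asarray(fold_tprs)
    mean_tpr = fold_tprs.mean(axis=0)
    return RocResult(
        fold_curves=fold_curves,
        fpr_grid=grid,
        mean_tpr=mean_tpr,
        auc=trapezoid_auc(grid, mean_tpr),
        n_folds=n_folds,
        seed=seed,
        fold_aucs=fold_aucs,
        fold_tprs_on_grid=fold_tprs,
    )


# ---------------------------------------------------------------------------
# positional density


@dataclass
class PositionalDensity:
    """Per-offset k-mer hit-start frequency around the crosslink center."""

    offsets: np.ndarray
    density: np.ndarray
    cumulative: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.density = np.asarray(self.density, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if (self.density < 0).any():
            raise ValueError("density must be nonnegative")
        if (np.diff(self.cumulative) < -1e-12).any():
            raise ValueError("cumulative must be nondecreasing")


def _density_for(seqs, centers, kmer_set, k, flank) -> PositionalDensity:
    offsets = np.arange(-flank, flank + 1)
    hits = np.zeros(len(offsets))
    for s, c in zip(seqs, centers):
        for i, o in enumerate(offsets):
            start = c + int(o)
            if s[start : start + k] in kmer_set:
                hits[i] += 1
    density = hits / max(len(seqs), 1)
    total = hits.sum()
    cumulative = np.cumsum(hits) / total if total > 0 else np.zeros_like(hits)
    return PositionalDensity(offsets, density, cumulative)


def kmer_positional_density(labeled_set, kmer_set, flank: int) -> dict:
    """Per-class positional density of k-mer hit starts around the center.

    Returns {1: PositionalDensity, 0: PositionalDensity} (classes present
    only). All k-mers in `kmer_set` must share one length.
    """
    kmers = {normalize_rna(m) for m in kmer_set}
    if not kmers:
        raise ValueError("kmer_set must be nonempty")
    ks = {len(m) for m in kmers}
    if len(ks) != 1:
        raise ValueError("kmer_set must contain a single k")
    k = ks.pop()
    L = min(len(s) for s in labeled_set.sequences)
    centers = np.asarray(labeled_set.centers, dtype=int)
    if flank > centers.min() or centers.max() + flank + k > L:
        raise ValueError("flank exceeds the distance from center to sequence edge")
    out = {}
    labels = np.asarray(labeled_set.labels, dtype=int)
    for cls in (1, 0):
        idx = np.nonzero(labels == cls)[0]
        if len(idx) == 0:
            continue
        out[cls] = _density_for(
            [labeled_set.sequences[i] for i in idx], centers[idx], kmers, k, flank
        )
    return out
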