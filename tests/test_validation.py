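"""Mann–Whitney, fold partitions, ROC/AUC, cross-validated ROC, positional
density."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import roc_auc_score

from seqrs_kit import (
    LabeledSequenceSet,
    cross_validated_auc,
    kfold_partition,
    kmer_positional_density,
    likelihood_trainer,
    mann_whitney,
    roc_curve,
    trapezoid_auc,
)
from conftest import occupancy_with_matched_negatives


def enumerate_exact_p(x, y, alternative):
    """Brute-force oracle: every assignment of the pooled ranks to groups."""
    pooled = sorted(x) + sorted(y)
    n1 = len(x)
    values = np.array(sorted(pooled))
    u_obs = sum(1 for a in x for b in y if a > b) + 0.5 * sum(
        1 for a in x for b in y if a == b
    )
    us = []
    for idx in itertools.combinations(range(len(values)), n1):
        grp = set(idx)
        xs = values[list(idx)]
        ys = values[[i for i in range(len(values)) if i not in grp]]
        us.append(sum(1 for a in xs for b in ys if a > b))
    us = np.array(us, dtype=float)
    total = len(us)
    ge = (us >= u_obs - 1e-12).sum() / total
    le = (us <= u_obs + 1e-12).sum() / total
    if alternative == "greater":
        return ge
    if alternative == "less":
        return le
    return min(1.0, 2 * min(ge, le))


class TestMannWhitney:
    def test_identical_groups_midpoint_u(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.u_statistic == pytest.approx(4.5)

    def test_two_vs_two_exact(self):
        res = mann_whitney([1, 2], [3, 4], alternative="less")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / comb(4, 2) / 1.0)  # 1/6

    @pytest.mark.parametrize("alternative", ["two_sided", "greater", "less"])
    def test_exact_matches_enumeration_oracle(self, alternative):
        rng = np.random.default_rng(31)
        for _ in range(30):
            n1, n2 = rng.integers(2, 8, 2)
            x = list(rng.normal(size=n1))
            y = list(rng.normal(size=n2))
            res = mann_whitney(x, y, alternative)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(
                enumerate_exact_p(x, y, alternative), abs=1e-12
            )

    def test_tied_large_samples_match_scipy(self):
        rng = np.random.default_rng(17)
        x = rng.integers(0, 6, 40).astype(float)
        y = rng.integers(1, 7, 35).astype(float)
        res = mann_whitney(x, y, "greater")
        ref = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        assert res.method == "normal_tie_corrected"
        assert res.u_statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_all_identical_values(self):
        with pytest.warns(UserWarning):
            res = mann_whitney([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_value == 1.0

    def test_planted_motif_scores_significant(self, labeled_occupancy):
        scorer = likelihood_trainer(k=5)(
            [s for s, l in zip(labeled_occupancy.sequences, labeled_occupancy.labels) if l == 1][:100],
            [s for s, l in zip(labeled_occupancy.sequences, labeled_occupancy.labels) if l == 0][:100],
        )
        pos = [scorer(s) for s, l in zip(labeled_occupancy.sequences, labeled_occupancy.labels) if l == 1][100:]
        neg = [scorer(s) for s, l in zip(labeled_occupancy.sequences, labeled_occupancy.labels) if l == 0][100:]
        res = mann_whitney(pos, neg, alternative="greater")
        assert res.p_value < 0.01


class TestKfoldPartition:
    def test_even_folds(self):
        assign = kfold_partition(20, n_folds=10, seed=0)
        sizes = np.bincount(assign, minlength=10)
        assert (sizes == 2).all()

    def test_partition_axioms(self):
        labels = np.r_[np.ones(13, int), np.zeros(24, int)]
        assign = kfold_partition(labels, n_folds=5, seed=1)
        assert len(assign) == 37
        assert set(assign) == set(range(5))

    def test_stratified_class_balance(self):
        labels = np.r_[np.ones(30, int), np.zeros(70, int)]
        assign = kfold_partition(labels, n_folds=10, stratified=True, seed=2)
        for fold in range(10):
            sub = labels[assign == fold]
            assert (sub == 1).sum() == 3 and (sub == 0).sum() == 7

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError):
            kfold_partition(10, n_folds=1)


class TestRocAuc:
    def test_perfect_separation(self):
        fpr, tpr = roc_curve([3.0, 2.0, 1.0, 0.0], [1, 1, 0, 0])
        assert trapezoid_auc(fpr, tpr) == 1.0

    def test_curve_endpoints(self):
        rng = np.random.default_rng(7)
        s = rng.normal(size=30)
        l = (rng.random(30) < 0.5).astype(int)
        l[0], l[1] = 0, 1
        fpr, tpr = roc_curve(s, l)
        assert (fpr[0], tpr[0]) == (0.0, 0.0) and (fpr[-1], tpr[-1]) == (1.0, 1.0)
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], [1, 1])

    @settings(derandomize=True, max_examples=80)
    @given(
        n=st.integers(4, 50),
        seed=st.integers(0, 2**31 - 1),
        levels=st.integers(2, 6),
    )
    def test_auc_equals_pair_counting(self, n, seed, levels):
        rng = np.random.default_rng(seed)
        labels = np.r_[np.ones(n // 2 + 1, int), np.zeros(n - n // 2 - 1, int)]
        scores = rng.integers(0, levels, len(labels)).astype(float)
        fpr, tpr = roc_curve(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        conc = (pos[:, None] > neg[None, :]).sum()
        tied = (pos[:, None] == neg[None, :]).sum()
        expected = (conc + 0.5 * tied) / (len(pos) * len(neg))
        assert trapezoid_auc(fpr, tpr) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_auc_complement_and_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.5).astype(int)
        labels[:2] = [0, 1]
        auc = trapezoid_auc(*roc_curve(scores, labels))
        assert trapezoid_auc(*roc_curve(-scores, labels)) == pytest.approx(1 - auc, abs=1e-12)
        assert trapezoid_auc(*roc_curve(np.exp(scores), labels)) == pytest.approx(auc, abs=1e-12)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(9)
        scores = rng.integers(0, 5, 60).astype(float)
        labels = (rng.random(60) < 0.4).astype(int)
        labels[:2] = [0, 1]
        assert trapezoid_auc(*roc_curve(scores, labels)) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


class TestCrossValidatedAuc:
    def test_separable_data_scores_high(self, labeled_occupancy):
        res = cross_validated_auc(labeled_occupancy, likelihood_trainer(5), n_folds=10, seed=0)
        assert res.auc >= 0.95
        assert len(res.fold_curves) == 10

    def test_mean_curve_within_fold_envelope(self, labeled_occupancy):
        res = cross_validated_auc(labeled_occupancy, likelihood_trainer(5), n_folds=5, seed=3)
        lo = res.fold_tprs_on_grid.min(axis=0)
        hi = res.fold_tprs_on_grid.max(axis=0)
        assert ((lo - 1e-12 <= res.mean_tpr) & (res.mean_tpr <= hi + 1e-12)).all()

    def test_permuted_labels_near_chance(self):
        aucs = []
        for seed in range(8):
            ls = occupancy_with_matched_negatives(n=100, seed=seed)
            rng = np.random.default_rng(seed + 500)
            perm = LabeledSequenceSet(
                ls.sequences, rng.permutation(ls.labels), ls.centers
            )
            aucs.append(cross_validated_auc(perm, likelihood_trainer(5), seed=seed).auc)
        assert 0.42 <= float(np.mean(aucs)) <= 0.58

    def test_fold_count_stability(self, labeled_occupancy):
        a2 = cross_validated_auc(labeled_occupancy, likelihood_trainer(5), n_folds=2, seed=1).auc
        a10 = cross_validated_auc(labeled_occupancy, likelihood_trainer(5), n_folds=10, seed=1).auc
        assert abs(a2 - a10) < 0.05

    def test_reproducible_under_seed(self, labeled_occupancy):
        a = cross_validated_auc(labeled_occupancy, likelihood_trainer(5), seed=11)
        b = cross_validated_auc(labeled_occupancy, likelihood_trainer(5), seed=11)
        assert a.auc == b.auc and np.array_equal(a.mean_tpr, b.mean_tpr)


class TestPositionalDensity:
    def test_centered_motif_is_delta(self):
        from seqrs_kit import OccupancySimConfig, simulate_occupancy_sites

        cfg = OccupancySimConfig(
            n_positive=40, n_negative=40, window_len=41, motif="ACGGUCA",
            plant_offset_jitter=0, seed=6,
        )
        ls = simulate_occupancy_sites(cfg)
        dens = kmer_positional_density(ls, {"ACGGUCA"}, flank=6)
        pos = dens[1]
        assert pos.density[pos.offsets == 0][0] == 1.0
        # shifted starts occur only by chance; the center dominates
        assert pos.density[pos.offsets != 0].max() < 0.2
        assert pos.cumulative[-1] == pytest.approx(1.0)

    def test_negatives_flat(self):
        ls = occupancy_with_matched_negatives(n=300, seed=12)
        dens = kmer_positional_density(ls, {"A" * 8}, flank=10)
        neg = dens[0].density
        assert neg.max() < 3 * max(neg.mean(), 1e-9) + 0.05

    def test_empty_kmer_set_rejected(self, labeled_occupancy):
        with pytest.raises(ValueError):
            kmer_positional_density(labeled_occupancy, set(), flank=3)

    def test_flank_bounds_enforced(self, labeled_occupancy):
        with pytest.raises(ValueError):
            kmer_positional_density(labeled_occupancy, {"A" * 8}, flank=30)
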