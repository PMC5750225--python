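"""Generators: determinism, selection dynamics, matched shuffles, curves,
image fixtures."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from seqrs_kit import (
    AffinityModel,
    CurveSimConfig,
    OccupancySimConfig,
    SelectionSimConfig,
    SequencePool,
    binding_model,
    decay_model,
    generate_initial_library,
    make_matched_negatives,
    simulate_binding_curve,
    simulate_colocalization_image,
    simulate_decay,
    simulate_occupancy_sites,
    simulate_selection_round,
    simulate_seqrs,
)

rna = st.text(alphabet="ACGU", min_size=2, max_size=40)


class TestInitialLibrary:
    def test_lengths_and_flanks(self):
        cfg = SelectionSimConfig(pool_size=500, reads_per_round=100, seed=3)
        pool = generate_initial_library(cfg)
        L = cfg.random_region_len + len(cfg.primer_5) + len(cfg.primer_3)
        assert all(len(s) == L for s in pool.sequences)
        assert all(s.startswith(cfg.primer_5) and s.endswith(cfg.primer_3) for s in pool.sequences)
        assert pool.total == 500

    def test_deterministic_under_seed(self):
        cfg = SelectionSimConfig(pool_size=1000, reads_per_round=100, seed=7)
        a = generate_initial_library(cfg)
        b = generate_initial_library(cfg)
        assert a.sequences == b.sequences
        assert (a.counts == b.counts).all()

    def test_base_usage_uniform(self):
        counts = Counter()
        for seed in range(10):
            cfg = SelectionSimConfig(pool_size=2000, reads_per_round=100, seed=seed)
            pool = generate_initial_library(cfg)
            for s in pool.sequences:
                counts.update(s[len(cfg.primer_5) : -len(cfg.primer_3)])
        freqs = np.array([counts[b] for b in "ACGU"], float)
        freqs /= freqs.sum()
        assert np.allclose(freqs, 0.25, atol=0.01)

    def test_invalid_pool_size(self):
        with pytest.raises(ValueError):
            SelectionSimConfig(pool_size=0)


class TestSelectionRound:
    def test_pure_nonspecific_preserves_frequencies(self):
        # beta = 1: next-round expected frequencies equal current frequencies
        model = AffinityModel.from_weights(2, {"AA": 100.0}, background=1.0)
        pool = SequencePool(["AAAA", "CCCC", "GGGG"], np.array([500, 300, 200]))
        pvals = []
        for seed in range(20):
            out = simulate_selection_round(pool, model, 1.0, 1000, seed)
            obs = np.array([out.as_dict().get(s, 0) for s in pool.sequences])
            pvals.append(stats.chisquare(obs, pool.counts).pvalue)
        assert min(pvals) > 0.01 / 20  # no seed wildly off
        assert np.mean(pvals) > 0.2

    def test_degenerate_selection(self):
        model = AffinityModel.from_weights(10, {"A" * 10: 1.0}, background=0.0)
        pool = SequencePool(["A" * 20, "C" * 20], np.array([10, 10]))
        out = simulate_selection_round(pool, model, 0.0, 200, seed=0)
        assert out.as_dict() == {"A" * 20: 200}

    def test_all_zero_weight_errors(self):
        model = AffinityModel.from_weights(10, {"A" * 10: 1.0}, background=0.0)
        pool = SequencePool(["C" * 20], np.array([5]))
        with pytest.raises(ValueError, match="background"):
            simulate_selection_round(pool, model, 0.0, 10, seed=0)

    def test_a_rich_frequency_nondecreasing(self):
        # dominant-affinity target frequency grows across rounds in expectation
        model = AffinityModel.a_preferring(k=6, factor=4.0)
        target = "A" * 6
        gains = []
        for seed in range(25):
            cfg = SelectionSimConfig(
                random_region_len=12, n_rounds=3, pool_size=4000,
                reads_per_round=2000, nonspecific_fraction=0.2, seed=seed,
            )
            lib = generate_initial_library(cfg)
            f5, f3 = len(cfg.primer_5), len(cfg.primer_3)
            cur = lib
            freqs = []
            for r in range(cfg.n_rounds):
                cur = simulate_selection_round(
                    cur, model, 0.2, cfg.reads_per_round, seed * 100 + r, f5, f3
                )
                n_hit = sum(
                    c for s, c in cur.as_dict().items()
                    if target in s[f5 : len(s) - f3]
                )
                freqs.append(n_hit / cur.total)
            gains.append(np.diff(freqs))
        mean_gain = np.mean(gains, axis=0)
        assert (mean_gain > 0).all()


class TestSimulateSeqrs:
    def test_file_counts_and_manifest(self, tmp_path):
        cfg = SelectionSimConfig(
            random_region_len=12, n_rounds=3, pool_size=300, reads_per_round=100, seed=5
        )
        model = AffinityModel.a_preferring(k=6)
        res = simulate_seqrs(cfg, model, tmp_path)
        assert sorted(res["rounds"]) == [0, 1, 2, 3]
        assert all(p.exists() for p in res["rounds"].values())
        lines = res["manifest"].read_text().strip().splitlines()
        assert len(lines) - 1 == cfg.n_rounds + 1

    def test_fastq_byte_identical_across_runs(self, tmp_path):
        cfg = SelectionSimConfig(
            random_region_len=10, n_rounds=1, pool_size=200, reads_per_round=80, seed=7
        )
        model = AffinityModel.a_preferring(k=5)
        a = simulate_seqrs(cfg, model, tmp_path / "a")
        b = simulate_seqrs(cfg, model, tmp_path / "b")
        for r in a["rounds"]:
            assert a["rounds"][r].read_bytes() == b["rounds"][r].read_bytes()


class TestOccupancySites:
    def test_motif_planted_at_center_without_jitter(self):
        cfg = OccupancySimConfig(
            n_positive=20, n_negative=5, window_len=30, motif="ACGGUCA",
            plant_offset_jitter=0, seed=2,
        )
        ls = simulate_occupancy_sites(cfg)
        center = 15
        for s, lab in zip(ls.sequences, ls.labels):
            if lab == 1:
                assert s[center : center + 7] == "ACGGUCA"

    def test_all_negative_set_is_valid(self):
        cfg = OccupancySimConfig(n_positive=0, n_negative=10, window_len=20, motif="AA", seed=0)
        ls = simulate_occupancy_sites(cfg)
        assert len(ls.sequences) == 10 and (ls.labels == 0).all()

    def test_jittered_plant_found_by_string_search(self):
        cfg = OccupancySimConfig(
            n_positive=50, n_negative=0, window_len=50, motif="A" * 12,
            plant_offset_jitter=4, seed=9,
        )
        ls = simulate_occupancy_sites(cfg)
        for s in ls.sequences:
            start = s.find("A" * 12)
            # the planted copy begins within center +/- jitter, so the
            # leftmost occurrence can only be there or further left
            assert 0 <= start <= 25 + 4

    def test_motif_longer_than_window_rejected(self):
        with pytest.raises(ValueError):
            OccupancySimConfig(window_len=5, motif="AAAAAA")


class TestMatchedNegatives:
    def test_homopolymer_fixed_point(self):
        assert make_matched_negatives(["AAAA"], 0, 0) == ["AAAA"]
        assert make_matched_negatives(["AAAA"], 1, 0) == ["AAAA"]

    def test_short_sequence_warns_and_passes_through(self):
        with pytest.warns(UserWarning):
            assert make_matched_negatives(["A"], 1, 0) == ["A"]

    @settings(derandomize=True, max_examples=60)
    @given(seq=rna, seed=st.integers(0, 2**31 - 1))
    def test_order0_preserves_base_multiset(self, seq, seed):
        (out,) = make_matched_negatives([seq], 0, seed)
        assert Counter(out) == Counter(seq)

    @settings(derandomize=True, max_examples=60)
    @given(seq=st.text(alphabet="ACGU", min_size=3, max_size=40), seed=st.integers(0, 2**31 - 1))
    def test_order1_preserves_dinucleotide_multiset(self, seq, seed):
        (out,) = make_matched_negatives([seq], 1, seed)
        assert Counter(zip(out, out[1:])) == Counter(zip(seq, seq[1:]))
        assert out[0] == seq[0] and out[-1] == seq[-1]

    def test_deterministic_under_seed(self):
        seqs = ["ACGUACGUAC", "GGAUCCAAGU"]
        assert make_matched_negatives(seqs, 1, 42) == make_matched_negatives(seqs, 1, 42)


class TestCurveSimulation:
    def test_half_saturation_point(self):
        cfg = CurveSimConfig(true_param=300.0, x_values=(1.0, 10.0, 300.0, 1000.0, 3000.0),
                             y_floor=0.1, y_ceiling=0.3, seed=0)
        x, y = simulate_binding_curve(cfg)
        mid = y[x == 300.0][0]
        assert mid == pytest.approx(0.2, abs=1e-12)

    def test_decay_closed_form_and_limit(self):
        cfg = CurveSimConfig(true_param=18.0, x_values=(0.0, 18.0, 36.0, 1800.0),
                             y_ceiling=100.0, seed=0)
        t, y = simulate_decay(cfg)
        assert y[1] == pytest.approx(50.0)
        assert y[2] == pytest.approx(25.0)
        assert y[3] < 1e-25

    def test_noiseless_points_on_model(self):
        cfg = CurveSimConfig(true_param=50.0, x_values=(1.0, 5.0, 50.0, 500.0, 5000.0),
                             y_floor=0.0, y_ceiling=1.0, seed=1)
        x, y = simulate_binding_curve(cfg)
        assert np.allclose(y, binding_model(x, 50.0, 0.0, 1.0))

    def test_proportional_noise_scales_with_signal(self):
        cfg = CurveSimConfig(true_param=18.0, x_values=(0.0, 36.0), y_ceiling=100.0,
                             noise_sd=0.05, n_replicates=400,
                             noise_model="proportional", seed=0)
        t, y = simulate_decay(cfg)
        sd0 = y[t == 0].std()
        sd36 = y[t == 36.0].std()
        assert sd0 == pytest.approx(5.0, rel=0.2)
        assert sd36 == pytest.approx(1.25, rel=0.2)


class TestColocalizationFixture:
    @pytest.mark.parametrize("frac", [0.0, 0.25, 0.5, 1.0])
    def test_ground_truth_matches_pixel_count(self, frac):
        A, B, mask, truth = simulate_colocalization_image(
            overlap_fraction=frac, seed=3, n_object_pixels=200
        )
        thr = truth["threshold"]
        overlap = ((A > thr) & (B > thr)).sum()
        assert overlap / (A > thr).sum() == pytest.approx(truth["m1"])
        assert truth["m1"] == pytest.approx(frac)
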