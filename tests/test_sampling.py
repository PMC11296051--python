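import numpy as np
import pytest

from pcedetect.dives import Dive
from pcedetect.sampling import (SamplerConfig, masked_runs, n_windows,
                                segment_cnn_windows, split_individuals,
                                vnet_global_generator)


def _dive(start, end):
    return Dive(dive_id=0, start_idx=start, end_idx=end, max_depth_m=10,
                duration_s=(end - start) / 25.0)


class TestCnnWindows:
    def _batch(self, n_masked, label_spans=(), total=400):
        data = np.random.default_rng(0).normal(size=(total, 3))
        labels = np.zeros(total, dtype=np.uint8)
        for a, b in label_spans:
            labels[a:b] = 1
        mask = np.zeros(total, dtype=bool)
        mask[100:100 + n_masked] = True
        cfg = SamplerConfig()
        return segment_cnn_windows(data, labels, mask, [_dive(50, 380)], cfg)

    def test_window_count_matches_closed_form(self):
        for run in (8, 9, 20, 100, 101, 103):
            batch = self._batch(run)
            assert len(batch) == (run - 8) // 4 + 1
        assert n_windows(100, 8, 4) == 24
        assert n_windows(7, 8, 4) == 0

    def test_single_window_run(self):
        batch = self._batch(8)
        assert len(batch) == 1
        assert batch.provenance[0][1] == 100

    def test_full_label_window_inside_segment_is_positive(self):
        # labelled 8-sample capture aligned with a window start
        batch = self._batch(100, label_spans=[(108, 116)])
        starts = [s for _, s in batch.provenance]
        labels = dict(zip(starts, batch.labels))
        assert labels[108] == 1  # fully overlapping window
        assert labels[100] == 0  # disjoint window
        # every capture annotation yields at least one positive window
        assert batch.labels.sum() >= 1

    def test_windows_do_not_cross_dive_boundaries(self):
        data = np.zeros((400, 3))
        labels = np.zeros(400, dtype=np.uint8)
        mask = np.ones(400, dtype=bool)
        dives = [_dive(100, 110), _dive(110, 122)]
        batch = segment_cnn_windows(data, labels, mask, dives, SamplerConfig())
        for _, s in batch.provenance:
            assert (100 <= s and s + 8 <= 110) or (110 <= s and s + 8 <= 122)

    def test_short_masked_runs_are_skipped(self):
        batch = self._batch(5)
        assert len(batch) == 0


class TestVnetGenerator:
    def _pool(self, n=4000, n_events=6, seed=3):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(n, 3))
        labels = np.zeros(n, dtype=np.uint8)
        centers = np.linspace(300, n - 300, n_events).astype(int)
        for c in centers:
            labels[c - 3:c + 5] = 1
        return [("a", data, labels)], labels

    def test_bias_zero_matches_uniform_rate(self):
        pool, labels = self._pool()
        cfg = SamplerConfig(vnet_bias=0.0)
        rng = np.random.default_rng(0)
        batch = vnet_global_generator(pool, cfg, 4000, rng)
        frac = np.mean(batch.labels.any(axis=1))
        # uniform hit rate: fraction of window starts overlapping a label
        n = len(labels)
        starts = np.arange(n - 128 + 1)
        hits = np.array([labels[s:s + 128].any() for s in starts])
        u = hits.mean()
        sd = np.sqrt(u * (1 - u) / 4000)
        assert abs(frac - u) < 3 * sd + 1e-9

    def test_bias_one_always_contains_a_label(self):
        pool, _ = self._pool()
        cfg = SamplerConfig(vnet_bias=1.0)
        batch = vnet_global_generator(pool, cfg, 500,
                                      np.random.default_rng(1))
        assert batch.labels.any(axis=1).all()

    def test_default_bias_mixture_rate(self):
        pool, labels = self._pool()
        cfg = SamplerConfig(vnet_bias=0.9)
        batch = vnet_global_generator(pool, cfg, 6000,
                                      np.random.default_rng(2))
        frac = np.mean(batch.labels.any(axis=1))
        n = len(labels)
        starts = np.arange(n - 128 + 1)
        u = np.mean([labels[s:s + 128].any() for s in starts])
        expected = 0.9 + 0.1 * u
        sd = np.sqrt(expected * (1 - expected) / 6000)
        assert abs(frac - expected) < 3 * sd + 1e-9

    def test_draws_reproducible_under_seed(self):
        pool, _ = self._pool()
        cfg = SamplerConfig()
        b1 = vnet_global_generator(pool, cfg, 100, np.random.default_rng(7))
        b2 = vnet_global_generator(pool, cfg, 100, np.random.default_rng(7))
        np.testing.assert_array_equal(b1.data, b2.data)
        np.testing.assert_array_equal(b1.labels, b2.labels)
        assert b1.provenance == b2.provenance

    def test_no_labels_falls_back_to_uniform(self, caplog):
        rng = np.random.default_rng(4)
        pool = [("a", rng.normal(size=(1000, 3)),
                 np.zeros(1000, dtype=np.uint8))]
        batch = vnet_global_generator(pool, SamplerConfig(), 50,
                                      np.random.default_rng(0))
        assert len(batch) == 50
        assert not batch.labels.any()

    def test_windows_never_span_individuals(self):
        rng = np.random.default_rng(5)
        pool = [(f"i{k}", rng.normal(size=(500, 3)),
                 np.zeros(500, dtype=np.uint8)) for k in range(3)]
        pool[0][2][200:208] = 1
        batch = vnet_global_generator(pool, SamplerConfig(), 300,
                                      np.random.default_rng(1))
        for ind, start in batch.provenance:
            assert 0 <= start <= 500 - 128


class TestSplitIndividuals:
    def test_three_individuals_exact_split_is_forced(self):
        counts = {"a": 50, "b": 20, "c": 30}
        cfg = SamplerConfig(split_tolerance=0.0)
        res = split_individuals(counts, cfg, np.random.default_rng(0))
        assert res.train_ids == ["a"]
        assert res.val_ids == ["b"]
        assert res.test_ids == ["c"]
        assert res.within_tolerance

    def test_equal_counts_any_permutation_seed_fixes_one(self):
        counts = {c: 10 for c in "abc"}
        cfg = SamplerConfig(split_fractions=(1 / 3, 1 / 3, 1 / 3),
                            split_tolerance=0.01)
        r1 = split_individuals(counts, cfg, np.random.default_rng(9))
        r2 = split_individuals(counts, cfg, np.random.default_rng(9))
        assert (r1.train_ids, r1.val_ids, r1.test_ids) == \
            (r2.train_ids, r2.val_ids, r2.test_ids)
        assert len(r1.train_ids) == len(r1.val_ids) == len(r1.test_ids) == 1

    def test_achieved_shares_verified_by_recount(self):
        rng = np.random.default_rng(13)
        for trial in range(10):
            counts = {f"i{k}": int(rng.integers(1, 60)) for k in range(15)}
            cfg = SamplerConfig(split_tolerance=0.05)
            res = split_individuals(counts, cfg, rng)
            total = sum(counts.values())
            groups = [res.train_ids, res.val_ids, res.test_ids]
            shares = [sum(counts[i] for i in g) / total for g in groups]
            np.testing.assert_allclose(shares, res.shares, rtol=1e-12)
            if res.within_tolerance:
                for s, f in zip(shares, cfg.split_fractions):
                    assert abs(s - f) <= cfg.split_tolerance + 1e-12

    def test_zero_pce_individuals_go_to_side_list(self):
        counts = {"a": 50, "b": 20, "c": 30, "z1": 0, "z2": 0}
        res = split_individuals(counts, SamplerConfig(split_tolerance=0.0),
                                np.random.default_rng(0))
        assert sorted(res.zero_pce_ids) == ["z1", "z2"]
        assigned = res.train_ids + res.val_ids + res.test_ids
        assert "z1" not in assigned and "z2" not in assigned

    def test_disjoint_groups(self):
        rng = np.random.default_rng(21)
        counts = {f"i{k}": int(rng.integers(1, 40)) for k in range(12)}
        res = split_individuals(counts, SamplerConfig(), rng)
        groups = [set(res.train_ids), set(res.val_ids), set(res.test_ids)]
        assert not (groups[0] & groups[1])
        assert not (groups[0] & groups[2])
        assert not (groups[1] & groups[2])

    def test_too_few_active_individuals_is_an_error(self):
        with pytest.raises(ValueError, match="at least 3"):
            split_individuals({"a": 5, "b": 3, "z": 0}, SamplerConfig(),
                              np.random.default_rng(0))


def test_masked_runs_restricted_to_interval():
    mask = np.zeros(100, dtype=bool)
    mask[10:30] = True
    mask[50:60] = True
    assert masked_runs(mask, 0, 100) == [(10, 30), (50, 60)]
    assert masked_runs(mask, 20, 55) == [(20, 30), (50, 55)]
    assert masked_runs(~np.zeros(10, dtype=bool), 2, 8) == [(2, 8)]
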