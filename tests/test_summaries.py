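"""Density maps, metagenes, half-life fitting, queue statistics and the
profile distance."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import uvpol
from uvpol.engine import Snapshot
from uvpol.summaries import _l1
from uvpol.synth import CoverageTrack


def make_snapshot(positions, time=0.0, gene="g", reasons=None, causes=None,
                  lesions=(), statuses=None):
    n = len(positions)
    return Snapshot(
        time=time, free_pool=0, degraded_count=0, mrna_counts={gene: 0},
        genes={gene: {
            "pol_ids": np.arange(n),
            "positions": np.asarray(positions, dtype=float),
            "statuses": statuses or ["moving"] * n,
            "reasons": reasons or [None] * n,
            "cause_ids": np.asarray(causes if causes is not None else [-1] * n),
        }},
        lesions={gene: list(lesions)},
    )


class TestDensityProfile:
    def test_single_polymerase_lands_in_its_bin(self):
        snap = make_snapshot([10_500.0])
        dmap = uvpol.density_profile([snap], {"g": 100_000}, 1000)
        prof = dmap.profile("g", 0.0)
        assert prof[10] == 1.0 and prof.sum() == 1.0

    def test_half_open_bin_boundary(self):
        snap = make_snapshot([10_000.0])
        dmap = uvpol.density_profile([snap], {"g": 100_000}, 1000)
        assert dmap.profile("g", 0.0)[10] == 1.0

    def test_empty_snapshot_all_zero(self):
        dmap = uvpol.density_profile([make_snapshot([])], {"g": 100_000}, 1000)
        assert dmap.profile("g", 0.0).sum() == 0.0

    @given(st.lists(st.floats(min_value=0, max_value=99_999.99), max_size=40))
    def test_counts_conserved(self, positions):
        dmap = uvpol.density_profile([make_snapshot(positions)], {"g": 100_000}, 1000)
        assert dmap.profile("g", 0.0).sum() == pytest.approx(len(positions))


class TestMetagene:
    def _track(self, gid, values, bin_size=1000):
        return CoverageTrack(gene_id=gid, bin_size=bin_size,
                             counts=np.asarray(values, float), spike_scale=1.0)

    def test_single_gene_is_its_own_metagene(self):
        tr = self._track("a", np.arange(50.0))
        prof = uvpol.metagene_profile([tr], n_points=50)["all"]
        assert np.allclose(prof, np.arange(50.0))

    def test_two_identical_genes_average_to_either(self):
        tr1, tr2 = self._track("a", np.ones(30)), self._track("b", np.ones(60))
        prof = uvpol.metagene_profile([tr1, tr2], n_points=40)["all"]
        assert np.allclose(prof, 1.0)

    def test_stratification_uses_length_classes(self):
        tracks = [self._track("short", np.ones(5)),
                  self._track("medium", np.ones(63)),
                  self._track("long", np.ones(100))]
        out = uvpol.metagene_profile(tracks, stratify=True)
        assert set(out) == {"short", "medium", "long"}

    def test_tss_profile_absolute_scale(self):
        """TSS-anchored profile keeps the absolute bin grid: a short gene
        contributes only its own bins, a long one is truncated at the
        window."""
        short = self._track("s", np.full(5, 2.0))      # 5 kb
        long_ = self._track("L", np.arange(150.0))     # 150 kb
        out = uvpol.tss_profile([short, long_], window=100_000)
        assert set(out) == {"short", "long"}
        assert out["short"].size == 5
        assert out["long"].size == 100
        assert np.allclose(out["long"], np.arange(100.0))

    def test_order_and_duplication_invariance(self):
        a = self._track("a", np.linspace(0, 1, 20))
        b = self._track("b", np.linspace(1, 0, 25))
        base = uvpol.metagene_profile([a, b])["all"]
        shuffled = uvpol.metagene_profile([b, a])["all"]
        duplicated = uvpol.metagene_profile([a, b, a])["all"]  # a given twice
        assert np.allclose(base, shuffled)
        assert np.allclose(base, duplicated)


class TestFitHalfLife:
    def test_exact_on_closed_form_input(self):
        t = np.array([0.0, 3600.0, 7200.0, 10800.0])
        counts = np.exp(-t * math.log(2) / 5400.0)
        fit = uvpol.fit_half_life(t, counts)
        assert fit.half_life == pytest.approx(5400.0, rel=1e-6)
        assert fit.half_life_hours == pytest.approx(1.5, rel=1e-6)

    def test_constant_series_is_infinite(self):
        fit = uvpol.fit_half_life([0, 1, 2, 3], [7.0, 7.0, 7.0, 7.0])
        assert fit.half_life == math.inf

    def test_scale_invariance(self):
        t = np.linspace(0, 10_000, 8)
        counts = 100 * np.exp(-t / 3000.0)
        h1 = uvpol.fit_half_life(t, counts).half_life
        h2 = uvpol.fit_half_life(t, 17.3 * counts).half_life
        assert h1 == pytest.approx(h2)

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(uvpol.ConfigError):
            uvpol.fit_half_life([0, 1, 2], [1.0, 0.0, 1.0])

    def test_noisy_decay_recovers_half_life(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 14400, 900.0)
        counts = 500 * np.exp(-t * math.log(2) / 5400.0) * rng.lognormal(0, 0.02, t.size)
        fit = uvpol.fit_half_life(t, counts)
        assert fit.half_life == pytest.approx(5400.0, rel=0.1)


class TestShutdownRatio:
    def _map(self, early, late):
        snaps = [make_snapshot(early, time=1.0), make_snapshot(late, time=2.0)]
        return uvpol.density_profile(snaps, {"g": 100_000}, 1000)

    def test_identical_snapshots_ratio_one(self):
        dmap = self._map([5000.0, 6000.0], [5000.0, 6000.0])
        assert uvpol.shutdown_ratio(dmap, 1.0, 2.0)["g"] == pytest.approx(1.0)

    def test_empty_late_ratio_zero(self):
        dmap = self._map([5000.0], [])
        assert uvpol.shutdown_ratio(dmap, 1.0, 2.0)["g"] == 0.0

    def test_zero_early_reported_missing(self):
        dmap = self._map([], [5000.0])
        assert math.isnan(uvpol.shutdown_ratio(dmap, 1.0, 2.0)["g"])


class TestQueueStatistics:
    def test_three_polymerase_queue(self):
        snap = make_snapshot(
            [920.0, 960.0, 1000.0],
            statuses=["stalled"] * 3,
            reasons=["queue", "queue", "lesion"],
            causes=[1, 2, 7],  # 0 queued behind 1, 1 behind 2, 2 at lesion 7
            lesions=[(7, 1000.0)])
        qs = uvpol.queue_statistics(snap)
        assert qs.max == 3 and qs.mean == 3.0

    def test_no_stalled_polymerases(self):
        snap = make_snapshot([500.0, 900.0], lesions=[(3, 2000.0)])
        qs = uvpol.queue_statistics(snap)
        assert qs.max == 0 and qs.mean == 0.0
        assert list(qs.per_lesion["queue_len"]) == [0]


class TestProfileDistance:
    def test_identical_profiles_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert uvpol.profile_distance(a, a).statistic == 0.0

    def test_disjoint_masses_maximal(self):
        a, b = np.array([1.0, 0.0]), np.array([0.0, 5.0])
        assert uvpol.profile_distance(a, b).statistic == pytest.approx(2.0)

    def test_zero_mass_rejected(self):
        with pytest.raises(uvpol.UvpolError):
            uvpol.profile_distance(np.zeros(3), np.ones(3))

    @given(st.lists(st.lists(st.floats(min_value=0.01, max_value=10), min_size=4,
                             max_size=4), min_size=3, max_size=3))
    def test_pseudometric_on_random_triples(self, triples):
        a, b, c = (np.asarray(x) for x in triples)
        dab = _l1(a, b)
        dba = _l1(b, a)
        assert dab == pytest.approx(dba)  # symmetry
        assert _l1(a, a) == pytest.approx(0.0)  # identity
        assert dab <= _l1(a, c) + _l1(c, b) + 1e-9  # triangle
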