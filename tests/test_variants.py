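"""Variant tracks: capping, EMA smoothing, Pearson r, variant constraint."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import holespec as hs
from holespec.variants import cap_frequencies, ema_smooth, pearson_r


class TestCap:
    def test_below_cap_unchanged(self):
        v = hs.VariantTrack(g=np.array([10.0, 0.0, 349.0]))
        assert np.array_equal(cap_frequencies(v, 350).g, [10, 0, 349])

    def test_huge_spike_clipped(self):
        v = hs.VariantTrack(g=np.array([19501.0, 5.0, 0.0]))
        assert np.array_equal(cap_frequencies(v, 350).g, [350, 5, 0])

    def test_idempotent(self, rng):
        v = hs.VariantTrack(g=rng.integers(0, 2000, size=100).astype(float))
        once = cap_frequencies(v, 350)
        assert np.array_equal(cap_frequencies(once, 350).g, once.g)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            hs.VariantTrack(g=np.array([1.0, -2.0]))


class TestEma:
    def test_constant_preserved(self):
        assert np.allclose(ema_smooth(np.full(30, 7.5)), 7.5)

    def test_impulse_response_halfwidth_one(self):
        x = np.zeros(7)
        x[3] = 1.0
        out = ema_smooth(x, halfwidth=1, decay=0.5)
        assert out[2:5] == pytest.approx([0.25, 0.5, 0.25])
        assert out.sum() == pytest.approx(1.0)

    def test_halfwidth_zero_is_identity(self, rng):
        x = rng.random(20)
        assert np.array_equal(ema_smooth(x, halfwidth=0), x)

    def test_linearity(self, rng):
        x, y = rng.random(50), rng.random(50)
        lhs = ema_smooth(2 * x + 3 * y)
        rhs = 2 * ema_smooth(x) + 3 * ema_smooth(y)
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_interior_mass_conserved(self):
        x = np.zeros(50)
        x[20:25] = [1, 4, 2, 8, 1]
        assert ema_smooth(x, halfwidth=8).sum() == pytest.approx(x.sum())


class TestPearson:
    def test_self_correlation(self):
        assert pearson_r([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_anti_correlation(self):
        assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_partial(self):
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_matches_scipy(self, rng):
        import scipy.stats

        x, y = rng.random(100), rng.random(100)
        assert pearson_r(x, y) == pytest.approx(
            scipy.stats.pearsonr(x, y).statistic, abs=1e-12)

    def test_zero_variance_is_error_not_nan(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_r([1.0, 1.0, 1.0], [1, 2, 3])

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    @settings(deadline=None, max_examples=30)
    def test_affine_invariance(self, a, b):
        x = np.array([0.3, 1.7, 0.2, 2.2, 0.9, 1.1])
        y = np.array([1.0, 2.0, 0.5, 2.5, 1.5, 0.7])
        assert pearson_r(a * x + b, y) == pytest.approx(pearson_r(x, y), abs=1e-9)


class TestConstrain:
    def test_identity_at_zero_scale(self, rng):
        g = rng.integers(0, 400, size=30).astype(float)
        v = hs.VariantTrack(g=g)
        n = rng.random(30)
        assert np.array_equal(hs.variant_constrain(n, v, 0.0).values, n)

    def test_zero_variant_site_never_suppressed(self):
        v = hs.VariantTrack(g=np.array([0.0, 349.0, 0.0]))
        out = hs.variant_constrain(np.array([2.0, 2.0, 2.0]), v, 1000.0)
        assert out.values[0] == 2.0 and out.values[2] == 2.0
        assert out.values[1] == pytest.approx(2 / 349001)

    def test_monotone_suppression_in_A(self, rng):
        g = rng.integers(0, 400, size=50).astype(float)
        v = hs.VariantTrack(g=g)
        n = rng.random(50) + 0.1
        prev = hs.variant_constrain(n, v, 0.0).values
        for A in (0.1, 1.0, 10.0, 1e4):
            cur = hs.variant_constrain(n, v, A).values
            assert np.all(cur <= prev + 1e-15)
            assert np.all(cur <= n) and np.all(cur >= 0)
            prev = cur
        # A -> infinity keeps only zero-variant sites
        limit = hs.variant_constrain(n, v, 1e12).values
        assert np.allclose(limit[g == 0], n[g == 0])
        assert np.all(limit[g > 0] < 1e-9)

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            hs.variant_constrain(np.ones(3), hs.VariantTrack(g=np.zeros(3)), -1.0)


class TestPipeline:
    def test_identical_tracks_give_unity(self):
        x = np.array([0.0, 3, 1, 4, 1, 5, 9, 2, 6])
        v = hs.VariantTrack(g=x)
        out = hs.correlation_pipeline(x, v, hs.CorrelationConfig(gb_cap=100))
        assert out["raw"] == pytest.approx(1.0)
        assert out["capped"] == pytest.approx(1.0)   # nothing reaches the cap
        assert out["smoothed"] == pytest.approx(1.0)  # same smoothing both tracks

    def test_smoothing_rescues_offset_spikes(self, rng):
        """Spikes offset from hole peaks by 1-2 bp barely correlate raw;
        the EMA widens both tracks so they overlap."""
        n = 1000
        holes = np.zeros(n)
        spikes = []
        for pos in range(50, 1000, 100):
            holes[pos] = 5.0
            spikes.append((pos + 1 + int(rng.integers(0, 2)), 200.0))
        v = hs.make_variant_track(n, spikes=spikes)
        cfg = hs.CorrelationConfig()
        out = hs.correlation_pipeline(holes, v, cfg)
        assert out["smoothed"] > out["raw"]
        assert out["smoothed"] > 0.5

    def test_independent_tracks_near_zero(self, rng):
        x = rng.random(1000)
        v = hs.VariantTrack(g=rng.integers(0, 300, size=1000).astype(float))
        out = hs.correlation_pipeline(x, v)
        assert abs(out["raw"]) < 0.1

    def test_subrange_reported(self):
        x = np.arange(100, dtype=float)
        v = hs.VariantTrack(g=np.arange(100, dtype=float), start=1)
        cfg = hs.CorrelationConfig(subrange=(10, 60))
        out = hs.correlation_pipeline(x, v, cfg)
        assert set(out) >= {"raw", "capped", "smoothed",
                            "raw_sub", "capped_sub", "smoothed_sub"}
        assert out["raw_sub"] == pytest.approx(1.0)

    def test_bad_subrange_rejected(self):
        v = hs.VariantTrack(g=np.zeros(10), start=100)
        with pytest.raises(ValueError, match="subrange"):
            hs.correlation_pipeline(np.ones(10), v,
                                    hs.CorrelationConfig(subrange=(1, 5)))


def test_mutation_track_from_positions():
    mut = hs.MutationTrack.from_positions(
        {3460: "LHON", 9999: "outside"}, start=3307, end=4262, magnitude=2.0)
    assert mut.m[3460 - 3307] == 2.0
    assert mut.positions_present.tolist() == [3460]
    assert mut.labels == {3460: "LHON"}
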