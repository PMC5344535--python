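import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lequant import (
    ImagePlane,
    LineProfile,
    SegmentProfile,
    compartment_stats,
    correct_background,
    estimate_background,
    normalize_segment,
    pool,
    split_segments,
)


def _profile(s, i):
    return LineProfile(np.asarray(s, float), np.asarray(i, float))


class TestEstimateBackground:
    def test_constant_region(self):
        img = ImagePlane(np.full((50, 50), 7.0), pixel_size=1.0)
        roi = [(5, 5), (20, 5), (20, 20), (5, 20)]
        assert estimate_background(img, roi) == 7.0

    def test_median_robust_to_bright_speck_vs_sort_oracle(self):
        pixels = np.ones((40, 40))
        pixels[10, 10] = 100.0
        img = ImagePlane(pixels, pixel_size=1.0)
        roi = [(8, 8), (13, 8), (13, 13), (8, 13)]  # 36 pixels, one speck
        inside = [pixels[y, x] for x in range(8, 14) for y in range(8, 14)]
        oracle = float(np.sort(inside)[len(inside) // 2])  # even count, both mid values 1
        assert estimate_background(img, roi) == oracle == 1.0

    def test_tiny_roi_rejected(self):
        img = ImagePlane(np.ones((20, 20)), pixel_size=1.0)
        with pytest.raises(ValueError, match="too small"):
            estimate_background(img, [(1, 1), (3, 1), (2, 3)])

    def test_roi_outside_image_rejected(self):
        img = ImagePlane(np.ones((20, 20)), pixel_size=1.0)
        with pytest.raises(ValueError):
            estimate_background(img, [(100, 100), (120, 100), (110, 120)])


class TestCorrectBackground:
    def test_below_background_clamps_to_zero(self):
        out = correct_background(_profile([0, 1], [5.0, 5.0]), background=7.0)
        assert np.array_equal(out.intensity, [0.0, 0.0])

    def test_zero_background_is_identity(self):
        p = _profile([0, 1, 2], [3.0, 0.5, 9.0])
        out = correct_background(p, background=0.0)
        assert np.array_equal(out.intensity, p.intensity)

    def test_simple_subtraction(self):
        out = correct_background(_profile([0], [10.0]), background=3.0)
        assert out.intensity[0] == 7.0

    def test_negative_background_rejected(self):
        with pytest.raises(ValueError):
            correct_background(_profile([0], [1.0]), background=-1.0)


class TestSplitSegments:
    def test_two_segments_from_three_boundaries(self):
        s = np.arange(0.0, 20.0, 0.5)
        segs = split_segments(
            _profile(s, np.ones_like(s)),
            boundaries=[(0.0, "T1"), (10.0, "T2"), (20.0, "end")],
        )
        assert [g.label for g in segs] == ["T1", "T2"]
        assert (segs[0].s_start, segs[0].s_end) == (0.0, 10.0)
        assert segs[0].s.max() < 10.0  # half-open on the right

    def test_equal10_splits_into_ten_equal_segments(self):
        s = np.arange(0.0, 100.0, 1.0)
        segs = split_segments(_profile(s, np.ones_like(s)), mode="equal-10")
        assert len(segs) == 10
        assert [g.label for g in segs] == [f"S{i}" for i in range(1, 11)]
        assert all(g.length == pytest.approx(9.9) for g in segs)

    def test_sample_on_internal_boundary_goes_right(self):
        s = np.array([0.0, 5.0, 10.0, 15.0, 20.0])
        segs = split_segments(
            _profile(s, s), boundaries=[(0.0, "a"), (10.0, "b"), (20.0, "end")]
        )
        assert 10.0 not in segs[0].s
        assert 10.0 in segs[1].s

    def test_boundary_outside_profile_rejected(self):
        s = np.arange(0.0, 10.0)
        with pytest.raises(ValueError, match="outside"):
            split_segments(
                _profile(s, s), boundaries=[(0.0, "a"), (50.0, "end")]
            )


class TestNormalizeSegment:
    def _shell(self, s, i, lo, hi):
        return SegmentProfile(
            label="T1", s_start=lo, s_end=hi,
            s=np.asarray(s, float), intensity=np.asarray(i, float),
        )

    def test_constant_segment(self):
        s = np.linspace(0, 10, 40, endpoint=False)
        seg = normalize_segment(self._shell(s, np.full_like(s, 4.0), 0.0, 10.0))
        assert np.allclose(seg.d_ns, 4.0)
        assert seg.d_le == pytest.approx(4.0)
        assert compartment_stats(seg).ap_ratio == pytest.approx(1.0)

    def test_seven_three_step_recovered(self):
        """A profile equal to `a` on the anterior 70% of the segment and `p`
        on the posterior 30% yields d_NS = [a]*7 + [p]*3."""
        a, p = 5.0, 2.0
        s = np.arange(0.0, 30.0, 0.01)
        i = np.where(s < 21.0, a, p)
        seg = normalize_segment(self._shell(s, i, 0.0, 30.0))
        assert np.allclose(seg.d_ns[:7], a, rtol=2e-3)
        assert np.allclose(seg.d_ns[7:], p, rtol=2e-3)
        stats = compartment_stats(seg)
        assert stats.anterior_mean == pytest.approx(a, rel=1e-3)
        assert stats.posterior_mean == pytest.approx(p, rel=1e-3)

    def test_five_sample_segment_resampled_conserves_mean(self):
        s = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
        i = np.array([2.0, 4.0, 6.0, 4.0, 2.0])
        seg = normalize_segment(self._shell(s, i, 0.0, 10.0))
        assert len(seg.d_ns) == 10
        # equal-length bins: plain mean of bin means is the segment mean
        assert seg.d_le == pytest.approx(np.mean(seg.d_ns), rel=1e-12)
        # piecewise-linear (trapezoid, edge-extended) mean as direct oracle
        edges = np.concatenate([[0.0], s, [10.0]])
        vals = np.concatenate([[i[0]], i, [i[-1]]])
        direct = np.trapezoid(vals, edges) / 10.0
        assert seg.d_le == pytest.approx(direct, rel=1e-6)

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            normalize_segment(self._shell([], [], 0.0, 1.0))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_conservation_and_scale_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 200)
        length = rng.uniform(5.0, 50.0)
        s = np.sort(rng.uniform(0, length, n))
        i = rng.uniform(0, 100, n)
        seg = normalize_segment(self._shell(s, i, 0.0, length))
        assert abs(seg.d_le - np.mean(seg.d_ns)) <= 1e-9 * max(seg.d_le, 1e-30)
        assert np.all(seg.d_ns >= 0)
        k = rng.uniform(0.1, 10.0)
        scaled = normalize_segment(self._shell(s, k * i, 0.0, length))
        assert np.allclose(scaled.d_ns, k * seg.d_ns, rtol=1e-12)
        r0 = compartment_stats(seg).ap_ratio
        r1 = compartment_stats(scaled).ap_ratio
        if np.isfinite(r0):
            assert r1 == pytest.approx(r0, rel=1e-9)


class TestCompartmentStats:
    def test_uniform_ratio_one(self):
        seg = SegmentProfile("T1", 0, 1, d_le=1.0, d_ns=np.ones(10))
        assert compartment_stats(seg).ap_ratio == pytest.approx(1.0)

    def test_two_to_one_step(self):
        seg = SegmentProfile("T1", 0, 1, d_le=1.7, d_ns=np.array([2.0] * 7 + [1.0] * 3))
        stats = compartment_stats(seg)
        assert stats.ap_ratio == pytest.approx(2.0)

    def test_zero_posterior_gives_nan_sentinel(self):
        seg = SegmentProfile("T1", 0, 1, d_le=0.7, d_ns=np.array([1.0] * 7 + [0.0] * 3))
        stats = compartment_stats(seg)
        assert np.isnan(stats.ap_ratio)
        assert not stats.defined


def _embryo(d_les, d_nss=None):
    segs = []
    for j, v in enumerate(d_les):
        d_ns = np.full(10, v) if d_nss is None else np.asarray(d_nss[j], float)
        segs.append(
            SegmentProfile(f"S{j + 1}", j * 10.0, (j + 1) * 10.0,
                           d_le=float(v), d_ns=d_ns)
        )
    return segs


class TestPool:
    def test_single_embryo_mean_with_missing_dispersion(self):
        pooled = pool({"e1": _embryo([1.0, 2.0])}, axis="AP")
        assert list(pooled.data["mean"]) == [1.0, 2.0]
        assert pooled.data["sd"].isna().all()
        assert (pooled.data["n"] == 1).all()

    def test_two_identical_embryos_zero_sd(self):
        pooled = pool({"e1": _embryo([3.0]), "e2": _embryo([3.0])}, axis="AP")
        assert pooled.data.loc[0, "sd"] == 0.0
        assert pooled.data.loc[0, "sem"] == 0.0
        assert pooled.data.loc[0, "n"] == 2

    def test_sem_matches_sampling_theory_for_unit_variance(self):
        rng = np.random.default_rng(11)
        profiles = {
            f"e{k}": _embryo(rng.normal(10.0, 1.0, size=5)) for k in range(20)
        }
        pooled = pool(profiles, axis="AP")
        expected = 1.0 / np.sqrt(20)
        assert np.all(np.abs(pooled.data["sem"] - expected) < 0.3 * expected)

    def test_compartmental_axis_counts_segments(self):
        d_nss = [np.arange(10.0), np.arange(10.0) + 1.0]
        profiles = {
            "e1": _embryo([4.5, 5.5], d_nss),
            "e2": _embryo([4.5, 5.5], d_nss),
        }
        pooled = pool(profiles, axis="compartmental")
        assert (pooled.data["n"] == 4).all()  # 2 segments x 2 embryos
        assert list(pooled.data["bin"]) == list(range(1, 11))
        assert pooled.data.loc[0, "mean"] == pytest.approx(0.5)

    def test_sem_equals_sd_over_sqrt_n(self):
        rng = np.random.default_rng(12)
        profiles = {f"e{k}": _embryo(rng.uniform(0, 5, 3)) for k in range(7)}
        pooled = pool(profiles, axis="AP")
        assert np.allclose(pooled.data["sem"], pooled.data["sd"] / np.sqrt(7))

    def test_label_mismatch_rejected(self):
        a = _embryo([1.0])
        b = _embryo([1.0])
        b[0].label = "other"
        with pytest.raises(ValueError, match="labels differ"):
            pool({"e1": a, "e2": b}, axis="AP")

    def test_unnormalized_segment_rejected(self):
        seg = SegmentProfile("S1", 0.0, 10.0)
        with pytest.raises(ValueError, match="not normalized"):
            pool({"e1": [seg]}, axis="AP")
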