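"""Geometry and summarization of tract profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tractquant import (DataError, DegenerateFiberError,
                        ExcludedProfileError, Fiber, FiberBundle,
                        combine_control_sides, profile_bundle,
                        recode_laterality, resample_fiber,
                        summarize_profile)
from tractquant.errors import ConfigurationError

from conftest import make_profile, make_subject


# ---------------------------------------------------------------------------
# resampling

class TestResampleFiber:
    def test_straight_fiber_yields_uniform_nodes(self):
        pts = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 99.0]])
        out = resample_fiber(pts, 100)
        assert out.shape == (100, 3)
        np.testing.assert_allclose(out[:, 2], np.arange(100.0), atol=1e-12)

    def test_already_uniform_input_is_identity(self):
        pts = np.column_stack([np.linspace(0, 10, 25),
                               np.zeros(25), np.zeros(25)])
        np.testing.assert_allclose(resample_fiber(pts, 25), pts, atol=1e-9)

    def test_quarter_circle_matches_analytic_arc_length(self):
        # dense polyline on a radius-10 quarter circle; equal arc-length
        # nodes must land at equally spaced angles
        theta = np.linspace(0, np.pi / 2, 1000)
        pts = np.column_stack([10 * np.cos(theta), 10 * np.sin(theta),
                               np.zeros_like(theta)])
        out = resample_fiber(pts, 5)
        want_theta = np.linspace(0, np.pi / 2, 5)
        want = np.column_stack([10 * np.cos(want_theta),
                                10 * np.sin(want_theta),
                                np.zeros(5)])
        assert np.abs(out - want).max() < 0.01

    def test_endpoints_preserved_exactly(self):
        pts = np.array([[1.0, 2.0, 3.0], [4.0, 6.0, 3.0], [9.0, 0.0, 1.0]])
        out = resample_fiber(pts, 7)
        np.testing.assert_array_equal(out[0], pts[0])
        np.testing.assert_array_equal(out[-1], pts[-1])

    def test_zero_length_fiber_rejected(self):
        pts = np.zeros((3, 3))
        with pytest.raises(DegenerateFiberError):
            resample_fiber(pts, 10)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 50.0), min_size=2, max_size=12),
           st.integers(2, 40))
    def test_collinear_resampling_equally_spaced(self, steps, n_nodes):
        # a polyline along one axis with uneven spacing: arc length equals
        # coordinate, so output nodes must be exactly evenly spaced
        z = np.concatenate([[0.0], np.cumsum(steps)])
        pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        out = resample_fiber(pts, n_nodes)
        gaps = np.diff(out[:, 2])
        assert np.allclose(gaps, gaps[0], rtol=1e-9, atol=1e-12)


# ---------------------------------------------------------------------------
# bundle profiling

def _bundle(fibers, tract="CH", side="left", voxel=2.0):
    return FiberBundle("S1", "pre", tract, side, tuple(fibers),
                       voxel_size=voxel)


def _straight_fiber(offset=(0.0, 0.0), fa=0.5, md=0.8, n=50, length=198.0):
    z = np.linspace(0.0, length, n)
    pts = np.column_stack([np.full(n, 1.0 + offset[0]),
                           np.full(n, 1.0 + offset[1]), z])
    return Fiber(pts, np.full(n, fa), np.full(n, md))


class TestProfileBundle:
    def test_identical_fibers_average_to_their_scalar(self):
        prof = profile_bundle(_bundle([_straight_fiber()] * 3), 100,
                              min_fibers=2)
        assert prof.fib == 3
        assert prof.valid
        np.testing.assert_allclose(prof.fa_nodes, 0.5, atol=1e-12)
        np.testing.assert_allclose(prof.md_nodes, 0.8, atol=1e-12)

    def test_volume_matches_voxel_occupancy_enumeration(self):
        # one straight fiber whose 100 nodes fall in 100 distinct 2 mm
        # voxels: each node contributes one 8 mm^3 cell
        prof = profile_bundle(_bundle([_straight_fiber()]), 100,
                              min_fibers=1)
        np.testing.assert_allclose(prof.vol_nodes, 8.0)
        assert prof.vol_nodes.sum() == pytest.approx(100 * 8.0)
        # independent enumeration of occupied voxels at each node
        nodes = resample_fiber(_straight_fiber().points, 100)
        occupied = {tuple(np.floor(p / 2.0).astype(int)) for p in nodes}
        assert len(occupied) == 100

    def test_insufficient_fibers_flagged_not_raised(self):
        prof = profile_bundle(_bundle([_straight_fiber()] * 2), 100,
                              min_fibers=5)
        assert prof.valid is False
        assert prof.fib == 2

    def test_fiber_order_does_not_matter(self):
        fibers = [_straight_fiber(offset=(dx, 0.0), fa=0.3 + 0.1 * i)
                  for i, dx in enumerate((0.0, 3.0, 6.0))]
        a = profile_bundle(_bundle(fibers), 50, min_fibers=1)
        b = profile_bundle(_bundle(fibers[::-1]), 50, min_fibers=1)
        np.testing.assert_array_equal(a.fa_nodes, b.fa_nodes)
        np.testing.assert_array_equal(a.vol_nodes, b.vol_nodes)

    def test_fa_bounds_enforced_on_input(self):
        n = 10
        pts = np.column_stack([np.zeros(n), np.zeros(n),
                               np.linspace(0, 9, n)])
        with pytest.raises(DataError):
            Fiber(pts, np.full(n, 1.5), np.full(n, 0.8))


# ---------------------------------------------------------------------------
# summarization

class TestSummarizeProfile:
    def test_ramp_profile_segment_means(self):
        ramp = np.arange(1.0, 101.0)          # 1..100 (MD-like scale)
        prof = make_profile(md=ramp)
        summ = summarize_profile(prof)
        want = [10.5, 30.5, 50.5, 70.5, 90.5]
        got = [summ.segment_means[("MD", s)] for s in range(1, 6)]
        assert got == pytest.approx(want)
        assert summ.global_means["MD"] == pytest.approx(50.5)

    def test_constant_profile_all_means_equal(self):
        summ = summarize_profile(make_profile(md=0.8))
        assert all(summ.segment_means[("MD", s)] == pytest.approx(0.8)
                   for s in range(1, 6))
        assert summ.global_means["MD"] == pytest.approx(0.8)

    def test_global_mean_is_mean_of_segment_means_exactly(self, rng):
        prof = make_profile(fa=rng.uniform(0.2, 0.8, 100),
                            md=rng.uniform(0.5, 1.2, 100),
                            vol=rng.uniform(5, 25, 100))
        summ = summarize_profile(prof)
        for var in ("FA", "MD", "Vol"):
            segs = [summ.segment_means[(var, s)] for s in range(1, 6)]
            assert summ.global_means[var] == np.mean(segs)  # bitwise

    def test_fib_is_global_only(self):
        summ = summarize_profile(make_profile(fib=42))
        assert summ.global_means["Fib"] == 42
        assert all(key[0] != "Fib" for key in summ.segment_means)

    def test_invalid_profile_rejected(self):
        with pytest.raises(ExcludedProfileError):
            summarize_profile(make_profile(valid=False))

    def test_indivisible_segmentation_rejected(self):
        with pytest.raises(ConfigurationError):
            summarize_profile(make_profile(), n_segments=7)


# ---------------------------------------------------------------------------
# laterality recoding and control combination

def _summaries(sid, tracts_sides, **kw):
    return [summarize_profile(make_profile(sid=sid, tract=t, side=s, **kw))
            for t, s in tracts_sides]


class TestRecodeLaterality:
    def test_ioz_side_maps_to_ipsi_and_opposite_to_contra(self):
        subj = make_subject("P01", ioz="left")
        summs = _summaries("P01", [("ILF", "left"), ("TR", "right")])
        out = recode_laterality(summs, [subj])
        assert [s.laterality for s in out] == ["ipsi", "contra"]

    def test_cfme_always_midline(self):
        for ioz in ("left", "right"):
            subj = make_subject("P01", ioz=ioz)
            out = recode_laterality(
                _summaries("P01", [("CFMe", "midline")]), [subj])
            assert out[0].laterality == "midline"

    def test_recoding_changes_no_numeric_field(self):
        subj = make_subject("P01", ioz="right")
        summ = _summaries("P01", [("Un", "left")], fa=0.41, md=0.93)[0]
        out = recode_laterality([summ], [subj])[0]
        assert out.global_means == summ.global_means
        assert out.segment_means == summ.segment_means

    def test_recoding_is_idempotent(self):
        subj = make_subject("P01", ioz="left")
        once = recode_laterality(
            _summaries("P01", [("ILF", "left")]), [subj])
        twice = recode_laterality(once, [subj])
        assert twice == once

    def test_unknown_subject_rejected(self):
        summ = _summaries("P01", [("ILF", "left")])[0]
        with pytest.raises(DataError):
            recode_laterality([summ], [make_subject("X", ioz="left")])


class TestCombineControlSides:
    def test_pool_doubles_bilateral_observations(self):
        summs = []
        for i in range(19):
            summs += _summaries(f"C{i}", [("ILF", "left"), ("ILF", "right")])
        out = combine_control_sides(summs, policy="pool")
        assert len(out) == 38
        assert all(s.laterality == "pooled-control" for s in out)

    def test_subject_mean_averages_sides(self):
        summs = (_summaries("C1", [("ILF", "left")], fa=0.4)
                 + _summaries("C1", [("ILF", "right")], fa=0.5))
        out = combine_control_sides(summs, policy="subject-mean")
        assert len(out) == 1
        assert out[0].global_means["FA"] == pytest.approx(0.45)

    def test_cfme_passes_once_under_either_policy(self):
        summs = _summaries("C1", [("CFMe", "midline")])
        for policy in ("pool", "subject-mean"):
            out = combine_control_sides(summs, policy=policy)
            assert len(out) == 1
            assert out[0].laterality == "midline"

    def test_patient_summary_rejected(self):
        patient = make_subject("P01", ioz="left")
        summ = _summaries("P01", [("ILF", "left")])[0]
        with pytest.raises(DataError):
            combine_control_sides([summ], subjects=[patient])
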