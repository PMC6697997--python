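"""NGTDM construction and features against hand enumeration and a
brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ngtdmpet import (
    EmptyNgtdmError,
    QuantizedPatch,
    build_ngtdm,
    busyness,
    coarseness,
    contrast,
    texture_triplet,
)

from _oracles import features_brute_force, ngtdm_brute_force
from conftest import random_patch

CROSS3 = QuantizedPatch(
    np.array([[1, 1, 1], [1, 2, 1], [1, 1, 1]]), np.ones((3, 3), bool)
)


class TestBuildNgtdm:
    def test_single_interior_pixel(self):
        """3x3 patch with a bright center: only the center is eligible
        under strict interior; its neighbors average to 1."""
        t = build_ngtdm(CROSS3, distance=1, policy="strict-interior")
        assert t.n_considered == 1
        assert t.s[2] == pytest.approx(1.0)
        assert t.s[1] == 0.0
        assert t.p[2] == pytest.approx(1.0)
        assert list(t.levels_present) == [2]

    def test_constant_patch(self):
        patch = QuantizedPatch(np.full((5, 5), 7), np.ones((5, 5), bool))
        t = build_ngtdm(patch)
        assert t.s[7] == 0.0
        assert t.p[7] == pytest.approx(1.0)
        assert t.n_gray_levels == 1

    def test_no_eligible_pixel_raises(self):
        # a lone valid cell has no neighbors and no full neighborhood
        valid = np.zeros((3, 3), bool)
        valid[1, 1] = True
        patch = QuantizedPatch(np.ones((3, 3), int), valid)
        with pytest.raises(EmptyNgtdmError):
            build_ngtdm(patch, policy="strict-interior")
        with pytest.raises(EmptyNgtdmError):
            build_ngtdm(patch, policy="all-valid-neighbors")

    @pytest.mark.parametrize("policy", ["strict-interior", "all-valid-neighbors"])
    def test_matches_brute_force(self, rng, policy):
        for _ in range(200):
            patch = random_patch(rng)
            try:
                t = build_ngtdm(patch, policy=policy)
            except EmptyNgtdmError:
                s, p, n = ngtdm_brute_force(patch.values, patch.valid, policy=policy)
                assert n == 0
                continue
            s, p, n = ngtdm_brute_force(patch.values, patch.valid, policy=policy)
            assert t.n_considered == n
            for i in range(1, t.s.size):
                assert t.s[i] == pytest.approx(s.get(i, 0.0), rel=1e-10, abs=1e-12)
                assert t.p[i] == pytest.approx(p.get(i, 0.0), rel=1e-10, abs=1e-12)


class TestFeatures:
    def test_constant_patch_limits(self):
        """A textureless region hits the coarseness cap and zeroes the
        other two features."""
        patch = QuantizedPatch(np.full((5, 5), 3), np.ones((5, 5), bool))
        t = build_ngtdm(patch)
        assert coarseness(t, 1e-8) == pytest.approx(1e8)
        assert contrast(t) == 0.0
        assert busyness(t) == 0.0

    def test_cross_patch_values(self):
        t = build_ngtdm(CROSS3)
        assert coarseness(t, 1e-8) == pytest.approx(1.0 / (1e-8 + 1.0))
        # one gray level among considered pixels: contrast 0 by convention
        assert contrast(t) == 0.0

    def test_coarseness_decreases_when_s_doubles(self, rng):
        patch = random_patch(rng, random_validity=False)
        t = build_ngtdm(patch)
        if np.dot(t.p, t.s) == 0:
            pytest.skip("degenerate draw")
        doubled = type(t)(s=2 * t.s, p=t.p, n_considered=t.n_considered)
        assert coarseness(doubled) < coarseness(t)

    def test_checkerboard_busier_than_half_split(self):
        """Maximal spatial frequency of intensity change beats two
        homogeneous halves of the same two tones."""
        cb = np.indices((4, 4)).sum(axis=0) % 2 + 1
        halves = np.array([[1, 1, 2, 2]] * 4)
        ones = np.ones((4, 4), bool)
        b_cb = busyness(build_ngtdm(QuantizedPatch(cb, ones), policy="all-valid-neighbors"))
        b_half = busyness(
            build_ngtdm(QuantizedPatch(halves, ones), policy="all-valid-neighbors")
        )
        assert b_cb > b_half

    @pytest.mark.parametrize("policy", ["strict-interior", "all-valid-neighbors"])
    def test_features_match_brute_force(self, rng, policy):
        for _ in range(200):
            patch = random_patch(rng, size_lo=5, size_hi=5, max_bins=8)
            try:
                t = build_ngtdm(patch, policy=policy)
            except EmptyNgtdmError:
                continue
            s, p, n = ngtdm_brute_force(patch.values, patch.valid, policy=policy)
            ref = features_brute_force(s, p, n)
            got = texture_triplet(t)
            assert got.coarseness == pytest.approx(ref[0], rel=1e-10)
            assert got.contrast == pytest.approx(ref[1], rel=1e-10, abs=1e-12)
            assert got.busyness == pytest.approx(ref[2], rel=1e-10, abs=1e-12)


class TestProperties:
    @given(data=st.data())
    @settings(max_examples=150, deadline=None)
    def test_finite_and_nonnegative(self, data):
        """Every feature is finite and >= 0 on any valid patch."""
        h = data.draw(st.integers(3, 7))
        w = data.draw(st.integers(3, 7))
        vals = np.array(
            data.draw(
                st.lists(
                    st.lists(st.integers(1, 16), min_size=w, max_size=w),
                    min_size=h,
                    max_size=h,
                )
            )
        )
        mask_bits = np.array(
            data.draw(
                st.lists(
                    st.lists(st.booleans(), min_size=w, max_size=w),
                    min_size=h,
                    max_size=h,
                )
            )
        )
        if not mask_bits.any():
            mask_bits[0, 0] = True
        patch = QuantizedPatch(vals, mask_bits)
        for policy in ("strict-interior", "all-valid-neighbors"):
            try:
                t = build_ngtdm(patch, policy=policy)
            except EmptyNgtdmError:
                continue
            trip = texture_triplet(t)
            for v in (trip.coarseness, trip.contrast, trip.busyness):
                assert np.isfinite(v) and v >= 0
            assert t.p.sum() == pytest.approx(1.0, abs=1e-12)
            assert (t.s >= 0).all()

    def test_bin_translation_invariance(self, rng):
        """Shifting every bin by a constant leaves s, p (shifted),
        coarseness and contrast unchanged; busyness is label-dependent
        through its |i p(i) - j p(j)| denominator and may change."""
        for _ in range(50):
            patch = random_patch(rng, max_bins=8)
            shifted = QuantizedPatch(patch.values + 5, patch.valid)
            try:
                t0 = build_ngtdm(patch)
                t1 = build_ngtdm(shifted)
            except EmptyNgtdmError:
                continue
            np.testing.assert_allclose(t0.s[1:], t1.s[6:], atol=1e-12)
            np.testing.assert_allclose(t0.p[1:], t1.p[6:], atol=1e-15)
            assert coarseness(t0) == pytest.approx(coarseness(t1), rel=1e-12)
            assert contrast(t0) == pytest.approx(contrast(t1), rel=1e-12)

    def test_coarseness_busyness_anticorrelated_along_stripe_sweep(self):
        """From homogeneous to single-pixel stripes, coarseness never
        increases and busyness never decreases."""
        size = 8
        ones = np.ones((size, size), bool)
        cols = np.arange(size)
        coars_vals, busy_vals = [], []
        for width in (size, 4, 2, 1):
            vals = (cols // width) % 2 + 1
            patch = QuantizedPatch(np.tile(vals, (size, 1)), ones)
            t = build_ngtdm(patch, policy="all-valid-neighbors")
            coars_vals.append(coarseness(t))
            busy_vals.append(busyness(t))
        assert all(a >= b - 1e-12 for a, b in zip(coars_vals, coars_vals[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(busy_vals, busy_vals[1:]))
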