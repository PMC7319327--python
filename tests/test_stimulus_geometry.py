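"""Contour-patch geometry: enumeration counts, mask invariants, mirror
involution, descriptor oracles, and point-label consistency."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from fgpop import stimulus_geometry as sg


def test_straight_patch_is_half_plane():
    p = sg.generate_patch(1, (0.0, 0.0, 1.0))
    mask = p.mask()
    # the mask must equal the sign of the normal projection at every pixel
    pts = sg.lattice_points(p.scale)
    v = (pts - 0.0) @ p.normal()
    assert np.array_equal(mask, v > 0)
    assert 0.45 < mask.mean() < 0.55


@pytest.mark.parametrize("seed,targets", [
    (7, (0.75, 0.5, 1.0)),     # semicircular contour
    (3, (0.8, 0.3, 0.9)),
    (11, (-0.8, 0.25, 1.0)),   # concave-figure side
])
def test_descriptor_targets_met(seed, targets):
    p = sg.generate_patch(seed, targets)
    d = p.descriptors
    assert d["convexity"] == pytest.approx(targets[0], abs=0.05)
    assert d["closure"] == pytest.approx(targets[1], abs=0.05)
    assert d["symmetry"] == pytest.approx(targets[2], abs=0.06)


def test_closure_matches_turning_angle_oracle():
    """Closure recomputed from the rasterised contour polyline (sum of
    absolute turning angles / 2*pi) matches the semicircular target."""
    p = sg.generate_patch(7, (0.75, 0.5, 1.0))
    pts = p.polyline()
    seg = np.diff(pts, axis=0)
    seg = seg[np.linalg.norm(seg, axis=1) > 1e-12]
    ang = np.unwrap(np.arctan2(seg[:, 1], seg[:, 0]))
    turning = np.sum(np.abs(np.diff(ang)))
    assert turning / (2 * np.pi) == pytest.approx(0.5, abs=0.02)


def test_unreachable_descriptors_raise():
    with pytest.raises(sg.DescriptorError):
        sg.generate_patch(2, (0.0, 0.0, 0.3))       # straight but asymmetric
    with pytest.raises(sg.DescriptorError):
        sg.generate_patch(2, (0.1, 0.4, 1.0))       # flat arc exceeds frame
    with pytest.raises(sg.DescriptorError):
        sg.generate_patch(2, (0.0, 0.5, 1.0))       # closure without curvature


def test_mask_invariants_on_random_patches(bases12):
    for p in bases12:
        m = p.mask()
        assert 0 < m.sum() < m.size            # both regions non-empty
        assert ndimage.label(m)[1] == 1        # figure connected
        assert ndimage.label(~m)[1] == 1       # ground connected
        # conservation: figure + ground partition the patch
        assert m.sum() + (~m).sum() == m.size


def test_variant_counts_per_base(bases12):
    p = bases12[0]
    assert len(sg.make_variants(p, "natural")) == 2
    assert len(sg.make_variants(p, "filled")) == 8
    assert len(sg.make_variants(sg.SquareBase("sq", 8.0), "square")) == 64


def test_enumeration_counts(bases105):
    ss = sg.enumerate_set(bases105, ["natural", "filled", "square", "grating"],
                          seed=0)
    assert ss.family_counts == {
        "natural": 210, "filled": 840, "square": 64, "grating": 300,
    }


def test_grating_set_structure():
    gs = sg.grating_set()
    assert len(gs) == 300
    assert len({g.position for g in gs}) == 25
    assert len({(g.frequency, g.orientation) for g in gs}) == 12


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 500))
def test_mirror_involution(seed):
    """Reflecting about the centre tangent twice is the identity on the
    figure mask."""
    p = sg.random_patch(seed)
    v = [x for x in sg.make_variants(p, "filled")
         if x.mirrored and not x.translated][0]
    pts = sg.lattice_points(p.scale)
    assert np.allclose(v._base_coords(v._base_coords(pts)), pts, atol=1e-9)
    # mirrored mask at p equals the base mask at the reflected point
    rng = np.random.default_rng(seed)
    q = rng.uniform(-3.5, 3.5, size=(200, 2))
    assert np.array_equal(v.figure_at(q), p.figure_at(v._base_coords(q)))


def test_translated_mask_is_shifted_base_mask(bases12):
    p = bases12[0]
    v = [x for x in sg.make_variants(p, "filled")
         if x.translated and not x.mirrored][0]
    rng = np.random.default_rng(0)
    q = rng.uniform(-3.0, 3.0, size=(300, 2))
    shifted = q - v.offset * p.normal()
    assert np.array_equal(v.figure_at(q), p.figure_at(shifted))


def test_fg_at_agrees_with_mask_lookup_oracle(bases12):
    """fg_at must agree with a nearest-lattice-cell mask lookup at every
    point whose surrounding cells agree (i.e. away from the contour)."""
    rng = np.random.default_rng(42)
    for p in bases12[:4]:
        v = sg.make_variants(p, "filled")[0]
        mask = v.mask()
        scale = p.scale
        pts = rng.uniform(-scale / 2 + 0.2, scale / 2 - 0.2, size=(1000, 2))
        # nearest-cell index (mask rows are y, columns x)
        ix = np.clip(((pts[:, 0] + scale / 2) / scale * sg.GRID).astype(int),
                     0, sg.GRID - 1)
        iy = np.clip(((pts[:, 1] + scale / 2) / scale * sg.GRID).astype(int),
                     0, sg.GRID - 1)
        # keep points whose 3x3 cell neighbourhood is label-unanimous
        keep = np.ones(len(pts), dtype=bool)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                keep &= mask[np.clip(iy + dy, 0, sg.GRID - 1),
                             np.clip(ix + dx, 0, sg.GRID - 1)] == mask[iy, ix]
        assert keep.sum() > 700
        got = np.array([sg.fg_at(v, q)[0] == "figure" for q in pts[keep]])
        assert np.array_equal(got, mask[iy[keep], ix[keep]])


def test_fg_at_outside_frame_raises(bases12):
    v = sg.make_variants(bases12[0], "filled")[0]
    with pytest.raises(ValueError):
        sg.fg_at(v, (10.0, 0.0))


def test_mirror_polarity_convention():
    """A point on the dark figure side becomes (ground, dark) in the
    mirrored variant: FG flips, the spatial colour does not."""
    p = sg.generate_patch(3, (0.8, 0.1, 1.0))
    variants = sg.make_variants(p, "filled")
    orig = [v for v in variants if not v.mirrored and not v.translated
            and v.contrast == "dark"][0]
    mirr = [v for v in variants if v.mirrored and not v.translated
            and v.contrast == "dark"][0]
    pt = tuple(0.4 * p.normal())  # on the canonical figure side, off-axis
    assert sg.fg_at(orig, pt) == ("figure", "dark")
    assert sg.fg_at(mirr, pt) == ("ground", "dark")


def test_consistency_values_in_range(bases105):
    ss = sg.enumerate_set(bases105, ["natural", "filled"], seed=0)
    cons = np.array([v.consistency for v in ss.variants])
    assert np.all((cons > 0) & (cons < 1))
    nat = np.array([v.consistency for v in ss.variants if v.family == "natural"])
    fil = np.array([v.consistency for v in ss.variants if v.family == "filled"])
    # family means near the perceptual-consistency targets
    assert nat.mean() == pytest.approx(0.69, abs=0.05)
    assert fil.mean() == pytest.approx(0.77, abs=0.05)


def test_manifest_roundtrip(filled_set):
    import json

    doc = json.loads(sg.manifest(filled_set))
    assert doc["family_counts"]["filled"] == len(filled_set.variants)
    assert len(doc["variants"]) == len(filled_set.variants)
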