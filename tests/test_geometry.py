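"""Closed-form volumes, voxelization convergence and cortical shells."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from skelvox import geometry
from skelvox.geometry import BACKGROUND, CORTICAL, MARROW, ShapeSpec


class TestAnalyticVolume:
    @pytest.mark.parametrize(
        "spec, expected, rel",
        [
            # adult male lumbar body, elliptic cylinder pi*h*a*b/4
            (ShapeSpec("cylinder", 27, 35, 47), math.pi * 27 * 35 * 47 / 4, 1e-12),
            # pelvic acetabulum wall between nested cylinders
            (ShapeSpec("tube", 29, 26, 21), math.pi * 29 * (26**2 - 21**2) / 4, 1e-12),
            # sacral ala prism: h * a/2 * sqrt(b^2 - a^2/4)
            (ShapeSpec("prism", 19, 18, 38.5), 19 * 9 * math.sqrt(38.5**2 - 81), 1e-12),
            # newborn precarpal ellipsoid (pi/6) h a b
            (ShapeSpec("ellipsoid", 7.8, 12, 7.8), math.pi / 6 * 7.8 * 12 * 7.8, 1e-12),
            (ShapeSpec("box", 2, 30, 30), 1800.0, 1e-12),
        ],
    )
    def test_closed_forms(self, spec, expected, rel):
        assert spec.volume() == pytest.approx(expected, rel=rel)

    def test_reference_magnitudes(self):
        # values a reader can check by hand from the segment tables
        assert ShapeSpec("cylinder", 27, 35, 47).volume() == pytest.approx(34_884, rel=1e-4)
        assert ShapeSpec("tube", 29, 26, 21).volume() == pytest.approx(5_352, rel=1e-3)
        assert ShapeSpec("prism", 19, 18, 38.5).volume() == pytest.approx(6_401, rel=1e-3)

    @given(
        h=st.floats(1, 60), a=st.floats(1, 60), b=st.floats(1, 60),
        c=st.floats(1, 60), d=st.floats(1, 60),
    )
    @settings(max_examples=100, deadline=None)
    def test_deformed_cylinder_with_equal_bases_is_a_cylinder(self, h, a, b, c, d):
        dc = ShapeSpec("deformed_cylinder", h, a, b, c=a, d=b)
        assert dc.volume() == pytest.approx(ShapeSpec("cylinder", h, a, b).volume(), rel=1e-12)
        # and the general form integrates the linearly interpolated ellipse
        dc2 = ShapeSpec("deformed_cylinder", h, a, b, c=c, d=d)
        t = np.linspace(0, 1, 20001)
        numeric = np.trapezoid(math.pi / 4 * (a + (c - a) * t) * (b + (d - b) * t), t) * h
        assert dc2.volume() == pytest.approx(numeric, rel=1e-6)

    @pytest.mark.parametrize(
        "kind, kwargs, message",
        [
            ("box", dict(h=-1, a=1, b=1), "must be > 0"),
            ("tube", dict(h=5, a=3, b=4), "outer diameter"),
            ("prism", dict(h=5, a=10, b=5), "triangle does not exist"),
            ("cylinder", dict(h=5, a=3, b=4, c=1), "does not take c/d"),
            ("deformed_cylinder", dict(h=5, a=3, b=4), "requires positive c and d"),
        ],
    )
    def test_invalid_dimensions_are_named(self, kind, kwargs, message):
        with pytest.raises(geometry.ShapeError, match=message):
            ShapeSpec(kind, **kwargs)


class TestDefaultVoxelSize:
    def test_rule_and_clamp(self):
        assert geometry.default_voxel_size(0.29) == pytest.approx(0.203)
        assert geometry.default_voxel_size(0.10) == pytest.approx(0.07)
        assert geometry.default_voxel_size(0.02) == 0.04  # clamp floor
        assert geometry.default_voxel_size(1.0) == 0.25  # clamp ceiling


class TestVoxelization:
    def test_axis_aligned_box_is_exact(self):
        ph = geometry.voxelize_shape(ShapeSpec("box", 10, 10, 10), 0.5)
        assert int((ph.labels == MARROW).sum()) == 8000

    @pytest.mark.parametrize(
        "spec, voxel",
        [
            (ShapeSpec("cylinder", 27, 35, 47), 0.2),
            (ShapeSpec("ellipsoid", 7.8, 12, 7.8), 0.1),
            (ShapeSpec("tube", 29, 26, 21), 0.1),
            (ShapeSpec("prism", 19, 18, 38.5), 0.1),
            (ShapeSpec("deformed_cylinder", 17, 19, 11, c=11, d=8.3), 0.1),
        ],
    )
    def test_volume_converges_to_closed_form(self, spec, voxel):
        ph = geometry.voxelize_shape(spec, voxel)
        vol = (ph.labels == MARROW).sum() * voxel**3
        assert vol == pytest.approx(spec.volume(), rel=0.01)

    def test_convergence_is_first_order(self):
        spec = ShapeSpec("cylinder", 10, 14, 9)
        errs = []
        for voxel in (0.4, 0.2, 0.1):
            ph = geometry.voxelize_shape(spec, voxel)
            vol = (ph.labels == MARROW).sum() * voxel**3
            errs.append(abs(vol - spec.volume()) / spec.volume())
        # error roughly halves per refinement (allow stochastic slack)
        assert errs[2] < errs[0]
        assert errs[2] < 0.6 * errs[0]

    def test_grid_budget_refusal(self):
        with pytest.raises(MemoryError, match="exceeds the budget"):
            geometry.voxelize_shape(ShapeSpec("box", 30, 30, 30), 0.01, max_voxels=10_000)

    def test_labels_stay_inside_envelope(self):
        spec = ShapeSpec("ellipsoid", 8, 12, 8)
        ph = geometry.voxelize_shape(spec, 0.2)
        assert set(np.unique(ph.labels)) <= {BACKGROUND, MARROW}


class TestCorticalShell:
    def test_empty_spec_leaves_no_cortex(self):
        ph = geometry.voxelize_shape(ShapeSpec("box", 6.3, 15, 7.5), 0.1)
        out = geometry.apply_cortical_shell(ph, ShapeSpec("box", 6.3, 15, 7.5), {})
        assert int((out.labels == CORTICAL).sum()) == 0

    def test_cylinder_bases_stay_uncovered(self):
        spec = ShapeSpec("cylinder", 10, 14, 9)
        ph = geometry.voxelize_shape(spec, 0.1)
        out = geometry.apply_cortical_shell(ph, spec, {"lateral": 1.8})
        # base slices (extreme z) contain marrow at the center, not cortex
        base = out.labels[:, :, 0]
        assert (base == MARROW).sum() > 0
        nx, ny = base.shape
        assert base[nx // 2, ny // 2] == MARROW
        # but the equatorial slice rim is cortical
        mid = out.labels[:, :, out.labels.shape[2] // 2]
        xs = np.nonzero(mid.any(axis=1))[0]
        assert mid[xs[0], ny // 2] == CORTICAL

    def test_box_asymmetric_slabs_match_slab_oracle(self):
        # plate with 1.2 mm on one large face and 0.5 mm on the other
        spec = ShapeSpec("box", 4, 24, 24)
        ph = geometry.voxelize_shape(spec, 0.1)
        out = geometry.apply_cortical_shell(ph, spec, {"ab1": 1.2, "ab2": 0.5})
        shell = (out.labels == CORTICAL).sum() * 0.1**3
        assert shell == pytest.approx((1.2 + 0.5) * 24 * 24, rel=0.05)

    @pytest.mark.parametrize(
        "spec, cortical",
        [
            (ShapeSpec("box", 10, 20, 15), {"ha": 1.0, "ab1": 0.6}),
            (ShapeSpec("cylinder", 10, 14, 9), {"lateral": 1.1}),
            (ShapeSpec("tube", 29, 26, 21), {"lateral": 0.5, "ab1": 3.6}),
            (ShapeSpec("prism", 19, 18, 38.5), {"bh": 1.2, "ch": 1.2, "abb1": 1.2}),
            (ShapeSpec("ellipsoid", 7.8, 12, 7.8), {"total": 0.2}),
            (ShapeSpec("deformed_cylinder", 17, 22, 20, c=11, d=8.3), {"lateral": 0.8}),
        ],
    )
    def test_shell_volume_matches_eroded_closed_form(self, spec, cortical):
        analytic_shell = spec.volume() - geometry.spongiosa_volume(spec, cortical)
        voxel = 0.08
        ph = geometry.voxelize_shape(spec, voxel)
        out = geometry.apply_cortical_shell(ph, spec, cortical)
        shell = (out.labels == CORTICAL).sum() * voxel**3
        assert shell == pytest.approx(analytic_shell, rel=0.04)

    def test_volume_conservation_under_shelling(self):
        spec = ShapeSpec("cylinder", 10, 14, 9)
        ph = geometry.voxelize_shape(spec, 0.1)
        out = geometry.apply_cortical_shell(ph, spec, {"lateral": 1.0})
        assert (ph.labels != BACKGROUND).sum() == (out.labels != BACKGROUND).sum()

    def test_consuming_shell_is_rejected(self):
        spec = ShapeSpec("cylinder", 10, 6, 6)
        ph = geometry.voxelize_shape(spec, 0.1)
        with pytest.raises(geometry.CorticalError, match="consumes"):
            geometry.apply_cortical_shell(ph, spec, {"lateral": 3.0})

    def test_invalid_face_is_rejected(self):
        spec = ShapeSpec("cylinder", 10, 6, 6)
        ph = geometry.voxelize_shape(spec, 0.2)
        with pytest.raises(geometry.CorticalError, match="not valid"):
            geometry.apply_cortical_shell(ph, spec, {"ha": 0.5})
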