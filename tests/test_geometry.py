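"""Dice overlap, extents, slicing, boundary profiles and composites."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from tdekit import (RegionMask, boundary_profile, composite_average,
                    csf_compartment_volumes, dice, laser_position_measures,
                    measure_extent, slice_mask)


def _mask(arr, spacing=1.0):
    arr = np.asarray(arr, dtype=bool)
    return RegionMask(arr, (spacing,) * arr.ndim)


def disc_mask(n=64, r=20.0, center=None, spacing=1.0):
    center = center or (n / 2, n / 2)
    rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return _mask((rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= (r / spacing) ** 2,
                 spacing)


class TestDice:
    def test_identity(self):
        a = disc_mask()
        assert dice(a, a).dsc == 1.0

    def test_disjoint(self):
        a = np.zeros((8, 8), dtype=bool)
        b = np.zeros((8, 8), dtype=bool)
        a[0, 0] = b[7, 7] = True
        assert dice(_mask(a), _mask(b)).dsc == 0.0

    def test_hand_countable(self):
        """|A|=3, |B|=5, |A∩B|=2 gives 2*2/(3+5) = 0.5."""
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, :3] = True
        b[0, 1:4] = True
        b[1, :2] = True
        res = dice(_mask(a), _mask(b))
        assert res.dsc == 0.5
        assert res.area_a == 3.0 and res.area_b == 5.0

    def test_errors(self):
        with pytest.raises(ValueError):
            dice(_mask(np.zeros((4, 4))), _mask(np.zeros((5, 5))))
        with pytest.raises(ValueError):
            dice(_mask(np.ones((4, 4)), 1.0), _mask(np.ones((4, 4)), 2.0))
        with pytest.raises(ValueError):
            dice(_mask(np.zeros((4, 4))), _mask(np.zeros((4, 4))))

    @settings(deadline=None, max_examples=50)
    @given(hnp.arrays(bool, (6, 6)), hnp.arrays(bool, (6, 6)))
    def test_symmetry_bounds_and_union_dominance(self, a, b):
        if not (a.any() or b.any()):
            return
        r_ab = dice(_mask(a), _mask(b)).dsc
        assert dice(_mask(b), _mask(a)).dsc == r_ab
        assert 0.0 <= r_ab <= 1.0
        if a.any():
            assert dice(_mask(a), _mask(a | b)).dsc >= r_ab


class TestExtentAndSlice:
    def test_extent_physical_units(self):
        m = np.zeros((20, 20), dtype=bool)
        m[:10, :10] = True
        assert measure_extent(_mask(m)) == 100.0
        assert measure_extent(RegionMask(m, (0.5, 0.5))) == 25.0
        assert measure_extent(_mask(np.zeros((4, 4)))) == 0.0

    def test_synthetic_area_ratio(self, default_subject):
        s = default_subject
        spacing = (1.3, 1.3)
        tde = RegionMask(s.footprint, spacing)
        imm = RegionMask(s.immediate_mask, spacing)
        ratio = measure_extent(imm) / measure_extent(tde)
        assert ratio == pytest.approx(565 / 493, rel=0.02)

    def test_cube_slices(self):
        vol = np.zeros((10, 10, 10), dtype=bool)
        vol[2:8, 2:8, 2:8] = True
        cube = RegionMask(vol, (1.0, 1.0, 1.0))
        mid = slice_mask(cube, axis=0, index=5)
        assert mid.voxels.sum() == 36
        assert slice_mask(cube, axis=0, index=0).voxels.sum() == 0
        with pytest.raises(IndexError):
            slice_mask(cube, axis=0, index=10)
        with pytest.raises(ValueError):
            slice_mask(mid, axis=0, index=0)

    def test_sphere_section_area_analytic(self):
        """Slicing a radius-r sphere at offset d gives area ~ pi(r^2-d^2)."""
        n, r, d = 41, 12.0, 5.0
        rr, cc, zz = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        c = n // 2
        sphere = (rr - c) ** 2 + (cc - c) ** 2 + (zz - c) ** 2 <= r**2
        sec = slice_mask(RegionMask(sphere, (1.0,) * 3), axis=0, index=c + int(d))
        expected = np.pi * (r**2 - d**2)
        # discretization error scales with the section circumference
        assert abs(measure_extent(sec) - expected) < 2 * np.pi * np.sqrt(r**2 - d**2)


class TestBoundaryProfile:
    def test_disc_matches_chord_geometry(self):
        """Laser along the diameter: distances equal the half-chord width."""
        r_mm = 20.0
        mask = disc_mask(n=64, r=r_mm)
        laser = ((32 - r_mm, 32.0), (32 + r_mm, 32.0))
        stations, d1, d2 = boundary_profile(mask, laser, n_stations=20)
        x = (2 * stations - 1) * r_mm  # signed position along the diameter
        expected = np.sqrt(r_mm**2 - x**2)
        assert np.all(np.abs(d1 - expected) <= 1.0)
        assert np.all(np.abs(d2 - expected) <= 1.0)

    def test_ellipse_center_distance_is_semi_minor(self):
        a, b = 24.0, 10.0
        rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        mask = _mask(((rr - 32) / a) ** 2 + ((cc - 32) / b) ** 2 <= 1)
        laser = ((32 - a, 32.0), (32 + a, 32.0))
        stations, d1, d2 = boundary_profile(mask, laser, n_stations=21)
        mid = len(stations) // 2
        assert d1[mid] == pytest.approx(b, abs=1.0)
        assert d2[mid] == pytest.approx(b, abs=1.0)

    def test_star_convex_matches_dense_ray_march_oracle(self, rng):
        """Distances agree with an independent fine-stepped ray-marching oracle."""
        # star-convex blob: radius varies smoothly with angle
        n = 80
        rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        theta = np.arctan2(rr - 40, cc - 40)
        coeffs = rng.normal(0, 2, 3)
        radius = 18 + coeffs[0] * np.sin(theta) + coeffs[1] * np.cos(2 * theta) \
            + coeffs[2] * np.sin(3 * theta)
        mask = _mask((rr - 40) ** 2 + (cc - 40) ** 2 <= radius**2)
        laser = ((25.0, 40.0), (55.0, 40.0))
        stations, d1, d2 = boundary_profile(mask.__class__(mask.voxels, mask.spacing),
                                            laser, n_stations=20)

        p0, p1 = np.array(laser[0]), np.array(laser[1])
        d = p1 - p0
        dhat = d / np.hypot(*d)
        nhat = np.array([dhat[1], -dhat[0]])
        for i, t in enumerate(stations):
            P = p0 + t * d
            for sign, got in ((+1, d1[i]), (-1, d2[i])):
                s = np.arange(0, 60, 0.02)
                pts = P[None] + sign * s[:, None] * nhat[None]
                ij = np.round(pts).astype(int)
                ok = (ij[:, 0] >= 0) & (ij[:, 0] < n) & (ij[:, 1] >= 0) & (ij[:, 1] < n)
                inside = np.zeros(s.size, dtype=bool)
                inside[ok] = mask.voxels[ij[ok, 0], ij[ok, 1]]
                oracle = s[inside][-1] if inside.any() else 0.0
                assert abs(got - oracle) <= 1.0

    def test_station_outside_mask_gives_zero(self):
        mask = disc_mask(n=64, r=5.0)
        laser = ((2.0, 32.0), (62.0, 32.0))  # spans far beyond the lesion
        _, d1, d2 = boundary_profile(mask, laser, n_stations=20)
        assert d1[0] == 0.0 and d2[-1] == 0.0

    def test_degenerate_laser_errors(self):
        with pytest.raises(ValueError):
            boundary_profile(disc_mask(), ((5.0, 5.0), (5.0, 5.0)))

    def test_profile_integral_recovers_disc_area(self):
        """Midpoint-rule integral of the widths reproduces the mask area to 5%."""
        r_mm = 20.0
        mask = disc_mask(n=64, r=r_mm)
        laser = ((32 - r_mm, 32.0), (32 + r_mm, 32.0))
        stations, d1, d2 = boundary_profile(mask, laser, n_stations=20)
        L = 2 * r_mm
        integral = np.sum((d1 + d2) * (L / len(stations)))
        assert integral == pytest.approx(measure_extent(mask), rel=0.05)


class TestCompositeAverage:
    def test_identical_profiles_mean_and_zero_se(self):
        prof = (np.linspace(5, 10, 20), np.linspace(4, 9, 20))
        comp = composite_average([prof] * 6)
        assert np.allclose(comp.mean_side1, prof[0])
        assert np.allclose(comp.se_side1, 0.0)

    def test_self_comparison_never_significant(self):
        prof = [(np.random.default_rng(i).normal(8, 1, 20),
                 np.random.default_rng(i + 99).normal(8, 1, 20)) for i in range(8)]
        comp = composite_average(prof, group_b=prof, n_boot=500, seed=0)
        assert not comp.sig_side1.any() and not comp.sig_side2.any()

    def test_planted_offset_all_stations_flagged(self, rng):
        base = [(rng.normal(10, 0.2, 20), rng.normal(10, 0.2, 20))
                for _ in range(20)]
        shifted = [(a + 2.0, b + 2.0) for a, b in base]
        comp = composite_average(shifted, group_b=base, n_boot=1000, seed=1)
        assert comp.sig_side1.all() and comp.sig_side2.all()

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            composite_average([(np.ones(20), np.ones(20))] * 2)

    def test_false_flag_rate_calibrated(self, rng):
        """Exchangeable groups: per-station flag rate stays near nominal 0.05."""
        rates = []
        for _ in range(200):
            a = [(rng.normal(10, 1, 20), rng.normal(10, 1, 20)) for _ in range(30)]
            b = [(rng.normal(10, 1, 20), rng.normal(10, 1, 20)) for _ in range(30)]
            comp = composite_average(a, group_b=b, n_boot=1000,
                                     seed=int(rng.integers(2**31)))
            rates.append(np.concatenate([comp.sig_side1, comp.sig_side2]).mean())
        assert 0.03 <= np.mean(rates) <= 0.07


class TestLaserMeasures:
    LANDMARKS = {"mesial_wall_x": 10.0, "lateral_wall_x": 30.0,
                 "cranial_y": 5.0, "caudal_y": 25.0,
                 "ap_midline": (1.0, 0.0), "ac": (0.0, 0.0), "pc": (10.0, 0.0)}

    def test_wall_and_midpoint_positions(self):
        g = laser_position_measures((10.0, 15.0), (1, 0), (1, 0), self.LANDMARKS)
        assert g.ml_position == 0.0
        g = laser_position_measures((20.0, 15.0), (1, 0), (1, 0), self.LANDMARKS)
        assert g.ml_position == 0.5 and g.si_position == 0.5

    def test_angles(self):
        g = laser_position_measures((20.0, 15.0), (1, 0), (0, 1), self.LANDMARKS)
        assert g.axial_angle == pytest.approx(0.0, abs=1e-9)
        assert g.sagittal_angle == pytest.approx(90.0)

    def test_outside_span_warns(self):
        with pytest.warns(UserWarning):
            laser_position_measures((40.0, 15.0), (1, 0), (1, 0), self.LANDMARKS)

    def test_coincident_walls_error(self):
        bad = dict(self.LANDMARKS, lateral_wall_x=10.0)
        with pytest.raises(ValueError):
            laser_position_measures((20.0, 15.0), (1, 0), (1, 0), bad)


class TestCsfVolumes:
    def test_volumes_and_empty(self):
        a = np.zeros((10, 10, 10), dtype=bool)
        a[:10, :10, :10][:10, :5] = True
        above = RegionMask(a, (1.0,) * 3)
        empty = RegionMask(np.zeros_like(a), (1.0,) * 3)
        va, vl = csf_compartment_volumes(above, empty)
        assert va == 500.0 and vl == 0.0

    def test_overlap_warns(self):
        a = np.ones((4, 4, 4), dtype=bool)
        with pytest.warns(UserWarning):
            csf_compartment_volumes(RegionMask(a, (1.0,) * 3),
                                    RegionMask(a, (1.0,) * 3))

    def test_synthetic_csf_fraction_exact(self, default_subject):
        csf = default_subject.csf_mask
        frac = csf.sum() / csf.size
        assert frac == pytest.approx(0.06, rel=0.02)
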