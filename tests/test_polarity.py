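"""Polarity pipeline: per-cilium vectors, per-cell and field metrics, groups."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import special

from ciliapol import (
    Cilium,
    Point2D,
    cell_polarity,
    cilium_angle,
    circular_summary,
    compare_groups,
    field_polarity,
    generate_study,
    generate_tissue,
    CONTROL_PRESET,
    TissueParams,
)
from ciliapol.geometry import InvalidGeometryError

from conftest import make_cell, make_field

DEG = 180.0 / math.pi


def vm_csd_deg(kappa: float) -> float:
    return DEG * math.sqrt(-2.0 * math.log(special.i1(kappa) / special.i0(kappa)))


class TestCiliumAngle:
    @pytest.mark.parametrize(
        "gtub, expected", [((1, 0), 0.0), ((0, -2), -90.0), ((-1, 0), -180.0)]
    )
    def test_angles(self, gtub, expected):
        c = Cilium(fop=Point2D(0, 0), gtub=Point2D(*gtub))
        assert cilium_angle(c) == pytest.approx(expected)

    def test_coincident_points_skipped_not_fatal(self):
        cell = make_cell(cilium_angles_deg=[0.0, 0.0, 0.0])
        cell.cilia.append(Cilium(fop=Point2D(1, 1), gtub=Point2D(1, 1)))
        with pytest.warns(UserWarning, match="coincident"):
            pol = cell_polarity(cell)
        assert pol.n_cilia == 3  # degenerate cilium excluded from the count


class TestCellPolarity:
    def test_aligned_patch_cell(self):
        """Radius-10 cell, patch offset 3 px along +x, 10 cilia at 0 deg."""
        cell = make_cell(disp_angle_deg=0.0, disp_len=3.0, cilium_angles_deg=[0.0] * 10)
        pol = cell_polarity(cell, pixel_size_um=0.09)
        assert pol.disp_angle_deg == pytest.approx(0.0, abs=1e-9)
        assert pol.csd_deg == pytest.approx(0.0, abs=1e-9)
        assert pol.orient_valid
        assert pol.mean_orient_deg == pytest.approx(0.0, abs=1e-9)
        # strength = 3 / sqrt(area/pi); the 64-gon area is marginally under pi r^2
        assert pol.strength == pytest.approx(0.3, abs=1e-3)
        assert pol.n_cilia == 10
        assert pol.cell_area_um2 == pytest.approx(math.pi * 10**2 * 0.09**2, rel=0.01)

    def test_uniformly_spread_cilia_invalidate_orientation(self):
        angles = list(np.arange(10) * 36.0)  # evenly spread over 360
        cell = make_cell(cilium_angles_deg=angles)
        pol = cell_polarity(cell)
        assert math.isinf(pol.csd_deg)
        assert not pol.orient_valid
        assert pol.mean_orient_deg is None

    def test_csd_matches_vonmises_closed_form(self, rng):
        angles = np.degrees(rng.vonmises(0.2, 4.0, 5000))
        cell = make_cell(cilium_angles_deg=list(angles))
        pol = cell_polarity(cell)
        assert pol.csd_deg == pytest.approx(vm_csd_deg(4.0), rel=0.02)

    def test_primary_cilium_mode(self):
        """No patch and exactly one cilium: basal body stands in for the patch."""
        cell = make_cell(
            disp_angle_deg=90.0, disp_len=4.0, cilium_angles_deg=[30.0], with_patch=False
        )
        pol = cell_polarity(cell)
        assert pol.disp_angle_deg == pytest.approx(90.0, abs=1e-6)
        assert pol.csd_deg is None  # 1 cilium < min_cilia: rotational undefined
        assert not pol.orient_valid
        assert pol.patch_area_um2 is None

    def test_no_patch_no_cilia_displacement_undefined(self):
        cell = make_cell(cilium_angles_deg=None, with_patch=False)
        pol = cell_polarity(cell)
        assert pol.disp_angle_deg is None
        assert pol.strength is None

    def test_below_min_cilia_csd_undefined_not_zero(self):
        cell = make_cell(cilium_angles_deg=[10.0, 10.0])
        pol = cell_polarity(cell)
        assert pol.csd_deg is None


class TestFieldPolarity:
    def test_uniform_displacement_gives_zero_vpatchD(self):
        cells = [
            make_cell(cell_id=f"c{i}", center=(30.0 * i, 0.0), disp_angle_deg=0.0)
            for i in range(5)
        ]
        fp = field_polarity(make_field(cells))
        assert fp.field_disp_mean_deg == pytest.approx(0.0, abs=1e-9)
        for c in fp.cells:
            assert c.vpatchD_deg == pytest.approx(0.0, abs=1e-9)

    def test_single_deviant_cell_vs_direct_recomputation(self):
        """9 cells at 0 deg, one at 90: check against the hand-computed mean."""
        angles = [0.0] * 9 + [90.0]
        cells = [
            make_cell(cell_id=f"c{i}", center=(30.0 * i, 0.0), disp_angle_deg=a)
            for i, a in enumerate(angles)
        ]
        fp = field_polarity(make_field(cells))
        # direct recomputation: circular mean of the ten unit vectors
        expected_mean = math.degrees(math.atan2(np.mean(np.sin(np.radians(angles))),
                                                np.mean(np.cos(np.radians(angles)))))
        assert fp.field_disp_mean_deg == pytest.approx(expected_mean, abs=1e-9)
        assert fp.cells[-1].vpatchD_deg == pytest.approx(90.0 - expected_mean, abs=1e-6)

    def test_aligned_disp_and_orientation_gives_zero_vpatchDO(self):
        cells = [
            make_cell(
                cell_id=f"c{i}",
                center=(30.0 * i, 0.0),
                disp_angle_deg=30.0,
                cilium_angles_deg=[30.0] * 5,
            )
            for i in range(3)
        ]
        fp = field_polarity(make_field(cells))
        for c in fp.cells:
            assert c.vpatchDO_deg == pytest.approx(0.0, abs=1e-6)

    def test_needs_two_displacement_cells(self):
        cells = [make_cell(with_patch=False, cilium_angles_deg=None) for _ in range(3)]
        with pytest.raises(ValueError, match="displacement"):
            field_polarity(make_field(cells))

    def test_invalid_contour_excluded_with_warning(self):
        from ciliapol import CellRecord, Polygon

        good = [make_cell(cell_id=f"c{i}", center=(30.0 * i, 0.0)) for i in range(3)]
        bad = CellRecord(
            cell_id="bad", contour=Polygon([(0, 0), (1, 1), (2, 2)])  # collinear
        )
        with pytest.warns(UserWarning, match="bad"):
            fp = field_polarity(make_field(good + [bad]))
        assert len(fp.cells) == 3

    def test_vpatchD_resultant_direction_near_zero(self):
        fieldrec, _ = generate_tissue(TissueParams(n_cells=80, seed=3))
        fp = field_polarity(fieldrec)
        vd = [c.vpatchD_deg for c in fp.cells if c.vpatchD_deg is not None]
        s = circular_summary(vd)
        # the field mean is the reference, so the vpatchD sample re-centers on 0
        assert abs(s.mean_deg) < 1e-6

    def test_csd_threshold_exclusion_count_matches(self):
        fieldrec, _ = generate_tissue(
            TissueParams(n_cells=60, kappa_cil=1.0, seed=9)  # many high-CSD cells
        )
        fp = field_polarity(fieldrec, csd_threshold_deg=45.0)
        failing = [c for c in fp.cells if c.csd_deg is None or c.csd_deg > 45.0]
        without_vpatchO = [c for c in fp.cells if c.vpatchO_deg is None]
        assert len(failing) == len(without_vpatchO)
        assert {c.cell_id for c in failing} == {c.cell_id for c in without_vpatchO}

    def test_rigid_motion_invariance(self):
        """Translating and rotating a whole field leaves relative metrics fixed."""
        fieldrec, _ = generate_tissue(TissueParams(n_cells=30, seed=4))
        fp0 = field_polarity(fieldrec)

        theta, tx, ty = math.radians(37.0), 123.4, -55.5
        c, s = math.cos(theta), math.sin(theta)

        def move(p: Point2D) -> Point2D:
            return Point2D(c * p.x - s * p.y + tx, s * p.x + c * p.y + ty)

        from ciliapol import CellRecord, Cilium as Cil, Polygon

        moved_cells = []
        for cell in fieldrec.cells:
            moved_cells.append(
                CellRecord(
                    cell_id=cell.cell_id,
                    contour=Polygon([move(p) for p in cell.contour.vertices]),
                    patch_contour=Polygon([move(p) for p in cell.patch_contour.vertices]),
                    cilia=[Cil(fop=move(x.fop), gtub=move(x.gtub)) for x in cell.cilia],
                )
            )
        fp1 = field_polarity(make_field(moved_cells, field_id="moved"))
        for a, b in zip(fp0.cells, fp1.cells):
            assert b.vpatchD_deg == pytest.approx(a.vpatchD_deg, abs=1e-6)
            assert b.vpatchDO_deg == pytest.approx(a.vpatchDO_deg, abs=1e-6)
            if a.vpatchO_deg is not None:
                assert b.vpatchO_deg == pytest.approx(a.vpatchO_deg, abs=1e-6)
            assert b.csd_deg == pytest.approx(a.csd_deg, abs=1e-6)
            assert b.strength == pytest.approx(a.strength, rel=1e-6)
            assert b.cell_area_um2 == pytest.approx(a.cell_area_um2, rel=1e-6)

    def test_vpatchD_dispersion_monotone_in_kappa(self):
        """Lower kappa_D must give a wider vpatchD sample, across seeds."""
        kappas = [8.0, 4.0, 2.0, 1.0, 0.5]
        ordered = 0
        n_seeds = 20
        for seed in range(n_seeds):
            csds = []
            for k in kappas:
                fieldrec, _ = generate_tissue(
                    TissueParams(n_cells=150, kappa_D=k, n_cilia_range=(0, 0), seed=seed)
                )
                fp = field_polarity(fieldrec)
                vd = [c.vpatchD_deg for c in fp.cells if c.vpatchD_deg is not None]
                csds.append(circular_summary(vd).csd_deg)
            ordered += all(a < b for a, b in zip(csds, csds[1:]))
        assert ordered >= 19  # >= 95% of seeds strictly ordered


class TestCompareGroups:
    def _quantified_group(self, params, n_fields, seed, label):
        ctrl, _ = generate_study(params, params, n_fields=n_fields, seed=seed,
                                 labels=(label, label + "_b"))
        return [field_polarity(f) for f, _ in ctrl]

    def test_same_group_gives_null_results(self):
        group = self._quantified_group(CONTROL_PRESET, 2, 11, "g")
        comp = compare_groups(group, group, n_permutations=199, seed=0)
        for res in comp.watson.values():
            assert res.u2 == pytest.approx(0.0, abs=1e-12)
            assert res.p_value == pytest.approx(1.0)
        for name, res in comp.ttests.items():
            assert res.t == pytest.approx(0.0, abs=1e-12)

    def test_contributing_counts_match_defined_cells(self):
        a = self._quantified_group(CONTROL_PRESET, 2, 21, "a")
        b = self._quantified_group(CONTROL_PRESET, 2, 22, "b")
        comp = compare_groups(a, b, n_permutations=199, seed=0)
        n_vpO_a = sum(1 for f in a for c in f.cells if c.vpatchO_deg is not None)
        assert comp.watson["vpatchO_deg"].n1 == n_vpO_a

    def test_kappa_cil_contrast_hits_csd_not_vpatchD(self):
        """Groups differing only in within-cell alignment: the CSD t test fires,
        the vpatchD Watson test stays quiet in >= 90% of replicates."""
        import dataclasses

        base = dataclasses.replace(
            CONTROL_PRESET, n_cells=40, n_cilia_range=(10, 20)
        )
        low_cil = dataclasses.replace(base, kappa_cil=2.0)
        csd_hits = vpd_quiet = 0
        n_rep = 50
        for i in range(n_rep):
            a_fields, b_fields = generate_study(base, low_cil, n_fields=2, seed=1000 + i)
            a = [field_polarity(f) for f, _ in a_fields]
            b = [field_polarity(f) for f, _ in b_fields]
            comp = compare_groups(a, b, n_permutations=99, seed=i)
            csd_hits += comp.ttests["csd_deg"].p_value < 0.05
            vpd_quiet += comp.watson["vpatchD_deg"].p_value >= 0.05
        assert csd_hits >= 45
        assert vpd_quiet >= 45
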