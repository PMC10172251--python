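"""Planar-cell-polarity quantification for multiciliated epithelial fields.

From traced cell contours, ciliary-patch contours and per-cilium marker
point pairs (basal-body point -> basal-foot point), this module derives:

* per-cilium beating vectors (vCil) — the basal foot points in the
  effective-stroke direction, so the marker-pair vector encodes beating
  direction;
* per-cell translational polarity — the displacement of the ciliary patch
  centroid from the cell centroid, its angle, and a dimensionless
  ``strength`` (displacement length over the equivalent cell radius
  ``sqrt(area/pi)``);
* per-cell rotational polarity — the circular mean and circular standard
  deviation (CSD) of the cell's vCil angles; cells whose CSD exceeds a
  threshold (default 45 deg) have no defined mean beating orientation;
* field-referenced angle families: VpatchD (cell displacement angle minus
  the field's mean displacement direction), VpatchO (cell mean orientation
  minus the field's mean orientation, for CSD-valid cells), and VpatchD&O
  (per-cell angle between displacement and mean orientation);
* group comparisons: Watson U² permutation tests on the circular families
  and two-sample t tests on the linear quantities (CSD, strength, areas,
  cilia counts).

Cells with undefined metrics are never imputed; each statistic reports the
number of cells actually contributing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .circstats import (
    TTestResult,
    WatsonResult,
    angular_difference,
    circular_summary,
    two_sample_t,
    watson_u2_test,
)
from .geometry import (
    InvalidGeometryError,
    Point2D,
    Polygon,
    polygon_area,
    polygon_centroid,
    vector_between,
)

__all__ = [
    "Cilium",
    "CellRecord",
    "FieldRecord",
    "CellPolarity",
    "FieldPolarity",
    "GroupComparison",
    "cilium_angle",
    "cell_polarity",
    "field_polarity",
    "compare_groups",
    "DEFAULT_PIXEL_SIZE_UM",
    "DEFAULT_CSD_THRESHOLD_DEG",
    "DEFAULT_MIN_CILIA",
]

DEFAULT_PIXEL_SIZE_UM = 0.09  # acquisition pixel size, 90 nm
DEFAULT_CSD_THRESHOLD_DEG = 45.0
DEFAULT_MIN_CILIA = 3

CIRCULAR_METRICS = ("vpatchD_deg", "vpatchO_deg", "vpatchDO_deg")
LINEAR_METRICS = ("csd_deg", "strength", "cell_area_um2", "patch_area_um2", "n_cilia")


@dataclass(frozen=True)
class Cilium:
    """One cilium's marker pair: basal-body point and basal-foot point."""

    fop: Point2D
    gtub: Point2D


@dataclass
class CellRecord:
    cell_id: str
    contour: Polygon
    patch_contour: Optional[Polygon] = None
    cilia: list[Cilium] = field(default_factory=list)
    extra: dict = field(default_factory=dict)


@dataclass
class FieldRecord:
    """One imaged tissue field of traced cells."""

    field_id: str
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    group_label: str = ""
    cells: list[CellRecord] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass(frozen=True)
class CellPolarity:
    """Per-cell polarity metrics; ``None`` marks an undefined quantity."""

    cell_id: str
    disp_angle_deg: Optional[float]
    disp_length_px: Optional[float]
    mean_orient_deg: Optional[float]
    csd_deg: Optional[float]  # may be the inf sentinel (zero resultant)
    orient_valid: bool
    strength: Optional[float]
    cell_area_um2: float
    patch_area_um2: Optional[float]
    n_cilia: int
    vpatchD_deg: Optional[float] = None
    vpatchO_deg: Optional[float] = None
    vpatchDO_deg: Optional[float] = None


@dataclass(frozen=True)
class FieldPolarity:
    field_id: str
    group_label: str
    field_disp_mean_deg: Optional[float]
    field_orient_mean_deg: Optional[float]
    cells: tuple[CellPolarity, ...]


def cilium_angle(c: Cilium) -> float:
    """Beating direction of one cilium: angle of the fop -> gtub vector."""
    v = vector_between(c.fop, c.gtub)
    return v.angle_deg  # raises InvalidGeometryError for coincident points


def _usable_cilium_angles(cell: CellRecord) -> list[float]:
    angles = []
    n_skipped = 0
    for c in cell.cilia:
        v = vector_between(c.fop, c.gtub)
        if v.is_zero:
            n_skipped += 1
            continue
        angles.append(v.angle_deg)
    if n_skipped:
        warnings.warn(
            f"cell {cell.cell_id!r}: skipped {n_skipped} cilium/cilia with "
            "coincident marker points",
            stacklevel=3,
        )
    return angles


def cell_polarity(
    cell: CellRecord,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    csd_threshold_deg: float = DEFAULT_CSD_THRESHOLD_DEG,
    min_cilia: int = DEFAULT_MIN_CILIA,
) -> CellPolarity:
    """Translational and rotational polarity of a single cell.

    The displacement vector runs from the cell contour centroid to the patch
    contour centroid; a cell with no patch contour but exactly one cilium is
    treated in primary-cilium mode (the basal-body point stands in for the
    patch center).  Rotational metrics require at least ``min_cilia`` usable
    cilia; the mean orientation is only considered valid when the CSD is at
    or below ``csd_threshold_deg``.
    """
    area_px = polygon_area(cell.contour)  # raises on degenerate contours
    centroid = polygon_centroid(cell.contour)
    px2_to_um2 = pixel_size_um**2
    cell_area_um2 = area_px * px2_to_um2

    angles = _usable_cilium_angles(cell)
    n_cilia = len(angles)

    # translational polarity: patch centroid, or the single cilium's basal body
    patch_area_um2: Optional[float] = None
    target: Optional[Point2D] = None
    if cell.patch_contour is not None:
        target = polygon_centroid(cell.patch_contour)
        patch_area_um2 = polygon_area(cell.patch_contour) * px2_to_um2
    elif n_cilia == 1:
        target = cell.cilia[0].fop

    disp_angle: Optional[float] = None
    disp_len: Optional[float] = None
    strength: Optional[float] = None
    if target is not None:
        v = vector_between(centroid, target)
        disp_len = v.length
        strength = disp_len / math.sqrt(area_px / math.pi)
        if not v.is_zero:
            disp_angle = v.angle_deg

    # rotational polarity
    mean_orient: Optional[float] = None
    csd: Optional[float] = None
    if n_cilia >= min_cilia:
        summ = circular_summary(angles)
        csd = summ.csd_deg
        if summ.mean_defined:
            mean_orient = summ.mean_deg
    orient_valid = csd is not None and csd <= csd_threshold_deg and mean_orient is not None

    return CellPolarity(
        cell_id=cell.cell_id,
        disp_angle_deg=disp_angle,
        disp_length_px=disp_len,
        mean_orient_deg=mean_orient,
        csd_deg=csd,
        orient_valid=orient_valid,
        strength=strength,
        cell_area_um2=cell_area_um2,
        patch_area_um2=patch_area_um2,
        n_cilia=n_cilia,
    )


def field_polarity(
    fieldrec: FieldRecord,
    csd_threshold_deg: float = DEFAULT_CSD_THRESHOLD_DEG,
    min_cilia: int = DEFAULT_MIN_CILIA,
) -> FieldPolarity:
    """Field-level polarity: field mean vectors and the Vpatch angle families.

    The field mean displacement (orientation) direction is the unit-weighted
    circular mean of the per-cell displacement angles (valid mean
    orientations).  VpatchD/VpatchO are the per-cell angles relative to those
    field means; VpatchD&O is the per-cell angle between displacement and
    mean beating orientation, defined for displacement-bearing, CSD-valid
    cells.
    """
    per_cell: list[CellPolarity] = []
    for cell in fieldrec.cells:
        try:
            per_cell.append(
                cell_polarity(
                    cell,
                    pixel_size_um=fieldrec.pixel_size_um,
                    csd_threshold_deg=csd_threshold_deg,
                    min_cilia=min_cilia,
                )
            )
        except InvalidGeometryError as exc:
            warnings.warn(
                f"cell {cell.cell_id!r} excluded: {exc}", stacklevel=2
            )

    disp_angles = [c.disp_angle_deg for c in per_cell if c.disp_angle_deg is not None]
    if len(disp_angles) < 2:
        raise ValueError(
            f"field {fieldrec.field_id!r}: need >= 2 cells with defined "
            f"displacement, got {len(disp_angles)}"
        )
    disp_summary = circular_summary(disp_angles)
    field_disp_mean = disp_summary.mean_deg if disp_summary.mean_defined else None
    if field_disp_mean is None:
        warnings.warn(
            f"field {fieldrec.field_id!r}: zero-resultant displacement sample; "
            "VpatchD undefined for all cells",
            stacklevel=2,
        )

    orient_angles = [c.mean_orient_deg for c in per_cell if c.orient_valid]
    field_orient_mean: Optional[float] = None
    if orient_angles:
        orient_summary = circular_summary(orient_angles)
        if orient_summary.mean_defined:
            field_orient_mean = orient_summary.mean_deg

    cells_out = []
    for c in per_cell:
        vpatchD = vpatchO = vpatchDO = None
        if c.disp_angle_deg is not None and field_disp_mean is not None:
            vpatchD = float(angular_difference(c.disp_angle_deg, field_disp_mean))
        if c.orient_valid and field_orient_mean is not None:
            vpatchO = float(angular_difference(c.mean_orient_deg, field_orient_mean))
        if c.disp_angle_deg is not None and c.orient_valid:
            vpatchDO = float(angular_difference(c.disp_angle_deg, c.mean_orient_deg))
        cells_out.append(
            replace(c, vpatchD_deg=vpatchD, vpatchO_deg=vpatchO, vpatchDO_deg=vpatchDO)
        )

    return FieldPolarity(
        field_id=fieldrec.field_id,
        group_label=fieldrec.group_label,
        field_disp_mean_deg=field_disp_mean,
        field_orient_mean_deg=field_orient_mean,
        cells=tuple(cells_out),
    )


@dataclass(frozen=True)
class GroupComparison:
    """Pooled two-group statistics with per-metric contributing counts."""

    label_a: str
    label_b: str
    watson: dict[str, Optional[WatsonResult]]
    ttests: dict[str, Optional[TTestResult]]
    n_csd_inf_excluded: tuple[int, int]


def _pool_metric(group: Sequence[FieldPolarity], name: str) -> np.ndarray:
    vals = [
        getattr(c, name)
        for f in group
        for c in f.cells
        if getattr(c, name) is not None
    ]
    return np.asarray(vals, dtype=float)


def compare_groups(
    group_a: Sequence[FieldPolarity],
    group_b: Sequence[FieldPolarity],
    n_permutations: int = 999,
    seed: int = 0,
) -> GroupComparison:
    """Compare two groups of quantified fields.

    Per-cell angles are pooled across the fields of each group.  The three
    circular families get Watson U² permutation tests; CSD (inf-sentinel
    cells excluded and counted), strength, areas and cilia counts get
    pooled-variance t tests.  Metrics with fewer than two defined values in
    either group are reported as not testable (``None``).
    """
    watson: dict[str, Optional[WatsonResult]] = {}
    for i, name in enumerate(CIRCULAR_METRICS):
        a = _pool_metric(group_a, name)
        b = _pool_metric(group_b, name)
        if a.size < 2 or b.size < 2:
            watson[name] = None
            continue
        watson[name] = watson_u2_test(a, b, n_permutations=n_permutations, seed=seed + i)

    n_inf_a = n_inf_b = 0
    ttests: dict[str, Optional[TTestResult]] = {}
    for name in LINEAR_METRICS:
        a = _pool_metric(group_a, name)
        b = _pool_metric(group_b, name)
        if name == "csd_deg":
            n_inf_a = int(np.sum(np.isinf(a)))
            n_inf_b = int(np.sum(np.isinf(b)))
            a = a[np.isfinite(a)]
            b = b[np.isfinite(b)]
        try:
            ttests[name] = two_sample_t(a, b)
        except ValueError:
            ttests[name] = None

    return GroupComparison(
        label_a=group_a[0].group_label if group_a else "",
        label_b=group_b[0].group_label if group_b else "",
        watson=watson,
        ttests=ttests,
        n_csd_inf_excluded=(n_inf_a, n_inf_b),
    )
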