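"""Shared fixtures: small hand-built cells and fields for the polarity tests."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ciliapol import CellRecord, Cilium, FieldRecord, Point2D, Polygon


def regular_polygon(cx: float, cy: float, radius: float, n: int = 64) -> Polygon:
    phi = np.linspace(0.0, 2.0 * math.pi, n + 1)[:-1]
    return Polygon(np.column_stack([cx + radius * np.cos(phi), cy + radius * np.sin(phi)]))


def make_cell(
    cell_id: str = "c0",
    center: tuple[float, float] = (0.0, 0.0),
    radius: float = 10.0,
    disp_angle_deg: float | None = 0.0,
    disp_len: float = 3.0,
    cilium_angles_deg: list[float] | None = None,
    with_patch: bool = True,
) -> CellRecord:
    """A circular cell with an offset circular patch and specified vCil angles."""
    cx, cy = center
    contour = regular_polygon(cx, cy, radius)
    patch = None
    px, py = cx, cy
    if disp_angle_deg is not None:
        a = math.radians(disp_angle_deg)
        px, py = cx + disp_len * math.cos(a), cy + disp_len * math.sin(a)
    if with_patch:
        patch = regular_polygon(px, py, radius * 0.3, n=16)
    cilia = []
    for ang in cilium_angles_deg or []:
        r = math.radians(ang)
        fop = Point2D(px, py)
        cilia.append(Cilium(fop=fop, gtub=Point2D(px + math.cos(r), py + math.sin(r))))
    return CellRecord(cell_id=cell_id, contour=contour, patch_contour=patch, cilia=cilia)


def make_field(cells, field_id="f0", pixel_size_um=0.09, group_label="test") -> FieldRecord:
    return FieldRecord(
        field_id=field_id, pixel_size_um=pixel_size_um, group_label=group_label, cells=list(cells)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
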