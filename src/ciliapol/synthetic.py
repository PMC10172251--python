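"""Ground-truth generators for polarity fields and beating-cilium recordings.

Two emulators cover the two input kinds the analysis consumes:

* **Tissue fields** — a Voronoi tessellation of Lloyd-relaxed random seeds
  stands in for an epithelial sheet.  Each cell draws a displacement
  direction and a beating-orientation direction from von Mises
  distributions centered on a global tissue direction ``mu``, with
  separately controllable concentrations ``kappa_D`` (translational
  polarity), ``kappa_O`` (cell-to-cell rotational coordination) and
  ``kappa_cil`` (within-cell cilium alignment).  The two-level hierarchy
  makes translational and rotational polarity independently tunable, which
  is exactly what the analysis is supposed to tease apart.

* **Cilium recordings** — intensity traces and rendered image stacks whose
  Gaussian-spot cilia oscillate at known frequencies, with mono-exponential
  photobleaching and Gaussian noise, at the acquisition geometry of the
  study design (600 frames at 21 frames/s).

von Mises is the maximum-entropy circular analogue of the Gaussian and has
a closed-form circular standard deviation, which the test suite uses as an
independent oracle.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Polygon as _ShapelyPolygon
from shapely.geometry import box as _shapely_box

from .cbf import DEFAULT_FS_HZ, DEFAULT_N_FRAMES, ImageStack, Trace
from .geometry import Point2D, Polygon
from .polarity import CellRecord, Cilium, FieldRecord, DEFAULT_PIXEL_SIZE_UM

__all__ = [
    "TissueParams",
    "GroundTruth",
    "VideoParams",
    "generate_tissue",
    "generate_trace",
    "generate_stack",
    "generate_study",
    "CONTROL_PRESET",
    "MUTANT_PRESET",
]

_GTUB_OFFSET_UM = 0.5  # physical basal-body -> basal-foot marker separation


@dataclass(frozen=True)
class TissueParams:
    """Generator settings for one synthetic epithelial field."""

    n_cells: int = 50
    field_size_px: float = 600.0
    mu_deg: float = 0.0
    kappa_D: float = 6.0
    kappa_O: float = 6.0
    kappa_cil: float = 8.0
    disp_frac: float = 0.3  # patch displacement as fraction of cell radius
    patch_frac: float = 0.35  # patch radius as fraction of cell radius
    n_cilia_range: tuple[int, int] = (15, 40)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 4:
            raise ValueError("need at least 4 cells for a tessellation")
        if min(self.kappa_D, self.kappa_O, self.kappa_cil) < 0:
            raise ValueError("von Mises concentrations must be >= 0")
        if not 0 <= self.disp_frac < 1:
            raise ValueError("disp_frac must be in [0, 1)")
        if self.disp_frac + self.patch_frac >= 1:
            raise ValueError("patch would not fit inside the cell")
        lo, hi = self.n_cilia_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid n_cilia_range")


# presets qualitatively matching a coordinated control tissue vs a
# polarity-impaired mutant tissue
CONTROL_PRESET = TissueParams(kappa_D=6.0, kappa_O=6.0, kappa_cil=8.0)
MUTANT_PRESET = TissueParams(kappa_D=1.0, kappa_O=1.0, kappa_cil=2.0)


@dataclass(frozen=True)
class GroundTruth:
    """True generator angles, cell by cell, for recovery tests."""

    mu_deg: float
    disp_angles_deg: tuple[float, ...]
    orient_angles_deg: tuple[float, ...]
    cilium_angles_deg: tuple[tuple[float, ...], ...]
    params: TissueParams


def _vonmises_deg(rng: np.random.Generator, mu_deg: float, kappa: float, size) -> np.ndarray:
    """von Mises sample in degrees wrapped to [-180, 180); kappa=0 is uniform."""
    rad = rng.vonmises(math.radians(mu_deg), kappa, size=size)
    return (np.degrees(rad) + 180.0) % 360.0 - 180.0


def _bounded_voronoi(points: np.ndarray, size: float) -> list[np.ndarray]:
    """Voronoi cells of ``points`` clipped to [0, size]^2 via mirror points."""
    mirrored = [points]
    for axis, bound in ((0, 0.0), (0, size), (1, 0.0), (1, size)):
        m = points.copy()
        m[:, axis] = 2 * bound - m[:, axis]
        mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    cells = []
    clip = _shapely_box(0.0, 0.0, size, size)
    for i in range(points.shape[0]):
        region = vor.regions[vor.point_region[i]]
        verts = vor.vertices[region]
        # regions are convex; order vertices by angle around their mean
        center = verts.mean(axis=0)
        order = np.argsort(np.arctan2(verts[:, 1] - center[1], verts[:, 0] - center[0]))
        poly = _ShapelyPolygon(verts[order]).intersection(clip)
        cells.append(np.asarray(poly.exterior.coords)[:-1])
    return cells


def _lloyd_relax(rng: np.random.Generator, n: int, size: float, iterations: int = 2) -> np.ndarray:
    points = rng.uniform(0.05 * size, 0.95 * size, size=(n, 2))
    for _ in range(iterations):
        cells = _bounded_voronoi(points, size)
        points = np.array(
            [np.asarray(_ShapelyPolygon(c).centroid.coords[0]) for c in cells]
        )
    return points


def generate_tissue(params: TissueParams) -> tuple[FieldRecord, GroundTruth]:
    """One synthetic field with full ground truth.

    Cell contours come from a bounded Voronoi tessellation of Lloyd-relaxed
    uniform seeds.  Per cell: the patch center sits ``disp_frac * r`` from
    the cell centroid along a von Mises displacement direction (``r`` the
    equivalent cell radius), the patch contour is a small circle, and each
    cilium is a basal-body point scattered in the patch with a marker-pair
    vector of fixed 0.5 um length along a von Mises angle about the cell's
    orientation direction.
    """
    rng = np.random.default_rng(params.seed)
    size = params.field_size_px
    points = _lloyd_relax(rng, params.n_cells, size)
    contours = _bounded_voronoi(points, size)

    n = params.n_cells
    disp_angles = _vonmises_deg(rng, params.mu_deg, params.kappa_D, n)
    orient_angles = _vonmises_deg(rng, params.mu_deg, params.kappa_O, n)
    lo, hi = params.n_cilia_range
    n_cilia = rng.integers(lo, hi + 1, size=n)
    gtub_offset_px = _GTUB_OFFSET_UM / params.pixel_size_um

    cells: list[CellRecord] = []
    truth_cilia: list[tuple[float, ...]] = []
    for i, verts in enumerate(contours):
        poly = _ShapelyPolygon(verts)
        centroid = np.asarray(poly.centroid.coords[0])
        r_eq = math.sqrt(poly.area / math.pi)
        theta = math.radians(disp_angles[i])
        patch_center = centroid + params.disp_frac * r_eq * np.array(
            [math.cos(theta), math.sin(theta)]
        )
        patch_r = params.patch_frac * r_eq
        phi = np.linspace(0.0, 2.0 * math.pi, 17)[:-1]
        patch_verts = patch_center + patch_r * np.column_stack([np.cos(phi), np.sin(phi)])

        k = int(n_cilia[i])
        cilium_angles = _vonmises_deg(rng, float(orient_angles[i]), params.kappa_cil, k)
        rad_u = patch_r * np.sqrt(rng.uniform(size=k))
        ang_u = rng.uniform(0.0, 2.0 * math.pi, size=k)
        anchors = patch_center + rad_u[:, None] * np.column_stack(
            [np.cos(ang_u), np.sin(ang_u)]
        )
        cilia = []
        for j in range(k):
            a = math.radians(cilium_angles[j])
            fop = Point2D(float(anchors[j, 0]), float(anchors[j, 1]))
            gtub = Point2D(
                fop.x + gtub_offset_px * math.cos(a),
                fop.y + gtub_offset_px * math.sin(a),
            )
            cilia.append(Cilium(fop=fop, gtub=gtub))
        truth_cilia.append(tuple(float(x) for x in cilium_angles))

        cells.append(
            CellRecord(
                cell_id=f"cell_{i:03d}",
                contour=Polygon(verts),
                patch_contour=Polygon(patch_verts),
                cilia=cilia,
            )
        )

    fieldrec = FieldRecord(
        field_id=f"synthetic_{params.seed}",
        pixel_size_um=params.pixel_size_um,
        group_label="",
        cells=cells,
    )
    truth = GroundTruth(
        mu_deg=params.mu_deg,
        disp_angles_deg=tuple(float(x) for x in disp_angles),
        orient_angles_deg=tuple(float(x) for x in orient_angles),
        cilium_angles_deg=tuple(truth_cilia),
        params=params,
    )
    return fieldrec, truth


# ---------------------------------------------------------------------------
# beating-cilium recordings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VideoParams:
    """Generator settings for oscillating-cilium traces and stacks.

    ``true_freqs_hz`` is either an explicit list (one entry per cilium) or a
    ``("normal", mean, sd)`` distribution spec.  ``noise_sd`` is the Gaussian
    noise standard deviation in the same units as ``amplitude``, so
    amplitude/noise_sd is the SNR.
    """

    n_cilia: int = 10
    true_freqs_hz: tuple = ("normal", 5.0, 0.4)
    fs_hz: float = DEFAULT_FS_HZ
    n_frames: int = DEFAULT_N_FRAMES
    baseline: float = 100.0
    amplitude: float = 10.0
    noise_sd: float = 2.0
    bleach_tau_s: float = 20.0  # inf disables bleaching
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 64:
            raise ValueError("need at least 64 frames")
        if self.n_cilia < 0:
            raise ValueError("n_cilia must be >= 0")

    def draw_freq(self, rng: np.random.Generator) -> float:
        spec = self.true_freqs_hz
        if isinstance(spec, tuple) and len(spec) == 3 and spec[0] == "normal":
            return float(rng.normal(spec[1], spec[2]))
        return float(np.asarray(spec, dtype=float).ravel()[0])

    def freq_for(self, rng: np.random.Generator, index: int) -> float:
        spec = self.true_freqs_hz
        if isinstance(spec, tuple) and len(spec) == 3 and spec[0] == "normal":
            return float(rng.normal(spec[1], spec[2]))
        arr = np.asarray(spec, dtype=float).ravel()
        return float(arr[index % arr.size])


def generate_trace(params: VideoParams, index: int = 0) -> tuple[Trace, float]:
    """One synthetic cilium intensity trace and its true frequency.

    ``values(t) = (baseline + amplitude * sin(2 pi f t + phi)) * exp(-t/tau)
    + noise``; phase uniform; deterministic given ``(seed, index)``.
    """
    rng = np.random.default_rng([params.seed, index])
    f = params.freq_for(rng, index)
    t = np.arange(params.n_frames) / params.fs_hz
    phi = rng.uniform(0.0, 2.0 * math.pi)
    decay = (
        np.exp(-t / params.bleach_tau_s)
        if math.isfinite(params.bleach_tau_s)
        else np.ones_like(t)
    )
    values = (params.baseline + params.amplitude * np.sin(2 * math.pi * f * t + phi)) * decay
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, size=t.size)
    return Trace(values, params.fs_hz), f


def generate_stack(
    params: VideoParams,
    shape: tuple[int, int] = (96, 96),
    spot_sigma_px: float = 2.0,
    arc_amplitude_px: float = 3.0,
) -> tuple[ImageStack, list[list[Point2D]], list[float]]:
    """Render a stack of oscillating Gaussian-spot cilia plus their polylines.

    Each cilium's spot center oscillates along a short linear arc at its true
    frequency; the whole scene bleaches mono-exponentially and Gaussian
    noise is added.  One short polyline per cilium crosses the end of its
    arc perpendicular to the motion, so the spot sweeps across the line once
    per beat cycle and the line-averaged intensity oscillates at the true
    frequency.
    """
    rng = np.random.default_rng(params.seed)
    H, W = shape
    T = params.n_frames
    t = np.arange(T) / params.fs_hz
    margin = 4 * spot_sigma_px + arc_amplitude_px + 3
    if 2 * margin >= min(H, W):
        raise ValueError("image too small for the requested cilia geometry")

    yy, xx = np.mgrid[0:H, 0:W]
    frames = np.zeros((T, H, W))
    polylines: list[list[Point2D]] = []
    true_freqs: list[float] = []
    for i in range(params.n_cilia):
        f = params.freq_for(rng, i)
        true_freqs.append(f)
        cx = rng.uniform(margin, W - margin)
        cy = rng.uniform(margin, H - margin)
        direction = rng.uniform(0.0, 2.0 * math.pi)
        ux, uy = math.cos(direction), math.sin(direction)
        phi = rng.uniform(0.0, 2.0 * math.pi)
        s = arc_amplitude_px * np.sin(2 * math.pi * f * t + phi)
        px = cx + s * ux
        py = cy + s * uy
        # accumulate the moving Gaussian spot over time (vectorized over pixels)
        d2 = (xx[None] - px[:, None, None]) ** 2 + (yy[None] - py[:, None, None]) ** 2
        frames += params.amplitude * np.exp(-d2 / (2 * spot_sigma_px**2))
        # polyline crossing the end of the arc, perpendicular to the motion
        ex = cx + arc_amplitude_px * ux
        ey = cy + arc_amplitude_px * uy
        half = 2.0 * spot_sigma_px
        polylines.append(
            [
                Point2D(ex - half * -uy, ey - half * ux),
                Point2D(ex + half * -uy, ey + half * ux),
            ]
        )

    frames += params.baseline / 10.0
    if math.isfinite(params.bleach_tau_s):
        frames *= np.exp(-t / params.bleach_tau_s)[:, None, None]
    if params.noise_sd > 0:
        frames += rng.normal(0.0, params.noise_sd, size=frames.shape)

    stack = ImageStack(frames, fs_hz=params.fs_hz, integration_ms=10.0)
    return stack, polylines, true_freqs


def generate_study(
    control: TissueParams,
    mutant: TissueParams,
    n_fields: int = 5,
    seed: int = 0,
    labels: tuple[str, str] = ("control", "mutant"),
) -> tuple[
    list[tuple[FieldRecord, GroundTruth]], list[tuple[FieldRecord, GroundTruth]]
]:
    """Two groups of independent fields with derived per-field seeds."""
    rng = np.random.default_rng(seed)
    out = []
    for group_params, label in zip((control, mutant), labels):
        fields = []
        for i in range(n_fields):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            fieldrec, truth = generate_tissue(replace(group_params, seed=sub_seed))
            fieldrec.field_id = f"{label}_field_{i:02d}"
            fieldrec.group_label = label
            fields.append((fieldrec, truth))
        out.append(fields)
    return out[0], out[1]
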