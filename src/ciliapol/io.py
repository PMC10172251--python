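"""File formats: field-record JSON, metrics CSV, statistics reports, config.

The field-record JSON schema is the interchange contract for traced ROI
data::

    {
      "field_id": str,
      "pixel_size_um": float,
      "group_label": str,
      "cells": [
        {
          "cell_id": str,
          "contour": [[x, y], ...],          # >= 3 vertices, pixels
          "patch_contour": [[x, y], ...] | null,
          "cilia": [{"fop": [x, y], "gtub": [x, y]}, ...]
        },
        ...
      ]
    }

Coordinates are serialized 0-based in pixels; conversion to physical units
happens only in the metrics output.  Unknown keys are preserved on
round-trip.  Missing metric values are serialized as empty CSV cells, never
as zeros.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .circstats import TTestResult, WatsonResult
from .geometry import Point2D, Polygon
from .polarity import (
    CellRecord,
    Cilium,
    FieldRecord,
    FieldPolarity,
    GroupComparison,
    DEFAULT_CSD_THRESHOLD_DEG,
    DEFAULT_MIN_CILIA,
    DEFAULT_PIXEL_SIZE_UM,
)

__all__ = [
    "FieldIOError",
    "RunConfig",
    "METRICS_COLUMNS",
    "read_field_json",
    "write_field_json",
    "metrics_table",
    "write_metrics_csv",
    "read_metrics_csv",
    "comparison_report",
    "write_report_json",
    "write_config_sidecar",
]

METRICS_COLUMNS = [
    "field_id",
    "group_label",
    "cell_id",
    "vpatchD_deg",
    "vpatchO_deg",
    "vpatchDO_deg",
    "csd_deg",
    "orient_valid",
    "strength",
    "cell_area_um2",
    "patch_area_um2",
    "n_cilia",
    "disp_angle_deg",
    "mean_orient_deg",
]

_FIELD_KEYS = {"field_id", "pixel_size_um", "group_label", "cells"}
_CELL_KEYS = {"cell_id", "contour", "patch_contour", "cilia"}


class FieldIOError(ValueError):
    """Schema or content error in a field-record file."""


@dataclass
class RunConfig:
    """Effective analysis configuration, echoed into every output sidecar."""

    csd_threshold_deg: float = DEFAULT_CSD_THRESHOLD_DEG
    min_cilia: int = DEFAULT_MIN_CILIA
    n_permutations: int = 999
    seed: int = 0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    f_min_hz: float = 0.5
    threshold_k: float = 6.0
    window: Optional[str] = None
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        data.pop("version", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FieldIOError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def write_config_sidecar(config: RunConfig, out_path: str | Path) -> Path:
    """Write ``<out>.config.json`` next to an output artifact."""
    sidecar = Path(str(out_path) + ".config.json")
    sidecar.write_text(json.dumps(config.to_dict(), indent=2) + "\n", encoding="utf-8")
    return sidecar


# ---------------------------------------------------------------------------
# field-record JSON
# ---------------------------------------------------------------------------


def _check_xy(value, where: str) -> tuple[float, float]:
    if (
        not isinstance(value, (list, tuple))
        or len(value) != 2
        or not all(isinstance(v, (int, float)) for v in value)
        or not all(math.isfinite(float(v)) for v in value)
    ):
        raise FieldIOError(f"{where}: expected a finite [x, y] pair, got {value!r}")
    return float(value[0]), float(value[1])


def _parse_polygon(coords, where: str) -> Polygon:
    if not isinstance(coords, list) or len(coords) < 3:
        raise FieldIOError(
            f"{where}: contour needs >= 3 [x, y] vertices, got "
            f"{len(coords) if isinstance(coords, list) else type(coords).__name__}"
        )
    return Polygon([Point2D(*_check_xy(c, where)) for c in coords])


def read_field_json(path: str | Path) -> FieldRecord:
    """Read and validate a field record; errors name the file and cell."""
    path = Path(path)
    try:
        data = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FieldIOError(f"{path}: malformed JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise FieldIOError(f"{path}: expected a JSON object at top level")
    for key in ("field_id", "pixel_size_um", "cells"):
        if key not in data:
            raise FieldIOError(f"{path}: missing required key {key!r}")
    pixel_size = data["pixel_size_um"]
    if not isinstance(pixel_size, (int, float)) or not pixel_size > 0:
        raise FieldIOError(f"{path}: pixel_size_um must be a positive number")

    cells = []
    for entry in data["cells"]:
        cell_id = entry.get("cell_id", "<missing cell_id>")
        where = f"{path} cell {cell_id!r}"
        if "contour" not in entry:
            raise FieldIOError(f"{where}: missing contour")
        contour = _parse_polygon(entry["contour"], where)
        patch = entry.get("patch_contour")
        patch_poly = _parse_polygon(patch, f"{where} patch") if patch is not None else None
        cilia = []
        for j, c in enumerate(entry.get("cilia", [])):
            cwhere = f"{where} cilium {j}"
            if not isinstance(c, dict) or "fop" not in c or "gtub" not in c:
                raise FieldIOError(f"{cwhere}: expected {{'fop': [x,y], 'gtub': [x,y]}}")
            cilia.append(
                Cilium(
                    fop=Point2D(*_check_xy(c["fop"], cwhere + " fop")),
                    gtub=Point2D(*_check_xy(c["gtub"], cwhere + " gtub")),
                )
            )
        extra = {k: v for k, v in entry.items() if k not in _CELL_KEYS}
        cells.append(
            CellRecord(
                cell_id=str(cell_id),
                contour=contour,
                patch_contour=patch_poly,
                cilia=cilia,
                extra=extra,
            )
        )
    field_extra = {k: v for k, v in data.items() if k not in _FIELD_KEYS}
    return FieldRecord(
        field_id=str(data["field_id"]),
        pixel_size_um=float(pixel_size),
        group_label=str(data.get("group_label", "")),
        cells=cells,
        extra=field_extra,
    )


def field_to_dict(fieldrec: FieldRecord) -> dict:
    cells = []
    for cell in fieldrec.cells:
        entry = {
            "cell_id": cell.cell_id,
            "contour": cell.contour.coords(),
            "patch_contour": (
                cell.patch_contour.coords() if cell.patch_contour is not None else None
            ),
            "cilia": [
                {"fop": [c.fop.x, c.fop.y], "gtub": [c.gtub.x, c.gtub.y]}
                for c in cell.cilia
            ],
        }
        entry.update(cell.extra)
        cells.append(entry)
    out = {
        "field_id": fieldrec.field_id,
        "pixel_size_um": fieldrec.pixel_size_um,
        "group_label": fieldrec.group_label,
        "cells": cells,
    }
    out.update(fieldrec.extra)
    return out


def write_field_json(fieldrec: FieldRecord, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(field_to_dict(fieldrec), indent=2) + "\n", encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# metrics table
# ---------------------------------------------------------------------------


def metrics_table(fields: Sequence[FieldPolarity]) -> pd.DataFrame:
    """One row per cell with the full per-cell metric set.

    Undefined metrics are NaN in the frame and empty cells in the CSV; the
    CSD inf sentinel is serialized as ``inf``.
    """
    rows = []
    for f in fields:
        for c in f.cells:
            rows.append(
                {
                    "field_id": f.field_id,
                    "group_label": f.group_label,
                    "cell_id": c.cell_id,
                    "vpatchD_deg": c.vpatchD_deg,
                    "vpatchO_deg": c.vpatchO_deg,
                    "vpatchDO_deg": c.vpatchDO_deg,
                    "csd_deg": c.csd_deg,
                    "orient_valid": c.orient_valid,
                    "strength": c.strength,
                    "cell_area_um2": c.cell_area_um2,
                    "patch_area_um2": c.patch_area_um2,
                    "n_cilia": c.n_cilia,
                    "disp_angle_deg": c.disp_angle_deg,
                    "mean_orient_deg": c.mean_orient_deg,
                }
            )
    df = pd.DataFrame(rows, columns=METRICS_COLUMNS)
    return df


def write_metrics_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, na_rep="")


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# statistics report
# ---------------------------------------------------------------------------


def comparison_report(comp: GroupComparison) -> dict:
    """JSON-serializable ``{metric: {statistic, p_value, n1, n2, method}}``."""
    report: dict = {
        "group_a": comp.label_a,
        "group_b": comp.label_b,
        "n_csd_inf_excluded": list(comp.n_csd_inf_excluded),
        "metrics": {},
    }
    for name, res in comp.watson.items():
        if res is None:
            report["metrics"][name] = {"method": "watson_u2_permutation", "testable": False}
        else:
            report["metrics"][name] = {
                "method": "watson_u2_permutation",
                "testable": True,
                "statistic": res.u2,
                "p_value": res.p_value,
                "n1": res.n1,
                "n2": res.n2,
                "n_permutations": res.n_permutations,
                "seed": res.seed,
            }
    for name, res in comp.ttests.items():
        if res is None:
            report["metrics"][name] = {"method": "two_sample_t", "testable": False}
        else:
            report["metrics"][name] = {
                "method": "two_sample_t",
                "testable": True,
                "statistic": res.t,
                "p_value": res.p_value,
                "n1": res.n1,
                "n2": res.n2,
            }
    return report


def write_report_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n", encoding="utf-8")


def compare_tables(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict:
    """Group comparison straight from two metrics tables (CSV round-trips).

    Same statistics as :func:`ciliapol.polarity.compare_groups`: Watson U²
    on the circular families, pooled-variance t on the linear metrics, with
    CSD inf-sentinel cells excluded and counted.
    """
    from .circstats import two_sample_t as _ttest
    from .circstats import watson_u2_test as _watson

    def col(df: pd.DataFrame, name: str) -> np.ndarray:
        return pd.to_numeric(df[name], errors="coerce").dropna().to_numpy(dtype=float)

    report: dict = {
        "group_a": str(table_a["group_label"].iloc[0]) if len(table_a) else "",
        "group_b": str(table_b["group_label"].iloc[0]) if len(table_b) else "",
        "metrics": {},
    }
    circular = ["vpatchD_deg", "vpatchO_deg", "vpatchDO_deg"]
    linear = ["csd_deg", "strength", "cell_area_um2", "patch_area_um2", "n_cilia"]
    for i, name in enumerate(circular):
        a, b = col(table_a, name), col(table_b, name)
        if a.size < 2 or b.size < 2:
            report["metrics"][name] = {"method": "watson_u2_permutation", "testable": False}
            continue
        res = _watson(a, b, n_permutations=n_permutations, seed=seed + i)
        report["metrics"][name] = {
            "method": "watson_u2_permutation",
            "testable": True,
            "statistic": res.u2,
            "p_value": res.p_value,
            "n1": res.n1,
            "n2": res.n2,
            "n_permutations": res.n_permutations,
            "seed": res.seed,
        }
    n_inf = [0, 0]
    for name in linear:
        a, b = col(table_a, name), col(table_b, name)
        if name == "csd_deg":
            n_inf = [int(np.sum(np.isinf(a))), int(np.sum(np.isinf(b)))]
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        try:
            res = _ttest(a, b)
        except ValueError:
            report["metrics"][name] = {"method": "two_sample_t", "testable": False}
            continue
        report["metrics"][name] = {
            "method": "two_sample_t",
            "testable": True,
            "statistic": res.t,
            "p_value": res.p_value,
            "n1": res.n1,
            "n2": res.n2,
        }
    report["n_csd_inf_excluded"] = n_inf
    return report
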