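"""Readers and writers: cohort CSV, predictions CSV, legacy ASCII VTK."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import SUBREGIONS, DiscGeometryParams, TetMesh
from .synth_cohort import CohortRecord

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "write_predictions_csv",
    "write_vtk",
]

COHORT_COLUMNS = (
    "id", "pjk", "weight_kg", "age_yr", "gender",
    "pre_pja_deg", "applied_post_pja_deg",
)
OPTIONAL_COHORT_COLUMNS = ("reported_risk", "optimal_post_pja_deg")
GEOMETRY_COLUMNS = ("lateral_radius_mm", "ap_radius_mm", "height_mm", "nucleus_scale",
                    "nucleus_offset_x_mm", "nucleus_offset_y_mm")

_COMPONENT_INT = {"annulus": 0, "nucleus": 1}
_SUBREGION_INT = {name: i for i, name in enumerate(SUBREGIONS)}


def write_cohort_csv(records: list[CohortRecord], path: str | Path) -> None:
    """Write a cohort table with documented column names (lossless)."""
    rows = []
    with_geometry = any(r.geometry is not None for r in records)
    for r in records:
        row = {
            "id": r.id, "pjk": r.pjk_label, "weight_kg": r.weight,
            "age_yr": r.age, "gender": r.gender, "pre_pja_deg": r.pre_pja,
            "applied_post_pja_deg": r.applied_post_pja,
            "reported_risk": r.reported_risk,
            "optimal_post_pja_deg": r.optimal_post_pja,
        }
        if with_geometry:
            g = r.geometry
            row.update({
                "lateral_radius_mm": None if g is None else g.lateral_radius,
                "ap_radius_mm": None if g is None else g.ap_radius,
                "height_mm": None if g is None else g.height,
                "nucleus_scale": None if g is None else g.nucleus_scale,
                "nucleus_offset_x_mm": None if g is None else g.nucleus_offset_x,
                "nucleus_offset_y_mm": None if g is None else g.nucleus_offset_y,
            })
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[CohortRecord]:
    """Read a cohort table, validating every required cell.

    Raises ``ValueError`` naming the offending row and column on a missing
    column, a non-numeric cell, or an invalid gender code.
    """
    df = pd.read_csv(path, dtype={"gender": str})
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"cohort file {path} is missing column {col!r}")
    records = []
    for idx, row in df.iterrows():
        def num(col, row=row, idx=idx):
            value = row[col]
            try:
                out = float(value)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric value {value!r} in row {idx + 1}, column {col!r}"
                ) from None
            if not np.isfinite(out):
                raise ValueError(f"missing value in row {idx + 1}, column {col!r}")
            return out

        def opt(col, row=row):
            if col not in row or pd.isna(row[col]):
                return None
            return float(row[col])

        geometry = None
        if all(opt(c) is not None for c in GEOMETRY_COLUMNS):
            # disc anatomy travels with the record; mesh resolutions are a
            # run-configuration concern and stay at their defaults here
            geometry = DiscGeometryParams(
                lateral_radius=opt("lateral_radius_mm"),
                ap_radius=opt("ap_radius_mm"),
                height=opt("height_mm"),
                nucleus_scale=opt("nucleus_scale"),
                nucleus_offset_x=opt("nucleus_offset_x_mm"),
                nucleus_offset_y=opt("nucleus_offset_y_mm"),
            )
        try:
            record = CohortRecord(
                id=int(num("id")), pjk_label=int(num("pjk")),
                weight=num("weight_kg"), age=num("age_yr"),
                gender=str(row["gender"]),
                pre_pja=num("pre_pja_deg"),
                applied_post_pja=num("applied_post_pja_deg"),
                reported_risk=opt("reported_risk"),
                optimal_post_pja=opt("optimal_post_pja_deg"),
                geometry=geometry,
            )
        except ValueError as exc:
            raise ValueError(f"row {idx + 1}: {exc}") from None
        records.append(record)
    return records


def write_predictions_csv(
    path: str | Path,
    ids: list[int],
    risks: np.ndarray,
    labels: np.ndarray,
    folds: list[int] | None = None,
) -> None:
    df = pd.DataFrame({
        "id": ids,
        "risk": np.asarray(risks, dtype=float),
        "label": np.asarray(labels, dtype=int),
        "fold": folds if folds is not None else list(range(len(ids))),
        "predicted": (np.asarray(risks) >= 0.5).astype(int),
    })
    df.to_csv(path, index=False)


def write_vtk(
    mesh: TetMesh,
    path: str | Path,
    cell_scalars: dict[str, np.ndarray] | None = None,
    point_vectors: dict[str, np.ndarray] | None = None,
) -> None:
    """Export a mesh as a legacy ASCII VTK unstructured grid.

    Component and subregion labels are always written as integer cell data
    (codes follow :data:`~pjaplan.geometry.SUBREGIONS` order); extra
    per-element scalars and per-node vectors are optional.
    """
    lines = [
        "# vtk DataFile Version 3.0",
        "pjaplan disc mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in mesh.nodes]
    lines.append(f"CELLS {mesh.n_elements} {mesh.n_elements * 5}")
    lines += ["4 " + " ".join(str(int(i)) for i in tet) for tet in mesh.tets]
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines += ["10"] * mesh.n_elements  # VTK_TETRA

    lines.append(f"CELL_DATA {mesh.n_elements}")
    for name, values in (
        ("component", np.array([_COMPONENT_INT[c] for c in mesh.component_of_element])),
        ("subregion", np.array([_SUBREGION_INT[s] for s in mesh.subregion_of_element])),
    ):
        lines += [f"SCALARS {name} int 1", "LOOKUP_TABLE default"]
        lines += [str(int(v)) for v in values]
    for name, values in (cell_scalars or {}).items():
        lines += [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
        lines += [f"{float(v):.9g}" for v in values]

    if point_vectors:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, values in point_vectors.items():
            lines.append(f"VECTORS {name} double")
            lines += [" ".join(f"{float(v):.9g}" for v in row) for row in values]

    Path(path).write_text("\n".join(lines) + "\n")
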