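"""Visualization export and YAML configuration loading."""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from .fibers import AngleBC
from .geometry import Mesh
from .mechanics import BoundaryConditionConfig, GuccioneParameters
from .pipeline import ExperimentConfig, LVGeometryConfig


def write_vtu(path, mesh: Mesh, point_data: dict[str, np.ndarray] | None = None) -> None:
    """ASCII VTU (unstructured grid) with optional per-vertex arrays.

    Vector fields are written with three components, scalars with one;
    suitable for ParaView inspection of displacement and fiber fields.
    """
    n, m = mesh.n_vertices, len(mesh.cells)
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
    ]
    lines += [" ".join(f"{x:.12g}" for x in v) for v in mesh.vertices]
    lines += ["</DataArray>", "</Points>", "<Cells>",
              '<DataArray type="Int64" Name="connectivity" format="ascii">']
    lines += [" ".join(map(str, c)) for c in mesh.cells]
    lines += ["</DataArray>", '<DataArray type="Int64" Name="offsets" format="ascii">',
              " ".join(str(4 * (i + 1)) for i in range(m)),
              "</DataArray>", '<DataArray type="UInt8" Name="types" format="ascii">',
              " ".join("10" for _ in range(m)), "</DataArray>", "</Cells>"]
    if point_data:
        lines.append("<PointData>")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            lines.append(
                f'<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">'
            )
            if arr.ndim == 1:
                lines += [f"{v:.12g}" for v in arr]
            else:
                lines += [" ".join(f"{x:.12g}" for x in row) for row in arr]
            lines.append("</DataArray>")
        lines.append("</PointData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(lines) + "\n")


def _build(cls, block: dict | None, **extra):
    block = dict(block or {})
    block.update(extra)
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    for key in ("endo_semi_axes", "epi_semi_axes", "correlation_lengths"):
        if key in block and isinstance(block[key], list):
            block[key] = tuple(block[key])
    return cls(**block)


def config_from_yaml(path) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a YAML file.

    Recognized blocks: ``geometry``, ``material``, ``loading``, ``fibers``
    (mean angles, degrees), ``randomfield`` and top-level experiment keys
    (``model``, ``pce_order``, ``seed`` ...).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    geometry = _build(LVGeometryConfig, raw.pop("geometry", None))
    material = _build(GuccioneParameters, raw.pop("material", None))
    loading = _build(BoundaryConditionConfig, raw.pop("loading", None))
    angles = _build(AngleBC, raw.pop("fibers", None))
    rf = raw.pop("randomfield", {}) or {}
    top = {
        "sigma_kl": rf.get("sigma_kl", 0.1),
        "kle_threshold": rf.get("threshold", 0.05),
        "kle_fraction": rf.get("fraction", 0.92),
    }
    if "correlation_lengths" in rf:
        top["correlation_lengths"] = tuple(rf["correlation_lengths"])
    elif "l" in rf:
        top["correlation_lengths"] = (float(rf["l"]),)
    return _build(
        ExperimentConfig, raw, geometry=geometry, material=material,
        loading=loading, angles=angles, **top,
    )
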