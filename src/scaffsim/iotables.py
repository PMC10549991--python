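"""Nodal table file I/O, FE-CFD node matching, and frame assembly.

CSV is the canonical interchange format for solver exports: one row per
node with columns ``node_id, x_mm, y_mm, z_mm[, area_mm2]`` plus one column
per nodal quantity (``oss``, ``wss_mpa``, ...), and the frame time carried
in a leading ``# time_s = <t>`` comment line.  A minimal ASCII VTK
unstructured-grid (.vtu) dialect is supported for visualisation
round-trips: one vertex cell per node, nodal quantities as PointData and
the time as a TimeValue FieldData entry.

``match_nodes`` reconstructs the node correspondence between two solver
exports on a shared (conformal) interface by nearest-neighbour search with
a k-d tree, with strict tolerance and ambiguity handling; ``assemble_frames``
merges matched per-time OSS and WSS tables into co-indexed nodal frames.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .mechanoreg import NodalFieldFrame

__all__ = [
    "SchemaError",
    "MatchError",
    "NodalTable",
    "NodeMatching",
    "write_nodal_csv",
    "read_nodal_csv",
    "write_nodal_vtu",
    "read_nodal_vtu",
    "read_nodal_table",
    "write_surface_mesh_csv",
    "match_nodes",
    "assemble_frames",
]

_COORD_COLS = ("x_mm", "y_mm", "z_mm")


class SchemaError(ValueError):
    """A nodal table file violates the expected schema."""


class MatchError(ValueError):
    """Node matching between two coordinate sets failed."""


@dataclass
class NodalTable:
    """In-memory nodal table: coordinates plus named per-node fields."""

    coords: np.ndarray
    fields: dict[str, np.ndarray]
    area: np.ndarray | None = None
    time: float | None = None
    path: Path | None = None

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]


def write_nodal_csv(
    path: str | Path,
    coords: np.ndarray,
    fields: dict[str, np.ndarray],
    area: np.ndarray | None = None,
    time: float | None = None,
) -> Path:
    """Write a nodal table in the canonical CSV schema."""
    path = Path(path)
    coords = np.asarray(coords, dtype=float)
    data = {
        "node_id": np.arange(coords.shape[0]),
        "x_mm": coords[:, 0],
        "y_mm": coords[:, 1],
        "z_mm": coords[:, 2],
    }
    if area is not None:
        data["area_mm2"] = np.asarray(area, dtype=float)
    for name, arr in fields.items():
        data[name] = np.asarray(arr, dtype=float)
    df = pd.DataFrame(data)
    with open(path, "w") as fh:
        if time is not None:
            fh.write(f"# time_s = {time!r}\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.17g")
    return path


def read_nodal_csv(path: str | Path) -> NodalTable:
    """Read a canonical nodal CSV; validates schema strictly."""
    path = Path(path)
    time = None
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise SchemaError(f"{path}: file is empty")
        if first.startswith("#"):
            if "time_s" in first:
                try:
                    time = float(first.split("=", 1)[1])
                except (IndexError, ValueError) as exc:
                    raise SchemaError(f"{path}: malformed time header {first!r}") from exc
            header_line = fh.readline()
        else:
            header_line = first
        if not header_line.strip():
            raise SchemaError(f"{path}: missing column header")
        try:
            df = pd.read_csv(
                fh, names=header_line.strip().split(","), float_precision="round_trip"
            )
        except Exception as exc:
            raise SchemaError(f"{path}: cannot parse CSV body: {exc}") from exc
    return _table_from_dataframe(df, path, time)


def _table_from_dataframe(df: pd.DataFrame, path: Path, time: float | None) -> NodalTable:
    required = ("node_id",) + _COORD_COLS
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if df.shape[0] == 0:
        raise SchemaError(f"{path}: table contains no nodes")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())
        if df[col].isna().any() or bad.size:
            row = int(bad[0]) if bad.size else int(np.flatnonzero(df[col].isna())[0])
            raise SchemaError(f"{path}: non-numeric or missing value in column {col!r}, row {row}")
        df[col] = vals
    ids = df["node_id"].to_numpy()
    if np.unique(ids).size != ids.size:
        dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate node_id {int(dup)}")
    coords = df[list(_COORD_COLS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise SchemaError(f"{path}: non-finite coordinates")
    area = df["area_mm2"].to_numpy(dtype=float) if "area_mm2" in df.columns else None
    fields = {
        c: df[c].to_numpy(dtype=float)
        for c in df.columns
        if c not in required and c != "area_mm2"
    }
    return NodalTable(coords=coords, fields=fields, area=area, time=time, path=path)


# ---------------------------------------------------------------------------
# minimal ASCII VTU (XML UnstructuredGrid) dialect

_VTU_NS = "VTKFile"


def write_nodal_vtu(
    path: str | Path,
    coords: np.ndarray,
    fields: dict[str, np.ndarray],
    area: np.ndarray | None = None,
    time: float | None = None,
) -> Path:
    """Write the node cloud as an ASCII .vtu with one vertex cell per node."""
    path = Path(path)
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    point_data = dict(fields)
    if area is not None:
        point_data["area_mm2"] = np.asarray(area, dtype=float)

    def arr_text(a: np.ndarray) -> str:
        return " ".join(repr(float(v)) for v in np.asarray(a, dtype=float).ravel())

    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
    ]
    if time is not None:
        lines += [
            "<FieldData>",
            '<DataArray type="Float64" Name="TimeValue" NumberOfTuples="1" format="ascii">',
            repr(float(time)),
            "</DataArray>",
            "</FieldData>",
        ]
    lines += [f'<Piece NumberOfPoints="{n}" NumberOfCells="{n}">', "<Points>"]
    lines += [
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        arr_text(coords),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        " ".join(str(i) for i in range(n)),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(str(i + 1) for i in range(n)),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join("1" for _ in range(n)),
        "</DataArray>",
        "</Cells>",
        "<PointData>",
    ]
    for name, arr in point_data.items():
        arr = np.asarray(arr, dtype=float)
        if arr.shape[0] != n:
            raise ValueError(f"field {name!r} length {arr.shape[0]} != {n} nodes")
        lines += [
            f'<DataArray type="Float64" Name="{name}" format="ascii">',
            arr_text(arr),
            "</DataArray>",
        ]
    lines += ["</PointData>", "</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_nodal_vtu(path: str | Path) -> NodalTable:
    """Read the ASCII .vtu dialect written by :func:`write_nodal_vtu`."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise SchemaError(f"{path}: file is empty")
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise SchemaError(f"{path}: invalid XML: {exc}") from exc
    grid = root.find("UnstructuredGrid")
    if grid is None:
        raise SchemaError(f"{path}: not an UnstructuredGrid VTU file")
    time = None
    fd = grid.find("FieldData")
    if fd is not None:
        for da in fd.findall("DataArray"):
            if da.get("Name") == "TimeValue":
                time = float((da.text or "").split()[0])
    piece = grid.find("Piece")
    if piece is None:
        raise SchemaError(f"{path}: missing Piece element")
    n = int(piece.get("NumberOfPoints", "0"))
    pts_da = piece.find("Points/DataArray")
    if pts_da is None:
        raise SchemaError(f"{path}: missing Points data")
    try:
        coords = np.array((pts_da.text or "").split(), dtype=float).reshape(n, 3)
    except ValueError as exc:
        raise SchemaError(f"{path}: malformed Points array") from exc
    fields: dict[str, np.ndarray] = {}
    area = None
    pd_el = piece.find("PointData")
    if pd_el is not None:
        for da in pd_el.findall("DataArray"):
            name = da.get("Name") or "field"
            vals = np.array((da.text or "").split(), dtype=float)
            if vals.shape[0] != n:
                raise SchemaError(f"{path}: PointData {name!r} has {vals.shape[0]} values, expected {n}")
            if name == "area_mm2":
                area = vals
            else:
                fields[name] = vals
    if not np.all(np.isfinite(coords)):
        raise SchemaError(f"{path}: non-finite coordinates")
    return NodalTable(coords=coords, fields=fields, area=area, time=time, path=path)


def read_nodal_table(path: str | Path, fmt: str | None = None) -> NodalTable:
    """Read a nodal table, dispatching on ``fmt`` or the file suffix."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        return read_nodal_csv(path)
    if fmt == "vtu":
        return read_nodal_vtu(path)
    raise ValueError(f"unsupported nodal table format {fmt!r}")


_REGION_CODES = {"intersection": 0, "strand_free": 1, "strand_top": 2, "strand_bottom": 3}


def write_surface_mesh_csv(mesh, path: str | Path) -> Path:
    """Write a surface mesh (coords, area, region) as a nodal CSV."""
    codes = np.array([_REGION_CODES[r] for r in mesh.node_region], dtype=float)
    return write_nodal_csv(
        path,
        mesh.node_coords,
        {"region_code": codes},
        area=mesh.node_area,
    )


# ---------------------------------------------------------------------------
# node matching


@dataclass
class NodeMatching:
    """Injective FE -> CFD node correspondence within a distance tolerance."""

    mapping: np.ndarray  # index into CFD array per FE node; -1 if unmatched
    tolerance: float
    distances: np.ndarray
    unmatched_fe: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    unmatched_cfd: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_matched(self) -> int:
        return int(np.sum(self.mapping >= 0))

    @property
    def is_bijection(self) -> bool:
        return self.unmatched_fe.size == 0 and self.unmatched_cfd.size == 0

    def invert(self) -> "NodeMatching":
        """CFD -> FE view of a bijective matching."""
        if not self.is_bijection:
            raise MatchError("cannot invert a non-bijective matching")
        inv = np.empty_like(self.mapping)
        inv[self.mapping] = np.arange(self.mapping.size)
        return NodeMatching(
            mapping=inv,
            tolerance=self.tolerance,
            distances=self.distances[inv],
        )


def default_match_tolerance(fe_coords: np.ndarray, cfd_coords: np.ndarray) -> float:
    """1e-6 times the joint bounding-box diagonal."""
    allc = np.vstack([fe_coords, cfd_coords])
    diag = float(np.linalg.norm(allc.max(axis=0) - allc.min(axis=0)))
    return 1e-6 * diag if diag > 0 else 1e-12


def match_nodes(
    fe_coords: np.ndarray,
    cfd_coords: np.ndarray,
    tolerance: float | None = None,
    strict: bool = True,
) -> NodeMatching:
    """Match every FE node to its coincident CFD node.

    Nearest-neighbour search on a k-d tree; a pair is accepted only when
    its distance is within ``tolerance`` (default: 1e-6 of the bounding-box
    diagonal).  Two CFD candidates within tolerance of one FE node — or two
    FE nodes claiming the same CFD node — are ambiguous and raise.  In
    strict mode any unmatched FE node raises with the count and the worst
    offending distance; lenient mode records unmatched lists instead.
    """
    fe = np.asarray(fe_coords, dtype=float)
    cfd = np.asarray(cfd_coords, dtype=float)
    if fe.size == 0 or cfd.size == 0:
        raise MatchError("both coordinate sets must be nonempty")
    if tolerance is None:
        tolerance = default_match_tolerance(fe, cfd)
    tree = cKDTree(cfd)
    k = min(2, cfd.shape[0])
    dist, idx = tree.query(fe, k=k)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    ambiguous = np.flatnonzero(dist[:, -1] <= tolerance) if k == 2 else np.empty(0, int)
    if ambiguous.size:
        worst = ambiguous[:10].tolist()
        raise MatchError(
            f"{ambiguous.size} FE node(s) have multiple CFD candidates within "
            f"tolerance {tolerance:g} mm (first offenders: {worst})"
        )
    matched = dist[:, 0] <= tolerance
    mapping = np.where(matched, idx[:, 0], -1)

    # injectivity: two FE nodes mapped to the same CFD node
    taken = mapping[mapping >= 0]
    uniq, counts = np.unique(taken, return_counts=True)
    dupes = uniq[counts > 1]
    if dupes.size:
        raise MatchError(
            f"{dupes.size} CFD node(s) claimed by multiple FE nodes "
            f"(first offenders: {dupes[:10].tolist()}); ambiguous matching"
        )

    unmatched_fe = np.flatnonzero(~matched)
    if strict and unmatched_fe.size:
        worst_d = float(dist[unmatched_fe, 0].max())
        raise MatchError(
            f"{unmatched_fe.size} FE node(s) unmatched within tolerance "
            f"{tolerance:g} mm; worst distance {worst_d:g} mm"
        )
    unmatched_cfd = np.setdiff1d(np.arange(cfd.shape[0]), taken)
    return NodeMatching(
        mapping=mapping,
        tolerance=float(tolerance),
        distances=dist[:, 0],
        unmatched_fe=unmatched_fe,
        unmatched_cfd=unmatched_cfd,
    )


# ---------------------------------------------------------------------------
# frame assembly


def assemble_frames(
    fe_tables: list[NodalTable],
    cfd_tables: list[NodalTable],
    matching: NodeMatching,
    dt: float | None = None,
    oss_field: str = "oss",
    wss_field: str = "wss_mpa",
) -> list[NodalFieldFrame]:
    """Merge matched per-time OSS and WSS tables into nodal frames.

    Tables are paired by time stamp (exact, or within dt/2 when ``dt`` is
    given); the CFD field is re-indexed onto the FE node order through the
    matching.  Missing or misaligned time stamps raise with the offending
    list.
    """
    if not fe_tables or not cfd_tables:
        raise ValueError("need at least one FE and one CFD table")
    if not matching.is_bijection:
        raise MatchError("frame assembly requires a bijective node matching")
    fe_sorted = sorted(fe_tables, key=lambda t: _require_time(t))
    cfd_sorted = sorted(cfd_tables, key=lambda t: _require_time(t))
    fe_times = np.array([t.time for t in fe_sorted])
    cfd_times = np.array([t.time for t in cfd_sorted])
    tol = (dt / 2.0) if dt is not None else 1e-9
    if fe_times.size != cfd_times.size or np.any(np.abs(fe_times - cfd_times) > tol):
        missing = [
            float(t)
            for t in fe_times
            if not np.any(np.abs(cfd_times - t) <= tol)
        ]
        extra = [
            float(t)
            for t in cfd_times
            if not np.any(np.abs(fe_times - t) <= tol)
        ]
        raise ValueError(
            f"FE/CFD time stamps misaligned (tolerance {tol:g} s): "
            f"FE-only {missing}, CFD-only {extra}"
        )
    frames = []
    for fe_t, cfd_t in zip(fe_sorted, cfd_sorted):
        if oss_field not in fe_t.fields:
            raise SchemaError(f"{fe_t.path}: missing field {oss_field!r}")
        if wss_field not in cfd_t.fields:
            raise SchemaError(f"{cfd_t.path}: missing field {wss_field!r}")
        wss_on_fe = cfd_t.fields[wss_field][matching.mapping]
        area = fe_t.area if fe_t.area is not None else np.ones(fe_t.n_nodes)
        frames.append(
            NodalFieldFrame(
                time=float(fe_t.time),
                oss=fe_t.fields[oss_field],
                wss_mpa=wss_on_fe,
                node_area=area,
            )
        )
    return frames


def _require_time(table: NodalTable) -> float:
    if table.time is None:
        raise ValueError(f"{table.path}: nodal table carries no time stamp")
    return table.time
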