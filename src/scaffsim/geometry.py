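"""Parametric 0/90 strand-lattice scaffold geometry and surface sampling.

The scaffold is the kind produced by direct ink writing (DIW): circular
strands of radius ``R`` laid down in horizontal layers, with all strands of
one layer parallel (spaced ``Y`` apart) and successive layers rotated by
90 degrees.  The lattice is clipped to a cylinder of diameter ``D`` and
height ``H``; the vertical centre-to-centre distance between adjacent
layers is ``h``.

The vertical axis is ``y`` and the origin sits at the bottom centre of the
scaffold.  All lengths are millimetres.

The surface sampler discretises each strand's lateral cylinder surface into
an approximately uniform point cloud with per-node quadrilateral patch
areas, removes points buried inside a neighbouring strand, and tags each
node by region (strand crossing, free span, top/bottom of a strand).  These
nodes are the carriers of all nodal fields downstream (octahedral shear
strain, wall shear stress, stimulus, phenotype).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "ScaffoldSpec",
    "Strand",
    "SurfaceMesh",
    "strand_centerlines",
    "build_scaffold_surface",
    "REGIONS",
]

#: Region tags a surface node can carry.
REGIONS = ("intersection", "strand_free", "strand_top", "strand_bottom")

Orientation = Literal["x", "z"]


@dataclass(frozen=True)
class ScaffoldSpec:
    """Parametric description of the 0/90 strand lattice.

    Defaults are the printed scaffold dimensions: strand radius
    R = 0.35 mm, horizontal span Y = 1.4 mm, vertical pitch h = 1.12 mm,
    scaffold diameter D = 10 mm and height H = 4.8 mm.

    Parameters
    ----------
    strand_radius : float
        Strand (cylinder) radius R in mm.
    horizontal_span : float
        Centre-to-centre spacing Y of parallel strands within a layer, mm.
    vertical_pitch : float
        Centre-to-centre vertical distance h between adjacent layers, mm.
    diameter : float
        Scaffold envelope diameter D, mm; strands are clipped to this circle.
    height : float
        Scaffold envelope height H, mm; limits the number of layers.
    fusion_offset : float
        Optional vertical interpenetration of adjacent layers, mm.  The
        effective layer pitch is ``h - fusion_offset``; the default 0 keeps
        layers exactly ``h`` apart (strands of adjacent layers touch only if
        ``h <= 2R``).
    n_layers : int or None
        Override for the layer count.  ``None`` packs layers from the
        bottom (first centre at R, pitch as above) while the lattice
        bounding box stays within H.
    """

    strand_radius: float = 0.35
    horizontal_span: float = 1.4
    vertical_pitch: float = 1.12
    diameter: float = 10.0
    height: float = 4.8
    fusion_offset: float = 0.0
    n_layers: int | None = None

    def __post_init__(self) -> None:
        R, Y, h = self.strand_radius, self.horizontal_span, self.vertical_pitch
        D, H = self.diameter, self.height
        if R <= 0:
            raise ValueError(f"strand_radius must be > 0, got {R}")
        if Y <= 2 * R:
            raise ValueError(f"horizontal_span must exceed 2R={2*R} for open pores, got {Y}")
        if h <= 0:
            raise ValueError(f"vertical_pitch must be > 0, got {h}")
        if D <= Y:
            raise ValueError(f"diameter must exceed horizontal_span {Y}, got {D}")
        if H < 2 * R:
            raise ValueError(f"height must be >= strand diameter {2*R}, got {H}")
        if self.fusion_offset < 0 or self.fusion_offset >= h:
            raise ValueError("fusion_offset must lie in [0, vertical_pitch)")
        if self.n_layers is not None and self.n_layers < 1:
            raise ValueError("n_layers override must be >= 1")

    @property
    def effective_pitch(self) -> float:
        return self.vertical_pitch - self.fusion_offset

    @property
    def pore_width(self) -> float:
        """Clear channel width between adjacent parallel strands, mm."""
        return self.horizontal_span - 2 * self.strand_radius

    @property
    def open_area_fraction(self) -> float:
        """In-plane open fraction phi = (Y - 2R)/Y of the lattice."""
        return self.pore_width / self.horizontal_span

    def layer_heights(self) -> np.ndarray:
        """Centre heights of the strand layers (mm), bottom to top."""
        R, H = self.strand_radius, self.height
        pitch = self.effective_pitch
        if self.n_layers is None:
            n = int(np.floor((H - 2 * R) / pitch + 1e-12)) + 1
        else:
            n = self.n_layers
        if n < 1:
            raise ValueError("scaffold spec yields zero strand layers")
        return R + pitch * np.arange(n)


@dataclass(frozen=True)
class Strand:
    """One straight strand segment of the lattice.

    ``orientation`` is the horizontal axis the strand runs along; ``offset``
    is its position along the perpendicular horizontal axis; ``y`` the layer
    centre height; ``half_length`` half the chord cut by the envelope circle.
    """

    layer: int
    orientation: Orientation
    offset: float
    y: float
    half_length: float

    @property
    def length(self) -> float:
        return 2.0 * self.half_length

    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        if self.orientation == "x":
            p0 = np.array([-self.half_length, self.y, self.offset])
            p1 = np.array([self.half_length, self.y, self.offset])
        else:
            p0 = np.array([self.offset, self.y, -self.half_length])
            p1 = np.array([self.offset, self.y, self.half_length])
        return p0, p1


def strand_centerlines(spec: ScaffoldSpec) -> list[Strand]:
    """Enumerate the strand centrelines of the lattice.

    Layers alternate orientation (even layers along x, odd along z); within
    a layer strands sit at offsets ``m * Y`` (m integer, symmetric about the
    axis) and are clipped to the envelope circle of diameter D.

    Raises
    ------
    ValueError
        If the spec yields zero layers or zero strands in a layer.
    """
    heights = spec.layer_heights()
    half_d = spec.diameter / 2.0
    m_max = int(np.floor((half_d - 1e-12) / spec.horizontal_span))
    strands: list[Strand] = []
    for k, y in enumerate(heights):
        orientation: Orientation = "x" if k % 2 == 0 else "z"
        layer_count = 0
        for m in range(-m_max, m_max + 1):
            offset = m * spec.horizontal_span
            chord = half_d * half_d - offset * offset
            if chord <= 0:
                continue
            strands.append(
                Strand(
                    layer=k,
                    orientation=orientation,
                    offset=offset,
                    y=float(y),
                    half_length=float(np.sqrt(chord)),
                )
            )
            layer_count += 1
        if layer_count == 0:
            raise ValueError(f"layer {k} contains no strands (D={spec.diameter}, Y={spec.horizontal_span})")
    return strands


@dataclass
class SurfaceMesh:
    """Discretised scaffold surface: the carrier of all nodal fields.

    Attributes
    ----------
    node_coords : (n, 3) float array, mm.
    node_area : (n,) float array, mm^2, local quad patch area weights.
    node_region : (n,) str array with values from :data:`REGIONS`.
    node_normal : (n, 3) float array, outward unit normals of the strand
        cylinder at each node.
    node_strand : (n,) int array, index into the strand list.
    spec : ScaffoldSpec that produced the mesh.
    """

    node_coords: np.ndarray
    node_area: np.ndarray
    node_region: np.ndarray
    node_normal: np.ndarray
    node_strand: np.ndarray
    spec: ScaffoldSpec
    strands: list[Strand] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def total_area(self) -> float:
        return float(self.node_area.sum())

    def region_mask(self, region: str) -> np.ndarray:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
        return self.node_region == region

    def validate(self) -> None:
        n = self.n_nodes
        if n == 0:
            raise ValueError("surface mesh has no nodes")
        if not np.all(self.node_area > 0):
            raise ValueError("all node areas must be positive")
        r_xy = np.hypot(self.node_coords[:, 0], self.node_coords[:, 2])
        R = self.spec.strand_radius
        if np.any(r_xy > self.spec.diameter / 2 + R):
            raise ValueError("node outside scaffold envelope (diameter + R tolerance)")
        y = self.node_coords[:, 1]
        if np.any(y < -R) or np.any(y > self.spec.height + R):
            raise ValueError("node outside scaffold envelope (height + R tolerance)")


def _strand_frame(strand: Strand) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Axis origin, axis direction and the two radial basis vectors.

    The first radial vector is global +y for every strand, so circumferential
    sampling patterns are preserved by 90-degree rotations about the vertical
    axis (lattice symmetry is exact at the node level).
    """
    if strand.orientation == "x":
        axis = np.array([1.0, 0.0, 0.0])
        e2 = np.array([0.0, 0.0, 1.0])
    else:
        axis = np.array([0.0, 0.0, 1.0])
        e2 = np.array([1.0, 0.0, 0.0])
    origin = np.array([0.0, strand.y, 0.0])
    if strand.orientation == "x":
        origin[2] = strand.offset
    else:
        origin[0] = strand.offset
    e1 = np.array([0.0, 1.0, 0.0])
    return origin, axis, e1, e2


def build_scaffold_surface(
    spec: ScaffoldSpec, resolution: int = 16, intersection_band: float | None = None
) -> SurfaceMesh:
    """Sample the lateral surfaces of all strands into a node cloud.

    ``resolution`` is the number of nodes around each strand circumference;
    axial spacing is matched to the circumferential spacing, so node patches
    are approximately square and refinement is isotropic (node count grows
    ~ resolution^2, total area stays fixed).

    Nodes that fall strictly inside another strand's cylinder are removed.
    A node is tagged ``intersection`` when its axial position lies within
    ``intersection_band`` of a crossing strand of an adjacent layer — the
    default band is R, the lateral footprint of the crossing strand (with
    the reference lattice Y = 4R, a wider band would swallow the whole
    strand and leave no free span).  Other nodes are tagged by the facing
    of the surface normal (``strand_top`` / ``strand_bottom`` for within
    45 degrees of vertical, ``strand_free`` for sideways-facing).
    """
    if resolution < 8:
        raise ValueError(f"resolution must be >= 8, got {resolution}")
    if intersection_band is None:
        intersection_band = spec.strand_radius
    if intersection_band <= 0:
        raise ValueError("intersection_band must be > 0")
    strands = strand_centerlines(spec)
    R = spec.strand_radius

    coords_parts: list[np.ndarray] = []
    area_parts: list[np.ndarray] = []
    normal_parts: list[np.ndarray] = []
    strand_idx_parts: list[np.ndarray] = []
    axial_parts: list[np.ndarray] = []

    ds_circ = 2 * np.pi * R / resolution
    theta = 2 * np.pi * np.arange(resolution) / resolution

    for si, s in enumerate(strands):
        n_ax = max(1, int(round(s.length / ds_circ)))
        da = s.length / n_ax
        axial = -s.half_length + (np.arange(n_ax) + 0.5) * da
        origin, axis, e1, e2 = _strand_frame(s)
        # radial unit vectors for each theta (theta measured from global +y)
        radial = np.outer(np.cos(theta), e1) + np.outer(np.sin(theta), e2)
        pts = (
            origin[None, None, :]
            + axial[:, None, None] * axis[None, None, :]
            + R * radial[None, :, :]
        ).reshape(-1, 3)
        coords_parts.append(pts)
        normal_parts.append(np.broadcast_to(radial[None, :, :], (n_ax, resolution, 3)).reshape(-1, 3))
        area_parts.append(np.full(pts.shape[0], ds_circ * da))
        strand_idx_parts.append(np.full(pts.shape[0], si, dtype=np.intp))
        axial_parts.append(np.repeat(axial, resolution))

    coords = np.vstack(coords_parts)
    areas = np.concatenate(area_parts)
    normals = np.vstack(normal_parts)
    strand_idx = np.concatenate(strand_idx_parts)
    axial_pos = np.concatenate(axial_parts)

    keep = ~_inside_other_strand(coords, strand_idx, strands, R)
    coords, areas, normals = coords[keep], areas[keep], normals[keep]
    strand_idx, axial_pos = strand_idx[keep], axial_pos[keep]

    region = _tag_regions(strands, strand_idx, axial_pos, normals, intersection_band)

    mesh = SurfaceMesh(
        node_coords=coords,
        node_area=areas,
        node_region=region,
        node_normal=normals,
        node_strand=strand_idx,
        spec=spec,
        strands=strands,
    )
    mesh.validate()
    return mesh


def _inside_other_strand(
    coords: np.ndarray, strand_idx: np.ndarray, strands: list[Strand], R: float
) -> np.ndarray:
    """Boolean mask of nodes strictly inside a strand other than their own."""
    inside = np.zeros(coords.shape[0], dtype=bool)
    tol = 1e-9
    for si, s in enumerate(strands):
        origin, axis, _, _ = _strand_frame(s)
        rel = coords - origin
        t_ax = rel @ axis
        radial = rel - np.outer(t_ax, axis)
        r = np.linalg.norm(radial, axis=1)
        hit = (
            (strand_idx != si)
            & (r < R * (1 - tol))
            & (np.abs(t_ax) <= s.half_length)
        )
        inside |= hit
    return inside


def _tag_regions(
    strands: list[Strand],
    strand_idx: np.ndarray,
    axial_pos: np.ndarray,
    normals: np.ndarray,
    band: float,
) -> np.ndarray:
    region = np.empty(strand_idx.shape[0], dtype="<U16")
    # crossing-strand offsets per layer/orientation
    offsets_by_layer: dict[int, np.ndarray] = {}
    for s in strands:
        offsets_by_layer.setdefault(s.layer, [])
    tmp: dict[int, list[float]] = {s.layer: [] for s in strands}
    for s in strands:
        tmp[s.layer].append(s.offset)
    offsets_by_layer = {k: np.sort(np.asarray(v)) for k, v in tmp.items()}

    vertical = normals[:, 1]
    region[:] = "strand_free"
    region[vertical > np.sqrt(0.5)] = "strand_top"
    region[vertical < -np.sqrt(0.5)] = "strand_bottom"

    for si, s in enumerate(strands):
        mask = strand_idx == si
        if not np.any(mask):
            continue
        cross_offsets = []
        for nb in (s.layer - 1, s.layer + 1):
            if nb in offsets_by_layer:
                cross_offsets.append(offsets_by_layer[nb])
        if not cross_offsets:
            continue
        cross = np.concatenate(cross_offsets)
        d = np.min(np.abs(axial_pos[mask][:, None] - cross[None, :]), axis=1)
        m = mask.copy()
        m[mask] = d <= band
        region[m] = "intersection"
    return region


def rotated_mirror_copy(mesh: SurfaceMesh) -> np.ndarray:
    """Coordinates after 90-degree rotation about y plus mid-lattice height flip.

    For an even layer count this composite map sends the node multiset onto
    itself (lattice symmetry); exposed for property checks.
    """
    heights = mesh.spec.layer_heights()
    mid = float(heights[0] + heights[-1]) / 2.0
    x, y, z = mesh.node_coords.T
    # rotate (x, z) -> (z, -x); flip heights about the lattice mid-plane
    return np.column_stack([z, 2 * mid - y, -x])
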