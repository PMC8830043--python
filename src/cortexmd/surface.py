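"""Cortical-ribbon surface geometry.

Meshes, vertex maps, ribbon-midpoint computation, per-vertex thickness and
area, volume-to-surface sampling, and geodesic Gaussian smoothing of vertex
maps.  Coordinates are world mm (RAS for NIfTI affines); vertex indices are
0-based throughout.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import connected_components, dijkstra

__all__ = [
    "SurfaceMesh",
    "SurfacePair",
    "VertexMap",
    "ScalarVolume",
    "ribbon_midpoints",
    "sample_volume_at_points",
    "cortical_thickness",
    "vertex_areas",
    "smoothing_operator",
    "smooth_vertex_map",
    "mesh_edge_graph",
    "read_ply",
    "write_ply",
    "read_freesurfer_geometry",
    "write_freesurfer_geometry",
]

# FWHM = sigma * sqrt(8 ln 2)
FWHM_PER_SIGMA = float(np.sqrt(8.0 * np.log(2.0)))


@dataclass
class SurfaceMesh:
    """Triangle mesh: ``vertices`` (N, 3) world mm, ``faces`` (M, 3) indices.

    Faces are counter-clockwise when viewed from outside.  Analysis meshes
    must be a single connected component with no zero-area faces.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (N, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (M, 3)")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        a = v[self.faces[:, 1]] - v[self.faces[:, 0]]
        b = v[self.faces[:, 2]] - v[self.faces[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)

    def total_area(self) -> float:
        return float(self.face_areas().sum())

    def euler_characteristic(self) -> int:
        edges = np.sort(
            np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]),
            axis=1,
        )
        n_edges = len(np.unique(edges, axis=0))
        return self.n_vertices - n_edges + self.n_faces

    def validate(self) -> None:
        """Raise if the mesh has degenerate faces or is disconnected."""
        if np.any(self.face_areas() <= 0.0):
            raise ValueError("mesh has zero-area (degenerate) faces")
        n_comp, _ = connected_components(mesh_edge_graph(self), directed=False)
        if n_comp != 1:
            raise ValueError(f"mesh has {n_comp} connected components; expected 1")


@dataclass
class SurfacePair:
    """White and pial meshes with 1:1 vertex correspondence.

    The gray-matter ribbon lies between the two; identical face lists are
    required so every white vertex pairs with the same-index pial vertex.
    """

    white: SurfaceMesh
    pial: SurfaceMesh

    def __post_init__(self) -> None:
        if self.white.n_vertices != self.pial.n_vertices:
            raise ValueError(
                f"white/pial vertex counts differ: {self.white.n_vertices} vs {self.pial.n_vertices}"
            )
        if self.white.n_faces != self.pial.n_faces or not np.array_equal(
            self.white.faces, self.pial.faces
        ):
            raise ValueError("white/pial face lists differ; 1:1 correspondence required")

    @property
    def n_vertices(self) -> int:
        return self.white.n_vertices


@dataclass
class VertexMap:
    """One scalar per vertex plus an explicit missing mask.

    Missing vertices (e.g. out-of-FOV samples) are carried as NaN in
    ``values`` and True in ``missing``; they are never silently imputed.
    """

    values: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        else:
            self.missing = np.asarray(self.missing, dtype=bool).ravel()
            if self.missing.shape != self.values.shape:
                raise ValueError("missing mask length must equal values length")
            self.missing = self.missing | ~np.isfinite(self.values)
        self.values = np.where(self.missing, np.nan, self.values)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())


@dataclass
class ScalarVolume:
    """Per-voxel scalar (e.g. MD in mm^2/s) with a voxel-to-world affine.

    Invalid voxels are NaN.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")


# ---------------------------------------------------------------------------
# ribbon geometry


def ribbon_midpoints(pair: SurfacePair) -> np.ndarray:
    """Midpoint of the cortical ribbon: half-way between corresponding
    white and pial vertices, (N, 3) world mm."""
    return pair.white.vertices + 0.5 * (pair.pial.vertices - pair.white.vertices)


def cortical_thickness(pair: SurfacePair) -> VertexMap:
    """Per-vertex thickness = Euclidean distance between corresponding
    white and pial vertices, mm."""
    t = np.linalg.norm(pair.pial.vertices - pair.white.vertices, axis=1)
    return VertexMap(t)


def vertex_areas(mesh: SurfaceMesh) -> VertexMap:
    """Barycentric vertex areas: one third of each incident triangle's area.

    Sums to the total mesh area, so cluster areas in mm^2 are additive over
    member vertices.
    """
    fa = mesh.face_areas() / 3.0
    areas = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(areas, mesh.faces[:, k], fa)
    return VertexMap(areas)


# ---------------------------------------------------------------------------
# volume sampling


def sample_volume_at_points(
    volume: ScalarVolume,
    points: np.ndarray,
    affine_adjust: np.ndarray | None = None,
) -> VertexMap:
    """Trilinear sampling of a volume at world-coordinate points.

    World coordinates go to voxel indices through the inverse of the volume
    affine, optionally composed with an extra world-to-world ``affine_adjust``
    (diffusion-to-anatomical alignment).  Points outside the grid, or whose
    8-neighbor support touches an invalid (NaN) voxel, come back missing —
    never extrapolated.
    """
    points = np.asarray(points, dtype=np.float64)
    if not np.all(np.isfinite(points)):
        raise ValueError("sample points must be finite")
    A = volume.affine
    if affine_adjust is not None:
        affine_adjust = np.asarray(affine_adjust, dtype=np.float64)
        if affine_adjust.shape != (4, 4):
            raise ValueError("affine_adjust must be 4x4")
        # voxel -> native world -> adjusted world
        A = affine_adjust @ volume.affine
    if abs(np.linalg.det(A[:3, :3])) < 1e-300:
        raise np.linalg.LinAlgError("singular volume affine")
    inv = np.linalg.inv(A)
    ijk = points @ inv[:3, :3].T + inv[:3, 3]

    shape = np.array(volume.data.shape, dtype=np.float64)
    inside = np.all((ijk >= 0.0) & (ijk <= shape - 1.0), axis=1)

    vals = ndimage.map_coordinates(
        volume.data, ijk.T, order=1, mode="constant", cval=np.nan
    )
    vals[~inside] = np.nan
    return VertexMap(vals)


# ---------------------------------------------------------------------------
# geodesic Gaussian smoothing


def mesh_edge_graph(mesh: SurfaceMesh, weighted: bool = True) -> sparse.csr_matrix:
    """Symmetric sparse adjacency of mesh edges; weights are edge lengths (mm)
    when ``weighted`` else 1."""
    e = np.concatenate([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]])
    if weighted:
        w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    else:
        w = np.ones(len(e))
    n = mesh.n_vertices
    g = sparse.coo_matrix((w, (e[:, 0], e[:, 1])), shape=(n, n)).tocsr()
    return g.maximum(g.T)


def smoothing_operator(mesh: SurfaceMesh, fwhm: float) -> sparse.csr_matrix:
    """Row-stochastic geodesic Gaussian smoothing matrix S.

    Weights exp(-d^2 / (2 sigma^2)) with sigma = fwhm / sqrt(8 ln 2), d the
    shortest edge-path distance (Dijkstra, mm), truncated at 3 sigma and
    renormalized per row.  fwhm=0 gives the identity.  Precompute once and
    reuse for repeated smoothing (e.g. Monte Carlo nulls).
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    n = mesh.n_vertices
    if fwhm == 0:
        return sparse.identity(n, format="csr")
    sigma = fwhm / FWHM_PER_SIGMA
    graph = mesh_edge_graph(mesh)
    d = dijkstra(graph, directed=False, limit=3.0 * sigma)
    finite = np.isfinite(d)
    rows, cols = np.nonzero(finite)
    w = np.exp(-d[finite] ** 2 / (2.0 * sigma**2))
    S = sparse.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    rowsum = np.asarray(S.sum(axis=1)).ravel()
    return sparse.diags(1.0 / rowsum) @ S


def smooth_vertex_map(
    mesh: SurfaceMesh,
    vmap: VertexMap | np.ndarray,
    fwhm: float,
    operator: sparse.csr_matrix | None = None,
) -> VertexMap:
    """Geodesic Gaussian smoothing of a vertex map.

    Missing vertices are excluded from both numerator and denominator at
    their neighbors and stay missing themselves.  Pass a precomputed
    ``operator`` (from :func:`smoothing_operator`) to amortize the geodesic
    computation over many maps.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if not isinstance(vmap, VertexMap):
        vmap = VertexMap(vmap)
    if len(vmap) != mesh.n_vertices:
        raise ValueError("vertex map length must equal mesh vertex count")
    if fwhm == 0:
        return VertexMap(vmap.values.copy(), vmap.missing.copy())
    S = operator if operator is not None else smoothing_operator(mesh, fwhm)
    ok = (~vmap.missing).astype(np.float64)
    num = S @ np.where(vmap.missing, 0.0, vmap.values)
    den = S @ ok
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[vmap.missing | (den <= 0.0)] = np.nan
    return VertexMap(out)


# ---------------------------------------------------------------------------
# mesh I/O


def write_ply(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write the mesh as binary little-endian PLY."""
    path = Path(path)
    header = (
        "ply\n"
        "format binary_little_endian 1.0\n"
        f"element vertex {mesh.n_vertices}\n"
        "property float64 x\nproperty float64 y\nproperty float64 z\n"
        f"element face {mesh.n_faces}\n"
        "property list uchar int32 vertex_indices\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(mesh.vertices.astype("<f8").tobytes())
        face_rec = np.empty(mesh.n_faces, dtype=[("n", "u1"), ("idx", "<i4", 3)])
        face_rec["n"] = 3
        face_rec["idx"] = mesh.faces
        fh.write(face_rec.tobytes())


def read_ply(path: str | Path) -> SurfaceMesh:
    """Read a binary little-endian PLY written by :func:`write_ply`."""
    with open(path, "rb") as fh:
        line = fh.readline().strip()
        if line != b"ply":
            raise ValueError(f"{path}: not a PLY file")
        n_vert = n_face = None
        vprops: list[str] = []
        element = None
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated PLY header")
            tok = line.decode("ascii").split()
            if not tok:
                continue
            if tok[0] == "format" and tok[1] != "binary_little_endian":
                raise ValueError(f"{path}: only binary little-endian PLY supported")
            elif tok[0] == "element":
                element = tok[1]
                if element == "vertex":
                    n_vert = int(tok[2])
                elif element == "face":
                    n_face = int(tok[2])
            elif tok[0] == "property" and element == "vertex":
                vprops.append(tok[1])
            elif tok[0] == "end_header":
                break
        if n_vert is None or n_face is None:
            raise ValueError(f"{path}: missing vertex/face elements")
        fmt = {"float64": "<f8", "double": "<f8", "float32": "<f4", "float": "<f4"}
        dt = np.dtype([(f"p{i}", fmt[p]) for i, p in enumerate(vprops)])
        vraw = np.frombuffer(fh.read(dt.itemsize * n_vert), dtype=dt, count=n_vert)
        vertices = np.stack([vraw[f"p{i}"] for i in range(3)], axis=1).astype(np.float64)
        faces = np.empty((n_face, 3), dtype=np.int64)
        buf = fh.read()
        off = 0
        for i in range(n_face):
            (cnt,) = struct.unpack_from("<B", buf, off)
            if cnt != 3:
                raise ValueError(f"{path}: non-triangular face")
            faces[i] = struct.unpack_from("<3i", buf, off + 1)
            off += 1 + 12
    return SurfaceMesh(vertices, faces)


def write_freesurfer_geometry(mesh: SurfaceMesh, path: str | Path) -> None:
    from nibabel.freesurfer.io import write_geometry

    write_geometry(str(path), mesh.vertices, mesh.faces.astype(np.int32))


def read_freesurfer_geometry(path: str | Path) -> SurfaceMesh:
    from nibabel.freesurfer.io import read_geometry

    v, f = read_geometry(str(path))
    return SurfaceMesh(np.asarray(v, dtype=np.float64), np.asarray(f, dtype=np.int64))
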