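"""Synthetic cortical phantoms and multi-site cohorts with known ground truth.

The phantom is a sphere, not a brain: the white surface is an icosphere, the
pial surface the same vertices displaced outward, so ribbon geometry, vertex
areas, mesh connectivity and cross-subject correspondence are all exact by
construction.  Patient groups receive regional cortical thinning in an
"atrophy core" and mean-diffusivity elevation in a wider core+halo, scaled by
a disease-severity score; sites add additive/multiplicative MD perturbations
before DWI synthesis.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .dti import DiffusionProtocol, DWIVolume, TensorVolume
from .surface import SurfaceMesh, SurfacePair, VertexMap, mesh_edge_graph

__all__ = [
    "PhantomSpec",
    "EffectSpec",
    "SiteEffectSpec",
    "icosphere",
    "make_surface_pair",
    "geodesic_cap",
    "make_tensor_volume",
    "simulate_dwi",
    "default_cohort_table",
    "simulate_cohort",
    "SimulatedCohort",
    "PPA_GROUPS",
    "DEFAULT_GROUP_SIZES",
]

PPA_GROUPS = ("nfvppa", "svppa", "lvppa", "ppa-grn")
VALID_GROUPS = ("control",) + PPA_GROUPS

# study-like default cohort: 52 non-fluent, 31 semantic, 32 logopenic
# variants plus 89 controls, spread over 4 scanners
DEFAULT_GROUP_SIZES = {"control": 89, "nfvppa": 52, "svppa": 31, "lvppa": 32}
DEFAULT_SITES = ("siteA", "siteB", "siteC", "siteD")


@dataclass
class PhantomSpec:
    """Geometry, tissue and acquisition parameters of the sphere phantom.

    Defaults: 50 mm white radius / 3 mm ribbon (cortex-like), isotropic
    ribbon MD 0.8e-3 mm^2/s (literature-typical cortical gray value),
    white-matter tensor eigenvalues (1.7, 0.3, 0.3)e-3 mm^2/s, 2.7 mm
    isotropic DWI voxels.
    """

    icosphere_subdivisions: int = 3
    white_radius: float = 50.0
    baseline_thickness: float = 3.0
    ribbon_md: float = 0.8e-3
    wm_tensor_eigenvalues: tuple[float, float, float] = (1.7e-3, 0.3e-3, 0.3e-3)
    voxel_size: float = 2.7
    noise_sigma: float = 0.0
    s0: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.icosphere_subdivisions < 2:
            raise ValueError("icosphere_subdivisions must be >= 2")
        if self.white_radius <= 0:
            raise ValueError("white_radius must be > 0")
        if self.baseline_thickness <= 0:
            raise ValueError("baseline_thickness must be > 0")
        if not (0.0 < self.ribbon_md < 4.0e-3):
            raise ValueError("ribbon_md must lie in (0, 4e-3) mm^2/s")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")


@dataclass
class EffectSpec:
    """Regional disease effect injected into patient phantoms.

    ``core_region`` receives both thinning and MD elevation; ``halo_region``
    (may overlap the core) receives MD elevation only — mirroring
    microstructural damage that extends beyond macroscopic atrophy.
    ``thickness_only_region`` is an optional control region with thinning but
    no MD change.  ``severity_slope`` adds ``slope * severity`` to the
    per-subject effect magnitudes (effect units per severity point).
    """

    core_region: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    halo_region: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    thickness_reduction: float = 0.0
    md_elevation: float = 0.0
    severity_slope: float = 0.0
    thickness_only_region: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=np.int64)
    )

    def __post_init__(self) -> None:
        self.core_region = np.unique(np.asarray(self.core_region, dtype=np.int64))
        self.halo_region = np.unique(np.asarray(self.halo_region, dtype=np.int64))
        self.thickness_only_region = np.unique(
            np.asarray(self.thickness_only_region, dtype=np.int64)
        )

    def validate(self, n_vertices: int, baseline_thickness: float) -> None:
        for region in (self.core_region, self.halo_region, self.thickness_only_region):
            if region.size and (region.min() < 0 or region.max() >= n_vertices):
                raise ValueError("effect region contains out-of-range vertex ids")
        if self.thickness_reduction >= baseline_thickness:
            raise ValueError("thickness_reduction must be smaller than baseline thickness")

    def md_region(self) -> np.ndarray:
        """Vertices with MD elevation: core ∪ halo."""
        return np.union1d(self.core_region, self.halo_region)

    def thinning_region(self) -> np.ndarray:
        return np.union1d(self.core_region, self.thickness_only_region)


@dataclass
class SiteEffectSpec:
    """Per-site additive MD shift (mm^2/s) and residual variance scale (>0)."""

    additive_shift: dict[str, float] = field(default_factory=dict)
    variance_scale: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for site, scale in self.variance_scale.items():
            if scale <= 0:
                raise ValueError(f"variance_scale for site {site!r} must be > 0")

    def shift(self, site: str) -> float:
        return float(self.additive_shift.get(site, 0.0))

    def scale(self, site: str) -> float:
        return float(self.variance_scale.get(site, 1.0))


# ---------------------------------------------------------------------------
# geometry


def icosphere(subdivisions: int, radius: float = 1.0) -> SurfaceMesh:
    """Icosahedron subdivided ``subdivisions`` times and projected to a
    sphere: 10*4^n + 2 vertices, 20*4^n faces, Euler characteristic 2."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    for _ in range(subdivisions):
        edge_mid: dict[tuple[int, int], int] = {}
        new_verts = [verts]
        n = len(verts)

        def midpoint(i: int, j: int) -> int:
            nonlocal n
            key = (i, j) if i < j else (j, i)
            if key not in edge_mid:
                m = verts[i] + verts[j]
                m /= np.linalg.norm(m)
                new_verts.append(m[None, :])
                edge_mid[key] = n
                n += 1
            return edge_mid[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.concatenate(new_verts)
        faces = np.array(new_faces, dtype=np.int64)
    return SurfaceMesh(verts * radius, faces)


def make_surface_pair(spec: PhantomSpec) -> SurfacePair:
    """White icosphere plus a pial surface displaced outward along vertex
    normals (radial on the sphere) by the baseline thickness."""
    white = icosphere(spec.icosphere_subdivisions, spec.white_radius)
    normals = white.vertices / np.linalg.norm(white.vertices, axis=1, keepdims=True)
    pial = SurfaceMesh(white.vertices + spec.baseline_thickness * normals, white.faces)
    return SurfacePair(white, pial)


def geodesic_cap(mesh: SurfaceMesh, seed_vertex: int, radius_mm: float) -> np.ndarray:
    """Vertex ids within geodesic (edge-path) distance ``radius_mm`` of the
    seed vertex — the phantom's stand-in for an anatomical region."""
    d = dijkstra(mesh_edge_graph(mesh), directed=False, indices=seed_vertex, limit=radius_mm)
    return np.nonzero(np.isfinite(d))[0].astype(np.int64)


def displaced_pair(
    base: SurfacePair, thickness: np.ndarray | VertexMap
) -> SurfacePair:
    """Pair with the pial surface moved so the per-vertex white→pial distance
    equals ``thickness`` (direction preserved)."""
    t = thickness.values if isinstance(thickness, VertexMap) else np.asarray(thickness)
    d = base.pial.vertices - base.white.vertices
    norm = np.linalg.norm(d, axis=1, keepdims=True)
    unit = np.divide(d, norm, out=np.zeros_like(d), where=norm > 0)
    pial = SurfaceMesh(base.white.vertices + unit * t[:, None], base.white.faces)
    return SurfacePair(base.white, pial)


# ---------------------------------------------------------------------------
# forward tensor model


def _wm_tensor(eigenvalues: tuple[float, float, float]) -> np.ndarray:
    """Anisotropic WM tensor, principal axis along z (lab frame)."""
    l1, l2, l3 = eigenvalues
    return np.diag([l2, l3, l1]).astype(np.float64)


def phantom_grid(spec: PhantomSpec, margin_voxels: int = 2) -> tuple[tuple[int, int, int], np.ndarray]:
    """Default grid: isotropic voxels, affine a scaled identity centered on
    the sphere, sized to contain the pial surface plus a margin."""
    half = spec.white_radius + spec.baseline_thickness + margin_voxels * spec.voxel_size
    n = int(np.ceil(2.0 * half / spec.voxel_size)) + 1
    affine = np.diag([spec.voxel_size] * 3 + [1.0])
    affine[:3, 3] = -spec.voxel_size * (n - 1) / 2.0
    return (n, n, n), affine


def make_tensor_volume(
    spec: PhantomSpec,
    pair: SurfacePair,
    effect: EffectSpec | None = None,
    subject_md_map: VertexMap | np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
    affine: np.ndarray | None = None,
) -> TensorVolume:
    """Forward tensor field for the sphere phantom.

    Ribbon voxels (centers radially between the white and the — possibly
    thinned — pial surface) carry an isotropic tensor whose MD is the nearest
    vertex's value: ``subject_md_map`` if given, else the baseline ribbon MD
    plus the effect's elevation in core ∪ halo.  Interior voxels carry the
    anisotropic WM tensor, exterior voxels the zero tensor.
    """
    if shape is None or affine is None:
        if (shape is None) != (affine is None):
            raise ValueError("pass both shape and affine, or neither")
        shape, affine = phantom_grid(spec)
    affine = np.asarray(affine, dtype=np.float64)

    # voxel centers in world coordinates
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    ijk = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(np.float64)
    xyz = ijk @ affine[:3, :3].T + affine[:3, 3]

    pial_r = np.linalg.norm(pair.pial.vertices, axis=1)
    if np.any(np.max(np.abs(xyz), axis=0) < pial_r.max()):
        raise ValueError("voxel grid too small: it does not contain the pial surface")

    r = np.linalg.norm(xyz, axis=1)
    # nearest vertex by direction on the unit sphere
    unit_v = pair.white.vertices / np.linalg.norm(pair.white.vertices, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit_x = np.divide(xyz, r[:, None], out=np.zeros_like(xyz), where=r[:, None] > 0)
    nearest = cKDTree(unit_v).query(unit_x)[1]

    ribbon = (r >= spec.white_radius) & (r <= pial_r[nearest])
    interior = r < spec.white_radius

    md = np.full(pair.n_vertices, spec.ribbon_md)
    if subject_md_map is not None:
        vals = (
            subject_md_map.values
            if isinstance(subject_md_map, VertexMap)
            else np.asarray(subject_md_map, dtype=np.float64)
        )
        if len(vals) != pair.n_vertices:
            raise ValueError("subject_md_map length must equal vertex count")
        md = vals
    elif effect is not None:
        effect.validate(pair.n_vertices, spec.baseline_thickness)
        md[effect.md_region()] += effect.md_elevation

    n_vox = len(xyz)
    d6 = np.zeros((n_vox, 6))
    ribbon_md_vox = md[nearest[ribbon]]
    d6[ribbon, 0] = d6[ribbon, 1] = d6[ribbon, 2] = ribbon_md_vox
    wm = _wm_tensor(spec.wm_tensor_eigenvalues)
    d6[interior, :3] = np.diag(wm)

    ln_s0 = np.full(n_vox, np.log(spec.s0))
    valid = np.ones(n_vox, dtype=bool)
    return TensorVolume(
        d6.reshape(shape + (6,)),
        ln_s0.reshape(shape),
        affine,
        valid.reshape(shape),
    )


def simulate_dwi(
    tensors: TensorVolume,
    protocol: DiffusionProtocol,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> DWIVolume:
    """Forward DWI synthesis: S(g, b) = S0 exp(-b g^T D g) per voxel, with
    Rician noise of scale ``noise_sigma`` (Gaussian on the two quadrature
    channels).  Deterministic given the seed."""
    b = tensors.d6.reshape(-1, 6)
    g = protocol.bvecs
    # g^T D g = gx^2 Dxx + gy^2 Dyy + gz^2 Dzz + 2 gx gy Dxy + 2 gx gz Dxz + 2 gy gz Dyz
    quad = np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2.0 * g[:, 0] * g[:, 1],
            2.0 * g[:, 0] * g[:, 2],
            2.0 * g[:, 1] * g[:, 2],
        ]
    )  # (n_volumes, 6)
    expo = -(b @ quad.T) * protocol.bvals[None, :]
    sig = np.exp(tensors.ln_s0.reshape(-1, 1) + expo)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        re = sig + rng.normal(0.0, noise_sigma, sig.shape)
        im = rng.normal(0.0, noise_sigma, sig.shape)
        sig = np.hypot(re, im)
    return DWIVolume(sig.reshape(tensors.shape + (protocol.n_volumes,)), tensors.affine)


# ---------------------------------------------------------------------------
# cohorts


def default_cohort_table(
    group_sizes: dict[str, int] | None = None,
    sites: tuple[str, ...] = DEFAULT_SITES,
    seed: int = 0,
) -> pd.DataFrame:
    """Study-like cohort table: demographics, site assignment, CDR plus NACC
    FTLD sum-of-boxes severity (0 for controls), global stage, and MMSE."""
    sizes = dict(DEFAULT_GROUP_SIZES if group_sizes is None else group_sizes)
    for g in sizes:
        if g not in VALID_GROUPS:
            raise ValueError(f"unknown group label {g!r}; valid: {VALID_GROUPS}")
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for group, n in sizes.items():
        for _ in range(n):
            site = sites[idx % len(sites)]
            age = float(np.clip(rng.normal(68.0, 8.0), 40.0, 90.0))
            sex = "F" if rng.random() < 0.5 else "M"
            hand = "R" if rng.random() < 0.9 else "L"
            if group == "control":
                stage, severity = 0.0, 0.0
                mmse = float(np.clip(np.round(rng.normal(29.0, 1.0)), 24, 30))
            else:
                stage = float(rng.choice([0.5, 1.0, 2.0], p=[0.4, 0.4, 0.2]))
                lo, hi = {0.5: (0.5, 4.0), 1.0: (4.0, 9.0), 2.0: (9.0, 18.0)}[stage]
                severity = float(np.round(rng.uniform(lo, hi) * 2) / 2)
                mmse = float(np.clip(np.round(30.0 - 0.9 * severity + rng.normal(0, 1.5)), 0, 30))
            rows.append(
                dict(
                    id=f"sub-{idx:04d}",
                    group=group,
                    site=site,
                    age=round(age, 1),
                    sex=sex,
                    handedness=hand,
                    severity=severity,
                    global_stage=stage,
                    mmse=mmse,
                )
            )
            idx += 1
    return pd.DataFrame(rows)


@dataclass
class SimulatedCohort:
    """Bundle returned by :func:`simulate_cohort`.

    Vertex-map matrices are (n_subjects, n_vertices) aligned with ``cohort``
    rows.  ``md_clean``/``thickness_clean`` are the noiseless, site-free
    ground truth; ``md_observed``/``thickness_observed`` add measurement
    noise and (MD only) site effects.  ``dwi`` maps subject id to a
    DWIVolume when synthesis was requested.
    """

    cohort: pd.DataFrame
    base_pair: SurfacePair
    phantom: PhantomSpec
    effect: EffectSpec
    md_clean: np.ndarray
    md_observed: np.ndarray
    thickness_clean: np.ndarray
    thickness_observed: np.ndarray
    dwi: dict[str, DWIVolume] = field(default_factory=dict)

    def subject_pair(self, row: int) -> SurfacePair:
        """White/pial pair for one subject, pial displaced to the subject's
        ground-truth thickness."""
        return displaced_pair(self.base_pair, self.thickness_clean[row])


def simulate_cohort(
    design: pd.DataFrame | None,
    phantom: PhantomSpec,
    effect: EffectSpec,
    site_effects: SiteEffectSpec | None = None,
    seed: int = 0,
    md_noise: float = 0.06e-3,
    thickness_noise: float = 0.3,
    with_dwi: bool = False,
    protocol: DiffusionProtocol | None = None,
) -> SimulatedCohort:
    """Simulate a multi-site cohort of cortical phantoms.

    Patients receive thinning in the core and MD elevation in core ∪ halo,
    scaled per subject by ``severity_slope * severity``; controls stay at
    baseline.  Per-subject measurement noise defaults to 0.06e-3 mm^2/s (MD)
    and 0.3 mm (thickness) — realistic vertex-wise repeatability scales.
    Site effects shift the MD mean and scale the MD residual per the ComBat
    generative model.  When ``with_dwi`` is set, a DWI volume is synthesized
    per subject from the observed MD map (requires a protocol).
    """
    cohort = default_cohort_table(seed=seed) if design is None else design.copy()
    required = {"id", "group", "site", "age", "sex", "handedness", "severity"}
    if not required.issubset(cohort.columns):
        raise ValueError(f"cohort table missing columns: {sorted(required - set(cohort.columns))}")
    bad = set(cohort["group"]) - set(VALID_GROUPS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    if cohort["id"].duplicated().any():
        raise ValueError("subject ids must be unique")
    if site_effects is not None:
        bad_sites = set(site_effects.additive_shift) | set(site_effects.variance_scale)
        bad_sites -= set(cohort["site"])
        if bad_sites:
            raise ValueError(f"site effects name unknown sites: {sorted(bad_sites)}")
    site_effects = site_effects or SiteEffectSpec()

    pair = make_surface_pair(phantom)
    effect.validate(pair.n_vertices, phantom.baseline_thickness)
    n, V = len(cohort), pair.n_vertices
    rng = np.random.default_rng(seed)

    md_clean = np.full((n, V), phantom.ribbon_md)
    th_clean = np.full((n, V), phantom.baseline_thickness)
    md_region = effect.md_region()
    thin_region = effect.thinning_region()
    is_patient = (cohort["group"] != "control").to_numpy()
    severity = cohort["severity"].to_numpy(dtype=np.float64)
    # per-subject effect magnitudes; severity raises both in lockstep
    gain = np.where(is_patient, 1.0 + effect.severity_slope * severity, 0.0)
    md_clean[:, md_region] += np.outer(gain, np.full(md_region.size, effect.md_elevation))
    th_clean[:, thin_region] -= np.outer(gain, np.full(thin_region.size, effect.thickness_reduction))
    th_clean = np.maximum(th_clean, 0.05)

    shifts = cohort["site"].map(site_effects.shift).to_numpy(dtype=np.float64)
    scales = cohort["site"].map(site_effects.scale).to_numpy(dtype=np.float64)
    md_obs = (
        md_clean
        + shifts[:, None]
        + np.sqrt(scales)[:, None] * rng.normal(0.0, md_noise, (n, V))
    )
    th_obs = th_clean + rng.normal(0.0, thickness_noise, (n, V))

    dwi: dict[str, DWIVolume] = {}
    if with_dwi:
        if protocol is None:
            raise ValueError("with_dwi=True requires a diffusion protocol")
        for i, sid in enumerate(cohort["id"]):
            spair = displaced_pair(pair, th_clean[i])
            tensors = make_tensor_volume(phantom, spair, subject_md_map=md_obs[i])
            dwi[sid] = simulate_dwi(
                tensors, protocol, phantom.noise_sigma, seed=int(rng.integers(2**31))
            )

    return SimulatedCohort(
        cohort=cohort,
        base_pair=pair,
        phantom=phantom,
        effect=effect,
        md_clean=md_clean,
        md_observed=md_obs,
        thickness_clean=th_clean,
        thickness_observed=th_obs,
        dwi=dwi,
    )
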