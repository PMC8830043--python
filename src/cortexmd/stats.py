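"""Vertex-wise GLM inference on surface maps.

Group comparison and severity/MMSE correlation by per-vertex OLS, cluster
extraction on the mesh at a forming threshold, cluster-wise family-wise
error correction against a Monte Carlo max-cluster-area null (smoothed
Gaussian noise), Cohen's d effect-size maps, and the net effect-size map
contrasting MD and thickness effect magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats as sps
from scipy.sparse.csgraph import connected_components

from .surface import (
    SurfaceMesh,
    VertexMap,
    mesh_edge_graph,
    smoothing_operator,
    vertex_areas,
)

__all__ = [
    "GLMResult",
    "Cluster",
    "ClusterResult",
    "EffectSizeMap",
    "build_design",
    "glm_fit",
    "correlation_analysis",
    "cluster_extract",
    "monte_carlo_null",
    "cluster_fwe",
    "cohens_d",
    "net_effect_size",
]


@dataclass
class GLMResult:
    """Per-vertex OLS results for one contrast.

    ``beta`` is (p, V); ``t``/``p`` are the contrast t-statistic and
    two-sided Student-t p-value; ``dof`` the residual degrees of freedom of
    complete vertices; ``degenerate`` flags zero-residual fits (p is NaN
    there); ``missing`` flags vertices with too few complete cases.
    """

    beta: np.ndarray
    t: np.ndarray
    p: np.ndarray
    dof: int
    contrast: np.ndarray
    column_names: list[str] = field(default_factory=list)
    degenerate: np.ndarray | None = None
    missing: np.ndarray | None = None


@dataclass
class Cluster:
    vertices: np.ndarray
    area: float
    peak_vertex: int
    sign: int
    p_fwe: float | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    alpha_forming: float

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self) -> int:
        return len(self.clusters)

    def significant(self, fwe_alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_fwe is not None and c.p_fwe < fwe_alpha]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    cluster=i,
                    n_vertices=c.n_vertices,
                    area_mm2=c.area,
                    peak_vertex=c.peak_vertex,
                    sign=c.sign,
                    p_fwe=c.p_fwe,
                )
                for i, c in enumerate(self.clusters)
            ]
        )


@dataclass
class EffectSizeMap:
    """Per-vertex Cohen's d (unitless); NaN where undefined or masked."""

    d: np.ndarray
    mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# design construction


def build_design(
    cohort: pd.DataFrame,
    predictor: str | None,
    covariates: tuple[str, ...],
    group_pair: tuple[str, str] | None = None,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Design matrix with intercept, a predictor of interest, and nuisance
    covariates; returns (X, column names, contrast vector).

    For a two-class comparison pass ``group_pair=(a, b)``: the predictor
    column is an indicator (1 for group a, 0 for group b) and the contrast
    tests a - b.  For a correlation pass ``predictor`` naming a numeric
    column.  Categorical covariates are reference-coded (k-1 indicators).
    """
    cols = [np.ones(len(cohort))]
    names = ["intercept"]
    if group_pair is not None:
        a, b = group_pair
        groups = cohort["group"].astype(str)
        if not set(groups) <= {a, b}:
            raise ValueError(f"cohort contains groups other than {a!r}/{b!r}")
        cols.append((groups == a).to_numpy(dtype=np.float64))
        names.append(f"group[{a}]")
    elif predictor is not None:
        x = cohort[predictor].to_numpy(dtype=np.float64)
        if np.all(x == x[0]):
            raise ValueError(f"predictor {predictor!r} is constant; nothing to correlate")
        cols.append(x)
        names.append(predictor)
    else:
        raise ValueError("either predictor or group_pair is required")
    for cov in covariates:
        series = cohort[cov]
        if series.dtype.kind in "ifu":
            cols.append(series.to_numpy(dtype=np.float64))
            names.append(cov)
        else:
            for lev in sorted(series.astype(str).unique())[1:]:
                cols.append((series.astype(str) == lev).to_numpy(dtype=np.float64))
                names.append(f"{cov}[{lev}]")
    X = np.column_stack(cols)
    contrast = np.zeros(X.shape[1])
    contrast[1] = 1.0
    return X, names, contrast


def _raise_rank_deficiency(X: np.ndarray, names: list[str]) -> None:
    kept: list[int] = []
    bad: list[str] = []
    for j in range(X.shape[1]):
        if np.linalg.matrix_rank(X[:, kept + [j]]) == len(kept) + 1:
            kept.append(j)
        else:
            bad.append(names[j] if j < len(names) else f"col{j}")
    raise ValueError("rank-deficient design matrix; collinear columns: " + ", ".join(bad))


# ---------------------------------------------------------------------------
# GLM


def _ols_block(X: np.ndarray, Y: np.ndarray, c: np.ndarray):
    """OLS of Y (n, V) on X (n, p) with contrast c; returns beta, t, p, dof,
    degenerate flags."""
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    rss = np.sum(resid**2, axis=0)
    dof = n - p
    sigma2 = rss / dof
    cvar = float(c @ xtx_inv @ c)
    scale = np.sqrt(sigma2 * cvar)
    est = c @ beta
    degenerate = scale <= np.sqrt(np.finfo(float).eps) * np.maximum(np.abs(est), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / scale
    pvals = 2.0 * sps.t.sf(np.abs(t), dof)
    pvals = np.minimum(np.maximum(pvals, np.finfo(float).tiny), 1.0)
    t[degenerate] = np.where(est[degenerate] > 0, np.inf, -np.inf)
    pvals[degenerate] = np.nan
    return beta, t, pvals, dof, degenerate


def glm_fit(
    Y: np.ndarray,
    X: np.ndarray,
    contrast: np.ndarray,
    column_names: list[str] | None = None,
    min_complete_fraction: float = 0.9,
) -> GLMResult:
    """Per-vertex ordinary least squares with a single contrast.

    Missing subject values are dropped listwise per vertex; vertices where
    fewer than ``min_complete_fraction`` of subjects (or fewer than p+2
    subjects) contribute come back missing.  Raises on a rank-deficient
    design, naming the collinear columns.
    """
    Y = np.asarray(Y, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    c = np.asarray(contrast, dtype=np.float64)
    n, p = X.shape
    names = column_names or [f"col{j}" for j in range(p)]
    if Y.shape[0] != n:
        raise ValueError("Y rows must match design rows")
    if n <= p + 1:
        raise ValueError(f"n={n} subjects cannot identify p={p} columns (need n > p+1)")
    if np.linalg.matrix_rank(X) < p:
        _raise_rank_deficiency(X, names)

    V = Y.shape[1]
    beta = np.full((p, V), np.nan)
    t = np.full(V, np.nan)
    pv = np.full(V, np.nan)
    degenerate = np.zeros(V, dtype=bool)
    missing = np.zeros(V, dtype=bool)

    obs = ~np.isnan(Y)
    n_obs = obs.sum(axis=0)
    min_n = max(p + 2, int(np.ceil(min_complete_fraction * n)))
    usable = n_obs >= min_n
    missing[~usable] = True

    complete = usable & (n_obs == n)
    if complete.any():
        b, tt, pp, dof, dg = _ols_block(X, Y[:, complete], c)
        beta[:, complete] = b
        t[complete] = tt
        pv[complete] = pp
        degenerate[complete] = dg
    else:
        dof = n - p
    partial = usable & ~complete
    if partial.any():
        cols = np.nonzero(partial)[0]
        patterns: dict[bytes, list[int]] = {}
        for v in cols:
            patterns.setdefault(obs[:, v].tobytes(), []).append(v)
        for key, vs in patterns.items():
            rows = np.frombuffer(key, dtype=bool)
            Xs = X[rows]
            if np.linalg.matrix_rank(Xs) < p:
                missing[vs] = True
                continue
            b, tt, pp, _, dg = _ols_block(Xs, Y[np.ix_(rows, vs)], c)
            beta[:, vs] = b
            t[vs] = tt
            pv[vs] = pp
            degenerate[vs] = dg
    return GLMResult(beta, t, pv, dof, c, names, degenerate, missing)


def correlation_analysis(
    Y: np.ndarray,
    cohort: pd.DataFrame,
    predictor: str,
    covariates: tuple[str, ...] = ("age", "sex", "handedness"),
) -> GLMResult:
    """Vertex-wise association with a continuous predictor (severity or
    MMSE), adjusting for nuisance covariates.  Positive t means the map
    increases with the predictor."""
    X, names, c = build_design(cohort, predictor, covariates)
    return glm_fit(Y, X, c, names)


# ---------------------------------------------------------------------------
# clusters and family-wise error


def cluster_extract(
    mesh: SurfaceMesh,
    pmap: np.ndarray | VertexMap,
    tmap: np.ndarray | VertexMap,
    alpha_forming: float,
    areas: np.ndarray | None = None,
) -> ClusterResult:
    """Connected suprathreshold components under mesh-edge connectivity.

    The suprathreshold set is {v : p_v < alpha_forming}, split by the sign of
    t so opposite-direction effects never merge; cluster area is the sum of
    member (barycentric) vertex areas in mm^2.
    """
    p = pmap.values if isinstance(pmap, VertexMap) else np.asarray(pmap, dtype=np.float64)
    t = tmap.values if isinstance(tmap, VertexMap) else np.asarray(tmap, dtype=np.float64)
    if len(p) != mesh.n_vertices or len(t) != mesh.n_vertices:
        raise ValueError("maps must align with the mesh vertex count")
    if areas is None:
        areas = vertex_areas(mesh).values
    graph = mesh_edge_graph(mesh, weighted=False)
    clusters: list[Cluster] = []
    with np.errstate(invalid="ignore"):
        supra = p < alpha_forming
    for sign in (1, -1):
        sel = supra & ((t > 0) if sign > 0 else (t < 0))
        idx = np.nonzero(sel)[0]
        if idx.size == 0:
            continue
        sub = graph[np.ix_(idx, idx)]
        n_comp, labels = connected_components(sub, directed=False)
        for k in range(n_comp):
            members = idx[labels == k]
            peak = members[np.nanargmax(np.abs(t[members]))]
            clusters.append(
                Cluster(
                    vertices=members,
                    area=float(areas[members].sum()),
                    peak_vertex=int(peak),
                    sign=sign,
                )
            )
    clusters.sort(key=lambda cl: -cl.area)
    return ClusterResult(clusters, alpha_forming)


def monte_carlo_null(
    mesh: SurfaceMesh,
    fwhm: float,
    alpha_forming: float,
    n_sims: int = 10_000,
    seed: int = 0,
    operator: sparse.csr_matrix | None = None,
    areas: np.ndarray | None = None,
    batch: int = 200,
) -> np.ndarray:
    """Null distribution of the maximum cluster area.

    Each repeat draws independent standard-normal noise per vertex, smooths
    it with the analysis kernel, re-standardizes the smoothed field to unit
    variance, converts z to two-sided p, extracts clusters at the forming
    threshold and records the largest area (0 if none).  Deterministic given
    the seed.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100 for a usable null")
    S = operator if operator is not None else smoothing_operator(mesh, fwhm)
    if areas is None:
        areas = vertex_areas(mesh).values
    graph = mesh_edge_graph(mesh, weighted=False)
    rng = np.random.default_rng(seed)
    z_crit = sps.norm.isf(alpha_forming / 2.0)
    maxima = np.empty(n_sims)
    done = 0
    while done < n_sims:
        nb = min(batch, n_sims - done)
        noise = rng.standard_normal((mesh.n_vertices, nb))
        smoothed = S @ noise
        sd = smoothed.std(axis=0, ddof=1)
        z = smoothed / sd[None, :]
        for j in range(nb):
            zj = z[:, j]
            best = 0.0
            for sign in (1, -1):
                idx = np.nonzero(zj * sign > z_crit)[0]
                if idx.size == 0:
                    continue
                if idx.size == 1:
                    best = max(best, float(areas[idx].sum()))
                    continue
                sub = graph[np.ix_(idx, idx)]
                n_comp, labels = connected_components(sub, directed=False)
                comp_areas = np.bincount(labels, weights=areas[idx])
                best = max(best, float(comp_areas.max()))
            maxima[done + j] = best
        done += nb
    return maxima


def cluster_fwe(observed: ClusterResult, null_max_areas: np.ndarray) -> ClusterResult:
    """Attach FWE-corrected p-values by the add-one Monte Carlo rule:
    p_fwe = (1 + #{null maxima >= area}) / (n_sims + 1)."""
    null_max_areas = np.asarray(null_max_areas, dtype=np.float64)
    if null_max_areas.size == 0:
        raise ValueError("empty null distribution")
    n = null_max_areas.size
    for cl in observed.clusters:
        exceed = int(np.sum(null_max_areas >= cl.area))
        cl.p_fwe = (1 + exceed) / (n + 1)
    return observed


# ---------------------------------------------------------------------------
# effect sizes


def cohens_d(
    Y: np.ndarray,
    group_a_mask: np.ndarray,
    group_b_mask: np.ndarray,
    nuisance: np.ndarray | None = None,
) -> EffectSizeMap:
    """Vertex-wise Cohen's d between two groups, a minus b.

    When nuisance covariates are given, Y is first residualized on
    [intercept, nuisance] fitted over both groups; d is the residual group
    mean difference over the pooled residual SD.  Vertices with zero pooled
    SD come back missing.
    """
    Y = np.asarray(Y, dtype=np.float64)
    ga = np.asarray(group_a_mask, dtype=bool)
    gb = np.asarray(group_b_mask, dtype=bool)
    if ga.sum() < 2 or gb.sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    if np.any(ga & gb):
        raise ValueError("group masks overlap")
    sel = ga | gb
    Ysel = Y[sel]
    if nuisance is not None:
        Xn = np.column_stack([np.ones(sel.sum()), np.asarray(nuisance, dtype=np.float64)[sel]])
        coef, *_ = np.linalg.lstsq(Xn, np.where(np.isnan(Ysel), 0.0, Ysel), rcond=None)
        Ysel = Ysel - Xn @ coef
    a = Ysel[ga[sel]]
    b = Ysel[gb[sel]]
    n1, n2 = len(a), len(b)
    m1, m2 = np.nanmean(a, axis=0), np.nanmean(b, axis=0)
    s1, s2 = np.nanvar(a, axis=0, ddof=1), np.nanvar(b, axis=0, ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (m1 - m2) / pooled
    d[pooled == 0] = np.nan
    return EffectSizeMap(d)


def net_effect_size(
    d_md: EffectSizeMap,
    d_ct: EffectSizeMap,
    sig_mask: np.ndarray,
) -> EffectSizeMap:
    """Net effect size |d_MD| - |d_thickness| inside the significance mask.

    Positive values mark vertices where the mean-diffusivity effect exceeds
    the thickness effect; outside the mask the map is missing.  ``sig_mask``
    is a boolean map or an index array of FWE-significant vertices from
    either metric.
    """
    dm = np.asarray(d_md.d, dtype=np.float64)
    dc = np.asarray(d_ct.d, dtype=np.float64)
    if dm.shape != dc.shape:
        raise ValueError("effect-size maps must share the mesh")
    V = dm.shape[0]
    sig_mask = np.asarray(sig_mask)
    if sig_mask.dtype == bool:
        if sig_mask.shape != (V,):
            raise ValueError("boolean mask length must equal vertex count")
        mask = sig_mask
    else:
        if sig_mask.size and (sig_mask.min() < 0 or sig_mask.max() >= V):
            raise ValueError("mask vertex ids out of range")
        mask = np.zeros(V, dtype=bool)
        mask[sig_mask.astype(np.int64)] = True
    net = np.full(V, np.nan)
    net[mask] = np.abs(dm[mask]) - np.abs(dc[mask])
    return EffectSizeMap(net, mask)
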