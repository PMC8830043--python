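"""End-to-end analyses: each patient group vs controls, the mild-stage
subgroup, and severity/MMSE correlations.

Each run smooths the vertex maps with the analysis kernel, harmonizes MD
across sites (ComBat; thickness instead keeps site as a GLM covariate),
fits the vertex-wise GLM, corrects clusters by the Monte Carlo max-area
null, maps Cohen's d, and writes maps/cluster tables plus a JSON manifest
that fully determines a re-run.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .harmonize import combat_fit_apply, make_covariate_design
from .stats import (
    ClusterResult,
    EffectSizeMap,
    GLMResult,
    build_design,
    cluster_extract,
    cluster_fwe,
    cohens_d,
    correlation_analysis,
    glm_fit,
    monte_carlo_null,
    net_effect_size,
)
from .surface import SurfaceMesh, smooth_vertex_map, smoothing_operator, vertex_areas

__all__ = ["AnalysisConfig", "MetricResult", "AnalysisBundle",
           "run_group_comparison", "run_mild_subgroup", "run_correlation"]

# thickness keeps site/center as a GLM nuisance covariate; MD does not,
# because MD is harmonized across sites beforehand
THICKNESS_COVARIATES = ("age", "sex", "handedness", "site")
MD_COVARIATES = ("age", "sex", "handedness")


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters with study-default values."""

    fwhm: float = 15.0
    alpha_forming_group: float = 0.001
    alpha_forming_subgroup: float = 0.05
    fwe_alpha: float = 0.05
    n_sims: int = 10_000
    harmonize_md: bool = True
    combat_covariates: tuple[str, ...] = ("group", "age", "sex", "handedness")
    thickness_covariates: tuple[str, ...] = THICKNESS_COVARIATES
    md_covariates: tuple[str, ...] = MD_COVARIATES
    mild_stage: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for a in (self.alpha_forming_group, self.alpha_forming_subgroup, self.fwe_alpha):
            if not (0.0 < a < 1.0):
                raise ValueError("alpha thresholds must lie in (0, 1)")
        if self.n_sims < 100:
            raise ValueError("n_sims must be >= 100")
        if self.fwhm < 0:
            raise ValueError("fwhm must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("combat_covariates", "thickness_covariates", "md_covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("combat_covariates", "thickness_covariates", "md_covariates"):
            d[key] = list(d[key])
        return d


@dataclass
class MetricResult:
    metric: str
    glm: GLMResult
    clusters: ClusterResult
    null_max_areas: np.ndarray
    d: EffectSizeMap | None = None

    def significant_vertices(self, fwe_alpha: float = 0.05) -> np.ndarray:
        ids = [c.vertices for c in self.clusters.significant(fwe_alpha)]
        return np.unique(np.concatenate(ids)) if ids else np.array([], dtype=np.int64)


@dataclass
class AnalysisBundle:
    config: AnalysisConfig
    md: MetricResult
    thickness: MetricResult
    net: EffectSizeMap | None
    manifest: dict
    cohort: pd.DataFrame = field(default_factory=pd.DataFrame)


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def _prepare_metric(
    Y: np.ndarray,
    mesh: SurfaceMesh,
    cohort: pd.DataFrame,
    config: AnalysisConfig,
    metric: str,
    operator,
) -> np.ndarray:
    """Smooth per subject, then (MD only) harmonize across sites."""
    sm = np.vstack(
        [smooth_vertex_map(mesh, Y[i], config.fwhm, operator=operator).values for i in range(len(Y))]
    )
    if metric == "md" and config.harmonize_md:
        if cohort["site"].nunique() > 1:
            Xc, names = make_covariate_design(cohort, config.combat_covariates)
            sm, _ = combat_fit_apply(sm, cohort["site"].to_numpy(), Xc, names)
    return sm


def _analyze_metric(
    Y: np.ndarray,
    mesh: SurfaceMesh,
    cohort: pd.DataFrame,
    config: AnalysisConfig,
    metric: str,
    alpha_forming: float,
    group_pair: tuple[str, str] | None,
    predictor: str | None,
    operator,
    areas: np.ndarray,
    null_max: np.ndarray,
) -> MetricResult:
    covs = config.md_covariates if metric == "md" else config.thickness_covariates
    covs = tuple(c for c in covs if c != "site" or cohort["site"].nunique() > 1)
    Ysm = _prepare_metric(Y, mesh, cohort, config, metric, operator)
    if group_pair is not None:
        X, names, c = build_design(cohort, None, covs, group_pair=group_pair)
        glm = glm_fit(Ysm, X, c, names)
    else:
        glm = correlation_analysis(Ysm, cohort, predictor, covs)
    clusters = cluster_extract(mesh, glm.p, glm.t, alpha_forming, areas=areas)
    clusters = cluster_fwe(clusters, null_max)
    d = None
    if group_pair is not None:
        ga = (cohort["group"] == group_pair[0]).to_numpy()
        gb = (cohort["group"] == group_pair[1]).to_numpy()
        Xn, _ = make_covariate_design(cohort, tuple(c for c in covs if c != "group"))
        d = cohens_d(Ysm, ga, gb, nuisance=Xn if Xn.shape[1] else None)
    return MetricResult(metric, glm, clusters, null_max, d)


def run_group_comparison(
    cohort: pd.DataFrame,
    md_maps: np.ndarray,
    ct_maps: np.ndarray,
    mesh: SurfaceMesh,
    config: AnalysisConfig,
    group_a: str,
    group_b: str = "control",
    alpha_forming: float | None = None,
    out_dir: str | Path | None = None,
) -> AnalysisBundle:
    """Two-class vertex-wise comparison for both metrics.

    MD is smoothed, harmonized and modeled with age/sex/handedness;
    thickness is smoothed and modeled with age/sex/handedness/site.  Both
    are cluster-corrected against the same smoothed-noise max-area null, and
    the net effect-size map is restricted to the union of either metric's
    FWE-significant vertices.
    """
    t0 = time.time()
    _check_alignment(cohort, md_maps, ct_maps, mesh)
    sel = cohort["group"].isin([group_a, group_b]).to_numpy()
    if (cohort.loc[sel, "group"] == group_a).sum() < 2 or (
        cohort.loc[sel, "group"] == group_b
    ).sum() < 2:
        raise ValueError(f"groups {group_a!r}/{group_b!r} need >= 2 subjects each")
    sub = cohort.loc[sel].reset_index(drop=True)
    alpha = config.alpha_forming_group if alpha_forming is None else alpha_forming

    operator = smoothing_operator(mesh, config.fwhm)
    areas = vertex_areas(mesh).values
    null_max = monte_carlo_null(
        mesh, config.fwhm, alpha, config.n_sims, seed=config.seed,
        operator=operator, areas=areas,
    )
    md_res = _analyze_metric(
        md_maps[sel], mesh, sub, config, "md", alpha,
        (group_a, group_b), None, operator, areas, null_max,
    )
    ct_res = _analyze_metric(
        ct_maps[sel], mesh, sub, config, "thickness", alpha,
        (group_a, group_b), None, operator, areas, null_max,
    )
    sig = np.union1d(
        md_res.significant_vertices(config.fwe_alpha),
        ct_res.significant_vertices(config.fwe_alpha),
    )
    net = net_effect_size(md_res.d, ct_res.d, sig)

    manifest = _make_manifest(
        kind="group_comparison",
        config=config,
        cohort=sub,
        inputs={"md_maps": _hash_array(md_maps[sel]), "ct_maps": _hash_array(ct_maps[sel]),
                "mesh_vertices": _hash_array(mesh.vertices)},
        extra={
            "group_a": group_a,
            "group_b": group_b,
            "alpha_forming": alpha,
            "n_in": int(len(cohort)),
            "n_excluded": int(len(cohort) - len(sub)),
            "n_analyzed": int(len(sub)),
            "n_vertices": int(mesh.n_vertices),
            "n_md_clusters_significant": len(md_res.clusters.significant(config.fwe_alpha)),
            "n_ct_clusters_significant": len(ct_res.clusters.significant(config.fwe_alpha)),
            "elapsed_s": round(time.time() - t0, 3),
        },
    )
    bundle = AnalysisBundle(config, md_res, ct_res, net, manifest, sub)
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def run_mild_subgroup(
    cohort: pd.DataFrame,
    md_maps: np.ndarray,
    ct_maps: np.ndarray,
    mesh: SurfaceMesh,
    config: AnalysisConfig,
    group_a: str,
    group_b: str = "control",
    out_dir: str | Path | None = None,
) -> AnalysisBundle:
    """Group comparison restricted to mild-stage patients (global severity
    stage equal to ``config.mild_stage``) plus all of group_b, at the
    subgroup forming threshold (default 0.05)."""
    if "global_stage" not in cohort.columns:
        raise ValueError("cohort table needs a 'global_stage' column for staging")
    keep = (cohort["group"] == group_b) | (
        (cohort["group"] == group_a) & (cohort["global_stage"] == config.mild_stage)
    )
    n_mild = int(((cohort["group"] == group_a) & keep).sum())
    if n_mild == 0:
        raise ValueError(f"no {group_a!r} participants at stage {config.mild_stage}")
    sel = keep.to_numpy()
    bundle = run_group_comparison(
        cohort.loc[sel].reset_index(drop=True),
        md_maps[sel],
        ct_maps[sel],
        mesh,
        config,
        group_a,
        group_b,
        alpha_forming=config.alpha_forming_subgroup,
        out_dir=None,
    )
    bundle.manifest["kind"] = "mild_subgroup"
    bundle.manifest["mild_stage"] = config.mild_stage
    bundle.manifest["n_mild_patients"] = n_mild
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def run_correlation(
    cohort: pd.DataFrame,
    md_maps: np.ndarray,
    ct_maps: np.ndarray,
    mesh: SurfaceMesh,
    config: AnalysisConfig,
    predictor: str = "severity",
    group: str | None = None,
    out_dir: str | Path | None = None,
) -> AnalysisBundle:
    """Vertex-wise correlation of both metrics with a continuous predictor
    (severity or MMSE), within one patient group if given, at the
    correlation forming threshold (default 0.05)."""
    t0 = time.time()
    _check_alignment(cohort, md_maps, ct_maps, mesh)
    if group is not None:
        sel = (cohort["group"] == group).to_numpy()
        if sel.sum() < 3:
            raise ValueError(f"group {group!r} too small for correlation")
    else:
        sel = np.ones(len(cohort), dtype=bool)
    sub = cohort.loc[sel].reset_index(drop=True)
    x = sub[predictor].to_numpy(dtype=np.float64)
    if np.all(x == x[0]):
        raise ValueError(f"predictor {predictor!r} is constant in the analyzed sample")
    alpha = config.alpha_forming_subgroup

    operator = smoothing_operator(mesh, config.fwhm)
    areas = vertex_areas(mesh).values
    null_max = monte_carlo_null(
        mesh, config.fwhm, alpha, config.n_sims, seed=config.seed,
        operator=operator, areas=areas,
    )
    md_res = _analyze_metric(
        md_maps[sel], mesh, sub, config, "md", alpha, None, predictor,
        operator, areas, null_max,
    )
    ct_res = _analyze_metric(
        ct_maps[sel], mesh, sub, config, "thickness", alpha, None, predictor,
        operator, areas, null_max,
    )
    manifest = _make_manifest(
        kind="correlation",
        config=config,
        cohort=sub,
        inputs={"md_maps": _hash_array(md_maps[sel]), "ct_maps": _hash_array(ct_maps[sel]),
                "mesh_vertices": _hash_array(mesh.vertices)},
        extra={
            "predictor": predictor,
            "group": group,
            "alpha_forming": alpha,
            "n_in": int(len(cohort)),
            "n_excluded": int(len(cohort) - len(sub)),
            "n_analyzed": int(len(sub)),
            "elapsed_s": round(time.time() - t0, 3),
        },
    )
    bundle = AnalysisBundle(config, md_res, ct_res, None, manifest, sub)
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


# ---------------------------------------------------------------------------
# plumbing


def _check_alignment(cohort, md_maps, ct_maps, mesh) -> None:
    n, V = len(cohort), mesh.n_vertices
    if md_maps.shape != (n, V):
        raise ValueError(
            f"MD matrix shape {md_maps.shape} does not match cohort x mesh ({n}, {V})"
        )
    if ct_maps.shape != (n, V):
        raise ValueError(
            f"thickness matrix shape {ct_maps.shape} does not match cohort x mesh ({n}, {V})"
        )
    if cohort["id"].duplicated().any():
        raise ValueError("duplicate subject ids in cohort table")


def _make_manifest(kind, config, cohort, inputs, extra) -> dict:
    m = {
        "kind": kind,
        "software": {"name": "cortexmd", "version": __version__},
        "config": config.to_dict(),
        "inputs": inputs,
        "cohort_hash": hashlib.sha256(
            cohort.to_csv(index=False).encode()
        ).hexdigest()[:16],
        "groups": cohort["group"].value_counts().to_dict(),
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    m.update(extra)
    return m


def write_bundle(bundle: AnalysisBundle, out_dir: str | Path) -> None:
    """Write maps/*.csv, clusters/*.csv and manifest.json under a run dir."""
    out = Path(out_dir)
    (out / "maps").mkdir(parents=True, exist_ok=True)
    (out / "clusters").mkdir(exist_ok=True)
    for res in (bundle.md, bundle.thickness):
        df = pd.DataFrame(
            {
                "vertex_id": np.arange(len(res.glm.t)),
                "t": res.glm.t,
                "p": res.glm.p,
            }
        )
        if res.d is not None:
            df["d"] = res.d.d
        if bundle.net is not None:
            df["net"] = bundle.net.d
        df.to_csv(out / "maps" / f"{res.metric}.csv", index=False)
        res.clusters.to_frame().to_csv(out / "clusters" / f"{res.metric}.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2, default=str))
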