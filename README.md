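# cortexmd

Surface-based cortical mean diffusivity (cMD) analysis for group studies of
neurodegeneration — built so that every stage can be validated end-to-end on
synthetic cortical phantoms with known ground truth.

Cortical mean diffusivity, the trace/3 of the diffusion tensor sampled inside
the cortical gray matter, is a microstructural marker that often changes
before (and beyond) macroscopic cortical thinning. Comparing cMD and
thickness maps vertex by vertex therefore asks a clinically meaningful
question: *where does microstructural damage extend beyond atrophy?* This
package implements the full analysis chain used for that comparison in
multi-center studies of primary progressive aphasia and similar conditions:

1. **Tensor fitting** (`cortexmd.dti`) — per-voxel OLS on the log signal,
   `ln S(g,b) = ln S0 − b·gᵀDg`, and MD = trace(D)/3.
2. **Ribbon sampling** (`cortexmd.surface`) — the MD volume is sampled by
   trilinear interpolation at the midpoint of the cortical ribbon,
   `m_v = w_v + ½(p_v − w_v)` between corresponding white/pial vertices;
   thickness is `‖p_v − w_v‖`.
3. **Geodesic smoothing** — Gaussian kernel on the mesh
   (FWHM 15 mm default, σ = FWHM/√(8 ln 2), Dijkstra geodesics, 3σ
   truncation).
4. **Multi-site harmonization** (`cortexmd.harmonize`) — parametric ComBat:
   empirical-Bayes estimation of each site's additive (location) and
   multiplicative (scale) effect per vertex, preserving modeled biological
   covariates.
5. **Vertex-wise inference** (`cortexmd.stats`) — per-vertex GLM with
   nuisance covariates, cluster extraction at a forming threshold
   (α = 0.001 for whole-group contrasts, 0.05 for subgroup/correlation
   analyses), cluster-wise family-wise error control against a Monte Carlo
   max-cluster-area null (10,000 smoothed-noise repeats by default), Cohen's
   d maps, and the **net effect size** `|d_MD| − |d_thickness|` restricted to
   vertices significant for either metric.
6. **Phantoms** (`cortexmd.phantom`) — icosphere white/pial pairs, forward
   tensor fields (isotropic ribbon ≈ 0.8×10⁻³ mm²/s, anisotropic white
   matter), Rician-noise DWI synthesis, and multi-site cohorts with a
   thinning "core", an MD-only "halo", severity scaling and injected site
   effects.

`cortexmd.pipeline` wires these into the three study analyses (each patient
group vs controls, mild-stage subgroup, severity/MMSE correlation) and writes
per-vertex maps, cluster tables and a JSON manifest per run.

## Worked example

Simulate a two-site cohort of 30 patients and 30 controls on a 642-vertex
sphere phantom. Patients get 0.36 mm of thinning plus a 0.048×10⁻³ mm²/s MD
elevation in a 12 mm "core" cap, and the same MD elevation alone in a 45 mm
"halo"; one site has a +0.05×10⁻³ MD offset and another doubled variance.

```python
import numpy as np
import cortexmd as cm

spec = cm.PhantomSpec(icosphere_subdivisions=3)   # 642-vertex sphere phantom
pair = cm.make_surface_pair(spec)
core = cm.geodesic_cap(pair.white, 0, 12.0)       # atrophy core
halo = cm.geodesic_cap(pair.white, 0, 45.0)       # wider MD-only halo
effect = cm.EffectSpec(core_region=core, halo_region=halo,
                       thickness_reduction=0.36, md_elevation=0.048e-3)
design = cm.default_cohort_table({"control": 30, "nfvppa": 30}, seed=7)
sites = cm.SiteEffectSpec({"siteB": 0.05e-3}, {"siteC": 2.0})
sim = cm.simulate_cohort(design, spec, effect, sites, seed=7)

cfg = cm.AnalysisConfig(n_sims=10_000, seed=7)
bundle = cm.run_group_comparison(sim.cohort, sim.md_observed,
                                 sim.thickness_observed, pair.white, cfg, "nfvppa")

for res in (bundle.md, bundle.thickness):
    for c in res.clusters.significant():
        print(f"{res.metric:9s} cluster: {c.n_vertices:3d} vertices, "
              f"{c.area:7.0f} mm^2, peak |t| at vertex {c.peak_vertex}, "
              f"p_fwe = {c.p_fwe:.4f}")
halo_only = np.setdiff1d(halo, core)
print(f"net effect size: halo mean {np.nanmean(bundle.net.d[halo_only]):+.2f}")
```

Output:

```
md        cluster: 101 vertices,    4997 mm^2, peak |t| at vertex 195, p_fwe = 0.0001
thickness cluster:   8 vertices,     360 mm^2, peak |t| at vertex 0, p_fwe = 0.0001
net effect size: halo mean +1.63
```

The MD cluster (≈5,000 mm²) covers the core *and* the halo, while the
thickness cluster stays confined to the core — the dissociation the analysis
is designed to expose. The positive net effect size in the halo marks
cortex where microstructure is affected but thickness is not. `p_fwe` is the
add-one Monte Carlo estimate: with 10,000 repeats the smallest attainable
value is 1/10001.

A command-line interface mirrors the stages
(`cortexmd simulate | fit-dti | sample | harmonize | analyze`); run
`cortexmd --help`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole chain from scratch: it simulates the two-site phantom
cohort, synthesizes and refits DWI for one subject (forward → inverse tensor
round trip, ribbon sampling), then executes the full group comparison with
harmonization and 10,000-repeat cluster correction, printing the cluster
counts, halo coverage by each metric and the net effect size, and writes the
results JSON to `--out`.

See `docs/methods.md` for the model details, parameter defaults, numerical
choices and known limitations.
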