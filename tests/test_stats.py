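"""Vertex-wise GLM, cluster inference, effect sizes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import cortexmd as cm
from cortexmd.stats import (
    build_design,
    cluster_extract,
    cluster_fwe,
    cohens_d,
    correlation_analysis,
    glm_fit,
    monte_carlo_null,
    net_effect_size,
)


def brute_force_glm(X, y, c):
    """Independent normal-equations oracle for a single vertex."""
    xtx_inv = np.linalg.inv(X.T @ X)
    b = xtx_inv @ X.T @ y
    dof = len(y) - X.shape[1]
    s2 = np.sum((y - X @ b) ** 2) / dof
    t = (c @ b) / np.sqrt(s2 * (c @ xtx_inv @ c))
    p = 2 * sps.t.sf(abs(t), dof)
    return b, t, p


class TestGLM:
    @pytest.fixture()
    def fixture8(self):
        rng = np.random.default_rng(20)
        X = np.column_stack([np.ones(8), [0, 0, 0, 0, 1, 1, 1, 1], rng.uniform(50, 80, 8)])
        Y = rng.standard_normal((8, 6)) + X[:, 1:2] * 0.5
        c = np.array([0.0, 1.0, 0.0])
        return X, Y, c

    def test_matches_brute_force_oracle(self, fixture8):
        X, Y, c = fixture8
        res = glm_fit(Y, X, c, min_complete_fraction=0.0)
        for v in range(Y.shape[1]):
            b, t, p = brute_force_glm(X, Y[:, v], c)
            assert np.allclose(res.beta[:, v], b, atol=1e-10)
            assert np.isclose(res.t[v], t, atol=1e-10)
            assert np.isclose(res.p[v], p, atol=1e-10)
        assert res.dof == 5

    def test_exact_fit_degenerate(self, fixture8):
        X, _, c = fixture8
        b_true = np.array([[1.0], [2.0], [0.5]])
        Y = X @ b_true
        res = glm_fit(Y, X, c, min_complete_fraction=0.0)
        assert np.allclose(res.beta, b_true, atol=1e-10)
        assert res.degenerate[0]
        assert np.isnan(res.p[0])

    def test_rank_deficiency_names_columns(self, fixture8):
        X, Y, c = fixture8
        Xbad = np.column_stack([X, X[:, 1]])
        with pytest.raises(ValueError, match="collinear"):
            glm_fit(Y, Xbad, np.r_[c, 0.0], ["intercept", "group", "age", "group_copy"])

    def test_missing_listwise_per_vertex(self):
        rng = np.random.default_rng(21)
        n = 40
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        Y = rng.standard_normal((n, 3))
        Y[0, 1] = np.nan          # 1 of 40 missing: still analyzed
        Y[: n // 2, 2] = np.nan   # half missing: dropped at 90% rule
        res = glm_fit(Y, X, np.array([0.0, 1.0]))
        assert not res.missing[0] and not res.missing[1]
        assert res.missing[2] and np.isnan(res.t[2])
        # vertex 1 equals oracle on its complete cases
        ok = ~np.isnan(Y[:, 1])
        _, t, _ = brute_force_glm(X[ok], Y[ok, 1], np.array([0.0, 1.0]))
        assert np.isclose(res.t[1], t, atol=1e-10)

    def test_null_pvalues_uniform(self):
        # 10,000 independent null vertices: KS test not rejected at 1%
        rng = np.random.default_rng(22)
        n, V = 30, 10_000
        X = np.column_stack([np.ones(n), rng.standard_normal(n), rng.standard_normal(n)])
        Y = rng.standard_normal((n, V))
        res = glm_fit(Y, X, np.array([0.0, 1.0, 0.0]))
        stat = sps.kstest(res.p, "uniform")
        assert stat.pvalue > 0.01

    def test_design_builder_group_and_covariates(self):
        tab = pd.DataFrame(
            {
                "group": ["nfvppa", "control", "nfvppa", "control"],
                "age": [60.0, 65.0, 70.0, 75.0],
                "sex": ["F", "M", "F", "M"],
                "handedness": ["R", "R", "L", "R"],
                "site": ["A", "A", "B", "B"],
            }
        )
        X, names, c = build_design(tab, None, ("age", "sex", "handedness", "site"),
                                   group_pair=("nfvppa", "control"))
        assert names[0] == "intercept" and names[1] == "group[nfvppa]"
        assert "site[B]" in names and "sex[M]" in names
        assert c[1] == 1.0 and c.sum() == 1.0
        X2, names2, _ = build_design(tab, None, ("age", "sex", "handedness"),
                                     group_pair=("nfvppa", "control"))
        assert "site[B]" not in names2


class TestCorrelation:
    def test_sign_recovery(self):
        rng = np.random.default_rng(23)
        n, V = 40, 50
        tab = pd.DataFrame(
            {
                "group": ["nfvppa"] * n,
                "age": rng.uniform(55, 80, n),
                "sex": rng.choice(["F", "M"], n),
                "handedness": rng.choice(["R", "L"], n, p=[0.9, 0.1]),
                "severity": rng.uniform(0.5, 12.0, n),
            }
        )
        a = 0.01
        Y = a * tab["severity"].to_numpy()[:, None] + rng.normal(0, 0.02, (n, V))
        res = correlation_analysis(Y, tab, "severity")
        assert np.all(np.sign(res.beta[1]) == np.sign(a))

    def test_constant_predictor_rejected(self):
        tab = pd.DataFrame(
            {"group": ["control"] * 5, "age": [60.0] * 5, "sex": ["F"] * 5,
             "handedness": ["R"] * 5, "severity": [0.0] * 5}
        )
        with pytest.raises(ValueError, match="constant"):
            correlation_analysis(np.zeros((5, 3)), tab, "severity")

    def test_null_type_one_calibration(self):
        # zero-slope null: ~5% of 200 vertices below p=0.05
        rng = np.random.default_rng(24)
        n, V = 40, 200
        tab = pd.DataFrame(
            {
                "group": ["svppa"] * n,
                "age": rng.uniform(55, 80, n),
                "sex": rng.choice(["F", "M"], n),
                "handedness": rng.choice(["R", "L"], n),
                "severity": rng.uniform(0.5, 12.0, n),
            }
        )
        Y = rng.standard_normal((n, V))
        res = correlation_analysis(Y, tab, "severity")
        frac = np.mean(res.p < 0.05)
        ci = 3 * np.sqrt(0.05 * 0.95 / V)
        assert abs(frac - 0.05) <= ci


def flood_fill_components(mesh, mask):
    """Brute-force BFS connected components over suprathreshold vertices."""
    adj = {v: set() for v in np.nonzero(mask)[0]}
    for f in mesh.faces:
        for a, b in ((0, 1), (1, 2), (2, 0)):
            u, w = f[a], f[b]
            if mask[u] and mask[w]:
                adj[u].add(w)
                adj[w].add(u)
    seen, comps = set(), []
    for start in adj:
        if start in seen:
            continue
        comp, queue = set(), [start]
        while queue:
            v = queue.pop()
            if v in comp:
                continue
            comp.add(v)
            queue.extend(adj[v] - comp)
        seen |= comp
        comps.append(np.array(sorted(comp)))
    return comps


class TestClusters:
    def test_no_suprathreshold_empty(self, mesh642):
        p = np.ones(mesh642.n_vertices)
        t = np.zeros(mesh642.n_vertices)
        assert len(cluster_extract(mesh642, p, t, 0.001)) == 0

    def test_all_suprathreshold_one_cluster(self, mesh642):
        p = np.zeros(mesh642.n_vertices)
        t = np.ones(mesh642.n_vertices)
        res = cluster_extract(mesh642, p, t, 0.05)
        assert len(res) == 1
        assert np.isclose(res.clusters[0].area, mesh642.total_area(), rtol=1e-6)

    def test_antipodal_caps_vs_flood_fill_oracle(self, mesh642):
        capA = cm.geodesic_cap(mesh642, 0, 15.0)
        anti = int(np.argmax(np.linalg.norm(mesh642.vertices - mesh642.vertices[0], axis=1)))
        capB = cm.geodesic_cap(mesh642, anti, 15.0)
        p = np.ones(mesh642.n_vertices)
        t = np.zeros(mesh642.n_vertices)
        p[capA] = p[capB] = 1e-5
        t[capA] = t[capB] = 3.0
        res = cluster_extract(mesh642, p, t, 0.001)
        assert len(res) == 2
        mask = p < 0.001
        oracle = flood_fill_components(mesh642, mask)
        areas = cm.vertex_areas(mesh642).values
        got = sorted(round(c.area, 9) for c in res)
        exp = sorted(round(float(areas[c].sum()), 9) for c in oracle)
        assert got == exp
        members = sorted(tuple(c.vertices) for c in res)
        assert members == sorted(tuple(c) for c in oracle)

    def test_sign_split(self, mesh642):
        cap = cm.geodesic_cap(mesh642, 0, 20.0)
        half = cap[: len(cap) // 2]
        other = cap[len(cap) // 2:]
        p = np.ones(mesh642.n_vertices)
        t = np.zeros(mesh642.n_vertices)
        p[cap] = 1e-5
        t[half] = 4.0
        t[other] = -4.0
        res = cluster_extract(mesh642, p, t, 0.001)
        assert {c.sign for c in res} == {1, -1}


class TestMonteCarlo:
    def test_determinism(self, mesh642):
        a = monte_carlo_null(mesh642, 15.0, 0.01, 200, seed=3)
        b = monte_carlo_null(mesh642, 15.0, 0.01, 200, seed=3)
        assert np.array_equal(a, b)

    def test_tiny_alpha_no_clusters(self):
        # expected suprathreshold count << 1 at alpha=1e-6 on ~1000 vertices
        mesh = cm.icosphere(3, 50.0)
        null = monte_carlo_null(mesh, 0.0, 1e-6, 500, seed=4)
        assert np.mean(null == 0) >= 0.99

    def test_min_sims_enforced(self, mesh642):
        with pytest.raises(ValueError, match="100"):
            monte_carlo_null(mesh642, 15.0, 0.01, 50, seed=0)

    def test_fwe_add_one_rule(self, mesh642):
        res = cluster_extract(
            mesh642, np.full(mesh642.n_vertices, 1e-9), np.ones(mesh642.n_vertices), 0.05
        )
        null = np.zeros(999)
        out = cluster_fwe(res, null)
        assert out.clusters[0].p_fwe == pytest.approx(1 / 1000)

    def test_zero_area_cluster_p_one(self):
        c = cm.Cluster(np.array([0]), 0.0, 0, 1)
        res = cm.ClusterResult([c], 0.05)
        cluster_fwe(res, np.random.default_rng(0).uniform(1, 10, 99))
        assert c.p_fwe == 1.0


class TestEffectSizes:
    def test_null_small_d(self):
        rng = np.random.default_rng(30)
        Y = rng.standard_normal((400, 100))
        ga = np.zeros(400, bool)
        ga[:200] = True
        d = cohens_d(Y, ga, ~ga).d
        assert np.all(np.abs(d) < 0.1 + 3 * np.sqrt(1 / 100))

    def test_shifted_groups_d_one(self):
        rng = np.random.default_rng(31)
        n = 1000
        Y = rng.standard_normal((2 * n, 50))
        ga = np.zeros(2 * n, bool)
        ga[:n] = True
        Y[ga] += 1.0
        d = cohens_d(Y, ga, ~ga).d
        assert abs(d[0] - 1.0) < 0.1          # single-vertex estimate
        assert abs(d.mean() - 1.0) < 0.02     # average over 50 null replicates

    def test_constant_y_missing(self):
        Y = np.ones((10, 3))
        ga = np.zeros(10, bool)
        ga[:5] = True
        d = cohens_d(Y, ga, ~ga).d
        assert np.all(np.isnan(d))

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            cohens_d(np.zeros((3, 2)), np.array([1, 0, 0], bool), np.array([0, 1, 1], bool))

    def test_residualization_removes_covariate(self):
        rng = np.random.default_rng(32)
        n = 200
        age = rng.uniform(50, 80, 2 * n)
        ga = np.zeros(2 * n, bool)
        ga[:n] = True
        Y = 0.05 * age[:, None] + rng.standard_normal((2 * n, 30))
        d_raw = cohens_d(Y, ga, ~ga).d
        d_adj = cohens_d(Y, ga, ~ga, nuisance=age).d
        # ages are randomized so both are near 0, but adjusted has less spread
        assert np.abs(d_adj).mean() <= np.abs(d_raw).mean() + 0.05

    def test_net_effect_sign_and_mask(self):
        d_md = cm.EffectSizeMap(np.array([1.0, 0.5, 0.2, -0.4]))
        d_ct = cm.EffectSizeMap(np.array([1.0, -1.0, 0.1, -0.1]))
        mask = np.array([0, 1, 2])
        net = net_effect_size(d_md, d_ct, mask)
        assert net.d[0] == 0.0
        assert net.d[1] == pytest.approx(-0.5)
        assert net.d[2] == pytest.approx(0.1)
        assert np.isnan(net.d[3])

    def test_net_effect_bad_mask_rejected(self):
        d = cm.EffectSizeMap(np.zeros(4))
        with pytest.raises(ValueError, match="out of range"):
            net_effect_size(d, d, np.array([7]))
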