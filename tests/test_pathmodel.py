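"""Path model: spec expansion, estimation, effect decomposition, SRMR, CIs."""

import numpy as np
import pandas as pd
import pytest

from claimspath import PathModel, PathSpec, build_spec
from claimspath.pathmodel import (
    PathSpecError,
    indirect_from_standardized,
    srmr_from_matrices,
)

# ---------------------------------------------------------------------------
# spec construction


def test_block_expansion_edge_count():
    # 2 PC, 1 CM, 1 ITR, 1 CP, 1 HCRU -> 6 edges into cost + 3 into ITR
    # + 2 into HCRU + 2 into complications = 13
    spec = PathSpec.from_blocks(
        {
            "patient_characteristics": ["x1", "x2"],
            "comorbidities": ["c1"],
            "itr": ["t1"],
            "complications": ["p1"],
            "hcru": ["h1"],
            "thcc": ["y"],
        }
    )
    assert len(spec.edges) == 13


def test_single_node_per_block_gives_eleven_lettered_edges():
    spec = _single_node_spec()
    assert len(spec.edges) == 11
    assert set(spec.parents("y")) == {"pc", "cm", "t", "cp", "h"}
    assert set(spec.parents("t")) == {"pc", "cm"}
    assert set(spec.parents("h")) == {"t", "cp"}
    assert set(spec.parents("cp")) == {"cm", "t"}


def test_disallowed_edge_rejected():
    blocks = {
        "patient_characteristics": ["pc"], "comorbidities": ["cm"],
        "itr": ["t"], "complications": ["cp"], "hcru": ["h"], "thcc": ["y"],
    }
    with pytest.raises(PathSpecError, match="not permitted"):
        PathSpec.from_blocks(blocks, extra_edges=[("h", "t")])
    with pytest.raises(PathSpecError):
        PathSpec.from_blocks({**blocks, "thcc": ["y", "y2"]})
    with pytest.raises(PathSpecError, match="not assigned"):
        build_spec(["a", "b"], {"a": "thcc"})


def _single_node_spec():
    return PathSpec.from_blocks(
        {
            "patient_characteristics": ["pc"], "comorbidities": ["cm"],
            "itr": ["t"], "complications": ["cp"], "hcru": ["h"], "thcc": ["y"],
        }
    )


# ---------------------------------------------------------------------------
# estimation


def _noiseless_data(n=400, seed=0, mediator_noise=0.0):
    """Structural data; mediators need a little noise to stay full rank."""
    rng = np.random.default_rng(seed)
    pc = rng.normal(size=n)
    cm = rng.normal(size=n)
    e = lambda: rng.normal(scale=mediator_noise, size=n) if mediator_noise else 0.0
    t = 0.5 * pc + 0.3 * cm + e()
    cp = 0.2 * cm + 0.1 * t + e()
    h = 0.4 * t + 0.2 * cp + e()
    y = 1.0 * pc + 0.8 * cm + 0.6 * t + 0.5 * cp + 0.4 * h
    return pd.DataFrame({"pc": pc, "cm": cm, "t": t, "cp": cp, "h": h, "y": y})


def test_zero_noise_outcome_equation_recovers_coefficients_exactly():
    # noise-free outcome: its equation is recovered to numerical precision
    data = _noiseless_data(mediator_noise=0.4)
    res = PathModel(data, _single_node_spec()).fit()
    idx = {c: i for i, c in enumerate(res.nodes)}
    expected = {
        ("y", "pc"): 1.0, ("y", "cm"): 0.8, ("y", "t"): 0.6,
        ("y", "cp"): 0.5, ("y", "h"): 0.4,
    }
    for (c, p), v in expected.items():
        assert res.B[idx[c], idx[p]] == pytest.approx(v, abs=1e-8)
    assert res.resid_var[idx["y"]] == pytest.approx(0.0, abs=1e-12)


def test_row_permutation_leaves_fit_invariant(table4k, default_spec):
    res1 = PathModel(table4k, default_spec).fit()
    perm = table4k.sample(frac=1.0, random_state=5)
    res2 = PathModel(perm, default_spec).fit()
    np.testing.assert_allclose(res1.B, res2.B, atol=1e-10)
    np.testing.assert_allclose(res1.beta, res2.beta, atol=1e-10)
    assert res1.srmr == pytest.approx(res2.srmr, abs=1e-12)


def test_collinear_parents_raise_naming_columns():
    data = _noiseless_data(mediator_noise=0.4)
    data["pc2"] = data["pc"] * 2.0  # exact collinearity inside the PC block
    spec = PathSpec.from_blocks(
        {
            "patient_characteristics": ["pc", "pc2"], "comorbidities": ["cm"],
            "itr": ["t"], "complications": ["cp"], "hcru": ["h"], "thcc": ["y"],
        }
    )
    with pytest.raises(np.linalg.LinAlgError, match="pc"):
        PathModel(data, spec).fit()


def test_scale_invariance_of_standardized_fit(table4k, default_spec):
    res1 = PathModel(table4k, default_spec).fit()
    scaled = table4k.copy()
    scaled["thcc_adj_usd"] = scaled["thcc_adj_usd"] * 1e-3 + 7.0
    scaled["los_days"] = scaled["los_days"] * 24.0  # days -> hours
    res2 = PathModel(scaled, default_spec).fit()
    np.testing.assert_allclose(res1.beta, res2.beta, atol=1e-8)
    assert res1.srmr == pytest.approx(res2.srmr, abs=1e-8)


# ---------------------------------------------------------------------------
# effect decomposition


def _letter_formulas(w):
    """Published closed-form indirect effects for the single-node DAG.

    The comorbidity formula includes the CM->ITR->CP->cost path (b*d*v),
    required by the DAG even though the source text omits that term.
    """
    a, b, c, d, k, m, v, y, z = (
        w["a"], w["b"], w["c"], w["d"], w["k"], w["m"], w["v"], w["y"], w["z"]
    )
    return {
        "pc": a * y + a * k * z + a * d * v + a * d * m * z,
        "cm": b * y + b * k * z + b * d * v + b * d * m * z + c * v + c * m * z,
        "t": k * z + d * m * z + d * v,
        "cp": m * z,
    }


def _dfs_paths(adj, src, dst):
    """Exhaustive DFS enumeration of all simple directed paths."""
    out = []

    def walk(node, path):
        if node == dst:
            out.append(list(path))
            return
        for nxt in adj.get(node, ()):
            walk(nxt, path + [nxt])

    walk(src, [src])
    return out


def test_indirect_effects_match_letter_formulas_and_dfs():
    rng = np.random.default_rng(2024)
    nodes = ["pc", "cm", "t", "cp", "h", "y"]
    idx = {n: i for i, n in enumerate(nodes)}
    edges = {
        "a": ("t", "pc"), "b": ("t", "cm"), "c": ("cp", "cm"), "d": ("cp", "t"),
        "k": ("h", "t"), "m": ("h", "cp"), "v": ("y", "cp"), "w": ("y", "pc"),
        "x": ("y", "cm"), "yy": ("y", "t"), "z": ("y", "h"),
    }
    adj = {}
    wts = {}
    for letter, (to, frm) in edges.items():
        adj.setdefault(frm, []).append(to)
    for _ in range(1000):
        beta = np.zeros((6, 6))
        w = {}
        for letter, (to, frm) in edges.items():
            val = rng.uniform(-1, 1)
            beta[idx[to], idx[frm]] = val
            w[letter] = val
            wts[(frm, to)] = val
        ind = indirect_from_standardized(beta)
        formulas = _letter_formulas({**w, "y": w["yy"]})
        for pred, expected in formulas.items():
            assert ind[idx["y"], idx[pred]] == pytest.approx(expected, abs=1e-10)
        # independent oracle: exhaustive DFS path products
        for pred in ("pc", "cm", "t", "cp"):
            dfs = sum(
                np.prod([wts[(p[i], p[i + 1])] for i in range(len(p) - 1)])
                for p in _dfs_paths(adj, pred, "y")
                if len(p) >= 3
            )
            assert ind[idx["y"], idx[pred]] == pytest.approx(dfs, abs=1e-10)


def test_total_equals_direct_plus_indirect(fitted4k):
    d = fitted4k.direct_effects()
    i = fitted4k.indirect_effects().fillna(0.0)
    t = fitted4k.total_effects()
    assert (t - d - i).abs().max() < 1e-12


def test_hcru_predictors_carry_no_indirect_effect(fitted4k):
    ind = fitted4k.indirect_effects()
    for col in ("los_days", "n_hospitalizations", "any_icu", "any_sct"):
        assert np.isnan(ind[col])
    eff = fitted4k.effects(ci="delta")
    assert eff.loc["los_days", "total"] == eff.loc["los_days", "direct"]


# ---------------------------------------------------------------------------
# SRMR


def test_srmr_zero_when_model_reproduces_covariance():
    rng = np.random.default_rng(0)
    A = rng.normal(size=(8, 8))
    S = A @ A.T + 8 * np.eye(8)
    assert srmr_from_matrices(S, S) == 0.0
    with pytest.raises(ValueError, match="variance"):
        srmr_from_matrices(np.diag([1.0, -1.0]), np.eye(2))


def test_implied_covariance_reproduces_fitted_moments_exactly():
    """Variances, exogenous covariances and the mediator equations'
    child-parent covariances of the implied matrix equal their sample
    counterparts exactly (OLS normal equations propagated recursively)."""
    rng = np.random.default_rng(3)
    n = 200
    data = _noiseless_data(n=n, seed=3, mediator_noise=0.3)
    data["y"] = data["y"] + rng.normal(scale=0.3, size=n)
    spec = _single_node_spec()
    res = PathModel(data, spec).fit()
    idx = {c: i for i, c in enumerate(res.nodes)}
    # exact for nodes whose parent sets are upstream-closed (not the outcome,
    # whose parents include pairs the sparse DAG leaves unmodelled)
    for node in ("pc", "cm", "t", "cp", "h"):
        assert res.sigma_hat[idx[node], idx[node]] == pytest.approx(
            res.S[idx[node], idx[node]], rel=1e-10
        )
    for a in spec.exogenous:
        for b in spec.exogenous:
            assert res.sigma_hat[idx[a], idx[b]] == pytest.approx(
                res.S[idx[a], idx[b]], abs=1e-10
            )
    # mediator parent sets are upstream-closed, so these entries are exact
    for child in ("t", "cp", "h"):
        for par in spec.parents(child):
            assert res.sigma_hat[idx[child], idx[par]] == pytest.approx(
                res.S[idx[child], idx[par]], abs=1e-9
            )
    assert res.srmr < 0.05  # remaining entries deviate only by sampling noise


# ---------------------------------------------------------------------------
# confidence intervals


def test_bootstrap_is_seed_deterministic(fitted4k):
    e1 = fitted4k.effects(ci="bootstrap", reps=120, seed=9)
    e2 = fitted4k.effects(ci="bootstrap", reps=120, seed=9)
    pd.testing.assert_frame_equal(e1, e2)
    with pytest.raises(ValueError):
        fitted4k.effects(ci="bootstrap", reps=1)
    with pytest.raises(ValueError):
        fitted4k.effects(ci="nope")


def test_delta_ci_of_single_direct_effect_matches_sandwich(fitted4k):
    # a pure direct effect's delta variance is the equation-level sandwich
    eff = fitted4k.effects(ci="delta")
    idx = {c: i for i, c in enumerate(fitted4k.nodes)}
    t = idx["thcc_adj_usd"]
    j = idx["los_days"]
    se = fitted4k.beta_se[t, j]
    beta = fitted4k.beta[t, j]
    assert eff.loc["los_days", "direct_lo"] == pytest.approx(beta - 1.96 * se, abs=2e-4)
    assert eff.loc["los_days", "direct_hi"] == pytest.approx(beta + 1.96 * se, abs=2e-4)


def test_summary_renders(fitted4k):
    text = fitted4k.summary()
    assert "SRMR" in text and "los_days" in text
    j = fitted4k.to_fit_json()
    assert j["n"] == 4000 and len(j["nodes"]) == len(j["B"])
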