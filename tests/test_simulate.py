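"""Synthetic generator: config validation, determinism, planted ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import claimspath as cp
from claimspath.simulate import (
    EndogBinary,
    EndogCost,
    ExogBinary,
    SimConfigError,
    StructuralModel,
)


def test_degenerate_configs_rejected():
    with pytest.raises(SimConfigError):
        cp.SimConfig(n_patients=0)
    with pytest.raises(SimConfigError):
        cp.SimConfig(cost_split={"inpatient": 0.5, "outpatient": 0.4})
    with pytest.raises(SimConfigError, match="id_window"):
        import datetime as dt

        cp.SimConfig(id_window=(dt.date(2019, 1, 1), dt.date(2010, 1, 1)))


def test_planted_edge_outside_dag_rejected():
    # HCRU -> ITR is not a permitted arrow
    bad = StructuralModel([
        ExogBinary("x", "patient_characteristics", 0.5),
        EndogBinary("h1", "hcru", 0.2, {"x": 0.0}),
        EndogBinary("t1", "itr", 0.3, {"h1": 0.1}),
        EndogCost("y", "thcc", 100.0, 10.0, {"h1": 0.2}),
    ])
    with pytest.raises(SimConfigError, match="not allowed"):
        bad.validate_edges()


def test_zero_coefficients_zero_noise_cost_equals_intercept():
    m = StructuralModel([
        ExogBinary("x", "patient_characteristics", 0.5),
        EndogCost("y", "thcc", mean=1234.5, sd=0.0, edges={"x": 0.0}),
    ])
    t = m.sample(50, np.random.default_rng(0))
    assert np.allclose(t["y"], 1234.5)


def test_infeasible_planting_rejected():
    # base rate near the boundary with a large planted effect cannot stay a
    # probability on the support hull
    m = StructuralModel([
        ExogBinary("x", "comorbidities", 0.5),
        EndogBinary("b", "complications", 0.02, {"x": 0.5}),
    ])
    with pytest.raises(SimConfigError, match="probability"):
        m.resolve()


def test_generation_is_seed_deterministic():
    b1 = cp.generate_bundle(cp.SimConfig(n_patients=40, seed=3))
    b2 = cp.generate_bundle(cp.SimConfig(n_patients=40, seed=3))
    for t in ("patients", "drug_claims", "dx_claims", "encounters", "truth", "truth_lines"):
        pd.testing.assert_frame_equal(getattr(b1, t), getattr(b2, t))
    b3 = cp.generate_bundle(cp.SimConfig(n_patients=40, seed=4))
    assert not b3.truth["thcc_adj_usd"].equals(b1.truth["thcc_adj_usd"])


def test_claim_costs_sum_to_planted_total(small_bundle):
    jpy = (
        small_bundle.drug_claims.groupby("patient_id")["cost_jpy"].sum()
        .add(small_bundle.encounters.groupby("patient_id")["cost_jpy"].sum(), fill_value=0.0)
    )
    truth = small_bundle.truth.set_index("patient_id")
    assert (jpy - truth["total_cost_jpy"]).abs().max() < 1e-6


def test_generated_cost_is_right_skewed(structure):
    t = cp.simulate_analysis_table(structure, 2000, 99)
    assert stats.skew(t["thcc_adj_usd"]) > 0
    assert t["thcc_adj_usd"].min() > 0


def test_population_moments_match_analytic_resolution(structure):
    res = structure.resolve()
    t = cp.simulate_analysis_table(structure, 60000, 5)
    mu_hat = t[res["names"]].mean().to_numpy()
    np.testing.assert_allclose(mu_hat, res["mu"], atol=4 * 1.0 / np.sqrt(60000) * 70000)
    # spot-check key variances/covariances on comparable scales
    i = {c: k for k, c in enumerate(res["names"])}
    for a, b in [("thcc_adj_usd", "los_days"), ("los_days", "comp_heart"),
                 ("itr_other_r", "itr_r_chase"), ("thcc_adj_usd", "thcc_adj_usd")]:
        pop = res["cov"][i[a], i[b]]
        emp = np.cov(t[a], t[b], ddof=1)[0, 1]
        scale = np.sqrt(res["cov"][i[a], i[a]] * res["cov"][i[b], i[b]])
        assert abs(emp - pop) / scale < 0.04


def test_planted_los_effect_recovered_from_truth_table(structure):
    """Direct regression on the truth table recovers the planted standardized
    LOS effect (0.75) within three robust standard errors."""
    t = cp.simulate_analysis_table(structure, 5000, 17)
    res = cp.PathModel(t, cp.PathSpec.from_blocks(cp.default_blocks())).fit()
    i = {c: k for k, c in enumerate(res.nodes)}
    est = res.beta[i["thcc_adj_usd"], i["los_days"]]
    se = res.beta_se[i["thcc_adj_usd"], i["los_days"]]
    assert abs(est - 0.75) < 3 * se


def test_unknown_corruption_scenario_rejected(small_bundle):
    with pytest.raises(ValueError, match="unknown scenario"):
        cp.corrupt_bundle(small_bundle, "meteor_strike")


def test_corruption_flags_exact_count_and_construction(small_bundle):
    n = len(small_bundle.truth)
    cb = cp.corrupt_bundle(small_bundle, "missing_lookback", fraction=0.25, seed=1)
    flagged = cb.truth[cb.truth["corrupt_scenario"] == "missing_lookback"]
    assert len(flagged) == round(0.25 * n)
    # flagged patients have no claim of any kind in the 6 months before 1L
    import datetime as dt

    for rec in flagged.itertuples(index=False):
        t1 = rec.first_treatment_date
        lo = t1 - dt.timedelta(days=183)
        for tbl, col in (("drug_claims", "service_date"), ("dx_claims", "service_date"),
                         ("encounters", "admit_date")):
            d = getattr(cb, tbl)
            d = d[d["patient_id"] == rec.patient_id][col]
            assert not ((d >= lo) & (d < t1)).any()
    # untouched patients keep their lookback claims
    ok = cb.truth[cb.truth["corrupt_scenario"] == ""].iloc[0]
    d = cb.dx_claims[cb.dx_claims["patient_id"] == ok.patient_id]["service_date"]
    t1 = ok.first_treatment_date
    assert ((d >= t1 - dt.timedelta(days=183)) & (d < t1)).any()


def test_immunotherapy_combo_adds_rituximab_plus_other_immunotherapy(small_bundle):
    cb = cp.corrupt_bundle(small_bundle, "immunotherapy_combo", fraction=0.2, seed=2)
    flagged = cb.truth[cb.truth["corrupt_scenario"] == "immunotherapy_combo"]
    for rec in flagged.itertuples(index=False):
        day = cb.drug_claims[
            (cb.drug_claims["patient_id"] == rec.patient_id)
            & (cb.drug_claims["service_date"] == rec.index_date)
        ]["drug_code"]
        assert "OBZ-1" in set(day)
        assert any(c.startswith("RTX") for c in day)


def test_bundle_round_trips_through_csv(tmp_path, small_bundle):
    small_bundle.write(tmp_path / "b")
    back = cp.ClaimsBundle.read(tmp_path / "b")
    assert len(back.patients) == len(small_bundle.patients)
    assert back.meta["seed"] == small_bundle.meta["seed"]
    assert back.drug_claims["service_date"].iloc[0] == \
        small_bundle.drug_claims["service_date"].iloc[0]
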