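"""Single-iteration engine: expansion, adjustment, eligibility, adoption,
treatment, reclassification, costing."""

import numpy as np
import pandas as pd
import pytest

from flaxcoi import IndividualRecord, Thresholds, UniformEffect, default_cost_table
from flaxcoi.coi_engine import (
    CostTable,
    adjust_medication,
    apply_flax,
    attach_costs,
    eligible_set,
    expand_by_weights,
    iterate_expanded,
    reclassify,
    round_half_away,
    run_iteration,
    sample_adopters,
)


def _rec(pid, sbp, dbp, med=False, w=1.0, age=40):
    return IndividualRecord(pid, age, "M", sbp, dbp, med, w)


def _h(*specs):
    return [_rec(*s) for s in specs]


# --- effect distributions ---------------------------------------------------


def test_uniform_effect_validation_and_stats():
    with pytest.raises(ValueError):
        UniformEffect(3.0, 2.0)
    with pytest.raises(ValueError):
        UniformEffect(-1.0, 2.0)
    e = UniformEffect(2.24, 4.15)
    assert e.mean == pytest.approx(3.195)
    assert not e.is_degenerate
    assert UniformEffect(9.0, 9.0).is_degenerate


def test_uniform_effect_exceedance_closed_form():
    e = UniformEffect(2.24, 4.15)
    assert e.exceedance(np.array([3.0]))[0] == pytest.approx((4.15 - 3.0) / 1.91)
    assert e.exceedance(np.array([-5.0]))[0] == 1.0  # clamp above
    assert e.exceedance(np.array([10.0]))[0] == 0.0  # clamp below
    point = UniformEffect(2.0, 2.0)
    assert point.exceedance(np.array([1.9]))[0] == 1.0
    assert point.exceedance(np.array([2.0]))[0] == 0.0


# --- cost table -------------------------------------------------------------


def test_cost_table_published_rows():
    table = default_cost_table()
    assert table.cost_for_age(30) == pytest.approx(2095.73)
    assert table.cost_for_age(50) == pytest.approx(2305.30)
    assert table.cost_for_age(60) == pytest.approx(2514.87)
    assert table.cost_for_age(70) == pytest.approx(2934.02)
    # no published 75+ row: default imputes the 65-74 value
    assert table.cost_for_age(80) == pytest.approx(2934.02)


def test_cost_table_validation():
    with pytest.raises(ValueError, match="start at age 18"):
        CostTable(bands=((20, None, 100.0),))
    with pytest.raises(ValueError, match="gaps"):
        CostTable(bands=((18, 44, 100.0), (46, None, 200.0)))
    with pytest.raises(ValueError, match="open-ended"):
        CostTable(bands=((18, 64, 100.0),))
    table = CostTable(bands=((18, None, 100.0),))
    with pytest.raises(ValueError, match="outside"):
        table.costs_for_ages(np.array([17]))


# --- expansion --------------------------------------------------------------


def test_expand_replicate_integer_weights():
    h = _h(("a", 150.0, 80.0, False, 3.0))
    out = expand_by_weights(h, mode="replicate")
    assert len(out) == 3
    assert (out["multiplicity"] == 1.0).all()

    h2 = _h(("a", 150.0, 80.0, False, 2.0), ("b", 145.0, 95.0, False, 5.0))
    assert len(expand_by_weights(h2, mode="replicate")) == 7


def test_expand_replicate_rounds_half_away_from_zero():
    h = _h(("a", 150.0, 80.0, False, 2.4), ("b", 145.0, 95.0, False, 2.6))
    out = expand_by_weights(h, mode="replicate")
    # independent check: sum of individually rounded weights
    expected = int(sum(round_half_away(np.array([2.4, 2.6]))))
    assert len(out) == expected == 5
    assert int(round_half_away(np.array([2.5]))[0]) == 3


def test_expand_weighted_keeps_rows_with_multiplicity():
    h = _h(("a", 150.0, 80.0, False, 2.4), ("b", 145.0, 95.0, False, 0.3))
    out = expand_by_weights(h, mode="weighted")
    assert len(out) == 2
    assert out["multiplicity"].tolist() == [2.4, 0.3]
    assert out["units"].tolist() == [2, 1]  # units floor at 1


def test_expand_rejects_non_hypertensive():
    with pytest.raises(ValueError, match="non-hypertensive"):
        expand_by_weights(_h(("ok", 150.0, 80.0, False, 1.0),
                             ("no", 120.0, 70.0, False, 1.0)))
    with pytest.raises(ValueError, match="mode"):
        expand_by_weights(_h(("ok", 150.0, 80.0, False, 1.0)), mode="bogus")


# --- medication adjustment --------------------------------------------------


def test_adjust_medication_bounds_and_exactness():
    h = expand_by_weights(
        _h(("unmed", 150.0, 95.0, False, 1.0), ("med", 135.0, 85.0, True, 1.0))
    )
    rng = np.random.default_rng(0)
    out = adjust_medication(h, rng=rng)
    unmed = out[out["person_id"] == "unmed"].iloc[0]
    assert unmed["sbp_adj"] == 150.0 and unmed["dbp_adj"] == 95.0  # exact
    med = out[out["person_id"] == "med"].iloc[0]
    assert 135.0 + 8.8 <= med["sbp_adj"] <= 135.0 + 9.3
    assert 85.0 + 5.4 <= med["dbp_adj"] <= 85.0 + 5.7


def test_adjust_medication_degenerate_point_mass():
    h = expand_by_weights(_h(("med", 135.0, 85.0, True, 1.0)))
    out = adjust_medication(
        h, UniformEffect(9.0, 9.0), UniformEffect(5.5, 5.5),
        np.random.default_rng(1),
    )
    assert out.loc[0, "sbp_adj"] == pytest.approx(144.0, abs=1e-12)
    assert out.loc[0, "dbp_adj"] == pytest.approx(90.5, abs=1e-12)


# --- eligibility ------------------------------------------------------------


def test_eligible_set_boundaries():
    h = expand_by_weights(
        _h(("sbp_high", 141.0, 70.0, False, 1.0),
           ("controlled", 128.0, 82.0, True, 1.0),
           ("dbp_edge", 139.99, 90.0, False, 1.0))
    )
    out = h.copy()
    out["sbp_adj"] = [141.0, 128.0, 139.99]
    out["dbp_adj"] = [70.0, 82.0, 90.0]
    out = eligible_set(out)
    flags = dict(zip(out["person_id"], out["is_eligible"]))
    assert bool(flags["sbp_high"])
    # medicated but controlled after adjustment: hypertensive yet not in K
    assert not bool(flags["controlled"])
    assert bool(flags["dbp_edge"])  # DBP boundary inclusive


# --- adoption ---------------------------------------------------------------


def _eligible_frame(n, w=1.0, mode="weighted"):
    h = expand_by_weights(
        _h(*[(f"p{i}", 150.0, 80.0, False, w) for i in range(n)]), mode=mode
    )
    h["sbp_adj"] = h["sbp"]
    h["dbp_adj"] = h["dbp"]
    return eligible_set(h)


def test_sample_adopters_extremes():
    k = _eligible_frame(10, mode="replicate")
    rng = np.random.default_rng(0)
    assert sample_adopters(k, 0.0, rng, mode="replicate")["adopt_mult"].sum() == 0
    out = sample_adopters(k, 1.0, rng, mode="replicate")
    assert (out["adopt_mult"] == out["multiplicity"]).all()
    with pytest.raises(ValueError, match="rate"):
        sample_adopters(k, 1.5, rng)


def test_sample_adopters_srs_size_and_marginal_rate():
    """|F| = round(r * n_K) exactly; each member's inclusion frequency
    over 500 seeds is r within 3 binomial SEs."""
    k = _eligible_frame(1000, mode="replicate")
    rng = np.random.default_rng(3)
    out = sample_adopters(k, 0.25, rng, mode="replicate")
    assert int((out["adopt_mult"] > 0).sum()) == 250

    n_seeds = 500
    k_small = _eligible_frame(8, mode="replicate")
    counts = np.zeros(8)
    for s in range(n_seeds):
        out = sample_adopters(k_small, 0.25, np.random.default_rng(s), mode="replicate")
        counts += (out["adopt_mult"].to_numpy() > 0)
    se = np.sqrt(0.25 * 0.75 / n_seeds)
    assert np.all(np.abs(counts / n_seeds - 0.25) <= 3 * se)


def test_sample_adopters_binomial_thinning_expectation():
    k = _eligible_frame(200, w=7.3, mode="weighted")
    total = np.mean([
        sample_adopters(k, 0.4, np.random.default_rng(s))["adopt_mult"].sum()
        for s in range(200)
    ])
    assert total == pytest.approx(0.4 * 7.3 * 200, rel=0.02)


# --- flax application -------------------------------------------------------


def test_apply_flax_null_treatment_is_identity():
    k = _eligible_frame(5)
    k = sample_adopters(k, 1.0, np.random.default_rng(0), mode="weighted")
    out = apply_flax(k, UniformEffect(0, 0), UniformEffect(0, 0),
                     np.random.default_rng(1))
    assert (out["sbp_flax"] == out["sbp_adj"]).all()


def test_apply_flax_draws_within_support():
    k = _eligible_frame(200)
    k = sample_adopters(k, 1.0, np.random.default_rng(0))
    out = apply_flax(k, rng=np.random.default_rng(2))
    red_s = out["sbp_adj"] - out["sbp_flax"]
    red_d = out["dbp_adj"] - out["dbp_flax"]
    assert ((red_s >= 2.24) & (red_s <= 4.15)).all()
    assert ((red_d >= 1.94) & (red_d <= 3.27)).all()


def test_apply_flax_conversion_frequency_matches_uniform_tail():
    """P(SBP drops below cut) for adjusted SBP 143 under U(2.24, 4.15)
    equals (4.15 - 3) / (4.15 - 2.24) ~ 0.6021, checked by simulated
    frequency over 1e5 draws."""
    n = 100_000
    h = expand_by_weights(
        _h(*[(f"p{i}", 143.0, 80.0, False, 1.0) for i in range(n)]),
        mode="weighted",
    )
    h["sbp_adj"] = h["sbp"]
    h["dbp_adj"] = h["dbp"]
    h = eligible_set(h)
    h = sample_adopters(h, 1.0, np.random.default_rng(0))
    out = apply_flax(h, rng=np.random.default_rng(5))
    freq = float((out["sbp_flax"] < 140.0).mean())
    expected = (4.15 - 3.0) / (4.15 - 2.24)
    assert freq == pytest.approx(expected, abs=3 * np.sqrt(expected * (1 - expected) / n))


def test_apply_flax_common_draw_couples_effects():
    k = _eligible_frame(100)
    k = sample_adopters(k, 1.0, np.random.default_rng(0))
    out = apply_flax(k, rng=np.random.default_rng(3), common_draw=True)
    u_s = (out["sbp_adj"] - out["sbp_flax"] - 2.24) / (4.15 - 2.24)
    u_d = (out["dbp_adj"] - out["dbp_flax"] - 1.94) / (3.27 - 1.94)
    assert np.allclose(u_s, u_d)


# --- reclassification -------------------------------------------------------


def test_reclassify_rules():
    h = expand_by_weights(
        _h(("non_adopter", 150.0, 80.0, False, 1.0),
           ("converted", 150.0, 80.0, False, 1.0),
           ("dbp_still_high", 150.0, 95.0, False, 1.0))
    )
    h["sbp_adj"] = h["sbp"]
    h["dbp_adj"] = h["dbp"]
    h["adopt_mult"] = [0.0, 1.0, 1.0]
    h["sbp_flax"] = [np.nan, 138.0, 138.0]
    h["dbp_flax"] = [np.nan, 85.0, 91.0]
    out = reclassify(h)
    new = dict(zip(out["person_id"], out["hypertension_new"]))
    assert new["non_adopter"] == 1
    assert new["converted"] == 0
    assert new["dbp_still_high"] == 1
    conv = dict(zip(out["person_id"], out["converted_mult"]))
    assert conv["converted"] == 1.0 and conv["dbp_still_high"] == 0.0


# --- costing ----------------------------------------------------------------


def test_attach_costs_by_age_band():
    h = expand_by_weights(
        _h(("a", 150.0, 80.0, False, 1.0, 30), ("b", 150.0, 80.0, False, 1.0, 60),
           ("c", 150.0, 80.0, False, 1.0, 80))
    )
    out = attach_costs(h, default_cost_table())
    assert out["cost"].tolist() == pytest.approx([2095.73, 2514.87, 2934.02])


# --- full iteration ---------------------------------------------------------


def test_run_iteration_zero_rate_zero_savings(toy_h_records):
    res = run_iteration(toy_h_records, 0.0, np.random.default_rng(0))
    assert res.savings == 0.0
    assert res.adjusted_cost == res.total_cost
    assert res.n_adopters == 0


def test_run_iteration_null_treatment_zero_savings(toy_h_records):
    for seed in range(5):
        res = run_iteration(
            toy_h_records, 0.5, np.random.default_rng(seed),
            flax_sbp=UniformEffect(0, 0), flax_dbp=UniformEffect(0, 0),
        )
        assert res.savings == 0.0


@pytest.mark.parametrize("mode", ["weighted", "replicate"])
def test_run_iteration_saturation_equals_cost_of_k(toy_h_records, mode):
    """r=1 with an overwhelming effect converts all of K: savings equal
    the independently-summed cost of K exactly, and cost conservation
    holds."""
    med = UniformEffect(9.1, 9.1)
    res = run_iteration(
        toy_h_records, 1.0, np.random.default_rng(1),
        flax_sbp=UniformEffect(200, 200), flax_dbp=UniformEffect(200, 200),
        med_sbp=med, med_dbp=UniformEffect(5.5, 5.5), mode=mode,
    )
    # independent oracle: K under degenerate medication effects
    table = default_cost_table()
    expected = sum(
        table.cost_for_age(r.age_years)
        for r in toy_h_records
        if (r.sbp + 9.1 * r.on_medication >= 140) or (r.dbp + 5.5 * r.on_medication >= 90)
    )
    assert res.savings == pytest.approx(expected, rel=1e-12)
    assert res.adjusted_cost + res.savings == pytest.approx(res.total_cost, rel=1e-6)


def test_iteration_count_ordering(mixed_records):
    h = [r for r in mixed_records
         if r.sbp >= 140 or r.dbp >= 90 or r.on_medication]
    res = run_iteration(h, 0.5, np.random.default_rng(7))
    assert res.n_converted <= res.n_adopters <= res.n_eligible <= res.n_expanded


def test_staged_pipeline_matches_fast_iteration(toy_h_records):
    """Composing the exported stage functions reproduces run_iteration
    bit for bit under an identically seeded generator."""
    costs = default_cost_table()
    for mode in ("weighted", "replicate"):
        h = expand_by_weights(toy_h_records, mode=mode)
        fast = iterate_expanded(h, 0.5, np.random.default_rng(42), costs, mode=mode)
        rng = np.random.default_rng(42)
        df = adjust_medication(h, rng=rng)
        df = eligible_set(df)
        df = sample_adopters(df, 0.5, rng, mode=mode)
        df = apply_flax(df, rng=rng)
        df = reclassify(df)
        df = attach_costs(df, costs)
        total = float((df["multiplicity"] * df["cost"]).sum())
        savings = float((df["converted_mult"] * df["cost"]).sum())
        assert total == fast.total_cost
        assert savings == fast.savings


def test_mode_equivalence_in_expectation():
    """Replicate and weighted expansion agree on expected savings within
    3 Monte Carlo standard errors (50 records, 2000 iterations).  Integer
    weights isolate the sampling schemes from weight rounding."""
    rng = np.random.default_rng(12)
    recs = []
    for i in range(50):
        sbp = float(rng.uniform(138, 152))
        dbp = float(rng.uniform(80, 94))
        med = bool(rng.random() < 0.3)
        if sbp < 140 and dbp < 90 and not med:
            med = True
        recs.append(IndividualRecord(f"r{i}", int(rng.integers(18, 90)), "F",
                                     sbp, dbp, med, float(rng.integers(1, 5))))
    n_iter = 2000
    means, ses = [], []
    for mode in ("replicate", "weighted"):
        sav = np.array([
            run_iteration(recs, 0.3, np.random.default_rng([mode == "weighted", i]),
                          mode=mode).savings
            for i in range(n_iter)
        ])
        means.append(sav.mean())
        ses.append(sav.std(ddof=1) / np.sqrt(n_iter))
    se = np.hypot(*ses)
    assert abs(means[0] - means[1]) <= 3 * se


def test_expected_savings_monotone_in_effect_size(toy_h_records):
    """Stochastically larger dietary effects never reduce mean savings."""
    small = (UniformEffect(1.0, 2.0), UniformEffect(0.5, 1.5))
    large = (UniformEffect(3.0, 6.0), UniformEffect(2.0, 4.0))
    means = []
    for flax_s, flax_d in (small, large):
        sav = [
            run_iteration(toy_h_records, 0.5, np.random.default_rng(i),
                          flax_sbp=flax_s, flax_dbp=flax_d).savings
            for i in range(200)
        ]
        means.append(np.mean(sav))
    assert means[1] >= means[0]
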