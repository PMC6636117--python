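"""Propensity fit and greedy caliper matching, incl. brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from adaptmatch.cohort import OutcomeModel, recruit_cohort
from adaptmatch.matching import (
    MatchPair,
    MatchResult,
    PropensityFitError,
    caliper_match,
    compute_caliper,
    fit_propensity,
    matching_rate,
)

# ---------------------------------------------------------------------------
# propensity fit


def test_fit_matches_statsmodels_on_shared_data(medium_cohort):
    """Dual-route check: in-package IRLS vs statsmodels ML logistic fit."""
    sm = pytest.importorskip("statsmodels.api")
    df = medium_cohort.all_subjects()
    names = ["x2", "x3", "x5"]
    model = fit_propensity(df, names)
    X = np.column_stack([np.ones(len(df))] + [df[c] for c in names])
    ref = sm.Logit(df["z"].to_numpy(), X).fit(disp=0)
    np.testing.assert_allclose(model.coefficients, ref.params, atol=1e-6)
    np.testing.assert_allclose(model.bse, ref.bse, rtol=1e-4)
    # propensity scores strictly inside (0, 1)
    ps = model.predict_proba(df)
    assert ((ps > 0) & (ps < 1)).all()


def test_null_assignment_gives_flat_propensity(rng):
    """Covariates independent of the arm: slopes ~0, e(X) ~ arm fraction."""
    cohort = recruit_cohort(12_000, 8_000, OutcomeModel(), rng,
                            assignment_prob=0.5)
    df = cohort.all_subjects()
    model = fit_propensity(df, ["x2", "x3"])  # x2/x3 are arm-independent
    for slope, se in zip(model.coefficients[1:], model.bse[1:]):
        assert abs(slope) < 4 * se
    ps = model.predict_proba(df)
    frac = 8_000 / 20_000
    assert ps.mean() == pytest.approx(frac, abs=0.01)
    assert np.abs(ps - frac).max() < 0.1


def test_perfect_separation_is_signalled(rng):
    df = pd.DataFrame({"z": [0] * 20 + [1] * 20,
                       "sep": [0.0] * 20 + [1.0] * 20,
                       "noise": rng.normal(size=40)})
    with pytest.raises(PropensityFitError):
        fit_propensity(df, ["sep", "noise"])


def test_constant_covariate_rejected(rng):
    df = pd.DataFrame({"z": [0, 0, 1, 1], "c": [3.0, 3.0, 3.0, 3.0],
                       "x": rng.normal(size=4)})
    with pytest.raises(ValueError, match="constant"):
        fit_propensity(df, ["c", "x"])
    with pytest.raises(ValueError):
        fit_propensity(pd.DataFrame({"z": [0, 0], "x": [1.0, 2.0]}), ["x"])


def test_wald_interval_coverage_of_known_model():
    """99% Wald CIs cover the generating coefficients at ~nominal rate."""
    beta = np.array([0.3, 0.8, -0.5])
    n, n_sims = 400, 250
    master = np.random.default_rng(314)
    covered = np.zeros(3)
    for _ in range(n_sims):
        g = np.random.default_rng(master.integers(2**31))
        X = np.column_stack([np.ones(n), g.normal(size=n), g.normal(size=n)])
        z = (g.random(n) < expit(X @ beta)).astype(int)
        df = pd.DataFrame({"z": z, "a": X[:, 1], "b": X[:, 2]})
        m = fit_propensity(df, ["a", "b"])
        half = 2.5758 * m.bse  # z_{0.995}
        covered += (np.abs(m.coefficients - beta) <= half).astype(int)
    assert (covered / n_sims >= 0.95).all()


# ---------------------------------------------------------------------------
# caliper


def test_caliper_is_fraction_of_pooled_logit_sd():
    assert compute_caliper([0.0, 2.0], 0.2) == pytest.approx(0.2 * np.sqrt(2))
    assert compute_caliper([1.3, 1.3, 1.3], 0.2) == 0.0
    assert compute_caliper([0.0, 5.0, -1.0], 0.0) == 0.0
    with pytest.raises(ValueError):
        compute_caliper([0.7], 0.2)


# ---------------------------------------------------------------------------
# greedy matching


def _oracle_greedy(treated, controls, caliper, order):
    """Independent re-implementation: nearest unmatched control within the
    caliper, ties to the lowest control id, treated visited in ``order``."""
    available = dict(sorted(controls.items()))
    pairs = {}
    for tid in order:
        best, best_d = None, None
        for cid, cval in available.items():
            d = abs(cval - treated[tid])
            if best_d is None or d < best_d:
                best, best_d = cid, d
        if best is not None and best_d <= caliper:
            pairs[tid] = best
            del available[best]
    return pairs


def test_single_candidate_within_caliper(rng):
    res = caliper_match({"t1": 0.0}, {"c1": 0.05}, 0.1, rng)
    assert [(p.treated_id, p.control_id) for p in res.pairs] == [("t1", "c1")]
    assert res.pairs[0].logit_distance == pytest.approx(0.05)


def test_far_treated_stays_unmatched_for_every_order():
    treated = {"t1": 0.00, "t2": 1.00}
    controls = {"c1": 0.04, "c2": 0.05}
    for seed in range(20):
        res = caliper_match(treated, controls, 0.1, np.random.default_rng(seed))
        assert res.n_pairs == 1
        assert all(p.treated_id == "t1" for p in res.pairs)


def test_zero_caliper_distinct_scores_gives_no_pairs(rng):
    res = caliper_match({0: 0.1, 1: 0.2}, {10: 0.15, 11: 0.3}, 0.0, rng)
    assert res.n_pairs == 0
    assert res.matching_rate == 0.0


def test_empty_arm_yields_zero_pairs(rng):
    assert caliper_match({}, {1: 0.0}, 1.0, rng).n_pairs == 0
    assert caliper_match({1: 0.0}, {}, 1.0, rng).n_pairs == 0


def test_greedy_equals_bruteforce_oracle_on_small_instances():
    """Package result == independent oracle run with the same treated order."""
    master = np.random.default_rng(99)
    for trial in range(40):
        n_t = int(master.integers(1, 7))
        n_c = int(master.integers(1, 7))
        treated = {i: float(master.normal()) for i in range(n_t)}
        controls = {100 + j: float(master.normal()) for j in range(n_c)}
        caliper = float(master.uniform(0, 2))
        seed = int(master.integers(2**31))
        res = caliper_match(treated, controls, caliper,
                            np.random.default_rng(seed))
        # reproduce the processing order the package drew
        order_idx = np.random.default_rng(seed).permutation(n_t)
        order = [list(treated.keys())[i] for i in order_idx]
        expected = _oracle_greedy(treated, controls, caliper, order)
        got = {p.treated_id: p.control_id for p in res.pairs}
        assert got == expected


def test_all_orders_agree_with_oracle_on_tie_rule():
    # two controls at exactly equal distance: the lower id must win
    treated = {"t": 0.0}
    controls = {"b": 0.1, "a": -0.1}
    for seed in range(5):
        res = caliper_match(treated, controls, 0.5, np.random.default_rng(seed))
        assert res.pairs[0].control_id == "a"


def test_expected_pair_count_monotone_in_caliper():
    master = np.random.default_rng(5)
    for _ in range(10):
        n_t, n_c = 5, 5
        treated = {i: float(master.normal()) for i in range(n_t)}
        controls = {10 + j: float(master.normal()) for j in range(n_c)}
        counts = []
        for caliper in (0.1, 0.5, 1.0, 3.0):
            total = 0
            for order in itertools.permutations(treated):
                total += len(_oracle_greedy(treated, controls, caliper, order))
            counts.append(total)
        assert counts == sorted(counts)


def test_id_permutation_preserves_pair_count(rng):
    master = np.random.default_rng(17)
    treated = {i: float(master.normal()) for i in range(6)}
    controls = {10 + j: float(master.normal()) for j in range(8)}
    res1 = caliper_match(treated, controls, 0.6, np.random.default_rng(3))
    shifted_t = {k + 1000: v for k, v in treated.items()}
    shifted_c = {k + 1000: v for k, v in controls.items()}
    res2 = caliper_match(shifted_t, shifted_c, 0.6, np.random.default_rng(3))
    assert res1.n_pairs == res2.n_pairs


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    t_vals=st.lists(st.floats(-3, 3), min_size=1, max_size=8),
    c_vals=st.lists(st.floats(-3, 3), min_size=1, max_size=8),
    caliper=st.floats(0, 2),
    seed=st.integers(0, 2**31 - 1),
)
def test_match_invariants_hold_for_random_instances(t_vals, c_vals, caliper, seed):
    """No subject reused, every distance within the caliper, |pairs| bounded."""
    treated = {i: v for i, v in enumerate(t_vals)}
    controls = {1000 + i: v for i, v in enumerate(c_vals)}
    res = caliper_match(treated, controls, caliper, np.random.default_rng(seed))
    t_ids = [p.treated_id for p in res.pairs]
    c_ids = [p.control_id for p in res.pairs]
    assert len(set(t_ids)) == len(t_ids)
    assert len(set(c_ids)) == len(c_ids)
    assert all(p.logit_distance <= caliper + 1e-12 for p in res.pairs)
    assert res.n_pairs <= min(len(t_vals), len(c_vals))


def test_equal_arms_infinite_caliper_matches_everyone(rng):
    vals = rng.normal(size=12)
    treated = {i: float(v) for i, v in enumerate(vals)}
    controls = {100 + i: float(v) for i, v in enumerate(rng.normal(size=12))}
    res = caliper_match(treated, controls, np.inf, rng)
    assert res.n_pairs == 12
    assert res.matching_rate == 1.0


def test_pairs_serialize_to_tidy_frame(rng):
    treated = {7: 0.0, 8: 1.0}
    controls = {1: 0.05, 2: 0.90}
    res = caliper_match(treated, controls, 0.2, rng)
    frame = res.to_frame(treated, controls)
    assert list(frame.columns) == [
        "treated_id", "control_id", "logit_treated", "logit_control", "distance"]
    assert len(frame) == res.n_pairs == 2
    row = frame.set_index("treated_id").loc[7]
    assert row["control_id"] == 1
    assert row["distance"] == pytest.approx(0.05)


def test_match_result_validates_its_invariants():
    with pytest.raises(ValueError):
        MatchResult(pairs=[MatchPair(1, 2, 0.5)], caliper=0.1,
                    caliper_multiplier=0.2, n_treated_in=1, n_control_in=1,
                    rate_denominator="treated")
    with pytest.raises(ValueError):
        MatchResult(pairs=[MatchPair(1, 2, 0.0), MatchPair(1, 3, 0.0)],
                    caliper=1.0, caliper_multiplier=0.2,
                    n_treated_in=2, n_control_in=2, rate_denominator="treated")


# ---------------------------------------------------------------------------
# matching rate


@pytest.mark.parametrize(
    "n_pairs, denom, expected",
    [(69, 73, 0.945), (63, 73, 0.863), (0, 17, 0.0)],
)
def test_matching_rate_values(n_pairs, denom, expected):
    assert matching_rate(n_pairs, denom) == pytest.approx(expected, abs=5e-4)


def test_matching_rate_domain():
    with pytest.raises(ValueError):
        matching_rate(1, 0)
    with pytest.raises(ValueError):
        matching_rate(5, 3)
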