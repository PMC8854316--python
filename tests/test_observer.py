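"""Synthetic-observer tests: AQ scoring, cohort statistics, decisions, RTs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dotbias.observer import (CohortSpec, ObserverModel, SessionPlan,
                              TRIAL_COLUMNS, perceived_numerosity,
                              sample_aq_scores, sample_cohort, score_aq,
                              simulate_response, simulate_session)
from dotbias.psychometrics import fit_psychometric, trim_rt


# ---------------------------------------------------------------------------
# AQ questionnaire scoring
# ---------------------------------------------------------------------------

def test_score_aq_extremes():
    key = [True] * 50
    assert score_aq(["slightly agree"] * 50, key) == 50
    assert score_aq(["strongly disagree"] * 50, key) == 0


def test_score_aq_mixed_sheet_hand_count():
    """17 keyed endorsements, mixed slight/strong, mixed key directions."""
    key = [i % 2 == 0 for i in range(50)]          # even items agree-keyed
    responses = []
    score = 0
    for i in range(50):
        endorse = score < 17                       # first 17 items endorsed
        if key[i]:
            responses.append(("slightly agree" if i % 2 == 0 else
                              "strongly agree") if endorse else "slightly disagree")
        else:
            responses.append(("slightly disagree" if i % 2 == 0 else
                              "strongly disagree") if endorse else "slightly agree")
        score += endorse
    assert score_aq(responses, key) == 17


@pytest.mark.parametrize("bad", [
    (["slightly agree"] * 49, [True] * 50),
    (["yes"] * 50, [True] * 50),
])
def test_score_aq_validation(bad):
    with pytest.raises(ValueError):
        score_aq(*bad)


@given(st.lists(st.sampled_from(["strongly agree", "slightly agree",
                                 "slightly disagree", "strongly disagree"]),
                min_size=50, max_size=50),
       st.lists(st.booleans(), min_size=50, max_size=50))
@settings(derandomize=True, max_examples=100)
def test_score_aq_complement_property(responses, key):
    """Flipping every key direction maps a score s to 50 - s."""
    s = score_aq(responses, key)
    assert 0 <= s <= 50
    assert score_aq(responses, [not k for k in key]) == 50 - s


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def test_cohort_aq_distribution_and_anchor_biases(rng):
    spec = CohortSpec(n_subjects=10_000)
    aq = sample_aq_scores(spec, rng)
    assert abs(np.median(aq) - spec.aq_centre) <= 2
    assert aq.min() >= 0 and aq.max() <= 50
    cohort = sample_cohort(CohortSpec(n_subjects=10_000), rng)
    aq = np.array([o.aq for o in cohort])
    b_low = np.array([o.bias_low for o in cohort])
    b_high = np.array([o.bias_high for o in cohort])
    # group-mean biases anchored to the 27/13% (low N) and 11/8% (N100) effects
    assert abs(b_low[aq < 15].mean() - 0.27) < 0.03
    assert abs(b_low[aq >= 15].mean() - 0.13) < 0.03
    assert abs(b_high[aq < 15].mean() - 0.11) < 0.03
    assert abs(b_high[aq >= 15].mean() - 0.08) < 0.03
    # discrimination precision does not depend on AQ
    w = np.array([o.weber for o in cohort])
    assert abs(w[aq < 15].mean() - w[aq >= 15].mean()) < 0.01


def test_null_cohort_has_aq_independent_bias(rng):
    spec = CohortSpec(n_subjects=2000, bias_slope_low=0.0, bias_slope_high=0.0)
    cohort = sample_cohort(spec, rng)
    assert len({round(o.bias_low, 12) for o in cohort}) == 1


# ---------------------------------------------------------------------------
# perception and decision
# ---------------------------------------------------------------------------

def test_perceived_numerosity_step_surface():
    obs = ObserverModel(aq=10, bias_low=0.27, bias_high=0.08)
    for n in (5, 15, 50, 100):
        assert perceived_numerosity(obs, n, "isolated") == n
    assert perceived_numerosity(obs, 15, "connected") == pytest.approx(10.95)
    assert perceived_numerosity(obs, 50, "connected") == pytest.approx(36.5)
    assert perceived_numerosity(obs, 100, "connected") == pytest.approx(92.0)
    obs2 = ObserverModel(aq=10, bias_low=0.27, bias_high=0.08,
                         bias_by_n={25: 0.2})
    assert perceived_numerosity(obs2, 25, "connected") == pytest.approx(20.0)


def test_decision_rule_hits_75_percent_at_0p6745_weber(rng):
    obs = ObserverModel(aq=10, bias_low=0.2, bias_high=0.1, weber=0.25,
                        lapse=0.0)
    ref = 20.0
    probe = ref * (1 + obs.weber * 0.6744897501960817)
    chose = [simulate_response(obs, probe, ref, rng)[0] for _ in range(100_000)]
    assert abs(np.mean(chose) - 0.75) < 0.005


def test_decision_noiseless_limit(rng):
    obs = ObserverModel(aq=10, bias_low=0.2, bias_high=0.1, weber=1e-9,
                        lapse=0.0)
    assert all(simulate_response(obs, 21, 20.0, rng)[0] for _ in range(50))
    assert not any(simulate_response(obs, 19, 20.0, rng)[0] for _ in range(50))


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

def test_session_bookkeeping_small(rng):
    plan = SessionPlan(reference_numerosities=(15,), conditions=("isolated",),
                       trials_per_cell=10)
    obs = ObserverModel(aq=15, bias_low=0.2, bias_high=0.1)
    tr = simulate_session(obs, plan, rng)
    assert len(tr) == 10
    assert list(tr.columns) == TRIAL_COLUMNS


def test_session_reference_side_balanced():
    obs = ObserverModel(aq=15, bias_low=0.2, bias_high=0.1)
    plan = SessionPlan(reference_numerosities=(15,), conditions=("isolated",))
    tr = simulate_session(obs, plan, np.random.default_rng(3))
    n_left = (tr.reference_side == "left").sum()
    # binomial(180, .5): 3.5 sigma ~ 23
    assert abs(n_left - 90) < 24


def test_rt_trimming_fraction_below_5_percent():
    obs = ObserverModel(aq=15, bias_low=0.2, bias_high=0.1)
    plan = SessionPlan(reference_numerosities=(15, 25),
                       conditions=("isolated", "connected"))
    tr = simulate_session(obs, plan, np.random.default_rng(7))
    kept, removed = trim_rt(tr)
    assert len(removed) / len(tr) < 0.05


def test_unbiased_observer_recovers_reference(unbiased_block):
    fit = fit_psychometric(unbiased_block, 15)
    se = fit.sigma / np.sqrt(len(unbiased_block))
    assert abs(fit.pse - 15) < max(2 * se, 1.0)


def test_biased_observer_recovers_shifted_pse(biased_block):
    fit = fit_psychometric(biased_block, 15)
    assert abs(fit.pse - 15 * (1 - 0.27)) < 1.0
    assert fit.bias_pct < -20
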