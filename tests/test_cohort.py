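import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from epletmm.cohort import (
    CohortRecord,
    Detection,
    apply_cohort_filters,
    cox_fit,
    define_dndsa_events,
    derive_two_stage_thresholds,
    flag_early_dsa,
    km_estimate,
    load_cohort_records,
    logrank_test,
    optimal_cutpoint,
    roc_auc,
    write_outcomes_csv,
)
from epletmm.errors import ContractError, CoxError, DerivationError
from epletmm.registry import enumerate_molecules
from epletmm.risk import WIEBE

from conftest import make_typing


def _record(pair_id="P1", detections=(), flags=None, follow_up=6.0, **kw):
    return CohortRecord(
        pair_id=pair_id,
        follow_up_years=follow_up,
        detections=list(detections),
        flags=flags or {},
        **kw,
    )


@pytest.fixture()
def donor_mols(tiny_registry):
    donor = make_typing(
        subject_id="D", role="donor", drb345=("DRB3*02:02", None),
        dqb1=("DQB1*05:02", "DQB1*03:01"),
    )
    return enumerate_molecules(donor, tiny_registry)


# ---------------------------------------------------------------------------
# cohort filters
# ---------------------------------------------------------------------------


def test_filters_by_reason_order():
    records = [
        _record("P1", flags={"abo_incompatible": True}),
        _record("P2", flags={"spk": True, "pretransplant_dsa": True}),
        _record("P3"),
        _record("P4", flags={"dsa_within_14d": True}),
    ]
    retained, tally = apply_cohort_filters(records)
    assert [r.pair_id for r in retained] == ["P3"]
    assert tally["abo_incompatible"] == 1
    assert tally["spk"] == 1  # first matching reason wins
    assert tally["pretransplant_dsa"] == 0
    assert tally["dsa_within_14d"] == 1
    assert len(retained) + sum(tally.values()) == len(records)


def test_early_dsa_flag(donor_mols):
    rec = _record(detections=[Detection(10, "DQB1*05:02", 900.0)])
    assert flag_early_dsa(rec, donor_mols)
    # below MFI cutoff or third-party: not a memory response
    assert not flag_early_dsa(
        _record(detections=[Detection(10, "DQB1*05:02", 300.0)]), donor_mols
    )
    assert not flag_early_dsa(
        _record(detections=[Detection(10, "DQB1*06:01", 900.0)]), donor_mols
    )


# ---------------------------------------------------------------------------
# dnDSA events
# ---------------------------------------------------------------------------


def test_event_rule_application(donor_mols):
    rec = _record(
        detections=[
            Detection(400, "DQB1*05:02", 800.0),
            Detection(900, "DRB1*01:01", 600.0),
        ]
    )
    ev = define_dndsa_events(rec, donor_mols)
    assert ev["DQ"].event and math.isclose(ev["DQ"].time_years, 400 / 365.25)
    assert ev["DR"].event and math.isclose(ev["DR"].time_years, 900 / 365.25)


def test_subthreshold_mfi_censored(donor_mols):
    rec = _record(detections=[Detection(400, "DQB1*05:02", 450.0)])
    ev = define_dndsa_events(rec, donor_mols)
    assert not ev["DQ"].event
    assert ev["DQ"].time_years == rec.follow_up_years


def test_third_party_antibody_censored(donor_mols):
    rec = _record(detections=[Detection(400, "DQB1*06:01", 5000.0)])
    ev = define_dndsa_events(rec, donor_mols)
    assert not ev["DQ"].event and not ev["DR"].event


def test_memory_window_detection_not_an_event(donor_mols):
    rec = _record(detections=[Detection(10, "DQB1*05:02", 5000.0)])
    ev = define_dndsa_events(rec, donor_mols)
    assert not ev["DQ"].event


def test_earliest_qualifying_detection_wins(donor_mols):
    rec = _record(
        detections=[
            Detection(500, "DQB1*05:02", 800.0),
            Detection(300, "DQB1*03:01", 700.0),
        ]
    )
    ev = define_dndsa_events(rec, donor_mols)
    assert math.isclose(ev["DQ"].time_years, 300 / 365.25)


def test_missing_mfi_configurable(donor_mols):
    rec = _record(detections=[Detection(400, "DQB1*05:02", None)])
    ev = define_dndsa_events(rec, donor_mols, missing_mfi="skip")
    assert not ev["DQ"].event
    from epletmm.errors import ParseError

    with pytest.raises(ParseError):
        define_dndsa_events(rec, donor_mols, missing_mfi="error")


def test_outcomes_roundtrip(tmp_path):
    records = [
        _record("P1", detections=[Detection(400.0, "DQB1*05:02", 800.0),
                                  Detection(30.0, "DR15", None)],
                flags={"spk": True}),
        _record("P2", cni="tacrolimus", antimetabolite="azathioprine"),
    ]
    write_outcomes_csv(records, tmp_path / "o.csv", tmp_path / "d.csv")
    back = load_cohort_records(tmp_path / "o.csv", tmp_path / "d.csv")
    assert [r.pair_id for r in back] == ["P1", "P2"]
    assert back[0].flags["spk"] and not back[1].flags.get("spk")
    assert back[0].detections[0].mfi is None  # sorted by day; day 30 first
    assert back[0].detections[1].mfi == 800.0
    assert back[1].cni == "tacrolimus"


# ---------------------------------------------------------------------------
# ROC / cutpoint
# ---------------------------------------------------------------------------


def test_auc_perfect_separation():
    roc = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
    assert roc.auc == 1.0


def test_auc_constant_scores():
    roc = roc_auc([5, 5, 5, 5], [0, 1, 0, 1])
    assert roc.auc == 0.5


def test_auc_single_class_errors():
    with pytest.raises(ContractError):
        roc_auc([1, 2, 3], [1, 1, 1])


def test_operating_points_monotone():
    rng = np.random.default_rng(0)
    scores = rng.integers(0, 20, size=100)
    labels = rng.integers(0, 2, size=100)
    labels[0], labels[1] = 0, 1
    roc = roc_auc(scores, labels)
    assert np.all(np.diff(roc.sensitivity) <= 1e-12)
    assert np.all(np.diff(roc.specificity) >= -1e-12)
    assert np.all((roc.sensitivity >= 0) & (roc.sensitivity <= 1))
    assert np.all((roc.specificity >= 0) & (roc.specificity <= 1))


@settings(max_examples=200, deadline=None)
@given(
    st.lists(st.integers(0, 15), min_size=4, max_size=40),
    st.data(),
)
def test_auc_equals_pairwise_oracle(scores, data):
    labels = [data.draw(st.integers(0, 1)) for _ in scores]
    if len(set(labels)) < 2:
        labels[0], labels[1] = 0, 1
    roc = roc_auc(scores, labels)
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    assert abs(roc.auc - wins / (len(pos) * len(neg))) < 1e-12


def test_cutpoint_separable_step():
    scores = [1, 2, 3, 7, 8, 9]
    labels = [0, 0, 0, 1, 1, 1]
    assert optimal_cutpoint(roc_auc(scores, labels)) == 7


def test_cutpoint_flat_j_takes_highest_threshold():
    # one positive above all negatives at every threshold >= 2: J flat at 1
    roc = roc_auc([1, 5], [0, 1])
    # thresholds are [1, 5, 6]; J = [0, 1, 0] -> 5
    assert optimal_cutpoint(roc) == 5
    # fully non-informative: J == 0 everywhere, tie -> highest threshold
    flat = roc_auc([4, 4], [0, 1])
    assert optimal_cutpoint(flat) == int(flat.thresholds[-1])


@settings(max_examples=200, deadline=None)
@given(st.lists(st.integers(0, 12), min_size=4, max_size=30), st.data())
def test_cutpoint_equals_exhaustive_scan(scores, data):
    labels = [data.draw(st.integers(0, 1)) for _ in scores]
    if len(set(labels)) < 2:
        labels[0], labels[1] = 0, 1
    roc = roc_auc(scores, labels)
    got = optimal_cutpoint(roc)
    npos = sum(labels)
    nneg = len(labels) - npos
    cand = []
    for t in sorted(set(scores) | {max(scores) + 1}):
        sens = sum(1 for s, l in zip(scores, labels) if l == 1 and s >= t) / npos
        spec = sum(1 for s, l in zip(scores, labels) if l == 0 and s < t) / nneg
        cand.append((sens + spec - 1, t))
    best_j = max(j for j, _ in cand)
    best_t = max(t for j, t in cand if j >= best_j - 1e-12)
    assert got == best_t


# ---------------------------------------------------------------------------
# two-stage threshold derivation
# ---------------------------------------------------------------------------


def _mol_frame(rows):
    return pd.DataFrame(rows, columns=["pair_id", "score", "label"])


def test_two_stage_noise_free_recovery():
    rows_dr, rows_dq, summaries = [], [], []
    for i in range(40):
        pid = f"P{i}"
        dr_score = i % 22
        dq_score = (i * 3) % 33
        rows_dr.append({"pair_id": pid, "score": dr_score, "label": int(dr_score >= 12)})
        rows_dq.append({"pair_id": pid, "score": dq_score, "label": int(dq_score >= 15)})
        summaries.append((pid, max(dr_score, 9), max(dq_score, 10)))  # nobody LOW
    scheme = derive_two_stage_thresholds(
        {"DR": _mol_frame(rows_dr), "DQ": _mol_frame(rows_dq)}, summaries, WIEBE
    )
    assert scheme.high_dr_ge == 12
    assert scheme.high_dq_ge == 15
    assert scheme.dr_low_lt == WIEBE.dr_low_lt and scheme.dq_low_lt == WIEBE.dq_low_lt
    assert scheme.high_rule(12, 15) and not scheme.high_rule(11, 20)


def test_two_stage_low_risk_recipients_excluded():
    # the only positives sit on LOW recipients; after exclusion: single class
    rows = [{"pair_id": "P1", "score": 20, "label": 1},
            {"pair_id": "P2", "score": 1, "label": 0}]
    summaries = [("P1", 0, 0), ("P2", 10, 10)]
    with pytest.raises(DerivationError):
        derive_two_stage_thresholds(
            {"DR": _mol_frame(rows), "DQ": _mol_frame(rows)}, summaries, WIEBE
        )


# ---------------------------------------------------------------------------
# survival machinery
# ---------------------------------------------------------------------------


def test_km_no_events_constant_one():
    curve = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
    assert np.allclose(curve.survival, 1.0)
    assert curve.survival[0] == 1.0


def test_km_no_censoring_equals_empirical_survival():
    rng = np.random.default_rng(1)
    t = rng.exponential(2.0, size=200)
    curve = km_estimate(t, np.ones_like(t))
    for time, s in zip(curve.times[1:], curve.survival[1:]):
        assert abs(s - (t > time).mean()) < 1e-12
    assert np.all(np.diff(curve.survival) <= 1e-12)


def test_km_requires_subjects():
    with pytest.raises(ContractError):
        km_estimate([], [])


def test_logrank_identical_groups_nonsignificant():
    t = np.linspace(0.5, 5.0, 30)
    stat, p = logrank_test(t, np.ones(30), t, np.ones(30))
    assert stat < 1e-9 and p > 0.99


def test_cox_binary_covariate_matches_partial_likelihood_oracle():
    # n=8, untied times: grid/golden-search maximizer of the partial likelihood
    df = pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
            "event": [1, 1, 0, 1, 1, 0, 1, 1],
            "x": [1, 0, 1, 1, 0, 0, 1, 0],
        }
    )

    def neg_pl(beta):
        order = np.argsort(df["time"].values)
        t, e, x = (df["time"].values[order], df["event"].values[order],
                   df["x"].values[order])
        ll = 0.0
        for i in range(len(t)):
            if e[i]:
                risk = x[i:]  # all with time >= t[i]
                ll += beta * x[i] - math.log(np.exp(beta * risk).sum())
        return -ll

    oracle = minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                             options={"xatol": 1e-10})
    fit = cox_fit(df, "time", "event", ["x"])
    assert abs(fit.summary.loc["x", "coef"] - oracle.x) < 1e-4


def test_cox_constant_covariate_rejected():
    df = pd.DataFrame({"time": [1, 2, 3], "event": [1, 1, 0], "x": [1, 1, 1]})
    with pytest.raises(CoxError):
        cox_fit(df, "time", "event", ["x"])


def test_cox_categorical_contrasts_consistent():
    rng = np.random.default_rng(7)
    n = 300
    cat = rng.choice(["LOW", "INTERMEDIATE", "HIGH"], size=n)
    beta = {"LOW": 0.0, "INTERMEDIATE": 0.8, "HIGH": 1.6}
    t = rng.exponential(1.0 / (0.1 * np.exp([beta[c] for c in cat])))
    df = pd.DataFrame({"time": t, "event": np.ones(n, dtype=int), "cat": cat})
    fit = cox_fit(df, "time", "event", ["cat"],
                  categorical={"cat": ["LOW", "INTERMEDIATE", "HIGH"]})
    # contrast vs reference equals the fitted term
    c = fit.contrast("cat", "HIGH", "LOW")
    assert abs(c["coef"] - fit.summary.loc["cat[HIGH]", "coef"]) < 1e-12
    # high-vs-intermediate equals the coefficient difference
    c2 = fit.contrast("cat", "HIGH", "INTERMEDIATE")
    diff = (fit.summary.loc["cat[HIGH]", "coef"]
            - fit.summary.loc["cat[INTERMEDIATE]", "coef"])
    assert abs(c2["coef"] - diff) < 1e-12
    assert c2["ci_low"] < c2["hr"] < c2["ci_high"]
    # point estimates recover the generating contrasts loosely
    assert abs(c["coef"] - 1.6) < 0.5


def test_cox_hr_equals_exp_coef():
    df = pd.DataFrame(
        {"time": [1.0, 2, 3, 4, 5, 6], "event": [1, 1, 1, 1, 0, 1],
         "x": [0, 1, 0, 1, 0, 1]}
    )
    fit = cox_fit(df, "time", "event", ["x"])
    row = fit.summary.loc["x"]
    assert math.isclose(row["hr"], math.exp(row["coef"]), rel_tol=1e-12)
    assert row["ci_low"] <= row["hr"] <= row["ci_high"]
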