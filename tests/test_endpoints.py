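"""Responder endpoints: scalar rules, the vectorized pipeline, and
AO / NRI-MI aggregation."""

import numpy as np
import pandas as pd
import pytest

import psaphen as pp
from psaphen.endpoints import ENDPOINTS


# -- DAPSA ------------------------------------------------------------------


@pytest.mark.parametrize(
    "components,score,lda",
    [
        ((0, 0, 0, 0, 0), 0.0, True),
        ((10, 7, 0.5, 5.0, 5.0), 27.5, False),
        ((5, 4, 1.0, 2.0, 2.0), 14.0, True),      # boundary: score == 14 is LDA
        ((5, 4, 1.1, 2.0, 2.0), 14.1, False),
    ],
)
def test_dapsa_sum_and_lda_threshold(components, score, lda):
    s = pp.dapsa(*components)
    assert s == pytest.approx(score)
    assert pp.dapsa_lda(s) is lda


def test_dapsa_missing_component_gives_missing_flag():
    assert pp.dapsa(1, 2, None, 3, 4) is pd.NA
    assert pp.dapsa_lda(pd.NA) is pd.NA


# -- MDA --------------------------------------------------------------------


def test_mda_all_zero_meets_all_seven():
    assert pp.mda(0, 0, 0, 0, 0, 0, 0) is True


def test_mda_five_of_seven_boundary():
    # exactly 5 criteria met (TJC and SJC fail)
    assert pp.mda(5, 5, 0, 0, 0, 0, 0) is True
    # exactly 4 criteria met (TJC, SJC, BSA fail)
    assert pp.mda(5, 5, 10, 0, 0, 0, 0) is False


def test_mda_six_of_seven_counts():
    assert pp.mda(2, 0, 0, 0, 0, 0, 0) is True


def test_mda_missing_component_gives_missing():
    assert pp.mda(0, 0, None, 0, 0, 0, 0) is pd.NA


# -- percentage improvement -------------------------------------------------


@pytest.mark.parametrize(
    "baseline,visit,expected",
    [(10, 5, True), (10, 6, False), (10, 4, True), (0, 0, True), (0, 2, False)],
)
def test_fifty_percent_improvement_rule(baseline, visit, expected):
    assert pp.pct_improvement_flag(baseline, visit) is expected


def test_improvement_missing_visit_gives_missing_and_missing_baseline_raises():
    assert pp.pct_improvement_flag(10, None) is pd.NA
    with pytest.raises(ValueError):
        pp.pct_improvement_flag(None, 5)


# -- ACR50 ------------------------------------------------------------------


def _record(**kwargs):
    base = dict(tjc68=10, sjc66=8, pain=50, patient_global=50, physician_global=50,
                haq_di=1.0, facit_f=30, crp=10.0)
    base.update(kwargs)
    return base


def test_acr50_full_improvement_responds():
    visit = {k: 0 for k in _record()}
    assert pp.acr50(_record(), visit) is True


def test_acr50_needs_three_of_five_extras():
    base = _record()
    # joints halve, but only pain and patient global improve >= 50%
    visit = _record(tjc68=5, sjc66=4, pain=20, patient_global=20,
                    physician_global=40, haq_di=0.9, crp=9.0)
    assert pp.acr50(base, visit) is False
    visit["physician_global"] = 25
    assert pp.acr50(base, visit) is True


def test_acr50_missing_component_gives_missing():
    assert pp.acr50(_record(), _record(crp=None)) is pd.NA


# -- MCIDs ------------------------------------------------------------------


@pytest.mark.parametrize(
    "base,visit,expected",
    [
        (dict(haq_di=1.00), dict(haq_di=0.65), (True, pd.NA, pd.NA)),   # exactly 0.35
        (dict(pain=50.0), dict(pain=41.0), (pd.NA, False, pd.NA)),      # 9 mm < 10 mm
        (dict(pain=50.0), dict(pain=40.0), (pd.NA, True, pd.NA)),
        (dict(facit_f=30.0), dict(facit_f=34.0), (pd.NA, pd.NA, True)),
        (dict(facit_f=30.0), dict(facit_f=33.9), (pd.NA, pd.NA, False)),
    ],
)
def test_mcid_thresholds(base, visit, expected):
    got = pp.mcid_flags(base, visit)
    for g, e in zip(got, expected):
        assert g is e if e is pd.NA else g == e


def test_eligibility_gates():
    assert pp.eligibility_filter(0.25, 50.0) == {"MCID_HAQ": False, "MCID_pain": True}
    assert pp.eligibility_filter(1.0, 8.0) == {"MCID_HAQ": True, "MCID_pain": False}
    assert pp.eligibility_filter(0.35, 10.0) == {"MCID_HAQ": True, "MCID_pain": True}


# -- vectorized pipeline vs scalar reference --------------------------------


def _random_visits(n=60, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        pid = f"P{i:03d}"
        base = dict(
            tjc68=rng.integers(5, 40), sjc66=rng.integers(5, 30),
            pain=rng.uniform(10, 90), patient_global=rng.uniform(10, 90),
            physician_global=rng.uniform(10, 90), haq_di=rng.uniform(0.1, 2.5),
            facit_f=rng.uniform(10, 45), crp=rng.uniform(0.2, 30),
            bsa=rng.uniform(0, 30), entheseal_points=rng.integers(0, 10),
        )
        rows.append({"patient_id": pid, "week": 0, "missing_reason": "none", **base})
        for week in (12, 24):
            if rng.random() < 0.15:
                rows.append(
                    {"patient_id": pid, "week": week, "missing_reason": "other",
                     **{k: np.nan for k in base}}
                )
                continue
            visit = {
                k: (max(v * rng.uniform(0.0, 1.2), 0) if k not in ("tjc68", "sjc66")
                    else int(v * rng.uniform(0.0, 1.2)))
                for k, v in base.items()
            }
            rows.append({"patient_id": pid, "week": week, "missing_reason": "none", **visit})
    return pd.DataFrame(rows)


def test_pipeline_flags_match_scalar_rule_evaluation():
    """The vectorized flag computation agrees with independent row-by-row
    evaluation through the scalar endpoint rules."""
    visits = _random_visits()
    flags, _ = pp.compute_endpoint_flags(visits)
    base = visits[visits.week == 0].set_index("patient_id")
    for (pid, week), row in flags.iterrows():
        v = visits[(visits.patient_id == pid) & (visits.week == week)].iloc[0]
        b = base.loc[pid]
        if v["missing_reason"] != "none":
            assert all(row[ep] is pd.NA for ep in ENDPOINTS)
            continue
        expected_mda = pp.mda(v.tjc68, v.sjc66, v.bsa, v.pain, v.patient_global,
                              v.haq_di, v.entheseal_points)
        assert row["MDA"] == expected_mda
        score = pp.dapsa(v.tjc68, v.sjc66, v.crp / 10, v.pain / 10, v.patient_global / 10)
        assert row["DAPSA_LDA"] == pp.dapsa_lda(score)
        assert row["TJC50"] == pp.pct_improvement_flag(b.tjc68, v.tjc68)
        assert row["SJC50"] == pp.pct_improvement_flag(b.sjc66, v.sjc66)
        assert row["ACR50"] == pp.acr50(dict(b), dict(v))
        haq, pain, facit = pp.mcid_flags(dict(b), dict(v))
        assert (row["MCID_HAQ"], row["MCID_pain"], row["MCID_FACITF"]) == (haq, pain, facit)


# -- aggregation ------------------------------------------------------------


def _flags_frame(entries):
    """entries: {patient: flag} at a single week for endpoint MDA."""
    idx = pd.MultiIndex.from_tuples(
        [(p, 12) for p in entries], names=["patient_id", "week"]
    )
    return pd.DataFrame({"MDA": pd.array(list(entries.values()), dtype="boolean")}, index=idx)


def test_as_observed_rate_and_denominator():
    flags = _flags_frame({f"P{i}": i < 5 for i in range(10)})
    labels = pd.Series(0, index=[f"P{i}" for i in range(10)])
    rates = pp.responder_rates(flags, labels, endpoints=["MDA"])
    assert rates.iloc[0]["rate"] == pytest.approx(50.0)
    assert rates.iloc[0]["n"] == 10


def test_as_observed_excludes_missing_from_denominator():
    entries = {f"P{i}": (True if i < 5 else False) for i in range(10)}
    entries["P9"] = pd.NA
    flags = _flags_frame(entries)
    labels = pd.Series(0, index=list(entries))
    rates = pp.responder_rates(flags, labels, endpoints=["MDA"])
    assert rates.iloc[0]["n"] == 9
    assert rates.iloc[0]["rate"] == pytest.approx(100 * 5 / 9)


def test_wilson_interval_matches_closed_form():
    flags = _flags_frame({f"P{i}": i < 5 for i in range(10)})
    labels = pd.Series(0, index=[f"P{i}" for i in range(10)])
    row = pp.responder_rates(flags, labels, endpoints=["MDA"]).iloc[0]
    z, p, n = 1.959963984540054, 0.5, 10
    centre = (p + z**2 / (2 * n)) / (1 + z**2 / n)
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
    assert row["ci_low"] == pytest.approx(100 * (centre - half))
    assert row["ci_high"] == pytest.approx(100 * (centre + half))
    assert row["ci_low"] < row["rate"] < row["ci_high"]


def _reasons(entries, reason):
    return pd.DataFrame(
        {
            "patient_id": list(entries),
            "week": 12,
            "missing_reason": [
                reason if entries[p] is pd.NA else "none" for p in entries
            ],
        }
    )


def test_nri_mi_equals_ao_without_missingness():
    flags = _flags_frame({f"P{i}": i < 4 for i in range(10)})
    labels = pd.Series(0, index=[f"P{i}" for i in range(10)])
    ao = pp.responder_rates(flags, labels, endpoints=["MDA"])
    nri = pp.nri_mi_rates(flags, _reasons({f"P{i}": True for i in range(10)}, "none"),
                          labels, endpoints=["MDA"], m=5, seed=0)
    assert nri.iloc[0]["rate"] == pytest.approx(ao.iloc[0]["rate"])


def test_other_reason_missingness_counts_as_non_response():
    entries = {f"P{i}": (True if i < 5 else pd.NA) for i in range(10)}
    flags = _flags_frame(entries)
    labels = pd.Series(0, index=list(entries))
    ao = pp.responder_rates(flags, labels, endpoints=["MDA"])
    nri = pp.nri_mi_rates(flags, _reasons(entries, "other"), labels,
                          endpoints=["MDA"], m=5, seed=0)
    assert ao.iloc[0]["rate"] == pytest.approx(100.0)     # 5/5 observed
    assert nri.iloc[0]["rate"] == pytest.approx(50.0)     # 5/10 after NRI
    assert nri.iloc[0]["rate"] <= ao.iloc[0]["rate"]


def test_covid_missingness_imputed_from_observed_rate():
    """One pandemic-missing patient in a cluster-week with observed rate
    0.5: the pooled NRI-MI rate converges to (responders + 0.5) / n."""
    entries = {f"P{i}": (i < 5) for i in range(10)}
    entries["P10"] = pd.NA
    flags = _flags_frame(entries)
    labels = pd.Series(0, index=list(entries))
    nri = pp.nri_mi_rates(flags, _reasons(entries, "covid_geo"), labels,
                          endpoints=["MDA"], m=4000, seed=1)
    assert nri.iloc[0]["rate"] == pytest.approx(100 * 5.5 / 11, abs=1.0)


def test_no_observed_basis_falls_back_to_non_responder():
    entries = {"P0": pd.NA, "P1": pd.NA}
    flags = _flags_frame(entries)
    labels = pd.Series(0, index=list(entries))
    with pytest.warns(UserWarning, match="no observed data"):
        nri = pp.nri_mi_rates(flags, _reasons(entries, "covid_geo"), labels,
                              endpoints=["MDA"], m=5, seed=0)
    assert nri.iloc[0]["rate"] == pytest.approx(0.0)


def test_eligibility_excludes_patients_from_both_analyses():
    idx = pd.MultiIndex.from_tuples([(f"P{i}", 12) for i in range(4)],
                                    names=["patient_id", "week"])
    flags = pd.DataFrame({"MCID_HAQ": pd.array([True, True, False, True],
                                               dtype="boolean")}, index=idx)
    eligibility = pd.DataFrame(
        {"MCID_HAQ": [True, True, True, False]},
        index=pd.Index([f"P{i}" for i in range(4)], name="patient_id"),
    )
    labels = pd.Series(0, index=eligibility.index)
    ao = pp.responder_rates(flags, labels, eligibility, endpoints=["MCID_HAQ"])
    assert ao.iloc[0]["n"] == 3
    assert ao.iloc[0]["rate"] == pytest.approx(100 * 2 / 3)
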