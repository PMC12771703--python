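"""Responder endpoints and phenotype-level response-rate analyses.

Per patient-visit the module derives composite responder flags from raw
endpoint components, then aggregates them into cluster x week response
rates under two analyses:

* as observed (AO): the denominator is everyone with a non-missing flag;
* non-responder imputation with multiple imputation (NRI-MI): missing
  visits count as failures, except visits missing because of pandemic or
  geopolitical disruption, which are multiply imputed from the observed
  response probability of the same cluster-week and pooled by Rubin's
  rules.

Component units: joint counts (0-68 tender / 0-66 swollen), VAS scores in
mm (0-100), HAQ-DI 0-3, FACIT-F 0-52, CRP in mg/L (converted to mg/dL
inside the DAPSA sum), body surface area in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

ENDPOINTS = [
    "MDA", "DAPSA_LDA", "TJC50", "SJC50", "ACR50",
    "MCID_HAQ", "MCID_pain", "MCID_FACITF",
]

#: minimal-disease-activity cut-offs; a patient is in MDA when at least
#: MDA_REQUIRED of the seven criteria hold
MDA_CRITERIA = {
    "tjc68": 1.0,
    "sjc66": 1.0,
    "bsa": 3.0,
    "pain": 15.0,
    "patient_global": 20.0,
    "haq_di": 0.5,
    "entheseal_points": 1.0,
}
MDA_REQUIRED = 5

DAPSA_LDA_CUTOFF = 14.0
HAQ_MCID = 0.35
PAIN_MCID_MM = 10.0
FACITF_MCID = 4.0

#: ACR50 auxiliary measures; at least 3 of these 5 must improve >= 50%
ACR_EXTRAS = ["pain", "patient_global", "physician_global", "haq_di", "crp"]
ACR_EXTRAS_REQUIRED = 3


def _is_missing(*values) -> bool:
    return any(v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NA for v in values)


# ---------------------------------------------------------------------------
# scalar endpoint rules (also serve as the reference evaluators in tests)
# ---------------------------------------------------------------------------


def dapsa(tjc68, sjc66, crp_mg_dl, pain_cm, patient_global_cm):
    """DAPSA score: TJC68 + SJC66 + CRP (mg/dL) + pain (cm) + patient global (cm)."""
    if _is_missing(tjc68, sjc66, crp_mg_dl, pain_cm, patient_global_cm):
        return pd.NA
    return float(tjc68 + sjc66 + crp_mg_dl + pain_cm + patient_global_cm)


def dapsa_lda(score):
    """Low disease activity: DAPSA <= 14 (boundary inclusive)."""
    if _is_missing(score):
        return pd.NA
    return bool(score <= DAPSA_LDA_CUTOFF)


def mda(tjc68, sjc66, bsa, pain_mm, patient_global_mm, haq_di, entheseal_points):
    """Minimal disease activity: at least 5 of the 7 cut-offs hold."""
    components = dict(
        tjc68=tjc68, sjc66=sjc66, bsa=bsa, pain=pain_mm,
        patient_global=patient_global_mm, haq_di=haq_di,
        entheseal_points=entheseal_points,
    )
    if _is_missing(*components.values()):
        return pd.NA
    met = sum(components[k] <= cut for k, cut in MDA_CRITERIA.items())
    return bool(met >= MDA_REQUIRED)


def pct_improvement_flag(baseline, visit, threshold: float = 0.50):
    """True when (baseline - visit)/baseline >= threshold.

    A zero baseline cannot improve by a percentage; the patient counts as
    a responder only when the visit value is also zero.
    """
    if _is_missing(baseline):
        raise ValueError("baseline value is required")
    if _is_missing(visit):
        return pd.NA
    if baseline == 0:
        return bool(visit == 0)
    return bool((baseline - visit) / baseline >= threshold)


def acr50(baseline: dict, visit: dict):
    """ACR50: both joint counts improved >= 50% and >= 3 of 5 auxiliary
    measures (pain, both globals, HAQ-DI, CRP) improved >= 50%."""
    required = ["tjc68", "sjc66"] + ACR_EXTRAS
    if _is_missing(*(visit.get(k) for k in required)):
        return pd.NA
    if _is_missing(*(baseline.get(k) for k in required)):
        return pd.NA
    joints = all(
        pct_improvement_flag(baseline[k], visit[k]) for k in ("tjc68", "sjc66")
    )
    extras = sum(bool(pct_improvement_flag(baseline[k], visit[k])) for k in ACR_EXTRAS)
    return bool(joints and extras >= ACR_EXTRAS_REQUIRED)


def mcid_flags(baseline: dict, visit: dict):
    """(MCID_HAQ, MCID_pain, MCID_FACITF) minimal clinically important
    differences: HAQ-DI decrease >= 0.35, pain decrease >= 10 mm, FACIT-F
    increase >= 4."""
    haq = pd.NA if _is_missing(baseline.get("haq_di"), visit.get("haq_di")) else bool(
        baseline["haq_di"] - visit["haq_di"] >= HAQ_MCID
    )
    pain = pd.NA if _is_missing(baseline.get("pain"), visit.get("pain")) else bool(
        baseline["pain"] - visit["pain"] >= PAIN_MCID_MM
    )
    facit = pd.NA if _is_missing(baseline.get("facit_f"), visit.get("facit_f")) else bool(
        visit["facit_f"] - baseline["facit_f"] >= FACITF_MCID
    )
    return haq, pain, facit


def eligibility_filter(baseline_haq_di, baseline_pain_mm) -> dict:
    """Endpoint-denominator eligibility gates from the baseline visit.

    The HAQ-DI MCID is only assessable in patients with baseline HAQ-DI
    >= 0.35 and the pain MCID in patients with baseline pain VAS >= 10 mm
    (both boundaries inclusive); all patients are eligible elsewhere.
    """
    return {
        "MCID_HAQ": bool(not _is_missing(baseline_haq_di) and baseline_haq_di >= HAQ_MCID),
        "MCID_pain": bool(not _is_missing(baseline_pain_mm) and baseline_pain_mm >= PAIN_MCID_MM),
    }


# ---------------------------------------------------------------------------
# vectorized per-visit flag computation
# ---------------------------------------------------------------------------


def compute_endpoint_flags(visits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive all responder flags for every follow-up visit.

    ``visits`` is the long visit table (one row per patient-week) with a
    complete week-0 row per patient.  Returns ``(flags, eligibility)``:
    ``flags`` indexed by (patient_id, week) with one nullable-boolean
    column per endpoint (NA when the visit or a required component is
    missing), and ``eligibility`` indexed by patient_id with the MCID
    denominator gates.
    """
    base = visits[visits["week"] == 0].set_index("patient_id")
    if base.index.duplicated().any():
        raise ValueError("duplicate week-0 rows")
    followup = visits[visits["week"] != 0].copy()
    missing_base = set(followup["patient_id"]) - set(base.index)
    if missing_base:
        raise ValueError(f"patients without a week-0 baseline: {sorted(missing_base)[:5]}")

    b = base.loc[followup["patient_id"]].reset_index(drop=True)
    v = followup.reset_index(drop=True)

    def imp50(col: str) -> pd.Series:
        base_vals = b[col].to_numpy(dtype=float)
        visit_vals = v[col].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = (base_vals - visit_vals) / base_vals
        ok = np.where(base_vals == 0, visit_vals == 0, frac >= 0.50)
        return pd.Series(ok, dtype="boolean").mask(np.isnan(visit_vals))

    flags = pd.DataFrame({"patient_id": v["patient_id"], "week": v["week"]})

    present = v[list(MDA_CRITERIA)].notna().all(axis=1)
    met = sum(
        (v[col] <= cut).astype(int) for col, cut in MDA_CRITERIA.items()
    )
    flags["MDA"] = pd.array((met >= MDA_REQUIRED).to_numpy(), dtype="boolean")
    flags.loc[~present, "MDA"] = pd.NA

    score = v["tjc68"] + v["sjc66"] + v["crp"] / 10.0 + v["pain"] / 10.0 + v["patient_global"] / 10.0
    flags["DAPSA_LDA"] = pd.array((score <= DAPSA_LDA_CUTOFF).to_numpy(), dtype="boolean")
    flags.loc[score.isna(), "DAPSA_LDA"] = pd.NA

    flags["TJC50"] = imp50("tjc68")
    flags["SJC50"] = imp50("sjc66")

    extras = sum(imp50(col).fillna(False).astype(int) for col in ACR_EXTRAS)
    acr = imp50("tjc68") & imp50("sjc66") & (extras >= ACR_EXTRAS_REQUIRED)
    acr_present = v[["tjc68", "sjc66"] + ACR_EXTRAS].notna().all(axis=1)
    flags["ACR50"] = acr.mask(~acr_present)

    haq_delta = b["haq_di"].to_numpy(dtype=float) - v["haq_di"].to_numpy(dtype=float)
    flags["MCID_HAQ"] = pd.Series(haq_delta >= HAQ_MCID, dtype="boolean").mask(np.isnan(haq_delta))
    pain_delta = b["pain"].to_numpy(dtype=float) - v["pain"].to_numpy(dtype=float)
    flags["MCID_pain"] = pd.Series(pain_delta >= PAIN_MCID_MM, dtype="boolean").mask(
        np.isnan(pain_delta)
    )
    facit_delta = v["facit_f"].to_numpy(dtype=float) - b["facit_f"].to_numpy(dtype=float)
    flags["MCID_FACITF"] = pd.Series(facit_delta >= FACITF_MCID, dtype="boolean").mask(
        np.isnan(facit_delta)
    )

    flags = flags.set_index(["patient_id", "week"])[ENDPOINTS]

    eligibility = pd.DataFrame(
        {
            "MCID_HAQ": base["haq_di"].astype(float) >= HAQ_MCID,
            "MCID_pain": base["pain"].astype(float) >= PAIN_MCID_MM,
        },
        index=base.index,
    )
    return flags, eligibility


# ---------------------------------------------------------------------------
# cluster x week response rates
# ---------------------------------------------------------------------------


def _eligible_ids(endpoint: str, ids: pd.Index, eligibility: pd.DataFrame | None) -> pd.Index:
    if eligibility is None or endpoint not in eligibility.columns:
        return ids
    ok = eligibility.loc[eligibility.index.intersection(ids), endpoint]
    return ids[ids.isin(ok[ok].index)]


def responder_rates(
    flags: pd.DataFrame,
    labels: pd.Series,
    eligibility: pd.DataFrame | None = None,
    endpoints: list[str] | None = None,
) -> pd.DataFrame:
    """As-observed response rates by cluster, week and endpoint.

    The denominator is the eligible patients of the cluster with a
    non-missing flag at that week; the interval is the Wilson score 95% CI.
    Rates are percentages.
    """
    endpoints = endpoints or [c for c in ENDPOINTS if c in flags.columns]
    labels = pd.Series(labels)
    weeks = sorted(flags.index.get_level_values("week").unique())
    rows = []
    for cluster in sorted(labels.unique()):
        members = pd.Index(labels[labels == cluster].index)
        for week in weeks:
            week_flags = flags.xs(week, level="week")
            for ep in endpoints:
                ids = _eligible_ids(ep, members, eligibility)
                col = week_flags.reindex(ids)[ep]
                observed = col.dropna()
                n, resp = len(observed), int(observed.sum())
                if n == 0:
                    rows.append((cluster, week, ep, 0, 0, np.nan, np.nan, np.nan, "AO"))
                    continue
                lo, hi = proportion_confint(resp, n, alpha=0.05, method="wilson")
                rows.append((cluster, week, ep, n, resp, 100 * resp / n, 100 * lo, 100 * hi, "AO"))
    return pd.DataFrame(
        rows,
        columns=["cluster", "week", "endpoint", "n", "responders", "rate", "ci_low", "ci_high",
                 "analysis"],
    )


def nri_mi_rates(
    flags: pd.DataFrame,
    reasons: pd.DataFrame,
    labels: pd.Series,
    eligibility: pd.DataFrame | None = None,
    endpoints: list[str] | None = None,
    m: int = 20,
    seed: int | None = None,
) -> pd.DataFrame:
    """Non-responder-imputation rates with multiple imputation.

    Missing flags whose visit reason is ``other`` or ``dropout`` (or whose
    visit is absent altogether) are non-responders.  Flags missing because
    of ``covid_geo`` are imputed ``m`` times as Bernoulli draws from the
    cluster-week as-observed response probability and pooled by Rubin's
    rules: pooled rate = mean of the per-imputation rates, total variance =
    within-imputation + (1 + 1/m) x between-imputation variance, normal
    95% CI.  ``reasons`` is a frame with patient_id, week, missing_reason.

    The denominator is every eligible cluster member, so with purely
    ``other``-reason missingness the NRI-MI rate can only fall below the
    as-observed rate.
    """
    endpoints = endpoints or [c for c in ENDPOINTS if c in flags.columns]
    labels = pd.Series(labels)
    rng = np.random.default_rng(seed)
    weeks = sorted(flags.index.get_level_values("week").unique())
    reason_lookup = reasons.set_index(["patient_id", "week"])["missing_reason"]

    rows = []
    for cluster in sorted(labels.unique()):
        members = pd.Index(labels[labels == cluster].index)
        for week in weeks:
            week_flags = flags.xs(week, level="week")
            for ep in endpoints:
                ids = _eligible_ids(ep, members, eligibility)
                n = len(ids)
                if n == 0:
                    rows.append((cluster, week, ep, 0, np.nan, np.nan, np.nan, np.nan, "NRI_MI", m))
                    continue
                col = week_flags.reindex(ids)[ep]
                observed = col.dropna().astype(bool)
                missing_ids = col.index[col.isna()]
                reason = reason_lookup.reindex(
                    pd.MultiIndex.from_product([missing_ids, [week]])
                ).fillna("other").to_numpy()
                n_covid = int((reason == "covid_geo").sum())
                n_resp_obs = int(observed.sum())

                if n_covid and len(observed):
                    p_obs = n_resp_obs / len(observed)
                    draws = rng.random((m, n_covid)) < p_obs
                    q = (n_resp_obs + draws.sum(axis=1)) / n
                else:
                    if n_covid:
                        warnings.warn(
                            f"cluster {cluster} week {week} {ep}: no observed data to "
                            "impute from; counting as non-responders",
                            stacklevel=2,
                        )
                    q = np.full(m, n_resp_obs / n)

                q_bar = float(q.mean())
                within = float(np.mean(q * (1 - q) / n))
                between = float(q.var(ddof=1)) if m > 1 else 0.0
                total_var = within + (1 + 1 / m) * between
                half = 1.959963984540054 * np.sqrt(total_var)
                lo, hi = max(0.0, q_bar - half), min(1.0, q_bar + half)
                rows.append(
                    (cluster, week, ep, n, 100 * q_bar, 100 * lo, 100 * hi,
                     100**2 * total_var, "NRI_MI", m)
                )
    return pd.DataFrame(
        rows,
        columns=["cluster", "week", "endpoint", "n", "rate", "ci_low", "ci_high",
                 "total_variance", "analysis", "m"],
    )
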