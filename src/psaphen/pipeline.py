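"""End-to-end convenience: raw cohort table -> model-ready matrix.

Chains the cleaning rules in their fixed order — feature exclusions
(missingness, then collinearity), patient completeness, encoding — and
returns everything downstream stages need.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .encode import CohortEncoder
from .io import (
    DEFAULT_COLLINEARITY_THRESHOLD,
    DEFAULT_MISSING_THRESHOLD,
    ExclusionReport,
    apply_feature_exclusions,
    drop_incomplete_patients,
)
from .schema import FeatureSchema


@dataclass
class PreparedCohort:
    cohort: pd.DataFrame           # complete rows, retained features, raw values
    encoded: pd.DataFrame          # model-ready matrix
    schema: FeatureSchema          # schema restricted to retained features
    report: ExclusionReport
    n_loaded: int

    @property
    def retention_pct(self) -> float:
        return 100.0 * len(self.cohort) / self.n_loaded


def prepare_cohort(
    cohort: pd.DataFrame,
    schema: FeatureSchema,
    missing_threshold: float = DEFAULT_MISSING_THRESHOLD,
    collinearity_threshold: float = DEFAULT_COLLINEARITY_THRESHOLD,
    **encoder_kwargs,
) -> PreparedCohort:
    n_loaded = len(cohort)
    filtered, report = apply_feature_exclusions(
        cohort, schema, missing_threshold, collinearity_threshold
    )
    complete, n_dropped = drop_incomplete_patients(filtered)
    report.dropped_patients = n_dropped
    kept_schema = schema.subset(complete.columns)
    encoder = CohortEncoder(kept_schema, **encoder_kwargs).fit(complete)
    return PreparedCohort(
        cohort=complete,
        encoded=encoder.transform(complete),
        schema=kept_schema,
        report=report,
        n_loaded=n_loaded,
    )
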