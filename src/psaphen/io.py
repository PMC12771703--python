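"""Reading, validating, and filtering baseline cohort tables.

A cohort table is a :class:`pandas.DataFrame` indexed by ``patient_id``
whose columns match a :class:`~psaphen.schema.FeatureSchema`.  Missing
values are a single sentinel (``NaN``) regardless of feature kind.

The filtering rules implemented here mirror the pre-modelling cleaning of
a pooled clinical-trial baseline table: features are dropped when too
sparsely observed or collinear with an earlier feature, then patients with
any remaining missing value are removed so the model never sees gaps.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import FeatureSchema

logger = logging.getLogger(__name__)

#: fraction of missing values above which a feature is excluded
DEFAULT_MISSING_THRESHOLD = 0.20
#: absolute pairwise correlation at or above which the later feature is excluded
DEFAULT_COLLINEARITY_THRESHOLD = 0.95


class CohortError(ValueError):
    """Fatal cohort validation or filtering failure."""


@dataclass
class ExclusionReport:
    """Record of feature and patient exclusions applied to a cohort."""

    dropped_features: list[tuple[str, str]] = field(default_factory=list)
    dropped_patients: int = 0
    missing_threshold: float = DEFAULT_MISSING_THRESHOLD
    collinearity_threshold: float = DEFAULT_COLLINEARITY_THRESHOLD

    def to_json(self, path=None) -> str:
        payload = {
            "dropped_features": [
                {"feature": name, "reason": reason} for name, reason in self.dropped_features
            ],
            "dropped_patients": self.dropped_patients,
            "thresholds": {
                "missing": self.missing_threshold,
                "collinearity": self.collinearity_threshold,
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def load_cohort(path, schema: FeatureSchema) -> pd.DataFrame:
    """Read a baseline CSV and validate it against ``schema``.

    The file must have a header with a ``patient_id`` column plus exactly
    the schema's feature names.  Cells that fail to parse for their declared
    kind become missing with a warning; structural problems (missing id
    column, unknown columns, duplicate ids) are fatal.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=True)
    if "patient_id" not in raw.columns:
        raise CohortError("baseline table lacks required 'patient_id' column")
    unknown = [c for c in raw.columns if c != "patient_id" and c not in schema]
    if unknown:
        raise CohortError(f"columns not in schema: {unknown}")
    missing_cols = [n for n in schema.names if n not in raw.columns]
    if missing_cols:
        raise CohortError(f"schema features absent from table: {missing_cols}")
    if raw["patient_id"].isna().any():
        raise CohortError("missing patient_id value")
    if raw["patient_id"].duplicated().any():
        dupes = raw.loc[raw["patient_id"].duplicated(), "patient_id"].tolist()
        raise CohortError(f"duplicated patient_id values: {dupes}")

    cohort = pd.DataFrame(index=pd.Index(raw["patient_id"], name="patient_id"))
    for feat in schema:
        col = raw[feat.name]
        col.index = cohort.index
        if feat.kind == "continuous":
            parsed = pd.to_numeric(col, errors="coerce")
            bad = parsed.isna() & col.notna()
            if bad.any():
                warnings.warn(
                    f"{int(bad.sum())} unparseable value(s) in continuous column "
                    f"{feat.name!r} set to missing",
                    stacklevel=2,
                )
            cohort[feat.name] = parsed.astype(float)
        else:
            valid = col.isin(feat.levels)
            bad = ~valid & col.notna()
            if bad.any():
                warnings.warn(
                    f"{int(bad.sum())} value(s) outside declared levels in column "
                    f"{feat.name!r} set to missing",
                    stacklevel=2,
                )
            cohort[feat.name] = col.where(valid, np.nan)
    return cohort


def _numeric_view(cohort: pd.DataFrame, schema: FeatureSchema) -> pd.DataFrame:
    """Numeric representation used for pairwise correlation screening.

    Continuous features pass through; binary/categorical features are
    replaced by their level codes so exact duplicates (however labelled)
    reach |r| = 1.
    """
    out = {}
    for name in cohort.columns:
        feat = schema[name]
        if feat.is_numeric:
            out[name] = cohort[name].astype(float)
        else:
            mapping = {lvl: i for i, lvl in enumerate(feat.levels)}
            out[name] = cohort[name].map(mapping).astype(float)
    return pd.DataFrame(out, index=cohort.index)


def apply_feature_exclusions(
    cohort: pd.DataFrame,
    schema: FeatureSchema,
    missing_threshold: float = DEFAULT_MISSING_THRESHOLD,
    collinearity_threshold: float = DEFAULT_COLLINEARITY_THRESHOLD,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop high-missingness features, then collinear features.

    Missingness fractions are computed over all loaded rows.  Collinearity
    is absolute Pearson correlation on complete cases between each pair of
    numerically coded features; within a flagged pair the feature that
    appears later in schema order is dropped (keep-first rule), and a
    feature already dropped cannot trigger further drops.
    """
    if cohort.shape[0] == 0:
        raise CohortError("empty cohort")
    report = ExclusionReport(
        missing_threshold=missing_threshold, collinearity_threshold=collinearity_threshold
    )

    keep = list(cohort.columns)
    for name in cohort.columns:
        frac = float(cohort[name].isna().mean())
        if frac > missing_threshold:
            keep.remove(name)
            report.dropped_features.append((name, "missing_gt_threshold"))
            logger.info("dropping %s: missing fraction %.3f", name, frac)

    num = _numeric_view(cohort[keep], schema.subset(keep))
    dropped = set()
    for i, a in enumerate(keep):
        if a in dropped:
            continue
        for b in keep[i + 1 :]:
            if b in dropped:
                continue
            pair = num[[a, b]].dropna()
            if len(pair) < 2:
                continue
            with np.errstate(invalid="ignore"):
                r = pair[a].corr(pair[b])
            if np.isfinite(r) and abs(r) >= collinearity_threshold:
                dropped.add(b)
                report.dropped_features.append((b, f"collinear_with:{a}"))
                logger.info("dropping %s: |r|=%.3f with %s", b, abs(r), a)
    keep = [c for c in keep if c not in dropped]

    if not keep:
        raise CohortError(f"all features excluded: {report.to_json()}")
    return cohort[keep], report


def drop_incomplete_patients(cohort: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Remove rows with any missing value among the remaining features."""
    complete = cohort.dropna(axis=0, how="any")
    n_dropped = cohort.shape[0] - complete.shape[0]
    if complete.shape[0] == 0:
        raise CohortError("no complete patients remain after exclusions")
    return complete, n_dropped
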