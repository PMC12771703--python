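"""Encoding of complete cohort tables for mixture modelling.

Continuous features pass through as floats.  Binary and categorical
features become :class:`pandas.Categorical` columns over their declared
levels.  Two clinically motivated recodings are applied on the way:

* a raw age-in-years feature is banded into ``<= 45``, ``45 to 65`` and
  ``> 65`` (age 45 falls in the first band, age 65 in the second, so the
  bands partition the axis);
* a raw race feature is collapsed to four classes — White, Black/African
  American, Asian, and multiple/others — with every other recorded label
  mapped to multiple/others.

The encoded frame is the model-ready matrix: the mixture estimator reads
feature kinds off the column dtypes (float = continuous, categorical =
discrete).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CohortError
from .schema import Feature, FeatureSchema

AGE_BANDS = ("<= 45", "45 to 65", "> 65")
RACE_CLASSES = ("White", "Black/African American", "Asian", "multiple/others")


def band_age(age_years: float) -> str:
    """Age in years -> age band; 45 and 65 go to the lower band."""
    if not np.isfinite(age_years) or age_years < 0:
        raise CohortError(f"invalid age: {age_years!r}")
    if age_years <= 45:
        return AGE_BANDS[0]
    if age_years <= 65:
        return AGE_BANDS[1]
    return AGE_BANDS[2]


def collapse_race(label: str) -> str:
    """Raw race label -> one of the four modelling classes."""
    return label if label in RACE_CLASSES[:3] else RACE_CLASSES[3]


class CohortEncoder(BaseEstimator, TransformerMixin):
    """Transformer from a complete, schema-valid cohort to a model matrix.

    Parameters
    ----------
    schema : FeatureSchema
        Declarations for every column of the cohorts to be transformed.
    age_feature, race_feature : str
        Names of the raw age (continuous, years) and race (categorical)
        features to recode.  Either may be absent from the schema, or
        already supplied in banded/collapsed form, in which case the
        corresponding recode is a no-op.
    """

    def __init__(self, schema: FeatureSchema, age_feature: str = "age", race_feature: str = "race"):
        self.schema = schema
        self.age_feature = age_feature
        self.race_feature = race_feature

    def fit(self, X: pd.DataFrame, y=None):
        self.feature_names_in_ = list(X.columns)
        self.encoded_schema_ = self._encoded_schema(X.columns)
        return self

    def _encoded_schema(self, columns) -> FeatureSchema:
        feats = []
        for name in columns:
            feat = self.schema[name]
            if name == self.age_feature and feat.is_numeric:
                feat = Feature(name, "categorical", feat.group, AGE_BANDS, units="age band")
            elif name == self.race_feature and not feat.is_numeric:
                feat = Feature(name, "categorical", feat.group, RACE_CLASSES, units=feat.units)
            feats.append(feat)
        return FeatureSchema(feats)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if X.isna().any().any():
            raise CohortError("cohort has missing values; drop incomplete patients first")
        out = {}
        for name in X.columns:
            feat = self.schema[name]
            col = X[name]
            if name == self.age_feature and feat.is_numeric:
                banded = col.astype(float).map(band_age)
                out[name] = pd.Categorical(banded, categories=AGE_BANDS)
            elif name == self.race_feature and not feat.is_numeric:
                bad = ~col.isin(feat.levels)
                if bad.any():
                    raise CohortError(f"race values outside schema levels: {col[bad].unique()}")
                out[name] = pd.Categorical(col.map(collapse_race), categories=RACE_CLASSES)
            elif feat.is_numeric:
                out[name] = col.astype(float).to_numpy()
            else:
                bad = ~col.isin(feat.levels)
                if bad.any():
                    raise CohortError(
                        f"values outside declared levels in {name!r}: {col[bad].unique()}"
                    )
                out[name] = pd.Categorical(col, categories=feat.levels)
        return pd.DataFrame(out, index=X.index)


def encode_features(cohort: pd.DataFrame, schema: FeatureSchema, **kwargs) -> pd.DataFrame:
    """Functional one-shot form of :class:`CohortEncoder`."""
    return CohortEncoder(schema, **kwargs).fit(cohort).transform(cohort)


def decode_levels(encoded: pd.DataFrame) -> pd.DataFrame:
    """Inverse of the categorical encoding: categorical codes back to labels.

    Continuous columns and the age/race recodings are left as-is (banding
    and collapsing are lossy by design); this exists to check that level
    labels round-trip through :class:`pandas.Categorical`.
    """
    out = {}
    for name in encoded.columns:
        col = encoded[name]
        out[name] = col.astype(object) if isinstance(col.dtype, pd.CategoricalDtype) else col
    return pd.DataFrame(out, index=encoded.index)
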