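"""Synthetic cohort generator with latent-phenotype structure.

The generator emulates the baseline table of a pooled biologic-naive PsA
trial population: five latent phenotypes with fixed mixing proportions,
per-phenotype Gaussian continuous features (joint counts truncated and
rounded to integers) and per-phenotype categorical level frequencies, all
parameterized from the published stratified baseline-characteristics
table.  Within a phenotype, features are drawn independently — the same
conditional-independence model the mixture estimator fits — so parameter
recovery is well-posed.

On top of the clean table the generator plants the artefacts the cleaning
pipeline must handle: a sparse per-feature missingness, one feature with
heavy (>20%) missingness, and exact duplicate columns that trip the
collinearity screen.

A second stage simulates follow-up visits: per patient and week, endpoint
components improve from baseline by phenotype-specific Beta-distributed
improvement fractions on a saturating week ramp, with visit-level
missingness attributed to a reason (pandemic/geopolitical disruption,
other, or absorbing dropout).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .schema import Feature, FeatureSchema

# ---------------------------------------------------------------------------
# phenotype parameterization (five components, ordered by frequency)
# ---------------------------------------------------------------------------

#: mixing proportions: Moderate-to-High Disease Activity, Enthesitis and
#: Large Joints Dominant, Very High Disease Activity, Hand Dominant,
#: Dactylitis and Feet Dominant
DEFAULT_WEIGHTS = (0.403, 0.208, 0.140, 0.138, 0.111)

PHENOTYPE_NAMES = (
    "Moderate to High Disease Activity",
    "Enthesitis and Large Joints Dominant",
    "Very High Disease Activity",
    "Hand Dominant",
    "Dactylitis and Feet Dominant",
)


@dataclass(frozen=True)
class ContinuousSpec:
    """Per-phenotype Gaussian parameters for one continuous feature."""

    name: str
    group: str
    means: tuple[float, ...]
    sds: tuple[float, ...]
    lower: float = 0.0
    upper: float | None = None
    integer: bool = False
    units: str = ""


@dataclass(frozen=True)
class CategoricalSpec:
    """Per-phenotype level frequencies for one categorical feature."""

    name: str
    group: str
    levels: tuple[str, ...]
    probs: tuple[tuple[float, ...], ...]   # (K, L)

    @property
    def kind(self) -> str:
        return "binary" if len(self.levels) == 2 else "categorical"


def _freq(*counts_by_level: tuple[float, ...]) -> tuple[tuple[float, ...], ...]:
    """Transpose per-level phenotype counts into per-phenotype frequencies."""
    arr = np.asarray(counts_by_level, dtype=float)   # (L, K)
    return tuple(tuple(col / col.sum()) for col in arr.T)


# Continuous features: per-phenotype mean (SD) from the stratified
# baseline table.  Joint counts are integer-valued and bounded.
DEFAULT_CONTINUOUS = (
    ContinuousSpec(
        "tjc68", "tender-joint",
        means=(10.1, 20.0, 46.6, 25.3, 24.7), sds=(3.3, 7.2, 9.8, 7.0, 8.4),
        lower=0, upper=68, integer=True, units="tender joints (0-68)",
    ),
    ContinuousSpec(
        "sjc66", "swollen-joint",
        means=(7.4, 10.1, 24.0, 15.0, 15.5), sds=(2.1, 4.0, 11.3, 5.5, 7.9),
        lower=0, upper=66, integer=True, units="swollen joints (0-66)",
    ),
    ContinuousSpec(
        "pain_vas", "other",
        means=(52.6, 57.7, 66.5, 59.0, 54.8), sds=(23.0, 21.6, 19.7, 20.3, 23.9),
        lower=0, upper=100, units="mm VAS",
    ),
)

# Per-location joint-involvement binaries.  The published feature list
# includes tender/swollen involvement by joint alongside the summary
# counts; the generator uses one binary per anatomical region, with
# frequencies encoding the phenotype descriptions (hand-dominant disease
# concentrated in hands/wrists, feet-dominant in ankles/feet, the
# enthesitis phenotype in large joints, very-high activity everywhere).
_TENDER_REGION_PROBS = {
    "hand": (0.45, 0.40, 0.95, 0.98, 0.30),
    "wrist": (0.35, 0.40, 0.90, 0.85, 0.30),
    "elbow": (0.15, 0.55, 0.80, 0.30, 0.20),
    "shoulder": (0.15, 0.60, 0.85, 0.30, 0.20),
    "knee": (0.40, 0.75, 0.90, 0.35, 0.45),
    "ankle": (0.30, 0.50, 0.85, 0.25, 0.80),
    "foot": (0.40, 0.35, 0.90, 0.30, 0.95),
}
_SWOLLEN_REGION_PROBS = {
    "hand": (0.40, 0.30, 0.90, 0.95, 0.25),
    "wrist": (0.30, 0.35, 0.85, 0.80, 0.25),
    "elbow": (0.10, 0.45, 0.70, 0.25, 0.15),
    "shoulder": (0.10, 0.50, 0.75, 0.25, 0.15),
    "knee": (0.35, 0.70, 0.85, 0.30, 0.40),
    "ankle": (0.25, 0.45, 0.80, 0.20, 0.75),
    "foot": (0.35, 0.30, 0.85, 0.25, 0.92),
}

_JOINT_BINARIES = tuple(
    CategoricalSpec(
        f"tender_{region}", "tender-joint", ("no", "yes"),
        probs=tuple((1 - p, p) for p in probs),
    )
    for region, probs in _TENDER_REGION_PROBS.items()
) + tuple(
    CategoricalSpec(
        f"swollen_{region}", "swollen-joint", ("no", "yes"),
        probs=tuple((1 - p, p) for p in probs),
    )
    for region, probs in _SWOLLEN_REGION_PROBS.items()
)

# Categorical features: per-phenotype counts from the stratified baseline
# table, normalised to frequencies; dactylitis/psoriasis location
# binaries are part of the published feature list but not tabulated, so
# their frequencies follow the phenotype descriptions.
DEFAULT_CATEGORICAL = _JOINT_BINARIES + (
    CategoricalSpec(
        "bsa_band", "psoriasis", ("0", "<3", "3-10", ">=10"),
        probs=_freq(
            (20, 14, 5, 8, 9),
            (170, 107, 65, 54, 39),
            (155, 64, 43, 56, 39),
            (106, 48, 44, 36, 37),
        ),
    ),
    CategoricalSpec(
        "spondylitis", "psoriasis", ("no", "yes"),
        probs=tuple((1 - p, p) for p in (0.182, 0.167, 0.223, 0.143, 0.290)),
    ),
    CategoricalSpec(
        "dactylitis", "dactylitis", ("no", "yes"),
        probs=tuple((1 - p, p) for p in (0.184, 0.210, 0.471, 0.266, 0.605)),
    ),
    CategoricalSpec(
        "dactylitis_hands", "dactylitis", ("no", "yes"),
        probs=tuple((1 - p, p) for p in (0.10, 0.12, 0.30, 0.22, 0.25)),
    ),
    CategoricalSpec(
        "dactylitis_feet", "dactylitis", ("no", "yes"),
        probs=tuple((1 - p, p) for p in (0.10, 0.12, 0.30, 0.10, 0.52)),
    ),
    CategoricalSpec(
        "psoriasis_head", "psoriasis", ("no", "yes"),
        probs=tuple((1 - p, p) for p in (0.55, 0.52, 0.60, 0.52, 0.58)),
    ),
    CategoricalSpec(
        "psoriasis_trunk", "psoriasis", ("no", "yes"),
        probs=tuple((1 - p, p) for p in (0.50, 0.48, 0.55, 0.48, 0.54)),
    ),
    CategoricalSpec(
        "psoriasis_upper", "psoriasis", ("no", "yes"),
        probs=tuple((1 - p, p) for p in (0.60, 0.57, 0.65, 0.58, 0.62)),
    ),
    CategoricalSpec(
        "psoriasis_lower", "psoriasis", ("no", "yes"),
        probs=tuple((1 - p, p) for p in (0.62, 0.60, 0.68, 0.60, 0.66)),
    ),
    CategoricalSpec(
        "enthesitis_band", "enthesitis", ("0", "1-5", "6-16"),
        probs=_freq(
            (244, 3, 7, 44, 29),
            (203, 73, 22, 81, 76),
            (4, 157, 128, 29, 19),
        ),
    ),
    CategoricalSpec(
        "crp_band", "other", ("<1", "1-3", "3-10", ">=10"),
        probs=_freq(
            (55, 15, 17, 10, 5),
            (84, 60, 30, 41, 28),
            (194, 93, 69, 64, 44),
            (118, 65, 41, 39, 47),
        ),
    ),
    CategoricalSpec(
        "duration_band", "other", ("<2", "2-5", "5-10", ">=10"),
        probs=_freq(
            (136, 59, 42, 38, 29),
            (120, 71, 36, 37, 43),
            (104, 57, 33, 39, 27),
            (91, 46, 46, 40, 25),
        ),
    ),
    CategoricalSpec(
        "sex", "demographic", ("male", "female"),
        probs=tuple((1 - p, p) for p in (0.443, 0.622, 0.599, 0.545, 0.363)),
    ),
    CategoricalSpec(
        "age_band", "demographic", ("<= 45", "45 to 65", "> 65"),
        probs=_freq(
            (176, 73, 35, 46, 57),
            (220, 124, 100, 84, 62),
            (55, 36, 22, 24, 5),
        ),
    ),
    CategoricalSpec(
        "bmi_band", "demographic", ("<25", "25-30", ">=30"),
        probs=_freq(
            (84, 33, 24, 22, 32),
            (184, 66, 45, 68, 43),
            (183, 134, 88, 64, 49),
        ),
    ),
    CategoricalSpec(
        "race", "demographic",
        ("White", "Black/African American", "Asian", "multiple/others"),
        probs=tuple((0.75, 0.05, 0.12, 0.08) for _ in range(5)),
    ),
)

# A fatigue score carried with heavy missingness, so the cleaning pipeline
# always has a >20%-missing feature to exclude.
HIGH_MISSING_FEATURE = ContinuousSpec(
    "facit_f", "other",
    means=(32.0, 30.0, 25.0, 29.0, 30.0), sds=(9.0, 9.0, 9.0, 9.0, 9.0),
    lower=0, upper=52, units="FACIT-F (0-52)",
)


@dataclass
class GeneratorConfig:
    """Baseline-cohort generator configuration.

    Defaults reproduce the published five-phenotype baseline structure:
    mixing weights and the per-phenotype continuous/categorical parameters
    above, a base per-feature missing rate calibrated so that roughly
    93.6% of patients are complete on the final feature set, one feature
    with 25% missingness, and three exact duplicate columns.
    """

    n_patients: int = 1119
    weights: tuple[float, ...] = DEFAULT_WEIGHTS
    continuous: tuple[ContinuousSpec, ...] = DEFAULT_CONTINUOUS
    categorical: tuple[CategoricalSpec, ...] = DEFAULT_CATEGORICAL
    base_missing_rate: float = 0.002
    missing_rates: dict = field(default_factory=dict)   # per-feature overrides
    high_missing: ContinuousSpec | None = HIGH_MISSING_FEATURE
    high_missing_rate: float = 0.25
    collinear_duplicates: tuple[str, ...] = ("tjc68", "sjc66", "pain_vas")
    seed: int = 0

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def validate(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("mixing weights must sum to 1")
        K = len(w)
        for spec in self.continuous:
            if len(spec.means) != K or len(spec.sds) != K:
                raise ValueError(f"{spec.name}: needs {K} per-phenotype parameters")
            if any(sd <= 0 for sd in spec.sds):
                raise ValueError(f"{spec.name}: SDs must be positive")
        for spec in self.categorical:
            probs = np.asarray(spec.probs, dtype=float)
            if probs.shape != (K, len(spec.levels)):
                raise ValueError(f"{spec.name}: probs must be ({K}, {len(spec.levels)})")
            if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError(f"{spec.name}: level probabilities must sum to 1")
        if self.n_patients < K:
            raise ValueError("n_patients must be at least the number of components")

    def schema(self) -> FeatureSchema:
        """Schema of the generated table, duplicates placed right after
        their source so the keep-first collinearity rule removes them."""
        feats: list[Feature] = []
        for spec in self.continuous:
            feats.append(Feature(spec.name, "continuous", spec.group, units=spec.units))
            if spec.name in self.collinear_duplicates:
                feats.append(
                    Feature(f"{spec.name}_v2", "continuous", spec.group, units=spec.units)
                )
        for spec in self.categorical:
            feats.append(Feature(spec.name, spec.kind, spec.group, tuple(spec.levels)))
            if spec.name in self.collinear_duplicates:
                feats.append(
                    Feature(f"{spec.name}_v2", spec.kind, spec.group, tuple(spec.levels))
                )
        if self.high_missing is not None:
            feats.append(
                Feature(
                    self.high_missing.name, "continuous", self.high_missing.group,
                    units=self.high_missing.units,
                )
            )
        return FeatureSchema(feats)


def _draw_continuous(spec: ContinuousSpec, z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    means = np.asarray(spec.means)[z]
    sds = np.asarray(spec.sds)[z]
    vals = rng.normal(means, sds)
    vals = np.clip(vals, spec.lower, spec.upper if spec.upper is not None else np.inf)
    if spec.integer:
        vals = np.rint(vals)
    return vals


def generate_baseline(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a baseline cohort and its ground-truth phenotype labels.

    Returns the cohort table (with planted missingness and duplicate
    columns) indexed by patient id, and a ``truth`` series of latent
    component labels recorded before any corruption is applied.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, K = config.n_patients, config.n_components

    z = rng.choice(K, size=n, p=np.asarray(config.weights))
    ids = pd.Index([f"P{i:05d}" for i in range(n)], name="patient_id")
    truth = pd.Series(z, index=ids, name="component")

    cols: dict[str, np.ndarray] = {}
    for spec in config.continuous:
        cols[spec.name] = _draw_continuous(spec, z, rng)
    for spec in config.categorical:
        probs = np.asarray(spec.probs)
        u = rng.random(n)
        codes = (u[:, None] > probs.cumsum(axis=1)[z]).sum(axis=1)
        cols[spec.name] = np.asarray(spec.levels, dtype=object)[codes]
    if config.high_missing is not None:
        cols[config.high_missing.name] = _draw_continuous(config.high_missing, z, rng)

    cohort = pd.DataFrame(cols, index=ids)

    # corruption after truth is recorded: sparse missingness, then the
    # heavy-missing feature, then exact duplicate columns
    for name in cohort.columns:
        if config.high_missing is not None and name == config.high_missing.name:
            rate = config.high_missing_rate
        else:
            rate = config.missing_rates.get(name, config.base_missing_rate)
        if rate > 0:
            mask = rng.random(n) < rate
            cohort.loc[mask, name] = np.nan

    for src in config.collinear_duplicates:
        if src not in cohort.columns:
            raise ValueError(f"collinear duplicate source {src!r} not generated")
        cohort[f"{src}_v2"] = cohort[src]

    return cohort[config.schema().names], truth


# ---------------------------------------------------------------------------
# longitudinal visits
# ---------------------------------------------------------------------------

FOLLOWUP_WEEKS = (12, 24, 52, 100, 196)

#: fraction of the asymptotic response realised by each follow-up week
DEFAULT_RAMP = {12: 0.60, 24: 0.75, 52: 0.85, 100: 0.92, 196: 0.97}


@dataclass
class LongitudinalConfig:
    """Visit-response simulator configuration.

    Improvement in counts, pain, function and skin is sampled per patient
    and week as a Beta-distributed fraction of the baseline value with a
    phenotype-specific asymptote (``*_asym``) on a saturating week ramp;
    fatigue improves additively (``facit_gain`` points at the asymptote).
    The asymptotes are calibrated once so that week-196 responder rates
    land in a clinically plausible range (week-196 minimal-disease-activity
    rates by phenotype bracketing roughly 43-59%).
    """

    weeks: tuple[int, ...] = FOLLOWUP_WEEKS
    ramp: dict = field(default_factory=lambda: dict(DEFAULT_RAMP))
    count_asym: tuple[float, ...] = (0.87, 0.90, 0.90, 0.90, 0.91)
    pain_asym: tuple[float, ...] = (0.69, 0.71, 0.82, 0.74, 0.76)
    haq_asym: tuple[float, ...] = (0.61, 0.64, 0.78, 0.68, 0.70)
    bsa_asym: tuple[float, ...] = (0.80, 0.83, 0.90, 0.84, 0.86)
    enthes_asym: tuple[float, ...] = (0.84, 0.85, 0.92, 0.88, 0.88)
    crp_asym: tuple[float, ...] = (0.70, 0.68, 0.66, 0.68, 0.70)
    facit_gain: tuple[float, ...] = (7.0, 8.0, 10.0, 8.0, 8.0)
    beta_concentration: float = 10.0
    covid_geo_rate: float = 0.02
    other_rate: float = 0.03
    dropout_rate: float = 0.015
    seed: int = 0

    def validate(self) -> None:
        if list(self.weeks) != sorted(set(self.weeks)):
            raise ValueError("weeks must be strictly increasing")
        rates = (self.covid_geo_rate, self.other_rate, self.dropout_rate)
        if any(not 0 <= r <= 1 for r in rates) or sum(rates) > 1:
            raise ValueError("missingness-reason rates must lie in [0,1] and sum to <= 1")
        for w in self.weeks:
            if w not in self.ramp:
                raise ValueError(f"week {w} has no ramp entry")


VISIT_COLUMNS = [
    "patient_id", "week", "tjc68", "sjc66", "pain", "patient_global",
    "physician_global", "haq_di", "facit_f", "crp", "bsa",
    "entheseal_points", "missing_reason",
]

_BSA_DRAW = {"0": (0.0, 0.0), "<3": (0.1, 3.0), "3-10": (3.0, 10.0), ">=10": (10.0, 40.0)}
_CRP_DRAW = {"<1": (0.1, 1.0), "1-3": (1.0, 3.0), "3-10": (3.0, 10.0), ">=10": (10.0, 40.0)}
_ENTH_DRAW = {"0": (0, 0), "1-5": (1, 5), "6-16": (6, 16)}

_HAQ_MEANS = (1.1, 1.3, 1.6, 1.4, 1.3)
_FACIT_MEANS = (32.0, 30.0, 25.0, 29.0, 30.0)


def _beta_frac(mean: np.ndarray, conc: float, rng: np.random.Generator) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    clipped = np.clip(mean, 1e-3, 1 - 1e-3)
    draws = rng.beta(clipped * conc, (1 - clipped) * conc)
    # degenerate limits are honoured exactly (improvement forced to 0 or 1)
    return np.where(mean >= 1.0, 1.0, np.where(mean <= 0.0, 0.0, draws))


def _baseline_components(
    cohort: pd.DataFrame, z: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Week-0 endpoint components, derived from the baseline table where
    available and drawn from phenotype-typical distributions otherwise."""
    n = len(cohort)

    def col_or_mean(name: str, spec_means) -> np.ndarray:
        if name in cohort.columns:
            vals = cohort[name].astype(float).to_numpy()
            means = np.asarray(spec_means)[z]
            return np.where(np.isfinite(vals), vals, means)
        return np.asarray(spec_means)[z]

    tjc = col_or_mean("tjc68", (10.1, 20.0, 46.6, 25.3, 24.7))
    sjc = col_or_mean("sjc66", (7.4, 10.1, 24.0, 15.0, 15.5))
    pain = col_or_mean("pain_vas", (52.6, 57.7, 66.5, 59.0, 54.8))

    def band_draw(name: str, table: dict, integer=False) -> np.ndarray:
        out = np.zeros(n)
        if name in cohort.columns:
            bands = cohort[name].astype(object)
            for label, (lo, hi) in table.items():
                mask = (bands == label).to_numpy()
                if integer:
                    out[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
                else:
                    out[mask] = rng.uniform(lo, hi, size=int(mask.sum()))
            miss = bands.isna().to_numpy()
            if miss.any():
                lo, hi = list(table.values())[1]
                out[miss] = rng.uniform(lo, hi, size=int(miss.sum()))
        else:
            lo, hi = list(table.values())[1]
            out[:] = rng.uniform(lo, hi, size=n)
        return out

    base = pd.DataFrame(index=cohort.index)
    base["tjc68"] = tjc
    base["sjc66"] = sjc
    base["pain"] = pain
    base["patient_global"] = np.clip(pain + rng.normal(0, 8, n), 0, 100)
    base["physician_global"] = np.clip(0.8 * pain + rng.normal(0, 10, n), 0, 100)
    base["haq_di"] = np.round(np.clip(rng.normal(np.asarray(_HAQ_MEANS)[z], 0.55), 0, 3), 3)
    if "facit_f" in cohort.columns:
        vals = cohort["facit_f"].astype(float).to_numpy()
        fall = np.clip(rng.normal(np.asarray(_FACIT_MEANS)[z], 9.0), 0, 52)
        base["facit_f"] = np.where(np.isfinite(vals), vals, fall)
    else:
        base["facit_f"] = np.clip(rng.normal(np.asarray(_FACIT_MEANS)[z], 9.0), 0, 52)
    base["crp"] = band_draw("crp_band", _CRP_DRAW)
    base["bsa"] = band_draw("bsa_band", _BSA_DRAW)
    base["entheseal_points"] = band_draw("enthesitis_band", _ENTH_DRAW, integer=True)
    return base


def generate_visits(
    cohort: pd.DataFrame,
    truth: pd.Series,
    config: LongitudinalConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the longitudinal visit table for a generated cohort.

    Week 0 is always present and complete.  At each follow-up week every
    still-enrolled patient either attends (components simulated from the
    phenotype-specific response model) or is missing with a recorded
    reason; dropout is absorbing.  Rows with a non-``none`` reason carry no
    component values.
    """
    config = config or LongitudinalConfig()
    config.validate()
    if not cohort.index.equals(truth.index):
        raise ValueError("cohort and truth labels are not aligned")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    z = truth.to_numpy()
    n = len(cohort)

    base = _baseline_components(cohort, z, rng)
    rows: list[pd.DataFrame] = []
    week0 = base.copy()
    week0.insert(0, "week", 0)
    week0["missing_reason"] = "none"
    rows.append(week0.reset_index())

    conc = config.beta_concentration
    dropped = np.zeros(n, dtype=bool)
    for week in config.weeks:
        ramp = config.ramp[week]
        reason = np.full(n, "none", dtype=object)
        u = rng.random(n)
        r1 = config.covid_geo_rate
        r2 = r1 + config.other_rate
        r3 = r2 + config.dropout_rate
        reason[u < r1] = "covid_geo"
        reason[(u >= r1) & (u < r2)] = "other"
        newly_dropped = (u >= r2) & (u < r3)
        dropped |= newly_dropped
        reason[dropped] = "dropout"

        def asym(values) -> np.ndarray:
            return np.asarray(values)[z] * ramp

        f_cnt_t = _beta_frac(asym(config.count_asym), conc, rng)
        f_cnt_s = _beta_frac(asym(config.count_asym), conc, rng)
        f_pain = _beta_frac(asym(config.pain_asym), conc, rng)
        f_pga = _beta_frac(asym(config.pain_asym), conc, rng)
        f_phys = _beta_frac(asym(config.pain_asym), conc, rng)
        f_haq = _beta_frac(asym(config.haq_asym), conc, rng)
        f_bsa = _beta_frac(asym(config.bsa_asym), conc, rng)
        f_enth = _beta_frac(asym(config.enthes_asym), conc, rng)
        f_crp = _beta_frac(asym(config.crp_asym), conc, rng)

        visit = pd.DataFrame(index=cohort.index)
        visit["week"] = week
        visit["tjc68"] = np.rint(base["tjc68"] * (1 - f_cnt_t))
        visit["sjc66"] = np.rint(base["sjc66"] * (1 - f_cnt_s))
        visit["pain"] = np.clip(base["pain"] * (1 - f_pain) + rng.normal(0, 4, n), 0, 100)
        visit["patient_global"] = np.clip(
            base["patient_global"] * (1 - f_pga) + rng.normal(0, 4, n), 0, 100
        )
        visit["physician_global"] = np.clip(
            base["physician_global"] * (1 - f_phys) + rng.normal(0, 4, n), 0, 100
        )
        visit["haq_di"] = np.clip(base["haq_di"] * (1 - f_haq) + rng.normal(0, 0.1, n), 0, 3)
        gain = np.asarray(config.facit_gain)[z] * ramp + rng.normal(0, 3, n)
        visit["facit_f"] = np.clip(base["facit_f"] + gain, 0, 52)
        visit["crp"] = np.maximum(base["crp"] * (1 - f_crp) + rng.normal(0, 0.3, n), 0.1)
        visit["bsa"] = np.clip(base["bsa"] * (1 - f_bsa), 0, 100)
        visit["entheseal_points"] = np.rint(base["entheseal_points"] * (1 - f_enth))
        visit["missing_reason"] = reason
        missing = reason != "none"
        visit.loc[missing, visit.columns.difference(["week", "missing_reason"])] = np.nan
        rows.append(visit.reset_index())

    visits = pd.concat(rows, ignore_index=True)
    return visits[VISIT_COLUMNS]
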