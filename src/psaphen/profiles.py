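"""Per-phenotype descriptive statistics and heatmap ordering.

`cluster_profile` builds the stratified baseline-characteristics summary
(the "Table 1" of a clustering report): per cluster, its size and share
of the cohort, mean (SD) for continuous features and n (%) per level for
categorical ones.  Selected continuous features can be summarised
conditionally on a paired positivity indicator (e.g., dactylitic joint
count among patients with any dactylitis), mirroring how involvement
scores are reported only among the involved.

`heatmap_order` gives the display permutation for cluster-ordered
heatmaps: patients by cluster then by how confidently they belong to it,
features by clinical group then name.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import GROUP_ORDER, FeatureSchema


@dataclass
class PhenotypeProfile:
    """Nested per-cluster summary; values stored at full precision."""

    clusters: dict[int, dict]
    n_total: int

    def to_json(self, path=None, ndigits: int = 1) -> str:
        def fmt(x):
            if isinstance(x, float):
                return round(x, ndigits) if np.isfinite(x) else None
            return x

        payload = {
            "n_total": self.n_total,
            "clusters": {
                str(k): _map_nested(v, fmt) for k, v in self.clusters.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: cluster, feature, level, statistic, value."""
        rows = []
        for k, summary in self.clusters.items():
            rows.append((k, "_cluster", "", "n", summary["n"]))
            rows.append((k, "_cluster", "", "pct", summary["pct"]))
            for feat, stats in summary["features"].items():
                for key, val in stats.items():
                    if isinstance(val, dict):
                        for level, v in val.items():
                            rows.append((k, feat, level, key, v))
                    else:
                        rows.append((k, feat, "", key, val))
        return pd.DataFrame(rows, columns=["cluster", "feature", "level", "statistic", "value"])


def _map_nested(obj, fn):
    if isinstance(obj, dict):
        return {k: _map_nested(v, fn) for k, v in obj.items()}
    return fn(obj)


def cluster_profile(
    cohort: pd.DataFrame,
    labels,
    schema: FeatureSchema,
    conditional_specs: dict[str, str] | None = None,
    n_clusters: int | None = None,
) -> PhenotypeProfile:
    """Descriptive statistics per cluster.

    ``conditional_specs`` maps a continuous feature to the name of its
    positivity indicator: the mean (SD) is then computed only over cluster
    members whose indicator is positive (nonzero / "yes").  When no member
    qualifies the statistic is reported absent (NaN), never zero.  Empty
    clusters appear with n = 0 and absent statistics.
    """
    labels = np.asarray(labels)
    if len(labels) != len(cohort):
        raise ValueError("labels not aligned with cohort")
    conditional_specs = conditional_specs or {}
    ks = range(n_clusters) if n_clusters is not None else sorted(np.unique(labels))

    clusters: dict[int, dict] = {}
    for k in ks:
        sub = cohort[labels == k]
        feats: dict[str, dict] = {}
        for feat in schema:
            if feat.name not in cohort.columns:
                continue
            col = sub[feat.name]
            if feat.is_numeric:
                if feat.name in conditional_specs:
                    ind = sub[conditional_specs[feat.name]]
                    positive = _positive_mask(ind)
                    col = col[positive]
                vals = col.dropna().astype(float)
                feats[feat.name] = {
                    "mean": float(vals.mean()) if len(vals) else float("nan"),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                    "n": int(len(vals)),
                }
            else:
                counts = {lvl: int((col == lvl).sum()) for lvl in feat.levels}
                total = sum(counts.values())
                feats[feat.name] = {
                    "n": counts,
                    "pct": {
                        lvl: (100.0 * c / total if total else float("nan"))
                        for lvl, c in counts.items()
                    },
                }
        clusters[int(k)] = {
            "n": int(len(sub)),
            "pct": 100.0 * len(sub) / len(cohort),
            "features": feats,
        }
    return PhenotypeProfile(clusters=clusters, n_total=len(cohort))


def _positive_mask(indicator: pd.Series) -> pd.Series:
    if indicator.dtype.kind in "fiu":
        return indicator.astype(float) > 0
    return indicator.isin(["yes", "Yes", "true", "True", "1"])


def heatmap_order(
    labels,
    responsibilities: np.ndarray,
    schema: FeatureSchema,
    feature_names: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Display ordering for cluster-ordered heatmaps.

    Patients are sorted by cluster label and, within a cluster, by
    descending responsibility for that cluster; features by clinical group
    (tender-joint, swollen-joint, psoriasis, dactylitis, enthesitis,
    other, demographic) then alphabetically.
    """
    labels = np.asarray(labels)
    resp = np.asarray(responsibilities)
    if resp.shape[0] != len(labels):
        raise ValueError("responsibilities not aligned with labels")
    own = resp[np.arange(len(labels)), labels]
    patient_order = np.lexsort((-own, labels))

    names = feature_names if feature_names is not None else schema.names
    rank = {g: i for i, g in enumerate(GROUP_ORDER)}
    feature_order = sorted(names, key=lambda n: (rank[schema[n].group], n))
    return patient_order, feature_order
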