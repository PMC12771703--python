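"""Feature schema for baseline cohort tables.

Every baseline feature is declared up front: its name, measurement kind
(continuous, binary, categorical), the ordered category levels where
applicable, and the clinical feature group it belongs to.  Nothing is
inferred from the data; a table is valid only relative to a schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import yaml

# Clinical feature groups in display order: joint-related groups first,
# then the other disease domains, demographics last.
GROUP_ORDER: tuple[str, ...] = (
    "tender-joint",
    "swollen-joint",
    "psoriasis",
    "dactylitis",
    "enthesitis",
    "other",
    "demographic",
)

KINDS = ("continuous", "binary", "categorical")


@dataclass(frozen=True)
class Feature:
    """A single declared baseline feature."""

    name: str
    kind: str
    group: str
    levels: tuple[str, ...] = ()
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"feature {self.name!r}: unknown kind {self.kind!r}")
        if self.group not in GROUP_ORDER:
            raise ValueError(f"feature {self.name!r}: unknown group {self.group!r}")
        if self.kind == "continuous":
            if self.levels:
                raise ValueError(f"feature {self.name!r}: continuous features have no levels")
        else:
            if len(self.levels) < 2:
                raise ValueError(f"feature {self.name!r}: needs >= 2 levels, got {self.levels}")
            if self.kind == "binary" and len(self.levels) != 2:
                raise ValueError(f"feature {self.name!r}: binary features need exactly 2 levels")
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"feature {self.name!r}: duplicate levels")

    @property
    def is_numeric(self) -> bool:
        return self.kind == "continuous"


class FeatureSchema:
    """Ordered collection of :class:`Feature` declarations.

    The declaration order is meaningful: it drives the deterministic
    keep-first rule when collinear features are dropped, and the column
    order of encoded matrices.
    """

    def __init__(self, features: Iterable[Feature]):
        feats = list(features)
        names = [f.name for f in feats]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names in schema: {dupes}")
        self._features: dict[str, Feature] = {f.name: f for f in feats}

    def __iter__(self) -> Iterator[Feature]:
        return iter(self._features.values())

    def __len__(self) -> int:
        return len(self._features)

    def __contains__(self, name: str) -> bool:
        return name in self._features

    def __getitem__(self, name: str) -> Feature:
        return self._features[name]

    @property
    def names(self) -> list[str]:
        return list(self._features)

    def subset(self, names: Sequence[str]) -> "FeatureSchema":
        """Schema restricted to ``names``, preserving declaration order."""
        keep = set(names)
        return FeatureSchema(f for f in self if f.name in keep)

    def by_group(self) -> dict[str, list[Feature]]:
        out: dict[str, list[Feature]] = {g: [] for g in GROUP_ORDER}
        for f in self:
            out[f.group].append(f)
        return out

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> list[dict]:
        return [
            {
                "name": f.name,
                "kind": f.kind,
                "group": f.group,
                **({"levels": list(f.levels)} if f.levels else {}),
                **({"units": f.units} if f.units else {}),
            }
            for f in self
        ]

    @classmethod
    def from_dict(cls, entries: Sequence[dict]) -> "FeatureSchema":
        return cls(
            Feature(
                name=e["name"],
                kind=e["kind"],
                group=e["group"],
                levels=tuple(e.get("levels", ())),
                units=e.get("units", ""),
            )
            for e in entries
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"features": self.to_dict()}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureSchema":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls.from_dict(payload["features"])
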