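"""Versioned feature schemas and named feature vectors.

A schema fixes the identity and order of every feature a scorer consumes.
Two schemas matter in practice: the full "PB" schema, and the "PS" schema
which is the PB schema minus exactly one named feature (the two scorers of
the consensus are trained on differently-curated data and the PS curation
pipeline drops one input dimension).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import math

__all__ = ["FeatureSchema", "FeatureVector", "SchemaError"]


class SchemaError(ValueError):
    """Feature set does not match the declared schema."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered, named feature universe with optional exclusions.

    ``excluded`` names are dropped from ``feature_names`` at construction,
    so ``feature_names`` is always the effective (post-exclusion) order.
    """

    schema_id: str
    feature_names: tuple[str, ...]
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        names = [n for n in self.feature_names if n not in set(self.excluded)]
        if len(set(names)) != len(names):
            raise SchemaError("feature names must be unique")
        object.__setattr__(self, "feature_names", tuple(names))

    def __len__(self) -> int:
        return len(self.feature_names)

    def __contains__(self, name: str) -> bool:
        return name in set(self.feature_names)

    def subset_schema(self, schema_id: str, drop: Iterable[str]) -> "FeatureSchema":
        """Derive a schema excluding the given features (e.g. PS from PB)."""
        drop = tuple(drop)
        missing = [d for d in drop if d not in self]
        if missing:
            raise SchemaError(f"cannot exclude unknown features: {missing}")
        return FeatureSchema(schema_id, self.feature_names, drop)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"schema_id": self.schema_id,
             "feature_names": list(self.feature_names),
             "excluded": list(self.excluded)}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSchema":
        d = json.loads(Path(path).read_text())
        return cls(d["schema_id"], tuple(d["feature_names"]), tuple(d.get("excluded", ())))


@dataclass
class FeatureVector:
    """Mapping of schema feature names to finite float values."""

    schema: FeatureSchema
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = set(self.schema.feature_names)
        got = set(self.values)
        if got != expected:
            extra, miss = got - expected, expected - got
            raise SchemaError(
                f"feature keys do not match schema {self.schema.schema_id}"
                + (f"; unexpected: {sorted(extra)[:5]}" if extra else "")
                + (f"; missing: {sorted(miss)[:5]}" if miss else "")
            )
        bad = [n for n, v in self.values.items() if not math.isfinite(v)]
        if bad:
            raise SchemaError(f"non-finite feature values: {bad[:5]}")

    def as_array(self):
        import numpy as np
        return np.array([self.values[n] for n in self.schema.feature_names], dtype=float)

    @classmethod
    def from_partial(cls, schema: FeatureSchema, values: Mapping[str, float]) -> "FeatureVector":
        """Build a vector filling schema features absent from `values` with 0."""
        full = {n: float(values.get(n, 0.0)) for n in schema.feature_names}
        return cls(schema, full)
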