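"""Training-set curation: pose labelling by RMSD and max-abs feature scaling.

Redocked poses of a crystal ligand are labelled against the crystal
reference by heavy-atom RMSD (no superposition — docked poses share the
receptor frame): poses at or below the positive cutoff (2.0, 2.5 or 3.0 Å
depending on the tolerance profile) are positives, poses at or above 4.0 Å
are low-quality negatives, and the ambiguous band in between is discarded.
Negatives additionally include property-matched topology decoys, capped per
target with seeded sampling.

Features are scaled by per-column maximum absolute value fitted on training
rows only, which maps training values into [-1, 1] while preserving sign
and skew — boosted trees are insensitive to monotone rescaling, but a
shared scaler keeps the two consensus scorers' inputs commensurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .structio import MolecularStructure, PoseSet

__all__ = [
    "LabeledExample",
    "ScalerState",
    "TrainingSet",
    "rmsd",
    "label_poses",
    "assemble_training_set",
    "compute_scale_pos_weight",
    "fit_maxabs",
    "apply_maxabs",
]

Provenance = Literal["crystal", "redock_pos", "redock_lowq", "decoy"]

NEGATIVE_RMSD_CUTOFF = 4.0
POSITIVE_RMSD_CUTOFFS = (2.0, 2.5, 3.0)


@dataclass
class LabeledExample:
    """One training row: a pose (or decoy) with its binary label."""

    pose_id: str
    label: int
    provenance: Provenance
    rmsd: float | None = None
    weight: float = 1.0
    features: object = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


def rmsd(pose_a: MolecularStructure, pose_b: MolecularStructure) -> float:
    """Heavy-atom RMSD between two poses of the same molecule, in Å.

    Hydrogens (polar or not) are ignored.  Atoms correspond by canonical
    order; no superposition is applied, since docked poses live in the
    receptor's fixed frame.
    """
    ha, hb = pose_a.heavy_atoms(), pose_b.heavy_atoms()
    if len(ha) != len(hb):
        raise ValueError(
            f"heavy-atom count mismatch: {len(ha)} vs {len(hb)}")
    xa = np.array([a.coords for a in ha])
    xb = np.array([a.coords for a in hb])
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def label_poses(poses: PoseSet, reference: MolecularStructure,
                pos_cutoff: float = 2.0,
                neg_cutoff: float = NEGATIVE_RMSD_CUTOFF,
                include_reference: bool = True) -> list[LabeledExample]:
    """Label each redocked pose positive/negative/discarded by RMSD.

    RMSD ≤ ``pos_cutoff`` → label 1 (provenance ``redock_pos``);
    RMSD ≥ ``neg_cutoff`` → label 0 (``redock_lowq``); strictly between →
    dropped.  The crystal reference itself is emitted as a positive
    (``crystal``) when ``include_reference``.
    """
    if not pos_cutoff < neg_cutoff:
        raise ValueError("pos_cutoff must be below neg_cutoff")
    out: list[LabeledExample] = []
    if include_reference:
        out.append(LabeledExample(f"{poses.compound_id}_xtal", 1, "crystal", 0.0))
    for pose in poses.poses:
        r = rmsd(pose.ligand, reference)
        pid = pose.pose_id or f"{poses.compound_id}_pose{pose.pose_rank}"
        if r <= pos_cutoff:
            out.append(LabeledExample(pid, 1, "redock_pos", r))
        elif r >= neg_cutoff:
            out.append(LabeledExample(pid, 0, "redock_lowq", r))
        # ambiguous band: neither near-native nor clearly wrong — dropped
    return out


@dataclass
class TrainingSet:
    """Scaled feature matrix with labels and per-row weights."""

    X: np.ndarray
    y: np.ndarray
    weights: np.ndarray
    schema_id: str
    feature_names: tuple[str, ...] = ()
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")
        if np.isnan(self.X).any():
            raise ValueError("training features contain missing values")
        if len(self.y) < 2 or len(np.unique(self.y)) < 2:
            raise ValueError("training set needs both classes present")

    @property
    def imbalance_ratio(self) -> float:
        pos = int(self.y.sum())
        return (len(self.y) - pos) / pos


def assemble_training_set(positives: pd.DataFrame,
                          topology_decoys: pd.DataFrame | None = None,
                          lowq_poses: pd.DataFrame | None = None,
                          decoys_per_target_cap: int = 150,
                          seed: int = 42) -> pd.DataFrame:
    """Merge positives with the mixed negative pool, capping decoys per target.

    Each frame needs columns ``pose_id``, ``label``, ``provenance`` and, for
    decoys, ``target_id``; feature columns are carried through.  Topology
    decoys are truncated to at most ``decoys_per_target_cap`` per target by
    seeded sampling.  Returns the merged table with an ``imbalance_ratio``
    attribute in ``.attrs``.
    """
    if decoys_per_target_cap < 0:
        raise ValueError("cap must be non-negative")
    n_pos = int((positives["label"] == 1).sum())
    if n_pos == 0:
        raise ValueError("degenerate training set: zero positive examples")
    parts = [positives]
    if topology_decoys is not None and len(topology_decoys) and decoys_per_target_cap > 0:
        rng = np.random.default_rng(seed)
        kept = []
        for target, grp in topology_decoys.groupby("target_id", sort=True):
            if len(grp) > decoys_per_target_cap:
                idx = rng.choice(len(grp), size=decoys_per_target_cap, replace=False)
                grp = grp.iloc[np.sort(idx)]
            kept.append(grp)
        parts.append(pd.concat(kept, ignore_index=True))
    if lowq_poses is not None and len(lowq_poses):
        parts.append(lowq_poses)
    merged = pd.concat(parts, ignore_index=True)
    n_neg = int((merged["label"] == 0).sum())
    merged.attrs["imbalance_ratio"] = n_neg / n_pos
    return merged


def compute_scale_pos_weight(labels: Sequence[int] | np.ndarray) -> float:
    """Positive-class weight (n_neg / n_pos) that balances total class mass."""
    y = np.asarray(labels)
    pos = float(y.sum())
    if pos == 0:
        raise ZeroDivisionError(
            "scale_pos_weight undefined: no positive labels in y")
    return (len(y) - pos) / pos


@dataclass
class ScalerState:
    """Fitted per-feature max-absolute scale factors."""

    scales: dict[str, float]
    schema_id: str = ""

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.scales.items() if v < 0}
        if bad:
            raise ValueError(f"negative scale factors: {list(bad)[:5]}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"schema_id": self.schema_id, "scales": self.scales}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalerState":
        d = json.loads(Path(path).read_text())
        return cls(d["scales"], d["schema_id"])


def fit_maxabs(features: pd.DataFrame, schema_id: str = "") -> ScalerState:
    """Fit per-column max-absolute scales on training rows only.

    Zero-variance (all-zero) columns get scale 1 so scaling stays invertible
    and never divides by zero.
    """
    scales = {}
    for col in features.columns:
        m = float(np.max(np.abs(features[col].to_numpy(dtype=float)))) if len(features) else 0.0
        scales[col] = m if m > 0 else 1.0
    return ScalerState(scales, schema_id)


def apply_maxabs(features: pd.DataFrame, state: ScalerState) -> pd.DataFrame:
    """Divide each column by its fitted max-abs value (sign preserved).

    Unseen values may scale outside [-1, 1]; that is intentional — the
    transform is linear, not clipping.
    """
    missing = set(features.columns) - set(state.scales)
    if missing:
        raise ValueError(f"scaler has no scale for columns: {sorted(missing)[:5]}")
    out = features.copy()
    for col in out.columns:
        out[col] = out[col].astype(float) / state.scales[col]
    return out
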