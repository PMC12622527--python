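"""Synthetic inputs for every stage of the pipeline.

Three generator families, all pure functions of (spec, seed):

* **Toy 3D complexes** with atoms placed at exact distances and angles, so
  the expected interaction features are computable by hand (one hydrogen
  bond at 1.9 Å, one salt bridge at 3.5 Å, ...).
* **Screening libraries** shaped like a DEKOIS 2.0 target — 40 actives and
  1200 property-matched decoys by default — where actives differ from
  decoys by a planted mean shift (in SD units) on a chosen block of
  informative features and everything else is noise.  The planted block is
  the ground truth that parameter-recovery and attribution tests check.
* **Pose sets** with exactly realised RMSDs: each pose is the reference
  rigidly translated, so the RMSD to the reference equals the translation
  length to machine precision.

These libraries emulate the class geometry and separability structure of
real screens, not their chemistry: features are Gaussian, independent, and
carry no receptor identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .structio import AtomRecord, ComplexPose, MolecularStructure, PoseSet

__all__ = [
    "SyntheticSpec",
    "GeometryError",
    "gen_toy_complex",
    "toy_hbond_complex",
    "gen_screening_library",
    "gen_pose_set",
    "gen_knowledge_pattern_libraries",
]


class GeometryError(ValueError):
    """Directive places two atoms on top of each other."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions of a synthetic screen.

    Defaults copy the DEKOIS 2.0 library geometry (40 actives : 1200
    decoys) so enrichment at 0.5/1/5% has non-degenerate top sets.
    ``effect_size`` is the active-vs-decoy mean shift in SD units on the
    ``n_informative`` features starting at ``informative_offset``.
    """

    seed: int
    n_actives: int = 40
    n_decoys: int = 1200
    n_features: int = 100
    n_informative: int = 5
    informative_offset: int = 0
    effect_size: float = 2.0
    label_noise: float = 0.0
    pose_count: int = 1

    def __post_init__(self) -> None:
        if min(self.n_actives, self.n_decoys, self.n_features, self.pose_count) <= 0:
            raise ValueError("counts must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.informative_offset + self.n_informative > self.n_features:
            raise ValueError("informative block exceeds feature count")

    @property
    def informative_features(self) -> tuple[str, ...]:
        return tuple(f"f{j}" for j in range(
            self.informative_offset, self.informative_offset + self.n_informative))


def _check_overlap(atoms: Sequence[AtomRecord]) -> None:
    pts = np.array([a.coords for a in atoms])
    if len(pts) < 2:
        return
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() < 0.1:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise GeometryError(
            f"atoms {atoms[i].serial} and {atoms[j].serial} overlap "
            f"(d = {d[i, j]:.3f} Å)")


def gen_toy_complex(receptor_atoms: Sequence[tuple[str, tuple[float, float, float], float]],
                    ligand_atoms: Sequence[tuple[str, tuple[float, float, float], float]],
                    pose_rank: int = 1, pose_id: str = "toy") -> ComplexPose:
    """Build a complex from (autodock_type, coords, charge) directives.

    Atom names default to the type token; serials run in directive order.
    Overlapping atoms (< 0.1 Å apart) raise :class:`GeometryError`.
    """
    def build(directives, role, serial0):
        atoms = [AtomRecord(serial0 + k, t, t, tuple(map(float, xyz)), float(q))
                 for k, (t, xyz, q) in enumerate(directives)]
        return MolecularStructure(atoms, role, f"toy_{role}")

    receptor = build(receptor_atoms, "receptor", 1)
    ligand = build(ligand_atoms, "ligand", 1001)
    _check_overlap(list(receptor.atoms) + list(ligand.atoms))
    return ComplexPose(receptor, ligand, pose_rank, pose_id)


def toy_hbond_complex(distance: float = 1.9, angle: float = 175.0) -> ComplexPose:
    """One receptor OA acceptor facing a ligand N-HD donor pair.

    The donor-H-acceptor angle and the H···acceptor distance are realised
    exactly, so the expected hydrogen-bond count follows directly from the
    configured criteria.
    """
    theta = np.radians(180.0 - angle)
    h = np.array([0.0, 0.0, 0.0])
    donor = h + 1.0 * np.array([np.cos(theta), np.sin(theta), 0.0])
    acceptor = h - np.array([distance, 0.0, 0.0])
    return gen_toy_complex(
        receptor_atoms=[("OA", tuple(acceptor), -0.4)],
        ligand_atoms=[("N", tuple(donor), -0.3), ("HD", tuple(h), 0.2)],
    )


def gen_screening_library(spec: SyntheticSpec) -> pd.DataFrame:
    """Feature table of one synthetic screen, labels included.

    Columns: ``compound_id``, ``label`` and features ``f0..f{p-1}``.
    Decoys are standard normal on every feature; actives get a mean shift
    of ``effect_size`` SD on the informative block.  Optional label noise
    flips a seeded fraction of labels.  Row order is a seeded permutation.
    ``df.attrs["informative_features"]`` records the planted ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.n_features
    X_act = rng.standard_normal((spec.n_actives, p))
    lo = spec.informative_offset
    X_act[:, lo:lo + spec.n_informative] += spec.effect_size
    X_dec = rng.standard_normal((spec.n_decoys, p))
    X = np.vstack([X_act, X_dec])
    y = np.concatenate([np.ones(spec.n_actives, dtype=int),
                        np.zeros(spec.n_decoys, dtype=int)])
    ids = ([f"act_{i:05d}" for i in range(spec.n_actives)]
           + [f"dec_{i:05d}" for i in range(spec.n_decoys)])
    if spec.label_noise > 0:
        flip = rng.random(len(y)) < spec.label_noise
        y = np.where(flip, 1 - y, y)
    perm = rng.permutation(len(y))
    df = pd.DataFrame(X[perm], columns=[f"f{j}" for j in range(p)])
    df.insert(0, "label", y[perm])
    df.insert(0, "compound_id", np.array(ids)[perm])
    df.attrs["informative_features"] = list(spec.informative_features)
    df.attrs["spec_seed"] = spec.seed
    return df


def _reference_ligand() -> MolecularStructure:
    # 5-heavy-atom rigid fragment plus one polar hydrogen (ignored by RMSD)
    atoms = [
        AtomRecord(1, "C1", "C", (0.0, 0.0, 0.0), 0.05),
        AtomRecord(2, "C2", "C", (1.5, 0.0, 0.0), 0.05),
        AtomRecord(3, "OA", "OA", (2.2, 1.2, 0.0), -0.4),
        AtomRecord(4, "N1", "N", (-0.8, 1.2, 0.0), -0.35),
        AtomRecord(5, "C3", "C", (0.7, -1.3, 0.8), 0.05),
        AtomRecord(6, "HD", "HD", (-0.4, 2.05, 0.3), 0.17),
    ]
    return MolecularStructure(atoms, "ligand", "synthetic_reference")


def gen_pose_set(rmsd_targets: Sequence[float], seed: int = 42,
                 compound_id: str = "synthetic_compound"
                 ) -> tuple[PoseSet, MolecularStructure]:
    """Pose set whose heavy-atom RMSDs to the reference are exactly as asked.

    Each pose is the reference rigidly translated along a seeded random
    direction by the target RMSD (a uniform translation shifts every atom
    equally, so realised RMSD equals the translation length).  Pose ranks
    follow target order, rank 1 first.
    """
    if any(t < 0 for t in rmsd_targets):
        raise ValueError("rmsd targets must be non-negative")
    rng = np.random.default_rng(seed)
    reference = _reference_ligand()
    receptor = MolecularStructure(
        [AtomRecord(1, "C", "C", (8.0, 8.0, 8.0), 0.1),
         AtomRecord(2, "OA", "OA", (9.0, 8.0, 8.0), -0.35)],
        "receptor", "synthetic_receptor")
    poses = []
    for rank, target in enumerate(rmsd_targets, start=1):
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        shifted = reference.transformed(np.eye(3), target * direction)
        shifted.role = "ligand"
        poses.append(ComplexPose(receptor, shifted, rank,
                                 f"{compound_id}_pose{rank}"))
    return PoseSet(compound_id, poses), reference


def gen_knowledge_pattern_libraries(seed: int, n_features: int = 100,
                                    n_informative: int = 5,
                                    effect_size: float = 2.0,
                                    spec_overrides: dict | None = None
                                    ) -> dict[str, pd.DataFrame]:
    """Two training screens with disjoint informative blocks + a mixed test.

    Library A plants its signal on features ``f0..f4``, library B on
    ``f5..f9``.  A scorer trained on A learns pattern A only, and vice
    versa — two genuinely different knowledge patterns.  The mixed test
    screen contains half A-pattern and half B-pattern actives against a
    common decoy background, so neither single model can enrich all
    actives but a consensus can.
    """
    ov = spec_overrides or {}
    base = dict(n_features=n_features, n_informative=n_informative,
                effect_size=effect_size, **ov)
    spec_a = SyntheticSpec(seed=seed, informative_offset=0, **base)
    spec_b = SyntheticSpec(seed=seed + 1, informative_offset=n_informative, **base)
    train_a = gen_screening_library(spec_a)
    train_b = gen_screening_library(spec_b)

    half = spec_a.n_actives // 2
    test_a = gen_screening_library(replace(spec_a, seed=seed + 2, n_actives=half))
    test_b = gen_screening_library(replace(spec_b, seed=seed + 3, n_actives=half,
                                           n_decoys=spec_a.n_decoys))
    # merge: A-pattern actives + B-pattern actives + one decoy background
    actives_a = test_a[test_a["label"] == 1].assign(
        compound_id=lambda d: "A_" + d["compound_id"])
    actives_b = test_b[test_b["label"] == 1].assign(
        compound_id=lambda d: "B_" + d["compound_id"])
    decoys = test_a[test_a["label"] == 0]
    mixed = pd.concat([actives_a, actives_b, decoys], ignore_index=True)
    rng = np.random.default_rng(seed + 4)
    mixed = mixed.iloc[rng.permutation(len(mixed))].reset_index(drop=True)
    mixed.attrs["informative_features"] = (
        list(spec_a.informative_features) + list(spec_b.informative_features))
    return {"train_a": train_a, "train_b": train_b, "test_mixed": mixed}
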