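"""Conformation-sensitive interaction features of a receptor-ligand pose.

The feature families, in the spirit of the BINANA and ECIF descriptor
methods:

* typed close-contact counts at 2.5 and 4.0 Å cutoffs, keyed
  ``"2.5(HD, OA)"`` with the type pair in canonical alphabetical order;
* per-type-pair summed electrostatic energies
  ``V(a,b) = Σ q_ai·q_bi / r_aibi`` over receptor-ligand atom pairs within
  the contact cutoff (charge²/Å units, sign preserved), keyed ``"elec(a, b)"``;
* hydrogen-bond, salt-bridge and π-stacking counts under fixed, auditable
  geometric criteria;
* ECIF-style counts of (protein extended type, ligand extended type) pairs,
  where an extended type encodes element, heavy-atom degree and aromaticity.

All geometric thresholds live in :class:`InteractionConfig`; the defaults
follow the published BINANA/ECIF conventions and are frozen in one place so
they can be audited and overridden from a config file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .schema import FeatureSchema, FeatureVector, SchemaError
from .structio import ComplexPose, MolecularStructure

__all__ = [
    "InteractionConfig",
    "DegenerateGeometryError",
    "close_contact_counts",
    "electrostatic_sums",
    "detect_hydrogen_bonds",
    "detect_salt_bridges",
    "detect_pi_stacking",
    "ecif_pair_counts",
    "assemble_interaction_features",
    "build_pb_schema",
    "build_ps_schema",
    "INTERACTION_COUNT_FEATURES",
]


class DegenerateGeometryError(ValueError):
    """Distinct atoms at zero separation make pairwise energies undefined."""


@dataclass(frozen=True)
class InteractionConfig:
    """Frozen geometric criteria for all interaction detectors.

    Distances in Å, angles in degrees.  The hydrogen-bond distance is
    measured from the polar hydrogen to the acceptor heavy atom; the angle
    is donor-H-acceptor and only enforced when a donor heavy atom can be
    identified (nearest heavy atom within ``covalent_h_cutoff`` of the H).
    """

    contact_cutoffs: tuple[float, float] = (2.5, 4.0)
    electrostatics_cutoff: float = 4.0
    hbond_dist_cutoff: float = 4.0
    hbond_angle_min: float = 120.0
    covalent_h_cutoff: float = 1.6
    salt_bridge_dist_cutoff: float = 5.5
    salt_bridge_min_charge: float = 0.5
    pi_ftf_dist_cutoff: float = 7.0
    pi_ftf_angle_max: float = 30.0
    pi_etf_dist_cutoff: float = 5.0
    pi_etf_angle_min: float = 60.0
    ecif_cutoff: float = 6.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "InteractionConfig":
        import json, yaml
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        fixed = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
        return cls(**fixed)


DEFAULT_CONFIG = InteractionConfig()

ACCEPTOR_TYPES = frozenset({"OA", "NA", "SA"})
AROMATIC_TYPES = frozenset({"A"})

INTERACTION_COUNT_FEATURES = ("hbond_count", "salt_bridge_count", "pi_stack_count")

# AutoDock types the default schema enumerates; pairs outside this universe
# are still counted by the detectors but dropped at assembly time.
DEFAULT_TYPE_UNIVERSE = (
    "A", "Br", "C", "Cl", "F", "HD", "I", "N", "NA", "OA", "P", "S", "SA",
)


def _pair_key(prefix: str, t1: str, t2: str) -> str:
    a, b = sorted((t1, t2))
    return f"{prefix}({a}, {b})"


def _pairwise(pose: ComplexPose) -> np.ndarray:
    return cdist(pose.receptor.coords, pose.ligand.coords)


def close_contact_counts(pose: ComplexPose, cutoff: float) -> dict[str, int]:
    """Count receptor-ligand atom pairs within `cutoff` Å per type pair."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    d = _pairwise(pose)
    rt, lt = pose.receptor.types, pose.ligand.types
    counts: dict[str, int] = {}
    for i, j in zip(*np.nonzero(d <= cutoff)):
        key = _pair_key(f"{cutoff:.1f}", rt[i], lt[j])
        counts[key] = counts.get(key, 0) + 1
    return counts


def electrostatic_sums(pose: ComplexPose, cutoff: float | None = None,
                       config: InteractionConfig = DEFAULT_CONFIG) -> dict[str, float]:
    """Per-type-pair summed pairwise electrostatic energy Σ q_i·q_j / r_ij.

    Only receptor-ligand pairs within the electrostatics cutoff contribute;
    the sign of each term is preserved, so attractive and repulsive
    contributions of one type pair can cancel.
    """
    cutoff = config.electrostatics_cutoff if cutoff is None else cutoff
    d = _pairwise(pose)
    qr, ql = pose.receptor.charges, pose.ligand.charges
    rt, lt = pose.receptor.types, pose.ligand.types
    sums: dict[str, float] = {}
    for i, j in zip(*np.nonzero(d <= cutoff)):
        r = d[i, j]
        if r == 0.0:
            raise DegenerateGeometryError(
                f"receptor atom {pose.receptor.atoms[i].serial} and ligand atom "
                f"{pose.ligand.atoms[j].serial} coincide; pairwise energy undefined"
            )
        key = _pair_key("elec", rt[i], lt[j])
        sums[key] = sums.get(key, 0.0) + qr[i] * ql[j] / r
    return sums


def _donor_heavy(structure: MolecularStructure, h_index: int,
                 cutoff: float) -> int | None:
    """Index of the heavy atom the hydrogen is covalently bound to, if any."""
    h = np.array(structure.atoms[h_index].coords)
    best, best_d = None, cutoff
    for k, a in enumerate(structure.atoms):
        if a.is_hydrogen:
            continue
        dd = float(np.linalg.norm(np.array(a.coords) - h))
        if dd <= best_d:
            best, best_d = k, dd
    return best


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b of the triangle a-b-c, degrees."""
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hydrogen_bonds(pose: ComplexPose,
                          config: InteractionConfig = DEFAULT_CONFIG
                          ) -> tuple[int, list[dict]]:
    """Count donor-H···acceptor contacts across the interface.

    A bond requires a polar hydrogen (type HD) on one side within
    ``hbond_dist_cutoff`` of an acceptor-typed heavy atom (OA/NA/SA) on the
    other, with donor-H-acceptor angle ≥ ``hbond_angle_min`` whenever the
    donor heavy atom is identifiable.
    """
    bonds: list[dict] = []
    for donor_side, acceptor_side, tag in (
        (pose.receptor, pose.ligand, "receptor_donor"),
        (pose.ligand, pose.receptor, "ligand_donor"),
    ):
        h_idx = [i for i, a in enumerate(donor_side.atoms) if a.autodock_type == "HD"]
        acc_idx = [j for j, a in enumerate(acceptor_side.atoms)
                   if a.autodock_type in ACCEPTOR_TYPES]
        if not h_idx or not acc_idx:
            continue
        for i in h_idx:
            h = np.array(donor_side.atoms[i].coords)
            donor_k = _donor_heavy(donor_side, i, config.covalent_h_cutoff)
            for j in acc_idx:
                acc = np.array(acceptor_side.atoms[j].coords)
                dist = float(np.linalg.norm(h - acc))
                if dist > config.hbond_dist_cutoff:
                    continue
                if donor_k is not None:
                    donor = np.array(donor_side.atoms[donor_k].coords)
                    ang = _angle_deg(donor, h, acc)
                    if ang < config.hbond_angle_min:
                        continue
                else:
                    ang = float("nan")
                bonds.append({
                    "direction": tag,
                    "h_serial": donor_side.atoms[i].serial,
                    "acceptor_serial": acceptor_side.atoms[j].serial,
                    "acceptor_type": acceptor_side.atoms[j].autodock_type,
                    "distance": dist,
                    "angle": ang,
                })
    return len(bonds), bonds


def detect_salt_bridges(pose: ComplexPose,
                        config: InteractionConfig = DEFAULT_CONFIG) -> int:
    """Count oppositely charged receptor-ligand atom pairs within the cutoff.

    Both partners must carry at least ``salt_bridge_min_charge`` in absolute
    value, which keeps ordinary polar atoms (|q| ~ 0.2-0.4) from counting.
    """
    d = _pairwise(pose)
    qr, ql = pose.receptor.charges, pose.ligand.charges
    qmin = config.salt_bridge_min_charge
    strong = (np.abs(qr)[:, None] >= qmin) & (np.abs(ql)[None, :] >= qmin)
    opposite = (qr[:, None] * ql[None, :]) < 0
    return int(np.sum(strong & opposite & (d <= config.salt_bridge_dist_cutoff)))


def _aromatic_rings(structure: MolecularStructure,
                    ring_indices: Sequence[Sequence[int]] | None = None
                    ) -> list[tuple[np.ndarray, np.ndarray]]:
    """(centroid, unit normal) of each aromatic ring.

    With explicit ring atom indices those are used directly; otherwise rings
    are detected by clustering aromatic-typed atoms (AutoDock type ``A``)
    into connected components at covalent range — PDBQT carries no bond
    table, so distance clustering stands in for ring perception.
    """
    coords = structure.coords
    if ring_indices is None:
        arom = [i for i, a in enumerate(structure.atoms)
                if a.autodock_type in AROMATIC_TYPES]
        if len(arom) < 5:
            return []
        sub = coords[arom]
        adj = cdist(sub, sub) <= 1.75
        n = len(arom)
        seen, comps = set(), []
        for s in range(n):
            if s in seen:
                continue
            stack, comp = [s], []
            while stack:
                u = stack.pop()
                if u in seen:
                    continue
                seen.add(u)
                comp.append(u)
                stack.extend(v for v in range(n) if adj[u, v] and v not in seen)
            if len(comp) >= 5:
                comps.append([arom[k] for k in comp])
        ring_indices = comps
    rings = []
    for idx in ring_indices:
        pts = coords[list(idx)]
        centroid = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - centroid)
        rings.append((centroid, vt[2] / np.linalg.norm(vt[2])))
    return rings


def detect_pi_stacking(pose: ComplexPose,
                       ligand_rings: Sequence[Sequence[int]] | None = None,
                       receptor_rings: Sequence[Sequence[int]] | None = None,
                       config: InteractionConfig = DEFAULT_CONFIG) -> int:
    """Count aromatic ring pairs in face-to-face or edge-to-face geometry.

    Face-to-face: centroid distance ≤ 7.0 Å and interplanar angle ≤ 30°.
    Edge-to-face: centroid distance ≤ 5.0 Å and interplanar angle ≥ 60°.
    """
    r_rings = _aromatic_rings(pose.receptor, receptor_rings)
    l_rings = _aromatic_rings(pose.ligand, ligand_rings)
    count = 0
    for rc, rn in r_rings:
        for lc, ln in l_rings:
            dist = float(np.linalg.norm(rc - lc))
            cosang = abs(float(np.dot(rn, ln)))
            angle = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
            if dist <= config.pi_ftf_dist_cutoff and angle <= config.pi_ftf_angle_max:
                count += 1
            elif dist <= config.pi_etf_dist_cutoff and angle >= config.pi_etf_angle_min:
                count += 1
    return count


# --- ECIF-style extended-type pair counts ---------------------------------

def _infer_heavy_adjacency(structure: MolecularStructure) -> np.ndarray:
    """Covalent adjacency among heavy atoms inferred from distance.

    PDBQT has no CONECT records; a generous 1.9 Å heavy-heavy threshold
    recovers organic covalent bonds without bridging non-bonded contacts.
    """
    heavy = structure.heavy_atoms()
    pts = np.array([a.coords for a in heavy])
    d = cdist(pts, pts)
    adj = (d > 0.1) & (d <= 1.9)
    return adj


def protein_extended_types(structure: MolecularStructure) -> list[str]:
    """Extended type token ``element;degree;aromatic`` for each heavy atom."""
    heavy = structure.heavy_atoms()
    adj = _infer_heavy_adjacency(structure)
    deg = adj.sum(axis=1)
    return [
        f"{a.element};{int(deg[k])};{1 if a.autodock_type in AROMATIC_TYPES else 0}"
        for k, a in enumerate(heavy)
    ]


def ligand_extended_types(topology) -> list[str]:
    """Extended types of the topology's heavy atoms, in atom order.

    `topology` is a :class:`~ibvs.ligand.LigandTopology` (or RDKit mol);
    hydrogens are excluded, matching the heavy-atom order of a docked
    ligand structure.
    """
    from .ligand import LigandTopology
    if isinstance(topology, LigandTopology):
        mol = topology.mol
    else:
        mol = topology
    types = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            continue
        deg = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1)
        types.append(f"{atom.GetSymbol()};{deg};{1 if atom.GetIsAromatic() else 0}")
    return types


def ecif_pair_counts(pose: ComplexPose, ligand_topology,
                     cutoff: float | None = None,
                     config: InteractionConfig = DEFAULT_CONFIG) -> dict[str, int]:
    """Count (protein extended type, ligand extended type) pairs within range.

    The ligand topology must list heavy atoms in the same order as the
    docked ligand structure; hydrogens never enter the typing.
    """
    if ligand_topology is None:
        raise SchemaError("ECIF typing requires the ligand topology (SDF/SMILES)")
    cutoff = config.ecif_cutoff if cutoff is None else cutoff
    p_types = protein_extended_types(pose.receptor)
    l_types = ligand_extended_types(ligand_topology)
    p_heavy = pose.receptor.heavy_atoms()
    l_heavy = pose.ligand.heavy_atoms()
    if len(l_types) != len(l_heavy):
        raise SchemaError(
            f"ligand topology has {len(l_types)} heavy atoms but the docked "
            f"structure has {len(l_heavy)}"
        )
    d = cdist(np.array([a.coords for a in p_heavy]),
              np.array([a.coords for a in l_heavy]))
    counts: dict[str, int] = {}
    for i, j in zip(*np.nonzero(d <= cutoff)):
        key = f"ecif({p_types[i]}, {l_types[j]})"
        counts[key] = counts.get(key, 0) + 1
    return counts


# --- schema construction and assembly -------------------------------------

_CONTACT_RE = re.compile(r"^(\d+\.\d)\((\S+), (\S+)\)$")
_ELEC_RE = re.compile(r"^elec\((\S+), (\S+)\)$")
_ECIF_RE = re.compile(r"^ecif\((\S+), (\S+)\)$")


def build_pb_schema(ligand_descriptor_names: Sequence[str] = (),
                    include_ecif: bool = True,
                    type_universe: Sequence[str] = DEFAULT_TYPE_UNIVERSE,
                    config: InteractionConfig = DEFAULT_CONFIG) -> FeatureSchema:
    """Full feature schema: contacts, electrostatics, named interactions,
    ECIF pair counts, and the conformation-invariant ligand block."""
    names: list[str] = []
    types = sorted(type_universe)
    for cutoff in config.contact_cutoffs:
        for i, t1 in enumerate(types):
            for t2 in types[i:]:
                names.append(f"{cutoff:.1f}({t1}, {t2})")
    for i, t1 in enumerate(types):
        for t2 in types[i:]:
            names.append(f"elec({t1}, {t2})")
    names.extend(INTERACTION_COUNT_FEATURES)
    if include_ecif:
        p_tokens = [f"{el};{d};{ar}" for el in ("C", "N", "O", "S")
                    for d in (1, 2, 3, 4) for ar in (0, 1)]
        l_tokens = list(p_tokens)
        names.extend(f"ecif({p}, {l})" for p in p_tokens for l in l_tokens)
    names.extend(f"lig_{n}" for n in ligand_descriptor_names)
    names.append("kier_flexibility")
    return FeatureSchema("PB", tuple(names))


def build_ps_schema(pb: FeatureSchema,
                    excluded_feature: str = "kier_flexibility") -> FeatureSchema:
    """PS schema: the PB schema minus exactly one named feature."""
    return pb.subset_schema("PS", (excluded_feature,))


def assemble_interaction_features(pose: ComplexPose, schema: FeatureSchema,
                                  ligand_topology=None,
                                  ligand_rings: Sequence[Sequence[int]] | None = None,
                                  config: InteractionConfig = DEFAULT_CONFIG
                                  ) -> FeatureVector:
    """Compute every feature the schema names for one pose.

    Contact/electrostatic/ECIF pairs the schema does not name are dropped;
    schema pairs not observed in the pose are zero.  Ligand-block features
    (``lig_*``, ``kier_flexibility``) require the topology.  A schema name
    matching no producer raises :class:`SchemaError`.
    """
    produced: dict[str, float] = {}
    for cutoff in config.contact_cutoffs:
        produced.update(close_contact_counts(pose, cutoff))
    produced.update(electrostatic_sums(pose, config=config))
    n_hb, _ = detect_hydrogen_bonds(pose, config)
    produced["hbond_count"] = float(n_hb)
    produced["salt_bridge_count"] = float(detect_salt_bridges(pose, config))
    produced["pi_stack_count"] = float(
        detect_pi_stacking(pose, ligand_rings=ligand_rings, config=config))

    needs_ligand = [n for n in schema.feature_names
                    if n.startswith("lig_") or n == "kier_flexibility"]
    needs_ecif = any(_ECIF_RE.match(n) for n in schema.feature_names)
    if needs_ecif:
        produced.update(ecif_pair_counts(pose, ligand_topology, config=config))
    if needs_ligand:
        if ligand_topology is None:
            raise SchemaError(
                "schema includes ligand-descriptor features but no topology given")
        from .ligand import compute_descriptors, kier_flexibility
        wanted = [n[4:] for n in needs_ligand if n.startswith("lig_")]
        desc = compute_descriptors(ligand_topology, wanted)
        produced.update({f"lig_{k}": v for k, v in desc.items()})
        if "kier_flexibility" in schema:
            produced["kier_flexibility"] = kier_flexibility(ligand_topology)

    for name in schema.feature_names:
        known = (name in produced
                 or _CONTACT_RE.match(name) or _ELEC_RE.match(name)
                 or _ECIF_RE.match(name))
        if not known:
            raise SchemaError(f"schema feature {name!r} has no producer")
    return FeatureVector.from_partial(schema, produced)
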