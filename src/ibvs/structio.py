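"""Structure and table I/O for docked protein-ligand complexes.

PDBQT is the working format of AutoDock-family docking engines: fixed-column
PDB-like records that additionally carry a Gasteiger partial charge and an
AutoDock atom type (``HD`` polar hydrogen, ``OA`` oxygen acceptor, ``A``
aromatic carbon, ...) on every ATOM/HETATM line.  Multi-pose ligand files
separate poses with MODEL/ENDMDL blocks in docking-rank order.

Charges are always read from the file, never recomputed: the electrostatic
features downstream are meaningless without the charges the docking engine
actually used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "MolecularStructure",
    "ComplexPose",
    "PoseSet",
    "PdbqtFormatError",
    "EmptyPocketError",
    "parse_pdbqt",
    "write_pdbqt",
    "extract_pocket",
    "write_feature_table",
    "read_feature_table",
]

_HYDROGEN_TYPES = {"H", "HD"}


class PdbqtFormatError(ValueError):
    """Raised for malformed or empty PDBQT input."""


class EmptyPocketError(ValueError):
    """Raised when pocket truncation leaves no receptor atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: AutoDock type, coordinates (Å) and partial charge (e)."""

    serial: int
    name: str
    autodock_type: str
    coords: tuple[float, float, float]
    partial_charge: float

    def __post_init__(self) -> None:
        if not self.autodock_type:
            raise ValueError("autodock_type must be non-empty")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")

    @property
    def is_hydrogen(self) -> bool:
        return self.autodock_type in _HYDROGEN_TYPES

    @property
    def element(self) -> str:
        """Element symbol inferred from the AutoDock type token."""
        t = self.autodock_type
        if t in _HYDROGEN_TYPES:
            return "H"
        if t == "A":
            return "C"
        if t in {"OA", "NA", "SA"}:
            return t[0]
        if len(t) == 2 and t[1].islower():  # Cl, Br, Fe, Zn, Mg ...
            return t
        return t[0]


@dataclass
class MolecularStructure:
    """Ordered atom list with a receptor/ligand role."""

    atoms: list[AtomRecord]
    role: Literal["receptor", "ligand"]
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("structure must contain at least one atom")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique within a structure")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array in Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    @property
    def types(self) -> list[str]:
        return [a.autodock_type for a in self.atoms]

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "MolecularStructure":
        """Return a rigidly moved copy: x -> R x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new_atoms = [
            AtomRecord(a.serial, a.name, a.autodock_type,
                       tuple(R @ np.array(a.coords) + t), a.partial_charge)
            for a in self.atoms
        ]
        return MolecularStructure(new_atoms, self.role, self.source_id)


@dataclass
class ComplexPose:
    """One receptor + one ligand pose; pose_rank 1 is the docking top pose."""

    receptor: MolecularStructure
    ligand: MolecularStructure
    pose_rank: int = 1
    pose_id: str = ""

    def __post_init__(self) -> None:
        if self.pose_rank < 1:
            raise ValueError("pose_rank must be >= 1")


@dataclass
class PoseSet:
    """All retained poses of one compound against one receptor."""

    compound_id: str
    poses: list[ComplexPose] = field(default_factory=list)

    def __post_init__(self) -> None:
        ranks = [p.pose_rank for p in self.poses]
        if len(set(ranks)) != len(ranks):
            raise ValueError("pose_ranks must be unique within a PoseSet")

    def __len__(self) -> int:
        return len(self.poses)


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    # PDBQT fixed columns: serial 7-11, name 13-16, x/y/z 31-54,
    # partial charge 67-76, AutoDock type 78-79.
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PdbqtFormatError(f"line {lineno}: malformed ATOM/HETATM record") from exc
    charge_field = line[66:76].strip().split()
    type_field = line[76:].strip().split()
    if not charge_field or not type_field:
        raise PdbqtFormatError(
            f"line {lineno}: missing partial charge or AutoDock type column"
        )
    try:
        charge = float(charge_field[-1])
    except ValueError as exc:
        raise PdbqtFormatError(f"line {lineno}: unreadable partial charge") from exc
    return AtomRecord(serial, name, type_field[0], (x, y, z), charge)


def parse_pdbqt(path: str | Path, role: Literal["receptor", "ligand"]) -> list[MolecularStructure]:
    """Parse a PDBQT file into one structure per MODEL block.

    Receptors and single-model ligands yield a one-element list.  ROOT /
    BRANCH / TORSDOF and other torsion-tree records are skipped.  Missing
    charge or type columns raise :class:`PdbqtFormatError` naming the line.
    """
    path = Path(path)
    text = path.read_text()
    structures: list[MolecularStructure] = []
    current: list[AtomRecord] = []
    model_index = 0
    saw_model = False

    def flush() -> None:
        nonlocal current, model_index
        if current:
            model_index += 1
            structures.append(
                MolecularStructure(list(current), role, f"{path.stem}:{model_index}")
            )
            current = []

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            current.append(_parse_atom_line(line, lineno))
        elif rec == "MODEL":
            saw_model = True
            flush()
        elif rec == "ENDMDL":
            flush()
    flush()
    if not structures:
        raise PdbqtFormatError(f"{path}: no ATOM/HETATM records found")
    if not saw_model and len(structures) == 1:
        structures[0].source_id = path.stem
    return structures


def write_pdbqt(structures: Sequence[MolecularStructure] | MolecularStructure,
                path: str | Path) -> None:
    """Serialize structure(s) to PDBQT; multiple structures get MODEL blocks."""
    if isinstance(structures, MolecularStructure):
        structures = [structures]
    lines: list[str] = []
    multi = len(structures) > 1
    for i, s in enumerate(structures, start=1):
        if multi:
            lines.append(f"MODEL {i:8d}")
        for a in s.atoms:
            x, y, z = a.coords
            lines.append(
                f"ATOM  {a.serial:5d} {a.name:<4s} LIG A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"{a.partial_charge:10.4f} {a.autodock_type:<2s}"
            )
        if multi:
            lines.append("ENDMDL")
    Path(path).write_text("\n".join(lines) + "\n")


def poses_from_pdbqt(receptor_path: str | Path, ligand_path: str | Path,
                     compound_id: str | None = None) -> PoseSet:
    """Assemble a PoseSet from a receptor file and a (multi-MODEL) ligand file."""
    receptor = parse_pdbqt(receptor_path, "receptor")[0]
    ligands = parse_pdbqt(ligand_path, "ligand")
    cid = compound_id or Path(ligand_path).stem
    poses = [
        ComplexPose(receptor, lig, pose_rank=i, pose_id=f"{cid}_pose{i}")
        for i, lig in enumerate(ligands, start=1)
    ]
    return PoseSet(cid, poses)


def extract_pocket(receptor: MolecularStructure, ligand: MolecularStructure,
                   radius: float = 12.0) -> MolecularStructure:
    """Truncate the receptor to atoms within `radius` Å of any ligand atom.

    Pocket truncation changes no feature values (all interaction cutoffs are
    well below the default 12 Å) but makes featurization much cheaper on
    whole-protein receptors.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    d = np.linalg.norm(
        receptor.coords[:, None, :] - ligand.coords[None, :, :], axis=-1
    )
    keep = (d.min(axis=1) <= radius)
    if not keep.any():
        raise EmptyPocketError(
            f"no receptor atoms within {radius} Å of the ligand"
        )
    atoms = [a for a, k in zip(receptor.atoms, keep) if k]
    return MolecularStructure(atoms, "receptor", receptor.source_id + f"|pocket{radius:g}")


def write_feature_table(rows: Iterable, path: str | Path, schema=None) -> None:
    """Write labelled feature vectors to CSV in canonical schema order.

    `rows` are (pose_id, FeatureVector, label) triples or dicts with keys
    ``pose_id``, ``features``, ``label`` (and optionally ``compound_id``).
    All rows must share one schema; header order is the schema order.  An
    empty row iterable yields a header-only file (requires `schema`).
    """
    records = []
    schema_id = schema.schema_id if schema is not None else None
    names: list[str] | None = list(schema.feature_names) if schema is not None else None
    for row in rows:
        if isinstance(row, dict):
            pose_id, fv, label = row["pose_id"], row["features"], row["label"]
            extra = {k: v for k, v in row.items() if k not in ("pose_id", "features", "label")}
        else:
            pose_id, fv, label = row
            extra = {}
        if schema_id is None:
            schema_id = fv.schema.schema_id
            names = list(fv.schema.feature_names)
        elif fv.schema.schema_id != schema_id or list(fv.schema.feature_names) != names:
            raise ValueError(
                f"schema mismatch: expected {schema_id}, got {fv.schema.schema_id}"
            )
        rec = {"pose_id": pose_id, **extra, "label": label}
        rec.update({n: fv.values[n] for n in names})
        records.append(rec)
    if names is None:
        raise ValueError("cannot infer schema from an empty row iterable; "
                         "pass schema= to write a header-only file")
    if not records:
        pd.DataFrame(columns=["pose_id", "label", *names]).to_csv(path, index=False)
        return
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV written by :func:`write_feature_table`."""
    return pd.read_csv(path)
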