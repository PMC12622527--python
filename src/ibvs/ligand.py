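"""Conformation-invariant topological ligand descriptors.

Everything here is a pure function of the molecular graph (elements, bonds,
aromaticity): two conformers of the same molecule always produce identical
values.  This block is what lets a scorer recognise molecular identity even
when a pose is garbage — a badly docked pose of an active still *is* the
active, topologically.

The default registry ships 59 RDKit 2D descriptors spanning connectivity
(Chi), shape (kappa), complexity (BertzCT, BalabanJ), counts and surface
estimates; the Kier molecular-flexibility index Φ is computed separately
from first principles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import Descriptors

__all__ = [
    "LigandTopology",
    "DescriptorRegistryError",
    "DEFAULT_DESCRIPTOR_NAMES",
    "kier_flexibility",
    "compute_descriptors",
]


class DescriptorRegistryError(KeyError):
    """Requested descriptor is not in the supported registry."""


# 59 topology-only 2D descriptors; membership is declared here, explicitly,
# and can be overridden by passing your own name list to compute_descriptors.
DEFAULT_DESCRIPTOR_NAMES: tuple[str, ...] = (
    "BalabanJ", "BertzCT",
    "Chi0", "Chi1",
    "Chi0n", "Chi1n", "Chi2n", "Chi3n", "Chi4n",
    "Chi0v", "Chi1v", "Chi2v", "Chi3v", "Chi4v",
    "HallKierAlpha", "Kappa1", "Kappa2", "Kappa3",
    "FractionCSP3",
    "HeavyAtomCount", "HeavyAtomMolWt", "MolWt", "ExactMolWt",
    "NHOHCount", "NOCount",
    "NumHAcceptors", "NumHDonors", "NumHeteroatoms", "NumRotatableBonds",
    "RingCount",
    "NumAromaticRings", "NumAliphaticRings", "NumSaturatedRings",
    "NumAromaticCarbocycles", "NumAromaticHeterocycles",
    "NumAliphaticCarbocycles", "NumAliphaticHeterocycles",
    "NumSaturatedCarbocycles", "NumSaturatedHeterocycles",
    "TPSA", "LabuteASA", "MolLogP", "MolMR",
    "NumValenceElectrons", "NumRadicalElectrons",
    "MaxEStateIndex", "MinEStateIndex",
    "MaxAbsEStateIndex", "MinAbsEStateIndex",
    "qed",
    "SlogP_VSA1", "SlogP_VSA2", "SlogP_VSA3", "SMR_VSA1", "SMR_VSA5",
    "SMR_VSA7", "EState_VSA2", "EState_VSA9", "VSA_EState1",
)
assert len(DEFAULT_DESCRIPTOR_NAMES) == 59
assert len(set(DEFAULT_DESCRIPTOR_NAMES)) == 59


@dataclass
class LigandTopology:
    """Molecular graph of a ligand, independent of any 3D conformation."""

    mol: Chem.Mol
    source: str = ""

    def __post_init__(self) -> None:
        if self.mol is None or self.mol.GetNumAtoms() == 0:
            raise ValueError("empty or unparsable ligand topology")
        frags = Chem.GetMolFrags(self.mol)
        if len(frags) > 1:
            warnings.warn(
                f"ligand topology {self.source!r} has {len(frags)} disconnected "
                "fragments; graph descriptors treat the whole graph", stacklevel=2)

    @classmethod
    def from_smiles(cls, smiles: str, source: str = "") -> "LigandTopology":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparsable SMILES: {smiles!r}")
        return cls(mol, source or smiles)

    @classmethod
    def from_sdf(cls, path: str | Path, index: int = 0) -> "LigandTopology":
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        mols = [m for m in supplier if m is not None]
        if not mols:
            raise ValueError(f"no parsable molecules in {path}")
        return cls(mols[index], f"{Path(path).stem}[{index}]")

    @property
    def heavy_atom_count(self) -> int:
        return sum(1 for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1)


def _path_counts(mol: Chem.Mol) -> tuple[int, int]:
    """(#heavy-heavy bonds, #length-2 heavy paths) of the molecular graph."""
    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    p1 = sum(1 for b in mol.GetBonds()
             if b.GetBeginAtom().GetAtomicNum() > 1
             and b.GetEndAtom().GetAtomicNum() > 1)
    p2 = 0
    for a in heavy:
        d = sum(1 for nb in a.GetNeighbors() if nb.GetAtomicNum() > 1)
        p2 += d * (d - 1) // 2
    return p1, p2


def kier_flexibility(topology: LigandTopology | Chem.Mol, use_alpha: bool = True) -> float:
    """Kier molecular flexibility Φ = (¹κ · ²κ) / A.

    ¹κ = (A+α)(A+α−1)² / (P₁+α)² and ²κ = (A+α−1)(A+α−2)² / (P₂+α)², with
    A the heavy-atom count, P₁ the bond count, P₂ the number of two-bond
    paths, and α the Hall-Kier covalent-radius correction (α = 0 when
    ``use_alpha`` is off, giving the plain kappa indices).  Linear alkanes
    score high (n-hexane: Φ = 5); rigid aromatics score low.  Degenerate
    graphs (single atoms, no two-bond path) return 0 with a warning.
    """
    mol = topology.mol if isinstance(topology, LigandTopology) else topology
    heavy = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)
    if heavy < 1:
        raise ValueError("kier_flexibility needs at least one heavy atom")
    alpha = Descriptors.HallKierAlpha(mol) if use_alpha else 0.0
    p1, p2 = _path_counts(mol)
    a = float(heavy)
    if heavy < 3 or p1 + alpha <= 0 or p2 + alpha <= 0:
        if heavy > 2:
            warnings.warn("degenerate graph for kappa indices; Φ set to 0",
                          stacklevel=2)
        return 0.0
    kappa1 = (a + alpha) * (a + alpha - 1.0) ** 2 / (p1 + alpha) ** 2
    kappa2 = (a + alpha - 1.0) * (a + alpha - 2.0) ** 2 / (p2 + alpha) ** 2
    return kappa1 * kappa2 / a


def compute_descriptors(topology: LigandTopology | Chem.Mol,
                        names: "list[str] | tuple[str, ...]" = DEFAULT_DESCRIPTOR_NAMES
                        ) -> dict[str, float]:
    """Evaluate named registry descriptors on the molecular graph.

    Raises :class:`DescriptorRegistryError` for names outside the registry.
    All returned values are finite floats.
    """
    mol = topology.mol if isinstance(topology, LigandTopology) else topology
    out: dict[str, float] = {}
    for name in names:
        fn = getattr(Descriptors, name, None)
        if fn is None or name not in _REGISTRY:
            raise DescriptorRegistryError(
                f"{name!r} is not a registered topological descriptor")
        val = float(fn(mol))
        if val != val:  # NaN guard for pathological graphs
            val = 0.0
        out[name] = val
    return out


_REGISTRY = frozenset(DEFAULT_DESCRIPTOR_NAMES)
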