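import numpy as np
import pytest

from ibvs import (FeatureSchema, close_contact_counts, detect_hydrogen_bonds,
                  detect_pi_stacking, detect_salt_bridges, electrostatic_sums,
                  ecif_pair_counts, assemble_interaction_features,
                  build_pb_schema, build_ps_schema)
from ibvs.interactions import DegenerateGeometryError, InteractionConfig
from ibvs.ligand import DEFAULT_DESCRIPTOR_NAMES, LigandTopology
from ibvs.schema import SchemaError
from ibvs.synthetic import gen_toy_complex

from oracles import contact_counts_brute, electrostatics_brute

AD_TYPES = ["A", "C", "HD", "N", "NA", "OA", "SA", "S"]


def _random_toy(rng, n_rec=None, n_lig=None):
    n_rec = n_rec or int(rng.integers(2, 11))
    n_lig = n_lig or int(rng.integers(2, 11))
    def atoms(n, offset):
        out = []
        while len(out) < n:
            xyz = tuple(rng.uniform(-4, 4, size=3) + offset)
            out.append((str(rng.choice(AD_TYPES)), xyz,
                        float(rng.uniform(-0.7, 0.7))))
        return out
    while True:
        try:
            return gen_toy_complex(atoms(n_rec, 0.0), atoms(n_lig, 2.0))
        except ValueError:
            continue


# --- close contacts -------------------------------------------------------

def test_single_contact_inside_cutoff():
    pose = gen_toy_complex([("OA", (0, 0, 0), -0.4)], [("HD", (0, 0, 2.0), 0.2)])
    assert close_contact_counts(pose, 2.5) == {"2.5(HD, OA)": 1}
    assert close_contact_counts(pose, 1.5) == {}


def test_contact_count_at_4A_counts_distances_below_cutoff():
    pose = gen_toy_complex(
        [("C", (3.0, 0, 0), 0.0), ("C", (0, 3.9, 0), 0.0), ("C", (0, 0, 4.2), 0.0)],
        [("A", (0, 0, 0), 0.0)])
    assert close_contact_counts(pose, 4.0) == {"4.0(A, C)": 2}


def test_contact_pair_naming_is_canonical():
    pose = gen_toy_complex([("OA", (0, 0, 0), -0.4)], [("HD", (2.0, 0, 0), 0.2)])
    counts = close_contact_counts(pose, 4.0)
    assert "4.0(HD, OA)" in counts and "4.0(OA, HD)" not in counts


def test_contact_counts_match_brute_force(rng):
    """All-pairs recount agrees on random ≤20-atom toy complexes."""
    for _ in range(25):
        pose = _random_toy(rng)
        for cutoff in (2.5, 4.0):
            assert close_contact_counts(pose, cutoff) == \
                contact_counts_brute(pose, cutoff)


def test_counts_monotone_in_cutoff(rng):
    for _ in range(10):
        pose = _random_toy(rng)
        c25, c40 = close_contact_counts(pose, 2.5), close_contact_counts(pose, 4.0)
        for key, val in c25.items():
            assert val <= c40[key.replace("2.5(", "4.0(")]


# --- electrostatics -------------------------------------------------------

def test_pairwise_energy_arithmetic():
    pose = gen_toy_complex([("OA", (0, 0, 0), 0.5)], [("N", (2.5, 0, 0), -0.5)])
    sums = electrostatic_sums(pose)
    assert sums["elec(N, OA)"] == pytest.approx(-0.1, abs=1e-12)


def test_zero_charge_gives_zero_energy():
    pose = gen_toy_complex([("C", (0, 0, 0), 0.0)], [("N", (2.0, 0, 0), -0.5)])
    assert electrostatic_sums(pose)["elec(C, N)"] == pytest.approx(0.0, abs=1e-15)


def test_energies_sum_within_type_pair():
    pose = gen_toy_complex(
        [("C", (0, 0, 0), 1.0), ("C", (0, 5, 0), 1.0)],
        [("C", (1.0, 0, 0), 1.0), ("C", (0, 3.0, 0), -1.0)])
    # (+1,+1,r=1) and (+1,-1,r=2) in the same type pair: 1 - 0.5
    sums = electrostatic_sums(pose, cutoff=2.0)
    assert sums["elec(C, C)"] == pytest.approx(0.5, abs=1e-12)


def test_coincident_atoms_are_degenerate():
    from ibvs.structio import AtomRecord, ComplexPose, MolecularStructure
    rec = MolecularStructure([AtomRecord(1, "C", "C", (0.0, 0.0, 0.0), 0.1)],
                             "receptor", "r")
    lig = MolecularStructure([AtomRecord(1, "N", "N", (0.0, 0.0, 0.0), -0.1)],
                             "ligand", "l")
    with pytest.raises(DegenerateGeometryError):
        electrostatic_sums(ComplexPose(rec, lig), cutoff=4.0)


def test_electrostatics_bilinear_in_ligand_charges(rng):
    """Scaling all ligand charges by k scales every energy by exactly k."""
    pose = _random_toy(rng)
    base = electrostatics_brute(pose, 4.0)
    k = 2.5
    scaled_lig = [(a.autodock_type, a.coords, a.partial_charge * k)
                  for a in pose.ligand.atoms]
    rec = [(a.autodock_type, a.coords, a.partial_charge) for a in pose.receptor.atoms]
    scaled = electrostatic_sums(gen_toy_complex(rec, scaled_lig))
    for key, val in electrostatic_sums(pose).items():
        assert scaled[key] == pytest.approx(k * val, rel=1e-12)
        assert val == pytest.approx(base[key], rel=1e-10)


# --- hydrogen bonds -------------------------------------------------------

def test_prototypical_hbond_detected():
    from ibvs.synthetic import toy_hbond_complex
    n, bonds = detect_hydrogen_bonds(toy_hbond_complex(1.9, 175.0))
    assert n == 1
    assert bonds[0]["acceptor_type"] == "OA"


def test_bent_geometry_rejected_by_angle_filter():
    from ibvs.synthetic import toy_hbond_complex
    n, _ = detect_hydrogen_bonds(toy_hbond_complex(1.9, 90.0))
    assert n == 0


def test_hbond_distance_cap_counts_collinear_grid():
    """HD···OA at {1.8, 2.2, 3.9, 4.1, 5.0} Å: three pass the 4.0 Å cap."""
    dists = [1.8, 2.2, 3.9, 4.1, 5.0]
    lig = []
    rec = []
    for i, d in enumerate(dists):
        y = 10.0 * i  # separate the pairs so they cannot cross-count
        lig.append(("N", (-1.0, y, 0.0), -0.3))
        lig.append(("HD", (0.0, y, 0.0), 0.2))
        rec.append(("OA", (d, y, 0.0), -0.4))
    n, _ = detect_hydrogen_bonds(gen_toy_complex(rec, lig))
    assert n == 3


# --- salt bridges ---------------------------------------------------------

def test_opposite_charges_form_salt_bridge():
    pose = gen_toy_complex([("N", (0, 0, 0), 1.0)], [("OA", (3.5, 0, 0), -1.0)])
    assert detect_salt_bridges(pose) == 1


def test_like_charges_do_not():
    pose = gen_toy_complex([("N", (0, 0, 0), 1.0)], [("N", (3.5, 0, 0), 1.0)])
    assert detect_salt_bridges(pose) == 0


def test_salt_bridge_distance_cutoff():
    rec = [("N", (0, 0, 0), 1.0), ("N", (0, 20, 0), 1.0), ("N", (0, 40, 0), 1.0)]
    lig = [("OA", (3.0, 0, 0), -1.0), ("OA", (4.4, 20, 0), -1.0),
           ("OA", (6.0, 40, 0), -1.0)]
    assert detect_salt_bridges(gen_toy_complex(rec, lig)) == 2


# --- pi stacking ----------------------------------------------------------

def _hexagon(center, z, radius=1.4):
    pts = []
    for k in range(6):
        ang = np.pi / 3 * k
        pts.append(("A", (center[0] + radius * np.cos(ang),
                          center[1] + radius * np.sin(ang), z), 0.0))
    return pts


def test_parallel_rings_stack_face_to_face():
    pose = gen_toy_complex(_hexagon((0, 0), 0.0), _hexagon((0, 0), 3.8))
    assert detect_pi_stacking(pose) == 1


def test_distant_rings_do_not_stack():
    pose = gen_toy_complex(_hexagon((0, 0), 0.0), _hexagon((0, 0), 9.0))
    assert detect_pi_stacking(pose) == 0


def test_coaxial_ring_pairs_under_centroid_cap():
    """Ligand rings at 3.5/5.0/7.5 Å: two fall under the 7.0 Å cap."""
    lig = _hexagon((0, 0), 3.5) + _hexagon((30, 0), 5.0) + _hexagon((60, 0), 7.5)
    rec = _hexagon((0, 0), 0.0) + _hexagon((30, 0), 0.0) + _hexagon((60, 0), 0.0)
    assert detect_pi_stacking(gen_toy_complex(rec, lig)) == 2


# --- ECIF pair counts -----------------------------------------------------

def test_single_pair_within_ecif_cutoff():
    topo = LigandTopology.from_smiles("CC")  # ethane: C;1;0 twice
    pose = gen_toy_complex(
        [("OA", (0, 0, 0), -0.4)],
        [("C", (5.0, 0, 0), 0.0), ("C", (6.5, 0, 0), 0.0)])
    counts = ecif_pair_counts(pose, topo)
    assert counts["ecif(O;0;0, C;1;0)"] == 1


def test_pair_outside_cutoff_not_counted():
    topo = LigandTopology.from_smiles("CC")
    pose = gen_toy_complex(
        [("OA", (0, 0, 0), -0.4)],
        [("C", (7.0, 0, 0), 0.0), ("C", (8.5, 0, 0), 0.0)])
    assert ecif_pair_counts(pose, topo) == {}


def test_ecif_distance_cutoff_counts():
    topo = LigandTopology.from_smiles("C")
    rec = [("C", (2.0, 0, 0), 0.0), ("C", (0, 4.0, 0), 0.0),
           ("C", (0, 0, 6.0), 0.0), ("C", (8.0, 0, 0), 0.0)]
    pose = gen_toy_complex(rec, [("C", (0, 0, 0), 0.0)])
    counts = ecif_pair_counts(pose, topo)
    assert sum(counts.values()) == 3


def test_ecif_requires_topology():
    pose = gen_toy_complex([("C", (0, 0, 0), 0.0)], [("C", (3.0, 0, 0), 0.0)])
    with pytest.raises(SchemaError):
        ecif_pair_counts(pose, None)


# --- assembly and schema --------------------------------------------------

def test_far_apart_pose_has_zero_interaction_features():
    topo = LigandTopology.from_smiles("CC")
    pose = gen_toy_complex([("OA", (100.0, 0, 0), -0.4)],
                           [("C", (0, 0, 0), 0.0), ("C", (1.5, 0, 0), 0.0)])
    schema = build_pb_schema(DEFAULT_DESCRIPTOR_NAMES, include_ecif=True)
    fv = assemble_interaction_features(pose, schema, ligand_topology=topo)
    inter = [n for n in schema.feature_names
             if not n.startswith("lig_") and n != "kier_flexibility"]
    assert all(fv.values[n] == 0.0 for n in inter)
    # ligand block unaffected by geometry
    assert fv.values["lig_HeavyAtomCount"] == 2.0


def test_assembly_is_deterministic():
    topo = LigandTopology.from_smiles("CCO")
    pose = gen_toy_complex(
        [("OA", (0, 0, 0), -0.4), ("C", (3.0, 0, 0), 0.1)],
        [("C", (2.0, 1.0, 0), 0.05), ("C", (3.5, 1.0, 0), 0.05),
         ("OA", (4.6, 1.8, 0), -0.4)])
    schema = build_pb_schema(DEFAULT_DESCRIPTOR_NAMES)
    fv1 = assemble_interaction_features(pose, schema, ligand_topology=topo)
    fv2 = assemble_interaction_features(pose, schema, ligand_topology=topo)
    assert fv1.values == fv2.values


def test_ps_schema_is_pb_minus_one_feature():
    pb = build_pb_schema(DEFAULT_DESCRIPTOR_NAMES)
    ps = build_ps_schema(pb)
    assert len(ps) == len(pb) - 1
    assert set(pb.feature_names) - set(ps.feature_names) == {"kier_flexibility"}

    topo = LigandTopology.from_smiles("CCO")
    pose = gen_toy_complex([("OA", (0, 0, 0), -0.4)],
                           [("C", (2.0, 1.0, 0), 0.05), ("C", (3.5, 1.0, 0), 0.05),
                            ("OA", (4.6, 1.8, 0), -0.4)])
    fv_pb = assemble_interaction_features(pose, pb, ligand_topology=topo)
    fv_ps = assemble_interaction_features(pose, ps, ligand_topology=topo)
    assert {n: v for n, v in fv_pb.values.items() if n != "kier_flexibility"} == fv_ps.values


def test_unproducible_schema_feature_is_error():
    schema = FeatureSchema("bad", ("2.5(C, C)", "mystery_feature"))
    pose = gen_toy_complex([("C", (0, 0, 0), 0.0)], [("C", (3.0, 0, 0), 0.0)])
    with pytest.raises(SchemaError, match="mystery_feature"):
        assemble_interaction_features(pose, schema)


def test_rigid_motion_invariance(rng):
    """A joint rotation+translation changes no feature by more than 1e-9."""
    from scipy.spatial.transform import Rotation
    topo = LigandTopology.from_smiles("CCO")
    pose = gen_toy_complex(
        [("OA", (0, 0, 0), -0.4), ("N", (3.0, 1.0, 0), 1.0), ("C", (2.0, -2.0, 1.0), 0.1)],
        [("C", (2.0, 1.0, 0), 0.05), ("C", (3.5, 1.0, 0), 0.05),
         ("OA", (4.6, 1.8, 0), -0.4)])
    schema = build_pb_schema(DEFAULT_DESCRIPTOR_NAMES)
    fv = assemble_interaction_features(pose, schema, ligand_topology=topo)
    R = Rotation.random(random_state=7).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    moved = type(pose)(pose.receptor.transformed(R, t),
                       pose.ligand.transformed(R, t), pose.pose_rank, pose.pose_id)
    fv2 = assemble_interaction_features(moved, schema, ligand_topology=topo)
    for name in schema.feature_names:
        assert abs(fv.values[name] - fv2.values[name]) < 1e-9


def test_mirror_image_leaves_distance_features_unchanged():
    pose = gen_toy_complex(
        [("OA", (0, 0, 0), -0.4), ("N", (3.0, 1.0, 0), 1.0)],
        [("HD", (1.9, 0, 0), 0.2), ("C", (2.9, 0.5, 1.0), 0.1)])
    mirror = np.diag([-1.0, 1.0, 1.0])
    moved = type(pose)(pose.receptor.transformed(mirror, np.zeros(3)),
                       pose.ligand.transformed(mirror, np.zeros(3)), 1, "m")
    for cutoff in (2.5, 4.0):
        assert close_contact_counts(pose, cutoff) == close_contact_counts(moved, cutoff)
    assert detect_salt_bridges(pose) == detect_salt_bridges(moved)
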