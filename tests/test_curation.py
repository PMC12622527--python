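import numpy as np
import pandas as pd
import pytest

from ibvs import (compute_scale_pos_weight, fit_maxabs, apply_maxabs,
                  label_poses, rmsd, assemble_training_set)
from ibvs.structio import AtomRecord, MolecularStructure
from ibvs.synthetic import gen_pose_set


def _mol(coords, types=None):
    types = types or ["C"] * len(coords)
    atoms = [AtomRecord(i + 1, t, t, tuple(map(float, c)), 0.0)
             for i, (t, c) in enumerate(zip(types, coords))]
    return MolecularStructure(atoms, "ligand", "m")


class TestRmsd:
    def test_identical_coordinates(self):
        m = _mol([(0, 0, 0), (1, 1, 1)])
        assert rmsd(m, m) == 0.0

    def test_uniform_translation(self):
        a = _mol([(0, 0, 0), (1, 1, 1), (2, 0, 1)])
        b = _mol([(3, 0, 0), (4, 1, 1), (5, 0, 1)])
        assert rmsd(a, b) == pytest.approx(3.0, abs=1e-12)

    def test_mixed_displacements_formula(self):
        a = _mol([(0, 0, 0), (5, 0, 0)])
        b = _mol([(1, 0, 0), (5, 2, 0)])
        assert rmsd(a, b) == pytest.approx(np.sqrt((1 + 4) / 2), abs=1e-12)

    def test_hydrogens_ignored(self):
        a = _mol([(0, 0, 0), (9, 9, 9)], ["C", "HD"])
        b = _mol([(0, 0, 0), (0, 0, 0)], ["C", "HD"])
        assert rmsd(a, b) == 0.0

    def test_atom_count_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            rmsd(_mol([(0, 0, 0)]), _mol([(0, 0, 0), (1, 0, 0)]))


class TestLabelPoses:
    def test_default_cutoffs_partition(self):
        poses, ref = gen_pose_set([1.0, 2.7, 5.0], seed=11)
        out = label_poses(poses, ref, pos_cutoff=2.0, include_reference=False)
        by_id = {e.pose_id: e for e in out}
        assert len(out) == 2  # the 2.7 Å pose falls in the discarded band
        assert by_id["synthetic_compound_pose1"].label == 1
        assert by_id["synthetic_compound_pose3"].label == 0

    def test_maximized_tolerance_cutoff(self):
        poses, ref = gen_pose_set([1.0, 2.7, 5.0], seed=11)
        out = label_poses(poses, ref, pos_cutoff=3.0, include_reference=False)
        labels = [e.label for e in sorted(out, key=lambda e: e.pose_id)]
        assert labels == [1, 1, 0]

    def test_reference_is_crystal_positive(self):
        poses, ref = gen_pose_set([5.0], seed=1)
        out = label_poses(poses, ref, pos_cutoff=2.0)
        assert out[0].provenance == "crystal" and out[0].label == 1

    def test_uniform_rmsd_simulation_counts(self):
        """RMSDs uniform on [0, 8]: ≈25% positive, ≈50% negative at 2/4 Å."""
        rng = np.random.default_rng(123)
        targets = rng.uniform(0, 8, size=100)
        poses, ref = gen_pose_set(targets, seed=5)
        out = label_poses(poses, ref, pos_cutoff=2.0, include_reference=False)
        n_pos = sum(e.label == 1 for e in out)
        n_neg = sum(e.label == 0 for e in out)
        assert n_pos == int(np.sum(targets <= 2.0))
        assert n_neg == int(np.sum(targets >= 4.0))
        assert 15 <= n_pos <= 35 and 40 <= n_neg <= 60

    def test_partition_is_exhaustive_and_exclusive(self):
        targets = np.linspace(0.05, 8.05, 33)  # off the cutoff boundaries
        poses, ref = gen_pose_set(targets, seed=3)
        out = label_poses(poses, ref, pos_cutoff=2.5, include_reference=False)
        dropped = len(targets) - len(out)
        assert dropped == int(np.sum((targets > 2.5) & (targets < 4.0)))

    def test_invalid_cutoff_order(self):
        poses, ref = gen_pose_set([1.0], seed=1)
        with pytest.raises(ValueError):
            label_poses(poses, ref, pos_cutoff=5.0, neg_cutoff=4.0)


def _frame(n, label, provenance, target="t1"):
    return pd.DataFrame({
        "pose_id": [f"{provenance}_{i}" for i in range(n)],
        "label": label, "provenance": provenance, "target_id": target,
        "f0": np.arange(n, dtype=float),
    })


class TestAssembleTrainingSet:
    def test_decoy_cap_per_target(self):
        pos = _frame(10, 1, "redock_pos")
        dec = _frame(300, 0, "decoy")
        merged = assemble_training_set(pos, dec, decoys_per_target_cap=150, seed=0)
        assert (merged["provenance"] == "decoy").sum() == 150

    def test_cap_zero_keeps_positives_only(self):
        pos = _frame(5, 1, "redock_pos")
        dec = _frame(20, 0, "decoy")
        merged = assemble_training_set(pos, dec, decoys_per_target_cap=0)
        assert len(merged) == 5

    def test_imbalance_ratio_reported(self):
        pos = _frame(5, 1, "redock_pos")
        dec = _frame(20, 0, "decoy")
        merged = assemble_training_set(pos, dec, decoys_per_target_cap=150)
        assert merged.attrs["imbalance_ratio"] == pytest.approx(4.0)

    def test_zero_positives_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            assemble_training_set(_frame(3, 0, "decoy"))

    def test_seeded_truncation_reproducible(self):
        pos = _frame(4, 1, "redock_pos")
        dec = _frame(500, 0, "decoy")
        m1 = assemble_training_set(pos, dec, decoys_per_target_cap=150, seed=9)
        m2 = assemble_training_set(pos, dec, decoys_per_target_cap=150, seed=9)
        assert m1["pose_id"].tolist() == m2["pose_id"].tolist()


class TestScalePosWeight:
    def test_quarter_positive(self):
        assert compute_scale_pos_weight([1, 1, 1] + [0] * 9) == pytest.approx(3.0)

    def test_balanced(self):
        assert compute_scale_pos_weight([1, 0, 1, 0]) == pytest.approx(1.0)

    def test_matches_reported_production_ratio(self):
        """At a 35.79 negatives-per-positive composition the weight is 35.79."""
        n_pos = 1000
        n_neg = int(round(35.79 * n_pos))
        y = np.concatenate([np.ones(n_pos), np.zeros(n_neg)])
        assert compute_scale_pos_weight(y) == pytest.approx(35.79, abs=1e-9)

    def test_balance_identity(self, rng):
        """scale_pos_weight × n_pos equals n_neg exactly."""
        y = (rng.random(500) < 0.08).astype(int)
        spw = compute_scale_pos_weight(y)
        assert spw * y.sum() == pytest.approx(len(y) - y.sum(), abs=1e-9)

    def test_no_positives_is_error(self):
        with pytest.raises(ZeroDivisionError):
            compute_scale_pos_weight([0, 0, 0])


class TestMaxAbsScaling:
    def test_worked_column(self):
        df = pd.DataFrame({"x": [-2.0, 1.0, 4.0]})
        state = fit_maxabs(df)
        out = apply_maxabs(df, state)
        assert out["x"].tolist() == pytest.approx([-0.5, 0.25, 1.0])

    def test_all_zero_column_unchanged(self):
        df = pd.DataFrame({"z": [0.0, 0.0, 0.0]})
        state = fit_maxabs(df)
        assert state.scales["z"] == 1.0
        assert apply_maxabs(df, state)["z"].tolist() == [0.0, 0.0, 0.0]

    def test_unseen_value_scales_linearly(self):
        train = pd.DataFrame({"x": [-2.0, 1.0, 4.0]})
        state = fit_maxabs(train)
        out = apply_maxabs(pd.DataFrame({"x": [8.0]}), state)
        assert out["x"].iloc[0] == pytest.approx(2.0)

    def test_roundtrip_invertible(self, rng):
        df = pd.DataFrame(rng.normal(scale=7.0, size=(40, 6)),
                          columns=[f"c{i}" for i in range(6)])
        state = fit_maxabs(df)
        scaled = apply_maxabs(df, state)
        back = scaled * pd.Series(state.scales)
        assert np.max(np.abs(back.to_numpy() - df.to_numpy())) < 1e-12
        assert scaled.to_numpy().min() >= -1.0 and scaled.to_numpy().max() <= 1.0

    def test_schema_mismatch_on_apply(self):
        state = fit_maxabs(pd.DataFrame({"x": [1.0]}))
        with pytest.raises(ValueError, match="no scale"):
            apply_maxabs(pd.DataFrame({"y": [1.0]}), state)

    def test_scaler_json_roundtrip(self, tmp_path):
        state = fit_maxabs(pd.DataFrame({"x": [-3.0, 2.0]}), schema_id="PB")
        path = tmp_path / "scaler.json"
        state.to_json(path)
        loaded = type(state).from_json(path)
        assert loaded.scales == state.scales and loaded.schema_id == "PB"
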