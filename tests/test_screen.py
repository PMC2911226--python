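import itertools

import numpy as np
import pytest

from cycloscan import screen as sc
from cycloscan.screen import (
    MCParams,
    Peptide,
    PlacementError,
    generate_library,
    mc_sample,
    peptide_seed,
    place_peptide,
    run_screen,
    s2_distance,
    sampling_energy,
    score_energy,
    tether_penalty,
)


class TestGenerateLibrary:
    def test_standard_alphabet_gives_400(self):
        lib = generate_library()
        assert len(lib) == 400
        assert len({p.sequence for p in lib}) == 400
        assert all(p.sequence.endswith("GP") for p in lib)

    def test_singleton_alphabet(self):
        lib = generate_library("A")
        assert [p.sequence for p in lib] == ["AAGP"]

    def test_two_letter_enumeration(self):
        lib = generate_library("DF")
        assert [(p.p3, p.p2) for p in lib] == [
            ("D", "D"), ("D", "F"), ("F", "D"), ("F", "F")
        ]

    def test_deterministic_order(self):
        assert [p.sequence for p in generate_library("WAC")] == [
            p.sequence for p in generate_library("CAW")
        ]

    def test_empty_alphabet_rejected(self):
        with pytest.raises(ValueError):
            generate_library("")

    def test_invalid_letter_rejected(self):
        with pytest.raises(ValueError):
            Peptide(p3="X", p2="A")


class TestPlacePeptide:
    def test_glycine_peptide_anchor_rmsd(self, aromatic_scene):
        pose = place_peptide(
            Peptide(p3="G", p2="G"),
            aromatic_scene["receptor"], aromatic_scene["template"],
            aromatic_scene["map"],
        )
        d = pose.structure.coord[pose.anchor_atom_indices] - pose.anchor_reference
        rmsd = np.sqrt((d**2).sum(axis=1).mean())
        assert rmsd < 0.1

    def test_different_peptides_share_anchor(self, aromatic_scene):
        args = (aromatic_scene["receptor"], aromatic_scene["template"],
                aromatic_scene["map"])
        p1 = place_peptide(Peptide(p3="D", p2="W"), *args)
        p2 = place_peptide(Peptide(p3="K", p2="S"), *args)
        np.testing.assert_allclose(p1.anchor_reference, p2.anchor_reference)
        np.testing.assert_allclose(
            p1.structure.coord[p1.anchor_atom_indices],
            p2.structure.coord[p2.anchor_atom_indices],
            atol=1e-6,
        )

    def test_template_without_ligand_raises(self, aromatic_scene):
        with pytest.raises(PlacementError, match="Gly-Pro ligand"):
            place_peptide(
                Peptide(p3="A", p2="A"),
                aromatic_scene["receptor"],
                aromatic_scene["receptor"],  # receptor alone: no ligand
                aromatic_scene["map"],
            )

    def test_known_transform_recovered(self, aromatic_scene, rng):
        # transform the template rigidly; anchor must follow it exactly
        from _oracles import random_rotation

        rot = random_rotation(rng)
        t = np.array([5.0, -3.0, 7.0])
        template = aromatic_scene["template"].transformed(rot, t)
        pose = place_peptide(
            Peptide(p3="A", p2="A"),
            aromatic_scene["receptor"], template, aromatic_scene["map"],
        )
        base = place_peptide(
            Peptide(p3="A", p2="A"),
            aromatic_scene["receptor"], aromatic_scene["template"],
            aromatic_scene["map"],
        )
        np.testing.assert_allclose(
            pose.anchor_reference,
            base.anchor_reference @ rot.T + t,
            atol=1e-9,
        )


class TestTetherPenalty:
    def test_zero_at_anchor(self, aromatic_scene):
        pose = place_peptide(
            Peptide(p3="G", p2="G"),
            aromatic_scene["receptor"], aromatic_scene["template"],
            aromatic_scene["map"],
        )
        pose.structure.coord[pose.anchor_atom_indices] = pose.anchor_reference
        assert tether_penalty(pose, 10.0) == 0.0

    def test_single_displaced_atom(self, aromatic_scene):
        pose = place_peptide(
            Peptide(p3="G", p2="G"),
            aromatic_scene["receptor"], aromatic_scene["template"],
            aromatic_scene["map"],
        )
        pose.structure.coord[pose.anchor_atom_indices] = pose.anchor_reference
        pose.structure.coord[pose.anchor_atom_indices[0]] += [1.0, 0.0, 0.0]
        assert tether_penalty(pose, 10.0) == pytest.approx(10.0)

    def test_hand_sum(self, aromatic_scene):
        pose = place_peptide(
            Peptide(p3="G", p2="G"),
            aromatic_scene["receptor"], aromatic_scene["template"],
            aromatic_scene["map"],
        )
        pose.structure.coord[pose.anchor_atom_indices] = pose.anchor_reference
        for i, d in zip(pose.anchor_atom_indices[:3], (0.5, 1.0, 2.0)):
            pose.structure.coord[i] += [0.0, 0.0, d]
        assert tether_penalty(pose, 2.0) == pytest.approx(2 * (0.25 + 1 + 4))


class TestScoring:
    def test_separated_pose_scores_exactly_zero(self, aromatic_scene, model):
        pose = place_peptide(
            Peptide(p3="D", p2="W"),
            aromatic_scene["receptor"], aromatic_scene["template"],
            aromatic_scene["map"],
        )
        far = pose.copy_with_coords(pose.structure.coord + np.array([500.0, 0, 0]))
        e, comp = score_energy(far, aromatic_scene["receptor"], model)
        assert comp["lj"] == 0.0 and comp["coulomb"] == 0.0 and comp["hbond"] == 0.0
        # strain is conformational, not interaction: report separately
        assert e == pytest.approx(comp["strain"])

    def test_s2_distance_examples(self, aromatic_scene):
        rec = aromatic_scene["receptor"]
        m = aromatic_scene["map"]
        pose = place_peptide(
            Peptide(p3="A", p2="A"), rec, aromatic_scene["template"], m
        )
        gk2_ca = rec.coord[
            rec.atom_index(rec.residue_index(m.residue_number(82)), "CA")
        ]
        # brute-force scan oracle
        expect = min(
            float(np.linalg.norm(c - gk2_ca)) for c in pose.structure.coord
        )
        assert s2_distance(pose, rec, m) == pytest.approx(expect, abs=1e-12)
        # coincident atom -> 0
        shifted = pose.copy_with_coords(pose.structure.coord.copy())
        shifted.structure.coord[0] = gk2_ca
        assert s2_distance(shifted, rec, m) == 0.0
        # far translation -> >= 15
        far = pose.copy_with_coords(pose.structure.coord + 500.0)
        assert s2_distance(far, rec, m) >= 15.0

    def test_s2_requires_gk2(self, aromatic_scene):
        m = aromatic_scene["map"]
        pose = place_peptide(
            Peptide(p3="A", p2="A"),
            aromatic_scene["receptor"], aromatic_scene["template"], m,
        )
        import copy

        m2 = copy.deepcopy(m)
        m2.entries[82] = "unmapped"
        with pytest.raises(KeyError):
            s2_distance(pose, aromatic_scene["receptor"], m2)


class TestMCSample:
    def test_zero_iterations_returns_initial(self, aromatic_scene, model):
        pose = place_peptide(
            Peptide(p3="A", p2="F"),
            aromatic_scene["receptor"], aromatic_scene["template"],
            aromatic_scene["map"],
        )
        e0, _ = score_energy(pose, aromatic_scene["receptor"], model)
        rec, _ = mc_sample(
            pose, aromatic_scene["receptor"], aromatic_scene["map"], model,
            MCParams(iterations=0, seed=1),
        )
        assert rec.e_bind == pytest.approx(e0, abs=1e-9)
        assert rec.accepted_moves == 0
        np.testing.assert_allclose(
            rec.pose.structure.coord, pose.structure.coord, atol=1e-12
        )

    def test_same_seed_bit_identical(self, aromatic_scene, model):
        pose = place_peptide(
            Peptide(p3="D", p2="Y"),
            aromatic_scene["receptor"], aromatic_scene["template"],
            aromatic_scene["map"],
        )
        params = MCParams(iterations=3000, seed=42, log_interval=500)
        r1, t1 = mc_sample(
            pose, aromatic_scene["receptor"], aromatic_scene["map"], model, params
        )
        r2, t2 = mc_sample(
            pose, aromatic_scene["receptor"], aromatic_scene["map"], model, params
        )
        assert r1.e_bind == r2.e_bind
        assert r1.d_s2 == r2.d_s2
        assert r1.n_hb == r2.n_hb
        assert r1.accepted_moves == r2.accepted_moves
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_array_equal(
            r1.pose.structure.coord, r2.pose.structure.coord
        )

    def test_best_so_far_trace_monotone(self, aromatic_scene, model):
        pose = place_peptide(
            Peptide(p3="E", p2="W"),
            aromatic_scene["receptor"], aromatic_scene["template"],
            aromatic_scene["map"],
        )
        _, trace = mc_sample(
            pose, aromatic_scene["receptor"], aromatic_scene["map"], model,
            MCParams(iterations=5000, seed=5, log_interval=100),
        )
        assert np.all(np.diff(trace) <= 1e-9)

    def test_zero_temperature_is_greedy(self, aromatic_scene, model):
        pose = place_peptide(
            Peptide(p3="A", p2="F"),
            aromatic_scene["receptor"], aromatic_scene["template"],
            aromatic_scene["map"],
        )
        e0 = sampling_energy(pose, aromatic_scene["receptor"], model)
        rec, trace = mc_sample(
            pose, aromatic_scene["receptor"], aromatic_scene["map"], model,
            MCParams(iterations=2000, seed=9, temperature=0.0, log_interval=100),
        )
        # greedy: the final (current) state equals the best state, and the
        # best objective never exceeds the initial one
        e_best = sampling_energy(rec.pose, aromatic_scene["receptor"], model)
        assert e_best <= e0 + 1e-9

    def test_discrete_nine_state_exhaustive_oracle(self, aromatic_scene, model):
        pose0 = place_peptide(
            Peptide(p3="A", p2="F"),
            aromatic_scene["receptor"], aromatic_scene["template"],
            aromatic_scene["map"],
        )
        grid = (-60.0, 60.0, 180.0)
        params = MCParams(
            iterations=2000, seed=11, temperature=3000.0,
            discrete_angles=grid,
            move_weights={
                "peptide_chi": 1.0, "peptide_backbone": 0.0, "gatekeeper_chi": 0.0
            },
            log_interval=200,
        )
        rec, _ = mc_sample(
            pose0, aromatic_scene["receptor"], aromatic_scene["map"], model, params
        )
        mc_best = sampling_energy(rec.pose, aromatic_scene["receptor"], model)
        # independent exhaustive enumeration over the 3^2 = 9 grid states
        torsions = sc._peptide_chi_torsions(pose0)
        assert len(torsions) == 2
        best = np.inf
        for vals in itertools.product(grid, repeat=len(torsions)):
            p = pose0.copy_with_coords(pose0.structure.coord)
            for t, v in zip(sc._peptide_chi_torsions(p), vals):
                t.set_value(p.structure.coord, v)
            best = min(best, sampling_energy(p, aromatic_scene["receptor"], model))
        assert mc_best == pytest.approx(best, abs=1e-6)

    def test_zero_weight_move_set_rejected(self, aromatic_scene, model):
        with pytest.raises(ValueError):
            MCParams(move_weights={"peptide_chi": 0.0})

    def test_glycine_only_peptide_still_samples_backbone(self, aromatic_scene, model):
        pose = place_peptide(
            Peptide(p3="G", p2="G"),
            aromatic_scene["receptor"], aromatic_scene["template"],
            aromatic_scene["map"],
        )
        rec, _ = mc_sample(
            pose, aromatic_scene["receptor"], aromatic_scene["map"], model,
            MCParams(iterations=500, seed=2, log_interval=100),
        )
        assert rec.accepted_moves >= 0


class TestRunScreen:
    def test_four_records_in_library_order(self, aromatic_scene, model):
        lib = generate_library("DF")
        params = MCParams(iterations=200, seed=3, log_interval=100)
        recs = run_screen(
            aromatic_scene["receptor"], aromatic_scene["map"], lib, model, params,
            aromatic_scene["template"],
        )
        assert [r.peptide.sequence for r in recs] == [p.sequence for p in lib]
        assert all(r.status == "ok" for r in recs)

    def test_rerun_identical_table(self, aromatic_scene, model):
        lib = generate_library("DW")
        params = MCParams(iterations=500, seed=17, log_interval=100)
        a = run_screen(
            aromatic_scene["receptor"], aromatic_scene["map"], lib, model, params,
            aromatic_scene["template"],
        )
        b = run_screen(
            aromatic_scene["receptor"], aromatic_scene["map"], lib, model, params,
            aromatic_scene["template"],
        )
        for ra, rb in zip(a, b):
            assert ra.e_bind == rb.e_bind
            assert ra.d_s2 == rb.d_s2
            assert ra.n_hb == rb.n_hb

    def test_per_peptide_seeds_differ(self):
        assert peptide_seed(1, "AAGP") != peptide_seed(1, "ACGP")
        assert peptide_seed(1, "AAGP") != peptide_seed(2, "AAGP")
        assert peptide_seed(5, "WYGP") == peptide_seed(5, "WYGP")

    def test_failed_placement_recorded_not_raised(self, aromatic_scene, model):
        lib = generate_library("A")
        recs = run_screen(
            aromatic_scene["receptor"], aromatic_scene["map"], lib, model,
            MCParams(iterations=10, seed=0),
            aromatic_scene["receptor"],  # no Gly-Pro ligand -> placement fails
        )
        assert len(recs) == 1
        assert recs[0].status.startswith("failed")
        assert np.isnan(recs[0].e_bind)

    def test_partial_flush(self, aromatic_scene, model, tmp_path):
        out = tmp_path / "screen.tsv"
        lib = generate_library("A")
        run_screen(
            aromatic_scene["receptor"], aromatic_scene["map"], lib, model,
            MCParams(iterations=100, seed=0, log_interval=50),
            aromatic_scene["template"], out_path=out,
        )
        lines = out.read_text().strip().splitlines()
        assert lines[0].split("\t")[:3] == ["peptide", "e_bind", "d_s2"]
        assert len(lines) == 2
        assert lines[1].startswith("AAGP\t")

    def test_empty_library_rejected(self, aromatic_scene, model):
        with pytest.raises(ValueError):
            run_screen(
                aromatic_scene["receptor"], aromatic_scene["map"], [], model,
                MCParams(iterations=1), aromatic_scene["template"],
            )
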