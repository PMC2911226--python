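import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import horn_superpose_rmsd, random_rotation
from cycloscan.core import Structure
from cycloscan.peptide import build_peptide
from cycloscan.structures import (
    ActiveSiteMap,
    DomainAlignment,
    align_sequences,
    classify_loops,
    classify_position121,
    kabsch_superpose,
    map_active_site,
    superpose_domains,
)


def chain(seq: str, res_ids=None) -> Structure:
    return build_peptide(seq, res_ids=res_ids).structure


def delete_residues(s: Structure, res_ids) -> Structure:
    keep = [i for i, rid in enumerate(s.residue_ids()) if rid not in set(res_ids)]
    return s.extract_residues(keep)


class TestAlignSequences:
    def test_identical_sequences(self):
        a = chain("ACDEFGHIKL")
        aln = align_sequences(a, a)
        assert aln.identity_fraction == 1.0
        assert aln.coverage == 1.0
        assert len(aln.pairs) == 10

    def test_truncated_partner(self):
        a = chain("ACDEF")
        b = chain("ACDE")
        aln = align_sequences(a, b)
        assert aln.coverage == pytest.approx(0.8)
        assert aln.identity_fraction == 1.0

    def test_identity_matches_brute_force_column_count(self):
        # two 20-mers differing at 4 positions, no gaps
        sa = "ACDEFGHIKLMNPQRSTVWY"
        sb = "ACDEFAHIKLANPQRSTAWA"
        n_same = sum(1 for x, y in zip(sa, sb) if x == y)
        assert n_same == 16
        aln = align_sequences(chain(sa), chain(sb))
        assert len(aln.pairs) == 20
        assert aln.identity_fraction == pytest.approx(n_same / 20)

    def test_empty_structure_rejected(self):
        a = chain("ACD")
        with pytest.raises(ValueError):
            align_sequences(a, a.extract_residues([]))

    def test_crossing_pairs_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            DomainAlignment(np.array([[0, 1], [1, 0]]), 1.0, 1.0)


class TestKabsch:
    def test_self_superposition_zero(self, rng):
        pts = rng.standard_normal((10, 3))
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0)

    def test_rigid_motion_recovered(self, rng):
        pts = rng.standard_normal((12, 3)) * 5
        rot90 = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        moved = pts @ rot90.T + np.array([1.0, 2.0, 3.0])
        sup = kabsch_superpose(pts, moved)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.apply(moved), pts, atol=1e-9)

    def test_matches_independent_quaternion_oracle(self, rng):
        for n in (4, 7, 23, 50):
            a = rng.standard_normal((n, 3)) * 3
            b = rng.standard_normal((n, 3)) * 3
            assert kabsch_superpose(a, b).rmsd == pytest.approx(
                horn_superpose_rmsd(a, b), abs=1e-8
            )

    def test_noncongruent_four_points(self, rng):
        a = rng.standard_normal((4, 3))
        b = a + rng.standard_normal((4, 3)) * 0.3
        assert kabsch_superpose(a, b).rmsd == pytest.approx(
            horn_superpose_rmsd(a, b), abs=1e-8
        )

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_rmsd_invariant_under_rigid_motion(self, seed):
        g = np.random.default_rng(seed)
        a = g.standard_normal((8, 3))
        b = g.standard_normal((8, 3))
        base = kabsch_superpose(a, b).rmsd
        rot = random_rotation(g)
        t = g.uniform(-20, 20, 3)
        assert kabsch_superpose(a @ rot.T + t, b).rmsd == pytest.approx(base, abs=1e-8)
        assert kabsch_superpose(a, b @ rot.T + t).rmsd == pytest.approx(base, abs=1e-8)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_no_reflection(self):
        # mirrored points must still give det(+1) rotation
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        sup = kabsch_superpose(pts, mirrored)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0)
        assert sup.rmsd > 0.1


class TestSuperposeDomains:
    def test_self_identity_zero(self, chain160):
        aln = DomainAlignment.identity(chain160)
        sup = superpose_domains(chain160, chain160, aln)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_missing_sidechain_atoms_intersected(self):
        a = chain("AFKW")
        b = a.copy()
        # delete PHE sidechain beyond CB in b
        sl = b.residue_slice(1)
        drop = [
            j for j in range(sl.start, sl.stop)
            if b.atom_name[j] in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
        ]
        keep = np.setdiff1d(np.arange(b.n_atoms), drop)
        b = Structure(
            id=b.id, chain=b.chain, atom_name=b.atom_name[keep],
            element=b.element[keep], res_id=b.res_id[keep],
            res_name=b.res_name[keep], coord=b.coord[keep],
        )
        aln = align_sequences(a, b)
        full = superpose_domains(a, a, DomainAlignment.identity(a))
        sup = superpose_domains(a, b, aln)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert sup.n_atoms == full.n_atoms - len(drop)

    def test_gaussian_noise_rmsd_matches_expectation(self, chain160, rng):
        sigma = 0.5
        noisy = chain160.copy()
        noisy.coord = noisy.coord + sigma * rng.standard_normal(noisy.coord.shape)
        aln = DomainAlignment.identity(chain160)
        sup = superpose_domains(chain160, noisy, aln)
        expected = sigma * np.sqrt(3.0)
        assert abs(sup.rmsd - expected) / expected < 0.10
        # exact recomputation over the matched atom list
        from cycloscan.structures import matched_coordinates

        ca, cb, _ = matched_coordinates(chain160, noisy, aln, "all")
        assert sup.rmsd == pytest.approx(kabsch_superpose(ca, cb).rmsd, abs=1e-12)

    def test_swap_inverts_transform_keeps_rmsd(self, rng):
        a = chain("ACDEFGHIKL")
        b = a.copy()
        b.coord = b.coord + 0.3 * rng.standard_normal(b.coord.shape)
        aln = DomainAlignment.identity(a)
        sup_ab = superpose_domains(a, b, aln)
        sup_ba = superpose_domains(b, a, aln)
        assert sup_ab.rmsd == pytest.approx(sup_ba.rmsd, abs=1e-8)
        np.testing.assert_allclose(
            sup_ba.rotation, sup_ab.rotation.T, atol=1e-8
        )
        np.testing.assert_allclose(
            sup_ba.translation,
            -sup_ab.rotation.T @ sup_ab.translation,
            atol=1e-8,
        )

    def test_ca_only_mode(self, chain160):
        aln = DomainAlignment.identity(chain160)
        sup = superpose_domains(chain160, chain160, aln, atom_set="ca")
        assert sup.n_atoms == chain160.n_residues


class TestActiveSiteMap:
    def test_toy_self_map_is_identity(self, aromatic_scene):
        rec = aromatic_scene["receptor"]
        ref_like = rec  # toy uses reference numbering directly
        aln = DomainAlignment.identity(rec)
        m = map_active_site(rec, ref_like, aln)
        assert m[55] == ("ARG", 55)
        assert m[121] == ("TRP", 121)
        assert m[103] == ("ALA", 103)

    def test_total_and_idempotent(self, aromatic_scene):
        rec = aromatic_scene["receptor"]
        aln = DomainAlignment.identity(rec)
        m1 = map_active_site(rec, rec, aln)
        m2 = map_active_site(rec, rec, aln)
        assert m1.entries == m2.entries
        assert set(m1.entries) == {
            55, 60, 61, 63, 73, 81, 82, 101, 103, 107, 110, 111, 113, 121, 122, 126
        }

    def test_gap_propagates_to_unmapped(self, aromatic_scene):
        rec = aromatic_scene["receptor"]
        aln = DomainAlignment.identity(rec)
        idx73 = rec.residue_index(73)
        pruned = DomainAlignment(
            aln.pairs[aln.pairs[:, 0] != idx73], 1.0, 1.0
        )
        m = map_active_site(rec, rec, pruned)
        assert m[73] == "unmapped"
        assert m.is_mapped(82)

    def test_missing_reference_residue_raises(self, aromatic_scene):
        rec = aromatic_scene["receptor"]
        bad_ref = delete_residues(rec, [55])
        with pytest.raises(KeyError, match="55"):
            map_active_site(rec, bad_ref, DomainAlignment.identity(bad_ref))


class TestPosition121:
    @pytest.mark.parametrize(
        "res,label,note",
        [
            ("TRP", "permissive", ""),
            ("HIS", "permissive", ""),
            ("TYR", "non-permissive", ""),
            ("GLU", "non-permissive", ""),
            ("LYS", "non-permissive", "novel residue"),
        ],
    )
    def test_labels(self, aromatic_scene, res, label, note):
        m = ActiveSiteMap(
            {
                **{p: ("ALA", p) for p in (
                    55, 60, 61, 63, 73, 81, 82, 101, 103, 107, 110, 111, 113, 122, 126
                )},
                121: (res, 121),
            }
        )
        got_label, got_note = classify_position121(m)
        assert got_label == label
        assert got_note == note

    def test_unmapped_raises(self):
        m = ActiveSiteMap(
            {
                **{p: ("ALA", p) for p in (
                    55, 60, 61, 63, 73, 81, 82, 101, 103, 107, 110, 111, 113, 122, 126
                )},
                121: "unmapped",
            }
        )
        with pytest.raises(KeyError):
            classify_position121(m)


class TestClassifyLoops:
    def test_self_comparison(self, chain160):
        aln = DomainAlignment.identity(chain160)
        cls = classify_loops(chain160, chain160, aln)
        assert (cls.b1b2, cls.a1b3, cls.a2b8) == (
            "full-length", "PPIA-class", "standard"
        )

    def test_b1b2_deletion_by_construction(self, chain160):
        target = delete_residues(chain160, [12, 13, 14, 15])
        aln = align_sequences(chain160, target)
        cls = classify_loops(target, chain160, aln)
        assert cls.b1b2 == "deleted"

    def test_a1b3_shorter_loop(self, chain160):
        target = delete_residues(chain160, [44, 45, 46])
        aln = align_sequences(chain160, target)
        cls = classify_loops(target, chain160, aln)
        assert cls.a1b3 == "short"

    def test_a2b8_alternate_conformation(self, chain160, rng):
        target = chain160.copy()
        ids = target.res_id
        loop = (ids >= 146) & (ids <= 155)
        target.coord = target.coord.copy()
        target.coord[loop] += np.array([0.0, 0.0, 4.0])
        aln = DomainAlignment.identity(chain160)
        cls = classify_loops(target, chain160, aln)
        assert cls.a2b8 == "alternate"
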