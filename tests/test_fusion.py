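"""Align-and-splice fusion and cyclic closure."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from strandlink.fixtures import RepeatProteinSpec, build_dhr, build_ideal_helix
from strandlink.fusion import (
    annotate_repeats,
    align_and_splice,
    assemble_ring,
    closure_check,
    idealize_cn,
    sample_fusion_points,
    validate_fusion_contacts,
)
from strandlink.geometry import RigidTransform, superimpose


def rotz(angle_deg, translation=(0.0, 0.0, 0.0)):
    return RigidTransform(
        Rotation.from_euler("z", angle_deg, degrees=True).as_matrix(),
        np.array(translation, dtype=float),
    )


class TestAnnotate:
    def test_finds_all_windows_with_tiny_rmsd(self, dhr4, dhr_spec):
        ann = annotate_repeats(dhr4, dhr_spec.repeat_len)
        assert len(ann.windows) == 4
        ca = dhr4.backbone_coords("A")
        for (a0, a1), (b0, b1) in zip(ann.windows, ann.windows[1:]):
            _, rmsd = superimpose(ca[a0 - 1 : a1], ca[b0 - 1 : b1])
            assert rmsd < 1e-6

    def test_wrong_repeat_length_is_error(self, dhr4):
        # 19 is incommensurate with the true repeat, so consecutive windows
        # never superpose; note a lone ideal helix is genuinely periodic at
        # any window length and is NOT an error case
        with pytest.raises(ValueError, match="no repeat"):
            annotate_repeats(dhr4, 19)

    def test_tolerates_coordinate_noise(self, dhr4, dhr_spec, rng):
        noisy = dhr4.copy()
        for _, res in noisy.residues():
            for atom in res.atoms.values():
                atom.coord = atom.coord + rng.normal(scale=0.2 / np.sqrt(3), size=3)
        ann = annotate_repeats(noisy, dhr_spec.repeat_len)
        assert len(ann.windows) == 4
        ca = noisy.backbone_coords("A")
        for (a0, a1), (b0, b1) in zip(ann.windows, ann.windows[1:]):
            _, rmsd = superimpose(ca[a0 - 1 : a1], ca[b0 - 1 : b1])
            assert rmsd < 0.4


class TestSplice:
    def test_self_splice_is_identity(self, dhr4, dhr_spec):
        ann = annotate_repeats(dhr4, dhr_spec.repeat_len)
        res = align_and_splice(dhr4, ann, dhr4.copy(), ann, (2, 2))
        assert res.fused.n_residues() == dhr4.n_residues()
        _, rmsd = superimpose(
            res.fused.backbone_coords("A"), dhr4.backbone_coords("A")
        )
        assert rmsd < 1e-6

    def test_fused_length_is_exact_index_arithmetic(self, dhr_spec):
        a = build_dhr(RepeatProteinSpec(4))
        b = build_dhr(RepeatProteinSpec(3))
        ann_a = annotate_repeats(a, dhr_spec.repeat_len)
        ann_b = annotate_repeats(b, dhr_spec.repeat_len)
        res = align_and_splice(a, ann_a, b, ann_b, (3, 2))
        L = dhr_spec.repeat_len
        junction_a = ann_a.windows[2][1]          # end of a's 3rd window
        junction_b = ann_b.windows[1][1]          # matching position in b
        expected = junction_a + (b.n_residues() - junction_b)
        assert res.fused.n_residues() == expected
        assert res.junction == junction_a

    def test_pose_invariance_of_b(self, dhr4, dhr_spec):
        ann = annotate_repeats(dhr4, dhr_spec.repeat_len)
        res0 = align_and_splice(dhr4, ann, dhr4.copy(), ann, (2, 3))
        R = Rotation.from_euler("xyz", [40, -25, 65], degrees=True).as_matrix()
        moved = dhr4.transformed(RigidTransform(R, np.array([12.0, 3.0, -8.0])))
        res1 = align_and_splice(dhr4, ann, moved, ann, (2, 3))
        assert np.abs(
            res1.fused.backbone_coords("A") - res0.fused.backbone_coords("A")
        ).max() < 1e-6

    def test_repeat_mismatch_rejected(self, dhr4, dhr_spec):
        ann = annotate_repeats(dhr4, dhr_spec.repeat_len)
        other = build_dhr(RepeatProteinSpec(4, helix_len=10))
        ann_o = annotate_repeats(other, RepeatProteinSpec(4, helix_len=10).repeat_len)
        with pytest.raises(ValueError, match="repeat mismatch|equal length"):
            align_and_splice(dhr4, ann, other, ann_o, (2, 2))

    def test_splice_associativity(self, dhr4, dhr_spec):
        """(a+b)+c equals a+(b+c) when all three share exact repeat geometry."""
        ann = annotate_repeats(dhr4, dhr_spec.repeat_len)
        L = dhr_spec.repeat_len
        ab = align_and_splice(dhr4, ann, dhr4.copy(), ann, (3, 2)).fused
        ann_ab = annotate_repeats(ab, L)
        abc1 = align_and_splice(ab, ann_ab, dhr4.copy(), ann, (4, 2)).fused
        bc = align_and_splice(dhr4, ann, dhr4.copy(), ann, (3, 2)).fused
        ann_bc = annotate_repeats(bc, L)
        abc2 = align_and_splice(dhr4, ann, bc, ann_bc, (3, 2)).fused
        assert abc1.n_residues() == abc2.n_residues()
        _, rmsd = superimpose(
            abc1.backbone_coords("A"), abc2.backbone_coords("A")
        )
        assert rmsd < 1e-6


class TestFusionContacts:
    def test_appendage_pointing_away_passes(self, dhr4, helix18):
        partner = helix18.transformed(
            RigidTransform(np.eye(3), np.array([200.0, 0.0, 0.0]))
        )
        ok, contacts = validate_fusion_contacts(dhr4, partner)
        assert ok and contacts == []

    def test_appendage_through_partner_fails_with_contacts(self, dhr4):
        overlapping = dhr4.transformed(
            RigidTransform(np.eye(3), np.array([1.0, 0.0, 0.0]))
        )
        ok, contacts = validate_fusion_contacts(dhr4, overlapping)
        assert not ok
        assert len(contacts) > 0

    def test_empty_partner_passes(self, dhr4):
        from strandlink.structure import Structure

        ok, contacts = validate_fusion_contacts(dhr4, Structure("empty"))
        assert ok


class TestSampling:
    def test_three_by_three_combinations(self, dhr4, dhr_spec):
        ann = annotate_repeats(dhr4, dhr_spec.repeat_len)
        succ, fail = sample_fusion_points(dhr4, ann, dhr4.copy(), ann)
        assert len(succ) + len(fail) == 9
        assert [s.rmsd for s in succ] == sorted(s.rmsd for s in succ)

    def test_single_window_sampled(self, dhr4, dhr_spec):
        ann = annotate_repeats(dhr4, dhr_spec.repeat_len)
        succ, fail = sample_fusion_points(dhr4, ann, dhr4.copy(), ann, 1)
        assert len(succ) + len(fail) == 1

    def test_incompatible_repeats_all_logged_as_failures(self, dhr4, dhr_spec):
        spec_o = RepeatProteinSpec(4, helix_len=10)
        other = build_dhr(spec_o)
        ann_a = annotate_repeats(dhr4, dhr_spec.repeat_len)
        ann_o = annotate_repeats(other, spec_o.repeat_len)
        succ, fail = sample_fusion_points(dhr4, ann_a, other, ann_o)
        assert succ == []
        assert len(fail) == 9


class TestClosure:
    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_exact_rotation_closes(self, n):
        report = closure_check(rotz(360.0 / n), n)
        assert report.closed
        assert report.angle_error == pytest.approx(0.0, abs=1e-9)
        assert report.axial_error == pytest.approx(0.0, abs=1e-9)
        assert report.composition_error < 1e-9

    def test_wrong_angle_rejected(self):
        report = closure_check(rotz(120.0), 4)
        assert not report.closed
        assert report.angle_error == pytest.approx(30.0)

    def test_axial_translation_rejected(self):
        report = closure_check(rotz(90.0, (0, 0, 5.0)), 4)
        assert not report.closed
        assert report.axial_error == pytest.approx(5.0)

    def test_identity_never_closes(self):
        assert not closure_check(RigidTransform(), 4).closed

    def test_composition_error_bounded_by_tolerance_budget(self):
        t = rotz(90.0 + 2.0, (0.1, 0.0, 0.5))
        report = closure_check(t, 4)
        assert report.closed
        probe_radius = np.sqrt(200.0)  # farthest default probe point
        bound = 4 * (np.radians(2.0) * probe_radius + 0.6)
        assert report.composition_error <= bound

    def test_off_axis_rotation_accepted(self):
        t = rotz(90.0)
        shifted = RigidTransform(
            t.rotation, t.translation + (np.eye(3) - t.rotation) @ np.array([5.0, 2.0, 0.0])
        )
        report = closure_check(shifted, 4)
        assert report.closed
        assert report.axial_error < 1e-9


class TestRing:
    def test_chains_related_by_ideal_step(self):
        asym = build_ideal_helix(8).transformed(
            RigidTransform(np.eye(3), np.array([14.0, 0.0, 0.0]))
        )
        t = rotz(89.0, (0.2, 0.0, 0.4))
        ring, clashes = assemble_ring(asym, t, 4)
        assert ring.chain_ids == ["A", "B", "C", "D"]
        assert clashes == []
        step = idealize_cn(t, 4)
        for c1, c2 in zip("ABC", "BCD"):
            assert np.abs(
                step.apply(ring.backbone_coords(c1)) - ring.backbone_coords(c2)
            ).max() < 1e-9

    def test_step_to_the_power_n_is_identity(self):
        t = rotz(91.5, (0.0, 0.1, -0.3))
        step = idealize_cn(t, 4)
        probe = np.array([[12.0, 1.0, 3.0], [-4.0, 8.0, 0.0]])
        assert np.abs(step.power(4).apply(probe) - probe).max() < 1e-9

    def test_c3_and_c4_differ_only_in_chain_count(self):
        asym = build_ideal_helix(8).transformed(
            RigidTransform(np.eye(3), np.array([14.0, 0.0, 0.0]))
        )
        r3, _ = assemble_ring(asym, rotz(120.0), 3)
        r4, _ = assemble_ring(asym, rotz(90.0), 4)
        assert len(r3.chain_ids) == 3 and len(r4.chain_ids) == 4
        assert np.array_equal(r3.backbone_coords("A"), r4.backbone_coords("A"))

    def test_clashing_ring_still_emitted_with_report(self):
        asym = build_ideal_helix(8)  # sits on the symmetry axis
        ring, clashes = assemble_ring(asym, rotz(90.0), 4)
        assert len(ring.chain_ids) == 4
        assert len(clashes) > 0
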