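"""Edge-strand docking: detection, motif placement, trimming, scoring, grafting."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from strandlink.edge_dock import (
    ScoreThresholds,
    dock_motif,
    enumerate_registers,
    find_exposed_edge_strands,
    graft_partner,
    interface_metrics,
    minimize_rigid,
    score_backbone_hbonds,
    trim_clashes,
    _merge,
    HeterodimerDock,
)
from strandlink.fixtures import build_ideal_sheet
from strandlink.geometry import RigidTransform
from strandlink.sasa import compute_sasa
from strandlink.structure import Atom, Residue, Structure


def brute_force_register_count(edge_len, motif_len, min_overlap=3):
    """Oracle: count index alignments with enough paired residues, by direct
    enumeration over every possible shift."""
    count = 0
    for offset in range(-motif_len - 2, edge_len + 3):
        paired = sum(
            1 for k in range(1, edge_len + 1) if 1 <= k - offset <= motif_len
        )
        if paired >= min_overlap:
            count += 1
    return 2 * count  # both orientations


@pytest.fixture(scope="module")
def edge_b(sheet_2x5_module):
    reports = find_exposed_edge_strands(sheet_2x5_module)
    return next(r.segment for r in reports if r.segment.chain_id == "B")


@pytest.fixture(scope="module")
def edge_b_full(sheet_2x5_module):
    """The whole 5-residue strand of chain B as a dockable segment."""
    from strandlink.structure import StrandSegment

    ca = sheet_2x5_module.backbone_coords("B")
    return StrandSegment("B", 1, 5, ca)


@pytest.fixture(scope="module")
def sheet_2x5_module():
    from strandlink.secondary import assign_secondary_structure

    s = build_ideal_sheet(2, 5, "antiparallel")
    assign_secondary_structure(s)
    return s


class TestEdgeDetection:
    def test_two_strand_sheet_reports_both(self, sheet_2x5):
        chains = {r.segment.chain_id for r in find_exposed_edge_strands(sheet_2x5)}
        assert chains == {"A", "B"}

    def test_reports_sorted_by_exposure(self, sheet_4x6):
        reports = find_exposed_edge_strands(sheet_4x6)
        exposures = [r.mean_sasa_per_residue for r in reports]
        assert exposures == sorted(exposures, reverse=True)

    def test_no_strands_gives_empty(self, helix18):
        s = helix18.copy()
        assert find_exposed_edge_strands(s) == []


class TestDockMotif:
    @pytest.mark.parametrize("m,n", [(5, 5), (4, 6), (3, 5)])
    def test_register_enumeration_matches_brute_force(self, m, n):
        assert len(enumerate_registers(m, n)) == brute_force_register_count(m, n)
        assert len(enumerate_registers(m, n)) == 2 * (m + n - 5)

    def test_docked_strand_at_sheet_spacing(self, edge_b, sheet_2x5_module):
        cand = dock_motif(edge_b, edge_b.length, "antiparallel", 0, scaffold=sheet_2x5_module)
        dmat = np.linalg.norm(
            cand.strand_ca()[:, None] - edge_b.ca_coords[None], axis=-1
        )
        nearest = dmat.min(axis=1)
        assert np.all(nearest > 3.5) and np.all(nearest < 6.0)

    def test_offset_shifts_strand_along_axis(self, edge_b_full, sheet_2x5_module):
        c0 = dock_motif(edge_b_full, edge_b_full.length, "antiparallel", 0, scaffold=sheet_2x5_module)
        c2 = dock_motif(edge_b_full, edge_b_full.length, "antiparallel", 2, scaffold=sheet_2x5_module)
        axis = edge_b_full.ca_coords[-1] - edge_b_full.ca_coords[0]
        axis /= np.linalg.norm(axis)
        shift = np.dot(c2.strand_ca().mean(axis=0) - c0.strand_ca().mean(axis=0), axis)
        # two residues of extended-strand rise, sign set by the register convention
        assert abs(abs(shift) - 2 * 3.47) < 0.7

    def test_short_motif_rejected(self, edge_b):
        with pytest.raises(ValueError):
            dock_motif(edge_b, 2, "antiparallel", 0)

    def test_insufficient_overlap_rejected(self, edge_b):
        with pytest.raises(ValueError, match="paired"):
            dock_motif(edge_b, edge_b.length, "antiparallel", edge_b.length - 2)


class TestTrim:
    def test_clash_free_candidate_unchanged(self, edge_b, sheet_2x5_module):
        cand = dock_motif(edge_b, edge_b.length, "antiparallel", 0, scaffold=sheet_2x5_module)
        trimmed = trim_clashes(cand, sheet_2x5_module)
        assert not trimmed.rejected
        assert trimmed.trimmed_length == cand.trimmed_length

    def test_constructed_terminal_clash_removes_that_residue(
        self, edge_b_full, sheet_2x5_module
    ):
        cand = dock_motif(edge_b_full, edge_b_full.length, "antiparallel", 0, scaffold=sheet_2x5_module)
        bumped = sheet_2x5_module.copy()
        # clash probe beyond the strand's first residue, away from the second
        ca0, ca1 = cand.strand_residues[0]["CA"], cand.strand_residues[1]["CA"]
        away = (ca0 - ca1) / np.linalg.norm(ca0 - ca1)
        bumped.add_chain(
            "X", [Residue(1, "G", {"O": Atom("O", "O", ca0 + 1.2 * away)})]
        )
        trimmed = trim_clashes(cand, bumped)
        assert not trimmed.rejected
        assert trimmed.trimmed_length == cand.trimmed_length - 1
        assert trimmed.strand_residues[0] is not cand.strand_residues[0]

    def test_fully_buried_strand_rejected(self, edge_b, sheet_2x5_module):
        cand = dock_motif(edge_b, edge_b.length, "antiparallel", 0, scaffold=sheet_2x5_module)
        blob = sheet_2x5_module.copy()
        atoms = {
            f"O{i}": Atom(f"O{i}", "O", r["CA"])
            for i, r in enumerate(cand.strand_residues)
        }
        blob.add_chain("X", [Residue(1, "G", atoms)])
        assert trim_clashes(cand, blob).rejected


class TestHbondScore:
    def test_ideal_antiparallel_pair_scores_four_bonds(self, sheet_2x5):
        assert score_backbone_hbonds(sheet_2x5["A"], sheet_2x5["B"]) <= -3.5

    def test_distant_strands_score_zero(self, sheet_2x5):
        far = [r.copy() for r in sheet_2x5["B"]]
        for r in far:
            for a in r.atoms.values():
                a.coord = a.coord + np.array([0.0, 8.0, 0.0])
        assert score_backbone_hbonds(sheet_2x5["A"], far) == 0.0

    def test_symmetric_in_arguments(self, sheet_2x5):
        ab = score_backbone_hbonds(sheet_2x5["A"], sheet_2x5["B"])
        ba = score_backbone_hbonds(sheet_2x5["B"], sheet_2x5["A"])
        assert ab == pytest.approx(ba, abs=1e-12)


class TestMinimize:
    @pytest.fixture(scope="class")
    def optimal_dock(self, edge_b_full, sheet_2x5_module):
        """A dock strand sitting at its H-bond optimum."""
        cand = dock_motif(
            edge_b_full, edge_b_full.length, "antiparallel", 0,
            scaffold=sheet_2x5_module,
        )
        return minimize_rigid(cand, sheet_2x5_module)

    def test_never_worsens_and_optimal_pose_barely_moves(
        self, optimal_dock, edge_b_full, sheet_2x5_module
    ):
        score0 = score_backbone_hbonds(
            edge_b_full.residues(sheet_2x5_module), optimal_dock.strand_residues
        )
        again = minimize_rigid(optimal_dock, sheet_2x5_module)
        assert again.hbond_score <= score0 + 1e-9
        assert np.abs(again.strand_ca() - optimal_dock.strand_ca()).max() < 0.1

    def test_perturbation_recovered(self, optimal_dock, sheet_2x5_module):
        from dataclasses import replace

        ideal = optimal_dock.strand_ca()
        shifted = []
        for r in optimal_dock.strand_residues:
            rc = r.copy()
            for a in rc.atoms.values():
                a.coord = a.coord + np.array([0.0, 0.0, 0.5])
            shifted.append(rc)
        pert = replace(optimal_dock, strand_residues=shifted)
        out = minimize_rigid(pert, sheet_2x5_module)
        assert np.abs(out.strand_ca() - ideal).max() < 0.15

    def test_no_basin_leaves_pose_unchanged(self, edge_b, sheet_2x5_module, caplog):
        import logging
        from dataclasses import replace

        cand = dock_motif(edge_b, edge_b.length, "antiparallel", 0, scaffold=sheet_2x5_module)
        far = []
        for r in cand.strand_residues:
            rc = r.copy()
            for a in rc.atoms.values():
                a.coord = a.coord + np.array([0.0, 8.0, 0.0])
            far.append(rc)
        pert = replace(cand, strand_residues=far)
        with caplog.at_level(logging.WARNING):
            out = minimize_rigid(pert, sheet_2x5_module)
        assert out.hbond_score == pytest.approx(0.0, abs=1e-6)
        assert np.array_equal(out.strand_ca(), pert.strand_ca())


class TestGraft:
    def test_matching_library_scaffold_found_exactly(self, edge_b, sheet_2x5_module):
        cand = dock_motif(edge_b, edge_b.length, "antiparallel", 0, scaffold=sheet_2x5_module)
        # the dock strand was cut from an ideal sheet, so an identical sheet's
        # edge strand is an exact geometric match
        library = [build_ideal_sheet(2, 5, "antiparallel")]
        library[0].name = "partner"
        docks = graft_partner(cand, sheet_2x5_module, library)
        assert len(docks) >= 1
        assert docks[0].graft_rmsd < 1e-6

    def test_pose_invariance_of_library_entry(self, edge_b, sheet_2x5_module, rng):
        cand = dock_motif(edge_b, edge_b.length, "antiparallel", 0, scaffold=sheet_2x5_module)
        lib = build_ideal_sheet(2, 5, "antiparallel")
        lib.name = "partner"
        R = Rotation.random(random_state=np.random.RandomState(11)).as_matrix()
        moved = lib.transformed(RigidTransform(R, np.array([30.0, -12.0, 7.0])))
        moved.name = "partner"
        d0 = graft_partner(cand, sheet_2x5_module, [lib])
        d1 = graft_partner(cand, sheet_2x5_module, [moved])
        assert len(d0) == len(d1) > 0

        def placements(docks):
            cents = []
            for d in docks:
                partner_chains = d.complex.chain_ids[d.complex._split:]
                ca = np.concatenate(
                    [d.complex.backbone_coords(c) for c in partner_chains]
                )
                cents.append(ca.mean(axis=0))
            return sorted(tuple(np.round(c, 4)) for c in cents)

        assert placements(d0) == placements(d1)

    def test_clashing_graft_rejected(self, edge_b, sheet_2x5_module):
        cand = dock_motif(edge_b, edge_b.length, "antiparallel", 0, scaffold=sheet_2x5_module)
        lib = build_ideal_sheet(2, 5, "antiparallel")
        lib.name = "partner"
        baseline = graft_partner(cand, sheet_2x5_module, [lib])
        # appendage on chain A's free face: any graft pairing that face with
        # scaffold A's edge now buries the appendage into scaffold A
        blob_atoms = {}
        for k, r in enumerate(lib["A"]):
            blob_atoms[f"C{k}"] = Atom("C", "C", r["CA"] + np.array([0.0, -6.5, 0.0]))
        lib2 = lib.copy()
        lib2.name = "partner+appendage"
        lib2.add_chain("X", [Residue(1, "G", blob_atoms)])
        filtered = graft_partner(cand, sheet_2x5_module, [lib2])
        assert len(filtered) < len(baseline)
        # whatever survives is genuinely clash-free against scaffold A
        from strandlink.contacts import min_distance

        a_heavy = sheet_2x5_module.heavy_coords()
        for d in filtered:
            placed = np.concatenate([
                r.heavy_coords()
                for c in d.complex.chain_ids[d.complex._split:]
                for r in d.complex[c]
            ])
            assert min_distance(placed, a_heavy) >= 2.8

    def test_empty_library(self, edge_b, sheet_2x5_module):
        cand = dock_motif(edge_b, edge_b.length, "antiparallel", 0, scaffold=sheet_2x5_module)
        assert graft_partner(cand, sheet_2x5_module, []) == []


class TestInterfaceMetrics:
    def test_distant_bodies_have_null_interface(self, sheet_2x5):
        a = sheet_2x5.copy()
        b = sheet_2x5.transformed(RigidTransform(np.eye(3), np.array([50.0, 0, 0])))
        dock = HeterodimerDock("a", "b", RigidTransform(), 0.0, _merge(a, b))
        m = interface_metrics(dock)
        assert m.buried_surface_area == pytest.approx(0.0, abs=1e-6)
        assert m.packing_contacts == 0

    def test_paired_strands_fully_satisfied(self, sheet_2x5):
        a = Structure("a")
        a.add_chain("A", [r.copy() for r in sheet_2x5["A"]])
        b = Structure("b")
        b.add_chain("A", [r.copy() for r in sheet_2x5["B"]])
        dock = HeterodimerDock("a", "b", RigidTransform(), 0.0, _merge(a, b))
        m = interface_metrics(dock)
        assert m.unsatisfied_buried_polar == 0
        assert m.buried_surface_area > 0

    def test_bsa_matches_direct_sasa_differencing(self, sheet_2x5):
        a = Structure("a")
        a.add_chain("A", [r.copy() for r in sheet_2x5["A"]])
        b = Structure("b")
        b.add_chain("A", [r.copy() for r in sheet_2x5["B"]])
        complex_ = _merge(a, b)
        dock = HeterodimerDock("a", "b", RigidTransform(), 0.0, complex_)
        m = interface_metrics(dock)
        _, sasa_a = compute_sasa(a)
        _, sasa_b = compute_sasa(b)
        _, sasa_ab = compute_sasa(complex_)
        assert m.buried_surface_area == pytest.approx(
            (sasa_a + sasa_b - sasa_ab) / 2, rel=1e-9
        )


class TestPipelineProperties:
    def test_determinism(self, edge_b, sheet_2x5_module):
        runs = []
        for _ in range(2):
            out = []
            for ori, off in enumerate_registers(edge_b.length, edge_b.length):
                c = dock_motif(edge_b, edge_b.length, ori, off, scaffold=sheet_2x5_module)
                c = trim_clashes(c, sheet_2x5_module)
                out.append((ori, off, c.rejected, c.trimmed_length))
            runs.append(out)
        assert runs[0] == runs[1]

    def test_hbond_threshold_monotonicity(self, edge_b, sheet_2x5_module):
        scores = []
        for ori, off in enumerate_registers(edge_b.length, edge_b.length):
            c = dock_motif(edge_b, edge_b.length, ori, off, scaffold=sheet_2x5_module)
            c = trim_clashes(c, sheet_2x5_module)
            if c.rejected:
                continue
            c = minimize_rigid(c, sheet_2x5_module)
            scores.append(c.hbond_score)
        survivors = [sum(1 for s in scores if s <= tmax) for tmax in (-2, -4, -6)]
        assert survivors[0] >= survivors[1] >= survivors[2]
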