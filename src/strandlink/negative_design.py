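"""Homodimer self-docking: the implicit negative-design screen.

Each protomer is docked against itself on the edge strand that forms its
heterodimer interface: for both strand orientations and every register
offset with at least three paired residues, a disembodied strand is
placed against the edge, and a second copy of the protomer is superimposed
onto that strand by its own edge strand.  The resulting homodimer models
are stripped to polyglycine (all sidechain atoms removed) and clash
checked with a quadratic soft-sphere repulsive score; docks above the
clash gate are discarded as sterically impossible.  Survivors are scored
with the heterodimer interface metrics, and the protomer is classified
monomer-compatible if no survivor looks like a viable homodimer
interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from scipy.optimize import minimize as _sp_minimize
from scipy.spatial.transform import Rotation

from .contacts import soft_sphere_repulsion
from .edge_dock import (
    InterfaceMetrics,
    HeterodimerDock,
    ScoreThresholds,
    _merge,
    dock_motif,
    enumerate_registers,
    find_exposed_edge_strands,
    interface_metrics,
)
from .geometry import RigidTransform, superimpose
from .structure import BACKBONE_ATOMS, StrandSegment, Structure

logger = logging.getLogger(__name__)

R_CLASH = 3.2   # A, soft-sphere onset
K_REP = 100.0   # A^-2, quadratic prefactor


@dataclass
class HomodimerDock:
    protomer_id: str
    orientation: str
    offset: int
    transform: RigidTransform        # places the second copy
    clash_score: float = np.nan
    passed: bool | None = None
    metrics: InterfaceMetrics | None = None


@dataclass
class ProtomerVerdict:
    protomer_id: str
    n_enumerated: int
    n_passing: int
    best_energy_proxy: float | None
    classification: str              # monomer-compatible | homodimer-prone

    def __post_init__(self):
        assert self.n_passing <= self.n_enumerated


def polyglycine(structure: Structure) -> Structure:
    """Strip all sidechain atoms (CB and beyond), keeping N, CA, C, O."""
    out = structure.copy()
    for _, res in out.residues():
        res.atoms = {k: v for k, v in res.atoms.items() if k in BACKBONE_ATOMS}
        res.aa = "G"
    return out


def enumerate_self_docks(
    protomer: Structure,
    edge: StrandSegment,
    thresholds: ScoreThresholds = ScoreThresholds(),
) -> list[HomodimerDock]:
    """Complete, deterministic enumeration of homodimer docks.

    For edge length L and minimum overlap 3 this yields 2*(2L-5) docks
    (both orientations, all offsets).  Each dock's transform superimposes
    the second copy's edge strand CA trace onto the disembodied strand
    produced by motif docking at that register.
    """
    reports = find_exposed_edge_strands(protomer, thresholds)
    if not any(
        r.segment.chain_id == edge.chain_id
        and r.segment.start <= edge.start
        and r.segment.end >= edge.end
        for r in reports
    ):
        raise ValueError("the given edge is not an exposed edge strand of the protomer")
    L = edge.length
    docks = []
    for orientation, offset in enumerate_registers(L, L, thresholds.min_overlap):
        cand = dock_motif(
            edge, L, orientation, offset, thresholds.min_overlap, scaffold=protomer
        )
        dock_ca = cand.strand_ca()
        # the second copy binds with its own edge strand running along the
        # disembodied strand in the strand's own N->C direction
        transform, rmsd = superimpose(edge.ca_coords, dock_ca)
        docks.append(
            HomodimerDock(protomer.name, orientation, offset, transform)
        )
    return docks


def clash_screen(
    dock: HomodimerDock,
    protomer: Structure,
    thresholds: ScoreThresholds = ScoreThresholds(),
) -> HomodimerDock:
    """Polyglycine conversion + soft-sphere clash gate (fail if > clash_max)."""
    gly = polyglycine(protomer)
    copy2 = gly.transformed(dock.transform)
    score = soft_sphere_repulsion(
        gly.heavy_coords(), copy2.heavy_coords(), r_clash=R_CLASH, k=K_REP
    )
    dock.clash_score = score
    dock.passed = score <= thresholds.clash_max
    return dock


def _minimize_homodimer(
    protomer: Structure,
    edge: StrandSegment,
    transform: RigidTransform,
    max_shift: float = 1.5,
    max_rot_deg: float = 15.0,
) -> RigidTransform:
    """Bounded rigid-body polish of the second copy's pose.

    Optimizes the cross-copy backbone H-bond score between the two edge
    strands, with a soft-sphere penalty keeping the copies clash-free;
    never returns a pose worse than the input.
    """
    from scipy.spatial import cKDTree

    from .fixtures import _residue_arrays, _smooth_hbond_energy, _transform_arrays

    edge_res_1 = edge.residues(protomer)
    edge_arr_1 = _residue_arrays(edge_res_1)
    heavy1_tree = cKDTree(protomer.heavy_coords())
    base = protomer.transformed(transform)
    edge_idx = set(range(edge.start, edge.end + 1))
    edge_res_2_base = [r for r in base[edge.chain_id] if r.index in edge_idx]
    edge_arr_2 = _residue_arrays(edge_res_2_base)
    base_heavy = base.heavy_coords()
    center = np.mean([r["CA"] for r in edge_res_2_base], axis=0)

    def posed(p):
        R = Rotation.from_rotvec(p[3:], degrees=True).as_matrix()
        return RigidTransform(R, center + p[:3] - R @ center)

    def objective(p):
        local = posed(p)
        score = _smooth_hbond_energy(edge_arr_1, _transform_arrays(edge_arr_2, local))
        moved_heavy = local.apply(base_heavy)
        d, _ = heavy1_tree.query(moved_heavy, k=1, distance_upper_bound=2.8)
        close = d[np.isfinite(d)]
        rep = float(((2.8 - close) ** 2).sum())
        return score + rep

    score0 = objective(np.zeros(6))
    result = _sp_minimize(
        objective,
        np.zeros(6),
        method="Powell",
        bounds=[(-max_shift, max_shift)] * 3 + [(-max_rot_deg, max_rot_deg)] * 3,
        options={"maxiter": 600, "xtol": 1e-4, "ftol": 1e-8},
    )
    if result.fun >= score0 - 1e-12:
        return transform
    return posed(result.x).compose(transform)


def assess_protomer(
    protomer: Structure,
    edge: StrandSegment,
    thresholds: ScoreThresholds = ScoreThresholds(),
    energy_cutoff: float = -3.0,
    bsa_cutoff: float = 200.0,
) -> ProtomerVerdict:
    """Run the full screen and classify homodimerization propensity.

    A protomer is monomer-compatible iff no clash-passing dock combines a
    favorable binding-energy proxy (<= energy_cutoff) with a substantial
    buried surface area (>= bsa_cutoff A^2).  The area default is
    calibrated for backbone+CB models, which bury systematically less
    area than full-atom interfaces: a full-length beta sheet-extension
    homodimer buries roughly 220 A^2 here, a marginal 3-residue-overlap
    dock well under 150 A^2.
    """
    docks = enumerate_self_docks(protomer, edge, thresholds)
    survivors = []
    for d in docks:
        clash_screen(d, protomer, thresholds)
        if d.passed:
            survivors.append(d)
    best = None
    prone = False
    for d in survivors:
        d.transform = _minimize_homodimer(protomer, edge, d.transform)
        copy2 = protomer.transformed(d.transform)
        complex_ = _merge(protomer, copy2)
        hd = HeterodimerDock(protomer.name, protomer.name, d.transform, 0.0, complex_)
        d.metrics = interface_metrics(hd)
        proxy = d.metrics.binding_energy_proxy
        if best is None or proxy < best:
            best = proxy
        if proxy <= energy_cutoff and d.metrics.buried_surface_area >= bsa_cutoff:
            prone = True
    return ProtomerVerdict(
        protomer.name,
        n_enumerated=len(docks),
        n_passing=len(survivors),
        best_energy_proxy=best,
        classification="homodimer-prone" if prone else "monomer-compatible",
    )
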