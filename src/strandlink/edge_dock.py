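"""Beta edge-strand docking.

The docking procedure mirrors the implicit-negative-design pipeline:

1. find exposed edge strands by backbone (N, O) solvent accessibility of
   strand residues;
2. align one strand of an ideal two-stranded beta motif (parallel or
   antiparallel) onto the edge strand at a chosen register offset, delete
   the aligned (clashing) strand, and keep the partner as a disembodied
   "dock" strand;
3. trim the dock strand's termini against clashes with the host scaffold
   and locally minimize its rigid-body pose to optimize backbone-backbone
   hydrogen bonds;
4. discard docks whose backbone H-bond score misses a threshold;
5. graft a second scaffold from a library by superimposing one of its own
   exposed edge strands onto the dock strand, yielding a docked
   protein-protein complex with interface metrics.

The H-bond score is a smooth well calibrated so one ideal backbone
hydrogen bond scores about -1; the default acceptance threshold of -4
therefore reads "at least four good hydrogen bonds".  Scores, clash
distances and tolerances are all configurable through ScoreThresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .contacts import close_pairs, count_contacts, min_distance
from .fixtures import build_ideal_sheet
from .geometry import RigidTransform, superimpose
from .sasa import backbone_polar_sasa, compute_sasa
from .secondary import assign_secondary_structure, reconstruct_amide_h, strand_runs
from .structure import Residue, StrandSegment, Structure

logger = logging.getLogger(__name__)

ORIENTATIONS = ("parallel", "antiparallel")


@dataclass(frozen=True)
class ScoreThresholds:
    """Configurable gates of the docking pipeline."""

    hbond_max: float = -4.0          # dock H-bond score must be <= this
    clash_max: float = 250.0         # homodimer repulsive-score gate
    graft_rmsd: float = 0.75         # A, edge-strand-onto-dock-strand fit
    edge_sasa_min: float = 15.0      # A^2 mean backbone N+O SASA per residue
    clash_distance: float = 2.8      # A, heavy-atom clash during trim/graft
    min_overlap: int = 3             # paired residues per register

    def __post_init__(self):
        if self.graft_rmsd <= 0:
            raise ValueError("graft rmsd tolerance must be positive")


@dataclass
class EdgeStrandReport:
    segment: StrandSegment
    backbone_sasa: float                 # summed N+O SASA over the strand, A^2
    free_face: list[bool] = field(default_factory=list)

    @property
    def mean_sasa_per_residue(self) -> float:
        return self.backbone_sasa / self.segment.length


@dataclass
class DockCandidate:
    scaffold_id: str
    edge: StrandSegment
    strand_residues: list[Residue]       # the disembodied dock strand
    orientation: str
    offset: int
    trimmed_length: int
    hbond_score: float = 0.0
    rejected: bool = False

    def strand_ca(self) -> np.ndarray:
        return np.array([r["CA"] for r in self.strand_residues])


@dataclass
class InterfaceMetrics:
    buried_surface_area: float           # A^2, delta-SASA / 2
    shape_complementarity: float         # dimensionless proxy in [-1, 1]
    unsatisfied_buried_polar: int
    packing_contacts: int
    hbond_score: float

    @property
    def binding_energy_proxy(self) -> float:
        """H-bond score plus a weak packing reward; a proxy, not an energy."""
        return self.hbond_score - 0.01 * self.packing_contacts


@dataclass
class HeterodimerDock:
    scaffold_a: str
    scaffold_b: str
    transform: RigidTransform            # places scaffold B
    graft_rmsd: float
    complex: Structure
    metrics: InterfaceMetrics | None = None


# -- edge strand detection -------------------------------------------------


def find_exposed_edge_strands(
    structure: Structure, thresholds: ScoreThresholds = ScoreThresholds()
) -> list[EdgeStrandReport]:
    """Strand runs whose backbone N/O face is solvent exposed.

    Requires secondary structure; assigns it if missing.  Results are
    sorted by mean per-residue exposure, most exposed first.
    """
    if not structure.ss:
        assign_secondary_structure(structure)
    polar = backbone_polar_sasa(structure)
    reports = []
    for cid, start, end in strand_runs(structure, min_len=3):
        chain = {r.index: r for r in structure[cid]}
        per_res = [polar.get((cid, i), 0.0) for i in range(start, end + 1)]
        total = float(sum(per_res))
        if total / (end - start + 1) < thresholds.edge_sasa_min:
            continue
        ca = np.array([chain[i]["CA"] for i in range(start, end + 1)])
        seg = StrandSegment(cid, start, end, ca)
        reports.append(
            EdgeStrandReport(
                seg, total, [a >= thresholds.edge_sasa_min for a in per_res]
            )
        )
    reports.sort(key=lambda r: -r.mean_sasa_per_residue)
    return reports


# -- motif docking ---------------------------------------------------------


def _register_offsets(edge_len: int, motif_len: int, min_overlap: int):
    """All offsets with >= min_overlap paired residues.

    Offset o pairs edge residue (1-based, within segment) k with motif
    strand residue k - o; valid while both indices stay in range.
    """
    return range(-(motif_len - min_overlap), edge_len - min_overlap + 1)


def enumerate_registers(edge_len: int, motif_len: int, min_overlap: int = 3):
    """Deterministic (orientation, offset) enumeration order."""
    out = []
    for orientation in ORIENTATIONS:
        for offset in _register_offsets(edge_len, motif_len, min_overlap):
            out.append((orientation, offset))
    return out


def dock_motif(
    edge: StrandSegment,
    motif_len: int,
    orientation: str,
    offset: int,
    min_overlap: int = 3,
    scaffold: Structure | None = None,
) -> DockCandidate:
    """Place a disembodied strand against an edge strand.

    An ideal two-stranded motif of the requested orientation is aligned by
    the CA trace of its first strand onto the edge strand at the given
    register offset; the aligned strand is deleted and the partner strand
    kept.  For antiparallel motifs the partner runs opposite to the edge.

    A pleated CA trace is (nearly) two-fold symmetric about the strand
    axis, so the alignment has two solutions placing the partner on either
    face of the edge.  When `scaffold` is given, the face pointing away
    from it (the exposed face) is chosen; otherwise the branch with the
    better trace fit wins, ties broken toward the first branch.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"unknown orientation {orientation!r}")
    if motif_len < 3:
        raise ValueError("motif strands need at least 3 residues")
    edge_len = edge.length
    # paired window in segment-local 1-based indices
    lo = max(1, 1 + offset)
    hi = min(edge_len, motif_len + offset)
    overlap = hi - lo + 1
    if overlap < min_overlap:
        raise ValueError(
            f"offset {offset} leaves {overlap} paired residues (< {min_overlap})"
        )
    motif = build_ideal_sheet(2, motif_len, orientation)
    motif_ca = motif.backbone_coords("A")
    edge_window = edge.ca_coords[lo - 1 : hi]
    motif_window = motif_ca[lo - 1 - offset : hi - offset]

    transform, rmsd = superimpose(motif_window, edge_window)

    # the partner can pair either face of the edge: the second branch is the
    # placement translated across the edge by twice the perpendicular
    # inter-strand offset (the sheet-lattice image on the opposite face)
    motif_b_ca = motif.backbone_coords("B")
    dock1_ca = transform.apply(motif_b_ca)
    e_axis = edge.ca_coords[-1] - edge.ca_coords[0]
    e_axis /= np.linalg.norm(e_axis)
    u = dock1_ca.mean(axis=0) - edge.ca_coords.mean(axis=0)
    u_perp = u - np.dot(u, e_axis) * e_axis
    other = RigidTransform(np.eye(3), -2.0 * u_perp)

    branches = [transform, other.compose(transform)]
    if scaffold is not None:
        heavy = scaffold.heavy_coords()
        branches.sort(
            key=lambda tr: -min_distance(tr.apply(motif_b_ca), heavy)
        )
    full = branches[0]

    dock_res = []
    for r in motif["B"]:
        rc = r.copy()
        for a in rc.atoms.values():
            a.coord = full.apply(a.coord)
        dock_res.append(rc)
    cand = DockCandidate(
        scaffold_id="",
        edge=edge,
        strand_residues=dock_res,
        orientation=orientation,
        offset=offset,
        trimmed_length=len(dock_res),
    )
    logger.debug(
        "dock_motif %s offset %+d: motif alignment rmsd %.3f", orientation, offset, rmsd
    )
    return cand


def trim_clashes(
    cand: DockCandidate,
    scaffold: Structure,
    thresholds: ScoreThresholds = ScoreThresholds(),
) -> DockCandidate:
    """Iteratively remove clashing terminal residues of the dock strand."""
    scaffold_heavy = scaffold.heavy_coords()
    residues = list(cand.strand_residues)

    def clashes(res: Residue) -> bool:
        return min_distance(res.heavy_coords(), scaffold_heavy) < thresholds.clash_distance

    while len(residues) >= 3:
        if clashes(residues[0]):
            residues = residues[1:]
        elif clashes(residues[-1]):
            residues = residues[:-1]
        else:
            break
    rejected = len(residues) < 3 or clashes(residues[0])
    if not rejected:
        # interior clashes cannot be trimmed away
        interior = np.concatenate([r.heavy_coords() for r in residues])
        rejected = min_distance(interior, scaffold_heavy) < thresholds.clash_distance
    return replace(
        cand,
        strand_residues=residues,
        trimmed_length=len(residues),
        rejected=rejected,
    )


# -- backbone H-bond scoring -----------------------------------------------

HB_OPT_DIST = 1.9    # A, optimal H...O distance
HB_SIGMA = 0.3       # A
HB_CUTOFF = 3.2      # A, beyond this a pair contributes nothing


def _hb_atoms(residues):
    """Donor (N, H) and acceptor (C, O) arrays for a residue segment."""
    donors, acceptors = [], []
    prev = None
    for r in residues:
        if not r.has_backbone():
            prev = None
            continue
        if prev is not None and r.aa != "P":
            donors.append((r["N"], reconstruct_amide_h(prev["C"], prev["O"], r["N"])))
        acceptors.append((r["C"], r["O"]))
        prev = r
    return donors, acceptors


def score_backbone_hbonds(segment_a, segment_b) -> float:
    """Smooth backbone N-H...O=C well summed over inter-segment pairs.

    Each pair contributes -f(d) * g(theta) with f a Gaussian in the H...O
    distance (optimum 1.9 A, sigma 0.3 A) and g = cos^2 of the deviation
    from N-H...O linearity; pairs beyond 3.2 A contribute 0.  One ideal
    bond scores about -1, so a threshold of -4 demands four good bonds.
    The score is symmetric in its two arguments.
    """
    total = 0.0
    for donors, acceptors in (
        (_hb_atoms(segment_a)[0], _hb_atoms(segment_b)[1]),
        (_hb_atoms(segment_b)[0], _hb_atoms(segment_a)[1]),
    ):
        for n, h in donors:
            for c, o in acceptors:
                d = np.linalg.norm(h - o)
                if d > HB_CUTOFF:
                    continue
                f = np.exp(-((d - HB_OPT_DIST) ** 2) / (2 * HB_SIGMA**2))
                nh = h - n
                ho = o - h
                cosang = np.dot(nh, ho) / (np.linalg.norm(nh) * np.linalg.norm(ho))
                if cosang <= 0.0:
                    continue  # bent beyond 90 degrees from linear
                total -= f * cosang**2
    return float(total)


def minimize_rigid(
    cand: DockCandidate,
    scaffold: Structure,
    max_shift: float = 1.5,
    max_rot_deg: float = 15.0,
) -> DockCandidate:
    """Bounded 6-DOF local optimization of the dock strand pose.

    Minimizes the backbone H-bond score against the edge strand region of
    the scaffold; guaranteed never to return a worse pose than the input.
    """
    edge_res = cand.edge.residues(scaffold)
    base = [r.copy() for r in cand.strand_residues]
    center = np.mean([r["CA"] for r in base], axis=0)

    def posed(p):
        R = Rotation.from_rotvec(p[3:], degrees=True).as_matrix()
        out = []
        for r in base:
            rc = r.copy()
            for a in rc.atoms.values():
                a.coord = R @ (a.coord - center) + center + p[:3]
            out.append(rc)
        return out

    def objective(p):
        return score_backbone_hbonds(edge_res, posed(p))

    score0 = objective(np.zeros(6))
    result = minimize(
        objective,
        np.zeros(6),
        method="Powell",
        bounds=[(-max_shift, max_shift)] * 3 + [(-max_rot_deg, max_rot_deg)] * 3,
        options={"maxiter": 1500, "xtol": 1e-5, "ftol": 1e-9},
    )
    if not result.success and result.fun >= score0:
        logger.warning("rigid minimization failed to improve; returning input pose")
        return replace(cand, hbond_score=score0)
    if result.fun >= score0 - 1e-12:
        if abs(score0) < 1e-6:
            logger.warning("no H-bond basin near dock strand; pose unchanged")
        return replace(cand, hbond_score=score0)
    return replace(cand, strand_residues=posed(result.x), hbond_score=float(result.fun))


# -- grafting and interface metrics ----------------------------------------


def graft_partner(
    cand: DockCandidate,
    scaffold_a: Structure,
    library: list[Structure],
    thresholds: ScoreThresholds = ScoreThresholds(),
) -> list[HeterodimerDock]:
    """Superimpose library scaffolds onto the dock strand via their edges.

    For each exposed edge strand of each library scaffold, every window of
    the dock strand's length is aligned (CA trace) onto the dock strand;
    placements within the graft rmsd tolerance and free of inter-scaffold
    clashes become heterodimer docks.
    """
    dock_ca = cand.strand_ca()
    m = len(dock_ca)
    a_heavy = scaffold_a.heavy_coords()
    docks = []
    for lib_idx, scaffold_b in enumerate(library):
        reports = find_exposed_edge_strands(scaffold_b, thresholds)
        for rep in reports:
            seg = rep.segment
            if seg.length < m:
                continue
            for w in range(seg.length - m + 1):
                window = seg.ca_coords[w : w + m]
                transform, rmsd = superimpose(window, dock_ca)
                if rmsd > thresholds.graft_rmsd:
                    continue
                placed = scaffold_b.transformed(transform)
                if min_distance(placed.heavy_coords(), a_heavy) < thresholds.clash_distance:
                    continue
                complex_ = _merge(scaffold_a, placed)
                dock = HeterodimerDock(
                    scaffold_a.name, scaffold_b.name, transform, rmsd, complex_
                )
                dock.metrics = interface_metrics(dock)
                docks.append(dock)
    docks.sort(key=lambda d: (d.graft_rmsd, d.scaffold_b))
    return docks


def _merge(a: Structure, b: Structure) -> Structure:
    """Two structures as one complex; chains renamed A... then B..."""
    out = Structure(name=f"{a.name}+{b.name}")
    next_id = iter("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    for src in (a, b):
        for cid in src.chain_ids:
            out.add_chain(next(next_id), [r.copy() for r in src[cid]])
    out._split = len(a.chain_ids)  # boundary between the two bodies
    return out


def _body_chains(complex_: Structure):
    split = getattr(complex_, "_split", 1)
    ids = complex_.chain_ids
    return ids[:split], ids[split:]


def interface_metrics(dock: HeterodimerDock) -> InterfaceMetrics:
    """Buried area, shape complementarity proxy, unsatisfied polars, packing."""
    complex_ = dock.complex
    ids_a, ids_b = _body_chains(complex_)

    def subset(ids):
        s = Structure("body")
        for cid in ids:
            s.add_chain(cid, [r.copy() for r in complex_[cid]])
        return s

    body_a, body_b = subset(ids_a), subset(ids_b)
    _, sasa_a = compute_sasa(body_a)
    _, sasa_b = compute_sasa(body_b)
    areas_ab, sasa_ab = compute_sasa(complex_)
    bsa = max(0.0, (sasa_a + sasa_b - sasa_ab) / 2.0)

    ha = body_a.heavy_coords()
    hb = body_b.heavy_coords()
    packing = count_contacts(ha, hb, 4.5)
    sc = _shape_complementarity(ha, hb)
    unsat = _unsatisfied_buried_polar(complex_, body_a, body_b, areas_ab, ids_a)
    hscore = _cross_hbond_score(complex_, ids_a, ids_b)
    return InterfaceMetrics(bsa, sc, unsat, packing, hscore)


def _cross_hbond_score(complex_: Structure, ids_a, ids_b) -> float:
    res_a = [r for cid in ids_a for r in complex_[cid]]
    res_b = [r for cid in ids_b for r in complex_[cid]]
    return score_backbone_hbonds(res_a, res_b)


def _shape_complementarity(ha: np.ndarray, hb: np.ndarray, sigma: float = 1.5) -> float:
    """Mean of (-n_a . n_b) * exp(-d^2 / 2 sigma^2) over close surface pairs.

    Atom normals are approximated as the direction away from the local
    body centroid (atoms within 8 A of the same body).
    """
    pairs = close_pairs(ha, hb, 4.5)
    if not pairs:
        return 0.0

    def normal(coords, idx):
        p = coords[idx]
        d = np.linalg.norm(coords - p, axis=1)
        local = coords[d < 8.0]
        v = p - local.mean(axis=0)
        n = np.linalg.norm(v)
        return v / n if n > 1e-9 else np.zeros(3)

    num, den = 0.0, 0.0
    for i, j, d in pairs:
        w = np.exp(-(d**2) / (2 * sigma**2))
        num += w * (-np.dot(normal(ha, i), normal(hb, j)))
        den += w
    return float(num / den) if den > 0 else 0.0


def _unsatisfied_buried_polar(complex_, body_a, body_b, areas_ab, ids_a) -> int:
    """Backbone N/O buried by the interface with no H-bond partner <= 3.2 A."""
    areas_a, _ = compute_sasa(body_a)
    areas_b, _ = compute_sasa(body_b)
    mono = {**areas_a, **areas_b}
    # all polar backbone atoms with candidate partners
    polar = []
    for cid, res in complex_.residues():
        for name in ("N", "O"):
            if name in res:
                polar.append((cid, res.index, name, res[name]))
    count = 0
    for cid, ridx, name, coord in polar:
        key = (cid, ridx, name)
        if areas_ab.get(key, 0.0) >= 1.0:
            continue  # not buried in the complex
        if mono.get(key, 0.0) < 1.0:
            continue  # was already buried within its own body
        partners = [
            c for c2, r2, n2, c in polar
            if n2 != name and not (c2 == cid and r2 == ridx)
        ]
        if partners:
            dmin = np.min(np.linalg.norm(np.array(partners) - coord, axis=1))
            if dmin <= 3.2:
                continue
        count += 1
    return count
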