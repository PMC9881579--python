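"""Rigid align-and-splice fusion on shared helical repeats, and cyclic closure.

Bivalent connectors are built by superimposing two structures that share
repeat-protein geometry on a common repeat window and concatenating the
chains at a junction inside the overlap.  Ring (Cn) designs are validated
by decomposing the transform relating successive subunits into a screw
motion: the assembly closes iff the rotation is 360/n degrees about a
fixed axis with (near) zero translation along it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .contacts import close_pairs, min_distance
from .geometry import RigidTransform, superimpose
from .structure import Structure

logger = logging.getLogger(__name__)


@dataclass
class RepeatAnnotation:
    structure_id: str
    windows: list[tuple[int, int]]     # inclusive residue ranges, consecutive
    repeat_len: int


@dataclass
class SpliceResult:
    fused: Structure
    junction: int                      # last residue index kept from parent a
    rmsd: float
    parents: tuple[str, str]


@dataclass
class ClosureReport:
    n: int
    transform: RigidTransform
    angle_error: float                 # deg
    axial_error: float                 # A
    closed: bool
    composition_error: float = np.nan  # max probe displacement under T^n


# -- repeat annotation -------------------------------------------------------


def annotate_repeats(
    structure: Structure,
    repeat_len: int,
    chain_id: str | None = None,
    rmsd_tol: float = 1.0,
) -> RepeatAnnotation:
    """Find consecutive equal-length repeat windows by self-superposition.

    Tries every start phase and keeps the longest run of windows for which
    each window superposes onto the next below the tolerance.  Raises if
    fewer than two repeats are found.
    """
    cid = chain_id or structure.chain_ids[0]
    ca = structure.backbone_coords(cid)
    n = len(ca)
    best: list[tuple[int, int]] = []
    for phase in range(repeat_len):
        starts = list(range(phase, n - repeat_len + 1, repeat_len))
        run: list[tuple[int, int]] = []
        for s in starts:
            if not run:
                run = [(s, s + repeat_len - 1)]
                continue
            prev = run[-1]
            if s != prev[1] + 1:
                break
            _, rmsd = superimpose(
                ca[prev[0] : prev[1] + 1], ca[s : s + repeat_len]
            )
            if rmsd < rmsd_tol:
                run.append((s, s + repeat_len - 1))
            else:
                if len(run) > len(best):
                    best = run
                run = [(s, s + repeat_len - 1)]
        if len(run) > len(best):
            best = run
    if len(best) < 2:
        raise ValueError(
            f"no repeat structure of length {repeat_len} detected in {structure.name}"
        )
    first = structure[cid][0].index
    windows = [(first + a, first + b) for a, b in best]
    return RepeatAnnotation(structure.name, windows, repeat_len)


# -- align and splice --------------------------------------------------------


def _window_ca(structure: Structure, window: tuple[int, int], chain_id=None):
    cid = chain_id or structure.chain_ids[0]
    by_idx = {r.index: r for r in structure[cid]}
    return np.array([by_idx[i]["CA"] for i in range(window[0], window[1] + 1)])


def align_and_splice(
    a: Structure,
    ann_a: RepeatAnnotation,
    b: Structure,
    ann_b: RepeatAnnotation,
    overlap: tuple[int, int],
    junction_offset: int | None = None,
    rmsd_tol: float = 1.0,
    clash_distance: float = 2.8,
) -> SpliceResult:
    """Fuse b onto a by superposing repeat window i_b onto window i_a.

    `overlap` gives 1-based repeat-window indices (i_a, i_b).  The fused
    single chain keeps a's residues up to the junction (by default the end
    of window i_a) and b's transformed residues after the corresponding
    junction in window i_b; the result is renumbered from 1.
    """
    if ann_a.repeat_len != ann_b.repeat_len:
        raise ValueError(
            f"repeat mismatch: window lengths {ann_a.repeat_len} != {ann_b.repeat_len}"
        )
    i_a, i_b = overlap
    win_a = ann_a.windows[i_a - 1]
    win_b = ann_b.windows[i_b - 1]
    ca_a = _window_ca(a, win_a)
    ca_b = _window_ca(b, win_b)
    transform, rmsd = superimpose(ca_b, ca_a)
    if rmsd > rmsd_tol:
        raise ValueError(
            f"repeat mismatch: window alignment rmsd {rmsd:.2f} A > {rmsd_tol} A"
        )
    if junction_offset is None:
        junction_offset = ann_a.repeat_len - 1   # splice at the window end
    junction_a = win_a[0] + junction_offset
    junction_b = win_b[0] + junction_offset

    cid_a, cid_b = a.chain_ids[0], b.chain_ids[0]
    prefix = [r.copy() for r in a[cid_a] if r.index <= junction_a]
    moved_b = b.transformed(transform)
    suffix = [r.copy() for r in moved_b[cid_b] if r.index > junction_b]

    # clash check between the retained parts, ignoring a 2-residue junction window
    pre_coords = [
        r.heavy_coords() for r in prefix if r.index < junction_a - 1
    ]
    suf_coords = [
        r.heavy_coords()
        for r in suffix
        if r.index > junction_b + 2
    ]
    if pre_coords and suf_coords:
        pre_arr = np.concatenate(pre_coords)
        suf_arr = np.concatenate(suf_coords)
        pairs = close_pairs(pre_arr, suf_arr, clash_distance)
        if pairs:
            i, j, d = min(pairs, key=lambda p: p[2])
            raise ValueError(
                f"splice clash: retained parts approach to {d:.2f} A"
            )

    fused = Structure(name=f"{a.name}*{b.name}")
    residues = prefix + suffix
    for k, r in enumerate(residues, start=1):
        r.index = k
    fused.add_chain("A", residues)
    return SpliceResult(fused, junction=len(prefix), rmsd=rmsd, parents=(a.name, b.name))


def validate_fusion_contacts(
    fused_part: Structure,
    partner: Structure,
    interface_residues: set | None = None,
    cutoff: float = 4.0,
):
    """Check that a fused appendage makes no new contacts with the partner.

    Returns (passed, contacts) where contacts lists (fused residue index,
    partner residue index, distance) for appendage atoms within `cutoff`
    of partner atoms outside the designed interface residue set.
    """
    interface_residues = interface_residues or set()
    contacts = []
    partner_res = [(cid, r) for cid, r in partner.residues()]
    if not partner_res:
        return True, []
    p_coords = []
    p_owner = []
    for cid, r in partner_res:
        if (cid, r.index) in interface_residues:
            continue
        for c in r.heavy_coords():
            p_coords.append(c)
            p_owner.append(r.index)
    if not p_coords:
        return True, []
    p_coords = np.array(p_coords)
    for cid, r in fused_part.residues():
        pr = close_pairs(r.heavy_coords(), p_coords, cutoff)
        for _, j, d in pr:
            contacts.append((r.index, p_owner[j], d))
    return len(contacts) == 0, contacts


def sample_fusion_points(
    a: Structure,
    ann_a: RepeatAnnotation,
    b: Structure,
    ann_b: RepeatAnnotation,
    max_repeats_sampled: int = 3,
    rmsd_tol: float = 1.0,
) -> tuple[list[SpliceResult], list[tuple[tuple[int, int], str]]]:
    """Attempt splices over the first `max_repeats_sampled` windows of each.

    Junctions are placed at repeat-window boundaries.  Returns (successes
    sorted by alignment rmsd, failures as ((i_a, i_b), reason)).
    """
    successes, failures = [], []
    for i_a in range(1, min(max_repeats_sampled, len(ann_a.windows)) + 1):
        for i_b in range(1, min(max_repeats_sampled, len(ann_b.windows)) + 1):
            try:
                successes.append(
                    align_and_splice(a, ann_a, b, ann_b, (i_a, i_b), rmsd_tol=rmsd_tol)
                )
            except ValueError as exc:
                failures.append(((i_a, i_b), str(exc)))
    successes.sort(key=lambda s: s.rmsd)
    return successes, failures


# -- cyclic closure ----------------------------------------------------------


def screw_decompose(transform: RigidTransform):
    """(angle_deg, axis, axial_translation) of a rigid motion.

    The rotation angle comes from the rotation matrix; the axial
    translation is the component of the translation along the rotation
    axis (the screw pitch contribution).  For near-identity rotations the
    axis is conventionally +z and the whole translation counts as axial.
    """
    angle = transform.angle_deg()
    axis = transform.axis()
    if angle < 1e-9:
        return angle, axis, float(np.linalg.norm(transform.translation))
    return angle, axis, float(np.dot(transform.translation, axis))


def closure_check(
    transform: RigidTransform,
    n: int,
    angle_tol: float = 5.0,
    axial_tol: float = 1.5,
    probe: np.ndarray | None = None,
) -> ClosureReport:
    """Does applying `transform` n times close a Cn ring?

    Closed iff |angle - 360/n| <= angle_tol and |axial translation| <=
    axial_tol.  A composition test is also run: T^n applied to a probe
    point set must displace no point by more than n * (bound implied by
    the tolerances); the max displacement is reported.
    """
    if n not in (3, 4, 5, 6):
        raise ValueError("symmetry order must be 3..6")
    angle, axis, axial = screw_decompose(transform)
    angle_error = abs(angle - 360.0 / n)
    axial_error = abs(axial)
    closed = angle_error <= angle_tol and axial_error <= axial_tol
    if probe is None:
        probe = np.array(
            [[10.0, 0.0, 0.0], [0.0, 10.0, 0.0], [0.0, 0.0, 10.0], [5.0, 5.0, 0.0]]
        )
    moved = transform.power(n).apply(probe)
    comp_err = float(np.max(np.linalg.norm(moved - probe, axis=1)))
    return ClosureReport(
        n, transform, float(angle_error), float(axial_error), closed, comp_err
    )


def _axis_point(transform: RigidTransform, axis: np.ndarray) -> np.ndarray:
    """A point on the screw axis (solves (I - R) p = t_perp)."""
    R, t = transform.rotation, transform.translation
    t_perp = t - np.dot(t, axis) * axis
    p = np.linalg.pinv(np.eye(3) - R) @ t_perp
    return p - np.dot(p, axis) * axis


def idealize_cn(transform: RigidTransform, n: int) -> RigidTransform:
    """Snap a near-closing transform to an exact Cn step.

    The rotation angle is set to exactly 360/n about the original axis
    through the original axis point, and the axial translation is zeroed.
    """
    _, axis, _ = screw_decompose(transform)
    p = _axis_point(transform, axis)
    R = Rotation.from_rotvec(axis * (2 * np.pi / n)).as_matrix()
    return RigidTransform(R, p - R @ p)


def assemble_ring(
    asym_unit: Structure,
    transform: RigidTransform,
    n: int,
    clash_distance: float = 2.5,
) -> tuple[Structure, list]:
    """Place n copies of the asymmetric unit by the idealized Cn step.

    Returns the ring (chains A, B, ...) and a list of inter-subunit clash
    reports (pairs of chain ids with their minimum heavy-atom distance);
    clashes warn but the ring is still emitted.
    """
    step = idealize_cn(transform, n)
    ring = Structure(name=f"C{n}_ring")
    bodies = []
    for k in range(n):
        placed = asym_unit.transformed(step.power(k))
        cid = chr(ord("A") + k)
        ring.add_chain(cid, [r.copy() for r in placed[asym_unit.chain_ids[0]]])
        bodies.append((cid, placed.heavy_coords()))
    clashes = []
    for i in range(n):
        for j in range(i + 1, n):
            d = min_distance(bodies[i][1], bodies[j][1])
            if d < clash_distance:
                clashes.append((bodies[i][0], bodies[j][0], d))
    if clashes:
        logger.warning("ring has %d clashing subunit pairs", len(clashes))
    return ring, clashes
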