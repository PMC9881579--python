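"""Deterministic idealized-geometry fixtures.

Generators for the structure classes the pipeline consumes: alpha
helices, parallel/antiparallel beta sheets, designed-helical-repeat (DHR)
analogs, and mixed alpha/beta monomer scaffolds with an exposed edge
strand and optional homodimer-blocking helices.  Everything is built from
ideal internal coordinates; given identical parameters the output is
bitwise deterministic (the only optimization used, the inter-strand
placement, is a fixed-grid search plus a bounded deterministic simplex
refinement).

These emulate only the properties the pipeline consumes -- an exposed
edge strand with a free hydrogen-bonding face, a compact helical core,
exact internal repeat symmetry -- not any particular natural or designed
topology.  Loop realism is explicitly out of scope.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .contacts import min_distance
from .geometry import RigidTransform, superimpose
from .nerf import build_backbone, residues_to_structure
from .structure import Atom, Residue, Structure

# ideal backbone dihedrals (phi, psi)
HELIX_PHI_PSI = (-57.0, -47.0)
SHEET_PHI_PSI = {"antiparallel": (-139.0, 135.0), "parallel": (-119.0, 113.0)}


# -- helices ---------------------------------------------------------------


def build_ideal_helix(n: int) -> Structure:
    """Poly-alanine alpha helix of n >= 4 residues (rise ~1.5 A/residue)."""
    if n < 4:
        raise ValueError("a helix needs at least 4 residues")
    return residues_to_structure(
        build_backbone([(*HELIX_PHI_PSI, 180.0)] * n), name=f"helix{n}"
    )


# -- beta sheets -----------------------------------------------------------


def _strand_residues(length: int, orientation: str) -> list[Residue]:
    phi_psi = SHEET_PHI_PSI[orientation]
    return build_backbone([(*phi_psi, 180.0)] * length)


def _canonical_frame(residues) -> RigidTransform:
    """Transform into a strand-local frame: CA centroid at origin, strand
    axis along +x, mean even-residue carbonyl direction toward +y."""
    ca = np.array([r["CA"] for r in residues])
    x = ca[-1] - ca[0]
    x /= np.linalg.norm(x)
    co = np.mean(
        [residues[i]["O"] - residues[i]["C"] for i in range(0, len(residues), 2)],
        axis=0,
    )
    y = co - np.dot(co, x) * x
    y /= np.linalg.norm(y)
    z = np.cross(x, y)
    R = np.vstack([x, y, z])  # rows: world directions of local axes
    return RigidTransform(R, -R @ ca.mean(axis=0))


def _apply_to_residues(residues, transform: RigidTransform) -> list[Residue]:
    out = []
    for r in residues:
        rc = r.copy()
        for a in rc.atoms.values():
            a.coord = transform.apply(a.coord)
        out.append(rc)
    return out


def _bb_arrays(residues):
    """Backbone arrays (N, CA, C, O, H); H[0] is NaN (no preceding carbonyl)."""
    N = np.array([r["N"] for r in residues])
    C = np.array([r["C"] for r in residues])
    O = np.array([r["O"] for r in residues])
    H = np.full_like(N, np.nan)
    for i in range(1, len(residues)):
        v = C[i - 1] - O[i - 1]
        H[i] = N[i] + v / np.linalg.norm(v)
    return N, C, O, H


def _ks_pair_energy(res_a, res_b):
    """(n_hbonds, total_energy) of Kabsch-Sander bonds between two segments."""
    const = 0.084 * 332.0
    total, count = 0.0, 0
    for donors, acceptors in ((res_a, res_b), (res_b, res_a)):
        N, _, _, H = _bb_arrays(donors)
        _, C, O, _ = _bb_arrays(acceptors)
        ok = ~np.isnan(H[:, 0])
        d_on = np.linalg.norm(N[:, None] - O[None], axis=-1)
        d_ch = np.linalg.norm(H[:, None] - C[None], axis=-1)
        d_oh = np.linalg.norm(H[:, None] - O[None], axis=-1)
        d_cn = np.linalg.norm(N[:, None] - C[None], axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            e = const * (1.0 / d_on + 1.0 / d_ch - 1.0 / d_oh - 1.0 / d_cn)
        e[~ok] = 0.0
        e = np.nan_to_num(e)
        # overlapping atoms are a clash, not a favorable bond
        dmin = np.minimum(np.minimum(d_on, d_ch), np.minimum(d_oh, d_cn))
        e[dmin < 1.0] = 0.0
        e = np.clip(e, -9.9, None)
        bonded = e < -0.5
        count += int(bonded.sum())
        total += float(e[bonded].sum())
    return count, total


def _heavy(residues) -> np.ndarray:
    return np.array(
        [a.coord for r in residues for a in r.atoms.values() if a.element != "H"]
    )


def _pair_objective(res_a, res_b_moved) -> float:
    _, energy = _ks_pair_energy(res_a, res_b_moved)
    dmin = min_distance(_heavy(res_a), _heavy(res_b_moved))
    penalty = 500.0 * (2.6 - dmin) ** 2 if dmin < 2.6 else 0.0
    return energy + penalty


def _ks_arrays_energy(A, B):
    """(n_hbonds, total, n_interior) between backbone dicts {N,C,O,H} (H[0] NaN)."""
    const = 0.084 * 332.0
    total, count, interior = 0.0, 0, 0
    for don, acc in ((A, B), (B, A)):
        N, H = don["N"], don["H"]
        C, O = acc["C"], acc["O"]
        ok = ~np.isnan(H[:, 0])
        d_on = np.linalg.norm(N[:, None] - O[None], axis=-1)
        d_ch = np.linalg.norm(H[:, None] - C[None], axis=-1)
        d_oh = np.linalg.norm(H[:, None] - O[None], axis=-1)
        d_cn = np.linalg.norm(N[:, None] - C[None], axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            e = const * (1.0 / d_on + 1.0 / d_ch - 1.0 / d_oh - 1.0 / d_cn)
        e[~ok] = 0.0
        e = np.nan_to_num(e)
        dmin = np.minimum(np.minimum(d_on, d_ch), np.minimum(d_oh, d_cn))
        e[dmin < 1.0] = 0.0
        e = np.clip(e, -9.9, None)
        bonded = e < -0.5
        count += int(bonded.sum())
        total += float(e[bonded].sum())
        # bonds whose donor and acceptor are both interior residues; used to
        # prefer the register phase whose bonds can all reciprocate (the
        # first residue of a segment has no reconstructable amide H)
        nd, na = len(N), len(C)
        inner = bonded.copy()
        inner[0, :] = inner[-1, :] = False
        inner[:, 0] = inner[:, -1] = False
        interior += int(inner.sum())
    return count, total, interior


def _smooth_hbond_energy(A, B):
    """Gaussian-well N-H...O=C score between backbone array dicts.

    Same functional form as the docking score (optimum H...O 1.9 A, sigma
    0.3 A, cos^2 angular factor, cutoff 3.2 A); the fixture placement is
    refined on this so that ideal sheets sit at the scoring optimum.
    """
    total = 0.0
    for don, acc in ((A, B), (B, A)):
        N, H = don["N"], don["H"]
        C, O = acc["C"], acc["O"]
        ok = ~np.isnan(H[:, 0])
        d = np.linalg.norm(H[:, None] - O[None], axis=-1)
        nh = H - N
        ho = O[None] - H[:, None]
        denom = np.linalg.norm(nh, axis=-1)[:, None] * np.linalg.norm(ho, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.einsum("id,ijd->ij", nh, ho) / denom
        e = -np.exp(-((d - 1.9) ** 2) / (2 * 0.3**2)) * np.clip(cosang, 0.0, None) ** 2
        e[~ok] = 0.0
        e[d > 3.2] = 0.0
        total += float(np.nan_to_num(e).sum())
    return total


def _residue_arrays(residues):
    heavy = _heavy(residues)
    N, C, O, H = _bb_arrays(residues)
    return {"N": N, "C": C, "O": O, "H": H, "heavy": heavy}


def _transform_arrays(arrays, transform: RigidTransform):
    return {k: transform.apply(v) for k, v in arrays.items()}


@functools.lru_cache(maxsize=64)
def _strand_pair_transform(length: int, orientation: str) -> RigidTransform:
    """The rigid step placing strand k+1 next to strand k in an ideal sheet.

    Found once per (length, orientation) by a deterministic grid search over
    discrete flips and in-plane offsets, refined by a bounded deterministic
    Powell minimization of the Kabsch-Sander pair energy.  For antiparallel
    sheets the step includes a 180-degree rotation, so applying it twice is
    a pure translation and the sheet alternates strand directions as it must.
    """
    base = _strand_residues(length, orientation)
    frame = _canonical_frame(base)
    arr0 = _transform_arrays(_residue_arrays(base), frame)

    if orientation == "antiparallel":
        flips = [
            Rotation.from_euler("z", 180, degrees=True).as_matrix(),
            Rotation.from_euler("y", 180, degrees=True).as_matrix(),
        ]
    else:
        flips = [np.eye(3), Rotation.from_euler("x", 180, degrees=True).as_matrix()]

    def score(T: RigidTransform):
        moved = _transform_arrays(arr0, T)
        count, energy, interior = _ks_arrays_energy(arr0, moved)
        d = np.linalg.norm(arr0["heavy"][:, None] - moved["heavy"][None], axis=-1)
        return count, energy, interior, float(d.min())

    best = None
    for R in flips:
        for dy in np.arange(4.0, 5.81, 0.2):
            for dx in np.arange(-4.0, 4.01, 0.25):
                for dz in (-0.8, -0.4, 0.0, 0.4, 0.8):
                    T = RigidTransform(R, np.array([dx, dy, dz]))
                    count, energy, interior, dmin = score(T)
                    if dmin < 2.2:
                        continue
                    key = (-interior, -count, energy)
                    if best is None or key < best[0]:
                        best = (key, R, np.array([dx, dy, dz]))
    if best is None:
        raise RuntimeError("no clash-free strand pairing found")
    _, R0, t0 = best

    def objective(p):
        T = RigidTransform(
            Rotation.from_rotvec(p[3:], degrees=True).as_matrix() @ R0, t0 + p[:3]
        )
        moved = _transform_arrays(arr0, T)
        energy = _smooth_hbond_energy(arr0, moved)
        d = np.linalg.norm(arr0["heavy"][:, None] - moved["heavy"][None], axis=-1)
        dmin = float(d.min())
        penalty = 500.0 * (2.6 - dmin) ** 2 if dmin < 2.6 else 0.0
        return energy + penalty

    res = minimize(
        objective,
        np.zeros(6),
        method="Powell",
        bounds=[(-0.8, 0.8)] * 3 + [(-8.0, 8.0)] * 3,
        options={"maxiter": 2000, "xtol": 1e-5, "ftol": 1e-8},
    )
    p = res.x
    step_local = RigidTransform(
        Rotation.from_rotvec(p[3:], degrees=True).as_matrix() @ R0, t0 + p[:3]
    )
    # express the step in the original (pre-canonical-frame) coordinates
    return frame.inverse().compose(step_local.compose(frame))


def build_ideal_sheet(n_strands: int, strand_len: int, orientation: str) -> Structure:
    """Ideal poly-alanine beta sheet; one chain per strand (A, B, ...)."""
    if orientation not in SHEET_PHI_PSI:
        raise ValueError(f"orientation must be parallel|antiparallel, got {orientation!r}")
    if n_strands < 2:
        raise ValueError("a sheet needs at least 2 strands")
    if strand_len < 3:
        raise ValueError("strands must have at least 3 residues")
    base = _strand_residues(strand_len, orientation)
    step = _strand_pair_transform(strand_len, orientation)
    s = Structure(name=f"sheet_{orientation}_{n_strands}x{strand_len}")
    for k in range(n_strands):
        s.add_chain(chr(ord("A") + k), _apply_to_residues(base, step.power(k)))
    return s


# -- repeat proteins -------------------------------------------------------

# 2-residue inter-helix turns; chosen so that the helix-loop-helix repeat
# is compact and clash-free and successive repeats stack with a gentle twist
DHR_LOOP1 = ((-150.0, 180.0), (-70.0, -140.0))
DHR_LOOP2 = ((-130.0, 40.0), (-30.0, -40.0))


@dataclass(frozen=True)
class RepeatProteinSpec:
    """Parameters of an idealized helix-loop-helix repeat protein."""

    n_repeats: int = 4
    helix_len: int = 12
    loop1: tuple = DHR_LOOP1
    loop2: tuple = DHR_LOOP2

    def __post_init__(self):
        if self.n_repeats < 2:
            raise ValueError("need at least 2 repeats for align-and-splice overlap")

    @property
    def repeat_len(self) -> int:
        return 2 * self.helix_len + len(self.loop1) + len(self.loop2)

    def repeat_dihedrals(self) -> list[tuple[float, float, float]]:
        helix = [(*HELIX_PHI_PSI, 180.0)] * self.helix_len
        loop1 = [(p, s, 180.0) for p, s in self.loop1]
        loop2 = [(p, s, 180.0) for p, s in self.loop2]
        return helix + loop1 + helix + loop2


def build_dhr(spec: RepeatProteinSpec) -> Structure:
    """Idealized DHR: the repeat dihedral block repeated n times.

    Because the chain is built from a repeating internal-coordinate block,
    repeat i+1 is related to repeat i by exactly the same rigid transform
    for every i (exact internal repeat symmetry).
    """
    dihedrals = spec.repeat_dihedrals() * spec.n_repeats
    return residues_to_structure(build_backbone(dihedrals), name="dhr")


def dhr_repeat_transform(spec: RepeatProteinSpec) -> RigidTransform:
    """The rigid transform relating consecutive repeats."""
    s = build_dhr(RepeatProteinSpec(2, spec.helix_len, spec.loop1, spec.loop2))
    ca = s.backbone_coords("A")
    L = spec.repeat_len
    t, _ = superimpose(ca[:L], ca[L : 2 * L])
    return t


# -- mixed alpha/beta scaffold --------------------------------------------

_SHEET_STRANDS = 4
_STRAND_LEN = 8
_FLANK_GAP = 7.4       # in-plane distance from a covered edge strand to its helix
_CORE_DEPTH = -8.6     # z offset of the core helix below the sheet plane
_BLOCK_Y = 10.2        # blocking helices: lateral offset beyond the edge strand
_BLOCK_Z = 4.2         # and height above/below the sheet plane


def _helix_at(n: int, origin, direction, phase_ref) -> list[Residue]:
    """An ideal helix with its axis through `origin` along `direction`."""
    res = build_backbone([(*HELIX_PHI_PSI, 180.0)] * n)
    ca = np.array([r["CA"] for r in res])
    # helix axis by averaging i -> i+1 CA midpoint drift
    mid = 0.5 * (ca[:-1] + ca[1:])
    axis = mid[-1] - mid[0]
    axis /= np.linalg.norm(axis)
    centroid = ca.mean(axis=0)
    direction = np.asarray(direction, dtype=float)
    direction /= np.linalg.norm(direction)
    rot, _ = Rotation.align_vectors(
        np.vstack([direction, phase_ref]), np.vstack([axis, phase_ref])
    )
    R = rot.as_matrix()
    T = RigidTransform(R, np.asarray(origin, float) - R @ centroid)
    return _apply_to_residues(res, T)


def _bridge_loop(
    prev_res: Residue, next_res: Residue, avoid_centroid: np.ndarray
) -> list[Residue]:
    """Geometric loop residues bridging two anchors (CA-CA steps <= 4.2 A).

    The loop bows away from `avoid_centroid` (the body being connected
    around).  Loops are placeholders: internal geometry is approximate,
    which is acceptable because no fixture property depends on loop
    realism.
    """
    p0 = prev_res["CA"]
    p1 = next_res["CA"]
    gap = p1 - p0
    dist = np.linalg.norm(gap)
    mid = 0.5 * (p0 + p1)
    away = mid - avoid_centroid
    d_hat = gap / (dist + 1e-9)
    away = away - np.dot(away, d_hat) * d_hat
    norm = np.linalg.norm(away)
    if norm < 1e-6:
        away = np.cross(d_hat, [0.0, 0.0, 1.0])
        norm = np.linalg.norm(away)
        if norm < 1e-6:
            away = np.cross(d_hat, [0.0, 1.0, 0.0])
            norm = np.linalg.norm(away)
    bulge = 4.0 * away / norm
    n_loop = max(1, int(np.ceil(dist / 3.2)) - 1)
    out = []
    ts = np.linspace(0.0, 1.0, n_loop + 2)[1:-1]
    up = away / norm
    for t in ts:
        ca = p0 + t * gap + np.sin(np.pi * t) * bulge
        atoms = {
            "N": Atom("N", "N", ca - 1.0 * d_hat + 0.4 * up),
            "CA": Atom("CA", "C", ca),
            "C": Atom("C", "C", ca + 1.0 * d_hat + 0.4 * up),
            "O": Atom("O", "O", ca + 1.1 * d_hat + 1.5 * up),
        }
        out.append(Residue(0, "G", atoms))
    return out


def build_scaffold(edge_exposed: bool, blocking_helix: bool) -> Structure:
    """Mixed alpha/beta monomer: 4-stranded antiparallel sheet + packed helices.

    With `edge_exposed` the last strand keeps a free hydrogen-bonding face
    (the other edge is covered by an in-plane helix); otherwise both edges
    are covered and no exposed edge strand remains.  With `blocking_helix`
    two additional helices flank the exposed edge above and below the sheet
    plane, placed so that any second copy of the scaffold docked by sheet
    extension on that edge clashes with them.
    """
    strand = _strand_residues(_STRAND_LEN, "antiparallel")
    frame = _canonical_frame(strand)
    strand = _apply_to_residues(strand, frame)
    step_raw = _strand_pair_transform(_STRAND_LEN, "antiparallel")
    step = frame.compose(step_raw.compose(frame.inverse()))
    strands = [_apply_to_residues(strand, step.power(k)) for k in range(_SHEET_STRANDS)]

    ca0 = np.array([r["CA"] for r in strands[0]])
    x_dir = np.array([1.0, 0.0, 0.0])
    edge_y = np.array([r["CA"] for r in strands[-1]]).mean(axis=0)[1]
    span_x = ca0[:, 0]

    y_mid = 0.5 * (ca0.mean(axis=0)[1] + edge_y)
    x_mid = span_x.mean()
    # hydrophobic-core proxy: one helix packed under the sheet center
    core = _helix_at(16, [x_mid, y_mid, _CORE_DEPTH], x_dir, [0, 1.0, 0])
    # helix covering the first edge strand's free face (in plane)
    flank1 = _helix_at(16, [x_mid, -_FLANK_GAP, 0.0], -x_dir, [0, 0, 1.0])
    tail: list[list[Residue]] = []
    if not edge_exposed:
        tail.append(
            _helix_at(16, [x_mid, edge_y + _FLANK_GAP, 0.0], -x_dir, [0, 0, 1.0])
        )
    if blocking_helix:
        tail.append(
            _helix_at(18, [x_mid, edge_y + _BLOCK_Y, _BLOCK_Z], -x_dir, [0, 1.0, 0])
        )
        tail.append(
            _helix_at(18, [x_mid, edge_y + _BLOCK_Y, -_BLOCK_Z], x_dir, [0, 1.0, 0])
        )

    # thread everything into one chain: flank, sheet meander, core, extras
    segments: list[list[Residue]] = [flank1] + strands + [core] + tail
    body_centroid = np.mean(
        [r["CA"] for seg in segments for r in seg], axis=0
    )
    residues: list[Residue] = []
    for seg in segments:
        if residues:
            residues.extend(_bridge_loop(residues[-1], seg[0], body_centroid))
        residues.extend(seg)
    for i, r in enumerate(residues, start=1):
        r.index = i
    s = Structure(name=f"scaffold(edge={edge_exposed},block={blocking_helix})")
    s.add_chain("A", residues)
    return s
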