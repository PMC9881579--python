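"""Solvent-accessible surface area via the Shrake-Rupley method.

The numerical integration itself is delegated to biotite's SASA routine
(deterministic Fibonacci sphere points); this module supplies the radii
handling, atom selection and per-residue backbone aggregation used by
the edge-strand exposure screen.
"""

from __future__ import annotations

import logging

import biotite.structure as bst
import numpy as np

from .structure import Structure

logger = logging.getLogger(__name__)

DEFAULT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
FALLBACK_RADIUS = 1.70
DEFAULT_PROBE = 1.4
DEFAULT_POINTS = 960


def _to_atom_array(structure: Structure):
    """Flatten to a biotite AtomArray, keeping (chain, residue index, atom name)."""
    keys, coords, elements = [], [], []
    for cid, res in structure.residues():
        for atom in res.atoms.values():
            keys.append((cid, res.index, atom.name))
            coords.append(atom.coord)
            elements.append(atom.element)
    arr = bst.AtomArray(len(keys))
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = np.array([k[0] for k in keys])
    arr.res_id = np.array([k[1] for k in keys])
    arr.atom_name = np.array([k[2] for k in keys])
    arr.res_name = np.array(["ALA"] * len(keys))
    arr.element = np.array([e.upper() for e in elements])
    arr.hetero = np.zeros(len(keys), dtype=bool)
    return keys, arr


def compute_sasa(
    structure: Structure,
    selector=None,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
    radii: dict | None = None,
) -> tuple[dict, float]:
    """Per-atom solvent-accessible areas in A^2.

    Parameters
    ----------
    structure
        The structure; all atoms occlude, whatever the selector.
    selector
        Optional predicate (chain_id, residue_index, atom_name) -> bool
        choosing the atoms whose areas are summed and returned.
    probe_radius, n_points
        Water-probe radius and Shrake-Rupley sphere-point count.
    radii
        Element -> van der Waals radius override table; unknown elements
        fall back to 1.70 A with a warning.

    Returns
    -------
    areas
        Mapping (chain_id, residue_index, atom_name) -> area for the
        selected atoms.
    total
        Sum of the selected areas.
    """
    table = dict(DEFAULT_RADII)
    if radii:
        table.update(radii)
    keys, arr = _to_atom_array(structure)
    if len(keys) == 0:
        return {}, 0.0
    vdw = np.empty(len(keys))
    for i, el in enumerate(arr.element):
        if el not in table:
            logger.warning("unknown element %r; using %.2f A radius", el, FALLBACK_RADIUS)
        vdw[i] = table.get(el, FALLBACK_RADIUS)
    per_atom = bst.sasa(
        arr,
        probe_radius=probe_radius,
        point_number=n_points,
        vdw_radii=vdw,
    )
    per_atom = np.nan_to_num(np.asarray(per_atom, dtype=float))
    areas = {}
    for key, area in zip(keys, per_atom):
        if selector is None or selector(*key):
            areas[key] = float(area)
    return areas, float(sum(areas.values()))


def backbone_polar_sasa(structure: Structure, **kwargs) -> dict:
    """Per-residue summed SASA of backbone N and O atoms.

    Returns (chain_id, residue_index) -> area; the quantity gating
    edge-strand exposure (a strand H-bonded on both faces has these atoms
    buried, an exposed edge strand does not).
    """
    areas, _ = compute_sasa(
        structure, selector=lambda c, r, a: a in ("N", "O"), **kwargs
    )
    out: dict = {}
    for (cid, ridx, _), area in areas.items():
        out[(cid, ridx)] = out.get((cid, ridx), 0.0) + area
    return out
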