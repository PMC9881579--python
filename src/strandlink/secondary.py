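"""Backbone hydrogen bonds and secondary-structure assignment.

Secondary structure is assigned from backbone N-H...O=C hydrogen bonds
using the Kabsch-Sander electrostatic criterion: the interaction energy

    E = 0.084 * 332 * (1/d_ON + 1/d_CH - 1/d_OH - 1/d_CN)   [kcal/mol]

defines a hydrogen bond when E < -0.5 kcal/mol.  Amide hydrogens are
reconstructed geometrically: the N-H vector of residue i is taken
anti-parallel to the C=O vector of residue i-1 with a 1.0 A bond.

Helices are called from i -> i+4 turn ladders, strands from inter-strand
bridges (parallel or antiparallel).  A lone extended strand with no bridge
partner is therefore labelled 'L': the strand definition used here is
bridge-based.
"""

from __future__ import annotations

import numpy as np

from .structure import Structure

HB_ENERGY_CUTOFF = -0.5  # kcal/mol
_KS_CONST = 0.084 * 332.0


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def reconstruct_amide_h(prev_c, prev_o, n) -> np.ndarray:
    """Amide H position from the previous residue's C=O and this N."""
    return n + _normalize(np.asarray(prev_c) - np.asarray(prev_o))


def _flat_backbone(structure: Structure):
    """Flatten residues across chains with amide H; gap of 10 between chains.

    Returns (entries, positions) where entries[i] is a dict with keys
    chain, res (Residue object), N, CA, C, O, H (H may be None at chain
    starts or after incomplete predecessors).
    """
    entries = []
    for cid, residues in structure.chains.items():
        prev = None
        for res in residues:
            if not res.has_backbone():
                prev = None
                entries.append(None)  # keep spacing but unusable
                continue
            h = None
            if prev is not None and res.index == prev.index + 1 and res.aa != "P":
                h = reconstruct_amide_h(prev["C"], prev["O"], res["N"])
            entries.append(
                {"chain": cid, "res": res, "N": res["N"], "CA": res["CA"],
                 "C": res["C"], "O": res["O"], "H": h}
            )
            prev = res
        entries.extend([None] * 3)  # separator so i+-1 never crosses chains
    return entries


def ks_energy(donor, acceptor) -> float:
    """Kabsch-Sander electrostatic energy of donor N-H vs acceptor C=O."""
    if donor is None or acceptor is None or donor["H"] is None:
        return 0.0
    n, h = donor["N"], donor["H"]
    c, o = acceptor["C"], acceptor["O"]
    d_on = np.linalg.norm(o - n)
    d_ch = np.linalg.norm(c - h)
    d_oh = np.linalg.norm(o - h)
    d_cn = np.linalg.norm(c - n)
    if min(d_on, d_ch, d_oh, d_cn) < 0.5:
        return -9.9  # atoms essentially on top of each other
    return _KS_CONST * (1.0 / d_on + 1.0 / d_ch - 1.0 / d_oh - 1.0 / d_cn)


def backbone_hbond_matrix(structure: Structure):
    """All Kabsch-Sander H-bonds; returns (entries, set of (donor_i, acceptor_j))."""
    entries = _flat_backbone(structure)
    bonds = set()
    n = len(entries)
    for i in range(n):
        ei = entries[i]
        if ei is None or ei["H"] is None:
            continue
        for j in range(n):
            if abs(i - j) < 2:
                continue
            ej = entries[j]
            if ej is None:
                continue
            # cheap distance gate before the 4-distance energy
            if np.linalg.norm(ei["N"] - ej["O"]) > 5.2:
                continue
            if ks_energy(ei, ej) < HB_ENERGY_CUTOFF:
                bonds.add((i, j))
    return entries, bonds


def assign_secondary_structure(structure: Structure) -> Structure:
    """Assign per-residue {H, E, L} labels in place and return the structure.

    Strand ('E') labels come from inter-strand bridges and take precedence
    over helix labels where both patterns fire.  Chains shorter than 3
    residues are all loop.
    """
    entries, bonds = backbone_hbond_matrix(structure)
    n = len(entries)
    labels = ["L"] * n

    def hb(di, aj) -> bool:
        return (di, aj) in bonds

    # helices: two consecutive i -> i+4 turns label i+1..i+4
    for i in range(n - 5):
        if entries[i] is None:
            continue
        # turn(i): CO(i) accepts from NH(i+4)
        if hb(i + 4, i) and hb(i + 5, i + 1):
            for k in range(i + 1, i + 6):
                if entries[k] is not None:
                    labels[k] = "H"

    # bridges (Kabsch-Sander parallel/antiparallel patterns)
    for i in range(1, n - 1):
        if entries[i] is None:
            continue
        for j in range(i + 3, n - 1):
            if entries[j] is None:
                continue
            parallel = (hb(i, j - 1) and hb(j + 1, i)) or (hb(j, i - 1) and hb(i + 1, j))
            anti = (hb(i, j) and hb(j, i)) or (
                hb(j + 1, i - 1) and hb(i + 1, j - 1)
            )
            if parallel or anti:
                labels[i] = "E"
                labels[j] = "E"

    # map flat labels back onto chains
    structure.ss = {}
    pos = 0
    for cid, residues in structure.chains.items():
        chain_labels = []
        for _ in residues:
            chain_labels.append(labels[pos])
            pos += 1
        if len(residues) < 3:
            chain_labels = ["L"] * len(residues)
        structure.ss[cid] = chain_labels
        pos += 3  # separator entries
    return structure


def strand_runs(structure: Structure, min_len: int = 3):
    """Yield (chain_id, start_index, end_index) for 'E' runs of >= min_len."""
    for cid, residues in structure.chains.items():
        labels = structure.ss.get(cid)
        if labels is None:
            continue
        run_start = None
        for k, lab in enumerate(labels + ["L"]):
            if lab == "E" and run_start is None:
                run_start = k
            elif lab != "E" and run_start is not None:
                if k - run_start >= min_len:
                    yield cid, residues[run_start].index, residues[k - 1].index
                run_start = None
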