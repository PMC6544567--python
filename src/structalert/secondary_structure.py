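"""Kabsch–Sander (DSSP-style) 8-class secondary-structure assignment.

Backbone H-bonds are scored with the Kabsch–Sander electrostatic model

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

with the amide hydrogen placed geometrically (1.0 Å from N, opposite the
bisector of the C(i-1)–N and CA–N bonds).  A hydrogen bond exists when
E < −0.5 kcal/mol; proline contributes no donor.  Pattern rules then produce
the 8 classes H, B, E, G, I, T, S, C with the classic priority
H > E/B > G > I > T > S > C.  A bend (S) is a CA-trace curvature above 70°.

Exact agreement with any particular DSSP release is not claimed; the contract
used downstream is only whether the class at a position changes between two
models that share a backbone.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .structure_io import Residue, Structure
from .geometry import PEPTIDE_BOND_MAX

__all__ = ["SSAssignment", "assign_secondary_structure", "ss_changed_at",
           "kabsch_sander_energy"]

Q1Q2_F = 0.084 * 332.0  # kcal/mol·Å, Kabsch–Sander coupling constant
HBOND_ENERGY_CUTOFF = -0.5
BEND_ANGLE_MIN = 70.0  # degrees of CA-trace curvature for a bend (S)
_MIN_E = -9.9


@dataclasses.dataclass
class SSAssignment:
    """Per-residue 8-class assignment plus the backbone H-bond list."""

    classes: dict[tuple, str]                       # res_id -> class
    hbonds: list[tuple[tuple, tuple, float]]        # (donor res_id, acceptor res_id, E)

    def at(self, res_id: tuple) -> str:
        return self.classes.get(res_id, "C")


def kabsch_sander_energy(n: np.ndarray, h: np.ndarray,
                         c: np.ndarray, o: np.ndarray) -> float:
    """Electrostatic H-bond energy of donor (N–H) vs acceptor (C=O), kcal/mol."""
    r_on = float(np.linalg.norm(o - n))
    r_ch = float(np.linalg.norm(c - h))
    r_oh = float(np.linalg.norm(o - h))
    r_cn = float(np.linalg.norm(c - n))
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return _MIN_E
    e = Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return max(e, _MIN_E)


def _amide_h(prev_c: np.ndarray, n: np.ndarray, ca: np.ndarray) -> np.ndarray:
    """Geometric amide H: 1.0 Å from N, opposite the bisector of C(i-1)–N and CA–N."""
    v1 = prev_c - n
    v2 = ca - n
    v1 /= np.linalg.norm(v1)
    v2 /= np.linalg.norm(v2)
    d = -(v1 + v2)
    norm = np.linalg.norm(d)
    if norm < 1e-6:  # degenerate colinear geometry
        d = np.cross(v1, np.array([1.0, 0.0, 0.0]))
        norm = np.linalg.norm(d)
    return n + d / norm


def _chain_segments(s: Structure) -> list[list[Residue]]:
    """Split each chain into covalently continuous segments of standard residues."""
    from .geometry import _connected
    segments = []
    for cid in s.chain_ids():
        chain = [r for r in s.chains[cid] if not r.het and r.one_letter is not None]
        seg: list[Residue] = []
        for res in chain:
            if seg and not _connected(seg[-1], res):
                segments.append(seg)
                seg = []
            seg.append(res)
        if seg:
            segments.append(seg)
    return segments


def assign_secondary_structure(s: Structure) -> SSAssignment:
    segments = _chain_segments(s)
    residues: list[Residue] = [r for seg in segments for r in seg]
    index = {id(r): i for i, r in enumerate(residues)}
    n_res = len(residues)
    classes = {r.res_id: "C" for r in residues}

    # segment id and position-in-segment for adjacency checks
    seg_of = {}
    pos_in_seg = {}
    for si, seg in enumerate(segments):
        for pi, r in enumerate(seg):
            seg_of[id(r)] = si
            pos_in_seg[id(r)] = pi

    # H-bond matrix: bond[i][j] = donor i -> acceptor j
    hbonds: list[tuple[tuple, tuple, float]] = []
    bond = np.zeros((n_res, n_res), dtype=bool)
    ca_coords = []
    for r in residues:
        ca = r.atom("CA")
        ca_coords.append(ca.coord if ca is not None else None)

    # donors: N-H of every residue with a predecessor in its segment, except Pro
    for si, seg in enumerate(segments):
        for pi, don in enumerate(seg):
            if pi == 0 or don.one_letter == "P":
                continue
            n_at, ca_at = don.atom("N"), don.atom("CA")
            prev_c = seg[pi - 1].atom("C")
            if n_at is None or ca_at is None or prev_c is None:
                continue
            h = _amide_h(prev_c.coord, n_at.coord, ca_at.coord)
            i = index[id(don)]
            for acc in residues:
                j = index[id(acc)]
                if acc is don:
                    continue
                # skip immediate neighbours within the same segment
                if seg_of[id(acc)] == si and abs(pos_in_seg[id(acc)] - pi) < 2:
                    continue
                c_at, o_at = acc.atom("C"), acc.atom("O")
                if c_at is None or o_at is None:
                    continue
                acc_ca = acc.atom("CA")
                if acc_ca is not None and \
                        float(np.linalg.norm(ca_at.coord - acc_ca.coord)) > 9.0:
                    continue
                e = kabsch_sander_energy(n_at.coord, h, c_at.coord, o_at.coord)
                if e < HBOND_ENERGY_CUTOFF:
                    bond[i, j] = True
                    hbonds.append((don.res_id, acc.res_id, e))

    def same_seg_offset(i: int, n: int) -> Optional[int]:
        """Index of residue n positions after i within the same segment."""
        j = i + n
        if 0 <= j < n_res and seg_of[id(residues[i])] == seg_of[id(residues[j])]:
            return j
        return None

    # n-turns: donor i+n -> acceptor i
    def turn(i: int, n: int) -> bool:
        j = same_seg_offset(i, n)
        return j is not None and bond[j, i]

    # helices: two consecutive n-turns starting at i-1 and i -> i..i+n-1 helical
    helix_marks = {3: np.zeros(n_res, bool), 4: np.zeros(n_res, bool), 5: np.zeros(n_res, bool)}
    for n in (3, 4, 5):
        for i in range(1, n_res):
            if turn(i - 1, n) and turn(i, n):
                for k in range(i, min(i + n, n_res)):
                    if seg_of[id(residues[k])] == seg_of[id(residues[i])]:
                        helix_marks[n][k] = True

    # bridges
    parallel = np.zeros((n_res, n_res), bool)
    antipar = np.zeros((n_res, n_res), bool)
    for i in range(n_res):
        for j in range(n_res):
            if abs(i - j) < 3 and seg_of[id(residues[i])] == seg_of[id(residues[j])]:
                continue
            im1 = same_seg_offset(i, -1)
            ip1 = same_seg_offset(i, 1)
            jm1 = same_seg_offset(j, -1)
            jp1 = same_seg_offset(j, 1)
            # parallel: Hbond(i-1 -> j) and Hbond(j -> i+1), or Hbond(j-1 -> i) and Hbond(i -> j+1)
            p = False
            if im1 is not None and ip1 is not None and bond[im1, j] and bond[j, ip1]:
                p = True
            if jm1 is not None and jp1 is not None and bond[jm1, i] and bond[i, jp1]:
                p = True
            if p:
                parallel[i, j] = True
            # antiparallel: Hbond(i -> j) and Hbond(j -> i), or Hbond(i-1 -> j+1) and Hbond(j-1 -> i+1)
            a = False
            if bond[i, j] and bond[j, i]:
                a = True
            if im1 is not None and ip1 is not None and jm1 is not None and jp1 is not None \
                    and bond[im1, jp1] and bond[jm1, ip1]:
                a = True
            if a:
                antipar[i, j] = True

    bridge = parallel | antipar
    has_bridge = bridge.any(axis=1)
    # ladders: consecutive bridges -> E; isolated bridge -> B
    strand = np.zeros(n_res, bool)
    for i in range(n_res):
        if not has_bridge[i]:
            continue
        for j in np.nonzero(bridge[i])[0]:
            ip1 = same_seg_offset(i, 1)
            im1 = same_seg_offset(i, -1)
            neighbour_bridge = False
            for di in (im1, ip1):
                if di is None:
                    continue
                if bridge[di].any():
                    for jj in np.nonzero(bridge[di])[0]:
                        if abs(int(jj) - int(j)) <= 1:
                            neighbour_bridge = True
            if neighbour_bridge:
                strand[i] = True

    # turns: residues spanned by an n-turn
    turn_mark = np.zeros(n_res, bool)
    for n in (3, 4, 5):
        for i in range(n_res):
            if turn(i, n):
                for k in range(i + 1, i + n):
                    if 0 <= k < n_res and seg_of[id(residues[k])] == seg_of[id(residues[i])]:
                        turn_mark[k] = True

    # bends: CA curvature > 70 degrees
    bend = np.zeros(n_res, bool)
    for i in range(n_res):
        a = same_seg_offset(i, -2)
        b = same_seg_offset(i, 2)
        if a is None or b is None:
            continue
        if ca_coords[a] is None or ca_coords[i] is None or ca_coords[b] is None:
            continue
        u = ca_coords[i] - ca_coords[a]
        v = ca_coords[b] - ca_coords[i]
        cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if ang > BEND_ANGLE_MIN:
            bend[i] = True

    # priority: H > E > B > G > I > T > S > C
    for i, r in enumerate(residues):
        if helix_marks[4][i]:
            classes[r.res_id] = "H"
        elif strand[i]:
            classes[r.res_id] = "E"
        elif has_bridge[i]:
            classes[r.res_id] = "B"
        elif helix_marks[3][i]:
            classes[r.res_id] = "G"
        elif helix_marks[5][i]:
            classes[r.res_id] = "I"
        elif turn_mark[i]:
            classes[r.res_id] = "T"
        elif bend[i]:
            classes[r.res_id] = "S"
        else:
            classes[r.res_id] = "C"
    return SSAssignment(classes, hbonds)


def ss_changed_at(wt: SSAssignment, mut: SSAssignment, res_id: tuple) -> bool:
    """True iff the 8-class assignment differs at the given residue."""
    if set(wt.classes) != set(mut.classes):
        raise ValueError("assignments cover different residue sets")
    return wt.at(res_id) != mut.at(res_id)
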