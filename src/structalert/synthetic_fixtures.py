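"""Deterministic synthetic structures exercising every geometric kernel and
every alert feature without any external coordinate files.

Backbones are built from ideal peptide geometry by torsion-driven chain
extension (NeRF); side chains are grafted from ideal residue templates at
requested chi angles (default: extended/trans).  Engineered fixtures place
disulfide partners, salt-bridge partners, burial cages and carved cavities at
exactly requested geometry.  Optional Gaussian coordinate jitter emulates
homology-model error; backbone jitter can be suppressed separately, mirroring
the observation that predicted models preserve the backbone better than the
side chains.

All generators are pure functions of their arguments (plus seed): identical
calls give bitwise-identical structures.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .structure_io import AA1_TO_3, Atom, Residue, Structure
from .geometry import dihedral
from .mutant_builder import CHI_ATOMS, _SidechainModel, sidechain_template

__all__ = [
    "place_atom", "build_backbone", "build_peptide", "ideal_helix",
    "ideal_strand", "ideal_strand_pair", "disulfide_pair", "salt_bridge_pair",
    "hbond_pair", "buried_hbond_pair", "buried_salt_bridge", "buried_core",
    "add_cage", "carved_cavity", "cis_pro_loop", "bend_gly", "rama_trap",
    "apply_jitter", "make_cohort", "cohort_recipe", "evaluate_cohort",
    "FixtureSpec", "make_fixture", "DEFAULT_CAGE_SHELLS",
]

# ideal backbone geometry (Å, degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O = 111.2, 116.2, 121.7, 120.8

HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -139.0, 135.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF: position of atom D given A-B-C, |CD|, angle(BCD), torsion(ABCD)."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(n_res: int, phi: Sequence[float], psi: Sequence[float],
                   omega: Sequence[float]) -> list[dict[str, np.ndarray]]:
    """Backbone coordinates (N, CA, C, O per residue) from torsion angles.

    ``phi[i]``/``psi[i]``/``omega[i]`` follow the usual convention: omega[i]
    is the peptide torsion preceding residue i (omega[0] unused)."""
    res: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([B_N_CA, 0.0, 0.0])
    ang = math.radians(A_N_CA_C)
    c0 = ca0 + np.array([-B_CA_C * math.cos(ang), B_CA_C * math.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = res[-1]
        n = place_atom(prev["N"], prev["CA"], prev["C"], B_C_N, A_CA_C_N, psi[i - 1])
        ca = place_atom(prev["CA"], prev["C"], n, B_N_CA, A_C_N_CA, omega[i])
        c = place_atom(prev["C"], n, ca, B_CA_C, A_N_CA_C, phi[i])
        res.append({"N": n, "CA": ca, "C": c})
    # carbonyl O: anti to the next amide N; last residue uses trans psi of 180
    for i, bb in enumerate(res):
        if i + 1 < n_res:
            next_n = res[i + 1]["N"]
            o = place_atom(next_n, bb["CA"], bb["C"], B_C_O, A_CA_C_O, 180.0)
        else:
            o = place_atom(bb["N"], bb["CA"], bb["C"], B_C_O, A_CA_C_O, psi[i] + 180.0)
        bb["O"] = o
    return res


def build_peptide(sequence: str, phi: Sequence[float], psi: Sequence[float],
                  omega: Optional[Sequence[float]] = None, chain_id: str = "A",
                  start: int = 1,
                  chis: Optional[dict[int, tuple[float, ...]]] = None) -> Structure:
    """Full heavy-atom peptide from sequence and backbone torsions.

    Side chains are grafted from ideal templates; all defined chi angles are
    set to 180° (extended) unless overridden via ``chis`` (0-based residue
    index -> chi tuple)."""
    n = len(sequence)
    omega = list(omega) if omega is not None else [180.0] * n
    bbs = build_backbone(n, list(phi), list(psi), omega)
    s = Structure(provenance="synthetic")
    chain: list[Residue] = []
    for i, aa in enumerate(sequence):
        resname = AA1_TO_3[aa]
        res = Residue(resname, start + i, "", chain_id)
        for name in ("N", "CA", "C", "O"):
            el = name[0]
            res.atoms.append(Atom(name, el, bbs[i][name].copy()))
        if resname not in ("GLY",):
            model = _SidechainModel(res, resname)
            n_chi = len(model.chi_quads)
            if chis is not None and i in chis:
                target = tuple(chis[i])[:n_chi]
                target += (180.0,) * (n_chi - len(target))
            else:
                target = (180.0,) * n_chi
            coords = model.with_chis(target) if n_chi else model.base_coords
            for nm, xyz, elm in zip(model.names, coords, model.elements):
                res.atoms.append(Atom(nm, elm, np.array(xyz)))
        chain.append(res)
    s.chains[chain_id] = chain
    return s


def ideal_helix(sequence: str = "A" * 12, chain_id: str = "A",
                phi: float = HELIX_PHI, psi: float = HELIX_PSI,
                chis: Optional[dict[int, tuple[float, ...]]] = None) -> Structure:
    n = len(sequence)
    return build_peptide(sequence, [phi] * n, [psi] * n, chain_id=chain_id, chis=chis)


def ideal_strand(sequence: str = "A" * 8, chain_id: str = "A",
                 phi: float = STRAND_PHI, psi: float = STRAND_PSI) -> Structure:
    n = len(sequence)
    return build_peptide(sequence, [phi] * n, [psi] * n, chain_id=chain_id)


def _transform(s: Structure, rot: np.ndarray, trans: np.ndarray) -> None:
    for res in s.residues(standard_only=False):
        for a in res.atoms:
            a.coord = rot @ a.coord + trans


def _merge(a: Structure, b: Structure) -> Structure:
    out = Structure(provenance="synthetic")
    for cid, chain in a.chains.items():
        out.chains[cid] = [r.copy() for r in chain]
    for cid, chain in b.chains.items():
        if cid in out.chains:
            raise ValueError(f"duplicate chain id {cid!r} when merging fixtures")
        out.chains[cid] = [r.copy() for r in chain]
    return out


_ROT_Z_180 = np.diag([-1.0, -1.0, 1.0])


def _align_to_repeat_axis(s: Structure, chain_id: str) -> Structure:
    """Rotate/translate a uniform-torsion chain so its 2-residue repeat axis
    lies along +x and the carbonyl direction of residue 4 along +y."""
    ch = s.chains[chain_id]
    ca = np.array([r.atom("CA").coord for r in ch])
    t = ca[4] - ca[2]
    x = t / np.linalg.norm(t)
    co = ch[3].atom("O").coord - ch[3].atom("C").coord
    y = co - x * np.dot(co, x)
    y /= np.linalg.norm(y)
    z = np.cross(x, y)
    rot = np.stack([x, y, z])
    origin = ca[0].copy()
    for r in ch:
        for a in r.atoms:
            a.coord = rot @ (a.coord - origin)
    return s


def _count_ks_bonds(a: Structure, b: Structure) -> int:
    """Fast count of inter-chain Kabsch–Sander bonds between two segments."""
    from .secondary_structure import (HBOND_ENERGY_CUTOFF, _amide_h,
                                      kabsch_sander_energy)

    def donors(s: Structure):
        out = []
        for chain in s.chains.values():
            for k in range(1, len(chain)):
                res, prev = chain[k], chain[k - 1]
                if res.one_letter == "P":
                    continue
                out.append((res.atom("N").coord,
                            _amide_h(prev.atom("C").coord, res.atom("N").coord,
                                     res.atom("CA").coord)))
        return out

    def acceptors(s: Structure):
        return [(res.atom("C").coord, res.atom("O").coord)
                for chain in s.chains.values() for res in chain]

    n = 0
    for s_d, s_a in ((a, b), (b, a)):
        for nc, hc in donors(s_d):
            for cc, oc in acceptors(s_a):
                if np.linalg.norm(nc - oc) > 5.2:
                    continue
                if kabsch_sander_energy(nc, hc, cc, oc) < HBOND_ENERGY_CUTOFF:
                    n += 1
    return n


def ideal_strand_pair(n_res: int = 10, sequence: Optional[str] = None) -> Structure:
    """Two H-bond-paired antiparallel strands (central residues assign E).

    Fully extended chains (phi = psi = 180°) are exactly periodic (their
    2-residue repeat is a pure translation), so once one mutual narrow-pair
    H-bond forms, the whole ladder does.  Chain A is aligned to its repeat
    axis; chain B is its C2 image about z, at the register that gives six
    mutual Kabsch-Sander bonds with no steric clash (constants derived for
    the default 10-residue glycine chains; the register shifts by half a
    repeat per added residue pair).  Glycine is the default sequence: with
    no side chains the inter-strand space stays clash-free.  Substituting a
    proline into one strand removes an amide donor and deletes the bridge at
    that position."""
    if n_res % 2 or n_res < 8:
        raise ValueError("n_res must be even and >= 8")
    seq = sequence if sequence is not None else "G" * n_res
    if len(seq) != n_res:
        raise ValueError("sequence length must equal n_res")
    phi = [180.0] * n_res
    psi = [180.0] * n_res
    s1 = _align_to_repeat_axis(build_peptide(seq, phi, psi, chain_id="A"), "A")
    s2 = _align_to_repeat_axis(build_peptide(seq, phi, psi, chain_id="B"), "B")
    dx = 21.0 + 3.6265 * (n_res - 10)
    _transform(s2, _ROT_Z_180, np.array([dx, 4.4, 0.0]))
    return _merge(s1, s2)


def disulfide_pair(sg_distance: float = 2.05, arm: str = "AACAA") -> Structure:
    """Two short segments whose Cys SG atoms sit at exactly ``sg_distance``
    with proper disulfide stereochemistry (CB–S–S angles ≈ 104°, CB–S–S–CB
    dihedral ≈ 90°), the free azimuth chosen by a deterministic scan that
    maximises backbone separation."""
    from scipy.spatial import cKDTree
    from .mutant_builder import _kabsch

    if sg_distance < 1.0:
        raise ValueError("SG-SG distance below 1 Å is not a feasible geometry")
    cys_pos = arm.index("C")
    s1 = ideal_strand(arm, chain_id="A")
    cys1 = s1.chains["A"][cys_pos]
    sg1 = cys1.atom("SG").coord
    cb1 = cys1.atom("CB").coord
    tree = cKDTree(np.array([a.coord for r in s1.chains["A"] for a in r.atoms]))

    best = None
    for phi in np.arange(0.0, 360.0, 5.0):
        # S2 at 104° from the CB1-S1 bond, azimuth phi
        s2_pos = place_atom(cys1.atom("CA").coord, cb1, sg1,
                            sg_distance, 104.0, phi)
        # CB of the partner Cys: proper angle at S2 and ~90° S-S dihedral
        cb2_pos = place_atom(cb1, sg1, s2_pos, 1.81, 104.0, 90.0)
        ca2_pos = place_atom(sg1, s2_pos, cb2_pos, 1.53, 114.0, 180.0)
        s2 = ideal_strand(arm, chain_id="B")
        cys2 = s2.chains["B"][cys_pos]
        mobile = np.array([cys2.atom("SG").coord, cys2.atom("CB").coord,
                           cys2.atom("CA").coord])
        target = np.array([s2_pos, cb2_pos, ca2_pos])
        r, cm, ct = _kabsch(mobile, target)
        _transform(s2, r, ct - r @ cm)
        # exact SG distance (Kabsch residual is within template tolerance)
        _transform(s2, np.eye(3), s2_pos - cys2.atom("SG").coord)
        b_coords = np.array([a.coord for res in s2.chains["B"] for a in res.atoms])
        clearance = float(np.sort(tree.query(b_coords, k=1)[0])[2])
        if best is None or clearance > best[0] + 1e-12:
            best = (clearance, s2)
    return _merge(s1, best[1])


def salt_bridge_pair(distances: tuple[float, float] = (2.6, 3.8),
                     pos_aa: str = "H", neg_aa: str = "E") -> Structure:
    """A positively charged residue facing an acidic one, with the two
    charged-group N–O distances set to the requested values.

    The first distance is exact by construction; the second is matched by a
    rotation about the first contact.  Both the approach azimuth and the
    rotation angle are chosen by a deterministic scan that meets the distance
    target and maximises the separation of everything except the bridging
    groups, so the contact itself is the only close approach."""
    from scipy.spatial import cKDTree
    from .interactions import POSITIVE_N, NEGATIVE_O
    from .mutant_builder import _rotate_about_axis

    d1, d2 = distances
    s1 = ideal_strand(f"AA{pos_aa}AA", chain_id="A")
    res_pos = s1.chains["A"][2]
    n_atoms = POSITIVE_N[res_pos.resname]
    o_names = NEGATIVE_O[AA1_TO_3[neg_aa]]
    n1 = res_pos.atom(n_atoms[-1]).coord
    a_tree = cKDTree(np.array([a.coord for r in s1.chains["A"] for a in r.atoms]))
    contact_names = set(n_atoms) | set(o_names)

    best_global = None
    for az in np.arange(0.0, 360.0, 30.0):
        direction = np.array([0.0, math.cos(math.radians(az)),
                              math.sin(math.radians(az))])
        s2 = ideal_strand(f"AA{neg_aa}AA", chain_id="B")
        _transform(s2, _ROT_Z_180, np.zeros(3))
        res_neg = s2.chains["B"][2]
        o1 = res_neg.atom(o_names[0])
        _transform(s2, np.eye(3), (n1 + d1 * direction) - o1.coord)
        o2 = res_neg.atom(o_names[-1]) if len(o_names) > 1 else None
        if o2 is None:
            cands = [0.0]
            axis_p1 = o1.coord.copy()
            axis_p2 = axis_p1 + np.array([1.0, 0.0, 0.0])
        else:
            a_vec = n1 - o1.coord
            w_vec = o2.coord - o1.coord
            u = np.cross(a_vec, w_vec)
            if np.linalg.norm(u) < 1e-6:
                u = np.cross(a_vec, np.array([0.0, 0.0, 1.0]))
            u /= np.linalg.norm(u)
            axis_p1 = o1.coord.copy()
            axis_p2 = axis_p1 + u
            errs = []
            for ang in np.arange(0.0, 360.0, 0.25):
                ro2 = _rotate_about_axis(o2.coord[None, :], axis_p1, axis_p2, ang)[0]
                errs.append((abs(float(np.linalg.norm(ro2 - n1)) - d2), ang))
            emin = min(e for e, _ in errs)
            cands = [ang for e, ang in errs if e <= emin + 0.02]
        far = np.array([a.coord for r in s2.chains["B"] for a in r.atoms
                        if a.name not in contact_names])
        for ang in cands:
            rb = _rotate_about_axis(far, axis_p1, axis_p2, ang)
            clearance = float(a_tree.query(rb, k=1)[0].min())
            if best_global is None or clearance > best_global[0] + 1e-12:
                best_global = (clearance, az, ang)

    _, az, ang = best_global
    direction = np.array([0.0, math.cos(math.radians(az)),
                          math.sin(math.radians(az))])
    s2 = ideal_strand(f"AA{neg_aa}AA", chain_id="B")
    _transform(s2, _ROT_Z_180, np.zeros(3))
    res_neg = s2.chains["B"][2]
    o1 = res_neg.atom(o_names[0])
    _transform(s2, np.eye(3), (n1 + d1 * direction) - o1.coord)
    if res_neg.atom(o_names[-1]) is not None and len(o_names) > 1:
        a_vec = n1 - o1.coord
        w_vec = res_neg.atom(o_names[-1]).coord - o1.coord
        u = np.cross(a_vec, w_vec)
        if np.linalg.norm(u) < 1e-6:
            u = np.cross(a_vec, np.array([0.0, 0.0, 1.0]))
        u /= np.linalg.norm(u)
        axis_p1 = o1.coord.copy()
        axis_p2 = axis_p1 + u
        for res in s2.chains["B"]:
            for a in res.atoms:
                a.coord = _rotate_about_axis(a.coord[None, :], axis_p1,
                                             axis_p2, ang)[0]
    return _merge(s1, s2)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


DEFAULT_CAGE_SHELLS: tuple[tuple[float, int], ...] = ((5.4, 30), (8.8, 70))


def add_cage(s: Structure, center: np.ndarray,
             shells: tuple[tuple[float, int], ...] = DEFAULT_CAGE_SHELLS,
             min_clearance: float = 3.2, chain_id: str = "Z") -> Structure:
    """Enclose a structure in concentric spherical shells of carbon blockers.

    Each blocker is a single-CA glycine pseudo-residue; two Fibonacci-sphere
    shells with ~3 Å spacing occlude solvent (burying whatever sits at
    ``center``) without creating steric clashes (closest approach stays above
    the 0.4 Å-overlap clash criterion) and without enlarging the repack zone
    (no side chains, no backbone).  Points closer than ``min_clearance`` to an
    existing atom are dropped."""
    from scipy.spatial import cKDTree

    core_pts = np.array([a.coord for r in s.residues() for a in r.atoms])
    tree = cKDTree(core_pts)
    out = s.copy()
    cage: list[Residue] = []
    k = 0
    for radius, n_points in shells:
        pts = _fibonacci_sphere(n_points) * radius + center
        for p in pts:
            if tree.query(p)[0] < min_clearance:
                continue
            k += 1
            res = Residue("GLY", k, "", chain_id)
            res.atoms.append(Atom("CA", "C", p.copy()))
            cage.append(res)
    if chain_id in out.chains:
        raise ValueError(f"chain id {chain_id!r} already used")
    out.chains[chain_id] = cage
    return out


def buried_core(target_aa: str = "L",
                shells: tuple[tuple[float, int], ...] = DEFAULT_CAGE_SHELLS) -> Structure:
    """A short helix whose central residue is buried (RSA < 9%) in a cage."""
    seq = "AA" + target_aa + "AA"
    core = ideal_helix(seq, chain_id="A")
    center = core.chains["A"][2].atom("CA").coord
    return add_cage(core, center, shells=shells)


def carved_cavity(void: float = 5.0, wall_layers: int = 3,
                  spacing: float = 2.0) -> Structure:
    """A dense carbon lattice with a cubic void of side ``void`` between the
    van-der-Waals surfaces of the walls (analytic volume = void**3)."""
    from .geometry import vdw_radius

    r_c = vdw_radius("C")
    half_inner = void / 2.0 + r_c        # nearest atom-centre plane
    # 1D coordinates anchored on the inner wall faces so the van-der-Waals
    # surfaces of the innermost atoms sit exactly at ±void/2
    outer = [half_inner + k * spacing for k in range(wall_layers)]
    n_inner = int(math.ceil(2.0 * half_inner / spacing)) + 1
    inner = list(np.linspace(-half_inner, half_inner, n_inner))
    axis_vals = sorted(set([-v for v in outer] + inner + outer))
    coords = []
    for x in axis_vals:
        for y in axis_vals:
            for z in axis_vals:
                if max(abs(x), abs(y), abs(z)) < half_inner - 1e-9:
                    continue  # carved void
                coords.append((x, y, z))
    s = Structure(provenance="synthetic")
    chain: list[Residue] = []
    for k, xyz in enumerate(coords):
        res = Residue("GLY", k + 1, "", "A")
        res.atoms.append(Atom("CA", "C", np.array(xyz, dtype=float)))
        chain.append(res)
    s.chains["A"] = chain
    return s


def rama_trap(gly_index: int = 4, length: int = 9) -> Structure:
    """A strand with its glycine at (phi, psi) = (80°, −100°): inside the
    glycine-specific allowed region but an outlier for every other residue
    class, so any substitution of the glycine trips the torsion alert."""
    seq = ("A" * gly_index) + "G" + ("A" * (length - gly_index - 1))
    n = len(seq)
    phi = [STRAND_PHI] * n
    psi = [STRAND_PSI] * n
    phi[gly_index] = 80.0
    psi[gly_index] = -100.0
    return build_peptide(seq, phi, psi)


def hbond_pair(distance: float = 3.0) -> Structure:
    """A glutamine whose side-chain NE2 donates to a facing glutamine OE1 at
    the requested N–O distance; substituting away the target side chain
    breaks every side-chain H-bond of the target.  Long side chains keep the
    two backbones well separated."""
    from scipy.spatial import cKDTree
    from .mutant_builder import _rotate_about_axis

    s1 = ideal_strand("AAQAA", chain_id="A")
    ne2 = s1.chains["A"][2].atom("NE2").coord
    tree = cKDTree(np.array([a.coord for r in s1.chains["A"] for a in r.atoms]))
    target_polar = np.array([s1.chains["A"][2].atom(n).coord
                             for n in ("OE1", "NE2")])
    polar_tree = cKDTree(target_polar)

    # scan the approach azimuth and the spin about the N-O axis; prefer
    # placements where no *other* B-side N/O sits in H-bond range of the
    # target's polar atoms (a single clean side-chain bond), then maximise
    # the overall clearance
    best = None
    for az in np.arange(0.0, 360.0, 30.0):
        direction = np.array([0.0, math.cos(math.radians(az)),
                              math.sin(math.radians(az))])
        s2 = ideal_strand("AAQAA", chain_id="B")
        _transform(s2, _ROT_Z_180, np.zeros(3))
        og = s2.chains["B"][2].atom("OE1")
        _transform(s2, np.eye(3), (ne2 + distance * direction) - og.coord)
        axis_p1 = og.coord.copy()
        axis_p2 = axis_p1 + (axis_p1 - ne2)
        b_all = np.array([a.coord for r in s2.chains["B"] for a in r.atoms])
        b_no = np.array([a.coord for r in s2.chains["B"] for a in r.atoms
                         if a.element.upper() in ("N", "O") and a.name != "OE1"])
        for ang in np.arange(0.0, 360.0, 5.0):
            rb = _rotate_about_axis(b_all, axis_p1, axis_p2, ang)
            clearance = float(np.sort(tree.query(rb, k=1)[0])[1])
            rno = _rotate_about_axis(b_no, axis_p1, axis_p2, ang)
            extra_no = float(polar_tree.query(rno, k=1)[0].min())
            key = (extra_no > 4.2, clearance)
            if best is None or key > best[0]:
                best = (key, az, ang)

    _, az, ang = best
    direction = np.array([0.0, math.cos(math.radians(az)),
                          math.sin(math.radians(az))])
    s2 = ideal_strand("AAQAA", chain_id="B")
    _transform(s2, _ROT_Z_180, np.zeros(3))
    og = s2.chains["B"][2].atom("OE1")
    _transform(s2, np.eye(3), (ne2 + distance * direction) - og.coord)
    axis_p1 = og.coord.copy()
    axis_p2 = axis_p1 + (axis_p1 - ne2)
    for res in s2.chains["B"]:
        for a in res.atoms:
            a.coord = _rotate_about_axis(a.coord[None, :], axis_p1, axis_p2,
                                         ang)[0]
    return _merge(s1, s2)


def buried_hbond_pair(distance: float = 3.0) -> Structure:
    """:func:`hbond_pair` enclosed in a cage so the donor residue is buried."""
    pair = hbond_pair(distance)
    center = pair.chains["A"][2].atom("CA").coord
    return add_cage(pair, center)


def buried_salt_bridge(distances: tuple[float, float] = (2.6, 3.8)) -> Structure:
    """:func:`salt_bridge_pair` enclosed in a cage so the charged residue is
    buried."""
    pair = salt_bridge_pair(distances)
    center = pair.chains["A"][2].atom("CA").coord
    return add_cage(pair, center)


def cis_pro_loop(pro_index: int = 3, length: int = 7) -> Structure:
    """A peptide whose proline has a cis (omega ≈ 0°) preceding peptide bond."""
    seq = ("A" * pro_index) + "P" + ("A" * (length - pro_index - 1))
    n = len(seq)
    phi = [STRAND_PHI] * n
    psi = [STRAND_PSI] * n
    phi[pro_index] = -75.0
    omega = [180.0] * n
    omega[pro_index] = 0.0
    return build_peptide(seq, phi, psi, omega)


def bend_gly(gly_index: int = 4, length: int = 9) -> Structure:
    """An extended chain with a sharp CA-trace kink at a glycine (DSSP 'S')."""
    seq = ("A" * gly_index) + "G" + ("A" * (length - gly_index - 1))
    n = len(seq)
    phi = [STRAND_PHI] * n
    psi = [STRAND_PSI] * n
    # a localised kink produces >70° CA curvature; (-90, 0) stays inside the
    # generally allowed torsion region so only the bend criterion is special
    phi[gly_index] = -90.0
    psi[gly_index] = 0.0
    return build_peptide(seq, phi, psi)


def apply_jitter(s: Structure, sigma: float, seed: int,
                 jitter_backbone: bool = True) -> Structure:
    """Gaussian coordinate noise (i.i.d., σ in Å); optionally leave the
    backbone exact to emulate homology models with well-conserved backbones."""
    from .structure_io import BACKBONE_ATOMS
    rng = np.random.default_rng(seed)
    out = s.copy()
    for res in out.residues(standard_only=False):
        for a in res.atoms:
            noise = rng.normal(0.0, sigma, 3)
            if not jitter_backbone and a.name in BACKBONE_ATOMS:
                continue
            a.coord = a.coord + noise
    return out


# ---------------------------------------------------------------------------
# labelled cohorts with planted effects
# ---------------------------------------------------------------------------

# feature -> (fixture builder, firing substitution (chain, position, wt, mut))
_FIRING_RECIPES: dict[str, tuple] = {
    "disulfide_breakage": (lambda: disulfide_pair(2.05), ("A", 3, "C", "A")),
    "buried_pro_introduced": (lambda: buried_core("L"), ("A", 3, "L", "P")),
    "buried_hydrophilic_introduced": (lambda: buried_core("L"), ("A", 3, "L", "N")),
    "buried_charge_introduced": (lambda: buried_core("V"), ("A", 3, "V", "D")),
    "buried_charge_switch": (lambda: buried_core("D"), ("A", 3, "D", "K")),
    "buried_charge_replaced": (lambda: buried_core("D"), ("A", 3, "D", "S")),
    "buried_gly_replaced": (lambda: buried_core("G"), ("A", 3, "G", "A")),
    "cis_pro_replaced": (lambda: cis_pro_loop(), ("A", 4, "P", "A")),
    "gly_in_bend": (lambda: bend_gly(), ("A", 5, "G", "A")),
}

#: benign substitution on an exposed helix surface: fires nothing
_BENIGN_RECIPE = (lambda: ideal_helix("A" * 9), ("A", 5, "A", "S"))


def cohort_recipe(feature: str, fire: bool):
    """(structure builder, variant tuple) for a planted cohort entry."""
    if not fire:
        return _BENIGN_RECIPE
    if feature not in _FIRING_RECIPES:
        raise KeyError(f"no firing recipe for feature {feature!r}")
    return _FIRING_RECIPES[feature]


def make_cohort(n_disease: int, n_neutral: int,
                rates: dict[str, tuple[float, float]],
                seed: int) -> pd.DataFrame:
    """Labelled variant table with planted per-feature firing.

    ``rates`` maps feature name -> (disease firing rate, neutral firing rate).
    Features are assigned to variants round-robin; each variant then fires its
    assigned feature with the planted probability (seeded, reproducible).
    Columns: id, chain, position, wt, mut, label, MAF, assigned_feature,
    planted_fire.  Structures are rebuilt on demand via
    :func:`cohort_recipe`, keeping the table plain data."""
    feats = sorted(rates)
    if not feats:
        raise ValueError("at least one planted feature required")
    for f, (r1, r2) in rates.items():
        if not (0.0 <= r1 <= 1.0 and 0.0 <= r2 <= 1.0):
            raise ValueError(f"rates for {f} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for label, n, which in (("disease", n_disease, 0), ("neutral", n_neutral, 1)):
        for k in range(n):
            feat = feats[k % len(feats)]
            fire = bool(rng.random() < rates[feat][which])
            _, (chain, pos, wt, mut) = cohort_recipe(feat, fire)
            maf = float(np.round(rng.choice([0.05, 0.001, np.nan]), 6)) \
                if label == "neutral" else np.nan
            rows.append({"id": f"{label[:1]}{k:04d}", "chain": chain,
                         "position": pos, "wt": wt, "mut": mut, "label": label,
                         "MAF": maf, "assigned_feature": feat,
                         "planted_fire": fire})
    return pd.DataFrame(rows)


import dataclasses


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic structure.

    ``kind`` selects the generator; ``params`` are its keyword arguments;
    ``sigma``/``seed`` add optional Gaussian coordinate jitter (Å).  The
    same spec always produces a bitwise-identical structure."""

    kind: str
    params: tuple = ()            # sorted (key, value) pairs
    sigma: float = 0.0
    seed: int = 0
    jitter_backbone: bool = True

    def param_dict(self) -> dict:
        return dict(self.params)


_FIXTURE_KINDS = {
    "ideal-helix": lambda **kw: ideal_helix(**kw),
    "ideal-strand-pair": lambda **kw: ideal_strand_pair(**kw),
    "disulfide-pair": lambda **kw: disulfide_pair(**kw),
    "salt-bridge-pair": lambda **kw: salt_bridge_pair(**kw),
    "hbond-pair": lambda **kw: hbond_pair(**kw),
    "buried-core": lambda **kw: buried_core(**kw),
    "carved-cavity": lambda **kw: carved_cavity(**kw),
    "cis-pro-loop": lambda **kw: cis_pro_loop(**kw),
    "bend-gly": lambda **kw: bend_gly(**kw),
    "rama-trap": lambda **kw: rama_trap(**kw),
}


def make_fixture(spec: FixtureSpec) -> Structure:
    """Build the structure a :class:`FixtureSpec` describes."""
    if spec.kind not in _FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {spec.kind!r}; "
                         f"one of {sorted(_FIXTURE_KINDS)}")
    s = _FIXTURE_KINDS[spec.kind](**spec.param_dict())
    if spec.sigma > 0.0:
        s = apply_jitter(s, spec.sigma, spec.seed,
                         jitter_backbone=spec.jitter_backbone)
    return s


def evaluate_cohort(table: pd.DataFrame, config=None) -> list:
    """Run the full pipeline on every cohort row, returning one alert report
    per row.

    Rows produced by :func:`make_cohort` with the same (assigned feature,
    planted outcome) share a fixture and a substitution, so each distinct
    recipe is modelled and evaluated once and the report reused — the
    pipeline itself stays deterministic, making the reuse exact."""
    from .config import DEFAULT_CONFIG
    from .structure_io import VariantSpec
    from .mutant_builder import build_models
    from .feature_engine import evaluate

    config = config if config is not None else DEFAULT_CONFIG
    cache: dict[tuple, object] = {}
    reports = []
    for _, row in table.iterrows():
        key = (row["assigned_feature"], bool(row["planted_fire"]))
        if key not in cache:
            builder, (chain, pos, wt, mut) = cohort_recipe(*key)
            s = builder()
            v = VariantSpec(chain, int(pos), wt, mut)
            models = build_models(s, v, config=config)
            cache[key] = evaluate(models, v, config=config)
        reports.append(cache[key])
    return reports
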