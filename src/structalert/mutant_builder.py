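"""Local side-chain repacking: build WT, MUTANT and WT-CONTROL models.

The modelling protocol mirrors the classic "strip and repack" scheme: the side
chain of the target residue and of every residue with any heavy atom within
5 Å of it are removed; the mutant side chain is grafted from ideal geometry;
and the whole zone is repacked.  The backbone (N, CA, C, O) is never moved —
all three models share it bitwise with the input.

The placement engine is a deterministic clash-minimising chi-angle search:
ideal residue geometry (heavy atoms) is superimposed onto the local backbone,
then the chi angles are searched on a 15° grid (joint over chi1/chi2,
sequential for chi3/chi4) followed by a 5° local refinement, minimising the
summed van-der-Waals overlap beyond 0.4 Å against all surrounding atoms.
Ties are broken deterministically towards extended (trans) chi angles.

* MUTANT: target residue replaced by the mutant type, free repack of the zone.
* WT: wild-type retained; each zone side chain is rebuilt at its native chi
  angles with only a ±5° local refinement ("minor adjustment").
* WT-CONTROL: wild-type retained, but the zone is repacked freely exactly as
  in MUTANT — a control that flags interaction features unstable under
  repacking alone.
"""

from __future__ import annotations

import dataclasses
import math
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .config import DEFAULT_CONFIG, RunConfig
from .structure_io import (AA1_TO_3, Atom, Residue, Structure, VariantSpec,
                           ResidueMapping, resolve_variant, BACKBONE_ATOMS)
from .geometry import dihedral, neighbors_within, vdw_radius
from .interactions import interaction_set_for

__all__ = ["RepackZone", "ModelTriple", "build_models", "control_excluded_features",
           "graft_sidechain", "sidechain_template", "CHI_ATOMS"]

# Standard chi-angle definitions (heavy-atom quadruples), chi1..chi4.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ALA": [],
    "GLY": [],
    "PRO": [],  # rigid ring, grafted as a unit
    "SER": [("N", "CA", "CB", "OG")],
    "CYS": [("N", "CA", "CB", "SG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
}

OVERLAP_SLACK = 0.4       # Å of vdW overlap tolerated before penalty
STERIC_FAIL_CEILING = 10.0  # summed overlap (Å) above which placement is flagged
SS_BOND_RANGE = (1.8, 2.5)  # plausible S-S bond length window, Å
SS_BOND_REWARD = 2.0        # objective credit for re-forming a disulfide
NO_CONTACT_MIN = 2.4        # N···O pairs at or beyond this are treated as
                            # potential hydrogen bonds, not clashes
SS_CB_MIN = 2.6             # SG···CB contacts of a disulfide at or beyond this
                            # are part of the bond geometry, not clashes


@dataclasses.dataclass
class RepackZone:
    target: tuple                 # res_id
    neighbors: list[tuple]        # res_ids of the stripped/repacked shell

    @property
    def members(self) -> list[tuple]:
        return [self.target] + self.neighbors


@dataclasses.dataclass
class PlacementDiagnostics:
    chis: dict[tuple, tuple[float, ...]]     # res_id -> chosen chi angles
    residual: dict[tuple, float]             # res_id -> residual overlap score
    steric_failure: bool = False


@dataclasses.dataclass
class ModelTriple:
    wt: Structure
    mutant: Structure
    wt_control: Structure
    zone: RepackZone
    diagnostics: dict[str, PlacementDiagnostics]


# ---------------------------------------------------------------------------
# ideal residue templates
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def sidechain_template(resname: str) -> tuple[tuple[str, ...], np.ndarray, tuple[str, ...]]:
    """Ideal heavy-atom geometry of a residue type.

    Returns (atom names, coordinates, elements); backbone atoms first
    (N, CA, C, O), then side-chain atoms in template order.  Geometry comes
    from the chemical-component dictionary bundled with biotite.
    """
    import biotite.structure.info as info

    arr = info.residue(resname)
    if arr is None:
        raise KeyError(f"no ideal template for residue {resname!r}")
    keep = (arr.element != "H") & (arr.atom_name != "OXT")
    arr = arr[keep]
    names = list(arr.atom_name)
    coords = np.asarray(arr.coord, dtype=float)
    elements = list(arr.element)
    order = [names.index(n) for n in BACKBONE_ATOMS if n in names]
    order += [i for i, n in enumerate(names) if n not in BACKBONE_ATOMS]
    names = tuple(names[i] for i in order)
    elements = tuple(str(elements[i]).capitalize() for i in order)
    coords = coords[order]
    coords.setflags(write=False)
    return names, coords, elements


@lru_cache(maxsize=32)
def _template_bonds(resname: str) -> dict[str, set[str]]:
    """Covalent bond graph of the template (distance < 1.9 Å, S pairs < 2.2)."""
    names, coords, elements = sidechain_template(resname)
    adj: dict[str, set[str]] = {n: set() for n in names}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            limit = 2.2 if "S" in (elements[i].upper(), elements[j].upper()) else 1.9
            if d < limit:
                adj[names[i]].add(names[j])
                adj[names[j]].add(names[i])
    return adj


@lru_cache(maxsize=256)
def _moving_atoms(resname: str, chi_index: int) -> tuple[str, ...]:
    """Atoms distal to the rotated bond of chi ``chi_index`` (0-based)."""
    a, b, c, d = CHI_ATOMS[resname][chi_index]
    adj = _template_bonds(resname)
    # everything reachable from c without crossing the b-c bond, minus c itself
    seen = {b}
    stack = [c]
    while stack:
        cur = stack.pop()
        if cur in seen:
            continue
        seen.add(cur)
        stack.extend(adj.get(cur, ()))
    return tuple(sorted(seen - {b, c}))


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotation R and centroids so that (mobile - cm) @ R.T + ct ≈ target."""
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    return r, cm, ct


def _rotate_about_axis(coords: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                       angle_deg: float) -> np.ndarray:
    axis = p2 - p1
    axis = axis / np.linalg.norm(axis)
    ang = math.radians(angle_deg)
    c, s = math.cos(ang), math.sin(ang)
    rel = coords - p1
    return (rel * c
            + np.cross(axis, rel) * s
            + np.outer(rel @ axis, axis) * (1.0 - c)) + p1


def graft_sidechain(residue_backbone: dict[str, np.ndarray], resname: str
                    ) -> tuple[list[str], np.ndarray, list[str]]:
    """Ideal side chain (names, coords, elements) superimposed onto a backbone.

    Superposition is on (N, CA, C); only atoms outside the backbone set are
    returned (for GLY this is empty)."""
    names, tcoords, elements = sidechain_template(resname)
    anchor = ["N", "CA", "C"]
    t_idx = [names.index(n) for n in anchor]
    mobile = tcoords[t_idx]
    target = np.array([residue_backbone[n] for n in anchor])
    r, cm, ct = _kabsch(mobile, target)
    placed = (tcoords - cm) @ r.T + ct
    sc = [(n, placed[i], elements[i]) for i, n in enumerate(names)
          if n not in BACKBONE_ATOMS]
    if not sc:
        return [], np.zeros((0, 3)), []
    sc_names, sc_coords, sc_el = zip(*sc)
    return list(sc_names), np.array(sc_coords), list(sc_el)


# ---------------------------------------------------------------------------
# clash objective
# ---------------------------------------------------------------------------

class _Context:
    """KD-tree over fixed surrounding atoms for fast overlap scoring.

    Cys SG-SG pairs are exempt from the overlap penalty: a disulfide bond is
    a covalent contact at ~2.05 A and must not be scored as a clash."""

    def __init__(self, coords: np.ndarray, radii: np.ndarray,
                 is_sg: Optional[np.ndarray] = None,
                 elements: Optional[np.ndarray] = None,
                 is_cys_cb: Optional[np.ndarray] = None):
        self.coords = coords
        self.radii = radii
        self.is_sg = is_sg if is_sg is not None else np.zeros(len(coords), bool)
        self.is_cys_cb = is_cys_cb if is_cys_cb is not None \
            else np.zeros(len(coords), bool)
        els = elements if elements is not None else np.array([""] * len(coords))
        self.is_n = els == "N"
        self.is_o = els == "O"
        self.tree = cKDTree(coords) if len(coords) else None
        self.rmax = float(radii.max()) if len(radii) else 0.0

    def overlap_score(self, coords: np.ndarray, radii: np.ndarray,
                      is_sg: Optional[np.ndarray] = None,
                      elements: Optional[np.ndarray] = None,
                      is_cys_cb: Optional[np.ndarray] = None) -> float:
        if self.tree is None or len(coords) == 0:
            return 0.0
        total = 0.0
        for i in range(len(coords)):
            reach = radii[i] + self.rmax - OVERLAP_SLACK
            idx = self.tree.query_ball_point(coords[i], reach)
            if not idx:
                continue
            idx = np.asarray(idx)
            if is_sg is not None and is_sg[i]:
                sg_idx = idx[self.is_sg[idx]]
                if len(sg_idx):
                    d_sg = np.linalg.norm(self.coords[sg_idx] - coords[i], axis=1)
                    n_bonds = int(((d_sg >= SS_BOND_RANGE[0])
                                   & (d_sg <= SS_BOND_RANGE[1])).sum())
                    total -= SS_BOND_REWARD * n_bonds
                idx = idx[~self.is_sg[idx]]
                if len(idx) == 0:
                    continue
            d = np.linalg.norm(self.coords[idx] - coords[i], axis=1)
            over = (radii[i] + self.radii[idx]) - d - OVERLAP_SLACK
            if is_sg is not None and is_sg[i]:
                over[self.is_cys_cb[idx] & (d >= SS_CB_MIN)] = 0.0
            if is_cys_cb is not None and is_cys_cb[i]:
                over[self.is_sg[idx] & (d >= SS_CB_MIN)] = 0.0
            if elements is not None:
                # N···O contacts at plausible H-bond distance are not clashes
                if elements[i] == "N":
                    over[self.is_o[idx] & (d >= NO_CONTACT_MIN)] = 0.0
                elif elements[i] == "O":
                    over[self.is_n[idx] & (d >= NO_CONTACT_MIN)] = 0.0
            total += float(np.clip(over, 0.0, None).sum())
        return total


def _circ_dist(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def _chi_preference(chis: tuple[float, ...],
                    ref: Optional[tuple[float, ...]] = None) -> float:
    # deterministic tie-break: towards the reference chis (native pose) when
    # given, otherwise towards extended (trans) side chains
    if ref is None:
        ref = (180.0,) * len(chis)
    return sum(_circ_dist(c, r) for c, r in zip(chis, ref))


def _measure_chis(res: Residue) -> list[Optional[float]]:
    out = []
    for quad in CHI_ATOMS.get(res.resname, []):
        atoms = [res.atom(n) for n in quad]
        if any(a is None for a in atoms):
            out.append(None)
        else:
            out.append(dihedral(*[a.coord for a in atoms]))
    return out


class _SidechainModel:
    """A grafted side chain whose chi angles can be set efficiently."""

    def __init__(self, res: Residue, resname: str):
        bb = {n: res.atom(n).coord for n in ("N", "CA", "C") if res.atom(n) is not None}
        if len(bb) < 3:
            raise ValueError(f"{res.label()}: incomplete backbone, cannot graft")
        self.resname = resname
        self.names, self.base_coords, self.elements = graft_sidechain(
            {**bb}, resname)
        self.radii = np.array([vdw_radius(e) for e in self.elements]) \
            if self.names else np.zeros(0)
        self.is_sg = np.array([resname == "CYS" and n == "SG" for n in self.names],
                              dtype=bool)
        self.is_cys_cb = np.array([resname == "CYS" and n == "CB"
                                   for n in self.names], dtype=bool)
        self.element_arr = np.array([e.upper() for e in self.elements])
        self.backbone = {n: res.atom(n).coord for n in BACKBONE_ATOMS
                         if res.atom(n) is not None}
        self.chi_quads = CHI_ATOMS.get(resname, [])
        self.name_idx = {n: i for i, n in enumerate(self.names)}

    def _atom_pos(self, coords: np.ndarray, name: str) -> np.ndarray:
        if name in self.name_idx:
            return coords[self.name_idx[name]]
        return self.backbone[name]

    def with_chis(self, chis: tuple[float, ...]) -> np.ndarray:
        coords = self.base_coords.copy()
        for k, chi in enumerate(chis):
            a, b, c, d = self.chi_quads[k]
            current = dihedral(self._atom_pos(coords, a), self._atom_pos(coords, b),
                               self._atom_pos(coords, c), self._atom_pos(coords, d))
            delta = chi - current
            moving = [self.name_idx[n] for n in _moving_atoms(self.resname, k)
                      if n in self.name_idx]
            if not moving:
                continue
            coords[moving] = _rotate_about_axis(
                coords[moving], self._atom_pos(coords, b),
                self._atom_pos(coords, c), delta)
        return coords


def _search_placement(model: _SidechainModel, ctx: _Context,
                      coarse_step: float, refine_step: float,
                      native_chis: Optional[list[Optional[float]]] = None
                      ) -> tuple[tuple[float, ...], np.ndarray, float]:
    """Pick chi angles minimising the overlap objective.

    Free mode (native_chis None): joint 15°-grid search over chi1/chi2,
    sequential over chi3/chi4, then a ±refine_step sweep per chi.
    Native mode: start at the native chis and refine within ±refine_step only.
    """
    n_chi = len(model.chi_quads)
    if n_chi == 0:
        return (), model.base_coords, ctx.overlap_score(
            model.base_coords, model.radii, model.is_sg, model.element_arr,
            model.is_cys_cb)

    def score_of(chis: tuple[float, ...]) -> float:
        return ctx.overlap_score(model.with_chis(chis), model.radii,
                                 model.is_sg, model.element_arr, model.is_cys_cb)

    ref_chis: Optional[tuple[float, ...]] = None
    if native_chis is not None:
        ref_chis = tuple(180.0 if c is None else c for c in native_chis[:n_chi])
        ref_chis += (180.0,) * (n_chi - len(ref_chis))

    def better(cand: tuple[float, tuple[float, ...]],
               best: tuple[float, tuple[float, ...]]) -> bool:
        if cand[0] < best[0] - 1e-9:
            return True
        if cand[0] > best[0] + 1e-9:
            return False
        return _chi_preference(cand[1], ref_chis) < \
            _chi_preference(best[1], ref_chis) - 1e-9

    if native_chis is not None:
        current = ref_chis
    else:
        grid = [float(a) for a in np.arange(-180.0, 180.0, coarse_step)]
        n_joint = min(2, n_chi)
        best = None
        from itertools import product
        for combo in product(grid, repeat=n_joint):
            chis = tuple(combo) + (180.0,) * (n_chi - n_joint)
            cand = (score_of(chis), chis)
            if best is None or better(cand, best):
                best = cand
        current = best[1]
        # sequential search for chi3, chi4
        for k in range(n_joint, n_chi):
            best_k = None
            for val in grid:
                chis = current[:k] + (val,) + current[k + 1:]
                cand = (score_of(chis), chis)
                if best_k is None or better(cand, best_k):
                    best_k = cand
            current = best_k[1]

    # local refinement, one sweep per chi
    offsets = [-2.0 * refine_step, -refine_step, 0.0, refine_step, 2.0 * refine_step]
    for k in range(n_chi):
        best_k = (score_of(current), current)
        for off in offsets:
            if off == 0.0:
                continue
            chis = current[:k] + (current[k] + off,) + current[k + 1:]
            cand = (score_of(chis), chis)
            if better(cand, best_k):
                best_k = cand
        current = best_k[1]

    coords = model.with_chis(current)
    return current, coords, ctx.overlap_score(coords, model.radii, model.is_sg,
                                              model.element_arr, model.is_cys_cb)


# ---------------------------------------------------------------------------
# model building
# ---------------------------------------------------------------------------

def _strip_sidechain(res: Residue) -> None:
    res.atoms = [a for a in res.atoms if a.name in BACKBONE_ATOMS]


def _set_sidechain(res: Residue, names: list[str], coords: np.ndarray,
                   elements: list[str]) -> None:
    _strip_sidechain(res)
    for n, xyz, el in zip(names, coords, elements):
        res.atoms.append(Atom(n, el, np.array(xyz, dtype=float)))


def _repack(structure: Structure, zone_ids: list[tuple],
            native: dict[tuple, list[Optional[float]]],
            mode: str, config: RunConfig) -> PlacementDiagnostics:
    """Repack the zone in place.  mode: "free" or "native"."""
    by_id = {res.res_id: res for res in structure.residues()}
    zone = [by_id[rid] for rid in zone_ids if rid in by_id]
    zone = [r for r in zone if r.has_backbone()]
    # largest side chains first
    zone.sort(key=lambda r: (-len(sidechain_template(r.resname)[0]), r.res_id))
    zone_set = {id(r) for r in zone}

    # fixed context: every heavy atom not in a repacked side chain; a residue's
    # own backbone is excluded from its own placement score (1-2/1-3 contacts)
    fixed_coords, fixed_radii, fixed_owner = [], [], []
    fixed_sg, fixed_el, fixed_cb = [], [], []
    for res, atom in structure.atoms():
        if atom.element.upper() in ("H", "D"):
            continue
        if id(res) in zone_set and atom.name not in BACKBONE_ATOMS:
            continue
        fixed_coords.append(atom.coord)
        fixed_radii.append(vdw_radius(atom.element))
        fixed_owner.append(res.res_id)
        fixed_sg.append(res.resname == "CYS" and atom.name == "SG")
        fixed_cb.append(res.resname == "CYS" and atom.name == "CB")
        fixed_el.append(atom.element.upper())

    placed: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    diags = PlacementDiagnostics(chis={}, residual={})

    def context_for(skip: tuple) -> _Context:
        keep = [k for k, rid in enumerate(fixed_owner) if rid != skip]
        coords = [fixed_coords[k] for k in keep]
        radii = [fixed_radii[k] for k in keep]
        sg = [fixed_sg[k] for k in keep]
        els = [fixed_el[k] for k in keep]
        cb = [fixed_cb[k] for k in keep]
        for rid, (c, r, m, e, b) in placed.items():
            if rid == skip:
                continue
            coords.extend(c)
            radii.extend(r)
            sg.extend(m)
            els.extend(e)
            cb.extend(b)
        if coords:
            return _Context(np.array(coords), np.array(radii), np.array(sg, bool),
                            np.array(els), np.array(cb, bool))
        return _Context(np.zeros((0, 3)), np.zeros(0))

    def place(res: Residue) -> None:
        model = _SidechainModel(res, res.resname)
        ctx = context_for(res.res_id)
        nat = native.get(res.res_id) if mode == "native" else None
        chis, coords, score = _search_placement(
            model, ctx, config.chi_grid_step, config.chi_refine_step, nat)
        placed[res.res_id] = (coords, model.radii, model.is_sg,
                              model.element_arr, model.is_cys_cb)
        _set_sidechain(res, model.names, coords, model.elements)
        diags.chis[res.res_id] = chis
        diags.residual[res.res_id] = score

    for res in zone:          # greedy pass
        if res.resname == "GLY":
            _strip_sidechain(res)
            diags.chis[res.res_id] = ()
            diags.residual[res.res_id] = 0.0
            continue
        place(res)
    for res in zone:          # one re-refinement sweep against the full context
        if res.resname == "GLY":
            continue
        place(res)

    if diags.residual and max(diags.residual.values()) > STERIC_FAIL_CEILING:
        diags.steric_failure = True
    return diags


def build_models(s: Structure, v: VariantSpec,
                 mapping: Optional[ResidueMapping] = None,
                 config: RunConfig = DEFAULT_CONFIG) -> ModelTriple:
    """Build the WT / MUTANT / WT-CONTROL triple for one variant.

    The three models share the input backbone bitwise; residues outside the
    5 Å repack zone are untouched.  Unresolvable steric strain is reported in
    the diagnostics (``steric_failure``), never raised.
    """
    target = resolve_variant(v, s, mapping)
    if not target.has_backbone():
        raise ValueError(f"target {target.label()} lacks a complete backbone")
    shell = neighbors_within(s, target, config.repack_shell, metric="any")
    shell = [r for r in shell if r.has_backbone() and not r.het]
    zone = RepackZone(target.res_id, [r.res_id for r in shell])

    native = {rid: None for rid in zone.members}
    by_id = {res.res_id: res for res in s.residues()}
    for rid in zone.members:
        native[rid] = _measure_chis(by_id[rid])

    mut_name = AA1_TO_3[v.mut]

    wt = s.copy()
    diag_wt = _repack(wt, zone.members, native, "native", config)

    mutant = s.copy()
    mut_target = mutant.get_residue(*target.res_id)
    mut_target.resname = mut_name
    _strip_sidechain(mut_target)
    # native chis keyed for the mutant residue are meaningless; free repack
    diag_mut = _repack(mutant, zone.members, {}, "free", config)

    control = s.copy()
    diag_ctrl = _repack(control, zone.members, {}, "free", config)

    return ModelTriple(wt, mutant, control, zone,
                       {"wt": diag_wt, "mutant": diag_mut, "wt_control": diag_ctrl})


def control_excluded_features(wt: Structure, ctrl: Structure, res_id: tuple,
                              config: RunConfig = DEFAULT_CONFIG) -> set[str]:
    """Distance features whose interactions differ between WT and WT-CONTROL.

    Any feature in the returned subset of {"disulfide", "hbond", "saltbridge"}
    is unstable under repacking alone and must be excluded from the WT-vs-
    MUTANT comparison."""
    out: set[str] = set()
    wt_res = wt.get_residue(*res_id)
    ctrl_res = ctrl.get_residue(*res_id)
    if wt_res is None or ctrl_res is None:
        raise KeyError(f"residue {res_id} missing from WT or WT-CONTROL")
    a = interaction_set_for(wt, wt_res, config.disulfide_cutoff,
                            config.hbond_cutoff, config.saltbridge_cutoff)
    b = interaction_set_for(ctrl, ctrl_res, config.disulfide_cutoff,
                            config.hbond_cutoff, config.saltbridge_cutoff)

    def ds_key(x):
        return frozenset((x.res_a, x.res_b))

    def hb_key(x):
        return (x.donor_res, x.donor_atom, x.acceptor_res, x.acceptor_atom)

    def sb_key(x):
        return (x.pos_res, x.pos_atom, x.neg_res, x.neg_atom)

    if {ds_key(x) for x in a.disulfides} != {ds_key(x) for x in b.disulfides}:
        out.add("disulfide")
    if {hb_key(x) for x in a.hbonds} != {hb_key(x) for x in b.hbonds}:
        out.add("hbond")
    if {sb_key(x) for x in a.saltbridges} != {sb_key(x) for x in b.saltbridges}:
        out.add("saltbridge")
    return out
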