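"""Geometric substrates: solvent accessibility, burial, torsions, Ramachandran
classification and neighbour search.

Solvent-accessible surface area uses the Shrake–Rupley sphere-point method with
a fixed, deterministic golden-section spiral point set (960 points by default)
on heavy atoms; hydrogens, if present, are ignored.  Relative solvent
accessibility (RSA) divides per-residue SASA by a bundled theoretical max-ASA
reference; a residue is *buried* when its RSA is below 9%.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
from functools import lru_cache
from typing import Iterable, Optional

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Atom, Residue, Structure

__all__ = [
    "SasaProfile",
    "TorsionRecord",
    "RamaClass",
    "vdw_radius",
    "max_asa",
    "sphere_points",
    "shrake_rupley_sasa",
    "relative_accessibility",
    "is_buried",
    "dihedral",
    "backbone_torsions",
    "residue_rama_class",
    "rama_classify",
    "neighbors_within",
]

RSA_BURIED_THRESHOLD = 9.0  # percent; buried iff RSA < 9


# ---------------------------------------------------------------------------
# bundled tables
# ---------------------------------------------------------------------------

def _load_table(name: str) -> list[list[str]]:
    text = importlib.resources.files("structalert.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


@lru_cache(maxsize=1)
def _vdw_table() -> dict[str, float]:
    return {el.capitalize(): float(r) for el, r in _load_table("vdw_radii.tsv")}


@lru_cache(maxsize=1)
def _max_asa_table() -> dict[str, float]:
    return {res: float(a) for res, a in _load_table("max_asa.tsv")}


def vdw_radius(element: str) -> float:
    table = _vdw_table()
    el = element.capitalize()
    if el not in table:
        raise KeyError(f"no van der Waals radius for element {element!r}")
    return table[el]


def max_asa(resname: str) -> float:
    table = _max_asa_table()
    if resname not in table:
        raise KeyError(f"no max-ASA reference for residue type {resname!r}")
    return table[resname]


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SasaProfile:
    """Per-atom and per-residue solvent accessibility of one structure."""

    atom_sasa: dict[tuple, float]                      # (res_id, atom_name) -> Å^2
    residue_sasa: dict[tuple, float]                   # res_id -> Å^2
    rsa: dict[tuple, float] = dataclasses.field(default_factory=dict)  # res_id -> %


@lru_cache(maxsize=8)
def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    pts = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
    pts.setflags(write=False)
    return pts


def _heavy_atoms(s: Structure) -> tuple[list[Residue], list[Atom], np.ndarray, np.ndarray]:
    residues, atoms = [], []
    for res, atom in s.atoms(standard_only=True):
        if atom.element.upper() in ("H", "D"):
            continue
        residues.append(res)
        atoms.append(atom)
    if not atoms:
        raise ValueError("structure has no heavy atoms with known element")
    coords = np.array([a.coord for a in atoms])
    radii = np.array([vdw_radius(a.element) for a in atoms])
    return residues, atoms, coords, radii


def shrake_rupley_sasa(s: Structure, probe: float = 1.4, points: int = 960) -> SasaProfile:
    """Shrake–Rupley SASA on heavy atoms with a fixed spiral point set."""
    residues, atoms, coords, radii = _heavy_atoms(s)
    unit = sphere_points(points)
    ext = radii + probe
    tree = cKDTree(coords)
    max_ext = float(ext.max())

    atom_sasa: dict[tuple, float] = {}
    residue_sasa: dict[tuple, float] = {}
    for i in range(len(atoms)):
        ri = ext[i]
        neigh = [j for j in tree.query_ball_point(coords[i], ri + max_ext) if j != i]
        pts = coords[i] + ri * unit
        if neigh:
            nc = coords[neigh]
            nr = ext[neigh]
            d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            r2 = (nr ** 2)[None, :]
            buried = (d2 < r2 - 1e-9).any(axis=1)
            # a point exactly on a neighbour's sphere (degenerate co-located
            # atoms): credit the surface to the lower-index atom only
            on_edge = np.abs(d2 - r2) <= 1e-9
            if on_edge.any():
                lower = np.array(neigh) < i
                buried |= (on_edge & lower[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        area = 4.0 * math.pi * ri * ri * frac
        key = (residues[i].res_id, atoms[i].name)
        atom_sasa[key] = area
        residue_sasa[residues[i].res_id] = residue_sasa.get(residues[i].res_id, 0.0) + area
    return SasaProfile(atom_sasa, residue_sasa)


def relative_accessibility(profile: SasaProfile, structure: Structure,
                           scale: Optional[dict[str, float]] = None) -> dict[tuple, float]:
    """RSA (%) = 100 × residue SASA / max-ASA(residue type), capped at 100."""
    scale = scale if scale is not None else _max_asa_table()
    rsa: dict[tuple, float] = {}
    by_id = {res.res_id: res for res in structure.residues()}
    for rid, area in profile.residue_sasa.items():
        res = by_id.get(rid)
        if res is None:
            continue
        resname = res.resname if res.resname in scale else None
        if resname is None:
            from .structure_io import MODIFIED_PARENT
            resname = MODIFIED_PARENT.get(res.resname)
        if resname is None or resname not in scale:
            raise KeyError(f"no max-ASA entry for {res.label()}")
        rsa[rid] = min(100.0, 100.0 * area / scale[resname])
    profile.rsa = rsa
    return rsa


def sasa_profile(s: Structure, probe: float = 1.4, points: int = 960) -> SasaProfile:
    """Convenience: SASA + RSA in one call."""
    prof = shrake_rupley_sasa(s, probe=probe, points=points)
    relative_accessibility(prof, s)
    return prof


def is_buried(rsa: float, threshold: float = RSA_BURIED_THRESHOLD) -> bool:
    """Buried iff RSA strictly below the threshold (default 9%)."""
    if not 0.0 <= rsa <= 100.0:
        raise ValueError(f"RSA must be in [0, 100], got {rsa}")
    return rsa < threshold


# ---------------------------------------------------------------------------
# torsions
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TorsionRecord:
    """Backbone phi/psi/omega per residue; None where neighbouring backbone
    atoms are missing (chain termini or chain breaks)."""

    phi: dict[tuple, Optional[float]]
    psi: dict[tuple, Optional[float]]
    omega: dict[tuple, Optional[float]]


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle (degrees, in (−180, 180]) of four points."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = -math.degrees(math.atan2(y, x))  # IUPAC sign convention
    return 180.0 if ang <= -180.0 + 1e-12 else ang


PEPTIDE_BOND_MAX = 2.5  # Å; C(i)–N(i+1) beyond this is a chain break


def _connected(prev: Residue, curr: Residue) -> bool:
    c = prev.atom("C")
    n = curr.atom("N")
    if c is None or n is None:
        return False
    return float(np.linalg.norm(c.coord - n.coord)) < PEPTIDE_BOND_MAX


def backbone_torsions(s: Structure) -> TorsionRecord:
    phi: dict[tuple, Optional[float]] = {}
    psi: dict[tuple, Optional[float]] = {}
    omega: dict[tuple, Optional[float]] = {}
    for cid in s.chain_ids():
        chain = [r for r in s.chains[cid] if not r.het and r.one_letter is not None]
        for k, res in enumerate(chain):
            phi[res.res_id] = psi[res.res_id] = omega[res.res_id] = None
            n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
            if n is None or ca is None or c is None:
                continue
            prev = chain[k - 1] if k > 0 and _connected(chain[k - 1], res) else None
            nxt = chain[k + 1] if k + 1 < len(chain) and _connected(res, chain[k + 1]) else None
            if prev is not None and prev.atom("C") is not None:
                phi[res.res_id] = dihedral(prev.atom("C").coord, n.coord, ca.coord, c.coord)
                if prev.atom("CA") is not None:
                    omega[res.res_id] = dihedral(prev.atom("CA").coord, prev.atom("C").coord,
                                                 n.coord, ca.coord)
            if nxt is not None and nxt.atom("N") is not None:
                psi[res.res_id] = dihedral(n.coord, ca.coord, c.coord, nxt.atom("N").coord)
    return TorsionRecord(phi, psi, omega)


# ---------------------------------------------------------------------------
# Ramachandran classification
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class RamaClass:
    category: str       # favored | allowed | outlier
    residue_class: str  # general | glycine | proline | preproline

    @property
    def is_outlier(self) -> bool:
        return self.category == "outlier"


@lru_cache(maxsize=1)
def _rama_polygons() -> dict[str, dict[str, list[np.ndarray]]]:
    regions: dict[str, dict[str, list[np.ndarray]]] = {}
    for cls, level, verts in _load_table("rama_regions.tsv"):
        poly = np.array([[float(x) for x in v.split(",")] for v in verts.split(";")])
        regions.setdefault(cls, {"favored": [], "allowed": []})[level].append(poly)
    return regions


def point_in_polygon(point: tuple[float, float], poly: np.ndarray) -> bool:
    """Ray-casting point-in-polygon; boundary points count as inside."""
    x, y = point
    n = len(poly)
    inside = False
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        # on-edge check (axis-aligned and general)
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-9 and min(x1, x2) - 1e-9 <= x <= max(x1, x2) + 1e-9 \
                and min(y1, y2) - 1e-9 <= y <= max(y1, y2) + 1e-9:
            return True
        if (y1 > y) != (y2 > y):
            xin = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xin:
                inside = not inside
    return inside


def residue_rama_class(resname1: str, next_resname1: Optional[str] = None) -> str:
    """Which Ramachandran table applies to a residue of this type."""
    if resname1 == "G":
        return "glycine"
    if resname1 == "P":
        return "proline"
    if next_resname1 == "P":
        return "preproline"
    return "general"


def rama_classify(phi: float, psi: float, residue_class: str = "general") -> RamaClass:
    """Classify a defined (phi, psi) pair as favored / allowed / outlier."""
    if residue_class not in _rama_polygons():
        raise KeyError(f"unknown Ramachandran residue class {residue_class!r}")
    regions = _rama_polygons()[residue_class]
    pt = (phi, psi)
    for poly in regions["favored"]:
        if point_in_polygon(pt, poly):
            return RamaClass("favored", residue_class)
    for poly in regions["allowed"] + regions["favored"]:
        if point_in_polygon(pt, poly):
            return RamaClass("allowed", residue_class)
    return RamaClass("outlier", residue_class)


# ---------------------------------------------------------------------------
# neighbour search
# ---------------------------------------------------------------------------

def neighbors_within(s: Structure, center: Residue, radius: float,
                     metric: str = "any") -> list[Residue]:
    """Residues within ``radius`` of ``center`` (excluding it).

    metric "any": minimal inter-residue heavy-atom distance; metric "CA":
    CA–CA distance.
    """
    out: list[Residue] = []
    if metric == "CA":
        ca0 = center.atom("CA")
        if ca0 is None:
            return out
        for res in s.residues():
            if res is center:
                continue
            ca = res.atom("CA")
            if ca is not None and np.linalg.norm(ca.coord - ca0.coord) <= radius:
                out.append(res)
        return out
    if metric != "any":
        raise ValueError(f"unknown metric {metric!r}")
    center_coords = np.array([a.coord for a in center.atoms
                              if a.element.upper() not in ("H", "D")])
    if center_coords.size == 0:
        return out
    tree = cKDTree(center_coords)
    for res in s.residues():
        if res is center:
            continue
        coords = np.array([a.coord for a in res.atoms
                           if a.element.upper() not in ("H", "D")])
        if coords.size == 0:
            continue
        d, _ = tree.query(coords, k=1)
        if float(np.min(d)) <= radius:
            out.append(res)
    return out
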