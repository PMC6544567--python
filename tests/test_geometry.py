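"""Solvent accessibility, torsions, Ramachandran classes, neighbour search."""

import math

import numpy as np
import pytest

from structalert.structure_io import Atom, Residue, Structure
from structalert.geometry import (backbone_torsions, dihedral, is_buried,
                                  max_asa, neighbors_within, rama_classify,
                                  relative_accessibility, residue_rama_class,
                                  sasa_profile, shrake_rupley_sasa, vdw_radius,
                                  _rama_polygons)
import structalert.synthetic_fixtures as sf


def _atom_structure(coords, elements):
    s = Structure(provenance="synthetic")
    chain = []
    for k, (xyz, el) in enumerate(zip(coords, elements)):
        res = Residue("GLY", k + 1, "", "A")
        res.atoms.append(Atom("CA", el, np.asarray(xyz, float)))
        chain.append(res)
    s.chains["A"] = chain
    return s


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def test_single_atom_sasa_closed_form():
    s = _atom_structure([[0, 0, 0]], ["C"])
    prof = shrake_rupley_sasa(s)
    expected = 4 * math.pi * (1.70 + 1.40) ** 2
    assert prof.atom_sasa[(("A", 1, ""), "CA")] == pytest.approx(expected, rel=0.01)


def test_colocated_atoms_total_equals_single_sphere():
    s = _atom_structure([[0, 0, 0], [0, 0, 0]], ["C", "C"])
    prof = shrake_rupley_sasa(s)
    single = 4 * math.pi * (1.70 + 1.40) ** 2
    assert sum(prof.atom_sasa.values()) == pytest.approx(single, rel=0.02)


def _mc_sasa_oracle(coords, radii, probe, n_points, seed):
    """Monte-Carlo surface sampling, independent of the spiral point set."""
    rng = np.random.default_rng(seed)
    areas = []
    ext = radii + probe
    for i, (c, r) in enumerate(zip(coords, ext)):
        pts = rng.normal(size=(n_points, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts = c + r * pts
        free = np.ones(n_points, bool)
        for j, (c2, r2) in enumerate(zip(coords, ext)):
            if j == i:
                continue
            free &= np.linalg.norm(pts - c2, axis=1) >= r2
        areas.append(4 * math.pi * r * r * free.mean())
    return np.array(areas)


def test_cluster_sasa_matches_monte_carlo_oracle():
    rng = np.random.default_rng(3)
    coords = rng.uniform(0, 8, size=(20, 3))
    elements = ["C", "N", "O", "S"] * 5
    s = _atom_structure(coords, elements)
    prof = shrake_rupley_sasa(s, points=960)
    mine = np.array([prof.atom_sasa[(("A", k + 1, ""), "CA")] for k in range(20)])
    radii = np.array([vdw_radius(e) for e in elements])
    oracle = _mc_sasa_oracle(coords, radii, 1.4, 100_000, seed=11)
    total_err = abs(mine.sum() - oracle.sum()) / oracle.sum()
    assert total_err < 0.02
    # per-atom agreement within 2% of the sphere area scale
    scale = 4 * math.pi * (radii + 1.4) ** 2
    assert np.all(np.abs(mine - oracle) / scale < 0.02)


def test_distant_atom_cannot_change_sasa():
    s1 = _atom_structure([[0, 0, 0], [3, 0, 0]], ["C", "C"])
    p1 = shrake_rupley_sasa(s1)
    far = [[0, 0, 0], [3, 0, 0], [50, 0, 0]]
    p2 = shrake_rupley_sasa(_atom_structure(far, ["C", "C", "C"]))
    for key, val in p1.atom_sasa.items():
        assert p2.atom_sasa[key] == pytest.approx(val, abs=1e-9)


# ---------------------------------------------------------------------------
# RSA / burial
# ---------------------------------------------------------------------------

def test_rsa_arithmetic_and_burial_monotonicity():
    helix = sf.ideal_helix("A" * 20)
    prof = sasa_profile(helix)
    # arithmetic: RSA = 100 * sasa / max_asa, capped
    for rid in [("A", 1, ""), ("A", 10, ""), ("A", 20, "")]:
        expected = min(100.0, 100.0 * prof.residue_sasa[rid] / max_asa("ALA"))
        assert prof.rsa[rid] == pytest.approx(expected)
    # a central helix residue is more buried than the same residue extended
    extended = sf.build_peptide("A" * 20, [180] * 20, [180] * 20)
    prof_ext = sasa_profile(extended)
    assert prof.rsa[("A", 10, "")] < prof_ext.rsa[("A", 10, "")]


def test_zero_sasa_gives_zero_rsa():
    prof = sasa_profile(sf.buried_core("A"))
    assert prof.rsa[("A", 3, "")] < 9.0
    assert min(prof.rsa.values()) >= 0.0


@pytest.mark.parametrize("rsa,expected", [(8.99, True), (9.0, False), (0.0, True)])
def test_burial_threshold_is_strict(rsa, expected):
    assert is_buried(rsa) is expected


def test_burial_rejects_out_of_range():
    with pytest.raises(ValueError):
        is_buried(-1.0)


# ---------------------------------------------------------------------------
# torsions
# ---------------------------------------------------------------------------

def test_helix_torsions_recover_construction():
    t = backbone_torsions(sf.ideal_helix("A" * 12))
    phis = [v for v in t.phi.values() if v is not None]
    psis = [v for v in t.psi.values() if v is not None]
    omegas = [v for v in t.omega.values() if v is not None]
    assert np.allclose(phis, -57.0, atol=0.5)
    assert np.allclose(psis, -47.0, atol=0.5)
    assert np.allclose(np.abs(omegas), 180.0, atol=0.5)


def test_termini_are_undefined():
    t = backbone_torsions(sf.ideal_helix("A" * 6))
    assert t.phi[("A", 1, "")] is None
    assert t.psi[("A", 6, "")] is None
    assert t.omega[("A", 1, "")] is None


def test_dihedral_matches_projection_oracle():
    def oracle(p0, p1, p2, p3):
        b0 = p0 - p1
        b1 = p2 - p1
        b2 = p3 - p2
        b1n = b1 / np.linalg.norm(b1)
        v = b0 - np.dot(b0, b1n) * b1n
        w = b2 - np.dot(b2, b1n) * b1n
        x = np.dot(v, w)
        y = np.dot(np.cross(b1n, v), w)
        return math.degrees(math.atan2(y, x))

    rng = np.random.default_rng(5)
    for _ in range(50):
        p = rng.normal(size=(4, 3)) * 4
        assert dihedral(*p) == pytest.approx(oracle(*p), abs=1e-9)


def test_planar_trans_omega_is_180():
    p = [np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 0.0]),
         np.array([1.0, 0.0, 0.0]), np.array([1.0, -1.0, 0.0])]
    assert abs(dihedral(*p)) == pytest.approx(180.0)


# ---------------------------------------------------------------------------
# Ramachandran
# ---------------------------------------------------------------------------

def test_rama_canonical_points():
    assert rama_classify(-57, -47, "general").category == "favored"
    assert rama_classify(-57, -47, "proline").category in ("favored", "allowed")
    assert rama_classify(60, 60, "proline").category == "outlier"
    assert rama_classify(80, -100, "glycine").category != "outlier"
    assert rama_classify(80, -100, "general").category == "outlier"


def test_rama_residue_class_selection():
    assert residue_rama_class("G") == "glycine"
    assert residue_rama_class("P") == "proline"
    assert residue_rama_class("A", "P") == "preproline"
    assert residue_rama_class("A", "L") == "general"


def test_rama_partition_and_matplotlib_oracle():
    """Every grid point gets exactly one class; the point-in-polygon kernel
    agrees with matplotlib's independent implementation."""
    from matplotlib.path import Path

    polys = _rama_polygons()
    for cls in ("general", "glycine", "proline", "preproline"):
        fav = [Path(p) for p in polys[cls]["favored"]]
        alw = [Path(p) for p in polys[cls]["allowed"] + polys[cls]["favored"]]
        counts = {"favored": 0, "allowed": 0, "outlier": 0}
        mismatch = 0
        for phi in range(-179, 180, 7):
            for psi in range(-179, 180, 7):
                mine = rama_classify(phi, psi, cls).category
                counts[mine] += 1
                if any(p.contains_point((phi, psi), radius=1e-9) for p in fav):
                    ref = "favored"
                elif any(p.contains_point((phi, psi), radius=1e-9) for p in alw):
                    ref = "allowed"
                else:
                    ref = "outlier"
                if ref != mine:
                    mismatch += 1
        total = sum(counts.values())
        assert counts["favored"] > 0 and counts["outlier"] > 0
        assert mismatch / total < 0.005  # boundary-only disagreements


# ---------------------------------------------------------------------------
# neighbour search
# ---------------------------------------------------------------------------

def test_neighbors_isolated_and_cutoff():
    lone = _atom_structure([[0, 0, 0]], ["C"])
    assert neighbors_within(lone, lone.chains["A"][0], 5.0) == []
    s = _atom_structure([[0, 0, 0], [0, 0, 4.9], [0, 0, 9.8]], ["C", "C", "C"])
    mid = s.chains["A"][1]
    ids = {r.res_id for r in neighbors_within(s, mid, 5.0)}
    assert ids == {("A", 1, ""), ("A", 3, "")}  # both 4.9 Å away
    first = s.chains["A"][0]
    ids = {r.res_id for r in neighbors_within(s, first, 5.0)}
    assert ids == {("A", 2, "")}  # 9.8 Å residue outside the shell
    # closest-atom distance 5.1 Å misses a 5 Å shell
    s2 = _atom_structure([[0, 0, 0], [0, 0, 5.1]], ["C", "C"])
    assert neighbors_within(s2, s2.chains["A"][0], 5.0) == []


def test_neighbors_match_brute_force_and_symmetry():
    s = sf.buried_core("L")
    residues = list(s.residues())

    def brute(center, radius):
        out = set()
        cpts = np.array([a.coord for a in center.atoms])
        for r in residues:
            if r is center:
                continue
            pts = np.array([a.coord for a in r.atoms])
            d = np.linalg.norm(cpts[:, None, :] - pts[None, :, :], axis=2)
            if d.min() <= radius:
                out.add(r.res_id)
        return out

    for center in residues[:8]:
        mine = {r.res_id for r in neighbors_within(s, center, 5.0)}
        assert mine == brute(center, 5.0)
    # symmetry on a subset
    for a in residues[:6]:
        for b in residues[:6]:
            if a is b:
                continue
            in_a = any(r is b for r in neighbors_within(s, a, 6.0))
            in_b = any(r is a for r in neighbors_within(s, b, 6.0))
            assert in_a == in_b
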