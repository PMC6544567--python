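"""Model triple construction: grafting, repacking, backbone preservation."""

import numpy as np
import pytest

from structalert.structure_io import VariantSpec, BACKBONE_ATOMS
from structalert.mutant_builder import (CHI_ATOMS, OVERLAP_SLACK,
                                        build_models,
                                        control_excluded_features,
                                        sidechain_template)
from structalert.geometry import dihedral, vdw_radius
import structalert.synthetic_fixtures as sf


def _backbone_equal(a, b):
    for res in a.residues():
        other = b.get_residue(*res.res_id)
        for name in BACKBONE_ATOMS:
            aa, bb = res.atom(name), other.atom(name)
            if aa is None and bb is None:
                continue
            if not np.array_equal(aa.coord, bb.coord):
                return False
    return True


def test_mutation_to_glycine_strips_side_chain(helix12):
    v = VariantSpec("A", 6, "A", "G")
    m = build_models(helix12, v)
    tgt = m.mutant.get_residue("A", 6, "")
    assert tgt.resname == "GLY"
    assert sorted(a.name for a in tgt.atoms) == ["C", "CA", "N", "O"]


def test_identity_substitution_self_consistency():
    s = sf.ideal_helix("AALAA")
    v = VariantSpec("A", 3, "L", "L")
    m = build_models(s, v)
    orig = s.get_residue("A", 3, "")
    mut = m.mutant.get_residue("A", 3, "")
    sc = [a.name for a in orig.atoms if a.name not in BACKBONE_ATOMS]
    rmsd = np.sqrt(np.mean([np.sum((mut.atom(n).coord - orig.atom(n).coord) ** 2)
                            for n in sc]))
    assert rmsd < 0.5


def test_backbone_bitwise_identical_and_outside_zone_untouched(buried_leu):
    v = VariantSpec("A", 3, "L", "W")
    m = build_models(buried_leu, v)
    for model in (m.wt, m.mutant, m.wt_control):
        assert _backbone_equal(buried_leu, model)
    zone = set(m.zone.members)
    for res in buried_leu.residues():
        if res.res_id in zone:
            continue
        for model in (m.wt, m.mutant, m.wt_control):
            other = model.get_residue(*res.res_id)
            assert [a.name for a in other.atoms] == [a.name for a in res.atoms]
            for a, b in zip(res.atoms, other.atoms):
                assert np.array_equal(a.coord, b.coord)


def test_zone_is_the_5A_shell(buried_leu):
    from structalert.geometry import neighbors_within
    v = VariantSpec("A", 3, "L", "W")
    m = build_models(buried_leu, v)
    target = buried_leu.get_residue("A", 3, "")
    shell = {r.res_id for r in neighbors_within(buried_leu, target, 5.0)
             if r.has_backbone()}
    assert set(m.zone.neighbors) == shell
    assert m.zone.target == ("A", 3, "")


def test_placement_is_deterministic(buried_leu):
    v = VariantSpec("A", 3, "L", "K")
    m1 = build_models(buried_leu, v)
    m2 = build_models(buried_leu, v)
    for s1, s2 in ((m1.mutant, m2.mutant), (m1.wt_control, m2.wt_control)):
        for (r1, a1), (r2, a2) in zip(s1.atoms(), s2.atoms()):
            assert a1.name == a2.name and np.array_equal(a1.coord, a2.coord)


def test_mutant_atom_set_is_canonical(buried_leu):
    for mut in "WKDS":
        v = VariantSpec("A", 3, "L", mut)
        m = build_models(buried_leu, v)
        tgt = m.mutant.get_residue("A", 3, "")
        names, _, _ = sidechain_template(tgt.resname)
        assert sorted(a.name for a in tgt.atoms) == sorted(names)


def test_chi_choice_matches_exhaustive_grid_oracle():
    """A cysteine in a crowded pocket: the engine's chi1 must match a
    brute-force 15°-grid minimiser of the same overlap objective."""
    from structalert.structure_io import Atom, Residue

    s = sf.ideal_helix("AACAA")
    # place a blocker carbon near the extended SG position to make the
    # objective non-trivial
    cys = s.get_residue("A", 3, "")
    blocker = Residue("GLY", 99, "", "Z")
    blocker.atoms.append(Atom("CA", "C", cys.atom("SG").coord + np.array([0.4, 0.4, 0.0])))
    s.chains["Z"] = [blocker]

    v = VariantSpec("A", 3, "C", "C")
    m = build_models(s, v)
    chosen = m.diagnostics["mutant"].chis[("A", 3, "")]

    # independent oracle: rebuild the side chain at every 15° chi1, score by
    # plain pairwise loops with the same rules (SG-SG exempt, N-O >= 2.4
    # exempt, overlap beyond 0.4 Å)
    from structalert.mutant_builder import _SidechainModel

    model = _SidechainModel(cys, "CYS")
    context = []
    for res in s.residues():
        if res.res_id == ("A", 3, ""):
            continue
        for a in res.atoms:
            mut_res = m.mutant.get_residue(*res.res_id)
            b = mut_res.atom(a.name)
            context.append((b.coord, vdw_radius(b.element), b.element.upper()))

    def score(chi):
        coords = model.with_chis((chi,))
        total = 0.0
        for xyz, rad, el in zip(coords, model.radii, model.elements):
            el = el.upper()
            for cxyz, crad, cel in context:
                d = float(np.linalg.norm(xyz - cxyz))
                if {el, cel} == {"N", "O"} and d >= 2.4:
                    continue
                over = rad + crad - d - OVERLAP_SLACK
                if over > 0:
                    total += over
        return total

    grid = np.arange(-180.0, 180.0, 15.0)
    scores = {chi: score(chi) for chi in grid}
    best = min(scores.values())
    best_chis = [chi for chi, sc in scores.items() if sc < best + 1e-9]
    # the engine refines ±10° around the coarse optimum
    assert any(min(abs(chosen[0] - c), 360 - abs(chosen[0] - c)) <= 10.0
               for c in best_chis)
    assert score(chosen[0]) <= best + 1e-6


def test_steric_failure_is_flagged_not_raised():
    # an impossible pocket: a dense blocker cluster fills the entire
    # side-chain hemisphere, so no tryptophan rotamer can avoid overlap
    from structalert.structure_io import Atom, Residue

    s = sf.ideal_helix("AAAAA")
    ala = s.get_residue("A", 3, "")
    ca, cb = ala.atom("CA").coord, ala.atom("CB").coord
    u = (cb - ca) / np.linalg.norm(cb - ca)
    p1 = np.cross(u, [0.0, 0.0, 1.0])
    p1 /= np.linalg.norm(p1)
    p2 = np.cross(u, p1)
    blockers = []
    k = 0
    for d in (2.6, 3.4, 4.2, 5.0):
        for a in (-1.2, 0.0, 1.2):
            for b in (-1.2, 0.0, 1.2):
                k += 1
                r = Residue("GLY", k, "", "Z")
                r.atoms.append(Atom("CA", "C", ca + d * u + a * p1 + b * p2))
                blockers.append(r)
    s.chains["Z"] = blockers
    m = build_models(s, VariantSpec("A", 3, "A", "W"))  # must not raise
    assert m.diagnostics["mutant"].steric_failure


def test_control_exclusion_empty_when_identical(buried_leu):
    assert control_excluded_features(buried_leu, buried_leu, ("A", 3, "")) == set()


def test_control_exclusion_flags_lost_bridge(salt_bridge_fixture):
    broken = salt_bridge_fixture.copy()
    glu = broken.get_residue("B", 3, "")
    for a in glu.atoms:
        if a.name not in BACKBONE_ATOMS:
            a.coord = a.coord + np.array([0.0, 20.0, 0.0])
    excl = control_excluded_features(salt_bridge_fixture, broken, ("A", 3, ""))
    assert "saltbridge" in excl
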