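"""Shared fixtures: expensive synthetic structures and pipeline runs are
computed once per session (everything is deterministic, so reuse is exact)."""

from __future__ import annotations

import pytest

from structalert.structure_io import VariantSpec
from structalert.mutant_builder import build_models
from structalert.feature_engine import evaluate
import structalert.synthetic_fixtures as sf


@pytest.fixture(scope="session")
def helix12():
    return sf.ideal_helix("A" * 12)


@pytest.fixture(scope="session")
def strand_pair():
    return sf.ideal_strand_pair()


@pytest.fixture(scope="session")
def disulfide_fixture():
    return sf.disulfide_pair(2.05)


@pytest.fixture(scope="session")
def salt_bridge_fixture():
    return sf.salt_bridge_pair((2.6, 3.8))


@pytest.fixture(scope="session")
def buried_leu():
    return sf.buried_core("L")


# ---------------------------------------------------------------------------
# the per-feature truth table: every alert feature with a dedicated fixture
# and substitution, plus the hand-derived expected alert sets (co-firing
# features are listed where the geometry genuinely satisfies several rules)
# ---------------------------------------------------------------------------

TRUTH_TABLE = {
    "disulfide_breakage": (
        lambda: sf.disulfide_pair(2.05), ("A", 3, "C", "R"),
        {"disulfide_breakage"}),
    "buried_pro_introduced": (
        lambda: sf.buried_core("L"), ("A", 3, "L", "P"),
        {"buried_pro_introduced"}),
    "clash": (
        # a tighter cage: the bulky tryptophan cannot avoid steric overlap
        lambda: sf.buried_core("A", shells=((4.8, 26), (8.2, 62))),
        ("A", 3, "A", "W"),
        {"clash", "cavity_altered"}),
    "buried_hydrophilic_introduced": (
        lambda: sf.buried_core("L"), ("A", 3, "L", "N"),
        {"buried_hydrophilic_introduced"}),
    "buried_charge_introduced": (
        # an introduced charge is necessarily hydrophilic: both rules fire
        lambda: sf.buried_core("V"), ("A", 3, "V", "D"),
        {"buried_hydrophilic_introduced", "buried_charge_introduced"}),
    "buried_charge_switch": (
        lambda: sf.buried_core("D"), ("A", 3, "D", "K"),
        {"buried_charge_switch"}),
    "secondary_structure_altered": (
        # proline removes the amide donor of a beta-bridge: the bridge at the
        # substituted position disappears; proline is also a torsion outlier
        # at the extended phi and its ring contacts the partner strand
        lambda: sf.ideal_strand_pair(), ("A", 4, "G", "P"),
        {"secondary_structure_altered", "disallowed_phi_psi", "clash"}),
    "buried_charge_replaced": (
        lambda: sf.buried_core("D"), ("A", 3, "D", "S"),
        {"buried_charge_replaced"}),
    "disallowed_phi_psi": (
        # (80, -100) is glycine-only torsion space; an alanine there is both
        # an outlier and sterically strained, and the kink is a DSSP bend
        lambda: sf.rama_trap(), ("A", 5, "G", "A"),
        {"disallowed_phi_psi", "gly_in_bend", "clash"}),
    "buried_gly_replaced": (
        lambda: sf.buried_core("G"), ("A", 3, "G", "A"),
        {"buried_gly_replaced"}),
    "buried_hbond_breakage": (
        lambda: sf.buried_hbond_pair(), ("A", 3, "Q", "L"),
        {"buried_hbond_breakage"}),
    "buried_saltbridge_breakage": (
        # a charged residue replaced by an uncharged one also trips the
        # charge-replacement rule
        lambda: sf.buried_salt_bridge(), ("A", 3, "H", "Y"),
        {"buried_saltbridge_breakage", "buried_charge_replaced"}),
    "cavity_altered": (
        # removing the large tryptophan side chain from the cage interior
        # opens a void and raises the small mutant's relative accessibility
        lambda: sf.buried_core("W"), ("A", 3, "W", "A"),
        {"cavity_altered", "buried_exposed_switch"}),
    "buried_exposed_switch": (
        lambda: sf.buried_core("W"), ("A", 3, "W", "A"),
        {"cavity_altered", "buried_exposed_switch"}),
    "cis_pro_replaced": (
        lambda: sf.cis_pro_loop(), ("A", 4, "P", "A"),
        {"cis_pro_replaced"}),
    "gly_in_bend": (
        lambda: sf.bend_gly(), ("A", 5, "G", "A"),
        {"gly_in_bend"}),
    "exposed_hydrophobic_introduced": (
        lambda: sf.ideal_helix("AAAAADAAAAA"), ("A", 6, "D", "L"),
        {"exposed_hydrophobic_introduced"}),
}

NEGATIVE_CASES = {
    "benign_surface": (lambda: sf.ideal_helix("A" * 9), ("A", 5, "A", "S"), set()),
    "identity": (lambda: sf.disulfide_pair(2.05), ("A", 3, "C", "C"), set()),
}


@pytest.fixture(scope="session")
def truth_table_reports():
    """Evaluate every truth-table case once; returns {name: (report, expected)}."""
    out = {}
    for name, (builder, var, expected) in {**TRUTH_TABLE, **NEGATIVE_CASES}.items():
        s = builder()
        v = VariantSpec(var[0], var[1], var[2], var[3])
        models = build_models(s, v)
        out[name] = (evaluate(models, v), expected)
    return out
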