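"""PDB I/O, the coordinate hierarchy, and variant-position resolution."""

import numpy as np
import pytest

from structalert.structure_io import (
    EmptyStructureError, MappingRejectedError, NotInStructureError,
    PDBParseError, VariantSpec, WildTypeMismatchError,
    map_sequence_to_structure, parse_pdb, resolve_variant, write_pdb)
import structalert.synthetic_fixtures as sf

MINIMAL = "ATOM      1  N   GLY A   1      11.104   6.134  -6.504  1.00  0.00           N\n"


def test_parse_minimal_record():
    s = parse_pdb(MINIMAL)
    assert s.chain_ids() == ["A"]
    (res,) = list(s.residues())
    assert res.resname == "GLY" and res.seqnum == 1
    assert [a.name for a in res.atoms] == ["N"]
    assert np.allclose(res.atoms[0].coord, [11.104, 6.134, -6.504])


def test_parse_errors_name_line_and_empty_input():
    bad = "ATOM      1  N   GLY A  XX      11.104   6.134  -6.504\n"
    with pytest.raises(PDBParseError, match="line 1"):
        parse_pdb(bad)
    with pytest.raises(PDBParseError):
        parse_pdb("REMARK nothing here\n")
    # water-only input has records but no standard residue
    water = "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
    with pytest.raises(PDBParseError):
        parse_pdb(water)


def test_altloc_keeps_highest_occupancy_tie_prefers_A():
    text = (
        "ATOM      1  CA ASER A   1       0.000   0.000   0.000  0.40  0.00           C\n"
        "ATOM      2  CA BSER A   1       1.000   0.000   0.000  0.60  0.00           C\n"
        "ATOM      3  OG ASER A   1       2.000   0.000   0.000  0.50  0.00           O\n"
        "ATOM      4  OG BSER A   1       3.000   0.000   0.000  0.50  0.00           O\n"
    )
    s = parse_pdb(text)
    res = s.get_residue("A", 1)
    assert res.atom("CA").coord[0] == 1.0      # occupancy 0.6 wins
    assert res.atom("OG").coord[0] == 2.0      # tie -> altloc A


def test_write_pdb_degenerate_and_single_atom():
    from structalert.structure_io import Structure
    with pytest.raises(EmptyStructureError):
        write_pdb(Structure())
    s = parse_pdb(MINIMAL)
    text = write_pdb(s)
    lines = text.strip().splitlines()
    assert lines[0].startswith("ATOM")
    assert lines[1].startswith("TER")
    assert lines[-1] == "END"


@pytest.mark.parametrize("builder", [
    lambda: sf.ideal_helix("ADERLYW"),
    lambda: sf.disulfide_pair(2.05),
    lambda: sf.buried_core("L"),
])
def test_round_trip_is_identity_on_hierarchy(builder):
    s = builder()
    s2 = parse_pdb(write_pdb(s))
    orig = [(r.chain_id, r.seqnum, r.resname, a.name, tuple(np.round(a.coord, 3)))
            for r, a in s.atoms(standard_only=False)]
    back = [(r.chain_id, r.seqnum, r.resname, a.name, tuple(a.coord))
            for r, a in s2.atoms(standard_only=False)]
    assert orig == back
    # and writing again is byte-stable
    assert write_pdb(s2) == write_pdb(parse_pdb(write_pdb(s2)))


def test_parse_agrees_with_gemmi_on_fixture():
    gemmi = pytest.importorskip("gemmi")
    s = sf.ideal_helix("AKDWY")
    text = write_pdb(s)
    gst = gemmi.read_pdb_string(text)
    g_atoms = [(res.name, atom.name, round(atom.pos.x, 3))
               for model in gst for chain in model for res in chain
               for atom in res]
    mine = [(r.resname, a.name, round(float(a.coord[0]), 3))
            for r, a in parse_pdb(text).atoms()]
    assert g_atoms == mine


# ---------------------------------------------------------------------------
# sequence -> structure mapping
# ---------------------------------------------------------------------------

def _gotoh_oracle(seq_a, seq_b):
    """Independent affine-gap global alignment (BLOSUM62, -10/-0.5)."""
    from Bio.Align import substitution_matrices
    blosum = substitution_matrices.load("BLOSUM62")
    go, ge = -10.0, -0.5
    n, m = len(seq_a), len(seq_b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)   # gap in seq_b (consume a)
    Y = np.full((n + 1, m + 1), NEG)   # gap in seq_a (consume b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + ge * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = go + ge * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = blosum[seq_a[i - 1], seq_b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + sub
            X[i, j] = max(M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go)
            Y[i, j] = max(M[i, j - 1] + go, Y[i, j - 1] + ge, X[i, j - 1] + go)
    # traceback for the aligned pairs
    i, j = n, m
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    pairs = []
    while i > 0 or j > 0:
        if state == 0:
            pairs.append((i - 1, j - 1))
            sub = blosum[seq_a[i - 1], seq_b[j - 1]]
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1:
            cands = [M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go]
            state = int(np.argmax(cands))
            i -= 1
        else:
            cands = [M[i, j - 1] + go, Y[i, j - 1] + ge, X[i, j - 1] + go]
            state = 2 if cands[1] >= max(cands[0], cands[2]) else int(np.argmax(cands))
            state = {0: 0, 1: 1, 2: 2}[state]
            j -= 1
    return max(M[n, m], X[n, m], Y[n, m]), list(reversed(pairs))


def test_mapping_identity_and_shift():
    s = sf.ideal_helix("AKDWYLE")
    seq, residues = s.chain_sequence("A")
    m = map_sequence_to_structure(seq, s, "A")
    assert all(m.matches)
    assert [p for p in m.pairs] == [(i, r.res_id) for i, r in enumerate(residues)]
    # one leading extra residue shifts everything by one
    m2 = map_sequence_to_structure("G" + seq, s, "A")
    assert [p[0] for p in m2.pairs] == list(range(1, len(seq) + 1))
    assert all(m2.matches)


def test_mapping_matches_affine_dp_oracle():
    rng = np.random.default_rng(7)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    seq = "".join(rng.choice(list(aas)) for _ in range(50))
    # structure carries the same sequence with an internal 5-residue deletion
    struct_seq = seq[:20] + seq[25:]
    s = sf.ideal_helix(struct_seq)
    m = map_sequence_to_structure(seq, s, "A")
    _, residues = s.chain_sequence("A")
    rid_to_j = {r.res_id: j for j, r in enumerate(residues)}
    mine = [(i, rid_to_j[rid]) for i, rid in m.pairs]
    _, oracle = _gotoh_oracle(seq, struct_seq)
    assert mine == oracle


def test_mapping_monotone_injective_and_floor():
    s = sf.ideal_helix("AKDWYLE")
    seq, _ = s.chain_sequence("A")
    m = map_sequence_to_structure(seq, s, "A")
    seq_idx = [p[0] for p in m.pairs]
    str_idx = [p[1] for p in m.pairs]
    assert seq_idx == sorted(seq_idx) and len(set(seq_idx)) == len(seq_idx)
    assert len(set(str_idx)) == len(str_idx)
    with pytest.raises(MappingRejectedError):
        map_sequence_to_structure("W" * 7, s, "A", identity_floor=90.0)


def test_resolve_variant_paths():
    s = sf.ideal_helix("AKDWYLE")
    res = resolve_variant(VariantSpec("A", 3, "D", "G"), s)
    assert res.resname == "ASP"
    with pytest.raises(WildTypeMismatchError):
        resolve_variant(VariantSpec("A", 3, "A", "G"), s)
    with pytest.raises(NotInStructureError):
        resolve_variant(VariantSpec("A", 99, "A", "G"), s)
    # sequence frame through a mapping with a gap: position 22 was deleted
    seq = "AKDWYLE"
    full = "AK" + "QQQ" + "DWYLE"  # structure lacks the QQQ insert
    st = sf.ideal_helix(seq)
    mapping = map_sequence_to_structure(full, st, "A")
    with pytest.raises(NotInStructureError):
        resolve_variant(VariantSpec("A", 4, "Q", "A", frame="sequence"), st, mapping)
    res = resolve_variant(VariantSpec("A", 6, "D", "A", frame="sequence"), st, mapping)
    assert res.resname == "ASP"


def test_variant_spec_validation():
    with pytest.raises(ValueError):
        VariantSpec("A", 1, "B", "G")
    with pytest.raises(ValueError):
        VariantSpec("A", 1, "A", "G", frame="author")
    v = VariantSpec.from_string("A", "C52R")
    assert (v.wt, v.position, v.mut) == ("C", 52, "R")
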