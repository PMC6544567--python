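"""Detection of disulfide bonds, side-chain hydrogen bonds and salt bridges.

All three detectors are pure heavy-atom distance criteria at relaxed cutoffs
(standard distance + 1 Å): S–S < 3.3 Å for disulfides, N–O < 3.9 Å for
hydrogen bonds and N–O < 5.0 Å for salt bridges.  Angular criteria,
pi-interactions and metal coordination are out of scope.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .structure_io import Residue, Structure

__all__ = [
    "Disulfide", "HBond", "SaltBridge", "InteractionSet",
    "find_disulfides", "find_sidechain_hbonds", "find_salt_bridges",
    "interaction_set_for",
]

# Side-chain H-bond donor atoms (N unless noted; S/T/Y hydroxyl O can donate).
SC_DONORS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
    "TRP": ("NE1",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}
# Side-chain H-bond acceptor atoms (O unless noted; His N accepts as well).
SC_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}
# charged-group atoms for salt bridges
POSITIVE_N: dict[str, tuple[str, ...]] = {
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
}
NEGATIVE_O: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

CHARGED_RES = {"ASP", "GLU", "HIS", "LYS", "ARG"}


@dataclasses.dataclass(frozen=True)
class Disulfide:
    res_a: tuple
    res_b: tuple
    distance: float


@dataclasses.dataclass(frozen=True)
class HBond:
    donor_res: tuple
    donor_atom: str
    acceptor_res: tuple
    acceptor_atom: str
    distance: float
    kind: str  # "sc/sc" | "sc/mc"


@dataclasses.dataclass(frozen=True)
class SaltBridge:
    pos_res: tuple
    pos_atom: str
    neg_res: tuple
    neg_atom: str
    distance: float


@dataclasses.dataclass
class InteractionSet:
    """Interactions involving one target residue (or a whole structure)."""

    disulfides: list[Disulfide] = dataclasses.field(default_factory=list)
    hbonds: list[HBond] = dataclasses.field(default_factory=list)
    saltbridges: list[SaltBridge] = dataclasses.field(default_factory=list)


def _dist(a, b) -> float:
    return float(np.linalg.norm(a.coord - b.coord))


def find_disulfides(s: Structure, cutoff: float = 3.3) -> list[Disulfide]:
    """All Cys SG–SG pairs closer than ``cutoff``."""
    sgs = [(res, res.atom("SG")) for res in s.residues() if res.resname == "CYS"]
    sgs = [(r, a) for r, a in sgs if a is not None]
    out: list[Disulfide] = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            d = _dist(sgs[i][1], sgs[j][1])
            if d < cutoff:
                out.append(Disulfide(sgs[i][0].res_id, sgs[j][0].res_id, d))
    return out


def _chain_index(s: Structure) -> dict[tuple, int]:
    """Sequential index of standard residues within their chain (for adjacency)."""
    idx = {}
    for cid in s.chain_ids():
        k = 0
        for res in s.chains[cid]:
            if res.het or res.one_letter is None:
                continue
            idx[res.res_id] = k
            k += 1
    return idx


def _adjacent(a: Residue, b: Residue, idx: dict[tuple, int]) -> bool:
    if a.chain_id != b.chain_id:
        return False
    ia, ib = idx.get(a.res_id), idx.get(b.res_id)
    return ia is not None and ib is not None and abs(ia - ib) <= 1


def find_sidechain_hbonds(s: Structure, res: Residue,
                          cutoff: float = 3.9) -> list[HBond]:
    """Hydrogen bonds (N–O / O–N distance criterion) with one member in the
    side chain of ``res``; partners may be side chain or main chain of another
    residue.  Sequence-adjacent main-chain partners are excluded."""
    idx = _chain_index(s)
    out: list[HBond] = []
    seen: set[tuple] = set()

    def record(donor_res, donor_atom, acc_res, acc_atom, kind):
        d = _dist(donor_atom, acc_atom)
        if d >= cutoff:
            return
        # require one N and one O between donor/acceptor atoms
        els = {donor_atom.element.upper(), acc_atom.element.upper()}
        if els != {"N", "O"}:
            return
        key = (donor_res.res_id, donor_atom.name, acc_res.res_id, acc_atom.name)
        if key in seen:
            return
        seen.add(key)
        out.append(HBond(donor_res.res_id, donor_atom.name,
                         acc_res.res_id, acc_atom.name, d, kind))

    res_donors = [res.atom(n) for n in SC_DONORS.get(res.resname, ())]
    res_donors = [a for a in res_donors if a is not None]
    res_acceptors = [res.atom(n) for n in SC_ACCEPTORS.get(res.resname, ())]
    res_acceptors = [a for a in res_acceptors if a is not None]

    for other in s.residues():
        if other is res:
            continue
        adjacent = _adjacent(res, other, idx)
        # side-chain donors of res -> side-chain acceptors of other
        for da in res_donors:
            for an in SC_ACCEPTORS.get(other.resname, ()):
                aa = other.atom(an)
                if aa is not None:
                    record(res, da, other, aa, "sc/sc")
            # -> main-chain O of other
            if not adjacent:
                o = other.atom("O")
                if o is not None:
                    record(res, da, other, o, "sc/mc")
        # side-chain acceptors of res <- side-chain donors of other
        for aa in res_acceptors:
            for dn in SC_DONORS.get(other.resname, ()):
                da = other.atom(dn)
                if da is not None:
                    record(other, da, res, aa, "sc/sc")
            # <- main-chain N of other
            if not adjacent:
                n = other.atom("N")
                if n is not None and other.one_letter != "P":
                    record(other, n, res, aa, "sc/mc")
    return out


def find_salt_bridges(s: Structure, res: Residue,
                      cutoff: float = 5.0) -> list[SaltBridge]:
    """Salt bridges of ``res``: opposite-charge side-chain N–O pairs < cutoff.

    An uncharged residue yields an empty list (not an error)."""
    if res.resname not in CHARGED_RES:
        return []
    out: list[SaltBridge] = []
    if res.resname in POSITIVE_N:
        atoms = [res.atom(n) for n in POSITIVE_N[res.resname]]
        atoms = [a for a in atoms if a is not None]
        for other in s.residues():
            if other is res or other.resname not in NEGATIVE_O:
                continue
            for oa_name in NEGATIVE_O[other.resname]:
                oa = other.atom(oa_name)
                if oa is None:
                    continue
                for pa in atoms:
                    d = _dist(pa, oa)
                    if d < cutoff:
                        out.append(SaltBridge(res.res_id, pa.name,
                                              other.res_id, oa.name, d))
    else:  # negative residue
        atoms = [res.atom(n) for n in NEGATIVE_O[res.resname]]
        atoms = [a for a in atoms if a is not None]
        for other in s.residues():
            if other is res or other.resname not in POSITIVE_N:
                continue
            for pn_name in POSITIVE_N[other.resname]:
                pa = other.atom(pn_name)
                if pa is None:
                    continue
                for oa in atoms:
                    d = _dist(pa, oa)
                    if d < cutoff:
                        out.append(SaltBridge(other.res_id, pa.name,
                                              res.res_id, oa.name, d))
    return out


def interaction_set_for(s: Structure, res: Residue,
                        disulfide_cutoff: float = 3.3,
                        hbond_cutoff: float = 3.9,
                        saltbridge_cutoff: float = 5.0) -> InteractionSet:
    """All three interaction types touching one residue."""
    ds = [d for d in find_disulfides(s, disulfide_cutoff)
          if res.res_id in (d.res_a, d.res_b)]
    hb = find_sidechain_hbonds(s, res, hbond_cutoff)
    sb = find_salt_bridges(s, res, saltbridge_cutoff)
    return InteractionSet(ds, hb, sb)
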