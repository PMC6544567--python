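"""PDB-format I/O, the structural hierarchy, and variant-position resolution.

The coordinate model is deliberately small: a :class:`Structure` is an ordered
list of chains, a chain an ordered list of :class:`Residue`, a residue a list
of :class:`Atom`.  Author numbering (sequence number + insertion code) is the
canonical structure frame; sequence-space positions are mapped onto it through
a global alignment (:func:`map_sequence_to_structure`).

Only the first MODEL of a multi-model file is read.  Alternate locations are
collapsed to a single conformer per atom name (highest occupancy; ties prefer
altloc 'A', then lexicographic).  HETATM records are retained for round-trip
but excluded from the analysis set, except that MSE and other common modified
residues are mapped to their parent amino acid for sequence purposes.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator, Optional

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "VariantSpec",
    "ResidueMapping",
    "PDBParseError",
    "EmptyStructureError",
    "MappingRejectedError",
    "NotInStructureError",
    "WildTypeMismatchError",
    "parse_pdb",
    "write_pdb",
    "map_sequence_to_structure",
    "resolve_variant",
]

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# common modified residues mapped to their parent amino acid for sequence purposes
MODIFIED_PARENT = {"MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO", "SEP": "SER",
                   "TPO": "THR", "PTR": "TYR", "CSO": "CYS", "MLY": "LYS"}

WATER_NAMES = {"HOH", "WAT", "DOD"}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class PDBParseError(ValueError):
    """A fixed-width record could not be parsed (reports the 1-based line number)."""


class EmptyStructureError(ValueError):
    """No standard amino-acid residue was found."""


class MappingRejectedError(ValueError):
    """Sequence-to-structure alignment identity fell below the floor."""


class NotInStructureError(KeyError):
    """Variant position is not resolved in the structure."""


class WildTypeMismatchError(ValueError):
    """Stated wild-type amino acid differs from the residue observed in the structure."""


@dataclasses.dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) float64, Å
    altloc: str = ""
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            self.element = infer_element(self.name)

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coord.copy(), self.altloc,
                    self.occupancy, self.bfactor)


@dataclasses.dataclass
class Residue:
    resname: str              # 3-letter code
    seqnum: int               # author sequence number
    icode: str                # insertion code ('' if none)
    chain_id: str
    atoms: list[Atom] = dataclasses.field(default_factory=list)
    het: bool = False
    modified: bool = False    # non-standard residue mapped to a parent type

    @property
    def res_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seqnum, self.icode)

    @property
    def one_letter(self) -> Optional[str]:
        name = MODIFIED_PARENT.get(self.resname, self.resname)
        return AA3_TO_1.get(name)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in BACKBONE_ATOMS)

    def backbone_coords(self) -> dict[str, np.ndarray]:
        return {n: self.atom(n).coord for n in BACKBONE_ATOMS if self.atom(n) is not None}

    def sidechain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.name not in BACKBONE_ATOMS]

    def label(self) -> str:
        return f"{self.chain_id}/{self.resname}{self.seqnum}{self.icode}"

    def copy(self) -> "Residue":
        return Residue(self.resname, self.seqnum, self.icode, self.chain_id,
                       [a.copy() for a in self.atoms], self.het, self.modified)


@dataclasses.dataclass
class Structure:
    """Ordered chains of residues; residue order follows file order."""

    chains: dict[str, list[Residue]] = dataclasses.field(default_factory=dict)
    provenance: str = "experimental"  # experimental | predicted | synthetic

    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def residues(self, standard_only: bool = True) -> Iterator[Residue]:
        for chain in self.chains.values():
            for res in chain:
                if standard_only and (res.het or res.one_letter is None):
                    continue
                yield res

    def atoms(self, standard_only: bool = True) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues(standard_only=standard_only):
            for a in res.atoms:
                yield res, a

    def get_residue(self, chain_id: str, seqnum: int, icode: str = "") -> Optional[Residue]:
        for res in self.chains.get(chain_id, ()):
            if res.seqnum == seqnum and res.icode == icode:
                return res
        return None

    def chain_sequence(self, chain_id: str) -> tuple[str, list[Residue]]:
        """One-letter sequence of observed standard residues + the residue list."""
        residues = [r for r in self.chains.get(chain_id, ())
                    if not r.het and r.one_letter is not None]
        return "".join(r.one_letter for r in residues), residues

    def copy(self) -> "Structure":
        out = Structure(provenance=self.provenance)
        for cid, chain in self.chains.items():
            out.chains[cid] = [r.copy() for r in chain]
        return out

    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms(standard_only=False))


@dataclasses.dataclass(frozen=True)
class VariantSpec:
    """A missense substitution: chain, position, and the two amino acids.

    ``frame`` selects how ``position`` is interpreted: ``"structure"`` means the
    author numbering of the coordinate file, ``"sequence"`` means a 1-based index
    into a protein sequence that must first be aligned onto the structure.
    """

    chain_id: str
    position: int
    wt: str
    mut: str
    frame: str = "structure"  # "structure" | "sequence"
    icode: str = ""

    def __post_init__(self) -> None:
        for aa, tag in ((self.wt, "wild-type"), (self.mut, "mutant")):
            if aa not in AA1_TO_3:
                raise ValueError(f"{tag} amino acid {aa!r} is not one of the 20 canonical")
        if self.frame not in ("structure", "sequence"):
            raise ValueError(f"frame must be 'structure' or 'sequence', got {self.frame!r}")

    @classmethod
    def from_string(cls, chain_id: str, text: str, frame: str = "structure") -> "VariantSpec":
        """Parse compact notation like ``C52R`` (wt, position, mut)."""
        text = text.strip()
        if len(text) < 3 or text[0] not in AA1_TO_3 or text[-1] not in AA1_TO_3:
            raise ValueError(f"cannot parse variant {text!r}; expected e.g. 'C52R'")
        return cls(chain_id, int(text[1:-1]), text[0], text[-1], frame=frame)


@dataclasses.dataclass
class ResidueMapping:
    """Pairs (0-based sequence index -> structure residue id) from a global alignment."""

    pairs: list[tuple[int, tuple[str, int, str]]]
    matches: list[bool]          # per-pair: aligned amino acids identical
    identity: float              # percent identity over aligned pairs

    def to_structure(self, seq_index: int) -> Optional[tuple[str, int, str]]:
        for i, rid in self.pairs:
            if i == seq_index:
                return rid
        return None


# ---------------------------------------------------------------------------
# PDB parsing / writing
# ---------------------------------------------------------------------------

_ELEMENT_2 = {"FE", "ZN", "MG", "MN", "CU", "NA", "CL", "BR", "SE", "CA", "NI", "CO", "CD"}


def infer_element(atom_name: str) -> str:
    """Infer the element from a PDB atom name when the element column is absent."""
    name = atom_name.strip()
    if not name:
        raise ValueError("empty atom name")
    # digits may lead remote hydrogens (1HB2); strip them
    stripped = name.lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    if stripped[:2].upper() in _ELEMENT_2 and len(name) >= 4:
        return stripped[:2].capitalize()
    return stripped[0].upper()


def parse_pdb(text: str, provenance: str = "experimental") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Keeps the first MODEL only, collapses altlocs to a single conformer
    (highest occupancy, tie broken towards '' / 'A' / lexicographic), and
    drops waters.  HETATM residues are retained (flagged) for round-trip.
    """
    raw: dict[str, dict[tuple[int, str, str], Residue]] = {}
    chain_order: list[str] = []
    per_atom: dict[tuple, list[Atom]] = {}
    n_atom_records = 0
    in_first_model = True

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            continue
        if rec.startswith("ENDMDL"):
            in_first_model = False
            continue
        if not in_first_model:
            continue
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: ATOM/HETATM record shorter than 54 columns")
        try:
            name = line[12:16].strip()
            altloc = line[16].strip()
            resname = line[17:20].strip()
            chain_id = line[21].strip() or " "
            seqnum = int(line[22:26])
            icode = line[26].strip()
            x = float(line[30:38]); y = float(line[38:46]); z = float(line[46:54])
            occ = float(line[54:60]) if line[54:60].strip() else 1.0
            bfac = float(line[60:66]) if line[60:66].strip() else 0.0
            element = line[76:78].strip() if len(line) >= 78 else ""
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: malformed record ({exc})") from None
        if resname in WATER_NAMES:
            continue
        het = rec == "HETATM"
        if resname in MODIFIED_PARENT:
            het = False  # analysed as parent amino acid
        atom = Atom(name, element, np.array([x, y, z]), altloc, occ, bfac)
        n_atom_records += 1
        key = (chain_id, seqnum, icode, resname)
        if chain_id not in raw:
            raw[chain_id] = {}
            chain_order.append(chain_id)
        rkey = (seqnum, icode, resname)
        if rkey not in raw[chain_id]:
            res = Residue(resname, seqnum, icode, chain_id, [], het,
                          modified=resname in MODIFIED_PARENT)
            raw[chain_id][rkey] = res
        per_atom.setdefault(key + (name,), []).append(atom)
        # store placeholder order by first occurrence
        res = raw[chain_id][rkey]
        if atom.name not in [a.name for a in res.atoms]:
            res.atoms.append(atom)  # replaced below by altloc winner

    if n_atom_records == 0:
        raise PDBParseError("no ATOM/HETATM record found")

    # altloc resolution: replace each named atom by the winning conformer
    def altloc_rank(a: Atom) -> tuple:
        pref = {"": 0, "A": 1}.get(a.altloc, 2)
        return (-a.occupancy, pref, a.altloc)

    structure = Structure(provenance=provenance)
    n_standard = 0
    for cid in chain_order:
        chain: list[Residue] = []
        for rkey, res in raw[cid].items():
            resolved: list[Atom] = []
            for a in res.atoms:
                candidates = per_atom[(cid, res.seqnum, res.icode, res.resname, a.name)]
                best = min(candidates, key=altloc_rank)
                resolved.append(best)
            res.atoms = resolved
            chain.append(res)
            if not res.het and res.one_letter is not None:
                n_standard += 1
        structure.chains[cid] = chain
    if n_standard == 0:
        raise EmptyStructureError("no standard amino-acid residue in input")
    return structure


def write_pdb(s: Structure) -> str:
    """Serialize a :class:`Structure` to fixed-width PDB text (3-decimal coords)."""
    if not s.chains or all(len(c) == 0 for c in s.chains.values()):
        raise EmptyStructureError("cannot write a structure with no residues")
    lines: list[str] = []
    serial = 1
    for cid, chain in s.chains.items():
        last_res = None
        for res in chain:
            for a in res.atoms:
                if not np.all(np.isfinite(a.coord)):
                    raise ValueError(f"atom {a.name} of {res.label()} has non-finite coordinates")
                rec = "HETATM" if res.het and not res.modified else "ATOM  "
                name = a.name
                # PDB atom-name alignment: element right-justified in cols 13-14
                if len(name) < 4:
                    name = (" " + name) if len(a.element) == 1 else name
                lines.append(
                    f"{rec}{serial:5d} {name:<4s}{(a.altloc or ' ')[:1]}{res.resname:>3s} "
                    f"{cid[:1]}{res.seqnum:4d}{(res.icode or ' ')[:1]}   "
                    f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
                    f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {a.element:>2s}"
                )
                serial += 1
            last_res = res
        if last_res is not None:
            lines.append(f"TER   {serial:5d}      {last_res.resname:>3s} "
                         f"{cid[:1]}{last_res.seqnum:4d}{(last_res.icode or ' ')[:1]}")
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Sequence -> structure mapping
# ---------------------------------------------------------------------------

def map_sequence_to_structure(seq: str, s: Structure, chain_id: str,
                              identity_floor: float = 30.0) -> ResidueMapping:
    """Globally align ``seq`` to the chain's observed residues (BLOSUM62,
    gap open −10 / extend −0.5) and return the index mapping.

    Raises :class:`MappingRejectedError` when percent identity over aligned
    pairs falls below ``identity_floor``.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    if chain_id not in s.chains:
        raise NotInStructureError(f"chain {chain_id!r} not in structure")
    if not seq:
        raise ValueError("empty sequence")
    chain_seq, residues = s.chain_sequence(chain_id)
    if not chain_seq:
        raise EmptyStructureError(f"chain {chain_id!r} has no standard residues")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq, chain_seq)[0]

    pairs: list[tuple[int, tuple[str, int, str]]] = []
    matches: list[bool] = []
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        for off in range(qe - qs):
            i, j = qs + off, ts + off
            pairs.append((i, residues[j].res_id))
            matches.append(seq[i] == chain_seq[j])
    if not pairs:
        raise MappingRejectedError("alignment produced no aligned pairs")
    identity = 100.0 * sum(matches) / len(matches)
    if identity < identity_floor:
        raise MappingRejectedError(
            f"alignment identity {identity:.1f}% below floor {identity_floor:.1f}%")
    return ResidueMapping(pairs, matches, identity)


def resolve_variant(v: VariantSpec, s: Structure,
                    mapping: Optional[ResidueMapping] = None) -> Residue:
    """Locate the structure residue addressed by a variant and verify its type."""
    if v.frame == "sequence":
        if mapping is None:
            raise ValueError("sequence-frame variant requires a ResidueMapping")
        rid = mapping.to_structure(v.position - 1)  # sequence positions are 1-based
        if rid is None:
            raise NotInStructureError(
                f"sequence position {v.position} is not resolved in the structure")
        res = s.get_residue(*rid)
    else:
        res = s.get_residue(v.chain_id, v.position, v.icode)
    if res is None:
        raise NotInStructureError(
            f"position {v.position}{v.icode} not found in chain {v.chain_id!r}")
    observed = res.one_letter
    if observed != v.wt:
        raise WildTypeMismatchError(
            f"variant states wild-type {v.wt} but structure has "
            f"{res.resname} ({observed}) at {res.label()}")
    return res
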