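"""Reading, sanitizing and partitioning of two-partner protein coordinate files.

Input structures follow the one-interface-per-file convention: each PDB file
contains exactly the two interacting partners (possibly several chains each),
already placed in a common frame.  No crystal-symmetry expansion is performed.

Sanitization policy
-------------------
* waters and non-amino-acid heteroatoms are removed,
* hydrogens (and deuteriums) are dropped,
* for alternate locations the highest-occupancy conformer is kept
  (ties resolved toward altloc ``A``, then first encountered),
* selenomethionine (MSE) is renamed to MET; a small table of further
  unambiguous parent-residue mappings (SEP, TPO, PTR, HYP, CSO, MLY) is
  applied, anything else non-standard is dropped,
* every action is appended to ``Structure.sanitization_log``.

Coordinates of retained atoms are never modified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Atom import DisorderedAtom

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "InterfacePair",
    "StructureError",
    "EmptyStructureError",
    "ChainGroupingError",
    "STANDARD_AA",
    "PARENT_RESIDUE",
    "load_structure",
    "make_interface_pair",
    "write_structure",
]

#: the twenty standard three-letter amino-acid codes
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: unambiguous parent-residue renames applied during sanitization.
#: MSE -> MET is the canonical case; the others are common PTM variants
#: whose parent is not in doubt.
PARENT_RESIDUE = {
    "MSE": "MET",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "HYP": "PRO",
    "CSO": "CYS",
    "MLY": "LYS",
}

#: atom renames that accompany a residue rename (selenium -> sulfur for MSE)
_ATOM_RENAME = {("MSE", "SE"): ("SD", "S")}

_WATER = {"HOH", "WAT", "DOD", "H2O"}


class StructureError(ValueError):
    """Problem reading or manipulating a structure."""


class EmptyStructureError(StructureError):
    """The file contains no usable protein residues."""


class ChainGroupingError(StructureError):
    """Invalid or ambiguous partner chain grouping."""


@dataclass
class Atom:
    """A heavy atom with coordinates in angstroms."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = " "

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    """An amino-acid residue; ``seq_id`` is the author number plus insertion code."""

    resname: str
    chain_id: str
    seq_id: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, str]:
        return (self.chain_id, self.seq_id)

    def coord_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class Structure:
    """A sanitized atomic model: ordered chains of residues of heavy atoms."""

    chains: dict[str, list[Residue]] = field(default_factory=dict)
    source_id: str = ""
    sanitization_log: list[str] = field(default_factory=list)

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    @property
    def n_atoms(self) -> int:
        return sum(len(res.atoms) for r in self.chains.values() for res in r)

    def residues(self) -> list[Residue]:
        return [res for chain in self.chains.values() for res in chain]

    def subset(self, chain_ids) -> "Structure":
        """A new Structure containing only the given chains (shared residues)."""
        missing = set(chain_ids) - set(self.chains)
        if missing:
            raise ChainGroupingError(f"chains not in structure: {sorted(missing)}")
        return Structure(
            chains={c: self.chains[c] for c in self.chains if c in set(chain_ids)},
            source_id=self.source_id,
        )


@dataclass
class InterfacePair:
    """Two disjoint groups of chains forming one putative interface."""

    partner1: frozenset
    partner2: frozenset
    structure: Structure

    def __post_init__(self) -> None:
        self.partner1 = frozenset(self.partner1)
        self.partner2 = frozenset(self.partner2)
        if not self.partner1 or not self.partner2:
            raise ChainGroupingError("both partners must contain at least one chain")
        if self.partner1 & self.partner2:
            raise ChainGroupingError(
                f"partners overlap on chains {sorted(self.partner1 & self.partner2)}"
            )
        known = set(self.structure.chains)
        extra = (self.partner1 | self.partner2) - known
        if extra:
            raise ChainGroupingError(f"chains not in structure: {sorted(extra)}")

    def partner_structure(self, which: int) -> Structure:
        return self.structure.subset(self.partner1 if which == 1 else self.partner2)

    def swapped(self) -> "InterfacePair":
        return InterfacePair(self.partner2, self.partner1, self.structure)


def _pick_altloc(disordered: DisorderedAtom):
    """Highest occupancy wins; ties go to altloc 'A', then first encountered."""
    children = sorted(
        disordered.disordered_get_list(),
        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc() != "A"),
    )
    return children[0]


def load_structure(path, model_index: int = 0) -> Structure:
    """Read and sanitize a PDB file into a :class:`Structure`.

    Parameters
    ----------
    path : str or Path
        PDB-format coordinate file.
    model_index : int
        Which MODEL to use for multi-model files (default: the first).

    Raises
    ------
    EmptyStructureError
        If no amino-acid residues survive sanitization.
    StructureError
        If the file cannot be parsed or the model index does not exist.
    """
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio_structure = parser.get_structure("input", str(path))
    except Exception as exc:  # Bio.PDB raises assorted exception types
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc

    models = list(bio_structure)
    if not models:
        raise EmptyStructureError(f"{path}: file contains no coordinate model")
    if model_index >= len(models):
        raise StructureError(
            f"{path}: model index {model_index} out of range ({len(models)} models)"
        )
    model = models[model_index]

    structure = Structure(source_id=str(path))
    log = structure.sanitization_log
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            hetflag, resseq, icode = res.get_id()
            resname = res.get_resname().strip()
            seq_id = f"{resseq}{icode.strip()}"
            if resname in _WATER:
                log.append(f"removed water {chain.id}:{seq_id}")
                continue
            renamed_from = None
            if resname not in STANDARD_AA:
                if resname in PARENT_RESIDUE:
                    renamed_from = resname
                    log.append(
                        f"renamed {resname} -> {PARENT_RESIDUE[resname]} at {chain.id}:{seq_id}"
                    )
                    resname = PARENT_RESIDUE[resname]
                else:
                    log.append(f"dropped non-standard residue {resname} {chain.id}:{seq_id}")
                    continue
            atoms: list[Atom] = []
            for bio_atom in res:
                if isinstance(bio_atom, DisorderedAtom):
                    kept = _pick_altloc(bio_atom)
                    log.append(
                        f"altloc at {chain.id}:{seq_id}:{kept.get_name()} -> kept "
                        f"'{kept.get_altloc()}' (occupancy {kept.get_occupancy()})"
                    )
                    bio_atom = kept
                element = (bio_atom.element or "").strip().upper()
                name = bio_atom.get_name().strip()
                if element in ("H", "D") or (not element and name.startswith("H")):
                    continue
                if (renamed_from, name) in _ATOM_RENAME:
                    name, element = _ATOM_RENAME[(renamed_from, name)]
                    log.append(f"renamed atom SE -> SD at {chain.id}:{seq_id}")
                occ = bio_atom.get_occupancy()
                occ = 1.0 if occ is None else min(max(float(occ), 0.0), 1.0)
                atoms.append(
                    Atom(
                        name=name,
                        element=element or name[:1],
                        coords=bio_atom.get_coord(),
                        occupancy=occ,
                        altloc=(bio_atom.get_altloc() or " "),
                    )
                )
            if not atoms:
                log.append(f"dropped residue with no heavy atoms {chain.id}:{seq_id}")
                continue
            heavy_names = {a.name for a in atoms}
            if resname != "GLY" and {"N", "CA", "C", "O"} - heavy_names and "CA" in heavy_names:
                log.append(f"incomplete backbone retained at {chain.id}:{seq_id}")
            residues.append(Residue(resname=resname, chain_id=chain.id, seq_id=seq_id, atoms=atoms))
        if residues:
            structure.chains[chain.id] = residues

    if not structure.chains:
        raise EmptyStructureError(f"{path}: no protein residues after sanitization")
    return structure


def make_interface_pair(structure: Structure, partner1=(), partner2=()) -> InterfacePair:
    """Group the chains of ``structure`` into the two interface partners.

    With no explicit grouping, a two-chain structure defaults to one chain
    per partner; more chains require an explicit split.
    """
    partner1, partner2 = list(partner1), list(partner2)
    if not partner1 and not partner2:
        chain_ids = list(structure.chains)
        if len(chain_ids) == 2:
            partner1, partner2 = [chain_ids[0]], [chain_ids[1]]
        else:
            raise ChainGroupingError(
                f"structure has {len(chain_ids)} chains; explicit partner grouping required"
            )
    if not partner1 or not partner2:
        raise ChainGroupingError("both partners must be specified (or neither)")
    return InterfacePair(frozenset(partner1), frozenset(partner2), structure)


def write_structure(structure: Structure, path) -> None:
    """Write ``structure`` as standard PDB ATOM records.

    Atom serial numbers above 99999 wrap back to 1 (the plain-PDB
    convention for oversized files); coordinates are emitted at the
    format's three-decimal precision.
    """
    if structure.n_atoms == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    lines = []
    serial = 0
    for chain_id, residues in structure.chains.items():
        for res in residues:
            resseq, icode = _split_seq_id(res.seq_id)
            for atom in res.atoms:
                serial += 1
                if serial > 99999:
                    serial = 1
                name = atom.name
                # PDB rule: 1-char element symbols start in column 14
                padded = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial:5d} {padded}{' '}{res.resname:<3s} {chain_id:1s}"
                    f"{resseq:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2s}"
                )
        lines.append(f"TER   {min(serial + 1, 99999):5d}      {residues[-1].resname:<3s} {chain_id:1s}")
        serial += 1
    lines.append("END")
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")


def _split_seq_id(seq_id: str) -> tuple[int, str]:
    digits = seq_id
    icode = " "
    if seq_id and seq_id[-1].isalpha():
        digits, icode = seq_id[:-1], seq_id[-1]
    return int(digits), icode
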