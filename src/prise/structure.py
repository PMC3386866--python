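"""Structure model: PDB reading/writing and the internal atomic model.

The internal model keeps only heavy atoms of the 20 standard amino
acids, one alternate location per atom, with NACCESS-style Van der
Waals radii assigned.  Hydrogens, waters, hetero groups and nonstandard
residues are dropped on parse; only the first MODEL of multi-model
files is read.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

from .chemistry import (STANDARD_RESIDUES, THREE_TO_ONE, element_of,
                        vdw_radius)


class ParseError(ValueError):
    """Raised when a PDB text cannot be turned into a usable model."""


@dataclass
class AtomRecord:
    """A single heavy atom with an assigned Van der Waals radius."""

    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    vdw_radius: float
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.name!r}: vdw_radius must be > 0")
        self.name = self.name.strip()
        if not self.name:
            raise ValueError("atom name empty after whitespace stripping")


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of a residue within a complex (PDB numbering)."""

    chain_id: str
    seq_number: int
    insertion_code: str = ""
    residue_name: str = ""


@dataclass
class ChainModel:
    """One protein chain: ordered residues, each a list of heavy atoms."""

    chain_id: str
    residues: list[tuple[ResidueKey, list[AtomRecord]]]
    species: str | None = None

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE[key.residue_name]
                       for key, _ in self.residues)

    def atoms(self):
        """Iterate (ResidueKey, AtomRecord) over all atoms in order."""
        for key, atoms in self.residues:
            for atom in atoms:
                yield key, atom


@dataclass
class ComplexModel:
    """A (multi-chain) protein complex."""

    structure_id: str
    chains: list[ChainModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.structure_id:
            raise ValueError("structure_id must be non-empty")
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain ids in {self.structure_id}")

    def chain(self, chain_id: str) -> ChainModel:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(
            f"chain {chain_id!r} not in {self.structure_id}; "
            f"available: {[c.chain_id for c in self.chains]}")


def _pick_altloc(atoms) -> "object":
    # highest occupancy wins; ties broken by altloc character order
    return min(atoms, key=lambda a: (-(a.get_occupancy() or 0.0),
                                     a.get_altloc()))


def parse_structure(pdb_text: str, structure_id: str) -> ComplexModel:
    """Parse PDB-format text into a :class:`ComplexModel`.

    Keeps heavy atoms of standard residues only; hydrogens/deuteriums,
    waters and HETATM groups are dropped, one altloc is kept per atom
    (highest occupancy, ties by altloc character), and only the first
    MODEL is read.

    Raises
    ------
    ParseError
        On malformed ATOM records (the message names the offending
        line) or when no usable atom survives filtering.
    """
    if "ATOM" not in pdb_text:
        raise ParseError(f"{structure_id}: no ATOM record in input")
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure(structure_id,
                                             io.StringIO(pdb_text))
    except PDBConstructionException as exc:
        raise ParseError(f"{structure_id}: malformed record ({exc})") from exc
    try:
        model = next(structure.get_models())
    except StopIteration:  # pragma: no cover - no ATOM guard above
        raise ParseError(f"{structure_id}: empty structure")

    chains: list[ChainModel] = []
    for bio_chain in model:
        residues: list[tuple[ResidueKey, list[AtomRecord]]] = []
        for res in bio_chain:
            hetflag, seqnum, icode = res.get_id()
            resname = res.get_resname().strip()
            if hetflag.strip() or resname not in STANDARD_RESIDUES:
                continue  # waters, HETATM groups, nonstandard residues
            key = ResidueKey(chain_id=bio_chain.id, seq_number=seqnum,
                             insertion_code=icode.strip(),
                             residue_name=resname)
            atoms: list[AtomRecord] = []
            # group alternate locations by atom name
            by_name: dict[str, list] = {}
            for atom in res.get_unpacked_list():
                by_name.setdefault(atom.get_name().strip(), []).append(atom)
            for name, alts in by_name.items():
                elem = (alts[0].element or "").strip().upper() or element_of(name)
                if elem in ("H", "D"):
                    continue
                chosen = _pick_altloc(alts)
                atoms.append(AtomRecord(
                    name=name,
                    element=elem,
                    coords=np.array(chosen.get_coord(), dtype=float),
                    vdw_radius=vdw_radius(name, elem),
                    occupancy=float(chosen.get_occupancy() or 1.0),
                    altloc=chosen.get_altloc().strip(),
                ))
            if atoms:
                residues.append((key, atoms))
        if residues:
            chains.append(ChainModel(chain_id=bio_chain.id, residues=residues))
    if not chains:
        raise ParseError(f"{structure_id}: no standard-residue heavy atoms")
    return ComplexModel(structure_id=structure_id, chains=chains)


def write_structure(complex_model: ComplexModel) -> str:
    """Serialize a :class:`ComplexModel` as PDB-format text.

    Round-trip property: re-parsing the output reproduces the model's
    atoms, names and chain ids, with coordinates at PDB precision
    (0.001 Å).
    """
    if not complex_model.chains:
        raise ValueError("cannot write an empty complex")
    lines: list[str] = []
    serial = 1
    for chain in complex_model.chains:
        key = None
        for key, atom in chain.atoms():
            name = atom.name
            # PDB atom-name column convention: 1-char elements start at col 14
            padded = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:>5d} {padded}{(atom.altloc or ' '):1s}"
                f"{key.residue_name:>3s} {chain.chain_id:1s}"
                f"{key.seq_number:>4d}{(key.insertion_code or ' '):1s}   "
                f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}"
                f"{atom.coords[2]:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}")
            serial += 1
        if key is not None:
            lines.append(
                f"TER   {serial:>5d}      {key.residue_name:>3s} "
                f"{chain.chain_id:1s}{key.seq_number:>4d}"
                f"{(key.insertion_code or ' '):1s}")
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_chain_metadata(tsv_text: str) -> dict[str, dict[str, tuple[str, str]]]:
    """Read a sidecar metadata table.

    Tab-separated columns: structure_id, chain_id, species, sequence.
    Returns ``{structure_id: {chain_id: (sequence, species)}}``.
    """
    table: dict[str, dict[str, tuple[str, str]]] = {}
    for lineno, line in enumerate(tsv_text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 4:
            raise ParseError(f"metadata line {lineno}: expected 4 columns, "
                             f"got {len(parts)}")
        sid, cid, species, seq = parts
        table.setdefault(sid, {})[cid] = (seq, species)
    return table


def apply_chain_metadata(complex_model: ComplexModel,
                         table: dict[str, dict[str, tuple[str, str]]]) -> None:
    """Attach species annotations from a sidecar table in place."""
    per_chain = table.get(complex_model.structure_id, {})
    for chain in complex_model.chains:
        if chain.chain_id in per_chain:
            chain.species = per_chain[chain.chain_id][1]
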