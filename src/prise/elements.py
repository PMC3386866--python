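"""Structural elements: surface decomposition and the 4-feature record.

A structural element is a surface residue (the central residue)
together with its surface neighbors.  Its representation has four
features: the central residue name, the central residue's monomer ASA,
the element's total ASA (sum over member residues), and a 36-bin
histogram counting, per atom nomenclature, the member atoms whose own
ASA is > 0 Å².  OXT atoms contribute to the ASA sums but are not part
of the nomenclature vocabulary, so they never enter the histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .chemistry import ATOM_VOCABULARY, VOCABULARY_INDEX
from .structure import ChainModel, ResidueKey
from .surface import AsaMap, InterfaceLabels

LABEL_INTERFACE = "interface"
LABEL_NON_INTERFACE = "non-interface"
LABEL_UNKNOWN = "unknown"

ASA_DECIMALS = 3  # stored ASA precision, Å²


@dataclass
class StructuralElement:
    """A surface residue plus its surface neighbors, with features."""

    central: ResidueKey
    central_asa: float
    element_asa: float
    histogram: np.ndarray  # 36 non-negative ints, vocabulary order
    members: frozenset[ResidueKey]
    structure_id: str
    chain_id: str
    label: str = LABEL_UNKNOWN

    def __post_init__(self) -> None:
        self.histogram = np.asarray(self.histogram, dtype=np.int64)
        if self.histogram.shape != (len(ATOM_VOCABULARY),):
            raise ValueError("histogram must have exactly "
                             f"{len(ATOM_VOCABULARY)} bins")
        if (self.histogram < 0).any():
            raise ValueError("histogram bins must be non-negative")
        if self.central not in self.members:
            raise ValueError("central residue must be a member")
        if self.label not in (LABEL_INTERFACE, LABEL_NON_INTERFACE,
                              LABEL_UNKNOWN):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def residue_name(self) -> str:
        return self.central.residue_name

    def __eq__(self, other) -> bool:
        if not isinstance(other, StructuralElement):
            return NotImplemented
        return (self.central == other.central
                and self.central_asa == other.central_asa
                and self.element_asa == other.element_asa
                and bool(np.array_equal(self.histogram, other.histogram))
                and self.members == other.members
                and self.structure_id == other.structure_id
                and self.chain_id == other.chain_id
                and self.label == other.label)


@dataclass
class ElementSet:
    """The structural elements of one chain, keyed by central residue."""

    structure_id: str
    chain_id: str
    elements: dict[ResidueKey, StructuralElement] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements.values())

    def __getitem__(self, key: ResidueKey) -> StructuralElement:
        return self.elements[key]


def compute_histogram(members: frozenset[ResidueKey] | set[ResidueKey],
                      chain: ChainModel, asa: AsaMap,
                      vocabulary: tuple[str, ...] = ATOM_VOCABULARY,
                      ) -> np.ndarray:
    """Histogram of atom nomenclatures over a member-residue set.

    Bin v counts the member atoms named v whose monomer ASA is > 0 Å².
    Atom names outside the vocabulary (e.g. OXT) are ignored.
    """
    index = (VOCABULARY_INDEX if vocabulary is ATOM_VOCABULARY
             else {n: i for i, n in enumerate(vocabulary)})
    hist = np.zeros(len(vocabulary), dtype=np.int64)
    for key, atoms in chain.residues:
        if key not in members:
            continue
        for atom in atoms:
            if atom.name in index and asa.atom_asa[(key, atom.name)] > 0:
                hist[index[atom.name]] += 1
    return hist


def extract_elements(chain: ChainModel, asa: AsaMap, graph: nx.Graph,
                     labels: InterfaceLabels | None = None,
                     structure_id: str = "") -> ElementSet:
    """Decompose a chain's surface into structural elements.

    One element per surface residue; the members are the residue's
    closed neighborhood in the surface-neighbor graph.  When interface
    ``labels`` are given, each element's label is copied from its
    central residue's flag.
    """
    element_set = ElementSet(structure_id=structure_id,
                             chain_id=chain.chain_id)
    for key, _ in chain.residues:
        if key not in graph:
            continue  # buried residue
        members = frozenset({key} | set(graph.neighbors(key)))
        central_asa = round(asa.residue_asa[key], ASA_DECIMALS)
        element_asa = round(
            float(sum(asa.residue_asa[m] for m in members)), ASA_DECIMALS)
        if labels is None:
            label = LABEL_UNKNOWN
        elif labels.is_interface(key):
            label = LABEL_INTERFACE
        else:
            label = LABEL_NON_INTERFACE
        element_set.elements[key] = StructuralElement(
            central=key,
            central_asa=central_asa,
            element_asa=element_asa,
            histogram=compute_histogram(members, chain, asa),
            members=members,
            structure_id=structure_id,
            chain_id=chain.chain_id,
            label=label,
        )
    return element_set


def element_to_row(element: StructuralElement) -> str:
    """One tab-separated repository row for an element."""
    key = element.central
    fields = [element.structure_id, element.chain_id,
              str(key.seq_number), key.insertion_code or ".",
              key.residue_name,
              f"{element.central_asa:.{ASA_DECIMALS}f}",
              f"{element.element_asa:.{ASA_DECIMALS}f}",
              element.label]
    fields.extend(str(int(v)) for v in element.histogram)
    return "\t".join(fields)


ROW_HEADER = ("structure_id\tchain_id\tresnum\ticode\tresname\t"
              "central_asa\telement_asa\tlabel\t"
              + "\t".join(ATOM_VOCABULARY))


def element_from_row(row: str) -> StructuralElement:
    """Parse one repository row (inverse of :func:`element_to_row`)."""
    parts = row.rstrip("\n").split("\t")
    expected = 8 + len(ATOM_VOCABULARY)
    if len(parts) != expected:
        raise ValueError(f"expected {expected} columns, got {len(parts)}")
    sid, cid, resnum, icode, resname, c_asa, e_asa, label = parts[:8]
    key = ResidueKey(chain_id=cid, seq_number=int(resnum),
                     insertion_code="" if icode == "." else icode,
                     residue_name=resname)
    return StructuralElement(
        central=key,
        central_asa=float(c_asa),
        element_asa=float(e_asa),
        histogram=np.array([int(v) for v in parts[8:]], dtype=np.int64),
        members=frozenset({key}),
        structure_id=sid,
        chain_id=cid,
        label=label,
    )
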