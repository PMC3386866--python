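"""Repository of labeled structural elements.

The repository stores every structural element extracted from the
interacting chains (≥ 5 contact residues under the 0.5 Å Van der Waals
gap rule) of a set of complexes, labeled interface / non-interface by
the same rule, grouped by central residue type, together with the
per-residue-type ASA maxima needed by the retrieval constraints and a
source table (sequence, species per chain) for homolog exclusion.

On disk a repository is a JSON header (version, maxima, source table)
plus a tab-separated entries file, both plain text.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .elements import (LABEL_UNKNOWN, ROW_HEADER, StructuralElement,
                       element_from_row, element_to_row, extract_elements)
from .surface import (DEFAULT_N_POINTS, DEFAULT_PROBE_RADIUS, RULE_VDW_05,
                      compute_asa, find_surface_neighbors, is_interacting_chain,
                      label_interface_residues)

logger = logging.getLogger("prise")

FORMAT_VERSION = 1


@dataclass
class _TypeBlock:
    """Vectorized view of all entries of one central residue type."""

    indices: np.ndarray        # positions in Repository.entries
    histograms: np.ndarray     # (m, 36) int64
    central_asa: np.ndarray    # (m,) float
    element_asa: np.ndarray    # (m,) float
    structure_ids: np.ndarray  # (m,) str
    labels: np.ndarray         # (m,) bool, True = interface


@dataclass
class Repository:
    """Labeled structural elements with retrieval-side indices."""

    entries: list[StructuralElement] = field(default_factory=list)
    #: ``{structure_id: {chain_id: (sequence, species or "")}}``
    source_table: dict[str, dict[str, tuple[str, str]]] = field(
        default_factory=dict)
    #: empirical per-residue-type maxima (overridable)
    max_residue_asa: dict[str, float] = field(default_factory=dict)
    max_element_asa: dict[str, float] = field(default_factory=dict)
    _blocks: dict[str, _TypeBlock] = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, element: StructuralElement) -> None:
        if element.label == LABEL_UNKNOWN:
            raise ValueError("repository entries must be labeled")
        self.entries.append(element)
        self._blocks.clear()

    def recompute_maxima(self) -> None:
        self.max_residue_asa = {}
        self.max_element_asa = {}
        for e in self.entries:
            t = e.residue_name
            self.max_residue_asa[t] = max(
                self.max_residue_asa.get(t, 0.0), e.central_asa)
            self.max_element_asa[t] = max(
                self.max_element_asa.get(t, 0.0), e.element_asa)

    def block(self, residue_name: str) -> _TypeBlock | None:
        """Vectorized entry block for one central residue type."""
        if not self._blocks:
            self._build_blocks()
        return self._blocks.get(residue_name)

    def _build_blocks(self) -> None:
        from .elements import LABEL_INTERFACE
        by_type: dict[str, list[int]] = {}
        for i, e in enumerate(self.entries):
            by_type.setdefault(e.residue_name, []).append(i)
        self._blocks = {}
        for t, idx in by_type.items():
            ents = [self.entries[i] for i in idx]
            self._blocks[t] = _TypeBlock(
                indices=np.asarray(idx, dtype=np.int64),
                histograms=np.stack([e.histogram for e in ents]),
                central_asa=np.asarray([e.central_asa for e in ents]),
                element_asa=np.asarray([e.element_asa for e in ents]),
                structure_ids=np.asarray([e.structure_id for e in ents]),
                labels=np.asarray(
                    [e.label == LABEL_INTERFACE for e in ents], dtype=bool),
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Repository):
            return NotImplemented
        return (self.entries == other.entries
                and self.source_table == other.source_table
                and self.max_residue_asa == other.max_residue_asa
                and self.max_element_asa == other.max_element_asa)


def build_repository(complexes, probe_radius: float = DEFAULT_PROBE_RADIUS,
                     n_points: int = DEFAULT_N_POINTS) -> Repository:
    """Build a repository from a collection of complexes.

    Only interacting chains contribute elements; labels come from the
    0.5 Å gap rule.  Complexes without any interacting chain are
    skipped with a warning.
    """
    repo = Repository()
    for complex_model in complexes:
        if len(complex_model.chains) < 2:
            raise ValueError(
                f"{complex_model.structure_id}: repository complexes need "
                ">= 2 chains")
        labels = label_interface_residues(complex_model, RULE_VDW_05)
        kept_any = False
        for chain in complex_model.chains:
            if not is_interacting_chain(chain, labels):
                continue
            kept_any = True
            asa = compute_asa(chain, probe_radius, n_points)
            graph = find_surface_neighbors(chain, asa)
            element_set = extract_elements(
                chain, asa, graph, labels=labels,
                structure_id=complex_model.structure_id)
            for element in element_set:
                # member sets are a query-side concept; entries keep
                # only the persisted features
                element.members = frozenset({element.central})
                repo.add(element)
            repo.source_table.setdefault(
                complex_model.structure_id, {})[chain.chain_id] = (
                    chain.sequence, chain.species or "")
        if not kept_any:
            logger.warning("%s: no interacting chain; complex skipped",
                           complex_model.structure_id)
    repo.recompute_maxima()
    return repo


def save_repository(repo: Repository, path: str | Path) -> None:
    """Write ``repo.json`` + ``repo.tsv`` under directory ``path``."""
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    header = {
        "format_version": FORMAT_VERSION,
        "n_entries": len(repo.entries),
        "max_residue_asa": repo.max_residue_asa,
        "max_element_asa": repo.max_element_asa,
        "source_table": {
            sid: {cid: list(v) for cid, v in chains.items()}
            for sid, chains in repo.source_table.items()},
    }
    (directory / "repo.json").write_text(
        json.dumps(header, indent=1, sort_keys=True) + "\n")
    with open(directory / "repo.tsv", "w") as fh:
        fh.write(ROW_HEADER + "\n")
        for element in repo.entries:
            fh.write(element_to_row(element) + "\n")


def load_repository(path: str | Path) -> Repository:
    """Load a repository saved by :func:`save_repository`."""
    directory = Path(path)
    try:
        header = json.loads((directory / "repo.json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"corrupt or missing repository header: {exc}")
    version = header.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported repository format version {version!r}")
    repo = Repository(
        max_residue_asa=dict(header["max_residue_asa"]),
        max_element_asa=dict(header["max_element_asa"]),
        source_table={
            sid: {cid: (v[0], v[1]) for cid, v in chains.items()}
            for sid, chains in header["source_table"].items()},
    )
    lines = (directory / "repo.tsv").read_text().splitlines()
    if not lines or lines[0] != ROW_HEADER:
        raise ValueError("repository entries file has a bad header row")
    for rowno, line in enumerate(lines[1:], start=2):
        try:
            repo.entries.append(element_from_row(line))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"repo.tsv row {rowno}: {exc}")
    if len(repo.entries) != header.get("n_entries"):
        raise ValueError(
            f"repo.tsv has {len(repo.entries)} entries, header says "
            f"{header.get('n_entries')}")
    return repo
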