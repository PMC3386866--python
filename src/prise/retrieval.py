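"""Constrained similarity retrieval of structural elements.

For a query element q, candidate repository entries must (i) come from
a different complex, (ii) share q's central residue type, (iii) differ
in central-residue ASA by at most 5% of the repository maximum for
that residue type, and (iv) differ in element ASA by at most 15% of
the repository's element-ASA maximum for that type.  Among candidates,
similarity is the city-block distance between the 36-bin histograms of
atom nomenclatures; ties are broken by the smaller central-ASA
difference, then by repository insertion order (stable).

A homolog-exclusion policy optionally removes every entry from
structures containing a chain with high sequence identity to the query
(optionally restricted to the same species), to prevent evaluation
leakage from near-duplicates of the query protein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .elements import StructuralElement
from .repository import Repository

CENTRAL_ASA_FRACTION = 0.05  # constraint (iii)
ELEMENT_ASA_FRACTION = 0.15  # constraint (iv)

MODE_SAME_STRUCTURE = "same_structure_only"
MODE_HOMOLOG_SAME_SPECIES = "homolog_same_species"
MODE_HOMOLOG_ANY_SPECIES = "homolog_any_species"
_MODES = (MODE_SAME_STRUCTURE, MODE_HOMOLOG_SAME_SPECIES,
          MODE_HOMOLOG_ANY_SPECIES)


@dataclass(frozen=True)
class ExclusionPolicy:
    """Homolog-exclusion policy applied at query time.

    Excluding the query's own structure (constraint i) always applies,
    whatever the mode.
    """

    mode: str = MODE_SAME_STRUCTURE
    identity_threshold: float = 95.0  # percent

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown policy mode {self.mode!r}")


@dataclass
class RetrievalResult:
    """Ranked samples for one query element."""

    query: StructuralElement
    #: list of (entry, city-block distance, |central ASA difference|)
    samples: list[tuple[StructuralElement, int, float]]
    k_requested: int

    @property
    def k_returned(self) -> int:
        return len(self.samples)


# global alignment, match=1 / mismatch=0 / small negative gap costs;
# parameters are fixed (see the methods note)
_aligner = Align.PairwiseAligner(mode="global", match_score=1.0,
                                 mismatch_score=0.0, open_gap_score=-0.5,
                                 extend_gap_score=-0.1)


def histogram_distance(x, y) -> int:
    """City-block distance between two 36-bin histograms."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape != y.shape:
        raise ValueError(f"histogram shapes differ: {x.shape} vs {y.shape}")
    return int(np.abs(x - y).sum())


def sequence_identity(a: str, b: str) -> float:
    """Percent sequence identity under a fixed global alignment.

    Identities of the optimal alignment divided by the shorter
    sequence's length.  The pair is ordered canonically before
    aligning, so the function is exactly symmetric.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    first, second = sorted((a, b))
    alignment = _aligner.align(first, second)[0]
    identities = alignment.counts().identities
    return 100.0 * identities / min(len(a), len(b))


def passes_constraints(q: StructuralElement, entry: StructuralElement,
                       repo: Repository) -> bool:
    """Check retrieval constraints (i)–(iv) for one candidate entry."""
    if entry.structure_id == q.structure_id:
        return False
    if entry.residue_name != q.residue_name:
        return False
    max_res = repo.max_residue_asa.get(q.residue_name)
    max_elem = repo.max_element_asa.get(q.residue_name)
    if max_res is None or max_elem is None:
        return False
    if abs(entry.central_asa - q.central_asa) > CENTRAL_ASA_FRACTION * max_res:
        return False
    if abs(entry.element_asa - q.element_asa) > ELEMENT_ASA_FRACTION * max_elem:
        return False
    return True


def excluded_structure_ids(repo: Repository, policy: ExclusionPolicy,
                           query_chains: list[tuple[str, str | None]] | None,
                           ) -> frozenset[str]:
    """Structure ids removed from consideration by the homolog policy.

    ``query_chains`` is a list of (sequence, species) pairs describing
    the query protein; it is required for the homolog modes.  A source
    structure is excluded when any of its chains reaches the identity
    threshold against any query chain (and, for the same-species mode,
    shares a known species annotation).
    """
    if policy.mode == MODE_SAME_STRUCTURE:
        return frozenset()
    if not query_chains:
        raise ValueError(
            f"policy {policy.mode!r} needs query chain sequences")
    excluded: set[str] = set()
    for sid, chains in repo.source_table.items():
        for seq, species in chains.values():
            if not seq:
                continue
            for q_seq, q_species in query_chains:
                if not q_seq:
                    continue
                if policy.mode == MODE_HOMOLOG_SAME_SPECIES:
                    if not species or not q_species or species != q_species:
                        continue
                if sequence_identity(seq, q_seq) >= policy.identity_threshold:
                    excluded.add(sid)
                    break
            if sid in excluded:
                break
    return frozenset(excluded)


def retrieve_similar(repo: Repository, q: StructuralElement, k: int,
                     policy: ExclusionPolicy = ExclusionPolicy(),
                     query_chains: list[tuple[str, str | None]] | None = None,
                     excluded: frozenset[str] | None = None,
                     ) -> RetrievalResult:
    """The k most similar repository entries satisfying all constraints.

    ``excluded`` may carry a precomputed result of
    :func:`excluded_structure_ids` (per query protein) to avoid
    re-aligning sequences for every query element.  Returns fewer than
    k samples when fewer candidates pass; zero candidates yield an
    empty result (flagged downstream).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if excluded is None:
        excluded = excluded_structure_ids(repo, policy, query_chains)
    block = repo.block(q.residue_name)
    if block is None:
        return RetrievalResult(query=q, samples=[], k_requested=k)
    max_res = repo.max_residue_asa[q.residue_name]
    max_elem = repo.max_element_asa[q.residue_name]
    delta_central = np.abs(block.central_asa - q.central_asa)
    mask = (block.structure_ids != q.structure_id)
    mask &= delta_central <= CENTRAL_ASA_FRACTION * max_res
    mask &= (np.abs(block.element_asa - q.element_asa)
             <= ELEMENT_ASA_FRACTION * max_elem)
    if excluded:
        mask &= ~np.isin(block.structure_ids, list(excluded))
    if not mask.any():
        return RetrievalResult(query=q, samples=[], k_requested=k)
    cand = np.flatnonzero(mask)
    dist = np.abs(block.histograms[cand]
                  - q.histogram[np.newaxis, :]).sum(axis=1)
    delta = delta_central[cand]
    order = np.lexsort((block.indices[cand], delta, dist))[:k]
    samples = [(repo.entries[int(block.indices[cand[i]])],
                int(dist[i]), float(delta[i])) for i in order]
    return RetrievalResult(query=q, samples=samples, k_requested=k)
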