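"""Synthetic test inputs: toy complexes and element populations.

Two generators cover the two kinds of input the predictor consumes.

``generate_toy_complex`` emits a small two-chain complex as a valid
PDB model: each chain is a run of idealized heavy-atom residue
templates laid along a gentle helical curve, and a designated patch of
the second chain is lowered onto the first until each patch residue
sits at a prescribed Van der Waals surface gap from its partner.  The
templates use standard-geometry bond lengths but make no claim of
stereochemical realism; the fidelity target is "valid and
self-consistent", so that the full ingestion path (parse → ASA →
elements → repository) runs without special-casing.

``generate_element_population`` emits a statistical stand-in for a
large element repository: per-bin histogram counts are independent
Poisson draws, the interface class receives an additive rate shift on
a designated bin subset (the local signal), entries are spread over a
set of source structures of which a configurable fraction are
label-pure (the global signal), and ASA features are drawn from ranges
wide enough that the retrieval constraints admit matches.  A held-out
query element set with recorded true labels is drawn from the same
mixture.

All outputs are deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemistry import RESIDUE_ATOMS
from .elements import (LABEL_INTERFACE, LABEL_NON_INTERFACE, LABEL_UNKNOWN,
                       ElementSet, StructuralElement)
from .repository import Repository
from .structure import AtomRecord, ChainModel, ComplexModel, ResidueKey
from .structure import write_structure
from .chemistry import element_of, vdw_radius

_RESIDUE_TYPES = tuple(sorted(RESIDUE_ATOMS))

# chain layout parameters (Å): residue spacing along x, helix radius,
# helix angular step
_SPACING = 5.1
_HELIX_RADIUS = 2.0
_HELIX_STEP = 0.5


@dataclass(frozen=True)
class ToyComplexSpec:
    """Recipe for a deterministic two-chain toy complex.

    ``inter_chain_gap`` is the Van der Waals surface gap (Å) at which
    each designated patch residue of chain B is planted against its
    partner in chain A; at ≤ 0.5 Å the patch satisfies the repository
    contact rule.
    """

    seed: int
    residues_per_chain: int = 12
    inter_chain_gap: float = 0.35
    contact_patch_size: int = 6
    residue_composition: tuple[float, ...] | None = None  # over 20 types

    def __post_init__(self) -> None:
        if self.contact_patch_size > self.residues_per_chain:
            raise ValueError("contact patch larger than the chain")


def _residue_template(resname: str) -> list[tuple[str, np.ndarray]]:
    """Idealized heavy-atom coordinates for one residue, CA at origin."""
    backbone = {
        "N": np.array([-1.46, 0.00, 0.00]),
        "CA": np.array([0.00, 0.00, 0.00]),
        "C": np.array([1.52, 0.00, 0.00]),
        "O": np.array([2.13, 1.06, 0.00]),
    }
    atoms = []
    side_index = 0
    for name in RESIDUE_ATOMS[resname]:
        if name in backbone:
            atoms.append((name, backbone[name]))
        else:
            # zigzag growth away from the backbone, ~1.4 Å per step
            j = side_index
            pos = np.array([0.25 * (-1.0) ** j, -1.50 - 1.25 * j,
                            0.45 * (j % 2)])
            atoms.append((name, pos))
            side_index += 1
    return atoms


def _build_chain(chain_id: str, composition: list[str],
                 offset: np.ndarray) -> ChainModel:
    residues = []
    for i, resname in enumerate(composition):
        origin = offset + np.array([
            _SPACING * i,
            _HELIX_RADIUS * np.cos(_HELIX_STEP * i),
            _HELIX_RADIUS * np.sin(_HELIX_STEP * i)])
        key = ResidueKey(chain_id=chain_id, seq_number=i + 1,
                         residue_name=resname)
        atoms = [AtomRecord(name=name, element=element_of(name),
                            coords=origin + xyz,
                            vdw_radius=vdw_radius(name))
                 for name, xyz in _residue_template(resname)]
        residues.append((key, atoms))
    return ChainModel(chain_id=chain_id, residues=residues)


def _min_gap(atoms_a, coords_b, radii_b) -> float:
    best = np.inf
    for atom in atoms_a:
        d = np.linalg.norm(coords_b - atom.coords, axis=1)
        gap = d - radii_b - atom.vdw_radius
        best = min(best, float(gap.min()))
    return best


def _patch_indices(n: int, patch: int) -> list[int]:
    if patch == 0:
        return []
    stride = max(1, n // patch)
    idx = [min(j * stride, n - 1) for j in range(patch)]
    return sorted(set(idx)) if len(set(idx)) == patch else list(range(patch))


def generate_toy_complex(spec: ToyComplexSpec,
                         ) -> tuple[ComplexModel, str, dict[ResidueKey, bool]]:
    """Build a toy two-chain complex.

    Returns ``(complex, pdb_text, truth)`` where ``truth`` flags the
    planted contact residues of both chains (partners at the planted
    gap), i.e. the residues the 0.5 Å rule should recover when
    ``inter_chain_gap`` ≤ 0.5.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.residue_composition
    # sample without replacement where possible: duplicate residue
    # types in one chain can yield byte-identical elements (degenerate
    # retrieval ties), which no real chain fixture should exhibit
    replace = spec.residues_per_chain > len(_RESIDUE_TYPES)
    comp_a = [str(r) for r in rng.choice(
        _RESIDUE_TYPES, spec.residues_per_chain, replace=replace, p=p)]
    comp_b = [str(r) for r in rng.choice(
        _RESIDUE_TYPES, spec.residues_per_chain, replace=replace, p=p)]
    chain_a = _build_chain("A", comp_a, np.zeros(3))
    far_offset = np.array([0.0, 25.0, 0.0])
    chain_b = _build_chain("B", comp_b, far_offset)

    coords_a = np.array([a.coords for _, atoms in chain_a.residues
                         for a in atoms])
    radii_a = np.array([a.vdw_radius for _, atoms in chain_a.residues
                        for a in atoms])

    truth: dict[ResidueKey, bool] = {
        key: False for c in (chain_a, chain_b) for key, _ in c.residues}
    patch = _patch_indices(spec.residues_per_chain, spec.contact_patch_size)
    for i in patch:
        key_b, atoms_b = chain_b.residues[i]
        # bisect the vertical drop until the minimum gap to chain A
        # equals the planted gap
        def gap_at(drop: float) -> float:
            shifted = [AtomRecord(name=a.name, element=a.element,
                                  coords=a.coords - np.array([0, drop, 0]),
                                  vdw_radius=a.vdw_radius)
                       for a in atoms_b]
            return _min_gap(shifted, coords_a, radii_a)

        lo, hi = 0.0, 25.0  # gap_at(lo) is large, gap_at(hi) is negative
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if gap_at(mid) > spec.inter_chain_gap:
                lo = mid
            else:
                hi = mid
        drop = 0.5 * (lo + hi)
        for a in atoms_b:
            a.coords = a.coords - np.array([0.0, drop, 0.0])
        if spec.inter_chain_gap <= 0.5:
            truth[key_b] = True
    # chain-A truth: every residue the planted patch actually reaches
    # (a planted residue may straddle two partners)
    if spec.inter_chain_gap <= 0.5:
        for key_a, atoms_a2 in chain_a.residues:
            for i in patch:
                _, atoms_b = chain_b.residues[i]
                g = _min_gap(atoms_a2,
                             np.array([a.coords for a in atoms_b]),
                             np.array([a.vdw_radius for a in atoms_b]))
                if g <= 0.5:
                    truth[key_a] = True
                    break

    complex_model = ComplexModel(structure_id=f"TOY{spec.seed:04d}",
                                 chains=[chain_a, chain_b])
    return complex_model, write_structure(complex_model), truth


@dataclass(frozen=True)
class ElementPopulationSpec:
    """Recipe for a synthetic population of structural-element records.

    Local signal: interface-class histograms receive an additive
    Poisson-rate shift (``effect_shift``) on ``shift_bins``.

    Global signal: entries live either in a few *reliable* source
    structures (many entries each, labels faithful to the histogram
    class, a ``global_signal`` fraction of them label-pure) or — with
    probability ``decoy_fraction`` — in a sea of small *decoy*
    structures whose entry labels are random coin flips.  Decoys
    pollute purely local voting; because each decoy structure
    contributes few retrievals protein-wide, provenance-aggregating
    weights can discount them, which is what the general and combined
    schemes exploit.

    ASA features are drawn from deliberately narrow ranges so the
    retrieval ASA constraints admit many same-type candidates, and
    entries are spread over ``n_residue_types`` central residue types
    so each type's candidate pool is large enough for similarity
    ranking to be selective at the retrieval depths used in tests.
    """

    seed: int
    n_interface: int = 2000
    n_noninterface: int = 2000
    bin_rates: tuple[float, ...] = tuple([1.0] * 36)
    effect_shift: float = 3.0
    shift_bins: tuple[int, ...] = (0, 1, 2, 3, 4)
    asa_central_range: tuple[float, float] = (100.0, 120.0)
    asa_element_extra: tuple[float, float] = (300.0, 340.0)
    n_structures: int = 20          # reliable structures
    global_signal: float = 0.0      # fraction of label-pure reliable ones
    n_residue_types: int = 4
    decoy_structures: int = 0
    decoy_fraction: float = 0.0     # entries landing in decoy structures
    n_queries: int = 200

    def __post_init__(self) -> None:
        if self.n_interface < 1 or self.n_noninterface < 1:
            raise ValueError("class counts must be >= 1")
        if len(self.bin_rates) != 36:
            raise ValueError("bin_rates must have 36 entries")
        if not 0.0 <= self.global_signal <= 1.0:
            raise ValueError("global_signal must be in [0, 1]")
        if not 0.0 <= self.decoy_fraction <= 1.0:
            raise ValueError("decoy_fraction must be in [0, 1]")
        if self.decoy_fraction > 0 and self.decoy_structures < 1:
            raise ValueError("decoy_fraction > 0 needs decoy_structures >= 1")
        if not 1 <= self.n_residue_types <= 20:
            raise ValueError("n_residue_types must be in 1..20")


def _draw_histogram(rng, rates: np.ndarray, interface: bool,
                    spec: ElementPopulationSpec) -> np.ndarray:
    lam = rates.copy()
    if interface:
        lam[list(spec.shift_bins)] += spec.effect_shift
    return rng.poisson(lam).astype(np.int64)


def generate_element_population(spec: ElementPopulationSpec,
                                ) -> tuple[Repository, ElementSet,
                                           dict[ResidueKey, bool]]:
    """Draw a labeled repository plus a held-out query element set.

    Returns ``(repository, queries, truth)``; ``truth`` maps each query
    residue key to its true (hidden) interface label.  Query elements
    carry an ``unknown`` label and singleton member sets, and all share
    the structure id ``QUERY`` (one query protein).
    """
    rng = np.random.default_rng(spec.seed)
    rates = np.asarray(spec.bin_rates, dtype=float)
    types = _RESIDUE_TYPES[:spec.n_residue_types]

    n_pure = int(round(spec.global_signal * spec.n_structures))
    pure_pos = [f"SYN{i:04d}" for i in range(0, n_pure // 2)]
    pure_neg = [f"SYN{i:04d}" for i in range(n_pure // 2, n_pure)]
    mixed = [f"SYN{i:04d}" for i in range(n_pure, spec.n_structures)]
    decoys = [f"DEC{i:04d}" for i in range(spec.decoy_structures)]
    pos_pool = (pure_pos + mixed) or pure_pos
    neg_pool = (pure_neg + mixed) or pure_neg

    def draw_features(is_interface: bool):
        resname = str(types[int(rng.integers(len(types)))])
        central = round(float(rng.uniform(*spec.asa_central_range)), 3)
        element = round(
            central + float(rng.uniform(*spec.asa_element_extra)), 3)
        hist = _draw_histogram(rng, rates, is_interface, spec)
        return resname, central, element, hist

    repo = Repository()
    order = ([True] * spec.n_interface + [False] * spec.n_noninterface)
    for idx, hist_class in enumerate(order):
        resname, central, element, hist = draw_features(hist_class)
        if spec.decoy_fraction and rng.random() < spec.decoy_fraction:
            sid = str(decoys[int(rng.integers(len(decoys)))])
            label_interface = bool(rng.random() < 0.5)  # uninformative
        else:
            pool = pos_pool if hist_class else neg_pool
            sid = str(pool[int(rng.integers(len(pool)))])
            label_interface = hist_class
        key = ResidueKey(chain_id="A", seq_number=idx + 1,
                         residue_name=resname)
        repo.add(StructuralElement(
            central=key, central_asa=central, element_asa=element,
            histogram=hist, members=frozenset({key}), structure_id=sid,
            chain_id="A",
            label=(LABEL_INTERFACE if label_interface
                   else LABEL_NON_INTERFACE)))
    for sid in pure_pos + pure_neg + mixed + decoys:
        repo.source_table.setdefault(sid, {})["A"] = ("", "")
    repo.recompute_maxima()

    queries = ElementSet(structure_id="QUERY", chain_id="Q")
    truth: dict[ResidueKey, bool] = {}
    n_pos_queries = spec.n_queries // 2
    for idx in range(spec.n_queries):
        is_interface = idx < n_pos_queries
        resname, central, element, hist = draw_features(is_interface)
        key = ResidueKey(chain_id="Q", seq_number=idx + 1,
                         residue_name=resname)
        queries.elements[key] = StructuralElement(
            central=key, central_asa=central, element_asa=element,
            histogram=hist, members=frozenset({key}), structure_id="QUERY",
            chain_id="Q", label=LABEL_UNKNOWN)
        truth[key] = is_interface
    return repo, queries, truth


def null_scenario(seed: int) -> ElementPopulationSpec:
    """No planted signal: local prediction should be at chance."""
    return ElementPopulationSpec(seed=seed, effect_shift=0.0, n_queries=1000)


def strong_local_scenario(seed: int) -> ElementPopulationSpec:
    """Strong local signal: +3 on 5 bins over a base rate of 1."""
    return ElementPopulationSpec(seed=seed, effect_shift=3.0)


def mixed_scenario(seed: int) -> ElementPopulationSpec:
    """Moderate local signal plus a global trustworthiness signal.

    70% of entries sit in 150 small decoy structures with coin-flip
    labels; the rest sit in 10 reliable structures, half label-pure.
    Local voting is polluted by the decoys while provenance
    aggregation can discount them, so the general and combined schemes
    outperform the purely local one.
    """
    return ElementPopulationSpec(seed=seed, effect_shift=1.5,
                                 global_signal=0.5, n_structures=10,
                                 decoy_structures=150, decoy_fraction=0.7,
                                 n_queries=400)


#: retrieval depth used by the population scenarios (scaled to the
#: candidate pools these repository sizes support)
SCENARIO_K = 30
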