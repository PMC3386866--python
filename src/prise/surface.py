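"""Surface geometry: accessible surface areas, neighbor graph, contacts.

ASA is computed with the Shrake–Rupley method: each atom is wrapped in
a deterministic golden-spiral point set on the solvent-expanded sphere
(radius r + probe) and the fraction of points not buried inside any
neighboring expanded sphere gives the exposed area.  Each chain is
always treated in isolation (monomer ASA), so the presence of partner
chains never changes a chain's surface definition.

Inter-residue proximity uses the Van der Waals surface gap
``|a − b| − r_a − r_b``; residue pairs with a minimum heavy-atom gap of
at most 1.5 Å are surface neighbors, and inter-chain gaps of at most
0.5 Å define contact (interface) residues for repository labeling.
Evaluation datasets may instead use a 3.0 Å gap rule or a plain 5.0 Å
center-distance rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure import AtomRecord, ChainModel, ComplexModel, ResidueKey

DEFAULT_PROBE_RADIUS = 1.4  # Å, water probe
DEFAULT_N_POINTS = 960      # sphere sample points per atom
NEIGHBOR_GAP_CUTOFF = 1.5   # Å, surface-neighbor rule
CONTACT_GAP_CUTOFF = 0.5    # Å, repository contact rule
MIN_CONTACTS_INTERACTING = 5


@dataclass(frozen=True)
class ContactRule:
    """Inter-chain contact criterion.

    ``kind`` is ``"vdw_gap"`` (threshold on the Van der Waals surface
    gap) or ``"atom_dist"`` (threshold on atom center distance).
    """

    kind: str
    threshold: float

    def __post_init__(self) -> None:
        if self.kind not in ("vdw_gap", "atom_dist"):
            raise ValueError(f"unknown contact rule kind {self.kind!r}")

    @property
    def name(self) -> str:
        return f"{self.kind}_{self.threshold:g}"


#: Contact rule used to label repository elements.
RULE_VDW_05 = ContactRule("vdw_gap", 0.5)
#: Looser gap rule used by some evaluation datasets.
RULE_VDW_30 = ContactRule("vdw_gap", 3.0)
#: Plain heavy-atom distance rule used by docking-benchmark datasets.
RULE_DIST_50 = ContactRule("atom_dist", 5.0)

CONTACT_RULES = {"vdw0.5": RULE_VDW_05, "vdw3": RULE_VDW_30,
                 "dist5": RULE_DIST_50}


@dataclass
class AsaMap:
    """Monomer accessible surface areas of one chain.

    ``atom_asa`` is keyed by ``(ResidueKey, atom name)``; ``residue_asa``
    is the sum over each residue's atoms (exact by construction).
    """

    atom_asa: dict[tuple[ResidueKey, str], float]
    residue_asa: dict[ResidueKey, float]
    probe_radius: float = DEFAULT_PROBE_RADIUS
    n_points: int = DEFAULT_N_POINTS


@dataclass
class InterfaceLabels:
    """Per-residue interface flags of a complex under one contact rule."""

    flags: dict[ResidueKey, bool]
    rule: ContactRule

    def is_interface(self, key: ResidueKey) -> bool:
        return self.flags.get(key, False)


@lru_cache(maxsize=8)
def _unit_sphere(n_points: int) -> np.ndarray:
    """Deterministic golden-spiral point set on the unit sphere."""
    i = np.arange(n_points)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack((rho * np.cos(phi), rho * np.sin(phi), z))
    pts.setflags(write=False)
    return pts


def _flatten(chain: ChainModel):
    keys, names, coords, radii = [], [], [], []
    for key, atom in chain.atoms():
        keys.append(key)
        names.append(atom.name)
        coords.append(atom.coords)
        radii.append(atom.vdw_radius)
    return keys, names, np.asarray(coords, float), np.asarray(radii, float)


def compute_asa(chain: ChainModel,
                probe_radius: float = DEFAULT_PROBE_RADIUS,
                n_points: int = DEFAULT_N_POINTS) -> AsaMap:
    """Shrake–Rupley ASA of one chain in isolation (monomer context)."""
    if not chain.residues:
        raise ValueError("chain has no residues")
    if probe_radius <= 0 or n_points < 1:
        raise ValueError("probe_radius must be > 0 and n_points >= 1")
    keys, names, coords, radii = _flatten(chain)
    n = len(keys)
    if len({(k, nm) for k, nm in zip(keys, names)}) != n:
        raise ValueError("duplicate atom name within a residue")
    ext = radii + probe_radius
    sphere = _unit_sphere(n_points)
    tree = cKDTree(coords)
    max_ext = float(ext.max())

    atom_asa: dict[tuple[ResidueKey, str], float] = {}
    residue_asa: dict[ResidueKey, float] = {}
    for i in range(n):
        pts = coords[i] + ext[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i],
                                                      ext[i] + max_ext)
                     if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 >= ext[j] ** 2
            if not exposed.any():
                break
        area = exposed.sum() / n_points * 4.0 * np.pi * ext[i] ** 2
        atom_asa[(keys[i], names[i])] = float(area)
    for key, atoms in chain.residues:
        residue_asa[key] = float(sum(atom_asa[(key, a.name)] for a in atoms))
    return AsaMap(atom_asa=atom_asa, residue_asa=residue_asa,
                  probe_radius=probe_radius, n_points=n_points)


def vdw_gap(a: AtomRecord, b: AtomRecord) -> float:
    """Gap between two Van der Waals surfaces (may be negative)."""
    d = float(np.linalg.norm(a.coords - b.coords))
    return d - (a.vdw_radius + b.vdw_radius)


def find_surface_neighbors(chain: ChainModel, asa: AsaMap,
                           cutoff: float = NEIGHBOR_GAP_CUTOFF) -> nx.Graph:
    """Neighbor graph over the chain's surface residues.

    Nodes are residues with monomer ASA > 0; an edge joins two residues
    when some heavy-atom pair has a Van der Waals surface gap ≤ cutoff
    (inclusive).  A KD-tree prunes candidate pairs; the result equals
    the all-pairs scan exactly.
    """
    graph = nx.Graph()
    surface = {key for key, _ in chain.residues if asa.residue_asa[key] > 0}
    graph.add_nodes_from(
        key for key, _ in chain.residues if key in surface)
    keys, _, coords, radii = _flatten(chain)
    idx = [i for i, k in enumerate(keys) if k in surface]
    if not idx:
        return graph
    sub_coords = coords[idx]
    sub_radii = radii[idx]
    sub_keys = [keys[i] for i in idx]
    tree = cKDTree(sub_coords)
    reach = cutoff + 2.0 * float(sub_radii.max())
    for i, j in tree.query_pairs(reach):
        if sub_keys[i] == sub_keys[j]:
            continue
        gap = (float(np.linalg.norm(sub_coords[i] - sub_coords[j]))
               - sub_radii[i] - sub_radii[j])
        if gap <= cutoff:
            graph.add_edge(sub_keys[i], sub_keys[j])
    return graph


def label_interface_residues(complex_model: ComplexModel,
                             rule: ContactRule = RULE_VDW_05,
                             ) -> InterfaceLabels:
    """Flag residues in contact with another chain under ``rule``."""
    if len(complex_model.chains) < 2:
        raise ValueError(
            f"{complex_model.structure_id}: interface labels require >= 2 "
            "chains")
    flat = {c.chain_id: _flatten(c) for c in complex_model.chains}
    flags: dict[ResidueKey, bool] = {
        key: False for c in complex_model.chains for key, _ in c.residues}
    chains = complex_model.chains
    for a_i in range(len(chains)):
        for b_i in range(a_i + 1, len(chains)):
            keys_a, _, xyz_a, r_a = flat[chains[a_i].chain_id]
            keys_b, _, xyz_b, r_b = flat[chains[b_i].chain_id]
            tree_b = cKDTree(xyz_b)
            if rule.kind == "vdw_gap":
                reach = rule.threshold + float(r_a.max()) + float(r_b.max())
            else:
                reach = rule.threshold
            for i, hits in enumerate(tree_b.query_ball_point(xyz_a, reach)):
                for j in hits:
                    d = float(np.linalg.norm(xyz_a[i] - xyz_b[j]))
                    if rule.kind == "vdw_gap":
                        ok = d - r_a[i] - r_b[j] <= rule.threshold
                    else:
                        ok = d <= rule.threshold
                    if ok:
                        flags[keys_a[i]] = True
                        flags[keys_b[j]] = True
    return InterfaceLabels(flags=flags, rule=rule)


def is_interacting_chain(chain: ChainModel, labels: InterfaceLabels) -> bool:
    """True iff the chain has at least five contact residues.

    ``labels`` must have been computed with the 0.5 Å gap rule — the
    repository's own contact definition.
    """
    count = sum(1 for key, _ in chain.residues if labels.is_interface(key))
    return count >= MIN_CONTACTS_INTERACTING


def write_residue_asa(chain: ChainModel, asa: AsaMap) -> str:
    """Per-residue ASA dump (tab-separated text)."""
    lines = ["chain\tresnum\ticode\tresname\tresidue_asa"]
    for key, _ in chain.residues:
        lines.append(f"{key.chain_id}\t{key.seq_number}\t"
                     f"{key.insertion_code or '.'}\t{key.residue_name}\t"
                     f"{asa.residue_asa[key]:.3f}")
    return "\n".join(lines) + "\n"
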