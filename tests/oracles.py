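"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — plain Python loops and direct
transcriptions of the definitions — and shares no code path with the
package's accelerated implementations.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter


# ---------------------------------------------------------------- geometry

def all_pairs_gap(atoms_a, atoms_b):
    """Minimum Van der Waals surface gap over two atom lists."""
    best = math.inf
    for a in atoms_a:
        for b in atoms_b:
            d = math.dist(tuple(a.coords), tuple(b.coords))
            best = min(best, d - a.vdw_radius - b.vdw_radius)
    return best


def brute_force_neighbor_edges(chain, asa, cutoff=1.5):
    """All surface-residue pairs with min heavy-atom gap <= cutoff."""
    surface = [(key, atoms) for key, atoms in chain.residues
               if asa.residue_asa[key] > 0]
    edges = set()
    for (ka, aa), (kb, ab) in itertools.combinations(surface, 2):
        if all_pairs_gap(aa, ab) <= cutoff:
            edges.add(frozenset((ka, kb)))
    return edges


def brute_force_interface_flags(complex_model, rule):
    """Per-residue contact flags from an all-pairs inter-chain scan."""
    flags = {key: False for c in complex_model.chains
             for key, _ in c.residues}
    for ca, cb in itertools.combinations(complex_model.chains, 2):
        for ka, aa in ca.residues:
            for kb, ab in cb.residues:
                for a in aa:
                    for b in ab:
                        d = math.dist(tuple(a.coords), tuple(b.coords))
                        if rule.kind == "vdw_gap":
                            hit = d - a.vdw_radius - b.vdw_radius <= rule.threshold
                        else:
                            hit = d <= rule.threshold
                        if hit:
                            flags[ka] = True
                            flags[kb] = True
    return flags


def point_count_asa(atoms, index, probe=1.4, n_points=3840):
    """Direct Shrake-Rupley point count for one atom, no spatial index."""
    golden = math.pi * (3.0 - math.sqrt(5.0))
    target = atoms[index]
    big_r = target.vdw_radius + probe
    exposed = 0
    for i in range(n_points):
        z = 1.0 - 2.0 * (i + 0.5) / n_points
        rho = math.sqrt(max(0.0, 1.0 - z * z))
        phi = golden * i
        p = (target.coords[0] + big_r * rho * math.cos(phi),
             target.coords[1] + big_r * rho * math.sin(phi),
             target.coords[2] + big_r * z)
        buried = False
        for j, other in enumerate(atoms):
            if j == index:
                continue
            if math.dist(p, tuple(other.coords)) < other.vdw_radius + probe:
                buried = True
                break
        if not buried:
            exposed += 1
    return exposed / n_points * 4.0 * math.pi * big_r ** 2


# --------------------------------------------------------------- alignment

def gotoh_global_score(a, b, match=1.0, mismatch=0.0, gap_open=-0.5,
                       gap_extend=-0.1):
    """Optimal global alignment score with affine gaps (end gaps scored)."""
    n, m = len(a), len(b)
    neg = -math.inf
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (up moves)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (left moves)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


# --------------------------------------------------------------- retrieval

def brute_force_retrieve(repo, q, k, excluded=frozenset()):
    """Filter-then-sort retrieval: constraints (i)-(iv), policy, ranking."""
    candidates = []
    for idx, entry in enumerate(repo.entries):
        if entry.structure_id == q.structure_id:
            continue
        if entry.structure_id in excluded:
            continue
        if entry.residue_name != q.residue_name:
            continue
        max_res = repo.max_residue_asa.get(q.residue_name)
        max_elem = repo.max_element_asa.get(q.residue_name)
        if max_res is None or max_elem is None:
            continue
        if abs(entry.central_asa - q.central_asa) > 0.05 * max_res:
            continue
        if abs(entry.element_asa - q.element_asa) > 0.15 * max_elem:
            continue
        dist = sum(abs(int(x) - int(y))
                   for x, y in zip(q.histogram, entry.histogram))
        delta = abs(entry.central_asa - q.central_asa)
        candidates.append((dist, delta, idx, entry))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    return [(entry, dist, delta) for dist, delta, _, entry in candidates[:k]]


# -------------------------------------------------------------- prediction

def enumerate_probabilities(repo, query_elements, method, k,
                            excluded=frozenset()):
    """Recompute the weighted-vote probabilities from first principles.

    Independent enumeration: brute-force retrieval per element,
    explicit multiset unions for the whole-protein and per-patch
    collections, explicit contribution tallies, and the weight
    equations applied sample by sample.
    """
    retrievals = {key: brute_force_retrieve(repo, q, k, excluded)
                  for key, q in query_elements.items()}
    z_multiset = [entry for samples in retrievals.values()
                  for entry, _, _ in samples]
    cont_z = Counter(e.structure_id for e in z_multiset)
    probs = {}
    for key, q in query_elements.items():
        n_multiset = []
        for member in q.members:
            if member in retrievals:
                n_multiset.extend(e for e, _, _ in retrievals[member])
        cont_n = Counter(e.structure_id for e in n_multiset)
        w_pos = w_neg = 0.0
        samples = retrievals[key]
        if not samples:
            probs[key] = None
            continue
        for entry, _, _ in samples:
            w_g = cont_z[entry.structure_id]
            w_l = cont_n[entry.structure_id]
            w = {"G": w_g, "L": w_l, "C": w_g * w_l}[method]
            if entry.label == "interface":
                w_pos += w
            else:
                w_neg += w
        total = w_pos + w_neg
        if total == 0:
            probs[key] = (sum(1 for e, _, _ in samples
                              if e.label == "interface") / len(samples))
        else:
            probs[key] = w_pos / total
    return probs


# -------------------------------------------------------------- evaluation

def pair_count_auc(scores, labels):
    """(concordant + ties/2) / (P*N) over all positive-negative pairs."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    num = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                num += 1.0
            elif p == q:
                num += 0.5
    return num / (len(pos) * len(neg))


def random_population_spec(rng):
    """A small randomized population recipe for oracle-equality sweeps."""
    from prise.synthetic import ElementPopulationSpec
    return ElementPopulationSpec(
        seed=int(rng.integers(2 ** 31)),
        n_interface=int(rng.integers(20, 300)),
        n_noninterface=int(rng.integers(20, 300)),
        effect_shift=float(rng.uniform(0, 3)),
        n_structures=int(rng.integers(4, 25)),
        n_residue_types=int(rng.integers(1, 9)),
        global_signal=float(rng.uniform(0, 1)),
        n_queries=3,
    )
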