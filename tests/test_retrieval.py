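"""Retrieval: city-block distance, constraints, identity, ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_retrieve, gotoh_global_score
from prise.elements import StructuralElement
from prise.repository import Repository
from prise.retrieval import (ExclusionPolicy, MODE_HOMOLOG_ANY_SPECIES,
                             MODE_HOMOLOG_SAME_SPECIES, excluded_structure_ids,
                             histogram_distance, passes_constraints,
                             retrieve_similar, sequence_identity)
from prise.structure import ResidueKey
from prise.synthetic import (ElementPopulationSpec,
                             generate_element_population)

AMINO = "ACDEFGHIKLMNPQRSTVWY"


def make_element(structure_id, resname="ALA", central=100.0, element=400.0,
                 hist=None, label="interface", seq=1):
    key = ResidueKey("A", seq, residue_name=resname)
    h = np.zeros(36, dtype=int) if hist is None else np.asarray(hist)
    return StructuralElement(central=key, central_asa=central,
                             element_asa=element, histogram=h,
                             members=frozenset({key}),
                             structure_id=structure_id, chain_id="A",
                             label=label)


# --------------------------------------------------------------- distance

def test_histogram_distance_examples():
    assert histogram_distance([1] * 36, [1] * 36) == 0
    x = [2, 1] + [0] * 34
    y = [0, 2, 1] + [0] * 33
    assert histogram_distance(x, y) == 4
    with pytest.raises(ValueError):
        histogram_distance([0] * 35, [0] * 36)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(st.integers(0, 30), min_size=36, max_size=36),
       st.lists(st.integers(0, 30), min_size=36, max_size=36),
       st.lists(st.integers(0, 30), min_size=36, max_size=36))
def test_histogram_distance_properties(x, y, z):
    assert histogram_distance(x, y) == sum(
        abs(a - b) for a, b in zip(x, y))
    assert histogram_distance(x, y) == histogram_distance(y, x)
    assert (histogram_distance(x, z)
            <= histogram_distance(x, y) + histogram_distance(y, z))


# ------------------------------------------------------------- constraints

def constraint_repo():
    repo = Repository()
    repo.max_residue_asa = {"ALA": 200.0}
    repo.max_element_asa = {"ALA": 1000.0}
    return repo


def test_same_structure_fails_constraint_i():
    repo = constraint_repo()
    q = make_element("S1")
    assert not passes_constraints(q, make_element("S1"), repo)
    assert passes_constraints(q, make_element("S2"), repo)


def test_different_central_type_fails():
    repo = constraint_repo()
    repo.max_residue_asa["GLY"] = 200.0
    repo.max_element_asa["GLY"] = 1000.0
    q = make_element("S1", resname="ALA")
    assert not passes_constraints(q, make_element("S2", resname="GLY"), repo)


def test_central_asa_five_percent_boundary():
    repo = constraint_repo()  # 5% of 200 = 10
    q = make_element("S1", central=100.0)
    assert passes_constraints(q, make_element("S2", central=109.0), repo)
    assert passes_constraints(q, make_element("S2", central=110.0), repo)
    assert not passes_constraints(q, make_element("S2", central=111.0), repo)


def test_element_asa_fifteen_percent_boundary():
    repo = constraint_repo()  # 15% of 1000 = 150
    q = make_element("S1", element=400.0)
    assert passes_constraints(q, make_element("S2", element=549.0), repo)
    assert not passes_constraints(q, make_element("S2", element=551.0), repo)


# ---------------------------------------------------------------- identity

def test_identity_examples():
    assert sequence_identity("ACDEFGHIKL", "ACDEFGHIKL") == pytest.approx(100.0)
    assert sequence_identity("ACDEFGHIKL", "ACDEFGHIKV") == pytest.approx(90.0)


def test_identity_symmetric_and_bounded():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a = "".join(rng.choice(list(AMINO), rng.integers(5, 25)))
        b = "".join(rng.choice(list(AMINO), rng.integers(5, 25)))
        ab = sequence_identity(a, b)
        assert ab == sequence_identity(b, a)
        assert 0.0 <= ab <= 100.0


def test_alignment_score_matches_dp_oracle():
    """The aligner's optimal score equals an independent Gotoh DP."""
    from prise.retrieval import _aligner

    rng = np.random.default_rng(1)
    for _ in range(15):
        a = "".join(rng.choice(list(AMINO), rng.integers(3, 15)))
        b = "".join(rng.choice(list(AMINO), rng.integers(3, 15)))
        assert _aligner.score(a, b) == pytest.approx(
            gotoh_global_score(a, b))


# --------------------------------------------------------------- retrieval

def test_exact_copy_ranks_first():
    repo, queries, _ = generate_element_population(
        ElementPopulationSpec(seed=70, n_interface=100, n_noninterface=100))
    q = next(iter(queries))
    clone = make_element("OTHER", resname=q.residue_name,
                         central=q.central_asa, element=q.element_asa,
                         hist=q.histogram)
    repo.add(clone)
    repo.source_table["OTHER"] = {"A": ("", "")}
    repo.recompute_maxima()
    result = retrieve_similar(repo, q, k=3)
    entry, dist, delta = result.samples[0]
    assert entry.structure_id == "OTHER" and dist == 0 and delta == 0.0


def test_tie_broken_by_central_asa_delta():
    repo = Repository()
    h = [1] * 36
    repo.add(make_element("S1", central=102.0, hist=h, seq=1))
    repo.add(make_element("S2", central=101.0, hist=h, seq=2))
    repo.max_residue_asa = {"ALA": 200.0}
    repo.max_element_asa = {"ALA": 1000.0}
    q = make_element("Q", central=100.0, hist=h)
    result = retrieve_similar(repo, q, k=1)
    assert result.samples[0][0].structure_id == "S2"  # delta 1.0 < 2.0


def test_final_tie_broken_by_insertion_order():
    repo = Repository()
    h = [1] * 36
    repo.add(make_element("S1", hist=h, seq=1))
    repo.add(make_element("S2", hist=h, seq=2))
    repo.max_residue_asa = {"ALA": 200.0}
    repo.max_element_asa = {"ALA": 1000.0}
    q = make_element("Q", hist=h)
    result = retrieve_similar(repo, q, k=2)
    assert [s[0].structure_id for s in result.samples] == ["S1", "S2"]


@pytest.mark.parametrize("seed", [71, 72, 73])
@pytest.mark.parametrize("k", [1, 5, 50])
def test_retrieval_equals_brute_force_oracle(seed, k):
    repo, queries, _ = generate_element_population(
        ElementPopulationSpec(seed=seed, n_interface=300, n_noninterface=300,
                              n_structures=8, n_queries=5))
    for q in queries:
        got = retrieve_similar(repo, q, k=k)
        expected = brute_force_retrieve(repo, q, k)
        assert [(e.central, d, x) for e, d, x in got.samples] == [
            (e.central, d, x) for e, d, x in expected]
        assert got.k_returned <= got.k_requested
        dists = [d for _, d, _ in got.samples]
        assert dists == sorted(dists)


# ------------------------------------------------------------------ policy

def homolog_repo():
    """Population repo with planted sequences at graded identity."""
    repo, queries, _ = generate_element_population(
        ElementPopulationSpec(seed=74, n_interface=400, n_noninterface=400,
                              n_structures=10, n_queries=4))
    rng = np.random.default_rng(74)
    base = "".join(rng.choice(list(AMINO), 40))

    def mutate(seq, n_mut):
        out = list(seq)
        for pos in rng.choice(len(seq), n_mut, replace=False):
            out[pos] = AMINO[(AMINO.index(out[pos]) + 1) % 20]
        return "".join(out)

    sids = sorted(repo.source_table)
    identities = [0, 2, 16, 26, 36]  # 100%, 95%, 60%, 35%, 10%
    for i, sid in enumerate(sids):
        n_mut = identities[i % len(identities)]
        species = "E. coli" if i % 2 == 0 else "H. sapiens"
        repo.source_table[sid] = {"A": (mutate(base, n_mut), species)}
    return repo, queries, base


def test_policy_nesting_30_50_95():
    repo, queries, base = homolog_repo()
    query_chains = [(base, "E. coli")]
    results = {}
    for cutoff in (30.0, 50.0, 95.0):
        policy = ExclusionPolicy(mode=MODE_HOMOLOG_ANY_SPECIES,
                                 identity_threshold=cutoff)
        excluded = excluded_structure_ids(repo, policy, query_chains)
        # k beyond the candidate-pool size: nesting is a property of
        # the admitted candidate sets, not of a truncated top-k
        results[cutoff] = {
            q.central: {(e.structure_id, e.central) for e, _, _ in
                        retrieve_similar(repo, q, k=10_000,
                                         excluded=excluded).samples}
            for q in queries}
    for q in queries:
        assert (results[30.0][q.central] <= results[50.0][q.central]
                <= results[95.0][q.central])


def test_same_species_mode_requires_species_match():
    repo, _, base = homolog_repo()
    any_species = excluded_structure_ids(
        repo, ExclusionPolicy(MODE_HOMOLOG_ANY_SPECIES, 95.0),
        [(base, "E. coli")])
    same_species = excluded_structure_ids(
        repo, ExclusionPolicy(MODE_HOMOLOG_SAME_SPECIES, 95.0),
        [(base, "E. coli")])
    assert same_species <= any_species
    assert all(repo.source_table[sid]["A"][1] == "E. coli"
               for sid in same_species)


def test_retrieval_with_policy_equals_oracle():
    repo, queries, base = homolog_repo()
    policy = ExclusionPolicy(MODE_HOMOLOG_ANY_SPECIES, 50.0)
    query_chains = [(base, "E. coli")]
    excluded = excluded_structure_ids(repo, policy, query_chains)
    assert excluded  # the planted homologs are actually excluded
    for q in queries:
        got = retrieve_similar(repo, q, k=10, policy=policy,
                               query_chains=query_chains)
        expected = brute_force_retrieve(repo, q, 10, excluded=excluded)
        assert [(e.central, d) for e, d, _ in got.samples] == [
            (e.central, d) for e, d, _ in expected]


def test_homolog_mode_without_sequences_errors(toy_repo):
    q = toy_repo.entries[0]
    with pytest.raises(ValueError):
        retrieve_similar(toy_repo, q, k=1,
                         policy=ExclusionPolicy(MODE_HOMOLOG_ANY_SPECIES))
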