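"""Weighted-majority prediction: contexts, weights, probabilities."""

from collections import Counter

import numpy as np
import pytest

from oracles import enumerate_probabilities
from prise.elements import (LABEL_INTERFACE, LABEL_NON_INTERFACE,
                            ElementSet, StructuralElement)
from prise.prediction import (FLAG_NO_SAMPLES, FLAG_OK, FLAG_ZERO_WEIGHT,
                              PredictionContext, build_context,
                              compute_weight, contribution,
                              posterior_probability, predict_element_set,
                              predict_interface_residues)
from prise.repository import build_repository
from prise.retrieval import RetrievalResult
from prise.structure import ResidueKey
from prise.synthetic import (ElementPopulationSpec, ToyComplexSpec,
                             generate_element_population,
                             generate_toy_complex)


def element(sid, seq, resname="ALA", hist=None, label=LABEL_INTERFACE,
            central=100.0, elem_asa=400.0, members=None, chain="A"):
    key = ResidueKey(chain, seq, residue_name=resname)
    h = np.zeros(36, dtype=int) if hist is None else np.asarray(hist)
    return StructuralElement(
        central=key, central_asa=central, element_asa=elem_asa, histogram=h,
        members=frozenset(members) if members else frozenset({key}),
        structure_id=sid, chain_id=chain, label=label)


class _Sample:
    def __init__(self, sid):
        self.structure_id = sid


def test_contribution_counts_multiplicity():
    samples = [_Sample("A"), _Sample("A"), _Sample("B")]
    assert contribution("A", samples) == 2
    assert contribution("B", samples) == 1
    assert contribution("C", samples) == 0
    assert contribution("A", []) == 0


def small_population(seed=80):
    return generate_element_population(
        ElementPopulationSpec(seed=seed, n_interface=200, n_noninterface=200,
                              n_structures=6, n_queries=6))


def test_single_element_query_degenerate_context():
    repo, queries, _ = small_population()
    key, q = next(iter(queries.elements.items()))
    solo = ElementSet(structure_id="QUERY", chain_id="Q",
                      elements={key: q})
    ctx = build_context(repo, solo, "L", k=10)
    per_q = Counter(e.structure_id
                    for e, _, _ in ctx.retrievals[key].samples)
    assert ctx.cont_global == per_q
    assert ctx.cont_local[key] == per_q
    assert ctx.z_size == len(ctx.retrievals[key].samples)


def test_disjoint_elements_union_is_multiset_sum():
    repo, queries, _ = small_population()
    items = list(queries.elements.items())[:2]
    pair = ElementSet(structure_id="QUERY", chain_id="Q",
                      elements=dict(items))
    ctx = build_context(repo, pair, "G", k=10)
    expected = Counter()
    for key, _ in items:
        expected += Counter(e.structure_id
                            for e, _, _ in ctx.retrievals[key].samples)
    assert ctx.cont_global == expected
    # non-neighbors: each N_q is just the element's own retrieval
    for key, _ in items:
        assert ctx.cont_local[key] == Counter(
            e.structure_id for e, _, _ in ctx.retrievals[key].samples)


def test_weights_match_hand_recount():
    repo, queries, _ = small_population(81)
    ctx = build_context(repo, queries, "C", k=15)
    for key, q in queries.elements.items():
        for entry, _, _ in ctx.retrievals[key].samples:
            w_g = compute_weight(entry, key, ctx, "G")
            w_l = compute_weight(entry, key, ctx, "L")
            assert w_g == ctx.cont_global[entry.structure_id]
            assert w_l == ctx.cont_local[key][entry.structure_id]
            assert compute_weight(entry, key, ctx, "C") == w_g * w_l


def test_general_weight_invariant_under_query_order():
    repo, queries, _ = small_population(82)
    reversed_set = ElementSet(
        structure_id="QUERY", chain_id="Q",
        elements=dict(reversed(list(queries.elements.items()))))
    a = build_context(repo, queries, "G", k=10)
    b = build_context(repo, reversed_set, "G", k=10)
    assert a.cont_global == b.cont_global


def make_context(samples, method="L"):
    """Hand-built context around a single query element Q1."""
    key = ResidueKey("Q", 1, residue_name="ALA")
    retrieval = RetrievalResult(
        query=element("QUERY", 1), samples=[(s, 0, 0.0) for s in samples],
        k_requested=max(len(samples), 1))
    cont = Counter(s.structure_id for s in samples)
    return key, PredictionContext(
        method=method, k=5, retrievals={key: retrieval},
        cont_global=cont, cont_local={key: cont})


def test_posterior_all_positive_gives_one():
    key, ctx = make_context([element("S1", 1), element("S2", 2)])
    prob, flag, n = posterior_probability(key, ctx)
    assert prob == 1.0 and flag == FLAG_OK and n == 2


def test_posterior_arithmetic():
    # weights: S1 appears 3x, S2 once -> W+ = 3+3+3, W- = 1 at L
    samples = [element("S1", 1), element("S1", 2), element("S1", 3),
               element("S2", 4, label=LABEL_NON_INTERFACE)]
    key, ctx = make_context(samples)
    prob, flag, _ = posterior_probability(key, ctx)
    assert prob == pytest.approx(9.0 / 10.0)
    assert flag == FLAG_OK


def test_posterior_no_samples_undefined():
    key, ctx = make_context([])
    prob, flag, n = posterior_probability(key, ctx)
    assert prob is None and flag == FLAG_NO_SAMPLES and n == 0


def test_posterior_zero_weight_fallback():
    samples = [element("S1", 1), element("S2", 2),
               element("S3", 3, label=LABEL_NON_INTERFACE),
               element("S4", 4, label=LABEL_NON_INTERFACE),
               element("S5", 5, label=LABEL_NON_INTERFACE)]
    key, ctx = make_context(samples, method="C")
    ctx.cont_local[key] = Counter()  # no provenance mass locally
    prob, flag, _ = posterior_probability(key, ctx)
    assert flag == FLAG_ZERO_WEIGHT
    assert prob == pytest.approx(2.0 / 5.0)


def test_relabel_sample_never_decreases_probability():
    repo, queries, _ = small_population(83)
    ctx = build_context(repo, queries, "L", k=10)
    key = next(iter(queries.elements))
    before, _, _ = posterior_probability(key, ctx)
    for entry, _, _ in ctx.retrievals[key].samples:
        if entry.label == LABEL_NON_INTERFACE:
            old = entry.label
            entry.label = LABEL_INTERFACE
            after, _, _ = posterior_probability(key, ctx)
            entry.label = old
            assert after >= before


@pytest.mark.parametrize("method", ["L", "G", "C"])
def test_probabilities_match_independent_enumeration(method):
    repo, queries, _ = small_population(84)
    expected = enumerate_probabilities(repo, queries.elements, method, k=10)
    preds = predict_element_set(repo, queries, method, k=10)
    assert len(preds) == len(queries)
    for p in preds:
        if expected[p.key] is None:
            assert p.probability is None
        else:
            assert p.probability == pytest.approx(expected[p.key],
                                                  abs=1e-12)


def test_threshold_extremes():
    repo, queries, _ = small_population(85)
    low = predict_element_set(repo, queries, "L", k=10, threshold=0.0)
    assert all(p.label for p in low if p.n_samples > 0)
    high = predict_element_set(repo, queries, "L", k=10, threshold=1.001)
    assert not any(p.label for p in high if p.probability is not None)


def test_probability_bounds_and_mass():
    repo, queries, _ = small_population(86)
    for method in ("L", "G", "C"):
        for p in predict_element_set(repo, queries, method, k=10):
            if p.probability is not None:
                assert 0.0 <= p.probability <= 1.0


def test_self_retrieval_reproduces_repository_labels():
    """A verbatim copy of the query in the repository dominates at k=1."""
    donor = generate_toy_complex(ToyComplexSpec(seed=90))[0]
    repo = build_repository([donor])
    query_complex = generate_toy_complex(ToyComplexSpec(seed=90))[0]
    query_complex.structure_id = "QUERYCOPY"
    by_label = {e.central: e.label for e in repo.entries
                if e.chain_id == "A"}
    predictions = predict_interface_residues(
        repo, query_complex, chain_ids=["A"], method="L", k=1,
        threshold=0.5)["A"]
    assert predictions
    for p in predictions:
        assert p.probability in (0.0, 1.0)
        assert (p.probability == 1.0) == (by_label[p.key] == LABEL_INTERFACE)
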