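"""Interface prediction by weighted majority vote over retrieved elements.

Three weighting schemes share one machinery.  For a query protein Q
with element set S(Q), each element q retrieves its k most similar
repository samples S_q.  With Z_Q the multiset union of all S_q and,
for each q, N_q the multiset union of the retrievals of the elements
centered inside q's patch (q's members), the weight of a sample s with
provenance π(s) is

    general  (G):  w_G(s, q) = cont(π(s), Z_Q)
    local    (L):  w_L(s, q) = cont(π(s), N_q)
    combined (C):  w_C(s, q) = w_G(s, q) × w_L(s, q)

where cont(P, R) counts the samples of R originating from structure P.
The interface probability of q's central residue is
W+/(W+ + W−), the weighted fraction of interface-labeled samples, and
a residue is called interface when the probability reaches the
method's threshold.

Default retrieval depths are 50 (L), 200 (G) and 500 (C); default
decision thresholds are 0.5 (L, G) and 0.34 (C).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .elements import (LABEL_INTERFACE, LABEL_NON_INTERFACE, ElementSet,
                       StructuralElement)
from .repository import Repository
from .retrieval import (ExclusionPolicy, RetrievalResult,
                        excluded_structure_ids, retrieve_similar)
from .structure import ComplexModel, ResidueKey
from .surface import (DEFAULT_N_POINTS, DEFAULT_PROBE_RADIUS, compute_asa,
                      find_surface_neighbors)

METHOD_LOCAL = "L"
METHOD_GENERAL = "G"
METHOD_COMBINED = "C"
METHODS = (METHOD_LOCAL, METHOD_GENERAL, METHOD_COMBINED)

DEFAULT_K = {METHOD_LOCAL: 50, METHOD_GENERAL: 200, METHOD_COMBINED: 500}
DEFAULT_THRESHOLD = {METHOD_LOCAL: 0.5, METHOD_GENERAL: 0.5,
                     METHOD_COMBINED: 0.34}

FLAG_OK = "ok"
FLAG_NO_SAMPLES = "no_samples"
FLAG_ZERO_WEIGHT = "zero_weight_fallback"


def contribution(structure_id: str, samples) -> int:
    """cont(P, R): samples in R from structure P, with multiplicity."""
    return sum(1 for s in samples if s.structure_id == structure_id)


@dataclass
class PredictionContext:
    """Per-query retrieval state shared by the weighting schemes."""

    method: str
    k: int
    retrievals: dict[ResidueKey, RetrievalResult]
    cont_global: Counter          # cont(·, Z_Q)
    cont_local: dict[ResidueKey, Counter]  # cont(·, N_q) per element

    @property
    def z_size(self) -> int:
        return sum(self.cont_global.values())


@dataclass
class ResiduePrediction:
    """Probability and thresholded label for one surface residue."""

    key: ResidueKey
    method: str
    probability: float | None
    label: bool | None           # True = interface; None when undefined
    flag: str = FLAG_OK
    n_samples: int = 0


def build_context(repo: Repository, query: ElementSet, method: str,
                  k: int | None = None,
                  policy: ExclusionPolicy = ExclusionPolicy(),
                  query_chains: list[tuple[str, str | None]] | None = None,
                  ) -> PredictionContext:
    """Retrieve samples for every query element and tabulate cont().

    Z_Q and each N_q are multisets: an entry retrieved for two query
    elements counts twice in the contribution tables.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of "
                         f"{METHODS}")
    if k is None:
        k = DEFAULT_K[method]
    excluded = excluded_structure_ids(repo, policy, query_chains)
    retrievals: dict[ResidueKey, RetrievalResult] = {}
    for key, q in query.elements.items():
        retrievals[key] = retrieve_similar(repo, q, k, policy=policy,
                                           excluded=excluded)
    cont_global: Counter = Counter()
    for result in retrievals.values():
        for entry, _, _ in result.samples:
            cont_global[entry.structure_id] += 1
    cont_local: dict[ResidueKey, Counter] = {}
    for key, q in query.elements.items():
        counter: Counter = Counter()
        for member in q.members:
            result = retrievals.get(member)
            if result is None:
                continue  # member has no element (not a surface residue)
            for entry, _, _ in result.samples:
                counter[entry.structure_id] += 1
        cont_local[key] = counter
    return PredictionContext(method=method, k=k, retrievals=retrievals,
                             cont_global=cont_global, cont_local=cont_local)


def compute_weight(sample: StructuralElement, q_key: ResidueKey,
                   ctx: PredictionContext, method: str | None = None) -> int:
    """Weight of one retrieved sample under a scheme (default: ctx's)."""
    method = method or ctx.method
    if method == METHOD_GENERAL:
        return ctx.cont_global[sample.structure_id]
    if method == METHOD_LOCAL:
        return ctx.cont_local[q_key][sample.structure_id]
    if method == METHOD_COMBINED:
        return (ctx.cont_global[sample.structure_id]
                * ctx.cont_local[q_key][sample.structure_id])
    raise ValueError(f"unknown method {method!r}")


def posterior_probability(q_key: ResidueKey, ctx: PredictionContext,
                          method: str | None = None,
                          ) -> tuple[float | None, str, int]:
    """Interface probability W+/(W+ + W−) for one query element.

    Returns ``(probability, flag, n_samples)``.  With no retrieved
    samples the probability is undefined (``no_samples``).  When every
    weight is zero but samples exist (possible for the combined
    scheme), the unweighted vote |S+|/|S_q| is used and flagged.
    """
    method = method or ctx.method
    result = ctx.retrievals[q_key]
    if not result.samples:
        return None, FLAG_NO_SAMPLES, 0
    w_pos = 0.0
    w_neg = 0.0
    n_pos = 0
    for entry, _, _ in result.samples:
        w = compute_weight(entry, q_key, ctx, method)
        if entry.label == LABEL_INTERFACE:
            w_pos += w
            n_pos += 1
        elif entry.label == LABEL_NON_INTERFACE:
            w_neg += w
        else:
            raise ValueError("retrieved sample has unknown label")
    total = w_pos + w_neg
    if total == 0:
        return n_pos / len(result.samples), FLAG_ZERO_WEIGHT, len(result.samples)
    return w_pos / total, FLAG_OK, len(result.samples)


def predict_element_set(repo: Repository, query: ElementSet, method: str,
                        k: int | None = None,
                        policy: ExclusionPolicy = ExclusionPolicy(),
                        query_chains=None,
                        threshold: float | None = None,
                        ) -> list[ResiduePrediction]:
    """Predict interface residues for an already-extracted element set."""
    if threshold is None:
        threshold = DEFAULT_THRESHOLD[method]
    ctx = build_context(repo, query, method, k=k, policy=policy,
                        query_chains=query_chains)
    predictions = []
    for key in query.elements:
        prob, flag, n = posterior_probability(key, ctx)
        label = None if prob is None else bool(prob >= threshold)
        predictions.append(ResiduePrediction(
            key=key, method=method, probability=prob, label=label,
            flag=flag, n_samples=n))
    return predictions


def predict_interface_residues(repo: Repository,
                               complex_model: ComplexModel,
                               chain_ids: list[str] | None = None,
                               method: str = METHOD_COMBINED,
                               k: int | None = None,
                               policy: ExclusionPolicy = ExclusionPolicy(),
                               threshold: float | None = None,
                               probe_radius: float = DEFAULT_PROBE_RADIUS,
                               n_points: int = DEFAULT_N_POINTS,
                               ) -> dict[str, list[ResiduePrediction]]:
    """Run the full pipeline on a query structure.

    Each requested chain is decomposed into structural elements
    (monomer ASA → neighbor graph → elements) and voted on against the
    repository.  Returns one prediction per surface residue per chain.
    """
    from .elements import extract_elements

    if chain_ids is None:
        chain_ids = [c.chain_id for c in complex_model.chains]
    query_chains = [(c.sequence, c.species) for c in complex_model.chains]
    out: dict[str, list[ResiduePrediction]] = {}
    for chain_id in chain_ids:
        chain = complex_model.chain(chain_id)
        asa = compute_asa(chain, probe_radius, n_points)
        graph = find_surface_neighbors(chain, asa)
        query = extract_elements(chain, asa, graph,
                                 structure_id=complex_model.structure_id)
        out[chain_id] = predict_element_set(
            repo, query, method, k=k, policy=policy,
            query_chains=query_chains, threshold=threshold)
    return out


def predictions_to_tsv(predictions: dict[str, list[ResiduePrediction]],
                       structure_id: str) -> str:
    """Serialize predictions as tab-separated text."""
    lines = ["structure_id\tchain_id\tresnum\ticode\tresname\tmethod\t"
             "probability\tlabel\tflag\tn_samples"]
    for chain_id, rows in predictions.items():
        for p in rows:
            prob = "NA" if p.probability is None else f"{p.probability:.6f}"
            label = ("NA" if p.label is None
                     else ("interface" if p.label else "non-interface"))
            lines.append(
                f"{structure_id}\t{chain_id}\t{p.key.seq_number}\t"
                f"{p.key.insertion_code or '.'}\t{p.key.residue_name}\t"
                f"{p.method}\t{prob}\t{label}\t{p.flag}\t{p.n_samples}")
    return "\n".join(lines) + "\n"
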