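# Methods

This note documents the model implemented by `prise`, its parameters
and defaults, the synthetic data used to exercise it, and the
numerical and design choices that were genuinely open.

## Surface model

Accessible surface areas are computed with the Shrake–Rupley method:
every heavy atom is wrapped in a deterministic golden-spiral point set
on its solvent-expanded sphere (radius r + r_probe) and the fraction
of points falling outside every neighboring expanded sphere gives the
exposed area. Defaults: probe radius 1.4 Å (water), 960 points per
atom. Each chain is always processed in isolation, so a chain's
surface definition never depends on its partners (monomer ASA). A
residue is a surface residue iff its monomer ASA is strictly
positive; an atom is a surface atom iff its own ASA is strictly
positive. No epsilon is applied: a single exposed sample point makes
an atom a surface atom.

The point set is anchored at each atom's center with a fixed global
orientation. ASA values are therefore exactly invariant under
translation of the structure and only statistically invariant under
rotation (the binary exposed/buried classification, which is what the
histograms consume, is stable in practice; the sampling error itself
is about 0.5% of an atom's sphere area at 960 points, and halving the
grid spacing moves fixture values by well under 2%).

Van der Waals radii follow the NACCESS/Chothia-style table: backbone
carbonyl C 1.76 Å, all other carbons 1.87 Å, N 1.65 Å, O 1.40 Å,
S 1.85 Å; unknown atom names fall back to 1.80 Å with a logged
warning. Hydrogens, waters, hetero groups and nonstandard residues
are dropped at parse time; one alternate location is kept per atom
(highest occupancy, ties by altloc letter); only the first MODEL of a
multi-model file is read. These parsing rules are deliberate
simplifications: the method is defined entirely over heavy atoms of
the 20 standard amino acids.

Two residues are surface neighbors when some heavy-atom pair has a
Van der Waals surface gap (center distance minus the sum of radii) of
at most 1.5 Å. Inter-chain contacts use the same gap at 0.5 Å for
repository labeling; evaluation against other interface conventions
is supported with a 3.0 Å gap rule and a plain 5.0 Å atom-distance
rule. All threshold comparisons are inclusive (≤). Neighbor and
contact searches are KD-tree pruned with the contract — enforced by
tests — that the output is identical to the all-pairs scan.

## Structural elements

One element per surface residue: the residue plus its surface
neighbors. Features: central residue type; central residue ASA;
element ASA (sum over member residues); and a 36-bin histogram
counting, per heavy-atom nomenclature, the member atoms with positive
ASA. The vocabulary is the set of heavy-atom PDB names occurring in
the 20 standard amino acids, which numbers exactly 36; it is defined
in one table (`chemistry.ATOM_VOCABULARY`) whose order fixes the bin
order. The terminal OXT is not in the vocabulary: it contributes to
ASA sums but never to histograms. Stored ASA values are rounded to
3 decimals (the repository's on-disk precision) at element-extraction
time, so persistence round-trips are bit-exact and retrieval
arithmetic is identical before and after a save/load cycle.

## Repository and retrieval

The repository keeps every element extracted from interacting chains
(≥ 5 contact residues at the 0.5 Å rule) of the input complexes, each
labeled interface/non-interface by its central residue's contact
flag. Per residue type it records the empirical maxima of central and
element ASA, used to scale the retrieval constraints; both maxima can
be overridden by a configuration table. Persistence is one JSON
header (format version, maxima, per-chain sequence and species) plus
one tab-separated entries file.

Retrieval for a query element returns the k candidates with the
smallest city-block histogram distance among entries that (i) come
from a different complex (same structure id = same complex),
(ii) share the central residue type, (iii) differ in central ASA by
at most 5% of the type's maximum and (iv) differ in element ASA by at
most 15% of the type's element maximum. Ties are broken by the
smaller central-ASA difference, then by repository insertion order
(stable). The 5%/15% constants are fixed defaults adopted from prior
calibration; they are configuration, not fitted here. The type-indexed
vectorized search is contractually identical to a full
filter-then-sort scan, which the tests verify exhaustively.

Homolog exclusion removes every element of a source structure
containing a chain whose sequence identity to any query chain reaches
the cutoff (95% default; 50% and 30% supported), optionally only when
the species annotations match. Identity is computed from a global
alignment (match 1, mismatch 0, gap open −0.5, gap extend −0.1) as
identities over the shorter sequence's length; the sequence pair is
ordered canonically before aligning so the function is exactly
symmetric. Identity counted on one optimal alignment is not unique
when co-optimal alignments exist; the implementation pins the
aligner's deterministic choice and the tests therefore check the
optimal score against an independent dynamic program, plus exact
values only on unambiguous cases. Note that the subset relation
between admitted sample sets at tightening cutoffs (30 ⊆ 50 ⊆ 95)
holds for the candidate pools; after top-k truncation it can be
violated legitimately, because excluding a structure frees ranked
slots.

## Voting

For a query protein Q with elements S(Q), retrieval depth k per
scheme (defaults 50/200/500 for local/general/combined; the combined
scheme performs a single k = 500 retrieval reused for both of its
contribution contexts). Z_Q is the union of all retrievals of Q and,
for each element q, N_q the union of the retrievals of the elements
centered in q's member set (which includes q itself). Both unions are
multisets: an entry retrieved for two query elements counts twice in
the contribution tables, because contributions are defined as counts
over retrieved samples. Weights: w_G = cont(π(s), Z_Q),
w_L = cont(π(s), N_q), w_C = w_G · w_L. Probability:
W₊/(W₊ + W₋) over the interface/non-interface samples of S_q.

Degenerate cases are explicit, never silent: an element with no
admitted candidates yields an undefined probability flagged
`no_samples` (evaluation scores it as a negative prediction with
score 0 and reports the count); a non-empty S_q whose weights are all
zero — unreachable through the normal pipeline since q's own
retrieval always contributes to N_q, but possible for externally
constructed contexts — falls back to the unweighted vote |S₊|/|S_q|
with flag `zero_weight_fallback`. Labels use probability ≥ threshold
(inclusive); defaults 0.5 (L, G) and 0.34 (C, the deployed default of
the combined predictor).

## Evaluation

Confusion metrics follow the standard formulas, including the
Matthews correlation; any zero denominator yields a missing value
("NA"), never 0. The precision–recall curve has one point per
distinct score with "interface iff score ≥ threshold"; ROC AUC is the
trapezoidal/rank-sum area (ties count 1/2) via scikit-learn, and is
cross-checked in tests against an exhaustive pair-counting oracle.
Curves pool residues across chains; per-protein averaging is left to
the caller.

## Synthetic data

Two generators produce all test inputs at run time.

**Toy complexes.** Two chains of idealized heavy-atom residue
templates (standard-geometry backbone, zigzag side chains) laid along
gentle helical curves; a designated patch of chain B is lowered by
bisection until each patch residue sits at a prescribed Van der Waals
gap (default 0.35 Å) from chain A, so the planted contact set is
recovered exactly by the 0.5 Å rule. Residue types are drawn without
replacement per chain, because duplicate types in these regular
geometries can create byte-identical elements and degenerate
retrieval ties no real chain exhibits. The templates are valid and
self-consistent but make no claim of stereochemical realism: ASA
magnitudes, neighbor counts and contact geometry are plausible, while
side-chain packing and secondary structure are not emulated, so
passing tests demonstrate correctness of the machinery, not
biological accuracy on real complexes.

**Element populations.** A statistical stand-in for a large
repository: per-bin histogram counts are independent Poisson draws
(base rate 1 per bin); the interface class adds `effect_shift` to
five designated bins (the local signal). ASA features are drawn from
narrow ranges (central 100–120 Å², element +300–340 Å²) chosen so the
5%/15% constraint windows admit many same-type candidates, and
entries are spread over a small number of residue types (default 4)
so each candidate pool is large enough for similarity ranking to be
selective at the retrieval depths the tests use (k = 30–50; the
full-scale defaults of 200/500 presume repositories of millions of
elements). Entries are distributed over reliable source structures —
labels faithful, a configurable fraction label-pure — and optionally
over many small decoy structures whose labels are coin flips. Decoys
pollute purely local voting; because each decoy contributes few
retrievals protein-wide, provenance-aggregating weights discount
them. Three scenarios are fixed as study conditions:

- *null*: no shift; local prediction sits at chance (AUC ≈ 0.5,
  1000 held-out queries);
- *strong local*: shift +3 on 5 bins at 2000 entries per class;
  local AUC > 0.99;
- *mixed*: shift +1.5 with 70% of entries in 150 decoy structures
  and 10 reliable structures (half label-pure); the general scheme
  beats the local one and the combined scheme matches the best of
  the two, reproducing the qualitative ordering the weighting is
  designed for.

Held-out query elements are singletons (their patch is themselves),
so the local scheme reduces to within-retrieval provenance weighting;
patch-union behavior is exercised separately with overlapping member
sets in the hand-check tests.

## Numerical choices and limitations

- All distance thresholds inclusive; gap computed as
  d − (r_a + r_b) so it is exactly symmetric.
- Retrieval ordering is fully deterministic: (distance, ASA delta,
  insertion index) lexicographic, so results are reproducible across
  repository file row orders except where two entries tie in all
  three keys, which requires identical rows.
- Problem sizes in tests (12-residue toy chains, populations of a few
  thousand elements, 40–100 randomized repositories in the oracle
  sweeps) were chosen to exercise every code path with exact oracles
  while keeping the suite fast; they are far below the repository
  scale the method targets in production.
- Naccess itself is not reproduced; ASA equivalence to it is
  approximate by construction and nothing here depends on matching
  its output to machine precision.
- mmCIF input, assembly regeneration from symmetry operators and
  relative-ASA normalization are out of scope.
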