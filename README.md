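# prise

Prediction of protein–protein interface residues from local surface
structural similarity.

Knowing which surface residues of a protein take part in
protein–protein interactions guides mutagenesis, docking and interface
engineering, but most proteins with a solved structure have no solved
complex. `prise` predicts interface residues of a query structure by
comparing its surface, patch by patch, against a repository of surface
patches extracted from known complexes, where each patch's central
residue is already labeled interface or non-interface.

## The method

A chain's surface is decomposed into **structural elements**: one per
surface residue (monomer accessible surface area, ASA, > 0 Å²),
consisting of the residue and its surface neighbors (some heavy-atom
pair within 1.5 Å between Van der Waals surfaces). An element is
represented by four features: the central residue type, the central
residue's ASA, the element's total ASA, and a 36-bin histogram
counting the solvent-exposed heavy atoms of the element per atom
nomenclature (CA, CB, OG1, …; the 20 standard amino acids contain
exactly 36 distinct heavy-atom names).

A **repository** stores the elements of every interacting chain (≥ 5
residues in inter-chain contact at a 0.5 Å Van der Waals gap) of a set
of complexes, each labeled by whether its central residue is in
contact. For a query element *q*, the *k* most similar repository
elements S_q are retrieved by city-block distance between histograms,
subject to four constraints: different source complex, identical
central residue type, central-ASA difference ≤ 5% of the residue
type's maximum, and element-ASA difference ≤ 15% of the type's
element maximum. Homologs of the query protein can be excluded by
sequence identity (95/50/30% cutoffs, optionally same-species only).

Each retrieved sample *s* votes with a weight built from contribution
counts cont(P, R) — the number of retrieved samples in a collection R
originating from structure P:

- general: w_G(s, q) = cont(π(s), Z_Q), with Z_Q the union of all
  retrievals of the query protein;
- local: w_L(s, q) = cont(π(s), N_q), with N_q the union of the
  retrievals of the elements in q's patch;
- combined: w_C(s, q) = w_G(s, q) · w_L(s, q).

The interface probability of q's central residue is
W₊/(W₊ + W₋), the weighted fraction of interface-labeled samples; a
residue is called interface when the probability reaches the decision
threshold (0.5 for L and G, 0.34 for C). Default retrieval depths are
k = 50 (L), 200 (G) and 500 (C).

## Worked example

```sh
prise simulate fixtures --kind toy --seed 101   # one toy complex
prise simulate fixtures2 --kind toy --seed 102
mkdir -p repo_in && cp fixtures/*.pdb fixtures2/*.pdb repo_in/
prise build-repo repo_in repo
prise simulate queries --kind toy --seed 103
prise predict queries/TOY0103.pdb repo pred.tsv --method L --k 3
prise eval pred.tsv queries/TOY0103.pdb report.json --contact-rule vdw0.5
```

`pred.tsv` contains one row per surface residue; with this tiny
two-complex repository it prints rows such as

```
structure_id  chain_id  resnum  icode  resname  method  probability  label          flag        n_samples
TOY0103       A         1      .      GLU      L       NA           NA             no_samples  0
TOY0103       A         9      .      TRP      L       1.000000     interface      ok          1
TOY0103       B         3      .      SER      L       0.500000     interface      ok          2
TOY0103       B         4      .      TYR      L       0.000000     non-interface  ok          1
```

`probability` is the weighted fraction of the retrieved samples whose
central residues are interface residues (SER B3 found two samples that
disagree, hence 0.5), `label` applies the 0.5 threshold, and residues
for which no repository element passed the retrieval constraints are
flagged `no_samples` rather than silently scored 0 — expected here,
since a two-complex repository offers few candidates within the ASA
constraint windows. `report.json` scores the labels against the true
contacts of the complex; this run prints TP=3, FP=2, FN=9, TN=10
(precision 0.6, recall 0.25, F1 0.353, accuracy 0.542, Matthews
correlation 0.103), with the 14 `no_samples` residues counted as
negative predictions.

The same pipeline is available as library calls
(`build_repository`, `predict_interface_residues`,
`evaluate_predictions`), which is what the test-suite uses.

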