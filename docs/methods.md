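# Methods

This note documents the models and conventions implemented in `il13pep`:
what each stage computes, the parameters that matter, the choices made
where the design was genuinely open, and what the synthetic tests do and do
not establish about real data.

## The prediction problem

The positive class is peptides experimentally shown to induce IL-13
(IEDB-derived, 8–35 residues); the negative class is non-inducing peptides
from the same source, outnumbering positives roughly 9:1. The classifier
sees only sequence, encoded as composition descriptors, so the model can
capture residue-usage and local-order preferences but not structure or
MHC-binding context.

## The 9151-dimensional feature space

Twelve descriptor families, concatenated in catalog order. All constants
(per-residue chemistry, residue groupings) are bundled as TSV data files so
they are auditable and replaceable without touching code.

| family | dim | definition |
|---|---|---|
| AAC | 20 | % of each residue |
| DPC | 400 | % of each overlapping dipeptide (denominator L−1) |
| TPC | 8000 | % of each overlapping tripeptide (denominator L−2) |
| ATC | 5 | % of C/H/N/O/S atoms, from residue molecular formulas |
| BTC | 4 | total / hydrogen / single / double bond counts summed over residues |
| PCP | 30 | % of residues in each of 30 physicochemical classes (classes overlap, so this family does not sum to 100) |
| SER | 20 | per-residue-type Shannon entropy −f·log₂f (bits) |
| SE | 1 | whole-sequence entropy = Σ SER |
| RRI | 20 | 100·Σ(run length)²/L² over maximal runs of each residue |
| DDR | 20 | 100·(mean gap between consecutive occurrences)/L, 0 if < 2 occurrences |
| CTC | 343 | % of each class-triad after mapping residues to the 7 conjoint-triad classes |
| CeTD | 288 | composition/transition/distribution over 8 three-group partitions |

Composition families use the percent (×100) convention throughout; AAC,
DPC, TPC, ATC, CTC and each CeTD per-attribute composition block sum to
100 for every valid peptide.

**CeTD details.** Eight attributes: hydrophobicity (HB), normalized van der
Waals volume (VW), polarity (PO), polarizability (PZ), charge (CH),
secondary-structure propensity (SS), solvent accessibility (SA) — the
Dubchak-standard groupings — plus a three-way split of the Vihinen
flexibility scale (FL), this package's addition. Per attribute:
3 composition values (% per group), 3 transition values (% of adjacent
pairs crossing each unordered group pair, denominator L−1), and 30
distribution values. Distribution convention, per group g and quantile q ∈
{0, 25, 50, 75, 100}: the *position* feature is 100·(position of the
⌈q/100·n_g⌉-th group member)/L (1-based; the first member for q = 0; 0 when
the group is absent), and the *count* feature (`CeTD_q_p_ATTRg`) is the
number of group members within the first max(1, ⌈q/100·L⌉) positions.
These quantile formulas are not uniquely fixed by prior art; the
convention here is one concrete, testable choice, isolated in the CeTD
encoder so it can be revised without touching callers.

**Entropy convention.** Log base 2 (bits) everywhere; SER_r is defined as
−f_r·log₂f_r, which makes SE exactly the sum of the SER block — an
identity the tests assert.

**Bond/atom constants.** Derived from the standard residue (amino acid
minus water) molecular formulas: total bonds = atoms − 1 + rings, double
bonds = backbone C=O plus side-chain doubles (aromatic rings counted
Kekulé-style: benzene 3, imidazole 2, indole 4), single = total − double,
hydrogen = H-atom count.

**Degenerate inputs.** Peptides shorter than 3 residues (the TPC/CTC
window) are rejected at encode time rather than zero-filled; benchmark
validation additionally enforces 8–35 residues. Non-canonical residues
(B, J, O, U, X, Z, gaps) are rejected, never silently dropped — silent
mutation of the input would corrupt every composition feature.

## Mutual information and mRMR

The MI estimator is the empirical plug-in on discretized features:
each feature is binned into `bin_count` (default 10) equal-width bins over
its observed range, occupied bins are relabelled to consecutive codes
(so binary features keep codes 0/1 for any bin count), and
I(X,Y) = Σ p(x,y) log₂[p(x,y)/(p(x)p(y))] over the joint histogram, with
empty cells contributing 0. The estimator is exactly symmetric (the
argument pair is canonically ordered before histogramming), non-negative,
and satisfies I(X,X) = H(X). Ten equal-width bins is the reference mRMR
practice for a few hundred samples; the estimator sits behind one
interface so an alternative (e.g. adaptive binning) can be swapped in.

Greedy forward selection: step 1 maximizes relevance I(i,c); step t > 1
maximizes the difference (MID) or quotient (MIQ) criterion with redundancy
measured against already-selected features only (incremental mRMR,
O(k·d) MI evaluations). MID is the default — it is numerically safer; MIQ
uses a 1e-12 redundancy floor for its zero-redundancy first step. Ties
break by lexicographic feature name for cross-platform determinism. The
per-step relevance, redundancy and criterion values are recorded in the
result.

Selection is always computed on the training partition only, preventing
leakage into validation metrics.

A consequence worth knowing: when two features carry the same signal
(e.g. AAC_H and SER_H, both monotone in histidine frequency), whichever
wins the first pick makes the other maximally redundant, and the loser may
drop out of a short ranking entirely. That is mRMR behaving as designed.

## Training protocol

- **Split**: per-class seeded shuffle; training size = ⌊0.8·n⌋ per class.
  This floor-rounding convention is the one that maps 313/2908 peptides to
  exactly 250/2326 training and 63/582 validation.
- **CV**: stratified 5-fold (shuffled, seeded). A class with fewer samples
  than folds is rejected with a clear error rather than silently producing
  a single-class fold.
- **Grid search**: exhaustive; the winner maximizes mean CV AUCROC, the
  headline threshold-independent metric. Ties resolve deterministically by
  parameter order, with grids listed simplest-first so ties favour the
  less complex setting. Default grids are deliberately conservative
  (tens, not thousands, of candidates) and fully overridable per
  classifier — grids are configuration, not algorithmics.
- **Scaling**: min–max scaling lives inside each pipeline, so it is fitted
  on training folds only; distance-based classifiers (KNN, SVM) need it
  and the tree ensembles are unharmed by it.
- **Metrics**: sensitivity/specificity/accuracy in percent from the
  confusion matrix at the evaluation threshold (default 0.5 for benchmark
  reports), MCC with the 0-on-degenerate-denominator convention, AUCROC as
  the Mann–Whitney pair probability. The screening decision threshold
  (0.06) is a separate, deliberately permissive convention from the
  published webserver; raising it can only reduce positive calls.
- **Reproducibility**: one top-level seed drives the split, the folds and
  every classifier; trained-model artifacts store the seed, parameters,
  selected features and a training-data fingerprint.

## Synthetic fixtures and what they show

The generator draws i.i.d. residues with lengths uniform on 8–35. The
default study conditions are 60 positives / 540 negatives (the benchmark's
~1:9 imbalance at desk scale) with the positive class drawing histidine
with probability 0.05 + 0.3 and other letters renormalized — so the
expected AAC_H gap between classes is exactly 30 percentage points, and
recovery assertions can be exact. The recovery study runs 20 seeded
replicates of encode → mRMR → top-10 → XGB (fixed, modest XGB settings:
100 trees, depth 3, learning rate 0.3 — the study probes the feature
pathway, not hyperparameter choice) and a 10-replicate effect-size-zero
null whose validation AUCROC must sit at chance.

These fixtures validate the machinery — encoding correctness, selection
behaviour, leakage-free evaluation — under a model where the truth is
known. They do **not** emulate real epitope statistics: real
IL-13-inducing peptides differ from non-inducers in subtler, correlated
ways than a single-residue frequency shift, so passing the planted tests
says nothing about real-data AUCROC. The published benchmark figures
(validation AUCROC ≈ 0.84 for RF on the top 95 features, ≈ 0.83 for XGB on
the top 10) are reproducible only with the external benchmark download,
and — because the original split/CV seeds are unpublished — agreement
within about ±0.03 AUCROC is the realistic criterion for that integration
check.

## Known limitations

- The exact per-family composition of the original 9151-feature space is
  described only in supplementary material not reproduced here; this
  catalog is a faithful reconstruction constrained to the published total
  (9151) and the ten published top-feature names, with its own documented
  conventions for the under-specified families (PCP, RRI, DDR, CeTD
  quantiles). Rankings of individual features may therefore differ from
  the original tool's.
- Plug-in MI on 10 bins is biased upward for small samples; rankings are
  stable in practice but absolute MI values should not be over-read.
- The screening threshold 0.06 is calibrated to the original tool's score
  distribution; a model retrained here has its own distribution, and the
  threshold should be re-examined against a labelled validation set.
- No structure, MHC context, or host covariates: sequence composition
  only.
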