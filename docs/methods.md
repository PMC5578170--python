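# Methods notes

This note records the modelling assumptions, the numerical conventions,
and the design decisions taken where the underlying method is commonly
described ambiguously. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Sequence encoding

The six physicochemical scales (H, VSC, P1, P2, SASA, NCISC) are shipped
as a packaged CSV and z-scored per column over the 20 standard amino
acids. Because the alphabet is a fixed, finite population rather than a
sample, the default standard deviation is the population form (divide by
20); the sample convention (divide by 19) is available via
`normalize_property_table(ddof=1)`. Channel order is fixed to
(H, VSC, P1, P2, SASA, NCISC) so downstream feature indices are stable.

Non-standard residues (B, Z, J, X, U, O) have no row in the scale table.
The default policy drops them with a logged warning; `map` substitutes a
chemically similar standard residue (B→N, Z→Q, J→L, U→C, O→K; X is
dropped even here since it has no defensible representative); `error`
refuses the sequence. Parsing is case-insensitive and strips whitespace,
digits, `*`, `-` and `.`.

## Wavelet feature extraction

The cascade refilters only the approximation band at each of 4 levels.
Conventions, all recorded in the feature layout:

- **Mother wavelet: Daubechies-4 by default.** The wavelet family is the
  single largest free choice in this kind of sequence featurizer and is
  rarely stated precisely in the literature it comes from; db4 is the
  common default in protein-signal work. Haar and any other PyWavelets
  name are accepted (`--wavelet`).
- **Boundary handling: half-point symmetric extension** by default
  (PyWavelets `symmetric`), configurable to zero-padding or periodic.
  The test-suite oracle reproduces this convention from scratch: extend
  by `filter_len − 1` on each side with repeated reflection, convolve
  with the analysis filter, keep every second sample starting at offset
  `filter_len`, truncate to ⌊(n + filter_len − 1)/2⌋.
- **Decomposition feasibility.** For extension modes, a level whose
  coefficients would be dominated by the boundary is refused: minimum
  length for L levels is `(filter_len − 1)·2^L` (the `dwt_max_level`
  rule). Periodic wrapping introduces no extension, so there the only
  limit is the halving itself (`2^L`). Sequences too short for 4 levels
  fall back to the deepest feasible decomposition with the missing
  levels' features zero-filled (logged), keeping the feature matrix
  rectangular.
- **Band statistics** are (max, min, mean, SD) in that order, sample SD
  (n−1); a single-coefficient band has SD 0 by convention.
- **DCT head**: orthonormal DCT-II, first 5 coefficients of *each*
  level's approximation band by default (`dct_scope="all"`, 120 values);
  "from the approximation coefficients" is ambiguous between per-level
  and deepest-level-only, so `dct_scope="last"` (30 values) is also
  supported and tested. Bands shorter than 5 are zero-padded.
- **Energy conservation.** Parseval's identity holds to machine
  precision only when no boundary redundancy is introduced: the energy
  test uses periodic handling with lengths even at every level
  (multiples of 16 for 4 levels). Symmetric extension emits more
  coefficients than input samples and does not conserve energy; this is
  a property of the boundary mode, not an implementation error.

Default geometry: 6 channels × 4 levels × 2 bands × 4 statistics + 6 ×
4 × 5 DCT coefficients = 312 features per target, independent of
sequence length.

## Fingerprints

MACCS key semantics are delegated to RDKit rather than re-implemented
pattern by pattern; the 166-key definition set is an external MDL
standard, and the toolkit emits 167 bits whose dummy bit 0 is dropped so
the vector is keys 1–166 in order. Bit-level parity across chemistry
toolkits (e.g. Open Babel) is not guaranteed; precomputed fingerprint
tables can be loaded instead, which decouples the pipeline from any one
toolkit. Empty molecules are rejected by default (`allow_empty` yields
an all-zero vector); unparsable records in a batch are collected and
reported, not fatal.

## Network profiles and leakage

The profile feature of a pair excludes the query target's column and the
query drug's row, giving (n_t − 1) + (n_d − 1) bits regardless of the
pair. Whether published cross-validated results of profile-based
predictors masked held-out edges before building profiles is usually
unknowable; unmasked profiles *contain the test label*. The default here
is strict: during CV the held-out positive edges are zeroed
(`mask_test_edges`) before any training- or test-fold profile is built.
The permissive variant is available (`--oracle-network`) for comparison
with evaluations that did not mask.

## Datasets

Balanced subsets contain every known interaction plus an equal-count
uniform sample (without replacement) of unknown pairs; the ten default
subsets differ only in the negative draw and may share negatives
(independent sampling — expected pairwise overlap m²/N, verified by
test). Degree-matched negative sampling is deliberately not the default.
The imbalanced regime labels all n_d × n_t pairs by adjacency. Folds are
stratified and seeded, assigned per subset.

## Synthetic benchmark

The generator emulates the three real inputs with a planted
latent-group signal. Drugs and targets belong to 4 hidden groups;
membership is expressed in

- a 10-bit fingerprint block per group firing at probability 0.1 + 0.8·s
  against a 0.1 baseline,
- 5 group-specific amino acids oversampled by a factor 1 + 3·s in the
  target's composition (lengths uniform on 100–600),
- interaction sampling weight = drug-group affinity × target-group
  affinity × (1 + 15·s for group-matched pairs), with affinity
  multipliers (1 + 2s)^g — graded binding propensity emulating
  promiscuous scaffolds and druggable target families.

s = 0 reduces everything to uniform noise. A purely symmetric
group-match signal was rejected during design: it is a second-order
interaction with no marginal component, which a linear-weight feature
ranker cannot see; real DTI networks show strong marginal structure
(heavy-tailed degrees, family-specific interaction rates). The defaults
(100 drugs × 80 targets, 400 edges, s = 1) are calibrated so that the
pipeline's balanced 5-fold AUC lands in the low-to-mid 0.9s — the
separability regime reported for this feature family on the real
gold-standard collections.

What the generator does **not** emulate: real sequence statistics
(domain structure, conserved motifs, length–family correlation),
correlated fingerprint bits from shared scaffolds, transitive network
structure beyond the group model, and dataset-specific degree
distributions. Passing the planted-signal tests therefore shows the
pipeline is wired correctly end to end and can recover a known signal
through its own features — not that any particular accuracy will be
achieved on real collections.

## Feature selection

SVM-RFE with a linear ranking SVM (the squared-weight criterion needs an
explicit weight vector; the final classifier stays RBF). Correlation-bias
reduction is implemented as group-max scoring: features with absolute
pairwise correlation above the threshold (default 0.9) form connected
components, and each member inherits the component's best score, so a
duplicated informative feature cannot be eliminated early. This is one
defensible reading of "correlation bias reduction"; variants exist.
Elimination removes 10% of survivors per iteration (at least one, never
the last survivor); ranks are reverse elimination order, ties broken by
raw score then feature index. Constant-variance columns are pre-filtered
with a warning and assigned the worst ranks. `select_top_k("auto")`
picks k from a 12-point logarithmic grid by inner stratified-CV AUC on
the training fold only.

## Classifier and evaluation

Per-feature z-scoring uses training-fold statistics; zero-variance
columns get scale 1 so binary blocks pass through. Defaults C = 8,
γ = `scale`; an inner-CV grid search over C ∈ 2^{−5..15}, γ ∈ 2^{−15..3}
(powers of 4) is available as `'grid'` and recorded in model metadata.
AUPR uses step-wise precision–recall integration (average precision);
linear PR interpolation is avoided because it inflates AUPR. Probability
ranking uses Platt scaling (`CalibratedClassifierCV`, sigmoid,
`ensemble=False`) fit on training data only; raw decision values are the
default. Novel-pair ranking sorts unknown pairs by score, ties broken
lexicographically by (drug_id, target_id).

## Problem sizes

The acceptance script and test suite run the full pipeline on the
default 100×80 benchmark (800 balanced samples, 656 features, 5 folds,
per-fold RFE to k = 300), which completes in well under a minute on one
CPU; oracle checks use 100 random signals each. Full-scale replication
on the real gold-standard collections (hundreds of drugs/targets,
thousands of interactions) is supported through the same loaders but is
an external workflow: those files are not redistributed here.

## Known limitations

- Heavy class imbalance is not remedied (no weighting or resampling);
  AUPR on very sparse networks will be modest, as expected for an
  unweighted SVM.
- Feature ranking is linear; purely non-marginal interaction signals are
  invisible to it (the final RBF stage can still use such features if
  they survive selection).
- MACCS bit parity across toolkits is not guaranteed; record the toolkit
  version with any exported fingerprint table.
- The wavelet family/boundary/DCT-scope conventions materially change
  feature values; all are recorded in layouts and manifests, and results
  should only be compared across runs with identical conventions.
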