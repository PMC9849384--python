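# Methods

## Variant model and classification

A variant is one substitution W → M at an author-numbered position of a
PDB chain, with an experimentally measured ΔΔG = ΔG_M − ΔG_W in kcal/mol
(destabilizing = negative).  The individual ΔG values are never inputs;
only their difference is observable in the curated tables.  Variants are
partitioned at ±0.5 kcal/mol — the average experimental error — with the
boundaries assigned to the non-neutral classes (ΔΔG ≤ −0.5 destabilizing,
ΔΔG ≥ +0.5 stabilizing, the open interval between them neutral).  The
thermodynamic reverse of a variant swaps the residues and negates ΔΔG
(ΔΔG_WM = −ΔΔG_MW); the operation is an involution up to a provenance tag.

Datasets are deduplicated and merged on the key (protein, chain, position,
wild-type, mutant); the key is a design choice — repeated measurements of
the same substitution collapse to the highest-priority source, and
colliding measurements more than 0.5 kcal/mol apart are reported as
conflicts rather than silently resolved.  Pairwise and higher-order key
overlaps are reported with every merge, and composition percentages are
rounded half-away-from-zero for display (full precision in the TSVs).

## The seven features

* **Hydrophobicity difference** h(W) − h(M), Kyte-Doolittle hydropathies.
  The orientation (wild-type minus mutant) is a configurable flag: only a
  sign convention, chosen so the feature anti-correlates with ΔΔG on real
  data.
* **Volume difference** V(M) − V(W) in Å³ (Zamyatnin crystallographic
  volumes), oriented mutant-minus-wild-type so that a positive value means
  the substitution crams a larger side chain into the site — the
  disruptive direction.  Configurable.
* **Conservation log-ratio** ln((CONS_W + ε)/(CONS_M + ε)) with ε = 0.01,
  from a per-position amino-acid frequency profile.  Natural log: the base
  only rescales the feature, so correlations and AUCs are invariant.
  Positive when the substitution moves to a less conserved residue.  A
  position absent from the profile yields a missing value, never zero.
* **Substitution-matrix score** B(W, M) from BLOSUM62 (or any matrix in
  NCBI text format).  Symmetric in W and M by construction.
* **Relative solvent accessibility**: absolute ASA divided by the
  residue-type theoretical maximum (Tien et al. set), clipped to [0, 1].
  ASA comes from a precomputed DSSP file when one is supplied; otherwise it
  is computed on the wild-type structure with the Shrake-Rupley rolling-
  probe method.  The provenance difference only shifts absolute ASA
  slightly; both routes are normalized by the same maxima.
* **Skolnick sequence-contact difference** Σ_i sk(W, a_i) − sk(M, a_i) over
  window offsets {−2, −1, +1, +2} in the wild-type chain sequence,
  truncated at the termini.  The self-offset 0 is excluded by default — a
  pairwise contact potential has no self-interaction term — but a config
  switch restores the literal i = 0 term for comparison.
* **Bastolla-Vendruscolo structural-contact difference** over the
  neighborhood I of the mutated residue: all residues whose *minimal
  heavy-atom distance* to it is ≤ 5 Å, excluding the residue itself;
  Cβ-only and Cα-only metrics are available by configuration.  An empty
  neighborhood contributes 0.

All features are computed on the wild-type structure; no mutant modelling.
Five features negate exactly under W ↔ M; B(W, M) and the accessibility
are swap-invariant.  This symmetry split is the mechanical explanation for
why symmetric scores cannot tell a stabilizing substitution from the
destabilizing reverse of the same residue pair.

**Exclusions.** A variant whose structural neighborhood cannot be resolved
— structure missing, residue absent, or the structure's residue type
contradicting the table's wild-type — is excluded with reason
"3D neighbors" and logged; the count is data-driven, never hard-coded.
Missing non-structural resources produce per-feature missing values.

## Evaluation protocols

Stratified metrics report Pearson ρ and RMSE per class, on the whole set,
and on the non-neutral subset; strata with fewer than two points (or zero
variance) report ρ as missing rather than a fabricated value.

The balanced-resampling protocol draws `per_class` variants per class
without replacement (independently re-drawn across subsets), 100 times by
default; `per_class` defaults to half the smallest class — 328 for a
corpus with 656 stabilizing variants, giving subsets of 984.  A single
master seed expands to per-subset child seeds (numpy `SeedSequence`), so
any individual subset is reproducible in isolation.

Pairwise-class discrimination draws balanced subsets from each pair of
classes (656 variants per subset at the default size) and computes the
rank-based AUC with mid-rank tie handling, which equals Mann-Whitney
U/(n₁n₂) exactly.  The positive label is the higher-ΔΔG (more stabilizing)
class of the pair, and the three anti-correlated features (conservation
log-ratio, volume and hydrophobicity differences) are scored with opposite
sign, so every reported AUC reads "above 0.5 = discriminative in the
expected direction".  Mann-Whitney p-values are two-sided, computed on the
full class distributions by default (a per-subset option exists); exact
enumeration is used for tie-free samples of at most 20 per group,
otherwise the tie-corrected normal approximation.

## Predictors

The untrained linear scorer combines component scores with fixed weights
(0.20, 0.29, 0.18, 0.33; accessibility offset 1.1); the components default
to this package's feature implementations through a documented adapter
map, so alternative component transforms can be plugged in.  The ablation
trains a Random-Forest regressor (scikit-learn, library-default
hyperparameters unless overridden, all seeds recorded) on repeated
balanced subsamples of the training pool — per-class size again half the
smallest training class — and evaluates on a fixed test set guarded
against key overlap.  Test metrics are computed on the per-variant *mean*
prediction across the subsample models (an ensemble); the per-model spread
of the total metrics is emitted alongside, since the alternative
aggregation (averaging metrics over models) is also defensible.

## Synthetic data

The generator emulates the statistical structure of the curated benchmark
corpus: 4,428 variants at 55/30/15 class proportions, with per-class ΔΔG
drawn from truncated Gaussians confined to the class bands.  Defaults:
destabilizing N(−1.0, 0.9²) on (−∞, −0.5], neutral N(0, 1.5²) on
(−0.5, 0.5) (wide scale ⇒ the band fills nearly uniformly), stabilizing
N(0.8, 0.9²) on [0.5, ∞).  These were chosen so the pooled histogram is
unimodal with mode near −1 kcal/mol, matching the shape of the real
corpora; the per-class shapes themselves are not identifiable from pooled
histograms and are configurable.

Features with target per-class correlations are built as
f = ρ_c·z_c + √(1 − ρ_c²)·ε within each class, with z_c the within-class
standardized ΔΔG — exact in expectation, so recovery tests use ±3/√n-style
tolerances.  Under this construction the feature's class means are zero
and the *pooled* balanced correlation is attenuated by the between-class
ΔΔG spread, with the closed form Σ_c ρ_c σ_c / (k σ_bal) (implemented as
`expected_balanced_correlation` and used as the oracle in tests).  For
correlation patterns like the substitution-matrix one
(+0.26 / −0.02 / −0.18) the attenuated value lands near the class average,
which is the behaviour observed on real data.

Toy structures are short peptides with a fixed five-heavy-atom residue
template on an extended (3.8 Å CA spacing) or ideal-helix CA trace —
deterministic, collision-free geometry adequate for distance-cutoff and
exposure tests, not chemically realistic.  Profiles assign the native
residue a chosen conservation level with the remainder spread evenly.
Matrices are random symmetric 20×20 arrays written in the same file
formats the real resources use.

What passing synthetic tests do **not** show: real features are not
Gaussian within classes, real class means of features are not zero, real
structures have irregular packing, and real conservation profiles carry
phylogenetic correlation.  Results on synthetic data validate the
*protocols* (estimators, resampling, symmetry mechanics), not the
empirical feature rankings, which require the curated tables, structures
and alignments.

## Numerical and design choices

* Correlation errors (zero variance, n < 2) raise or report missing —
  never silently 0.
* AUC ties are mid-ranked; `auc(s) + auc(−s) = 1` holds exactly.
* Resample std is the sample std (ddof 1) across subsets.
* The 19-exclusion-style curation is implemented as a rule (unresolvable
  neighborhood ⇒ drop + log), not a hard-coded count.
* RF determinism: per-subset child RNGs seed both the subsample draw and
  the forest, so a fixed config reproduces metric tables bit-identically.
* Problem sizes in the test suite and acceptance script (50,000-variant
  recovery corpora, 100 × 328 resampling, 2,000/500 ablation tables with
  10-model forests) were chosen as the smallest sizes at which the
  Monte-Carlo tolerances above are comfortably resolvable.

## Known limitations

* No mmCIF input; PDB coordinate files only.
* Conservation profiles are consumed, never computed from alignments.
* The external-predictor comparison layer accepts prediction tables but no
  wrappers for running third-party tools are included.
* The linear scorer's component transforms default to this package's
  feature definitions; the original tool's exact internal scalings are not
  re-derived, so absolute (not relative) scores may differ from it.
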