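# ddgfeat

Substitution features and class-balanced evaluation for protein-stability
(ΔΔG) prediction.

## The problem

Single amino-acid substitutions change a protein's unfolding free energy by
ΔΔG = ΔG(mutant) − ΔG(wild-type) (kcal/mol; negative = destabilizing under
this convention).  Computational ΔΔG predictors are consistently worse on
*stabilizing* variants (ΔΔG ≥ 0.5) than on destabilizing ones (ΔΔG ≤ −0.5),
and the benchmark corpora are heavily skewed — roughly 55 % destabilizing,
30 % neutral (|ΔΔG| < 0.5, the average experimental error), 15 % stabilizing.
`ddgfeat` implements the machinery needed to ask *why*: it computes the
seven residue-substitution features that most predictors consume, measures
their per-class informativeness with protocols that remove the class
imbalance, and runs a feature-ablation experiment on two predictors.

It is aimed at structural bioinformaticians benchmarking or designing
stability predictors.

## What it computes

**Seven features** for a substitution W → M at a structure position:
Kyte-Doolittle hydrophobicity difference h(W) − h(M); residue-volume
difference V(M) − V(W) (Å³); conservation log-ratio
ln((CONS_W + ε)/(CONS_M + ε)), ε = 0.01; BLOSUM62 score B(W, M); relative
solvent accessibility (ASA / max-ASA ∈ [0, 1]); Skolnick sequence-contact
potential difference Σ_{i=±1,±2} sk(W, a_i) − sk(M, a_i); and the
Bastolla-Vendruscolo structural-contact difference Σ_{i∈I} bv(W, a_i) −
bv(M, a_i) over the 5 Å neighborhood I of the mutated residue.  Five of
these negate exactly under the W ↔ M swap; B(W, M) and the accessibility
are swap-invariant — which is precisely why a symmetric score cannot
separate stabilizing variants from destabilizing ones on
thermodynamically paired data (ΔΔG_WM = −ΔΔG_MW).

**Evaluation**: stratified Pearson ρ = Cov(ΔΔG_exp, ΔΔG_pred)/(σ_exp σ_pred)
and RMSE per class / total / non-neutral; mean ± std correlation over 100
random balanced subsets (default 328 per class, drawn without replacement);
pairwise-class AUC-ROC (rank-based, mid-rank ties, identical to
Mann-Whitney U/(n₁n₂)) on balanced draws, with the conventional sign flip
for anti-correlated features; two-sided Mann-Whitney tests.

**Predictors**: the untrained linear scorer

    score_full = 0.20·S_Bl + 0.29·S_Sk + 0.18·S_Hp + 0.33·S_BV·(1.1 − acc)

with "reduced" (drop S_Bl, S_Hp) and "red-no-acc" (also drop acc) variants,
and a Random-Forest regressor trained on repeated balanced subsamples and
ablated over the same three feature sets.

**Synthetic data**: generators for variant tables with the empirical
55/30/15 imbalance, features with target per-class correlations, toy PDB
structures, conservation profiles and symmetric potential matrices — the
whole pipeline runs without any downloads.

## Worked example

```bash
ddgfeat make-fixtures --out-dir fx --seed 3
cat > fx/config.yaml <<EOF
data_dir: fx
out_dir: out
skolnick: matrices/skolnick.tsv
bv: matrices/bv.tsv
blosum: matrices/substitution.mat
n_subsets: 20
per_class: 2
seed: 0
EOF
ddgfeat features --config fx/config.yaml
ddgfeat evaluate --config fx/config.yaml --features-table out/features.tsv
```

prints

```
features: 17 variants scored, 0 excluded
            feature  total  total_balanced_mean  total_balanced_std  destabilizing  neutral  stabilizing
hydrophobicity_diff  -0.34                -0.46                0.26          -0.67     0.01        -0.93
        volume_diff  -0.07                -0.23                0.31           0.62     0.39         0.19
     cons_log_ratio  -0.23                -0.39                0.40           0.71    -0.18         0.19
       blosum_score  -0.01                -0.10                0.43          -0.42    -0.40        -0.46
      accessibility  -0.15                -0.18                0.29          -0.36     0.11        -0.34
      skolnick_diff  -0.07                 0.08                0.39          -0.34    -0.18         0.51
            bv_diff   0.41                 0.55                0.19          -0.18     0.75         0.61
```

`features` evaluates all seven features for every variant of the toy study
(17 variants survived deduplication; none needed structural exclusion).
`evaluate` then reports, per feature, the Pearson correlation with the
experimental ΔΔG on the whole table ("total"), its mean ± std over balanced
class subsets, and the correlation inside each class.  On a 17-variant toy
fixture these numbers are dominated by sampling noise — they demonstrate
the workflow, not a scientific result; the statistically meaningful runs
are the synthetic-corpus analyses in `scripts/acceptance.py` and the test
suite.

A broken-input run (`ddgfeat make-fixtures --break-structure …`) drops the
variants of the missing structure and logs each with reason "3D neighbors",
mirroring the curation rule for unresolvable structural neighborhoods.

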