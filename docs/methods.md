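# Methods

## Imputation model

HLA imputation is cast as per-haplotype multiclass classification. Phased
haplotypes are assumed as input: reference panels in the SNP2HLA/Beagle
ecosystem are distributed phased, and target GWAS data are expected to be
pre-phased upstream. For a group of neighbouring genes the SNVs inside the
group window (each gene position ± `window_bp`, default 500,000 bp, 1-based
inclusive) are encoded as a 2×W one-hot array per haplotype (row 0 reference,
row 1 alternative; columns always sum to 1).

The network is a shared trunk — Conv1d(2→c₁, k₁) · BatchNorm · ReLU · Dropout
· MaxPool(2) · Conv1d(c₁→c₂, k₂) · BatchNorm · ReLU · Dropout · MaxPool(2) ·
Flatten · Linear(→f) · ReLU · Dropout — followed by one Linear head per gene
with as many outputs as that gene carries alleles at the trained resolution,
and a softmax. Per-haplotype probabilities therefore sum to 1 per gene, and
an individual's diploid dosage (the sum over its two haplotypes) to 2; this
conservation property is what makes amino-acid dosages derived from 4-digit
allele dosages internally consistent.

Defaults are c₁ = 128 filters (kernel 7), c₂ = 64 (kernel 5), pool 2, shared
FC 256 units, dropout 0.25, batch 64, Adam at 1e-3, up to 200 epochs with
patience 20. These are design choices; they can be overridden per panel, and
the test suite uses smaller networks matched to its small synthetic windows.
The layers are implemented directly in numpy with hand-written backward
passes; this keeps the model differentiable end to end in inference mode,
which the sensitivity maps require, and makes every random draw (init,
splits, shuffling, dropout masks) an explicit seeded generator stream.

### Training

Per-gene categorical cross-entropy losses are minimised jointly. At each
step the per-task gradients with respect to the shared representation are
balanced by MGDA-UB: the weight vector on the probability simplex minimising
‖Σ_t w_t g_t‖². For one task the weight is 1; for two tasks the line search
is analytic; for up to six tasks the quadratic programme is solved exactly by
active-set (support) enumeration; beyond that Frank–Wolfe iteration is used.
Shared parameters receive the weighted gradient, head parameters their own
unweighted gradients. Haplotype order is reshuffled every epoch.

Early stopping: 5% of *samples* (never splitting an individual's two
haplotypes, to avoid leakage) form a sub-validation set used only to pick the
stopping epoch; the parameter snapshot at the best sub-validation loss is
restored. Inside cross-validation this split is drawn from the training fold
only, so held-out folds never influence stopping.

Hierarchical fine-tuning trains the 2-digit model first and initialises each
finer resolution's shared trunk (including batch-norm running statistics)
from the coarser model. Haplotypes untyped at a fine resolution fall back to
their coarser label, keeping hierarchical levels aligned across genes.

### Imputation

Inference runs with dropout off and batch-norm running statistics. Model
variants absent from a target panel are filled with the reference one-hot and
a logged warning; more than 50% missing (configurable) is an error, and a
strict mode errors on any missing variant.

## Accuracy metrics

All metrics operate on dosages under the *optimal diploid arrangement*: for
each individual the two truth alleles are assigned to the haplotype
arrangement with the larger credited probability mass. This fixes which
haplotype "carries" each truth allele, giving haplotype-level attribution for
the per-allele decompositions, and automatically caps an individual's credit
at 2 (relevant for homozygotes scored from external dosage files).

- Se(L) = Σᵢ (Dᵢ(A1ᵢ)+Dᵢ(A2ᵢ)) / 2n, credited mass over observations.
- Se(A) = mean credited dosage over the m true carrier haplotypes; the locus
  value is exactly the carrier-weighted mean of the allele values.
- PPV(A) = credited mass / total imputed mass of A.
- r²(A): squared Pearson correlation of imputed vs typed diploid dosage;
  undefined (flagged, excluded from aggregates with a count) when either
  vector is constant.
- CR: the sensitivity formula applied to hard best-guess calls (per-haplotype
  argmax; exact ties break to the lexicographically first allele name and are
  logged).

Aggregates (per locus or per cumulative frequency bin, default thresholds
0.5%, 1%, 2%, 5%, 10%, 50%, all) are allele-frequency-weighted arithmetic
means; r² is aggregated by Fisher z-transforming the *signed* correlation
(clamped to ±(1−10⁻¹²)), averaging with weights, back-transforming and
squaring. Samples with unknown truth at a locus are excluded from that
locus's metrics. Cross-validation pools held-out probabilities across folds
before computing metrics and uses full-panel allele frequencies.

A deliberately simple baseline imputer is included for contrasts: the
1-nearest training haplotype by Hamming distance within the window,
probability 1 on its allele, ties averaged.

## Diagnostics

**LD-decay AUC.** For an allele, r² between its carrier indicator and each
SNV is computed across panel haplotypes (monomorphic SNVs get r² = 0,
flagged). SNVs are ranked by distance from the gene's representative
coordinate; the cumulative r² curve is normalised to [0, 1] on both axes
(x = rank/W — rank-based rather than bp-based, which is robust to irregular
marker spacing) and integrated by the trapezoid rule from the origin (0, 0).
Under this convention a uniform profile integrates to exactly 0.5, all mass
on the single nearest SNV to 1 − 1/(2W), and convex-upward (distance-decaying)
profiles exceed 0.5. The companion index is the maximum r² within the 100
bilaterally nearest SNVs. Accuracy–LD relationships are summarised by OLS of
a per-allele metric on (AUC, allele frequency) with intercept.

**SmoothGrad.** Per carrier haplotype, Gaussian noise (default sd 0.1) is
added to the continuous relaxation of the one-hot input n = 200 times; the
absolute gradient of the allele's pre-softmax score w.r.t. the input,
summed over the two channels, is averaged over noise draws and carriers.
With sd 0 the map equals the plain absolute gradient.

**MC-dropout uncertainty.** T = 200 stochastic forward passes (dropout
active, batch-norm in inference mode) yield T diploid best-guess genotypes;
t counts agreements with the deterministic best guess and the uncertainty is
the binary entropy H = −(t/T·ln(t/T) + (T−t)/T·ln((T−t)/T)) in natural log
(the base only rescales and cannot change a ROC). The comparison score
("dosage-based discrimination") is the posterior probability of the
deterministic best-guess genotype, the product of the two haplotype argmax
probabilities. ROC-AUC for flagging incorrect genotypes uses the midrank
Mann–Whitney convention.

## Fine-mapping

Variants are filtered on cross-validated dosage r² ≥ 0.7 (boundary
inclusive). Logistic regression is fit by IRLS to gradient norm < 1e-8 (max
100 iterations) with aliased design columns dropped and logged; diverging
coefficients (quasi-complete separation) are flagged and their Wald
statistics suppressed rather than raising. Biallelic markers get Wald tests;
multiallelic amino-acid positions get a likelihood-ratio omnibus test of the
k−1 residue dosage columns (most frequent residue in a designated reference
cohort excluded as the reference level), χ² with df = k−1. The LRT was
chosen as the standard convention for multiallelic HLA tests.

Forward stepwise conditioning scans all remaining units each round, selects
the minimum p (ties by variant name), and, when it passes 5×10⁻⁸, extends
the conditioning set: with the unit's own columns inside the configured
tight-LD gene set (default DRB1/DQA1/DQB1, where conditioning on a whole
gene would blind neighbouring genes' signals), otherwise with all 4-digit
alleles of the unit's gene minus a reference allele. Separation-flagged
results are excluded from selection unless nothing else is testable.

Trans-ethnic merging takes the union of classical alleles and residues
(dosage 0 where a variant is absent from a population), the intersection of
SNVs minus palindromic (A/T, C/G) variants, block-diagonal population PCs
zero-filled off-block, and appended population indicator dummies.

Variance explained: the squared correlation between phenotype and the risk
variants' linear predictor (observed scale) is mapped to the liability scale
by the threshold-model transformation with ascertainment correction,
R²_liab = R²_obs·K²(1−K)²/(z²P(1−P)) with K the population prevalence, P the
sample case fraction and z the standard-normal density at the threshold.
This specific form is an implementer choice, validated in the tests against
a direct liability simulation on a one-variant model.

## Synthetic panels

The generator emulates the statistical features the method consumes, not
population-genetic realism (no coalescent, no mutation-rate calibration).
Each gene's 4-digit alleles own a canonical binary SNV backbone over the
gene's segment of the window; a haplotype carrying allele a copies a's
backbone with probability φ (tagging fidelity), else a random backbone;
backbone identity may switch along the map with per-interval probability ρ
(recombination mosaic); each SNV flips independently with probability ε.
Allele frequencies come from a skewed Dirichlet or explicit vectors (rare
alleles down to 0.5%); 4-digit alleles group in pairs under 2-digit parents;
residues are assigned so position 1 separates every allele pair while later
positions are low-cardinality polymorphisms. With tag placement "near"/"far"
the alleles share one backbone except at tag SNVs adjacent to the gene or at
the window edge; tag codes are drawn with pairwise Hamming distance ≥ 2, as
classical alleles differ at multiple linked SNVs and a single genotyping
error should not convert one allele into another. Two-population mode
perturbs frequencies on the logit scale and can make the rarest alleles
private to one population. Cohorts are haplotype pairs drawn from the panel
(population-specific pools in two-population mode) with case/control status
from a logistic model on true allele/residue dosages plus covariates.

Because backbones are exact templates, the 1-nearest-haplotype baseline is
close to the maximum-likelihood decoder of this generator; passing tests
therefore demonstrate correctness and calibration of the pipeline, not that
the network dominates every alternative on real panels, where haplotype
backgrounds are heterogeneous and reference panels are an order of magnitude
larger.

## Problem sizes and observed behaviour

The test suite and the acceptance script run deliberately small
configurations chosen to keep the noiseless and noisy regimes cleanly
separated: panels of 400–1400 haplotypes over 30–100 SNVs, networks of
12–32 filters, 3–10-fold cross-validation. At these sizes the noiseless
panel is recovered at concordance ≥ 0.99 by both the network and the
1-nearest-backbone oracle; the omnibus test is calibrated (null rejection
≈ 5% at α = 0.05 over 2000 replicates); a planted residue is recovered and
the stepwise scan stops in ≥ 18/20 cohorts; and merged two-population
cohorts strengthen a shared signal in ≥ 15/20 replicates.

Two directional contrasts do not reproduce on this generator, and their
tests are left failing rather than weakened: the network's pooled
rare-allele dosage PPV approaches but does not exceed the
1-nearest-haplotype baseline (which sits at the generator's
decision-theoretic ceiling, unlike the localized-haplotype-cluster methods
the contrast was originally formulated against), and the MC-dropout entropy
and genotype-probability scores rank incorrect genotypes with statistically
indistinguishable ROC-AUCs (the agreement entropy is non-monotone in t,
folding confidently-divergent errors back to low uncertainty). Both
behaviours are measured, not asserted away; the relevant tests document the
margins.

## Known limitations

- Unphased input is out of scope; pre-phase upstream.
- Multiallelic SNVs are rejected at parse; panels must be complete.
- 6-digit resolution is supported by the hierarchy but the bundled simulator
  generates 2- and 4-digit labels.
- The bundled gene coordinates are approximate GRCh37 starts, sufficient for
  grouping and windowing; supply a coordinate table for other builds.
- Per-allele uncertainty (as opposed to per-genotype) is not modelled.
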