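# hlaconv

Multitask convolutional imputation of classical HLA alleles and amino-acid
polymorphisms from phased SNV haplotypes, with dosage-based accuracy metrics,
model diagnostics (LD-decay indices, SmoothGrad sensitivity maps, Monte-Carlo
dropout uncertainty) and trans-ethnic stepwise MHC fine-mapping.

## The problem

Association signals in the MHC region (chr6p21.3) are usually resolved down to
classical HLA alleles and their amino-acid residues by *HLA imputation*:
inferring HLA genotypes from flanking SNV haplotypes using a reference panel
typed for both. Conventional imputation degrades for low-frequency alleles,
which is exactly where trans-ethnic fine-mapping needs reliable dosages,
because risk alleles common in one population are often rare in another.

`hlaconv` implements a deep-learning approach to this problem end to end:

- **Model.** For each group of neighbouring HLA genes, each phased haplotype's
  SNVs inside the group window (±500 kb by default) are one-hot encoded and
  passed through a shared trunk — two 1-D convolution + batch-norm + max-pool
  blocks and a fully-connected layer — into per-gene softmax heads, one output
  per classical allele. Per-haplotype allele probabilities therefore sum to 1
  and diploid dosages to 2. Training minimises per-gene categorical
  cross-entropy with Adam, balances the genes' losses each step with MGDA-UB
  (the min-norm point of the task gradients at the shared representation),
  early-stops on a 5% sub-validation split, and transfers the shared trunk
  from 2-digit to 4-digit to 6-digit resolution (hierarchical fine-tuning).
  The network is implemented directly in numpy with hand-written backward
  passes, so inference is differentiable end to end for the diagnostics.
- **Accuracy metrics.** Dosage sensitivity Se(L) = Σᵢ(Dᵢ(A1ᵢ)+Dᵢ(A2ᵢ))/2n
  under the optimal diploid arrangement, its per-allele decomposition Se(A),
  PPV(A) (credited over total imputed mass), dosage r², and the best-guess
  concordance rate; locus and frequency-bin aggregates are frequency-weighted,
  with r² averaged through Fisher's z.
- **Diagnostics.** Distance-dependent LD decay summarised as the AUC of the
  normalised bilateral cumulative r² curve; SmoothGrad input-sensitivity maps;
  MC-dropout uncertainty H = −(t/T·ln t/T + (T−t)/T·ln (T−t)/T) with ROC
  comparison against the best-guess genotype probability.
- **Fine-mapping.** Post-imputation r² ≥ 0.7 filtering, additive logistic
  association (IRLS), likelihood-ratio omnibus tests over the k−1 residue
  dosages of each amino-acid position, forward stepwise conditioning at
  P < 5×10⁻⁸ with gene-level or variant-level conditioning sets, trans-ethnic
  cohort merging (zero-filled population PCs, population indicator,
  absent-allele convention, palindromic-SNV removal) and liability-scale
  variance explained.
- **Synthetic panels.** Real HLA reference panels are access-restricted, so a
  simulator generates phased panels with the statistical structure the method
  consumes — per-allele SNV backbones, tunable tagging fidelity, skewed
  frequency spectra with rare alleles, recombination mosaics, two-population
  structure — plus case-control cohorts from a logistic disease model.

## Worked example

```python
import hlaconv as h

# a phased reference panel: two HLA genes, four alleles each, 200 samples
cfg = h.SimConfig(n_haplotypes=400, n_snvs_per_group=80,
                  snv_noise_rate=0.02, tagging_fidelity=0.95, seed=7)
sim = h.simulate_reference_panel(cfg)

hp = h.ModelHyperparams(conv1_filters=16, conv2_filters=16, kernel1=5,
                        kernel2=3, shared_fc_units=64, dropout_rate=0.15,
                        batch_size=64, learning_rate=2e-3,
                        max_epochs=40, patience=8, seed=0)

# 5-fold cross-validated imputation accuracy
_, alleles, loci = h.cross_validate(sim.panel, sim.group, hp, k=5, seed=0)
print(loci.round(4).to_string(index=False))
print(h.aggregate(alleles)[["bin", "n_alleles", "Se", "PPV", "r2", "CR"]]
      .round(4).to_string(index=False))
```

prints

```
gene   n     Se    CR
  G1 200 0.8692 0.945
  G2 200 0.8475 0.955
  bin  n_alleles     Se    PPV     r2     CR
<=0.1          1 0.5823 0.6890 0.6270 0.6667
<=0.5          7 0.8358 0.8396 0.8293 0.9429
  <=1          8 0.8583 0.8631 0.8372 0.9500
  all          8 0.8583 0.8631 0.8372 0.9500
```

Per-locus rows give dosage sensitivity and best-guess concordance on the
held-out folds; the binned table aggregates per-allele metrics over alleles
with frequency below each threshold (the single allele under 10% frequency is
imputed markedly worse than the common ones — the behaviour the rare-allele
analyses quantify). On a noiseless panel (`snv_noise_rate=0`,
`tagging_fidelity=1`) the same pipeline reaches concordance ≥ 0.99.

A thin CLI wraps the same functions for shell use:

```bash
hlaconv simulate --config sim.yaml --out panel
hlaconv train    --panel panel.bgl.phased --hp hp.yaml --out models/
hlaconv impute   --model models/synthetic --target panel.bgl.phased --out dosage.tsv
hlaconv evaluate --panel panel.bgl.phased --k 10 --out report.tsv
hlaconv finemap  --dosages dosage.tsv --pheno pheno.tsv --out state.json
```

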