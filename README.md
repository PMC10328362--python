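# linaprs

Multi-task linearizing neural networks for parallel polygenic risk score
(PRS) estimation across many binary disease traits, with a decoy-SNP
false-discovery interpretation pipeline and a synthetic cohort simulator.

## Who this is for

Statistical geneticists and ML-for-genomics researchers who want to study —
or extend — joint PRS estimation across comorbid diseases without needing
biobank access. Many complex diseases share genetic determinants; training
one model to predict a whole vector of traits can transfer knowledge between
related diseases and beat per-disease models, especially for rare traits
where cases are scarce. This package provides the model, the single-task
baseline, the benchmarking and interpretation machinery, and a simulator
that generates cohorts with exactly the structure the method assumes.

## The model

For a genotype vector *X* ∈ {0,1,2}<sup>m</sup> (0 = homozygous minor
allele) the multi-task model predicts d trait probabilities as

    Y = σ(K · (A ∘ X) + B),        A = F(X)

where *F* is a three-hidden-layer attention subnetwork (leaky-ReLU, dropout,
batch-norm; linear m-unit attention output), ∘ is the element-wise product,
**K** is a d × m coefficient matrix and *B* a bias vector. The loss is
**W**ᵀ**E** + β‖**K**‖₂ (per-trait cross-entropies **E**, Frobenius
penalty). Given *A*, every trait's prediction is *exactly* a logistic-linear
model with coefficients K<sub>tj</sub>A<sub>j</sub>(x) — so per-SNP
importance scores, decoy-based FDR control, per-trait selected SNP sets, and
Spearman genetic correlations between traits all follow without any
approximate attribution method. Second-order (SNP–SNP interaction) scores
are equally exact: the Hessian of the pre-sigmoid output is
K<sub>ik</sub>J<sub>kl</sub> + K<sub>il</sub>J<sub>lk</sub> with *J* the
attention Jacobian.

See `docs/methods.md` for the full model description, the simulator's
generative assumptions, and known limitations.

## Worked example

```python
import linaprs as lp

# a cohort of 4000 subjects, 300 SNPs, 8 traits at 5% prevalence,
# 20 causal SNPs per trait of which 80% come from a shared pleiotropic pool
cfg = lp.SimConfig(seed=7)
geno, effects, phen = lp.simulate_cohort(cfg)

# train the multi-task model and one single-task baseline
X, Y = geno.genotypes.astype(float), phen.outcomes
split = lp.split_cohort(cfg.n_subjects, seed=7)
mcfg = lp.MTLModelConfig(n_snps=300, n_traits=8, hidden_sizes=(64, 32, 16))
model = lp.init_model(mcfg, seed=7)
tcfg = lp.TrainConfig(batch_size=128, learning_rate=2e-3, n_epochs=40, seed=7)
res = lp.train(model, X, Y, split, tcfg)
model, best = lp.select_best_checkpoint(res.checkpoints, model,
                                        X[split.val_idx], Y[split.val_idx])
rec = lp.evaluate_model(model, X[split.test_idx], Y[split.test_idx],
                        phen.trait_names)
print(rec.table.head(3).to_string(index=False))
```

prints (best checkpoint at epoch 39):

```
 trait  prevalence  roc_auc   pr_auc
trait0    0.055000 0.762600 0.184744
trait1    0.038333 0.737623 0.113825
trait2    0.056667 0.792039 0.289865
```

Each row is one trait's test-set ROC AUC and PR AUC; the ROC baseline is 0.5
and the PR baseline the trait's prevalence (~0.04–0.06), so AUCs of
0.74–0.79 and PR AUCs of 0.11–0.29 reflect substantial polygenic signal
recovered from a heritability-0.5 liability. The same pipeline end-to-end, including the
decoy-SNP interpretation and genetic-correlation report, is one call
(`lp.run_experiment(lp.ExperimentConfig())`) or one shell command:

```bash
linaprs run --seed 7 --out results/demo
```

A transfer comparison against per-trait single-task models
(`lp.positive_transfer_study(seed=1, n_seeds=1)`) prints

```
   seed  mtl_mean_auc  stl_mean_auc       gap
0     1       0.80578      0.784498  0.021282
```

— the jointly trained model beats the matched single-task models by ~0.02
mean ROC AUC when 80% of causal SNPs are shared across traits.

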