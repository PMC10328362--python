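# Methods

## The model

`linaprs` implements a multi-task linearizing network for parallel polygenic
risk score (PRS) estimation across many binary disease traits. For a subject
with genotype vector *X* ∈ {0,1,2}<sup>m</sup> (0 = homozygous minor, 1 =
heterozygous, 2 = homozygous major), the model predicts the d-trait outcome
vector

&nbsp;&nbsp;&nbsp;&nbsp;*Y* = σ(**K**·(*A* ∘ *X*) + *B*),&nbsp;&nbsp;&nbsp;&nbsp;*A* = *F*(*X*),

where *F* is a feedforward attention subnetwork with three hidden layers
(default 1000/250/50 units; each block is affine → batch-norm → leaky-ReLU →
dropout, and the final m-unit attention layer is linear), ∘ is the
element-wise product, **K** is a d × m coefficient matrix, *B* a d-vector of
biases and σ the element-wise sigmoid. The training loss is

&nbsp;&nbsp;&nbsp;&nbsp;loss = **W**ᵀ**E** + β‖**K**‖₂,

with **E** the per-trait mean binary cross-entropies, **W** per-trait loss
weights (default all ones), β = 10⁻³, and ‖·‖₂ the Frobenius norm read
literally (a squared-norm variant sits behind `MTLModelConfig.squared_penalty`
for comparison). The single-task (STL) baseline is a plain feedforward net of
the same hidden geometry with one sigmoid output and cross-entropy loss.

The defining property is the *linearization identity*: given the attention
vector, each trait's prediction is exactly a logistic-linear model with
per-SNP coefficients K<sub>tj</sub>·A<sub>j</sub>(x). The forward pass
literally evaluates this expression, so interpretation requires no sampling
or perturbation approximation.

Because the eval-mode attention net is piecewise linear in *X* (leaky-ReLU
with frozen batch-norm statistics; dropout disabled), the pre-sigmoid output
z<sub>i</sub> = Σ<sub>j</sub> K<sub>ij</sub>A<sub>j</sub>(x)x<sub>j</sub> +
B<sub>i</sub> is piecewise quadratic, and its Hessian away from activation
kinks is exactly

&nbsp;&nbsp;&nbsp;&nbsp;H<sup>(i)</sup><sub>kl</sub> = K<sub>ik</sub>J<sub>kl</sub> + K<sub>il</sub>J<sub>lk</sub>,&nbsp;&nbsp;&nbsp;&nbsp;J<sub>jk</sub> = ∂A<sub>j</sub>/∂x<sub>k</sub>,

since the attention Jacobian *J* is locally constant (the third-derivative
term vanishes). `interpret.attention_jacobian` computes *J* in closed form by
chaining the per-layer affine maps and activation slopes; tests validate both
identities against central finite differences, which are themselves exact (to
rounding) for piecewise-quadratic functions within one linear region. At a
kink the Hessian is one-sided and the formula applies to either limit; kinks
form a measure-zero set and are detected in validation by comparing two
finite-difference step sizes.

### Numerical and design choices

- **Hidden-block ordering** (affine → batch-norm → leaky-ReLU → dropout) is
  the common convention; only eval-mode behaviour matters for interpretation.
- **Leaky-ReLU slope** defaults to 0.01, configurable.
- **Initialization**: Kaiming-uniform for hidden weights, **K** ~
  N(0, 1/m), *B* = 0. At training start the output biases are reset to
  logit(train-set prevalence) — standard for rare binary outcomes, and
  necessary at small step counts because Adam moves a parameter by roughly
  (learning rate) × (number of steps).
- **Readout**: one affine row of **K** per trait. A per-trait hidden layer
  would break the exact linear-coefficient reading of **K**·A, which is the
  architecture's purpose, so none is offered.
- **Stability**: cross-entropy is computed from pre-sigmoid scores via
  softplus; the Frobenius-norm gradient uses a 10⁻¹² floor at ‖K‖ = 0.

## Training and benchmarking

Subjects are split 70/15/15 into train/validation/test at the subject level.
Training is mini-batch Adam (reference settings: batch 512, learning rate
10⁻⁴, 100 epochs) with one checkpoint per epoch; the checkpoint with the best
validation score is kept. The selection metric defaults to mean validation
ROC AUC over traits (validation loss is available via config); exact ties
resolve to the earliest epoch. Metrics are ROC AUC by the rank statistic
(mid-rank ties) and PR AUC by average precision (step interpolation — the
conservative standard; trapezoidal PR is deliberately not used). Baselines
are 0.5 for ROC and the trait prevalence for PR. Transfer is quantified by
the relative increase of over-baseline AUC gain,
((model − baseline) − (stl − baseline)) / (stl − baseline) × 100%, undefined
when the STL AUC sits exactly at the baseline. No class re-weighting is
applied (**W** = 1); prevalence is controlled in the simulator instead.

## Interpretation

First-order model-wise importance of SNP j for trait t is the magnitude of
the model-wise linear coefficient, s<sub>tj</sub> =
|mean<sub>x</sub> K<sub>tj</sub>A<sub>j</sub>(x)| over the test split in eval
mode (train mode is rejected — dropout would make scores stochastic). The
alternative aggregation mean<sub>x</sub>|K<sub>tj</sub>A<sub>j</sub>(x)| is
available (`aggregation="abs_mean"`); the signed mean is the default because
it preserves a coherent model-wise coefficient — a SNP whose instance
coefficients cancel across subjects carries no consistent effect direction.
The choice is recorded in the table's metadata. Only autosomal (chromosome
1–22) SNPs are scored; sex-chromosome columns are dropped at interpretation
time, not at load time.

FDR is estimated empirically with decoy SNPs: the interpretation model is a
*separately trained* model on a decoy-augmented panel (decoys appended at
training time, not post hoc). Each decoy is drawn i.i.d. per subject from its
paired real SNP's empirical genotype proportions, so it matches the real
SNP's genotype frequencies while being independent of every trait. The FDR
at an importance threshold is (#decoys ≥ t)/(#reals ≥ t) — ties inclusive,
no pseudocount by default (a +1-decoy pseudocount variant exists for
conservative use). Selection at a target FDR takes the smallest threshold
whose estimate meets the target and returns all real SNPs at or above it; an
unreachable target yields an empty set with a warning.

Genetic correlation between two traits is the Spearman rank correlation
(mid-rank ties) of their importance scores over the union of their
FDR-selected SNP sets (5% level by default).

## The synthetic cohort generator

The simulator provides the statistical structure the method assumes, with
defaults that describe the package's reference desk-scale cohort: n = 4000
subjects, m = 300 SNPs, d = 8 traits at 5% prevalence, 20 causal SNPs per
trait with 80% drawn from a shared pleiotropic pool, liability heritability
0.5, MAF ~ U(0.05, 0.5).

- **Genotypes**: minor-allele counts ~ Binomial(2, p) (Hardy–Weinberg),
  independent across SNPs by default; an optional block-exchangeable LD mode
  (Gaussian copula on allele draws within blocks) exists but is off by
  default since no operation requires LD.
- **Effects**: a pleiotropic pool of round(shared_fraction × k) SNPs is drawn
  once and shared by all traits; each trait adds private causal SNPs.
  Nonzero effects are Gaussian and then rescaled per trait so that
  Σβ² = h² exactly — this makes the liability variance exactly 1 and the
  realized prevalence match its target, instead of fluctuating with the
  χ²-distributed realized genetic variance (at k = 20 that fluctuation would
  move a 5% prevalence by about a percentage point).
- **Phenotypes**: liability L = Zβ + ε with standardized genotypes Z and
  ε ~ N(0, 1 − h²); a subject is a case when L exceeds Φ⁻¹(1 − prevalence).
- **Determinism**: all generators are bit-reproducible given the config seed;
  the pipeline fans a global seed out to stages through fixed offsets so
  adding a stage never perturbs earlier stages.

What the simulator does *not* emulate: linkage disequilibrium by default,
population structure, relatedness, genotyping/imputation error, sex-specific
traits, and covariate effects (age, sex, principal components). Passing tests
therefore demonstrate correctness of the algorithms under the generative
model's assumptions — not calibrated performance on real biobank data, where
LD in particular will spread importance across correlated SNPs and make
decoy-FDR selection less interpretable at the single-variant level.

## Desk-scale study conditions

The two replication studies run at deliberately reduced scale so the full
suite completes on one CPU:

- **Positive transfer**: d = 8 traits, 5% prevalence, n = 4000, m = 300,
  h² = 0.5, shared_fraction 0.8 vs 0.0, 5 seeds per condition; hidden sizes
  64/32/16. The expectation is that the jointly trained model's mean test ROC
  AUC beats the matched single-task models under strong sharing, and that
  the gap shrinks without sharing (negative transfer can make it negative).
- **FDR calibration / recovery**: d = 4 traits, n = 4000, m = 300 real + 300
  decoy SNPs, 20 causal per trait, h² = 0.6, 20 seeds; selection at nominal
  20% FDR. Non-causal real SNPs and decoys are exchangeable here (both pure
  noise), which is what makes the decoy ratio an unbiased estimate of the
  false-discovery proportion in this regime.

Study training uses batch 128, learning rate 2 × 10⁻³, 40 epochs with
validation-based checkpoint selection: roughly 900 Adam steps, chosen so
coefficients of the magnitude the liability model implies (~0.1–0.5 per
standardized SNP) are reachable from zero; these are the package's reference
settings for cohorts of this size, fixed once for all studies.

## Known limitations

- No GPU path; the numpy implementation is intended for method study and
  desk-scale cohorts, not 800k-SNP biobank panels.
- The decoy-FDR guarantee is empirical (count ratio), not a knockoff-style
  exchangeability theorem; with LD or confounding the ratio can be
  optimistic.
- PR AUC for very rare traits is noisy at desk scale; single-class test sets
  are reported as undefined rather than silently zero.
- PLINK1 .bed/.bim/.fam is the only genotype format (no VCF/BGEN/PLINK2);
  missing genotype calls are imputed to the per-SNP mode by default, with a
  strict mode that rejects them.
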