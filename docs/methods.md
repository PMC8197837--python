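# Methods

This note documents the models, default parameters and numerical choices
behind `vitalgan`, and what the test suite does and does not establish.

## Problem setting

One COPD patient monitored daily by consumer medical sensors yields records
of 11 continuous vital signs.  The classification target is breathing
performance: `high` iff peak expiratory flow (PEF) ≥ 400 L/min.  The
boundary value 400 itself maps to `high`; the cut is otherwise stated only
as "under/over", so the convention is ours and is documented here and in
`derive_label`.  PEF is excluded from the 10 predictor features — any model
allowed to see it would simply re-read the label.  Datasets in the tens of
records are the design point throughout.

Missing-value policy on CSV ingest is listwise deletion (rows with any
missing predictor are dropped and counted).  Imputation is out of scope.

## Cohort simulator

`generate_cohort` draws class-conditional multivariate Gaussians sharing one
correlation matrix, then clamps to physiological bounds and **rederives**
each record's label from its generated PEF, so `label ==
derive_label(pef)` holds by construction and the class boundary behaves
exactly like the real labelling rule.

Default moments (mean low / mean high, sd) are chosen to be physiologically
plausible for a middle-aged COPD patient and strong enough that an FEV1
threshold rule is learnable from ~43 records with FET p < 0.05:

| feature            | low   | high  | sd   |
|--------------------|-------|-------|------|
| fev1 (L)           | 2.0   | 2.6   | 0.25 |
| pef (L/min)        | 360   | 440   | 30   |
| heart_rate (bpm)   | 80    | 70    | 6    |
| heart_rate_master  | 80    | 70    | 6    |
| map (mmHg)         | 88    | 95    | 6    |
| diastolic (mmHg)   | 74    | 80    | 7    |
| systolic (mmHg)    | 116   | 125   | 9    |
| oxygen (%)         | 95    | 95    | 1.5  |
| body_temp (°C)     | 36.6  | 36.6  | 0.3  |
| weight (kg)        | 78    | 78    | 8    |
| bmi (kg/m²)        | 26    | 26    | 3    |

Default correlations: fev1–pef +0.7, systolic–map +0.8, diastolic–map +0.8,
heart_rate–heart_rate_master +0.9, and diastolic–systolic +0.5.  The last
pair is required: with the two MAP correlations at 0.8 and
diastolic–systolic at 0, the matrix is not positive semi-definite (the 3×3
block has determinant −0.28); +0.5 is also the physiologically sensible
sign.  User-supplied matrices that are not PSD are projected to the nearest
PSD matrix (eigenvalue clipping, diagonal rescaled to 1) with a warning.

Optional AR(1) filtering (`rho`) over record order mimics day-to-day
autocorrelation of a monitored subject; the default is 0 (exchangeable
records).

Two estimation caveats follow from the design. First, the *marginal*
fev1–pef correlation in a two-class cohort exceeds the within-class 0.7
(class mean shifts add between-class covariance); parameter-recovery tests
therefore run at `p_high=1`.  Second, label rederivation slightly biases
class-conditional means of PEF-correlated features relative to the drawn
component (records near the 400 cut can switch class), which is intended —
it is how the real labelling behaves.

What the simulator does **not** emulate: multi-subject hierarchy, attrition,
measurement error structure, device-specific artifacts, non-Gaussian tails.
Tests that pass on simulated cohorts show the pipeline's machinery is
correct under its stated assumptions, not that a GAN trained on any real
clinic's data will transfer.

## Conditional GAN

Generator: (noise[32] ⊕ one-hot class[2]) → 64 → 64 → 10, leaky-ReLU hidden
(slope 0.2), **sigmoid output** on min-max-scaled features.  Discriminator:
(features[10] ⊕ one-hot[2]) → 64 → 64 → 1 logit.  Binary cross-entropy on
logits; Adam with lr 2e-4, β₁ 0.5, β₂ 0.999; batch 16; one
discriminator and one generator step per batch; one epoch = one shuffled
pass over the real records.  All sizes and rates sit in `GanConfig`.

The sigmoid-bounded output means samples always lie inside the training
envelope after inverse scaling — deliberate: a few dozen records give no
support for extrapolation.  The cost is that the generator cannot place
mass outside the observed range; for this use case that is the right trade.

Everything — parameter init, noise, shuffling — is driven by one seeded
`numpy.random.Generator`, so training and sampling are bit-for-bit
reproducible.  The networks, backpropagation and Adam are implemented
directly in NumPy; at this scale (widths of 64, batches of 16) dense matrix
products are all that is needed and a framework would add nothing but
weight.  Non-finite losses abort with a diagnostic.  An optional per-epoch
probe logs the Fréchet distance between a generator sample and the scaled
training data.

Sampling draws ⌊n·class_mix⌉ high-conditioned records and the rest
low-conditioned; a synthetic record's label *is* its conditioning class.

## Quality metrics

**JS divergence.**  The defining formula acts on probability vectors, so
continuous samples are reduced per feature to equal-width histograms over
the pooled min–max range (default 10 bins), smoothed with ε = 1e-10 and
renormalized; base-2 logarithms bound each per-feature score in [0, 1]; the
reported score is the mean over features.  Bin count and log base are our
choices (documented, configurable); base 2 is what makes the [0, 1] range
hold.  `js_between_classes` compares the class-high and class-low subsets
of one sample; a cross-sample variant (`js_between_classes_cross`) compares
same-class subsets of two samples.

**Fréchet distance.**  Samples are z-scored by the reference sample's
moments (else mmHg features dominate liters), then
`‖Δμ‖² + Tr(C_P + C_Q − 2(C_P C_Q)^{1/2})` with sample covariances
(ddof 1).  The matrix square root is taken through the symmetric form
`C_P^{1/2} C_Q C_P^{1/2}` with eigenvalues clipped at 0, which avoids
complex intermediates; a tiny diagonal regularizer (1e-12) guards
singular covariances.  `pooled=True` standardizes by the stacked samples and
makes the score symmetric.  A widely printed variant of the trace term with
`+2 C_P C_Q` is available as `variant="printed"` for auditability only — it
is not a distance (nonzero for identical samples) and is never used by the
pipeline.  The name "FID" is kept by convention although no embedding
network is involved: the score is computed on raw tabular features.

## Rule model

A rule is `if((c₁)∧(c₂)…)then class` with threshold conditions on predictor
features, at most one lower and one upper bound per feature.  On an
evaluation dataset it carries covering `C = P(premise | consequence class)`
and error `r = P(premise | other class)` — the class-conditional reading,
which is the only one under which a rule can simultaneously have C ≈ 40%
and r ≈ 5% on a 43-record two-class dataset.

**Tree inducer** — a Gini decision tree (scikit-learn, fixed random state,
default depth 3) whose leaf paths become rules; redundant bounds merged;
leaf majority class is the consequence; default class is the dataset
majority.

**Greedy inducer** — sequential covering over equal-frequency discretized
features (default quartiles): grow a premise by repeatedly adding the
bin-edge condition that covers the most still-uncovered records of the
target class, preferring conditions meeting the error budget
(`max_error`, default 0.1) and skipping conditions that do not shrink the
premise's extent; accept the rule when the budget is met within
`max_conditions` (default 3); remove covered records; stop when no feasible
rule adds coverage.  An infeasible budget yields an empty rule set with a
warning.  `q_bins`, `max_conditions` and `max_error` realize the
granularity / covering-vs-precision trade-off of logic-learning rule
extractors; this is a transparent stand-in for proprietary Boolean
latticization engines, not a reimplementation of one.

The greedy learner is the workflow default: the error budget acts as an
intrinsic precision floor, which keeps overfit noise rules from flooding
the downstream statistical gate (relevant at n = 1000 synthetic records,
where tree leaves can pass a same-data exact test by selection alone).

**Classification.**  All firing rules vote with weight `C·(1−r)`; the
class with the larger summed weight wins; no firing rule or an exact tie
falls back to the default class.  The weight rewards high covering and low
error and reduces to majority-of-firing-rules when all rules are equally
good; any scheme here is a design choice, this one is deterministic and
monotone in both statistics.

Rules print in the style `if((fev1<=2.23)∧(map<=104.18))then low
(C = 41%) (r = 4.9%) (p = 0.003)` and parse back losslessly (thresholds are
printed at full float precision for that reason); `∧`, `^` and `&` are all
accepted conjunctions, `≤`/`≥` are accepted operators, and feature
spellings like `FEV1`, `heartrate`, `diastolicpressure` resolve to schema
names.  The bare spelling `heartrate` binds to the oximeter rate
(`heart_rate`); the sphygmomanometer rate carries the `master` suffix.

## Statistical validation

Each rule is tested on the 2×2 table premise × class.  Because a rule is a
directional claim (premise ⇒ class), the default test is the one-sided
enrichment Fisher exact p-value — a two-sided test would also certify
anti-predictive rules; `two_sided=True` is available.  Degenerate margins
(premise fires on no record or on all) return p = 1 with a logged flag.
α defaults to 0.05 and rules are tested individually, matching per-rule
validation practice; an optional Benjamini–Hochberg correction
(`bh_correct=True`) is provided as an extension.  `filter_rules_fet` keeps
rules with p < α, except α ≥ 1 which is the vacuous keep-all filter.

The augmentation workflow:

1. **baseline** — induce on real, FET-filter on real;
2. **candidate augmented** — induce on synthetic, FET-filter on synthetic;
3. **augmented** — re-score the candidate rules' C, r on real and keep those
   passing FET on real.  Candidate rules are *not* re-induced on real data —
   only re-tested — so the augmented set is a subset of the candidate set
   by construction.

Accuracy and F1 (class `high` positive) are reported for the baseline and
augmented models on real data and for the candidate model on both its
synthetic training data and the real data; the real-data evaluation of the
synthetic-trained model is the headline transfer measurement.

## Epoch sweep

For each training length: train from scratch, sample `n_synth` (default
1000) records at the real class prevalence, compute JS real-fake,
JS between classes and FID, run the full workflow, and emit one report row.
The recommended setting is the FID minimizer, and the report carries the
Spearman rank correlation between FID and real-data accuracy across rows so
the "FID anticipates XAI quality" heuristic can be inspected on any run.
One seed per row by default; `replicates=k` averages each row over k
independently seeded runs, since GAN training on tens of records is
high-variance.  A failed setting becomes a failed row, never a crash.
Deterministic sub-seeds are derived by hashing (seed, row, replicate).

## Problem sizes used in tests and the acceptance script

Simulated cohorts of n = 43 (the design point) and n = 1000 (synthetic
corpus); GAN grids of {100, 500, 2000} epochs; 20-replicate negative
controls; 100-replicate null calibrations; exact-test oracle enumeration
over all 2×2 tables with total ≤ 30.  These sizes make the full suite and
the acceptance run complete in minutes on one CPU while keeping every
statistical check adequately powered.

## Known limitations

- Single-subject, two-class, 11-feature schema; no multi-class or
  multi-subject support.
- The GAN offers no Wasserstein/CTGAN variants, gradient penalty, label
  smoothing or differential privacy.
- FET on the same data a rule was induced from is anti-conservative
  (selection bias); the workflow's real-data re-test is the guard, and the
  permuted-label negative control measures how well it holds.
- Quality scores are moment- and histogram-based; they cannot certify
  higher-order structure (e.g. tail dependence) of the synthetic data.
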