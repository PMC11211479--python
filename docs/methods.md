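# Methods

This note documents the models, the synthetic data, and the numerical
choices behind the package, in the spirit of a methods appendix.

## Study design

The package reproduces, at desk scale on synthetic data, a cross-hospital
foundation-model adaptability study for structured EHRs. Two synthetic
hospital sites (A: pediatric-like; B: adult-like) each yield coded patient
timelines. Per site we pretrain a miniature decoder-only transformer with a
next-code objective ("local FM"), transfer the other site's model either
off-the-shelf ("external FM") or after continued pretraining on the target
site's training corpus ("external FM⁺"), and compare frozen-encoder linear
probes against a count-featurized LightGBM baseline on eight binary
prediction tasks. Three experiment families: overall comparison with
hierarchical-bootstrap inference, balanced few-shot label efficiency, and
pretraining-subsample curves (continued vs from-scratch).

## Synthetic EHR generator

Each patient carries a latent severity state in {0..3}. The state at first
admission doubles as a frailty variable that also drives the patient's
outpatient history (codes emitted from the same state-conditional
distribution over the two years before admission), so the observation
window available at prediction time is genuinely informative about
in-admission outcomes. During an admission the state evolves daily by a
row-stochastic transition matrix; each admitted day emits Poisson-many
coded events from a state- and site-conditional categorical plus Bernoulli
lab measurements with state-dependent Gaussian values; the day ends with a
death hazard, then a discharge hazard (zero on the admission day), then a
transition. Admissions start at 12:00 and end at 12:00 (discharge) or
18:00 (death), so length of stay in days equals the final day index and
the closed forms are exact.

Outcomes are emergent, never painted on: mortality from death hazards,
long stay from discharge hazards, lab outcomes from threshold crossings of
the measured values, readmission from a post-discharge Bernoulli
conditioned on the final state (gap 3–30 days; a 10% chance of an
unrelated later admission at 35–90 days provides labeled negatives with
follow-up). Later admissions draw a fresh initial state from the site
distribution; this deliberate simplification makes every admission
marginally identically distributed, which is what gives the generator
*closed-form per-admission outcome prevalences* by iterating the day-level
recursion (`analytic_prevalences`). Tests compare empirical label rates
over all eligible admissions against these closed forms with exact
binomial 99% intervals. The one-admission-per-patient cohort sampling
changes the readmission rate relative to the per-admission closed form
(multi-admission patients are down-weighted); the oracle check therefore
uses the all-admissions view.

Site contrast: site A draws milder initial states (55% stable) than site B
(30% stable, 15% critical); ages are pediatric (Beta-distributed, 40 days
to 17 years) vs adult (18–85 years); 64 core codes are shared while each
site has 8 exclusive codes (≈89% vocabulary overlap); shared codes get an
opposite-signed log-frequency tilt at the two sites. Two semantic levers
make the shift more than a frequency tilt: at site B every 4th shared
code has its severity affinity displaced by one state, and every 6th has
it *mirrored* — the same code signals the opposite acuity. A pure
frequency tilt turned out to be learnable by continued pretraining (large
next-code loss gains) without moving probe quality at all, because the
external model's state-discriminative features were already adequate;
mirrored semantics are what an external model actively misreads and what
continued pretraining genuinely repairs. Stronger scrambling (every 3rd
code) breaks the other direction — the continued model can no longer
catch the local one within the training budget — so the moderate setting
is the default. With the default profiles the total-variation distance
between site code marginals is ≈0.57.

Learnability is analytic, not hoped-for: the conditional entropy of a code
given the latent state is strictly below the unigram entropy (≈3.71 vs
≈4.12 nats at site A), so next-code pretraining has signal by
construction.

The benchmark uses 5,000 patients at the external provider site A and
2,000 at the evaluation site B: a shared foundation model's pretraining
population is substantially larger than the site adopting it, and that
asymmetry — not any architectural difference — is what gives continued
pretraining its sample-efficiency advantage over local pretraining from
scratch. The scale itself is a deliberate reduction from a larger nominal
design so that the full five-seed benchmark, which trains seven
transformer instances per seed, runs on a single CPU in minutes
(prevalence-oracle tests use ≈5,000 admissions). Half the patients are
reserved as pretraining-only background (`cohort_fraction = 0.5`):
supervised cohorts are drawn from the other half, mirroring the real
setting where pretraining populations dwarf task cohorts and keeping the
few-shot pretraining-exclusion rule from emptying the corpus.

What the generator does *not* emulate: real clinical semantics of codes,
code hierarchies/ontologies, irregular visit processes, measurement
batteries ordered jointly, documentation drift over calendar time, or
inter-site age-conditional case mix. Passing tests therefore demonstrate
that the pipeline's machinery behaves as designed under a controlled shift
— not that the effect sizes transfer to any real hospital pair.

## Cohort and task definitions

Eight tasks: in-hospital mortality; long length of stay (≥ 7 days);
30-day readmission; and five abnormal-lab tasks with strict thresholds —
glucose < 3 mmol/L, sodium < 125 mmol/L, potassium > 7 mmol/L, hemoglobin
< 70 g/L, platelets < 50 × 10⁹/L. Boundary values do not fire.

Prediction time is midnight at the *end* of the admission calendar day
(discharge day for readmission): the exclusion of admissions where death
or discharge precedes the prediction time only makes sense when the
prediction time follows the admission, and timestamps are integer minutes
so the boundary is exact. Features see events strictly before prediction
time; the prediction window is (prediction time, discharge], or a 30-day
post-discharge window for readmission. Admissions with the outcome between
admission (or discharge) and prediction time are excluded for that task;
the first qualifying lab crossing determines timing. Death during the
30-day window labels readmission 0 — death precludes readmission; treating
it as censoring would be equally defensible but adds a competing-risk
machinery the study does not need. Readmission ascertainment uses *all*
later admissions, not only cohort-selected ones: the one-admission rule
governs example rows, not outcomes.

Splits are by patient, 70/15/15, largest-remainder rounding, seeded;
task-specific folds inherit the patient's global fold, so no patient
appears in two folds of any task.

## Foundation model

A compact decoder-only pre-LayerNorm transformer (default 2 layers,
64-hidden, 4 heads, causal sliding-window attention) over a
frequency-ranked code vocabulary with out-of-vocabulary *drop* semantics.
Implemented directly on numpy with hand-written backpropagation (verified
against finite differences in the test suite) and Adam; this keeps the
package dependency-light and bit-deterministic on one machine. Time enters
only through event order and learned positions. Lab values drive labels
but are not tokenized; value-binned tokens are a possible extension.

Pretraining minimizes mean next-code cross-entropy with causal masking;
sequences are chunked to the maximum length; a "step" is one optimizer
update on a fixed token budget (batch of chunks). Early stopping tracks
validation loss every `eval_every` steps and halts after `patience` steps
without improvement, returning the best-validation parameters. The
learning rate is chosen from a candidate grid by validation loss (the
benchmark uses a single candidate, 1e-3, as a scale choice). Continued
pretraining restarts the optimizer from the parent checkpoint and always
inherits the parent vocabulary — codes the parent never saw stay dropped,
as when a shared model moves to a new hospital.

Correctness anchors: on a first-order Markov corpus the converged
validation loss must land in `[H_cond − 0.02, H_unigram]` and within 0.1
nats of the conditional entropy, both computed in closed form from the
transition matrix.

The frozen representation of a history is the final-LayerNorm hidden state
at the last token of the (truncated to the most recent `max_seq_len`
tokens) pre-prediction-time history; a mean-pooling alternative is a
config option; an empty history maps to the zero vector.

## Task heads

The baseline features are raw per-code counts over the full observation
window plus age (days) at prediction time and a sex indicator; the code
space is frozen on the task training fold; no time binning, no ontology
rollup. The GBM head is LightGBM with a small grid — learning rate {0.1,
0.03} × leaves {15, 31} × boosting variant {gbdt, dart} (the
"optimization algorithm" axis) — with early-stopped rounds; the probe is
L2 logistic regression (lbfgs) with C ∈ {0.01, 0.1, 1, 10} on standardized
features. All selection is by validation-fold log loss; no class
reweighting anywhere, matching plain log-loss tuning under skewed
prevalences. Single-class training draws fall back to a flagged
constant-rate head.

## Few-shot protocol

k ∈ (2, 4, 8, …, 1024) (the benchmark stops at 64 and uses 5 iterations
per cell as a scale choice; the protocol default is 20). Each draw takes
k/2 positives and k/2 negatives without replacement; when only k_p < k/2
positives exist, all k_p positives plus negatives filling the draw to
*total* k — keeping the x-axis the true training-set size; the
fill-to-k/2-negatives alternative sits behind `total_fill=False`.
Validation sets are never subsampled. Per-cell seeds derive from
SHA-256 of (global seed, task, k, iteration), so draws are independent
across iterations yet exactly reproducible. For the few-shot experiments
the continued-pretraining corpus excludes every patient contributing a
task-training example. Few-shot ECE is computed on prior-corrected risks
p′ = p·b′ / (p·b′ + (1−p)(1−b′)) with b′ the task training-pool outcome
rate — the Bayes-odds correction from the balanced training prior back to
the deployment prevalence.

## Evaluation and inference

AUROC is the Mann–Whitney statistic with midrank ties (identical to
exhaustive pair counting, which the tests verify). ECE uses 10 quantile
bins of the predicted risks; duplicate bin edges from tied risks are
merged, and the fully degenerate case reduces to |mean p − prevalence|.

Model comparisons bootstrap the across-task mean metric difference:
each of B = 1000 replicates resamples tasks (outcomes) with replacement,
then patients with replacement within each resampled task, with paired
patient draws for the two models. The two-tailed p-value is twice the
smaller tail proportion of replicate differences around zero (exact zeros
split half-half), capped at 1. A flat patients-only nesting is available
behind `nesting="patients"`; with a single task the two coincide.

A known property worth stating: when the true per-task effects are
identical, the task-resampling level double-counts patient noise and the
test is conservative (≈1% type-I error at α = 0.05 in our simulations with
8 homogeneous tasks). In the patient-resampling regime the test is
well calibrated (≈5% over 500 null runs, bootstrap p-values near-uniform),
and power for a 0.15 AUROC gap at n = 2000 is essentially 1. The
calibration tests exercise exactly these two regimes.

## Leakage audit

Every checkpoint records the patient ids of its pretraining corpus; the
audit asserts that no test-fold patient of either site appears in any
pretraining corpus, that task folds are patient-disjoint and contained in
their global folds, and that few-shot continuations exclude task-train
patients. The audit runs inside every benchmark pass and is itself tested
with a deliberately planted leak.

## Benchmark scale and runtime

The default benchmark (`default_benchmark_plan`) uses 5,000 + 2,000
patients (provider/evaluation site),
a 2-layer 64-hidden FM with 48-token chunks and a 32-token attention
window, 300 optimizer steps with patience 150, subsample fractions
(0.05, 0.2, 0.8), and a few-shot grid to k = 64 with 5 iterations. One
seed of the full pipeline (three base pretrainings, the few-shot
continuation, three subsample continuations, head fitting, bootstrap
comparisons, audit) takes a few minutes on one CPU. Directional
conclusions (continued ≥ off-the-shelf external; FM probes ≥ count-GBM in
few-shot; continued pretraining matching the full local FM from a smaller
patient fraction) are asserted over five seeds with a 4-of-5 majority
rule, since individual seeds at this scale are noisy.

## Known limitations

* Effect sizes are not comparable to any real multi-hospital study; only
  directions and mechanisms are.
* The transformer is orders of magnitude smaller than production EHR
  foundation models; no day-position embeddings, no value tokens.
* The generator's site shift is a single frequency/semantics tilt; real
  inter-site shifts are higher-dimensional.
* The hierarchical bootstrap's task level is conservative under
  homogeneous effects (see above).
* Count featurization is deliberately minimal; ontology rollups or time
  bins would strengthen the baseline.
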