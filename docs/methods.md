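# Methods

## Pathway activity model

The scorer treats each signaling pathway independently as a two-layer
naive-Bayes network: a latent binary transcription-factor (TF) state
(active / inactive) and, conditionally independent given that state, one
binary evidence node per target gene (high / low expression).  The pathway
activity score is the log2 posterior odds of the active state,

PAS = log2 π/(1−π) + Σ_g log2 L_g,

with prior π and per-gene likelihood ratios L_g determined by the
conditional probability table (CPT) entries `p_high_active` /
`p_high_inactive`.  Unmeasured genes contribute a likelihood ratio of 1:
absence of measurement is not evidence.  An exhaustive enumeration oracle
(`enumerate_posterior_oracle`, capped at 12 genes) computes the same
posterior by summing the explicit joint distribution and is used
throughout the tests as an independent check of the summation form.

Assumptions worth stating: target genes are conditionally independent
given the TF state (co-regulation beyond the TF is ignored); evidence is
binary, so graded expression within the high or low range carries no
additional information; and probes of one gene are exchangeable (they are
averaged before discretization).  A richer three-layer TF→gene→probe
network would relax the last two at the cost of parameters that cannot be
identified from a probeset matrix alone; the two-layer form keeps the
log2-odds semantics fully specifiable from a labeled calibration cohort.

Interpretation contracts, enforced in documentation and tests: PAS ranges
are pathway-specific (never compare scores across pathways within a
sample); absolute values are only interpretable against a calibration with
known activity; a negative PAS does not by itself mean the pathway is off.

## Discretization and calibration

Discretization: probes of a gene are aggregated by mean log2 intensity and
compared with the mean of their per-probe thresholds; ties go high.  The
tie rule makes the noiseless limit deterministic (a value exactly at its
calibration median counts as high).

Calibration (`fit`) on samples with known state estimates:

- per-probe thresholds as the **pooled median** over all calibration
  samples, and
- CPT entries with Laplace smoothing,
  `p_high_active = (k + α) / (n_active + 2α)` (default α = 1), keeping all
  probabilities strictly inside (0, 1) so every PAS is finite.

The pooled-median rule assumes a calibration cohort in which each gene is
high in roughly half the samples (balanced classes with informative,
roughly complementary conditional probabilities).  When that fails — e.g.
a gene high in 80% of *all* calibration samples — the median lands inside
one intensity cluster and discretization becomes biased; parameter-recovery
guarantees are stated for the balanced design only.  This is a known
limitation of median thresholds, accepted for their robustness and
determinism.

Defaults: prior π = 0.5 (PAS is then a pure evidence score; any other
prior shifts every PAS by exactly log2 π/(1−π), a property under test),
pseudocount α = 1.0.

## Quality control

Metrics per sample: mean log2 probe intensity; fraction of negative and of
saturated linear intensities; GAPDH and ACTB 3′/5′ ratios (linear-scale
ratio of mean 3′ to mean 5′ housekeeping-probe intensity); RNA degradation
slope (least-squares slope of log2 intensity against probe position index
over position-annotated probes); spike-order flags for the poly-A
(sample-prep) and labelled-cRNA (hybridization) control series, which must
be non-decreasing in expected rank.

Scale convention: the matrix stores log2 intensities, but negativity and
saturation are linear-scale concepts.  A non-positive linear reading has
no log2 representation, so it is encoded as NaN and counted by the
negativity check; saturation is an entry above log2(2^16).  After QC the
surviving matrix is finite.

Default bounds: max fraction negative 0 (any invalid reading fails), max
fraction saturated 0.01, saturation level 2^16, max 3′/5′ ratio 3.0 for
GAPDH and 10.0 for ACTB (ACTB's longer transcript tolerates more 3′ bias),
spike order required, degradation slope recorded but warn-only unless a
bound is configured.  A sample passes iff every enabled check passes;
checks whose control probes are absent are recorded as skipped, not
failed.  Spatial checks (center of intensity, border-control positions)
require raw array geometry that a probeset matrix does not carry and are
reported as not evaluable.

## Cohort statistics

Group contrasts use the two-sided Mann-Whitney-Wilcoxon test with the U
statistic oriented so that U counts cross pairs (a, b) with a < b plus
half the ties — large U means group B stochastically larger — and
AUC = U/(n_A·n_B) estimates P(A < B).  The p-value is exact when
n_A·n_B ≤ 200 and the pooled sample is tie-free, otherwise a normal
approximation with tie and continuity corrections (scipy supplies both
paths; a brute-force pair-counting oracle independently checks U and AUC
in the tests).  When either group has fewer than 8 samples the default
test switches to Welch's two-sided t-test (the "low sample numbers"
regime); the cutoff 8 is a package choice, configurable per call.  U and
AUC are reported from the rank statistics regardless of which test
supplies p.

Degenerate inputs are resolved explicitly: zero variance with equal means
gives (statistic 0, p = 1); zero variance with a nonzero difference is
perfect separation, reported with a warning as (±inf, p = 0).

Per-patient treatment dynamics: delta = PAS_pre − PAS_post, so positive
delta means the score decreased under treatment.  Deltas are computed only
for patients with both timepoints (duplicated timepoints are an error;
incomplete patients are excluded and listed); paired t-tests compare pre
vs post within each response group, and Mann-Whitney compares deltas
between responders and non-responders.

Significance convention: p < 0.01 significant, 0.01 ≤ p < 0.05 marginal,
otherwise ns; raw p-values are the default (an optional Benjamini-Hochberg
flag exists but is off, matching the raw-p reporting convention of the
application domain).

## Synthetic cohorts

The generator emulates the statistical skeleton of the clinical cohorts
the pipeline targets: groups of n samples; per (group, pathway) activity
states; probe intensity μ + δ·[active] + N(0, σ²) on the log2 scale for
target probes (δ/2 for partially active pathways), μ + N(0, σ²) for
off-target probes; a fixed control-probe block (housekeeping 3′/5′ pairs,
two spike series with 2-log2-unit rank gaps, eleven degradation-position
probes) with σ = 0.1 noise so control checks are stable; and paired
pre/post samples sharing patient ids.  Defaults δ = 1.0 log2 units,
σ = 0.5, baseline μ = 7.0, 50 off-target probes: one log2 unit of shift
against half a unit of noise makes default scenarios comfortably but not
trivially separable at n = 20 per group.

Presets encode the study conditions: `diagnosis` (healthy, CDc, CDi, UC;
MAPK active in every disease group, AR in the colon-localized groups,
JAK-STAT1/2 only in CDi, TGFβ only in UC, marginally elevated pathways as
partial), `anti_tnf_response` (NFκB/TGFβ/JAK-STAT3 fully elevated
pre-treatment only in non-responders and marginal in responders, with
post-treatment normalization only in responders), and `null` (no effects).
Partial (δ/2) states are the single mechanism for "marginal" ground truth;
against healthy controls they still produce strong effects at default
settings, so end-to-end pattern checks constrain active pathways (must be
significant) and inactive pathways (must not be), leaving partial ones
free.

Calibration sets are drawn by fixing the TF state per class, sampling
evidence from specified CPTs, and mapping it to two intensity levels
(default 7 and 9, σ = 0.3) whose pooled median separates them — the
balanced design the median-threshold rule assumes.  End-to-end runs
calibrate on 100 samples per class; CPT-recovery checks use 2000 per class
(binomial standard error ≈ 0.009, comfortably inside the ±0.03 recovery
band).

What the generator does **not** emulate: probe-affinity effects, batch and
background structure, heavy-tailed noise, correlated genes within or
across pathways, overlapping target-gene sets, or the intensity
distributions of real arrays.  Passing the end-to-end tests therefore
shows that the inference, QC and statistics machinery recovers known
structure under idealized noise — not that the bundled illustrative gene
sets or default parameters would reproduce clinical results on real data.

QC-failure injection corrupts a chosen fraction of samples (round-robin
over the requested kinds): NaN entries (negative readings), values above
the 16-bit ceiling, a positive slope over degradation-position probes, a
reversed hybridization-spike series, or inflated 3′/5′ ratios.  Each kind
perturbs only the probes its check reads, so removals can be attributed
exactly; exercising the degradation kind requires configuring the
(default warn-only) slope bound.

## Validation problem sizes

The test and acceptance runs use: 500 random models (1–12 genes) for
oracle agreement; exhaustive group-size sweeps up to 8×8 for U/AUC against
brute-force counting; 1000 null simulations (n = 20 per group) for the
type-I error rate; 100 seeded diagnosis cohorts and 50 seeded
treatment-response cohorts (n = 20 per group, δ = 1.0, σ = 0.5) for
pattern-recovery rates.  These sizes give stable rates (binomial standard
errors of a few percent) at about a minute of total compute.

## Known limitations

- The naive-Bayes structure and all bundled parameters are a transparent,
  fully specified instantiation of log2-odds pathway scoring — not a
  reproduction of any commercial assay's calibrated models, whose
  parameters and full target-gene lists are proprietary.
- Median thresholds assume the balanced calibration design described
  above.
- The bundled GMT is illustrative; scores on real data require
  platform-appropriate gene sets, probe maps and calibration cohorts.
- No normalization (RMA et al.) or batch correction is performed; inputs
  are assumed normalized log2 intensities.
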