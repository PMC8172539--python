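# Methods

This note documents the models, estimators and numerical choices behind
`impulscreen`, what the synthetic data do and do not emulate, and where the
design was genuinely open.

## Differential GPCR expression screen

### Sets

Set-T is either (a) all reporter-positive glutamatergic cells ("reporter"
mode, modelling a fluorescence pull from a layer-5 driver line) or (b) all
cells in L4/5-IT clusters ("cluster" mode). Set-C grows over three
conservatism levels: GABAergic only (1); plus non-neuronal and L6
glutamatergic (2); plus L2/3 glutamatergic (3). Cluster membership is
resolved by configurable regular expressions over free-text cluster labels
(`LAYER_PATTERNS`), which is also how a different taxonomy — e.g. human
deep-layer cluster names — is accommodated without a separate code path.
A cell eligible for both sets (a reporter-positive L2/3 cell at level 3)
goes to Set-T; disjointness is an invariant, and the biological contrast
sets exclude the target class by construction anyway.

### Measures and criteria

Per gene: `GE` = arithmetic mean CPM per set; `expr = log2(1+GE)`;
`diff_mean = expr_T − expr_C`; `pct` = fraction of cells at ≥ 1 CPM;
`beta = sign(diff_mean)·|pct_T − pct_C|` with `sign(0) = 0`; two-sided
Wilcoxon rank-sum p on per-cell expression; Bonferroni correction.

**Pseudocount placement.** Defining expression as `log2(1+GE)` but
fold-change as `log2(GE_T/GE_C)` disagrees near zero and is undefined at
`GE_C = 0`. We use one definition throughout:
`diff_mean = log2(1+GE_T) − log2(1+GE_C)`, and the k-fold criterion is
`(1+GE_T)/(1+GE_C) ≥ k`. This is finite everywhere, converges to the raw
ratio for well-expressed genes, and keeps the threefold threshold at
log2 3 ≈ 1.58 in the regime where candidates live.

**Detection threshold.** `pct` counts cells with CPM ≥ 1. Since
log2(1+CPM) ≥ 1 ⇔ CPM ≥ 1, thresholding on the log scale selects the
identical cell set; the choice of scale is vacuous and not configurable.

**Wilcoxon details.** The test is rank-based, hence identical on raw CPM and
log2(1+CPM); raw CPM is used. When min(|T|,|C|) ≤ 8 and a gene's pooled
values are distinct, the exact null distribution is enumerated
(`scipy.stats.mannwhitneyu`, exact method); otherwise the normal
approximation with midranks, tie-corrected variance and continuity
correction. Genes constant across both sets get p = 1 directly — a rank
test on zero variation carries no evidence. Bonferroni `m` defaults to the
number of genes in the matrix (a transcriptome-wide export); it is
configurable (e.g. to 402 for a GPCR-only panel) because either family is
defensible and the two differ only in stringency.

**Ranking.** Candidates must be GPCRs (optionally non-sensory), pass the
primary criteria in every required comparison, and match the coupling
filter (Gi by default: an endogenous Gi-coupled receptor is the druggable
proxy for inhibitory chemogenetics). Sort key: descending minimum
`diff_mean` across required comparisons, then descending minimum `beta`,
then ascending maximum `expr_C`, then gene symbol — worst-case selectivity
first, ties broken by low off-target expression, fully deterministic.

## 5-CSRTT engine

### Trial cycle and classification conventions

A trial starts at ITI onset (so premature trials count toward the trial
total). The response window is half-open, `[stim_on, stim_on + SD + LH)`;
the premature window is `[iti_start, stim_on)`. Pokes during a timeout
belong to no trial and are counted separately. Receptacle pokes during the
ITI are ignored. A perseverative response is a re-poke of the correct hole
after a correct response and before receptacle entry; it is a flag only and
triggers nothing. Response latency = first poke − stim_on; reward latency =
exit from the correct hole → receptacle entry. After a rewarded trial the
next ITI starts at receptacle exit; after any failed trial, at timeout end.
A trial unresolved at `session_end` is discarded by both simulator and
classifier.

Event logs are a minimal CSV (`time_s, event, arg`), with a 1 ms tolerance
for time jitter (stable re-sort); the classifier applies the same 1 ms
tolerance at the response-window boundary, and the simulator keeps response
latencies 2 ms clear of the boundary, so a log can be written at 0.1 ms
precision and re-read without any trial changing class. Adapters for richer
vendor log formats are an extension point, not core: acquisition systems
differ and none prints a canonical schema.

### Generative agent

Per trial, a premature poke time is drawn exponentially at the agent's
`premature_hazard` (events/s) and races stimulus onset — so
P(premature) = 1 − exp(−hazard · ITI), which makes longer ITIs harder, the
defining property of the impulsivity challenge. If the stimulus wins, the
agent responds with probability `p_detect · (1 − p_omit_given_detect)` at a
log-normal latency truncated within the response window, hitting the lit
hole with probability `accuracy_given_response` (else a uniform other
hole). Correct trials always collect the reward (collection failure is out
of scope); a perseverative re-poke occurs with `p_perseverate`. Drug
conditions act as multiplicative factors on the hazard, the omission
probability and the latency medians — the multiplicative form is what the
downstream log-ratio statistic is designed for. Latencies are log-normal by
default; any positive distribution honouring the median/σ contract can be
substituted.

Defaults (hazard 0.06/s, p_detect 0.95, p_omit 0.08, accuracy 0.85,
response latency median 0.7 s, reward latency median 1.2 s, p_perseverate
0.15) were chosen once to land a trained mouse in realistic ranges on the
9 s fixed-ITI challenge: ~40% premature, ~80% accuracy, <10% omissions,
~120 trials in a 30-minute session.

Stimulus holes are uniform i.i.d. ("pseudo-random" placement); an optional
no-immediate-repeat flag exists but is off by default since no balancing
scheme is canonical. The variable-ITI challenge uses {2, 5, 7.5, 12.5} s
with equal weights — an explicitly arbitrary stand-in, since only the fact
of trial-wise variation is defined, not the values. Challenge presets:
baseline (ITI 5 s, SD 2 s), fiti9 (ITI 9 s), sd1 (SD 1 s), combined
(ITI 7 s, SD 1 s), viti; limited hold SD + 2 s, timeout 5 s, sessions
1800 s, throughout.

## Challenge statistics

Every behavioural parameter is summarised per subject as
`log10(drug/vehicle)`. %premature and %perseverative are first integerised
by `floor(x) + 1` — i.e. [0,1) → 1, [1,2) → 2 — applied to *both* conditions
symmetrically, so identical values always give a ratio of 0 and sub-1%
noise cannot dominate the log scale. The "round up to the next full
integer" wording together with the stated bands forces the integer-input
case 1.0 → 2, which `floor(x)+1` reproduces.

Group tests are classical one-sample t against 0 (two-sided) with
t-distribution confidence intervals (95% by default; the level is
configurable since figure conventions vary). Paired t is implemented as the
one-sample t on differences. Sidak adjustment `1 − (1−p)^m` is provided as
a function; family composition is the caller's, because families follow
the omnibus ANOVA structure, which this package deliberately does not
re-implement — mixed-design RM-ANOVA/ANCOVA belongs to general statistics
software, and only the bespoke normalisation feeding it is in scope. The
confound screen correlates the %premature log-ratio with every other
parameter's log-ratio per group (Pearson, two-sided), asking whether an
apparent anti-impulsive effect merely tracks disengagement or slowing.
Latency summaries are emitted both as per-session means and medians, since
either convention is common.

Zero-denominator session metrics (accuracy with no responses,
%perseverative with no correct trials) are reported as absent, never 0 —
a 0 would silently fake a measurement.

## Synthetic data

The expression generator emulates the structure of the mouse anterior
cingulate reference data: ~10 named clusters over the three classes, an
L4/5-IT target cluster of 1238 cells, a 676-cell reporter pull of which 502
overlap L4/5-IT, a level-3 contrast pool of 3514 cells, 5190 cells total,
and 402 GPCR genes (3 flagged sensory) among 20,000. Background genes draw
a per-gene mean CPM log-normally and a per-gene detection probability
uniformly; observed values are Bernoulli dropout × log-normal. Non-planted
GPCRs share the background distribution — there is no GPCR-specific
background to emulate. Planted markers are controlled exactly: detection
counts are hit by exact thinning (rounded counts, not Bernoulli), and the
expressed-value means are solved so the per-set mean-CPM ratio equals the
requested fold; a pct/fold combination that would push an expressed mean
below twice the detection threshold is rejected as infeasible. Markers are
planted in the union of the L4/5-IT cluster and the reporter pull, so a
planted gene is selective under both target definitions.

What this generator does **not** model: count noise and library-size
variation (the screen consumes CPM, and rank tests plus set means see
nothing a count layer would add at these depths), correlated gene modules,
batch effects, or the real cluster taxonomy beyond class/layer labels.
Passing tests therefore demonstrate correctness of the statistics and
recovery under the stated noise model — not robustness to artefacts of any
particular real dataset.

Cohort simulation applies log-normal subject random effects (σ = 0.25) to
the hazard and latency medians, on the log scale so effects compose
multiplicatively with drug factors, and runs each subject under every
condition with per-subject seed streams (`numpy` `SeedSequence.spawn`).

## Problem sizes and determinism

Validation workloads are sized for a single CPU: null calibration uses
2,000 genes × 400 cells × 100 seeds; planted-marker recovery 50 datasets at
a 0.2-scaled roster (≥ 100 cells per set, 1,000 genes); simulator/classifier
agreement 1,000 two-minute sessions; effect-direction recovery 100 drug and
100 null cohorts of 12 subjects. All randomness flows from explicit seeds;
the CLI derives per-stage seeds by hashing the stage name into a global
seed, and every output file records the configuration hash it was produced
under.

## Known limitations

- The screen takes cluster labels and CPM normalisation as inputs; it does
  no clustering, embedding, or raw-count processing.
- The exact candidate counts reported on real reference atlases depend on
  those external datasets and are out of reach of the synthetic emulation;
  the tests validate calibration and recovery, not dataset-specific tallies.
- The trial classifier expects logs in the package's own dialect; truncated
  or vendor-specific logs are handled only insofar as the tolerant state
  transitions allow.
- Training-stage curricula, reward devaluation, and locomotor analytics are
  out of scope.
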