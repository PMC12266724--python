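# Methods

This note documents the models behind each analysis stage, what the
synthetic generators do and do not emulate, the numerical choices, and
known limitations. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Optogenetic response detection

Sweeps are trial-organized (default 10 trials), averaged pointwise,
and a response is quantified as

    magnitude = ∫ post − ∫ pre,

the trapezoidal integrals of the averaged trace over a 30 ms window
starting at stimulus offset and a 30 ms window ending at stimulus
onset. Significance combines two gates:

- **SD rule** — any sample between stimulus onset and 30 ms after
  offset deviating from the baseline mean by more than 3 SD (current
  clamp) or 5 SD (voltage clamp). The baseline for this rule and for
  the per-trial Mann–Whitney summaries is the 30 ms pre-onset window,
  mirroring the magnitude definition; the full pre-stimulus period is
  available via `baseline_window="full"`.
- **Mann–Whitney** — two-sided test on per-trial pre/post window
  integrals, exact enumeration when the combined n ≤ 12 and the
  tie-corrected normal approximation otherwise, corrected with
  Benjamini–Hochberg at 10% FDR. The BH family is all
  (cell, channel) tests within one batch (one dataset file); this is
  a configurable default because the family definition is genuinely
  open.

**Latency** needs a reproducible rule (in practice it is often read
manually). We use the first crossing of baseline mean ± k·SD that is
*sustained for 2 ms*, with the SD estimated over the full
pre-stimulus period. Both choices are robustness choices: the 30 ms
window holds too few independent samples for a stable SD estimate,
and unsustained crossings are typically noise excursions, whereas a
monosynaptic EPSP (decay ≈ 10 ms) stays above threshold far longer.
Cells crossing before 3 ms are classed as expressing opsin directly
and excluded from all connectivity counts; 3–12 ms is monosynaptic;
later crossings are polysynaptic or late.

**Connectivity calls** require the SD rule, the BH-corrected test,
*and* a monosynaptic latency. Restricting to the 3–12 ms window is
deliberate: long-latency significance on an unconnected channel is
almost always either noise or network-mediated, and the integration
statistic is defined over direct connections.

**Integration.** For cells probed with two inputs,
p(input1) and p(input2) are marginal response probabilities;
independence predicts p_expected = p1·p2, compared against
p_measured = P(both). The ratio's uncertainty is reported as a
seeded bootstrap SD over cells (10,000 resamples) since no
closed-form error is standard for this statistic. Simultaneous
dual-wavelength sweeps are flagged and skipped (the red-shifted opsin
is also blue-sensitive, confounding magnitudes).

## Axonal calcium imaging

ΔF/F = (F − F̄)/F̄ per ROI with F̄ the full-session temporal mean of
the neuropil-corrected trace (F − 0.7·F_neu). ROIs with non-positive
F̄ are degenerate and excluded with a log entry. Trials are windowed
from 2 s before to 6 s after onset; the window start frame is the
first frame at or after onset, and edge trials are dropped.

Responsiveness per (axon, trial type): two-sided Mann–Whitney on
per-trial mean ΔF/F over the 1 s before vs. after onset, BH at 1%
FDR across all testable (axon, type) pairs of a dataset. Types with
fewer than 3 complete trials are untestable and leave the family.
Per-trial *means* (not per-frame samples) are the test units — frames
within a trial are strongly autocorrelated, so per-frame testing
would badly overstate the effective sample size.

**Taxonomy.** Only the 7 stimulus-containing types enter; blank
responsiveness is tested identically but reported separately. An axon
is unisensory iff its pattern is the closure of exactly one modality
(all types containing it, none that do not); every other non-empty
pattern is multisensory, including "responds to a unimodal stimulus
but not its combinations", which is modulation by the added modality.
The modal category (exclusively multimodal / exclusively unimodal /
mixed) describes which kinds of trial types drive the axon. The rule
is a total function on the 128 patterns and is checked against an
independent rule table in the tests.

**Reliability.** Per trial, the AUC of ΔF/F over [onset, onset+1 s)
after subtracting that trial's 1 s pre-onset mean; a presentation
counts as a response when its AUC exceeds the pooled mean + 1 SD over
all axons and trials of the dataset (pooling across types; a
per-recording threshold is available). Response probability is
responding over total presentations per type; types without trials
are absent, not zero. Population-level structure is assessed with
Kruskal–Wallis across trial types and a Pearson correlation between
session index and session-mean probability.

## Behavior

**Three-port conditioning.** Stimulus→port map fixed (A→left,
V→right, AV→center); the response is the first poke within 10 s of
onset. Every trial yields one outcome per stimulus (hit/miss when
present, false alarm/correct rejection when absent); pokes at
non-task ports are miss-producing and never false alarms, and pokes
preceding any stimulus are ignored. HR = hits/(hits+misses),
FR = FA/(FA+CR), d′ = Z(HR) − Z(FR). Extreme rates are replaced by
1/(2N) and 1 − 1/(2N) with N the relevant trial count — the standard
correction, configurable, since no specific correction is canonical.

**Reversal learning.** Correctness is smoothed with
e_t = e_{t−1} + (x_t − e_{t−1})(1 − e^{−1/τ}), τ = 12, e_0 = 0.5
(chance). When the EMA first exceeds 0.8 and no reversal is pending,
a delay is drawn uniformly from 5–10 trials and the good port flips
that many trials later. Transition-aligned curves average the
indicator of choosing the currently-good port per lag around each
boundary. The lagged choice model is a logistic regression of the
current choice on ±1-coded previous choice, previous outcome and
their product (the win-stay/lose-shift axis), fit by Newton MLE to
1e-8; (quasi-)separation is detected and flagged rather than
silently reported.

## Home-cage activity

RA = (AI_D − AI_L)/(AI_D + AI_L) over phase means; undefined when
both are zero. Bin phases are assigned by bin start time. Bouts are
maximal runs of bins at or above 0.2 a.u.; sub-threshold gaps shorter
than 1 min are merged into the surrounding bout *before* bouts
shorter than 1 min are discarded — the inter-bout-interval constraint
semantically precedes the duration filter. Bout duration includes
absorbed gaps. Inter-daily stability, intra-daily variability and
sample-entropy indices are out of scope (platform-defined
elsewhere).

## Intrinsic-profile QC and subtypes

Gates, with strict inequalities so boundary values fail: R_access
< 35 MΩ or < 20% of R_input; resting Vm < −50 mV; |drift| < 10 mV;
threshold AP amplitude > 50 mV from spike onset with absolute peak
> 0 mV; |holding current| < 30 pA. Missing fields make a criterion
unevaluable, which fails the gate with an explicit reason.

E1/E2 discrimination uses the spike-amplitude adaptation profile
normalized to the first spike: biphasic means some later amplitude
recovers above the running minimum by more than 2% of the first
spike's amplitude after a decline; monophasic means no successive
increase exceeds that 2% tolerance (the tolerance is ours — no
published value exists). An ADP forces E2. The E/I call scores
spininess, half-width ≥ 1 ms and input resistance within
200–500 MΩ toward excitatory by majority of evaluable criteria; ties
are unknown. Feature extraction from raw sweeps and unsupervised
interneuron clustering are out of scope; the module consumes a
feature table.

## Synthetic generators

The generators produce data with the statistical structure the
analyses assume, not biophysics:

- **Axons**: constant baseline (1.0 so ΔF/F is well defined) plus
  i.i.d. Gaussian noise (SD 0.1 ΔF/F) plus instantaneous-rise,
  single-exponential-decay transients (amplitude 0.3, decay 0.5 s) at
  matching trial onsets — the simplest GCaMP-like kernel sufficient
  for detection testing. Conjunction-only units fire only when ≥ 2 of
  their tuned modalities co-occur. Blank trials emit nothing by
  construction; a configurable spontaneous event rate can inject
  blank-trial false positives. Stimuli: 500 ms, 8–11 s uniform ITIs,
  30 Hz frames. No indicator kinetics, motion, bleaching or optical
  crosstalk.
- **Sweeps**: 10 kHz, double-exponential EPSPs (rise 1 ms, decay
  10 ms) at onset + 5 ms with 10% amplitude jitter, amplitude 0.4
  against noise SD 0.1. The noise is Gaussian smoothed over 2 ms —
  white noise at 10 kHz is not a usable model of a patch-clamp
  baseline (a per-sample SD rule would false-positive on more than
  half of all windows), whereas membrane and amplifier filtering make
  real baselines smooth at the millisecond scale. Opsin-expressing
  cells deflect on both channels at 2 ms latency.
- **Agents**: the conditioning agent first-pokes each port with
  configured per-stimulus probabilities (hence closed-form HR/FR/d′);
  reversal agents implement perfect, random, win-stay/lose-shift and
  perseverative policies against the 85%/15% schedule.
- **Activity**: phase mean plus Gaussian noise clipped at zero, 12 h
  alternation, 60 s bins, 2 days. Clipping biases phase means upward
  when noise is comparable to the mean — noiseless or low-noise
  settings are used wherever exact values are asserted.

Determinism: one seeded stream per generator call, split per unit via
`SeedSequence.spawn`, so outputs are bit-identical for fixed
(seed, config) but not preserved across unit-count changes.

Problem sizes used by the tests and the acceptance script (chosen to
exercise the statistics at realistic scale): 20 cohorts × 200 axons ×
120 trials for FDR/power, 200 cells × 10 trials for connectivity
recovery, 25 agents × 1000 trials for the d′ grid, 100 sessions for
outcome bookkeeping, 50 seeds for reversal timing.

## What passing tests do and do not show

Passing parameter-recovery tests show the analysis code implements
its stated rules correctly and has the designed error-rate behavior
under the generators' assumptions (independent Gaussian noise, known
transient/EPSP shapes, stationary tuning). They do not certify
performance on real recordings, where noise is correlated across ROIs
and time, neuropil contamination varies, axonal ROIs can duplicate an
axon, and behavioral agents are non-stationary. The latency rule's
2 ms sustain and full-baseline SD were chosen for robustness to the
generator's noise model; sharper real noise spectra may warrant
retuning both.
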