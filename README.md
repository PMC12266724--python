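# clapipe

Analysis pipeline for four data streams that arise when studying how
the claustrum (CLA) — a subcortical nucleus densely and reciprocally
connected with cortex — integrates cortical input and shapes
multisensory behavior:

1. **Optogenetic circuit mapping** (`clapipe.opto`): trial-organized
   patch-clamp sweeps recorded while two cortical input pathways are
   photostimulated with a dual-color opsin strategy. The module
   averages sweeps, quantifies evoked-response magnitude as the
   difference of the 30 ms post-offset and 30 ms pre-onset signal
   integrals, calls significance with an SD rule (3 SD in current
   clamp, 5 SD in voltage clamp) backed by Mann–Whitney tests under
   Benjamini–Hochberg control (FDR 10%), gates out cells with < 3 ms
   latencies (direct opsin expression) and restricts connections to
   the monosynaptic 3–12 ms window. The headline statistic compares
   the measured probability that one cell responds to *both* inputs
   with the product of the marginal response probabilities:
   `p_expected = p(input1) · p(input2)`, `ratio = p_measured / p_expected`.
2. **Axonal two-photon calcium imaging** (`clapipe.imaging`): ROI ×
   frame fluorescence at 30 Hz under passive sensory stimulation
   (sound, light, whisker and their combinations, 500 ms stimuli at
   8–11 s intervals). ΔF/F = (F − F̄)/F̄ after neuropil correction
   (F − 0.7·F_neu); responsiveness per trial type by Mann–Whitney on
   the second before vs. after onset (BH, FDR 1%); axons classified
   as uni- or multisensory from their response patterns; trial-wise
   reliability from baselined 1 s AUCs against a pooled mean + 1 SD
   threshold.
3. **Operant behavior** (`clapipe.behavior`): three-port signal
   detection (sound → left, light → right, audiovisual → center,
   response = first poke within 10 s) with per-stimulus hit and
   false-alarm rates and sensitivity `d′ = Z(HR) − Z(FR)`; and
   probabilistic reversal learning (85%/15% reward) tracked with an
   exponential moving average (τ = 12 trials), reversals triggered
   5–10 trials after crossing 80% correct, plus transition-aligned
   choice curves and a lagged logistic choice model.
4. **Home-cage activity** (`clapipe.homecage`): circadian relative
   amplitude RA = (AI_D − AI_L)/(AI_D + AI_L) over dark/light phase
   means, and activity bouts (threshold 0.2 a.u., 1 min minimum
   duration, sub-minute gaps merged before the duration filter).

A fifth module (`clapipe.ephys_qc`) applies the recording
quality-control gates for intrinsic profiles (access resistance,
resting potential, drift, AP amplitude, holding current) and the
rule-based E1/E2 excitatory subtype and excitatory/inhibitory calls.

Because the original recordings are not required, every stream has a
synthetic generator with ground truth (`clapipe.synthetic`): tuned
GCaMP-like axons (including conjunction-only multimodal units),
EPSP-bearing sweep sets with configurable connectivity and latency,
parameterized behavioral agents, and circadian-modulated activity.
All generators are deterministic in (seed, config).

## Worked example

Simulate a conditioning session from an agent that first-pokes the
correct port with probability 0.7 and each wrong port with
probability 0.1, then score it:

```python
from clapipe import behavior, synthetic
from clapipe.config import SimConfig

cfg = SimConfig(seed=42)
agent = synthetic.rate_agent(hit_p=0.7, fa_p=0.1)
session = synthetic.simulate_behavior_session(cfg, agent, "multimodal", n_trials=300)
table = behavior.classify_trials(session)
print(behavior.dprime_table(table).round(3))
```

```
       HR     FR  n_signal  n_noise  dprime
A   0.663  0.090     101.0    199.0   1.760
V   0.725  0.076     102.0    198.0   2.033
AV  0.732  0.113      97.0    203.0   1.828
```

Each row is one stimulus. `HR` is hits over presented trials, `FR`
false alarms over absent trials, and `dprime` the difference of their
normal quantiles — the closed form for this agent is
Z(0.7) − Z(0.1) ≈ 1.81, which the 300-trial estimates scatter around.

The same pattern applies to the other streams, e.g.
`imaging.profile_axons(...)` for per-axon taxonomy tables or
`opto.expected_integration(...)` for the integration ratio. A thin
CLI wraps the library: `clapipe simulate axons --seed 1 --out rec.h5`
then `clapipe axons --in rec.h5 --out results/`.

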