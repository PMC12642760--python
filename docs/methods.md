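# Methods

`efish` is an agent-based model of collective electro-sensing and
electro-communication in weakly electric fish (mormyrids such as
*Gnathonemus petersii*). Recurrent agents forage in a 2D arena, probe their
surroundings with brief electric organ discharges (EODs), hear each other's
pulses through a long-range social channel, and are trained with multi-agent
PPO on purely individual rewards. This note documents the model, its
assumptions, the parameters that matter, and the numerical choices.

## Arena and agent dynamics

The arena is a rectangle (default 200 × 200 cm) with insulating walls,
discretized at dt = 0.04 s (25 Hz). The timestep was chosen so that a
0.36 s behavioral analysis window is exactly 9 steps and an EOD pulse is one
step wide. Agents are point fish with a heading; per step each picks

* `thrust` ∈ [0, 1] — forward speed fraction of v_max = 20 cm/s,
* `turn` ∈ [−1, 1] — turn-rate fraction of ω_max = π rad/s,
* `eod` ∈ {0, 1} — whether to discharge this step,
* `bite` ∈ {0, 1} — whether to snap at a conspecific.

Heading updates before translation; positions are clamped per-axis to the
arena, which for straight-line motion within a step equals sliding along the
wall with the normal velocity zeroed (verified against a sub-step collision
oracle in the tests). Episodes run 1500 steps (60 s) by default.

Food comes in circular patches (radius 10 cm). In **competitive** mode each
patch below capacity gains one item per step with probability
min(1, r·dt) (finite replenishment, zero-sum at r = 0); in
**non-competitive** mode patches are topped up to capacity every step.
Eating is automatic within a 2 cm radius — the fish has no explicit eat
action, mirroring the action set, which lists none.

**Bites.** A bite lands on the nearest conspecific within 4 cm in the
biter's frontal half-plane. With biter dominance d_b and victim dominance
d_v (fixed per-agent scalars in [0, 1], resampled each episode),

    victim penalty = −c_bite · σ(k (d_b − d_v)),
    biter  penalty = −c_bite · σ(k (d_v − d_b)),   σ = logistic, k = 6,

so penalties are asymmetric in dominance and the more dominant party in any
encounter always loses less; at equal dominance both lose c_bite/2.
Dominance is not directly observable to conspecifics — only its behavioral
consequences are.

**Rewards** contain exactly three terms: +1 per food item, −c_eod = −0.01
per discharge, and the bite penalties. The EOD cost is what makes discharge
rate a meaningful decision variable (without it there is no incentive to
freeload); nothing rewards proximity, coordination or signalling, so any
social structure in trained behavior is emergent.

## Electric-field forward model

Every field contributor is an ideal point dipole evaluated in the plane:

    E(r) = κ [3 (p·r̂) r̂ − p] / max(|r|, r_min)³,   κ = 1, r_min = 1 cm.

The 1/r³ (3D) law rather than a true 2D solution follows the convention of
electric-fish modeling at fish scale; the softening radius removes the
singularity. Three source kinds exist:

1. **Emitters** — an agent with eod = 1 carries a dipole of amplitude 100
   along its body axis for exactly one step (EODs are binary events, no
   intra-pulse waveform).
2. **Induced sources** — each polarizable object (food item, α = 100;
   conspecific body, α = 200) acquires p = α · E_emitters at its location.
   First Born approximation: objects do not re-polarize each other, and a
   body is never polarized by its own emitter.
3. **Images** — each real source is mirrored once across each of the four
   walls with the wall-normal moment component negated, which cancels the
   normal field at the wall (insulating/Neumann boundary; tank walls and the
   water surface conduct poorly). No images of images.

First-order scattering keeps the per-step cost O(sources × objects) and is
the dominant contribution at these polarizabilities. A config flag
`reflections_enabled=False` gives open-water physics (no walls in the field;
motion is still confined) — used where exact rotational symmetry is needed.

## Sensors

Each agent carries 8 point receptors on a 6 × 2 cm body ellipse and builds a
fixed-length egocentric observation with four blocks:

* **active** (8): |E_total| − |E_direct| per receptor, where E_direct is the
  field of the illuminating emitters alone and E_total adds induced sources
  and images. The agent's own EOD always illuminates; with
  `collective_sensing_enabled` the neighbors' EODs illuminate too. This *is*
  the collective-sensing pathway — extra illumination of the same channels,
  so the downstream network need not know who lit the scene. The round trip
  (emitter → object → receptor) decays like 1/r⁶, making this the
  short-range channel (~10 cm).
* **passive** (8): |E| of weak static dipoles (moment 5, random orientation
  at spawn) carried by food items, standing in for prey bioelectric fields;
  effective range ~5 cm.
* **knollenorgan** (8 bins): conspecific EOD pulses binned by egocentric
  direction with amplitude A₀/max(d, r_min)², hard cutoff at the
  communication radius (50 cm). The slower 1/r² falloff realizes "long
  range" relative to active sensing. Own pulses are excluded. Binned
  directions were chosen over per-receptor pulse images or identity-tagged
  events as the simplest representation that preserves bearing.
* **proprio** (3): speed/v_max, last turn command, own EOD flag.

Field blocks are compressed elementwise with y = sign(x)·log(1 + |x|/s),
s = 1, because magnitudes span decades. No sensory noise by default;
per-block Gaussian noise is available in config. Rotating the entire scene
and the agent together leaves the observation unchanged (exactly so in open
water; walls break the symmetry, which is why the invariance checks disable
reflections).

## Controller and training

All agents share one parameter set and keep private hidden states: a
recurrent core (plain tanh recurrence by default — matching the tanh
nonlinearity of the rest of the network — with a GRU available by config)
followed by parallel actor and critic two-layer MLPs, all layers equally
wide (512 at full scale; tests and the bundled experiments use 16–64 units
to keep runtimes in minutes). Continuous heads are Beta distributions on
bounded supports (softplus(·)+1 concentrations, so densities stay unimodal);
EOD and bite are Bernoulli logits.

Training is multi-agent PPO: rollouts from 8 parallel arenas, GAE
(γ = 0.99, λ = 0.95), clipped surrogate (ε = 0.2), advantage normalization
per batch, entropy bonus 0.01, value coefficient 0.5, Adam at 3·10⁻⁴,
global-norm gradient clipping at 0.5, rollout length T = 256 (the bundled
experiments use 128), 4 epochs per batch. Recurrent segments are replayed
exactly from hidden-state snapshots taken at rollout starts (burn-in 0 —
exactness over sophistication). The critic is decentralized by default
(reads the shared recurrent state); a `centralized_critic` flag substitutes
a MAPPO-style feedforward value network over the concatenation of all
agents' observations plus a one-hot agent index. Gradients come from a
small reverse-mode tape (`efish.autodiff`) validated against central finite
differences.

Everything is seeded through named substreams of a single root seed
(`efish.rng`): stream names are hashed with the root so adding an RNG
consumer never perturbs existing draws. Single-threaded runs are
bit-reproducible.

## Analytics

All analyses are pure functions of an `EpisodeTrace`:

* **SPI** — sequential pulse intervals per agent. The tail diagnostic fits a
  least-squares line to the log survival function below the 90th-percentile
  cut and reports `excess_mass`, the mean positive deviation of the
  empirical log-survival above the line beyond the cut: ~0 for exponential
  trains, positive for heavy tails. Survival (not density) avoids binning;
  degenerate single-valued trains return a flat fit rather than an error.
* **EOD probability** — fraction of steps discharging, with bootstrap
  (1000 resamples, seeded) CIs over per-episode means.
* **Displacement** — Euclidean displacement over non-overlapping 9-step
  (0.36 s) windows.
* **Theil index** — T = (1/N) Σ (xᵢ/μ) ln(xᵢ/μ) of food consumption, 0 at
  equality, ln N at maximal concentration.
* **Social EOD motifs** — within maximal windows where a pair stays ≤ 15 cm
  apart for ≥ 4 steps, a 4-step window slides over both agents' binary EOD
  strings; the ordered string pair (lexicographically smaller first) is
  counted and the top 6 reported. Motif length and the canonical ordering
  are this package's conventions.
* **Freeloading** — per pair, |rate_A − rate_B| / (rate_A + rate_B) over
  pooled interaction-window steps (0 if both silent); a planted 3:1 rate
  asymmetry gives 0.5. A companion rank-sum compares pooled SPI
  distributions across collective-sensing conditions.
* **Two-fish assay** — agent A starts inside a fully replenishing patch,
  B within communication radius of A; across dominance pairs and ablations
  (A removed; Knollenorgan off) the harness reports how often B's center
  enters the patch disc ("reach") and B's food intake over 100 seeded runs,
  binned by B's start bearing and distance. Scripted controllers (periodic
  emitter A, Knollenorgan-climbing B) let the assay quantify the information
  content of the social channel without any training.

## Synthetic traces

`efish.synth` emits schema-identical traces with exactly known structure:
Bernoulli/renewal/scripted EOD trains, stationary/straight/waypoint
trajectories, planted close-proximity windows, planted consumption tallies.
It emulates the *record format* of real rollouts, not their dynamics: no
field physics, no policy, no wall interactions. Tests that pass on
synthetic traces therefore validate the analytics' arithmetic and recovery
properties, not the realism of trained behavior — that is what the training
and assay checks are for.

## Problem sizes in the bundled checks

The packaged verification runs are scaled to commodity hardware: the
learning check trains a 16-unit policy for 2·10⁵ env steps (×3 seeds) in a
50 × 50 cm dense-food arena and requires trained food intake > 3× a uniform
random baseline in ≥ 2 of 3 seeds; analytics recovery uses 10⁴-interval
trains (100 control + 100 mixture); the assay uses 100 paired episodes.
Full-scale replication of trained-agent condition contrasts (e.g.
Knollenorgan raising EOD rates only under competition) needs multi-hour
multi-agent training at width 512 and is exposed through the CLI
(`efish train`) rather than gated into the test suite.

## Known limitations

* Point fish: no body flexion, no hydrodynamics, no 3D.
* First-order scattering and first-order images only.
* EODs are single-step binary events; no waveform discrimination, no
  mormyromast A/B-cell coding.
* Dominance is exogenous and static within an episode, not learned.
* Passive sensing covers prey-like static dipoles only, not conspecific DC
  fields.
* The scripted assay policies are deliberately minimal probes of the sensor
  channel, not models of fish approach behavior.
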