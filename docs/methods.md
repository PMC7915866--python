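# Methods

## Scope and data model

The pipeline analyses multichannel surface EMG recorded during repeated
stereotyped movements (lift 1.5 s, hold 1 s, lower 1.5 s; ten repetitions;
2000 Hz; 33 channels V1…V33 covering the front, back and side of a residual
limb).  A recording is a samples × channels matrix plus phase-span
annotations.  Network analysis runs on the lift phase, where the prosthesis
load falls on the stump.

## Preprocessing

Zero-phase (forward–backward) Butterworth band-pass, order 4, 20–450 Hz,
followed by per-channel mean subtraction ("zero-drift removal").
Zero-phase filtering is chosen so envelope timing is not shifted by group
delay, which matters for the causality stage.  An optional edge trim
(default off) can drop the first/last 0.1 s of each repetition.  Filter
order and band are conventional for surface EMG; they are exposed in the
configuration because the acquisition literature does not fix them.

## Functional network

* **Estimator.** Histogram entropies over B equal-width bins per channel
  spanning the observed range, default B = 16.  `MI = H(S)+H(Q)−H(S,Q)` is
  clipped at 0 (the identity is exact for the histogram model, so negative
  values are floating-point noise).
* **Normalization.** Default `MI/√(H_S·H_Q)`: intrinsically bounded in
  [0, 1] because `MI ≤ min(H_S, H_Q)`, and comparable across recordings.
  Channels with zero entropy share no information and score 0.
* **Aggregation.** One matrix per repetition segment, arithmetic mean
  across the ten repetitions.
* **Threshold.** Strict rule `a_ij = 1 iff w_ij > TH`.  TH is scanned on a
  0.01 grid; feasible values keep a single connected component with no
  isolated nodes and average degree above `2 ln n`; the largest feasible
  value (sparsest valid network) is selected, and the full diagnostic trace
  (average degree, isolated-node count, component count per TH) is
  returned.  Across movement conditions one common threshold is used — the
  largest value feasible for every condition — so per-condition network
  features remain comparable.  Note the normalized-MI scale depends on the
  estimator; thresholds selected here (≈0.05 on surrogate data) are not
  comparable to values reported for other estimators or normalizations.

## Topology metrics and importance

Degrees, degree distribution, local clustering (`C_i := 0` for degree < 2,
keeping the network value a mean over all nodes), and BFS average path
length; disconnected input raises an error carrying component sizes.
Cohesion is `∂(M) = 1/(nL)`; contracting node *i* merges `{i} ∪ N(i)` into
one supernode (parallel edges collapse, self-loops drop), and
`IMC(i) = 1 − ∂(M)/∂(M×i)`.  When a contraction collapses the network to a
single node, its cohesion is defined as 1 — the supremum 1/(nL) can
approach — giving fully dominating nodes the maximal score.  Ties in IMC
are reported as equal.  Key nodes are those with `IMC > 0.5` in any
condition (the union); the cut is the published convention and is exposed
as a parameter.

The default six-area electrode map (front V1–V6/V7–V12, back V13–V17/
V18–V23, side V24–V28/V29–V33) splits each surface into two roughly equal
areas without anatomical claim about which half is nearer the wound; it is
fully overridable.

## Convergent cross-mapping

* **Embedding.** `x(t) = ⟨x[t], x[t−τ], …, x[t−(E−1)τ]⟩`.  Defaults:
  E = 3 at the function level (the pipeline uses E = 4, which resolved
  band-limited carrier dynamics noticeably better in calibration);
  τ = first local minimum of the autocorrelation, capped at 50 ms of
  samples, computed per channel and combined per pair as the maximum.
* **Simplex projection.** E+1 nearest library neighbours of the target
  point, excluding points within a Theiler window of `(E−1)τ` samples;
  weights `w_i ∝ exp(−d_i/d_1)`.  The weighting ratio sometimes printed
  for this estimator is degenerate (identically one); `weights="uniform"`
  reproduces that variant.  Libraries are random subsets of manifold
  points; skill is the Pearson r between estimate and truth, averaged over
  repeats, with convergence summarized by the Spearman trend of skill
  against library size.  For long series the correlation is evaluated on a
  random subsample of prediction points (default 1200), which leaves the
  skill estimate unbiased.
* **Decision rules.**  With `D = Mx − My` (Mx = skill of estimating x from
  y's manifold): D > 0.3 → x→y;  D ≤ 0.1 → none;  0.1 < D ≤ 0.3 with
  Mx ≥ 0.5 → none;  with Mx < 0.5 → x→y; mirrored for y→x.  Boundary
  conventions (0.1 → rule 2; 0.3 → rules 3/4; Mx = 0.5 → rule 3) are fixed
  and tested.  Rules 3/4 reward the *lower* Mx with a causal call — this is
  counterintuitive but implemented exactly as published.  Because the rules
  presuppose skills that have converged to a meaningfully positive value,
  the network-building stage only records a verdict when at least one
  direction's converged skill reaches 0.2; without this floor rule 4 fires
  on noise pairs whose skills hover near zero.
* **Channel series.**  Three modes.  The default, `carrier`, band-passes
  the signal to 50–320 Hz and divides by the repetition-locked mean
  amplitude profile (a deterministic divisor that removes the movement
  envelope without imprinting per-repetition noise).  `envelope` feeds
  rectified 10-Hz low-pass envelopes, decimated ×20 and profile-normalized;
  `raw` feeds the filtered signal as-is.  The envelope mode is the
  traditional choice, but a quantitative noise analysis (below) shows it
  cannot resolve direction at these recording lengths, which is why the
  carrier mode is the default.

### Why causality is sought in carrier dynamics, not envelopes

Amplitude envelopes of a wide-band stochastic carrier are estimated with a
relative error of roughly `0.6/√N_eff`, where `N_eff ≈ bandwidth × window`
is the number of independent samples per smoothing window.  At 2 kHz with a
20–450 Hz carrier and the ~15 s of lift data a session provides, that floor
is tens of percent of any physiologically plausible slow modulation.
Cross-map direction detection is extremely sensitive to observation noise:
on the canonical unidirectionally coupled logistic pair, 10 % additive
observation noise already flattens the skill asymmetry and 30 % inverts it
(the robust direction becomes the *functional regression* driver→target,
which the rules map to the anti-causal arrow).  Envelope-level couplings
are therefore undetectable-by-construction in short sessions — an honest
negative, not an implementation gap.  The surrogate generator instead
plants causality where cross-mapping can see it: in deterministic carrier
dynamics occupying a dedicated sub-band.

## Surrogate data generator

Signal model per channel: band-limited stochastic carrier × deterministic
phase envelope × slow stochastic modulation.

* **Carrier.** White Gaussian noise band-passed to 20–450 Hz.  A channel's
  carrier mixes a shared source and a private source with weight
  `g = group_strength`; the shared source itself blends a per-group source
  with one global source (`global_mix`, default 0.6), giving cross-group
  pairs a graded baseline dependence.  `g = 0` is exactly independent;
  `g = 1` makes same-group channels bit-identical.
* **Envelope.** Per repetition: linear ramp up (lift), plateau (hold),
  ramp down (lower); rests between repetition blocks are omitted as they
  carry no analysis weight.
* **Modulation.** Logistic-map streams at 20 Hz ticks (global / per-group /
  private, mixed with weight g), smoothed at 8 Hz, entering as the
  multiplier `(1−depth) + 2·depth·m` with `mod_depth` default 0.5.  Shared
  slow co-modulation is what gives high-density EMG its strong within-group
  mutual information.
* **Planted causality.** Coupled channels add a chaotic oscillator
  component (Roessler-type; base cycle 160 Hz, inside the EMG band) at
  amplitude weight 0.85, while their stochastic carrier part is band-stop
  filtered over 40–360 Hz so the 50–320 Hz analysis band belongs to the
  oscillator alone.  The driver's oscillator runs free; each target's is
  detuned in frequency and receives a weak diffusive force
  `k·(x_driver(t−lag) − x_target)`, `k` default 0.1, lag default 5 ms
  (within one carrier decorrelation time — longer lags destroy zero-offset
  cross-map alignment).  The chaotic component follows the phase envelope
  and only a shallow fraction (0.45) of the channel's modulation depth:
  deep multiplicative modulation would mask the dynamics.  Free-running
  chaotic channels cycle through detuned frequency factors so no two
  oscillators coincide.
* **Determinism.** One seeded generator per call; identical configurations
  give bit-identical recordings.

What the surrogates emulate: channel counts, rates, phase structure,
group-structured dependence with graded background, envelope-dominated
pairwise MI, and recoverable directed coupling.  What they do not emulate:
motor-unit physiology, electrode lift-off and motion artifacts, fatigue,
volume-conduction crosstalk profiles, or realistic amplitude units.
Passing tests therefore demonstrate the *pipeline's* correctness and
sensitivity under a controlled model, not clinical performance.

### Canonical scenarios

`planted_sensor_scenario(seed)` plants a strongly coupled side group
(V24–V33 at g = 0.8, all carrying chaotic components) with driver V28 →
{V24, V31}, against loosely coupled front/back groups (g = 0.3).  The low
background strength keeps the selected threshold low enough that the
chaotic side channels — whose stochastic (network-visible) share is small —
stay connected and above the importance cut.  Across seeds this recovers
the full side group in the key-node set and exactly the two planted arcs,
with the driver heading the sensor ranking.  `movement_condition_configs`
scales that design into three movement conditions with graded coordination
so the weakly coordinated condition separates at the 2-cluster cut.

## Movement-difference analysis

Per condition, the key-node network (induced subgraph of the full binary
network on the key nodes) yields the feature row (C, ⟨k⟩, L).  Conditions
are clustered by average-linkage agglomeration on z-scored features with
Euclidean distances; partitions, not dendrogram heights, are the contract
(the published workflow's proprietary rescaling is not reproduced).
Statistical comparisons across conditions are reported as descriptive
differences only; single-subject surrogate runs cannot reproduce cohort
p-values.

## Numerical choices and degenerate inputs

Constant channels have zero entropy (not an error) and zero normalized MI;
constant series in cross-mapping yield skill 0 with a warning; exact
nearest-neighbour ties at distance zero receive all the weight; the
threshold scan reports an explicit failure with its full trace when no
grid value is feasible; disconnected networks raise errors carrying
component sizes everywhere a path-based quantity is requested, except the
per-condition feature table, which flags the row instead.  Library draws,
prediction subsets and generator streams all flow from explicit seeds.

## Problem sizes

Default test and reproduction runs use: 20-seed nulls at 3000 samples for
the MI independence check; 20 seeded coupled-logistic pairs of length 1000
for direction recovery; 33-channel, 10-repetition surrogate sessions
(80 000 samples) for end-to-end recovery, with 2 library repeats and
1200-point prediction subsets in the pipeline's cross-mapping stage; and
exhaustive enumeration of all connected graphs up to six nodes for the
metric-oracle equivalence.  These sizes were chosen to make the statistical
claims stable while keeping a full reproduction run in the minutes range.

## Known limitations

* The published threshold (0.55) and nine-node key set derive from an
  undeposited human cohort and a normalization the source does not state;
  they are not recomputable and are used only as worked-example inputs
  where printed.
* Rule 4's preference for low skills makes the classifier vulnerable to
  spurious calls on weakly converged pairs; the 0.2 skill floor is a
  pragmatic guard, not part of the published rules.
* CCM on common-drive structures can flag indirect edges (two targets of
  one driver are mutually predictable); the rules' "none" verdict for
  symmetric skills suppresses this in practice but is not a guarantee.
* The sensor-ranking key (path depth, then net flow, then label) is a
  declared formalization of a narrative ranking; other keys are defensible.
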