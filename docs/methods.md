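# Methods

## Model

### Physiology

All developmental physiology derives from a single exponential clock, the
depletion of the brown-adipose-tissue (BAT) reserve P = e^(−t/k) over
postnatal days t, with time constant k = 8.31 days. The entropy associated
with consuming the reserve, S = −kP ln P ≡ t·e^(−t/k), vanishes at birth,
peaks at exactly t = k, and decays back towards zero; the mass-specific
metabolic rate is modelled as basal-plus-entropy, G = k(1 + S), in
cal·g⁻¹·h⁻¹, so the same constant k plays three roles (decay time, basal
rate, and — below — asymptotic muscle mass). Growth splits the body into
muscle mass M = k(1 − P), which satisfies the saturating law
dM/dt = (k − M)/k, and non-muscle mass N = c·e^(−kT₁) with asymptote
c = 19 g, which satisfies dN/dM = c₁N exactly. Behavioural
thermoregulation emerges from two competing preferred-temperature
deviations around an adult target T_p = 36 °C: a warm deviation T₁ = c₁P
(c₁ = 3 °C) reflecting BAT dependence, and a cool deviation T₂ = c₂GN
(c₂ = 0.025) reflecting whole-body non-muscle metabolism.

Time is continuous (real-valued days); the daily simulation samples it at
integer days. Functions are NumPy-vectorized and reject negative days.

Two deliberate readings of the printed model are kept as-is rather than
"corrected":

- The non-muscle exponent is k·T₁ literally, which makes
  N(0) = c·e^(−kc₁) ≈ 2.8×10⁻¹⁰ g. Birth mass in the model is therefore
  essentially the muscle offset, a model artifact, not a claim about
  neonatal mass.
- The muscle growth law is stated in the source literature as
  dM/dt = k − M, but the closed form M = k(1 − e^(−t/k)) implies the
  proportional law dM/dt = (k − M)/k. The package documents and tests the
  proportional form, which is the one consistent with the closed form.

The competition "select either T_p + T₁ or T_p − T₂" is resolved by a
dominant-deviation rule: whichever deviation is larger wins. This is the
only deterministic rule consistent with both asymptotes (≈ 39 °C at birth,
≈ 32 °C at day 60) and it produces a single warm-to-cool switch at
t ≈ 16.46 days, where T₁ = T₂. The huddling drive handed to the Monte
Carlo layer is β(T₁ − T₂) with β = 0.2: +0.6 at birth, −0.81 at day 60,
one sign change, at the same day as the temperature switch.

### Monte Carlo group formation

The litter state is a set partition of n = 7 pups into huddle groups,
starting as one group (pups are born huddled). One encounter: pick pup a
uniformly; pick b uniformly from pups outside a's group; join the two
groups with probability ρ = sigmoid(T), else detach a into a singleton.
Two boundary conventions keep the chain irreducible and the learning
reward stream defined:

- When the whole litter is one group, b is drawn uniformly from the other
  pups and the "join" branch is a no-op (recorded as joined, reward 1):
  the single-group state is sticky but not absorbing.
- Detaching a pup that is already a singleton leaves the partition
  unchanged.

Merged groups keep the initiator's label; labels are an internal detail
and partition equality is label-invariant. Two mean-group-size estimators
are exposed: pups-per-group n/#groups (default, the literal reading of
"average group size") and the pup-weighted Σsizes²/n (the expected size of
a random pup's group); the source description does not disambiguate, so
both are configuration.

For litters of up to 5 pups the package builds the exact transition matrix
over all labelled set partitions (Bell(5) = 52 states) and extracts the
stationary distribution as the unit left eigenvector. This oracle is
independent of the sampling path and anchors the correctness of the
simulator: empirical visit frequencies at n = 4 match it to total
variation < 0.02 over 2×10⁵ steps.

### Learning

Each pup a holds a directed associative strength α_{a,b} for littermate
b's odour (diagonal unused, values unbounded, no clamping or decay). The
drive gating an encounter is the partner's association for the initiator
times the thermal drive, T = α_{b,a}·β(T₁ − T₂); the Delta-rule update
trains the initiator's entry with a compound prediction,
Δα_{a,b} = γ(r − Σ_{i≠a} α_{a,i}), γ = 0.001, r ∈ {0, 1}. Exactly one
update is applied per encounter (the initiator's), preserving the
asymmetry of the two equations as written; a `symmetric_update` flag
additionally applies the mirrored update, off by default. The compound sum
makes total outgoing association self-limiting: under i.i.d. rewards at
rate q the sum settles within ±0.05 of q, which is the boundedness
mechanism that enforces competition among pairwise strengths. In the
control condition all α are pinned at 1, reducing the gated drive to the
physiological one; running the learning machinery with γ = 0 and α ≡ 1
reproduces the control bit for bit (the constants type allows γ = 0 for
exactly this purpose).

### Simulation protocol

Days 0–60 inclusive; 1000 encounters per day; 10 replicate litters;
partition and association state persist across days within a replicate.
Daily statistics average the estimator over all encounters of the day
(not just the final state) and then across replicates. Replicates draw
independent child streams from one seeded `SeedSequence`; every CLI run
writes a JSON manifest (config, seed, version) beside its CSV.

The 1000-encounters/day default puts ≈ 6.1×10⁴ sigmoid evaluations in a
replicate. The encounter rate matters qualitatively: it sets how far the
Delta rule can discriminate among littermates. At 1000/day the day-60
association matrices are tightly clustered (spread ≈ 0.02 around a mean of
≈ 0.08) and effectively all positive; at 20000/day the closed loop between
behaviour and learning amplifies early chance differences into strongly
positive and negative associations (|α| up to ≈ 2, both signs present in
every replicate). The headline developmental results — the divergence day
and the late critical join probability — are insensitive to this choice;
the sign heterogeneity of individual preferences is not, and the test
suite checks it at the high encounter rate. Mechanistically, the
directed pair (α_{a,b}, α_{b,a}) is cross-coupled through behaviour with
gain |σ′·β(T₁−T₂)| < 1 per update, so discrimination grows diffusively
with the number of updates rather than explosively; more encounters per
day mean more spread.

The divergence day is the smallest day d from which the learning
condition's replicate-averaged mean group size strictly exceeds the
control's for a persistence window of 5 consecutive grid days (window
truncated at the end of the grid); the 5-day window guards against noise
crossings and is exposed as a flag. The steady-state join probability is
the mean recorded ρ over the final 15 days (days 45–60 of a full run) and
all replicates; since every day contributes equally many encounters, the
day-mean average equals the per-encounter average.

The simulation inner loop is a hand-unrolled equivalent of the elementary
`mc_step` + `delta_update` operations. It consumes the random stream
identically (three uniform draws per encounter) and uses the same
two-branch stable sigmoid and left-to-right row summation, so its
trajectories are bit-for-bit equal to composing the elementary operations
— asserted in the test suite, and the reason `join_probability`'s scalar
path avoids `scipy.special.expit` (which differs in the last ulp).

### Calibration on synthetic data

The historical calibration measurements exist only as plotted scatter, so
the package ships a generator that emulates their structure instead: for
a chosen day grid (default one observation per day, days 1–60) it
evaluates the physiology curves and adds independent Gaussian noise. A
scalar noise spec means "sd = that fraction of the variable's noiseless
range" (so 0.05 is 5%-of-range noise on every column); a mapping gives
absolute sds per column. Raw BAT observations are mapped to a percent
scale between synthetic anchors 4.0% (birth) → 0.8% (adult), a realistic
interscapular-BAT fraction range for neonatal rodents; the affine
normalization (p − p₀)/(p₁ − p₀) recovers the unit decay.

What the generator does **not** emulate: day-to-day correlation within an
animal, heteroscedastic measurement error, animal-to-animal variation in
the constants, attrition, or the bimodal scatter of thermocline selections
around both branches at once. Passing recovery tests therefore show that
the staged fit is consistent and correctly implemented — not that the
constants are identifiable from the historical data themselves.

The fit is staged to mirror the model's causal order and avoid
identifiability tangles between c₂ and T_p: (1) k from a three-parameter
exponential fit to the BAT column (anchors free, robust to noise in the
first/final measurements); (2) c, c₁ from body mass given k; (3) c₂ and
optionally T_p from the selected temperatures given the rest, scoring
each observation against its nearest branch (warm T_p + T₁ or cool
T_p − T₂) since an animal may sit on either. All stages are ordinary
`scipy.optimize` least squares (`curve_fit`, `least_squares` with tight
tolerances); noiseless self-generated data is recovered to ≤ 10⁻⁶ on k and
≤ 10⁻⁴ relative on the rest, and at 5%-of-range noise the median relative
error on k stays under 5% across 20 seeds (200 observations). The fit
refuses datasets without ≥ 10 distinct days spanning early (< k) and late
(> 3k) development, since the stages are then unconstrained.

## Numerical choices

- Entropy is computed as −kP ln P with a guard returning 0 where P
  underflows to 0 (t ≳ 6200 days); the closed-form equivalence S = t·e^(−t/k)
  holds to 10⁻¹² relative error on [0, 60].
- W = M + N is computed literally as the sum of the two mass functions,
  so conservation holds to the last bit.
- Uniform integers in the sampler are floor-of-uniform with a clamp at the
  upper bound, making block pre-generation exactly reproduce scalar draws.
- The stationary oracle normalizes the eigenvector with |·|₁ and verifies
  the leading eigenvalue is 1 to 10⁻⁹.
- Problem sizes in the test suite (2×10⁵-step chain comparisons, 10⁵-step
  monotonicity grids, 10-replicate developmental runs, 20-seed recovery
  studies) were chosen so the whole suite exercises every claim at
  meaningful precision while remaining a routine desk-side run.

## Known limitations

- Aspatial: groups are abstract sets, so geometry-dependent phenomena
  (surface-to-volume scaling, pup flow between huddle core and periphery,
  ambient-temperature fields) are out of scope by design.
- One update per encounter and a single litter-wide clock: no individual
  differences in physiology (all pups share k, c₁, c₂), so emergent
  preference heterogeneity is purely history-driven.
- The learning rule is the simplest error-correcting form; richer
  conditioning models are expected to behave qualitatively the same but
  are not implemented.
- Mean-group-size traces depend mildly on the estimator; both estimators
  are reported machinery, and cross-condition conclusions (divergence,
  late ordering, ρ) are estimator-robust in the suite's checks.
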