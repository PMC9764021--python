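# Methods

## Coordinate conventions and geometry

All analyses project particle positions onto a single pore axis oriented
from the intracellular (CTD) side to the extracellular side; `z` denotes
the axial coordinate in Å. The extended pore is partitioned into
contiguous half-open intervals `[z_lo, z_hi)` with the upper site winning
at boundaries, so site assignment is total, deterministic and never double
counts. The bundled synthetic geometry uses canonical 3.3-Å SF site
spacing — S6 = [−6.6, −3.3) up through S0 = [13.2, 16.5), S4 starting at
z = 0 — with the cavity at [−20, −6.6), G-loop [−30, −20), CTD [−55, −30)
and an extracellular vestibule S_ext = [16.5, 25). The hydration cylinder
is radius 8 Å over z ∈ [−20, 0). For real trajectories the axis is the
line from the CTD-ring center of mass to the SF-backbone center of mass;
all analyzers read boundaries from the geometry object and hard-code
nothing.

Applied-field voltages convert as `V = E · L_z · 43.3641 mV` with `E` in
kcal mol⁻¹ Å⁻¹ e⁻¹ and `L_z` in Å (1 kcal/mol per e is 0.0433641 V). The
constant is exact; published field/voltage pairs that disagree with it at
the fourth digit are treated as rounded values, and the consistency check
in `VoltageProtocol` uses the exact constant.

## The kinetic generator

`kirpore.synthetic.simulate` is an exact-jump (next-reaction/Gillespie)
simulation of a continuous-time Markov chain over the chain of pore sites
`bulk_in → CTD → G_loop → cavity → S6 … S0 → S_ext → bulk_out`.

* **Rates and voltage.** Each directed edge carries a zero-field rate k₀
  (µs⁻¹) and each undirected edge a voltage-coupling fraction δ, with Σδ
  over the full transmembrane path equal to 1. Hops are biased with the
  symmetric Eyring factor `k(V) = k₀·exp(± z q δ V F / (2RT))` (charge +1
  for K⁺, +4 for the fully protonated spermine; T = 310 K, RT/F ≈ 26.71
  mV). Simulations hold V fixed, so all biased rates are precomputed once.
* **Exclusion.** SF sites and the vestibule hold one ion; the cavity and
  CTD hold four (G-loop one). Hops into a full site have zero propensity.
* **Permeation bookkeeping.** A per-ion two-sided state machine mirrors
  the coordinate-space detector exactly: the side flips to "intracellular"
  in bulk_in/CTD/G-loop/cavity and to "extracellular" in bulk_out; an
  in→out flip logs `permeation_out` (out→in logs `permeation_in`). Frame
  placement respects the same semantics (cavity ions are drawn below the
  detector's inner threshold, vestibule ions below the outer threshold,
  and absorbed/injected ions carry a few parked bulk frames), which is why
  analyzer event counts equal the log exactly rather than approximately.
* **Water co-permeation** is Bernoulli per completed outward permeation
  (default p = 0.22) rather than explicit single-file water; the analyzers
  consume only the ratio. Each co-permeating water marker appears parked
  on the intracellular side and reappears extracellularly after its event.
* **Gate.** Closure is a single absorbing hazard λ_c; a replicate closes
  at an exponential time and never reopens. Open-state cavity hydration is
  N(56, 8) waters per frame (closed: N(20, 5)); the I177 Cα–Cα diagonal is
  N(16.5, 0.8) Å open and N(10.0, 0.5) Å closed, realized by four
  pseudo-atoms per gate residue paired A–C/B–D by subunit order. The
  CTD–SF center-of-mass separation decreases by 3 Å upon opening.
* **Blocker.** One SPM bead hops over ordered stations (bulk, CTD, G-loop,
  cavity, deep site above D173, SF, translocated) with per-pair (k₀, δ).
  Entering the deep site logs `spm_bind`, instantaneously evicts cavity-
  and SF-resident ions in the direction of the field, and zeroes all ion
  transport into or within cavity+SF while bound. The eviction direction
  and the transport shutdown together reproduce the 5–6 displaced charges;
  zeroing only SF hops would let the cavity refill within the displacement
  window and halve the count.
* **Reproducibility.** One master seed feeds a single `numpy` Generator;
  per-replicate seeds in the pipeline derive from the replicate index by
  fixed arithmetic. Identical configuration + seed ⇒ bit-identical events
  and frames.

Frames are sampled every `dt_ns` (default 2 ns) with Gaussian jitter
(default 0.5 Å, required to stay below half the narrowest site width so
site assignment is recoverable); multi-ion sites place ions uniformly
within the interval.

### Calibration of the wild-type scenario

The model has no experimentally known absolute hop rates; they are free
parameters. The WT preset was calibrated once against published
steady-state observables for open Kir2.2 pores, and then frozen:

* kinetic SF occupancy ≈ 2.87 ions with the axial density peaking at
  S1/S2/S3–S4 (realized by a detailed-balance parametrization of the SF
  hops: fast shuttle sites S6/S5, ~0.8 kT wells at S4–S1, slow S1→S0
  escape);
* cavity ≈ 2.7 and CTD ≈ 2.8 ions;
* an overall rate scale (a uniform factor that leaves the stationary
  distribution unchanged) chosen so occupancy time averages decorrelate
  within a few µs, keeping multi-seed scatter of a 120-µs average near
  ±0.04 ions.

The E225A/E300A preset divides CTD exit rates by 18 and cavity exit rates
by 4. The divisors exceed the target residence ratios (10× CTD, 2×
cavity) because site exclusion makes realized residence sublinear in the
divisor; the calibration targets the observable ratios, not the raw
factors. The blocker's deep-site escape edge is calibrated analytically
through two (voltage, τoff) anchors via
`τ(V) = (1/k₀)·exp(−|V|/V_s)` (`calibrate_blocker_rates`; the two-point
solve gives V_s ≈ 39.1 mV), mapped onto the Eyring form by
δ = 2·(RT/F)/(4·V_s). Downstream (deep→cavity→G-loop→CTD) transit is made
fast (~40 ns) so the detected unbinding time adds only a small positive
offset to the rate-limiting escape.

The mechanism-constrained mode replaces SF dynamics with the concerted
four-state knock-on cycle
`S6[S4,S2],S1 → S5[S4,S2],S1 → S5[S3,S2],S0 → S4[S2,S1],S_ext`
(+ exit and cavity refill), with the second step rate-limiting. It exists
to exercise the configuration-labeling and histogram analyzers on a known
mechanism; it ignores the blocker's eviction flag (blocking only).

## Analyzers

* **Permeation detection** uses two thresholds — inner `z_lo(S6) − 2 Å`,
  outer `z_hi(S0) + 2 Å` — and commits an outward event only when an ion
  last seen below the inner threshold rises above the outer one. This is
  immune to sub-Å jitter and, by construction, excludes ions transiently
  approaching the SF from the extracellular side.
* **Kinetic occupancy** time-averages per-frame region counts. Under the
  `intracellular_entry_only` rule a frame counts only while the particle's
  current visit began by crossing the region's lower boundary; this is the
  causal/streaming version of "outwardly permeating ions" (it does not
  require the ion to eventually permeate). Visits already in progress at
  the start of a record are treated as intracellular entries. Standard
  errors use block averaging (5 blocks) because the series is
  autocorrelated; the windowing behind any published ±error is not
  reproduced, only the estimator is.
* **Water-to-ion ratio** is N_water/N_ion with a Wilson interval.
* **Axial density** is reported either normalized to peak 1 or as mean
  count per frame per Å, so its integral over a range equals the mean
  occupancy of that range.
* **Residence times** are maximal contiguous visits; visits truncated by
  the record end are flagged censored.
* **Closure detection** finds the first frame from which the cavity water
  count stays ≤ 35 for a persistence window (default 1 µs of frames;
  persistence 1 recovers the "first touch" reading, both are exposed
  because the original criterion names only the threshold). Replicate
  summaries use Kaplan–Meier survival so never-closing replicates censor
  correctly; a median the survival curve never reaches is reported as a
  lower bound.
* **Blocker kinetics** smooth the SPM–D173 distance with a centered
  running median (odd window of `round(w/dt) | 1` frames, truncated at the
  edges — no invented data), then apply the 10/20-Å hysteresis pair:
  bound at ≤ 10 Å, unbound at > 20 Å, nothing in between, so bind/unbind
  strictly alternate. τ estimates use the right-censored exponential MLE
  `τ̂ = (Σ observed + Σ censored)/k` with a χ²(2k) interval; whether
  published values were MLEs or simple averages is unstated, censored MLE
  is this package's choice. τon is measured from trajectory start, τoff
  from block start, both censored at the record end.
* **Displaced ions** compare the cavity+SF ion count just before the
  detected deep-binding time against the count 0.5 µs after it (the
  "TM pore" extent is cavity+SF and is configurable, since no numeric
  extent is standard).
* **Torsional corrections** use the single-cosine form because only two
  point values (depth A at θ₀, zero at θ₀ + 180°) are constrained; the
  writer interface accepts alternative shapes. θ₀ values must be supplied
  by the user; no structures are fetched.

## What the generator does and does not emulate

The generator reproduces the *event statistics* the analyzers consume:
crossing counts, occupancies, residence/waiting-time distributions,
hydration and gate-distance distributions, blocker kinetics, and their
voltage dependence. It does not emulate atomistic forces, explicit water
files, chloride, lipids, SF pinning, or correlated sub-site dynamics —
positions within a site are i.i.d. jitter, so passing tests demonstrate
that the estimators are correct and well-calibrated on a process with the
stated statistics, not that any particular force field or channel behaves
this way. Analyzer correctness on real trajectories additionally depends
on choosing geometry boundaries and landmarks appropriate to the system.

## Numerical and edge-case choices

* Half-open intervals with upper-site wins; axial sweeps are validated
  against a linear interval scan.
* Event times in a log are non-decreasing; concerted (multi-ion) moves
  share one timestamp.
* A nonzero-rate model whose reachable state has zero total propensity
  raises a deadlock error naming the state; an all-zero-rate model is
  simply static (empty log).
* Frame counts are `floor(duration/dt) + 1`; oracle comparisons use
  durations aligned to the frame grid.
* `conductance` is undefined (None) at V = 0; the water-to-ion ratio is an
  error with zero ion events; a displacement count without a binding event
  is an error, not zero.
* Problem sizes in the test and acceptance runs (40-µs permeation chunks
  pooled to ≥ 2000 events and ≥ 120 µs of frames; 200 closure replicates
  of 240 µs at 250-ns frames; 30 unbinding replicates per voltage; 25
  displacement replicates) were chosen so each estimator's Monte-Carlo
  scatter sits well inside the tolerance it is checked against.

## Known limitations

* The survival median over 200 exponential closure replicates has ~10%
  relative scatter by construction; occasional excursions near the 15%
  check boundary are expected sampling behavior, not estimator error.
* The blocker bead has no conformational degrees of freedom; station
  anchors make the distance-to-landmark series piecewise stationary, which
  slightly sharpens detection compared with a diffusing polyamine.
* Inward (hyperpolarizing) conduction is modeled but not calibrated to a
  measured inward conductance; only its sign and rectification behavior
  are meaningful.
* The CTD/cavity are radially featureless cylinders; analyses that depend
  on azimuthal structure (per-subunit contacts on real coordinates) are
  supported by the distance operators but not emulated by the generator
  beyond fixed landmarks.
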