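# Methods

## Binding model and fitting

All kinetics assume pseudo-first-order 1:1 Langmuir binding of a protein at
constant concentration C to DNA immobilised on a biosensor:

- association: `Y(t) = Y0 + R_eq (1 − e^(−k_obs t))` with
  `k_obs = k_a C + k_d` and `R_eq = R_max · C / (C + K_d)`;
- dissociation, re-zeroed at the phase boundary:
  `Y(t) = Y0 + R_end e^(−k_d t)` with `R_end` the association-end response;
- `K_d = k_d / k_a`, an identity that holds exactly for every fit result (it
  is derived, never fitted independently).

Two estimation routes are provided and tested against each other:

1. **Two-stage** (`two_stage_fit`): a single-exponential fit per association
   segment gives per-concentration `k_obs`; a straight line in C gives
   `k_a` (slope), and `k_d` comes from the highest-concentration dissociation.
2. **Global** (`global_fit_1to1`): one nonlinear least-squares problem over
   all association and dissociation points of the series, sharing `(k_a, k_d)`
   with per-sensor `R_max` and offset. The dissociation amplitude is tied to
   the association model (`R_end = R_eq (1 − e^(−k_obs T_assoc))`), so the
   two segments constrain the same parameters. The closed form is used
   directly — no ODE integration is needed at constant analyte concentration.
   Initial values are seeded from the two-stage route; optimisation is
   Levenberg-Marquardt (lmfit) with `k_a ≥ 1 M⁻¹s⁻¹` and `k_d ≥ 0`.

Standard errors are 1 SE from the fit covariance; the SE of `K_d` combines the
relative errors of `k_d` and `k_a` in quadrature. No confidence-interval claim
is attached, since fit covariances understate replicate-to-replicate scatter.
R² is pooled over all fitted points (association + dissociation, all sensors),
`1 − SS_res/SS_tot`, reported even when poor. Each sensor gets its own
`R_max` — replicates of one concentration are not forced to share one, since
loading density varies between biosensors in practice.

On noiseless synthetic data the global fit recovers `(k_a, k_d)` to machine
precision; with the default 1% noise model, the spread of recovered `K_d`
across seeds is well under 10% of truth for the default series.

## Preprocessing

Order of operations (each step optional): Savitzky-Golay smoothing, reference
baseline subtraction, interstep alignment.

- **Smoothing**: `scipy.signal.savgol_filter` applied per phase segment so no
  information leaks across step boundaries; defaults window 11 samples,
  polynomial order 3. At the default 0.2 s sampling this preserves exponential
  rates up to roughly 2 s⁻¹; segments shorter than the window fall back to the
  largest valid odd window with a logged warning.
- **Baseline referencing**: the across-sensor mean secondary-baseline trace is
  summarised by an ordinary least-squares line in absolute time and that line
  is subtracted from every sensor's full trace. For a flat common baseline
  this is exactly mean subtraction; the linear form extends the correction to
  the association/dissociation window so common-mode drift is removed there
  too, which pointwise subtraction of a 180-s baseline window alone cannot do.
- **Interstep alignment**: each phase is offset so its first sample equals the
  last sample of the preceding phase. This removes the per-boundary step
  offsets biosensors exhibit and makes the dissociation start equal the
  association end exactly. Numerical note: on a sampled grid the underlying
  signal still rises between the last association sample and the boundary, so
  enforcing sample-level continuity biases slow kinetics (k_obs·dt ≪ 1 and far
  from plateau) by up to ~0.2% in the rates at dt = 0.2 s; this is far below
  the noise floor of real data but visible on noiseless synthetic traces,
  which is why exact-recovery checks run the fit without alignment.

## Binding call

`classify_binding` maps a fit to the qualitative matrix categories: `++`
(strong) for converged fits with K_d < 250 nM, `+` (weak) up to the top assay
concentration (default 3 µM, the highest protein concentration used in the
underlying assays), `−` otherwise. The 250 nM cut is editorial — the published
categories come without numeric thresholds — and is chosen to separate the
measured strong interactions (tens to ~160 nM) from the 16-base minimal site
(360 nM), which sits an order of magnitude above them but still well inside
the assay range.

## Sensorgram simulator

`simulate_sensorgram` follows the five-phase Octet protocol (primary baseline
60 s, loading 150 s, secondary baseline 180 s, association 180 s, dissociation
270 s; sampling 0.2 s, dense enough for k_obs ≈ 1 s⁻¹). The loading phase is a
saturating ramp to an arbitrary load level (default 1.0 response unit) — its
shape never enters any fit, only its endpoint offset does. Noise comprises
white Gaussian noise (default sd 0.01, i.e. 1% of the default R_max), a random
offset at each phase boundary (sd 0.02, emulating interstep artifacts), and
optional linear drift. `simulate_set` derives per-sensor sub-seeds from one
seed (bit-identical reruns) and always appends a zero-concentration reference
sensor.

What the simulator does *not* emulate: mass-transport limitation, bivalent or
heterogeneous binding, biosensor-to-biosensor loading variation, regeneration
effects, and the loading-geometry artifact where a biotin-adjacent operator
binds weaker. Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the stated model, not robustness to systematic
deviations from 1:1 kinetics.

## Operator scanner

Patterns are IUPAC degenerate strings compiled to per-position base sets;
subject sequences must be pure A/C/G/T (ambiguity codes in subjects are
rejected rather than guessed). Scanning slides the pattern over the forward
strand and its reverse complement; coordinates are 0-based, half-open,
forward-strand. A window may match both strands (the consensus is nearly
palindromic) and then yields two hits.

For counting and spacing, overlapping windows are collapsed to the leftmost
hit (two overlapping windows are one physical site). The operator count class
caps at 2 ("two or more"); spacing is end-to-start — the number of bases
between the exclusive end of one collapsed hit and the start of the next
(start-to-start is available as an option). Spacing-distribution modes break
ties toward the smaller gap for determinism. Because counting uses the
16-base consensus rather than the longer repeats a motif-discovery tool would
report, absolute gap values can differ from repeat-to-repeat distances by a
constant offset.

Shipped presets: `OLD_CORE` (`KACANNTGTA`), `MINIMAL_16`
(`ATTGACAAATGTAGAT`), `PNEUMO_16` (`RNYKACAAATGTMRNY`), `FAMILY_16`
(`RNYKACANNYGTMRNY`), `INTERMEDIATE_16` (`RNYKACANNTGTARNY`). Several
non-identical 16-base consensus strings circulate for this family; all are
shipped as named presets and none is asserted as canonical. `FAMILY_16` is the
default for scanning because it is the most inclusive form and cleanly
separates the 18 published probe sequences into their 9 bound / 9 unbound
outcomes.

## Promoter generator

`generate_promoter` builds 100-base upstream regions with exactly 0, 1 or 2
planted operator instances drawn uniformly from the consensus (reverse
complemented when planted on the minus strand), in uniform-random background.
The whole record is rejection-sampled (cap 10,000 attempts) until a
both-strand scan finds hits only at the planted starts with the planted
strands present, so recovered counts and gaps are exact by construction. One
deliberate relaxation: an instance whose draw happens to match the pattern on
both strands at the same start is accepted — rejecting those would bias the
generator against palindromic operators, which are common in this family —
and the duplicate hit collapses to one site downstream.

Two-operator gaps default to a discrete triangular distribution on 24–39
bases peaked at 26, matching the reported range and mode of inter-operator
distances; weights rise linearly to the peak and fall linearly to the upper
bound. With 67 two-operator promoters per panel the *sample* mode of such a
flat-peaked distribution is itself noisy (the per-panel mode is 26 in roughly
a third of panels, 27 next most often), so mode recovery is assessed by
majority vote across 100 panel seeds, which returns 26 reliably.

## Problem sizes and determinism

Default analyses run in seconds on one core: a global fit covers ~13,500
points and ~14 parameters; the acceptance script fits 15 simulated series
(5 affinities × 3 seeds), generates 100 × 67 two-operator promoters for the
gap-mode vote, and one 88-promoter panel. All randomness flows from explicit
integer seeds through `numpy.random.SeedSequence`-derived child seeds, so
every output is bit-reproducible; output files record the tool version, a
configuration hash, and the seed (FASTA, which has no comment syntax, carries
its metadata in the sidecar TSV instead).

## Known limitations

- The binding-call thresholds are calibrated to this assay family; other
  instruments/ranges need different cut-offs.
- The two-stage route assumes the association amplitude is measurable at every
  concentration; very weak binders (K_d far above the top concentration) fall
  back to generic initial values in the global fit.
- Published "±" uncertainties on affinities cannot be reproduced without the
  raw sensorgrams; only recovery of the central values is claimed.
- The scanner does no PWM/log-odds scoring and no de novo motif discovery;
  it tests the stated consensus forms only.
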