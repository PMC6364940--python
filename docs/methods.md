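# Methods

## The model

`isletsync.model` implements a beta-cell islet oscillator in the
dual-oscillator tradition: two conditional oscillators — an electrical one
and a glycolytic/metabolic one — coupled in both directions, extended with
an IP3 pulse pathway and an IP3-gated endoplasmic-reticulum (ER) Ca2+
release flux.  One model cell stands for a whole islet, on the assumption
that gap-junction coupling keeps the cells of an islet synchronized.

State variables (8 ODEs): membrane potential `v`, delayed-rectifier K+
activation `n`, cytosolic and ER free Ca2+ `ca_c`/`ca_er`, fructose
6-phosphate `f6p`, fructose 1,6-bisphosphate `fbp`, ATP `atp`, and `ip3`.
ADP is computed from a conserved adenine pool (`ADP = A_tot − ATP`) so the
nucleotide regulation of the K(ATP) channel — MgADP activating, free ADP3−
and ATP4− inhibiting, in the standard beta-cell formulation — is well
defined with ATP as the only tracked nucleotide.  AMP enters the PFK
scheme through the adenylate-kinase equilibrium `AMP = ADP²/ATP`.

The couplings are the ones that define this model family:

* **metabolism → electricity**: ATP closes K(ATP) channels, depolarizing
  the membrane;
* **electricity → metabolism**: Ca2+ entering through CaV channels
  activates pyruvate dehydrogenase (PDH), increasing the consumption of
  glycolytic FBP and the production of ATP; Ca2+ handling and the ion
  fluxes of the depolarized phase consume ATP;
* **muscarinic input**: a stimulus pulse drives IP3 production,
  `d[IP3]/dt = (IP3_amp(t) − [IP3])/tau_IP3` with `IP3_amp = 0.35 uM`
  while a 10-s pulse is on and 0 otherwise, `tau_IP3 = 10 s`; IP3 opens an
  ER release flux proportional to a Hill function of [IP3] and to the
  ER–cytosol gradient, producing a transient cytosolic Ca2+ rise.

Glucose is not a variable: all experiments the package addresses use a
constant 11 mM bath, represented by a fixed glucokinase flux `j_gk`.
Stimulus concentration is likewise not modeled — any saturating agonist
pulse maps to the single IP3 drive amplitude.

### Design choices

The published account of this model family specifies its structure and
behavior (the equation listing lives in code released elsewhere), so the
kinetic forms here are standard Boltzmann/Hill expressions assembled to
that structure and calibrated to the behavioral constraints: a sustained
cytosolic Ca2+ rhythm with a period near 5 min at default parameters,
metabolic (FBP) oscillations phase-locked to the Ca2+ rhythm, a type-2
phase response curve whose advance region covers the active phase, whose
no-shift band begins near phase 0.5 and whose delay region begins near
phase 0.6, and 1:1 entrainment by 10-s pulses repeated every 5 min.
Within that brief the specific choices worth recording are:

* **Non-spiking plateau regime.**  The depolarized phase is a stable
  quasi-steady plateau, not a train of millisecond action potentials.
  Fluorescence traces sampled every 20 s resolve only the burst envelope,
  and every analysis in the package (nadir timing, FFT periods,
  spectrograms) consumes that envelope; simulating spikes would add
  stiffness without adding observable content.  Accordingly the membrane
  time "capacitance" and the delayed-rectifier time constant are envelope
  timescales, chosen fast enough that the plateau transitions are sharp
  on the minutes scale of the slow rhythm.
* **Slow-rhythm architecture.**  FBP is the pacing variable: during the
  silent phase PFK refills it while Ca2+-starved PDH consumes little, and
  ATP rises with it until K(ATP) closure depolarizes the cell; during the
  plateau, Ca2+-activated PDH drains FBP faster than PFK supplies it, ATP
  production falls below the elevated consumption of the active phase,
  K(ATP) reopens and the burst ends.  Activity-dependent ATP consumption
  is gated by membrane potential (ion pumping during the depolarized
  phase) rather than by cytosolic Ca2+ directly; this keeps the silent
  phase metabolically cheap, so an IP3-evoked Ca2+ transient early in the
  silent phase — when FBP is depleted — has almost no effect on the
  timing of the next burst.  That is what produces the no-shift band of
  the phase response curve, while the same transient late in the silent
  phase drains rebuilt FBP and delays the next burst.
* **PFK allosterics.**  The four-ligand weighted-state PFK scheme (AMP
  and FBP activating, ATP inhibiting, F6P2 as substrate) is retained
  structurally, with nucleotide affinities set weak enough that PFK flux
  tracks the glucokinase input on the burst timescale.  Strong AMP
  feedback is homeostatic on exactly that timescale — low ATP would
  re-activate PFK and clamp ATP — and a clamped ATP cannot pace a
  relaxation oscillation.
* **ER compartment.**  SERCA/leak rates are slow enough that the ER is a
  quasi-static Ca2+ reservoir over one burst cycle; it matters as the
  source of the IP3-evoked transient, not as a pacemaker.  Each 10-s
  pulse lowers `ca_er` by well under one percent of the store.
* **Heterogeneity.**  Islet-to-islet variability is two conductances,
  `g_cav` and `g_katp`, drawn uniformly from ranges calibrated so the
  natural periods fall in the 3–7 min band seen across islets.

### Numerics

Integration uses LSODA with rtol 1e-8 and per-variable atol on each
field's natural scale.  Pulse boundaries are exact: the integration is
split at every onset and offset, so no step straddles a drive switch, and
the IP3 trajectory matches the piecewise-exponential closed form to
better than 1e-6 uM.  The default initial state is a frozen point on the
default-parameter limit cycle near a Ca2+ nadir (transient from cold
starts is a single cycle); a 20-min transient is still discarded before
any measurement.

## Phase response curves

Phase 0 is the onset of a burst active phase, detected as the upward
crossing of the cycle midline with hysteresis (±20% of the cycle
amplitude) so noise cannot split cycles.  The nadir — the Ca2+ minimum
marking the end of a silent phase — is detected as the last sample within
1% of the inter-burst minimum, then refined by parabolic interpolation;
on traces whose troughs are flat every trough sample ties for the
minimum, and the end-of-trough convention is what "end of the silent
phase" means.  `phase_shift` pairs the first post-pulse nadir of the
perturbed run with the nearest unperturbed nadir (ties toward the earlier
one), normalizes by the natural period, and wraps into (−0.5, 0.5]; a
perturbed nadir farther than 0.75 period from every unperturbed nadir is
a matching error, not a silent guess.  `compute_prc` applies one 10-s
pulse per run on an evenly spaced phase grid (default 50 points) measured
from an active-phase onset after the discarded transient.

## Trace analysis

The analysis pipeline mirrors the workflow used on islet fluorescence
recordings.  The group-mean trace is background subtracted with a
least-squares line, smoothed by inserting two linearly interpolated
points between samples (a single-point variant is a parameter), and run
through a short-time Fourier transform: 256-sample Hanning window,
advanced 5 samples at a time, each window zero-padded to 2000 samples so
the spectrum has 1000 positive-frequency bins.  Zero-padding is the only
reading that reconciles a 256-point window with 1000 output bins.  The
frequency axis is reported as period in minutes.  Dominant-band readout
restricts periods to 2–10 min by default — slower bands approach the
window length and are analysis artifacts — and takes the median of
per-window peak periods over the requested time range, preferring windows
whose whole span lies inside the range (windows straddling a regime
change blur two bands together).

Per-islet dominant periods use a plain FFT of the linearly detrended
segment, zero-padded so the period axis is resolved to 0.1 min across the
reportable 2–15 min range, and are reported rounded to 0.1 min.  A
low-confidence flag marks segments whose spectral peak does not stand
above the in-band mean magnitude by a factor of 6 (white noise fails, any
clean oscillation passes by a wide margin).

Entrainment is classified as the smallest coprime p:q (p, q ≤ 3, p
stimulus pulses per q response oscillations) with
`|p·Ts − q·Tr| ≤ tol·q·Tr`, default tol 0.15; "before/during/after
pulsing" windows are delimited by the first and last pulse onsets.

The synchronization index is the package's own summary (the source
workflow assessed synchrony visually): each trace gets an instantaneous
phase growing linearly from 0 to 1 between successive nadirs, and the
index is the time average of the modulus of the mean unit phase vector —
1 for a perfectly locked group, near 0 for independent or antiphase
traces.  It is undefined for a single trace.

## Synthetic data

`isletsync.synth` generates the inputs the analysis assumes: per-islet
oscillations with heterogeneous periods (defaults within 2–10 min, group
size 4), phases and amplitudes, baseline plus linear drift, additive
Gaussian noise, 20-s sampling.  Two waveforms are provided — a sinusoid
and a burst-like relaxation wave (plateau and trough each half a cycle,
with 5%-of-cycle raised-cosine edges).  `s2_fixture` builds the 90-min
piecewise sinusoid used to validate the spectrogram workflow: period
5 min at amplitude 30 for the first 30 min, 3 min at 50 for the next 30,
4 min at 20 for the last 30, on a constant background.
`resettable_oscillator_group` is a cheap phase-oscillator surrogate whose
phases move a set fraction toward phase 0 at every pulse; it exercises
the synchronization metrics without ODE runs.

What the generators do not emulate: photobleaching, motion artifacts,
instrument delivery lag, amplitude rundown, or any coupling between
islets.  Tests passing on synthetic groups therefore demonstrate the
pipeline's correctness on data with the assumed structure, not robustness
to every pathology of real recordings.

## Problem sizes

Default measurement runs are sized to the phenomena: 90–120 min of model
time for period measurements (the slow rhythm completes ~20–25 cycles),
50 single-pulse runs of a few cycles each for a PRC, three islets over
95 min for entrainment runs, and 200 noisy synthetic traces for the
recovery sweep.  On one core the full test suite and the acceptance
script each complete in minutes.

## Known limitations

* The model is calibrated to the behavioral constraints listed above, not
  to a published parameter listing; absolute concentrations (e.g. the
  F6P scale) are stylized, and only the dynamical structure and the
  calibrated observables should be compared against experiments.
* The phase response at the very start of the cycle is the least
  faithful part of the curve: a pulse landing on the burst upstroke
  (the first few percent of the cycle) transiently boosts PDH while FBP
  is at its cycle maximum and prolongs the newborn burst, giving a small
  delay where a strong advance would be expected.  Parameter variants
  that terminate newborn bursts instead over-advance (the re-burst after
  an early kill is fast because ATP is still charged), so the defaults
  keep the accurate dead-zone and delay structure and accept this
  upstroke artifact.
* The entrainment window has only been verified for the protocols the
  package ships (R = 2, 5, 10 min and the random trains); no Arnold
  tongue is mapped.
* Spectrogram magnitudes are unnormalized; only relative magnitude within
  a record is meaningful, matching the qualitative use of the published
  spectrograms.
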