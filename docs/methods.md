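# Methods

## What is being modelled

A laboratory calibration study couples a wearable's raw acceleration to a
metabolic criterion. Children perform scripted activity bouts spanning
sedentary to moderate intensity while wearing triaxial accelerometers at four
body sites and breathing into an indirect calorimeter. The analysis then asks:
what threshold on the accelerometer summary best separates the
calorimetry-defined intensity classes at each wear site, and how much does the
answer degrade for activities — cycling above all — whose metabolic cost is
decoupled from movement at a given site?

`accelcal` implements that analysis as a pipeline plus a synthetic-study
generator with known ground truth. The generator exists to make the pipeline
testable end to end, not to imitate human biomechanics.

## Synthetic cohort

Thirty children by default, sexes split evenly, ages uniform on 8–11, mass
~ N(34.6, 8.6²) kg truncated above 15 kg, height ~ N(1.4, 0.1²) m. Resting
VO₂ — the per-child 1-MET basis — comes from a configurable per-age table
defaulting to a constant 5.8 ml·kg⁻¹·min⁻¹ for ages 8–11, a deliberate
stand-in at the centre of the child literature's range; the MET scale, not
its absolute anchor, is what the calibration consumes.

## Raw-signal model

Per bout, location and participant the signal is

    a(t) = u + A(t)·[sin(2πft+φ)·v₁ + ½cos(2πft+φ)·v₂] + ε(t)

with `u` a random fixed unit gravity orientation per bout (so downstream
rotation invariance is exercised), `v₁, v₂` random orthogonal movement axes,
`f` the activity's dominant movement frequency, and white noise
ε ~ N(0, 0.01² g). The amplitude A(t) is the activity × location table value
scaled by a per-bout lognormal "vigour" factor (σ = 0.25) and a slow
sinusoidal modulation (depth 0.3, 0.05–0.2 Hz) that spreads epoch values
within a bout; for the two object-control skills it is gated by the 3-s
action cadence (full amplitude for 0.9 s per action, 25 % between actions).

The amplitude table encodes only ordinal claims: locomotion rises
supine < slow walk < medium walk < run at every site; throwing/catching loads
the arms, instep passing the kicking leg; cycling moves the ankle at least
5× more than the wrists or waist. This last constraint, combined with a
cycling MET target ≥ 3, is the misclassification mechanism the
cycling-excluded re-analysis is designed to reveal.

With amplitude and noise both zero the signal is exactly the unit gravity
vector, so every sample magnitude is 1 g to floating-point precision — the
generator's null case and the SVMgs zero case coincide by construction.

## VO₂ model

Breaths arrive at uniform random intervals of 2–4 s (15–30 breaths/min).
Within each schedule segment VO₂ relaxes mono-exponentially (τ = 30 s) from
the level inherited at the segment boundary toward `MET_target × resting VO₂`,
with multiplicative lognormal breath noise (σ = 0.07). The MET target is
drawn once per bout from N(met_mean, met_sd²) truncated above 0.5; rests
target 1.1 METs. Default means place supine (1.10) and Lego (1.25) below
1.5 METs; slow walk (2.20), medium walk (2.70) and throw-catch (2.50) in the
light band; run (4.40), instep pass (3.30) and cycle (3.50) at or above
3 METs. The per-bout SDs (0.12–0.40) intentionally let individual bouts cross
category boundaries — the criterion labels real studies get are exactly this
noisy, and perfect labels would make every AUC 1.

Because τ = 30 s and the first 60 s of each bout are discarded, the residual
onset transient biases the 3-min window mean by under 0.1 MET.

## Seed derivation

Every random stream derives from one master seed through
`numpy.random.SeedSequence` entropy tuples
`(master_seed, domain, participant, [location, segment])`, domain 0 = cohort,
1 = raw signal, 2 = VO₂. Identical configuration and seed give byte-identical
CSVs; any participant/location/bout subset is reproducible in isolation, and
the in-memory and file-based pipelines consume the same per-segment streams.

## Processing and numerical choices

* SVMgs uses the absolute deviation |r − 1| (not the positive part), the
  convention of raw-accelerometry post-processing; the 1 g constant is
  exactly 1.0 in signal units.
* Epochs are half-open `[t, t+1)`, aligned to recording start; a trailing
  partial epoch is dropped; at 80 Hz each 1-s epoch aggregates exactly 80
  samples. Epochs map to bouts by epoch start time.
* Bout trimming keeps bout-relative `[60 s, duration − 60 s)` — 180 epochs of
  a 300 s bout.
* Breath averaging is time-weighted (interval to the next breath; last breath
  to window end); at least 3 window breaths are required.
* Intensity boundaries are half-open [1.5, 3), [3, 6), ≥ 6 so the partition
  is total; criterion intensity is assigned per bout and broadcast to its
  epochs — steady state is the point of the trimming, and per-breath
  alignment to 1-s epochs would add noise without information.
* Candidate ROC thresholds are midpoints between consecutive distinct scores
  plus sentinels outside the range, making selection invariant to monotone
  perturbation between observed values. Selection maximises Se + Sp under the
  min(Se, Sp) ≥ 0.60 floor; ties break toward smaller |Se − Sp|, then the
  lower threshold (an explicit, arbitrary pair of rules — the field reports
  single cut-points without stating one).
* The sedentary ROC runs with the positive region *below* the threshold;
  AUC in that direction is 1 − AUC of the conventional orientation, ties ½.
* The AUC interval is Hanley–McNeil with normal approximation, clipped to
  [0, 1]; the method is a documented choice where common practice hides
  behind statistics packages.
* Epochs are pooled across participants for ROC — matching common calibration
  practice, and a known statistical limitation (within-child correlation is
  ignored, so CIs are optimistic).
* Cut-points are displayed at 0.1 gs resolution and the light band is
  reported one display unit inside the open interval (SB cut 4.8 → band
  lower 4.9); classification itself uses `< sb_cut` / `≥ mpa_cut` exactly.
* When either cut-point at a location fails the Se/Sp floor the pipeline
  reports it flagged and derives no light band there (an unconstrained
  fallback MPA cut can legitimately sit below the SB cut, which would make a
  nonsensical band); `light_band` itself rejects non-monotone inputs.

## Problem sizes

The default study — 30 children × 4 locations × 8 bouts at 80 Hz, 172 800
labeled epochs — simulates and calibrates in memory in about 10 s on one
core. The raw signal is generated bout by bout and reduced to epochs
immediately; serialising a full raw study (≈ 43 million samples) is supported
through a streaming CSV writer but the analysis never requires it. The
multi-seed checks in the test suite run the full-size study per seed.

## What passing tests do and do not show

The generator reproduces ordinal structure: activity and location orderings
of dynamic acceleration, MET orderings and category membership in
expectation, onset kinetics, irregular breaths, bout-level label noise, and
the cycling wrist/waist dissociation. It does not model harmonics-rich gait
waveforms, sensor miscalibration or drift, inter-site correlated vigour,
posture-dependent gravity shifts within a bout, or non-steady-state
metabolism. Passing tests therefore validate the *pipeline* — the reduction
arithmetic, coding rules, constrained selection, and the direction of the
cycling effect — not the transferability of any particular numeric cut-point
to real children. Absolute cut-point magnitudes here are smaller than
published GENEActiv child values; only their ordering and the pattern of
AUCs/validity across locations and variants are claims the synthetic study
can support. One consequence faithfully mirrored: with cycling included the
wrist MPA analyses cannot reach min(Se, Sp) ≥ 60 % and are flagged, where
real-data calibrations scrape past the floor — a gap stated rather than
tuned away.

## Known limitations

Vigorous cut-points are out of scope (the protocol elicits no ≥ 6 MET bouts);
no mixed-effects or clustered ROC; no bootstrap CIs for cut-points;
VCO₂ is carried through I/O but unused; the GENEActiv binary format is not
parsed (CSV in, CSV out).
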