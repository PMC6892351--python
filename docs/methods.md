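# Methods

This note records the model assumptions, parameter choices and numerical
decisions behind `eegcharge`, and what the synthetic-data tests do and do
not demonstrate about real recordings.

## Head model and lead field

The head is three concentric spheres (brain 0.08 m, skull 0.085 m, scalp
0.09 m; conductivities 0.33, 0.0042, 0.33 S/m — the conventional ~1:80
brain:skull ratio).  The dipole potential is computed as a Legendre series;
for each harmonic degree the layered-sphere boundary conditions (potential
and radial-current continuity at interfaces, insulating scalp) are solved
as a small linear system, which reduces to the classic `(2n+1)/n` transfer
for a single homogeneous sphere.  The series is truncated at 150 terms;
with sources at most 0.079/0.09 ≈ 0.88 of the outer radius, the truncated
tail is below 1e-8 of the leading terms.  The implementation is
cross-checked in the tests against an independent concentric-sphere solver
(mne's sphere model) to better than 1 %.

Sensor montages are golden-angle (Fibonacci) spirals on the upper scalp
hemisphere — deterministic, quasi-uniform, and configurable in count
(default 64 for desk-scale runs; 256 mirrors a dense-array net).

The source space carries one label per source from a controlled vocabulary
(BA04–BA47, AMYGDALA, HIPPOCAMPUS).  The default 12-parcel layout covers
the parcels that dominate IGT group tables (amygdala, hippocampus, BA04,
BA05, BA09, BA17, BA27, BA29, BA34, BA36, BA45, BA46).  Parcel directions
are schematic, not atlas coordinates: motor/parietal parcels superior,
visual parcels posterior, prefrontal anterior, limbic parcels inferior and,
for the two deep structures, close to the sphere center (r = 0.030/0.032 m
vs ≥ 0.064 m for cortex).  The inferior cortical parcels are tilted no
lower than z ≈ −0.2·r so that the upper-hemisphere montage still samples
their field; with more extreme tilts, montage coverage — not depth — would
dominate scalp amplitude, confounding the deep-vs-cortical attenuation
property the geometry is meant to exhibit.

Units: gain is μV of scalp potential per source unit, with one unit mapped
to a 10 nA·m equivalent dipole.  Source amplitudes throughout use the
"μA" reporting convention; a single calibration constant (default 1.0)
relates standardized inverse amplitudes to it.  No absolute physical μA/μC
scale is claimed (see "Charge quantification").

## Synthetic sessions

A session is a balanced, randomly ordered sequence of reward and punishment
trials (default 100 trials, 7 s spacing, ≈ 11.8 min, 500 Hz).  Each
condition activates configured parcels with a Hann-windowed sinusoid at the
band's center frequency (δ 1.5, θ 5.5, α 9.5, β 21, γ 40 Hz), default
latency 300 ms, duration 400 ms, peak amplitude 20 source units.  Sensor
noise is i.i.d. Gaussian, default 5 μV per sample — this makes single-trial
peaks comparable to the noise floor while 50-trial evoked responses have
SNR ≫ 5 (we define evoked SNR as noiseless evoked peak divided by
noise_sd/√n_trials).  An optional 1/f background and blink artifacts
(300 ms raised cosine, frontally weighted, Poisson arrivals) complete the
generator.  All randomness flows through one seeded generator; a fixed
seed reproduces sessions bit for bit.

What the generator does **not** emulate: resting rhythms, saccades,
ECG/EMG, electrode drift, inter-subject anatomical variation, or any
behavioral (card-choice) dynamics.  Passing recovery tests therefore shows
the pipeline is correct and self-consistent under controlled conditions —
not that its effect tables would replicate on real patients.

## Preprocessing

The chain is: common-average reference → segmentation → artifact flagging →
rejection → baseline correction → per-condition averaging.  Thresholds are
peak-to-peak (max−min) over an 80 ms moving window: > 200 μV flags a bad
channel, > 140 μV on any frontal channel flags ocular activity (both
strictly greater).  Segments run from 100 ms before to 700 ms after the
stimulus with a +13 ms display-latency offset added to event times; events
whose window leaves the recording are dropped and logged.  Baseline is the
100 ms pre-stimulus span.  Trials with **more than** 10 bad channels are
rejected (exactly 10 is kept); channels flagged in surviving trials are
excluded from the inverse for that evoked response rather than
interpolated — deterministic, and repair methods are out of scope.

Filters are windowed-sinc FIRs (Hamming window) with order set by the 2 Hz
transition width (≈ 3.3·fs/2 Hz → 825 taps at 500 Hz), applied forward-
backward for zero phase.  This meets the 99 % passband / 1 % stopband gain
specification with ~1 Hz of transition on each side of a band edge.  Epochs
shorter than the impulse response are reflection-padded by one kernel
length before filtering and cropped afterwards; the evoked responses used
for charge quantification are 400 samples, so narrow low-frequency bands
(δ) necessarily carry some edge leakage — a property of filtering 800 ms
segments, kept because band decomposition of the averaged response is the
workflow being mirrored.

## sLORETA

For average-referenced gain `K` (sensors × 3M, free orientation), the
transfer matrix is `T = Kᵀ(KKᵀ + αH)⁺` with centering operator
`H = I − 11ᵀ/N`, and per-source standardized power
`σ_l = ĵ_lᵀ [ (TK)_ll ]⁺ ĵ_l`.  All pseudo-inverses use eigendecomposition
with a 1e-12 relative eigenvalue cutoff — deterministic and robust to the
rank-1 null space the average reference leaves.  `α = 0` is allowed and
exact for noiseless tests; an error is raised only when the gain itself is
rank-deficient (fewer than min(3M, N−1) nonzero eigenvalues).  The default
regularization policy is `α = λ·trace(KKᵀ)/N` with λ = 1e-2.

Zero localization error — the standardized map peaking exactly at a true
noiseless single dipole — is the module's primary oracle and holds on the
test grids for λ ∈ {0, 1e-3, 1e-2}.  Standardized amplitudes are
pseudo-statistics: scale-equivariant and reference-invariant, but not
physical current densities.

## Charge quantification

Bands are half-open intervals: δ [0.1, 3), θ [4, 7), α [7, 12), β [12, 30),
γ [32, 0.9·Nyquist) Hz — the 7 Hz edge belongs to α, and the open γ top is
capped so the FIR design stays valid.  "Full" is the 0.1 Hz high-pass only.
Band filtering is applied to the averaged evoked response, not per trial.

Source amplitudes are averaged within 5 ms bins over the 800 ms segment
(160 bins).  At 500 Hz a 5 ms bin holds 2.5 samples, so bins alternate
deterministically between 2 and 3 samples (sample k joins bin
⌊t_k/5 ms⌋).  Parcel amperage is the maximum over the parcel's sources
("highest electric current through the area"); mean aggregation is
available behind a switch.  The most active parcel has the highest peak
amperage, with BA1–BA3 excluded; ties break toward larger ι, then the
lexicographically smaller label.  ι is the left-Riemann sum Σ I_k·Δt.

Sustained μA-scale parcel currents integrating to μC-scale charges are a
reporting convention inherited from the workflow this package mirrors, not
a physical claim; the calibration constant carries the entire absolute
scale and defaults to 1.

## Benchmark

Feature rows are (subject, condition) with one ι per (band, parcel) in a
fixed documented order (default 6 × 12 = 72 features); a parcel missing for
a subject contributes 0, a missing band is an error.  Stratified 5-fold CV
shuffles with the given seed; features are z-scored with training-fold
statistics only (no leakage); test predictions are pooled into a single
confusion matrix, so metric denominators equal whole-cohort class sizes.

The positive class for recall/precision is STD (punishment).  This is the
reverse of the common TGT-positive convention, but it is the only reading
under which the published benchmark table is internally consistent
(e.g. 39/55 = 0.709 precision, 39/71 = 0.549 recall for the broadband
logistic row), so it is encoded in the metric formulas and documented
prominently.  The audit tool recomputes all three metrics from each printed
row's counts and flags cells that disagree at 3 decimals; 34 of 42 rows
are consistent, and the flagged ones (e.g. accuracy cells equal to the
precision value) are reported as inconsistent rather than reproduced.

Implemented classifiers: elastic-net logistic regression (L1 = L2 = 0.1,
tolerance 1e-4, mapped to the sklearn parameterization C = 1/(l1+l2),
l1_ratio = l1/(l1+l2)); an averaged perceptron written in-package (lr 0.1
decaying as (1+epoch)^−0.5, 101 epochs, prediction from the running weight
average); a linear hinge-loss SVM under the λ-penalized objective
(λ = 1.0, C = 1/(nλ)); and a one-hidden-layer (100 unit) SGD network with
cross-entropy loss, lr 0.1, 51 iterations.  Ensemble/Bayesian classifiers
from the published comparison whose algorithms are proprietary are
represented only at the metrics/audit layer.

## Problem sizes used in tests

Unit and property tests run on 32-channel geometries and 10–20-trial
sessions; the localization sweep uses 64 channels over a 64-source grid
(4 radii × 16 directions); the cohort recovery check uses 20 subjects at
full session size (100 trials) plus 50 short-session replicates; the
classifier checks use 71 synthetic subjects (142 responses), matching the
published cohort size.  These sizes were chosen so the full suite documents
the method at realistic scale while remaining convenient to rerun.

## Known limitations

- Spherical geometry and schematic parcel centroids; no individualized
  anatomy, so parcel labels are nominal rather than anatomical claims.
- Deep-structure estimates inherit the usual EEG caveat: a deep source's
  scalp pattern can be approximated by distributed cortical activity; the
  zero-localization property holds for isolated dipoles, not arbitrary
  mixtures.
- Absolute ι values are convention-scaled and not comparable across
  different calibration constants or inverse regularizations.
- The EDF exporter is minimal (16-bit, one-second records, no embedded
  annotations); events travel in the sidecar TSV.
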