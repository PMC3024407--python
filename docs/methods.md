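# Methods

## Protocol timing model

The acquisition is a cardiac-triggered, respiratory-navigated, segmented
gradient-echo cine with black-blood saturation. Per cardiac phase one
segment of `klines_per_segment = 3` phase-encode lines plus one startup echo
is acquired at TR = 7.1 ms, preceded by a 12 ms saturation module, giving a
phase interval of (3 + 1)·7.1 + 12 = 40.4 ms. The usable window per beat is
90 % of the RR interval minus the navigator (15.5 ms) and its feedback
(5 ms); the maximum number of cardiac phases is the floor of window /
interval (21 at RR = 1000 ms). The number of reconstructed phases is
rounded down to a multiple of the k-t factor R so every k-space region sees
the same undersampling.

Nominal scan duration (100 % gating efficiency) in heartbeats:

* R = 1: `n_encodings · ceil(n_pe / 3) + prep_beats` with 4 encodings
  (reference + 3 directions), 168 phase-encode lines and 1 preparation beat
  → 225 beats.
* R ≥ 2: `n_encodings · floor(n_pe / (3 R)) + training_overhead_beats` with
  a constant 13-beat training overhead → 125/85/69/57/49/45 beats for
  R = 2…7.

The 13-beat training overhead and the 1 preparation beat are exposed as
config fields; they are the unique pair of constants for which this rounding
scheme reproduces the whole published sweep, consistent with a training
stage of constant duration (11 central k_y lines regardless of R). The
per-phase interval is R-independent because undersampling removes whole
segments (heartbeats), not lines within a phase.

## Phantom and velocity encoding

The phantom is a 2-D short-axis slice: an annular myocardium around a
suppressed blood pool, a static-tissue ring outside, air elsewhere.
Each velocity waveform (radial and longitudinal) is a sum of two
opposite-signed periodic raised-cosine (Hann) pulses of width `pulse_width`
(default 0.18 cycles) centred at the systolic and diastolic peak times
(defaults 0.15 and 0.55), plus a baseline constant C = −w(P_s + P_d)/(2(1−w))
chosen so that the cycle integral is exactly zero *and* the extrema equal
the configured peaks exactly. The waveform is C¹ and periodic by
construction. Default peak velocities — radial +3.5/−3.0 cm/s,
longitudinal +8/−7 cm/s (positive = toward the blood-pool centroid /
toward the apex) — are of the order of healthy in-vivo values; they are
generator defaults, not reproductions of any measured subject.

The annulus translates radially with the running integral of the radial
waveform (wall thickness preserved, thin-slice approximation: through-plane
motion does not move pixels between slices). Per-pixel velocity is the
radial waveform times the unit vector toward the centroid plus the
longitudinal waveform through-plane; it is identically zero on the static
ring.

Image formation is the referenced 4-point scheme: the reference segment has
phase zero and each encoded segment has phase π v_e / VENC (VENC 30 cm/s;
|v| ≥ VENC raises rather than wraps). A linear background phase plane
(offset, row slope, col slope — an eddy-current surrogate from the bipolar
encoding gradients) is applied to the three velocity-encoded segments only,
so it survives the phase difference and must be removed by the static-tissue
plane fit; magnitudes (myocardium 1.0, static 0.7, blood 0.05, air 0.1) are
identical across segments.

## Sampling and reconstruction

All Fourier transforms are unitary and centred (DC at index n//2), so round
trips are exact and noise variance is domain-invariant. Complex Gaussian
noise of standard deviation `noise_sd` per complex k-space sample is added
at acquisition. The k-t schedule is the standard sheared lattice: phase t
samples lines j with (j − t) mod R = 0; any R consecutive phases cover every
line exactly once. The training set is the central 11 k_y lines at all
phases, taken from the same simulated acquisition (interleaved-training
approximation of a separate constant-length training stage).

k-t BLAST operates per readout column in (y, f) space. The alias geometry
is *calibrated, not assumed*: a single x-f delta is pushed through the exact
sampling chain and the R non-zero responses give the shifts and complex
weights a_q (for this lattice: shifts (q·n_pe/R, q·T/R), |a_q| = 1/R); the
test suite verifies the calibration against a brute-force DFT of the mask.
Each alias set is resolved with

    ŝ_b = θ²_b ā_b (Σ_j |a_j|² θ²_j + ψ)⁻¹ d ,

where θ² is the expected squared x-f magnitude from the zero-filled
low-resolution training reconstruction (averaged over the four encoding
segments, optionally boxcar-smoothed along f) and ψ the noise power,
estimated by default as the mean squared magnitude in an outer corner of
the acquired k-space. The temporal-average (baseline) k-space — the mean of
the acquired samples per line — is subtracted before filtering and added
back afterwards, protecting the dominant static signal. For ψ > 0 the
filter's gain on every alias set is ≤ 1, which is the mechanism behind the
progressive attenuation of sharp velocity peaks at higher R.

Exact integer alias shifts require the phase-encode count to be divisible
by R. Accelerated acquisitions therefore use a centrally cropped
phase-encode grid of R·floor(n_pe/R) lines (the outermost high-frequency
lines are not acquired), and the reconstruction is zero-padded back to the
nominal matrix — the same flavour of per-R matrix adjustment the segment
arithmetic floor(n_pe/(3R)) implies for the scanner protocol. The small
scale factors √(n_new/n_old) keep image amplitudes comparable across grids.

`KTBlastReconstructor` exposes this as a scikit-learn transformer:
`fit(training)` learns `theta2_`, `transform(kspace)` infers the lattice
from the sampling mask and unaliases; at R = 1 it returns the direct
inverse transform (nothing to unalias).

## Quantification

Velocity maps are v = ∠(E·R̄)/π·VENC per pixel; zero-magnitude pixels are
flagged invalid (NaN) and excluded from all mask means. A least-squares
plane fitted to the static-tissue mask is subtracted from every velocity
map. Radial curves are the myocardial-mask mean of the in-plane velocity
projected onto unit vectors toward the blood-pool centroid; longitudinal
curves the mask mean of the through-plane component (apex positive).
Ground-truth masks from the generator stand in for in-vivo segmentation;
user-supplied mask NIfTIs are accepted through the CLI.

Curves are resampled by periodic cubic splines onto a uniform grid. The
default step is 0.01 ms, as used in the correlation definition below; this
is almost certainly finer than physiologically necessary (0.01 s would be a
plausible intent) but it is cheap, so the printed value is kept as the
default and remains configurable. A constant shift equal to the dense-grid
mean enforces the physiological zero cycle integral of velocity. Peak
features are searched in configurable systole/diastole windows (defaults:
first/second half of the acquisition window, since no windowing rule is
published): v_p,sys is the largest-magnitude signed extremum in systole,
v_p,dias the opposite-signed extremum in diastole, Δv = v_p,sys − v_p,dias,
t_dias the dense-grid time of the diastolic extremum (ties to the earliest
time).

## Comparison statistics

With sequence 1 the non-accelerated reference and sequence 2 the test
acquisition: PF = Δv₂/Δv₁; nRMSD = RMS(u − w)/|Δv_nokt| on the common dense
window; c is the standard Pearson correlation (the printed ideal c = 1 only
holds with the 1/n normalization, so plain Pearson is used); Bland-Altman
differences are oriented seq2 − seq1 throughout, with sample sd (n−1) and
limits ±1.96 sd; group comparisons versus the reproducibility arm use the
unpaired two-tailed pooled-variance t-test (α = 0.05, no multiple-testing
correction by design).

## Cohort experiment and problem sizes

The standard simulated experiment uses 10 subjects at 128 × 128 with
k-space noise sd 0.03 (SNR ≈ 33 on the unit-magnitude myocardium), a
background plane of (0.05, 0.0008, −0.0012) rad, k-t factors 2…7 and, per
subject, three non-accelerated acquisitions (one reference for the k-t
comparisons, two repeats for the reproducibility arm). Per-subject motion
amplitudes (±15 %), peak times (±0.02 cycles) and annulus radii (±10 %) are
drawn uniformly with per-subject seeds spawned from the experiment seed;
acquisitions differ by independent noise. The matrix is scaled down from
the printed 172 × 168 (available via config) to keep a full cohort run
around a minute; all trends reported by the test suite are computed at
these sizes.

## What the phantom does and does not show

The generator reproduces the features the evaluation depends on — periodic
multi-harmonic velocity waveforms with distinct systolic/diastolic peaks, a
moving annulus, black-blood contrast, background phase, k-space noise, and
the exact sampling/training geometry — so it supports conclusions about the
*direction* and *mechanism* of k-t-induced distortion (peak attenuation
growing with R, rising nRMSD, preserved timing). It does not model torsion
or strain gradients, coil sensitivities, off-resonance, flow artifacts,
respiratory-gating inefficiency or segmentation error, and its velocity
amplitudes are stylized; absolute PF/nRMSD values of the synthetic cohort
are therefore not calibrated to any in-vivo cohort, and the vendor
implementation's filter details (ψ choice, baseline handling) are unknown,
so agreement with published in-vivo tables is expected at trend level only.

## Numerical conventions and edge cases

* Unitary centred FFTs everywhere; DC line n//2; temporal-frequency bin 0 is
  DC (unshifted).
* `phases_for_factor` errors when max_phases < R; the usable gating window
  must be positive.
* Aliased velocity (|v| ≥ VENC) is an error, not a wrap.
* Plane fits require ≥ 3 non-collinear static pixels.
* Pattern recovery from a mask validates the lattice property and rejects
  arbitrary masks.
* Degenerate statistics (zero Δv reference, constant curves, < 2 pairs)
  raise rather than return silent values; identical t-test groups return
  (t = 0, p = 1).
* All randomness flows from `numpy.random.SeedSequence` spawns of a single
  experiment seed; outputs embed the config hash and seeds.
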