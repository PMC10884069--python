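# Methods

## Overview

`covmap` implements a regression-style link between two simultaneously
recorded signal streams: scalp EEG, summarized as microstate class
timelines, and intracranial local field potentials, summarized as
band-limited log amplitude envelopes (temporo-spectral evolutions, TSE).
The core quantity is the per-channel covariance map — the
timeline-weighted mean of the centered TSE — with permutation significance
and a back-projection correlation (R) as effect-strength measure.

The analysis assumes the two streams are time-aligned at a common sampling
rate (both are resampled to 500 Hz and truncated to common length; a
residual mismatch of more than one sample is an error), that the scalp
data can be meaningfully average-referenced, and that amplitude — not
phase — carries the coupling of interest.

## Preprocessing

Channels are demeaned before filtering. Intracranial grids receive a
within-grid common average reference; strips and depth shafts are
re-referenced to their neighboring contact (bipolar montage, contact order
taken from channel order within the montage group). All channels are
notch-filtered at 50 Hz. Scalp channels are band-passed 2–20 Hz and
common-average referenced. Every frequency-selective filter in the
pipeline is a 4th-order Butterworth IIR applied forward-backward
(`sosfiltfilt`), i.e. zero-phase: sample-wise weighting of one stream by
the other is only meaningful if the filters do not introduce group delay.
The one exception is interictal-discharge detection (below), which uses a
2nd-order Butterworth, keeping the detector's ring-down short.
Resampling is polyphase with anti-alias filtering; the output length is
`round(n·sfreq_new/sfreq)` so duration is preserved to within one sample.

## Microstate segmentation

Global Field Power is the spatial standard deviation of the
average-referenced potential. Segmentation is template-based ("winner
takes all"): at each strict GFP local maximum the momentary topography is
assigned to the template with the largest absolute spatial Pearson
correlation — polarity-invariant, consistent with the clustering
convention — and samples between peaks inherit the label of the nearest
peak in time (equidistant ties go to the earlier peak, deterministically).

The per-class timeline is `w_k(t) = r_k(t)²·GFP(t)²` where class k is
assigned and zero elsewhere: the portion of squared field strength
explained by the template. The squared-correlation weighting makes poorly
fitting samples contribute little when the timeline is used as a
regressor; the GFP² factor makes strong fields count more. Masked samples
are unassigned and carry zero weight. No minimum-correlation floor is
applied before assignment.

Polarity-invariant modified k-means (distance 1 − r²) clusters GFP-peak
maps: assignment by largest squared correlation, prototype update as the
principal eigenvector of the members' outer-product sum, best of
`n_restarts` random initializations by global explained variance. Template
sets are compared by optimal one-to-one matching (Hungarian algorithm) of
absolute spatial correlations.

Template sets can be spatially resampled between montages with spherical
splines (Perrin-type, order m = 4, Legendre series truncated at degree 7).
The spline system is regularized with 1e-8 on the diagonal — small
relative to the g-kernel scale (~1e-2), so resampling a template set onto
its own montage reproduces it essentially exactly. Electrode positions
come from an idealized standard-montage table projected onto the unit
sphere.

## Temporo-spectral evolution

Five canonical bands: theta 4–8, alpha 9–12, beta 13–30, low-gamma 30–70,
broadband high-gamma 70–150 Hz. Per channel and band: zero-phase
band-pass, rectification, zero-phase low-pass at half the band's lower
edge (theta smooths at 2 Hz, high-gamma at 35 Hz), then a natural log with
an amplitude floor of ε = 1e-12 µV so silent channels stay finite. The
smoothed envelope is clipped at zero before the log because zero-phase
smoothing can slightly undershoot. The log is applied before artifact
exclusion; exclusion is handled downstream by masking.

## Covariance mapping

`β[c] = Σ_t w(t)(TSE[c,t] − mean TSE[c,·]) / Σ_t w(t)` over unmasked
samples. Centering is what makes the uniform-weight case vanish and the
quantity behave as a covariance; without it β would approximate mean log
band power. β is invariant to positive rescaling of the timeline and to
channel-constant TSE offsets.

Significance: the timeline is circularly rotated against the TSE by
offsets drawn without replacement, excluding offsets within 2 s of zero
(in either direction). Rotation preserves the autocorrelation of both
series; a sample-wise shuffle would destroy the timeline's temporal
smoothness and grossly inflate significance. The map-level statistic is
the RMS of β across channels; p = (1 + #{null ≥ observed})/(n_perm + 1),
so the minimum attainable p with the default 1000 iterations is 1/1001.
A rotation that parks all timeline weight inside the artifact mask is
counted as an exceedance (conservative) rather than aborting the test.

Back-projection: `y(t) = Σ_c β[c](TSE[c,t] − mean)`; R is the Pearson
correlation of y with the timeline over unmasked samples. R > 0.1 is a
reporting filter, not a test: both filtered and unfiltered tables are
written. ROI aggregation is the arithmetic mean of member-channel betas
per (region, band, class); channels without a region entry are skipped
with a warning.

## Interictal-discharge detection

Per channel: 25–80 Hz band-pass (2nd-order Butterworth, forward-backward),
analytic amplitude via the Hilbert transform, z-score against the whole
recording's mean and SD (global, hence deterministic and scale-invariant),
events = maximal runs with z > 3 lasting strictly more than 20 ms and
strictly less than 100 ms. Events from any channel are dilated by 2.5 s on
both sides and united into one global exclusion mask, since the covariance
analysis mixes streams. The nominal 2nd-order FIR description of this
band filter is not realizable; the 2nd-order IIR used here is the closest
realizable choice.

A consequence worth knowing: on stationary Gaussian noise this rule fires
at its intrinsic false-alarm rate (roughly 0.03–0.1 events/s/channel), and
with ±2.5 s padding a clean hour-less synthetic record masks out entirely.
On clinical data the amplitude distribution is heavy-tailed — large true
discharges inflate the global SD — which is what keeps detections sparse.
The end-to-end self-test therefore runs with masking disabled
(`RunConfig(apply_ied_mask=False)`); the rule itself is validated on
targeted burst fixtures. Masking defaults to on.

## Synthetic ground truth

The generator emulates the joint structure the analysis targets:

- **Sequence.** Piecewise-constant labels, geometric segment lengths
  (mean 80 ms, minimum 2 samples) — memoryless, the simplest law
  consistent with quasi-stability. Successive segments always change
  class; the incoming class is drawn from a softmax over per-class
  preference signals drifting on a ~0.5 s timescale (tanh-bounded so no
  class collapses), emulating the slow waxing and waning of class
  occupancy and giving timelines realistic low-frequency power. The
  amplitude envelope is rectified smoothed noise squashed into
  [0.75, 1.25] µV-scale units: smooth, strictly positive, many local
  maxima per second.
- **Scalp.** `amplitude(t) × map(label(t))` plus white spatial noise,
  average-referenced. The bundled 7-map template set is *synthetic*: QR-
  orthonormalized dipolar/quadrupolar fields sampled at idealized 10–20
  positions, labelled A–G. It stands in for normative published templates
  (not redistributable) and carries no anatomical meaning; orthogonality
  makes recovery tests sharp.
- **Intracranial.** Unit-variance 1/f noise (flat below 1 Hz) scaled to
  20 µV per channel. A coupling (channel, band, class, gain) adds
  `gain · w(t) · x_band(t)` where `x_band` is the channel's own
  band-filtered component and `w` is the class timeline normalized by its
  maximum — the band's analytic amplitude becomes `(1 + gain·w)` times
  baseline while other bands stay untouched. |gain| < 1 keeps amplitude
  positive; the gain's sign is the ground truth for the recovered beta's
  sign.
- **Bursts.** IED-like transients are Tukey-windowed 50 Hz carriers of
  stated duration, scaled in units of the channel's 25–80 Hz band SD (the
  scale the detector's z-score lives on), so supra-threshold time tracks
  nominal duration rather than filter ring-down.

What the generator does *not* emulate: volume conduction and realistic
lead fields, non-stationary background spectra, heavy-tailed clinical
amplitude distributions, realistic discharge morphology, or phase
coupling. Passing recovery tests therefore demonstrates correctness of
the estimator chain, not robustness to every pathology of clinical data.

### Attainable effect sizes (why test thresholds sit where they do)

A band-limited stochastic carrier has Rayleigh envelope self-noise
(std/mean ≈ 0.52) that no amount of data removes from a sample-wise
correlation. At gain 0.5 and ~1/7 class occupancy this caps the raw
envelope–timeline Pearson correlation near 0.29 even for a binary
timeline; envelope smoothing at half the band's low edge raises the
attainable value only modestly. Coupling tests therefore validate against
oracle-computed levels (coupled ≈ 0.2–0.3, uncoupled < 0.1) rather than
an aspirational constant.

Identifiability of a single coupled cell among 8 channels scales with the
time–bandwidth product. At 60 s, broadband high-gamma (80 Hz wide) yields
sign margins above 7 SD and reliable top-|beta| recovery; theta (4 Hz
wide) and alpha (3 Hz wide) recover the *sign* reliably but not always
the top rank. The coupled-cell recovery battery therefore runs in
high-gamma, and the theta/high-gamma opposed-gain (inverse-relationship)
check uses 5-minute records — the recording length of the intended
application — where the theta sign margin is ≥ 4 SD.

## Defaults

| parameter | default | note |
|---|---|---|
| analysis rate | 500 Hz | common resampling target for both streams |
| scalp band-pass | 2–20 Hz | microstate convention |
| notch | 50 Hz | line frequency |
| bands | 5 (theta…high-gamma) | see above |
| TSE smoothing | band lo/2 | tied to band definition |
| n_perm | 1000 | min p = 1/1001 |
| rotation exclusion | 2 s | keeps null offsets away from identity |
| R floor | 0.1 | reporting filter only |
| IED rule | 25–80 Hz, z > 3, 20–100 ms, ±2.5 s | strict inequalities |
| k, templates | 7, A–G | polarity-invariant throughout |
| spline order / truncation / reg | 4 / degree 7 / 1e-8 | |
| log floor ε | 1e-12 µV | |

## Limitations

- Timelines and TSEs are coupled at zero lag only; no lagged covariance.
- No multiple-comparison correction across the 35 (class × band) maps; the
  R floor is a reporting convention, not an error-rate control.
- The permutation scheme assumes approximate joint stationarity; strong
  slow drifts shared by both streams would not be exchangeable under
  rotation.
- EDF writing uses 16-bit quantization with per-channel physical ranges;
  round trips are exact only to the quantization step.
- Microstate syntax statistics (durations, coverage, transition matrices)
  and group-level template estimation are out of scope.
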