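# Methods

## Data model and assumptions

A session is a 4-D tensor *(rows, cols, frames, channels)* spanning
ordered on-disk blocks, one randomized stimulus sequence per block.
The package assumes planar imaging at a fixed frame rate, episodic
stimulation with known per-stimulus durations, rigid (translation-only)
frame motion, and an additive instrument offset (black level) common to
all pixels of a frame.  Indices are 0-based throughout the API; the
1-based `block_index` / `frame_in_block` / `presentation_index` columns
inside frame-info records preserve the acquisition metadata convention.

## Lazy stack layer

Raw-binary blocks are mapped with `numpy.memmap` windows opened per
read, so no file handles or address space persist between accesses;
TIFF blocks keep their directory parsed once at open (via `tifffile`)
and read pages through the cached offsets.  Axis permutation and the
affine value transform *(a, b)* are view metadata: derived views share
one I/O counter with their parent, which is how the tests assert that
structural operations perform zero block reads.  Writes (raw backend
only) store native dtype values and deliberately ignore the read-side
transform; integer overflow clips to the dtype range with a warning,
mirroring acquisition saturation rather than wrapping.  `slice_apply`
streams results into a temporary disk-backed stack so peak memory is
one slice plus constant overhead; the largest single read is
instrumented and checked in tests.

## Registration

The shift estimator is two-stage cross-correlation in the Fourier
domain: the whole-pixel argmax of `ifft2(conj(F_ref) * F_mov)` with
wrap-around resolved into (−n/2, n/2], then a matrix-multiply DFT of
the same product on a grid upsampled by κ within a 1.5 px neighborhood
of the coarse peak, giving 1/κ px precision (default κ = 20).

The cross-power spectrum is *not* whitened by default.  Phase-only
normalization is exact for circular shifts, but real frames are
bilinear-resampled by the motion itself and carry border fill, which
corrupts precisely the high frequencies whitening amplifies; in testing
this produced a systematic ~0.1 px bias, versus ~0.02–0.03 px RMS for
the unnormalized product.  `normalization="phase"` remains available.

Sign convention: a stored shift *(dy, dx)* is the displacement of the
frame's content relative to the reference (`moving(x) = ref(x − d)`);
re-registration samples the frame at `x + d`.  `estimate_shift`,
`apply_shift`, the generator's motion planting and the shifts CSV all
share this convention.

Stack-level regularization: optional Gaussian low-pass before
estimation; centered sliding-window averaging of the *moving* frame
(window truncated at stack ends; the reference frame gets the same
window in fixed mode); estimates whose magnitude exceeds `max_shift`
(default 10 px) are rejected and replaced by per-component linear
interpolation between the nearest accepted frames (endpoints copy the
nearest accepted value).  Progressive mode estimates frame-to-frame
steps and accumulates them into frame 0's coordinate system.
Re-registration uses bilinear interpolation rather than Fourier
shifting: no ringing, and the invalid border is exact — pixels sampling
outside the frame become NaN and are excluded (not zero-filled) from
ROI means, avoiding motion-correlated artifacts.  Aligned frames are
cached on disk keyed by frame index and the exact shift/black values,
so changing shifts can never serve stale data; an unwritable cache
degrades to uncached computation with a warning.

## Black level and baseline

The black level is the per-frame mean raw value over a user-supplied
pixel region expected to contain no fluorescence.  It is subtracted
before every downstream computation; negative black-subtracted values
are kept, preserving the noise statistics that σ_F₀ estimates.  The
baseline distribution (per-pixel mean and sample s.d., ddof = 1, of
processed blank frames) attaches to disjoint half-open frame ranges per
channel, with no interpolation between entries.  ΔF/F₀ is computed per
frame *before* any response measure; pixels or ROIs with F₀ ≤ 0 are
marked invalid (NaN) and logged.  Baseline source frames may be any
frame set; the CLI defaults to frames with no stimulus tag.

## ROI detection

The two detectors share one operator chain on a detection image —
channel 1's mean processed projection, or channel 1 minus channel 2 to
cancel structures present in both channels: Gaussian smoothing
(`smooth_sigma`, default 2 px), a robust threshold at `threshold_z`
(default 4) times 1.4826·MAD above the image median, 3 × 3 local maxima,
greedy acceptance in decreasing height with a `min_separation`
exclusion radius (default one cell diameter), and a disc of
`cell_radius` (default 6 px, a soma at 128 × 128 two-photon scale)
stamped at each accepted peak, clipped to the frame.  A mean projection
(rather than max or per-frame detection) was chosen as the most
noise-robust reading of peak-of-intensity detection.  ImageJ import
rasterizes rectangle, oval, polygon and freehand ROIs with the
pixel-center-inside rule; unsupported types are skipped with a warning.

## Derandomization and response measures

Frames are tagged by the presentation whose half-open interval
[start, end) contains their onset time — a partition, so the trial
mapping is injective by construction.  For each stimulus ID, trials are
its presentations in timeline order.  Responses restrict to each
trial's frames inside the stimulus use-window, apply the scale (raw or
per-frame ΔF/F₀ against the baseline covering that frame), then the
measure: mean, peak (max of the unsmoothed trace — an optional
pre-measure filter is deliberately absent by default), or channel ratio
(FRET reading: the ratio trace of two black-subtracted channels, then
the mean).  PSTHs truncate all trials of a stimulus to the shortest
trial before frame-wise averaging.  Trials with no usable frames are
invalid (NaN) with a warning and excluded from trial averages.

## Analyses

*Tuning curves* report trial mean and s.e.m. (ddof = 1, n = finite
trials) per direction.  *RF maps* sum per-stimulus-pixel Gaussian
fields weighted by the trial-averaged response; the Gaussian's FWHM is
set equal to the stimulus pixel diameter (σ = d / (2√(2 ln 2))), the
conventional visual-field reading of "diameter"; the RF center is the
field argmax, undefined (flagged None) for all-zero responses.
*Sparseness* is the biased sample skewness g₁ = m₃/m₂^{3/2}
(divisor-n moments, `scipy.stats.skew` with `bias=True`) — lifetime per
neuron over time, population per time point across neurons, reported
per unit with summarization left to the caller; fewer than 3 finite
values or zero variance yields NaN.

## Synthetic experiments

The generator emulates a cortical drifting-grating session at the scale
the pipeline targets: 128 × 128 px frames at 7.81 Hz, 8-bit, 16 drift
directions of 2 s separated by 1 s blanks, independently randomized per
block, 5 blocks ≙ 5 trials.  Pixel model, channel 1:

    value = black + bg + Σ_i profile_i(p) · (1 + dff_i(t)) + N(0, σ²)
    dff_i(t) = Σ_p a_i · max(0, cos(θ_p − pref_i)) · exp(−(t − t_p)/τ)

summed over presentations with onset t_p ≤ t.  Design choices:

- **Transient kernel**: instantaneous rise, single-exponential decay,
  τ = 0.6 s (a GCaMP6m-like time constant).
- **Tuning**: half-wave-rectified cosine, so transients are
  non-negative and the peak ΔF/F₀ at the preferred direction equals the
  planted amplitude exactly — every expected response has a closed
  form.
- **Cell profile**: Gaussian (σ = radius/2) truncated at the radius, by
  default.  Per-pixel ΔF/F₀ is profile-independent, so ROI-level
  recovery stays exact, while the smooth profile keeps phase
  correlation unbiased under bilinear motion (a flat disc's hard edges
  produced a measurable sub-pixel bias).  `cell_profile="disc"` is
  available.
- **Motion** is applied after noise by the same bilinear operator the
  aligner inverts, with the background level as border fill, making
  shift recovery well-posed; the path is a slow bounded sinusoid,
  zero at frame 0 (the default reference).
- **Black region**: the ground truth designates ≤256 guaranteed
  cell-free pixels, enough that black-level estimation noise is
  negligible against ROI trace noise.
- Quantization rounds and clips to the target dtype; with the default
  F₀ = 60 raw units this bounds ΔF/F₀ recovery error at roughly one
  part in 30 (one dtype step on F and on F₀), which is what
  "recovery within quantization" means in the tests.
- Channel 2, when present, carries no cells — a structural/counterstain
  channel, which is what the difference-image detector expects.

What the generator does *not* emulate: optics (no PSF), shot noise
proper (Gaussian, not Poisson), neuropil contamination, slow drift of
baseline or focus, non-rigid motion, spiking statistics.  Passing tests
therefore demonstrate correctness of the *pipeline machinery* — lazy
access, registration of rigid motion, scaling, derandomization,
measure arithmetic — not robustness to every artifact of real tissue.

## Problem sizes in the tests and acceptance script

Most checks run at 32–64 px frame sizes with seconds-long sessions;
the byte-accounting check generates the full 128 × 128 × 7378 × 2
session (~242 MB, written to a temporary directory and deleted); the
tuning-recovery check runs 128 × 128 × ~1900 frames at 20 cells per
seed over 3 seeds.  The direction-recovery analysis uses a
[0, 1] s use-window — with a τ = 0.6 s decaying transient, later frames
of a 2 s presentation contribute mostly noise, and restricting the
analysis window to the early response is the standard practice the
use-window metadata exists for.

## Known limitations

- Registration is translation-only; rotation or non-rigid deformation
  must be corrected upstream.
- TIFF support targets uncompressed/deflate grayscale baseline TIFF
  with ≤ 2 samples per pixel; TIFF stacks are read-only.
- One baseline entry per frame range and channel, with no temporal
  interpolation between entries.
- The ImageJ reader handles rectangle, oval, polygon and freehand
  types; lines, points and composite ROIs are skipped.
- Population sparseness is reported per time point; summarizing the
  distribution is left to the caller.
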