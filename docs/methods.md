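# Methods

This note documents the models, numerical choices and limitations of
`echotrack`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic tests do and do not demonstrate
about real ultrasound data.

## Coordinate and indexing conventions

Points are subpixel `(x, y)` pairs, `x` = column, `y` = row, 0-based,
origin top-left. Frame indices are 0-based. Human-facing *label ordinals*
("labeled frame number 4") are 1-based over the sorted labeled frames;
`core.ordinal_to_frame` converts. Videos are decoded to single-channel
grayscale (channel mean for RGB input) and normalised to floats in
[0, 1] before any gradient computation, so eigenvalue thresholds are
independent of the input bit depth.

## Lucas–Kanade tracker

The tracker solves the translational brightness-constancy problem per
point: spatial gradients `f_x, f_y` are central differences of the
previous frame sampled bilinearly over an `n×n` window around the point,
`f_t` is the difference between the next frame's window (sampled at the
current displacement estimate) and the template, and the 2×2 normal
equations are solved for `(u, v)`.

The solve is **iterated** (up to `max_iterations = 25`, stopping when the
update norm falls below `convergence_tol = 0.01` px), re-sampling the
moving window each time. A single linearised solve is only valid for
sub-pixel motion; iteration extends the capture range to several pixels on
smooth textures, which the shift-recovery tests exercise up to 3 px at a
single pyramid level. A coarse-to-fine pyramid (`pyramid_levels > 1`,
factor-2 Gaussian downsampling) is available for larger displacements but
off by default.

Parameters (all on `LKConfig`):

| parameter | default | meaning |
|---|---|---|
| `window_n` | 21 px | template side; larger = smoother, less local |
| `max_displacement_px` | 20 px | per-step failure threshold |
| `min_eigen_threshold` | 1e-4 | min eigenvalue of the per-pixel-normalised normal matrix |
| `pyramid_levels` | 1 | coarse-to-fine levels |

Degenerate windows (flat speckle — the aperture problem) are detected by
the smallest eigenvalue of the normal matrix divided by `n²`; such points
hold their position and are flagged invalid rather than producing an
unstable solve. The same hold-and-flag policy applies to points leaving
the frame and to steps exceeding `max_displacement_px`.

## Bounding-box tracker protocol

Template trackers of the CSRT/MOSSE/KCF family are not re-implemented;
they plug in behind the `BoxBackend` adapter (`init(frame, box)` /
`update(frame) -> (ok, box)`). What `echotrack` owns is the protocol
around any such backend: the tracked quantity is the box *centre*, the
initial box is a `box_side_px` square (default 100 px) centred on the
point, and after every update the box is recentred and its size forcibly
reset to the initial dimensions so the box cannot distort over time.
Boxes clipped at the frame border contribute the centre of the clipped
region and are flagged. A minimal integer-shift NCC backend is included
for tests and as a reference implementation of the interface.

## Despeckling

Optional wavelet denoising (`BayesShrink`, soft thresholding, `db2`) can
be applied per frame before tracking; `denoise_frame` also reports the
PSNR of the denoised frame relative to the input. It is off by default:
on the synthetic scenes LK does not need it, and on real data it is a
judgement call for the user.

## Drift corrections

**STC.** Segments run between consecutive correction frames, starting at
the trajectory's (labeled) first frame. Within a segment of length `T`
(end frame at segment-relative index `j = T`), the correction added to
each coordinate is `d / (1 + exp(−B (j − T/2)))` with
`B = 2 ln(1/ε − 1)/T` and `d = label − tracked` at the segment end, so the
corrected path carries `ε·d` of correction at the segment start and
`(1−ε)·d` at its end — the residual from the label is exactly `ε·|d|` per
coordinate. Choices worth stating:

- The sign convention `d = label − tracked` is the one under which adding
  the sigmoid *corrects* the drift; with the opposite convention the same
  formula would double it.
- `j` is segment-relative, so the midpoint is `C = T/2` per segment; this
  makes multi-segment schedules well-defined.
- The shared frame between two segments keeps the *corrected endpoint
  value* of the earlier segment (`label − ε·d`); the tracker itself is
  re-initialised at the label for the next segment, which writes from its
  second frame on.
- A schedule frame equal to the trajectory's first frame initialises
  rather than corrects.
- Frames after the last correction frame are tracked but uncorrected and
  recorded in `result.meta["uncorrected_from"]`.
- A useful consequence of the sigmoid's symmetry: a perfectly linear drift
  ramp is cancelled almost exactly at the segment midpoint, so STC is
  strongest against steady drift.

ε defaults to 0.01 (a 1% residual) and must lie strictly in (0, 0.5).

**RTC** is the plain average of forward and backward paths; validity is
the conjunction of the two.

**RSTC** blends the same paths with weights
`w_f(x) = 1/(1 + exp(B(x − C)))`, `w_b = 1 − w_f`,
`B = 2 ln(1/ε − 1)/(t_e − t_i)`, `C = (t_i + t_e)/2`. The *decreasing*
sigmoid multiplies the forward path: the forward weight is `1 − ε` at the
start frame and `ε` at the end frame, matching the stated intent that each
path dominates near its own initialisation. (A literal reading of the
printed weight formulas gives the opposite assignment for positive `B`;
we treat that as a sign typo and follow the intent.) Because
`σ(z) + σ(−z) = 1`, the weights sum to 1 identically.

**Segment-wise RSTC** splits the labeled range at the schedule frames,
tracks each segment forward from its start label and backward from its
end label, blends with RSTC, and pins the boundary frames to the labels
exactly. **Pseudo-labels** sample an external trajectory every `stride`
frames (plus the final frame) into a label set for the same machinery;
invalid frames are skipped with a warning.

## Correction schedules

For the standard design of 8 labeled frames per video, the correction
frames for k = 0..4 are the fixed ordinals {}, {4}, {3, 6}, {2, 4, 6},
{1, 3, 5, 7} (1-based over the 8 labels). Other label counts use an
even-spacing fallback only behind an explicit `allow_generic` flag, since
the fixed ordinals are part of the standard protocol. Label density is
otherwise data-driven: nothing requires exactly 8 labels elsewhere.

## Evaluation protocols

**Mirrored-video drift.** `mirror_video(video, N)` builds the
`2N−1`-frame palindrome (frame `k` equals frame `2N−2−k`). The drift error
for each `N` is the mean over points of the Euclidean distance between
final tracked positions and the initial points; the drift *rate* is an
ordinary least-squares slope constrained through the origin on
`(2N−2, error)` pairs — through the origin because a zero-length track has
zero drift by construction. Entries where the tracker invalidates all
points are excluded from the fit. Default grid: N = 200, 400, …, 1600.

**Labeled-frame accuracy.** Euclidean distance at each labeled frame,
unweighted mean over points and frames; invalid points are measured
against their held position and flagged rather than dropped, so failures
are visible in the error rather than silently removed. The millimetre
conversion uses 13 px/mm by default (configurable).

**Jitter.** Zero-phase (forward–backward `sosfiltfilt`) 4th-order
Butterworth high-pass, default cutoff 15 Hz; the metric is the mean
absolute filtered value per point, averaged over x and y. The zero-phase
choice avoids group delay that would misalign jitter with the motion that
caused it. At 60 fps the filter's passband gain at 25 Hz is ≈ 0.98 after
the two passes, which bounds how closely the analytic `2a/π` value of a
passband sinusoid can be recovered.

## Synthetic scenes

`make_trajectory` builds per-point paths as a low-frequency sinusoid
(full amplitude in x, 60% in y, independent uniform phases) with motion
presets walk (15 px, 1.5 Hz, plus raised-cosine impact transients),
mvc (5 px, 2 Hz), reach (30 px, 0.1 Hz) and rest (1 px, 0.2 Hz) at
60 fps — plausible magnitudes chosen for the synthetic study, not
calibrated to any measured tissue displacement. Paths keep a 30 px margin
(plus amplitude) from the frame border.

`render_video` draws a fixed smoothed-uniform speckle texture advected
with the scene's mean motion, a bright Gaussian blob (σ = 2.5 px) at each
true point, Rayleigh-distributed multiplicative speckle and additive
Gaussian noise, both scaled by `noise_sigma` (default 0.03), clipped to
[0, 1]. This mimics the granular look of B-mode texture well enough to
exercise the trackers; it does **not** model acoustics, point-spread
functions, out-of-plane motion, shadowing or probe pressure, so passing
tests bound algorithmic behaviour, not clinical accuracy.

`DriftingTracker` returns ground truth plus accumulated deterministic
bias and/or a seeded Gaussian random walk. Each `initialize` starts an
independent substream derived from `(seed, initialisation count)`, so a
forward and a backward pass have independent drift realisations — as two
real tracking passes would — while reconstruction reproduces everything
bit-identically.

Two drift regimes are used deliberately in the experiments:

- *random walk* for comparing correction methods (drift as accumulated
  independent per-frame errors; under this model bidirectional blending
  genuinely adds information, and forward/backward drifts are
  independent);
- *steady bias* (with small noise) for the drift-rate recovery and the
  correction-frame-count experiments, where a deterministic slope is the
  quantity being recovered.

Under a pure steady bias shared by both passes, RTC/RSTC cannot cancel
drift (both paths err the same way) while STC cancels it almost exactly;
the ordering of methods therefore depends on the drift character, which
is why the ordering experiment specifies the noise-like regime.

## Problem sizes

The standard experiment scene is 1601 frames at 60 fps with 3 points and
8 labels; drift protocols run to N = 1600 (3199-frame palindromes);
Monte-Carlo comparisons use 20 paired replicates (50 for the random-walk
growth fit); shift-recovery tests use 100 seeded 96×96 speckle patterns.
These sizes give stable estimates while keeping the whole suite fast.

## Known limitations

- The LK tracker is translation-only; affine deformation of the template
  is not modelled (by design — the simplified form is the method under
  study).
- Template-tracker internals (CSRT/MOSSE/KCF) are not included; only the
  box protocol around an external backend is.
- No significance testing, Kalman/low-pass post-filtering, or DLC-style
  learned tracking; pseudo-labels from such a tracker are supported as
  input.
- The synthetic speckle is a visual, not physical, model; quantitative
  claims about clinical data require real labeled recordings.
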