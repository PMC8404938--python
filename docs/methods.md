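# Methods

`neovitals` estimates an infant's heart rate (HR) and respiratory rate (RR)
from ordinary RGB video without any skin contact. This note describes the
measurement model, every processing stage with its tunable parameters, what
the synthetic validation scenes do and do not establish, and the numerical
choices and known limitations of the implementation.

## Measurement model

Two physical mechanisms couple the cardiorespiratory system to a video
signal:

* **Colour (photoplethysmographic) mechanism.** Pulsatile blood volume in
  the microvascular bed changes how much light skin absorbs. The effect is
  strongest in the green channel, so the spatial mean of green over a skin
  region of interest (ROI),

      pG(t) = Σ_{i,j∈ROI} G(i,j,t) / |ROI|,

  carries a weak tone at the cardiac frequency. Spatial averaging over the
  ROI is itself the first denoising step: uncorrelated per-pixel sensor
  noise is attenuated by √|ROI|.

* **Motion mechanism.** Breathing moves the chest/abdomen contour through
  the (fixed) ROI. Converting each pixel to NTSC luminance
  Y = 0.299 R + 0.587 G + 0.114 B and spatially averaging gives pY(t),
  whose mean is modulated at the respiratory frequency by the bright/dark
  structure sweeping through the box. Only the Y row of the RGB→YIQ
  transform is evaluated; the chrominance planes are never needed.

The ROI is resolved once, on the first frame, and held fixed for the whole
analysis window — the method targets short clips in which the subject is
still. ROI sources are pluggable (a structured text file or any callable
mapping the first frame to a box); a neural-network infant detector is an
obvious plug-in but is deliberately not bundled. One ROI per vital is
supported and recommended: the cardiac box should sit in the *interior* of
a skin area (pure colour signal, no motion leakage), while the respiratory
box should straddle a moving body contour (maximal motion signal). Using a
single box for both works but couples the channels.

## Processing pipeline

Per non-overlapping window (default 10 s):

1. **Detrend.** The raw spatial-mean signal has a large DC offset
   (baseline skin/scene brightness); the window mean is subtracted before
   decomposition so the slow modes are not dominated by it.

2. **EEMD denoising.** The detrended signal is decomposed by ensemble
   empirical mode decomposition (below) into oscillatory modes IMF₁..IMF_N
   ordered fast to slow.

3. **Mode selection.** Each mode's one-sided FFT amplitude spectrum is
   computed and its dominant (maximum-magnitude, DC-excluded) frequency
   found. The mode whose dominant frequency falls inside the physiological
   band — cardiac 1.5–3 Hz (90–180 beats/min), respiratory 0.3–1.5 Hz
   (18–90 breaths/min) — is selected; among several candidates the one with
   the largest dominant-bin magnitude wins. If no mode lands in the band
   the pipeline falls back to filtering the detrended raw signal and flags
   the window (`fallback` diagnostic) rather than failing.

4. **Ideal band-pass.** Forward FFT over the window (rectangular window —
   a taper would shift the spectral peaks the selector relies on), zero
   every bin outside the band (edges inclusive; DC always removed), inverse
   FFT. The real-FFT representation keeps conjugate symmetry implicit, so
   the output is exactly real.

5. **Rate from peaks.** Local maxima of the filtered signal are detected
   with a minimum-separation rule, then the rate follows from the mean
   cycle length:

       CL = mean(diff(locs)) / fs   [s],   M = t / CL,   rate = 60·M/t = 60/CL.

   M (the implied cycle count) is kept real-valued; the rate depends only
   on CL. A rate outside the band's per-minute range is flagged
   `out-of-band`, not discarded; a window with fewer than two peaks is
   flagged `insufficient-peaks` and the pipeline continues.

### Peak separation

The band-limited signal cannot oscillate faster than the band's upper edge
f_hi, so peaks are required to be at least `floor(fs/f_hi) − 1` samples
apart. The −1 gives one sample of slack: a tone at exactly f_hi has peaks
one period apart with ±1-sample quantisation jitter, and demanding the
exact period would drop legitimate peaks. Additionally, when the filtered
signal has a well-defined dominant frequency f_dom, the separation is
raised to `0.7·fs/f_dom`: the filtered signal is narrowband, so local
maxima closer than ~a period are window-edge ringing of the ideal filter
(visible for off-grid tones near a band edge, e.g. 0.333 Hz analysed over
3.3 cycles), not real cycles. The 0.7 factor admits ±30% cycle-to-cycle
jitter. On clean tones both rules coincide with one peak per period.

## EMD and EEMD

Empirical mode decomposition represents a non-stationary signal x(t) as a
sum of intrinsic mode functions plus a slow residue, x = Σᵢ IMFᵢ + r_N. An
IMF satisfies two conditions: (i) its numbers of extrema and zero
crossings differ by at most one, and (ii) the mean of the envelope midline
(average of the cubic-spline envelopes through the maxima and through the
minima) is near zero.

Each IMF is extracted by sifting: subtract the envelope midline m(t) from
the current signal, d = x − m, and iterate on d. A candidate is accepted
when the Cauchy-type criterion

    SD = Σ(d_{k−1} − d_k)² / Σ d_{k−1}² < 0.2

indicates the iteration has stabilised *and* the candidate satisfies both
IMF conditions (count condition exactly; midline mean within 5% of the
candidate's standard deviation). Enforcing the conditions as well as SD
matters: with SD alone, roughly 10% of accepted modes on random
band-limited test signals violate the count condition. A hard cap of 50
sifts per mode bounds the loop. The outer loop stops when the residue has
at most two interior extrema (monotonic-or-trend).

Numerical details:

* **Extrema.** Strict interior maxima/minima; a plateau (run of equal
  values, common in quantised video signals) contributes one extremum at
  its midpoint index — a deterministic tie-break.
* **Envelopes.** Cubic splines through the extrema after mirror-extending
  two extrema beyond each end of the window; uncontrolled spline ends
  otherwise corrupt short 10-s records. With fewer than four knots the
  envelope degrades gracefully to linear interpolation; with no extrema on
  one side it falls back to the constant max/min of the signal (which
  makes the degenerate zero signal sift to a zero detail).
* **Completeness** holds to floating-point rounding by construction
  (each residue is the exact difference), measured at ~1e−16 relative.

**EEMD** suppresses mode mixing (one mode carrying widely different time
scales) by decomposing L noise-perturbed copies x_m = x + ω_m, with ω_m
white Gaussian noise of standard deviation ε·std(x), and averaging the
modes across the ensemble; member decompositions with fewer modes than the
ensemble maximum are padded with zero modes before averaging, and residues
are averaged likewise. Defaults L = 100, ε = 0.2 (the canonical settings;
the averaged-mode bias from residual ensemble noise scales as ε/√L).
Realisation m draws from `default_rng(master_seed + m)`, so the output is
a pure function of (signal, configs, master_seed). With ε = 0 all members
are identical and the ensemble average is computed as a single plain
decomposition — bit-identical to `emd` (naively averaging L identical
arrays would reintroduce rounding for L not a power of two). Averaged
ensemble modes are *not* guaranteed to satisfy the IMF conditions; this is
a known property of EEMD and is documented, not enforced.

## Agreement statistics

For validating measured rates against a reference (e.g. ECG-derived), the
package computes the standard method-comparison panel on paired series:
Pearson correlation; ordinary least-squares regression of measured on
reference; Bland–Altman bias (mean difference), limits of agreement
bias ± 1.96·SD and reproducibility coefficient RPC = 1.96·SD, with SD the
n−1 standard deviation of the differences; RMSE and MAE. The percentage
RPC uses the pooled grand mean of both series as denominator — a
convention choice, recorded in the output. A constant reference leaves the
correlation/regression undefined; those fields are returned as NaN with a
warning while the difference-based panel is still computed.

## Synthetic validation scenes

No clinical recordings ship with the package, so every stage is validated
on scenes with exact ground truth. A scene is a grey background plus a
skin-toned, soft-edged ellipse ("torso") whose

* green channel oscillates sinusoidally at hr_bpm/60 Hz with depth
  `cardiac_amp` (default 0.01, ≈1% of full scale — a typical rPPG pulse
  amplitude), and
* vertical position oscillates at rr_bpm/60 Hz with amplitude
  `resp_motion_px` (default 4 px at the 240×320 desk-test frame size).

The ellipse is centred horizontally in the ROI but shifted toward its
lower edge, with the body extending below the box, so the upper contour
lies inside the ROI — a patch wholly inside the box would leave the
spatial mean unchanged to first order and the breathing plant would be
invisible by construction. The soft (sigmoid) edge makes the luminance
response smooth in sub-pixel displacement. The default amplitudes were
fixed at generator-design time so that each mechanism dominates its
designated channel, as in real recordings: breathing dominates luminance,
pulse colour dominates green. `SceneConfig.cardiac_roi` /
`.respiratory_roi` expose the recommended per-vital analysis boxes.
Optional per-pixel Gaussian noise (`noise_std`) and a linear illumination
drift (`drift`, per second) complete the model. All generators are pure
functions of the `SceneConfig` (randomness flows from its seed).

Scenes default to 30 fps and 10 s, the acquisition conditions the method
is designed for; the 240×320 frame keeps a 16-point recovery grid
(HR ∈ {95,120,150,175} × RR ∈ {20,40,60,80} per minute) plus 5 noisy
replicates comfortably inside a desk-scale run.

**What passing does and does not show.** Recovery within ±2/min noiseless
and ±5/min under noise and drift demonstrates that the chain —
extraction, decomposition, selection, filtering, peak-rate — is correct
and self-consistent. The scenes are deliberately idealised: one sinusoid
per vital (no harmonics or waveform shape), no subject motion other than
breathing, no occlusion, no specular lighting, no camera shake, no
Bayer/codec artefacts. Success here does not establish clinical accuracy;
it establishes that failures on real data are attributable to real-data
effects, not to the implementation.

## Known limitations

* The cardiac band's 1.5 Hz lower edge excludes bradycardia below
  90 beats/min; bands are configurable but widening them invites overlap
  with the respiratory band and its harmonics.
* Rates from a 10 s window quantise: one sample of peak-placement error
  changes the rate by about 60/(fs·CL²) per minute, largest for slow
  respiratory rates.
* Two tones closer than roughly a factor of 1.5 in frequency (e.g. HR
  95 beats/min against RR 80 breaths/min) cannot be separated by EMD-type
  decomposition; the pipeline then relies on the band-pass stage and on
  per-vital ROI placement to keep each channel clean.
* ROI is fixed per window; subject motion within a window violates the
  model and shows up as flagged or out-of-band windows, not silent errors.
* Video decoding of compressed containers (MOV/MP4) requires a suitable
  imageio backend; lossless TIFF stacks and raw NumPy stacks are always
  supported and are the formats the test-suite uses.
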