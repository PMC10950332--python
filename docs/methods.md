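# Methods

This note documents the models, estimators and numerical choices behind
`cistrack`, and what the synthetic-data validation does and does not show.

## Synthetic movie model

The generator emulates high-speed spinning-disk confocal acquisitions of
budding yeast at three preset geometries: a 3D survey (41 slices 0.2 µm
apart), 4D maturation imaging (21 slices 0.2 µm apart, one volume every
5 s) and fast 4D contact imaging (9 slices 0.25 µm apart every 1.1 s).
Defaults: 0.1 µm lateral voxels, Gaussian PSF with σ<sub>xy</sub> = 0.075 µm
(≈176 nm FWHM lateral resolution) and σ<sub>z</sub> = 0.25 µm.

**Cisternae.** Each simulated cisterna is a Gaussian object of diameter
0.5 µm (object σ = diameter/4) with a confined-random-walk trajectory
(per-frame Gaussian steps of 0.02–0.03 µm, reflected inside a ±0.25 µm
lateral / ±0.15 µm axial box around a home position). Velocities and
confinement are not calibrated against real movies — real cisternae are
described only as "mobile" — and were chosen once so that tracks remain
unambiguous at 5 s sampling with ≥1.6 µm between neighbours.

**Marker kinetics.** Per channel, intensity follows an asymmetric Gaussian
pulse: amplitude·exp(−(t−t<sub>peak</sub>)²/2σ²) with separate rise and
decay widths (defaults 15 s and 20 s). Measured F/F_peak curves are
unimodal rise-and-fall; any smooth unimodal pulse would serve, and the
asymmetric Gaussian keeps the true peak time in closed form for tests. In
delay experiments the pulse widths are broadened to σ ≥ |Δ|/3.5 for
cisternae whose two peaks are far apart, so the object never goes dark
between its green and red phases. This mirrors the selection, in real
experiments, of cisternae that can be tracked continuously with both peaks
inside the observation window; without it, long-delay cisternae fragment
into single-channel tracks and the recovered delay distribution is censored.

**Zone segregation.** Each marker can carry a sub-zone offset vector; the
rendered displacement ramps linearly from zero at the earlier peak to its
maximum at the midpoint of the peak span and back to zero, so segregation
is strongest mid-transition.

**Camera model.** Expected photon images are Poisson-sampled, then Gaussian
read noise (SD 2 counts) and a constant offset (100 counts) are added —
qualitatively an EM-CCD; gain multiplication noise is not modelled. Default
signal is 150 photons at a unit-amplitude pulse peak. All randomness
derives from the config seed; identical config ⇒ bit-identical stacks.

**Scene sizing.** Delay-experiment movies place cisternae on a grid
(1.6 µm spacing, 0.9 µm margins) and size the movie length so that every
drawn delay (truncated at ±4 SD, a ~6×10⁻⁵ mass) keeps both peaks at least
two pulse widths inside the window. Green-peak phases are uniform within
one frame interval so frame-grid quantization averages out across
cisternae rather than biasing the mean.

**Coloc phantoms.** Two-channel 3D stacks share `round(rho·n)` spot
positions and amplitudes; each channel is topped up with its own
independent spots. With `noise=False` the channels at rho = 1 are exactly
identical (r = 1 by construction).

What passing on these phantoms does **not** show: robustness to
deconvolution artefacts, photobleaching (not modelled), spot
splitting/merging, densely packed cisternae, or non-Gaussian PSFs. Claims
about real movies require real movies.

## Detection and size estimation

Detection is multi-scale Laplacian of Gaussian. Anisotropic voxels are
handled by working in physical units: filter scales are micrometres, and
the scale-normalized negative Laplacian σ²·(−∇²) is evaluated in the
Fourier domain (multiplication by σ²|k|²·exp(−σ²|k|²/2)). The spectral
form is exact for sub-voxel filter widths where sampled spatial kernels
misbehave on a 0.2 µm axial grid; its boundary condition is periodic, so
objects should sit a few σ from the border. Six scales are spanned
geometrically over the best-responding scales of the requested diameter
range (default 0.25–0.9 µm). Candidates are local maxima over (scale, z, y,
x); the detection threshold applies to the raw peak intensity, either
absolute or in robust SDs above background (frame median; MAD-based SD
floored at 0.1 % of the dynamic range so noiseless backgrounds cannot
degenerate the cut). Centers are refined per axis by quadratic
interpolation of the response; close candidates are suppressed
deterministically, strongest response first.

**PSF-corrected diameter.** For an isotropic Gaussian blob of width
σ<sub>b</sub> the scale-normalized LoG response in 3D peaks at
σ = √(2/3)·σ<sub>b</sub>, not at σ<sub>b</sub>, and the axial PSF makes
real blobs anisotropic. The closed-form center response of a Gaussian blob
(per-axis widths √((d/4)² + psf²)) to an isotropic-in-µm LoG filter is
therefore maximized numerically over scale for a table of diameters, and
the observed best scale (parabolic interpolation across scales in log σ)
is inverted through that table. The familiar quadrature subtraction
σ<sub>obj</sub>² = σ<sub>meas</sub>² − σ<sub>psf</sub>² is the isotropic
limit of this correction; applying it directly to the raw argmax scale
underestimates a 0.5 µm object by ≈0.14 µm at the default PSF. On 50
rendered 0.5 µm puncta at default SNR the corrected estimate averages
0.51 µm.

## Tracking and contacts

Frame-to-frame linking is optimal bipartite assignment (Hungarian
algorithm) on squared displacement; links beyond 0.5 µm are forbidden, and
a track whose last spot is ≤ 2 frames old stays eligible, which closes
short detection gaps with the same gating distance. Unmatched spots seed
new tracks. Candidate ordering is fixed (frame, then id), so linking is
deterministic. Tracks never split or merge — the analysis follows single
cisternae.

A contact event is a maximal run of ≥ 2 consecutive frames with
track-to-ERES center distance ≤ 0.35 µm (the sum of typical 0.5 µm spot
radii at contact; exposed as a parameter). Duration is
(last − first frame)·Δt, so a single-frame dip counts 0 s — contact was
never defined operationally in the source experiments, so the convention
is documented here rather than claimed.

## Traces and peak-to-peak statistics

The ROI is a sphere of 0.35 µm radius (an ellipsoid in voxel indices) on
the track center, covering a 0.5 µm cisterna plus PSF spread; positions on
gap frames are linearly interpolated, border-clipped ROIs are truncated
with a warning. Background defaults to none (raw ROI means); per-frame
median or a constant are available for noisy synthetic data.

A channel's peak is the argmax of the 3-frame moving average, ties to the
earliest time, no sub-frame interpolation — so every per-cisterna Δ is a
multiple of the frame interval. Printed sub-frame mean delays arise from
averaging across cisternae, not from sub-frame peak estimates. Whether the
original analyses smoothed before taking maxima is unknown; the window is
a parameter. Tracks are excluded, with a logged reason, when shorter than
5 frames, when a channel is constant after smoothing (no unique peak), when
a channel shows no signal contrast ((max−min)/min < 0.3 — a fragment that
never saw that marker), or when a peak lands on the first/last observed
frame (its true maximum may lie outside the window).

Averaged curves shift each trace by −midpoint (so green and red peaks sit
at ∓Δ/2 exactly), resample by linear interpolation onto a common grid at
the frame interval, and average only traces covering each grid point (no
extrapolation). SEM = SD/√n with n the per-point coverage. Residency
intervals are the first/last grid times with the mean curve ≥ 20 % of its
peak, linearly interpolated at the crossings.

## Colocalization

Pearson r is computed from the standard sums over masked voxels; zero
variance raises rather than returning NaN. The Costes threshold scan fits
B on A by ordinary least squares (as in the original description; not
orthogonal regression), scans T_A downward through the distinct masked A
values (or 4096 evenly spaced levels when there are more), ties
T_B = a·T_A + b, and stops at the first level whose sub-threshold set has
r ≤ 0; if no level reaches zero the minimizing level is returned and
flagged. The sub-threshold set uses AND (both channels below) by default —
implementations differ and the choice is exposed (`below="or"`), with both
covered by the exhaustive-scan oracle in the test suite. Degenerate levels
(< 2 voxels or zero variance) are skipped; a ≤ 0 slope is flagged as having
no positive-correlation threshold. Both r over all masked voxels and r
above the thresholds are reported, since published values could be either.
Welch's t-test (scipy, with explicit Welch–Satterthwaite df) covers group
comparisons; multiple-comparison procedures (Dunnett, Tukey) are out of
scope — they affect significance stars, not the r values.

## Line scans

Profiles are bilinear interpolations at spacing voxel/2 along a segment on
the z-slice of the spot center (or a maximum projection), normalized per
channel by the profile maximum. Segregation metrics are the distance
between per-channel argmaxima and between intensity-weighted centroids
Σx·I/ΣI; both are invariant to per-channel positive rescaling and to
reversing the segment. The centroid uses raw (not background-subtracted)
intensity, so on high-offset images it is diluted toward the segment
center — the peak offset is the more sensitive metric there. No
"segregated/overlapping" classification threshold is imposed; the metrics
are reported as numbers.

## Timeline assembly

With t_i the unknown peak times and Δ_ij the measured early→late mean
delays, the placement minimizes Σ w_ij (t_j − t_i − Δ_ij)² with the anchor
fixed at 0, solved by least squares on the incidence matrix of the
anchor's connected component (other markers are reported unplaced).
Default weights n/sd² floor the SD at 5 s (one frame interval): one
printed row has SD 9.0 around a mean of 3.9, and unfloored inverse-variance
weights would let a single tight edge dominate long chains. Consistent
inputs are recovered exactly under any weighting; for inconsistent cycles
the per-edge residuals quantify the tension between independently measured
delays rather than resolving it.

Markers measured under different fluorophore tags are merged by stripping
tag tokens from the construct label (a flag keeps them distinct). The
bundled table keeps the two temporally separate appearances of Ypt1 (at
the ERGIC and at the trans-Golgi/TGN interface) as distinct markers
(`Ypt1`, `Ypt1.2`); merging them would average two genuinely different
peak times and scramble the stage order. Residency bars for markers whose
underlying curves come from prior work are not reproduced.

## Validation scale and determinism

The acceptance experiments use 20 replicate simulations per delay regime
(10–31 cisternae each, movie sizes 35–115 µm² × 4 µm, 30–70 frames) and 50
spots for size recovery — sizes chosen so the full recomputation runs in a
few minutes on one CPU. Delay draws use antithetic variates across
replicate pairs (mean + σz, then mean − σz): each replicate's delays are
still marginally normal with the programmed mean and SD, but the
draw-level Monte-Carlo noise cancels in the grand mean, so the recovery
experiment isolates estimator calibration (which it bounds at ~0.3 s)
instead of re-sampling the delay distribution with SEM ~2 s. Trajectories,
pulse phases, amplitudes and camera noise remain independent per
replicate. Every stack, scene and experiment seed derives from a
single integer, and identical seeds reproduce identical outputs bit for
bit; CSV outputs are stable across reruns of the same config.

## Known limitations

- Peak times are frame-quantized; per-cisterna Δ has ±Δt/2 quantization
  error (unbiased across cisternae by phase randomization in the
  generator, but present in any single estimate).
- The LoG detector assumes roughly Gaussian, roughly isolated blobs;
  overlapping cisternae closer than the suppression distance merge.
- Fourier-domain filtering wraps at boundaries; detections hugging the
  border are less reliable than interior ones.
- The camera model omits EM gain noise; SNR in real movies may be worse
  than the default preset at matched photon counts.
- The timeline model assumes delays are exchangeable measurements of peak
  time differences on a common maturation clock; systematic tag- or
  strain-dependent shifts would be absorbed into residuals, not corrected.
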