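# Methods

## Spin system and signal model

The signal model is the Bloch-McConnell system for two exchanging ³¹P
pools, phosphocreatine (PCr, chemical shift 0 ppm) and the γ-phosphate of
ATP (−2.52 ppm; 120.67 Hz/ppm at 7 T, so the pools are ≈ 304 Hz apart).
Magnetization is expressed in multiples of the equilibrium γATP
magnetization: M0(ATP) = 1, M0(PCr) = Cr. Exchange acts on all three
magnetization components of both pools; the reverse rate follows detailed
balance, k_rev = k_CK · Cr, so the equilibrium pool ratio equals Cr. Four
parameters are free — k_CK, Cr, T1(PCr) and a global off-resonance ΔB0 —
and three are fixed to literature values: T1(ATP) = 1 s, T2(PCr) = 135 ms,
T2(ATP) = 25 ms.

Free evolution is the matrix exponential of the homogeneous-coordinate
generator. A vectorized two-pool path exploits the block structure between
RF events: the transverse components form a 2 × 2 complex system and the
longitudinal components a 2 × 2 real affine system, both with closed-form
exponentials, which makes dictionary generation fast (≈ 10⁵ parameter
tuples per minute on one core).

An optional third pool models inorganic phosphate (Pi, +4.9 ppm)
exchanging with γATP through ATP synthase at forward rate k_atp (reverse
rate k_atp · M0(Pi) by detailed balance). Pi constants are configuration
values chosen as typical human-brain figures, not fitted quantities:
M0(Pi) = 0.4 (Pi/ATP concentration ratio), T1(Pi) = 4 s, T2(Pi) = 50 ms,
and an in-vivo k_atp range of 0.05–0.30 s⁻¹.

### Excitation and preparation pulses

Excitation uses the single-isochromat nominal-flip model: an instantaneous
rotation at the temporal centre of the 10 ms Gaussian pulse, with each
pool's flip scaled by the unit-peak Gaussian frequency profile
(FWHM 170 Hz) at that pool's offset from the active carrier, including
ΔB0. At the ≈ 304 Hz separation the profile factor is 1.4 × 10⁻⁴, so the
non-targeted metabolite is essentially untouched. A piecewise-constant
("hard-pulse") decomposition of the shaped pulse exists as a validation
mode only.

The receiver phase follows the RF phase (standard bSSFP phase cycling) and
the active block carrier, so consecutive samples are sign-coherent. This
matters for the conditioning step: the phasing references are the means of
the odd PCr samples and of all ATP samples, and without receiver phase
cycling those means would vanish and the phases would be undefined.

The four asymmetric inversion preparations are modelled as per-pool
longitudinal efficiencies ε ∈ [−1, 1] applied at the midpoint of the 40 ms
pulse window (configurable to start/end), with free evolution across the
pulse, the 2 ms delay and the 8 ms crusher, which finally zeroes all
transverse components. The default pool mapping follows from the printed
carriers and the mirrored profiles: the first preparation (+1.25 ppm,
inverting the band below its transition) inverts both pools; preparations
2 and 4 (−1.25 ppm, opposite orientation) invert only PCr, whose inversion
recovery then runs undisturbed through the ATP readout blocks (this is the
IR that encodes T1 of PCr); preparation 3 (−1.25 ppm, same orientation as
the first) inverts only γATP, so the following PCr block reads the
inversion transfer through the CK exchange. Pi lies ≈ 590 Hz from every
preparation carrier, far outside the narrow band of a 40 ms pulse, and is
left untouched by default; all of this is configurable per preparation.

### Timing

One pattern repetition is: per block, inversion (40 ms) → 2 ms delay →
8 ms crusher → 200 excitations → 400 ms pause. PCr blocks alternate
TR = 19.82 / 23.82 ms (every second excitation carries the Te⁺ = 4 ms echo
shift that encodes ΔB0 in the sample phase); ATP blocks use 19.82 ms
throughout. Samples are taken at pulse end + Te (410 µs, plus Te⁺ where
present); signal evolution during the 8.61 ms readout is neglected, the
single-sample-per-TR model. The summed event durations give 18.456 s per
repetition (≈ 92 s per volume over the five kz repetitions). A feasibility
audit reports that the printed timing leaves the readout + refocus window
0.12 ms short of the nominal TR for the short-TR excitations; the schedule
reports, but does not resolve, this inconsistency.

## Conditioning and matching

Each 800-point complex evolution is split into its 400 PCr and 400 ATP
samples. The PCr half is phased by the mean phase of the odd in-block
excitations (the transient without Te⁺), the ATP half by the mean phase of
all ATP samples; the vector [Re PCr ∥ Im PCr ∥ Re ATP] (1200 points) is
L2-normalised. Matching maximises the inner product over the dictionary,
making the estimate invariant to global scale and phase; ties break to the
lowest atom index. Constrained matching restricts the search to a
sub-grid, either globally (T1 fixed at 4.5 s for the functional mode) or
per voxel (ΔB0 and Cr pinned to a previous estimate).

The default desk-scale grid covers k_CK 0.05–0.60 s⁻¹ (step 0.01),
Cr 0.5–2 (step 0.05) then 2.25–6 (step 0.25, honouring the upper bound 6),
T1(PCr) 2–7 s (step 0.25, 4.5 s on-grid), ΔB0 ±25 Hz (step 1). The
supplementary ranges of the original acquisition are not public, so these
are declared package defaults. The bias experiments (fixed-parameter and
three-pool) use a locally refined grid (k_CK step 0.0025 around the
operating point) so that grid quantization (±1.7 %) does not dominate the
few-percent biases being measured.

The fingerprint landscape is strongly anisotropic: Cr is well conditioned
(1 − score ≈ 1.3 × 10⁻³ for a 10 % change), while k_CK and T1(PCr) share a
shallow ridge (1 − score ≈ 3 × 10⁻⁴ for a compensated ±20 % k_CK move).
The Monte-Carlo precision figures are consequences of this geometry.

## Reconstruction

Raw data is ordered (readout 861, kz 5, FA 800, coil, average), with k-space
coordinates in cycles/FOV (Nyquist radius 16 for the 32 matrix).

- The spiral is a variable-density Archimedean design; "33 % kxy coverage"
  is read as sampled-area fraction of the Nyquist disc, so the outermost
  radius is √0.33 · 16 ≈ 9.2 cycles/FOV. The radius grows as
  t^1.3 (denser centre); the number of turns defaults to the radial-Nyquist
  requirement.
- Density compensation is the Voronoi cell area per sample, with boundary
  cells clipped to a disc extending half the outer ring spacing beyond the
  outermost sample, then multiplied by the radial half-period Hann window
  (1 at the centre, 0 at the outermost radius). Voronoi quadrature is a
  few percent imperfect where the spiral is much denser along-track than
  ring-to-ring (near the centre); this limits the spectral flatness of the
  chain to ≈ 3 % at full coverage and is inherent to the method, not a
  numerical defect.
- Gridding uses a width-4 Kaiser-Bessel kernel on a 1.5× oversampled grid
  with the standard minimum-aliasing shape parameter; deapodisation uses
  the image response of the discretely sampled kernel, which makes a
  DC-only acquisition exactly flat. Gridding and degridding are exact
  adjoints by construction.
- The kz dimension measures the 5 central of 11 planes; the centred
  inverse DFT implicitly zero-fills the outer 3 planes per side.
- Coil combination is whitened SVD per voxel with the FA index as the
  temporal dimension. The noise covariance comes from reconstructing
  interleaved average differences through the same chain; each voxel is
  divided by the chain's analytically computed noise gain so the estimates
  carry the raw per-sample scale. The combined series is the principal
  temporal component of the whitened coil × FA matrix, rescaled to the
  voxel's original data energy; its temporal shape is invariant to
  invertible coil recombination (with correspondingly transformed
  covariance), while its amplitude follows the original units.
- MP-PCA denoising flattens the volume to an (n_voxels × 1600) real matrix
  (real and imaginary parts concatenated along the FA dimension), detects
  the Marchenko-Pastur noise bulk from the eigenvalue spectrum of the Gram
  matrix, and nulls the bulk components. One global spatial block is used.

## Synthetic data

The digital phantom is an ellipsoidal brain on the 32 × 32 × 11 grid:
a white-matter core inside a gray-matter shell, two CSF ventricles (low
amplitude 0.15 — metabolite-poor), an occipital ROI (posterior 35 % of the
brain), and smooth seeded per-voxel parameter jitter (SD 0.02 / 0.06 /
0.20 for k_CK / Cr / T1, smoothed over ≈ 1.5 voxels). Tissue means anchor
the reported human values: GM (0.30 s⁻¹, 1.27, 4.67 s), WM (0.30, 1.23,
4.50). ΔB0 is a smooth field within ±10 Hz with a stronger frontal bump.
`brain_mask` covers GM and WM only — parameter estimates in CSF are not
meaningful in vivo either — while `support_mask` covers all signal-bearing
voxels for the forward model.

The forward model simulates every voxel's evolution, weights by smooth
complex Gaussian-profile coil sensitivities (Toeplitz noise coupling, 0.2
neighbour correlation), evaluates the exact discrete Fourier sum on the
spiral for the 5 central kz planes (no inverse crime against the gridding
adjoint; a calibrated degridding fast mode exists and agrees to ≈ 1 %),
and adds correlated complex Gaussian noise per average.

Study-condition choices, made once:

- The functional effect size is a 15 % multiplicative k_CK increase in the
  occipital ROI, the reported group-mean activation.
- The "realistic" raw-noise level used by the seeded noisy experiments is
  σ = 10 per real component at 4 averages (raw-signal RMS ≈ 41). At this
  level the matched gray-matter maps show a voxelwise k_CK scatter of
  ≈ 4 %, matching the scale of the reported intrasession CVs, and the
  residual-based SNR metric sits in the upper in-vivo range.
- Desk-scale datasets use 2–8 averages and 2–4 coils instead of 32/32;
  precision results scale accordingly and are checked against
  evolution-level SNR, not against average counts.

What the phantom does *not* emulate: anatomical geometry beyond nested
ellipsoids, B1 transmit inhomogeneity (assumed homogeneous, as in the
modelled acquisition), motion or physiological noise, susceptibility-induced
intra-voxel dephasing, and scanner-specific artefacts (gradient delays,
eddy currents). Passing the end-to-end tests therefore demonstrates the
correctness and internal consistency of the chain under its own physics,
not robustness to those effects.

## Numerical choices

- Exactly-invertible test settings: a z-invariant phantom (band-limited to
  the measured kz planes), a full-coverage spiral, the Hann filter off and
  zero jitter. Only in that configuration is the discrete forward model
  exactly invertible, so the nearest-grid recovery check isolates
  grid quantization; ΔB0 truth is snapped to the analysis grid there
  because a truth exactly between two grid values is a tie, not an error.
- The independent integration oracles are first order: plain explicit
  Euler (nanosecond steps) and Euler with exact per-pool precession
  splitting (microsecond steps). Plain first-order stepping cannot reach
  much below ≈ 10⁻⁴ relative error at feasible step counts because the
  ≈ 2π·304 rad/s precession dominates the local truncation error; the
  splitting variant removes that term analytically and reaches ≈ 5 × 10⁻⁶
  at 1 µs steps. Equivalence tolerances are set at 10⁻⁴.
- Degenerate inputs: all-zero evolutions raise (undefined phasing phase);
  duplicate k-space samples are jittered by 10⁻⁹ with a warning; singular
  noise covariances raise with a regularisation hint; voxels with zero
  rest-state k_CK are masked out of the percent-difference map.
- Cluster connectivity defaults to 6-neighbour (face) connectivity in 3-D,
  configurable to 26, and is recorded in the cluster report.
- The "combined dataset" of the functional analysis is the equal-weight
  average of the rest and stimulation reconstructions.
- The residual-based SNR scales the unit-norm matched atom onto the
  measured conditioned vector by least squares before forming the
  fit-power/residual-power ratio; ±∞ sentinels mark exact fits and zero
  fits.

## Known limitations

- The Voronoi density compensation is a quadrature approximation; its
  few-percent low-frequency ripple bounds the achievable image fidelity of
  the non-iterative chain.
- The asymmetric inversion pulses are reduced to per-pool efficiencies;
  actual slice-profile and adiabaticity effects are not modelled.
- Fingerprint precision figures are grid-dependent near the k_CK–T1 ridge;
  the reported Monte-Carlo SDs use a grid wide enough to contain several
  SDs of error in every direction.
- Cohort-level inference (ANOVA, post-hoc tests) is out of scope; the
  analysis stops at descriptive per-dataset tables and cluster reports.
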