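# Methods

This note documents the models, numerical choices and limitations behind
`cryofocus`. It is written for users who want to know what the package
actually computes, and what passing its tests does and does not demonstrate
about real data.

## Image formation model

A particle image is modeled as

    D_i = CTF_i · P(R_i, t_i) V  +  N_i

where `P(R, t)` projects a 3D density `V` along the z-axis after rotating the
reference by `R` (ZYZ Euler angles rot/tilt/psi; the projection direction is
the rotated z-axis), then shifts the projection by the in-plane offset `t`
(in pixels, applied as a Fourier phase ramp toward the particle).  `CTF_i` is
the weak-phase contrast transfer function

    CTF(f) = −[ √(1−Q²)·sin γ(f) + Q·cos γ(f) ],
    γ(f)  = π λ Δz(θ) |f|² − (π/2) Cs λ³ |f|⁴ + φ,

with `Q` the amplitude contrast, `Δz(θ)` the astigmatic defocus (underfocus
positive), `λ` the relativistic electron wavelength and `φ` an optional phase
shift.  The sign convention puts `CTF(0) = −Q`, so projected protein density
appears dark.  No envelope/B-factor decay is included in the CTF itself;
spectral decay belongs to the simulator's signal and noise spectra.  One
projector implementation serves the simulator, the subtractor and the
classifier, which is what makes projection subtraction an exact algebraic
operation on self-consistent data.

`N_i` is zero-mean Gaussian noise, independent between particles, with a
per-Fourier-shell power spectrum.  Spectra are quoted as per-component
powers `E|N(f)|²` of the normalized transform `fft2(n)/N`, per integer
frequency shell.

## Projection and reconstruction numerics

Forward projection uses the Fourier-slice theorem on a 2× zero-padded
(oversampled) transform with trilinear interpolation of the central slice.
The interpolation blur is compensated by dividing the real-space volume by
the separable `sinc²(r/(2N))` transform of the trilinear kernel before
padding.  This pre-correction is exact only for slices that must actually be
interpolated: orientations that are signed axis permutations (identity and
90° views) sample grid planes exactly, where the correction would *introduce*
a few-percent bias.  Those orientations therefore take an exact real-space
permute-and-sum path (periodic index convention, matching the DFT).  As a
result, identity-view projections preserve the voxel sum exactly, and
oblique projections of compact, band-limited volumes agree with a
spline-rotate-and-sum oracle to within ~2% relative RMS at box 16 (and
~0.5% at box 32).

Backprojection is the exact adjoint of the interpolating projector: the
conjugate phase ramp is applied, slice values are spread with the same
trilinear weights, and the inner-product identity
`⟨P V, I⟩ = ⟨V, Pᵀ I⟩` holds to floating-point precision (tested at 1e−6
relative).  Reconstruction accumulates `Σ w·CTF·D` and `Σ w·CTF²` on the
oversampled grid and divides them Wiener-style, `num/(den + ε)` with
`ε = 10⁻³ × mean(den > 0)` by default — a documented stabilizer, not a
tuned constant.  The inverse transform is cropped and divided by the same
`sinc²` correction.  With 1,000 uniform views and no noise this recovers a
phantom with real-space correlation > 0.999; with defocus diversity over
0.7–3.2 μm the CTF² accumulation fills the CTF zeros (correlation > 0.999
at 2,000 views).

## Residual signal subtraction

Given a consensus map split as `V = V1 + V2` (V1 = the part to ignore,
V2 = the focus region), the subtractor computes, for every particle,

    D'_i = D_i − CTF_i · P(R_i, t_i) V1

using the particle's refined orientation *and offsets* — the projection is
shifted into the particle frame before subtraction, since the offsets are
part of the consensus alignment.  No rescaling is applied; any intensity
mismatch is the classifier's noise model's concern.  On simulator output the
residual identity `D'_i − CTF_i·P(V2) = N_i` holds exactly (tested at 1e−9),
because simulator and subtractor share one projector.

## Masks

Soft masks are built the standard way: binarize a map at a threshold, extend
the binary region by a Euclidean distance (`extend_px`, default 3), then add
a raised-cosine falloff `½(1 + cos(π d/edge))` over `soft_edge_px` voxels
(default 6).  Focus masks in the benchmark are generated from the
pseudo-atom model of the focus region itself (the rod), mirroring the
workflow of converting an atomic model to a map and soft-edging it; the
"everything else" mask is the whole-complex mask minus the focus mask,
clipped to [0, 1].

## Fixed-orientation masked classification

Classification is maximum-likelihood over K references with orientations
and offsets frozen at their consensus values ("no image alignment") — the
regime for focus regions too small to drive an orientation search.  With
normalized data transforms and references masked by the focus mask, the
per-particle class log-likelihood is

    ln L_ik = − Σ_f |D_i(f) − CTF_i(f)·S_k(f)|² / (2σ²(ν_f))
              − Σ_s m_s ln(2π σ²(s))

summed from shell 1 (DC is excluded; it measures background) up to the
classification resolution limit, by default two shells below Nyquist.
`σ²(s)` is a single shared per-shell variance of the real and imaginary
components.  E-step responsibilities are `softmax_k(ln π_k + ln L_ik)`; the
M-step rebuilds each reference by responsibility-weighted reconstruction,
reapplies the focus mask, and updates `π` and `σ²` (the latter from
residuals against the *updated* references, so each update is an exact
conditional maximizer given the others).

**Coarse-to-fine schedule.**  The first iterations (default 6 of 25) score
the likelihood only up to a coarse resolution (default 12 Å).  The class
differences of interest are low-frequency, while the high-frequency content
of freshly initialized references is pure sampling noise; restricting the
early comparisons keeps responsibilities soft and lets the true class split
grow before the full band opens up.  Without this, data that are too clean
can freeze EM near its random initial partition (saturated responsibilities
reproduce the initialization), while heavily low-pass-filtered
initializations can stall in the symmetric state.  Evidence values recorded
in the run history carry the shell limit they were computed with and are
comparable only within a stage; at the single band switch the evidence is
re-baselined before the ascent guard resumes.

Because the reconstruction update is approximate (Wiener regularization,
masking, interpolation), plain alternation can overshoot by ~1e−5 in
relative log-evidence.  The loop therefore runs as a monotone generalized
EM: after each update the marginal log-evidence is evaluated (this doubles
as the next E-step, so it costs nothing extra), and if it decreased the
reference step is halved toward the previous references until ascent is
restored.  Since the `π` and `σ²` updates are exact conditional maximizers,
a small enough reference step always restores ascent; in practice
backtracking triggers rarely.  The run uses a fixed iteration count
(default 25, no convergence early-exit), seeded random hard partitions for
class divergence, argmax ties broken toward the lowest class index, and a
single `numpy` generator per run — bit-reproducible given the seed.

## The forward simulator and what it emulates

The benchmark phantom pair consists of a fixed, asymmetric two-lobed "body"
of 36 Gaussian pseudo-atoms (radius 7 Å) plus, in one class only, a ~30 Å
rod of Gaussian atoms (radius 6 Å) at the body's periphery — a stand-in for
a helix that is ordered in one conformational class and disordered in the
other.  The body layout is part of the phantom definition (fixed internal
seed); the rod position scales with the box so the same geometry holds at
box 32 and 64.  Orientations are uniform over SO(3) by default (tabulated
distributions are supported); defocus is uniform in 0.7–3.2 μm at 300 kV,
Cs 2.7 mm, Q = 0.1, astigmatism 0; pixel size 2.8 Å at box 64 in the
benchmark.  Noise is drawn as white real-space Gaussian noise colored
shell-wise in Fourier space, and every realization is retained so
bookkeeping identities can be tested exactly.

**Noise calibration.**  The benchmark's noise spectrum is proportional to
the radial power spectrum of the clean CTF-affected projections (i.e. flat
per-shell SNR, low across all shells), with the amplitude fixed by a
discriminability rule: the single-image Bayes error of the two-class
likelihood-ratio test is set to 2%.  Concretely, with
`E = Σ_f |CTF·(A−B)(f)|²/power(f)` summed over the shells the classifier
scores, conjugate-pair redundancy of real images gives error
`Φ(−√E/2)`, so the noise scale solves `E = 4 z*²` with `z* = Φ⁻¹(0.98)`.
This is the package's scale-down rule: a desk-scale box cannot match an
experimental data set's absolute SNR and its classification difficulty at
the same time, and the difficulty statistic is the one that makes a
scaled-down re-enactment of a full-scale classification experiment
meaningful.  At box 64 this yields per-shell SNR ≈ 0.1 and real-space
signal-to-noise variance ratio ≈ 0.1 — values typical of cryo-EM particle
images.

**What passing does not show.**  The simulator draws noise from the
classifier's own model family (shell-wise Gaussian), uses exact orientations
and CTFs, and contains no solvent, motion, dose damage or detector MTF in
the forward model.  Benchmark accuracies therefore measure the method's
behavior under its stated assumptions, not robustness to model mismatch on
experimental micrographs.

## Validation

FSC is the shell-wise normalized cross-correlation of Fourier coefficients;
resolution is reported at the first downward crossing of FSC = 0.143 with
linear interpolation (gold-standard half-sets are even/odd labels after a
seeded shuffle).  Masked FSC curves are corrected by high-resolution noise
substitution: phases beyond a chosen frequency (default: where the unmasked
FSC first drops below 0.8) are randomized in both half-maps, the spurious
masked correlation `FSC_n` is measured, and shells beyond the randomization
frequency are reported as `(FSC_t − FSC_n)/(1 − FSC_n)`.

One point here deserves care: masking two *fully independent* noise maps
does not inflate their expected FSC (masking correlates frequencies within
each map, not between maps).  The inflation the correction removes arises
when the half-maps share a component — signal leaking through the mask
convolution into noise-dominated shells.  The tests therefore exercise the
correction on shared-signal-plus-independent-noise half-maps, where the
uncorrected masked FSC is visibly positive at high shells and the corrected
curve returns to zero.  With a very tight mask the per-shell FSC estimator
has few effective degrees of freedom, so assertions are made on
seed-averaged means rather than single shells.

## Problem sizes used by the tests and the acceptance script

The headline benchmark (the acceptance script) runs 2 × 2,000 particles at
box 64 (2.8 Å/px), 25 EM iterations, K = 2 — about 8 minutes on one CPU —
and classifies ~96% of particles correctly across seeds.  The test suite
exercises the same code path at 2 × 1,200 particles (~95%), and the rest at
box 32: EM property checks at 2 × 500 particles, an SNR sweep at noise
powers ×[0.5, 0.8, 1.25, 2, 3.2] of calibrated (5 seeds, common random
numbers across scales), and a K = 8 negative control on 6,400 homogeneous
particles with noise low enough (0.05× calibrated) that per-class map SNR
(~15) does not limit the map comparison — at experimental scale (hundreds
of thousands of particles) it never does.  Unit oracles (projection, masks,
FSC) use boxes 8–64.

## Known limitations

- **High-SNR, small-n lock-in.**  With very low noise and few particles per
  class, responsibilities saturate in the first iterations and vanilla EM
  can freeze near its random initial partition (the classic hard-EM
  pathology).  The method's operating regime — low per-shell SNR, thousands
  of particles — does not trigger this, and truthful or user-supplied
  initial references avoid it entirely, but the package implements no
  annealing schedule.
- **Subtraction benefit scales with residual-to-noise ratio.**  When the
  noise power is much larger than the out-of-focus signal in every shell
  (as under the benchmark's flat low per-shell SNR), classifying raw images
  against masked references costs only a little accuracy; the benefit of
  subtraction grows as the un-modeled residual becomes comparable to the
  noise, and the comparison test runs at the sweep's low-noise end where
  the effect is well resolved.
- C1 symmetry only; no orientation or translation search; no marginalization
  over poses; a single shared noise spectrum across classes and particles.
- The negative-control similarity of K = 8 class maps is judged after
  low-pass filtering to the resolution the per-class reconstructions
  actually support; raw voxel-level correlations at desk scale are dominated
  by per-class reconstruction noise that the paper-scale experiment (400k
  particles) does not have.
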