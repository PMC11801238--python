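# Methods

## Signal model of the simulator

Each synthetic 2D plane is a sum over 40–200 cross-peaks (uniform count)
of separable time-domain signals. For cross-peak *k* with ¹³C offset
Ω_C, ¹H offset Ω_H (Hz relative to the carrier), amplitude I_k and
transverse relaxation rates R₂C, R₂H:

    s_k(t₁, t₂) = I_k · e^{(i2πΩ_C − R₂C) t₁} · M_C(t₁ + τ_coup)
                      · e^{(i2πΩ_H − R₂H) t₂} · M_H(t₂)

with the coupling modulation per dimension

    M(t) = [cos(πJ₁t) + ϱ₁ i sin(πJ₁t)] · [cos(πJ₂t) + ϱ₂ i sin(πJ₂t)].

The imaginary sine terms (ϱ ~ N(0, 0.08)) produce roofing — the
intensity asymmetry of multiplet lines near the strong-coupling limit.
During the coupling-evolution delay τ_coup only phase evolves; no
amplitude decay is applied there, consistent with analysing the
multiplet encoding while ignoring relaxation.

Distribution defaults (the training conditions):

| parameter | default | notes |
| --- | --- | --- |
| J₁C, J₂C | N(63, 10) Hz, each zeroed with p = 0.2 | gives 64/32/4 % triplet/doublet/singlet |
| J₁H | N(8, 2) Hz, zeroed with p = 0.1 | ¹H passive coupling |
| J₂H | N(4, 2) Hz, zeroed with p = 0.5 | ¹H passive coupling |
| roofing ϱ | N(0, 0.08) | both dimensions |
| R₂C input | N(50, 20) s⁻¹, floor 1 s⁻¹ | target uses exactly half |
| R₂H | N(50, 20) s⁻¹, floor 1 s⁻¹ | distribution not stated for training; same family adopted |
| intensity | \|N(1, 0.3)\| | also used for the solvent amplitude |
| ¹³C shifts | uniform over the sweep width | |
| ¹H shifts | δ_H = 0.2·SW·tanh(6δ₀/SW) + 0.3·SW·tanh(2δ₀/SW), δ₀ ~ N(0, SW/4) | compresses peaks toward centre, keeps them off the edge |
| solvent | 10·amp·[slp·(1/(x+0.1) − 0.9) − (1−slp)·x], x = i/N | ¹H frequency domain; mirrored for half the sets |
| noise | complex Gaussian, SD = 10⁻³ × max input amplitude | inputs only |
| phase errors | zero/first order, uniform ±5°, per input plane | inputs only |
| acquisition | n_C uniform 96–200, n_H uniform 128–256 complex points | SW 5000 / 10000 Hz |

The target plane omits the ¹³C coupling modulation entirely, halves the
¹³C relaxation (R₂,tar = 0.5·R₂,inp), and carries no solvent, noise or
phase errors; ¹H passive couplings are retained identically, since the
decoupling and sharpening act on the ¹³C dimension only.

Two readings in the source material are ambiguous (the ¹H-placement
equation and the solvent formula); the forms above preserve the printed
coefficients, oddness and the half-sweep-width bound, and each is
isolated behind a single function so an alternative reading is a
one-line change.

**Hypercomplex storage.** Planes are stored with shape (2, n_h, n_c)
complex: the first axis holds the cosine- and sine-modulated t₁
interferograms (States quadrature), the complex dtype the ¹H
quadrature. This carries the four real components per complex-point
pair that the network's fixed (2, 400, 512) input tensor requires; a
plain complex 2D array has only two and cannot fill it. The solvent
signal is added identically to every t₁ increment (it carries no ¹³C
coherence), producing the axial ridge at the ¹³C carrier.

**What the generator does not emulate.** t₁-noise ridges (deliberately
out of distribution), spectrometer artifacts beyond small phase errors,
chemical-shift correlations between residues, cross-correlated
relaxation, and real solvent dynamics. Tests passing on these synthetic
conditions therefore demonstrate the correctness of the implementation
and the internal consistency of the training objective, not performance
on experimental spectra.

## Objective and calibration

The network predicts an intensity plane and a confidence plane;
σ = 1/(0.998·sigmoid(conf) + 0.001) − 1 maps confidences to strictly
positive uncertainties in (≈0.001001, 999). The training loss is

* loss1: mean squared error over the 400×512-point plane;
* loss2: Σ_m |mean_i(χ_i^m) − M_m|² over m ∈ {1/2, 1, 2, 3, 7/2}, with
  χ = (target − pred)/σ, fractional powers on the principal complex
  branch, and M_m = (1 + e^{iπm})·2^{m/2}·Γ((m+1)/2)/(2√π) the complex
  fractional moments of a standard normal (M₁ = 0, M₂ = 1, M₃ = 0);
* loss3: σ binned into 200 linear bins on [0, max σ]; per non-empty bin,
  (mean σ − RMS residual)²; empty bins contribute zero;
* total = (2 − S)·loss1 + S·(loss2 + loss3) with
  S = sigmoid(−exp(100·min(loss1, 0.03))/0.268), so the calibration
  terms switch on only once loss1 falls below 0.03.

Both predicted and target intensity planes are convolved with a
sine-bell window (offset 0.4π) before the losses, implemented as
time-domain apodization through the transform pair; the operator is
linear and self-adjoint. The σ plane is **not** convolved: doing so
could violate σ's strict positivity, which the rest of the machinery
relies on.

Gradient-flow choices (both standard in heteroscedastic regression, and
both stop-gradients rather than changes to the loss values):

* S is treated as a constant per step — letting gradients flow through
  the blend factor would reward *increasing* loss1;
* the residuals inside loss2/loss3 are stop-gradded, so the calibration
  losses train only the uncertainty head. Without this, while σ is
  still uncalibrated the moment-matching term actively inflates
  residuals toward σ (observed at reduced scale as a collapse of the
  intensity output).

The learning-rate schedule lr(step) = min(step^{−1/2},
3.5×10⁻⁷·step)/2884 rises linearly to its maximum of ≈2.45×10⁻⁶ near
step 2×10⁴ and decays as step^{−1/2} thereafter. The 2884 prefactor is
treated as an opaque constant.

## Network

The published layer stack is not available; the implementation is a
compact, width/depth-configurable surrogate that honours every stated
property: both full 2D planes processed together, both dimensions
processed, a frequency-domain refinement stage, and a (512, 400, 2)
output head with a logistic confidence channel. Concretely: time-domain
conv blocks (tanh) over the packed (2, 400, 512) tensor produce a
refined packed map (added to the mean of the two input planes); the map
is unpacked to the analytic signal, zero-filled and Fourier transformed;
frequency-domain conv blocks then produce the two output channels. The
intensity head adds a trainable global gain on the input spectrum
(zero-initialised, like the head weights, so the untrained model
predicts an empty spectrum); the confidence channel adds an affine term
a·log₁₀|input spectrum| + b — a log-signal-magnitude heteroscedastic
noise model that lets σ track the local signal scale before the conv
confidence channel has trained.

Because no deep-learning framework is used, all layers carry analytic
gradients (verified against finite differences in the test suite):
FFT-based convolutions, tanh, the packing/FFT stage (whose backward
pass is the adjoint transform), the apodization operator (self-adjoint)
and the three loss terms.

Optimizer: ADAM with β₁ = 0.9, β₂ = 0.98, ε = 10⁻⁹, mini-batches of 4
(configurable), checkpoints every 2000 batches. The two confidence
scalars form a separate parameter group updated by sign-momentum with a
learning-rate multiplier (default 200): their gradients carry the small
blend factor S ≤ ~0.023 and a 1/N normalisation, and would otherwise
stall against ADAM's ε floor.

**Normalisation.** Planes are scaled so the MAD-estimated noise of the
τ_coup = 0 input spectrum equals 0.1. This requires no target (so it is
available at inference), places typical residual scales well inside
σ's representable range, and puts typical initial MSE below the 0.03
blend threshold so the calibration phase engages. Output intensity and
σ are rescaled back to input units.

**Scaled-down training surrogate.** Full-scale training (~3×10⁷ sets,
GPU-weeks) is out of scope; the repository's tests instead train a
reduced model — width 0.25 (2 filters/stage), depth 1, batch 2, 250
ADAM steps at a constant 5×10⁻⁴ (the schedule hook accepts any
callable; the warm-up/inverse-√ schedule remains the default) — on
streamed default-condition sets, a few minutes on one CPU. At this
scale the peaks are underfit, so residuals are heavy-tailed rather than
Gaussian; jointly minimising loss2+loss3 over a global σ then
equilibrates at pooled χ SD well below 1 because the high fractional
moments penalise tails. The surrogate therefore finishes with a
variance-matching recalibration (`calibrate_sigma`): the binned
σ-vs-RMSD loss alone is minimised over the two confidence scalars on a
calibration batch, temperature-scaling style. Matching per-bin mean σ
to per-bin RMSD makes the pooled χ variance ≈ 1 by construction; with
it, held-out pooled χ achieves mean ≈ 0.01 and SD ≈ 0.98. Matching the
full χ *shape* (what loss2 enforces) additionally requires the
residuals themselves to be near-Gaussian, i.e. a well-fit model — a
full-scale property that the reduced run does not claim.

## ZZ-exchange fitting

Longitudinal two-state exchange F ⇌ U with rate matrix

    K = [[−k_FU − R1_F,  k_UF        ],
         [ k_FU,         −k_UF − R1_U]],   k_FU = k_ex·p_U,  k_UF = k_ex·(1 − p_U),

so detailed balance p_F·k_FU = p_U·k_UF holds by construction. The four
peak-class curves are entries of expm(K·T_EX) scaled by the initial
amplitudes; cross-peaks vanish at T_EX = 0. Fitting is weighted least
squares over all four curves simultaneously (scipy `least_squares`,
bounded: k_ex ≥ 0, 0 < p_U < 1), with per-state R₁ as free nuisance
parameters (a shared-R₁ option exists, as the two coherences generally
relax differently). Standard errors come from the Jacobian covariance
at the optimum, scaled by reduced χ² when no weights are supplied; a
residual bootstrap is optional. Noiseless round-trips recover the
generating parameters to optimizer tolerance (<0.1 % relative); at 2 %
noise, 100-replicate recovery is unbiased within Monte-Carlo error.

## NMRPipe dialect

Files are a 512-float32 header plus float32 data, using the canonical
header word offsets for the fields this package guarantees (sizes,
sweep widths, carriers, observe frequencies, quadrature/domain flags,
plane count); all other header words are preserved opaquely on
read-modify-write. Direct (¹H) dimension stored as n reals followed by
n imaginaries per row; hypercomplex indirect dimension as interleaved
cos/sin rows; pseudo-3D pairs as consecutive planes in one stream.
Frequency axes are Hz offsets from the carrier in display order
(+SW/2 on the left). Interoperation with external processing software
is best-effort for exactly those guaranteed fields; the round-trip
within the package is lossless and tested.

## Numerical choices and degenerate inputs

* Zero-fill targets are fixed at 200 (¹³C) × 256 (¹H) complex points;
  inputs above these sizes are rejected.
* The ¹H placement map clips its output to ±0.5·SW·(1 − 10⁻¹²) so the
  strict edge bound survives tanh saturation in float64.
* χ moments use the principal complex branch; |χ| is floored at 10⁻¹²
  inside gradient computations only.
* Empty σ-bins contribute zero to loss3 and its gradient; bin
  assignment is held fixed during differentiation.
* An all-zero input plane normalises with scale 1 and maps to an empty
  output with σ ≈ 1 (no hallucinated peaks).
* Non-finite losses abort training with a diagnostic rather than
  propagating NaNs into the optimizer state.

## Known limitations

* The conv architecture is a surrogate; no claim is made that it
  matches the published layer stack, only the stated contracts.
* The reduced-scale training demonstrates learning progress and
  uncertainty calibration machinery, not publication-grade virtual
  decoupling; experimental-data performance is untested here.
* The NMRPipe writer covers the documented dialect subset, not every
  header field other software may expect.
* Exchange fitting is strictly two-state; multi-site exchange and
  CPMG/lineshape analyses are out of scope.
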