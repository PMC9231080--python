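# Methods

## Forward model

Each tablet class is a homogeneous slab whose dielectric function is a sum
of Lorentz oscillators placed at the compound's measured low-THz peaks:

    eps(f) = eps_inf + Σ_j S_j f_j² / (f_j² − f² − i g_j f)

The complex index ñ = n + iκ is the principal square root (n > 0, κ ≥ 0);
parameter sets that drive Re(eps) non-positive are rejected rather than
silently branch-switched. Because n and κ derive from one analytic
function, their peak/dispersion pairing is Kramers–Kronig consistent by
construction — the physical basis for combining the two metrics in the
classifier input.

Defaults (all overridable):

- **Oscillators**: damping g = 0.07 THz (FWHM of the ε″ Lorentzian ≈ g);
  strength chosen so each resonance peaks at α ≈ 3 mm⁻¹, via
  S = α_peak·g·√eps_inf·c/(2π f₀²). These give peak heights and widths
  comparable to published pressed-tablet spectra.
- **Broadband baseline**: α_base(f) = a₁·f² (a₁ in mm⁻¹ at 1 THz) added to
  κ, emulating the featureless scattering rise of powder tablets.
- **Per-class constants**: every class draws (eps_inf, a₁) deterministically
  from its compound family (n_inf = 1.60 + 0.015·family index,
  a₁ = 0.30 + 0.04·family index); the eight peakless classes receive an
  extra per-class increment (+0.008 in n_inf, +0.08 mm⁻¹ in a₁) so all 20
  classes are distinct in principle. Enantiomer pairs with peaks (D-/L-
  alanine) share family constants and differ only through their sub-grid
  peak split — deliberately the hard case.
- **`separable=True`**: cross-class peak clusters closer than 0.02 THz (the
  grid cannot resolve them) are spread to 0.04 THz spacing, and the
  peakless-class increments widen to +0.02 / +0.12 mm⁻¹ — inter-compound
  scale, clearly above tablet-to-tablet variation. This is the mode meant
  for classification benchmarks; the default library keeps the measured
  values and is intentionally partly degenerate.
- **Instrument**: 90 ps delay window sampled at 0.05 ps (Nyquist 10 THz),
  60 Hz acquisition rate. The reference pulse has spectral magnitude
  (f/f₀)²·exp(−(f/f₀)²) with f₀ = 1.5 THz and linear phase (pulse at
  15 ps): a single-cycle sub-ps pulse whose magnitude at 4.5 THz is below
  0.5% of its maximum, giving usable signal over the whole working band.
  Noise is white Gaussian with σ = noise_sigma_single/√n_averaged and
  noise_sigma_single = 0.02 of the peak amplitude (single-scan SNR ≈ 50).
- **Etalon**: transmission includes Fresnel entry/exit 4ñ/(ñ+1)², the
  propagation factor exp(i(ñ−1)ωd/c) referenced to air, and a truncated
  Fabry–Pérot series (default 2 echoes, round-trip spacing 2nd/c ≈ 14 ps
  for a 1.2 mm tablet).
- **Tablet variability**: thickness jitter σ = 1% of d = 1.2 mm. An
  optional per-tablet scattering-baseline spread (``baseline_jitter``,
  off by default) is available for studying compaction/grain variability
  of pressed powders; it is not part of the standard conditions.

Randomness is keyed by (seed, class, tablet, record), so any record is
reproducible in isolation.

## Extraction

Both traces are gated by a raised-cosine window around their main pulse
(5 ps before, 10 ps after, 2 ps edges). The gate excludes etalon echoes
and the long noise-only tail; it is applied *before* wavelet denoising —
thresholding first and gating second leaves a shrinkage bias that can
shift high-frequency peak positions by a grid step.

Denoising is sym4 wavelet decomposition to level 5 with soft thresholding
at the universal threshold σ√(2 ln N), σ estimated by the median absolute
deviation of the finest detail level. All detail levels are thresholded.

Traces are zero-padded to 100 ps so the frequency step is exactly
0.01 THz (the native 90 ps window would give 0.0111 THz and could not
produce a 240-point band). Phases follow the |E|e^{−iφ} convention, so a
delayed sample has positive Δφ. After 1-D unwrapping, a line is fitted to
Δφ on the 0.3–1.0 THz anchor band (high SNR, below the strong-absorption
region) and the multiple of 2π nearest the DC intercept is subtracted —
the physical branch for a dispersion-free delay.

A phase-plausibility guard rejects bins whose anchored phase deviates
from the anchor-band line by more than min(π, 0.2·ωd/c): noise at
low-SNR bins can inject spurious ±2π unwrapping cascades that corrupt
the whole high-frequency tail of n, and at low frequency even sub-π
phase noise implies unphysical index excursions because n scales as
Δφ/ω. The 0.2 cap is an upper bound on plausible index deviation from
the record's own dispersion-free trend (real dispersion wiggles here are
below 0.05). Rejected bins follow the same clamping rule as invalid
absorption bins. Then

    n(ω) = Δφ·c/(ωd) + 1,
    α(ω) = (2/d)·ln[4n/(ρ(n+1)²)]  (mm⁻¹; ×10 for cm⁻¹),

the thick-slab inversion in which a purely Fresnel-attenuated sample has
α = 0. Bins where ρ ≤ 0 or the log argument is non-positive (deep
absorption swamped by noise) are flagged and clamped to the last valid
value, preserving the 240-length contract on [0.1, 2.5) THz.

On noise-free, echo-free traces the round trip forward→extraction
recovers programmed n within 10⁻³ and α within 1% (relative) on
0.3–2.2 THz for every library class; this is the package's primary
internal oracle. At single-record average-100 noise with etalon echoes,
≈97% of programmed peak positions localize to one 0.01 THz bin and the
rest to two; per-tablet full-campaign averages localize every peak to one
bin.

## Features and datasets

The hybrid spectrum stacks (α, n) column-wise into a 240×2 matrix.
Columns are standardized (zero mean, unit variance) with statistics from
the training split only — the two metrics live on incompatible scales
(mm⁻¹ vs a dimensionless ~1.7) and the network needs comparable ranges.
The average-100 records are split 80/20 into train/validation per class;
average-20 and average-10 records form the two noisier test sets.
Input modes `absorption`/`refractive` keep a single column, enabling the
single-metric ablations. The PCA diagnostic flattens items row-major
(frequency-major) and fixes each component's sign by making its largest
loading positive.

## Network and training

Input block: 1-D convolution (32 filters, kernel 7, same padding, ReLU)
along the frequency axis; the 32 filtered signals are stacked into a
single-channel 240×32 map. Conv2 and Conv3 are 3×3 with 32 output
channels, each followed by batch normalization, ReLU, and 2×2 max
pooling; Conv4 is 1×1 to 64 channels (BN, ReLU, no pooling). The ECA
module global-average-pools the channels, applies a learned k-tap
cross-channel convolution with k = |log₂(C)/γ + b/γ|_odd (γ = 2, b = 1 →
k = 3 at C = 64; nearest odd, ties up, floor 1), a sigmoid, and channel-
wise rescaling. `use_eca=False` skips the module (plain-CNN ablation).
Dense layers 256 → 128 → n_classes with softmax close the model
(≈7.9 M parameters; kernel and pooling sizes are the smallest standard
choices, since only the depth and channel counts are pinned).

Everything, including gradients, is NumPy float32; convolutions are
im2col matrix products in channels-last layout, and the
memory-bandwidth-bound steps (batch-norm backward, 2×2 pooling, the
SGD update) are fused single-pass numba kernels. Backpropagation is
verified against finite differences in double precision.

Training: SGD with Nesterov momentum 0.9, initial lr 10⁻³, per-update
decay lr_t = lr₀/(1 + 10⁻⁵·t) (the usual convention for a "decay"
hyperparameter), batch 128, cross-entropy, early stopping on validation
loss with patience 30 over 300 epochs, then 100 fine-tuning epochs at
10⁻⁴ from the best-validation weights. The *reduced* schedule used by the
demo and the test-suite benchmarks scales this to 30 + 10 epochs with
batch 16 and patience 3 (the same 10% patience-to-epochs ratio).

## Desk-scale problem sizes

The statistical benchmarks run the full pipeline at reduced size, chosen
as the package's standard desk-scale configuration: 20 classes × 5
tablets with the record count capped per tablet and average group, an
80/20 train/validation split of the average-100 group, and the reduced
training schedule. The five-seed ablation sweep ({hybrid, absorption,
refractive} × ECA plus the plain CNN) uses 1 record per tablet (100 per
average group); the single headline model and the demo use 3 (300 per
group). These sizes trade statistical margin against single-CPU
wall-clock and are stated here as the package's standard benchmark
conditions.

## What the generator does and does not emulate

Emulated: class-specific resonances with Kramers–Kronig-paired dispersion,
averaging-dependent white noise (1/√N), etalon echoes and their
frequency-domain ripple, tablet thickness and scattering variability,
the acquisition layout (2400 raw signals/tablet; 24 avg-100 records),
and the loss of α fidelity in deep-absorption/low-SNR regions.

Not emulated: humidity lines, temperature effects, delay-line drift with
colored spectra, scattering with frequency-dependent structure, detector
nonlinearity, and the rich multi-mode baseline variability of real
campaigns. Consequently, passing benchmarks here demonstrate correctness
of the chain and qualitative reproduction of the method's behavior, not
field performance. One knock-on effect: with so low-rank a nuisance
subspace, per-tablet synthetic spectra are much more reproducible than
real ones, so a first-principal-component embedding of the hybrid
spectrum does not dominate single-metric PC1–PC2 embeddings on the
4-class PCA diagnostic the way it does on real data, where leading
single-metric variance is nuisance-dominated. Enabling the optional
scattering-baseline spread moves the absorption embedding toward the
real-data behavior (its silhouette drops from ≈0.95 to ≈0.5 at a 15%
spread) but does not reverse the comparison.

## Numerical choices and degenerate inputs

- Speed of light fixed at 0.299792458 mm/ps; frequencies in THz, times in
  ps, lengths in mm.
- The f = 0 bin is excluded from the index formula (copied from its
  neighbor); band cropping removes it anyway.
- Band convention is half-open [0.1, 2.5): the only convention giving 240
  points at 0.01 THz.
- Argmax ties in prediction resolve to the lowest class index; max-pooling
  ties route gradients to the first element.
- Empty oscillator lists are legal (featureless classes); empty traces,
  non-uniform time axes, even attention kernels, and out-of-range labels
  raise immediately.

## Known limitations

- The network parameter count (≈7.9 M) exceeds the compact original's
  because unstated kernel/pooling sizes were filled with standard
  choices; no claim of parameter parity is made.
- Per-class scores use the printed row-normalized form (recall-like)
  under the name "precision", as in the source material for this metric
  pair.
- fps/throughput numbers are informational only and excluded from any
  assertion (hardware-dependent).
- The noise model is white and Gaussian; delay-line vibration in real
  instruments is colored.
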