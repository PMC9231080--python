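# thzamino

Terahertz time-domain spectroscopy (THz-TDS) identifies crystalline
biomolecules by their low-THz vibrational fingerprints. This package
implements, end to end, a classification chain for pressed amino-acid
tablets measured in transmission:

1. **Forward model** — each of 20 amino-acid classes is a Lorentz-oscillator
   dielectric, `eps(f) = eps_inf + Σ_j S_j f_j² / (f_j² − f² − i g_j f)`,
   with oscillators at the compounds' measured absorption peaks. A
   band-limited single-cycle pulse is transmitted through the slab
   (Fresnel factors, propagation phase, absorption, Fabry–Pérot echoes)
   and rendered as time traces with averaging-dependent white noise —
   a physics-based stand-in for a 90 ps / 60 Hz fiber-coupled spectrometer.
2. **Extraction** — traces are gated around the main pulse, denoised by
   sym4/level-5 wavelet shrinkage, zero-padded to 100 ps, and Fourier
   transformed. From the transfer function `T(ω) = ρ(ω) e^{−iΔφ(ω)}`:

       n(ω) = Δφ(ω)·c/(ω d) + 1
       α(ω) = (2/d)·ln[ 4n / (ρ (n+1)²) ]      [mm⁻¹]

   cropped to the 0.1–2.5 THz band — 240 points at 0.01 THz.
3. **Hybrid features** — absorption rate and refractive index are stacked
   into a standardized 240×2 "hybrid spectrum"; the two metrics are
   Kramers–Kronig partners, so every resonance is seen twice.
4. **ECA-CNN classifier** — a compact CNN written from scratch in NumPy:
   a 32-filter 1-D convolution whose outputs are stacked into a 240×32
   feature map, two 3×3 convolutions with batch norm and 2×2 max pooling,
   a 1×1 convolution to 64 channels, an efficient-channel-attention (ECA)
   module whose cross-channel kernel size adapts as
   `k = |log₂(C)/γ + b/γ|_odd` (k = 3 at C = 64), and dense layers
   256→128→20 with softmax. Trained with SGD (Nesterov momentum 0.9,
   lr 10⁻³ with 10⁻⁵ decay, batch 128, early stopping, 10⁻⁴ fine-tuning).
5. **Evaluation** — accuracy `Acc = Σᵢ n_ii / Σᵢⱼ n_ij` and per-class score
   `Pr_i = n_ii / Σⱼ n_ij` from the confusion matrix.

## Worked example

```python
import numpy as np, thzamino as tz

instr = tz.InstrumentSpec(noise_sigma_single=0.0)
lib = tz.build_material_library()
glu = next(m for m in lib if m.name == "D-Glutamic acid")

ref = tz.simulate_reference(instr)
trace = tz.simulate_sample_trace(glu, instr, n_echoes=0)
oc = tz.extract_optical_constants(trace, ref, glu.thickness_d)

print(oc.f.size)                                 # 240
i = np.argmin(abs(oc.f - 1.22))
print(round(oc.f[i], 2), round(oc.n[i], 3), round(oc.alpha[i], 2))
```

prints

```
240
1.22 1.642 3.6
```

i.e. the extracted spectrum has the 240-point band contract, and at the
programmed 1.216 THz resonance of D-glutamic acid the absorption rate
peaks (≈3.6 mm⁻¹, resonance on top of the broadband baseline) while the
refractive index traverses its anomalous dispersion around the class's
base index of ≈1.65. On noise-free traces
the extraction recovers the programmed n to better than 10⁻³ and α to
better than 1% across 0.3–2.2 THz for every library class.

The end-to-end scaled demo (simulate → extract → train → evaluate, with
the single-metric ablations) runs as

```sh
thzamino demo --seed 1 --out runs/demo
```

and prints per-input-mode accuracies on the noisier average-20/average-10
test sets plus a per-class score table. `thzamino simulate / extract /
train / evaluate` expose the individual stages.

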