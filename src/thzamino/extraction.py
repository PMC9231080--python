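"""Optical-constant extraction from (sample, reference) trace pairs.

The chain is the standard transmission THz-TDS inversion for an optically
thick slab: Fourier transform both traces (zero-padded to 100 ps so the
frequency step is exactly 0.01 THz), form the transfer function
T(w) = rho(w) exp(-i dphi(w)), unwrap and anchor the phase, then

    n(w)     = dphi(w) * c / (w d) + 1
    alpha(w) = (2/d) * ln[ 4 n / (rho (n+1)^2) ]

so that a sample attenuating only by Fresnel reflection (rho = 4n/(n+1)^2)
has zero absorption.  The band is cropped to [0.1, 2.5) THz — 240 points at
the 0.01 THz step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from thzamino.forward_model import C_MM_PS, TimeTrace

__all__ = [
    "ComplexSpectrum",
    "TransferFunction",
    "OpticalConstants",
    "fourier_spectrum",
    "transfer_function",
    "unwrap_and_anchor_phase",
    "refractive_index",
    "absorption_rate",
    "crop_band",
    "extract_optical_constants",
    "write_optical_constants",
    "read_optical_constants",
]


@dataclass
class ComplexSpectrum:
    """One-sided spectrum in the |E| exp(-i phi) convention: a delayed pulse
    has a positive, linearly increasing phase."""

    f: np.ndarray
    amp: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.amp < 0):
            raise ValueError("amplitude must be non-negative")
        df = np.diff(self.f)
        if np.any(df <= 0) or not np.allclose(df, df[0], rtol=1e-9):
            raise ValueError("frequency axis must be ascending and uniform")


@dataclass
class TransferFunction:
    f: np.ndarray
    rho: np.ndarray
    dphi: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.f.shape, dtype=bool)


@dataclass
class OpticalConstants:
    """Refractive index and absorption rate (1/mm) on a frequency grid (THz)."""

    f: np.ndarray
    n: np.ndarray
    alpha: np.ndarray
    d: float

    @property
    def alpha_per_cm(self) -> np.ndarray:
        return self.alpha * 10.0


def window_main_pulse(
    trace: TimeTrace,
    t_before: float = 5.0,
    t_after: float = 10.0,
    edge: float = 2.0,
) -> TimeTrace:
    """Gate the trace around its main pulse with raised-cosine edges.

    Standard THz-TDS practice for suppressing Fabry-Perot echoes (the first
    echo of a ~1.2 mm tablet arrives ~14 ps after the main pulse) and late
    delay-line noise before the transform.  The gate is 1 on
    ``[t_peak - t_before, t_peak + t_after]`` and rolls off to 0 over
    ``edge`` ps on both sides.
    """
    i_pk = int(np.argmax(np.abs(trace.amplitude)))
    t = trace.t - trace.t[i_pk]
    win = np.zeros_like(t)
    flat = (t >= -t_before) & (t <= t_after)
    win[flat] = 1.0
    lead = (t < -t_before) & (t >= -t_before - edge)
    win[lead] = 0.5 * (1.0 + np.cos(np.pi * (-t[lead] - t_before) / edge))
    tail = (t > t_after) & (t <= t_after + edge)
    win[tail] = 0.5 * (1.0 + np.cos(np.pi * (t[tail] - t_after) / edge))
    return replace(trace, amplitude=trace.amplitude * win)


def fourier_spectrum(trace: TimeTrace, pad_to_ps: float = 100.0) -> ComplexSpectrum:
    """Zero-padded real FFT of a trace; frequency step = 1/pad_to_ps THz."""
    dt = trace.dt
    duration = trace.t[-1] - trace.t[0] + dt
    if pad_to_ps < duration - 1e-9:
        raise ValueError(
            f"pad_to_ps={pad_to_ps} shorter than trace duration {duration:.3f} ps"
        )
    n_fft = round(pad_to_ps / dt)
    spec = np.fft.rfft(trace.amplitude, n_fft)
    f = np.fft.rfftfreq(n_fft, dt)
    # exp(-i phi) convention of the slab inversion: phi = -angle of the
    # numpy transform, so a delay t0 gives phi = +w t0.
    return ComplexSpectrum(f=f, amp=np.abs(spec), phase=-np.angle(spec))


def transfer_function(
    sample: ComplexSpectrum, ref: ComplexSpectrum
) -> TransferFunction:
    """Amplitude ratio and (wrapped) phase change, positive for a delayed sample."""
    if sample.f.shape != ref.f.shape or not np.allclose(sample.f, ref.f):
        raise ValueError("sample and reference must share one frequency grid")
    valid = ref.amp > 0
    rho = np.divide(sample.amp, ref.amp, out=np.zeros_like(sample.amp), where=valid)
    dphi = sample.phase - ref.phase
    return TransferFunction(f=ref.f.copy(), rho=rho, dphi=dphi, valid=valid)


def unwrap_and_anchor_phase(
    tf: TransferFunction,
    anchor_band: tuple[float, float] = (0.3, 1.0),
    residual_threshold: float = 0.5,
) -> TransferFunction:
    """Unwrap dphi along frequency and remove the 2*pi branch ambiguity.

    A line is fitted to the unwrapped phase on the high-SNR ``anchor_band``;
    the multiple of 2*pi nearest to its DC intercept is subtracted, so the
    extrapolated intercept is minimal in magnitude — the physical branch for
    a dispersion-free delay.  A large fit residual triggers a low-SNR
    warning.
    """
    lo, hi = anchor_band
    sel = (tf.f >= lo) & (tf.f <= hi)
    if not np.any(sel):
        raise ValueError("anchor band outside the frequency grid")
    dphi = np.unwrap(tf.dphi)
    slope, intercept = np.polyfit(tf.f[sel], dphi[sel], 1)
    residual = float(
        np.sqrt(np.mean((dphi[sel] - (slope * tf.f[sel] + intercept)) ** 2))
    )
    if residual > residual_threshold:
        warnings.warn(
            f"phase anchor fit residual {residual:.2f} rad: low SNR in the "
            f"anchor band {anchor_band}",
            stacklevel=2,
        )
    dphi = dphi - 2.0 * np.pi * np.round(intercept / (2.0 * np.pi))
    return replace(tf, dphi=dphi)


def refractive_index(tf: TransferFunction, d: float) -> np.ndarray:
    """n(f) = dphi * c / (w d) + 1 with w = 2 pi f; the f = 0 bin is excluded
    (copied from its neighbor so array length is preserved)."""
    if not d > 0:
        raise ValueError("thickness must be > 0 mm")
    omega = 2.0 * np.pi * tf.f  # rad/ps
    with np.errstate(divide="ignore", invalid="ignore"):
        n = tf.dphi * C_MM_PS / (omega * d) + 1.0
    zero = tf.f == 0
    if np.any(zero) and n.size > 1:
        n[zero] = n[np.argmin(zero)]
    return n


def absorption_rate(
    tf: TransferFunction, n: np.ndarray, d: float
) -> tuple[np.ndarray, np.ndarray]:
    """alpha(f) = (2/d) ln[4n / (rho (n+1)^2)] in 1/mm.

    Returns ``(alpha, valid)``: bins where rho <= 0 or the logarithm argument
    is non-positive are flagged invalid (alpha set to NaN there).
    """
    if not d > 0:
        raise ValueError("thickness must be > 0 mm")
    valid = (tf.rho > 0) & (n > 0) & np.asarray(tf.valid, dtype=bool)
    arg = np.full(n.shape, np.nan)
    np.divide(4.0 * n, tf.rho * (n + 1.0) ** 2, out=arg, where=valid)
    valid &= arg > 0
    alpha = np.full(n.shape, np.nan)
    np.log(arg, out=alpha, where=valid)
    alpha *= 2.0 / d
    alpha[~valid] = np.nan
    return alpha, valid


def _forward_fill(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace invalid entries with the last valid value (first valid at the start)."""
    out = values.copy()
    if not np.any(valid):
        raise ValueError("no valid bins to fill from")
    idx = np.where(valid, np.arange(values.size), -1)
    idx = np.maximum.accumulate(idx)
    first = np.argmax(valid)
    idx[idx < 0] = first
    return out[idx]


def crop_band(
    oc: OpticalConstants,
    f_lo: float = 0.1,
    f_hi: float = 2.5,
    step: float = 0.01,
) -> OpticalConstants:
    """Keep bins on the half-open band [f_lo, f_hi); defaults give 240 points."""
    if not f_hi > f_lo:
        raise ValueError("band must satisfy f_hi > f_lo")
    df = np.diff(oc.f)
    if not np.allclose(df, step, rtol=0, atol=1e-9):
        raise ValueError(
            f"grid step {df[0]:.6g} THz does not match the required {step} THz; "
            "zero-pad the traces so that 1/pad_to_ps equals the step"
        )
    sel = (oc.f >= f_lo - 1e-9) & (oc.f < f_hi - 1e-9)
    if not np.any(sel):
        raise ValueError("empty band after cropping")
    return OpticalConstants(
        f=oc.f[sel].copy(), n=oc.n[sel].copy(), alpha=oc.alpha[sel].copy(), d=oc.d
    )


def extract_optical_constants(
    sample: TimeTrace,
    ref: TimeTrace,
    d: float,
    *,
    pad_to_ps: float = 100.0,
    anchor_band: tuple[float, float] = (0.3, 1.0),
    f_lo: float = 0.1,
    f_hi: float = 2.5,
    window: tuple[float, float] | None = None,
) -> OpticalConstants:
    """Full inversion pipeline for one trace pair, cropped to the working band.

    ``window=(t_before, t_after)`` gates each trace around its main pulse
    (see :func:`window_main_pulse`) to suppress etalon echoes.  Invalid
    deep-absorption bins (rho or log-argument non-positive) are clamped to
    the last valid value so the band-length contract holds.
    """
    if window is not None:
        sample = window_main_pulse(sample, *window)
        ref = window_main_pulse(ref, *window)
    spec_s = fourier_spectrum(sample, pad_to_ps)
    spec_r = fourier_spectrum(ref, pad_to_ps)
    tf = unwrap_and_anchor_phase(
        transfer_function(spec_s, spec_r), anchor_band=anchor_band
    )
    # phase-plausibility guard: noise at low-SNR bins can inject spurious
    # +-2*pi unwrapping cascades, and at low frequency even sub-pi phase
    # noise implies unphysical index excursions (n scales as dphi/omega).
    # Accept bins within the smaller of pi and 0.2 index units of the
    # anchor-band line; dispersion wiggles stay well inside both bounds.
    sel_anchor = (tf.f >= anchor_band[0]) & (tf.f <= anchor_band[1])
    slope, intercept = np.polyfit(tf.f[sel_anchor], tf.dphi[sel_anchor], 1)
    bound = np.minimum(np.pi, 0.2 * (2.0 * np.pi * tf.f) * d / C_MM_PS)
    phase_ok = np.abs(tf.dphi - (slope * tf.f + intercept)) <= bound
    n = refractive_index(tf, d)
    alpha, valid = absorption_rate(tf, n, d)
    valid &= phase_ok
    step = round(1.0 / pad_to_ps, 12)
    oc = crop_band(
        OpticalConstants(f=tf.f, n=n, alpha=alpha, d=d), f_lo=f_lo, f_hi=f_hi, step=step
    )
    sel = (tf.f >= f_lo - 1e-9) & (tf.f < f_hi - 1e-9)
    band_valid = valid[sel]
    oc.alpha = _forward_fill(oc.alpha, band_valid & np.isfinite(oc.alpha))
    oc.n = _forward_fill(oc.n, phase_ok[sel] & np.isfinite(oc.n))
    return oc


def write_optical_constants(path, oc: OpticalConstants, provenance: str = "") -> None:
    header = f"d_mm={oc.d}"
    if provenance:
        header += f"\nprovenance={provenance}"
    header += "\nf_THz n alpha_per_mm"
    np.savetxt(path, np.column_stack([oc.f, oc.n, oc.alpha]), header=header)


def read_optical_constants(path) -> OpticalConstants:
    d = np.nan
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            text = line.lstrip("# ").strip()
            if text.startswith("d_mm="):
                d = float(text.split("=", 1)[1])
    data = np.loadtxt(path)
    return OpticalConstants(f=data[:, 0], n=data[:, 1], alpha=data[:, 2], d=d)
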