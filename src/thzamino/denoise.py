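"""Wavelet-shrinkage denoising and trace averaging.

Traces are decomposed with a sym4 wavelet to level 5; detail coefficients
below the universal threshold sigma*sqrt(2 ln N) are soft-thresholded
(sigma estimated from the median absolute deviation of the finest detail
level) and the signal is reconstructed to its original length.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pywt

__all__ = ["DenoiseConfig", "wavelet_denoise", "average_traces"]


@dataclass(frozen=True)
class DenoiseConfig:
    wavelet_name: str = "sym4"
    level: int = 5
    threshold_rule: str = "universal"
    threshold_mode: str = "soft"

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("decomposition level must be >= 1")
        if self.threshold_rule != "universal":
            raise ValueError(f"unknown threshold rule {self.threshold_rule!r}")
        if self.threshold_mode not in ("soft", "hard"):
            raise ValueError(f"unknown threshold mode {self.threshold_mode!r}")


def wavelet_denoise(trace, cfg: DenoiseConfig = DenoiseConfig(), threshold: float | None = None):
    """Shrink wavelet detail coefficients and reconstruct.

    ``threshold`` overrides the universal threshold (0 forces perfect
    reconstruction).  Length and time axis are preserved.
    """
    x = trace.amplitude
    wavelet = pywt.Wavelet(cfg.wavelet_name)
    max_level = pywt.dwt_max_level(x.size, wavelet.dec_len)
    if cfg.level > max_level:
        raise ValueError(
            f"level {cfg.level} infeasible for a length-{x.size} trace; "
            f"maximum feasible level is {max_level}"
        )
    coeffs = pywt.wavedec(x, wavelet, level=cfg.level)
    if threshold is None:
        finest = coeffs[-1]
        sigma = np.median(np.abs(finest - np.median(finest))) / 0.6745
        threshold = sigma * np.sqrt(2.0 * np.log(x.size))
    details = [
        pywt.threshold(c, threshold, mode=cfg.threshold_mode) if threshold > 0 else c
        for c in coeffs[1:]
    ]
    rec = pywt.waverec([coeffs[0], *details], wavelet)
    return replace(trace, amplitude=rec[: x.size].copy())


def average_traces(traces):
    """Pointwise mean of traces sharing one time axis and label;
    ``n_averaged`` accumulates."""
    traces = list(traces)
    if not traces:
        raise ValueError("no traces to average")
    first = traces[0]
    for tr in traces[1:]:
        if tr.t.shape != first.t.shape or not np.allclose(tr.t, first.t):
            raise ValueError("traces must share one time axis")
        if tr.label != first.label:
            raise ValueError("traces must share one label")
    amp = np.mean([tr.amplitude for tr in traces], axis=0)
    return replace(
        first,
        amplitude=amp,
        n_averaged=int(sum(tr.n_averaged for tr in traces)),
    )
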