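"""Shared FIR filter primitives for the recording pipeline.

The high-pass follows a least-squares linear-phase design of order
1.5 x sampling rate with band edges 0.85/SR and 1/SR of Nyquist (a ~0.5 Hz
cutoff at 512 Hz); the visualisation/testing low-pass is a 20 Hz windowed
FIR.  Both are applied forward-backward, i.e. the effective kernel is the
filter convolved with its own reverse, making the net response zero-phase
with squared magnitude.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = ["design_highpass", "design_lowpass20", "zero_phase_fir"]


def design_highpass(sfreq: float) -> np.ndarray:
    order = int(round(1.5 * sfreq))
    if order % 2:
        order += 1  # least-squares design needs an odd symmetric tap count
    return signal.firls(order + 1, [0.0, 0.85 / sfreq, 1.0 / sfreq, 1.0],
                        [0.0, 0.0, 1.0, 1.0], fs=2.0)


def design_lowpass20(sfreq: float, numtaps: int = 257) -> np.ndarray:
    return signal.firwin(numtaps, 20.0, fs=sfreq)


def zero_phase_fir(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Forward-backward FIR via FFT convolution with reflected edge padding."""
    data = np.asarray(data, float)
    n = data.shape[-1]
    pad = min(3 * len(taps), n - 1)
    ext = np.concatenate(
        [data[..., 1:pad + 1][..., ::-1], data, data[..., -pad - 1:-1][..., ::-1]],
        axis=-1,
    )
    h2 = np.convolve(taps, taps[::-1])
    kernel = h2.reshape((1,) * (data.ndim - 1) + (-1,))
    out = signal.fftconvolve(ext, kernel, mode="same", axes=-1)
    return out[..., pad:pad + n]
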