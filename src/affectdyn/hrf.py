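"""Canonical haemodynamic response function and event convolution.

The double-gamma kernel (response peak at 6 s, undershoot peaking at 16 s,
peak-to-undershoot ratio 6) is the standard choice for event-related BOLD
modelling.  All convolution in this package happens at volume resolution:
with a 2 s repetition time and 2 s stimuli, sub-TR microtime modelling buys
nothing at the scales we work at.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["double_gamma_hrf", "convolve_amplitudes", "boxcar"]

#: total support of the kernel, seconds
HRF_DURATION_S = 32.0


def double_gamma_hrf(tr: float, duration_s: float = HRF_DURATION_S) -> np.ndarray:
    """Sample the canonical double-gamma HRF at volume times.

    Parameters
    ----------
    tr
        Repetition time in seconds; the kernel is sampled at ``t = i * tr``.
    duration_s
        Kernel support in seconds (default 32 s).

    Returns
    -------
    1-D array, peak-normalized so that ``max(h) == 1``.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, duration_s + 0.5 * tr, tr)
    peak = stats.gamma.pdf(t, a=6.0, scale=1.0)
    undershoot = stats.gamma.pdf(t, a=16.0, scale=1.0)
    h = peak - undershoot / 6.0
    return h / h.max()


def boxcar(onset: float, duration: float, n_volumes: int, tr: float) -> np.ndarray:
    """Volume-resolution indicator of a stimulus interval.

    Volume ``i`` (acquired at ``t = i * tr``, 0-based) is covered iff
    ``onset <= i * tr < onset + duration``.
    """
    t = np.arange(n_volumes) * tr
    return ((t >= onset) & (t < onset + duration)).astype(float)


def convolve_amplitudes(amplitudes: np.ndarray, tr: float) -> np.ndarray:
    """Convolve a volume-sampled neural amplitude time course with the HRF.

    The output is truncated to the input length (causal convolution).
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    h = double_gamma_hrf(tr)
    return np.convolve(amplitudes, h)[: amplitudes.shape[0]]
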