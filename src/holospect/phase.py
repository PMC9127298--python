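"""Direct-quadrature phase and instantaneous frequency.

The phase of an intrinsic mode is estimated without a Hilbert transform:
the mode is normalised by its envelope, F(t) = c(t)/a(t) in [-1, 1], and the
quadrature is reconstructed analytically as ±sqrt(1 - F²) with the sign
taken from the direction of travel of F.  This avoids the FFT edge bias of
the Hilbert transform, which matters for instantaneous-frequency work on
short epochs.
"""

from __future__ import annotations

import numpy as np

_ENVELOPE_FLOOR = 1e-12


def dq_phase(imf_c: np.ndarray, imf_a: np.ndarray) -> np.ndarray:
    """Unwrapped direct-quadrature phase (radians) of a mode c with envelope a.

    Samples where the envelope is (numerically) zero are masked as NaN.
    |c/a| values that exceed 1 by numerical error are clipped.
    """
    c = np.asarray(imf_c, dtype=float)
    a = np.asarray(imf_a, dtype=float)
    if c.shape != a.shape:
        raise ValueError("mode and envelope must have the same shape")
    dead = a <= _ENVELOPE_FLOOR * max(float(np.max(a, initial=0.0)), 1.0)
    F = np.clip(c / np.where(dead, 1.0, a), -1.0, 1.0)

    # sign of the quadrature: cosθ decreasing <=> sinθ > 0 (θ increasing)
    s = np.sign(-np.gradient(F))
    # carry the last non-zero sign across flat samples (extrema of F)
    nz = s != 0
    if nz.any():
        idx = np.where(nz, np.arange(len(s)), 0)
        np.maximum.accumulate(idx, out=idx)
        filled = s[idx]
        filled[: np.argmax(nz)] = s[nz][0]  # backfill before first non-zero
        s = filled
    else:
        s = np.ones_like(F)

    q = s * np.sqrt(np.maximum(1.0 - F * F, 0.0))
    theta = np.unwrap(np.arctan2(q, F))
    theta[dead] = np.nan
    return theta


def inst_freq(theta: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Instantaneous frequency (Hz) as the central-difference phase derivative.

    Negative estimates (unphysical, occasionally produced near envelope
    minima) are masked as NaN rather than clamped.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.size < 3:
        raise ValueError("phase series must have at least 3 samples")
    f = np.gradient(theta) * (sampling_rate / (2.0 * np.pi))
    f[~np.isfinite(f)] = np.nan
    f[f < 0] = np.nan
    return f
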