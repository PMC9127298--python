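"""Empirical mode decomposition: sifting, plain EMD, improved CEEMDAN.

The two-layer decomposition at the heart of the package: a signal is
decomposed into intrinsic mode functions (IMFs) c_j(t) = a_j(t) cos θ_j(t),
and each amplitude function a_j(t) is decomposed again into rhythmic
amplitude modulations a_jk(t) cos Θ_jk(t) plus an unmodulated trend.  The
ensemble variant is the improved complete-ensemble EMD with adaptive noise:
stage-matched modes of stored white-noise realisations are added before
extracting each local mean, which reduces mode mixing and keeps the
reconstruction error at the averaging level rather than the noise level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from holospect.phase import dq_phase, inst_freq

# ------------------------------------------------------------------ config


@dataclass(frozen=True)
class EMDConfig:
    """Parameters of the (ensemble) decomposition.

    ``noise_ratio`` is the added-noise amplitude as a fraction of the
    current residue's SD; ``sift_stop`` is the S-number (extrema and
    zero-crossing counts unchanged for S consecutive sifts).
    """

    ensemble_size: int = 50
    noise_ratio: float = 0.2
    max_imfs: int | None = None  # default: ceil(log2 N)
    sift_stop: int = 4
    max_sift_iters: int = 50
    seed: int = 0
    sampling_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if not 0.0 < self.noise_ratio < 1.0:
            raise ValueError("noise_ratio must lie in (0, 1)")
        if self.max_imfs is not None and self.max_imfs < 1:
            raise ValueError("max_imfs must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    def imf_cap(self, n_samples: int) -> int:
        cap = int(np.ceil(np.log2(max(n_samples, 2))))
        return cap if self.max_imfs is None else min(self.max_imfs, cap)


# ------------------------------------------------------------- primitives


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateau midpoints)."""
    d = np.diff(x)
    # collapse flat segments: zero slopes carry the previous non-zero sign
    s = np.sign(d)
    zero = s == 0
    if zero.any():
        idx = np.where(~zero, np.arange(len(s)), 0)
        np.maximum.accumulate(idx, out=idx)
        s = s[idx]
    ds = np.diff(s)
    maxima = np.where(ds < 0)[0] + 1
    minima = np.where(ds > 0)[0] + 1
    return maxima, minima


def count_zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    return int(np.sum(s[1:] != s[:-1]))


def _mirror_extend(idx: np.ndarray, val: np.ndarray, n: int, n_mirror: int = 2):
    """Reflect up to ``n_mirror`` extrema about each boundary sample."""
    left_i = 2 * 0 - idx[:n_mirror][::-1]
    left_v = val[:n_mirror][::-1]
    right_i = 2 * (n - 1) - idx[-n_mirror:][::-1]
    right_v = val[-n_mirror:][::-1]
    xs = np.concatenate([left_i, idx, right_i]).astype(float)
    vs = np.concatenate([left_v, val, right_v])
    order = np.argsort(xs, kind="stable")
    xs, vs = xs[order], vs[order]
    keep = np.concatenate([[True], np.diff(xs) > 0])
    return xs[keep], vs[keep]


def _spline_through(idx: np.ndarray, val: np.ndarray, n: int) -> np.ndarray:
    xs, vs = _mirror_extend(idx, val, n)
    if len(xs) < 2:
        return np.full(n, vs[0] if len(vs) else 0.0)
    if len(xs) < 4:
        return np.interp(np.arange(n), xs, vs)
    return CubicSpline(xs, vs, bc_type="natural")(np.arange(n))


def envelope_mean(x: np.ndarray) -> np.ndarray | None:
    """Mean of the upper/lower cubic-spline envelopes; None if < 4 extrema."""
    maxima, minima = find_extrema(x)
    if len(maxima) + len(minima) < 4 or len(maxima) < 2 or len(minima) < 2:
        return None
    n = len(x)
    upper = _spline_through(maxima, x[maxima], n)
    lower = _spline_through(minima, x[minima], n)
    return 0.5 * (upper + lower)


def _abs_envelope(h: np.ndarray) -> np.ndarray:
    """Positive cubic-spline envelope through the maxima of |h|."""
    ah = np.abs(h)
    maxima, _ = find_extrema(ah)
    n = len(h)
    if len(maxima) < 2:
        peak = float(np.max(ah, initial=0.0))
        return np.full(n, peak if peak > 0 else 1e-12)
    env = _spline_through(maxima, ah[maxima], n)
    floor = 1e-10 * max(float(np.max(ah)), 1e-30)
    return np.maximum(env, floor)


def amplitude_envelope(c: np.ndarray) -> np.ndarray:
    """Amplitude function a(t): spline envelope of |c|, floored at |c|.

    The cubic-spline envelope through the maxima of |c| can locally
    undershoot the mode; tying the amplitude to |c| at those samples keeps
    the normalised carrier F = c/a inside [-1, 1], so the envelope-phase
    representation a cos θ reproduces the mode exactly — the property the
    nested spectral reconstruction relies on.
    """
    x = np.asarray(c, dtype=float)
    return np.maximum(_abs_envelope(x), np.abs(x))


# ----------------------------------------------------------------- sifting


def sift(
    signal: np.ndarray,
    s_number: int = 4,
    max_iters: int = 50,
) -> tuple[np.ndarray | None, np.ndarray]:
    """Extract one IMF candidate by iterative envelope-mean subtraction.

    Stops when the extrema/zero-crossing counts differ by at most one and
    have been unchanged for ``s_number`` consecutive sifts, or after
    ``max_iters``.  Returns (imf, remainder); if the signal has too few
    extrema to sift it is a monotone-like residue and (None, signal) is
    returned.
    """
    h = np.asarray(signal, dtype=float).copy()
    m = envelope_mean(h)
    if m is None:
        return None, h
    stable = 0
    prev_counts: tuple[int, int] | None = None
    best: np.ndarray | None = None
    stopped = False
    for _ in range(max_iters):
        h = h - m
        maxima, minima = find_extrema(h)
        n_ext = len(maxima) + len(minima)
        n_zc = count_zero_crossings(h)
        counts = (n_ext, n_zc)
        if abs(n_ext - n_zc) <= 1:
            best = h.copy()
            stable = stable + 1 if counts == prev_counts else 1
            if stable >= s_number:
                stopped = True
                break
        else:
            stable = 0
        prev_counts = counts
        m = envelope_mean(h)
        if m is None:
            break
    # If the S-number stability was never reached, fall back to the last
    # iterate that satisfied the extrema/zero-crossing property so the
    # returned candidate is a valid IMF whenever one was seen.
    if not stopped and best is not None:
        h = best
    return h, np.asarray(signal, dtype=float) - h


def _emd_modes(
    x: np.ndarray, max_imfs: int, s_number: int = 4, max_iters: int = 50
) -> tuple[list[np.ndarray], np.ndarray]:
    """Plain EMD returning raw modes and the residue (exact by telescoping)."""
    modes: list[np.ndarray] = []
    residue = np.asarray(x, dtype=float).copy()
    for _ in range(max_imfs):
        imf, remainder = sift(residue, s_number=s_number, max_iters=max_iters)
        if imf is None:
            break
        modes.append(imf)
        residue = remainder
    return modes, residue


def _local_mean(x: np.ndarray, s_number: int, max_iters: int) -> np.ndarray:
    """M(x) = x minus its first EMD mode; x itself if it cannot be sifted."""
    imf, remainder = sift(x, s_number=s_number, max_iters=max_iters)
    return x if imf is None else remainder


# ------------------------------------------------------------ public types


@dataclass
class FirstLayerIMF:
    """One first-layer mode c_j with envelope, phase and carrier frequency."""

    c: np.ndarray
    a: np.ndarray
    theta: np.ndarray
    inst_freq: np.ndarray  # Hz; NaN where masked


@dataclass
class FirstLayerDecomposition:
    imfs: list[FirstLayerIMF]
    residue: np.ndarray
    sampling_rate: float

    @property
    def n(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf.c
        return out


@dataclass
class SecondLayerIMF:
    """One rhythmic amplitude modulation of a first-layer envelope."""

    c2: np.ndarray  # the raw second-layer mode
    a2: np.ndarray  # its envelope a_jk
    Theta2: np.ndarray  # its phase
    am_freq: np.ndarray  # Hz; NaN where masked


@dataclass
class SecondLayerDecomposition:
    parent_imf_index: int
    imfs2: list[SecondLayerIMF]
    residue2: np.ndarray

    @property
    def l2(self) -> int:
        return len(self.imfs2)

    def reconstruct(self) -> np.ndarray:
        out = self.residue2.copy()
        for imf in self.imfs2:
            out += imf.c2
        return out


@dataclass
class TwoLayerDecomposition:
    first: FirstLayerDecomposition
    second: list[SecondLayerDecomposition]
    sampling_rate: float

    def nested_reconstruction(self) -> np.ndarray:
        """Σ_j [Σ_k a_jk cos Θ_jk + R_jl2] cos θ_j + r_n.

        Approximate: both layers replace modes by their envelope-phase
        representation a cos θ.
        """
        out = self.first.residue.copy()
        for imf1, dec2 in zip(self.first.imfs, self.second):
            env = dec2.residue2.copy()
            for imf2 in dec2.imfs2:
                env += imf2.a2 * np.cos(np.nan_to_num(imf2.Theta2))
            out += env * np.cos(np.nan_to_num(imf1.theta))
        return out


def _wrap_first_layer(
    modes: Sequence[np.ndarray], residue: np.ndarray, sampling_rate: float
) -> FirstLayerDecomposition:
    imfs = []
    for c in modes:
        a = amplitude_envelope(c)
        theta = dq_phase(c, a)
        f = inst_freq(np.nan_to_num(theta), sampling_rate)
        f[~np.isfinite(theta)] = np.nan
        imfs.append(FirstLayerIMF(c=c, a=a, theta=theta, inst_freq=f))
    return FirstLayerDecomposition(
        imfs=imfs, residue=residue, sampling_rate=sampling_rate
    )


# --------------------------------------------------------------- operations


def emd(signal: np.ndarray, config: EMDConfig | None = None) -> FirstLayerDecomposition:
    """Plain EMD of a signal into IMFs ordered fast to slow."""
    config = config or EMDConfig()
    x = np.asarray(signal, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("signal contains non-finite samples")
    modes, residue = _emd_modes(
        x, config.imf_cap(len(x)), config.sift_stop, config.max_sift_iters
    )
    return _wrap_first_layer(modes, residue, config.sampling_rate)


def make_noise_bank(
    n: int, config: EMDConfig, rng: np.random.Generator
) -> list[list[np.ndarray]]:
    """EMD modes of ``ensemble_size`` stored white-noise realisations.

    The k-th stage of the complete-ensemble decomposition perturbs the
    residue with the k-th mode of each realisation; precomputing the bank
    once per signal length lets the first layer and every second-layer
    (envelope) decomposition share it.
    """
    cap = config.imf_cap(n)
    bank = []
    for _ in range(config.ensemble_size):
        w = rng.standard_normal(n)
        nm, _ = _emd_modes(w, cap + 1, config.sift_stop, config.max_sift_iters)
        bank.append(nm)
    return bank


def _ceemdan_modes(
    x: np.ndarray,
    config: EMDConfig,
    rng: np.random.Generator,
    noise_modes: list[list[np.ndarray]] | None = None,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Improved complete-ensemble EMD with adaptive noise (raw modes)."""
    n = len(x)
    cap = config.imf_cap(n)
    s, it = config.sift_stop, config.max_sift_iters
    sd_x = float(np.std(x))
    if sd_x == 0:
        return [], x.copy()

    if noise_modes is None:
        noise_modes = make_noise_bank(n, config, rng)

    modes: list[np.ndarray] = []
    residue = x.copy()
    for k in range(cap):
        maxima, minima = find_extrema(residue)
        if len(maxima) + len(minima) < 4:
            break
        beta = config.noise_ratio * float(np.std(residue))
        acc = np.zeros(n)
        count = 0
        for nm in noise_modes:
            if k < len(nm):
                mode_k = nm[k]
                sd_m = float(np.std(mode_k))
                perturbed = residue + beta * (mode_k / sd_m if sd_m > 0 else mode_k)
            else:
                perturbed = residue
            acc += _local_mean(perturbed, s, it)
            count += 1
        new_residue = acc / count
        d = residue - new_residue
        if float(np.std(d)) <= 1e-12 * sd_x:
            break
        modes.append(d)
        residue = new_residue
    return modes, residue


def ceemdan(
    signal: np.ndarray,
    config: EMDConfig | None = None,
    noise_modes: list[list[np.ndarray]] | None = None,
) -> FirstLayerDecomposition:
    """Improved CEEMDAN decomposition, deterministic given ``config.seed``."""
    config = config or EMDConfig()
    x = np.asarray(signal, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("signal contains non-finite samples")
    rng = np.random.default_rng(config.seed)
    modes, residue = _ceemdan_modes(x, config, rng, noise_modes=noise_modes)
    return _wrap_first_layer(modes, residue, config.sampling_rate)


#: Envelopes with SD below this fraction of their mean skip the second layer.
DEGENERATE_ENVELOPE_RTOL = 1e-6


def decompose_two_layer(
    signal: np.ndarray, config: EMDConfig | None = None
) -> TwoLayerDecomposition:
    """Two-layer CEEMDAN: decompose the signal, then each mode's envelope.

    Near-constant envelopes (SD < 1e-6 x mean) are not decomposed further;
    their full power is routed to the second-layer residue and hence to the
    unmodulated trend row of the spectrum.
    """
    config = config or EMDConfig()
    x = np.asarray(signal, dtype=float)
    bank = make_noise_bank(len(x), config, np.random.default_rng(config.seed))
    first = ceemdan(x, config, noise_modes=bank)
    second: list[SecondLayerDecomposition] = []
    for j, imf1 in enumerate(first.imfs):
        a_j = imf1.a
        mean_a = float(np.mean(np.abs(a_j)))
        if mean_a == 0 or float(np.std(a_j)) < DEGENERATE_ENVELOPE_RTOL * mean_a:
            second.append(
                SecondLayerDecomposition(
                    parent_imf_index=j, imfs2=[], residue2=a_j.copy()
                )
            )
            continue
        sub_config = replace(config, seed=config.seed + 1000003 * (j + 1))
        rng = np.random.default_rng(sub_config.seed)
        modes2, residue2 = _ceemdan_modes(a_j, sub_config, rng, noise_modes=bank)
        imfs2 = []
        for c2 in modes2:
            a2 = amplitude_envelope(c2)
            Theta2 = dq_phase(c2, a2)
            amf = inst_freq(np.nan_to_num(Theta2), config.sampling_rate)
            amf[~np.isfinite(Theta2)] = np.nan
            imfs2.append(SecondLayerIMF(c2=c2, a2=a2, Theta2=Theta2, am_freq=amf))
        second.append(
            SecondLayerDecomposition(
                parent_imf_index=j, imfs2=imfs2, residue2=residue2
            )
        )
    return TwoLayerDecomposition(
        first=first, second=second, sampling_rate=config.sampling_rate
    )
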