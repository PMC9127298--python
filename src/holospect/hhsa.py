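"""Holo-Hilbert spectra from two-layer decompositions.

The square of each second-layer amplitude function is projected, sample by
sample, onto a (carrier frequency, AM frequency) grid: the carrier
coordinate is the instantaneous frequency of the parent first-layer IMF,
the AM coordinate the instantaneous frequency of the second-layer IMF.
Power from each second-layer residue — the unmodulated part of every
envelope — lands in a dedicated ``trend_AM`` row below all AM bins.  Both
axes are log2-scaled and pooled into physiological bands; AM power can only
exist below the carrier = AM "equi-frequency" line, and cells violating it
are identically zero (the offending samples are excluded, not clamped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from holospect.emd import EMDConfig, TwoLayerDecomposition, decompose_two_layer
from holospect.phase import dq_phase, inst_freq

__all__ = [
    "BAND_DEFINITIONS", "FrequencyBins", "HoloHilbertSpectrum3D",
    "MarginalHHS", "BandSpectrum", "dq_phase", "inst_freq", "build_hhs",
    "marginal_hhs", "time_marginal", "band_binning", "log_ratio_rescale",
    "condition_contrast", "topography", "epochs_to_band_spectra",
]

#: Physiological bands (label, low Hz, high Hz); log2-octave partition.
BAND_DEFINITIONS: tuple[tuple[str, float, float], ...] = (
    ("low_delta", 0.5, 1.0),
    ("delta1", 1.0, 2.0),
    ("delta2", 2.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 16.0),
    ("beta", 16.0, 32.0),
    ("low_gamma", 32.0, 64.0),
    ("high_gamma", 64.0, 128.0),
    ("gamma_plus", 128.0, 256.0),  # carrier-axis extension only
)

TREND_LABEL = "trend_AM"


def _log2_edges(lo: float, hi: float, per_octave: int) -> np.ndarray:
    n = int(round(np.log2(hi / lo) * per_octave))
    return lo * 2.0 ** (np.arange(n + 1) / per_octave)


@dataclass(frozen=True)
class FrequencyBins:
    """Log2-spaced fine bins on both axes plus the physiological bands.

    The AM axis has an extra ``trend_AM`` row (index 0 of every AM axis in
    this package) holding unmodulated power; fine bins subdivide each octave
    band so pooling is lossless.
    """

    carrier_edges: np.ndarray
    am_edges: np.ndarray
    carrier_bands: tuple[tuple[str, float, float], ...]
    am_bands: tuple[tuple[str, float, float], ...]

    @classmethod
    def octave(
        cls,
        bins_per_octave: int = 8,
        carrier_max: float = 128.0,
        am_max: float = 128.0,
    ) -> "FrequencyBins":
        carrier_bands = tuple(
            b for b in BAND_DEFINITIONS if b[2] <= carrier_max + 1e-9
        )
        am_bands = tuple(
            b for b in BAND_DEFINITIONS[:8] if b[2] <= am_max + 1e-9
        )
        return cls(
            carrier_edges=_log2_edges(0.5, carrier_bands[-1][2], bins_per_octave),
            am_edges=_log2_edges(0.5, am_bands[-1][2], bins_per_octave),
            carrier_bands=carrier_bands,
            am_bands=am_bands,
        )

    def __post_init__(self) -> None:
        for edges in (self.carrier_edges, self.am_edges):
            if np.any(np.diff(edges) <= 0):
                raise ValueError("frequency bin edges must be strictly increasing")

    @property
    def n_carrier(self) -> int:
        return len(self.carrier_edges) - 1

    @property
    def n_am(self) -> int:  # fine AM bins, excluding the trend row
        return len(self.am_edges) - 1

    @property
    def carrier_centers(self) -> np.ndarray:
        return np.sqrt(self.carrier_edges[:-1] * self.carrier_edges[1:])

    @property
    def am_centers(self) -> np.ndarray:
        return np.sqrt(self.am_edges[:-1] * self.am_edges[1:])

    @property
    def carrier_band_labels(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.carrier_bands)

    @property
    def am_band_labels(self) -> tuple[str, ...]:
        """Band labels on the AM axis, trend row first."""
        return (TREND_LABEL,) + tuple(b[0] for b in self.am_bands)

    def _fine_to_band(self, edges: np.ndarray, bands) -> np.ndarray:
        centers = np.sqrt(edges[:-1] * edges[1:])
        out = np.full(len(centers), -1, dtype=int)
        for bi, (_, lo, hi) in enumerate(bands):
            out[(centers > lo) & (centers < hi)] = bi
        if (out < 0).any():
            raise ValueError("fine bins do not align with the band edges")
        return out

    def carrier_fine_to_band(self) -> np.ndarray:
        return self._fine_to_band(self.carrier_edges, self.carrier_bands)

    def am_fine_to_band(self) -> np.ndarray:
        return self._fine_to_band(self.am_edges, self.am_bands)

    def carrier_band_index(self, label: str) -> int:
        return self.carrier_band_labels.index(label)

    def am_band_index(self, label: str) -> int:
        """Index on the trend-first AM band axis."""
        return self.am_band_labels.index(label)


@dataclass
class HoloHilbertSpectrum3D:
    """Carrier x (trend + AM) x time power array (µV²)."""

    power: np.ndarray  # (n_carrier, 1 + n_am, n_times)
    bins: FrequencyBins
    channel: str | None = None
    projected_power: float = 0.0
    excluded_power: float = 0.0


@dataclass
class MarginalHHS:
    """Time-summed carrier x (trend + AM) spectrum."""

    power: np.ndarray  # (n_carrier, 1 + n_am)
    bins: FrequencyBins
    channel: str | None = None
    condition: str | None = None
    projected_power: float = 0.0
    excluded_power: float = 0.0


@dataclass
class BandSpectrum:
    """Physiological-band pooled spectrum: carrier bands x (trend + AM bands)."""

    power: np.ndarray  # (n_carrier_bands, 1 + n_am_bands)
    bins: FrequencyBins
    channel: str | None = None
    subject_id: str | None = None
    condition: str | None = None


# ---------------------------------------------------------------- building


def _project_samples(
    two_layer: TwoLayerDecomposition, bins: FrequencyBins
) -> Iterator[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Yield (carrier_fine_idx, am_axis_idx, time_idx, power) batches.

    ``am_axis_idx`` is on the trend-first axis (0 = trend).  Samples whose
    carrier or AM frequency is masked or out of range, or that would land
    on/above the equi-frequency line, are skipped.
    """
    ce, ae = bins.carrier_edges, bins.am_edges
    cc, ac = bins.carrier_centers, bins.am_centers
    for imf1, dec2 in zip(two_layer.first.imfs, two_layer.second):
        fi = imf1.inst_freq
        ci = np.searchsorted(ce, fi, side="right") - 1
        carrier_ok = np.isfinite(fi) & (ci >= 0) & (ci < len(cc))
        ci_safe = np.clip(ci, 0, len(cc) - 1)
        t_idx = np.arange(len(fi))
        for imf2 in dec2.imfs2:
            fa = imf2.am_freq
            ai = np.searchsorted(ae, fa, side="right") - 1
            am_ok = np.isfinite(fa) & (ai >= 0) & (ai < len(ac))
            ai_safe = np.clip(ai, 0, len(ac) - 1)
            below_line = ac[ai_safe] < cc[ci_safe]
            ok = carrier_ok & am_ok & below_line
            yield ci_safe[ok], ai_safe[ok] + 1, t_idx[ok], imf2.a2[ok] ** 2
        trend_power = dec2.residue2 ** 2
        ok = carrier_ok
        yield ci_safe[ok], np.zeros(ok.sum(), dtype=int), t_idx[ok], trend_power[ok]


def _second_layer_total(two_layer: TwoLayerDecomposition) -> float:
    total = 0.0
    for dec2 in two_layer.second:
        for imf2 in dec2.imfs2:
            total += float(np.sum(imf2.a2 ** 2))
        total += float(np.sum(dec2.residue2 ** 2))
    return total


def build_hhs(
    two_layer: TwoLayerDecomposition, bins: FrequencyBins
) -> HoloHilbertSpectrum3D:
    """Project a two-layer decomposition onto the 3-D Holo-Hilbert spectrum."""
    n_t = len(two_layer.first.residue)
    power = np.zeros((bins.n_carrier, 1 + bins.n_am, n_t))
    projected = 0.0
    for ci, ai, ti, p in _project_samples(two_layer, bins):
        np.add.at(power, (ci, ai, ti), p)
        projected += float(p.sum())
    return HoloHilbertSpectrum3D(
        power=power,
        bins=bins,
        projected_power=projected,
        excluded_power=_second_layer_total(two_layer) - projected,
    )


def marginal_hhs(
    two_layer: TwoLayerDecomposition,
    bins: FrequencyBins,
    channel: str | None = None,
    condition: str | None = None,
) -> MarginalHHS:
    """Time-marginal spectrum accumulated directly (no 3-D intermediate)."""
    power = np.zeros((bins.n_carrier, 1 + bins.n_am))
    projected = 0.0
    for ci, ai, _, p in _project_samples(two_layer, bins):
        np.add.at(power, (ci, ai), p)
        projected += float(p.sum())
    return MarginalHHS(
        power=power,
        bins=bins,
        channel=channel,
        condition=condition,
        projected_power=projected,
        excluded_power=_second_layer_total(two_layer) - projected,
    )


def time_marginal(hhs3d: HoloHilbertSpectrum3D) -> MarginalHHS:
    """Exact sum of the 3-D spectrum over the time axis."""
    return MarginalHHS(
        power=hhs3d.power.sum(axis=2),
        bins=hhs3d.bins,
        channel=hhs3d.channel,
        projected_power=hhs3d.projected_power,
        excluded_power=hhs3d.excluded_power,
    )


def band_binning(marg: MarginalHHS) -> BandSpectrum:
    """Pool fine bins into physiological bands (totals conserved exactly)."""
    bins = marg.bins
    c_map = bins.carrier_fine_to_band()
    a_map = bins.am_fine_to_band()
    n_cb = len(bins.carrier_bands)
    n_ab = len(bins.am_bands)
    out = np.zeros((n_cb, 1 + n_ab))
    np.add.at(out[:, 0], c_map, marg.power[:, 0])
    cgrid, agrid = np.meshgrid(c_map, a_map + 1, indexing="ij")
    np.add.at(out, (cgrid.ravel(), agrid.ravel()), marg.power[:, 1:].ravel())
    return BandSpectrum(
        power=out, bins=bins, channel=marg.channel, condition=marg.condition
    )


# -------------------------------------------------------------- statistics


def log_ratio_rescale(stack: np.ndarray, floor_rtol: float = 1e-12) -> np.ndarray:
    """Rescale a collection of spectra by the log ratio to their mean.

    ``stack`` has the collection on axis 0 (epochs, or all epochs of a
    cohort); each cell becomes log(value / mean of that cell across the
    collection).  Cells whose mean is zero are masked (NaN); zero values
    against a positive mean are floored at ``floor_rtol`` x mean before the
    log.  Invariant under global rescaling of the whole stack.
    """
    stack = np.asarray(stack, dtype=float)
    mean = stack.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = stack / mean
        out = np.log(np.maximum(ratio, floor_rtol))
    out[np.broadcast_to(mean == 0, stack.shape)] = np.nan
    if np.any(mean == 0):
        import warnings

        warnings.warn("all-zero cells across the collection were masked")
    return out


def condition_contrast(ec, eo):
    """Cellwise eyes-closed minus eyes-open spectrum."""
    ec_p = ec.power if isinstance(ec, BandSpectrum) else np.asarray(ec)
    eo_p = eo.power if isinstance(eo, BandSpectrum) else np.asarray(eo)
    if ec_p.shape != eo_p.shape:
        raise ValueError("condition spectra have mismatched shapes")
    diff = ec_p - eo_p
    if isinstance(ec, BandSpectrum):
        return BandSpectrum(
            power=diff, bins=ec.bins, channel=ec.channel,
            subject_id=ec.subject_id, condition="EC-EO",
        )
    return diff


def topography(
    spectra: Sequence[BandSpectrum],
    carrier_band: str,
    am_bands: Iterable[str] | None = None,
) -> np.ndarray:
    """Per-channel scalar: carrier-band power summed over an AM band range.

    ``spectra`` holds one BandSpectrum per channel in montage order;
    ``am_bands`` defaults to the full AM axis including the trend row.
    """
    if not spectra:
        raise ValueError("no spectra given")
    bins = spectra[0].bins
    ci = bins.carrier_band_index(carrier_band)
    if am_bands is None:
        am_idx = list(range(1 + len(bins.am_bands)))
    else:
        am_idx = [bins.am_band_index(b) for b in am_bands]
    return np.array([sp.power[ci, am_idx].sum() for sp in spectra])


# ----------------------------------------------------------- pipeline glue


def epochs_to_band_spectra(
    epochs: np.ndarray,
    emd_config: EMDConfig,
    bins: FrequencyBins | None = None,
) -> np.ndarray:
    """Band spectra for an (n_epochs, n_channels, n_times) array.

    Runs the two-layer decomposition and band-pooled marginal spectrum per
    channel per epoch; returns (n_epochs, n_channels, n_carrier_bands,
    1 + n_am_bands).  This is the expensive step of the chain.
    """
    if bins is None:
        nyq = emd_config.sampling_rate / 2.0
        carrier_max = 256.0 if nyq >= 256.0 else 128.0 if nyq >= 128.0 else 64.0
        bins = FrequencyBins.octave(carrier_max=carrier_max, am_max=carrier_max / 2)
    n_ep, n_ch, _ = epochs.shape
    out = np.zeros(
        (n_ep, n_ch, len(bins.carrier_bands), 1 + len(bins.am_bands))
    )
    for e in range(n_ep):
        for c in range(n_ch):
            two = decompose_two_layer(epochs[e, c], emd_config)
            out[e, c] = band_binning(marginal_hhs(two, bins)).power
    return out
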