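"""EEG file reading and the preprocessing chain.

Downsample -> re-reference (Fz) -> standardise to the 26-channel 10-20 set
-> fragment into consecutive 8000-ms epochs -> amplitude/flatline epoch
rejection.  Independent-component denoising is deliberately not included;
``reject_artifacts`` accepts a plug-in mask function for any external
epoch-screening procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import signal as sps

from holospect.montage import CHANNELS_26, ChannelMontage, make_montage


@dataclass
class Recording:
    """Multichannel time series in µV with montage and sampling metadata."""

    samples: np.ndarray  # (n_channels, n_times) µV
    sampling_rate: float
    channel_names: tuple[str, ...]
    montage: ChannelMontage | None = None
    condition: str | None = None  # "EC" / "EO"
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError("channel count does not match label count")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.isfinite(self.samples).all():
            raise ValueError("recording contains NaN or infinite samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]


@dataclass
class EpochSet:
    """Consecutive fixed-length epochs cut from one recording."""

    epochs: np.ndarray  # (n_epochs, n_channels, n_times)
    epoch_ms: float
    sampling_rate: float
    channel_names: tuple[str, ...]
    kept_mask: np.ndarray  # (n_epochs,) bool
    montage: ChannelMontage | None = None
    condition: str | None = None
    provenance: str | None = None
    remainder: np.ndarray | None = None  # trailing samples not epoched

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        expected = int(round(self.epoch_ms * self.sampling_rate / 1000.0))
        if self.epochs.ndim != 3 or self.epochs.shape[2] != expected:
            raise ValueError(
                f"epochs must be (n, ch, {expected}) for {self.epoch_ms} ms "
                f"at {self.sampling_rate} Hz"
            )
        if self.kept_mask.shape != (self.epochs.shape[0],):
            raise ValueError("kept_mask length must equal epoch count")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def kept(self) -> np.ndarray:
        return self.epochs[self.kept_mask]


# ---------------------------------------------------------------- reading

class MissingChannelError(ValueError):
    pass


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read an EDF file or BrainVision .vhdr triplet into a Recording (µV).

    Channel labels are normalised to upper case.  ``format`` may be "edf" or
    "brainvision"; by default it is inferred from the file suffix.
    """
    import mne

    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".edf": "edf", ".vhdr": "brainvision"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer EEG format from suffix {suffix!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    if format == "edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif format == "brainvision":
        for member in (path.with_suffix(".eeg"), path.with_suffix(".vmrk")):
            if not member.exists():
                raise FileNotFoundError(
                    f"BrainVision triplet incomplete: missing {member.name}"
                )
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unknown EEG format {format!r}")

    data_uv = raw.get_data() * 1e6
    names = tuple(name.strip().upper() for name in raw.ch_names)
    return Recording(
        samples=data_uv,
        sampling_rate=float(raw.info["sfreq"]),
        channel_names=names,
    )


# ----------------------------------------------------------- preprocessing

def downsample(rec: Recording, target_rate: float) -> Recording:
    """Anti-aliased decimation to ``target_rate``.

    A zero-phase FIR low-pass with cutoff at 0.4 x target rate precedes
    integer decimation (phase preservation matters for the downstream
    instantaneous-frequency estimates).  Non-integer rational ratios go
    through polyphase resampling.
    """
    if target_rate > rec.sampling_rate:
        raise ValueError(
            f"cannot upsample: target {target_rate} Hz > source {rec.sampling_rate} Hz"
        )
    if target_rate == rec.sampling_rate:
        return replace(rec, samples=rec.samples.copy())

    ratio = Fraction(target_rate / rec.sampling_rate).limit_denominator(1000)
    if ratio.numerator == 1:
        q = ratio.denominator
        numtaps = min(2 * 16 * q + 1, 2001)
        fir = sps.firwin(numtaps, 0.4 * target_rate, fs=rec.sampling_rate)
        filtered = sps.filtfilt(fir, [1.0], rec.samples, axis=1)
        out = filtered[:, ::q]
    else:
        out = sps.resample_poly(
            rec.samples, ratio.numerator, ratio.denominator, axis=1
        )
    return replace(rec, samples=out, sampling_rate=float(target_rate))


def rereference(rec: Recording, scheme: str = "FZ") -> Recording:
    """Subtract a reference series from every channel.

    ``scheme`` is a channel name (e.g. "FZ", the analysis reference) or
    "mastoid-average" (mean of A1 and A2, the acquisition reference).
    """
    names = [n.upper() for n in rec.channel_names]
    if scheme.lower() in ("mastoid-average", "mastoid"):
        missing = [m for m in ("A1", "A2") if m not in names]
        if missing:
            raise MissingChannelError(
                f"mastoid-average reference needs A1/A2; missing {missing}"
            )
        ref = 0.5 * (
            rec.samples[names.index("A1")] + rec.samples[names.index("A2")]
        )
    else:
        ref_name = scheme.upper()
        if ref_name not in names:
            raise MissingChannelError(f"reference channel {ref_name} not present")
        ref = rec.samples[names.index(ref_name)].copy()
    return replace(rec, samples=rec.samples - ref[None, :])


def standardize_channels(
    rec: Recording, montage: ChannelMontage | None = None
) -> Recording:
    """Select the 26 canonical 10-20 channels, in canonical order."""
    names = [n.upper() for n in rec.channel_names]
    missing = [c for c in CHANNELS_26 if c not in names]
    if missing:
        raise MissingChannelError(f"required channels absent: {missing}")
    idx = [names.index(c) for c in CHANNELS_26]
    if montage is None:
        montage = make_montage()
    return replace(
        rec,
        samples=rec.samples[idx],
        channel_names=CHANNELS_26,
        montage=montage,
    )


def epoch(rec: Recording, epoch_ms: float = 8000.0) -> EpochSet:
    """Cut the recording into consecutive non-overlapping epochs.

    Epochs are half-open sample intervals [k*L, (k+1)*L); the trailing
    remainder shorter than one epoch is kept aside (not analysed).
    """
    n_per = int(round(epoch_ms * rec.sampling_rate / 1000.0))
    n_full = rec.n_times // n_per
    if n_full < 1:
        raise ValueError(
            f"recording of {rec.n_times} samples is shorter than one "
            f"{epoch_ms} ms epoch ({n_per} samples)"
        )
    used = rec.samples[:, : n_full * n_per]
    epochs = used.reshape(rec.n_channels, n_full, n_per).transpose(1, 0, 2).copy()
    remainder = rec.samples[:, n_full * n_per :].copy()
    return EpochSet(
        epochs=epochs,
        epoch_ms=epoch_ms,
        sampling_rate=rec.sampling_rate,
        channel_names=rec.channel_names,
        kept_mask=np.ones(n_full, dtype=bool),
        montage=rec.montage,
        condition=rec.condition,
        provenance=rec.subject_id,
        remainder=remainder,
    )


def reject_artifacts(
    es: EpochSet,
    abs_threshold_uv: float = 100.0,
    flat_threshold_uv: float = 0.1,
    extra_mask_fn: Callable[[np.ndarray], np.ndarray] | None = None,
) -> EpochSet:
    """Flag epochs with extreme amplitudes or flat channels.

    An epoch is rejected when any channel's peak absolute value exceeds
    ``abs_threshold_uv`` or any channel's peak-to-peak range falls below
    ``flat_threshold_uv``.  ``extra_mask_fn`` (epochs array -> keep mask)
    plugs in any additional screening procedure.  Data are left untouched;
    only ``kept_mask`` changes.
    """
    if abs_threshold_uv <= 0 or flat_threshold_uv <= 0:
        raise ValueError("thresholds must be positive")
    peak = np.abs(es.epochs).max(axis=2).max(axis=1)
    rng = (es.epochs.max(axis=2) - es.epochs.min(axis=2)).min(axis=1)
    keep = es.kept_mask & (peak <= abs_threshold_uv) & (rng >= flat_threshold_uv)
    if extra_mask_fn is not None:
        extra = np.asarray(extra_mask_fn(es.epochs), dtype=bool)
        if extra.shape != keep.shape:
            raise ValueError("extra mask function returned a wrong-length mask")
        keep &= extra
    if not keep.any():
        raise ValueError("artifact rejection removed every epoch")
    return replace(es, kept_mask=keep)
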