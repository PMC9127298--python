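"""Synthetic resting-EEG cohorts with known cross-frequency structure.

Every downstream stage (preprocessing, two-layer decomposition, spectra,
group statistics, classification) is exercised against cohorts generated
here, where the ground truth — which carrier is modulated at which rate,
which group has reduced β/γ power, how strongly a depression-like score
tracks a band amplitude — is planted and therefore known exactly.

The signal model per channel is a sum of amplitude-modulated carriers over
1/f background noise::

    x(t) = Σ_osc  gain_ch · A_subj · amp · (1 + depth · cos(2π f_am t + φ_am))
                  · cos(2π f_c t + φ_c)   +   noise(t)

with subject-level amplitude factors ``A_subj`` drawn jointly with the
depression-like score to realise a configurable Pearson correlation.

Two fidelity levels are provided: full time-series cohorts
(:func:`simulate_cohort`) for the signal-processing chain, and band-spectrum
cohorts (:func:`simulate_spectral_dataset`) that plant effects directly in
the subjects x channels x carrier-band x AM-band array for the statistics
and classification stages, where synthesising hours of EEG would add
nothing but runtime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from holospect.montage import CHANNELS_26, ChannelMontage, make_montage
from holospect.preprocess import Recording

GROUPS = ("HC", "EPD", "LPD")
CONDITIONS = ("EC", "EO")

#: Clinical-score distributions per group: (mean, sd, lower, upper) for the
#: truncated normals the metadata table is drawn from.
SCORE_DISTRIBUTIONS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "HC": {
        "ham_d": (1.63, 2.73, 0.0, 52.0),
        "bdi_ii": (1.68, 2.89, 0.0, 63.0),
        "moca": (27.86, 2.39, 0.0, 30.0),
        "updrs": (1.63, 2.20, 0.0, 199.0),
        "hy": (0.0, 0.0, 0.0, 5.0),
        "ledd": (0.0, 0.0, 0.0, 5000.0),
    },
    "EPD": {
        "ham_d": (5.05, 3.62, 0.0, 52.0),
        "bdi_ii": (6.23, 4.83, 0.0, 63.0),
        "moca": (24.53, 5.73, 0.0, 30.0),
        "updrs": (28.92, 16.93, 0.0, 199.0),
        "hy": (1.58, 0.54, 1.0, 2.0),
        "ledd": (467.09, 435.39, 0.0, 5000.0),
    },
    "LPD": {
        "ham_d": (10.89, 6.40, 0.0, 52.0),
        "bdi_ii": (16.21, 7.14, 0.0, 63.0),
        "moca": (18.00, 8.67, 0.0, 30.0),
        "updrs": (79.20, 39.88, 0.0, 199.0),
        "hy": (2.89, 0.46, 2.5, 5.0),
        "ledd": (1351.63, 659.26, 0.0, 5000.0),
    },
}

METADATA_COLUMNS = (
    "subject_id", "group", "condition",
    "ham_d", "bdi_ii", "moca", "updrs", "hy", "ledd",
)


@dataclass(frozen=True)
class OscillatorSpec:
    """A band-limited carrier whose amplitude is rhythmically modulated."""

    band: str  # physiological band label, e.g. "beta"
    carrier_freq: float  # Hz
    am_freq: float  # Hz; 0 = unmodulated
    carrier_amp: float  # µV
    modulation_depth: float  # in [0, 1]
    channel_gains: np.ndarray | None = None  # per-channel multiplier

    def __post_init__(self) -> None:
        if self.carrier_amp < 0:
            raise ValueError("carrier_amp must be >= 0")
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must lie in [0, 1]")
        if self.am_freq != 0 and self.am_freq >= self.carrier_freq:
            raise ValueError("am_freq must be below carrier_freq (or 0)")

    def gains(self, n_channels: int) -> np.ndarray:
        if self.channel_gains is None:
            return np.ones(n_channels)
        g = np.asarray(self.channel_gains, dtype=float)
        if g.shape != (n_channels,):
            raise ValueError("channel_gains length must equal channel count")
        return g


def default_oscillators(
    pd_beta_gamma_factor: float = 0.7,
    lpd_slow_factor: float = 1.3,
    ec_alpha_gain: float = 2.0,
) -> dict[tuple[str, str], tuple[OscillatorSpec, ...]]:
    """Per-(group, condition) oscillator sets embodying the planted effects.

    Baseline amplitudes put most resting power in α, with θ/β/γ and δ2
    contributions; the patient-like groups get β and γ carriers scaled by
    ``pd_beta_gamma_factor`` (default 0.7), the late-stage group additionally
    θ and δ2 scaled by ``lpd_slow_factor`` (default 1.3), and eyes-closed
    recordings get an α gain of ``ec_alpha_gain`` over eyes-open.
    """
    base = {
        "delta2": OscillatorSpec("delta2", 3.0, 0.5, 2.5, 0.4),
        "theta": OscillatorSpec("theta", 6.0, 1.0, 2.0, 0.4),
        "alpha": OscillatorSpec("alpha", 10.0, 2.0, 4.0, 0.5),
        "beta": OscillatorSpec("beta", 20.0, 4.0, 1.5, 0.4),
        "gamma": OscillatorSpec("gamma", 40.0, 6.0, 0.8, 0.4),
    }
    factors = {
        "HC": {},
        "EPD": {"beta": pd_beta_gamma_factor, "gamma": pd_beta_gamma_factor},
        "LPD": {
            "beta": pd_beta_gamma_factor,
            "gamma": pd_beta_gamma_factor,
            "theta": lpd_slow_factor,
            "delta2": lpd_slow_factor,
        },
    }
    out: dict[tuple[str, str], tuple[OscillatorSpec, ...]] = {}
    for group in GROUPS:
        for condition in CONDITIONS:
            specs = []
            for name, osc in base.items():
                amp = osc.carrier_amp * factors[group].get(name, 1.0)
                if name == "alpha" and condition == "EC":
                    amp *= ec_alpha_gain
                specs.append(
                    OscillatorSpec(
                        osc.band, osc.carrier_freq, osc.am_freq,
                        amp, osc.modulation_depth,
                    )
                )
            out[(group, condition)] = tuple(specs)
    return out


@dataclass
class CohortConfig:
    """Full description of a simulated cohort.

    ``score_effect`` is the target Pearson correlation between the
    depression-like score (``score_name``) and the subject-level amplitude
    factor of the ``score_band`` oscillator; the pair is drawn from a
    bivariate normal so the realised correlation converges to the target.
    """

    n_per_group: tuple[int, int, int] = (59, 80, 19)  # HC, EPD, LPD
    sampling_rate: float = 2500.0
    epoch_ms: float = 8000.0
    n_epochs: int = 4
    oscillators: dict[tuple[str, str], tuple[OscillatorSpec, ...]] = field(
        default_factory=default_oscillators
    )
    noise_exponent: float = 1.0
    noise_amp: float = 3.0  # µV (SD of the 1/f background)
    amp_cv: float = 0.2  # subject-level amplitude coefficient of variation
    score_effect: float = 0.7
    score_band: str = "theta"
    score_name: str = "ham_d"
    conditions: tuple[str, ...] = CONDITIONS
    seed: int = 0

    def validate(self) -> list[str]:
        problems = []
        if any(n < 0 for n in self.n_per_group):
            problems.append("n_per_group counts must be non-negative")
        max_f = max(
            (osc.carrier_freq for specs in self.oscillators.values() for osc in specs),
            default=0.0,
        )
        if self.sampling_rate <= 2 * max_f:
            problems.append(
                f"sampling_rate {self.sampling_rate} Hz violates Nyquist for "
                f"a {max_f} Hz carrier"
            )
        n_samp = self.epoch_ms * self.sampling_rate / 1000.0
        if abs(n_samp - round(n_samp)) > 1e-9:
            problems.append("epoch_ms x sampling_rate must be an integer sample count")
        if not abs(self.score_effect) <= 1.0:
            problems.append("|score_effect| must be <= 1")
        if self.noise_amp < 0:
            problems.append("noise_amp must be >= 0")
        if self.n_epochs < 1:
            problems.append("n_epochs must be >= 1")
        if self.score_effect != 0 and any(n == 1 for n in self.n_per_group):
            problems.append(
                "score_effect != 0 needs at least 2 subjects per non-empty group "
                "(correlation undefined otherwise)"
            )
        return problems

    def check(self) -> None:
        problems = self.validate()
        if problems:
            raise ValueError("invalid cohort config: " + "; ".join(problems))

    @property
    def epoch_samples(self) -> int:
        return int(round(self.epoch_ms * self.sampling_rate / 1000.0))


@dataclass
class SubjectRecord:
    """One simulated subject: group, clinical scores, per-condition EEG."""

    subject_id: str
    group: str
    scores: dict[str, float]
    recordings: dict[str, Recording] = field(default_factory=dict)
    latent_amp_factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        for name, v in self.scores.items():
            if not np.isfinite(v):
                raise ValueError(f"score {name} is not finite")


# ------------------------------------------------------------- generators

def one_over_f_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int,
    sampling_rate: float, exponent: float, amp: float,
) -> np.ndarray:
    """Coloured Gaussian noise with power spectral density ∝ 1/f^exponent.

    Spectral shaping of white Gaussian noise; the DC bin is zeroed and the
    result is rescaled so each channel's SD equals ``amp``.
    """
    if amp == 0.0:
        return np.zeros((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1) * shaping[None, :]
    noise = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = noise.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return noise / sd * amp


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float,
    lower: float, upper: float,
) -> float:
    if sd == 0:
        return float(np.clip(mean, lower, upper))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lower <= v <= upper:
            return float(v)
    return float(np.clip(mean, lower, upper))


def _draw_scores_and_latents(
    rng: np.random.Generator, group: str, config: CohortConfig
) -> tuple[dict[str, float], dict[str, float]]:
    """Clinical scores plus subject-level oscillator amplitude factors.

    The ``score_band`` amplitude factor and the coupled score share a
    bivariate-normal latent with correlation ``score_effect``; the coupled
    score is therefore left untruncated so the realised Pearson r is
    unbiased.  All other scores are truncated normals with the group's
    published means/SDs.
    """
    bands = {osc.band for specs in config.oscillators.values() for osc in specs}
    latents: dict[str, float] = {}
    z_score_band = 0.0
    for band in sorted(bands):
        z = rng.standard_normal()
        if band == config.score_band:
            z_score_band = z
        latents[band] = float(max(1.0 + config.amp_cv * z, 0.05))

    scores: dict[str, float] = {}
    dists = SCORE_DISTRIBUTIONS[group]
    for name, (mean, sd, lo, hi) in dists.items():
        if name == config.score_name and config.score_effect != 0:
            rho = config.score_effect
            eps = rng.standard_normal()
            scores[name] = float(
                mean + sd * (rho * z_score_band + np.sqrt(1 - rho**2) * eps)
            )
        else:
            scores[name] = _truncated_normal(rng, mean, sd, lo, hi)
    return scores, latents


def simulate_subject(
    subject_id: str,
    group: str,
    config: CohortConfig,
    seed: int | np.random.SeedSequence,
    montage: ChannelMontage | None = None,
    signals: bool = True,
) -> SubjectRecord:
    """Simulate one subject: clinical scores and per-condition recordings.

    Deterministic given (subject_id-independent) ``seed``.  With
    ``signals=False`` only metadata and latent amplitude factors are drawn —
    used when the test of interest lives at the metadata level.
    """
    config.check()
    if montage is None:
        montage = make_montage()
    rng = np.random.default_rng(seed)
    scores, latents = _draw_scores_and_latents(rng, group, config)
    rec_dict: dict[str, Recording] = {}
    if signals:
        n_ch = montage.n_channels
        n_samp = config.epoch_samples * config.n_epochs
        t = np.arange(n_samp) / config.sampling_rate
        for condition in config.conditions:
            x = one_over_f_noise(
                rng, n_ch, n_samp, config.sampling_rate,
                config.noise_exponent, config.noise_amp,
            )
            for osc in config.oscillators[(group, condition)]:
                phi_c = rng.uniform(0, 2 * np.pi)
                phi_am = rng.uniform(0, 2 * np.pi)
                amp = osc.carrier_amp * latents.get(osc.band, 1.0)
                envelope = 1.0 + osc.modulation_depth * np.cos(
                    2 * np.pi * osc.am_freq * t + phi_am
                )
                carrier = np.cos(2 * np.pi * osc.carrier_freq * t + phi_c)
                x += osc.gains(n_ch)[:, None] * (amp * envelope * carrier)[None, :]
            rec_dict[condition] = Recording(
                samples=x,
                sampling_rate=config.sampling_rate,
                channel_names=montage.channel_names,
                montage=montage,
                condition=condition,
                subject_id=subject_id,
            )
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        scores=scores,
        recordings=rec_dict,
        latent_amp_factors=latents,
    )


def simulate_cohort(
    config: CohortConfig, signals: bool = True
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Simulate a full cohort and its metadata table (one row per subject)."""
    config.check()
    montage = make_montage()
    root = np.random.SeedSequence(config.seed)
    subjects: list[SubjectRecord] = []
    counter = 0
    rows = []
    for group, n in zip(GROUPS, config.n_per_group):
        for _ in range(n):
            child = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(counter,)
            )
            sid = f"S{counter:03d}"
            rec = simulate_subject(
                sid, group, config, child, montage=montage, signals=signals
            )
            subjects.append(rec)
            row = {
                "subject_id": sid,
                "group": group,
                "condition": ",".join(config.conditions),
                **{k: rec.scores.get(k, np.nan) for k in
                   ("ham_d", "bdi_ii", "moca", "updrs", "hy", "ledd")},
            }
            for band, factor in rec.latent_amp_factors.items():
                row[f"latent_{band}_amp"] = factor
            rows.append(row)
            counter += 1
    metadata = pd.DataFrame(rows)
    return subjects, metadata


def write_fixture(
    subjects: list[SubjectRecord],
    metadata: pd.DataFrame,
    out_dir: str | Path,
) -> list[Path]:
    """Write one EDF per subject per condition plus a metadata TSV."""
    from holospect.io_edf import write_edf

    if not subjects:
        raise ValueError("cohort is empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for rec in subjects:
        for condition, recording in rec.recordings.items():
            path = out_dir / f"{rec.subject_id}_{condition}.edf"
            write_edf(
                path,
                recording.samples,
                recording.sampling_rate,
                list(recording.channel_names),
                patient_id=rec.subject_id,
                recording_id=f"{rec.group} {condition}",
            )
            written.append(path)
    meta_path = out_dir / "metadata.tsv"
    metadata.loc[:, list(METADATA_COLUMNS)].to_csv(
        meta_path, sep="\t", index=False
    )
    written.append(meta_path)
    return written


# ------------------------------------------- band-spectrum level cohorts

def simulate_spectral_dataset(
    n_per_group: dict[str, int],
    n_carrier_bands: int = 9,
    n_am_bands: int = 9,
    effect_cells: list[tuple[int, int, int]] | None = None,
    effect_size: float = 1.5,
    effect_groups: tuple[str, str] | None = None,
    score_effect: float = 0.0,
    score_cells: list[tuple[int, int, int]] | None = None,
    score_name: str = "ham_d",
    seed: int = 0,
    montage: ChannelMontage | None = None,
):
    """Simulate subjects x channels x carrier x AM band data directly.

    Cell values are unit-variance Gaussians (the scale of log-ratio rescaled
    spectra).  ``effect_cells`` — (channel, carrier band, AM band) indices —
    get a mean shift of ``effect_size`` SD in the second group of
    ``effect_groups``; ``score_cells`` covary with a per-subject score at
    correlation ``score_effect``.  Returns a :class:`holospect.stats.
    SpectralDataset`.
    """
    from holospect.stats import SpectralDataset

    if montage is None:
        montage = make_montage()
    rng = np.random.default_rng(seed)
    groups = [g for g, n in n_per_group.items() for _ in range(n)]
    n_subj = len(groups)
    n_ch = montage.n_channels
    data = rng.standard_normal((n_subj, n_ch, n_carrier_bands, n_am_bands))
    groups_arr = np.array(groups)

    if effect_cells and effect_groups is not None:
        shifted = groups_arr == effect_groups[1]
        for ch, cb, ab in effect_cells:
            data[shifted, ch, cb, ab] += effect_size

    score = rng.standard_normal(n_subj)
    if score_cells and score_effect != 0:
        rho = score_effect
        for ch, cb, ab in score_cells:
            noise = data[:, ch, cb, ab]
            data[:, ch, cb, ab] = rho * score + np.sqrt(1 - rho**2) * noise

    metadata = pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(n_subj)],
            "group": groups_arr,
            score_name: score,
        }
    )
    return SpectralDataset(data=data, metadata=metadata, montage=montage)
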