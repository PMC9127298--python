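import numpy as np
import pytest
from scipy import signal as ssig

from holospect.synthetic import (
    SCORE_DISTRIBUTIONS, CohortConfig, OscillatorSpec, default_oscillators,
    one_over_f_noise, simulate_cohort, simulate_spectral_dataset,
    simulate_subject, write_fixture,
)


def small_config(**kw):
    defaults = dict(
        n_per_group=(4, 4, 3),
        sampling_rate=256.0,
        epoch_ms=2000.0,
        n_epochs=1,
        seed=11,
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


# ------------------------------------------------------------- determinism

def test_cohort_deterministic():
    cfg = small_config()
    s1, m1 = simulate_cohort(cfg, signals=False)
    s2, m2 = simulate_cohort(cfg, signals=False)
    assert m1.equals(m2)
    assert [r.scores for r in s1] == [r.scores for r in s2]


def test_cohort_seed_changes_draws():
    _, m1 = simulate_cohort(small_config(seed=1), signals=False)
    _, m2 = simulate_cohort(small_config(seed=2), signals=False)
    assert not m1.drop(columns=["subject_id", "group", "condition"]).equals(
        m2.drop(columns=["subject_id", "group", "condition"])
    )


def test_subject_signals_deterministic(montage):
    cfg = small_config()
    seed = np.random.SeedSequence(42)
    a = simulate_subject("S0", "HC", cfg, np.random.SeedSequence(42), montage)
    b = simulate_subject("S0", "HC", cfg, np.random.SeedSequence(42), montage)
    for cond in cfg.conditions:
        assert np.array_equal(a.recordings[cond].samples, b.recordings[cond].samples)


# ------------------------------------------------------------ composition

def test_group_counts_and_columns():
    cfg = small_config()
    _, meta = simulate_cohort(cfg, signals=False)
    counts = meta.groupby("group")["subject_id"].count()
    assert counts["HC"] == 4 and counts["EPD"] == 4 and counts["LPD"] == 3
    for col in ("ham_d", "bdi_ii", "moca", "updrs", "hy", "ledd"):
        assert col in meta.columns
    assert meta["subject_id"].is_unique


def test_scores_respect_truncation_bounds():
    # the coupled score (ham_d by default) is deliberately untruncated so the
    # realised correlation with the latent amplitude is unbiased; all other
    # scores follow truncated normals within their published ranges
    cfg = small_config(n_per_group=(30, 30, 20), seed=5)
    _, meta = simulate_cohort(cfg, signals=False)
    for group, rows in meta.groupby("group"):
        for score, (mean, sd, lo, hi) in SCORE_DISTRIBUTIONS[group].items():
            if score == cfg.score_name:
                continue
            vals = rows[score].dropna()
            if len(vals):
                assert vals.min() >= lo - 1e-9
                assert vals.max() <= hi + 1e-9


def test_score_latent_correlation_recovers_target():
    cfg = small_config(n_per_group=(120, 120, 60), score_effect=0.7, seed=9)
    _, meta = simulate_cohort(cfg, signals=False)
    pd_rows = meta[meta["group"] != "HC"]
    r = np.corrcoef(pd_rows["ham_d"], pd_rows["latent_theta_amp"])[0, 1]
    assert abs(r - 0.7) < 0.12


# ----------------------------------------------------------------- signals

def test_one_over_f_noise_spectrum(rng):
    x = one_over_f_noise(rng, n_channels=1, n_samples=2 ** 14,
                         sampling_rate=256.0, exponent=1.0, amp=3.0)
    assert x.shape == (1, 2 ** 14)
    assert np.std(x) == pytest.approx(3.0, rel=0.15)
    f, p = ssig.welch(x[0], fs=256.0, nperseg=2048)
    band = (f > 1) & (f < 64)
    slope = np.polyfit(np.log(f[band]), np.log(p[band]), 1)[0]
    assert slope == pytest.approx(-1.0, abs=0.25)


def test_single_oscillator_tone(montage):
    osc = OscillatorSpec(
        band="alpha", carrier_freq=10.0, am_freq=1.0,
        carrier_amp=4.0, modulation_depth=0.5,
    )
    cfg = small_config(
        oscillators={(g, c): (osc,) for g in ("HC", "EPD", "LPD")
                     for c in ("EC", "EO")},
        noise_amp=0.0, amp_cv=0.0, score_effect=0.0,
    )
    rec = simulate_subject("S0", "HC", cfg, np.random.SeedSequence(1), montage)
    x = rec.recordings["EC"].samples[0]
    f, p = ssig.welch(x, fs=256.0, nperseg=512)
    peak = f[np.argmax(p)]
    assert abs(peak - 10.0) < 1.0
    # AM sidebands but nothing far from the carrier
    assert p[(f < 5) | (f > 15)].max() < 1e-3 * p.max()


def test_ec_alpha_dominates_eo(montage):
    cfg = small_config(noise_amp=0.5, amp_cv=0.0, score_effect=0.0)
    rec = simulate_subject("S0", "HC", cfg, np.random.SeedSequence(3), montage)
    def alpha_power(x):
        f, p = ssig.welch(x, fs=256.0, nperseg=512)
        return p[(f >= 8) & (f <= 13)].sum()
    ec = alpha_power(rec.recordings["EC"].samples[5])
    eo = alpha_power(rec.recordings["EO"].samples[5])
    assert ec > 1.5 * eo


# ---------------------------------------------------------------- fixtures

def test_write_fixture_roundtrip(tmp_path):
    cfg = small_config(n_per_group=(1, 1, 1), score_effect=0.0, n_epochs=1)
    subjects, meta = simulate_cohort(cfg)
    written = write_fixture(subjects, meta, tmp_path)
    # one EDF per subject per condition plus the metadata table
    assert len(written) == 3 * 2 + 1
    assert (tmp_path / "metadata.tsv").exists()
    from holospect.preprocess import read_recording
    rec = read_recording(tmp_path / f"{subjects[0].subject_id}_EC.edf")
    assert rec.samples.shape == subjects[0].recordings["EC"].samples.shape


# -------------------------------------------------- spectral-level cohorts

def test_spectral_dataset_shapes_and_effect():
    ds = simulate_spectral_dataset(
        {"HC": 80, "PD": 80},
        effect_cells=[(0, 2, 3)],
        effect_size=1.5,
        effect_groups=("HC", "PD"),
        seed=3,
    )
    assert ds.data.shape[0] == 160
    assert ds.data.shape[1] == 26
    pd_mask = ds.group_mask("PD")
    hc_mask = ds.group_mask("HC")
    delta = ds.data[pd_mask, 0, 2, 3].mean() - ds.data[hc_mask, 0, 2, 3].mean()
    assert delta == pytest.approx(1.5, abs=0.5)
    # untouched cell has no shift
    delta0 = ds.data[pd_mask, 5, 1, 1].mean() - ds.data[hc_mask, 5, 1, 1].mean()
    assert abs(delta0) < 0.5


def test_spectral_dataset_deterministic():
    kw = dict(n_per_group={"HC": 10, "PD": 10}, seed=8)
    a = simulate_spectral_dataset(**kw)
    b = simulate_spectral_dataset(**kw)
    assert np.array_equal(a.data, b.data)


# ------------------------------------------------------------- validation

def test_config_validation_collects_problems():
    cfg = CohortConfig(sampling_rate=10.0, n_epochs=0)
    problems = cfg.validate()
    assert len(problems) >= 2
    with pytest.raises(ValueError):
        cfg.check()
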