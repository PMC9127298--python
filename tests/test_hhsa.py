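import numpy as np
import pytest

from holospect.emd import EMDConfig, decompose_two_layer
from holospect.hhsa import (
    BAND_DEFINITIONS, TREND_LABEL, BandSpectrum, FrequencyBins, band_binning,
    build_hhs, condition_contrast, epochs_to_band_spectra, log_ratio_rescale,
    marginal_hhs, time_marginal, topography,
)
from holospect.phase import dq_phase, inst_freq


# ------------------------------------------------------------------- phase

def test_dq_phase_recovers_tone_frequency():
    fs, f0 = 256.0, 10.0
    t = np.arange(1024) / fs
    c = np.cos(2 * np.pi * f0 * t)
    theta = dq_phase(c, np.ones_like(c))
    fi = inst_freq(theta, fs)
    core = slice(16, -16)
    assert np.nanmax(np.abs(fi[core] - f0)) < 0.5


def test_dq_phase_tracks_chirp():
    fs = 512.0
    t = np.arange(2048) / fs
    f0, f1 = 5.0, 25.0
    phase = 2 * np.pi * (f0 * t + (f1 - f0) * t**2 / (2 * t[-1]))
    c = np.cos(phase)
    fi = inst_freq(dq_phase(c, np.ones_like(c)), fs)
    expected = f0 + (f1 - f0) * t / t[-1]
    core = slice(64, -64)
    assert np.nanmedian(np.abs(fi[core] - expected[core])) < 0.5


def test_dq_phase_masks_dead_envelope():
    c = np.zeros(100)
    a = np.zeros(100)
    theta = dq_phase(c, a)
    assert np.isnan(theta).all()


def test_inst_freq_masks_negative_estimates():
    theta = np.array([2.5, 2.0, 1.5, 1.0, 0.5])  # phase running backwards
    f = inst_freq(theta, 10.0)
    assert np.isnan(f).all()
    with pytest.raises(ValueError):
        inst_freq(np.array([0.0, 1.0]), 10.0)


# -------------------------------------------------------------------- bins

def test_band_definitions_are_octaves():
    for label, lo, hi in BAND_DEFINITIONS:
        assert hi == pytest.approx(2 * lo)
    los = [b[1] for b in BAND_DEFINITIONS]
    assert los == sorted(los)


def test_octave_bins_align_with_bands():
    bins = FrequencyBins.octave(bins_per_octave=8)
    # 8 fine bins per octave, bands span 0.5..128 -> 8 octaves
    assert len(bins.carrier_edges) - 1 == 8 * len(bins.carrier_bands)
    c_map = bins.carrier_fine_to_band()
    # each band receives exactly 8 fine bins
    assert (np.bincount(c_map) == 8).all()
    assert bins.am_band_labels[0] == TREND_LABEL


def test_gamma_plus_carrier_only():
    bins = FrequencyBins.octave(carrier_max=256.0, am_max=128.0)
    assert bins.carrier_band_labels[-1] == "gamma_plus"
    assert "gamma_plus" not in bins.am_band_labels


# -------------------------------------------------------------- projection

@pytest.fixture(scope="module")
def am_decomposition():
    fs = 256.0
    t = np.arange(2048) / fs
    x = (1 + 0.5 * np.cos(2 * np.pi * 3.0 * t)) * np.cos(2 * np.pi * 20.0 * t)
    cfg = EMDConfig(ensemble_size=8, sampling_rate=fs, seed=0)
    return decompose_two_layer(x, cfg), FrequencyBins.octave(
        carrier_max=128.0, am_max=64.0
    )


def test_marginal_equals_time_summed_3d(am_decomposition):
    two, bins = am_decomposition
    hhs3 = build_hhs(two, bins)
    marg_direct = marginal_hhs(two, bins)
    marg_summed = time_marginal(hhs3)
    assert np.allclose(marg_direct.power, marg_summed.power, rtol=1e-12)
    assert marg_direct.projected_power == pytest.approx(hhs3.projected_power)


def test_band_binning_conserves_power(am_decomposition):
    two, bins = am_decomposition
    marg = marginal_hhs(two, bins)
    band = band_binning(marg)
    assert band.power.sum() == pytest.approx(marg.power.sum(), rel=1e-12)
    assert band.power[:, 0].sum() == pytest.approx(marg.power[:, 0].sum(), rel=1e-12)


def test_am_signal_lands_in_expected_cell(am_decomposition):
    two, bins = am_decomposition
    band = band_binning(marginal_hhs(two, bins))
    ci = bins.carrier_band_index("beta")  # 20 Hz carrier
    ai = bins.am_band_index("delta2")  # 3 Hz AM
    non_trend = band.power[:, 1:].sum()
    assert band.power[ci, ai] > 0.7 * non_trend


def test_equi_frequency_exclusion(am_decomposition):
    two, bins = am_decomposition
    marg = marginal_hhs(two, bins)
    cc = bins.carrier_centers
    ac = bins.am_centers
    for ci in range(len(cc)):
        for ai in range(len(ac)):
            if ac[ai] >= cc[ci]:
                assert marg.power[ci, ai + 1] == 0.0
    assert marg.excluded_power >= 0.0


def test_unmodulated_tone_goes_to_trend_row():
    fs = 256.0
    t = np.arange(2048) / fs
    x = np.cos(2 * np.pi * 10.0 * t)
    cfg = EMDConfig(ensemble_size=8, sampling_rate=fs, seed=0)
    bins = FrequencyBins.octave(carrier_max=128.0, am_max=64.0)
    band = band_binning(marginal_hhs(decompose_two_layer(x, cfg), bins))
    ci = bins.carrier_band_index("alpha")
    assert np.unravel_index(np.argmax(band.power), band.power.shape) == (ci, 0)
    assert band.power[ci, 0] > 0.8 * band.power.sum()


def test_modulation_depth_monotonicity():
    fs = 256.0
    t = np.arange(2048) / fs
    bins = FrequencyBins.octave(carrier_max=128.0, am_max=64.0)
    cfg = EMDConfig(ensemble_size=4, sampling_rate=fs, seed=0)
    fractions = []
    for depth in (0.0, 0.4, 0.8):
        x = (1 + depth * np.cos(2 * np.pi * 3.0 * t)) * np.cos(2 * np.pi * 20.0 * t)
        band = band_binning(marginal_hhs(decompose_two_layer(x, cfg), bins))
        fractions.append(band.power[:, 1:].sum() / band.power.sum())
    assert fractions[0] < fractions[1] < fractions[2]


# --------------------------------------------------------------- rescaling

def test_log_ratio_rescale_properties(rng):
    stack = rng.lognormal(size=(6, 3, 4))
    out = log_ratio_rescale(stack)
    assert out.shape == stack.shape
    # invariant under global rescaling
    out2 = log_ratio_rescale(stack * 37.5)
    assert np.allclose(out, out2)
    # a cell that is zero across the whole collection is masked
    stack[:, 0, 0] = 0.0
    with pytest.warns(UserWarning):
        masked = log_ratio_rescale(stack)
    assert np.isnan(masked[:, 0, 0]).all()
    assert np.isfinite(masked[:, 1:, :]).all()


def test_condition_contrast_antisymmetric(rng):
    a, b = rng.normal(size=(2, 5, 7))
    assert np.allclose(condition_contrast(a, b), -condition_contrast(b, a))
    with pytest.raises(ValueError):
        condition_contrast(a, rng.normal(size=(4, 7)))


def test_topography_sums_selected_bands():
    bins = FrequencyBins.octave(carrier_max=128.0, am_max=64.0)
    n_cb = len(bins.carrier_bands)
    n_ab = len(bins.am_bands)
    spectra = []
    for ch in range(3):
        p = np.full((n_cb, 1 + n_ab), float(ch + 1))
        spectra.append(BandSpectrum(power=p, bins=bins, channel=f"CH{ch}"))
    vals = topography(spectra, "alpha", am_bands=["delta1", "delta2"])
    assert np.allclose(vals, [2.0, 4.0, 6.0])
    full = topography(spectra, "alpha")
    assert np.allclose(full, [(1 + n_ab) * (c + 1) for c in range(3)])


# ------------------------------------------------------------ pipeline glue

def test_epochs_to_band_spectra_shape(rng):
    fs = 128.0
    cfg = EMDConfig(ensemble_size=2, sampling_rate=fs, seed=3)
    epochs = rng.normal(size=(2, 3, 256))
    out = epochs_to_band_spectra(epochs, cfg)
    bins = FrequencyBins.octave(carrier_max=64.0, am_max=32.0)
    assert out.shape == (2, 3, len(bins.carrier_bands), 1 + len(bins.am_bands))
    assert (out >= 0).all()
    assert out.sum() > 0
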