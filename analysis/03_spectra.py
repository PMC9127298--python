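"""Two-layer decomposition and band-pooled Holo-Hilbert spectra.

The expensive stage: per epoch and channel, ensemble empirical mode
decomposition of the signal, a second decomposition of each amplitude
envelope, projection onto the carrier x amplitude-modulation plane, and
pooling into physiological bands.  Epoch spectra are log-ratio rescaled
against the cohort mean and averaged within subject.
"""

import numpy as np
import pandas as pd
from _common import parse_config, stage_dir

from holospect.hhsa import FrequencyBins, epochs_to_band_spectra, log_ratio_rescale
from holospect.storage import load_epochs, save_spectra


def main() -> None:
    config = parse_config(__doc__)
    epochs_dir = stage_dir(config, "epochs")
    fixtures = stage_dir(config, "fixtures")
    out = stage_dir(config, "spectra")
    metadata = pd.read_csv(fixtures / "metadata.tsv", sep="\t")

    nyq = config.emd.sampling_rate / 2.0
    carrier_max = 256.0 if nyq >= 256.0 else 128.0 if nyq >= 128.0 else 64.0
    bins = FrequencyBins.octave(carrier_max=carrier_max, am_max=carrier_max / 2)

    for condition in config.cohort.conditions:
        per_subject = []
        for sid in metadata["subject_id"]:
            es = load_epochs(epochs_dir / f"{sid}_{condition}.h5")
            per_subject.append(
                epochs_to_band_spectra(es.kept(), config.emd, bins=bins)
            )
        counts = [s.shape[0] for s in per_subject]
        pooled = np.concatenate(per_subject, axis=0)
        rescaled = np.nan_to_num(log_ratio_rescale(pooled))
        split = np.split(rescaled, np.cumsum(counts)[:-1], axis=0)
        subj_mean = np.stack([s.mean(axis=0) for s in split])
        save_spectra(
            subj_mean, metadata, bins, out / f"bands_{condition}.h5",
            condition=condition,
        )
        gm = subj_mean.mean(axis=(0, 1))  # carrier x (trend + AM) grand mean
        table = pd.DataFrame(
            gm, index=bins.carrier_band_labels, columns=bins.am_band_labels
        )
        print(f"\n{condition}: grand-mean log-ratio power (carrier x AM)")
        print(table.round(2).to_string())


if __name__ == "__main__":
    main()
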