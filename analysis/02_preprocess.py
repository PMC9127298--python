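"""Preprocess the raw EDF recordings into clean epoch sets.

Downsamples, selects the 26 canonical 10-20 channels, cuts consecutive
epochs, rejects artifact epochs, and subtracts the reference channel.
One HDF5 epoch file per subject per condition.
"""

import pandas as pd
from _common import parse_config, stage_dir

from holospect.montage import make_montage
from holospect.pipeline import preprocess_recording
from holospect.storage import save_epochs


def main() -> None:
    config = parse_config(__doc__)
    fixtures = stage_dir(config, "fixtures")
    out = stage_dir(config, "epochs")
    metadata = pd.read_csv(fixtures / "metadata.tsv", sep="\t")
    montage = make_montage()
    n_kept = n_total = 0
    for sid in metadata["subject_id"]:
        for condition in config.cohort.conditions:
            es = preprocess_recording(
                fixtures / f"{sid}_{condition}.edf", config, montage
            )
            es.condition = condition
            es.provenance = sid
            save_epochs(es, out / f"{sid}_{condition}.h5")
            n_kept += int(es.kept_mask.sum())
            n_total += es.n_epochs
    print(
        f"preprocessed {len(metadata)} subjects x "
        f"{len(config.cohort.conditions)} conditions -> {out}"
    )
    print(f"epochs kept: {n_kept}/{n_total}")


if __name__ == "__main__":
    main()
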