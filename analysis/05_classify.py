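"""PD-versus-control classification from the band spectra.

Builds the feature universe from the eyes-closed minus eyes-open cell
powers, prunes near-duplicate features, runs the chunked LogitBoost
prioritisation down to a small panel, and evaluates seven classifier
families with stratified cross-validation plus a held-out test split.
"""

import json
from dataclasses import asdict

import numpy as np
import pandas as pd
from _common import parse_config, stage_dir
from sklearn.model_selection import train_test_split

from holospect.classify import (
    FeatureMatrix, SelectionConfig, build_features, iterative_selection,
    prune_correlated, train_and_evaluate,
)
from holospect.storage import load_spectra


def main() -> None:
    config = parse_config(__doc__)
    spectra_dir = stage_dir(config, "spectra")
    out = stage_dir(config, "classify")

    conditions = list(config.cohort.conditions)
    data0, meta, _ = load_spectra(spectra_dir / f"bands_{conditions[0]}.h5")
    if len(conditions) >= 2:
        data1, _, _ = load_spectra(spectra_dir / f"bands_{conditions[1]}.h5")
        contrast = data0 - data1
    else:
        contrast = data0
    labels = (meta["group"] != "HC").astype(int).to_numpy()

    fm_all = build_features(contrast, labels, universe="component")
    train_idx, test_idx = train_test_split(
        np.arange(len(labels)), train_size=config.train_fraction,
        stratify=labels, random_state=config.seed + 2,
    )
    fm_train = prune_correlated(
        FeatureMatrix(fm_all.values[train_idx], fm_all.specs, labels[train_idx])
    )
    selected = iterative_selection(
        fm_train, SelectionConfig(final_k=min(config.final_k, fm_train.n_features))
    )
    sel_idx = [fm_all.specs.index(s) for s in selected.specs]
    fm_test = FeatureMatrix(
        fm_all.values[np.ix_(test_idx, sel_idx)], selected.specs, labels[test_idx]
    )
    folds = int(min(config.cv_folds, np.bincount(labels[train_idx]).min()))
    report = train_and_evaluate(
        selected, fm_test, cv_folds=max(folds, 2), seed=config.seed + 3
    )

    (out / "selected_features.json").write_text(
        json.dumps([asdict(s) for s in selected.specs], indent=2)
    )
    table = pd.DataFrame(
        [
            {"algorithm": name, "cv_auc": ar.cv_auc, **ar.test_metrics}
            for name, ar in report.algorithms.items()
        ]
    )
    table.to_csv(out / "metrics.tsv", sep="\t", index=False)
    print("selected features:")
    for s in selected.specs:
        print(f"  {s.kind}: {s.numerator}" + (f" / {s.denominator}" if s.denominator else ""))
    print(table.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
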