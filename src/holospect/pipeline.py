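"""Configuration validation and end-to-end orchestration.

``run_pipeline`` drives the whole chain on a simulated cohort:
simulate -> preprocess -> band spectra -> group statistics ->
classification -> report, writing every stage output plus a manifest
with content hashes so a rerun with the same configuration is verifiably
identical.  These functions (together with the numbered drivers under
``analysis/``) form the command-line surface of the package.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from holospect.emd import EMDConfig
from holospect.hhsa import FrequencyBins, epochs_to_band_spectra, log_ratio_rescale
from holospect.montage import make_montage
from holospect.preprocess import (
    downsample, epoch, read_recording, reject_artifacts, standardize_channels,
)
from holospect.synthetic import CohortConfig, simulate_cohort, write_fixture

logger = logging.getLogger("holospect")


@dataclass
class PipelineConfig:
    """Validated parameters of one full pipeline run."""

    cohort: CohortConfig
    emd: EMDConfig
    target_rate: float = 500.0
    reference: str = "FZ"
    epoch_ms: float = 8000.0
    reject_uv: float = 500.0
    flat_uv: float = 1e-6
    n_perm: int = 500
    alpha: float = 0.05
    cv_folds: int = 10
    final_k: int = 3
    train_fraction: float = 0.6
    seed: int = 0
    out_dir: str = "pipeline_out"
    log_level: str = "WARNING"


_COHORT_KEYS = {
    "n_per_group", "sampling_rate", "epoch_ms", "n_epochs", "noise_exponent",
    "noise_amp", "amp_cv", "score_effect", "score_band", "score_name",
    "conditions", "seed",
}
_EMD_KEYS = {
    "ensemble_size", "noise_ratio", "max_imfs", "sift_stop",
    "max_sift_iters", "seed",
}
_TOP_KEYS = {
    "cohort", "emd", "target_rate", "reference", "epoch_ms", "reject_uv",
    "flat_uv", "n_perm", "alpha", "cv_folds", "final_k", "train_fraction",
    "seed", "out_dir", "log_level",
}


def validate_config(document: dict) -> tuple[PipelineConfig | None, list[str]]:
    """Validate a JSON-style configuration document.

    Collects ALL violations rather than stopping at the first; unknown
    keys are violations (strict mode).  Returns ``(config, [])`` on
    success or ``(None, violations)`` on failure.
    """
    errors: list[str] = []
    if not isinstance(document, dict):
        return None, ["config document must be a JSON object"]
    for key in document:
        if key not in _TOP_KEYS:
            errors.append(f"unknown key {key!r}")
    sections: dict[str, dict] = {}
    for section, allowed in (("cohort", _COHORT_KEYS), ("emd", _EMD_KEYS)):
        sub = document.get(section, {})
        if not isinstance(sub, dict):
            errors.append(f"{section} must be an object")
            sub = {}
        for key in sub:
            if key not in allowed:
                errors.append(f"unknown key {section}.{key!r}")
        sections[section] = {k: v for k, v in sub.items() if k in allowed}

    seed = document.get("seed", 0)
    cohort_doc = dict(sections["cohort"])
    cohort_doc.setdefault("seed", seed)
    if "n_per_group" in cohort_doc:
        cohort_doc["n_per_group"] = tuple(cohort_doc["n_per_group"])
    if "conditions" in cohort_doc:
        cohort_doc["conditions"] = tuple(cohort_doc["conditions"])
    cohort = None
    try:
        cohort = CohortConfig(**cohort_doc)
        errors.extend(f"cohort.{msg}" for msg in cohort.validate())
    except (TypeError, ValueError) as exc:
        errors.append(f"cohort: {exc}")

    target_rate = document.get(
        "target_rate", cohort.sampling_rate if cohort else 500.0
    )
    emd_doc = dict(sections["emd"])
    emd_doc.setdefault("seed", seed)
    emd_cfg = None
    try:
        emd_cfg = EMDConfig(sampling_rate=target_rate, **emd_doc)
    except (TypeError, ValueError) as exc:
        errors.append(f"emd: {exc}")

    top = {
        k: document[k]
        for k in _TOP_KEYS - {"cohort", "emd"}
        if k in document
    }
    top.setdefault("target_rate", target_rate)
    if cohort is not None:
        top.setdefault("epoch_ms", cohort.epoch_ms)
    for name, lo in (("n_perm", 1), ("cv_folds", 2), ("final_k", 1)):
        if name in top and top[name] < lo:
            errors.append(f"{name} must be >= {lo}")
    if "alpha" in top and not 0 < top["alpha"] < 1:
        errors.append("alpha must lie in (0, 1)")
    if "train_fraction" in top and not 0 < top["train_fraction"] < 1:
        errors.append("train_fraction must lie in (0, 1)")
    for name in ("reject_uv", "flat_uv"):
        if name in top and top[name] <= 0:
            errors.append(f"{name} must be positive")
    if cohort is not None:
        if top["target_rate"] > cohort.sampling_rate:
            errors.append("target_rate exceeds the simulated sampling rate")
        if top.get("epoch_ms", cohort.epoch_ms) > cohort.epoch_ms * cohort.n_epochs:
            errors.append("epoch_ms is longer than the simulated recording")
        if top.get("reference", "FZ").upper() not in [
            c.upper() for c in make_montage().channel_names
        ]:
            errors.append("reference is not one of the montage channels")
    if errors:
        return None, errors
    return PipelineConfig(cohort=cohort, emd=emd_cfg, **top), []


def load_config(path: str | Path) -> PipelineConfig:
    """Read and validate a JSON config file; raise listing every problem."""
    with open(path) as fh:
        document = json.load(fh)
    config, errors = validate_config(document)
    if config is None:
        raise ValueError(
            "invalid configuration:\n" + "\n".join(f"- {e}" for e in errors)
        )
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_snapshot(config: PipelineConfig) -> dict:
    cohort = {
        k: v for k, v in asdict(config.cohort).items() if k != "oscillators"
    }
    top = {
        k: v for k, v in asdict(config).items() if k not in ("cohort", "emd")
    }
    return {"cohort": cohort, "emd": asdict(config.emd), **top}


def preprocess_recording(path, config: PipelineConfig, montage):
    """Read one EDF and apply the standard preprocessing chain.

    Downsample, select the 26 canonical channels, epoch, reject artifact
    epochs, then subtract the reference channel.  The reference is
    subtracted after artifact screening because the re-referenced
    reference channel is identically zero and would otherwise trip the
    flat-channel check.
    """
    rec = read_recording(path)
    if config.target_rate < rec.sampling_rate:
        rec = downsample(rec, config.target_rate)
    rec = standardize_channels(rec, montage)
    es = epoch(rec, config.epoch_ms)
    es = reject_artifacts(es, config.reject_uv, config.flat_uv)
    ref_idx = [c.upper() for c in es.channel_names].index(config.reference.upper())
    return replace(es, epochs=es.epochs - es.epochs[:, ref_idx : ref_idx + 1, :])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate -> preprocess -> spectra -> stats -> classify -> report.

    Returns the manifest (also written to ``manifest.json`` under the
    output directory): the per-stage output files with SHA-256 content
    hashes plus a configuration snapshot.  Deterministic given the seeds
    in the configuration.
    """
    from sklearn.model_selection import train_test_split

    from holospect.classify import (
        FeatureMatrix, SelectionConfig, build_features, iterative_selection,
        prune_correlated, train_and_evaluate,
    )
    from holospect.stats import AdjacencySpec, SpectralDataset, cluster_permutation
    from holospect.storage import save_epochs, save_spectra, write_cluster_table

    logging.basicConfig(level=config.log_level, stream=sys.stderr)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_outputs: dict[str, list[str]] = {}

    def record(stage: str, paths) -> None:
        stage_outputs.setdefault(stage, []).extend(str(p) for p in paths)

    montage = make_montage()
    nyq = config.emd.sampling_rate / 2.0
    carrier_max = 256.0 if nyq >= 256.0 else 128.0 if nyq >= 128.0 else 64.0
    bins = FrequencyBins.octave(carrier_max=carrier_max, am_max=carrier_max / 2)

    # ---- 1. simulate
    logger.info("stage simulate")
    subjects, metadata = simulate_cohort(config.cohort)
    fixture_dir = out / "fixtures"
    record("simulate", write_fixture(subjects, metadata, fixture_dir))

    # ---- 2. preprocess
    logger.info("stage preprocess")
    epoch_dir = out / "epochs"
    epoch_dir.mkdir(exist_ok=True)
    epoch_sets = {}
    for rec in subjects:
        for condition in config.cohort.conditions:
            es = preprocess_recording(
                fixture_dir / f"{rec.subject_id}_{condition}.edf", config, montage
            )
            es.condition = condition
            es.provenance = rec.subject_id
            p = epoch_dir / f"{rec.subject_id}_{condition}.h5"
            save_epochs(es, p)
            epoch_sets[(rec.subject_id, condition)] = es
            record("preprocess", [p])

    # ---- 3. band spectra (the expensive stage)
    logger.info("stage spectra")
    spectra_dir = out / "spectra"
    spectra_dir.mkdir(exist_ok=True)
    per_condition: dict[str, np.ndarray] = {}
    for condition in config.cohort.conditions:
        per_subject = [
            epochs_to_band_spectra(
                epoch_sets[(rec.subject_id, condition)].kept(),
                config.emd,
                bins=bins,
            )
            for rec in subjects
        ]
        counts = [s.shape[0] for s in per_subject]
        pooled = np.concatenate(per_subject, axis=0)
        rescaled = np.nan_to_num(log_ratio_rescale(pooled))
        split = np.split(rescaled, np.cumsum(counts)[:-1], axis=0)
        subj_mean = np.stack([s.mean(axis=0) for s in split])
        per_condition[condition] = subj_mean
        p = spectra_dir / f"bands_{condition}.h5"
        save_spectra(subj_mean, metadata, bins, p, condition=condition)
        record("spectra", [p])

    # ---- 4. group statistics on the EC-EO contrast (or single condition)
    logger.info("stage stats")
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    conditions = list(config.cohort.conditions)
    if len(conditions) >= 2:
        contrast = per_condition[conditions[0]] - per_condition[conditions[1]]
    else:
        contrast = per_condition[conditions[0]]
    meta = metadata.copy()
    meta["group3"] = meta["group"]
    meta["group"] = np.where(meta["group3"] == "HC", "HC", "PD")
    ds = SpectralDataset(data=contrast, metadata=meta, montage=montage)
    stats_paths = []
    if ds.group_mask("PD").sum() >= 2 and ds.group_mask("HC").sum() >= 2:
        result = cluster_permutation(
            ds, "independent", groups=("PD", "HC"),
            adjacency=AdjacencySpec(), n_perm=config.n_perm,
            alpha=config.alpha, seed=config.seed + 1,
        )
        p = stats_dir / "clusters_pd_vs_hc.tsv"
        write_cluster_table(result, p, ds.cell_shape)
        stats_paths.append(p)
    record("stats", stats_paths)

    # ---- 5. classification (PD vs HC)
    logger.info("stage classify")
    clf_dir = out / "classify"
    clf_dir.mkdir(exist_ok=True)
    labels = (meta["group"] == "PD").astype(int).to_numpy()
    fm_all = build_features(contrast, labels, universe="component")
    idx_all = np.arange(len(labels))
    train_idx, test_idx = train_test_split(
        idx_all,
        train_size=config.train_fraction,
        stratify=labels,
        random_state=config.seed + 2,
    )
    fm_train = FeatureMatrix(
        fm_all.values[train_idx], fm_all.specs, labels[train_idx]
    )
    fm_train = prune_correlated(fm_train)
    selected = iterative_selection(
        fm_train,
        SelectionConfig(final_k=min(config.final_k, fm_train.n_features)),
    )
    sel_idx = [fm_all.specs.index(s) for s in selected.specs]
    fm_test = FeatureMatrix(
        fm_all.values[np.ix_(test_idx, sel_idx)], selected.specs, labels[test_idx]
    )
    folds = int(min(config.cv_folds, np.bincount(labels[train_idx]).min()))
    report = train_and_evaluate(
        selected, fm_test, cv_folds=max(folds, 2), seed=config.seed + 3
    )
    sel_path = clf_dir / "selected_features.json"
    sel_path.write_text(json.dumps([asdict(s) for s in selected.specs], indent=2))
    metrics_path = clf_dir / "metrics.tsv"
    pd.DataFrame(
        [
            {"algorithm": name, "cv_auc": ar.cv_auc, **ar.test_metrics}
            for name, ar in report.algorithms.items()
        ]
    ).to_csv(metrics_path, sep="\t", index=False)
    record("classify", [sel_path, metrics_path])

    # ---- 6. manifest
    logger.info("stage report")
    manifest = {
        "config": _config_snapshot(config),
        "stages": {
            stage: [{"path": p, "sha256": _sha256(Path(p))} for p in paths]
            for stage, paths in stage_outputs.items()
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
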