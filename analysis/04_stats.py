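"""Group statistics on the eyes-closed minus eyes-open spectra.

Cluster-based non-parametric permutation tests over the 3-D cell grid
(sensors x carrier bands x AM bands): PD (early + late pooled) versus
healthy controls, and the correlation of cell power with the depression
score within the PD group when the cohort is large enough.
"""

import numpy as np
from _common import parse_config, stage_dir

from holospect.montage import make_montage
from holospect.stats import AdjacencySpec, SpectralDataset, cluster_permutation, correlation_map
from holospect.storage import load_spectra, write_cluster_table


def summarize(name, result):
    sig = result.significant(0.05)
    print(f"{name}: {len(result.clusters)} cluster(s), {len(sig)} significant")
    for c in result.clusters[:5]:
        print(f"  mass={c.mass:10.2f}  cells={len(c.cells):4d}  p={c.p_value:.4f}")


def main() -> None:
    config = parse_config(__doc__)
    spectra_dir = stage_dir(config, "spectra")
    out = stage_dir(config, "stats")
    montage = make_montage()

    conditions = list(config.cohort.conditions)
    data0, meta, _ = load_spectra(spectra_dir / f"bands_{conditions[0]}.h5")
    if len(conditions) >= 2:
        data1, _, _ = load_spectra(spectra_dir / f"bands_{conditions[1]}.h5")
        contrast = data0 - data1
    else:
        contrast = data0
    meta = meta.copy()
    meta["group3"] = meta["group"]
    meta["group"] = np.where(meta["group3"] == "HC", "HC", "PD")
    ds = SpectralDataset(data=contrast, metadata=meta, montage=montage)

    result = cluster_permutation(
        ds, "independent", groups=("PD", "HC"), adjacency=AdjacencySpec(),
        n_perm=config.n_perm, alpha=config.alpha, seed=config.seed + 1,
    )
    write_cluster_table(result, out / "clusters_pd_vs_hc.tsv", ds.cell_shape)
    summarize("PD vs HC", result)

    pd_mask = ds.group_mask("PD")
    score = meta.loc[pd_mask, config.cohort.score_name].to_numpy(dtype=float)
    if pd_mask.sum() >= 4 and np.std(score) > 0:
        ds_pd = SpectralDataset(
            data=contrast[pd_mask], metadata=meta[pd_mask], montage=montage
        )
        _, corr = correlation_map(
            ds_pd, config.cohort.score_name, adjacency=AdjacencySpec(),
            n_perm=config.n_perm, alpha=config.alpha, seed=config.seed + 4,
        )
        write_cluster_table(
            corr, out / f"clusters_{config.cohort.score_name}.tsv", ds.cell_shape
        )
        summarize(f"{config.cohort.score_name} correlation (PD)", corr)
    else:
        print("cohort too small for the score-correlation analysis; skipped")


if __name__ == "__main__":
    main()
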