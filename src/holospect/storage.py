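"""HDF5 / delimited-text serialisation of intermediate results."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from holospect.emd import (
    FirstLayerDecomposition, FirstLayerIMF, SecondLayerDecomposition,
    SecondLayerIMF, TwoLayerDecomposition,
)
from holospect.hhsa import FrequencyBins
from holospect.montage import ChannelMontage
from holospect.preprocess import EpochSet


def save_epochs(es: EpochSet, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=es.epochs, track_times=False)
        f.create_dataset("kept_mask", data=es.kept_mask, track_times=False)
        if es.remainder is not None:
            f.create_dataset("remainder", data=es.remainder, track_times=False)
        f.attrs["epoch_ms"] = es.epoch_ms
        f.attrs["sampling_rate"] = es.sampling_rate
        f.attrs["channel_names"] = list(es.channel_names)
        if es.condition:
            f.attrs["condition"] = es.condition
        if es.provenance:
            f.attrs["provenance"] = es.provenance
        if es.montage is not None:
            f.create_dataset("montage_positions", data=es.montage.positions, track_times=False)
    return path


def load_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        names = tuple(
            n.decode() if isinstance(n, bytes) else str(n)
            for n in f.attrs["channel_names"]
        )
        montage = None
        if "montage_positions" in f:
            montage = ChannelMontage(names, f["montage_positions"][()])
        return EpochSet(
            epochs=f["epochs"][()],
            epoch_ms=float(f.attrs["epoch_ms"]),
            sampling_rate=float(f.attrs["sampling_rate"]),
            channel_names=names,
            kept_mask=f["kept_mask"][()],
            montage=montage,
            condition=f.attrs.get("condition"),
            provenance=f.attrs.get("provenance"),
            remainder=f["remainder"][()] if "remainder" in f else None,
        )


def save_decomposition(two: TwoLayerDecomposition, path: str | Path) -> Path:
    """Two-layer decomposition as /imf1/<j>, /imf2/<j>/<k>, /residue."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate"] = two.sampling_rate
        f.create_dataset("residue", data=two.first.residue, track_times=False)
        for j, imf in enumerate(two.first.imfs):
            g = f.create_group(f"imf1/{j}")
            for name in ("c", "a", "theta", "inst_freq"):
                g.create_dataset(name, data=getattr(imf, name), track_times=False)
        for dec2 in two.second:
            g = f.create_group(f"imf2/{dec2.parent_imf_index}")
            g.create_dataset("residue2", data=dec2.residue2, track_times=False)
            for k, imf2 in enumerate(dec2.imfs2):
                gk = g.create_group(str(k))
                for name in ("c2", "a2", "Theta2", "am_freq"):
                    gk.create_dataset(name, data=getattr(imf2, name), track_times=False)
    return path


def load_decomposition(path: str | Path) -> TwoLayerDecomposition:
    with h5py.File(path, "r") as f:
        rate = float(f.attrs["sampling_rate"])
        n = len(f["imf1"]) if "imf1" in f else 0
        imfs = [
            FirstLayerIMF(
                **{k: f[f"imf1/{j}/{k}"][()] for k in ("c", "a", "theta", "inst_freq")}
            )
            for j in range(n)
        ]
        second = []
        for j in range(n):
            g = f[f"imf2/{j}"]
            ks = sorted((k for k in g if k != "residue2"), key=int)
            second.append(
                SecondLayerDecomposition(
                    parent_imf_index=j,
                    imfs2=[
                        SecondLayerIMF(
                            **{nm: g[f"{k}/{nm}"][()]
                               for nm in ("c2", "a2", "Theta2", "am_freq")}
                        )
                        for k in ks
                    ],
                    residue2=g["residue2"][()],
                )
            )
        first = FirstLayerDecomposition(
            imfs=imfs, residue=f["residue"][()], sampling_rate=rate
        )
        return TwoLayerDecomposition(first=first, second=second, sampling_rate=rate)


def save_spectra(
    data: np.ndarray,
    metadata: pd.DataFrame,
    bins: FrequencyBins,
    path: str | Path,
    condition: str | None = None,
) -> Path:
    """Subjects x channels x carrier-band x AM-band array with band labels."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("bands", data=np.asarray(data, dtype=float), track_times=False)
        f.attrs["carrier_band_labels"] = list(bins.carrier_band_labels)
        f.attrs["am_band_labels"] = list(bins.am_band_labels)
        f.attrs["carrier_edges"] = bins.carrier_edges
        f.attrs["am_edges"] = bins.am_edges
        if condition:
            f.attrs["condition"] = condition
        f.attrs["metadata_json"] = metadata.to_json(orient="split")
    return path


def load_spectra(path: str | Path):
    import io

    with h5py.File(path, "r") as f:
        data = f["bands"][()]
        meta = pd.read_json(io.StringIO(f.attrs["metadata_json"]), orient="split")
        labels = {
            "carrier": tuple(
                s.decode() if isinstance(s, bytes) else str(s)
                for s in f.attrs["carrier_band_labels"]
            ),
            "am": tuple(
                s.decode() if isinstance(s, bytes) else str(s)
                for s in f.attrs["am_band_labels"]
            ),
        }
    return data, meta, labels


def write_cluster_table(result, path: str | Path, cell_shape) -> Path:
    """Cluster table as TSV: one row per member cell with mass and p."""
    path = Path(path)
    rows = []
    for ci, cluster in enumerate(result.clusters):
        for flat in cluster.cells:
            ch, cb, ab = np.unravel_index(flat, cell_shape)
            rows.append(
                {
                    "cluster": ci,
                    "channel": int(ch),
                    "carrier_band": int(cb),
                    "am_band": int(ab),
                    "t": float(result.t_map[ch, cb, ab]),
                    "mass": cluster.mass,
                    "p_value": cluster.p_value,
                }
            )
    pd.DataFrame(
        rows,
        columns=["cluster", "channel", "carrier_band", "am_band", "t", "mass", "p_value"],
    ).to_csv(path, sep="\t", index=False)
    return path
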