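"""Plain-text and HDF5 interchange for study data and derived artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .inverse import ROISeries
from .network import ConnectivityMatrix, Partition
from .synth import Envelope, GroundTruth, MultiSubjectEEG

__all__ = [
    "save_study",
    "load_study",
    "save_ground_truth",
    "load_ground_truth",
    "envelope_to_tsv",
    "envelope_from_tsv",
    "roi_series_to_tsv",
    "trf_to_tsv",
    "connectivity_to_tsv",
    "partition_to_tsv",
    "scan_to_tsv",
]


def save_study(path, eeg: MultiSubjectEEG) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=eeg.data, compression="gzip", compression_opts=1)
        f.attrs["fs"] = eeg.fs
        f.create_dataset("condition_labels", data=np.array(eeg.condition_labels, dtype="S"))
        f.create_dataset("subject_ids", data=np.array(eeg.subject_ids, dtype="S"))


def load_study(path) -> MultiSubjectEEG:
    with h5py.File(path, "r") as f:
        return MultiSubjectEEG(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            condition_labels=[s.decode() for s in f["condition_labels"][()]],
            subject_ids=[s.decode() for s in f["subject_ids"][()]],
        )


def save_ground_truth(path, gt: GroundTruth) -> None:
    """HDF5 arrays plus a JSON sidecar with labels and seeds."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for cond, k in gt.kernels.items():
            f.create_dataset(f"kernels/{cond}", data=k)
        f.create_dataset("lag_grid_ms", data=gt.lag_grid_ms)
        f.create_dataset("leadfield", data=gt.leadfield)
        f.create_dataset("parcellation", data=gt.parcellation)
        f.create_dataset("subject_transforms", data=gt.subject_transforms)
        f.attrs["n_roi"] = gt.n_roi
        f.attrs["misalignment"] = gt.misalignment
    sidecar = {
        "community_labels": {c: np.asarray(v).tolist() for c, v in gt.community_labels.items()},
        "seeds": {k: int(v) for k, v in gt.seeds.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_ground_truth(path) -> GroundTruth:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    with h5py.File(path, "r") as f:
        return GroundTruth(
            n_roi=int(f.attrs["n_roi"]),
            community_labels={c: np.asarray(v, dtype=int) for c, v in sidecar["community_labels"].items()},
            kernels={c: f[f"kernels/{c}"][()] for c in f["kernels"]},
            lag_grid_ms=f["lag_grid_ms"][()],
            leadfield=f["leadfield"][()],
            parcellation=f["parcellation"][()],
            subject_transforms=f["subject_transforms"][()],
            misalignment=float(f.attrs["misalignment"]),
            seeds=sidecar["seeds"],
        )


def envelope_to_tsv(path, env: Envelope) -> None:
    """Single amplitude column with the sampling rate in the header name."""
    pd.DataFrame({f"amplitude@fs={env.fs:g}Hz": env.values}).to_csv(path, sep="\t", index=False)


def envelope_from_tsv(path) -> Envelope:
    df = pd.read_csv(path, sep="\t")
    col = df.columns[0]
    fs = float(col.split("fs=")[1].rstrip("Hz"))
    return Envelope(values=df[col].to_numpy(), fs=fs)


def roi_series_to_tsv(path, roi: ROISeries) -> None:
    pd.DataFrame(roi.values, index=roi.roi_ids).to_csv(path, sep="\t", header=False)


def trf_to_tsv(path, weights: np.ndarray, lags_ms: np.ndarray, roi_ids=None) -> None:
    """Rows = regions, columns = lag in ms (header row carries the lags)."""
    weights = np.atleast_2d(weights)
    idx = roi_ids if roi_ids is not None else [f"ROI{i:02d}" for i in range(weights.shape[0])]
    pd.DataFrame(weights, index=idx, columns=[f"{l:g}" for l in lags_ms]).to_csv(path, sep="\t")


def connectivity_to_tsv(path, C: ConnectivityMatrix) -> None:
    pd.DataFrame(C.values, index=C.roi_ids, columns=C.roi_ids).to_csv(path, sep="\t")


def partition_to_tsv(path, partition: Partition, roi_ids=None) -> None:
    ids = roi_ids if roi_ids is not None else [f"ROI{i:02d}" for i in range(partition.labels.size)]
    pd.DataFrame({"roi_id": ids, "community": partition.labels}).to_csv(path, sep="\t", index=False)


def scan_to_tsv(path, scan) -> None:
    n = scan.densities.size
    vi_col = np.concatenate([[np.nan], scan.vi]) if scan.vi.size == n - 1 else np.full(n, np.nan)
    df = pd.DataFrame(
        {
            "density": scan.densities,
            "Q": scan.Q,
            "n_communities": [p.n_communities for p in scan.partitions],
            "vi_to_previous": vi_col,
            "f1": scan.f1 if scan.f1 is not None else np.full(n, np.nan),
        }
    )
    df.to_csv(path, sep="\t", index=False)
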