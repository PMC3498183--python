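"""Reading and writing cohort arrays, metrics tables, and partitions.

Cohorts are stored as one ``.npy`` array per subject (channels x samples x
epochs) next to a tab-separated metadata table; connectivity matrices and
partitions are plain delimited text with JSON sidecars, so every stage's
output is individually re-loadable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .modularity import Partition
from .preprocessing import EpochedRecording
from .simulate import COGNITIVE_DOMAINS, SubjectRecord

__all__ = [
    "write_cohort",
    "load_cohort",
    "read_text_epochs",
    "write_partition",
    "load_partition",
]

METADATA_FILE = "metadata.tsv"


def write_cohort(pairs, outdir: str | Path, sampling_rate: float | None = None) -> Path:
    """Write (EpochedRecording, SubjectRecord) pairs to a cohort directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, meta in pairs:
        np.save(outdir / f"{meta.subject_id}.npy", rec.data)
        row = {
            "subject_id": meta.subject_id,
            "group": meta.group,
            "sampling_rate": rec.sampling_rate,
            "seizure_freq_per_month": meta.seizure_freq,
            "epilepsy_duration_months": meta.epilepsy_duration,
        }
        for d in COGNITIVE_DOMAINS:
            row[f"cognition_{d}"] = meta.cognition.get(d, np.nan)
        row["cognition_avg"] = meta.cognition_avg
        for key, val in meta.ground_truth.items():
            row[f"truth_{key}"] = val
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / METADATA_FILE, sep="\t", index=False)
    return outdir


def load_cohort(indir: str | Path) -> tuple[list[EpochedRecording], pd.DataFrame]:
    """Load a cohort directory back into recordings plus a metadata table."""
    indir = Path(indir)
    meta = pd.read_csv(indir / METADATA_FILE, sep="\t")
    recordings = []
    for _, row in meta.iterrows():
        sid = str(row["subject_id"])
        data = np.load(indir / f"{sid}.npy")
        recordings.append(
            EpochedRecording(
                data=data, sampling_rate=float(row["sampling_rate"]), subject_id=sid
            )
        )
    return recordings, meta


def read_text_epochs(
    paths, sampling_rate: float, subject_id: str = "", delimiter: str | None = None
) -> EpochedRecording:
    """Build a recording from plain-text channels x samples matrices, one per epoch."""
    epochs = [np.loadtxt(p, delimiter=delimiter) for p in paths]
    if not epochs:
        raise ValueError("need at least one epoch file")
    data = np.stack([np.atleast_2d(e) for e in epochs], axis=2)
    return EpochedRecording(data=data, sampling_rate=sampling_rate, subject_id=subject_id)


def write_partition(p: Partition, path: str | Path, meta: dict | None = None) -> None:
    """Write a partition as two-column text (vertex, module) plus a JSON sidecar."""
    path = Path(path)
    arr = np.column_stack([np.arange(p.labels.size), p.labels])
    np.savetxt(path, arr, fmt="%d", delimiter="\t", header="vertex\tmodule")
    sidecar = {"Q": p.Q, "n_modules": p.n_modules}
    if meta:
        sidecar.update(meta)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_partition(path: str | Path) -> Partition:
    arr = np.loadtxt(path, dtype=int)
    sidecar = Path(path).with_suffix(".json")
    q = np.nan
    if sidecar.exists():
        q = json.loads(sidecar.read_text()).get("Q", np.nan)
    return Partition(labels=arr[:, 1], Q=q)
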