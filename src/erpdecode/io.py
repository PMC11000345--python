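"""Plain-text epoch interchange format.

One delimited numeric matrix per subject and channel
(``<subject>_<channel>.csv``, rows = trials, columns = samples, uV) plus a
JSON sidecar ``<subject>.json`` holding subject id, sampling rate, channel
list, per-trial label records and the retention mask. Floats are written
with 17 significant digits, so write -> read round-trips bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import EpochSet

_LABEL_COLUMNS = ["emotion", "modality", "exemplar", "repetition", "catch", "stim_id", "trial"]


def write_epochs(epochs: EpochSet, out_dir: str | Path) -> Path:
    """Write one subject's epochs; returns the sidecar path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for ci, ch in enumerate(epochs.channels):
        np.savetxt(
            out_dir / f"{epochs.subject_id}_{ch}.csv",
            epochs.data[:, ci, :],
            fmt="%.17g",
            delimiter=",",
        )
    cols = [c for c in _LABEL_COLUMNS if c in epochs.labels.columns]
    sidecar = {
        "subject_id": epochs.subject_id,
        "sampling_rate": epochs.sampling_rate,
        "channels": list(epochs.channels),
        "labels": epochs.labels[cols].to_dict(orient="records"),
        "retained": [bool(r) for r in epochs.retained],
    }
    path = out_dir / f"{epochs.subject_id}.json"
    path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_epochs(in_dir: str | Path, subject_id: str) -> EpochSet:
    """Read one subject's epochs written by :func:`write_epochs`."""
    in_dir = Path(in_dir)
    sidecar_path = in_dir / f"{subject_id}.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"no sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    labels = pd.DataFrame(meta["labels"])
    if "catch" in labels.columns:
        labels["catch"] = labels["catch"].astype(bool)
    mats = []
    for ch in meta["channels"]:
        mat = np.loadtxt(in_dir / f"{subject_id}_{ch}.csv", delimiter=",", ndmin=2)
        mats.append(mat)
    data = np.stack(mats, axis=1)
    return EpochSet(
        subject_id=meta["subject_id"],
        sampling_rate=float(meta["sampling_rate"]),
        channels=list(meta["channels"]),
        data=data,
        labels=labels,
        retained=np.asarray(meta["retained"], dtype=bool),
    )


def list_subjects(in_dir: str | Path) -> list[str]:
    """Subject ids present in a directory of epoch files, sorted."""
    return sorted(p.stem for p in Path(in_dir).glob("*.json"))
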