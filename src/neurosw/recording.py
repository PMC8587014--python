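"""Epoched multichannel recordings at the cortical-source (ROI) level.

The in-memory container for one subject's data is
:class:`EpochedRecording`: a ``(n_epochs, n_rois, samples_per_epoch)``
array of consecutive, non-overlapping fixed-length epochs, together with
subject/group metadata.  The full-resolution network uses 84 ROIs: 42
Brodmann areas per hemisphere, left hemisphere first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidSpecError

__all__ = ["EpochedRecording", "ROI_LABELS_84", "BRODMANN_AREAS"]

# Brodmann areas used as cortical nodes (42 per hemisphere).
BRODMANN_AREAS: tuple[int, ...] = (
    1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 13, 17, 18, 19, 20, 21, 22, 23, 24,
    25, 27, 28, 29, 30, 31, 32, 33, 34, 35, 36, 37, 38, 39, 40, 41, 42, 43,
    44, 45, 46, 47,
)

#: Canonical ROI order: 42 left-hemisphere Brodmann areas, then 42 right.
ROI_LABELS_84: tuple[str, ...] = tuple(
    f"BA{ba}_{hemi}" for hemi in ("L", "R") for ba in BRODMANN_AREAS
)


def default_roi_labels(n: int) -> tuple[str, ...]:
    """Canonical 84-ROI labels for n=84, generic ``ROI##`` labels otherwise."""
    if n == len(ROI_LABELS_84):
        return ROI_LABELS_84
    return tuple(f"ROI{i:02d}" for i in range(n))


@dataclass
class EpochedRecording:
    """One subject's ROI time series cut into fixed-length epochs.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    group : str
        Cohort label (``"PD"``, ``"Nold"`` or ``"unknown"``).
    fs : float
        Sampling rate in Hz.
    roi_labels : sequence of str
        One label per ROI, in row order of ``data``.
    data : ndarray, shape (n_epochs, n_rois, samples_per_epoch)
        Epoched time series.  Epochs are consecutive and non-overlapping,
        so concatenating them restores the continuous record.
    epoch_length_s : float
        Epoch duration in seconds (default 2).
    """

    subject_id: str
    group: str
    fs: float
    roi_labels: tuple[str, ...]
    data: np.ndarray
    epoch_length_s: float = 2.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.roi_labels = tuple(self.roi_labels)
        if self.data.ndim != 3:
            raise InvalidSpecError(
                f"data must be (epochs, rois, samples), got shape {self.data.shape}"
            )
        if self.data.shape[1] != len(self.roi_labels):
            raise InvalidSpecError(
                f"{len(self.roi_labels)} ROI labels but data has "
                f"{self.data.shape[1]} channels"
            )
        expected = int(round(self.fs * self.epoch_length_s))
        if self.data.shape[0] > 0 and self.data.shape[2] != expected:
            raise InvalidSpecError(
                f"samples_per_epoch={self.data.shape[2]} but fs*epoch_length_s={expected}"
            )

    # -- conveniences -------------------------------------------------
    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def samples_per_epoch(self) -> int:
        return self.data.shape[2]

    @property
    def duration_s(self) -> float:
        """Total retained duration in seconds."""
        return self.n_epochs * self.epoch_length_s

    def continuous(self) -> np.ndarray:
        """Concatenate epochs back into a ``(n_rois, n_samples)`` array."""
        return self.data.transpose(1, 0, 2).reshape(self.n_rois, -1)

    def with_data(self, data: np.ndarray) -> "EpochedRecording":
        return replace(self, data=data)

    # -- plain-text I/O ------------------------------------------------
    def write_csv(self, path: str | Path) -> Path:
        """Write the continuous series as CSV (rows = samples, cols = ROIs)
        plus a JSON sidecar with subject metadata."""
        path = Path(path)
        df = pd.DataFrame(self.continuous().T, columns=list(self.roi_labels))
        df.to_csv(path, index=False, float_format="%.8g")
        sidecar = {
            "subject_id": self.subject_id,
            "group": self.group,
            "fs": self.fs,
            "epoch_length_s": self.epoch_length_s,
            **{k: v for k, v in self.meta.items()},
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
        return path

    @classmethod
    def read_csv(cls, path: str | Path) -> "EpochedRecording":
        """Read a continuous CSV + JSON sidecar and re-epoch it."""
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        series = df.to_numpy(dtype=float).T
        fs = float(sidecar["fs"])
        epoch_s = float(sidecar.get("epoch_length_s", 2.0))
        spe = int(round(fs * epoch_s))
        n_ep = series.shape[1] // spe
        data = (
            series[:, : n_ep * spe].reshape(series.shape[0], n_ep, spe)
            .transpose(1, 0, 2)
        )
        meta = {
            k: v
            for k, v in sidecar.items()
            if k not in {"subject_id", "group", "fs", "epoch_length_s"}
        }
        return cls(
            subject_id=str(sidecar["subject_id"]),
            group=str(sidecar.get("group", "unknown")),
            fs=fs,
            roi_labels=tuple(df.columns),
            data=data,
            epoch_length_s=epoch_s,
            meta=meta,
        )
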