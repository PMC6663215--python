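"""Core data containers: sample x feature matrices and per-sample label tracks.

A :class:`DataMatrix` is the universal input to the Mapper pipeline: rows are
samples (e.g., fMRI time frames), columns are features (e.g., voxels).  A
:class:`LabelTrack` carries one categorical label per sample (e.g., the visual
stimulus condition shown during each frame, with a designated rest label).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataMatrix",
    "LabelTrack",
    "load_matrix_csv",
    "save_matrix_csv",
    "load_labels_csv",
    "save_labels_csv",
    "normalize_frames",
]


@dataclass
class DataMatrix:
    """n_samples x n_features real matrix with row/column identifiers.

    Parameters
    ----------
    values
        2-D array of finite floats, one row per sample.
    sample_ids
        Ordered sample identifiers; defaults to ``s0000, s0001, ...``.
    feature_ids
        Ordered feature identifiers; defaults to ``f0000, f0001, ...``.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features array")
        n, v = self.values.shape
        if n < 1 or v < 1:
            raise ValueError("matrix must have at least one sample and one feature")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite values")
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(n)]
        if not self.feature_ids:
            self.feature_ids = [f"f{j:04d}" for j in range(v)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")
        if len(self.feature_ids) != v:
            raise ValueError("feature_ids length does not match number of columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class LabelTrack:
    """Ordered categorical labels, one per sample.

    ``rest_label`` names the background condition; it is an ordinary category
    for counting purposes but several analyses can exclude it on request.
    """

    labels: list[str]
    rest_label: str = "rest"

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) == 0:
            raise ValueError("label track is empty")
        if any(l == "" for l in self.labels):
            raise ValueError("labels must be non-empty strings")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def categories(self) -> list[str]:
        """Sorted distinct categories present in the track."""
        return sorted(set(self.labels))

    def indices_of(self, category: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels, dtype=object) == category)

    def shifted(self, n_frames: int) -> "LabelTrack":
        """Shift labels forward in time by ``n_frames``, padding with rest.

        Used to align a stimulus track with the delayed hemodynamic response
        (e.g., 2 frames at TR 2.5 s for a ~5 s response rise).
        """
        if n_frames < 0:
            raise ValueError("shift must be non-negative")
        if n_frames == 0:
            return LabelTrack(list(self.labels), self.rest_label)
        shifted = [self.rest_label] * n_frames + self.labels[: len(self.labels) - n_frames]
        return LabelTrack(shifted, self.rest_label)


def normalize_frames(data: DataMatrix) -> DataMatrix:
    """Scale each row (sample) to unit L2 norm.

    Puts samples on a common sphere so distances reflect pattern *shape*
    rather than amplitude — the correlation-style geometry customary for
    multivoxel fMRI patterns.  Zero rows are left unchanged.
    """
    norms = np.linalg.norm(data.values, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return DataMatrix(data.values / norms, list(data.sample_ids), list(data.feature_ids))


def save_matrix_csv(data: DataMatrix, path: str | Path) -> None:
    """Write a matrix as CSV: header = feature ids, first column = sample ids."""
    df = pd.DataFrame(data.values, index=data.sample_ids, columns=data.feature_ids)
    df.to_csv(path, index_label="sample")


def load_matrix_csv(path: str | Path) -> DataMatrix:
    """Read a delimited matrix (CSV/TSV; delimiter sniffed by pandas).

    The header row supplies feature ids.  A first column named ``sample`` (or
    any non-numeric first column) supplies sample ids.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    first = df.columns[0]
    if first == "sample" or df[first].dtype == object:
        df = df.set_index(first)
    return DataMatrix(
        df.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


def save_labels_csv(track: LabelTrack, path: str | Path) -> None:
    pd.DataFrame({"label": track.labels}).to_csv(path, index=False)


def load_labels_csv(path: str | Path, rest_label: str = "rest") -> LabelTrack:
    """Read a single-column delimited label file with a header row."""
    df = pd.read_csv(path, sep=None, engine="python")
    return LabelTrack([str(x) for x in df.iloc[:, 0]], rest_label=rest_label)


def as_sequence(x, d: int, name: str) -> list:
    """Broadcast a scalar to ``d`` values, or validate a length-``d`` sequence."""
    if isinstance(x, (list, tuple, np.ndarray)):
        seq = list(x)
        if len(seq) != d:
            raise ValueError(f"{name} has length {len(seq)}, expected {d}")
        return seq
    return [x] * d


def _ids_like(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(n)]
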