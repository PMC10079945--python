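"""Normalization, windowing, labeling, class balancing and splitting.

The fixed pipeline order is: L2-normalize the whole recording, affinely
rescale it to [0, 1], then cut windows.  Rescaling is applied over the
whole recording (not per window) so relative amplitudes between windows
survive; rasterization downstream requires amplitudes in [0, 1].

Spike windows are centered on each ground-truth annotation; noise
windows are non-overlapping stretches that contain no part of any spike
support.  Windows at recording edges, or overlapping two annotations of
different classes, are dropped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import Recording

__all__ = [
    "NOISE_LABEL",
    "Window",
    "WindowSet",
    "SplitSpec",
    "l2_normalize",
    "rescale_unit_interval",
    "segment",
    "balance_noise",
    "split",
    "load_binary_epochs",
    "save_windowset",
    "load_windowset",
]

NOISE_LABEL = "noise"


def spike_label(class_id: int) -> str:
    return f"spike-{class_id}"


@dataclass(frozen=True)
class Window:
    """Fixed-length [0,1] segment with a label and provenance."""

    values: np.ndarray
    label: str
    source: tuple[str, int]  # (recording id, start sample index)


class WindowSet:
    """Ordered collection of equal-length windows.

    Stores values as one (n_windows, n) float array plus parallel label
    and source sequences; ``class_counts`` tallies labels.
    """

    def __init__(self, values: np.ndarray, labels, sources) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be 2D (n_windows, window_len)")
        if not (len(labels) == len(sources) == values.shape[0]):
            raise ValueError("labels/sources length mismatch")
        self.values = values
        self.labels = list(labels)
        self.sources = [tuple(s) for s in sources]

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def class_counts(self) -> dict[str, int]:
        return dict(Counter(self.labels))

    def subset(self, idx) -> "WindowSet":
        idx = np.asarray(idx)
        return WindowSet(
            self.values[idx],
            [self.labels[i] for i in idx],
            [self.sources[i] for i in idx],
        )

    def windows(self):
        for i in range(len(self)):
            yield Window(self.values[i], self.labels[i], self.sources[i])


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split: seeded shuffle, train size = floor(fraction * total)."""

    train_fraction: float = 0.30
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")


def l2_normalize(x: np.ndarray) -> np.ndarray:
    """Scale a vector to unit Euclidean norm: y = x / sqrt(sum x_i^2)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    norm = float(np.sqrt(np.sum(x * x)))
    if norm == 0.0:
        raise ValueError("cannot L2-normalize an all-zero vector")
    return x / norm


def rescale_unit_interval(y: np.ndarray) -> np.ndarray:
    """Affine map of the whole vector onto [0, 1]: (y - min)/(max - min)."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("input contains non-finite values")
    lo, hi = float(np.min(y)), float(np.max(y))
    if hi == lo:
        raise ValueError("constant input has an undefined [0,1] rescale")
    return (y - lo) / (hi - lo)


def segment(
    recording: Recording,
    window_len: int = 56,
    *,
    values: np.ndarray | None = None,
    support_len: int | None = None,
    recording_id: str = "rec0",
) -> WindowSet:
    """Cut a normalized+rescaled recording into labeled windows.

    ``values`` defaults to the normalize→rescale transform of the raw
    samples.  ``support_len`` is the spike support used for the
    no-spike-content rule for noise windows (defaults to window_len,
    matching the simulator's template support).
    """
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    if values is None:
        values = rescale_unit_interval(l2_normalize(recording.samples))
    values = np.asarray(values, dtype=float)
    if values.shape != recording.samples.shape:
        raise ValueError("values must match the recording length")
    if window_len > values.size:
        raise ValueError("window_len exceeds recording length")
    support_len = window_len if support_len is None else support_len
    half_w = window_len // 2
    half_s = support_len // 2
    n = values.size

    anns = sorted(recording.annotations, key=lambda a: a.time_index)
    peaks = np.array([a.time_index for a in anns], dtype=int)

    rows, labels, sources = [], [], []
    # spike windows: centered on each annotation peak
    for k, ann in enumerate(anns):
        start = ann.time_index - half_w
        stop = start + window_len
        if start < 0 or stop > n:
            continue  # truncated at the recording edge
        clash = False
        for j in (k - 1, k + 1):
            if 0 <= j < len(anns) and anns[j].class_id != ann.class_id:
                o_start = anns[j].time_index - half_s
                if o_start < stop and o_start + support_len > start:
                    clash = True
        if clash:
            continue
        rows.append(values[start:stop])
        labels.append(spike_label(ann.class_id))
        sources.append((recording_id, start))

    # noise windows: non-overlapping stretches free of any spike support
    spike_free = np.ones(n, dtype=bool)
    for p in peaks:
        s = max(p - half_s, 0)
        spike_free[s:s + support_len] = False
    start = 0
    while start + window_len <= n:
        if spike_free[start:start + window_len].all():
            rows.append(values[start:start + window_len])
            labels.append(NOISE_LABEL)
            sources.append((recording_id, start))
            start += window_len
        else:
            # jump to just past the next blocked sample
            blocked = np.flatnonzero(~spike_free[start:start + window_len])
            start += int(blocked[-1]) + 1

    if not rows:
        return WindowSet(np.empty((0, window_len)), [], [])
    return WindowSet(np.stack(rows), labels, sources)


def balance_noise(ws: WindowSet, cap_ratio: float = 1.18, seed: int = 0) -> WindowSet:
    """Subsample noise windows to <= cap_ratio x mean spike-class count."""
    counts = ws.class_counts
    spike_counts = [c for lbl, c in counts.items() if lbl != NOISE_LABEL]
    n_noise = counts.get(NOISE_LABEL, 0)
    if not spike_counts or n_noise == 0:
        return ws
    cap = int(math.floor(cap_ratio * (sum(spike_counts) / len(spike_counts))))
    if n_noise <= cap:
        return ws
    rng = np.random.default_rng(seed)
    noise_idx = np.flatnonzero(np.array(ws.labels) == NOISE_LABEL)
    keep_noise = rng.choice(noise_idx, size=cap, replace=False)
    keep = np.sort(np.concatenate(
        [np.flatnonzero(np.array(ws.labels) != NOISE_LABEL), keep_noise]
    ))
    return ws.subset(keep)


def split(ws: WindowSet, spec: SplitSpec) -> tuple[WindowSet, WindowSet]:
    """Seeded shuffle then disjoint exhaustive train/test partition."""
    total = len(ws)
    if total == 0:
        raise ValueError("cannot split an empty WindowSet")
    order = np.arange(total)
    if spec.shuffle:
        np.random.default_rng(spec.seed).shuffle(order)
    n_train = int(math.floor(spec.train_fraction * total))
    return ws.subset(order[:n_train]), ws.subset(order[n_train:])


def load_binary_epochs(path: str | Path, *, binarize_multiclass: bool = True) -> WindowSet:
    """Read pre-windowed epochs from the feature-columns + ``y`` CSV dialect.

    With ``binarize_multiclass`` (the default), the five-class EEG
    labeling collapses to binary: label 1 -> "seizure", labels 2-5 ->
    "non-seizure".  Rows are already windows, so each row is min-max
    rescaled on its own.
    """
    frame = pd.read_csv(path)
    if "y" not in frame.columns:
        raise ValueError("expected a 'y' label column")
    raw = frame.drop(columns=["y"]).to_numpy(dtype=float)
    y = frame["y"].to_numpy()
    if binarize_multiclass:
        labels = np.where(y == 1, "seizure", "non-seizure")
    else:
        labels = y.astype(str)
    values = np.stack([rescale_unit_interval(row) for row in raw])
    sources = [(str(Path(path).name), i) for i in range(len(frame))]
    return WindowSet(values, list(labels), sources)


def save_windowset(ws: WindowSet, path: str | Path) -> None:
    """CSV: n value columns + label + provenance columns."""
    frame = pd.DataFrame(ws.values, columns=[f"X{i + 1}" for i in range(ws.n)])
    frame["label"] = ws.labels
    frame["source_id"] = [s[0] for s in ws.sources]
    frame["source_start"] = [s[1] for s in ws.sources]
    frame.to_csv(path, index=False, lineterminator="\n")


def load_windowset(path: str | Path) -> WindowSet:
    frame = pd.read_csv(path)
    meta_cols = ["label", "source_id", "source_start"]
    if any(c not in frame.columns for c in meta_cols):
        raise ValueError("not a WindowSet CSV (missing label/source columns)")
    values = frame.drop(columns=meta_cols).to_numpy(dtype=float)
    sources = list(zip(frame["source_id"].astype(str), frame["source_start"].astype(int)))
    return WindowSet(values, frame["label"].astype(str).tolist(), sources)


def write_split_manifest(path: str | Path, spec: SplitSpec,
                         train: WindowSet, test: WindowSet) -> None:
    Path(path).write_text(json.dumps({
        "seed": spec.seed,
        "train_fraction": spec.train_fraction,
        "shuffle": spec.shuffle,
        "train_counts": train.class_counts,
        "test_counts": test.class_counts,
    }, indent=1))
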