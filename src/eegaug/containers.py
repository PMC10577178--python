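"""Core data containers: continuous recordings and labeled window sets."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

GROUPS = ("HC", "MDD")

#: 13-channel montage shared by both study datasets: left hemisphere first
#: (Fp1, F3, C3, P3, O1, F7), then the midline Fz, then the right homologues.
DEFAULT_CHANNELS = (
    "Fp1", "F3", "C3", "P3", "O1", "F7", "Fz",
    "Fp2", "F4", "C4", "P4", "O2", "F8",
)


class EEGError(ValueError):
    """Base class for domain validation errors."""


@dataclass
class Recording:
    """One subject's continuous multichannel EEG with a diagnosis label.

    ``data`` is a ``(channels, samples)`` float array in arbitrary units;
    row order follows ``channel_names``.
    """

    subject_id: str
    group: str
    dataset_id: str
    channel_names: tuple[str, ...]
    sampling_rate: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.channel_names = tuple(self.channel_names)
        self.data = np.asarray(self.data, dtype=float)
        if self.group not in GROUPS:
            raise EEGError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.sampling_rate <= 0:
            raise EEGError("sampling_rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise EEGError(
                f"data must be (n_channels, n_samples) with "
                f"{len(self.channel_names)} rows, got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise EEGError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy(self, **changes) -> "Recording":
        out = replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        return out


@dataclass
class WindowSet:
    """A labeled collection of fixed-length EEG frames with provenance.

    ``frames`` has shape ``(n_frames, n_channels, window_samples)``. Each frame
    carries its source subject, diagnosis group, dataset and a data-type tag
    (``real``, ``noise`` or ``synthetic``). ``normalized`` indicates that every
    value lies in [-1, 1] (joint per-frame min/max scaling).
    """

    frames: np.ndarray
    subject_ids: np.ndarray
    groups: np.ndarray
    dataset_ids: np.ndarray
    channel_names: tuple[str, ...]
    sampling_rate: float
    window_seconds: float = 8.0
    normalized: bool = False
    data_types: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.groups = np.asarray(self.groups, dtype=object)
        self.dataset_ids = np.asarray(self.dataset_ids, dtype=object)
        if self.data_types is None:
            self.data_types = np.asarray(["real"] * len(self.subject_ids), dtype=object)
        else:
            self.data_types = np.asarray(self.data_types, dtype=object)
        self.channel_names = tuple(self.channel_names)
        if self.frames.ndim != 3:
            raise EEGError("frames must be (n, channels, samples)")
        n = self.frames.shape[0]
        for name, arr in (
            ("subject_ids", self.subject_ids),
            ("groups", self.groups),
            ("dataset_ids", self.dataset_ids),
            ("data_types", self.data_types),
        ):
            if len(arr) != n:
                raise EEGError(f"{name} length {len(arr)} != n_frames {n}")
        bad = set(self.groups) - set(GROUPS)
        if bad:
            raise EEGError(f"unknown groups {sorted(bad)}")
        if self.frames.shape[1] != len(self.channel_names):
            raise EEGError("channel axis does not match channel_names")
        if self.normalized and self.n_frames and (
            self.frames.min() < -1.0 - 1e-9 or self.frames.max() > 1.0 + 1e-9
        ):
            raise EEGError("normalized window set has values outside [-1, 1]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def labels(self) -> np.ndarray:
        """Binary labels with MDD as the positive class."""
        return (self.groups == "MDD").astype(float)

    def subjects(self) -> list[str]:
        """Distinct subject ids in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.subject_ids:
            seen.setdefault(s, None)
        return list(seen)

    def select(self, index) -> "WindowSet":
        index = np.asarray(index)
        return WindowSet(
            frames=self.frames[index].copy(),
            subject_ids=self.subject_ids[index].copy(),
            groups=self.groups[index].copy(),
            dataset_ids=self.dataset_ids[index].copy(),
            data_types=self.data_types[index].copy(),
            channel_names=self.channel_names,
            sampling_rate=self.sampling_rate,
            window_seconds=self.window_seconds,
            normalized=self.normalized,
        )

    def for_subject(self, subject_id: str) -> "WindowSet":
        mask = self.subject_ids == subject_id
        if not mask.any():
            raise EEGError(f"unknown subject {subject_id!r}")
        return self.select(mask)

    @classmethod
    def concat(cls, sets: Sequence["WindowSet"]) -> "WindowSet":
        sets = list(sets)
        if not sets:
            raise EEGError("cannot concatenate zero window sets")
        first = sets[0]
        for ws in sets[1:]:
            if ws.frame_shape != first.frame_shape:
                raise EEGError("frame shapes differ across window sets")
            if ws.channel_names != first.channel_names:
                raise EEGError("channel names differ across window sets")
        return cls(
            frames=np.concatenate([ws.frames for ws in sets]),
            subject_ids=np.concatenate([ws.subject_ids for ws in sets]),
            groups=np.concatenate([ws.groups for ws in sets]),
            dataset_ids=np.concatenate([ws.dataset_ids for ws in sets]),
            data_types=np.concatenate([ws.data_types for ws in sets]),
            channel_names=first.channel_names,
            sampling_rate=first.sampling_rate,
            window_seconds=first.window_seconds,
            normalized=all(ws.normalized for ws in sets),
        )


def concat_windowsets(sets: Iterable[WindowSet]) -> WindowSet:
    return WindowSet.concat(list(sets))
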