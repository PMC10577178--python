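"""Shared fixtures: programmatically generated miniature cohorts and frames."""

from __future__ import annotations

import numpy as np
import pytest

from eegaug.containers import Recording, WindowSet

SMALL_CHANNELS = ("Fp1", "F3", "C3", "P3")


def make_windowset(
    frames: np.ndarray,
    subject_ids,
    groups,
    *,
    rate: float = 64.0,
    window_seconds: float = 4.0,
    normalized: bool = False,
    data_types=None,
    channel_names=None,
) -> WindowSet:
    n = frames.shape[0]
    return WindowSet(
        frames=frames,
        subject_ids=np.asarray(subject_ids, dtype=object),
        groups=np.asarray(groups, dtype=object),
        dataset_ids=np.array(["test"] * n, dtype=object),
        data_types=None if data_types is None else np.asarray(data_types, dtype=object),
        channel_names=channel_names
        or tuple(f"ch{i}" for i in range(frames.shape[1])),
        sampling_rate=rate,
        window_seconds=window_seconds,
        normalized=normalized,
    )


def normalized_frames(rng: np.random.Generator, n: int, channels: int,
                      samples: int) -> np.ndarray:
    """Random frames rescaled jointly per frame to span exactly [-1, 1]."""
    fr = rng.standard_normal((n, channels, samples))
    mins = fr.min(axis=(1, 2), keepdims=True)
    maxs = fr.max(axis=(1, 2), keepdims=True)
    return 2.0 * (fr - mins) / (maxs - mins) - 1.0


def balanced_windowset(
    rng: np.random.Generator,
    n_subjects_per_group: int,
    windows_per_subject: int,
    channels: int = 4,
    samples: int = 64,
    normalized: bool = True,
) -> WindowSet:
    """A balanced normalized window set with per-subject provenance."""
    n = 2 * n_subjects_per_group * windows_per_subject
    frames = normalized_frames(rng, n, channels, samples)
    subjects, groups = [], []
    for grp in ("HC", "MDD"):
        for i in range(n_subjects_per_group):
            sid = f"{grp.lower()}{i:03d}"
            subjects += [sid] * windows_per_subject
            groups += [grp] * windows_per_subject
    return make_windowset(frames, subjects, groups, normalized=normalized)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy_recording(rng) -> Recording:
    data = rng.standard_normal((4, 1024))
    return Recording(
        subject_id="s01", group="HC", dataset_id="test",
        channel_names=SMALL_CHANNELS, sampling_rate=64.0, data=data,
    )
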