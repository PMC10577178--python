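"""Preprocessing chain: continuous recordings -> balanced normalized windows.

The chain mirrors standard resting-state EEG cleaning for a two-dataset
MDD/HC study: channel intersection and topological ordering, average
re-referencing, 1-40 Hz zero-phase band-pass, per-subject/channel
z-normalization, 8 s windowing, outlier-window rejection, joint [-1, 1]
rescaling per window, and subsampling to a balanced design.

ICA-based artifact removal (which needs a pretrained component classifier
and real electrode physics) is represented by a pluggable stage whose
default is the identity; the spike filter plus the band-pass cover the
synthetic use case.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import DEFAULT_CHANNELS, EEGError, Recording, WindowSet

#: Fixed 13-channel montage order (left hemisphere, midline, right hemisphere).
ChannelMontage = tuple[str, ...]
DEFAULT_MONTAGE: ChannelMontage = DEFAULT_CHANNELS

#: Aliases for common channel-name spellings, applied case-insensitively.
_CHANNEL_ALIASES = {
    "t3": "T7", "t4": "T8", "t5": "P7", "t6": "P8",
}


class MissingChannelsError(EEGError):
    def __init__(self, missing: Sequence[str]):
        self.missing = tuple(missing)
        super().__init__(f"recording is missing channels: {', '.join(missing)}")


def _canonical(name: str) -> str:
    low = name.strip().lower()
    return _CHANNEL_ALIASES.get(low, low)


def select_and_order_channels(
    recording: Recording, montage: ChannelMontage = DEFAULT_MONTAGE
) -> Recording:
    """Keep exactly the montage channels, reordered to the montage order.

    Matching is case-insensitive and alias-aware; sample data per channel is
    untouched.
    """
    available = {_canonical(n): i for i, n in enumerate(recording.channel_names)}
    missing = [name for name in montage if _canonical(name) not in available]
    if missing:
        raise MissingChannelsError(missing)
    rows = [available[_canonical(name)] for name in montage]
    return recording.copy(
        channel_names=tuple(montage), data=recording.data[rows].copy()
    )


def rereference_average(recording: Recording) -> Recording:
    """Subtract the instantaneous mean across channels (average reference)."""
    if recording.n_channels < 2:
        raise EEGError("average reference requires at least 2 channels")
    data = recording.data - recording.data.mean(axis=0, keepdims=True)
    return recording.copy(data=data)


def bandpass(recording: Recording, low: float = 1.0, high: float = 40.0) -> Recording:
    """Zero-phase Butterworth band-pass (forward-backward, order 5)."""
    nyq = recording.sampling_rate / 2.0
    if not 0 < low < high < nyq:
        raise EEGError(
            f"invalid band ({low}, {high}) Hz for sampling rate "
            f"{recording.sampling_rate} Hz"
        )
    sos = sps.butter(5, [low, high], btype="bandpass", fs=recording.sampling_rate,
                     output="sos")
    data = sps.sosfiltfilt(sos, recording.data, axis=1)
    return recording.copy(data=np.ascontiguousarray(data))


def znormalize_subject(recording: Recording) -> Recording:
    """Scale each channel to mean 0, standard deviation 1."""
    mean = recording.data.mean(axis=1, keepdims=True)
    std = recording.data.std(axis=1, keepdims=True)
    dead = np.flatnonzero(std[:, 0] < 1e-12)
    if dead.size:
        names = [recording.channel_names[i] for i in dead]
        raise EEGError(f"zero-variance channels cannot be z-normalized: {names}")
    return recording.copy(data=(recording.data - mean) / std)


def split_windows(recording: Recording, window_seconds: float = 8.0) -> WindowSet:
    """Cut the recording into consecutive non-overlapping windows.

    The trailing remainder shorter than one window is discarded; each frame
    keeps the subject/group/dataset provenance of its recording.
    """
    nwin = int(round(recording.sampling_rate * window_seconds))
    if nwin < 1:
        raise EEGError("window too short for the sampling rate")
    n_frames = recording.n_samples // nwin
    if n_frames < 1:
        raise EEGError(
            f"recording of {recording.n_samples} samples shorter than one "
            f"{window_seconds} s window ({nwin} samples)"
        )
    frames = recording.data[:, : n_frames * nwin].reshape(
        recording.n_channels, n_frames, nwin
    ).transpose(1, 0, 2)
    n = n_frames
    return WindowSet(
        frames=frames.copy(),
        subject_ids=np.array([recording.subject_id] * n, dtype=object),
        groups=np.array([recording.group] * n, dtype=object),
        dataset_ids=np.array([recording.dataset_id] * n, dtype=object),
        channel_names=recording.channel_names,
        sampling_rate=recording.sampling_rate,
        window_seconds=window_seconds,
        normalized=False,
    )


def remove_outlier_windows(ws: WindowSet) -> tuple[WindowSet, np.ndarray]:
    """Drop frames with extreme minima or maxima, per subject.

    For each subject let ``m_i``/``M_i`` be the minimum/maximum over all
    entries of frame ``i``. Frame ``i`` is flagged iff
    ``m_i < mean(m) - 2*std(m)`` or ``M_i > mean(M) + 2*std(M)``
    (population standard deviation). Flagged frames are removed; the boolean
    flag vector is returned aligned with the input frame order.
    """
    flags = np.zeros(ws.n_frames, dtype=bool)
    for subject in ws.subjects():
        idx = np.flatnonzero(ws.subject_ids == subject)
        if idx.size < 2:
            raise EEGError(
                f"subject {subject!r} has {idx.size} frame(s); "
                "the outlier rule needs at least 2"
            )
        mins = ws.frames[idx].min(axis=(1, 2))
        maxs = ws.frames[idx].max(axis=(1, 2))
        lo = mins.mean() - 2.0 * mins.std()
        hi = maxs.mean() + 2.0 * maxs.std()
        flags[idx] = (mins < lo) | (maxs > hi)
    return ws.select(~flags), flags


def outlier_log(ws: WindowSet, flags: np.ndarray) -> pd.DataFrame:
    """Tabulate removed windows (subject, window index within subject)."""
    rows = []
    counter: dict[str, int] = {}
    for i in range(ws.n_frames):
        sid = ws.subject_ids[i]
        k = counter.get(sid, 0)
        counter[sid] = k + 1
        if flags[i]:
            rows.append({"subject_id": sid, "window_index": k,
                         "reason": "min/max beyond 2 std of subject average"})
    return pd.DataFrame(rows, columns=["subject_id", "window_index", "reason"])


def rescale_minus1_1(ws: WindowSet) -> WindowSet:
    """Rescale each frame jointly over channels to span exactly [-1, 1].

    The joint (not per-channel) scaling preserves inter-channel amplitude
    relations, which are clinically meaningful.
    """
    mins = ws.frames.min(axis=(1, 2), keepdims=True)
    maxs = ws.frames.max(axis=(1, 2), keepdims=True)
    if np.any(maxs - mins <= 0):
        bad = np.flatnonzero((maxs - mins).ravel() <= 0)
        raise EEGError(f"constant frames cannot be rescaled: indices {bad.tolist()}")
    out = ws.select(np.arange(ws.n_frames))
    out.frames = 2.0 * (ws.frames - mins) / (maxs - mins) - 1.0
    out.normalized = True
    return out


def subsample_balance(
    windows: WindowSet | Iterable[WindowSet], seed: int = 0
) -> WindowSet:
    """Balance the design: equal subjects per group, equal windows per subject.

    Subjects per group are subsampled (uniformly, seeded) to the smaller
    group; windows per subject to the minimum count over retained subjects.
    """
    ws = windows if isinstance(windows, WindowSet) else WindowSet.concat(list(windows))
    rng = np.random.default_rng(seed)
    by_group: dict[str, list[str]] = {"HC": [], "MDD": []}
    for subject in ws.subjects():
        grp = ws.groups[ws.subject_ids == subject][0]
        by_group[grp].append(subject)
    if not by_group["HC"] or not by_group["MDD"]:
        raise EEGError("both groups must be non-empty")
    n_keep = min(len(by_group["HC"]), len(by_group["MDD"]))
    kept: list[str] = []
    for grp in ("HC", "MDD"):
        subjects = sorted(by_group[grp])
        sel = rng.choice(len(subjects), size=n_keep, replace=False)
        kept.extend(subjects[i] for i in sorted(sel))
    counts = {s: int((ws.subject_ids == s).sum()) for s in kept}
    if min(counts.values()) < 1:
        raise EEGError("a retained subject has zero windows")
    n_win = min(counts.values())
    picks: list[int] = []
    for subject in kept:
        idx = np.flatnonzero(ws.subject_ids == subject)
        sel = rng.choice(idx.size, size=n_win, replace=False)
        picks.extend(idx[i] for i in sorted(sel))
    return ws.select(np.array(picks))


ArtifactStage = Callable[[Recording], Recording]


def no_op_artifact_removal(recording: Recording) -> Recording:
    """Pluggable artifact-removal stage; the default does nothing."""
    return recording


def preprocess_recording(
    recording: Recording,
    montage: ChannelMontage = DEFAULT_MONTAGE,
    low: float = 1.0,
    high: float = 40.0,
    window_seconds: float = 8.0,
    artifact_stage: ArtifactStage = no_op_artifact_removal,
) -> tuple[WindowSet, np.ndarray]:
    """Run the per-subject chain; returns (normalized windows, outlier flags)."""
    rec = select_and_order_channels(recording, montage)
    rec = rereference_average(rec)
    rec = bandpass(rec, low, high)
    rec = artifact_stage(rec)
    rec = znormalize_subject(rec)
    ws = split_windows(rec, window_seconds)
    ws, flags = remove_outlier_windows(ws)
    return rescale_minus1_1(ws), flags


def preprocess_cohort(
    recordings: Sequence[Recording],
    montage: ChannelMontage = DEFAULT_MONTAGE,
    low: float = 1.0,
    high: float = 40.0,
    window_seconds: float = 8.0,
    artifact_stage: ArtifactStage = no_op_artifact_removal,
    balance_seed: int | None = 0,
) -> tuple[WindowSet, pd.DataFrame]:
    """Preprocess every recording and optionally balance the cohort.

    Returns the (balanced) normalized window set and the log of removed
    outlier windows. Pass ``balance_seed=None`` to skip subsampling (e.g.,
    when preparing GAN training data, which uses all available windows).
    """
    cleaned: list[WindowSet] = []
    logs: list[pd.DataFrame] = []
    for rec in recordings:
        sel = select_and_order_channels(rec, montage)
        sel = rereference_average(sel)
        sel = bandpass(sel, low, high)
        sel = artifact_stage(sel)
        sel = znormalize_subject(sel)
        ws = split_windows(sel, window_seconds)
        kept, flags = remove_outlier_windows(ws)
        logs.append(outlier_log(ws, flags))
        cleaned.append(rescale_minus1_1(kept))
    combined = WindowSet.concat(cleaned)
    if balance_seed is not None:
        combined = subsample_balance(combined, seed=balance_seed)
    log = pd.concat(logs, ignore_index=True) if logs else outlier_log(
        combined, np.zeros(0, dtype=bool)
    )
    return combined, log
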