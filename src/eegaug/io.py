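"""HDF5 cohort/window containers, GAN checkpoints and optional EDF import."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from . import gan as gan_mod
from .containers import EEGError, Recording, WindowSet


def save_cohort(recordings: Sequence[Recording], path) -> None:
    """One HDF5 group per subject: data matrix + label/rate/channel attrs."""
    path = Path(path)
    manifest = []
    with h5py.File(path, "w") as f:
        for rec in recordings:
            grp = f.create_group(rec.subject_id)
            grp.create_dataset("data", data=rec.data, compression="gzip")
            grp.attrs["group"] = rec.group
            grp.attrs["dataset_id"] = rec.dataset_id
            grp.attrs["sampling_rate"] = rec.sampling_rate
            grp.attrs["channel_names"] = list(rec.channel_names)
            manifest.append({
                "subject_id": rec.subject_id,
                "group": rec.group,
                "dataset_id": rec.dataset_id,
                "sampling_rate": rec.sampling_rate,
                "n_channels": rec.n_channels,
                "n_samples": rec.n_samples,
            })
        f.attrs["manifest"] = json.dumps(manifest)


def load_cohort(path) -> list[Recording]:
    recordings = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f.keys()):
            grp = f[sid]
            recordings.append(Recording(
                subject_id=sid,
                group=str(grp.attrs["group"]),
                dataset_id=str(grp.attrs["dataset_id"]),
                channel_names=tuple(
                    str(c) for c in np.asarray(grp.attrs["channel_names"])
                ),
                sampling_rate=float(grp.attrs["sampling_rate"]),
                data=grp["data"][...],
            ))
    return recordings


_STR = h5py.string_dtype(encoding="utf-8")


def save_windowset(ws: WindowSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=ws.frames, compression="gzip")
        for name in ("subject_ids", "groups", "dataset_ids", "data_types"):
            values = [str(v) for v in getattr(ws, name)]
            f.create_dataset(name, data=values, dtype=_STR)
        f.attrs["channel_names"] = list(ws.channel_names)
        f.attrs["sampling_rate"] = ws.sampling_rate
        f.attrs["window_seconds"] = ws.window_seconds
        f.attrs["normalized"] = ws.normalized


def load_windowset(path) -> WindowSet:
    with h5py.File(path, "r") as f:
        fields = {
            name: np.array([s.decode() if isinstance(s, bytes) else str(s)
                            for s in f[name][...]], dtype=object)
            for name in ("subject_ids", "groups", "dataset_ids", "data_types")
        }
        return WindowSet(
            frames=f["frames"][...],
            channel_names=tuple(str(c) for c in np.asarray(f.attrs["channel_names"])),
            sampling_rate=float(f.attrs["sampling_rate"]),
            window_seconds=float(f.attrs["window_seconds"]),
            normalized=bool(f.attrs["normalized"]),
            **fields,
        )


def _bundle_base(path) -> str:
    base = str(path)
    return base[:-4] if base.endswith(".npz") else base


def save_bundle(bundle: gan_mod.GanBundle, path) -> None:
    """Checkpoint: npz of parameters/BN state + JSON sidecar with the specs.

    ``path`` is the checkpoint base name; ``<base>.npz`` and ``<base>.json``
    are written. Parameters round-trip bit-exactly.
    """
    base = _bundle_base(path)
    arrays = {}
    for tag, model in (("g", bundle.generator), ("c", bundle.critic)):
        for i, p in enumerate(model.seq.all_params):
            arrays[f"{tag}_param_{i}"] = p
        for j, lay in enumerate(model.seq.layers):
            if hasattr(lay, "running_mean"):
                arrays[f"{tag}_rmean_{j}"] = lay.running_mean
                arrays[f"{tag}_rvar_{j}"] = lay.running_var
    arrays["critic_loss_history"] = np.asarray(bundle.critic_loss_history)
    arrays["generator_loss_history"] = np.asarray(bundle.generator_loss_history)
    np.savez(base + ".npz", **arrays)
    sidecar = {
        "generator_spec": asdict(bundle.generator_spec),
        "critic_spec": asdict(bundle.critic_spec),
        "config": asdict(bundle.config),
        "labels": list(bundle.labels),
        "channel_names": list(bundle.channel_names or []),
        "sampling_rate": bundle.sampling_rate,
        "window_seconds": bundle.window_seconds,
    }
    Path(base + ".json").write_text(json.dumps(sidecar, indent=2))


def _tupled(d: dict, keys: tuple[str, ...]) -> dict:
    out = dict(d)
    for k in keys:
        if k in out and isinstance(out[k], list):
            out[k] = tuple(
                tuple(v) if isinstance(v, list) else v for v in out[k]
            ) if out[k] and isinstance(out[k][0], list) else tuple(out[k])
    return out


def load_bundle(path) -> gan_mod.GanBundle:
    base = _bundle_base(path)
    sidecar = json.loads(Path(base + ".json").read_text())
    gspec = gan_mod.GeneratorSpec(
        **_tupled(sidecar["generator_spec"], ("output_shape", "kernel"))
    )
    cspec = gan_mod.CriticSpec(
        **_tupled(sidecar["critic_spec"],
                  ("input_shape", "conv_strides", "conv_filters", "kernel"))
    )
    config = gan_mod.GanTrainingConfig(**sidecar["config"])
    generator = gan_mod.build_generator(gspec, len(sidecar["labels"]))
    critic = gan_mod.build_critic(cspec, len(sidecar["labels"]))
    with np.load(base + ".npz") as data:
        for tag, model in (("g", generator), ("c", critic)):
            for i, p in enumerate(model.seq.all_params):
                p[...] = data[f"{tag}_param_{i}"]
            for j, lay in enumerate(model.seq.layers):
                if hasattr(lay, "running_mean"):
                    lay.running_mean[...] = data[f"{tag}_rmean_{j}"]
                    lay.running_var[...] = data[f"{tag}_rvar_{j}"]
        closs = [float(v) for v in data["critic_loss_history"]]
        gloss = [float(v) for v in data["generator_loss_history"]]
    return gan_mod.GanBundle(
        generator=generator, critic=critic, generator_spec=gspec,
        critic_spec=cspec, config=config,
        critic_loss_history=closs, generator_loss_history=gloss,
        labels=tuple(sidecar["labels"]),
        channel_names=tuple(sidecar["channel_names"]) or None,
        sampling_rate=float(sidecar["sampling_rate"]),
        window_seconds=float(sidecar["window_seconds"]),
    )


def import_edf(path, group: str, subject_id: str | None = None,
               dataset_id: str = "edf") -> Recording:
    """Read one subject's EDF file into a :class:`Recording` (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise EEGError("EDF import requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(
        subject_id=subject_id or Path(path).stem,
        group=group,
        dataset_id=dataset_id,
        channel_names=tuple(raw.ch_names),
        sampling_rate=float(raw.info["sfreq"]),
        data=raw.get_data(),
    )
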