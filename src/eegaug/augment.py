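"""Noise-based augmentation baseline.

Adds i.i.d. uniform noise (default +-0.1, i.e. 10% of the normalized signal
range) to normalized windows and re-applies the joint [-1, 1] rescaling.
This is the non-generative comparison condition for the GAN-synthesized
data: spectrally it is near-neutral at the band-power granularity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EEGError, WindowSet
from .preprocess import rescale_minus1_1


@dataclass(frozen=True)
class NoiseSpec:
    """Uniform-noise amplitude as a fraction of the normalized range."""

    amplitude: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise EEGError("noise amplitude must be >= 0")


def add_uniform_noise(ws: WindowSet, spec: NoiseSpec) -> WindowSet:
    """Return a noise-augmented copy of a normalized window set.

    Noise is independent per channel and sample. With ``amplitude == 0`` the
    input is returned unchanged (as a copy). Labels and provenance are kept;
    the data-type tag becomes ``"noise"``.
    """
    if not ws.normalized:
        raise EEGError("noise augmentation expects a normalized window set")
    out = ws.select(np.arange(ws.n_frames))
    if spec.amplitude == 0:
        return out
    rng = np.random.default_rng(spec.seed)
    out.frames = ws.frames + rng.uniform(
        -spec.amplitude, spec.amplitude, size=ws.frames.shape
    )
    out.normalized = False
    out = rescale_minus1_1(out)
    out.data_types = np.array(["noise"] * out.n_frames, dtype=object)
    return out
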