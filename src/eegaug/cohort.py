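"""Seeded synthetic EEG cohort generation.

Recordings are synthesized as filtered Gaussian noise shaped in the frequency
domain: the target power spectral density is a 1/f-type background (power
proportional to f^-exponent), multiplied by per-band offset factors and
augmented with Gaussian bumps at the delta and alpha centers. The default
parameters emulate eyes-closed resting-state EEG: most power below 15 Hz,
peaks in delta and alpha, a dip in theta, and elevated low-frequency (delta/
theta) power in the MDD group.

Channels share a common latent source mixed with independent per-channel
noise so that the expected pairwise correlation equals
``channel_correlation``. Per-subject log-normal jitter of the spectral
parameters (``subject_variability``) supplies the between-subject variance
that any between-subjects analysis of the cohort requires; resting EEG band
power is highly heterogeneous across individuals, so the default sigma is
deliberately large (0.5).

Every operation is a pure function of its inputs and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .containers import DEFAULT_CHANNELS, GROUPS, EEGError, Recording

#: Clinical band edges in Hz, half-open intervals [low, high).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.3, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
}


def _per_group(value, name: str) -> dict:
    """Broadcast a single value to both groups, or validate a per-group dict."""
    if isinstance(value, Mapping):
        missing = set(GROUPS) - set(value)
        if missing:
            raise EEGError(f"{name} missing groups {sorted(missing)}")
        return {g: value[g] for g in GROUPS}
    return {g: value for g in GROUPS}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a synthetic two-group resting-state EEG cohort.

    Peak tuples are ``(center_hz, bandwidth_hz, amplitude)`` where amplitude
    is in units of the background power at 1 Hz. ``band_offsets`` multiply
    the 1/f background power within each clinical band, per group.
    """

    n_hc: int = 24
    n_mdd: int = 24
    sampling_rate: float = 250.0
    duration: float = 300.0
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    one_over_f_exponent: Mapping[str, float] | float = 1.2
    alpha_peak: Mapping[str, tuple] | tuple = (10.0, 1.5, 0.3)
    delta_bump: Mapping[str, tuple] | tuple = (1.5, 0.8, 0.6)
    band_offsets: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "HC": {"delta": 1.0, "theta": 0.55, "alpha": 1.0, "beta": 1.0},
            "MDD": {"delta": 1.35, "theta": 0.75, "alpha": 1.0, "beta": 1.0},
        }
    )
    channel_correlation: float = 0.6
    artifact_rate: float = 0.0
    artifact_magnitude: float = 10.0
    subject_variability: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc < 1 or self.n_mdd < 1:
            raise EEGError("n_hc and n_mdd must be >= 1")
        if self.sampling_rate <= 0:
            raise EEGError("sampling_rate must be positive")
        if self.duration <= 0:
            raise EEGError("duration must be positive")
        if not 0.0 <= self.channel_correlation <= 1.0:
            raise EEGError("channel_correlation must lie in [0, 1]")
        if self.artifact_rate < 0:
            raise EEGError("artifact_rate must be non-negative")
        if len(self.channel_names) < 1:
            raise EEGError("at least one channel required")
        for name in ("alpha_peak", "delta_bump"):
            for g, (c, bw, amp) in _per_group(getattr(self, name), name).items():
                if amp < 0:
                    raise EEGError(f"{name} amplitude must be >= 0 (group {g})")
                if bw <= 0:
                    raise EEGError(f"{name} bandwidth must be positive (group {g})")

    # resolved per-group views -------------------------------------------------
    def exponent(self) -> dict[str, float]:
        return _per_group(self.one_over_f_exponent, "one_over_f_exponent")

    def alpha(self) -> dict[str, tuple]:
        return _per_group(self.alpha_peak, "alpha_peak")

    def delta(self) -> dict[str, tuple]:
        return _per_group(self.delta_bump, "delta_bump")

    def offsets(self) -> dict[str, dict[str, float]]:
        out = {}
        for g in GROUPS:
            off = dict(self.band_offsets[g])
            missing = set(BANDS) - set(off)
            if missing:
                raise EEGError(f"band_offsets[{g}] missing bands {sorted(missing)}")
            out[g] = off
        return out


def _target_psd(
    freqs: np.ndarray,
    exponent: float,
    alpha: tuple,
    delta: tuple,
    offsets: Mapping[str, float],
) -> np.ndarray:
    """Target one-sided PSD on the rfft frequency grid (arbitrary units)."""
    f = np.maximum(freqs, 0.5)  # clamp so the 1/f pole stays finite
    background = f ** (-exponent)
    mult = np.ones_like(freqs)
    for band, (lo, hi) in BANDS.items():
        mult[(freqs >= lo) & (freqs < hi)] = offsets[band]
    ac, abw, aamp = alpha
    dc, dbw, damp = delta
    psd = background * mult
    psd = psd + aamp * np.exp(-0.5 * ((freqs - ac) / abw) ** 2)
    psd = psd + damp * np.exp(-0.5 * ((freqs - dc) / dbw) ** 2)
    psd[freqs == 0] = 0.0
    return psd


def generate_recording(
    spec: SyntheticCohortSpec, subject_id: str, group: str, seed: int
) -> Recording:
    """Synthesize one subject's continuous recording.

    The signal is the inverse transform of a white complex-Gaussian spectrum
    scaled by the square root of the group's target PSD (with per-subject
    parameter jitter), so the expected periodogram follows the target PSD.
    Identical ``(spec, subject_id, group, seed)`` reproduce the data exactly.
    """
    if group not in GROUPS:
        raise EEGError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration * spec.sampling_rate))
    if n < 2:
        raise EEGError("duration x sampling_rate must give at least 2 samples")
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.sampling_rate)

    # per-subject spectral jitter (consistent across channels)
    sv = spec.subject_variability
    exponent = spec.exponent()[group] + 0.2 * sv * rng.standard_normal()
    ac, abw, aamp = spec.alpha()[group]
    dc, dbw, damp = spec.delta()[group]
    aamp = aamp * np.exp(sv * rng.standard_normal())
    damp = damp * np.exp(sv * rng.standard_normal())
    offsets = {
        band: v * np.exp(sv * rng.standard_normal())
        for band, v in spec.offsets()[group].items()
    }
    amp = np.sqrt(_target_psd(freqs, exponent, (ac, abw, aamp), (dc, dbw, damp), offsets))

    def shaped_noise() -> np.ndarray:
        z = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
        return np.fft.irfft(amp * z, n=n)

    rho = spec.channel_correlation
    shared = shaped_noise()
    data = np.empty((len(spec.channel_names), n))
    for c in range(len(spec.channel_names)):
        data[c] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * shaped_noise()

    rec = Recording(
        subject_id=subject_id,
        group=group,
        dataset_id="synthetic",
        channel_names=spec.channel_names,
        sampling_rate=spec.sampling_rate,
        data=data,
    )
    if spec.artifact_rate > 0:
        rec = inject_spike_artifacts(
            rec,
            rate=spec.artifact_rate,
            magnitude=spec.artifact_magnitude,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    return rec


def generate_cohort(spec: SyntheticCohortSpec) -> list[Recording]:
    """Generate ``n_hc + n_mdd`` recordings with per-subject derived seeds."""
    ss = np.random.SeedSequence(spec.seed)
    seeds = ss.generate_state(spec.n_hc + spec.n_mdd)
    recordings = []
    k = 0
    for group, count in (("HC", spec.n_hc), ("MDD", spec.n_mdd)):
        for i in range(count):
            sid = f"{group.lower()}{i + 1:03d}"
            recordings.append(generate_recording(spec, sid, group, int(seeds[k])))
            k += 1
    return recordings


def inject_spike_artifacts(
    recording: Recording, rate: float, magnitude: float, seed: int
) -> Recording:
    """Add short (<= 50 ms) high-amplitude transients at Poisson times.

    ``rate`` is the expected number of spikes per minute across the whole
    recording; ``magnitude`` scales each spike relative to the pre-injection
    standard deviation of its channel. Returns a modified copy.
    """
    if rate < 0:
        raise EEGError("artifact rate must be non-negative")
    if magnitude <= 0:
        raise EEGError("artifact magnitude must be positive")
    out = recording.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    minutes = recording.duration / 60.0
    n_spikes = rng.poisson(rate * minutes)
    stds = recording.data.std(axis=1)
    width = max(1, int(round(0.04 * recording.sampling_rate)))  # 40 ms
    window = np.hanning(width + 2)[1:-1] if width > 1 else np.ones(1)
    for _ in range(n_spikes):
        t0 = int(rng.integers(0, recording.n_samples))
        ch = int(rng.integers(0, recording.n_channels))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        stop = min(t0 + width, recording.n_samples)
        out.data[ch, t0:stop] += sign * magnitude * stds[ch] * window[: stop - t0]
    return out
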