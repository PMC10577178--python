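"""Spectral evaluation: periodograms, band powers and band-power tables.

Band power is the *mean* periodogram power over the bins of a clinical band
(delta 0.3-4, theta 4-8, alpha 8-12, beta 12-30 Hz; half-open intervals).
For real and noise data the analysis unit is the subject (mean spectrum
across that subject's windows, a robust individual estimate); for synthetic
data each sampled frame acts as one pseudo-subject, with the number of
frames matched to the number of subjects per clinical group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .cohort import BANDS
from .containers import EEGError, WindowSet


def periodogram(series: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Standard (boxcar, un-detrended) periodogram.

    1-D input: one channel. 2-D input ``(channels, samples)``: per-channel
    periodograms averaged across channels. Frequency resolution is
    ``rate / n_samples``; total power integrates to the mean square value.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0 or series.shape[-1] < 2:
        raise EEGError("periodogram needs a series of length >= 2")
    freqs, power = sps.periodogram(
        series, fs=rate, window="boxcar", detrend=False, axis=-1
    )
    if series.ndim == 2:
        power = power.mean(axis=0)
    return freqs, power


def frame_spectra(ws: WindowSet) -> tuple[np.ndarray, np.ndarray]:
    """Channel-averaged periodogram of every frame; returns (freqs, (n, nf))."""
    if ws.n_frames == 0:
        raise EEGError("empty window set")
    freqs, _ = periodogram(ws.frames[0], ws.sampling_rate)
    _, power = sps.periodogram(
        ws.frames, fs=ws.sampling_rate, window="boxcar", detrend=False, axis=-1
    )
    return freqs, power.mean(axis=1)


def subject_mean_spectrum(ws: WindowSet, subject: str) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean of the per-frame periodograms of one subject."""
    sub = ws.for_subject(subject)
    freqs, power = frame_spectra(sub)
    return freqs, power.mean(axis=0)


def band_power(freqs: np.ndarray, power: np.ndarray, band) -> float:
    """Mean power over bins with ``low <= f < high``.

    ``band`` is a band name from :data:`~eegaug.cohort.BANDS` or a
    ``(low, high)`` tuple.
    """
    lo, hi = BANDS[band] if isinstance(band, str) else band
    mask = (freqs >= lo) & (freqs < hi)
    if not mask.any():
        raise EEGError(f"no frequency bins inside band [{lo}, {hi}) Hz")
    return float(np.asarray(power)[..., mask].mean())


def match_synthetic_units(
    ws: WindowSet, n_per_group: int, seed: int = 0
) -> WindowSet:
    """Seeded selection of exactly ``n_per_group`` frames per group.

    Each selected frame acts as one analysis unit (pseudo-subject) so that
    synthetic data enter the between-subjects analyses with the same unit
    count as the real cohort.
    """
    rng = np.random.default_rng(seed)
    picks: list[int] = []
    for grp in ("HC", "MDD"):
        idx = np.flatnonzero(ws.groups == grp)
        if idx.size < n_per_group:
            raise EEGError(
                f"insufficient frames for group {grp}: have {idx.size}, "
                f"need {n_per_group}"
            )
        sel = rng.choice(idx.size, size=n_per_group, replace=False)
        picks.extend(idx[i] for i in sorted(sel))
    return ws.select(np.array(picks))


def band_power_table(
    *windowsets: WindowSet,
    n_units_per_group: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format per-unit band powers for the two-way ANOVA and plots.

    Real/noise window sets contribute one row per (subject, band); synthetic
    sets one row per (matched frame, band). Columns: ``unit_id``,
    ``unit_kind``, ``diagnosis``, ``data_type``, ``band``, ``power``.
    """
    rows = []
    for ws in windowsets:
        types = set(ws.data_types)
        if types <= {"real", "noise"}:
            for subject in ws.subjects():
                sub = ws.for_subject(subject)
                freqs, spec = frame_spectra(sub)
                mean_spec = spec.mean(axis=0)
                for band in BANDS:
                    rows.append({
                        "unit_id": f"{sub.data_types[0]}:{subject}",
                        "unit_kind": "subject",
                        "diagnosis": sub.groups[0],
                        "data_type": sub.data_types[0],
                        "band": band,
                        "power": band_power(freqs, mean_spec, band),
                    })
        elif types == {"synthetic"}:
            if n_units_per_group is None:
                raise EEGError(
                    "n_units_per_group is required for synthetic window sets"
                )
            matched = match_synthetic_units(ws, n_units_per_group, seed=seed)
            freqs, spec = frame_spectra(matched)
            for i in range(matched.n_frames):
                for band in BANDS:
                    rows.append({
                        "unit_id": f"synthetic:{matched.subject_ids[i]}",
                        "unit_kind": "synthetic frame-group",
                        "diagnosis": matched.groups[i],
                        "data_type": "synthetic",
                        "band": band,
                        "power": band_power(freqs, spec[i], band),
                    })
        else:
            raise EEGError(f"window set mixes data types {sorted(types)}")
    table = pd.DataFrame(rows)
    if (table["power"] < 0).any():
        raise EEGError("negative band power")
    return table


def mean_spectrum_with_ci(
    spectra: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise mean and 95% t-interval across units; for CSV plot export."""
    from scipy import stats as st

    spectra = np.asarray(spectra)
    n = spectra.shape[0]
    mean = spectra.mean(axis=0)
    if n < 2:
        return mean, mean, mean
    half = st.t.ppf(0.975, n - 1) * spectra.std(axis=0, ddof=1) / np.sqrt(n)
    return mean, mean - half, mean + half
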