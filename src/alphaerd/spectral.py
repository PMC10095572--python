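"""Spectral reduction: epoching, artifact rejection, periodograms, band powers.

The estimator is deliberately simple and classical: non-overlapping fixed-length
epochs, an automated peak-to-peak artifact surrogate, per-epoch FFT periodograms
averaged across retained epochs (Bartlett's method), and band power as the sum of
periodogram bins falling in a half-open frequency interval.  With a rectangular
window the periodogram satisfies Parseval's identity exactly, which the tests
exploit as an oracle.  Because the downstream desynchronization statistic is a
power *ratio*, the absolute normalization convention cancels out.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .eeg_io import EEGRecording

__all__ = [
    "Band",
    "ALPHA1",
    "ALPHA2",
    "DEFAULT_BANDS",
    "EpochSet",
    "InsufficientDataError",
    "segment",
    "reject_artifacts",
    "epoch_spectrum",
    "band_power",
    "band_power_table",
    "recording_band_powers",
]


@dataclass(frozen=True)
class Band:
    """Half-open frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError(f"band {self.name}: f_lo must be < f_hi")

    def bin_mask(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.f_lo) & (freqs < self.f_hi)


#: Lower alpha sub-band, 8-10.99 Hz (bins 8.00-10.75 at 0.25 Hz resolution).
ALPHA1 = Band("alpha1", 8.0, 11.0)
#: Upper alpha sub-band, 11-12.99 Hz (bins 11.00-12.75 at 0.25 Hz resolution).
ALPHA2 = Band("alpha2", 11.0, 13.0)

DEFAULT_BANDS = (ALPHA1, ALPHA2)


class InsufficientDataError(RuntimeError):
    """Raised when too few artifact-free epochs remain for a subject/condition."""


@dataclass
class EpochSet:
    """Fixed-length epochs of a multichannel recording."""

    subject_id: str
    condition: str
    channel_labels: tuple[str, ...]
    sampling_rate: float
    epochs: np.ndarray  # (n_epochs, n_channels, n_samples)
    rejected_count: int = 0

    @property
    def retained_count(self) -> int:
        return int(self.epochs.shape[0])

    @property
    def epoch_len_s(self) -> float:
        return self.epochs.shape[2] / self.sampling_rate


def segment(recording: EEGRecording, epoch_len_s: float = 4.0) -> EpochSet:
    """Cut a recording into consecutive non-overlapping epochs.

    The trailing remainder shorter than one epoch is discarded.
    """
    n_samp = int(round(epoch_len_s * recording.sampling_rate))
    total = recording.samples.shape[1]
    if total < n_samp:
        raise ValueError(
            f"recording {recording.subject_id}/{recording.condition} shorter than "
            f"one {epoch_len_s} s epoch"
        )
    n_ep = total // n_samp
    cut = recording.samples[:, : n_ep * n_samp]
    epochs = cut.reshape(cut.shape[0], n_ep, n_samp).transpose(1, 0, 2).copy()
    return EpochSet(
        subject_id=recording.subject_id,
        condition=recording.condition,
        channel_labels=tuple(recording.channel_labels),
        sampling_rate=recording.sampling_rate,
        epochs=epochs,
    )


def reject_artifacts(
    epoch_set: EpochSet,
    peak_to_peak_threshold_uV: float = 100.0,
    min_epochs: int = 30,
) -> EpochSet:
    """Drop epochs whose peak-to-peak amplitude exceeds the threshold on any channel.

    An automated surrogate for visual artifact screening.  Raises
    :class:`InsufficientDataError` when fewer than ``min_epochs`` epochs survive.
    """
    if peak_to_peak_threshold_uV <= 0:
        raise ValueError("peak_to_peak_threshold_uV must be > 0")
    p2p = epoch_set.epochs.max(axis=2) - epoch_set.epochs.min(axis=2)  # (ep, ch)
    keep = (p2p <= peak_to_peak_threshold_uV).all(axis=1)
    retained = epoch_set.epochs[keep]
    out = replace(
        epoch_set,
        epochs=retained,
        rejected_count=epoch_set.rejected_count + int((~keep).sum()),
    )
    if out.retained_count < min_epochs:
        raise InsufficientDataError(
            f"subject {epoch_set.subject_id}, condition {epoch_set.condition}: "
            f"only {out.retained_count} artifact-free epochs (< {min_epochs})"
        )
    return out


def epoch_spectrum(
    epoch: np.ndarray, sampling_rate: float, window: str = "rect"
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum of one epoch (last axis = time), in signal units².

    Normalized so that the spectrum sums to the mean squared signal (Parseval).
    ``window='hann'`` applies a Hann taper with gain compensation; the default
    rectangular window keeps Parseval exact.
    """
    epoch = np.asarray(epoch, dtype=float)
    if not np.all(np.isfinite(epoch)):
        raise ValueError("epoch contains non-finite samples")
    n = epoch.shape[-1]
    if window == "rect":
        tapered = epoch
        gain = 1.0
    elif window == "hann":
        w = np.hanning(n)
        tapered = epoch * w
        gain = float(np.mean(w**2))
    else:
        raise ValueError(f"unknown window {window!r}")
    spec = np.abs(np.fft.rfft(tapered, axis=-1)) ** 2 / (n * n * gain)
    # fold negative frequencies into the one-sided spectrum
    if n % 2 == 0:
        spec[..., 1:-1] *= 2.0
    else:
        spec[..., 1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    return freqs, spec


def band_power(freqs: np.ndarray, spectrum: np.ndarray, band: Band) -> float | np.ndarray:
    """Sum of spectrum bins with f_lo <= f < f_hi (half-open interval)."""
    nyquist = float(freqs[-1])
    if band.f_lo >= nyquist:
        raise ValueError(f"band {band.name} lies outside the Nyquist range")
    mask = band.bin_mask(freqs)
    return spectrum[..., mask].sum(axis=-1)


def mean_spectrum(epoch_set: EpochSet, window: str = "rect") -> tuple[np.ndarray, np.ndarray]:
    """Bartlett average: mean of per-epoch periodograms, per channel."""
    if epoch_set.retained_count == 0:
        raise InsufficientDataError(
            f"no epochs to average for {epoch_set.subject_id}/{epoch_set.condition}"
        )
    freqs, specs = epoch_spectrum(epoch_set.epochs, epoch_set.sampling_rate, window)
    return freqs, specs.mean(axis=0)  # (n_channels, n_freqs)


def band_power_table(
    epoch_set: EpochSet,
    bands: tuple[Band, ...] = DEFAULT_BANDS,
    window: str = "rect",
):
    """Tidy per-channel absolute band powers for one subject/condition.

    Returns a DataFrame with columns
    (subject_id, condition, channel, band, absolute_power).
    """
    import pandas as pd

    freqs, mspec = mean_spectrum(epoch_set, window)
    rows = []
    for ci, ch in enumerate(epoch_set.channel_labels):
        for band in bands:
            rows.append(
                {
                    "subject_id": epoch_set.subject_id,
                    "condition": epoch_set.condition,
                    "channel": ch,
                    "band": band.name,
                    "absolute_power": float(band_power(freqs, mspec[ci], band)),
                }
            )
    return pd.DataFrame(rows)


def recording_band_powers(
    recording: EEGRecording,
    bands: tuple[Band, ...] = DEFAULT_BANDS,
    epoch_len_s: float = 4.0,
    p2p_threshold_uV: float = 100.0,
    min_epochs: int = 30,
    window: str = "rect",
):
    """Full spectral reduction of one recording: segment → reject → average → integrate.

    Returns ``(band_power_frame, epoch_set)`` so callers can log retention counts.
    """
    es = segment(recording, epoch_len_s)
    es = reject_artifacts(es, p2p_threshold_uV, min_epochs)
    return band_power_table(es, bands, window), es
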