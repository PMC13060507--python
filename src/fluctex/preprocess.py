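"""Band-pass filtering, epoch segmentation and amplitude-based epoch screening.

The pipeline filters the continuous record first (zero-phase, so epoch
boundaries carry no phase distortion), then cuts contiguous non-overlapping
fixed-length epochs, and optionally rejects epochs whose peak amplitude
betrays gross artifacts. Defaults follow the extraction protocol: a 3-14 Hz
band-pass and 2-second epochs, which on a 3-minute record yield 90 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import EmptyAnalysisError, ParameterError
from .recording_io import Recording

DEFAULT_BAND = (3.0, 14.0)
DEFAULT_EPOCH_LEN_S = 2.0
DEFAULT_AMP_LIMIT_UV = 100.0
DEFAULT_FILTER_ORDER = 4


@dataclass
class EpochArray:
    """Contiguous fixed-length epochs cut from one recording.

    Attributes
    ----------
    data : ndarray, shape (n_epochs, n_channels, n_samples_per_epoch)
        Potentials in microvolts; epochs in temporal order.
    fs : float
        Sampling rate (Hz).
    epoch_len_s : float
        Epoch length in seconds; ``fs * epoch_len_s`` is an exact integer.
    channel_labels : list of str
    kept_mask : ndarray of bool, shape (n_epochs,)
        False for epochs rejected by screening.
    """

    data: np.ndarray
    fs: float
    epoch_len_s: float
    channel_labels: list[str]
    kept_mask: np.ndarray

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())

    @property
    def kept_data(self) -> np.ndarray:
        return self.data[self.kept_mask]


def bandpass(rec: Recording, lo: float = DEFAULT_BAND[0], hi: float = DEFAULT_BAND[1],
             order: int = DEFAULT_FILTER_ORDER) -> Recording:
    """Zero-phase Butterworth band-pass, applied per channel.

    A forward-backward (filtfilt) 4th-order Butterworth by default; the
    effective magnitude response is therefore the squared Butterworth
    response and the phase is exactly zero.
    """
    if not (0 < lo < hi < rec.fs / 2):
        raise ParameterError(
            f"corner frequencies must satisfy 0 < lo < hi < fs/2; got "
            f"lo={lo}, hi={hi}, fs={rec.fs}")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=-1)
    return Recording(filtered, rec.fs, list(rec.channel_labels),
                     list(rec.missing_channels))


def segment(rec: Recording, epoch_len_s: float = DEFAULT_EPOCH_LEN_S) -> EpochArray:
    """Cut the recording into contiguous non-overlapping epochs.

    ``floor(duration / epoch_len_s)`` epochs are produced; trailing partial
    samples are discarded. All epochs start kept.
    """
    n_per = epoch_len_s * rec.fs
    if abs(n_per - round(n_per)) > 1e-9:
        raise ParameterError(
            f"epoch length {epoch_len_s}s is not an integer number of samples at fs={rec.fs}")
    n_per = int(round(n_per))
    n_epochs = rec.n_samples // n_per
    if n_epochs < 1:
        raise ParameterError(
            f"recording of {rec.duration_s:.2f}s shorter than one {epoch_len_s}s epoch")
    trimmed = rec.samples[:, : n_epochs * n_per]
    data = trimmed.reshape(rec.n_channels, n_epochs, n_per).transpose(1, 0, 2).copy()
    return EpochArray(data, rec.fs, epoch_len_s, list(rec.channel_labels),
                      np.ones(n_epochs, dtype=bool))


def screen_epochs(ep: EpochArray, amp_limit_uv: float = DEFAULT_AMP_LIMIT_UV) -> EpochArray:
    """Reject epochs whose absolute amplitude exceeds ``amp_limit_uv`` on any channel.

    A crude automated stand-in for manual artifact review: gross ocular or
    movement artifacts reach amplitudes far above ongoing rhythm. Data are
    untouched; only ``kept_mask`` changes.
    """
    if amp_limit_uv <= 0:
        raise ParameterError(f"amplitude limit must be positive, got {amp_limit_uv}")
    peak = np.abs(ep.data).max(axis=2)  # epochs x channels
    mask = ep.kept_mask & ~(peak > amp_limit_uv).any(axis=1)
    if not mask.any():
        per_channel = dict(zip(ep.channel_labels,
                               (peak > amp_limit_uv).sum(axis=0).tolist()))
        raise EmptyAnalysisError(
            f"all {ep.n_epochs} epochs rejected at |amplitude| > {amp_limit_uv} uV; "
            f"violations per channel: {per_channel}")
    return EpochArray(ep.data, ep.fs, ep.epoch_len_s, list(ep.channel_labels), mask)


def take_first_kept(ep: EpochArray, n: int) -> EpochArray:
    """Restrict the kept mask to the first ``n`` kept epochs (temporal order)."""
    kept_idx = np.flatnonzero(ep.kept_mask)
    mask = np.zeros_like(ep.kept_mask)
    mask[kept_idx[:n]] = True
    return EpochArray(ep.data, ep.fs, ep.epoch_len_s, list(ep.channel_labels), mask)
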