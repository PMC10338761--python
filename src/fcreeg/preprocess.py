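"""Epoch segmentation and frequency-band decomposition.

Recordings are cut into fixed-length non-overlapping windows (10 s by
default, so a 60 s recording at 128 Hz yields 6 multi-channel epochs =
96 single-channel segments).  Each epoch is then band-pass filtered into
the conventional EEG rhythms with a zero-phase Butterworth filter —
zero-phase because the phase-lag index downstream depends entirely on
phase relationships, which forward-backward filtering preserves.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .io import EEGRecording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandSpec:
    """A frequency band with edges in Hz."""

    name: str
    low: float
    high: float

    def validate(self, fs: float) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"invalid band edges for {self.name}: "
                             f"({self.low}, {self.high})")
        if self.high >= fs / 2:
            raise ValueError(
                f"band {self.name} upper edge {self.high} Hz reaches the "
                f"Nyquist frequency {fs / 2} Hz")


# Conventional rhythms; the gamma band is implemented as 30-45 Hz to match
# the 45 Hz broadband ceiling (the open-ended ">30 Hz" convention has no
# upper edge and would collide with Nyquist at 128 Hz sampling).
BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 0.5, 4.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 13.0),
    "beta": BandSpec("beta", 13.0, 30.0),
    "gamma": BandSpec("gamma", 30.0, 45.0),
    "broadband": BandSpec("broadband", 0.5, 45.0),
}


@dataclass
class Epoch:
    """One fixed-length multi-channel window of a recording."""

    subject_id: str
    group: str
    index: int
    fs: float
    data: np.ndarray  # channels x samples
    band: str | None = None  # set after band-pass filtering

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def segment(rec: EEGRecording, window_s: float = 10.0,
            overlap_s: float = 0.0) -> list[Epoch]:
    """Cut a recording into contiguous windows.

    Returns floor((n - L) / (L - overlap)) + 1 epochs of L = window_s * fs
    samples; trailing samples that do not fill a window are discarded.  A
    recording shorter than one window yields an empty list with a logged
    warning (not an exception) so cohort loops keep going.
    """
    L = int(round(window_s * rec.fs))
    if L < 1:
        raise ValueError("window_s * fs must be at least 1 sample")
    step = L - int(round(overlap_s * rec.fs))
    if step < 1:
        raise ValueError("overlap_s must be smaller than window_s")
    n = rec.n_samples
    if n < L:
        logger.warning("recording %s has %d samples < one %d-sample window; "
                       "no epochs produced", rec.subject_id, n, L)
        return []
    n_epochs = (n - L) // step + 1
    return [
        Epoch(subject_id=rec.subject_id, group=rec.group, index=k,
              fs=rec.fs, data=rec.data[:, k * step: k * step + L].copy())
        for k in range(n_epochs)
    ]


def count_segments(epochs: list[Epoch]) -> tuple[int, int]:
    """Bookkeeping: (multi-channel epochs, single-channel segments).

    A 60 s 16-channel recording in 10 s windows gives (6, 96); a cohort of
    84 such recordings gives (504, 8064).
    """
    n_multi = len(epochs)
    n_single = sum(e.n_channels for e in epochs)
    return n_multi, n_single


def _design_sos(band: BandSpec, fs: float, order: int = 4) -> np.ndarray:
    band.validate(fs)
    return signal.butter(order, [band.low, band.high], btype="bandpass",
                         fs=fs, output="sos")


def bandpass(epoch: Epoch, band: BandSpec | str, order: int = 4) -> Epoch:
    """Zero-phase Butterworth band-pass of one epoch.

    Forward-backward application (sosfiltfilt) removes group delay so the
    instantaneous phases used by PLI are not shifted by the filter.
    """
    if isinstance(band, str):
        band = BANDS[band]
    sos = _design_sos(band, epoch.fs, order)
    filtered = signal.sosfiltfilt(sos, epoch.data, axis=-1)
    return replace(epoch, data=np.ascontiguousarray(filtered), band=band.name)


def bandpass_recording(rec: EEGRecording, band: BandSpec | str,
                       order: int = 4) -> EEGRecording:
    """Filter a whole recording before segmentation (edge-effect variant)."""
    if isinstance(band, str):
        band = BANDS[band]
    sos = _design_sos(band, rec.fs, order)
    filtered = signal.sosfiltfilt(sos, rec.data, axis=-1)
    return EEGRecording(subject_id=rec.subject_id, group=rec.group,
                        channel_names=list(rec.channel_names), fs=rec.fs,
                        data=filtered)
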