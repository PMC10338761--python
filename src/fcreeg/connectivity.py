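"""Phase lag index (PLI) functional connectivity.

The PLI between two signals is the absolute mean sign of their wrapped
instantaneous phase difference,

    PLI = | (1/T) sum_t sgn( wrap(phi1(t) - phi2(t)) ) |,

with the difference wrapped into (-pi, pi] and sgn(0) = 0.  It measures
the *asymmetry* of the phase-difference distribution: 0 means no
consistently lagged coupling (including the zero-lag correlations that
volume conduction produces), 1 means a perfectly consistent nonzero lag.
Instantaneous phases come from the analytic signal (Hilbert transform).

For a 16-channel epoch all pairwise PLIs form a symmetric 16x16 matrix
with zero diagonal and entries in [0, 1].
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .montage import CANONICAL_CHANNELS
from .preprocess import Epoch


#: Wrapped phase differences smaller than this (radians) count as zero lag.
#: Floating-point rounding in the Hilbert transform gives *identical-phase*
#: signals (e.g. amplitude-scaled copies) differences of order 1e-16, which
#: would otherwise contribute random +/-1 signs instead of sgn(0) = 0.
ZERO_LAG_TOL = 1e-9


def wrap_phase(d: np.ndarray | float) -> np.ndarray:
    """Wrap phase differences into (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(d, dtype=float)))


def _lag_signs(d: np.ndarray) -> np.ndarray:
    """sgn of wrapped phase differences with sgn(0) = 0 up to ZERO_LAG_TOL."""
    w = wrap_phase(d)
    return np.sign(w) * (np.abs(w) > ZERO_LAG_TOL)


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase of the analytic signal, radians in (-pi, pi].

    Raises on constant (zero-variance) input, where phase is undefined.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("signal must be a 1-D array of length >= 4")
    if not np.isfinite(x).all():
        raise ValueError("signal contains non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("constant signal: instantaneous phase is undefined")
    return np.angle(hilbert(x))


def pli(phi1: np.ndarray, phi2: np.ndarray) -> float:
    """PLI of two equal-length phase series (radians)."""
    phi1 = np.asarray(phi1, dtype=float)
    phi2 = np.asarray(phi2, dtype=float)
    if phi1.shape != phi2.shape or phi1.ndim != 1:
        raise ValueError(
            f"phase series must be 1-D with equal length, got shapes "
            f"{phi1.shape} and {phi2.shape}")
    return float(abs(np.mean(_lag_signs(phi1 - phi2))))


@dataclass
class ConnectivityMatrix:
    """Symmetric 16x16 PLI matrix for one epoch and one band."""

    values: np.ndarray
    band: str
    subject_id: str
    epoch_index: int
    group: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(CANONICAL_CHANNELS),) * 2:
            raise ValueError(f"expected a 16x16 matrix, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero (self-connectivity excluded)")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("PLI entries must lie in [0, 1]")
        self.values = v


def pli_matrix(phases: np.ndarray) -> np.ndarray:
    """All pairwise PLIs of a channels x samples phase array (vectorized)."""
    phases = np.asarray(phases, dtype=float)
    n = phases.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    diffs = phases[iu] - phases[ju]          # n_pairs x T
    vals = np.abs(np.mean(_lag_signs(diffs), axis=1))
    m = np.zeros((n, n))
    m[iu, ju] = vals
    m[ju, iu] = vals
    return m


def connectivity_matrix(epoch_band: Epoch) -> ConnectivityMatrix:
    """PLI connectivity matrix of a band-filtered 16-channel epoch."""
    if epoch_band.n_channels != len(CANONICAL_CHANNELS):
        raise ValueError(
            f"expected {len(CANONICAL_CHANNELS)} channels, got {epoch_band.n_channels}")
    if epoch_band.band is None:
        raise ValueError("epoch must be band-filtered before connectivity")
    phases = np.empty_like(epoch_band.data)
    for i, row in enumerate(epoch_band.data):
        if np.ptp(row) == 0:
            raise ValueError(
                f"channel {CANONICAL_CHANNELS[i]} is constant; phase undefined")
        phases[i] = np.angle(hilbert(row))
    return ConnectivityMatrix(values=pli_matrix(phases),
                              band=epoch_band.band,
                              subject_id=epoch_band.subject_id,
                              epoch_index=epoch_band.index,
                              group=epoch_band.group)


def cohort_connectivity(recordings, band: str = "beta", window_s: float = 10.0,
                        overlap_s: float = 0.0,
                        filter_first: bool = False) -> list[ConnectivityMatrix]:
    """Segment + band-filter + PLI for a whole cohort of recordings.

    Filtering is applied per epoch after segmentation by default; set
    ``filter_first`` to filter the continuous recording instead (reduces
    filter edge effects at epoch boundaries).
    """
    from .preprocess import BANDS, bandpass, bandpass_recording, segment

    spec = BANDS[band] if isinstance(band, str) else band
    out: list[ConnectivityMatrix] = []
    for rec in recordings:
        if filter_first:
            rec = bandpass_recording(rec, spec)
        for ep in segment(rec, window_s=window_s, overlap_s=overlap_s):
            ep_b = bandpass(ep, spec) if not filter_first else \
                Epoch(ep.subject_id, ep.group, ep.index, ep.fs, ep.data, spec.name)
            out.append(connectivity_matrix(ep_b))
    return out
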