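"""The 16-channel 10-20 montage used throughout the package.

All connectivity matrices, images and statistics index channels in the
canonical order below.  Region membership follows standard 10-20 naming
(F* frontal, C* central, T* temporal, P* parietal, O* occipital).
"""
from __future__ import annotations

CANONICAL_CHANNELS: tuple[str, ...] = (
    "O1", "O2", "P3", "P4", "Pz", "T5", "T6", "C3",
    "C4", "Cz", "T3", "T4", "F3", "F4", "F7", "F8",
)

N_CHANNELS = len(CANONICAL_CHANNELS)

_REGION_PREFIX = {"F": "frontal", "C": "central", "T": "temporal",
                  "P": "parietal", "O": "occipital"}

# Schematic head-surface coordinates (x: left-, right+, y: back-, front+),
# unit head radius; used by the connectogram plot only.
CHANNEL_POSITIONS: dict[str, tuple[float, float]] = {
    "F7": (-0.59, 0.59), "F3": (-0.34, 0.54), "F4": (0.34, 0.54), "F8": (0.59, 0.59),
    "T3": (-0.81, 0.0), "C3": (-0.40, 0.0), "Cz": (0.0, 0.0), "C4": (0.40, 0.0),
    "T4": (0.81, 0.0),
    "T5": (-0.59, -0.59), "P3": (-0.34, -0.54), "Pz": (0.0, -0.40),
    "P4": (0.34, -0.54), "T6": (0.59, -0.59),
    "O1": (-0.26, -0.78), "O2": (0.26, -0.78),
}


def region_of(channel: str) -> str:
    """Map a 10-20 channel name to its scalp region."""
    if channel not in CANONICAL_CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; expected one of {CANONICAL_CHANNELS}")
    return _REGION_PREFIX[channel[0]]


def channel_index(channel: str) -> int:
    """Index of *channel* in the canonical montage order."""
    try:
        return CANONICAL_CHANNELS.index(channel)
    except ValueError:
        raise ValueError(f"unknown channel {channel!r}") from None
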