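"""Synthetic two-class 16-channel EEG with controllable phase coupling.

Each channel is a sum of narrowband phase-noisy oscillators: one private
oscillator per channel plus one shared oscillator per coupled pair.  The
two members of a coupled pair carry the shared component at a distinct
carrier frequency with a fixed phase lag (+lag/2 vs -lag/2) and
independent per-channel phase jitter, so the pair's phase-difference
distribution is asymmetric and its PLI rises monotonically with the
coupling amplitude c.  Uncoupled channels share no component and their
PLI tends to 0.  Optional zero-lag channel mixing emulates volume
conduction (which PLI rejects by design), and additive white noise sets
the SNR.

The "patient-like" (SZ) class is generated with reduced coupling on a
set of parietal <-> central/occipital/temporal pairs, mirroring the
connectivity deficit the group analysis is meant to recover; the
healthy-control class uses the unmodified coupling graph.  Everything is
reproducible from (config, seed); subject s uses seed + s.

These are stylized oscillators, not biophysical EEG: spectra are line
spectra with phase noise rather than 1/f broadband (a pink-noise
background can be added), so classifier accuracies on synthetic cohorts
characterize the pipeline, not clinical performance.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr
from scipy.signal import fftconvolve

from .io import EEGRecording
from .montage import CANONICAL_CHANNELS
from .preprocess import BANDS

Pair = tuple[str, str]

# Designed class deficit: parietal <-> central/occipital/temporal pairs.
DEFAULT_EFFECT_PAIRS: tuple[Pair, ...] = (
    ("Pz", "Cz"), ("P3", "O1"), ("P4", "O2"), ("P3", "T5"), ("P4", "C4"),
)
# Structure shared by both classes (no class difference).
DEFAULT_NEUTRAL_PAIRS: tuple[Pair, ...] = (
    ("F3", "F4"), ("O1", "O2"), ("C3", "C4"), ("F7", "T3"), ("F8", "T4"),
)


def _default_coupling() -> dict[Pair, float]:
    g = {p: 0.7 for p in DEFAULT_EFFECT_PAIRS}
    g.update({p: 0.5 for p in DEFAULT_NEUTRAL_PAIRS})
    return g


def _default_effects() -> dict[Pair, float]:
    return {p: 0.3 for p in DEFAULT_EFFECT_PAIRS}


@dataclass
class SynthConfig:
    """Study conditions for a synthetic cohort (defaults = reference cohort)."""

    n_sz: int = 45
    n_hc: int = 39
    fs: float = 128.0
    duration_s: float = 60.0
    band: str = "beta"
    coupling: dict[Pair, float] = field(default_factory=_default_coupling)
    class_effects: dict[Pair, float] = field(default_factory=_default_effects)
    lag_rad: float = np.pi / 4
    jitter_sd: float = 0.4        # radians, per-channel phase noise
    baseline_amp: float = 1.0     # private oscillator amplitude
    noise_sd: float = 0.3         # additive white noise, relative to signal RMS
    mixing: np.ndarray | float | None = None  # zero-lag leakage (volume conduction)
    pink_background: float = 0.0  # amplitude of 1/f background, 0 = off
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sz < 0 or self.n_hc < 0:
            raise ValueError("subject counts must be non-negative")
        if self.jitter_sd < 0 or self.noise_sd < 0:
            raise ValueError("jitter_sd and noise_sd must be non-negative")
        for pair, c in self.coupling.items():
            for ch in pair:
                if ch not in CANONICAL_CHANNELS:
                    raise ValueError(f"unknown channel {ch!r} in pair {pair}")
            if not 0 <= c <= 1:
                raise ValueError(f"coupling strength for {pair} outside [0,1]")
            d = self.class_effects.get(pair, 0.0)
            if not 0 <= c - d <= 1:
                raise ValueError(
                    f"coupling minus class effect for {pair} outside [0,1]")
        for pair in self.class_effects:
            if pair not in self.coupling:
                raise ValueError(f"class effect on uncoupled pair {pair}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class CohortManifest:
    """Who was generated, with which seed."""

    entries: list[tuple[str, str, int]]  # (subject_id, group, seed)
    generator_version: str = "fcreeg-synth-1"


def expected_pair_pli(lag_rad: float, jitter_sd: float) -> float:
    """Closed-form PLI of a constant lag plus Gaussian phase jitter.

    P(dphi > 0) = Phi(lag/sd), so PLI = |2 Phi(lag/sd) - 1|; valid while
    lag +- 3 sd stays inside (-pi, pi) (wrapping negligible).
    """
    if jitter_sd == 0:
        return 0.0 if lag_rad == 0 else 1.0
    return abs(2.0 * float(ndtr(lag_rad / jitter_sd)) - 1.0)


#: Phase-jitter ceiling (radians); at this SD the wrapped phase difference is
#: close to uniform and the pair coherence is effectively zero.
_MAX_COUPLING_JITTER = 2.5


def _pair_jitter_params(c_hc: float, c_sz: float,
                        lag_rad: float) -> tuple[float, float, float]:
    """(marginal jitter SD, rho_hc, rho_sz) realizing both coherence targets.

    Both channels' jitter processes have the same class-independent
    marginal SD sigma; the two copies are correlated with class-dependent
    rho, so the phase-*difference* SD is sqrt(2 (1 - rho)) sigma and the
    shared components' coherence is 2 Phi(lag / (sqrt(2 (1-rho)) sigma)) - 1.
    sigma is chosen so the weaker class sits at rho = 0 (capped at the
    decoherence ceiling, which floors the achievable minimum coherence at
    about 0.18 for the default pi/4 lag).
    """
    from scipy.special import ndtri

    def z(c: float) -> float:
        return float(ndtri((1.0 + min(c, 1.0 - 1e-12)) / 2.0))

    c_lo = min(c_hc, c_sz)
    sigma = _MAX_COUPLING_JITTER if c_lo <= 0 else \
        min(lag_rad / (np.sqrt(2.0) * z(c_lo)), _MAX_COUPLING_JITTER)

    def rho(c: float) -> float:
        if c >= 1.0 or sigma == 0.0:
            return 1.0
        if c <= 0.0:
            return 0.0
        one_minus = lag_rad ** 2 / (2.0 * sigma ** 2 * z(c) ** 2)
        return float(np.clip(1.0 - one_minus, 0.0, 1.0))

    return float(sigma), rho(c_hc), rho(c_sz)


def _smooth_jitter(rng: np.random.Generator, sd: float, t: int) -> np.ndarray:
    """Band-limited Gaussian phase noise with marginal SD = sd."""
    if sd == 0:
        return np.zeros(t)
    w = np.hanning(9)
    x = fftconvolve(rng.standard_normal(t + 16), w / w.sum(), mode="same")[8:8 + t]
    return sd * x / x.std()


def generate_pair(T: int, lag_rad: float, jitter_sd: float, seed: int,
                  fs: float = 128.0, carrier_hz: float = 10.0):
    """Two unit-amplitude signals with a fixed lag and per-sample jitter.

    Signal 2's phase is signal 1's phase minus lag_rad plus iid Gaussian
    jitter, so the pair's PLI approaches :func:`expected_pair_pli`.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.arange(T) / fs
    phi0 = rng.uniform(0, 2 * np.pi)
    phase1 = 2 * np.pi * carrier_hz * t + phi0
    jitter = rng.normal(0.0, jitter_sd, size=T) if jitter_sd > 0 else 0.0
    x1 = np.cos(phase1)
    x2 = np.cos(phase1 - lag_rad + jitter)
    return x1, x2


def _carrier_grid(cfg: SynthConfig, n_slots: int) -> np.ndarray:
    band = BANDS[cfg.band]
    lo, hi = band.low + 1.0, band.high - 2.0
    if hi <= lo:  # very narrow bands: stay inside the band edges
        lo, hi = band.low + 0.2, band.high - 0.2
    return lo + (np.arange(n_slots) + 0.5) * (hi - lo) / n_slots


def _mixing_matrix(cfg: SynthConfig) -> np.ndarray | None:
    m = cfg.mixing
    if m is None:
        return None
    n = len(CANONICAL_CHANNELS)
    if np.isscalar(m):
        mat = np.full((n, n), float(m) / (n - 1))
        np.fill_diagonal(mat, 1.0)
    else:
        mat = np.asarray(m, dtype=float)
        if mat.shape != (n, n):
            raise ValueError(f"mixing matrix must be {n}x{n}")
    return mat / mat.sum(axis=1, keepdims=True)  # rows normalized


def generate_subject(cfg: SynthConfig, group: str, seed: int,
                     subject_id: str | None = None) -> EEGRecording:
    """One 16-channel recording whose pairwise couplings follow the config."""
    if group not in ("SZ", "HC"):
        raise ValueError(f"group must be 'SZ' or 'HC', got {group!r}")
    rng = np.random.default_rng(seed)
    n_ch = len(CANONICAL_CHANNELS)
    T = cfg.n_samples
    t = np.arange(T) / cfg.fs
    pairs = sorted(cfg.coupling)
    freqs = _carrier_grid(cfg, n_ch + len(pairs))
    idx = {c: k for k, c in enumerate(CANONICAL_CHANNELS)}

    # effective coupling per pair for this group
    c_eff = {}
    for pair in pairs:
        c = cfg.coupling[pair]
        if group == "SZ":
            c = c - cfg.class_effects.get(pair, 0.0)
        c_eff[pair] = c

    data = np.zeros((n_ch, T))
    # Component amplitudes are *class-independent* (budgeted from the
    # unmodified coupling graph): coupling strength acts purely on phase
    # coherence, never on power.  Changing any amplitude between classes
    # would alter the phase-velocity statistics of every pair sharing a
    # channel with a designed pair and bias their finite-sample PLI,
    # leaking the class effect into undesigned pairs.
    incident = {ch: 0.0 for ch in CANONICAL_CHANNELS}
    for pair in pairs:
        for ch in pair:
            incident[ch] += cfg.coupling[pair]
    for k, ch in enumerate(CANONICAL_CHANNELS):
        amp = cfg.baseline_amp * max(0.1, 1.0 - incident[ch])
        phi0 = rng.uniform(0, 2 * np.pi)
        jit = _smooth_jitter(rng, cfg.jitter_sd, T)
        data[k] += amp * np.cos(2 * np.pi * freqs[k] * t + phi0 + jit)
    # Shared oscillator per coupled pair, +lag/2 / -lag/2 around a common
    # phase.  The two copies' phase-jitter processes have class-independent
    # marginal SD; coupling strength acts only on their *correlation* rho,
    # so each channel's marginal signal law is identical in both classes
    # (the class effect cannot leak into undesigned pairs) while the
    # designed pair's phase-difference coherence follows c.  Cross-talk
    # from the channels' other components lowers the realized pair PLI
    # below c but keeps it monotone in c.
    for p, pair in enumerate(pairs):
        amp = cfg.baseline_amp * cfg.coupling[pair]
        c_hc = cfg.coupling[pair]
        c_sz = c_hc - cfg.class_effects.get(pair, 0.0)
        sigma, rho_hc, rho_sz = _pair_jitter_params(c_hc, c_sz, cfg.lag_rad)
        rho = rho_sz if group == "SZ" else rho_hc
        f = freqs[n_ch + p]
        psi0 = rng.uniform(0, 2 * np.pi)
        base = 2 * np.pi * f * t + psi0
        common = _smooth_jitter(rng, sigma, T)
        ji = np.sqrt(rho) * common + np.sqrt(1 - rho) * _smooth_jitter(rng, sigma, T)
        jj = np.sqrt(rho) * common + np.sqrt(1 - rho) * _smooth_jitter(rng, sigma, T)
        data[idx[pair[0]]] += amp * np.cos(base + cfg.lag_rad / 2 + ji)
        data[idx[pair[1]]] += amp * np.cos(base - cfg.lag_rad / 2 + jj)
    if cfg.pink_background > 0:
        data += cfg.pink_background * _pink_noise(rng, (n_ch, T))
    mix = _mixing_matrix(cfg)
    if mix is not None:
        data = mix @ data
    if cfg.noise_sd > 0:
        scale = cfg.noise_sd * data.std()
        data = data + rng.normal(0.0, scale, size=data.shape)
    return EEGRecording(
        subject_id=subject_id or f"{group.lower()}{seed}",
        group=group, channel_names=list(CANONICAL_CHANNELS),
        fs=cfg.fs, data=data)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping."""
    n_ch, T = shape
    spec = (rng.standard_normal((n_ch, T // 2 + 1))
            + 1j * rng.standard_normal((n_ch, T // 2 + 1)))
    f = np.arange(T // 2 + 1, dtype=float)
    f[0] = 1.0
    x = np.fft.irfft(spec / np.sqrt(f), n=T, axis=1)
    return x / x.std()


def generate_cohort(cfg: SynthConfig) -> tuple[list[EEGRecording], CohortManifest]:
    """n_sz + n_hc recordings; subject s uses seed cfg.seed + s."""
    if cfg.class_effects and (cfg.n_sz == 0 or cfg.n_hc == 0):
        raise ValueError("class effects require subjects in both classes")
    recordings, entries = [], []
    s = 0
    for group, count in (("SZ", cfg.n_sz), ("HC", cfg.n_hc)):
        for k in range(count):
            sid = f"{group.lower()}_{k:03d}"
            seed = cfg.seed + s
            recordings.append(generate_subject(cfg, group, seed, subject_id=sid))
            entries.append((sid, group, seed))
            s += 1
    return recordings, CohortManifest(entries=entries)
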