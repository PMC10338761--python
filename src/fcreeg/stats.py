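"""Per-channel-pair group comparison of PLI connectivity (one-way ANOVA).

For every unordered channel pair (120 pairs for 16 channels), the
epoch-level PLI values of the SZ and HC groups are compared with a
classical one-way ANOVA, df = (1, n_sz + n_hc - 2).  Two raw-p
significance tiers are reported: tier1 for 0.001 <= p < 0.05 and tier2
for p < 0.001; no multiple-testing correction by default (Bonferroni /
Benjamini-Hochberg available as an option).  The unit of analysis is the
epoch by default; ``per_subject`` first averages each subject's epochs
(more conservative, removes the within-subject dependence of epochs).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .connectivity import ConnectivityMatrix
from .montage import CANONICAL_CHANNELS, CHANNEL_POSITIONS, channel_index

TIER_NS = "ns"
TIER1 = "tier1"   # 0.001 <= p < 0.05
TIER2 = "tier2"   # p < 0.001


@dataclass
class PairStats:
    """Group comparison of one channel pair's PLI distribution."""

    ch_i: str
    ch_j: str
    band: str
    mean_sz: float
    sd_sz: float
    mean_hc: float
    sd_hc: float
    F: float
    p: float
    tier: str
    direction: str  # "SZ_higher" | "HC_higher"


def assign_tier(p: float) -> str:
    if p < 0.001:
        return TIER2
    if p < 0.05:
        return TIER1
    return TIER_NS


def pairwise_anova(values_sz, values_hc) -> tuple[float, float]:
    """One-way ANOVA F and p for two groups of PLI values.

    Equivalent to the squared pooled-variance two-sample t statistic
    (F = t^2) with the same p-value.
    """
    a = np.asarray(values_sz, dtype=float)
    b = np.asarray(values_hc, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        raise ValueError("degenerate data: all values identical")
    f, p = sps.f_oneway(a, b)
    return float(f), float(p)


def compare_groups(matrices: list[ConnectivityMatrix], band: str | None = None,
                   per_subject: bool = False,
                   correction: str | None = None) -> list[PairStats]:
    """PairStats for every unordered channel pair.

    ``correction``: None (raw p, the default), "bonferroni", or "fdr_bh";
    tiers are assigned on the (possibly corrected) p-values.
    """
    if band is not None:
        matrices = [m for m in matrices if m.band == band]
    if not matrices:
        raise ValueError("no matrices to compare")
    bands = {m.band for m in matrices}
    if len(bands) > 1:
        raise ValueError(f"mixed bands {sorted(bands)}; pass band= to select one")
    band = bands.pop()
    groups = {m.group for m in matrices}
    if groups != {"SZ", "HC"}:
        missing = {"SZ", "HC"} - groups
        raise ValueError(f"group(s) absent from cohort: {sorted(missing)}")

    stacks = {g: np.stack([m.values for m in matrices if m.group == g])
              for g in ("SZ", "HC")}
    subj = {g: np.array([m.subject_id for m in matrices if m.group == g])
            for g in ("SZ", "HC")}
    if per_subject:
        for g in ("SZ", "HC"):
            ids = sorted(set(subj[g]))
            stacks[g] = np.stack([stacks[g][subj[g] == s].mean(axis=0)
                                  for s in ids])

    n = len(CANONICAL_CHANNELS)
    records, ps = [], []
    for i in range(n):
        for j in range(i + 1, n):
            vs, vh = stacks["SZ"][:, i, j], stacks["HC"][:, i, j]
            f, p = pairwise_anova(vs, vh)
            records.append(PairStats(
                ch_i=CANONICAL_CHANNELS[i], ch_j=CANONICAL_CHANNELS[j],
                band=band, mean_sz=float(vs.mean()), sd_sz=float(vs.std(ddof=1)),
                mean_hc=float(vh.mean()), sd_hc=float(vh.std(ddof=1)),
                F=f, p=p, tier="", direction=(
                    "SZ_higher" if vs.mean() > vh.mean() else "HC_higher")))
            ps.append(p)
    ps = np.asarray(ps)
    if correction == "bonferroni":
        ps = np.minimum(ps * len(ps), 1.0)
    elif correction == "fdr_bh":
        ps = _fdr_bh(ps)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    for r, p in zip(records, ps):
        r.p = float(p)
        r.tier = assign_tier(p)
    return records  # already sorted by canonical (i, j)


def _fdr_bh(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def significant_pairs(records: list[PairStats], tier: str) -> list[PairStats]:
    """Pairs at or above the requested tier (tier1 includes tier2)."""
    if tier == TIER2:
        return [r for r in records if r.tier == TIER2]
    if tier == TIER1:
        return [r for r in records if r.tier in (TIER1, TIER2)]
    raise ValueError(f"tier must be {TIER1!r} or {TIER2!r}, got {tier!r}")


def plot_connectogram(records: list[PairStats], tier: str,
                      path: str | Path) -> Path:
    """Schematic head plot: edges for significant pairs, colored by the
    pooled mean connectivity strength.  Deterministic for fixed input."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not records:
        raise ValueError("stats must be non-empty")
    for r in records:
        for ch in (r.ch_i, r.ch_j):
            if ch not in CHANNEL_POSITIONS:
                raise ValueError(f"unknown channel name {ch!r}")
    edges = significant_pairs(records, tier)
    fig, ax = plt.subplots(figsize=(5, 5))
    head = plt.Circle((0, 0), 1.0, fill=False, lw=2)
    ax.add_patch(head)
    ax.plot([-0.1, 0, 0.1], [0.995, 1.08, 0.995], "k-", lw=2)  # nose
    cmap = matplotlib.colormaps["viridis"]
    for r in sorted(edges, key=lambda r: (channel_index(r.ch_i),
                                          channel_index(r.ch_j))):
        x1, y1 = CHANNEL_POSITIONS[r.ch_i]
        x2, y2 = CHANNEL_POSITIONS[r.ch_j]
        strength = 0.5 * (r.mean_sz + r.mean_hc)
        ax.plot([x1, x2], [y1, y2], color=cmap(strength), lw=1.5, zorder=1)
    for ch, (x, y) in CHANNEL_POSITIONS.items():
        ax.scatter([x], [y], s=180, c="white", edgecolors="black", zorder=2)
        ax.text(x, y, ch, ha="center", va="center", fontsize=7, zorder=3)
    ax.set_xlim(-1.25, 1.25)
    ax.set_ylim(-1.25, 1.25)
    ax.set_aspect("equal")
    ax.axis("off")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)
    return path
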