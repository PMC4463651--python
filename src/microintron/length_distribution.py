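"""Intron length-distribution statistics and ultra-short threshold detection.

Builds per-length counts of canonical (GT-AG) versus noncanonical introns,
the noncanonical/canonical ratio curve, and detects the length below which
the noncanonical fraction rises sharply — the signature of false introns
(artifactual alignment gaps) contaminating the ultra-short range.  Human
data place this threshold at 65 nt: introns of <=65 nt are classed
ultra-short, 66-85 nt short.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .genome_io import Intron, classify_termini

DEFAULT_MAX_LENGTH = 949          # plotted domain of the length distribution
ULTRA_SHORT_THRESHOLD = 65        # nt; <=65 ultra-short, 66-85 short
SHORT_UPPER = 85


class NoThresholdError(RuntimeError):
    """The ratio curve has too few defined points for changepoint detection."""


@dataclass
class LengthHistogram:
    """Per-length intron counts, split by GT-AG terminus class.

    Arrays are indexed by length (index 0 unused).  Introns longer than
    ``max_length`` are excluded and tallied in ``excluded``.
    """

    max_length: int
    canonical_counts: np.ndarray
    noncanonical_counts: np.ndarray
    excluded: int = 0

    @property
    def total_counted(self) -> int:
        return int(self.canonical_counts.sum() + self.noncanonical_counts.sum())


@dataclass
class RatioCurve:
    """Noncanonical/canonical count ratio per length.

    ``ratio`` is NaN where undefined; ``undefined_mask`` is True at lengths
    with zero canonical count (degenerate denominator, skipped rather than
    imputed).
    """

    ratio: np.ndarray
    undefined_mask: np.ndarray


def build_histogram(
    introns: Iterable[Intron], max_length: int = DEFAULT_MAX_LENGTH
) -> LengthHistogram:
    canonical = np.zeros(max_length + 1, dtype=np.int64)
    noncanonical = np.zeros(max_length + 1, dtype=np.int64)
    excluded = 0
    for it in introns:
        if it.length > max_length:
            excluded += 1
            continue
        if classify_termini(it) == "canonical":
            canonical[it.length] += 1
        else:
            noncanonical[it.length] += 1
    return LengthHistogram(max_length, canonical, noncanonical, excluded)


def ratio_curve(hist: LengthHistogram) -> RatioCurve:
    can = hist.canonical_counts.astype(float)
    non = hist.noncanonical_counts.astype(float)
    undefined = can == 0
    ratio = np.full_like(can, np.nan)
    np.divide(non, can, out=ratio, where=~undefined)
    ratio[0] = np.nan
    undefined[0] = True
    return RatioCurve(ratio=ratio, undefined_mask=undefined)


def detect_threshold(
    curve: RatioCurve,
    window: int = 10,
    search_range: tuple[int, int] = (40, 120),
) -> int:
    """Two-window mean-difference changepoint on the ratio curve.

    Returns the length T maximizing
    mean(ratio on [T-window, T]) - mean(ratio on (T, T+window])
    over defined values; ties break toward the smaller T.  A candidate T
    needs at least ``window`` defined points on each side; if no candidate
    qualifies a :class:`NoThresholdError` is raised.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    lo, hi = search_range
    n = len(curve.ratio) - 1
    lo = max(lo, 1)
    hi = min(hi, n)
    best_t: Optional[int] = None
    best_drop = -np.inf
    for t in range(lo, hi + 1):
        left = curve.ratio[max(1, t - window): t + 1]
        right = curve.ratio[t + 1: min(n, t + window) + 1]
        left = left[~np.isnan(left)]
        right = right[~np.isnan(right)]
        if len(left) < window or len(right) < window:
            continue
        drop = float(left.mean() - right.mean())
        if drop > best_drop:
            best_drop = drop
            best_t = t
    if best_t is None:
        raise NoThresholdError(
            f"fewer than {window} defined ratio points on either side "
            f"everywhere in {search_range}"
        )
    return best_t


def classify_length(length: int, threshold: int = ULTRA_SHORT_THRESHOLD) -> str:
    """'ultra_short' (<= threshold), 'short' (threshold+1..85) or 'other'."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if length <= threshold:
        return "ultra_short"
    if length <= SHORT_UPPER:
        return "short"
    return "other"


def peak_length(hist: LengthHistogram) -> int:
    """Mode of the canonical-intron length distribution (argmax of counts)."""
    return int(np.argmax(hist.canonical_counts))


def write_distribution_tsv(
    hist: LengthHistogram, curve: RatioCurve, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("length\tcanonical\tnoncanonical\tratio\n")
        for length in range(1, hist.max_length + 1):
            r = curve.ratio[length]
            r_str = "NA" if np.isnan(r) else f"{r:.6g}"
            fh.write(
                f"{length}\t{hist.canonical_counts[length]}\t"
                f"{hist.noncanonical_counts[length]}\t{r_str}\n"
            )


def plot_distribution(
    hist: LengthHistogram, curve: RatioCurve, path: str | Path
) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lengths = np.arange(1, hist.max_length + 1)
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(9, 6))
    ax1.fill_between(lengths, hist.canonical_counts[1:], color="firebrick",
                     alpha=0.6, label="GT-AG")
    ax1.set_ylabel("introns (GT-AG)")
    ax1.legend()
    ax2.fill_between(lengths, hist.noncanonical_counts[1:], color="seagreen",
                     alpha=0.6, label="non-GT-AG")
    ax2.plot(lengths, curve.ratio[1:], color="black", lw=1,
             label="non-GT-AG / GT-AG")
    ax2.set_xlabel("intron length (nt)")
    ax2.set_ylabel("introns / ratio")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
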