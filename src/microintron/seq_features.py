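"""Intronic sequence features: base composition, G-runs, ISE motif scan.

Ultra-short human introns are strikingly G-rich, carry G-triplets or
longer runs, and in several cases an 11-nt G-rich intronic splicing
enhancer (ISE), CAGGGGCTGGG.  This module computes base composition with
tie-aware most-frequent-base reporting, maximal G-runs, approximate ISE
occurrences by edit distance, and mean G-content per intron length class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import edlib

from .genome_io import Intron
from .length_distribution import classify_length

ISE_MOTIF = "CAGGGGCTGGG"
DEFAULT_MAX_EDITS = 2
DEFAULT_MIN_G_RUN = 3


@dataclass
class CompositionProfile:
    """Composition facts for one intron sequence.

    ``counts`` covers A/C/G/T only; N positions are tallied separately and
    excluded from ``fractions``.  ``most_frequent_base`` reports every tied
    maximum.
    """

    intron_key: tuple[str, int]
    counts: dict[str, int]
    fractions: dict[str, float]
    most_frequent_base: list[str]
    n_count: int = 0
    g_runs: list[tuple[int, int]] = field(default_factory=list)
    ise_hits: list[tuple[int, int]] = field(default_factory=list)


def base_composition(
    seq: str, intron_key: tuple[str, int] = ("seq", 0)
) -> CompositionProfile:
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    counts = {b: seq.count(b) for b in "ACGT"}
    n_count = seq.count("N")
    total = sum(counts.values())
    fractions = {b: (c / total if total else 0.0) for b, c in counts.items()}
    peak = max(counts.values())
    most = [b for b in "ACGT" if counts[b] == peak and peak > 0]
    return CompositionProfile(
        intron_key=intron_key,
        counts=counts,
        fractions=fractions,
        most_frequent_base=most,
        n_count=n_count,
    )


def find_g_runs(seq: str, min_run: int = DEFAULT_MIN_G_RUN) -> list[tuple[int, int]]:
    """Maximal runs of G of length >= min_run, as (offset, length)."""
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    seq = seq.upper()
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "G":
            j = i
            while j < n and seq[j] == "G":
                j += 1
            if j - i >= min_run:
                runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def ise_scan(
    seq: str,
    motif: str = ISE_MOTIF,
    max_edits: int = DEFAULT_MAX_EDITS,
) -> list[tuple[int, int]]:
    """Approximate occurrences of the ISE motif by unit-cost edit distance.

    Every window within ``max_edits`` substitutions/insertions/deletions of
    the motif is a candidate; overlapping candidates are reduced to the
    best non-overlapping windows (smallest distance, then leftmost).
    Returns (offset, distance) pairs sorted by offset.
    """
    seq = seq.upper()
    motif = motif.upper()
    m = len(motif)
    if m > len(seq):
        raise ValueError("motif longer than sequence")
    candidates: list[tuple[int, int]] = []
    for i in range(len(seq) - max(1, m - max_edits) + 1):
        best = None
        for width in range(max(1, m - max_edits), m + max_edits + 1):
            if i + width > len(seq):
                break
            d = edlib.align(motif, seq[i:i + width], mode="NW")["editDistance"]
            if best is None or d < best:
                best = d
        if best is not None and best <= max_edits:
            candidates.append((i, best))
    # keep best non-overlapping windows (motif-length footprint)
    candidates.sort(key=lambda c: (c[1], c[0]))
    chosen: list[tuple[int, int]] = []
    for off, dist in candidates:
        if all(abs(off - o) >= m for o, _ in chosen):
            chosen.append((off, dist))
    return sorted(chosen)


def profile_intron(
    intron: Intron,
    min_run: int = DEFAULT_MIN_G_RUN,
    ise_motif: str = ISE_MOTIF,
    max_edits: int = DEFAULT_MAX_EDITS,
) -> CompositionProfile:
    profile = base_composition(intron.sequence, intron.key)
    profile.g_runs = find_g_runs(intron.sequence, min_run)
    if len(ise_motif) <= intron.length:
        profile.ise_hits = ise_scan(intron.sequence, ise_motif, max_edits)
    return profile


def gcontent_by_class(
    introns: Iterable[Intron], threshold: int = 65
) -> dict[str, tuple[float, int]]:
    """Mean G fraction (N excluded) and n per intron length class."""
    import logging
    sums: dict[str, list[float]] = {}
    for it in introns:
        cls = classify_length(it.length, threshold)
        frac = base_composition(it.sequence).fractions["G"]
        sums.setdefault(cls, []).append(frac)
    out = {}
    for cls in ("ultra_short", "short", "other"):
        vals = sums.get(cls)
        if not vals:
            logging.getLogger(__name__).warning("no introns in class %s", cls)
            continue
        out[cls] = (sum(vals) / len(vals), len(vals))
    return out


def write_features_tsv(profiles: Iterable[CompositionProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("intron\tA\tC\tG\tT\tN\tg_fraction\tmost_frequent\t"
                 "g_runs\tise_hits\n")
        for p in profiles:
            runs = ";".join(f"{o}:{l}" for o, l in p.g_runs) or "-"
            hits = ";".join(f"{o}:{d}" for o, d in p.ise_hits) or "-"
            fh.write(
                f"{p.intron_key[0]}|{p.intron_key[1]}\t"
                f"{p.counts['A']}\t{p.counts['C']}\t{p.counts['G']}\t"
                f"{p.counts['T']}\t{p.n_count}\t{p.fractions['G']:.4f}\t"
                f"{'/'.join(p.most_frequent_base)}\t{runs}\t{hits}\n"
            )
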