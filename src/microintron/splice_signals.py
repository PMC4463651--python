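"""Splice-signal strength scoring.

Scores 5' splice sites (donors) and 3' splice sites (acceptors) with
Shapiro-Senapathy-style position-weight-matrix percent scores, donors
additionally by the free energy of the duplex with the U1 snRNA 5' end,
and branch sites by consensus-pattern search; raw scores are calibrated
as mid-rank percentiles against reference site collections and flagged
inefficient when every percentile in a signal's pair is < 0.1 or NA.

Windows follow the common convention: donor positions -3..+6 relative to
the exon|intron boundary (9 nt, 3 exonic + 6 intronic), acceptor
-14..+1 (16 nt, 14 intronic + 2 exonic), both configurable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DONOR_WINDOW = 9       # -3..+6
ACCEPTOR_WINDOW = 16   # -14..+1
BRANCH_PATTERN = re.compile(r"(?=([CT]T[ACGT]A[CT]))")
DEFAULT_BRANCH_WINDOW = 40      # last 40 nt of the intron ...
DEFAULT_BRANCH_EXCLUDE_3P = 3   # ... excluding the final 3 nt (the acceptor)
INEFFICIENT_CUTOFF = 0.1

# --- U1 duplex model -------------------------------------------------------
# The U1 snRNA 5' end written 3'->5' opposite donor positions -3..+6; the
# consensus donor CAGGTAAGT is its perfect Watson-Crick complement.
U1_TEMPLATE_3TO5 = "GUCCAUUCA"

# Base-pair strengths (kcal/mol magnitudes) used to build the
# nearest-neighbor stack table: a stack of two adjacent pairs contributes
# -(s1 + s2)/2.  Watson-Crick pairs stack more strongly than G.U wobbles;
# unpaired positions contribute nothing (no stack across a mismatch).
# The absolute scale is an approximation — only orderings are meaningful.
_PAIR_STRENGTH = {
    ("G", "C"): 3.3, ("C", "G"): 3.3,
    ("A", "U"): 2.1, ("U", "A"): 2.1,
    ("G", "U"): 1.0, ("U", "G"): 1.0,
}


@dataclass
class PwmModel:
    """Position-weight matrix of per-position base frequencies (percent)."""

    site_kind: str                 # donor | acceptor | branch
    freq: np.ndarray               # (window, 4) percentages, pseudocounted
    pseudocount: float

    @property
    def window(self) -> int:
        return self.freq.shape[0]


@dataclass
class SpliceSignalScores:
    """Per-intron signal scores, percentiles and inefficiency flags.

    Donor percentiles pair the S&S percent score with the U1 duplex energy;
    acceptor percentiles pair the S&S score with the best branch-site
    score.  ``percentiles`` values are fractions in [0, 1], None = NA.
    """

    intron_key: tuple[str, int]
    donor_ss: float
    donor_dg: float
    acceptor_ss: float
    branch_hits: list[tuple[int, str, float]]
    percentiles: dict[str, Optional[float]] = field(default_factory=dict)
    inefficient_flags: dict[str, bool] = field(default_factory=dict)


def train_pwm(
    sites: Sequence[str], kind: str, pseudocount: float = 0.5
) -> PwmModel:
    """Column base-frequency percentages from >= 20 aligned site sequences."""
    sites = [s.upper() for s in sites]
    if len(sites) < 20:
        raise ValueError(f"need >= 20 sites to train a PWM, got {len(sites)}")
    window = len(sites[0])
    if any(len(s) != window for s in sites):
        raise ValueError("ragged site lengths")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    counts = np.full((window, 4), pseudocount, dtype=float)
    for s in sites:
        for pos, base in enumerate(s):
            if base in _BASE_INDEX:
                counts[pos, _BASE_INDEX[base]] += 1
    freq = 100.0 * counts / counts.sum(axis=1, keepdims=True)
    return PwmModel(site_kind=kind, freq=freq, pseudocount=pseudocount)


def ss_score(site: str, pwm: PwmModel) -> float:
    """Shapiro-Senapathy percent score.

    t = sum over positions of the matrix frequency of the site's base;
    score = 100 * (t - t_min) / (t_max - t_min), where t_min / t_max are the
    sums of the column minima / maxima.  An N contributes the column
    minimum (conservative).
    """
    site = site.upper()
    if len(site) != pwm.window:
        raise ValueError(f"site length {len(site)} != PWM window {pwm.window}")
    col_min = pwm.freq.min(axis=1)
    col_max = pwm.freq.max(axis=1)
    t = 0.0
    for pos, base in enumerate(site):
        if base in _BASE_INDEX:
            t += pwm.freq[pos, _BASE_INDEX[base]]
        else:
            t += col_min[pos]
    t_min, t_max = col_min.sum(), col_max.sum()
    if t_max == t_min:
        return 0.0
    return 100.0 * (t - t_min) / (t_max - t_min)


def u1_duplex_energy(
    donor_site: str,
    template_3to5: str = U1_TEMPLATE_3TO5,
    pair_strength: dict[tuple[str, str], float] = _PAIR_STRENGTH,
) -> float:
    """Free energy (kcal/mol) of the donor / U1 snRNA 5'-end duplex.

    The donor 9-mer (positions -3..+6, DNA alphabet) is read as RNA and
    paired position-by-position against the U1 template; adjacent paired
    positions contribute a nearest-neighbor stack energy, mismatches
    contribute nothing.  More negative = stronger.
    """
    if len(donor_site) != len(template_3to5):
        raise ValueError(
            f"donor site must be {len(template_3to5)} nt, got {len(donor_site)}")
    donor_rna = donor_site.upper().replace("T", "U")
    if set(donor_rna) - set("ACGU"):
        raise ValueError(f"non-ACGT symbol in donor site {donor_site!r}")
    strengths = [
        pair_strength.get((b, t)) for b, t in zip(donor_rna, template_3to5)
    ]
    energy = 0.0
    for s1, s2 in zip(strengths, strengths[1:]):
        if s1 is not None and s2 is not None:
            energy -= (s1 + s2) / 2.0
    return energy


def find_branch_sites(
    intron_seq: str,
    search_window: Optional[int] = None,
    exclude_3p: int = 0,
) -> list[tuple[int, str]]:
    """All matches of the human branch consensus (C/T)T(N)A(C/T).

    Matches (overlapping allowed) are returned 5'->3' as (offset, 5-mer)
    with offsets relative to the intron start; the branched A is pattern
    position 4.  ``search_window`` restricts the scan to the last
    ``search_window`` nt before the final ``exclude_3p`` nt.
    """
    seq = intron_seq.upper()
    end = len(seq) - exclude_3p
    if search_window is None:
        start = 0
    else:
        if search_window > len(seq):
            raise ValueError("search window longer than intron")
        start = max(0, end - search_window)
    region = seq[start:end]
    return [
        (start + m.start(), m.group(1)) for m in BRANCH_PATTERN.finditer(region)
    ]


def percentile_score(raw: float, reference: Sequence[float]) -> float:
    """Mid-rank percentile of ``raw`` in a sorted reference collection:
    fraction strictly below plus half the ties."""
    ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValueError("reference collection is empty")
    below = np.searchsorted(ref, raw, side="left")
    upto = np.searchsorted(ref, raw, side="right")
    return (below + 0.5 * (upto - below)) / ref.size


def flag_inefficient(
    values: Iterable[Optional[float]], cutoff: float = INEFFICIENT_CUTOFF
) -> bool:
    """A signal is inefficient iff EVERY percentile in its pair/triplet is
    below the cutoff or NA (None); any single value >= cutoff clears it."""
    values = list(values)
    if not values:
        return False
    return all(v is None or v < cutoff for v in values)


def score_intron(
    intron_key: tuple[str, int],
    donor_site: str,
    acceptor_site: str,
    intron_seq: str,
    donor_pwm: PwmModel,
    acceptor_pwm: PwmModel,
    branch_pwm: Optional[PwmModel] = None,
    references: Optional[dict[str, Sequence[float]]] = None,
    branch_window: int = DEFAULT_BRANCH_WINDOW,
    branch_exclude_3p: int = DEFAULT_BRANCH_EXCLUDE_3P,
) -> SpliceSignalScores:
    """Score one intron's signals and calibrate against reference scores.

    ``references`` maps signal name ('donor_ss', 'donor_dg', 'acceptor_ss',
    'branch') to a sorted collection of reference raw scores.  The ΔG
    percentile is computed on -ΔG so that larger = stronger throughout.
    """
    donor_ss = ss_score(donor_site, donor_pwm)
    donor_dg = u1_duplex_energy(donor_site)
    acceptor_ss = ss_score(acceptor_site, acceptor_pwm)
    window = min(branch_window, len(intron_seq))
    raw_hits = find_branch_sites(intron_seq, window, branch_exclude_3p)
    branch_hits = []
    for off, mer in raw_hits:
        score = ss_score(mer, branch_pwm) if branch_pwm is not None else float(
            sum(a == b for a, b in zip(mer, "CTNAC") if b != "N"))
        branch_hits.append((off, mer, score))

    percentiles: dict[str, Optional[float]] = {}
    if references:
        def pct(name: str, raw: Optional[float]) -> Optional[float]:
            ref = references.get(name)
            if ref is None or raw is None:
                return None
            return percentile_score(raw, ref)

        percentiles["donor_ss"] = pct("donor_ss", donor_ss)
        percentiles["donor_dg"] = pct("donor_dg", -donor_dg)
        percentiles["acceptor_ss"] = pct("acceptor_ss", acceptor_ss)
        best_branch = max((h[2] for h in branch_hits), default=None)
        percentiles["branch"] = pct("branch", best_branch)

    flags = {}
    if percentiles:
        flags["donor"] = flag_inefficient(
            [percentiles.get("donor_ss"), percentiles.get("donor_dg")])
        flags["acceptor"] = flag_inefficient(
            [percentiles.get("acceptor_ss"), percentiles.get("branch")])

    return SpliceSignalScores(
        intron_key=intron_key,
        donor_ss=donor_ss,
        donor_dg=donor_dg,
        acceptor_ss=acceptor_ss,
        branch_hits=branch_hits,
        percentiles=percentiles,
        inefficient_flags=flags,
    )
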