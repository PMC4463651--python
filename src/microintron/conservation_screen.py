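"""Conservation screen for candidate ultra-short introns.

Mirrors a dual local-alignment screen: candidate introns are searched both
against a transcriptome (concatenated flanking exons as query) and against
genomic sequence (intron plus flanking exons as query), hits are filtered
under fixed thresholds (alignment length > 55, bit score > 99, E-value
<= 1e-19, identity >= 96%), and an intron is called conserved only when
the same species survives in both searches.  A desk-scale Smith-Waterman
(`local_align`) stands in for BLAST so the screen is testable end-to-end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import Align

from .genome_io import Intron, TranscriptModel, ValidationError

# Karlin-Altschul parameters for ungapped DNA scoring at match +1 / mismatch -2
# (approximation: E-values here gate a filter, not a publication claim).
DEFAULT_LAMBDA = 1.28
DEFAULT_K = 0.46

HIT_COLUMNS = [
    "qseqid", "sseqid", "species", "length", "bitscore", "evalue",
    "pident", "gaps",
]


@dataclass(frozen=True)
class AlignmentHit:
    """One tabular local-alignment record (BLAST outfmt-6 dialect row)."""

    query_key: tuple[str, int]      # (transcript_id, intron_number)
    subject_id: str
    species: str
    aln_length: int
    bit_score: float
    e_value: float
    identity_pct: float
    gap_count: int

    def __post_init__(self) -> None:
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if not 0 <= self.identity_pct <= 100:
            raise ValueError("identity_pct must be in [0, 100]")


@dataclass(frozen=True)
class ScreenThresholds:
    """Hit-filter thresholds; bound senses follow the printed rule exactly:
    length > 55 and bit score > 99 are exclusive, E-value <= 1e-19 and
    identity >= 96% inclusive."""

    min_aln_length_exclusive: int = 55
    min_bit_score_exclusive: float = 99.0
    max_e_value_inclusive: float = 1e-19
    min_identity_inclusive: float = 96.0


def _norm_species(name: str) -> str:
    return name.strip().lower()


def mapping_error_filter(
    hits_exon_vs_transcriptome: Iterable[AlignmentHit],
    self_species: str = "human",
) -> set[str]:
    """Transcripts whose exons align to their own transcriptome with indels.

    A transcript is discarded when its best self-species hit (lowest
    E-value) contains gap columns: the annotated intron is then suspected
    to be an artifactual alignment gap over-fitted to the GT-AG rule.
    """
    self_sp = _norm_species(self_species)
    best: dict[str, AlignmentHit] = {}
    for hit in hits_exon_vs_transcriptome:
        if _norm_species(hit.species) != self_sp:
            continue
        tid = hit.query_key[0]
        if tid not in best or hit.e_value < best[tid].e_value:
            best[tid] = hit
    return {tid for tid, hit in best.items() if hit.gap_count > 0}


def filter_hits(
    hits: Iterable[AlignmentHit],
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> list[AlignmentHit]:
    t = thresholds
    return [
        h for h in hits
        if h.aln_length > t.min_aln_length_exclusive
        and h.bit_score > t.min_bit_score_exclusive
        and h.e_value <= t.max_e_value_inclusive
        and h.identity_pct >= t.min_identity_inclusive
    ]


def intersect_searches(
    transcriptome_hits: Iterable[AlignmentHit],
    genome_hits: Iterable[AlignmentHit],
) -> set[tuple[str, int]]:
    """Intron keys with a surviving hit for the same species in both searches."""
    tx = {(h.query_key, _norm_species(h.species)) for h in transcriptome_hits}
    gn = {(h.query_key, _norm_species(h.species)) for h in genome_hits}
    return {key for key, _sp in tx & gn}


def local_align(
    query: str,
    subject: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    *,
    species: str = "",
    query_key: tuple[str, int] = ("query", 0),
    subject_id: str = "subject",
    lam: float = DEFAULT_LAMBDA,
    k: float = DEFAULT_K,
) -> Optional[AlignmentHit]:
    """Optimal Smith-Waterman local alignment wrapped as a tabular hit.

    The raw score S is converted with Karlin-Altschul statistics:
    bits = (lambda * S - ln K) / ln 2 and E = m * n * 2**(-bits).
    Identity is computed over all aligned columns (gap columns included in
    the denominator); a gap of length L costs ``gap_open`` for the first
    position plus ``gap_extend`` for each further position.  Returns None
    when no positive-scoring local alignment exists.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    alignments = aligner.align(query, subject)
    if alignments.score <= 0:
        return None
    aln = alignments[0]
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    if columns == 0:
        return None
    bit_score = (lam * alignments.score - math.log(k)) / math.log(2)
    e_value = len(query) * len(subject) * 2.0 ** (-bit_score)
    return AlignmentHit(
        query_key=query_key,
        subject_id=subject_id,
        species=species,
        aln_length=int(columns),
        bit_score=float(bit_score),
        e_value=float(e_value),
        identity_pct=100.0 * counts.identities / columns,
        gap_count=int(counts.gaps),
    )


def select_ultra_short(
    conserved_keys: set[tuple[str, int]],
    introns: Iterable[Intron],
    models: dict[str, TranscriptModel],
    threshold: int = 65,
) -> list[Intron]:
    """Conserved introns of <= threshold nt hosted by complete transcripts.

    Partial transcripts (no annotated UTR) are removed: an apparent
    ultra-short intron in a partial transcript cannot be distinguished from
    a truncation artifact.
    """
    by_key = {it.key: it for it in introns}
    selected = []
    for key in sorted(conserved_keys):
        if key not in by_key:
            raise ValidationError(f"conserved key {key} has no matching intron")
        it = by_key[key]
        if it.length > threshold:
            continue
        model = models.get(it.transcript_id)
        if model is not None and model.partial_flag:
            continue
        selected.append(it)
    return selected


def run_screen(
    introns: Iterable[Intron],
    models: dict[str, TranscriptModel],
    transcriptome_hits: Iterable[AlignmentHit],
    genome_hits: Iterable[AlignmentHit],
    thresholds: ScreenThresholds = ScreenThresholds(),
    length_threshold: int = 65,
) -> list[Intron]:
    """Full screen: filter both hit tables, intersect on (key, species),
    then keep ultra-short introns of complete hosts."""
    tx = filter_hits(transcriptome_hits, thresholds)
    gn = filter_hits(genome_hits, thresholds)
    conserved = intersect_searches(tx, gn)
    return select_ultra_short(conserved, introns, models, length_threshold)


# ---------------------------------------------------------------------------
# TSV interface (outfmt-6 dialect with an appended species column)
# ---------------------------------------------------------------------------

def _parse_qseqid(qseqid: str) -> tuple[str, int]:
    transcript, _, number = qseqid.rpartition("|")
    return (transcript, int(number))


def read_hits_tsv(path: str | Path) -> list[AlignmentHit]:
    df = pd.read_csv(path, sep="\t")
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing hit columns {sorted(missing)}")
    return [
        AlignmentHit(
            query_key=_parse_qseqid(str(row.qseqid)),
            subject_id=str(row.sseqid),
            species=str(row.species),
            aln_length=int(row.length),
            bit_score=float(row.bitscore),
            e_value=float(row.evalue),
            identity_pct=float(row.pident),
            gap_count=int(row.gaps),
        )
        for row in df.itertuples()
    ]


def hits_to_frame(hits: Iterable[AlignmentHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "qseqid": f"{h.query_key[0]}|{h.query_key[1]}",
                "sseqid": h.subject_id,
                "species": h.species,
                "length": h.aln_length,
                "bitscore": round(h.bit_score, 2),
                "evalue": h.e_value,
                "pident": round(h.identity_pct, 2),
                "gaps": h.gap_count,
            }
            for h in hits
        ],
        columns=HIT_COLUMNS,
    )


def write_hits_tsv(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)
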