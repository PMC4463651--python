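"""Splice-junction read evidence.

Builds exon-only junction fragments (the last F nt of the upstream exon
concatenated to the first F nt of the downstream exon) and calls per-sample
splicing support from short reads by ungapped near-exact matching: a read
supports a junction only when it spans the breakpoint with a minimum anchor
on both sides, so reads from unspliced pre-mRNA can never produce support.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

from .genome_io import (
    GenomeSequence,
    Intron,
    TranscriptModel,
    exon_sequences,
    reverse_complement,
)

log = logging.getLogger(__name__)

DEFAULT_MIN_ANCHOR = 8
DEFAULT_MAX_MISMATCHES = 1
DEFAULT_MIN_READS = 1


@dataclass(frozen=True)
class JunctionFragment:
    """Exon-only sequence across one splice junction.

    ``break_offset`` is the breakpoint position inside ``sequence`` (equal
    to the realized upstream flank, < ``flank`` when the upstream exon is
    shorter than requested — ``truncated`` records that)."""

    junction_id: tuple[str, int]
    sequence: str
    flank: int
    break_offset: int
    truncated: bool = False


@dataclass(frozen=True)
class JunctionSupport:
    junction_id: tuple[str, int]
    sample_id: str
    read_count: int
    spliced_call: bool


def build_junction_index(
    introns: Iterable[Intron],
    models: dict[str, TranscriptModel],
    genome: GenomeSequence,
    flank: int = 42,
) -> list[JunctionFragment]:
    """One exon-only fragment per intron, transcript-strand orientation.

    Junctions with a zero-length realized flank are skipped with a warning.
    """
    if flank < 8:
        raise ValueError("flank must be >= 8")
    fragments = []
    exon_cache: dict[str, list[str]] = {}
    for it in introns:
        model = models[it.transcript_id]
        if it.transcript_id not in exon_cache:
            exon_cache[it.transcript_id] = exon_sequences(model, genome)
        ts_exons = exon_cache[it.transcript_id]
        j = it.intron_number       # junction between ts exon j-1 and j
        up = ts_exons[j - 1][-flank:]
        down = ts_exons[j][:flank]
        if not up or not down:
            log.warning("junction %s|%s has a zero-length flanking exon; skipped",
                        it.transcript_id, it.intron_number)
            continue
        fragments.append(
            JunctionFragment(
                junction_id=it.key,
                sequence=up + down,
                flank=flank,
                break_offset=len(up),
                truncated=len(up) < flank or len(down) < flank,
            )
        )
    return fragments


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from plain or gzipped FASTQ."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq).upper()


def _read_supports_fragment(
    read: str,
    fragment: JunctionFragment,
    min_anchor: int,
    max_mismatches: int,
) -> bool:
    frag = fragment.sequence
    bp = fragment.break_offset
    if len(read) > len(frag) or len(read) < 2 * min_anchor:
        return False
    lo = max(0, bp + min_anchor - len(read))
    hi = min(len(frag) - len(read), bp - min_anchor)
    for seq in (read, reverse_complement(read)):
        for off in range(lo, hi + 1):
            mism = 0
            window = frag[off:off + len(seq)]
            for a, b in zip(seq, window):
                if a != b:
                    mism += 1
                    if mism > max_mismatches:
                        break
            else:
                return True
    return False


def match_reads(
    reads: Iterable[tuple[str, str]],
    index: Iterable[JunctionFragment],
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    sample_id: str = "sample",
    min_reads: int = DEFAULT_MIN_READS,
) -> list[JunctionSupport]:
    """Count breakpoint-spanning reads per junction for one sample.

    A read (or its reverse complement) supports a junction when it aligns
    ungapped within the fragment with <= ``max_mismatches`` mismatches and
    covers >= ``min_anchor`` nt on BOTH sides of the breakpoint.
    """
    if min_anchor < 5:
        raise ValueError("min_anchor must be >= 5")
    index = list(index)
    counts = {f.junction_id: 0 for f in index}
    for _read_id, seq in reads:
        for frag in index:
            if _read_supports_fragment(seq, frag, min_anchor, max_mismatches):
                counts[frag.junction_id] += 1
    return [
        JunctionSupport(
            junction_id=jid,
            sample_id=sample_id,
            read_count=c,
            spliced_call=c >= min_reads,
        )
        for jid, c in counts.items()
    ]


def summarize_support(
    supports: Iterable[JunctionSupport],
    samples: list[str],
) -> dict[tuple[str, int], dict]:
    """Per-junction sample->spliced_call map with a splicing-breadth label:
    'ubiquitous' (all samples), 'tissue_specific' (some), 'none'."""
    calls: dict[tuple[str, int], dict[str, bool]] = {}
    for s in supports:
        calls.setdefault(s.junction_id, {})[s.sample_id] = s.spliced_call
    out = {}
    for jid, per_sample in calls.items():
        n_pos = sum(per_sample.get(s, False) for s in samples)
        if n_pos == len(samples) and samples:
            label = "ubiquitous"
        elif n_pos > 0:
            label = "tissue_specific"
        else:
            label = "none"
        out[jid] = {"calls": {s: per_sample.get(s, False) for s in samples},
                    "label": label}
    return out


def write_index_fasta(index: Iterable[JunctionFragment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in index:
            fh.write(f">{f.junction_id[0]}|{f.junction_id[1]}|flank{f.flank}\n"
                     f"{f.sequence}\n")


def write_support_tsv(supports: Iterable[JunctionSupport], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("junction\tsample\treads\tcall\n")
        for s in supports:
            fh.write(f"{s.junction_id[0]}|{s.junction_id[1]}\t{s.sample_id}\t"
                     f"{s.read_count}\t{'yes' if s.spliced_call else 'no'}\n")
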