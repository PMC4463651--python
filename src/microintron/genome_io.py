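"""Genome / transcript-model I/O and intron extraction.

Reads genome FASTA and transcript annotation (GFF3 or BED12), extracts the
introns of each transcript with their terminal dinucleotides and region
(CDS / UTR) assignment, and classifies termini under the GT-AG rule.

Coordinates are 0-based, half-open everywhere inside the package; GFF3's
1-based inclusive coordinates are converted on read.  Intron numbering
follows transcription order (5'->3' of the mRNA) on either strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

NUCLEOTIDES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

Interval = tuple[int, int]


class FormatError(ValueError):
    """Malformed input file (FASTA/GFF3/BED12)."""


class ValidationError(ValueError):
    """Internally inconsistent annotation (overlapping exons, CDS outside exons...)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSequence:
    """One genome sequence record (upper-case DNA over {A,C,G,T,N})."""

    seq_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise FormatError(f"empty sequence for {self.seq_id!r}")
        bad = set(self.residues) - NUCLEOTIDES
        if bad:
            raise FormatError(
                f"non-nucleotide symbols {sorted(bad)} in {self.seq_id!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class TranscriptModel:
    """A transcript as ordered exon intervals on a genome sequence.

    ``exons`` are 0-based half-open genomic intervals, ascending on the
    genome regardless of strand.  ``cds`` is the genomic interval of the
    coding sequence (None for non-coding transcripts).  ``partial_flag``
    marks transcripts lacking an annotated UTR (the CDS spans the full
    exonic extent) or explicitly flagged partial by the source.
    """

    transcript_id: str
    gene_id: str
    seq_id: str
    strand: str
    exons: list[Interval]
    cds: Optional[Interval] = None
    partial_flag: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript with zero exons")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValidationError(f"{self.transcript_id}: empty exon {start}-{end}")
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end
        if self.cds is not None:
            cs, ce = self.cds
            covered = sum(
                max(0, min(e, ce) - max(s, cs)) for s, e in self.exons
            )
            if ce <= cs:
                raise ValidationError(f"{self.transcript_id}: empty CDS")
            if cs < self.exons[0][0] or ce > self.exons[-1][1] or covered == 0:
                raise ValidationError(f"{self.transcript_id}: CDS outside exons")

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def n_junctions(self) -> int:
        return len(self.exons) - 1


@dataclass(frozen=True)
class Intron:
    """One excised intron, with its transcript-strand sequence."""

    transcript_id: str
    intron_number: int          # 1-based, transcription order
    interval: Interval          # genomic, 0-based half-open
    sequence: str               # transcript-strand orientation
    region: str                 # CDS | UTR5 | UTR3 | noncoding

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]

    @property
    def donor_dinuc(self) -> str:
        return self.sequence[:2]

    @property
    def acceptor_dinuc(self) -> str:
        return self.sequence[-2:]

    @property
    def key(self) -> tuple[str, int]:
        return (self.transcript_id, self.intron_number)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a (multi-)FASTA genome.

    Residues are upper-cased and U is converted to T.  Duplicate record ids,
    an empty file or non-nucleotide symbols raise :class:`FormatError`.
    """
    records: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        residues = str(rec.seq).upper().replace("U", "T")
        records[rec.id] = GenomeSequence(rec.id, residues)
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def _finish_model(
    transcript_id: str,
    gene_id: str,
    seq_id: str,
    strand: str,
    exons: list[Interval],
    cds_parts: list[Interval],
    explicit_partial: bool = False,
) -> TranscriptModel:
    exons = sorted(exons)
    cds: Optional[Interval] = None
    if cds_parts:
        cds = (min(s for s, _ in cds_parts), max(e for _, e in cds_parts))
    partial = explicit_partial
    if cds is not None and cds == (exons[0][0], exons[-1][1]):
        partial = True  # no UTR on either side
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id,
        seq_id=seq_id,
        strand=strand,
        exons=exons,
        cds=cds,
        partial_flag=partial,
    )


def _read_gff3(path: str | Path) -> list[TranscriptModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    exons: dict[str, list[Interval]] = {}
    cds: dict[str, list[Interval]] = {}
    meta: dict[str, dict] = {}

    def _parents(feat) -> list[str]:
        return list(feat.attributes.get("Parent", [])) or [feat.id]

    for feat in db.all_features():
        if feat.featuretype == "exon":
            for p in _parents(feat):
                exons.setdefault(p, []).append((feat.start - 1, feat.end))
                meta.setdefault(p, {})["seq_id"] = feat.seqid
                meta[p]["strand"] = feat.strand
        elif feat.featuretype == "CDS":
            for p in _parents(feat):
                cds.setdefault(p, []).append((feat.start - 1, feat.end))
        elif feat.featuretype in ("mRNA", "transcript"):
            m = meta.setdefault(feat.id, {})
            m["seq_id"] = feat.seqid
            m["strand"] = feat.strand
            m["gene_id"] = (feat.attributes.get("Parent", [None])[0]
                            or feat.attributes.get("gene_id", [feat.id])[0])
            m["partial"] = feat.attributes.get("partial", ["false"])[0].lower() in (
                "true", "1", "yes")

    models = []
    for tid, ex in exons.items():
        if not ex:
            raise ValidationError(f"{tid}: transcript with zero exons")
        m = meta.get(tid, {})
        models.append(
            _finish_model(
                transcript_id=tid,
                gene_id=m.get("gene_id", tid),
                seq_id=m["seq_id"],
                strand=m.get("strand") or "+",
                exons=ex,
                cds_parts=cds.get(tid, []),
                explicit_partial=m.get("partial", False),
            )
        )
    if not models:
        raise FormatError(f"no transcripts with exons in {path}")
    return models


def _read_bed12(path: str | Path) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: BED12 needs 12 columns")
            chrom, start, _end, name, _score, strand = fields[:6]
            start = int(start)
            thick_start, thick_end = int(fields[6]), int(fields[7])
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}:{lineno}: blockCount mismatch")
            exons = [(start + off, start + off + sz) for off, sz in zip(starts, sizes)]
            cds_parts = []
            if thick_end > thick_start:
                cds_parts = [(thick_start, thick_end)]
            models.append(
                _finish_model(
                    transcript_id=name,
                    gene_id=name,
                    seq_id=chrom,
                    strand=strand,
                    exons=exons,
                    cds_parts=cds_parts,
                )
            )
    if not models:
        raise FormatError(f"no BED12 records in {path}")
    return models


def read_annotation(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from GFF3 or BED12 (chosen by file suffix)."""
    suffix = Path(path).suffix.lower()
    if suffix == ".bed":
        return _read_bed12(path)
    return _read_gff3(path)


# ---------------------------------------------------------------------------
# Intron extraction
# ---------------------------------------------------------------------------

def _region_of_gap(model: TranscriptModel, gap: Interval) -> str:
    """Assign CDS/UTR5/UTR3/noncoding to an exon-exon gap.

    A gap abutting the CDS boundary is CDS whenever either exonic base
    adjacent to the junction is coding: a retained intron there would
    interrupt codons.
    """
    if model.cds is None:
        return "noncoding"
    cs, ce = model.cds
    gs, ge = gap
    upstream_base = gs - 1   # last base of the genomic-left exon
    downstream_base = ge     # first base of the genomic-right exon
    if cs <= upstream_base < ce or cs <= downstream_base < ce:
        return "CDS"
    if ge <= cs:   # gap genomically left of the CDS
        return "UTR5" if model.strand == "+" else "UTR3"
    if gs >= ce:   # gap genomically right of the CDS
        return "UTR3" if model.strand == "+" else "UTR5"
    return "CDS"


def extract_introns(
    model: TranscriptModel, genome: GenomeSequence
) -> list[Intron]:
    """Extract one intron per gap between consecutive exons.

    On the minus strand the sequence is reverse-complemented and
    ``intron_number`` counts from the transcript's 5' end (genomic right).
    """
    if model.seq_id != genome.seq_id:
        raise ValidationError(
            f"{model.transcript_id}: model on {model.seq_id!r}, genome is "
            f"{genome.seq_id!r}"
        )
    if model.exons[-1][1] > len(genome):
        raise ValidationError(f"{model.transcript_id}: exons beyond genome end")
    n_gaps = model.n_junctions
    introns = []
    for i in range(n_gaps):
        gap = (model.exons[i][1], model.exons[i + 1][0])
        seq = genome.residues[gap[0]:gap[1]]
        if model.strand == "-":
            seq = reverse_complement(seq)
            number = n_gaps - i
        else:
            number = i + 1
        introns.append(
            Intron(
                transcript_id=model.transcript_id,
                intron_number=number,
                interval=gap,
                sequence=seq,
                region=_region_of_gap(model, gap),
            )
        )
    introns.sort(key=lambda it: it.intron_number)
    return introns


def classify_termini(intron: Intron) -> str:
    """GT-AG rule: 'canonical' iff the intron starts GT and ends AG.

    An N at a terminal dinucleotide position is noncanonical (conservative
    under ambiguity).  Introns shorter than 4 nt cannot carry both termini.
    """
    if intron.length < 4:
        raise ValidationError(
            f"{intron.transcript_id} intron {intron.intron_number}: "
            f"length {intron.length} < 4, termini undefined"
        )
    ok = intron.donor_dinuc == "GT" and intron.acceptor_dinuc == "AG"
    return "canonical" if ok else "noncanonical"


# ---------------------------------------------------------------------------
# Transcript-coordinate helpers (shared with junction / retention modules)
# ---------------------------------------------------------------------------

def exon_sequences(model: TranscriptModel, genome: GenomeSequence) -> list[str]:
    """Exon sequences in transcription order, transcript-strand orientation."""
    seqs = [genome.residues[s:e] for s, e in model.exons]
    if model.strand == "-":
        seqs = [reverse_complement(s) for s in reversed(seqs)]
    return seqs


def spliced_sequence(model: TranscriptModel, genome: GenomeSequence) -> str:
    """The fully spliced (mature) transcript sequence."""
    return "".join(exon_sequences(model, genome))


def transcript_coord(model: TranscriptModel, gpos: int) -> int:
    """Map an exonic genomic position to its 0-based spliced-transcript offset."""
    if model.strand == "+":
        offset = 0
        for s, e in model.exons:
            if s <= gpos < e:
                return offset + (gpos - s)
            offset += e - s
        raise ValidationError(f"position {gpos} not exonic in {model.transcript_id}")
    offset = 0
    for s, e in reversed(model.exons):
        if s <= gpos < e:
            return offset + (e - 1 - gpos)
        offset += e - s
    raise ValidationError(f"position {gpos} not exonic in {model.transcript_id}")


def cds_transcript_interval(model: TranscriptModel) -> Optional[Interval]:
    """The CDS as a half-open interval in spliced-transcript coordinates."""
    if model.cds is None:
        return None
    cs, ce = model.cds
    if model.strand == "+":
        return (transcript_coord(model, cs), transcript_coord(model, ce - 1) + 1)
    return (transcript_coord(model, ce - 1), transcript_coord(model, cs) + 1)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_introns_bed(introns: Iterable[Intron], path: str | Path,
                      models: Optional[dict[str, TranscriptModel]] = None) -> None:
    """Write introns as BED6: name = transcript|intronN, score = length."""
    with open(path, "w") as fh:
        for it in introns:
            strand = "+"
            seq_id = "."
            if models is not None and it.transcript_id in models:
                strand = models[it.transcript_id].strand
                seq_id = models[it.transcript_id].seq_id
            fh.write(
                f"{seq_id}\t{it.interval[0]}\t{it.interval[1]}\t"
                f"{it.transcript_id}|{it.intron_number}\t{it.length}\t{strand}\n"
            )


def write_introns_fasta(introns: Iterable[Intron], path: str | Path) -> None:
    with open(path, "w") as fh:
        for it in introns:
            fh.write(f">{it.transcript_id}|{it.intron_number}\n{it.sequence}\n")


def write_genome_fasta(genomes: Iterable[GenomeSequence], path: str | Path,
                       width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.seq_id}\n")
            for i in range(0, len(g.residues), width):
                fh.write(g.residues[i:i + width] + "\n")


def write_gff3(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GFF3 (gene/mRNA/exon/CDS features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            s, e = m.span
            attrs = f"ID={m.transcript_id};Parent={m.gene_id}"
            if m.partial_flag:
                attrs += ";partial=true"
            fh.write(
                f"{m.seq_id}\t.\tgene\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            fh.write(
                f"{m.seq_id}\t.\tmRNA\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for es, ee in m.exons:
                fh.write(
                    f"{m.seq_id}\t.\texon\t{es + 1}\t{ee}\t.\t{m.strand}\t.\t"
                    f"Parent={m.transcript_id}\n"
                )
            if m.cds is not None:
                cs, ce = m.cds
                for es, ee in m.exons:
                    os_, oe = max(es, cs), min(ee, ce)
                    if oe > os_:
                        fh.write(
                            f"{m.seq_id}\t.\tCDS\t{os_ + 1}\t{oe}\t.\t{m.strand}"
                            f"\t0\tParent={m.transcript_id}\n"
                        )
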