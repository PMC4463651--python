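"""Seeded synthetic data with known ground truth.

Generates every input the pipeline consumes: a genome with multi-exon
genes whose intron lengths follow the bimodal distribution of human
introns (a narrow short mode near 85 nt and a broad long mode near
2000 nt) plus a planted ultra-short population; "false introns" with
noncanonical termini injected only below a planted length threshold
(emulating artifactual alignment gaps); G-rich ultra-short introns that
may carry the CAGGGGCTGGG intronic splicing enhancer; transcript isoform
sets with per-intron splice frequencies; junction-spanning short reads;
and ortholog hit tables with controlled identity.  All generators derive
their randomness from one root seed through fixed per-stream spawn keys,
so each generator is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .conservation_screen import AlignmentHit, local_align, write_hits_tsv
from .genome_io import (
    GenomeSequence,
    Intron,
    TranscriptModel,
    exon_sequences,
    extract_introns,
    reverse_complement,
    write_genome_fasta,
    write_gff3,
)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

# per-generator random stream ids (root seed, stream id) -> SeedSequence
STREAM_GENOME = 0
STREAM_TRANSCRIPTS = 1
STREAM_READS = 2
STREAM_HITS = 3
STREAM_EVIDENCE = 4

NONCANONICAL_DONORS = ("AT", "CT", "GG", "TT")
NONCANONICAL_ACCEPTORS = ("AC", "CG", "TG", "GA")


@dataclass
class SimulationConfig:
    """Generator parameters; defaults are the study conditions.

    Intron lengths mix a log-normal short mode (median 85 nt) and a
    log-normal long mode (median 2000 nt) with a planted ultra-short
    population; false (noncanonical) introns appear only at or below
    ``planted_threshold``.  Ultra-short introns are G-enriched relative to
    short introns, mirroring the G-content gradient of conserved human
    introns.
    """

    seed: int = 0
    n_genes: int = 200
    introns_per_gene: tuple[int, int] = (6, 10)
    exon_length: tuple[int, int] = (80, 160)
    p_ultra_short: float = 0.4
    ultra_short_range: tuple[int, int] = (38, 65)
    planted_ultra_short_lengths: Optional[Sequence[int]] = None
    short_mode_median: float = 85.0
    short_mode_sigma: float = 0.25
    long_mode_median: float = 2000.0
    long_mode_sigma: float = 0.6
    p_long: float = 0.08
    false_intron_rate_below_threshold: float = 0.5
    planted_threshold: int = 65
    g_fraction_ultra_short: float = 0.40
    g_fraction_short: float = 0.25
    ise_motif: str = "CAGGGGCTGGG"
    ise_insertion_rate: float = 0.25
    splice_frequency: float = 0.9
    p_partial: float = 0.05
    p_conserved: float = 0.8
    ortholog_identity: dict[str, float] = field(
        default_factory=lambda: {"chimpanzee": 98.0, "macaque": 97.0})
    nonconserved_identity: float = 90.0
    ortholog_flank: int = 60
    conserved_max_length: int = 120   # the screen targets the short range
    read_length: int = 50
    coverage: float = 20.0
    error_rate: float = 0.005
    utr_length: int = 30
    spacer: int = 60

    def __post_init__(self) -> None:
        for name in ("p_ultra_short", "false_intron_rate_below_threshold",
                     "ise_insertion_rate", "splice_frequency", "p_partial",
                     "p_conserved", "p_long", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ultra_short_range[0] < 4 + len(self.ise_motif):
            raise ValueError("ultra-short introns too short to carry termini "
                             "and the ISE motif")
        if self.exon_length[0] <= self.utr_length:
            raise ValueError("exons must be longer than the UTR length")


def stream_rng(seed: int, stream: int) -> np.random.Generator:
    """The documented per-generator random stream derivation."""
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def _random_seq(rng: np.random.Generator, n: int,
                p: Optional[Sequence[float]] = None) -> str:
    return rng.choice(_BASE_BYTES, size=n, p=p).tobytes().decode()


def _g_biased(rng: np.random.Generator, n: int, g_fraction: float) -> str:
    rest = (1.0 - g_fraction) / 3.0
    return _random_seq(rng, n, p=[rest, rest, g_fraction, rest])


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def _draw_intron_length(rng: np.random.Generator, cfg: SimulationConfig,
                        planted_cycle: list[int]) -> tuple[int, str]:
    if rng.random() < cfg.p_ultra_short:
        if cfg.planted_ultra_short_lengths:
            if not planted_cycle:
                planted_cycle.extend(cfg.planted_ultra_short_lengths)
            return planted_cycle.pop(0), "ultra_short"
        lo, hi = cfg.ultra_short_range
        return int(rng.integers(lo, hi + 1)), "ultra_short"
    if rng.random() < cfg.p_long:
        length = int(round(rng.lognormal(math.log(cfg.long_mode_median),
                                         cfg.long_mode_sigma)))
        return max(length, 301), "long"
    # truncated log-normal: the sub-threshold tail is rejected rather than
    # clipped so the canonical histogram keeps its natural mode near 85 nt
    for _ in range(1000):
        length = int(round(rng.lognormal(math.log(cfg.short_mode_median),
                                         cfg.short_mode_sigma)))
        if cfg.planted_threshold < length <= 300:
            return length, "short"
    raise RuntimeError("short-mode length sampling failed to converge")


def make_genome(
    config: SimulationConfig,
) -> tuple[GenomeSequence, list[TranscriptModel], pd.DataFrame]:
    """Synthesize a genome, one transcript model per gene, and the truth table.

    True introns carry GT...AG termini; false introns (noncanonical
    termini) occur only at lengths <= ``planted_threshold`` at the
    configured rate.  Ultra-short introns get the configured G fraction
    and, at ``ise_insertion_rate``, an embedded ISE motif.  ``conserved``
    is planted for canonical introns up to ``conserved_max_length``.
    """
    rng = stream_rng(config.seed, STREAM_GENOME)
    chrom_parts: list[str] = []
    offset = 0
    models: list[TranscriptModel] = []
    truth_rows: list[dict] = []
    planted_cycle: list[int] = []

    for g in range(config.n_genes):
        tid = f"TX{g:04d}"
        gid = f"GENE{g:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        partial = rng.random() < config.p_partial
        n_introns = int(rng.integers(config.introns_per_gene[0],
                                     config.introns_per_gene[1] + 1))
        exon_lens = [int(rng.integers(config.exon_length[0],
                                      config.exon_length[1] + 1))
                     for _ in range(n_introns + 1)]

        intron_seqs: list[str] = []
        intron_meta: list[dict] = []
        for _ in range(n_introns):
            length, cls = _draw_intron_length(rng, config, planted_cycle)
            is_false = (length <= config.planted_threshold
                        and rng.random() < config.false_intron_rate_below_threshold)
            g_frac = {"ultra_short": config.g_fraction_ultra_short,
                      "short": config.g_fraction_short}.get(cls, 0.25)
            seq = _g_biased(rng, length, g_frac)
            if is_false:
                donor = NONCANONICAL_DONORS[rng.integers(len(NONCANONICAL_DONORS))]
                acceptor = NONCANONICAL_ACCEPTORS[
                    rng.integers(len(NONCANONICAL_ACCEPTORS))]
            else:
                donor, acceptor = "GT", "AG"
            seq = donor + seq[2:-2] + acceptor
            has_ise = False
            if (not is_false and cls == "ultra_short"
                    and rng.random() < config.ise_insertion_rate):
                m = config.ise_motif
                pos = int(rng.integers(6, length - 6 - len(m) + 1))
                seq = seq[:pos] + m + seq[pos + len(m):]
                has_ise = True
            conserved = (not is_false
                         and length <= config.conserved_max_length
                         and rng.random() < config.p_conserved)
            intron_seqs.append(seq)
            intron_meta.append({
                "length": length, "class": cls, "canonical": not is_false,
                "is_false": is_false, "has_ise": has_ise,
                "conserved": conserved, "g_fraction_target": g_frac,
            })

        # exon sequences in transcript orientation, with a start codon at
        # the CDS start and a stop codon closing the CDS
        exon_seqs = [_random_seq(rng, elen) for elen in exon_lens]
        total_exonic_pre = sum(exon_lens)
        cds_start_spliced = 0 if partial else config.utr_length
        cds_end_spliced = total_exonic_pre - (0 if partial else config.utr_length)
        s0 = cds_start_spliced                      # inside the first exon
        exon_seqs[0] = (exon_seqs[0][:s0] + "ATG" + exon_seqs[0][s0 + 3:])
        tail = exon_lens[-1] - (total_exonic_pre - cds_end_spliced) - 3
        exon_seqs[-1] = (exon_seqs[-1][:tail] + "TAA"
                         + exon_seqs[-1][tail + 3:])

        # gene layout in transcript orientation
        layout_parts: list[str] = []
        exon_layout: list[tuple[int, int]] = []
        pos = 0
        for i, elen in enumerate(exon_lens):
            layout_parts.append(exon_seqs[i])
            exon_layout.append((pos, pos + elen))
            pos += elen
            if i < n_introns:
                layout_parts.append(intron_seqs[i])
                pos += len(intron_seqs[i])
        gene_seq = "".join(layout_parts)
        gene_len = len(gene_seq)
        total_exonic = sum(exon_lens)

        # CDS in spliced-transcript coordinates
        if partial:
            cds_spliced = (0, total_exonic)
        else:
            cds_spliced = (config.utr_length, total_exonic - config.utr_length)

        def spliced_to_layout(t: int) -> int:
            acc = 0
            for (ls, le), elen in zip(exon_layout, exon_lens):
                if t < acc + elen:
                    return ls + (t - acc)
                acc += elen
            raise AssertionError("spliced offset out of range")

        cds_layout = (spliced_to_layout(cds_spliced[0]),
                      spliced_to_layout(cds_spliced[1] - 1) + 1)

        # place on the chromosome
        chrom_parts.append(_random_seq(rng, config.spacer))
        offset += config.spacer
        if strand == "+":
            chrom_parts.append(gene_seq)
            exons = [(offset + s, offset + e) for s, e in exon_layout]
            cds = (offset + cds_layout[0], offset + cds_layout[1])
        else:
            chrom_parts.append(reverse_complement(gene_seq))
            exons = sorted(
                (offset + gene_len - e, offset + gene_len - s)
                for s, e in exon_layout
            )
            cds = (offset + gene_len - cds_layout[1],
                   offset + gene_len - cds_layout[0])
        offset += gene_len

        models.append(TranscriptModel(
            transcript_id=tid, gene_id=gid, seq_id="chrS",
            strand=strand, exons=exons, cds=cds, partial_flag=partial,
        ))
        for i, meta in enumerate(intron_meta):
            truth_rows.append({
                "transcript_id": tid,
                "intron_number": i + 1,
                "partial_host": partial,
                **meta,
            })

    chrom_parts.append(_random_seq(rng, config.spacer))
    genome = GenomeSequence("chrS", "".join(chrom_parts))
    truth = pd.DataFrame(truth_rows)
    return genome, models, truth


# ---------------------------------------------------------------------------
# Isoforms and reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Isoform:
    isoform_id: str
    transcript_id: str
    retained: tuple[int, ...]      # retained intron numbers
    sequence: str


def make_transcripts(
    models: Iterable[TranscriptModel],
    genome: GenomeSequence,
    splice_frequencies: float | dict[tuple[str, int], float],
    n_transcripts: int,
    seed: int = 0,
) -> tuple[list[Isoform], pd.DataFrame]:
    """Sample isoforms retaining/splicing each intron independently.

    ``splice_frequencies`` is a scalar default or a per-intron map keyed by
    (transcript_id, intron_number).  Returns the isoforms and the realized
    per-intron spliced/aligned counts.
    """
    rng = stream_rng(seed, STREAM_TRANSCRIPTS)
    isoforms: list[Isoform] = []
    count_rows = []
    for model in models:
        introns = extract_introns(model, genome)
        ts_exons = exon_sequences(model, genome)
        spliced_counts = {it.intron_number: 0 for it in introns}
        for k in range(n_transcripts):
            retained = []
            for it in introns:
                if isinstance(splice_frequencies, dict):
                    freq = splice_frequencies.get(it.key, 1.0)
                else:
                    freq = splice_frequencies
                if rng.random() < freq:
                    spliced_counts[it.intron_number] += 1
                else:
                    retained.append(it.intron_number)
            parts = []
            by_number = {it.intron_number: it for it in introns}
            for i, exon_seq in enumerate(ts_exons):
                parts.append(exon_seq)
                if i + 1 in retained:
                    parts.append(by_number[i + 1].sequence)
            isoforms.append(Isoform(
                isoform_id=f"{model.transcript_id}.iso{k}",
                transcript_id=model.transcript_id,
                retained=tuple(sorted(retained)),
                sequence="".join(parts),
            ))
        for number, c in spliced_counts.items():
            count_rows.append({
                "transcript_id": model.transcript_id,
                "intron_number": number,
                "spliced_hits": c,
                "aligned_hits": n_transcripts,
            })
    return isoforms, pd.DataFrame(count_rows)


def make_reads(
    isoforms: Iterable[Isoform],
    read_length: int = 50,
    coverage: float = 20.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Uniform-start short reads with substitution errors.

    Read ids encode the origin isoform and start position for truth-based
    testing.
    """
    rng = stream_rng(seed, STREAM_READS)
    reads: list[tuple[str, str]] = []
    for iso in isoforms:
        L = len(iso.sequence)
        if read_length > L:
            raise ValueError(
                f"read_length {read_length} exceeds isoform length {L}")
        n = max(1, int(round(coverage * L / read_length)))
        starts = rng.integers(0, L - read_length + 1, size=n)
        for start in starts:
            seq = list(iso.sequence[start:start + read_length])
            if error_rate > 0:
                errs = np.flatnonzero(rng.random(read_length) < error_rate)
                for e in errs:
                    alternatives = [b for b in "ACGT" if b != seq[e]]
                    seq[e] = alternatives[rng.integers(3)]
            reads.append((f"{iso.isoform_id}|pos{start}", "".join(seq)))
    return reads


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Ortholog hit tables
# ---------------------------------------------------------------------------

def _mutate(seq: str, identity_pct: float, rng: np.random.Generator) -> str:
    n_mut = int(round(len(seq) * (1.0 - identity_pct / 100.0)))
    if n_mut == 0:
        return seq
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != out[p]]
        out[p] = alternatives[rng.integers(3)]
    return "".join(out)


def make_hit_tables(
    introns: Iterable[Intron],
    models: dict[str, TranscriptModel],
    genome: GenomeSequence,
    truth: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[list[AlignmentHit], list[AlignmentHit]]:
    """Transcriptome- and genome-search hit tables from mutated orthologs.

    For each canonical intron up to ``conserved_max_length`` and each
    species, an ortholog of the transcriptome query (concatenated flanking
    exons) and of the genomic query (intron with flanking exons) is
    generated at the planted identity (``ortholog_identity`` for introns
    planted conserved, ``nonconserved_identity`` otherwise) and aligned
    with ``local_align``.
    """
    rng = stream_rng(config.seed, STREAM_HITS)
    flank = config.ortholog_flank
    conserved_map = {
        (row.transcript_id, row.intron_number): bool(row.conserved)
        for row in truth.itertuples()
    }
    exon_cache: dict[str, list[str]] = {}
    tx_hits: list[AlignmentHit] = []
    gn_hits: list[AlignmentHit] = []
    for it in introns:
        if it.donor_dinuc != "GT" or it.acceptor_dinuc != "AG":
            continue
        if it.length > config.conserved_max_length:
            continue
        model = models[it.transcript_id]
        if it.transcript_id not in exon_cache:
            exon_cache[it.transcript_id] = exon_sequences(model, genome)
        ts_exons = exon_cache[it.transcript_id]
        j = it.intron_number
        up, down = ts_exons[j - 1][-flank:], ts_exons[j][:flank]
        tx_query = up + down
        gn_query = up + it.sequence + down
        conserved = conserved_map.get(it.key, False)
        for species in config.ortholog_identity:
            identity = (config.ortholog_identity[species] if conserved
                        else config.nonconserved_identity)
            for query, target, kind in ((tx_query, tx_hits, "tx"),
                                        (gn_query, gn_hits, "gn")):
                subject = _mutate(query, identity, rng)
                hit = local_align(
                    query, subject,
                    species=species,
                    query_key=it.key,
                    subject_id=f"{species}_{kind}_{it.key[0]}_{it.key[1]}",
                )
                if hit is not None:
                    target.append(hit)
    return tx_hits, gn_hits


# ---------------------------------------------------------------------------
# Synthetic evidence matrix
# ---------------------------------------------------------------------------

def make_evidence_matrix(truth: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Synthetic evidence matrix over the planted conserved ultra-short
    introns, sampling the three evidence channels independently."""
    rng = stream_rng(seed, STREAM_EVIDENCE)
    sub = truth[(truth["conserved"]) & (truth["class"] == "ultra_short")]
    rows = []
    for serial, row in enumerate(sub.itertuples(), start=1):
        aligned = int(rng.integers(1, 16))
        spliced = max(1, int(rng.binomial(aligned, 0.8)))
        rows.append({
            "serial": serial,
            "length": row.length,
            "transcript_id": row.transcript_id,
            "intron_number": row.intron_number,
            "total_introns": int(
                truth[truth.transcript_id == row.transcript_id].shape[0]),
            "region": "CDS",
            "in_second_db": "Yes" if rng.random() < 0.9 else "No",
            "protein_category": rng.choice(
                ["I", "II", "III", "IV", "VI", "VII"],
                p=[0.45, 0.3, 0.08, 0.08, 0.05, 0.04]),
            "spliced_hits": spliced,
            "aligned_hits": aligned,
            "rtpcr": rng.choice(
                ["Spliced", "Expressed", "No-Exp", "No-PCR", "n/a"],
                p=[0.4, 0.4, 0.1, 0.05, 0.05]),
            "rnaseq": rng.choice(["Yes", "No"], p=[0.55, 0.45]),
            "indiv_seq": rng.choice(["Yes", "No", "RM", "UC"],
                                    p=[0.35, 0.45, 0.15, 0.05]),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# One-call simulation writing all pipeline inputs
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write genome, annotation, reads, hit tables, truth and
    evidence matrix under ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, models, truth = make_genome(config)
    introns = [it for m in models for it in extract_introns(m, genome)]
    isoforms, counts = make_transcripts(
        models, genome, config.splice_frequency, n_transcripts=2,
        seed=config.seed)
    reads = make_reads(isoforms, config.read_length, config.coverage,
                       config.error_rate, seed=config.seed)
    tx_hits, gn_hits = make_hit_tables(introns, {m.transcript_id: m for m in models},
                                       genome, truth, config)
    evidence = make_evidence_matrix(truth, seed=config.seed)

    paths = {
        "genome": out / "genome.fa",
        "annotation": out / "models.gff3",
        "reads": out / "reads_s1.fastq",
        "tx_hits": out / "tx_hits.tsv",
        "gn_hits": out / "gn_hits.tsv",
        "truth": out / "truth.tsv",
        "counts": out / "splice_counts.tsv",
        "evidence": out / "evidence.tsv",
    }
    write_genome_fasta([genome], paths["genome"])
    write_gff3(models, paths["annotation"])
    write_fastq(reads, paths["reads"])
    write_hits_tsv(tx_hits, paths["tx_hits"])
    write_hits_tsv(gn_hits, paths["gn_hits"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    counts.to_csv(paths["counts"], sep="\t", index=False)
    evidence.to_csv(paths["evidence"], sep="\t", index=False)
    return paths
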