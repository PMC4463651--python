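"""Reading-frame, premature-stop and NMD consequences of intron retention.

For each intron the retained-mRNA model is built (all other introns
spliced, the target retained), the reading-frame effect is classed by
length mod 3, the first premature termination codon (PTC) is located by
in-frame translation from the annotated start, and the mRNA is called an
NMD target when the PTC lies more than a boundary distance (50-55 nt)
upstream of the 3'-most remaining exon-exon junction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .genome_io import (
    GenomeSequence,
    Intron,
    TranscriptModel,
    cds_transcript_interval,
    exon_sequences,
)

log = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}
DEFAULT_NMD_BOUNDARY = 50    # nt upstream of the last junction; 50-55 admissible


@dataclass
class RetentionModel:
    """An mRNA with one target intron retained.

    Offsets are 0-based in the retained mRNA.  ``junction_offsets`` are the
    positions of the remaining exon-exon junctions; ``intron_span`` is the
    half-open span of the retained intron; ``native_stop_offset`` is the
    codon-start offset of the annotated stop, mapped through the retention.
    """

    retained_mrna: str
    cds_start: int
    junction_offsets: list[int]
    target_region: str
    intron_span: tuple[int, int]
    native_stop_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 <= self.cds_start < len(self.retained_mrna):
            raise ValueError("cds_start outside retained mRNA")
        if any(b > a for a, b in zip(self.junction_offsets[1:],
                                     self.junction_offsets)):
            raise ValueError("junction_offsets must be ascending")


@dataclass
class RetentionConsequence:
    transcript_id: str
    intron_number: int
    region: str
    frame_effect: str                      # frame_preserving | frameshift | not_applicable_UTR
    in_intron_stop: bool
    ptc_offset: Optional[int]
    distance_to_last_junction: Optional[int]
    nmd_target: bool


def frame_effect(intron_length: int, region: str) -> str:
    """Frame class of retaining an intron: UTR introns cannot shift the
    frame; a CDS intron preserves frame iff its length is a multiple of 3."""
    if intron_length < 1:
        raise ValueError("intron_length must be >= 1")
    if region in ("UTR5", "UTR3", "noncoding"):
        return "not_applicable_UTR"
    return "frame_preserving" if intron_length % 3 == 0 else "frameshift"


def scan_ptc(model: RetentionModel) -> tuple[Optional[int], bool]:
    """First in-frame stop codon other than the annotated native stop.

    Translates codon-by-codon from ``cds_start``; returns
    (ptc_offset or None, in_intron_stop) where ``in_intron_stop`` is True
    when the PTC lies inside the retained intron's span.
    """
    mrna = model.retained_mrna
    if len(mrna) < model.cds_start + 3:
        raise ValueError("retained mRNA shorter than one codon after cds_start")
    if mrna[model.cds_start:model.cds_start + 3] != "ATG":
        log.warning("no ATG at cds_start %d; scanning anyway", model.cds_start)
    for off in range(model.cds_start, len(mrna) - 2, 3):
        codon = mrna[off:off + 3]
        if codon in STOP_CODONS:
            if model.native_stop_offset is not None and off == model.native_stop_offset:
                return None, False
            in_intron = model.intron_span[0] <= off < model.intron_span[1]
            return off, in_intron
    return None, False


def nmd_classify(
    ptc_offset: Optional[int],
    junction_offsets: list[int],
    boundary: int = DEFAULT_NMD_BOUNDARY,
) -> bool:
    """NMD-target call under the junction-distance rule.

    True iff a PTC exists, at least one exon-exon junction lies downstream
    of it, and the 3'-most junction is more than ``boundary`` nt downstream.
    """
    if not 50 <= boundary <= 55:
        raise ValueError("boundary must be in [50, 55]")
    if ptc_offset is None or not junction_offsets:
        return False
    last = max(junction_offsets)
    if last <= ptc_offset:
        return False
    return (last - ptc_offset) > boundary


def build_retention_model(
    intron: Intron,
    model: TranscriptModel,
    genome: GenomeSequence,
) -> RetentionModel:
    """Retained-mRNA model for one intron (all other introns spliced)."""
    ts_exons = exon_sequences(model, genome)
    j = intron.intron_number
    cum = [0]
    for seq in ts_exons:
        cum.append(cum[-1] + len(seq))
    insert_at = cum[j]               # spliced offset of the target junction
    ilen = intron.length
    retained = "".join(ts_exons[:j]) + intron.sequence + "".join(ts_exons[j:])

    junction_offsets = [
        cum[i] + (ilen if i > j else 0)
        for i in range(1, len(ts_exons))
        if i != j
    ]

    cds_t = cds_transcript_interval(model)
    if cds_t is None:
        raise ValueError(f"{model.transcript_id}: no CDS annotated")
    cds_start = cds_t[0] + (ilen if cds_t[0] >= insert_at else 0)
    native_stop_spliced = cds_t[1] - 3
    native_stop = native_stop_spliced + (ilen if native_stop_spliced >= insert_at else 0)

    return RetentionModel(
        retained_mrna=retained,
        cds_start=cds_start,
        junction_offsets=junction_offsets,
        target_region=intron.region,
        intron_span=(insert_at, insert_at + ilen),
        native_stop_offset=native_stop,
    )


def retention_report(
    introns: Iterable[Intron],
    models: dict[str, TranscriptModel],
    genome: GenomeSequence,
    boundary: int = DEFAULT_NMD_BOUNDARY,
) -> tuple[list[RetentionConsequence], dict[str, int]]:
    """Frame / PTC / NMD consequence for every intron, plus summary counts."""
    consequences = []
    for it in introns:
        model = models[it.transcript_id]
        effect = frame_effect(it.length, it.region)
        if effect == "not_applicable_UTR" or model.cds is None:
            consequences.append(
                RetentionConsequence(
                    transcript_id=it.transcript_id,
                    intron_number=it.intron_number,
                    region=it.region,
                    frame_effect=effect,
                    in_intron_stop=False,
                    ptc_offset=None,
                    distance_to_last_junction=None,
                    nmd_target=False,
                )
            )
            continue
        try:
            rmodel = build_retention_model(it, model, genome)
            ptc, in_intron = scan_ptc(rmodel)
        except ValueError as exc:
            log.error("%s intron %d: %s", it.transcript_id, it.intron_number, exc)
            continue
        distance = None
        if ptc is not None and rmodel.junction_offsets:
            last = max(rmodel.junction_offsets)
            if last > ptc:
                distance = last - ptc
        consequences.append(
            RetentionConsequence(
                transcript_id=it.transcript_id,
                intron_number=it.intron_number,
                region=it.region,
                frame_effect=effect,
                in_intron_stop=in_intron,
                ptc_offset=ptc,
                distance_to_last_junction=distance,
                nmd_target=nmd_classify(ptc, rmodel.junction_offsets, boundary),
            )
        )
    summary = {
        "n_cds": sum(c.region == "CDS" for c in consequences),
        "n_utr": sum(c.region in ("UTR5", "UTR3") for c in consequences),
        "n_frame_preserving": sum(
            c.frame_effect == "frame_preserving" for c in consequences),
        "n_frameshift": sum(c.frame_effect == "frameshift" for c in consequences),
        "n_nmd_target": sum(c.nmd_target for c in consequences),
    }
    return consequences, summary


def nmd_targets_from_facts(
    facts, boundary: int = DEFAULT_NMD_BOUNDARY
) -> dict[int, bool]:
    """Apply the frame/PTC/junction-distance rule to recorded retention facts.

    ``facts`` is a table with columns serial, length, region, in_intron_stop
    (yes/no) and ptc_position, one of 'upstream_far' (PTC more than the
    boundary upstream of the 3'-most junction), 'downstream_of_last_junction',
    or 'no_ptc'.  Each category is realized as representative retained-mRNA
    offsets and classified with :func:`nmd_classify`; frame-preserving
    introns without an internal stop yield no PTC by construction.
    Returns serial -> NMD-target call.
    """
    calls: dict[int, bool] = {}
    for row in facts.itertuples():
        effect = frame_effect(int(row.length), str(row.region))
        in_stop = str(row.in_intron_stop).lower() in ("yes", "true", "1")
        position = str(row.ptc_position)
        if effect == "not_applicable_UTR":
            calls[int(row.serial)] = False
            continue
        if effect == "frame_preserving" and not in_stop:
            position = "no_ptc"
        if position == "no_ptc":
            ptc, junctions = None, [100]
        elif position == "upstream_far":
            # PTC with a junction well beyond the boundary downstream
            ptc, junctions = 300, [100, 300 + boundary + 50]
        elif position == "downstream_of_last_junction":
            ptc, junctions = 300, [100, 250]
        else:
            raise ValueError(f"unknown ptc_position {position!r}")
        calls[int(row.serial)] = nmd_classify(ptc, junctions, boundary)
    return calls


def write_retention_tsv(
    consequences: Iterable[RetentionConsequence], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("transcript\tintron_number\tregion\tframe_effect\t"
                 "in_intron_stop\tptc_offset\tdistance_to_last_junction\t"
                 "nmd_target\n")
        for c in consequences:
            fh.write(
                f"{c.transcript_id}\t{c.intron_number}\t{c.region}\t"
                f"{c.frame_effect}\t{c.in_intron_stop}\t"
                f"{'NA' if c.ptc_offset is None else c.ptc_offset}\t"
                f"{'NA' if c.distance_to_last_junction is None else c.distance_to_last_junction}\t"
                f"{c.nmd_target}\n"
            )
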