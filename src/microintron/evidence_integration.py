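"""Integration of per-intron evidence into a candidate report.

Each candidate ultra-short intron carries three experimental evidence
channels — RT-PCR outcome, RNA-Seq junction support, and whether the host
transcript was individually cloned and sequenced — plus annotation facts
(region, protein-similarity category, per-intron splice frequency among
aligned transcripts).  A candidate is *confirmed* when at least one
channel is positive.  The packaged evidence matrix transcribes the 22
conserved ultra-short intron candidates of the human transcriptome with
their recorded evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

RTPCR_STATES = {"Spliced", "Expressed", "No-Exp", "No-PCR", "n/a"}
RNASEQ_STATES = {"Yes", "No"}
# RM = source accession removed by contributors, UC = description unclear:
# explicit states, modeled as not-positive rather than missing data.
INDIV_STATES = {"Yes", "No", "RM", "UC"}
REGIONS = {"CDS", "UTR5", "UTR3"}
PROTEIN_CATEGORIES = {"I", "II", "III", "IV", "V", "VI", "VII"}


@dataclass(frozen=True)
class EvidenceRecord:
    """One row of the evidence matrix for a candidate ultra-short intron."""

    serial: int
    length: int
    transcript_id: str
    intron_number: int
    total_introns: int
    region: str
    in_second_db: bool
    protein_category: str
    spliced_hits: int
    aligned_hits: int
    rtpcr: str
    rnaseq: str
    indiv_seq: str

    def __post_init__(self) -> None:
        if not 0 <= self.spliced_hits <= self.aligned_hits:
            raise ValueError(
                f"SN{self.serial}: spliced_hits must be in [0, aligned_hits]")
        if self.intron_number > self.total_introns:
            raise ValueError(f"SN{self.serial}: intron_number > total_introns")
        if self.region not in REGIONS:
            raise ValueError(f"SN{self.serial}: bad region {self.region!r}")
        if self.rtpcr not in RTPCR_STATES:
            raise ValueError(f"SN{self.serial}: bad rtpcr {self.rtpcr!r}")
        if self.rnaseq not in RNASEQ_STATES:
            raise ValueError(f"SN{self.serial}: bad rnaseq {self.rnaseq!r}")
        if self.indiv_seq not in INDIV_STATES:
            raise ValueError(f"SN{self.serial}: bad indiv_seq {self.indiv_seq!r}")
        if self.protein_category not in PROTEIN_CATEGORIES:
            raise ValueError(
                f"SN{self.serial}: bad protein_category {self.protein_category!r}")


@dataclass
class ConfirmationReport:
    confirmed: dict[int, bool]
    n_confirmed: int
    n_rtpcr_spliced: int
    n_rnaseq_yes: int
    n_indiv_yes: int
    n_cds: int
    n_utr: int
    n_cat_I_II: int
    n_freq_100pct: int


def intron_frequency(spliced_hits: int, aligned_hits: int) -> Optional[float]:
    """Fraction of aligned transcripts spliced at the intron (NA when no
    transcript spans the region)."""
    if aligned_hits == 0:
        return None
    return spliced_hits / aligned_hits


def confirm(record: EvidenceRecord) -> bool:
    """At-least-one-positive rule over the three experimental channels.

    Positive states: RT-PCR 'Spliced', RNA-Seq 'Yes', individually
    sequenced 'Yes'.  'RM' and 'UC' are explicitly not positive.
    """
    return (
        record.rtpcr == "Spliced"
        or record.rnaseq == "Yes"
        or record.indiv_seq == "Yes"
    )


def summarize(records: Iterable[EvidenceRecord]) -> ConfirmationReport:
    """Direct tabulation of the evidence matrix.

    ``n_freq_100pct`` counts the introns spliced in 100% of transcripts
    among those supported by multiple spliced transcripts (spliced_hits
    >= 2); a single spliced transcript cannot establish a frequency.
    """
    records = list(records)
    serials = [r.serial for r in records]
    if len(serials) != len(set(serials)):
        raise ValueError("duplicate serial numbers in evidence records")
    confirmed = {r.serial: confirm(r) for r in records}
    return ConfirmationReport(
        confirmed=confirmed,
        n_confirmed=sum(confirmed.values()),
        n_rtpcr_spliced=sum(r.rtpcr == "Spliced" for r in records),
        n_rnaseq_yes=sum(r.rnaseq == "Yes" for r in records),
        n_indiv_yes=sum(r.indiv_seq == "Yes" for r in records),
        n_cds=sum(r.region == "CDS" for r in records),
        n_utr=sum(r.region in ("UTR5", "UTR3") for r in records),
        n_cat_I_II=sum(r.protein_category in ("I", "II") for r in records),
        n_freq_100pct=sum(
            r.spliced_hits >= 2 and r.spliced_hits == r.aligned_hits
            for r in records
        ),
    )


# ---------------------------------------------------------------------------
# TSV interface and the packaged evidence matrix
# ---------------------------------------------------------------------------

def records_from_frame(df: pd.DataFrame) -> list[EvidenceRecord]:
    return [
        EvidenceRecord(
            serial=int(row.serial),
            length=int(row.length),
            transcript_id=str(row.transcript_id),
            intron_number=int(row.intron_number),
            total_introns=int(row.total_introns),
            region=str(row.region),
            in_second_db=str(row.in_second_db) == "Yes",
            protein_category=str(row.protein_category),
            spliced_hits=int(row.spliced_hits),
            aligned_hits=int(row.aligned_hits),
            rtpcr=str(row.rtpcr),
            rnaseq=str(row.rnaseq),
            indiv_seq=str(row.indiv_seq),
        )
        for row in df.itertuples()
    ]


def read_evidence_tsv(path: str | Path) -> list[EvidenceRecord]:
    return records_from_frame(
        pd.read_csv(path, sep="\t", keep_default_na=False))


def load_candidate_table() -> list[EvidenceRecord]:
    """The packaged 22-row evidence matrix of conserved ultra-short introns."""
    with resources.files("microintron.data").joinpath(
            "candidate_evidence.tsv").open() as fh:
        return records_from_frame(
            pd.read_csv(fh, sep="\t", keep_default_na=False))


def load_retention_facts() -> pd.DataFrame:
    """Per-candidate intron-retention facts (frame region, in-intron stop,
    PTC position relative to the 3'-most junction) as recorded for the 22
    candidates."""
    with resources.files("microintron.data").joinpath(
            "retention_facts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def write_report(
    records: Iterable[EvidenceRecord],
    report: ConfirmationReport,
    out_dir: str | Path,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        freq = intron_frequency(r.spliced_hits, r.aligned_hits)
        rows.append({
            "serial": r.serial,
            "length": r.length,
            "transcript_id": r.transcript_id,
            "intron_number": r.intron_number,
            "region": r.region,
            "protein_category": r.protein_category,
            "splice_frequency": "NA" if freq is None else round(freq, 4),
            "rtpcr": r.rtpcr,
            "rnaseq": r.rnaseq,
            "indiv_seq": r.indiv_seq,
            "confirmed": "Yes" if report.confirmed[r.serial] else "No",
        })
    pd.DataFrame(rows).to_csv(out / "evidence_report.tsv", sep="\t", index=False)
    with open(out / "summary.txt", "w") as fh:
        fh.write(
            f"candidates:              {len(report.confirmed)}\n"
            f"confirmed (>=1 channel): {report.n_confirmed}\n"
            f"RT-PCR spliced:          {report.n_rtpcr_spliced}\n"
            f"RNA-Seq supported:       {report.n_rnaseq_yes}\n"
            f"individually sequenced:  {report.n_indiv_yes}\n"
            f"CDS / UTR:               {report.n_cds} / {report.n_utr}\n"
            f"protein category I/II:   {report.n_cat_I_II}\n"
            f"spliced in 100% (multi): {report.n_freq_100pct}\n"
        )
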