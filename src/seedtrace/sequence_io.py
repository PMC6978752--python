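"""Transcript, miRNA and ortholog-pair I/O.

All coordinates are 0-based, half-open. RNA input (U) is normalized to the
DNA alphabet (T) on ingest so that seed strings printed in DNA alphabet
match transcripts directly. ``N`` is permitted in transcripts and never
matches any seed base.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
RNA_ALPHABET = frozenset("ACGU")

PathLike = Union[str, Path, io.IOBase]


class Region(str, enum.Enum):
    """The three regions of an mRNA: untranslated leader, coding sequence,
    untranslated trailer."""

    UTR5 = "UTR5"
    CDS = "CDS"
    UTR3 = "UTR3"

    def __str__(self) -> str:  # tidy TSV output
        return self.value


def normalize_dna(sequence: str, *, context: str = "sequence") -> str:
    """Uppercase and convert U->T; reject characters outside {A,C,G,T,U,N}."""
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(
            f"{context}: characters outside A/C/G/T/U/N: {sorted(bad)!r}"
        )
    return seq


@dataclass
class TranscriptRecord:
    """One mRNA with its CDS coordinates.

    The three regions [0, cds_start), [cds_start, cds_end), [cds_end, len)
    partition the sequence; either UTR may be empty.
    """

    transcript_id: str
    species: str
    gene_symbol: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        self.sequence = normalize_dna(self.sequence, context=self.transcript_id)
        if not self.sequence:
            raise ValueError(f"{self.transcript_id}: empty sequence")
        if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise ValueError(
                f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                f"invalid for length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def utr5(self) -> str:
        return self.sequence[: self.cds_start]

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]

    @property
    def utr3(self) -> str:
        return self.sequence[self.cds_end :]

    def region_bounds(self, region: Region) -> tuple[int, int]:
        if region is Region.UTR5:
            return 0, self.cds_start
        if region is Region.CDS:
            return self.cds_start, self.cds_end
        return self.cds_end, len(self.sequence)


@dataclass
class MicroRNA:
    """A mature miRNA, 5'->3', RNA alphabet."""

    name: str
    mature_sequence: str

    def __post_init__(self) -> None:
        seq = self.mature_sequence.upper().replace("T", "U")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ValueError(f"{self.name}: non-RNA characters {sorted(bad)!r}")
        if len(seq) < 10:
            raise ValueError(f"{self.name}: mature sequence shorter than 10 nt")
        self.mature_sequence = seq


@dataclass
class OrthologPair:
    """Corresponding transcripts of one gene in two species."""

    species_a_transcript: TranscriptRecord
    species_b_transcript: TranscriptRecord
    gene_symbol: str = field(default="")

    def __post_init__(self) -> None:
        a, b = self.species_a_transcript, self.species_b_transcript
        if not self.gene_symbol:
            self.gene_symbol = a.gene_symbol
        if a.species == b.species:
            raise ValueError(
                f"{self.gene_symbol}: ortholog pair requires distinct species, "
                f"got {a.species!r} twice"
            )


def region_of(transcript: TranscriptRecord, position: int) -> Region:
    """Region label of a 0-based position: UTR5 / CDS / UTR3."""
    if not 0 <= position < len(transcript.sequence):
        raise ValueError(
            f"position {position} out of range for {transcript.transcript_id} "
            f"(length {len(transcript.sequence)})"
        )
    if position < transcript.cds_start:
        return Region.UTR5
    if position < transcript.cds_end:
        return Region.CDS
    return Region.UTR3


ANNOTATION_COLUMNS = ["transcript_id", "species", "gene_symbol", "cds_start", "cds_end"]


def read_transcripts(
    fasta_source: PathLike, annotation_source: PathLike
) -> list[TranscriptRecord]:
    """Read transcripts from FASTA plus a TSV region-annotation table.

    The TSV has a header row with columns transcript_id, species,
    gene_symbol, cds_start, cds_end (0-based half-open). Every FASTA record
    must have an annotation row. FASTA order is preserved.
    """
    ann = pd.read_csv(annotation_source, sep="\t", dtype={"transcript_id": str})
    missing_cols = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing_cols:
        raise ValueError(f"annotation table lacks columns: {sorted(missing_cols)}")
    ann = ann.set_index("transcript_id", drop=False)

    records: list[TranscriptRecord] = []
    for rec in SeqIO.parse(fasta_source, "fasta"):
        if rec.id not in ann.index:
            raise ValueError(f"no annotation row for transcript {rec.id!r}")
        row = ann.loc[rec.id]
        records.append(
            TranscriptRecord(
                transcript_id=rec.id,
                species=str(row["species"]),
                gene_symbol=str(row["gene_symbol"]),
                sequence=str(rec.seq),
                cds_start=int(row["cds_start"]),
                cds_end=int(row["cds_end"]),
            )
        )
    return records


def write_transcripts(
    records: Sequence[TranscriptRecord],
    fasta_path: PathLike,
    annotation_path: PathLike,
) -> None:
    """Inverse of :func:`read_transcripts`; round-trips bit-identically."""
    seq_records = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id, description="")
        for t in records
    ]
    SeqIO.write(seq_records, fasta_path, "fasta")
    pd.DataFrame(
        [
            {
                "transcript_id": t.transcript_id,
                "species": t.species,
                "gene_symbol": t.gene_symbol,
                "cds_start": t.cds_start,
                "cds_end": t.cds_end,
            }
            for t in records
        ],
        columns=ANNOTATION_COLUMNS,
    ).to_csv(annotation_path, sep="\t", index=False)


def read_mirnas(fasta_source: PathLike) -> list[MicroRNA]:
    """Read mature miRNAs from FASTA (DNA or RNA alphabet; T normalized to U)."""
    return [
        MicroRNA(name=rec.id, mature_sequence=str(rec.seq))
        for rec in SeqIO.parse(fasta_source, "fasta")
    ]


def read_ortholog_pairs(
    pairing_source: PathLike, transcripts: Iterable[TranscriptRecord]
) -> list[OrthologPair]:
    """Read a pairing TSV (gene_symbol, transcript_id_a, transcript_id_b) and
    resolve IDs against already-loaded transcripts."""
    by_id = {t.transcript_id: t for t in transcripts}
    table = pd.read_csv(pairing_source, sep="\t", dtype=str)
    needed = {"gene_symbol", "transcript_id_a", "transcript_id_b"}
    if not needed <= set(table.columns):
        raise ValueError(f"pairing table lacks columns: {sorted(needed - set(table.columns))}")
    pairs = []
    for row in table.itertuples(index=False):
        for tid in (row.transcript_id_a, row.transcript_id_b):
            if tid not in by_id:
                raise ValueError(f"pairing references unknown transcript {tid!r}")
        pairs.append(
            OrthologPair(
                species_a_transcript=by_id[row.transcript_id_a],
                species_b_transcript=by_id[row.transcript_id_b],
                gene_symbol=row.gene_symbol,
            )
        )
    return pairs
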