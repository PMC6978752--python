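"""Design of wild-type / mutant inserts for dual-luciferase reporters.

Given a native context containing one or more predicted binding sites, the
designer applies a minimal set of transversions (A<->C, G<->T) spaced so
that no contiguous seed match of length >= min_match survives anywhere in
the mutant, then re-verifies with the scanner — the guarantee behind a
site-ablated reporter control.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seed_scan import SeedQuery, Site, find_sites
from .sequence_io import TranscriptRecord, normalize_dna

TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G", "N": "A"}

_MAX_REPAIR_ROUNDS = 25


@dataclass
class ReporterInsert:
    label: str
    wild_type_sequence: str
    mutant_sequence: str
    edited_positions: list[int]
    seed: SeedQuery

    def __post_init__(self) -> None:
        wt, mut = self.wild_type_sequence, self.mutant_sequence
        if len(wt) != len(mut):
            raise ValueError("wild-type and mutant inserts must be equal length")
        diffs = [i for i, (a, b) in enumerate(zip(wt, mut)) if a != b]
        if diffs != sorted(self.edited_positions):
            raise ValueError("edited_positions inconsistent with sequence diff")


def _as_record(sequence: str, label: str) -> TranscriptRecord:
    # scanning scaffold: region structure is irrelevant for an insert
    return TranscriptRecord(
        transcript_id=label,
        species="construct",
        gene_symbol=label,
        sequence=sequence,
        cds_start=0,
        cds_end=len(sequence),
    )


def scan_insert(sequence: str, seed: SeedQuery, label: str = "insert") -> list[Site]:
    """Scanner applied to a bare insert sequence."""
    return find_sites(_as_record(sequence, label), seed)


def design_mutant(
    wild_type_context: str, seed: SeedQuery, label: str = "insert"
) -> ReporterInsert:
    """Mutate every binding site in ``wild_type_context`` out of existence.

    Edits are transversions placed left-to-right every min_match-th base
    within each matched span, so that every window of min_match consecutive
    bases of a former site contains at least one edit; the result is
    re-scanned and deterministically repaired if an edit happens to create a
    new match. Edit count per site never exceeds ceil(span / min_match).
    """
    wt = normalize_dna(wild_type_context, context=label)
    if len(wt) < seed.min_match:
        raise ValueError(
            f"{label}: context shorter than min_match ({seed.min_match})"
        )
    wt_sites = scan_insert(wt, seed, label)
    if not wt_sites:
        raise ValueError(f"{label}: context contains no binding site to mutate")

    m = seed.min_match
    mutant = list(wt)
    for site in wt_sites:
        # offsets m-1, 2m-1, ... within the span cover every length-m window
        for pos in range(site.start + m - 1, site.end, m):
            mutant[pos] = TRANSVERSION[mutant[pos]]

    # edits can, rarely, assemble a fresh seed match at a junction; break any
    # survivor at the midpoint of its matched block until the scan is clean
    for _ in range(_MAX_REPAIR_ROUNDS):
        residual = scan_insert("".join(mutant), seed, label)
        if not residual:
            break
        for site in residual:
            pos = site.match_start + site.match_len // 2
            mutant[pos] = TRANSVERSION[mutant[pos]]
    else:
        raise RuntimeError(f"{label}: mutant design failed to converge")

    mutant_seq = "".join(mutant)
    edited = [i for i, (a, b) in enumerate(zip(wt, mutant_seq)) if a != b]
    return ReporterInsert(
        label=label,
        wild_type_sequence=wt,
        mutant_sequence=mutant_seq,
        edited_positions=edited,
        seed=seed,
    )


def build_insert(
    transcript: TranscriptRecord,
    site: Site,
    seed: SeedQuery,
    flank: int = 10,
    label: str | None = None,
) -> ReporterInsert:
    """Cut a site plus symmetric native flanks out of its transcript and
    design the matching mutant insert."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    start = max(0, site.start - flank)
    end = min(len(transcript.sequence), site.end + flank)
    context = transcript.sequence[start:end]
    name = label or f"{transcript.gene_symbol}_{site.start}"
    return design_mutant(context, seed, label=name)
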