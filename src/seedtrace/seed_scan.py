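"""Extended-seed binding-site scanning.

A binding site is a contiguous stretch of the transcript (sense strand)
exactly matching a substring of the extended antisense seed, at least
``min_match`` bp long. The extended seed is the reverse complement of the
miRNA's 5'-terminal k nucleotides written in target-sense orientation; for
the let-7 family with k=10 this is TACTACCTCA. Matches are perfect: no
mismatches, no G:U wobble, no gaps, and N never matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .sequence_io import MicroRNA, Region, TranscriptRecord, region_of

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: The extended let-7 antisense seed (reverse complement of the shared
#: 5'-terminal decamer of the let-7 family).
LET7_EXTENDED_SEED = "TACTACCTCA"


@dataclass(frozen=True)
class SeedQuery:
    """An extended antisense seed plus the minimum perfect-match length."""

    mirna_name: str
    extended_seed: str
    min_match: int = 6

    def __post_init__(self) -> None:
        seed = self.extended_seed.upper().replace("U", "T")
        object.__setattr__(self, "extended_seed", seed)
        if set(seed) - set("ACGT"):
            raise ValueError(f"extended seed must be unambiguous DNA: {seed!r}")
        if not 1 <= self.min_match <= len(seed):
            raise ValueError(
                f"min_match {self.min_match} outside [1, {len(seed)}]"
            )

    @property
    def k(self) -> int:
        return len(self.extended_seed)


def let7_query(min_match: int = 6) -> SeedQuery:
    return SeedQuery("let-7", LET7_EXTENDED_SEED, min_match=min_match)


@dataclass
class Site:
    """One predicted binding locus on a transcript.

    ``start``/``end`` span the full locus. When overlapping maximal matches
    are merged into one locus, the span is their union while ``match_start``,
    ``match_len`` and ``seed_offset`` describe the longest constituent match
    (ties broken by smaller seed_offset, then smaller start), so
    ``transcript[match_start : match_start + match_len] ==
    extended_seed[seed_offset : seed_offset + match_len]`` always holds.
    For an unmerged locus, match_start == start and end - start == match_len.
    """

    transcript_id: str
    start: int
    end: int
    match_len: int
    seed_offset: int
    match_start: int
    region: Region
    straddles_boundary: bool = False
    conserved: Optional[bool] = None

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end

    def same_locus(self, other: "Site") -> bool:
        return (
            self.transcript_id == other.transcript_id
            and self.interval == other.interval
            and self.match_len == other.match_len
            and self.seed_offset == other.seed_offset
        )


def derive_extended_seed(
    mirna: MicroRNA, k: int = 10, min_match: int = 6
) -> SeedQuery:
    """Reverse-complement the miRNA's 5'-terminal ``k`` nucleotides into a
    target-sense DNA seed string.

    >>> derive_extended_seed(MicroRNA("let-7g", "UGAGGUAGUAGUUUGUACAGUU")).extended_seed
    'TACTACCTCA'
    """
    if k > len(mirna.mature_sequence):
        raise ValueError(
            f"k={k} exceeds miRNA length {len(mirna.mature_sequence)}"
        )
    if k < min_match:
        raise ValueError(f"k={k} shorter than min_match={min_match}")
    five_prime = mirna.mature_sequence[:k].replace("U", "T")
    seed = five_prime.translate(_COMPLEMENT)[::-1]
    return SeedQuery(mirna.name, seed, min_match=min_match)


def _maximal_matches(sequence: str, seed: SeedQuery) -> list[tuple[int, int, int]]:
    """All maximal exact matches (start, seed_offset, length) with
    length >= min_match.

    Anchored search: every qualifying match contains at least one of the
    seed's min_match-length substrings, so each occurrence of one of those
    anchors is extended to its maximal run and de-duplicated.
    """
    s = seed.extended_seed
    m, k = seed.min_match, seed.k
    anchors: dict[str, list[int]] = {}
    for j in range(k - m + 1):
        anchors.setdefault(s[j : j + m], []).append(j)

    seen: set[tuple[int, int]] = set()
    out: list[tuple[int, int, int]] = []
    for word, offsets in anchors.items():
        pos = sequence.find(word)
        while pos != -1:
            for j in offsets:
                i0, j0 = pos, j
                while i0 > 0 and j0 > 0 and sequence[i0 - 1] == s[j0 - 1]:
                    i0 -= 1
                    j0 -= 1
                if (i0, j0) in seen:
                    continue
                seen.add((i0, j0))
                i1, j1 = pos + m, j + m
                while i1 < len(sequence) and j1 < k and sequence[i1] == s[j1]:
                    i1 += 1
                    j1 += 1
                length = i1 - i0
                out.append((i0, j0, length))
            pos = sequence.find(word, pos + 1)
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def merge_matches(
    matches: Sequence[tuple[int, int, int]]
) -> list[tuple[int, int, tuple[int, int, int]]]:
    """Merge maximal matches whose transcript intervals overlap.

    Returns (union_start, union_end, best_match) per locus where best_match
    is the constituent with the greatest length (ties: smaller seed_offset,
    then smaller start).
    """
    loci: list[tuple[int, int, tuple[int, int, int]]] = []
    for match in sorted(matches, key=lambda t: t[0]):
        i, j, length = match
        if loci and i < loci[-1][1]:  # overlaps previous locus
            u0, u1, best = loci[-1]
            u1 = max(u1, i + length)
            if (length, -j, -i) > (best[2], -best[1], -best[0]):
                best = match
            loci[-1] = (u0, u1, best)
        else:
            loci.append((i, i + length, match))
    return loci


def find_sites(
    transcript: TranscriptRecord,
    seed: SeedQuery,
    merge_overlapping: bool = True,
) -> list[Site]:
    """Enumerate all binding sites of ``seed`` on the transcript sense strand.

    Every maximal contiguous exact match of length >= min_match between the
    transcript and any substring of the extended seed is reported; with
    ``merge_overlapping`` (default), maximal matches at overlapping loci are
    collapsed into a single Site spanning their union, mirroring one mark per
    locus on a gene diagram. Sites are sorted by start; output is
    deterministic.
    """
    matches = _maximal_matches(transcript.sequence, seed)
    if merge_overlapping:
        loci = merge_matches(matches)
    else:
        loci = [(i, i + length, (i, j, length)) for i, j, length in matches]

    sites = []
    for u0, u1, (mi, mj, mlen) in loci:
        start_region = region_of(transcript, u0)
        end_region = region_of(transcript, u1 - 1)
        sites.append(
            Site(
                transcript_id=transcript.transcript_id,
                start=u0,
                end=u1,
                match_len=mlen,
                seed_offset=mj,
                match_start=mi,
                region=start_region,
                straddles_boundary=start_region is not end_region,
            )
        )
    return sites


SITE_COLUMNS = [
    "transcript_id",
    "start",
    "end",
    "name",
    "match_len",
    "seed_offset",
    "match_start",
    "region",
    "straddles_boundary",
    "conserved",
]


def sites_to_frame(sites: Sequence[Site], mirna_name: str = "") -> pd.DataFrame:
    """BED-like tidy table of sites (one row per locus)."""
    rows = []
    for s in sites:
        rows.append(
            {
                "transcript_id": s.transcript_id,
                "start": s.start,
                "end": s.end,
                "name": f"{mirna_name or 'seed'}:{s.seed_offset}",
                "match_len": s.match_len,
                "seed_offset": s.seed_offset,
                "match_start": s.match_start,
                "region": str(s.region),
                "straddles_boundary": s.straddles_boundary,
                "conserved": "" if s.conserved is None else bool(s.conserved),
            }
        )
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def frame_to_sites(frame: pd.DataFrame) -> list[Site]:
    """Inverse of :func:`sites_to_frame` (round-trips without loss)."""
    sites = []
    for row in frame.itertuples(index=False):
        conserved_raw = getattr(row, "conserved", "")
        if conserved_raw in ("", None) or pd.isna(conserved_raw):
            conserved: Optional[bool] = None
        else:
            conserved = str(conserved_raw).strip().lower() in ("true", "1")
        sites.append(
            Site(
                transcript_id=str(row.transcript_id),
                start=int(row.start),
                end=int(row.end),
                match_len=int(row.match_len),
                seed_offset=int(row.seed_offset),
                match_start=int(row.match_start),
                region=Region(str(row.region)),
                straddles_boundary=bool(row.straddles_boundary),
                conserved=conserved,
            )
        )
    return sites
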