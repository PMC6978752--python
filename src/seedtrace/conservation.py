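"""Cross-species conservation of binding sites.

A site is conserved when its position is retained between ortholog mRNAs
under an optimal global pairwise alignment: the site's interval, projected
through the alignment into the partner transcript's coordinates, must
overlap a site predicted on the partner by at least ``min_overlap``
alignment columns (default: the scanner's minimum match length, 6).

Scoring convention: match/mismatch are per-column; a gap of length L scores
``gap_open + (L - 1) * gap_extend`` (the first gapped column pays the open
penalty). End gaps are penalized — the alignment is truly global.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import Align

from .seed_scan import SeedQuery, Site, find_sites
from .sequence_io import OrthologPair


@dataclass(frozen=True)
class ScoringParams:
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= self.match:
            raise ValueError("require mismatch < match and match > 0")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")


DEFAULT_SCORING = ScoringParams()


@dataclass
class PairwiseAlignment:
    """Optimal global alignment with column-level coordinate maps.

    ``a_to_column[p]`` is the alignment column holding residue p of sequence
    A (likewise for B); removing gaps from the aligned strings recovers the
    inputs exactly.
    """

    seq_a: str
    seq_b: str
    aligned_a: str
    aligned_b: str
    score: float
    scoring_params: ScoringParams
    a_to_column: list[int] = field(repr=False)
    b_to_column: list[int] = field(repr=False)

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)


def _column_map(gapped: str) -> list[int]:
    return [col for col, ch in enumerate(gapped) if ch != "-"]


def global_align(
    seq_a: str, seq_b: str, scoring_params: ScoringParams = DEFAULT_SCORING
) -> PairwiseAlignment:
    """Needleman–Wunsch global optimum with affine gaps.

    Returns one optimal alignment; ties between co-optimal tracebacks are
    broken by the aligner's canonical enumeration order, so the result is
    deterministic and bit-stable for fixed inputs.
    """
    if not seq_a or not seq_b:
        raise ValueError("global_align requires two nonempty sequences")
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=scoring_params.match,
        mismatch_score=scoring_params.mismatch,
        open_gap_score=scoring_params.gap_open,
        extend_gap_score=scoring_params.gap_extend,
    )
    alignment = aligner.align(seq_a, seq_b)[0]
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])
    return PairwiseAlignment(
        seq_a=seq_a,
        seq_b=seq_b,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(alignment.score),
        scoring_params=scoring_params,
        a_to_column=_column_map(aligned_a),
        b_to_column=_column_map(aligned_b),
    )


def project_interval(
    alignment: PairwiseAlignment, start: int, end: int
) -> tuple[int, int]:
    """Project an A-coordinate interval [start, end) into B coordinates.

    Returns the smallest B interval whose columns cover the A interval's
    columns. When every covered column is a gap in B the interval is empty:
    (anchor, anchor) at the B position where the A block would insert.
    """
    if not 0 <= start < end <= len(alignment.seq_a):
        raise ValueError(
            f"interval [{start}, {end}) out of bounds for sequence A "
            f"(length {len(alignment.seq_a)})"
        )
    col_lo = alignment.a_to_column[start]
    col_hi = alignment.a_to_column[end - 1]
    b_cols = alignment.b_to_column
    b_start = bisect_left(b_cols, col_lo)
    b_end = bisect_right(b_cols, col_hi)
    if b_start >= b_end:  # aligned wholly to gaps in B
        return b_start, b_start
    return b_start, b_end


@dataclass
class ConservationCall:
    """Conservation verdict for one species-A site."""

    site: Site
    projected_start: int
    projected_end: int
    overlap_columns: int
    conserved: bool
    partner_index: Optional[int] = None  # index into sites_b of best partner


def _site_columns(site: Site, pos_to_column: Sequence[int]) -> set[int]:
    return set(pos_to_column[site.start : site.end])


def classify_sites(
    pair: OrthologPair,
    sites_a: Sequence[Site],
    sites_b: Sequence[Site],
    alignment: Optional[PairwiseAlignment] = None,
    min_overlap: int = 6,
    scoring_params: ScoringParams = DEFAULT_SCORING,
) -> list[ConservationCall]:
    """Call each species-A site conserved/non-conserved against species B.

    A site is conserved iff at least ``min_overlap`` alignment columns carry
    both a residue of the A site and a residue of some B site. Sets
    ``site.conserved`` in place and returns the calls in sites_a order.
    Swap the pair's members (and the site lists) for the reciprocal calls.
    """
    a_seq = pair.species_a_transcript.sequence
    b_seq = pair.species_b_transcript.sequence
    if alignment is None:
        alignment = global_align(a_seq, b_seq, scoring_params)
    if alignment.seq_a != a_seq or alignment.seq_b != b_seq:
        raise ValueError(
            f"alignment was not built from the {pair.gene_symbol} pair's sequences"
        )

    b_columns = [_site_columns(s, alignment.b_to_column) for s in sites_b]
    calls = []
    for site in sites_a:
        cols = _site_columns(site, alignment.a_to_column)
        best_overlap, best_idx = 0, None
        for idx, bc in enumerate(b_columns):
            overlap = len(cols & bc)
            if overlap > best_overlap:
                best_overlap, best_idx = overlap, idx
        p_start, p_end = project_interval(alignment, site.start, site.end)
        conserved = best_overlap >= min_overlap
        site.conserved = conserved
        calls.append(
            ConservationCall(
                site=site,
                projected_start=p_start,
                projected_end=p_end,
                overlap_columns=best_overlap,
                conserved=conserved,
                partner_index=best_idx,
            )
        )
    return calls


def annotate_pair(
    pair: OrthologPair,
    seed: SeedQuery,
    min_overlap: int = 6,
    scoring_params: ScoringParams = DEFAULT_SCORING,
) -> tuple[list[Site], list[Site], PairwiseAlignment]:
    """Scan both transcripts of an ortholog pair and fill in conservation
    labels on both sides. Returns (sites_a, sites_b, alignment)."""
    sites_a = find_sites(pair.species_a_transcript, seed)
    sites_b = find_sites(pair.species_b_transcript, seed)
    alignment = global_align(
        pair.species_a_transcript.sequence,
        pair.species_b_transcript.sequence,
        scoring_params,
    )
    classify_sites(pair, sites_a, sites_b, alignment, min_overlap)
    # reciprocal labels for B sites against A, reusing the same alignment
    reverse = PairwiseAlignment(
        seq_a=alignment.seq_b,
        seq_b=alignment.seq_a,
        aligned_a=alignment.aligned_b,
        aligned_b=alignment.aligned_a,
        score=alignment.score,
        scoring_params=alignment.scoring_params,
        a_to_column=alignment.b_to_column,
        b_to_column=alignment.a_to_column,
    )
    reverse_pair = OrthologPair(
        species_a_transcript=pair.species_b_transcript,
        species_b_transcript=pair.species_a_transcript,
        gene_symbol=pair.gene_symbol,
    )
    classify_sites(reverse_pair, sites_b, sites_a, reverse, min_overlap)
    return sites_a, sites_b, alignment
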