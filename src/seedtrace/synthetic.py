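"""Ground-truthed synthetic inputs for every pipeline stage.

Transcripts are random backgrounds at a chosen GC content with seed-site
blocks planted verbatim at known positions; the background (including the
plant junctions) is rejection-sampled until the scanner reports exactly the
planted sites, so the returned ground truth is exact by construction.
Ortholog partners apply i.i.d. substitutions and geometric-length indels
under a divergence spec; assay tables add the stated noise models around
known true effects.

Reproducibility: every generator is a pure function of its rng_seed.
Substitution draws are threshold-coupled (one uniform per position,
substitute where it falls below the rate), so raising the substitution rate
at a fixed seed only ever adds edits — site survival is nested across a
rate grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .reporter_design import TRANSVERSION
from .seed_scan import SeedQuery, Site, find_sites, let7_query
from .sequence_io import Region, TranscriptRecord, region_of

_BASES = np.array(list("ACGT"))
_REJECTION_CAP = 10_000


@dataclass(frozen=True)
class PlantSpec:
    """One binding-site block to plant: which region, where in it, and which
    slice of the extended seed."""

    region: Region
    offset_within_region: int
    match_len: int
    seed_offset: int = 0

    def __post_init__(self) -> None:
        if self.offset_within_region < 0 or self.seed_offset < 0:
            raise ValueError("offsets must be >= 0")


@dataclass(frozen=True)
class DivergenceSpec:
    """Stochastic divergence model between ortholog transcripts.

    site_policy: "preserve" shields planted blocks from all edits; "expose"
    lets them mutate like background; "ablate" force-edits every block so no
    planted site survives.
    """

    substitution_rate: float
    indel_rate: float = 0.0
    mean_indel_len: float = 2.0
    site_policy: Literal["preserve", "expose", "ablate"] = "preserve"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must lie in [0, 1]")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate must lie in [0, 1]")
        if self.mean_indel_len < 1.0:
            raise ValueError("mean_indel_len must be >= 1")
        if self.site_policy not in ("preserve", "expose", "ablate"):
            raise ValueError(f"unknown site_policy {self.site_policy!r}")


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def _sites_match(found: Sequence[Site], expected: Sequence[Site]) -> bool:
    if len(found) != len(expected):
        return False
    return all(
        f.same_locus(e) and f.match_start == e.match_start
        for f, e in zip(found, expected)
    )


def generate_transcript(
    length: int,
    gc_fraction: float = 0.5,
    plants: Sequence[PlantSpec] = (),
    seed: Optional[SeedQuery] = None,
    rng_seed: int = 0,
    cds_start: Optional[int] = None,
    cds_end: Optional[int] = None,
    transcript_id: str = "synthetic-1",
    species: str = "mouse",
    gene_symbol: str = "SynGene",
) -> tuple[TranscriptRecord, list[Site]]:
    """Random transcript with planted seed sites and an exact ground truth.

    The CDS defaults to the middle 60% of the transcript (5'UTR 15%, 3'UTR
    25%), loosely mimicking mRNA architecture. Returns the transcript and
    the Site list the scanner is guaranteed to report.
    """
    seed = seed or let7_query()
    if cds_start is None:
        cds_start = max(1, round(0.15 * length))
    if cds_end is None:
        cds_end = min(length - 1, round(0.75 * length))
    if not 0 <= cds_start < cds_end <= length:
        raise ValueError("invalid CDS layout for requested length")

    bounds = {
        Region.UTR5: (0, cds_start),
        Region.CDS: (cds_start, cds_end),
        Region.UTR3: (cds_end, length),
    }
    blocks: list[tuple[int, int, PlantSpec]] = []
    for plant in plants:
        if not seed.min_match <= plant.match_len <= seed.k:
            raise ValueError(
                f"plant match_len {plant.match_len} outside "
                f"[{seed.min_match}, {seed.k}]"
            )
        if plant.seed_offset + plant.match_len > seed.k:
            raise ValueError("plant block runs off the end of the extended seed")
        lo, hi = bounds[plant.region]
        start = lo + plant.offset_within_region
        end = start + plant.match_len
        if end > hi:
            raise ValueError(
                f"plant in {plant.region} at offset {plant.offset_within_region} "
                f"does not fit (region [{lo}, {hi}))"
            )
        blocks.append((start, end, plant))
    blocks.sort()
    for (s0, e0, _), (s1, _, _) in zip(blocks, blocks[1:]):
        if s1 < e0 + seed.k:
            raise ValueError(
                f"planted blocks at {s0} and {s1} closer than k={seed.k} nt"
            )

    expected: list[Site] = []
    rng = np.random.default_rng(rng_seed)
    planted_mask = np.zeros(length, dtype=bool)
    plant_chars = np.zeros(length, dtype="<U1")
    for start, end, plant in blocks:
        block = seed.extended_seed[plant.seed_offset : plant.seed_offset + plant.match_len]
        planted_mask[start:end] = True
        plant_chars[start:end] = list(block)

    for _attempt in range(_REJECTION_CAP):
        codes = _random_background(rng, length, gc_fraction)
        chars = _BASES[codes]
        chars[planted_mask] = plant_chars[planted_mask]
        record = TranscriptRecord(
            transcript_id=transcript_id,
            species=species,
            gene_symbol=gene_symbol,
            sequence="".join(chars),
            cds_start=cds_start,
            cds_end=cds_end,
        )
        if not expected:
            expected = [
                Site(
                    transcript_id=transcript_id,
                    start=start,
                    end=end,
                    match_len=plant.match_len,
                    seed_offset=plant.seed_offset,
                    match_start=start,
                    region=region_of(record, start),
                    straddles_boundary=False,
                )
                for start, end, plant in blocks
            ]
        if _sites_match(find_sites(record, seed), expected):
            return record, expected
        expected = expected if blocks else []
    raise RuntimeError(
        f"rejection sampling exceeded {_REJECTION_CAP} attempts "
        f"(length={length}, gc={gc_fraction}); the seed content is too likely "
        "at this length — lower length or plant density"
    )


def generate_ortholog(
    transcript: TranscriptRecord,
    sites: Sequence[Site],
    spec: DivergenceSpec,
) -> tuple[TranscriptRecord, list[Site]]:
    """Diverged ortholog of ``transcript`` plus the surviving planted sites
    in the ortholog's coordinates.

    Substitutions are i.i.d. per position; indels start at a position with
    probability indel_rate, have geometric lengths with the stated mean, and
    never split a preserved planted block. A planted site survives when its
    block reaches the ortholog unedited and contiguous.
    """
    seq = transcript.sequence
    n = len(seq)
    rng = np.random.default_rng(spec.rng_seed)
    u_sub = rng.random(n)
    alt_pick = rng.integers(0, 3, size=n)
    u_indel = rng.random(n)
    ins_flag = rng.random(n) < 0.5
    indel_len = rng.geometric(1.0 / spec.mean_indel_len, size=n)
    ins_rng = np.random.default_rng(
        np.random.SeedSequence([spec.rng_seed, 1]).generate_state(1)[0]
    )

    protected = np.zeros(n, dtype=bool)
    interior = np.zeros(n, dtype=bool)
    forced: set[int] = set()
    for site in sites:
        if site.end - site.start > 1:
            interior[site.start + 1 : site.end] = True
        if spec.site_policy in ("preserve", "ablate"):
            # indels and stochastic substitutions never touch the block;
            # under "ablate" the block is destroyed by forced edits instead
            protected[site.start : site.end] = True
        if spec.site_policy == "ablate":
            # one transversion per 6-bp window of the block kills every
            # contiguous sub-match the scanner could still detect
            span = site.end - site.start
            first = site.start + min(5, span - 1)
            forced.update(range(first, site.end, 6))

    alternatives = {
        "A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG", "N": "ACG",
    }
    out: list[str] = []
    new_pos = np.full(n, -1, dtype=int)
    skip_until = 0
    for p in range(n):
        if p < skip_until:
            continue
        if u_indel[p] < spec.indel_rate:
            length = int(indel_len[p])
            if ins_flag[p]:
                if not interior[p]:  # never insert inside a planted block
                    out.extend(_BASES[ins_rng.integers(0, 4, size=length)])
            else:
                del_end = min(n, p + length)
                if not protected[p:del_end].any():
                    skip_until = del_end
                    continue
        base = seq[p]
        if p in forced:
            base = TRANSVERSION[base]
        elif u_sub[p] < spec.substitution_rate and not protected[p]:
            base = alternatives[base][alt_pick[p]]
        new_pos[p] = len(out)
        out.append(base)

    new_len = len(out)

    def _map_boundary(old: int) -> int:
        for q in range(old, n):
            if new_pos[q] >= 0:
                return int(new_pos[q])
        return new_len

    new_cds_start = _map_boundary(transcript.cds_start)
    new_cds_end = max(new_cds_start + 1, _map_boundary(transcript.cds_end))
    new_cds_start = min(new_cds_start, new_len - 1)
    new_cds_end = min(max(new_cds_end, new_cds_start + 1), new_len)

    ortholog = TranscriptRecord(
        transcript_id=f"{transcript.transcript_id}-orth",
        species="human" if transcript.species != "human" else "mouse",
        gene_symbol=transcript.gene_symbol,
        sequence="".join(out),
        cds_start=new_cds_start,
        cds_end=new_cds_end,
    )

    survivors: list[Site] = []
    for site in sites:
        positions = new_pos[site.start : site.end]
        if (positions < 0).any():
            continue
        if not (np.diff(positions) == 1).all():
            continue
        s0, s1 = int(positions[0]), int(positions[-1]) + 1
        if ortholog.sequence[s0:s1] != seq[site.start : site.end]:
            continue
        survivors.append(
            Site(
                transcript_id=ortholog.transcript_id,
                start=s0,
                end=s1,
                match_len=site.match_len,
                seed_offset=site.seed_offset,
                match_start=s0 + (site.match_start - site.start),
                region=region_of(ortholog, s0),
                straddles_boundary=False,
            )
        )
    return ortholog, survivors


# ---------------------------------------------------------------------------
# assay tables


@dataclass
class AssayEffectModel:
    """True effects behind the generated assay tables.

    Defaults mirror the study's reporter/chemotaxis/expression design:
    technical triplicates; let-7 sites repress reporter output ~2-fold and
    their mutants restore it; let-7-high cells lose chemokine-driven
    migration; chemokine-receptor transcripts drop with let-7 dosage; EAE
    severity tracks let-7 loss (groups n=7/7/8 scored daily to day 25).
    """

    luciferase_true_rlu: dict[str, float] = field(
        default_factory=lambda: {
            "Ccr2_WT": 0.5, "Ccr2_mut": 1.0,
            "Ccr5_WT": 0.5, "Ccr5_mut": 1.0,
            "seed_WT": 0.3, "seed_mut": 1.0,
        }
    )
    luciferase_sigma: float = 0.1
    renilla_mean: float = 5e5
    transwell_fold: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("WT", "CCL2"): 3.5, ("WT", "CCL4"): 3.0, ("WT", "CCL2+CCL4"): 4.5,
            ("Let7Tg", "CCL2"): 1.3, ("Let7Tg", "CCL4"): 1.2,
            ("Let7Tg", "CCL2+CCL4"): 1.5,
            ("Lin28Tg", "CCL2"): 5.0, ("Lin28Tg", "CCL4"): 4.5,
            ("Lin28Tg", "CCL2+CCL4"): 6.0,
        }
    )
    transwell_control_mean: float = 200.0
    qpcr_fold: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("WT", "Ccr2"): 0.8, ("WT", "Ccr5"): 0.6,
            ("Let7Tg", "Ccr2"): 0.2, ("Let7Tg", "Ccr5"): 0.15,
            ("Lin28Tg", "Ccr2"): 1.6, ("Lin28Tg", "Ccr5"): 1.2,
        }
    )
    ct_reference_mean: float = 20.0
    ct_sigma: float = 0.15
    clinical_trajectories: dict[str, list[float]] = field(
        default_factory=lambda: {
            # day 0..25; onset ~day 8, peak ~day 15
            "WT": [0] * 8 + [0.5, 1, 1.5, 2, 2.5, 3, 3.3, 3.5, 3.4, 3.3,
                             3.2, 3.0, 2.8, 2.7, 2.6, 2.5, 2.4, 2.3],
            "Let7Tg": [0] * 10 + [0.3, 0.5, 0.8, 1.0, 1.2, 1.3, 1.2, 1.1,
                                  1.0, 0.9, 0.8, 0.8, 0.7, 0.7, 0.6, 0.6],
            "Lin28Tg": [0] * 7 + [0.8, 1.5, 2.2, 2.8, 3.4, 3.8, 4.2, 4.5,
                                  4.4, 4.3, 4.2, 4.1, 4.0, 3.9, 3.8, 3.7,
                                  3.6, 3.5],
        }
    )
    clinical_n_mice: dict[str, int] = field(
        default_factory=lambda: {"WT": 7, "Let7Tg": 7, "Lin28Tg": 8}
    )
    clinical_sigma: float = 0.5
    n_replicates: int = 3


def generate_assay_tables(
    model: Optional[AssayEffectModel] = None,
    rng_seed: int = 0,
    noise: bool = True,
) -> dict[str, pd.DataFrame | dict]:
    """Tidy replicate tables for all four assays plus the ground truth.

    Noise models: luciferase channels lognormal (so RLU is lognormal around
    the true ratio), transwell counts Poisson around their means, Ct values
    Gaussian, clinical scores rounded and clipped to the 0-5 scale. With
    ``noise=False`` every measurement equals its true mean exactly.
    """
    model = model or AssayEffectModel()
    rng = np.random.default_rng(rng_seed)

    def _lognormal(sigma: float, size: int) -> np.ndarray:
        if not noise or sigma == 0:
            return np.ones(size)
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)

    rows = []
    for label, true_rlu in model.luciferase_true_rlu.items():
        ren = model.renilla_mean * _lognormal(model.luciferase_sigma, model.n_replicates)
        fire = true_rlu * ren * _lognormal(model.luciferase_sigma, model.n_replicates)
        for i in range(model.n_replicates):
            rows.append(
                {
                    "sample_id": f"{label}_r{i + 1}",
                    "group_label": label,
                    "replicate_index": i + 1,
                    "firefly": float(fire[i]),
                    "renilla": float(ren[i]),
                }
            )
    luciferase = pd.DataFrame(rows)

    rows = []
    groups = sorted({g for g, _ in model.transwell_fold})
    conditions = ["media"] + sorted({c for _, c in model.transwell_fold})
    for group in groups:
        for condition in conditions:
            fold = 1.0 if condition == "media" else model.transwell_fold[(group, condition)]
            mean_count = fold * model.transwell_control_mean
            for i in range(model.n_replicates):
                count = rng.poisson(mean_count) if noise else mean_count
                rows.append(
                    {
                        "sample_id": f"{group}_{condition}_r{i + 1}",
                        "group_label": group,
                        "condition": condition,
                        "replicate_index": i + 1,
                        "migrated_count": float(count),
                    }
                )
    transwell = pd.DataFrame(rows)

    rows = []
    for (group, gene), fold in model.qpcr_fold.items():
        for i in range(model.n_replicates):
            ct_ref = model.ct_reference_mean + (
                rng.normal(0, model.ct_sigma) if noise else 0.0
            )
            ct_tgt = (
                model.ct_reference_mean
                - np.log2(fold)
                + (rng.normal(0, model.ct_sigma) if noise else 0.0)
            )
            rows.append(
                {
                    "sample_id": f"{group}_{gene}_r{i + 1}",
                    "group_label": group,
                    "gene": gene,
                    "replicate_index": i + 1,
                    "ct_target": float(ct_tgt),
                    "ct_reference": float(ct_ref),
                }
            )
    qpcr = pd.DataFrame(rows)

    rows = []
    for group, trajectory in model.clinical_trajectories.items():
        for mouse in range(model.clinical_n_mice[group]):
            for day, true_mean in enumerate(trajectory):
                raw = true_mean + (rng.normal(0, model.clinical_sigma) if noise else 0.0)
                score = int(np.clip(round(raw), 0, 5))
                rows.append(
                    {
                        "sample_id": f"{group}_m{mouse + 1}",
                        "group_label": group,
                        "mouse_id": f"{group}_m{mouse + 1}",
                        "day": day,
                        "score": score,
                    }
                )
    clinical = pd.DataFrame(rows)

    truth = {
        "rng_seed": rng_seed,
        "rlu": dict(model.luciferase_true_rlu),
        "percent_migration": {
            f"{g}:{c}": 100.0 * f for (g, c), f in model.transwell_fold.items()
        },
        "fold_expression": {f"{g}:{x}": f for (g, x), f in model.qpcr_fold.items()},
        "clinical_trajectories": {
            g: list(t) for g, t in model.clinical_trajectories.items()
        },
    }
    return {
        "luciferase": luciferase,
        "transwell": transwell,
        "qpcr": qpcr,
        "clinical_score": clinical,
        "truth": truth,
    }
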