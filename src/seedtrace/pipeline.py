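"""End-to-end pipeline: scan -> conserve -> report.

A pipeline run is configured by a small YAML (or dict) naming the inputs of
each requested stage; every output is stamped with the tool version, the
parameters used and SHA-256 digests of the inputs, and re-runs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .conservation import ScoringParams, annotate_pair
from .seed_scan import SeedQuery, find_sites, let7_query, sites_to_frame
from .sequence_io import read_ortholog_pairs, read_transcripts
from .sitemap import SiteMap, render_site_map


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _log(stream, stage: str, message: str, **extra: Any) -> None:
    record = {"stage": stage, "message": message, **extra}
    print(json.dumps(record, sort_keys=True), file=stream)


def load_config(source: str | Path | dict) -> dict:
    if isinstance(source, dict):
        return dict(source)
    with open(source) as handle:
        config = yaml.safe_load(handle)
    if not isinstance(config, dict):
        raise ValueError("pipeline config must be a mapping")
    return config


def seed_from_config(config: dict) -> SeedQuery:
    min_match = int(config.get("min_match", 6))
    if "extended_seed" in config:
        return SeedQuery(
            config.get("mirna_name", "seed"),
            config["extended_seed"],
            min_match=min_match,
        )
    return let7_query(min_match=min_match)


def run_pipeline(
    config: str | Path | dict,
    out_dir: str | Path,
    log_stream=sys.stderr,
) -> dict[str, Path]:
    """Execute scan [-> conserve] -> report per the config.

    Config keys: transcripts_fasta, annotations (required); extended_seed /
    mirna_name, k, min_match (optional, default let-7); pairs_tsv and
    min_overlap to enable conservation; map_format ("svg"/"text").
    Returns the paths of the written outputs.
    """
    config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    t0 = time.monotonic()

    for key in ("transcripts_fasta", "annotations"):
        if key not in config:
            raise ValueError(f"scan stage: config missing {key!r}")
    fasta = Path(config["transcripts_fasta"])
    annotations = Path(config["annotations"])
    transcripts = read_transcripts(fasta, annotations)
    seed = seed_from_config(config)
    _log(log_stream, "scan", "scanning transcripts",
         n_transcripts=len(transcripts), extended_seed=seed.extended_seed,
         min_match=seed.min_match)

    sites_by_tx = {t.transcript_id: find_sites(t, seed) for t in transcripts}

    if config.get("conserve") and "pairs_tsv" not in config:
        raise ValueError("conserve stage: config missing 'pairs_tsv'")
    conserve = "pairs_tsv" in config
    if conserve:
        pairs = read_ortholog_pairs(Path(config["pairs_tsv"]), transcripts)
        min_overlap = int(config.get("min_overlap", seed.min_match))
        scoring = ScoringParams(
            match=float(config.get("match", 2.0)),
            mismatch=float(config.get("mismatch", -1.0)),
            gap_open=float(config.get("gap_open", -4.0)),
            gap_extend=float(config.get("gap_extend", -1.0)),
        )
        conservation_rows = []
        for pair in pairs:
            sites_a, sites_b, alignment = annotate_pair(
                pair, seed, min_overlap=min_overlap, scoring_params=scoring
            )
            sites_by_tx[pair.species_a_transcript.transcript_id] = sites_a
            sites_by_tx[pair.species_b_transcript.transcript_id] = sites_b
            conservation_rows.append(
                {
                    "gene_symbol": pair.gene_symbol,
                    "transcript_id_a": pair.species_a_transcript.transcript_id,
                    "transcript_id_b": pair.species_b_transcript.transcript_id,
                    "alignment_score": alignment.score,
                    "n_sites_a": len(sites_a),
                    "n_sites_b": len(sites_b),
                    "n_conserved_a": sum(bool(s.conserved) for s in sites_a),
                }
            )
        conservation_path = out / "conservation.tsv"
        pd.DataFrame(conservation_rows).to_csv(conservation_path, sep="\t", index=False)
        outputs["conservation"] = conservation_path
        _log(log_stream, "conserve", "conservation calls written",
             n_pairs=len(pairs), min_overlap=min_overlap)

    frames = [
        sites_to_frame(sites_by_tx[t.transcript_id], seed.mirna_name)
        for t in transcripts
    ]
    sites_path = out / "sites.tsv"
    pd.concat(frames, ignore_index=True).to_csv(sites_path, sep="\t", index=False)
    outputs["sites"] = sites_path

    map_format = config.get("map_format", "svg")
    suffix = "svg" if map_format == "svg" else "txt"
    maps_dir = out / "maps"
    maps_dir.mkdir(exist_ok=True)
    for t in transcripts:
        site_map = SiteMap(
            transcript_id=t.transcript_id,
            length=len(t.sequence),
            cds_start=t.cds_start,
            cds_end=t.cds_end,
            sites=sites_by_tx[t.transcript_id],
        )
        path = maps_dir / f"{t.transcript_id}.{suffix}"
        path.write_text(render_site_map(site_map, map_format) + "\n")
        outputs[f"map:{t.transcript_id}"] = path

    manifest = {
        "tool": "seedtrace",
        "version": __version__,
        "parameters": {
            "extended_seed": seed.extended_seed,
            "min_match": seed.min_match,
            "min_overlap": int(config.get("min_overlap", seed.min_match)),
            "conserve": conserve,
        },
        "input_digests": {
            "transcripts_fasta": _sha256(fasta),
            "annotations": _sha256(annotations),
            **({"pairs_tsv": _sha256(Path(config["pairs_tsv"]))} if conserve else {}),
        },
        "outputs": {k: str(v.relative_to(out)) for k, v in outputs.items()},
    }
    manifest_path = out / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    outputs["manifest"] = manifest_path
    _log(log_stream, "report", "pipeline complete",
         seconds=round(time.monotonic() - t0, 3), out_dir=str(out))
    return outputs
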