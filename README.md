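# seedtrace

Discovery and cross-species conservation analysis of microRNA
extended-seed binding sites in mRNAs, with reporter-mutant design and the
quantification formulas of the accompanying functional assays.

## What it is for

let-7-family microRNAs repress targets through complementarity between the
mRNA and the miRNA's 5'-terminal seed region. `seedtrace` implements the
binding-site definition used in studies of let-7-mediated repression of
pathogenic Th17 programs (chemokine receptors *Ccr2*/*Ccr5*, cytokine
receptors *Il1r1*/*Il23r*):

- **Extended-seed scan.** The extended antisense seed is the DNA reverse
  complement of the miRNA's 5'-terminal *k* = 10 nucleotides; for the let-7
  family this is `TACTACCTCA`. A **binding site** is any maximal contiguous
  exact match of length ≥ *L*<sub>min</sub> = 6 bp between a transcript
  (sense strand, any region — 5'UTR, CDS or 3'UTR) and a substring of the
  extended seed. No mismatches, G:U wobble or gaps; `N` never matches.
  Overlapping maximal matches are merged into one site per locus.
- **Conservation.** Mouse/human ortholog transcripts are globally aligned
  (Needleman–Wunsch, affine gaps: match +2, mismatch −1, gap open −4, gap
  extend −1). A site is **conserved** when its position is retained: its
  interval, projected through the alignment, shares ≥ 6 alignment columns
  with a site predicted on the ortholog.
- **Reporter design.** For dual-luciferase constructs, the designer emits a
  wild-type insert (site + flanks) and a mutant with transversions spaced so
  that no ≥ 6 bp seed match survives anywhere in the insert — verified by
  re-scanning.
- **Assay quantification.** RLU = Firefly/Renilla; transwell chemotaxis as
  percent of the media-only control (≡ 100%); qPCR fold expression
  2^−ΔCt against a reference gene; EAE clinical-score curves
  (mean ± SEM over mice, integer scale 0–5); equal-variance two-tailed
  Student's *t*-test with the usual star thresholds.
- **Synthetic data.** Every stage can be driven by ground-truthed
  simulations: transcripts with planted sites on rejection-sampled seed-free
  backgrounds, ortholog pairs with tunable substitution/indel divergence,
  and assay tables with explicit noise models.

## Worked example

```python
from seedtrace import (MicroRNA, TranscriptRecord, OrthologPair,
                       derive_extended_seed, find_sites, design_mutant,
                       annotate_pair, rlu)

let7g = MicroRNA("let-7g", "UGAGGUAGUAGUUUGUACAGUU")
seed = derive_extended_seed(let7g, k=10, min_match=6)
print(seed.extended_seed)            # TACTACCTCA

tx = TranscriptRecord("Ccr2-demo", "mouse", "Ccr2",
    "GGAUUGCAGG" "UACUACCUCA" "UUGCACGGAU" "UACCUC" "AUGGCAGGAU",
    cds_start=8, cds_end=30)         # RNA input is normalized to DNA
for s in find_sites(tx, seed):
    print(s.start, s.end, s.match_len, s.seed_offset, s.region)
# 10 20 10 0 Region.CDS              <- planted full seed
# 30 37 7 3 Region.UTR3              <- partial match TACCTCA

ins = design_mutant(tx.sequence, seed, label="Ccr2-demo")
print(ins.mutant_sequence)           # GGATTGCAGGTACTAACTCATTGCACGGATTACCTAATGGCAGGAT
print(ins.edited_positions)          # [15, 35]  (two transversions suffice)

human = TranscriptRecord("CCR2-demo", "human", "Ccr2",
    tx.sequence[:14] + tx.sequence[16:], cds_start=8, cds_end=28)
sites_m, sites_h, aln = annotate_pair(OrthologPair(tx, human), seed)
print(aln.score)                     # 83.0
print([(s.start, s.conserved) for s in sites_m])
# [(10, False), (30, True)]          <- the deletion destroyed the CDS site;
#                                       the 3'UTR site is retained = conserved

print(rlu(5200, 10400))              # 0.5  (firefly repressed to half of renilla)
```

The site table, conservation table and gene-diagram site maps (red ticks
conserved, black non-conserved; SVG or text) are also available from the
command line:

```bash
seedtrace simulate --out-dir bundle --seed 7          # ground-truthed inputs
seedtrace scan --fasta bundle/transcripts.fasta --annotations bundle/annotations.tsv
seedtrace conserve --fasta ... --annotations ... --pairs bundle/pairs.tsv --out-dir out
seedtrace run --config config.yaml --out-dir out      # scan -> conserve -> report
```

## Layout

| module | contents |
| --- | --- |
| `seedtrace.sequence_io` | transcripts + CDS annotations, miRNAs, ortholog pairings; region arithmetic |
| `seedtrace.seed_scan` | extended-seed derivation and site enumeration |
| `seedtrace.conservation` | global alignment, interval projection, conservation calls |
| `seedtrace.reporter_design` | WT/mutant reporter inserts |
| `seedtrace.assay_quant` | RLU, chemotaxis %, 2^−ΔCt, clinical curves, *t*-test |
| `seedtrace.synthetic` | ground-truthed generators for all of the above |
| `seedtrace.sitemap`, `seedtrace.pipeline`, `seedtrace.cli` | diagrams, `run` pipeline, `seedtrace` CLI |

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
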