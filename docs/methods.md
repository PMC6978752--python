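# Methods

## Binding-site model

A site is a maximal contiguous exact match of length ≥ `min_match`
(default 6) between the transcript sense strand and any substring of the
extended antisense seed (default `TACTACCTCA`, the reverse complement of
the let-7 family's shared 5'-terminal decamer; `derive_extended_seed`
rebuilds it from any mature miRNA and any k). Design choices worth making
explicit:

- **"Partial match" means any seed substring.** The matched block is not
  required to cover the canonical seed core (miRNA positions 2–8); length is
  the only criterion. This is deliberately the most permissive reading of a
  length-threshold rule, and it makes the scan symmetric over the extended
  seed.
- **Perfect matches only.** No mismatches, no G:U wobble, no gaps; `N` in a
  transcript never matches (conservative handling of ambiguity).
- **Maximality.** A match contained in a longer match on the same diagonal
  is not reported separately; every reported block is non-extendable on
  either side.
- **Merge policy.** Maximal matches whose transcript intervals overlap are
  collapsed into one `Site` spanning their union — one mark per locus on a
  gene diagram. The `Site` records the longest constituent block
  (`match_start`, `match_len`, `seed_offset`; ties broken by smaller seed
  offset, then smaller start), so the verbatim-substring invariant is always
  checkable. Note that for a merged locus `end − start` can exceed
  `match_len`; the two coincide exactly when the locus is a single maximal
  match. Merging can be disabled (`merge_overlapping=False`, CLI
  `--no-merge`) to enumerate each maximal match separately.
- **Region labels** come from the site's start position; a site crossing a
  region boundary keeps that single label and sets `straddles_boundary`.
- Coordinates are 0-based half-open throughout; RNA input is normalized to
  DNA on ingest so seed strings printed in DNA alphabet apply directly.

The scanner anchors on the seed's `min_match`-length substrings
(`str.find`) and extends each hit to its maximal run, de-duplicated by
run origin — O(n·k) in practice. Its correctness is established against an
independent brute-force enumeration over every (position, seed-offset)
start pair (tests and acceptance script), not assumed.

## Conservation

Ortholog transcripts are aligned with true global Needleman–Wunsch/affine
gaps via `Bio.Align.PairwiseAligner` (end gaps penalized). Defaults:
match +2, mismatch −1, gap open −4, gap extend −1, where a length-L gap
scores `open + (L−1)·extend`. These are conventional DNA values — the
original desktop-alignment parameters behind this kind of analysis are not
standardized — and all four are exposed (`ScoringParams`, CLI flags), so
the conservation calls can be audited under any scoring. Optimality is
verified against an independent three-matrix Gotoh DP and, at tiny lengths,
exhaustive enumeration of all alignments. Among co-optimal alignments the
aligner's first canonical traceback is returned; this is deterministic and
bit-stable, which is the property the pipeline needs — the optimal score,
which the calls depend on, is tie-invariant.

A species-A site is **conserved** iff ≥ `min_overlap` alignment columns
(default 6, tied to `min_match` so the one length parameter governs both
detection and retention; CLI `--min-overlap`) carry both a residue of the
A site and a residue of some B site. Conservation is per-site, not
per-gene, and reciprocal calls for the B side reuse the same alignment.
`project_interval` maps an A interval to the smallest covering B interval;
a block aligned wholly against gaps projects to an empty interval at its
insertion point.

## Reporter design

`design_mutant` places transversions (A↔C, G↔T — chosen over transitions to
maximize disruption of base pairing) at every `min_match`-th position of
each matched span, so every 6-bp window of a former site contains an edit;
the mutant is re-scanned, and in the rare case an edit assembles a fresh
match at a junction, the survivor's block midpoint is edited and the scan
repeated (deterministic, bounded). The published constructs' actual mutant
sequences are not known; no equivalence to them is claimed — the guarantee
is functional (zero detectable sites at the design's `min_match`). Default
flank: 10 nt of native context per side.

## Assay quantification

- RLU = firefly / renilla (renilla = 0 is an error, not a 0/∞ convention).
- Percent chemotaxis = 100 · migrated / control; the media-only control is
  100% by definition. Table-level normalization uses the mean of each
  group's media-only replicates as the denominator.
- qPCR uses the 2^−ΔCt form (relative to the reference gene only, no ΔΔCt
  calibrator) with ideal doubling efficiency assumed.
- Clinical scores are integers 0–5 only (no half-points). Missing
  mouse-days are excluded from that day's n and flagged `incomplete`; no
  last-observation-carried-forward. SEM = sd/√n (ddof 1); with n = 1 it is
  reported as 0 with `sem_undefined` set rather than NaN.
- Group comparison is the equal-variance (Student's) two-tailed t-test;
  two identical constant groups return p = 1 by convention. Stars:
  p < 0.05 `*`, < 0.01 `**`, < 0.001 `***`, < 0.0001 `****`.

## Synthetic data

`generate_transcript` draws an i.i.d. background at the requested GC
fraction (default 0.5; CDS defaults to the middle 60% of the transcript —
5'UTR 15%, 3'UTR 25%), writes the planted blocks verbatim, and
rejection-samples the background until the scanner reports exactly the
planted loci (cap 10,000 attempts). Rejection — rather than post-hoc
masking — is what makes the returned ground truth exact: no chance
background site, and no background base accidentally extending a planted
block and shifting its coordinates. Planted blocks must sit inside one
region and be ≥ k apart so each is its own locus.

`generate_ortholog` applies i.i.d. substitutions and geometric-length
indels (mean length 2 by default; insertions never inside, deletions never
across a protected block). `site_policy` selects how planted blocks are
treated: `preserve` (shielded; conservation should hold), `expose`
(mutate like background; survival decays with rate), `ablate` (forced
transversions; nothing survives). One uniform draw per position is
thresholded against the substitution rate, so at a fixed seed a higher
rate strictly adds edits — survival and hence the conserved fraction are
monotone across a rate grid by construction, not just in expectation.

`generate_assay_tables` defaults to triplicate technical replicates and
EAE groups of 7/7/8 mice scored daily to day 25 with onset near day 8 and
peak near day 15 — typical of adoptive-transfer EAE — and effect sizes of
~2-fold reporter repression by intact sites, ~3–5-fold chemokine-driven
migration in let-7-low cells vs ~1.2–1.5-fold in let-7-high cells, and
reduced chemokine-receptor expression with let-7 dosage. Noise models:
lognormal on both luciferase channels (σ = 0.1 each, so the RLU ratio is
lognormal), Poisson transwell counts, Gaussian Ct (σ = 0.15), Gaussian
jitter (σ = 0.5) on clinical scores before rounding/clipping to 0–5.
`noise=False` returns the true means exactly. These magnitudes are chosen
as realistic for the respective instruments; they are defaults of the
generator, not estimates of any particular dataset.

What the simulations do **not** emulate: codon structure or selection in
the CDS, context-dependent miRNA efficacy (site accessibility,
thermodynamics), correlated evolution around binding sites, plate/batch
effects in assays, and mouse attrition in clinical curves. Passing the
recovery tests therefore demonstrates correctness of the algorithms under
the stated generative model, not predictive accuracy on biological
transcripts.

## Problem sizes and numerics

The verification suite uses 1,000 random transcripts of length 50–2,000
for scanner/oracle equivalence, 500 planted transcripts for recovery, 500
alignment pairs (≤ 12 nt against exhaustive/DP oracles, ≤ 200 nt against
the DP oracle), a 5-point substitution-rate grid over 60 ortholog pairs of
length 400 (two planted sites each), 500 reporter contexts, and 1,000 null
replicates for t-test calibration — sizes at which every check is exact or
binomially bounded while the whole suite runs in seconds. Score
comparisons between alignment routes are exact float equality (identical
arithmetic on integer-valued scores); the type-I-error check uses a
±3.5·binomial-SE band around 0.05.

## Known limitations

- Single-isoform transcripts only; no GenBank/Ensembl retrieval, no splice
  handling — transcript choice is the user's input.
- Pairwise (two-species) conservation only; no multiple alignment or
  phylogenetic conservation scores.
- No thermodynamic or context scoring of sites; every ≥ 6 bp perfect match
  is reported, which at transcript scale includes chance matches
  (≈ 5·(1/4)^6 per position for the default seed).
- The two-group test is exactly the printed convention (equal-variance t);
  curve-level inference such as two-way ANOVA is out of scope — tidy tables
  export cleanly to any stats package.
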