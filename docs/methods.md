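# Methods

## The discovery model

`pepthla` treats a therapeutic target as a (9-mer peptide, HLA allele,
cancer type) triple and scores its safety by counting predicted
off-targets. The underlying assumptions are:

- HLA class I presentation is dominated by 9-mers, so only 9-residue
  windows over the 20 standard amino acids are considered. Windows
  containing any other letter (ambiguity codes, U, O, X, ...) are dropped.
- Binding is an external prediction consumed as an IC50 table. A peptide
  is a putative complex when IC50 < 500 nM and a strong binder when
  IC50 < 50 nM; both comparisons are strict, so a value exactly at a cutoff
  falls in the weaker class.
- Gene expression is a proxy for peptide presentation. A gene's
  75th-percentile RPKM > 5.0 in a cancer type means at least one transcript
  copy in ≥ 25 % of that type's samples; < 0.5 in every essential normal
  tissue means essentially zero copies there. Together these define cancer
  specificity. For the off-target side the criterion is deliberately more
  sensitive: 95th-percentile RPKM > 0.5 in *any* essential tissue flags the
  gene as dangerous.
- Cross-reactivity risk is monotone in sequence similarity. The degree of
  similarity (DoS) of two 9-mers counts identical residues at identical
  positions (DoS = 9 − Hamming distance). DoS ≥ 5 — at most four
  mismatches, the worst documented clinically cross-reactive pair — defines
  "similar".
- TCR/antibody recognition engages only some peptide positions. Contact
  patterns derived from solved peptide–HLA–TCR structures vote on which
  positions are important; a similar peptide sharing fewer than 3 identical
  important positions is discarded as an off-target candidate (a TCR
  footprint engages at least ~3 peptide positions).

## Parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `strong_ic50_nM` | 50 | nM | strong-binder cutoff (strict <) |
| `binder_ic50_nM` | 500 | nM | putative-complex cutoff for targets (strict <) |
| `offtarget_ic50_max` | 500 | nM | binder gate for off-target candidates |
| `tumor_p75_min` | 5.0 | RPKM | tumor 75th-percentile threshold (strict >) |
| `normal_p75_max` | 0.5 | RPKM | essential-normal 75th-percentile cap (strict <) |
| `offtarget_p95_min` | 0.5 | RPKM | essential-normal 95th-percentile trigger (strict >) |
| `min_dos` | 5 | positions | similarity threshold, range 5–9 |
| `min_important_overlap` | 3 | positions | importance-masking retention rule |
| `vote_threshold` | 2 | patterns | votes needed to call a position important |
| `vdw_gap_min/max` | 0.0 / 0.4 | Å | hydrophobic-contact gap window (inclusive) |
| `hbond_da_max` | 4.0 | Å | donor–acceptor distance (strict <) |
| `hbond_angle_dev_max` | 30 | ° | D–H–A deviation from linearity (inclusive) |
| `clash_overlap` | 0.6 | Å | vdW overlap beyond which atoms clash (strict >) |

Non-essential tissues default to the reproductive organs (breast, cervix,
fallopian tube, testis, uterus, vagina); every other normal tissue is
essential. The normal-tissue maximum is taken jointly over all essential
normal groups regardless of source repository; requiring each source
independently would only relax the filter and is left to configuration.

The binder gate on off-target candidates (`offtarget_ic50_max`) is kept
separate from the target gate because an off-target only matters if its
complex can form; it defaults to the same 500 nM and is configurable.

## Geometry conventions

- Van der Waals radii are a Bondi-style element table shipped in code and
  overridable; contact calls are sensitive to the radius set, so it is part
  of `GeometryConfig`.
- The hydrophobic-contact criterion is the signed gap d − r₁ − r₂ of a
  peptide *side-chain* atom against *any* partner-chain atom, inside
  [0.0, 0.4] Å inclusive. Peptide backbone atoms (N, CA, C, O, OXT and
  their hydrogens) never count; HLA-chain atoms never count as partners.
- The hydrogen-bond "angle < 30°" convention is implemented as deviation
  from D–H–A linearity ≤ 30° (i.e. the angle at the hydrogen is ≥ 150°);
  a literal donor–hydrogen–acceptor angle below 30° is geometrically
  impossible for a hydrogen bond. Because crystal structures usually lack
  hydrogens, the angle term applies only when the structure contains
  explicit hydrogens; otherwise the donor–acceptor distance alone decides.
  No hydrogen positions are ever invented.
- Cutoff comparisons snap to 1e-9 (`GEOM_EPS`) so that a coordinate placed
  exactly at a boundary behaves per the boundary rule independent of binary
  representation.

## Neighbor search

Scanning a proteome-scale index (11 M peptides in a full run) per query is
wasteful, so `find_similar` uses a pigeonhole block index: the 9 positions
are split into five contiguous blocks (2+2+2+2+1). Any peptide within four
mismatches of the query (DoS ≥ 5) must match it exactly in at least one
block, so the union of exact-block buckets contains every true hit; full
DoS verification removes false positives. The result is provably identical
to the linear scan, which is retained both as a fallback for tiny indexes
and as the test oracle. A target's own dos = 9 entry is excluded unless
the identical peptide also occurs in a different gene, in which case it is
a legitimate off-target (same-gene expression is already covered by the
specificity filter). Results order by descending DoS, then lexicographic
sequence, so reports are byte-deterministic.

## Importance predictor and its validation

Each solved complex yields a 9-bit contact pattern (hydrophobic contact OR
hydrogen bond per position). Patterns are deduplicated by vector (with
provenance) and vote: a position is important when at least
`vote_threshold` unique patterns mark it. The default threshold of 2
favors precision — positions called non-important should really be
non-important, since masking *removes* off-target candidates and a false
removal is the costly error.

Validation is structure-level leave-one-out: the held-out structure's
pattern is removed, unique patterns are recomputed from the remainder, and
their votes predict each held-out position at every threshold. The
positive class is *non-important*. Counts are pooled over all held-out
positions; the ROC sweeps the threshold and AUC is trapezoidal with (0,0)
and (1,1) appended, which for vote-count scores equals the Mann–Whitney
rank statistic (asserted to 1e-9 in tests). The modeling-based variant of
the predictor consumes a directory of pre-modeled, clash-filtered
structures per query peptide (side-chain mutation and energy minimization
are external, tool-specific steps and are out of scope); the voting and
validation machinery is shared.

## Numerical choices

- Percentiles use linear interpolation between order statistics at rank
  (n−1)·q/100 — the default of mainstream numerics libraries. The choice
  is pinned and configurable in intent because genes near the 0.5/5.0 RPKM
  boundaries can flip between percentile conventions.
- Duplicate gene rows in an expression matrix aggregate by max, and
  peptides mapping to several genes take the max across genes in every
  expression rule — both err toward detecting expression, i.e. toward
  calling more off-targets, never fewer.
- Duplicate peptides in an affinity table resolve to the minimum IC50
  (strongest binding), again the cautious direction.
- Ranking ties break lexicographically on the peptide, making the
  prioritization a deterministic permutation of its input.

## The synthetic studies

The `synthetic` module emulates the four real inputs at desk scale:

- **Proteome**: ~25 random-background proteins of 40–80 residues; each
  planted target and off-target peptide sits verbatim in its own dedicated
  gene. Off-targets are realized by mutating 9 − DoS positions of their
  target. Background proteins and flanking sequence are re-drawn until no
  accidental window reaches DoS 5 with any planted target, so the planted
  similarity structure is the only one present.
- **Affinity**: planted peptides receive their prescribed IC50 (< 500 nM);
  every other 9-mer gets a deterministic hash-derived value in
  [600, 40 600) nM.
- **Expression**: three cancer types plus the targets' types, six
  essential tissues, one non-essential tissue (testis), eight samples per
  group. Target genes draw 8–30 RPKM in their cancer type and < 0.1
  elsewhere; off-target genes draw 1–10 RPKM in their designated essential
  tissue; background genes draw log-normal noise (median ≈ 0.37 RPKM).
  Every guarantee is re-verified by running the actual classification
  rules and violating genes are re-drawn, so planted truth is exact by
  construction, not in expectation.
- **Structures**: a 9-residue alanine-like peptide chain with CB
  pseudo-side-chains spaced 10 Å apart, an inert HLA chain, and partner
  carbon probes placed at a 0.2 Å vdW gap from the CB of exactly the
  important positions (> 8 Å from all others), written as minimal PDB and
  read back through gemmi.

What passing these tests shows: the gates, search and ranking are
implemented exactly as specified, with zero false positives/negatives on
inputs whose truth is known. What it does not show: performance on real
data, where binding predictions are noisy, expression is batch-confounded
and far from the planted margins, similar peptides share genes and
haplotypes, and contact patterns come from imperfect crystal structures.
The synthetic expression generator makes no attempt at biological
covariance structure; it only realizes the threshold geometry of the
rules.

Problem sizes in the automated runs — twenty (tests: one hundred) random
10,000-peptide indexes for search-exactness, five targets / twelve
off-targets end-to-end, all 512 contact patterns, 30–200 synthetic
complexes for the ROC machinery — were chosen as the smallest sets that
exercise every code path and pin the statistics (an uninformed predictor's
pooled AUC over 1,800 positions is 0.5 within a few hundredths).

## Known limitations

- 9-mers and a single allele per run; no proteasomal-cleavage or TAP
  modeling, no isoform or variant peptidomes — binding and presentation
  fidelity is bounded by the external affinity table supplied.
- The simple importance predictor is sequence-agnostic; the
  modeling-based refinement depends on externally modeled structures.
- Expression thresholds are population-level (percentiles across cohort
  samples) and say nothing about any individual patient.
- Auto-detection of chain roles in structures (unique 9-residue chain =
  peptide, longest other chain = HLA) is a convenience for well-formed
  complexes; curated chain manifests are the reliable path.
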