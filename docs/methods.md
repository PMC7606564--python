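# Methods

This note records the models, estimators, numerical conventions and design
choices behind `nadscape`, and what the synthetic-data experiments do and
do not establish.

## Coordinates and windows

All intervals are 0-based half-open internally; GFF3 keeps its native
1-based inclusive convention and BED-like read tables their 0-based one,
converted exactly once at I/O. Every offset ("upstream", transcript-leader
length, window bounds) is computed in transcript orientation, so one code
path serves both strands.

Three windows recur:

* **Counting window**: a read is assigned to a gene when its 5′ end lies
  in [TLS − 120, TLS + 65] (TLS = first CDS base, position 0), boundaries
  inclusive, matching strand. Overlapping windows each receive the read;
  rRNA/tRNA spans are tallied separately and excluded from the mRNA
  matrix.
* **TSS scan window**: read starts are collected over the 5′-UTR plus a
  50-nt upstream extension and expressed as TL length (0 at the TLS,
  growing upstream).
* **Promoter window**: 21 bases, tss−10..tss+10 in transcript orientation.
  The TSS base is labeled +1 and there is no position 0 (labels −10..−1,
  +1..+11), so the YAAG positions are −1 (pyrimidine), +1/+2 (A), +3 (G).

## Enrichment model

S-vs-N enrichment is a negative-binomial Wald test. Counts are normalized
by median-of-ratios size factors; per feature, the dispersion α is
estimated by method of moments, pooled over the two groups and floored at
0.01 (a ~10% biological CV — the level we also plant between simulated
replicates, so the floor acts as a matched prior rather than a fudge).
The statistic is log((m_S + 0.5)/(m_N + 0.5)) over its delta-method
standard error, with (1/μ + α)/n per group; two-sided normal reference.
Verdicts use strict inequalities: enriched ⇔ FC > 1.414 ∧ NBM > 1 ∧
p < 0.05, depleted ⇔ FC < 0.707 ∧ NBM > 1 ∧ p < 0.05.

**Two-pass normalization.** When a sizeable minority of features is truly
captured, a single median-of-ratios pass sits on the edge of the null
cluster and shrinks every fold change by 5–10% — enough to matter against
the 1.414 cut. The test therefore re-estimates size factors on the
features *not* flagged as enriched in a first pass and recomputes.
Because capture enrichment is one-sided, only up-flagged features are
excluded from the control set; apparent depletion among unflagged features
is usually the artifact being corrected. Limitation: if the truly captured
fraction approaches half of all features, no global normalization is
identifiable (the pipeline then under-calls and may report spurious
depletion); spike-in-based factors (`size_factors(..., control_features=)`)
are the remedy when such data are expected.

A cross-check against pyDESeq2 on simulated counts (r > 0.99 on log2FC,
>90% agreement of p < 0.05 calls) is part of the test suite; the
implementation itself never calls it.

## Trend test for alternative TSS usage

Per gene, read starts of both groups are pooled on the TL axis and 18-nt
windows are extracted greedily, densest first, until no window holds
`min_reads` (2); each cluster's representative is its modal position, and
the 2×n table of S/N counts per cluster (columns sorted by TL length) is
tested for linear-by-linear association: per-read scores X = 2 (S) or
1 (N), Y = cluster TL length, r = cov(X,Y)/(σ_X σ_Y) with population
moments, M² = (n_obs − 1) r² referred to χ² with 1 df. Genes with fewer
than 30 reads, a single cluster, or an empty row are flagged untestable
(no exception). Before expansion the N row is rescaled to the S row's
total (rounded), so library depth cannot masquerade as trend. The grouped
computation is oracle-tested against literal per-observation expansion
(|Δ| < 1e−10).

Calibration caveat: the χ²(1) reference is accurate when TSS modes are
separated beyond the 18-nt merging window (measured KS ≈ 0.03, type-I
0.04–0.05 on 2,000 null genes). Modes closer than the window are merged
adaptively, which perturbs the null slightly (KS ≈ 0.06); the calibration
benchmark therefore plants resolved clusters, which is also the structure
the windowing assumes.

## Sharp-A calls, promoter matrices, shifts, TLI

* **Sharp A**: TSS = modal read-start; ties resolved toward the position
  whose downstream neighbor (+2) holds more starts, then the shorter TL.
  Sharp value = count(+1)/max(count(−1), 1); a call requires base A and
  sharp > 4 (`sharp_min`, configurable — a three-fold variant of the rule
  exists in the literature).
* **Promoter matrix**: PFM over the 21-base window with pseudo-count 0.25
  per base; information content = 2 − Shannon entropy (bits). With 25
  perfectly conserved sites the pseudo-counts cap IC at ≈1.77 bits.
  Consensus reports a single base at ≥60% frequency, an IUPAC two-base
  code (e.g. Y) when the top two bases jointly reach 75%.
* **TSS shift vs reference**: Δ = modal S TL − reference TL. Against a
  distribution (N starts as all-cap proxy) significance is a two-sided
  unpaired rank-sum; against a user-supplied canonical TSS it is a
  two-sided sign test. Distal ⇔ Δ > 10 ∧ FDR < 0.1.
* **TLI**: (μ_B − μ_A)/W, μ = mean TL of each strain's S-group starts,
  W = UTR + 50 scan-window length. The formula is this package's
  definition satisfying the sign semantics (positive = distal shift upon
  mutation); it is antisymmetric and halves exactly when W doubles. FDR
  comes from the trend test applied to the B-vs-A cluster table. Direction
  calls use |TLI| > 0.1 with FDR < 0.1 (hierarchy) or 0.05 (pairwise
  plots), both configurable.

## Geometry and truncation

Reads are binned by (5′ − canonical TSS, 3′ − canonical TSS). "Full
length" is defined *among reads sharing the dominant TSS* (within ±tol,
default 3 nt): of those, the fraction also ending within ±tol of the
annotated TES. Conditioning on the dominant TSS keeps multi-TSS genes from
confounding 3′-truncation with 5′ heterogeneity. The truncation contrast
is R = (FL_S/FL_N over enriched genes)/(FL_S/FL_N over non-enriched
genes), pooled counts; R < 1 indicates NAD-linked truncation. The
normalization formula is this package's choice (ratio-of-ratios).

## Decapping hierarchy

Strains are keyed by their set of active enzymes (triple knockout = none).
For each ordered pair (E1, E2): species shifted upon reintroducing E1
(|TLI| > 0.1, FDR < 0.1 vs the triple knockout) that are enriched in that
strain and then either lose the enriched verdict or drop ≥2-fold in FC
upon adding E2 count as resolved. Paths are scored by n_resolved (count
logic, no fitted model); the ≥2-fold rule quantifies "significantly
reduced", which has no printed numeric definition. Both shift directions
are counted and reported split.

## The generator

`SimConfig` defaults are the simulated study conditions: 300 genes on one
chromosome (both strands), transcript lengths 200–400 nt, UTRs 30–90 nt,
three biological replicates per group, per-gene NAD fractions uniform in
1–5% for the 20% of genes that are capped at all (`null_fraction` 0.8 —
matching the minority of enriched species in real capture libraries),
capture efficiency c = 0.5 and background b = 0.02 (placeholders, not
biology — no quantitative values are published), 6000 transcript draws
per gene per library scaled by lognormal expression (σ = 0.4) and a 10%
replicate-level CV, 5′ jitter (70/10/5% at 0/±1/±2 nt), geometric
3′-truncation with stop probability 0.001 per nt (×3 for NAD
transcripts), 12–17-nt small-RNA fragments and a fixed 60-nt spike-in.

Each capped gene carries **two NAD TSS variants** — distal (20–45 nt
upstream of the canonical TSS, capped at 118 − UTR so it stays inside
both the counting and scan windows) and proximal (10–25 nt downstream) —
mixed per transcript (`distal_mix`) or assigned per gene. Two variants
are what make decapping-hierarchy signatures plantable: an enzyme that
removes one TL class shifts the start distribution while the species
remains enriched through the other class. Decapping is a per-enzyme,
per-TL-class survival probability; the defaults encode a TL-selective,
nuclear first actor (rai1: distal 0.1, proximal 1.0) and two
non-selective downstream enzymes (dxo1 0.6, npy1 0.3), consistent with
the localization-based ordering the analysis is designed to detect.

The first transcribed base of every variant is forced non-G so that 5′
G-run trimming cannot eat into real inserts; consequently the chance rate
of a spurious YAAG at an unplanted TSS is (2/4)(1/3)(1/4)(1/4).
`add_adapters` redraws its random hexamer when it would create an adapter
match upstream of the true one, making trimming an exact inverse for
unambiguous inserts (not starting with G/N, not containing the motif).

What the generator does **not** model: sequencing errors and quality
scores, PCR duplication and amplification bias, fragmented-library
shearing, secondary structure, and genuine promoter grammar beyond the
planted core. Passing recovery tests therefore show the *statistics*
behave as designed under their assumed sampling model, not that the
pipeline is robust to artifacts real libraries may carry.

## Validation experiment designs (`nadscape/benchmarks.py`)

Each benchmark fixes its own design; sizes were chosen to finish in
seconds to minutes while leaving clear statistical margins.

* *Trend oracle*: 200 random 2×n tables vs per-observation expansion.
* *Trend null calibration*: 2,000 null genes, 2–4 TSS modes ≥25 nt apart,
  100 reads per group.
* *TSS shift*: ±30-nt planted shifts, per-gene NAD fractions 0.25–0.35 so
  the S library's modal start is the NAD TSS (~100 captured S reads/gene),
  sign test vs the canonical TL.
* *Motif*: top-25 enriched sharp-A genes at NAD fractions 0.2–0.3 —
  mirroring the fact that motif work targets the most-enriched species,
  whose S reads are NAD-dominated; with the default 1–5% fractions and
  b/c as above, background reads at the canonical TSS would dominate the
  modal start and no 5′-end method could see the NAD promoter.
* *Enrichment recovery*: 8 pooled default-condition simulations; power is
  the fraction of genes with effective NAD fraction ρ′ ≥ 0.02 called
  enriched (true FC at the 0.02 boundary is 1.5 against the 1.414 cut, so
  single-simulation estimates carry ±3% noise; pooling is an estimator
  choice). False positives are enriched calls among ρ = 0 genes.
* *Ratio recovery*: Spearman of k·TPM_S/TPM_transcriptome against planted
  ρ′ over 300 genes, half capped, half null.
* *Truncation*: 50 seeds each at truncation factor 3 (expect R < 1) and 1
  (expect R in [0.9, 1.1]); 60 genes, 70% null.
* *Hierarchy*: 20 lattice simulations at the default survival pattern;
  recovery = fraction ranking an rai1-first path top by n_resolved.
* *Trimming*: 10,000 unambiguous inserts round-tripped exactly, plus the
  12/17/18-nt class boundaries.
* *Determinism*: the full pipeline run twice with one seed must produce
  byte-identical outputs; the global seed fans out to per-stage seeds by
  CRC-32 of the stage name.

## Known limitations

* Global normalization is unidentifiable when ≥~50% of features are truly
  captured; use spike-in control features there.
* The mapper is exact/ungapped with a small mismatch budget and intended
  for toy genomes (oracle-tested to 10 kb); real data should arrive as
  pre-aligned BED-like tables.
* The NB Wald test is a documented substitute for a full GLM framework:
  no shrinkage of fold changes or dispersions, normal (not t) reference.
* Small-RNA cluster identity is ungapped best-offset (±3 nt) matching over
  the shorter read — the simplest reproducible choice; clusters with zero
  N-group copies report infinite enrichment under an `n_zero` flag rather
  than a pseudo-counted value.
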