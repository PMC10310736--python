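# Methods

## Scope of the automated scheme

The ACMG/ClinGen point-based standard for CNV interpretation has five
evidence sections. Sections 4 (beyond option 4O) and 5 require case
counts, inheritance and patient phenotype — information a
coordinates-only tool does not have — so `cnvscore` scores Sections 1
and 3 completely, Section 2 for every option derivable from position and
annotation, and option 4O. The loss options 2J/2K (and gain options
2I–2K) hinge on whether the patient's phenotype matches the expectation
for an established haploinsufficient gene; they are never scored and are
returned in `unevaluated_options` so every report states its own
coverage honestly.

## Coordinates

Internally all intervals are 0-based half-open; every file and
command-line surface is 1-based inclusive, converted exactly once at the
I/O boundary. Chromosome names are normalized to the `chr`-prefixed
form. CNVs are unstranded; dosage targets are matched by position only.
Any positive intersection counts as overlap — no reciprocal-overlap or
single-base special-casing.

## Section-2 conventions

The standard leaves several operational details to the analyst. The
fixed, tested conventions here are:

* **Complete vs partial.** A dosage target is completely overlapped when
  it lies entirely within the CNV (2A); otherwise the overlap is partial
  (2B for regions; breakpoint geometry for genes).
* **Transcript resolution (losses).** A partially overlapped
  haploinsufficient gene is resolved over *all* of its transcripts:
  per transcript, a covered 5′ end gives 2C, a covered 3′ end 2D, both
  breakpoints inside the transcript 2E (a fully contained transcript
  ranks with 2C). The most severe outcome — largest absolute points,
  ties toward the pathogenic direction, then lexicographic for
  determinism — is kept. The 5′ end is identified per transcript by a
  `cds_start_side` flag rather than a strand, since nothing else here
  needs strand.
* **One evidence line per option.** Several records firing the same
  option are aggregated into one evidence entry (all supporting records
  listed); a single record never yields both 2A and 2B.
* **Benign comparisons.** Benign-overlap evidence is evaluated
  independently of dosage evidence. For losses, containment in a benign
  record (2F) suppresses the weaker extends-beyond comparison (2G);
  "additional genomic material" in 2G means at least one protein-coding
  gene overlapped by the CNV but not by the benign record — gene-level
  granularity, matching how Section 3 counts. For gains, each benign
  gain record is classified as 2C (identical protein-coding gene
  content; checked first, so a smaller CNV covering exactly the record's
  genes counts as identical content), 2D/2E (smaller and fully
  contained, breakpoints outside/inside genes), 2F (containing the
  record with no additional protein-coding genes) or 2G (additional
  genes); the single most severe candidate is kept.
* **Predictor consensus (loss 2H).** A gene fully contained in the loss
  with at least two (configurable) positive computational
  haploinsufficiency calls scores 2H, but only when no established
  HI evidence fired — the predictors are supporting, not primary,
  evidence.
* **4O containment.** "Overlap with common population variation" is
  operationalized as the CNV being completely contained in a population
  record of matching type with allele frequency ≥ 1 % (configurable),
  mirroring 2F's containment semantics.

## Scoring table and thresholds

Per-option points, the Section-3 gene-count bands (loss: 0–24 / 25–34 /
≥ 35; gain: 0–34 / 35–49 / ≥ 50, lower bounds inclusive) and the class
thresholds ship in an editable YAML file; nothing is hard-coded, so a
locally corrected sheet changes scores without touching logic. The loss
options 2C–2E collapse the standard's graded sub-options into one
representative value each (0.90 / 0.30 / 0.45).

The printed 5-tier boundaries leave the micro-gaps (−0.99, −0.98) and
(0.98, 0.99) unassigned; they close toward LB and LP respectively, and
the outer boundaries are inclusive: P iff score ≥ 0.99, B iff ≤ −0.99,
consistent with a 0.9931 joint score classifying Pathogenic. A 1e-9
tolerance absorbs float summation noise at the boundaries.

## The probability blend

`f_joint = ACMG_score + r·(p − 0.5)` with `p ∈ [0, 1]` and ratio
`r ≥ 0`. The probability is always an input — a results column or a
callable — never computed here; a toy logistic-of-gene-count provider is
bundled solely so end-to-end runs need no model file. Default `r = 1`;
presets expose 0.19 and 1.99, the two-decimal ratios at which confident
probabilities start flipping LP-range scores (0.90 + r·0.49 ≥ 0.99 at
r = 0.19) and VUS-range scores respectively. Note the VUS-side
breakpoint is not exact under the formula: flipping a score of 0 needs
r·(p − 0.5) ≥ 0.99, i.e. r ≈ 2.02 at p = 0.99 or r = 1.98 at p = 1; the
band and sweep operations compute the exact thresholds rather than
forcing a nominal value.

The *undecidable band* at ratio r is found by scanning ACMG scores on a
0.01 grid (the granularity of every printed score) over ±1.50: a score
is decidable when some probability reaches the P or B range, and since
`f_joint` is monotone in `p` only the endpoints p = 0, 1 need checking.
At r = 1 the band is [−0.48, 0.48]; it shrinks monotonically with r and
is empty by r = 2.

## Evaluation conventions

Pathogenic is the positive class. LB, VUS and LP all count as
*uncertain*: accuracy is (TP+TN)/(TP+TN+FP+FN) over decided calls only
(reported as undefined, never 0, when nothing is decided), and
*unambiguous* is decided/total. The full 5-tier vector is preserved so
finer views remain derivable. Paired classifiers are compared with the
McNemar–Bowker symmetry test on the 3-class (B/Uncertain/P) collapse:
B = Σ_{i<j} (n_ij − n_ji)²/(n_ij + n_ji), zero-sum off-diagonal pairs
skipped with a corresponding reduction in degrees of freedom (the
standard Bowker convention); the implementation is cross-checked against
statsmodels in the tests.

The benign-database sweep crosses the four source settings (GnomAD, DGV,
and the curated gold-standard set in inner and outer coordinate flavors)
with no-filter plus the six frequency thresholds 0.01 %, 0.1 %, 0.5 %,
1 %, 2 % and 10 % — 28 settings — rebuilding only the benign registry
per setting. Thresholding is monotone: raising the frequency floor can
only shrink the registry, hence never decides more CNVs.

## Synthetic fixtures

The generator emulates the *structure* of the real annotation sources at
toy scale: two chromosomes of 10 Mb partitioned into zones (gene desert,
HI genes + one HI region, TS genes, predictor-called genes with
regulatory elements, curated benign records over bystander genes,
population variants, and a dense gene run for the gene-number bands).
Dosage scores cycle through the ClinGen scale {3,3,3,2,1,0,30,40};
benign frequencies cycle through values straddling every sweep
threshold; gold-standard records are emitted in inner and outer flavors
(outer ⊇ inner). Chromosomes are kept small so the per-base and
linear-scan test oracles stay fast.

CNV sets mirror a ClinVar-style curation: *basic* (1 kb–5 Mb,
copy numbers 1/3, 60 CNVs by default), *large* (> 5 Mb, spanning the
dosage zones) and *multiple* (copy numbers 0/4). Each CNV is *planted*
to hit specific evidence (2A, 2F, 4O, 2H, the Section-3 bands, or
nothing) and carries its truth label and planted options; the round-trip
guarantee is planted ⊆ emitted, since a large CNV legitimately collects
additional co-occurring evidence. One integer seed drives fixed
per-stream sub-seeds (`default_rng([stream, seed])`), so outputs are
byte-identical per seed and adding a stream never perturbs existing
files.

What the fixtures do **not** emulate: real size and frequency
distributions, label noise, hg38 coordinates, or the tabular dialects of
the real exports at full fidelity. Passing tests therefore demonstrate
the correctness of the scoring logic and the evaluation machinery, not
field performance on real ClinVar/DGV/ClinGen data.

## Numerical and degenerate-input choices

Registry queries return position-sorted, order-independent results.
Undefined accuracy (no decided CNVs) is `None`, never 0. A Bowker test
with no contributing pair reports df = 0 and an inapplicable p-value. An
empty annotation file loads as an empty registry with a warning; a
missing mandatory column is a hard error naming the file, and malformed
rows are reported with their line numbers. A missing registry fails
`score_cnv` with the name of the section it blocks. Grid searches over
ratios and scores use integer step counts with rounding to avoid float
drift.

## Problem sizes

Default test problem sizes — 200 random CNVs for engine-vs-oracle
equality, ~230 genes and ~30 benign records per bundle, 28-setting
sweeps over 60 labeled CNVs — were chosen so the brute-force oracles
(per-base set intersection, exhaustive linear scans) remain exact
companions to every optimized path while the whole suite runs in well
under a minute.

## Known limitations

* Section 2 sums one evidence line per fired option; the standard's
  guidance on combining multiple lines within a section is not explicit,
  and a different cap would change totals for CNVs with several strong
  lines.
* The gain 2C "identical gene content" check ignores span geometry, so a
  smaller CNV with identical content scores the identity option rather
  than the smaller-than-benign option (same points in the shipped
  table).
* Dosage evidence for gains uses TS scores only for 2A/2B and HI scores
  only for 2H/2L-adjacent logic; mixed-evidence genes are not
  special-cased.
* The bundled probability provider is plumbing, not a model.
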