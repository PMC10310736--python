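# cnvscore

Automated, point-based clinical scoring of copy-number variants (CNVs),
with an optional blend of a machine-learning pathogenicity probability.

## The problem

Clinical interpretation of CNVs follows the ACMG/ClinGen technical
standard: a CNV is walked through five evidence sections — (1) genomic
content, (2) overlap with established dosage-sensitive or benign
genes/regions, (3) gene number, (4) published/population evidence,
(5) inheritance and family history — each selected option contributes
signed points, and the summed score maps to a 5-tier class:

| class | score |
|---|---|
| Pathogenic (P) | ≥ 0.99 |
| Likely pathogenic (LP) | 0.90 … 0.99 |
| Uncertain significance (VUS) | −0.90 … 0.90 |
| Likely benign (LB) | −0.99 … −0.90 |
| Benign (B) | ≤ −0.99 |

Sections 1–3 and the common-population-variation option 4O depend only on
the CNV's coordinates and public annotation, so they can be automated.
`cnvscore` implements exactly that automatable core: given a CNV
(`chrom:start-end`, loss or gain) and flat-table annotation registries
(gene models, ClinGen-style HI/TS dosage records, DGV-style benign CNVs
with inner/outer coordinate flavors, GnomAD-style population variants,
dbNSFP-style haploinsufficiency predictor calls), it selects the evidence
options, sums the points from an editable scoring table, and classifies.

Rule-based scoring is conservative — most CNVs land in VUS. An external
machine-learning classifier that outputs a pathogenicity probability
`p ∈ [0, 1]` can be blended in:

```
f_joint = ACMG_score + r · (p − 0.50)
```

The centred probability moves the score by at most `r/2` in either
direction, preserving the ACMG ranges; `r = 0` recovers the pure
rule-based classifier. The package also ships the evaluation machinery
for such classifiers — accuracy over decided calls, the *unambiguous*
(decided) fraction, McNemar–Bowker paired comparisons — plus a sweep
harness over benign-database filter settings and a deterministic
synthetic fixture generator, so every pipeline runs end to end with no
downloads.

## Worked example

```python
from cnvscore import combine, undecidable_band

res = combine(acmg_score=0.90, ml_probability=0.99, ratio=0.19)
print(round(res.joint_score, 4), res.classification)
# 0.9931 P

print(undecidable_band(1.0, grid_step=0.01))
# (-0.48, 0.48)
```

A CNV scored 0.90 by the rules alone is Likely pathogenic — an
*uncertain* call. Blending a confident probability of 0.99 at ratio
0.19 lifts it to 0.9931, across the 0.99 Pathogenic threshold. The
second line shows the flip side: at ratio 1, no probability whatsoever
can decide a CNV whose rule score lies in [−0.48, 0.48].

End to end, from a synthetic bundle:

```
cnvscore fixtures --seed 3 --out fx
cnvscore classify --bundle fx --cnv "chr1:150000-2150000 loss" --out res.tsv
cat res.tsv
# id     chrom  start   end      cnv_type  total_score  classification
# cnv-0  chr1   150000  2150000  loss      -0.6         VUS
cnvscore sweep --bundle fx --cnvs fx/cnv_basic.tsv --out grid.tsv   # 28 settings
```

All coordinates on the command line and in files are 1-based inclusive.
Per-option points live in an editable YAML table
(`src/cnvscore/data/scoring_default.yaml`); the engine hard-codes no
point value. `--preset acmg-default` is the standard as written;
`--preset gold-outer-0.5` restricts benign evidence to curated
gold-standard records (outer coordinates) at ≥ 0.5 % population
frequency, the best-performing setting.

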