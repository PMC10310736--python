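# Default scoring table for the ACMG/ClinGen point-based CNV scheme.
#
# Points are per evidence option, signed; the summed score is mapped to the
# 5-tier classification with the thresholds below.  Sections 2C-2E (loss)
# collapse the standard's graded sub-options into a single representative
# point value per geometry; edit this file to tune any value — the engine
# never hard-codes points.
#
# Dosage scores use the ClinGen scale: 0-3 (3 = established), 30 = autosomal
# recessive, 40 = dosage-insensitive.

thresholds:
  pathogenic: 0.99        # score >= 0.99 -> P
  likely_pathogenic: 0.90 # 0.90 <= score < 0.99 -> LP
  likely_benign: -0.90    # -0.99 < score <= -0.90 -> LB
  benign: -0.99           # score <= -0.99 -> B

loss:
  options:
    "1A": 0.0     # contains protein-coding or other known functionally important elements
    "1B": -0.60   # no protein-coding genes or known functional elements
    "2A": 1.0     # complete overlap of an established HI gene/region
    "2B": 0.0     # partial overlap of an established HI region
    "2C": 0.90    # partial overlap with the 5' end of an established HI gene
    "2D": 0.30    # partial overlap with the 3' end of an established HI gene
    "2E": 0.45    # both breakpoints within the same established HI gene
    "2F": -1.0    # completely contained within an established benign CNV region
    "2G": 0.0     # overlaps benign CNV region but includes additional genomic material
    "2H": 0.15    # two or more computational HI predictors call a contained gene haploinsufficient
    "3A": 0.0
    "3B": 0.45
    "3C": 0.90
    "4O": -1.0    # overlap with common population variation
  gene_count_bands:   # protein-coding gene count -> section-3 option
    "3A": [0, 24]
    "3B": [25, 34]
    "3C": [35, null]
  unevaluated: ["2J", "2K"]   # need patient phenotype; never automated here

gain:
  options:
    "1A": 0.0
    "1B": -0.60
    "2A": 1.0     # complete overlap of an established TS gene/region
    "2B": 0.0     # partial overlap of an established TS region
    "2C": -1.0    # identical in gene content to an established benign gain
    "2D": -1.0    # smaller than established benign gain, breakpoints outside protein-coding genes
    "2E": 0.0     # smaller than established benign gain, breakpoints inside gene(s)
    "2F": -1.0    # larger than established benign gain, no additional protein-coding genes
    "2G": 0.0     # overlaps a benign gain but includes additional genomic material
    "2H": 0.0     # HI gene fully contained within the gain
    "2L": 0.0     # one breakpoint inside a gene of unestablished significance
    "3A": 0.0
    "3B": 0.45
    "3C": 0.90
    "4O": -1.0
  gene_count_bands:
    "3A": [0, 34]
    "3B": [35, 49]
    "3C": [50, null]
  unevaluated: ["2I", "2J", "2K"]
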