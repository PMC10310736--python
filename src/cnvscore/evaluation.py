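"""Performance accounting for CNV classifiers.

The positive class is *pathogenic*.  Only outright Benign and Pathogenic
predictions are "decided": Likely benign, VUS and Likely pathogenic all
count as *uncertain* (they indicate a direction without conclusive
evidence), so

* ``accuracy``   = (TP + TN) / (TP + TN + FP + FN) — uncertain excluded
  from both numerator and denominator;
* ``unambiguous`` = decided / total — the fraction of CNVs the classifier
  commits on at all.

Two classifiers run on the same CNVs are compared with the McNemar-Bowker
symmetry test on the paired k×k table of their (collapsed, k = 3:
Benign / Uncertain / Pathogenic) classes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .acmg_engine import EngineOptions, Registries, score_cnv
from .annotation_db import BenignCNVRecord, BenignSource, CoordinateFlavor, build_benign_db
from .intervals import CNVCall
from .scoring import ScoringTable, load_scoring_table

#: Canonical truth labels.
LABELS = ("benign", "pathogenic")

#: Three-class collapse used for paired comparison (k = 3).
THREE_CLASSES = ("B", "U", "P")


@dataclass(frozen=True)
class LabeledCNV:
    cnv: CNVCall
    truth_label: str

    def __post_init__(self) -> None:
        if self.truth_label not in LABELS:
            raise ValueError(f"truth label must be one of {LABELS}, got {self.truth_label!r}")


@dataclass(frozen=True)
class ConfusionSummary:
    """TP/TN/FP/FN/uncertain counts, pathogenic positive."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    uncertain: int = 0

    @property
    def decided(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def total(self) -> int:
        return self.decided + self.uncertain


def collapse_class(five_tier: str) -> str:
    """Collapse the 5-tier class to Benign / Uncertain / Pathogenic."""
    if five_tier == "P":
        return "P"
    if five_tier == "B":
        return "B"
    if five_tier in ("LB", "VUS", "LP"):
        return "U"
    raise ValueError(f"unknown class {five_tier!r}")


def tally(predicted: Sequence[str], labels: Sequence[str]) -> ConfusionSummary:
    """Confusion counts of 5-tier predictions against binary truth labels."""
    if len(predicted) != len(labels):
        raise ValueError(f"length mismatch: {len(predicted)} predictions vs {len(labels)} labels")
    tp = tn = fp = fn = uncertain = 0
    for cls, label in zip(predicted, labels):
        if label not in LABELS:
            raise ValueError(f"truth label must be one of {LABELS}, got {label!r}")
        c3 = collapse_class(cls)
        if c3 == "U":
            uncertain += 1
        elif c3 == "P":
            tp += label == "pathogenic"
            fp += label == "benign"
        else:
            tn += label == "benign"
            fn += label == "pathogenic"
    return ConfusionSummary(tp=tp, tn=tn, fp=fp, fn=fn, uncertain=uncertain)


def accuracy(summary: ConfusionSummary) -> Optional[float]:
    """Fraction of decided CNVs predicted correctly; ``None`` (undefined)
    when nothing was decided."""
    if summary.decided == 0:
        return None
    return (summary.tp + summary.tn) / summary.decided


def unambiguous(summary: ConfusionSummary) -> float:
    """Fraction of CNVs decided outright as B or P."""
    if summary.total == 0:
        raise ValueError("unambiguous undefined on empty input")
    return summary.decided / summary.total


# ---------------------------------------------------------------------------
# paired comparison

@dataclass(frozen=True)
class BowkerResult:
    statistic: float
    df: int
    pvalue: Optional[float]  # None when no off-diagonal pair contributes


def paired_table(
    classes_a: Sequence[str],
    classes_b: Sequence[str],
    categories: Sequence[str] = THREE_CLASSES,
) -> np.ndarray:
    """k×k contingency table of two methods' classes on the same CNVs
    (rows: method A, columns: method B)."""
    if len(classes_a) != len(classes_b):
        raise ValueError("paired classifications must align")
    index = {c: i for i, c in enumerate(categories)}
    table = np.zeros((len(categories), len(categories)), dtype=int)
    for a, b in zip(classes_a, classes_b):
        table[index[a], index[b]] += 1
    return table


def bowker_test(table: np.ndarray) -> BowkerResult:
    """McNemar-Bowker symmetry test on a paired k×k table.

    B = Σ_{i<j} (n_ij − n_ji)² / (n_ij + n_ji), skipping pairs with
    n_ij + n_ji = 0; each skipped pair reduces the degrees of freedom
    (k(k−1)/2 when all contribute).  With k = 2 this is the uncorrected
    McNemar test.  A table symmetric in every pair gives B = 0, p = 1;
    when no pair contributes the test is inapplicable (p is ``None``).
    """
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ValueError(f"table must be square, got shape {table.shape}")
    if (table < 0).any():
        raise ValueError("table cells must be non-negative")
    k = table.shape[0]
    statistic = 0.0
    df = 0
    for i in range(k):
        for j in range(i + 1, k):
            denom = table[i, j] + table[j, i]
            if denom == 0:
                continue
            statistic += (table[i, j] - table[j, i]) ** 2 / denom
            df += 1
    pvalue = None if df == 0 else float(stats.chi2.sf(statistic, df))
    return BowkerResult(statistic=float(statistic), df=df, pvalue=pvalue)


# ---------------------------------------------------------------------------
# database sweep harness

#: The benign-CNV database settings compared in the filtering study:
#: each named source maps to (source tag, coordinate flavor).
SWEEP_SOURCES: dict[str, tuple[BenignSource, CoordinateFlavor]] = {
    "GnomAD": (BenignSource.GNOMAD, CoordinateFlavor.PLAIN),
    "DGV": (BenignSource.DGV, CoordinateFlavor.PLAIN),
    "DGV-GOLD-INNER": (BenignSource.DGV_GOLD, CoordinateFlavor.INNER),
    "DGV-GOLD-OUTER": (BenignSource.DGV_GOLD, CoordinateFlavor.OUTER),
}

#: Minimum-population-frequency filters swept (fractions): no filter plus
#: 0.01%, 0.1%, 0.5%, 1%, 2% and 10%.
SWEEP_THRESHOLDS: tuple[Optional[float], ...] = (None, 0.0001, 0.001, 0.005, 0.01, 0.02, 0.10)


def sweep_benign_db(
    labeled: Sequence[LabeledCNV],
    registries: Registries,
    benign_records: Sequence[BenignCNVRecord],
    sources: Sequence[str] = tuple(SWEEP_SOURCES),
    thresholds: Sequence[Optional[float]] = SWEEP_THRESHOLDS,
    type_filter: str = "both",
    table: Optional[ScoringTable] = None,
    options: EngineOptions = EngineOptions(),
) -> pd.DataFrame:
    """Score the labeled CNVs under every benign-database setting.

    One row per (source × threshold) combination — e.g. 4 sources crossed
    with "no filter" plus 6 frequency thresholds gives the full 28-setting
    grid — carrying the confusion counts, accuracy and unambiguous
    fraction.  The non-benign registries are shared across settings.
    """
    if not sources or not thresholds:
        raise ValueError("sweep grid must contain at least one source and one threshold")
    if table is None:
        table = load_scoring_table()
    unknown = [s for s in sources if s not in SWEEP_SOURCES]
    if unknown:
        raise ValueError(f"unknown sweep source(s) {unknown}; known: {sorted(SWEEP_SOURCES)}")

    labels = [lc.truth_label for lc in labeled]
    rows = []
    for source_name in sources:
        source, flavor = SWEEP_SOURCES[source_name]
        for threshold in thresholds:
            benign = build_benign_db(
                benign_records,
                maf_threshold=threshold,
                type_filter=type_filter,
                flavor=flavor,
                source=source,
            )
            regs = replace(registries, benign=benign)
            classes = [
                score_cnv(lc.cnv, regs, table, options).classification for lc in labeled
            ]
            summary = tally(classes, labels)
            acc = accuracy(summary)
            rows.append(
                {
                    "source": source_name,
                    "maf_threshold": np.nan if threshold is None else threshold,
                    "n_benign_records": len(benign),
                    "tp": summary.tp,
                    "tn": summary.tn,
                    "fp": summary.fp,
                    "fn": summary.fn,
                    "uncertain": summary.uncertain,
                    "accuracy": np.nan if acc is None else acc,
                    "unambiguous": unambiguous(summary) if summary.total else np.nan,
                }
            )
    return pd.DataFrame(rows)
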