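"""Blending the rule-based ACMG score with a machine-learning
pathogenicity probability.

The joint score is

    f_joint = acmg_score + r * (p - 0.5)

where ``p`` in [0, 1] is the probability that the CNV is pathogenic as
returned by an external classifier, and the non-negative ratio ``r``
scales its influence.  Centring the probability at 0.5 means a maximally
confident prediction moves the score by at most ``r/2`` in either
direction, so the blend preserves the ranges set by the ACMG thresholds:
with ``r = 0`` the classifier is ignored entirely, and the joint score is
classified through the same 5-tier thresholds as the raw ACMG score.

The probability is always consumed, never computed: it arrives from a
results table or any callable provider.  A deliberately simple bundled
provider (:func:`gene_count_probability`) exists only so end-to-end runs
work without an external model file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .acmg_engine import Registries
from .intervals import CNVCall
from .scoring import Thresholds, DEFAULT_THRESHOLDS, classify_score

#: Ratio presets: the neutral default and the two band-edge ratios at which
#: confident probabilities start flipping near-threshold scores (an LP score
#: of 0.90 needs r*(p-0.5) >= 0.09, hence r around 0.19 at p near 1; a VUS
#: score of 0 needs about 0.99, hence r around 1.99).
RATIO_PRESETS = {"default": 1.0, "lp-flip": 0.19, "vus-flip": 1.99}


@dataclass(frozen=True)
class PathogenicityProbability:
    """A [0,1] probability that a CNV is pathogenic, with provenance."""

    value: float
    source: str = "precomputed"

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"probability {self.value} outside [0,1]")


@dataclass(frozen=True)
class CombinedResult:
    acmg_score: float
    ml_probability: float
    ml_ratio: float
    joint_score: float
    classification: str


def combine(
    acmg_score: float,
    ml_probability: float,
    ratio: float = 1.0,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> CombinedResult:
    """Blend one ACMG score with one pathogenicity probability."""
    if not 0.0 <= ml_probability <= 1.0:
        raise ValueError(f"probability {ml_probability} outside [0,1]")
    if ratio < 0:
        raise ValueError(f"ratio must be non-negative, got {ratio}")
    if not math.isfinite(acmg_score):
        raise ValueError(f"ACMG score must be finite, got {acmg_score}")
    joint = acmg_score + ratio * (ml_probability - 0.50)
    return CombinedResult(
        acmg_score=acmg_score,
        ml_probability=ml_probability,
        ml_ratio=ratio,
        joint_score=joint,
        classification=classify_score(joint, thresholds),
    )


def max_ml_contribution(ratio: float) -> float:
    """Largest possible |f_joint - acmg_score|: ``r/2``, attained at a
    probability of 0 or 1."""
    if ratio < 0:
        raise ValueError(f"ratio must be non-negative, got {ratio}")
    return ratio * 0.50


def undecidable_band(
    ratio: float,
    grid_step: float = 0.01,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    grid_limit: float = 1.50,
) -> Optional[tuple[float, float]]:
    """The symmetric band of ACMG scores the classifier cannot decide.

    Scans ACMG scores on a centred grid (``-grid_limit`` … ``grid_limit``
    in steps of ``grid_step``).  A score is *decidable* when some
    probability in [0, 1] pushes the joint score into the Pathogenic or
    Benign range; since f_joint is monotone in p, only the endpoints
    matter.  Returns the largest contiguous symmetric band around 0 in
    which no grid score is decidable, or ``None`` when even score 0 is
    decidable (the band is empty).  The band shrinks as ``ratio`` grows.
    """
    if ratio < 0 or grid_step <= 0:
        raise ValueError("ratio must be >= 0 and grid_step > 0")
    eps = 1e-9

    def decidable(score: float) -> bool:
        return (
            score + ratio * 0.5 >= thresholds.pathogenic - eps
            or score - ratio * 0.5 <= thresholds.benign + eps
        )

    n_steps = int(round(grid_limit / grid_step))
    half = 0
    for k in range(n_steps + 1):
        s = k * grid_step
        if decidable(s) or decidable(-s):
            break
        half = k
    else:
        k = n_steps + 1
    if k == 0:
        return None
    return (round(-half * grid_step, 10), round(half * grid_step, 10))


def smallest_decisive_ratio(
    acmg_score: float,
    ml_probability: float,
    target_class: str = "P",
    step: float = 0.01,
    max_ratio: float = 10.0,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> Optional[float]:
    """Smallest ratio on an upward grid from 0 at which the combination
    reaches ``target_class``; ``None`` when no ratio up to ``max_ratio``
    does."""
    n_steps = int(round(max_ratio / step))
    for k in range(n_steps + 1):
        r = round(k * step, 10)
        if combine(acmg_score, ml_probability, r, thresholds).classification == target_class:
            return r
    return None


def combine_batch(
    acmg_scores: Sequence[float],
    probabilities: Sequence[float],
    ratio: float = 1.0,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> list[CombinedResult]:
    if len(acmg_scores) != len(probabilities):
        raise ValueError(
            f"length mismatch: {len(acmg_scores)} scores vs {len(probabilities)} probabilities"
        )
    return [combine(s, p, ratio, thresholds) for s, p in zip(acmg_scores, probabilities)]


def ratio_sweep(
    acmg_scores: Sequence[float],
    probabilities: Sequence[float],
    labels: Sequence[str],
    ratios: Sequence[float],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Tally true / false / uncertain predictions at each blend ratio.

    ``labels`` are the truth labels (``"pathogenic"`` / ``"benign"``);
    predictions of P against a pathogenic label (or B against benign) are
    true, P against benign or B against pathogenic false, and everything
    else (LB/VUS/LP) uncertain.  At ``ratio = 0`` the tallies are exactly
    those of the raw ACMG scores.
    """
    from .evaluation import tally  # local import avoids a cycle

    if not (len(acmg_scores) == len(probabilities) == len(labels)):
        raise ValueError("acmg_scores, probabilities and labels must align")
    rows = []
    for r in ratios:
        classes = [
            combine(s, p, r, thresholds).classification
            for s, p in zip(acmg_scores, probabilities)
        ]
        summary = tally(classes, labels)
        rows.append(
            {
                "ratio": r,
                "tp": summary.tp,
                "tn": summary.tn,
                "fp": summary.fp,
                "fn": summary.fn,
                "uncertain": summary.uncertain,
                "true": summary.tp + summary.tn,
                "false": summary.fp + summary.fn,
            }
        )
    return pd.DataFrame(rows)


def gene_count_probability(cnv: CNVCall, registries: Registries, scale: float = 0.15) -> float:
    """Bundled toy probability provider: a logistic function of the number
    of overlapped protein-coding genes.

    Exists so end-to-end pipelines run without an external model; it is not
    a pathogenicity model and tests treat it only as a plumbing stand-in.
    """
    if registries.genes is None:
        raise ValueError("gene registry required for the bundled provider")
    n = len(registries.genes.protein_coding_overlapping(cnv.interval))
    return 1.0 / (1.0 + math.exp(-scale * (n - 5)))
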