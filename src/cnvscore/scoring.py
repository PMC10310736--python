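"""The declarative scoring table: per-option points, classification
thresholds and gene-count bands.

The point sheet ships as an editable YAML file
(:data:`DEFAULT_TABLE_PATH`); nothing in the engine hard-codes a point
value, so a locally corrected table changes scores without touching code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .intervals import CNVType

#: The five classification tiers, benign to pathogenic.
CLASSES = ("B", "LB", "VUS", "LP", "P")


@dataclass(frozen=True)
class Thresholds:
    """Score boundaries of the 5-tier classification.

    Outer boundaries are inclusive (score ≥ ``pathogenic`` is P, score ≤
    ``benign`` is B); the narrow LP/LB bands are closed toward VUS on their
    inner edge.
    """

    pathogenic: float = 0.99
    likely_pathogenic: float = 0.90
    likely_benign: float = -0.90
    benign: float = -0.99

    def __post_init__(self) -> None:
        if not (self.benign <= self.likely_benign < self.likely_pathogenic <= self.pathogenic):
            raise ValueError("thresholds must be ordered B <= LB < LP <= P")


DEFAULT_THRESHOLDS = Thresholds()


def classify_score(score: float, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> str:
    """Map a summed section score to its 5-tier class.

    P iff score ≥ 0.99; LP iff 0.90 ≤ score < 0.99; VUS iff −0.90 < score
    < 0.90; LB iff −0.99 < score ≤ −0.90; B iff score ≤ −0.99 (with the
    default thresholds).  A small tolerance absorbs float summation noise
    at the boundaries.
    """
    if not math.isfinite(score):
        raise ValueError(f"score must be finite, got {score}")
    eps = 1e-9
    if score >= thresholds.pathogenic - eps:
        return "P"
    if score >= thresholds.likely_pathogenic - eps:
        return "LP"
    if score <= thresholds.benign + eps:
        return "B"
    if score <= thresholds.likely_benign + eps:
        return "LB"
    return "VUS"


@dataclass(frozen=True)
class ScoringTable:
    """Per-option points and section-3 gene-count bands for each CNV type."""

    loss_options: dict[str, float]
    gain_options: dict[str, float]
    loss_bands: dict[str, tuple[int, Optional[int]]]
    gain_bands: dict[str, tuple[int, Optional[int]]]
    thresholds: Thresholds = DEFAULT_THRESHOLDS
    loss_unevaluated: tuple[str, ...] = ("2J", "2K")
    gain_unevaluated: tuple[str, ...] = ("2I", "2J", "2K")

    def options_for(self, cnv_type: CNVType) -> dict[str, float]:
        return self.loss_options if cnv_type is CNVType.LOSS else self.gain_options

    def points(self, option_id: str, cnv_type: CNVType) -> float:
        options = self.options_for(cnv_type)
        try:
            return options[option_id]
        except KeyError:
            raise KeyError(
                f"option {option_id!r} not in the {cnv_type.value} scoring table"
            ) from None

    def bands_for(self, cnv_type: CNVType) -> dict[str, tuple[int, Optional[int]]]:
        return self.loss_bands if cnv_type is CNVType.LOSS else self.gain_bands

    def band_option(self, gene_count: int, cnv_type: CNVType) -> str:
        """Section-3 option for a protein-coding gene count (band lower
        bounds inclusive)."""
        for option_id, (lo, hi) in sorted(self.bands_for(cnv_type).items()):
            if gene_count >= lo and (hi is None or gene_count <= hi):
                return option_id
        raise ValueError(f"gene count {gene_count} not covered by any section-3 band")

    def unevaluated_for(self, cnv_type: CNVType) -> tuple[str, ...]:
        return self.loss_unevaluated if cnv_type is CNVType.LOSS else self.gain_unevaluated

    def classify(self, score: float) -> str:
        return classify_score(score, self.thresholds)


def _parse_bands(raw: dict) -> dict[str, tuple[int, Optional[int]]]:
    return {
        opt: (int(lo), None if hi is None else int(hi)) for opt, (lo, hi) in raw.items()
    }


def load_scoring_table(path: str | Path | None = None) -> ScoringTable:
    """Load a scoring table from YAML; the shipped default when ``path`` is
    None."""
    if path is None:
        text = (
            resources.files("cnvscore").joinpath("data/scoring_default.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    thr = raw.get("thresholds", {})
    thresholds = Thresholds(
        pathogenic=float(thr.get("pathogenic", 0.99)),
        likely_pathogenic=float(thr.get("likely_pathogenic", 0.90)),
        likely_benign=float(thr.get("likely_benign", -0.90)),
        benign=float(thr.get("benign", -0.99)),
    )
    return ScoringTable(
        loss_options={k: float(v) for k, v in raw["loss"]["options"].items()},
        gain_options={k: float(v) for k, v in raw["gain"]["options"].items()},
        loss_bands=_parse_bands(raw["loss"]["gene_count_bands"]),
        gain_bands=_parse_bands(raw["gain"]["gene_count_bands"]),
        thresholds=thresholds,
        loss_unevaluated=tuple(raw["loss"].get("unevaluated", ["2J", "2K"])),
        gain_unevaluated=tuple(raw["gain"].get("unevaluated", ["2I", "2J", "2K"])),
    )
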