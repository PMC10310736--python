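"""Rule-based ACMG/ClinGen scoring of CNVs.

Implements Sections 1 (genomic content), 2 (overlap with established
dosage-sensitive and benign regions — the options automatable from
position alone), 3 (gene number) and option 4O (common population
variation) of the point-based consensus scheme, and maps the summed score
through the 5-tier classification.  Options that require patient phenotype
(2J/2K for losses, 2I-2K for gains) are never scored; they are listed in
``unevaluated_options`` so every report is explicit about coverage.

Section-2 evidence selection rules (the standard leaves some of this to
the analyst; these are the fixed, tested conventions here):

* complete overlap of an established dosage-sensitive target scores 2A;
  partial overlap of a *region* scores 2B; partial overlap of a *gene*
  (losses) is resolved by breakpoint geometry over **all** transcripts of
  the gene, keeping the most severe outcome (largest absolute points,
  ties toward the pathogenic direction);
* established-target evidence (2A/2B/2C-2E) suppresses the computational
  haploinsufficiency-predictor option 2H;
* benign-overlap options are evaluated independently of dosage evidence;
  full containment in a benign record (2F for losses) suppresses the
  weaker extends-beyond comparison (2G).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .annotation_db import (
    BenignRegistry,
    BenignSource,
    Biotype,
    CoordinateFlavor,
    DosageRegistry,
    FunctionalElementRegistry,
    GeneModel,
    GeneRegistry,
    PopulationRegistry,
    PredictorRegistry,
    TargetKind,
    build_benign_db,
    load_benign_records,
    load_dosage_records,
    load_functional_elements,
    load_gene_models,
    load_hi_predictors,
    load_population_variants,
)
from .intervals import CNVCall, CNVType, GenomicInterval, intersect_length, is_contained
from .scoring import ScoringTable, classify_score, load_scoring_table


class MissingRegistryError(RuntimeError):
    """An annotation registry required by a section is absent."""


@dataclass(frozen=True)
class EngineOptions:
    """Tunable knobs of the scoring engine.

    Defaults reproduce the recommended configuration: only established
    (score-3) dosage targets, benign evidence from the curated gold-standard
    set with outer breakpoint coordinates filtered at 0.5% population
    frequency, both losses and gains searched, and 1% as the "common"
    population-frequency bar for 4O.
    """

    dosage_min_scores: frozenset[int] = frozenset({3})
    benign_source: BenignSource = BenignSource.DGV_GOLD
    benign_flavor: CoordinateFlavor = CoordinateFlavor.OUTER
    maf_threshold: Optional[float] = 0.005
    benign_type_filter: str = "both"
    common_af_threshold: float = 0.01
    predictor_min_calls: int = 2


#: Named presets selectable from the command line.
PRESETS: dict[str, EngineOptions] = {
    # the scheme exactly as the standard writes it: score-3 targets only,
    # benign search over both losses and gains, no frequency filter
    "acmg-default": EngineOptions(maf_threshold=None),
    # the best-performing benign-database setting: curated gold-standard
    # records, outer coordinates, population frequency >= 0.5%
    "gold-outer-0.5": EngineOptions(),
}


@dataclass(frozen=True)
class SectionEvidence:
    """One selected evidence option with its points and supporting records."""

    section: str  # "S1" | "S2" | "S3" | "S4"
    option_id: str
    points: float
    supporting: tuple[str, ...] = ()
    note: str = ""


@dataclass(frozen=True)
class ACMGResult:
    cnv: CNVCall
    evidence: tuple[SectionEvidence, ...]
    total_score: float
    classification: str
    unevaluated_options: tuple[str, ...]


@dataclass
class Registries:
    """The annotation registries the engine consults, bundled.

    ``benign`` is already filtered (source/flavor/frequency/type) — build it
    with :func:`cnvscore.annotation_db.build_benign_db` or via
    :meth:`from_dir`, which applies the filters in :class:`EngineOptions`.
    """

    genes: Optional[GeneRegistry] = None
    functional: Optional[FunctionalElementRegistry] = None
    dosage: Optional[DosageRegistry] = None
    benign: Optional[BenignRegistry] = None
    population: Optional[PopulationRegistry] = None
    predictors: Optional[PredictorRegistry] = None

    @classmethod
    def from_dir(
        cls, bundle_dir: str | Path, options: EngineOptions = EngineOptions()
    ) -> "Registries":
        """Load a bundle directory written by the fixture generator (or any
        directory following the same file layout)."""
        bundle_dir = Path(bundle_dir)
        functional_path = bundle_dir / "functional.tsv"
        predictors_path = bundle_dir / "predictors.tsv"
        raw_benign = load_benign_records(bundle_dir / "benign.tsv")
        return cls(
            genes=load_gene_models(bundle_dir / "genes.tsv"),
            functional=(
                load_functional_elements(functional_path)
                if functional_path.exists()
                else FunctionalElementRegistry([])
            ),
            dosage=load_dosage_records(bundle_dir / "dosage.tsv"),
            benign=build_benign_db(
                raw_benign,
                maf_threshold=options.maf_threshold,
                type_filter=options.benign_type_filter,
                flavor=options.benign_flavor,
                source=options.benign_source,
            ),
            population=load_population_variants(bundle_dir / "population.tsv"),
            predictors=(
                load_hi_predictors(predictors_path)
                if predictors_path.exists()
                else PredictorRegistry([])
            ),
        )


def _require(registry, name: str, blocks: str):
    if registry is None:
        raise MissingRegistryError(f"{name} registry missing: blocks {blocks}")
    return registry


def _covers_base(cnv: GenomicInterval, chrom: str, pos_left: int, *, right_end: bool) -> bool:
    """Whether the CNV covers a transcript endpoint (half-open spans: the
    right endpoint is the base at ``pos - 1``)."""
    base = pos_left - 1 if right_end else pos_left
    return cnv.chrom == chrom and cnv.start <= base < cnv.end


def _breakpoint_inside(cnv: GenomicInterval, span: GenomicInterval) -> bool:
    """True when either CNV breakpoint falls strictly inside ``span``."""
    if cnv.chrom != span.chrom:
        return False
    return (span.start < cnv.start < span.end) or (span.start < cnv.end < span.end)


def _most_severe(option_points: Sequence[tuple[str, float]]) -> Optional[tuple[str, float]]:
    """Pick the option with the largest absolute points; ties break toward
    the pathogenic (positive) direction, then lexicographically for
    determinism."""
    if not option_points:
        return None
    return max(option_points, key=lambda op: (abs(op[1]), op[1], op[0]))


# ---------------------------------------------------------------------------
# Section 1 — initial assessment of genomic content

def evaluate_section1(
    cnv: CNVCall,
    genes: GeneRegistry,
    functional: Optional[FunctionalElementRegistry],
    table: ScoringTable,
) -> SectionEvidence:
    """1A when the CNV overlaps protein-coding genes or known functionally
    important elements; 1B otherwise."""
    hits = genes.protein_coding_overlapping(cnv.interval)
    supporting = [g.symbol for g in hits]
    if functional is not None:
        supporting += [
            f"{el.element_class}:{el.span}" for el in functional.overlapping(cnv.interval)
        ]
    option = "1A" if supporting else "1B"
    return SectionEvidence(
        section="S1",
        option_id=option,
        points=table.points(option, cnv.cnv_type),
        supporting=tuple(supporting),
    )


# ---------------------------------------------------------------------------
# Section 2 — overlap with established dosage-sensitive / benign regions

def _transcript_geometry(cnv: GenomicInterval, gene: GeneModel) -> Optional[list[str]]:
    """Breakpoint geometry of a partial gene overlap, resolved over all
    transcripts (most severe kept by the caller via option points).

    Per transcript: 5'-end covered only → 2C; 3'-end covered only → 2D;
    neither end covered but overlapping (both breakpoints inside) → 2E;
    both ends covered (transcript fully contained) ranks with 2C, the most
    severe geometry.
    """
    geometries = []
    for tx in gene.transcripts:
        if intersect_length(cnv, tx.span) == 0:
            continue
        left = _covers_base(cnv, tx.span.chrom, tx.span.start, right_end=False)
        right = _covers_base(cnv, tx.span.chrom, tx.span.end, right_end=True)
        covers5 = left if tx.cds_start_side == "left" else right
        covers3 = right if tx.cds_start_side == "left" else left
        if covers5:
            geometries.append("2C")  # includes the fully-contained-transcript case
        elif covers3:
            geometries.append("2D")
        else:
            geometries.append("2E")
    return geometries or None


def evaluate_section2_loss(
    cnv: CNVCall,
    registries: Registries,
    table: ScoringTable,
    options: EngineOptions,
) -> tuple[list[SectionEvidence], list[str]]:
    """Section-2 evidence for a copy-number loss.

    Evaluates, in priority order: 2A (complete overlap of an established HI
    gene/region), 2B (partial overlap of an established HI region), 2C-2E
    (breakpoint geometry over a partially overlapped HI gene's transcripts),
    2F (containment in an established benign CNV), 2G (overlap of a benign
    CNV with additional protein-coding content), 2H (computational HI
    predictor consensus on a fully contained gene, only when no established
    HI evidence fired).  2J/2K require the patient phenotype and are
    reported as unevaluated.
    """
    if cnv.cnv_type is not CNVType.LOSS:
        raise ValueError(f"evaluate_section2_loss called on a {cnv.cnv_type.value}")
    genes = _require(registries.genes, "gene", "Section 2 (loss)")
    dosage = _require(registries.dosage, "dosage", "Section 2 (loss)")
    benign = _require(registries.benign, "benign CNV", "Section 2 (loss)")

    evidence: list[SectionEvidence] = []

    # -- established HI targets (2A/2B/2C-2E)
    per_option: dict[str, list[str]] = {}
    for rec, kind in dosage.query_dosage(
        cnv.interval, options.dosage_min_scores, score_field="hi"
    ):
        if kind == "complete":
            per_option.setdefault("2A", []).append(rec.symbol)
            continue
        if rec.target_kind is TargetKind.REGION:
            per_option.setdefault("2B", []).append(rec.symbol)
            continue
        gene = genes.by_symbol.get(rec.symbol)
        geoms = _transcript_geometry(cnv.interval, gene) if gene is not None else None
        if not geoms:
            # gene model unavailable: fall back to the generic partial overlap
            per_option.setdefault("2B", []).append(rec.symbol)
            continue
        chosen = _most_severe([(g, table.points(g, cnv.cnv_type)) for g in geoms])
        per_option.setdefault(chosen[0], []).append(rec.symbol)
    for option_id in sorted(per_option):
        evidence.append(
            SectionEvidence(
                section="S2",
                option_id=option_id,
                points=table.points(option_id, cnv.cnv_type),
                supporting=tuple(sorted(per_option[option_id])),
            )
        )
    established_hi_fired = bool(per_option)

    # -- benign-database comparison (2F/2G); database build decides the
    #    loss-only vs gains-and-losses question, so no type filter here
    benign_hits = benign.query_benign(cnv.interval, cnv_type=None)
    contained_in = [rec for rec, contained in benign_hits if contained]
    if contained_in:
        evidence.append(
            SectionEvidence(
                section="S2",
                option_id="2F",
                points=table.points("2F", cnv.cnv_type),
                supporting=tuple(sorted(r.id or str(r.span) for r in contained_in)),
            )
        )
    elif benign_hits:
        cnv_genes = {g.symbol for g in genes.protein_coding_overlapping(cnv.interval)}
        extra_sets = []
        for rec, _ in benign_hits:
            rec_genes = {g.symbol for g in genes.protein_coding_overlapping(rec.span)}
            if cnv_genes - rec_genes:
                extra_sets.append((rec, sorted(cnv_genes - rec_genes)))
        if extra_sets:
            evidence.append(
                SectionEvidence(
                    section="S2",
                    option_id="2G",
                    points=table.points("2G", cnv.cnv_type),
                    supporting=tuple(
                        sorted(r.id or str(r.span) for r, _ in extra_sets)
                    ),
                    note="additional protein-coding genes beyond the benign record",
                )
            )

    # -- computational HI predictors (2H), only without established evidence
    if not established_hi_fired and registries.predictors is not None:
        called = []
        for gene in genes.protein_coding_overlapping(cnv.interval):
            if not is_contained(gene.span, cnv.interval):
                continue
            rec = registries.predictors.calls_for(gene.symbol)
            if rec is not None and rec.n_positive >= options.predictor_min_calls:
                called.append(gene.symbol)
        if called:
            evidence.append(
                SectionEvidence(
                    section="S2",
                    option_id="2H",
                    points=table.points("2H", cnv.cnv_type),
                    supporting=tuple(sorted(called)),
                )
            )

    return evidence, list(table.unevaluated_for(cnv.cnv_type))


def _gene_content(genes: GeneRegistry, interval: GenomicInterval) -> frozenset[str]:
    return frozenset(g.symbol for g in genes.protein_coding_overlapping(interval))


def evaluate_section2_gain(
    cnv: CNVCall,
    registries: Registries,
    table: ScoringTable,
    options: EngineOptions,
) -> tuple[list[SectionEvidence], list[str]]:
    """Section-2 evidence for a copy-number gain.

    2A/2B against established TS targets; one benign-gain comparison among
    2C (identical gene content), 2D/2E (smaller and fully contained,
    breakpoints outside/inside genes), 2F/2G (larger or extending beyond,
    without/with additional protein-coding genes); 2H when an established
    HI gene is fully contained; 2L when a breakpoint falls inside any gene.
    Phenotype-dependent options are reported as unevaluated.
    """
    if cnv.cnv_type is not CNVType.GAIN:
        raise ValueError(f"evaluate_section2_gain called on a {cnv.cnv_type.value}")
    genes = _require(registries.genes, "gene", "Section 2 (gain)")
    dosage = _require(registries.dosage, "dosage", "Section 2 (gain)")
    benign = _require(registries.benign, "benign CNV", "Section 2 (gain)")

    evidence: list[SectionEvidence] = []

    # -- established TS targets (2A/2B)
    per_option: dict[str, list[str]] = {}
    for rec, kind in dosage.query_dosage(
        cnv.interval, options.dosage_min_scores, score_field="ts"
    ):
        per_option.setdefault("2A" if kind == "complete" else "2B", []).append(rec.symbol)
    for option_id in sorted(per_option):
        evidence.append(
            SectionEvidence(
                section="S2",
                option_id=option_id,
                points=table.points(option_id, cnv.cnv_type),
                supporting=tuple(sorted(per_option[option_id])),
            )
        )

    # -- benign gain comparison (2C-2G): one option per record, most severe kept
    cnv_genes = _gene_content(genes, cnv.interval)
    candidates: list[tuple[str, float, str]] = []
    for rec, cnv_contained in benign.query_benign(cnv.interval, cnv_type=CNVType.GAIN):
        rec_genes = _gene_content(genes, rec.span)
        rec_id = rec.id or str(rec.span)
        if cnv_genes == rec_genes:
            option = "2C"
        elif cnv_contained:
            breaks_gene = any(
                _breakpoint_inside(cnv.interval, g.span)
                for g in genes.overlapping(cnv.interval)
            )
            option = "2E" if breaks_gene else "2D"
        elif cnv_genes - rec_genes:
            option = "2G"
        elif is_contained(rec.span, cnv.interval):
            option = "2F"  # larger than the benign record, no additional genes
        else:
            continue  # partial overlap with no additional protein-coding content
        candidates.append((option, table.points(option, cnv.cnv_type), rec_id))
    if candidates:
        chosen = _most_severe([(opt, pts) for opt, pts, _ in candidates])
        supporting = sorted(rid for opt, _, rid in candidates if opt == chosen[0])
        evidence.append(
            SectionEvidence(
                section="S2",
                option_id=chosen[0],
                points=chosen[1],
                supporting=tuple(supporting),
            )
        )

    # -- established HI gene fully contained within the gain (2H)
    hi_contained = []
    for rec, kind in dosage.query_dosage(
        cnv.interval, options.dosage_min_scores, score_field="hi"
    ):
        if kind == "complete" and rec.target_kind is TargetKind.GENE:
            hi_contained.append(rec.symbol)
    if hi_contained:
        evidence.append(
            SectionEvidence(
                section="S2",
                option_id="2H",
                points=table.points("2H", cnv.cnv_type),
                supporting=tuple(sorted(hi_contained)),
            )
        )

    # -- breakpoint inside any gene (2L)
    broken = sorted(
        g.symbol
        for g in genes.overlapping(cnv.interval)
        if _breakpoint_inside(cnv.interval, g.span)
    )
    if broken:
        evidence.append(
            SectionEvidence(
                section="S2",
                option_id="2L",
                points=table.points("2L", cnv.cnv_type),
                supporting=tuple(broken),
            )
        )

    return evidence, list(table.unevaluated_for(cnv.cnv_type))


# ---------------------------------------------------------------------------
# Section 3 — evaluation of gene number

def evaluate_section3(
    cnv: CNVCall, genes: GeneRegistry, table: ScoringTable
) -> SectionEvidence:
    """Count distinct protein-coding genes with any overlap and map the
    count through the type-specific bands."""
    hits = genes.protein_coding_overlapping(cnv.interval)
    option = table.band_option(len(hits), cnv.cnv_type)
    return SectionEvidence(
        section="S3",
        option_id=option,
        points=table.points(option, cnv.cnv_type),
        supporting=tuple(g.symbol for g in hits),
        note=f"{len(hits)} protein-coding gene(s)",
    )


# ---------------------------------------------------------------------------
# Section 4, option 4O — common population variation

def evaluate_section4o(
    cnv: CNVCall,
    population: PopulationRegistry,
    table: ScoringTable,
    options: EngineOptions,
) -> Optional[SectionEvidence]:
    """4O when the CNV is completely contained in a population variant of
    matching type whose allele frequency reaches the common-variant bar."""
    freq = population.query_population_frequency(cnv.interval, cnv.cnv_type)
    if freq >= options.common_af_threshold:
        return SectionEvidence(
            section="S4",
            option_id="4O",
            points=table.points("4O", cnv.cnv_type),
            note=f"population AF {freq:g}",
        )
    return None


# ---------------------------------------------------------------------------
# full scoring

def score_cnv(
    cnv: CNVCall,
    registries: Registries,
    table: Optional[ScoringTable] = None,
    options: EngineOptions = EngineOptions(),
) -> ACMGResult:
    """Score one CNV through Sections 1-3 and option 4O and classify it."""
    if table is None:
        table = load_scoring_table()
    genes = _require(registries.genes, "gene", "Sections 1 and 3")
    population = _require(registries.population, "population variant", "option 4O")

    evidence: list[SectionEvidence] = [
        evaluate_section1(cnv, genes, registries.functional, table)
    ]
    if cnv.cnv_type is CNVType.LOSS:
        s2, unevaluated = evaluate_section2_loss(cnv, registries, table, options)
    else:
        s2, unevaluated = evaluate_section2_gain(cnv, registries, table, options)
    evidence.extend(s2)
    evidence.append(evaluate_section3(cnv, genes, table))
    s4 = evaluate_section4o(cnv, population, table, options)
    if s4 is not None:
        evidence.append(s4)

    total = sum(e.points for e in evidence)
    return ACMGResult(
        cnv=cnv,
        evidence=tuple(evidence),
        total_score=total,
        classification=table.classify(total),
        unevaluated_options=tuple(unevaluated),
    )


def score_batch(
    cnvs: Sequence[CNVCall],
    registries: Registries,
    table: Optional[ScoringTable] = None,
    options: EngineOptions = EngineOptions(),
) -> list[ACMGResult]:
    if table is None:
        table = load_scoring_table()
    return [score_cnv(cnv, registries, table, options) for cnv in cnvs]


# ---------------------------------------------------------------------------
# result serialization

def results_table(results: Sequence[ACMGResult]) -> pd.DataFrame:
    """One row per CNV: coordinates, type, total score, class."""
    rows = []
    for res in results:
        chrom, start, end = res.cnv.interval.to_1based()
        rows.append(
            {
                "id": res.cnv.id or "",
                "chrom": chrom,
                "start": start,
                "end": end,
                "cnv_type": res.cnv.cnv_type.value,
                "total_score": round(res.total_score, 6),
                "classification": res.classification,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id", "chrom", "start", "end", "cnv_type", "total_score", "classification"],
    )


def result_detail(result: ACMGResult) -> dict:
    """Per-option detail for one CNV, JSON-serializable."""
    chrom, start, end = result.cnv.interval.to_1based()
    return {
        "id": result.cnv.id,
        "cnv": {"chrom": chrom, "start": start, "end": end, "type": result.cnv.cnv_type.value},
        "evidence": [
            {
                "section": e.section,
                "option": e.option_id,
                "points": e.points,
                "supporting": list(e.supporting),
                "note": e.note,
            }
            for e in result.evidence
        ],
        "total_score": round(result.total_score, 6),
        "classification": result.classification,
        "unevaluated_options": list(result.unevaluated_options),
    }


def write_results(
    results: Sequence[ACMGResult], table_path: str | Path, detail_path: str | Path | None = None
) -> None:
    results_table(results).to_csv(table_path, sep="\t", index=False)
    if detail_path is not None:
        with open(detail_path, "w") as fh:
            json.dump([result_detail(r) for r in results], fh, indent=1)
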