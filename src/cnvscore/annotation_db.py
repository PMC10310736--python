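"""Readers and queryable registries for the annotation sources the scoring
engine consults.

Four kinds of flat-table inputs are supported, each modelled on the export
dialect of the public database a clinical pipeline would pull it from:

* **gene models** — BED12-like TSV, one row per transcript, with exon lists
  (Gencode-style content at toy scale);
* **dosage-sensitivity records** — ClinGen-style table of haploinsufficiency
  (HI) and triplosensitivity (TS) scores for genes and genomic regions;
* **benign CNV records** — DGV-style table of known variants with population
  frequency, a ``coordinate_flavor`` distinguishing curated inner/outer
  breakpoint representations, and a source tag;
* **population variants** — GnomAD-style table of structural variants with
  allele frequencies (serves both as a benign-CNV source and as the common
  population-variation registry);
* **haploinsufficiency predictor calls** — dbNSFP-style per-gene boolean
  calls from several computational HI predictors.

All on-disk coordinates are 1-based inclusive; loaders convert to the
internal 0-based half-open convention.  Registries answer overlap and
containment queries through per-chromosome interval trees and return
deterministic, position-sorted results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .intervals import (
    CNVType,
    GenomicInterval,
    coverage_fraction,
    intersect_length,
    is_contained,
    parse_cnv_type,
)


class Biotype(str, Enum):
    PROTEIN_CODING = "protein_coding"
    OTHER = "other"


class TargetKind(str, Enum):
    GENE = "gene"
    REGION = "region"


class CoordinateFlavor(str, Enum):
    PLAIN = "plain"
    INNER = "inner"
    OUTER = "outer"


class BenignSource(str, Enum):
    DGV = "DGV"
    DGV_GOLD = "DGV_GOLD"
    GNOMAD = "GnomAD"


#: Valid ClinGen dosage scores: 0-3 (3 = established), 30 = autosomal
#: recessive, 40 = dosage-insensitive.
DOSAGE_SCORES = frozenset({0, 1, 2, 3, 30, 40})


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    cds_start_side: str  # "left" | "right": which genomic end carries the 5' end

    def __post_init__(self) -> None:
        if self.cds_start_side not in ("left", "right"):
            raise ValueError(f"cds_start_side must be left|right, got {self.cds_start_side!r}")
        prev_end = None
        for exon in self.exons:
            if not is_contained(exon, self.span):
                raise ValueError(
                    f"transcript {self.transcript_id}: exon {exon} outside span {self.span}"
                )
            if prev_end is not None and exon.start < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = exon.end

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the transcript's 5' end."""
        return self.span.start if self.cds_start_side == "left" else self.span.end

    @property
    def three_prime(self) -> int:
        return self.span.end if self.cds_start_side == "left" else self.span.start


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    symbol: str
    biotype: Biotype
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        chroms = {t.span.chrom for t in self.transcripts}
        if len(chroms) > 1:
            raise ValueError(f"gene {self.gene_id} has transcripts on multiple chromosomes")

    @property
    def span(self) -> GenomicInterval:
        """Union span over all transcripts."""
        return GenomicInterval(
            self.transcripts[0].span.chrom,
            min(t.span.start for t in self.transcripts),
            max(t.span.end for t in self.transcripts),
        )


@dataclass(frozen=True)
class FunctionalElement:
    span: GenomicInterval
    element_class: str


@dataclass(frozen=True)
class DosageRecord:
    target: GenomicInterval
    target_kind: TargetKind
    hi_score: Optional[int]
    ts_score: Optional[int]
    symbol: str

    def __post_init__(self) -> None:
        if self.hi_score is None and self.ts_score is None:
            raise ValueError(f"dosage record {self.symbol}: neither HI nor TS score set")
        for s in (self.hi_score, self.ts_score):
            if s is not None and s not in DOSAGE_SCORES:
                raise ValueError(f"dosage record {self.symbol}: invalid score {s}")


@dataclass(frozen=True)
class BenignCNVRecord:
    span: GenomicInterval
    cnv_type: CNVType
    frequency: float
    coordinate_flavor: CoordinateFlavor
    source: BenignSource
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"benign record frequency {self.frequency} outside [0,1]")


@dataclass(frozen=True)
class PopulationVariantRecord:
    span: GenomicInterval
    cnv_type: CNVType
    allele_frequency: float
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError(
                f"population record AF {self.allele_frequency} outside [0,1]"
            )


@dataclass(frozen=True)
class HIPredictorRecord:
    symbol: str
    predictor_calls: tuple[bool, ...]

    def __post_init__(self) -> None:
        if not self.predictor_calls:
            raise ValueError(f"predictor record {self.symbol}: no predictor calls")

    @property
    def n_positive(self) -> int:
        return sum(self.predictor_calls)


# ---------------------------------------------------------------------------
# interval index

class _ChromIndex:
    """Per-chromosome interval trees over arbitrary payload records."""

    def __init__(self, items: Iterable[tuple[GenomicInterval, object]]):
        self._trees: dict[str, IntervalTree] = {}
        for span, payload in items:
            self._trees.setdefault(span.chrom, IntervalTree()).addi(
                span.start, span.end, payload
            )

    def overlapping(self, query: GenomicInterval) -> list:
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(query.start, query.end)]


def _sort_key(span: GenomicInterval, ident: str) -> tuple:
    return (span.chrom, span.start, span.end, ident)


# ---------------------------------------------------------------------------
# registries

class GeneRegistry:
    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = tuple(genes)
        self.by_symbol = {g.symbol: g for g in self.genes}
        self._index = _ChromIndex((g.span, g) for g in self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def overlapping(self, interval: GenomicInterval) -> list[GeneModel]:
        hits = self._index.overlapping(interval)
        return sorted(hits, key=lambda g: _sort_key(g.span, g.gene_id))

    def query_overlapping_genes(
        self, interval: GenomicInterval
    ) -> list[tuple[GeneModel, dict[str, float]]]:
        """Genes overlapping ``interval`` with per-transcript coverage fractions."""
        out = []
        for gene in self.overlapping(interval):
            fractions = {
                t.transcript_id: coverage_fraction(t.span, interval)
                for t in gene.transcripts
            }
            out.append((gene, fractions))
        return out

    def protein_coding_overlapping(self, interval: GenomicInterval) -> list[GeneModel]:
        return [
            g for g in self.overlapping(interval) if g.biotype is Biotype.PROTEIN_CODING
        ]


class FunctionalElementRegistry:
    def __init__(self, elements: Sequence[FunctionalElement]):
        self.elements = tuple(elements)
        self._index = _ChromIndex((e.span, e) for e in self.elements)

    def __len__(self) -> int:
        return len(self.elements)

    def overlapping(self, interval: GenomicInterval) -> list[FunctionalElement]:
        hits = self._index.overlapping(interval)
        return sorted(hits, key=lambda e: _sort_key(e.span, e.element_class))


class DosageRegistry:
    def __init__(self, records: Sequence[DosageRecord]):
        self.records = tuple(records)
        self._index = _ChromIndex((r.target, r) for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def query_dosage(
        self,
        interval: GenomicInterval,
        min_scores: frozenset[int] | set[int],
        score_field: str = "hi",
    ) -> list[tuple[DosageRecord, str]]:
        """Dosage records overlapping ``interval`` whose HI (or TS) score is
        in ``min_scores``, tagged ``"complete"`` when the record's target is
        fully contained in the queried interval, else ``"partial"``."""
        if score_field not in ("hi", "ts"):
            raise ValueError("score_field must be 'hi' or 'ts'")
        out = []
        for rec in self._index.overlapping(interval):
            score = rec.hi_score if score_field == "hi" else rec.ts_score
            if score is None or score not in min_scores:
                continue
            kind = "complete" if is_contained(rec.target, interval) else "partial"
            out.append((rec, kind))
        out.sort(key=lambda pair: _sort_key(pair[0].target, pair[0].symbol))
        return out


class BenignRegistry:
    def __init__(self, records: Sequence[BenignCNVRecord]):
        self.records = tuple(records)
        self._index = _ChromIndex((r.span, r) for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def query_benign(
        self, interval: GenomicInterval, cnv_type: Optional[CNVType] = None
    ) -> list[tuple[BenignCNVRecord, bool]]:
        """Benign records overlapping ``interval`` (optionally restricted to a
        CNV type) with a flag marking whether the interval is completely
        contained in the record."""
        out = []
        for rec in self._index.overlapping(interval):
            if cnv_type is not None and rec.cnv_type is not cnv_type:
                continue
            out.append((rec, is_contained(interval, rec.span)))
        out.sort(key=lambda pair: _sort_key(pair[0].span, pair[0].id or ""))
        return out


class PopulationRegistry:
    def __init__(self, records: Sequence[PopulationVariantRecord]):
        self.records = tuple(records)
        self._index = _ChromIndex((r.span, r) for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def query_population_frequency(
        self, interval: GenomicInterval, cnv_type: CNVType
    ) -> float:
        """Best-supported population frequency: the maximum allele frequency
        over records of matching type that completely contain ``interval``;
        0.0 when no record contains it."""
        best = 0.0
        for rec in self._index.overlapping(interval):
            if rec.cnv_type is cnv_type and is_contained(interval, rec.span):
                best = max(best, rec.allele_frequency)
        return best


class PredictorRegistry:
    def __init__(self, records: Sequence[HIPredictorRecord]):
        self.records = tuple(records)
        self.by_symbol = {r.symbol: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def calls_for(self, symbol: str) -> Optional[HIPredictorRecord]:
        return self.by_symbol.get(symbol)


# ---------------------------------------------------------------------------
# benign database construction (the filtering studied in the sweep harness)

def build_benign_db(
    records: Iterable[BenignCNVRecord],
    maf_threshold: Optional[float] = None,
    type_filter: str = "both",
    flavor: CoordinateFlavor | str = CoordinateFlavor.PLAIN,
    source: Optional[BenignSource | str] = None,
) -> BenignRegistry:
    """Assemble a filtered registry of established benign CNVs.

    Retains records with population frequency ≥ ``maf_threshold`` (all
    records when ``None``), of the requested coordinate flavor and source,
    and — when ``type_filter="losses_only"`` — only loss records.  Raising
    the threshold can only shrink the registry (monotone filtering), which
    is what makes the threshold a trade-off dial between accuracy and the
    fraction of CNVs the benign evidence can decide.
    """
    if maf_threshold is not None and not 0.0 < maf_threshold <= 1.0:
        raise ValueError(f"maf_threshold must be in (0,1] or None, got {maf_threshold}")
    if type_filter not in ("both", "losses_only"):
        raise ValueError(f"unknown type_filter {type_filter!r}")
    flavor = CoordinateFlavor(flavor)
    if source is not None:
        source = BenignSource(source)

    kept = []
    for rec in records:
        if rec.coordinate_flavor is not flavor:
            continue
        if source is not None and rec.source is not source:
            continue
        if type_filter == "losses_only" and rec.cnv_type is not CNVType.LOSS:
            continue
        if maf_threshold is not None and rec.frequency < maf_threshold:
            continue
        kept.append(rec)
    return BenignRegistry(kept)


# ---------------------------------------------------------------------------
# loaders — all dialects are TSV with a header row, 1-based inclusive coords

GENE_COLUMNS = [
    "chrom", "start", "end", "gene_id", "symbol", "biotype",
    "transcript_id", "tx_start", "tx_end", "exon_starts", "exon_ends", "cds_side",
]
DOSAGE_COLUMNS = ["symbol", "target_kind", "chrom", "start", "end", "hi_score", "ts_score"]
BENIGN_COLUMNS = ["id", "chrom", "start", "end", "cnv_type", "frequency", "coordinate_flavor", "source"]
POPULATION_COLUMNS = ["id", "chrom", "start", "end", "cnv_type", "allele_frequency"]
PREDICTOR_COLUMNS = ["symbol", "predictor_calls"]
FUNCTIONAL_COLUMNS = ["chrom", "start", "end", "element_class"]


class AnnotationFormatError(ValueError):
    """A malformed annotation table; the message names the offending line."""


def _read_table(path: str | Path, required: list[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=required)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AnnotationFormatError(f"{what} file {path}: missing column(s) {missing}")
    if df.empty:
        warnings.warn(f"{what} file {path} is empty; registry will be empty", stacklevel=3)
    return df


def _int_list(text: str) -> list[int]:
    return [int(tok) for tok in str(text).split(",") if tok != ""]


def load_gene_models(path: str | Path) -> GeneRegistry:
    """Load the BED12-like gene-model table (one row per transcript)."""
    df = _read_table(path, GENE_COLUMNS, "gene model")
    per_gene: dict[str, dict] = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            exon_starts = _int_list(row.exon_starts)
            exon_ends = _int_list(row.exon_ends)
            if len(exon_starts) != len(exon_ends):
                raise ValueError("exon start/end lists differ in length")
            exons = tuple(
                GenomicInterval.from_1based(row.chrom, s, e)
                for s, e in zip(exon_starts, exon_ends)
            )
            tx = TranscriptModel(
                transcript_id=row.transcript_id,
                span=GenomicInterval.from_1based(row.chrom, int(row.tx_start), int(row.tx_end)),
                exons=exons,
                cds_start_side=row.cds_side,
            )
        except ValueError as exc:
            raise AnnotationFormatError(f"{path} line {lineno}: {exc}") from exc
        entry = per_gene.setdefault(
            row.gene_id, {"symbol": row.symbol, "biotype": row.biotype, "txs": []}
        )
        entry["txs"].append(tx)
    genes = []
    for gene_id, entry in per_gene.items():
        biotype = (
            Biotype.PROTEIN_CODING
            if entry["biotype"] == "protein_coding"
            else Biotype.OTHER
        )
        genes.append(
            GeneModel(
                gene_id=gene_id,
                symbol=entry["symbol"],
                biotype=biotype,
                transcripts=tuple(sorted(entry["txs"], key=lambda t: (t.span.start, t.transcript_id))),
            )
        )
    genes.sort(key=lambda g: _sort_key(g.span, g.gene_id))
    return GeneRegistry(genes)


def _parse_score(text: str) -> Optional[int]:
    text = str(text).strip()
    if text in ("", "NA", "nan", "None", "."):
        return None
    return int(text)


def load_dosage_records(path: str | Path) -> DosageRegistry:
    """Load the ClinGen-style dosage-sensitivity table."""
    df = _read_table(path, DOSAGE_COLUMNS, "dosage")
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                DosageRecord(
                    target=GenomicInterval.from_1based(row.chrom, int(row.start), int(row.end)),
                    target_kind=TargetKind(row.target_kind),
                    hi_score=_parse_score(row.hi_score),
                    ts_score=_parse_score(row.ts_score),
                    symbol=row.symbol,
                )
            )
        except ValueError as exc:
            raise AnnotationFormatError(f"{path} line {lineno}: {exc}") from exc
    records.sort(key=lambda r: _sort_key(r.target, r.symbol))
    return DosageRegistry(records)


def load_benign_records(path: str | Path) -> list[BenignCNVRecord]:
    """Load the DGV-style table of known benign CNVs (raw, pre-filter)."""
    df = _read_table(path, BENIGN_COLUMNS, "benign CNV")
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                BenignCNVRecord(
                    span=GenomicInterval.from_1based(row.chrom, int(row.start), int(row.end)),
                    cnv_type=parse_cnv_type(row.cnv_type),
                    frequency=float(row.frequency),
                    coordinate_flavor=CoordinateFlavor(row.coordinate_flavor),
                    source=BenignSource(row.source),
                    id=row.id or None,
                )
            )
        except ValueError as exc:
            raise AnnotationFormatError(f"{path} line {lineno}: {exc}") from exc
    records.sort(key=lambda r: _sort_key(r.span, r.id or ""))
    return records


def load_population_variants(path: str | Path) -> PopulationRegistry:
    """Load the GnomAD-style population-variant table."""
    df = _read_table(path, POPULATION_COLUMNS, "population variant")
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                PopulationVariantRecord(
                    span=GenomicInterval.from_1based(row.chrom, int(row.start), int(row.end)),
                    cnv_type=parse_cnv_type(row.cnv_type),
                    allele_frequency=float(row.allele_frequency),
                    id=row.id or None,
                )
            )
        except ValueError as exc:
            raise AnnotationFormatError(f"{path} line {lineno}: {exc}") from exc
    records.sort(key=lambda r: _sort_key(r.span, r.id or ""))
    return PopulationRegistry(records)


def load_hi_predictors(path: str | Path) -> PredictorRegistry:
    """Load dbNSFP-style per-gene haploinsufficiency predictor calls."""
    df = _read_table(path, PREDICTOR_COLUMNS, "HI predictor")
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            calls = tuple(bool(int(tok)) for tok in str(row.predictor_calls).split(",") if tok != "")
            records.append(HIPredictorRecord(symbol=row.symbol, predictor_calls=calls))
        except ValueError as exc:
            raise AnnotationFormatError(f"{path} line {lineno}: {exc}") from exc
    return PredictorRegistry(records)


def load_functional_elements(path: str | Path) -> FunctionalElementRegistry:
    """Load the regulatory/functional-element table."""
    df = _read_table(path, FUNCTIONAL_COLUMNS, "functional element")
    elements = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            elements.append(
                FunctionalElement(
                    span=GenomicInterval.from_1based(row.chrom, int(row.start), int(row.end)),
                    element_class=row.element_class,
                )
            )
        except ValueError as exc:
            raise AnnotationFormatError(f"{path} line {lineno}: {exc}") from exc
    elements.sort(key=lambda e: _sort_key(e.span, e.element_class))
    return FunctionalElementRegistry(elements)


# ---------------------------------------------------------------------------
# writers (round-trip counterparts of the loaders; used by the fixture
# generator and by tests)

def write_benign_records(records: Sequence[BenignCNVRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        chrom, s, e = rec.span.to_1based()
        rows.append(
            {
                "id": rec.id or "",
                "chrom": chrom,
                "start": s,
                "end": e,
                "cnv_type": rec.cnv_type.value,
                "frequency": repr(rec.frequency),
                "coordinate_flavor": rec.coordinate_flavor.value,
                "source": rec.source.value,
            }
        )
    pd.DataFrame(rows, columns=BENIGN_COLUMNS).to_csv(path, sep="\t", index=False)


def write_population_variants(
    records: Sequence[PopulationVariantRecord], path: str | Path
) -> None:
    rows = []
    for rec in records:
        chrom, s, e = rec.span.to_1based()
        rows.append(
            {
                "id": rec.id or "",
                "chrom": chrom,
                "start": s,
                "end": e,
                "cnv_type": rec.cnv_type.value,
                "allele_frequency": repr(rec.allele_frequency),
            }
        )
    pd.DataFrame(rows, columns=POPULATION_COLUMNS).to_csv(path, sep="\t", index=False)


def write_dosage_records(records: Sequence[DosageRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        chrom, s, e = rec.target.to_1based()
        rows.append(
            {
                "symbol": rec.symbol,
                "target_kind": rec.target_kind.value,
                "chrom": chrom,
                "start": s,
                "end": e,
                "hi_score": "NA" if rec.hi_score is None else rec.hi_score,
                "ts_score": "NA" if rec.ts_score is None else rec.ts_score,
            }
        )
    pd.DataFrame(rows, columns=DOSAGE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = []
    for gene in genes:
        gchrom, gs, ge = gene.span.to_1based()
        for tx in gene.transcripts:
            _, ts, te = tx.span.to_1based()
            rows.append(
                {
                    "chrom": gchrom,
                    "start": gs,
                    "end": ge,
                    "gene_id": gene.gene_id,
                    "symbol": gene.symbol,
                    "biotype": gene.biotype.value,
                    "transcript_id": tx.transcript_id,
                    "tx_start": ts,
                    "tx_end": te,
                    "exon_starts": ",".join(str(ex.to_1based()[1]) for ex in tx.exons),
                    "exon_ends": ",".join(str(ex.to_1based()[2]) for ex in tx.exons),
                    "cds_side": tx.cds_start_side,
                }
            )
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_hi_predictors(records: Sequence[HIPredictorRecord], path: str | Path) -> None:
    rows = [
        {
            "symbol": rec.symbol,
            "predictor_calls": ",".join("1" if c else "0" for c in rec.predictor_calls),
        }
        for rec in records
    ]
    pd.DataFrame(rows, columns=PREDICTOR_COLUMNS).to_csv(path, sep="\t", index=False)


def write_functional_elements(
    elements: Sequence[FunctionalElement], path: str | Path
) -> None:
    rows = []
    for el in elements:
        chrom, s, e = el.span.to_1based()
        rows.append({"chrom": chrom, "start": s, "end": e, "element_class": el.element_class})
    pd.DataFrame(rows, columns=FUNCTIONAL_COLUMNS).to_csv(path, sep="\t", index=False)
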