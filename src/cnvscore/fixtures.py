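"""Deterministic synthetic annotation bundles and labeled CNV sets.

The generator lays out a toy genome whose chromosomes are partitioned into
functional *zones*, so that a CNV planted in one zone triggers exactly the
evidence it was built to demonstrate and nothing else:

====================  =====================================================
zone (fraction)       content
====================  =====================================================
desert   [0.00-0.15)  nothing — CNVs here score 1B + 3A
hi       [0.15-0.225) haploinsufficient genes (ClinGen-style scores
                      3/2/1/0/30/40) plus one established HI region
ts       [0.225-0.30) triplosensitive genes (TS scores), for gains
predictor[0.30-0.40)  genes with computational HI-predictor calls (no
                      established dosage record) plus regulatory elements
benign   [0.40-0.55)  curated benign CNV records (three source dialects,
                      inner/outer flavors for the curated gold set) with
                      population frequencies spanning the filter
                      thresholds, and a few bystander genes
population[0.55-0.65) population structural variants with allele
                      frequencies straddling the common-variant bar
dense    [0.65-0.95)  a dense run of ordinary protein-coding genes, for
                      the gene-number bands
====================  =====================================================

Every CNV row carries its truth label and the *planted* evidence options;
the round-trip guarantee (generate → load → score ⇒ planted ⊆ emitted) is
the package's core end-to-end oracle.  One integer seed drives everything
through fixed per-stream sub-seeds, so the same spec yields byte-identical
files.

The CNV sets mirror a ClinVar-style curation: a *basic* set of single-copy
events between 1 kb and 5 Mb (copy numbers 1/3), a *large* set of events
above 5 Mb, and a *multiple* set of homozygous-loss / double-gain events
(copy numbers 0/4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation_db import (
    BenignCNVRecord,
    BenignSource,
    Biotype,
    CoordinateFlavor,
    DosageRecord,
    FunctionalElement,
    GeneModel,
    HIPredictorRecord,
    PopulationVariantRecord,
    TargetKind,
    TranscriptModel,
    write_benign_records,
    write_dosage_records,
    write_functional_elements,
    write_gene_models,
    write_hi_predictors,
    write_population_variants,
)
from .intervals import CNVCall, CNVType, GenomicInterval, parse_cnv_type

ZONES = {
    "desert": (0.00, 0.15),
    "hi": (0.15, 0.225),
    "ts": (0.225, 0.30),
    "predictor": (0.30, 0.40),
    "benign": (0.40, 0.55),
    "population": (0.55, 0.65),
    "dense": (0.65, 0.95),
}

#: Population frequencies cycled over curated benign records; chosen to
#: straddle every filter threshold in the sweep (0.01% … 10%).
BENIGN_FREQUENCIES = (0.00005, 0.0005, 0.002, 0.007, 0.015, 0.05, 0.2)

#: Allele frequencies cycled over population variants (the common-variant
#: bar defaults to 1%).
POPULATION_AFS = (0.002, 0.05, 0.008, 0.3, 0.0005, 0.02, 0.09, 0.004)

#: Default planted-truth mix for the basic set.
DEFAULT_MIX = {
    "2A": 0.15,       # loss fully containing an established HI gene
    "2A-gain": 0.10,  # gain fully containing an established TS gene
    "2F": 0.20,       # loss contained in a high-frequency curated benign CNV
    "4O": 0.15,       # CNV contained in a common population variant
    "2H": 0.10,       # loss containing a predictor-called gene
    "band3B": 0.05,   # loss over the middle gene-number band
    "band3C": 0.05,   # loss over the top gene-number band
    "none": 0.20,     # desert CNV: no evidence beyond 1B/3A
}

BUNDLE_FILES = {
    "genes": "genes.tsv",
    "dosage": "dosage.tsv",
    "benign": "benign.tsv",
    "population": "population.tsv",
    "predictors": "predictors.tsv",
    "functional": "functional.tsv",
}

CNV_COLUMNS = [
    "id", "chrom", "start", "end", "cnv_type", "copy_number",
    "truth_label", "planted_options",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of a synthetic bundle; identical specs yield identical bytes."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    genes_per_zone: int = 8       # hi / ts / predictor zones
    benign_zone_genes: int = 4
    dense_genes: int = 80
    benign_per_chrom: int = 12    # curated benign records per chromosome
    population_per_chrom: int = 8
    n_basic: int = 60
    n_large: int = 8
    n_multiple: int = 12
    planted_mix: tuple[tuple[str, float], ...] = tuple(DEFAULT_MIX.items())

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        total = sum(f for _, f in self.planted_mix)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"planted mix fractions must sum to 1, got {total}")
        unknown = [k for k, _ in self.planted_mix if k not in DEFAULT_MIX]
        if unknown:
            raise ValueError(f"unknown planted kinds {unknown}")
        # reject specs that cannot be laid out: each zone must fit its genes
        for zone, n in (("hi", self.genes_per_zone), ("dense", self.dense_genes)):
            lo, hi = self.zone_bounds(zone)
            if n > 0 and (hi - lo) // n < 45_000 and zone == "hi":
                raise ValueError(f"{zone} zone too small for {n} genes")
            if n > 0 and (hi - lo) // n < 30_000 and zone == "dense":
                raise ValueError(f"{zone} zone too small for {n} genes")
        if self.n_large > 0 and self.chrom_length < 7_000_000:
            raise ValueError("chromosomes too short to host CNVs above 5 Mb")

    def zone_bounds(self, zone: str) -> tuple[int, int]:
        lo, hi = ZONES[zone]
        return int(lo * self.chrom_length), int(hi * self.chrom_length)

    def chroms(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def rng(self, stream: int) -> np.random.Generator:
        # fixed per-stream sub-seeds: adding a stream never perturbs others
        return np.random.default_rng([stream, self.seed])


@dataclass
class AnnotationBundle:
    """In-memory counterpart of a bundle directory."""

    spec: FixtureSpec
    genes: list[GeneModel]
    functional: list[FunctionalElement]
    dosage: list[DosageRecord]
    benign: list[BenignCNVRecord]
    population: list[PopulationVariantRecord]
    predictors: list[HIPredictorRecord]
    # bookkeeping for the planting routines
    hi3_genes: list[GeneModel] = field(default_factory=list)
    ts3_genes: list[GeneModel] = field(default_factory=list)
    predictor_genes: list[GeneModel] = field(default_factory=list)
    dense_by_chrom: dict[str, list[GeneModel]] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_gene_models(self.genes, out_dir / BUNDLE_FILES["genes"])
        write_dosage_records(self.dosage, out_dir / BUNDLE_FILES["dosage"])
        write_benign_records(self.benign, out_dir / BUNDLE_FILES["benign"])
        write_population_variants(self.population, out_dir / BUNDLE_FILES["population"])
        write_hi_predictors(self.predictors, out_dir / BUNDLE_FILES["predictors"])
        write_functional_elements(self.functional, out_dir / BUNDLE_FILES["functional"])
        return out_dir


def _make_gene(
    chrom: str,
    start: int,
    length: int,
    gene_id: str,
    symbol: str,
    biotype: Biotype,
    rng: np.random.Generator,
) -> GeneModel:
    end = start + length
    n_tx = int(rng.integers(1, 4))
    transcripts = []
    for t in range(n_tx):
        if t == 0:
            ts, te = start, end
        else:
            d1 = int(rng.integers(0, max(1, length // 4)))
            d2 = int(rng.integers(0, max(1, length // 4)))
            ts, te = start + d1, end - d2
            if te - ts < 1_000:
                ts, te = start, end
        span = GenomicInterval(chrom, ts, te)
        n_ex = int(rng.integers(1, 5))
        chunk = (te - ts) // n_ex
        exons = tuple(
            GenomicInterval(chrom, ts + i * chunk, ts + i * chunk + max(1, chunk // 2))
            for i in range(n_ex)
        )
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gene_id}.t{t + 1}",
                span=span,
                exons=exons,
                cds_start_side="left" if rng.integers(0, 2) == 0 else "right",
            )
        )
    return GeneModel(
        gene_id=gene_id, symbol=symbol, biotype=biotype,
        transcripts=tuple(sorted(transcripts, key=lambda tx: (tx.span.start, tx.transcript_id))),
    )


def _place_genes(
    spec: FixtureSpec,
    chrom: str,
    zone: str,
    n: int,
    prefix: str,
    rng: np.random.Generator,
    min_len: int = 10_000,
    max_len: int = 40_000,
    jitter: int = 20_000,
) -> list[GeneModel]:
    lo, hi = spec.zone_bounds(zone)
    spacing = (hi - lo) // max(n, 1)
    genes = []
    for i in range(n):
        start = lo + i * spacing + int(rng.integers(0, jitter))
        length = int(rng.integers(min_len, max_len))
        length = min(length, spacing - jitter - 1_000)  # keep neighbours disjoint
        gene_id = f"{prefix}{chrom[3:]}_{i:03d}"
        genes.append(
            _make_gene(chrom, start, length, gene_id, gene_id.upper(), Biotype.PROTEIN_CODING, rng)
        )
    return genes


#: ClinGen-style score cycle for dosage genes: mostly established (3), with
#: emerging (1/2), no-evidence (0), recessive (30) and insensitive (40) mixed in.
_DOSAGE_SCORE_CYCLE = (3, 3, 3, 2, 1, 0, 30, 40)


def generate_annotation_bundle(spec: FixtureSpec) -> AnnotationBundle:
    """Build the self-consistent toy genome for a spec."""
    genes: list[GeneModel] = []
    dosage: list[DosageRecord] = []
    benign: list[BenignCNVRecord] = []
    population: list[PopulationVariantRecord] = []
    predictors: list[HIPredictorRecord] = []
    functional: list[FunctionalElement] = []

    bundle = AnnotationBundle(
        spec=spec, genes=genes, functional=functional, dosage=dosage,
        benign=benign, population=population, predictors=predictors,
    )

    g_rng = spec.rng(1)
    b_rng = spec.rng(3)
    p_rng = spec.rng(4)

    for chrom in spec.chroms():
        # -- haploinsufficient genes + one established region
        hi_genes = _place_genes(spec, chrom, "hi", spec.genes_per_zone, "hig", g_rng)
        genes.extend(hi_genes)
        for i, gene in enumerate(hi_genes):
            score = _DOSAGE_SCORE_CYCLE[i % len(_DOSAGE_SCORE_CYCLE)]
            dosage.append(
                DosageRecord(
                    target=gene.span, target_kind=TargetKind.GENE,
                    hi_score=score, ts_score=None, symbol=gene.symbol,
                )
            )
            if score == 3:
                bundle.hi3_genes.append(gene)
        if len(hi_genes) >= 2:
            region = GenomicInterval(chrom, hi_genes[0].span.start, hi_genes[1].span.end)
            dosage.append(
                DosageRecord(
                    target=region, target_kind=TargetKind.REGION,
                    hi_score=3, ts_score=None, symbol=f"HIR{chrom[3:]}",
                )
            )

        # -- triplosensitive genes
        ts_genes = _place_genes(spec, chrom, "ts", spec.genes_per_zone, "tsg", g_rng)
        genes.extend(ts_genes)
        for i, gene in enumerate(ts_genes):
            score = _DOSAGE_SCORE_CYCLE[i % len(_DOSAGE_SCORE_CYCLE)]
            dosage.append(
                DosageRecord(
                    target=gene.span, target_kind=TargetKind.GENE,
                    hi_score=None, ts_score=score, symbol=gene.symbol,
                )
            )
            if score == 3:
                bundle.ts3_genes.append(gene)

        # -- predictor-called genes (no established dosage record)
        pred_genes = _place_genes(spec, chrom, "predictor", spec.genes_per_zone, "prg", g_rng)
        genes.extend(pred_genes)
        for i, gene in enumerate(pred_genes):
            n_true = 3 if i % 2 == 0 else 1  # even genes reach the >=2 consensus
            calls = tuple(j < n_true for j in range(5))
            predictors.append(HIPredictorRecord(symbol=gene.symbol, predictor_calls=calls))
            if n_true >= 2:
                bundle.predictor_genes.append(gene)
        # a couple of regulatory elements between predictor genes
        lo, hi = spec.zone_bounds("predictor")
        for i in range(2):
            start = hi - 60_000 - i * 30_000
            functional.append(
                FunctionalElement(
                    span=GenomicInterval(chrom, start, start + 8_000),
                    element_class="enhancer",
                )
            )

        # -- bystander genes inside the benign zone
        genes.extend(
            _place_genes(
                spec, chrom, "benign", spec.benign_zone_genes, "bng", g_rng,
                min_len=10_000, max_len=25_000, jitter=10_000,
            )
        )

        # -- curated benign records: sources and types cycled so every sweep
        #    setting has records, frequencies straddling every threshold
        lo, hi = spec.zone_bounds("benign")
        spacing = (hi - lo) // max(spec.benign_per_chrom, 1)
        for i in range(spec.benign_per_chrom):
            start = lo + i * spacing + int(b_rng.integers(0, 10_000))
            length = int(b_rng.integers(40_000, min(100_000, spacing - 12_000)))
            span = GenomicInterval(chrom, start, start + length)
            source = (BenignSource.DGV, BenignSource.DGV_GOLD, BenignSource.GNOMAD)[i % 3]
            cnv_type = CNVType.LOSS if i % 2 == 0 else CNVType.GAIN
            freq = BENIGN_FREQUENCIES[i % len(BENIGN_FREQUENCIES)]
            rec_id = f"bnv{chrom[3:]}_{i:03d}"
            if source is BenignSource.DGV_GOLD:
                shrink = length // 10
                inner = GenomicInterval(chrom, span.start + shrink, span.end - shrink)
                outer = GenomicInterval(chrom, span.start - shrink, span.end + shrink)
                benign.append(BenignCNVRecord(inner, cnv_type, freq, CoordinateFlavor.INNER, source, rec_id + "i"))
                benign.append(BenignCNVRecord(outer, cnv_type, freq, CoordinateFlavor.OUTER, source, rec_id + "o"))
            else:
                benign.append(BenignCNVRecord(span, cnv_type, freq, CoordinateFlavor.PLAIN, source, rec_id))

        # -- population variants
        lo, hi = spec.zone_bounds("population")
        spacing = (hi - lo) // max(spec.population_per_chrom, 1)
        for i in range(spec.population_per_chrom):
            start = lo + i * spacing + int(p_rng.integers(0, 10_000))
            length = int(p_rng.integers(30_000, min(80_000, spacing - 12_000)))
            population.append(
                PopulationVariantRecord(
                    span=GenomicInterval(chrom, start, start + length),
                    cnv_type=CNVType.LOSS if i % 2 == 0 else CNVType.GAIN,
                    allele_frequency=POPULATION_AFS[i % len(POPULATION_AFS)],
                    id=f"pop{chrom[3:]}_{i:03d}",
                )
            )

        # -- the dense gene run for the gene-number bands
        dense = _place_genes(
            spec, chrom, "dense", spec.dense_genes, "dng", g_rng,
            min_len=8_000, max_len=20_000, jitter=8_000,
        )
        genes.extend(dense)
        bundle.dense_by_chrom[chrom] = dense

    genes.sort(key=lambda g: (g.span.chrom, g.span.start, g.gene_id))
    return bundle


# ---------------------------------------------------------------------------
# CNV planting

@dataclass(frozen=True)
class PlantedCNV:
    cnv: CNVCall
    truth_label: str
    planted_options: tuple[str, ...]


def _plant(
    kind: str,
    chrom: str,
    bundle: AnnotationBundle,
    rng: np.random.Generator,
    cnv_type_cycle: int,
    copy_numbers: tuple[int, int] = (1, 3),  # (loss, gain)
) -> tuple[GenomicInterval, CNVType, int, str, tuple[str, ...]]:
    """Construct one CNV of the requested planted kind on ``chrom``.

    Returns (interval, type, copy_number, truth_label, planted options);
    the planted options are a guaranteed subset of what the engine emits
    under default options.
    """
    spec = bundle.spec
    cn_loss, cn_gain = copy_numbers
    if kind == "2A":
        cands = [g for g in bundle.hi3_genes if g.span.chrom == chrom]
        gene = cands[int(rng.integers(0, len(cands)))]
        margin_l = int(rng.integers(2_000, 20_000))
        margin_r = int(rng.integers(2_000, 20_000))
        iv = GenomicInterval(chrom, gene.span.start - margin_l, gene.span.end + margin_r)
        return iv, CNVType.LOSS, cn_loss, "pathogenic", ("1A", "2A")
    if kind == "2A-gain":
        cands = [g for g in bundle.ts3_genes if g.span.chrom == chrom]
        gene = cands[int(rng.integers(0, len(cands)))]
        margin_l = int(rng.integers(2_000, 20_000))
        margin_r = int(rng.integers(2_000, 20_000))
        iv = GenomicInterval(chrom, gene.span.start - margin_l, gene.span.end + margin_r)
        return iv, CNVType.GAIN, cn_gain, "pathogenic", ("1A", "2A")
    if kind == "2F":
        # inside the *inner* flavor of a high-frequency curated loss record,
        # hence contained under every flavor the engine may be configured with
        cands = [
            r for r in bundle.benign
            if r.span.chrom == chrom
            and r.source is BenignSource.DGV_GOLD
            and r.coordinate_flavor is CoordinateFlavor.INNER
            and r.cnv_type is CNVType.LOSS
            and r.frequency >= 0.015
        ]
        rec = cands[int(rng.integers(0, len(cands)))]
        inner_len = rec.span.length
        start = rec.span.start + int(rng.integers(1_000, max(2_000, inner_len // 4)))
        end = rec.span.end - int(rng.integers(1_000, max(2_000, inner_len // 4)))
        iv = GenomicInterval(chrom, start, max(end, start + 1_000))
        return iv, CNVType.LOSS, cn_loss, "benign", ("2F",)
    if kind == "4O":
        want_gain = cnv_type_cycle % 2 == 1
        want_type = CNVType.GAIN if want_gain else CNVType.LOSS
        cands = [
            r for r in bundle.population
            if r.span.chrom == chrom and r.cnv_type is want_type and r.allele_frequency >= 0.01
        ]
        rec = cands[int(rng.integers(0, len(cands)))]
        start = rec.span.start + int(rng.integers(1_000, rec.span.length // 4))
        end = rec.span.end - int(rng.integers(1_000, rec.span.length // 4))
        iv = GenomicInterval(chrom, start, max(end, start + 1_000))
        cn = cn_gain if want_gain else cn_loss
        return iv, want_type, cn, "benign", ("4O",)
    if kind == "2H":
        cands = [g for g in bundle.predictor_genes if g.span.chrom == chrom]
        gene = cands[int(rng.integers(0, len(cands)))]
        margin_l = int(rng.integers(2_000, 15_000))
        margin_r = int(rng.integers(2_000, 15_000))
        iv = GenomicInterval(chrom, gene.span.start - margin_l, gene.span.end + margin_r)
        return iv, CNVType.LOSS, cn_loss, "pathogenic", ("1A", "2H")
    if kind in ("band3B", "band3C"):
        dense = bundle.dense_by_chrom[chrom]
        k = 28 if kind == "band3B" else 40  # gene counts inside the 25-34 / >=35 loss bands
        if len(dense) < k + 2:
            raise ValueError(f"dense zone has too few genes for {kind}")
        i0 = int(rng.integers(1, len(dense) - k))
        first, last = dense[i0], dense[i0 + k - 1]
        start = max(dense[i0 - 1].span.end + 100, first.span.start - 1_000)
        next_start = (
            dense[i0 + k].span.start if i0 + k < len(dense) else spec.zone_bounds("dense")[1]
        )
        end = min(next_start - 100, last.span.end + 1_000)
        iv = GenomicInterval(chrom, start, end)
        option = "3B" if kind == "band3B" else "3C"
        return iv, CNVType.LOSS, cn_loss, "pathogenic", ("1A", option)
    if kind == "none":
        lo, hi = spec.zone_bounds("desert")
        length = int(rng.integers(2_000, 200_000))
        start = int(rng.integers(lo + 1_000, hi - length - 1_000))
        iv = GenomicInterval(chrom, start, start + length)
        return iv, CNVType.LOSS, cn_loss, "benign", ("1B", "3A")
    raise ValueError(f"unknown planted kind {kind!r}")


def _mix_counts(mix: Sequence[tuple[str, float]], n: int) -> list[tuple[str, int]]:
    """Largest-remainder apportionment of n CNVs over the mix fractions."""
    raw = [(kind, frac * n) for kind, frac in mix]
    counts = {kind: int(x) for kind, x in raw}
    short = n - sum(counts.values())
    for kind, x in sorted(raw, key=lambda kv: -(kv[1] - int(kv[1])))[:short]:
        counts[kind] += 1
    return [(kind, counts[kind]) for kind, _ in mix if counts[kind] > 0]


def generate_cnv_sets(
    spec: FixtureSpec, bundle: AnnotationBundle
) -> dict[str, list[PlantedCNV]]:
    """Build the basic / large / multiple labeled CNV sets.

    basic: 1 kb ≤ length ≤ 5 Mb, copy numbers 1/3, planted per the mix;
    large: length > 5 Mb spanning the dosage zones (established-overlap
    evidence); multiple: copy numbers 0/4, same plantings as basic.
    """
    rng = spec.rng(6)
    chroms = spec.chroms()
    sets: dict[str, list[PlantedCNV]] = {"basic": [], "large": [], "multiple": []}

    def plant_batch(name: str, n: int, copy_numbers: tuple[int, int]) -> None:
        idx = 0
        for kind, count in _mix_counts(spec.planted_mix, n):
            for j in range(count):
                chrom = chroms[idx % len(chroms)]
                iv, cnv_type, cn, label, opts = _plant(
                    kind, chrom, bundle, rng, cnv_type_cycle=j, copy_numbers=copy_numbers
                )
                sets[name].append(
                    PlantedCNV(
                        cnv=CNVCall(iv, cnv_type, copy_number=cn, id=f"{name}-{idx:04d}"),
                        truth_label=label,
                        planted_options=opts,
                    )
                )
                idx += 1

    plant_batch("basic", spec.n_basic, (1, 3))
    plant_batch("multiple", spec.n_multiple, (0, 4))

    # large events: > 5 Mb, sweeping from the desert across the dosage zones
    for i in range(spec.n_large):
        chrom = chroms[i % len(chroms)]
        gain = i % 2 == 1
        start = int(rng.integers(100_000, 400_000))
        end = int(rng.integers(5_600_000, min(6_400_000, spec.chrom_length - 100_000)))
        iv = GenomicInterval(chrom, start, end)
        sets["large"].append(
            PlantedCNV(
                cnv=CNVCall(
                    iv,
                    CNVType.GAIN if gain else CNVType.LOSS,
                    copy_number=3 if gain else 1,
                    id=f"large-{i:04d}",
                ),
                truth_label="pathogenic",
                planted_options=("1A", "2A"),
            )
        )
    return sets


# ---------------------------------------------------------------------------
# CNV table I/O

def write_cnv_set(planted: Sequence[PlantedCNV], path: str | Path) -> None:
    rows = []
    for p in planted:
        chrom, start, end = p.cnv.interval.to_1based()
        rows.append(
            {
                "id": p.cnv.id,
                "chrom": chrom,
                "start": start,
                "end": end,
                "cnv_type": p.cnv.cnv_type.value,
                "copy_number": p.cnv.copy_number,
                "truth_label": p.truth_label,
                "planted_options": ",".join(p.planted_options),
            }
        )
    pd.DataFrame(rows, columns=CNV_COLUMNS).to_csv(path, sep="\t", index=False)


def load_cnv_set(path: str | Path) -> list[PlantedCNV]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PlantedCNV(
                cnv=CNVCall(
                    interval=GenomicInterval.from_1based(row.chrom, int(row.start), int(row.end)),
                    cnv_type=parse_cnv_type(row.cnv_type),
                    copy_number=int(row.copy_number) if row.copy_number != "" else None,
                    id=row.id,
                ),
                truth_label=row.truth_label,
                planted_options=tuple(
                    tok for tok in row.planted_options.split(",") if tok
                ),
            )
        )
    return out


def write_fixture_bundle(spec: FixtureSpec, out_dir: str | Path) -> Path:
    """Generate and write a complete bundle: annotation files + CNV sets."""
    out_dir = Path(out_dir)
    bundle = generate_annotation_bundle(spec)
    bundle.write(out_dir)
    for name, planted in generate_cnv_sets(spec, bundle).items():
        write_cnv_set(planted, out_dir / f"cnv_{name}.tsv")
    return out_dir
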