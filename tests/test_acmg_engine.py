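import math
from dataclasses import replace

import pytest
from hypothesis import given, settings, strategies as st

from cnvscore.acmg_engine import (
    EngineOptions,
    MissingRegistryError,
    Registries,
    evaluate_section1,
    evaluate_section2_gain,
    evaluate_section2_loss,
    evaluate_section3,
    evaluate_section4o,
    score_cnv,
)
from cnvscore.annotation_db import (
    BenignCNVRecord,
    BenignRegistry,
    BenignSource,
    Biotype,
    CoordinateFlavor,
    DosageRecord,
    DosageRegistry,
    FunctionalElement,
    FunctionalElementRegistry,
    GeneModel,
    GeneRegistry,
    HIPredictorRecord,
    PopulationRegistry,
    PopulationVariantRecord,
    PredictorRegistry,
    TargetKind,
    TranscriptModel,
    build_benign_db,
)
from cnvscore.intervals import CNVCall, CNVType, GenomicInterval
from cnvscore.scoring import classify_score
from conftest import make_registries
from oracle import filter_benign, oracle_options, oracle_total


def gene(gene_id, chrom, start, end, biotype=Biotype.PROTEIN_CODING, cds_side="left"):
    span = GenomicInterval(chrom, start, end)
    tx = TranscriptModel(f"{gene_id}.t1", span, (span,), cds_side)
    return GeneModel(gene_id, gene_id.upper(), biotype, (tx,))


def mini_registries(
    genes=(), functional=(), dosage=(), benign=(), population=(), predictors=()
):
    return Registries(
        genes=GeneRegistry(genes),
        functional=FunctionalElementRegistry(functional),
        dosage=DosageRegistry(dosage),
        benign=BenignRegistry(benign),
        population=PopulationRegistry(population),
        predictors=PredictorRegistry(predictors),
    )


def loss(chrom, start, end):
    return CNVCall(GenomicInterval(chrom, start, end), CNVType.LOSS)


def gain(chrom, start, end):
    return CNVCall(GenomicInterval(chrom, start, end), CNVType.GAIN)


OPTS = EngineOptions()

G1 = gene("g1", "chr1", 100_000, 150_000)


class TestSection1:
    def test_protein_coding_overlap_gives_1a(self, table):
        regs = mini_registries(genes=[G1])
        ev = evaluate_section1(loss("chr1", 140_000, 200_000), regs.genes, regs.functional, table)
        assert ev.option_id == "1A"

    def test_gene_desert_gives_1b(self, table):
        regs = mini_registries(genes=[G1])
        ev = evaluate_section1(loss("chr1", 500_000, 600_000), regs.genes, regs.functional, table)
        assert ev.option_id == "1B"
        assert ev.points == table.points("1B", CNVType.LOSS)

    def test_functional_element_alone_gives_1a(self, table):
        el = FunctionalElement(GenomicInterval("chr1", 500_000, 505_000), "enhancer")
        regs = mini_registries(functional=[el])
        ev = evaluate_section1(loss("chr1", 499_000, 501_000), regs.genes, regs.functional, table)
        assert ev.option_id == "1A"

    def test_non_coding_gene_does_not_count(self, table):
        nc = gene("nc1", "chr1", 100_000, 150_000, biotype=Biotype.OTHER)
        regs = mini_registries(genes=[nc])
        ev = evaluate_section1(loss("chr1", 120_000, 130_000), regs.genes, regs.functional, table)
        assert ev.option_id == "1B"


class TestSection2Loss:
    def hi_record(self, score=3):
        return DosageRecord(G1.span, TargetKind.GENE, score, None, G1.symbol)

    def test_complete_overlap_of_established_hi_gene_is_2a(self, table):
        regs = mini_registries(genes=[G1], dosage=[self.hi_record(3)])
        ev, unevaluated = evaluate_section2_loss(loss("chr1", 90_000, 160_000), regs, table, OPTS)
        assert [e.option_id for e in ev] == ["2A"]
        assert set(unevaluated) == {"2J", "2K"}

    def test_score2_excluded_by_default_included_when_widened(self, table):
        regs = mini_registries(genes=[G1], dosage=[self.hi_record(2)])
        cnv = loss("chr1", 90_000, 160_000)
        ev, _ = evaluate_section2_loss(cnv, regs, table, OPTS)
        assert not any(e.option_id in ("2A", "2B") for e in ev)
        widened = replace(OPTS, dosage_min_scores=frozenset({1, 2, 3}))
        ev, _ = evaluate_section2_loss(cnv, regs, table, widened)
        assert [e.option_id for e in ev] == ["2A"]

    def test_partial_region_overlap_is_2b(self, table):
        region = DosageRecord(
            GenomicInterval("chr1", 100_000, 300_000), TargetKind.REGION, 3, None, "HIR1"
        )
        regs = mini_registries(dosage=[region], genes=[])
        ev, _ = evaluate_section2_loss(loss("chr1", 90_000, 200_000), regs, table, OPTS)
        assert [e.option_id for e in ev] == ["2B"]

    @pytest.mark.parametrize(
        "cds_side, cnv_span, expected",
        [
            ("left", (90_000, 120_000), "2C"),   # covers the 5' (left) end
            ("left", (120_000, 160_000), "2D"),  # covers the 3' (right) end
            ("left", (110_000, 140_000), "2E"),  # both breakpoints inside
            ("right", (90_000, 120_000), "2D"),  # left end is the 3' end here
            ("right", (120_000, 160_000), "2C"),
        ],
    )
    def test_breakpoint_geometry(self, table, cds_side, cnv_span, expected):
        g = gene("g1", "chr1", 100_000, 150_000, cds_side=cds_side)
        rec = DosageRecord(g.span, TargetKind.GENE, 3, None, g.symbol)
        regs = mini_registries(genes=[g], dosage=[rec])
        ev, _ = evaluate_section2_loss(loss("chr1", *cnv_span), regs, table, OPTS)
        assert [e.option_id for e in ev] == [expected]

    def test_most_severe_transcript_kept(self, table):
        # two transcripts: the short one is fully inside the CNV (5' covered,
        # -> 2C); the long one only has its interior clipped (-> 2E); the
        # most severe (2C, 0.90 points) must win
        chrom = "chr1"
        tx_long = TranscriptModel(
            "g1.t1", GenomicInterval(chrom, 100_000, 150_000),
            (GenomicInterval(chrom, 100_000, 150_000),), "left",
        )
        tx_short = TranscriptModel(
            "g1.t2", GenomicInterval(chrom, 112_000, 118_000),
            (GenomicInterval(chrom, 112_000, 118_000),), "left",
        )
        g = GeneModel("g1", "G1", Biotype.PROTEIN_CODING, (tx_long, tx_short))
        rec = DosageRecord(g.span, TargetKind.GENE, 3, None, g.symbol)
        regs = mini_registries(genes=[g], dosage=[rec])
        ev, _ = evaluate_section2_loss(loss(chrom, 110_000, 120_000), regs, table, OPTS)
        assert [e.option_id for e in ev] == ["2C"]

    def test_containment_in_filtered_benign_record_is_2f(self, table):
        rec = BenignCNVRecord(
            GenomicInterval("chr1", 100_000, 300_000), CNVType.LOSS, 0.02,
            CoordinateFlavor.OUTER, BenignSource.DGV_GOLD, "b1",
        )
        regs = mini_registries(benign=build_benign_db([rec], 0.005, flavor="outer").records)
        ev, _ = evaluate_section2_loss(loss("chr1", 150_000, 250_000), regs, table, OPTS)
        assert [e.option_id for e in ev] == ["2F"]

    def test_low_frequency_record_filtered_out(self, table):
        rec = BenignCNVRecord(
            GenomicInterval("chr1", 100_000, 300_000), CNVType.LOSS, 0.001,
            CoordinateFlavor.OUTER, BenignSource.DGV_GOLD, "b1",
        )
        regs = mini_registries(benign=build_benign_db([rec], 0.005, flavor="outer").records)
        ev, _ = evaluate_section2_loss(loss("chr1", 150_000, 250_000), regs, table, OPTS)
        assert ev == []

    def test_extension_beyond_benign_over_extra_gene_is_2g(self, table):
        rec = BenignCNVRecord(
            GenomicInterval("chr1", 100_000, 200_000), CNVType.LOSS, 0.02,
            CoordinateFlavor.PLAIN, BenignSource.DGV, "b1",
        )
        extra = gene("g2", "chr1", 220_000, 240_000)
        regs = mini_registries(genes=[extra], benign=[rec])
        ev, _ = evaluate_section2_loss(loss("chr1", 150_000, 250_000), regs, table, OPTS)
        assert "2G" in [e.option_id for e in ev]

    def test_predictor_consensus_is_2h_only_without_established_evidence(self, table):
        pred = HIPredictorRecord(G1.symbol, (True, True, False))
        regs = mini_registries(genes=[G1], predictors=[pred])
        cnv = loss("chr1", 90_000, 160_000)
        ev, _ = evaluate_section2_loss(cnv, regs, table, OPTS)
        assert [e.option_id for e in ev] == ["2H"]
        # with an established record on the same gene, 2H is suppressed
        regs2 = mini_registries(
            genes=[G1], predictors=[pred],
            dosage=[DosageRecord(G1.span, TargetKind.GENE, 3, None, G1.symbol)],
        )
        ev2, _ = evaluate_section2_loss(cnv, regs2, table, OPTS)
        assert [e.option_id for e in ev2] == ["2A"]

    def test_single_predictor_call_insufficient(self, table):
        pred = HIPredictorRecord(G1.symbol, (True, False, False))
        regs = mini_registries(genes=[G1], predictors=[pred])
        ev, _ = evaluate_section2_loss(loss("chr1", 90_000, 160_000), regs, table, OPTS)
        assert ev == []

    def test_wrong_type_rejected(self, table):
        regs = mini_registries()
        with pytest.raises(ValueError):
            evaluate_section2_loss(gain("chr1", 1_000, 2_000), regs, table, OPTS)


class TestSection2Gain:
    def ts_record(self, score=3):
        return DosageRecord(G1.span, TargetKind.GENE, None, score, G1.symbol)

    def test_complete_ts_overlap_is_2a(self, table):
        regs = mini_registries(genes=[G1], dosage=[self.ts_record()])
        ev, unevaluated = evaluate_section2_gain(gain("chr1", 90_000, 160_000), regs, table, OPTS)
        ids = [e.option_id for e in ev]
        assert "2A" in ids
        assert set(unevaluated) == {"2I", "2J", "2K"}

    def test_identical_gene_content_scores_benign_identity(self, table):
        rec = BenignCNVRecord(
            GenomicInterval("chr1", 95_000, 155_000), CNVType.GAIN, 0.02,
            CoordinateFlavor.PLAIN, BenignSource.DGV, "b1",
        )
        regs = mini_registries(genes=[G1], benign=[rec])
        ev, _ = evaluate_section2_gain(gain("chr1", 95_000, 155_000), regs, table, OPTS)
        by_id = {e.option_id: e for e in ev}
        assert "2C" in by_id
        assert by_id["2C"].points == table.points("2C", CNVType.GAIN) < 0

    def test_contained_gain_without_gene_breakpoints_is_2d(self, table):
        # the record carries an extra gene the CNV misses, so the contents
        # differ and the smaller-than-benign comparison applies
        rec = BenignCNVRecord(
            GenomicInterval("chr1", 300_000, 500_000), CNVType.GAIN, 0.02,
            CoordinateFlavor.PLAIN, BenignSource.DGV, "b1",
        )
        inner_gene = gene("g3", "chr1", 350_000, 360_000)
        edge_gene = gene("g4", "chr1", 450_000, 460_000)
        regs = mini_registries(genes=[inner_gene, edge_gene], benign=[rec])
        ev, _ = evaluate_section2_gain(gain("chr1", 340_000, 380_000), regs, table, OPTS)
        assert "2D" in [e.option_id for e in ev]

    def test_breakpoint_inside_gene_adds_2e_and_2l(self, table):
        rec = BenignCNVRecord(
            GenomicInterval("chr1", 300_000, 500_000), CNVType.GAIN, 0.02,
            CoordinateFlavor.PLAIN, BenignSource.DGV, "b1",
        )
        split_gene = gene("g3", "chr1", 350_000, 420_000)
        edge_gene = gene("g4", "chr1", 450_000, 460_000)
        regs = mini_registries(genes=[split_gene, edge_gene], benign=[rec])
        ev, _ = evaluate_section2_gain(gain("chr1", 340_000, 380_000), regs, table, OPTS)
        ids = [e.option_id for e in ev]
        assert "2E" in ids and "2L" in ids

    def test_identical_content_outranks_smaller_than_benign(self, table):
        # when the gain covers exactly the record's gene content, the
        # content-identity option wins over the size comparison
        rec = BenignCNVRecord(
            GenomicInterval("chr1", 300_000, 500_000), CNVType.GAIN, 0.02,
            CoordinateFlavor.PLAIN, BenignSource.DGV, "b1",
        )
        inner_gene = gene("g3", "chr1", 350_000, 360_000)
        regs = mini_registries(genes=[inner_gene], benign=[rec])
        ev, _ = evaluate_section2_gain(gain("chr1", 340_000, 380_000), regs, table, OPTS)
        assert "2C" in [e.option_id for e in ev]

    def test_contained_hi_gene_flags_2h(self, table):
        hi = DosageRecord(G1.span, TargetKind.GENE, 3, None, G1.symbol)
        regs = mini_registries(genes=[G1], dosage=[hi])
        ev, _ = evaluate_section2_gain(gain("chr1", 90_000, 160_000), regs, table, OPTS)
        assert "2H" in [e.option_id for e in ev]


class TestSections3And4:
    def test_gene_counting_bands(self, table):
        genes = [gene(f"g{i}", "chr1", 100_000 + i * 10_000, 105_000 + i * 10_000)
                 for i in range(60)]
        regs = mini_registries(genes=genes)
        desert = evaluate_section3(loss("chr1", 1, 50_000), regs.genes, table)
        assert desert.option_id == "3A"
        # exactly 25 genes: the loss 3B lower bound is inclusive
        at_bound = evaluate_section3(
            loss("chr1", 100_000, 100_000 + 24 * 10_000 + 5_000), regs.genes, table
        )
        assert at_bound.note.startswith("25 ")
        assert at_bound.option_id == "3B"
        many = evaluate_section3(loss("chr1", 100_000, 800_000), regs.genes, table)
        assert many.option_id == "3C"
        # gain bands are wider: 25 genes is still 3A for a gain
        gain_band = evaluate_section3(
            gain("chr1", 100_000, 100_000 + 24 * 10_000 + 5_000), regs.genes, table
        )
        assert gain_band.option_id == "3A"

    def test_common_population_variant_fires_4o(self, table):
        rec = PopulationVariantRecord(
            GenomicInterval("chr1", 100_000, 300_000), CNVType.LOSS, 0.05, "p1"
        )
        regs = mini_registries(population=[rec])
        ev = evaluate_section4o(loss("chr1", 150_000, 250_000), regs.population, table, OPTS)
        assert ev is not None and ev.option_id == "4O" and ev.points < 0

    def test_rare_or_uncontained_variant_gives_none(self, table):
        rec = PopulationVariantRecord(
            GenomicInterval("chr1", 100_000, 300_000), CNVType.LOSS, 0.001, "p1"
        )
        regs = mini_registries(population=[rec])
        assert evaluate_section4o(loss("chr1", 150_000, 250_000), regs.population, table, OPTS) is None
        common = PopulationVariantRecord(
            GenomicInterval("chr1", 100_000, 300_000), CNVType.LOSS, 0.05, "p2"
        )
        regs = mini_registries(population=[common])
        # overlapping but not contained
        assert evaluate_section4o(loss("chr1", 250_000, 400_000), regs.population, table, OPTS) is None


class TestScoreCnv:
    def test_gene_overlap_only_is_vus(self, table):
        regs = mini_registries(genes=[G1])
        res = score_cnv(loss("chr1", 120_000, 130_000), regs, table, OPTS)
        assert {e.option_id for e in res.evidence} == {"1A", "3A"}
        assert res.total_score == 0.0
        assert res.classification == "VUS"

    def test_established_hi_gene_loss_is_pathogenic(self, table):
        regs = mini_registries(
            genes=[G1], dosage=[DosageRecord(G1.span, TargetKind.GENE, 3, None, G1.symbol)]
        )
        res = score_cnv(loss("chr1", 90_000, 160_000), regs, table, OPTS)
        assert res.classification == "P"
        assert res.total_score >= 0.99

    def test_benign_containment_plus_common_variant_is_benign(self, table):
        span = GenomicInterval("chr1", 100_000, 300_000)
        regs = mini_registries(
            benign=[BenignCNVRecord(span, CNVType.LOSS, 0.02, CoordinateFlavor.OUTER,
                                    BenignSource.DGV_GOLD, "b1")],
            population=[PopulationVariantRecord(span, CNVType.LOSS, 0.05, "p1")],
        )
        res = score_cnv(loss("chr1", 150_000, 250_000), regs, table, OPTS)
        assert {"2F", "4O"} <= {e.option_id for e in res.evidence}
        assert res.classification == "B"

    def test_missing_registry_names_blocked_section(self, table):
        regs = mini_registries()
        regs.genes = None
        with pytest.raises(MissingRegistryError, match="Sections 1 and 3"):
            score_cnv(loss("chr1", 1_000, 2_000), regs, table, OPTS)
        regs2 = mini_registries()
        regs2.benign = None
        with pytest.raises(MissingRegistryError, match="Section 2"):
            score_cnv(loss("chr1", 1_000, 2_000), regs2, table, OPTS)

    def test_exactly_one_section1_and_section3_option(self, registries11, random_cnvs11, table):
        for cnv in random_cnvs11[:50]:
            res = score_cnv(cnv, registries11, table, OPTS)
            sections = [e.section for e in res.evidence]
            assert sections.count("S1") == 1
            assert sections.count("S3") == 1
            by_support = {}
            for e in res.evidence:
                if e.option_id in ("2A", "2B"):
                    for sym in e.supporting:
                        assert by_support.setdefault(sym, e.option_id) == e.option_id, (
                            "2A and 2B fired for the same dosage record"
                        )


class TestEngineAgainstOracle:
    def test_option_selection_equals_brute_force(
        self, bundle11, registries11, random_cnvs11, table
    ):
        """On 200 random CNVs, the engine's selected options and total score
        equal an exhaustive rule-by-rule linear-scan re-derivation."""
        for cnv in random_cnvs11:
            res = score_cnv(cnv, registries11, table, OPTS)
            expected = oracle_options(cnv, bundle11, table, OPTS)
            got = {e.option_id for e in res.evidence}
            assert got == expected, f"{cnv.id}: {sorted(got)} != {sorted(expected)}"
            assert res.total_score == pytest.approx(
                oracle_total(expected, cnv.cnv_type, table)
            )

    def test_planted_cnvs_equal_oracle_too(
        self, bundle11, registries11, planted_sets, table
    ):
        for planted in planted_sets.values():
            for p in planted:
                res = score_cnv(p.cnv, registries11, table, OPTS)
                expected = oracle_options(p.cnv, bundle11, table, OPTS)
                assert {e.option_id for e in res.evidence} == expected


class TestMonotonicity:
    def test_widening_dosage_scores_never_removes_evidence(
        self, registries11, random_cnvs11, table
    ):
        widened = replace(OPTS, dosage_min_scores=frozenset({1, 2, 3}))
        for cnv in random_cnvs11[:80]:
            narrow = score_cnv(cnv, registries11, table, OPTS)
            wide = score_cnv(cnv, registries11, table, widened)
            narrow_s2 = {e.option_id for e in narrow.evidence if e.section == "S2"}
            wide_s2 = {e.option_id for e in wide.evidence if e.section == "S2"}
            # established-target evidence only grows; 2H may be displaced by it
            assert narrow_s2 - {"2H"} <= wide_s2 | {"2H"}
            narrow_est = narrow_s2 & {"2A", "2B", "2C", "2D", "2E"}
            assert narrow_est <= wide_s2

    def test_raising_maf_threshold_never_moves_toward_benign(
        self, bundle11, random_cnvs11, table
    ):
        order = {c: i for i, c in enumerate(["B", "LB", "VUS", "LP", "P"])}
        regs_by_thr = []
        for thr in (0.0001, 0.005, 0.02, 0.10):
            opts = replace(OPTS, maf_threshold=thr)
            regs_by_thr.append((opts, make_registries(bundle11, opts)))
        for cnv in random_cnvs11[:60]:
            ranks = [
                order[score_cnv(cnv, regs, table, opts).classification]
                for opts, regs in regs_by_thr
            ]
            assert ranks == sorted(ranks), f"{cnv.id}: {ranks}"
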