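"""Independent brute-force oracles used by the test suite.

Everything here re-derives results from first principles with plain linear
scans and per-base arithmetic — no interval trees, no shared code paths
with the library's query or scoring machinery — so agreement between the
two routes is meaningful.
"""

from __future__ import annotations

from cnvscore.annotation_db import Biotype, TargetKind, BenignSource, CoordinateFlavor
from cnvscore.intervals import CNVType


def per_base_overlap(a, b) -> int:
    """Set-intersection overlap, base by base (small intervals only)."""
    if a.chrom != b.chrom:
        return 0
    return len(set(range(a.start, a.end)) & set(range(b.start, b.end)))


def ov(a, b) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def contains(outer, inner) -> bool:
    return outer.chrom == inner.chrom and outer.start <= inner.start and inner.end <= outer.end


def filter_benign(records, options):
    kept = []
    for r in records:
        if r.source is not options.benign_source:
            continue
        if r.coordinate_flavor is not options.benign_flavor:
            continue
        if options.benign_type_filter == "losses_only" and r.cnv_type is not CNVType.LOSS:
            continue
        if options.maf_threshold is not None and r.frequency < options.maf_threshold:
            continue
        kept.append(r)
    return kept


def _protein_coding_symbols(genes, interval):
    return {
        g.symbol
        for g in genes
        if g.biotype is Biotype.PROTEIN_CODING and ov(g.span, interval) > 0
    }


def _geometry_options(cnv_iv, gene, table):
    """Per-transcript breakpoint geometry of a partial gene overlap."""
    opts = []
    for tx in gene.transcripts:
        if ov(cnv_iv, tx.span) == 0:
            continue
        left = cnv_iv.chrom == tx.span.chrom and cnv_iv.start <= tx.span.start < cnv_iv.end
        right = cnv_iv.chrom == tx.span.chrom and cnv_iv.start <= tx.span.end - 1 < cnv_iv.end
        covers5 = left if tx.cds_start_side == "left" else right
        covers3 = right if tx.cds_start_side == "left" else left
        opts.append("2C" if covers5 else ("2D" if covers3 else "2E"))
    if not opts:
        return None
    pts = {o: table.points(o, CNVType.LOSS) for o in opts}
    return max(opts, key=lambda o: (abs(pts[o]), pts[o], o))


def oracle_options(cnv, bundle, table, options):
    """Exhaustive rule-by-rule re-derivation of the engine's selected
    options on a fixture bundle.  Returns the set of option ids."""
    iv = cnv.interval
    genes = bundle.genes
    by_symbol = {g.symbol: g for g in genes}
    selected: set[str] = set()

    # section 1
    s1_hit = bool(_protein_coding_symbols(genes, iv)) or any(
        ov(el.span, iv) > 0 for el in bundle.functional
    )
    selected.add("1A" if s1_hit else "1B")

    # section 2
    benign = filter_benign(bundle.benign, options)
    if cnv.cnv_type is CNVType.LOSS:
        dosage_opts = set()
        for rec in bundle.dosage:
            if rec.hi_score is None or rec.hi_score not in options.dosage_min_scores:
                continue
            if ov(rec.target, iv) == 0:
                continue
            if contains(iv, rec.target):
                dosage_opts.add("2A")
            elif rec.target_kind is TargetKind.REGION:
                dosage_opts.add("2B")
            else:
                gene = by_symbol.get(rec.symbol)
                geo = _geometry_options(iv, gene, table) if gene is not None else None
                dosage_opts.add(geo if geo else "2B")
        selected |= dosage_opts
        hits = [r for r in benign if ov(r.span, iv) > 0]
        if any(contains(r.span, iv) for r in hits):
            selected.add("2F")
        elif hits:
            cnv_genes = _protein_coding_symbols(genes, iv)
            for r in hits:
                if cnv_genes - _protein_coding_symbols(genes, r.span):
                    selected.add("2G")
                    break
        if not dosage_opts:
            by_pred = {p.symbol: p for p in bundle.predictors}
            for g in genes:
                if g.biotype is not Biotype.PROTEIN_CODING or not contains(iv, g.span):
                    continue
                p = by_pred.get(g.symbol)
                if p is not None and sum(p.predictor_calls) >= options.predictor_min_calls:
                    selected.add("2H")
                    break
    else:
        for rec in bundle.dosage:
            if rec.ts_score is None or rec.ts_score not in options.dosage_min_scores:
                continue
            if ov(rec.target, iv) == 0:
                continue
            selected.add("2A" if contains(iv, rec.target) else "2B")
        cnv_genes = _protein_coding_symbols(genes, iv)

        def bp_inside(span):
            return span.chrom == iv.chrom and (
                span.start < iv.start < span.end or span.start < iv.end < span.end
            )

        candidates = []
        for r in benign:
            if r.cnv_type is not CNVType.GAIN or ov(r.span, iv) == 0:
                continue
            rec_genes = _protein_coding_symbols(genes, r.span)
            if cnv_genes == rec_genes:
                opt = "2C"
            elif contains(r.span, iv):
                breaks = any(
                    bp_inside(g.span) for g in genes if ov(g.span, iv) > 0
                )
                opt = "2E" if breaks else "2D"
            elif cnv_genes - rec_genes:
                opt = "2G"
            elif contains(iv, r.span):
                opt = "2F"
            else:
                continue
            candidates.append(opt)
        if candidates:
            pts = {o: table.points(o, CNVType.GAIN) for o in candidates}
            selected.add(max(candidates, key=lambda o: (abs(pts[o]), pts[o], o)))
        for rec in bundle.dosage:
            if (
                rec.hi_score is not None
                and rec.hi_score in options.dosage_min_scores
                and rec.target_kind is TargetKind.GENE
                and contains(iv, rec.target)
            ):
                selected.add("2H")
                break
        if any(bp_inside(g.span) for g in genes if ov(g.span, iv) > 0):
            selected.add("2L")

    # section 3
    n_pc = len(_protein_coding_symbols(genes, iv))
    for opt, (lo, hi) in table.bands_for(cnv.cnv_type).items():
        if n_pc >= lo and (hi is None or n_pc <= hi):
            selected.add(opt)
            break

    # section 4O
    best = 0.0
    for rec in bundle.population:
        if rec.cnv_type is cnv.cnv_type and contains(rec.span, iv):
            best = max(best, rec.allele_frequency)
    if best >= options.common_af_threshold:
        selected.add("4O")

    return selected


def oracle_total(option_ids, cnv_type, table) -> float:
    return sum(table.points(o, cnv_type) for o in option_ids)
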