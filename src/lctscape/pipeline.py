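"""End-to-end orchestration of the LCT survey on a simulated study.

Stages run in order: reference construction, chimera finding, annotation,
long-read TSS mapping, differential expression, methylation/CNV, chromatin.
Every stage writes a TSV alongside a JSON summary; the chimera stage summary
carries the filter accounting (candidates = retained + per-reason
rejections).  A fixed seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotation, chimera, epigenomics, expression, longread, reference
from . import simulate as sim

logger = logging.getLogger(__name__)

ALL_STAGES = ("reference", "chimeras", "annotate", "tss", "diffexpr",
              "methylation", "chromatin", "report")


@dataclass
class RunConfig:
    outdir: Path
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    stages: tuple[str, ...] = ALL_STAGES
    min_l1: int = chimera.MIN_L1_MATCH
    max_mm: int = chimera.MAX_MISMATCHES
    min_unique: int = chimera.MIN_UNIQUE
    max_insert: int = chimera.MAX_INSERT
    merge_gap: int = chimera.MERGE_GAP
    g_cutoff: float = expression.DEFAULT_CUTOFF
    min_mapq: int = longread.MIN_MAPQ

    def __post_init__(self) -> None:
        for name in ("min_l1", "min_unique", "max_insert", "merge_gap", "min_mapq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.outdir = Path(self.outdir)

    def thresholds(self) -> dict:
        return {k: getattr(self, k) for k in (
            "min_l1", "max_mm", "min_unique", "max_insert", "merge_gap",
            "g_cutoff", "min_mapq")}


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and return the report bundle (a dict of
    per-stage summaries; tables land in ``config.outdir``)."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"seed": config.sim.seed, "thresholds": config.thresholds()}

    truth = sim.simulate_genome(config.sim)
    sim.write_genome_fasta(truth, out / "genome.fa")
    sim.write_rmsk(truth, out / "rmsk.tsv")
    sim.write_gtf(truth, out / "genes.gtf")
    sim.write_truth_table(truth, out / "truth.tsv")

    elements = {e.id: e for e in truth.elements}
    refs: dict[str, str] = {}
    if "reference" in config.stages:
        records = reference.parse_rmsk(out / "rmsk.tsv")
        asp = reference.select_asp_l1(records)
        reference.write_element_table(truth.elements, out / "elements.tsv")
        # the finder reference carries every recent element's 5' 500 bp, ASP
        # or not, so the 5'-UTR filter is exercised downstream
        for e in truth.elements:
            refs[e.id], _ = reference.extract_5p_sequence(truth.genome, e)
        reference.write_reference_fasta(truth.genome, truth.elements,
                                        out / "l1_5p_reference.fa")
        bundle["reference"] = {
            "n_rmsk_rows": len(records),
            "n_recent_elements": len(truth.elements),
            "n_asp_elements": len(asp),
            "subfamily_counts": reference.subfamily_counts(truth.elements).to_dict(),
        }
        _write_json(bundle["reference"], out / "reference_summary.json")

    result = None
    if "chimeras" in config.stages:
        pairs = sim.simulate_reads(truth)
        for s, _ in config.sim.samples():
            sel = [p for p in pairs if p.sample == s]
            sim.write_fastq(sel, out / f"{s}_R1.fastq", out / f"{s}_R2.fastq")
        sim.write_mate_alignments(pairs, out / "mate_alignments.tsv")
        sim.write_fragment_bed(pairs, out / "fragments.bed")
        repeats = chimera.RepeatAnnotation.from_rmsk_rows(truth.rmsk_rows)
        result = chimera.find_chimeras(
            pairs, refs, elements, repeats,
            min_len=config.min_l1, max_mm=config.max_mm,
            min_unique=config.min_unique, max_insert=config.max_insert,
            merge_gap=config.merge_gap)
        chimera.loci_to_frame(result.pooled).to_csv(
            out / "lct_loci.tsv", sep="\t", index=False)
        sat = chimera.saturation_curve(result.per_sample_loci, n_perm=10,
                                       seed=config.sim.seed)
        sat.to_csv(out / "saturation.tsv", sep="\t", index=False)
        bundle["chimeras"] = {
            **result.accounting(),
            "n_loci_pooled": len(result.pooled),
            "n_elements_with_lct": len({l.element.id for l in result.pooled}),
        }
        _write_json(bundle["chimeras"], out / "chimera_summary.json")

    if "annotate" in config.stages and result is not None:
        junctions = [(l.chrom, min(l.unique_interval[1], l.exons[0][0]),
                      l.exons[0][0]) for l in truth.lcts if l.spliced]
        genes = pd.DataFrame([{
            "gene_id": g.id, "chrom": g.chrom, "start": g.start,
            "end": g.end, "strand": g.strand} for g in truth.genes])
        for locus in result.pooled:
            locus.splice_status = annotation.splice_status(locus, junctions).status
        ctx, ctx_summary = annotation.genic_context(result.pooled, genes)
        ctx.to_csv(out / "genic_context.tsv", sep="\t", index=False)
        n_all = len(truth.elements)
        n_intra_all = sum(
            1 for e in truth.elements if any(
                g.start < e.end and e.start < g.end for g in truth.genes))
        enrich_p = annotation.binomial_enrichment(
            ctx_summary["n_intragenic"], ctx_summary["n_loci"],
            n_intra_all / n_all) if ctx_summary["n_loci"] else float("nan")
        splice_counts = pd.Series(
            [l.splice_status for l in result.pooled]).value_counts().to_dict()
        bundle["annotate"] = {
            **{k: v for k, v in ctx_summary.items()},
            "splice_status_counts": splice_counts,
            "intragenic_enrichment_p": enrich_p,
            "background_intragenic_fraction": n_intra_all / n_all,
        }
        _write_json(bundle["annotate"], out / "annotation_summary.json")
        chimera.loci_to_frame(result.pooled).to_csv(
            out / "lct_loci.tsv", sep="\t", index=False)

    if "tss" in config.stages and result is not None:
        aln, lr_truth = sim.simulate_longreads(truth)
        aln.to_csv(out / "longread_alignments.tsv", sep="\t", index=False)
        lr_truth.to_csv(out / "longread_truth.tsv", sep="\t", index=False)
        lct_elements = sorted({l.element.id for l in result.pooled})
        filtered = longread.filter_chimeric_longreads(
            aln, [elements[i] for i in lct_elements], min_mapq=config.min_mapq)
        profiles = longread.build_profiles(filtered,
                                           [elements[i] for i in lct_elements])
        summary, mat = longread.tss_summary(profiles)
        mat.to_csv(out / "tss_heatmap.tsv", sep="\t")
        bundle["tss"] = summary
        _write_json(summary, out / "tss_summary.json")

    if "diffexpr" in config.stages and result is not None:
        groups = dict(config.sim.samples())
        counts = pd.DataFrame(
            {s: {l.id: l.reads_per_sample.get(s, 0) for l in result.pooled}
             for s in groups}).fillna(0)
        counts.to_csv(out / "counts.tsv", sep="\t")
        hed = expression.hedges_table(counts, groups, cutoff=config.g_cutoff)
        hed.to_csv(out / "deregulation.tsv", sep="\t", index=False)
        ct_df, eff = sim.simulate_qpcr(truth)
        ct_table = expression.CtTable(ct_df, eff)
        expr = expression.expression_matrix(ct_table)
        expr.to_csv(out / "relative_expression.tsv", sep="\t", index=False)
        mw = expression.mw_holm(expr.rename(columns={"R": "value"}))
        mw.to_csv(out / "mw_holm.tsv", sep="\t", index=False)
        bundle["diffexpr"] = {
            "n_loci": len(hed),
            "calls": hed["call"].value_counts().to_dict(),
            "n_significant_qpcr": int((mw["p_holm"] < 0.05).sum()),
        }
        _write_json(bundle["diffexpr"], out / "diffexpr_summary.json")
        bundle["_expression"] = expr

    if "methylation" in config.stages:
        qamp = sim.simulate_qamp(truth)
        qamp.to_csv(out / "qamp_ct.tsv", sep="\t", index=False)
        idx = epigenomics.qamp_table(qamp)
        idx.to_csv(out / "methylation_index.tsv", sep="\t", index=False)
        cnv = sim.simulate_cnv(truth)
        cnv.to_csv(out / "cnv.tsv", sep="\t", index=False)
        summary = {"n_assays": len(idx),
                   "mean_index": float(idx["index"].mean()) if len(idx) else None}
        expr = bundle.get("_expression")
        if expr is not None and len(expr):
            meth_corr = epigenomics.methylation_expression_correlation(
                idx, expr.rename(columns={"locus": "locus"}))
            meth_corr.to_csv(out / "methylation_correlation.tsv", sep="\t",
                             index=False)
            cnv_corr = epigenomics.cnv_expression_correlation(cnv, expr)
            cnv_corr.to_csv(out / "cnv_correlation.tsv", sep="\t", index=False)
            summary["n_meth_corr"] = int((~meth_corr["skipped"]).sum())
            summary["n_cnv_corr"] = int((~cnv_corr["skipped"]).sum())
        bundle["methylation"] = summary
        _write_json(summary, out / "methylation_summary.json")

    if "chromatin" in config.stages:
        cov = sim.simulate_coverage(truth)
        sim.write_bedgraph(cov, out / "h3k36me3.bedgraph")
        track = epigenomics.CoverageTrack(
            cov, {config.sim.chrom: len(truth.genome[config.sim.chrom])})
        pos_ids = {l.element_id for l in truth.lcts}
        pos = [e for e in truth.elements if e.id in pos_ids]
        neg = [e for e in truth.elements if e.id not in pos_ids]
        if pos and neg:
            contrast = epigenomics.profile_contrast(track, pos, neg)
            contrast.to_csv(out / "chromatin_profile.tsv", sep="\t", index=False)
            body = contrast[(contrast["bin_start"] >= 0)
                            & (contrast["bin_start"] < 1000)]
            bundle["chromatin"] = {
                "mean_body_lct_pos": float(body["lct_pos"].mean()),
                "mean_body_lct_neg": float(body["lct_neg"].mean()),
            }
            _write_json(bundle["chromatin"], out / "chromatin_summary.json")

    bundle.pop("_expression", None)
    if "report" in config.stages:
        (out / "report.md").write_text(make_report(bundle))
    _write_json(bundle, out / "run_summary.json")
    return bundle


def make_report(bundle: dict) -> str:
    """Human-readable markdown summary of a pipeline run."""
    lines = ["# LCT survey report", ""]
    lines.append(f"Seed: {bundle.get('seed')}")
    lines.append(f"Thresholds: {bundle.get('thresholds')}")
    ref = bundle.get("reference")
    if ref:
        lines += ["", "## Reference", "",
                  f"- recent L1 elements: {ref['n_recent_elements']}",
                  f"- ASP-competent: {ref['n_asp_elements']}",
                  "", "| subfamily | n |", "|---|---|"]
        lines += [f"| {k} | {v} |" for k, v in sorted(ref["subfamily_counts"].items())]
    chim = bundle.get("chimeras")
    if chim:
        lines += ["", "## Chimera detection", "",
                  f"- candidate pairs: {chim['candidates']}"]
        lines += [f"- {k.replace('_', ' ')}: {v}" for k, v in chim.items()
                  if k.startswith("rejected_")]
        lines += [f"- retained: {chim['retained']}",
                  f"- pooled LCT loci: {chim['n_loci_pooled']}",
                  f"- elements with an LCT: {chim['n_elements_with_lct']}"]
    ann = bundle.get("annotate")
    if ann:
        lines += ["", "## Annotation", "",
                  f"- intragenic: {ann['n_intragenic']}/{ann['n_loci']}"
                  f" ({100 * ann['fraction_intragenic']:.1f}%)"
                  if ann["n_loci"] else "- no loci",
                  f"- splice status: {ann['splice_status_counts']}",
                  f"- intragenic enrichment p (binomial): "
                  f"{ann['intragenic_enrichment_p']:.3g}"]
    tss = bundle.get("tss")
    if tss:
        lines += ["", "## Long-read TSS", "",
                  f"- detected elements: {tss['n_detected']}/{tss['n_elements']}",
                  f"- fraction with TSS in 0-500: {tss['fraction_tss_0_500']:.2%}",
                  f"- fraction with TSS in 0-900: {tss['fraction_tss_0_900']:.2%}"]
    de = bundle.get("diffexpr")
    if de:
        lines += ["", "## Deregulation prediction", "",
                  f"- calls: {de['calls']}",
                  f"- qPCR-significant loci (Holm < 0.05): "
                  f"{de['n_significant_qpcr']}"]
    meth = bundle.get("methylation")
    if meth:
        lines += ["", "## Methylation", "",
                  f"- assays: {meth['n_assays']}, mean index: "
                  f"{meth['mean_index']}"]
    chrom = bundle.get("chromatin")
    if chrom:
        lines += ["", "## Chromatin", "",
                  f"- mean body signal LCT+: {chrom['mean_body_lct_pos']:.3f}, "
                  f"LCT-: {chrom['mean_body_lct_neg']:.3f}"]
    return "\n".join(lines) + "\n"
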