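"""Classification of LCT loci: 5' splice status, genic context, TSS region
from walking-PCR amplification patterns, and polyadenylation status.

The splice call combines three sufficient rules — a large strand-aware gap
between the L1 side and the unique sequence (>500 bp), a large locus
(>1000 bp) whose unique part is very large (>700 bp, the signature of
concatenated spliced reads), or a splice junction within +/-200 bp of the L1
element start.  A distance of 200-499 bp with a size of 600-999 bp is called
undetermined; everything else is unspliced.  Precedence is
spliced > undetermined > unspliced, any single rule being sufficient.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .chimera import ChimeraLocus

SPLICE_DISTANCE_MIN = 500  # r1r2 distance strictly above -> spliced
SPLICE_SIZE_MIN = 1000  # total size strictly above, with ...
SPLICE_UNIQUE_MIN = 700  # ... unique length strictly above -> spliced
JUNCTION_WINDOW = 200  # bp around the element 5' start


@dataclass(frozen=True)
class SpliceCall:
    status: str  # spliced | unspliced | undetermined
    triggered_rules: frozenset[str]
    flagged: bool = False  # distance 1-199 with size 600-999: rules silent


def splice_status(
    locus: ChimeraLocus,
    junctions: Sequence[tuple[str, int, int]] | pd.DataFrame | None = None,
) -> SpliceCall:
    """Classify the 5' splice status of one locus.

    ``junctions`` are splice-junction intervals (chrom, start, end); a
    junction end lying within +/-200 bp of the L1 element start triggers the
    junction rule.
    """
    d = locus.r1r2_distance
    size = locus.total_size
    ulen = locus.unique_length
    rules = set()
    if d > SPLICE_DISTANCE_MIN:
        rules.add("distance")
    if size > SPLICE_SIZE_MIN and ulen > SPLICE_UNIQUE_MIN:
        rules.add("size")
    if junctions is not None and _junction_near_start(locus, junctions):
        rules.add("junction")
    if rules:
        return SpliceCall("spliced", frozenset(rules))
    if 200 <= d <= 499 and 600 <= size <= 999:
        return SpliceCall("undetermined", frozenset())
    flagged = 1 <= d <= 199 and 600 <= size <= 999
    return SpliceCall("unspliced", frozenset(), flagged=flagged)


def _junction_near_start(locus: ChimeraLocus, junctions) -> bool:
    start = locus.element.five_prime_boundary()
    if isinstance(junctions, pd.DataFrame):
        rows = junctions[["chrom", "start", "end"]].itertuples(index=False)
    else:
        rows = junctions
    for chrom, jstart, jend in rows:
        if chrom != locus.element.chrom:
            continue
        for pos in (int(jstart), int(jend)):
            if abs(pos - start) <= JUNCTION_WINDOW:
                return True
    return False


# ---------------------------------------------------------------------------
# Genic context


def genic_context(
    loci: Sequence[ChimeraLocus], genes: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Annotate loci against gene bodies and summarise.

    ``genes`` needs columns chrom, start, end, strand, gene_id.  A locus is
    intragenic when its L1 element overlaps a gene body; orientation compares
    the LCT transcript strand with each host gene's strand.  Returns the
    per-locus annotation (one row per locus-gene pair, intergenic loci one
    row with empty gene) and a summary dict with the intragenic fraction,
    antisense fraction among intragenic, and the genes-per-LCT histogram.
    """
    bad = ~genes["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"strandless gene rows: {genes[bad].to_dict('records')}")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for row in genes.itertuples(index=False):
        trees[row.chrom].addi(int(row.start), int(row.end), (row.gene_id, row.strand))
    rows = []
    lct_per_gene: dict[str, int] = defaultdict(int)
    n_intragenic = n_antisense = 0
    for l in loci:
        hits = sorted(trees[l.element.chrom].overlap(l.element.start, l.element.end),
                      key=lambda iv: iv.data[0]) if l.element.chrom in trees else []
        if not hits:
            rows.append({"locus": l.id, "gene_id": "", "context": "intergenic"})
            l.genic_context = "intergenic"
            continue
        n_intragenic += 1
        antisense_any = False
        for iv in hits:
            gid, gstrand = iv.data
            orient = "sense" if gstrand == l.transcript_strand else "antisense"
            antisense_any |= orient == "antisense"
            lct_per_gene[gid] += 1
            rows.append({"locus": l.id, "gene_id": gid,
                         "context": f"intragenic_{orient}"})
        l.genic_context = "intragenic_antisense" if antisense_any else "intragenic_sense"
        n_antisense += antisense_any
    hist: dict[int, int] = defaultdict(int)
    for gid, k in lct_per_gene.items():
        hist[k] += 1
    n = len(loci)
    summary = {
        "n_loci": n,
        "n_intragenic": n_intragenic,
        "fraction_intragenic": n_intragenic / n if n else float("nan"),
        "fraction_antisense_of_intragenic": (
            n_antisense / n_intragenic if n_intragenic else float("nan")),
        "genes_per_lct_histogram": dict(sorted(hist.items())),
    }
    return pd.DataFrame(rows), summary


def binomial_enrichment(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p-value (sum of outcomes no more likely
    than the observed one)."""
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0={p0} outside (0, 1)")
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# Walking-PCR TSS-region classifier


@dataclass(frozen=True)
class AmpPattern:
    """Amplification outcome of one chimera in one RT-PCR assay.

    ``amplified`` maps primer/condition names to booleans: for walking mode
    {"common", "downstream", "upstream"}, for polyA mode {"random_hexamer",
    "oligodT", "polyU_oligodA"}.
    """

    chimera_id: str
    subfamily: str
    amplified: Mapping[str, bool]


def walking_classify(pattern: AmpPattern) -> str:
    """TSS-region call from the three walking primers.

    The "common" primer sits 5'-most in the L1 antisense 5' UTR, the
    "downstream"/"upstream" primers flank the +450 ASP position.  Returns
    ASP450, ASP200, NO_LCT or UNDETERMINED (no common amplification, or an
    inconsistent upstream-only pattern).
    """
    a = pattern.amplified
    common, down, up = bool(a.get("common")), bool(a.get("downstream")), bool(
        a.get("upstream"))
    if not common:
        return "UNDETERMINED"
    if down and up:
        return "NO_LCT"
    if down:
        return "ASP450"
    if up:  # upstream without downstream amplification is not interpretable
        return "UNDETERMINED"
    return "ASP200"


def is_lct(call: str) -> bool:
    return call in ("ASP450", "ASP200")


def walking_summary(patterns: Sequence[AmpPattern]) -> dict:
    """Per-call counts plus the LCT fraction among non-L1PA8 chimeras."""
    calls = {p.chimera_id: walking_classify(p) for p in patterns}
    counts: dict[str, int] = defaultdict(int)
    for c in calls.values():
        counts[c] += 1
    non_pa8 = [p for p in patterns if p.subfamily != "L1PA8"]
    n_lct = sum(is_lct(calls[p.chimera_id]) for p in non_pa8)
    return {
        "calls": calls,
        "counts": dict(counts),
        "n_tested": len(patterns),
        "n_non_l1pa8": len(non_pa8),
        "n_lct_non_l1pa8": n_lct,
        "pct_lct_non_l1pa8": 100.0 * n_lct / len(non_pa8) if non_pa8 else float("nan"),
    }


# ---------------------------------------------------------------------------
# polyA classifier


def polya_classify(patterns: Iterable[AmpPattern]) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Per-LCT polyadenylation status plus (min, max) non-polyA bounds.

    Evaluable patterns amplify with random hexamers; oligodT amplification
    means polyA, absence of oligodT with amplification after polyU tailing
    (oligodA RT) means non-polyA, absence of both leaves the status
    undetermined.  ``min_nonpolya`` counts confirmed non-polyA LCTs,
    ``max_nonpolya`` counts all oligodT-negative ones.
    """
    rows = []
    for p in patterns:
        a = p.amplified
        if not a.get("random_hexamer"):
            rows.append({"chimera_id": p.chimera_id, "status": "not_evaluable"})
            continue
        if a.get("oligodT"):
            status = "polyA"
        elif a.get("polyU_oligodA"):
            status = "non_polyA"
        else:
            status = "undetermined"
        rows.append({"chimera_id": p.chimera_id, "status": status})
    df = pd.DataFrame(rows)
    evaluable = df[df["status"] != "not_evaluable"]
    min_np = int((evaluable["status"] == "non_polyA").sum())
    max_np = int((evaluable["status"] != "polyA").sum())
    return df, (min_np, max_np)
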