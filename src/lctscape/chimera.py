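"""Detection of L1-chimeric read pairs and clustering into LCT loci.

A chimeric pair has one read matching the 5'-most 500 bp of a recent L1
element (gapless, >=50 bp, <=1 substitution — the mismatch budget absorbs
SNPs) while its mate aligns to unique (non-repeat-annotated) genomic
sequence of >=30 bp within 50 kb.  Pairs transcribed antisense to an
ASP-bearing element are kept and merged per element and transcript strand
into :class:`ChimeraLocus` records; rejected pairs carry a reason
(``same_orientation`` / ``no_5utr`` / ``insert_too_large``) so the filter
accounting is conservative (candidates = retained + sum of rejections).

Matching uses an exact k-mer seed (k = min_len // (max_mm + 1), complete by
pigeonhole for gapless matches) followed by a per-diagonal longest-run
extension; a brute-force diagonal scan takes over when the seed would be
shorter than 6 bp.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .reference import L1Element
from .simulate import revcomp

MIN_L1_MATCH = 50
MAX_MISMATCHES = 1
MIN_UNIQUE = 30
MAX_INSERT = 50_000
MERGE_GAP = 300


@dataclass(frozen=True)
class L1Match:
    element_id: str
    match_length: int
    mismatches: int
    orientation: str  # read vs element: "sense" | "antisense"
    offset_in_element: int  # element-sense bp offset of the matched window


@dataclass
class Candidate:
    sample: str
    read_id: str
    element: L1Element
    match: L1Match
    l1_interval: tuple[int, int]  # genomic span of the L1-side match
    unique_chrom: str
    unique_interval: tuple[int, int]
    transcript_strand: str


@dataclass
class ChimeraLocus:
    """A merged LCT locus: one element plus a concatenated unique interval."""

    id: str
    element: L1Element
    transcript_strand: str
    unique_chrom: str
    unique_start: int
    unique_end: int
    l1_start: int
    l1_end: int
    reads_per_sample: dict[str, int] = field(default_factory=dict)
    splice_status: str | None = None
    genic_context: str | None = None
    polya_status: str | None = None

    @property
    def n_reads(self) -> int:
        return sum(self.reads_per_sample.values())

    @property
    def unique_length(self) -> int:
        return self.unique_end - self.unique_start

    @property
    def total_size(self) -> int:
        """Outermost genomic span covered by the locus."""
        return max(self.unique_end, self.l1_end) - min(self.unique_start, self.l1_start)

    @property
    def r1r2_distance(self) -> int:
        """Gap between the L1-side alignment end and the unique-sequence
        start, measured along transcription; <= 0 means overlap or
        juxtaposition."""
        if self.transcript_strand == "-":  # + element, transcription leftward
            return self.l1_start - self.unique_end
        return self.unique_start - self.l1_end


# ---------------------------------------------------------------------------
# Reference index and read matching


class L1ReferenceIndex:
    """Exact k-mer seed index over the element 5'-end reference sequences."""

    def __init__(self, references: Mapping[str, str],
                 min_len: int = MIN_L1_MATCH, max_mm: int = MAX_MISMATCHES):
        if not references:
            raise ValueError("empty L1 reference set")
        self.min_len = min_len
        self.max_mm = max_mm
        self.ids = sorted(references)
        self.seqs = [references[i].upper() for i in self.ids]
        self.k = min_len // (max_mm + 1)
        self._seeds: dict[str, list[tuple[int, int]]] | None = None
        if self.k >= 6:
            seeds: dict[str, list[tuple[int, int]]] = defaultdict(list)
            for ri, seq in enumerate(self.seqs):
                for p in range(len(seq) - self.k + 1):
                    seeds[seq[p : p + self.k]].append((ri, p))
            self._seeds = dict(seeds)

    def _diagonals(self, query: str) -> Iterable[tuple[int, int]]:
        if self._seeds is None:  # exhaustive: every diagonal of every ref
            for ri, seq in enumerate(self.seqs):
                for d in range(-len(query) + 1, len(seq)):
                    yield ri, d
            return
        seen = set()
        for q in range(len(query) - self.k + 1):
            for ri, p in self._seeds.get(query[q : q + self.k], ()):
                key = (ri, p - q)
                if key not in seen:
                    seen.add(key)
                    yield key

    def _extend(self, query: str, ri: int, diag: int):
        """Longest window with <= max_mm mismatches on one diagonal.

        Returns (length, mismatches, ref_start) or None.
        """
        ref = self.seqs[ri]
        qs = max(0, -diag)
        qe = min(len(query), len(ref) - diag)
        if qe - qs < self.min_len:
            return None
        mm = [i for i in range(qs, qe) if query[i] != ref[i + diag]]
        best = None  # (length, n_mm, q_start)
        # windows bounded by max_mm+1 consecutive mismatch positions
        bounds = [qs - 1] + mm + [qe]
        for i in range(len(bounds) - 1):
            j = min(i + self.max_mm + 1, len(bounds) - 1)
            lo, hi = bounds[i] + 1, bounds[j] - 1 if j < len(bounds) - 1 else qe - 1
            length = hi - lo + 1
            n_mm = j - i - 1
            # trailing/leading mismatches inside the window are not useful;
            # this enumeration already excludes them
            cand = (length, n_mm, lo)
            if length >= self.min_len and (
                best is None or (-length, n_mm) < (-best[0], best[1])
            ):
                best = cand
        if best is None:
            return None
        return best[0], best[1], best[2] + diag


#: a best hit is treated as ambiguous (and the read discarded) when a hit on
#: a different element is within this many bases of it with no more
#: mismatches — the paralog-uniqueness analogue of a MapQ filter
AMBIGUITY_MARGIN = 5


def match_read_to_l1(
    read: str, index: L1ReferenceIndex, margin: int = AMBIGUITY_MARGIN
) -> L1Match | None:
    """Best gapless match of ``read`` against the reference set, both strands.

    Ties broken by (longest, fewest mismatches, lowest element id, sense
    before antisense).  Returns None when no window of ``min_len`` with at
    most ``max_mm`` substitutions exists, or when the best hit is ambiguous:
    a hit on another element whose length is within ``margin`` bases and
    whose mismatch count is no larger means the read cannot be assigned to a
    single L1 copy (young-subfamily paralogy) and is dropped, as a read-level
    mapping-uniqueness filter would do.
    """
    read = read.upper()
    per_element: dict[str, tuple] = {}
    for orientation, query in (("sense", read), ("antisense", revcomp(read))):
        for ri, diag in index._diagonals(query):
            hit = index._extend(query, ri, diag)
            if hit is None:
                continue
            length, n_mm, ref_start = hit
            eid = index.ids[ri]
            key = (-length, n_mm, eid, orientation == "antisense")
            if eid not in per_element or key < per_element[eid][0]:
                per_element[eid] = (key, L1Match(eid, length, n_mm,
                                                 orientation, ref_start))
    if not per_element:
        return None
    ranked = sorted(per_element.values(), key=lambda kv: kv[0])
    best = ranked[0][1]
    if len(ranked) > 1:
        second = ranked[1][1]
        if (best.match_length - second.match_length < margin
                and second.mismatches <= best.mismatches):
            return None
    return best


# ---------------------------------------------------------------------------
# Unique-segment search


class RepeatAnnotation:
    """Interval set of all repeat-annotated genomic spans."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for chrom, start, end in intervals:
            if end > start:
                self._trees[chrom].addi(start, end)

    @classmethod
    def from_rmsk_rows(cls, rows: Iterable[Sequence]) -> "RepeatAnnotation":
        return cls((r[0], int(r[1]), int(r[2])) for r in rows)

    def repeat_spans(self, chrom: str, start: int, end: int) -> list[tuple[int, int]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        spans = sorted((max(iv.begin, start), min(iv.end, end))
                       for iv in tree.overlap(start, end))
        merged: list[list[int]] = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]


def find_unique_segment(
    mate_interval: tuple[str, int, int],
    repeats: RepeatAnnotation,
    min_unique: int = MIN_UNIQUE,
) -> tuple[int, int] | None:
    """Longest repeat-free sub-interval of the mate alignment, if >= min_unique."""
    chrom, start, end = mate_interval
    if end <= start:
        return None
    cursor = start
    best: tuple[int, int] | None = None
    for s, e in repeats.repeat_spans(chrom, start, end) + [(end, end)]:
        if s - cursor > 0 and (best is None or s - cursor > best[1] - best[0]):
            best = (cursor, s)
        cursor = max(cursor, e)
    if best is not None and best[1] - best[0] >= min_unique:
        return best
    return None


# ---------------------------------------------------------------------------
# Pair filtering


def pair_to_candidate(
    match: L1Match,
    unique: tuple[str, int, int],
    element: L1Element,
    *,
    sample: str = "sample",
    read_id: str = "",
    max_insert: int = MAX_INSERT,
    read1_is_sense: bool = True,
) -> tuple[Candidate | None, str | None]:
    """Apply the orientation / 5'-UTR / insert-size filters to one pair.

    Returns ``(candidate, None)`` when retained, else ``(None, reason)`` with
    reason in {"same_orientation", "no_5utr", "insert_too_large"}.  The
    genomic insert bound is inclusive at ``max_insert``.
    """
    if read1_is_sense:
        transcript_strand = element.strand if match.orientation == "sense" else (
            "-" if element.strand == "+" else "+")
    else:
        transcript_strand = element.strand if match.orientation == "antisense" else (
            "-" if element.strand == "+" else "+")
    if transcript_strand == element.strand:
        return None, "same_orientation"
    if not element.has_asp:
        return None, "no_5utr"
    uchrom, ustart, uend = unique
    a, b = match.offset_in_element, match.offset_in_element + match.match_length
    if element.strand == "+":
        l1_iv = (element.start + a, element.start + b)
    else:
        l1_iv = (element.end - b, element.end - a)
    if uchrom != element.chrom:
        return None, "insert_too_large"
    gap = max(ustart - l1_iv[1], l1_iv[0] - uend)
    if gap > max_insert:
        return None, "insert_too_large"
    return Candidate(sample, read_id, element, match, l1_iv,
                     uchrom, (ustart, uend), transcript_strand), None


# ---------------------------------------------------------------------------
# Clustering, pooling, saturation


def cluster_candidates(
    candidates: Sequence[Candidate], merge_gap: int = MERGE_GAP
) -> list[ChimeraLocus]:
    """Merge candidates per (element, transcript strand) into loci.

    Unique intervals overlapping or within ``merge_gap`` bp are merged into a
    union span; supporting reads accumulate per sample; the L1-side span is
    the union of member matches.
    """
    groups: dict[tuple[str, str], list[Candidate]] = defaultdict(list)
    for c in candidates:
        groups[(c.element.id, c.transcript_strand)].append(c)
    loci: list[ChimeraLocus] = []
    for (eid, strand), members in sorted(groups.items()):
        members.sort(key=lambda c: c.unique_interval)
        cluster: list[Candidate] = []
        idx = 0
        for c in members:
            if cluster and c.unique_interval[0] - max(
                m.unique_interval[1] for m in cluster
            ) > merge_gap:
                loci.append(_make_locus(f"{eid}|{strand}|{idx}", cluster, strand))
                idx += 1
                cluster = []
            cluster.append(c)
        if cluster:
            loci.append(_make_locus(f"{eid}|{strand}|{idx}", cluster, strand))
    return loci


def _make_locus(lid: str, members: Sequence[Candidate], strand: str) -> ChimeraLocus:
    elem = members[0].element
    return ChimeraLocus(
        id=lid, element=elem, transcript_strand=strand,
        unique_chrom=members[0].unique_chrom,
        unique_start=min(c.unique_interval[0] for c in members),
        unique_end=max(c.unique_interval[1] for c in members),
        l1_start=min(c.l1_interval[0] for c in members),
        l1_end=max(c.l1_interval[1] for c in members),
        reads_per_sample=dict(Counter(c.sample for c in members)),
    )


def pool_samples(
    per_sample_loci: Iterable[Sequence[ChimeraLocus]], merge_gap: int = MERGE_GAP
) -> list[ChimeraLocus]:
    """Union of loci across samples, re-merged per element and strand.

    Associative and commutative: pooling pools is the same as pooling all
    samples at once.
    """
    flat = [l for loci in per_sample_loci for l in loci]
    groups: dict[tuple[str, str], list[ChimeraLocus]] = defaultdict(list)
    elements = {}
    for l in flat:
        groups[(l.element.id, l.transcript_strand)].append(l)
        elements[l.element.id] = l.element
    pooled: list[ChimeraLocus] = []
    for (eid, strand), members in sorted(groups.items()):
        members.sort(key=lambda l: (l.unique_start, l.unique_end))
        cluster: list[ChimeraLocus] = []
        idx = 0

        def flush():
            nonlocal idx
            counts: Counter = Counter()
            for m in cluster:
                counts.update(m.reads_per_sample)
            pooled.append(ChimeraLocus(
                id=f"{eid}|{strand}|{idx}", element=elements[eid],
                transcript_strand=strand, unique_chrom=cluster[0].unique_chrom,
                unique_start=min(m.unique_start for m in cluster),
                unique_end=max(m.unique_end for m in cluster),
                l1_start=min(m.l1_start for m in cluster),
                l1_end=max(m.l1_end for m in cluster),
                reads_per_sample=dict(counts)))
            idx += 1

        for l in members:
            if cluster and l.unique_start - max(m.unique_end for m in cluster) > merge_gap:
                flush()
                cluster = []
            cluster.append(l)
        if cluster:
            flush()
    return pooled


def saturation_curve(
    per_sample_loci: Mapping[str, Sequence[ChimeraLocus]],
    n_perm: int = 20,
    seed: int = 0,
    merge_gap: int = MERGE_GAP,
) -> pd.DataFrame:
    """Mean pooled LCT count as a function of the number of samples pooled."""
    samples = sorted(per_sample_loci)
    if not samples:
        raise ValueError("no samples")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_perm):
        order = list(rng.permutation(samples))
        for k in range(1, len(samples) + 1):
            pooled = pool_samples([per_sample_loci[s] for s in order[:k]], merge_gap)
            rows.append((k, len(pooled)))
    df = pd.DataFrame(rows, columns=["n_samples", "n_loci"])
    return df.groupby("n_samples", as_index=False)["n_loci"].mean().rename(
        columns={"n_loci": "mean_lct_count"})


def compare_to_known_loci(
    loci: Sequence[ChimeraLocus], known: pd.DataFrame | Sequence[tuple[str, int, int]]
) -> tuple[int, list[str]]:
    """Count LCT-producing elements whose span intersects a known locus."""
    if isinstance(known, pd.DataFrame):
        rows = list(known[["chrom", "start", "end"]].itertuples(index=False))
    else:
        rows = list(known)
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for chrom, start, end in rows:
        start, end = int(start), int(end)
        if end <= start:
            raise ValueError(f"malformed known-locus interval {chrom}:{start}-{end}")
        trees[chrom].addi(start, end)
    matched = sorted({
        l.element.id for l in loci
        if l.element.chrom in trees
        and trees[l.element.chrom].overlap(l.element.start, l.element.end)
    })
    return len(matched), matched


def read_known_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError("known-locus BED needs at least 3 columns")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


# ---------------------------------------------------------------------------
# End-to-end driver


@dataclass
class FinderResult:
    per_sample_loci: dict[str, list[ChimeraLocus]]
    pooled: list[ChimeraLocus]
    rejections: Counter
    n_candidates: int

    def accounting(self) -> dict[str, int]:
        out = {"candidates": self.n_candidates}
        out.update({f"rejected_{k}": v for k, v in sorted(self.rejections.items())})
        out["retained"] = self.n_candidates - sum(self.rejections.values())
        return out


def find_chimeras(
    pairs,
    references: Mapping[str, str],
    elements: Mapping[str, L1Element],
    repeats: RepeatAnnotation,
    *,
    min_len: int = MIN_L1_MATCH,
    max_mm: int = MAX_MISMATCHES,
    min_unique: int = MIN_UNIQUE,
    max_insert: int = MAX_INSERT,
    merge_gap: int = MERGE_GAP,
    read1_is_sense: bool = True,
    margin: int = AMBIGUITY_MARGIN,
) -> FinderResult:
    """Run matching, unique-segment search, pair filters and clustering.

    ``pairs`` is an iterable with attributes (sample, read_id, r1,
    mate_chrom, mate_start, mate_end), e.g. :class:`lctscape.simulate.ReadPair`
    records or rows of a normalised alignment table.
    """
    index = L1ReferenceIndex(references, min_len=min_len, max_mm=max_mm)
    retained: dict[str, list[Candidate]] = defaultdict(list)
    rejections: Counter = Counter()
    n_candidates = 0
    for p in pairs:
        match = match_read_to_l1(p.r1, index, margin=margin)
        if match is None:
            continue
        unique = find_unique_segment(
            (p.mate_chrom, p.mate_start, p.mate_end), repeats, min_unique)
        if unique is None:
            continue
        n_candidates += 1
        cand, reason = pair_to_candidate(
            match, (p.mate_chrom, *unique), elements[match.element_id],
            sample=p.sample, read_id=p.read_id, max_insert=max_insert,
            read1_is_sense=read1_is_sense)
        if cand is None:
            rejections[reason] += 1
        else:
            retained[p.sample].append(cand)
    per_sample = {s: cluster_candidates(c, merge_gap) for s, c in sorted(retained.items())}
    pooled = pool_samples(per_sample.values(), merge_gap)
    return FinderResult(per_sample, pooled, rejections, n_candidates)


def loci_to_frame(loci: Sequence[ChimeraLocus]) -> pd.DataFrame:
    return pd.DataFrame([{
        "id": l.id, "element_id": l.element.id, "subfamily": l.element.subfamily,
        "chrom": l.element.chrom, "element_start": l.element.start,
        "element_end": l.element.end, "element_strand": l.element.strand,
        "transcript_strand": l.transcript_strand,
        "unique_start": l.unique_start, "unique_end": l.unique_end,
        "unique_length": l.unique_length, "r1r2_distance": l.r1r2_distance,
        "total_size": l.total_size, "n_reads": l.n_reads,
        "splice_status": l.splice_status, "genic_context": l.genic_context,
        "polya_status": l.polya_status,
    } for l in loci])
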