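"""Chimera finder: matching, unique segments, pair filters, clustering."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_element
from lctscape import chimera
from lctscape.chimera import (
    Candidate,
    L1Match,
    L1ReferenceIndex,
    RepeatAnnotation,
    cluster_candidates,
    compare_to_known_loci,
    find_unique_segment,
    match_read_to_l1,
    pair_to_candidate,
    pool_samples,
    saturation_curve,
)
from lctscape.simulate import revcomp


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


# ---------------------------------------------------------------------------
# Matching


def brute_force_match(read, references, min_len=50, max_mm=1):
    """Independent oracle: enumerate every window of every diagonal of every
    reference on both strands."""
    best = None
    for orientation, query in (("sense", read), ("antisense", revcomp(read))):
        for rid in sorted(references):
            ref = references[rid]
            for diag in range(-len(query) + 1, len(ref)):
                qs, qe = max(0, -diag), min(len(query), len(ref) - diag)
                for i in range(qs, qe):
                    mm = 0
                    for j in range(i, qe):
                        if query[j] != ref[j + diag]:
                            mm += 1
                            if mm > max_mm:
                                break
                        length = j - i + 1
                        if length >= min_len:
                            key = (-length, mm, rid, orientation == "antisense")
                            if best is None or key < best[0]:
                                best = (key, L1Match(rid, length, mm,
                                                     orientation, i + diag))
    return None if best is None else best[1]


@pytest.fixture(scope="module")
def refs():
    rng = np.random.default_rng(7)
    return {f"L1_{i:02d}": random_seq(rng, 500) for i in range(4)}


class TestMatchReadToL1:
    def test_exact_50bp_boundary(self, refs):
        rng = np.random.default_rng(1)
        index = L1ReferenceIndex(refs)
        window = refs["L1_01"][100:150]
        read = random_seq(rng, 30) + window + random_seq(rng, 20)
        m = match_read_to_l1(read, index)
        assert m is not None and m.element_id == "L1_01"
        assert m.match_length >= 50 and m.offset_in_element <= 100

        read49 = random_seq(rng, 30) + refs["L1_01"][100:149] + random_seq(rng, 21)
        # 49 bp cannot qualify unless flanking bases extend the run by chance
        oracle = brute_force_match(read49, refs)
        assert match_read_to_l1(read49, L1ReferenceIndex(refs)) == oracle

    def test_mismatch_budget(self):
        rng = np.random.default_rng(3)
        refs = {"L1_00": random_seq(rng, 500)}
        index = L1ReferenceIndex(refs)
        base = refs["L1_00"][200:260]

        def substituted(s, positions):
            s = list(s)
            for p in positions:
                s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
            return "".join(s)

        one = substituted(base, [30])
        two = substituted(base, [15, 45])
        assert match_read_to_l1(one, index) is not None
        # two substitutions split the 60-mer into runs below 50 bp
        assert match_read_to_l1(two, index) == brute_force_match(two, refs)
        assert brute_force_match(two, refs) is None

    def test_antisense_orientation_detected(self, refs):
        index = L1ReferenceIndex(refs)
        read = revcomp(refs["L1_02"][50:150])
        m = match_read_to_l1(read, index)
        assert m.orientation == "antisense"
        assert m.offset_in_element == 50

    def test_agrees_with_brute_force_oracle(self, refs):
        rng = np.random.default_rng(9)
        small = {k: v[:120] for k, v in list(refs.items())[:2]}
        index = L1ReferenceIndex(small)
        for _ in range(40):
            kind = rng.integers(0, 3)
            if kind == 0:
                read = random_seq(rng, 80)
            else:
                rid = rng.choice(sorted(small))
                start = int(rng.integers(0, 60))
                window = list(small[rid][start : start + 60])
                for p in rng.integers(0, 60, size=int(rng.integers(0, 3))):
                    window[p] = "ACGT"[int(rng.integers(0, 4))]
                read = "".join(window)
                if kind == 2:
                    read = revcomp(read)
            assert match_read_to_l1(read, index) == brute_force_match(read, small)

    def test_threshold_monotonicity(self, refs):
        """Lowering min_len or raising max_mm never loses a match."""
        rng = np.random.default_rng(11)
        reads = []
        for _ in range(30):
            rid = rng.choice(sorted(refs))
            s = int(rng.integers(0, 440))
            w = list(refs[rid][s : s + 55])
            for p in rng.integers(0, 55, size=int(rng.integers(0, 4))):
                w[p] = "ACGT"[int(rng.integers(0, 4))]
            reads.append("".join(w))
        strict = L1ReferenceIndex(refs, min_len=50, max_mm=1)
        shorter = L1ReferenceIndex(refs, min_len=40, max_mm=1)
        looser = L1ReferenceIndex(refs, min_len=50, max_mm=2)
        for read in reads:
            if match_read_to_l1(read, strict) is not None:
                assert match_read_to_l1(read, shorter) is not None
                assert match_read_to_l1(read, looser) is not None

    def test_empty_reference_error(self):
        with pytest.raises(ValueError, match="empty"):
            L1ReferenceIndex({})


# ---------------------------------------------------------------------------
# Unique segments


class TestFindUniqueSegment:
    def test_fully_unique_mate(self):
        repeats = RepeatAnnotation([("chr1", 5000, 6000)])
        assert find_unique_segment(("chr1", 100, 200), repeats) == (100, 200)

    def test_min_unique_boundary(self):
        repeats = RepeatAnnotation([("chr1", 0, 100)])
        assert find_unique_segment(("chr1", 70, 129), repeats) is None  # 29 bp
        assert find_unique_segment(("chr1", 70, 130), repeats) == (100, 130)

    def test_unaligned_or_empty(self):
        repeats = RepeatAnnotation([])
        assert find_unique_segment(("chr1", 100, 100), repeats) is None

    def test_agrees_with_per_base_oracle(self):
        rng = np.random.default_rng(21)
        spans = [("chr1", int(s), int(s) + int(rng.integers(20, 400)))
                 for s in rng.integers(0, 5000, size=15)]
        repeats = RepeatAnnotation(spans)
        for _ in range(50):
            start = int(rng.integers(0, 5200))
            end = start + int(rng.integers(10, 300))
            mask = np.zeros(end - start, dtype=bool)  # True = repeat
            for _, rs, re in spans:
                lo, hi = max(rs, start), min(re, end)
                if lo < hi:
                    mask[lo - start : hi - start] = True
            best, run, run_start = None, 0, 0
            for i, m in enumerate(list(mask) + [True]):
                if not m:
                    if run == 0:
                        run_start = i
                    run += 1
                else:
                    if run and (best is None or run > best[1] - best[0]):
                        best = (start + run_start, start + run_start + run)
                    run = 0
            expected = best if best and best[1] - best[0] >= 30 else None
            assert find_unique_segment(("chr1", start, end), repeats) == expected


# ---------------------------------------------------------------------------
# Pair filters


def antisense_match(eid="L1_X", length=80, offset=100):
    return L1Match(eid, length, 0, "antisense", offset)


class TestPairToCandidate:
    def test_insert_bound_inclusive_at_50kb(self):
        e = make_element(start=10_000, end=16_000)
        m = antisense_match(length=60, offset=0)  # L1 side at [10000,10060)
        for gap, kept in ((50_000, True), (50_001, False)):
            unique = ("chrT", 10_060 + gap, 10_060 + gap + 100)
            cand, reason = pair_to_candidate(m, unique, e)
            assert (cand is not None) == kept
            assert reason == (None if kept else "insert_too_large")

    def test_same_orientation_rejected(self):
        e = make_element()
        m = L1Match("L1_X", 60, 0, "sense", 0)
        cand, reason = pair_to_candidate(m, ("chrT", 9000, 9100), e)
        assert cand is None and reason == "same_orientation"

    def test_missing_5utr_rejected(self):
        e = make_element(has_asp=False)
        cand, reason = pair_to_candidate(antisense_match(), ("chrT", 9000, 9100), e)
        assert cand is None and reason == "no_5utr"

    def test_different_chromosome_rejected(self):
        e = make_element()
        cand, reason = pair_to_candidate(antisense_match(), ("chr9", 9000, 9100), e)
        assert cand is None and reason == "insert_too_large"

    def test_transcript_strand_opposes_element(self):
        for strand, expected in (("+", "-"), ("-", "+")):
            e = make_element(strand=strand)
            cand, _ = pair_to_candidate(antisense_match(), ("chrT", 9500, 9600), e)
            assert cand.transcript_strand == expected


# ---------------------------------------------------------------------------
# Clustering and pooling


def make_candidate(e, ustart, uend, sample="s1"):
    return Candidate(sample, f"r{ustart}", e, antisense_match(e.id),
                     (e.start, e.start + 80), e.chrom, (ustart, uend), "-")


class TestClustering:
    def test_disjoint_beyond_gap_two_loci(self):
        e = make_element()
        loci = cluster_candidates(
            [make_candidate(e, 9000, 9100), make_candidate(e, 9500, 9600)],
            merge_gap=300)
        assert len(loci) == 2

    def test_overlapping_one_locus_two_reads(self):
        e = make_element()
        loci = cluster_candidates(
            [make_candidate(e, 9000, 9100), make_candidate(e, 9050, 9150)])
        assert len(loci) == 1
        assert loci[0].n_reads == 2
        assert (loci[0].unique_start, loci[0].unique_end) == (9000, 9150)

    def test_matches_union_find_oracle(self):
        """Random 200-candidate fixture partitions exactly as union-find."""
        rng = np.random.default_rng(31)
        elements = [make_element(eid=f"L1_{i}", start=10_000 + 100_000 * i,
                                 end=16_000 + 100_000 * i) for i in range(3)]
        cands = []
        for i in range(200):
            e = elements[int(rng.integers(0, 3))]
            s = e.start - int(rng.integers(100, 8_000))
            cands.append(make_candidate(e, s, s + int(rng.integers(30, 400))))
        merge_gap = 300
        parent = list(range(len(cands)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(cands)):
            for j in range(i + 1, len(cands)):
                a, b = cands[i], cands[j]
                if a.element.id != b.element.id:
                    continue
                gap = max(b.unique_interval[0] - a.unique_interval[1],
                          a.unique_interval[0] - b.unique_interval[1])
                if gap <= merge_gap:
                    parent[find(i)] = find(j)
        expected = {}
        for i, c in enumerate(cands):
            expected.setdefault(find(i), set()).add(c.read_id)
        oracle_partition = {frozenset(v) for v in expected.values()}
        loci = cluster_candidates(cands, merge_gap=merge_gap)
        got = set()
        # reconstruct membership by re-assigning candidates to loci spans
        for l in loci:
            members = frozenset(
                c.read_id for c in cands
                if c.element.id == l.element.id
                and c.unique_interval[0] >= l.unique_start
                and c.unique_interval[1] <= l.unique_end)
            got.add(members)
        assert got == oracle_partition
        assert sum(l.n_reads for l in loci) == len(cands)

    def test_pooling_union_and_commutativity(self):
        e = make_element()
        s1 = cluster_candidates([make_candidate(e, 9000, 9100, "a")])
        s2 = cluster_candidates([make_candidate(e, 9050, 9150, "b"),
                                 make_candidate(e, 4000, 4100, "b")])
        pooled = pool_samples([s1, s2])
        assert len(pooled) >= max(len(s1), len(s2))
        flipped = pool_samples([s2, s1])
        assert {(l.element.id, l.unique_start, l.unique_end, l.n_reads)
                for l in pooled} == {
               (l.element.id, l.unique_start, l.unique_end, l.n_reads)
               for l in flipped}
        nested = pool_samples([pool_samples([s1]), s2])
        assert {(l.unique_start, l.unique_end) for l in nested} == {
            (l.unique_start, l.unique_end) for l in pooled}

    def test_saturation_curve(self):
        e = make_element()
        per_sample = {
            "a": cluster_candidates([make_candidate(e, 9000, 9100, "a")]),
            "b": cluster_candidates([make_candidate(e, 4000, 4100, "b")]),
            "c": cluster_candidates([make_candidate(e, 9050, 9150, "c")]),
        }
        curve = saturation_curve(per_sample, n_perm=50, seed=0)
        assert list(curve["n_samples"]) == [1, 2, 3]
        assert curve["mean_lct_count"].is_monotonic_increasing
        assert curve["mean_lct_count"].iloc[0] == 1.0
        assert curve["mean_lct_count"].iloc[-1] == 2.0  # a and c merge
        single = saturation_curve({"a": per_sample["a"]}, n_perm=3, seed=0)
        assert single["mean_lct_count"].iloc[0] == len(per_sample["a"])


class TestKnownLoci:
    def test_empty_and_self_comparison(self):
        e = make_element()
        loci = cluster_candidates([make_candidate(e, 9000, 9100)])
        assert compare_to_known_loci(loci, [])[0] == 0
        n, ids = compare_to_known_loci(loci, [(e.chrom, e.start, e.end)])
        assert n == 1 and ids == [e.id]

    def test_interval_oracle(self):
        elements = [make_element(eid=f"L1_{i}", start=1000 * i + 100,
                                 end=1000 * i + 700) for i in range(10)]
        loci = cluster_candidates(
            [make_candidate(e, e.start - 500, e.start - 400) for e in elements])
        known = [("chrT", 1000 * i + 650, 1000 * i + 800) for i in range(0, 10, 2)]
        n, ids = compare_to_known_loci(loci, known)
        assert n == 5 and ids == [f"L1_{i}" for i in range(0, 10, 2)]

    def test_malformed_bed_error(self):
        e = make_element()
        loci = cluster_candidates([make_candidate(e, 9000, 9100)])
        with pytest.raises(ValueError, match="malformed"):
            compare_to_known_loci(loci, [("chrT", 100, 100)])


# ---------------------------------------------------------------------------
# End-to-end truth closure (small scale; the 200-locus version lives in the
# acceptance suite)


def test_planted_truth_closure_small(small_truth, finder_result):
    truth_elements = {l.element_id for l in small_truth.lcts}
    found_elements = {l.element.id for l in finder_result.pooled}
    assert found_elements == truth_elements
    assert len(finder_result.pooled) == len(small_truth.lcts)
    by_elem = {l.element_id: l for l in small_truth.lcts}
    for locus in finder_result.pooled:
        assert locus.transcript_strand == by_elem[locus.element.id].transcript_strand
    acc = finder_result.accounting()
    assert acc["candidates"] == acc["retained"] + sum(
        v for k, v in acc.items() if k.startswith("rejected_"))
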