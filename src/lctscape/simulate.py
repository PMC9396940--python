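"""Synthetic study generator with planted ground truth.

Emulates the inputs of an LCT survey end to end: a toy genome carrying L1
copies of the L1PA1..L1PA8 subfamilies (younger subfamilies less diverged
from their consensus, variable 5' truncation), host genes, antisense chimeric
transcripts initiating at the +200/+450 ASP positions (a fraction spliced, a
fraction non-polyadenylated), stranded 280-340 bp paired-end libraries for a
control and a tumor sample group with planted standardized effect sizes,
long-read alignments with 5' loss and a MapQ-failing fraction, qPCR cycle
thresholds, enzyme-digest (qAMP) Ct quadruples encoding per-locus methylation
fractions, CNV mean-log2 tables and an H3K36me3-like coverage track.

Every stage draws from its own child generator of ``config.seed``, so a fixed
seed gives byte-identical outputs regardless of which stages are run.
The planted truth (:class:`SimTruth`) is what downstream recovery tests
compare against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .reference import L1Element

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = str.maketrans("ACGTN", "TGCAN")

CONSENSUS_LENGTH = 6000
UTR_LENGTH = 900

#: per-copy divergence from the subfamily consensus; the ladder emulates the
#: age (and hence mappability) gradient from L1PA1 (youngest) to L1PA8.
#: The floor is set so that two copies of the same subfamily are almost
#: surely distinguishable over a read-length window, which keeps the planted
#: truth recoverable; real L1HS copies are less diverged and genuinely
#: ambiguous at read scale (see the methods note).
DIVERGENCE = {
    "L1PA1": 0.04, "L1PA2": 0.05, "L1PA3": 0.06, "L1PA4": 0.07,
    "L1PA5": 0.08, "L1PA6": 0.09, "L1PA7": 0.10, "L1PA8": 0.11,
}

HOUSEKEEPING = ("TBP", "RPL13A", "PPIA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Configuration and truth containers


@dataclass
class SimConfig:
    seed: int = 0
    chrom: str = "chrT"
    genome_length: int = 1_200_000
    n_genes: int = 14
    n_l1_per_subfamily: dict[str, int] = field(
        default_factory=lambda: {s: 3 for s in DIVERGENCE}
    )
    frac_intragenic_l1: float = 0.5
    frac_lct: float = 0.5
    tss_mix: dict[int, float] = field(default_factory=lambda: {450: 0.6, 200: 0.4})
    frac_spliced: float = 0.029
    frac_nonpolya: float = 0.5
    n_control: int = 3
    n_tumor: int = 8
    #: per-locus standardized mean differences; None -> drawn with the
    #: fractions below (positive = overexpressed in tumor)
    effect_sizes: dict[str, float] | None = None
    frac_up: float = 0.5
    frac_down: float = 0.1
    effect_magnitude: float = 2.0
    base_read_count: float = 20.0
    read_count_sd: float = 4.0
    insert_range: tuple[int, int] = (280, 340)
    read_length: int = 100
    error_rate: float = 0.001
    longread_per_locus: float = 6.0
    longread_5p_loss: float = 30.0
    frac_longread_undetected: float = 0.1
    longread_mapq_fail: float = 0.15
    #: per-locus methylation fractions; None -> drawn uniform below
    methylation_fractions: dict[str, tuple[float, float]] | None = None
    methylation_range: tuple[float, float] = (0.5, 0.95)
    frac_hypomethylated: float = 0.33
    hypomethylation_drop: float = 0.28
    ct_noise_sd: float = 0.15
    ct_baseline: float = 22.0
    qamp_baseline: float = 24.0
    cnv_gain_log2: float = 0.58
    cnv_loss_log2: float = -1.0
    frac_cnv_gain: float = 0.15
    frac_cnv_loss: float = 0.10
    coverage_bin: int = 50
    coverage_signal: float = 3.0

    def validate(self) -> None:
        fracs = {
            "frac_lct": self.frac_lct, "frac_spliced": self.frac_spliced,
            "frac_nonpolya": self.frac_nonpolya, "frac_up": self.frac_up,
            "frac_down": self.frac_down, "error_rate": self.error_rate,
            "frac_intragenic_l1": self.frac_intragenic_l1,
            "frac_longread_undetected": self.frac_longread_undetected,
            "longread_mapq_fail": self.longread_mapq_fail,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.insert_range[0] > self.insert_range[1]:
            raise ValueError("insert_range min > max")
        if self.methylation_fractions is not None:
            for loc, pair in self.methylation_fractions.items():
                for m in pair:
                    if not 0.0 <= m <= 1.0:
                        raise ValueError(
                            f"methylation fraction {m} for {loc} outside [0, 1]"
                        )

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])

    def samples(self) -> list[tuple[str, str]]:
        return [(f"control_{i+1}", "control") for i in range(self.n_control)] + [
            (f"tumor_{i+1}", "tumor") for i in range(self.n_tumor)
        ]


@dataclass
class Gene:
    id: str
    chrom: str
    start: int
    end: int
    strand: str
    #: exon intervals in genomic order; embedded L1s are spliced out of the
    #: mature transcript (so host-gene reads never carry L1 sequence)
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            self.exons = [(self.start, self.end)]

    def transcript_exons(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))


@dataclass
class PlantedLCT:
    """One planted antisense chimeric transcript and its phenotypes."""

    lct_id: str
    element_id: str
    chrom: str
    tss_offset: int  # bp from the element 5' boundary (200 or 450)
    tss_genomic: int  # 0-based genomic coordinate of the first transcribed base
    transcript_strand: str  # opposite of the element strand
    #: exon genomic intervals in transcription order (L1 part first)
    exons: list[tuple[int, int]]
    unique_interval: tuple[int, int]
    spliced: bool
    splice_gap: int
    polya: bool
    effect_size: float
    methylation: tuple[float, float]  # (control, tumor) fractions
    cnv_log2_tumor: float


@dataclass
class SimTruth:
    config: SimConfig
    genome: dict[str, str]
    elements: list[L1Element]
    genes: list[Gene]
    lcts: list[PlantedLCT]
    rmsk_rows: list[tuple]  # UCSC-dialect rows as written to the TSV

    def lct_elements(self) -> list[L1Element]:
        ids = {l.element_id for l in self.lcts}
        return [e for e in self.elements if e.id in ids]

    def transcripts(self) -> list["Transcript"]:
        """Host-gene transcripts plus LCT transcripts."""
        out = [
            Transcript(g.id, g.chrom, g.strand, g.transcript_exons())
            for g in self.genes
        ]
        out.extend(
            Transcript(l.lct_id, l.chrom, l.transcript_strand, l.exons)
            for l in self.lcts
        )
        return out


@dataclass
class Transcript:
    id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # transcription order

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def sequence(self, genome: dict[str, str]) -> str:
        chrom = genome[self.chrom]
        parts = []
        for s, e in self.exons:
            block = chrom[s:e]
            parts.append(revcomp(block) if self.strand == "-" else block)
        return "".join(parts)

    def to_genomic(self, t: int) -> int:
        """Genomic coordinate of transcript position ``t``."""
        off = t
        for s, e in self.exons:
            n = e - s
            if off < n:
                return (e - 1 - off) if self.strand == "-" else (s + off)
            off -= n
        raise IndexError(t)

    def block_intervals(self, a: int, b: int) -> list[tuple[int, int]]:
        """Genomic intervals covered by transcript span [a, b)."""
        blocks = []
        off = 0
        for s, e in self.exons:
            n = e - s
            lo, hi = max(a, off), min(b, off + n)
            if lo < hi:
                if self.strand == "+":
                    blocks.append((s + (lo - off), s + (hi - off)))
                else:
                    blocks.append((e - (hi - off), e - (lo - off)))
            off += n
        return blocks


# ---------------------------------------------------------------------------
# Genome


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    if rate <= 0:
        return out
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def _consensus(subfamily: str, seed: int) -> np.ndarray:
    rng = np.random.default_rng([seed, 1000, sorted(DIVERGENCE).index(subfamily)])
    return rng.choice(_BASES, CONSENSUS_LENGTH)


def simulate_genome(config: SimConfig) -> SimTruth:
    """Build the toy genome, rmsk table, gene models and planted-LCT truth.

    Raises ``ValueError`` when ``config.genome_length`` cannot host the
    requested features.
    """
    config.validate()
    rng = config.rng(0)
    chrom = config.chrom

    consensi = {s: _consensus(s, config.seed) for s in DIVERGENCE}

    # --- plan the element roster (subfamily, truncation category)
    l1_plans = []
    for sub, n in config.n_l1_per_subfamily.items():
        if sub not in DIVERGENCE:
            raise ValueError(f"unknown subfamily {sub!r}")
        for _ in range(n):
            u = rng.random()
            if u < 0.60:  # intact 5' UTR
                t5, cend = int(rng.integers(0, 50)), CONSENSUS_LENGTH
            elif u < 0.75:  # mild 5' truncation, ASP retained
                t5, cend = int(rng.integers(50, 400)), CONSENSUS_LENGTH
            elif u < 0.90:  # heavy 5' truncation, ASP lost
                t5, cend = int(rng.integers(400, 4500)), CONSENSUS_LENGTH
            else:  # short 3'-only fragment, ASP lost
                t5, cend = int(rng.integers(0, 100)), int(rng.integers(300, 601))
            l1_plans.append((sub, t5, cend))
    rng.shuffle(l1_plans)

    n_l1 = len(l1_plans)
    n_host = min(int(round(n_l1 * config.frac_intragenic_l1)), config.n_genes)

    # --- lay out features left to right with repeat-free flanks
    slots: list[tuple] = []  # ("gene", l1_plan|None) or ("l1", plan)
    plans = list(l1_plans)
    for i in range(config.n_genes):
        slots.append(("gene", plans.pop() if i < n_host and plans else None))
    while plans:
        slots.append(("l1", plans.pop()))
    rng.shuffle(slots)

    genes: list[Gene] = []
    elements: list[L1Element] = []
    rmsk_rows: list[tuple] = []
    stamps: list[tuple[int, np.ndarray]] = []
    cursor = 2000
    gi = ei = 0
    for kind, plan in slots:
        cursor += int(rng.integers(3500, 6001))
        if kind == "gene":
            gene_strand = "+" if rng.random() < 0.5 else "-"
            if plan is not None:
                sub, t5, cend = plan
                l1_len = cend - t5
                pad5 = int(rng.integers(3000, 5000))
                pad3 = int(rng.integers(3000, 5000))
                gene_len = pad5 + l1_len + pad3
                l1_start = cursor + pad5
                genes.append(Gene(
                    f"GENE_{gi:03d}", chrom, cursor, cursor + gene_len, gene_strand,
                    exons=[(cursor, l1_start), (l1_start + l1_len, cursor + gene_len)],
                ))
                gi += 1
                elements.append(_plant_element(
                    f"L1_{ei:04d}", chrom, l1_start, sub, t5, cend, rng,
                    consensi, stamps, rmsk_rows))
                ei += 1
                cursor += gene_len
            else:
                gene_len = int(rng.integers(6000, 15001))
                genes.append(Gene(f"GENE_{gi:03d}", chrom, cursor, cursor + gene_len,
                                  gene_strand))
                gi += 1
                cursor += gene_len
        else:
            sub, t5, cend = plan
            elements.append(_plant_element(
                f"L1_{ei:04d}", chrom, cursor, sub, t5, cend, rng,
                consensi, stamps, rmsk_rows))
            ei += 1
            cursor += cend - t5
    cursor += 2000

    if cursor > config.genome_length:
        raise ValueError(
            f"genome_length={config.genome_length} too small: layout of "
            f"{n_l1} L1 elements and {config.n_genes} genes needs {cursor} bp"
        )

    seq = rng.choice(_BASES, config.genome_length)
    for start, block in stamps:
        seq[start : start + len(block)] = block

    # a few non-L1 decoy repeats inside gene interiors, away from any L1
    decoys = 0
    for g in genes:
        if decoys >= 4:
            break
        pos = g.start + 1000
        if all(not (e.start - 3000 < pos < e.end + 3000) for e in elements):
            rmsk_rows.append((chrom, pos, pos + 300, "+", "AluY", 0, 300, 0))
            decoys += 1

    genome = {chrom: seq.tobytes().decode("ascii")}
    truth = SimTruth(config, genome, elements, genes, [], rmsk_rows)
    _plant_lcts(truth, rng)
    return truth


def _plant_element(eid, chrom, start, sub, t5, cend, rng, consensi, stamps, rmsk_rows):
    strand = "+" if rng.random() < 0.5 else "-"
    copy = _mutate(consensi[sub][t5:cend], DIVERGENCE[sub], rng)
    block = copy if strand == "+" else np.frombuffer(
        revcomp(copy.tobytes().decode("ascii")).encode(), dtype=np.uint8
    ).copy()
    stamps.append((start, block))
    end = start + (cend - t5)
    rep_left = -(CONSENSUS_LENGTH - cend)
    if strand == "+":
        rmsk_rows.append((chrom, start, end, "+", sub, t5, cend, rep_left))
    else:  # UCSC minus-strand dialect: repStart/repLeft swap roles
        rmsk_rows.append((chrom, start, end, "-", sub, -rep_left, cend, -t5))
    return L1Element(id=eid, chrom=chrom, start=start, end=end, strand=strand,
                     subfamily=sub, consensus_5p_offset=t5, consensus_end=cend)


def _plant_lcts(truth: SimTruth, rng: np.random.Generator) -> None:
    config = truth.config
    offsets = sorted(config.tss_mix)
    weights = np.array([config.tss_mix[o] for o in offsets], dtype=float)
    weights /= weights.sum()
    k = 0
    for elem in truth.elements:
        if not elem.has_asp or rng.random() >= config.frac_lct:
            continue
        o = int(rng.choice(offsets, p=weights))
        if elem.length <= o:
            continue
        u_len = int(rng.integers(250, 1200))
        spliced = rng.random() < config.frac_spliced
        gap = int(rng.integers(600, 1500)) if spliced else 0
        if elem.strand == "+":
            tss = elem.start + o
            u = (elem.start - gap - u_len, elem.start - gap)
            exons = [(elem.start, tss + 1), u]
            t_strand = "-"
        else:
            tss = elem.end - 1 - o
            u = (elem.end + gap, elem.end + gap + u_len)
            exons = [(tss, elem.end), u]
            t_strand = "+"
        delta = _draw_effect(config, rng)
        m_ctrl = float(rng.uniform(*config.methylation_range))
        m_tum = m_ctrl
        if rng.random() < config.frac_hypomethylated:
            m_tum = max(0.0, m_ctrl - config.hypomethylation_drop)
        u_cnv = rng.random()
        cnv = (config.cnv_gain_log2 if u_cnv < config.frac_cnv_gain
               else config.cnv_loss_log2
               if u_cnv < config.frac_cnv_gain + config.frac_cnv_loss else 0.0)
        lct = PlantedLCT(
            lct_id=f"LCT_{k:04d}", element_id=elem.id, chrom=elem.chrom,
            tss_offset=o, tss_genomic=tss, transcript_strand=t_strand,
            exons=exons, unique_interval=u, spliced=spliced, splice_gap=gap,
            polya=rng.random() >= config.frac_nonpolya, effect_size=delta,
            methylation=(m_ctrl, m_tum), cnv_log2_tumor=cnv,
        )
        if config.methylation_fractions and lct.lct_id in config.methylation_fractions:
            lct.methylation = config.methylation_fractions[lct.lct_id]
        if config.effect_sizes and lct.lct_id in config.effect_sizes:
            lct.effect_size = config.effect_sizes[lct.lct_id]
        truth.lcts.append(lct)
        k += 1


def _draw_effect(config: SimConfig, rng: np.random.Generator) -> float:
    u = rng.random()
    if u < config.frac_up:
        return config.effect_magnitude
    if u < config.frac_up + config.frac_down:
        return -config.effect_magnitude
    return 0.0


# ---------------------------------------------------------------------------
# Short reads


@dataclass
class ReadPair:
    read_id: str
    sample: str
    r1: str
    r2: str
    transcript_id: str
    # genomic placement of the mate (R2) main alignment block
    mate_chrom: str
    mate_start: int
    mate_end: int
    # fragment origin (outermost genomic span), for the truth BED
    frag_start: int
    frag_end: int


def expected_count(config: SimConfig, group: str, effect_size: float) -> float:
    """Mean fragment count for one transcript in one sample of ``group``.

    Planted effects are standardized mean differences: tumor mean is shifted
    by ``effect_size * read_count_sd``.
    """
    mu = config.base_read_count
    if group == "tumor":
        mu += effect_size * config.read_count_sd
    return max(mu, 0.0)


def simulate_counts(
    config: SimConfig, effect_size: float, rng: np.random.Generator,
    n_control: int | None = None, n_tumor: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample supporting-read counts for one locus under the read model
    (normal around the group mean, floored at zero) without simulating the
    reads themselves."""
    nc = n_control if n_control is not None else config.n_control
    nt = n_tumor if n_tumor is not None else config.n_tumor
    c = rng.normal(expected_count(config, "control", effect_size),
                   config.read_count_sd, nc)
    t = rng.normal(expected_count(config, "tumor", effect_size),
                   config.read_count_sd, nt)
    return np.maximum(np.round(c), 0.0), np.maximum(np.round(t), 0.0)


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for i in np.nonzero(rng.random(len(arr)) < rate)[0]:
        arr[i] = rng.choice(_BASES[_BASES != arr[i]])
    return arr.tobytes().decode("ascii")


def simulate_reads(truth: SimTruth, config: SimConfig | None = None) -> list[ReadPair]:
    """Draw stranded paired-end fragments from all transcripts.

    Read 1 carries the fragment end nearer the transcript 5' end (it is
    transcript-sense); read 2 is its reverse complement on the 3' side.
    Fragment inserts are uniform on ``insert_range``; per-base substitution
    errors at ``error_rate``.
    """
    config = config or truth.config
    rng = config.rng(1)
    rl = config.read_length
    lo, hi = config.insert_range
    effects = {l.lct_id: l.effect_size for l in truth.lcts}
    pairs: list[ReadPair] = []
    for sample, group in config.samples():
        for tr in truth.transcripts():
            seq = tr.sequence(truth.genome)
            L = len(seq)
            mu = expected_count(config, group, effects.get(tr.id, 0.0))
            n = max(0, int(round(rng.normal(mu, config.read_count_sd))))
            for i in range(n):
                insert = int(rng.integers(lo, hi + 1))
                insert = min(insert, L)
                fstart = int(rng.integers(0, L - insert + 1))
                frag = seq[fstart : fstart + insert]
                r1 = _add_errors(frag[:rl], config.error_rate, rng)
                r2 = _add_errors(revcomp(frag[-rl:]), config.error_rate, rng)
                mate_span = tr.block_intervals(fstart + insert - min(rl, insert),
                                               fstart + insert)
                mate = max(mate_span, key=lambda b: b[1] - b[0])
                frag_blocks = tr.block_intervals(fstart, fstart + insert)
                pairs.append(ReadPair(
                    read_id=f"{sample}:{tr.id}:{i}", sample=sample, r1=r1, r2=r2,
                    transcript_id=tr.id, mate_chrom=tr.chrom,
                    mate_start=mate[0], mate_end=mate[1],
                    frag_start=min(b[0] for b in frag_blocks),
                    frag_end=max(b[1] for b in frag_blocks),
                ))
    return pairs


# ---------------------------------------------------------------------------
# Long reads


def simulate_longreads(
    truth: SimTruth, config: SimConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emulate post-alignment long reads spanning each LCT.

    Returns ``(alignments, per_read_truth)``.  Alignments carry
    (read_id, chrom, start, end, strand, mapq); reads lose an exponential
    amount of 5' sequence (mean ``longread_5p_loss``) and a configured
    fraction fails the MapQ >= 30 filter.  Decoy sense-strand reads over
    non-LCT elements exercise the orientation filter.
    """
    config = config or truth.config
    rng = config.rng(2)
    aln_rows, truth_rows = [], []
    by_id = {e.id: e for e in truth.elements}
    rid = 0

    def mapq() -> int:
        if rng.random() < config.longread_mapq_fail:
            return int(rng.integers(0, 30))
        return int(rng.integers(30, 61))

    for lct in truth.lcts:
        if rng.random() < config.frac_longread_undetected:
            continue
        n = 1 + rng.poisson(max(config.longread_per_locus - 1, 0.0))
        elem = by_id[lct.element_id]
        for _ in range(n):
            loss = (int(round(rng.exponential(config.longread_5p_loss)))
                    if config.longread_5p_loss > 0 else 0)
            if lct.transcript_strand == "-":  # + element; 5' end slides left
                five = lct.tss_genomic - loss
                start, end = lct.unique_interval[0], five + 1
                strand = "-"
            else:
                five = lct.tss_genomic + loss
                start, end = five, lct.unique_interval[1]
                strand = "+"
            if end <= start:
                continue
            q = mapq()
            aln_rows.append((f"lr_{rid:05d}", lct.chrom, start, end, strand, q))
            truth_rows.append((f"lr_{rid:05d}", lct.lct_id, lct.element_id,
                               lct.tss_offset - loss, q))
            rid += 1

    for elem in truth.elements:  # decoys: sense-oriented reads, never LCTs
        if elem.id in {l.element_id for l in truth.lcts} or rng.random() > 0.3:
            continue
        start = max(0, elem.start - 200)
        aln_rows.append((f"lr_{rid:05d}", elem.chrom, start, elem.start + 800,
                         elem.strand, mapq()))
        truth_rows.append((f"lr_{rid:05d}", "", elem.id, -1, aln_rows[-1][5]))
        rid += 1

    aln = pd.DataFrame(aln_rows,
                       columns=["read_id", "chrom", "start", "end", "strand", "mapq"])
    tr = pd.DataFrame(truth_rows,
                      columns=["read_id", "lct_id", "element_id", "tss_offset", "mapq"])
    return aln, tr


# ---------------------------------------------------------------------------
# qPCR / qAMP / CNV / coverage


def simulate_qpcr(truth: SimTruth, config: SimConfig | None = None):
    """Cycle-threshold table for LCT targets plus housekeeping genes.

    Ct = baseline - log_E(relative abundance) + Normal(0, ct_noise_sd); the
    planted effect size doubles as a log2 fold change on the qPCR scale
    (tumor abundance = control * 2**effect_size).
    """
    config = config or truth.config
    rng = config.rng(3)
    targets = [l.lct_id for l in truth.lcts]
    eff = {t: float(rng.uniform(1.86, 2.0)) for t in targets}
    eff.update({h: float(rng.uniform(1.9, 2.0)) for h in HOUSEKEEPING})
    rows = []
    lfc = {l.lct_id: l.effect_size for l in truth.lcts}
    for sample, group in config.samples():
        for t in targets + list(HOUSEKEEPING):
            a = 1.0
            if t in lfc and group == "tumor":
                a = 2.0 ** lfc[t]
            ct_true = config.ct_baseline - math.log(a) / math.log(eff[t])
            for rep in (1, 2):
                rows.append((sample, group, t, rep,
                             ct_true + rng.normal(0.0, config.ct_noise_sd)))
    df = pd.DataFrame(rows, columns=["sample", "group", "target", "replicate", "ct"])
    return df, eff


_DELTA_CT_CAP = 20.0  # qPCR detection limit on the ΔCt scale


def simulate_qamp(truth: SimTruth, config: SimConfig | None = None) -> pd.DataFrame:
    """Enzyme-digest Ct quadruples (sham, HhaI, HpaII, McrBC) per locus/sample.

    The methylation-sensitive enzymes leave the methylated fraction m intact
    (2**-dCt = m); the methylation-dependent McrBC leaves 1 - m.
    """
    config = config or truth.config
    config.validate()
    rng = config.rng(4)

    def dct(frac: float) -> float:
        if frac <= 0.0:
            return _DELTA_CT_CAP
        return min(-math.log2(frac), _DELTA_CT_CAP)

    rows = []
    for lct in truth.lcts:
        for sample, group in config.samples():
            m = lct.methylation[0 if group == "control" else 1]
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"methylation fraction {m} outside [0, 1]")
            sham = config.qamp_baseline + rng.normal(0.0, config.ct_noise_sd)
            noise = lambda: rng.normal(0.0, config.ct_noise_sd)
            rows.append((lct.lct_id, sample, group, sham,
                         sham + dct(m) + noise(),
                         sham + dct(m) + noise(),
                         sham + dct(1.0 - m) + noise()))
    return pd.DataFrame(
        rows, columns=["locus", "sample", "group",
                       "ct_sham", "ct_hhai", "ct_hpaii", "ct_mcrbc"])


def simulate_cnv(truth: SimTruth, config: SimConfig | None = None) -> pd.DataFrame:
    """Mean log2-ratio CNV table per locus and sample."""
    config = config or truth.config
    rng = config.rng(5)
    rows = []
    for lct in truth.lcts:
        for sample, group in config.samples():
            mu = lct.cnv_log2_tumor if group == "tumor" else 0.0
            rows.append((lct.lct_id, sample, group, mu + rng.normal(0.0, 0.05)))
    return pd.DataFrame(rows, columns=["locus", "sample", "group", "mean_log2"])


def simulate_coverage(truth: SimTruth, config: SimConfig | None = None) -> pd.DataFrame:
    """H3K36me3-like bedGraph: baseline noise, elevated over LCT+ elements."""
    config = config or truth.config
    rng = config.rng(6)
    chrom = config.chrom
    n = len(truth.genome[chrom])
    bin_ = config.coverage_bin
    edges = np.arange(0, n + bin_, bin_)
    values = np.abs(rng.normal(1.0, 0.2, size=len(edges) - 1))
    pos_ids = {l.element_id for l in truth.lcts}
    for elem in truth.elements:
        if elem.id not in pos_ids:
            continue
        lo = max(0, (elem.start - 1000) // bin_)
        hi = min(len(values), (elem.end + 1000) // bin_ + 1)
        values[lo:hi] += config.coverage_signal
    return pd.DataFrame({
        "chrom": chrom,
        "start": edges[:-1][: len(values)],
        "end": np.minimum(edges[1:], n)[: len(values)],
        "value": np.round(values, 4),
    })


# ---------------------------------------------------------------------------
# Writers (plain-text formats only)


def write_genome_fasta(truth: SimTruth, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in truth.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_rmsk(truth: SimTruth, path: str | Path) -> None:
    cols = ["genoName", "genoStart", "genoEnd", "strand", "repName",
            "repStart", "repEnd", "repLeft"]
    pd.DataFrame(truth.rmsk_rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_gtf(truth: SimTruth, path: str | Path) -> None:
    """Gene models, 1-based closed coordinates."""
    with open(path, "w") as fh:
        for g in truth.genes:
            attrs = f'gene_id "{g.id}"; transcript_id "{g.id}.t1";'
            for feat in ("gene", "transcript"):
                fh.write("\t".join([g.chrom, "sim", feat, str(g.start + 1),
                                    str(g.end), ".", g.strand, ".", attrs]) + "\n")
            for s, e in g.exons:
                fh.write("\t".join([g.chrom, "sim", "exon", str(s + 1),
                                    str(e), ".", g.strand, ".", attrs]) + "\n")


def write_truth_table(truth: SimTruth, path: str | Path) -> None:
    rows = [{
        "lct_id": l.lct_id, "element_id": l.element_id, "chrom": l.chrom,
        "tss_offset": l.tss_offset, "transcript_strand": l.transcript_strand,
        "unique_start": l.unique_interval[0], "unique_end": l.unique_interval[1],
        "spliced": l.spliced, "polya": l.polya, "effect_size": l.effect_size,
        "methylation_control": l.methylation[0], "methylation_tumor": l.methylation[1],
        "cnv_log2_tumor": l.cnv_log2_tumor,
    } for l in truth.lcts]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_fastq(pairs: Sequence[ReadPair], r1_path: str | Path, r2_path: str | Path) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.r1}\n+\n{'I' * len(p.r1)}\n")
            f2.write(f"@{p.read_id}/2\n{p.r2}\n+\n{'I' * len(p.r2)}\n")


def write_mate_alignments(pairs: Sequence[ReadPair], path: str | Path) -> None:
    pd.DataFrame({
        "read_id": [p.read_id for p in pairs],
        "sample": [p.sample for p in pairs],
        "chrom": [p.mate_chrom for p in pairs],
        "start": [p.mate_start for p in pairs],
        "end": [p.mate_end for p in pairs],
    }).to_csv(path, sep="\t", index=False)


def write_fragment_bed(pairs: Sequence[ReadPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.mate_chrom}\t{p.frag_start}\t{p.frag_end}\t"
                     f"{p.read_id}\t0\t.\n")


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, header=False)
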