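"""Build the reference set of ASP-competent L1 elements.

The LINE-1 antisense promoter (L1-ASP) lives in the first ~900 bp of the L1
5' UTR, with transcription-start hotspots near +200 and +450.  An element can
only drive an antisense chimeric transcript if its 5' UTR is reasonably
intact, which is decided from RepeatMasker consensus coordinates: the element
must start before consensus position 400 (``repStart``/``repLeft`` depending
on strand) and extend past consensus position 600 (``repEnd``).

All genomic coordinates are 0-based half-open.  The UCSC rmsk dialect swaps
the roles of ``repStart`` and ``repLeft`` on the minus strand (and stores the
"left" field as a negative number); :func:`parse_rmsk` normalises this at the
boundary so that every record carries an unambiguous ``consensus_5p_offset``
and ``consensus_end``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: Subfamilies whose ASP is known to be active (L1PA1, L1P1 and L1HS are
#: synonyms across RepeatMasker versions).
RECENT_SUBFAMILIES = frozenset(
    {"L1PA1", "L1P1", "L1HS", "L1PA2", "L1PA3", "L1PA4", "L1PA5", "L1PA6",
     "L1PA7", "L1PA8"}
)

ASP_MAX_5P_OFFSET = 400  # element must begin before this consensus position
ASP_MIN_END = 600  # and extend beyond this consensus position
REFERENCE_LENGTH = 500  # bp of 5'-most sequence extracted per element


@dataclass(frozen=True)
class RmskRecord:
    """One RepeatMasker annotation row, consensus fields already normalised."""

    chrom: str
    geno_start: int
    geno_end: int
    strand: str
    rep_name: str
    consensus_5p_offset: int
    consensus_end: int

    def __post_init__(self) -> None:
        if self.geno_start >= self.geno_end:
            raise ValueError(f"empty interval {self.geno_start}:{self.geno_end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")


@dataclass
class L1Element:
    """A genomic L1 locus promoted from an rmsk row."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    consensus_5p_offset: int
    consensus_end: int
    has_asp: bool = field(init=False)

    def __post_init__(self) -> None:
        self.has_asp = (
            self.consensus_5p_offset < ASP_MAX_5P_OFFSET
            and self.consensus_end > ASP_MIN_END
        )

    @property
    def length(self) -> int:
        return self.end - self.start

    def five_prime_boundary(self) -> int:
        """Genomic coordinate of the element's 5'-most base (0-based)."""
        return self.start if self.strand == "+" else self.end - 1


# ---------------------------------------------------------------------------
# rmsk parsing


def _normalise_consensus(strand: str, rep_start: int, rep_end: int, rep_left: int):
    """Return (consensus_5p_offset, consensus_end) for either strand.

    UCSC stores, for + strand rows, (repStart, repEnd, repLeft=-remaining);
    for - strand rows repStart and repLeft swap roles, the "left" slot holding
    the (negative) 5' offset.
    """
    if strand == "+":
        return rep_start, rep_end
    return abs(rep_left), rep_end


def parse_rmsk(path: str | Path) -> list[RmskRecord]:
    """Parse a UCSC-schema rmsk TSV into normalised records.

    Expected columns (tab-separated, header optional):
    genoName, genoStart, genoEnd, strand, repName, repStart, repEnd, repLeft.
    Malformed rows are skipped with a logged warning that names the row.
    """
    records: list[RmskRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] in ("genoName", "chrom"):
                continue
            try:
                chrom, gs, ge, strand, name, rs, re_, rl = parts[:8]
                gs_i, ge_i = int(gs), int(ge)
                off, cend = _normalise_consensus(strand, int(rs), int(re_), int(rl))
                records.append(
                    RmskRecord(chrom, gs_i, ge_i, strand, name, off, cend)
                )
            except (ValueError, IndexError) as exc:
                logger.warning("rmsk row %d skipped (%s): %r", lineno, exc, line)
    return records


# ---------------------------------------------------------------------------
# Operations


def select_asp_l1(
    records: Iterable[RmskRecord | L1Element],
    subfamilies: frozenset[str] | set[str] = RECENT_SUBFAMILIES,
) -> list[L1Element]:
    """Keep elements of the requested subfamilies with an intact ASP.

    An element qualifies when its consensus 5' offset is strictly below 400 bp
    and its consensus end strictly beyond 600 bp, i.e. the antisense-promoter
    region of the 5' UTR is present.  Input order is preserved and the filter
    is idempotent (L1Element inputs pass through the same predicate).
    """
    out: list[L1Element] = []
    for i, rec in enumerate(records):
        if isinstance(rec, L1Element):
            elem = rec
            name = elem.subfamily
        else:
            name = rec.rep_name
            elem = L1Element(
                id=f"L1_{i:05d}",
                chrom=rec.chrom,
                start=rec.geno_start,
                end=rec.geno_end,
                strand=rec.strand,
                subfamily=name,
                consensus_5p_offset=rec.consensus_5p_offset,
                consensus_end=rec.consensus_end,
            )
        if name in subfamilies and elem.has_asp:
            out.append(elem)
    return out


def extract_5p_sequence(genome, element: L1Element, length: int = REFERENCE_LENGTH):
    """Extract the element's 5'-most ``length`` bp in element orientation.

    ``genome`` is any mapping of chrom -> indexable sequence (a
    ``pyfaidx.Fasta``, a dict of strings, ...).  On the minus strand the last
    ``length`` genomic bases are reverse-complemented.  Elements shorter than
    ``length`` yield a truncated sequence with ``truncated=True``.

    Returns ``(seq: str, truncated: bool)``; raises ``ValueError`` when the
    element lies outside the genome.
    """
    chrom_seq = genome[element.chrom]
    chrom_len = len(chrom_seq)
    if element.start < 0 or element.end > chrom_len:
        raise ValueError(
            f"element {element.id} [{element.start},{element.end}) outside "
            f"{element.chrom} (length {chrom_len})"
        )
    take = min(length, element.length)
    if element.strand == "+":
        seq = str(chrom_seq[element.start : element.start + take])
    else:
        seq = str(Seq(str(chrom_seq[element.end - take : element.end])).reverse_complement())
    return seq.upper(), take < length


def subfamily_counts(elements: Sequence[L1Element]) -> pd.Series:
    """Tally elements per subfamily (counts partition the input)."""
    return pd.Series(
        [e.subfamily for e in elements], dtype="object"
    ).value_counts().sort_index()


# ---------------------------------------------------------------------------
# IO


def write_reference_fasta(
    genome, elements: Sequence[L1Element], path: str | Path, length: int = REFERENCE_LENGTH
) -> None:
    """Write the 5'-most ``length`` bp of each element as a FASTA reference."""
    with open(path, "w") as fh:
        for e in elements:
            seq, truncated = extract_5p_sequence(genome, e, length)
            flag = " truncated" if truncated else ""
            fh.write(f">{e.id} {e.subfamily}{flag}\n{seq}\n")


def elements_to_frame(elements: Sequence[L1Element]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [e.id for e in elements],
            "chrom": [e.chrom for e in elements],
            "start": [e.start for e in elements],
            "end": [e.end for e in elements],
            "strand": [e.strand for e in elements],
            "subfamily": [e.subfamily for e in elements],
            "has_asp": [e.has_asp for e in elements],
        }
    )


def write_element_table(elements: Sequence[L1Element], path: str | Path) -> None:
    elements_to_frame(elements).to_csv(path, sep="\t", index=False)


def read_element_table(path: str | Path) -> list[L1Element]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        e = L1Element(
            id=row.id,
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            subfamily=row.subfamily,
            # table stores has_asp, not raw consensus fields: reconstruct a
            # consistent pair so has_asp round-trips
            consensus_5p_offset=0 if row.has_asp else ASP_MAX_5P_OFFSET,
            consensus_end=ASP_MIN_END + 1 if row.has_asp else ASP_MIN_END,
        )
        out.append(e)
    return out
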