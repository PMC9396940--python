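"""Methylation indices, CNV correlates and chromatin metaprofiles.

The qAMP model: after digestion with a methylation-sensitive enzyme (HhaI,
HpaII) the surviving, amplifiable template fraction is the methylated
fraction m, so ``2**(-dCt) = m`` with ``dCt = Ct_enzyme - Ct_sham``; the
methylation-dependent McrBC cuts methylated DNA, so ``2**(-dCt) = 1 - m``.
Each enzyme yields an estimate on a 0-100 scale and the index is their
arithmetic mean.  Slightly negative dCt (well-to-well noise) is clamped to 0.

The metaprofile mirrors a scale-regions computation: each element body is
rescaled to a fixed length by per-base resampling, flanks are taken as-is,
everything is oriented 5'->3' of the element, then bin-averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import spearman_rho
from .reference import L1Element


@dataclass
class QampAssay:
    """One locus/sample enzyme-digest Ct quadruple (NaN = missing enzyme)."""

    locus: str
    sample: str
    ct_sham: float
    ct_hhai: float = float("nan")
    ct_hpaii: float = float("nan")
    ct_mcrbc: float = float("nan")


def qamp_index(assay: QampAssay) -> tuple[float, dict[str, float], bool]:
    """Methylation index in [0, 100] plus per-enzyme estimates.

    Returns ``(index, estimates, incomplete)``; ``incomplete`` flags an
    index computed from fewer than three enzymes.
    """
    if assay.ct_sham <= 0:
        raise ValueError("Ct values must be positive")

    def dct(ct_enzyme: float) -> float | None:
        if math.isnan(ct_enzyme):
            return None
        return max(ct_enzyme - assay.ct_sham, 0.0)

    estimates: dict[str, float] = {}
    for name, ct in (("HhaI", assay.ct_hhai), ("HpaII", assay.ct_hpaii)):
        d = dct(ct)
        if d is not None:
            estimates[name] = 100.0 * 2.0 ** (-d)
    d = dct(assay.ct_mcrbc)
    if d is not None:
        estimates["McrBC"] = 100.0 * (1.0 - 2.0 ** (-d))
    if not estimates:
        raise ValueError(f"no enzyme Ct available for {assay.locus}/{assay.sample}")
    index = min(max(sum(estimates.values()) / len(estimates), 0.0), 100.0)
    return index, estimates, len(estimates) < 3


def qamp_table(assays: pd.DataFrame) -> pd.DataFrame:
    """Vectorised qAMP over a frame with columns locus, sample, ct_sham,
    ct_hhai, ct_hpaii, ct_mcrbc (extra columns pass through)."""
    rows = []
    for r in assays.itertuples(index=False):
        idx, est, incomplete = qamp_index(QampAssay(
            r.locus, r.sample, r.ct_sham, r.ct_hhai, r.ct_hpaii, r.ct_mcrbc))
        d = {"locus": r.locus, "sample": r.sample, "index": idx,
             "incomplete": incomplete}
        d.update({f"m_{k.lower()}": v for k, v in est.items()})
        if hasattr(r, "group"):
            d["group"] = r.group
        rows.append(d)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-locus correlations


def _per_locus_correlation(
    left: pd.DataFrame, right: pd.DataFrame, left_col: str, right_col: str
) -> pd.DataFrame:
    """Spearman per locus over paired samples, Bonferroni over loci."""
    merged = left.merge(right, on=["locus", "sample"])
    rows = []
    for locus, sel in merged.groupby("locus"):
        if len(sel) < 3:
            rows.append({"locus": locus, "n": len(sel), "rho": float("nan"),
                         "p": float("nan"), "skipped": True})
            continue
        rho, p = spearman_rho(sel[left_col].to_numpy(), sel[right_col].to_numpy())
        rows.append({"locus": locus, "n": len(sel), "rho": rho, "p": p,
                     "skipped": False})
    df = pd.DataFrame(rows)
    m = int((~df["skipped"]).sum())
    df["p_bonferroni"] = np.minimum(df["p"] * max(m, 1), 1.0)
    return df


def methylation_expression_correlation(
    indices: pd.DataFrame, expression: pd.DataFrame
) -> pd.DataFrame:
    """Spearman of methylation index vs relative expression per locus.

    ``indices``: columns locus, sample, index; ``expression``: columns
    locus, sample, R.  Loci with fewer than 3 paired samples are skipped.
    """
    return _per_locus_correlation(indices, expression, "index", "R")


def cnv_expression_correlation(
    cnv: pd.DataFrame, expression: pd.DataFrame
) -> pd.DataFrame:
    """Spearman of CNV mean log2 ratio vs relative expression per locus."""
    return _per_locus_correlation(cnv, expression, "mean_log2", "R")


# ---------------------------------------------------------------------------
# Coverage tracks and metaprofiles


class CoverageTrack:
    """Piecewise-constant genome signal backed by dense per-chrom arrays;
    positions not covered by any interval read as 0."""

    def __init__(self, bedgraph: pd.DataFrame,
                 chrom_lengths: Mapping[str, int] | None = None):
        self._arrays: dict[str, np.ndarray] = {}
        for chrom, sel in bedgraph.groupby("chrom"):
            sel = sel.sort_values("start")
            starts, ends = sel["start"].to_numpy(int), sel["end"].to_numpy(int)
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"overlapping bedGraph intervals on {chrom}")
            n = int(chrom_lengths[chrom]) if chrom_lengths else int(ends.max())
            arr = np.zeros(n, dtype=float)
            for s, e, v in zip(starts, ends, sel["value"].to_numpy(float)):
                arr[s:e] = v
            self._arrays[str(chrom)] = arr

    def values(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        arr = self._arrays.get(chrom)
        if arr is None:
            return np.zeros(len(positions))
        out = np.zeros(len(positions))
        ok = (positions >= 0) & (positions < len(arr))
        out[ok] = arr[positions[ok]]
        return out

    @classmethod
    def from_bedgraph_file(cls, path, **kw) -> "CoverageTrack":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"])
        return cls(df, **kw)


def _element_positions(e: L1Element, before: int, body: int, after: int) -> np.ndarray:
    elen = e.length
    if e.strand == "+":
        pre = np.arange(e.start - before, e.start)
        mid = e.start + (np.arange(body) * elen) // body
        post = np.arange(e.end, e.end + after)
    else:
        pre = np.arange(e.end + before - 1, e.end - 1, -1)
        mid = e.end - 1 - (np.arange(body) * elen) // body
        post = np.arange(e.start - 1, e.start - 1 - after, -1)
    return np.concatenate([pre, mid, post])


def metaprofile(
    track: CoverageTrack,
    elements: Sequence[L1Element],
    before: int = 1000,
    body: int = 1000,
    after: int = 1000,
    bin_size: int = 10,
    skip_zeros: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Scale-regions mean profile over ``elements``.

    Returns ``(mean_vector, matrix)``: the matrix holds one bin-averaged row
    per region (rows that are entirely zero are dropped when
    ``skip_zeros``); the mean vector has length (before+body+after)/bin_size.
    """
    for name, length in (("before", before), ("body", body), ("after", after)):
        if length % bin_size:
            raise ValueError(f"bin_size={bin_size} does not divide {name}={length}")
    if not elements:
        raise ValueError("no elements")
    total = before + body + after
    rows = []
    for e in elements:
        vals = track.values(e.chrom, _element_positions(e, before, body, after))
        rows.append(vals.reshape(total // bin_size, bin_size).mean(axis=1))
    mat = np.asarray(rows)
    if skip_zeros:
        keep = ~(mat == 0).all(axis=1)
        mat = mat[keep]
    mean = mat.mean(axis=0) if len(mat) else np.zeros(total // bin_size)
    return mean, mat


def profile_contrast(
    track: CoverageTrack,
    elements_pos: Sequence[L1Element],
    elements_neg: Sequence[L1Element],
    **kw,
) -> pd.DataFrame:
    """Side-by-side metaprofiles for LCT-producing vs non-producing elements.

    The two sets must be disjoint (by element id and span).
    """
    if not elements_pos or not elements_neg:
        raise ValueError("both element sets must be non-empty")
    ids_pos = {e.id for e in elements_pos}
    overlap = ids_pos & {e.id for e in elements_neg}
    if overlap:
        raise ValueError(f"element sets overlap: {sorted(overlap)}")
    mean_pos, _ = metaprofile(track, elements_pos, **kw)
    mean_neg, _ = metaprofile(track, elements_neg, **kw)
    bin_size = kw.get("bin_size", 10)
    before = kw.get("before", 1000)
    return pd.DataFrame({
        "bin_start": np.arange(len(mean_pos)) * bin_size - before,
        "lct_pos": mean_pos,
        "lct_neg": mean_neg,
    })
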