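"""Expression quantification and group statistics for LCT loci.

Covers the efficiency-corrected relative-expression model
``R = E_TOI**(-Ct_TOI) / geomean_k(E_HKk**(-Ct_HKk))``, Mann-Whitney tests
with Holm step-down correction, the Hedges' g standardized effect size used
to predict deregulation from supporting-read counts, cutoff calibration
against qPCR-derived truth labels, Spearman correlations, and host-gene
fpkm comparisons.

Sign convention (fixed, since it decides the up/down mapping): g is computed
as control minus tumor over the pooled SD, so a locus overexpressed in tumor
has g < 0 and ``g < -cutoff`` is called "up".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

HOUSEKEEPING = ("TBP", "RPL13A", "PPIA")
DEFAULT_CUTOFF = 1.0


# ---------------------------------------------------------------------------
# qPCR relative expression


@dataclass
class CtTable:
    """Cycle thresholds (long format) plus per-target primer efficiencies."""

    data: pd.DataFrame  # columns: sample, group, target, replicate, ct
    efficiencies: Mapping[str, float]
    housekeeping: tuple[str, ...] = HOUSEKEEPING

    def __post_init__(self) -> None:
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        low = [t for t, e in self.efficiencies.items() if e < 1.85]
        if low:
            import logging
            logging.getLogger(__name__).warning(
                "primer efficiency below 1.85 for %s", low)

    def mean_ct(self, sample: str, target: str) -> float:
        sel = self.data[(self.data["sample"] == sample)
                        & (self.data["target"] == target)]
        if sel.empty:
            raise KeyError(f"no Ct for target {target!r} in sample {sample!r}")
        return float(sel["ct"].mean())


def relative_expression(ct: CtTable, sample: str, target: str) -> float:
    """Efficiency-corrected expression of ``target`` relative to the
    geometric mean of the housekeeping targets (replicates averaged on the
    Ct scale)."""
    if target not in ct.efficiencies:
        raise KeyError(f"no efficiency for target {target!r}")
    e_t = ct.efficiencies[target]
    num = e_t ** (-ct.mean_ct(sample, target))
    logs = []
    for hk in ct.housekeeping:
        if hk not in ct.efficiencies:
            raise KeyError(f"no efficiency for housekeeping target {hk!r}")
        logs.append(-ct.mean_ct(sample, hk) * math.log(ct.efficiencies[hk]))
    denom = math.exp(sum(logs) / len(logs))
    return num / denom


def expression_matrix(ct: CtTable) -> pd.DataFrame:
    """Relative expression for every (locus, sample); loci are the non-HK
    targets."""
    targets = sorted(set(ct.data["target"]) - set(ct.housekeeping))
    samples = ct.data[["sample", "group"]].drop_duplicates()
    rows = [
        {"locus": t, "sample": row.sample, "group": row.group,
         "R": relative_expression(ct, row.sample, t)}
        for t in targets for row in samples.itertuples(index=False)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group tests


def mannwhitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact enumeration when both n <= 8 and the
    data are tie-free, tie-corrected normal approximation otherwise.  Fully
    degenerate input (every value identical) yields p = 1."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observations per group")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return len(x) * len(y) / 2.0, 1.0
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=method == "asymptotic")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (never smaller than the raw ones,
    order preserving)."""
    return multipletests(np.asarray(pvalues, float), method="holm")[1]


def mw_holm(values: pd.DataFrame, loci: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-locus Mann-Whitney between control and tumor, Holm-adjusted.

    ``values`` is long format with columns locus, group, value.
    """
    loci = list(loci) if loci is not None else sorted(values["locus"].unique())
    rows = []
    for locus in loci:
        sel = values[values["locus"] == locus]
        x = sel.loc[sel["group"] == "control", "value"].to_numpy()
        y = sel.loc[sel["group"] == "tumor", "value"].to_numpy()
        u, p = mannwhitney(x, y)
        rows.append({"locus": locus, "U": u, "p": p})
    df = pd.DataFrame(rows)
    df["p_holm"] = holm_adjust(df["p"])
    return df


# ---------------------------------------------------------------------------
# Hedges' g


def hedges_g(control: Sequence[float], tumor: Sequence[float]) -> float:
    """Small-sample-corrected standardized mean difference, control - tumor.

    g = J * (mean_c - mean_t) / s_pooled with J = 1 - 3 / (4(n1+n2) - 9).
    Tumor overexpression therefore gives g < 0.  Zero pooled SD returns 0
    for equal means and signed infinity otherwise.
    """
    c, t = np.asarray(control, float), np.asarray(tumor, float)
    n1, n2 = len(c), len(t)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 observations per group")
    s1, s2 = c.var(ddof=1), t.var(ddof=1)
    sp = math.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    diff = c.mean() - t.mean()
    if sp == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return j * diff / sp


def classify_deregulation(g: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """up if g < -cutoff, down if g > +cutoff, else unchanged (strict)."""
    if g < -cutoff:
        return "up"
    if g > cutoff:
        return "down"
    return "unchanged"


def hedges_table(
    counts: pd.DataFrame, groups: Mapping[str, str], cutoff: float = DEFAULT_CUTOFF,
    log1p: bool = False,
) -> pd.DataFrame:
    """Per-locus g and deregulation call from a locus x sample count table.

    ``groups`` maps sample name -> {control, tumor}.  Counts are used raw by
    default; ``log1p`` applies log(1+x) first.
    """
    ctrl = [s for s in counts.columns if groups.get(s) == "control"]
    tum = [s for s in counts.columns if groups.get(s) == "tumor"]
    rows = []
    for locus, row in counts.iterrows():
        c, t = row[ctrl].to_numpy(float), row[tum].to_numpy(float)
        if log1p:
            c, t = np.log1p(c), np.log1p(t)
        g = hedges_g(c, t)
        rows.append({"locus": locus, "g": g, "n_control": len(c), "n_tumor": len(t),
                     "call": classify_deregulation(g, cutoff)})
    return pd.DataFrame(rows)


def calibrate_cutoff(
    g_values: Mapping[str, float],
    truth_labels: Mapping[str, str],
    cutoffs: Sequence[float] = tuple(np.round(np.arange(0.25, 3.25, 0.25), 2)),
) -> tuple[pd.DataFrame, float]:
    """Sensitivity/specificity over candidate |g| cutoffs.

    ``truth_labels`` maps locus -> {deregulated_up, deregulated_down,
    unchanged} (e.g. from Holm-adjusted Mann-Whitney on qPCR data).
    Sensitivity is direction-matched: a truly deregulated locus counts only
    when |g| clears the cutoff with the matching sign.  The chosen cutoff
    maximises Youden's J; ties go to the smaller cutoff.
    """
    dereg = {k: v for k, v in truth_labels.items() if v != "unchanged"}
    null = {k for k, v in truth_labels.items() if v == "unchanged"}
    if not dereg:
        raise ValueError("no deregulated loci in the truth labels")
    rows = []
    for c in cutoffs:
        tp = sum(
            1 for k, lab in dereg.items()
            if classify_deregulation(g_values[k], c)
            == ("up" if lab == "deregulated_up" else "down"))
        tn = sum(1 for k in null
                 if classify_deregulation(g_values[k], c) == "unchanged")
        sens = tp / len(dereg)
        spec = tn / len(null) if null else float("nan")
        rows.append({"cutoff": float(c), "sensitivity": sens, "specificity": spec,
                     "youden_j": sens + (spec if null else 0.0) - 1.0})
    table = pd.DataFrame(rows)
    best = table.sort_values(["youden_j", "cutoff"], ascending=[False, True])
    return table, float(best.iloc[0]["cutoff"])


# ---------------------------------------------------------------------------
# Correlations and host-gene comparisons


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with t-approximation p-value.

    Constant input is undefined: returns (nan, nan).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of >= 3 points")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def compare_host_gene_expression(
    fpkm: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]],
    transform: str = "log2p1",
) -> pd.DataFrame:
    """Median fpkm and Welch t-test per pair of gene sets.

    ``fpkm`` is gene x sample; ``gene_sets`` maps set name -> gene ids.  All
    unordered pairs of sets are compared on the chosen transform
    ("log2p1" -> log2(fpkm + 1), "none" -> raw).  Set medians are reported
    on the raw fpkm scale.
    """
    names = list(gene_sets)
    pooled = {}
    for name in names:
        genes = [g for g in gene_sets[name] if g in fpkm.index]
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
        pooled[name] = fpkm.loc[genes].to_numpy(float).ravel()
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            xa, xb = pooled[a], pooled[b]
            ta, tb = (np.log2(xa + 1), np.log2(xb + 1)) if transform == "log2p1" \
                else (xa, xb)
            t, p = stats.ttest_ind(ta, tb, equal_var=False)
            rows.append({"set_a": a, "set_b": b,
                         "median_a": float(np.median(xa)),
                         "median_b": float(np.median(xb)),
                         "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)
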