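"""Relative expression, group tests, Hedges' g and cutoff calibration."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from lctscape.expression import (
    CtTable,
    calibrate_cutoff,
    classify_deregulation,
    compare_host_gene_expression,
    hedges_g,
    hedges_table,
    holm_adjust,
    mannwhitney,
    mw_holm,
    relative_expression,
    spearman_rho,
)
from lctscape.simulate import SimConfig, simulate_counts


def ct_table(rows, eff, hk=("HK1",)):
    df = pd.DataFrame(rows, columns=["sample", "group", "target", "replicate", "ct"])
    return CtTable(df, eff, housekeeping=hk)


class TestRelativeExpression:
    def test_equal_ct_single_hk_gives_one(self):
        t = ct_table([("s", "control", "L", 1, 20.0), ("s", "control", "HK1", 1, 20.0)],
                     {"L": 2.0, "HK1": 2.0})
        assert relative_expression(t, "s", "L") == pytest.approx(1.0)

    def test_geometric_mean_of_housekeepers(self):
        # target Ct 21 between HK Cts 20 and 22 at E=2: R = 2^-21 / sqrt(2^-20 * 2^-22)
        t = ct_table(
            [("s", "c", "L", 1, 21.0), ("s", "c", "HK1", 1, 20.0),
             ("s", "c", "HK2", 1, 22.0)],
            {"L": 2.0, "HK1": 2.0, "HK2": 2.0}, hk=("HK1", "HK2"))
        assert relative_expression(t, "s", "L") == pytest.approx(1.0)

    def test_doubling_abundance_doubles_r(self):
        rows = [("s", "c", "L", 1, 21.0), ("s", "c", "HK1", 1, 20.0),
                ("s2", "c", "L", 1, 20.0), ("s2", "c", "HK1", 1, 20.0)]
        t = ct_table(rows, {"L": 2.0, "HK1": 2.0})
        assert relative_expression(t, "s2", "L") == pytest.approx(
            2.0 * relative_expression(t, "s", "L"))

    def test_replicates_averaged_on_ct_scale(self):
        rows = [("s", "c", "L", 1, 20.0), ("s", "c", "L", 2, 22.0),
                ("s", "c", "HK1", 1, 21.0)]
        t = ct_table(rows, {"L": 2.0, "HK1": 2.0})
        assert relative_expression(t, "s", "L") == pytest.approx(1.0)

    def test_missing_housekeeper_or_efficiency_errors(self):
        t = ct_table([("s", "c", "L", 1, 20.0)], {"L": 2.0, "HK1": 2.0})
        with pytest.raises(KeyError):
            relative_expression(t, "s", "L")
        t2 = ct_table([("s", "c", "L", 1, 20.0), ("s", "c", "HK1", 1, 20.0)],
                      {"HK1": 2.0})
        with pytest.raises(KeyError):
            relative_expression(t2, "s", "L")


class TestMannWhitneyHolm:
    def test_identical_groups_p_one(self):
        _, p = mannwhitney([1.0, 1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_holm_step_down_hand_example(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_holm_monotone_and_order_preserving(self):
        raw = np.array([0.001, 0.2, 0.03, 0.6])
        adj = holm_adjust(raw)
        assert (adj >= raw).all()
        assert list(np.argsort(adj)) == list(np.argsort(raw))

    def test_exact_agrees_with_enumeration_oracle(self):
        """Exact p at n=5 per group equals full label enumeration, and the
        normal approximation is within 0.02 of it."""
        from scipy import stats

        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 5)
        y = rng.normal(0.8, 1, 5)
        u_obs, p_exact = mannwhitney(x, y)
        pooled = np.concatenate([x, y])
        n = 0
        total = 0
        for idx in itertools.combinations(range(10), 5):
            a = pooled[list(idx)]
            b = pooled[[i for i in range(10) if i not in idx]]
            u = sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b)
            stat = max(u, 25 - u)
            if stat >= max(u_obs, 25 - u_obs):
                n += 1
            total += 1
        assert p_exact == pytest.approx(n / total)
        p_approx = stats.mannwhitneyu(x, y, alternative="two-sided",
                                      method="asymptotic").pvalue
        assert abs(p_approx - p_exact) < 0.02

    def test_mw_holm_frame(self):
        rows = []
        for locus, shift in (("a", 0.0), ("b", 5.0)):
            for i in range(6):
                rows.append((locus, "control", float(i)))
                rows.append((locus, "tumor", float(i) + shift))
        df = mw_holm(pd.DataFrame(rows, columns=["locus", "group", "value"]))
        assert df.loc[df.locus == "a", "p_holm"].iloc[0] == pytest.approx(1.0)
        assert df.loc[df.locus == "b", "p_holm"].iloc[0] < 0.05


def brute_force_g(c, t):
    n1, n2 = len(c), len(t)
    m1 = sum(c) / n1
    m2 = sum(t) / n2
    v1 = sum((x - m1) ** 2 for x in c) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in t) / (n2 - 1)
    sp = math.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    if sp == 0:
        return 0.0 if m1 == m2 else math.copysign(math.inf, m1 - m2)
    return (1 - 3 / (4 * (n1 + n2) - 9)) * (m1 - m2) / sp


class TestHedgesG:
    def test_worked_example(self):
        # J = 1 - 3/15 = 0.8; s_pooled = 1 -> g = 0.8 * (2 - 5) = -2.4
        assert hedges_g([1, 2, 3], [4, 5, 6]) == pytest.approx(-2.4)

    def test_identical_groups_zero(self):
        assert hedges_g([2, 2, 3], [2, 2, 3]) == 0.0

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=6), rng.normal(size=9)
        assert hedges_g(a, b) == pytest.approx(-hedges_g(b, a))

    def test_zero_variance_cases(self):
        assert hedges_g([1, 1], [1, 1]) == 0.0
        assert hedges_g([2, 2], [1, 1]) == math.inf

    def test_exact_agreement_with_brute_force(self):
        rng = np.random.default_rng(19)
        for _ in range(1000):
            n1, n2 = rng.integers(2, 12, size=2)
            c = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), n1)
            t = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), n2)
            assert hedges_g(c, t) == pytest.approx(brute_force_g(list(c), list(t)),
                                                   rel=1e-12)

    def test_effect_size_recovery(self):
        """mean(-g) over replicates tracks the planted standardized
        difference within two standard errors (n=8 per group)."""
        cfg = SimConfig(seed=0)
        rng = np.random.default_rng(77)
        for delta in (0.0, 0.5, 1.0, 2.0):
            gs = []
            for _ in range(500):
                c, t = simulate_counts(cfg, delta, rng, n_control=8, n_tumor=8)
                gs.append(-hedges_g(c, t))
            gs = np.asarray(gs)
            se = gs.std(ddof=1) / math.sqrt(len(gs))
            assert abs(gs.mean() - delta) < 2 * se


class TestClassification:
    @pytest.mark.parametrize("g,call", [(-2.4, "up"), (0.0, "unchanged"),
                                        (1.0, "unchanged"), (-1.0, "unchanged"),
                                        (1.01, "down")])
    def test_cutoff_strict(self, g, call):
        assert classify_deregulation(g) == call

    def test_hedges_table_calls(self):
        counts = pd.DataFrame(
            {"c1": [10, 10], "c2": [11, 12], "c3": [9, 11],
             "t1": [30, 10], "t2": [28, 12], "t3": [31, 9]},
            index=["locusA", "locusB"])
        groups = {"c1": "control", "c2": "control", "c3": "control",
                  "t1": "tumor", "t2": "tumor", "t3": "tumor"}
        out = hedges_table(counts, groups).set_index("locus")
        assert out.loc["locusA", "call"] == "up"
        assert out.loc["locusB", "call"] == "unchanged"


class TestCalibration:
    def test_perfect_separation(self):
        g = {f"d{i}": -3.0 for i in range(5)}
        g.update({f"n{i}": 0.1 for i in range(5)})
        labels = {f"d{i}": "deregulated_up" for i in range(5)}
        labels.update({f"n{i}": "unchanged" for i in range(5)})
        table, chosen = calibrate_cutoff(g, labels, cutoffs=[0.5, 1.0, 2.0])
        row = table[table.cutoff == chosen].iloc[0]
        assert (row.sensitivity, row.specificity) == (1.0, 1.0)
        assert chosen == 0.5  # ties resolved toward the smaller cutoff

    def test_hand_counted_table(self):
        g = {"a": -2.0, "b": -0.5, "c": 2.5, "d": 0.2, "e": -1.5,
             "f": 0.0, "g": 1.2, "h": -0.1, "i": 3.0, "j": -0.8}
        labels = {"a": "deregulated_up", "b": "deregulated_up",
                  "c": "deregulated_down", "e": "deregulated_up",
                  "i": "deregulated_down",
                  "d": "unchanged", "f": "unchanged", "g": "unchanged",
                  "h": "unchanged", "j": "unchanged"}
        table, _ = calibrate_cutoff(g, labels, cutoffs=[1.0])
        row = table.iloc[0]
        # direction-matched at |g|>1: a, e, c, i called correctly; b missed
        assert row.sensitivity == pytest.approx(4 / 5)
        # unchanged loci: d,f,h,j stay unchanged; g (1.2) is called down
        assert row.specificity == pytest.approx(4 / 5)

    def test_monotone_tradeoff(self):
        rng = np.random.default_rng(4)
        g = {f"l{i}": float(v) for i, v in enumerate(rng.normal(0, 2, 40))}
        labels = {k: ("deregulated_up" if v < -1 else
                      "deregulated_down" if v > 1 else "unchanged")
                  for k, v in g.items()}
        table, _ = calibrate_cutoff(g, labels,
                                    cutoffs=np.arange(0.25, 3.0, 0.25))
        assert (np.diff(table.sensitivity) <= 1e-12).all()
        assert (np.diff(table.specificity) >= -1e-12).all()

    def test_no_deregulated_truth_errors(self):
        with pytest.raises(ValueError, match="deregulated"):
            calibrate_cutoff({"a": 0.0}, {"a": "unchanged"})


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(8.0)
        assert spearman_rho(x, x)[0] == pytest.approx(1.0)
        assert spearman_rho(x, -x)[0] == pytest.approx(-1.0)

    def test_constant_vector_flagged(self):
        rho, p = spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(rho) and math.isnan(p)

    def test_tied_fixture_matches_rank_formula(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0]
        y = [2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0, 6.0]

        def midranks(v):
            order = sorted(range(len(v)), key=lambda i: v[i])
            ranks = [0.0] * len(v)
            i = 0
            while i < len(v):
                j = i
                while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                    j += 1
                for k in range(i, j + 1):
                    ranks[order[k]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        rx, ry = midranks(x), midranks(y)
        mx, my = np.mean(rx), np.mean(ry)
        num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
        den = math.sqrt(sum((a - mx) ** 2 for a in rx)
                        * sum((b - my) ** 2 for b in ry))
        assert spearman_rho(x, y)[0] == pytest.approx(num / den)


class TestHostGeneExpression:
    def frame(self):
        rng = np.random.default_rng(8)
        idx = [f"g{i}" for i in range(40)]
        base = rng.lognormal(1.0, 0.5, size=(40, 6))
        base[20:] *= 4  # second half clearly higher expressed
        return pd.DataFrame(base, index=idx,
                            columns=[f"s{i}" for i in range(6)])

    def test_identical_sets_p_near_one(self):
        f = self.frame()
        out = compare_host_gene_expression(
            f, {"a": f.index[:10], "b": f.index[:10]})
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_shifted_sets_detected_and_medians(self):
        f = self.frame()
        out = compare_host_gene_expression(
            f, {"low": f.index[:20], "high": f.index[20:]})
        row = out.iloc[0]
        assert row.p < 1e-6 and row.median_b > row.median_a
        assert np.median([1, 2, 3]) == 2

    def test_empty_set_error(self):
        f = self.frame()
        with pytest.raises(ValueError, match="empty"):
            compare_host_gene_expression(f, {"a": ["nope"], "b": f.index[:3]})
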