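"""Thresholded co-expression edges, sign partitions, module summaries, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncbrain.core_io import ValidationError
from lncbrain.network import (
    correlation_pvalues,
    hypergeometric_enrichment,
    interaction_strength,
    module_module_counts,
    negative_regulator_summary,
    pairwise_network,
    sign_partition,
)


def _frame(rows, prefix="g", n_samples=None):
    rows = np.asarray(rows, dtype=float)
    return pd.DataFrame(
        rows,
        index=[f"{prefix}{i}" for i in range(len(rows))],
        columns=[f"s{j}" for j in range(rows.shape[1])],
    )


class TestPairwiseNetwork:
    def test_identical_and_negated_profiles(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=8)
        expr = _frame([base, base + 1e-9 * rng.normal(size=8), -base])
        edges = pairwise_network(expr, r_min=0.7, p_max=0.05)
        by_pair = {(r.gene_a, r.gene_b): r for r in edges.itertuples()}
        assert by_pair[("g0", "g1")].sign == "positive"
        assert by_pair[("g0", "g1")].r == pytest.approx(1.0, abs=1e-6)
        assert by_pair[("g0", "g2")].sign == "negative"
        assert by_pair[("g0", "g2")].r == pytest.approx(-1.0, abs=1e-6)

    def test_boundary_correlation_kept_at_n64(self):
        # r = 0.7 at n = 64: t = 7.718, p ~ 1e-10, well below 0.01
        t = 0.7 * np.sqrt(62) / np.sqrt(1 - 0.49)
        assert t == pytest.approx(7.718, abs=1e-3)
        p = correlation_pvalues(np.array([0.7]), 64)[0]
        assert p < 1e-9
        assert p == pytest.approx(2 * stats.t.sf(t, 62), rel=1e-9)

    def test_pvalues_match_permutation_oracle_at_n10(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10)
        y = 0.8 * x + 0.6 * rng.normal(size=10)
        r_obs = np.corrcoef(x, y)[0, 1]
        p_t = correlation_pvalues(np.array([r_obs]), 10)[0]
        n_perm = 100_000
        perms = np.array([np.random.default_rng(s).permutation(y) for s in range(n_perm)])
        r_perm = (
            (perms - perms.mean(axis=1, keepdims=True))
            @ ((x - x.mean()) / x.std())
        ) / (perms.std(axis=1) * 10)
        p_perm = (np.abs(r_perm) >= abs(r_obs) - 1e-12).mean()
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p_t - p_perm) < max(5 * se, 0.01)

    def test_within_set_pairs_counted_once_no_self_pairs(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=12)
        expr = _frame([base + 0.01 * rng.normal(size=12) for _ in range(4)])
        edges = pairwise_network(expr, r_min=0.7, p_max=0.05)
        assert len(edges) == 6  # C(4,2)
        assert (edges["gene_a"] != edges["gene_b"]).all()
        pairs = set(map(tuple, edges[["gene_a", "gene_b"]].to_numpy()))
        assert all((b, a) not in pairs for a, b in pairs)

    def test_constant_gene_excluded_with_warning(self):
        expr = _frame([np.arange(8.0), np.ones(8)])
        with pytest.warns(UserWarning, match="constant"):
            edges = pairwise_network(expr, r_min=0.1, p_max=1.0)
        assert "g1" not in set(edges["gene_a"]) | set(edges["gene_b"])

    def test_too_few_samples_rejected(self):
        expr = _frame([[1.0, 2, 3], [3, 2, 1]])
        with pytest.raises(ValidationError):
            pairwise_network(expr)

    def test_null_edge_rate_matches_analytic_tail(self, null_study):
        _, mat, _, _ = null_study
        log_expr = mat.log_rpkm().iloc[:1000]
        log_expr = log_expr[log_expr.std(axis=1) > 0]
        n_genes = len(log_expr)
        n = log_expr.shape[1]
        # moderate threshold where the null tail has measurable mass
        r_min = 0.35
        edges = pairwise_network(log_expr, r_min=r_min, p_max=1.0)
        t = r_min * np.sqrt(n - 2) / np.sqrt(1 - r_min**2)
        tail = 2 * stats.t.sf(t, n - 2)
        n_pairs = n_genes * (n_genes - 1) // 2
        expected = tail * n_pairs
        # pairs share samples, so allow a generous band around the tail rate
        assert expected * 0.7 < len(edges) < expected * 1.4
        # at the pipeline threshold 0.7 the tail is ~1e-10: essentially no edges
        strict = pairwise_network(log_expr, r_min=0.7, p_max=0.01)
        assert len(strict) <= 3


class TestSignPartition:
    def _edges(self, signs):
        return pd.DataFrame(
            {
                "gene_a": [f"a{i}" for i in range(len(signs))],
                "gene_b": [f"b{i}" for i in range(len(signs))],
                "r": [0.9 if s == "positive" else -0.9 for s in signs],
                "p": 1e-5,
                "sign": signs,
            }
        )

    def test_fractions(self):
        out = sign_partition(
            {
                "lnc-mRNA": self._edges(["positive", "positive", "negative"]),
                "mRNA-mRNA": self._edges(["positive"]),
            }
        ).set_index("class_pair")
        assert out.loc["lnc-mRNA", "frac_negative"] == pytest.approx(1 / 3)
        assert out.loc["lnc-mRNA", "frac_positive"] == pytest.approx(2 / 3)
        assert out.loc["mRNA-mRNA", "frac_negative"] == 0.0

    def test_empty_class_reported_missing(self):
        out = sign_partition({"lnc-lnc": self._edges([])}).set_index("class_pair")
        assert out.loc["lnc-lnc", "n_edges"] == 0
        assert np.isnan(out.loc["lnc-lnc", "frac_negative"])

    def test_order_invariance(self):
        e = self._edges(["positive", "negative", "negative", "positive"])
        a = sign_partition({"x": e})
        b = sign_partition({"x": e.iloc[::-1].reset_index(drop=True)})
        pd.testing.assert_frame_equal(a, b)


def _toy_edges():
    return pd.DataFrame(
        {
            "gene_a": ["l1", "l1", "l2", "l3"],
            "gene_b": ["m1", "m2", "m1", "m3"],
            "r": [0.8, -0.9, 0.75, -0.7],
            "p": [1e-4] * 4,
            "sign": ["positive", "negative", "positive", "negative"],
        }
    )


class TestModuleSummaries:
    def test_module_module_counts_and_conservation(self):
        edges = _toy_edges()
        lnc_mod = pd.Series({"l1": 1, "l2": 1, "l3": 0})
        mrna_mod = pd.Series({"m1": 1, "m2": 2, "m3": 1})
        tab = module_module_counts(edges, lnc_mod, mrna_mod)
        assert tab.loc[1, 1] == 2  # l1-m1, l2-m1
        assert tab.loc[1, 2] == 1  # l1-m2
        labeled = edges[
            edges["gene_a"].map(lnc_mod).ne(0) & edges["gene_b"].map(mrna_mod).ne(0)
        ]
        assert tab.to_numpy().sum() == len(labeled)

    def test_interaction_strength_sums_absolute_r(self):
        edges = _toy_edges()
        strength = interaction_strength(edges, ["m1", "m2"])
        assert strength["l1"] == pytest.approx(0.8 + 0.9)
        assert strength["l2"] == pytest.approx(0.75)
        assert list(strength.index) == ["l1", "l2"]  # sorted descending

    def test_interaction_strength_absent_focal_is_error(self):
        with pytest.raises(ValidationError):
            interaction_strength(_toy_edges(), ["zz"])

    def test_negative_regulators_counted_once_and_monotone_in_k(self):
        edges = pd.DataFrame(
            {
                "gene_a": ["l1", "l1", "l1", "l2"],
                "gene_b": ["m1", "m2", "m3", "m1"],
                "r": [-0.8, -0.9, -0.7, -0.75],
                "p": [1e-4] * 4,
                "sign": ["negative"] * 4,
            }
        )
        lnc_mod = pd.Series({"l1": 1, "l2": 1})
        mrna_mod = pd.Series({"m1": 1, "m2": 1, "m3": 1})
        k1 = negative_regulator_summary(edges, lnc_mod, mrna_mod, min_negative_edges=1)
        k3 = negative_regulator_summary(edges, lnc_mod, mrna_mod, min_negative_edges=3)
        assert k1.loc[1, "n_regulators"] == 2  # l1 counted once despite 3 edges
        assert k3.loc[1, "n_regulators"] == 1  # only l1 reaches 3 edges
        assert (k3["n_regulators"] <= k1["n_regulators"]).all()

    def test_no_negative_edges_gives_zero_matrix(self):
        edges = _toy_edges()
        edges = edges[edges["sign"] == "positive"]
        out = negative_regulator_summary(
            edges, pd.Series({"l1": 1}), pd.Series({"m1": 1})
        )
        assert (out["n_regulators"] == 0).all()


class TestEnrichment:
    def test_exact_match_closed_form(self):
        background = [f"g{i}" for i in range(100)]
        target = {"hit": background[:10]}
        out = hypergeometric_enrichment(background[:10], target, background)
        from math import comb

        assert out.loc[0, "p"] == pytest.approx(1 / comb(100, 10), rel=1e-9)

    def test_disjoint_set_p_is_one(self):
        background = [f"g{i}" for i in range(50)]
        out = hypergeometric_enrichment(
            background[:5], {"other": background[40:]}, background
        )
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_q_values_follow_bh_step_up(self):
        rng = np.random.default_rng(3)
        background = [f"g{i}" for i in range(200)]
        targets = {
            f"set{j}": list(rng.choice(background, size=20, replace=False))
            for j in range(5)
        }
        out = hypergeometric_enrichment(background[:30], targets, background)
        # step-up oracle: q_(i) = min_{j >= i} p_(j) * m / j
        p = out["p"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        q_sorted = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        q_oracle = np.empty(m)
        q_oracle[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(out["q"].to_numpy(), q_oracle, rtol=1e-9)

    def test_empty_background_is_error(self):
        with pytest.raises(ValidationError):
            hypergeometric_enrichment(["g1"], {"s": ["g1"]}, [])
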