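"""Thresholded signed co-expression network between and within gene classes.

Edges are Pearson correlations on log2(RPKM+1) kept at |r| >= 0.7 and
p <= 0.01 (p from the t transform with n-2 degrees of freedom).  Edge sign
partitions, module-module pair counts, per-partner interaction strength,
negative-regulator summaries, and a generic hypergeometric gene-set
enrichment live here.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import ValidationError

EDGE_COLUMNS = ["gene_a", "gene_b", "r", "p", "sign"]


def correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via t = r sqrt(n-2) / sqrt(1-r^2), df = n-2."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def _standardize_rows(expr: pd.DataFrame, label: str) -> tuple[pd.DataFrame, np.ndarray]:
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s) excluded from {label}",
            stacklevel=3,
        )
    x = x[~constant]
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    return expr.index[~constant], x


def pairwise_network(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame | None = None,
    r_min: float = 0.7,
    p_max: float = 0.01,
    block_size: int = 2000,
) -> pd.DataFrame:
    """All thresholded co-expression edges between (or within) gene sets.

    ``expr_a``/``expr_b`` are genes x samples frames of log2(RPKM+1) over
    identical samples.  With ``expr_b=None`` the within-set network is built
    (each unordered pair counted once, no self-pairs).  Returns a DataFrame
    with columns ``gene_a, gene_b, r, p, sign``.
    """
    within = expr_b is None
    if within:
        expr_b = expr_a
    if list(expr_a.columns) != list(expr_b.columns):
        raise ValidationError("expression frames must share identical samples")
    n = expr_a.shape[1]
    if n < 4:
        raise ValidationError("need >= 4 samples for correlation p-values")
    idx_a, za = _standardize_rows(expr_a, "gene set A")
    idx_b, zb = _standardize_rows(expr_b, "gene set B") if not within else (idx_a, za)

    rows = []
    for start in range(0, len(idx_a), block_size):
        stop = min(start + block_size, len(idx_a))
        r_block = za[start:stop] @ zb.T / n
        np.clip(r_block, -1.0, 1.0, out=r_block)
        ii, jj = np.nonzero(np.abs(r_block) >= r_min)
        if within:
            keep = (ii + start) < jj
            ii, jj = ii[keep], jj[keep]
        if len(ii) == 0:
            continue
        r_vals = r_block[ii, jj]
        p_vals = correlation_pvalues(r_vals, n)
        keep = p_vals <= p_max
        for i, j, r, p in zip(ii[keep], jj[keep], r_vals[keep], p_vals[keep]):
            rows.append((idx_a[start + i], idx_b[j], float(r), float(p)))
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS[:4])
    edges["sign"] = np.where(edges["r"] >= 0, "positive", "negative")
    return edges


def sign_partition(
    edges_by_classpair: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Fraction of positive/negative edges per class pair.

    ``edges_by_classpair`` maps a label (e.g. ``lnc-mRNA``) to its edge
    table.  Class pairs with no edges are reported with NaN fractions.
    """
    rows = []
    for label, edges in edges_by_classpair.items():
        n = len(edges)
        if n == 0:
            rows.append({"class_pair": label, "n_edges": 0,
                         "frac_positive": np.nan, "frac_negative": np.nan})
            continue
        neg = float((edges["sign"] == "negative").mean())
        rows.append(
            {
                "class_pair": label,
                "n_edges": n,
                "frac_positive": 1.0 - neg,
                "frac_negative": neg,
            }
        )
    return pd.DataFrame(rows)


def module_module_counts(
    edges: pd.DataFrame,
    modules_a: pd.Series,
    modules_b: pd.Series,
) -> pd.DataFrame:
    """Count edges between module pairs (label-0 genes excluded).

    Entry (L, M) is the number of edges with ``gene_a`` in module L of
    ``modules_a`` and ``gene_b`` in module M of ``modules_b``.  A companion
    log10 display table is available as ``np.log10(counts.replace(0, np.nan))``.
    """
    ma = edges["gene_a"].map(modules_a)
    mb = edges["gene_b"].map(modules_b)
    keep = ma.notna() & mb.notna() & (ma != 0) & (mb != 0)
    tab = pd.crosstab(ma[keep].astype(int), mb[keep].astype(int))
    rows = sorted(set(modules_a) - {0})
    cols = sorted(set(modules_b) - {0})
    return tab.reindex(index=rows, columns=cols, fill_value=0)


def interaction_strength(edges: pd.DataFrame, focal: Iterable[str]) -> pd.Series:
    """Per-partner summed |r| over edges to the focal gene set, descending.

    Absolute values are summed so negative regulators register as strong
    rather than cancelling.
    """
    focal = set(focal)
    present = set(edges["gene_a"]) | set(edges["gene_b"])
    if not focal & present:
        raise ValidationError("no focal gene participates in any edge")
    a_in = edges["gene_a"].isin(focal)
    b_in = edges["gene_b"].isin(focal)
    partners = pd.concat(
        [
            edges.loc[a_in & ~b_in, ["gene_b", "r"]].rename(columns={"gene_b": "partner"}),
            edges.loc[b_in & ~a_in, ["gene_a", "r"]].rename(columns={"gene_a": "partner"}),
        ]
    )
    if partners.empty:
        return pd.Series(dtype=float, name="strength")
    out = partners.assign(r=partners["r"].abs()).groupby("partner")["r"].sum()
    return out.sort_values(ascending=False).rename("strength")


def negative_regulator_summary(
    edges: pd.DataFrame,
    lnc_modules: pd.Series,
    target_modules: pd.Series,
    min_negative_edges: int = 1,
) -> pd.DataFrame:
    """Distinct lncRNA regulators per target module, with size-normalized ratio.

    A lncRNA (``gene_a`` side) counts as a regulator of a target module when
    it has at least ``min_negative_edges`` negative edges into that module
    (label-0 targets excluded).  Returns a table indexed by target module
    with columns ``n_regulators`` and ``ratio_to_module_size``.
    """
    neg = edges[edges["sign"] == "negative"]
    tm = neg["gene_b"].map(target_modules)
    keep = tm.notna() & (tm != 0)
    neg = neg[keep]
    tm = tm[keep].astype(int)
    counts = (
        pd.DataFrame({"lnc": neg["gene_a"], "module": tm})
        .groupby(["lnc", "module"])
        .size()
    )
    regulators = counts[counts >= min_negative_edges].reset_index()
    per_module = regulators.groupby("module")["lnc"].nunique()
    module_sizes = target_modules[target_modules != 0].value_counts()
    out = pd.DataFrame(
        {
            "n_regulators": per_module.reindex(sorted(module_sizes.index), fill_value=0),
        }
    )
    out["ratio_to_module_size"] = out["n_regulators"] / module_sizes.loc[out.index]
    out.index.name = "target_module"
    return out


def hypergeometric_enrichment(
    gene_set: Iterable[str],
    target_sets: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``gene_set`` in each target set.

    ``p`` is the upper tail P(X >= overlap) with population = background,
    successes = target set, draws = gene set; ``q`` is the Benjamini-
    Hochberg adjusted value across target sets.
    """
    bg = set(background)
    if not bg:
        raise ValidationError("empty background")
    query = set(gene_set) & bg
    rows = []
    for name, members in target_sets.items():
        members = set(members) & bg
        overlap = len(query & members)
        p = float(
            stats.hypergeom.sf(overlap - 1, len(bg), len(members), len(query))
        )
        rows.append(
            {"set": name, "overlap": overlap, "set_size": len(members),
             "query_size": len(query), "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
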