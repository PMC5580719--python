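"""Sex-biased expression: paired t-tests across matched F/M samples.

Every (region, age) design cell with both sexes contributes one pair; the
paired two-sided t-test runs on log2(RPKM+1) differences (F - M) across all
pairs jointly (32 in the full design), so a gene biased consistently across
space and time is detected regardless of its temporal regulation.  Class
frequencies of biased genes (lncRNA vs mRNA) are compared by Fisher's exact
test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, ValidationError


def _pair_samples(samples: pd.DataFrame, by_age: int | None = None):
    """Match F and M sample ids per (region, age) cell."""
    meta = samples
    if by_age is not None:
        meta = meta[meta["age"] == by_age]
    pairs = []
    missing = []
    for (region, age), cell in meta.groupby(["region", "age"]):
        f = cell.index[cell["sex"] == "F"]
        m = cell.index[cell["sex"] == "M"]
        if len(f) == 1 and len(m) == 1:
            pairs.append((f[0], m[0]))
        else:
            missing.append((region, age))
    return pairs, missing


def paired_sex_test(
    matrix: ExpressionMatrix,
    alpha: float = 0.01,
    by_age: int | None = None,
) -> pd.DataFrame:
    """Per-gene paired t-test of female vs male expression.

    Returns a DataFrame with ``gene_id, class_label, mean_diff, t, df, p,
    direction, significant, degenerate``.  Direction follows the sign of the
    mean F-M difference.  Genes with zero-variance nonzero differences are
    flagged degenerate with p = 0 (the paired t statistic diverges); genes
    with all-zero differences get t = 0, p = 1.

    ``by_age`` restricts pairing to one age group (the sex-temporal
    contrast); by default all (region, age) cells pair jointly.
    """
    pairs, missing = _pair_samples(matrix.samples, by_age=by_age)
    if len(pairs) < 3:
        raise ValidationError(
            f"need >= 3 complete F/M pairs (got {len(pairs)}; "
            f"incomplete cells: {missing})"
        )
    if missing:
        warnings.warn(f"incomplete design cells skipped: {missing}", stacklevel=2)
    log_expr = matrix.log_rpkm()
    f_ids = [p[0] for p in pairs]
    m_ids = [p[1] for p in pairs]
    diffs = log_expr[f_ids].to_numpy() - log_expr[m_ids].to_numpy()
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    df = n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=df)

    zero_sd = sd == 0
    degenerate = zero_sd & (mean != 0)
    all_zero = zero_sd & (mean == 0)
    t = np.where(all_zero, 0.0, t)
    p = np.where(all_zero, 1.0, p)
    p = np.where(degenerate, 0.0, p)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with constant nonzero F-M "
            "difference flagged degenerate (p set to 0)",
            stacklevel=2,
        )
    out = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "class_label": matrix.gene_info["class_label"].to_numpy(),
            "mean_diff": mean,
            "t": t,
            "df": df,
            "p": p,
            "direction": np.where(mean >= 0, "female-biased", "male-biased"),
            "degenerate": degenerate,
        }
    )
    out["significant"] = out["p"] < alpha
    return out


def sex_bias_summary(results: pd.DataFrame) -> dict:
    """Counts of female-/male-biased significant genes."""
    sig = results[results["significant"]]
    return {
        "n_biased": int(len(sig)),
        "n_female_biased": int((sig["direction"] == "female-biased").sum()),
        "n_male_biased": int((sig["direction"] == "male-biased").sum()),
    }


def frequency_comparison(
    n_biased_a: int, n_total_a: int, n_biased_b: int, n_total_b: int
) -> tuple[float, float]:
    """Two-sided Fisher's exact test comparing biased-gene frequencies.

    The 2x2 table is [[biased_a, total_a - biased_a],
    [biased_b, total_b - biased_b]].  Returns ``(p, conditional odds ratio)``.
    """
    for biased, total in ((n_biased_a, n_total_a), (n_biased_b, n_total_b)):
        if biased < 0 or total < 0 or biased > total:
            raise ValidationError(
                f"inconsistent counts: biased={biased}, total={total}"
            )
    table = [
        [n_biased_a, n_total_a - n_biased_a],
        [n_biased_b, n_total_b - n_biased_b],
    ]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    odds = stats.contingency.odds_ratio(table, kind="conditional").statistic
    return float(p), float(odds)
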