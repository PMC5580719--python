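"""Expression quantification and comparison.

RPKM computation, the [0.1, 20] expression-band filter, super-group exclusive
expression (Venn partition over neocortex / hippocampus / cerebellum),
sample-similarity summaries (PCA and Pearson correlation on log2(RPKM+1)),
and differential expression between adjacent age groups within one region.

The adjacent-age test is a conditional negative-binomial exact test: counts
are library-size normalized, summed per age group, and the first group's sum
is compared with its conditional distribution given the pooled total.  A
common dispersion is estimated by the method of moments across genes; when
the moment estimate is not positive the test reduces to the conditional
binomial (Poisson) exact test.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import REGION_GROUPS, ExpressionMatrix, ValidationError


def rpkm(counts, exonic_length_nt, library_size):
    """Reads per kilobase of exonic length per million mapped reads.

    Vectorized over ``counts``.  ``exonic_length_nt`` and ``library_size``
    must be strictly positive.
    """
    length = np.asarray(exonic_length_nt, dtype=float)
    lib = np.asarray(library_size, dtype=float)
    if np.any(length <= 0):
        raise ValidationError("exonic length must be positive")
    if np.any(lib <= 0):
        raise ValidationError("library size must be positive")
    return np.asarray(counts, dtype=float) / (length / 1e3) / (lib / 1e6)


def expression_band_filter(
    matrix: ExpressionMatrix, low: float = 0.1, high: float = 20.0
) -> pd.Index:
    """Genes whose maximum RPKM across samples lies in ``[low, high]``.

    The band (default 0.1–20) restricts comparisons of lncRNAs and mRNAs to
    a shared moderate-expression regime.
    """
    if low >= high:
        raise ValidationError(f"band filter needs low < high (got {low}, {high})")
    mx = matrix.rpkm.max(axis=1)
    return matrix.gene_ids[((mx >= low) & (mx <= high)).to_numpy()]


def exclusive_expression_sets(
    matrix: ExpressionMatrix,
    grouping: Mapping[str, str] = REGION_GROUPS,
    detect_threshold: float = 0.1,
) -> dict[tuple[str, ...], set[str]]:
    """Venn partition of gene detection over region super-groups.

    A gene is *detected* in a super-group when any member sample's RPKM
    exceeds ``detect_threshold``.  Returns a dict keyed by the sorted tuple
    of super-groups a gene is detected in (singletons are the exclusive
    sets); genes detected nowhere appear under the empty tuple.
    """
    unmapped = set(matrix.samples["region"]) - set(grouping)
    if unmapped:
        raise ValidationError(f"regions not mapped to a super-group: {sorted(unmapped)}")
    groups = sorted(set(grouping.values()))
    rpkm_df = matrix.rpkm
    detected = {}
    for g in groups:
        cols = matrix.sample_ids[
            matrix.samples["region"].map(grouping).to_numpy() == g
        ]
        detected[g] = (rpkm_df[cols] > detect_threshold).any(axis=1)
    partition: dict[tuple[str, ...], set[str]] = {}
    pattern = pd.DataFrame(detected)
    for gene, row in pattern.iterrows():
        key = tuple(g for g in groups if row[g])
        partition.setdefault(key, set()).add(gene)
    return partition


def venn_counts(partition: dict[tuple[str, ...], set[str]]) -> pd.Series:
    keys = sorted(partition, key=lambda k: (len(k), k))
    return pd.Series(
        {("&".join(k) if k else "none"): len(partition[k]) for k in keys},
        name="n_genes",
    )


# ---------------------------------------------------------------------------
# adjacent-age differential expression
# ---------------------------------------------------------------------------


def _moment_dispersion(norm_counts: np.ndarray, groups: Sequence[np.ndarray]) -> float:
    """Common NB dispersion by the method of moments pooled across genes.

    For each gene and group with mean m and variance v the moment relation
    v = m + phi * m^2 gives phi = (v - m) / m^2; the pooled estimate uses
    summed numerators and denominators so large-mean genes dominate less
    erratically than a per-gene average.
    """
    num = 0.0
    den = 0.0
    for idx in groups:
        if len(idx) < 2:
            continue
        sub = norm_counts[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += float(np.sum(v - m))
        den += float(np.sum(m * m))
    if den <= 0:
        return 0.0
    return num / den


def _conditional_exact_pvalue(
    y1: int, total: int, n1: int, n2: int, dispersion: float, mid_p: bool
) -> float:
    """Exact two-sided p for the first group's sum given the pooled total.

    Sums of NB(mu, phi) counts over n replicates are NB with mean n*mu and
    size n/phi; conditioning on the total gives a discrete distribution over
    y1 in 0..total whose two-sided p sums probabilities no larger than the
    observed outcome's.  ``mid_p`` counts only half the probability of
    outcomes exactly as likely as the observed one, removing the conservative
    bias of discrete exact tests.
    """
    if total == 0:
        return 1.0
    k = np.arange(total + 1)
    if dispersion > 0:
        mu = total / (n1 + n2)
        r1, r2 = n1 / dispersion, n2 / dispersion
        m1, m2 = n1 * mu, n2 * mu
        logw = stats.nbinom.logpmf(k, r1, r1 / (r1 + m1)) + stats.nbinom.logpmf(
            total - k, r2, r2 / (r2 + m2)
        )
        logw -= logw.max()
        w = np.exp(logw)
        probs = w / w.sum()
    else:
        probs = stats.binom.pmf(k, total, n1 / (n1 + n2))
    p_obs = probs[y1]
    tol = 1e-12 * max(p_obs, 1e-300)
    below = probs < p_obs - tol
    equal = np.abs(probs - p_obs) <= tol
    if mid_p:
        return float(probs[below].sum() + 0.5 * probs[equal].sum())
    return float(min(1.0, probs[below].sum() + probs[equal].sum()))


def adjacent_age_de(
    matrix: ExpressionMatrix,
    region: str,
    age_pair: tuple[int, int],
    alpha: float = 0.01,
    min_lfc: float = 1.0,
    mid_p: bool = True,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Differential expression between two adjacent age groups in one region.

    Returns a DataFrame with columns ``gene_id, region, age_low, age_high,
    log2_fold_change, p_value, significant``.  The fold change is
    (mean normalized count older + 0.5) over (younger + 0.5), log2.

    ``mid_p`` (default) reports mid-p values, which are calibrated
    (approximately uniform under the null); set it to False for the strictly
    conservative exact p, under which identical groups score exactly 1.
    """
    meta = matrix.samples
    if region not in set(meta["region"]):
        raise ValidationError(f"region {region!r} absent from the design")
    a_lo, a_hi = age_pair
    idx1 = np.flatnonzero((meta["region"] == region) & (meta["age"] == a_lo))
    idx2 = np.flatnonzero((meta["region"] == region) & (meta["age"] == a_hi))
    if len(idx1) == 0 or len(idx2) == 0:
        raise ValidationError(
            f"no samples for region {region} at ages {age_pair}"
        )
    counts = matrix.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    norm = counts * (lib.mean() / lib)[None, :]

    if dispersion is None:
        # common dispersion pooled over every (region, age) replicate cell of
        # the whole experiment, not just the contrasted samples: the moment
        # estimate from a single 2-vs-2 contrast is too noisy to calibrate on
        cells = [
            np.flatnonzero((meta["region"] == r) & (meta["age"] == a))
            for r, a in meta.groupby(["region", "age"]).groups
        ]
        dispersion = _moment_dispersion(norm, cells)
    n1, n2 = len(idx1), len(idx2)
    mean1 = norm[:, idx1].mean(axis=1)
    mean2 = norm[:, idx2].mean(axis=1)
    lfc = np.log2((mean2 + 0.5) / (mean1 + 0.5))

    y1 = np.rint(norm[:, idx1].sum(axis=1)).astype(np.int64)
    y2 = np.rint(norm[:, idx2].sum(axis=1)).astype(np.int64)
    pvals = np.array(
        [
            _conditional_exact_pvalue(a, a + b, n1, n2, dispersion, mid_p)
            for a, b in zip(y1, y2)
        ]
    )
    out = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "region": region,
            "age_low": a_lo,
            "age_high": a_hi,
            "log2_fold_change": lfc,
            "p_value": pvals,
            "significant": (pvals < alpha) & (np.abs(lfc) >= min_lfc),
        }
    )
    return out


def adjacent_age_de_all(
    matrix: ExpressionMatrix,
    ages: Sequence[int] = (1, 4, 10, 20),
    **kwargs,
) -> pd.DataFrame:
    """Run :func:`adjacent_age_de` for every region and adjacent age pair."""
    frames = []
    for region in sorted(set(matrix.samples["region"])):
        for a_lo, a_hi in zip(ages, ages[1:]):
            frames.append(adjacent_age_de(matrix, region, (a_lo, a_hi), **kwargs))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# sample similarity
# ---------------------------------------------------------------------------


def sample_similarity(
    matrix: ExpressionMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PCA coordinates and sample-sample Pearson correlations.

    Both are computed on log2(RPKM+1) with genes centered.  Returns
    ``(pca_coords, correlation)`` where ``pca_coords`` has one row per
    sample (columns PC1..PCk) and ``correlation`` is the symmetric sample
    correlation matrix with unit diagonal.
    """
    if matrix.counts.shape[1] < 2:
        raise ValidationError("sample similarity needs >= 2 samples")
    log_expr = matrix.log_rpkm().to_numpy()
    if np.allclose(log_expr.std(axis=1).sum(), 0.0):
        raise ValidationError("expression matrix is constant; no variance to analyze")
    from sklearn.decomposition import PCA

    centered = log_expr - log_expr.mean(axis=1, keepdims=True)
    k = min(n_components, matrix.counts.shape[1] - 1)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(centered.T)
    coords_df = pd.DataFrame(
        coords,
        index=matrix.sample_ids,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    coords_df.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(log_expr.T)
    corr_df = pd.DataFrame(corr, index=matrix.sample_ids, columns=matrix.sample_ids)
    return coords_df, corr_df
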