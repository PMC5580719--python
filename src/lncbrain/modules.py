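"""WGCNA-style co-expression module detection and classification.

Pipeline: soft-thresholded absolute-correlation adjacency, topological
overlap matrix (TOM), average-linkage hierarchical clustering on 1 - TOM
with a static cut, module eigengenes as first principal components, and a
variance-decomposition classification of each module into spatiotemporal
(region-driven), tempo-spatial (age-driven), or sex-temporal (sex-by-age
driven).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core_io import ValidationError


def _corr_abs(expr: np.ndarray) -> np.ndarray:
    """|Pearson correlation| between rows (genes) of expr."""
    sd = expr.std(axis=1)
    if (sd == 0).any():
        n_bad = int((sd == 0).sum())
        raise ValidationError(
            f"{n_bad} constant gene(s): correlation undefined; filter them first"
        )
    c = np.corrcoef(expr)
    np.fill_diagonal(c, 0.0)
    return np.clip(np.abs(c), 0.0, 1.0)


def adjacency(expr: np.ndarray, beta: float) -> np.ndarray:
    """Unsigned soft-threshold adjacency |cor|^beta with zero diagonal."""
    return _corr_abs(np.asarray(expr, dtype=float)) ** beta


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution fit (WGCNA criterion).

    Connectivities are binned, and log10 frequency is regressed on log10
    mean connectivity per bin.  Returns R^2 when the slope is negative
    (scale-free-like decay), else 0.
    """
    k = connectivity[connectivity > 0]
    if k.size < 4:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * np.asarray(xs) + intercept
    ss_res = float(np.sum((np.asarray(ys) - pred) ** 2))
    ss_tot = float(np.sum((np.asarray(ys) - np.mean(ys)) ** 2))
    if ss_tot == 0:
        return 0.0
    r2 = 1.0 - ss_res / ss_tot
    return r2 if slope < 0 else 0.0


def pick_soft_threshold(
    expr,
    candidate_betas=(1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14, 16),
    target_r2: float = 0.8,
) -> int:
    """Smallest soft power whose network is approximately scale-free.

    Evaluates the signed scale-free fit R^2 at each candidate power and
    returns the smallest one reaching ``target_r2``; if none does, the power
    with the best fit is returned with a warning.
    """
    betas = list(candidate_betas)
    if len(betas) < 2:
        raise ValidationError("need at least 2 candidate powers")
    expr = np.asarray(expr, dtype=float)
    if expr.shape[0] < 20:
        raise ValidationError("soft-threshold selection needs >= 20 genes")
    corr = _corr_abs(expr)
    fits = {}
    for beta in betas:
        a = corr ** beta
        fits[beta] = scale_free_fit(a.sum(axis=1))
    for beta in sorted(betas):
        if fits[beta] >= target_r2:
            return beta
    best = max(sorted(betas), key=lambda b: fits[b])
    warnings.warn(
        f"no candidate power reached scale-free R^2 {target_r2}; "
        f"using beta={best} (R^2={fits[best]:.3f})",
        stacklevel=2,
    )
    return best


def tom_similarity(adjacency_matrix: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap: w_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    ``l_ij`` counts shared neighborhood weight, so genes connected to the
    same partners score high even if weakly connected directly.  The input
    must be symmetric with entries in [0, 1] and zero diagonal; the output
    has unit diagonal by convention.
    """
    a = np.asarray(adjacency_matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValidationError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    if not np.allclose(np.diag(a), 0.0):
        raise ValidationError("adjacency diagonal must be zero")
    k = a.sum(axis=1)
    shared = a @ a  # diagonal of a is 0, so u = i, j terms vanish
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


@dataclass
class ModuleSet:
    """Result of module detection.

    ``labels`` maps gene id -> integer module label; 0 collects genes in no
    module.  ``eigengenes`` is a modules x samples DataFrame of unit-norm
    first principal components, sign-oriented to correlate positively with
    the module's mean expression.
    """

    labels: pd.Series
    eigengenes: pd.DataFrame
    beta: float
    variance_explained: dict[int, float] = field(default_factory=dict)

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {0})

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def genes_in(self, module_id: int) -> pd.Index:
        return self.labels.index[self.labels == module_id]


def _eigengene(sub: np.ndarray) -> tuple[np.ndarray, float]:
    """First PC over samples of the per-gene standardized submatrix."""
    sd = sub.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    var_explained = float(s[0] ** 2 / np.sum(s ** 2)) if s.sum() > 0 else 0.0
    mean_profile = z.mean(axis=0)
    orient = np.dot(eig, mean_profile)
    if orient < 0 or (orient == 0 and eig.sum() < 0):
        eig = -eig
    return eig, var_explained


def detect_modules(
    expr: pd.DataFrame,
    beta: float | None = 4,
    min_module_size: int = 30,
    cut_height: float = 0.95,
) -> ModuleSet:
    """Detect co-expression modules on a genes x samples expression frame.

    ``expr`` should be log2(RPKM+1) of the gene subset of interest.  The
    dendrogram (average linkage on 1 - TOM) is cut statically at
    ``cut_height``; clusters smaller than ``min_module_size`` fall into
    label 0.  Module labels are assigned by decreasing size (1 = largest).

    The defaults (soft power 4, cut height 0.95) suit unsigned TOM
    dissimilarities, which concentrate near 1 for moderately correlated
    modules: a moderate power keeps within-module overlap well above the
    between-module background, and the cut sits between the two.  When
    ``beta`` is None it is chosen by :func:`pick_soft_threshold`.
    """
    genes = expr.index
    x = expr.to_numpy(dtype=float)
    if x.shape[0] < min_module_size:
        labels = pd.Series(0, index=genes)
        return ModuleSet(labels=labels, eigengenes=pd.DataFrame(columns=expr.columns), beta=float(beta or 1))
    if beta is None:
        beta = pick_soft_threshold(x)
    a = adjacency(x, beta)
    tom = tom_similarity(a)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    keep = sizes.index[sizes >= min_module_size]
    order = sorted(keep, key=lambda c: (-sizes[c], c))
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series([remap.get(c, 0) for c in raw], index=genes)

    eigs = {}
    var_exp = {}
    for mod in sorted(remap.values()):
        sub = x[(labels == mod).to_numpy()]
        eig, ve = _eigengene(sub)
        eigs[mod] = eig
        var_exp[mod] = ve
    eigengenes = pd.DataFrame(eigs, index=expr.columns).T
    return ModuleSet(
        labels=labels, eigengenes=eigengenes, beta=float(beta),
        variance_explained=var_exp,
    )


# ---------------------------------------------------------------------------
# module classification
# ---------------------------------------------------------------------------


def _eta_squared(values: np.ndarray, groups: pd.Series) -> float:
    """One-way variance explained (between-group SS / total SS)."""
    total = float(np.sum((values - values.mean()) ** 2))
    if total == 0:
        return 0.0
    between = 0.0
    for _, idx in groups.groupby(groups).groups.items():
        sub = values[groups.index.get_indexer(idx)]
        between += len(sub) * (sub.mean() - values.mean()) ** 2
    return float(np.clip(between / total, 0.0, 1.0))


def classify_modules(
    module_set: ModuleSet, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Classify each module by the design factor driving its eigengene.

    For every module eigengene, the variance explained (eta^2) is computed
    for brain region, for age, and for the sex-by-age combination *beyond*
    age (its incremental eta^2 over the age main effect, so a purely
    age-driven eigengene does not register as sex-driven).  Classes:

    - ``sex-temporal`` when the incremental sex-by-age eta^2 is at least as
      large as both the region and the age eta^2;
    - otherwise ``spatiotemporal`` when region dominates age, else
      ``tempo-spatial``.
    """
    n_cells = metadata.groupby(["region", "age", "sex"], observed=True).size()
    expected = (
        len(set(metadata["region"])) * len(set(metadata["age"])) * len(set(metadata["sex"]))
    )
    if len(n_cells) < expected:
        warnings.warn(
            "incomplete design: eta^2 computed on available cells", stacklevel=2
        )
    rows = []
    meta = metadata.loc[module_set.eigengenes.columns]
    region = meta["region"]
    age = meta["age"].astype(str)
    sexage = meta["sex"].astype(str) + ":" + age
    for mod in module_set.module_ids:
        eig = module_set.eigengenes.loc[mod].to_numpy()
        eta_region = _eta_squared(eig, region)
        eta_age = _eta_squared(eig, age)
        eta_sexage = max(0.0, _eta_squared(eig, sexage) - eta_age)
        if eta_sexage >= eta_region and eta_sexage >= eta_age:
            cls = "sex-temporal"
        elif eta_region >= eta_age:
            cls = "spatiotemporal"
        else:
            cls = "tempo-spatial"
        rows.append(
            {
                "module": mod,
                "class": cls,
                "eta2_region": eta_region,
                "eta2_age": eta_age,
                "eta2_sex_age": eta_sexage,
                "n_genes": int((module_set.labels == mod).sum()),
            }
        )
    return pd.DataFrame(rows)
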