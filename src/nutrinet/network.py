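"""Signed-hybrid weighted gene co-expression network analysis.

Builds the classic pipeline: Pearson correlation -> signed-hybrid
adjacency a_ij = max(cor, 0)^beta -> topological overlap matrix (TOM) ->
average-linkage clustering of 1 - TOM -> size-filtered modules labelled by
the canonical color sequence -> module eigengenes (first principal
component of the standardized module block) -> eigengene merging at a
dissimilarity cut height -> module-trait correlation, eigengene-based
connectivity (kME), gene significance (GS) and intramodular connectivity.

Module detection uses a static tree cut plus the minimum-size rule; the
cut algorithm is configurable but intentionally simple, since only the
minimum module size (30) and the eigengene merge height (0.20, i.e. merge
eigengenes correlated above 0.80) are pinned-down conventions here.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "COLOR_SEQUENCE",
    "GREY",
    "soft_threshold_scan",
    "scale_free_fit",
    "signed_hybrid_adjacency",
    "tom_similarity",
    "detect_modules",
    "module_eigengenes",
    "merge_modules",
    "module_trait_correlation",
    "gene_statistics",
    "intramodular_connectivity",
    "sample_outlier_report",
    "CoexpressionNetwork",
]

GREY = "grey"

#: Canonical module color order (size rank 1 = turquoise, 2 = blue, ...).
COLOR_SEQUENCE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown",
    "steelblue", "paleturquoise", "violet", "darkolivegreen",
    "darkmagenta",
)


def _as_expr(expr) -> tuple[np.ndarray, pd.Index]:
    """Coerce samples x genes input to (array, gene index)."""
    if isinstance(expr, pd.DataFrame):
        return expr.to_numpy(float), expr.columns
    arr = np.asarray(expr, float)
    return arr, pd.RangeIndex(arr.shape[1])


def signed_hybrid_adjacency(expr, beta: int = 8) -> pd.DataFrame:
    """Signed-hybrid adjacency: a_ij = max(cor(x_i, x_j), 0)^beta.

    Negative correlations are zeroed rather than folded in, so modules are
    groups of positively co-regulated genes. Diagonal is 1.
    """
    values, genes = _as_expr(expr)
    sd = values.std(axis=0)
    if (sd == 0).any():
        bad = list(np.asarray(genes)[sd == 0][:10])
        raise ValueError(f"zero-variance genes: {bad}")
    corr = np.corrcoef(values, rowvar=False)
    adj = np.clip(corr, 0.0, 1.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=genes, columns=genes)


def tom_similarity(adjacency) -> pd.DataFrame:
    """Topological overlap: shared-neighborhood-weighted similarity.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with connectivity k excluding the diagonal; TOM_ii = 1.
    """
    if isinstance(adjacency, pd.DataFrame):
        genes = adjacency.index
        a = adjacency.to_numpy(float)
    else:
        a = np.asarray(adjacency, float)
        genes = pd.RangeIndex(a.shape[0])
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency values must lie in [0, 1]")
    # off-diagonal shared-neighbor sums; (A @ A)_ij counts u = i and u = j,
    # each contributing a_ij when the diagonal is 1
    shared = a @ a - 2.0 * a
    k = a.sum(axis=0) - np.diag(a)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + a) / denom
    tom = np.where(denom > 0, tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=genes, columns=genes)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of a connectivity vector.

    Bins k into ``n_bins`` equal-width intervals, regresses log10 of the
    bin frequency p(k) on log10 of the bin mean connectivity, and returns
    ``(R^2 * sign(-slope), slope)`` — positive only when the degree
    distribution decays.
    """
    k = np.asarray(k, float)
    k = k[k > 0]
    if len(np.unique(k)) < n_bins:
        warnings.warn("fewer distinct connectivities than bins; reducing bins")
        n_bins = max(2, len(np.unique(k)))
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    dk, pk = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            dk.append(k[mask].mean())
            pk.append(mask.mean())
    log_k, log_p = np.log10(dk), np.log10(pk)
    if len(log_k) < 3 or np.allclose(log_k, log_k[0]):
        return 0.0, 0.0
    slope, _, r, _, _ = stats.linregress(log_k, log_p)
    return float(r**2 * np.sign(-slope)), float(slope)


def soft_threshold_scan(
    expr,
    powers=tuple(range(1, 21)),
    fit_threshold: float = 0.8,
    default_power: int = 8,
) -> tuple[pd.DataFrame, int]:
    """Scan soft-threshold powers for scale-free topology.

    For each power the signed-hybrid connectivities are computed and the
    scale-free fit index evaluated; the recommended power is the smallest
    one with fit >= ``fit_threshold``, falling back to ``default_power``.
    Constant genes are dropped before the scan.
    """
    values, _ = _as_expr(expr)
    values = values[:, values.std(axis=0) > 0]
    corr = np.clip(np.corrcoef(values, rowvar=False), 0.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    rows = []
    for power in powers:
        k = (corr**power).sum(axis=0)
        fit, slope = scale_free_fit(k)
        rows.append(
            {
                "power": power,
                "fit": fit,
                "slope": slope,
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    table = pd.DataFrame(rows)
    ok = table[table["fit"] >= fit_threshold]
    recommended = int(ok["power"].iloc[0]) if len(ok) else int(default_power)
    return table, recommended


def detect_modules(
    diss,
    min_module_size: int = 30,
    cut_height: float = 0.95,
) -> pd.Series:
    """Average-linkage clustering of a dissimilarity matrix into modules.

    The tree is cut statically at ``cut_height`` (default 0.95, low
    enough that chance-level topological overlap does not chain background
    genes onto real modules); clusters smaller than
    ``min_module_size`` become unassigned (grey). Surviving clusters are
    labelled with the canonical colors by decreasing size (ties broken by
    first member position).
    """
    if isinstance(diss, pd.DataFrame):
        genes = diss.index
        d = diss.to_numpy(float)
    else:
        d = np.asarray(diss, float)
        genes = pd.RangeIndex(d.shape[0])
    if d.min() < -1e-10 or d.max() > 1 + 1e-10:
        raise ValueError("dissimilarity must lie in [0, 1]")
    z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")

    labels = pd.Series(GREY, index=genes, name="module", dtype=object)
    sizes = pd.Series(raw).value_counts()
    ordered = sorted(
        (c for c in sizes.index if sizes[c] >= min_module_size),
        key=lambda c: (-sizes[c], int(np.argmax(raw == c))),
    )
    if not ordered:
        warnings.warn("no module reached the minimum size; all genes grey")
    for rank, cluster in enumerate(ordered):
        color = (
            COLOR_SEQUENCE[rank]
            if rank < len(COLOR_SEQUENCE)
            else f"module{rank + 1}"
        )
        labels.iloc[np.where(raw == cluster)[0]] = color
    return labels


def module_eigengenes(
    expr, partition: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """First principal component per module ("eigengene").

    Genes are z-scored across samples; the eigengene is the leading left
    singular vector of the samples x genes block, unit norm, oriented so
    that its correlation with the module's average expression profile is
    non-negative. Returns (eigengenes samples x modules, variance
    explained per module). Constant genes are dropped with a warning.
    """
    if not isinstance(expr, pd.DataFrame):
        expr = pd.DataFrame(np.asarray(expr, float))
    me: dict[str, np.ndarray] = {}
    var_explained: dict[str, float] = {}
    for module in [m for m in partition.unique() if m != GREY]:
        members = partition.index[partition == module]
        block = expr[members].to_numpy(float)
        sd = block.std(axis=0, ddof=1)
        if (sd == 0).any():
            warnings.warn(f"dropping constant genes in module {module!r}")
            block = block[:, sd > 0]
            sd = sd[sd > 0]
        if block.shape[1] < 2:
            raise ValueError(f"module {module!r} has < 2 usable genes")
        z = (block - block.mean(axis=0)) / sd
        u, s, _ = np.linalg.svd(z, full_matrices=False)
        vec = u[:, 0]
        mean_profile = z.mean(axis=1)
        if np.dot(vec, mean_profile - mean_profile.mean()) < 0:
            vec = -vec
        me[module] = vec
        var_explained[module] = float(s[0] ** 2 / (s**2).sum())
    me_df = pd.DataFrame(me, index=expr.index)
    return me_df, pd.Series(var_explained, name="variance_explained")


def merge_modules(
    expr,
    partition: pd.Series,
    cut_height: float = 0.20,
    max_iter: int = 100,
) -> tuple[pd.Series, pd.DataFrame, pd.Series]:
    """Merge modules whose eigengenes are highly correlated.

    Iteratively clusters eigengenes by dissimilarity 1 - cor, merges every
    group joined below ``cut_height`` (0.20 merges eigengenes with
    r > 0.80) into the largest constituent's color, recomputes eigengenes
    and repeats until no pair remains below the cut. Returns the merged
    partition, eigengenes and variance explained.
    """
    partition = partition.copy()
    for _ in range(max_iter):
        me, var_exp = module_eigengenes(expr, partition)
        if me.shape[1] <= 1:
            return partition, me, var_exp
        corr = np.corrcoef(me.to_numpy(float), rowvar=False)
        diss = 1.0 - corr
        off = diss[np.triu_indices_from(diss, k=1)]
        if (off >= cut_height).all():
            return partition, me, var_exp
        z = linkage(squareform(diss, checks=False), method="average")
        groups = fcluster(z, t=cut_height, criterion="distance")
        sizes = partition.value_counts()
        for g in np.unique(groups):
            members = [me.columns[i] for i in np.where(groups == g)[0]]
            if len(members) < 2:
                continue
            target = max(members, key=lambda m: (sizes.get(m, 0), m))
            partition[partition.isin(members)] = target
    warnings.warn("module merging did not converge")
    me, var_exp = module_eigengenes(expr, partition)
    return partition, me, var_exp


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(x)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0 or n < 3:
        return np.nan, np.nan
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return r, float(2.0 * stats.t.sf(abs(t), n - 2))


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of each eigengene with each numeric trait.

    p-values from the t-distribution with n - 2 degrees of freedom.
    Constant traits give missing values.
    """
    if len(eigengenes) < 3:
        raise ValueError("need at least 3 samples")
    r = pd.DataFrame(index=eigengenes.columns, columns=traits.columns, dtype=float)
    p = r.copy()
    for module in eigengenes.columns:
        for trait in traits.columns:
            r.loc[module, trait], p.loc[module, trait] = _pearson_with_p(
                eigengenes[module].to_numpy(float),
                traits[trait].to_numpy(float),
            )
    return r, p


def gene_statistics(
    expr, eigengenes: pd.DataFrame, trait
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Per-gene kME matrix, gene significance and primary module.

    kME_im = cor(x_i, ME_m) (eigengene-based connectivity / module
    membership); GS_i = cor(x_i, trait); the primary module of a gene is
    the one maximizing kME. Constant genes get missing values.
    """
    if not isinstance(expr, pd.DataFrame):
        expr = pd.DataFrame(np.asarray(expr, float))
    x = expr.to_numpy(float)
    me = eigengenes.to_numpy(float)
    t = np.asarray(trait, float)

    def _cols_cor(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        az = a - a.mean(axis=0)
        bz = b - b.mean(axis=0)
        denom = np.outer(
            np.sqrt((az**2).sum(axis=0)), np.sqrt((bz**2).sum(axis=0))
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(denom > 0, az.T @ bz / denom, np.nan)

    kme = pd.DataFrame(
        _cols_cor(x, me), index=expr.columns, columns=eigengenes.columns
    )
    gs = pd.Series(
        _cols_cor(x, t[:, None])[:, 0], index=expr.columns, name="GS"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)  # all-NaN rows
        primary = kme.idxmax(axis=1)
    primary.name = "primary_module"
    return kme, gs, primary


def intramodular_connectivity(
    adjacency: pd.DataFrame, partition: pd.Series
) -> pd.Series:
    """Within-module connectivity kWithin_i = sum of adjacencies to the
    gene's module co-members (self excluded); grey genes are missing."""
    kwithin = pd.Series(np.nan, index=adjacency.index, name="kWithin")
    for module in [m for m in partition.unique() if m != GREY]:
        members = partition.index[partition == module]
        block = adjacency.loc[members, members].to_numpy(float)
        kwithin[members] = block.sum(axis=1) - np.diag(block)
    return kwithin


def sample_outlier_report(expr, threshold_sd: float = 2.5) -> pd.DataFrame:
    """Report-only outlier screen: average-linkage clustering height of
    each sample (Euclidean), flagged when beyond ``threshold_sd`` standard
    deviations of the mean merge height. Nothing is removed."""
    if not isinstance(expr, pd.DataFrame):
        expr = pd.DataFrame(np.asarray(expr, float))
    from scipy.spatial.distance import pdist

    d = pdist(expr.to_numpy(float))
    z = linkage(d, method="average")
    n = len(expr)
    # height at which each sample first merges
    heights = np.zeros(n)
    for a, b, h, _ in z:
        for leaf in (int(a), int(b)):
            if leaf < n and heights[leaf] == 0:
                heights[leaf] = h
    mu, sd = heights.mean(), heights.std()
    return pd.DataFrame(
        {
            "sample_id": np.asarray(expr.index),
            "merge_height": heights,
            "outlier": (heights > mu + threshold_sd * sd) if sd > 0 else False,
        }
    )


class CoexpressionNetwork(ClusterMixin, BaseEstimator):
    """Signed-hybrid weighted co-expression network as a clusterer.

    ``fit(X)`` takes samples x genes expression (already filtered and
    log-transformed) and produces:

    - ``labels_`` / ``partition_``: module color per gene (grey =
      unassigned), after eigengene merging;
    - ``eigengenes_`` (samples x modules) and ``variance_explained_``;
    - ``kwithin_``: intramodular connectivity;
    - ``adjacency_``, kept for hub-gene ranking downstream.

    Defaults follow the conventions used throughout this package:
    soft-threshold power beta = 8, minimum module size 30, eigengene merge
    height 0.20 and a static tree cut at 0.99.
    """

    def __init__(
        self,
        beta: int = 8,
        min_module_size: int = 30,
        merge_cut_height: float = 0.20,
        cut_height: float = 0.95,
        keep_tom: bool = False,
    ) -> None:
        self.beta = beta
        self.min_module_size = min_module_size
        self.merge_cut_height = merge_cut_height
        self.cut_height = cut_height
        self.keep_tom = keep_tom

    def fit(self, X, y=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, float))
        self.feature_names_in_ = np.asarray(X.columns)
        adjacency = signed_hybrid_adjacency(X, beta=self.beta)
        tom = tom_similarity(adjacency)
        diss = 1.0 - tom
        partition = detect_modules(
            diss,
            min_module_size=self.min_module_size,
            cut_height=self.cut_height,
        )
        if (partition != GREY).any():
            partition, me, var_exp = merge_modules(
                X, partition, cut_height=self.merge_cut_height
            )
        else:
            me = pd.DataFrame(index=X.index)
            var_exp = pd.Series(dtype=float)
        self.adjacency_ = adjacency
        if self.keep_tom:
            self.tom_ = tom
        self.partition_ = partition
        self.labels_ = partition.to_numpy()
        self.eigengenes_ = me
        self.variance_explained_ = var_exp
        self.kwithin_ = intramodular_connectivity(adjacency, partition)
        return self

    def module_trait(self, traits: pd.DataFrame):
        """Module-trait Pearson correlations and p-values."""
        return module_trait_correlation(self.eigengenes_, traits)

    def gene_statistics(self, X, trait):
        """kME, GS and primary module for the fitted eigengenes."""
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, float))
        return gene_statistics(X, self.eigengenes_, trait)
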