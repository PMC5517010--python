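"""Negative-binomial two-group differential expression.

A deliberately transparent NB Wald test: median-of-ratios size factors,
method-of-moments dispersion pooled within groups, delta-method standard
error for the log2 fold-change and Benjamini-Hochberg adjustment. It is
count-model faithful but *not* bit-compatible with shrinkage-based DE
packages (no dispersion shrinkage, outlier replacement or independent
filtering) — the focus of this package is the downstream integration.

The four design contrasts of the 2x2 trial are fixed:

========== ======================= =======================
name       baseline                delta
========== ======================= =======================
selection  non_selected / PM       selected / PM
diet       selected / FM           selected / PM
strain     non_selected / FM       selected / FM
enteritis  non_selected / FM       non_selected / PM
========== ======================= =======================
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Contrast",
    "CONTRASTS",
    "estimate_size_factors",
    "NegativeBinomialWald",
    "nb_wald_contrast",
    "bh_adjust",
    "run_design_contrasts",
    "venn_overlap",
]


@dataclass(frozen=True)
class Contrast:
    name: str
    baseline: tuple[str, str]  # (strain, diet)
    delta: tuple[str, str]


CONTRASTS: tuple[Contrast, ...] = (
    Contrast("selection", ("non_selected", "PM"), ("selected", "PM")),
    Contrast("diet", ("selected", "FM"), ("selected", "PM")),
    Contrast("strain", ("non_selected", "FM"), ("selected", "FM")),
    Contrast("enteritis", ("non_selected", "FM"), ("non_selected", "PM")),
)


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors, geometric mean 1.

    The reference is the per-gene geometric mean over samples, restricted
    to genes expressed in every sample; each sample's factor is the median
    ratio to that reference. Falls back to total-count ratios (with a
    warning) when no gene is expressed everywhere.
    """
    values = counts.to_numpy(float)
    all_pos = (values > 0).all(axis=1)
    if all_pos.any():
        logs = np.log(values[all_pos])
        ref = logs.mean(axis=1)
        factors = np.exp(np.median(logs - ref[:, None], axis=0))
    else:
        warnings.warn(
            "no gene expressed in all samples; using total-count ratios"
        )
        totals = values.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("sample with zero total counts")
        factors = totals
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def bh_adjust(pvals) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries (untested genes) are left NaN and do not count toward the
    number of tests.
    """
    arr = np.asarray(pvals, float)
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    if mask.any():
        if ((arr[mask] < 0) | (arr[mask] > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[mask] = multipletests(arr[mask], method="fdr_bh")[1]
    if isinstance(pvals, pd.Series):
        return pd.Series(out, index=pvals.index)
    return out


class NegativeBinomialWald(BaseEstimator):
    """Two-group NB Wald test in a scikit-learn estimator shell.

    Parameters
    ----------
    pseudocount : added to normalized group means before the log2 ratio,
        stabilizing fold-changes of lowly expressed genes.
    alpha : significance level applied to BH-adjusted p-values.
    min_dispersion : floor for the method-of-moments dispersion.
    reference : "t" (default) refers the Wald statistic to a t
        distribution with n_A + n_B - 2 degrees of freedom, which keeps
        the test calibrated at small group sizes where the plug-in
        dispersion is noisy; "normal" is the large-sample limit.

    After ``fit(X, y)`` — X of shape (n_samples, n_genes), y with exactly
    two labels (baseline = ``baseline`` or the lexicographically smaller
    label) — results are in ``results_``: log2fc (delta vs baseline),
    base_mean, se, stat, pvalue, padj, tested, significant.
    """

    def __init__(
        self,
        pseudocount: float = 0.5,
        alpha: float = 0.05,
        min_dispersion: float = 1e-8,
        baseline: str | None = None,
        reference: str = "t",
    ) -> None:
        self.pseudocount = pseudocount
        self.alpha = alpha
        self.min_dispersion = min_dispersion
        self.baseline = baseline
        self.reference = reference

    def fit(self, X, y, size_factors=None):
        if isinstance(X, pd.DataFrame):
            genes = np.asarray(X.columns)
            values = X.to_numpy(float)
        else:
            values = np.asarray(X, float)
            genes = np.arange(values.shape[1])
        y = np.asarray(y)
        labels = sorted(pd.unique(y))
        if len(labels) != 2:
            raise ValueError("y must contain exactly two groups")
        base = self.baseline if self.baseline is not None else labels[0]
        if base not in labels:
            raise ValueError(f"baseline {base!r} not found in y")
        other = [lab for lab in labels if lab != base][0]
        mask_a = y == base
        mask_b = y == other
        if mask_a.sum() < 2 or mask_b.sum() < 2:
            raise ValueError("each group needs >= 2 samples")

        counts = values.T  # genes x samples
        if size_factors is None:
            sf = estimate_size_factors(
                pd.DataFrame(counts, index=genes)
            ).to_numpy()
        else:
            sf = np.asarray(size_factors, float)
        q = counts / sf[None, :]

        qa, qb = q[:, mask_a], q[:, mask_b]
        na, nb = qa.shape[1], qb.shape[1]
        mu_a, mu_b = qa.mean(axis=1), qb.mean(axis=1)
        # pooled within-group method-of-moments dispersion
        var_pool = (
            (na - 1) * qa.var(axis=1, ddof=1) + (nb - 1) * qb.var(axis=1, ddof=1)
        ) / (na + nb - 2)
        mu_pool = q.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            disp = (var_pool - mu_pool) / mu_pool**2
        disp = np.where(np.isfinite(disp), disp, self.min_dispersion)
        disp = np.maximum(disp, self.min_dispersion)

        c = self.pseudocount
        log2fc = np.log2(mu_b + c) - np.log2(mu_a + c)
        var_mu_a = (mu_a + disp * mu_a**2) / na
        var_mu_b = (mu_b + disp * mu_b**2) / nb
        ln2sq = np.log(2.0) ** 2
        se = np.sqrt(
            (var_mu_a / (mu_a + c) ** 2 + var_mu_b / (mu_b + c) ** 2) / ln2sq
        )

        tested = (counts.sum(axis=1) > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, log2fc / se, 0.0)
        if self.reference == "t":
            tail = stats.t.sf(np.abs(z), na + nb - 2)
        elif self.reference == "normal":
            tail = stats.norm.sf(np.abs(z))
        else:
            raise ValueError("reference must be 't' or 'normal'")
        pvalue = np.where(tested, 2.0 * tail, np.nan)
        pvalue = np.where(tested & (se == 0) & (log2fc == 0), 1.0, pvalue)
        log2fc = np.where(tested, log2fc, 0.0)
        padj = bh_adjust(pvalue)

        self.groups_ = (base, other)
        self.size_factors_ = pd.Series(sf, index=pd.RangeIndex(len(sf))
                                       if isinstance(X, np.ndarray) else pd.Index(np.asarray(X.index)))
        res = pd.DataFrame(
            {
                "log2fc": log2fc,
                "base_mean": mu_pool,
                "se": se,
                "stat": z,
                "pvalue": np.where(tested, pvalue, 1.0),
                "padj": padj,
                "tested": tested,
            },
            index=pd.Index(genes, name="gene"),
        )
        res["significant"] = res["padj"].lt(self.alpha).fillna(False) & res["tested"]
        self.results_ = res
        return self

    def fit_predict(self, X, y, **kwargs) -> np.ndarray:
        """Fit and return the per-gene significance flags."""
        return self.fit(X, y, **kwargs).results_["significant"].to_numpy()


def nb_wald_contrast(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    group_a: list[str],
    group_b: list[str],
    pseudocount: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Functional wrapper: test group_b (delta) against group_a (baseline)
    on a genes x samples count matrix."""
    cols = list(group_a) + list(group_b)
    y = np.array(["A"] * len(group_a) + ["B"] * len(group_b))
    est = NegativeBinomialWald(
        pseudocount=pseudocount, alpha=alpha, baseline="A"
    )
    est.fit(
        counts[cols].T,
        y,
        size_factors=size_factors.reindex(cols).to_numpy(),
    )
    return est.results_


def run_design_contrasts(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    tissue: str,
    fpkm: pd.DataFrame | None = None,
    alpha: float = 0.05,
    fpkm_threshold: float = 1.0,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Run the four fixed contrasts within one tissue.

    Size factors are estimated once over the tissue's samples. When an
    FPKM matrix is given, the final DE table of each contrast drops genes
    whose mean FPKM over the contrast's samples is below the threshold
    (applied after testing). Returns the per-contrast tables and an
    up/down summary of significant genes.
    """
    sub = samples[samples["tissue"] == tissue]
    groups: dict[tuple[str, str], list[str]] = {}
    for (strain, diet), block in sub.groupby(["strain", "diet"]):
        groups[(strain, diet)] = list(block["sample_id"])
    sf = estimate_size_factors(counts[list(sub["sample_id"])])

    results: dict[str, pd.DataFrame] = {}
    summary = []
    for contrast in CONTRASTS:
        for grp in (contrast.baseline, contrast.delta):
            if grp not in groups:
                raise ValueError(
                    f"missing group {grp} for contrast {contrast.name!r}"
                )
        cols_a = groups[contrast.baseline]
        cols_b = groups[contrast.delta]
        res = nb_wald_contrast(counts, sf, cols_a, cols_b, alpha=alpha)
        if fpkm is not None:
            from .preprocess import filter_fpkm_de

            res = filter_fpkm_de(
                res, fpkm, samples=cols_a + cols_b, threshold=fpkm_threshold
            )
        results[contrast.name] = res
        sig = res[res["significant"]]
        summary.append(
            {
                "contrast": contrast.name,
                "tissue": tissue,
                "n_significant": len(sig),
                "n_up": int((sig["log2fc"] > 0).sum()),
                "n_down": int((sig["log2fc"] < 0).sum()),
            }
        )
    return results, pd.DataFrame(summary)


def venn_overlap(deg_sets: dict[str, set]) -> pd.DataFrame:
    """Exclusive region counts of an n-set Venn diagram.

    One row per non-empty combination of set names, with the number of
    elements belonging to exactly those sets and its percentage of the
    union (one decimal, as printed on Venn figures).
    """
    if len(deg_sets) < 2:
        raise ValueError("need at least 2 sets")
    names = list(deg_sets)
    union: set = set().union(*deg_sets.values())
    rows = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(deg_sets[n] for n in combo))
            outside = set().union(
                *(deg_sets[n] for n in names if n not in combo), set()
            )
            exclusive = inside - outside
            rows.append(
                {
                    "region": "&".join(combo),
                    "n_sets": r,
                    "count": len(exclusive),
                    "percent": round(100.0 * len(exclusive) / len(union), 1)
                    if union
                    else 0.0,
                }
            )
    return pd.DataFrame(rows)
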