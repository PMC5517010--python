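"""Expression-matrix construction and filtering.

Two distinct filtering rules coexist downstream of the same FPKM matrix:
the differential-expression filter drops genes whose mean FPKM over the
contrast's samples falls below 1 *after* testing, while the network filter
drops genes whose FPKM is below 1 in at least 90% of samples *before*
network construction. Network input is additionally variance-stabilized as
log2(FPKM + 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "compute_fpkm",
    "filter_fpkm_de",
    "filter_network_genes",
    "log_transform",
]


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series,
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads.

    FPKM_ij = counts_ij * 1e9 / (length_i * library_size_j).
    """
    lengths = gene_lengths.reindex(counts.index)
    libs = library_sizes.reindex(counts.columns)
    bad_genes = lengths.index[~(lengths > 0) | lengths.isna()]
    if len(bad_genes):
        raise ValueError(
            f"non-positive or missing gene length for: {list(bad_genes[:5])}"
        )
    bad_samples = libs.index[~(libs > 0) | libs.isna()]
    if len(bad_samples):
        raise ValueError(
            f"non-positive or missing library size for: {list(bad_samples[:5])}"
        )
    return counts * 1e9 / np.outer(lengths.to_numpy(), libs.to_numpy())


def filter_fpkm_de(
    de_result: pd.DataFrame,
    fpkm: pd.DataFrame,
    samples: list[str] | None = None,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Drop genes with mean FPKM below `threshold` from a DE table.

    Applied after testing ("lastly removed"): rows are removed, p-values
    are not recomputed. The mean is taken over `samples` (the contrast's
    columns) or over all FPKM columns when not given; genes exactly at the
    threshold are retained (only FPKM < threshold is removed).
    """
    cols = list(fpkm.columns) if samples is None else list(samples)
    common = de_result.index.intersection(fpkm.index)
    if len(common) == 0:
        raise ValueError("DE result and FPKM matrix share no gene ids")
    mean_fpkm = fpkm.loc[common, cols].mean(axis=1)
    keep = mean_fpkm[mean_fpkm >= threshold].index
    return de_result.loc[de_result.index.intersection(keep)]


def filter_network_genes(
    fpkm: pd.DataFrame, frac: float = 0.9, threshold: float = 1.0
) -> pd.DataFrame:
    """Remove genes lowly expressed in at least ``frac`` of samples.

    A gene is removed iff the number of samples with FPKM < threshold is
    >= ceil(frac * n_samples); with 20 samples and frac 0.9 that is 18.
    """
    n = fpkm.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples")
    cutoff = int(np.ceil(frac * n))
    n_low = (fpkm < threshold).sum(axis=1)
    return fpkm.loc[n_low < cutoff]


def log_transform(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Variance-stabilizing transform log2(FPKM + 1)."""
    values = np.asarray(fpkm)
    if (values < 0).any():
        raise ValueError("negative expression values")
    return np.log2(fpkm + 1.0)
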