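"""Synthetic strain-by-diet RNA-seq study generator.

Emulates the structure of a 2 strain x 2 diet x 2 tissue feeding trial in
rainbow trout: per-fish body traits (weight, liver weight, hepatosomatic
index), negative-binomial read counts with planted co-expression modules
that track the diet contrast, flat functional annotation (GO terms, EC
numbers, pathway memberships) and seven-variable histopathology scores of
the distal intestine.

The generative model for expression is a one-factor-per-module latent
model: every planted module m has a per-sample Gaussian factor f_mj whose
correlation with the plant-meal (PM) diet indicator is controlled by the
module's ``trait_correlation``; member genes load on that factor with
uniform loadings in [0.5, 1]. Background genes are independent noise.
All randomness flows from a single integer seed, so identical
configurations give byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModuleSpec",
    "PlantedTerm",
    "SimulationConfig",
    "Annotation",
    "generate_design",
    "generate_counts",
    "generate_annotation",
    "generate_histology",
    "planted_module_genes",
]

STRAINS = ("non_selected", "selected")
DIETS = ("FM", "PM")
TISSUES = ("liver", "muscle")

#: Seven histopathology variables scored on the distal intestine:
#: mucosal fold fusion, lamina propria, sub-epithelial mucosa, supranuclear
#: vacuolization, goblet cells, eosinophilic granulocytes, total
#: inflammatory cells.
HISTOLOGY_VARIABLES = ("MF", "LP", "SM", "SNV", "GC", "EG", "TIC")


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module.

    Parameters
    ----------
    size : number of member genes.
    trait_correlation : Pearson correlation between the module's latent
        factor and the (standardized) PM-diet indicator, in [-1, 1]. A
        nonzero value already implies a diet mean-shift of
        2 * trait_correlation * module_factor_sd * loading log2 units, so
        diet-coupled modules are differentially expressed by construction.
    base_log2fc : additional deterministic diet log2 fold-change added to
        member genes (scaled per gene by its factor loading); 0 leaves
        the diet effect entirely to the factor coupling, which keeps the
        planted gene-diet correlation at its nominal value.
    """

    size: int
    trait_correlation: float
    base_log2fc: float

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("module size must be >= 2")
        if not -1.0 <= self.trait_correlation <= 1.0:
            raise ValueError("trait_correlation must lie in [-1, 1]")


@dataclass(frozen=True)
class PlantedTerm:
    """An annotation term enriched in a chosen gene set."""

    term: str
    category: str
    genes: tuple[str, ...]
    probability: float  # assignment probability inside `genes`


@dataclass(frozen=True)
class SimulationConfig:
    """Full configuration of the synthetic study.

    Defaults mirror the feeding-trial design this package targets: 10 fish
    per strain-by-diet group sampled in two tissues (80 libraries), 5000
    transcripts of which three modules of 100 genes correlate with diet at
    |r| = 0.8 (one positively, two negatively, echoing one up- and two
    down-regulated diet modules), NB dispersion 0.1 and ~1e6 mapped reads
    per library (a desk-scale stand-in for the ~25M of a real run).
    """

    n_fish_per_group: int = 10
    n_genes: int = 5000
    module_specs: tuple[ModuleSpec, ...] = (
        ModuleSpec(100, 0.8, 0.0),
        ModuleSpec(100, -0.8, 0.0),
        ModuleSpec(100, -0.8, 0.0),
    )
    nb_dispersion: float = 0.1
    nonselected_diet_attenuation: float = 0.25
    library_size_mean: float = 1e6
    library_size_sigma: float = 0.2
    gene_length_range: tuple[int, int] = (500, 3000)
    baseline_log2_mean: float = 4.5
    baseline_log2_sd: float = 2.0
    module_factor_sd: float = 1.5
    hsi_mean: float = 1.5
    hsi_sd: float = 0.15
    hsi_diet_correlation: float = -0.5
    weight_log_mean: float = float(np.log(400.0))
    weight_log_sd: float = 0.15
    n_fish_histology: int = 6
    histology_group_means: Mapping[tuple[str, str], float] | float = field(
        default_factory=lambda: {
            ("non_selected", "PM"): 3.2,
            ("non_selected", "FM"): 2.4,
            ("selected", "FM"): 2.2,
            ("selected", "PM"): 1.8,
        }
    )
    histology_sd: float = 0.5
    fraction_uncharacterized: float = 0.10
    n_go_terms: Mapping[str, int] = field(
        default_factory=lambda: {"BP": 30, "MF": 20, "CC": 15}
    )
    max_terms_per_category: int = 5
    n_pathways: int = 12
    ec_probability: float = 0.3
    pathway_probability: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fish_per_group < 2:
            raise ValueError(
                "n_fish_per_group must be >= 2 "
                f"(got {self.n_fish_per_group})"
            )
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if sum(m.size for m in self.module_specs) > self.n_genes:
            raise ValueError("sum of module sizes exceeds n_genes")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, order-insensitive stream per operation
    return np.random.default_rng([config.seed % (2**31), stream])


def gene_ids(config: SimulationConfig) -> list[str]:
    width = len(str(config.n_genes))
    return [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]


def planted_module_genes(config: SimulationConfig) -> dict[str, list[str]]:
    """Ground-truth membership of the planted modules.

    Modules occupy the head of the gene list in specification order and
    are keyed ``planted1``, ``planted2``, ...
    """
    ids = gene_ids(config)
    truth: dict[str, list[str]] = {}
    start = 0
    for k, spec in enumerate(config.module_specs, start=1):
        truth[f"planted{k}"] = ids[start : start + spec.size]
        start += spec.size
    return truth


def generate_design(config: SimulationConfig) -> pd.DataFrame:
    """Sample table of the 2x2 factorial design, two tissues per fish.

    Returns one row per RNA library (4 groups x n fish x 2 tissues) with
    columns sample_id, fish_id, strain, diet, tissue, weight, liver_weight
    and hsi. Weight is lognormal; HSI is drawn so that its expected Pearson
    correlation with the PM-diet indicator equals
    ``config.hsi_diet_correlation`` (the point-biserial identity
    delta = 2*sigma*r/sqrt(1-r^2) for balanced groups); liver weight is
    weight * HSI / 100.
    """
    rng = _rng(config, 1)
    n = config.n_fish_per_group
    r = config.hsi_diet_correlation
    delta = 2.0 * config.hsi_sd * r / np.sqrt(1.0 - r**2)

    rows = []
    for strain in STRAINS:
        for diet in DIETS:
            weight = np.exp(
                rng.normal(config.weight_log_mean, config.weight_log_sd, n)
            )
            hsi = (
                config.hsi_mean
                + delta * (diet == "PM")
                + rng.normal(0.0, config.hsi_sd, n)
            )
            hsi = np.clip(hsi, 0.2, None)  # HSI is a positive percentage
            for i in range(n):
                fish = f"{strain}_{diet}_{i + 1:02d}"
                for tissue in TISSUES:
                    rows.append(
                        {
                            "sample_id": f"{fish}_{tissue}",
                            "fish_id": fish,
                            "strain": strain,
                            "diet": diet,
                            "tissue": tissue,
                            "weight": weight[i],
                            "liver_weight": weight[i] * hsi[i] / 100.0,
                            "hsi": hsi[i],
                        }
                    )
    return pd.DataFrame(rows)


def generate_counts(
    design: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Negative-binomial count matrix with planted modules.

    Per gene i and library j the log2 mean is
    ``baseline_i + l_i * (sigma_f * f_mj + base_log2fc * PM_j) + offset_j``
    where f_mj is the module's latent factor (unit variance, correlation
    ``trait_correlation`` with the standardized PM indicator), l_i ~ U(0.5,
    1) is the gene loading, and offset_j the log2 library-size offset.
    Counts are NB with variance mu + alpha*mu^2.

    Returns ``(counts, gene_lengths, library_sizes)`` with genes as rows
    and ``design.sample_id`` as columns.
    """
    rng = _rng(config, 2)
    ids = gene_ids(config)
    samples = design["sample_id"].to_numpy()
    n_samples = len(samples)
    pm = (design["diet"] == "PM").to_numpy(float)
    # The diet response is concentrated in the selected strain: the
    # non-selected strain sees an attenuated version of the same signal.
    # z is the standardized diet indicator of the selected cohort (+-1),
    # so trait_correlation is exact for the samples entering the network.
    sel = (design["strain"] == "selected").to_numpy(float)
    atten = np.where(sel > 0, 1.0, config.nonselected_diet_attenuation)
    z = (2.0 * pm - 1.0) * atten
    coupled = pm * atten

    lengths = pd.Series(
        rng.integers(*config.gene_length_range, size=config.n_genes),
        index=ids,
        name="length",
    )
    lib = pd.Series(
        np.round(
            np.exp(
                rng.normal(
                    np.log(config.library_size_mean),
                    config.library_size_sigma,
                    n_samples,
                )
            )
        ),
        index=samples,
        name="library_size",
    )
    offset = np.log2(lib.to_numpy() / config.library_size_mean)

    baseline = rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes
    )
    log2_mu = baseline[:, None] + offset[None, :]

    start = 0
    for spec in config.module_specs:
        rho = spec.trait_correlation
        factor = rho * z + np.sqrt(1.0 - rho**2) * rng.normal(size=n_samples)
        loadings = rng.uniform(0.5, 1.0, spec.size)
        effect = config.module_factor_sd * factor + spec.base_log2fc * coupled
        log2_mu[start : start + spec.size, :] += np.outer(loadings, effect)
        start += spec.size

    mu = np.exp2(log2_mu)
    alpha = config.nb_dispersion
    counts = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))
    return (
        pd.DataFrame(counts, index=ids, columns=samples),
        lengths,
        lib,
    )


class Annotation:
    """Flat functional annotation: per-gene descriptions plus long-format
    GO-term and pathway/EC assignments.

    Attributes
    ----------
    genes : DataFrame with columns gene, symbol, description.
    go : DataFrame with columns gene, category, term.
    pathways : DataFrame with columns gene, pathway_id, ec ("" if none).
    """

    def __init__(
        self, genes: pd.DataFrame, go: pd.DataFrame, pathways: pd.DataFrame
    ) -> None:
        self.genes = genes
        self.go = go
        self.pathways = pathways

    def descriptions(self) -> pd.Series:
        return self.genes.set_index("gene")["description"]

    def write(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        self.genes.to_csv(d / "annotation_genes.tsv", sep="\t", index=False)
        self.go.to_csv(d / "annotation_go.tsv", sep="\t", index=False)
        self.pathways.to_csv(
            d / "annotation_pathways.tsv", sep="\t", index=False
        )

    @classmethod
    def read(cls, directory) -> "Annotation":
        from pathlib import Path

        d = Path(directory)
        return cls(
            pd.read_csv(d / "annotation_genes.tsv", sep="\t"),
            pd.read_csv(d / "annotation_go.tsv", sep="\t"),
            pd.read_csv(
                d / "annotation_pathways.tsv", sep="\t", keep_default_na=False
            ),
        )


def generate_annotation(
    genes: Sequence[str],
    config: SimulationConfig,
    planted_terms: Sequence[PlantedTerm] = (),
    planted_pathway: tuple[str, Sequence[str]] | None = None,
) -> Annotation:
    """Synthetic flat annotation standing in for a BLAST-based pipeline.

    Each gene receives a symbol, a description (a configurable fraction
    flagged uncharacterized/hypothetical so the downstream description
    filter has something to remove), 0-5 GO terms per category with skewed
    base frequencies, and optionally an EC number and pathway memberships.
    ``planted_terms`` / ``planted_pathway`` overlay extra assignments on
    chosen gene sets so that enrichment is recoverable by construction.
    """
    if len(genes) == 0:
        raise ValueError("gene list is empty")
    rng = _rng(config, 3)
    genes = list(genes)
    n = len(genes)

    flagged = rng.random(n) < config.fraction_uncharacterized
    flag_text = ("uncharacterized protein", "hypothetical protein")
    gene_table = pd.DataFrame(
        {
            "gene": genes,
            "symbol": [f"SYM{i + 1}" for i in range(n)],
            "description": [
                flag_text[i % 2] if flagged[i] else f"protein SYM{i + 1}"
                for i in range(n)
            ],
        }
    )

    go_rows: list[tuple[str, str, str]] = []
    for category, n_terms in config.n_go_terms.items():
        terms = [f"GO:{category}{t + 1:04d}" for t in range(n_terms)]
        # skewed base frequencies so some terms are common, most rare
        freq = rng.uniform(0.01, 0.12, n_terms)
        for t, term in enumerate(terms):
            hit = rng.random(n) < freq[t]
            go_rows.extend((genes[i], category, term) for i in np.where(hit)[0])
    for planted in planted_terms:
        target = set(planted.genes)
        hit = rng.random(n) < planted.probability
        go_rows.extend(
            (genes[i], planted.category, planted.term)
            for i in np.where(hit)[0]
            if genes[i] in target
        )
    go = (
        pd.DataFrame(go_rows, columns=["gene", "category", "term"])
        .drop_duplicates()
        .sort_values(["gene", "category", "term"], kind="stable")
        .reset_index(drop=True)
    )
    # cap assignments per gene x category
    go = go.groupby(["gene", "category"], sort=False).head(
        config.max_terms_per_category
    )

    ec_pool = [f"ec:{a}.{b}.1.{c}" for a in (1, 2, 3) for b in (1, 2) for c in range(1, 6)]
    pathway_pool = [f"map{100 + p:05d}" for p in range(config.n_pathways)]
    path_rows: list[tuple[str, str, str]] = []
    has_ec = rng.random(n) < config.ec_probability
    for i, g in enumerate(genes):
        ec = ec_pool[rng.integers(len(ec_pool))] if has_ec[i] else ""
        member = np.where(rng.random(config.n_pathways) < config.pathway_probability)[0]
        path_rows.extend((g, pathway_pool[p], ec) for p in member)
    if planted_pathway is not None:
        pid, members = planted_pathway
        for g in members:
            path_rows.append((g, pid, ec_pool[rng.integers(len(ec_pool))]))
    pathways = pd.DataFrame(
        path_rows, columns=["gene", "pathway_id", "ec"]
    ).drop_duplicates(subset=["gene", "pathway_id"])

    return Annotation(gene_table, go, pathways.reset_index(drop=True))


def generate_histology(
    design: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Seven-variable histopathology scores on a continuous 1-5 scale.

    One row per scored fish (``n_fish_histology`` per strain-by-diet
    group, default 6 for 24 fish total). Group means follow
    ``histology_group_means`` — by default the non-selected/PM group
    scores highest, then non-selected/FM, selected/FM and selected/PM —
    with Gaussian noise; values outside [1, 5] are clipped with a warning.
    """
    groups = design[["strain", "diet"]].drop_duplicates().itertuples(index=False)
    groups = [(g.strain, g.diet) for g in groups]
    if len(groups) != 4:
        raise ValueError("design must contain 4 strain-by-diet groups")
    rng = _rng(config, 4)
    means = config.histology_group_means
    rows = []
    for strain, diet in groups:
        mu = means if np.isscalar(means) else means[(strain, diet)]
        for i in range(config.n_fish_histology):
            scores = rng.normal(mu, config.histology_sd, len(HISTOLOGY_VARIABLES))
            row = {
                "fish_id": f"{strain}_{diet}_h{i + 1:02d}",
                "strain": strain,
                "diet": diet,
                "group": f"{strain}_{diet}",
            }
            row.update(dict(zip(HISTOLOGY_VARIABLES, scores)))
            rows.append(row)
    table = pd.DataFrame(rows)
    values = table[list(HISTOLOGY_VARIABLES)]
    if (values.to_numpy() < 1).any() or (values.to_numpy() > 5).any():
        warnings.warn("histology scores outside [1, 5] were clipped")
        table[list(HISTOLOGY_VARIABLES)] = values.clip(1.0, 5.0)
    return table
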