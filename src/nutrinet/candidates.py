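"""Candidate-gene integration.

Combines three selectors over the diet-significant modules of the
co-expression network into one provenance-tagged candidate list:

- ``hub``: top genes per module by intramodular connectivity (kWithin);
- ``kme_cor``: top genes per module by module membership (kME), re-ranked
  by the combined network/trait score |kME + Cor| where Cor is the gene's
  Pearson correlation to diet;
- ``deg``: the top 1% of significant diet DEGs by magnitude fold-change,
  restricted to genes whose primary module is diet-significant.

All three lists are filtered of genes whose description matches a keyword
list (unknown / uncharacterized / hypothetical / structural / unnamed),
approximating a manual curation step. A ``go`` tag marks genes mapping to
a module-level over-represented annotation term.

A transcription of the published candidate table (63 genes over the
salmon, purple and turquoise modules) ships as package data and serves as
a worked example for the union and summary logic.
"""

from __future__ import annotations

import math
import re
import warnings
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "FILTER_KEYWORDS",
    "annotation_keep_mask",
    "select_hub_genes",
    "select_kme_cor",
    "select_top_degs",
    "assemble_candidates",
    "summarize_candidates",
    "load_table7",
]

FILTER_KEYWORDS = (
    "unknown",
    "uncharacterized",
    "hypothetical",
    "structural",
    "unnamed",
)

TAGS = ("hub", "kme_cor", "deg", "go")


def annotation_keep_mask(
    descriptions: pd.Series, keywords=FILTER_KEYWORDS
) -> pd.Series:
    """True where the description does NOT match any filter keyword
    (case-insensitive substring match). Missing descriptions are kept."""
    pattern = re.compile("|".join(map(re.escape, keywords)), re.IGNORECASE)
    return ~descriptions.fillna("").str.contains(pattern)


def _filtered(genes: list[str], descriptions: pd.Series) -> list[str]:
    keep = annotation_keep_mask(descriptions.reindex(genes))
    return [g for g in genes if keep.get(g, True)]


def select_hub_genes(
    kwithin: pd.Series,
    partition: pd.Series,
    descriptions: pd.Series,
    modules: list[str],
    top_n: int = 30,
) -> dict[str, list[str]]:
    """Top-``top_n`` hub genes per module by intramodular connectivity,
    description-filtered; ties broken by gene id."""
    out: dict[str, list[str]] = {}
    for module in modules:
        members = partition.index[partition == module]
        if len(members) < top_n:
            warnings.warn(
                f"module {module!r} has only {len(members)} genes (< {top_n})"
            )
        ranked = (
            kwithin.reindex(members)
            .sort_index(kind="stable")  # lexicographic tie-break
            .sort_values(ascending=False, kind="stable")
        )
        top = list(ranked.index[:top_n])
        out[module] = _filtered(top, descriptions)
    return out


def select_kme_cor(
    kme: pd.DataFrame,
    gs_diet: pd.Series,
    partition: pd.Series,
    descriptions: pd.Series,
    modules: list[str],
    top_n: int = 30,
) -> dict[str, pd.DataFrame]:
    """Weighted |kME + Cor| lists per module.

    Takes the ``top_n`` module members with highest kME (module
    membership), scores each as |kME + Cor| with Cor the gene's diet
    correlation, ranks by the score and applies the description filter.
    Genes with missing Cor are skipped with a warning.
    """
    out: dict[str, pd.DataFrame] = {}
    for module in modules:
        members = partition.index[partition == module]
        ranked = (
            kme.loc[members, module]
            .sort_index(kind="stable")
            .sort_values(ascending=False, kind="stable")
        )
        top = list(ranked.index[:top_n])
        cor = gs_diet.reindex(top)
        if cor.isna().any():
            warnings.warn(
                f"skipping {int(cor.isna().sum())} genes without a diet "
                f"correlation in module {module!r}"
            )
            top = [g for g in top if not np.isnan(cor[g])]
        table = pd.DataFrame(
            {
                "gene": top,
                "kme": kme.loc[top, module].to_numpy(),
                "cor": gs_diet.reindex(top).to_numpy(),
            }
        )
        table["score"] = (table["kme"] + table["cor"]).abs()
        table = table.sort_values(
            ["score", "gene"], ascending=[False, True], kind="stable"
        )
        keep = annotation_keep_mask(descriptions.reindex(table["gene"]))
        out[module] = table[keep.to_numpy()].reset_index(drop=True)
    return out


def select_top_degs(
    de_diet: pd.DataFrame,
    primary_module: pd.Series,
    significant_modules: list[str],
    descriptions: pd.Series,
    frac: float = 0.01,
    mode: str = "by_fc",
) -> list[str]:
    """Top fraction of significant diet DEGs by magnitude fold-change.

    ``mode='by_fc'`` (default) ranks all significant DEGs by |log2FC|
    (ties by adjusted p); ``mode='padj_head'`` instead takes the
    ceil(frac*N) head of the p-adj-sorted list. Either way the selection
    size before filtering is ceil(frac * N). The description filter is
    applied, then genes whose primary module is not diet-significant are
    removed.
    """
    sig = de_diet[de_diet["significant"]]
    if len(sig) == 0:
        return []
    n_take = math.ceil(frac * len(sig))
    if mode == "by_fc":
        ranked = sig.assign(_abs=sig["log2fc"].abs()).sort_values(
            ["_abs", "padj"], ascending=[False, True], kind="stable"
        )
    elif mode == "padj_head":
        ranked = sig.sort_values(
            ["padj", "pvalue"], ascending=True, kind="stable"
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    top = list(ranked.index[:n_take])
    top = _filtered(top, descriptions)
    return [
        g
        for g in top
        if primary_module.get(g, None) in set(significant_modules)
    ]


def assemble_candidates(
    hub_lists: dict[str, list[str]],
    kme_cor_lists: dict[str, pd.DataFrame],
    deg_list: list[str],
    partition: pd.Series,
    kme: pd.DataFrame,
    gs_diet: pd.Series,
    de_diet: pd.DataFrame | None = None,
    go_genes: set | None = None,
    symbols: pd.Series | None = None,
) -> pd.DataFrame:
    """Union of the three selector outputs, keyed by gene within module.

    Each record keeps its module, log2 fold-change (missing when the gene
    is absent from the final DE table, e.g. expression-filtered), kME in
    its module, diet correlation, and the set of selectors that
    contributed as comma-separated tags; a ``go`` tag is added for genes
    in ``go_genes``.
    """
    records: dict[str, dict] = {}

    def _module_of(gene: str, module: str) -> None:
        seen = records[gene]["module"]
        if seen != module:
            raise ValueError(
                f"gene {gene!r} assigned to both {seen!r} and {module!r}"
            )

    def _add(gene: str, module: str, tag: str) -> None:
        if gene in records:
            _module_of(gene, module)
            records[gene]["tags"].add(tag)
        else:
            records[gene] = {"module": module, "tags": {tag}}

    for module, genes in hub_lists.items():
        for g in genes:
            _add(g, module, "hub")
    for module, table in kme_cor_lists.items():
        for g in table["gene"]:
            _add(g, module, "kme_cor")
    for g in deg_list:
        _add(g, str(partition.get(g)), "deg")
    if go_genes:
        for g in records:
            if g in go_genes:
                records[g]["tags"].add("go")

    rows = []
    for gene, rec in records.items():
        module = rec["module"]
        fc = np.nan
        if de_diet is not None and gene in de_diet.index:
            fc = float(de_diet.loc[gene, "log2fc"])
        rows.append(
            {
                "gene": gene,
                "symbol": symbols.get(gene, gene) if symbols is not None else gene,
                "module": module,
                "fc": fc,
                "kme": float(kme.loc[gene, module])
                if gene in kme.index and module in kme.columns
                else np.nan,
                "cor": float(gs_diet.get(gene, np.nan)),
                "tags": ",".join(t for t in TAGS if t in rec["tags"]),
            }
        )
    out = pd.DataFrame(
        rows, columns=["gene", "symbol", "module", "fc", "kme", "cor", "tags"]
    )
    return out.sort_values(["module", "gene"], kind="stable").reset_index(
        drop=True
    )


def summarize_candidates(table: pd.DataFrame) -> dict:
    """Marginal counts of a candidate table.

    Returns total, per-module counts, how many records lack a fold-change,
    how many are supported only by the DEG selector, and symbols appearing
    in more than one module (possible isoforms).
    """
    if len(table) == 0:
        return {
            "total": 0,
            "per_module": {},
            "n_missing_fc": 0,
            "n_deg_only": 0,
            "duplicated_symbols": [],
        }
    tags = table["tags"].map(lambda s: set(s.split(",")) if s else set())
    sym_modules = table.groupby("symbol")["module"].nunique()
    return {
        "total": int(len(table)),
        "per_module": table["module"].value_counts().to_dict(),
        "n_missing_fc": int(table["fc"].isna().sum()),
        "n_deg_only": int((tags == {"deg"}).sum()),
        "duplicated_symbols": sorted(sym_modules.index[sym_modules > 1]),
    }


def load_table7() -> pd.DataFrame:
    """Load the packaged transcription of the published candidate table.

    Returns the assemble_candidates schema (gene, symbol, module, fc, kme,
    cor, tags) with tags normalized to {hub, kme_cor, deg, go}.
    """
    with resources.files("nutrinet.data").joinpath("table7.tsv").open() as fh:
        raw = pd.read_csv(fh, sep="\t")
    tag_map = {"hub": "hub", "|kME + Cor|": "kme_cor", "DEG": "deg", "GO": "go"}
    tags = raw["significance"].map(
        lambda s: ",".join(
            tag_map[t.strip()] for t in s.split(",") if t.strip() in tag_map
        )
    )
    return pd.DataFrame(
        {
            "gene": raw["gene_id"],
            "symbol": raw["symbol"],
            "module": raw["module"],
            "description": raw["description"],
            "fc": raw["fc"],
            "kme": raw["mm"],
            "cor": raw["cor"],
            "tags": tags,
        }
    )
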