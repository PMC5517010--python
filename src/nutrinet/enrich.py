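"""Term enrichment and pathway perturbation counting.

Fisher's exact test of a gene list ("test set") against the full
transcriptome ("reference set") on flat term assignments, with BH FDR
across terms — two-sided for differential-expression contrasts, one-sided
(over-representation) for module candidate lists. Pathway perturbation is
a counting exercise: how many member sequences of each pathway occur in
the combined DEG union, and how many distinct enzyme codes those
sequences carry, reported above a minimum-sequences and a minimum-enzymes
cutoff respectively.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

__all__ = ["fisher_enrichment", "kegg_perturbation"]


def fisher_enrichment(
    test_set,
    reference_set,
    go: pd.DataFrame,
    sided: str = "two-sided",
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Per-term Fisher's exact test of test vs reference-minus-test.

    ``go`` is long-format (gene, category, term). The 2x2 table per term
    counts term membership inside the test set against the rest of the
    reference; the two-sided p sums all tables at most as probable as the
    observed one, the one-sided p is the upper (over-representation) tail.
    Direction is "over" when the term is denser in the test set than in
    the reference. BH adjustment runs across all tested terms.
    """
    test = set(test_set)
    ref = set(reference_set)
    if not test <= ref:
        raise ValueError("test set must be a subset of the reference set")
    if sided not in ("two-sided", "greater"):
        raise ValueError("sided must be 'two-sided' or 'greater'")
    go = go[go["gene"].isin(ref)]
    n_test = len(test)
    n_ref = len(ref)
    rows = []
    for (category, term), block in go.groupby(["category", "term"]):
        members = set(block["gene"])
        a = len(members & test)  # in test, with term
        b = n_test - a  # in test, without term
        c = len(members) - a  # in rest, with term
        d = (n_ref - n_test) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative=sided)
        over = (a / n_test if n_test else 0.0) > (len(members) / n_ref)
        rows.append(
            {
                "term": term,
                "category": category,
                "direction": "over" if over else "under",
                "test_in": a,
                "test_out": b,
                "ref_in": c,
                "ref_out": d,
                "pvalue": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term", "category", "direction",
            "test_in", "test_out", "ref_in", "ref_out", "pvalue",
        ],
    )
    if len(out):
        out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
        out["significant"] = out["fdr"] < fdr_cut
        out = out.sort_values(["fdr", "pvalue", "term"], kind="stable")
    return out.reset_index(drop=True)


def kegg_perturbation(
    gene_union,
    pathways: pd.DataFrame,
    min_sequences: int = 20,
    min_enzymes: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pathway perturbation by sequence and enzyme counts.

    ``gene_union`` is the set of unique significant DEGs combined across
    tissues; ``pathways`` is long-format (gene, pathway_id, ec) where ec
    may be empty (such genes count toward sequences only). Returns two
    ranked tables: pathways with at least ``min_sequences`` member
    sequences, and pathways with at least ``min_enzymes`` distinct EC
    numbers.
    """
    union = set(gene_union)
    hits = pathways[pathways["gene"].isin(union)].copy()
    hits["ec"] = hits["ec"].fillna("").astype(str)
    rows = []
    for pathway, block in hits.groupby("pathway_id"):
        ecs = {e for e in block["ec"] if e}
        rows.append(
            {
                "pathway_id": pathway,
                "n_sequences": int(block["gene"].nunique()),
                "n_enzymes": len(ecs),
            }
        )
    table = pd.DataFrame(
        rows, columns=["pathway_id", "n_sequences", "n_enzymes"]
    )
    by_seq = (
        table[table["n_sequences"] >= min_sequences]
        .sort_values(["n_sequences", "n_enzymes"], ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    by_enz = (
        table[table["n_enzymes"] >= min_enzymes]
        .sort_values(["n_enzymes", "n_sequences"], ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return by_seq, by_enz
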