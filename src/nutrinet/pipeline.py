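"""End-to-end orchestration over a run directory of TSV artifacts.

Stages communicate exclusively through tab-separated files in one
directory (diff-able, re-runnable per stage): simulate -> preprocess ->
de -> network -> candidates -> enrich -> histo. ``run_pipeline`` executes
them in order and writes a manifest (seed, parameters, versions) so a run
is reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, candidates as cand, de as de_mod, enrich, histo
from . import network as net
from .preprocess import compute_fpkm, filter_network_genes, log_transform
from .simulate import (
    Annotation,
    SimulationConfig,
    generate_annotation,
    generate_counts,
    generate_design,
    generate_histology,
)

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "STAGES"]


@dataclass
class PipelineConfig:
    """Thresholds and parameters of a full run."""

    seed: int = 0
    padj_threshold: float = 0.05
    fpkm_threshold: float = 1.0
    network_filter_frac: float = 0.9
    beta: int = 8
    min_module_size: int = 30
    merge_cut_height: float = 0.20
    cut_height: float = 0.95
    module_p_threshold: float = 0.003
    top_n: int = 30
    deg_frac: float = 0.01
    min_sequences: int = 20
    min_enzymes: int = 10
    simulation: dict = field(default_factory=dict)

    def simulation_config(self) -> SimulationConfig:
        from .simulate import ModuleSpec

        kwargs = dict(self.simulation)
        if "module_specs" in kwargs:
            kwargs["module_specs"] = tuple(
                ModuleSpec(*m) for m in kwargs["module_specs"]
            )
        kwargs.setdefault("seed", self.seed)
        return SimulationConfig(**kwargs)


def _read(path: Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def stage_simulate(config: PipelineConfig, run_dir: Path) -> None:
    run_dir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation_config()
    design = generate_design(sim)
    counts, lengths, libs = generate_counts(design, sim)
    fpkm = compute_fpkm(counts, lengths, libs)
    annotation = generate_annotation(list(counts.index), sim)
    histology = generate_histology(design, sim)

    design.to_csv(run_dir / "samples.tsv", sep="\t", index=False)
    counts.to_csv(run_dir / "counts.tsv", sep="\t", index_label="gene")
    fpkm.to_csv(run_dir / "fpkm.tsv", sep="\t", index_label="gene")
    lengths.to_frame().to_csv(run_dir / "lengths.tsv", sep="\t", index_label="gene")
    libs.to_frame().to_csv(
        run_dir / "library_sizes.tsv", sep="\t", index_label="sample_id"
    )
    annotation.write(run_dir)
    histology.to_csv(run_dir / "histology.tsv", sep="\t", index=False)


def stage_de(config: PipelineConfig, run_dir: Path) -> None:
    counts = _read(run_dir / "counts.tsv", index_col="gene")
    fpkm = _read(run_dir / "fpkm.tsv", index_col="gene")
    samples = _read(run_dir / "samples.tsv")
    summaries = []
    for tissue in sorted(samples["tissue"].unique()):
        results, summary = de_mod.run_design_contrasts(
            counts,
            samples,
            tissue,
            fpkm=fpkm,
            alpha=config.padj_threshold,
            fpkm_threshold=config.fpkm_threshold,
        )
        summaries.append(summary)
        deg_sets = {}
        for name, res in results.items():
            res.to_csv(
                run_dir / f"de_{name}_{tissue}.tsv", sep="\t", index_label="gene"
            )
            deg_sets[name] = set(res.index[res["significant"]])
        de_mod.venn_overlap(deg_sets).to_csv(
            run_dir / f"venn_{tissue}.tsv", sep="\t", index=False
        )
    pd.concat(summaries, ignore_index=True).to_csv(
        run_dir / "de_summary.tsv", sep="\t", index=False
    )


def network_input(
    config: PipelineConfig, run_dir: Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filtered, log-transformed liver expression of the selected strain
    (both diets) plus the matching trait table."""
    fpkm = _read(run_dir / "fpkm.tsv", index_col="gene")
    samples = _read(run_dir / "samples.tsv")
    sub = samples[(samples["strain"] == "selected") & (samples["tissue"] == "liver")]
    mat = filter_network_genes(
        fpkm[list(sub["sample_id"])],
        frac=config.network_filter_frac,
        threshold=config.fpkm_threshold,
    )
    expr = log_transform(mat).T  # samples x genes
    traits = pd.DataFrame(
        {
            "diet": (sub["diet"] == "PM").astype(float).to_numpy(),
            "weight": sub["weight"].to_numpy(),
            "liver_weight": sub["liver_weight"].to_numpy(),
            "hsi": sub["hsi"].to_numpy(),
        },
        index=sub["sample_id"],
    )
    return expr, traits


def stage_network(config: PipelineConfig, run_dir: Path) -> None:
    expr, traits = network_input(config, run_dir)

    scan, _ = net.soft_threshold_scan(expr, default_power=config.beta)
    scan.to_csv(run_dir / "soft_threshold.tsv", sep="\t", index=False)
    net.sample_outlier_report(expr).to_csv(
        run_dir / "sample_outliers.tsv", sep="\t", index=False
    )

    model = net.CoexpressionNetwork(
        beta=config.beta,
        min_module_size=config.min_module_size,
        merge_cut_height=config.merge_cut_height,
        cut_height=config.cut_height,
    ).fit(expr)
    r, p = model.module_trait(traits)
    kme, gs, primary = model.gene_statistics(expr, traits["diet"])

    modules = pd.DataFrame(
        {
            "module": model.partition_,
            "kWithin": model.kwithin_,
            "primary_module": primary,
            "GS_diet": gs,
        }
    )
    modules = modules.join(kme.add_prefix("kME_"))
    modules.to_csv(run_dir / "modules.tsv", sep="\t", index_label="gene")
    model.eigengenes_.to_csv(
        run_dir / "eigengenes.tsv", sep="\t", index_label="sample_id"
    )
    mt = r.stack().rename("r").to_frame()
    mt["p"] = p.stack()
    mt.index.names = ["module", "trait"]
    mt.reset_index().to_csv(run_dir / "module_trait.tsv", sep="\t", index=False)


def significant_modules(
    module_trait: pd.DataFrame, p_threshold: float
) -> list[str]:
    diet = module_trait[module_trait["trait"] == "diet"]
    return sorted(diet.loc[diet["p"] <= p_threshold, "module"])


def stage_candidates(config: PipelineConfig, run_dir: Path) -> None:
    modules = _read(run_dir / "modules.tsv", index_col="gene")
    module_trait = _read(run_dir / "module_trait.tsv")
    de_diet = _read(run_dir / "de_diet_liver.tsv", index_col="gene")
    annotation = Annotation.read(run_dir)
    descriptions = annotation.descriptions()
    symbols = annotation.genes.set_index("gene")["symbol"]

    sig_modules = significant_modules(module_trait, config.module_p_threshold)
    partition = modules["module"]
    kme = modules.filter(like="kME_").rename(columns=lambda c: c[4:])
    gs = modules["GS_diet"]

    hub = cand.select_hub_genes(
        modules["kWithin"], partition, descriptions, sig_modules, config.top_n
    )
    kme_cor = cand.select_kme_cor(
        kme, gs, partition, descriptions, sig_modules, config.top_n
    )
    degs = cand.select_top_degs(
        de_diet,
        modules["primary_module"],
        sig_modules,
        descriptions,
        frac=config.deg_frac,
    )

    # module-level over-representation -> go provenance tag
    go_genes: set = set()
    reference = list(partition.index)
    for module in sig_modules:
        members = partition.index[partition == module]
        result = enrich.fisher_enrichment(
            members, reference, annotation.go, sided="greater"
        )
        over = set(
            result.loc[result["significant"], "term"]
        )
        if over:
            hits = annotation.go[
                annotation.go["term"].isin(over)
                & annotation.go["gene"].isin(members)
            ]
            go_genes |= set(hits["gene"])

    table = cand.assemble_candidates(
        hub, kme_cor, degs, partition, kme, gs,
        de_diet=de_diet[de_diet["significant"]],
        go_genes=go_genes,
        symbols=symbols,
    )
    table.to_csv(run_dir / "candidates.tsv", sep="\t", index=False)
    summary = cand.summarize_candidates(table)
    (run_dir / "candidates_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True)
    )


def stage_enrich(config: PipelineConfig, run_dir: Path) -> None:
    annotation = Annotation.read(run_dir)
    counts = _read(run_dir / "counts.tsv", index_col="gene")
    reference = list(counts.index)
    union: set = set()
    for path in sorted(run_dir.glob("de_*_*.tsv")):
        res = _read(path, index_col="gene")
        degs = set(res.index[res["significant"]])
        union |= degs
        result = enrich.fisher_enrichment(
            degs, reference, annotation.go, sided="two-sided"
        )
        result.to_csv(
            run_dir / f"enrichment_{path.stem[3:]}.tsv", sep="\t", index=False
        )
    by_seq, by_enz = enrich.kegg_perturbation(
        union,
        annotation.pathways,
        min_sequences=config.min_sequences,
        min_enzymes=config.min_enzymes,
    )
    by_seq.to_csv(run_dir / "kegg_by_sequences.tsv", sep="\t", index=False)
    by_enz.to_csv(run_dir / "kegg_by_enzymes.tsv", sep="\t", index=False)


def stage_histo(config: PipelineConfig, run_dir: Path) -> None:
    table = _read(run_dir / "histology.tsv")
    per_fish, per_group = histo.cumulative_score(table)
    groups = [
        per_fish[table["group"].to_numpy() == g].to_numpy()
        for g in per_group.index
    ]
    h, p = histo.kruskal_wallis(groups)
    dunn = histo.dunn_posthoc(groups, labels=list(per_group.index))
    per_group.to_frame().assign(kw_h=h, kw_p=p).to_csv(
        run_dir / "histology_summary.tsv", sep="\t", index_label="group"
    )
    dunn.to_csv(run_dir / "histology_dunn.tsv", sep="\t", index=False)


STAGES = {
    "simulate": stage_simulate,
    "de": stage_de,
    "network": stage_network,
    "candidates": stage_candidates,
    "enrich": stage_enrich,
    "histo": stage_histo,
}


def run_pipeline(config: PipelineConfig, run_dir) -> Path:
    """Execute all stages in dependency order and write a manifest."""
    run_dir = Path(run_dir)
    for name, stage in STAGES.items():
        try:
            stage(config, run_dir)
        except Exception as exc:  # noqa: BLE001 - annotate the stage
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    params = asdict(config)
    manifest = {
        "package": "nutrinet",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "parameters": params,
        "parameter_hash": hashlib.sha256(
            json.dumps(params, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": list(STAGES),
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return run_dir


def validate_inputs(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    annotation: Annotation | None = None,
) -> dict:
    """Consistency report over the raw inputs.

    Fatal: samples in the matrix missing from the metadata, duplicate gene
    ids, negative counts, missing trait columns. Warning: annotation
    covering genes absent from the matrix.
    """
    fatal: list[str] = []
    warning: list[str] = []
    missing = set(counts.columns) - set(samples["sample_id"])
    if missing:
        fatal.append(f"samples missing from metadata: {sorted(missing)[:5]}")
    if counts.index.duplicated().any():
        dupes = counts.index[counts.index.duplicated()].unique()
        fatal.append(f"duplicate gene ids: {list(dupes[:5])}")
    if (counts.to_numpy() < 0).any():
        fatal.append("negative counts")
    for trait in ("weight", "liver_weight", "hsi"):
        if trait not in samples.columns:
            fatal.append(f"missing trait column: {trait}")
    if annotation is not None:
        extra = set(annotation.genes["gene"]) - set(counts.index)
        if extra:
            warning.append(
                f"annotation covers {len(extra)} genes absent from the matrix"
            )
    return {"fatal": fatal, "warning": warning, "ok": not fatal}
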