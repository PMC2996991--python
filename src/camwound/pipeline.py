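"""End-to-end orchestration of the wound-screen pipeline.

The screen shape mirrors the study: normalize -> paired differential
expression -> chicken-to-human ortholog mapping -> endothelial EST-pool
filter joined with the literature Angioscore and the expression fold change,
producing a published-screen-shaped endothelial report (gene, qvalue, EST
counts, Endofactor, direction, Angioscore, fold change).  A machine-readable
run manifest records versions, seeds and parameters; outputs carry
'#'-prefixed metadata headers naming the producing stage.
"""

from __future__ import annotations

import contextlib
import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import statsmodels
import yaml

from . import __version__
from .angioscore import KeywordSet, angioscore_table, read_corpus, write_corpus
from .differential_expression import (
    DEConfig,
    permutation_fdr,
    select_de_genes,
    write_results_table,
)
from .endothelial_filter import (
    EndoRecord,
    endothelial_screen,
    filter_endothelial,
    read_est_counts,
    write_endo_report,
)
from .expression_matrix import (
    normalize_global_scaling,
    read_design_table,
    read_expression_table,
    write_design_table,
    write_expression_table,
)
from .functional_summary import enrichment_table, read_annotation
from .ortholog_rbh import (
    ortholog_map,
    read_blast_tabular,
    reciprocal_best_hits,
    write_blast_tabular,
    write_pairs_table,
)
from .qpcr import gene_summary_table, read_ct_table, write_fold_change_table
from .synthetic_data import (
    generate_abstract_corpus,
    generate_est_pools,
    generate_expression_experiment,
    generate_hit_tables,
    generate_qpcr_plate,
)



class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML-loadable, unknown keys rejected)."""

    expression_path: str = ""
    design_path: str = ""
    hits_ab_path: str = ""
    hits_ba_path: str = ""
    est_counts_path: str = ""
    corpus_path: str = ""
    qpcr_path: str | None = None
    annotation_path: str | None = None
    endo_total: float = 10000.0
    nonendo_total: float = 43910.0
    q_max: float = 0.01
    keywords: tuple[str, ...] | None = None
    normalize: bool = True
    target_intensity: float = 100.0
    trim_fraction: float = 0.02
    de: DEConfig = field(default_factory=DEConfig)
    seed: int = 0
    outdir: str = "pipeline_out"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        raw = dict(raw)
        de_raw = raw.pop("de", {})
        if isinstance(de_raw, DEConfig):
            de = de_raw
        else:
            de_known = {f.name for f in fields(DEConfig)}
            de_unknown = set(de_raw) - de_known
            if de_unknown:
                raise ConfigError(f"unknown de config key(s): {sorted(de_unknown)}")
            de = DEConfig(**de_raw)
        if raw.get("keywords") is not None:
            raw["keywords"] = tuple(raw["keywords"])
        return cls(de=de, **raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def validate(self) -> None:
        required = {
            "expression_path": self.expression_path,
            "design_path": self.design_path,
            "hits_ab_path": self.hits_ab_path,
            "hits_ba_path": self.hits_ba_path,
            "est_counts_path": self.est_counts_path,
            "corpus_path": self.corpus_path,
        }
        for name, p in required.items():
            if not p:
                raise ConfigError(f"missing required input path: {name}")
            if not Path(p).exists():
                raise ConfigError(f"{name} does not exist: {p}")
        for name, p in (("qpcr_path", self.qpcr_path), ("annotation_path", self.annotation_path)):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} does not exist: {p}")
        if self.endo_total <= 0 or self.nonendo_total <= 0:
            raise ConfigError("pool totals must be positive")
        if not 0 < self.q_max <= 1:
            raise ConfigError("q_max must lie in (0, 1]")


@contextlib.contextmanager
def _stage(name: str):
    try:
        yield
    except (PipelineError, ConfigError):
        raise
    except Exception as exc:  # noqa: BLE001 - deliberate stage wrapping
        raise PipelineError(name, str(exc)) from exc


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full screen and write the report bundle under ``config.outdir``.

    Returns a dict with the key tables and output paths.  The run is a pure
    function of (config, seed): re-running writes byte-identical outputs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    de_cfg = config.de

    with _stage("load"):
        matrix = read_expression_table(config.expression_path)
        design = read_design_table(config.design_path)

    if config.normalize:
        with _stage("normalize"):
            matrix = normalize_global_scaling(matrix, config.target_intensity, config.trim_fraction)
            write_expression_table(
                matrix,
                outdir / "normalized_expression.tsv",
                [
                    "stage: normalize",
                    f"target_intensity: {config.target_intensity}",
                    f"trim_fraction: {config.trim_fraction}",
                ],
            )

    with _stage("differential_expression"):
        results = permutation_fdr(matrix, design, de_cfg)
        up, down = select_de_genes(results, de_cfg)
        write_results_table(
            results,
            outdir / "de_results.tsv",
            [
                "stage: differential_expression",
                f"n_permutations: {de_cfg.n_permutations} paired: {de_cfg.paired} seed: {de_cfg.seed}",
                f"fdr_max: {de_cfg.fdr_max} fc_min: {de_cfg.fc_min}",
            ],
        )

    with _stage("ortholog_rbh"):
        a_to_b = read_blast_tabular(config.hits_ab_path)
        b_to_a = read_blast_tabular(config.hits_ba_path)
        pairs = reciprocal_best_hits(a_to_b, b_to_a)
        orthologs = ortholog_map(pairs)
        write_pairs_table(pairs, outdir / "orthologs.tsv", ["stage: ortholog_rbh"])

    with _stage("endothelial_filter"):
        counts = read_est_counts(config.est_counts_path)
        screen = endothelial_screen(counts, config.endo_total, config.nonendo_total)
        by_gene = {r.gene_symbol: r for r in screen}

    with _stage("angioscore"):
        corpus = read_corpus(config.corpus_path)
        keywords = KeywordSet(config.keywords) if config.keywords else KeywordSet()

    with _stage("report"):
        de_called = up + down
        joined: list[EndoRecord] = []
        human_genes = []
        for r in de_called:
            human = orthologs.get(r.probe_id)
            if human is None or human not in by_gene:
                continue
            human_genes.append(human)
            rec = by_gene[human]
            joined.append(
                dataclasses.replace(rec, fold_change=round(r.signed_fold_change, 2))
            )
        scores = angioscore_table(human_genes, corpus, keywords)
        joined = [
            dataclasses.replace(rec, angioscore=int(scores[rec.gene_symbol])) for rec in joined
        ]
        report = filter_endothelial(joined, config.q_max)
        report_path = outdir / "endothelial_report.tsv"
        write_endo_report(
            report,
            report_path,
            [
                "stage: report (endothelial screen joined with Angioscore and fold change)",
                f"q_max: {config.q_max} pool_totals: {config.endo_total}/{config.nonendo_total}",
            ],
        )

    qpcr_table = None
    if config.qpcr_path:
        with _stage("qpcr"):
            ct = read_ct_table(config.qpcr_path)
            qpcr_table = gene_summary_table(ct)
            write_fold_change_table(qpcr_table, outdir / "qpcr_fold_changes.tsv", ["stage: qpcr"])

    enrichment = None
    if config.annotation_path:
        with _stage("functional_summary"):
            annotation = read_annotation(config.annotation_path)
            background = list(matrix.probe_ids)
            enrichment = enrichment_table([r.probe_id for r in up], background, annotation)
            with open(outdir / "enrichment_up.tsv", "w") as fh:
                fh.write("# stage: functional_summary (up-regulated list)\n")
                enrichment.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    with _stage("manifest"):
        manifest = {
            "camwound_version": __version__,
            "versions": {
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "statsmodels": statsmodels.__version__,
            },
            "config": config.to_dict(),
            "counts": {
                "probes": matrix.n_probes,
                "de_up": len(up),
                "de_down": len(down),
                "ortholog_pairs": len(pairs),
                "endothelial_screen_genes": len(screen),
                "report_genes": len(report),
            },
        }
        with open(outdir / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    return {
        "de_results": results,
        "up": up,
        "down": down,
        "pairs": pairs,
        "screen": screen,
        "report": report,
        "report_path": report_path,
        "qpcr": qpcr_table,
        "enrichment": enrichment,
        "outdir": outdir,
    }


def simulate_input_bundle(
    outdir,
    seed: int = 0,
    n_genes: int = 400,
    n_pairs: int = 3,
    de_fraction: float = 0.1,
    noise_cv: float = 0.1,
    n_decoys: int = 10,
    n_enriched_de: int = 15,
    n_enriched_other: int = 5,
    n_qpcr_genes: int = 9,
) -> Path:
    """Write a coherent synthetic input bundle plus config.yaml and truth.json.

    The same genes flow through every stage: chicken probes cGENExxxxx map
    one-to-one to human symbols HGENExxxxx via the planted ortholog graph;
    the endothelial pool enrichment is planted on human orthologs of a subset
    of the differentially expressed genes; the literature corpus covers the
    human genes; the qPCR plate re-measures a subset of the planted effects.

    Returns the path to the written config.yaml.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # effects planted at 3..80-fold: within the observed range and clearly
    # separable with three egg pairs
    fc_dist = lambda r, n: np.exp(r.uniform(np.log(3.0), np.log(80.0), n))
    matrix, design, truth_expr = generate_expression_experiment(
        n_genes=n_genes,
        n_pairs=n_pairs,
        de_fraction=de_fraction,
        fc_distribution=fc_dist,
        noise_cv=noise_cv,
        seed=seed,
        gene_prefix="cGENE",
    )
    write_expression_table(matrix, outdir / "expression.tsv")
    write_design_table(design, outdir / "design.tsv")

    a_to_b, b_to_a, truth_rbh = generate_hit_tables(
        n_orthologs=n_genes, n_decoys=n_decoys, seed=seed + 1, a_prefix="cGENE", b_prefix="HGENE"
    )
    write_blast_tabular(a_to_b, outdir / "hits_chick_to_human.tsv")
    write_blast_tabular(b_to_a, outdir / "hits_human_to_chick.tsv")
    human_of = dict(truth_rbh.ortholog_pairs)

    de_genes = [g for g, flag in truth_expr.de_flags.items() if flag]
    enriched = [human_of[g] for g in de_genes[:n_enriched_de]]
    non_de = [g for g, flag in truth_expr.de_flags.items() if not flag]
    extra_idx = rng.choice(len(non_de), size=n_enriched_other, replace=False)
    enriched += [human_of[non_de[i]] for i in extra_idx]
    human_genes = [human_of[g] for g in matrix.probe_ids]
    est_table, truth_est = generate_est_pools(
        genes=human_genes, enriched_genes=enriched, seed=seed + 2
    )
    est_table.to_csv(outdir / "est_counts.tsv", sep="\t", index=False)

    corpus, truth_corpus = generate_abstract_corpus(
        human_genes, per_gene_abstract_rate=2.0, keyword_rate=0.5, seed=seed + 3
    )
    write_corpus(corpus, outdir / "corpus.tsv")

    qpcr_genes = de_genes[:n_qpcr_genes]
    gene_fcs = {g: truth_expr.true_fold_change[g] for g in qpcr_genes}
    ct_table, truth_qpcr = generate_qpcr_plate(gene_fcs, ct_noise_sd=0.2, n_eggs=9, seed=seed + 4)
    ct_table.to_csv(outdir / "qpcr_ct.tsv", sep="\t", index=False)

    terms = [
        ("GO:0001525", "angiogenesis", "biological_process"),
        ("GO:0008283", "cell population proliferation", "biological_process"),
        ("GO:0005576", "extracellular region", "cellular_component"),
        ("GO:0005488", "binding", "molecular_function"),
    ]
    ann_rows = []
    for g in matrix.probe_ids:
        for t, name, ns in terms:
            if rng.random() < 0.3:
                ann_rows.append({"gene_symbol": g, "term_id": t, "term_name": name, "namespace": ns})
    pd.DataFrame(ann_rows).to_csv(outdir / "annotation.tsv", sep="\t", index=False)

    truth = (
        truth_expr.merged_with(truth_rbh)
        .merged_with(truth_est)
        .merged_with(truth_corpus)
        .merged_with(truth_qpcr)
    )
    truth.to_json(outdir / "truth.json")

    config = {
        "expression_path": str(outdir / "expression.tsv"),
        "design_path": str(outdir / "design.tsv"),
        "hits_ab_path": str(outdir / "hits_chick_to_human.tsv"),
        "hits_ba_path": str(outdir / "hits_human_to_chick.tsv"),
        "est_counts_path": str(outdir / "est_counts.tsv"),
        "corpus_path": str(outdir / "corpus.tsv"),
        "qpcr_path": str(outdir / "qpcr_ct.tsv"),
        "annotation_path": str(outdir / "annotation.tsv"),
        "endo_total": 10000,
        "nonendo_total": 43910,
        "q_max": 0.01,
        # generated intensities are already on a common scale; rescaling a
        # matrix with many large planted effects would violate the
        # mostly-unchanged-genes assumption behind global scaling
        "normalize": False,
        "seed": seed,
        "de": {"seed": seed, "paired": False},
        "outdir": str(outdir / "pipeline_out"),
    }
    config_path = outdir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config_path
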