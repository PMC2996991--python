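"""Seeded generators emulating every input of the wound-screen pipeline.

Each generator is a pure function of its parameters and seed, and emits a
:class:`SimulationTruth` alongside its data so that parameter-recovery tests
can compare estimates against known ground truth.  With all noise parameters
at zero, every downstream estimator inverts its generator exactly.

The defaults mirror the study conditions: three matched wound/control egg
pairs on a ~2000-gene chip slice, planted wound effects reaching the
observed up-to-~79-fold range, an endothelial/non-endothelial EST pool pair
at the published screen's pool-size ratio (~4.391), and nine-egg qPCR plates
with a stable housekeeping gene.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .angioscore import DEFAULT_KEYWORDS, AbstractRecord
from .endothelial_filter import DEFAULT_POOL_RATIO
from .expression_matrix import ExpressionMatrix, SampleDesign
from .ortholog_rbh import AlignmentHit


@dataclass
class SimulationTruth:
    """Ground truth emitted by the generators (unused slots stay empty)."""

    true_fold_change: dict[str, float] = field(default_factory=dict)
    de_flags: dict[str, bool] = field(default_factory=dict)
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    endothelial_genes: list[str] = field(default_factory=list)
    keyword_abstract_counts: dict[str, int] = field(default_factory=dict)
    qpcr_fold_changes: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        obj = dataclasses.asdict(self)
        obj["ortholog_pairs"] = [list(p) for p in self.ortholog_pairs]
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            obj = json.load(fh)
        obj["ortholog_pairs"] = [tuple(p) for p in obj.get("ortholog_pairs", [])]
        return cls(**obj)

    def merged_with(self, other: "SimulationTruth") -> "SimulationTruth":
        return SimulationTruth(
            {**self.true_fold_change, **other.true_fold_change},
            {**self.de_flags, **other.de_flags},
            self.ortholog_pairs + other.ortholog_pairs,
            self.endothelial_genes + other.endothelial_genes,
            {**self.keyword_abstract_counts, **other.keyword_abstract_counts},
            {**self.qpcr_fold_changes, **other.qpcr_fold_changes},
        )


def _draw_fold_changes(rng: np.random.Generator, n: int, fc_distribution) -> np.ndarray:
    """Planted wound/control ratios.

    ``fc_distribution`` may be a scalar (constant FC), a sequence to sample
    from, or a callable ``f(rng, n)``.  The default is log-uniform on
    [2, 80], covering the observed effect range up to ~79-fold.
    """
    if fc_distribution is None:
        return np.exp(rng.uniform(math.log(2.0), math.log(80.0), n))
    if callable(fc_distribution):
        return np.asarray(fc_distribution(rng, n), dtype=float)
    if np.isscalar(fc_distribution):
        return np.full(n, float(fc_distribution))
    choices = np.asarray(fc_distribution, dtype=float)
    return choices[rng.integers(0, choices.size, n)]


def generate_expression_experiment(
    n_genes: int = 2000,
    n_pairs: int = 3,
    de_fraction: float = 0.0,
    fc_distribution=None,
    noise_cv: float = 0.3,
    egg_effect_sd: float = 0.1,
    seed: int = 0,
    gene_prefix: str = "g",
):
    """Matched wound/control expression experiment with planted fold changes.

    Baseline intensities are log-normal; each egg carries a shared
    multiplicative random effect (both its samples move together, as in the
    paired design); measurement noise is multiplicative log-normal with
    coefficient of variation ``noise_cv``.  Differentially expressed genes
    (fraction ``de_fraction``) get a multiplicative wound effect drawn from
    ``fc_distribution``.

    Returns ``(ExpressionMatrix, SampleDesign, SimulationTruth)``.
    """
    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must lie in [0, 1]")
    if noise_cv < 0 or egg_effect_sd < 0:
        raise ValueError("noise parameters must be non-negative")
    rng = np.random.default_rng(seed)
    genes = [f"{gene_prefix}{i:05d}" for i in range(n_genes)]
    base = np.exp(rng.normal(math.log(100.0), 1.0, n_genes))

    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    fc = np.ones(n_genes)
    fc[de_idx] = _draw_fold_changes(rng, n_de, fc_distribution)

    egg_effects = np.exp(rng.normal(0.0, egg_effect_sd, n_pairs))
    sigma = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0

    columns = {}
    design_rows = []
    for i in range(n_pairs):
        egg = f"egg{i + 1}"
        for group in ("wound", "control"):
            sample = f"{group}_{i + 1}"
            effect = fc if group == "wound" else 1.0
            noise = np.exp(rng.normal(0.0, sigma, n_genes)) if sigma > 0 else 1.0
            columns[sample] = base * effect * egg_effects[i] * noise
            design_rows.append({"sample_id": sample, "group": group, "egg_id": egg})
    matrix = ExpressionMatrix(pd.DataFrame(columns, index=genes))
    design = SampleDesign(pd.DataFrame(design_rows))
    truth = SimulationTruth(
        true_fold_change={g: float(f) for g, f in zip(genes, fc)},
        de_flags={g: bool(i in set(de_idx)) for i, g in enumerate(genes)},
    )
    return matrix, design, truth


def generate_hit_tables(
    n_orthologs: int = 30,
    n_decoys: int = 10,
    score_model=None,
    seed: int = 0,
    a_prefix: str = "chick",
    b_prefix: str = "human",
    identity_range: tuple[float, float] = (96.0, 99.9),
):
    """Bidirectional alignment hit tables with a planted one-to-one ortholog set.

    Planted pairs are mutual best hits with Good-rank alignments; decoy
    paralogs get an inflated score in one direction only, so a plain
    best-hit mapping would pick them up but the reciprocal rule discards
    them.  Additional low-quality hits exercise the Reasonable and Bad rank
    classes.  ``score_model(rng)`` may override the base bit-score draw.

    Returns ``(a_to_b_hits, b_to_a_hits, SimulationTruth)``.
    """
    rng = np.random.default_rng(seed)
    a_genes = [f"{a_prefix}{i:05d}" for i in range(n_orthologs)]
    b_genes = [f"{b_prefix}{i:05d}" for i in range(n_orthologs)]
    draw_score = score_model or (lambda r: float(r.uniform(400.0, 600.0)))

    a_to_b: list[AlignmentHit] = []
    b_to_a: list[AlignmentHit] = []
    lo_ident, hi_ident = identity_range
    for a, b in zip(a_genes, b_genes):
        score = draw_score(rng)
        ident = float(rng.uniform(lo_ident, hi_ident))
        length = int(rng.integers(150, 900))
        a_to_b.append(AlignmentHit(a, b, ident, length, score, 1e-50))
        b_to_a.append(AlignmentHit(b, a, ident, length, score * float(rng.uniform(0.95, 1.0)), 1e-50))
        # weaker cross-hits to a wrong partner (Reasonable or Bad rank)
        if n_orthologs > 1:
            other = b_genes[int(rng.integers(0, n_orthologs))]
            if other != b:
                a_to_b.append(
                    AlignmentHit(
                        a,
                        other,
                        min(float(rng.uniform(85.0, 95.0)), hi_ident),
                        int(rng.integers(60, 400)),
                        score * float(rng.uniform(0.3, 0.7)),
                        1e-10,
                    )
                )
    # decoys: a-side paralogs whose best hit is a real b gene, one-way only
    for j in range(n_decoys):
        decoy = f"{a_prefix}_decoy{j:03d}"
        target_i = int(rng.integers(0, n_orthologs))
        target = b_genes[target_i]
        inflated = 700.0 + float(rng.uniform(0.0, 100.0))
        a_to_b.append(
            AlignmentHit(decoy, target, float(rng.uniform(96.0, 99.0)), int(rng.integers(150, 600)), inflated, 1e-60)
        )
        # the b gene still prefers its true ortholog: decoy reverse hit scores lower
        b_to_a.append(
            AlignmentHit(target, decoy, float(rng.uniform(90.0, 95.0)), int(rng.integers(120, 400)), 100.0 + float(rng.uniform(0.0, 50.0)), 1e-20)
        )
    truth = SimulationTruth(ortholog_pairs=list(zip(a_genes, b_genes)))
    return a_to_b, b_to_a, truth


def generate_est_pools(
    n_genes: int = 500,
    endo_total: int = 10000,
    nonendo_total: int | None = None,
    enriched_fraction: float = 0.04,
    enrichment_factor: float = 20.0,
    seed: int = 0,
    gene_prefix: str = "HGENE",
    genes: list[str] | None = None,
    enriched_genes: list[str] | None = None,
    exact_counts: bool = False,
):
    """EST counts for an endothelial and a non-endothelial library pool.

    Per-gene counts are multinomial draws over the genes plus an explicit
    unreported remainder category (libraries contain many transcripts beyond
    the genes under study), so pool totals are conserved exactly while null
    genes keep identical per-EST probabilities in both pools.  Enriched
    genes' endothelial-pool rates are multiplied by ``enrichment_factor``.

    Returns ``(count table, SimulationTruth)``; the count table has columns
    gene, endo_count, nonendo_count.
    """
    if nonendo_total is None:
        nonendo_total = int(round(endo_total * DEFAULT_POOL_RATIO))
    if endo_total <= 0 or nonendo_total <= 0:
        raise ValueError("pool totals must be positive")
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = [f"{gene_prefix}{i:05d}" for i in range(n_genes)]
    n_genes = len(genes)
    if enriched_genes is None:
        n_enriched = int(round(enriched_fraction * n_genes))
        enriched_idx = rng.choice(n_genes, size=n_enriched, replace=False)
        enriched_genes = [genes[i] for i in enriched_idx]
    enriched_set = set(enriched_genes)

    weights = rng.gamma(5.0, 1.0, n_genes)
    base_prob = weights / weights.sum() * 0.3  # genes take ~30% of each library
    boost = np.array([enrichment_factor if g in enriched_set else 1.0 for g in genes])
    endo_prob = base_prob * boost
    # keep probabilities proper in both pools with a single common rescale,
    # so null genes' pool ratio stays exactly 1
    scale = min(1.0, 0.9 / endo_prob.sum())
    endo_prob = endo_prob * scale
    non_prob = base_prob * scale

    if exact_counts:
        # noise-free mode: emit the exact expected counts (possibly fractional),
        # under which the enrichment factor is recovered without sampling error
        endo_counts = endo_total * endo_prob
        non_counts = nonendo_total * non_prob
    else:
        endo_counts = rng.multinomial(endo_total, np.append(endo_prob, 1.0 - endo_prob.sum()))[:-1]
        non_counts = rng.multinomial(nonendo_total, np.append(non_prob, 1.0 - non_prob.sum()))[:-1]
    table = pd.DataFrame({"gene": genes, "endo_count": endo_counts, "nonendo_count": non_counts})
    truth = SimulationTruth(endothelial_genes=sorted(enriched_set))
    return table, truth


_FILLER_SENTENCES = (
    "bone mineral density was measured in aging mice",
    "the enzyme kinetics of the purified protein were characterized",
    "chromatin remodeling factors were profiled during differentiation",
    "a cohort study of dietary fiber intake and colon health",
    "ribosome assembly requires coordinated rRNA processing steps",
)

_KEYWORD_SENTENCES = tuple(
    f"this study examines {kw} signalling in tissue repair" for kw in DEFAULT_KEYWORDS
)


def generate_abstract_corpus(
    genes,
    per_gene_abstract_rate: float = 3.0,
    keyword_rate: float = 0.5,
    seed: int = 0,
):
    """Gene-linked abstracts with a controllable keyword rate.

    Every gene receives ``Poisson(per_gene_abstract_rate)`` abstracts, each of
    which independently contains an angiogenesis keyword with probability
    ``keyword_rate``.  Truth records each gene's exact keyword-abstract count
    (its expected Angioscore under abstract counting).

    Returns ``(corpus, SimulationTruth)``.
    """
    if per_gene_abstract_rate < 0 or not 0 <= keyword_rate <= 1:
        raise ValueError("rates must be non-negative (keyword_rate in [0, 1])")
    rng = np.random.default_rng(seed)
    corpus: list[AbstractRecord] = []
    counts: dict[str, int] = {}
    k = 0
    for gene in genes:
        n_abs = int(rng.poisson(per_gene_abstract_rate))
        hits = 0
        for _ in range(n_abs):
            keyworded = bool(rng.random() < keyword_rate)
            if keyworded:
                text = _KEYWORD_SENTENCES[int(rng.integers(0, len(_KEYWORD_SENTENCES)))]
                hits += 1
            else:
                text = _FILLER_SENTENCES[int(rng.integers(0, len(_FILLER_SENTENCES)))]
            corpus.append(AbstractRecord(f"abs{k:06d}", frozenset([gene]), text))
            k += 1
        counts[gene] = hits
    truth = SimulationTruth(keyword_abstract_counts=counts)
    return corpus, truth


def generate_qpcr_plate(
    gene_fcs: dict[str, float],
    ct_noise_sd: float = 0.2,
    n_eggs: int = 9,
    seed: int = 0,
    housekeeping: str = "HNRPH1",
):
    """qPCR Ct table for target genes with planted fold changes.

    The housekeeping gene's Ct is stable across conditions; a target's wound
    Ct is shifted by ``-log2(FC)`` relative to its control.  Gaussian Ct
    noise with standard deviation ``ct_noise_sd`` is added per well.

    Returns ``(CtRecord table, SimulationTruth)``; the table has columns
    gene, sample_id, condition, egg_id, ct.
    """
    if any(fc <= 0 for fc in gene_fcs.values()):
        raise ValueError("planted fold changes must be positive")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    base_ct = {g: float(rng.uniform(20.0, 28.0)) for g in gene_fcs}
    hk_base = 18.0
    rows = []
    for i in range(n_eggs):
        egg = f"egg{i + 1}"
        for condition in ("wound", "control"):
            sample = f"{condition}_{i + 1}"
            noise = float(rng.normal(0.0, ct_noise_sd)) if ct_noise_sd > 0 else 0.0
            rows.append(
                {
                    "gene": housekeeping,
                    "sample_id": sample,
                    "condition": condition,
                    "egg_id": egg,
                    "ct": hk_base + noise,
                }
            )
            for gene, fc in gene_fcs.items():
                shift = -math.log2(fc) if condition == "wound" else 0.0
                noise = float(rng.normal(0.0, ct_noise_sd)) if ct_noise_sd > 0 else 0.0
                rows.append(
                    {
                        "gene": gene,
                        "sample_id": sample,
                        "condition": condition,
                        "egg_id": egg,
                        "ct": base_ct[gene] + shift + noise,
                    }
                )
    table = pd.DataFrame(rows)
    truth = SimulationTruth(qpcr_fold_changes={g: float(f) for g, f in gene_fcs.items()})
    return table, truth
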