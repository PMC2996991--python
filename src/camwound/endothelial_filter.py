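"""Endothelial-signature screen over two cDNA-library EST pools.

Genes preferentially expressed in endothelial cells are detected by comparing
per-gene EST counts between a pooled endothelial cDNA library and a pooled
non-endothelial library.  The "Endofactor" is the ratio of the gene's
normalized EST frequency between the pools; significance comes from a 2x2
likelihood-ratio (G) test against the pooled proportion, with
Benjamini-Hochberg q-values and an inclusive q <= 0.01 retention filter.

Pool totals are inputs: only their ratio matters for the Endofactor, and the
published table's arithmetic is internally consistent with a single
non-endothelial/endothelial pool-size ratio of about 4.391014.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

#: Non-endothelial / endothelial pool-size ratio that reproduces the published
#: screen's finite Endofactor values from their printed EST counts.
DEFAULT_POOL_RATIO = 2.195507 * 68 / 34


@dataclass(frozen=True)
class EndoRecord:
    """Per-gene endothelial screen record (optionally joined with the
    literature Angioscore and the wound/control fold change)."""

    gene_symbol: str
    endo_count: int
    nonendo_count: int
    endo_factor: float  # may be math.inf
    p_value: float
    q_value: float
    direction: str  # "up" iff endo_factor > 1 else "down"
    angioscore: int | None = None
    fold_change: float | None = None


def endo_factor(endo_count: int, nonendo_count: int, endo_total: float, nonendo_total: float) -> float:
    """Endothelial enrichment factor: (c_e/N_e) / (c_n/N_n).

    Infinite when the gene is absent from the non-endothelial pool but
    present in the endothelial one; zero in the mirror case; a gene absent
    from both pools has no defined factor and raises.
    """
    if endo_total <= 0 or nonendo_total <= 0:
        raise ValueError("pool totals must be positive")
    if endo_count < 0 or nonendo_count < 0:
        raise ValueError("counts must be non-negative")
    if endo_count > endo_total or nonendo_count > nonendo_total:
        raise ValueError("counts cannot exceed pool totals")
    if endo_count == 0 and nonendo_count == 0:
        raise ValueError("gene absent from both pools")
    if nonendo_count == 0:
        return math.inf
    return (endo_count / endo_total) / (nonendo_count / nonendo_total)


def lr_test(endo_count: int, nonendo_count: int, endo_total: float, nonendo_total: float):
    """2x2 likelihood-ratio (G) test of equal EST proportions in the two pools.

    The table is ``[[c_e, N_e - c_e], [c_n, N_n - c_n]]`` with the convention
    0*log(0) = 0; the p-value comes from the chi-square distribution with one
    degree of freedom.  Returns ``(statistic, p_value)``.
    """
    if endo_count > endo_total or nonendo_count > nonendo_total:
        raise ValueError("counts cannot exceed pool totals")
    if endo_count < 0 or nonendo_count < 0:
        raise ValueError("counts must be non-negative")
    table = np.array(
        [
            [endo_count, endo_total - endo_count],
            [nonendo_count, nonendo_total - nonendo_count],
        ],
        dtype=float,
    )
    if table.sum(axis=1).min() <= 0 or table.sum(axis=0).min() < 0:
        raise ValueError("pool totals must be positive")
    if endo_count + nonendo_count == 0:
        return 0.0, 1.0  # empty margin: trivially null
    res = chi2_contingency(table, correction=False, lambda_="log-likelihood")
    return float(res.statistic), float(res.pvalue)


def q_values(p_values, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjusted q-values.

    ``method="bh"`` is Benjamini-Hochberg step-up; ``method="storey"``
    additionally estimates the null proportion pi0 (at lambda = 0.5) and
    rescales the BH values, clipped to [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    bh = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return bh
    if method == "storey":
        lam = 0.5
        pi0 = min(1.0, float((p > lam).mean()) / (1.0 - lam))
        return np.clip(pi0 * bh, 0.0, 1.0)
    raise ValueError(f"unknown q-value method: {method!r}")


def endothelial_screen(
    counts: pd.DataFrame,
    endo_total: float,
    nonendo_total: float,
    q_method: str = "bh",
) -> list[EndoRecord]:
    """Score every gene in a count table (columns: gene, endo_count, nonendo_count).

    Genes absent from both pools are dropped (their factor is undefined).
    """
    required = {"gene", "endo_count", "nonendo_count"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    counts = counts[(counts["endo_count"] > 0) | (counts["nonendo_count"] > 0)]
    records = []
    p_values = []
    for row in counts.itertuples():
        ce, cn = int(row.endo_count), int(row.nonendo_count)
        ef = endo_factor(ce, cn, endo_total, nonendo_total)
        g, p = lr_test(ce, cn, endo_total, nonendo_total)
        p_values.append(p)
        records.append(
            EndoRecord(
                gene_symbol=str(row.gene),
                endo_count=ce,
                nonendo_count=cn,
                endo_factor=ef,
                p_value=p,
                q_value=math.nan,
                direction="up" if ef > 1 else "down",
            )
        )
    qs = q_values(p_values, method=q_method)
    return [replace(r, q_value=float(q)) for r, q in zip(records, qs)]


def _sort_key(r: EndoRecord):
    # within equal q: most extreme factor first; infinite (and zero) factors
    # have |log factor| = inf and therefore lead
    if r.endo_factor == 0 or math.isinf(r.endo_factor):
        extremity = math.inf
    else:
        extremity = abs(math.log(r.endo_factor))
    return (r.q_value, -extremity)


def filter_endothelial(records: list[EndoRecord], q_max: float = 0.01) -> list[EndoRecord]:
    """Retain records with q <= q_max (inclusive), sorted by q then extremity."""
    kept = [r for r in records if r.q_value <= q_max]
    return sorted(kept, key=_sort_key)


def read_est_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return df


def records_table(records: list[EndoRecord]) -> pd.DataFrame:
    """Published-screen-shaped table (Endofactor spelled ``inf`` when infinite)."""
    return pd.DataFrame(
        {
            "gene": [r.gene_symbol for r in records],
            "qvalue": [r.q_value for r in records],
            "endo_count": [r.endo_count for r in records],
            "nonendo_count": [r.nonendo_count for r in records],
            "endo_factor": ["inf" if math.isinf(r.endo_factor) else f"{r.endo_factor:.6f}" for r in records],
            "direction": [r.direction for r in records],
            "angioscore": [r.angioscore for r in records],
            "fold_change": [r.fold_change for r in records],
        }
    )


def write_endo_report(records: list[EndoRecord], path, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        records_table(records).to_csv(fh, sep="\t", index=False, float_format="%.6g")
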