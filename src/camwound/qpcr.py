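"""Relative qPCR quantification by the ddCt method.

Target-gene cycle thresholds are normalized within each sample against the
housekeeping gene HNRPH1, the housekeeping-normalized difference between
wound and matched control gives ddCt, and the fold change is 2**(-ddCt)
(assuming perfect doubling per cycle).  Primer pairs are gated on standard-
curve amplification efficiency: only efficiencies between 90 and 100% pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

DEFAULT_HOUSEKEEPING = "HNRPH1"


class QPCRError(ValueError):
    """Raised for malformed or incomplete Ct tables."""


@dataclass(frozen=True)
class StandardCurve:
    """Linear standard curve: Ct versus log10 template dilution."""

    gene: str
    slope: float  # cycles per log10 dilution; negative for amplifying primers
    intercept: float = 0.0


class EfficiencyResult(NamedTuple):
    efficiency: float
    passes: bool


def amplification_efficiency(
    curve: StandardCurve, min_efficiency: float = 0.90, max_efficiency: float = 1.00
) -> EfficiencyResult:
    """Amplification efficiency from the standard-curve slope.

    ``E = 10**(-1/slope) - 1``; a slope of -3.3219 (= -1/log10(2)) means
    perfect doubling, E = 1.  The pass flag applies the 90-100% acceptance
    window used to gate primer pairs.
    """
    if curve.slope >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {curve.slope}")
    eff = 10.0 ** (-1.0 / curve.slope) - 1.0
    # gate on the efficiency rounded to 0.1%: the conventional 4-digit
    # "perfect doubling" slope -3.3219 yields E = 1.000024, which the
    # 90-100% window is meant to accept
    gated = round(eff, 3)
    return EfficiencyResult(eff, min_efficiency <= gated <= max_efficiency)


def ddct_fold_change(
    ct_target_wound: float,
    ct_hk_wound: float,
    ct_target_control: float,
    ct_hk_control: float,
) -> float:
    """Fold change 2**(-ddCt) from four cycle thresholds.

    dCt_w = Ct(target, wound) - Ct(housekeeping, wound); likewise for the
    control; ddCt is their difference, so the result is shift-invariant
    within a sample and log2(FC) is exactly linear in -ddCt.
    """
    dct_w = ct_target_wound - ct_hk_wound
    dct_c = ct_target_control - ct_hk_control
    return 2.0 ** (-(dct_w - dct_c))


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"ct": float})
    required = {"gene", "sample_id", "condition", "egg_id", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise QPCRError(f"Ct table missing columns: {sorted(missing)}")
    return df


def average_technical_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Average Ct over technical replicates of the same (gene, egg, condition).

    Averaging happens on the Ct scale before any ddCt arithmetic.
    """
    keys = ["gene", "egg_id", "condition"]
    out = records.groupby(keys, as_index=False, sort=False).agg(
        sample_id=("sample_id", "first"), ct=("ct", "mean")
    )
    return out[["gene", "sample_id", "condition", "egg_id", "ct"]]


def _lookup_ct(records: pd.DataFrame, gene: str, egg, condition: str) -> float:
    sub = records[
        (records["gene"] == gene)
        & (records["egg_id"] == egg)
        & (records["condition"] == condition)
    ]
    if len(sub) == 0:
        raise QPCRError(f"missing Ct record for gene {gene!r}, egg {egg!r}, condition {condition!r}")
    return float(sub["ct"].mean())


def per_egg_fold_changes(
    records: pd.DataFrame, gene: str, housekeeping: str = DEFAULT_HOUSEKEEPING
) -> pd.DataFrame:
    """One ddCt fold change per egg for ``gene``, normalized to ``housekeeping``.

    Every egg carrying any record for the gene must have all four Ct values
    (target and housekeeping in both conditions); a missing record raises a
    :class:`QPCRError` naming the gene, egg and condition.
    """
    records = average_technical_replicates(records)
    eggs = list(dict.fromkeys(records.loc[records["gene"] == gene, "egg_id"]))
    if not eggs:
        raise QPCRError(f"no Ct records for gene {gene!r}")
    rows = []
    for egg in eggs:
        fc = ddct_fold_change(
            _lookup_ct(records, gene, egg, "wound"),
            _lookup_ct(records, housekeeping, egg, "wound"),
            _lookup_ct(records, gene, egg, "control"),
            _lookup_ct(records, housekeeping, egg, "control"),
        )
        rows.append({"egg_id": egg, "fold_change": fc})
    return pd.DataFrame(rows)


def summarize_fold_change(fold_changes, method: str = "geometric") -> float:
    """Summary fold change across eggs (geometric mean by default).

    Fold changes are ratios, so the geometric mean is the natural summary;
    an arithmetic mean is available behind the flag.
    """
    fc = np.asarray(fold_changes, dtype=float)
    if fc.size == 0:
        raise QPCRError("no fold changes to summarize")
    if (fc <= 0).any():
        raise QPCRError("fold changes must be positive")
    if method == "geometric":
        return float(np.exp(np.log(fc).mean()))
    if method == "arithmetic":
        return float(fc.mean())
    raise ValueError(f"unknown summary method: {method!r}")


def gene_summary_table(
    records: pd.DataFrame,
    genes=None,
    housekeeping: str = DEFAULT_HOUSEKEEPING,
    method: str = "geometric",
) -> pd.DataFrame:
    """Per-egg fold changes plus a summary row per gene (long format).

    Rows with ``egg_id == "summary"`` carry the across-egg summary.
    """
    if genes is None:
        genes = [g for g in dict.fromkeys(records["gene"]) if g != housekeeping]
    frames = []
    for gene in genes:
        per_egg = per_egg_fold_changes(records, gene, housekeeping)
        per_egg.insert(0, "gene", gene)
        summary = pd.DataFrame(
            [
                {
                    "gene": gene,
                    "egg_id": "summary",
                    "fold_change": summarize_fold_change(per_egg["fold_change"], method),
                }
            ]
        )
        frames.append(pd.concat([per_egg, summary], ignore_index=True))
    return pd.concat(frames, ignore_index=True)


def write_fold_change_table(table: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
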