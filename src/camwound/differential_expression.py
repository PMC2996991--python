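"""SAM-style two-class differential expression with permutation FDR.

The statistic is the Wilcoxon rank sum (midranks for ties), following the
Wilcoxon variant of Significance Analysis of Microarrays; significance comes
from sample-label permutation.  Because the rank statistic is permutation-
invariant by construction, ranks are computed once per gene and every
relabeling only re-sums them, which keeps exhaustive enumeration cheap for
small designs (a 3v3 experiment has exactly 20 label assignments).

The fold-change criterion (mean wound/control ratio beyond the configured
threshold) is part of the calling rule and is therefore applied inside the
permutation counting as well: a gene counts as a (permuted) positive only if
both its rank statistic exceeds the cutoff and its permuted fold change
clears the threshold.  The estimated FDR for the list at a cutoff is the
median (optionally mean) permutation false-call count divided by the observed
call count, regularized to be non-increasing as the cutoff becomes more
extreme.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import comb
from scipy.stats import rankdata

from .expression_matrix import ExpressionMatrix, SampleDesign

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NS = "not_significant"


@dataclass
class DEConfig:
    """Settings for the differential-expression screen.

    Defaults reproduce the published analysis: 200 permutations, FDR kept
    below 5%, fold change above 2.  ``paired`` switches the permutation
    scheme from free label shuffling to within-egg label swaps (sign flips),
    respecting the matched design.
    """

    n_permutations: int = 200
    fdr_max: float = 0.05
    fc_min: float = 2.0
    seed: int = 0
    paired: bool = False
    center: str = "median"  # summary of permutation false-call counts

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        if not 0 < self.fdr_max < 1:
            raise ValueError("fdr_max must lie in (0, 1)")
        if self.fc_min <= 1:
            raise ValueError("fc_min must exceed 1")
        if self.center not in ("median", "mean"):
            raise ValueError("center must be 'median' or 'mean'")


@dataclass(frozen=True)
class DEResult:
    """Per-probe differential expression result."""

    probe_id: str
    statistic: float  # Wilcoxon rank sum of the wound group
    fold_change: float  # linear mean ratio wound/control
    signed_fold_change: float
    fdr: float
    call: str


def wilcoxon_statistic(group_a, group_b) -> float:
    """Rank sum of ``group_a`` within the pooled ranking (midranks for ties)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = rankdata(np.concatenate([a, b]))
    return float(ranks[: a.size].sum())


def mean_fold_change(m: ExpressionMatrix, d: SampleDesign) -> pd.Series:
    """Per-probe linear fold change: mean(wound) / mean(control)."""
    wound = d.wound_samples
    control = d.control_samples
    if not wound or not control:
        raise ValueError("both wound and control groups must be present")
    cm = m.data[control].mean(axis=1)
    if (cm <= 0).any():
        probe = cm.index[int(np.argmax((cm <= 0).to_numpy()))]
        raise ValueError(f"probe {probe!r} has non-positive control mean")
    fc = m.data[wound].mean(axis=1) / cm
    fc.name = "fold_change"
    return fc


def signed_fold_change(ratio: float) -> float:
    """Signed fold-change convention: ratio if >= 1, else -1/ratio.

    Down-regulation is reported as a negative reciprocal, so a wound/control
    ratio of 0.11 becomes -9.09 and the value never falls inside (-1, 1).
    """
    if not ratio > 0:
        raise ValueError("fold-change ratio must be positive")
    return float(ratio) if ratio >= 1 else -1.0 / float(ratio)


def _relabelings(d: SampleDesign, sample_ids: list[str], cfg: DEConfig):
    """Wound-group index sets under the permutation scheme.

    Returns ``(masks, exhaustive)`` where each mask is an integer index array
    selecting the permuted "wound" columns.  Exhaustive enumeration is used
    whenever the number of distinct relabelings does not exceed
    ``cfg.n_permutations``; otherwise relabelings are sampled with a seeded
    generator.
    """
    col_index = {s: i for i, s in enumerate(sample_ids)}
    wound_idx = [col_index[s] for s in d.wound_samples]
    control_idx = [col_index[s] for s in d.control_samples]
    n_w = len(wound_idx)
    rng = np.random.default_rng(cfg.seed)
    if cfg.paired:
        eggs = d.egg_ids
        pairs = [
            (col_index[d.sample_for(e, "wound")], col_index[d.sample_for(e, "control")])
            for e in eggs
        ]
        total = 2 ** len(eggs)
        if total <= 1:
            raise ValueError("design admits no distinct relabelings")
        if total <= cfg.n_permutations:
            patterns = itertools.product((0, 1), repeat=len(eggs))
            masks = [
                np.array([p[1] if f else p[0] for p, f in zip(pairs, flips)])
                for flips in patterns
            ]
        else:
            masks = [
                np.array(
                    [p[1] if f else p[0] for p, f in zip(pairs, rng.integers(0, 2, len(pairs)))]
                )
                for _ in range(cfg.n_permutations)
            ]
        return masks, total <= cfg.n_permutations
    n = len(sample_ids)
    total = int(comb(n, n_w, exact=True))
    if total <= 1:
        raise ValueError("design admits no distinct relabelings")
    if total <= cfg.n_permutations:
        masks = [np.array(c) for c in itertools.combinations(range(n), n_w)]
        return masks, True
    masks = [np.sort(rng.permutation(n)[:n_w]) for _ in range(cfg.n_permutations)]
    return masks, False


def _fold_changes(values: np.ndarray, wound_cols: np.ndarray, all_cols: np.ndarray) -> np.ndarray:
    """Per-gene wound/control mean ratio for one labeling (inf for zero control mean)."""
    control_cols = np.setdiff1d(all_cols, wound_cols)
    mw = values[:, wound_cols].mean(axis=1)
    mc = values[:, control_cols].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mc > 0, mw / np.where(mc > 0, mc, 1.0), np.inf)
    return fc


def _fc_pass(fc: np.ndarray, fc_min: float) -> np.ndarray:
    return (fc > fc_min) | (fc < 1.0 / fc_min)


def _cutoff_table(m: ExpressionMatrix, d: SampleDesign, cfg: DEConfig):
    """Permutation machinery shared by per-gene and per-list FDR.

    Returns observed W, score (|W - E0[W]|), fold changes, and a per-unique-
    cutoff table of observed counts, permutation false-call summaries and
    monotone FDR estimates.
    """
    values = m.values
    sample_ids = m.sample_ids
    missing = set(d.table["sample_id"]) - set(sample_ids)
    if missing:
        raise ValueError(f"design samples absent from matrix: {sorted(missing)}")
    col_index = {s: i for i, s in enumerate(sample_ids)}
    wound_cols = np.array([col_index[s] for s in d.wound_samples])
    if len(d.wound_samples) < 2 or len(d.control_samples) < 2:
        raise ValueError("need at least 2 samples per group")
    design_cols = np.array(sorted(set(col_index[s] for s in d.table["sample_id"])))

    ranks = rankdata(values[:, design_cols], axis=1)
    # column positions inside the design-restricted matrix
    pos = {c: i for i, c in enumerate(design_cols)}
    n = len(design_cols)
    n_w = len(wound_cols)
    e0 = n_w * (n + 1) / 2.0

    def score_for(mask_cols: np.ndarray) -> np.ndarray:
        mask_pos = np.array([pos[c] for c in mask_cols])
        w = ranks[:, mask_pos].sum(axis=1)
        return np.abs(w - e0), w

    obs_score, obs_w = score_for(wound_cols)
    obs_fc = _fold_changes(values, wound_cols, design_cols)
    obs_pass = _fc_pass(obs_fc, cfg.fc_min)

    masks, exhaustive = _relabelings(d, sample_ids, cfg)
    cutoffs = np.unique(obs_score)  # ascending
    passing_scores = np.sort(obs_score[obs_pass])
    obs_counts = passing_scores.size - np.searchsorted(passing_scores, cutoffs, side="left")

    perm_counts = np.empty((len(masks), cutoffs.size))
    for i, mask in enumerate(masks):
        s_p, _ = score_for(mask)
        fc_p = _fold_changes(values, mask, design_cols)
        sp = np.sort(s_p[_fc_pass(fc_p, cfg.fc_min)])
        perm_counts[i] = sp.size - np.searchsorted(sp, cutoffs, side="left")
    if cfg.center == "median":
        false_calls = np.median(perm_counts, axis=0)
    else:
        false_calls = perm_counts.mean(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(obs_counts > 0, false_calls / np.where(obs_counts > 0, obs_counts, 1), 1.0)
    raw = np.clip(raw, 0.0, 1.0)
    # regularize: FDR non-increasing as the cutoff becomes more extreme
    mono = np.minimum.accumulate(raw)
    table = pd.DataFrame(
        {
            "cutoff": cutoffs,
            "observed_calls": obs_counts,
            "permutation_false_calls": false_calls,
            "fdr_raw": raw,
            "fdr": mono,
        }
    )
    return obs_w, obs_score, obs_fc, obs_pass, table, exhaustive


def permutation_fdr(m: ExpressionMatrix, d: SampleDesign, cfg: DEConfig | None = None) -> list[DEResult]:
    """Per-gene SAM-style results with permutation FDR.

    Each gene's FDR is the (monotone-regularized) list FDR at the cutoff
    equal to its own statistic — a q-value-like convenience on top of the
    per-list convention of :func:`fdr_at_cutoff`.
    """
    cfg = cfg or DEConfig()
    obs_w, obs_score, obs_fc, obs_pass, table, _ = _cutoff_table(m, d, cfg)
    cut_idx = np.searchsorted(table["cutoff"].to_numpy(), obs_score)
    fdr = table["fdr"].to_numpy()[cut_idx]
    results = []
    for probe, w, fc, passes, q in zip(m.probe_ids, obs_w, obs_fc, obs_pass, fdr):
        sfc = signed_fold_change(fc) if fc > 0 else -math.inf
        if q < cfg.fdr_max and fc > cfg.fc_min:
            call = CALL_UP
        elif q < cfg.fdr_max and fc < 1.0 / cfg.fc_min:
            call = CALL_DOWN
        else:
            call = CALL_NS
        results.append(DEResult(str(probe), float(w), float(fc), float(sfc), float(q), call))
    return results


def fdr_at_cutoff(m: ExpressionMatrix, d: SampleDesign, cutoff: float, cfg: DEConfig | None = None):
    """List-level FDR at an explicit statistic cutoff.

    Returns ``(n_called, fdr)`` for the gene list with ``|W - E0[W]| >=
    cutoff`` and fold change beyond the configured threshold.
    """
    cfg = cfg or DEConfig()
    _, obs_score, _, obs_pass, table, _ = _cutoff_table(m, d, cfg)
    cutoffs = table["cutoff"].to_numpy()
    idx = np.searchsorted(cutoffs, cutoff)
    if idx >= cutoffs.size:
        return 0, 0.0
    return int(table["observed_calls"].iloc[idx]), float(table["fdr"].iloc[idx])


def select_de_genes(results: list[DEResult], cfg: DEConfig | None = None):
    """Split results into (up, down) gene lists at the configured thresholds.

    Up-regulated: fdr < fdr_max and FC > fc_min; down-regulated: fdr <
    fdr_max and FC < 1/fc_min (both strict, so FC exactly 2.0 is excluded).
    Lists are sorted by |signed fold change| descending.
    """
    cfg = cfg or DEConfig()
    up = [r for r in results if r.fdr < cfg.fdr_max and r.fold_change > cfg.fc_min]
    down = [r for r in results if r.fdr < cfg.fdr_max and r.fold_change < 1.0 / cfg.fc_min]
    key = lambda r: abs(r.signed_fold_change)
    return sorted(up, key=key, reverse=True), sorted(down, key=key, reverse=True)


def results_table(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in results],
            "statistic": [r.statistic for r in results],
            "fold_change": [r.fold_change for r in results],
            "signed_fold_change": [r.signed_fold_change for r in results],
            "fdr": [r.fdr for r in results],
            "call": [r.call for r in results],
        }
    )


def write_results_table(results: list[DEResult], path, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        results_table(results).to_csv(fh, sep="\t", index=False, float_format="%.6g")
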