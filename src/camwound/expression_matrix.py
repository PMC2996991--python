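"""Expression-table I/O, global-scaling normalization and sample QC clustering.

The screen starts from a probe x sample matrix of linear-scale fluorescence
intensities (Affymetrix-style), with a matched wound/control design: every
egg contributes one wounded and one unwounded control CAM sample.  Probe-level
summarization and background correction happen upstream; this module only
rescales arrays to a common trimmed-mean target intensity (the classic
GCOS-style "TGT" global scaling) and provides a correlation-distance
hierarchical clustering of samples for quality control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import trim_mean


class ExpressionFormatError(ValueError):
    """Raised for malformed expression tables or design files."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Linear-scale probe x sample intensity matrix.

    Parameters
    ----------
    data
        DataFrame indexed by probe id with sample ids as columns.  All
        values must be finite and non-negative; probe and sample ids must
        be unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0:
            raise ExpressionFormatError("no probes in expression table")
        dup_probes = self.data.index[self.data.index.duplicated()]
        if len(dup_probes):
            raise ExpressionFormatError(f"duplicate probe id: {dup_probes[0]!r}")
        dup_samples = self.data.columns[self.data.columns.duplicated()]
        if len(dup_samples):
            raise ExpressionFormatError(f"duplicate sample id: {dup_samples[0]!r}")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ExpressionFormatError("expression values must be numeric")
        if not np.isfinite(vals).all():
            raise ExpressionFormatError("expression values must be finite")
        if (vals < 0).any():
            raise ExpressionFormatError("expression values must be non-negative")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SampleDesign:
    """Matched wound/control sample design.

    ``table`` has columns sample_id, group ("wound" or "control") and
    egg_id.  Every egg occurs exactly once per group, mirroring the paired
    design in which each wound has its own-egg control.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "egg_id"}
        missing = required - set(self.table.columns)
        if missing:
            raise ExpressionFormatError(f"design table missing columns: {sorted(missing)}")
        bad = set(self.table["group"]) - {"wound", "control"}
        if bad:
            raise ExpressionFormatError(f"unknown group label(s): {sorted(bad)}")
        dup = self.table["sample_id"][self.table["sample_id"].duplicated()]
        if len(dup):
            raise ExpressionFormatError(f"duplicate sample id in design: {dup.iloc[0]!r}")
        counts = self.table.groupby(["egg_id", "group"]).size()
        if (counts != 1).any():
            egg, group = counts[counts != 1].index[0]
            raise ExpressionFormatError(
                f"egg {egg!r} has {counts.loc[(egg, group)]} {group} samples (expected 1)"
            )
        eggs_per_group = self.table.groupby("group")["egg_id"].apply(set)
        if len(eggs_per_group) == 2 and eggs_per_group.iloc[0] != eggs_per_group.iloc[1]:
            raise ExpressionFormatError("wound and control groups cover different eggs")

    def samples(self, group: str) -> list[str]:
        sub = self.table[self.table["group"] == group]
        return list(sub["sample_id"])

    @property
    def wound_samples(self) -> list[str]:
        return self.samples("wound")

    @property
    def control_samples(self) -> list[str]:
        return self.samples("control")

    @property
    def egg_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["egg_id"]))

    @property
    def n_pairs(self) -> int:
        return len(self.egg_ids)

    def sample_for(self, egg_id, group: str) -> str:
        sub = self.table[(self.table["egg_id"] == egg_id) & (self.table["group"] == group)]
        if len(sub) != 1:
            raise ExpressionFormatError(f"no unique {group} sample for egg {egg_id!r}")
        return sub["sample_id"].iloc[0]


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative clustering result.

    ``merges`` is a sequence of ``(node_a, node_b, height)`` triples using the
    usual numbering: leaves are ``0 .. n-1`` and the k-th merge creates node
    ``n + k``.  ``leaf_order`` is the left-to-right leaf ordering of the tree,
    ``labels`` the sample ids of the leaves.
    """

    merges: tuple[tuple[int, int, float], ...]
    leaf_order: tuple[int, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges for {n} leaves, got {len(self.merges)}")
        heights = [h for _, _, h in self.merges]
        for lo, hi in zip(heights, heights[1:]):
            if hi < lo - 1e-12:
                raise ValueError("merge heights must be non-decreasing")
        if sorted(self.leaf_order) != list(range(n)):
            raise ValueError("leaf_order must be a permutation of the leaves")

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def linkage_matrix(self) -> np.ndarray:
        """SciPy-style ``Z`` matrix (columns: node, node, height, cluster size)."""
        n = len(self.labels)
        sizes = {i: 1 for i in range(n)}
        rows = []
        for k, (a, b, h) in enumerate(self.merges):
            size = sizes[a] + sizes[b]
            sizes[n + k] = size
            rows.append([float(a), float(b), float(h), float(size)])
        return np.asarray(rows, dtype=float)

    def cut(self, n_clusters: int) -> list[set[int]]:
        """Leaf partition obtained by undoing the last ``n_clusters - 1`` merges."""
        n = len(self.labels)
        members: dict[int, set[int]] = {i: {i} for i in range(n)}
        active = set(range(n))
        for k, (a, b, _) in enumerate(self.merges):
            if len(active) <= n_clusters:
                break
            members[n + k] = members.pop(a) | members.pop(b)
            active -= {a, b}
            active.add(n + k)
        return [members[i] for i in sorted(active)]


def read_expression_table(path) -> ExpressionMatrix:
    """Read a TSV expression table (header = sample ids, first column = probe ids).

    Lines starting with ``#`` are treated as metadata and skipped.  Raises
    :class:`ExpressionFormatError` naming the offending cell for non-numeric
    values and the offending id for duplicates.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ExpressionFormatError("no probes in expression table")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        bad = numeric.isna()
        row = bad.any(axis=1).idxmax()
        col = bad.loc[row].idxmax()
        raise ExpressionFormatError(
            f"non-numeric value {raw.loc[row, col]!r} at probe {row!r}, sample {col!r}"
        )
    return ExpressionMatrix(numeric.astype(float))


def write_expression_table(m: ExpressionMatrix, path, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        m.data.to_csv(fh, sep="\t", index_label="probe_id")


def read_design_table(path) -> SampleDesign:
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return SampleDesign(table)


def write_design_table(d: SampleDesign, path) -> None:
    d.table.to_csv(path, sep="\t", index=False)


def trimmed_mean(x, trim_fraction: float = 0.02) -> float:
    """Mean after discarding the top and bottom ``trim_fraction`` of values."""
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    return float(trim_mean(np.asarray(x, dtype=float), trim_fraction))


def normalize_global_scaling(
    m: ExpressionMatrix, target: float = 100.0, trim_fraction: float = 0.02
) -> ExpressionMatrix:
    """Scale every array so its trimmed mean equals ``target``.

    This is the GCOS-style global scaling with trimmed-mean target intensity
    (TGT), conventionally 100.  The trimmed mean discards the most extreme
    ``trim_fraction`` of probes at each tail before averaging, so saturated
    probes do not dominate the scale factor.
    """
    if target <= 0:
        raise ValueError("target intensity must be positive")
    scaled = {}
    for sample in m.sample_ids:
        col = m.data[sample].to_numpy(dtype=float)
        tm = trimmed_mean(col, trim_fraction)
        if tm <= 0:
            raise ExpressionFormatError(f"sample {sample!r} has non-positive trimmed mean")
        scaled[sample] = col * (target / tm)
    return ExpressionMatrix(pd.DataFrame(scaled, index=m.data.index))


def cluster_samples(m: ExpressionMatrix) -> Dendrogram:
    """Cluster samples by average linkage on correlation distance (1 - Pearson r).

    Agglomeration is deterministic: at every step the pair of clusters with
    the smallest average inter-cluster distance merges, ties broken by the
    lowest pair index.  Average linkage here means the mean of all pairwise
    leaf distances between the two clusters (UPGMA), so heights lie in
    ``[0, 2]`` and never decrease along the merge sequence.
    """
    X = m.values.T  # samples x probes
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = m.sample_ids[int(np.argmax(sd == 0))]
        raise ValueError(f"sample {bad!r} has zero variance; correlation distance undefined")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)

    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    active: list[int] = list(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best: tuple[float, int, int] | None = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                d = float(dist[np.ix_(members[a], members[b])].mean())
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best  # type: ignore[misc]
        merges.append((a, b, d))
        members[next_id] = members[a] + members[b]
        del members[a], members[b]
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    leaf_order = tuple(members[next_id - 1])
    return Dendrogram(tuple(merges), leaf_order, tuple(m.sample_ids))
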