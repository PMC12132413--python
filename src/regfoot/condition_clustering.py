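"""Which environments does a promoter perceive as similar?

Footprints for one promoter across conditions (or for all promoters jointly)
are compared by Pearson correlation and grouped by average-linkage
hierarchical clustering on the correlation distance 1 - r.  The same
correlations drive replicate quality control: within-condition replicate
pairs that barely correlate are flagged, the convention used to decide when
an experiment needs a third replicate or exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform

from .footprint_stats import Footprint


@dataclass
class ConditionMatrix:
    """Rows: condition x replicate; columns: concatenated promoter positions."""

    values: np.ndarray                      # (n_rows, n_promoters * L)
    row_labels: list[tuple[str, int | str]]  # (condition, replicate)
    promoter_ids: list[str]
    mask: np.ndarray = field(default=None)  # True where the cell was observed

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.row_labels):
            raise ValueError("row labels must match the matrix")
        if self.mask is None:
            self.mask = np.ones_like(self.values, dtype=bool)


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: np.ndarray
    cophenetic: np.ndarray
    row_labels: list
    reason: str | None = None

    @property
    def n_clusters(self) -> int:
        return int(len(np.unique(self.labels))) if self.labels.size else 0


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def replicate_correlation(footprints: dict[tuple[str, int | str], Footprint],
                          floor: float = 0.3
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation across footprints plus replicate exclusion flags.

    Returns the full experiment x experiment correlation matrix and a flag
    table: when a condition's replicates correlate below ``floor``, the
    replicate that correlates worse with the ensemble of all experiments is
    flagged for exclusion (or a third replicate).  Constant footprints are
    flagged as degenerate.
    """
    keys = list(footprints)
    vecs = np.stack([footprints[k].mi for k in keys])
    n = len(keys)
    corr = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            corr[i, j] = corr[j, i] = _pearson(vecs[i], vecs[j])
    corr_df = pd.DataFrame(corr, index=pd.MultiIndex.from_tuples(keys),
                           columns=pd.MultiIndex.from_tuples(keys))

    flags = []
    by_condition: dict[str, list[int]] = {}
    for i, (cond, _rep) in enumerate(keys):
        by_condition.setdefault(cond, []).append(i)
    for cond, idx in by_condition.items():
        for i in idx:
            if vecs[i].std() == 0:
                flags.append((cond, keys[i][1], "degenerate", np.nan))
        partners = [i for i in idx if vecs[i].std() > 0]
        if len(partners) < 2:
            continue
        r_within = np.nanmin([corr[i, j] for i in partners for j in partners
                              if i < j])
        if r_within >= floor:
            continue
        ensemble = {i: np.nanmean([corr[i, j] for j in range(n) if j != i])
                    for i in partners}
        worst = min(ensemble, key=ensemble.get)
        flags.append((cond, keys[worst][1], "poor_correlation", float(r_within)))
    flag_df = pd.DataFrame(flags, columns=["condition", "replicate", "reason",
                                           "r_within"])
    return corr_df, flag_df


def _cluster_rows(vecs: np.ndarray, row_labels: list,
                  cut: float | None = None) -> ClusterResult:
    """Average-linkage clustering on correlation distance (1 - Pearson r).

    Flat clusters are taken at distance ``cut``; by default at 0.7 times the
    deepest merge, a relative criterion that separates distinct regulatory
    programs even when they share the polymerase-site signal (absolute
    correlation floors do not).  Deterministic given the matrix; ties are
    broken by row order through scipy's stable condensed-distance ordering.
    """
    corr = np.corrcoef(vecs)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    condensed = squareform(dist, checks=False)
    Z = average(condensed)
    t = max(0.7 * Z[:, 2].max(), 1e-8) if cut is None else cut
    labels = fcluster(Z, t=t, criterion="distance")
    coph = cophenet(Z)
    return ClusterResult(linkage=Z, labels=labels, cophenetic=coph,
                         row_labels=list(row_labels))


def cluster_promoter_conditions(footprints: dict[str, Footprint],
                                eligible: set[str] | None = None,
                                cut: float | None = None) -> ClusterResult:
    """Cluster one promoter's footprints across conditions.

    Only conditions classified active_with_sites should enter (pass them as
    ``eligible``); with fewer than two eligible conditions an empty result
    with a reason is returned.
    """
    conditions = [c for c in footprints if eligible is None or c in eligible]
    if len(conditions) < 2:
        return ClusterResult(linkage=np.empty((0, 4)), labels=np.array([]),
                             cophenetic=np.array([]), row_labels=conditions,
                             reason="fewer than 2 eligible conditions")
    vecs = np.stack([footprints[c].mi for c in conditions])
    return _cluster_rows(vecs, conditions, cut)


def build_condition_matrix(
        footprints: dict[tuple[str, int | str], dict[str, Footprint]],
        promoter_ids: list[str] | None = None,
        length: int = 160) -> ConditionMatrix:
    """Assemble the global condition x position MI matrix.

    ``footprints`` maps (condition, replicate) -> {promoter_id -> Footprint}.
    Missing promoter x condition blocks are filled with zeros -- a promoter
    silent in a condition carries signal, not missingness -- and recorded in
    the mask so a masking analysis remains possible.
    """
    rows = list(footprints)
    if promoter_ids is None:
        promoter_ids = sorted({p for d in footprints.values() for p in d})
    values = np.zeros((len(rows), len(promoter_ids) * length))
    mask = np.zeros_like(values, dtype=bool)
    for i, key in enumerate(rows):
        for j, pid in enumerate(promoter_ids):
            fp = footprints[key].get(pid)
            if fp is not None:
                values[i, j * length:(j + 1) * length] = fp.mi
                mask[i, j * length:(j + 1) * length] = True
    return ConditionMatrix(values=values, row_labels=rows,
                           promoter_ids=list(promoter_ids), mask=mask)


def cluster_global(matrix: ConditionMatrix,
                   cut: float | None = None) -> ClusterResult:
    """Cluster all condition x replicate rows of the global MI matrix."""
    if matrix.values.size == 0:
        raise ValueError("empty condition matrix")
    return _cluster_rows(matrix.values, matrix.row_labels, cut)


def nearest_neighbors(matrix: ConditionMatrix) -> pd.DataFrame:
    """Each row's nearest neighbor by correlation distance (replicate QC)."""
    corr = np.nan_to_num(np.corrcoef(matrix.values), nan=-1.0)
    np.fill_diagonal(corr, -np.inf)
    nn = corr.argmax(axis=1)
    return pd.DataFrame({
        "row": matrix.row_labels,
        "nearest": [matrix.row_labels[i] for i in nn],
        "r": corr[np.arange(len(nn)), nn],
    })
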