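"""Functional and structural network construction and activity summaries.

Functional connectivity is the matrix of pairwise Pearson correlations
between regional timeseries; structural matrices are normalized so the
total edge weight is one.  System-level summaries average raw edge
values over region pairs (no Fisher transform; the source estimates are
averaged directly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import RegionalTimeseries
from .io import Parcellation, SYSTEMS

__all__ = [
    "FunctionalNetwork",
    "compute_functional_network",
    "average_system_network",
    "subnetwork_system_coupling",
    "subnetwork_rms",
    "normalize_structural",
    "threshold_structural",
    "mean_structural_coupling",
]


@dataclass
class FunctionalNetwork:
    """N x N Pearson correlation matrix; diagonal excluded from analysis."""

    matrix: np.ndarray
    subject_id: int | None = None
    run_id: int | None = None


def compute_functional_network(ts: RegionalTimeseries) -> FunctionalNetwork:
    """Pairwise Pearson correlations between regional timeseries."""
    data = ts.data
    if data.shape[1] < 3:
        raise ValueError("need at least 3 timepoints for correlations")
    sd = data.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(
            f"constant timeseries for region index(es) {constant.tolist()}"
        )
    mat = np.corrcoef(data)
    return FunctionalNetwork(mat, ts.subject_id, ts.run_id)


def _group_indices(
    parc: Parcellation, level: str
) -> tuple[list[str], list[np.ndarray]]:
    if level == "systems":
        names = [s for s in SYSTEMS if (parc.systems == s).any()]
        return names, [parc.indices_of_system(s) for s in names]
    if level == "subnetworks":
        names, idx = [], []
        for lab in ("A", "B"):
            members = parc.indices_of_subnetwork(lab)
            if members.size:
                names.append(lab)
                idx.append(members)
        for s in SYSTEMS:
            if s == "frontoparietal":
                continue
            members = parc.indices_of_system(s)
            if members.size:
                names.append(s)
                idx.append(members)
        return names, idx
    raise ValueError(f"unknown level {level!r}")


def _pair_mean(matrix: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> float:
    """Mean over cross pairs; for identical groups, distinct pairs only."""
    if rows.size == cols.size and np.array_equal(rows, cols):
        if rows.size < 2:
            raise ValueError("within-group mean needs >= 2 regions")
        block = matrix[np.ix_(rows, rows)]
        n = rows.size
        return float((block.sum() - np.trace(block)) / (n * (n - 1)))
    if np.intersect1d(rows, cols).size:
        raise ValueError("overlapping groups")
    return float(matrix[np.ix_(rows, cols)].mean())


def average_system_network(
    matrix: np.ndarray | FunctionalNetwork,
    parc: Parcellation,
    level: str = "systems",
) -> tuple[np.ndarray, list[str]]:
    """S x S matrix of mean within/between-group edge values.

    The (s, s) entry averages only distinct-region pairs inside group s.
    Returns the matrix and the group-name order.
    """
    if isinstance(matrix, FunctionalNetwork):
        matrix = matrix.matrix
    names, groups = _group_indices(parc, level)
    for name, idx in zip(names, groups):
        if idx.size == 0:
            raise ValueError(f"empty group {name!r}")
    s = len(names)
    out = np.zeros((s, s))
    for i in range(s):
        for j in range(i, s):
            if i == j and groups[i].size < 2:
                out[i, j] = np.nan
                continue
            out[i, j] = out[j, i] = _pair_mean(matrix, groups[i], groups[j])
    return out, names


def subnetwork_system_coupling(
    net: np.ndarray | FunctionalNetwork,
    parc: Parcellation,
    subnet: str,
    system: str,
) -> float:
    """Mean edge value over (subnetwork region, system region) pairs."""
    matrix = net.matrix if isinstance(net, FunctionalNetwork) else net
    rows = parc.indices_of_subnetwork(subnet)
    cols = parc.indices_of_system(system)
    if rows.size == 0 or cols.size == 0:
        raise ValueError("empty subnetwork or system")
    if np.intersect1d(rows, cols).size:
        raise ValueError("subnetwork and system overlap")
    return float(matrix[np.ix_(rows, cols)].mean())


def subnetwork_rms(
    ts: RegionalTimeseries | np.ndarray, parc: Parcellation, subnet: str
) -> float:
    """RMS of the across-region mean timeseries of the subnetwork."""
    data = ts.data if isinstance(ts, RegionalTimeseries) else np.asarray(ts)
    idx = parc.indices_of_subnetwork(subnet)
    if idx.size == 0:
        raise ValueError(f"empty subnetwork {subnet!r}")
    mean_series = data[idx].mean(axis=0)
    return float(np.sqrt(np.mean(mean_series**2)))


# ---------------------------------------------------------------------------
# Structural matrices
# ---------------------------------------------------------------------------


def normalize_structural(c_s: np.ndarray) -> np.ndarray:
    """Divide by the total weight of all connections (idempotent)."""
    c_s = np.asarray(c_s, dtype=float)
    if (c_s < 0).any():
        raise ValueError("structural weights must be nonnegative")
    total = c_s.sum()
    if total == 0:
        raise ValueError("all-zero structural matrix")
    return c_s / total


def threshold_structural(c_s: np.ndarray, drop_fraction: float) -> np.ndarray:
    """Zero the weakest ``drop_fraction`` of nonzero edges, re-normalize.

    Equal weights at the cut are dropped in ascending (row, column)
    order of the upper triangle for determinism.
    """
    if not 0.0 <= drop_fraction < 1.0:
        raise ValueError("drop_fraction must be in [0, 1)")
    c_s = np.asarray(c_s, dtype=float)
    if (c_s < 0).any():
        raise ValueError("structural weights must be nonnegative")
    out = c_s.copy()
    iu = np.triu_indices(c_s.shape[0], k=1)
    weights = c_s[iu]
    nz = np.flatnonzero(weights > 0)
    if nz.size == 0:
        raise ValueError("all-zero structural matrix")
    n_drop = int(np.floor(drop_fraction * nz.size))
    if n_drop:
        # stable sort: ties cut in ascending (row, col) order
        order = np.argsort(weights[nz], kind="stable")
        drop = nz[order[:n_drop]]
        out[iu[0][drop], iu[1][drop]] = 0.0
        out[iu[1][drop], iu[0][drop]] = 0.0
    return normalize_structural(out)


def mean_structural_coupling(
    matrices: list[np.ndarray],
    groups: list[np.ndarray],
) -> np.ndarray:
    """Across-subject mean of group-averaged structural weight.

    ``groups`` is an ordered list of 0-based region-index arrays; the
    result is symmetric with a zero diagonal (self-coupling is not
    meaningful for difference coupling).
    """
    if not matrices:
        raise ValueError("need at least one subject matrix")
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            if np.intersect1d(g1, g2).size:
                raise ValueError("groups overlap")
    k = len(groups)
    acc = np.zeros((k, k))
    for mat in matrices:
        for i in range(k):
            for j in range(i + 1, k):
                acc[i, j] += _pair_mean(mat, groups[i], groups[j])
    acc = (acc + acc.T) / len(matrices)
    return acc
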