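"""Probe aggregation, parcel-parcel coexpression, and the bootstrap test
of within- vs between-subnetwork coexpression.

The test statistic per bootstrap resample of genes is the ratio of mean
within-subnetwork to mean between-subnetwork coexpression minus the
mean of that ratio under random permutation of subnetwork membership
(permutation restricted to the labeled parcels).  The reported p-value
is the fraction of bootstrap indices below zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneExpressionMatrix",
    "CoexpressionResult",
    "aggregate_probes",
    "coexpression_matrix",
    "coexpression_bootstrap_test",
]


@dataclass
class GeneExpressionMatrix:
    """Parcels x genes matrix of mean probe-centered expression."""

    values: np.ndarray
    parcel_ids: np.ndarray
    gene_ids: np.ndarray


def aggregate_probes(probe_table: pd.DataFrame) -> GeneExpressionMatrix:
    """Center each probe by its across-parcel mean, then average per gene.

    Expects columns ``parcel``, ``gene``, ``probe``, ``value``.  Cells
    with no probe coverage are flagged missing; parcels with any missing
    cell are dropped (logged via the returned ids).
    """
    required = {"parcel", "gene", "probe", "value"}
    if not required.issubset(probe_table.columns):
        raise ValueError(f"probe table must have columns {sorted(required)}")
    df = probe_table.copy()
    df["value"] = df["value"] - df.groupby(["gene", "probe"])["value"].transform("mean")
    cell = df.groupby(["parcel", "gene"], sort=True)["value"].mean()
    wide = cell.unstack("gene")
    complete = wide.dropna(axis=0)
    return GeneExpressionMatrix(
        values=complete.to_numpy(dtype=float),
        parcel_ids=complete.index.to_numpy(),
        gene_ids=complete.columns.to_numpy(),
    )


def coexpression_matrix(expr: GeneExpressionMatrix | np.ndarray) -> np.ndarray:
    """Parcel x parcel Pearson correlation of gene-expression profiles."""
    values = expr.values if isinstance(expr, GeneExpressionMatrix) else np.asarray(expr)
    if values.shape[1] < 3:
        raise ValueError("need at least 3 genes")
    if (values.std(axis=1) == 0).any():
        raise ValueError("constant parcel profile")
    return np.corrcoef(values)


def _ratio(coexpr: np.ndarray, mask_in: np.ndarray, mask_out: np.ndarray) -> float:
    """Mean within-group coexpression over mean between-group coexpression."""
    within = coexpr[np.ix_(mask_in, mask_in)]
    n_in = mask_in.sum()
    w = (within.sum() - np.trace(within)) / (n_in * (n_in - 1))
    b = coexpr[np.ix_(mask_in, mask_out)].mean()
    return float(w / b)


@dataclass
class CoexpressionResult:
    within: float
    between: float
    ratio: float
    null_ratio: float
    indices: np.ndarray
    p_value: float


def coexpression_bootstrap_test(
    expr: GeneExpressionMatrix | np.ndarray,
    subnet_labels: np.ndarray,
    n_boot: int = 1000,
    n_perm: int = 200,
    seed: int | np.random.Generator | None = None,
    subnetwork: str = "A",
    with_replacement: bool = True,
) -> CoexpressionResult:
    """Bootstrap-over-genes test of within- vs between-subnetwork coexpression.

    ``subnet_labels`` holds "A"/"B" per parcel row of ``expr`` (other
    values mark unlabeled parcels, which are excluded).  Per bootstrap
    resample of genes the within(``subnetwork``)/between ratio is
    compared with its mean over ``n_perm`` permutations of the
    subnetwork membership; p is the fraction of bootstrap indices < 0.
    """
    if n_boot < 1 or n_perm < 1:
        raise ValueError("n_boot and n_perm must be >= 1")
    values = expr.values if isinstance(expr, GeneExpressionMatrix) else np.asarray(expr)
    labels = np.asarray(subnet_labels)
    keep = np.isin(labels, ("A", "B"))
    values = values[keep]
    labels = labels[keep]
    n_a = (labels == "A").sum()
    n_b = (labels == "B").sum()
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 parcels in each subnetwork")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_parcels, n_genes = values.shape
    mask_in = labels == ("A" if subnetwork == "A" else "B")
    if subnetwork not in ("A", "B"):
        raise ValueError("subnetwork must be 'A' or 'B'")
    mask_out = ~mask_in

    # fixed permutation set reused across bootstraps for comparability
    perms = np.stack([rng.permutation(n_parcels) for _ in range(n_perm)])
    indices = np.empty(n_boot)
    obs_within = obs_between = obs_ratio = null_ratio_acc = 0.0
    for b in range(n_boot):
        if with_replacement:
            sample = rng.integers(0, n_genes, size=n_genes)
        else:
            sample = rng.permutation(n_genes)
        coexpr = np.corrcoef(values[:, sample])
        ratio = _ratio(coexpr, mask_in, mask_out)
        null_ratios = np.empty(n_perm)
        for p in range(n_perm):
            pm_in = np.zeros(n_parcels, dtype=bool)
            pm_in[perms[p][: mask_in.sum()]] = True
            null_ratios[p] = _ratio(coexpr, pm_in, ~pm_in)
        indices[b] = ratio - null_ratios.mean()
        if b == 0:
            within_block = coexpr[np.ix_(mask_in, mask_in)]
            n_in = mask_in.sum()
            obs_within = float(
                (within_block.sum() - np.trace(within_block)) / (n_in * (n_in - 1))
            )
            obs_between = float(coexpr[np.ix_(mask_in, mask_out)].mean())
            obs_ratio = ratio
            null_ratio_acc = float(null_ratios.mean())
    p_value = float((indices < 0).mean())
    return CoexpressionResult(
        within=obs_within,
        between=obs_between,
        ratio=obs_ratio,
        null_ratio=null_ratio_acc,
        indices=indices,
        p_value=p_value,
    )
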