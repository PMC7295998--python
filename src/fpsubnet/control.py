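"""Regional boundary control over two target systems, with enrichment test.

For region i with total strength k_i and strengths k_i(J), k_i(L) to the
two target systems,

    BC(i) = 1 - (k_i(J)/k_i)^2 - (k_i(L)/k_i)^2   if k_i(J)+k_i(L) = k_i
    BC(i) = (k_i(J)/k_i)^2 + (k_i(L)/k_i)^2       otherwise (sum < k_i)

The equality branch is evaluated with relative tolerance 1e-9; exact
equality almost never holds for real-valued strengths, and the
discontinuity between branches is inherited from the definition.  BC
depends on strength ratios only, so it is invariant to global rescaling
of the structural matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import Parcellation

__all__ = [
    "BoundaryControlMap",
    "boundary_control",
    "top_percentile_regions",
    "enrichment_test",
]


@dataclass
class BoundaryControlMap:
    bc: np.ndarray  # per-region value in [0, 1]
    k_total: np.ndarray
    k_j: np.ndarray
    k_l: np.ndarray
    system_j: str
    system_l: str


def boundary_control(
    c_s: np.ndarray,
    parc: Parcellation,
    system_j: str,
    system_l: str,
    rtol: float = 1e-9,
) -> BoundaryControlMap:
    """Per-region boundary control with respect to two systems.

    Strengths to each system sum region i's weights to all regions of
    that system; a region's own intra-system connections count toward
    k_i but a region never contributes to its own k_i(J)/k_i(L) target
    sums (the diagonal is zero).
    """
    c_s = np.asarray(c_s, dtype=float)
    idx_j = parc.indices_of_system(system_j)
    idx_l = parc.indices_of_system(system_l)
    if np.intersect1d(idx_j, idx_l).size:
        raise ValueError("target systems overlap")
    k_total = c_s.sum(axis=1)
    isolated = np.flatnonzero(k_total == 0)
    if isolated.size:
        raise ValueError(f"isolated region(s) with zero strength: {isolated.tolist()}")
    # contiguous copies keep the summation order identical to a
    # per-row brute-force evaluation (bit-exact oracle equivalence)
    k_j = np.ascontiguousarray(c_s[:, idx_j]).sum(axis=1)
    k_l = np.ascontiguousarray(c_s[:, idx_l]).sum(axis=1)
    fj = (k_j / k_total) ** 2
    fl = (k_l / k_total) ** 2
    equal = np.isclose(k_j + k_l, k_total, rtol=rtol, atol=0.0)
    bc = np.where(equal, 1.0 - fj - fl, fj + fl)
    return BoundaryControlMap(bc, k_total, k_j, k_l, system_j, system_l)


def top_percentile_regions(bc: BoundaryControlMap | np.ndarray, pct: float = 95.0) -> np.ndarray:
    """0-based indices of regions above the given percentile of BC.

    Exactly ceil(N * (1 - pct/100)) regions are returned; ties are
    broken deterministically by lower region index first.
    """
    values = bc.bc if isinstance(bc, BoundaryControlMap) else np.asarray(bc)
    if not 0.0 < pct < 100.0:
        raise ValueError("pct must be in (0, 100)")
    n = len(values)
    # guard against float artifacts like 400 * (1 - 0.95) = 20.000000000000004
    n_top = int(np.ceil(n * (100.0 - pct) / 100.0 - 1e-9))
    # stable sort on (-value, index): ties resolved by lower index
    order = np.lexsort((np.arange(n), -values))
    return np.sort(order[:n_top])


def enrichment_test(
    region_set: np.ndarray,
    target_system: str,
    parc: Parcellation,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Is the region set over-represented in the target system?

    Returns the observed member count, a permutation p (exchangeable
    region-label null) and the exact hypergeometric tail probability
    P(X >= observed), which serves as the closed-form oracle for the
    permutation estimate.
    """
    region_set = np.asarray(region_set, dtype=int)
    n = parc.n_regions
    if region_set.min(initial=0) < 0 or region_set.max(initial=0) >= n:
        raise ValueError("region_set contains indices outside the parcellation")
    target = parc.indices_of_system(target_system)
    if target.size == 0:
        raise ValueError(f"empty target system {target_system!r}")
    if n_perm < 100:
        warnings.warn("n_perm < 100: permutation p will be coarse")
    in_target = np.zeros(n, dtype=bool)
    in_target[target] = True
    observed = int(in_target[region_set].sum())
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_set = len(region_set)
    counts = np.empty(n_perm, dtype=int)
    for p in range(n_perm):
        counts[p] = in_target[rng.choice(n, size=n_set, replace=False)].sum()
    p_perm = float((1 + (counts >= observed).sum()) / (n_perm + 1))
    p_exact = float(stats.hypergeom.sf(observed - 1, n, target.size, n_set))
    return {
        "observed": observed,
        "p_perm": p_perm,
        "p_exact": p_exact,
        "n_set": n_set,
        "target_size": int(target.size),
        "n_regions": n,
    }
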