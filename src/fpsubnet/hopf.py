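"""Coupled noisy Stuart-Landau (Hopf normal form) oscillator networks.

Each unit obeys  du/dt = u [a + i*omega - |u|^2] + xi*eta(t), split into
real and imaginary parts with diffusive coupling through a symmetric
nonnegative matrix D:

    dx_j = [(a_j - x_j^2 - y_j^2) x_j - omega_j y_j
            + G sum_i D_ij (x_i - x_j)] dt + xi sqrt(dt) N(0,1)
    dy_j = [(a_j - x_j^2 - y_j^2) y_j + omega_j x_j
            + G sum_i D_ij (y_i - y_j)] dt + xi sqrt(dt) N(0,1)

integrated with Euler-Maruyama; noise draws are independent between the
x and y updates.  x is the oscillatory signal of interest.  For a_j > 0
the noise-free unit settles on a limit cycle of radius sqrt(a_j); for
a_j < 0 it decays to a low-activity fixed point.

Synchrony is the Kuramoto order parameter R(t) = |sum_j e^{i phi_j}|/n,
with instantaneous phases from the Hilbert transform of the unfiltered
post-transient signal.

Multi-run experiments (amplitude manipulation, coupling ablation,
anticorrelation census) integrate all runs as one batch and accumulate
only the second moments of the group-mean signals, so hundreds of runs
fit in constant memory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "HopfConfig",
    "Trajectory",
    "sample_frequencies",
    "simulate_hopf",
    "kuramoto_order",
    "parameter_sweep",
    "amplitude_experiment",
    "build_grouped_config",
    "default_group_coupling",
    "preset_config",
    "ablate_coupling",
    "anticorrelation_census",
]

GROUPS_OF_INTEREST = ("SN-A", "SN-B", "DM", "DA")

#: Synthetic group-level coupling motif (order SN-A, SN-B, DM, DA):
#: strong SN-A<->DM and SN-B<->DA anchors with weak everything else.
#: The empirical group coupling matrix is not available; this motif
#: keeps the qualitative structural contrast (A anchored to DM, B to
#: DA) with enough separation that raising one subnetwork's amplitude
#: tilts the frontoparietal composite toward its anchor system.
_MOTIF = np.array(
    [
        [0.0, 0.1, 2.0, 0.2],
        [0.1, 0.0, 0.2, 1.5],
        [2.0, 0.2, 0.0, 0.1],
        [0.2, 1.5, 0.1, 0.0],
    ]
)


def default_group_coupling(scale: float = 1.0) -> np.ndarray:
    return _MOTIF * scale


@dataclass
class HopfConfig:
    """Oscillator network parameters."""

    n_o: int
    a: np.ndarray
    omega: np.ndarray  # rad/s
    d: np.ndarray
    coupling: float = 0.1
    xi: float = 0.02
    dt: float = 0.01
    duration: float = 360.0
    transient_discard: float = 20.0
    seed: int = 0
    groups: dict[str, np.ndarray] | None = None
    freq_mean_hz: float = 0.04
    freq_sd_hz: float = 0.01

    def __post_init__(self) -> None:
        a = np.broadcast_to(np.asarray(self.a, dtype=float), (self.n_o,)).copy()
        omega = np.broadcast_to(np.asarray(self.omega, dtype=float), (self.n_o,)).copy()
        d = np.asarray(self.d, dtype=float)
        if d.shape != (self.n_o, self.n_o):
            raise ValueError("coupling matrix shape mismatch")
        if not np.allclose(d, d.T):
            raise ValueError("coupling matrix must be symmetric")
        if (d < 0).any():
            raise ValueError("coupling matrix must be nonnegative")
        if np.diag(d).any():
            raise ValueError("coupling matrix must have zero diagonal")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < self.transient_discard:
            raise ValueError("duration must cover the transient discard")
        if (omega <= 0).any():
            raise ValueError("angular frequencies must be positive")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "d", d)


@dataclass
class Trajectory:
    """Simulated signals; the first ``discard`` samples are transient."""

    x: np.ndarray  # n_o x T
    y: np.ndarray
    time: np.ndarray
    discard: int
    config: HopfConfig = field(repr=False)

    @property
    def x_post(self) -> np.ndarray:
        return self.x[:, self.discard:]

    @property
    def y_post(self) -> np.ndarray:
        return self.y[:, self.discard:]

    def rms(self) -> np.ndarray:
        """Per-oscillator RMS of the post-transient signal."""
        return np.sqrt(np.mean(self.x_post**2, axis=1))


def sample_frequencies(
    mean_hz: float,
    sd_hz: float,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Angular frequencies (rad/s) from a normal truncated to > 0 Hz."""
    if mean_hz <= 0:
        raise ValueError("mean frequency must be positive")
    if sd_hz < 0:
        raise ValueError("frequency sd must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = rng.normal(mean_hz, sd_hz, size=n)
    while (bad := freqs <= 0).any():
        freqs[bad] = rng.normal(mean_hz, sd_hz, size=int(bad.sum()))
    return 2.0 * np.pi * freqs


def _step(x, y, a, omega, gd, deg, g, xi_sqdt, dt, rng):
    """One Euler-Maruyama step for batched state arrays (B, n)."""
    r2 = x * x + y * y
    cx = g * (x @ gd - x * deg)
    cy = g * (y @ gd - y * deg)
    nx = x + dt * ((a - r2) * x - omega * y + cx)
    ny = y + dt * ((a - r2) * y + omega * x + cy)
    if xi_sqdt:
        nx += xi_sqdt * rng.standard_normal(x.shape)
        ny += xi_sqdt * rng.standard_normal(y.shape)
    return nx, ny


def simulate_hopf(config: HopfConfig) -> Trajectory:
    """Integrate a single network realization, returning full trajectories."""
    rng = np.random.default_rng(config.seed)
    n_steps = int(round(config.duration / config.dt))
    n = config.n_o
    x = np.empty((n, n_steps))
    y = np.empty((n, n_steps))
    cx = 0.1 * rng.standard_normal((1, n))
    cy = 0.1 * rng.standard_normal((1, n))
    a = config.a[None, :]
    omega = config.omega[None, :]
    deg = config.d.sum(axis=1)
    xi_sqdt = config.xi * np.sqrt(config.dt)
    for t in range(n_steps):
        cx, cy = _step(
            cx, cy, a, omega, config.d, deg, config.coupling, xi_sqdt, config.dt, rng
        )
        if t % 100 == 0:
            peak = (cx * cx + cy * cy).max()
            if not np.isfinite(peak) or peak > 1e6:
                raise RuntimeError(
                    "numerical blow-up (|u| > 1e3); try a smaller dt"
                )
        x[:, t] = cx[0]
        y[:, t] = cy[0]
    time = np.arange(n_steps) * config.dt
    discard = int(round(config.transient_discard / config.dt))
    return Trajectory(x, y, time, discard, config)


def kuramoto_order(traj: Trajectory | np.ndarray) -> tuple[np.ndarray, float]:
    """Instantaneous Kuramoto order parameter R(t) and its time mean.

    Phases come from the Hilbert transform of the (post-transient,
    unfiltered) signals.
    """
    x = traj.x_post if isinstance(traj, Trajectory) else np.asarray(traj)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 oscillators")
    if (x.std(axis=1) == 0).any():
        raise ValueError("constant signal: phase undefined")
    phases = np.angle(signal.hilbert(x, axis=1))
    r_t = np.abs(np.exp(1j * phases).mean(axis=0))
    return r_t, float(r_t.mean())


# ---------------------------------------------------------------------------
# Batched experiments
# ---------------------------------------------------------------------------


def _batch_group_moments(
    config: HopfConfig,
    a_batch: np.ndarray,
    omega_batch: np.ndarray,
    rng: np.random.Generator,
    projector: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a batch of runs, accumulating group-signal moments.

    ``projector`` is (n_groups, n_o) mapping oscillators to group-mean
    signals.  Returns per-run covariance matrices (B, n_groups,
    n_groups) and per-run group-signal mean squares (B, n_groups) over
    the post-transient samples.
    """
    n_steps = int(round(config.duration / config.dt))
    discard = int(round(config.transient_discard / config.dt))
    b, n = a_batch.shape
    x = 0.1 * rng.standard_normal((b, n))
    y = 0.1 * rng.standard_normal((b, n))
    deg = config.d.sum(axis=1)
    xi_sqdt = config.xi * np.sqrt(config.dt)
    ng = projector.shape[0]
    s1 = np.zeros((b, ng))
    s2 = np.zeros((b, ng, ng))
    count = 0
    pt = projector.T
    for t in range(n_steps):
        x, y = _step(
            x, y, a_batch, omega_batch, config.d, deg, config.coupling,
            xi_sqdt, config.dt, rng,
        )
        if t % 500 == 0:
            peak = (x * x + y * y).max()
            if not np.isfinite(peak) or peak > 1e6:
                raise RuntimeError(
                    "numerical blow-up (|u| > 1e3); try a smaller dt"
                )
        if t >= discard:
            g = x @ pt
            s1 += g
            s2 += g[:, :, None] * g[:, None, :]
            count += 1
    mean = s1 / count
    cov = s2 / count - mean[:, :, None] * mean[:, None, :]
    mean_sq = np.einsum("bii->bi", s2) / count
    return cov, mean_sq


def _group_projector(config: HopfConfig, names: Sequence[str]) -> np.ndarray:
    if config.groups is None:
        raise ValueError("config has no group definitions")
    proj = np.zeros((len(names), config.n_o))
    for gi, name in enumerate(names):
        if name not in config.groups:
            raise ValueError(f"unknown group name {name!r}")
        idx = config.groups[name]
        proj[gi, idx] = 1.0 / len(idx)
    return proj


def _corr_from_cov(cov: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.einsum("bii->bi", cov))
    return cov / (sd[:, :, None] * sd[:, None, :])


def _corrected_couplings(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Corrected FP-DM and FP-DA correlations from 4-group covariances.

    The frontoparietal composite is the mean of the SN-A and SN-B group
    signals; the correction subtracts the mean of all six pairwise
    group-signal correlations of that run.
    """
    corr = _corr_from_cov(cov)
    iu = np.triu_indices(4, k=1)
    mean_coupling = corr[:, iu[0], iu[1]].mean(axis=1)
    # composite FP = (A + B)/2 in group-signal space
    var_fp = (cov[:, 0, 0] + cov[:, 1, 1] + 2 * cov[:, 0, 1]) / 4.0
    cov_fp_dm = (cov[:, 0, 2] + cov[:, 1, 2]) / 2.0
    cov_fp_da = (cov[:, 0, 3] + cov[:, 1, 3]) / 2.0
    r_fp_dm = cov_fp_dm / np.sqrt(var_fp * cov[:, 2, 2])
    r_fp_da = cov_fp_da / np.sqrt(var_fp * cov[:, 3, 3])
    return r_fp_dm - mean_coupling, r_fp_da - mean_coupling


def amplitude_experiment(
    config: HopfConfig,
    target_group: str,
    a_values: np.ndarray | None = None,
    reps: int = 10,
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Vary one group's bifurcation parameter; relate it to coupling.

    Per run the target group's oscillators get one sampled ``a`` value
    (all other units stay at the base value), frequencies are freshly
    drawn, and the corrected FP-DM / FP-DA couplings are computed from
    the group-mean signals.  Returns the per-run table and the Pearson
    association between the target ``a`` and each corrected coupling.
    """
    if a_values is None:
        a_values = np.linspace(-0.07, 0.08, 16)
    a_values = np.asarray(a_values, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    proj = _group_projector(config, GROUPS_OF_INTEREST)
    if target_group not in GROUPS_OF_INTEREST:
        raise ValueError(f"unknown group name {target_group!r}")
    target_idx = config.groups[target_group]
    a_run = np.repeat(a_values, reps)
    b = len(a_run)
    a_batch = np.tile(config.a, (b, 1))
    a_batch[:, target_idx] = a_run[:, None]
    omega_batch = np.stack(
        [
            sample_frequencies(config.freq_mean_hz, config.freq_sd_hz, config.n_o, rng)
            for _ in range(b)
        ]
    )
    cov, mean_sq = _batch_group_moments(config, a_batch, omega_batch, rng, proj)
    corrected_dm, corrected_da = _corrected_couplings(cov)
    gi = GROUPS_OF_INTEREST.index(target_group)
    rms_target = np.sqrt(mean_sq[:, gi])
    table = pd.DataFrame(
        {
            "run": np.arange(b),
            "a_target": a_run,
            "rms_target": rms_target,
            "fc_fp_dm_corrected": corrected_dm,
            "fc_fp_da_corrected": corrected_da,
        }
    )
    r_dm, p_dm = stats.pearsonr(a_run, corrected_dm)
    r_da, p_da = stats.pearsonr(a_run, corrected_da)
    return {
        "table": table,
        "target_group": target_group,
        "r_dm": float(r_dm),
        "p_dm": float(p_dm),
        "r_da": float(r_da),
        "p_da": float(p_da),
    }


def anticorrelation_census(
    config: HopfConfig,
    n_runs: int = 200,
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Count runs in which the two subnetwork signals are anticorrelated."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    proj = _group_projector(config, GROUPS_OF_INTEREST)
    a_batch = np.tile(config.a, (n_runs, 1))
    omega_batch = np.stack(
        [
            sample_frequencies(config.freq_mean_hz, config.freq_sd_hz, config.n_o, rng)
            for _ in range(n_runs)
        ]
    )
    cov, _ = _batch_group_moments(config, a_batch, omega_batch, rng, proj)
    corr = _corr_from_cov(cov)
    r_ab = corr[:, 0, 1]
    count = int((r_ab < 0).sum())
    p = stats.binomtest(count, n_runs, 0.5, alternative="greater").pvalue
    return {"count": count, "n_runs": n_runs, "sign_test_p": float(p), "r_ab": r_ab}


# ---------------------------------------------------------------------------
# Parameter sweep
# ---------------------------------------------------------------------------


def parameter_sweep(
    a_grid: np.ndarray,
    g_grid: np.ndarray,
    base: HopfConfig,
    reps: int = 10,
    seed: int | np.random.Generator | None = None,
    working_point: tuple[float, float] = (-0.075, 0.1),
) -> dict:
    """Grids of time-mean synchrony R and mean RMS over (a, G).

    Each grid point averages ``reps`` initializations with freshly drawn
    frequencies.  Also reports whether the working point's mean R lies
    strictly between the sweep's minimum and maximum ("intermediate").
    """
    a_grid = np.asarray(a_grid, dtype=float)
    g_grid = np.asarray(g_grid, dtype=float)
    if a_grid.size == 0 or g_grid.size == 0:
        raise ValueError("sweep grids must be nonempty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r_grid = np.zeros((a_grid.size, g_grid.size))
    rms_grid = np.zeros_like(r_grid)
    for ai, a in enumerate(a_grid):
        for gi, g in enumerate(g_grid):
            r_acc = rms_acc = 0.0
            for _ in range(reps):
                omega = sample_frequencies(
                    base.freq_mean_hz, base.freq_sd_hz, base.n_o, rng
                )
                cfg = dataclasses.replace(
                    base,
                    a=np.full(base.n_o, a),
                    omega=omega,
                    coupling=float(g),
                    seed=int(rng.integers(2**31)),
                )
                traj = simulate_hopf(cfg)
                _, r_mean = kuramoto_order(traj)
                r_acc += r_mean
                rms_acc += traj.rms().mean()
            r_grid[ai, gi] = r_acc / reps
            rms_grid[ai, gi] = rms_acc / reps
    result = {"a_grid": a_grid, "g_grid": g_grid, "mean_r": r_grid, "mean_rms": rms_grid}
    wa, wg = working_point
    ai = np.flatnonzero(np.isclose(a_grid, wa))
    gi = np.flatnonzero(np.isclose(g_grid, wg))
    if ai.size and gi.size:
        r_wp = r_grid[ai[0], gi[0]]
        result["working_point_r"] = float(r_wp)
        result["working_point_intermediate"] = bool(
            r_grid.min() < r_wp < r_grid.max()
        )
    return result


# ---------------------------------------------------------------------------
# Configuration builders
# ---------------------------------------------------------------------------

_PRESET_SIZES = {
    "4": {"SN-A": 1, "SN-B": 1, "DM": 1, "DA": 1},
    "192": {"SN-A": 30, "SN-B": 31, "DM": 79, "DA": 52},
    "400": {"SN-A": 30, "SN-B": 31, "DM": 79, "DA": 52, "other": 208},
}


def build_grouped_config(
    group_sizes: Mapping[str, int],
    d_group: np.ndarray,
    *,
    a: float = -0.075,
    coupling: float = 0.1,
    xi: float = 0.02,
    dt: float = 0.01,
    duration: float = 360.0,
    transient_discard: float = 20.0,
    freq_mean_hz: float = 0.04,
    freq_sd_hz: float = 0.01,
    seed: int = 0,
) -> HopfConfig:
    """Expand a group-level coupling matrix to oscillator level.

    The oscillator-pair weight between groups p and q is
    ``d_group[p, q] / (n_p * n_q)`` (within-group analogously over
    ordered pairs), so the summed inter-group coupling matches the
    one-oscillator-per-group case regardless of group sizes.
    """
    names = list(group_sizes)
    sizes = [int(group_sizes[name]) for name in names]
    if any(s < 1 for s in sizes):
        raise ValueError("group sizes must be >= 1")
    d_group = np.asarray(d_group, dtype=float)
    if d_group.shape != (len(names), len(names)):
        raise ValueError("group coupling matrix does not match group count")
    n = sum(sizes)
    bounds = np.cumsum([0] + sizes)
    groups = {
        name: np.arange(bounds[i], bounds[i + 1]) for i, name in enumerate(names)
    }
    d = np.zeros((n, n))
    for i, ni in enumerate(names):
        for j, nj in enumerate(names):
            if i == j:
                if sizes[i] > 1 and d_group[i, i] > 0:
                    w = d_group[i, i] / (sizes[i] * (sizes[i] - 1))
                    blk = np.full((sizes[i], sizes[i]), w)
                    np.fill_diagonal(blk, 0.0)
                    d[np.ix_(groups[ni], groups[ni])] = blk
            else:
                w = d_group[i, j] / (sizes[i] * sizes[j])
                d[np.ix_(groups[ni], groups[nj])] = w
    rng = np.random.default_rng(seed)
    omega = sample_frequencies(freq_mean_hz, freq_sd_hz, n, rng)
    return HopfConfig(
        n_o=n,
        a=np.full(n, a),
        omega=omega,
        d=d,
        coupling=coupling,
        xi=xi,
        dt=dt,
        duration=duration,
        transient_discard=transient_discard,
        seed=seed,
        groups=groups,
        freq_mean_hz=freq_mean_hz,
        freq_sd_hz=freq_sd_hz,
    )


def preset_config(
    preset: str,
    d_group: np.ndarray | None = None,
    background_coupling: float = 0.1,
    **kwargs,
) -> HopfConfig:
    """4-, 192- or 400-unit network with the default coupling motif."""
    if preset not in _PRESET_SIZES:
        raise ValueError(f"unknown preset {preset!r}")
    sizes = _PRESET_SIZES[preset]
    if d_group is None:
        d_group = default_group_coupling()
    d_group = np.asarray(d_group, dtype=float)
    if preset == "400" and d_group.shape == (4, 4):
        padded = np.full((5, 5), background_coupling)
        padded[:4, :4] = d_group
        padded[4, 4] = 0.0
        d_group = padded
    return build_grouped_config(sizes, d_group, **kwargs)


def ablate_coupling(config: HopfConfig) -> HopfConfig:
    """Copy of the configuration with all structural coupling removed."""
    return dataclasses.replace(config, d=np.zeros_like(config.d))
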