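"""Synthetic multi-subject, multi-run cohort with planted effects.

The generator produces regional timeseries, per-subject structural
matrices, probe-level gene expression and behavior tables whose
second-order structure matches what the downstream analysis assumes:

* subnetwork A positively / subnetwork B negatively coupled to the
  default-mode system (and oppositely to dorsal attention),
* a structural motif with strong A<->DM and B<->DA blocks,
* behavior decreasing with subnetwork-A amplitude and with FP-DM
  coupling, increasing with subnetwork-B amplitude,
* two runs nested per subject, sharing subject-level amplitudes.

Latent construction is a shared Gaussian factor model: the analysis only
consumes second-order structure, so no hemodynamics are simulated.  Each
system has a unit-variance latent signal; the subnetwork latents are

    s_A = g_A * (w_ad * s_DM + w_ada * s_DA) + sqrt(g_A) * gamma_A * e_A
    s_B = g_B * (w_bd * s_DM + w_bda * s_DA) + sqrt(g_B) * gamma_B * e_B

where g_A, g_B are per-subject amplitude gains.  Scaling the private
component e_A by sqrt(g_A) makes both the subnetwork RMS and the
subnetwork-system coupling increase with the gain, which is what plants
a recoverable activity->coupling relationship.  Region signals load on
their system latent with sqrt(rho) so that the within-system region-pair
correlation equals ``within_subnetwork_corr`` at ``noise_sd = 1``.

The mixing weights are calibrated by Gauss-Hermite quadrature over the
gain distribution so the cohort-average subnetwork-system coupling hits
the configured targets in expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Parcellation, stage_rng, write_matrix, write_parcellation, write_timeseries

__all__ = [
    "CohortSpec",
    "RegionalTimeseries",
    "generate_cohort_timeseries",
    "generate_structural_network",
    "generate_gene_expression",
    "generate_behavior",
    "write_cohort",
]

_COUPLING_KEYS = ("a_dm", "b_dm", "a_da", "b_da")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort generator."""

    n_subjects: int = 50
    runs_per_subject: int = 2
    n_timepoints: int = 405
    tr: float = 0.72
    coupling_targets: dict = field(
        default_factory=lambda: {
            "a_dm": 0.042,
            "b_dm": -0.082,
            "a_da": -0.014,
            "b_da": 0.12,
        }
    )
    within_subnetwork_corr: float = 0.25
    structural_motif_means: dict = field(
        default_factory=lambda: {
            "a_dm": 2.07,
            "b_dm": 0.676,
            "a_da": 1.03,
            "b_da": 1.54,
        }
    )
    structural_background_mean: float = 0.3
    structural_shape: float = 4.0
    behavior_effects: dict = field(
        default_factory=lambda: {
            "intercept": 0.8,
            "beta_a": 0.10,
            "beta_b": 0.08,
            "beta_fc": 1.0,
            "subject_sd": 0.02,
            "noise_sd": 0.02,
        }
    )
    noise_sd: float = 1.0
    gain_sd: float = 0.35
    coexpr_baseline: float = 0.4
    coexpr_margin: float = 0.15
    probe_noise_sd: float = 0.5
    seed: int = 0
    #: Optional override of the latent mixing weights (keys as in
    #: ``coupling_targets``); skips target calibration when given.
    latent_coeffs: dict | None = None

    def __post_init__(self) -> None:
        for key in _COUPLING_KEYS:
            if key not in self.coupling_targets:
                raise ValueError(f"coupling_targets missing {key!r}")
            t = self.coupling_targets[key]
            if not -1.0 < t < 1.0:
                raise ValueError(f"coupling target {key}={t} outside (-1, 1)")
        if not 0.0 < self.within_subnetwork_corr < 1.0:
            raise ValueError("within_subnetwork_corr must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for key, v in self.structural_motif_means.items():
            if v < 0:
                raise ValueError(f"negative structural motif mean for {key}")
        if self.n_timepoints < 10:
            raise ValueError("n_timepoints must be at least 10")


@dataclass
class RegionalTimeseries:
    """Per subject/run matrix of regional activity (regions x timepoints)."""

    subject_id: int
    run_id: int
    data: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[1] < 2:
            raise ValueError("timeseries needs >= 2 timepoints")
        if np.isnan(data).any():
            raise ValueError("timeseries contains missing values")
        object.__setattr__(self, "data", data)


# ---------------------------------------------------------------------------
# Timeseries
# ---------------------------------------------------------------------------


def _gain_expectation(func, gain_sd: float, order: int = 41) -> float:
    """E[func(g)] for g ~ N(1, gain_sd^2) clipped below at 0.05."""
    if gain_sd == 0:
        return float(func(np.array([1.0]))[0])
    nodes, weights = np.polynomial.hermite_e.hermegauss(order)
    g = np.maximum(1.0 + gain_sd * nodes, 0.05)
    return float(np.sum(weights * func(g)) / np.sum(weights))


def _calibrate_weights(spec: CohortSpec, parc: Parcellation) -> dict:
    """Solve latent mixing weights so cohort-average couplings hit targets."""
    if spec.latent_coeffs is not None:
        return dict(spec.latent_coeffs)
    rho = spec.within_subnetwork_corr
    # targets are mean region-pair correlations, so the denominator uses
    # per-region variances (system latent share rho, idiosyncratic rest)
    q = (1 - rho) * spec.noise_sd**2
    weights: dict[str, float] = {}
    for sub in ("a", "b"):
        c2 = 0.0
        for _ in range(3):  # fixed-point refinement of the variance term
            new = {}
            for sysk in ("dm", "da"):
                key = f"{sub}_{sysk}"

                def factor(g, c2=c2):
                    var_lat = g**2 * c2 + g * (1 - c2)
                    return rho * g / np.sqrt((rho * var_lat + q) * (rho + q))

                k = _gain_expectation(factor, spec.gain_sd)
                new[key] = spec.coupling_targets[key] / k
            c2 = new[f"{sub}_dm"] ** 2 + new[f"{sub}_da"] ** 2
            weights.update(new)
            if not np.isfinite(c2) or c2 > 1.0:
                break
        if not np.isfinite(c2) or c2 > 1.0:
            raise ValueError(
                "infeasible covariance: coupling targets imply a latent "
                "loading above 1 (not positive semidefinite)"
            )
    return weights


def generate_cohort_timeseries(
    spec: CohortSpec, parc: Parcellation
) -> tuple[list[RegionalTimeseries], pd.DataFrame]:
    """Generate all subject/run timeseries plus per-subject latent gains.

    Returns the list of :class:`RegionalTimeseries` (ordered by subject,
    then run) and a data frame with columns ``subject``, ``g_a``, ``g_b``.
    """
    idx_a = parc.indices_of_subnetwork("A")
    idx_b = parc.indices_of_subnetwork("B")
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("parcellation has no subnetwork labels")
    weights = _calibrate_weights(spec, parc)
    c2_a = weights["a_dm"] ** 2 + weights["a_da"] ** 2
    c2_b = weights["b_dm"] ** 2 + weights["b_da"] ** 2
    if c2_a > 1.0 or c2_b > 1.0:
        raise ValueError("infeasible covariance: latent loadings exceed 1")
    gamma_a = np.sqrt(1.0 - c2_a)
    gamma_b = np.sqrt(1.0 - c2_b)

    rho = spec.within_subnetwork_corr
    load = np.sqrt(rho)
    noise_scale = np.sqrt(1.0 - rho) * spec.noise_sd

    other_systems = [
        s
        for s in np.unique(parc.systems)
        if s not in ("default-mode", "dorsal-attention", "frontoparietal")
    ]
    sys_idx = {s: parc.indices_of_system(s) for s in other_systems}
    idx_dm = parc.indices_of_system("default-mode")
    idx_da = parc.indices_of_system("dorsal-attention")

    rng = stage_rng(spec.seed, "cohort-timeseries")
    gains = np.maximum(
        rng.normal(1.0, spec.gain_sd, size=(spec.n_subjects, 2)), 0.05
    )
    out: list[RegionalTimeseries] = []
    n, t = parc.n_regions, spec.n_timepoints
    for subj in range(spec.n_subjects):
        g_a, g_b = gains[subj]
        for run in range(spec.runs_per_subject):
            s_dm = rng.standard_normal(t)
            s_da = rng.standard_normal(t)
            e_a = rng.standard_normal(t)
            e_b = rng.standard_normal(t)
            s_a = (
                g_a * (weights["a_dm"] * s_dm + weights["a_da"] * s_da)
                + np.sqrt(g_a) * gamma_a * e_a
            )
            s_b = (
                g_b * (weights["b_dm"] * s_dm + weights["b_da"] * s_da)
                + np.sqrt(g_b) * gamma_b * e_b
            )
            data = noise_scale * rng.standard_normal((n, t))
            data[idx_dm] += load * s_dm
            data[idx_da] += load * s_da
            data[idx_a] += load * s_a
            data[idx_b] += load * s_b
            for s in other_systems:
                data[sys_idx[s]] += load * rng.standard_normal(t)
            out.append(RegionalTimeseries(subj, run, data, spec.tr))
    gains_df = pd.DataFrame(
        {
            "subject": np.arange(spec.n_subjects),
            "g_a": gains[:, 0],
            "g_b": gains[:, 1],
        }
    )
    return out, gains_df


# ---------------------------------------------------------------------------
# Structural matrices
# ---------------------------------------------------------------------------


def _block_mean_matrix(spec: CohortSpec, parc: Parcellation) -> np.ndarray:
    n = parc.n_regions
    means = np.full((n, n), spec.structural_background_mean, dtype=float)
    groups = {
        "a": parc.indices_of_subnetwork("A"),
        "b": parc.indices_of_subnetwork("B"),
        "dm": parc.indices_of_system("default-mode"),
        "da": parc.indices_of_system("dorsal-attention"),
    }
    for key, value in spec.structural_motif_means.items():
        g1, g2 = key.split("_")
        means[np.ix_(groups[g1], groups[g2])] = value
        means[np.ix_(groups[g2], groups[g1])] = value
    np.fill_diagonal(means, 0.0)
    return means


def generate_structural_network(
    spec: CohortSpec, parc: Parcellation
) -> list[np.ndarray]:
    """One symmetric nonnegative structural matrix per subject.

    Edge weights are gamma distributed with the planted block means
    (motif blocks for subnetwork-system pairs, small background mean
    elsewhere) and per-subject noise; diagonal is zero.
    """
    means = _block_mean_matrix(spec, parc)
    n = parc.n_regions
    iu = np.triu_indices(n, k=1)
    mean_upper = means[iu]
    shape = spec.structural_shape
    rng = stage_rng(spec.seed, "cohort-structural")
    out = []
    for _ in range(spec.n_subjects):
        w = np.zeros_like(mean_upper)
        pos = mean_upper > 0
        w[pos] = rng.gamma(shape, mean_upper[pos] / shape)
        mat = np.zeros((n, n))
        mat[iu] = w
        mat += mat.T
        out.append(mat)
    return out


# ---------------------------------------------------------------------------
# Gene expression
# ---------------------------------------------------------------------------


def generate_gene_expression(
    spec: CohortSpec,
    parc: Parcellation,
    n_genes: int = 2000,
    probes_per_gene: int = 2,
) -> pd.DataFrame:
    """Probe-level expression table with a planted subnetwork signature.

    Each parcel's gene profile is a mixture of a shared baseline factor
    (weight ``coexpr_baseline``), a subnetwork factor for A/B parcels
    (weight ``coexpr_margin``) and idiosyncratic noise, so that
    within-subnetwork parcel-parcel profile correlation exceeds
    between-subnetwork correlation by the margin.  Probe values are the
    gene value plus a per-probe offset plus noise.

    Returns a long table with columns ``parcel``, ``gene``, ``probe``,
    ``value``.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if probes_per_gene < 1:
        raise ValueError("probes_per_gene must be >= 1")
    b = spec.coexpr_baseline
    m = spec.coexpr_margin
    if b + m > 1.0:
        raise ValueError("coexpr_baseline + coexpr_margin must be <= 1")
    rng = stage_rng(spec.seed, "cohort-genes")
    n_parcels = parc.n_regions
    # Probe aggregation removes anything constant across parcels, so the
    # planted structure lives in per-subnetwork gene factors: the A and B
    # factors share a common component (between-subnetwork coexpression
    # ~= coexpr_baseline) plus own components raising within-subnetwork
    # coexpression to baseline + margin.
    v = b + m  # factor share of parcel-profile variance
    s = 1.0 if v == 0 else b / v  # shared fraction of the two factors
    shared = rng.standard_normal(n_genes)
    own_a = rng.standard_normal(n_genes)
    own_b = rng.standard_normal(n_genes)
    factor_a = np.sqrt(s) * shared + np.sqrt(1.0 - s) * own_a
    factor_b = np.sqrt(s) * shared + np.sqrt(1.0 - s) * own_b
    expr = np.sqrt(1.0 - v) * rng.standard_normal((n_parcels, n_genes))
    idx_a = parc.indices_of_subnetwork("A")
    idx_b = parc.indices_of_subnetwork("B")
    if v > 0:
        expr[idx_a] += np.sqrt(v) * factor_a
        expr[idx_b] += np.sqrt(v) * factor_b
    probe_offsets = rng.normal(0.0, 1.0, size=(n_genes, probes_per_gene))
    # long-format assembly without per-row python loops
    parcels = np.repeat(parc.region_ids, n_genes * probes_per_gene)
    genes = np.tile(np.repeat(np.arange(n_genes), probes_per_gene), n_parcels)
    probes = np.tile(np.arange(probes_per_gene), n_parcels * n_genes)
    values = (
        np.repeat(expr.ravel(), probes_per_gene)
        + probe_offsets[genes, probes]
        + spec.probe_noise_sd * rng.standard_normal(parcels.shape[0])
    )
    return pd.DataFrame(
        {
            "parcel": parcels,
            "gene": genes,
            "probe": probes,
            "value": values,
        }
    )


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------


def generate_behavior(
    g_a: Sequence[float],
    g_b: Sequence[float],
    fc_fp_dm: pd.DataFrame,
    spec: CohortSpec,
) -> pd.DataFrame:
    """Accuracy-like behavior per (subject, run), clipped to [0, 1].

    ``fc_fp_dm`` must have columns ``subject``, ``run``, ``fc``.  The
    score is  intercept - beta_a*g_A + beta_b*g_B - beta_fc*fc
    + subject random intercept + noise.
    """
    g_a = np.asarray(g_a, dtype=float)
    g_b = np.asarray(g_b, dtype=float)
    if len(g_a) != len(g_b):
        raise ValueError("g_a and g_b length mismatch")
    n_subjects = len(g_a)
    subjects = fc_fp_dm["subject"].to_numpy()
    if subjects.max() >= n_subjects:
        raise ValueError("fc table references unknown subjects")
    eff = spec.behavior_effects
    rng = stage_rng(spec.seed, "cohort-behavior")
    u = rng.normal(0.0, eff["subject_sd"], size=n_subjects)
    score = (
        eff["intercept"]
        - eff["beta_a"] * g_a[subjects]
        + eff["beta_b"] * g_b[subjects]
        - eff["beta_fc"] * fc_fp_dm["fc"].to_numpy()
        + u[subjects]
        + rng.normal(0.0, eff["noise_sd"], size=len(fc_fp_dm))
    )
    return pd.DataFrame(
        {
            "subject": subjects,
            "run": fc_fp_dm["run"].to_numpy(),
            "score": np.clip(score, 0.0, 1.0),
        }
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_cohort(
    directory: str | Path,
    parc: Parcellation,
    timeseries: list[RegionalTimeseries],
    structural: list[np.ndarray] | None = None,
    behavior: pd.DataFrame | None = None,
    gene_table: pd.DataFrame | None = None,
    spec: CohortSpec | None = None,
) -> Path:
    """Write the cohort as a directory tree of TSVs plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_parcellation(parc, directory / "parcellation.tsv")
    ts_dir = directory / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    for ts in timeseries:
        write_timeseries(
            ts.data,
            ts_dir / f"sub-{ts.subject_id:03d}_run-{ts.run_id}.tsv",
            parc.region_ids,
        )
    if structural is not None:
        sc_dir = directory / "structural"
        sc_dir.mkdir(exist_ok=True)
        for subj, mat in enumerate(structural):
            write_matrix(mat, sc_dir / f"sub-{subj:03d}.tsv", parc.region_ids)
    if behavior is not None:
        behavior.to_csv(directory / "behavior.tsv", sep="\t", index=False)
    if gene_table is not None:
        gene_table.to_csv(directory / "gene_probes.tsv", sep="\t", index=False)
    manifest = {
        "n_subjects": len({ts.subject_id for ts in timeseries}),
        "runs_per_subject": len({ts.run_id for ts in timeseries}),
        "n_regions": parc.n_regions,
        "spec": None if spec is None else {
            k: v for k, v in spec.__dict__.items() if not k.startswith("_")
        },
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory
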