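"""End-to-end study on a synthetic cohort.

generate -> connectomics -> subnetwork detection -> coupling/behavior
statistics -> boundary control -> gene coexpression -> oscillator
experiments -> consolidated JSON-serializable report.

The report's ten canonical sign checks mirror the qualitative result
pattern the analysis is designed to recover on the planted cohort:
four subnetwork-system coupling signs, two activity->coupling slopes,
two structural motif orderings, and two oscillator amplitude-experiment
signs.  Each check records its sign, its p-value, and whether it passes
at the Bonferroni-corrected level.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from . import coexpression as cx
from . import connectomics as cn
from . import control as bc
from . import hopf
from . import stats as st
from . import wsbm
from .cohort import (
    CohortSpec,
    generate_behavior,
    generate_cohort_timeseries,
    generate_gene_expression,
    generate_structural_network,
)
from .io import AnalysisConfig, Parcellation, default_parcellation, stage_rng

__all__ = ["run_study", "SIGN_CHECK_NAMES", "build_cohort_spec", "build_parcellation"]

SIGN_CHECK_NAMES = (
    "coupling_a_dm_positive",
    "coupling_b_dm_negative",
    "coupling_a_da_negative",
    "coupling_b_da_positive",
    "slope_rms_a_fc_positive",
    "slope_rms_b_fc_negative",
    "structural_a_dm_exceeds_b_dm",
    "structural_b_da_exceeds_a_da",
    "hopf_amp_a_fc_positive",
    "hopf_amp_b_fc_negative",
)


def build_parcellation(config: AnalysisConfig) -> Parcellation:
    cohort_cfg = config.stage("cohort")
    return default_parcellation(
        system_sizes=cohort_cfg["system_sizes"],
        subnetwork_split=(
            tuple(cohort_cfg["subnetwork_split"])
            if cohort_cfg["subnetwork_split"] is not None
            else None
        ),
    )


def build_cohort_spec(config: AnalysisConfig) -> CohortSpec:
    cohort_cfg = config.stage("cohort")
    kwargs = {
        k: v
        for k, v in cohort_cfg.items()
        if k
        not in ("n_genes", "probes_per_gene", "system_sizes", "subnetwork_split")
        and v is not None
    }
    return CohortSpec(seed=config.seed, **kwargs)


def _check(name: str, estimate: float, p: float, want_positive: bool, alpha: float) -> dict:
    sign_ok = (estimate > 0) == want_positive
    return {
        "name": name,
        "estimate": float(estimate),
        "p_value": float(p),
        "sign_ok": bool(sign_ok),
        "significant": bool(p < alpha),
        "passed": bool(sign_ok and p < alpha),
    }


def _mlm_record(fit: st.MultilevelFit, names: list[str]) -> dict:
    return {
        "coefficients": {
            name: {
                "estimate": float(fit.params[i]),
                "se": float(fit.se[i]),
                "t": float(fit.tvalues[i]),
                "p": float(fit.pvalues[i]),
                "ci": [float(fit.ci_lower[i]), float(fit.ci_upper[i])],
            }
            for i, name in enumerate(names)
        },
        "sigma2_subject": fit.sigma2_subject,
        "sigma2_residual": fit.sigma2_residual,
        "df": fit.df,
        "n_obs": fit.n_obs,
        "n_subjects": fit.n_subjects,
    }


def run_study(config: AnalysisConfig, out_dir: str | Path | None = None) -> dict:
    """Execute all stages in dependency order and return the report."""
    t0 = time.time()
    seed = config.seed
    alpha = config.stage("stats")["alpha"]
    alpha_corrected = alpha / len(SIGN_CHECK_NAMES)
    report: dict = {
        "version": _version,
        "seed": seed,
        "config": {"seed": seed, "stages": config.stages},
        "stages": {},
    }

    parc = build_parcellation(config)
    spec = build_cohort_spec(config)
    cohort_cfg = config.stage("cohort")

    # --- generation -------------------------------------------------------
    timeseries, gains = generate_cohort_timeseries(spec, parc)
    structural = generate_structural_network(spec, parc)

    # --- connectomics per run --------------------------------------------
    rows = []
    n_fp = parc.indices_of_system("frontoparietal").size
    fp_idx = parc.indices_of_system("frontoparietal")
    subgraph_sum: dict[int, np.ndarray] = {}
    subgraph_count: dict[int, int] = {}
    for ts in timeseries:
        net = cn.compute_functional_network(ts)
        rows.append(
            {
                "subject": ts.subject_id,
                "run": ts.run_id,
                "a_dm": cn.subnetwork_system_coupling(net, parc, "A", "default-mode"),
                "b_dm": cn.subnetwork_system_coupling(net, parc, "B", "default-mode"),
                "a_da": cn.subnetwork_system_coupling(net, parc, "A", "dorsal-attention"),
                "b_da": cn.subnetwork_system_coupling(net, parc, "B", "dorsal-attention"),
                "fc_fp_dm": float(
                    net.matrix[np.ix_(fp_idx, parc.indices_of_system("default-mode"))].mean()
                ),
                "fc_fp_da": float(
                    net.matrix[np.ix_(fp_idx, parc.indices_of_system("dorsal-attention"))].mean()
                ),
                "rms_a": cn.subnetwork_rms(ts, parc, "A"),
                "rms_b": cn.subnetwork_rms(ts, parc, "B"),
            }
        )
        sub = net.matrix[np.ix_(fp_idx, fp_idx)]
        if ts.subject_id in subgraph_sum:
            subgraph_sum[ts.subject_id] += sub
            subgraph_count[ts.subject_id] += 1
        else:
            subgraph_sum[ts.subject_id] = sub.copy()
            subgraph_count[ts.subject_id] = 1
    runs = pd.DataFrame(rows).sort_values(["subject", "run"]).reset_index(drop=True)
    subgraphs = [
        subgraph_sum[s] / subgraph_count[s] for s in sorted(subgraph_sum)
    ]
    report["stages"]["connectomics"] = {
        "mean_couplings": {
            k: float(runs[k].mean()) for k in ("a_dm", "b_dm", "a_da", "b_da")
        },
        "n_runs": int(len(runs)),
        "n_fp_regions": int(n_fp),
    }

    # --- behavior (depends on per-run FC) --------------------------------
    behavior = generate_behavior(
        gains["g_a"].to_numpy(),
        gains["g_b"].to_numpy(),
        runs.rename(columns={"fc_fp_dm": "fc"})[["subject", "run", "fc"]],
        spec,
    )
    runs = runs.merge(behavior, on=["subject", "run"])

    # --- subnetwork detection --------------------------------------------
    wsbm_cfg = config.stage("wsbm")
    rng_wsbm = stage_rng(seed, "wsbm")
    fits = [
        wsbm.fit_wsbm(
            sg,
            wsbm_cfg["k"],
            restarts=wsbm_cfg["restarts"],
            seed=rng_wsbm,
            variance_floor=wsbm_cfg["variance_floor"],
            max_sweeps=wsbm_cfg["max_sweeps"],
        )
        for sg in subgraphs
    ]
    consensus = wsbm.consensus_partition([f.z for f in fits])
    planted = np.where(
        np.array([parc.subnetworks[i] for i in fp_idx]) == "A", 1, 2
    )
    ll_true, ll_perm = wsbm.partition_permutation_null(
        subgraphs, consensus.partition, seed=stage_rng(seed, "wsbm-null")
    )
    null_fit = st.fit_random_intercept_model(
        np.concatenate([ll_true, ll_perm]),
        np.concatenate([np.zeros_like(ll_true), np.ones_like(ll_perm)])[:, None],
        np.concatenate([np.arange(len(ll_true))] * 2),
    )
    ck_cfg = config.stage("compare_k")
    ck = wsbm.compare_k(
        subgraphs,
        k_values=tuple(ck_cfg["k_values"]),
        n_boot=ck_cfg["n_boot"],
        seed=stage_rng(seed, "compare-k"),
    )
    report["stages"]["subnetworks"] = {
        "consensus_vs_planted_zrand": float(
            wsbm.zrand(consensus.partition, planted)
        ),
        "consensus_matches_planted": bool(
            (consensus.partition == planted).all()
            or (consensus.partition == (3 - planted)).all()
        ),
        "permutation_null": _mlm_record(null_fit, ["intercept", "permuted"]),
        "compare_k_tails": {
            str(k): float(v["tail"]) for k, v in ck.items() if "tail" in v
        },
    }

    # --- coupling / behavior statistics ----------------------------------
    checks: dict[str, dict] = {}
    subj = runs["subject"].to_numpy()
    for key, name, positive in (
        ("a_dm", "coupling_a_dm_positive", True),
        ("b_dm", "coupling_b_dm_negative", False),
        ("a_da", "coupling_a_da_negative", False),
        ("b_da", "coupling_b_da_positive", True),
    ):
        fit = st.fit_random_intercept_model(
            runs[key].to_numpy(), np.empty((len(runs), 0)), subj
        )
        checks[name] = _check(
            name, fit.params[0], fit.pvalues[0], positive, alpha_corrected
        )

    fc_fit = st.fit_random_intercept_model(
        runs["fc_fp_dm"].to_numpy(),
        runs[["rms_a", "rms_b"]].to_numpy(),
        subj,
    )
    checks["slope_rms_a_fc_positive"] = _check(
        "slope_rms_a_fc_positive", fc_fit.params[1], fc_fit.pvalues[1], True,
        alpha_corrected,
    )
    checks["slope_rms_b_fc_negative"] = _check(
        "slope_rms_b_fc_negative", fc_fit.params[2], fc_fit.pvalues[2], False,
        alpha_corrected,
    )
    beh_fit = st.fit_random_intercept_model(
        runs["score"].to_numpy(), runs[["rms_a", "rms_b"]].to_numpy(), subj
    )
    beh_fc_fit = st.fit_random_intercept_model(
        runs["score"].to_numpy(), runs[["fc_fp_dm", "rms_a"]].to_numpy(), subj
    )
    rm = st.rmcorr(
        runs["score"].to_numpy(), runs["fc_fp_dm"].to_numpy(), subj
    )
    report["stages"]["statistics"] = {
        "fc_by_rms": _mlm_record(fc_fit, ["intercept", "rms_a", "rms_b"]),
        "behavior_by_rms": _mlm_record(beh_fit, ["intercept", "rms_a", "rms_b"]),
        "behavior_by_fc_covaried": _mlm_record(
            beh_fc_fit, ["intercept", "fc_fp_dm", "rms_a"]
        ),
        "behavior_fc_rmcorr": {
            "rrm": rm.rrm,
            "df": rm.df,
            "p": rm.p_value,
        },
        "extra_sign_pattern": {
            "behavior_rms_a_negative": bool(beh_fit.params[1] < 0),
            "behavior_rms_b_positive": bool(beh_fit.params[2] > 0),
            "behavior_fc_negative_covaried": bool(
                beh_fc_fit.params[1] < 0
                and beh_fc_fit.pvalues[1] < alpha_corrected
            ),
        },
    }

    # --- structural analyses ---------------------------------------------
    normalized = [cn.normalize_structural(m) for m in structural]
    groups = [
        parc.indices_of_subnetwork("A"),
        parc.indices_of_subnetwork("B"),
        parc.indices_of_system("default-mode"),
        parc.indices_of_system("dorsal-attention"),
    ]
    d_matrix = cn.mean_structural_coupling(normalized, groups)
    per_subj = {
        key: np.array([cn._pair_mean(m, groups[i], groups[j]) for m in normalized])
        for key, (i, j) in {
            "a_dm": (0, 2),
            "b_dm": (1, 2),
            "a_da": (0, 3),
            "b_da": (1, 3),
        }.items()
    }
    rng_swap = stage_rng(seed, "structural-swap")
    n_perm_stats = config.stage("stats")["n_perm"]
    obs_adm, p_adm = st.paired_swap_permutation(
        per_subj["a_dm"], per_subj["b_dm"], n_perm=n_perm_stats, seed=rng_swap
    )
    obs_bda, p_bda = st.paired_swap_permutation(
        per_subj["b_da"], per_subj["a_da"], n_perm=n_perm_stats, seed=rng_swap
    )
    checks["structural_a_dm_exceeds_b_dm"] = _check(
        "structural_a_dm_exceeds_b_dm", obs_adm, p_adm, True, alpha_corrected
    )
    checks["structural_b_da_exceeds_a_da"] = _check(
        "structural_b_da_exceeds_a_da", obs_bda, p_bda, True, alpha_corrected
    )

    mean_structural = cn.normalize_structural(sum(normalized))
    bc_cfg = config.stage("boundary_control")
    bc_map = bc.boundary_control(
        mean_structural, parc, "default-mode", "dorsal-attention"
    )
    top = bc.top_percentile_regions(bc_map, bc_cfg["pct"])
    enrich = bc.enrichment_test(
        top,
        "frontoparietal",
        parc,
        n_perm=bc_cfg["n_perm"],
        seed=stage_rng(seed, "bc-enrichment"),
    )
    report["stages"]["structural"] = {
        "group_coupling_matrix": d_matrix.tolist(),
        "group_order": ["A", "B", "default-mode", "dorsal-attention"],
        "block_means": {k: float(v.mean()) for k, v in per_subj.items()},
        "boundary_control_enrichment": {
            k: v for k, v in enrich.items() if not isinstance(v, np.ndarray)
        },
    }

    # --- gene coexpression ------------------------------------------------
    gene_table = generate_gene_expression(
        spec, parc, cohort_cfg["n_genes"], cohort_cfg["probes_per_gene"]
    )
    expr = cx.aggregate_probes(gene_table)
    id_to_sub = {
        rid: sub for rid, sub in zip(parc.region_ids, parc.subnetworks)
    }
    labels = np.array(
        [id_to_sub.get(rid) or "" for rid in expr.parcel_ids], dtype=object
    )
    cx_cfg = config.stage("coexpression")
    cx_results = {}
    rng_cx = stage_rng(seed, "coexpression")
    for subnet in ("A", "B"):
        res = cx.coexpression_bootstrap_test(
            expr,
            labels,
            n_boot=cx_cfg["n_boot"],
            n_perm=cx_cfg["n_perm"],
            seed=rng_cx,
            subnetwork=subnet,
        )
        cx_results[subnet] = {
            "within": res.within,
            "between": res.between,
            "ratio": res.ratio,
            "null_ratio": res.null_ratio,
            "p_value": res.p_value,
        }
    report["stages"]["coexpression"] = cx_results

    # --- oscillator experiments -------------------------------------------
    hopf_cfg = config.stage("hopf")
    base = hopf.preset_config(
        hopf_cfg["preset"],
        d_group=hopf.default_group_coupling(hopf_cfg["coupling_scale"]),
        duration=hopf_cfg["duration"],
        dt=hopf_cfg["dt"],
        seed=seed,
    )
    if hopf_cfg["ablate"]:
        base = hopf.ablate_coupling(base)
    a_values = np.linspace(-0.07, 0.08, hopf_cfg["n_a_values"])
    rng_hopf = stage_rng(seed, "hopf")
    exp_a = hopf.amplitude_experiment(
        base, "SN-A", a_values, reps=hopf_cfg["reps"], seed=rng_hopf
    )
    exp_b = hopf.amplitude_experiment(
        base, "SN-B", a_values, reps=hopf_cfg["reps"], seed=rng_hopf
    )
    census = hopf.anticorrelation_census(
        base, n_runs=hopf_cfg["census_runs"], seed=rng_hopf
    )
    checks["hopf_amp_a_fc_positive"] = _check(
        "hopf_amp_a_fc_positive", exp_a["r_dm"], exp_a["p_dm"], True, alpha_corrected
    )
    checks["hopf_amp_b_fc_negative"] = _check(
        "hopf_amp_b_fc_negative", exp_b["r_dm"], exp_b["p_dm"], False, alpha_corrected
    )
    report["stages"]["hopf"] = {
        "amp_a": {k: v for k, v in exp_a.items() if k != "table"},
        "amp_b": {k: v for k, v in exp_b.items() if k != "table"},
        "anticorrelation_census": {
            "count": census["count"],
            "n_runs": census["n_runs"],
            "sign_test_p": census["sign_test_p"],
        },
    }

    # --- consolidated sign checks -----------------------------------------
    report["sign_checks"] = {name: checks[name] for name in SIGN_CHECK_NAMES}
    report["n_sign_checks_passed"] = int(
        sum(c["passed"] for c in report["sign_checks"].values())
    )
    report["n_sign_checks_triggered"] = int(
        sum(c["significant"] for c in report["sign_checks"].values())
    )
    report["alpha_per_check"] = alpha_corrected
    report["runtime_seconds"] = round(time.time() - t0, 3)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
    return report
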