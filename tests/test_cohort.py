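import numpy as np
import pandas as pd
import pytest

from fpsubnet import coexpression as cx
from fpsubnet import connectomics as cn
from fpsubnet.cohort import (
    CohortSpec,
    generate_behavior,
    generate_cohort_timeseries,
    generate_gene_expression,
    generate_structural_network,
    write_cohort,
)
from fpsubnet.io import default_parcellation, read_timeseries


class TestSpecValidation:
    def test_target_outside_open_interval_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            CohortSpec(coupling_targets={"a_dm": 1.0, "b_dm": 0, "a_da": 0, "b_da": 0})

    def test_negative_motif_mean_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            CohortSpec(
                structural_motif_means={"a_dm": -1, "b_dm": 0, "a_da": 0, "b_da": 0}
            )

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError, match="n_timepoints"):
            CohortSpec(n_timepoints=5)


class TestTimeseries:
    def test_deterministic_under_seed(self, parc_small):
        spec = CohortSpec(n_subjects=3, n_timepoints=50, seed=9)
        ts1, g1 = generate_cohort_timeseries(spec, parc_small)
        ts2, g2 = generate_cohort_timeseries(spec, parc_small)
        assert all(np.array_equal(a.data, b.data) for a, b in zip(ts1, ts2))
        pd.testing.assert_frame_equal(g1, g2)

    def test_noise_free_unit_coupling(self, parc_small):
        # c1=1, other mixing weights 0, no noise, fixed gain: the
        # subnetwork-A mean signal is exactly the default-mode signal
        spec = CohortSpec(
            n_subjects=2,
            n_timepoints=60,
            noise_sd=0.0,
            gain_sd=0.0,
            latent_coeffs={"a_dm": 1.0, "a_da": 0.0, "b_dm": 0.0, "b_da": 0.0},
            seed=4,
        )
        ts, _ = generate_cohort_timeseries(spec, parc_small)
        a = ts[0].data[parc_small.indices_of_subnetwork("A")].mean(axis=0)
        dm = ts[0].data[parc_small.indices_of_system("default-mode")].mean(axis=0)
        assert abs(np.corrcoef(a, dm)[0, 1] - 1.0) < 1e-12

    def test_infeasible_targets_rejected(self, parc_small):
        spec = CohortSpec(
            coupling_targets={"a_dm": 0.9, "b_dm": -0.9, "a_da": -0.9, "b_da": 0.9},
            n_subjects=2,
            n_timepoints=50,
        )
        with pytest.raises(ValueError, match="infeasible"):
            generate_cohort_timeseries(spec, parc_small)

    @pytest.mark.slow
    def test_cohort_average_couplings_hit_targets(self, parc400):
        spec = CohortSpec(seed=3)
        ts, _ = generate_cohort_timeseries(spec, parc400)
        acc = {k: 0.0 for k in ("a_dm", "b_dm", "a_da", "b_da")}
        for t in ts:
            net = cn.compute_functional_network(t)
            acc["a_dm"] += cn.subnetwork_system_coupling(net, parc400, "A", "default-mode")
            acc["b_dm"] += cn.subnetwork_system_coupling(net, parc400, "B", "default-mode")
            acc["a_da"] += cn.subnetwork_system_coupling(net, parc400, "A", "dorsal-attention")
            acc["b_da"] += cn.subnetwork_system_coupling(net, parc400, "B", "dorsal-attention")
        n = len(ts)
        for key, target in spec.coupling_targets.items():
            assert abs(acc[key] / n - target) < 0.02, key


class TestStructural:
    def test_block_means_within_5pct(self, parc400):
        spec = CohortSpec(n_subjects=1, seed=7)
        mat = generate_structural_network(spec, parc400)[0]
        groups = {
            "a_dm": (parc400.indices_of_subnetwork("A"), parc400.indices_of_system("default-mode")),
            "b_dm": (parc400.indices_of_subnetwork("B"), parc400.indices_of_system("default-mode")),
            "a_da": (parc400.indices_of_subnetwork("A"), parc400.indices_of_system("dorsal-attention")),
            "b_da": (parc400.indices_of_subnetwork("B"), parc400.indices_of_system("dorsal-attention")),
        }
        for key, (rows, cols) in groups.items():
            target = spec.structural_motif_means[key]
            observed = mat[np.ix_(rows, cols)].mean()
            assert abs(observed - target) / target < 0.05, key

    def test_symmetric_nonnegative_zero_diagonal(self, parc_small):
        spec = CohortSpec(n_subjects=2, seed=1)
        for mat in generate_structural_network(spec, parc_small):
            assert np.allclose(mat, mat.T)
            assert (mat >= 0).all()
            assert np.diag(mat).sum() == 0

    def test_equal_motif_means_exchangeable(self, parc_small):
        spec = CohortSpec(
            n_subjects=4,
            structural_motif_means={"a_dm": 0.3, "b_dm": 0.3, "a_da": 0.3, "b_da": 0.3},
            seed=11,
        )
        mats = generate_structural_network(spec, parc_small)
        ga = parc_small.indices_of_subnetwork("A")
        gb = parc_small.indices_of_subnetwork("B")
        gdm = parc_small.indices_of_system("default-mode")
        diffs = [
            m[np.ix_(ga, gdm)].mean() - m[np.ix_(gb, gdm)].mean() for m in mats
        ]
        assert abs(np.mean(diffs)) < 0.1

    def test_all_zero_means_give_zero_matrix(self, parc_small):
        spec = CohortSpec(
            n_subjects=1,
            structural_motif_means={"a_dm": 0, "b_dm": 0, "a_da": 0, "b_da": 0},
            structural_background_mean=0.0,
            seed=2,
        )
        mat = generate_structural_network(spec, parc_small)[0]
        assert not mat.any()


class TestGeneExpression:
    def _labels(self, parc):
        return np.array(
            [s if s is not None else "" for s in parc.subnetworks], dtype=object
        )

    def test_zero_margin_ratio_near_one(self, parc_small):
        ratios = []
        for seed in range(8):
            spec = CohortSpec(coexpr_margin=0.0, seed=100 + seed)
            tab = generate_gene_expression(spec, parc_small, n_genes=150, probes_per_gene=1)
            expr = cx.aggregate_probes(tab)
            co = cx.coexpression_matrix(expr)
            labels = self._labels(parc_small)[np.isin(expr.parcel_ids, parc_small.region_ids)]
            mask_a = labels == "A"
            mask_b = labels == "B"
            wa = co[np.ix_(mask_a, mask_a)]
            within = (wa.sum() - np.trace(wa)) / (mask_a.sum() * (mask_a.sum() - 1))
            between = co[np.ix_(mask_a, mask_b)].mean()
            ratios.append(within / between)
        assert abs(np.mean(ratios) - 1.0) < 0.1

    def test_large_margin_ratio_above_one(self, parc_small):
        # planted-effect check across seeds: ratio > 1 essentially always
        for seed in range(25):
            spec = CohortSpec(
                coexpr_margin=0.4, coexpr_baseline=0.3, probe_noise_sd=0.1,
                seed=200 + seed,
            )
            tab = generate_gene_expression(spec, parc_small, n_genes=200, probes_per_gene=1)
            expr = cx.aggregate_probes(tab)
            co = cx.coexpression_matrix(expr)
            labels = self._labels(parc_small)
            mask_a = labels == "A"
            mask_b = labels == "B"
            wa = co[np.ix_(mask_a, mask_a)]
            within = (wa.sum() - np.trace(wa)) / (mask_a.sum() * (mask_a.sum() - 1))
            between = co[np.ix_(mask_a, mask_b)].mean()
            assert within / between > 1.0

    def test_invalid_probe_count_rejected(self, parc_small):
        with pytest.raises(ValueError, match="probes_per_gene"):
            generate_gene_expression(CohortSpec(), parc_small, 10, 0)

    @pytest.mark.slow
    def test_paper_scale_shape(self):
        # 338 labeled parcels x 16,699 genes after aggregation
        parc = default_parcellation(
            system_sizes={
                "visual": 50, "somatomotor": 50, "dorsal-attention": 44,
                "ventral-attention": 30, "limbic": 20, "frontoparietal": 61,
                "default-mode": 63, "temporoparietal": 20,
            }
        )
        assert parc.n_regions == 338
        spec = CohortSpec(seed=1)
        tab = generate_gene_expression(spec, parc, n_genes=16699, probes_per_gene=1)
        expr = cx.aggregate_probes(tab)
        assert expr.values.shape == (338, 16699)


class TestBehavior:
    def test_constant_when_no_effects(self):
        spec = CohortSpec(
            behavior_effects={
                "intercept": 0.5, "beta_a": 0, "beta_b": 0, "beta_fc": 0,
                "subject_sd": 0, "noise_sd": 0,
            }
        )
        fc = pd.DataFrame({"subject": [0, 0, 1, 1], "run": [0, 1, 0, 1], "fc": [0.1, 0.2, 0.0, -0.1]})
        beh = generate_behavior([1.0, 1.0], [1.0, 1.0], fc, spec)
        assert (beh["score"] == 0.5).all()

    def test_fc_effect_sign(self, rng):
        spec = CohortSpec(
            behavior_effects={
                "intercept": 0.5, "beta_a": 0, "beta_b": 0, "beta_fc": 1.0,
                "subject_sd": 0, "noise_sd": 1e-9,
            }
        )
        n = 40
        fc = pd.DataFrame(
            {"subject": np.repeat(np.arange(n // 2), 2),
             "run": np.tile([0, 1], n // 2),
             "fc": rng.normal(0, 0.1, n)}
        )
        beh = generate_behavior(np.ones(n // 2), np.ones(n // 2), fc, spec)
        assert np.corrcoef(beh["score"], fc["fc"])[0, 1] < -0.99

    def test_length_mismatch_rejected(self):
        fc = pd.DataFrame({"subject": [0], "run": [0], "fc": [0.1]})
        with pytest.raises(ValueError):
            generate_behavior([1.0], [1.0, 2.0], fc, CohortSpec())


class TestSerialization:
    def test_write_cohort_roundtrip(self, tmp_path, parc_small):
        spec = CohortSpec(n_subjects=2, n_timepoints=30, seed=3)
        ts, _ = generate_cohort_timeseries(spec, parc_small)
        out = write_cohort(tmp_path / "cohort", parc_small, ts, spec=spec)
        back = read_timeseries(out / "timeseries" / "sub-000_run-0.tsv")
        assert np.array_equal(back, ts[0].data)
        assert (out / "manifest.json").exists()
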