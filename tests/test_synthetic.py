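"""Synthetic cohort generator: determinism, feasibility and recovery."""

import logging

import numpy as np
import pytest

from glioconn import SimulationConfig, simulate_cohort
from glioconn.connectome import (control_edge_mask, edge_weight_matrix,
                                 fa_connectivity, fc_matrix, restrict)
from glioconn.parcellation import compartment_codes, make_atlas
from glioconn.summarize import hemispheric_means
from glioconn.synthetic import (SimulationError, _CODE_BY_COMPARTMENT,
                                _expected_compartment_ew, build_template,
                                sample_counts, sample_fa_edges,
                                sample_timeseries)


class TestConfig:
    def test_default_group_sizes_match_study(self):
        cfg = SimulationConfig()
        assert cfg.group_sizes == {"control": 27, "IDHmut": 15, "IDHwt": 14}
        assert cfg.n_regions == 246 and cfg.n_timepoints == 300

    def test_infeasible_fa_effect_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(delta_fa_ipsi_idhwt=-0.5)

    def test_tiny_groups_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(group_sizes={"control": 3, "IDHmut": 15,
                                          "IDHwt": 14})

    def test_null_variant_removes_effects_and_equalizes_loadings(self):
        cfg = SimulationConfig.reduced().null_variant()
        assert cfg.delta_ew_inter_patients == 0.0
        assert cfg.delta_fa_ipsi_idhwt == 0.0
        loadings = {frozenset(v.items()) for v in cfg.loadings.values()}
        assert len(loadings) == 1


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig.reduced()
        a = simulate_cohort(cfg, 42)
        b = simulate_cohort(cfg, 42)
        for x, y in zip(a.bundles, b.bundles):
            assert x.record == y.record
            np.testing.assert_array_equal(x.counts.counts, y.counts.counts)
            np.testing.assert_array_equal(x.fa.fa, y.fa.fa)
            np.testing.assert_array_equal(x.timeseries.values,
                                          y.timeseries.values)

    def test_different_seed_differs(self):
        cfg = SimulationConfig.reduced()
        a = simulate_cohort(cfg, 1)
        b = simulate_cohort(cfg, 2)
        assert not np.array_equal(a.bundles[0].counts.counts,
                                  b.bundles[0].counts.counts)


class TestCohortComposition:
    def test_group_sizes_and_metadata(self, reduced_cohort):
        records = reduced_cohort.records
        groups = [r.group for r in records]
        assert groups.count("control") == 27
        assert groups.count("IDHmut") == 15
        assert groups.count("IDHwt") == 14
        for r in records:
            assert 18 <= r.age < 80
            assert (r.lesion_hemisphere == "none") == (r.group == "control")

    def test_bundle_invariants_hold(self, reduced_cohort):
        for b in reduced_cohort.bundles[:5]:
            off = ~np.eye(b.counts.n_regions, dtype=bool)
            support = b.counts.counts > 0
            defined = ~np.isnan(b.fa.fa)
            np.testing.assert_array_equal(defined[off], support[off])
            fc = fc_matrix(b.timeseries)
            assert fc.n_regions == reduced_cohort.config.n_regions


class TestMaskRetention:
    def test_control_mask_retains_template_edges(self):
        cfg = SimulationConfig.reduced()
        for seed in range(3):
            cohort = simulate_cohort(cfg, 100 + seed)
            controls = [b.counts for b in cohort.bundles
                        if b.record.group == "control"]
            mask = control_edge_mask(controls)
            template_edges = len(cohort.template.edge_i)
            assert mask.n_edges >= 0.95 * template_edges
            # the diffuse background field must not leak into the mask
            assert mask.n_edges <= 1.02 * template_edges


class TestTargetRecovery:
    def test_pipeline_recovers_compartment_targets(self, reduced_cohort):
        cohort = reduced_cohort
        controls = [b.counts for b in cohort.bundles
                    if b.record.group == "control"]
        mask = control_edge_mask(controls)
        deviations = {m: [] for m in ("EW", "FA", "FC")}
        for b in cohort.bundles:
            mats = {"EW": edge_weight_matrix(b.counts),
                    "FA": fa_connectivity(b.fa, b.counts),
                    "FC": fc_matrix(b.timeseries)}
            for m, mat in mats.items():
                hm = hemispheric_means(restrict(mat, mask), mask,
                                       cohort.atlas)
                for comp, value in (("left", hm.left), ("right", hm.right),
                                    ("inter", hm.inter)):
                    deviations[m].append(value - b.targets[(m, comp)])
        n = len(cohort.bundles) * 3
        for m, tol in (("EW", 0.004), ("FA", 0.01), ("FC", 0.05)):
            dev = np.asarray(deviations[m])
            # unbiased realization: mean deviation within 3 SE of zero
            assert abs(dev.mean()) < max(3 * dev.std() / np.sqrt(n), 1e-4)
            assert np.abs(dev).mean() < tol

    def test_expected_ew_scale_invariance(self):
        cfg = SimulationConfig.reduced()
        tpl = build_template(cfg, np.random.default_rng(0))
        scales = dict(tpl.baseline_solution)
        bg = scales.pop("background")
        doubled = type(tpl)(tpl.n_regions, tpl.edge_i, tpl.edge_j,
                            tpl.edge_rate * 2.0, tpl.edge_comp,
                            tpl.baseline_solution)
        a = _expected_compartment_ew(tpl, scales, bg)
        b = _expected_compartment_ew(doubled, scales, bg * 2.0)
        for comp in a:
            assert b[comp] == pytest.approx(a[comp], rel=1e-12)


class TestSampleCounts:
    def test_zero_inter_target_gives_zero_inter_counts(self):
        cfg = SimulationConfig.reduced()
        tpl = build_template(cfg, np.random.default_rng(0))
        counts = sample_counts({"left": 0.12, "right": 0.12, "inter": 0.0},
                               tpl, np.random.default_rng(1))
        inter = tpl.edge_comp == _CODE_BY_COMPARTMENT["inter"]
        assert counts.counts[tpl.edge_i[inter], tpl.edge_j[inter]].sum() == 0

    def test_infeasible_target_raises(self):
        cfg = SimulationConfig.reduced()
        tpl = build_template(cfg, np.random.default_rng(0))
        with pytest.raises(SimulationError):
            sample_counts({"left": 0.9, "right": 0.9, "inter": 0.4},
                          tpl, np.random.default_rng(1))


class TestSampleFaEdges:
    def test_noiseless_edges_equal_compartment_targets(self):
        cfg = SimulationConfig.reduced()
        tpl = build_template(cfg, np.random.default_rng(0))
        counts = sample_counts({"left": 0.12, "right": 0.12, "inter": 0.04},
                               tpl, np.random.default_rng(1))
        codes = compartment_codes(make_atlas(cfg.n_regions))
        fa = sample_fa_edges(counts, {"left": 0.4, "right": 0.5,
                                      "inter": 0.45},
                             0.0, codes, np.random.default_rng(2))
        left = tpl.edge_comp == _CODE_BY_COMPARTMENT["left"]
        vals = fa.fa[tpl.edge_i[left], tpl.edge_j[left]]
        np.testing.assert_allclose(vals, 0.4)

    def test_missing_exactly_where_counts_zero(self):
        cfg = SimulationConfig.reduced()
        tpl = build_template(cfg, np.random.default_rng(3))
        counts = sample_counts({"left": 0.12, "right": 0.12, "inter": 0.04},
                               tpl, np.random.default_rng(4))
        codes = compartment_codes(make_atlas(cfg.n_regions))
        fa = sample_fa_edges(counts, {"left": 0.4, "right": 0.5,
                                      "inter": 0.45},
                             0.05, codes, np.random.default_rng(5))
        off = ~np.eye(cfg.n_regions, dtype=bool)
        np.testing.assert_array_equal(~np.isnan(fa.fa)[off],
                                      (counts.counts > 0)[off])

    def test_out_of_unit_interval_target_rejected(self):
        cfg = SimulationConfig.reduced()
        tpl = build_template(cfg, np.random.default_rng(0))
        counts = sample_counts({"left": 0.12, "right": 0.12, "inter": 0.04},
                               tpl, np.random.default_rng(1))
        codes = compartment_codes(make_atlas(cfg.n_regions))
        with pytest.raises(SimulationError):
            sample_fa_edges(counts, {"left": 1.2, "right": 0.5,
                                     "inter": 0.45},
                            0.05, codes, np.random.default_rng(2))


class TestSampleTimeseries:
    IS_LEFT = np.arange(40) % 2 == 0

    def test_zero_targets_give_identity_correlation(self):
        ts = sample_timeseries({"left": 0.0, "right": 0.0, "inter": 0.0},
                               3000, self.IS_LEFT, np.random.default_rng(0))
        corr = np.corrcoef(ts.values, rowvar=False)
        off = ~np.eye(40, dtype=bool)
        assert np.abs(corr[off]).max() < 0.1

    def test_block_means_match_targets(self):
        targets = {"left": 0.4, "right": 0.3, "inter": 0.2}
        zs = []
        for seed in range(10):
            ts = sample_timeseries(targets, 300, self.IS_LEFT,
                                   np.random.default_rng(seed))
            z = np.arctanh(np.clip(np.corrcoef(ts.values, rowvar=False),
                                   -1 + 1e-12, 1 - 1e-12))
            left = self.IS_LEFT
            iu = np.triu_indices(40, k=1)
            mask_ll = left[iu[0]] & left[iu[1]]
            mask_rr = ~left[iu[0]] & ~left[iu[1]]
            mask_lr = left[iu[0]] != left[iu[1]]
            zs.append([z[iu][mask_ll].mean(), z[iu][mask_rr].mean(),
                       z[iu][mask_lr].mean()])
        means = np.asarray(zs).mean(axis=0)
        ses = np.asarray(zs).std(axis=0, ddof=1) / np.sqrt(10)
        for got, want, se in zip(means, [0.4, 0.3, 0.2], ses):
            assert abs(got - want) < max(3 * se, 0.01)

    def test_infeasible_block_structure_repaired_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            sample_timeseries({"left": 0.1, "right": 0.1, "inter": 0.5},
                              100, self.IS_LEFT, np.random.default_rng(0))
        assert any("feasible" in r.message for r in caplog.records)

    def test_same_seed_identical(self):
        targets = {"left": 0.3, "right": 0.3, "inter": 0.2}
        a = sample_timeseries(targets, 50, self.IS_LEFT,
                              np.random.default_rng(9))
        b = sample_timeseries(targets, 50, self.IS_LEFT,
                              np.random.default_rng(9))
        np.testing.assert_array_equal(a.values, b.values)


class TestGroundTruthEffects:
    def test_planted_effects_appear_in_targets(self, reduced_cohort):
        cfg = reduced_cohort.config
        by_group = {}
        for b in reduced_cohort.bundles:
            ipsi = (b.record.lesion_hemisphere
                    if b.record.group != "control" else None)
            fa_ipsi = (b.targets[("FA", ipsi)] if ipsi
                       else (b.targets[("FA", "left")]
                             + b.targets[("FA", "right")]) / 2)
            by_group.setdefault(b.record.group, []).append(
                (b.targets[("EW", "inter")], fa_ipsi))
        means = {g: np.mean(v, axis=0) for g, v in by_group.items()}
        assert means["IDHmut"][0] < means["control"][0]
        assert means["IDHwt"][0] < means["control"][0]
        assert means["IDHwt"][1] < means["control"][1] + \
            cfg.delta_fa_ipsi_idhwt / 2
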