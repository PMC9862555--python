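"""Gating cascade: bead anchor, corner exclusion, tail gate, singlets repair."""

import numpy as np
import pytest
from scipy.stats import chi2

from sputumflow.gating import (BeadQCError, GateConfig, SingletsGateError,
                               bse_gate, core_viable_gate,
                               exclude_corner_artifacts, find_bead_threshold,
                               fit_singlets_polygon, polygon_mask, rle_decode,
                               run_gating, viability_threshold)
from sputumflow.gating import _rle_encode
from sputumflow.synthetic import generate_sample
from sputumflow.transforms import logicle_table
from sputumflow.channels import channel_map

from conftest import LIVE_POPS, gate_sample, table_from_roles


CFG = GateConfig(seed=1)


def _bead_table(n_cluster=9000, n_noise=1000, mean=3.0e4, sd=2.0e3, seed=0):
    rng = np.random.default_rng(seed)
    fsc = np.concatenate([rng.normal(mean, sd, n_cluster),
                          rng.uniform(0, 2.6e5, n_noise)])
    ssc = np.concatenate([rng.normal(1.5e4, 1.5e3, n_cluster),
                          rng.uniform(0, 2.6e5, n_noise)])
    return table_from_roles({"FSC-A": fsc, "SSC-A": ssc})


class TestBeadThreshold:
    def test_dominant_gaussian_cluster_lower_contour(self):
        fsc_min = find_bead_threshold(_bead_table(), CFG)
        c = np.sqrt(chi2.ppf(CFG.bead_contour_quantile, 2))
        assert fsc_min == pytest.approx(3.0e4 - c * 2.0e3, abs=1.5e3)

    def test_tight_cluster_zero_noise_degenerate(self):
        t = _bead_table(n_cluster=5000, n_noise=0, sd=10.0)
        fsc_min = find_bead_threshold(t, CFG)
        assert abs(fsc_min - 3.0e4) < 200.0

    def test_uniform_noise_only_fails_bead_qc(self):
        t = _bead_table(n_cluster=0, n_noise=5000)
        with pytest.raises(BeadQCError, match="bead tube QC failure"):
            find_bead_threshold(t, CFG)


class TestBseGate:
    def test_boundary_conventions_closed_on_kept_side(self):
        t = table_from_roles({
            "FSC-A": np.array([CFG.bse_upper, 1.0e4, 5.0e4, 2.6e5]),
            "SSC-A": np.array([0.0, 1.0e3, 1.0e3, 1.0e3]),
        })
        mask = bse_gate(t, fsc_min=2.0e4, cfg=CFG)
        # upper bound kept, below fsc_min excluded, in-range kept, above excluded
        np.testing.assert_array_equal(mask, [True, False, True, False])

    def test_planted_mixture_kept_fraction(self):
        rng = np.random.default_rng(3)
        n = 10_000
        inside = rng.uniform(3.0e4, 2.0e5, (int(n * 0.7), 2))
        outside = rng.uniform(0, 1.9e4, (n - inside.shape[0], 2))
        pts = np.vstack([inside, outside])
        t = table_from_roles({"FSC-A": pts[:, 0], "SSC-A": pts[:, 1]})
        mask = bse_gate(t, fsc_min=2.0e4, cfg=CFG)
        assert mask.mean() == pytest.approx(0.7, abs=0.02)


class TestCornerArtifacts:
    def test_no_corner_population_leaves_mask_unchanged(self, gated_healthy):
        tube, result = gated_healthy
        bse = result.masks["bead_size_exclusion"]
        out = exclude_corner_artifacts(tube, bse, CFG)
        np.testing.assert_array_equal(out, bse)

    def test_planted_corner_population_removed(self):
        s = generate_sample("non-cancer", n_events=30_000, seed=5,
                            corner_fraction=0.05)
        tube, _ = gate_sample(s)
        fsc_min = find_bead_threshold(s.tubes["beads"], CFG)
        bse = bse_gate(tube, fsc_min, CFG)
        nd = exclude_corner_artifacts(tube, bse, CFG)
        corner = s.truth_mask("blood", "corner_artifact")
        removed = bse & ~nd
        assert (removed & corner).sum() / (bse & corner).sum() >= 0.95
        assert (removed & ~corner).sum() / (bse & ~corner).sum() <= 0.01

    def test_corner_only_degenerate_removes_all_with_warning(self):
        rng = np.random.default_rng(0)
        n = 3000
        t = table_from_roles({
            "FSC-H": rng.normal(2.1e5, 5e3, n),
            "SSC-H": np.abs(rng.normal(150.0, 40.0, n)),
        })
        with pytest.warns(UserWarning, match="every event"):
            out = exclude_corner_artifacts(t, np.ones(n, bool), CFG)
        assert out.sum() == 0


class TestCoreViableGate:
    def _two_component(self, low_frac=0.6, n=20_000, seed=0):
        rng = np.random.default_rng(seed)
        n_low = int(n * low_frac)
        low = np.column_stack([rng.normal(5e4, 5e3, n_low),
                               rng.normal(1.5e4, 2e3, n_low)])
        high = np.column_stack([rng.normal(8e4, 8e3, n - n_low),
                                rng.normal(9e4, 8e3, n - n_low)])
        pts = np.vstack([low, high])
        t = table_from_roles({"FSC-H": pts[:, 0], "SSC-H": pts[:, 1]})
        labels = np.array([True] * n_low + [False] * (n - n_low))
        return t, labels

    def test_low_scatter_component_captured(self):
        t, low = self._two_component()
        mask, tags = core_viable_gate(t, np.ones(len(low), bool), CFG)
        assert tags == []
        assert (mask & low).sum() / low.sum() >= 0.9 * CFG.core_quantile
        assert (mask & ~low).sum() / (~low).sum() < 0.10

    def test_small_low_component_triggers_fallback_quantile(self):
        t, low = self._two_component(low_frac=0.08)
        mask, tags = core_viable_gate(t, np.ones(len(low), bool), CFG)
        assert "core_quantile_fallback" in tags

    def test_single_homogeneous_population_captures_core_quantile(self):
        rng = np.random.default_rng(4)
        n = 20_000
        t = table_from_roles({"FSC-H": rng.normal(5e4, 5e3, n),
                              "SSC-H": rng.normal(2e4, 3e3, n)})
        mask, _ = core_viable_gate(t, np.ones(n, bool), CFG)
        assert mask.mean() == pytest.approx(CFG.core_quantile, abs=0.05)


class TestViabilityTailGate:
    def _unimodal(self, m=1.0, s=0.3, n=20_000, seed=0):
        rng = np.random.default_rng(seed)
        return table_from_roles({"FVS510": rng.normal(m, s, n)})

    def test_gaussian_tail_matches_closed_form(self):
        # density falls to 10% of the peak at m + s*sqrt(2 ln 10) = m + 2.146 s
        m, s = 1.0, 0.3
        t = self._unimodal(m, s)
        thr = viability_threshold(t, np.ones(t.n_events, bool), CFG)
        assert thr == pytest.approx(m + s * np.sqrt(2 * np.log(10)), abs=0.05)

    def test_bimodal_live_dead_threshold_between_modes(self):
        rng = np.random.default_rng(1)
        live = rng.normal(0.8, 0.2, 15_000)
        dead = rng.normal(3.6, 0.2, 5_000)
        t = table_from_roles({"FVS510": np.concatenate([live, dead])})
        thr = viability_threshold(t, np.ones(t.n_events, bool), CFG)
        assert 1.2 < thr < 3.0
        assert (live < thr).mean() >= 0.99

    def test_tolerance_one_returns_the_mode(self):
        t = self._unimodal()
        cfg = GateConfig(tail_tolerance=1.0, seed=1)
        thr = viability_threshold(t, np.ones(t.n_events, bool), cfg)
        assert thr == pytest.approx(1.0, abs=0.05)

    def test_threshold_nonincreasing_in_tolerance(self):
        # the tail criterion is met earlier as the tolerance rises
        t = self._unimodal()
        tols = [0.05, 0.10, 0.25, 0.5, 1.0]
        thrs = [viability_threshold(t, np.ones(t.n_events, bool),
                                    GateConfig(tail_tolerance=tol, seed=1))
                for tol in tols]
        assert all(a >= b - 1e-9 for a, b in zip(thrs, thrs[1:]))

    def test_degenerate_signal_is_an_error(self):
        t = table_from_roles({"FVS510": np.full(500, 1.5)})
        with pytest.raises(Exception, match="degenerate"):
            viability_threshold(t, np.ones(500, bool), CFG)


class TestSingletsPolygon:
    def test_planted_ridge_recovery_against_doublets(self, gated_replicates):
        sample, tube, result = gated_replicates[0]
        viable = result.masks["viable"]
        poly, tags = fit_singlets_polygon(tube, viable, CFG)
        inside = polygon_mask(tube, poly, viable, CFG.singlet_channels)
        live = sample.truth_mask("blood", *LIVE_POPS)
        doublets = sample.truth_mask("blood", "doublet")
        assert (inside & live).sum() / (viable & live).sum() >= 0.95
        assert (inside & doublets).sum() / max((viable & doublets).sum(), 1) <= 0.10

    def test_high_ssc_contaminant_triggers_repair(self):
        s = generate_sample("non-cancer", n_events=30_000, seed=9,
                            ssc_contaminant_fraction=0.12)
        tube, result = gate_sample(s, seed=1)
        assert "ssc_temp_gate" in result.heuristics_applied
        assert result.singlets_polygon[0][1] >= 0.0  # repaired lower-left

    def test_contaminant_free_sample_has_no_repair_tags(self, gated_healthy):
        _, result = gated_healthy
        assert "ssc_temp_gate" not in result.heuristics_applied
        assert "viability_reset" not in result.heuristics_applied

    def test_too_few_viable_events_fail(self):
        t = table_from_roles({"FSC-A": np.ones(50), "FSC-W": np.ones(50),
                              "SSC-A": np.ones(50)})
        with pytest.raises(SingletsGateError):
            fit_singlets_polygon(t, np.ones(50, bool), CFG)


class TestRefineViability:
    def test_intermediate_population_resets_threshold(self):
        s = generate_sample("non-cancer", n_events=30_000, seed=13,
                            intermediate_viability_fraction=0.18)
        _, result = gate_sample(s, seed=1)
        assert "viability_reset" in result.heuristics_applied
        assert result.viability_threshold == pytest.approx(
            CFG.viability_natural_cutoff)

    def test_small_intermediate_population_leaves_threshold(self):
        s = generate_sample("non-cancer", n_events=30_000, seed=13,
                            intermediate_viability_fraction=0.03)
        _, result = gate_sample(s, seed=1)
        assert "viability_reset" not in result.heuristics_applied


class TestRunGating:
    def test_nesting_invariants_on_seeded_replicates(self, gated_replicates):
        for _, _, result in gated_replicates:
            result.assert_nested()
            counts = result.counts
            assert counts["viable_singlets"] <= counts["viable"] \
                <= counts["non_debris"] <= counts["bead_size_exclusion"]

    def test_enough_planted_live_singlets_yield_enough_viable_singlets(
            self, gated_replicates):
        for sample, _, result in gated_replicates:
            planted = sample.truth_mask("blood", *LIVE_POPS).sum()
            if planted >= 15_000:
                assert result.counts["viable_singlets"] >= 10_000

    def test_planted_population_recovery(self, gated_replicates):
        recalls, leaks = [], []
        for sample, _, result in gated_replicates:
            vs = result.masks["viable_singlets"]
            live = sample.truth_mask("blood", *LIVE_POPS)
            dead = sample.truth_mask("blood", "dead")
            recalls.append((vs & live).sum() / live.sum())
            leaks.append((vs & dead).sum() / dead.sum())
        assert min(recalls) >= 0.9
        assert max(leaks) <= 0.05

    def test_dead_only_sample_has_no_viable_singlets(self):
        from sputumflow.synthetic import default_populations
        pops = [p for p in default_populations("non-cancer")
                if p.name in ("debris", "dead")]
        total = sum(p.fraction for p in pops)
        for p in pops:
            p.fraction /= total
        s = generate_sample("non-cancer", n_events=20_000, seed=3,
                            populations=pops, doublet_fraction=0.0)
        from sputumflow.gating import GatingError
        try:
            _, result = gate_sample(s)
        except GatingError:
            return  # an explicit gating failure is an equally valid outcome
        assert result.counts["viable_singlets"] < 1_000

    def test_determinism_with_fixed_seed(self, healthy_sample):
        _, r1 = gate_sample(healthy_sample, seed=5)
        _, r2 = gate_sample(healthy_sample, seed=5)
        assert r1.viability_threshold == r2.viability_threshold
        assert r1.fsc_min == r2.fsc_min
        np.testing.assert_array_equal(r1.singlets_polygon, r2.singlets_polygon)
        for key in r1.masks:
            np.testing.assert_array_equal(r1.masks[key], r2.masks[key])
        assert r1.heuristics_applied == r2.heuristics_applied


def test_rle_roundtrip_and_result_serialization(gated_healthy):
    _, result = gated_healthy
    doc = result.to_dict()
    n = len(result.masks["viable"])
    for key, runs in doc["masks_rle"].items():
        np.testing.assert_array_equal(rle_decode(runs, n), result.masks[key])
    rng = np.random.default_rng(0)
    for _ in range(20):
        m = rng.random(rng.integers(1, 50)) < 0.4
        np.testing.assert_array_equal(rle_decode(_rle_encode(m), m.size), m)
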