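import numpy as np
import pytest

from ahpkit.concordance import PriorityProfile, concordance_matrix
from ahpkit.elicitation import DEFAULT_SCALE, build_judgment_matrix, build_schedule
from ahpkit.pipeline import run_study
from ahpkit.priorities import consistency_report, principal_priorities
from ahpkit.simulate import (
    SimulationConfig,
    judgments_from_profile,
    recovery_report,
    responses_from_matrix,
    sample_latent_profile,
    simulate_study,
)

GRID = {1 / 5, 1 / 4, 1 / 3, 1 / 2, 1.0, 2.0, 3.0, 4.0, 5.0}


class TestLatentProfiles:
    def test_simplexes_sum_to_one(self, ct_hierarchy):
        cfg = SimulationConfig(hierarchy=ct_hierarchy, seed=3)
        p = sample_latent_profile(cfg, 0)
        assert sum(p.category_weights.values()) == pytest.approx(1, abs=1e-12)
        for lw in p.local_weights.values():
            assert sum(lw.values()) == pytest.approx(1, abs=1e-12)
        assert sum(p.global_weights.values()) == pytest.approx(1, abs=1e-12)

    def test_seed_determinism(self, ct_hierarchy):
        cfg = SimulationConfig(hierarchy=ct_hierarchy, seed=5)
        a = sample_latent_profile(cfg, 2)
        b = sample_latent_profile(cfg, 2)
        assert a == b
        c = sample_latent_profile(cfg, 3)
        assert a.category_weights != c.category_weights

    def test_large_concentration_flattens(self, tiny_hierarchy):
        """At high concentration the simplex piles up near uniform: the mean
        max category weight approaches 1/n."""
        cfg = SimulationConfig(hierarchy=tiny_hierarchy, seed=8,
                               concentration=500.0)
        maxima = [max(sample_latent_profile(cfg, i).category_weights.values())
                  for i in range(500)]
        assert np.mean(maxima) == pytest.approx(0.5, abs=0.02)  # n = 2 cats

    def test_config_validation(self, tiny_hierarchy):
        with pytest.raises(ValueError, match="sigma"):
            SimulationConfig(hierarchy=tiny_hierarchy, noise=-0.1)
        with pytest.raises(ValueError, match="concentration"):
            SimulationConfig(hierarchy=tiny_hierarchy, concentration=0)


class TestJudgments:
    def test_noiseless_unquantized_is_transitive(self, ct_hierarchy):
        cfg = SimulationConfig(hierarchy=ct_hierarchy, seed=1)
        p = sample_latent_profile(cfg, 0)
        m = judgments_from_profile(p, ct_hierarchy, "performance",
                                   sigma=0.0, quantize=False)
        assert consistency_report(m).cr == pytest.approx(0, abs=1e-12)
        w = p.local_weights["performance"]
        rec = principal_priorities(m).as_dict()
        for need in w:
            assert rec[need] == pytest.approx(w[need], abs=1e-10)

    def test_quantized_entries_on_grid_and_order_preserved(self, tiny_hierarchy):
        from ahpkit.hierarchy import load_hierarchy
        h = load_hierarchy({
            "goal": {"id": "g"},
            "categories": [{"id": "c", "children": [
                {"id": "x"}, {"id": "y"}, {"id": "z"}]}],
        })
        from ahpkit.simulate import LatentProfile
        p = LatentProfile("r", {"c": 1.0},
                          {"c": {"x": 0.6, "y": 0.3, "z": 0.1}})
        m = judgments_from_profile(p, h, "c", sigma=0.0, quantize=True)
        upper = m.values[np.triu_indices(3, 1)]
        assert all(any(abs(v - g) < 1e-12 for g in GRID) for v in upper)
        rec = principal_priorities(m).as_dict()
        assert rec["x"] > rec["y"] > rec["z"]

    def test_reciprocity_always_exact(self, ct_hierarchy):
        cfg = SimulationConfig(hierarchy=ct_hierarchy, seed=2)
        p = sample_latent_profile(cfg, 0)
        rng = np.random.default_rng(0)
        for sigma in (0.0, 0.4, 1.5):
            for quant in (True, False):
                m = judgments_from_profile(p, ct_hierarchy, "safety",
                                           sigma=sigma, quantize=quant, rng=rng)
                a = m.values
                # lower triangle is the bitwise float reciprocal of the upper
                iu = np.triu_indices(3, 1)
                assert np.array_equal(a[(iu[1], iu[0])], 1.0 / a[iu])
                if quant:  # grid ratios multiply out to exactly 1
                    assert np.array_equal(a * a.T, np.ones((3, 3)))
                else:
                    np.testing.assert_allclose(a * a.T, 1.0, rtol=1e-15)

    def test_mean_cr_increases_with_noise(self, ct_hierarchy):
        """Responder inconsistency (CR) grows monotonically with σ."""
        from ahpkit.hierarchy import load_hierarchy
        h4 = load_hierarchy({
            "goal": {"id": "g"},
            "categories": [{"id": "c", "children": [
                {"id": f"n{i}"} for i in range(4)]}],
        })
        means = []
        for sigma in (0.0, 0.3, 0.6):
            crs = []
            for rep in range(500):
                cfg = SimulationConfig(hierarchy=h4, seed=100 + rep,
                                       noise=sigma, quantize=True)
                p = sample_latent_profile(cfg, 0)
                rng = np.random.default_rng([100 + rep, 7])
                m = judgments_from_profile(p, h4, "c", sigma=sigma,
                                           quantize=True, rng=rng)
                crs.append(consistency_report(m).cr)
            means.append(float(np.mean(crs)))
        assert means[0] < means[1] < means[2]


class TestStudySimulation:
    def test_noiseless_end_to_end_identity(self, ct_hierarchy):
        """σ = 0 without quantization: the pipeline inverts exactly —
        recovered global weights equal the latent truth to 1e-8."""
        cfg = SimulationConfig(hierarchy=ct_hierarchy, n_responders=4,
                               noise=0.0, quantize=False, seed=11)
        study = simulate_study(cfg)
        report = run_study(ct_hierarchy, matrices=study.matrices)
        recs = recovery_report(
            study.profiles,
            [report.global_priorities[p.responder_id] for p in study.profiles])
        for r in recs:
            assert r.l1_distance < 1e-8
            assert r.spearman_rho == 1.0
            assert r.top_k_overlap == r.k

    def test_shared_profile_gives_unit_concordance(self, ct_hierarchy):
        cfg = SimulationConfig(hierarchy=ct_hierarchy, n_responders=1,
                               noise=0.0, quantize=False, seed=4)
        study = simulate_study(cfg)
        [prof] = study.profiles
        mats = study.matrices[prof.responder_id]
        report = run_study(ct_hierarchy, matrices={"r1": mats, "r2": dict(mats)})
        assert report.concordance_needs.rho[0, 1] == 1.0

    def test_quantized_responses_roundtrip_to_matrices(self, ct_hierarchy):
        """Grading a quantized matrix and re-building it is the identity."""
        cfg = SimulationConfig(hierarchy=ct_hierarchy, n_responders=2,
                               noise=0.25, quantize=True, seed=6)
        study = simulate_study(cfg)
        for rid, per_node in study.response_sets.items():
            for node_id, rs in per_node.items():
                sched_elements = study.matrices[rid][node_id].elements
                rebuilt = build_judgment_matrix(rs, sched_elements, DEFAULT_SCALE)
                np.testing.assert_array_equal(
                    rebuilt.values, study.matrices[rid][node_id].values)

    def test_moderate_noise_recovery(self, ct_hierarchy):
        """σ = 0.2 with quantization, 20 responders: median rank agreement
        between recovered and latent global weights stays at or above 0.9."""
        cfg = SimulationConfig(hierarchy=ct_hierarchy, n_responders=20,
                               noise=0.2, quantize=True, seed=17)
        study = simulate_study(cfg)
        report = run_study(ct_hierarchy, matrices=study.matrices,
                           include_inconsistent=True)
        recs = recovery_report(
            study.profiles,
            [report.global_priorities[p.responder_id] for p in study.profiles])
        assert float(np.median([r.spearman_rho for r in recs])) >= 0.9

    def test_recovery_degrades_with_noise(self, ct_hierarchy):
        """Mean L1 recovery error is non-decreasing across σ ∈ {0, .3, .6}."""
        means = []
        for sigma in (0.0, 0.3, 0.6):
            errs = []
            for rep in range(40):
                cfg = SimulationConfig(hierarchy=ct_hierarchy, n_responders=1,
                                       noise=sigma, quantize=True,
                                       seed=1000 + rep)
                study = simulate_study(cfg)
                report = run_study(ct_hierarchy, matrices=study.matrices,
                                   include_inconsistent=True)
                recs = recovery_report(study.profiles,
                                       list(report.global_priorities.values()))
                errs.append(recs[0].l1_distance)
            means.append(float(np.mean(errs)))
        assert means[0] <= means[1] <= means[2]

    def test_truth_payload_and_frame(self, tiny_hierarchy):
        cfg = SimulationConfig(hierarchy=tiny_hierarchy, n_responders=2,
                               noise=0.1, seed=9)
        study = simulate_study(cfg)
        df = study.responses_frame()
        # 3 comparison pairs in c1, 1 in c2, 1 at the goal, per responder
        assert len(df) == 2 * (3 + 1 + 1)
        payload = study.truth_payload()
        assert len(payload["profiles"]) == 2
        assert payload["seed"] == 9


class TestRecoveryReport:
    def test_identity(self, ct_hierarchy):
        cfg = SimulationConfig(hierarchy=ct_hierarchy, seed=2)
        p = sample_latent_profile(cfg, 0)
        from ahpkit.priorities import GlobalPriorities
        gp = GlobalPriorities(p.responder_id, p.category_weights,
                              {}, p.global_weights, {})
        [m] = recovery_report([p], [gp])
        assert m.l1_distance == 0.0
        assert m.spearman_rho == 1.0
        assert m.top_k_overlap == m.k

    def test_uniform_vs_concentrated_l1_closed_form(self, ct_hierarchy):
        from ahpkit.priorities import GlobalPriorities
        from ahpkit.simulate import LatentProfile
        h = ct_hierarchy
        n = len(h.need_ids)
        cfg = SimulationConfig(hierarchy=h, seed=31)
        truth = sample_latent_profile(cfg, 0)
        uniform = GlobalPriorities(
            truth.responder_id, {}, {},
            {need: 1 / n for need in h.need_ids}, {})
        [m] = recovery_report([truth], [uniform])
        expected = sum(abs(w - 1 / n) for w in truth.global_weights.values())
        assert m.l1_distance == pytest.approx(expected, abs=1e-12)

    def test_id_mismatch(self, ct_hierarchy):
        cfg = SimulationConfig(hierarchy=ct_hierarchy, seed=2)
        p = sample_latent_profile(cfg, 0)
        with pytest.raises(ValueError, match="no recovered weights"):
            recovery_report([p], [])
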