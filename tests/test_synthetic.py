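"""Generator contracts: template construction, run simulation, study coupling."""

import numpy as np
import pytest

from statedyn.core import MEDITATION
from statedyn.synthetic import (
    InfeasibleCorrelationPattern,
    RatingCoupling,
    SynthStudyParams,
    make_state_covariances,
    simulate_run,
    simulate_study,
    default_stage_plan,
    default_occupancy_schedule,
)

from conftest import small_params


class TestStateCovariances:
    def test_all_zero_offdiagonal_gives_identity(self):
        spec = [
            {"description": "ident", "baseline_r": 0.0, "blocks": []},
            {"description": "other", "baseline_r": 0.3, "blocks": []},
        ]
        templates = make_state_covariances(8, structure_spec=spec, separation_floor=0.5)
        assert np.allclose(templates[0].covariance, np.eye(8))

    def test_block_pattern_recovered_by_monte_carlo(self, rng):
        spec = [
            {
                "description": "one-block",
                "baseline_r": 0.0,
                "blocks": [{"nodes": list(range(10)), "within_r": 0.6, "to_rest_r": None}],
            },
            {"description": "flat", "baseline_r": 0.3, "blocks": []},
        ]
        tpl = make_state_covariances(20, structure_spec=spec, separation_floor=0.5)[0]
        L = np.linalg.cholesky(tpl.covariance)
        draws = rng.standard_normal((5000, 20)) @ L.T
        emp = np.corrcoef(draws, rowvar=False)
        block = emp[np.ix_(range(10), range(10))]
        off = block[np.triu_indices(10, k=1)]
        assert abs(off.mean() - 0.6) < 0.05

    def test_anticorrelated_block_mean_negative(self):
        templates = make_state_covariances(49)
        dmn = templates[0]
        block = list(range(10))
        rest = list(range(10, 49))
        cross = dmn.covariance[np.ix_(block, rest)]
        assert cross.mean() < 0

    def test_templates_unit_diagonal_and_pd(self):
        for tpl in make_state_covariances(49):
            vals = np.linalg.eigvalsh(tpl.covariance)
            assert vals.min() > 0
            assert np.allclose(np.diag(tpl.covariance), 1.0)

    def test_infeasible_pattern_raises_with_name(self):
        # a large block all at r = -0.9 cannot be a correlation matrix
        spec = [
            {
                "description": "impossible",
                "baseline_r": -0.9,
                "blocks": [],
            },
            {"description": "flat", "baseline_r": 0.2, "blocks": []},
        ]
        with pytest.raises(InfeasibleCorrelationPattern, match="impossible"):
            make_state_covariances(20, structure_spec=spec)

    def test_separation_floor_enforced(self):
        spec = [
            {"description": "a", "baseline_r": 0.30, "blocks": []},
            {"description": "b", "baseline_r": 0.31, "blocks": []},
        ]
        with pytest.raises(ValueError, match="separable"):
            make_state_covariances(10, structure_spec=spec, separation_floor=1.0)


class TestSimulateRun:
    def _setup(self, n=8):
        templates = make_state_covariances(
            n,
            structure_spec=[
                {"description": "a", "baseline_r": 0.5, "blocks": []},
                {"description": "b", "baseline_r": 0.0, "blocks": []},
            ],
            separation_floor=0.5,
        )
        return templates

    def test_degenerate_chain_sticks_to_initial_state(self):
        templates = self._setup()
        plan = [("J1", 500)]
        sched = {"J1": np.array([0.5, 0.5])}
        tc, gt = simulate_run(
            templates, plan, sched, stickiness=1.0, noise_sd=0.0, seed=3,
            initial_state=1,
        )
        assert (gt.labels == 1).all()
        emp = np.corrcoef(tc.values, rowvar=False)
        assert np.abs(emp - templates[0].covariance).max() < 0.15

    def test_occupancy_approaches_stationary_weights(self):
        templates = self._setup()
        plan = [("J1", 5000)]
        sched = {"J1": np.array([0.7, 0.3])}
        _, gt = simulate_run(templates, plan, sched, stickiness=0.9, seed=4)
        assert abs(gt.occupancy[1] - 0.7) < 0.05
        assert abs(gt.occupancy[2] - 0.3) < 0.05

    def test_same_seed_bitwise_identical(self):
        templates = self._setup()
        plan = [("J1", 100)]
        sched = {"J1": np.array([0.6, 0.4])}
        tc1, gt1 = simulate_run(templates, plan, sched, seed=9)
        tc2, gt2 = simulate_run(templates, plan, sched, seed=9)
        assert np.array_equal(tc1.values, tc2.values)
        assert np.array_equal(gt1.labels, gt2.labels)

    def test_empty_stage_rejected(self):
        templates = self._setup()
        with pytest.raises(ValueError, match="empty stage"):
            simulate_run(templates, [("J1", 0)], {"J1": np.array([1.0, 0.0])})

    def test_schedule_state_count_mismatch_rejected(self):
        templates = self._setup()
        with pytest.raises(ValueError, match="mismatch"):
            simulate_run(templates, [("J1", 10)], {"J1": np.array([0.5, 0.3, 0.2])})


class TestSimulateStudy:
    def test_run_count_contract(self):
        study = simulate_study(SynthStudyParams(
            n_nodes=8, run_length_trs=48, control_length_trs=48,
            stage_plan=[(s, 6) for s in
                        ("AC", "J1", "J2", "J3", "J4", "J5", "J6-8", "afterglow")],
            seed=0,
        ))
        assert len(study.runs) == 27 + 4
        assert len(study.meditation_runs()) == 27
        assert len(study.control_runs()) == 4

    def test_occupancies_sum_to_one(self, small_study):
        for gt in small_study.truths.values():
            assert abs(sum(gt.occupancy.values()) - 1.0) < 1e-12

    def test_whole_study_determinism(self):
        p = small_params(seed=77)
        a = simulate_study(p)
        b = simulate_study(p)
        for ra, rb in zip(a.runs, b.runs):
            assert np.array_equal(ra.values, rb.values)
        assert a.ratings.global_items.equals(b.ratings.global_items)

    def test_no_coupling_gives_null_width_correlation(self):
        # with the coupling switched off the width/occupancy correlation is
        # null-typical; average over studies to beat the n=27 sampling noise
        rs = []
        for seed in range(6):
            p = small_params(
                seed=seed, n_meditation_runs=27,
                rating_coupling=RatingCoupling(width_slope=0.0),
            )
            study = simulate_study(p)
            occ2 = np.array(
                [study.truths[r].occupancy[2]
                 for r in study.ratings.global_items["run_id"]]
            )
            width = study.ratings.global_items["width"].to_numpy()
            rs.append(np.corrcoef(width, occ2)[0, 1])
        assert abs(np.mean(rs)) < 0.15

    def test_default_coupling_gives_negative_width_correlation(self, small_study):
        g = small_study.ratings.global_items
        occ2 = np.array([small_study.truths[r].occupancy[2] for r in g["run_id"]])
        assert np.corrcoef(g["width"].to_numpy(), occ2)[0, 1] < 0

    def test_ratings_within_scale(self, small_study):
        small_study.ratings.validate()

    def test_default_stage_plan_tiles_run(self):
        plan = default_stage_plan(176)
        assert sum(n for _, n in plan) == 176
        assert [s for s, _ in plan] == [
            "AC", "J1", "J2", "J3", "J4", "J5", "J6-8", "afterglow"
        ]

    def test_default_schedule_monotone_trend(self):
        sched = default_occupancy_schedule()
        j = ["J1", "J2", "J3", "J4", "J5", "J6-8"]
        s1 = [sched[s][0] for s in j]
        s2 = [sched[s][1] for s in j]
        assert all(np.diff(s1) > 0) and all(np.diff(s2) < 0)
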