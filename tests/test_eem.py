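"""Move engine: objectives, second exemplars, R1/R2 moves, sweeps."""

import numpy as np
import pytest

from feeclust import (
    ExemplarConfig,
    MaskedDataset,
    apply_move,
    build_similarity,
    config_objective,
    evaluate_addition,
    evaluate_removal,
    run_eem,
    second_exemplar,
    sweep,
)
from conftest import random_complete_dataset
from oracles import brute_force_exemplar_optimum


def _points_1d(*xs):
    return MaskedDataset.from_values(np.array([[float(x)] for x in xs]))


class TestConfigObjective:
    def test_all_self_exemplars(self, rng):
        data = random_complete_dataset(rng, 6, 2)
        s = build_similarity(data)
        assert config_objective(s, np.arange(6)) == pytest.approx(6 * s.preference)

    def test_single_exemplar(self, rng):
        data = random_complete_dataset(rng, 7, 2)
        s = build_similarity(data)
        expected = s.preference + sum(s.values[i, 3] for i in range(7) if i != 3)
        assert config_objective(s, np.full(7, 3)) == pytest.approx(expected)

    def test_invalid_config_is_minus_inf(self, rng):
        data = random_complete_dataset(rng, 3, 2)
        s = build_similarity(data)
        # 0 -> 1 but 1 is not its own exemplar
        assert config_objective(s, np.array([1, 2, 2])) == -np.inf
        with pytest.raises(ValueError, match="validity"):
            config_objective(s, np.array([1, 2, 2]), raise_on_invalid=True)

    def test_non_candidate_assignment_rejected(self, rng):
        data = random_complete_dataset(rng, 5, 2)
        from feeclust import build_compressed_similarity

        s = build_compressed_similarity(data, [0, 2])
        with pytest.raises(KeyError, match="not a candidate"):
            config_objective(s, np.array([0, 0, 2, 3, 2]))


class TestSecondExemplar:
    def test_two_exemplars_all_map_to_other(self):
        s = build_similarity(_points_1d(0, 0.5, 10, 10.5))
        cfg = ExemplarConfig.from_assignments(s, np.array([0, 0, 2, 2]))
        mapping = second_exemplar(s, cfg, 0)
        assert mapping == {0: 2, 1: 2}

    def test_nearest_remaining_exemplar(self):
        s = build_similarity(_points_1d(0, 10, 11, 9))
        cfg = ExemplarConfig.from_assignments(s, np.array([0, 1, 2, 1]))
        mapping = second_exemplar(s, cfg, 1)
        assert mapping[3] == 2  # member at 9 prefers 11 over 0... closest remaining
        assert mapping[1] == 2

    def test_matches_naive_scan(self, rng):
        data = random_complete_dataset(rng, 12, 2)
        s = build_similarity(data)
        exemplars = np.array([0, 3, 7, 10])
        e = exemplars[s.values[:, exemplars].argmax(axis=1)]
        e[exemplars] = exemplars
        cfg = ExemplarConfig.from_assignments(s, e)
        for alpha in exemplars:
            mapping = second_exemplar(s, cfg, alpha)
            others = [x for x in exemplars if x != alpha]
            for i, target in mapping.items():
                best = max(others, key=lambda r: (s.values[i, r], -r))
                assert target == best

    def test_singleton_set_rejected(self, rng):
        data = random_complete_dataset(rng, 4, 2)
        s = build_similarity(data)
        cfg = ExemplarConfig.from_assignments(s, np.zeros(4, dtype=int))
        with pytest.raises(ValueError, match="last exemplar"):
            second_exemplar(s, cfg, 0)


class TestRemoval:
    def test_clamped_to_zero_when_losing(self):
        # two tight, far blobs: removing either exemplar only loses similarity
        s = build_similarity(_points_1d(0, 0.1, 100, 100.1))
        cfg = ExemplarConfig.from_assignments(s, np.array([0, 0, 2, 2]))
        move = evaluate_removal(s, cfg, 0)
        assert move.reduction == 0.0
        assert move.new_assignments == {}

    def test_boundary_tie_gives_zero(self):
        # removing exemplar at 100 trades its preference for S(100, 0)
        data = _points_1d(0, 0.1, 100)
        s = build_similarity(data, preference=-(10_000.0))
        cfg = ExemplarConfig.from_assignments(s, np.array([0, 0, 2]))
        move = evaluate_removal(s, cfg, 2)
        assert move.reduction == pytest.approx(0.0, abs=1e-9)

    def test_self_certification(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            data = random_complete_dataset(rng, n, 2)
            s = build_similarity(data)
            exemplars = np.sort(rng.choice(n, size=2, replace=False))
            e = exemplars[s.values[:, exemplars].argmax(axis=1)]
            e[exemplars] = exemplars
            cfg = ExemplarConfig.from_assignments(s, e)
            move = evaluate_removal(s, cfg, int(exemplars[0]))
            if move.new_assignments:
                after = apply_move(s, cfg, move)
                assert after.valid
                assert after.objective - cfg.objective == pytest.approx(
                    move.reduction, abs=1e-9
                )


class TestAddition:
    def test_far_pair_promotes_new_exemplar(self):
        data = _points_1d(0, 1, 100, 101)
        s = build_similarity(data, preference=-1.0)
        cfg = ExemplarConfig.from_assignments(s, np.zeros(4, dtype=int))
        move = evaluate_addition(s, cfg, 2)
        # alpha's own swing: preference - S(2,0) = -1 + 10000
        # plus member 3 migrating: S(3,2) - S(3,0) = -1 + 10201
        assert move.reduction == pytest.approx((-1 + 10_000) + (-1 + 10_201))
        assert move.new_assignments[2] == 2 and move.new_assignments[3] == 2
        after = apply_move(s, cfg, move)
        assert after.objective - cfg.objective == pytest.approx(move.reduction)

    def test_duplicate_location_never_accepted(self):
        # alpha sits exactly on its exemplar: the best the move can do is a
        # zero-gain swap (alpha takes over, the old exemplar defects to it),
        # so with strict-positivity acceptance it is always rejected
        data = _points_1d(0, 0, 5, 5.2)
        s = build_similarity(data, preference=-4.0)
        e = np.array([0, 0, 2, 2])
        cfg = ExemplarConfig.from_assignments(s, e)
        move = evaluate_addition(s, cfg, 1)  # duplicates exemplar 0 exactly
        assert move.reduction <= 0
        after = apply_move(s, cfg, move)
        assert after.objective - cfg.objective == pytest.approx(move.reduction)

    def test_already_exemplar_rejected(self, rng):
        data = random_complete_dataset(rng, 5, 2)
        s = build_similarity(data)
        cfg = ExemplarConfig.from_assignments(s, np.zeros(5, dtype=int))
        with pytest.raises(ValueError, match="already an exemplar"):
            evaluate_addition(s, cfg, 0)

    @pytest.mark.parametrize("combination", ["per_cluster", "global"])
    def test_self_certification(self, rng, combination):
        for _ in range(30):
            n = int(rng.integers(4, 9))
            data = random_complete_dataset(rng, n, 2)
            s = build_similarity(data)
            exemplars = np.sort(rng.choice(n, size=2, replace=False))
            e = exemplars[s.values[:, exemplars].argmax(axis=1)]
            e[exemplars] = exemplars
            cfg = ExemplarConfig.from_assignments(s, e)
            non_ex = [i for i in range(n) if i not in exemplars]
            alpha = int(rng.choice(non_ex))
            move = evaluate_addition(s, cfg, alpha, r2_combination=combination)
            after = apply_move(s, cfg, move)
            assert after.valid
            assert after.objective - cfg.objective == pytest.approx(
                move.reduction, abs=1e-9
            )


class TestSweepAndRun:
    def test_no_move_at_global_optimum(self, rng):
        data = random_complete_dataset(rng, 6, 2)
        s = build_similarity(data)
        _, best_e = brute_force_exemplar_optimum(s, np.arange(6))
        cfg = ExemplarConfig.from_assignments(s, best_e)
        new_cfg, improved = sweep(s, cfg)
        assert not improved
        assert np.array_equal(new_cfg.assignments, cfg.assignments)

    def test_identical_points_collapse_to_one_exemplar(self):
        data = MaskedDataset.from_values(np.zeros((8, 2)))
        s = build_similarity(data, preference=-5.0)
        cfg = ExemplarConfig.from_assignments(s, np.arange(8))
        while True:
            cfg, improved = sweep(s, cfg)
            if not improved:
                break
        assert cfg.n_clusters == 1

    def test_objective_trace_monotone(self, rng):
        data = random_complete_dataset(rng, 30, 2)
        s = build_similarity(data)
        report = run_eem(s)
        trace = report.meta["objective_trace"]
        assert all(b >= a - 1e-12 for a, b in zip(trace, trace[1:]))
        assert report.meta["converged"]

    def test_blob_recovery(self, rng):
        from conftest import two_blob_dataset
        from feeclust import nmi

        data, labels = two_blob_dataset(rng, per_blob=15)
        report = run_eem(build_similarity(data))
        assert report.n_clusters == 2
        assert nmi(report.labels, labels) == pytest.approx(1.0)

    def test_single_candidate_single_cluster(self, rng):
        data = random_complete_dataset(rng, 9, 2)
        from feeclust import build_compressed_similarity

        s = build_compressed_similarity(data, [4])
        report = run_eem(s)
        assert report.n_clusters == 1
        assert report.exemplars.tolist() == [4]
        full = build_similarity(data)
        expected = full.preference + sum(
            full.values[i, 4] for i in range(9) if i != 4
        )
        assert report.objective == pytest.approx(expected)

    def test_validity_preserved_through_run(self, rng):
        data = random_complete_dataset(rng, 25, 3)
        s = build_similarity(data)
        report = run_eem(s)
        e = np.array([report.exemplar_of(i) for i in range(25)])
        cfg = ExemplarConfig.from_assignments(s, e)
        assert cfg.valid
        assert cfg.objective == pytest.approx(report.objective)

    def test_matches_bruteforce_on_small_instances(self):
        matches = 0
        for seed in range(20):
            inst_rng = np.random.default_rng(1000 + seed)
            n = int(inst_rng.integers(5, 9))
            data = random_complete_dataset(inst_rng, n, 2)
            s = build_similarity(data)
            report = run_eem(s)
            best_obj, _ = brute_force_exemplar_optimum(s, np.arange(n))
            assert report.objective <= best_obj + 1e-9
            if report.objective == pytest.approx(best_obj, abs=1e-9):
                matches += 1
        assert matches >= 16
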