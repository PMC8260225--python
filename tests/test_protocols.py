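"""Pretraining, newborn birth, GABA-switch, maturation phases, controls."""

import numpy as np
import pytest

from neurogen import (ExperimentPlan, MaturationStage, NetworkConfig,
                      PlasticityConfig, birth_newborns, classify_units,
                      gaba_switch, init_network, pretrain, run_control,
                      run_neurogenesis)
from neurogen.protocols import _mixed_order


class TestPretrain:

    def test_two_clusters_each_captured(self):
        # two units, two well-separated clusters: each cluster ends up owned
        # by a unit whose weight vector points at its center
        from neurogen import ClusterSpec, build_dataset
        spec = ClusterSpec(K=3, xi=0.8, kappa=1e4, n_train=40, n_test=10,
                           seed=2)
        train, _ = build_dataset(spec)
        cfg = NetworkConfig(n_ec=8, n_dgc=2, n_inh=4, dt=1.0, tol=1e-6)
        state = init_network(cfg, 3)
        # threshold adaptation sharpens the competition between the two
        # units, letting each specialize on one cluster
        pretrain(state, train.subset([0, 1]), 20, cfg,
                 PlasticityConfig(eta=0.02), rng=7, adapt_mature_b=True)
        best = {}
        for i in range(2):
            cos = spec.centers @ state.W[i] / np.linalg.norm(state.W[i])
            best[int(np.argmax(cos))] = max(
                best.get(int(np.argmax(cos)), 0.0), float(np.max(cos)))
        assert set(best) == {0, 1}
        assert all(c > 0.95 for c in best.values())

    def test_zero_learning_rate_is_identity(self, tiny_similar, small_net_cfg):
        _, train, _ = tiny_similar
        state = init_network(small_net_cfg, 1)
        W0, b0 = state.W.copy(), state.b.copy()
        pretrain(state, train, 2, small_net_cfg,
                 PlasticityConfig(eta=0.0, eta_b=0.0), rng=0)
        assert np.array_equal(state.W, W0) and np.array_equal(state.b, b0)

    def test_seed_determinism(self, tiny_similar, small_net_cfg, bio_plast):
        _, train, _ = tiny_similar
        runs = []
        for _ in range(2):
            state = init_network(small_net_cfg, 1)
            pretrain(state, train.subset([0]), 2, small_net_cfg, bio_plast,
                     rng=9)
            runs.append(state.W.copy())
        assert np.array_equal(runs[0], runs[1])


class TestClassifyUnits:

    def test_zero_weight_cell_unresponsive(self, tiny_similar, small_net_cfg):
        _, train, _ = tiny_similar
        state = init_network(small_net_cfg, 1)
        state.W[2] = 0.0
        state.W[[0, 1, 3]] *= 10.0   # strong cells fire
        selective, unresponsive = classify_units(state, train, small_net_cfg)
        assert 2 in unresponsive

    def test_partition_covers_all_cells(self, tiny_similar, small_net_cfg):
        _, train, _ = tiny_similar
        state = init_network(small_net_cfg, 1)
        selective, unresponsive = classify_units(state, train, small_net_cfg)
        combined = np.sort(np.concatenate([selective, unresponsive]))
        assert np.array_equal(combined, np.arange(small_net_cfg.n_dgc))


class TestBirthAndSwitch:

    @pytest.fixture
    def state(self, small_net_cfg):
        return init_network(small_net_cfg, 4)

    def test_birth_resets_wiring(self, state, small_net_cfg):
        birth_newborns(state, [1, 2], small_net_cfg)
        for i in (1, 2):
            assert np.all(state.W[i] == 0.0)
            assert np.all(state.w_ie[:, i] == 0.0)
            assert np.all(state.w_ei[i] >= 0.0)       # depolarizing GABA
            assert state.b[i] == 0.0
            assert state.stage[i] is MaturationStage.NEWBORN_EARLY
        state.validate()

    def test_birth_of_selective_unit_requires_force(self, state,
                                                    small_net_cfg):
        with pytest.raises(ValueError, match="selective"):
            birth_newborns(state, [0], small_net_cfg, unresponsive=[1, 2])
        birth_newborns(state, [0], small_net_cfg, unresponsive=[1, 2],
                       force=True)
        assert state.stage[0] is MaturationStage.NEWBORN_EARLY

    def test_switch_flips_sign_on_same_mask(self, state, small_net_cfg):
        birth_newborns(state, [1], small_net_cfg)
        mask_before = state.mask_ei[1].copy()
        gaba_switch(state, [1], small_net_cfg)
        assert np.array_equal(state.mask_ei[1], mask_before)
        assert np.all(state.w_ei[1][mask_before] < 0.0)   # now inhibitory
        assert state.stage[1] is MaturationStage.NEWBORN_LATE

    def test_switch_wires_output_bernoulli(self, small_net_cfg):
        cfg = NetworkConfig(n_ec=8, n_dgc=40, n_inh=25, dt=1.0)
        state = init_network(cfg, 8)
        idx = list(range(40))
        birth_newborns(state, idx, cfg, force=True)
        gaba_switch(state, idx, cfg)
        out_degree = (state.w_ie != 0).sum(axis=0).mean()
        assert out_degree == pytest.approx(cfg.p_ie * cfg.n_inh, abs=2.0)

    def test_double_switch_rejected(self, state, small_net_cfg):
        birth_newborns(state, [1], small_net_cfg)
        gaba_switch(state, [1], small_net_cfg)
        with pytest.raises(ValueError, match="not an early-phase newborn"):
            gaba_switch(state, [1], small_net_cfg)

    def test_switch_of_mature_cell_rejected(self, state, small_net_cfg):
        with pytest.raises(ValueError):
            gaba_switch(state, [0], small_net_cfg)


class TestNeurogenesisRun:

    def test_newborn_acquires_similar_novel_cluster(self, similar_run):
        spec, cfg, result = similar_run
        best = max(
            float(result.state.W[i] @ spec.centers[2]
                  / np.linalg.norm(result.state.W[i]))
            for i in result.newborn)
        assert best > 0.9

    def test_newborn_norm_grows_monotonically_in_early_phase(self,
                                                             similar_run):
        _, _, result = similar_run
        norms = result.newborn_norms["early"]
        assert len(norms) >= 5
        assert np.all(np.diff(norms) > -1e-9)

    def test_mature_rows_frozen_through_maturation(self, similar_run):
        _, _, result = similar_run
        for i in result.selective:
            assert np.array_equal(result.snapshots["pretrain"][i],
                                  result.state.W[i])

    def test_stage_wiring_invariants(self, similar_run):
        _, _, result = similar_run
        early = result.state_snapshots["early"]
        for i in result.newborn:
            assert early.stage[i] is MaturationStage.NEWBORN_EARLY
            assert np.all(early.w_ie[:, i] == 0.0)
            assert np.all(early.w_ei[i] >= 0.0)
            late = result.state
            assert late.stage[i] is MaturationStage.NEWBORN_LATE
            assert np.all(late.w_ei[i][late.mask_ei[i]] < 0.0)

    def test_newborn_activity_declines_from_early_to_late(self,
                                                          tiny_distinct):
        spec, train, _ = tiny_distinct
        cfg = NetworkConfig(n_ec=8, n_dgc=4, n_inh=4, dt=1.0, tol=1e-6)
        plan = ExperimentPlan(pretrain_classes=(0, 1), novel_classes=(2,),
                              pretrain_epochs=15, late_epochs=10, seed=5)
        result = run_neurogenesis(plan, train, cfg,
                                  PlasticityConfig(eta=0.02), log_every=60)
        early = result.newborn_active_frac["early"].mean()
        late_tail = result.newborn_active_frac["late"][-10:].mean()
        assert late_tail < early

    def test_fixed_count_replacement_picks_lowest_norms(self, tiny_similar,
                                                        small_net_cfg,
                                                        bio_plast):
        _, train, _ = tiny_similar
        plan = ExperimentPlan(pretrain_classes=(0, 1), novel_classes=(2,),
                              pretrain_epochs=4, replacement=1, seed=3)
        result = run_neurogenesis(plan, train, small_net_cfg, bio_plast)
        assert result.newborn.size == 1
        assert result.newborn[0] in result.unresponsive


class TestMixedOrder:

    def test_novel_absent_before_split(self):
        rng = np.random.default_rng(0)
        order = _mixed_order(rng, n_familiar=100, n_novel=40,
                             novel_start_fraction=0.5)
        assert np.all(order[:50] < 100)          # only familiar in the head
        assert np.array_equal(np.sort(order), np.arange(140))

    def test_zero_fraction_is_single_shuffled_stream(self):
        rng = np.random.default_rng(0)
        order = _mixed_order(rng, 100, 40, 0.0)
        assert np.array_equal(np.sort(order), np.arange(140))
        # novel patterns appear early in the stream too
        assert np.any(order[:30] >= 100)


class TestControls:

    def test_control1_is_simultaneous_pretraining(self, tiny_similar,
                                                  small_net_cfg, bio_plast):
        _, train, _ = tiny_similar
        plan = ExperimentPlan(pretrain_classes=(0, 1), novel_classes=(2,),
                              pretrain_epochs=3, seed=6, control="control1")
        result = run_control(plan, train, small_net_cfg, bio_plast)
        # identical code path: init + pretrain on all classes
        state = init_network(small_net_cfg, np.random.default_rng([1, 6]))
        pretrain(state, train.subset((0, 1, 2)), 3, small_net_cfg, bio_plast,
                 rng=np.random.default_rng([2, 6]))
        assert np.array_equal(result.state.W, state.W)

    def test_control2_unresponsive_units_stay_unselective(self, tiny_similar,
                                                          small_net_cfg,
                                                          bio_plast):
        _, train, _ = tiny_similar
        plan = ExperimentPlan(pretrain_classes=(0, 1), novel_classes=(2,),
                              pretrain_epochs=15, seed=5, control="control2")
        result = run_control(plan, train, small_net_cfg, bio_plast)
        for i in result.unresponsive:
            before = result.snapshots["pretrain"][i]
            after = result.state.W[i]
            # weight vectors essentially unchanged: no acquisition
            assert np.linalg.norm(after - before) < 0.05
        sel_after, _ = classify_units(result.state, train, small_net_cfg)
        assert set(sel_after) == set(result.selective)

    def test_control3_mature_cells_retune_to_novel(self, tiny_distinct,
                                                   small_net_cfg, bio_plast):
        spec, train, _ = tiny_distinct
        plan = ExperimentPlan(pretrain_classes=(0, 1), novel_classes=(2,),
                              pretrain_epochs=15, late_epochs=2, seed=5,
                              control="control3")
        result = run_control(plan, train, small_net_cfg, bio_plast)
        retuned = []
        for i in result.selective:
            pref_before = int(np.argmax(
                spec.centers @ result.snapshots["pretrain"][i]))
            pref_after = int(np.argmax(spec.centers @ result.state.W[i]))
            if pref_before != 2 and pref_after == 2:
                retuned.append(i)
        assert retuned

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ExperimentPlan(control="control9")
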