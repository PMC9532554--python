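"""Progressive inference and self-calibrating training."""

import dataclasses

import numpy as np
import pytest

import proreg as pr
from proreg.progressive import Adam, TrainingError, train_step
from conftest import (SMALL_BACKBONE, desk_train_config,
                      perturbed_backbone, zeroed_backbone)


@pytest.fixture(scope="module")
def small_pair():
    pspec = pr.PhantomSpec(shape=(16, 16, 16), seed=3)
    dspec = pr.DeformationSpec(amplitude=3.0, seed=21)
    return pr.make_pair(pspec, dspec)


class TestProgressiveInfer:
    def test_single_pass_reduces_to_one_shot(self, small_pair):
        net = perturbed_backbone(seed=0)
        res = pr.progressive_infer(small_pair.moving, small_pair.fixed, net, 1)
        flow = pr.predict_flow(small_pair.moving, small_pair.fixed, net)
        np.testing.assert_array_equal(res.total_flow.data, flow.data)
        np.testing.assert_array_equal(
            res.warped.data, pr.warp_image(small_pair.moving, flow).data)

    def test_zero_weight_backbone_is_identity(self, small_pair):
        res = pr.progressive_infer(small_pair.moving, small_pair.fixed,
                                   zeroed_backbone(), 4)
        assert np.all(res.total_flow.data == 0)
        np.testing.assert_array_equal(res.warped.data, small_pair.moving.data)

    def test_final_output_is_single_interpolation(self, small_pair):
        net = perturbed_backbone(seed=1)
        for n in (1, 2, 3):
            res = pr.progressive_infer(small_pair.moving, small_pair.fixed,
                                       net, n)
            assert res.interp_count == 1
            assert len(res.per_pass) == n

    def test_warped_consistent_with_total_flow(self, small_pair):
        net = perturbed_backbone(seed=2)
        res = pr.progressive_infer(small_pair.moving, small_pair.fixed, net, 3)
        recomputed = pr.warp_image(small_pair.moving, res.total_flow)
        np.testing.assert_allclose(res.warped.data, recomputed.data, atol=1e-6)

    def test_invalid_pass_count_rejected(self, small_pair):
        with pytest.raises(ValueError):
            pr.progressive_infer(small_pair.moving, small_pair.fixed,
                                 perturbed_backbone(), 0)


class TestCascadeInfer:
    def test_accumulates_one_interpolation_per_pass(self, small_pair):
        net = perturbed_backbone(seed=3)
        for n in (1, 3):
            res = pr.cascade_infer(small_pair.moving, small_pair.fixed, net, n)
            assert res.interp_count == n


class TestTrainStep:
    def test_single_pass_is_standard_unsupervised_step(self, small_pair):
        # n_train=1: one flow prediction, one warp, one update
        net = pr.UNetBackbone(pr.BackboneConfig(), seed=0)
        opt = Adam(net, lr=1e-3)
        cfg = desk_train_config(steps=1, n_train=1, n_test=1)
        before = net.checksum()
        pr.counters.reset()
        diag = train_step(small_pair.moving, small_pair.fixed, net, opt, cfg)
        assert len(diag) == 1 and pr.counters.warp_calls == 1
        assert net.checksum() != before

    def test_one_interpolation_of_primary_moving_per_pass(self, small_pair):
        net = pr.UNetBackbone(pr.BackboneConfig(), seed=0)
        opt = Adam(net, lr=1e-3)
        cfg = desk_train_config(steps=1, n_train=4, n_test=1)
        pr.counters.reset()
        train_step(small_pair.moving, small_pair.fixed, net, opt, cfg)
        assert pr.counters.warp_calls == 4  # never warps of warps

    def test_objective_decreases_over_training(self, small_pair):
        cfg = desk_train_config(steps=50, n_train=3, n_test=2)
        net = pr.UNetBackbone(pr.BackboneConfig(), seed=0)
        hist = pr.train([small_pair], net, cfg)
        first = np.mean([h["objective"] for h in hist[:10]])
        last = np.mean([h["objective"] for h in hist[-10:]])
        assert last < first

    def test_per_sweep_update_mode(self, small_pair):
        net = pr.UNetBackbone(pr.BackboneConfig(), seed=0)
        opt = Adam(net, lr=1e-3)
        cfg = dataclasses.replace(desk_train_config(steps=1, n_train=3, n_test=1),
                                  update="per_sweep")
        before = net.checksum()
        train_step(small_pair.moving, small_pair.fixed, net, opt, cfg)
        assert opt.t == 1  # one update for the whole sweep
        assert net.checksum() != before

    def test_shared_weights_single_parameter_set(self, small_pair):
        # the set of mutated parameter tensors is the same one set,
        # regardless of pass count
        net = pr.UNetBackbone(pr.BackboneConfig(), seed=0)
        opt = Adam(net, lr=1e-3)
        cfg = desk_train_config(steps=1, n_train=3, n_test=1)
        ids_before = {k: id(p.value) for k, p in net.params.items()}
        snapshot = {k: p.value.copy() for k, p in net.params.items()}
        train_step(small_pair.moving, small_pair.fixed, net, opt, cfg)
        assert {k: id(p.value) for k, p in net.params.items()} == ids_before
        changed = [k for k, p in net.params.items()
                   if not np.array_equal(p.value, snapshot[k])]
        assert set(changed) == set(net.params)  # every tensor of the one set

    def test_divergent_loss_carries_pass_index(self, small_pair):
        net = perturbed_backbone(seed=4)
        net.params["head.b"].value[:] = np.inf
        opt = Adam(net, lr=1e-3)
        cfg = desk_train_config(steps=1, n_train=2, n_test=1)
        with pytest.raises(TrainingError) as err:
            train_step(small_pair.moving, small_pair.fixed, net, opt, cfg)
        assert err.value.pass_index == 1


class TestHierarchical:
    def test_zero_weight_backbones_are_identity(self, small_pair):
        res = pr.hierarchical_infer(small_pair.moving, small_pair.fixed,
                                    zeroed_backbone(SMALL_BACKBONE),
                                    zeroed_backbone(),
                                    pr.IterationSchedule(1, 2),
                                    pr.IterationSchedule(1, 2))
        assert np.all(res.total_flow.data == 0)
        np.testing.assert_array_equal(res.warped.data, small_pair.moving.data)

    def test_default_schedules_run_three_low_and_two_fine_passes(self, small_pair):
        # the default schedules follow the grid-search optima: low scale
        # tested with 3 passes, original scale with 2
        res = pr.hierarchical_infer(small_pair.moving, small_pair.fixed,
                                    zeroed_backbone(SMALL_BACKBONE),
                                    zeroed_backbone())
        assert len(res.per_pass) == 3 + 2

    def test_total_flow_aggregates_upsampled_low_flow(self, small_pair):
        low = perturbed_backbone(seed=5, config=SMALL_BACKBONE)
        orig = perturbed_backbone(seed=6)
        res = pr.hierarchical_infer(small_pair.moving, small_pair.fixed,
                                    low, orig,
                                    pr.IterationSchedule(1, 2),
                                    pr.IterationSchedule(1, 2))
        assert res.interp_count == 1
        recomputed = pr.warp_image(small_pair.moving, res.total_flow)
        np.testing.assert_allclose(res.warped.data, recomputed.data, atol=1e-6)
        # flow_algebra oracle: redo the low-scale chain + upsample + fine chain
        m_low = pr.downsample_volume(small_pair.moving)
        f_low = pr.downsample_volume(small_pair.fixed)
        low_res = pr.progressive_infer(m_low, f_low, low, 2)
        flow_up = pr.upsample_flow(low_res.total_flow)
        fine = pr.progressive_infer(small_pair.moving, small_pair.fixed, orig,
                                    2, init_agg=flow_up)
        np.testing.assert_allclose(res.total_flow.data, fine.total_flow.data,
                                   atol=1e-6)

    def test_phase_isolation_and_frozen_low_scale(self, small_pair):
        cfg_low = desk_train_config(steps=2, n_train=1, n_test=1)
        cfg_orig = desk_train_config(steps=0, n_train=1, n_test=1)
        low, orig, _, _ = pr.train_hierarchical([small_pair], cfg_low, cfg_orig,
                                                bb_low=SMALL_BACKBONE)
        # steps=0: original-scale checkpoint equals its initialization
        fresh = pr.UNetBackbone(pr.BackboneConfig(), seed=cfg_orig.seed + 1)
        assert orig.checksum() == fresh.checksum()
        # phase 2 training never mutates low-scale weights
        cfg_orig2 = desk_train_config(steps=2, n_train=1, n_test=1)
        low2, _, _, _ = pr.train_hierarchical([small_pair], cfg_low, cfg_orig2,
                                              bb_low=SMALL_BACKBONE)
        assert low2.checksum() == low.checksum()


class TestGridSearch:
    def test_degenerate_1x1_equals_single_run(self, small_pair):
        base = desk_train_config(steps=3, n_train=1, n_test=1)
        matrix, argmax = pr.grid_search([small_pair], [small_pair], base,
                                        [2], [2])
        assert matrix.shape == (1, 1) and argmax == (0, 0)
        cfg = dataclasses.replace(base, schedule=pr.IterationSchedule(2, 2))
        net = pr.UNetBackbone(pr.BackboneConfig(), seed=cfg.seed)
        pr.train([small_pair], net, cfg)
        res = pr.progressive_infer(small_pair.moving, small_pair.fixed, net, 2)
        wl = pr.warp_labels(small_pair.moving_labels, res.total_flow)
        expected = pr.dice_report(wl, small_pair.fixed_labels).mean
        assert matrix[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_empty_ranges_rejected(self, small_pair):
        with pytest.raises(ValueError):
            pr.grid_search([small_pair], [small_pair],
                           desk_train_config(1, 1, 1), [], [1])


def test_schedule_and_config_validation():
    with pytest.raises(ValueError):
        pr.IterationSchedule(0, 1)
    with pytest.raises(ValueError):
        pr.TrainConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        pr.TrainConfig(update="bogus")
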