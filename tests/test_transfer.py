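"""Transfer strategies: freeze contracts, schedules, trajectory identities."""

import numpy as np
import pytest

from specshift.losses import LossWeights
from specshift.model import GROUPS, ModelConfig, build_model
from specshift.synth import (
    InstrumentTransform,
    apply_instrument_transform,
    generate_component_profiles,
    generate_master_spectra,
)
from specshift.transfer import (
    PlateauScheduler,
    TrainSchedule,
    fine_tune,
    group_hashes,
    make_plan,
    plateau_scheduler,
    pretrain,
)


SMALL = ModelConfig(kernel_sizes=(3, 5, 7, 3), stem_channels=8,
                    block_channels=(8, 100), pool_len=5, dropout_p=0.0)


@pytest.fixture(scope="module")
def small_study():
    wl = 1100.0 + 2.0 * np.arange(64)
    profiles = generate_component_profiles(3, wl, peaks_per_component=3, seed=0)
    master = generate_master_spectra(
        profiles, 40, [(0.1, 0.5), (0.2, 0.8), (0.4, 1.0)],
        baseline_amp=0.0, noise_sd=0.001, seed=1,
    )
    slave = apply_instrument_transform(
        master,
        InstrumentTransform(shift_nm=2.0, broaden_sigma_nm=4.0, gain=1.1,
                            offset=0.05, scatter_sd=0.01, noise_sd=0.002, seed=2),
    )
    return master, slave


@pytest.fixture(scope="module")
def pretrained(small_study):
    master, _ = small_study
    sched = TrainSchedule(batch_size=8, epochs=30, lr=1e-3, seed=0)
    net, history = pretrain(SMALL, master, sched, target=0)
    return net, history


class TestMakePlan:
    @pytest.mark.parametrize("strategy,frozen,bda", [
        (1, set(GROUPS), False),
        (2, set(), False),
        (3, {"stem", "blocks", "fc2"}, False),
        (4, {"stem", "blocks", "fc1"}, False),
        (5, {"stem", "blocks"}, False),
        (6, {"stem", "blocks"}, True),
    ])
    def test_freeze_maps(self, strategy, frozen, bda):
        plan = make_plan(strategy)
        assert set(plan.freeze) == frozen
        assert plan.use_bda is bda

    @pytest.mark.parametrize("bad", [0, 7, -1])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError, match="strategy"):
            make_plan(bad)


class TestPlateauScheduler:
    def test_thirty_stalled_epochs_halve_lr(self):
        history = [1.0] + [1.0] * 30
        assert plateau_scheduler(history, 30, 0.5, 1e-3) == pytest.approx(5e-4)

    def test_monotone_improvement_keeps_lr(self):
        history = list(np.linspace(1.0, 0.1, 100))
        assert plateau_scheduler(history, 30, 0.5, 1e-3) == 1e-3

    def test_improvement_at_window_edge_keeps_lr(self):
        history = [1.0] + [1.0] * 29 + [0.5]
        assert plateau_scheduler(history, 30, 0.5, 1e-3) == 1e-3

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            plateau_scheduler([], 30, 0.5, 1e-3)

    def test_stateful_counter_resets_after_reduction(self):
        sched = PlateauScheduler(lr=1e-3, patience=3, factor=0.5)
        for loss in (1.0, 1.0, 1.0, 1.0):  # 3 stalls after the best
            lr = sched.step(loss)
        assert lr == pytest.approx(5e-4)
        for loss in (1.0, 1.0):  # only 2 stalls since reset
            lr = sched.step(loss)
        assert lr == pytest.approx(5e-4)
        lr = sched.step(1.0)  # third stall: halve again
        assert lr == pytest.approx(2.5e-4)


class TestPretrain:
    def test_zero_epochs_returns_initial_parameters(self, small_study):
        master, _ = small_study
        sched = TrainSchedule(batch_size=8, epochs=0, seed=3)
        net, history = pretrain(SMALL, master, sched, target=0)
        fresh = build_model(SMALL, seed=3)
        for (_, _, a), (_, _, b) in zip(net.named_group_parameters(),
                                        fresh.named_group_parameters()):
            np.testing.assert_array_equal(a.data, b.data)
        assert len(history) == 0

    def test_history_length_equals_epochs(self, pretrained):
        _, history = pretrained
        assert len(history) == 30
        assert len(history.lr) == 30

    def test_learns_noiseless_linear_mixture(self, small_study):
        from specshift.metrics import evaluate

        master, _ = small_study
        sched = TrainSchedule(batch_size=8, epochs=150, lr=1e-3, seed=0)
        net, history = pretrain(SMALL, master, sched, target=0)
        rep = evaluate(master.target(0), net.predict(master.X))
        assert rep.r2 >= 0.99
        assert history.loss[-1] < history.loss[0]

    def test_seeded_reproducibility(self, small_study):
        master, _ = small_study
        sched = TrainSchedule(batch_size=8, epochs=5, seed=7)
        _, h1 = pretrain(SMALL, master, sched, target=0)
        _, h2 = pretrain(SMALL, master, sched, target=0)
        assert h1.loss == h2.loss

    @pytest.mark.filterwarnings("ignore:overflow:RuntimeWarning")
    @pytest.mark.filterwarnings("ignore:invalid value:RuntimeWarning")
    def test_nan_loss_aborts_with_epoch(self, small_study):
        # an absurd learning rate makes the float32 parameters overflow; the
        # loop must abort with a diagnostic naming the epoch, not loop on NaN
        master, _ = small_study
        sched = TrainSchedule(batch_size=8, epochs=10, lr=1e12, seed=0)
        with pytest.raises(FloatingPointError, match="epoch"):
            pretrain(SMALL, master, sched, target=0)


class TestFineTune:
    def test_strategy1_is_identity(self, pretrained, small_study):
        net, _ = pretrained
        _, slave = small_study
        adapted, history = fine_tune(net, make_plan(1), slave,
                                     schedule=TrainSchedule(epochs=10, seed=0))
        assert group_hashes(adapted) == group_hashes(net)
        np.testing.assert_array_equal(adapted.predict(slave.X), net.predict(slave.X))
        assert len(history) == 0

    @pytest.mark.parametrize("strategy", [2, 3, 4, 5, 6])
    def test_frozen_groups_bit_identical_and_trainable_change(
        self, pretrained, small_study, strategy
    ):
        net, _ = pretrained
        master, slave = small_study
        plan = make_plan(strategy)
        before = group_hashes(net)
        adapted, _ = fine_tune(net, plan, slave, master,
                               TrainSchedule(batch_size=8, epochs=3, seed=1))
        after = group_hashes(adapted)
        for g in GROUPS:
            if g in plan.freeze:
                assert after[g] == before[g], f"frozen group {g} changed"
            else:
                assert after[g] != before[g], f"trainable group {g} did not move"

    def test_input_network_never_mutated(self, pretrained, small_study):
        net, _ = pretrained
        master, slave = small_study
        before = group_hashes(net)
        fine_tune(net, make_plan(2), slave, master,
                  TrainSchedule(batch_size=8, epochs=2, seed=0))
        assert group_hashes(net) == before

    def test_strategy6_lambda_zero_matches_strategy5_trajectory(
        self, pretrained, small_study
    ):
        net, _ = pretrained
        master, slave = small_study
        sched = TrainSchedule(batch_size=8, epochs=4, seed=5)
        a5, h5 = fine_tune(net, make_plan(5), slave, master, sched)
        a6, h6 = fine_tune(net, make_plan(6, LossWeights(lambda1=0.0)),
                           slave, master, sched)
        assert h5.loss == h6.loss
        assert group_hashes(a5) == group_hashes(a6)

    def test_bda_without_master_rejected(self, pretrained, small_study):
        net, _ = pretrained
        _, slave = small_study
        with pytest.raises(ValueError, match="master"):
            fine_tune(net, make_plan(6), slave, None,
                      TrainSchedule(epochs=1, seed=0))

    def test_bda_changes_trajectory_when_active(self, pretrained, small_study):
        net, _ = pretrained
        master, slave = small_study
        sched = TrainSchedule(batch_size=8, epochs=4, seed=5)
        _, h5 = fine_tune(net, make_plan(5), slave, master, sched)
        _, h6 = fine_tune(net, make_plan(6, LossWeights(lambda1=1.0)),
                          slave, master, sched)
        assert h5.loss != h6.loss


class TestScheduleValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(lr=0.0), dict(lr_factor=1.5), dict(plateau_patience=0),
        dict(batch_size=0), dict(epochs=-1),
    ])
    def test_invalid_schedules_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrainSchedule(**kwargs)
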