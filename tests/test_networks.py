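import numpy as np
import pytest

from mtlprofile import (
    ArchitectureConfig,
    GroupingResult,
    ItemSpec,
    TaskEnsemble,
    TrainingConfig,
    build_mtl_all,
    build_mtl_concat,
    build_mtl_group,
    build_stl,
    count_parameters,
    synthetic_profile_spec,
    task_f1,
    train,
    transfer_pretrained,
)
from mtlprofile.grouping import SelectedGroup
from mtlprofile.networks import Dense, build_group_ensemble

ARCH = ArchitectureConfig(h=4, r=100)


def _pair_grouping(M):
    """Disjoint pair groups (0,1), (2,3), ... with both members primary."""
    groups = [
        SelectedGroup((i, i + 1), (i, i + 1), ()) for i in range(0, M - 1, 2)
    ]
    return GroupingResult(M=M, groups=groups)


class TestParameterCounts:
    def test_single_dense_layer(self, rng):
        assert Dense(10, 5, rng).n_params == 55

    def test_stl_closed_form(self):
        model = build_stl(20, ItemSpec("a", (0, 1, 2)), ARCH)
        expected = (20 * 100 + 100) + 3 * (100 * 100 + 100) + (100 * 3 + 3)
        assert count_parameters(model) == expected

    def test_binary_head_single_unit(self):
        model = build_stl(20, ItemSpec("a", (0, 5)), ARCH)
        assert model.heads["a"].W.shape == (100, 1)

    def test_mtl_all_structure(self):
        profile = synthetic_profile_spec(10)
        model = build_mtl_all(20, profile, ARCH)
        assert len(model.trunk) == 2
        assert all(len(b) == 2 for b in model.branches.values())
        assert len(model.heads) == 10

    def test_mtl_all_smaller_than_stl_sum(self):
        profile = synthetic_profile_spec(4)
        mtl = count_parameters(build_mtl_all(20, profile, ARCH))
        stl_sum = sum(count_parameters(build_stl(20, it, ARCH)) for it in profile.items)
        assert mtl < stl_sum

    def test_full_group_equals_mtl_all(self):
        profile = synthetic_profile_spec(4)
        grp = build_mtl_group(20, profile, (0, 1, 2, 3), arch=ARCH)
        assert count_parameters(grp) == count_parameters(build_mtl_all(20, profile, ARCH))

    def test_concat_head_widths_for_pairs(self):
        profile = synthetic_profile_spec(4)
        model = build_mtl_concat(20, profile, _pair_grouping(4), ARCH)
        for head in model.heads.values():
            assert head.W.shape[0] == 200

    def test_concat_full_group_head_width_r_times_m(self):
        profile = synthetic_profile_spec(3)
        grouping = GroupingResult(M=3, groups=[SelectedGroup((0, 1, 2), (0, 1, 2), ())])
        model = build_mtl_concat(20, profile, grouping, ARCH)
        assert all(h.W.shape[0] == 300 for h in model.heads.values())

    def test_concat_exceeds_mtl_all_by_extra_head_inputs(self):
        profile = synthetic_profile_spec(4)
        concat = count_parameters(build_mtl_concat(20, profile, _pair_grouping(4), ARCH))
        base = count_parameters(build_mtl_all(20, profile, ARCH))
        # each of 4 heads gains (200-100) extra input weights x 3 classes
        assert concat - base == 4 * 100 * 3


class TestForwardBackward:
    def test_seeded_init_reproducible(self, small_cohort, tiny_arch):
        a = build_mtl_all(5, small_cohort.profile, tiny_arch, seed=9)
        b = build_mtl_all(5, small_cohort.profile, tiny_arch, seed=9)
        for wa, wb in zip(a.get_weights(), b.get_weights()):
            np.testing.assert_array_equal(wa, wb)

    def test_total_loss_is_sum_of_task_losses(self, encoded_splits, small_cohort, tiny_arch):
        tr, _, _ = encoded_splits
        model = build_mtl_all(tr.X.shape[1], small_cohort.profile, tiny_arch, seed=0)
        total, per_task, _ = model.loss_and_gradients(tr.X[:20], {t: v[:20] for t, v in tr.y.items()})
        assert total == pytest.approx(sum(per_task.values()), abs=1e-6)

    def test_gradients_match_finite_differences(self, small_cohort, tiny_arch):
        """Analytic backprop against central finite differences on a
        handful of parameters of every layer type."""
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, size=(8, 5))
        profile = small_cohort.profile
        y = {it.name: rng.integers(0, it.n_classes, 8) for it in profile.items}
        model = build_mtl_all(5, profile, tiny_arch, seed=1)
        _, _, grads = model.loss_and_gradients(X, y)
        params = model.parameters()
        eps = 1e-6
        for p_idx in range(len(params)):
            flat = params[p_idx].reshape(-1)
            for slot in (0, flat.size // 2):
                orig = flat[slot]
                flat[slot] = orig + eps
                up = sum(model.task_losses(X, y).values())
                flat[slot] = orig - eps
                down = sum(model.task_losses(X, y).values())
                flat[slot] = orig
                numeric = (up - down) / (2 * eps)
                assert grads[p_idx].reshape(-1)[slot] == pytest.approx(numeric, abs=1e-5)


class TestTraining:
    def test_lr_halving_schedule(self):
        cfg = TrainingConfig()
        assert cfg.lr_at(1) == 0.0005
        assert cfg.lr_at(15) == 0.0005
        assert cfg.lr_at(16) == 0.0005 / 2
        assert cfg.lr_at(31) == 0.0005 / 4

    def test_identical_seeds_identical_history(self, small_cohort, encoded_splits, tiny_arch, fast_cfg):
        tr, val, _ = encoded_splits
        hists = []
        for _ in range(2):
            model = build_mtl_all(tr.X.shape[1], small_cohort.profile, tiny_arch, seed=4)
            train(model, tr.X, tr.y, val.X, val.y, fast_cfg)
            hists.append(model.history)
        assert hists[0]["train_loss"] == hists[1]["train_loss"]
        assert hists[0]["val_loss"] == hists[1]["val_loss"]

    def test_early_stop_respects_min_epochs_and_best_weights(
        self, small_cohort, encoded_splits, tiny_arch
    ):
        tr, val, _ = encoded_splits
        cfg = TrainingConfig(max_epochs=40, patience=3, min_epochs=8, batch_size=16, seed=0)
        model = build_mtl_all(tr.X.shape[1], small_cohort.profile, tiny_arch, seed=4)
        train(model, tr.X, tr.y, val.X, val.y, cfg)
        hist = model.history
        assert hist["stop_epoch"] >= cfg.min_epochs
        assert hist["best_epoch"] == int(np.argmin(hist["val_loss"])) + 1
        # restored weights reproduce the minimal recorded validation loss
        val_loss = sum(model.task_losses(val.X, val.y).values())
        assert val_loss == pytest.approx(min(hist["val_loss"]), abs=1e-9)

    def test_separable_toy_reaches_perfect_f1(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, size=(200, 2))
        item = ItemSpec("a", (0, 5))
        y = {"a": (X[:, 0] > 0.5).astype(np.int64)}
        model = build_stl(2, item, ArchitectureConfig(h=2, r=16), seed=0)
        cfg = TrainingConfig(lr=0.2, lr_halving_period=50, max_epochs=150,
                             patience=150, min_epochs=5, seed=0)
        train(model, X[:150], {"a": y["a"][:150]}, X[150:], {"a": y["a"][150:]}, cfg)
        preds = model.predict(X[150:])
        assert task_f1(y["a"][150:], preds["a"], item) == pytest.approx(1.0)
        assert model.history["val_loss"][-1] < model.history["val_loss"][0]

    def test_nonfinite_loss_aborts(self, small_cohort, encoded_splits, tiny_arch, fast_cfg):
        tr, val, _ = encoded_splits
        model = build_mtl_all(tr.X.shape[1], small_cohort.profile, tiny_arch, seed=0)
        model.trunk[0].W[...] = np.nan
        with pytest.raises(RuntimeError, match="non-finite"):
            train(model, tr.X, tr.y, val.X, val.y, fast_cfg)


class TestTransfer:
    def test_trunk_and_branches_copied_heads_fresh(self, small_cohort, encoded_splits, tiny_arch, fast_cfg):
        tr, val, _ = encoded_splits
        profile = small_cohort.profile
        source = build_mtl_all(tr.X.shape[1], profile, tiny_arch, seed=2)
        train(source, tr.X, tr.y, val.X, val.y, fast_cfg)
        grouping = GroupingResult(
            M=3, groups=[SelectedGroup((0, 1), (0, 1), ()), SelectedGroup((1, 2), (2,), (1,))]
        )
        target = build_mtl_concat(tr.X.shape[1], profile, grouping, tiny_arch, seed=7)
        transfer_pretrained(source, target)
        for ls, lt in zip(source.trunk, target.trunk):
            np.testing.assert_array_equal(ls.W, lt.W)
        # branch activations identical on a fixed batch; only heads differ
        cs = source._forward(tr.X[:16])
        ct = target._forward(tr.X[:16])
        for name in profile.names:
            np.testing.assert_array_equal(cs["branch_out"][name], ct["branch_out"][name])
        assert target.heads[profile.names[0]].W.shape == (2 * tiny_arch.r, 3)

    def test_shape_mismatch_rejected(self, small_cohort, tiny_arch):
        profile = small_cohort.profile
        source = build_mtl_all(5, profile, tiny_arch, seed=0)
        target = build_mtl_all(6, profile, tiny_arch, seed=0)
        with pytest.raises(ValueError):
            transfer_pretrained(source, target)


class TestEnsembles:
    def test_ensemble_prediction_matches_owner_model(
        self, small_cohort, encoded_splits, tiny_arch, fast_cfg
    ):
        tr, val, te = encoded_splits
        profile = small_cohort.profile
        grouping = GroupingResult(
            M=3, groups=[SelectedGroup((0, 1), (0, 1), ()), SelectedGroup((1, 2), (2,), (1,))]
        )
        members = build_group_ensemble(tr.X.shape[1], profile, grouping, tiny_arch, seed=0)
        for m in members:
            train(m, tr.X, tr.y, val.X, val.y, fast_cfg)
        ens = TaskEnsemble(members)
        preds = ens.predict(te.X)
        for task, owner in ens.owner.items():
            np.testing.assert_array_equal(preds[task], owner.predict(te.X, tasks=(task,))[task])
        # secondary heads are not exposed at inference
        assert set(preds) == set(profile.names)

    def test_duplicate_primary_ownership_rejected(self, small_cohort, tiny_arch):
        profile = small_cohort.profile
        a = build_mtl_group(5, profile, (0, 1), (0, 1), tiny_arch)
        b = build_mtl_group(5, profile, (0, 2), (0, 2), tiny_arch)
        with pytest.raises(ValueError, match="owned by more than one"):
            TaskEnsemble([a, b])
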