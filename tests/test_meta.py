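"""Training stages: gradients, selective adaptation, episode sampling."""

import numpy as np
import pytest

import fewshot_synergy as fs
from fewshot_synergy import autodiff as ad
from fewshot_synergy.data import Episode, FewShotTask, group_by_cell_line
from fewshot_synergy.meta import (
    build_episode,
    fine_tune,
    inner_adapt,
    meta_train,
    mse_loss,
    outer_update,
    pretrain,
    zero_shot_predict,
    _task_query_loss,
)
from fewshot_synergy.model import init_state


@pytest.fixture(scope="module")
def toy_config():
    return fs.ModelConfig(
        gcn_dims=(8, 8, 8), cnn_channels=(2, 2), fd_hidden=6, fd_out=4,
        fc_out=4, head_hidden=6, dropout=0.0, alpha=0.05, beta=0.01,
    )


@pytest.fixture(scope="module")
def toy_world():
    return fs.make_world(
        fs.SyntheticWorldConfig(
            n_drugs=10, n_cell_lines=6, samples_per_cell_line=24, seed=21
        )
    )


def make_task(world, cell_line=None, K=4, Q=4, seed=0):
    pool = group_by_cell_line(world.dataset.samples)
    cl = cell_line or sorted(pool)[0]
    rng = np.random.default_rng(seed)
    return build_episode({cl: pool[cl]}, N=1, K=K, Q=Q, rng=rng).tasks[0]


def flat_params(state, keys):
    return np.concatenate([state.params[k].data.ravel() for k in keys])


class TestMseLoss:
    def test_matches_literal_loop_oracle(self, rng):
        pred = rng.normal(size=(9, 1))
        y = rng.normal(size=(9, 1))
        oracle = sum((y[i, 0] - pred[i, 0]) ** 2 for i in range(9)) / 9
        val = mse_loss(ad.constant(pred), y)
        assert abs(float(val.data) - oracle) < 1e-12


class TestPretrain:
    def test_zero_epochs_is_identity(self, toy_world, toy_config):
        state = init_state(toy_config, seed=0)
        out, _ = pretrain(toy_world.dataset, state, epochs=0)
        for k in state.params:
            assert np.array_equal(out.params[k].data, state.params[k].data)

    def test_empty_sample_list_rejected(self, toy_world, toy_config):
        empty = fs.SynergyDataset(
            graphs=toy_world.dataset.graphs, grids=toy_world.dataset.grids, samples=[]
        )
        with pytest.raises(ValueError, match="nonempty"):
            pretrain(empty, init_state(toy_config, seed=0), epochs=1)

    def test_no_pt_ablation_rejected(self, toy_world, toy_config):
        state = init_state(toy_config, seed=0, ablation="no_pt")
        with pytest.raises(ValueError, match="no_pt"):
            pretrain(toy_world.dataset, state, epochs=1)

    def test_single_sgd_step_moves_prediction_toward_target(self, toy_world, toy_config):
        ds = toy_world.dataset
        one = fs.SynergyDataset(graphs=ds.graphs, grids=ds.grids, samples=ds.samples[:1])
        state = init_state(toy_config, seed=1)
        s = one.samples[0]
        before = zero_shot_predict([s], state, ds.graphs, ds.grids)[0]
        out, _ = pretrain(one, state, epochs=1, optimizer="sgd", lr=1e-3)
        out.stage = "meta_trained"
        after = zero_shot_predict([s], out, ds.graphs, ds.grids)[0]
        assert abs(after - s.y) < abs(before - s.y)

    def test_loss_decreases_on_small_set(self, toy_world, toy_config):
        ds = toy_world.dataset
        sub = fs.SynergyDataset(graphs=ds.graphs, grids=ds.grids, samples=ds.samples[:20])
        out, log = pretrain(sub, init_state(toy_config, seed=2), epochs=40, seed=2)
        assert log.values()[-1] < log.values()[0]
        assert out.stage == "pretrained"


class TestBuildEpisode:
    def test_exact_capacity_pool_uses_every_sample(self, toy_world):
        pool = group_by_cell_line(toy_world.dataset.samples)
        trimmed = {cl: s[:8] for cl, s in list(pool.items())[:3]}
        ep = build_episode(trimmed, N=3, K=4, Q=4, rng=0)
        used = {id(s) for t in ep.tasks for s in t.support + t.query}
        assert len(used) == 24

    def test_same_seed_gives_identical_episode(self, toy_world):
        pool = group_by_cell_line(toy_world.dataset.samples)
        e1 = build_episode(pool, N=3, K=4, Q=4, rng=42)
        e2 = build_episode(pool, N=3, K=4, Q=4, rng=42)
        assert [t.cell_line for t in e1.tasks] == [t.cell_line for t in e2.tasks]
        for t1, t2 in zip(e1.tasks, e2.tasks):
            assert [s.pair for s in t1.support] == [s.pair for s in t2.support]
            assert [s.pair for s in t1.query] == [s.pair for s in t2.query]

    def test_capacity_error_names_requirement(self, toy_world):
        pool = group_by_cell_line(toy_world.dataset.samples)
        with pytest.raises(ValueError, match="cell lines"):
            build_episode(pool, N=50, K=4, Q=4, rng=0)
        with pytest.raises(ValueError, match="distinct drug pairs"):
            build_episode(pool, N=3, K=100, Q=100, rng=0)

    def test_cell_line_sampling_is_near_uniform(self, toy_world):
        pool = group_by_cell_line(toy_world.dataset.samples)
        n_lines = len(pool)
        rng = np.random.default_rng(7)
        counts = {cl: 0 for cl in pool}
        n_episodes, N = 600, 3
        for _ in range(n_episodes):
            for t in build_episode(pool, N=N, K=2, Q=2, rng=rng).tasks:
                counts[t.cell_line] += 1
        expected = n_episodes * N / n_lines
        for cl, c in counts.items():
            assert abs(c - expected) / (n_episodes * N) < 0.05

    def test_support_query_pair_disjoint(self, toy_world):
        pool = group_by_cell_line(toy_world.dataset.samples)
        ep = build_episode(pool, N=4, K=5, Q=5, rng=9)
        for t in ep.tasks:
            assert not ({s.pair for s in t.support} & {s.pair for s in t.query})


class TestInnerAdapt:
    def test_alpha_small_zero_loss_keeps_parameters(self, toy_world, toy_config):
        # if support predictions are exact the gradient vanishes
        state = init_state(toy_config, seed=3)
        task = make_task(toy_world)
        ds = toy_world.dataset
        pred = zero_shot_predict(task.support, state.with_flags(stage="meta_trained"),
                                 ds.graphs, ds.grids)
        exact = [
            fs.SynergySample(s.drug_a, s.drug_b, s.cell_line, float(p))
            for s, p in zip(task.support, pred)
        ]
        exact_task = FewShotTask(task.cell_line, exact, task.query)
        params, losses = inner_adapt(exact_task, state, ds.graphs, ds.grids)
        assert losses[0] < 1e-20
        for k in state.theta_p_keys():
            assert np.allclose(params[k].data, state.params[k].data, atol=1e-12)

    def test_selective_adaptation_theta_E_bit_identical(self, toy_world, toy_config):
        state = init_state(toy_config, seed=4)
        task = make_task(toy_world, K=4, Q=4)
        ds = toy_world.dataset
        params, _ = inner_adapt(task, state, ds.graphs, ds.grids)
        for k in state.theta_E_keys():
            assert params[k] is state.params[k]  # untouched tensors
        changed = [
            k for k in state.theta_p_keys()
            if not np.array_equal(params[k].data, state.params[k].data)
        ]
        assert changed  # the head actually moved

    def test_no_so_ablation_updates_theta_E(self, toy_world, toy_config):
        state = init_state(toy_config, seed=4, ablation="no_so")
        task = make_task(toy_world, K=4, Q=4)
        ds = toy_world.dataset
        params, _ = inner_adapt(task, state, ds.graphs, ds.grids)
        changed = [
            k for k in state.theta_E_keys()
            if not np.array_equal(params[k].data, state.params[k].data)
        ]
        assert changed

    def test_scalar_head_matches_closed_form(self):
        # one support sample, linear model y_hat = w*z: one inner step gives
        # w' = w - alpha * 2*(w*z - y)*z
        w0, z, y, alpha = 0.7, 1.3, 2.0, 0.05
        w = ad.parameter(np.array([[w0]]))
        pred = ad.matmul(ad.constant(np.array([[z]])), w)
        loss = mse_loss(pred, np.array([[y]]))
        (g,) = ad.grad(loss, [w])
        w_new = w0 - alpha * g.data[0, 0]
        closed = w0 - alpha * 2 * (w0 * z - y) * z
        assert abs(w_new - closed) < 1e-10

    def test_full_network_inner_gradient_matches_finite_differences(
        self, toy_world, toy_config
    ):
        state = init_state(toy_config, seed=5)
        task = make_task(toy_world, K=3, Q=3)
        ds = toy_world.dataset
        y_s = np.array([[s.y] for s in task.support])

        def support_loss():
            pred = fs.forward_scores(task.support, ds.graphs, ds.grids, state.params, state)
            return mse_loss(pred, y_s)

        keys = state.theta_p_keys()
        grads = ad.grad(support_loss(), [state.params[k] for k in keys])
        eps = 1e-5
        for k, g in zip(keys, grads):
            flat = state.params[k].data.ravel()
            for idx in [0, flat.size // 2, flat.size - 1]:
                orig = flat[idx]
                flat[idx] = orig + eps
                up = float(support_loss().data)
                flat[idx] = orig - eps
                dn = float(support_loss().data)
                flat[idx] = orig
                num = (up - dn) / (2 * eps)
                assert abs(num - g.data.ravel()[idx]) <= 1e-4 * max(1.0, abs(num))


class TestOuterUpdate:
    def test_beta_zero_leaves_state_unchanged(self, toy_world, toy_config):
        cfg = fs.ModelConfig(**{**toy_config.__dict__, "beta": 1e-300})
        state = init_state(cfg, seed=6)
        before = {k: v.data.copy() for k, v in state.params.items()}
        pool = group_by_cell_line(toy_world.dataset.samples)
        ep = build_episode(pool, N=2, K=3, Q=3, rng=1)
        outer_update(ep, state, toy_world.dataset.graphs, toy_world.dataset.grids,
                     training=False)
        for k in before:
            assert np.allclose(state.params[k].data, before[k], atol=1e-250)

    def test_no_ml_ablation_rejected(self, toy_world, toy_config):
        state = init_state(toy_config, seed=6, ablation="no_ml")
        pool = group_by_cell_line(toy_world.dataset.samples)
        ep = build_episode(pool, N=2, K=3, Q=3, rng=1)
        with pytest.raises(ValueError, match="no_ml"):
            outer_update(ep, state, toy_world.dataset.graphs, toy_world.dataset.grids)

    def test_quadratic_toy_matches_analytic_two_level_gradient(self):
        # model y_hat = w*z; support {(z_s, y_s)}, query {(z_q, y_q)}.
        # w' = w - a*2*z_s*(w*z_s - y_s); L_q(w') = (w'*z_q - y_q)^2
        # dL_q/dw = 2*(w'*z_q - y_q)*z_q*(1 - 2*a*z_s^2)
        w0, zs, ys, zq, yq, a = 0.4, 1.1, 0.9, -0.8, 0.3, 0.05
        w = ad.parameter(np.array([[w0]]))
        loss_s = mse_loss(ad.matmul(ad.constant([[zs]]), w), np.array([[ys]]))
        (gs,) = ad.grad(loss_s, [w], create_graph=True)
        w_ad = ad.sub(w, ad.mul(a, gs))
        loss_q = mse_loss(ad.matmul(ad.constant([[zq]]), w_ad), np.array([[yq]]))
        (gq,) = ad.grad(loss_q, [w])
        w_prime = w0 - a * 2 * zs * (w0 * zs - ys)
        analytic = 2 * (w_prime * zq - yq) * zq * (1 - 2 * a * zs**2)
        assert abs(gq.data[0, 0] - analytic) < 1e-8

    def test_full_network_outer_gradient_matches_finite_differences(
        self, toy_world, toy_config
    ):
        state = init_state(toy_config, seed=7)
        task = make_task(toy_world, K=3, Q=3, seed=5)
        ds = toy_world.dataset

        def query_loss_after_adaptation():
            return _task_query_loss(task, state, ds.graphs, ds.grids, create_graph=True)

        keys = ["embed.gcn.W1", "embed.fd.W2", "embed.fc.W", "head.W1", "head.W2"]
        grads = ad.grad(
            query_loss_after_adaptation(), [state.params[k] for k in keys]
        )
        eps = 1e-5
        for k, g in zip(keys, grads):
            flat = state.params[k].data.ravel()
            for idx in [0, flat.size // 2]:
                orig = flat[idx]
                flat[idx] = orig + eps
                up = float(query_loss_after_adaptation().data)
                flat[idx] = orig - eps
                dn = float(query_loss_after_adaptation().data)
                flat[idx] = orig
                num = (up - dn) / (2 * eps)
                assert abs(num - g.data.ravel()[idx]) <= 1e-3 * max(1e-6, abs(num))

    def test_episode_gradient_equals_sum_of_task_gradients(
        self, toy_world, toy_config
    ):
        # no cross-task leakage: the episode update equals accumulating
        # per-task query gradients computed independently from the same theta
        state = init_state(toy_config, seed=8)
        ds = toy_world.dataset
        pool = group_by_cell_line(ds.samples)
        ep = build_episode(pool, N=3, K=3, Q=3, rng=2)
        keys = sorted(state.params)

        per_task = {k: 0.0 for k in keys}
        for task in ep.tasks:
            lq = _task_query_loss(task, state, ds.graphs, ds.grids, create_graph=True)
            for k, g in zip(keys, ad.grad(lq, [state.params[k] for k in keys])):
                per_task[k] = per_task[k] + g.data
        before = {k: state.params[k].data.copy() for k in keys}
        outer_update(ep, state, ds.graphs, ds.grids, training=False)
        for k in keys:
            step = before[k] - state.params[k].data
            assert np.allclose(step, state.config.beta * per_task[k], atol=1e-10)


class TestMetaTrainAndFineTune:
    def test_zero_episodes_is_identity(self, toy_world, toy_config):
        state = init_state(toy_config, seed=9)
        out, _ = meta_train(toy_world.dataset, state, episodes=0, N=2, K=3, Q=3)
        for k in state.params:
            assert np.array_equal(out.params[k].data, state.params[k].data)

    def test_fixed_seed_reproducibility(self, toy_world, toy_config):
        state = init_state(toy_config, seed=10)
        out1, _ = meta_train(toy_world.dataset, state, episodes=5, N=2, K=3, Q=3, seed=3)
        out2, _ = meta_train(toy_world.dataset, state, episodes=5, N=2, K=3, Q=3, seed=3)
        for k in out1.params:
            assert np.array_equal(out1.params[k].data, out2.params[k].data)

    def test_query_loss_improves_over_training(self, toy_world, toy_config):
        state = init_state(toy_config, seed=11)
        out, log = meta_train(
            toy_world.dataset, state, episodes=120, N=3, K=5, Q=5, seed=4
        )
        vals = log.values()
        assert np.mean(vals[-30:]) < np.mean(vals[:30])
        assert out.stage == "meta_trained"

    def test_fine_tune_does_not_mutate_state(self, toy_world, toy_config):
        state = init_state(toy_config, seed=12).with_flags(stage="meta_trained")
        ds = toy_world.dataset
        task = make_task(toy_world, K=4, Q=4, seed=6)
        before = {k: v.data.copy() for k, v in state.params.items()}
        pred, adapted = fine_tune(task, state, ds.graphs, ds.grids)
        assert pred.shape == (4,)
        for k in before:
            assert np.array_equal(state.params[k].data, before[k])

    def test_no_ft_routes_to_zero_shot(self, toy_world, toy_config):
        state = init_state(toy_config, seed=13, ablation="no_ft")
        state.stage = "meta_trained"
        ds = toy_world.dataset
        task = make_task(toy_world, K=4, Q=4, seed=7)
        pred, _ = fine_tune(task, state, ds.graphs, ds.grids)
        zs = zero_shot_predict(task, state, ds.graphs, ds.grids)
        assert np.array_equal(pred, zs)

    def test_untrained_state_rejected_by_default(self, toy_world, toy_config):
        state = init_state(toy_config, seed=14)
        task = make_task(toy_world, K=4, Q=4)
        with pytest.raises(ValueError, match="stage"):
            fine_tune(task, state, toy_world.dataset.graphs, toy_world.dataset.grids)

    def test_zero_shot_predict_is_pure_and_repeatable(self, toy_world, toy_config):
        state = init_state(toy_config, seed=15).with_flags(stage="meta_trained")
        ds = toy_world.dataset
        task = make_task(toy_world, K=4, Q=4, seed=8)
        before = {k: v.data.copy() for k, v in state.params.items()}
        p1 = zero_shot_predict(task, state, ds.graphs, ds.grids)
        p2 = zero_shot_predict(task, state, ds.graphs, ds.grids)
        assert np.array_equal(p1, p2)
        for k in before:
            assert np.array_equal(state.params[k].data, before[k])

    def test_zero_shot_equals_forward_composition(self, toy_world, toy_config):
        state = init_state(toy_config, seed=16).with_flags(stage="meta_trained")
        ds = toy_world.dataset
        task = make_task(toy_world, K=4, Q=4, seed=9)
        direct = fs.forward_scores(
            task.query, ds.graphs, ds.grids, state.params, state
        ).data.ravel()
        assert np.array_equal(zero_shot_predict(task, state, ds.graphs, ds.grids), direct)
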