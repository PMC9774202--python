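"""Aggregation, similarity, submodel tuning, and the round loop."""

import numpy as np
import pytest

from fedprune.federation import (
    ClientState,
    FederatedConfig,
    GlobalModel,
    aggregate,
    client_similarity,
    local_update,
    run_federated,
    train_centralized,
    tune_submodels,
)
from fedprune.graph import build_plan, init_params, param_schema, resolve_indices, \
    slice_params
from fedprune.ir import Conv, Dense, GlobalAvgPool, ModelSpec
from fedprune.pruning import (
    FilterImportance,
    ResourceBudget,
    learn_importance,
    make_mask,
    prune,
)


def _full_mask(spec):
    return make_mask(spec, None, 0.0)


def _random_update(spec, seed):
    return init_params(spec, rng_seed=seed)


class TestAggregate:
    def test_rate_zero_equals_fedavg_oracle(self, tiny_spec, tiny_params):
        model = GlobalModel(tiny_spec, tiny_params)
        mask = _full_mask(tiny_spec)
        n = [30, 50, 20]
        subs = [_random_update(tiny_spec, s) for s in (1, 2, 3)]
        new = aggregate(model, [(mask, s, ni, 0.0) for s, ni in zip(subs, n)])
        w = np.array(n, dtype=float)
        for key in tiny_params:
            oracle = np.average(np.stack([s[key] for s in subs]), axis=0, weights=w)
            err = np.abs(new.params[key] - oracle)
            denom = np.maximum(np.abs(oracle), 1e-300)
            assert (err / denom).max() <= 1e-12
        assert new.round == model.round + 1

    def test_single_client_takes_its_values_exactly(self, tiny_spec, tiny_params,
                                                    tiny_data):
        imp = learn_importance(tiny_spec, tiny_params, tiny_data, epochs=1, rng_seed=0)
        _, sub_params, mask = prune(tiny_spec, tiny_params, imp, 0.5)
        shifted = {k: v + 1.0 for k, v in sub_params.items()}
        model = GlobalModel(tiny_spec, tiny_params)
        new = aggregate(model, [(mask, shifted, 10, mask.pruning_rate)])
        plan = build_plan(tiny_spec)
        for e in param_schema(plan):
            index = [np.arange(s, dtype=np.intp) for s in e.shape]
            for axis, ref in e.axis_refs.items():
                index[axis] = resolve_indices(ref, plan.groups, mask.as_dict())
            ix = np.ix_(*index) if len(e.shape) > 1 else (index[0],)
            assert (new.params[e.key][ix] == shifted[e.key]).all()

    def test_scaling_weights_follow_pruning_rates(self):
        # Two clients, equal n: rates 0 and 0.5 weight a shared coordinate 1 : 1.5;
        # a coordinate held only by the pruned client takes its value outright.
        spec = ModelSpec("m", (8, 8, 1), 2, [
            Conv("c", 4), GlobalAvgPool(), Dense("head", 2)])
        params = init_params(spec, 0)
        model = GlobalModel(spec, params)
        full = _full_mask(spec)
        imp = FilterImportance({"c": np.array([0.1, 0.2, 0.9, 0.8])})
        half = make_mask(spec, imp, 0.5)  # retains filters {2, 3}
        assert list(half.retained["c"]) == [2, 3]
        theta1 = {k: np.full_like(v, 1.0) for k, v in params.items()}
        theta2 = {k: np.full_like(v, 2.0) for k, v in
                  slice_params(spec, params, half.as_dict()).items()}
        new = aggregate(model, [(full, theta1, 100, 0.0), (half, theta2, 100, 0.5)])
        shared = new.params["c/W"][0, 0, 0, 2]
        only1 = new.params["c/W"][0, 0, 0, 0]
        assert shared == pytest.approx((1.0 * 1.0 + 1.5 * 2.0) / 2.5)
        assert only1 == pytest.approx(1.0)  # client 1 is its only holder

    def test_uncovered_coordinates_keep_previous_value(self):
        spec = ModelSpec("m", (8, 8, 1), 2, [
            Conv("c", 4), GlobalAvgPool(), Dense("head", 2)])
        params = init_params(spec, 0)
        model = GlobalModel(spec, params)
        imp = FilterImportance({"c": np.array([0.1, 0.2, 0.9, 0.8])})
        half = make_mask(spec, imp, 0.5)
        theta = {k: np.full_like(v, 7.0) for k, v in
                 slice_params(spec, params, half.as_dict()).items()}
        new = aggregate(model, [(half, theta, 10, 0.5)])
        # filters 0 and 1 were retained by nobody
        assert (new.params["c/W"][..., [0, 1]] == params["c/W"][..., [0, 1]]).all()
        assert (new.params["c/gamma"][[0, 1]] == params["c/gamma"][[0, 1]]).all()
        assert (new.params["c/W"][..., [2, 3]] == 7.0).all()

    def test_no_updates_rejected(self, tiny_spec, tiny_params):
        with pytest.raises(ValueError):
            aggregate(GlobalModel(tiny_spec, tiny_params), [])

    def test_shape_mismatch_rejected(self, tiny_spec, tiny_params):
        model = GlobalModel(tiny_spec, tiny_params)
        mask = _full_mask(tiny_spec)
        bad = {k: v[..., :1] if v.ndim > 1 else v for k, v in tiny_params.items()}
        with pytest.raises(ValueError, match="shape|mask"):
            aggregate(model, [(mask, bad, 10, 0.0)])


class TestSimilarity:
    def test_identical_importances_have_unit_similarity(self):
        imp = FilterImportance({"a": np.array([1.0, 2.0]), "b": np.array([3.0, 1.0])})
        sim = client_similarity([imp, imp])
        assert sim[0, 1] == pytest.approx(1.0)
        assert (np.diag(sim) == 1.0).all()

    def test_orthogonal_importances_have_zero_similarity(self):
        a = FilterImportance({"g": np.array([1.0, 0.0])})
        b = FilterImportance({"g": np.array([0.0, 1.0])})
        assert client_similarity([a, b])[0, 1] == pytest.approx(0.0)

    def test_matrix_matches_brute_force_cosine(self, rng):
        imps = [FilterImportance({"a": rng.random(5), "b": rng.random(3)})
                for _ in range(3)]
        sim = client_similarity(imps)
        for i in range(3):
            for j in range(3):
                vi = imps[i].concat(normalize=True)
                vj = imps[j].concat(normalize=True)
                expected = float(np.dot(vi, vj) /
                                 (np.linalg.norm(vi) * np.linalg.norm(vj)))
                assert sim[i, j] == pytest.approx(expected)
        assert (sim == sim.T).all()
        assert sim.min() >= -1.0 and sim.max() <= 1.0

    def test_zero_norm_importance_rejected(self):
        bad = FilterImportance({"g": np.zeros(3)})
        with pytest.raises(ValueError, match="zero-norm"):
            client_similarity([bad])


class TestTuneSubmodels:
    def _setup(self, scores_list, rate=0.5):
        spec = ModelSpec("m", (8, 8, 1), 2, [
            Conv("c", 4), GlobalAvgPool(), Dense("head", 2)])
        imps = [FilterImportance({"c": np.asarray(s, dtype=float)})
                for s in scores_list]
        masks = [make_mask(spec, imp, rate) for imp in imps]
        return spec, imps, masks

    def test_dissimilar_clients_keep_their_masks(self):
        spec, imps, masks = self._setup([[1, 0, 0, 0.1], [0, 1, 0.1, 0]])
        sim = client_similarity(imps)
        tuned = tune_submodels(spec, masks, imps, sim,
                               [ResourceBudget()] * 2, tau=0.99)
        for a, b in zip(masks, tuned):
            assert (a.retained["c"] == b.retained["c"]).all()

    def test_identical_clients_converge_to_identical_masks(self):
        spec, imps, masks = self._setup([[0.2, 0.9, 0.4, 0.6], [0.2, 0.9, 0.4, 0.6]])
        sim = client_similarity(imps)
        tuned = tune_submodels(spec, masks, imps, sim,
                               [ResourceBudget()] * 2, tau=0.9)
        assert (tuned[0].retained["c"] == tuned[1].retained["c"]).all()

    def test_nested_rates_give_nested_masks(self):
        spec = ModelSpec("m", (8, 8, 1), 2, [
            Conv("c", 8), GlobalAvgPool(), Dense("head", 2)])
        base = np.array([0.8, 0.7, 0.9, 0.1, 0.2, 0.3, 0.85, 0.05])
        imps = [FilterImportance({"c": base}),
                FilterImportance({"c": base + 0.01})]
        masks = [make_mask(spec, imps[0], 0.25), make_mask(spec, imps[1], 0.5)]
        sim = client_similarity(imps)
        tuned = tune_submodels(spec, masks, imps, sim, [ResourceBudget()] * 2, tau=0.9)
        sparse = set(tuned[1].retained["c"].tolist())
        dense = set(tuned[0].retained["c"].tolist())
        assert sparse <= dense

    def test_invalid_tau_rejected(self):
        spec, imps, masks = self._setup([[1, 0, 0, 0]])
        with pytest.raises(ValueError):
            tune_submodels(spec, masks, imps, np.eye(1), [ResourceBudget()], tau=1.5)


class TestLocalUpdate:
    def test_zero_lr_returns_sliced_globals(self, tiny_spec, tiny_params, tiny_data):
        client = ClientState(0, tiny_data, mask=_full_mask(tiny_spec))
        model = GlobalModel(tiny_spec, tiny_params)
        out, _ = local_update(client, model, epochs=2, lr=0.0,
                              rng_seed=np.random.default_rng(0))
        for k in tiny_params:
            assert (out[k] == tiny_params[k]).all()

    def test_zero_epochs_returns_sliced_globals(self, tiny_spec, tiny_params, tiny_data):
        client = ClientState(0, tiny_data, mask=_full_mask(tiny_spec))
        model = GlobalModel(tiny_spec, tiny_params)
        out, loss = local_update(client, model, epochs=0, lr=0.5)
        assert loss == 0.0
        for k in tiny_params:
            assert (out[k] == tiny_params[k]).all()

    def test_one_full_batch_epoch_decreases_loss(self, tiny_spec, tiny_params, tiny_data):
        from fedprune.nn import Network, softmax_cross_entropy

        X, y = tiny_data
        client = ClientState(0, tiny_data, mask=_full_mask(tiny_spec))
        model = GlobalModel(tiny_spec, tiny_params)
        before = softmax_cross_entropy(Network(tiny_spec, tiny_params).forward(X), y)[0]
        out, _ = local_update(client, model, epochs=1, lr=0.01,
                              batch_size=len(X), momentum=0.0)
        after = softmax_cross_entropy(Network(tiny_spec, out).forward(X), y)[0]
        assert after <= before


class TestRoundLoop:
    def test_zero_rounds_returns_initial_model(self, tiny_spec, tiny_params, tiny_data):
        cfg = FederatedConfig(rounds=0)
        model, logs = run_federated(tiny_spec, tiny_params, [tiny_data], tiny_data, cfg)
        assert logs == []
        assert model.round == 0
        for k in tiny_params:
            assert (model.params[k] == tiny_params[k]).all()

    def test_single_client_equals_centralized(self, tiny_spec, tiny_params, tiny_data):
        cfg = FederatedConfig(rounds=2, local_steps=None, local_epochs=1, lr=0.05,
                              batch_size=16, seed=5)
        fed_model, fed_logs = run_federated(
            tiny_spec, tiny_params, [tiny_data], tiny_data, cfg)
        cen_model, cen_logs = train_centralized(
            tiny_spec, tiny_params, tiny_data, tiny_data, cfg)
        for k in tiny_params:
            assert (fed_model.params[k] == cen_model.params[k]).all()
        assert [l.accuracy for l in fed_logs] == [l.accuracy for l in cen_logs]

    def test_budgeted_clients_get_pruned_submodels(self, tiny_spec, tiny_params,
                                                   tiny_data):
        from fedprune.graph import count_costs

        full = count_costs(tiny_spec)
        budgets = [ResourceBudget(),
                   ResourceBudget(max_params=int(full["params"] * 0.6))]
        X, y = tiny_data
        shards = [(X[::2], y[::2]), (X[1::2], y[1::2])]
        cfg = FederatedConfig(rounds=2, local_steps=2, lr=0.05, batch_size=16, seed=1)
        model, logs = run_federated(tiny_spec, tiny_params, shards, tiny_data,
                                    cfg, budgets)
        assert logs[-1].client_rates[0] == 0.0
        assert logs[-1].client_rates[1] > 0.0
        assert len(logs) == 2
        assert np.asarray(logs[-1].similarity).shape == (2, 2)

    def test_empty_shard_rejected(self, tiny_spec, tiny_params, tiny_data):
        empty = (np.zeros((0, 16, 16, 3)), np.zeros(0, dtype=int))
        with pytest.raises(ValueError, match="empty"):
            run_federated(tiny_spec, tiny_params, [empty], tiny_data,
                          FederatedConfig(rounds=1))
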