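import numpy as np
import pytest

from molprompt.finetune import (
    FinetuneConfig,
    GRID_FALLBACK,
    PromptWeights,
    composite_representation,
    finetune,
    init_prompt_weights_rogi,
    random_split,
    scaffold_split,
    simplex_grid,
    weights_from_logits,
)
from molprompt.qspr_probe import rogi


class TestPromptWeights:
    def test_simplex_validation(self):
        PromptWeights(np.array([0.2, 0.3, 0.5]))
        with pytest.raises(ValueError):
            PromptWeights(np.array([0.5, 0.5, 0.5]))
        with pytest.raises(ValueError):
            PromptWeights(np.array([-0.1, 0.6, 0.5]))
        with pytest.raises(ValueError):
            PromptWeights(np.array([0.5, 0.5]))

    def test_logits_roundtrip(self):
        w = PromptWeights(np.array([0.2, 0.3, 0.5]))
        assert np.allclose(weights_from_logits(w.logits()), w.weights, atol=1e-6)

    def test_uniform(self):
        assert np.allclose(PromptWeights.uniform().weights, 1 / 3)


class TestCompositeRepresentation:
    def test_weighted_combination(self):
        rng = np.random.default_rng(0)
        reprs = [rng.normal(size=(4, 6)) for _ in range(3)]
        w = PromptWeights(np.array([0.5, 0.25, 0.25]))
        comp = composite_representation(reprs, w)
        assert np.allclose(comp, 0.5 * reprs[0] + 0.25 * reprs[1] + 0.25 * reprs[2])

    def test_one_hot_selects_channel(self):
        rng = np.random.default_rng(1)
        reprs = [rng.normal(size=(3, 4)) for _ in range(3)]
        comp = composite_representation(reprs, PromptWeights(np.array([0.0, 1.0, 0.0])))
        assert np.allclose(comp, reprs[1])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            composite_representation(
                [np.zeros((2, 3)), np.zeros((2, 4)), np.zeros((2, 3))],
                PromptWeights.uniform(),
            )


class TestSimplexGrid:
    def test_grid_covers_simplex_at_resolution(self):
        g = simplex_grid(0.1)
        assert len(g) == 66
        assert np.allclose(g.sum(axis=1), 1.0)
        assert (g >= 0).all()
        # vertices present
        for v in np.eye(3):
            assert any(np.allclose(row, v) for row in g)

    def test_grid_points_unique(self):
        g = np.round(GRID_FALLBACK, 10)
        assert len({tuple(r) for r in g}) == len(g)


def _planted_channels(seed=0, n=80, d=8):
    """Channel 1 carries a smooth linear signal; channels 0 and 2 are noise."""
    rng = np.random.default_rng(seed)
    signal = rng.normal(size=(n, d))
    labels = signal @ rng.normal(size=d)
    reprs = [rng.normal(size=(n, d)), signal, rng.normal(size=(n, d))]
    return reprs, labels


class TestRogiInit:
    def test_budget_zero_returns_uniform(self):
        reprs, labels = _planted_channels()
        w = init_prompt_weights_rogi(reprs, labels, budget=0)
        assert np.allclose(w.weights, 1 / 3)

    def test_grid_search_recovers_planted_channel(self):
        reprs, labels = _planted_channels(seed=3)
        w = init_prompt_weights_rogi(reprs, labels, budget=100, seed=0)
        assert int(np.argmax(w.weights)) == 1

    def test_grid_result_is_argmin_over_candidates(self):
        reprs, labels = _planted_channels(seed=4, n=40)
        w = init_prompt_weights_rogi(reprs, labels, budget=100, seed=0)
        chosen = rogi(composite_representation(reprs, w), labels)[0]
        for cand in GRID_FALLBACK:
            other = rogi(composite_representation(reprs, PromptWeights(cand)), labels)[0]
            assert chosen <= other + 1e-12

    def test_small_budget_gp_search_runs_and_prefers_signal(self):
        reprs, labels = _planted_channels(seed=5)
        w = init_prompt_weights_rogi(reprs, labels, budget=12, seed=0)
        assert abs(w.weights.sum() - 1.0) < 1e-9
        uniform_r = rogi(composite_representation(reprs, PromptWeights.uniform()),
                         labels)[0]
        found_r = rogi(composite_representation(reprs, w), labels)[0]
        assert found_r <= uniform_r + 1e-12

    def test_constant_labels_fall_back_to_uniform(self):
        reprs, _ = _planted_channels()
        with pytest.warns(UserWarning, match="constant"):
            w = init_prompt_weights_rogi(reprs, np.ones(80), budget=100)
        assert np.allclose(w.weights, 1 / 3)


class TestSplits:
    def test_random_split_partitions(self):
        tr, va, te = random_split(100, seed=0)
        all_idx = np.concatenate([tr, va, te])
        assert sorted(all_idx) == list(range(100))
        assert len(va) == 10 and len(te) == 10

    def test_scaffold_split_keeps_groups_intact(self, small_corpus):
        tr, va, te = scaffold_split(small_corpus)
        assert sorted(np.concatenate([tr, va, te])) == list(range(len(small_corpus)))
        buckets = {}
        for name, idx in (("tr", tr), ("va", va), ("te", te)):
            for i in idx:
                scaf = small_corpus[i].scaffold_smiles
                assert buckets.setdefault(scaf, name) == name

    def test_scaffold_split_deterministic(self, small_corpus):
        a = scaffold_split(small_corpus)
        b = scaffold_split(small_corpus)
        for x, y in zip(a, b):
            assert (x == y).all()


@pytest.fixture(scope="module")
def result(pretrained, small_labels):
    ckpt, data = pretrained
    tr, va, _ = random_split(len(data.records), seed=0)
    cfg = FinetuneConfig(epochs=8, seed=0, rogi_init_budget=0,
                         snapshot_epochs=(0, 8))
    return finetune(ckpt, data, small_labels, tr, va, cfg), va


class TestFinetune:

    def test_aggregation_frozen_bit_identical(self, result):
        res, _ = result
        assert set(res.aggregation_before) == set(res.aggregation_after)
        for k in res.aggregation_before:
            assert (res.aggregation_before[k] == res.aggregation_after[k]).all()

    def test_prompt_weights_stay_on_simplex(self, result):
        res, _ = result
        for entry in res.metric_log:
            w = np.array(entry["prompt_weights"])
            assert abs(w.sum() - 1.0) < 1e-9 and (w >= 0).all()

    def test_training_loss_decreases(self, result):
        res, _ = result
        losses = [e["train_loss"] for e in res.metric_log if e["epoch"] >= 1]
        assert losses[-1] < losses[0]

    def test_snapshots_taken_at_configured_epochs(self, result, pretrained):
        res, _ = result
        _, data = pretrained
        assert set(res.snapshots) == {0, 8}
        for X in res.snapshots.values():
            assert X.shape[0] == len(data.records)
        assert not np.allclose(res.snapshots[0], res.snapshots[8])

    def test_metric_log_covers_all_epochs(self, result):
        res, _ = result
        assert [e["epoch"] for e in res.metric_log] == list(range(9))

    def test_classification_task_runs(self, pretrained, small_labels):
        ckpt, data = pretrained
        tr, va, _ = random_split(len(data.records), seed=1)
        y = (small_labels > np.median(small_labels)).astype(float)
        cfg = FinetuneConfig(task="classification", epochs=2, seed=1,
                             snapshot_epochs=())
        res = finetune(ckpt, data, y, tr, va, cfg)
        accs = [e["val_metric"] for e in res.metric_log]
        assert all(0.0 <= a <= 1.0 for a in accs)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FinetuneConfig(task="ranking")
        with pytest.raises(ValueError):
            FinetuneConfig(rogi_init_budget=-1)
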