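import itertools

import numpy as np
import pytest

from molprompt.chem_graph import BitFingerprint, parse_smiles
from molprompt.qspr_probe import (
    CliffPairSet,
    cliff_noncliff_ratio,
    default_n_clusters,
    identify_cliff_pairs,
    kmeans_labels,
    probe_timeline,
    rand_index,
    rogi,
    structural_similarity,
)


def brute_force_rogi(points: np.ndarray, labels: np.ndarray, n_grid: int = 20001):
    """Reference ROGI: explicit complete-linkage flat clusterings over a dense
    threshold grid, trapezoid-free left-Riemann sum on the step function."""
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import pdist

    y = labels.astype(np.float64)
    y = (y - y.min()) / (y.max() - y.min()) if y.max() > y.min() else np.zeros_like(y)
    d = pdist(np.atleast_2d(points).astype(np.float64))
    if d.max() > 0:
        d = d / d.max()
    Z = linkage(d, method="complete")
    n = len(y)

    def sigma_at(t):
        cl = fcluster(Z, t=t, criterion="distance")
        protos, weights = [], []
        for c in np.unique(cl):
            members = y[cl == c]
            protos.append(members.mean())
            weights.append(len(members))
        protos, weights = np.array(protos), np.array(weights, dtype=float)
        mu = (protos * weights).sum() / weights.sum()
        return np.sqrt(((protos - mu) ** 2 * weights).sum() / weights.sum())

    # merge heights define the breakpoints of the step function; integrate
    # exactly between them instead of on a grid
    heights = sorted({0.0, 1.0, *(min(h, 1.0) for h in Z[:, 2])})
    sigma0 = sigma_at(0.0)
    total = 0.0
    for a, b in zip(heights, heights[1:]):
        total += (b - a) * 2.0 * (sigma0 - sigma_at(a))
    return total


class TestRogi:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(30):
            n = int(rng.integers(4, 21))
            X = rng.normal(size=(n, 3))
            y = rng.normal(size=n)
            fast, _ = rogi(X, y)
            slow = brute_force_rogi(X, y)
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_two_point_endpoints(self):
        # maximal cliff: identical points (distance 0) with distinct labels
        v, _ = rogi(np.array([[0.0], [0.0]]), [0.0, 1.0])
        assert v == pytest.approx(1.0)
        # smooth: the label difference sits at the full distance range
        v, _ = rogi(np.array([[0.0], [1.0]]), [0.0, 1.0])
        assert v == pytest.approx(0.0)
        # identical labels: sigma_0 = 0, perfectly smooth
        v, _ = rogi(np.array([[0.0], [1.0]]), [3.0, 3.0])
        assert v == pytest.approx(0.0)

    def test_bounded_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            X = rng.normal(size=(15, 4))
            y = rng.normal(size=15)
            v, _ = rogi(X, y)
            assert 0.0 <= v <= 1.0

    def test_accepts_fingerprints(self):
        fps = [BitFingerprint(frozenset({i, i + 1}), 16, 2) for i in range(6)]
        v, curve = rogi(fps, np.arange(6.0))
        assert 0.0 <= v <= 1.0 and curve[0][0] == 0.0

    def test_label_scale_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        v1, _ = rogi(X, y)
        v2, _ = rogi(X, 100.0 * y + 7.0)
        assert v1 == pytest.approx(v2)

    def test_rejects_single_point(self):
        with pytest.raises(ValueError):
            rogi(np.zeros((1, 3)), [1.0])


def brute_force_rand(a, b):
    agree, total = 0, 0
    for i, j in itertools.combinations(range(len(a)), 2):
        total += 1
        agree += (a[i] == a[j]) == (b[i] == b[j])
    return agree / total


class TestRandIndex:
    def test_worked_examples(self):
        assert rand_index([0, 0, 1], [0, 1, 1]) == pytest.approx(1 / 3)
        assert rand_index([0, 0, 0], [0, 1, 2]) == pytest.approx(0.0)
        assert rand_index([0, 1, 0, 1], [5, 9, 5, 9]) == 1.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(2, 51))
            a = rng.integers(0, 4, n)
            b = rng.integers(0, 4, n)
            assert rand_index(a, b) == pytest.approx(brute_force_rand(a, b))

    def test_symmetry(self):
        a, b = [0, 1, 1, 2], [1, 1, 0, 0]
        assert rand_index(a, b) == rand_index(b, a)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rand_index([0, 1], [0, 1, 2])


class TestCliffPairs:
    def _pair(self):
        # chloro/bromo analogs of the same scaffold: matched by consensus sim
        return [parse_smiles("Clc1ccccc1"), parse_smiles("Brc1ccccc1")]

    def test_identical_structures_always_matched(self):
        mols = [parse_smiles("Cc1ccccc1"), parse_smiles("Cc1ccccc1")]
        pairs = identify_cliff_pairs(mols, [1.0, 100.0])
        assert pairs.cliff_pairs == [(0, 1)]

    def test_fold_threshold_splits_cliff_from_noncliff(self):
        mols = self._pair()
        assert structural_similarity(*mols) >= 0.9
        cliff = identify_cliff_pairs(mols, [1.0, 10.0])
        non = identify_cliff_pairs(mols, [1.0, 9.9])
        assert cliff.cliff_pairs == [(0, 1)] and cliff.noncliff_pairs == []
        assert non.noncliff_pairs == [(0, 1)] and non.cliff_pairs == []

    def test_dissimilar_molecules_never_pair(self):
        mols = [parse_smiles("C1CCCCC1CCCCN"), parse_smiles("Brc1ccc2ncccc2c1")]
        pairs = identify_cliff_pairs(mols, [1.0, 1000.0])
        assert pairs.cliff_pairs == [] and pairs.noncliff_pairs == []

    def test_nonpositive_potency_rejected(self):
        with pytest.raises(ValueError):
            identify_cliff_pairs(self._pair(), [0.0, 1.0])

    def test_matches_brute_force_on_corpus(self, small_corpus, small_labels):
        from molprompt.synthetic_fixtures import to_potency

        mols = small_corpus[:50]
        pot = to_potency(small_labels[:50])
        got = identify_cliff_pairs(mols, pot)
        cliff, non = [], []
        for i, j in itertools.combinations(range(len(mols)), 2):
            if structural_similarity(mols[i], mols[j]) >= 0.9:
                fold = max(pot[i], pot[j]) / min(pot[i], pot[j])
                (cliff if fold >= 10.0 else non).append((i, j))
        assert got.cliff_pairs == cliff and got.noncliff_pairs == non
        assert len(cliff) + len(non) > 0  # the check must not be vacuous


class TestCliffRatio:
    def test_worked_example(self):
        X = np.array([[0.0], [3.0], [10.0], [11.0]])
        pairs = CliffPairSet([(0, 1)], [(2, 3)], 0.9, 10.0)
        assert cliff_noncliff_ratio(X, pairs) == pytest.approx(3.0)

    def test_undefined_when_a_side_is_empty(self):
        X = np.zeros((3, 2))
        assert cliff_noncliff_ratio(X, CliffPairSet([], [(0, 1)], 0.9, 10.0)) is None
        assert cliff_noncliff_ratio(X, CliffPairSet([(0, 1)], [], 0.9, 10.0)) is None


class TestTimeline:
    def test_reports_shape_and_shift_baseline(self):
        rng = np.random.default_rng(4)
        fps = [BitFingerprint(frozenset(map(int, rng.integers(0, 64, 5))), 64, 2)
               for _ in range(30)]
        labels = rng.normal(size=30)
        snaps = [("epoch0", rng.normal(size=(30, 8))),
                 ("epoch1", rng.normal(size=(30, 8)))]
        reports = probe_timeline(snaps, fps, labels, seed=0)
        assert [r.timestamp for r in reports] == ["epoch0", "epoch1"]
        assert reports[0].shift_rand == pytest.approx(1.0)
        for r in reports:
            assert 0.0 <= r.rogi <= 1.0 and 0.0 <= r.rand_index <= 1.0

    def test_mismatched_snapshot_rejected(self):
        fps = [BitFingerprint(frozenset({i}), 16, 2) for i in range(5)]
        with pytest.raises(ValueError):
            probe_timeline([("a", np.zeros((4, 2)))], fps, np.zeros(5))

    def test_default_cluster_count(self):
        assert default_n_clusters(10) == 2
        assert default_n_clusters(200) == 8

    def test_kmeans_deterministic(self):
        X = np.random.default_rng(5).normal(size=(40, 3))
        assert (kmeans_labels(X, 3, seed=1) == kmeans_labels(X, 3, seed=1)).all()
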