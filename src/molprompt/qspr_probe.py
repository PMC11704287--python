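"""Structure-activity landscape and representation-robustness metrics.

* **ROGI** (roughness index): sweep a complete-linkage clustering threshold t
  over the normalized distance range [0, 1]; at each threshold compute the
  size-weighted standard deviation sigma_t of the cluster prototype labels
  (prototype = mean label of members).  sigma_t decreases monotonically from
  sigma_0 (all singletons) to 0 (one cluster), and

      ROGI = integral_0^1  2 * (sigma_0 - sigma_t) dt

  evaluated exactly by piecewise-constant integration over merge events.
  Labels are min-max normalized and distances max-normalized, so ROGI lies in
  [0, 1]; rough (cliff-rich) landscapes lose dispersion early and score high.

* **Rand index** between a fingerprint clustering and a representation
  clustering (same k), as a proxy for structural-knowledge retention, and
  between per-epoch clusterings as a representation-shift proxy.

* **Activity-cliff matched molecular pairs**: pairs passing a structural
  similarity threshold are "matched"; matched pairs whose potencies differ by
  at least a fold threshold are cliff pairs, the rest non-cliff.  Similarity
  is the maximum of whole-molecule fingerprint Tanimoto, scaffold fingerprint
  Tanimoto (only when both scaffolds are non-empty), and normalized
  string-edit similarity of the canonical SMILES.

* **Cliff/non-cliff distance ratio**: mean representation distance over cliff
  pairs divided by the mean over non-cliff pairs; an ideal landscape-aware
  representation keeps cliff pairs relatively far apart (ratio > 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import edlib
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import rand_score

from .chem_graph import BitFingerprint, MoleculeRecord, tanimoto

DEFAULT_SIM_THRESHOLD = 0.9
DEFAULT_FOLD_THRESHOLD = 10.0


@dataclass
class CliffPairSet:
    cliff_pairs: List[Tuple[int, int]]
    noncliff_pairs: List[Tuple[int, int]]
    similarity_threshold: float
    fold_threshold: float


@dataclass
class LandscapeReport:
    timestamp: str
    rogi: float
    sigma_curve: List[Tuple[float, float]]
    rand_index: Optional[float] = None
    shift_rand: Optional[float] = None
    cliff_noncliff_ratio: Optional[float] = None


# --------------------------------------------------------------------------
# ROGI
# --------------------------------------------------------------------------

def _normalized_distance_matrix(points) -> np.ndarray:
    """Condensed pairwise distances scaled to [0, 1]."""
    if isinstance(points, np.ndarray):
        d = pdist(np.atleast_2d(points).astype(np.float64))
    elif points and isinstance(points[0], BitFingerprint):
        d = np.array([1.0 - tanimoto(a, b) for a, b in combinations(points, 2)])
    else:
        d = pdist(np.asarray(points, dtype=np.float64))
    mx = d.max() if d.size else 0.0
    return d / mx if mx > 0 else d


def _normalize_labels(labels: np.ndarray) -> np.ndarray:
    lo, hi = labels.min(), labels.max()
    if hi == lo:
        return np.zeros_like(labels)
    return (labels - lo) / (hi - lo)


def rogi(points, labels: Sequence[float]) -> Tuple[float, List[Tuple[float, float]]]:
    """Roughness index of a labeled point set.

    `points` is either an (n, d) representation matrix or a list of
    :class:`BitFingerprint` (Tanimoto distances).  Returns (rogi, sigma_curve)
    where sigma_curve is the list of (threshold, sigma_t) steps starting at
    (0, sigma_0).
    """
    y = np.asarray(labels, dtype=np.float64)
    n = len(y)
    if n < 2:
        raise ValueError("ROGI needs at least two points")
    y = _normalize_labels(y)
    dist = _normalized_distance_matrix(points)

    sizes = {i: 1 for i in range(n)}
    means = {i: y[i] for i in range(n)}
    total_mean = y.mean()
    s2 = float((y**2).sum())  # sum of n_c * m_c^2 over clusters
    sigma0 = float(np.sqrt(max(s2 / n - total_mean**2, 0.0)))
    curve: List[Tuple[float, float]] = [(0.0, sigma0)]

    Z = linkage(dist, method="complete")
    for step, (c1, c2, height, _) in enumerate(Z):
        c1, c2 = int(c1), int(c2)
        n1, n2 = sizes.pop(c1), sizes.pop(c2)
        m1, m2 = means.pop(c1), means.pop(c2)
        m = (n1 * m1 + n2 * m2) / (n1 + n2)
        new = n + step
        sizes[new] = n1 + n2
        means[new] = m
        s2 += (n1 + n2) * m**2 - n1 * m1**2 - n2 * m2**2
        sigma = float(np.sqrt(max(s2 / n - total_mean**2, 0.0)))
        curve.append((float(min(height, 1.0)), sigma))

    value = 0.0
    for (t_a, sig_a), (t_b, _) in zip(curve, curve[1:]):
        value += (t_b - t_a) * 2.0 * (sigma0 - sig_a)
    t_last, sig_last = curve[-1]
    value += (1.0 - t_last) * 2.0 * (sigma0 - sig_last)
    return float(value), curve


# --------------------------------------------------------------------------
# Rand index and clusterings
# --------------------------------------------------------------------------

def rand_index(clustering_a: Sequence[int], clustering_b: Sequence[int]) -> float:
    """Fraction of point pairs on which two clusterings agree."""
    if len(clustering_a) != len(clustering_b):
        raise ValueError("clusterings must label the same points")
    if len(clustering_a) < 2:
        raise ValueError("need at least two points")
    return float(rand_score(list(clustering_a), list(clustering_b)))


def kmeans_labels(X: np.ndarray, n_clusters: int, seed: int = 0) -> np.ndarray:
    """Deterministic k-means partition used for the Rand-index probes."""
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    return km.fit_predict(np.asarray(X, dtype=np.float64))


def default_n_clusters(n_points: int) -> int:
    return max(2, n_points // 25)


# --------------------------------------------------------------------------
# Activity cliffs
# --------------------------------------------------------------------------

def _edit_similarity(a: str, b: str) -> float:
    if not a and not b:
        return 1.0
    dist = edlib.align(a, b)["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def structural_similarity(rec_a: MoleculeRecord, rec_b: MoleculeRecord) -> float:
    """Consensus similarity: max of fingerprint Tanimoto, scaffold Tanimoto
    (both scaffolds non-empty), and SMILES edit similarity."""
    sims = [
        tanimoto(rec_a.fingerprint, rec_b.fingerprint),
        _edit_similarity(rec_a.smiles_canonical, rec_b.smiles_canonical),
    ]
    if rec_a.scaffold_smiles and rec_b.scaffold_smiles:
        sims.append(tanimoto(rec_a.scaffold_fingerprint, rec_b.scaffold_fingerprint))
    return max(sims)


def identify_cliff_pairs(
    mols: Sequence[MoleculeRecord],
    potencies: Sequence[float],
    sim_threshold: float = DEFAULT_SIM_THRESHOLD,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> CliffPairSet:
    """Partition matched molecular pairs into cliff and non-cliff sets."""
    pot = np.asarray(potencies, dtype=np.float64)
    if (pot <= 0).any():
        raise ValueError("potencies must be positive for fold ratios")
    cliff, noncliff = [], []
    for i, j in combinations(range(len(mols)), 2):
        if structural_similarity(mols[i], mols[j]) < sim_threshold:
            continue
        fold = max(pot[i], pot[j]) / min(pot[i], pot[j])
        (cliff if fold >= fold_threshold else noncliff).append((i, j))
    return CliffPairSet(cliff, noncliff, sim_threshold, fold_threshold)


def cliff_noncliff_ratio(
    representations: np.ndarray, pairs: CliffPairSet
) -> Optional[float]:
    """Mean cliff-pair distance / mean non-cliff-pair distance; None if either
    list is empty (the ratio is undefined)."""
    if not pairs.cliff_pairs or not pairs.noncliff_pairs:
        return None
    X = np.asarray(representations, dtype=np.float64)
    d_cliff = np.mean([np.linalg.norm(X[i] - X[j]) for i, j in pairs.cliff_pairs])
    d_non = np.mean([np.linalg.norm(X[i] - X[j]) for i, j in pairs.noncliff_pairs])
    if d_non == 0:
        return None
    return float(d_cliff / d_non)


# --------------------------------------------------------------------------
# Timeline probing
# --------------------------------------------------------------------------

def probe_timeline(
    snapshots: Sequence[Tuple[str, np.ndarray]],
    fingerprints: Sequence[BitFingerprint],
    labels: Sequence[float],
    n_clusters: Optional[int] = None,
    cliff_pairs: Optional[CliffPairSet] = None,
    seed: int = 0,
) -> List[LandscapeReport]:
    """Landscape metrics for a series of (timestamp, representation) snapshots.

    Per snapshot: ROGI on the representations; Rand index between a k-means
    clustering of the fingerprints and of the representations (same k); Rand
    index against the first snapshot's clustering (representation-shift
    proxy, 1.0 at the first snapshot by construction); optional cliff/non-cliff
    distance ratio when a pair set is supplied.
    """
    if not snapshots:
        return []
    n = len(fingerprints)
    for _, X in snapshots:
        if X.shape[0] != n:
            raise ValueError("snapshots must cover the same molecule set")
    k = n_clusters or default_n_clusters(n)
    fp_matrix = np.stack([fp.to_array() for fp in fingerprints])
    fp_clust = kmeans_labels(fp_matrix, k, seed=seed)
    base_clust = None
    reports = []
    for name, X in snapshots:
        val, curve = rogi(X, labels)
        rep_clust = kmeans_labels(X, k, seed=seed)
        if base_clust is None:
            base_clust = rep_clust
        ratio = cliff_noncliff_ratio(X, cliff_pairs) if cliff_pairs else None
        reports.append(
            LandscapeReport(
                timestamp=name,
                rogi=val,
                sigma_curve=curve,
                rand_index=rand_index(fp_clust, rep_clust),
                shift_rand=rand_index(base_clust, rep_clust),
                cliff_noncliff_ratio=ratio,
            )
        )
    return reports
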