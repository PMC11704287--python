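"""Training objectives: adaptive-margin quadruplet contrastive loss,
context-prediction loss, attention and alignment regularization, and the
overall objective.

The contrastive channels use a quadruplet extension of the triplet loss.  For
an anchor G_i, its augmentation G_i', and two negatives G_j, G_k the loss is
three hinge terms over L2 representation distances d:

    max(0, a1(i,j) + d(i,i') - d(i,j))
  + max(0, a1(i,k) + d(i,i') - d(i,k))
  + max(0, a2(i,j,k) + d(i,j) - d(i,k))

with margins adapted to fingerprint Tanimoto similarity:

    a1(i,j)   = alpha_offset * (1 - sim(z_i, z_j))
    a2(i,j,k) = alpha_offset * (sim(z_i, z_j) - sim(z_i, z_k))

The molecule channel computes sim on whole-molecule fingerprints, the scaffold
channel on scaffold fingerprints.  Quadruplets with a2 < 0 are dropped at
sampling time (see :mod:`molprompt.pretrain`), so k is always the "more
different" negative.

The overall objective is
    L = L_MCD + L_SCD + L_CP + 0.1 * L_regu.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, cross_entropy, l2_distance, smooth_l1
from .chem_graph import BitFingerprint, tanimoto

REGULARIZATION_FACTOR = 0.1
DEFAULT_ALPHA_OFFSET = 1.0

# Channel order convention used everywhere: [MCD, SCD, CP].
# Alignment presets: prompt-weight mixtures for the supervised alignment tasks
# (task -> simplex weights over the three channels).
ALIGNMENT_PRESETS = {
    "mol_weight": np.array([0.45, 0.1, 0.45]),
    "scaffold_weight": np.array([0.1, 0.45, 0.45]),
    "mol_minus_scaffold_weight": np.array([0.45, 0.45, 0.1]),
}


@dataclass
class LossBreakdown:
    l_mcd: float
    l_scd: float
    l_cp: float
    l_regu: float

    @property
    def l_overall(self) -> float:
        return self.l_mcd + self.l_scd + self.l_cp + REGULARIZATION_FACTOR * self.l_regu


# --------------------------------------------------------------------------
# Adaptive margins
# --------------------------------------------------------------------------

def alpha1(fp_i: BitFingerprint, fp_j: BitFingerprint,
           offset: float = DEFAULT_ALPHA_OFFSET) -> float:
    """Primary margin: offset * (1 - Tanimoto). Zero for identical structures."""
    if offset <= 0:
        raise ValueError("alpha offset must be positive")
    return offset * (1.0 - tanimoto(fp_i, fp_j))


def alpha2(fp_i: BitFingerprint, fp_j: BitFingerprint, fp_k: BitFingerprint,
           offset: float = DEFAULT_ALPHA_OFFSET) -> float:
    """Secondary margin: offset * (sim(i,j) - sim(i,k)); may be negative."""
    return offset * (tanimoto(fp_i, fp_j) - tanimoto(fp_i, fp_k))


def adaptive_margin_loss(
    h_i: Tensor, h_i_pos: Tensor, h_j: Tensor, h_k: Tensor,
    a1_ij, a1_ik, a2_ijk,
) -> Tensor:
    """Quadruplet loss; inputs may be single vectors or (batch, dim) stacks.

    Returns the *sum* over the quadruplets in the batch.
    """
    d_pos = l2_distance(h_i, h_i_pos)
    d_j = l2_distance(h_i, h_j)
    d_k = l2_distance(h_i, h_k)
    t1 = (Tensor(a1_ij) + d_pos - d_j).relu()
    t2 = (Tensor(a1_ik) + d_pos - d_k).relu()
    t3 = (Tensor(a2_ijk) + d_j - d_k).relu()
    return (t1 + t2 + t3).sum()


def triplet_loss(h_i: Tensor, h_i_pos: Tensor, h_j: Tensor, margin: float) -> Tensor:
    """Conventional fixed-margin triplet loss (sum over batch)."""
    return (Tensor(margin) + l2_distance(h_i, h_i_pos) - l2_distance(h_i, h_j)).relu().sum()


# --------------------------------------------------------------------------
# Context prediction
# --------------------------------------------------------------------------

def context_prediction_loss(
    subgraph_logits: Tensor,
    subgraph_labels: np.ndarray,
    motif_pred: Tensor,
    motif_target: np.ndarray,
) -> Tensor:
    """L_CP = cross-entropy over masked-atom element classes + smooth-L1 on
    normalized functional-group descriptors (mean over masked units /
    descriptor slots)."""
    if subgraph_logits.shape[0] != len(subgraph_labels):
        raise ValueError("logit rows and labels differ in length")
    ce = cross_entropy(subgraph_logits, subgraph_labels)
    fg = smooth_l1(motif_pred, Tensor(motif_target))
    return ce + fg


# --------------------------------------------------------------------------
# Regularization
# --------------------------------------------------------------------------

def attention_regularization(attention: Tensor, importance: np.ndarray) -> Tensor:
    """Smooth-L1 between the readout attention and a target atom-importance
    distribution (uniform over all atoms for MCD; uniform over scaffold atoms,
    zero elsewhere, for SCD)."""
    importance = np.asarray(importance, dtype=np.float64)
    if attention.shape[0] != importance.shape[0]:
        raise ValueError("attention and importance lengths differ")
    if importance.size and not np.isclose(importance.sum(), 1.0, atol=1e-6):
        raise ValueError("importance must be a normalized distribution")
    return smooth_l1(attention, Tensor(importance))


def uniform_importance(n_atoms: int) -> np.ndarray:
    return np.full(n_atoms, 1.0 / n_atoms)


def scaffold_importance(scaffold_mask: np.ndarray) -> np.ndarray:
    """Uniform over scaffold atoms, zero on side-chain atoms."""
    mask = np.asarray(scaffold_mask, dtype=np.float64)
    total = mask.sum()
    if total == 0:
        raise ValueError("scaffold mask has no atoms")
    return mask / total


def alignment_regularization(
    channel_reprs: list,
    preset_weights: np.ndarray,
    supervised_target,
    head_w: Tensor,
    head_b: Tensor,
) -> Tensor:
    """Smooth-L1 loss of a linear head predicting a supervised descriptor from
    the preset-weighted composite representation."""
    preset_weights = np.asarray(preset_weights, dtype=np.float64)
    if len(channel_reprs) != preset_weights.shape[0]:
        raise ValueError("one preset weight per channel required")
    if not np.isclose(preset_weights.sum(), 1.0, atol=1e-9) or (preset_weights < 0).any():
        raise ValueError("preset weights must lie on the probability simplex")
    composite = channel_reprs[0] * preset_weights[0]
    for c in range(1, len(channel_reprs)):
        composite = composite + channel_reprs[c] * preset_weights[c]
    pred = composite @ head_w + head_b
    target = np.asarray(supervised_target, dtype=np.float64).reshape(pred.shape)
    return smooth_l1(pred, Tensor(target))


def overall_loss(l_mcd: float, l_scd: float, l_cp: float, l_regu: float) -> LossBreakdown:
    """Combine per-channel losses with down-weighted regularization."""
    return LossBreakdown(l_mcd=l_mcd, l_scd=l_scd, l_cp=l_cp, l_regu=l_regu)
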