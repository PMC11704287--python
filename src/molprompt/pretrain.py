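"""Multi-channel self-supervised pre-training.

Each optimization step draws a batch of anchor molecules and evaluates three
channels plus regularization:

* **MCD** (molecule contrastive distancing): positives are attribute-masked
  subgraphs of the anchor; quadruplet margins come from whole-molecule
  fingerprint Tanimoto.
* **SCD** (scaffold contrastive distancing): positives are precomputed
  scaffold-invariant side-chain perturbations (one of the five per anchor,
  sampled uniformly); margins come from scaffold fingerprints.  Molecules
  without a scaffold or without any accepted perturbation are excluded from
  this channel only.
* **CP** (context prediction): reconstruct the element classes of masked atoms
  (cross-entropy) and regress the molecule's normalized functional-group
  descriptors (smooth-L1) from the CP channel representation.

Regularization: smooth-L1 between readout attention and target atom-importance
distributions (uniform for MCD, scaffold-uniform for SCD), plus supervised
alignment tasks (molecular weight of the molecule / scaffold / their
difference) under fixed prompt-weight presets.  The overall objective is
L_MCD + L_SCD + L_CP + 0.1 * L_regu, minimized with Adam.

Quadruplet sampling is within-batch.  Negative-ordered pairs (a2 < 0) are put
in canonical order (the nearer negative as j) rather than resampled; under
exchangeable random pair sampling this is equivalent to dropping them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence

import numpy as np

from .autodiff import Adam, Tensor, smooth_l1
from .chem_graph import (
    MoleculeRecord,
    N_ELEMENT_CLASSES,
    FG_DESCRIPTOR_DIM,
    atom_element_class,
    featurize,
    molecular_weight,
    tanimoto,
)
from .encoder import (
    AggregationParams,
    BatchedGraphs,
    CHANNELS,
    EncoderParams,
    encode_nodes,
    glorot,
    prompt_aggregate,
)
from .losses import (
    ALIGNMENT_PRESETS,
    LossBreakdown,
    REGULARIZATION_FACTOR,
    adaptive_margin_loss,
    alignment_regularization,
    attention_regularization,
    context_prediction_loss,
    scaffold_importance,
    uniform_importance,
)
from .perturb import (
    FragmentPool,
    _scaffold_atom_set,
    build_fragment_pool,
    scaffold_invariant_perturb,
    subgraph_mask,
)

MW_SCALE = 500.0  # molecular-weight normalization for alignment targets


@dataclass
class PretrainConfig:
    n_layers: int = 2
    hidden_dim: int = 32
    n_heads: int = 2
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    alpha_offset: float = 1.0
    n_positive_per_anchor: int = 5
    quadruplets_per_anchor: int = 4
    max_changed_atoms: int = 5
    seed: int = 0
    channels: Dict[str, bool] = field(
        default_factory=lambda: {"MCD": True, "SCD": True, "CP": True}
    )

    def __post_init__(self):
        if self.n_positive_per_anchor < 1:
            raise ValueError("n_positive_per_anchor must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class QuadrupletBatch:
    anchor: np.ndarray
    j: np.ndarray
    k: np.ndarray
    a1_ij: np.ndarray
    a1_ik: np.ndarray
    a2: np.ndarray

    def __len__(self) -> int:
        return len(self.anchor)


def sample_quadruplets(
    fingerprints: Sequence,
    usable: Optional[np.ndarray],
    config: PretrainConfig,
    rng: np.random.Generator,
) -> QuadrupletBatch:
    """Sample (anchor, j, k) index triples with adaptive margins, a2 >= 0.

    `usable` restricts anchors/negatives (e.g. molecules with scaffolds for
    the SCD channel).  Fewer than three usable molecules yield an empty batch.
    """
    n = len(fingerprints)
    idx = np.arange(n) if usable is None else np.flatnonzero(usable)
    if len(idx) < 3:
        return QuadrupletBatch(*[np.zeros(0, dtype=t) for t in
                                 (np.intp, np.intp, np.intp, float, float, float)])
    anchors, js, ks, a1j, a1k, a2s = [], [], [], [], [], []
    for i in idx:
        others = idx[idx != i]
        for _ in range(config.quadruplets_per_anchor):
            j, k = rng.choice(others, size=2, replace=False)
            sim_ij = tanimoto(fingerprints[i], fingerprints[j])
            sim_ik = tanimoto(fingerprints[i], fingerprints[k])
            if sim_ij < sim_ik:  # canonical order: j is the nearer negative
                j, k = k, j
                sim_ij, sim_ik = sim_ik, sim_ij
            anchors.append(i)
            js.append(j)
            ks.append(k)
            a1j.append(config.alpha_offset * (1.0 - sim_ij))
            a1k.append(config.alpha_offset * (1.0 - sim_ik))
            a2s.append(config.alpha_offset * (sim_ij - sim_ik))
    return QuadrupletBatch(
        np.array(anchors, dtype=np.intp), np.array(js, dtype=np.intp),
        np.array(ks, dtype=np.intp), np.array(a1j), np.array(a1k), np.array(a2s),
    )


# --------------------------------------------------------------------------
# Model container
# --------------------------------------------------------------------------

@dataclass
class Model:
    encoder: EncoderParams
    aggregation: AggregationParams
    heads: Dict[str, Tensor]
    config: PretrainConfig

    @classmethod
    def init(cls, config: PretrainConfig) -> "Model":
        enc = EncoderParams.init(config.n_layers, config.hidden_dim, seed=config.seed)
        agg = AggregationParams.init(config.hidden_dim, config.n_heads, seed=config.seed)
        rng = np.random.default_rng(config.seed + 2)
        h = config.hidden_dim
        heads = {
            "cp_node_w": glorot(rng, h, N_ELEMENT_CLASSES),
            "cp_node_b": Tensor(np.zeros(N_ELEMENT_CLASSES), requires_grad=True),
            "motif_w": glorot(rng, h, FG_DESCRIPTOR_DIM),
            "motif_b": Tensor(np.zeros(FG_DESCRIPTOR_DIM), requires_grad=True),
        }
        for task in ALIGNMENT_PRESETS:
            heads[f"align_{task}_w"] = glorot(rng, h, 1)
            heads[f"align_{task}_b"] = Tensor(np.zeros(1), requires_grad=True)
        return cls(encoder=enc, aggregation=agg, heads=heads, config=config)

    def parameters(self) -> Dict[str, Tensor]:
        out: Dict[str, Tensor] = {}
        out.update({f"enc.{k}": v for k, v in self.encoder.tensors.items()})
        out.update({f"agg.{k}": v for k, v in self.aggregation.tensors.items()})
        out.update({f"head.{k}": v for k, v in self.heads.items()})
        return out


@dataclass
class PretrainData:
    """Featurized corpus plus precomputed scaffold-invariant perturbations."""

    records: List[MoleculeRecord]
    graphs: list
    scaffold_masks: List[np.ndarray]
    perturbed_graphs: List[list]           # per molecule: featurized positives
    mw: np.ndarray                         # molecule weight / MW_SCALE
    scaffold_mw: np.ndarray
    motif_targets: np.ndarray

    @classmethod
    def prepare(cls, records: Sequence[MoleculeRecord], config: PretrainConfig,
                pool: Optional[FragmentPool] = None) -> "PretrainData":
        records = list(records)
        if not records:
            raise ValueError("empty corpus")
        if pool is None:
            pool = build_fragment_pool(records)
        graphs, masks, perts = [], [], []
        mw, smw, motifs = [], [], []
        for m_idx, rec in enumerate(records):
            g = featurize(rec.smiles_canonical)
            graphs.append(g)
            scaf_atoms = _scaffold_atom_set(rec.mol())
            mask = np.zeros(g.n_atoms)
            mask[list(scaf_atoms)] = 1.0
            masks.append(mask)
            results = (
                scaffold_invariant_perturb(
                    rec, pool,
                    max_changed_atoms=config.max_changed_atoms,
                    n_samples=config.n_positive_per_anchor,
                    rng_seed=config.seed * 100003 + m_idx,
                )
                if rec.scaffold_smiles
                else []
            )
            perts.append([featurize(r.child_smiles) for r in results])
            mw.append(molecular_weight(rec.smiles_canonical) / MW_SCALE)
            smw.append(
                molecular_weight(rec.scaffold_smiles) / MW_SCALE
                if rec.scaffold_smiles else 0.0
            )
            motifs.append(rec.descriptor_vector)
        return cls(
            records=records, graphs=graphs, scaffold_masks=masks,
            perturbed_graphs=perts, mw=np.array(mw), scaffold_mw=np.array(smw),
            motif_targets=np.stack(motifs),
        )


# --------------------------------------------------------------------------
# Training step
# --------------------------------------------------------------------------

def _channel_outputs(graphs, model: Model, channel: str):
    batch = BatchedGraphs(graphs)
    h = encode_nodes(batch, model.encoder)
    out = prompt_aggregate(h, batch.graph_ids, batch.n_graphs, channel, model.aggregation)
    return batch, h, out


def pretrain_step(
    data: PretrainData,
    batch_idx: np.ndarray,
    model: Model,
    optimizer: Adam,
    rng: np.random.Generator,
) -> LossBreakdown:
    """One gradient step of the overall objective on a batch of anchors."""
    cfg = model.config
    graphs = [data.graphs[i] for i in batch_idx]
    zero = Tensor(0.0)

    # masked positives (shared by MCD and CP)
    masked = [subgraph_mask(g, int(rng.integers(2**31 - 1))) for g in graphs]

    # anchors per channel on clean graphs
    anchor_out = {}
    for ch in CHANNELS:
        _, _, anchor_out[ch] = _channel_outputs(graphs, model, ch)

    # ---- MCD -------------------------------------------------------------
    l_mcd = zero
    if cfg.channels.get("MCD", True):
        _, _, pos_out = _channel_outputs([m.base for m in masked], model, "MCD")
        fps = [data.records[i].fingerprint for i in batch_idx]
        quads = sample_quadruplets(fps, None, cfg, rng)
        if len(quads):
            reprs = anchor_out["MCD"].graph_repr
            anchor_r = reprs.gather(quads.anchor)
            pos_r = pos_out.graph_repr.gather(quads.anchor)
            j_r = reprs.gather(quads.j)
            k_r = reprs.gather(quads.k)
            l_mcd = adaptive_margin_loss(
                anchor_r, pos_r, j_r, k_r, quads.a1_ij, quads.a1_ik, quads.a2
            ) * (1.0 / len(quads))

    # ---- SCD -------------------------------------------------------------
    l_scd = zero
    if cfg.channels.get("SCD", True):
        usable = np.array([len(data.perturbed_graphs[i]) > 0 for i in batch_idx])
        scaf_fps = [data.records[i].scaffold_fingerprint for i in batch_idx]
        quads = sample_quadruplets(scaf_fps, usable, cfg, rng)
        if len(quads):
            pos_graphs = []
            pos_of = {}
            for local_i in np.flatnonzero(usable):
                choices = data.perturbed_graphs[batch_idx[local_i]]
                pos_of[local_i] = len(pos_graphs)
                pos_graphs.append(choices[int(rng.integers(len(choices)))])
            _, _, pos_out = _channel_outputs(pos_graphs, model, "SCD")
            reprs = anchor_out["SCD"].graph_repr
            pos_idx = np.array([pos_of[a] for a in quads.anchor], dtype=np.intp)
            l_scd = adaptive_margin_loss(
                reprs.gather(quads.anchor),
                pos_out.graph_repr.gather(pos_idx),
                reprs.gather(quads.j),
                reprs.gather(quads.k),
                quads.a1_ij, quads.a1_ik, quads.a2,
            ) * (1.0 / len(quads))

    # ---- CP --------------------------------------------------------------
    l_cp = zero
    if cfg.channels.get("CP", True):
        cp_batch = BatchedGraphs([m.base for m in masked])
        h_cp = encode_nodes(cp_batch, model.encoder)
        cp_out = prompt_aggregate(
            h_cp, cp_batch.graph_ids, cp_batch.n_graphs, "CP", model.aggregation
        )
        # masked-node rows in the batched graph
        offsets = np.cumsum([0] + [g.n_atoms for g in graphs[:-1]])
        rows, labels = [], []
        for m, off, gi in zip(masked, offsets, batch_idx):
            rows.extend(m.masked_atom_indices + off)
            mol = data.records[gi].mol()
            labels.extend(
                atom_element_class(mol.GetAtomWithIdx(int(a)))
                for a in m.masked_atom_indices
            )
        logits = h_cp.gather(np.array(rows, dtype=np.intp)) @ model.heads["cp_node_w"] \
            + model.heads["cp_node_b"]
        motif_pred = cp_out.graph_repr @ model.heads["motif_w"] + model.heads["motif_b"]
        l_cp = context_prediction_loss(
            logits, np.array(labels), motif_pred, data.motif_targets[batch_idx]
        )

    # ---- regularization ---------------------------------------------------
    # attention targets are per-graph distributions; smooth-L1 is element-wise,
    # so concatenating the per-graph targets matches concatenated attentions
    l_regu = zero
    n_atoms = [g.n_atoms for g in graphs]
    imp_mcd = np.concatenate([uniform_importance(n) for n in n_atoms])
    l_regu = l_regu + smooth_l1(anchor_out["MCD"].attention, Tensor(imp_mcd))
    imp_scd = np.concatenate(
        [scaffold_importance(data.scaffold_masks[i]) if data.scaffold_masks[i].sum() > 0
         else uniform_importance(data.graphs[i].n_atoms) for i in batch_idx]
    )
    l_regu = l_regu + smooth_l1(anchor_out["SCD"].attention, Tensor(imp_scd))

    channel_reprs = [anchor_out[ch].graph_repr for ch in CHANNELS]
    targets = {
        "mol_weight": data.mw[batch_idx],
        "scaffold_weight": data.scaffold_mw[batch_idx],
        "mol_minus_scaffold_weight": data.mw[batch_idx] - data.scaffold_mw[batch_idx],
    }
    for task, preset in ALIGNMENT_PRESETS.items():
        l_regu = l_regu + alignment_regularization(
            channel_reprs, preset, targets[task].reshape(-1, 1),
            model.heads[f"align_{task}_w"], model.heads[f"align_{task}_b"],
        )

    total = l_mcd + l_scd + l_cp + REGULARIZATION_FACTOR * l_regu
    if not np.isfinite(total.data):
        raise FloatingPointError(
            f"non-finite loss on batch {batch_idx.tolist()}: "
            f"mcd={l_mcd.data}, scd={l_scd.data}, cp={l_cp.data}, regu={l_regu.data}"
        )
    optimizer.zero_grad()
    total.backward()
    optimizer.step()
    return LossBreakdown(
        l_mcd=float(l_mcd.data), l_scd=float(l_scd.data),
        l_cp=float(l_cp.data), l_regu=float(l_regu.data),
    )


# --------------------------------------------------------------------------
# Training loop
# --------------------------------------------------------------------------

@dataclass
class Checkpoint:
    model: Model
    loss_log: List[LossBreakdown]
    seed: int

    def epoch_losses(self) -> np.ndarray:
        return np.array([b.l_overall for b in self.loss_log])


def run_pretraining(
    corpus: Sequence[MoleculeRecord],
    config: PretrainConfig,
    data: Optional[PretrainData] = None,
) -> Checkpoint:
    """Pre-train on a corpus; returns the model plus a per-epoch loss log."""
    if data is None:
        data = PretrainData.prepare(corpus, config)
    if config.channels.get("SCD", True) and not any(
        len(p) for p in data.perturbed_graphs
    ):
        warnings.warn("no perturbable molecules; disabling the SCD channel",
                      stacklevel=2)
        config.channels["SCD"] = False
    model = Model.init(config)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    n = len(data.records)
    log: List[LossBreakdown] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        parts = np.zeros(4)
        n_batches = 0
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            if len(batch) < 3:
                continue
            b = pretrain_step(data, batch, model, optimizer, rng)
            parts += [b.l_mcd, b.l_scd, b.l_cp, b.l_regu]
            n_batches += 1
        parts /= max(n_batches, 1)
        log.append(LossBreakdown(*parts))
    return Checkpoint(model=model, loss_log=log, seed=config.seed)


def channel_representations(
    data: PretrainData, model: Model, indices: Optional[np.ndarray] = None
) -> Dict[str, np.ndarray]:
    """Per-channel graph representations of (a subset of) the corpus."""
    idx = np.arange(len(data.records)) if indices is None else np.asarray(indices)
    graphs = [data.graphs[i] for i in idx]
    out = {}
    for ch in CHANNELS:
        _, _, o = _channel_outputs(graphs, model, ch)
        out[ch] = o.graph_repr.data.copy()
    return out
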