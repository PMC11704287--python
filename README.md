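# molprompt

Prompt-guided multi-channel self-supervised molecular representation learning,
at desk scale.

## The problem

Molecular property prediction from small labeled datasets benefits from
representations pre-trained on unlabeled molecules. A single self-supervised
objective, however, bakes in a single notion of "similar": two molecules close
in whole-structure fingerprint space may sit on opposite sides of an
*activity cliff* — a pair of structurally similar compounds whose potencies
differ by an order of magnitude — while two molecules sharing a scaffold but
differing in side chains may behave almost identically. Which notion of
similarity is right depends on the downstream task.

`molprompt` pre-trains one graph encoder under **three channels** that encode
different similarity structures, keeps all three, and lets each downstream
task choose its own mixture of them:

* **MCD** (molecule contrastive distancing) — whole-molecule similarity,
  supervised by ECFP4 fingerprint Tanimoto margins;
* **SCD** (scaffold contrastive distancing) — scaffold-level similarity,
  supervised by Bemis–Murcko scaffold fingerprints, with positives produced by
  *scaffold-invariant perturbation* (side-chain swaps that provably leave the
  scaffold untouched);
* **CP** (context prediction) — local chemistry, reconstructing masked atom
  identities and global functional-group counts.

The package also provides the probing side: the **ROGI** roughness index of a
structure–activity landscape, activity-cliff matched-pair detection, Rand-index
representation-drift tracking, and a synthetic fixture generator whose
landscape roughness is controllable, so every claim above is testable on a
laptop.

## The model

**Encoder.** A GIN-style message-passing network over the molecular graph.
With node features `h_v` and edge features `e_uv`,

```
h_v^(l+1) = MLP^(l)( h_v^(l) + Σ_{u∈N(v)} ReLU( h_u^(l) + W_e e_uv ) )
```

(default: 2 layers, 32 hidden dims — deliberately small; the architecture
scales but the defaults are sized for CPU experimentation).

**Prompt-guided readout.** Each channel `c` owns a learned prompt embedding
`h_p^c`. Graph representations are multi-head attention over atoms with the
prompt as query:

```
q = W_q h_p^c,   k_v = W_k h_v,   α_v = softmax_v( q·k_v / √d_k )
h_G^c = W_o [ Σ_v α_v W_v h_v ]_heads
```

so the *same* node embeddings yield three different graph representations,
one per channel.

**Adaptive-margin quadruplet loss.** For an anchor `i`, a positive `i'`
(masked subgraph for MCD, scaffold-invariant perturbation for SCD), and two
negatives `j, k` sampled within the batch with `sim(i,j) ≥ sim(i,k)`:

```
L = [d(i,i') − d(i,j) + α₁(i,j)]₊ + [d(i,i') − d(i,k) + α₁(i,k)]₊
  + [d(i,j)  − d(i,k) + α₂(i,j,k)]₊

α₁(i,j)   = α_offset · (1 − sim(i,j))
α₂(i,j,k) = α_offset · (sim(i,j) − sim(i,k))
```

where `d` is Euclidean distance and `sim` is fingerprint Tanimoto (molecule
fingerprints for MCD, scaffold fingerprints for SCD). Margins *adapt*: the
less similar the negative, the farther it must be pushed, and the two
negatives must be ordered consistently with their similarities.

**Overall objective.**

```
L_overall = L_MCD + L_SCD + L_CP + 0.1 · L_regu
```

`L_regu` = attention-shape regularizers (MCD attention pulled toward uniform,
SCD attention toward uniform-on-scaffold-atoms) plus three supervised alignment
tasks (molecular weight / scaffold weight / their difference) evaluated under
fixed channel-weight presets, which keeps the three channels specialized.

**Fine-tuning.** The aggregation module is frozen (bit-identical before and
after — asserted at runtime). A task learns a point `w` on the 3-simplex via
softmax of two free logits, giving the composite representation
`h = w₁ h^MCD + w₂ h^SCD + w₃ h^CP`, plus a linear head; the encoder is also
updated. `w` is initialized to the candidate whose composite representation
has the **lowest ROGI** (smoothest landscape) on the training set — an
exhaustive 0.1-step simplex grid when the evaluation budget allows, a small
Gaussian-process expected-improvement search otherwise.

**ROGI.** For labeled points, sweep a complete-linkage clustering threshold
`t` across the normalized distance range and track `σ_t`, the size-weighted
standard deviation of cluster mean-labels:

```
ROGI = ∫₀¹ 2·(σ₀ − σ_t) dt   ∈ [0, 1]
```

Rough landscapes (nearby points, different labels) lose dispersion at small
`t` and score high; ROGI is computed exactly by piecewise-constant integration
over merge events.

## Worked example

```python
import numpy as np
from molprompt import (
    FixtureSpec, generate_molecules, generate_labels,
    PretrainConfig, run_pretraining, FinetuneConfig, finetune,
    rogi, identify_cliff_pairs,
)
from molprompt.finetune import random_split
from molprompt.pretrain import PretrainData
from molprompt.synthetic_fixtures import to_potency

# 1. a 200-molecule analog series with injected activity cliffs
spec = FixtureSpec(n_molecules=200, label_mode="cliff", seed=0)
corpus = generate_molecules(spec)
labels = generate_labels(corpus, spec)          # log10 potencies

pairs = identify_cliff_pairs(corpus, to_potency(labels))
print(len(pairs.cliff_pairs), len(pairs.noncliff_pairs))
# 1972 1105

print(round(rogi([m.fingerprint for m in corpus], labels)[0], 3))
# 0.061

# 2. three-channel self-supervised pre-training (~10 s on one CPU)
cfg = PretrainConfig(seed=0)                    # 2 layers / 32 dims / 20 epochs
data = PretrainData.prepare(corpus, cfg)
ckpt = run_pretraining(corpus, cfg, data=data)
print(round(ckpt.epoch_losses()[0], 3), round(ckpt.epoch_losses()[-1], 3))
# 4.047 0.666

# 3. fine-tune with ROGI-initialized prompt weights
tr, va, _ = random_split(len(corpus), seed=0)
res = finetune(ckpt, data, labels, tr, va,
               FinetuneConfig(epochs=20, seed=0, rogi_init_budget=100,
                              snapshot_epochs=(0, 20)))
print(np.round(res.prompt_weights.weights, 3))  # [MCD, SCD, CP]
# [0.902 0.    0.098]
print(round(res.metric_log[-1]["val_metric"], 3))
# 0.111
```

The ROGI initialization puts nearly all prompt weight on the MCD channel for
this task (the synthetic labels are a function of whole-molecule
fingerprints), and fine-tuning barely moves it. The validation R² of 0.111 is
what a 32-dim encoder trained for seconds on 160 molecules with deliberately
injected 10-fold potency cliffs buys — the package is built for studying
representation behavior, not leaderboard numbers.

The same pipeline is available from the shell:

```bash
molprompt fixtures --n 200 --mode cliff --seed 0 --out corpus.csv
molprompt pretrain --corpus corpus.csv --seed 0 --out ckpt.json
molprompt finetune --ckpt ckpt.json --data corpus.csv --rogi-budget 100 --out ft/
molprompt probe --data corpus.csv --snapshots ft/snapshot_epoch0.tsv --out report.csv
molprompt show-config      # all defaults
```

## Reproduction

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline's headline quantities from scratch (~25 s, one CPU).
Values obtained with seed 1:

| quantity | value |
|---|---|
| `rogi_oracle_max_abs_delta` (vs. brute-force clustering oracle, 50 instances) | 1.2e-14 |
| `rogi_cliff_gt_smooth_fraction` (20 corpus seeds) | 1.0 |
| `scaffold_preservation_rate` (995 perturbations) | 1.0 |
| `injected_cliff_recovery_rate` | 1.0 |
| `pretrain_loss_ratio` (epoch 20 / epoch 1) | 0.137 |
| `repr_tanimoto_spearman` (composite distance vs. 1 − Tanimoto) | 0.69 |
| `prompt_channel_recovery_rate` (10 planted-channel tasks) | 1.0 |
| `aggregation_frozen` (bit-identical through fine-tuning) | true |
| `permutation_invariance_max_rel_err` (100 atom reorderings) | 4.3e-16 |

`tests/test_acceptance.py` asserts the same properties with thresholds;
`docs/methods.md` documents the model, defaults, numerical choices, and
limitations.

## Layout

```
src/molprompt/
  autodiff.py           reverse-mode autodiff + Adam (NumPy, float64)
  chem_graph.py         SMILES parsing, scaffolds, ECFP4, graph featurization
  perturb.py            attribute masking, scaffold-invariant side-chain swaps
  encoder.py            message passing + prompt-guided attention readout
  losses.py             adaptive-margin quadruplet loss, CP loss, regularizers
  pretrain.py           three-channel pre-training loop
  finetune.py           ROGI-initialized prompt weights, frozen-aggregation FT
  qspr_probe.py         ROGI, Rand index, activity-cliff pair analysis
  synthetic_fixtures.py controllable-roughness synthetic corpora
  io_cli.py             corpus/checkpoint/report I/O, config, CLI
scripts/acceptance.py   end-to-end quantity recomputation
docs/methods.md         methods, assumptions, limitations
```
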