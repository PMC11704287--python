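# Methods

This document records what the package computes, the assumptions behind it,
every tunable parameter with its default and rationale, what the synthetic
fixture generator does and does not emulate, the numerical choices, and known
limitations. Notation: `h_v` node embedding, `h_G^c` graph representation
under channel `c`, `d(·,·)` Euclidean distance, `sim(·,·)` Tanimoto
similarity, `[x]₊ = max(x, 0)`.

## 1. Chemical primitives (`chem_graph`)

* **Canonical SMILES** via RDKit; all internal identity (deduplication,
  scaffold comparison, perturbation acceptance) is canonical-SMILES equality.
* **Bemis–Murcko scaffold**: ring systems plus linkers, terminal side chains
  removed (RDKit `MurckoScaffold`). Acyclic molecules have the *empty*
  scaffold `""`; every consumer treats that case explicitly (SCD exclusion,
  scaffold-similarity skip, perturbation refusal).
* **Fingerprints**: Morgan/ECFP4, radius 2, **512 bits** everywhere (molecule
  and scaffold). 512 bits is enough to separate a desk-scale corpus while
  keeping Tanimoto loops and the label generator cheap. Convention: the
  Tanimoto of two *empty* fingerprints is 1.0 (identical absence), matching
  the identity axiom.
* **Graph featurization**: atoms → 24-dim vectors (10 element classes + a
  mask slot, degree 0–5, formal charge −2…+2, aromaticity, ring membership),
  bonds → 6-dim (4 bond types, conjugation, ring), both edge directions
  present. One-hot blocks, no learned embeddings outside the encoder.
* **Functional-group descriptors**: 48 SMARTS patterns; each slot is
  `min(count, 4)/4`, a saturating count normalized to [0, 1] so the motif
  regression target is bounded.

## 2. Perturbation operators (`perturb`)

* **Attribute masking** (MCD/CP positives): pick one atom uniformly, mask it
  and its one-hop neighborhood by replacing element/degree/charge blocks with
  the mask slot. Topology is untouched, so the positive is the same graph
  with hidden attributes. `MaskedGraph.restore()` is exact.
* **Scaffold-invariant perturbation** (SCD positives): detach one side chain
  at its scaffold attachment point and attach a single-attachment fragment
  (`*`-SMILES) from a pool harvested from the corpus' own side chains.
  A candidate is accepted only if (i) RDKit sanitization succeeds, (ii) the
  child's canonical Bemis–Murcko scaffold equals the parent's, and (iii)
  `changed_atoms = removed + added < 5` (default), keeping the perturbation
  "small" in the matched-molecular-pair sense. Acceptance checks are
  *verification*, not trust in the editing code. Molecules with empty
  scaffolds are refused with a warning.

## 3. Encoder and readout (`encoder`)

GIN-style message passing:

```
h_v^(l+1) = MLP( h_v^(l) + Σ_{u∈N(v)} ReLU( h_u^(l) + W_e e_uv ) )
```

Sum aggregation keeps the readout permutation-invariant (verified to ~1e-16
relative error under atom reorderings; tests use a 1e-5 tolerance).

Prompt-guided multi-head attention readout: per-channel prompt embedding
`h_p^c` forms the query; keys/values come from node embeddings through shared
`W_q, W_k, W_v, W_o`. Softmax is computed per graph within a batched
disjoint-union graph (segment softmax with per-graph max subtraction).
The per-atom attention `α_v` (summing to 1 per graph) doubles as the
atom-importance distribution used by the regularizers.

Defaults: 2 layers, 32 hidden dims, 2 heads. These are desk-scale choices:
they keep one pre-training run under ~10 s on a single CPU while leaving the
loss contracts, invariances, and recovery behavior unchanged in form.

## 4. Losses (`losses`)

**Adaptive-margin quadruplet loss** — for anchor `i`, positive `i'`,
negatives `j, k` with `sim(i,j) ≥ sim(i,k)`:

```
L(i,i',j,k) = [d(i,i') − d(i,j) + α₁(i,j)]₊
            + [d(i,i') − d(i,k) + α₁(i,k)]₊
            + [d(i,j) − d(i,k) + α₂(i,j,k)]₊
α₁(i,j) = α_offset (1 − sim(i,j)),  α₂ = α_offset (sim(i,j) − sim(i,k))
```

Negative pairs are sampled within the batch (`quadruplets_per_anchor = 4`)
and put in canonical order (the more similar negative as `j`), which makes
`α₂ ≥ 0`; under exchangeable sampling this is equivalent to rejecting
mis-ordered pairs. `α_offset = 1.0` (margins then span the full Tanimoto
range). With disjoint fingerprints and the α₂ hinge inactive the loss reduces
exactly to two fixed-margin triplet losses — a tested contract.

**Context prediction**: cross-entropy on the element class of each masked
atom (from node embeddings) + smooth-L1 between a linear readout of the CP
graph representation and the functional-group descriptor vector.

**Regularization** (`L_regu`, factor **0.1**):

* smooth-L1 between MCD attention and the uniform distribution, and between
  SCD attention and the uniform-on-scaffold-atoms distribution (falling back
  to uniform when the scaffold is empty). Smooth-L1 is element-wise, so
  per-graph targets are concatenated to match the batched attention vector.
* three supervised alignment tasks — molecular weight, scaffold weight, and
  their difference, each divided by `MW_SCALE = 500` to sit near unit scale —
  predicted from *fixed* channel mixtures `[0.45, 0.1, 0.45]`,
  `[0.1, 0.45, 0.45]`, `[0.45, 0.45, 0.1]` (order `[MCD, SCD, CP]`). Fixing
  the mixtures (rather than learning them) is what forces channel
  specialization.

Overall: `L = L_MCD + L_SCD + L_CP + 0.1 L_regu`, minimized with Adam
(lr 1e-3, β = 0.9/0.999, ε = 1e-8).

## 5. Pre-training (`pretrain`)

Defaults: 20 epochs, batch 32, seed 0, 5 perturbation positives per molecule
precomputed with per-molecule seeds (`seed·100003 + index`) so data
preparation is deterministic and independent of batch order. If no molecule
admits a scaffold-invariant perturbation the SCD channel is disabled with a
warning rather than silently contributing zero. A non-finite loss raises
immediately with the offending batch indices. Batches smaller than 3 are
skipped (quadruplets need 3 distinct molecules).

## 6. Fine-tuning (`finetune`)

Prompt weights are a point on the 3-simplex parameterized by 2 free logits
through a softmax with a fixed third logit of 0 — on-simplex by construction,
asserted at every logged epoch anyway. The composite representation is
`Σ_c w_c h_G^c`; trainables are the encoder, the prompt logits, and a linear
head. The **aggregation module is frozen**: its tensors are flagged
non-trainable, the autodiff engine refuses to accumulate gradients into them,
and the training loop additionally asserts after every backward pass that no
gradient reached them; before/after copies are compared bit-exactly.

**ROGI initialization** (`rogi_init_budget`):

* budget 0 (default): uniform weights — the neutral baseline;
* budget ≥ 66: exhaustive 0.1-step simplex grid (66 points) plus the uniform
  point, argmin of training-set ROGI of the composite representation;
* 0 < budget < 66: Gaussian-process expected-improvement search over the two
  free logits (bounds ±4, RBF kernel with *fixed* hyperparameters,
  `optimizer=None` — deterministic and cheap; with ≤ 65 evaluations in 2-D,
  kernel-hyperparameter fitting adds noise without value);
* constant labels make ROGI identically 0; uniform weights are returned with
  a warning.

Splits: seeded random split, and a deterministic scaffold split (whole
scaffold groups, largest first, into train → val → test) for
out-of-scaffold evaluation. Snapshot epochs default to {0, 10, 20, 50, 100}.

## 7. Landscape probing (`qspr_probe`)

**ROGI.** Labels min-max normalized, pairwise distances normalized by their
maximum. Complete-linkage dendrogram; at each merge the size-weighted standard
deviation of cluster mean-labels `σ_t` is updated incrementally via
`S = Σ_c n_c m_c²` (an O(1) update per merge), and

```
ROGI = ∫₀¹ 2 (σ₀ − σ_t) dt
```

is integrated exactly over the piecewise-constant curve (merge heights above 1
after normalization are clamped — complete linkage can exceed the max
pairwise distance). Agreement with a brute-force oracle that re-clusters at
every merge height: max |Δ| ≈ 1e-14 over 50 random instances. Endpoints:
coincident points with labels {0,1} → 1.0; the same labels at the full
distance range → 0.0.

**Cliff pairs.** A pair is *matched* when its consensus structural similarity
— the max of whole-molecule fingerprint Tanimoto, scaffold fingerprint
Tanimoto (only when both scaffolds are non-empty), and normalized
Levenshtein similarity of canonical SMILES (edlib) — reaches 0.9. Matched
pairs with a potency fold ratio ≥ 10 are cliff pairs. Potencies must be
positive (fold ratios are undefined otherwise; labels in log units are
converted by `to_potency`). The cliff/non-cliff distance ratio is the mean
representation distance over cliff pairs divided by the mean over non-cliff
pairs; it is `None` (not 0 or ∞) when either side is empty.

**Rand index** between k-means clusterings (k = max(2, n/25), fixed seeds,
`n_init=10`) of fingerprints vs. representations (structural-knowledge
retention) and of snapshot t vs. snapshot 0 (representation drift).

## 8. Synthetic fixtures (`synthetic_fixtures`)

**What it emulates**: a lead-optimization analog series — 8 ring templates
(benzene, pyridine, naphthalene, biphenyl, indole, quinoline, cyclohexane,
tetralin) decorated with 1–2 of 22 common substituents, enumerated
combinatorially, deduplicated, and seeded-shuffled. Every molecule has a
non-empty scaffold and the corpus is dense in matched molecular pairs — the
regime where scaffold-aware pre-training and cliff detection are meaningful.

**Labels** emulate log10 potencies: a random linear function of the 512-bit
fingerprint (drawn once per seed), standardized, centered at 5, plus Gaussian
noise (σ = 0.1). In **cliff mode**, for half of the matched pairs
(consensus similarity ≥ 0.9 — the same criterion the detector uses, so
injected cliffs are recoverable by construction) one member is shifted *away*
from its partner by 1.2 log units, guaranteeing a > 10-fold gap. Labels are
functions of fingerprints only, never of any trained representation, so the
generator is independent of the models it tests.

**What it does not emulate**: realistic potency distributions, assay noise
structure, stereochemistry, tautomers, charge states, molecule sizes beyond
~30 atoms, or any property other than a fingerprint-linear surrogate. Results
on fixtures demonstrate mechanism (losses optimize, channels specialize,
cliffs are detected), not medicinal-chemistry performance.

## 9. Numerical choices

* All floats are float64; gradients come from a small in-repo reverse-mode
  autodiff engine over NumPy (tape-based; gather/segment-sum primitives for
  batched graphs). Gradients were verified against central finite differences.
* `d(x,y) = sqrt(Σ(x−y)² + 1e-12)` — the epsilon keeps the derivative finite
  at coincident points (hinge losses routinely evaluate there).
* Segment softmax subtracts the per-graph max before exponentiation.
* Checkpoints are JSON with sorted keys; float64 round-trips exactly through
  shortest-repr encoding, so write → read → write is byte-identical
  (tested). A schema-version field guards against silent format drift.
* Determinism: every stochastic component takes an explicit seed
  (`numpy.random.default_rng`); identical inputs + seeds give bit-identical
  checkpoints and logs.

## 10. Design decisions

* **No deep-learning framework.** The model is small enough that a ~400-line
  autodiff engine is cheaper to audit than a framework dependency, and it
  makes the freeze contract enforceable at the engine level (non-trainable
  tensors cannot receive gradients at all).
* **Channel order `[MCD, SCD, CP]`** is fixed everywhere (presets, prompt
  weights, reports).
* **Consensus similarity** for matched pairs instead of fingerprint Tanimoto
  alone: ECFP4 Tanimoto almost never reaches 0.9 for single-substituent
  analogs (radius-2 environments change around the whole attachment
  neighborhood), which would leave desk-scale corpora with no matched pairs
  at all; scaffold and string-edit similarity restore the intended
  "same-series" semantics. Generator and detector share one function.
* **CSV/JSON text formats only** — artifacts are diffable and the repository
  stays text-only.

## 11. Limitations

* Desk-scale encoder (2×32) pre-trained on 200 synthetic molecules: absolute
  downstream metrics (e.g., validation R² ≈ 0.1–0.3) are illustrative, not
  competitive; conclusions should be drawn from the tested *properties*
  (loss contracts, invariances, recovery rates), not metric magnitudes.
* Quadruplet negatives are sampled within-batch, so effective negative
  diversity is bounded by batch size.
* The GP-EI search is a 2-D toy (fixed kernel, random candidate pools); for
  more channels a real Bayesian-optimization backend should replace it.
* `identify_cliff_pairs` is O(n²) in similarity evaluations — fine for
  thousands of molecules, not for millions.
* Scaffold-invariant perturbation swaps exactly one side chain per child and
  only accepts pool fragments with a single attachment point.
* No stereochemistry handling: SMILES are canonicalized with stereo flags
  preserved, but masking/perturbation do not reason about them.
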