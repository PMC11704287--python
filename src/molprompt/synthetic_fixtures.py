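"""Self-contained synthetic molecule corpora with controllable landscape
roughness.

Molecules are enumerated combinatorially as decorated ring templates
(scaffold x substituent placements), the way a lead-optimization analog series
is built, so every molecule has a non-empty Bemis-Murcko scaffold and the
corpus contains many structurally close pairs.

Labels emulate log10 potencies (pIC50-like):

* ``smooth`` mode: a fixed random linear function of the 512-bit fingerprint
  (drawn once per seed), standardized and centered at 5 log units, plus
  Gaussian noise — structurally similar molecules receive similar labels.
* ``cliff`` mode: smooth labels, then for a fraction of matched molecular
  pairs (consensus structural similarity >= 0.9, the same criterion the cliff
  detector uses) one member is shifted *away* from its partner by 1.2 log10
  units, guaranteeing a > 10-fold potency gap — a true activity cliff.

Labels are functions of fingerprints, never of any trained representation,
so the generator is independent of the models it is used to test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem

from .chem_graph import MoleculeRecord, parse_smiles
from .qspr_probe import structural_similarity

DEFAULT_TEMPLATES = [
    "c1ccccc1",                 # benzene
    "c1ccncc1",                 # pyridine
    "c1ccc2ccccc2c1",           # naphthalene
    "c1ccc(-c2ccccc2)cc1",      # biphenyl
    "c1ccc2[nH]ccc2c1",         # indole
    "c1ccc2ncccc2c1",           # quinoline
    "C1CCCCC1",                 # cyclohexane
    "c1ccc2c(c1)CCCC2",         # tetralin
]

DEFAULT_SUBSTITUENTS = [
    "C", "CC", "CCC", "C(C)C", "O", "OC", "OCC", "N", "NC", "N(C)C",
    "Cl", "F", "Br", "C#N", "C(F)(F)F", "C(=O)O", "C(=O)OC", "C(=O)N",
    "CO", "S", "SC", "C=C",
]

CLIFF_PAIR_TANIMOTO = 0.9
CLIFF_LOG_SHIFT = 1.2  # log10 units; > 1 guarantees a >= 10-fold potency change


@dataclass
class FixtureSpec:
    n_molecules: int = 200
    templates: List[str] = field(default_factory=lambda: list(DEFAULT_TEMPLATES))
    substituents: List[str] = field(default_factory=lambda: list(DEFAULT_SUBSTITUENTS))
    label_mode: str = "smooth"          # "smooth" | "cliff"
    cliff_fraction: float = 0.5         # fraction of matched pairs to relabel
    noise_sd: float = 0.1               # label noise, log10 units
    max_substituents: int = 2           # decorations per molecule
    seed: int = 0

    def __post_init__(self):
        if self.label_mode not in ("smooth", "cliff"):
            raise ValueError("label_mode must be 'smooth' or 'cliff'")
        if not (0.0 <= self.cliff_fraction <= 1.0):
            raise ValueError("cliff_fraction must be in [0, 1]")
        for smi in list(self.templates) + list(self.substituents):
            if Chem.MolFromSmiles(smi) is None:
                raise ValueError(f"fixture SMILES does not parse: {smi!r}")


# --------------------------------------------------------------------------
# Molecule enumeration
# --------------------------------------------------------------------------

def _open_positions(mol: Chem.Mol) -> List[int]:
    """Ring atoms that can accept one more substituent."""
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.IsInRing() and a.GetTotalNumHs() > 0
    ]


def _attach(template: Chem.Mol, placements: Sequence[Tuple[int, Chem.Mol]]) -> Optional[str]:
    rw = Chem.RWMol(template)
    for pos, sub in placements:
        offset = rw.GetNumAtoms()
        rw = Chem.RWMol(Chem.CombineMols(rw.GetMol(), sub))
        rw.AddBond(pos, offset, Chem.BondType.SINGLE)
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return Chem.MolToSmiles(out)


def generate_molecules(spec: FixtureSpec) -> List[MoleculeRecord]:
    """Enumerate decorated templates, deduplicated by canonical SMILES and
    sampled to `n_molecules` with the spec's seed."""
    if not spec.templates or not spec.substituents:
        raise ValueError("need at least one template and one substituent")
    rng = np.random.default_rng(spec.seed)
    subs = [Chem.MolFromSmiles(s) for s in spec.substituents]
    combos = []
    for t_idx, tmpl_smi in enumerate(spec.templates):
        tmpl = Chem.MolFromSmiles(tmpl_smi)
        positions = _open_positions(tmpl)
        for k in range(1, spec.max_substituents + 1):
            for pos_set in combinations(positions, k):
                for sub_idx in np.ndindex(*([len(subs)] * k)):
                    combos.append((t_idx, pos_set, sub_idx))
    order = rng.permutation(len(combos))
    templates = [Chem.MolFromSmiles(t) for t in spec.templates]
    seen, records = set(), []
    for ci in order:
        if len(records) >= spec.n_molecules:
            break
        t_idx, pos_set, sub_idx = combos[ci]
        smi = _attach(templates[t_idx], list(zip(pos_set, (subs[i] for i in sub_idx))))
        if smi is None or smi in seen:
            continue
        seen.add(smi)
        records.append(parse_smiles(smi))
    if len(records) < spec.n_molecules:
        warnings.warn(
            f"requested {spec.n_molecules} molecules but only {len(records)} "
            "unique products are enumerable; returning all",
            stacklevel=2,
        )
    return records


# --------------------------------------------------------------------------
# Label generation
# --------------------------------------------------------------------------

def matched_pairs(records: Sequence[MoleculeRecord],
                  threshold: float = CLIFF_PAIR_TANIMOTO) -> List[Tuple[int, int]]:
    """Index pairs passing the consensus structural-similarity threshold.

    Uses the same similarity function as the cliff-pair detector (max of
    fingerprint Tanimoto, scaffold Tanimoto, SMILES edit similarity) so that
    injected cliffs are recoverable by construction.
    """
    return [
        (i, j)
        for i, j in combinations(range(len(records)), 2)
        if structural_similarity(records[i], records[j]) >= threshold
    ]


def generate_labels(records: Sequence[MoleculeRecord], spec: FixtureSpec) -> np.ndarray:
    """Log10-potency labels per the spec's mode; see module docstring."""
    return generate_labels_with_cliffs(records, spec)[0]


def generate_labels_with_cliffs(
    records: Sequence[MoleculeRecord], spec: FixtureSpec
) -> Tuple[np.ndarray, List[Tuple[int, int]]]:
    """Labels plus the list of injected cliff pairs (empty in smooth mode)."""
    if not records:
        raise ValueError("empty corpus")
    rng = np.random.default_rng(spec.seed + 1)
    fp_matrix = np.stack([r.fingerprint.to_array() for r in records])
    w = rng.normal(size=fp_matrix.shape[1])
    latent = fp_matrix @ w
    sd = latent.std()
    latent = (latent - latent.mean()) / (sd if sd > 0 else 1.0)
    labels = 5.0 + latent + spec.noise_sd * rng.normal(size=len(records))
    if spec.label_mode == "smooth":
        return labels, []
    pairs = matched_pairs(records)
    if not pairs:
        warnings.warn("cliff mode requested but no matched pairs found; "
                      "returning smooth labels", stacklevel=2)
        return labels, []
    n_cliffs = max(1, int(round(spec.cliff_fraction * len(pairs))))
    order = rng.permutation(len(pairs))
    shifted = set()
    injected: List[Tuple[int, int]] = []
    for pi in order:
        if len(injected) >= n_cliffs:
            break
        i, j = pairs[pi]
        if i in shifted or j in shifted:
            continue
        # shift away from the partner so the pair's potency gap exceeds
        # 10-fold regardless of the smooth-label difference
        sign = 1.0 if labels[j] >= labels[i] else -1.0
        labels[j] += sign * CLIFF_LOG_SHIFT
        shifted.add(j)
        shifted.add(i)
        injected.append((min(i, j), max(i, j)))
    return labels, injected


def to_potency(labels: np.ndarray) -> np.ndarray:
    """Convert log10-potency labels to positive potencies (fold ratios apply)."""
    return np.power(10.0, np.asarray(labels, dtype=np.float64))
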