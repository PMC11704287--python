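"""Positive-sample generation for the contrastive channels.

Two augmentation families:

* **Attribute-level subgraph masking** (molecule channel / context prediction):
  a random center atom and its one-hop neighbors have their node features
  replaced by a reserved mask token.  Topology and edge features are retained,
  and the original rows are kept as reconstruction labels.

* **Scaffold-invariant side-chain perturbation** (scaffold channel): exactly
  one terminal side chain is detached at its attachment bond and replaced by a
  fragment from a pool, subject to chemical validity (sanitization), canonical
  scaffold preservation, and a bound on the number of changed heavy atoms
  (default: fewer than five, counted as removed + added).

The fragment-replacement engine is implemented directly on RDKit editable
molecules so that every accepted product is auditable against the invariants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chem_graph import GraphFeatures, MoleculeRecord, mask_vector

DEFAULT_MAX_CHANGED_ATOMS = 5


@dataclass
class MaskedGraph:
    """A graph with attribute-masked atoms and their original features."""

    base: GraphFeatures
    masked_atom_indices: np.ndarray
    mask_labels: np.ndarray  # original node-feature rows of the masked atoms

    def restore(self) -> GraphFeatures:
        """Undo the masking; returns a graph identical to the pre-mask input."""
        g = self.base.copy()
        g.node_features[self.masked_atom_indices] = self.mask_labels
        return g


@dataclass
class FragmentPool:
    """Side-chain fragments, each with exactly one ``[*]`` attachment point."""

    fragments: List[str]
    max_fragment_atoms: int = 8

    def __post_init__(self):
        for frag in self.fragments:
            mol = Chem.MolFromSmiles(frag)
            if mol is None:
                raise ValueError(f"fragment does not parse: {frag!r}")
            dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
            if len(dummies) != 1:
                raise ValueError(f"fragment must have exactly one attachment point: {frag!r}")

    def __len__(self) -> int:
        return len(self.fragments)


@dataclass
class PerturbationResult:
    parent_smiles: str
    child_smiles: str
    changed_atom_count: int
    replaced_site: int  # scaffold attachment atom index in the parent


# --------------------------------------------------------------------------
# Subgraph masking
# --------------------------------------------------------------------------

def subgraph_mask(graph: GraphFeatures, rng_seed: int) -> MaskedGraph:
    """Mask a uniformly random center atom and its one-hop neighborhood.

    Only node attributes change; the edge list and edge features are untouched.
    """
    if graph.n_atoms < 1:
        raise ValueError("graph must contain at least one atom")
    rng = np.random.default_rng(rng_seed)
    center = int(rng.integers(graph.n_atoms))
    neighbors = graph.edge_index[graph.edge_index[:, 0] == center, 1]
    masked = np.unique(np.concatenate([[center], neighbors])).astype(np.intp)
    out = graph.copy()
    labels = out.node_features[masked].copy()
    out.node_features[masked] = mask_vector()
    return MaskedGraph(base=out, masked_atom_indices=masked, mask_labels=labels)


# --------------------------------------------------------------------------
# Side-chain identification
# --------------------------------------------------------------------------

def _scaffold_atom_set(mol: Chem.Mol) -> set:
    scaf = MurckoScaffold.GetScaffoldForMol(mol)
    if scaf is None or scaf.GetNumAtoms() == 0:
        return set()
    match = mol.GetSubstructMatch(scaf)
    return set(match)


def identify_side_chains(record: MoleculeRecord) -> List[Tuple[int, str]]:
    """List every terminal side chain as (scaffold attachment atom, SMILES).

    A terminal side chain is a maximal connected set of non-scaffold atoms
    bonded to exactly one scaffold atom.  Acyclic molecules (empty scaffold)
    yield an empty list.
    """
    mol = record.mol()
    scaffold_atoms = _scaffold_atom_set(mol)
    if not scaffold_atoms:
        return []
    side_atoms = [a.GetIdx() for a in mol.GetAtoms() if a.GetIdx() not in scaffold_atoms]
    unvisited = set(side_atoms)
    chains: List[Tuple[int, str]] = []
    while unvisited:
        seed = unvisited.pop()
        comp = {seed}
        stack = [seed]
        while stack:
            u = stack.pop()
            for nb in mol.GetAtomWithIdx(u).GetNeighbors():
                j = nb.GetIdx()
                if j in unvisited:
                    unvisited.discard(j)
                    comp.add(j)
                    stack.append(j)
        attach = {
            nb.GetIdx()
            for i in comp
            for nb in mol.GetAtomWithIdx(i).GetNeighbors()
            if nb.GetIdx() in scaffold_atoms
        }
        if len(attach) == 1:
            smi = Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(comp), canonical=True)
            chains.append((attach.pop(), smi))
    return sorted(chains)


def _side_chain_components(mol: Chem.Mol):
    """Internal variant returning (attachment atom, component atom set)."""
    scaffold_atoms = _scaffold_atom_set(mol)
    if not scaffold_atoms:
        return []
    unvisited = {a.GetIdx() for a in mol.GetAtoms() if a.GetIdx() not in scaffold_atoms}
    comps = []
    while unvisited:
        seed = unvisited.pop()
        comp = {seed}
        stack = [seed]
        while stack:
            u = stack.pop()
            for nb in mol.GetAtomWithIdx(u).GetNeighbors():
                j = nb.GetIdx()
                if j in unvisited:
                    unvisited.discard(j)
                    comp.add(j)
                    stack.append(j)
        attach = {
            nb.GetIdx()
            for i in comp
            for nb in mol.GetAtomWithIdx(i).GetNeighbors()
            if nb.GetIdx() in scaffold_atoms
        }
        if len(attach) == 1:
            comps.append((attach.pop(), comp))
    return sorted(comps, key=lambda t: (t[0], sorted(t[1])))


# --------------------------------------------------------------------------
# Fragment pool
# --------------------------------------------------------------------------

def _fragment_with_dummy(mol: Chem.Mol, comp: set, attach_atom: int) -> str:
    """Canonical SMILES of a side-chain component with a [*] attachment point."""
    amap = {}
    em = Chem.RWMol()
    for idx in sorted(comp):
        a = mol.GetAtomWithIdx(idx)
        na = Chem.Atom(a.GetAtomicNum())
        na.SetFormalCharge(a.GetFormalCharge())
        amap[idx] = em.AddAtom(na)
    dummy = em.AddAtom(Chem.Atom(0))
    for idx in sorted(comp):
        for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
            j = nb.GetIdx()
            if j in comp and j > idx:
                em.AddBond(amap[idx], amap[j], mol.GetBondBetweenAtoms(idx, j).GetBondType())
            elif j == attach_atom:
                em.AddBond(amap[idx], dummy, Chem.BondType.SINGLE)
    frag = em.GetMol()
    Chem.SanitizeMol(frag)
    return Chem.MolToSmiles(frag)


def build_fragment_pool(
    corpus: Sequence[MoleculeRecord], max_fragment_atoms: int = 8
) -> FragmentPool:
    """Harvest unique terminal side chains from a corpus as a fragment pool."""
    if not corpus:
        raise ValueError("corpus is empty")
    frags = set()
    for rec in corpus:
        if not rec.scaffold_smiles:
            continue
        mol = rec.mol()
        for attach, comp in _side_chain_components(mol):
            if len(comp) > max_fragment_atoms:
                continue
            try:
                frags.add(_fragment_with_dummy(mol, comp, attach))
            except Exception:
                continue
    if not frags:
        raise ValueError(
            "no side-chain fragments could be harvested "
            "(corpus may contain only acyclic or unsubstituted molecules)"
        )
    return FragmentPool(fragments=sorted(frags), max_fragment_atoms=max_fragment_atoms)


# --------------------------------------------------------------------------
# Scaffold-invariant perturbation
# --------------------------------------------------------------------------

def _replace_side_chain(
    mol: Chem.Mol, comp: set, attach_atom: int, frag_smiles: str
) -> Chem.Mol | None:
    """Detach one side chain and attach a pool fragment; None if invalid."""
    frag = Chem.MolFromSmiles(frag_smiles)
    if frag is None:
        return None
    rw = Chem.RWMol(mol)
    rw.GetAtomWithIdx(attach_atom).SetAtomMapNum(1)
    for idx in sorted(comp, reverse=True):
        rw.RemoveAtom(idx)
    core = rw.GetMol()
    combo = Chem.RWMol(Chem.CombineMols(core, frag))
    attach_new = dummy_idx = frag_nb = None
    for a in combo.GetAtoms():
        if a.GetAtomMapNum() == 1:
            attach_new = a.GetIdx()
        if a.GetAtomicNum() == 0:
            dummy_idx = a.GetIdx()
            nbs = a.GetNeighbors()
            frag_nb = nbs[0].GetIdx() if nbs else None
    if attach_new is None or dummy_idx is None or frag_nb is None:
        return None
    combo.AddBond(attach_new, frag_nb, Chem.BondType.SINGLE)
    combo.RemoveAtom(dummy_idx)
    out = combo.GetMol()
    for a in out.GetAtoms():
        a.SetAtomMapNum(0)
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def scaffold_invariant_perturb(
    record: MoleculeRecord,
    pool: FragmentPool,
    max_changed_atoms: int = DEFAULT_MAX_CHANGED_ATOMS,
    n_samples: int = 5,
    rng_seed: int = 0,
) -> List[PerturbationResult]:
    """Generate up to `n_samples` scaffold-preserving side-chain replacements.

    Every accepted result replaces exactly one terminal side chain by a pool
    fragment, passes RDKit sanitization, preserves the canonical Bemis-Murcko
    scaffold, and changes (removed + added) fewer than `max_changed_atoms`
    heavy atoms.  Molecules without a scaffold yield an empty list.
    """
    if max_changed_atoms < 1:
        raise ValueError("max_changed_atoms must be >= 1")
    if len(pool) == 0:
        raise ValueError("fragment pool is empty")
    if not record.scaffold_smiles:
        warnings.warn(
            f"molecule {record.smiles_canonical} has no scaffold; skipped",
            stacklevel=2,
        )
        return []
    mol = record.mol()
    comps = _side_chain_components(mol)
    if not comps:
        return []
    rng = np.random.default_rng(rng_seed)
    # randomized candidate order over (side chain, fragment) pairs
    candidates = [(ci, fi) for ci in range(len(comps)) for fi in range(len(pool.fragments))]
    rng.shuffle(candidates)
    results: List[PerturbationResult] = []
    seen_children = set()
    for ci, fi in candidates:
        if len(results) >= n_samples:
            break
        attach, comp = comps[ci]
        frag_smiles = pool.fragments[fi]
        frag = Chem.MolFromSmiles(frag_smiles)
        added = frag.GetNumAtoms() - 1  # exclude the attachment dummy
        changed = len(comp) + added
        if changed >= max_changed_atoms:
            continue
        child = _replace_side_chain(mol, comp, attach, frag_smiles)
        if child is None:
            continue
        child_smiles = Chem.MolToSmiles(child)
        if child_smiles == record.smiles_canonical or child_smiles in seen_children:
            continue
        child_scaffold = MurckoScaffold.GetScaffoldForMol(child)
        if Chem.MolToSmiles(child_scaffold) != record.scaffold_smiles:
            continue
        seen_children.add(child_smiles)
        results.append(
            PerturbationResult(
                parent_smiles=record.smiles_canonical,
                child_smiles=child_smiles,
                changed_atom_count=changed,
                replaced_site=attach,
            )
        )
    return results
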