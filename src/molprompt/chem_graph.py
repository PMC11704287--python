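"""Molecule parsing, featurization, scaffolds, fingerprints and descriptors.

Everything downstream — perturbation, encoding, contrastive margins, landscape
probing — consumes the types defined here.  Chemistry is delegated to RDKit;
this module fixes the schemas (atom/bond features, functional-group
descriptors, fingerprint parameters) so they are identical across a corpus.

Conventions
-----------
* SMILES are canonicalized on ingest; a record's ``smiles_canonical`` always
  re-parses to the same molecule.
* The Bemis-Murcko scaffold (ring systems plus linkers, terminal side chains
  removed) of an acyclic molecule is the empty string.
* Fingerprints default to Morgan radius 2 hashed to 512 bits (ECFP4-style),
  the same parameters used for adaptive margins and representation probing.
* Tanimoto of two empty bit sets is defined as 1.0 (identical absence of
  features).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

DEFAULT_FP_RADIUS = 2
DEFAULT_FP_BITS = 512

# Atom feature schema (version 1):
#   element one-hot (incl. reserved MASK slot) | degree | formal charge |
#   aromatic flag | ring flag
ELEMENTS = ["C", "N", "O", "F", "P", "S", "Cl", "Br", "I"]
N_ELEMENT_CLASSES = len(ELEMENTS) + 1          # +1 = "other"
MASK_SLOT = N_ELEMENT_CLASSES                  # reserved masked-atom token
_DEGREES = 6                                   # 0..5, clipped
_CHARGES = 5                                   # -2..+2, clipped
ATOM_FEATURE_DIM = (N_ELEMENT_CLASSES + 1) + _DEGREES + _CHARGES + 2
BOND_FEATURE_DIM = 4 + 2                       # bond type | conjugated | ring
FEATURE_SCHEMA_VERSION = 1


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed/sanitized."""


@dataclass(frozen=True)
class BitFingerprint:
    """Sparse binary fingerprint: the set of on-bits of a hashed circular FP."""

    on_bits: frozenset
    n_bits: int
    radius: int

    def __post_init__(self):
        if self.n_bits < 1:
            raise ValueError(f"n_bits must be >= 1, got {self.n_bits}")
        if self.on_bits and max(self.on_bits) >= self.n_bits:
            raise ValueError("on_bits contain indices >= n_bits")

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.n_bits, dtype=np.float64)
        arr[list(self.on_bits)] = 1.0
        return arr


@dataclass
class GraphFeatures:
    """Node/edge feature matrices for the message-passing encoder.

    Each undirected bond is stored in both directions so that message passing
    can treat ``edge_index[:, 0] -> edge_index[:, 1]`` as directed messages.
    """

    node_features: np.ndarray          # (n_atoms, ATOM_FEATURE_DIM)
    edge_index: np.ndarray             # (n_edges, 2) int, both directions
    edge_features: np.ndarray          # (n_edges, BOND_FEATURE_DIM)
    atom_index_map: np.ndarray         # RDKit atom index per node row

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]

    def copy(self) -> "GraphFeatures":
        return GraphFeatures(
            self.node_features.copy(),
            self.edge_index.copy(),
            self.edge_features.copy(),
            self.atom_index_map.copy(),
        )


@dataclass
class MoleculeRecord:
    """A parsed molecule with its derived structural artifacts."""

    smiles_canonical: str
    atom_count: int
    scaffold_smiles: str
    fingerprint: BitFingerprint
    descriptor_vector: np.ndarray
    label: Optional[float] = None
    scaffold_fingerprint: BitFingerprint = field(default=None, repr=False)

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles_canonical)


# --------------------------------------------------------------------------
# Parsing and scaffolds
# --------------------------------------------------------------------------

def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"could not parse SMILES: {smiles!r}")
    return mol


def bemis_murcko_scaffold(smiles: str) -> str:
    """Canonical SMILES of the Bemis-Murcko framework; '' for acyclic input."""
    mol = _mol_from_smiles(smiles)
    scaf = MurckoScaffold.GetScaffoldForMol(mol)
    if scaf is None or scaf.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaf)


def ecfp_fingerprint(
    smiles: str, radius: int = DEFAULT_FP_RADIUS, n_bits: int = DEFAULT_FP_BITS
) -> BitFingerprint:
    """Hashed Morgan (circular) fingerprint of a molecule's canonical form."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    mol = _mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    return BitFingerprint(frozenset(bv.GetOnBits()), n_bits=n_bits, radius=radius)


def tanimoto(fp_a: BitFingerprint, fp_b: BitFingerprint) -> float:
    """|A ∩ B| / |A ∪ B|; two empty sets are defined as identical (1.0)."""
    if fp_a.n_bits != fp_b.n_bits:
        raise ValueError(f"fingerprint sizes differ: {fp_a.n_bits} vs {fp_b.n_bits}")
    union = len(fp_a.on_bits | fp_b.on_bits)
    if union == 0:
        return 1.0
    return len(fp_a.on_bits & fp_b.on_bits) / union


# --------------------------------------------------------------------------
# Functional-group descriptors
# --------------------------------------------------------------------------

# Fixed substructure schema (version 1): common functional groups and motifs.
# Counts are normalized per-slot by min(count, cap)/cap with cap=4, so the
# vector is corpus-independent and lies in [0, 1] element-wise.
FUNCTIONAL_GROUP_SMARTS = [
    ("hydroxyl", "[OX2H]"),
    ("carbonyl", "[CX3]=[OX1]"),
    ("carboxylic_acid", "[CX3](=O)[OX2H1]"),
    ("ester", "[CX3](=O)[OX2H0][#6]"),
    ("amide", "[NX3][CX3](=[OX1])"),
    ("primary_amine", "[NX3;H2;!$(NC=O)]"),
    ("secondary_amine", "[NX3;H1;!$(NC=O)]"),
    ("tertiary_amine", "[NX3;H0;!$(NC=O);!$(N=*)]"),
    ("nitrile", "[NX1]#[CX2]"),
    ("nitro", "[NX3](=O)=O"),
    ("ether", "[OD2]([#6])[#6]"),
    ("thiol", "[SX2H]"),
    ("thioether", "[SX2]([#6])[#6]"),
    ("sulfonamide", "[SX4](=O)(=O)[NX3]"),
    ("sulfone", "[SX4](=O)(=O)([#6])[#6]"),
    ("halogen_f", "[F]"),
    ("halogen_cl", "[Cl]"),
    ("halogen_br", "[Br]"),
    ("halogen_i", "[I]"),
    ("aldehyde", "[CX3H1]=O"),
    ("ketone", "[#6][CX3](=O)[#6]"),
    ("phenol", "[OX2H][cX3]"),
    ("aromatic_n", "[nX2,nX3]"),
    ("aromatic_o", "[oX2]"),
    ("aromatic_s", "[sX2]"),
    ("aromatic_ring_atom", "[a]"),
    ("aliphatic_ring_atom", "[A;R]"),
    ("alkene", "[CX3]=[CX3]"),
    ("alkyne", "[CX2]#[CX2]"),
    ("urea", "[NX3][CX3](=[OX1])[NX3]"),
    ("carbamate", "[NX3][CX3](=[OX1])[OX2]"),
    ("guanidine", "[NX3][CX3](=[NX2])[NX3]"),
    ("phosphate", "[PX4](=O)([OX2])([OX2])"),
    ("methyl", "[CH3]"),
    ("trifluoromethyl", "[CX4](F)(F)F"),
    ("quaternary_carbon", "[CX4]([#6])([#6])([#6])[#6]"),
    ("hydroxylamine", "[NX3][OX2H]"),
    ("azo", "[NX2]=[NX2]"),
    ("imine", "[CX3]=[NX2]"),
    ("hydrazine", "[NX3][NX3]"),
    ("isocyanate", "[NX2]=[CX2]=[OX1]"),
    ("epoxide", "[OX2r3]"),
    ("lactam", "[NX3R][CX3R](=[OX1])"),
    ("lactone", "[OX2R][CX3R](=[OX1])"),
    ("anhydride", "[CX3](=[OX1])[OX2][CX3](=[OX1])"),
    ("sulfoxide", "[SX3]=[OX1]"),
    ("boronic", "[BX3]"),
    ("silane", "[Si]"),
]
_FG_PATTERNS = [(name, Chem.MolFromSmarts(s)) for name, s in FUNCTIONAL_GROUP_SMARTS]
FG_DESCRIPTOR_DIM = len(FUNCTIONAL_GROUP_SMARTS)
FG_COUNT_CAP = 4


def functional_group_descriptors(smiles: str) -> np.ndarray:
    """Normalized functional-group counts: min(count, 4)/4 per fixed slot."""
    mol = _mol_from_smiles(smiles)
    vec = np.zeros(FG_DESCRIPTOR_DIM, dtype=np.float64)
    for i, (_, patt) in enumerate(_FG_PATTERNS):
        n = len(mol.GetSubstructMatches(patt))
        vec[i] = min(n, FG_COUNT_CAP) / FG_COUNT_CAP
    return vec


def molecular_weight(smiles: str) -> float:
    return Descriptors.MolWt(_mol_from_smiles(smiles))


# --------------------------------------------------------------------------
# Graph featurization
# --------------------------------------------------------------------------

def _atom_features(atom: Chem.Atom) -> np.ndarray:
    vec = np.zeros(ATOM_FEATURE_DIM, dtype=np.float64)
    sym = atom.GetSymbol()
    idx = ELEMENTS.index(sym) if sym in ELEMENTS else len(ELEMENTS)
    vec[idx] = 1.0
    off = N_ELEMENT_CLASSES + 1
    vec[off + min(atom.GetDegree(), _DEGREES - 1)] = 1.0
    off += _DEGREES
    charge = int(np.clip(atom.GetFormalCharge(), -2, 2))
    vec[off + charge + 2] = 1.0
    off += _CHARGES
    vec[off] = float(atom.GetIsAromatic())
    vec[off + 1] = float(atom.IsInRing())
    return vec


def atom_element_class(atom: Chem.Atom) -> int:
    """Element class index used as the masked-subgraph reconstruction target."""
    sym = atom.GetSymbol()
    return ELEMENTS.index(sym) if sym in ELEMENTS else len(ELEMENTS)


def mask_vector() -> np.ndarray:
    """Node-feature row for a masked atom: reserved token slot, zeros elsewhere."""
    vec = np.zeros(ATOM_FEATURE_DIM, dtype=np.float64)
    vec[MASK_SLOT] = 1.0
    return vec


_BOND_TYPE_INDEX = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}


def _bond_features(bond: Chem.Bond) -> np.ndarray:
    vec = np.zeros(BOND_FEATURE_DIM, dtype=np.float64)
    vec[_BOND_TYPE_INDEX.get(bond.GetBondType(), 0)] = 1.0
    vec[4] = float(bond.GetIsConjugated())
    vec[5] = float(bond.IsInRing())
    return vec


def featurize(smiles: str) -> GraphFeatures:
    """Node/edge feature matrices; each bond appears in both directions."""
    mol = _mol_from_smiles(smiles)
    n = mol.GetNumAtoms()
    x = np.stack([_atom_features(a) for a in mol.GetAtoms()]) if n else np.zeros((0, ATOM_FEATURE_DIM))
    edges, efeats = [], []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = _bond_features(bond)
        edges.extend([(u, v), (v, u)])
        efeats.extend([f, f])
    edge_index = (
        np.asarray(edges, dtype=np.intp) if edges else np.zeros((0, 2), dtype=np.intp)
    )
    edge_features = (
        np.stack(efeats) if efeats else np.zeros((0, BOND_FEATURE_DIM))
    )
    return GraphFeatures(x, edge_index, edge_features, np.arange(n, dtype=np.intp))


# --------------------------------------------------------------------------
# Record construction
# --------------------------------------------------------------------------

def parse_smiles(
    smiles: str,
    label: Optional[float] = None,
    fp_radius: int = DEFAULT_FP_RADIUS,
    fp_bits: int = DEFAULT_FP_BITS,
) -> MoleculeRecord:
    """Parse a SMILES string into a fully populated :class:`MoleculeRecord`."""
    mol = _mol_from_smiles(smiles)
    canonical = Chem.MolToSmiles(mol)
    scaffold = bemis_murcko_scaffold(canonical)
    fp = ecfp_fingerprint(canonical, fp_radius, fp_bits)
    scaf_fp = (
        ecfp_fingerprint(scaffold, fp_radius, fp_bits)
        if scaffold
        else BitFingerprint(frozenset(), n_bits=fp_bits, radius=fp_radius)
    )
    return MoleculeRecord(
        smiles_canonical=canonical,
        atom_count=mol.GetNumAtoms(),
        scaffold_smiles=scaffold,
        fingerprint=fp,
        descriptor_vector=functional_group_descriptors(canonical),
        label=label,
        scaffold_fingerprint=scaf_fp,
    )


def parse_corpus(smiles_list: Sequence[str], labels: Optional[Sequence[float]] = None):
    """Parse many SMILES; returns (records, failures) with duplicates collapsed.

    Failures are (row index, input, message) tuples; duplicate canonical
    SMILES keep the first occurrence.
    """
    records, failures, seen = [], [], set()
    for i, smi in enumerate(smiles_list):
        try:
            rec = parse_smiles(smi, label=None if labels is None else float(labels[i]))
        except (SmilesParseError, ValueError) as exc:
            failures.append((i, smi, str(exc)))
            continue
        if rec.smiles_canonical in seen:
            continue
        seen.add(rec.smiles_canonical)
        records.append(rec)
    return records, failures
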