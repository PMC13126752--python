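"""SMILES-level primitives.

Everything downstream (corpus filters, alignment, the sequence model and the
evaluation statistics) works on SMILES strings; this module is the single
place where strings meet the chemistry toolkit.  It provides tokenisation,
canonical and randomised forms, full and partial validity, Morgan
fingerprints with Tanimoto similarity, Bemis-Murcko scaffolds, ring systems,
Ertl functional groups and the descriptors the corpus filters need.
"""

from __future__ import annotations

import sys
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import DataStructs, Descriptors, rdFingerprintGenerator, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

from .partial import is_extensible  # re-exported  # noqa: F401

RDLogger.DisableLog("rdApp.*")

FP_RADIUS = 2
FP_BITS = 16_384

__all__ = [
    "SmilesError",
    "TokenizationError",
    "tokenize",
    "detokenize",
    "canonicalize",
    "enumerate_randomized",
    "is_valid",
    "is_extensible",
    "fingerprint",
    "tanimoto",
    "bm_scaffold",
    "molecule_properties",
    "ring_systems",
    "functional_groups",
    "MoleculeProperties",
]


class SmilesError(ValueError):
    """Raised when a string does not parse as a molecule."""


class TokenizationError(ValueError):
    """Raised when a string contains a character outside the SMILES lexicon."""

    def __init__(self, smiles: str, position: int):
        self.position = position
        super().__init__(
            f"unlexable character {smiles[position]!r} at position {position} in {smiles!r}"
        )


# Single-character tokens permitted outside brackets: organic-subset atoms,
# aromatic forms, digits (ring bonds), bonds, branches, dot and wildcard.
_SINGLE_CHAR = frozenset("BCNOPSFIbcnops0123456789()=#$:/\\.-*")


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into lexical tokens.

    Longest-match lexing with three multi-character classes: bracket atoms
    ``[...]`` as one token, the two-letter halogens ``Cl``/``Br``, and
    ``%nn`` two-digit ring closures.  Everything else is a single character.
    Concatenating the returned tokens reproduces the input exactly.
    """
    if not smiles:
        raise ValueError("empty SMILES string")
    tokens: list[str] = []
    i, n = 0, len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i)
            if j < 0:
                raise TokenizationError(smiles, i)
            tokens.append(smiles[i : j + 1])
            i = j + 1
        elif ch == "%":
            if i + 2 < n + 1 and smiles[i + 1 : i + 3].isdigit() and len(smiles[i + 1 : i + 3]) == 2:
                tokens.append(smiles[i : i + 3])
                i += 3
            else:
                raise TokenizationError(smiles, i)
        elif ch in ("C", "B") and i + 1 < n and smiles[i : i + 2] in ("Cl", "Br"):
            tokens.append(smiles[i : i + 2])
            i += 2
        elif ch in _SINGLE_CHAR:
            tokens.append(ch)
            i += 1
        else:
            raise TokenizationError(smiles, i)
    return tokens


def detokenize(tokens: list[str]) -> str:
    return "".join(tokens)


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"invalid SMILES: {smiles!r}")
    return mol


def canonicalize(smiles: str) -> str:
    """Toolkit-canonical form; deterministic and idempotent."""
    return Chem.MolToSmiles(_mol(smiles))


def is_valid(smiles: str) -> bool:
    """True iff the full string parses to a molecule."""
    if not smiles:
        return False
    return Chem.MolFromSmiles(smiles) is not None


def enumerate_randomized(smiles: str, n_max: int, seed: int) -> list[str]:
    """Distinct randomised SMILES of one molecule by atom-index shuffling.

    Draws ``n_max`` uniform atom permutations, writes each renumbered
    molecule unrooted and non-canonically, and deduplicates preserving first
    occurrence.  The list may be shorter than ``n_max`` (small molecules
    admit few distinct strings); there is no resampling to fill it up.
    """
    if n_max < 1:
        raise ValueError("n_max must be positive")
    mol = _mol(smiles)
    n_atoms = mol.GetNumAtoms()
    rng = np.random.default_rng(seed)
    seen: dict[str, None] = {}
    if n_atoms <= 1:
        seen[Chem.MolToSmiles(mol, canonical=False)] = None
    else:
        for _ in range(n_max):
            perm = rng.permutation(n_atoms).tolist()
            shuffled = Chem.RenumberAtoms(mol, perm)
            seen.setdefault(Chem.MolToSmiles(shuffled, canonical=False), None)
            if len(seen) >= n_max:
                break
    return list(seen)[:n_max]


@dataclass(frozen=True)
class Fingerprint:
    """Morgan fingerprint, radius 2 over 16,384 bits."""

    bits: DataStructs.ExplicitBitVect

    @property
    def n_bits(self) -> int:
        return self.bits.GetNumBits()

    @property
    def on_bits(self) -> frozenset[int]:
        return frozenset(self.bits.GetOnBits())


@lru_cache(maxsize=1)
def _morgan_generator():
    return rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=FP_BITS)


def fingerprint(smiles: str) -> Fingerprint:
    return Fingerprint(_morgan_generator().GetFingerprint(_mol(smiles)))


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprint lengths differ")
    return DataStructs.TanimotoSimilarity(a.bits, b.bits)


def similarity(smiles_a: str, smiles_b: str) -> float:
    """Tanimoto similarity of two molecules' Morgan fingerprints."""
    return tanimoto(fingerprint(smiles_a), fingerprint(smiles_b))


def bm_scaffold(smiles: str) -> str:
    """Canonical SMILES of the Bemis-Murcko framework ('' for acyclic input)."""
    return Chem.MolToSmiles(MurckoScaffold.GetScaffoldForMol(_mol(smiles)))


def strip_stereo(smiles: str) -> str:
    """Canonical SMILES with all tetrahedral/double-bond stereo removed."""
    mol = _mol(smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class MoleculeProperties:
    molecular_weight: float
    rotatable_bonds: int
    elements: frozenset[str]
    has_isotope: bool
    stereo_stripped: str
    n_fragments: int
    canonical: str


def molecule_properties(smiles: str, strict_rotatable: bool = True) -> MoleculeProperties:
    """Descriptor record used by the corpus filters.

    Rotatable bonds default to the strict definition (acyclic single bonds
    between non-terminal heavy atoms, amide C-N excluded).
    """
    mol = _mol(smiles)
    opt = (
        rdMolDescriptors.NumRotatableBondsOptions.Strict
        if strict_rotatable
        else rdMolDescriptors.NumRotatableBondsOptions.NonStrict
    )
    return MoleculeProperties(
        molecular_weight=Descriptors.MolWt(mol),
        rotatable_bonds=rdMolDescriptors.CalcNumRotatableBonds(mol, opt),
        elements=frozenset(a.GetSymbol() for a in mol.GetAtoms()),
        has_isotope=any(a.GetIsotope() != 0 for a in mol.GetAtoms()),
        stereo_stripped=strip_stereo(smiles),
        n_fragments=len(Chem.GetMolFrags(mol)),
        canonical=Chem.MolToSmiles(mol),
    )


def ring_systems(smiles: str) -> list[str]:
    """Ring systems as canonical fragment SMILES.

    A ring system is a connected component of the subgraph of ring bonds:
    fused and spiro rings merge into one system, rings joined only by an
    acyclic linker (biphenyl) stay separate.
    """
    mol = _mol(smiles)
    ring_bonds = [b for b in mol.GetBonds() if b.IsInRing()]
    if not ring_bonds:
        return []
    # union-find over atoms joined by ring bonds
    parent = {a.GetIdx(): a.GetIdx() for a in mol.GetAtoms()}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for b in ring_bonds:
        ra, rb = find(b.GetBeginAtomIdx()), find(b.GetEndAtomIdx())
        if ra != rb:
            parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for b in ring_bonds:
        groups.setdefault(find(b.GetBeginAtomIdx()), [])
    for b in ring_bonds:
        root = find(b.GetBeginAtomIdx())
        for idx in (b.GetBeginAtomIdx(), b.GetEndAtomIdx()):
            if idx not in groups[root]:
                groups[root].append(idx)
    out = []
    for atoms in groups.values():
        frag = Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(atoms), canonical=True)
        out.append(frag)
    return sorted(out)


@lru_cache(maxsize=1)
def _ifg_module():
    """RDKit's published implementation of Ertl's functional-group perception.

    Shipped with the toolkit under its Contrib tree; imported lazily so the
    rest of the module works even on stripped installations.
    """
    import os

    from rdkit import RDPaths

    path = os.path.join(RDPaths.RDContribDir, "IFG")
    if path not in sys.path:
        sys.path.append(path)
    import ifg  # type: ignore

    return ifg


def functional_groups(smiles: str) -> Counter:
    """Multiset of Ertl functional-group identifiers (atoms-in-group SMILES)."""
    mol = _mol(smiles)
    groups = _ifg_module().identify_functional_groups(mol)
    return Counter(g.type for g in groups)


def save_vocabulary_tokens(tokens: list[str], path: str) -> None:
    """Token-per-line plain-text export of a token inventory."""
    with open(path, "w") as fh:
        for tok in tokens:
            fh.write(tok + "\n")
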