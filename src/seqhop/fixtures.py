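"""Seeded synthetic data: assay tables, toy pair corpora, reference sets.

Everything downstream is testable offline from these generators.  Molecules
are assembled from a fragment grammar (aromatic/saturated cores with
enumerated attachment points, small substituents) so validity and the
property ranges the corpus filters look at (MW, elements, rotatable bonds)
are controlled by construction.  Assay tables emulate a ChEMBL-style
export: document/assay ids, B/F assay types, the six recognised activity
types, popularity columns, and - on request - planted molecules that each
violate exactly one filter rule, recorded in a manifest.

Toy pair corpora implement known source -> target string rules (identity,
Cl -> Br swap, benzene -> pyridine ring swap) that a small sequence model
can demonstrably learn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from . import chem

# Cores with format slots; every filled template must parse.
CORES: list[str] = [
    "c1ccc({0})cc1",
    "c1ccc({0})c({1})c1",
    "c1cc({0})cc({1})c1",
    "c1ccc2cc({0})ccc2c1",
    "c1csc({0})c1",
    "c1cc({0})on1",
    "c1cnc({0})nc1",
    "C1CCC({0})CC1",
    "C1CCN({0})CC1",
    "O=C({0})c1ccc({1})cc1",
    "c1c({0})cc({1})cc1{2}",
    "c1nc({0})cc({1})c1{2}",
    "C1CC({0})N({1})CC1{2}",
    "c1ccc(-c2ccc({0})cc2{1})cc1",
]

SUBSTITUENTS: list[str] = [
    "[H]", "C", "CC", "O", "OC", "N", "F", "Cl", "Br",
    "C(F)(F)F", "C#N", "C(C)C", "C(=O)N", "S(C)(=O)=O",
]

# compact decorations for the toy pair corpora: short strings keep the
# desk-scale sequence model's task well inside its training budget while
# the 3-slot cores keep the corpora diverse
SUBSTITUENTS_COMPACT: list[str] = [
    "[H]", "C", "O", "N", "F", "Cl", "Br", "OC", "C#N",
]

ACTIVITY_TYPES = ("IC50", "pIC50", "Ki", "pKi", "EC50", "pEC50")

PAIR_RULES = ("identity", "halogen_swap", "ring_swap")


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic assay table.

    Defaults give a desk-scale table: a few dozen documents, 8-25 molecules
    per assay (the assay-size window the corpus filter expects), no planted
    violations unless asked for.
    """

    seed: int = 0
    n_documents: int = 12
    assays_per_document: int = 2
    molecules_per_assay: tuple[int, int] = (8, 25)
    planted_violations: dict[str, int] = field(default_factory=dict)


def _assemble(rng: np.random.Generator, substituents: list[str] | None = None) -> str:
    substituents = substituents or SUBSTITUENTS
    core = CORES[rng.integers(len(CORES))]
    n_slots = core.count("{")
    subs = [substituents[rng.integers(len(substituents))] for _ in range(n_slots)]
    smi = core.format(*subs)
    assert chem.is_valid(smi), f"grammar produced invalid SMILES {smi!r}"
    return smi


def make_molecule(rng: np.random.Generator) -> str:
    """One canonical grammar molecule."""
    return chem.canonicalize(_assemble(rng))


def make_smiles_set(n: int, seed: int) -> list[str]:
    """n distinct canonical molecules from the grammar."""
    rng = np.random.default_rng(seed)
    out: dict[str, None] = {}
    guard = 0
    while len(out) < n:
        out.setdefault(make_molecule(rng), None)
        guard += 1
        if guard > 100 * n:
            raise RuntimeError("fragment grammar too small for requested set size")
    return list(out)[:n]


# ---- planted filter violations -----------------------------------------

def _spiro_chain(n_rings: int) -> str:
    """Linear chain of spiro-fused cyclohexanes with n_rings rings."""
    mol = Chem.MolFromSmiles("C1CCCCC1")
    for _ in range(n_rings - 1):
        rw = Chem.RWMol(mol)
        # spiro-fuse a new cyclohexane at the last ring carbon
        spiro = max(a.GetIdx() for a in rw.GetAtoms())
        first = None
        prev = spiro
        for i in range(5):
            idx = rw.AddAtom(Chem.Atom(6))
            rw.AddBond(prev, idx, Chem.BondType.SINGLE)
            if first is None:
                first = idx
            prev = idx
        rw.AddBond(prev, spiro, Chem.BondType.SINGLE)
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def _token_violation() -> str:
    """Cyclopentadecane written with explicit hydrogens: > 100 tokens,
    210 Da, zero rotatable bonds, C/H only."""
    mol = Chem.AddHs(Chem.MolFromSmiles("C1CCCCCCCCCCCCCC1"))
    return Chem.MolToSmiles(mol)


_VIOLATION_BUILDERS = {
    "invalid_smiles": lambda: ("C1CC(", {}),
    "multi_fragment": lambda: ("c1ccccc1.O", {}),
    "popular": lambda: ("Cc1ccccc1O", {"approved_drug": True}),
    "peptide": lambda: ("CC(C)Cc1ccccc1", {"peptide_flag": True}),
    "isotope": lambda: ("[13CH3]c1ccccc1", {}),
    "molecular_weight": lambda: (_spiro_chain(9), {}),
    "element": lambda: ("Ic1ccccc1", {}),
    "rotatable_bonds": lambda: ("CCCCCCCCCCC", {}),
    "token_count": lambda: (_token_violation(), {}),
}


def make_assay_table(spec: FixtureSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic assay table plus a manifest of planted violations.

    Returns (table, manifest); the manifest has columns molecule_id, rule
    and lists exactly the molecules that the corpus filter should reject.
    """
    unknown = set(spec.planted_violations) - set(_VIOLATION_BUILDERS)
    if unknown:
        raise ValueError(f"unknown violation rules: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    rows = []
    mol_counter = 0
    lo, hi = spec.molecules_per_assay
    for d in range(spec.n_documents):
        doc = f"DOC{d:04d}"
        for a in range(spec.assays_per_document):
            assay = f"ASSAY{d:04d}_{a}"
            assay_type = ("B", "F")[rng.integers(2)]
            activity = ACTIVITY_TYPES[rng.integers(len(ACTIVITY_TYPES))]
            n_mols = int(rng.integers(lo, hi + 1))
            seen: set[str] = set()
            while len(seen) < n_mols:
                seen.add(make_molecule(rng))
            for smi in sorted(seen):
                rows.append({
                    "document_id": doc, "assay_id": assay,
                    "assay_type": assay_type, "activity_type": activity,
                    "molecule_id": f"MOL{mol_counter:06d}", "smiles": smi,
                    "approved_drug": False, "wiki_listed": False,
                    "publication_count": 0, "peptide_flag": False,
                })
                mol_counter += 1
    table = pd.DataFrame(rows)
    manifest_rows = []
    assay_ids = sorted(table["assay_id"].unique())
    for rule, count in sorted(spec.planted_violations.items()):
        smi, flags = _VIOLATION_BUILDERS[rule]()
        for k in range(count):
            assay = assay_ids[int(rng.integers(len(assay_ids)))]
            doc = table.loc[table.assay_id == assay, "document_id"].iloc[0]
            row = {
                "document_id": doc, "assay_id": assay,
                "assay_type": table.loc[table.assay_id == assay, "assay_type"].iloc[0],
                "activity_type": table.loc[table.assay_id == assay, "activity_type"].iloc[0],
                "molecule_id": f"BAD_{rule}_{k}", "smiles": smi,
                "approved_drug": False, "wiki_listed": False,
                "publication_count": 0, "peptide_flag": False,
            }
            row.update(flags)
            manifest_rows.append({"molecule_id": row["molecule_id"], "rule": rule})
            table = pd.concat([table, pd.DataFrame([row])], ignore_index=True)
    manifest = pd.DataFrame(manifest_rows, columns=["molecule_id", "rule"])
    return table, manifest


def write_assay_table(table: pd.DataFrame, manifest: pd.DataFrame, path: str,
                      manifest_path: str | None = None) -> None:
    table.to_csv(path, sep="\t", index=False)
    if manifest_path:
        manifest.to_json(manifest_path, orient="records", indent=1)


# ---- toy transformation-pair corpora ------------------------------------

def _halogen_source(rng: np.random.Generator) -> str:
    """Compact grammar molecule containing at least one Cl and no Br."""
    while True:
        core = CORES[rng.integers(len(CORES))]
        n_slots = core.count("{")
        subs = [SUBSTITUENTS_COMPACT[rng.integers(len(SUBSTITUENTS_COMPACT))]
                for _ in range(n_slots)]
        pos = int(rng.integers(n_slots))
        subs[pos] = "Cl"
        smi = core.format(*subs)
        if "Br" not in smi:
            return smi


def make_pair_corpus(rule: str, n: int, seed: int = 0) -> pd.DataFrame:
    """n (source, target) SMILES pairs following a known string rule.

    identity      target = source
    halogen_swap  target replaces every Cl with Br (same scaffold)
    ring_swap     benzene core becomes pyridine (scaffold always changes)
    """
    if rule not in PAIR_RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {PAIR_RULES}")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    rows = []
    guard = 0
    while len(rows) < n:
        guard += 1
        if guard > 200 * n:
            raise RuntimeError("could not generate enough distinct pairs")
        if rule == "identity":
            src = _assemble(rng, SUBSTITUENTS_COMPACT)
            tgt = src
        elif rule == "halogen_swap":
            src = _halogen_source(rng)
            tgt = src.replace("Cl", "Br")
        else:  # ring_swap: benzene core -> pyridine core, substituents kept
            subs = [SUBSTITUENTS_COMPACT[rng.integers(len(SUBSTITUENTS_COMPACT))]
                    for _ in range(3)]
            src = "c1c({0})cc({1})cc1{2}".format(*subs)
            tgt = "c1c({0})cc({1})nc1{2}".format(*subs)
        if src in seen:
            continue
        if not (chem.is_valid(src) and chem.is_valid(tgt)):
            continue
        scaffold_change = chem.bm_scaffold(src) != chem.bm_scaffold(tgt)
        seen.add(src)
        rows.append({"source": src, "target": tgt, "rule": rule,
                     "scaffold_change": scaffold_change})
    return pd.DataFrame(rows)


def write_pair_corpus(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)
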