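"""Molecule-pairs corpus construction from assay tables.

Two molecules tested in the same (small) bioassay are treated as
medicinal-chemistry-similar: chemists chose to make and test them in the
same programme.  This module turns a tabular assay export into a corpus of
such unordered molecule pairs through a fixed sequence of stages:

1. molecule-level filters (validity, single fragment, popularity/peptide
   flags, isotopes, MW <= 600 Da, allowed elements, <= 7 rotatable bonds,
   <= 100 tokens);
2. assay-level filters (binding/functional type, listed activity types,
   8-25 surviving molecules);
3. exhaustive pairing within each assay, global deduplication by unordered
   canonical pair;
4. a per-document cap of 30 randomly sampled pairs;
5. exclusion of pairs differing only in stereochemistry;
6. a seeded 80/10/10 train/validation/test split (seed 42 by default).

Activity values are never used numerically; only the types gate inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import chem

ALLOWED_ELEMENTS = frozenset({"C", "N", "H", "O", "S", "F", "Cl", "Br"})
ALLOWED_ASSAY_TYPES = frozenset({"B", "F"})
ALLOWED_ACTIVITY_TYPES = frozenset({"IC50", "pIC50", "Ki", "pKi", "EC50", "pEC50"})

REQUIRED_COLUMNS = (
    "document_id", "assay_id", "assay_type", "activity_type", "molecule_id", "smiles",
)


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class FilterConfig:
    max_molecular_weight: float = 600.0
    max_rotatable_bonds: int = 7
    max_tokens: int = 100
    allowed_elements: frozenset = ALLOWED_ELEMENTS
    min_assay_size: int = 8
    max_assay_size: int = 25
    document_pair_cap: int = 30
    publication_count_limit: int = 5
    strict_rotatable: bool = True


@dataclass(frozen=True)
class MoleculePair:
    """Unordered pair of canonical SMILES sharing an assay.

    `source`/`target` are stored in sorted order so {A, B} has a single
    identity for deduplication; training-direction expansion happens later
    in the alignment stage.
    """

    source: str
    target: str
    assay_id: str
    document_id: str

    @property
    def key(self) -> tuple[str, str]:
        return (self.source, self.target)

    @property
    def pair_id(self) -> str:
        return f"{self.document_id}:{self.assay_id}:{hash_pair(self.source, self.target)}"


def hash_pair(a: str, b: str) -> str:
    import zlib

    return format(zlib.crc32(f"{a}|{b}".encode()), "08x")


@dataclass
class CorpusSplit:
    train: list
    validation: list
    test: list
    seed: int

    def __iter__(self):
        yield from (self.train, self.validation, self.test)


def read_assay_table(path: str, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("approved_drug", "wiki_listed", "peptide_flag"):
        if col in df:
            df[col] = df[col].map(lambda v: str(v).lower() in ("1", "true", "yes"))
    if "publication_count" in df:
        df["publication_count"] = pd.to_numeric(df["publication_count"], errors="coerce").fillna(0)
    return df


def filter_molecules(records: pd.DataFrame, config: FilterConfig | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply all molecule-level rules; return (retained, rejection log).

    Each rule is a pure predicate; the log names the first failing rule per
    molecule, in the order documented in the module docstring.
    """
    config = config or FilterConfig()
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"assay table is missing columns: {missing}")

    rejections: list[tuple[str, str]] = []
    keep_idx: list[int] = []
    canonical: dict[int, str] = {}
    for idx, row in records.iterrows():
        rule = _first_failing_rule(row, config)
        if rule is None:
            keep_idx.append(idx)
            canonical[idx] = chem.canonicalize(row["smiles"])
        else:
            rejections.append((row["molecule_id"], rule))
    retained = records.loc[keep_idx].copy()
    retained["canonical_smiles"] = pd.Series(canonical)
    log = pd.DataFrame(rejections, columns=["molecule_id", "rule"])
    return retained, log


def _first_failing_rule(row, config: FilterConfig) -> str | None:
    smiles = row["smiles"]
    if not isinstance(smiles, str) or not chem.is_valid(smiles):
        return "invalid_smiles"
    props = chem.molecule_properties(smiles, strict_rotatable=config.strict_rotatable)
    if props.n_fragments > 1:
        return "multi_fragment"
    if bool(row.get("approved_drug")) or bool(row.get("wiki_listed")) or (
        float(row.get("publication_count") or 0) > config.publication_count_limit
    ):
        return "popular"
    if bool(row.get("peptide_flag")) or _peptide_heuristic(smiles):
        return "peptide"
    if props.has_isotope:
        return "isotope"
    if props.molecular_weight > config.max_molecular_weight:
        return "molecular_weight"
    if not props.elements <= config.allowed_elements:
        return "element"
    if props.rotatable_bonds > config.max_rotatable_bonds:
        return "rotatable_bonds"
    if len(chem.tokenize(smiles)) > config.max_tokens:
        return "token_count"
    return None


_PEPTIDE_SMARTS = None


def _peptide_heuristic(smiles: str) -> bool:
    """Backbone of >= 4 amide repeats, used when no peptide flag is supplied."""
    global _PEPTIDE_SMARTS
    from rdkit import Chem as _C

    if _PEPTIDE_SMARTS is None:
        _PEPTIDE_SMARTS = _C.MolFromSmarts(
            "C(=O)NCC(=O)NCC(=O)NCC(=O)N"
        )
    mol = _C.MolFromSmiles(smiles)
    return mol is not None and mol.HasSubstructMatch(_PEPTIDE_SMARTS)


def filter_assays(records: pd.DataFrame, config: FilterConfig | None = None) -> pd.DataFrame:
    """Keep B/F assays with listed activity types and 8-25 surviving molecules."""
    config = config or FilterConfig()
    ok_type = records["assay_type"].isin(ALLOWED_ASSAY_TYPES)
    ok_act = records["activity_type"].isin(ALLOWED_ACTIVITY_TYPES)
    records = records[ok_type & ok_act]
    sizes = records.groupby("assay_id")["molecule_id"].nunique()
    keep = sizes[(sizes >= config.min_assay_size) & (sizes <= config.max_assay_size)].index
    return records[records["assay_id"].isin(keep)].copy()


def enumerate_pairs(assay_records: pd.DataFrame) -> list[MoleculePair]:
    """All unordered distinct pairs within one assay (n*(n-1)/2)."""
    pairs = []
    for assay_id, grp in assay_records.groupby("assay_id", sort=True):
        doc = grp["document_id"].iloc[0]
        mols = sorted(set(grp["canonical_smiles"]))
        for i in range(len(mols)):
            for j in range(i + 1, len(mols)):
                a, b = mols[i], mols[j]
                pairs.append(MoleculePair(a, b, str(assay_id), str(doc)))
    return pairs


def dedupe_pairs(pairs: list[MoleculePair]) -> list[MoleculePair]:
    """Corpus-level uniqueness by unordered canonical pair (first kept)."""
    seen: set[tuple[str, str]] = set()
    out = []
    for p in pairs:
        if p.key not in seen:
            seen.add(p.key)
            out.append(p)
    return out


def cap_document_pairs(pairs: list[MoleculePair], cap: int = 30, seed: int = 0
                       ) -> list[MoleculePair]:
    """Per document keep at most `cap` pairs, sampled uniformly without
    replacement with a seeded generator; documents below the cap pass
    through unchanged."""
    by_doc: dict[str, list[MoleculePair]] = {}
    for p in pairs:
        by_doc.setdefault(p.document_id, []).append(p)
    rng = np.random.default_rng(seed)
    out: list[MoleculePair] = []
    for doc in sorted(by_doc):
        doc_pairs = by_doc[doc]
        if len(doc_pairs) <= cap:
            out.extend(doc_pairs)
        else:
            idx = rng.choice(len(doc_pairs), size=cap, replace=False)
            out.extend(doc_pairs[i] for i in sorted(idx))
    return out


def exclude_stereo_only(pairs: list[MoleculePair]) -> list[MoleculePair]:
    """Drop pairs whose members share a stereo-stripped canonical form."""
    out = []
    cache: dict[str, str] = {}

    def stripped(s: str) -> str:
        if s not in cache:
            cache[s] = chem.strip_stereo(s)
        return cache[s]

    for p in pairs:
        if stripped(p.source) != stripped(p.target):
            out.append(p)
    return out


def split_pairs(pairs: list[MoleculePair], fractions=(0.8, 0.1, 0.1), seed: int = 42
                ) -> CorpusSplit:
    """Seeded disjoint train/validation/test partition.

    |train| = round(f_train * N); the remainder is divided between
    validation and test with any odd element going to validation.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    n = len(pairs)
    n_train = round(fractions[0] * n)
    rest = n - n_train
    n_valid = rest - rest // 2  # odd remainder goes to validation
    shuffled = [pairs[i] for i in order]
    return CorpusSplit(
        train=shuffled[:n_train],
        validation=shuffled[n_train : n_train + n_valid],
        test=shuffled[n_train + n_valid :],
        seed=seed,
    )


def scaffold_pair_stats(pairs: list[MoleculePair]) -> float:
    """Fraction of pairs whose members have distinct Bemis-Murcko scaffolds."""
    if not pairs:
        return 0.0
    cache: dict[str, str] = {}

    def scaf(s: str) -> str:
        if s not in cache:
            cache[s] = chem.bm_scaffold(s)
        return cache[s]

    distinct = sum(1 for p in pairs if scaf(p.source) != scaf(p.target))
    return distinct / len(pairs)


def build_corpus(records: pd.DataFrame, config: FilterConfig | None = None,
                 seed: int = 0, split_seed: int = 42):
    """Full pipeline: filters -> pairs -> cap -> stereo exclusion -> split.

    Returns (CorpusSplit, rejection_log, stats dict).
    """
    config = config or FilterConfig()
    retained, log = filter_molecules(records, config)
    assays = filter_assays(retained, config)
    pairs = dedupe_pairs(enumerate_pairs(assays))
    capped = cap_document_pairs(pairs, cap=config.document_pair_cap, seed=seed)
    kept = exclude_stereo_only(capped)
    split = split_pairs(kept, seed=split_seed)
    stats = {
        "molecules_in": int(len(records)),
        "molecules_retained": int(len(retained)),
        "assays_retained": int(assays["assay_id"].nunique()) if len(assays) else 0,
        "unique_pairs": len(pairs),
        "capped_pairs": len(capped),
        "pairs_after_stereo_exclusion": len(kept),
        "train": len(split.train),
        "validation": len(split.validation),
        "test": len(split.test),
        "distinct_scaffold_fraction": scaffold_pair_stats(kept),
    }
    return split, log, stats


def pairs_to_frame(pairs: list[MoleculePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.source, p.target, p.assay_id, p.document_id, p.pair_id) for p in pairs],
        columns=["source", "target", "assay_id", "document_id", "pair_id"],
    )


def write_pairs(pairs: list[MoleculePair], path: str) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)


def read_pairs(path: str) -> list[MoleculePair]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        MoleculePair(r.source, r.target, r.assay_id, r.document_id)
        for r in df.itertuples()
    ]
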