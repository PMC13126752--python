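"""Corpus construction rules: molecule/assay filters, pair enumeration,
per-document cap, stereo-only exclusion and the seeded split."""

import numpy as np
import pandas as pd
import pytest

from seqhop import chem, corpus, fixtures
from seqhop.corpus import FilterConfig, MoleculePair


def _table(planted=None, seed=3, n_documents=4):
    spec = fixtures.FixtureSpec(seed=seed, n_documents=n_documents,
                                planted_violations=planted or {})
    return fixtures.make_assay_table(spec)


ALL_RULES = {
    "invalid_smiles": 1, "multi_fragment": 1, "popular": 1, "peptide": 1,
    "isotope": 1, "molecular_weight": 2, "element": 1, "rotatable_bonds": 1,
    "token_count": 1,
}


class TestFilterMolecules:
    def test_clean_table_rejects_nothing(self):
        table, _ = _table()
        retained, log = corpus.filter_molecules(table)
        assert len(log) == 0
        assert len(retained) == len(table)

    def test_rejection_log_matches_planted_manifest_exactly(self):
        table, manifest = _table(planted=ALL_RULES)
        _, log = corpus.filter_molecules(table)
        key = ["molecule_id", "rule"]
        got = log.sort_values(key).reset_index(drop=True)
        want = manifest.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(got[key], want[key])

    @pytest.mark.parametrize("smiles,rule", [
        ("C[Si](C)(C)C", "element"),
        ("CCCCCCCCCCC", "rotatable_bonds"),       # 8 rotatable bonds
        ("[13CH3]c1ccccc1", "isotope"),
        ("c1ccccc1.O", "multi_fragment"),
    ])
    def test_single_rule_violations(self, smiles, rule):
        table, _ = _table()
        row = table.iloc[[0]].copy()
        row["molecule_id"] = "X"
        row["smiles"] = smiles
        _, log = corpus.filter_molecules(pd.concat([table, row], ignore_index=True))
        assert log.set_index("molecule_id")["rule"].to_dict() == {"X": rule}

    def test_retained_molecule_passes_all_rules(self):
        table, _ = _table()
        row = table.iloc[[0]].copy()
        row["molecule_id"] = "ETOH"
        row["smiles"] = "CCO"
        retained, log = corpus.filter_molecules(pd.concat([table, row], ignore_index=True))
        assert "ETOH" in set(retained["molecule_id"])

    def test_missing_columns_schema_error(self):
        with pytest.raises(corpus.SchemaError):
            corpus.filter_molecules(pd.DataFrame({"smiles": ["CCO"]}))

    def test_filter_rules_are_order_independent_predicates(self):
        # shuffling rows changes nothing about who is rejected
        table, manifest = _table(planted=ALL_RULES)
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        _, log_a = corpus.filter_molecules(table)
        _, log_b = corpus.filter_molecules(shuffled)
        assert set(map(tuple, log_a.values)) == set(map(tuple, log_b.values))


class TestFilterAssays:
    def _records(self, n, assay_type="B", activity="IC50"):
        mols = fixtures.make_smiles_set(n, seed=50)
        return pd.DataFrame({
            "document_id": "D", "assay_id": "A", "assay_type": assay_type,
            "activity_type": activity,
            "molecule_id": [f"m{i}" for i in range(n)],
            "smiles": mols, "canonical_smiles": mols,
        })

    def test_in_window_retained(self):
        assert len(corpus.filter_assays(self._records(10))) == 10

    @pytest.mark.parametrize("n", [7, 26])
    def test_size_bounds(self, n):
        assert len(corpus.filter_assays(self._records(n))) == 0

    def test_admet_assay_dropped(self):
        assert len(corpus.filter_assays(self._records(10, assay_type="A"))) == 0

    def test_unlisted_activity_dropped(self):
        assert len(corpus.filter_assays(self._records(10, activity="Kd"))) == 0


class TestPairs:
    def _pairs(self, n, seed=60):
        mols = fixtures.make_smiles_set(n, seed=seed)
        df = pd.DataFrame({
            "document_id": "D", "assay_id": "A", "assay_type": "B",
            "activity_type": "Ki", "molecule_id": [f"m{i}" for i in range(n)],
            "smiles": mols, "canonical_smiles": [chem.canonicalize(m) for m in mols],
        })
        return corpus.enumerate_pairs(df)

    @pytest.mark.parametrize("n,expected", [(8, 28), (25, 300)])
    def test_pair_count(self, n, expected):
        assert len(self._pairs(n)) == expected

    def test_unordered_identity(self):
        pairs = self._pairs(8)
        keys = {p.key for p in pairs}
        assert len(keys) == len(pairs)
        for p in pairs:
            assert p.source < p.target  # stored sorted, so {A,B} is unique

    def test_cap_document_pairs(self):
        pairs = self._pairs(25)  # 300 pairs in one document
        capped = corpus.cap_document_pairs(pairs, cap=30, seed=1)
        assert len(capped) == 30
        assert corpus.cap_document_pairs(pairs, cap=30, seed=1) == capped  # deterministic
        # idempotent and never increasing
        assert corpus.cap_document_pairs(capped, cap=30, seed=2) == capped
        below = corpus.cap_document_pairs(pairs[:10], cap=30, seed=1)
        assert below == pairs[:10]

    def test_stereo_only_exclusion(self):
        mk = lambda a, b: MoleculePair(a, b, "A", "D")
        pairs = [
            mk(chem.canonicalize("C[C@H](N)O"), chem.canonicalize("C[C@@H](N)O")),
            mk("CCO", "CCN"),
            mk(chem.canonicalize("CC(N)O"), chem.canonicalize("C[C@H](N)O")),
        ]
        kept = corpus.exclude_stereo_only(pairs)
        assert kept == [pairs[1]]


class TestSplit:
    def _pairs(self, n):
        return [MoleculePair(f"A{i}", f"B{i}", "a", "d") for i in range(n)]

    def test_sizes_80_10_10(self):
        split = corpus.split_pairs(self._pairs(1000), seed=42)
        assert (len(split.train), len(split.validation), len(split.test)) == (800, 100, 100)

    def test_odd_remainder_to_validation(self):
        split = corpus.split_pairs(self._pairs(11), seed=42)
        assert len(split.train) == 9
        assert len(split.validation) == 1
        assert len(split.test) == 1
        split = corpus.split_pairs(self._pairs(14), seed=42)
        assert (len(split.validation), len(split.test)) == (2, 1)

    def test_deterministic_and_partition(self):
        pairs = self._pairs(97)
        s1 = corpus.split_pairs(pairs, seed=42)
        s2 = corpus.split_pairs(pairs, seed=42)
        assert s1.train == s2.train and s1.validation == s2.validation and s1.test == s2.test
        combined = s1.train + s1.validation + s1.test
        assert sorted(p.key for p in combined) == sorted(p.key for p in pairs)

    def test_bad_fractions(self):
        with pytest.raises(ValueError):
            corpus.split_pairs(self._pairs(10), fractions=(0.5, 0.2, 0.2))


class TestScaffoldStats:
    def test_halogen_swap_pairs_share_scaffolds(self):
        df = fixtures.make_pair_corpus("halogen_swap", 20, seed=1)
        pairs = [MoleculePair(chem.canonicalize(r.source), chem.canonicalize(r.target), "a", "d")
                 for r in df.itertuples()]
        assert corpus.scaffold_pair_stats(pairs) == 0.0

    def test_ring_swap_pairs_change_scaffolds(self):
        df = fixtures.make_pair_corpus("ring_swap", 20, seed=1)
        pairs = [MoleculePair(chem.canonicalize(r.source), chem.canonicalize(r.target), "a", "d")
                 for r in df.itertuples()]
        assert corpus.scaffold_pair_stats(pairs) == 1.0


class TestEndToEnd:
    def test_no_split_member_fails_any_filter(self):
        table, _ = _table(planted=ALL_RULES, n_documents=6)
        split, _, stats = corpus.build_corpus(table, seed=0)
        cfg = FilterConfig()
        for part in split:
            for p in part:
                for smi in (p.source, p.target):
                    props = chem.molecule_properties(smi)
                    assert props.molecular_weight <= cfg.max_molecular_weight
                    assert props.rotatable_bonds <= cfg.max_rotatable_bonds
                    assert props.elements <= cfg.allowed_elements
                    assert not props.has_isotope
                    assert len(chem.tokenize(smi)) <= cfg.max_tokens
        assert stats["train"] == round(0.8 * stats["pairs_after_stereo_exclusion"])
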