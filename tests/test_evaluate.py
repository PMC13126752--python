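"""Evaluation statistics: invalid rate, similarity reports, global target,
NLL-similarity correlation, scaffold recall and neighbour attribution."""

import numpy as np
import pandas as pd
import pytest

from seqhop import chem, evaluate, fixtures
from seqhop.decode import GenerationResult


def _result(smiles: str, nll: float = 1.0) -> GenerationResult:
    valid = chem.is_valid(smiles)
    return GenerationResult(smiles, nll, valid, chem.canonicalize(smiles) if valid else "")


class TestInvalidRate:
    def test_all_valid(self):
        assert evaluate.invalid_rate([_result("CCO"), _result("CCN")]) == 0.0

    def test_one_of_four(self):
        rs = [_result("CCO"), _result("C("), _result("CCN"), _result("c1ccccc1")]
        assert evaluate.invalid_rate(rs) == 0.25

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evaluate.invalid_rate([])


class TestSimilarityAnalysis:
    def test_identity_generation(self):
        rep = evaluate.similarity_analysis([_result("CCO")], "CCO")
        assert rep.identity_rate == 1.0
        assert rep.records.sim_source.iloc[0] == 1.0

    def test_quantiles_recompute_from_records(self):
        mols = fixtures.make_smiles_set(12, seed=2)
        rep = evaluate.similarity_analysis([_result(m) for m in mols[1:]], mols[0])
        sims = rep.records.sim_source.to_numpy()
        assert rep.quantiles["q50"] == pytest.approx(np.quantile(sims, 0.5))
        for t, frac in rep.fraction_above.items():
            assert frac == pytest.approx((sims > t).mean())

    def test_reference_column_populated(self):
        rep = evaluate.similarity_analysis([_result("CCO")], "CCN", reference="CCO")
        assert rep.records.sim_reference.iloc[0] == 1.0


class TestGlobalTarget:
    def test_exact_copy_in_assay(self):
        assay = ["CCO", "CCN", "c1ccccc1"]
        best, sim = evaluate.global_target("CCO", assay, input_molecule="CCN")
        assert best == chem.canonicalize("CCO")
        assert sim == 1.0

    def test_single_candidate_after_exclusion(self):
        best, _ = evaluate.global_target("CCO", ["CCN", "CCC"], input_molecule="CCN")
        assert best == chem.canonicalize("CCC")

    def test_input_only_assay_rejected(self):
        with pytest.raises(ValueError):
            evaluate.global_target("CCO", ["CCN"], input_molecule="CCN")

    def test_matches_exhaustive_scan(self):
        assay = fixtures.make_smiles_set(15, seed=6)
        gen = fixtures.make_smiles_set(1, seed=60)[0]
        inp = assay[0]
        best, sim = evaluate.global_target(gen, assay, inp)
        fp = chem.fingerprint(gen)
        brute = max(
            ((chem.tanimoto(fp, chem.fingerprint(m)), m) for m in assay[1:]),
            key=lambda t: t[0])
        assert sim == pytest.approx(brute[0])


class TestCorrelation:
    def test_perfect_negative_relation(self):
        df = pd.DataFrame({"sim_source": np.linspace(1, 0, 10),
                           "nll": np.linspace(0, 30, 10)})
        rep = evaluate.nll_similarity_correlation(df)
        assert rep.spearman_rho == pytest.approx(-1.0)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"sim_source": rng.random(30), "nll": rng.random(30)})
        r1 = evaluate.nll_similarity_correlation(df)
        r2 = evaluate.nll_similarity_correlation(df.sample(frac=1.0, random_state=4))
        assert r1.spearman_rho == pytest.approx(r2.spearman_rho)

    def test_constant_column_reported_undefined(self):
        df = pd.DataFrame({"sim_source": [0.5] * 5, "nll": range(5)})
        rep = evaluate.nll_similarity_correlation(df)
        assert not rep.defined

    def test_binned_table_counts_all_records(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"sim_source": rng.random(40), "nll": rng.random(40)})
        rep = evaluate.nll_similarity_correlation(df)
        assert rep.binned.to_numpy().sum() == 40


@pytest.fixture(scope="module")
def reference():
    df = fixtures.make_pair_corpus("ring_swap", 40, seed=9)
    return sorted({chem.canonicalize(s) for s in df.source} |
                  {chem.canonicalize(t) for t in df.target})


class TestScaffoldRecall:
    def test_generating_reference_set_gives_full_recall(self, reference):
        universe = evaluate.scaffold_universe(reference)
        gen = [[_result(m) for m in reference]]
        rep = evaluate.scaffold_recall([reference[0]], gen, universe)
        assert rep.mean_recall == 1.0

    def test_empty_generation_zero(self, reference):
        universe = evaluate.scaffold_universe(reference)
        rep = evaluate.scaffold_recall([reference[0]], [[]], universe)
        assert rep.mean_recall == 0.0

    def test_own_scaffold_excluded(self, reference):
        universe = evaluate.scaffold_universe(reference)
        inp = reference[0]
        rep = evaluate.scaffold_recall([inp], [[_result(inp)]], universe)
        assert rep.mean_recall == 0.0

    def test_denominator_excludes_input_scaffold(self, reference):
        universe = evaluate.scaffold_universe(reference)
        other = [m for m in reference
                 if chem.bm_scaffold(m) != chem.bm_scaffold(reference[0])][0]
        rep = evaluate.scaffold_recall([reference[0]], [[_result(other)]], universe)
        assert rep.mean_recall == pytest.approx(1.0 / (len(universe) - 1))

    def test_recall_curve_monotone_in_generation_number(self, reference):
        universe = evaluate.scaffold_universe(reference)
        stream = [_result(m) for m in reference]  # nested prefixes
        curve = evaluate.recall_curve([reference[0]], [stream], universe,
                                      generation_numbers=[1, 5, 10, 20, len(stream)])
        recalls = curve.mean_recall.to_list()
        assert recalls == sorted(recalls)

    def test_degenerate_universe_rejected(self):
        with pytest.raises(ValueError):
            evaluate.scaffold_recall(["CCO"], [[]], {"c1ccccc1"})


class TestNeighbourOrigin:
    def test_empty_b_attributes_all_to_a(self):
        mols = fixtures.make_smiles_set(12, seed=3)
        rep = evaluate.neighbour_origin(mols, [], target=mols[0], top_n=10)
        assert rep.counts["A"] == 10
        assert rep.counts["B"] == 0

    def test_counts_sum_to_top_n(self):
        mols = fixtures.make_smiles_set(30, seed=4)
        rep = evaluate.neighbour_origin(mols[:15], mols[10:], target=mols[0], top_n=10)
        # shared molecules count for both models, so the sum is >= top_n
        assert rep.total == 10
        assert rep.counts["A"] + rep.counts["B"] >= 10

    def test_matches_brute_force_sort(self):
        mols = fixtures.make_smiles_set(20, seed=5)
        target = mols[0]
        rep = evaluate.neighbour_origin(mols[1:11], mols[8:], target, top_n=5)
        fp = chem.fingerprint(target)
        pool = sorted({chem.canonicalize(m) for m in mols[1:]})
        ranked = sorted(pool, key=lambda m: (-chem.tanimoto(fp, chem.fingerprint(m)), m))
        assert list(rep.top.molecule) == ranked[:5]

    def test_symmetric_under_label_swap(self):
        mols = fixtures.make_smiles_set(16, seed=7)
        a, b = mols[1:9], mols[7:]
        r1 = evaluate.neighbour_origin(a, b, mols[0], top_n=6)
        r2 = evaluate.neighbour_origin(b, a, mols[0], top_n=6)
        assert r1.counts["A"] == r2.counts["B"]
        assert r1.counts["B"] == r2.counts["A"]

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            evaluate.neighbour_origin([], [], "CCO")


class TestProfileDrift:
    def test_no_drift_for_identical(self):
        rep = evaluate.profile_drift(["Cc1ccccc1"], "Cc1ccccc1")
        assert not rep.added_groups and not rep.removed_groups
        assert not rep.added_rings and not rep.removed_rings

    def test_halogenation_adds_a_group(self):
        rep = evaluate.profile_drift(["Cc1ccc(Cl)cc1"], "Cc1ccccc1")
        assert any("Cl" in g for g in rep.added_groups)

    def test_ring_swap_replaces_ring_system(self):
        rep = evaluate.profile_drift(["c1ccncc1"], "c1ccccc1")
        assert chem.canonicalize("c1ccncc1") in rep.added_rings
        assert chem.canonicalize("c1ccccc1") in rep.removed_rings

    def test_invalid_generation_skipped(self):
        rep = evaluate.profile_drift(["C(", "CCO"], "CCO")
        assert rep.n_skipped == 1
        assert rep.n_compared == 1
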