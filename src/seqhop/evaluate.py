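"""Evaluation statistics for generated molecule sets.

Covers the whole assessment battery: invalid rate, similarity analysis
against source / target / global-target molecules, NLL-similarity rank
correlation, scaffold recall under canonical / prefix / prefix0 input
protocols, top-N neighbour-origin attribution between two models, and
functional-group / ring-system drift profiling.

Every report is a pure function of its per-record table, so persisted raw
records always recompute to the same summary.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import chem
from .decode import GenerationResult


# ---- invalid rate ---------------------------------------------------------


def invalid_rate(results: list[GenerationResult]) -> float:
    """Fraction of generated outputs that do not parse as valid SMILES."""
    if not results:
        raise ValueError("no generation results supplied")
    return sum(1 for r in results if not r.valid) / len(results)


# ---- similarity analysis --------------------------------------------------


@dataclass
class SimilarityReport:
    records: pd.DataFrame  # input_id, generated, sim_source, sim_reference, nll
    quantiles: dict[str, float]
    fraction_above: dict[float, float]
    identity_rate: float


def similarity_analysis(generated: list[GenerationResult], source: str,
                        reference: str | None = None, input_id: str = "",
                        thresholds=(0.7, 0.75)) -> SimilarityReport:
    """Tanimoto similarities of valid generations to the source (and an
    optional reference molecule), with distribution summaries.

    identity_rate counts generations whose canonical SMILES equals the
    source's (similarity exactly 1 by construction).
    """
    src_fp = chem.fingerprint(source)
    src_can = chem.canonicalize(source)
    ref_fp = chem.fingerprint(reference) if reference else None
    rows = []
    for r in generated:
        if not r.valid:
            continue
        fp = chem.fingerprint(r.canonical)
        rows.append({
            "input_id": input_id,
            "generated": r.canonical,
            "sim_source": chem.tanimoto(src_fp, fp),
            "sim_reference": chem.tanimoto(ref_fp, fp) if ref_fp else np.nan,
            "nll": r.nll,
            "identical": r.canonical == src_can,
        })
    records = pd.DataFrame(
        rows, columns=["input_id", "generated", "sim_source", "sim_reference",
                       "nll", "identical"])
    sims = records["sim_source"].to_numpy(dtype=float)
    if len(sims):
        quantiles = {q: float(np.quantile(sims, float(q[1:]) / 100))
                     for q in ("q25", "q50", "q75")}
        fraction_above = {t: float((sims > t).mean()) for t in thresholds}
        identity = float(records["identical"].mean())
    else:
        quantiles = {q: np.nan for q in ("q25", "q50", "q75")}
        fraction_above = {t: np.nan for t in thresholds}
        identity = np.nan
    return SimilarityReport(records, quantiles, fraction_above, identity)


# ---- global target --------------------------------------------------------


def global_target(generated: str, assay_molecules: list[str], input_molecule: str
                  ) -> tuple[str, float]:
    """Most similar assay member to a generated molecule, input excluded.

    Ties break on canonical SMILES order so the result is reproducible.
    """
    input_can = chem.canonicalize(input_molecule)
    candidates = sorted(
        {chem.canonicalize(m) for m in assay_molecules} - {input_can}
    )
    if not candidates:
        raise ValueError("assay has no members besides the input molecule")
    gen_fp = chem.fingerprint(generated)
    best, best_sim = None, -1.0
    for m in candidates:  # sorted, so the first of equal-similarity ties wins
        sim = chem.tanimoto(gen_fp, chem.fingerprint(m))
        if sim > best_sim:
            best, best_sim = m, sim
    return best, best_sim


# ---- NLL / similarity correlation -----------------------------------------


@dataclass
class CorrelationReport:
    spearman_rho: float
    p_value: float
    n: int
    binned: pd.DataFrame  # 2-D histogram of (similarity, NLL)
    defined: bool


def nll_similarity_correlation(records: pd.DataFrame, sim_col: str = "sim_source",
                               nll_col: str = "nll", bins: int = 8) -> CorrelationReport:
    """Spearman rank correlation between generation NLL and similarity,
    plus a binned 2-D summary table.  A constant column makes the statistic
    undefined and is reported as such."""
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    sims = records[sim_col].to_numpy(dtype=float)
    nlls = records[nll_col].to_numpy(dtype=float)
    hist, sim_edges, nll_edges = np.histogram2d(sims, nlls, bins=bins)
    binned = pd.DataFrame(
        hist.astype(int),
        index=pd.IntervalIndex.from_breaks(np.round(sim_edges, 6)),
        columns=pd.IntervalIndex.from_breaks(np.round(nll_edges, 6)),
    )
    if np.all(sims == sims[0]) or np.all(nlls == nlls[0]):
        return CorrelationReport(np.nan, np.nan, len(records), binned, defined=False)
    rho, p = sps.spearmanr(nlls, sims)
    return CorrelationReport(float(rho), float(p), len(records), binned, defined=True)


# ---- scaffold recall ------------------------------------------------------


@dataclass
class ScaffoldRecallReport:
    per_input: pd.DataFrame  # input_id, recall, n_recovered
    mean_recall: float
    protocol: str
    generation_number: int
    universe_size: int


def scaffold_universe(reference_smiles: list[str]) -> set[str]:
    """Unique Bemis-Murcko scaffolds of a reference compound set."""
    return {chem.bm_scaffold(s) for s in reference_smiles}


def scaffold_recall(inputs: list[str], generated_sets: list[list[GenerationResult]],
                    universe: set[str], protocol: str = "canonical",
                    generation_number: int | None = None) -> ScaffoldRecallReport:
    """Per-input fraction of the scaffold universe recovered by generation.

    For input i the denominator is |universe| - 1 (the input's own scaffold
    is excluded); the numerator counts distinct scaffolds of the valid
    generated molecules that lie in the remaining universe.
    """
    if len(universe) <= 1:
        raise ValueError("scaffold universe must contain more than one scaffold")
    if len(inputs) != len(generated_sets):
        raise ValueError("inputs and generated sets differ in length")
    rows = []
    for inp, gen in zip(inputs, generated_sets):
        own = chem.bm_scaffold(inp)
        target_universe = universe - {own}
        recovered = set()
        for r in gen:
            if r.valid:
                scaf = chem.bm_scaffold(r.canonical)
                if scaf in target_universe:
                    recovered.add(scaf)
        rows.append({"input": inp, "n_recovered": len(recovered),
                     "recall": len(recovered) / (len(universe) - 1)})
    per_input = pd.DataFrame(rows, columns=["input", "n_recovered", "recall"])
    gen_no = generation_number if generation_number is not None else max(
        (len(g) for g in generated_sets), default=0)
    return ScaffoldRecallReport(per_input, float(per_input["recall"].mean()),
                                protocol, gen_no, len(universe))


def recall_curve(inputs: list[str], generated_sets: list[list[GenerationResult]],
                 universe: set[str], generation_numbers: list[int],
                 protocol: str = "canonical") -> pd.DataFrame:
    """Mean recall as a function of generation number, using cumulative
    prefixes of each ordered generation stream (beam order = NLL rank,
    sampling order = draw order)."""
    rows = []
    for n in generation_numbers:
        rep = scaffold_recall(
            inputs, [g[:n] for g in generated_sets], universe, protocol, n)
        rows.append({"generation_number": n, "mean_recall": rep.mean_recall,
                     "protocol": protocol})
    return pd.DataFrame(rows)


# ---- neighbour origin -----------------------------------------------------


@dataclass
class NeighbourOriginReport:
    counts: dict[str, int]  # model label -> molecules in the top-N
    top: pd.DataFrame  # molecule, similarity, origins

    @property
    def total(self) -> int:
        return int(self.top.shape[0])


def neighbour_origin(set_a: list[str], set_b: list[str], target: str,
                     top_n: int = 10, labels: tuple[str, str] = ("A", "B")
                     ) -> NeighbourOriginReport:
    """Origin of the top-N generated molecules nearest to a target.

    The two sets are canonicalised, pooled and ranked by Tanimoto
    similarity to the target (descending, canonical-SMILES tie-break); a
    molecule generated by both models is attributed to both.
    """
    can_a = {chem.canonicalize(s) for s in set_a}
    can_b = {chem.canonicalize(s) for s in set_b}
    pool = sorted(can_a | can_b)
    if not pool:
        raise ValueError("both generated sets are empty")
    tgt_fp = chem.fingerprint(target)
    sims = [(chem.tanimoto(tgt_fp, chem.fingerprint(m)), m) for m in pool]
    sims.sort(key=lambda t: (-t[0], t[1]))
    top = sims[:top_n]
    counts = {labels[0]: 0, labels[1]: 0}
    rows = []
    for sim, m in top:
        origins = []
        if m in can_a:
            counts[labels[0]] += 1
            origins.append(labels[0])
        if m in can_b:
            counts[labels[1]] += 1
            origins.append(labels[1])
        rows.append({"molecule": m, "similarity": sim, "origins": "+".join(origins)})
    return NeighbourOriginReport(counts, pd.DataFrame(rows))


# ---- functional group / ring system drift ---------------------------------


@dataclass
class DriftReport:
    added_groups: Counter
    removed_groups: Counter
    added_rings: Counter
    removed_rings: Counter
    n_compared: int
    n_skipped: int


def profile_drift(generated: list[str], source: str) -> DriftReport:
    """Aggregated multiset differences of Ertl functional groups and ring
    systems between each generated molecule and the source."""
    src_groups = chem.functional_groups(source)
    src_rings = Counter(chem.ring_systems(source))
    added_g, removed_g = Counter(), Counter()
    added_r, removed_r = Counter(), Counter()
    compared = skipped = 0
    for smi in generated:
        if not chem.is_valid(smi):
            skipped += 1
            continue
        g = chem.functional_groups(smi)
        r = Counter(chem.ring_systems(smi))
        added_g += g - src_groups
        removed_g += src_groups - g
        added_r += r - src_rings
        removed_r += src_rings - r
        compared += 1
    return DriftReport(added_g, removed_g, added_r, removed_r, compared, skipped)
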