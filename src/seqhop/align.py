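"""Levenshtein alignment of SMILES pairs and the training-set builders.

A molecule has many valid SMILES; writing a pair so that the two strings
differ in as few characters as possible makes the structural edit between
the molecules explicit at the sequence level.  `best_alignment` searches a
pool of randomised SMILES of one molecule for the string closest (in edit
distance) to a fixed representation of the other; `build_dataset` assembles
the four corpus variants used to train models:

* ``canonical``     - canonical source -> canonical target, both directions;
* ``randomised``    - independently randomised source and target;
* ``lev_aligned``   - canonical source -> best-aligned randomised target;
* ``lev_extended``  - five source forms per direction (1 canonical + 4
  randomised), each aligned against the partner's candidate pool, giving
  ten records per input pair.

Edit distance is computed on raw character strings (single-character
insertions, deletions, substitutions) via edlib, with a pure-Python
dynamic-programming fallback.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

try:
    import edlib

    _HAVE_EDLIB = True
except ImportError:  # pragma: no cover
    _HAVE_EDLIB = False

from . import chem

logger = logging.getLogger(__name__)

MODES = ("canonical", "randomised", "lev_aligned", "lev_extended")


def levenshtein(a: str, b: str) -> int:
    """Minimum number of single-character edits transforming a into b."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    if _HAVE_EDLIB:
        return edlib.align(a, b, task="distance", mode="NW")["editDistance"]
    return _levenshtein_dp(a, b)


def _levenshtein_dp(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@dataclass(frozen=True)
class AlignmentConfig:
    """Candidate-pool settings for Levenshtein alignment.

    pool_size: randomised representations drawn per partner molecule
        (the full-scale protocol uses 10,000; pools are capped here).
    n_source_variants: source-side forms in extended mode (1 canonical +
        n-1 randomised).
    inject_canonical: also place the partner's canonical SMILES in the
        candidate pool (off by default: the pool is purely randomised).
    """

    pool_size: int = 10_000
    n_source_variants: int = 5
    seed: int = 0
    inject_canonical: bool = False
    max_resample_rounds: int = 50

    def __post_init__(self):
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.pool_size > 10_000:
            object.__setattr__(self, "pool_size", 10_000)


@dataclass(frozen=True)
class AlignedPair:
    """One directed training record: a concrete source/target string pair."""

    source_repr: str
    target_repr: str
    distance: int
    pair_id: str
    direction: str  # "A>B" or "B>A"


def _pool_seed(seed: int, pair_id: str, direction: str) -> int:
    """Stable per-(pair, direction) stream, independent of corpus order."""
    key = zlib.crc32(f"{pair_id}|{direction}".encode())
    ss = np.random.SeedSequence([seed, key])
    return int(ss.generate_state(1)[0] % (2**31))


def candidate_pool(partner: str, cfg: AlignmentConfig, seed: int) -> list[str]:
    pool = chem.enumerate_randomized(partner, cfg.pool_size, seed)
    if cfg.inject_canonical:
        can = chem.canonicalize(partner)
        if can not in pool:
            pool = pool + [can]
    return pool


def best_alignment(fixed: str, partner: str, cfg: AlignmentConfig,
                   pair_id: str = "", direction: str = "A>B",
                   pool: list[str] | None = None) -> AlignedPair:
    """Pool member of `partner` minimising the edit distance to `fixed`.

    Ties break on the lexicographically smallest candidate so the result is
    reproducible for a fixed seed.
    """
    if pool is None:
        pool = candidate_pool(partner, cfg, _pool_seed(cfg.seed, pair_id, direction))
    best_d, best_s = None, None
    for cand in pool:
        d = levenshtein(fixed, cand)
        if best_d is None or d < best_d or (d == best_d and cand < best_s):
            best_d, best_s = d, cand
    return AlignedPair(fixed, best_s, best_d, pair_id, direction)


def _source_variants(smiles: str, n: int, seed: int, max_rounds: int) -> list[str]:
    """1 canonical + (n-1) randomised forms, mutually distinct where possible."""
    canonical = chem.canonicalize(smiles)
    variants = [canonical]
    need = n - 1
    draw = max(need * 4, 8)
    for round_ in range(max_rounds):
        for cand in chem.enumerate_randomized(smiles, draw, seed + round_):
            if cand not in variants:
                variants.append(cand)
                if len(variants) == n:
                    return variants
    logger.warning(
        "only %d of %d distinct source representations for %s", len(variants), n, smiles
    )
    return variants


def build_dataset(pairs, mode: str, cfg: AlignmentConfig | None = None) -> pd.DataFrame:
    """Aligned training records for a list of molecule pairs.

    `pairs` yields objects with .source, .target and .pair_id attributes
    (or (source, target) tuples, in which case ids are positional).
    Returns a DataFrame with columns source_repr, target_repr, distance,
    pair_id, direction.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    cfg = cfg or AlignmentConfig()
    records: list[AlignedPair] = []
    for i, pair in enumerate(pairs):
        if hasattr(pair, "source"):
            a, b, pid = pair.source, pair.target, getattr(pair, "pair_id", str(i))
        else:
            a, b = pair
            pid = str(i)
        records.extend(_records_for_pair(a, b, pid, mode, cfg))
    return pd.DataFrame(
        [(r.source_repr, r.target_repr, r.distance, r.pair_id, r.direction) for r in records],
        columns=["source_repr", "target_repr", "distance", "pair_id", "direction"],
    )


def _records_for_pair(a: str, b: str, pid: str, mode: str, cfg: AlignmentConfig):
    can_a, can_b = chem.canonicalize(a), chem.canonicalize(b)
    out = []
    if mode == "canonical":
        for src, tgt, dirn in ((can_a, can_b, "A>B"), (can_b, can_a, "B>A")):
            out.append(AlignedPair(src, tgt, levenshtein(src, tgt), pid, dirn))
        return out
    if mode == "randomised":
        for dirn, (s_mol, t_mol) in (("A>B", (a, b)), ("B>A", (b, a))):
            seed_s = _pool_seed(cfg.seed, pid, dirn + ":src")
            seed_t = _pool_seed(cfg.seed, pid, dirn + ":tgt")
            src = chem.enumerate_randomized(s_mol, 1, seed_s)[0]
            tgt = chem.enumerate_randomized(t_mol, 1, seed_t)[0]
            out.append(AlignedPair(src, tgt, levenshtein(src, tgt), pid, dirn))
        return out
    if mode == "lev_aligned":
        for dirn, (fixed, partner) in (("A>B", (can_a, b)), ("B>A", (can_b, a))):
            out.append(best_alignment(fixed, partner, cfg, pid, dirn))
        return out
    # lev_extended: five source forms per direction, one shared partner pool
    for dirn, (s_mol, t_mol) in (("A>B", (a, b)), ("B>A", (b, a))):
        vseed = _pool_seed(cfg.seed, pid, dirn + ":variants")
        pool = candidate_pool(t_mol, cfg, _pool_seed(cfg.seed, pid, dirn))
        for src in _source_variants(s_mol, cfg.n_source_variants, vseed, cfg.max_resample_rounds):
            out.append(best_alignment(src, t_mol, cfg, pid, dirn, pool=pool))
    return out


def write_dataset(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_dataset(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"pair_id": str})
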