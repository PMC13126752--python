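"""Generation from a fitted seq2seq model.

Three decoding strategies over the shared vocabulary:

* greedy     - argmax token per step (deterministic);
* beam       - breadth-limited search keeping the k best partial sequences
               by cumulative negative log-likelihood (no length
               normalisation: ranking follows cumulative probability);
* sampling   - multinomial draws from softmax(logits / temperature),
               default temperature 1.2.

Two optional contract modifiers apply to every method:

* prefix control - generation starts from a user-supplied SMILES prefix
  whose tokens are treated as already emitted; they contribute nothing to
  the ranked NLL (conditioning, not choice);
* invalid filtering - after every emitted token the partial string is
  checked with the partial-SMILES feasibility test and doomed hypotheses
  are discarded before the next selection step; completed hypotheses must
  additionally parse as valid molecules.

Reported NLL is always the model's own (temperature never rescales it) and
includes the <eos> step, so a generated sequence's NLL coincides with
`score_target` on the same strings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import chem
from .model import OutOfVocabularyError, Seq2SeqResults
from .nn import no_grad
from .nn.autograd import Tensor

logger = logging.getLogger(__name__)

METHODS = ("greedy", "beam", "sampling")


@dataclass(frozen=True)
class DecodeConfig:
    method: str = "greedy"
    beam_width: int = 1
    n_samples: int = 1
    temperature: float = 1.2
    prefix: str = ""
    invalid_filtering: bool = False
    max_length: int = 150
    seed: int = 0
    dedupe: bool = False

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.beam_width < 1:
            raise ValueError("beam_width must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass(frozen=True)
class GenerationResult:
    smiles: str
    nll: float
    valid: bool
    canonical: str  # empty unless valid

    @classmethod
    def from_tokens(cls, tokens: list[str], nll: float) -> "GenerationResult":
        smiles = "".join(tokens)
        valid = chem.is_valid(smiles)
        return cls(smiles, float(nll), valid, chem.canonicalize(smiles) if valid else "")


# ---------------------------------------------------------------------------


class _Decoder:
    """Shared plumbing: encoded source memory + stepwise log-probabilities."""

    def __init__(self, results: Seq2SeqResults, source_smiles: str, cfg: DecodeConfig):
        self.res = results
        self.vocab = results.vocab
        self.cfg = cfg
        src_tokens = chem.tokenize(source_smiles)
        self.src_ids = self.vocab.encode(src_tokens)[None, :]
        with no_grad():
            self.memory = results.net.encode(results.params, self.src_ids)
        self.prefix_ids = self._encode_prefix(cfg.prefix)
        if cfg.max_length < len(self.prefix_ids):
            raise ValueError("max_length is smaller than the prefix token count")
        # the decoder input is <sos> + emitted tokens, bounded by the
        # positional-embedding table
        self.max_emit = min(cfg.max_length, results.net.max_positions - 1)
        # tokens never emitted as choices
        self.banned = np.array([self.vocab.pad_idx, self.vocab.sos_idx])

    def _encode_prefix(self, prefix: str) -> list[int]:
        if not prefix:
            return []
        ids = []
        for tok in chem.tokenize(prefix):
            if tok not in self.vocab:
                raise OutOfVocabularyError(tok)
            ids.append(self.vocab.index[tok])
        return ids

    def step_logprobs(self, hyp_ids: list[list[int]]) -> np.ndarray:
        """Next-token log-probabilities for a batch of target prefixes.

        Each prefix is [<sos>, t1, ...]; rows of the result align with the
        input order.  Equal lengths are not required (right padding).
        """
        B = len(hyp_ids)
        pad = self.vocab.pad_idx
        T = max(len(h) for h in hyp_ids)
        tgt = np.full((B, T), pad, dtype=np.int64)
        for i, h in enumerate(hyp_ids):
            tgt[i, : len(h)] = h
        src = np.repeat(self.src_ids, B, axis=0)
        mem = Tensor(np.repeat(self.memory.data, B, axis=0))
        with no_grad():
            logp = self.res.net.decode(self.res.params, mem, src, tgt)
        last = np.array([len(h) - 1 for h in hyp_ids])
        return logp.data[np.arange(B), last, :]

    def seed_hypothesis(self) -> list[int]:
        return [self.vocab.sos_idx] + list(self.prefix_ids)

    def smiles_of(self, hyp: list[int]) -> str:
        return "".join(self.vocab.tokens[i] for i in hyp[1:])

    def n_emitted(self, hyp: list[int]) -> int:
        return len(hyp) - 1  # excludes <sos>, includes prefix tokens


def _feasible(dec: _Decoder, hyp: list[int], tok: int) -> bool:
    if not dec.cfg.invalid_filtering:
        return True
    return chem.is_extensible(dec.smiles_of(hyp) + dec.vocab.tokens[tok])


def _completable(dec: _Decoder, hyp: list[int]) -> bool:
    if not dec.cfg.invalid_filtering:
        return True
    return chem.is_valid(dec.smiles_of(hyp))


# ---- greedy ---------------------------------------------------------------


def greedy(results: Seq2SeqResults, source_smiles: str,
           cfg: DecodeConfig | None = None) -> GenerationResult | None:
    """Deterministic argmax decoding; one result (None if filtering prunes
    every continuation)."""
    cfg = replace(cfg or DecodeConfig(), method="greedy")
    dec = _Decoder(results, source_smiles, cfg)
    hyp, nll = dec.seed_hypothesis(), 0.0
    eos = dec.vocab.eos_idx
    while dec.n_emitted(hyp) < dec.max_emit:
        logp = dec.step_logprobs([hyp])[0]
        logp[dec.banned] = -np.inf
        for tok in np.argsort(-logp, kind="stable"):
            tok = int(tok)
            if tok == eos:
                if _completable(dec, hyp):
                    return GenerationResult.from_tokens(
                        [dec.vocab.tokens[i] for i in hyp[1:]], nll - logp[tok]
                    )
                continue
            if _feasible(dec, hyp, tok):
                hyp = hyp + [tok]
                nll -= logp[tok]
                break
        else:
            warnings.warn("greedy decoding pruned every continuation")
            return None
    # length cap reached without <eos>
    result = GenerationResult.from_tokens([dec.vocab.tokens[i] for i in hyp[1:]], nll)
    if cfg.invalid_filtering and not result.valid:
        warnings.warn("greedy decoding hit the length cap without a valid SMILES")
        return None
    return result


# ---- beam -----------------------------------------------------------------


def beam(results: Seq2SeqResults, source_smiles: str,
         cfg: DecodeConfig | None = None) -> list[GenerationResult]:
    """Beam search; up to `beam_width` completed hypotheses sorted by
    ascending cumulative NLL.

    At each step all alive hypotheses are expanded over the vocabulary; the
    k best candidates by cumulative NLL are kept, <eos> candidates moving
    to the completed pool (frozen) and the rest staying alive.  Ties break
    on token id then hypothesis order, so results are reproducible.
    """
    cfg = replace(cfg or DecodeConfig(), method="beam")
    k = cfg.beam_width
    dec = _Decoder(results, source_smiles, cfg)
    eos = dec.vocab.eos_idx
    alive: list[tuple[list[int], float]] = [(dec.seed_hypothesis(), 0.0)]
    completed: list[tuple[list[int], float]] = []
    while alive and len(completed) < k:
        if dec.n_emitted(alive[0][0]) >= dec.max_emit:
            if not cfg.invalid_filtering:
                completed.extend(alive[: k - len(completed)])
            else:
                completed.extend(
                    (h, s) for h, s in alive if _completable(dec, h)
                )
            break
        logp = dec.step_logprobs([h for h, _ in alive])
        logp[:, dec.banned] = -np.inf
        # candidate matrix: cumulative NLL for every (hypothesis, token)
        cand_nll = np.array([s for _, s in alive])[:, None] - logp
        order = np.argsort(cand_nll, axis=None, kind="stable")
        new_alive: list[tuple[list[int], float]] = []
        taken = 0
        for flat in order:
            if taken >= k:
                break
            hi, tok = divmod(int(flat), logp.shape[1])
            score = float(cand_nll[hi, tok])
            if not np.isfinite(score):
                break
            hyp = alive[hi][0]
            if tok == eos:
                if _completable(dec, hyp):
                    completed.append((hyp, score))
                    taken += 1
                continue
            if not _feasible(dec, hyp, tok):
                continue
            new_alive.append((hyp + [tok], score))
            taken += 1
        alive = new_alive
    if not completed:
        warnings.warn("beam search pruned every hypothesis")
    out = [
        GenerationResult.from_tokens([dec.vocab.tokens[i] for i in h[1:]], s)
        for h, s in completed
    ]
    out.sort(key=lambda r: (r.nll, r.smiles))
    if cfg.dedupe:
        out = unique_by_canonical(out)
    return out[:k]


def unique_by_canonical(results: list[GenerationResult]) -> list[GenerationResult]:
    """Deduplicate by canonical SMILES, keeping the lowest NLL per molecule.

    Invalid results are deduplicated by their raw string.
    """
    best: dict[str, GenerationResult] = {}
    for r in sorted(results, key=lambda r: r.nll):
        key = r.canonical if r.valid else f"\x00{r.smiles}"
        best.setdefault(key, r)
    return sorted(best.values(), key=lambda r: (r.nll, r.smiles))


# ---- multinomial sampling -------------------------------------------------


def sample(results: Seq2SeqResults, source_smiles: str,
           cfg: DecodeConfig | None = None) -> list[GenerationResult]:
    """`n_samples` independent temperature-scaled multinomial chains.

    Each next token is drawn from softmax(z_t / T).  The reported NLL is
    the model's unscaled likelihood of the drawn sequence.  With invalid
    filtering, infeasible draws are redrawn from the renormalised
    remainder; a chain with no feasible continuation is dropped.
    """
    cfg = replace(cfg or DecodeConfig(), method="sampling")
    dec = _Decoder(results, source_smiles, cfg)
    rng = np.random.default_rng(cfg.seed)
    eos = dec.vocab.eos_idx
    chains = [(dec.seed_hypothesis(), 0.0) for _ in range(cfg.n_samples)]
    done: list[GenerationResult | None] = [None] * cfg.n_samples
    active = list(range(cfg.n_samples))
    while active:
        if dec.n_emitted(chains[active[0]][0]) >= dec.max_emit:
            for ci in active:
                hyp, nll = chains[ci]
                r = GenerationResult.from_tokens(
                    [dec.vocab.tokens[i] for i in hyp[1:]], nll)
                done[ci] = None if (cfg.invalid_filtering and not r.valid) else r
            break
        logp = dec.step_logprobs([chains[ci][0] for ci in active])
        logp[:, dec.banned] = -np.inf
        still = []
        for row, ci in enumerate(active):
            hyp, nll = chains[ci]
            scaled = logp[row] / cfg.temperature
            scaled -= scaled.max()
            probs = np.exp(scaled)
            probs[~np.isfinite(probs)] = 0.0
            finished = False
            while True:
                total = probs.sum()
                if total <= 0:
                    done[ci] = None  # chain died under filtering
                    finished = True
                    break
                tok = int(rng.choice(len(probs), p=probs / total))
                if tok == eos:
                    if _completable(dec, hyp):
                        done[ci] = GenerationResult.from_tokens(
                            [dec.vocab.tokens[i] for i in hyp[1:]],
                            nll - logp[row][tok],
                        )
                        finished = True
                        break
                    probs[tok] = 0.0
                    continue
                if _feasible(dec, hyp, tok):
                    chains[ci] = (hyp + [tok], nll - logp[row][tok])
                    break
                probs[tok] = 0.0
            if not finished and done[ci] is None:
                still.append(ci)
        active = still
    results_out = [r for r in done if r is not None]
    if len(results_out) < cfg.n_samples:
        logger.warning("%d of %d sampling chains were pruned",
                       cfg.n_samples - len(results_out), cfg.n_samples)
    return results_out


# ---- scoring --------------------------------------------------------------


def score_target(results: Seq2SeqResults, source_smiles: str,
                 target_smiles: str) -> float:
    """Cumulative NLL of a target SMILES conditioned on a source.

    Computed stepwise with the decoding plumbing (teacher-forced, one
    decoder call per position, <eos> included) - an independent path from
    the batched training loss, with which it must agree.
    """
    cfg = DecodeConfig()
    dec = _Decoder(results, source_smiles, cfg)
    vocab = results.vocab
    target_ids = []
    for tok in chem.tokenize(target_smiles):
        if tok not in vocab:
            raise OutOfVocabularyError(tok)
        target_ids.append(vocab.index[tok])
    target_ids.append(vocab.eos_idx)
    hyp = [vocab.sos_idx]
    nll = 0.0
    for tok in target_ids:
        logp = dec.step_logprobs([hyp])[0]
        nll -= float(logp[tok])
        hyp.append(tok)
    return nll


def generate(results: Seq2SeqResults, source_smiles: str,
             cfg: DecodeConfig) -> list[GenerationResult]:
    """Dispatch on cfg.method; always returns a list."""
    if cfg.method == "greedy":
        r = greedy(results, source_smiles, cfg)
        return [r] if r is not None else []
    if cfg.method == "beam":
        return beam(results, source_smiles, cfg)
    return sample(results, source_smiles, cfg)
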