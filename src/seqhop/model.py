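"""Sequence-to-sequence model over SMILES token sequences.

`Seq2Seq` follows the model/results idiom: the model object is built from a
corpus of (source, target) SMILES pairs, `fit()` runs seeded mini-batch
training and returns a `Seq2SeqResults` carrying the learned parameters,
the per-epoch loss history and a `summary()` table.  Generation and scoring
(see `seqhop.decode`) operate on the results object.

Objective: teacher-forced masked negative log-likelihood.  With the target
sequence y = (<sos>, y_2, ..., y_T) the decoder receives y[:-1] and at each
position predicts the next token; the per-token loss is -m_t log p_t(y_t)
with m_t = 0 at padding, summed from t = 2 (the <sos> is given, not
predicted).  Optimisation uses Adam on mini-batches of 64 by default.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import chem
from .nn import Adam, TransformerNet, init_params, no_grad
from .nn.autograd import Tensor, gather_last

PAD, SOS, EOS = "<pad>", "<sos>", "<eos>"
SPECIALS = (PAD, SOS, EOS)


class OutOfVocabularyError(KeyError):
    def __init__(self, token: str):
        self.token = token
        super().__init__(f"token {token!r} is not in the vocabulary")


class Vocabulary:
    """Frozen token -> index map with <pad>=0, <sos>=1, <eos>=2 first."""

    def __init__(self, tokens: list[str]):
        if tokens[:3] != list(SPECIALS):
            tokens = list(SPECIALS) + [t for t in tokens if t not in SPECIALS]
        self.tokens = list(tokens)
        self.index = {t: i for i, t in enumerate(self.tokens)}
        if len(self.index) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    @property
    def pad_idx(self) -> int:
        return self.index[PAD]

    @property
    def sos_idx(self) -> int:
        return self.index[SOS]

    @property
    def eos_idx(self) -> int:
        return self.index[EOS]

    @classmethod
    def build(cls, corpora) -> "Vocabulary":
        """Vocabulary over every token in the given token-sequence iterables.

        Deterministic order: specials, then by descending frequency with
        lexicographic tie-break, so shuffled corpora give identical maps.
        """
        counts: Counter = Counter()
        for seq in corpora:
            counts.update(seq)
        if not counts:
            raise ValueError("cannot build a vocabulary from an empty corpus")
        ordered = sorted(counts, key=lambda t: (-counts[t], t))
        return cls(list(SPECIALS) + [t for t in ordered if t not in SPECIALS])

    def encode(self, tokens: list[str], add_sos: bool = True, add_eos: bool = True) -> np.ndarray:
        ids = []
        if add_sos:
            ids.append(self.sos_idx)
        for t in tokens:
            if t not in self.index:
                raise OutOfVocabularyError(t)
            ids.append(self.index[t])
        if add_eos:
            ids.append(self.eos_idx)
        return np.asarray(ids, dtype=np.int64)

    def decode(self, ids) -> list[str]:
        out = []
        for i in ids:
            tok = self.tokens[int(i)]
            if tok == EOS:
                break
            if tok in (PAD, SOS):
                continue
            out.append(tok)
        return out

    def save(self, path: str) -> None:
        chem.save_vocabulary_tokens(self.tokens, path)

    @classmethod
    def load(cls, path: str) -> "Vocabulary":
        with open(path) as fh:
            return cls([line.rstrip("\n") for line in fh if line.rstrip("\n")])


def build_vocabulary(datasets) -> Vocabulary:
    """Shared vocabulary over one or more tokenised corpora."""
    def _iter():
        for ds in datasets:
            for seq in ds:
                yield seq

    return Vocabulary.build(_iter())


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults are the full-scale configuration (3+3 layers, 8 heads, width
    256, feed-forward 512, batch 64, Adam); `tiny()` is the desk-scale
    variant used throughout the tests.
    """

    encoder_layers: int = 3
    decoder_layers: int = 3
    heads: int = 8
    model_width: int = 256
    ff_width: int = 512
    batch_size: int = 64
    epochs: int = 100
    learning_rate: float = 5e-4
    dropout: float = 0.1
    max_positions: int = 128
    grad_clip: float = 1.0
    warmup_epochs: int = 5
    lr_decay: str = "cosine"  # "cosine" or "constant"
    min_lr_fraction: float = 0.05

    def __post_init__(self):
        if self.model_width % self.heads:
            raise ValueError("model_width must be divisible by heads")

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        base = dict(
            encoder_layers=2, decoder_layers=2, heads=4, model_width=64,
            ff_width=128, batch_size=32, epochs=150, learning_rate=4e-3,
            dropout=0.0, max_positions=96, min_lr_fraction=0.02,
        )
        base.update(overrides)
        return cls(**base)


class Seq2Seq:
    """Transformer seq2seq model bound to a training corpus.

    Parameters
    ----------
    train_pairs : sequence of (source, target) SMILES strings
    valid_pairs : optional held-out pairs monitored each epoch; the
        best-validation parameters are the ones the results object keeps.
    vocab : shared Vocabulary; built from both corpora when omitted.
    config : ModelConfig
    """

    def __init__(self, train_pairs, valid_pairs=None, vocab: Vocabulary | None = None,
                 config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        train_pairs = list(train_pairs)
        valid_pairs = list(valid_pairs) if valid_pairs is not None else []
        if not train_pairs:
            raise ValueError("training corpus is empty")
        tok = chem.tokenize
        self._train_tok = [(tok(s), tok(t)) for s, t in train_pairs]
        self._valid_tok = [(tok(s), tok(t)) for s, t in valid_pairs]
        if vocab is None:
            vocab = Vocabulary.build(
                seq for pair in self._train_tok + self._valid_tok for seq in pair
            )
        self.vocab = vocab
        self.net = TransformerNet(
            vocab_size=len(vocab),
            d_model=self.config.model_width,
            n_heads=self.config.heads,
            d_ff=self.config.ff_width,
            n_enc_layers=self.config.encoder_layers,
            n_dec_layers=self.config.decoder_layers,
            max_positions=self.config.max_positions,
            dropout_p=self.config.dropout,
            pad_idx=vocab.pad_idx,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, source_col: str = "source_repr",
                       target_col: str = "target_repr", valid_df: pd.DataFrame | None = None,
                       vocab: Vocabulary | None = None, config: ModelConfig | None = None,
                       ) -> "Seq2Seq":
        pairs = list(zip(df[source_col], df[target_col]))
        vpairs = None
        if valid_df is not None:
            vpairs = list(zip(valid_df[source_col], valid_df[target_col]))
        return cls(pairs, vpairs, vocab=vocab, config=config)

    # ---- encoding -------------------------------------------------------
    def _encode_batch(self, pairs_tok) -> tuple[np.ndarray, np.ndarray]:
        srcs = [self.vocab.encode(s) for s, _ in pairs_tok]
        tgts = [self.vocab.encode(t) for _, t in pairs_tok]
        pad = self.vocab.pad_idx
        ls, lt = max(map(len, srcs)), max(map(len, tgts))
        src = np.full((len(srcs), ls), pad, dtype=np.int64)
        tgt = np.full((len(tgts), lt), pad, dtype=np.int64)
        for i, (s, t) in enumerate(zip(srcs, tgts)):
            src[i, : len(s)] = s
            tgt[i, : len(t)] = t
        return src, tgt

    def _batch_nll(self, params, src, tgt, rng=None, training=False) -> Tensor:
        """Summed masked NLL of a padded batch (Tensor scalar)."""
        logp = self.net.forward(params, src, tgt[:, :-1], rng=rng, training=training)
        tgt_out = tgt[:, 1:]
        mask = (tgt_out != self.vocab.pad_idx).astype(np.float64)
        picked = gather_last(logp, tgt_out)
        return (picked * Tensor(mask)).sum() * -1.0

    # ---- training -------------------------------------------------------
    def fit(self, seed: int = 0, progress: bool = False) -> "Seq2SeqResults":
        cfg = self.config
        ss = np.random.SeedSequence(seed)
        init_rng, shuffle_rng, drop_rng = (np.random.default_rng(s) for s in ss.spawn(3))
        params = init_params(
            len(self.vocab), cfg.model_width, cfg.heads, cfg.ff_width,
            cfg.encoder_layers, cfg.decoder_layers, cfg.max_positions, init_rng,
        )
        opt = Adam(params.values(), lr=cfg.learning_rate, clip_norm=cfg.grad_clip)
        n = len(self._train_tok)
        history = []
        best = (np.inf, None, -1)
        for epoch in range(1, cfg.epochs + 1):
            opt.lr = self._epoch_lr(epoch)
            order = shuffle_rng.permutation(n)
            total, count = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                batch = [self._train_tok[i] for i in order[start : start + cfg.batch_size]]
                src, tgt = self._encode_batch(batch)
                opt.zero_grad()
                loss = self._batch_nll(params, src, tgt, rng=drop_rng, training=True)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch}"
                    )
                total += float(loss.data)
                count += len(batch)
                (loss * (1.0 / len(batch))).backward()
                opt.step()
            train_nll = total / count
            valid_nll = self.evaluate_nll(params, self._valid_tok) if self._valid_tok else np.nan
            history.append((epoch, train_nll, valid_nll))
            monitor = valid_nll if self._valid_tok else train_nll
            if monitor < best[0]:
                best = (monitor, {k: v.data.copy() for k, v in params.items()}, epoch)
            if progress:
                print(f"epoch {epoch:4d}  train_nll {train_nll:.4f}  valid_nll {valid_nll:.4f}")
        best_params = {k: Tensor(v, requires_grad=False) for k, v in best[1].items()}
        hist = pd.DataFrame(history, columns=["epoch", "train_nll", "valid_nll"])
        return Seq2SeqResults(self.net, self.vocab, cfg, best_params, hist, best[2], seed)

    def _epoch_lr(self, epoch: int) -> float:
        """Linear warmup then cosine decay to min_lr_fraction of the base rate."""
        cfg = self.config
        if epoch <= cfg.warmup_epochs:
            return cfg.learning_rate * epoch / max(cfg.warmup_epochs, 1)
        if cfg.lr_decay != "cosine" or cfg.epochs <= cfg.warmup_epochs:
            return cfg.learning_rate
        t = (epoch - cfg.warmup_epochs) / (cfg.epochs - cfg.warmup_epochs)
        lo = cfg.learning_rate * cfg.min_lr_fraction
        return lo + 0.5 * (cfg.learning_rate - lo) * (1 + np.cos(np.pi * t))

    def evaluate_nll(self, params, pairs_tok, batch_size: int | None = None) -> float:
        """Mean per-sequence NLL over a tokenised pair list (no dropout)."""
        if not pairs_tok:
            return np.nan
        bs = batch_size or self.config.batch_size
        total = 0.0
        with no_grad():
            for start in range(0, len(pairs_tok), bs):
                src, tgt = self._encode_batch(pairs_tok[start : start + bs])
                total += float(self._batch_nll(params, src, tgt).data)
        return total / len(pairs_tok)


class Seq2SeqResults:
    """Fitted model: parameters, loss history and scoring entry points."""

    def __init__(self, net: TransformerNet, vocab: Vocabulary, config: ModelConfig,
                 params: dict, history: pd.DataFrame, best_epoch: int, seed: int):
        self.net = net
        self.vocab = vocab
        self.config = config
        self.params = params
        self.history = history
        self.best_epoch = best_epoch
        self.seed = seed

    # ---- scoring --------------------------------------------------------
    def forward(self, source_tokens: list[str], target_prefix_tokens: list[str]) -> np.ndarray:
        """Next-token probability distributions, one row per prefix position.

        The prefix must start with <sos>; row t is p(. | prefix[:t+1], source).
        """
        src = self.vocab.encode(source_tokens)[None, :]
        tgt = np.asarray([self.vocab.index.get(t) for t in target_prefix_tokens])
        for tok, idx in zip(target_prefix_tokens, tgt):
            if idx is None:
                raise OutOfVocabularyError(tok)
        tgt = tgt.astype(np.int64)[None, :]
        with no_grad():
            logp = self.net.forward(self.params, src, tgt)
        return np.exp(logp.data[0])

    def sequence_nll(self, source_tokens: list[str], target_tokens: list[str]) -> float:
        """Masked NLL of a target token sequence (with <sos>/<eos> added)."""
        src = self.vocab.encode(source_tokens)[None, :]
        tgt = self.vocab.encode(target_tokens)[None, :]
        with no_grad():
            logp = self.net.forward(self.params, src, tgt[:, :-1])
            tgt_out = tgt[:, 1:]
            mask = (tgt_out != self.vocab.pad_idx)
            picked = np.take_along_axis(logp.data, tgt_out[..., None], axis=-1)[..., 0]
        return float(-(picked * mask).sum())

    def nll(self, source_smiles: str, target_smiles: str) -> float:
        """Cumulative NLL of one SMILES conditioned on another."""
        return self.sequence_nll(chem.tokenize(source_smiles), chem.tokenize(target_smiles))

    # ---- reporting ------------------------------------------------------
    def summary(self) -> str:
        cfg = self.config
        h = self.history
        lines = [
            "Seq2Seq transformer results",
            "=" * 43,
            f"{'vocabulary size':<28}{len(self.vocab):>15}",
            f"{'encoder/decoder layers':<28}{f'{cfg.encoder_layers}/{cfg.decoder_layers}':>15}",
            f"{'heads / width / ff width':<28}{f'{cfg.heads}/{cfg.model_width}/{cfg.ff_width}':>15}",
            f"{'parameters':<28}{sum(p.data.size for p in self.params.values()):>15,}",
            f"{'epochs run':<28}{len(h):>15}",
            f"{'best epoch':<28}{self.best_epoch:>15}",
            f"{'final train NLL/seq':<28}{h.train_nll.iloc[-1]:>15.4f}",
        ]
        if np.isfinite(h.valid_nll.iloc[-1]):
            lines.append(f"{'best valid NLL/seq':<28}{h.valid_nll.min():>15.4f}")
        lines.append("=" * 43)
        return "\n".join(lines)

    # ---- persistence ----------------------------------------------------
    def save(self, path: str) -> None:
        meta = {
            "config": asdict(self.config),
            "vocab": self.vocab.tokens,
            "best_epoch": int(self.best_epoch),
            "seed": int(self.seed),
            "history": self.history.to_dict(orient="list"),
        }
        arrays = {f"param:{k}": v.data for k, v in self.params.items()}
        np.savez_compressed(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "Seq2SeqResults":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            params = {
                k[len("param:"):]: Tensor(data[k]) for k in data.files if k.startswith("param:")
            }
        cfg = ModelConfig(**meta["config"])
        vocab = Vocabulary(meta["vocab"])
        net = TransformerNet(
            vocab_size=len(vocab), d_model=cfg.model_width, n_heads=cfg.heads,
            d_ff=cfg.ff_width, n_enc_layers=cfg.encoder_layers,
            n_dec_layers=cfg.decoder_layers, max_positions=cfg.max_positions,
            dropout_p=cfg.dropout, pad_idx=vocab.pad_idx,
        )
        hist = pd.DataFrame(meta["history"])
        return cls(net, vocab, cfg, params, hist, meta["best_epoch"], meta["seed"])
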