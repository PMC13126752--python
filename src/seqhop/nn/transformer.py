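"""Encoder-decoder transformer over token-id arrays.

Standard post-norm architecture: multi-head self attention (plus cross
attention in the decoder), position-wise feed-forward blocks, learned
positional embeddings, residual connections with layer norm after each
sublayer.  Parameters live in a flat name -> Tensor dict so the optimiser,
checkpointing and seeding stay trivial.

The decoder sees the target shifted by one position (teacher forcing) and
produces a log-probability distribution over the shared vocabulary at every
prefix position.  Source padding is masked out of attention; future target
positions are masked causally.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, dropout, embedding, layer_norm

_NEG = -1e9


def init_params(
    vocab_size: int,
    d_model: int,
    n_heads: int,
    d_ff: int,
    n_enc_layers: int,
    n_dec_layers: int,
    max_positions: int,
    rng: np.random.Generator,
) -> dict[str, Tensor]:
    """Xavier-uniform initialised parameter dict."""
    params: dict[str, Tensor] = {}

    def xavier(name, shape):
        bound = np.sqrt(6.0 / (shape[-2] + shape[-1])) if len(shape) >= 2 else 0.05
        params[name] = Tensor(rng.uniform(-bound, bound, shape), requires_grad=True, name=name)

    def zeros(name, shape):
        params[name] = Tensor(np.zeros(shape), requires_grad=True, name=name)

    def ones(name, shape):
        params[name] = Tensor(np.ones(shape), requires_grad=True, name=name)

    xavier("tok_emb", (vocab_size, d_model))
    xavier("pos_emb", (max_positions, d_model))

    def block(prefix, cross: bool):
        for sub in ["self"] + (["cross"] if cross else []):
            for mat in ("q", "k", "v", "o"):
                xavier(f"{prefix}.{sub}.{mat}_w", (d_model, d_model))
                zeros(f"{prefix}.{sub}.{mat}_b", (d_model,))
            ones(f"{prefix}.{sub}.ln_g", (d_model,))
            zeros(f"{prefix}.{sub}.ln_b", (d_model,))
        xavier(f"{prefix}.ff.w1", (d_model, d_ff))
        zeros(f"{prefix}.ff.b1", (d_ff,))
        xavier(f"{prefix}.ff.w2", (d_ff, d_model))
        zeros(f"{prefix}.ff.b2", (d_model,))
        ones(f"{prefix}.ff.ln_g", (d_model,))
        zeros(f"{prefix}.ff.ln_b", (d_model,))

    for i in range(n_enc_layers):
        block(f"enc.{i}", cross=False)
    for i in range(n_dec_layers):
        block(f"dec.{i}", cross=True)
    # output projection is tied to the token embedding (transposed)
    zeros("out_b", (vocab_size,))
    return params


class TransformerNet:
    """Stateless forward functions over a parameter dict."""

    def __init__(
        self,
        vocab_size: int,
        d_model: int,
        n_heads: int,
        d_ff: int,
        n_enc_layers: int,
        n_dec_layers: int,
        max_positions: int,
        dropout_p: float = 0.1,
        pad_idx: int = 0,
    ):
        if d_model % n_heads:
            raise ValueError("model width must be divisible by the head count")
        self.vocab_size = vocab_size
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.d_ff = d_ff
        self.n_enc_layers = n_enc_layers
        self.n_dec_layers = n_dec_layers
        self.max_positions = max_positions
        self.dropout_p = dropout_p
        self.pad_idx = pad_idx

    # ---- helpers --------------------------------------------------------
    def _attention(self, params, prefix, q_in, kv_in, mask, rng, training):
        B, Tq, D = q_in.shape
        Tk = kv_in.shape[1]
        H, Dh = self.n_heads, self.d_head

        def proj(x, name):
            return x @ params[f"{prefix}.{name}_w"] + params[f"{prefix}.{name}_b"]

        def split(x, T):
            return x.reshape(B, T, H, Dh).transpose((0, 2, 1, 3))

        q = split(proj(q_in, "q"), Tq)
        k = split(proj(kv_in, "k"), Tk)
        v = split(proj(kv_in, "v"), Tk)
        scores = q @ k.transpose((0, 1, 3, 2)) * (Dh ** -0.5)
        if mask is not None:
            scores = scores + Tensor(mask)  # additive, -1e9 at masked slots
        attn = scores.softmax(axis=-1)
        attn = dropout(attn, self.dropout_p, rng, training)
        ctx = (attn @ v).transpose((0, 2, 1, 3)).reshape(B, Tq, D)
        out = ctx @ params[f"{prefix}.o_w"] + params[f"{prefix}.o_b"]
        out = dropout(out, self.dropout_p, rng, training)
        res = q_in + out
        return layer_norm(res, params[f"{prefix}.ln_g"], params[f"{prefix}.ln_b"])

    def _ff(self, params, prefix, x, rng, training):
        h = (x @ params[f"{prefix}.w1"] + params[f"{prefix}.b1"]).relu()
        h = dropout(h, self.dropout_p, rng, training)
        out = h @ params[f"{prefix}.w2"] + params[f"{prefix}.b2"]
        out = dropout(out, self.dropout_p, rng, training)
        return layer_norm(x + out, params[f"{prefix}.ln_g"], params[f"{prefix}.ln_b"])

    def _embed(self, params, ids, rng, training):
        B, T = ids.shape
        if T > self.max_positions:
            raise ValueError(f"sequence length {T} exceeds max_positions {self.max_positions}")
        tok = embedding(params["tok_emb"], ids) * (self.d_model ** 0.5)
        pos = embedding(params["pos_emb"], np.tile(np.arange(T), (B, 1)))
        return dropout(tok + pos, self.dropout_p, rng, training)

    @staticmethod
    def _pad_mask(ids: np.ndarray, pad_idx: int) -> np.ndarray:
        # (B, 1, 1, Tk) additive mask
        return np.where(ids[:, None, None, :] == pad_idx, _NEG, 0.0)

    @staticmethod
    def _causal_mask(ids: np.ndarray, pad_idx: int) -> np.ndarray:
        B, T = ids.shape
        future = np.triu(np.full((T, T), _NEG), k=1)[None, None, :, :]
        pad = np.where(ids[:, None, None, :] == pad_idx, _NEG, 0.0)
        return future + pad

    # ---- forward --------------------------------------------------------
    def encode(self, params, src_ids: np.ndarray, rng=None, training=False) -> Tensor:
        rng = rng or np.random.default_rng()
        x = self._embed(params, src_ids, rng, training)
        mask = self._pad_mask(src_ids, self.pad_idx)
        for i in range(self.n_enc_layers):
            x = self._attention(params, f"enc.{i}.self", x, x, mask, rng, training)
            x = self._ff(params, f"enc.{i}.ff", x, rng, training)
        return x

    def decode(
        self,
        params,
        memory: Tensor,
        src_ids: np.ndarray,
        tgt_ids: np.ndarray,
        rng=None,
        training=False,
    ) -> Tensor:
        """Log-probabilities (B, T_tgt, |V|) for the next token after each prefix."""
        rng = rng or np.random.default_rng()
        x = self._embed(params, tgt_ids, rng, training)
        self_mask = self._causal_mask(tgt_ids, self.pad_idx)
        cross_mask = self._pad_mask(src_ids, self.pad_idx)
        for i in range(self.n_dec_layers):
            x = self._attention(params, f"dec.{i}.self", x, x, self_mask, rng, training)
            x = self._attention(params, f"dec.{i}.cross", x, memory, cross_mask, rng, training)
            x = self._ff(params, f"dec.{i}.ff", x, rng, training)
        logits = x @ params["tok_emb"].transpose((1, 0)) + params["out_b"]
        return logits.log_softmax(axis=-1)

    def forward(self, params, src_ids, tgt_in_ids, rng=None, training=False) -> Tensor:
        memory = self.encode(params, src_ids, rng, training)
        return self.decode(params, memory, src_ids, tgt_in_ids, rng, training)

    def logits(self, params, src_ids, tgt_in_ids) -> Tensor:
        """Raw (unnormalised) decoder scores, used by temperature sampling."""
        memory = self.encode(params, src_ids)
        rng = np.random.default_rng()
        x = self._embed(params, tgt_in_ids, rng, False)
        self_mask = self._causal_mask(tgt_in_ids, self.pad_idx)
        cross_mask = self._pad_mask(src_ids, self.pad_idx)
        for i in range(self.n_dec_layers):
            x = self._attention(params, f"dec.{i}.self", x, x, self_mask, rng, False)
            x = self._attention(params, f"dec.{i}.cross", x, memory, cross_mask, rng, False)
            x = self._ff(params, f"dec.{i}.ff", x, rng, False)
        return x @ params["tok_emb"].transpose((1, 0)) + params["out_b"]
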