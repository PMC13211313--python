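"""Patch-based multimodal spectrum encoder and formula-prompted SMILES decoder.

The encoder follows the Vision-Transformer recipe adapted to spectra:

* 1D spectra are cut into contiguous, non-overlapping patches along the
  chemical-shift axis (no pseudo-2D reshaping), each patch linearly
  projected to the latent width;
* HSQC matrices are cut into non-overlapping square patches, flattened
  row-major and projected;
* every modality has its own projection and learnable positional table;
  the embedded token sequences are concatenated along the sequence axis
  into one fused stream processed by a single shared pre-norm
  transformer encoder.

During training, *patch dropout* removes a fixed fraction of fused patch
tokens, sampled uniformly without intensity weighting and jointly across
modalities; survivors keep their positional embeddings and order. It is
identity at inference.

The decoder is an autoregressive transformer whose input starts with a
fixed-length molecular-formula token prefix, then BOS and SMILES tokens;
it cross-attends to the full encoder memory. Loss masking (formula
prefix and padding excluded) lives in :mod:`nmr2struct.training`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .spectra import Spectrum1D, SpectrumHSQC
from .tokenizer import Vocabulary

__all__ = [
    "ModelConfig",
    "patchify_1d",
    "unpatchify_1d",
    "patchify_2d",
    "unpatchify_2d",
    "patch_dropout_indices",
    "patch_dropout",
    "SpectrumTransformer",
]

#: Per-modality input geometry: ("1d", n_points) or ("2d", (H, W)).
DEFAULT_GEOMETRY = {
    "H1": ("1d", 10_000),
    "C13": ("1d", 10_000),
    "HSQC": ("2d", (256, 256)),
}


@dataclass
class ModelConfig:
    """Hyperparameters of the encoder-decoder transformer.

    The defaults are the desk-scale "tiny" configuration used throughout
    the test suite; all fields are free to scale up.
    """

    d_model: int = 128
    n_encoder_layers: int = 2
    n_decoder_layers: int = 2
    n_heads: int = 4
    ff_dim: int = 256
    patch_len_1d: int = 50
    patch_size_2d: int = 16
    patch_dropout_rate: float = 0.5
    max_decode_len: int = 80
    modalities: Tuple[str, ...] = ("H1",)
    geometry: Dict[str, tuple] = field(
        default_factory=lambda: {k: DEFAULT_GEOMETRY[k] for k in DEFAULT_GEOMETRY}
    )

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if not (0.0 <= self.patch_dropout_rate < 1.0):
            raise ValueError("patch_dropout_rate must be in [0, 1)")
        for m in self.modalities:
            kind, size = self.geometry[m]
            if kind == "1d":
                if size % self.patch_len_1d != 0:
                    raise ValueError(
                        f"{m}: patch_len_1d {self.patch_len_1d} does not divide {size}"
                    )
            else:
                h, w = size
                if h % self.patch_size_2d or w % self.patch_size_2d:
                    raise ValueError(
                        f"{m}: patch_size_2d {self.patch_size_2d} does not divide {size}"
                    )

    def patch_count(self, modality: str) -> int:
        kind, size = self.geometry[modality]
        if kind == "1d":
            return size // self.patch_len_1d
        h, w = size
        return (h // self.patch_size_2d) * (w // self.patch_size_2d)

    def patch_dim(self, modality: str) -> int:
        kind, _ = self.geometry[modality]
        return self.patch_len_1d if kind == "1d" else self.patch_size_2d**2


# ---------------------------------------------------------------------------
# Patchify / unpatchify (lossless partitions)
# ---------------------------------------------------------------------------


def patchify_1d(spec, patch_len: int) -> np.ndarray:
    """Cut a 1D spectrum into contiguous patches: (n_patches, patch_len).

    Patch order follows ascending grid index; concatenating the rows
    reconstructs the spectrum exactly. Non-divisible lengths are an
    error — no implicit padding.
    """
    x = spec.intensities if isinstance(spec, Spectrum1D) else np.asarray(spec)
    n = x.shape[-1]
    if n % patch_len != 0:
        raise ValueError(f"patch_len {patch_len} does not divide length {n}")
    return x.reshape(*x.shape[:-1], n // patch_len, patch_len)


def unpatchify_1d(patches: np.ndarray) -> np.ndarray:
    patches = np.asarray(patches)
    return patches.reshape(*patches.shape[:-2], -1)


def patchify_2d(spec, patch_size: int) -> np.ndarray:
    """Cut a matrix into flattened square patches: (n_patches, patch_size^2).

    Patches are ordered row-major over the patch grid and flattened
    row-major; :func:`unpatchify_2d` is the exact inverse.
    """
    x = spec.intensities if isinstance(spec, SpectrumHSQC) else np.asarray(spec)
    h, w = x.shape[-2:]
    if h % patch_size or w % patch_size:
        raise ValueError(f"patch_size {patch_size} does not divide shape {(h, w)}")
    lead = x.shape[:-2]
    x = x.reshape(*lead, h // patch_size, patch_size, w // patch_size, patch_size)
    x = np.moveaxis(x, -3, -2)
    return x.reshape(*lead, (h // patch_size) * (w // patch_size), patch_size**2)


def unpatchify_2d(patches: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    patches = np.asarray(patches)
    h, w = shape
    p = int(round(patches.shape[-1] ** 0.5))
    lead = patches.shape[:-2]
    x = patches.reshape(*lead, h // p, w // p, p, p)
    x = np.moveaxis(x, -3, -2)
    return x.reshape(*lead, h, w)


# ---------------------------------------------------------------------------
# Patch dropout
# ---------------------------------------------------------------------------


def patch_dropout_indices(
    n_tokens: int, rate: float, rng: np.random.Generator, batch: int = 1
) -> np.ndarray:
    """Survivor indices for patch dropout: exactly ``round((1-rate)*n)``
    tokens per batch row, sampled uniformly without replacement and
    returned sorted so survivors preserve their original order.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("patch dropout rate must be in [0, 1)")
    keep = int(round((1.0 - rate) * n_tokens))
    keep = max(keep, 1)
    idx = np.stack(
        [np.sort(rng.choice(n_tokens, size=keep, replace=False)) for _ in range(batch)]
    )
    return idx


def patch_dropout(
    tokens: Tensor,
    rate: float,
    training: bool,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Tensor, Optional[np.ndarray]]:
    """Randomly remove a fraction of fused patch tokens (training only).

    Applied to the concatenated multimodal stream, so tokens are sampled
    jointly across modalities, uniformly and without intensity
    weighting. At inference (``training=False``) this is the identity.

    Returns the surviving tokens and their original indices (or ``None``
    when nothing was dropped).
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("patch dropout rate must be in [0, 1)")
    if not training or rate == 0.0:
        return tokens, None
    if rng is None:
        raise ValueError("training-mode patch dropout needs an rng")
    batch, n_tokens, _ = tokens.shape
    idx = patch_dropout_indices(n_tokens, rate, rng, batch=batch)
    return ad.take_tokens(tokens, idx), idx


# ---------------------------------------------------------------------------
# The transformer
# ---------------------------------------------------------------------------


def _init_params(config: ModelConfig, vocab_size: int, rng: np.random.Generator):
    d = config.d_model
    params: Dict[str, Tensor] = {}

    def par(name, shape, std=0.02):
        if std == 0:
            data = np.zeros(shape, dtype=np.float32)
        elif std == 1:  # layer-norm gain
            data = np.ones(shape, dtype=np.float32)
        else:
            data = rng.normal(0.0, std, size=shape).astype(np.float32)
        params[name] = Tensor(data, requires_grad=True, name=name)

    for m in config.modalities:
        par(f"embed.{m}.w", (config.patch_dim(m), d))
        par(f"embed.{m}.b", (d,), std=0)
        par(f"embed.{m}.pos", (config.patch_count(m), d))

    def attn_block(prefix):
        for nm in ("wq", "wk", "wv", "wo"):
            par(f"{prefix}.{nm}", (d, d))
        for nm in ("bq", "bk", "bv", "bo"):
            par(f"{prefix}.{nm}", (d,), std=0)

    def ln_block(prefix):
        par(f"{prefix}.g", (d,), std=1)
        par(f"{prefix}.b", (d,), std=0)

    def ffn_block(prefix):
        par(f"{prefix}.w1", (d, config.ff_dim))
        par(f"{prefix}.b1", (config.ff_dim,), std=0)
        par(f"{prefix}.w2", (config.ff_dim, d))
        par(f"{prefix}.b2", (d,), std=0)

    for i in range(config.n_encoder_layers):
        ln_block(f"enc.{i}.ln1")
        attn_block(f"enc.{i}.attn")
        ln_block(f"enc.{i}.ln2")
        ffn_block(f"enc.{i}.ffn")
    ln_block("enc.final_ln")

    par("dec.tok_emb", (vocab_size, d))
    par("dec.pos_emb", (config.max_decode_len, d))
    for i in range(config.n_decoder_layers):
        ln_block(f"dec.{i}.ln1")
        attn_block(f"dec.{i}.self")
        ln_block(f"dec.{i}.ln2")
        attn_block(f"dec.{i}.cross")
        ln_block(f"dec.{i}.ln3")
        ffn_block(f"dec.{i}.ffn")
    ln_block("dec.final_ln")
    par("dec.out.w", (d, vocab_size))
    par("dec.out.b", (vocab_size,), std=0)
    return params


class SpectrumTransformer:
    """Encoder-decoder transformer from spectra patches to SMILES tokens."""

    def __init__(self, config: ModelConfig, vocab: Vocabulary, seed: int = 0):
        self.config = config
        self.vocab = vocab
        self.params = _init_params(config, len(vocab), np.random.default_rng(seed))

    # -- parameter utilities ------------------------------------------------

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def vocab_hash(self) -> str:
        blob = json.dumps(self.vocab.token_to_id, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- building blocks ----------------------------------------------------

    def _mha(self, prefix, x: Tensor, memory: Tensor, mask) -> Tensor:
        p = self.params
        h = self.config.n_heads
        d = self.config.d_model
        dh = d // h

        def heads(t: Tensor, length: int) -> Tensor:
            t = ad.reshape(t, (t.shape[0], length, h, dh))
            return ad.transpose(t, (0, 2, 1, 3))

        lq = x.shape[1]
        lk = memory.shape[1]
        q = heads(ad.linear(x, p[f"{prefix}.wq"], p[f"{prefix}.bq"]), lq)
        k = heads(ad.linear(memory, p[f"{prefix}.wk"], p[f"{prefix}.bk"]), lk)
        v = heads(ad.linear(memory, p[f"{prefix}.wv"], p[f"{prefix}.bv"]), lk)
        scores = ad.scale(ad.bmm(q, ad.transpose(k, (0, 1, 3, 2))), 1.0 / np.sqrt(dh))
        attn = ad.softmax(scores, additive_mask=mask)
        out = ad.bmm(attn, v)
        out = ad.reshape(ad.transpose(out, (0, 2, 1, 3)), (x.shape[0], lq, d))
        return ad.linear(out, p[f"{prefix}.wo"], p[f"{prefix}.bo"])

    def _ln(self, prefix, x: Tensor) -> Tensor:
        p = self.params
        return ad.layer_norm(x, p[f"{prefix}.g"], p[f"{prefix}.b"])

    def _ffn(self, prefix, x: Tensor) -> Tensor:
        p = self.params
        hidden = ad.relu(ad.linear(x, p[f"{prefix}.w1"], p[f"{prefix}.b1"]))
        return ad.linear(hidden, p[f"{prefix}.w2"], p[f"{prefix}.b2"])

    # -- encoder ------------------------------------------------------------

    def embed_and_fuse(self, patches: Dict[str, np.ndarray]) -> Tensor:
        """Project per-modality patches and concatenate into one stream.

        ``patches[m]`` has shape (B, n_patches_m, patch_dim_m). Each
        modality uses its own trainable projection and positional table;
        fusion order is the (fixed) order of ``config.modalities``, so
        runs are comparable.
        """
        streams: List[Tensor] = []
        for m in self.config.modalities:
            if m not in patches:
                continue
            arr = np.asarray(patches[m], dtype=np.float32)
            if arr.shape[-1] != self.config.patch_dim(m):
                raise ValueError(
                    f"{m}: patch width {arr.shape[-1]} != expected "
                    f"{self.config.patch_dim(m)}"
                )
            x = ad.linear(Tensor(arr), self.params[f"embed.{m}.w"], self.params[f"embed.{m}.b"])
            x = ad.add(x, self.params[f"embed.{m}.pos"])
            streams.append(x)
        if not streams:
            raise ValueError("no modalities present in input")
        return streams[0] if len(streams) == 1 else ad.concat(streams, axis=1)

    def encode_tokens(self, tokens: Tensor) -> Tensor:
        """Run the shared encoder stack over an (already fused) stream."""
        if tokens.shape[1] == 0:
            raise ValueError("empty token stream")
        x = tokens
        for i in range(self.config.n_encoder_layers):
            y = self._ln(f"enc.{i}.ln1", x)
            x = ad.add(x, self._mha(f"enc.{i}.attn", y, y, None))
            x = ad.add(x, self._ffn(f"enc.{i}.ffn", self._ln(f"enc.{i}.ln2", x)))
        return self._ln("enc.final_ln", x)

    def encode(
        self,
        patches: Dict[str, np.ndarray],
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> Tensor:
        """Full encoder: embed, fuse, patch-dropout (training), transform."""
        tokens = self.embed_and_fuse(patches)
        tokens, _ = patch_dropout(
            tokens, self.config.patch_dropout_rate, training=training, rng=rng
        )
        return self.encode_tokens(tokens)

    # -- decoder ------------------------------------------------------------

    def decode(self, memory: Tensor, dec_ids: np.ndarray) -> Tensor:
        """Next-token logits for every decoder position.

        ``dec_ids`` (B, T) must start with the formula prefix, then BOS,
        then SMILES tokens. Causal masking restricts position t to
        positions <= t; cross-attention sees the full memory.
        """
        dec_ids = np.asarray(dec_ids)
        t = dec_ids.shape[1]
        if t > self.config.max_decode_len:
            raise ValueError(
                f"decoder input length {t} exceeds max_decode_len "
                f"{self.config.max_decode_len}"
            )
        p = self.params
        x = ad.add(
            ad.embedding(p["dec.tok_emb"], dec_ids),
            _slice_rows(p["dec.pos_emb"], t),
        )
        causal = np.triu(np.full((t, t), -1e9, dtype=np.float32), k=1)[None, None]
        for i in range(self.config.n_decoder_layers):
            y = self._ln(f"dec.{i}.ln1", x)
            x = ad.add(x, self._mha(f"dec.{i}.self", y, y, causal))
            x = ad.add(x, self._mha(f"dec.{i}.cross", self._ln(f"dec.{i}.ln2", x), memory, None))
            x = ad.add(x, self._ffn(f"dec.{i}.ffn", self._ln(f"dec.{i}.ln3", x)))
        x = self._ln("dec.final_ln", x)
        return ad.linear(x, p["dec.out.w"], p["dec.out.b"])

    def next_token_logprobs(self, memory: Tensor, dec_ids: np.ndarray) -> np.ndarray:
        """Log-softmax over the next token after the last position (inference)."""
        with ad.no_grad():
            logits = self.decode(memory, dec_ids).data[:, -1, :]
        z = logits - logits.max(axis=-1, keepdims=True)
        return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))

    # -- checkpointing ------------------------------------------------------

    def save(self, path) -> None:
        """Single self-describing checkpoint: parameters + config + vocab."""
        meta = {
            "config": {**asdict(self.config), "modalities": list(self.config.modalities)},
            "vocab": self.vocab.token_to_id,
            "vocab_hash": self.vocab_hash(),
        }
        arrays = {f"param/{k}": v.data for k, v in self.params.items()}
        np.savez_compressed(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "SpectrumTransformer":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            cfg_dict = meta["config"]
            cfg_dict["modalities"] = tuple(cfg_dict["modalities"])
            cfg_dict["geometry"] = {
                k: (v[0], tuple(v[1]) if isinstance(v[1], list) else v[1])
                for k, v in cfg_dict["geometry"].items()
            }
            config = ModelConfig(**cfg_dict)
            vocab = Vocabulary({t: int(i) for t, i in meta["vocab"].items()})
            model = cls(config, vocab, seed=0)
            for k in model.params:
                model.params[k].data = data[f"param/{k}"].astype(np.float32)
        return model


def _slice_rows(table: Tensor, t: int) -> Tensor:
    """First ``t`` rows of a 2D parameter, gradient-aware."""
    return ad.embedding(table, np.arange(t))
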