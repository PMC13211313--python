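"""Optimization loop, schedule, fine-tuning, and top-k evaluation.

Training minimizes token-level cross-entropy over the SMILES positions
only — the molecular-formula prefix and padding are masked out, so
their gradient is identically zero. Optimization uses AdamW with linear
warmup followed by cosine decay of the learning rate. Evaluation
converts both predictions and targets to canonical non-stereochemical
SMILES and scores exact matches among the first k beam candidates.

A statsmodels-flavoured front door is provided:
``SpectrumToStructureModel(train, valid, ...).fit()`` returns a
:class:`FitResult` carrying the fitted transformer, the loss history
and a ``summary()`` table, with evaluation and prediction hanging off
it.
"""

from __future__ import annotations

import csv
import math
import time
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import autodiff as ad
from .decoding import filter_candidates, generate_candidates
from .model import ModelConfig, SpectrumTransformer, patchify_1d, patchify_2d
from .synthetic import DatasetManifest
from .tokenizer import (
    Vocabulary,
    canonicalize_nonstereo,
    tokenize_formula,
    tokenize_smiles,
)
from .tokenizer import vocab_for_dataset

__all__ = [
    "TrainConfig",
    "EvalReport",
    "lr_at_step",
    "AdamW",
    "prepare_batch_arrays",
    "train",
    "finetune",
    "evaluate_topk",
    "SpectrumToStructureModel",
    "FitResult",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    Defaults follow the reference protocol (peak learning rate 3e-4,
    10,000-step linear warmup, cosine decay over the full schedule,
    AdamW); desk-scale runs shrink ``epochs``/``warmup_steps``.
    """

    lr_peak: float = 3e-4
    warmup_steps: int = 10_000
    total_steps: Optional[int] = None  # derived from epochs when absent
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0
    finetune_from: Optional[str] = None
    betas: Tuple[float, float] = (0.9, 0.98)
    weight_decay: float = 0.01
    grad_clip: float = 1.0
    label_smoothing: float = 0.0

    def __post_init__(self) -> None:
        if self.lr_peak <= 0:
            raise ValueError("lr_peak must be > 0")
        if self.total_steps is not None and self.warmup_steps > self.total_steps:
            raise ValueError("warmup_steps must be <= total_steps")


def lr_at_step(step: int, cfg: TrainConfig) -> float:
    """Linear warmup to ``lr_peak`` then cosine decay to zero.

    ``step <= warmup``: ``lr_peak * step / warmup``; afterwards
    ``lr_peak * 0.5 * (1 + cos(pi * (step - warmup) / (total - warmup)))``.
    Steps beyond ``total_steps`` clamp to the final (zero) value. The
    schedule is continuous at the warmup/cosine junction and
    non-negative everywhere.
    """
    if cfg.total_steps is None:
        raise ValueError("total_steps must be set to evaluate the schedule")
    if step < 0:
        raise ValueError("step must be >= 0")
    warm = cfg.warmup_steps
    if warm > 0 and step <= warm:
        return cfg.lr_peak * step / warm
    step = min(step, cfg.total_steps)
    span = max(cfg.total_steps - warm, 1)
    return cfg.lr_peak * 0.5 * (1.0 + math.cos(math.pi * (step - warm) / span))


class AdamW:
    """AdamW with decoupled weight decay (no decay on 1-D parameters)."""

    def __init__(self, params: Dict[str, ad.Tensor], cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.cfg.betas
        if self.cfg.grad_clip > 0:
            sq = 0.0
            for p in self.params.values():
                if p.grad is not None:
                    sq += float((p.grad.astype(np.float64) ** 2).sum())
            norm = math.sqrt(sq)
            scale = min(1.0, self.cfg.grad_clip / (norm + 1e-12))
        else:
            scale = 1.0
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            update = (self.m[k] / bias1) / (np.sqrt(self.v[k] / bias2) + 1e-8)
            if p.data.ndim > 1:
                update = update + self.cfg.weight_decay * p.data
            p.data -= lr * update


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------


def encode_target(record, vocab: Vocabulary, max_len: int) -> Tuple[List[int], int]:
    """Decoder token ids: formula prefix, BOS, SMILES tokens, EOS."""
    prefix = vocab.encode(tokenize_formula(record.formula), strict=True)
    smiles_ids = vocab.encode(tokenize_smiles(record.smiles), strict=True)
    full = prefix + [vocab.bos_id] + smiles_ids + [vocab.eos_id]
    if len(full) > max_len:
        raise ValueError(
            f"{record.smiles}: decoder sequence length {len(full)} exceeds "
            f"max_decode_len {max_len}"
        )
    return full, len(prefix)


def prepare_batch_arrays(
    manifest: DatasetManifest, vocab: Vocabulary, config: ModelConfig
) -> Dict[str, np.ndarray]:
    """Patchified encoder inputs plus padded decoder inputs/targets/mask."""
    patches = {}
    for m in config.modalities:
        arr = manifest.arrays[m]
        kind, _ = config.geometry[m]
        patches[m] = (
            patchify_1d(arr, config.patch_len_1d)
            if kind == "1d"
            else patchify_2d(arr, config.patch_size_2d)
        ).astype(np.float32)
    sequences = [
        encode_target(rec, vocab, config.max_decode_len) for rec in manifest.records
    ]
    max_t = max(len(s) for s, _ in sequences)
    n = len(sequences)
    dec_in = np.full((n, max_t - 1), vocab.pad_id, dtype=np.int64)
    dec_tgt = np.full((n, max_t - 1), vocab.pad_id, dtype=np.int64)
    mask = np.zeros((n, max_t - 1), dtype=np.float32)
    for i, (full, prefix_len) in enumerate(sequences):
        t = len(full)
        dec_in[i, : t - 1] = full[:-1]
        dec_tgt[i, : t - 1] = full[1:]
        # supervise only positions predicting SMILES tokens and EOS
        mask[i, prefix_len : t - 1] = 1.0
    return {"patches": patches, "dec_in": dec_in, "dec_tgt": dec_tgt, "mask": mask}


def _batch_loss(model, data, idx, training, rng, label_smoothing=0.0) -> ad.Tensor:
    patches = {m: arr[idx] for m, arr in data["patches"].items()}
    memory = model.encode(patches, training=training, rng=rng)
    logits = model.decode(memory, data["dec_in"][idx])
    return ad.cross_entropy_masked(
        logits, data["dec_tgt"][idx], data["mask"][idx], label_smoothing
    )


def validation_loss(model, data, batch_size: int = 64) -> float:
    losses, weights = [], []
    n = data["dec_in"].shape[0]
    with ad.no_grad():
        for start in range(0, n, batch_size):
            idx = np.arange(start, min(start + batch_size, n))
            loss = _batch_loss(model, data, idx, training=False, rng=None)
            losses.append(float(loss.data))
            weights.append(float(data["mask"][idx].sum()))
    return float(np.average(losses, weights=weights))


# ---------------------------------------------------------------------------
# Training / fine-tuning
# ---------------------------------------------------------------------------


def train(
    train_manifest: DatasetManifest,
    valid_manifest: Optional[DatasetManifest],
    model: SpectrumTransformer,
    cfg: TrainConfig,
    log_path=None,
    verbose: bool = False,
) -> List[dict]:
    """Train ``model`` in place; returns the per-epoch metrics history.

    The best-validation-loss parameters are restored at the end; a CSV
    log (step, lr, loss) is written when ``log_path`` is given. Training
    aborts with a diagnostic on non-finite loss. Fully seeded: identical
    configs and seeds give identical loss curves on one device.
    """
    rng = np.random.default_rng(cfg.seed)
    data = prepare_batch_arrays(train_manifest, model.vocab, model.config)
    val_data = (
        prepare_batch_arrays(valid_manifest, model.vocab, model.config)
        if valid_manifest is not None and valid_manifest.records
        else None
    )
    n = data["dec_in"].shape[0]
    steps_per_epoch = max(1, math.ceil(n / cfg.batch_size))
    if cfg.total_steps is None:
        cfg = replace(cfg, total_steps=cfg.epochs * steps_per_epoch)
        if cfg.warmup_steps > cfg.total_steps:
            cfg = replace(cfg, warmup_steps=max(1, cfg.total_steps // 10))
    optimizer = AdamW(model.params, cfg)
    history: List[dict] = []
    best_val = math.inf
    best_state = None
    step = 0
    log_rows = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        t0 = time.time()
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            step += 1
            lr = lr_at_step(step, cfg)
            model.zero_grad()
            loss = _batch_loss(
                model, data, idx, training=True, rng=rng,
                label_smoothing=cfg.label_smoothing,
            )
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at step {step}"
                )
            loss.backward()
            optimizer.step(lr)
            epoch_losses.append(float(loss.data))
            log_rows.append((step, lr, float(loss.data)))
        entry = {
            "epoch": epoch + 1,
            "train_loss": float(np.mean(epoch_losses)),
            "lr": lr_at_step(step, cfg),
            "seconds": time.time() - t0,
        }
        if val_data is not None:
            entry["val_loss"] = validation_loss(model, val_data)
            if entry["val_loss"] < best_val:
                best_val = entry["val_loss"]
                best_state = {k: p.data.copy() for k, p in model.params.items()}
        history.append(entry)
        if verbose:
            print(
                f"epoch {entry['epoch']:3d} train {entry['train_loss']:.4f} "
                + (f"val {entry['val_loss']:.4f}" if "val_loss" in entry else ""),
                flush=True,
            )
    if best_state is not None:
        for k, p in model.params.items():
            p.data = best_state[k]
    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["step", "lr", "loss"])
            writer.writerows(log_rows)
    return history


def finetune(
    model: SpectrumTransformer,
    manifest: DatasetManifest,
    cfg: Optional[TrainConfig] = None,
    valid_manifest: Optional[DatasetManifest] = None,
    **train_kwargs,
) -> List[dict]:
    """Adapt a pretrained model to a small (e.g. experimental-style) corpus.

    Same loop as :func:`train` with a lower default peak learning rate
    (3e-5) and a short schedule; all weights remain trainable. The
    checkpoint's vocabulary must cover the new corpus — missing tokens
    are an error listing them.
    """
    missing = set()
    for rec in manifest.records:
        for tok in tokenize_smiles(rec.smiles):
            if tok not in model.vocab.token_to_id:
                missing.add(tok)
        for tok in tokenize_formula(rec.formula):
            if tok not in model.vocab.token_to_id:
                missing.add(tok)
    if missing:
        raise ValueError(
            f"fine-tuning corpus contains tokens absent from the model "
            f"vocabulary: {sorted(missing)}"
        )
    if cfg is None:
        cfg = TrainConfig(lr_peak=3e-5, epochs=10, warmup_steps=10)
    if cfg.epochs == 0:
        return []
    return train(manifest, valid_manifest, model, cfg, **train_kwargs)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Top-k exact-match accuracies plus validity of top-1 outputs."""

    accuracy: Dict[int, float]
    validity: float
    n_evaluated: int

    def __post_init__(self) -> None:
        ks = sorted(self.accuracy)
        for a, b in zip(ks, ks[1:]):
            if self.accuracy[a] > self.accuracy[b] + 1e-12:
                raise ValueError("top-k accuracy must be non-decreasing in k")
        for v in list(self.accuracy.values()) + [self.validity]:
            if not (0.0 <= v <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")


def spectra_for_record(manifest: DatasetManifest, i: int) -> Dict[str, np.ndarray]:
    return {m: manifest.arrays[m][i] for m in manifest.arrays}


def evaluate_topk(
    model: SpectrumTransformer,
    manifest: DatasetManifest,
    k_list: Sequence[int] = (1, 5, 10),
    beam_width: Optional[int] = None,
    limit: Optional[int] = None,
) -> EvalReport:
    """Top-k canonical exact-match accuracy via beam search.

    A record counts as a hit at k if its canonical non-stereo target
    appears among the first k *distinct molecules* in beam order.
    ``limit`` evaluates only the first ``limit`` records of the split
    (a deterministic subset, used to bound CPU cost).
    """
    if not manifest.records:
        raise ValueError("empty manifest")
    beam_width = beam_width or max(k_list)
    if beam_width < max(k_list):
        raise ValueError("beam_width must be >= max(k_list)")
    n = len(manifest.records) if limit is None else min(limit, len(manifest.records))
    hits = {k: 0 for k in k_list}
    valid_top1 = 0
    for i in range(n):
        rec = manifest.records[i]
        target = canonicalize_nonstereo(rec.smiles)
        cands = generate_candidates(
            model, spectra_for_record(manifest, i), rec.formula, width=beam_width
        )
        if cands and cands[0].is_valid:
            valid_top1 += 1
        molecules: List[str] = []
        seen = set()
        for cand in cands:
            canonical = canonicalize_nonstereo(cand.smiles)
            key = canonical if canonical is not None else f"<invalid:{cand.smiles}>"
            if key in seen:
                continue
            seen.add(key)
            molecules.append(canonical)
        for k in k_list:
            if target in molecules[:k]:
                hits[k] += 1
    return EvalReport(
        accuracy={k: hits[k] / n for k in k_list},
        validity=valid_top1 / n,
        n_evaluated=n,
    )


# ---------------------------------------------------------------------------
# Model/Results front door
# ---------------------------------------------------------------------------


class SpectrumToStructureModel:
    """Spectrum-to-structure transformer bound to a training dataset.

    Thin statsmodels-style front door: construct from train/valid
    manifests (vocabulary built from both unless given), call
    :meth:`fit`, get a :class:`FitResult`.
    """

    def __init__(
        self,
        train_manifest: DatasetManifest,
        valid_manifest: Optional[DatasetManifest] = None,
        model_config: Optional[ModelConfig] = None,
        train_config: Optional[TrainConfig] = None,
        vocab: Optional[Vocabulary] = None,
    ):
        self.train_manifest = train_manifest
        self.valid_manifest = valid_manifest
        self.model_config = model_config or ModelConfig()
        self.train_config = train_config or TrainConfig()
        records = list(train_manifest.records)
        if valid_manifest is not None:
            records += list(valid_manifest.records)
        self.vocab = vocab or vocab_for_dataset(records)

    def fit(self, log_path=None, verbose: bool = False) -> "FitResult":
        model = SpectrumTransformer(
            self.model_config, self.vocab, seed=self.train_config.seed
        )
        history = train(
            self.train_manifest,
            self.valid_manifest,
            model,
            self.train_config,
            log_path=log_path,
            verbose=verbose,
        )
        return FitResult(model, history, self.train_config)


@dataclass
class FitResult:
    """A fitted spectrum-to-structure transformer plus its training history."""

    model: SpectrumTransformer
    history: List[dict]
    train_config: TrainConfig

    @property
    def best_val_loss(self) -> Optional[float]:
        vals = [h["val_loss"] for h in self.history if "val_loss" in h]
        return min(vals) if vals else None

    def evaluate(self, manifest: DatasetManifest, **kwargs) -> EvalReport:
        return evaluate_topk(self.model, manifest, **kwargs)

    def predict(self, spectra, formula: str, width: int = 10, cap: int = 100):
        """Filtered candidate list for one spectrum set."""
        cands = generate_candidates(self.model, spectra, formula, width=width)
        return filter_candidates(cands, formula, cap=cap)

    def save(self, path) -> None:
        self.model.save(path)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Spectrum-to-structure transformer fit",
            "=" * 45,
            f"{'parameters':<28}{self.model.parameter_count():>12,}",
            f"{'modalities':<28}{'+'.join(cfg.modalities):>12}",
            f"{'d_model / heads':<28}{f'{cfg.d_model}/{cfg.n_heads}':>12}",
            f"{'encoder / decoder layers':<28}{f'{cfg.n_encoder_layers}/{cfg.n_decoder_layers}':>12}",
            f"{'patch dropout rate':<28}{cfg.patch_dropout_rate:>12.2f}",
            f"{'epochs':<28}{len(self.history):>12}",
        ]
        if self.history:
            lines.append(
                f"{'final train loss':<28}{self.history[-1]['train_loss']:>12.4f}"
            )
        if self.best_val_loss is not None:
            lines.append(f"{'best val loss':<28}{self.best_val_loss:>12.4f}")
        return "\n".join(lines)
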