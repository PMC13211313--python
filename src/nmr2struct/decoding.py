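"""Beam-search candidate generation and validity/formula filtering.

Beam search maintains the ``width`` highest cumulative-log-probability
partial token sequences (no length normalization by default; a Wu-style
normalization flag is provided for experimentation). Ties are broken
lexicographically on the token-id sequence so runs are reproducible.

The generated candidate pool is then filtered: chemically invalid
SMILES and candidates inconsistent with the known molecular formula
(full Hill formula, implicit hydrogens included) are dropped, duplicate
spellings of the same molecule are collapsed, and the list is truncated
to a cap (default 100 molecules).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import autodiff as ad
from .model import SpectrumTransformer, patchify_1d, patchify_2d
from .tokenizer import EOS, PROMPT_PAD, canonicalize_nonstereo, hill_formula, tokenize_formula

__all__ = ["Candidate", "beam_search", "filter_candidates", "generate_candidates"]


@dataclass
class Candidate:
    """A generated SMILES with its beam statistics and filter flags."""

    smiles: str
    log_prob: float
    source_rank: int
    is_valid: bool = False
    formula_ok: bool = False
    evidence_score: Optional[float] = None


def beam_search(
    score_fn: Callable[[np.ndarray], np.ndarray],
    prefix_ids: Sequence[int],
    eos_id: int,
    width: int,
    max_len: int,
    length_normalize: bool = False,
) -> List[Tuple[List[int], float]]:
    """Beam search over token sequences.

    ``score_fn`` maps a batch of full decoder inputs (n, t) to next-token
    log-probabilities (n, vocab). Sequences end at ``eos_id`` or after
    ``max_len`` generated tokens. Returns up to ``width`` distinct
    generated sequences (EOS excluded) with their total log-probability,
    sorted descending; ties broken lexicographically on token ids.

    ``width=1`` is exactly greedy decoding.
    """
    if width < 1:
        raise ValueError("beam width must be >= 1")
    prefix = list(prefix_ids)
    alive: List[Tuple[List[int], float]] = [([], 0.0)]
    finished: List[Tuple[List[int], float]] = []
    for _ in range(max_len):
        if not alive:
            break
        batch = np.array([prefix + seq for seq, _ in alive], dtype=np.int64)
        logprobs = score_fn(batch)
        expansions: List[Tuple[float, Tuple[int, ...], float]] = []
        for (seq, score), row in zip(alive, logprobs):
            for tok in range(row.shape[0]):
                new_score = score + float(row[tok])
                expansions.append((new_score, tuple(seq + [tok]), new_score))
        expansions.sort(key=lambda e: (-e[0], e[1]))
        # keep the width best expansions overall; EOS-ended ones retire
        # to the finished pool (width=1 is then exactly greedy decoding)
        alive = []
        for new_score, seq_t, _ in expansions[: width]:
            seq_list = list(seq_t)
            if seq_list[-1] == eos_id:
                finished.append((seq_list[:-1], new_score))
            else:
                alive.append((seq_list, new_score))
    finished.extend(alive)  # beams that hit max_len without EOS
    if length_normalize:
        ranked = [(seq, sc / max(len(seq) + 1, 1)) for seq, sc in finished]
    else:
        ranked = finished
    seen = set()
    unique = []
    for seq, sc in sorted(ranked, key=lambda e: (-e[1], tuple(e[0]))):
        key = tuple(seq)
        if key in seen:
            continue
        seen.add(key)
        unique.append((seq, sc))
    return unique[:width]


def _model_score_fn(model: SpectrumTransformer, memory) -> Callable[[np.ndarray], np.ndarray]:
    base = memory.data

    def score_fn(batch_ids: np.ndarray) -> np.ndarray:
        tiled = ad.Tensor(np.repeat(base, batch_ids.shape[0], axis=0))
        return model.next_token_logprobs(tiled, batch_ids)

    return score_fn


def encode_spectra(model: SpectrumTransformer, spectra: Dict[str, np.ndarray]):
    """Patchify per-modality spectra and run the encoder (inference mode)."""
    patches = {}
    for m in model.config.modalities:
        if m not in spectra:
            continue
        kind, _ = model.config.geometry[m]
        arr = spectra[m]
        arr = arr.intensities if hasattr(arr, "intensities") else np.asarray(arr)
        if kind == "1d":
            patches[m] = patchify_1d(arr, model.config.patch_len_1d)[None]
        else:
            patches[m] = patchify_2d(arr, model.config.patch_size_2d)[None]
    with ad.no_grad():
        return model.encode(patches, training=False)


def generate_candidates(
    model: SpectrumTransformer,
    spectra: Dict[str, np.ndarray],
    formula: str,
    width: int = 10,
    max_len: Optional[int] = None,
) -> List[Candidate]:
    """Beam-search SMILES candidates for one spectrum set.

    The decoder is prompted with the molecular-formula prefix; patch
    dropout is off (inference mode). Candidates are returned in beam
    order with validity and formula-consistency flags populated.
    """
    vocab = model.vocab
    prefix = vocab.encode(tokenize_formula(formula), strict=False) + [vocab.bos_id]
    if max_len is None:
        max_len = model.config.max_decode_len - len(prefix)
    memory = encode_spectra(model, spectra)
    results = beam_search(
        _model_score_fn(model, memory), prefix, vocab.eos_id, width, max_len
    )
    target_formula = hill_formula(formula)
    candidates = []
    for rank, (seq, score) in enumerate(results, start=1):
        tokens = vocab.decode(seq)
        smiles = "".join(t for t in tokens if t not in (EOS, PROMPT_PAD))
        canonical = canonicalize_nonstereo(smiles)
        formula_ok = False
        if canonical is not None:
            formula_ok = hill_formula(canonical, from_smiles=True) == target_formula
        candidates.append(
            Candidate(
                smiles=smiles,
                log_prob=score,
                source_rank=rank,
                is_valid=canonical is not None,
                formula_ok=formula_ok,
            )
        )
    return candidates


def filter_candidates(
    candidates: Sequence[Candidate], formula: str, cap: int = 100
) -> List[Candidate]:
    """Validity + formula filter with molecule-level deduplication.

    Invalid SMILES and candidates whose full Hill formula (implicit
    hydrogens included) disagrees with ``formula`` are dropped.
    Duplicate candidates that collapse to the same canonical non-stereo
    SMILES count as one molecule, keeping the highest-log-probability
    entry. Order is preserved and the result truncated to ``cap``
    molecules. Idempotent.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    target = hill_formula(formula)
    best: Dict[str, Tuple[int, Candidate]] = {}
    order: List[str] = []
    for pos, cand in enumerate(candidates):
        canonical = canonicalize_nonstereo(cand.smiles)
        if canonical is None:
            continue
        if hill_formula(canonical, from_smiles=True) != target:
            continue
        cand = replace(cand, is_valid=True, formula_ok=True)
        if canonical not in best:
            best[canonical] = (pos, cand)
            order.append(canonical)
        elif cand.log_prob > best[canonical][1].log_prob:
            best[canonical] = (best[canonical][0], cand)
    kept = [best[c][1] for c in sorted(order, key=lambda c: best[c][0])]
    return kept[:cap]
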