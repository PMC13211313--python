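"""Chemistry-aware tokenization of SMILES strings and molecular formulas.

SMILES are split into atom-level and syntax tokens with the regular
expression popularized by the Molecular Transformer line of work:
bracket atoms (``[NH4+]``), two-letter halogens (``Cl``, ``Br``) and
``%``-ring closures are single tokens; everything else is one character.
Molecular formulas become a short element/digit token sequence padded to
a fixed prompt-prefix capacity.

Prediction targets are canonical *non-stereochemical* SMILES: stereo
descriptors are stripped before canonicalization so that the model is
supervised on molecular constitution only.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # RDKit parse chatter is handled via return values

__all__ = [
    "SMILES_TOKEN_PATTERN",
    "PAD",
    "BOS",
    "EOS",
    "UNK",
    "PROMPT_PAD",
    "SPECIALS",
    "FORMULA_PREFIX_LEN",
    "Vocabulary",
    "tokenize_smiles",
    "tokenize_formula",
    "canonicalize_nonstereo",
    "hill_formula",
    "build_vocab",
]

# Molecular Transformer SMILES tokenization pattern.
SMILES_TOKEN_PATTERN = (
    r"(\[[^\]]+]|Br?|Cl?|N|O|S|P|F|I|b|c|n|o|s|p|\(|\)|\.|=|#|-|\+|\\|\/|:|~|@|\?|>|\*|\$|%[0-9]{2}|[0-9])"
)
_SMILES_RE = re.compile(SMILES_TOKEN_PATTERN)

PAD = "<pad>"
BOS = "<bos>"
EOS = "<eos>"
UNK = "<unk>"
PROMPT_PAD = "<fpad>"
SPECIALS = [PAD, BOS, EOS, UNK, PROMPT_PAD]

#: Fixed capacity (in tokens) of the molecular-formula decoder prefix.
#: 16 tokens comfortably covers Hill formulas in the 5-35 heavy-atom regime.
FORMULA_PREFIX_LEN = 16

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def tokenize_smiles(s: str) -> List[str]:
    """Split a SMILES string into chemistry-aware tokens.

    The concatenation of the returned tokens reproduces ``s`` exactly;
    a character the pattern cannot consume raises with its position.
    """
    if not s:
        raise ValueError("empty SMILES string")
    tokens = _SMILES_RE.findall(s)
    joined = "".join(tokens)
    if joined != s:
        # locate the first offending character
        pos = 0
        for tok in tokens:
            if s[pos : pos + len(tok)] != tok:
                break
            pos += len(tok)
        raise ValueError(f"cannot tokenize SMILES at position {pos}: {s[pos:pos+1]!r}")
    return tokens


def _parse_formula(formula: str) -> List[tuple]:
    pos = 0
    parts = []
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            break
        if not m.group(0):
            break
        parts.append((m.group(1), int(m.group(2)) if m.group(2) else 1))
        pos = m.end()
    if pos != len(formula) or not parts:
        raise ValueError(f"unparseable molecular formula: {formula!r}")
    return parts


def hill_formula(formula_or_smiles: str, *, from_smiles: bool = False) -> str:
    """Normalize to Hill notation (C, H, then other elements alphabetically).

    Counts of 1 are omitted, following the usual convention.
    """
    if from_smiles:
        mol = Chem.MolFromSmiles(formula_or_smiles)
        if mol is None:
            raise ValueError(f"invalid SMILES: {formula_or_smiles!r}")
        from rdkit.Chem import rdMolDescriptors

        return rdMolDescriptors.CalcMolFormula(mol)
    counts: Dict[str, int] = {}
    for elem, n in _parse_formula(formula_or_smiles):
        counts[elem] = counts.get(elem, 0) + n
    order = []
    if "C" in counts:
        order.append("C")
        if "H" in counts:
            order.append("H")
        order += sorted(e for e in counts if e not in ("C", "H"))
    else:
        order = sorted(counts)
    return "".join(e + (str(counts[e]) if counts[e] != 1 else "") for e in order)


def tokenize_formula(formula: str, prefix_len: int = FORMULA_PREFIX_LEN) -> List[str]:
    """Tokenize a molecular formula for the decoder prompt prefix.

    The formula is first normalized to Hill order, then segmented into
    alternating element-symbol and digit tokens (multi-digit counts split
    into single digits; implicit counts of 1 are not materialized). The
    result is padded with ``PROMPT_PAD`` to ``prefix_len`` tokens; a
    formula longer than the capacity is an error, never a truncation.
    """
    normalized = hill_formula(formula)
    tokens: List[str] = []
    for elem, n in _parse_formula(normalized):
        tokens.append(elem)
        if n != 1:
            tokens.extend(str(n))
    if len(tokens) > prefix_len:
        raise ValueError(
            f"formula {formula!r} needs {len(tokens)} tokens, exceeding the "
            f"prefix capacity of {prefix_len}"
        )
    return tokens + [PROMPT_PAD] * (prefix_len - len(tokens))


def canonicalize_nonstereo(smiles: str) -> Optional[str]:
    """Canonical non-stereochemical SMILES, or ``None`` if invalid.

    Stereo descriptors (``/ \\ @ @@``) are removed before RDKit
    canonicalization, so two spellings of the same constitution —
    including enantiomers — map to one string. Idempotent.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


@dataclass
class Vocabulary:
    """Bijective token<->id map with the special tokens at fixed low ids."""

    token_to_id: Dict[str, int]

    def __post_init__(self) -> None:
        ids = sorted(self.token_to_id.values())
        if ids != list(range(len(ids))):
            raise ValueError("vocabulary ids must be contiguous from 0")
        for i, tok in enumerate(SPECIALS):
            if self.token_to_id.get(tok) != i:
                raise ValueError(f"special token {tok!r} must have id {i}")
        self.id_to_token = {i: t for t, i in self.token_to_id.items()}

    def __len__(self) -> int:
        return len(self.token_to_id)

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def bos_id(self) -> int:
        return self.token_to_id[BOS]

    @property
    def eos_id(self) -> int:
        return self.token_to_id[EOS]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    @property
    def prompt_pad_id(self) -> int:
        return self.token_to_id[PROMPT_PAD]

    def encode(self, tokens: Sequence[str], *, strict: bool = False) -> List[int]:
        """Map tokens to ids; unknown tokens become UNK with a warning.

        With ``strict=True`` (training-data builds) unknown tokens raise
        instead, so vocabulary gaps fail fast.
        """
        ids = []
        for tok in tokens:
            tid = self.token_to_id.get(tok)
            if tid is None:
                if strict:
                    raise KeyError(f"token {tok!r} not in vocabulary")
                warnings.warn(f"token {tok!r} not in vocabulary: using UNK", stacklevel=2)
                tid = self.unk_id
            ids.append(tid)
        return ids

    def decode(self, ids: Sequence[int]) -> List[str]:
        return [self.id_to_token[int(i)] for i in ids]

    def save(self, path) -> None:
        Path(path).write_text(
            json.dumps({"version": 1, "tokens": self.token_to_id}, indent=1)
        )

    @classmethod
    def load(cls, path) -> "Vocabulary":
        obj = json.loads(Path(path).read_text())
        return cls({t: int(i) for t, i in obj["tokens"].items()})


def build_vocab(corpora: Iterable[Iterable[str]]) -> Vocabulary:
    """Build a vocabulary from token sequences (SMILES + formula tokens).

    Ids are assigned deterministically: the specials first, then all
    observed tokens in lexicographic order, so two builds over the same
    corpus agree exactly.
    """
    seen = set()
    n_seqs = 0
    for seq in corpora:
        n_seqs += 1
        seen.update(seq)
    if n_seqs == 0 or not seen:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    seen -= set(SPECIALS)
    mapping = {tok: i for i, tok in enumerate(SPECIALS)}
    for tok in sorted(seen):
        mapping[tok] = len(mapping)
    return Vocabulary(mapping)


def vocab_for_dataset(records: Iterable) -> Vocabulary:
    """Vocabulary over SMILES targets and formula prompts of a dataset.

    ``records`` yields objects with ``smiles`` and ``formula`` attributes
    (e.g. :class:`nmr2struct.synthetic.MoleculeRecord`).
    """
    corpora = []
    for rec in records:
        corpora.append(tokenize_smiles(rec.smiles))
        corpora.append([t for t in tokenize_formula(rec.formula) if t != PROMPT_PAD])
    return build_vocab(corpora)
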