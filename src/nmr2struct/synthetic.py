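"""Deterministic toy molecule/spectrum generator.

This module emulates the statistical structure of a large simulated
spectrum-structure corpus at desk scale, so the whole pipeline (spectra
encoding, sequence decoding, re-ranking) is trainable and testable
without any external download:

* small organic molecules built from a fragment grammar over C/N/O and
  halogens (acyclic chains, rings, carbonyls, ethers, amines), filtered
  to a heavy-atom range and deduplicated by canonical non-stereo SMILES;
* a fully deterministic additive rule table mapping atom environments to
  1H/13C chemical shifts (a stand-in for a real shift predictor);
* sparse Gaussian-peak spectra on dense ppm grids with [0, 1]
  instance-wise normalization, environment multiplicities driving peak
  intensities, and optional additive noise;
* a 7:2:1 train/valid/test split, disjoint by canonical SMILES.

The shift rules are intentionally unambiguous: distinct toy molecules
map to distinct shift multisets with high probability, so spectrum ->
structure is learnable by a small model. They make no claim of
quantitative accuracy for real chemistry.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .spectra import (
    DEFAULT_C13_GRID,
    DEFAULT_H1_GRID,
    DEFAULT_HSQC_C_GRID,
    DEFAULT_HSQC_H_GRID,
    Nucleus,
    PeakList1D,
    PeakListHSQC,
    PpmGrid,
    normalize_instance,
    reconstruct_hsqc,
    render_peaklist_1d,
)
from .tokenizer import canonicalize_nonstereo

__all__ = [
    "MoleculeRecord",
    "ShiftAssignment",
    "DatasetManifest",
    "SUPPORTED_ELEMENTS",
    "C13_RULES",
    "H1_RULES",
    "generate_toy_molecules",
    "assign_toy_shifts",
    "simulate_record",
    "build_dataset",
    "largest_remainder_split",
    "DEFAULT_LINE_SIGMA",
    "DEFAULT_NOISE_SD",
]

SUPPORTED_ELEMENTS = {"C", "H", "N", "O", "F", "Cl", "Br"}

#: Gaussian line widths (ppm) used when rendering toy peak lists.
DEFAULT_LINE_SIGMA = {Nucleus.H1: 0.02, Nucleus.C13: 0.3}
DEFAULT_HSQC_H_SIGMA = 0.05
#: Additive noise standard deviation on the post-normalization scale.
DEFAULT_NOISE_SD = 0.005


@dataclass(frozen=True)
class MoleculeRecord:
    """A target molecule: canonical non-stereo SMILES + Hill formula."""

    smiles: str
    formula: str
    heavy_atoms: int

    @classmethod
    def from_smiles(cls, smiles: str) -> "MoleculeRecord":
        canonical = canonicalize_nonstereo(smiles)
        if canonical is None:
            raise ValueError(f"invalid SMILES: {smiles!r}")
        mol = Chem.MolFromSmiles(canonical)
        return cls(
            smiles=canonical,
            formula=rdMolDescriptors.CalcMolFormula(mol),
            heavy_atoms=mol.GetNumHeavyAtoms(),
        )


@dataclass
class ShiftAssignment:
    """Per-environment chemical shifts with multiplicity weights.

    One entry per topologically distinct environment; weights are the
    number of equivalent nuclei and sum to the respective atom counts.
    ``hc_pairs`` lists one (h_ppm, c_ppm) cross-peak per protonated
    carbon environment, weighted by its hydrogen count.
    """

    h_shifts: List[float] = field(default_factory=list)
    h_weights: List[int] = field(default_factory=list)
    c_shifts: List[float] = field(default_factory=list)
    c_weights: List[int] = field(default_factory=list)
    hc_pairs: List[Tuple[float, float]] = field(default_factory=list)
    hc_weights: List[int] = field(default_factory=list)


@dataclass
class DatasetManifest:
    """One split of a generated dataset.

    ``arrays[modality]`` stacks all spectra of the split row-wise
    (row i belongs to ``records[i]``); ``paths`` holds file locations
    when the split was written to disk.
    """

    split: str
    seed: int
    records: List[MoleculeRecord]
    arrays: Dict[str, np.ndarray] = field(default_factory=dict)
    paths: Dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Toy molecule grammar
# ---------------------------------------------------------------------------

_SCAFFOLDS = [
    "CCC", "CCCC", "CCCCC", "CCCCCC", "CCCCCCC",
    "CCOCC", "CCNCC",
    "c1ccccc1", "c1ccncc1",
    "C1CCCCC1", "C1CCCC1", "C1CCOC1", "C1CCNC1",
]

# Substituent fragments; the first atom is the attachment point.
_SUBSTITUENTS = [
    "C", "CC", "O", "OC", "N", "N(C)C",
    "F", "Cl", "Br", "C#N",
    "C(C)=O", "C=O", "C(=O)O", "C(=O)OC",
]


def _attach(scaffold: Chem.Mol, frag_smiles: str, atom_idx: int) -> Optional[Chem.Mol]:
    frag = Chem.MolFromSmiles(frag_smiles)
    combined = Chem.RWMol(Chem.CombineMols(scaffold, frag))
    combined.AddBond(atom_idx, scaffold.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        mol = combined.GetMol()
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def generate_toy_molecules(
    n: int,
    seed: int,
    heavy_range: Tuple[int, int] = (5, 35),
    max_substituents: int = 3,
) -> List[MoleculeRecord]:
    """Generate ``n`` unique toy molecules from the fragment grammar.

    Scaffolds (carbon chains, carbo-/heterocycles) receive 0-3 random
    substituents at random carbon positions. Results are filtered to the
    heavy-atom range and deduplicated by canonical non-stereo SMILES;
    the output is reproducible given ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(seed)
    seen: set = set()
    out: List[MoleculeRecord] = []
    max_attempts = 200 * n + 10_000
    attempts = 0
    stagnant = 0  # attempts since the last new unique molecule
    while len(out) < n and attempts < max_attempts and stagnant < 3_000:
        attempts += 1
        stagnant += 1
        scaffold = Chem.MolFromSmiles(_SCAFFOLDS[rng.integers(len(_SCAFFOLDS))])
        mol = scaffold
        n_subs = int(rng.integers(0, max_substituents + 1))
        ok = True
        for _ in range(n_subs):
            sites = [
                a.GetIdx()
                for a in mol.GetAtoms()
                if a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
            ]
            if not sites:
                ok = False
                break
            frag = _SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]
            mol2 = _attach(mol, frag, int(sites[rng.integers(len(sites))]))
            if mol2 is None:
                ok = False
                break
            mol = mol2
        if not ok:
            continue
        smiles = canonicalize_nonstereo(Chem.MolToSmiles(mol))
        if smiles is None or smiles in seen:
            continue
        record = MoleculeRecord.from_smiles(smiles)
        if not (heavy_range[0] <= record.heavy_atoms <= heavy_range[1]):
            continue
        seen.add(smiles)
        out.append(record)
        stagnant = 0
    if len(out) < n:
        raise RuntimeError(
            f"fragment grammar yielded only {len(out)} unique molecules in the "
            f"heavy-atom range {heavy_range} (requested {n})"
        )
    return out


# ---------------------------------------------------------------------------
# Deterministic toy shift rules
# ---------------------------------------------------------------------------
#
# Additive rule tables: each environment class has a base shift (ppm) and
# fixed increments per alpha-substituent class. Values are loosely inspired
# by common organic correlation charts but serve only to give distinct
# environments distinct, reproducible positions.

C13_RULES = {
    "base_sp3": {3: 15.0, 2: 29.0, 1: 37.0, 0: 40.0},  # keyed by H count
    "base_aromatic": 128.0,
    "base_carbonyl_acid": 171.0,   # C(=O)O
    "base_carbonyl_aldehyde": 193.0,
    "base_carbonyl_ketone": 206.0,
    "base_nitrile": 118.0,
    "inc_sp3": {"O": 28.0, "N": 20.0, "F": 55.0, "Cl": 18.0, "Br": 10.0,
                "Car": 10.0, "C=O": 12.0, "C": 4.0},
    "inc_aromatic": {"O": 27.0, "N": 19.0, "F": 35.0, "Cl": 6.0, "Br": -5.0,
                     "C": 9.0, "Nring": 21.0},
}

H1_RULES = {
    "base_sp3": {3: 0.90, 2: 1.25, 1: 1.55},  # keyed by H count
    "base_aromatic": 7.30,
    "aldehyde": 9.75,
    "carboxylic_oh": 11.50,
    "alcohol_oh": 2.80,
    "amine_nh": 1.80,
    "inc_sp3": {"O": 2.45, "N": 1.45, "F": 3.30, "Cl": 2.10, "Br": 1.75,
                "Car": 1.45, "C=O": 1.15, "C": 0.10},
    "inc_aromatic_ortho": {"O": -0.35, "N": -0.25, "F": -0.20, "Cl": 0.10,
                           "Br": 0.25, "C": 0.05, "C=O": 0.55, "Nring": 1.20},
}


def _neighbor_class(atom: Chem.Atom, nbr: Chem.Atom) -> str:
    sym = nbr.GetSymbol()
    if sym == "C":
        if nbr.GetIsAromatic():
            return "Car"
        for bond in nbr.GetBonds():
            other = bond.GetOtherAtom(nbr)
            if other.GetSymbol() == "O" and bond.GetBondType() == Chem.BondType.DOUBLE:
                return "C=O"
        return "C"
    return sym


def _carbon_kind(atom: Chem.Atom) -> str:
    if atom.GetIsAromatic():
        return "aromatic"
    has_triple_n = False
    dbl_o = False
    sgl_o = False
    for bond in atom.GetBonds():
        other = bond.GetOtherAtom(atom)
        if other.GetSymbol() == "O":
            if bond.GetBondType() == Chem.BondType.DOUBLE:
                dbl_o = True
            else:
                sgl_o = True
        if other.GetSymbol() == "N" and bond.GetBondType() == Chem.BondType.TRIPLE:
            has_triple_n = True
    if has_triple_n:
        return "nitrile"
    if dbl_o:
        return "acid_ester" if sgl_o else (
            "aldehyde" if atom.GetTotalNumHs() >= 1 else "ketone"
        )
    return "sp3"


def _c13_shift(atom: Chem.Atom) -> float:
    kind = _carbon_kind(atom)
    if kind == "aromatic":
        shift = C13_RULES["base_aromatic"]
        for nbr in atom.GetNeighbors():
            if nbr.GetIsAromatic():
                if nbr.GetSymbol() == "N":
                    shift += C13_RULES["inc_aromatic"]["Nring"]
                continue
            cls = _neighbor_class(atom, nbr)
            cls = "C" if cls in ("C", "Car", "C=O") else cls
            shift += C13_RULES["inc_aromatic"].get(cls, 0.0)
        return shift
    if kind == "nitrile":
        return C13_RULES["base_nitrile"]
    if kind == "acid_ester":
        return C13_RULES["base_carbonyl_acid"]
    if kind == "aldehyde":
        return C13_RULES["base_carbonyl_aldehyde"]
    if kind == "ketone":
        return C13_RULES["base_carbonyl_ketone"]
    shift = C13_RULES["base_sp3"][min(atom.GetTotalNumHs(), 3)]
    for nbr in atom.GetNeighbors():
        shift += C13_RULES["inc_sp3"].get(_neighbor_class(atom, nbr), 0.0)
    return shift


def _h1_shift(atom: Chem.Atom) -> float:
    """Shift of the hydrogens attached to heavy atom ``atom``."""
    sym = atom.GetSymbol()
    if sym == "O":
        for nbr in atom.GetNeighbors():
            if _neighbor_class(atom, nbr) == "C=O":
                return H1_RULES["carboxylic_oh"]
        return H1_RULES["alcohol_oh"]
    if sym == "N":
        return H1_RULES["amine_nh"]
    kind = _carbon_kind(atom)
    if kind == "aromatic":
        shift = H1_RULES["base_aromatic"]
        for nbr in atom.GetNeighbors():
            if nbr.GetIsAromatic():
                if nbr.GetSymbol() == "N":
                    shift += H1_RULES["inc_aromatic_ortho"]["Nring"]
                else:
                    # ortho effects of the neighbour ring-carbon's substituents
                    for sub in nbr.GetNeighbors():
                        if sub.GetIdx() == atom.GetIdx() or sub.GetIsAromatic():
                            continue
                        shift += H1_RULES["inc_aromatic_ortho"].get(
                            _neighbor_class(nbr, sub), 0.0
                        )
        return shift
    if kind == "aldehyde":
        return H1_RULES["aldehyde"]
    shift = H1_RULES["base_sp3"][min(max(atom.GetTotalNumHs(), 1), 3)]
    for nbr in atom.GetNeighbors():
        shift += H1_RULES["inc_sp3"].get(_neighbor_class(atom, nbr), 0.0)
    return shift


def assign_toy_shifts(mol_or_smiles) -> ShiftAssignment:
    """Deterministic toy 1H/13C shifts per topologically distinct environment.

    Environments are symmetry classes of the molecular graph (RDKit
    canonical ranks without tie-breaking); each class contributes one
    shift with a weight equal to its nucleus count. No randomness is
    involved: the same molecule always yields the same assignment.
    """
    if isinstance(mol_or_smiles, MoleculeRecord):
        mol_or_smiles = mol_or_smiles.smiles
    if isinstance(mol_or_smiles, str):
        mol = Chem.MolFromSmiles(mol_or_smiles)
        if mol is None:
            raise ValueError(f"invalid SMILES: {mol_or_smiles!r}")
    else:
        mol = mol_or_smiles
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in SUPPORTED_ELEMENTS:
            raise ValueError(
                f"element {atom.GetSymbol()!r} outside the supported set "
                f"{sorted(SUPPORTED_ELEMENTS)}"
            )
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
    c_classes: Dict[int, List[Chem.Atom]] = {}
    h_classes: Dict[int, List[Chem.Atom]] = {}
    for atom in mol.GetAtoms():
        if atom.GetSymbol() == "C":
            c_classes.setdefault(ranks[atom.GetIdx()], []).append(atom)
        if atom.GetTotalNumHs() >= 1:
            h_classes.setdefault(ranks[atom.GetIdx()], []).append(atom)

    result = ShiftAssignment()
    c_shift_by_rank: Dict[int, float] = {}
    for rank in sorted(c_classes):
        atoms = c_classes[rank]
        shift = _c13_shift(atoms[0])
        c_shift_by_rank[rank] = shift
        result.c_shifts.append(shift)
        result.c_weights.append(len(atoms))
    for rank in sorted(h_classes):
        atoms = h_classes[rank]
        shift = _h1_shift(atoms[0])
        weight = sum(a.GetTotalNumHs() for a in atoms)
        result.h_shifts.append(shift)
        result.h_weights.append(weight)
        if atoms[0].GetSymbol() == "C":
            result.hc_pairs.append((shift, c_shift_by_rank[rank]))
            result.hc_weights.append(weight)
    return result


# ---------------------------------------------------------------------------
# Spectrum simulation
# ---------------------------------------------------------------------------


def simulate_record(
    mol: MoleculeRecord,
    modalities: Sequence[str] = ("H1", "C13", "HSQC"),
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    grids: Optional[Dict[str, PpmGrid]] = None,
    line_sigma: Optional[Dict[Nucleus, float]] = None,
):
    """Simulate spectra for one molecule from its toy shift assignment.

    Peak intensities are the environment multiplicities, so e.g. a methyl
    group is three times as intense as a methine — the informative
    intensity pattern a raw-spectrum model can exploit. Gaussian noise of
    standard deviation ``noise_sd`` (post-normalization scale) is added
    and the spectrum re-normalized; ``noise_sd=0`` gives a fully
    deterministic, noiseless record.

    Returns a dict mapping modality name ("H1", "C13", "HSQC") to
    :class:`Spectrum1D` / :class:`SpectrumHSQC`.
    """
    bad = set(modalities) - {"H1", "C13", "HSQC"}
    if bad:
        raise ValueError(f"unknown modalities: {sorted(bad)}")
    sigma = dict(DEFAULT_LINE_SIGMA)
    if line_sigma:
        sigma.update(line_sigma)
    grids = grids or {}
    assign = assign_toy_shifts(mol)
    rng = np.random.default_rng(seed)
    out = {}
    if "H1" in modalities:
        peaks = PeakList1D(
            Nucleus.H1,
            list(zip(assign.h_shifts, map(float, assign.h_weights))),
        )
        spec = render_peaklist_1d(
            peaks, grids.get("H1", DEFAULT_H1_GRID), sigma[Nucleus.H1]
        )
        out["H1"] = _add_noise(spec, noise_sd, rng)
    if "C13" in modalities:
        peaks = PeakList1D(
            Nucleus.C13,
            list(zip(assign.c_shifts, map(float, assign.c_weights))),
        )
        spec = render_peaklist_1d(
            peaks, grids.get("C13", DEFAULT_C13_GRID), sigma[Nucleus.C13]
        )
        out["C13"] = _add_noise(spec, noise_sd, rng)
    if "HSQC" in modalities:
        cross = PeakListHSQC(
            [
                (h, c, float(w))
                for (h, c), w in zip(assign.hc_pairs, assign.hc_weights)
            ]
        )
        if not cross.peaks:
            warnings.warn(
                f"{mol.smiles}: no C-H cross-peaks, HSQC is a zero matrix",
                stacklevel=2,
            )
        spec2d = reconstruct_hsqc(
            cross,
            grids.get("HSQC_H", DEFAULT_HSQC_H_GRID),
            grids.get("HSQC_C", DEFAULT_HSQC_C_GRID),
            h_sigma=DEFAULT_HSQC_H_SIGMA,
            power=1.0,  # dynamic-range compression is a re-ranking concern
        )
        out["HSQC"] = _add_noise(spec2d, noise_sd, rng)
    return out


def _add_noise(spec, noise_sd: float, rng: np.random.Generator):
    if noise_sd <= 0:
        return spec
    noisy = spec.intensities + rng.normal(0.0, noise_sd, size=spec.intensities.shape)
    spec.intensities = noisy
    spec.normalized = False
    return normalize_instance(spec)


# ---------------------------------------------------------------------------
# Dataset building
# ---------------------------------------------------------------------------


def largest_remainder_split(n: int, ratio: Tuple[int, ...]) -> List[int]:
    """Apportion ``n`` items to parts by largest-remainder rounding."""
    total = sum(ratio)
    quotas = [n * r / total for r in ratio]
    sizes = [int(np.floor(q)) for q in quotas]
    remainders = [q - s for q, s in zip(quotas, sizes)]
    for _ in range(n - sum(sizes)):
        i = int(np.argmax(remainders))
        sizes[i] += 1
        remainders[i] = -1.0
    return sizes


def build_dataset(
    n: int,
    seed: int,
    ratio: Tuple[int, int, int] = (7, 2, 1),
    out_dir=None,
    modalities: Sequence[str] = ("H1", "C13", "HSQC"),
    noise_sd: float = DEFAULT_NOISE_SD,
    heavy_range: Tuple[int, int] = (5, 35),
    grids: Optional[Dict[str, PpmGrid]] = None,
    line_sigma: Optional[Dict[Nucleus, float]] = None,
) -> Dict[str, DatasetManifest]:
    """Generate a full train/valid/test dataset of toy spectrum-structure pairs.

    Splits are disjoint by canonical SMILES at the given ratio (default
    7:2:1, largest-remainder rounding). Spectra are stacked per split and
    modality; when ``out_dir`` is given the stacks are written as ``.npz``
    files alongside a JSONL manifest per split. The whole pipeline is
    byte-identical for the same ``(n, seed)``.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    molecules = generate_toy_molecules(n, seed=seed, heavy_range=heavy_range)
    rng = np.random.default_rng(seed + 1)
    order = rng.permutation(n)
    molecules = [molecules[i] for i in order]
    sizes = largest_remainder_split(n, ratio)
    names = ["train", "valid", "test"]
    manifests: Dict[str, DatasetManifest] = {}
    offset = 0
    for split_idx, (name, size) in enumerate(zip(names, sizes)):
        records = molecules[offset : offset + size]
        offset += size
        stacks: Dict[str, List[np.ndarray]] = {m: [] for m in modalities}
        for i, rec in enumerate(records):
            rec_seed = int(
                np.random.SeedSequence(seed, spawn_key=(split_idx, i)).generate_state(1)[0]
                % (2**31)
            )
            spectra = simulate_record(
                rec, modalities, noise_sd=noise_sd, seed=rec_seed,
                grids=grids, line_sigma=line_sigma,
            )
            for m in modalities:
                stacks[m].append(spectra[m].intensities.astype(np.float32))
        manifest = DatasetManifest(
            split=name,
            seed=seed,
            records=records,
            arrays={m: np.stack(stacks[m]) if stacks[m] else np.empty((0,)) for m in modalities},
        )
        manifests[name] = manifest
    if out_dir is not None:
        write_dataset(manifests, out_dir)
    return manifests


def write_dataset(manifests: Dict[str, DatasetManifest], out_dir) -> None:
    """Write split manifests (JSONL) and stacked spectrum arrays (.npz)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, manifest in manifests.items():
        for m, arr in manifest.arrays.items():
            path = out_dir / f"{name}_{m}.npz"
            np.savez_compressed(path, intensities=arr)
            manifest.paths[m] = str(path)
        lines = []
        for i, rec in enumerate(manifest.records):
            lines.append(
                json.dumps(
                    {
                        "smiles": rec.smiles,
                        "formula": rec.formula,
                        "heavy_atoms": rec.heavy_atoms,
                        "split": name,
                        "seed": manifest.seed,
                        "row": i,
                        **{m: f"{name}_{m}.npz" for m in manifest.arrays},
                    }
                )
            )
        (out_dir / f"{name}.jsonl").write_text("\n".join(lines) + "\n")


def load_dataset(out_dir, splits: Iterable[str] = ("train", "valid", "test")) -> Dict[str, DatasetManifest]:
    """Load manifests written by :func:`write_dataset`."""
    out_dir = Path(out_dir)
    manifests = {}
    for name in splits:
        path = out_dir / f"{name}.jsonl"
        records = []
        seed = 0
        modality_paths: Dict[str, str] = {}
        for line in path.read_text().splitlines():
            obj = json.loads(line)
            records.append(
                MoleculeRecord(obj["smiles"], obj["formula"], obj["heavy_atoms"])
            )
            seed = obj["seed"]
            modality_paths = {
                k: v for k, v in obj.items()
                if k in ("H1", "C13", "HSQC")
            }
        arrays = {}
        for m, p in modality_paths.items():
            p = p if Path(p).is_absolute() else out_dir / p
            modality_paths[m] = str(p)
            with np.load(p) as data:
                arrays[m] = data["intensities"]
        manifests[name] = DatasetManifest(
            split=name, seed=seed, records=records, arrays=arrays,
            paths=dict(modality_paths),
        )
    return manifests
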