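# Methods

This note documents the models, numerical choices and limitations of
`nmr2struct`, in the spirit of a package's methods appendix. Everything
stated here is computed by the test suite or by `scripts/acceptance.py`;
no external results are quoted.

## Problem setting

Given one or more NMR spectra of an unknown small organic molecule — a
dense 1D ¹H spectrum, a dense 1D ¹³C spectrum, and/or a 2D ¹H–¹³C HSQC
intensity matrix — together with the molecular formula, the task is to
predict the molecule's constitution as a canonical non-stereochemical
SMILES string. Targets are deliberately constitution-only: stereo
descriptors are stripped before supervision and evaluation, because
stereochemistry is not reliably encoded by the inputs considered here.

## Spectrum representation

1D spectra are dense intensity vectors on an evenly spaced ppm grid
(default 10,000 points; ¹H −2 to 12 ppm, ¹³C −10 to 230 ppm). HSQC
spectra are intensity matrices on a 256 (¹H, 0–12 ppm) × 256 (¹³C,
0–200 ppm) grid. Grids are stored ascending in ppm; the conventional
reversed display axis is a plotting concern only. Every spectrum is
instance-wise min–max normalized to [0, 1]: this removes
instrument/simulator-specific intensity scales *and* baseline offsets,
which matters when moving between data sources. A constant (blank)
spectrum normalizes to all zeros with a warning rather than an error so
batch pipelines survive degenerate inputs.

When only cross-peak lists are available for HSQC (the common situation
for curated metabolite databases), a 2D image is reconstructed: each
peak is deposited at its nearest ¹³C grid column and broadened by a 1D
Gaussian (default σ = 0.05 ppm, a "mild" width chosen here) along the
¹H axis only. A power compression `I → I^p` with p = 0.3 is applied
before normalization so that a few very intense cross-peaks do not
dominate; negative raw intensities (phase artifacts) are clipped to
zero first. Power compression is monotone, so cell rankings are
preserved.

## Synthetic study corpus

No public corpus is downloaded; a deterministic toy generator emulates
the statistical structure the pipeline needs:

* **Molecules.** A fragment grammar over C/N/O/halogens: chain,
  carbocyclic, heterocyclic and aromatic scaffolds decorated with 0–3
  substituents (alkyl, hydroxy, ether, amino, halogen, nitrile,
  carbonyl, ester). Candidates are sanitized with RDKit, restricted to
  a heavy-atom window (default 5–35, matching common filters for
  synthetic-chemistry corpora; the grammar in practice yields 5–16),
  and deduplicated by canonical non-stereo SMILES.
* **Shifts.** A purely additive rule table maps each topologically
  distinct atom environment (RDKit symmetry classes) to a ¹H/¹³C shift:
  a base value per environment class (e.g. sp³ CH₃ ≈ 0.9 / 15 ppm,
  aromatic CH ≈ 7.3 / 128 ppm, ketone C ≈ 206 ppm) plus fixed
  increments per α-substituent class. The values are chart-plausible
  but make no accuracy claim; their purpose is to give distinct
  molecules distinct, reproducible shift multisets (measured: ≥99% of
  generated molecules have unique multisets), so spectrum→structure is
  learnable. Collisions are accepted and simply bound attainable
  accuracy.
* **Spectra.** Environments are rendered as Gaussians (default line
  widths: ¹H 0.02 ppm, ¹³C 0.3 ppm) with intensities equal to
  environment multiplicities — the informative intensity pattern that
  peak-picking pipelines discard. HSQC cross-peaks are one per
  protonated carbon environment. Optional additive Gaussian noise
  (default sd 0.005 on the normalized scale; 0 for oracle tests) is
  followed by re-normalization. ¹³C spectra come out sparse (<5% of
  grid points above 0.01 for small molecules), emulating the sparsity
  that motivates patch dropout.
* **Splits.** 7:2:1 train/valid/test by largest-remainder rounding,
  disjoint by canonical SMILES. The full pipeline is byte-identical
  given (n, seed).

What the generator does *not* emulate: J-coupling multiplets, solvent
effects, baseline/phase distortions, realistic shift accuracy, or
experimental peak-shape variability. Passing tests therefore
demonstrate that the architecture and pipeline work end-to-end and that
the documented contracts hold — not that real-spectrum accuracy is
achieved at this scale.

## Tokenization and formula prompting

SMILES are tokenized with the standard chemistry-aware regular
expression (bracket atoms, two-letter halogens and %-ring closures are
single tokens); concatenating tokens reproduces the string exactly.
Molecular formulas are normalized to Hill order and segmented into
element and digit tokens, then padded with a dedicated `<fpad>` token
to a fixed 16-token decoder prefix (16 covers every formula in the
5–35 heavy-atom regime; longer formulas error rather than truncate).
The decoder input is `[formula prefix][BOS][SMILES tokens]`; the prefix
counts toward the maximum decoder length (80 by default). Vocabulary
ids are deterministic: specials first, then observed tokens
lexicographically.

## Architecture

A pre-norm transformer encoder–decoder implemented on NumPy with a
small reverse-mode autodiff engine written for this package (the
environment provides no deep-learning framework; the engine implements
exactly the primitives needed and its gradients are verified against
finite differences in the test suite).

* **Patch encoder.** 1D spectra are cut into contiguous non-overlapping
  patches along the shift axis (default 50 points → 200 tokens at the
  10,000-point resolution); HSQC matrices into non-overlapping 16×16
  squares flattened row-major (256 tokens). Both partitions are
  lossless and exactly invertible. Each modality has its own linear
  projection to the latent width and its own learnable positional
  table, so adding a modality adds only these lightweight parameters.
  Embedded streams are concatenated (fixed modality order) into one
  fused sequence processed by a single shared encoder.
* **Patch dropout.** During training, exactly `round((1−r)·n)` of the
  fused tokens survive, sampled uniformly without replacement and
  without intensity weighting, jointly across modalities, preserving
  order and positions (default r = 0.5). The exact-count variant keeps
  batch shapes fixed; per-token keep frequency remains uniform.
  Disabled at inference.
* **Decoder.** Autoregressive with causal self-attention over
  the formula prefix + SMILES tokens and cross-attention over the full
  encoder memory. No class/summary token is needed. Learnable
  positional embeddings on both sides; pre-norm blocks for small-model
  stability; ReLU feed-forward.

The desk-scale default configuration is d_model 128, 2+2 layers, 4
heads, feed-forward 256 (~0.7M parameters); everything is configurable
upward.

## Training

Cross-entropy over SMILES (and EOS) positions only — formula-prefix
and padding positions are masked and their gradient is identically
zero. AdamW (betas 0.9/0.98, weight decay 0.01 on matrices only,
global-norm gradient clipping at 1.0), peak learning rate 3e-4 with
linear warmup followed by cosine decay to zero over the schedule; the
canonical warmup of 10,000 steps is automatically shortened to 10% of
the schedule for desk-scale runs whose total step count is smaller.
No label smoothing by default (a flag is provided). Checkpoints are
selected by validation loss. Fine-tuning reuses the same loop with a
lower default peak rate (3e-5) and short schedule, all weights
trainable, after verifying the vocabulary covers the new corpus.

Desk-scale problem sizes, chosen once for single-CPU runtimes and used
by both the acceptance tests and `scripts/acceptance.py`: 2,000
noiseless ¹H records (split 1400/400/200), 30 epochs at batch 32;
top-k evaluation on deterministic subsets of ~100–150 records;
re-ranking measured on the 200-record test split; fine-tuning on 100
distribution-shifted records (broader ¹H lines, added noise) with 100
held-out shifted records for the zero-shot/fine-tuned comparison.
Under these conditions the tiny model reaches roughly 10% top-1 /
30% top-10 exact-match on unseen molecules — far above the
permuted-target chance level (~0%), which is the property the tests
assert; absolute values at this scale are not comparable to
full-scale corpora.

## Decoding and filtering

Beam search keeps the `width` highest cumulative log-probability
expansions per step (no length normalization by default; a Wu-style
flag exists). Ties break lexicographically on token ids for
reproducibility, width 1 reduces exactly to greedy decoding, and
EOS-ended hypotheses retire to a finished pool. From the candidate
list, invalid SMILES and candidates whose full Hill formula (implicit
hydrogens included) disagrees with the known formula are dropped;
spellings that collapse to the same canonical non-stereo SMILES count
as one molecule (keeping the best log-probability), and the pool is
truncated to 100 molecules by default. Top-k accuracy is counted at
the molecule level over this deduplicated beam order.

## Evidence-based re-ranking

For a normalized spectrum y(δ) on grid {δ_j} and N predicted shifts
{s_i}, the local evidence score is

    S = (1/N) · Σ_i [ Σ_j K(δ_j − s_i) y(δ_j) / Σ_j K(δ_j − s_i) ],

the mean over predicted shifts of the Gaussian-kernel-weighted local
average intensity. The kernel-weighted *mean* (rather than a raw sum)
makes the score grid-length-independent and bounded in [0, 1]; a
uniform spectrum scores exactly 1 and adding a predicted shift in a
signal-free region strictly lowers a positive score. Bandwidths default
to expected shift tolerances σ_H = 0.2 ppm, σ_C = 2.0 ppm. The HSQC
analogue uses a separable kernel K(Δh)·K(Δc) after power-0.3
compression and re-normalization of the matrix. Kernel support is
truncated at 5σ for speed; an exact full-grid mode exists and the two
agree to 1e-9 against brute-force double summation in the tests.

Environments are weighted by their nucleus multiplicity in the mean by
default (an unweighted flag exists). When several modalities are
available, re-ranking scores with the ¹³C spectrum alone by default:
carbon shifts are the most transferable evidence and mixing in ¹H
scores is known to degrade ranking; a mean-combination mode is behind a
flag. Candidates a predictor fails on are ranked last with a warning,
never silently dropped, and ties are broken by generator log-probability
then SMILES. Re-ranking only reorders the pool — it cannot recover a
molecule the generator never proposed, which bounds its possible gain
by the top-cap hit rate.

The bundled predictor is the toy rule table itself, so on synthetic
fixtures predicted shifts coincide exactly with the shifts that
rendered the spectra; with a real shift predictor the same code path
applies (any callable SMILES → shifts JSON plugs in).

## Numerical and degenerate-input decisions

* Min–max (not max-only) normalization; constant inputs → zeros + warning.
* Peaks outside both HSQC grid ranges are dropped with a warning; empty
  peak lists render to zero spectra with a warning.
* Predicted shifts far outside the grid contribute their (near-zero)
  local average with a warning, deliberately penalizing the candidate.
* Patch counts must divide grid sizes exactly; no implicit padding.
* Training aborts on non-finite loss with a diagnostic.
* All randomness (generator, patch dropout, batch order, noise) flows
  from explicit integer seeds; identical seeds give identical runs on
  one device. Float32 parameters/activations; float64 spectra.

## Known limitations

* The NumPy training loop is single-device and unoptimized for scale;
  the desk configuration trains in minutes on one CPU but the design
  does not target large corpora.
* The toy corpus's learnability is by construction; transfer claims to
  experimental spectra are out of scope and untested here.
* Beam search recomputes the decoder prefix per step (no KV cache),
  acceptable at the sequence lengths used.
* The late-fusion variant with separate per-modality encoders is not
  implemented; fusion is concatenation into a shared encoder only.
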