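# Methods

## Sentence generation

A molecule is a hydrogen-suppressed graph; sentences enumerate its
atom-centered circular substructures in the extended-connectivity (Morgan)
style, to a default maximum radius of 1 (configurable).

Parsing keeps the bonding pattern exactly as drawn: RDKit's structural
normalization pass is disabled (it would, e.g., rewrite `N(=O)=O` into the
charge-separated nitro form and make the two oxygens inequivalent), while
ring perception and aromaticity perception are kept, so kekulized and
aromatic spellings of the same structure unify. Canonical atom order — the
sentence's primary sort key — is the canonical-SMILES ranking of the parsing
toolkit.

Identifiers are FNV-1a hashes of the little-endian 4-byte serialization of
the invariant tuple, truncated to 32 bits: seedless, platform-stable, and
reproducible across machines. Radius 0 hashes a tag plus five atomic
invariants (atomic number, heavy-neighbor count, attached hydrogens, formal
charge, ring membership); radius t ≥ 1 hashes the tag, the atom's previous
identifier, and the sorted (bond-order code, neighbor previous identifier)
pairs, with bond codes single=1, double=2, triple=3, aromatic=4. Sorting
the neighbor list before hashing makes identifiers independent of the input
atom order. Atoms whose bond neighborhood did not grow emit no new
environment, matching standard ECFP behaviour (methane has exactly one
environment).

Deduplication applies two rules in order: (a) among radius ≥ 1 environments
with identical bond sets, the smaller radius — then smaller canonical rank —
survives; (b) among the survivors, repeated identifier values keep the first
occurrence in sentence order. This removes duplicates entirely (unlike
sentence schemes that keep one copy per atom), so sentence length is bounded
by (max_radius + 1) · p and equals the number of unique substructures. On a
50-molecule panel the per-radius unique-environment counts match the
toolkit's Morgan bit-info counts exactly (identifier values differ by
design; equivalence classes match).

## Vocabulary and encoding

The vocabulary holds five special tokens at fixed indices 0–4
(`[PAD] [UNK] [CLS] [SEP] [MASK]`; `[PAD]`=0 simplifies masking arithmetic)
followed by the corpus's distinct identifiers in first-appearance order.
Sequences are `[CLS] tokens [SEP]` padded to a fixed length; sentences
longer than max_len − 2 are truncated from the tail (default max_len 256).
Identifiers unseen at vocabulary-build time map to `[UNK]` rather than
erroring, because downstream datasets routinely contain substructures absent
from the pre-training corpus. Segment ids are all zero (single-sentence
inputs only).

## Encoder and pre-training

The encoder sums token, learned-position, and segment embeddings and applies
post-norm transformer blocks (multi-head self-attention, GELU feed-forward,
residual connections, layer normalization). Padded positions are excluded
from attention via an additive −1e9 key bias, which underflows to exactly
zero attention weight in float32 — hence appending pads leaves real-token
states unchanged to ≤ 1e-5.

Only the hidden size is fixed by the method description (H = 256 at full
scale); depth 6, 4 heads, feed-forward 4H, dropout 0.1, and learned
positions up to 256 are this package's defaults, all configurable.

Masking selects exactly max(1, ⌊0.15·n_sub⌋) substructure positions per
sentence — a hard per-sentence bound rather than a per-token Bernoulli draw,
which would stochastically exceed 15% — and never selects
`[CLS]`/`[SEP]`/`[PAD]`. Actions are mask/random/keep at 0.8/0.1/0.1, with
"random" drawn uniformly from non-special vocabulary entries. The loss is
mean cross-entropy at the selected positions against the original
identifiers. Pre-training uses Adam (lr 1e-4 default, batch 32), runs up to
40 epochs, holds out 5% of the corpus by seeded shuffle, and early-stops
when validation masked-token top-1 accuracy has not improved for `patience`
(default 5) epochs, reverting to the best epoch. NaN loss aborts with a
diagnostic rather than silently continuing.

Because no tensor-autograd framework is part of the package's dependency
set, the neural stack runs on a purpose-built reverse-mode autograd engine
over NumPy (`molsent.nn`): ~15 primitives with hand-derived adjoints, each
verified against central finite differences in the test suite. Everything
is single-threaded deterministic; one integer seed reproduces training logs
bitwise.

## Property head

The frozen encoder's substructure-token states (specials excluded — the
encoded representation T covers substructure vectors only) form
x_in ∈ ℝ^{n×H}. A valid (no-padding) 1-D convolution along the token axis
with ReLU produces n − k + 1 feature vectors of n_kernels channels; global
max pooling over positions whose receptive field lies entirely within real
tokens yields o_max; a fully connected ReLU layer (fc_units) and a single
output unit produce the prediction. The output unit is sigmoid for
classification (a probability, paired with binary cross-entropy) and linear
for regression (mean squared error; negative targets such as log-solubility
require an unbounded output). ReLU is the hidden activation only — a
rectified output could represent neither probabilities nor negative property
values.

Defaults follow the stated experiment settings: kernel length 5 with 512
kernels for classification, kernel length 1 with 2048 for regression,
256 fully connected units, learning rate 0.001; batch size 32, 100 epochs
maximum and patience 10 are this package's choices. Early stopping monitors
validation ROC-AUC (classification) or RMSE (regression) with best-epoch
revert, and a parameter checksum asserts the encoder is bit-identical after
training.

Degenerate inputs: an explicit call with fewer substructure tokens than the
kernel raises an error instructing padding; inside the batched trainer,
molecules shorter than the kernel are zero-padded up to kernel length so a
single deterministic convolution position survives pooling.

## Evaluation kit

ROC-AUC uses the rank-sum form AUC = [Σ_{i∈pos} rank_i − M(1+M)/2]/(MN)
with ascending mid-ranks for ties (tie handling is this package's choice;
it makes the statistic equal the pairwise win/half-tie probability, verified
exhaustively against the pairwise oracle). R² = 1 − RSS/TSS is computed as
printed in this pipeline's convention with TSS centered on the *prediction*
mean; the conventional target-mean variant is available via
`center="targets"`. Constant predictions make the printed TSS zero and
raise rather than returning a silent value. Q² = 1 − PRESS/TSS takes an
explicit reference TSS. The paired t-test delegates to
`scipy.stats.ttest_rel` and treats zero-variance differences as an error,
not p = 1.

Random splits shuffle with a seed and cut at ⌊0.8n⌋ and ⌊0.9n⌋. Scaffold
splits group molecules by Bemis–Murcko framework and assign whole groups —
largest first, ties broken by scaffold string then seeded shuffle — to
train until its quota fills, then validation, then test; an oversized group
overflows into train so validation/test never receive a partial scaffold,
and an empty validation/test subset triggers a warning. The train→test
similarity diagnostic is Tanimoto over radius-1 identifier *sets* (the
package's own sentences), chosen for self-containedness.

## Synthetic data

The generator assembles molecules from a weighted grammar of chemically
valid fragments (alkyl chains, benzene, pyridine, cyclohexane, halogens,
nitro, hydroxyl, amide, methoxy, amine), joining each new fragment by a
single bond at hydrogen-bearing (or valence-capable) atoms, so every output
sanitizes without a rejection loop. Defaults produce 2–4 fragments per
molecule — roughly 5–30 heavy atoms with rings, heteroatoms, and common
functional groups, emulating small drug-like compounds.

Planted tasks define ground truth by toolkit substructure search,
deliberately independent of the hashing code under test: classification
labels are motif presence with a known flip rate; regression targets are
effect × (motif count) + Gaussian noise. The default motif is the pyridine
ring (~23% presence under the default grammar, a realistic class balance).

What the generator does *not* emulate: realistic property distributions,
activity cliffs, stereochemistry, tautomerism, or assay noise structure.
Passing the planted-recovery benchmarks therefore shows the pipeline is
correctly wired end to end and can recover substructure-determined signals;
it does not certify performance on real assay data.

## Desk-scale study conditions

The reference experiment (`molsent.pipeline`, also run by
`scripts/acceptance.py`) uses problem sizes chosen to exercise every stage
meaningfully on a single CPU in minutes: a 5,000-molecule pre-training
corpus; encoder H=64, 2 layers, 4 heads, 6 pre-training epochs at lr 1e-3;
2,000-molecule planted tasks split 8:1:1; classification with 5% label
flips (head: 256 kernels, length 5); regression with noise sd 0.1 (head:
512 kernels, length 1, trained up to 120 epochs — global max pooling makes
count regression a hard target, and the longer schedule is needed for the
head to converge). At these conditions the held-out classification AUC is
≈0.91 and the regression RMSE ≈0.16 (≈1.6× the noise floor).

## Known limitations

- Radius > 1 is supported but untested against an external oracle beyond
  internal invariants; the default pipeline uses radius 1.
- The float32 engine accumulates rounding differently than BLAS-backed
  frameworks; checkpoints reproduce bitwise on one platform but not
  necessarily across BLAS builds.
- Max pooling discards occurrence counts, so regression targets proportional
  to motif *count* are recoverable only through contextual state differences.
- The scaffold split's greedy largest-first fill can leave validation or
  test empty when scaffold diversity is low; this warns rather than errors.
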