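# Methods

## Model

The generative model is a denoising diffusion probabilistic model (DDPM)
acting on the latent space of a jointly trained autoencoder.

**Autoencoder.** Sequences are tokenized over the 20 canonical amino
acids plus three reserved symbols (pad `.`, gap `-`, unknown `X`) and
right-padded to the longest family member. The encoder adds learned
positional embeddings to token embeddings, projects to the transformer
width, and runs a pre-norm transformer stack in which pad positions are
excluded from attention keys. The per-position outputs are mean-pooled
over non-pad positions and passed through a single fully connected
bottleneck to the latent code z. This pooling choice makes the code
provably invariant to extra padding (tested against a one-sequence-at-a-
time oracle). The decoder expands z through one ReLU-activated fully
connected layer, reshapes to a channels × length feature map, and
refines it with a stack of same-padded 1-D convolutions (ReLU + batch
normalization between layers, none after the last), ending in
per-position scores over the full symbol vocabulary. Argmax decoding
breaks ties toward the lowest token index and strips trailing pads. The
regressor is a one-hidden-layer MLP with dropout before the output
unit.

**Joint objective.** Reconstruction is token-level cross-entropy (the
discrete realization of a sequence reconstruction norm), regression is
mean squared error in dataset units, and the diffusion term is the
standard noise-matching loss E‖ε − ε_θ(z_t, t, c)‖² with t uniform per
batch element and the squared norm summed over latent dimensions. The
three terms are summed unweighted.

**Diffusion.** The variance schedule is fixed (not learned); both a
linear β ramp and a constant β are supported. All coefficients derive
from β: α_t = 1 − β_t, ᾱ_t = Π_{s≤t} α_s with ᾱ_0 := 1, and
σ_t² = (1 − ᾱ_{t−1})/(1 − ᾱ_t)·β_t, which makes the final denoising
step deterministic (σ_1 = 0). When the step count T is reduced below
the conventional thousand, the β range is rescaled by 1000/T so that
ᾱ_T ≈ 0 — the ancestral sampler starts from N(0, I), so the forward
chain must actually reach it; with an unscaled ramp at T = 100 the
terminal signal fraction is ≈ 37% and sampling is biased.

The noise predictor is a small 1-D convolutional UNet: the latent
vector is treated as a one-channel signal, channels double per level
while mean-pooling halves the length, nearest-neighbour upsampling and
skip connections restore it, and sinusoidal timestep features plus a
learned label embedding (the null identifier ∅ has its own row) are
projected and added at every block. The level count is automatically
capped so pooling always divides the signal length.

**Latent standardization.** Diffusion operates on latents standardized
per dimension. During training the statistics are an exponential moving
average of batch statistics; at the end of training they are recomputed
exactly over the training set in evaluation mode and stored in the
checkpoint. Sampling denormalizes with the stored statistics.

**Classifier-free guidance.** Labels are dropped to ∅ with probability
p_uncond = 0.1 during training (the standard choice; the source
material for this architecture does not state a value). Sampling uses
ε̃ = (1+ω)ε_c − ωε_u; ω = 0 skips the unconditional evaluation since
the combination reduces to ε_c algebraically.

## Training procedure

By default the diffusion branch trains on *detached* latents: the
autoencoder shapes the latent space, and the noise predictor fits its
distribution. Fully joint gradient flow (the loss written as one sum
suggests it) is available via `detach_latents=False`, but at desk scale
it let the diffusion term reshape the encoder toward
trivially-predictable codes and collapsed both reconstruction and
conditional generation, so the detached two-stage reading is the desk
default. After the joint epochs, an optional refinement stage
(`diffusion_refine_epochs`) continues training the UNet alone on the
frozen, exactly-standardized latents — cheap epochs that noticeably
sharpen conditional sampling.

Optimization is AdamW under cosine annealing. One global seed fans out
to named substreams (init, shuffle, label dropout, diffusion-t,
sampling...), so toggling one stochastic stage never perturbs another,
and every pipeline output is bit-reproducible from (config, seed,
inputs). Training aborts with a diagnostic naming the offending term if
any loss goes non-finite. Parameters are float32 by default (float64 is
used wherever gradients are finite-difference-checked).

## Configuration profiles

| parameter | `paper` | `desk` |
|---|---|---|
| embedding / model dim | 100 / 200 | 32 / 64 |
| heads / layers | 4 / 6 | 4 / 2 |
| latent dim | 64 | 16 |
| decoder conv layers | 4 | 3 |
| diffusion steps T | 500 | 100 |
| β range | 1e-4 – 0.02 | 1e-3 – 0.2 (1000/T rescale) |
| lr (cosine start) | 2e-5 | 2e-3 |
| batch / epochs | 512 / 500 | 128 / 60 (+40 refine) |

The `paper` profile preserves the published full-scale settings and is
not exercised by the tests. The `desk` profile is sized for a single
CPU core: the full study (train + generate + evaluate) runs in about
six minutes. Desk training uses 60 epochs rather than a stricter 50
because the loss curves at feasible float32 learning rates are still
visibly descending at 50; the 40 refinement epochs cost a fraction of a
joint epoch each.

## Synthetic families

The generator emulates the *shape* of a deep-mutational-scanning (DMS)
dataset so the whole pipeline is testable without downloads:

- **Sequences.** Column-independent draws from an L × 20
  position-weight matrix. A chosen subset of columns is near-delta
  (probability 0.96 on one residue — strictly conserved sites); the
  rest are symmetric Dirichlet draws. The default concentration 0.03
  yields ≈ 5–6 substitutions from the modal (wild-type) sequence per
  30-mer, matching the few-percent per-position variability of real
  mutational scans. An optional coupled column pair (the second column
  copies the first 80% of the time) exercises the pairwise-frequency
  metric, and optional suffix truncation emulates indel sets.
- **Fitness.** Additive over (position, residue): the wild-type residue
  of each column scores 0, substitutions score −|N(0,1)| with a 10%
  chance of a small beneficial +0.3·|N(0,1)|, plus N(0, 0.5²)
  measurement noise. This mirrors measured DMS effect distributions
  (mostly deleterious, rare mild gains) and gives the landscape an
  interior optimum at/near the wild type — without it, an additive
  landscape grows without bound away from the family and the
  diversity/fidelity trade-off of guidance cannot exist. Labels come
  from uniform 8-bin discretization of the observed fitness range (the
  top boundary closes into the last bin).

What the generator does **not** emulate: epistasis (columns are
independent, so entropy and pairwise statistics have analytic
expectations), phylogenetic correlation between sequences, real
amino-acid substitution preferences, and alignment uncertainty. Passing
tests therefore demonstrate that the machinery recovers planted
structure under these idealized conditions, not performance on real
proteins.

## Evaluation metrics

- **Conservation entropy.** Per-column Shannon entropy in base 20 on a
  gap-filtered alignment (columns with > 75% gaps removed; pads count
  as gaps). Residual gaps are excluded from the column frequencies and
  the remainder renormalized, which keeps the value in [0, 1]; all-gap
  columns report 0 with a flag. Profiles are compared by positional MSE
  and Pearson correlation.
- **Pairwise frequency correlation.** For each sequence, an L × L
  matrix whose (i, j) cell is the frequency of that sequence's ordered
  residue pair at positions (i, j) within its own set; the flattened
  matrices are averaged over sequences and the two sets' mean vectors
  Pearson-correlated. (The per-cell content of this construction is
  ambiguous in the source description; this reading is brute-force
  tested.)
- **Identity.** Aligned mode: matching positions / compared positions ×
  100, pads ignored. Global mode: matches over alignment length of a
  global alignment (match 1, mismatch 0, gap −1, via Biopython's
  PairwiseAligner).
- **Diversity.** Greedy incremental clustering: sequences visited
  longest-first (ties lexicographic), each joins the first cluster
  whose founder is at least the identity threshold away, else founds
  one. Cluster count per threshold is the diversity value.
- **Minimum Hamming distance.** Per generated sequence, the minimum
  normalized mismatch fraction against the reference set, pads compared
  as ordinary symbols.
- **Recon KL.** KL(generated ‖ reference) between aggregate 20-residue
  compositions with additive pseudocount 1 — directional by
  construction (guarded by a test).
- **Instability index.** Guruprasad dipeptide-weight sum, 10/L ×
  Σ DIWV(x_i, x_{i+1}); < 40 flags a predicted-stable protein. The
  published weight table is bundled; agreement with an independent
  implementation is tested to 1e-6.

## Design choices where the source was open

- **Fitness trajectories** (regressor predictions along the denoising
  process) use the predicted-z0 convention: at snapshot time the
  current noise estimate is inverted through the forward marginal,
  ẑ₀ = (z_t − √(1−ᾱ_t)·ε̂)/√ᾱ_t, and the regressor scores ẑ₀. This
  gives a converging fan (early estimates highly dispersed, late ones
  settled) and keeps the regressor input on the scale it was fitted
  on. The final trajectory column equals the prediction on the fully
  denoised code.
- **Scoring generated sequences.** `GenerationResult.predicted_fitness`
  applies the regressor to the sampled latent directly. For
  out-of-distribution sampling (large ω) that latent leaves the domain
  the regressor was fitted on and its ReLU extrapolation is
  unbounded; the calibrated measure of a *design's* fitness is
  `predict_sequence_fitness`, which re-encodes the decoded sequence
  first. On synthetic families the re-encoded prediction tracks the
  true additive fitness to within ~0.1 at moderate ω.
- **Unsupervised runs** regress onto the constant 0 (keeping the loss
  bounded) rather than disabling the regressor; label 0 is used for
  training while the guidance null identifier ∅ remains a distinct
  code.
- **Bottleneck** is a single linear layer (no nonlinearity); the
  padding-invariance property fixed the pooling, and one linear map
  suffices after a mean-pooled representation.
- **Train/validation split** is random by default; an identity-
  threshold strategy (whole greedy clusters assigned to one side) is
  available for redundancy-aware splits.

## Numerical details and limitations

- Tokens use int64; tensors are float32 for training and float64 for
  gradient checking; checkpoints store exact arrays in a
  length-prefixed container that is byte-identical across runs (zip
  formats embed timestamps and are not).
- PCA projections use SVD with a fixed sign convention (the largest-
  magnitude loading of each component is positive), so latent-space
  plots are deterministic.
- The greedy clustering is O(n·k) in identity computations and is meant
  for evaluation-sized sets (hundreds to thousands), not databases.
- The desk-scale model carries a 16-dimensional latent; families much
  more diverse than a mutational scan (per-position substitution rates
  of tens of percent) exceed what that code can represent and
  reconstruction degrades to memorization. Use a larger latent (and
  the `paper` profile dimensions) for homolog-family-scale diversity.
- Decoded sequences may contain pad/gap/unknown symbols anywhere —
  the decoder scores the full vocabulary. Readers admit pad symbols in
  all modes, and the evaluation CLI strips non-residue symbols where a
  metric requires canonical residues (skipping sequences it cannot
  score and reporting the count).
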