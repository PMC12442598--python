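# prolatent

Conditional protein sequence design with a latent denoising diffusion
model over a jointly trained autoencoder.

## The problem

Given a family of protein sequences — optionally annotated with a scalar
fitness such as fluorescence or enzymatic activity from a deep mutational
scan — we want to (i) generate new sequences that look like the family
(conservation pattern, residue composition, pairwise structure), (ii)
generate sequences conditioned on a *target fitness range*, and (iii)
deliberately sample outside the training distribution to search for
unusual variants, with an explicit knob trading diversity against
fidelity.

`prolatent` is aimed at protein-engineering practitioners who want a
CPU-trainable, fully reproducible implementation of this design recipe,
plus the sequence statistics needed to judge the output.

## The model

Three components are trained together:

1. **Jointly trained autoencoder (JT-AE).** A transformer encoder
   f_θ maps a tokenized sequence x to a latent code z = f_θ(x) (pad
   positions are masked out of attention and pooling). A 1-D
   convolutional decoder g_θ reconstructs per-position residue scores
   from z, and an MLP regressor h_θ predicts fitness y from the same z,
   so the latent space organizes by sequence *and* function.

2. **Latent DDPM.** A forward chain q(z_t | z_{t-1}) =
   N(√(1−β_t) z_{t-1}, β_t I), t = 1..T, noises the (standardized)
   latent codes; a 1-D convolutional UNet ε_θ(z_t, t, c) is trained to
   predict the injected noise, conditioned on the fitness-bin label c
   (fitness is uniformly divided into 8 bins; unsupervised runs use
   label 0). The reverse (ancestral) step is

       z_{t-1} = (z_t − β_t/√(1−ᾱ_t) · ε̂) / √α_t + σ_t γ,   γ ~ N(0, I)

   with ᾱ_t = Π_{s≤t} α_s and σ_1 = 0.

3. **Classifier-free guidance.** During training the label is dropped to
   a null identifier ∅ with probability p_uncond; at sampling time the
   noise estimate is ε̃ = (1+ω) ε_θ(z_t, t, c) − ω ε_θ(z_t, t, ∅).
   ω = 0 is purely conditional sampling; large ω pushes samples outside
   the training distribution ("outlier design").

The joint objective is reconstruction cross-entropy + fitness squared
error + the diffusion noise-matching loss.

All neural components run on a small numpy reverse-mode autodiff engine
(`prolatent.nn`) that is finite-difference-checked in the test suite; no
GPU or deep-learning framework is required.

## Worked example

Sample a synthetic mutational-scanning-style family (position-weight-
matrix columns, additive fitness, 8 uniform fitness bins) and train the
desk-scale profile:

```bash
$ prolatent synth --length 30 --n-conserved 8 --n 2000 --seed 1 --out-prefix family
{"event": "synth", "n": 2000, "max_length": 30, "out_prefix": "family"}

$ head -2 family.fasta
>syn00000
EEYTDNMWYRTAIFMNTYDTFWIDWCGCVA

$ prolatent train --fasta family.fasta --fitness family.csv --seed 1 --out model.ckpt
$ prolatent sample --ckpt model.ckpt --label 7 --omega 1.0 --n 64 --seed 2 --out designs.fasta
$ prolatent eval --generated designs.fasta --reference family.fasta \
      --metrics entropy,kl,hamming --out report.json
```

`designs.fasta.csv` carries the regressor's predicted fitness per design;
`report.json` contains the conservation-entropy agreement (per-column
Shannon entropy in base 20, gap-filtered), the composition KL divergence
and the minimum-Hamming diversity of the designs against the family.

On this family (seed 1) the trained desk profile reaches, on held-out
sequences, reconstruction token accuracy **0.92** and Spearman
correlation **0.92** between predicted and true fitness; the mean
predicted fitness of generated sequences is perfectly ordered by the
conditioning label (Spearman 1.0 over the 8 bins), and the per-position
entropy profile of 500 unconditional samples correlates with the
training profile at Pearson r = **0.98**. Sweeping ω over
{0.1, 1, 5, 20} moves the mean minimum Hamming distance of the designs
from 0.05 to 0.26 while their (re-encoded) predicted fitness falls from
−0.00 to −1.67 — the diversity/fidelity trade-off the guidance strength
controls.

## Library surface

```python
import prolatent as pl

run  = pl.validate_config({"profile": "desk"})
spec = pl.make_family_spec(seed=1)              # synthetic family definition
data = pl.sample_family(spec, 2000, seed=1)     # SequenceDataset with labels
ckpt = pl.train(data, run.jtae, run.diffusion, run.train)
res  = pl.generate_sequences(ckpt, label=7, omega=1.0, n=64, seed=2,
                             trajectory_every=10)
```

`res.trajectory` traces the regressor prediction along the denoising
process (predicted-z0 convention); `prolatent.evaluate` exposes the full
metric suite (entropy profiles, logo matrices, pairwise-frequency
correlation, identity, diversity clustering, Recon-KL, minimum Hamming,
Guruprasad instability index).

Two configuration profiles ship with the package: `paper` (embedding
100, model dim 200, 4 heads / 6 layers, 64-D latent, T = 500, lr 2e-5,
batch 512, 500 epochs) and `desk` (the CPU-scale defaults used in the
tests; see `docs/methods.md`).

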