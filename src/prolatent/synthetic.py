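"""Synthetic PWM-defined protein families with additive fitness.

Emulates the shape of a deep-mutational-scanning dataset: a family of
related sequences drawn column-independently from a position weight matrix
(PWM), a subset of strongly conserved columns, and a scalar fitness that is
additive over (position, residue) contributions plus Gaussian measurement
noise.  Because generation is column-independent, conservation-entropy and
pairwise-frequency statistics of a sampled family have analytic
expectations, which the test suite exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._rng import substream
from .seqdata import (Alphabet, SequenceDataset, SequenceRecord, assign_labels,
                      write_fasta, write_fitness_table)

#: Default family conditions: a short, well-conserved family of the size a
#: desk-scale mutational-scanning study would have.
DEFAULT_LENGTH = 30
DEFAULT_N_CONSERVED = 8
DEFAULT_CONCENTRATION = 0.03
DEFAULT_NOISE_SD = 0.5


@dataclass
class SyntheticFamilySpec:
    """Fully deterministic description of one synthetic family."""

    length: int
    pwm: np.ndarray                    # (L, 20), column-stochastic (rows sum to 1)
    conserved_positions: np.ndarray    # indices with near-delta columns
    fitness_weights: np.ndarray        # (L, 20) additive contributions
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    coupled_pair: tuple[int, int] | None = None  # optional correlated column pair
    alphabet: Alphabet = field(default_factory=Alphabet)

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        self.fitness_weights = np.asarray(self.fitness_weights, dtype=float)
        if self.pwm.shape != (self.length, 20):
            raise ValueError("pwm must have shape (length, 20)")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("pwm rows must sum to 1")
        if self.fitness_weights.shape != (self.length, 20):
            raise ValueError("fitness_weights must have shape (length, 20)")

    def column_entropy(self) -> np.ndarray:
        """Shannon entropy (base 20) of each PWM column."""
        p = np.clip(self.pwm, 1e-300, None)
        return -(self.pwm * np.log(p) / np.log(20.0)).sum(axis=1)


def make_family_spec(length: int = DEFAULT_LENGTH,
                     n_conserved: int = DEFAULT_N_CONSERVED,
                     concentration: float = DEFAULT_CONCENTRATION,
                     seed: int = 0,
                     noise_sd: float = DEFAULT_NOISE_SD,
                     coupled_pair: tuple[int, int] | None = None
                     ) -> SyntheticFamilySpec:
    """Draw a reproducible family spec.

    Variable columns are symmetric Dirichlet(concentration) draws over the 20
    residues; ``n_conserved`` randomly chosen columns are near-delta (one
    residue at probability 0.96, the rest uniform).  Fitness weights follow
    the shape of measured mutational-scanning effect distributions: the
    wild-type (modal) residue of each column scores 0, substitutions are
    mostly deleterious (-|N(0,1)|) with a 10% chance of a small beneficial
    effect (+0.3|N(0,1)|), so the fitness landscape peaks at/near the wild
    type rather than growing without bound away from the family.
    """
    if not 0 <= n_conserved <= length:
        raise ValueError("need 0 <= n_conserved <= length")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = substream(seed, "family-spec")
    pwm = rng.dirichlet(np.full(20, concentration), size=length)
    conserved = np.sort(rng.choice(length, size=n_conserved, replace=False))
    for pos in conserved:
        top = rng.integers(20)
        col = np.full(20, 0.04 / 19)
        col[top] = 0.96
        pwm[pos] = col
    magnitudes = np.abs(rng.standard_normal((length, 20)))
    beneficial = rng.random((length, 20)) < 0.1
    weights = np.where(beneficial, 0.3 * magnitudes, -magnitudes)
    weights[np.arange(length), pwm.argmax(axis=1)] = 0.0
    return SyntheticFamilySpec(length=length, pwm=pwm,
                               conserved_positions=conserved,
                               fitness_weights=weights, noise_sd=noise_sd,
                               seed=seed, coupled_pair=coupled_pair)


def true_fitness(sequence: str, spec: SyntheticFamilySpec) -> float:
    """Noiseless additive fitness of one sequence under the spec."""
    if len(sequence) != spec.length:
        raise ValueError(f"sequence length {len(sequence)} != spec length {spec.length}")
    idx = [spec.alphabet.index_of(ch) for ch in sequence]
    if any(i >= 20 for i in idx):
        raise ValueError("true_fitness requires canonical residues only")
    return float(spec.fitness_weights[np.arange(spec.length), idx].sum())


def sample_family(spec: SyntheticFamilySpec, n: int, seed: int = 0,
                  n_bins: int = 8, truncate_fraction: float = 0.0
                  ) -> SequenceDataset:
    """Sample ``n`` sequences column-independently from the PWM.

    Fitness = additive true fitness + N(0, noise_sd); labels come from
    uniform binning into ``n_bins`` bins.  If ``coupled_pair`` is set on the
    spec, the second column of the pair copies the first one's residue 80% of
    the time, giving the family one strongly correlated position pair.
    ``truncate_fraction`` optionally drops a random suffix of up to that
    fraction of positions per sequence (indel emulation; padding restores a
    common tokenized length downstream).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = substream(seed ^ (spec.seed << 1), "family-sample")
    L = spec.length
    # inverse-CDF sampling per column, vectorized over sequences
    cdf = np.cumsum(spec.pwm, axis=1)
    u = rng.random((n, L))
    codes = (u[:, :, None] > cdf[None, :, :]).sum(axis=2)
    codes = np.minimum(codes, 19)
    if spec.coupled_pair is not None:
        i, j = spec.coupled_pair
        copy = rng.random(n) < 0.8
        codes[copy, j] = codes[copy, i]
    residue_str = spec.alphabet.residues
    noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else np.zeros(n)

    records = []
    fits = np.empty(n)
    for k in range(n):
        seq = "".join(residue_str[c] for c in codes[k])
        fit = true_fitness(seq, spec) + noise[k]
        if truncate_fraction > 0:
            keep = L - int(rng.integers(0, int(truncate_fraction * L) + 1))
            seq = seq[:keep]
        records.append(SequenceRecord(f"syn{k:05d}", seq, fitness=float(fit)))
        fits[k] = fit
    ds = SequenceDataset(records, spec.alphabet, n_bins=n_bins)
    if n > 0:
        labels, binning = assign_labels(fits, n_bins)
        for rec, lab in zip(ds.records, labels):
            rec.label = int(lab)
        ds.binning = binning
    return ds


def write_family(spec: SyntheticFamilySpec, n: int, seed: int,
                 out_prefix: str | Path, n_bins: int = 8) -> SequenceDataset:
    """Sample a family and write ``<prefix>.fasta`` + ``<prefix>.csv``.

    Files go through the public writers so synthetic data re-enters the tool
    via the same readers as real data.
    """
    ds = sample_family(spec, n, seed=seed, n_bins=n_bins)
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_fasta(ds, prefix.with_suffix(".fasta"))
    write_fitness_table(ds, prefix.with_suffix(".csv"))
    return ds


def spec_to_dict(spec: SyntheticFamilySpec) -> dict:
    return {"length": spec.length, "pwm": spec.pwm.tolist(),
            "conserved_positions": spec.conserved_positions.tolist(),
            "fitness_weights": spec.fitness_weights.tolist(),
            "noise_sd": spec.noise_sd, "seed": spec.seed,
            "coupled_pair": list(spec.coupled_pair) if spec.coupled_pair else None}


def spec_from_dict(d: dict) -> SyntheticFamilySpec:
    return SyntheticFamilySpec(
        length=d["length"], pwm=np.array(d["pwm"]),
        conserved_positions=np.array(d["conserved_positions"], dtype=int),
        fitness_weights=np.array(d["fitness_weights"]),
        noise_sd=d.get("noise_sd", DEFAULT_NOISE_SD), seed=d.get("seed", 0),
        coupled_pair=tuple(d["coupled_pair"]) if d.get("coupled_pair") else None)
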