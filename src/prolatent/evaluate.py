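"""Sequence-statistics suite for judging generated protein sets.

Conservation entropy profiles of alignments, logo frequency matrices,
pairwise amino-acid frequency correlation, sequence identity, minimum
Hamming distance to a reference set, aggregate-composition KL divergence,
identity-threshold diversity clustering, and the Guruprasad instability
index.  All metrics are deterministic and have brute-force oracles on
small inputs in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._diwv import DIWV
from .seqdata import Alphabet, SequenceDataset

_LOG20 = np.log(20.0)


class MetricError(ValueError):
    pass


def _char_matrix(sequences: list[str]) -> np.ndarray:
    lengths = {len(s) for s in sequences}
    if len(lengths) > 1:
        raise MetricError("rows of an alignment must have equal length")
    return np.array([list(s) for s in sequences], dtype="<U1")


@dataclass
class MSAProfile:
    """An alignment with high-gap columns (gap fraction > threshold) removed.

    Pad symbols are treated like gaps for the purposes of column filtering
    and frequency estimation.
    """

    sequences: list[str]
    gap_threshold: float = 0.75
    alphabet: Alphabet = field(default_factory=Alphabet)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise MetricError("alignment needs at least one row")
        self.matrix = _char_matrix([s.upper() for s in self.sequences])
        gap_like = (self.matrix == self.alphabet.gap_symbol) | \
                   (self.matrix == self.alphabet.pad_symbol)
        self.column_gap_fraction = gap_like.mean(axis=0)
        self.kept_columns = np.flatnonzero(
            self.column_gap_fraction <= self.gap_threshold)

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def column_frequencies(self) -> np.ndarray:
        """(n_kept, 20) frequencies over canonical residues per kept column.

        Non-residue symbols (gap, pad, unknown) are excluded and the
        remainder renormalized; all-gap columns give a zero row.
        """
        res = np.array(list(self.alphabet.residues), dtype="<U1")
        cols = self.matrix[:, self.kept_columns]
        counts = (cols[:, :, None] == res[None, None, :]).sum(axis=0).astype(float)
        totals = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(totals > 0, counts / totals, 0.0)
        return freq


def entropy_profile(msa: MSAProfile) -> tuple[np.ndarray, np.ndarray]:
    """Per-kept-column Shannon entropy in base 20, in [0, 1].

    0 marks a fully conserved column, 1 a column uniform over the 20 amino
    acids.  Returns (entropies, all_gap_flags); columns empty after gap
    removal report 0 with their flag set.
    """
    freq = msa.column_frequencies()
    p = np.where(freq > 0, freq, 1.0)
    se = -(freq * np.log(p) / _LOG20).sum(axis=1)
    empty = freq.sum(axis=1) == 0
    return np.where(empty, 0.0, se), empty


def entropy_compare(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Positional mean squared error and Pearson r of two entropy profiles."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise MetricError("profiles must have equal kept-column counts")
    mse = float(((a - b) ** 2).mean())
    if np.std(a) == 0 or np.std(b) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    return mse, r


def logo_matrix(msa: MSAProfile) -> np.ndarray:
    """Kept-column x 20 residue frequency matrix (rows sum to 1 or 0)."""
    return msa.column_frequencies()


def pairfreq_matrices(msa: MSAProfile) -> np.ndarray:
    """Per-sequence pairwise residue co-occurrence frequencies, (n, L*L).

    For sequence s, cell (i, j) holds the frequency within the alignment of
    the ordered residue pair (s_i, s_j) at positions (i, j) — how common
    that sequence's own pair choice is in the set.  Matrices are flattened
    row-wise.
    """
    cols = msa.matrix[:, msa.kept_columns]
    n, L = cols.shape
    _, inv = np.unique(cols, return_inverse=True)
    codes = inv.reshape(n, L)
    K = codes.max() + 1
    out = np.empty((n, L * L))
    for i in range(L):
        for j in range(L):
            pair = codes[:, i] * K + codes[:, j]
            counts = np.bincount(pair, minlength=K * K)
            out[:, i * L + j] = counts[pair] / n
    return out


def pairfreq_correlation(msa_a: MSAProfile, msa_b: MSAProfile) -> float:
    """Pearson correlation of mean pairwise co-occurrence structure."""
    if len(msa_a.kept_columns) != len(msa_b.kept_columns):
        raise MetricError("alignments must share their kept-column count")
    va = pairfreq_matrices(msa_a).mean(axis=0)
    vb = pairfreq_matrices(msa_b).mean(axis=0)
    if np.std(va) == 0 or np.std(vb) == 0:
        return 1.0 if np.allclose(va, vb) else float("nan")
    return float(np.corrcoef(va, vb)[0, 1])


def sequence_identity(a: str, b: str, mode: str = "aligned",
                      alphabet: Alphabet | None = None) -> float:
    """Percent identity between two sequences.

    ``aligned``: same-length comparison; positions where either side is a
    pad symbol are ignored.  ``global``: identity over the alignment length
    of a global alignment (match 1, mismatch 0, gap -1).
    """
    if not a or not b:
        raise MetricError("empty sequence")
    alphabet = alphabet or Alphabet()
    if mode == "aligned":
        if len(a) != len(b):
            raise MetricError("aligned mode requires equal lengths")
        pad = alphabet.pad_symbol
        pairs = [(x, y) for x, y in zip(a, b) if x != pad and y != pad]
        if not pairs:
            return 0.0
        matches = sum(x == y for x, y in pairs)
        return 100.0 * matches / len(pairs)
    if mode == "global":
        from Bio import Align
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = 0
        aligner.open_gap_score = -1
        aligner.extend_gap_score = -1
        aln = aligner.align(a.rstrip(alphabet.pad_symbol),
                            b.rstrip(alphabet.pad_symbol))[0]
        sa, sb = aln[0], aln[1]
        matches = sum(x == y and x != "-" for x, y in zip(sa, sb))
        return 100.0 * matches / len(sa)
    raise ValueError(f"unknown identity mode {mode!r}")


def _padded_code_matrix(seqs: list[str], alphabet: Alphabet,
                        length: int | None = None) -> np.ndarray:
    L = length if length is not None else max(len(s) for s in seqs)
    out = np.full((len(seqs), L), alphabet.pad_code, dtype=np.int16)
    for k, s in enumerate(seqs):
        for i, ch in enumerate(s):
            out[k, i] = alphabet.index_of(ch)
    return out


def min_hamming(generated: SequenceDataset | list[str],
                reference: SequenceDataset | list[str],
                alphabet: Alphabet | None = None
                ) -> tuple[float, float, np.ndarray]:
    """Minimum normalized Hamming distance of each generated sequence.

    All sequences are padded to a common length and pads compared as
    ordinary symbols; distance is mismatches/length, minimized over the
    reference set.  Returns (mean, sd, per-sequence distances).
    """
    gen = generated.sequences() if isinstance(generated, SequenceDataset) else list(generated)
    ref = reference.sequences() if isinstance(reference, SequenceDataset) else list(reference)
    if not ref:
        raise MetricError("empty reference set")
    if not gen:
        raise MetricError("empty generated set")
    alphabet = alphabet or (generated.alphabet if isinstance(generated, SequenceDataset)
                            else Alphabet())
    L = max(max(len(s) for s in gen), max(len(s) for s in ref))
    G = _padded_code_matrix(gen, alphabet, L)
    R = _padded_code_matrix(ref, alphabet, L)
    dists = np.empty(len(gen))
    block = max(1, 10_000_000 // (R.shape[0] * L + 1))
    for start in range(0, len(gen), block):
        sub = G[start:start + block]
        mism = (sub[:, None, :] != R[None, :, :]).sum(axis=2)
        dists[start:start + block] = mism.min(axis=1) / L
    return float(dists.mean()), float(dists.std()), dists


def recon_kl(generated: SequenceDataset | list[str],
             reference: SequenceDataset | list[str],
             pseudocount: float = 1.0,
             alphabet: Alphabet | None = None) -> float:
    """KL(generated || reference) between aggregate residue compositions.

    Counts are over the 20 canonical residues only (pads/gaps/unknowns
    excluded), smoothed additively by ``pseudocount`` before normalizing.
    """
    gen = generated.sequences() if isinstance(generated, SequenceDataset) else list(generated)
    ref = reference.sequences() if isinstance(reference, SequenceDataset) else list(reference)
    if not gen or not ref:
        raise MetricError("both sequence sets must be nonempty")
    alphabet = alphabet or Alphabet()

    def counts(seqs: list[str]) -> np.ndarray:
        c = np.zeros(20)
        for s in seqs:
            for ch in s:
                i = alphabet.symbols.find(ch)
                if 0 <= i < 20:
                    c[i] += 1
        return c

    p = counts(gen) + pseudocount
    q = counts(ref) + pseudocount
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))


def greedy_identity_clusters(seqs: list[str], threshold: float,
                             alphabet: Alphabet | None = None
                             ) -> list[list[int]]:
    """Greedy incremental clustering by identity to cluster representatives.

    Sequences are visited longest-first (ties lexicographic); each joins the
    first existing cluster whose *representative* (founder) has identity >=
    threshold (aligned mode when lengths match, global otherwise), else it
    founds a new cluster.  Returns member indices per cluster.
    """
    alphabet = alphabet or Alphabet()
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), seqs[i]))
    clusters: list[list[int]] = []
    reps: list[str] = []
    for i in order:
        s = seqs[i]
        for c, rep in enumerate(reps):
            mode = "aligned" if len(rep) == len(s) else "global"
            if sequence_identity(s, rep, mode=mode, alphabet=alphabet) >= threshold:
                clusters[c].append(i)
                break
        else:
            clusters.append([i])
            reps.append(s)
    return clusters


def diversity_curve(seqs: SequenceDataset | list[str],
                    thresholds: list[float],
                    alphabet: Alphabet | None = None) -> dict[float, int]:
    """Cluster count at each identity threshold (higher = more diverse)."""
    sequences = seqs.sequences() if isinstance(seqs, SequenceDataset) else list(seqs)
    if not sequences:
        raise MetricError("empty sequence set")
    if any(not 0 < t <= 100 for t in thresholds):
        raise MetricError("thresholds must lie in (0, 100]")
    alphabet = alphabet or (seqs.alphabet if isinstance(seqs, SequenceDataset)
                            else Alphabet())
    return {t: len(greedy_identity_clusters(sequences, t, alphabet))
            for t in thresholds}


def instability_index(seq: str) -> float:
    """Guruprasad instability index: (10/L) * sum of dipeptide weights.

    A value below 40 predicts an in-vivo stable protein.
    """
    seq = seq.upper()
    if len(seq) < 2:
        raise MetricError("instability index needs length >= 2")
    try:
        total = sum(DIWV[a][b] for a, b in zip(seq, seq[1:]))
    except KeyError as exc:
        raise MetricError(f"non-canonical residue {exc.args[0]!r}") from exc
    return 10.0 / len(seq) * total


def is_stable(seq: str) -> bool:
    return instability_index(seq) < 40.0


def aa_embedding_correlation(ckpt, dataset: SequenceDataset,
                             n_sample: int = 64, seed: int = 0
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Amino-acid similarity structure learned by the decoder.

    Random sequences are encoded and decoded; their per-position residue
    likelihood matrices (20 x L) are averaged, rows are correlated pairwise
    (20 x 20 Pearson matrix) and projected to 2-D by PCA, mirroring the
    visual check that biochemically similar residues cluster.
    """
    from .generate import project_latents
    from .nn import softmax

    if not ckpt.loss_log:
        warnings.warn("checkpoint carries no training log; embeddings may be random")
    rng = np.random.default_rng(seed)
    n = min(n_sample, len(dataset))
    if n == 0:
        raise MetricError("empty dataset")
    idx = rng.choice(len(dataset), size=n, replace=False)
    tokens = dataset.subset(idx).tokens(ckpt.max_length)
    ckpt.model.eval()
    z = ckpt.model.encode(tokens)
    scores = ckpt.model.decode_scores(z)
    probs = softmax(scores, axis=-1).data[:, :, :20]      # (B, L, 20)
    mean_embed = probs.mean(axis=0).T                      # (20, L)
    corr = np.corrcoef(mean_embed)
    proj, _ = project_latents(mean_embed, n_components=2)
    return corr, proj
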