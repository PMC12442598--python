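"""Sequence containers, tokenization and fitness-label binning.

Protein sequences are handled as strings over the 20 canonical amino acids
plus three reserved symbols (pad, gap, unknown).  Unequal-length sets are
right-padded to the longest member, mirroring the usual treatment of
unaligned family datasets; fitness values travel either in a CSV/TSV sidecar
(canonical) or in a ``>id|fitness=<float>`` header dialect.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


class SequenceDataError(ValueError):
    """Raised on malformed sequence input (bad symbol, duplicate id, ...)."""


@dataclass(frozen=True)
class Alphabet:
    """Bijection between sequence symbols and integer codes.

    The 20 canonical residues take codes ``0..19``; pad, gap and unknown are
    distinct reserved codes appended after them.
    """

    residues: str = CANONICAL_RESIDUES
    pad_symbol: str = "."
    gap_symbol: str = "-"
    unknown_symbol: str = "X"

    def __post_init__(self) -> None:
        if len(self.residues) != 20 or len(set(self.residues)) != 20:
            raise ValueError("alphabet must contain exactly 20 distinct residues")
        reserved = {self.pad_symbol, self.gap_symbol, self.unknown_symbol}
        if len(reserved) != 3 or reserved & set(self.residues):
            raise ValueError("pad/gap/unknown symbols must be distinct non-residues")

    @property
    def pad_code(self) -> int:
        return 20

    @property
    def gap_code(self) -> int:
        return 21

    @property
    def unknown_code(self) -> int:
        return 22

    @property
    def size(self) -> int:
        """Total vocabulary size (residues + reserved symbols)."""
        return 23

    @property
    def symbols(self) -> str:
        return self.residues + self.pad_symbol + self.gap_symbol + self.unknown_symbol

    def index_of(self, symbol: str) -> int:
        idx = self.symbols.find(symbol)
        if idx < 0:
            raise SequenceDataError(f"symbol {symbol!r} not in alphabet")
        return idx

    def symbol_of(self, code: int) -> str:
        if not 0 <= code < self.size:
            raise SequenceDataError(f"code {code} out of range")
        return self.symbols[code]

    def is_admissible(self, sequence: str, allow_gap: bool = False) -> bool:
        ok = set(self.residues) | {self.unknown_symbol}
        if allow_gap:
            ok.add(self.gap_symbol)
        return all(ch in ok for ch in sequence)


@dataclass
class SequenceRecord:
    """One protein sequence with optional fitness and label-bin index."""

    id: str
    residues: str
    fitness: float | None = None
    label: int | None = None


@dataclass
class LabelBinning:
    """Uniform partition of a fitness range into ``n_bins`` segments.

    The upper boundary is closed: a fitness equal to ``hi`` falls in the top
    bin.  ``degenerate`` flags the lo == hi case where every label is 0.
    """

    lo: float
    hi: float
    n_bins: int
    degenerate: bool = False

    @property
    def boundaries(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_bins + 1)

    def assign(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.degenerate:
            return np.zeros(values.shape, dtype=int)
        width = (self.hi - self.lo) / self.n_bins
        raw = np.floor((values - self.lo) / width).astype(int)
        return np.clip(raw, 0, self.n_bins - 1)

    def to_dict(self) -> dict:
        return {"lo": self.lo, "hi": self.hi, "n_bins": self.n_bins,
                "degenerate": self.degenerate}

    @classmethod
    def from_dict(cls, d: dict) -> "LabelBinning":
        return cls(**d)


@dataclass
class SequenceDataset:
    """A list of records padded (on tokenization) to a common length."""

    records: list[SequenceRecord] = field(default_factory=list)
    alphabet: Alphabet = field(default_factory=Alphabet)
    n_bins: int = 8
    binning: LabelBinning | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def max_length(self) -> int:
        return max((len(r.residues) for r in self.records), default=0)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def fitness_array(self) -> np.ndarray:
        return np.array([np.nan if r.fitness is None else r.fitness
                         for r in self.records], dtype=float)

    def label_array(self) -> np.ndarray:
        return np.array([0 if r.label is None else r.label for r in self.records],
                        dtype=int)

    def sequences(self) -> list[str]:
        return [r.residues for r in self.records]

    def tokens(self, max_length: int | None = None) -> np.ndarray:
        """Tokenize every record, padded to ``max_length`` (default: longest)."""
        L = self.max_length if max_length is None else max_length
        return np.stack([tokenize(r, self.alphabet, L) for r in self.records]) \
            if self.records else np.zeros((0, L), dtype=np.int64)

    def assign_labels_from_fitness(self, n_bins: int | None = None,
                                   bounds: tuple[float, float] | None = None) -> LabelBinning:
        """Bin every record's fitness in place and remember the binning."""
        nb = self.n_bins if n_bins is None else n_bins
        y = self.fitness_array()
        if np.isnan(y).any():
            raise SequenceDataError("cannot bin labels: some records lack fitness")
        labels, binning = assign_labels(y, nb, bounds)
        for rec, lab in zip(self.records, labels):
            rec.label = int(lab)
        self.n_bins = nb
        self.binning = binning
        return binning

    def subset(self, indices: Iterable[int]) -> "SequenceDataset":
        recs = [replace(self.records[i]) for i in indices]
        return SequenceDataset(recs, self.alphabet, self.n_bins, self.binning)


def tokenize(record: SequenceRecord | str, alphabet: Alphabet,
             max_length: int) -> np.ndarray:
    """Integer-encode one sequence, right-padded with the pad code."""
    seq = record.residues if isinstance(record, SequenceRecord) else record
    if len(seq) > max_length:
        raise SequenceDataError(
            f"sequence of length {len(seq)} exceeds max_length {max_length}")
    out = np.full(max_length, alphabet.pad_code, dtype=np.int64)
    for i, ch in enumerate(seq):
        out[i] = alphabet.index_of(ch)
    return out


def detokenize(codes: Sequence[int], alphabet: Alphabet,
               strip_pad: bool = True) -> str:
    """Invert :func:`tokenize`; trailing pads are stripped by default."""
    syms = [alphabet.symbol_of(int(c)) for c in codes]
    s = "".join(syms)
    if strip_pad:
        s = s.rstrip(alphabet.pad_symbol)
    return s


def assign_labels(fitness_values: Sequence[float], n_bins: int,
                  bounds: tuple[float, float] | None = None
                  ) -> tuple[np.ndarray, LabelBinning]:
    """Uniformly bin fitness values into ``n_bins`` integer labels.

    ``label = clamp(floor((y - lo)/width), 0, n_bins - 1)``; the maximum maps
    into the top bin.  Equal bounds yield all-zero labels with a degeneracy
    flag (and a warning).
    """
    y = np.asarray(fitness_values, dtype=float)
    if y.size == 0:
        raise SequenceDataError("assign_labels: empty input")
    if n_bins < 1:
        raise SequenceDataError("assign_labels: n_bins must be >= 1")
    lo, hi = (float(y.min()), float(y.max())) if bounds is None else map(float, bounds)
    if hi < lo:
        raise SequenceDataError("assign_labels: hi < lo")
    if hi == lo:
        warnings.warn("degenerate fitness range: all labels set to 0")
        binning = LabelBinning(lo, hi, n_bins, degenerate=True)
        return np.zeros(y.shape, dtype=int), binning
    binning = LabelBinning(lo, hi, n_bins)
    return binning.assign(y), binning


def unconditional_labels(n: int) -> np.ndarray:
    """All-zero labels for unsupervised training (label 0 everywhere)."""
    if n < 0:
        raise SequenceDataError("n must be >= 0")
    return np.zeros(n, dtype=int)


# ---------------------------------------------------------------------------
# I/O


def _parse_header_fitness(header: str) -> tuple[str, float | None]:
    if "|fitness=" in header:
        ident, _, val = header.rpartition("|fitness=")
        try:
            return ident, float(val)
        except ValueError as exc:
            raise SequenceDataError(f"bad fitness in header {header!r}") from exc
    return header, None


def read_fitness_table(path: str | Path) -> dict[str, float]:
    """Read an ``id,fitness`` CSV/TSV sidecar into a dict."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    if "id" not in cols or "fitness" not in cols:
        raise SequenceDataError(f"{path}: sidecar needs 'id' and 'fitness' columns")
    ids = df[cols["id"]].astype(str)
    if ids.duplicated().any():
        raise SequenceDataError(f"{path}: duplicate ids in sidecar")
    return dict(zip(ids, df[cols["fitness"]].astype(float)))


def read_fasta(path: str | Path, sidecar: str | Path | None = None,
               alphabet: Alphabet | None = None, gaps: str = "error",
               n_bins: int = 8) -> SequenceDataset:
    """Read a FASTA file (optionally with a fitness sidecar) into a dataset.

    ``gaps`` controls gap symbols in the sequences: ``"error"`` rejects them
    (training sets), ``"keep"`` admits them (aligned/MSA input), ``"pad"``
    rewrites them as pad symbols.
    """
    if gaps not in {"error", "keep", "pad"}:
        raise ValueError("gaps must be one of error/keep/pad")
    alphabet = alphabet or Alphabet()
    fitness_by_id = read_fitness_table(sidecar) if sidecar is not None else {}

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        ident, fit = _parse_header_fitness(rec.id)
        if ident in seen:
            raise SequenceDataError(f"duplicate id {ident!r} in {path}")
        seen.add(ident)
        seq = str(rec.seq).upper()
        if gaps == "pad":
            seq = seq.replace(alphabet.gap_symbol, alphabet.pad_symbol)
        # pad symbols are always admissible: generated sequences may carry them
        ok = set(alphabet.residues) | {alphabet.unknown_symbol,
                                       alphabet.pad_symbol}
        if gaps == "keep":
            ok.add(alphabet.gap_symbol)
        for pos, ch in enumerate(seq):
            if ch not in ok:
                raise SequenceDataError(
                    f"record {ident!r}: inadmissible symbol {ch!r} at position {pos}")
        if ident in fitness_by_id:
            fit = fitness_by_id[ident]
        records.append(SequenceRecord(ident, seq, fitness=fit))

    missing = set(fitness_by_id) - seen
    if missing:
        raise SequenceDataError(
            f"sidecar ids with no FASTA match: {sorted(missing)[:5]}")
    return SequenceDataset(records, alphabet, n_bins=n_bins)


def write_fasta(dataset: SequenceDataset, path: str | Path,
                fitness_in_header: bool = False) -> None:
    recs = []
    for r in dataset.records:
        ident = r.id
        if fitness_in_header and r.fitness is not None:
            ident = f"{r.id}|fitness={r.fitness:g}"
        recs.append(SeqRecord(Seq(r.residues), id=ident, description=""))
    SeqIO.write(recs, str(path), "fasta")


def write_fitness_table(dataset: SequenceDataset, path: str | Path) -> None:
    df = pd.DataFrame({"id": dataset.ids, "fitness": dataset.fitness_array()})
    df.to_csv(path, index=False)


def write_manifest(dataset: SequenceDataset, path: str | Path) -> None:
    """JSON manifest: ids, bin count and (if set) the fitness binning."""
    doc = {"ids": dataset.ids, "n_bins": dataset.n_bins,
           "max_length": dataset.max_length,
           "binning": dataset.binning.to_dict() if dataset.binning else None}
    Path(path).write_text(json.dumps(doc, indent=2))


# ---------------------------------------------------------------------------
# Train/validation splitting


def train_val_split(dataset: SequenceDataset, val_fraction: float = 0.1,
                    seed: int = 0, strategy: str = "random",
                    identity_threshold: float = 70.0
                    ) -> tuple[SequenceDataset, SequenceDataset]:
    """Split a dataset for training/validation.

    ``random`` shuffles with the seed.  ``identity`` first clusters at the
    given identity threshold (greedy, same procedure as the diversity metric)
    and assigns whole clusters to one side, so near-duplicates never straddle
    the split.
    """
    n = len(dataset)
    if n < 2:
        raise SequenceDataError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    n_val = max(1, int(round(val_fraction * n)))
    if strategy == "random":
        order = rng.permutation(n)
    elif strategy == "identity":
        from .evaluate import greedy_identity_clusters
        L = dataset.max_length
        padded = [r.residues.ljust(L, dataset.alphabet.pad_symbol)
                  for r in dataset.records]
        clusters = greedy_identity_clusters(padded, identity_threshold)
        cluster_order = rng.permutation(len(clusters))
        order = np.array([i for c in cluster_order for i in clusters[c]])
    else:
        raise ValueError(f"unknown split strategy {strategy!r}")
    val_idx, train_idx = order[:n_val], order[n_val:]
    return dataset.subset(train_idx), dataset.subset(val_idx)
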