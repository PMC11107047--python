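"""Canonical k-mer counting, count-matrix construction, recurrence filtering
and reference masking.

Strand is collapsed throughout: every k-mer is represented by its canonical
form, the lexicographic minimum of the k-mer and its reverse complement.
This is the right representation for unstranded RNA-seq libraries, where a
read and its reverse complement are indistinguishable.

Internally k-mers are packed 2 bits/base into uint64 (k <= 31); with the
encoding A=0 < C=1 < G=2 < T=3, integer order on packed k-mers equals
lexicographic order on the strings, so the canonical form and the sorted
row order of the count matrix can both be computed on the packed values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as kio

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

# byte -> 2-bit code; anything outside ACGT (upper or lower) maps to 4 = invalid
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    """Canonical (strand-collapsed) form: min(kmer, revcomp(kmer)).

    Raises ValueError on non-ACGT characters so the caller can decide the
    skip policy; idempotent.
    """
    if any(c not in "ACGT" for c in kmer):
        raise ValueError(f"non-ACGT character in k-mer {kmer!r}")
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def encode_canonical(seq: str, k: int) -> np.ndarray:
    """Packed canonical hashes of every valid k-window of ``seq``.

    Windows containing any non-ACGT character are skipped. Returns a uint64
    array in window order.
    """
    if not 2 <= k <= 31:
        raise ValueError("k must be in [2, 31] for 2-bit packing")
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = codes.size
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64)
    valid = codes < 4
    safe = np.where(valid, codes, 0).astype(np.uint64)
    comp = np.uint64(3) - safe
    two = np.uint64(2)
    fwd = np.zeros(m, dtype=np.uint64)
    rc = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << two) | safe[j : j + m]
        rc = (rc << two) | comp[k - 1 - j : k - 1 - j + m]
    bad = np.cumsum(np.concatenate(([0], (~valid).astype(np.int64))))
    window_ok = (bad[k:][:m] - bad[:m]) == 0
    return np.minimum(fwd, rc)[window_ok]


def hashes_to_kmers(hashes, k: int) -> list:
    """Decode packed k-mer hashes back to strings."""
    h = np.asarray(hashes, dtype=np.uint64)
    chars = np.empty((h.size, k), dtype=np.uint8)
    for j in range(k):
        chars[:, k - 1 - j] = _BASES[(h >> np.uint64(2 * j)) & np.uint64(3)]
    raw = chars.tobytes()
    return [raw[i * k : (i + 1) * k].decode("ascii") for i in range(h.size)]


def kmers_to_hashes(kmers, k: int) -> np.ndarray:
    """Packed hashes of already-canonical k-mer strings, in input order."""
    kmers = list(kmers)
    if not kmers:
        return np.empty(0, dtype=np.uint64)
    joined = "N".join(kmers)
    codes = _CODE[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)]
    starts = np.arange(len(kmers)) * (k + 1)
    safe = np.where(codes < 4, codes, 0).astype(np.uint64)
    two = np.uint64(2)
    out = np.zeros(len(kmers), dtype=np.uint64)
    for j in range(k):
        out = (out << two) | safe[starts + j]
    return np.minimum(out, _revcomp_hashes(out, k))


def _revcomp_hashes(h: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros_like(h)
    two = np.uint64(2)
    v = h.copy()
    for _ in range(k):
        out = (out << two) | (np.uint64(3) - (v & np.uint64(3)))
        v >>= two
    return out


def count_kmers(reads, k: int) -> dict:
    """Count canonical k-mers over a read set.

    ``reads`` is an iterable of sequence strings, or a path to a
    (gzip-transparent) FASTQ file. Every length-k window over {A,C,G,T}
    contributes 1 to its canonical k-mer; windows containing any other
    character are skipped; reads shorter than k contribute nothing.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if isinstance(reads, (str, Path)):
        reads = kio.read_fastq_sequences(reads)
    hashes, counts = count_kmer_hashes(reads, k)
    return dict(zip(hashes_to_kmers(hashes, k), counts.tolist()))


def count_kmer_hashes(reads, k: int, chunk_reads: int = 50000):
    """Fast path of :func:`count_kmers`: (unique sorted hashes, counts)."""
    parts = []
    buf = []
    for seq in reads:
        buf.append(seq.upper())
        if len(buf) >= chunk_reads:
            parts.append(encode_canonical("N".join(buf), k))
            buf = []
    if buf:
        parts.append(encode_canonical("N".join(buf), k))
    if not parts:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    allh = np.concatenate(parts)
    return np.unique(allh, return_counts=True)


@dataclass
class ReferenceKmerIndex:
    """Set of canonical k-mers occurring in a reference sequence set.

    Membership is symmetric under reverse complement because only canonical
    forms are stored and queries are canonicalized.
    """

    k: int
    hashes: np.ndarray  # sorted uint64

    def __contains__(self, kmer: str) -> bool:
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != k={self.k}")
        h = kmers_to_hashes([canonical(kmer)], self.k)
        return bool(self.contains_hashes(h)[0])

    def contains_hashes(self, hashes: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.hashes, hashes)
        idx = np.minimum(idx, max(len(self.hashes) - 1, 0))
        if len(self.hashes) == 0:
            return np.zeros(len(hashes), dtype=bool)
        return self.hashes[idx] == hashes

    def __len__(self) -> int:
        return len(self.hashes)


def index_reference_kmers(sequences, k: int) -> ReferenceKmerIndex:
    """Index every canonical k-mer window of the given reference sequences.

    ``sequences``: mapping name -> sequence, an iterable of sequences, or a
    FASTA path. Windows with non-ACGT characters are skipped.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if isinstance(sequences, (str, Path)):
        sequences = kio.read_fasta(sequences)
    if hasattr(sequences, "values"):
        sequences = list(sequences.values())
    else:
        sequences = list(sequences)
    if not sequences:
        raise ValueError("empty reference: no sequences to index")
    parts = [encode_canonical(s.upper(), k) for s in sequences]
    allh = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint64)
    return ReferenceKmerIndex(k=k, hashes=np.unique(allh))


@dataclass
class KmerCountMatrix:
    """Canonical k-mer x sample count matrix.

    ``counts`` rows are canonical k-mer strings in lexicographic order,
    columns follow the sample sheet. Values are raw non-negative integers,
    or non-negative reals after normalization.
    """

    counts: pd.DataFrame
    k: int
    conditions: pd.Series
    size_factors: pd.Series | None = None

    @property
    def kmers(self):
        return self.counts.index

    @property
    def samples(self):
        return self.counts.columns

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def __len__(self) -> int:
        return self.counts.shape[0]

    def row_hashes(self) -> np.ndarray:
        return kmers_to_hashes(self.counts.index, self.k)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="kmer")

    @classmethod
    def from_tsv(cls, path, k: int, sheet: pd.DataFrame) -> "KmerCountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="kmer")
        conditions = pd.Series(
            sheet["condition"].values, index=sheet["sample_id"].values
        )
        return cls(counts=df, k=k, conditions=conditions)


def build_matrix(per_sample_counts: dict, sheet: pd.DataFrame, k: int) -> KmerCountMatrix:
    """Assemble per-sample canonical k-mer counts into one matrix.

    K-mer universe is the union over samples; absent entries are 0; column
    order follows the sample sheet.
    """
    kio.validate_sample_sheet(sheet)
    missing = [s for s in sheet["sample_id"] if s not in per_sample_counts]
    if missing:
        raise ValueError(f"samples missing from counts: {missing}")
    cols = {}
    for sid in sheet["sample_id"]:
        cols[sid] = pd.Series(per_sample_counts[sid], dtype="int64")
    df = pd.DataFrame(cols).fillna(0).astype("int64")
    df = df.loc[sorted(df.index), list(sheet["sample_id"])]
    conditions = pd.Series(sheet["condition"].values, index=sheet["sample_id"].values)
    return KmerCountMatrix(counts=df, k=k, conditions=conditions)


def filter_recurrence(
    M: KmerCountMatrix, min_count: int = 5, min_samples: int = 10
) -> KmerCountMatrix:
    """Recurrence filter: keep k-mers with count >= min_count in >= min_samples samples.

    The two thresholds are read jointly per sample (>= min_count counts in
    >= min_samples samples), not as a total-count rule. Counts are not
    altered, only rows dropped.
    """
    if min_count < 1 or min_samples < 1:
        raise ValueError("min_count and min_samples must be >= 1")
    if min_samples > M.n_samples:
        warnings.warn(
            f"min_samples={min_samples} exceeds the {M.n_samples} available samples; "
            "result will be empty",
            stacklevel=2,
        )
    keep = (M.counts >= min_count).sum(axis=1) >= min_samples
    return KmerCountMatrix(
        counts=M.counts.loc[keep],
        k=M.k,
        conditions=M.conditions,
        size_factors=M.size_factors,
    )


def mask_reference(M: KmerCountMatrix, index: ReferenceKmerIndex) -> KmerCountMatrix:
    """Drop every k-mer present in the reference index; keep the rest."""
    if index.k != M.k:
        raise ValueError(f"k mismatch: matrix k={M.k}, index k={index.k}")
    if len(M) == 0:
        return M
    present = index.contains_hashes(M.row_hashes())
    return KmerCountMatrix(
        counts=M.counts.loc[~present],
        k=M.k,
        conditions=M.conditions,
        size_factors=M.size_factors,
    )
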