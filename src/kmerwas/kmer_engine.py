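"""Canonical k-mer counting and the presence/absence matrix.

k-mers are collapsed to canonical form (the lexicographic minimum of a
k-mer and its reverse complement; k must be odd so no k-mer is its own
reverse complement).  Internally a k-mer is held as ``k`` bytes of 2-bit
base codes (A=0, C=1, G=2, T=3) wrapped in a numpy ``S{k}`` scalar, so
byte-wise comparison equals lexicographic nucleotide comparison and the
encoded integer order used for serialization is the same order.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_MAGIC = b"KWM1"

# base -> 2-bit code lookup (255 = invalid)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class KmerError(ValueError):
    """Raised on invalid k-mer engine inputs."""


@dataclass(frozen=True)
class KmerConfig:
    """Counting parameters: k-mer length and within-accession multiplicity floor."""

    k: int = 51
    min_count: int = 2

    def __post_init__(self) -> None:
        if self.k < 3 or self.k % 2 == 0:
            raise KmerError(f"k must be odd and >= 3, got {self.k}")
        if self.min_count < 1:
            raise KmerError(f"min_count must be >= 1, got {self.min_count}")


def seq_to_codes(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string as 2-bit codes (255 for non-ACGT)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def encode_kmer(kmer: str) -> bytes:
    """Return the code-byte representation of a k-mer string."""
    codes = seq_to_codes(kmer)
    if (codes > 3).any():
        raise KmerError(f"non-ACGT character in k-mer {kmer!r}")
    return codes.tobytes()


def decode_kmer(code_bytes: bytes, k: int | None = None) -> str:
    if k is not None:
        code_bytes = code_bytes.ljust(k, b"\x00")  # numpy strips trailing NULs
    return codes_to_seq(np.frombuffer(code_bytes, dtype=np.uint8))


def packed_width(k: int) -> int:
    return (k + 3) // 4


def pack_kmer_array(arr: np.ndarray, k: int) -> np.ndarray:
    """S{k} code-byte array -> 2-bit-packed S{ceil(k/4)} array.

    Packing is big-endian within each byte, so byte order (and therefore
    numpy comparison/sort order) is preserved.
    """
    if len(arr) == 0:
        return np.empty(0, dtype=f"S{packed_width(k)}")
    codes = np.frombuffer(arr.tobytes(), dtype=np.uint8).reshape(-1, k)
    return np.ascontiguousarray(_pack_2bit(codes)).view(f"S{packed_width(k)}").ravel()


def unpack_kmer_array(arr: np.ndarray, k: int) -> np.ndarray:
    if len(arr) == 0:
        return np.empty(0, dtype=f"S{k}")
    kw = packed_width(k)
    packed = np.frombuffer(arr.tobytes(), dtype=np.uint8).reshape(-1, kw)
    return np.ascontiguousarray(_unpack_2bit(packed, k)).view(f"S{k}").ravel()


def packed_to_string(packed: bytes, k: int) -> str:
    arr = np.frombuffer(packed.ljust(packed_width(k), b"\x00"), dtype=np.uint8)
    return codes_to_seq(_unpack_2bit(arr[None, :], k)[0])


def string_to_packed(kmer: str) -> bytes:
    codes = seq_to_codes(kmer)
    if (codes > 3).any():
        raise KmerError(f"non-ACGT character in k-mer {kmer!r}")
    return _pack_2bit(codes[None, :]).tobytes()


def kmer_to_int(kmer: str) -> int:
    """2-bit integer encoding; preserves lexicographic order."""
    return int.from_bytes(encode_kmer(kmer), "big")  # base-4 digits


def revcomp(seq: str) -> str:
    return codes_to_seq(3 - seq_to_codes(seq)[::-1])


def canonicalize(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement.

    Idempotent.  Raises :class:`KmerError` on non-ACGT input; during bulk
    counting such windows are skipped and tallied instead (see
    :func:`count_kmers`).
    """
    if (seq_to_codes(kmer) > 3).any():
        raise KmerError(f"non-ACGT character in k-mer {kmer!r}")
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _window_bytes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All k-windows of a code array as (forward, canonical, valid-mask).

    Windows are returned 2-bit-packed (``S{ceil(k/4)}``); packing is
    order-preserving, so the canonical form is the byte-wise minimum of
    the packed forward and reverse-complement windows.  ``valid`` marks
    windows free of non-ACGT characters.
    """
    n = len(codes) - k + 1
    kw = packed_width(k)
    if n <= 0:
        empty = np.empty(0, dtype=f"S{kw}")
        return empty, empty, np.empty(0, dtype=bool)
    safe = np.where(codes > 3, 0, codes)  # invalid windows masked below
    fwd = np.ascontiguousarray(
        _pack_2bit(sliding_window_view(safe, k))).view(f"S{kw}").ravel()
    rc_codes = (3 - safe)[::-1]
    rc = np.ascontiguousarray(
        _pack_2bit(sliding_window_view(rc_codes, k)[::-1])).view(f"S{kw}").ravel()
    canon = np.where(fwd <= rc, fwd, rc)
    bad = np.concatenate(([0], np.cumsum(codes > 3)))
    valid = (bad[k:] - bad[:-k]) == 0
    return fwd, canon, valid


def canonical_windows(seq: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-position canonical windows of ``seq``.

    Returns ``(canonical packed S{ceil(k/4)} array, valid mask, forward
    packed array)``, indexed by 0-based window start.
    """
    codes = seq_to_codes(seq)
    fwd, canon, valid = _window_bytes(codes, k)
    return canon, valid, fwd


@dataclass
class KmerSet:
    """Canonical k-mers of one accession passing the multiplicity floor."""

    accession_id: str
    k: int
    kmers: np.ndarray  # sorted unique 2-bit-packed S{ceil(k/4)} array
    n_skipped: int = 0  # windows containing non-ACGT characters

    def __len__(self) -> int:
        return len(self.kmers)

    def __contains__(self, kmer: str) -> bool:
        key = np.array([string_to_packed(canonicalize(kmer))],
                       dtype=f"S{packed_width(self.k)}")[0]
        idx = np.searchsorted(self.kmers, key)
        return bool(idx < len(self.kmers) and self.kmers[idx] == key)

    def strings(self) -> list[str]:
        return [packed_to_string(b, self.k) for b in self.kmers.tolist()]


def count_kmers(
    sequences: Iterable[str],
    config: KmerConfig = KmerConfig(),
    accession_id: str = "",
) -> KmerSet:
    """Count canonical k-mers over all records and keep those with
    multiplicity >= ``config.min_count``.  Windows spanning a non-ACGT
    character are skipped and tallied in ``n_skipped``."""
    k = config.k
    chunks: list[np.ndarray] = []
    n_windows = 0
    n_valid = 0
    # short records (reads) are batched into one buffer with N separators:
    # windows crossing a separator are invalid and dropped, so the result
    # is identical to per-record counting
    sep = np.array([255], dtype=np.uint8)
    batch: list[np.ndarray] = []
    batch_len = 0

    def flush() -> None:
        nonlocal n_valid, batch_len
        if not batch:
            return
        buf = np.concatenate([x for c in batch for x in (c, sep)][:-1])
        _, canon, valid = _window_bytes(buf, k)
        nv = int(valid.sum())
        n_valid += nv
        if nv:
            chunks.append(canon[valid])
        batch.clear()
        batch_len = 0

    for seq in sequences:
        codes = seq if isinstance(seq, np.ndarray) else seq_to_codes(seq)
        n_windows += max(0, len(codes) - k + 1)
        batch.append(codes)
        batch_len += len(codes) + 1
        if batch_len >= 1 << 20:
            flush()
    flush()
    skipped = n_windows - n_valid
    if not chunks:
        return KmerSet(accession_id, k, np.empty(0, dtype=f"S{packed_width(k)}"), skipped)
    allk = np.concatenate(chunks)
    uniq, counts = _unique_counts(allk, packed_width(k))
    return KmerSet(accession_id, k, uniq[counts >= config.min_count], skipped)


@dataclass
class KmerMatrix:
    """Presence/absence of canonical k-mers (rows) across accessions (columns).

    Rows are sorted by encoded k-mer and restricted to occupancy in
    ``[2, n_accessions - 2]`` by :func:`build_matrix`.
    """

    k: int
    kmers: np.ndarray  # (n_rows,) 2-bit-packed S{ceil(k/4)}, sorted
    accessions: list[str]
    presence: np.ndarray  # (n_rows, n_accessions) bool

    @property
    def n_rows(self) -> int:
        return len(self.kmers)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def occupancy(self) -> np.ndarray:
        return self.presence.sum(axis=1)

    def row_strings(self) -> list[str]:
        return [packed_to_string(b, self.k) for b in self.kmers.tolist()]

    def subset_accessions(self, ids: Sequence[str]) -> "KmerMatrix":
        """Column subset in the given order (no occupancy re-filtering)."""
        index = {a: i for i, a in enumerate(self.accessions)}
        cols = [index[a] for a in ids]
        return KmerMatrix(self.k, self.kmers, list(ids), self.presence[:, cols])

    # --- serialization -------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("kmer\t" + "\t".join(self.accessions) + "\n")
            for kb, row in zip(self.kmers.tolist(), self.presence.astype(np.uint8)):
                fh.write(packed_to_string(kb, self.k)
                         + "\t" + "\t".join(map(str, row.tolist())) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KmerMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            accessions = header[1:]
            kmers, rows = [], []
            k = 51
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                k = len(parts[0])
                kmers.append(string_to_packed(parts[0]))
                rows.append([c == "1" for c in parts[1:]])
        arr = np.array(kmers, dtype=f"S{packed_width(k)}")
        return cls(k, arr, accessions, np.array(rows, dtype=bool))

    def to_binary(self, path: str | Path) -> None:
        """Compact format: header (k, rows, cols, ids), then per row the
        2-bit-packed k-mer (ceil(k/4) bytes) and a column bitset."""
        ids = "\n".join(self.accessions).encode()
        kw = packed_width(self.k)
        packed = np.frombuffer(self.kmers.tobytes(), dtype=np.uint8).reshape(-1, kw)
        bits = np.packbits(self.presence, axis=1)
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<IIII", self.k, self.n_rows, self.n_accessions, len(ids)))
            fh.write(ids)
            body = np.concatenate([packed, bits], axis=1) if self.n_rows else packed
            fh.write(body.tobytes())

    @classmethod
    def from_binary(cls, path: str | Path) -> "KmerMatrix":
        with open(path, "rb") as fh:
            if fh.read(4) != _MAGIC:
                raise KmerError(f"{path}: not a k-mer matrix file")
            k, n_rows, n_cols, id_len = struct.unpack("<IIII", fh.read(16))
            accessions = fh.read(id_len).decode().split("\n") if id_len else []
            kw = packed_width(k)
            bw = (n_cols + 7) // 8
            body = np.frombuffer(fh.read(), dtype=np.uint8).reshape(n_rows, kw + bw)
        kmers = np.ascontiguousarray(body[:, :kw]).view(f"S{kw}").ravel()
        presence = np.unpackbits(body[:, kw:], axis=1)[:, :n_cols].astype(bool)
        return cls(k, kmers, accessions, presence)


def _pack_2bit(codes: np.ndarray) -> np.ndarray:
    n, k = codes.shape
    kw = (k + 3) // 4
    padded = np.zeros((n, kw * 4), dtype=np.uint8)
    padded[:, :k] = codes
    shaped = padded.reshape(n, kw, 4)
    return (
        (shaped[:, :, 0] << 6) | (shaped[:, :, 1] << 4) | (shaped[:, :, 2] << 2) | shaped[:, :, 3]
    ).astype(np.uint8)


def _unpack_2bit(packed: np.ndarray, k: int) -> np.ndarray:
    n, kw = packed.shape
    out = np.empty((n, kw * 4), dtype=np.uint8)
    out[:, 0::4] = (packed >> 6) & 3
    out[:, 1::4] = (packed >> 4) & 3
    out[:, 2::4] = (packed >> 2) & 3
    out[:, 3::4] = packed & 3
    return out[:, :k]


def _unique_counts(arr: np.ndarray, kw: int) -> tuple[np.ndarray, np.ndarray]:
    """Sorted unique values + multiplicities of a packed k-mer array.

    Equivalent to ``np.unique(arr, return_counts=True)`` but sorts via
    uint64 hi/lo key pairs, which is much faster than fixed-width-bytes
    sorting for large arrays.
    """
    n = len(arr)
    if n == 0:
        return arr, np.empty(0, dtype=np.int64)
    hi, lo = _pair_keys(arr, kw)
    order = np.lexsort((lo, hi))
    hs, ls = hi[order], lo[order]
    new = np.empty(n, dtype=bool)
    new[0] = True
    new[1:] = (hs[1:] != hs[:-1]) | (ls[1:] != ls[:-1])
    first = np.flatnonzero(new)
    counts = np.diff(np.append(first, n))
    return arr[order[first]], counts


def _pair_keys(arr: np.ndarray, kw: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed S{kw} array -> order-preserving (hi, lo) uint64 key pair.

    Supports kw <= 16, i.e. k <= 63 (the desk-scale range of this
    pipeline; the default k is 51 -> kw = 13).
    """
    if kw > 16:
        raise KmerError(f"k-mers wider than 16 packed bytes unsupported (kw={kw})")
    b = np.zeros((len(arr), 16), dtype=np.uint8)
    b[:, :kw] = np.frombuffer(arr.tobytes(), dtype=np.uint8).reshape(-1, kw)
    v = b.view(">u8")
    return v[:, 0].astype(np.uint64), v[:, 1].astype(np.uint64)


def build_matrix(kmersets: Sequence[KmerSet]) -> KmerMatrix:
    """Union k-mer sets into a presence matrix, keeping rows whose
    occupancy ``c`` satisfies ``2 <= c <= n - 2``.

    k-mers seen in 0/1 accessions or in n-1/n accessions carry no usable
    contrast (the all-n case additionally has zero variance and would
    break the correlation prefilter), so they are dropped.
    """
    if len(kmersets) < 4:
        raise KmerError("build_matrix requires >= 4 accessions")
    ids = [s.accession_id for s in kmersets]
    if len(set(ids)) != len(ids):
        raise KmerError("duplicate accession ids")
    ks = {s.k for s in kmersets}
    if len(ks) != 1:
        raise KmerError(f"mixed k across accessions: {sorted(ks)}")
    k = ks.pop()
    n = len(kmersets)
    kw = packed_width(k)
    if sum(len(s.kmers) for s in kmersets) == 0:
        return KmerMatrix(k, np.empty(0, dtype=f"S{kw}"), ids,
                          np.empty((0, n), dtype=bool))
    # Entries are partitioned into 256 buckets by the first packed byte
    # (each set is sorted, so bucket slices come from searchsorted) and
    # each bucket is grouped independently.  This keeps the working set
    # cache-sized -- far faster than one global sort on a single CPU --
    # and bounds peak memory at roughly one bucket plus the output.
    edges = np.array([bytes([b]) for b in range(1, 256)], dtype=f"S{kw}")
    bounds = [np.concatenate(([0], np.searchsorted(s.kmers, edges),
                              [len(s.kmers)])) for s in kmersets]
    kept_kmers: list[np.ndarray] = []
    blocks: list[np.ndarray] = []
    for b in range(256):
        parts, accids = [], []
        for j, s in enumerate(kmersets):
            b0, b1 = bounds[j][b], bounds[j][b + 1]
            if b1 > b0:
                parts.append(s.kmers[b0:b1])
                accids.append(np.full(b1 - b0, j, dtype=np.uint16))
        if not parts:
            continue
        allk = np.concatenate(parts)
        acc = np.concatenate(accids)
        total = len(allk)
        hi, lo = _pair_keys(allk, kw)
        order = np.lexsort((lo, hi))
        hs, ls, accs = hi[order], lo[order], acc[order]
        new_grp = np.empty(total, dtype=bool)
        new_grp[0] = True
        new_grp[1:] = (hs[1:] != hs[:-1]) | (ls[1:] != ls[:-1])
        group = np.cumsum(new_grp) - 1
        occ = np.bincount(group)
        keep_group = (occ >= 2) & (occ <= n - 2)
        n_kept = int(keep_group.sum())
        if n_kept == 0:
            continue
        row_of = np.cumsum(keep_group) - 1
        entry_keep = keep_group[group]
        presence_b = np.zeros((n_kept, n), dtype=bool)
        presence_b[row_of[group[entry_keep]], accs[entry_keep]] = True
        first = order[new_grp]
        kept_kmers.append(allk[first[keep_group]])
        blocks.append(presence_b)
    if not kept_kmers:
        return KmerMatrix(k, np.empty(0, dtype=f"S{kw}"), ids,
                          np.empty((0, n), dtype=bool))
    return KmerMatrix(k, np.concatenate(kept_kmers), ids, np.vstack(blocks))


def sample_rows(matrix: KmerMatrix, n: int = 100_000, seed: int | None = None) -> KmerMatrix:
    """Uniform row sample without replacement (row order preserved)."""
    if n > matrix.n_rows:
        raise KmerError(f"cannot sample {n} rows from {matrix.n_rows}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(matrix.n_rows, size=n, replace=False))
    return KmerMatrix(matrix.k, matrix.kmers[idx], list(matrix.accessions), matrix.presence[idx])


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from a FASTA file (gzip allowed)."""
    import gzip

    from Bio import SeqIO

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.id, str(rec.seq)


def read_sequences(path: str | Path) -> list[str]:
    """Sequences from FASTA or FASTQ (gzip allowed), by extension."""
    import gzip

    from Bio import SeqIO

    p = str(path)
    fmt = "fastq" if p.rstrip(".gz").endswith(("fastq", "fq")) else "fasta"
    opener = gzip.open if p.endswith(".gz") else open
    with opener(p, "rt") as fh:
        return [str(rec.seq) for rec in SeqIO.parse(fh, fmt)]
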