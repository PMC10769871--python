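"""Compact read container and 2-bit k-mer machinery.

Shotgun read sets are held as a uint8 code matrix (A=0, C=1, G=2, T=3;
anything else 4) so that host subtraction and seed lookup stay vectorised.
The public surface is still the (id, sequence, quality) triple: iterating a
:class:`ReadSet` yields exactly those.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

__all__ = ["ReadSet", "encode", "decode", "kmer_values", "kmer_valid", "revcomp_codes"]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (non-ACGT -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse-complement along the last axis; invalid codes stay invalid."""
    comp = np.where(codes < 4, 3 - codes, np.uint8(4)).astype(np.uint8)
    return comp[..., ::-1]


def kmer_values(codes: np.ndarray, k: int) -> np.ndarray:
    """All k-mer integers of each row of an (N, L) code matrix, shape (N, L-k+1).

    Rolling Horner evaluation in base 4; fits uint64 for k <= 31.
    """
    if codes.ndim == 1:
        codes = codes[None, :]
    n, length = codes.shape
    if not 1 <= k <= length:
        raise ValueError(f"k={k} outside [1, read length {length}]")
    if k > 31:
        raise ValueError("k-mer size above 31 overflows the 2-bit encoding")
    w = length - k + 1
    c = codes.astype(np.uint64)
    vals = np.empty((n, w), dtype=np.uint64)
    v = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        v = v * np.uint64(4) + c[:, j]
    vals[:, 0] = v
    top = np.uint64(4 ** (k - 1))
    for j in range(1, w):
        v = (v - c[:, j - 1] * top) * np.uint64(4) + c[:, j + k - 1]
        vals[:, j] = v
    return vals


def kmer_valid(codes: np.ndarray, k: int) -> np.ndarray:
    """Boolean (N, L-k+1): window contains only ACGT codes."""
    if codes.ndim == 1:
        codes = codes[None, :]
    bad = (codes >= 4).astype(np.int32)
    cs = np.concatenate(
        [np.zeros((bad.shape[0], 1), dtype=np.int32), np.cumsum(bad, axis=1)], axis=1
    )
    return (cs[:, k:] - cs[:, :-k]) == 0


class ReadSet:
    """Fixed-length read collection: ids + code matrix + per-read quality.

    Iteration yields ``(id, sequence, quality)`` triples; quality strings are
    constant Phred-40 ("I") unless supplied.
    """

    def __init__(self, ids: list[str], codes: np.ndarray, qualities=None):
        codes = np.ascontiguousarray(codes, dtype=np.uint8)
        if codes.ndim != 2 or len(ids) != codes.shape[0]:
            raise ValueError("ids and code matrix disagree")
        if qualities is not None and len(qualities) != len(ids):
            raise ValueError("qualities length mismatch")
        self.ids = list(ids)
        self.codes = codes
        self._qualities = list(qualities) if qualities is not None else None

    @property
    def read_length(self) -> int:
        return self.codes.shape[1]

    def __len__(self) -> int:
        return self.codes.shape[0]

    def quality(self, i: int) -> str:
        if self._qualities is not None:
            return self._qualities[i]
        return "I" * self.read_length

    def sequence(self, i: int) -> str:
        if self._qualities is not None:
            # padded rows carry their true length in the quality string
            return decode(self.codes[i, : len(self._qualities[i])])
        return decode(self.codes[i])

    def __iter__(self):
        for i in range(len(self)):
            yield self.ids[i], self.sequence(i), self.quality(i)

    def __getitem__(self, i: int) -> tuple[str, str, str]:
        return self.ids[i], self.sequence(i), self.quality(i)

    def subset(self, mask_or_index) -> "ReadSet":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        quals = (
            [self._qualities[i] for i in idx] if self._qualities is not None else None
        )
        return ReadSet([self.ids[i] for i in idx], self.codes[idx], quals)

    @classmethod
    def from_triples(cls, triples) -> "ReadSet":
        triples = list(triples)
        if not triples:
            return cls([], np.zeros((0, 0), dtype=np.uint8))
        ids, seqs, quals = zip(*triples)
        for rid, s, q in triples:
            if len(s) != len(q):
                raise ValueError(f"sequence/quality length mismatch for read {rid!r}")
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            # pad with the invalid code; true lengths kept via qualities
            length = max(lengths)
            codes = np.full((len(seqs), length), 4, dtype=np.uint8)
            for i, s in enumerate(seqs):
                codes[i, : len(s)] = encode(s)
        else:
            codes = np.vstack([encode(s) for s in seqs])
        return cls(list(ids), codes, list(quals))

    @classmethod
    def concat(cls, parts: list["ReadSet"]) -> "ReadSet":
        parts = [p for p in parts if len(p)]
        if not parts:
            return cls([], np.zeros((0, 0), dtype=np.uint8))
        length = {p.read_length for p in parts}
        if len(length) > 1:
            raise ValueError("cannot concatenate read sets of differing length")
        ids = [i for p in parts for i in p.ids]
        codes = np.vstack([p.codes for p in parts])
        quals = None
        if any(p._qualities is not None for p in parts):
            quals = [p.quality(i) for p in parts for i in range(len(p))]
        return cls(ids, codes, quals)
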