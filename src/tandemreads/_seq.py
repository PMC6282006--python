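"""Low-level sequence helpers: complements, rotations, numeric k-mer codes.

Bases are encoded A=0, C=1, G=2, T=3 so that complementation is ``3 - code``.
Numeric codes pack a k-mer into a base-4 integer (exact for k <= 31 in
uint64); positions containing N are flagged invalid rather than encoded.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte -> 2-bit code; N (and anything else) maps to 0 but is masked separately
_CODE_LUT = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_LUT[ord(_b)] = _i
_VALID_LUT = np.zeros(256, dtype=bool)
for _b in "ACGT":
    _VALID_LUT[ord(_b)] = True

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def rotations(seq: str) -> list[str]:
    """All cyclic rotations of *seq* (with duplicates removed, order kept)."""
    seen: dict[str, None] = {}
    for i in range(len(seq)):
        seen.setdefault(seq[i:] + seq[:i], None)
    return list(seen)


def encode(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (2-bit codes, validity mask) for *seq*."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_LUT[raw], _VALID_LUT[raw]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for all-valid positions."""
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def kmer_code_of(kmer: str) -> int:
    """Base-4 integer code of a single k-mer (k <= 31)."""
    c = 0
    for ch in kmer:
        c = (c << 2) | int(_CODE_LUT[ord(ch)])
    return c


def decode_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append("ACGT"[(code >> shift) & 3])
    return "".join(out)


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Codes of every k-mer window of *seq* plus a validity (no-N) mask.

    Returns arrays of length ``len(seq) - k + 1``. Requires k <= 31.
    """
    if k > 31:
        raise ValueError("kmer_codes supports k <= 31")
    if k > len(seq):
        raise ValueError(f"k={k} exceeds sequence length {len(seq)}")
    codes2, valid = encode(seq)
    n = len(seq) - k + 1
    out = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        out = (out << np.uint64(2)) | codes2[j : j + n].astype(np.uint64)
    # window valid iff no N inside: sliding all() via cumulative sum
    cs = np.concatenate(([0], np.cumsum(valid.astype(np.int64))))
    ok = (cs[k:] - cs[:-k]) == k
    return out, ok


def kmer_set(seq: str, k: int, *, both_strands: bool = True) -> np.ndarray:
    """Sorted unique k-mer codes of *seq* (and optionally its reverse
    complement), N-containing windows excluded."""
    codes, ok = kmer_codes(seq, k)
    parts = [codes[ok]]
    if both_strands:
        rc_codes, rc_ok = kmer_codes(revcomp(seq), k)
        parts.append(rc_codes[rc_ok])
    return np.unique(np.concatenate(parts))


def codes_in_set(codes: np.ndarray, sorted_set: np.ndarray) -> np.ndarray:
    """Boolean membership of *codes* in a sorted unique code array."""
    if sorted_set.size == 0:
        return np.zeros(codes.shape, dtype=bool)
    idx = np.searchsorted(sorted_set, codes)
    idx[idx == sorted_set.size] = sorted_set.size - 1
    return sorted_set[idx] == codes
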