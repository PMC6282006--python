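"""Independent brute-force reference implementations used as oracles.

These deliberately share no code with the package: complements via a
lookup dict, rotations by slicing, scans by double loops over (offset,
unit size) with direct string comparison.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp_ref(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def canonical_ref(unit: str) -> str:
    candidates = []
    for s in (unit, revcomp_ref(unit)):
        for i in range(len(s)):
            candidates.append(s[i:] + s[:i])
    return min(candidates)


def is_primitive_ref(unit: str) -> bool:
    L = len(unit)
    for d in range(1, L):
        if L % d == 0 and unit == unit[:d] * (L // d):
            return False
    return True


def brute_force_scan(seq: str, lmin: int, lmax: int
                     ) -> list[tuple[int, int, str, int]]:
    """All duplication windows as (start, unit_length, canonical, run_length)."""
    out = []
    n = len(seq)
    for L in range(lmin, lmax + 1):
        for i in range(n - 2 * L + 1):
            window = seq[i : i + 2 * L]
            if "N" in window:
                continue
            unit = window[:L]
            if unit != window[L:]:
                continue
            if not is_primitive_ref(unit):
                continue
            # maximal run: extend while period-L equality holds over
            # N-free positions
            lo = i
            while lo - 1 >= 0 and seq[lo - 1] == seq[lo - 1 + L] \
                    and seq[lo - 1] != "N" and seq[lo - 1 + L] != "N":
                lo -= 1
            hi = i + L  # exclusive end of period-equality positions
            while hi + L < n and seq[hi] == seq[hi + L] \
                    and seq[hi] != "N" and seq[hi + L] != "N":
                hi += 1
            out.append((i, L, canonical_ref(unit), (hi - lo) + L))
    return out


def count_substring_ref(sequence: str, motif: str) -> int:
    """Naive full-sequence substring count by start position."""
    return sum(1 for i in range(len(sequence) - len(motif) + 1)
               if sequence[i : i + len(motif)] == motif)
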