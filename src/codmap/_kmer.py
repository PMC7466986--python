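"""Vectorized 2-bit k-mer machinery shared by the anchoring, placement and
tandem-repeat modules.

Sequences are encoded as uint8 arrays (A=0, C=1, G=2, T=3, anything else=4).
k-mer codes pack k bases into a uint64 (so k <= 31); windows containing a
non-ACGT base are flagged invalid rather than producing a code.
"""

from __future__ import annotations

import numpy as np

try:  # optional JIT for the rolling k-mer packer
    import numba

    @numba.njit(cache=False)
    def _roll_codes(base: np.ndarray, k: int, out: np.ndarray) -> None:
        mask = np.uint64((np.uint64(1) << np.uint64(2 * k)) - np.uint64(1))
        code = np.uint64(0)
        for i in range(base.size):
            code = ((code << np.uint64(2)) | np.uint64(base[i])) & mask
            if i >= k - 1:
                out[i - k + 1] = code

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into a uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENC[raw]


def decode(enc: np.ndarray) -> str:
    return _DEC[np.minimum(enc, 4)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving, case-preserving)."""
    return seq.translate(_RC_TABLE)[::-1]


def revcomp_enc(enc: np.ndarray) -> np.ndarray:
    return _COMP[enc][::-1]


def kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit packed codes for every k-window of ``enc``.

    Returns ``(codes, valid)`` where ``codes[i]`` packs ``enc[i:i+k]`` and
    ``valid[i]`` is False when the window contains a non-ACGT base (its code
    is then meaningless). Packing combines power-of-two sub-windows so the
    work is O(n log k) rather than O(nk).
    """
    if k < 1 or k > 31:
        raise ValueError("k must be in 1..31")
    n = enc.size - k + 1
    if n <= 0:
        return (np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool))
    if _HAVE_NUMBA:
        codes = np.empty(n, dtype=np.uint64)
        _roll_codes(enc & 3, k, codes)
    else:
        base = (enc & 3).astype(np.uint64)
        # codes of width-(2^j) windows, built by doubling
        widths = [1]
        levels = [base]
        while widths[-1] * 2 <= k:
            w = widths[-1]
            prev = levels[-1]
            m = prev.size - w
            nxt = (prev[:m] << np.uint64(2 * w)) | prev[w : w + m]
            widths.append(2 * w)
            levels.append(nxt)
        codes = None
        off = 0
        rem = k
        for w, lev in zip(reversed(widths), reversed(levels)):
            if w > rem:
                continue
            piece = lev[off : off + n]
            if codes is None:
                codes = piece.copy()
            else:
                codes <<= np.uint64(2 * w)
                codes |= piece
            off += w
            rem -= w
    # non-ACGT bases are usually rare (record separators): invalidate the k
    # windows covering each one directly; cumsum fallback when they are not
    bad_pos = np.flatnonzero(enc > 3)
    if bad_pos.size <= 10_000:
        valid = np.ones(n, dtype=bool)
        for p in bad_pos:
            valid[max(0, p - k + 1) : min(n, p + 1)] = False
    else:
        bad = np.concatenate(([0], np.cumsum(enc > 3, dtype=np.int64)))
        valid = (bad[k:] - bad[:-k]) == 0
    return codes, valid


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of packed k-mer codes, computed bitwise:
    complement every base (XOR) then reverse the 2-bit groups."""
    x = codes ^ np.uint64((1 << (2 * k)) - 1)
    m2 = np.uint64(0x3333333333333333)
    m4 = np.uint64(0x0F0F0F0F0F0F0F0F)
    x = ((x >> np.uint64(2)) & m2) | ((x & m2) << np.uint64(2))
    x = ((x >> np.uint64(4)) & m4) | ((x & m4) << np.uint64(4))
    x = x.byteswap()
    return x >> np.uint64(64 - 2 * k)


def canonical_codes(
    enc: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Forward, canonical (min of strand pair) codes plus orientation flags.

    Returns ``(fwd, canon, fwd_is_canonical, valid)``. With odd k a k-mer is
    never its own reverse complement, so orientation is well defined.
    """
    fwd, valid = kmer_codes(enc, k)
    rc = revcomp_codes(fwd, k)
    fwd_is_canon = fwd <= rc
    canon = np.where(fwd_is_canon, fwd, rc)
    return fwd, canon, fwd_is_canon, valid


class KmerIndex:
    """Sorted k-mer code index over a concatenation of sequences.

    Sequences are joined with k Ns so no window spans two records; hits are
    mapped back to (record, offset) pairs.
    """

    def __init__(self, sequences: dict[str, str], k: int):
        self.k = k
        self.names = list(sequences)
        parts = []
        offsets = []
        pos = 0
        sep = "N" * k
        for name in self.names:
            offsets.append(pos)
            parts.append(sequences[name])
            pos += len(sequences[name]) + k
        self.offsets = np.array(offsets, dtype=np.int64)
        self.lengths = np.array(
            [len(sequences[n]) for n in self.names], dtype=np.int64
        )
        self._enc = encode(sep.join(parts))
        codes, valid = kmer_codes(self._enc, k)
        positions = np.flatnonzero(valid).astype(np.int64)
        del valid
        sortable = codes[positions]
        del codes
        order = np.argsort(sortable)
        self._sorted_codes = sortable[order]
        self._sorted_pos = positions[order]

    def lookup(self, kmer: str) -> np.ndarray:
        """Global (concatenated) start positions of an exact k-mer match."""
        enc = encode(kmer)
        if enc.size != self.k or (enc > 3).any():
            return np.empty(0, dtype=np.int64)
        code, _ = kmer_codes(enc, self.k)
        lo = np.searchsorted(self._sorted_codes, code[0], side="left")
        hi = np.searchsorted(self._sorted_codes, code[0], side="right")
        return np.sort(self._sorted_pos[lo:hi])

    def locate(self, global_pos: int) -> tuple[str, int]:
        """Map a concatenated-space position to (record name, offset)."""
        i = int(np.searchsorted(self.offsets, global_pos, side="right")) - 1
        off = global_pos - int(self.offsets[i])
        if off >= int(self.lengths[i]):
            raise IndexError("position falls inside a record separator")
        return self.names[i], off

    def match_window(self, global_pos: int, pattern_enc: np.ndarray) -> int:
        """Number of mismatches of ``pattern_enc`` against the concatenation
        at ``global_pos``; positions where the pattern has code > 3 are
        wildcards. Returns a large number when out of bounds."""
        end = global_pos + pattern_enc.size
        if global_pos < 0 or end > self._enc.size:
            return 10**9
        window = self._enc[global_pos:end]
        care = pattern_enc <= 3
        if (window[care] > 3).any():
            return 10**9
        return int(np.count_nonzero(window[care] != pattern_enc[care]))
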