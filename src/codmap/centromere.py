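"""Tandem-repeat detection, centromere-candidate filtering, family
clustering and genome-wide occurrence counting.

The built-in detector seeds candidate loci by k-mer recurrence at a lag
within the period range and extends them copy-by-copy while per-copy
identity against the majority consensus stays high. It is a deliberately
simple array finder (substitution-tolerant, no indel model inside arrays);
TRF ``.dat`` ingestion provides parity on real data. The centromere
candidate filter follows the satellite heuristics: consensus more than 60%
AT, unit longer than 80 bp, family present on every chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np

from ._kmer import KmerIndex, encode, revcomp
from .io import SequenceRecord


@dataclass
class TandemArray:
    chrom: str
    start: int  # 0-based half-open
    end: int
    period: int
    copy_number: float
    consensus: str
    at_fraction: float
    mean_identity: float

    @property
    def score(self) -> float:
        return self.copy_number * self.period


@dataclass
class RepeatFamily:
    family_id: str
    consensus: str
    members: list[TandemArray] = field(default_factory=list)

    @property
    def chrom_coverage(self) -> set[str]:
        return {m.chrom for m in self.members}

    @property
    def total_occurrences(self) -> int:
        return int(sum(round(m.copy_number) for m in self.members))


@dataclass
class DensityTrack:
    chrom: str
    bin_size: int
    counts: list[int]


# ---------------------------------------------------------------------------
# detection


def _majority_consensus(matrix: np.ndarray) -> np.ndarray:
    """Per-column majority base over aligned copies (ties -> smaller code)."""
    counts = np.zeros((4, matrix.shape[1]), dtype=np.int32)
    for b in range(4):
        counts[b] = (matrix == b).sum(axis=0)
    return counts.argmax(axis=0).astype(np.uint8)


def _copy_identities(matrix: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    return (matrix == consensus).mean(axis=1)


def _refine_candidate(
    enc: np.ndarray,
    start: int,
    end: int,
    period: int,
    min_copies: int,
    min_copy_identity: float,
):
    """Snap a seeded interval to whole copies, trim/extend by per-copy
    identity, and compute consensus statistics."""
    L = enc.size
    cn = max(min_copies, (end - start) // period)
    cn = min(cn, (L - start) // period)
    if cn < min_copies:
        return None
    matrix = enc[start : start + cn * period].reshape(cn, period)
    cons = _majority_consensus(matrix)
    ident = _copy_identities(matrix, cons)
    # trim low-identity edge copies
    lo, hi = 0, cn
    while lo < hi and ident[lo] < min_copy_identity:
        lo += 1
    while hi > lo and ident[hi - 1] < min_copy_identity:
        hi -= 1
    if hi - lo < min_copies:
        return None
    start = start + lo * period
    cn = hi - lo
    # extend outward one copy at a time
    changed = True
    while changed:
        changed = False
        matrix = enc[start : start + cn * period].reshape(cn, period)
        cons = _majority_consensus(matrix)
        if start - period >= 0:
            cand = enc[start - period : start]
            if (cand == cons).mean() >= min_copy_identity:
                start -= period
                cn += 1
                changed = True
                continue
        if start + (cn + 1) * period <= L:
            cand = enc[start + cn * period : start + (cn + 1) * period]
            if (cand == cons).mean() >= min_copy_identity:
                cn += 1
                changed = True
    matrix = enc[start : start + cn * period].reshape(cn, period)
    cons = _majority_consensus(matrix)
    ident = _copy_identities(matrix, cons)
    cons_str = "ACGT"[0]  # placeholder replaced below
    cons_str = "".join("ACGT"[b] for b in cons)
    at = (cons_str.count("A") + cons_str.count("T")) / period
    return TandemArray(
        "",
        start,
        start + cn * period,
        period,
        float(cn),
        cons_str,
        at,
        float(ident.mean()),
    )


def _fold_fundamental(
    arr: TandemArray,
    enc: np.ndarray,
    min_period: int,
    min_copies: int,
    min_copy_identity: float,
) -> TandemArray:
    """Refold an array detected at a harmonic of its true period (e.g. a
    dimer of the repeat unit) to the smallest divisor period that still
    refines cleanly over the same interval."""
    for d in range(min_period, arr.period):
        if arr.period % d:
            continue
        folded = _refine_candidate(
            enc, arr.start, arr.end, d, min_copies, min_copy_identity
        )
        if (
            folded is not None
            and folded.end - folded.start >= 0.9 * (arr.end - arr.start)
            and folded.mean_identity >= min_copy_identity
        ):
            folded.chrom = arr.chrom
            return folded
    return arr


def detect_tandem_arrays(
    record: SequenceRecord,
    min_period: int = 50,
    max_period: int = 600,
    min_copies: int = 2,
    k: int = 12,
    min_copy_identity: float = 0.8,
) -> list[TandemArray]:
    """Find tandem arrays on one sequence by k-mer lag recurrence.

    A position seeds period p when its k-mer reoccurs at lag p within the
    period range; seed runs are refined into whole-copy arrays and
    overlapping calls are resolved best-score-first (score = copies x
    period).
    """
    if not (2 <= min_period <= max_period <= 2000):
        raise ValueError("period range must satisfy 2 <= min <= max <= 2000")
    seq = record.sequence
    if len(seq) < 2 * min_period:
        return []
    enc = encode(seq)
    from ._kmer import kmer_codes

    codes, valid = kmer_codes(enc, k)
    vpos = np.flatnonzero(valid)
    c = codes[vpos]
    order = np.argsort(c, kind="stable")
    cs, ps = c[order], vpos[order]
    eq = cs[1:] == cs[:-1]
    lag = ps[1:] - ps[:-1]
    sel = eq & (lag >= min_period) & (lag <= max_period)
    seed_pos = ps[:-1][sel]
    seed_lag = lag[sel]
    if seed_pos.size == 0:
        return []
    candidates: list[TandemArray] = []
    order = np.lexsort((seed_pos, seed_lag))
    seed_pos, seed_lag = seed_pos[order], seed_lag[order]
    run_start = 0
    for i in range(1, seed_pos.size + 1):
        is_break = (
            i == seed_pos.size
            or seed_lag[i] != seed_lag[run_start]
            or seed_pos[i] - seed_pos[i - 1] > seed_lag[run_start]
        )
        if not is_break:
            continue
        p = int(seed_lag[run_start])
        s = int(seed_pos[run_start])
        e = int(seed_pos[i - 1]) + p + k
        arr = _refine_candidate(enc, s, min(e, len(seq)), p, min_copies, min_copy_identity)
        if arr is not None:
            arr.chrom = record.id
            arr = _fold_fundamental(
                arr, enc, min_period, min_copies, min_copy_identity
            )
            candidates.append(arr)
        run_start = i
    # overlap resolution: keep the higher copies x period product
    candidates.sort(key=lambda a: (-a.score, a.start, a.period))
    kept: list[TandemArray] = []
    for a in candidates:
        if all(o.end <= a.start or o.start >= a.end for o in kept):
            kept.append(a)
    kept.sort(key=lambda a: a.start)
    return kept


def detect_genome_arrays(
    genome: list[SequenceRecord], **kwargs
) -> list[TandemArray]:
    out: list[TandemArray] = []
    for rec in genome:
        out.extend(detect_tandem_arrays(rec, **kwargs))
    return out


# ---------------------------------------------------------------------------
# TRF interoperability


def parse_trf_dat(path) -> list[TandemArray]:
    """Parse TRF .dat output into TandemArray records (1-based inclusive
    coordinates converted to 0-based half-open)."""
    arrays: list[TandemArray] = []
    skipped = 0
    chrom = ""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("Sequence:"):
                chrom = line.split(None, 1)[1].split()[0]
                continue
            if line.startswith(("Parameters:", "Tandem", "Program", "Version",
                                "Gary", "Boston", "Copyright")):
                continue
            f = line.split()
            try:
                start, end = int(f[0]), int(f[1])
                period = int(f[2])
                copy_number = float(f[3])
                pct_match = float(f[5])
                consensus = f[13]
            except (IndexError, ValueError):
                skipped += 1
                continue
            at = (
                (consensus.count("A") + consensus.count("T")) / len(consensus)
                if consensus
                else 0.0
            )
            arrays.append(
                TandemArray(
                    chrom,
                    start - 1,
                    end,
                    period,
                    copy_number,
                    consensus,
                    at,
                    pct_match / 100.0,
                )
            )
    if skipped:
        warnings.warn(f"{skipped} malformed TRF rows skipped")
    return arrays


# ---------------------------------------------------------------------------
# filtering and clustering


def filter_candidates(
    arrays: list[TandemArray],
    at_min: float = 0.60,
    unit_min_len: int = 80,
) -> list[TandemArray]:
    """Composition filter: strictly more than ``at_min`` AT and unit
    strictly longer than ``unit_min_len``. The all-chromosomes requirement
    is a family-level test applied after clustering."""
    return [
        a
        for a in arrays
        if a.at_fraction > at_min and a.period > unit_min_len
    ]


def _pair_identity(a: str, b: str) -> float:
    """Best global identity of two consensi over all cyclic rotations of
    ``a`` and both strands; identity = 1 - dist / max(len)."""
    best = 0.0
    denom = max(len(a), len(b))
    for variant in (a, revcomp(a)):
        doubled = variant + variant
        for r in range(len(variant)):
            rot = doubled[r : r + len(variant)]
            d = edlib.align(rot, b, mode="NW", task="distance")["editDistance"]
            best = max(best, 1.0 - d / denom)
            if best == 1.0:
                return best
    return best


def cluster_families(
    arrays: list[TandemArray], identity_threshold: float = 0.95
) -> list[RepeatFamily]:
    """Greedy centroid clustering: arrays sorted by copies x period join
    the first family whose consensus matches at >= the identity threshold
    (cyclic rotations and both strands considered), else found a new one."""
    families: list[RepeatFamily] = []
    for a in sorted(arrays, key=lambda x: (-x.score, x.chrom, x.start)):
        placed = False
        for fam in families:
            if (
                _pair_identity(a.consensus, fam.consensus)
                >= identity_threshold
            ):
                fam.members.append(a)
                placed = True
                break
        if not placed:
            families.append(
                RepeatFamily(f"fam{len(families) + 1:03d}", a.consensus, [a])
            )
    return families


def centromere_candidates(
    families: list[RepeatFamily],
    n_chroms: int,
) -> list[RepeatFamily]:
    """Families present on all chromosomes (>=1 member per chromosome)."""
    return [f for f in families if len(f.chrom_coverage) >= n_chroms]


# ---------------------------------------------------------------------------
# occurrence counting


def _semiglobal_distances(seq_enc: np.ndarray, pat_enc: np.ndarray) -> np.ndarray:
    """Best edit distance of the full pattern ending at each sequence
    position (semi-global: free ends on the sequence). Brute-force O(nm)
    dynamic programme, vectorized column-wise."""
    m = pat_enc.size
    n = seq_enc.size
    out = np.empty(n, dtype=np.int32)
    prev = np.arange(1, m + 1, dtype=np.int32)
    rows = np.arange(1, m + 1, dtype=np.int32)
    pat_bad = pat_enc > 3
    for j in range(n):
        c = seq_enc[j]
        sub = ((pat_enc != c) | pat_bad | (c > 3)).astype(np.int32)
        diag = np.concatenate(([np.int32(0)], prev[:-1])) + sub
        cand = np.minimum(diag, prev + 1)
        t = cand - rows
        pm = np.minimum.accumulate(np.minimum(t, 0))
        cur = rows + pm
        out[j] = cur[-1]
        prev = cur
    return out


def bruteforce_count(
    seq: str, consensus: str, min_identity: float = 0.95
) -> int:
    """All-offsets semi-global scanner (both strands) used as the
    independent check for :func:`count_occurrences` on short sequences."""
    m = len(consensus)
    max_d = int((1 - min_identity) * m)
    enc = encode(seq)
    hits = []
    for strand, pat in (("+", consensus), ("-", revcomp(consensus))):
        dist = _semiglobal_distances(enc, encode(pat))
        for j in np.flatnonzero(dist <= max_d):
            hits.append((int(dist[j]), max(0, int(j) - m + 1), int(j) + 1))
    hits.sort()
    chosen: list[tuple[int, int]] = []
    for _, s, e in hits:
        if all(
            min(e, ce) - max(s, cs) <= m // 2 for cs, ce in chosen
        ):
            chosen.append((s, e))
    return len(chosen)


def count_occurrences(
    genome: list[SequenceRecord],
    consensus: str,
    min_identity: float = 0.95,
    seed_k: int = 15,
) -> tuple[int, list[tuple[str, int, int]]]:
    """Count non-overlapping occurrences of a consensus across the genome.

    Candidate sites are located by exact seed k-mers tiled along the
    consensus (both strands), then scored by semi-global alignment; sites
    at >= ``min_identity`` are kept best-first without substantial overlap.
    Positions are reported on the forward strand, 0-based half-open.
    """
    if not consensus:
        raise ValueError("empty consensus")
    m = len(consensus)
    max_d = int((1 - min_identity) * m)
    index = KmerIndex({r.id: r.sequence for r in genome}, seed_k)
    seqs = {r.id: r.sequence for r in genome}
    candidates: dict[tuple[str, str, int], None] = {}
    for strand, pat in (("+", consensus), ("-", revcomp(consensus))):
        for off in range(0, m - seed_k + 1, seed_k):
            seed = pat[off : off + seed_k]
            for gp in index.lookup(seed):
                chrom, p = index.locate(int(gp))
                candidates[(strand, chrom, p - off)] = None
    hits: list[tuple[int, str, int, int]] = []
    for strand, chrom, s in candidates:
        pat = consensus if strand == "+" else revcomp(consensus)
        w0 = max(0, s - max_d)
        w1 = min(len(seqs[chrom]), s + m + max_d)
        res = edlib.align(
            pat, seqs[chrom][w0:w1], mode="HW", task="locations", k=max_d
        )
        if res["editDistance"] < 0:
            continue
        loc = res["locations"][0]
        hits.append((res["editDistance"], chrom, w0 + loc[0], w0 + loc[1] + 1))
    hits.sort()
    chosen: list[tuple[str, int, int]] = []
    for d, chrom, s, e in hits:
        if all(
            c != chrom or min(e, ce) - max(s, cs) <= m // 2
            for c, cs, ce in chosen
        ):
            chosen.append((chrom, s, e))
    chosen.sort()
    return len(chosen), chosen


# ---------------------------------------------------------------------------
# density


def density_track(
    positions: list[tuple[str, int, int]],
    chrom_lengths: dict[str, int],
    bin_size: int = 100_000,
) -> dict[str, DensityTrack]:
    """Per-chromosome occurrence counts in fixed bins (BED-like)."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    tracks = {}
    for chrom, L in chrom_lengths.items():
        n_bins = (L + bin_size - 1) // bin_size
        tracks[chrom] = DensityTrack(chrom, bin_size, [0] * n_bins)
    for chrom, start, _ in positions:
        if chrom not in tracks:
            raise ValueError(f"position on unknown chromosome {chrom!r}")
        if start >= chrom_lengths[chrom]:
            raise ValueError(
                f"position {start} beyond end of {chrom}"
            )
        tracks[chrom].counts[start // bin_size] += 1
    return tracks


def write_density(tracks: dict[str, DensityTrack], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcount\n")
        for chrom in sorted(tracks):
            t = tracks[chrom]
            for i, c in enumerate(t.counts):
                fh.write(
                    f"{chrom}\t{i * t.bin_size}\t{(i + 1) * t.bin_size}\t{c}\n"
                )


def dimer_subunit(
    consensus: str, min_unit: int = 40, min_identity: float = 0.9
) -> int | None:
    """Detect a unit-spacer-unit internal structure by comparing the two
    ends of the consensus; returns the sub-unit length or None."""
    m = len(consensus)
    best = None
    for u in range(min_unit, m // 2 + 1):
        head, tail = consensus[:u], consensus[-u:]
        matches = sum(1 for a, b in zip(head, tail) if a == b)
        if matches / u >= min_identity:
            best = u
    return best
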