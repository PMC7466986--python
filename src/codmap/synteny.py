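"""Pairwise genome comparison via unique k-mer anchors and co-linear
chains; detection of single and double inversions with breakpoint-interval
reports.

The comparator is MUM-style: k-mers occurring exactly once in each genome
(counting both strands) are matched, maximal runs of overlapping unique
k-mers are merged into anchors, and anchors are chained per strand into
synteny blocks by repeatedly extracting the maximum-weight co-linear chain
(exact dynamic programme). A run of reverse-strand blocks flanked by
forward blocks is an inversion; two adjacent reverse runs whose target
intervals are mutually reordered (they cannot belong to one reversal) are
reported as a double inversion with three breakpoint intervals.

Breakpoint intervals are reported in query coordinates, 1-based, with
``size = end - start``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kmer import canonical_codes, encode
from .io import PafRecord, SequenceRecord


@dataclass
class Anchor:
    """A merged run of unique k-mer matches between the two genomes."""

    q_chrom: str
    q_start: int
    q_end: int
    t_chrom: str
    t_start: int
    t_end: int
    strand: str

    @property
    def length(self) -> int:
        return self.q_end - self.q_start


@dataclass
class SyntenyBlock:
    q_chrom: str
    q_start: int
    q_end: int
    t_chrom: str
    t_start: int
    t_end: int
    strand: str
    n_anchors: int

    @property
    def span_bp(self) -> int:
        return self.q_end - self.q_start


@dataclass
class BreakpointInterval:
    """Reported (1-based) interval bounding a rearrangement junction."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("breakpoint interval start must be < end")

    @property
    def size(self) -> int:
        return self.end - self.start

    @classmethod
    def from_internal(cls, chrom: str, start0: int, end0: int):
        if end0 <= start0:
            end0 = start0 + 1
        return cls(chrom, start0 + 1, end0 + 1)

    def contains_internal(self, pos: int, slack: int = 0) -> bool:
        """Whether a 0-based coordinate falls in the interval; ``slack``
        allows for anchor ends sliding a few bases past a junction when
        the first rearranged base matches by chance."""
        return self.start - 1 - slack <= pos <= self.end - 1 + slack


@dataclass
class InversionCall:
    chrom: str
    kind: str  # "single" | "double"
    intervals: list[BreakpointInterval]
    within_contig: list[bool] | None = None

    @property
    def span_mb(self) -> float:
        return round(
            (self.intervals[-1].end - self.intervals[0].start) / 1e6, 2
        )


def call_from_report_intervals(
    chrom: str, pairs: list[tuple[int, int]]
) -> InversionCall:
    """Build a call directly from reported (1-based) interval coordinates;
    two intervals make a single inversion, three a double."""
    kind = {2: "single", 3: "double"}.get(len(pairs))
    if kind is None:
        raise ValueError("a call carries 2 (single) or 3 (double) intervals")
    return InversionCall(
        chrom, kind, [BreakpointInterval(chrom, s, e) for s, e in pairs]
    )


# ---------------------------------------------------------------------------
# anchors


def _genome_unique(genome: list[SequenceRecord], k: int):
    """Canonical codes unique genome-wide (both strands), with positions.

    Works in sorted-code order with int32 positions and eager frees so two
    ~50 Mb genomes fit comfortably in memory.
    """
    from ._kmer import kmer_codes, revcomp_codes

    sep = "N" * k
    offsets = []
    pos = 0
    for rec in genome:
        offsets.append(pos)
        pos += rec.length + k
    enc = encode(sep.join(r.sequence for r in genome))
    fwd, valid = kmer_codes(enc, k)
    del enc
    rc = revcomp_codes(fwd, k)
    fwd_is_canon = fwd <= rc
    np.minimum(fwd, rc, out=fwd)
    canon = fwd
    del rc
    vpos = np.flatnonzero(valid).astype(np.int32)
    del valid
    codes = canon[vpos]
    del canon
    orient = fwd_is_canon[vpos]
    del fwd_is_canon
    order = np.argsort(codes)
    codes = codes[order]
    vpos = vpos[order]
    orient = orient[order]
    del order
    uniq = np.ones(codes.size, dtype=bool)
    uniq[1:] &= codes[1:] != codes[:-1]
    uniq[:-1] &= codes[:-1] != codes[1:]
    names = [r.id for r in genome]
    lengths = np.array([r.length for r in genome], dtype=np.int64)
    return (
        codes[uniq],
        vpos[uniq],
        orient[uniq],
        np.array(offsets, dtype=np.int64),
        lengths,
        names,
    )


def find_unique_anchors(
    genome_q: list[SequenceRecord],
    genome_t: list[SequenceRecord],
    k: int = 21,
) -> list[Anchor]:
    """Match k-mers unique in both genomes and merge overlapping runs.

    Strand is '-' when the target carries the reverse complement of the
    query word. k must be odd so no k-mer equals its own reverse
    complement.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    cq, pq, oq, offs_q, lens_q, names_q = _genome_unique(genome_q, k)
    ct, pt, ot, offs_t, lens_t, names_t = _genome_unique(genome_t, k)
    # both code arrays are sorted and duplicate-free: intersect by merge
    idx = np.searchsorted(ct, cq).astype(np.int32)
    idx_c = np.minimum(idx, max(ct.size - 1, 0))
    match = (ct.size > 0) & (ct[idx_c] == cq)
    del idx_c, cq, ct
    iq = np.flatnonzero(match).astype(np.int32)
    it = idx[iq]
    del idx, match
    if iq.size == 0:
        warnings.warn("no unique shared k-mers between the genomes")
        return []
    qpos = pq[iq]
    tpos = pt[it]
    plus = oq[iq] == ot[it]
    del pq, pt, oq, ot, iq, it
    # order by query position via an inverse-position table (qpos values
    # are unique), avoiding a large argsort
    total = int(qpos.max()) + 1
    pos2idx = np.full(total, -1, dtype=np.int32)
    pos2idx[qpos] = np.arange(qpos.size, dtype=np.int32)
    order = pos2idx[pos2idx >= 0]
    del pos2idx
    qpos, tpos, plus = qpos[order], tpos[order], plus[order]
    del order
    # run breaks: q advances by 1 while t advances +1 (plus) or -1 (minus)
    dq = np.diff(qpos)
    dt = np.diff(tpos)
    same = (
        (dq == 1)
        & (plus[1:] == plus[:-1])
        & (dt == np.where(plus[:-1], 1, -1))
    )
    starts = np.flatnonzero(np.concatenate(([True], ~same)))
    ends = np.concatenate((starts[1:], [qpos.size])) - 1

    def locate(global_pos, offsets, lengths, names):
        i = int(np.searchsorted(offsets, global_pos, side="right")) - 1
        return names[i], int(global_pos - offsets[i])

    anchors: list[Anchor] = []
    for s, e in zip(starts, ends):
        qc, q0 = locate(qpos[s], offs_q, lens_q, names_q)
        q1 = q0 + int(qpos[e] - qpos[s]) + k
        if plus[s]:
            tc, t0 = locate(tpos[s], offs_t, lens_t, names_t)
            t1 = t0 + int(tpos[e] - tpos[s]) + k
        else:
            tc, t0 = locate(tpos[e], offs_t, lens_t, names_t)
            t1 = t0 + int(tpos[s] - tpos[e]) + k
        anchors.append(
            Anchor(qc, q0, q1, tc, t0, t1, "+" if plus[s] else "-")
        )
    return anchors


# ---------------------------------------------------------------------------
# chaining


def _compatible_gaps(qs, qe, ts, te, j, strand, max_gap):
    """Gap vectors from every earlier anchor i<j to anchor j."""
    gq = qs[j] - qe[:j]
    if strand == "+":
        gt = ts[j] - te[:j]
    else:
        gt = ts[:j] - te[j]
    ok = (gq >= 0) & (gq <= max_gap) & (gt >= 0) & (gt <= max_gap)
    return ok


def _best_chain(qs, qe, ts, te, w, strand, max_gap):
    """Exact maximum-weight co-linear chain over anchors sorted by q_start;
    returns (indices, weight)."""
    n = qs.size
    dp = w.astype(np.int64).copy()
    parent = np.full(n, -1, dtype=np.int64)
    for j in range(1, n):
        ok = _compatible_gaps(qs, qe, ts, te, j, strand, max_gap)
        if ok.any():
            cand = np.where(ok, dp[:j], -1)
            i = int(np.argmax(cand))
            if cand[i] >= 0:
                dp[j] += dp[i]
                parent[j] = i
    j = int(np.argmax(dp))
    weight = int(dp[j])
    chain = []
    while j >= 0:
        chain.append(j)
        j = int(parent[j])
    return chain[::-1], weight


def _chain_to_block(qc, tc, strand, qs, qe, ts, te, idx) -> SyntenyBlock:
    first, last = idx[0], idx[-1]
    if strand == "+":
        t0, t1 = int(ts[first]), int(te[last])
    else:
        t0, t1 = int(ts[last]), int(te[first])
    return SyntenyBlock(
        qc, int(qs[first]), int(qe[last]), tc, t0, t1, strand, len(idx)
    )


def chain_anchors(
    anchors: list[Anchor],
    max_gap: int = 100_000,
    min_block_bp: int = 20_000,
    min_anchors: int = 5,
) -> list[SyntenyBlock]:
    """Decompose anchors into strand-consistent co-linear chains.

    Per (query chromosome, target chromosome, strand) group the
    maximum-weight chain (weight = total anchored bp, gaps bounded by
    ``max_gap`` on both genomes) is extracted repeatedly until no anchors
    remain. A chain may legally bridge a rearranged segment shorter than
    ``max_gap``; a second pass therefore splits any chain at gaps that
    fully contain another substantial chain, so blocks do not overlap on
    the query. Chains spanning less than ``min_block_bp`` on the query or
    with fewer than ``min_anchors`` anchors are discarded; blocks are
    returned sorted by query interval.
    """
    groups: dict[tuple[str, str, str], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.q_chrom, a.t_chrom, a.strand), []).append(a)
    raw = []  # (qc, tc, strand, qs, qe, ts, te, idx_array)
    for (qc, tc, strand), group in groups.items():
        group.sort(key=lambda a: a.q_start)
        qs = np.array([a.q_start for a in group], dtype=np.int64)
        qe = np.array([a.q_end for a in group], dtype=np.int64)
        ts = np.array([a.t_start for a in group], dtype=np.int64)
        te = np.array([a.t_end for a in group], dtype=np.int64)
        w = qe - qs
        remaining = np.arange(qs.size)
        while remaining.size:
            chain, _ = _best_chain(
                qs[remaining],
                qe[remaining],
                ts[remaining],
                te[remaining],
                w[remaining],
                strand,
                max_gap,
            )
            idx = remaining[chain]
            raw.append((qc, tc, strand, qs, qe, ts, te, idx))
            mask = np.ones(remaining.size, dtype=bool)
            mask[chain] = False
            remaining = remaining[mask]

    def passes(qc, tc, strand, qs, qe, ts, te, idx) -> bool:
        b = _chain_to_block(qc, tc, strand, qs, qe, ts, te, idx)
        return b.span_bp >= min_block_bp and len(idx) >= min_anchors

    # q-intervals of substantial chains, used to split bridged gaps
    splitters: dict[str, list[tuple[int, int, int]]] = {}
    for ci, chain in enumerate(raw):
        qc, tc, strand, qs, qe, ts, te, idx = chain
        if passes(*chain):
            splitters.setdefault(qc, []).append(
                (int(qs[idx[0]]), int(qe[idx[-1]]), ci)
            )
    blocks: list[SyntenyBlock] = []
    for ci, (qc, tc, strand, qs, qe, ts, te, idx) in enumerate(raw):
        cuts = []
        others = [s for s in splitters.get(qc, []) if s[2] != ci]
        # anchors may overhang a junction by a few chance-matching bases,
        # so containment in the gap is tested with a small tolerance
        tol = 200
        for j in range(len(idx) - 1):
            g0, g1 = int(qe[idx[j]]), int(qs[idx[j + 1]])
            if g1 <= g0:
                continue
            if any(s >= g0 - tol and e <= g1 + tol for s, e, _ in others):
                cuts.append(j + 1)
        pieces = np.split(idx, cuts) if cuts else [idx]
        for piece in pieces:
            if piece.size == 0:
                continue
            b = _chain_to_block(qc, tc, strand, qs, qe, ts, te, piece)
            if b.span_bp >= min_block_bp and piece.size >= min_anchors:
                weight = int((qe[piece] - qs[piece]).sum())
                blocks.append((weight, b))
    # suppress shadow blocks: sparse leftover chains inside the query span
    # of a heavier block (blocks must not overlap on the query)
    overlap_tol = 1_000
    blocks.sort(key=lambda wb: (-wb[0], wb[1].q_chrom, wb[1].q_start))
    kept: list[SyntenyBlock] = []
    for _, b in blocks:
        if all(
            k.q_chrom != b.q_chrom
            or min(k.q_end, b.q_end) - max(k.q_start, b.q_start) <= overlap_tol
            for k in kept
        ):
            kept.append(b)
    kept.sort(key=lambda b: (b.q_chrom, b.q_start))
    return kept


# ---------------------------------------------------------------------------
# inversion calling


def _events_in_run(run: list[SyntenyBlock]) -> list[tuple[int, int]]:
    """Split a run of '-' blocks into inversion events: maximal subruns
    whose target intervals descend with query position (the geometry of one
    reversal); ascending target order between adjacent blocks separates
    events."""
    events = []
    start = 0
    for i in range(1, len(run)):
        if run[i].t_start >= run[i - 1].t_start:
            events.append((start, i - 1))
            start = i
    events.append((start, len(run) - 1))
    return events


def call_inversions(blocks: list[SyntenyBlock]) -> list[InversionCall]:
    """Call single/double inversions from ordered blocks of one query
    chromosome (runs of '-' blocks flanked by '+' blocks)."""
    by_chrom: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.q_chrom, []).append(b)
    calls: list[InversionCall] = []
    for chrom, bs in sorted(by_chrom.items()):
        bs.sort(key=lambda b: b.q_start)
        if len(bs) < 2:
            warnings.warn(f"{chrom}: fewer than 2 blocks; no calls")
            continue
        i = 0
        while i < len(bs):
            if bs[i].strand != "-":
                i += 1
                continue
            j = i
            while j + 1 < len(bs) and bs[j + 1].strand == "-":
                j += 1
            flanked = (
                i > 0
                and bs[i - 1].strand == "+"
                and j + 1 < len(bs)
                and bs[j + 1].strand == "+"
            )
            if flanked:
                run = bs[i : j + 1]
                events = _events_in_run(run)
                if len(events) == 2:
                    e1, e2 = events
                    calls.append(
                        InversionCall(
                            chrom,
                            "double",
                            [
                                BreakpointInterval.from_internal(
                                    chrom, bs[i - 1].q_end, run[e1[0]].q_start
                                ),
                                BreakpointInterval.from_internal(
                                    chrom,
                                    run[e1[1]].q_end,
                                    run[e2[0]].q_start,
                                ),
                                BreakpointInterval.from_internal(
                                    chrom, run[e2[1]].q_end, bs[j + 1].q_start
                                ),
                            ],
                        )
                    )
                else:
                    for ei, (a, b) in enumerate(events):
                        left = (
                            run[a - 1].q_end if a > 0 else bs[i - 1].q_end
                        )
                        right = (
                            run[b + 1].q_start
                            if b + 1 < len(run)
                            else bs[j + 1].q_start
                        )
                        calls.append(
                            InversionCall(
                                chrom,
                                "single",
                                [
                                    BreakpointInterval.from_internal(
                                        chrom, left, run[a].q_start
                                    ),
                                    BreakpointInterval.from_internal(
                                        chrom, run[b].q_end, right
                                    ),
                                ],
                            )
                        )
            i = j + 1
    return calls


def annotate_contig_boundaries(
    calls: list[InversionCall], agp_components
) -> None:
    """Flag each breakpoint interval as within a contig or between contigs,
    given the AGP of the query build."""
    gaps: dict[str, list[tuple[int, int]]] = {}
    for c in agp_components:
        if c.component_type == "gap":
            gaps.setdefault(c.object_id, []).append(
                (c.object_start - 1, c.object_end)
            )
    for call in calls:
        flags = []
        for iv in call.intervals:
            s0, e0 = iv.start - 1, iv.end - 1
            between = any(
                not (ge <= s0 or gs >= e0)
                for gs, ge in gaps.get(iv.chrom, [])
            )
            flags.append(not between)
        call.within_contig = flags


def report_table2(calls: list[InversionCall]) -> pd.DataFrame:
    """Breakpoint-interval report: one row per interval with
    ``size_bp = end - start`` and the outer span in Mb (2 decimals) printed
    on the first row of each call."""
    rows = []
    for call in calls:
        for i, iv in enumerate(call.intervals):
            rows.append(
                {
                    "LG": call.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "size_bp": iv.size,
                    "span_mb": call.span_mb if i == 0 else None,
                }
            )
    return pd.DataFrame(rows, columns=["LG", "start", "end", "size_bp", "span_mb"])


def write_table2(calls: list[InversionCall], path) -> None:
    df = report_table2(calls)
    df.to_csv(path, sep="\t", index=False, float_format="%.2f")


# ---------------------------------------------------------------------------
# PAF interoperability


def blocks_from_paf(
    paf_records: list[PafRecord],
    min_block_bp: int = 20_000,
    max_gap: int = 100_000,
    query_names: set[str] | None = None,
    target_names: set[str] | None = None,
) -> list[SyntenyBlock]:
    """Turn precomputed alignments into synteny blocks: each record becomes
    a block, adjacent co-linear same-strand records with gaps below
    ``max_gap`` are merged, and short blocks are discarded."""
    if query_names is not None:
        missing = sorted({r.query_id for r in paf_records} - set(query_names))
        if missing:
            raise ValueError(f"unknown query names in PAF: {missing}")
    if target_names is not None:
        missing = sorted(
            {r.target_id for r in paf_records} - set(target_names)
        )
        if missing:
            raise ValueError(f"unknown target names in PAF: {missing}")
    groups: dict[tuple[str, str, str], list[PafRecord]] = {}
    for r in paf_records:
        groups.setdefault((r.query_id, r.target_id, r.strand), []).append(r)
    blocks: list[SyntenyBlock] = []
    for (qc, tc, strand), group in groups.items():
        group.sort(key=lambda r: r.query_start)
        others = [
            (r.query_start, r.query_end)
            for r in paf_records
            if r.query_id == qc and (r.target_id, r.strand) != (tc, strand)
        ]
        current: SyntenyBlock | None = None
        for r in group:
            if current is not None:
                gq = r.query_start - current.q_end
                if strand == "+":
                    gt = r.target_start - current.t_end
                else:
                    gt = current.t_start - r.target_end
                occupied = any(
                    s >= current.q_end and e <= r.query_start
                    for s, e in others
                )
                if 0 <= gq <= max_gap and 0 <= gt <= max_gap and not occupied:
                    current.q_end = r.query_end
                    if strand == "+":
                        current.t_end = r.target_end
                    else:
                        current.t_start = r.target_start
                    current.n_anchors += 1
                    continue
                blocks.append(current)
            current = SyntenyBlock(
                qc,
                r.query_start,
                r.query_end,
                tc,
                r.target_start,
                r.target_end,
                strand,
                1,
            )
        if current is not None:
            blocks.append(current)
    blocks = [b for b in blocks if b.span_bp >= min_block_bp]
    blocks.sort(key=lambda b: (b.q_chrom, b.q_start))
    return blocks
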