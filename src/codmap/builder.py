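"""Linkage-map-guided chromosome construction.

Markers are positioned on contigs by exact search of their flanking
sequences (with a bounded-mismatch fallback), contigs are assigned to
linkage groups by marker vote, chimeric contigs (discordant linkage groups)
are split, and the survivors are ordered and oriented along each linkage
group by their genetic-map coordinates and concatenated into chromosome
sequences with AGP output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import kendalltau

from ._kmer import KmerIndex, encode, revcomp
from .io import AgpComponent, MarkerRow, SequenceRecord

WILDCARD = np.uint8(4)  # pattern slot that matches any base (the SNP site)


@dataclass
class MarkerPlacement:
    marker_id: str
    lg: int
    female_cM: float
    male_cM: float
    contig_id: str | None = None
    position: int | None = None  # 0-based SNP offset on the contig
    strand: str | None = None
    status: str = "absent"  # placed | ambiguous | absent
    reason: str = ""


@dataclass
class ContigAssignment:
    contig_id: str
    lg: int | None
    n_markers: int
    mean_female_cM: float | None
    is_chimeric: bool = False
    discordant_lgs: list[int] = field(default_factory=list)


@dataclass
class ChromosomeBuild:
    lg: int
    components: list[tuple[str, str, int]]  # (contig_id, orientation, length)
    gap_len: int = 500
    flagged_unoriented: list[str] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        if not self.components:
            return 0
        return sum(l for _, _, l in self.components) + self.gap_len * (
            len(self.components) - 1
        )


@dataclass
class AnchoringStats:
    n_contigs_anchored: int
    anchored_bp: int
    fraction_of_assembly: float
    mean_markers_per_contig: float
    n_contigs_lt5_markers: int


# ---------------------------------------------------------------------------
# marker placement


def _gapped_pattern(left: str, right: str) -> np.ndarray:
    """Encoded flank pair with a one-base wildcard at the SNP site."""
    return np.concatenate(
        [encode(left), np.array([WILDCARD]), encode(right)]
    )


def place_markers(
    contigs: list[SequenceRecord],
    markers: list[MarkerRow],
    min_flank_k: int = 31,
    max_mismatch: int = 2,
) -> list[MarkerPlacement]:
    """Locate each marker's flank pair on both strands of every contig.

    Exactly one exact hit places the marker at the SNP site between the
    flanks; several hits make it ambiguous; zero hits trigger a seeded
    search (exact leftmost ``min_flank_k``-mer of the concatenated flank)
    tolerating up to ``max_mismatch`` mismatches, else the marker is absent.
    """
    index = KmerIndex({c.id: c.sequence for c in contigs}, min_flank_k)
    out: list[MarkerPlacement] = []
    for m in markers:
        pl = MarkerPlacement(m.marker_id, m.lg, m.female_cM, m.male_cM)
        left, right = m.flank_left.upper(), m.flank_right.upper()
        if len(left) < min_flank_k or len(right) < min_flank_k:
            pl.reason = "flank shorter than seed length"
            out.append(pl)
            continue
        pat_f = _gapped_pattern(left, right)
        pat_r = _gapped_pattern(revcomp(right), revcomp(left))
        # seed = leftmost k-mer of the concatenated flank, per strand
        cand_f = index.lookup(left[:min_flank_k])
        cand_r = index.lookup(revcomp(right)[:min_flank_k])

        def collect(tolerance: int) -> list[tuple[str, int, str]]:
            hits = []
            for p in cand_f:
                if index.match_window(int(p), pat_f) <= tolerance:
                    ctg, off = index.locate(int(p))
                    hits.append((ctg, off + len(left), "+"))
            for p in cand_r:
                if index.match_window(int(p), pat_r) <= tolerance:
                    ctg, off = index.locate(int(p))
                    hits.append((ctg, off + len(right), "-"))
            return sorted(set(hits))

        hits = collect(0)
        if not hits:
            hits = collect(max_mismatch)
            if not hits:
                pl.reason = "no flank match"
                out.append(pl)
                continue
        if len(hits) > 1:
            pl.status = "ambiguous"
            pl.reason = f"{len(hits)} hits"
            out.append(pl)
            continue
        pl.contig_id, pl.position, pl.strand = hits[0]
        pl.status = "placed"
        out.append(pl)
    return out


# ---------------------------------------------------------------------------
# linkage-group assignment and chimera handling


def assign_contigs(
    placements: list[MarkerPlacement],
    contigs: list[SequenceRecord] | None = None,
    min_votes: int = 2,
) -> list[ContigAssignment]:
    """Assign each contig the modal linkage group of its placed markers.

    A contig is flagged chimeric when at least two linkage groups each
    collect ``min_votes`` markers; a single discordant marker is treated as
    placement noise.
    """
    by_contig: dict[str, list[MarkerPlacement]] = {}
    for p in placements:
        if p.status == "placed":
            by_contig.setdefault(p.contig_id, []).append(p)
    ids = [c.id for c in contigs] if contigs is not None else sorted(by_contig)
    out = []
    for cid in ids:
        pls = by_contig.get(cid, [])
        if not pls:
            out.append(ContigAssignment(cid, None, 0, None))
            continue
        counts: dict[int, int] = {}
        for p in pls:
            counts[p.lg] = counts.get(p.lg, 0) + 1
        modal = min(counts, key=lambda lg: (-counts[lg], lg))
        supported = sorted(lg for lg, n in counts.items() if n >= min_votes)
        chimeric = len(supported) >= 2
        modal_cms = [p.female_cM for p in pls if p.lg == modal]
        out.append(
            ContigAssignment(
                cid,
                modal,
                len(pls),
                float(np.mean(modal_cms)),
                chimeric,
                supported if chimeric else [],
            )
        )
    return out


def break_chimera(
    contig: SequenceRecord,
    placements: list[MarkerPlacement],
    max_discordance: float = 0.10,
):
    """Split a two-LG chimeric contig at the marker-gap midpoint.

    The split point is the floor midpoint between the last marker of the
    5' linkage-group run and the first marker of the 3' run, the runs being
    the best two-segment partition of marker positions by linkage group.
    Returns ``(child_a, child_b, split, updated_placements)`` or ``None``
    when no partition leaves <= ``max_discordance`` of markers discordant
    (interleaved linkage groups), in which case the contig should be dropped
    from anchoring.
    """
    pls = sorted(
        (p for p in placements if p.status == "placed" and p.contig_id == contig.id),
        key=lambda p: p.position,
    )
    labels = [p.lg for p in pls]
    n = len(labels)
    best = None
    for j in range(1, n):
        lc: dict[int, int] = {}
        rc: dict[int, int] = {}
        for x in labels[:j]:
            lc[x] = lc.get(x, 0) + 1
        for x in labels[j:]:
            rc[x] = rc.get(x, 0) + 1
        ml = min(lc, key=lambda g: (-lc[g], g))
        mr = min(rc, key=lambda g: (-rc[g], g))
        if ml == mr:
            continue
        discord = (j - lc[ml]) + ((n - j) - rc[mr])
        if best is None or discord < best[0]:
            best = (discord, j)
    if best is None or best[0] / n > max_discordance:
        warnings.warn(
            f"{contig.id}: no clean two-segment linkage-group partition; "
            "dropping from anchoring"
        )
        return None
    _, j = best
    split = (pls[j - 1].position + pls[j].position) // 2
    child_a = SequenceRecord(f"{contig.id}_a", contig.sequence[:split])
    child_b = SequenceRecord(f"{contig.id}_b", contig.sequence[split:])
    updated = []
    for p in placements:
        if p.status == "placed" and p.contig_id == contig.id:
            q = MarkerPlacement(**vars(p))
            if p.position < split:
                q.contig_id = child_a.id
            else:
                q.contig_id = child_b.id
                q.position = p.position - split
            updated.append(q)
        else:
            updated.append(p)
    return child_a, child_b, split, updated


def resolve_chimeras(
    contigs: list[SequenceRecord],
    placements: list[MarkerPlacement],
    min_votes: int = 2,
):
    """Break every flagged chimeric contig; returns updated contigs,
    placements, and a report of broken/dropped contig ids."""
    assignments = assign_contigs(placements, contigs, min_votes)
    flagged = [a.contig_id for a in assignments if a.is_chimeric]
    by_id = {c.id: c for c in contigs}
    report = {"flagged": flagged, "broken": [], "dropped": []}
    for cid in flagged:
        res = break_chimera(by_id[cid], placements)
        if res is None:
            report["dropped"].append(cid)
            del by_id[cid]
            continue
        child_a, child_b, _, placements = res
        del by_id[cid]
        by_id[child_a.id] = child_a
        by_id[child_b.id] = child_b
        report["broken"].append(cid)
    return list(by_id.values()), placements, report


# ---------------------------------------------------------------------------
# ordering, orientation, concatenation


def _orientation(pls: list[MarkerPlacement], min_abs_tau: float = 0.5) -> str:
    bp = [p.position for p in pls]
    cm = [p.female_cM for p in pls]
    if len(set(cm)) < 2:
        cm = [p.male_cM for p in pls]
    if len(set(cm)) < 2 or len(bp) < 2:
        return "?"
    tau = kendalltau(bp, cm).statistic
    if not np.isfinite(tau) or abs(tau) < min_abs_tau:
        return "?"
    return "+" if tau > 0 else "-"


def order_and_orient(
    assignments: list[ContigAssignment],
    placements: list[MarkerPlacement],
    contig_lengths: dict[str, int],
    gap_len: int = 500,
) -> dict[int, ChromosomeBuild]:
    """Sort contigs along each linkage group by mean female cM and orient
    them by the sign of Kendall's tau between contig bp and cM."""
    by_contig: dict[str, list[MarkerPlacement]] = {}
    for p in placements:
        if p.status == "placed":
            by_contig.setdefault(p.contig_id, []).append(p)
    lgs = sorted({a.lg for a in assignments if a.lg is not None})
    builds: dict[int, ChromosomeBuild] = {}
    for lg in lgs:
        rows = []
        for a in assignments:
            if a.lg != lg or a.is_chimeric or a.n_markers == 0:
                continue
            pls = [p for p in by_contig.get(a.contig_id, []) if p.lg == lg]
            mean_f = float(np.mean([p.female_cM for p in pls]))
            mean_m = float(np.mean([p.male_cM for p in pls]))
            rows.append((mean_f, mean_m, a.contig_id, _orientation(pls)))
        rows.sort()
        build = ChromosomeBuild(lg, [], gap_len)
        for _, _, cid, orient in rows:
            if orient == "?":
                build.flagged_unoriented.append(cid)
            build.components.append((cid, orient, contig_lengths[cid]))
        if not build.components:
            warnings.warn(f"LG{lg:02d}: no contigs assigned")
        builds[lg] = build
    return builds


def concatenate(
    build: ChromosomeBuild,
    contigs_by_id: dict[str, SequenceRecord],
    gap_len: int | None = None,
) -> tuple[SequenceRecord, list[AgpComponent]]:
    """Join the ordered contigs (reverse-complementing '-' components) with
    N gaps and emit the matching AGP rows; '?' orientations are emitted as
    '+' but remain flagged on the build."""
    gap = build.gap_len if gap_len is None else gap_len
    name = f"LG{build.lg:02d}"
    parts: list[str] = []
    agp: list[AgpComponent] = []
    pos = 0  # 0-based
    for i, (cid, orient, length) in enumerate(build.components):
        if cid not in contigs_by_id:
            raise ValueError(f"missing contig sequence {cid!r}")
        seq = contigs_by_id[cid].sequence
        if orient == "-":
            seq = revcomp(seq)
        if i > 0 and gap > 0:
            agp.append(
                AgpComponent(name, pos + 1, pos + gap, "gap")
            )
            parts.append("N" * gap)
            pos += gap
        agp.append(
            AgpComponent(
                name,
                pos + 1,
                pos + length,
                "contig",
                cid,
                1,
                length,
                "+" if orient == "?" else orient,
            )
        )
        parts.append(seq)
        pos += length
    return SequenceRecord(name, "".join(parts)), agp


def contig_offsets(build: ChromosomeBuild) -> dict[str, int]:
    """0-based start of each component on the emitted chromosome."""
    offsets = {}
    pos = 0
    for i, (cid, _, length) in enumerate(build.components):
        if i > 0:
            pos += build.gap_len
        offsets[cid] = pos
        pos += length
    return offsets


def anchoring_stats(
    builds: dict[int, ChromosomeBuild],
    all_contigs: list[SequenceRecord],
    placements: list[MarkerPlacement],
) -> AnchoringStats:
    anchored = {
        cid for b in builds.values() for cid, _, _ in b.components
    }
    total_bp = sum(c.length for c in all_contigs)
    anchored_bp = sum(c.length for c in all_contigs if c.id in anchored)
    per_contig: dict[str, int] = {}
    for p in placements:
        if p.status == "placed" and p.contig_id in anchored:
            per_contig[p.contig_id] = per_contig.get(p.contig_id, 0) + 1
    counts = [per_contig.get(cid, 0) for cid in anchored]
    return AnchoringStats(
        n_contigs_anchored=len(anchored),
        anchored_bp=anchored_bp,
        fraction_of_assembly=anchored_bp / total_bp if total_bp else 0.0,
        mean_markers_per_contig=float(np.mean(counts)) if counts else 0.0,
        n_contigs_lt5_markers=sum(1 for c in counts if c < 5),
    )


def map_points_on_build(
    build: ChromosomeBuild, placements: list[MarkerPlacement]
) -> list[tuple[str, int, float, float]]:
    """Placed markers projected onto the emitted chromosome: a list of
    (marker_id, bp, female_cM, male_cM) sorted by bp."""
    offsets = contig_offsets(build)
    lengths = {cid: l for cid, _, l in build.components}
    orients = {cid: o for cid, o, _ in build.components}
    pts = []
    for p in placements:
        if p.status != "placed" or p.contig_id not in offsets or p.lg != build.lg:
            continue
        if orients[p.contig_id] == "-":
            bp = offsets[p.contig_id] + lengths[p.contig_id] - 1 - p.position
        else:
            bp = offsets[p.contig_id] + p.position
        pts.append((p.marker_id, bp, p.female_cM, p.male_cM))
    return sorted(pts, key=lambda t: t[1])
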