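"""End-to-end pipeline runs against simulated ground truth.

These helpers wire the generator, builder, synteny, centromere and
recombination modules together and score the results against the planted
truth: breakpoint containment, chimera detection, contig order/orientation
accuracy, centromere-family uniqueness, morphology classification. They
are what the acceptance script and the integration tests run.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import builder, centromere, recomb, synteny
from .simulate import (
    SimConfig,
    simulate_all,
    simulate_marker_map,
    simulate_pair,
    simulate_reference,
)

#: Published breakpoint intervals (1-based query coordinates) of the four
#: Atlantic cod supergene inversions, from the pairwise comparison of the
#: Celtic Sea and NEAC chromosome assemblies. LG01 carries the double
#: inversion (three intervals); the others are singles.
COD_SUPERGENE_BREAKPOINTS: dict[str, list[tuple[int, int]]] = {
    "LG01": [(10_782_691, 10_787_755), (18_422_802, 18_425_099),
             (28_225_372, 28_228_130)],
    "LG02": [(21_733_338, 21_733_998), (26_233_253, 26_238_098)],
    "LG07": [(15_208_043, 15_210_043), (24_574_346, 24_575_510)],
    "LG12": [(493_527, 635_659), (14_330_965, 14_376_973)],
}

#: Published total sex-specific linkage-map lengths (cM) of the cod map.
COD_MAP_TOTALS_CM = {"female": 1662.7, "male": 1262.3}


def table2_selfcheck() -> dict:
    """Recompute interval sizes and outer spans from the published
    breakpoint coordinates through the report writer."""
    calls = [
        synteny.call_from_report_intervals(lg, pairs)
        for lg, pairs in COD_SUPERGENE_BREAKPOINTS.items()
    ]
    df = synteny.report_table2(calls)
    sizes = {
        lg: [iv.size for iv in call.intervals]
        for lg, call in zip(COD_SUPERGENE_BREAKPOINTS, calls)
    }
    spans = {call.chrom: call.span_mb for call in calls}
    return {"table": df, "sizes": sizes, "spans": spans}


# ---------------------------------------------------------------------------
# inversion recovery


def inversion_recovery(
    seed: int, config: SimConfig | None = None, k: int = 21
) -> dict:
    """Simulate a genome pair, call inversions, and score against truth.

    Breakpoint containment allows one anchor word (k bp) of slack: the
    anchor bounding a junction can slide past it when the first inverted
    base matches the reference by chance.
    """
    if config is None:
        config = SimConfig(seed=seed)
    else:
        config = dataclasses.replace(config, seed=seed)
    ref, alt, truth = simulate_pair(config)
    anchors = synteny.find_unique_anchors(alt, ref, k)
    blocks = synteny.chain_anchors(anchors)
    calls = synteny.call_inversions(blocks)
    calls_by_chrom: dict[str, list] = {}
    for c in calls:
        calls_by_chrom.setdefault(c.chrom, []).append(c)
    n_expected = len(truth.inversions)
    total_bp = contained_bp = 0
    kinds_ok = True
    double_intervals = None
    for inv in truth.inversions:
        chrom_calls = calls_by_chrom.get(inv["chrom"], [])
        for b in inv["breakpoints"]:
            total_bp += 1
            if any(
                iv.contains_internal(b, slack=k)
                for c in chrom_calls
                for iv in c.intervals
            ):
                contained_bp += 1
        if not any(c.kind == inv["kind"] for c in chrom_calls):
            kinds_ok = False
        if inv["kind"] == "double" and chrom_calls:
            doubles = [c for c in chrom_calls if c.kind == "double"]
            if doubles:
                double_intervals = len(doubles[0].intervals)
    return {
        "n_calls": len(calls),
        "n_expected": n_expected,
        "breakpoints_total": total_bp,
        "breakpoints_contained": contained_bp,
        "kinds_ok": kinds_ok,
        "double_interval_count": double_intervals,
        "calls": calls,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# anchoring recovery


def _builder_config(seed: int) -> SimConfig:
    # The builder is scored against the reference marker arrangement, so the
    # anchoring study condition carries no inversions; density, contig
    # length and chimera rate stay at the generator defaults.
    return SimConfig(seed=seed, inversion_specs=[])


def run_build(contigs, markers, min_votes: int = 2, gap_len: int = 500):
    """Placement -> chimera resolution -> assignment -> ordered builds."""
    placements = builder.place_markers(contigs, markers)
    contigs2, placements, report = builder.resolve_chimeras(
        contigs, placements, min_votes
    )
    assignments = builder.assign_contigs(placements, contigs2, min_votes)
    lengths = {c.id: c.length for c in contigs2}
    builds = builder.order_and_orient(assignments, placements, lengths, gap_len)
    return contigs2, placements, assignments, builds, report


def anchoring_recovery(seed: int, config: SimConfig | None = None) -> dict:
    """Fragment a simulated genome, rebuild chromosomes from the marker
    map, and score chimera detection, ordering and orientation."""
    if config is None:
        config = _builder_config(seed)
    ref, alt, contigs, markers, truth = simulate_all(config)
    contigs2, placements, assignments, builds, report = run_build(
        contigs, markers
    )
    truth_chimeras = {
        cid for cid, t in truth.contigs.items() if t["chimeric"]
    }
    flagged = set(report["flagged"])
    single_source = {
        cid: t["components"][0]
        for cid, t in truth.contigs.items()
        if not t["chimeric"]
    }
    ok_pairs = n_pairs = 0
    ok_orient = n_orient = 0
    by_contig_pl: dict[str, list] = {}
    for p in placements:
        if p.status == "placed":
            by_contig_pl.setdefault(p.contig_id, []).append(p)
    for lg, build in builds.items():
        comp = [cid for cid, _, _ in build.components if cid in single_source]
        for a, b in zip(comp, comp[1:]):
            if single_source[a]["chrom"] != single_source[b]["chrom"]:
                continue
            n_pairs += 1
            if single_source[a]["start"] < single_source[b]["start"]:
                ok_pairs += 1
        for cid, orient, _ in build.components:
            if cid not in single_source or orient == "?":
                continue
            cms = {p.female_cM for p in by_contig_pl.get(cid, [])}
            if len(cms) < 2:
                continue
            n_orient += 1
            if orient == single_source[cid]["strand"]:
                ok_orient += 1
    stats = builder.anchoring_stats(builds, contigs2, placements)
    return {
        "truth_chimeras": sorted(truth_chimeras),
        "flagged": sorted(flagged),
        "all_chimeras_flagged": truth_chimeras <= flagged,
        "false_flags": sorted(flagged - truth_chimeras),
        "broken": report["broken"],
        "order_pairs": n_pairs,
        "order_correct": ok_pairs,
        "orient_total": n_orient,
        "orient_correct": ok_orient,
        "stats": stats,
        "builds": builds,
        "placements": placements,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# centromere recovery


def centromere_recovery(seed: int, config: SimConfig | None = None) -> dict:
    """Scan a simulated genome for tandem arrays and check that the planted
    satellite is the unique family passing the centromere filter."""
    if config is None:
        config = SimConfig(seed=seed)
    else:
        config = dataclasses.replace(config, seed=seed)
    ref, truth = simulate_reference(config)
    arrays = centromere.detect_genome_arrays(ref)
    filtered = centromere.filter_candidates(arrays)
    families = centromere.cluster_families(filtered)
    candidates = centromere.centromere_candidates(
        families, config.n_chromosomes
    )
    planted_ok = False
    if len(candidates) == 1:
        planted_ok = (
            centromere._pair_identity(
                candidates[0].consensus, truth.element
            )
            >= 0.95
        )
    n_planted = config.n_chromosomes * config.centromere_spec.copies_per_array
    count, positions = centromere.count_occurrences(ref, truth.element)
    return {
        "n_arrays": len(arrays),
        "n_filtered": len(filtered),
        "n_families": len(families),
        "n_candidates": len(candidates),
        "candidate_is_planted": planted_ok,
        "n_planted_copies": n_planted,
        "count": count,
        "positions": positions,
        "candidates": candidates,
        "truth": truth,
        "ref": ref,
    }


def clean_count_check(seed: int, n_chroms: int = 3, chrom_len: int = 200_000,
                      copies: int = 7) -> dict:
    """Plant exact (unmutated) element copies on a clean random background
    and check count_occurrences recovers the planted count exactly, in
    agreement with the brute-force scanner."""
    from .io import SequenceRecord
    from .simulate import CentromereSpec, build_centromere_element, _random_seq

    rng = np.random.default_rng(seed)
    element = build_centromere_element(CentromereSpec(), rng)
    genome = []
    planted = 0
    for i in range(n_chroms):
        seq = _random_seq(chrom_len, 0.46, rng)
        step = chrom_len // (copies + 1)
        for j in range(1, copies + 1):  # well-separated exact copies
            p = j * step
            seq = seq[:p] + element + seq[p + len(element):]
            planted += 1
        genome.append(SequenceRecord(f"c{i}", seq))
    count, _ = centromere.count_occurrences(genome, element)
    brute = sum(
        centromere.bruteforce_count(rec.sequence, element) for rec in genome
    )
    return {"planted": planted, "count": count, "brute": brute}


# ---------------------------------------------------------------------------
# morphology and co-location


def morphology_recovery(
    seed: int, terminal: bool = False, config: SimConfig | None = None
) -> dict:
    """Simulate central (metacentric) or near-terminal centromere arrays,
    recover suppressed regions from the marker map, classify morphology,
    and test co-location with the repeat density peak."""
    if config is None:
        config = SimConfig(seed=seed, inversion_specs=[])
    if terminal:
        spec = dataclasses.replace(
            config.centromere_spec, array_position_fraction=0.05
        )
        config = dataclasses.replace(config, centromere_spec=spec)
    ref, truth = simulate_reference(config)
    markers = simulate_marker_map(ref, truth, config)
    tracks = None
    if not terminal:  # co-location is only scored for metacentrics
        _, positions = centromere.count_occurrences(ref, truth.element)
        tracks = centromere.density_track(
            positions, {r.id: r.length for r in ref}
        )
    points_by_chrom: dict[str, list[recomb.MapPoint]] = {}
    for m in truth.markers:
        points_by_chrom.setdefault(m["chrom"], []).append(
            recomb.MapPoint(
                m["marker_id"], m["chrom"], m["pos"], m["female_cM"],
                m["male_cM"],
            )
        )
    lengths = {r.id: r.length for r in ref}
    results = {}
    for chrom, pts in points_by_chrom.items():
        rates = recomb.window_rates(pts, lengths[chrom])
        region = recomb.find_suppressed(rates, chrom=chrom)
        call = recomb.classify_morphology(region, lengths[chrom], chrom=chrom)
        if region is not None and tracks is not None:
            flag, dist = recomb.colocalize(region, tracks[chrom])
            call.colocated_with_repeat = flag
        results[chrom] = call
    all_points = [p for pts in points_by_chrom.values() for p in pts]
    stats = recomb.map_stats(all_points)
    expected = "non_metacentric" if terminal else "metacentric"
    n_ok = sum(1 for c in results.values() if c.morphology == expected)
    meta = [c for c in results.values() if c.morphology == "metacentric"]
    n_coloc = sum(1 for c in meta if c.colocated_with_repeat)
    return {
        "calls": results,
        "expected": expected,
        "n_chroms": len(results),
        "n_correct": n_ok,
        "n_metacentric": len(meta),
        "n_colocated": n_coloc,
        "map_stats": stats,
    }


# ---------------------------------------------------------------------------
# chaining oracle


def random_anchor_instance(rng: np.random.Generator, max_anchors: int = 12):
    """A random chaining instance: disjoint query intervals with scrambled
    target intervals on one chromosome pair and strand."""
    n = int(rng.integers(2, max_anchors + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    q_starts = np.cumsum(rng.integers(50, 2000, size=n))
    lengths = rng.integers(30, 500, size=n)
    t_order = rng.permutation(n)
    t_starts = np.cumsum(rng.integers(50, 2000, size=n))
    anchors = []
    for i in range(n):
        ts = int(t_starts[t_order[i]])
        anchors.append(
            synteny.Anchor(
                "q", int(q_starts[i]), int(q_starts[i] + lengths[i]),
                "t", ts, ts + int(lengths[i]), strand,
            )
        )
    return anchors


def brute_force_max_chain_weight(anchors, max_gap: int) -> int:
    """Exhaustive maximum-weight co-linear chain (consecutive-pair gap and
    order constraints), by depth-first enumeration."""
    anchors = sorted(anchors, key=lambda a: a.q_start)
    n = len(anchors)

    def compatible(a, b) -> bool:
        gq = b.q_start - a.q_end
        if a.strand == "+":
            gt = b.t_start - a.t_end
        else:
            gt = a.t_start - b.t_end
        return 0 <= gq <= max_gap and 0 <= gt <= max_gap

    best = 0

    def dfs(last: int, weight: int):
        nonlocal best
        best = max(best, weight)
        for j in range(last + 1, n):
            if last < 0 or compatible(anchors[last], anchors[j]):
                dfs(j, weight + anchors[j].length)

    dfs(-1, 0)
    return best


def dp_max_chain_weight(anchors, max_gap: int) -> int:
    """First-chain weight from the production chaining routine."""
    group = sorted(anchors, key=lambda a: a.q_start)
    qs = np.array([a.q_start for a in group], dtype=np.int64)
    qe = np.array([a.q_end for a in group], dtype=np.int64)
    ts = np.array([a.t_start for a in group], dtype=np.int64)
    te = np.array([a.t_end for a in group], dtype=np.int64)
    w = qe - qs
    _, weight = synteny._best_chain(
        qs, qe, ts, te, w, group[0].strand, max_gap
    )
    return weight


def chain_oracle_agreement(seed: int, n_instances: int = 100) -> dict:
    """Fraction of random small instances where the production chainer
    finds the exhaustive maximum-weight chain."""
    rng = np.random.default_rng(seed)
    n_ok = 0
    for _ in range(n_instances):
        anchors = random_anchor_instance(rng)
        max_gap = int(rng.integers(500, 5000))
        if dp_max_chain_weight(anchors, max_gap) == brute_force_max_chain_weight(
            anchors, max_gap
        ):
            n_ok += 1
    return {"n_instances": n_instances, "n_agree": n_ok}
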