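"""Marker placement, linkage-group assignment, chimera breaking, and
chromosome construction."""

import numpy as np
import pytest

from codmap import builder, io
from codmap._kmer import revcomp
from codmap.io import MarkerRow, SequenceRecord


def _marker(mid, lg, f, m, left, right):
    return MarkerRow(mid, lg, f, m, left, right)


def brute_force_place(contigs, left, right):
    """Independent oracle: scan both strands of every contig for the
    flank_left + SNP + flank_right pattern with python string search."""
    hits = []
    for c in contigs:
        for strand, seq in (("+", c.sequence), ("-", revcomp(c.sequence))):
            start = 0
            while True:
                i = seq.find(left, start)
                if i < 0:
                    break
                j = i + len(left) + 1
                if seq[j : j + len(right)] == right:
                    snp = i + len(left)
                    if strand == "-":
                        snp = c.length - 1 - snp
                    hits.append((c.id, snp, strand))
                start = i + 1
    return sorted(set(hits))


class TestPlaceMarkers:
    def test_flanks_cut_from_contig_place_forward(self, make_dna):
        seq = make_dna(1000)
        pos = 500
        contig = SequenceRecord("c1", seq)
        m = _marker("m1", 1, 0, 0, seq[pos - 50 : pos], seq[pos + 1 : pos + 51])
        (pl,) = builder.place_markers([contig], [m])
        assert (pl.status, pl.contig_id, pl.position, pl.strand) == (
            "placed",
            "c1",
            pos,
            "+",
        )

    def test_reverse_complement_contig_mirrors_coordinate(self, make_dna):
        seq = make_dna(1000)
        pos = 321
        m = _marker("m1", 1, 0, 0, seq[pos - 50 : pos], seq[pos + 1 : pos + 51])
        rc = SequenceRecord("c1", revcomp(seq))
        (pl,) = builder.place_markers([rc], [m])
        oracle = brute_force_place([rc], m.flank_left, m.flank_right)
        assert oracle == [("c1", 1000 - 1 - pos, "-")]
        assert (pl.status, pl.position, pl.strand) == ("placed", 1000 - 1 - pos, "-")

    def test_duplicated_flanks_are_ambiguous(self, make_dna):
        insert = make_dna(120)
        filler = make_dna(300)
        seq = filler + insert + make_dna(200) + insert + filler
        contig = SequenceRecord("c1", seq)
        m = _marker("m1", 1, 0, 0, insert[:50], insert[51:101])
        (pl,) = builder.place_markers([contig], [m])
        assert pl.status == "ambiguous"

    def test_mismatch_fallback_places_mutated_flank(self, make_dna):
        seq = make_dna(1000)
        pos = 500
        right = seq[pos + 1 : pos + 51]
        # two substitutions beyond the seed region
        mutated = right[:40] + ("A" if right[40] != "A" else "C") + right[41:]
        m = _marker("m1", 1, 0, 0, seq[pos - 50 : pos], mutated)
        (pl,) = builder.place_markers([SequenceRecord("c1", seq)], [m])
        assert pl.status == "placed" and pl.position == pos

    def test_short_flanks_absent_with_reason(self, make_dna):
        contig = SequenceRecord("c1", make_dna(500))
        m = _marker("m1", 1, 0, 0, "ACGT", "ACGT")
        (pl,) = builder.place_markers([contig], [m])
        assert pl.status == "absent" and "flank" in pl.reason


def _placed(mid, lg, contig, pos, f=0.0, m=0.0):
    return builder.MarkerPlacement(
        mid, lg, f, m, contig, pos, "+", "placed"
    )


class TestAssign:
    def test_unanimous(self):
        pls = [_placed(f"m{i}", 3, "c1", 100 * i) for i in range(3)]
        (a,) = builder.assign_contigs(pls)
        assert (a.lg, a.is_chimeric) == (3, False)

    def test_two_supported_lgs_flag_chimera(self):
        pls = [_placed(f"m{i}", 1, "c1", 100 * i) for i in range(3)] + [
            _placed(f"n{i}", 2, "c1", 1000 + 100 * i) for i in range(2)
        ]
        (a,) = builder.assign_contigs(pls, min_votes=2)
        assert a.is_chimeric and a.discordant_lgs == [1, 2] and a.lg == 1

    def test_singleton_discordance_is_noise(self):
        pls = [_placed(f"m{i}", 1, "c1", 100 * i) for i in range(3)] + [
            _placed("n0", 2, "c1", 900)
        ]
        (a,) = builder.assign_contigs(pls, min_votes=2)
        assert (a.lg, a.is_chimeric) == (1, False)

    def test_markerless_contig_unassigned(self):
        contigs = [SequenceRecord("c1", "ACGT"), SequenceRecord("c2", "ACGT")]
        pls = [_placed("m0", 1, "c1", 1), _placed("m1", 1, "c1", 2)]
        a = builder.assign_contigs(pls, contigs)
        assert a[1].lg is None and a[1].n_markers == 0


class TestBreakChimera:
    def test_midpoint_rule(self, make_dna):
        contig = SequenceRecord("c1", make_dna(10_000))
        pls = [
            _placed("m1", 1, "c1", 1000),
            _placed("m2", 1, "c1", 2000),
            _placed("m3", 2, "c1", 8000),
        ]
        child_a, child_b, split, updated = builder.break_chimera(contig, pls)
        assert split == 5000
        assert child_a.length == 5000 and child_b.length == 5000
        a_markers = [p for p in updated if p.contig_id == "c1_a"]
        assert {p.lg for p in a_markers} == {1}
        (b_marker,) = [p for p in updated if p.contig_id == "c1_b"]
        assert b_marker.position == 3000

    def test_marker_distance_to_retained_end_unchanged(self, make_dna):
        contig = SequenceRecord("c1", make_dna(10_000))
        pls = [
            _placed("m1", 1, "c1", 1000),
            _placed("m2", 1, "c1", 2000),
            _placed("m3", 2, "c1", 8000),
        ]
        child_a, child_b, split, updated = builder.break_chimera(contig, pls)
        # 5' markers keep their distance to the contig start; 3' markers
        # keep their distance to the contig end
        for p in updated:
            if p.contig_id == "c1_a":
                assert p.position in (1000, 2000)
            else:
                assert child_b.length - p.position == 10_000 - 8000

    def test_interleaved_lgs_dropped(self, make_dna):
        contig = SequenceRecord("c1", make_dna(10_000))
        pls = [
            _placed(f"m{i}", 1 + i % 2, "c1", 500 * (i + 1)) for i in range(8)
        ]
        with pytest.warns(UserWarning, match="dropping"):
            assert builder.break_chimera(contig, pls) is None


class TestOrderOrient:
    def test_sort_by_mean_female_cm(self):
        pls = []
        for cid, cms in (("a", [10.0]), ("b", [5.0]), ("c", [20.0])):
            for i, cm in enumerate(cms):
                pls.append(_placed(f"{cid}{i}", 1, cid, 100 + i, cm, cm))
            pls.append(_placed(f"{cid}x", 1, cid, 200, cms[0], cms[0]))
        assignments = builder.assign_contigs(pls)
        builds = builder.order_and_orient(
            assignments, pls, {"a": 300, "b": 300, "c": 300}
        )
        assert [cid for cid, _, _ in builds[1].components] == ["b", "a", "c"]

    def test_decreasing_cm_gives_minus(self):
        pls = [
            _placed("m1", 1, "c1", 100, 2.0, 2.0),
            _placed("m2", 1, "c1", 900, 1.0, 1.0),
        ]
        assignments = builder.assign_contigs(pls)
        builds = builder.order_and_orient(assignments, pls, {"c1": 1000})
        assert builds[1].components[0][1] == "-"

    def test_tied_cm_flags_unoriented(self):
        pls = [
            _placed("m1", 1, "c1", 100, 2.0, 1.0),
            _placed("m2", 1, "c1", 900, 2.0, 1.0),
        ]
        assignments = builder.assign_contigs(pls)
        builds = builder.order_and_orient(assignments, pls, {"c1": 1000})
        assert builds[1].components[0][1] == "?"
        assert builds[1].flagged_unoriented == ["c1"]


class TestConcatenate:
    def test_two_contigs_with_gap(self, make_dna):
        c1 = SequenceRecord("c1", make_dna(100))
        c2 = SequenceRecord("c2", make_dna(100))
        build = builder.ChromosomeBuild(
            3, [("c1", "+", 100), ("c2", "-", 100)], gap_len=500
        )
        rec, agp = builder.concatenate(build, {"c1": c1, "c2": c2})
        assert rec.length == 700 == build.total_length
        assert rec.sequence == c1.sequence + "N" * 500 + revcomp(c2.sequence)
        io.validate_agp(agp)
        assert sum(c.span() for c in agp) == rec.length

    def test_single_contig_lg_equals_contig(self, make_dna):
        c1 = SequenceRecord("c1", make_dna(250))
        build = builder.ChromosomeBuild(14, [("c1", "-", 250)])
        rec, agp = builder.concatenate(build, {"c1": c1})
        assert rec.sequence == revcomp(c1.sequence)
        assert len(agp) == 1

    def test_missing_sequence_is_hard_error(self):
        build = builder.ChromosomeBuild(1, [("c1", "+", 100)])
        with pytest.raises(ValueError, match="c1"):
            builder.concatenate(build, {})


class TestStats:
    def test_fraction_and_mean(self):
        contigs = [
            SequenceRecord("a", "A" * 300),
            SequenceRecord("b", "A" * 200),
            SequenceRecord("c", "A" * 400),
            SequenceRecord("d", "A" * 100),
        ]
        pls = [_placed(f"m{i}", 1, "a", i) for i in range(3)] + [
            _placed(f"n{i}", 1, "b", i) for i in range(5)
        ]
        builds = {
            1: builder.ChromosomeBuild(1, [("a", "+", 300), ("b", "+", 200)])
        }
        st = builder.anchoring_stats(builds, contigs, pls)
        assert st.n_contigs_anchored == 2
        assert st.fraction_of_assembly == pytest.approx(0.5)
        assert st.mean_markers_per_contig == pytest.approx(4.0)
        assert st.n_contigs_lt5_markers == 1


def test_map_points_follow_orientation(make_dna):
    build = builder.ChromosomeBuild(
        1, [("a", "+", 100), ("b", "-", 100)], gap_len=10
    )
    pls = [
        _placed("m1", 1, "a", 20, 1.0, 1.0),
        _placed("m2", 1, "b", 30, 2.0, 2.0),
    ]
    pts = builder.map_points_on_build(build, pls)
    assert pts[0][1] == 20
    # contig b starts at 110; a '-' contig mirrors the marker offset
    assert pts[1][1] == 110 + (100 - 1 - 30)
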