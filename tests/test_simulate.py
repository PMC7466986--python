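"""Ground-truth generator: determinism, planted structures, map shape."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from codmap._kmer import revcomp
from codmap.io import SequenceRecord
from codmap.simulate import (
    CentromereSpec,
    InversionSpec,
    SimConfig,
    SimTruth,
    apply_inversions,
    build_centromere_element,
    fragment_into_contigs,
    map_derived_to_reference,
    simulate_marker_map,
    simulate_reference,
)


def small_config(**kw):
    defaults = dict(
        n_chromosomes=2,
        chrom_length_bp=120_000,
        inversion_specs=[],
        centromere_spec=CentromereSpec(copies_per_array=5),
        contig_mean_len=20_000,
        chimera_rate=0.0,
        decoy_chroms=0,
        suppression_window_bp=30_000,
        seed=7,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestReference:
    def test_seed_determinism(self):
        cfg = small_config()
        g1, _ = simulate_reference(cfg)
        g2, _ = simulate_reference(cfg)
        assert [r.sequence for r in g1] == [r.sequence for r in g2]

    def test_gc_zero_gives_at_only(self):
        cfg = small_config(gc_fraction=0.0, decoy_chroms=0)
        genome, truth = simulate_reference(cfg)
        # outside the planted arrays the background is strictly A/T
        s, e = truth.centromeres["chr01"]
        arm = genome[0].sequence[:s]
        assert set(arm) <= {"A", "T"}

    def test_element_length_is_258_by_default(self, rng):
        spec = CentromereSpec()
        elem = build_centromere_element(spec, rng)
        assert spec.element_length == 258 == len(elem)
        # the two 88 bp units are identical and similarly oriented
        assert elem[:88] == elem[170:258]

    def test_element_at_fraction_exact(self, rng):
        elem = build_centromere_element(CentromereSpec(), rng)
        at = (elem.count("A") + elem.count("T")) / len(elem)
        assert at > 0.60

    def test_array_planted_at_position(self):
        cfg = small_config()
        genome, truth = simulate_reference(cfg)
        s, e = truth.centromeres["chr01"]
        assert e - s == 5 * 258
        assert abs((s + e) // 2 - 60_000) < 3000

    def test_array_longer_than_chromosome_errors(self):
        cfg = small_config(
            chrom_length_bp=1000,
            centromere_spec=CentromereSpec(copies_per_array=10),
        )
        with pytest.raises(ValueError, match="longer"):
            simulate_reference(cfg)


class TestInversions:
    def test_empty_specs_identity(self):
        genome = [SequenceRecord("chr01", "ACGTACGT")]
        assert apply_inversions(genome, [])[0].sequence == "ACGTACGT"

    def test_toy_interval(self):
        genome = [SequenceRecord("chr01", "ACGTACGT")]
        out = apply_inversions(genome, [InversionSpec("chr01", 1, 5)])
        assert out[0].sequence == "ATACGCGT"

    def test_involution(self, make_dna):
        genome = [SequenceRecord("chr01", make_dna(5000))]
        spec = [InversionSpec("chr01", 1000, 4000)]
        twice = apply_inversions(apply_inversions(genome, spec), spec)
        assert twice[0].sequence == genome[0].sequence

    def test_double_is_two_sequential_reversals(self, make_dna):
        seq = make_dna(3000)
        genome = [SequenceRecord("chr01", seq)]
        double = apply_inversions(
            genome, [InversionSpec("chr01", 500, 1500, "double", 1500, 2500)]
        )
        manual = seq[:500] + revcomp(seq[500:1500]) + seq[1500:]
        manual = manual[:1500] + revcomp(manual[1500:2500]) + manual[2500:]
        assert double[0].sequence == manual

    def test_overlapping_specs_error(self, make_dna):
        genome = [SequenceRecord("chr01", make_dna(5000))]
        specs = [
            InversionSpec("chr01", 100, 2000),
            InversionSpec("chr01", 1500, 3000),
        ]
        with pytest.raises(ValueError, match="overlap"):
            apply_inversions(genome, specs)

    def test_out_of_bounds_error(self):
        genome = [SequenceRecord("chr01", "ACGT")]
        with pytest.raises(ValueError, match="beyond"):
            apply_inversions(genome, [InversionSpec("chr01", 1, 10)])

    @given(st.integers(0, 10_000))
    def test_coordinate_map_is_involution(self, pos):
        specs = [
            InversionSpec("chr01", 100, 2000),
            InversionSpec("chr01", 3000, 7000, "double", 7000, 9000),
        ]
        # undoing twice returns the original coordinate (each reversal is
        # self-inverse and the intervals are disjoint)
        back = map_derived_to_reference(
            map_derived_to_reference(pos, specs, "chr01"), specs, "chr01"
        )
        assert back == pos


class TestFragmentation:
    def test_conservation_without_chimeras(self):
        cfg = small_config()
        genome, truth = simulate_reference(cfg)
        contigs = fragment_into_contigs(genome, truth, 20_000, 0.0, 3)
        assert sum(c.length for c in contigs) == sum(
            r.length for r in genome
        )

    def test_chimera_rate_one_forces_two_source_contigs(self):
        cfg = small_config()
        genome, truth = simulate_reference(cfg)
        contigs = fragment_into_contigs(
            genome, truth, 60_000, 1.0, 3, chimera_min_len=10_000
        )
        chimeric = [
            cid for cid, t in truth.contigs.items() if t["chimeric"]
        ]
        assert chimeric
        for cid in chimeric:
            comp = truth.contigs[cid]["components"]
            assert len(comp) == 2
            assert comp[0]["chrom"] != comp[1]["chrom"]

    def test_fixed_seed_reproducible(self):
        cfg = small_config()
        genome, t1 = simulate_reference(cfg)
        c1 = fragment_into_contigs(genome, t1, 20_000, 0.2, 11)
        genome2, t2 = simulate_reference(cfg)
        c2 = fragment_into_contigs(genome2, t2, 20_000, 0.2, 11)
        assert [c.sequence for c in c1] == [c.sequence for c in c2]

    def test_sources_tile_each_contig(self):
        cfg = small_config()
        genome, truth = simulate_reference(cfg)
        seqs = {r.id: r.sequence for r in genome}
        contigs = fragment_into_contigs(genome, truth, 30_000, 0.0, 5)
        for c in contigs:
            (comp,) = truth.contigs[c.id]["components"]
            src = seqs[comp["chrom"]][comp["start"] : comp["end"]]
            assert c.sequence == (src if comp["strand"] == "+" else revcomp(src))


class TestMarkerMap:
    def test_female_total_is_expansion_times_male(self):
        cfg = small_config()
        genome, truth = simulate_reference(cfg)
        rows = simulate_marker_map(genome, truth, cfg)
        by_lg = {}
        for r in rows:
            by_lg.setdefault(r.lg, []).append(r)
        for lg, rs in by_lg.items():
            f = max(x.female_cM for x in rs) - min(x.female_cM for x in rs)
            m = max(x.male_cM for x in rs) - min(x.male_cM for x in rs)
            assert f / m == pytest.approx(cfg.female_male_expansion, abs=1e-6)

    def test_flat_profile_is_linear(self):
        cfg = small_config(suppression_window_bp=0)
        genome, truth = simulate_reference(cfg)
        simulate_marker_map(genome, truth, cfg)
        pts = [m for m in truth.markers if m["chrom"] == "chr01"]
        bp = np.array([m["pos"] for m in pts])
        cm = np.array([m["female_cM"] for m in pts])
        rho = np.corrcoef(bp, cm)[0, 1]
        assert rho == pytest.approx(1.0, abs=1e-9)

    def test_flanks_match_genome_at_positions(self):
        cfg = small_config()
        genome, truth = simulate_reference(cfg)
        rows = simulate_marker_map(genome, truth, cfg)
        seqs = {r.id: r.sequence for r in genome}
        by_id = {m["marker_id"]: m for m in truth.markers}
        for r in rows[:50]:
            m = by_id[r.marker_id]
            p, k = m["pos"], cfg.flank_k
            assert seqs[m["chrom"]][p - k : p] == r.flank_left
            assert seqs[m["chrom"]][p + 1 : p + 1 + k] == r.flank_right

    def test_cm_nondecreasing_in_bp(self):
        cfg = small_config()
        genome, truth = simulate_reference(cfg)
        simulate_marker_map(genome, truth, cfg)
        for chrom in ("chr01", "chr02"):
            pts = sorted(
                (m for m in truth.markers if m["chrom"] == chrom),
                key=lambda m: m["pos"],
            )
            cms = [m["male_cM"] for m in pts]
            assert all(b >= a for a, b in zip(cms, cms[1:]))

    def test_markers_inside_inversion_keep_reference_cm(self):
        cfg = small_config(
            inversion_specs=[InversionSpec("chr01", 20_000, 50_000)]
        )
        genome, truth = simulate_reference(cfg)
        alt = apply_inversions(genome, cfg.inversion_specs)
        simulate_marker_map(alt, truth, cfg)
        inside = [
            m
            for m in truth.markers
            if m["chrom"] == "chr01" and 20_000 <= m["pos"] < 50_000
        ]
        assert inside
        for m in inside:
            assert m["pos_ref"] == 20_000 + 50_000 - 1 - m["pos"]


def test_truth_json_round_trip(tmp_path):
    cfg = small_config()
    _, truth = simulate_reference(cfg)
    p = tmp_path / "truth.json"
    truth.to_json(p)
    back = SimTruth.from_json(p)
    assert back.centromeres == truth.centromeres
    assert back.element == truth.element
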