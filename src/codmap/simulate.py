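"""Synthetic genome-pair generator with known ground truth.

Emulates the data situation of a chromosome-level teleost assembly project:
two closely related genomes differing by planted single and double
inversions, centromeric satellite arrays built as unit-spacer-unit elements
(88 + 82 + 88 bp, AT-rich), contig fragmentation with occasional chimeric
joins, and a sex-specific marker map with recombination suppression around
each centromere and a female:male map-length expansion (default 1.3).

Every stage is seeded through :class:`SimConfig`; two runs with the same
config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._kmer import revcomp
from .io import MarkerRow, SequenceRecord

# ---------------------------------------------------------------------------
# configuration


@dataclass
class InversionSpec:
    """A planted rearrangement: one interval, or two applied sequentially."""

    chrom: str
    start: int
    end: int
    kind: str = "single"  # "single" | "double"
    second_start: int | None = None
    second_end: int | None = None

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("inversion start must be < end")
        if self.kind == "double":
            if self.second_start is None or self.second_end is None:
                raise ValueError("double inversion needs a second interval")
            if not self.second_start < self.second_end:
                raise ValueError("second interval start must be < end")
            if (self.start, self.end) == (self.second_start, self.second_end):
                raise ValueError("double inversion intervals must differ")
        elif self.kind != "single":
            raise ValueError(f"unknown inversion kind {self.kind!r}")

    def intervals(self) -> list[tuple[int, int]]:
        if self.kind == "single":
            return [(self.start, self.end)]
        return [(self.start, self.end), (self.second_start, self.second_end)]

    def breakpoints(self) -> list[int]:
        pts = sorted({p for iv in self.intervals() for p in iv})
        return pts


@dataclass
class CentromereSpec:
    """Centromeric satellite: two identical units flanking a spacer.

    Defaults give a 258 bp element (88 + 82 + 88) at 70% AT, comfortably
    above the >60% AT candidate filter downstream.
    """

    unit_len: int = 88
    spacer_len: int = 82
    at_fraction: float = 0.70
    copies_per_array: int = 20
    array_position_fraction: float | list[float] = 0.5
    copy_mutation_rate: float = 0.02

    @property
    def element_length(self) -> int:
        return 2 * self.unit_len + self.spacer_len

    def position_fraction(self, chrom_index: int) -> float:
        if isinstance(self.array_position_fraction, (int, float)):
            return float(self.array_position_fraction)
        return float(self.array_position_fraction[chrom_index])


def _default_inversions() -> list[InversionSpec]:
    # A double on chromosome 1 (two serial, boundary-sharing intervals) and
    # singles on chromosomes 2, 7 and 12, mirroring the four cod supergene
    # linkage groups; positioned away from the default centromere at 1.0 Mb.
    return [
        InversionSpec("chr01", 200_000, 700_000, "double", 700_000, 1_200_000),
        InversionSpec("chr02", 200_000, 700_000),
        InversionSpec("chr07", 1_200_000, 1_700_000),
        InversionSpec("chr12", 300_000, 850_000),
    ]


@dataclass
class SimConfig:
    """Study conditions for the desk-scale synthetic genome pair."""

    n_chromosomes: int = 23
    chrom_length_bp: int | list[int] = 2_000_000
    gc_fraction: float = 0.46
    inversion_specs: list[InversionSpec] = field(
        default_factory=_default_inversions
    )
    centromere_spec: CentromereSpec = field(default_factory=CentromereSpec)
    marker_density: float = 100.0  # markers per Mb
    contig_mean_len: int = 150_000
    chimera_rate: float = 0.01
    chimera_min_len: int = 100_000
    female_male_expansion: float = 1.3
    male_cM_per_chrom: float = 54.9
    suppression_window_bp: int = 300_000
    suppressed_rate_fraction: float = 0.02  # residual rate inside the window
    snp_divergence: float = 0.002
    flank_k: int = 50
    decoy_chroms: int = 3
    decoy_period: int = 120
    decoy_copies: int = 15
    decoy_position_fraction: float = 0.8
    decoy_at_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self):
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be positive")
        for r in (self.chimera_rate, self.gc_fraction, self.snp_divergence):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.female_male_expansion < 1.0:
            raise ValueError("female_male_expansion must be >= 1")
        if min(self.chrom_lengths()) <= 0:
            raise ValueError("chromosome lengths must be positive")

    def chrom_lengths(self) -> list[int]:
        if isinstance(self.chrom_length_bp, int):
            return [self.chrom_length_bp] * self.n_chromosomes
        if len(self.chrom_length_bp) != self.n_chromosomes:
            raise ValueError("per-chromosome length list has wrong length")
        return list(self.chrom_length_bp)

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1:02d}" for i in range(self.n_chromosomes)]


@dataclass
class SimTruth:
    """Ground truth of one simulated genome pair."""

    inversions: list[dict] = field(default_factory=list)
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)
    decoys: dict[str, tuple[int, int]] = field(default_factory=dict)
    element: str = ""
    decoy_element: str = ""
    contigs: dict[str, dict] = field(default_factory=dict)
    markers: list[dict] = field(default_factory=list)
    unanchorable: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        truth = cls(**d)
        truth.centromeres = {k: tuple(v) for k, v in truth.centromeres.items()}
        truth.decoys = {k: tuple(v) for k, v in truth.decoys.items()}
        return truth


# ---------------------------------------------------------------------------
# sequence construction helpers

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = np.searchsorted(np.cumsum(p), rng.random(n), side="right")
    return _BASES[np.minimum(idx, 3)].tobytes().decode("ascii")


def _random_at_seq(n: int, at_fraction: float, rng: np.random.Generator) -> str:
    """Random sequence with an exact A+T count of round(at_fraction * n)."""
    n_at = int(round(at_fraction * n))
    at = rng.choice(np.frombuffer(b"AT", dtype=np.uint8), size=n_at)
    gc = rng.choice(np.frombuffer(b"CG", dtype=np.uint8), size=n - n_at)
    arr = np.concatenate([at, gc])
    rng.shuffle(arr)
    return arr.tobytes().decode("ascii")


def build_centromere_element(
    spec: CentromereSpec, rng: np.random.Generator
) -> str:
    """One unit-spacer-unit monomer; the two units are identical copies."""
    unit = _random_at_seq(spec.unit_len, spec.at_fraction, rng)
    spacer = _random_at_seq(spec.spacer_len, spec.at_fraction, rng)
    return unit + spacer + unit


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hit:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode("ascii")


def _tandem_array(
    element: str, copies: int, mutation_rate: float, rng: np.random.Generator
) -> str:
    return "".join(_mutate(element, mutation_rate, rng) for _ in range(copies))


# ---------------------------------------------------------------------------
# operations


def simulate_reference(config: SimConfig) -> tuple[list[SequenceRecord], SimTruth]:
    """Random genome with planted centromeric (and decoy) tandem arrays.

    Bases are i.i.d. at the configured GC; each chromosome carries one
    satellite array centred at its ``array_position_fraction``. The first
    ``decoy_chroms`` chromosomes additionally carry an AT-rich decoy family
    that passes the composition filter but not the all-chromosome one.
    """
    rng = np.random.default_rng(config.seed)
    spec = config.centromere_spec
    element = build_centromere_element(spec, rng)
    decoy_element = _random_at_seq(
        config.decoy_period, config.decoy_at_fraction, rng
    )
    truth = SimTruth(element=element, decoy_element=decoy_element)
    genome: list[SequenceRecord] = []
    lengths = config.chrom_lengths()
    for ci, (name, L) in enumerate(zip(config.chrom_names(), lengths)):
        seq = _random_seq(L, config.gc_fraction, rng)
        array = _tandem_array(
            element, spec.copies_per_array, spec.copy_mutation_rate, rng
        )
        if len(array) > L:
            raise ValueError(
                f"centromere array ({len(array)} bp) longer than {name}"
            )
        centre = int(spec.position_fraction(ci) * L)
        start = min(max(0, centre - len(array) // 2), L - len(array))
        seq = seq[:start] + array + seq[start + len(array):]
        truth.centromeres[name] = (start, start + len(array))
        if ci < config.decoy_chroms:
            darr = _tandem_array(
                decoy_element,
                config.decoy_copies,
                spec.copy_mutation_rate,
                rng,
            )
            dstart = min(
                max(0, int(config.decoy_position_fraction * L) - len(darr) // 2),
                L - len(darr),
            )
            cs, ce = truth.centromeres[name]
            if not (dstart + len(darr) <= cs or dstart >= ce):
                raise ValueError("decoy array overlaps centromere array")
            seq = seq[:dstart] + darr + seq[dstart + len(darr):]
            truth.decoys[name] = (dstart, dstart + len(darr))
        genome.append(SequenceRecord(name, seq))
    for ispec in config.inversion_specs:
        truth.inversions.append(
            {
                "chrom": ispec.chrom,
                "kind": ispec.kind,
                "intervals": ispec.intervals(),
                "breakpoints": ispec.breakpoints(),
            }
        )
    return genome, truth


def apply_inversions(
    genome: list[SequenceRecord], specs: list[InversionSpec]
) -> list[SequenceRecord]:
    """Reverse-complement each specified interval (doubles sequentially).

    Distinct specs may not overlap on one chromosome: simultaneous
    application would be ambiguous; apply them sequentially instead.
    """
    by_chrom: dict[str, list[InversionSpec]] = {}
    for s in specs:
        by_chrom.setdefault(s.chrom, []).append(s)
    lengths = {r.id: r.length for r in genome}
    for chrom, chrom_specs in by_chrom.items():
        if chrom not in lengths:
            raise ValueError(f"inversion on unknown chromosome {chrom!r}")
        outer = [(min(p for p, _ in s.intervals()),
                  max(e for _, e in s.intervals())) for s in chrom_specs]
        outer.sort()
        for (s1, e1), (s2, e2) in zip(outer, outer[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping inversion specs on {chrom}; "
                    "apply them sequentially instead"
                )
        for s in chrom_specs:
            for _, e in s.intervals():
                if e > lengths[chrom]:
                    raise ValueError(f"inversion beyond end of {chrom}")
    out = []
    for rec in genome:
        seq = rec.sequence
        for s in by_chrom.get(rec.id, []):
            for a, b in s.intervals():
                seq = seq[:a] + revcomp(seq[a:b]) + seq[b:]
        out.append(SequenceRecord(rec.id, seq))
    return out


def map_derived_to_reference(pos: int, specs: list[InversionSpec], chrom: str) -> int:
    """Map a coordinate on the rearranged genome back to the reference
    arrangement by undoing the inversions in reverse order."""
    steps: list[tuple[int, int]] = []
    for s in specs:
        if s.chrom == chrom:
            steps.extend(s.intervals())
    for a, b in reversed(steps):
        if a <= pos < b:
            pos = a + b - 1 - pos
    return pos


def apply_snp_divergence(
    genome: list[SequenceRecord], rate: float, rng: np.random.Generator
) -> list[SequenceRecord]:
    """Uniform substitution divergence (no indels) to stress anchoring."""
    return [
        SequenceRecord(r.id, _mutate(r.sequence, rate, rng)) for r in genome
    ]


def fragment_into_contigs(
    genome: list[SequenceRecord],
    truth: SimTruth,
    mean_len: int,
    chimera_rate: float,
    rng: np.random.Generator | int,
    chimera_min_len: int = 100_000,
) -> list[SequenceRecord]:
    """Cut chromosomes at exponentially spaced points into contigs.

    With probability ``chimera_rate`` a fragment of at least
    ``chimera_min_len`` is joined to a fragment from a different chromosome,
    emulating an assembler misjoin; the junction carries no sequence
    signature. Each emitted contig is reverse-complemented with probability
    0.5. Source intervals (and the chimera flag) are recorded in ``truth``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    fragments: list[tuple[str, int, int]] = []
    for rec in genome:
        if mean_len >= rec.length:
            fragments.append((rec.id, 0, rec.length))
            continue
        pos = 0
        while pos < rec.length:
            step = max(1, int(rng.exponential(mean_len)))
            end = min(rec.length, pos + step)
            fragments.append((rec.id, pos, end))
            pos = end
    seqs = {r.id: r.sequence for r in genome}
    used = [False] * len(fragments)
    contigs: list[SequenceRecord] = []
    counter = 0
    for i, frag in enumerate(fragments):
        if used[i]:
            continue
        used[i] = True
        components = [frag]
        chimeric = False
        flen = frag[2] - frag[1]
        if flen >= chimera_min_len and rng.random() < chimera_rate:
            partners = [
                j
                for j, f in enumerate(fragments)
                if not used[j]
                and f[0] != frag[0]
                and (f[2] - f[1]) >= chimera_min_len
            ]
            if partners:
                j = partners[rng.integers(len(partners))]
                used[j] = True
                components.append(fragments[j])
                chimeric = True
        seq = "".join(seqs[c][s:e] for c, s, e in components)
        comp_records = [
            {"chrom": c, "start": s, "end": e, "strand": "+"}
            for c, s, e in components
        ]
        if rng.random() < 0.5:
            seq = revcomp(seq)
            comp_records = [
                {**c, "strand": "-"} for c in reversed(comp_records)
            ]
        counter += 1
        name = f"ctg{counter:05d}"
        contigs.append(SequenceRecord(name, seq))
        truth.contigs[name] = {
            "components": comp_records,
            "chimeric": chimeric,
        }
    return contigs


def _cumulative_cM(
    pos: np.ndarray,
    L: int,
    window: tuple[int, int],
    total_cM: float,
    residual: float,
) -> np.ndarray:
    """Genetic position at ``pos`` under a flat rate with a suppression
    window where the rate drops to ``residual`` of background."""
    w0, w1 = max(0, window[0]), min(L, window[1])
    w = max(0, w1 - w0)

    def covered(x):
        x = np.asarray(x, dtype=float)
        inside = np.clip(x, w0, w1) - w0
        return (x - inside) + residual * inside

    total_cov = covered(np.array([L]))[0]
    if total_cov <= 0:
        return np.zeros_like(pos, dtype=float)
    return total_cM * covered(pos) / total_cov


def simulate_marker_map(
    genome: list[SequenceRecord], truth: SimTruth, config: SimConfig
) -> list[MarkerRow]:
    """Place SNP markers uniformly and assign sex-specific cM positions.

    ``genome`` is the rearranged (contig-source) genome; cM positions follow
    the *reference* arrangement, so markers inside planted inversions carry
    the non-inverted genetic coordinates. The female map is the male map
    scaled by ``female_male_expansion`` (same suppression window). Flanks
    are the +-``flank_k`` bp around each SNP site, cut from ``genome``.
    """
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31) + 1)
    k = config.flank_k
    rows: list[MarkerRow] = []
    names = config.chrom_names()
    for rec in genome:
        lg = names.index(rec.id) + 1
        L = rec.length
        n_markers = int(round(config.marker_density * L / 1e6))
        if n_markers < 2:
            warnings.warn(f"{rec.id}: fewer than 2 markers; unanchorable")
            truth.unanchorable.append(rec.id)
        lo, hi = k, L - k - 1
        n_markers = min(n_markers, max(0, hi - lo))
        pos = np.sort(
            rng.choice(np.arange(lo, hi, dtype=np.int64), n_markers, replace=False)
        )
        ref_pos = np.array(
            [
                map_derived_to_reference(int(p), config.inversion_specs, rec.id)
                for p in pos
            ]
        )
        c0, c1 = truth.centromeres[rec.id]
        centre = (c0 + c1) // 2
        w = config.suppression_window_bp
        window = (centre - w // 2, centre + w // 2)
        male = _cumulative_cM(
            ref_pos, L, window, config.male_cM_per_chrom,
            config.suppressed_rate_fraction,
        )
        female = config.female_male_expansion * male
        for i, p in enumerate(pos):
            p = int(p)
            marker_id = f"snp_{rec.id}_{i:04d}"
            rows.append(
                MarkerRow(
                    marker_id,
                    lg,
                    round(float(female[i]), 6),
                    round(float(male[i]), 6),
                    rec.sequence[p - k : p],
                    rec.sequence[p + 1 : p + 1 + k],
                )
            )
            truth.markers.append(
                {
                    "marker_id": marker_id,
                    "chrom": rec.id,
                    "pos": p,
                    "pos_ref": int(ref_pos[i]),
                    "female_cM": round(float(female[i]), 6),
                    "male_cM": round(float(male[i]), 6),
                }
            )
    return rows


def simulate_pair(
    config: SimConfig,
) -> tuple[list[SequenceRecord], list[SequenceRecord], SimTruth]:
    """Reference genome, rearranged+diverged genome, and ground truth."""
    ref, truth = simulate_reference(config)
    alt = apply_inversions(ref, config.inversion_specs)
    div_rng = np.random.default_rng(
        np.random.default_rng(config.seed).integers(2**31) + 2
    )
    alt = apply_snp_divergence(alt, config.snp_divergence, div_rng)
    return ref, alt, truth


def simulate_all(config: SimConfig):
    """Full bundle: (ref, alt, contigs, markers, truth)."""
    ref, alt, truth = simulate_pair(config)
    frag_rng = np.random.default_rng(
        np.random.default_rng(config.seed).integers(2**31) + 3
    )
    contigs = fragment_into_contigs(
        alt,
        truth,
        config.contig_mean_len,
        config.chimera_rate,
        frag_rng,
        config.chimera_min_len,
    )
    markers = simulate_marker_map(alt, truth, config)
    return ref, alt, contigs, markers, truth
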