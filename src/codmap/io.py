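"""Readers/writers for the formats the pipeline touches, plus the shared
coordinate conventions.

All coordinates held in memory are 0-based half-open. Emitted AGP is 1-based
inclusive (AGP v2.1 semantics); breakpoint report tables are 1-based with
``size = end - start`` (end-exclusive subtraction). The two converters below
are inverse bijections and the only place the shift happens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

_VALID = set("ACGTN")
_U_TO_T = str.maketrans("Uu", "Tt")


def zero_to_one(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (AGP style)."""
    return start + 1, end


def one_to_zero(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


@dataclass
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N}."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AgpComponent:
    """One row of an AGP object: a placed contig or a gap."""

    object_id: str
    object_start: int  # 1-based inclusive
    object_end: int
    component_type: str  # "contig" or "gap"
    component_id: str = ""
    component_start: int = 0
    component_end: int = 0
    orientation: str = "+"

    def span(self) -> int:
        return self.object_end - self.object_start + 1


@dataclass
class PafRecord:
    """The 12 mandatory PAF columns (0-based half-open intervals)."""

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    n_matches: int
    block_len: int
    mapq: int = 255


@dataclass
class MarkerRow:
    """One SNP marker of the genetic map with its flanking sequence."""

    marker_id: str
    lg: int
    female_cM: float
    male_cM: float
    flank_left: str
    flank_right: str
    allele: str = ""


def _sanitize(seq: str, rec_id: str) -> str:
    s = seq.upper().translate(_U_TO_T).upper()
    if not set(s) <= _VALID:
        n_odd = sum(1 for c in s if c not in _VALID)
        warnings.warn(
            f"record {rec_id!r}: {n_odd} non-ACGTN (IUPAC) bases mapped to N"
        )
        s = "".join(c if c in _VALID else "N" for c in s)
    return s


def read_fasta(path) -> list[SequenceRecord]:
    """Read FASTA; bases upper-cased, U->T, other IUPAC codes -> N."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, _sanitize(str(rec.seq), rec.id)))
    if not records:
        warnings.warn(f"no sequences found in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path, wrap: int = 80) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(bio)


def validate_agp(components: list[AgpComponent]) -> None:
    """Check the AGP tiling invariant; raises ValueError with row numbers."""
    by_obj: dict[str, list[tuple[int, AgpComponent]]] = {}
    for i, c in enumerate(components):
        if c.object_end < c.object_start:
            raise ValueError(f"row {i + 1}: object_end < object_start")
        if c.component_type == "contig":
            if (c.component_end - c.component_start) != (
                c.object_end - c.object_start
            ):
                raise ValueError(f"row {i + 1}: component/object span mismatch")
        by_obj.setdefault(c.object_id, []).append((i, c))
    for obj, rows in by_obj.items():
        expected = 1
        for i, c in rows:
            if c.object_start != expected:
                raise ValueError(
                    f"row {i + 1}: object {obj!r} not tiled without "
                    f"gaps/overlaps (expected start {expected}, "
                    f"got {c.object_start})"
                )
            expected = c.object_end + 1


def write_agp(components: list[AgpComponent], path) -> None:
    """Emit AGP v2.1; gap rows use type N / scaffold / yes / map."""
    if not components:
        warnings.warn(f"writing empty AGP to {path}")
        open(path, "w").close()
        return
    validate_agp(components)
    part_no: dict[str, int] = {}
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for c in components:
            part_no[c.object_id] = part_no.get(c.object_id, 0) + 1
            if c.component_type == "gap":
                cols = [
                    c.object_id,
                    c.object_start,
                    c.object_end,
                    part_no[c.object_id],
                    "N",
                    c.span(),
                    "scaffold",
                    "yes",
                    "map",
                ]
            else:
                cols = [
                    c.object_id,
                    c.object_start,
                    c.object_end,
                    part_no[c.object_id],
                    "W",
                    c.component_id,
                    c.component_start,
                    c.component_end,
                    c.orientation,
                ]
            fh.write("\t".join(str(x) for x in cols) + "\n")


def read_agp(path) -> list[AgpComponent]:
    components: list[AgpComponent] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[4] in ("N", "U"):
                components.append(
                    AgpComponent(f[0], int(f[1]), int(f[2]), "gap")
                )
            else:
                components.append(
                    AgpComponent(
                        f[0],
                        int(f[1]),
                        int(f[2]),
                        "contig",
                        f[5],
                        int(f[6]),
                        int(f[7]),
                        f[8],
                    )
                )
    return components


def read_paf(path) -> list[PafRecord]:
    """Read the 12 mandatory PAF columns; short rows skipped with a warning."""
    records: list[PafRecord] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                skipped += 1
                continue
            if f[4] not in ("+", "-"):
                raise ValueError(f"invalid PAF strand {f[4]!r}")
            records.append(
                PafRecord(
                    f[0],
                    int(f[1]),
                    int(f[2]),
                    int(f[3]),
                    f[4],
                    f[5],
                    int(f[6]),
                    int(f[7]),
                    int(f[8]),
                    int(f[9]),
                    int(f[10]),
                    int(f[11]),
                )
            )
    if skipped:
        warnings.warn(f"{skipped} PAF rows with <12 columns skipped")
    return records


def write_paf(records: list[PafRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.query_id,
                        r.query_len,
                        r.query_start,
                        r.query_end,
                        r.strand,
                        r.target_id,
                        r.target_len,
                        r.target_start,
                        r.target_end,
                        r.n_matches,
                        r.block_len,
                        r.mapq,
                    )
                )
                + "\n"
            )


_MARKER_COLS = [
    "marker_id",
    "lg",
    "female_cM",
    "male_cM",
    "flank_left",
    "flank_right",
]


def read_marker_table(path, n_chromosomes: int = 23) -> list[MarkerRow]:
    """Read the header-bearing marker TSV and validate each row."""
    df = pd.read_csv(path, sep="\t", dtype={"flank_left": str, "flank_right": str})
    missing = [c for c in _MARKER_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"marker table missing columns: {missing}")
    bad_cm = df.index[(df["female_cM"] < 0) | (df["male_cM"] < 0)].tolist()
    if bad_cm:
        raise ValueError(f"negative cM in rows {bad_cm}")
    bad_lg = df.index[(df["lg"] < 1) | (df["lg"] > n_chromosomes)].tolist()
    if bad_lg:
        raise ValueError(
            f"lg outside 1..{n_chromosomes} in rows {bad_lg}"
        )
    rows = []
    for t in df.itertuples(index=False):
        rows.append(
            MarkerRow(
                str(t.marker_id),
                int(t.lg),
                float(t.female_cM),
                float(t.male_cM),
                str(t.flank_left),
                str(t.flank_right),
                str(getattr(t, "allele", "")),
            )
        )
    return rows


def write_marker_table(rows: list[MarkerRow], path) -> None:
    df = pd.DataFrame(
        {
            "marker_id": [r.marker_id for r in rows],
            "lg": [r.lg for r in rows],
            "female_cM": [r.female_cM for r in rows],
            "male_cM": [r.male_cM for r in rows],
            "flank_left": [r.flank_left for r in rows],
            "flank_right": [r.flank_right for r in rows],
            "allele": [r.allele for r in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False)
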