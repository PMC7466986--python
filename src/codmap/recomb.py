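"""Sex-specific recombination profiles, suppressed-region detection,
chromosome-morphology classification, and co-location with repeat density.

A metacentric chromosome shows a sigmoidal bp-vs-cM profile: near-zero
recombination around a central centromere, roughly constant rates on the
arms. The operations here quantify that picture: windowed cM/Mb rates from
interpolated map positions, the longest run of windows far below the
chromosome median, classification by where that run sits, and a check that
the centromere-repeat density peak falls inside it. Because inversion
heterozygotes also suppress recombination, co-location is evidence for a
centromere, not proof.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .centromere import DensityTrack


@dataclass
class MapPoint:
    marker_id: str
    chrom: str
    bp: int
    female_cM: float
    male_cM: float


@dataclass
class MapStats:
    female_total_cM: float
    male_total_cM: float

    @property
    def fm_ratio(self) -> float:
        """Female:male map-length ratio, rounded to 1 decimal for report."""
        return round(self.female_total_cM / self.male_total_cM, 1)

    @property
    def fm_ratio_raw(self) -> float:
        return self.female_total_cM / self.male_total_cM


@dataclass
class SuppressedRegion:
    chrom: str
    start: int
    end: int
    mean_rate: float  # cM/Mb
    sex: str = "female"

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class MorphologyCall:
    chrom: str
    morphology: str  # metacentric | non_metacentric | unclassified
    suppressed_midpoint_fraction: float | None
    colocated_with_repeat: bool | None = None


def map_stats(points: list[MapPoint]) -> MapStats:
    """Total sex-specific map lengths (sum over chromosomes of the cM range)
    and their ratio."""
    by_chrom: dict[str, list[MapPoint]] = {}
    for p in points:
        by_chrom.setdefault(p.chrom, []).append(p)
    f_total = m_total = 0.0
    for chrom, pts in by_chrom.items():
        if len(pts) < 2:
            raise ValueError(f"{chrom}: need >=2 map points")
        f = [p.female_cM for p in pts]
        m = [p.male_cM for p in pts]
        f_total += max(f) - min(f)
        m_total += max(m) - min(m)
    if m_total == 0:
        raise ValueError("male map has zero length")
    return MapStats(f_total, m_total)


def map_stats_from_totals(female_total: float, male_total: float) -> MapStats:
    """Stats object from already-summed map lengths."""
    if male_total == 0:
        raise ValueError("male map has zero length")
    return MapStats(female_total, male_total)


def _monotone_cM(bp: np.ndarray, cm: np.ndarray, tolerance: float = 0.5):
    """Clamp small monotonicity violations (map noise); larger ones are
    input errors."""
    out = cm.copy()
    high = out[0]
    for i in range(1, out.size):
        if out[i] < high:
            if high - out[i] > tolerance:
                raise ValueError(
                    f"cM decreases by {high - out[i]:.3f} at bp {bp[i]} "
                    f"(> tolerance {tolerance})"
                )
            out[i] = high
        else:
            high = out[i]
    return out


def window_rates(
    points: list[MapPoint],
    chrom_len: int,
    bin_bp: int = 100_000,
    sex: str = "female",
    tolerance: float = 0.5,
) -> list[tuple[int, int, float]]:
    """cM/Mb per fixed window on one chromosome, linearly interpolating the
    map between flanking markers. Returns (start, end, rate) triples."""
    if len(points) < 2:
        warnings.warn("fewer than 2 markers; skipping chromosome")
        return []
    pts = sorted(points, key=lambda p: p.bp)
    bp = np.array([p.bp for p in pts], dtype=float)
    cm = np.array(
        [p.female_cM if sex == "female" else p.male_cM for p in pts]
    )
    cm = _monotone_cM(bp, cm, tolerance)
    edges = np.arange(0, chrom_len + bin_bp, bin_bp, dtype=float)
    edges[-1] = chrom_len
    cm_at = np.interp(edges, bp, cm)
    out = []
    for i in range(edges.size - 1):
        width_mb = (edges[i + 1] - edges[i]) / 1e6
        rate = (cm_at[i + 1] - cm_at[i]) / width_mb if width_mb > 0 else 0.0
        out.append((int(edges[i]), int(edges[i + 1]), float(rate)))
    return out


def find_suppressed(
    rates: list[tuple[int, int, float]],
    rel_threshold: float = 0.2,
    chrom: str = "",
    sex: str = "female",
) -> SuppressedRegion | None:
    """Longest run of consecutive windows with rate below
    ``rel_threshold`` x the chromosome median rate (ties -> lower mean)."""
    if len(rates) < 3:
        return None
    values = np.array([r for _, _, r in rates])
    cut = rel_threshold * float(np.median(values))
    low = values < cut
    best = None
    i = 0
    while i < len(low):
        if not low[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(low) and low[j + 1]:
            j += 1
        length = j - i + 1
        mean_rate = float(values[i : j + 1].mean())
        key = (-length, mean_rate)
        if best is None or key < best[0]:
            best = (key, i, j)
        i = j + 1
    if best is None:
        return None
    _, i, j = best
    return SuppressedRegion(
        chrom, rates[i][0], rates[j][1], float(values[i : j + 1].mean()), sex
    )


def classify_morphology(
    region: SuppressedRegion | None,
    chrom_len: int,
    central_band: tuple[float, float] = (0.25, 0.75),
    chrom: str = "",
) -> MorphologyCall:
    """Metacentric when the suppressed-region midpoint falls in the central
    band of the chromosome; no region -> unclassified."""
    if region is None:
        return MorphologyCall(chrom, "unclassified", None)
    frac = region.midpoint / chrom_len
    lo, hi = central_band
    morph = "metacentric" if lo <= frac <= hi else "non_metacentric"
    return MorphologyCall(region.chrom or chrom, morph, frac)


def colocalize(
    region: SuppressedRegion,
    track: DensityTrack,
    flank_bp: int | None = None,
) -> tuple[bool | None, int | None]:
    """Does the maximum-density bin sit inside the suppressed region
    (extended by ``flank_bp``, default one bin)? Returns (flag, signed bp
    distance from region midpoint to peak midpoint)."""
    counts = np.array(track.counts)
    if counts.size == 0 or counts.max() == 0:
        warnings.warn(f"{track.chrom}: empty density track")
        return None, None
    if flank_bp is None:
        flank_bp = track.bin_size
    peak_bin = int(counts.argmax())
    peak_mid = peak_bin * track.bin_size + track.bin_size // 2
    inside = region.start - flank_bp <= peak_mid <= region.end + flank_bp
    return bool(inside), peak_mid - region.midpoint
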