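"""Coordinate frames: chromosome sizes, p/q arms and cytogenetic bands.

A :class:`GenomeSpec` carries chromosome lengths, the first base of the q arm
and a band table in 1-based inclusive coordinates.  Two built-in frames are
provided:

* :func:`demo_genome` — a reduced five-chromosome genome (three autosomes
  plus X and Y, 10–60 Mb each) used as the default simulation fixture;
* :func:`nomenclature_band_map` — a coarse, hg19-scale band map for the
  chromosomes that appear in the worked reporting examples.  Its band
  boundaries are synthetic approximations laid out to be internally
  consistent; it is not a replacement for the full UCSC cytoBand table,
  which can be loaded through :mod:`prenatalgs.io`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import CoordinateError

BAND_COLUMNS = ["chrom", "start", "end", "band"]
SEX_CHROMS = ("chrX", "chrY")


def chrom_sort_key(name: str):
    """Sort key placing chr1..chr22 numerically, then chrX, chrY, chrM."""
    body = name[3:] if name.startswith("chr") else name
    if body.isdigit():
        return (0, int(body))
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if body in special:
        return (0, special[body])
    return (1, 0)


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome lengths, arm boundaries and cytogenetic bands.

    Parameters
    ----------
    lengths
        Chromosome name -> length in bp.
    arm_start
        Chromosome name -> 1-based position of the first q-arm base.
    bands
        DataFrame with columns ``chrom, start, end, band`` in 1-based
        inclusive coordinates.  Bands must tile each chromosome without
        gaps or overlap.
    """

    lengths: Mapping[str, int]
    arm_start: Mapping[str, int]
    bands: pd.DataFrame

    def __post_init__(self):
        for chrom, n in self.lengths.items():
            if n <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        if list(self.bands.columns[:4]) != BAND_COLUMNS:
            raise ValueError(f"band table must have columns {BAND_COLUMNS}")
        for chrom, sub in self.bands.groupby("chrom"):
            if chrom not in self.lengths:
                raise ValueError(f"band table references unknown chromosome {chrom}")
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if starts[0] != 1 or ends[-1] != self.lengths[chrom]:
                raise ValueError(f"bands do not span chromosome {chrom}")
            if not np.all(starts[1:] == ends[:-1] + 1):
                raise ValueError(f"bands do not tile chromosome {chrom}")

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.lengths, key=chrom_sort_key)

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.chromosomes if c not in SEX_CHROMS]

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise CoordinateError(f"unknown chromosome {chrom}") from None

    def contains(self, chrom: str, start: int, end: int) -> bool:
        return chrom in self.lengths and 1 <= start <= end <= self.lengths[chrom]

    def band_at(self, chrom: str, pos: int) -> str:
        """Cytogenetic band label at a 1-based position."""
        if not self.contains(chrom, pos, pos):
            raise CoordinateError(f"{chrom}:{pos} outside genome")
        sub = self.bands[self.bands["chrom"] == chrom]
        hit = sub[(sub["start"] <= pos) & (sub["end"] >= pos)]
        if hit.empty:
            raise CoordinateError(f"no band covers {chrom}:{pos}")
        return str(hit.iloc[0]["band"])

    def window_grid(self, window_bp: int = 5000) -> pd.DataFrame:
        """Non-overlapping window grid (1-based inclusive).

        Windows are ``window_bp`` wide except the final window of each
        chromosome, which is truncated at the chromosome end.
        """
        frames = []
        for chrom in self.chromosomes:
            n = self.lengths[chrom]
            starts = np.arange(1, n + 1, window_bp, dtype=np.int64)
            ends = np.minimum(starts + window_bp - 1, n)
            frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(frames, ignore_index=True)


def _tile(chrom: str, segments: list[tuple[str, int]]) -> pd.DataFrame:
    rows, prev = [], 0
    for band, end in segments:
        rows.append((chrom, prev + 1, end, band))
        prev = end
    return pd.DataFrame(rows, columns=BAND_COLUMNS)


def demo_genome() -> GenomeSpec:
    """Reduced genome fixture: three autosomes plus X and Y, 10-60 Mb."""
    spec = {
        "chr1": (60_000_000, [("p22", 12_000_000), ("p11", 24_000_000),
                              ("q11", 42_000_000), ("q22", 60_000_000)]),
        "chr2": (45_000_000, [("p22", 9_000_000), ("p11", 18_000_000),
                              ("q11", 31_000_000), ("q22", 45_000_000)]),
        "chr3": (30_000_000, [("p21", 6_000_000), ("p11", 12_000_000),
                              ("q11", 21_000_000), ("q21", 30_000_000)]),
        "chrX": (25_000_000, [("p11", 10_000_000), ("q11", 25_000_000)]),
        "chrY": (10_000_000, [("p11", 4_000_000), ("q11", 10_000_000)]),
    }
    lengths = {c: n for c, (n, _) in spec.items()}
    bands = pd.concat([_tile(c, segs) for c, (_, segs) in spec.items()],
                      ignore_index=True)
    arm_start = {}
    for c, (_, segs) in spec.items():
        prev = 0
        for band, end in segs:
            if band.startswith("q"):
                arm_start[c] = prev + 1
                break
            prev = end
    return GenomeSpec(lengths, arm_start, bands)


def nomenclature_band_map() -> GenomeSpec:
    """Coarse hg19-scale band map for nomenclature rendering (synthetic).

    Boundaries are rounded approximations chosen so that the coordinates in
    the worked reporting examples resolve to their conventional band labels;
    they are not authoritative cytogenetic positions.
    """
    spec = {
        "chr1": [("p36", 28_000_000), ("p31", 70_000_000), ("p21", 100_000_000),
                 ("p11", 125_000_000), ("q12", 156_000_000), ("q23.1", 160_000_000),
                 ("q24", 173_000_000), ("q25.2", 178_000_000), ("q31", 210_000_000),
                 ("q42", 249_250_621)],
        "chr2": [("p25", 40_000_000), ("p16", 70_000_000), ("p11.2", 93_300_000),
                 ("q11.1", 95_000_000), ("q11.2", 102_700_000), ("q12", 129_900_000),
                 ("q21.1", 132_500_000), ("q22", 203_000_000), ("q33.2", 205_000_000),
                 ("q34", 243_199_373)],
        "chr7": [("p22", 30_000_000), ("p14", 59_100_000), ("q11", 90_000_000),
                 ("q21.3", 98_000_000), ("q22.3", 110_000_000), ("q31", 159_138_663)],
        "chr8": [("p23.3", 2_200_000), ("p23.2", 6_200_000), ("p22", 30_000_000),
                 ("p11", 45_600_000), ("q11", 95_000_000), ("q22.1", 99_000_000),
                 ("q23", 139_900_000), ("q24.3", 146_364_022)],
        "chr12": [("p13", 35_800_000), ("q13", 120_900_000), ("q24.31", 124_000_000),
                  ("q24.33", 133_851_895)],
        "chr16": [("p13", 16_800_000), ("p12", 28_100_000), ("p11.2", 34_600_000),
                  ("p11.1", 36_600_000), ("q11", 50_000_000), ("q22", 90_354_753)],
        "chr20": [("p13", 5_100_000), ("p12.3", 9_200_000), ("p12.1", 17_900_000),
                  ("p11", 27_500_000), ("q11", 40_000_000), ("q13", 63_025_520)],
        "chr22": [("p13", 14_700_000), ("q11.1", 17_900_000), ("q11.21", 22_200_000),
                  ("q11.22", 25_500_000), ("q12", 37_600_000), ("q13", 51_304_566)],
        "chrX": [("p22", 37_600_000), ("p11", 60_600_000), ("q13", 100_000_000),
                 ("q24", 155_270_560)],
        "chrY": [("p11", 12_500_000), ("q11", 28_800_000), ("q12", 59_373_566)],
    }
    lengths = {c: segs[-1][1] for c, segs in spec.items()}
    bands = pd.concat([_tile(c, segs) for c, segs in spec.items()],
                      ignore_index=True)
    arm_start = {}
    for c, segs in spec.items():
        prev = 0
        for band, end in segs:
            if band.startswith("q"):
                arm_start[c] = prev + 1
                break
            prev = end
    return GenomeSpec(lengths, arm_start, bands)
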