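"""Structural-rearrangement detection from chimeric read pairs.

A chimeric pair maps its two reads to different chromosomes, or to the same
chromosome farther apart than the library insert allows (> 10 kb by
default).  Pairs are clustered by sorted coordinates and joining type, then
pushed through a fixed filter cascade — systematic-error filtering against a
control set, random-error filtering on a cluster property vector, and
orientation-based typing — to yield translocations, inversions, insertions
or complex events.  Junction sequences can additionally be characterised
for non-templated insertions and microhomology.

Joining type: each junction fuses one side of each breakpoint.  A read on
the '+' strand points into the junction from upstream, so the retained
segment lies to its left (side L); a '-' read retains the downstream side
(R).  The joining type of a cluster is therefore the canonical strand pair
of its members.  This truth table is isolated here so an alternative
convention can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnv import cnv_size_kb
from .errors import ConfigError, InputError, RecordError
from .genome import chrom_sort_key

PAIR_COLUMNS = [
    "pair_id",
    "chrom1",
    "pos1",
    "strand1",
    "mapq1",
    "chrom2",
    "pos2",
    "strand2",
    "mapq2",
]

SV_TYPES = ("translocation", "inversion", "insertion", "complex")


@dataclass
class ChimeraCluster:
    """A coherent group of chimeric pairs supporting one junction."""

    chrom1: str
    chrom2: str
    jt: tuple[str, str]  # joining type: canonical strand pair
    pairs: pd.DataFrame
    start1: int
    end1: int
    start2: int
    end2: int
    systematic: bool = False

    @property
    def count(self) -> int:
        return len(self.pairs)

    @property
    def span1(self) -> int:
        return self.end1 - self.start1

    @property
    def span2(self) -> int:
        return self.end2 - self.start2

    @property
    def mid1(self) -> int:
        return (self.start1 + self.end1) // 2

    @property
    def mid2(self) -> int:
        return (self.start2 + self.end2) // 2

    @property
    def strand_consistency(self) -> float:
        s = self.pairs["strand1"] + self.pairs["strand2"]
        return float((s == s.mode().iloc[0]).mean())

    @property
    def median_mapq(self) -> float:
        return float(
            np.median(np.concatenate([self.pairs["mapq1"], self.pairs["mapq2"]]))
        )

    @property
    def interchromosomal(self) -> bool:
        return self.chrom1 != self.chrom2

    @property
    def inner1(self) -> int:
        """Footprint edge facing the junction on side 1 (breakpoint estimate)."""
        return self.end1 if self.jt[0] == "+" else self.start1

    @property
    def inner2(self) -> int:
        return self.end2 if self.jt[1] == "+" else self.start2


@dataclass
class SVEvent:
    """A typed rearrangement supported by one locus group of clusters."""

    type: str
    clusters: list[ChimeraCluster]
    chrom_a: str = ""
    bp_a: int = 0
    chrom_b: str = ""
    bp_b: int = 0
    receptor: tuple[str, int, int] | None = None
    source: tuple[str, int, int] | None = None
    fragments: list[tuple[int, int, str]] = field(default_factory=list)
    lost_segments: list[tuple[int, int]] = field(default_factory=list)
    reason: str = ""
    classification: str | None = None

    @property
    def support(self) -> int:
        return sum(c.count for c in self.clusters)

    @property
    def source_size_kb(self) -> float | None:
        if self.source is None:
            return None
        return cnv_size_kb(self.source[1], self.source[2])

    def breakpoints(self) -> list[tuple[str, int]]:
        out = []
        for c in self.clusters:
            out.append((c.chrom1, c.mid1))
            out.append((c.chrom2, c.mid2))
        return out


# ---------------------------------------------------------------------------
# extraction and clustering


def _canonical(row) -> tuple:
    a = (row["chrom1"], int(row["pos1"]), row["strand1"], int(row["mapq1"]))
    b = (row["chrom2"], int(row["pos2"]), row["strand2"], int(row["mapq2"]))
    if (chrom_sort_key(a[0]), a[1]) > (chrom_sort_key(b[0]), b[1]):
        a, b = b, a
    return a + b


def extract_chimeric_pairs(
    table: pd.DataFrame, distance_cutoff: int = 10_000, min_mapq: int = 20
) -> pd.DataFrame:
    """Select chimeric pairs: interchromosomal, or separated by more than
    ``distance_cutoff`` on one chromosome.  Reads below ``min_mapq`` are
    dropped; ends are put in canonical (lower chromosome/coordinate) order.
    """
    if distance_cutoff <= 0:
        raise ConfigError("distance cutoff must be positive")
    missing = [c for c in PAIR_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"pair table missing columns {missing}")
    rows = []
    for i, row in enumerate(table.to_dict("records")):
        try:
            if row["strand1"] not in "+-" or row["strand2"] not in "+-":
                raise ValueError("bad strand")
            a1, p1, s1, q1, a2, p2, s2, q2 = _canonical(row)
            if p1 < 1 or p2 < 1:
                raise ValueError("bad coordinate")
        except (ValueError, TypeError, KeyError) as exc:
            raise RecordError(f"malformed pair record: {exc}", line=i + 1) from None
        if q1 < min_mapq or q2 < min_mapq:
            continue
        if a1 == a2 and abs(p2 - p1) <= distance_cutoff:
            continue
        rows.append([row["pair_id"], a1, p1, s1, q1, a2, p2, s2, q2])
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def _gap_split(pos: np.ndarray, labels: np.ndarray, window: int) -> np.ndarray:
    """Refine cluster labels by splitting each label at coordinate gaps."""
    order = np.lexsort((pos, labels))
    lab_s, pos_s = labels[order], pos[order]
    brk = np.empty(len(pos), dtype=bool)
    brk[0] = True
    brk[1:] = (lab_s[1:] != lab_s[:-1]) | (np.diff(pos_s) > window)
    new_sorted = np.cumsum(brk) - 1
    out = np.empty(len(pos), dtype=np.int64)
    out[order] = new_sorted
    return out


def cluster_pairs(pairs: pd.DataFrame, window: int = 1000) -> list[ChimeraCluster]:
    """Single-pass clustering over coordinate-sorted pairs.

    Pairs join a cluster only when they share the chromosome pair and
    joining type and extend both footprints by at most ``window``.  The
    result is independent of input order (sorting is internal).
    """
    if pairs.empty:
        return []
    clusters: list[ChimeraCluster] = []
    for (c1, c2, s1, s2), g in pairs.groupby(
        ["chrom1", "chrom2", "strand1", "strand2"], sort=False
    ):
        pos1 = g["pos1"].to_numpy(dtype=np.int64)
        pos2 = g["pos2"].to_numpy(dtype=np.int64)
        labels = np.zeros(len(g), dtype=np.int64)
        # alternate gap-splitting on the two footprints until stable
        for _ in range(6):
            before = labels.max()
            labels = _gap_split(pos1, labels, window)
            labels = _gap_split(pos2, labels, window)
            if labels.max() == before:
                break
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            b = g.iloc[idx]
            clusters.append(
                ChimeraCluster(
                    chrom1=c1,
                    chrom2=c2,
                    jt=(s1, s2),
                    pairs=b.reset_index(drop=True),
                    start1=int(pos1[idx].min()),
                    end1=int(pos1[idx].max()),
                    start2=int(pos2[idx].min()),
                    end2=int(pos2[idx].max()),
                )
            )
    clusters.sort(
        key=lambda c: (
            chrom_sort_key(c.chrom1),
            chrom_sort_key(c.chrom2),
            c.start1,
            c.start2,
            c.jt,
        )
    )
    return clusters


# ---------------------------------------------------------------------------
# filter cascade


def _reciprocal(a1: int, a2: int, b1: int, b2: int, pad: int = 0) -> float:
    a1, a2, b1, b2 = a1 - pad, a2 + pad, b1 - pad, b2 + pad
    inter = min(a2, b2) - max(a1, b1) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (a2 - a1 + 1), inter / (b2 - b1 + 1))


def filter_systematic(
    clusters: list[ChimeraCluster],
    control_clusters: list[ChimeraCluster],
    min_reciprocal: float = 0.5,
    pad: int = 500,
) -> list[ChimeraCluster]:
    """Drop clusters matched by a control cluster (same chromosome pair and
    joining type, reciprocal overlap >= ``min_reciprocal`` on both
    footprints).  Footprints are padded by ``pad`` bp — roughly one insert
    size — before the overlap test, since two read clusters supporting the
    same junction need not tile the same bases."""
    buckets: dict[tuple, list[ChimeraCluster]] = {}
    for ctl in control_clusters:
        buckets.setdefault((ctl.chrom1, ctl.chrom2, ctl.jt), []).append(ctl)
    kept = []
    for c in clusters:
        hit = False
        for ctl in buckets.get((c.chrom1, c.chrom2, c.jt), ()):
            if (
                _reciprocal(c.start1, c.end1, ctl.start1, ctl.end1, pad)
                >= min_reciprocal
                and _reciprocal(c.start2, c.end2, ctl.start2, ctl.end2, pad)
                >= min_reciprocal
            ):
                hit = True
                break
        if hit:
            c.systematic = True
        else:
            kept.append(c)
    return kept


def filter_random(
    clusters: list[ChimeraCluster],
    min_support: int = 4,
    max_span: int = 1500,
    min_strand_consistency: float = 1.0,
    min_median_mapq: float = 30.0,
) -> list[ChimeraCluster]:
    """Keep clusters whose property vector passes every threshold."""
    if min_support < 1 or max_span < 1:
        raise ConfigError("thresholds must be positive")
    return [
        c
        for c in clusters
        if c.count >= min_support
        and c.span1 <= max_span
        and c.span2 <= max_span
        and c.strand_consistency >= min_strand_consistency
        and c.median_mapq >= min_median_mapq
    ]


# ---------------------------------------------------------------------------
# locus grouping and typing


def group_loci(
    clusters: list[ChimeraCluster], proximity: int = 1_000_000
) -> list[list[ChimeraCluster]]:
    """Group clusters that share a chromosome pair and lie within
    ``proximity`` on both footprints (single-linkage)."""
    n = len(clusters)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def near(a: ChimeraCluster, b: ChimeraCluster) -> bool:
        if (a.chrom1, a.chrom2) != (b.chrom1, b.chrom2):
            return False
        d1 = max(0, max(a.start1, b.start1) - min(a.end1, b.end1))
        d2 = max(0, max(a.start2, b.start2) - min(a.end2, b.end2))
        return d1 <= proximity and d2 <= proximity

    for i in range(n):
        for j in range(i + 1, n):
            if near(clusters[i], clusters[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[ChimeraCluster]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(clusters[i])
    return [groups[k] for k in sorted(groups)]


def _insertion_fragments(
    src_points: list[tuple[int, str]]
) -> tuple[list[tuple[int, int, str]], list[tuple[int, int]]]:
    """Reconstruct source fragments from junction endpoints.

    Each source-side junction endpoint either enters a fragment (side R,
    the fragment continues rightwards) or exits one (side L).  Endpoints
    are paired in coordinate order; uncovered sub-intervals between
    fragments are reported as lost segments.  Only simple geometries are
    resolved — interleaved or inverted multi-fragment layouts fall back to
    a single spanning fragment.
    """
    pts = sorted(src_points)
    starts = [p for p, side in pts if side == "R"]
    ends = [p for p, side in pts if side == "L"]
    span = (pts[0][0], pts[-1][0])
    if len(starts) == len(ends) and all(s < e for s, e in zip(starts, ends)):
        frags = [(s, e, "+") for s, e in zip(starts, ends)]
        if all(frags[i][1] < frags[i + 1][0] for i in range(len(frags) - 1)):
            lost = [
                (frags[i][1] + 1, frags[i + 1][0] - 1)
                for i in range(len(frags) - 1)
                if frags[i + 1][0] - frags[i][1] > 1
            ]
            return frags, lost
    if len(pts) == 2 and pts[0][1] == "L" and pts[1][1] == "R":
        return [(span[0], span[1], "-")], []
    return [(span[0], span[1], "+")], []


def classify_event(
    clusters: list[ChimeraCluster],
    narrow_span: int = 10_000,
    footprint_tol: int = 5_000,
) -> SVEvent:
    """Type one locus group of filtered clusters from its joining types.

    Two same-chromosome clusters with the complementary head-head and
    tail-tail joining types and matching footprints form an inversion; a
    reciprocal interchromosomal cluster pair forms a translocation; two or
    more interchromosomal clusters pinned to one narrow receptor footprint
    and flanking a source interval form an insertion.  Anything else is
    reported as complex/unresolved with a reason.
    """
    if not clusters:
        raise InputError("empty locus group")
    chrom_pairs = {(c.chrom1, c.chrom2) for c in clusters}
    if len(chrom_pairs) > 1:
        return SVEvent("complex", clusters, reason="mixed chromosome pairs")
    c1, c2 = next(iter(chrom_pairs))
    jts = {c.jt for c in clusters}

    if len(clusters) == 1:
        c = clusters[0]
        return SVEvent(
            "complex",
            clusters,
            chrom_a=c.chrom1,
            bp_a=c.mid1,
            chrom_b=c.chrom2,
            bp_b=c.mid2,
            reason="single cluster: insufficient evidence",
        )

    if c1 == c2:
        if len(clusters) == 2 and jts == {("+", "+"), ("-", "-")}:
            a, b = clusters
            if (
                abs(a.mid1 - b.mid1) <= footprint_tol
                and abs(a.mid2 - b.mid2) <= footprint_tol
            ):
                return SVEvent(
                    "inversion",
                    clusters,
                    chrom_a=c1,
                    bp_a=(a.inner1 + b.inner1) // 2,
                    chrom_b=c2,
                    bp_b=(a.inner2 + b.inner2) // 2,
                )
        return SVEvent("complex", clusters, reason="incompatible joining types",
                       chrom_a=c1, bp_a=clusters[0].mid1,
                       chrom_b=c2, bp_b=clusters[0].mid2)

    span_1 = max(c.end1 for c in clusters) - min(c.start1 for c in clusters)
    span_2 = max(c.end2 for c in clusters) - min(c.start2 for c in clusters)

    if (
        len(clusters) == 2
        and span_1 <= narrow_span
        and span_2 <= narrow_span
        and jts in ({("+", "-"), ("-", "+")}, {("+", "+"), ("-", "-")})
    ):
        a, b = clusters
        return SVEvent(
            "translocation",
            clusters,
            chrom_a=c1,
            bp_a=(a.inner1 + b.inner1) // 2,
            chrom_b=c2,
            bp_b=(a.inner2 + b.inner2) // 2,
        )

    narrow1, narrow2 = span_1 <= narrow_span, span_2 <= narrow_span
    if narrow1 != narrow2:
        # receptor is the pinned side; source spreads over the moved interval
        if narrow1:
            rec_side, src_side = 1, 2
            rec_chrom, src_chrom = c1, c2
        else:
            rec_side, src_side = 2, 1
            rec_chrom, src_chrom = c2, c1
        rec_sides = {c.jt[rec_side - 1] for c in clusters}
        if rec_sides == {"+", "-"}:
            rec_lo = min(c.inner1 if rec_side == 1 else c.inner2 for c in clusters)
            rec_hi = max(c.inner1 if rec_side == 1 else c.inner2 for c in clusters)
            src_points = []
            for c in clusters:
                pos = c.inner2 if src_side == 2 else c.inner1
                strand = c.jt[src_side - 1]
                side = "L" if strand == "+" else "R"
                src_points.append((pos, side))
            frags, lost = _insertion_fragments(src_points)
            return SVEvent(
                "insertion",
                clusters,
                chrom_a=rec_chrom,
                bp_a=(rec_lo + rec_hi) // 2,
                chrom_b=src_chrom,
                bp_b=frags[0][0],
                receptor=(rec_chrom, rec_lo, rec_hi),
                source=(src_chrom, min(f[0] for f in frags), max(f[1] for f in frags)),
                fragments=frags,
                lost_segments=lost,
            )
    return SVEvent("complex", clusters, chrom_a=c1, bp_a=clusters[0].mid1,
                   chrom_b=c2, bp_b=clusters[0].mid2,
                   reason="unresolved cluster geometry")


# ---------------------------------------------------------------------------
# junction sequence characterisation


def characterize_junction(
    junction: str, flank_a: str, flank_b: str, min_anchor: int = 10
) -> tuple[int, str, int]:
    """Non-templated insertion and microhomology at a breakpoint junction.

    ``flank_a`` is reference sequence ending at breakpoint A, ``flank_b``
    reference sequence starting at breakpoint B.  The longest junction
    prefix matching a suffix of ``flank_a`` and the longest junction suffix
    matching a prefix of ``flank_b`` are located; the gap between them is a
    non-templated insertion, their overlap is microhomology (mutually
    exclusive).  Returns (insert length, inserted sequence, microhomology
    length).
    """
    for s in (junction, flank_a, flank_b):
        if not s or set(s) - set("ACGT"):
            raise InputError("sequences must be non-empty uppercase ACGT")
    if len(flank_a) < 20 or len(flank_b) < 20:
        raise InputError("flanks must be at least 20 bases")
    p = 0
    for k in range(min(len(junction), len(flank_a)), 0, -1):
        if junction[:k] == flank_a[-k:]:
            p = k
            break
    s = 0
    for k in range(min(len(junction), len(flank_b)), 0, -1):
        if junction[-k:] == flank_b[:k]:
            s = k
            break
    if p < min_anchor and s < min_anchor:
        raise InputError("junction matches neither flank")
    overlap = p + s - len(junction)
    if overlap > 0:
        return 0, "", overlap
    insert = junction[p : len(junction) - s]
    return len(insert), insert, 0


# ---------------------------------------------------------------------------
# pipeline


def call_svs(
    case_pairs: pd.DataFrame,
    control_pairs: pd.DataFrame | None = None,
    distance_cutoff: int = 10_000,
    min_mapq: int = 20,
    window: int = 1000,
    min_support: int = 4,
    max_span: int = 1500,
    min_strand_consistency: float = 1.0,
    min_median_mapq: float = 30.0,
    proximity: int = 1_000_000,
) -> list[SVEvent]:
    """Full cascade: extract, cluster, systematic filter, random filter,
    orientation-based typing.  Each filter returns a subset of its input
    and the order is fixed."""
    pairs = extract_chimeric_pairs(case_pairs, distance_cutoff, min_mapq)
    clusters = cluster_pairs(pairs, window=window)
    if control_pairs is not None:
        ctl = cluster_pairs(
            extract_chimeric_pairs(control_pairs, distance_cutoff, min_mapq),
            window=window,
        )
        clusters = filter_systematic(clusters, ctl)
    clusters = filter_random(
        clusters,
        min_support=min_support,
        max_span=max_span,
        min_strand_consistency=min_strand_consistency,
        min_median_mapq=min_median_mapq,
    )
    return [classify_event(g) for g in group_loci(clusters, proximity=proximity)]
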