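"""Read-depth CNV detection from windowed genome-sequencing coverage.

The caller operates on non-overlapping 5-kb window counts.  Copy ratios are
obtained by median normalisation (autosomal median ratio is anchored at 1.0,
so a disomic autosome sits at ratio 1.0 and a single-copy male sex chromosome
at 0.5).  Candidate regions come from an adjustable sliding window (50 kb by
default, advancing in 5-kb increments); breakpoints are then refined on the
5-kb grid by maximising the coverage step between flanking spans.  Events are
screened for rarity against a reference panel with a two-sided rank-sum test,
and mosaicism is quantified from the depression (or elevation) of the mean
copy ratio relative to the expected and fully-mutant ratios.

Coordinates are 1-based inclusive throughout; BED-dialect inputs are
converted on read in :mod:`prenatalgs.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up
from .errors import CandidateRejected, ConfigError, CoordinateError, InputError
from .genome import SEX_CHROMS, chrom_sort_key

WINDOW_COLUMNS = ["chrom", "start", "end", "count", "gc", "ratio"]

CNV_TYPES = ("het-del", "hom-del", "dup", "trp")


@dataclass
class WindowProfile:
    """Per-window read counts and copy ratios for one sample."""

    sample_id: str
    windows: pd.DataFrame  # chrom, start, end, count, gc, ratio

    def __post_init__(self):
        missing = [c for c in WINDOW_COLUMNS if c not in self.windows.columns]
        if missing:
            raise InputError(f"window table missing columns {missing}")
        for _, sub in self.windows.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if np.any(np.diff(starts) <= 0) or np.any(starts[1:] <= ends[:-1]):
                raise InputError("windows must be sorted and non-overlapping")

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.windows["chrom"].unique(), key=chrom_sort_key)

    def chrom_windows(self, chrom: str) -> pd.DataFrame:
        return self.windows[self.windows["chrom"] == chrom]

    def region_ratios(self, chrom: str, start: int, end: int) -> np.ndarray:
        sub = self.chrom_windows(chrom)
        m = (sub["start"] >= start) & (sub["end"] <= end)
        return sub.loc[m, "ratio"].to_numpy()


@dataclass
class ReferencePanel:
    """Per-window copy ratios of N control samples on the same window grid."""

    windows: pd.DataFrame  # chrom, start, end
    ratios: np.ndarray  # (n_windows, n_samples)

    def __post_init__(self):
        if self.ratios.ndim != 2 or self.ratios.shape[0] != len(self.windows):
            raise InputError("panel ratio matrix does not match window grid")
        if self.ratios.shape[1] < 2:
            raise InputError("reference panel needs at least 2 samples")

    @classmethod
    def from_profiles(cls, profiles: list["WindowProfile"]) -> "ReferencePanel":
        grid = profiles[0].windows[["chrom", "start", "end"]].reset_index(drop=True)
        cols = []
        for p in profiles:
            if len(p.windows) != len(grid) or not (
                p.windows["start"].to_numpy() == grid["start"].to_numpy()
            ).all():
                raise CoordinateError("panel profiles are not on a common window grid")
            cols.append(p.windows["ratio"].to_numpy())
        return cls(grid, np.column_stack(cols))

    @property
    def n_samples(self) -> int:
        return self.ratios.shape[1]

    @property
    def mean(self) -> np.ndarray:
        return self.ratios.mean(axis=1)

    @property
    def sd(self) -> np.ndarray:
        return self.ratios.std(axis=1, ddof=1)

    def region_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        m = (
            (self.windows["chrom"] == chrom)
            & (self.windows["start"] >= start)
            & (self.windows["end"] <= end)
        ).to_numpy()
        if not m.any():
            raise CoordinateError(f"region {chrom}:{start}-{end} absent from panel grid")
        return self.ratios[m, :]


@dataclass
class Candidate:
    """A candidate CNV region from the sliding-window scan."""

    chrom: str
    start: int
    end: int
    mean_ratio: float
    n_windows: int
    whole_chromosome: bool = False


@dataclass
class CNVCall:
    """A refined copy-number event."""

    chrom: str
    start: int
    end: int
    type: str  # het-del | hom-del | dup | trp
    mean_ratio: float
    mosaic_fraction: float | None = None
    p_value: float | None = None
    inheritance: str = "unknown"  # de novo | paternal | maternal | unknown
    whole_chromosome: bool = False

    def __post_init__(self):
        if self.end < self.start:
            raise InputError("CNV end precedes start")
        if self.type not in CNV_TYPES:
            raise InputError(f"unknown CNV type {self.type!r}")

    @property
    def size_kb(self) -> float:
        return cnv_size_kb(self.start, self.end)


def cnv_size_kb(start: int, end: int) -> float:
    """Event size in kb, 1-based inclusive, reported to one decimal."""
    if end < start:
        raise InputError("end precedes start")
    return round_half_up((end - start + 1) / 1000.0, 1)


def estimate_mosaic_fraction(observed: float, expected: float, event: float) -> float:
    """Fraction of cells carrying an event, from the mean copy ratio.

    With a fraction ``f`` of cells at the event ratio and ``1 - f`` at the
    expected ratio, the observed mean is the mixture
    ``f * event + (1 - f) * expected``, hence
    ``f = (expected - observed) / (expected - event)``, clamped to [0, 1].
    """
    if expected == event:
        raise InputError("expected and event ratios coincide; fraction undefined")
    f = (expected - observed) / (expected - event)
    return float(min(1.0, max(0.0, f)))


def infer_sex(profile: WindowProfile) -> str | None:
    """Crude sex inference from the normalized chrX mean ratio."""
    x = profile.chrom_windows("chrX")
    if x.empty or x["ratio"].isna().all():
        return None
    return "male" if x["ratio"].mean() < 0.75 else "female"


def expected_baselines(profile: WindowProfile, sex: str | None = None) -> dict[str, float]:
    """Expected copy ratio per chromosome (autosomes 1.0; sex chroms by sex)."""
    sex = sex or infer_sex(profile)
    out = {}
    for chrom in profile.chromosomes:
        if chrom not in SEX_CHROMS:
            out[chrom] = 1.0
        elif sex == "male":
            out[chrom] = 0.5
        elif sex == "female":
            out[chrom] = 1.0 if chrom == "chrX" else 0.0
        else:
            out[chrom] = 1.0 if chrom == "chrX" else 0.0
    return out


def normalize_windows(
    profile: WindowProfile,
    panel: ReferencePanel | None = None,
    gc_correct: bool = False,
) -> WindowProfile:
    """Fill the copy-ratio column, anchoring the autosomal median at 1.0.

    Optionally divides each window by the panel mean ratio (sensible only
    when panel samples share the proband's sex) and/or removes residual GC
    dependence with a quadratic fit on autosomal windows.  Zero-count
    windows are retained with ratio 0.
    """
    if profile.windows.empty:
        raise InputError("empty window profile")
    df = profile.windows.copy()
    if (df["count"] < 0).any():
        raise InputError("negative window counts")
    autos = ~df["chrom"].isin(SEX_CHROMS)
    med = float(df.loc[autos, "count"].median()) if autos.any() else float(df["count"].median())
    if med <= 0:
        raise InputError("autosomal median count is zero")
    ratio = df["count"].to_numpy(dtype=float) / med

    if panel is not None:
        if len(panel.windows) != len(df):
            raise CoordinateError("panel grid does not match profile grid")
        pm = panel.mean
        safe = pm > 0.2  # avoid dividing by near-absent windows (e.g. female Y)
        ratio = np.where(safe, ratio / np.where(safe, pm, 1.0), ratio)

    if gc_correct:
        gc = df["gc"].to_numpy(dtype=float)
        fit_mask = autos.to_numpy() & (ratio > 0.1) & (ratio < 3.0)
        if fit_mask.sum() >= 10:
            coef = np.polyfit(gc[fit_mask], ratio[fit_mask], deg=2)
            pred = np.polyval(coef, gc)
            pred = np.clip(pred, 0.2, 5.0)
            ratio = ratio / pred * float(np.mean(pred[fit_mask]))

    med_r = float(np.median(ratio[autos.to_numpy()])) if autos.any() else float(np.median(ratio))
    if med_r > 0:
        ratio = ratio / med_r
    df["ratio"] = ratio
    return WindowProfile(profile.sample_id, df)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) index pairs."""
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), ends.tolist()))


def scan_candidates(
    profile: WindowProfile,
    scan_bp: int = 50_000,
    step_bp: int = 5_000,
    threshold: float = 0.2,
    min_consecutive: int = 3,
    chrom_threshold: float = 0.05,
    sex: str | None = None,
) -> list[Candidate]:
    """Sliding-window scan for candidate CNV regions.

    A candidate is a maximal run of at least ``min_consecutive`` sliding
    windows (``scan_bp`` wide, advancing one 5-kb step at a time) whose mean
    ratio deviates from the chromosome baseline by more than ``threshold``.
    Chromosome-wide deviations beyond ``chrom_threshold`` are reported as
    chromosome-level candidates — the entry point for mosaic aneuploidy.
    """
    if scan_bp % step_bp:
        raise ConfigError("step must divide the scan window")
    k = scan_bp // step_bp
    baselines = expected_baselines(profile, sex=sex)
    out: list[Candidate] = []
    for chrom in profile.chromosomes:
        sub = profile.chrom_windows(chrom).reset_index(drop=True)
        b = baselines.get(chrom, 1.0)
        r = sub["ratio"].to_numpy(dtype=float)
        if b <= 0:
            continue  # chromosome expected absent (e.g. female Y)
        if abs(float(r.mean()) - b) > chrom_threshold:
            out.append(
                Candidate(
                    chrom=chrom,
                    start=int(sub["start"].iloc[0]),
                    end=int(sub["end"].iloc[-1]),
                    mean_ratio=float(r.mean()),
                    n_windows=len(sub),
                    whole_chromosome=True,
                )
            )
        if len(r) < k:
            continue
        roll = np.convolve(r, np.full(k, 1.0 / k), mode="valid")
        dev = np.abs(roll - b) > threshold
        spans: list[tuple[int, int]] = []
        for i, j in _runs(dev):
            if j - i + 1 < min_consecutive:
                continue
            spans.append((i, j + k - 1))  # sliding hit i covers windows i..i+k-1
        # merge window spans separated by less than one scan window
        merged: list[list[int]] = []
        for s, e in spans:
            if merged and s - merged[-1][1] <= k:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            out.append(
                Candidate(
                    chrom=chrom,
                    start=int(sub["start"].iloc[s]),
                    end=int(sub["end"].iloc[e]),
                    mean_ratio=float(r[s : e + 1].mean()),
                    n_windows=e - s + 1,
                )
            )
    return out


def _type_event(mean_ratio: float, baseline: float, copies: int) -> tuple[str, float]:
    """Map a mean ratio to an event type and its fully-mutant event ratio."""
    if mean_ratio < baseline:
        if copies <= 1 or mean_ratio < 0.25 * baseline:
            return ("hom-del", 0.0)
        return ("het-del", baseline / 2.0)
    if mean_ratio > 1.75 * baseline:
        return ("trp", 2.0 * baseline)
    return ("dup", 1.5 * baseline)


def _finalize_call(
    chrom: str,
    start: int,
    end: int,
    mean_ratio: float,
    baseline: float,
    copies: int,
    whole_chromosome: bool = False,
    mosaic_band: tuple[float, float] = (0.1, 0.9),
) -> CNVCall:
    ev_type, ev_ratio = _type_event(mean_ratio, baseline, copies)
    f = estimate_mosaic_fraction(mean_ratio, baseline, ev_ratio)
    lo, hi = mosaic_band
    mosaic = f if lo <= f <= hi else None
    return CNVCall(
        chrom=chrom,
        start=start,
        end=end,
        type=ev_type,
        mean_ratio=float(mean_ratio),
        mosaic_fraction=None if mosaic is None else float(round(mosaic, 3)),
        whole_chromosome=whole_chromosome,
    )


def refine_breakpoints(
    profile: WindowProfile,
    candidate: Candidate,
    flank: int = 10,
    sex: str | None = None,
) -> CNVCall:
    """Refine candidate edges on the 5-kb grid via the coverage-step statistic.

    For each putative boundary the statistic is the absolute difference of
    the mean ratio over the ``flank`` windows on either side (the increment
    rate of coverage across the edge); the boundary maximising it within
    ``flank`` windows of the scan edge is chosen.  Chromosome-level
    candidates are converted directly into whole-chromosome calls.
    """
    baselines = expected_baselines(profile, sex=sex)
    b = baselines.get(candidate.chrom, 1.0)
    copies = 2 if candidate.chrom not in SEX_CHROMS else (1 if b == 0.5 else 2)

    if candidate.whole_chromosome:
        return _finalize_call(
            candidate.chrom,
            candidate.start,
            candidate.end,
            candidate.mean_ratio,
            b,
            copies,
            whole_chromosome=True,
        )

    sub = profile.chrom_windows(candidate.chrom).reset_index(drop=True)
    r = sub["ratio"].to_numpy(dtype=float)
    in_cand = (sub["start"] >= candidate.start) & (sub["end"] <= candidate.end)
    idx = np.flatnonzero(in_cand.to_numpy())
    if len(idx) < 2:
        raise CandidateRejected("candidate spans fewer than 2 windows")
    i0, i1 = int(idx[0]), int(idx[-1])

    def step(boundary: int) -> float:
        left = r[max(0, boundary - flank) : boundary]
        right = r[boundary : boundary + flank]
        if len(left) == 0 or len(right) == 0:
            return -1.0
        return abs(float(right.mean()) - float(left.mean()))

    s_lo, s_hi = max(1, i0 - flank), min(i0 + flank, i1)
    s = max(range(s_lo, s_hi + 1), key=step)
    t_lo, t_hi = max(s + 1, i1 + 1 - flank), min(len(r) - 1, i1 + 1 + flank)
    t = max(range(t_lo, t_hi + 1), key=step)  # t is the exclusive end boundary
    if t - s < 2:
        raise CandidateRejected("refined segment shorter than 2 windows")

    seg_mean = float(r[s:t].mean())
    return _finalize_call(
        candidate.chrom,
        int(sub["start"].iloc[s]),
        int(sub["end"].iloc[t - 1]),
        seg_mean,
        b,
        copies,
    )


@dataclass
class RarityResult:
    p_value: float
    keep: bool
    carriers: int
    panel_size: int
    reason: str = ""


def rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p: exact enumeration for small tie-free
    samples, normal approximation with tie correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    exact = (
        max(len(x), len(y)) <= 20
        and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    )
    method = "exact" if exact else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def rare_cnv_test(
    call: CNVCall,
    profile: WindowProfile,
    panel: ReferencePanel,
    alpha: float = 1e-4,
    max_carrier_fraction: float = 0.05,
    min_carriers: int = 2,
    sex: str | None = None,
) -> RarityResult:
    """Population screen: is the event both significant and rare?

    The p-value is a two-sided rank-sum test of the case's per-window copy
    ratios in the region against the pooled panel ratios over the same
    windows.  Because pooling dilutes but does not remove the signal of a
    polymorphic CNV segregating in the panel, events are additionally
    dropped as polymorphisms when the fraction of panel samples whose
    regional mean shifts in the same direction by at least half the case
    effect exceeds ``max_carrier_fraction`` (with at least ``min_carriers``
    such samples).  Kept events satisfy ``p < alpha`` and the rarity screen.
    """
    case = profile.region_ratios(call.chrom, call.start, call.end)
    if len(case) < 2:
        raise InputError("region must span at least 2 windows")
    pw = panel.region_values(call.chrom, call.start, call.end)
    p = rank_sum_p(case, pw.ravel())

    b = expected_baselines(profile, sex=sex).get(call.chrom, 1.0)
    effect = float(case.mean()) - b
    sample_means = pw.mean(axis=0)
    if abs(effect) > 1e-12:
        shifted = (sample_means - b) * np.sign(effect) >= 0.5 * abs(effect)
        carriers = int(shifted.sum())
    else:
        carriers = 0
    n = panel.n_samples
    polymorphic = carriers >= min_carriers and carriers / n >= max_carrier_fraction
    keep = (p < alpha) and not polymorphic
    reason = "polymorphism" if polymorphic else ("" if p < alpha else "not significant")
    return RarityResult(p_value=p, keep=keep, carriers=carriers, panel_size=n, reason=reason)


def call_cnvs(
    profile: WindowProfile,
    panel: ReferencePanel | None = None,
    scan_bp: int = 50_000,
    step_bp: int = 5_000,
    threshold: float = 0.2,
    alpha: float = 1e-4,
    min_size_kb: float = 25.0,
    flank: int = 10,
    gc_correct: bool = False,
    sex: str | None = None,
) -> list[CNVCall]:
    """End-to-end pipeline: normalize, scan, refine, rarity-screen.

    Local candidates on a chromosome that also yields a chromosome-level
    candidate are absorbed into the whole-chromosome call.
    """
    norm = normalize_windows(profile, panel=None, gc_correct=gc_correct)
    cands = scan_candidates(
        norm, scan_bp=scan_bp, step_bp=step_bp, threshold=threshold, sex=sex
    )
    whole = {c.chrom for c in cands if c.whole_chromosome}
    calls: list[CNVCall] = []
    for cand in cands:
        if not cand.whole_chromosome and cand.chrom in whole:
            continue
        try:
            call = refine_breakpoints(norm, cand, flank=flank, sex=sex)
        except CandidateRejected:
            continue
        if not call.whole_chromosome and call.size_kb < min_size_kb:
            continue
        if panel is not None and not call.whole_chromosome:
            res = rare_cnv_test(call, norm, panel, alpha=alpha, sex=sex)
            call.p_value = res.p_value
            if not res.keep:
                continue
        calls.append(call)
    calls.sort(key=lambda c: (chrom_sort_key(c.chrom), c.start, c.end))
    return calls
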