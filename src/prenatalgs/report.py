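"""Case integration, ISCN-style nomenclature, yield statistics and qPCR.

Per-case findings from the CNV, SV and small-variant arms are merged into a
ranked report with a diagnostic flag; findings are rendered in a constrained
ISCN dialect (del/dup/trp/ins/inv plus mosaic sex-chromosome counts).
Cohort-level diagnostic yields carry Clopper-Pearson exact binomial 95%
intervals, group differences are tested with the chi-square test without
continuity correction (Fisher's exact test when an expected cell count
drops below 5), and qPCR copy ratios follow the 2^-ddCt method against a
copy-number-neutral reference amplicon.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from ._util import round_half_up
from .errors import CoordinateError, InputError
from .genome import GenomeSpec, chrom_sort_key

TIER_RANK = {
    "pathogenic": 0,
    "likely pathogenic": 1,
    "potentially pathogenic": 2,
    "VOUS": 3,
    "likely benign": 4,
    "polymorphism": 4,
    "benign": 5,
}

DIAGNOSTIC_TIERS = {"pathogenic", "likely pathogenic"}


# ---------------------------------------------------------------------------
# SV interpretation


def classify_sv(
    event,
    gene_annotations: pd.DataFrame | None,
    tad_map: pd.DataFrame | None = None,
) -> tuple[str, str]:
    """Interpret a typed rearrangement: (classification, note).

    A breakpoint inside the body of an OMIM disease gene makes the event
    potentially pathogenic; a breakpoint disrupting only a TAD/regulatory
    interval yields VOUS; otherwise the event is a polymorphism.  With no
    gene annotation track the classification is deferred.
    """
    if gene_annotations is None:
        return ("deferred", "no gene annotation track supplied")
    bps = event.breakpoints() if hasattr(event, "breakpoints") else list(event)
    for chrom, pos in bps:
        hits = gene_annotations[
            (gene_annotations["chrom"] == chrom)
            & (gene_annotations["start"] <= pos)
            & (gene_annotations["end"] >= pos)
        ]
        for _, g in hits.iterrows():
            if g.get("omim_mode", "none") not in ("none", "", None):
                return (
                    "potentially pathogenic",
                    f"disrupts OMIM gene {g['gene']} ({g['omim_mode']})",
                )
    if tad_map is not None:
        for chrom, pos in bps:
            hit = tad_map[
                (tad_map["chrom"] == chrom)
                & (tad_map["start"] <= pos)
                & (tad_map["end"] >= pos)
            ]
            if not hit.empty:
                return ("VOUS", "disrupts a TAD/regulatory interval only")
    return ("polymorphism", "no OMIM gene or TAD disrupted")


# ---------------------------------------------------------------------------
# ISCN-style nomenclature


@dataclass
class Finding:
    """A reportable genomic finding in the constrained ISCN dialect."""

    kind: str  # del | dup | trp | inv | ins | mosaic-sex-loss
    chrom: str = ""
    start: int = 0
    end: int = 0
    de_novo: bool = False
    tier: str = "VOUS"
    # insertion extras
    receptor: tuple[str, int, int] | None = None
    source: tuple[str, int, int] | None = None
    source_deleted: bool = True


def _chrom_no(chrom: str) -> str:
    return chrom[3:] if chrom.startswith("chr") else chrom


_SEG_RE = re.compile(
    r"^seq\[hg19\]\s?(del|dup|trp)\((\w+)\)\(([^)]+)\)(dn)?\s"
    r"chr(\w+):g\.(\d+)_(\d+)(del|dup|trp)$"
)
_MOSAIC_RE = re.compile(r"^\(X\)x1,\(Y\)x0[~∼⁓]1$")
_INS_RE = re.compile(
    r"^seq\[hg19\]ins\((\w+);(\w+)\)\(([^;]+);([^)]+)\)"
    r"g\.\[chr(\w+):(\d+)_(\d+)inschr(\w+):(\d+)_(\d+)cx\]"
    r"(?:chr(\w+):g\.(\d+)_(\d+)del)?$"
)


def iscn_string(finding: Finding, genome: GenomeSpec) -> str:
    """Render a finding in the constrained ISCN 2016 dialect.

    Deletions/duplications/triplications:
    ``seq[hg19] del(16)(p11.2)dn chr16:g.29538256_30290160del``.
    Mosaic male chromosome-Y loss: ``(X)x1,(Y)x0~1`` (rendered with the
    tilde operator U+223C).  Insertions use the bracketed
    ``ins(receptor;source)`` form.
    """
    if finding.kind == "mosaic-sex-loss":
        return "(X)x1,(Y)x0∼1"
    if finding.kind in ("del", "dup", "trp"):
        chrom = _chrom_no(finding.chrom)
        b1 = genome.band_at(finding.chrom, finding.start)
        b2 = genome.band_at(finding.chrom, finding.end)
        bands = b1 if b1 == b2 else b1 + b2
        dn = "dn" if finding.de_novo else ""
        op = finding.kind
        return (
            f"seq[hg19] {op}({chrom})({bands}){dn} "
            f"chr{chrom}:g.{finding.start}_{finding.end}{op}"
        )
    if finding.kind == "ins":
        rc, r1, r2 = finding.receptor
        sc, s1, s2 = finding.source
        rb = genome.band_at(rc, (r1 + r2) // 2)
        sb = genome.band_at(sc, (s1 + s2) // 2)
        tail = f"chr{_chrom_no(sc)}:g.{s1}_{s2}del" if finding.source_deleted else ""
        return (
            f"seq[hg19]ins({_chrom_no(rc)};{_chrom_no(sc)})({rb};{sb})"
            f"g.[chr{_chrom_no(rc)}:{r1}_{r2}inschr{_chrom_no(sc)}:{s1}_{s2}cx]{tail}"
        )
    if finding.kind == "inv":
        chrom = _chrom_no(finding.chrom)
        b1 = genome.band_at(finding.chrom, finding.start)
        b2 = genome.band_at(finding.chrom, finding.end)
        return (
            f"seq[hg19] inv({chrom})({b1}{b2}) "
            f"chr{chrom}:g.{finding.start}_{finding.end}inv"
        )
    raise InputError(f"cannot render finding kind {finding.kind!r}")


def parse_iscn(s: str) -> Finding:
    """Parse a string of the dialect emitted by :func:`iscn_string`."""
    s = s.strip()
    if _MOSAIC_RE.match(s):
        return Finding(kind="mosaic-sex-loss", chrom="chrY")
    m = _SEG_RE.match(s)
    if m:
        op, chrom_a, _bands, dn, chrom_b, start, end, op2 = m.groups()
        if op != op2 or chrom_a != chrom_b:
            raise InputError(f"inconsistent nomenclature string: {s!r}")
        return Finding(
            kind=op,
            chrom=f"chr{chrom_a}",
            start=int(start),
            end=int(end),
            de_novo=dn == "dn",
        )
    m = _INS_RE.match(s)
    if m:
        (rc, sc, _rb, _sb, rc2, r1, r2, sc2, s1, s2, dc, d1, d2) = m.groups()
        if rc != rc2 or sc != sc2:
            raise InputError(f"inconsistent insertion string: {s!r}")
        return Finding(
            kind="ins",
            chrom=f"chr{rc}",
            receptor=(f"chr{rc}", int(r1), int(r2)),
            source=(f"chr{sc}", int(s1), int(s2)),
            source_deleted=dc is not None,
        )
    m = re.match(
        r"^seq\[hg19\] inv\((\w+)\)\(([^)]+)\) chr(\w+):g\.(\d+)_(\d+)inv$", s
    )
    if m:
        chrom, _bands, chrom2, start, end = m.groups()
        return Finding(kind="inv", chrom=f"chr{chrom}", start=int(start), end=int(end))
    raise InputError(f"unparseable nomenclature string: {s!r}")


# ---------------------------------------------------------------------------
# case integration


def integrate_case(
    case: dict | pd.Series | None = None,
    cnv_findings: list[dict] | None = None,
    sv_findings: list[dict] | None = None,
    variant_findings: list[dict] | None = None,
) -> dict:
    """Merge classified findings into one ranked case report.

    Each finding is a dict with at least ``kind`` and ``tier`` (and
    optionally coordinates and a nomenclature string).  Findings are ranked
    pathogenic first, then by decreasing size and position; the diagnostic
    flag is set when any finding is pathogenic or likely pathogenic.
    """
    findings = list(cnv_findings or []) + list(sv_findings or []) + list(
        variant_findings or []
    )
    for f in findings:
        if "tier" not in f:
            raise InputError("every finding needs a classified tier")

    def key(f):
        size = f.get("end", 0) - f.get("start", 0)
        return (
            TIER_RANK.get(f["tier"], 9),
            -size,
            chrom_sort_key(f.get("chrom", "chr99")),
            f.get("start", 0),
        )

    ranked = sorted(findings, key=key)
    report = {
        "findings": ranked,
        "diagnostic": any(f["tier"] in DIAGNOSTIC_TIERS for f in ranked),
    }
    if case is not None:
        c = dict(case)
        report["case_id"] = c.get("case_id")
        report["group"] = c.get("group")
    return report


# ---------------------------------------------------------------------------
# cohort statistics


def _cp_interval(k: int, n: int) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
    return float(lo), float(hi)


def diagnostic_yield(
    cohort: pd.DataFrame, method: str = "gs", kinds: list[str] | None = None
) -> pd.DataFrame:
    """Per-group and overall diagnostic yield with exact 95% CIs.

    A case is positive when its ``{method}_findings`` list holds a
    pathogenic or likely pathogenic finding (optionally restricted to
    ``kinds``, e.g. ``["snv"]`` for point-mutation yield).  Percentages and
    Clopper-Pearson bounds are reported in % to one decimal, half-up.
    """
    if cohort.empty:
        raise InputError("empty cohort")
    col = f"{method}_findings"
    if col not in cohort.columns:
        raise InputError(f"cohort lacks a {col!r} column")

    def positive(findings) -> bool:
        fs = findings if kinds is None else [f for f in findings if f.get("kind") in kinds]
        return integrate_case(None, fs)["diagnostic"]

    flags = cohort[col].map(positive)
    rows = []
    groups = list(dict.fromkeys(cohort["group"])) + ["overall"]
    for g in groups:
        m = slice(None) if g == "overall" else (cohort["group"] == g)
        sub = flags if g == "overall" else flags[m]
        n, k = len(sub), int(sub.sum())
        lo, hi = _cp_interval(k, n)
        rows.append(
            {
                "group": g,
                "n": n,
                "positives": k,
                "percent": round_half_up(100.0 * k / n, 1),
                "ci_low": round_half_up(100.0 * lo, 1),
                "ci_high": round_half_up(100.0 * hi, 1),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def compare_yields(
    a_pos: int, a_n: int, b_pos: int, b_n: int
) -> tuple[float, float, str]:
    """Two-group yield comparison: (statistic, p, method).

    Uses the chi-square test without continuity correction when all 2x2
    expected counts are at least 5, otherwise Fisher's exact two-sided
    test (statistic = odds ratio).
    """
    if a_n <= 0 or b_n <= 0:
        raise InputError("group totals must be positive")
    table = np.array([[a_pos, a_n - a_pos], [b_pos, b_n - b_pos]], dtype=float)
    if table.min() < 0:
        raise InputError("positives exceed group size")
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if (expected >= 5).all():
        if table[:, 0].sum() in (0, n) or (table[0] == table[1]).all():
            # degenerate or identical groups: no association
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(chi2), float(p), "chi-square"
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p), "fisher"


# ---------------------------------------------------------------------------
# qPCR ddCt


@dataclass
class QpcrPlate:
    """Replicate Ct values for target/reference amplicons in case/control.

    ``wells`` columns: primer, sample (case|control), amplicon
    (target|reference), replicate, ct.
    """

    wells: pd.DataFrame

    def __post_init__(self):
        needed = {"primer", "sample", "amplicon", "replicate", "ct"}
        if not needed <= set(self.wells.columns):
            raise InputError(f"plate table needs columns {sorted(needed)}")
        if (self.wells["ct"] <= 0).any():
            raise InputError("Ct values must be positive")


def ddct_copy_ratio(plate: QpcrPlate, min_replicates: int = 3) -> pd.DataFrame:
    """Relative copy number per primer pair by the 2^-ddCt method.

    ddCt = (mean Ct_target - mean Ct_reference) in the case minus the same
    difference in the control; the copy ratio is 2^-ddCt with the replicate
    standard error propagated onto the ratio scale.
    """
    out = []
    for primer, sub in plate.wells.groupby("primer"):
        means, sems = {}, {}
        for sample in ("case", "control"):
            for amplicon in ("target", "reference"):
                grp = sub[(sub["sample"] == sample) & (sub["amplicon"] == amplicon)]
                if len(grp) < min_replicates:
                    raise InputError(
                        f"well group {primer}/{sample}/{amplicon} has fewer than "
                        f"{min_replicates} replicates"
                    )
                means[(sample, amplicon)] = float(grp["ct"].mean())
                sems[(sample, amplicon)] = (
                    float(grp["ct"].std(ddof=1)) / np.sqrt(len(grp))
                    if len(grp) > 1
                    else 0.0
                )
        ddct = (means[("case", "target")] - means[("case", "reference")]) - (
            means[("control", "target")] - means[("control", "reference")]
        )
        sd_ddct = float(np.sqrt(sum(s**2 for s in sems.values())))
        ratio = float(2.0**-ddct)
        out.append(
            {
                "primer": primer,
                "ddct": ddct,
                "copy_ratio": ratio,
                "copy_ratio_sd": np.log(2.0) * ratio * sd_ddct,
            }
        )
    return pd.DataFrame(out).set_index("primer")
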