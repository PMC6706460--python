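"""Synthetic inputs with known truth for every pipeline stage.

The generators emulate the data a 30-fold short-read genome-sequencing run
produces after alignment: 5-kb window read counts (negative-binomial noise,
optional GC bias, embedded constitutional and mosaic CNVs), chimeric
read-pair tables with random noise and systematic artifact clusters shared
with a control set, annotated small-variant tables with trio genotypes,
cohort case tables with fixed marginals, and qPCR Ct plates.  Everything is
deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnv import WindowProfile, ReferencePanel, normalize_windows
from .errors import ConfigError, CoordinateError
from .genome import SEX_CHROMS, GenomeSpec
from .report import QpcrPlate
from .sv import PAIR_COLUMNS

VARIANT_COLUMNS = [
    "gene",
    "transcript",
    "hgvs_c",
    "hgvs_p",
    "consequence",
    "zygosity",
    "maf_max",
    "damaging_count",
    "known_status",
    "omim_mode",
    "region",
    "gt_proband",
    "gt_father",
    "gt_mother",
    "origin_truth",
    "is_truth",
]


# ---------------------------------------------------------------------------
# truth containers


@dataclass
class TrueCNV:
    chrom: str
    start: int
    end: int
    kind: str  # het-del | hom-del | dup | trp | chrom-loss
    mosaic_fraction: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.mosaic_fraction <= 1.0:
            raise ConfigError("mosaic fraction must lie in [0, 1]")
        if self.kind not in ("het-del", "hom-del", "dup", "trp", "chrom-loss"):
            raise ConfigError(f"unknown CNV kind {self.kind!r}")


@dataclass
class TrueSV:
    kind: str  # translocation | inversion | insertion
    # translocation breakpoints
    chrom_a: str | None = None
    pos_a: int | None = None
    chrom_b: str | None = None
    pos_b: int | None = None
    # inversion interval
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    # insertion geometry
    receptor: tuple[str, int, int] | None = None  # chrom, left bp, right bp
    source: tuple[str, int, int] | None = None  # chrom, start bp, end bp
    orientation: str = "+"
    n_pairs: int = 8

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ConfigError("each SV needs at least one supporting pair")


@dataclass
class TrueVariant:
    gene: str
    mode: str = "AD"  # OMIM inheritance mode
    consequence: str = "missense"
    origin: str = "de novo"  # de novo | paternal | maternal | biparental | unknown
    zygosity: str = "het"
    known_status: str = "none"  # ClinVar-P/LP | HGMD-DM | none
    maf: float = 0.0
    damaging: int = 3
    region: str = "coding"
    transcript: str = "NM_000000"
    hgvs_c: str = "c.1A>G"
    hgvs_p: str = "p.?"


@dataclass
class TruthSet:
    cnvs: list[TrueCNV] = field(default_factory=list)
    svs: list[TrueSV] = field(default_factory=list)
    variants: list[TrueVariant] = field(default_factory=list)
    seed: int = 0


@dataclass
class SimConfig:
    """Study conditions for the generators.

    ``mean_count`` is the expected fragment count of a 5-kb window at
    copy-number 2, scaled to a 30-fold paired-end run (about 750 fragments
    of ~400 bp per 5 kb).  Window noise is negative binomial with shape
    ``nb_dispersion`` (Poisson in the limit; ``count_model='exact'`` rounds
    the expectation for noise-free checks).  Insert sizes follow
    N(350, 50) bp, inside the 300-500 bp fragment-size band of the assay.
    """

    mean_count: float = 750.0
    nb_dispersion: float = 200.0
    count_model: str = "nb"  # nb | poisson | exact
    window_bp: int = 5000
    gc_bias: tuple[float, float] | None = None  # linear, quadratic coefficient
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    noise_pairs: int = 2000
    n_artifact_sites: int = 5
    artifact_sites: list | None = None
    panel_size: int = 8

    def __post_init__(self):
        if self.mean_count < 0:
            raise ConfigError("mean count must be non-negative")
        if self.noise_pairs < 0 or self.n_artifact_sites < 0:
            raise ConfigError("rates must be non-negative")
        if self.panel_size < 2:
            raise ConfigError("panel size must be at least 2")
        if self.count_model not in ("nb", "poisson", "exact"):
            raise ConfigError(f"unknown count model {self.count_model!r}")


# ---------------------------------------------------------------------------
# windowed coverage


def assign_gc(grid: pd.DataFrame) -> np.ndarray:
    """Smooth, deterministic per-window GC fraction (mean ~0.42)."""
    chrom_idx = pd.factorize(grid["chrom"])[0]
    phase = grid["start"].to_numpy(dtype=float) / 7e6 * 2 * np.pi + chrom_idx
    return 0.42 + 0.05 * np.sin(phase)


def _base_copies(grid: pd.DataFrame, sex: str) -> np.ndarray:
    copies = np.full(len(grid), 2.0)
    if sex == "male":
        copies[grid["chrom"].isin(SEX_CHROMS).to_numpy()] = 1.0
    else:
        copies[(grid["chrom"] == "chrY").to_numpy()] = 0.0
    return copies


_KIND_DELTA = {"het-del": -1.0, "hom-del": -2.0, "dup": 1.0, "trp": 2.0}


def simulate_coverage(
    genome: GenomeSpec,
    truth: TruthSet,
    cfg: SimConfig,
    seed: int,
    sex: str = "male",
    sample_id: str = "case",
) -> WindowProfile:
    """Windowed read counts with embedded CNVs and mosaicism.

    The expected count of a window scales linearly with its local copy
    number; a mosaic event contributes the ploidy mixture
    ``f * event + (1 - f) * base``.  The copy-ratio column is left as NaN
    until :func:`prenatalgs.cnv.normalize_windows` fills it.
    """
    rng = np.random.default_rng(seed)
    grid = genome.window_grid(cfg.window_bp)
    gc = assign_gc(grid)
    copies = _base_copies(grid, sex)

    for cnv in truth.cnvs:
        if cnv.kind == "chrom-loss":
            start, end = 1, genome.length(cnv.chrom)
        else:
            start, end = cnv.start, cnv.end
        if not genome.contains(cnv.chrom, start, end):
            raise CoordinateError(
                f"truth interval {cnv.chrom}:{start}-{end} outside genome"
            )
        mask = (
            (grid["chrom"] == cnv.chrom)
            & (grid["start"] <= end)
            & (grid["end"] >= start)
        ).to_numpy()
        base = copies[mask]
        if cnv.kind == "chrom-loss":
            event = np.zeros_like(base)
        else:
            event = np.maximum(base + _KIND_DELTA[cnv.kind], 0.0)
        f = cnv.mosaic_fraction
        copies[mask] = f * event + (1 - f) * base

    mult = np.ones(len(grid))
    if cfg.gc_bias is not None:
        a, b = cfg.gc_bias
        d = gc - 0.42
        mult = np.clip(1.0 + a * d + b * d * d, 0.05, None)
    mu = cfg.mean_count * (copies / 2.0) * mult

    if cfg.count_model == "exact":
        counts = np.rint(mu).astype(np.int64)
    elif cfg.count_model == "poisson":
        counts = rng.poisson(mu).astype(np.int64)
    else:
        r = cfg.nb_dispersion
        p = r / (r + np.maximum(mu, 1e-12))
        counts = np.where(mu > 0, rng.negative_binomial(r, p), 0).astype(np.int64)

    df = grid.copy()
    df["count"] = counts
    df["gc"] = gc
    df["ratio"] = np.nan
    return WindowProfile(sample_id, df)


def reference_panel(
    genome: GenomeSpec,
    cfg: SimConfig,
    seed: int,
    n: int | None = None,
    sex: str = "male",
    truths: list[TruthSet] | None = None,
) -> ReferencePanel:
    """Panel of normalized control profiles (optionally with planted CNVs)."""
    n = n or cfg.panel_size
    profiles = []
    for i in range(n):
        truth = truths[i] if truths is not None else TruthSet()
        raw = simulate_coverage(genome, truth, cfg, seed * 10_007 + i, sex=sex,
                                sample_id=f"ctrl{i}")
        profiles.append(normalize_windows(raw))
    return ReferencePanel.from_profiles(profiles)


# ---------------------------------------------------------------------------
# chimeric read pairs

# a junction fuses one side of each breakpoint; side 'L' keeps the sequence
# upstream (read maps on '+'), side 'R' keeps the downstream sequence ('-')
_SIDE_STRAND = {"L": "+", "R": "-"}


def sv_junctions(sv: TrueSV) -> list[tuple]:
    """Breakpoint junctions (chromA, posA, sideA, chromB, posB, sideB)."""
    if sv.kind == "translocation":
        return [
            (sv.chrom_a, sv.pos_a, "L", sv.chrom_b, sv.pos_b, "R"),
            (sv.chrom_a, sv.pos_a, "R", sv.chrom_b, sv.pos_b, "L"),
        ]
    if sv.kind == "inversion":
        return [
            (sv.chrom, sv.start, "L", sv.chrom, sv.end, "L"),
            (sv.chrom, sv.start, "R", sv.chrom, sv.end, "R"),
        ]
    if sv.kind == "insertion":
        rc, r1, r2 = sv.receptor
        sc, s1, s2 = sv.source
        if sv.orientation == "+":
            return [
                (rc, r1, "L", sc, s1, "R"),
                (rc, r2, "R", sc, s2, "L"),
            ]
        return [
            (rc, r1, "L", sc, s2, "L"),
            (rc, r2, "R", sc, s1, "R"),
        ]
    raise ConfigError(f"SV kind {sv.kind!r} has no defined joining type")


def _junction_pairs(rng, junction, n_pairs, cfg, prefix) -> list[list]:
    ca, pa, sa, cb, pb, sb = junction
    rows = []
    for i in range(n_pairs):
        da = int(rng.integers(20, max(21, int(cfg.insert_mean))))
        db = int(rng.integers(20, max(21, int(cfg.insert_mean))))
        posa = pa - da if sa == "L" else pa + da
        posb = pb - db if sb == "L" else pb + db
        rows.append(
            [
                f"{prefix}_{i}",
                ca,
                max(1, posa),
                _SIDE_STRAND[sa],
                int(rng.integers(40, 61)),
                cb,
                max(1, posb),
                _SIDE_STRAND[sb],
                int(rng.integers(40, 61)),
            ]
        )
    return rows


def _noise_pairs(rng, genome: GenomeSpec, n: int, prefix: str) -> list[list]:
    chroms = genome.chromosomes
    lens = np.array([genome.length(c) for c in chroms], dtype=float)
    w = lens / lens.sum()
    rows = []
    for i in range(n):
        c1, c2 = rng.choice(chroms, size=2, p=w)
        rows.append(
            [
                f"{prefix}_{i}",
                c1,
                int(rng.integers(1, genome.length(c1) + 1)),
                rng.choice(["+", "-"]),
                int(rng.integers(10, 61)),
                c2,
                int(rng.integers(1, genome.length(c2) + 1)),
                rng.choice(["+", "-"]),
                int(rng.integers(10, 61)),
            ]
        )
    return rows


def _artifact_sites(rng, genome: GenomeSpec, cfg: SimConfig) -> list[tuple]:
    if cfg.artifact_sites is not None:
        return list(cfg.artifact_sites)
    chroms = genome.chromosomes
    sites = []
    for _ in range(cfg.n_artifact_sites):
        c1, c2 = rng.choice(chroms, size=2, replace=False)
        sites.append(
            (
                c1,
                int(rng.integers(1_000_000, genome.length(c1) - 1_000_000)),
                rng.choice(["L", "R"]),
                c2,
                int(rng.integers(1_000_000, genome.length(c2) - 1_000_000)),
                rng.choice(["L", "R"]),
            )
        )
    return sites


def simulate_chimeric_pairs(
    genome: GenomeSpec,
    truth: TruthSet,
    cfg: SimConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Case and control chimeric-pair tables.

    Every true SV contributes one coherent cluster per breakpoint junction;
    uniform random noise pairs are added to both tables, and systematic
    artifact clusters appear at identical coordinates in case and control.
    """
    rng = np.random.default_rng(seed)
    art_rng = np.random.default_rng(seed ^ 0x5EED)
    sites = _artifact_sites(art_rng, genome, cfg)

    case_rows: list[list] = []
    for si, sv in enumerate(truth.svs):
        for ji, junction in enumerate(sv_junctions(sv)):
            case_rows += _junction_pairs(rng, junction, sv.n_pairs, cfg, f"sv{si}j{ji}")
    control_rows: list[list] = []
    for ai, site in enumerate(sites):
        n_case = int(art_rng.integers(4, 13))
        n_ctrl = int(art_rng.integers(4, 13))
        case_rows += _junction_pairs(art_rng, site, n_case, cfg, f"art{ai}c")
        control_rows += _junction_pairs(art_rng, site, n_ctrl, cfg, f"art{ai}n")
    case_rows += _noise_pairs(rng, genome, cfg.noise_pairs, "noise")
    control_rows += _noise_pairs(rng, genome, cfg.noise_pairs, "cnoise")

    case = pd.DataFrame(case_rows, columns=PAIR_COLUMNS)
    control = pd.DataFrame(control_rows, columns=PAIR_COLUMNS)
    return case, control


# ---------------------------------------------------------------------------
# annotated small-variant tables


def _genotypes(origin: str, zygosity: str) -> tuple[str, str, str]:
    father = mother = "ref"
    if origin == "paternal":
        father = "het"
    elif origin == "maternal":
        mother = "het"
    elif origin == "biparental":
        father = mother = "het"
    elif origin == "unknown":
        father = mother = "missing"
    return zygosity, father, mother


_DECOY_VIOLATIONS = ("maf", "region", "damaging", "mode")


def simulate_variant_table(
    truth: TruthSet, seed: int, n_decoys: int = 20
) -> pd.DataFrame:
    """Annotated proband variant table with trio genotypes.

    Truth variants carry every field the prioritization cascade consumes;
    each decoy is a novel variant violating exactly one retention criterion
    (high MAF, non-coding region, too few damaging predictions, or no OMIM
    disease gene), so a correct prioritizer retains exactly the truth set.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for v in truth.variants:
        gt_p, gt_f, gt_m = _genotypes(v.origin, v.zygosity)
        rows.append(
            [
                v.gene, v.transcript, v.hgvs_c, v.hgvs_p, v.consequence,
                v.zygosity, v.maf, v.damaging, v.known_status, v.mode,
                v.region, gt_p, gt_f, gt_m, v.origin, True,
            ]
        )
    for i in range(n_decoys):
        violation = _DECOY_VIOLATIONS[i % len(_DECOY_VIOLATIONS)]
        maf = 0.08 if violation == "maf" else float(rng.uniform(0, 0.04))
        region = "other" if violation == "region" else "coding"
        damaging = int(rng.integers(0, 2)) if violation == "damaging" else 3
        mode = "none" if violation == "mode" else "AD"
        origin = rng.choice(["paternal", "maternal", "de novo"])
        gt_p, gt_f, gt_m = _genotypes(origin, "het")
        rows.append(
            [
                f"DECOY{i}", f"NM_9{i:05d}", "c.100C>T", "p.?", "missense",
                "het", maf, damaging, "none", mode, region,
                gt_p, gt_f, gt_m, origin, False,
            ]
        )
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return df.sample(frac=1.0, random_state=int(rng.integers(0, 2**31))).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# cohort tables


def simulate_cohort(
    sizes: dict[str, int],
    gs_positives: dict[str, int],
    cma_positives: dict[str, int] | None = None,
    snv_positives: dict[str, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Case table with exactly the requested per-group marginals.

    ``gs_positives`` cases carry a P/LP genome-sequencing finding; of those,
    ``snv_positives`` carry a point-mutation finding and the remainder a CNV
    finding.  ``cma_positives`` is drawn from the CNV-positive cases (the
    microarray sees CNVs only, and the sequencing calls are a superset of
    the microarray calls).
    """
    cma_positives = cma_positives or {g: 0 for g in sizes}
    snv_positives = snv_positives or {g: 0 for g in sizes}
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in sizes.items():
        gs_k = gs_positives.get(group, 0)
        cma_k = cma_positives.get(group, 0)
        snv_k = snv_positives.get(group, 0)
        if gs_k > n or cma_k > n:
            raise ConfigError(f"positives exceed group size for {group!r}")
        if snv_k > gs_k:
            raise ConfigError(f"SNV positives exceed GS positives for {group!r}")
        if cma_k > gs_k - snv_k:
            raise ConfigError(
                f"CMA positives exceed CNV-positive GS cases for {group!r}"
            )
        order = rng.permutation(n)
        gs_idx = set(order[:gs_k].tolist())
        snv_idx = set(order[:snv_k].tolist())
        cnv_order = [i for i in order[:gs_k] if i not in snv_idx]
        cma_idx = set(cnv_order[:cma_k])
        for i in range(n):
            if i in snv_idx:
                gs_findings = [{"kind": "snv", "tier": "likely pathogenic"}]
            elif i in gs_idx:
                gs_findings = [{"kind": "cnv", "tier": "pathogenic"}]
            else:
                gs_findings = []
            cma_findings = (
                [{"kind": "cnv", "tier": "pathogenic"}] if i in cma_idx else []
            )
            rows.append(
                {
                    "case_id": f"{group[:3].upper()}{i:04d}",
                    "group": group,
                    "nt_mm": round(float(rng.uniform(3.5, 14.5)), 1),
                    "sample_type": rng.choice(["CVS", "AF"], p=[0.74, 0.26]),
                    "karyotype_available": bool(rng.random() < 0.9),
                    "gs_findings": gs_findings,
                    "cma_findings": cma_findings,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR plates


def simulate_qpcr_cts(
    copies_case: float,
    copies_control: float,
    efficiency: float = 1.0,
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    primers: tuple[str, ...] = ("P1", "P2"),
) -> QpcrPlate:
    """Ct plate for a target amplicon against a copy-neutral reference.

    At 100% efficiency one extra target copy lowers the Ct by one cycle;
    the reference amplicon has two copies in every sample.
    """
    if copies_case < 0 or copies_control < 0:
        raise ConfigError("copy numbers must be non-negative")
    if not 0.95 <= efficiency <= 1.05:
        raise ConfigError("PCR efficiency must lie in [0.95, 1.05]")
    if replicates < 1:
        raise ConfigError("at least one replicate per well group")
    rng = np.random.default_rng(seed)
    base = {"target": 26.0, "reference": 24.0}
    amp = np.log(1.0 + efficiency)
    rows = []
    for primer in primers:
        for sample, copies in (("case", copies_case), ("control", copies_control)):
            for amplicon in ("target", "reference"):
                c = 2.0 if amplicon == "reference" else copies
                if c <= 0:
                    ct0 = 40.0
                else:
                    ct0 = base[amplicon] - np.log(c / 2.0) / amp
                for rep in range(replicates):
                    ct = ct0 + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                    rows.append(
                        {
                            "primer": primer,
                            "sample": sample,
                            "amplicon": amplicon,
                            "replicate": rep + 1,
                            "ct": float(ct),
                        }
                    )
    return QpcrPlate(pd.DataFrame(rows))
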