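"""Readers and writers for the plain-text interchange formats.

Internal coordinates are 1-based inclusive (matching ISCN ``g.start_end``
notation).  BED-dialect inputs — UCSC cytoBand tables and BEDPE pair
tables — are 0-based half-open on disk and converted on read/write.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .cnv import WINDOW_COLUMNS, CNVCall, ReferencePanel, WindowProfile
from .errors import InputError
from .genome import BAND_COLUMNS, GenomeSpec
from .report import QpcrPlate
from .sv import PAIR_COLUMNS


# --- window profiles -------------------------------------------------------


def read_window_tsv(path, sample_id: str | None = None) -> WindowProfile:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in WINDOW_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    return WindowProfile(sample_id or Path(path).stem, df[WINDOW_COLUMNS])


def write_window_tsv(profile: WindowProfile, path) -> None:
    profile.windows[WINDOW_COLUMNS].to_csv(path, sep="\t", index=False)


def read_panel(path) -> ReferencePanel:
    """Panel from a directory of window TSVs (one control sample each)."""
    p = Path(path)
    files = sorted(p.glob("*.tsv"))
    if len(files) < 2:
        raise InputError(f"panel directory {path} needs at least 2 samples")
    return ReferencePanel.from_profiles([read_window_tsv(f) for f in files])


# --- genome ----------------------------------------------------------------


def read_genome(cytoband_path, chrom_sizes_path) -> GenomeSpec:
    """GenomeSpec from a UCSC cytoBand.txt (0-based half-open) and a
    chrom.sizes file."""
    bands = pd.read_csv(
        cytoband_path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "band", "stain"],
    )
    bands["start"] = bands["start"] + 1  # to 1-based inclusive
    sizes = pd.read_csv(
        chrom_sizes_path, sep="\t", header=None, names=["chrom", "length"]
    )
    lengths = dict(zip(sizes["chrom"], sizes["length"]))
    arm_start = {}
    for chrom, sub in bands.groupby("chrom"):
        q = sub[sub["band"].str.startswith("q")]
        if not q.empty:
            arm_start[chrom] = int(q["start"].min())
    return GenomeSpec(lengths, arm_start, bands[BAND_COLUMNS])


def write_genome(genome: GenomeSpec, cytoband_path, chrom_sizes_path) -> None:
    bands = genome.bands.copy()
    bands["start"] = bands["start"] - 1
    bands["stain"] = "gneg"
    bands.to_csv(cytoband_path, sep="\t", header=False, index=False)
    with open(chrom_sizes_path, "w") as fh:
        for chrom in genome.chromosomes:
            fh.write(f"{chrom}\t{genome.length(chrom)}\n")


# --- chimeric pairs (BEDPE) ------------------------------------------------

_BEDPE_COLS = [
    "chrom1", "bstart1", "bend1", "chrom2", "bstart2", "bend2",
    "name", "score", "strand1", "strand2", "mapq1", "mapq2",
]


def read_bedpe(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 10:
        raise InputError(f"{path}: BEDPE needs at least 10 columns")
    df = df.iloc[:, : len(_BEDPE_COLS)]
    df.columns = _BEDPE_COLS[: df.shape[1]]
    out = pd.DataFrame(
        {
            "pair_id": df["name"],
            "chrom1": df["chrom1"],
            "pos1": df["bstart1"] + 1,
            "strand1": df["strand1"],
            "mapq1": df.get("mapq1", 60),
            "chrom2": df["chrom2"],
            "pos2": df["bstart2"] + 1,
            "strand2": df["strand2"],
            "mapq2": df.get("mapq2", 60),
        }
    )
    return out[PAIR_COLUMNS]


def write_bedpe(pairs: pd.DataFrame, path) -> None:
    df = pd.DataFrame(
        {
            "chrom1": pairs["chrom1"],
            "bstart1": pairs["pos1"] - 1,
            "bend1": pairs["pos1"],
            "chrom2": pairs["chrom2"],
            "bstart2": pairs["pos2"] - 1,
            "bend2": pairs["pos2"],
            "name": pairs["pair_id"],
            "score": 0,
            "strand1": pairs["strand1"],
            "strand2": pairs["strand2"],
            "mapq1": pairs["mapq1"],
            "mapq2": pairs["mapq2"],
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


# --- variants and trios ----------------------------------------------------


def read_variant_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_variant_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_ped(path) -> dict[str, dict]:
    """Minimal PED reader: sample -> {family, father, mother, sex, role}."""
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fam, sid, father, mother, sex, *_ = line.split()
            out[sid] = {
                "family": fam,
                "father": father if father != "0" else None,
                "mother": mother if mother != "0" else None,
                "sex": {"1": "male", "2": "female"}.get(sex, "unknown"),
            }
    return out


# --- qPCR plates -----------------------------------------------------------


def read_ct_csv(path) -> QpcrPlate:
    return QpcrPlate(pd.read_csv(path))


def write_ct_csv(plate: QpcrPlate, path) -> None:
    plate.wells.to_csv(path, index=False)


# --- calls and reports -----------------------------------------------------


def write_cnv_calls(calls: list[CNVCall], path) -> None:
    rows = [
        {
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "type": c.type,
            "size_kb": c.size_kb,
            "mean_ratio": round(c.mean_ratio, 4),
            "mosaic_fraction": c.mosaic_fraction,
            "p_value": c.p_value,
            "inheritance": c.inheritance,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "type", "size_kb", "mean_ratio",
            "mosaic_fraction", "p_value", "inheritance",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
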