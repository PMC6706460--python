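"""Small-variant triage: filtering cascade, trio phasing, 5-tier class.

Variants arrive fully annotated (gene, consequence, population frequency,
in-silico predictions, ClinVar/HGMD status, OMIM inheritance mode); this
module only decides.  Retention requires either a prior disease report or
the conjunction of rarity (MAF <= 5%), a coding/junction location, support
from multiple prediction algorithms and an OMIM disease gene.  Retained
variants are phased against the trio where genotypes exist and mapped to
the five ACMG-style tiers by an editable, ordered rule table; a hard gate
keeps any recessive-gene variant without a second allele out of the
pathogenic/likely-pathogenic tiers regardless of the table contents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import InputError

TIERS = ("pathogenic", "likely pathogenic", "VOUS", "likely benign", "benign")

TRUNCATING = {"frameshift", "nonsense", "splice-site", "stop-gain", "start-loss"}
DOMINANT_MODES = {"AD", "XLD"}
RECESSIVE_MODES = {"AR", "XLR"}
KNOWN_STATUSES = {"ClinVar-P/LP", "HGMD-DM"}

#: criteria of the retention cascade, by number
CRITERIA = {
    1: "known disease report (ClinVar/HGMD)",
    2: "MAF <= threshold",
    3: "coding region or exon-intron junction",
    4: "damaging by multiple predictors",
    5: "OMIM disease-causing gene",
}


@dataclass
class Classification:
    tier: str
    notes: list[str] = field(default_factory=list)
    phenotype_consistent: bool = False

    def __post_init__(self):
        if self.tier not in TIERS:
            raise InputError(f"tier must be one of {TIERS}")

    @property
    def is_diagnostic(self) -> bool:
        return self.tier in ("pathogenic", "likely pathogenic")


def prioritize(
    variants: pd.DataFrame,
    max_maf: float = 0.05,
    min_damaging: int = 2,
) -> pd.DataFrame:
    """Apply the retention cascade; keep rows with a criterion trace.

    A variant is retained when it is previously reported (criterion 1), or
    when it simultaneously passes criteria 2-5: population MAF at most
    ``max_maf``, located in a coding region or exon-intron junction,
    called damaging/splice-altering by at least ``min_damaging`` of the
    five predictors, and located in an OMIM disease gene.  Missing
    annotations fail the criterion they belong to.  The returned frame
    carries a ``criteria`` column listing the numbers that fired.
    """
    df = variants.copy()
    maf = pd.to_numeric(df.get("maf_max"), errors="coerce")
    dmg = pd.to_numeric(df.get("damaging_count"), errors="coerce")
    c1 = df.get("known_status", "none").isin(KNOWN_STATUSES)
    c2 = maf.notna() & (maf <= max_maf)
    c3 = df.get("region", "other").isin(["coding", "junction", "exon-intron junction"])
    c4 = dmg.notna() & (dmg >= min_damaging)
    c5 = ~df.get("omim_mode", "none").isin(["none", "", np.nan])
    retained = c1 | (c2 & c3 & c4 & c5)

    fired = []
    for i in range(len(df)):
        trace = [
            n
            for n, flag in zip((1, 2, 3, 4, 5), (c1, c2, c3, c4, c5))
            if bool(flag.iloc[i])
        ]
        fired.append(",".join(str(n) for n in trace))
    df["criteria"] = fired
    out = df[retained.to_numpy()].reset_index(drop=True)
    return out


def determine_inheritance(
    proband_gt: str, father_gt: str, mother_gt: str
) -> str:
    """Variant origin from trio genotypes.

    Both parents reference -> de novo; exactly one carrier parent -> that
    parent; both carriers -> biparental; any missing parent -> unknown.
    """
    if proband_gt in ("ref", "missing", None):
        raise InputError("proband does not carry the variant")
    if father_gt == "missing" or mother_gt == "missing":
        return "unknown"
    pat = father_gt in ("het", "hom", "hemi")
    mat = mother_gt in ("het", "hom")
    if pat and mat:
        return "biparental"
    if pat:
        return "paternal"
    if mat:
        return "maternal"
    return "de novo"


def phase_compound_het(variants: pd.DataFrame) -> str:
    """Compound-heterozygote verdict for the variants of one recessive gene.

    Expects an ``origin`` column (from :func:`determine_inheritance`).
    Returns ``confirmed-trans`` when variants arrive from both parents,
    ``cis`` when all phased variants share one parent, ``suspected`` when
    two or more variants cannot be phased, and ``single-carrier`` for a
    lone heterozygous variant.
    """
    het = variants[variants.get("zygosity", "het") == "het"]
    if het.empty:
        raise InputError("no heterozygous variant supplied")
    if len(het) == 1:
        return "single-carrier"
    origins = set(het["origin"]) if "origin" in het.columns else {"unknown"}
    if "paternal" in origins and "maternal" in origins:
        return "confirmed-trans"
    if origins <= {"paternal"} or origins <= {"maternal"}:
        return "cis"
    return "suspected"


# ---------------------------------------------------------------------------
# rule-table classification


def default_rules() -> list[dict]:
    """Load the packaged classification rule table."""
    text = resources.files("prenatalgs").joinpath("data/classification_rules.yaml").read_text()
    return yaml.safe_load(text)["rules"]


def load_rules(path) -> list[dict]:
    with open(path) as fh:
        return yaml.safe_load(fh)["rules"]


def _consequence_class(consequence: str) -> str:
    if consequence in TRUNCATING:
        return "truncating"
    if consequence == "missense":
        return "missense"
    return "other"


def _mode_class(mode: str) -> str:
    if mode in DOMINANT_MODES:
        return "dominant"
    if mode in RECESSIVE_MODES:
        return "recessive"
    return "none"


def _matches(cond: dict, facts: dict) -> bool:
    for key, want in cond.items():
        if key == "any_of":
            if not any(facts.get(k, False) for k in want):
                return False
            continue
        have = facts.get(key)
        if isinstance(want, list):
            if have not in want:
                return False
        elif have != want:
            return False
    return True


def classify_variant(
    variant: pd.Series | dict,
    origin: str = "unknown",
    phenotype_consistent: bool = False,
    biallelic: bool | None = None,
    rules: list[dict] | None = None,
) -> Classification:
    """Map a retained variant to one of the five tiers.

    ``biallelic`` marks a homozygous/hemizygous genotype or a confirmed
    compound heterozygote in trans; when omitted it is derived from the
    variant's zygosity.  Whatever the rule table says, a recessive-gene
    variant without a biallelic state is capped at VOUS.
    """
    v = dict(variant)
    if biallelic is None:
        biallelic = v.get("zygosity") in ("hom", "hemi")
    facts = {
        "known": v.get("known_status", "none") in KNOWN_STATUSES,
        "consequence_class": _consequence_class(v.get("consequence", "other")),
        "mode_class": _mode_class(v.get("omim_mode", "none")),
        "de_novo": origin == "de novo",
        "phenotype_match": bool(phenotype_consistent),
        "biallelic": bool(biallelic),
    }
    rules = default_rules() if rules is None else rules
    tier, notes = "VOUS", []
    for rule in rules:
        if _matches(rule.get("if", {}), facts):
            tier = rule["tier"]
            if rule.get("note"):
                notes.append(rule["note"])
            break
    if facts["mode_class"] == "none" and not facts["known"]:
        notes.append("inheritance mode unknown for novel variant")
    if (
        facts["mode_class"] == "recessive"
        and not facts["biallelic"]
        and tier in ("pathogenic", "likely pathogenic")
    ):
        tier = "VOUS"
        notes.append("recessive gene without a second allele; capped at VOUS")
    return Classification(tier=tier, notes=notes, phenotype_consistent=facts["phenotype_match"])
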