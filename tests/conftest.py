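import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

import prenatalgs as pgs
from prenatalgs.simulate import SimConfig, TrueSV


@pytest.fixture(scope="session")
def genome():
    return pgs.demo_genome()


@pytest.fixture(scope="session")
def band_map():
    return pgs.nomenclature_band_map()


@pytest.fixture
def cfg():
    return SimConfig()


#: genome-sequencing nomenclature strings from the published CNV summary,
#: used for parse/emit round-trip checks
ISCN_EXAMPLES = [
    "(X)x1,(Y)x0∼1",
    "seq[hg19] del(16)(p11.2)dn chr16:g.29538256_30290160del",
    "seq[hg19] del(20)(p13p12.3) chr20:g.4937184_8674795del",
    "seq[hg19] del(8)(p23.3p23.2) chr8:g.10134_5523520del",
    "seq[hg19] dup(8)(q22.1q24.3) chr8:g.98620704_146298884dup",
    "seq[hg19] del(1)(q23.1q25.2)dn chr1:g.157878750_176611630del",
    "seq[hg19] trp(2)(q11.2q21.1)dn chr2:g.98070117_131452568trp",
    "seq[hg19] del(7)(q21.3q22.3)dn chr7:g.96777381_107062981del",
    "seq[hg19] del(22)(q11.21) chr22:g.18912476_21471029del",
    "seq[hg19] del(22)(q11.21)dn chr22:g.18912979_21443877del",
]


@pytest.fixture(scope="session")
def iscn_examples():
    return list(ISCN_EXAMPLES)


def planted_svs(rng) -> list[TrueSV]:
    """Twenty structural variants at well-separated loci on the demo genome:
    eight chr1-chr3 translocations, six chr2 inversions and six chrX<-chrY
    insertions, each with 6-11 supporting pairs."""
    svs = []
    slots1 = np.arange(2_000_000, 58_000_000, 7_000_000)
    slots3 = np.arange(2_000_000, 29_000_000, 3_300_000)
    for k in range(8):
        svs.append(
            TrueSV(
                "translocation",
                chrom_a="chr1",
                pos_a=int(slots1[k] + rng.integers(0, 1_000_000)),
                chrom_b="chr3",
                pos_b=int(slots3[k] + rng.integers(0, 1_000_000)),
                n_pairs=int(rng.integers(6, 12)),
            )
        )
    slots2 = np.arange(2_000_000, 43_000_000, 6_800_000)
    for k in range(6):
        s = int(slots2[k] + rng.integers(0, 1_000_000))
        e = s + int(rng.integers(200_000, 2_000_000))
        svs.append(
            TrueSV("inversion", chrom="chr2", start=s, end=e,
                   n_pairs=int(rng.integers(6, 12)))
        )
    slots_x = np.arange(2_000_000, 23_000_000, 3_500_000)
    slots_y = np.arange(1_000_000, 9_000_000, 1_300_000)
    for k in range(6):
        r = int(slots_x[k] + rng.integers(0, 500_000))
        s = int(slots_y[k] + rng.integers(0, 200_000))
        svs.append(
            TrueSV(
                "insertion",
                receptor=("chrX", r, r + 80),
                source=("chrY", s, s + 150_000),
                n_pairs=int(rng.integers(6, 12)),
            )
        )
    return svs


def match_sv(sv: TrueSV, events, used: set, tol: int = 2000) -> int | None:
    """Index of the called event matching a planted SV, if any."""
    for i, e in enumerate(events):
        if i in used:
            continue
        if (
            sv.kind == "translocation"
            and e.type == "translocation"
            and abs(e.bp_a - sv.pos_a) < tol
            and abs(e.bp_b - sv.pos_b) < tol
        ):
            return i
        if (
            sv.kind == "inversion"
            and e.type == "inversion"
            and abs(e.bp_a - sv.start) < tol
            and abs(e.bp_b - sv.end) < tol
        ):
            return i
        if (
            sv.kind == "insertion"
            and e.type == "insertion"
            and e.receptor is not None
            and abs(e.receptor[1] - sv.receptor[1]) < tol
        ):
            return i
    return None


@pytest.fixture(scope="session")
def sv_truth_factory():
    return planted_svs


@pytest.fixture(scope="session")
def sv_matcher():
    return match_sv
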