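import numpy as np
import pandas as pd
import pytest

from prenatalgs.errors import InputError, RecordError
from prenatalgs.simulate import SimConfig, TrueSV, TruthSet, simulate_chimeric_pairs
from prenatalgs.sv import (
    PAIR_COLUMNS,
    call_svs,
    characterize_junction,
    classify_event,
    cluster_pairs,
    extract_chimeric_pairs,
    filter_random,
    filter_systematic,
    group_loci,
)


def _pairs(rows):
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def _junction_fixture(rng, ca, pa, sa, cb, pb, sb, n=10, prefix="j"):
    """Coherent supporting pairs for one junction (side L -> '+', R -> '-')."""
    strand = {"L": "+", "R": "-"}
    rows = []
    for i in range(n):
        da, db = int(rng.integers(20, 350)), int(rng.integers(20, 350))
        rows.append(
            [
                f"{prefix}{i}",
                ca, pa - da if sa == "L" else pa + da, strand[sa], 60,
                cb, pb - db if sb == "L" else pb + db, strand[sb], 60,
            ]
        )
    return rows


# --- extraction ------------------------------------------------------------


def test_extraction_distance_and_chromosome_rules():
    rows = [
        ["a", "chr1", 100_000, "+", 60, "chr1", 109_000, "-", 60],  # 9 kb: kept out
        ["b", "chr2", 100_000, "+", 60, "chr3", 5_000_000, "-", 60],  # interchrom
        ["c", "chr1", 100_000, "+", 60, "chr1", 150_000, "-", 60],  # 50 kb apart
        ["d", "chr1", 100_000, "+", 60, "chr1", 110_001, "-", 60],  # just above 10 kb
    ]
    out = extract_chimeric_pairs(_pairs(rows), distance_cutoff=10_000)
    assert sorted(out["pair_id"]) == ["b", "c", "d"]


def test_extraction_drops_low_mapq_and_canonicalizes():
    rows = [
        ["a", "chr3", 5_000_000, "-", 60, "chr1", 100_000, "+", 60],
        ["b", "chr1", 100_000, "+", 10, "chr3", 5_000_000, "-", 60],
    ]
    out = extract_chimeric_pairs(_pairs(rows), min_mapq=20)
    assert list(out["pair_id"]) == ["a"]
    assert out.iloc[0]["chrom1"] == "chr1"  # ends reordered canonically


def test_malformed_record_reports_line_number():
    rows = [
        ["a", "chr1", 100_000, "+", 60, "chr3", 5_000_000, "-", 60],
        ["b", "chr1", 100_000, "x", 60, "chr3", 5_000_000, "-", 60],
    ]
    with pytest.raises(RecordError) as err:
        extract_chimeric_pairs(_pairs(rows))
    assert err.value.line == 2


# --- clustering ------------------------------------------------------------


def test_coherent_pairs_form_single_cluster():
    rng = np.random.default_rng(0)
    rows = _junction_fixture(rng, "chr1", 1_000_000, "L", "chr3", 2_000_000, "R", n=10)
    clusters = cluster_pairs(_pairs(rows))
    assert len(clusters) == 1
    c = clusters[0]
    assert c.count == 10 and c.jt == ("+", "-")
    assert c.span1 < 1000 and c.span2 < 1000


def test_distant_junctions_form_separate_clusters():
    rng = np.random.default_rng(1)
    rows = _junction_fixture(rng, "chr1", 1_000_000, "L", "chr3", 2_000_000, "R", n=5)
    rows += _junction_fixture(rng, "chr1", 6_000_000, "L", "chr3", 2_000_000, "R", n=5, prefix="k")
    clusters = cluster_pairs(_pairs(rows))
    assert len(clusters) == 2


def test_clustering_invariant_to_input_order():
    rng = np.random.default_rng(2)
    rows = _junction_fixture(rng, "chr1", 1_000_000, "L", "chr3", 2_000_000, "R", n=8)
    rows += _junction_fixture(rng, "chr2", 3_000_000, "R", "chr3", 9_000_000, "L", n=6, prefix="k")
    a = cluster_pairs(_pairs(rows))
    shuffled = _pairs(rows).sample(frac=1.0, random_state=7)
    b = cluster_pairs(shuffled)
    key = lambda c: (c.chrom1, c.chrom2, c.jt, c.start1, c.start2, c.count)
    assert sorted(map(key, a)) == sorted(map(key, b))


# --- filter cascade --------------------------------------------------------


def test_systematic_filter_drops_shared_artifacts_keeps_true(genome):
    cfg = SimConfig(noise_pairs=0, n_artifact_sites=3)
    sv = TrueSV("translocation", chrom_a="chr1", pos_a=10_000_000,
                chrom_b="chr3", pos_b=5_000_000, n_pairs=8)
    case, control = simulate_chimeric_pairs(genome, TruthSet(svs=[sv]), cfg, seed=5)
    cc = cluster_pairs(extract_chimeric_pairs(case))
    kc = cluster_pairs(extract_chimeric_pairs(control))
    kept = filter_systematic(cc, kc)
    assert len(cc) == 5 and len(kept) == 2  # both junction clusters survive
    mids = sorted((c.chrom1, c.chrom2) for c in kept)
    assert mids == [("chr1", "chr3"), ("chr1", "chr3")]


def test_systematic_filter_with_empty_control_is_identity():
    rng = np.random.default_rng(3)
    rows = _junction_fixture(rng, "chr1", 1_000_000, "L", "chr3", 2_000_000, "R")
    clusters = cluster_pairs(_pairs(rows))
    assert filter_systematic(clusters, []) == clusters


def test_random_filter_thresholds():
    rng = np.random.default_rng(4)
    rows = _junction_fixture(rng, "chr1", 1_000_000, "L", "chr3", 2_000_000, "R", n=10)
    rows += _junction_fixture(rng, "chr2", 1_000_000, "L", "chr3", 9_000_000, "R", n=1, prefix="s")
    clusters = cluster_pairs(_pairs(rows))
    kept = filter_random(clusters, min_support=4)
    assert len(kept) == 1 and kept[0].count == 10
    assert set(map(id, kept)) <= set(map(id, clusters))  # subset property


def test_noise_only_simulations_leave_no_events(genome):
    # default random-pair rate: the cascade should silence everything
    cfg = SimConfig(n_artifact_sites=0)
    survivors = []
    for seed in range(20):
        case, control = simulate_chimeric_pairs(genome, TruthSet(), cfg, seed=seed)
        survivors.append(len(call_svs(case, control)))
    assert np.mean(survivors) < 1.0


# --- typing ----------------------------------------------------------------


def test_inversion_from_complementary_joining_types():
    rng = np.random.default_rng(5)
    rows = _junction_fixture(rng, "chr2", 20_000_000, "L", "chr2", 21_000_000, "L", n=6)
    rows += _junction_fixture(rng, "chr2", 20_000_000, "R", "chr2", 21_000_000, "R", n=6, prefix="k")
    clusters = cluster_pairs(extract_chimeric_pairs(_pairs(rows)))
    groups = group_loci(clusters)
    assert len(groups) == 1
    event = classify_event(groups[0])
    assert event.type == "inversion"
    assert abs(event.bp_a - 20_000_000) < 500
    assert abs(event.bp_b - 21_000_000) < 500


def test_insertion_reconstruction_matches_source_interval():
    # receptor site on chr2 flanked by clusters pointing at both ends of a
    # 150.1-kb source interval on chr12 (the worked complex-insertion case)
    rng = np.random.default_rng(6)
    rows = _junction_fixture(rng, "chr2", 203_384_219, "L", "chr12", 122_757_221, "R", n=8)
    rows += _junction_fixture(rng, "chr2", 203_384_293, "R", "chr12", 122_907_271, "L", n=8, prefix="k")
    clusters = cluster_pairs(extract_chimeric_pairs(_pairs(rows)))
    event = classify_event(group_loci(clusters)[0])
    assert event.type == "insertion"
    assert event.receptor[0] == "chr2"
    assert abs(event.receptor[1] - 203_384_219) < 400
    assert event.source[0] == "chr12"
    assert event.source_size_kb == pytest.approx(150.1, abs=0.3)
    assert event.fragments and event.fragments[0][2] == "+"


def test_single_cluster_is_unresolved():
    rng = np.random.default_rng(7)
    rows = _junction_fixture(rng, "chr1", 1_000_000, "L", "chr3", 2_000_000, "R")
    clusters = cluster_pairs(_pairs(rows))
    event = classify_event(clusters)
    assert event.type == "complex"
    assert "insufficient" in event.reason


def test_classification_invariant_to_cluster_order_and_labeling():
    rng = np.random.default_rng(8)
    rows = _junction_fixture(rng, "chr2", 20_000_000, "L", "chr2", 21_000_000, "L", n=6)
    rows += _junction_fixture(rng, "chr2", 20_000_000, "R", "chr2", 21_000_000, "R", n=6, prefix="k")
    clusters = cluster_pairs(extract_chimeric_pairs(_pairs(rows)))
    forward = classify_event(clusters)
    backward = classify_event(list(reversed(clusters)))
    assert (forward.type, forward.bp_a, forward.bp_b) == (
        backward.type, backward.bp_a, backward.bp_b,
    )
    # swapping read A/B in the input rows must not change the call
    swapped = [[r[0], r[5], r[6], r[7], r[8], r[1], r[2], r[3], r[4]] for r in rows]
    clusters2 = cluster_pairs(extract_chimeric_pairs(_pairs(swapped)))
    again = classify_event(clusters2)
    assert (again.type, again.bp_a, again.bp_b) == (forward.type, forward.bp_a, forward.bp_b)


# --- junction characterisation --------------------------------------------


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_junction_with_poly_t_insert():
    # 18 consecutive thymines between the two reference flanks
    rng = np.random.default_rng(9)
    a, b = _random_seq(rng, 50), _random_seq(rng, 50)
    junction = a + "T" * 18 + b
    ins_len, ins_seq, micro = characterize_junction(junction, a, b)
    assert (ins_len, ins_seq, micro) == (18, "T" * 18, 0)


def test_blunt_junction():
    rng = np.random.default_rng(10)
    a, b = _random_seq(rng, 50), _random_seq(rng, 50)
    # guard against an accidental overlap at the join
    b = "G" + b[1:] if a[-1] == b[0] else b
    ins_len, ins_seq, micro = characterize_junction(a + b, a, b)
    assert (ins_len, ins_seq, micro) == (0, "", 0)


def test_microhomology_detected():
    rng = np.random.default_rng(11)
    core_a, core_b = _random_seq(rng, 46), _random_seq(rng, 46)
    hom = "ACGT"
    a = core_a + hom  # flank A ends with the shared 4-mer
    b = hom + core_b  # flank B starts with it
    junction = core_a + hom + core_b  # the 4-mer appears once at the join
    ins_len, ins_seq, micro = characterize_junction(junction, a, b)
    assert (ins_len, micro) == (0, 4)


def test_junction_matching_neither_flank_rejected():
    rng = np.random.default_rng(12)
    with pytest.raises(InputError):
        characterize_junction(_random_seq(rng, 40), _random_seq(rng, 40), _random_seq(rng, 40))
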