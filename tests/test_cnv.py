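import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from prenatalgs.cnv import (
    Candidate,
    ReferencePanel,
    WindowProfile,
    call_cnvs,
    cnv_size_kb,
    estimate_mosaic_fraction,
    infer_sex,
    normalize_windows,
    rank_sum_p,
    rare_cnv_test,
    refine_breakpoints,
    scan_candidates,
)
from prenatalgs.errors import CandidateRejected, ConfigError, InputError
from prenatalgs.simulate import SimConfig, TrueCNV, TruthSet, reference_panel, simulate_coverage
from tests_oracles import enumerated_ranksum_p


def _flat_profile(genome, count=800):
    grid = genome.window_grid(5000)
    grid["count"] = count
    grid["gc"] = 0.42
    grid["ratio"] = np.nan
    return WindowProfile("flat", grid)


# --- normalization ---------------------------------------------------------


def test_flat_counts_normalize_to_unity(genome):
    norm = normalize_windows(_flat_profile(genome))
    autos = norm.windows[~norm.windows["chrom"].isin(["chrX", "chrY"])]
    assert (autos["ratio"] == 1.0).all()


def test_halved_chromosome_normalizes_to_half(genome):
    prof = _flat_profile(genome)
    prof.windows.loc[prof.windows["chrom"] == "chr3", "count"] = 400
    norm = normalize_windows(prof)
    w = norm.windows
    assert w[w["chrom"] == "chr3"]["ratio"].mean() == pytest.approx(0.5)
    assert w[w["chrom"] == "chr1"]["ratio"].mean() == pytest.approx(1.0)


def test_gc_correction_flattens_ratio_gc_slope(genome):
    cfg = SimConfig(gc_bias=(2.0, 0.0))
    prof = simulate_coverage(genome, TruthSet(), cfg, seed=5, sex="female")
    biased = normalize_windows(prof, gc_correct=False)
    fixed = normalize_windows(prof, gc_correct=True)

    def slope(p):
        autos = p.windows[~p.windows["chrom"].isin(["chrX", "chrY"])]
        return np.polyfit(autos["gc"], autos["ratio"], 1)[0]

    assert abs(slope(biased)) > 0.5
    assert abs(slope(fixed)) < 0.05


def test_empty_profile_rejected():
    empty = pd.DataFrame(columns=["chrom", "start", "end", "count", "gc", "ratio"])
    with pytest.raises(InputError):
        normalize_windows(WindowProfile("x", empty))


def test_zero_count_windows_keep_zero_ratio(genome):
    prof = _flat_profile(genome)
    prof.windows.loc[prof.windows.index[:10], "count"] = 0
    norm = normalize_windows(prof)
    assert (norm.windows["ratio"].iloc[:10] == 0.0).all()


# --- sliding-window scan ---------------------------------------------------


def test_flat_profile_yields_no_candidates(genome):
    norm = normalize_windows(_flat_profile(genome))
    assert scan_candidates(norm, sex="female") == []


def test_scan_recovers_embedded_deletion(genome, cfg):
    # a 751,905-bp heterozygous deletion, same span as the worked example
    start, end = 29_538_256, 30_290_160
    truth = TruthSet(cnvs=[TrueCNV("chr1", start, end, "het-del")])
    norm = normalize_windows(simulate_coverage(genome, truth, cfg, seed=6, sex="female"))
    cands = [c for c in scan_candidates(norm, sex="female") if not c.whole_chromosome]
    assert len(cands) == 1
    c = cands[0]
    overlap = min(c.end, end) - max(c.start, start) + 1
    assert overlap / (end - start + 1) >= 0.95


def test_mosaic_chry_loss_flagged_at_chromosome_level(genome, cfg):
    truth = TruthSet(cnvs=[TrueCNV("chrY", 1, genome.length("chrY"), "chrom-loss", 0.4)])
    norm = normalize_windows(simulate_coverage(genome, truth, cfg, seed=7, sex="male"))
    assert infer_sex(norm) == "male"
    whole = [c for c in scan_candidates(norm) if c.whole_chromosome]
    assert [c.chrom for c in whole] == ["chrY"]
    assert whole[0].mean_ratio == pytest.approx(0.6 * 0.5, abs=0.02)


def test_step_must_divide_scan_window(genome):
    norm = normalize_windows(_flat_profile(genome))
    with pytest.raises(ConfigError):
        scan_candidates(norm, scan_bp=50_000, step_bp=7_000)


# --- breakpoint refinement -------------------------------------------------


def test_noise_free_edges_on_grid_recovered_exactly(genome):
    cfg = SimConfig(count_model="exact")
    start, end = 10_000_001, 10_500_000  # exactly on the 5-kb grid
    truth = TruthSet(cnvs=[TrueCNV("chr1", start, end, "het-del")])
    norm = normalize_windows(simulate_coverage(genome, truth, cfg, seed=1, sex="female"))
    cand = [c for c in scan_candidates(norm, sex="female") if not c.whole_chromosome][0]
    call = refine_breakpoints(norm, cand, sex="female")
    assert (call.start, call.end) == (start, end)
    assert call.type == "het-del"
    assert call.mosaic_fraction is None  # constitutional


def test_short_candidate_rejected(genome):
    norm = normalize_windows(_flat_profile(genome))
    cand = Candidate("chr1", 1, 5000, 0.5, 1)
    with pytest.raises(CandidateRejected):
        refine_breakpoints(norm, cand)


def test_deletion_size_matches_reported_kb(genome, cfg):
    truth = TruthSet(cnvs=[TrueCNV("chr1", 29_538_256, 30_290_160, "het-del")])
    norm = normalize_windows(simulate_coverage(genome, truth, cfg, seed=8, sex="female"))
    calls = call_cnvs(simulate_coverage(genome, truth, cfg, seed=8, sex="female"), sex="female")
    assert len(calls) == 1
    # breakpoints sit on the 5-kb grid: within one window of the true edges
    assert abs(calls[0].start - 29_538_256) <= 5000
    assert abs(calls[0].end - 30_290_160) <= 5000
    assert abs(calls[0].size_kb - 751.9) <= 10.0


# --- rarity test -----------------------------------------------------------


def _region_profile(genome, ratios, chrom="chr1"):
    """Profile whose first len(ratios) chr1 windows carry the given ratios."""
    prof = normalize_windows(_flat_profile(genome))
    idx = prof.windows[prof.windows["chrom"] == chrom].index[: len(ratios)]
    prof.windows.loc[idx, "ratio"] = ratios
    return prof


def test_strong_deletion_vs_clean_panel_is_kept(genome, cfg):
    start, end = 5_000_001, 5_750_000  # 150 windows
    truth = TruthSet(cnvs=[TrueCNV("chr1", start, end, "het-del")])
    norm = normalize_windows(simulate_coverage(genome, truth, cfg, seed=9, sex="male"))
    panel = reference_panel(genome, cfg, seed=77, n=30, sex="male")
    call = call_cnvs(simulate_coverage(genome, truth, cfg, seed=9, sex="male"), sex="male")[0]
    res = rare_cnv_test(call, norm, panel)
    assert res.p_value < 1e-4 and res.keep


def test_case_matching_panel_is_dropped(genome, cfg):
    norm = normalize_windows(simulate_coverage(genome, TruthSet(), cfg, seed=10, sex="male"))
    panel = reference_panel(genome, cfg, seed=78, n=10, sex="male")
    from prenatalgs.cnv import CNVCall

    call = CNVCall("chr1", 5_000_001, 5_750_000, "het-del", mean_ratio=1.0)
    res = rare_cnv_test(call, norm, panel)
    assert res.p_value > 1e-4 and not res.keep


def test_polymorphic_deletion_in_half_the_panel_is_dropped(genome, cfg):
    start, end = 5_000_001, 5_750_000
    event = TrueCNV("chr1", start, end, "het-del")
    truth = TruthSet(cnvs=[event])
    norm = normalize_windows(simulate_coverage(genome, truth, cfg, seed=11, sex="male"))
    truths = [TruthSet(cnvs=[event]) if i % 2 == 0 else TruthSet() for i in range(10)]
    panel = reference_panel(genome, cfg, seed=79, n=10, sex="male", truths=truths)
    call = call_cnvs(simulate_coverage(genome, truth, cfg, seed=11, sex="male"), sex="male")[0]
    res = rare_cnv_test(call, norm, panel)
    assert not res.keep
    assert res.reason == "polymorphism"
    assert res.carriers == 5


@pytest.mark.parametrize("m,n_samples,w", [(4, 2, 4), (5, 2, 5), (8, 1, 8), (4, 3, 4)])
def test_rank_sum_matches_brute_force_enumeration(m, n_samples, w):
    # region of w windows against a pooled panel of n_samples * w values
    rng = np.random.default_rng(m * 100 + n_samples)
    x = rng.normal(0.6, 0.05, size=m)
    y = rng.normal(1.0, 0.05, size=n_samples * w)
    assert rank_sum_p(x, y) == pytest.approx(enumerated_ranksum_p(x, y), rel=1e-9)
    # and under the null
    x0 = rng.normal(1.0, 0.05, size=m)
    assert rank_sum_p(x0, y) == pytest.approx(enumerated_ranksum_p(x0, y), rel=1e-9)


# --- mosaic fraction and size arithmetic -----------------------------------


def test_mosaic_fraction_algebra():
    # 40% of cells lacking the single-copy chromosome
    assert estimate_mosaic_fraction(0.6 * 0.5, 0.5, 0.0) == pytest.approx(0.40)
    assert estimate_mosaic_fraction(1.0, 1.0, 0.5) == 0.0
    assert estimate_mosaic_fraction(0.75, 1.0, 0.5) == pytest.approx(0.50)
    with pytest.raises(InputError):
        estimate_mosaic_fraction(0.5, 1.0, 1.0)


def test_mosaic_fraction_clamped_to_unit_interval():
    assert estimate_mosaic_fraction(1.2, 1.0, 0.5) == 0.0
    assert estimate_mosaic_fraction(0.1, 1.0, 0.5) == 1.0


@pytest.mark.parametrize(
    "start,end,expected",
    [
        (29_538_256, 30_290_160, 751.9),
        (29_832_358, 30_091_372, 259.0),
        (122_757_221, 122_907_271, 150.1),
        (100, 100, 0.0),
    ],
)
def test_cnv_size_kb_reported_examples(start, end, expected):
    assert cnv_size_kb(start, end) == expected


def test_cnv_size_kb_rejects_reversed_interval():
    with pytest.raises(InputError):
        cnv_size_kb(200, 100)


@given(
    start=st.integers(min_value=1, max_value=10**8),
    length=st.integers(min_value=0, max_value=10**7),
)
def test_cnv_size_kb_matches_direct_arithmetic(start, length):
    end = start + length
    assert cnv_size_kb(start, end) == pytest.approx((length + 1) / 1000, abs=0.051)


# --- whole-pipeline sanity -------------------------------------------------


def test_no_calls_on_flat_noisy_profile(genome, cfg):
    prof = simulate_coverage(genome, TruthSet(), cfg, seed=13, sex="female")
    assert call_cnvs(prof, sex="female") == []


def test_mosaic_recovery_across_fractions(genome, cfg):
    # whole-chromosome mosaics at 20-80%: per-replicate error under 5 points
    for frac in (0.2, 0.4, 0.6, 0.8):
        estimates = []
        for rep in range(10):
            truth = TruthSet(
                cnvs=[TrueCNV("chrY", 1, genome.length("chrY"), "chrom-loss", frac)]
            )
            prof = simulate_coverage(genome, truth, cfg, seed=1000 + rep, sex="male")
            norm = normalize_windows(prof)
            whole = [c for c in scan_candidates(norm) if c.whole_chromosome]
            assert whole, f"mosaic fraction {frac} not detected"
            estimates.append(estimate_mosaic_fraction(whole[0].mean_ratio, 0.5, 0.0))
        assert np.all(np.abs(np.array(estimates) - frac) < 0.05)
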