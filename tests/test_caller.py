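import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rohscan.caller import (
    ROHCallParams,
    ThresholdParams,
    call_roh,
    count_all_hom_windows,
    expected_chance_windows,
    information_reduction,
    ld_adjusted_length,
    mean_heterozygosity,
    min_run_length,
    segments_from_frame,
    segments_to_frame,
)
from rohscan.model import HET, HOM_A1, HOM_A2, MISSING
from rohscan.simulate import simulate_iid_null

from conftest import make_panel

COHORT_SCALE = ThresholdParams(
    heterozygosity_h=0.34, n_snps_S=484_072, n_samples_N=5_788
)


# ----------------------------------------------------------------------
# independent oracles
# ----------------------------------------------------------------------


def window_score_oracle(genotype_row, params):
    """Flagged-SNP set computed with explicit loops straight from the
    window rule definition (no cumulative sums, no vectorization)."""
    g = list(genotype_row)
    nc = len(g)
    w = params.window_snp
    if nc < w:
        return []
    passing = []
    for j in range(nc - w + 1):
        window = g[j : j + w]
        het = sum(1 for x in window if x == HET)
        mis = sum(1 for x in window if x == MISSING)
        passing.append(het <= params.window_het_max and mis <= params.window_missing_max)
    flagged = []
    for i in range(nc):
        covering = [j for j in range(len(passing)) if j <= i <= j + w - 1]
        score = sum(passing[j] for j in covering) / len(covering)
        if score >= params.snp_flag_threshold - 1e-12:
            flagged.append(i)
    return flagged


def maximal_run_scanner(panel, min_snp):
    """Maximal perfectly homozygous runs of at least min_snp SNPs,
    per sample and chromosome (inclusive chromosome-local indices)."""
    out = []
    for chrom, block in panel.chrom_blocks():
        g = panel.genotypes[:, block]
        for si in range(panel.n_samples):
            row = g[si]
            start = None
            for i in range(len(row) + 1):
                hom = i < len(row) and row[i] in (HOM_A1, HOM_A2)
                if hom and start is None:
                    start = i
                elif not hom and start is not None:
                    if i - start >= min_snp:
                        out.append((panel.samples[si].sample_id, chrom, start, i - 1))
                    start = None
    return sorted(out)


def _segments_as_tuples(segments):
    return sorted(
        (s.sample_id, s.chromosome, s.start_index, s.end_index) for s in segments
    )


# ----------------------------------------------------------------------
# calibration
# ----------------------------------------------------------------------


def test_mean_heterozygosity_examples():
    assert mean_heterozygosity(make_panel([[HET, HET], [HET, HET]])) == 1.0
    assert mean_heterozygosity(make_panel([[HET, 0, 2, 0, MISSING]])) == 0.25


def test_mean_heterozygosity_counting_oracle(rng):
    g = rng.integers(-1, 3, size=(20, 100)).astype(np.int8)
    panel = make_panel(g)
    het = sum(1 for x in g.ravel() if x == HET)
    called = sum(1 for x in g.ravel() if x != MISSING)
    assert mean_heterozygosity(panel) == pytest.approx(het / called)


def test_mean_heterozygosity_empty_subset_raises():
    panel = make_panel([[MISSING, MISSING]])
    with pytest.raises(ValueError):
        mean_heterozygosity(panel)


def test_expected_chance_windows_limits():
    assert expected_chance_windows(
        ThresholdParams(0.999999, 10, 10), 5
    ) == pytest.approx(0.0, abs=1e-20)
    tp = ThresholdParams(0.0, 100, 7)
    assert expected_chance_windows(tp, 3) == 700


def test_expected_chance_windows_cohort_scale():
    assert expected_chance_windows(COHORT_SCALE, 60) == pytest.approx(
        0.66**60 * 484_072 * 5_788
    )


def test_min_run_length_examples():
    assert min_run_length(COHORT_SCALE) == 60
    assert min_run_length(ThresholdParams(0.5, 1, 1, alpha=0.6)) == 1
    # linear-scan oracle for a tighter alpha
    tp = ThresholdParams(0.34, 484_072, 5_788, alpha=0.001)
    scan = next(
        L for L in range(1, 1000) if 0.66**L * 484_072 * 5_788 < 0.001
    )
    assert min_run_length(tp) == scan == 69


def test_min_run_length_h_zero_has_no_solution():
    with pytest.raises(ValueError):
        min_run_length(ThresholdParams(0.0, 10, 10, alpha=0.05))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.floats(0.05, 0.95),
    st.integers(10, 10**6),
    st.integers(10, 10**4),
    st.floats(1e-4, 0.5),
)
def test_min_run_length_monotone_in_alpha_and_scale(h, s, n, alpha):
    base = min_run_length(ThresholdParams(h, s, n, alpha=alpha))
    looser = min_run_length(ThresholdParams(h, s, n, alpha=alpha * 2))
    bigger = min_run_length(ThresholdParams(h, 2 * s, 2 * n, alpha=alpha))
    assert looser <= base <= bigger


def test_ld_adjusted_length():
    tp = ThresholdParams(0.34, 484_072, 5_788, n_tag_groups_T=363_152)
    assert ld_adjusted_length(60, tp) == 80
    same = ThresholdParams(0.34, 1000, 10, n_tag_groups_T=1000)
    assert ld_adjusted_length(60, same) == 60
    half = ThresholdParams(0.34, 100, 10, n_tag_groups_T=50)
    assert ld_adjusted_length(10, half) == 20


def test_information_reduction():
    assert information_reduction(100, 75) == pytest.approx(0.25)
    with pytest.raises(ValueError):
        information_reduction(100, 0)


# ----------------------------------------------------------------------
# detection
# ----------------------------------------------------------------------


def _hom_row(n):
    return np.full(n, HOM_A1, dtype=np.int8)


def test_uniform_homozygous_chromosome_yields_single_full_segment():
    panel = make_panel(_hom_row(100).reshape(1, -1))
    segs = call_roh(panel, ROHCallParams())
    assert len(segs) == 1
    (s,) = segs
    assert (s.start_index, s.end_index, s.n_snps, s.n_het) == (0, 99, 100, 0)
    assert s.start_bp == panel.positions[0] and s.end_bp == panel.positions[99]


def test_run_below_min_snp_not_called():
    panel = make_panel(_hom_row(83).reshape(1, -1))
    assert call_roh(panel, ROHCallParams()) == []


def test_single_het_inside_long_run_is_absorbed():
    g = _hom_row(200)
    g[100] = HET
    panel = make_panel(g.reshape(1, -1))
    segs = call_roh(panel, ROHCallParams())
    assert len(segs) == 1
    (s,) = segs
    assert (s.start_index, s.end_index, s.n_het, s.n_missing) == (0, 199, 1, 0)


def test_interior_run_edges_trimmed_by_window_score():
    """A homozygous tract bounded by heterozygous SNPs in the chromosome
    interior loses 2 SNPs per side: edge SNPs are covered by fewer than
    5% passing windows."""
    g = np.full(300, HET, dtype=np.int8)
    g[100:200] = HOM_A1  # 100-SNP tract at positions 100..199
    panel = make_panel(g.reshape(1, -1))
    segs = call_roh(
        panel,
        ROHCallParams(window_het_max=0, min_snp=84, min_kb=None,
                      max_gap_kb=None, min_density_kb_per_snp=None),
    )
    assert len(segs) == 1
    assert (segs[0].start_index, segs[0].end_index) == (102, 197)
    assert segs[0].n_snps == 96


def test_flagging_matches_window_score_oracle(rng):
    params = ROHCallParams(
        window_snp=10, window_het_max=1, window_missing_max=2,
        snp_flag_threshold=0.05, min_snp=5, min_kb=None, max_gap_kb=None,
        min_density_kb_per_snp=None,
    )
    from rohscan.caller import _flag_snps

    for _ in range(10):
        row = rng.choice(
            [HOM_A1, HET, HOM_A2, MISSING], size=60, p=[0.55, 0.2, 0.2, 0.05]
        ).astype(np.int8)
        het = (row == HET).astype(np.int8).reshape(1, -1)
        mis = (row == MISSING).astype(np.int8).reshape(1, -1)
        got = np.flatnonzero(_flag_snps(het, mis, params)[0]).tolist()
        assert got == window_score_oracle(row, params)


def test_caller_equals_scanner_with_permissive_threshold(rng):
    """With threshold 1/W (any passing window flags a SNP), H=0, M=0 and
    gap/length/density disabled, the windowed caller reduces exactly to
    the maximal homozygous run scanner for runs >= W."""
    params = ROHCallParams(
        window_snp=20, window_het_max=0, window_missing_max=0,
        snp_flag_threshold=1 / 20, min_snp=25, min_kb=None, max_gap_kb=None,
        min_density_kb_per_snp=None,
    )
    for _ in range(5):
        g = rng.choice([HOM_A1, HOM_A2, HET], size=(8, 400), p=[0.4, 0.4, 0.2])
        # plant a few long runs crossing the min_snp boundary
        for si, start, ln in [(0, 50, 30), (1, 100, 25), (2, 200, 24), (3, 300, 60)]:
            g[si, start : start + ln] = HOM_A1
        panel = make_panel(g.astype(np.int8))
        got = _segments_as_tuples(call_roh(panel, params))
        assert got == maximal_run_scanner(panel, params.min_snp)


def test_gap_splitting_breaks_runs_at_large_intervals():
    positions = list(range(20_000, 20_000 * 101, 20_000))
    positions = positions[:50] + [p + 2_000_000 for p in positions[50:]]
    panel = make_panel(_hom_row(100).reshape(1, -1), positions=positions)
    segs = call_roh(
        panel,
        ROHCallParams(min_snp=10, min_kb=None, max_gap_kb=1000,
                      min_density_kb_per_snp=None),
    )
    assert len(segs) == 2
    assert segs[0].end_index == 49 and segs[1].start_index == 50


def test_min_kb_and_density_filters():
    # 100 hom SNPs spaced 5 kb apart: span 495 kb < 1000 kb -> filtered
    panel = make_panel(_hom_row(100).reshape(1, -1), spacing_bp=5_000)
    assert call_roh(panel, ROHCallParams()) == []
    # spacing 60 kb: density 60 kb/SNP > 50 -> filtered
    panel = make_panel(_hom_row(100).reshape(1, -1), spacing_bp=60_000)
    assert call_roh(panel, ROHCallParams()) == []


def test_chromosome_shorter_than_window_yields_no_calls(caplog):
    panel = make_panel(_hom_row(30).reshape(1, -1))
    with caplog.at_level("WARNING", logger="rohscan.caller"):
        assert call_roh(panel, ROHCallParams()) == []
    assert "no calls" in caplog.text


def test_segments_never_span_chromosomes():
    g = _hom_row(200).reshape(1, -1)
    panel = make_panel(g, chromosomes=[1] * 100 + [2] * 100)
    segs = call_roh(panel, ROHCallParams())
    assert len(segs) == 2
    assert sorted(s.chromosome for s in segs) == [1, 2]
    assert all(s.n_snps == 100 for s in segs)


def test_null_window_count_matches_expectation_small():
    panel = simulate_iid_null(50, 5_000, 0.34, seed=5)
    count = count_all_hom_windows(panel, 20)
    expected = (5_000 - 20 + 1) * 0.66**20 * 50
    assert abs(count - expected) <= 3 * np.sqrt(expected) + 3 * np.sqrt(count + 1)


def test_segment_frame_round_trip(rng):
    g = rng.choice([HOM_A1, HOM_A2, HET], size=(5, 300), p=[0.45, 0.45, 0.1])
    g[2, 50:250] = HOM_A2
    panel = make_panel(g.astype(np.int8))
    segs = call_roh(panel, ROHCallParams(min_kb=None))
    assert segs  # the planted tract is called
    frame = segments_to_frame(segs, panel)
    back = segments_from_frame(frame, panel)
    assert _segments_as_tuples(back) == _segments_as_tuples(segs)
    assert list(frame.columns) == [
        "FID", "IID", "CHR", "POS1", "POS2", "KB", "NSNP", "NHET", "NMIS"
    ]
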