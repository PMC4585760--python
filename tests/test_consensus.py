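import numpy as np
import pytest

from rohscan.caller import ROHSegment
from rohscan.consensus import (
    carrier_table,
    consensus_from_frame,
    consensus_to_frame,
    find_common_roh,
    roh_indicator_matrix,
)

from conftest import make_panel


def exhaustive_consensus_oracle(indicator, chromosomes, min_carriers, min_snps):
    """Slow explicit-loop reference for the prune/trim procedure.

    Returns a list of (chrom, start, end, carrier_rows) with global SNP
    indices, one per consensus region, in genome order.
    """
    ind = (np.asarray(indicator) > 0).astype(int).copy()
    n, s = ind.shape
    # step 1: zero low-carrier columns
    for j in range(s):
        if sum(ind[i][j] for i in range(n)) < min_carriers:
            for i in range(n):
                ind[i][j] = 0
    # step 2: delete short per-sample runs (within chromosomes)
    for i in range(n):
        j = 0
        while j < s:
            if ind[i][j] == 1:
                k = j
                while (
                    k + 1 < s
                    and ind[i][k + 1] == 1
                    and chromosomes[k + 1] == chromosomes[k]
                ):
                    k += 1
                if k - j + 1 < min_snps:
                    for t in range(j, k + 1):
                        ind[i][t] = 0
                j = k + 1
            else:
                j += 1
    # step 3: maximal high-count intervals per chromosome
    counts = [sum(ind[i][j] for i in range(n)) for j in range(s)]
    regions = []
    j = 0
    while j < s:
        if counts[j] >= min_carriers:
            k = j
            while (
                k + 1 < s
                and counts[k + 1] >= min_carriers
                and chromosomes[k + 1] == chromosomes[k]
            ):
                k += 1
            if k - j + 1 >= min_snps:
                regions.append((j, k))
            j = k + 1
        else:
            j += 1

    def covers(i, a, b):
        return all(ind[i][t] == 1 for t in range(a, b + 1))

    out = []
    for lo, hi in regions:
        # step 4: exhaustive search for the sub-interval with the most
        # full-coverage carriers; ties -> longer, then leftmost
        best = None
        for a in range(lo, hi - min_snps + 2):
            for b in range(a + min_snps - 1, hi + 1):
                carriers = [i for i in range(n) if covers(i, a, b)]
                if len(carriers) < min_carriers:
                    continue
                key = (len(carriers), b - a, -a)
                if best is None or key > best[0]:
                    best = (key, a, b, carriers)
        if best is None:
            carriers = [i for i in range(n) if covers(i, lo, hi)]
            out.append((chromosomes[lo], lo, hi, carriers, True))
        else:
            _, a, b, carriers = best
            out.append((chromosomes[a], a, b, carriers, False))
    return out


def _as_tuples(regions, panel):
    row = {s.sample_id: i for i, s in enumerate(panel.samples)}
    return [
        (
            r.chromosome,
            r.start_index,
            r.end_index,
            [row[c] for c in r.carriers],
            r.low_coverage,
        )
        for r in regions
    ]


def _panel_for(n, s, chromosomes=None):
    return make_panel(
        np.zeros((n, s), dtype=np.int8), chromosomes=chromosomes
    )


def _seg(sample_id, a, b, panel, chrom=1):
    off = {c: bl.start for c, bl in panel.chrom_blocks()}[chrom]
    pos = panel.positions
    return ROHSegment(
        sample_id=sample_id,
        chromosome=chrom,
        start_bp=int(pos[off + a]),
        end_bp=int(pos[off + b]),
        start_index=a,
        end_index=b,
        n_snps=b - a + 1,
        n_het=0,
        n_missing=0,
    )


# ----------------------------------------------------------------------
# indicator matrix
# ----------------------------------------------------------------------


def test_indicator_empty_and_single_segment():
    panel = _panel_for(4, 20)
    assert roh_indicator_matrix([], panel).sum() == 0
    ind = roh_indicator_matrix([_seg("S3", 5, 10, panel)], panel)
    assert ind.sum() == 6
    assert ind[3, 5:11].all()


def test_indicator_overlapping_segments_union_idempotent():
    panel = _panel_for(2, 30)
    segs = [_seg("S0", 3, 12, panel), _seg("S0", 8, 20, panel)]
    ind = roh_indicator_matrix(segs, panel)
    expected = set(range(3, 21))
    assert set(np.flatnonzero(ind[0])) == expected
    assert np.array_equal(ind, roh_indicator_matrix(segs + segs, panel))


def test_indicator_rejects_out_of_panel_segment():
    panel = _panel_for(1, 10)
    with pytest.raises(ValueError, match="outside"):
        roh_indicator_matrix([_seg("S0", 5, 9, panel)._replace_end(12)], panel)


# dataclass is frozen; helper builds an out-of-range segment directly
def _replace_end(self, end):
    return ROHSegment(
        sample_id=self.sample_id,
        chromosome=self.chromosome,
        start_bp=self.start_bp,
        end_bp=self.end_bp + 1,
        start_index=self.start_index,
        end_index=end,
        n_snps=end - self.start_index + 1,
        n_het=0,
        n_missing=0,
    )


ROHSegment._replace_end = _replace_end


# ----------------------------------------------------------------------
# consensus
# ----------------------------------------------------------------------


def _aligned_indicator(n_carriers, n_samples=15, s=120, a=10, b=89):
    ind = np.zeros((n_samples, s), dtype=np.uint8)
    ind[:n_carriers, a : b + 1] = 1
    return ind


def test_fully_aligned_runs_make_one_consensus():
    panel = _panel_for(15, 120)
    regions = find_common_roh(_aligned_indicator(12), panel)
    assert len(regions) == 1
    (r,) = regions
    assert (r.start_index, r.end_index, r.n_snps) == (10, 89, 80)
    assert len(r.carriers) == 12 and not r.low_coverage
    assert r.roh_id == "ROH1"


def test_too_few_carriers_yield_no_consensus():
    panel = _panel_for(15, 120)
    assert find_common_roh(_aligned_indicator(9), panel) == []


def test_staggered_hand_trace():
    """12 samples share SNPs 0-99; 5 more share 39-139.  Columns 100-139
    drop below 10 carriers and are zeroed; the five trimmed runs (61
    SNPs) fall below 75 and are deleted; one consensus remains over SNPs
    0-99 with the 12 aligned carriers."""
    panel = _panel_for(17, 140)
    ind = np.zeros((17, 140), dtype=np.uint8)
    ind[:12, 0:100] = 1
    ind[12:, 39:140] = 1
    regions = find_common_roh(ind, panel, min_carriers=10, min_snps=75)
    assert len(regions) == 1
    (r,) = regions
    assert (r.start_index, r.end_index) == (0, 99)
    assert sorted(r.carriers) == sorted(f"S{i}" for i in range(12))
    assert not r.low_coverage


def test_matches_exhaustive_oracle_on_staggered_fixture():
    panel = _panel_for(17, 140)
    ind = np.zeros((17, 140), dtype=np.uint8)
    ind[:12, 0:100] = 1
    ind[12:, 39:140] = 1
    got = _as_tuples(find_common_roh(ind, panel, 10, 75), panel)
    want = exhaustive_consensus_oracle(ind, [1] * 140, 10, 75)
    assert got == want


def _random_indicator(rng, n=20, s=200, max_runs=3):
    ind = np.zeros((n, s), dtype=np.uint8)
    for i in range(n):
        for _ in range(rng.integers(0, max_runs + 1)):
            ln = int(rng.integers(5, 100))
            a = int(rng.integers(0, s - ln + 1))
            ind[i, a : a + ln] = 1
    return ind


def test_matches_exhaustive_oracle_on_random_indicators(rng):
    chromosomes = [1] * 100 + [2] * 100
    panel = _panel_for(20, 200, chromosomes=chromosomes)
    for _ in range(25):
        ind = _random_indicator(rng)
        got = _as_tuples(find_common_roh(ind, panel, 5, 20), panel)
        want = exhaustive_consensus_oracle(ind, chromosomes, 5, 20)
        assert got == want


def test_consensus_idempotent_on_own_output(rng):
    panel = _panel_for(20, 200)
    for _ in range(10):
        ind = _random_indicator(rng)
        regions = find_common_roh(ind, panel, 5, 20)
        restricted = np.zeros_like(ind)
        row = {s.sample_id: i for i, s in enumerate(panel.samples)}
        for r in regions:
            for c in r.carriers:
                restricted[row[c], r.start_index : r.end_index + 1] = 1
        again = find_common_roh(restricted, panel, 5, 20)
        assert _as_tuples(again, panel) == _as_tuples(regions, panel)


def test_reported_regions_are_sound(rng):
    """Every unflagged region's carriers genuinely cover its full
    interval in the input indicator, and number at least min_carriers;
    regions never span chromosomes and are reported in genome order."""
    chromosomes = [1] * 100 + [2] * 100
    panel = _panel_for(20, 200, chromosomes=chromosomes)
    row = {s.sample_id: i for i, s in enumerate(panel.samples)}
    for _ in range(10):
        ind = _random_indicator(rng)
        for min_carriers in (4, 8):
            regions = find_common_roh(ind, panel, min_carriers, 20)
            keys = [(r.chromosome, r.start_bp) for r in regions]
            assert keys == sorted(keys)
            for r in regions:
                assert chromosomes[r.start_index] == chromosomes[r.end_index]
                if r.low_coverage:
                    continue
                assert len(r.carriers) >= min_carriers
                for c in r.carriers:
                    assert ind[row[c], r.start_index : r.end_index + 1].all()


def test_parameter_validation():
    panel = _panel_for(2, 10)
    with pytest.raises(ValueError):
        find_common_roh(np.zeros((2, 10), dtype=np.uint8), panel, 0, 10)


# ----------------------------------------------------------------------
# carrier table
# ----------------------------------------------------------------------


def test_carrier_table_bounds_and_recount():
    panel = _panel_for(15, 120)
    regions = find_common_roh(_aligned_indicator(12), panel)
    table = carrier_table(regions, panel.samples)
    counts = table.sum(axis=1)
    assert counts.max() == len(regions)  # carrier of every region
    assert counts.min() == 0  # empty indicator sample
    # direct membership recount
    for k, r in enumerate(regions):
        members = {c for c in r.carriers}
        for i, s in enumerate(panel.samples):
            assert table[i, k] == (s.sample_id in members)


def test_consensus_frame_round_trip():
    panel = _panel_for(15, 120, chromosomes=[1] * 60 + [2] * 60)
    ind = np.zeros((15, 120), dtype=np.uint8)
    ind[:11, 65:115] = 1
    regions = find_common_roh(ind, panel, 10, 40)
    assert regions and regions[0].chromosome == 2
    frame = consensus_to_frame(regions)
    back = consensus_from_frame(frame, panel)
    assert [(r.roh_id, r.start_index, r.end_index, r.carriers) for r in back] == [
        (r.roh_id, r.start_index, r.end_index, r.carriers) for r in regions
    ]
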