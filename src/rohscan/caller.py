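"""Run-of-homozygosity detection and analytic calibration of the minimum
informative run length.

Calibration
-----------
Under a null of independent SNP calls that are heterozygous with
probability ``h``, the expected number of all-homozygous runs of length
``L`` across a cohort is approximated by the window count

    E[chance runs] = (1 - h)**L * S * N

with ``S`` SNPs and ``N`` individuals (no run-boundary correction).  The
minimum informative length is the smallest ``L`` driving this expectation
below a tolerance ``alpha``.  Because SNP-array markers are correlated,
the count of linkage-disequilibrium tag groups ``T`` (effectively
independent markers) is used to stretch an independent-call length onto
the SNP grid: ``ceil(L * S / T)``.

Detection
---------
The caller slides a window of ``W`` consecutive SNPs along each
chromosome for each sample.  A window passes when it contains at most
``H`` heterozygous and at most ``M`` missing calls; each SNP is scored by
the fraction of the windows containing it that pass, and is flagged when
the score reaches the flag threshold.  Maximal runs of flagged SNPs,
split at large inter-SNP gaps, become segments if they satisfy the SNP
count, physical length and SNP density criteria.

With the default 5% flag threshold and ``W`` = 50 a SNP needs at least 3
passing windows out of 50 when it sits in the chromosome interior, so
called segments start and end 2 SNPs inside the underlying homozygous
run; runs abutting a chromosome end are covered by fewer windows and are
not trimmed there.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import HET, MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class ThresholdParams:
    """Inputs to the chance-run calibration.

    heterozygosity_h : fraction of non-missing calls that are heterozygous
    n_snps_S, n_samples_N : panel dimensions
    alpha : tolerated expected number of chance runs cohort-wide
    n_tag_groups_T : LD-pruned count of effectively independent markers
    """

    heterozygosity_h: float
    n_snps_S: int
    n_samples_N: int
    alpha: float = 0.05
    n_tag_groups_T: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.heterozygosity_h < 1.0:
            raise ValueError("heterozygosity_h must be in [0, 1)")
        if self.n_snps_S <= 0 or self.n_samples_N <= 0:
            raise ValueError("S and N must be positive")
        if self.n_tag_groups_T is not None:
            if self.n_tag_groups_T <= 0:
                raise ValueError("n_tag_groups_T must be positive")
            if self.n_tag_groups_T > self.n_snps_S:
                raise ValueError("n_tag_groups_T cannot exceed n_snps_S")


@dataclass
class ROHCallParams:
    """Sliding-window parameters.

    Defaults follow the conventional tool settings: window of 50 SNPs
    allowing 1 heterozygote (2% of the window) and 5 missing calls, a 5%
    SNP flag threshold, minimum segment size 84 SNPs and 1000 kb, runs
    split at gaps over 1000 kb, and a maximum of 50 kb per SNP.  Length,
    gap and density criteria can be disabled by passing ``None``.
    """

    window_snp: int = 50
    window_het_max: int = 1
    window_missing_max: int = 5
    snp_flag_threshold: float = 0.05
    min_snp: int = 84
    min_kb: float | None = 1000.0
    max_gap_kb: float | None = 1000.0
    min_density_kb_per_snp: float | None = 50.0

    def __post_init__(self) -> None:
        if self.window_het_max >= self.window_snp:
            raise ValueError("window_het_max must be below window_snp")
        if self.window_missing_max >= self.window_snp:
            raise ValueError("window_missing_max must be below window_snp")
        if self.min_snp < 1:
            raise ValueError("min_snp must be at least 1")


@dataclass(frozen=True)
class ROHSegment:
    """One called run of homozygosity for one sample.

    Coordinates are 1-based inclusive base pairs; indices are SNP offsets
    within the segment's chromosome.
    """

    sample_id: str
    chromosome: int
    start_bp: int
    end_bp: int
    start_index: int
    end_index: int
    n_snps: int
    n_het: int
    n_missing: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp or self.start_index > self.end_index:
            raise ValueError("segment start must not exceed end")
        if self.n_snps != self.end_index - self.start_index + 1:
            raise ValueError("n_snps inconsistent with index range")
        if self.n_het + self.n_missing > self.n_snps:
            raise ValueError("het + missing cannot exceed segment SNP count")

    @property
    def span_kb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1000.0


# ----------------------------------------------------------------------
# calibration
# ----------------------------------------------------------------------


def mean_heterozygosity(
    panel: GenotypeMatrix, subset: np.ndarray | None = None
) -> float:
    """Fraction of heterozygous calls among all non-missing calls in the
    (optionally subset) panel."""
    g = panel.genotypes if subset is None else panel.genotypes[subset]
    if g.size == 0:
        raise ValueError("empty sample subset")
    called = int((g != MISSING).sum())
    if called == 0:
        raise ValueError("subset has no non-missing genotype calls")
    return float((g == HET).sum() / called)


def expected_chance_windows(params: ThresholdParams, run_length: int) -> float:
    """Expected cohort-wide count of chance all-homozygous runs of the
    given length: (1 - h)**L * S * N."""
    if run_length < 1:
        raise ValueError("run length must be at least 1")
    return (
        (1.0 - params.heterozygosity_h) ** run_length
        * params.n_snps_S
        * params.n_samples_N
    )


def min_run_length(params: ThresholdParams, max_length: int = 1_000_000) -> int:
    """Smallest run length whose expected chance count falls strictly
    below ``alpha``."""
    if params.alpha <= 0:
        raise ValueError("alpha must be positive")
    if params.heterozygosity_h == 0.0:
        raise ValueError(
            "no finite run length suppresses chance runs when h = 0"
        )
    for length in range(1, max_length + 1):
        if expected_chance_windows(params, length) < params.alpha:
            return length
    raise ValueError(f"no solution below max_length={max_length}")


def ld_adjusted_length(run_length_independent: int, params: ThresholdParams) -> int:
    """SNP count whose independent information content matches
    ``run_length_independent`` tag groups: ceil(L * S / T)."""
    t = params.n_tag_groups_T
    if t is None or t <= 0:
        raise ValueError("n_tag_groups_T must be set and positive")
    return -(-run_length_independent * params.n_snps_S // t)


def information_reduction(n_snps: int, n_tag_groups: int) -> float:
    """Fractional loss of independent information due to LD:
    1 - T / S."""
    if n_snps <= 0 or n_tag_groups <= 0:
        raise ValueError("counts must be positive")
    return 1.0 - n_tag_groups / n_snps


# ----------------------------------------------------------------------
# detection
# ----------------------------------------------------------------------


def _window_sums(x: np.ndarray, w: int) -> np.ndarray:
    """Sliding sums of width ``w`` along the last axis."""
    cs = np.zeros((x.shape[0], x.shape[1] + 1), dtype=np.int32)
    np.cumsum(x, axis=1, out=cs[:, 1:])
    return cs[:, w:] - cs[:, :-w]


def _flag_snps(
    het: np.ndarray, mis: np.ndarray, params: ROHCallParams
) -> np.ndarray:
    """Boolean flag per (sample, SNP) from the window-score rule."""
    w = params.window_snp
    nc = het.shape[1]
    passing = (
        (_window_sums(het, w) <= params.window_het_max)
        & (_window_sums(mis, w) <= params.window_missing_max)
    ).astype(np.int32)
    nw = nc - w + 1
    # windows covering SNP i are starts j in [max(0, i-w+1), min(nw-1, i)]
    cs = np.zeros((het.shape[0], nw + 1), dtype=np.int32)
    np.cumsum(passing, axis=1, out=cs[:, 1:])
    i = np.arange(nc)
    lo = np.maximum(0, i - w + 1)
    hi = np.minimum(nw - 1, i)
    n_pass = cs[:, hi + 1] - cs[:, lo]
    n_cover = hi - lo + 1
    return n_pass >= params.snp_flag_threshold * n_cover - 1e-9


def call_roh(panel: GenotypeMatrix, params: ROHCallParams) -> list[ROHSegment]:
    """Call runs of homozygosity for every sample in the panel."""
    segments: list[ROHSegment] = []
    max_gap_bp = (
        None if params.max_gap_kb is None else params.max_gap_kb * 1000.0
    )
    for chrom, block in panel.chrom_blocks():
        nc = block.stop - block.start
        if nc < params.window_snp:
            logger.warning(
                "chromosome %d has %d SNPs (< window of %d); no calls made",
                chrom,
                nc,
                params.window_snp,
            )
            continue
        g = panel.genotypes[:, block]
        het = (g == HET).astype(np.int8)
        mis = (g == MISSING).astype(np.int8)
        flags = _flag_snps(het, mis, params)
        pos = panel.positions[block]
        gap_break = (
            np.zeros(nc - 1, dtype=bool)
            if max_gap_bp is None
            else np.diff(pos) > max_gap_bp
        )
        het_cs = np.zeros((panel.n_samples, nc + 1), dtype=np.int32)
        np.cumsum(het, axis=1, out=het_cs[:, 1:])
        mis_cs = np.zeros((panel.n_samples, nc + 1), dtype=np.int32)
        np.cumsum(mis, axis=1, out=mis_cs[:, 1:])
        for si in range(panel.n_samples):
            idx = np.flatnonzero(flags[si])
            if idx.size == 0:
                continue
            # split flagged runs at index discontinuities and large gaps
            brk = (np.diff(idx) > 1) | gap_break[idx[:-1]]
            run_starts = np.concatenate(([0], np.flatnonzero(brk) + 1))
            run_stops = np.concatenate((np.flatnonzero(brk), [idx.size - 1]))
            sid = panel.samples[si].sample_id
            for a, b in zip(run_starts, run_stops):
                ia, ib = int(idx[a]), int(idx[b])
                n_snps = ib - ia + 1
                if n_snps < params.min_snp:
                    continue
                span_kb = (pos[ib] - pos[ia] + 1) / 1000.0
                if params.min_kb is not None and span_kb < params.min_kb:
                    continue
                if (
                    params.min_density_kb_per_snp is not None
                    and span_kb / n_snps > params.min_density_kb_per_snp
                ):
                    continue
                segments.append(
                    ROHSegment(
                        sample_id=sid,
                        chromosome=chrom,
                        start_bp=int(pos[ia]),
                        end_bp=int(pos[ib]),
                        start_index=ia,
                        end_index=ib,
                        n_snps=n_snps,
                        n_het=int(het_cs[si, ib + 1] - het_cs[si, ia]),
                        n_missing=int(mis_cs[si, ib + 1] - mis_cs[si, ia]),
                    )
                )
    return segments


def count_all_hom_windows(panel: GenotypeMatrix, window_snps: int) -> int:
    """Total number of windows of ``window_snps`` consecutive SNPs that
    are entirely homozygous (no heterozygous, no missing call), summed
    over samples and chromosomes.  Used for null calibration."""
    total = 0
    for _, block in panel.chrom_blocks():
        nc = block.stop - block.start
        if nc < window_snps:
            continue
        g = panel.genotypes[:, block]
        bad = ((g == HET) | (g == MISSING)).astype(np.int8)
        total += int((_window_sums(bad, window_snps) == 0).sum())
    return total


# ----------------------------------------------------------------------
# tabular interchange (.hom-like layout)
# ----------------------------------------------------------------------

_HOM_COLUMNS = ["FID", "IID", "CHR", "POS1", "POS2", "KB", "NSNP", "NHET", "NMIS"]


def segments_to_frame(
    segments: list[ROHSegment], panel: GenotypeMatrix
) -> pd.DataFrame:
    """Segments as a conventional .hom-style table."""
    fid = {s.sample_id: s.family_id for s in panel.samples}
    rows = [
        (
            fid[s.sample_id],
            s.sample_id,
            s.chromosome,
            s.start_bp,
            s.end_bp,
            round(s.span_kb, 3),
            s.n_snps,
            s.n_het,
            s.n_missing,
        )
        for s in segments
    ]
    return pd.DataFrame(rows, columns=_HOM_COLUMNS)


def segments_from_frame(
    frame: pd.DataFrame, panel: GenotypeMatrix
) -> list[ROHSegment]:
    """Rebuild segments from a .hom-style table against the panel's SNP map."""
    pos_by_chrom = {
        chrom: panel.positions[block] for chrom, block in panel.chrom_blocks()
    }
    segments = []
    for row in frame.itertuples(index=False):
        chrom = int(row.CHR)
        pos = pos_by_chrom.get(chrom)
        if pos is None:
            raise ValueError(f"chromosome {chrom} not present in panel")
        ia = int(np.searchsorted(pos, int(row.POS1)))
        ib = int(np.searchsorted(pos, int(row.POS2)))
        if (
            ia >= pos.size
            or ib >= pos.size
            or pos[ia] != int(row.POS1)
            or pos[ib] != int(row.POS2)
        ):
            raise ValueError(
                f"segment coordinates {row.POS1}-{row.POS2} on chromosome "
                f"{chrom} do not coincide with panel SNP positions"
            )
        segments.append(
            ROHSegment(
                sample_id=str(row.IID),
                chromosome=chrom,
                start_bp=int(row.POS1),
                end_bp=int(row.POS2),
                start_index=ia,
                end_index=ib,
                n_snps=int(row.NSNP),
                n_het=int(row.NHET),
                n_missing=int(row.NMIS),
            )
        )
    return segments
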