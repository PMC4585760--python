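"""Common (consensus) ROH identification.

Individual ROH calls are recoded into a samples x SNPs indicator matrix
(1 = SNP inside an ROH for that sample).  Consensus regions are then
produced by the prune/trim procedure:

1. zero every SNP column carried by fewer than ``min_carriers`` samples;
2. per sample, delete indicator runs that have become shorter than
   ``min_snps`` (runs never span chromosomes);
3. recompute carrier counts and take, per chromosome, the maximal SNP
   intervals with count >= ``min_carriers`` and length >= ``min_snps``;
4. within each such interval, select the sub-interval of at least
   ``min_snps`` SNPs covered end-to-end by the largest number of samples
   (ties broken by longer, then leftmost, sub-intervals).  Those samples
   are the region's carriers, so every carrier shares the same start and
   end.  If no sub-interval reaches ``min_carriers`` full-coverage
   carriers the untrimmed interval is reported flagged as
   ``low_coverage``.

Step 4 resolves the staggered-boundary case: when individual runs only
partially overlap a high-count interval, the reported consensus is the
core interval actually shared by the carriers, which is what gives the
"identical boundaries across carriers" property the procedure promises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .caller import ROHSegment
from .model import GenotypeMatrix, SampleRecord


@dataclass(frozen=True)
class ConsensusROH:
    """A common ROH with identical boundaries across its carriers.

    ``start_index``/``end_index`` are global SNP column indices into the
    panel used to build the indicator matrix.
    """

    roh_id: str
    chromosome: int
    start_bp: int
    end_bp: int
    start_index: int
    end_index: int
    n_snps: int
    carriers: tuple[str, ...]
    carrier_count_cases: int
    carrier_count_controls: int
    low_coverage: bool = False


def roh_indicator_matrix(
    segments: list[ROHSegment], panel: GenotypeMatrix
) -> np.ndarray:
    """Binary samples x SNPs matrix with 1 exactly on the SNPs covered by
    each sample's segments (overlapping segments union idempotently)."""
    ind = np.zeros(panel.shape, dtype=np.uint8)
    row = {s.sample_id: i for i, s in enumerate(panel.samples)}
    offsets = {chrom: block.start for chrom, block in panel.chrom_blocks()}
    sizes = {
        chrom: block.stop - block.start for chrom, block in panel.chrom_blocks()
    }
    for seg in segments:
        if seg.sample_id not in row:
            raise ValueError(f"segment sample {seg.sample_id!r} not in panel")
        if seg.chromosome not in offsets:
            raise ValueError(f"segment chromosome {seg.chromosome} not in panel")
        if seg.end_index >= sizes[seg.chromosome]:
            raise ValueError(
                f"segment indices {seg.start_index}-{seg.end_index} outside "
                f"chromosome {seg.chromosome} ({sizes[seg.chromosome]} SNPs)"
            )
        off = offsets[seg.chromosome]
        ind[row[seg.sample_id], off + seg.start_index : off + seg.end_index + 1] = 1
    return ind


def _runs_in_rows(block: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(row, start, stop_exclusive) of maximal 1-runs in each row."""
    n, nc = block.shape
    padded = np.zeros((n, nc + 1), dtype=np.int8)
    padded[:, :nc] = block
    flat = padded.ravel()
    d = np.diff(np.concatenate(([0], flat)))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    rows = starts // (nc + 1)
    return rows, starts % (nc + 1), stops - rows * (nc + 1)


def _trim_region(
    runs: list[tuple[int, int, int]],
    lo: int,
    hi: int,
    min_carriers: int,
    min_snps: int,
) -> tuple[int, int, list[int]] | None:
    """Pick the sub-interval of [lo, hi] (inclusive) with length >=
    min_snps covered end-to-end by the most runs.

    ``runs`` holds (row, a, b) inclusive intervals clipped to the region.
    Returns (i, j, carrier_rows) or None when no sub-interval reaches
    ``min_carriers`` coverage.
    """
    length = hi - lo + 1
    if length < min_snps or not runs:
        return None
    # coverage count of the minimal window [i, i + min_snps - 1] per i
    n_starts = length - min_snps + 1
    diff = np.zeros(n_starts + 1, dtype=np.int32)
    for _, a, b in runs:
        i_lo = max(a, lo)
        i_hi = min(b - min_snps + 1, hi - min_snps + 1)
        if i_hi >= i_lo:
            diff[i_lo - lo] += 1
            diff[i_hi - lo + 1] -= 1
    cover = np.cumsum(diff[:-1])
    c_max = int(cover.max(initial=0))
    if c_max < min_carriers:
        return None
    best: tuple[int, int] | None = None
    ends = np.array([b for _, a, b in runs])
    starts_arr = np.array([a for _, a, b in runs])
    for i0 in np.flatnonzero(cover == c_max):
        i = lo + int(i0)
        sel = (starts_arr <= i) & (ends >= i + min_snps - 1)
        bs = np.sort(ends[sel])[::-1]
        j = int(bs[c_max - 1])
        if best is None or (j - i) > (best[1] - best[0]):
            best = (i, j)
    i, j = best
    carrier_rows = sorted(
        {r for r, a, b in runs if a <= i and b >= j}
    )
    return i, j, carrier_rows


def find_common_roh(
    indicator: np.ndarray,
    panel: GenotypeMatrix,
    min_carriers: int = 10,
    min_snps: int = 75,
) -> list[ConsensusROH]:
    """Consensus ROH from an indicator matrix via the prune/trim
    procedure described in the module docstring."""
    if min_carriers < 1 or min_snps < 1:
        raise ValueError("min_carriers and min_snps must be at least 1")
    if indicator.shape != panel.shape:
        raise ValueError("indicator shape does not match panel")
    ind = (indicator > 0).astype(np.uint8)

    # step 1: zero columns with too few carriers
    counts = ind.sum(axis=0)
    ind[:, counts < min_carriers] = 0

    regions: list[ConsensusROH] = []
    positions = panel.positions
    phen = [s.phenotype for s in panel.samples]
    sample_ids = panel.sample_ids

    for chrom, block in panel.chrom_blocks():
        sub = ind[:, block]
        # step 2: delete per-sample runs now shorter than min_snps
        rows, starts, stops = _runs_in_rows(sub)
        short = (stops - starts) < min_snps
        for r, a, b in zip(rows[short], starts[short], stops[short]):
            sub[r, a:b] = 0
        # step 3: maximal high-count intervals
        counts2 = sub.sum(axis=0)
        ok = counts2 >= min_carriers
        if not ok.any():
            continue
        d = np.diff(np.concatenate(([0], ok.view(np.int8), [0])))
        reg_starts = np.flatnonzero(d == 1)
        reg_stops = np.flatnonzero(d == -1) - 1
        # surviving per-sample runs, as inclusive intervals
        rows2, starts2, stops2 = _runs_in_rows(sub)
        run_list = list(zip(rows2.tolist(), starts2.tolist(), (stops2 - 1).tolist()))
        for lo, hi in zip(reg_starts, reg_stops):
            if hi - lo + 1 < min_snps:
                continue
            overlapping = [
                (r, max(a, int(lo)), min(b, int(hi)))
                for r, a, b in run_list
                if a <= hi and b >= lo
            ]
            trimmed = _trim_region(
                overlapping, int(lo), int(hi), min_carriers, min_snps
            )
            if trimmed is None:
                i, j = int(lo), int(hi)
                carrier_rows = sorted(
                    {r for r, a, b in overlapping if a <= i and b >= j}
                )
                flag = True
            else:
                i, j, carrier_rows = trimmed
                flag = False
            gi, gj = block.start + i, block.start + j
            carriers = tuple(sample_ids[r] for r in carrier_rows)
            regions.append(
                ConsensusROH(
                    roh_id="",
                    chromosome=chrom,
                    start_bp=int(positions[gi]),
                    end_bp=int(positions[gj]),
                    start_index=gi,
                    end_index=gj,
                    n_snps=gj - gi + 1,
                    carriers=carriers,
                    carrier_count_cases=sum(
                        1 for r in carrier_rows if phen[r] == "case"
                    ),
                    carrier_count_controls=sum(
                        1 for r in carrier_rows if phen[r] == "control"
                    ),
                    low_coverage=flag,
                )
            )

    regions.sort(key=lambda r: (r.chromosome, r.start_bp))
    return [
        ConsensusROH(**{**r.__dict__, "roh_id": f"ROH{k + 1}"})
        for k, r in enumerate(regions)
    ]


def carrier_table(
    consensus: list[ConsensusROH], samples: list[SampleRecord]
) -> np.ndarray:
    """Samples x consensus binary membership table; row sums are the
    per-individual common-ROH counts."""
    row = {s.sample_id: i for i, s in enumerate(samples)}
    table = np.zeros((len(samples), len(consensus)), dtype=np.uint8)
    for k, region in enumerate(consensus):
        for sid in region.carriers:
            if sid in row:
                table[row[sid], k] = 1
    return table


def consensus_to_frame(consensus: list[ConsensusROH]) -> pd.DataFrame:
    """Consensus list as a table mirroring the conventional report layout."""
    rows = [
        (
            r.roh_id,
            r.chromosome,
            r.start_bp,
            r.end_bp,
            r.end_bp - r.start_bp + 1,
            r.n_snps,
            r.carrier_count_cases,
            r.carrier_count_controls,
            int(r.low_coverage),
            ",".join(r.carriers),
        )
        for r in consensus
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "ROH",
            "CHR",
            "START_BP",
            "END_BP",
            "LENGTH_BP",
            "NSNP",
            "CASE_CARRIERS",
            "CONTROL_CARRIERS",
            "LOW_COVERAGE",
            "CARRIERS",
        ],
    )


def consensus_from_frame(
    frame: pd.DataFrame, panel: GenotypeMatrix
) -> list[ConsensusROH]:
    """Rebuild a consensus list written by :func:`consensus_to_frame`."""
    pheno = {s.sample_id: s.phenotype for s in panel.samples}
    pos_index = {
        (snp.chromosome, snp.position_bp): k for k, snp in enumerate(panel.snps)
    }
    out = []
    for row in frame.itertuples(index=False):
        raw = "" if pd.isna(row.CARRIERS) else str(row.CARRIERS)
        carriers = tuple(raw.split(",")) if raw else ()
        gi = pos_index[(int(row.CHR), int(row.START_BP))]
        gj = pos_index[(int(row.CHR), int(row.END_BP))]
        out.append(
            ConsensusROH(
                roh_id=str(row.ROH),
                chromosome=int(row.CHR),
                start_bp=int(row.START_BP),
                end_bp=int(row.END_BP),
                start_index=gi,
                end_index=gj,
                n_snps=int(row.NSNP),
                carriers=carriers,
                carrier_count_cases=sum(
                    1 for c in carriers if pheno.get(c) == "case"
                ),
                carrier_count_controls=sum(
                    1 for c in carriers if pheno.get(c) == "control"
                ),
                low_coverage=bool(row.LOW_COVERAGE),
            )
        )
    return out
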