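"""Case-control statistics on consensus ROH.

Per-region association uses the Pearson chi-square on the 2x2 carrier
table (no continuity correction) with the odds ratio ad/bc; the
genome-wide burden comparison is a pooled-variance two-sample Student
t-test on per-individual common-ROH counts; cumulative-distribution
curves and an interval-union autosome coverage fraction summarise the
genome-wide homozygosity landscape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats as sps

from .consensus import ConsensusROH
from .caller import ROHSegment


class Chi2Result(NamedTuple):
    chi2: float
    p_value: float
    odds_ratio: float
    degenerate: bool


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> Chi2Result:
    """Pearson chi-square (1 df, no continuity correction) on the table
    [[a, b], [c, d]] with rows = groups and columns = carrier status.

    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); OR = ad / bc
    (infinite when bc = 0 and ad > 0).  A zero column margin makes the
    statistic undefined and returns a degenerate marker.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0 or c + d == 0:
        raise ValueError("both row totals must be positive")
    if a + c == 0 or b + d == 0:
        return Chi2Result(math.nan, math.nan, math.nan, True)
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = num / den
    p = float(sps.chi2.sf(chi2, df=1))
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return Chi2Result(float(chi2), p, float(odds), False)


def yates_chi2_2x2(a: int, b: int, c: int, d: int) -> Chi2Result:
    """Continuity-corrected variant, available behind this separate
    entry point for comparison."""
    base = pearson_chi2_2x2(a, b, c, d)
    if base.degenerate:
        return base
    n = a + b + c + d
    num = n * max(abs(a * d - b * c) - n / 2.0, 0.0) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = num / den
    return Chi2Result(float(chi2), float(sps.chi2.sf(chi2, df=1)), base.odds_ratio, False)


@dataclass(frozen=True)
class AssociationResult:
    """Per-consensus-ROH 2x2 association: a/b = case carriers and
    non-carriers, c/d = control carriers and non-carriers."""

    roh_id: str
    a: int
    b: int
    c: int
    d: int
    case_pct: float
    control_pct: float
    chi2: float
    p_value: float
    odds_ratio: float
    bonferroni_significant: bool


def per_roh_association(
    carriers: np.ndarray,
    phenotypes: np.ndarray,
    roh_ids: list[str],
    alpha: float = 0.05,
    report_p: float = 0.01,
    continuity_correction: bool = False,
) -> tuple[list[AssociationResult], list[AssociationResult]]:
    """Associate each consensus ROH with case status.

    ``carriers`` is the samples x regions binary table; ``phenotypes``
    the per-sample labels.  Returns all results (input order) plus the
    subset below the ``report_p`` threshold, sorted by p-value.  The
    Bonferroni flag marks p < alpha / n_regions.
    """
    case_mask = np.asarray(phenotypes) == "case"
    control_mask = np.asarray(phenotypes) == "control"
    n_case = int(case_mask.sum())
    n_control = int(control_mask.sum())
    if n_case == 0 or n_control == 0:
        raise ValueError("association needs at least one case and one control")
    n_tests = carriers.shape[1]
    test = yates_chi2_2x2 if continuity_correction else pearson_chi2_2x2
    results = []
    for k in range(n_tests):
        a = int(carriers[case_mask, k].sum())
        c = int(carriers[control_mask, k].sum())
        b, d = n_case - a, n_control - c
        r = test(a, b, c, d)
        results.append(
            AssociationResult(
                roh_id=roh_ids[k],
                a=a,
                b=b,
                c=c,
                d=d,
                case_pct=100.0 * a / n_case,
                control_pct=100.0 * c / n_control,
                chi2=r.chi2,
                p_value=r.p_value,
                odds_ratio=r.odds_ratio,
                bonferroni_significant=bool(
                    not r.degenerate and r.p_value < alpha / max(n_tests, 1)
                ),
            )
        )
    hits = sorted(
        (r for r in results if not math.isnan(r.p_value) and r.p_value < report_p),
        key=lambda r: r.p_value,
    )
    return results, hits


@dataclass(frozen=True)
class BurdenSummary:
    """Genome-wide burden comparison on per-individual common-ROH counts."""

    case_mean: float
    case_sd: float
    control_mean: float
    control_sd: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    degenerate: bool
    case_counts: np.ndarray
    control_counts: np.ndarray
    case_total_length_bp: np.ndarray
    control_total_length_bp: np.ndarray


def _total_lengths(
    segments: list[ROHSegment], sample_ids: list[str]
) -> np.ndarray:
    total = dict.fromkeys(sample_ids, 0)
    for s in segments:
        if s.sample_id in total:
            total[s.sample_id] += s.end_bp - s.start_bp + 1
    return np.array([total[sid] for sid in sample_ids], dtype=np.int64)


def burden_summary(
    carriers: np.ndarray,
    segments: list[ROHSegment],
    phenotypes: np.ndarray,
    sample_ids: list[str],
    welch: bool = False,
) -> BurdenSummary:
    """Pooled-variance Student t-test (Welch optional) comparing the
    per-individual count of consensus ROH between cases and controls;
    carries per-individual total called-ROH length for the ECDF."""
    phen = np.asarray(phenotypes)
    case_mask = phen == "case"
    control_mask = phen == "control"
    if case_mask.sum() < 2 or control_mask.sum() < 2:
        raise ValueError("both groups need at least two members")
    counts = carriers.sum(axis=1).astype(float)
    x, y = counts[case_mask], counts[control_mask]
    lengths = _total_lengths(segments, sample_ids)
    res = sps.ttest_ind(x, y, equal_var=not welch)
    degenerate = not math.isfinite(float(res.statistic))
    df = int(x.size + y.size - 2)
    return BurdenSummary(
        case_mean=float(x.mean()),
        case_sd=float(x.std(ddof=1)),
        control_mean=float(y.mean()),
        control_sd=float(y.std(ddof=1)),
        t_statistic=float(res.statistic),
        degrees_of_freedom=df,
        p_value=float(res.pvalue),
        degenerate=degenerate,
        case_counts=x,
        control_counts=y,
        case_total_length_bp=lengths[case_mask],
        control_total_length_bp=lengths[control_mask],
    )


def roh_length_ecdf(
    lengths: np.ndarray, phenotypes: np.ndarray
) -> tuple[dict[str, tuple[np.ndarray, np.ndarray]], float]:
    """Per-group survival curves of per-individual total ROH length.

    Each curve gives, at every observed length x, the fraction of the
    group's samples whose total is >= x (monotone non-increasing).
    Returns the curves and the supremum distance between the case and
    control curves over the pooled support.
    """
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths < 0):
        raise ValueError("lengths must be non-negative")
    phen = np.asarray(phenotypes)
    curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for group in ("case", "control"):
        vals = lengths[phen == group]
        if vals.size == 0:
            continue
        xs = np.unique(vals)
        frac = np.array([(vals >= x).mean() for x in xs])
        curves[group] = (xs, frac)
    if "case" in curves and "control" in curves:
        grid = np.unique(np.concatenate([curves["case"][0], curves["control"][0]]))
        fc = np.array([(lengths[phen == "case"] >= x).mean() for x in grid])
        fk = np.array([(lengths[phen == "control"] >= x).mean() for x in grid])
        sup = float(np.abs(fc - fk).max())
    else:
        sup = math.nan
    return curves, sup


def autosome_coverage(
    consensus: list[ConsensusROH], chromosome_lengths: dict[int, int]
) -> float:
    """Fraction of the autosome covered by the union of consensus
    intervals (1-based inclusive; overlaps merged)."""
    for c, ln in chromosome_lengths.items():
        if ln <= 0:
            raise ValueError(f"chromosome {c} length must be positive")
    by_chrom: dict[int, list[tuple[int, int]]] = {}
    for r in consensus:
        if r.chromosome not in chromosome_lengths:
            raise ValueError(f"no length given for chromosome {r.chromosome}")
        if r.end_bp > chromosome_lengths[r.chromosome]:
            raise ValueError(
                f"{r.roh_id} ends at {r.end_bp} beyond chromosome "
                f"{r.chromosome} length {chromosome_lengths[r.chromosome]}"
            )
        by_chrom.setdefault(r.chromosome, []).append((r.start_bp, r.end_bp))
    covered = 0
    for intervals in by_chrom.values():
        intervals.sort()
        cur_a, cur_b = intervals[0]
        for a, b in intervals[1:]:
            if a <= cur_b + 1:
                cur_b = max(cur_b, b)
            else:
                covered += cur_b - cur_a + 1
                cur_a, cur_b = a, b
        covered += cur_b - cur_a + 1
    return covered / sum(chromosome_lengths.values())
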