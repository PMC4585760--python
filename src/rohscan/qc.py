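"""Quality-control cascade for case-control SNP panels.

The cascade runs in a fixed, documented order:

1. call-rate filters (samples first, then SNPs recomputed on the
   retained samples),
2. identity-by-state relatedness pruning,
3. MAF and Hardy-Weinberg exclusion (HWE tested within cases and
   controls separately; failure in either group removes the SNP).

A PCA ancestry screen is provided as a separate operation: it is a
generic outlier detector on frequency-standardized genotypes, not an
assignment against external reference populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .model import HET, HOM_A1, HOM_A2, MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class QCParams:
    """Thresholds of the QC cascade.

    All call-rate/MAF/IBS values are fractions in [0, 1].  ``ibs_max`` is
    the fraction of identical genotypes above which a pair is treated as
    related (strictly greater than).  ``pca_outlier_sd`` defaults to a
    permissive 6 SD because without external reference panels the screen
    should only catch gross ancestry outliers.
    """

    sample_call_rate_min: float = 0.95
    snp_call_rate_min: float = 0.95
    maf_min: float = 0.05
    hwe_p_min: float = 1e-5
    ibs_max: float = 0.80
    pca_components: int = 2
    pca_outlier_sd: float = 6.0

    def __post_init__(self) -> None:
        for name in ("sample_call_rate_min", "snp_call_rate_min", "maf_min", "ibs_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.hwe_p_min <= 1.0:
            raise ValueError("hwe_p_min must be in (0, 1]")


@dataclass
class QCReport:
    """Removal lists with reasons plus per-stage tallies."""

    samples_removed: list[tuple[str, str]] = field(default_factory=list)
    snps_removed: list[tuple[str, str]] = field(default_factory=list)
    stage_counts: dict[str, int] = field(default_factory=dict)

    def merge(self, other: "QCReport") -> "QCReport":
        out = QCReport(
            samples_removed=self.samples_removed + other.samples_removed,
            snps_removed=self.snps_removed + other.snps_removed,
            stage_counts={**self.stage_counts, **other.stage_counts},
        )
        return out


def _sample_call_rates(panel: GenotypeMatrix) -> np.ndarray:
    if panel.n_snps == 0:
        return np.ones(panel.n_samples)
    return (panel.genotypes != MISSING).mean(axis=1)


def filter_call_rates(
    panel: GenotypeMatrix, params: QCParams
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop samples below the sample call-rate threshold, then drop SNPs
    whose call rate (recomputed on the retained samples) is below the SNP
    threshold."""
    if panel.n_samples == 0 or panel.n_snps == 0:
        raise ValueError("cannot run call-rate QC on an empty panel")
    report = QCReport()

    cr = _sample_call_rates(panel)
    keep_s = cr >= params.sample_call_rate_min
    for i in np.flatnonzero(~keep_s):
        report.samples_removed.append(
            (panel.samples[i].sample_id, f"call_rate={cr[i]:.4f}")
        )
    report.stage_counts["samples_call_rate"] = int((~keep_s).sum())
    if not keep_s.any():
        raise ValueError("all samples removed by the sample call-rate filter")
    panel = panel.subset_samples(keep_s) if not keep_s.all() else panel

    snp_cr = (panel.genotypes != MISSING).mean(axis=0)
    keep_v = snp_cr >= params.snp_call_rate_min
    for j in np.flatnonzero(~keep_v):
        report.snps_removed.append(
            (panel.snps[j].snp_id, f"call_rate={snp_cr[j]:.4f}")
        )
    report.stage_counts["snps_call_rate"] = int((~keep_v).sum())
    if not keep_v.any():
        raise ValueError("all SNPs removed by the SNP call-rate filter")
    panel = panel.subset_snps(keep_v) if not keep_v.all() else panel
    return panel, report


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test
# ----------------------------------------------------------------------


def _het_count_distribution(n_a: int, n_total: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact conditional distribution of the heterozygote count given the
    allele count ``n_a`` (copies of one allele) among ``2 * n_total``.

    Returns the support (all feasible het counts, sharing the parity of
    ``n_a``) and their probabilities, which sum to one.
    """
    n_b = 2 * n_total - n_a
    k_max = min(n_a, n_b)
    ks = np.arange(n_a % 2, k_max + 1, 2)
    n_aa = (n_a - ks) // 2
    n_bb = (n_b - ks) // 2
    logw = (
        ks * np.log(2.0)
        - gammaln(n_aa + 1)
        - gammaln(ks + 1)
        - gammaln(n_bb + 1)
    )
    logp = logw - logsumexp(logw)
    return ks, np.exp(logp)


def hwe_exact_p(n_hom_a1: int, n_het: int, n_hom_a2: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Enumerates every heterozygote count compatible with the observed
    allele counts and sums the probabilities of all configurations no
    more probable than the observed one.
    """
    for v in (n_hom_a1, n_het, n_hom_a2):
        if v < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_hom_a1 + n_het + n_hom_a2
    if n == 0:
        raise ValueError("HWE test undefined for zero total genotype count")
    n_a = 2 * n_hom_a1 + n_het
    ks, probs = _het_count_distribution(n_a, n)
    p_obs = probs[np.searchsorted(ks, n_het)]
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(1.0, max(p, np.finfo(float).tiny))


def _genotype_counts(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return (
        (genotypes == HOM_A1).sum(axis=0),
        (genotypes == HET).sum(axis=0),
        (genotypes == HOM_A2).sum(axis=0),
    )


def filter_maf_hwe(
    panel: GenotypeMatrix,
    params: QCParams,
    groups: dict[str, np.ndarray] | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove SNPs with MAF below threshold (over all samples) or an
    exact-HWE p-value below threshold in either phenotype group.

    ``groups`` maps group labels to boolean sample masks; by default the
    panel's case/control phenotypes are used.
    """
    if groups is None:
        groups = {"case": panel.case_mask, "control": panel.control_mask}
    report = QCReport()

    n_aa, n_ab, n_bb = _genotype_counts(panel.genotypes)
    called = n_aa + n_ab + n_bb
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called > 0, (2 * n_aa + n_ab) / (2 * called), 0.0)
    maf = np.minimum(freq, 1.0 - freq)
    fail_maf = maf < params.maf_min

    fail_hwe = np.zeros(panel.n_snps, dtype=bool)
    cache: dict[tuple[int, int, int], float] = {}
    for label, mask in groups.items():
        if not np.any(mask):
            continue
        g_aa, g_ab, g_bb = _genotype_counts(panel.genotypes[mask])
        for j in range(panel.n_snps):
            if fail_hwe[j]:
                continue
            key = (int(g_aa[j]), int(g_ab[j]), int(g_bb[j]))
            if sum(key) == 0:
                continue
            p = cache.get(key)
            if p is None:
                p = hwe_exact_p(*key)
                cache[key] = p
            if p < params.hwe_p_min:
                fail_hwe[j] = True

    for j in np.flatnonzero(fail_maf):
        report.snps_removed.append((panel.snps[j].snp_id, f"maf={maf[j]:.4f}"))
    for j in np.flatnonzero(fail_hwe & ~fail_maf):
        report.snps_removed.append((panel.snps[j].snp_id, "hwe"))
    report.stage_counts["snps_maf"] = int(fail_maf.sum())
    report.stage_counts["snps_hwe"] = int((fail_hwe & ~fail_maf).sum())

    keep = ~(fail_maf | fail_hwe)
    if not keep.any():
        logger.warning("MAF/HWE filter removed every SNP")
    panel = panel.subset_snps(keep) if not keep.all() else panel
    return panel, report


# ----------------------------------------------------------------------
# relatedness
# ----------------------------------------------------------------------


def pairwise_ibs(panel: GenotypeMatrix) -> np.ndarray:
    """Identity-by-state matrix: fraction of jointly called SNPs with
    identical genotype codes.  Pairs with no jointly called SNP get 0."""
    g = panel.genotypes
    called = g != MISSING
    n = panel.n_samples
    ibs = np.zeros((n, n))
    for i in range(n):
        joint = called[i] & called[i + 1 :]
        same = (g[i] == g[i + 1 :]) & joint
        denom = joint.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(denom > 0, same.sum(axis=1) / denom, 0.0)
        ibs[i, i + 1 :] = row
        ibs[i + 1 :, i] = row
    return ibs


def prune_related(
    panel: GenotypeMatrix, params: QCParams
) -> tuple[GenotypeMatrix, QCReport]:
    """Greedy relatedness pruning.

    Pairs with IBS strictly above ``ibs_max`` are processed in descending
    IBS order, skipping members already removed; the member with the
    lower call rate is dropped (call-rate ties drop the later sample
    index)."""
    report = QCReport()
    n = panel.n_samples
    if n < 2:
        report.stage_counts["samples_related"] = 0
        return panel, report
    ibs = pairwise_ibs(panel)
    cr = _sample_call_rates(panel)
    iu, ju = np.triu_indices(n, k=1)
    flagged = ibs[iu, ju] > params.ibs_max
    order = np.argsort(-ibs[iu, ju][flagged], kind="stable")
    pairs = list(zip(iu[flagged][order], ju[flagged][order]))

    removed: set[int] = set()
    for i, j in pairs:
        if i in removed or j in removed:
            continue
        if cr[i] < cr[j]:
            drop = i
        elif cr[j] < cr[i]:
            drop = j
        else:
            drop = max(i, j)
        removed.add(int(drop))
        report.samples_removed.append(
            (panel.samples[drop].sample_id, f"ibs={ibs[i, j]:.4f}")
        )
    report.stage_counts["samples_related"] = len(removed)
    if removed:
        keep = np.array([i not in removed for i in range(n)])
        panel = panel.subset_samples(keep)
    return panel, report


# ----------------------------------------------------------------------
# PCA ancestry screen
# ----------------------------------------------------------------------


def pca_outliers(
    panel: GenotypeMatrix, params: QCParams
) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of frequency-standardized genotypes and an
    outlier flag per sample.

    Genotypes are mean-imputed, centred and scaled by the binomial
    allele-frequency standard deviation sqrt(2 p (1 - p)); zero-variance
    (monomorphic) SNPs are skipped.  A sample is an outlier when any of
    the top ``pca_components`` coordinates lies beyond ``pca_outlier_sd``
    standard deviations of that component; the sign of a component is
    arbitrary and cannot affect the flags.
    """
    if panel.n_samples < 3:
        raise ValueError("PCA screen needs at least 3 samples")
    g = panel.genotypes.astype(float)
    g[panel.genotypes == MISSING] = np.nan
    mean = np.nanmean(g, axis=0)
    p_hat = mean / 2.0
    scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    observed_var = np.nanvar(g, axis=0)
    poly = (scale > 0) & (observed_var > 0)
    k = params.pca_components
    if poly.sum() < k:
        raise ValueError(
            f"need at least {k} polymorphic SNPs for {k} components, "
            f"got {int(poly.sum())}"
        )
    x = (g[:, poly] - mean[poly]) / scale[poly]
    x = np.nan_to_num(x, nan=0.0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    coords = u[:, :k] * s[:k]
    sd = coords.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    flags = (np.abs(coords) > params.pca_outlier_sd * sd).any(axis=1)
    return coords, flags


def run_qc(
    panel: GenotypeMatrix, params: QCParams
) -> tuple[GenotypeMatrix, QCReport]:
    """Full cascade: call rates -> relatedness -> MAF/HWE."""
    panel, rep1 = filter_call_rates(panel, params)
    panel, rep2 = prune_related(panel, params)
    panel, rep3 = filter_maf_hwe(panel, params)
    return panel, rep1.merge(rep2).merge(rep3)
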