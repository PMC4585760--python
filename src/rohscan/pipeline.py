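"""End-to-end orchestration: QC -> calibration -> ROH calling ->
consensus -> association/burden, with tab-separated outputs and a JSON
summary.

The pipeline takes exactly one input source — a PLINK fileset or a
simulation block — and writes six artefacts into the output directory:
``qc_report.tsv``, ``segments.tsv``, ``consensus.tsv``,
``association.tsv``, ``ecdf.tsv`` and ``summary.json`` (plus
``pipeline.log``).  Runs are reproducible: the same configuration and
seed yield byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .caller import (
    ROHCallParams,
    ThresholdParams,
    call_roh,
    expected_chance_windows,
    ld_adjusted_length,
    mean_heterozygosity,
    min_run_length,
    segments_to_frame,
)
from .consensus import (
    carrier_table,
    consensus_to_frame,
    find_common_roh,
    roh_indicator_matrix,
)
from .model import GenotypeMatrix
from .plink import read_plink_binary, read_plink_text, write_plink_binary
from .qc import QCParams, QCReport, pca_outliers, run_qc
from .simulate import SimulationConfig, SimulationTruth, simulate_panel
from .stats import (
    autosome_coverage,
    burden_summary,
    per_roh_association,
    roh_length_ecdf,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    bed_prefix: str | None = None
    ped_path: str | None = None
    map_path: str | None = None
    simulation: SimulationConfig | None = None
    qc: QCParams = field(default_factory=QCParams)
    roh: ROHCallParams = field(default_factory=ROHCallParams)
    alpha: float = 0.05
    consensus_min_carriers: int = 10
    consensus_min_snps: int = 75
    pca_screen: bool = True
    output_dir: str = "rohscan_out"
    seed: int = 0

    def __post_init__(self) -> None:
        sources = [
            self.bed_prefix is not None,
            self.ped_path is not None or self.map_path is not None,
            self.simulation is not None,
        ]
        if sum(sources) != 1:
            raise ValueError(
                "exactly one input source required: bed_prefix, ped/map "
                "paths, or a simulation block"
            )
        if (self.ped_path is None) != (self.map_path is None):
            raise ValueError("ped_path and map_path must be given together")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "simulation" in raw and raw["simulation"] is not None:
            sim = dict(raw["simulation"])
            for key in ("maf_range", "autozygous_segment_snps", "spacing_bp",
                        "risk_region"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            raw["simulation"] = SimulationConfig(**sim)
        if "qc" in raw and raw["qc"] is not None:
            raw["qc"] = QCParams(**raw["qc"])
        if "roh" in raw and raw["roh"] is not None:
            raw["roh"] = ROHCallParams(**raw["roh"])
        raw.update(overrides)
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _qc_report_frame(report: QCReport) -> pd.DataFrame:
    rows = [("sample", sid, reason) for sid, reason in report.samples_removed]
    rows += [("snp", sid, reason) for sid, reason in report.snps_removed]
    rows += [("stage_count", stage, str(count))
             for stage, count in sorted(report.stage_counts.items())]
    return pd.DataFrame(rows, columns=["KIND", "ID", "DETAIL"])


def load_input_panel(
    config: PipelineConfig,
) -> tuple[GenotypeMatrix, SimulationTruth | None]:
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        panel, truth = simulate_panel(sim)
        return panel, truth
    if config.bed_prefix is not None:
        prefix = Path(config.bed_prefix)
        panel = read_plink_binary(
            prefix.with_suffix(".bed"),
            prefix.with_suffix(".bim"),
            prefix.with_suffix(".fam"),
        )
        return panel, None
    return read_plink_text(config.ped_path, config.map_path), None


def calibration_summary(
    panel: GenotypeMatrix, alpha: float, min_snp_used: int
) -> dict:
    """Chance-run calibration on the post-QC panel: heterozygosity in
    controls (all samples as fallback), minimum informative run length
    and the expected chance-run count at the pinned segment size."""
    control = panel.control_mask
    subset = control if control.any() else None
    h = mean_heterozygosity(panel, subset)
    params = ThresholdParams(
        heterozygosity_h=h,
        n_snps_S=panel.n_snps,
        n_samples_N=panel.n_samples,
        alpha=alpha,
    )
    min_len = min_run_length(params) if h > 0 else None
    return {
        "heterozygosity": h,
        "n_snps": panel.n_snps,
        "n_samples": panel.n_samples,
        "alpha": alpha,
        "min_informative_run_length": min_len,
        "min_snp_used": min_snp_used,
        "expected_chance_runs_at_min_snp": expected_chance_windows(
            params, min_snp_used
        ),
    }


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute all stages; returns a manifest of written files."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    root = logging.getLogger("rohscan")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("rohscan %s, seed=%d", __version__, config.seed)
        logger.info("config: %s", json.dumps(config.to_dict(), default=str))

        panel, truth = load_input_panel(config)
        logger.info("input panel: %d samples x %d SNPs", *panel.shape)
        manifest: dict[str, str] = {}
        if truth is not None:
            write_plink_binary(panel, outdir / "simulated")
            truth_frame = pd.DataFrame(
                [
                    (t.sample_id, t.chromosome, t.start_index, t.end_index)
                    for t in truth.segments
                ],
                columns=["IID", "CHR", "START_INDEX", "END_INDEX"],
            )
            _write_tsv(truth_frame, outdir / "truth_segments.tsv")
            manifest["truth_segments"] = str(outdir / "truth_segments.tsv")

        # QC cascade
        panel_qc, report = run_qc(panel, config.qc)
        if config.pca_screen:
            coords, flags = pca_outliers(panel_qc, config.qc)
            if flags.any():
                for i in np.flatnonzero(flags):
                    report.samples_removed.append(
                        (panel_qc.samples[i].sample_id, "pca_outlier")
                    )
                panel_qc = panel_qc.subset_samples(~flags)
            report.stage_counts["samples_pca"] = int(flags.sum())
        logger.info("post-QC panel: %d samples x %d SNPs", *panel_qc.shape)
        _write_tsv(_qc_report_frame(report), outdir / "qc_report.tsv")
        manifest["qc_report"] = str(outdir / "qc_report.tsv")

        calibration = calibration_summary(
            panel_qc, config.alpha, config.roh.min_snp
        )

        # ROH calling
        segments = call_roh(panel_qc, config.roh)
        logger.info("called %d ROH segments", len(segments))
        _write_tsv(segments_to_frame(segments, panel_qc), outdir / "segments.tsv")
        manifest["segments"] = str(outdir / "segments.tsv")

        # consensus
        indicator = roh_indicator_matrix(segments, panel_qc)
        consensus = find_common_roh(
            indicator,
            panel_qc,
            min_carriers=config.consensus_min_carriers,
            min_snps=config.consensus_min_snps,
        )
        logger.info("found %d consensus ROH", len(consensus))
        _write_tsv(consensus_to_frame(consensus), outdir / "consensus.tsv")
        manifest["consensus"] = str(outdir / "consensus.tsv")

        # association + burden + ecdf + coverage
        phen = panel_qc.phenotypes
        association_rows = []
        ecdf_rows = []
        summary: dict = {
            "version": __version__,
            "seed": config.seed,
            "n_samples": panel_qc.n_samples,
            "n_snps": panel_qc.n_snps,
            "n_segments": len(segments),
            "n_consensus_roh": len(consensus),
            "calibration": calibration,
        }
        if consensus and panel_qc.case_mask.any() and panel_qc.control_mask.any():
            table = carrier_table(consensus, panel_qc.samples)
            results, hits = per_roh_association(
                table, phen, [r.roh_id for r in consensus]
            )
            for r in results:
                association_rows.append(
                    (
                        r.roh_id,
                        r.a,
                        f"{r.case_pct:.4g}",
                        r.c,
                        f"{r.control_pct:.4g}",
                        f"{r.chi2:.6g}",
                        f"{r.p_value:.6g}",
                        f"{r.odds_ratio:.6g}",
                        int(r.bonferroni_significant),
                    )
                )
            burden = burden_summary(
                table, segments, phen, panel_qc.sample_ids
            )
            curves, sup = roh_length_ecdf(
                np.concatenate(
                    [burden.case_total_length_bp, burden.control_total_length_bp]
                ),
                np.concatenate(
                    [
                        np.repeat("case", burden.case_total_length_bp.size),
                        np.repeat("control", burden.control_total_length_bp.size),
                    ]
                ),
            )
            for group, (xs, frac) in curves.items():
                for x, f in zip(xs, frac):
                    ecdf_rows.append((group, int(x), f"{f:.6g}"))
            chrom_lengths = {
                chrom: int(panel_qc.positions[block][-1])
                for chrom, block in panel_qc.chrom_blocks()
            }
            summary.update(
                {
                    "burden": {
                        "case_mean": burden.case_mean,
                        "case_sd": burden.case_sd,
                        "control_mean": burden.control_mean,
                        "control_sd": burden.control_sd,
                        "t_statistic": burden.t_statistic,
                        "degrees_of_freedom": burden.degrees_of_freedom,
                        "p_value": burden.p_value,
                    },
                    "ecdf_supremum_distance": sup,
                    "bonferroni_threshold": 0.05 / max(len(consensus), 1),
                    "autosome_coverage": autosome_coverage(
                        consensus, chrom_lengths
                    ),
                    "n_hits_p_lt_0.01": len(hits),
                }
            )
        association_frame = pd.DataFrame(
            association_rows,
            columns=[
                "ROH",
                "N_CASES",
                "PCT_CASES",
                "N_CONTROLS",
                "PCT_CONTROLS",
                "CHI2",
                "P",
                "OR",
                "BONFERRONI",
            ],
        )
        _write_tsv(association_frame, outdir / "association.tsv")
        manifest["association"] = str(outdir / "association.tsv")
        _write_tsv(
            pd.DataFrame(ecdf_rows, columns=["GROUP", "X_BP", "FRACTION_GE"]),
            outdir / "ecdf.tsv",
        )
        manifest["ecdf"] = str(outdir / "ecdf.tsv")

        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        manifest["summary"] = str(outdir / "summary.json")
        manifest["log"] = str(outdir / "pipeline.log")
        return manifest
    finally:
        root.removeHandler(handler)
        handler.close()
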