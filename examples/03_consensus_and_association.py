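"""Consensus ROH and case-control association on a panel with a planted
risk ROH.

Simulates the default study conditions (500 cases / 500 controls, a risk
ROH carried by 15% of cases vs 8% of controls), collapses individual
calls into common consensus ROH via the recode/prune/trim procedure and
tests each consensus region with the 2x2 Pearson chi-square.
"""

from rohscan import (
    ROHCallParams,
    SimulationConfig,
    call_roh,
    carrier_table,
    find_common_roh,
    per_roh_association,
    roh_indicator_matrix,
    simulate_panel,
)

config = SimulationConfig(seed=1)
panel, truth = simulate_panel(config)
segments = call_roh(panel, ROHCallParams())
indicator = roh_indicator_matrix(segments, panel)
consensus = find_common_roh(indicator, panel, min_carriers=10, min_snps=75)
table = carrier_table(consensus, panel.samples)
results, hits = per_roh_association(
    table, panel.phenotypes, [r.roh_id for r in consensus]
)

chrom, lo, hi = truth.risk_region
print(f"called segments    : {len(segments)}")
print(f"consensus ROH      : {len(consensus)}")
print(f"planted risk region: chromosome {chrom}, SNPs {lo}-{hi}")
for r in sorted(results, key=lambda x: x.p_value):
    region = next(c for c in consensus if c.roh_id == r.roh_id)
    mark = "*" if region.start_index <= hi and region.end_index >= lo else " "
    print(
        f"{mark} {r.roh_id}: SNPs {region.start_index}-{region.end_index}, "
        f"cases {r.a} ({r.case_pct:.1f}%) vs controls {r.c} "
        f"({r.control_pct:.1f}%), chi2={r.chi2:.2f}, p={r.p_value:.2g}, "
        f"OR={r.odds_ratio:.2f}"
    )
print()
print("The starred region overlaps the planted risk ROH: its carriers are")
print("enriched in cases roughly at the configured 15% vs 8% frequencies.")
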