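"""Screen candidate SNPs for probe targetability on a toy reference.

10% of flanks are duplicated elsewhere in the reference, mimicking wheat
homoeologues; those SNPs cannot be targeted by a locus-specific probe and
are rejected as 'multilocus'.
"""

from panelgwas.panel_design import flank_reports, probe_feasibility, FlankReport
from panelgwas.synthetic import SimulationConfig, simulate_reference

cfg = SimulationConfig(n_accessions=10, n_markers=200, n_chromosomes=6,
                       duplication_fraction=0.10, rng_seed=7, translocation=None)
seqs, markers, probes = simulate_reference(cfg)

reports = flank_reports(markers, seqs)
probes_by_marker = dict(tuple(probes.groupby("marker_id")))
n_feasible = n_multi = n_gc = 0
for _, row in reports.iterrows():
    ok, reason = probe_feasibility(
        FlankReport(row["marker_id"], row["gc_fraction"], int(row["n_exact_hits"])),
        probes_by_marker[row["marker_id"]],
    )
    n_feasible += ok
    n_multi += reason == "multilocus"
    n_gc += reason == "gc"

print(f"candidates: {len(reports)}")
print(f"flanks matching >1 locus: {(reports['n_exact_hits'] > 1).sum()} "
      f"(20 duplicated by construction)")
print(f"feasible probes: {n_feasible}, rejected multilocus: {n_multi}, "
      f"rejected GC: {n_gc}")
print(f"probe GC range: {probes['gc_fraction'].min():.2f}"
      f"-{probes['gc_fraction'].max():.2f}")
# Every duplicated flank shows n_exact_hits == 2 and is rejected; the rest
# fail only if no probe lands in the 30-70% GC hybridization band.
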