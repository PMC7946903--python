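"""Simulate a two-condition WGBS cohort and call the planted DMRs.

The generator plants 30 demethylated regions (methylation dropping from
0.85 to 0.45 in condition B) on two 1-Mb chromosomes and draws 4 + 6
replicate methylomes with beta-binomial counts at ~30x coverage. The
caller then works exactly as on real data: union the per-sample tracks,
apply the replicate coverage filter, test every CpG with the exact
Mann-Whitney test and assemble runs of consecutive qualifying CpGs.
"""

import numpy as np

from methylfoot import DmrConfig, call_dmrs, filter_coverage, union_sites
from methylfoot.simulate import SimConfig, simulate

sim = simulate(SimConfig.dmr_study(seed=1))
print(f"simulated {sum(len(p) for p in sim.cpg_positions.values())} CpGs, "
      f"{len(sim.tracks)} replicate methylomes, "
      f"{len(sim.truth.planted_dmrs)} planted DMRs")

table = filter_coverage(union_sites(sim.tracks, sim.groups))
print(f"{len(table)} CpGs survive the coverage filter "
      "(>=5 reads in >=2 A and >=3 B replicates)")

dmrs = call_dmrs(table, DmrConfig(), {c: len(s) for c, s in sim.genome.items()})
hypo = [d for d in dmrs if d.direction == "hypo_in_B"]
print(f"called {len(dmrs)} DMRs ({len(hypo)} demethylated in condition B)")

truth = [(d.chrom, d.start, d.end) for d in sim.truth.planted_dmrs]
calls = [(d.chrom, d.start, d.end) for d in dmrs]
overlap = lambda r, others: any(
    r[0] == c and r[1] < e and r[2] > s for c, s, e in others)
sens = np.mean([overlap(t, calls) for t in truth])
prec = np.mean([overlap(c, truth) for c in calls])
print(f"sensitivity {sens:.2f}, precision {prec:.2f} against the planted truth")
print("(a call 'hits' when it overlaps a planted region by >=1 bp)")

d = dmrs[0]
print(f"example: {d.name} {d.chrom}:{d.start}-{d.end}, {d.n_cpgs} CpGs, "
      f"mean methylation {d.mean_a:.2f} (A) -> {d.mean_b:.2f} (B)")
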