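"""Cluster-level analytics: coverage, rarefaction, error rate, RPM,
droplet occupancy.

Works on one simulated barcode group to show the per-cluster summary
statistics the pipeline computes after clustering: genome coverage and
saturation, the fraction of pooled reads not attributable to the
cluster's organism, antibiotic-resistance-gene reads per million, and
the gel-loading occupancy arithmetic.
"""

import pandas as pd

from microatlas import (
    SimulationConfig,
    cluster_error_rate,
    count_feature_hits,
    coverage_stats,
    droplet_occupancy,
    rarefaction,
    simulate_barcode_group,
    synthetic_community,
)

refset = synthetic_community(n_genera=3, genome_length=20_000, seed=4)
cfg = SimulationConfig(n_species=3)
group = simulate_barcode_group(refset, "g00_s00", cfg, seed=4,
                               n_pairs=2000, contamination=0.1)

placements = [
    (rp.truth.start, rp.truth.amplicon_len)
    for rp in group.read_pairs
    if not rp.truth.is_contaminant
]
frac, depth = coverage_stats(placements, 20_000)
print(f"coverage: {frac:.1%} of the genome at mean depth {depth:.1f}x")

curve = rarefaction(placements, 20_000, n_total=len(placements), n_points=5, seed=0)
print("rarefaction (reads -> covered fraction):")
print(curve.to_string(index=False))

err = cluster_error_rate(
    [rp.truth.source_genome for rp in group.read_pairs], {"g00_s00"}
)
print(f"cluster error rate: {err:.1%} of reads from other organisms")

alignments = pd.DataFrame(
    {
        "read_id": ["r1", "r2", "r3", "r4"],
        "feature_id": ["ARO:3000190"] * 3 + ["ARO:3004480"],
        "mapq": [42, 42, 30, 44],
        "position": [100, 250, 400, 90],
    }
)
rpm = count_feature_hits(alignments, total_reads=1_000_000)
print("resistance-gene hits (MAPQ >= 42, deduplicated, per million reads):")
print(rpm.to_string(index=False))

prof = droplet_occupancy(load_rate=0.02, gels_per_droplet=5)
print(
    f"droplet occupancy at 2% gel load, 5 gels/droplet: "
    f"{prof.p_zero:.1%} empty, {prof.p_any:.1%} with at least one cell"
)
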