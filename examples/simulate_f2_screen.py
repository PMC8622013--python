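"""Simulate a small F2 recombination screen with ground truth.

An F1 Col x Ler hybrid receives a CRISPR cut at the middle of a 2 Mb
chromosome segment; the germline repair outcome is sampled, the F1 is
selfed, and each F2 plant is genotyped at every marker from noisy read
counts — the exact inputs the downstream HMM and tract callers consume.
"""

import numpy as np

from ihrkit.markers import DsbTarget
from ihrkit.simulate import (
    SimulationConfig,
    apply_repair_event,
    emit_observations,
    make_f1,
    make_marker_map,
    simulate_f2_population,
    simulate_repair_event,
)

config = SimulationConfig(seed=42, chromosomes=(("Chr3", 2_000_000),), n_f2=12)
rng = np.random.default_rng(config.seed)
marker_map = make_marker_map(config, rng)
target = DsbTarget(id="Chr3:1000000", chromosome="Chr3", cut_position=1_000_000,
                   allele_specificity="P2_only")

f1 = make_f1(marker_map)
event = simulate_repair_event(target, marker_map, config, rng)
apply_repair_event(f1, event, marker_map, target)
plants = simulate_f2_population(f1, marker_map, config, rng)

print(f"markers simulated   : {marker_map.n_markers}")
print(f"F1 germline event   : {event.kind} on haplotype {event.affected_haplotype}")
print(f"F2 plants           : {len(plants)}")
het = np.mean([np.mean(p.genotype("Chr3") == 1) for p in plants])
print(f"mean het fraction   : {het:.2f} (Mendelian expectation 0.50)")
obs = emit_observations(plants[0], marker_map, config.coverage, config.error_rate, rng)
n1, n2 = obs.counts["Chr3"]
print(f"plant {plants[0].plant_id}: mean depth {float(np.mean(n1 + n2)):.1f} reads/marker")
# These per-marker read counts are exactly what the genotype HMM segments
# into Hom/Het blocks downstream.
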