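"""Reconstruct a somatic allele spectrum from long-amplicon molecules.

An F1 plant's ~5 kb amplicon is a mixture of molecule classes: the two
parental alleles, a +T NHEJ allele, and a +T allele that additionally
exchanged the markers on one side of the cut (an inter-homolog repair
product). Molecules are clustered into consensus alleles, alleles under 5%
are discarded, and the retained ones are classified by pattern topology.
"""

import numpy as np

from ihrkit.amplicon import (
    alleles_frame,
    classify_alleles,
    cluster_molecules,
    filter_alleles,
    somatic_ihr_rate,
)
from ihrkit.simulate import emit_amplicon_molecules

rng = np.random.default_rng(23)
positions = np.arange(10) * 500 + 100  # ten SNPs across the 5 kb window
mixture = [
    ("1" * 10, "", 0.42),            # parental Col
    ("2" * 10, "", 0.38),            # parental Ler
    ("2" * 10, "+T", 0.08),          # NHEJ on the Ler allele
    ("2" * 6 + "1" * 4, "+T", 0.12), # +T plus marker exchange right of the cut
]
molecules = emit_amplicon_molecules(mixture, 3000, rng, miscall_rate=0.002)

alleles = cluster_molecules(molecules)
retained, discarded = filter_alleles(alleles, min_freq=0.05)
classify_alleles(retained, positions)

print(alleles_frame(retained).to_string(index=False))
print(f"discarded mass (<5% alleles + noise): {discarded:.3f}")
print(f"somatic IHR rate: {somatic_ihr_rate(retained):.1%}")
# The somatic IHR rate is the molecule mass in exchange-class alleles — at
# amplicon scale a single switch cannot distinguish a crossover from a long
# conversion tract, so the class names describe topology, not mechanism.
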