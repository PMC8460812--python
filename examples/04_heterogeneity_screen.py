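"""Within-culture heterogeneity screen at the 35% consensus cutoff.

Simulates reads from a culture that is a 60/40 mixture of two haplotypes
differing at 30 engineered SNV sites, builds a pileup, and calls every site
where the alternate-allele fraction reaches 0.35.  All 30 sites are
recovered with alternate fractions near 0.4 and no false calls appear in
error-free reads.
"""

import numpy as np

from normcov import (
    GenomeModel,
    ReadPairSpec,
    build_pileup,
    call_variants,
    random_replicon,
    simulate_mixture,
)
from normcov.heterogeneity import calls_to_frame

replicon = random_replicon("chr", 5_000, 0.6, seed=61, role="chromosome")
sites = {
    int(p): ("A" if replicon.sequence[int(p)] != "A" else "C")
    for p in np.linspace(200, 4800, 30).astype(int)
}

spec = ReadPairSpec(n_pairs=33_000, seed=62, fragment_mean=300, fragment_sd=30)
alignments = simulate_mixture(replicon, sites, alt_fraction=0.4, spec=spec)

genome = GenomeModel([replicon])
calls = call_variants(build_pileup(alignments, genome), threshold=0.35, min_depth=10)

frame = calls_to_frame(calls)
print(frame.round(3).to_string(index=False))
print(f"\ncalled {len(calls)} of {len(sites)} engineered sites; "
      f"false calls: {len({(c.pos, c.alt_base) for c in calls} - set(sites.items()))}")
print("alt_fraction clusters near 0.40 - the minor-haplotype share of the "
      "culture - well above the 0.35 cutoff.")
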