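"""The full synthetic stability experiment, end to end.

Runs two scenarios of the simulate -> coverage -> NormCov -> colony-panel
pipeline on a 10%-scale registry genome: a polyploid population (ploidy 2,
all plasmids stable) and an unstable one (ploidy 1, six plasmids carried by
half the cells).  Colonies are individually sequenced and plasmid presence
is called from their NormCov.  The verdicts separate the two scenarios.
"""

import json
import tempfile
from pathlib import Path

from normcov import RunConfig, run_experiment

UNSTABLE = ["pBAM2", "pUSP1", "pUSP2", "pUSP3", "pUSP4", "pUSP5"]

with tempfile.TemporaryDirectory() as tmp:
    poly = RunConfig(
        seed=3, ploidy=2.0, genome_scale=0.1,
        n_pairs_bulk=20_000, n_pairs_colony=3_000,
    )
    report = run_experiment(poly, Path(tmp) / "polyploid")
    print("polyploid scenario (ploidy 2, stable plasmids):")
    print("  losses  :", report["losses"])
    print("  verdicts:", json.dumps(report["verdicts"], indent=4))

    unstable = RunConfig(
        seed=4, ploidy=1.0, genome_scale=0.1,
        n_pairs_bulk=20_000, n_pairs_colony=3_000,
        carriage={p: 0.5 for p in UNSTABLE},
    )
    report = run_experiment(unstable, Path(tmp) / "unstable")
    print("\nunstable scenario (ploidy 1, six plasmids at carriage 0.5):")
    print("  losses  :", report["losses"])
    print("  verdicts:", json.dumps(report["verdicts"], indent=4))

print(
    "\nBoth scenarios show plasmid NormCov ~0.5 in bulk, yet the colony "
    "panels differ sharply: near-zero losses under polyploidy, ~7 of 14 "
    "losses per unstable plasmid - which is what flips the verdict."
)
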