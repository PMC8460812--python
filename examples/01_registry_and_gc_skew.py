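"""Replicon registry and GC-skew tracks.

Prints the eight-replicon registry of Aminobacter sp. MSH1 (substrain DK1)
and computes a windowed GC/GC-skew track on a synthetic replicon.  The skew
(G - C)/(G + C) changes sign near the replication origin and terminus of a
bacterial replicon; here the sequence is random, so the skew just fluctuates
around zero.
"""

from normcov import gc_skew_track, msh1_registry, random_replicon

registry = msh1_registry()
print(f"{'replicon':<12}{'role':<12}{'length (bp)':>12}{'GC (%)':>8}")
for rep in registry:
    print(f"{rep.name:<12}{rep.role:<12}{rep.length_bp:>12,}{rep.gc_percent:>8.1f}")
print(f"total genome size: {registry.total_length:,} bp "
      f"({len(registry.plasmids)} plasmids)\n")

# a random 50 kb replicon at the chromosome's GC, 10 kb skew windows
rep = random_replicon("demo", 50_000, 0.632, seed=1)
track = gc_skew_track(rep, window_bp=10_000)
print("GC/GC-skew track (10 kb windows) of a random 63.2%-GC replicon:")
print(track.values.to_string(index=False))
print("\ngc_fraction should sit near 0.632; skew near 0 (random sequence has "
      "no strand bias).")
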