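"""GC-island detection: rank an operon-sized window against its replicon.

Simulates a 595,108 bp replicon at GC 0.592 carrying a 4,500 bp island at
GC 0.518, then tiles same-sized windows across it and places the island's GC
among them.  A quantile near 1/(n+1) means the island has (nearly) the
lowest GC of any same-sized window — the signature of a horizontally
acquired region.
"""

from rhizopipe import PlasmidSimConfig, gc_content, gc_rank_test, gen_plasmid

seq, island = gen_plasmid(PlasmidSimConfig(seed=1))
result = gc_rank_test(seq, island)

print(f"replicon: {len(seq):,} bp, mean GC {result.sequence_mean_gc:.3f}")
print(f"island {island.start:,}-{island.end:,}: GC {result.target_gc:.3f} "
      f"(deficit {result.sequence_mean_gc - result.target_gc:.3f})")
print(f"rank {result.rank:.0f} of {result.n_windows} same-sized windows "
      f"-> quantile {result.quantile:.5f}")
print("quantile <= 0.01: the island's GC deviates significantly from the replicon")
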