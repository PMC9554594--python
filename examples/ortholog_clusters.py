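"""Ortholog co-occurrence: cluster hits, pick best hits, summarise species.

Builds a small planned hit table (a full five-gene symbiotic strain, a
two-gene auxin-only species, an unassigned "sp." entry and an
iaaM-only strain), assigns clusters under the 600 kb same-contig rule with
iaaM+iaaH required, and prints the species-level co-occurrence summary.
"""

from rhizopipe import (
    HitSimConfig,
    SpeciesPlan,
    assign_clusters,
    gen_hit_table,
    select_best_hits,
    species_summary,
)
from rhizopipe.genomics import StrainRow

cfg = HitSimConfig(
    plan=(
        SpeciesPlan("Paraburkholderia phenoliruptrix",
                    genes=("iaaM", "iaaH", "nifA", "nifH", "nodA")),
        SpeciesPlan("Agrobacterium tumefaciens", n_strains=2, genes=("iaaM", "iaaH")),
        SpeciesPlan("Burkholderia sp.", genes=("iaaM", "iaaH")),
        SpeciesPlan("Rhizobium rhizogenes", genes=("iaaM",)),
    ),
    seed=3,
)
hits, truth = gen_hit_table(cfg)

rows = []
by_strain: dict[str, list] = {}
for h in hits:
    by_strain.setdefault(h.strain, []).append(h)
for strain, strain_hits in sorted(by_strain.items()):
    clusters = assign_clusters(strain_hits)
    best = select_best_hits(strain_hits, clusters)
    species = strain_hits[0].species
    rows.append(StrainRow(
        strain=strain, genus=species.split()[0], species=species, best_hits=best,
        max_cluster_score=max((c.score for c in clusters), default=0.0),
    ))
    print(f"{strain}: {len(clusters)} cluster(s), genes chosen: {sorted(best)}")

print("\nspecies summary (ordered by max cluster score; 'sp.' entries dropped):")
for row in species_summary(rows):
    sims = {q: f"{lo:.2f}-{hi:.2f}" for q, (lo, hi) in row.similarity_range.items()}
    print(f"  {row.species}: n={row.n_strains}, score {row.score_range[0]:.2f}-"
          f"{row.score_range[1]:.2f}, similarity {sims}")
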