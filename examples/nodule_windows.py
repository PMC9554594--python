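"""Nodule windowing: simulate two inoculation conditions and recover the windows.

Simulates 15 plants per condition (wild type at ~10 nodules/root, a
hypernodulating mutant at ~30), measures consecutive-nodule spacing and the
fraction of gaps under 3 mm, then classifies the pooled positions with
10-class Jenks natural breaks and prints the inferred nodulation windows.
The mutant's higher clustered fraction at an unchanged window layout is the
signature of densification within pre-defined root windows.
"""

from rhizopipe import (
    JenksConfig,
    StrainProfile,
    clustered_fraction,
    consecutive_spacings,
    derive_windows,
    gen_root_systems,
    jenks_iterative,
    pool_positions,
    randomized_control,
)

for name, rate in [("WT", 10.0), ("nifA", 30.0)]:
    profile = StrainProfile(name=name, mean_nodules_per_root=rate)
    root_set = gen_root_systems(profile, n_plants=15, seed=42)
    pooled = pool_positions(root_set)
    gaps = consecutive_spacings([r.positions() for r in root_set.iter_roots()])
    frac = clustered_fraction(gaps, threshold_mm=3.0)
    result = jenks_iterative(pooled, JenksConfig(n_classes=10, seed=42))
    windows = derive_windows(result, pooled)
    print(f"{name}: {pooled.size} nodules, {100 * frac:.1f}% of gaps < 3 mm, "
          f"GVF {100 * result.gvf:.2f}%")
    spans = ", ".join(f"{w.start_mm:.0f}-{w.end_mm:.0f}" for w in windows[:5])
    print(f"  first windows (mm): {spans} ...")

control = randomized_control(500, 0.0, 250.0, seed=42)
res = jenks_iterative(control, JenksConfig(n_classes=10, seed=42))
print(f"uniform control (500 values on 0-250 mm): GVF {100 * res.gvf:.2f}% "
      "(high GVF alone does not prove windowing; compare window spans)")
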