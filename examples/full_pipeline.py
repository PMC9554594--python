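"""One-shot synthetic study: every stage, one seed, one JSON report.

Runs the full simulate-analyze-report pipeline (seven simulated inoculation
conditions, the randomized control, the GC-island scan, ortholog clustering
and ion annotation) and prints the headline numbers of each stage.  The same
run is available from the shell as ``rhizopipe run --seed 42 --out <dir>``.
"""

import tempfile

from rhizopipe import RunConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    report = run_pipeline(RunConfig(seed=42, out_dir=tmp))

print(f"control GVF: {report['control']['gvf_percent']:.2f}% (bound: >= 98%)")
for strain in ("WT", "nifA"):
    entry = report["nodules"][strain]
    print(f"{strain}: {entry['n_nodules']} nodules, "
          f"{100 * entry['clustered_fraction_gap']:.1f}% of gaps < 3 mm, "
          f"GVF {100 * entry['gvf']:.2f}%")
gc = report["gcscan"]
print(f"GC island: deficit {gc['gc_deficit']:.3f}, quantile {gc['quantile']:.5f}")
print(f"species kept after curation: {report['clusters']['n_species_kept']}")
iam = report["ions"]["compounds"]["IAM"]["groups"]
print("IAM letters:", {g: v["letter"] for g, v in iam.items()})
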