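"""End-to-end orchestration: simulate -> analyze -> report.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(global_seed).spawn`` in a fixed stage order
(nodules, control, gcscan, clusters, ions), so each stage is independently
reproducible.  The JSON report is written with sorted keys and no
timestamps: identical config + seed gives a byte-identical report.  The
manifest records the config, derived stage seeds and SHA-256 hashes of every
written artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import io as rio
from .errors import RhizopipeError, ValidationError
from .genomics import assign_clusters, gc_rank_test, select_best_hits, species_summary, StrainRow
from .ions import CompoundRef, annotate_ions, compare_ion_groups
from .spatial import (
    JenksConfig,
    clustered_fraction,
    consecutive_spacings,
    derive_windows,
    frequency_map,
    jenks_iterative,
    pool_positions,
    randomized_control,
    spacing_histogram,
)
from .synthetic import (
    HitSimConfig,
    IonSimConfig,
    PlasmidSimConfig,
    SpeciesPlan,
    StrainProfile,
    gen_hit_table,
    gen_ion_table,
    gen_plasmid,
    gen_root_systems,
)

__all__ = ["RunConfig", "run_pipeline", "default_strain_profiles"]

_STAGES = ("nodules", "control", "gcscan", "clusters", "ions")


def default_strain_profiles() -> tuple[StrainProfile, ...]:
    """The seven simulated inoculation conditions of the synthetic study.

    All conditions share the same window layout; they differ in nodule
    numbers: loss of NifA roughly triples the per-root count, disrupting
    iaaMH in that background mitigates it, and iaaMH manipulations alone
    leave counts near wild type.
    """
    base = dict(pattern="windowed", n_windows=10, first_window_mm=10.0,
                window_growth=1.1, within_window_sd_mm=1.5)
    return (
        StrainProfile(name="WT", mean_nodules_per_root=10.0, **base),
        StrainProfile(name="nifA", mean_nodules_per_root=30.0, **base),
        StrainProfile(name="nifA-comp", mean_nodules_per_root=12.0, **base),
        StrainProfile(name="iaaMH", mean_nodules_per_root=9.0, **base),
        StrainProfile(name="iaaMH-comp", mean_nodules_per_root=8.0, **base),
        StrainProfile(name="nifA-iaaMH", mean_nodules_per_root=15.0, **base),
        StrainProfile(name="nifA-iaaMH-comp", mean_nodules_per_root=28.0, **base),
    )


@dataclass(frozen=True)
class RunConfig:
    """Stage selection and parameters; defaults are the study's settings."""

    stages: tuple[str, ...] = _STAGES
    seed: int = 0
    out_dir: str | None = None
    # nodule stage
    n_plants: int = 15
    roots_per_plant: int = 1
    root_length_mm: float = 250.0
    n_classes: int = 10
    max_iterations: int = 25_000
    spacing_bin_mm: float = 1.0
    cluster_threshold_mm: float = 3.0
    position_bin_mm: float = 5.0
    # randomized control
    control_n: int = 500
    control_range_mm: tuple[float, float] = (0.0, 250.0)
    # GC stage
    plasmid: PlasmidSimConfig = field(default_factory=PlasmidSimConfig)
    gc_window_bp: int = 2_000
    gc_step_bp: int = 400
    # cluster stage
    max_gap_bp: int = 600_000
    min_coverage: float = 0.5
    min_identity: float = 0.3
    # ion stage
    tolerance_da: float = 0.001
    alpha: float = 0.05

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        if self.n_classes > self.control_n:
            raise ValidationError("n_classes may not exceed the control population size")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        if self.control_range_mm[0] >= self.control_range_mm[1]:
            raise ValidationError("control range must be increasing")
        if self.tolerance_da <= 0 or not (0 < self.alpha < 1):
            raise ValidationError("tolerance_da must be > 0 and alpha in (0, 1)")


def _stage_seed(global_seed: int, stage: str) -> int:
    children = np.random.SeedSequence(global_seed).spawn(len(_STAGES))
    return int(children[_STAGES.index(stage)].generate_state(1)[0] % (2**31))


def _default_ion_config(seed: int) -> IonSimConfig:
    iam = CompoundRef("IAM", "C10H10N2O")
    iaa = CompoundRef("IAA", "C10H9NO2")
    groups = ("NI", "WT", "nifA", "iaaMH", "nifA-iaaMH")
    iam_means = {"NI": 500.0, "WT": 1000.0, "nifA": 2000.0, "iaaMH": 500.0, "nifA-iaaMH": 500.0}
    iaa_means = {"NI": 400.0, "WT": 800.0, "nifA": 1600.0, "iaaMH": 400.0, "nifA-iaaMH": 400.0}
    return IonSimConfig(
        true_compounds=((iam, iam_means), (iaa, iaa_means)),
        groups=groups,
        seed=seed,
    )


def _default_hit_config(seed: int) -> HitSimConfig:
    plan = (
        SpeciesPlan("Paraburkholderia phenoliruptrix", n_strains=2,
                    genes=("iaaM", "iaaH", "nifA", "nifH", "nodA")),
        SpeciesPlan("Paraburkholderia phymatum", n_strains=1,
                    genes=("iaaM", "iaaH", "nifA", "nifH", "nodA")),
        SpeciesPlan("Agrobacterium tumefaciens", n_strains=3, genes=("iaaM", "iaaH")),
        SpeciesPlan("Pseudomonas syringae", n_strains=2, genes=("iaaM", "iaaH")),
        SpeciesPlan("Burkholderia sp.", n_strains=1, genes=("iaaM", "iaaH")),
        SpeciesPlan("Dickeya dianthicola", n_strains=1, genes=("iaaM", "iaaH", "nifA", "nifH")),
        SpeciesPlan("Rhizobium rhizogenes", n_strains=1, genes=("iaaM",)),
    )
    return HitSimConfig(plan=plan, seed=seed)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the selected stages in dependency order; returns the report dict.

    When ``cfg.out_dir`` is set, writes ``report.json`` (sorted keys,
    deterministic) and ``manifest.json`` (config, stage seeds, artifact
    SHA-256 hashes) plus per-stage CSV artifacts.
    """
    report_cfg = _config_dict(cfg)
    report_cfg.pop("out_dir", None)  # report content must not depend on where it is written
    report: dict = {"config": report_cfg}
    artifacts: dict[str, str] = {}
    out = cfg.out_dir
    if out:
        os.makedirs(out, exist_ok=True)

    try:
        if "nodules" in cfg.stages:
            report["nodules"] = _run_nodules(cfg, out, artifacts)
        if "control" in cfg.stages:
            report["control"] = _run_control(cfg)
        if "gcscan" in cfg.stages:
            report["gcscan"] = _run_gcscan(cfg, out, artifacts)
        if "clusters" in cfg.stages:
            report["clusters"] = _run_clusters(cfg, out, artifacts)
        if "ions" in cfg.stages:
            report["ions"] = _run_ions(cfg, out, artifacts)
    except RhizopipeError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise RhizopipeError(f"stage execution failed: {exc}") from exc

    if out:
        report_path = os.path.join(out, "report.json")
        with open(report_path, "w") as fh:
            json.dump(report, fh, sort_keys=True, indent=1)
            fh.write("\n")
        artifacts["report.json"] = _sha256(report_path)
        manifest = {
            "config": _config_dict(cfg),
            "stage_seeds": {s: _stage_seed(cfg.seed, s) for s in cfg.stages},
            "artifacts": artifacts,
        }
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, sort_keys=True, indent=1)
            fh.write("\n")
    return report


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["plasmid"] = dataclasses.asdict(cfg.plasmid)
    return d


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _run_nodules(cfg: RunConfig, out: str | None, artifacts: dict) -> dict:
    seed = _stage_seed(cfg.seed, "nodules")
    results = {}
    for i, profile in enumerate(default_strain_profiles()):
        root_set = gen_root_systems(
            profile, cfg.n_plants, cfg.roots_per_plant, cfg.root_length_mm, seed=seed + i
        )
        pooled = pool_positions(root_set)
        gaps = consecutive_spacings([r.positions() for r in root_set.iter_roots()])
        entry: dict = {"n_nodules": int(pooled.size), "n_gaps": int(gaps.size)}
        if gaps.size:
            entry["clustered_fraction_gap"] = clustered_fraction(
                gaps, cfg.cluster_threshold_mm, basis="gap"
            )
            entry["clustered_fraction_nodule"] = clustered_fraction(
                [r.positions() for r in root_set.iter_roots()],
                cfg.cluster_threshold_mm,
                basis="nodule",
            )
            entry["spacing_histogram"] = spacing_histogram(
                gaps, cfg.spacing_bin_mm
            ).counts.tolist()
        entry["frequency_map"] = frequency_map(pooled, cfg.position_bin_mm).counts.tolist()
        if np.unique(pooled).size >= cfg.n_classes:
            jres = jenks_iterative(
                pooled,
                JenksConfig(
                    n_classes=cfg.n_classes, max_iterations=cfg.max_iterations, seed=seed + i
                ),
            )
            windows = derive_windows(jres, pooled)
            entry["gvf"] = jres.gvf
            entry["breaks"] = list(jres.breaks)
            entry["windows"] = [
                {"class": w.class_index, "start_mm": w.start_mm, "end_mm": w.end_mm,
                 "n": w.n_nodules}
                for w in windows
            ]
            if out:
                path = os.path.join(out, f"windows_{profile.name}.csv")
                rio.write_windows_csv(windows, path)
                artifacts[os.path.basename(path)] = _sha256(path)
        if out:
            path = os.path.join(out, f"nodules_{profile.name}.csv")
            rio.write_nodule_csv(root_set, path)
            artifacts[os.path.basename(path)] = _sha256(path)
        results[profile.name] = entry
    return results


def _run_control(cfg: RunConfig) -> dict:
    seed = _stage_seed(cfg.seed, "control")
    lo, hi = cfg.control_range_mm
    values = randomized_control(cfg.control_n, lo, hi, seed=seed)
    jres = jenks_iterative(
        values,
        JenksConfig(n_classes=cfg.n_classes, max_iterations=cfg.max_iterations, seed=seed),
    )
    windows = derive_windows(jres, values)
    spans = [w.span_mm for w in windows]
    return {
        "n": cfg.control_n,
        "gvf": jres.gvf,
        "gvf_percent": 100.0 * jres.gvf,
        "windows": [
            {"class": w.class_index, "start_mm": w.start_mm, "end_mm": w.end_mm, "n": w.n_nodules}
            for w in windows
        ],
        "mean_window_span_mm": float(np.mean(spans)),
    }


def _run_gcscan(cfg: RunConfig, out: str | None, artifacts: dict) -> dict:
    seed = _stage_seed(cfg.seed, "gcscan")
    plasmid_cfg = dataclasses.replace(cfg.plasmid, seed=seed)
    seq, island = gen_plasmid(plasmid_cfg)
    entry: dict = {"length_bp": len(seq)}
    from .genomics import gc_content

    entry["mean_gc"] = gc_content(seq)
    if island is not None:
        res = gc_rank_test(seq, island, step_bp=cfg.gc_step_bp)
        entry.update(
            island_start=island.start,
            island_end=island.end,
            island_gc=res.target_gc,
            gc_deficit=res.sequence_mean_gc - res.target_gc,
            rank=res.rank,
            n_windows=res.n_windows,
            quantile=res.quantile,
        )
        if out:
            path = os.path.join(out, "island.bed")
            rio.write_region_bed([island], path)
            artifacts["island.bed"] = _sha256(path)
    return entry


def _run_clusters(cfg: RunConfig, out: str | None, artifacts: dict) -> dict:
    seed = _stage_seed(cfg.seed, "clusters")
    hits, truth = gen_hit_table(_default_hit_config(seed))
    rows = []
    by_strain: dict[str, list] = {}
    for h in hits:
        by_strain.setdefault(h.strain, []).append(h)
    for strain, strain_hits in sorted(by_strain.items()):
        clusters = assign_clusters(strain_hits, max_gap_bp=cfg.max_gap_bp)
        best = select_best_hits(strain_hits, clusters)
        species = strain_hits[0].species
        rows.append(
            StrainRow(
                strain=strain,
                genus=species.split()[0],
                species=species,
                best_hits=best,
                max_cluster_score=max((c.score for c in clusters), default=0.0),
            )
        )
    summary = species_summary(rows)
    if out:
        path = os.path.join(out, "hits.tsv")
        rio.write_hits_tsv(hits, path)
        artifacts["hits.tsv"] = _sha256(path)
    return {
        "n_strains": len(rows),
        "n_species_kept": len(summary),
        "species": [
            {
                "genus": r.genus,
                "species": r.species,
                "n_strains": r.n_strains,
                "score_min": r.score_range[0],
                "score_max": r.score_range[1],
                "similarity": {q: list(v) for q, v in r.similarity_range.items()},
            }
            for r in summary
        ],
        "truth_species_kept": sorted(truth["species_kept"]),
    }


def _run_ions(cfg: RunConfig, out: str | None, artifacts: dict) -> dict:
    seed = _stage_seed(cfg.seed, "ions")
    ion_cfg = _default_ion_config(seed)
    ions, sample_groups, truth = gen_ion_table(ion_cfg)
    compounds = [c for c, _ in ion_cfg.true_compounds]
    annotations = annotate_ions(ions, compounds, tolerance_da=cfg.tolerance_da)
    entry: dict = {
        "n_ions": len(ions),
        "n_annotated": len(annotations),
        "compounds": {},
    }
    for ann in annotations:
        table = compare_ion_groups(ann, sample_groups, alpha=cfg.alpha)
        entry["compounds"][ann.compound.name] = {
            "delta_da": ann.delta_da,
            "groups": {
                r["group"]: {"mean": r["mean"], "letter": r["letter"]}
                for _, r in table.iterrows()
            },
        }
    if out:
        path = os.path.join(out, "ions.csv")
        rio.write_ion_csv(ions, path)
        artifacts["ions.csv"] = _sha256(path)
    return entry
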