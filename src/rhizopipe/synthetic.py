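"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study's four raw-data classes:

* nodule positions along root axes — either uniform or concentrated in
  discrete windows that widen toward the root apex, mimicking the windowed,
  front-loaded nodulation seen on real roots;
* a replicon with a low-GC island embedded in a higher-GC background
  (defaults are the symbiotic-plasmid scale: 595,108 bp at GC 0.592 with a
  4,500 bp island 0.074 lower);
* ortholog-hit tables with planned cluster structure;
* centroided negative-mode ion tables with known true compounds, group
  effects and decoy ions.

Every generator is deterministic given its seed, and each emits its ground
truth alongside the data so downstream recovery can be asserted exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .genomics import GenomicRegion, OrthologHit
from .ions import CompoundRef, IonRecord, deprotonated_mz
from .spatial import NoduleObservation, Plant, Root, RootSystemSet

__all__ = [
    "StrainProfile",
    "PlasmidSimConfig",
    "SpeciesPlan",
    "HitSimConfig",
    "IonSimConfig",
    "gen_root_systems",
    "gen_plasmid",
    "gen_hit_table",
    "gen_ion_table",
    "window_layout",
]


# ---------------------------------------------------------------------------
# Nodule positions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrainProfile:
    """Nodulation behaviour of one inoculation condition.

    ``pattern="windowed"`` places nodules in ``n_windows`` discrete intervals
    whose lengths grow multiplicatively (``window_growth``) toward the apex,
    the first window starting at the root--shoot junction.  The gap preceding
    window i+1 is ``gap_ratio`` times that window's length, so denser, smaller
    windows sit near the junction (front-loading).  Expected counts are split
    equally across windows; within a window positions are normal around the
    centre, truncated to the window.
    """

    name: str
    mean_nodules_per_root: float
    pattern: Literal["uniform", "windowed"] = "windowed"
    n_windows: int = 10
    first_window_mm: float = 10.0
    window_growth: float = 1.1
    within_window_sd_mm: float = 1.5
    nodule_diameter_mm: float = 1.0
    gap_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.mean_nodules_per_root < 0:
            raise ValidationError("mean_nodules_per_root must be >= 0")
        if self.pattern not in ("uniform", "windowed"):
            raise ValidationError(f"unknown pattern {self.pattern!r}")
        if self.n_windows < 1:
            raise ValidationError("n_windows must be >= 1")
        if self.first_window_mm <= 0:
            raise ValidationError("first_window_mm must be > 0")
        if self.window_growth < 1.0:
            raise ValidationError("window_growth must be >= 1")
        if self.within_window_sd_mm <= 0:
            raise ValidationError("within_window_sd_mm must be > 0")
        if self.nodule_diameter_mm <= 0:
            raise ValidationError("nodule_diameter_mm must be > 0")
        if self.gap_ratio < 0:
            raise ValidationError("gap_ratio must be >= 0")


def window_layout(profile: StrainProfile, root_length_mm: float) -> list[tuple[float, float]]:
    """True window intervals [(start, end), ...] for a windowed profile."""
    lengths = [
        profile.first_window_mm * profile.window_growth ** i for i in range(profile.n_windows)
    ]
    windows = []
    cursor = 0.0
    for i, ln in enumerate(lengths):
        if i > 0:
            cursor += profile.gap_ratio * ln
        windows.append((cursor, cursor + ln))
        cursor += ln
    if windows[-1][1] > root_length_mm:
        raise ValidationError(
            f"window layout spans {windows[-1][1]:.1f} mm, exceeding the "
            f"{root_length_mm:.1f} mm root; shrink first_window_mm/window_growth"
        )
    return windows


def gen_root_systems(
    profile: StrainProfile,
    n_plants: int,
    roots_per_plant: int = 1,
    root_length_mm: float = 250.0,
    seed: int = 0,
) -> RootSystemSet:
    """Simulate the nodule positions of one condition's root systems.

    Counts are Poisson; uniform patterns draw i.i.d. positions on the root,
    windowed patterns draw per window (equal share of the per-root mean)
    normal positions around the window centre, truncated to the window.
    The first root of each plant is the tap root, the rest basal.
    """
    if n_plants < 1 or roots_per_plant < 1:
        raise ValidationError("n_plants and roots_per_plant must be >= 1")
    if root_length_mm <= 0:
        raise ValidationError("root_length_mm must be > 0")
    rng = np.random.default_rng(seed)
    windows = (
        window_layout(profile, root_length_mm) if profile.pattern == "windowed" else None
    )
    plants = []
    for p in range(n_plants):
        plant = Plant(name=f"plant{p + 1:02d}")
        for r in range(roots_per_plant):
            rtype = "tap" if r == 0 else "basal"
            root = Root(name=f"{plant.name}:root{r + 1}", root_type=rtype, length_mm=root_length_mm)
            positions: list[float] = []
            if windows is None:
                n = rng.poisson(profile.mean_nodules_per_root)
                positions.extend(rng.uniform(0.0, root_length_mm, size=n))
            else:
                share = profile.mean_nodules_per_root / profile.n_windows
                for (lo, hi) in windows:
                    n = rng.poisson(share)
                    if n == 0:
                        continue
                    centre = 0.5 * (lo + hi)
                    sd = profile.within_window_sd_mm
                    a, b = (lo - centre) / sd, (hi - centre) / sd
                    draws = stats.truncnorm.rvs(
                        a, b, loc=centre, scale=sd, size=n, random_state=rng
                    )
                    positions.extend(np.atleast_1d(draws))
            for pos in sorted(positions):
                root.nodules.append(
                    NoduleObservation(
                        plant=plant.name,
                        root=root.name,
                        root_type=rtype,
                        position_mm=float(pos),
                        diameter_mm=profile.nodule_diameter_mm,
                    )
                )
            plant.roots.append(root)
        plants.append(plant)
    return RootSystemSet(strain=profile.name, plants=plants, true_windows=windows)


# ---------------------------------------------------------------------------
# Plasmid with a low-GC island
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlasmidSimConfig:
    """Replicon simulation: i.i.d. bases at a background GC with one island.

    Defaults mirror the symbiotic-plasmid setting: 595,108 bp at GC 0.592
    carrying a 4,500 bp island whose GC is 0.074 lower (0.518).
    """

    length_bp: int = 595_108
    background_gc: float = 0.592
    island_start_bp: int | None = 532_782
    island_length_bp: int = 4_500
    island_gc: float = 0.518
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValidationError("length_bp must be >= 1")
        for gc in (self.background_gc, self.island_gc):
            if not (0.0 <= gc <= 1.0):
                raise ValidationError("GC fractions must lie in [0, 1]")
        if self.island_start_bp is not None:
            if self.island_start_bp < 1 or self.island_length_bp < 1:
                raise ValidationError("island coordinates must be >= 1")
            if self.island_start_bp + self.island_length_bp - 1 > self.length_bp:
                raise ValidationError("island extends beyond the sequence")

    @property
    def island_region(self) -> GenomicRegion | None:
        if self.island_start_bp is None:
            return None
        return GenomicRegion(
            seq_id="synthetic_plasmid",
            start=self.island_start_bp,
            end=self.island_start_bp + self.island_length_bp - 1,
        )


_BASES = np.frombuffer(b"ATGC", dtype=np.uint8)


def _draw_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """Random bases at an exact G+C count (round(n*gc)), uniformly shuffled.

    Exact-count composition pins the realized GC of every segment to its
    nominal value (up to 1/n rounding) for every seed; the shuffle leaves no
    positional or dinucleotide structure.
    """
    n_gc = round(n * gc)
    n_at = n - n_gc
    n_g = n_gc // 2 + int(rng.integers(0, 2)) * (n_gc % 2)
    n_a = n_at // 2 + int(rng.integers(0, 2)) * (n_at % 2)
    arr = np.repeat(_BASES, [n_a, n_at - n_a, n_g, n_gc - n_g])
    return rng.permutation(arr)


def gen_plasmid(cfg: PlasmidSimConfig) -> tuple[str, GenomicRegion | None]:
    """Simulate the replicon sequence; returns (sequence, island region or None)."""
    rng = np.random.default_rng(cfg.seed)
    arr = _draw_bases(rng, cfg.length_bp, cfg.background_gc)
    region = cfg.island_region
    if region is not None:
        arr[region.start - 1: region.end] = _draw_bases(rng, region.length, cfg.island_gc)
    return arr.tobytes().decode("ascii"), region


# ---------------------------------------------------------------------------
# Ortholog-hit tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesPlan:
    """Planned hit structure for the strains of one species."""

    species: str
    n_strains: int = 1
    genes: tuple[str, ...] = ("iaaM", "iaaH")
    same_contig: bool = True
    gap_bp: int = 5_000
    coverage_range: tuple[float, float] = (0.6, 1.0)
    identity_range: tuple[float, float] = (0.4, 1.0)

    def __post_init__(self) -> None:
        if self.n_strains < 1:
            raise ValidationError("n_strains must be >= 1")
        if not self.genes:
            raise ValidationError("gene set must be non-empty")
        for lo, hi in (self.coverage_range, self.identity_range):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValidationError("coverage/identity ranges must lie within [0, 1]")

    @property
    def genus(self) -> str:
        return self.species.split()[0]


@dataclass(frozen=True)
class HitSimConfig:
    plan: tuple[SpeciesPlan, ...]
    gene_length_bp: int = 1_500
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.plan:
            raise ValidationError("species plan must be non-empty")


def gen_hit_table(cfg: HitSimConfig) -> tuple[list[OrthologHit], dict]:
    """Emit hits per the plan, plus ground truth.

    Ground truth maps strain -> {"clusters_expected": bool, "genes": [...]}
    and lists which species survive the "sp." filter.  A strain is expected
    to yield a cluster iff its genes include both iaaM and iaaH and they sit
    on one contig within the 600 kb rule (the plan's gap applies between
    consecutive genes).
    """
    rng = np.random.default_rng(cfg.seed)
    hits: list[OrthologHit] = []
    truth: dict = {"strains": {}, "species_kept": []}
    for plan in cfg.plan:
        if not plan.species.strip().endswith("sp."):
            truth["species_kept"].append(plan.species)
        for s in range(plan.n_strains):
            strain = f"{plan.species.replace(' ', '_')}_{s + 1:02d}"
            cursor = int(rng.integers(1, 50_000))
            for g_idx, gene in enumerate(plan.genes):
                contig = "contig1" if plan.same_contig else f"contig{g_idx + 1}"
                if g_idx > 0 and plan.same_contig:
                    cursor += plan.gap_bp
                elif not plan.same_contig:
                    cursor = int(rng.integers(1, 50_000))
                cov = float(rng.uniform(*plan.coverage_range))
                ident = float(rng.uniform(*plan.identity_range))
                hits.append(
                    OrthologHit(
                        query=gene,
                        subject=f"{strain}.{gene}",
                        strain=strain,
                        species=plan.species,
                        contig=contig,
                        start=cursor,
                        end=cursor + cfg.gene_length_bp - 1,
                        coverage=cov,
                        identity=ident,
                    )
                )
                cursor += cfg.gene_length_bp
            expected = (
                {"iaaM", "iaaH"} <= set(plan.genes)
                and plan.same_contig
                and plan.gap_bp <= 600_000
            )
            truth["strains"][strain] = {
                "species": plan.species,
                "genes": list(plan.genes),
                "cluster_expected": expected,
            }
    return hits, truth


# ---------------------------------------------------------------------------
# Ion tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IonSimConfig:
    """Centroided negative-mode ion list with known true compounds.

    ``true_compounds`` maps each reference compound to per-group mean ion
    counts; every group has ``n_replicates`` samples.  Intensities are
    log-normal with coefficient of variation ``noise_cv``.  Decoy ions are
    placed at least ``decoy_min_distance_da`` (default 0.002, twice the usual
    matching tolerance) from every true deprotonated mass so that annotation
    specificity is exactly testable.
    """

    true_compounds: tuple[tuple[CompoundRef, dict[str, float]], ...]
    groups: tuple[str, ...] = ("NI", "WT", "nifA", "iaaMH", "nifA-iaaMH")
    n_replicates: int = 6
    noise_cv: float = 0.2
    n_decoy_ions: int = 50
    mz_jitter_da: float = 0.0003
    decoy_min_distance_da: float = 0.002
    decoy_mz_range: tuple[float, float] = (100.0, 400.0)
    intended_tolerance_da: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2 per group")
        if self.noise_cv <= 0:
            raise ValidationError("noise_cv must be > 0")
        if self.n_decoy_ions < 0 or self.mz_jitter_da < 0:
            raise ValidationError("n_decoy_ions and mz_jitter_da must be >= 0")
        for _, means in self.true_compounds:
            missing = set(self.groups) - set(means)
            if missing:
                raise ValidationError(f"missing group means: {sorted(missing)}")
        if self.mz_jitter_da > self.intended_tolerance_da:
            warnings.warn(
                "mz jitter exceeds the intended matching tolerance; "
                "match rate will degrade by design",
                stacklevel=2,
            )


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def gen_ion_table(cfg: IonSimConfig) -> tuple[list[IonRecord], dict[str, str], dict]:
    """Simulate the ion table.

    Returns ``(ions, sample_groups, truth)`` where truth maps compound name
    -> its true deprotonated m/z and lists the decoy m/z values.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = tuple(
        f"{g}_{i + 1}" for g in cfg.groups for i in range(cfg.n_replicates)
    )
    sample_groups = {s: s.rsplit("_", 1)[0] for s in samples}
    true_mz = [deprotonated_mz(c.neutral_mass) for c, _ in cfg.true_compounds]
    ions: list[IonRecord] = []
    truth: dict = {"compounds": {}, "decoys": []}
    for (comp, means), mz0 in zip(cfg.true_compounds, true_mz):
        jitter = float(rng.uniform(-cfg.mz_jitter_da, cfg.mz_jitter_da)) if cfg.mz_jitter_da else 0.0
        intens = np.concatenate(
            [_lognormal(rng, means[g], cfg.noise_cv, cfg.n_replicates) for g in cfg.groups]
        )
        ions.append(IonRecord(mz=mz0 + jitter, intensities=tuple(intens), samples=samples))
        truth["compounds"][comp.name] = {"mz": mz0, "observed_mz": mz0 + jitter}
    placed = 0
    while placed < cfg.n_decoy_ions:
        mz = float(rng.uniform(*cfg.decoy_mz_range))
        if all(abs(mz - t) >= cfg.decoy_min_distance_da for t in true_mz):
            intens = _lognormal(rng, 500.0, cfg.noise_cv, len(samples))
            ions.append(IonRecord(mz=mz, intensities=tuple(intens), samples=samples))
            truth["decoys"].append(mz)
            placed += 1
    return ions, sample_groups, truth
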