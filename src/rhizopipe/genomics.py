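"""GC-island statistics and ortholog-cluster co-occurrence analysis.

Two halves:

* **GC profiling and the operon-window rank test.**  GC content is computed
  over sliding windows (defaults 2 kb window / 0.4 kb step for profiling);
  to ask whether an operon-sized region deviates from its replicon, windows
  of exactly the region's length are tiled across the replicon and the
  region's GC content is placed among the sorted window values.  The report
  is an empirical rank and quantile: quantile = rank / (n_windows + 1), with
  ties counted as one half, so a homogeneous sequence yields an (approximately)
  uniform quantile.

* **Ortholog-hit post-processing.**  Hits carry coverage and identity, both
  normalised to 1; similarity is their product.  Hits of one strain are
  grouped into clusters on a contig when consecutive hits are separated by at
  most a maximum intergenic distance (default 600 kb); clusters must contain
  the required query genes (default iaaM and iaaH).  A per-query best hit is
  chosen preferring in-cluster hits, strains are summarised per species with
  min/max similarity and cluster score, and a representative genome per
  species is selected.  Protein alignments of two genes can be concatenated
  with a partition definition assigning each gene its substitution model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "GenomicRegion",
    "GCWindow",
    "RankTestResult",
    "OrthologHit",
    "HitCluster",
    "CooccurrenceRow",
    "GenomeRecord",
    "PartitionedAlignment",
    "region_length",
    "gc_content",
    "gc_profile",
    "gc_rank_test",
    "score_similarity",
    "assign_clusters",
    "cluster_score",
    "select_best_hits",
    "species_summary",
    "select_representative",
    "concat_alignments",
]


# ---------------------------------------------------------------------------
# Regions and GC statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicRegion:
    """1-based, inclusive coordinates (NCBI style)."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValidationError("coordinates are 1-based and must be >= 1")
        if self.start > self.end:
            raise ValidationError(f"region start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_bed(self) -> tuple[str, int, int]:
        """0-based half-open triple for BED output."""
        return (self.seq_id, self.start - 1, self.end)

    @classmethod
    def from_string(cls, text: str) -> "GenomicRegion":
        """Parse ``seqid:start-end`` (or bare ``start-end`` with empty id)."""
        seq_id, _, span = text.rpartition(":")
        lo, _, hi = span.partition("-")
        return cls(seq_id=seq_id, start=int(lo.replace(",", "")), end=int(hi.replace(",", "")))


def region_length(region: GenomicRegion) -> int:
    """Inclusive length in nucleotides."""
    return region.length


@dataclass(frozen=True)
class GCWindow:
    start: int  # 1-based inclusive
    end: int
    gc: float


_GC_SET = frozenset("GCgc")
_ACGT_SET = frozenset("ACGTacgt")


def _seq_to_arrays(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Boolean per-base arrays: (is G/C, is unambiguous A/C/G/T)."""
    b = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    is_gc = (b == ord("G")) | (b == ord("C"))
    is_acgt = is_gc | (b == ord("A")) | (b == ord("T"))
    return is_gc, is_acgt


def gc_content(seq: str) -> float:
    """(G+C)/(A+C+G+T), case-insensitive; ambiguity codes are excluded entirely."""
    if len(seq) == 0:
        raise ValidationError("sequence must be non-empty")
    is_gc, is_acgt = _seq_to_arrays(str(seq))
    denom = int(is_acgt.sum())
    if denom == 0:
        raise DegenerateInputError("sequence contains no unambiguous A/C/G/T bases")
    return float(is_gc.sum() / denom)


def gc_profile(seq: str, window_bp: int = 2000, step_bp: int = 400) -> list[GCWindow]:
    """Sliding-window GC profile; trailing partial window discarded.

    Window count is ``floor((L - window) / step) + 1`` with windows starting
    at 1, 1 + step, ...
    """
    seq = str(seq)
    L = len(seq)
    if step_bp < 1:
        raise ValidationError("step_bp must be >= 1")
    if window_bp < 1 or window_bp > L:
        raise ValidationError(f"window_bp must lie in [1, {L}]")
    is_gc, is_acgt = _seq_to_arrays(seq)
    cg = np.concatenate([[0], np.cumsum(is_gc)])
    cn = np.concatenate([[0], np.cumsum(is_acgt)])
    n_win = (L - window_bp) // step_bp + 1
    starts0 = np.arange(n_win) * step_bp          # 0-based
    ends0 = starts0 + window_bp
    num = cg[ends0] - cg[starts0]
    den = cn[ends0] - cn[starts0]
    out = []
    for s0, e0, g, d in zip(starts0, ends0, num, den):
        gc = float(g / d) if d > 0 else math.nan
        out.append(GCWindow(start=int(s0) + 1, end=int(e0), gc=gc))
    return out


@dataclass(frozen=True)
class RankTestResult:
    """Empirical placement of a target region among same-sized windows."""

    target_gc: float
    n_windows: int
    rank: float            # 1 + #(window gc < target gc), ties counted 0.5
    windows_excluded: int
    sequence_mean_gc: float

    @property
    def quantile(self) -> float:
        return self.rank / (self.n_windows + 1)


def gc_rank_test(
    seq: str,
    target: GenomicRegion,
    step_bp: int = 400,
    exclude_overlap: bool = True,
) -> RankTestResult:
    """Place a target region's GC content among same-length windows of the replicon.

    Null windows of size ``target.length`` are tiled across the sequence at
    ``step_bp``; windows overlapping the target are removed when
    ``exclude_overlap``.  rank = 1 + #(gc < target_gc) + 0.5 * #(ties);
    quantile = rank / (n_windows + 1), so rank 1 (lowest GC of all) maps to
    1/(n+1).
    """
    seq = str(seq)
    L = len(seq)
    if target.end > L:
        raise ValidationError("target region extends beyond the sequence")
    windows = gc_profile(seq, window_bp=target.length, step_bp=step_bp)
    target_gc = gc_content(seq[target.start - 1: target.end])
    excluded = 0
    null_gc = []
    for w in windows:
        if exclude_overlap and not (w.end < target.start or w.start > target.end):
            excluded += 1
            continue
        null_gc.append(w.gc)
    if len(null_gc) < 20:
        raise DegenerateInputError(
            f"only {len(null_gc)} null windows available; rank uninformative"
        )
    arr = np.asarray(null_gc)
    below = int(np.count_nonzero(arr < target_gc))
    ties = int(np.count_nonzero(arr == target_gc))
    return RankTestResult(
        target_gc=target_gc,
        n_windows=len(null_gc),
        rank=1.0 + below + 0.5 * ties,
        windows_excluded=excluded,
        sequence_mean_gc=gc_content(seq),
    )


# ---------------------------------------------------------------------------
# Ortholog hits and clusters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrthologHit:
    """One search hit of a query gene against a subject genome."""

    query: str
    subject: str
    strain: str
    species: str
    contig: str
    start: int      # 1-based inclusive
    end: int
    coverage: float
    identity: float

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError("hit coordinates must satisfy 1 <= start <= end")
        if not (0.0 <= self.coverage <= 1.0 and 0.0 <= self.identity <= 1.0):
            raise ValidationError("coverage and identity must lie in [0, 1]")

    @property
    def similarity(self) -> float:
        return score_similarity(self)


def score_similarity(hit: OrthologHit) -> float:
    """Similarity = coverage x identity, both normalised to 1."""
    return hit.coverage * hit.identity


@dataclass(frozen=True)
class HitCluster:
    """Co-located hits of one strain on one contig."""

    hits: tuple[OrthologHit, ...]
    score: float

    @property
    def queries(self) -> frozenset[str]:
        return frozenset(h.query for h in self.hits)


def _gap_bp(prev: OrthologHit, nxt: OrthologHit) -> int:
    """Distance from the end of one hit to the start of the next; >= 0."""
    return max(0, nxt.start - prev.end)


def cluster_score(hits: Sequence[OrthologHit]) -> float:
    """Cluster summary: #distinct queries hit + mean similarity of the best hit per query.

    An approximation of a search tool's number-and-similarity cluster score;
    comparable only within this package.
    """
    best: dict[str, float] = {}
    for h in hits:
        best[h.query] = max(best.get(h.query, 0.0), score_similarity(h))
    if not best:
        return 0.0
    return len(best) + float(np.mean(list(best.values())))


def assign_clusters(
    hits: Iterable[OrthologHit],
    max_gap_bp: int = 600_000,
    required: frozenset[str] | set[str] = frozenset({"iaaM", "iaaH"}),
) -> list[HitCluster]:
    """Group one strain's hits into clusters by the maximum-intergenic-distance rule.

    Per contig, hits sorted by start coordinate; a new cluster begins whenever
    the gap (end of previous hit to start of the next, floored at 0) exceeds
    ``max_gap_bp``.  Clusters missing any required query gene are discarded.
    """
    hits = list(hits)
    strains = {h.strain for h in hits}
    if len(strains) > 1:
        raise ValidationError("assign_clusters operates on the hits of a single strain")
    required = frozenset(required)
    by_contig: dict[str, list[OrthologHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig, []).append(h)
    clusters: list[HitCluster] = []
    for contig in sorted(by_contig):
        chunk = sorted(by_contig[contig], key=lambda h: (h.start, h.end, h.query))
        run: list[OrthologHit] = []
        for h in chunk:
            if run and _gap_bp(run[-1], h) > max_gap_bp:
                clusters.append(HitCluster(hits=tuple(run), score=cluster_score(run)))
                run = []
            run.append(h)
        if run:
            clusters.append(HitCluster(hits=tuple(run), score=cluster_score(run)))
    return [c for c in clusters if required <= c.queries]


def select_best_hits(
    hits: Iterable[OrthologHit], clusters: Sequence[HitCluster]
) -> dict[str, OrthologHit]:
    """Per-query best hit: prefer the most similar in-cluster hit, else the global best.

    Ties break deterministically by higher identity, then lower subject
    accession lexicographically.
    """
    hits = list(hits)
    cluster_members = {h for c in clusters for h in c.hits}
    chosen: dict[str, OrthologHit] = {}
    queries = sorted({h.query for h in hits})
    key = lambda h: (score_similarity(h), h.identity, _NegStr(h.subject))
    for q in queries:
        q_hits = [h for h in hits if h.query == q]
        pool = [h for h in q_hits if h in cluster_members] or q_hits
        chosen[q] = max(pool, key=key)
    return chosen


class _NegStr(str):
    """Orders reversed, so max() prefers the lexicographically smaller string."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# Species summaries and representative genomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrainRow:
    """One strain's chosen hits, cluster score and curation flags."""

    strain: str
    genus: str
    species: str
    best_hits: dict[str, OrthologHit] = field(hash=False, default_factory=dict)
    max_cluster_score: float = 0.0
    contaminated: bool = False
    is_assembly: bool = True
    taxonomy_ok: bool = True


@dataclass(frozen=True)
class CooccurrenceRow:
    genus: str
    species: str
    n_strains: int
    similarity_range: dict[str, tuple[float, float]]  # query -> (min, max)
    score_range: tuple[float, float]


def species_summary(rows: Iterable[StrainRow]) -> list[CooccurrenceRow]:
    """Group curated strains by species; report per-query min/max similarity and scores.

    Unassigned species ("... sp."), contaminated entries, non-assemblies and
    taxonomy-check failures are dropped.  Output is ordered by max cluster
    score descending (ties by species name: a total order).
    """
    kept = [
        r
        for r in rows
        if not r.species.strip().endswith("sp.")
        and not r.contaminated
        and r.is_assembly
        and r.taxonomy_ok
    ]
    grouped: dict[tuple[str, str], list[StrainRow]] = {}
    for r in kept:
        grouped.setdefault((r.genus, r.species), []).append(r)
    out = []
    for (genus, species), members in grouped.items():
        sims: dict[str, list[float]] = {}
        for m in members:
            for q, h in m.best_hits.items():
                sims.setdefault(q, []).append(score_similarity(h))
        scores = [m.max_cluster_score for m in members]
        out.append(
            CooccurrenceRow(
                genus=genus,
                species=species,
                n_strains=len(members),
                similarity_range={q: (min(v), max(v)) for q, v in sorted(sims.items())},
                score_range=(min(scores), max(scores)),
            )
        )
    out.sort(key=lambda r: (-r.score_range[1], r.species))
    return out


@dataclass(frozen=True)
class GenomeRecord:
    """Assembly metadata used to pick one genome to represent a species."""

    accession: str
    is_representative: bool = False
    taxonomy_ok: bool = True
    completeness: int = 0   # higher is better (e.g. 3 complete, 2 chromosome, 1 scaffold, 0 contig)
    n_contigs: int = 1


def select_representative(genomes: Sequence[GenomeRecord]) -> GenomeRecord:
    """Pick the genome representing a species.

    Lexicographic preference: flagged representative genome, then taxonomy
    check passed, then higher completeness, then fewer contigs; final
    deterministic tie-break by accession.
    """
    if not genomes:
        raise ValidationError("no genomes to select from")
    return min(
        genomes,
        key=lambda g: (
            not g.is_representative,
            not g.taxonomy_ok,
            -g.completeness,
            g.n_contigs,
            g.accession,
        ),
    )


# ---------------------------------------------------------------------------
# Partitioned alignment concatenation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartitionedAlignment:
    """Concatenated alignment with per-gene model partitions (1-based column ranges)."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]
    partitions: tuple[tuple[str, str, int, int], ...]  # (model, name, start, end)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def partition_text(self) -> str:
        """RAxML-style partition block: ``MODEL, name = start-end`` lines."""
        return "\n".join(f"{model}, {name} = {s}-{e}" for model, name, s, e in self.partitions)


def _check_rectangular(aln: dict[str, str], label: str) -> int:
    lengths = {len(s) for s in aln.values()}
    if len(lengths) > 1:
        raise ValidationError(f"alignment {label!r} is not rectangular")
    return lengths.pop() if lengths else 0


def concat_alignments(
    aln_a: dict[str, str],
    aln_b: dict[str, str],
    model_a: str = "JTT",
    model_b: str = "LG",
    name_a: str = "geneA",
    name_b: str = "geneB",
    strict: bool = False,
) -> PartitionedAlignment:
    """Concatenate two aligned matrices over their shared taxa.

    Columns are A's then B's; partitions name each gene's model.  Taxa order
    follows alignment A.  In strict mode the taxon sets must be identical;
    otherwise the intersection is used.
    """
    la = _check_rectangular(aln_a, name_a)
    lb = _check_rectangular(aln_b, name_b)
    set_a, set_b = set(aln_a), set(aln_b)
    if strict and set_a != set_b:
        missing = sorted(set_a ^ set_b)
        raise ValidationError(f"taxon sets differ in strict mode: {missing}")
    taxa = [t for t in aln_a if t in set_b]
    if not taxa:
        raise ValidationError("no shared taxa between the two alignments")
    rows = tuple(aln_a[t] + aln_b[t] for t in taxa)
    partitions = (
        (model_a, name_a, 1, la),
        (model_b, name_b, la + 1, la + lb),
    )
    return PartitionedAlignment(taxa=tuple(taxa), rows=rows, partitions=partitions)
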