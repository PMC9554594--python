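"""GC statistics, rank test, ortholog clusters and alignment concatenation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from conftest import brute_force_clusters
from rhizopipe.errors import DegenerateInputError, ValidationError
from rhizopipe.genomics import (
    GenomeRecord,
    GenomicRegion,
    OrthologHit,
    StrainRow,
    assign_clusters,
    concat_alignments,
    gc_content,
    gc_profile,
    gc_rank_test,
    region_length,
    score_similarity,
    select_best_hits,
    select_representative,
    species_summary,
)
from rhizopipe.synthetic import PlasmidSimConfig, gen_plasmid


def hit(query="iaaM", start=1, end=1000, contig="c1", strain="s1", species="Genus species",
        coverage=0.9, identity=0.9, subject=None):
    return OrthologHit(
        query=query, subject=subject or f"{strain}.{query}.{start}", strain=strain,
        species=species, contig=contig, start=start, end=end,
        coverage=coverage, identity=identity,
    )


# -- regions and GC ----------------------------------------------------------

def test_region_length_printed_coordinates():
    assert region_length(GenomicRegion("NC_010627.1", 528492, 542282)) == 13_791
    assert region_length(GenomicRegion("x", 7, 7)) == 1
    assert region_length(GenomicRegion("x", 10, 19)) == 10
    with pytest.raises(ValidationError):
        GenomicRegion("x", 20, 10)


def test_region_string_roundtrip_and_bed():
    r = GenomicRegion.from_string("NC_010627.1:528,492-542,282")
    assert (r.start, r.end) == (528492, 542282)
    assert r.to_bed() == ("NC_010627.1", 528491, 542282)


@pytest.mark.parametrize("seq,expected", [
    ("GGCC", 1.0),
    ("ATGCATGCAT", 0.4),
    ("ATGNNN", 1 / 3),
    ("atgc", 0.5),
])
def test_gc_content(seq, expected):
    assert gc_content(seq) == pytest.approx(expected)


def test_gc_content_degenerate():
    with pytest.raises(ValidationError):
        gc_content("")
    with pytest.raises(DegenerateInputError):
        gc_content("NNNN")


def test_gc_profile_hand_windows():
    windows = gc_profile("ATGCATGCAT", window_bp=4, step_bp=2)
    assert [(w.start, w.end) for w in windows] == [(1, 4), (3, 6), (5, 8), (7, 10)]
    assert [w.gc for w in windows] == [0.5, 0.5, 0.5, 0.5]
    assert all(w.gc == 1.0 for w in gc_profile("G" * 50, window_bp=10, step_bp=7))


@given(st.integers(1, 300), st.integers(1, 300), st.integers(1, 40))
def test_gc_profile_window_count_formula(L, window, step):
    if window > L:
        with pytest.raises(ValidationError):
            gc_profile("A" * L, window, step)
        return
    windows = gc_profile("A" * L, window, step)
    assert len(windows) == (L - window) // step + 1
    assert windows[-1].end <= L


# -- rank test ---------------------------------------------------------------

def test_rank_test_extreme_low_target():
    seq = "G" * 30_000 + "A" * 2_000 + "G" * 30_000
    target = GenomicRegion("x", 30_001, 32_000)
    res = gc_rank_test(seq, target, step_bp=400)
    assert res.rank == 1.0
    assert res.quantile == pytest.approx(1 / (res.n_windows + 1))
    assert res.target_gc == 0.0


def test_rank_test_on_default_synthetic_island():
    seq, island = gen_plasmid(PlasmidSimConfig(seed=5))
    res = gc_rank_test(seq, island)
    assert res.quantile <= 0.01
    assert res.windows_excluded > 0


def test_rank_test_requires_enough_windows():
    with pytest.raises(DegenerateInputError):
        gc_rank_test("ACGT" * 500, GenomicRegion("x", 1, 1000), step_bp=400)


def test_rank_test_null_quantile_uniform():
    """A homogeneous replicon gives a uniform quantile over seeds (KS p > 0.01)."""
    quantiles = []
    for seed in range(200):
        seq, _ = gen_plasmid(
            PlasmidSimConfig(length_bp=60_000, background_gc=0.6,
                             island_start_bp=None, seed=seed)
        )
        rng = np.random.default_rng(seed + 10_000)
        start = int(rng.integers(1, 60_000 - 4_500))
        target = GenomicRegion("x", start, start + 4_499)
        quantiles.append(gc_rank_test(seq, target).quantile)
    assert sps.kstest(quantiles, "uniform").pvalue > 0.01


# -- similarity and clusters -------------------------------------------------

@pytest.mark.parametrize("cov,ident,expected", [
    (1.0, 1.0, 1.0),
    (0.5, 0.3, 0.15),   # the search-threshold floor
    (0.8, 0.9, 0.72),
])
def test_score_similarity(cov, ident, expected):
    assert score_similarity(hit(coverage=cov, identity=ident)) == pytest.approx(expected)


def test_similarity_floor_within_search_thresholds(rng):
    covs = rng.uniform(0.5, 1.0, 200)
    idents = rng.uniform(0.3, 1.0, 200)
    sims = covs * idents
    assert sims.min() >= 0.15 and sims.max() <= 1.0


def test_assign_clusters_basic_pair():
    hits = [hit("iaaM", 1, 1000), hit("iaaH", 5001, 6000)]
    clusters = assign_clusters(hits)
    assert len(clusters) == 1
    assert clusters[0].queries == {"iaaM", "iaaH"}


def test_assign_clusters_requires_same_contig():
    hits = [hit("iaaM", 1, 1000, contig="c1"), hit("iaaH", 5001, 6000, contig="c2")]
    assert assign_clusters(hits) == []


def test_assign_clusters_distant_hits_split_and_discard():
    # iaaM, then nifA 700 kb downstream with iaaH adjacent: both runs incomplete
    hits = [
        hit("iaaM", 1, 1000),
        hit("nifA", 701_001, 702_000),
        hit("iaaH", 702_100, 703_000),
    ]
    assert assign_clusters(hits) == []


def test_assign_clusters_rejects_mixed_strains():
    with pytest.raises(ValidationError):
        assign_clusters([hit(strain="s1"), hit("iaaH", 2000, 3000, strain="s2")])


@given(st.integers(0, 5_000), st.integers(2, 12))
def test_assign_clusters_matches_bruteforce_runs(seed, n_hits):
    """Sweep clustering equals exhaustive maximal-run enumeration on small instances."""
    rng = np.random.default_rng(seed)
    genes = ["iaaM", "iaaH", "nifA", "nifH", "nodA"]
    hits = []
    for i in range(n_hits):
        start = int(rng.integers(1, 3_000_000))
        hits.append(
            hit(
                query=genes[int(rng.integers(0, 5))],
                start=start,
                end=start + int(rng.integers(100, 2_000)),
                contig=f"c{int(rng.integers(1, 3))}",
            )
        )
    def canon(members):
        return tuple((h.contig, h.start, h.end, h.query) for h in members)

    got = assign_clusters(hits, max_gap_bp=600_000, required=set())
    expected = brute_force_clusters(hits, 600_000)
    assert sorted(canon(c.hits) for c in got) == sorted(canon(m) for m in expected)


def test_select_best_hits_prefers_in_cluster():
    in_cluster_m = hit("iaaM", 1, 1000, coverage=0.8, identity=0.5)      # sim 0.40
    in_cluster_h = hit("iaaH", 2_000, 3_000, coverage=0.9, identity=0.9)
    lone_m = hit("iaaM", 2_000_000, 2_001_000, coverage=1.0, identity=0.9)  # sim 0.90
    hits = [in_cluster_m, in_cluster_h, lone_m]
    clusters = assign_clusters(hits)
    best = select_best_hits(hits, clusters)
    assert best["iaaM"] == in_cluster_m


def test_select_best_hits_global_max_when_unclustered():
    a = hit("nodA", 1, 1000, coverage=0.6, identity=1.0)        # 0.6
    b = hit("nodA", 900_000, 901_000, coverage=0.7, identity=1.0)  # 0.7
    best = select_best_hits([a, b], clusters=[])
    assert best["nodA"] == b
    assert "iaaM" not in best


def test_select_best_hits_deterministic_tiebreak():
    a = hit("nifH", 1, 1000, coverage=0.9, identity=0.8, subject="ACC_B")
    b = hit("nifH", 5000, 6000, coverage=0.8, identity=0.9, subject="ACC_C")  # same sim, higher identity
    c = hit("nifH", 9000, 9900, coverage=0.8, identity=0.9, subject="ACC_A")  # ties -> lower accession
    best = select_best_hits([a, b, c], clusters=[])
    assert best["nifH"] == c


# -- species summary and representatives -------------------------------------

def make_row(species, score, strain="s", **flags):
    genus = species.split()[0]
    return StrainRow(
        strain=strain, genus=genus, species=species,
        best_hits={"iaaM": hit(species=species, strain=strain)},
        max_cluster_score=score, **flags,
    )


def test_species_summary_ranges_and_order():
    rows = [
        make_row("Paraburkholderia phymatum", 2.0, "s1"),
        make_row("Paraburkholderia phymatum", 3.5, "s2"),
        make_row("Agrobacterium tumefaciens", 5.0, "s3"),
    ]
    out = species_summary(rows)
    assert [r.species for r in out] == ["Agrobacterium tumefaciens", "Paraburkholderia phymatum"]
    pb = out[1]
    assert pb.n_strains == 2
    assert pb.score_range == (2.0, 3.5)
    lo, hi = pb.similarity_range["iaaM"]
    assert lo <= hi


def test_species_summary_filters():
    rows = [
        make_row("Burkholderia sp.", 9.0, "u1"),
        make_row("Genus species", 1.0, "u2", contaminated=True),
        make_row("Genus speciesb", 1.0, "u3", is_assembly=False),
        make_row("Genus speciesc", 1.0, "u4", taxonomy_ok=False),
        make_row("Genus keptum", 1.0, "u5"),
    ]
    out = species_summary(rows)
    assert [r.species for r in out] == ["Genus keptum"]
    assert species_summary([]) == []


def test_select_representative_rules():
    rep = GenomeRecord("GCF_2", is_representative=True, n_contigs=120)
    other = GenomeRecord("GCF_1", completeness=3, n_contigs=1)
    assert select_representative([other, rep]) == rep
    a = GenomeRecord("GCF_A", n_contigs=120)
    b = GenomeRecord("GCF_B", n_contigs=3)
    assert select_representative([a, b]) == b
    assert select_representative([a]) == a
    with pytest.raises(ValidationError):
        select_representative([])


# -- alignment concatenation -------------------------------------------------

def test_concat_alignments_partitions():
    aln_m = {"t1": "MKLV" * 2 + "MK", "t2": "MKIV" * 2 + "ML", "t3": "MKLV" * 2 + "MM"}
    aln_h = {"t1": "ADEFGHI", "t2": "ADEFGHV", "t3": "ADEYGHI"}
    out = concat_alignments(aln_m, aln_h, model_a="JTT", model_b="LG",
                            name_a="iaaM", name_b="iaaH")
    assert out.taxa == ("t1", "t2", "t3")
    assert out.n_columns == 17
    assert out.partitions == (("JTT", "iaaM", 1, 10), ("LG", "iaaH", 11, 17))
    assert out.partition_text().splitlines() == ["JTT, iaaM = 1-10", "LG, iaaH = 11-17"]


def test_concat_alignments_taxon_handling():
    aln_a = {"t1": "AAAA", "t2": "CCCC"}
    aln_b = {"t1": "GG"}
    out = concat_alignments(aln_a, aln_b)
    assert out.taxa == ("t1",)
    with pytest.raises(ValidationError):
        concat_alignments(aln_a, aln_b, strict=True)
    with pytest.raises(ValidationError):
        concat_alignments({"t1": "AA", "t2": "A"}, aln_b)
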