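"""Readers and writers for the pipeline's plain-text interfaces.

Formats and conventions:

* nodule tables — CSV ``plant,root,root_type,position_mm,area_mm2,circularity``,
  positions in mm from the root--shoot junction;
* sequences — FASTA wrapped at 60 columns (Biopython); regions as BED
  (0-based half-open) or NCBI-style 1-based inclusive strings;
* ortholog hits — TSV ``query,subject,strain,species,contig,start,end,
  coverage,identity`` with 1-based inclusive coordinates;
* ion tables — CSV ``mz,<sample columns...>`` plus a ``sample,group`` map CSV
  and a ``name,formula`` compound CSV;
* nodulation windows — CSV ``class,start_mm,end_mm,n`` and BED-like intervals.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError
from .genomics import GenomicRegion, OrthologHit
from .ions import CompoundRef, IonRecord
from .spatial import NodulationWindow, NoduleObservation, Plant, Root, RootSystemSet

__all__ = [
    "write_nodule_csv",
    "read_nodule_csv",
    "rootset_from_frame",
    "write_fasta",
    "read_fasta",
    "extract_region",
    "region_from_locus_tags",
    "write_region_bed",
    "write_hits_tsv",
    "read_hits_tsv",
    "write_windows_csv",
    "write_ion_csv",
    "read_ion_csv",
    "read_compound_csv",
    "read_sample_map",
]

NODULE_COLUMNS = ["plant", "root", "root_type", "position_mm", "area_mm2", "circularity"]
HIT_COLUMNS = [
    "query", "subject", "strain", "species", "contig", "start", "end", "coverage", "identity",
]


# -- nodule tables -----------------------------------------------------------

def write_nodule_csv(root_set: RootSystemSet, path: str | os.PathLike) -> None:
    rows = [
        {
            "plant": n.plant,
            "root": n.root,
            "root_type": n.root_type,
            "position_mm": n.position_mm,
            "area_mm2": n.area_mm2,
            "circularity": n.circularity,
        }
        for r in root_set.iter_roots()
        for n in r.nodules
    ]
    pd.DataFrame(rows, columns=NODULE_COLUMNS).to_csv(path, index=False)


def read_nodule_csv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("plant", "root", "position_mm") if c not in df.columns]
    if missing:
        raise ValidationError(f"nodule CSV missing required columns: {missing}")
    return df


def rootset_from_frame(
    df: pd.DataFrame, strain: str = "unknown", root_length_mm: float | None = None
) -> RootSystemSet:
    """Rebuild a RootSystemSet from a nodule table.

    Root lengths are not part of the table; they default to the largest
    position on the root (or ``root_length_mm`` when given).
    """
    plants: dict[str, Plant] = {}
    for (plant_id, root_id), sub in df.groupby(["plant", "root"], sort=True):
        plant = plants.setdefault(str(plant_id), Plant(name=str(plant_id)))
        rtype = str(sub["root_type"].iloc[0]) if "root_type" in sub else "tap"
        length = root_length_mm or max(float(sub["position_mm"].max()), 1.0)
        root = Root(name=str(root_id), root_type=rtype, length_mm=length)
        for _, row in sub.iterrows():
            root.nodules.append(
                NoduleObservation(
                    plant=str(plant_id),
                    root=str(root_id),
                    root_type=rtype,
                    position_mm=float(row["position_mm"]),
                    area_mm2=None if pd.isna(row.get("area_mm2")) else float(row["area_mm2"]),
                    circularity=None
                    if pd.isna(row.get("circularity"))
                    else float(row["circularity"]),
                )
            )
        plant.roots.append(root)
    return RootSystemSet(strain=strain, plants=list(plants.values()))


# -- sequences ---------------------------------------------------------------

def write_fasta(seq: str, path: str | os.PathLike, seq_id: str = "synthetic_plasmid") -> None:
    record = SeqRecord(Seq(seq), id=seq_id, description="")
    SeqIO.write([record], os.fspath(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(os.fspath(path), "fasta")}


def extract_region(seq: str, region: GenomicRegion) -> str:
    """Subsequence at 1-based inclusive coordinates."""
    if region.end > len(seq):
        raise ValidationError("region extends beyond the sequence")
    return seq[region.start - 1: region.end]


def region_from_locus_tags(genbank_path: str | os.PathLike, tags: Sequence[str]) -> GenomicRegion:
    """Span covering the named locus tags of a GenBank record (1-based inclusive)."""
    record = next(SeqIO.parse(os.fspath(genbank_path), "genbank"))
    wanted = set(tags)
    spans = []
    for feat in record.features:
        locus = feat.qualifiers.get("locus_tag", [None])[0]
        if locus in wanted:
            spans.append((int(feat.location.start) + 1, int(feat.location.end)))
    if not spans:
        raise ValidationError(f"no features with locus tags {sorted(wanted)}")
    return GenomicRegion(
        seq_id=record.id, start=min(s for s, _ in spans), end=max(e for _, e in spans)
    )


def write_region_bed(regions: Iterable[GenomicRegion], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in regions:
            seq_id, start0, end0 = r.to_bed()
            fh.write(f"{seq_id}\t{start0}\t{end0}\n")


# -- ortholog hits -----------------------------------------------------------

def write_hits_tsv(hits: Iterable[OrthologHit], path: str | os.PathLike) -> None:
    rows = [
        {c: getattr(h, c) for c in HIT_COLUMNS}
        for h in hits
    ]
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str | os.PathLike) -> list[OrthologHit]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"hit TSV missing columns: {missing}")
    return [
        OrthologHit(
            query=str(r["query"]),
            subject=str(r["subject"]),
            strain=str(r["strain"]),
            species=str(r["species"]),
            contig=str(r["contig"]),
            start=int(r["start"]),
            end=int(r["end"]),
            coverage=float(r["coverage"]),
            identity=float(r["identity"]),
        )
        for _, r in df.iterrows()
    ]


# -- windows -----------------------------------------------------------------

def write_windows_csv(windows: Iterable[NodulationWindow], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [
            {
                "class": w.class_index,
                "start_mm": w.start_mm,
                "end_mm": w.end_mm,
                "n": w.n_nodules,
            }
            for w in windows
        ]
    ).to_csv(path, index=False)


# -- ions --------------------------------------------------------------------

def write_ion_csv(ions: Sequence[IonRecord], path: str | os.PathLike) -> None:
    if not ions:
        raise ValidationError("no ions to write")
    samples = ions[0].samples
    rows = []
    for ion in ions:
        if ion.samples != samples:
            raise ValidationError("all ions must share the same sample columns")
        rows.append({"mz": ion.mz, **dict(zip(samples, ion.intensities))})
    pd.DataFrame(rows, columns=["mz", *samples]).to_csv(path, index=False)


def read_ion_csv(path: str | os.PathLike) -> list[IonRecord]:
    df = pd.read_csv(path)
    if "mz" not in df.columns:
        raise ValidationError("ion CSV must have an 'mz' column")
    samples = tuple(c for c in df.columns if c != "mz")
    return [
        IonRecord(
            mz=float(r["mz"]),
            intensities=tuple(float(r[s]) for s in samples),
            samples=samples,
        )
        for _, r in df.iterrows()
    ]


def read_compound_csv(path: str | os.PathLike) -> list[CompoundRef]:
    df = pd.read_csv(path)
    for col in ("name", "formula"):
        if col not in df.columns:
            raise ValidationError(f"compound CSV must have a {col!r} column")
    return [CompoundRef(name=str(r["name"]), formula=str(r["formula"])) for _, r in df.iterrows()]


def read_sample_map(path: str | os.PathLike) -> dict[str, str]:
    df = pd.read_csv(path)
    for col in ("sample", "group"):
        if col not in df.columns:
            raise ValidationError(f"sample map CSV must have a {col!r} column")
    return dict(zip(df["sample"].astype(str), df["group"].astype(str)))
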