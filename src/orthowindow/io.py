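"""File I/O: FASTA, GTF, bedGraph, BED, and the pipeline's TSV artifacts.

Genomic coordinates are 0-based half-open in memory and in bedGraph/BED;
GTF records are written and read as 1-based inclusive. Floating-point
fields are serialized at 6 significant digits so re-running a stage on
unchanged inputs reproduces its outputs byte for byte.
"""
from __future__ import annotations

import os
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .coverage import DepthTrack
from .models import (
    ComparableAnnotation,
    ComparableWindow,
    ExonModel,
    FormatError,
    GenomicWindow,
    PairAnnotation,
    PairwiseAlignment,
)

FLOAT_FMT = "%.6g"


def fmt_float(x: float) -> str:
    return FLOAT_FMT % x


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_alignment_fasta(path: str | os.PathLike, pair_id: str | None = None) -> PairwiseAlignment:
    """Read a 2-record aligned FASTA as a pairwise alignment.

    Record order defines species a/b. '.' gap characters are normalized
    to '-'. Raises FormatError for anything but 2 equal-length records or
    for an all-gap column.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise FormatError(f"{path}: expected exactly 2 records, found {len(records)}")
    rows = [str(r.seq).upper().replace(".", "-") for r in records]
    if len(rows[0]) != len(rows[1]):
        raise FormatError(
            f"{path}: rows '{records[0].id}' and '{records[1].id}' have unequal "
            f"lengths ({len(rows[0])} vs {len(rows[1])})"
        )
    return PairwiseAlignment(pair_id=pair_id or str(path), row_a=rows[0], row_b=rows[1])


def write_fasta(path: str | os.PathLike, records: Sequence[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------- pairs TSV

def read_pairs_tsv(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Two-column (gene_a, gene_b) ortholog list; '#' comment lines skipped."""
    pairs = []
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{ln}: expected 2 tab-separated columns")
            a, b = fields[0], fields[1]
            if a in seen_a or b in seen_b:
                raise FormatError(f"{path}:{ln}: gene appears in more than one pair (not 1:1)")
            seen_a.add(a)
            seen_b.add(b)
            pairs.append((a, b))
    return pairs


# ---------------------------------------------------------------- GTF

def read_exon_models_gtf(path: str | os.PathLike) -> dict[str, ExonModel]:
    """Parse exon records of a GTF/GFF into per-gene exon models."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_gene: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        gene_ids = feat.attributes.get("gene_id")
        if not gene_ids:
            raise FormatError(f"{path}: exon at {feat.seqid}:{feat.start} lacks gene_id")
        gid = gene_ids[0]
        entry = per_gene.setdefault(gid, {"chrom": feat.seqid, "strand": feat.strand, "exons": []})
        if entry["chrom"] != feat.seqid or entry["strand"] != feat.strand:
            raise FormatError(f"{path}: gene {gid} spans chromosomes or strands")
        entry["exons"].append((feat.start - 1, feat.end))  # GTF 1-based inclusive -> half-open
    models = {}
    for gid, entry in per_gene.items():
        models[gid] = ExonModel(
            gene_id=gid,
            chrom=entry["chrom"],
            strand=entry["strand"],
            exons=tuple(sorted(entry["exons"])),
        )
    return models


def write_annotation_gtf(annotation: ComparableAnnotation, which: str, path: str | os.PathLike) -> None:
    """Write one species' comparable windows as a GTF (one record per segment)."""
    attr_gene = "gene_a" if which == "a" else "gene_b"
    win_attr = "genomic_a" if which == "a" else "genomic_b"
    with open(path, "w") as fh:
        for pid in sorted(annotation.pairs):
            pann = annotation.pairs[pid]
            gene = getattr(pann, attr_gene)
            for w in sorted(pann.windows, key=lambda w: w.window_index):
                gw: GenomicWindow = getattr(w, win_attr)
                for s, e in gw.segments:
                    attrs = (
                        f'gene_id "{gene}"; transcript_id "{gene}.cmp"; '
                        f'window_id "{w.window_index}";'
                    )
                    fh.write(
                        f"{gw.chrom}\torthowindow\texon\t{s + 1}\t{e}\t.\t{gw.strand}\t.\t{attrs}\n"
                    )


# ------------------------------------------------------ windows TSV (annotation)

def _fmt_segments(segments: Iterable[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in segments)


def _parse_segments(text: str) -> tuple[tuple[int, int], ...]:
    out = []
    for part in text.split(";"):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return tuple(out)


WINDOWS_COLUMNS = [
    "pair_id", "gene_a", "gene_b", "window_index", "identity", "gap_cols",
    "chrom_a", "strand_a", "segments_a", "chrom_b", "strand_b", "segments_b",
]


def write_windows_tsv(annotation: ComparableAnnotation, path: str | os.PathLike) -> None:
    """Serialize the full paired annotation as the canonical windows TSV."""
    with open(path, "w") as fh:
        fh.write("# species_a=%s\tspecies_b=%s\n" % (annotation.species_a, annotation.species_b))
        fh.write("\t".join(WINDOWS_COLUMNS) + "\n")
        for pid in sorted(annotation.pairs):
            pann = annotation.pairs[pid]
            for w in sorted(pann.windows, key=lambda w: w.window_index):
                fh.write(
                    "\t".join(
                        [
                            pid, pann.gene_a, pann.gene_b, str(w.window_index),
                            fmt_float(w.identity), str(w.n_gap_cols),
                            w.genomic_a.chrom, w.genomic_a.strand, _fmt_segments(w.genomic_a.segments),
                            w.genomic_b.chrom, w.genomic_b.strand, _fmt_segments(w.genomic_b.segments),
                        ]
                    )
                    + "\n"
                )


def read_windows_tsv(path: str | os.PathLike) -> ComparableAnnotation:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise FormatError(f"{path}: missing species header line")
        meta = dict(kv.split("=") for kv in header[1:].strip().split("\t"))
        ann = ComparableAnnotation(species_a=meta["species_a"], species_b=meta["species_b"])
        cols = fh.readline().rstrip("\n").split("\t")
        if cols != WINDOWS_COLUMNS:
            raise FormatError(f"{path}: unexpected columns {cols}")
        for ln, line in enumerate(fh, 3):
            if not line.strip():
                continue
            f = dict(zip(WINDOWS_COLUMNS, line.rstrip("\n").split("\t")))
            pid = f["pair_id"]
            pann = ann.pairs.setdefault(
                pid, PairAnnotation(pair_id=pid, gene_a=f["gene_a"], gene_b=f["gene_b"])
            )
            j = int(f["window_index"])
            pann.windows.append(
                ComparableWindow(
                    window_index=j,
                    identity=float(f["identity"]),
                    n_gap_cols=int(f["gap_cols"]),
                    genomic_a=GenomicWindow(
                        pair_id=pid, window_index=j, species=ann.species_a,
                        gene_id=f["gene_a"], chrom=f["chrom_a"], strand=f["strand_a"],
                        segments=_parse_segments(f["segments_a"]),
                    ),
                    genomic_b=GenomicWindow(
                        pair_id=pid, window_index=j, species=ann.species_b,
                        gene_id=f["gene_b"], chrom=f["chrom_b"], strand=f["strand_b"],
                        segments=_parse_segments(f["segments_b"]),
                    ),
                )
            )
    return ann


# ---------------------------------------------------------------- bedGraph

def read_bedgraph(path: str | os.PathLike, sample_id: str, species: str) -> DepthTrack:
    """Read a bedGraph depth track (0-based half-open intervals).

    Track definition lines and comments are skipped; overlapping
    intervals, negative depth, and malformed lines raise FormatError with
    the line number.
    """
    intervals = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{ln}: expected 4 columns, got {len(fields)}")
            try:
                chrom, start, end, depth = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as err:
                raise FormatError(f"{path}:{ln}: {err}") from err
            if depth < 0:
                raise FormatError(f"{path}:{ln}: negative depth {depth}")
            if start >= end:
                raise FormatError(f"{path}:{ln}: empty or inverted interval [{start},{end})")
            intervals.append((chrom, start, end, depth))
    try:
        return DepthTrack.from_intervals(sample_id, species, intervals)
    except FormatError as err:
        raise FormatError(f"{path}: {err}") from err


def write_bedgraph(path: str | os.PathLike, intervals: Sequence[tuple[str, int, int, float]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, depth in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{fmt_float(depth)}\n")


# ---------------------------------------------------------------- BED fragments

def read_fragments_bed(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    """Read fragment intervals from a BED file (first 3 columns used)."""
    frags = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{ln}: expected >=3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as err:
                raise FormatError(f"{path}:{ln}: {err}") from err
            if start >= end:
                raise FormatError(f"{path}:{ln}: empty or inverted interval [{start},{end})")
            frags.append((chrom, start, end))
    return frags


# ---------------------------------------------------------------- sample sheets

def read_samples_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Sample sheet: sample_id, species, path (tab-separated with header)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "species", "path"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    base = os.path.dirname(os.path.abspath(path))
    df["path"] = [p if os.path.isabs(p) else os.path.join(base, p) for p in df["path"]]
    return df
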