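"""Stage functions chaining windows -> coverage -> filter -> quantify.

These are the library-level entry points behind the CLI sub-commands;
each consumes and produces the pipeline's file artifacts or their
in-memory equivalents.
"""
from __future__ import annotations

import glob
import logging
import os
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from . import io as owio
from .align import align_pair
from .concordance import (
    classify_all,
    concordance_report,
    finalize_annotation,
)
from .coverage import DepthTrack, coverage_table, profiles_from_coverage_table
from .models import (
    ComparableAnnotation,
    ConfigurationError,
    FilterConfig,
    GeneConcordance,
    InvalidInputError,
    OrthologPair,
)
from .quantify import CountMatrix, NormFactors, count_fragments, cpm, de_table, fpkm, tmm_factors
from .windows import build_annotation

log = logging.getLogger("orthowindow")


def _index_alignment_dir(aln_dir: str) -> dict[tuple[str, str], str]:
    """Map (first record id, second record id) -> aligned FASTA path."""
    index = {}
    for path in sorted(glob.glob(os.path.join(aln_dir, "*.fa*"))):
        ids = [rec.id for rec in SeqIO.parse(path, "fasta")]
        if len(ids) == 2:
            index[(ids[0], ids[1])] = path
    return index


def stage_windows(
    pairs_tsv: str,
    gtf_a: str,
    gtf_b: str,
    species_a: str,
    species_b: str,
    aln_dir: str | None = None,
    fasta_a: str | None = None,
    fasta_b: str | None = None,
    config: FilterConfig | None = None,
) -> tuple[ComparableAnnotation, dict[str, str]]:
    """Build the pre-filter comparable annotation from pipeline inputs.

    Alignments are looked up in ``aln_dir`` by the two record ids; pairs
    without a precomputed alignment are aligned internally when transcript
    FASTAs are supplied, otherwise excluded with reason ``no_alignment``.
    """
    config = config or FilterConfig()
    gene_pairs = owio.read_pairs_tsv(pairs_tsv)
    models_a = owio.read_exon_models_gtf(gtf_a)
    models_b = owio.read_exon_models_gtf(gtf_b)
    aln_index = _index_alignment_dir(aln_dir) if aln_dir else {}
    seqs_a = owio.read_fasta(fasta_a) if fasta_a else {}
    seqs_b = owio.read_fasta(fasta_b) if fasta_b else {}

    pairs, alignments = [], {}
    pre_excluded: dict[str, str] = {}
    for gene_a, gene_b in gene_pairs:
        pid = f"{gene_a}__{gene_b}"
        if gene_a not in models_a or gene_b not in models_b:
            pre_excluded[pid] = "missing_exon_model"
            continue
        aln_path = aln_index.get((gene_a, gene_b))
        if aln_path is not None:
            aln = owio.read_alignment_fasta(aln_path, pair_id=pid)
        elif gene_a in seqs_a and gene_b in seqs_b:
            aln = align_pair(seqs_a[gene_a], seqs_b[gene_b], pair_id=pid)
        else:
            pre_excluded[pid] = "no_alignment"
            continue
        sa = aln.ungapped(aln.row_a)
        sb = aln.ungapped(aln.row_b)
        try:
            pairs.append(
                OrthologPair(
                    pair_id=pid,
                    species_a=species_a, gene_a=gene_a, sequence_a=sa,
                    exon_model_a=models_a[gene_a],
                    species_b=species_b, gene_b=gene_b, sequence_b=sb,
                    exon_model_b=models_b[gene_b],
                )
            )
            alignments[pid] = aln
        except InvalidInputError as err:
            pre_excluded[pid] = f"inconsistent({err})"
    if not pairs:
        raise InvalidInputError("no usable ortholog pairs")
    annotation, excluded = build_annotation(pairs, alignments, config)
    excluded.update(pre_excluded)
    log.info(
        "windows: %d pairs in, %d annotated, %d excluded",
        len(gene_pairs), len(annotation.pairs), len(excluded),
    )
    return annotation, excluded


def load_depth_tracks(samples: pd.DataFrame) -> list[DepthTrack]:
    return [
        owio.read_bedgraph(row["path"], row["sample_id"], row["species"])
        for _, row in samples.iterrows()
    ]


def stage_coverage(annotation: ComparableAnnotation, samples: pd.DataFrame) -> pd.DataFrame:
    tracks = load_depth_tracks(samples)
    table = coverage_table(annotation, tracks)
    log.info("coverage: %d samples, %d window x sample rows", len(tracks), len(table))
    return table


def stage_filter(
    annotation: ComparableAnnotation,
    coverage: pd.DataFrame,
    config: FilterConfig | None = None,
) -> tuple[dict[str, GeneConcordance], ComparableAnnotation, pd.DataFrame]:
    config = config or FilterConfig()
    profiles = profiles_from_coverage_table(
        coverage, annotation.species_a, annotation.species_b
    )
    concordances = classify_all(profiles, annotation, config)
    final = finalize_annotation(annotation, concordances)
    report = concordance_report(concordances)
    tallies = report["decision"].value_counts().to_dict()
    log.info("filter: %s", ", ".join(f"{k}={v}" for k, v in sorted(tallies.items())))
    return concordances, final, report


def stage_quantify(
    annotation: ComparableAnnotation, samples: pd.DataFrame
) -> CountMatrix:
    frags = {
        row["sample_id"]: owio.read_fragments_bed(row["path"])
        for _, row in samples.iterrows()
    }
    species = dict(zip(samples["sample_id"], samples["species"]))
    matrix = count_fragments(frags, species, annotation)
    log.info(
        "quantify: %d genes, %d samples, %d fragments assigned",
        matrix.counts.shape[0], matrix.counts.shape[1], int(matrix.tallies["assigned"].sum()),
    )
    return matrix


@dataclass
class NormalizedExpression:
    factors: NormFactors
    cpm: pd.DataFrame
    fpkm: pd.DataFrame


def stage_normalize(matrix: CountMatrix, ref_sample: str | None = None) -> NormalizedExpression:
    factors = tmm_factors(matrix.counts, ref_sample=ref_sample)
    return NormalizedExpression(
        factors=factors, cpm=cpm(matrix, factors), fpkm=fpkm(matrix, factors)
    )


@dataclass
class PipelineResult:
    annotation: ComparableAnnotation
    concordances: dict[str, GeneConcordance]
    final_annotation: ComparableAnnotation
    report: pd.DataFrame
    matrix: CountMatrix
    normalized: NormalizedExpression
    de: pd.DataFrame


def run_fixture_pipeline(
    dataset_dir: str,
    species_a: str,
    species_b: str,
    config: FilterConfig | None = None,
) -> PipelineResult:
    """Run the full chain on a fixture-style dataset directory."""
    config = config or FilterConfig()
    d = dataset_dir
    annotation = owio.read_windows_tsv(os.path.join(d, "windows.tsv"))
    cov_samples = owio.read_samples_tsv(os.path.join(d, "samples_coverage.tsv"))
    coverage = stage_coverage(annotation, cov_samples)
    concordances, final, report = stage_filter(annotation, coverage, config)
    frag_samples = owio.read_samples_tsv(os.path.join(d, "samples_fragments.tsv"))
    matrix = stage_quantify(final, frag_samples)
    normalized = stage_normalize(matrix)
    de = de_table(matrix, normalized.factors, species_a, species_b)
    return PipelineResult(
        annotation=annotation, concordances=concordances, final_annotation=final,
        report=report, matrix=matrix, normalized=normalized, de=de,
    )
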