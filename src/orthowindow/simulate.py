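"""Seed-reproducible synthetic data: diverged ortholog pairs, exon models,
replicate coverage tracks, and fragment sets with ground-truth labels.

The generator emulates the data regime the comparability method assumes:
transcript pairs diverged by substitutions and short indels from a common
ancestor; per-gene coverage profiles that are highly correlated between
replicates of one species and linearly related between species for
concordant genes; per-gene species fold changes; and, for a fraction of
windows, a one-species coverage distortion that the robust-line outlier
screen should catch.

Each gene draws from its own RNG stream derived from ``(seed, gene
index)``, so per-gene results are stable when ``n_genes`` changes, and an
identical config + seed reproduces the fixture directory byte for byte.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import io as owio
from .models import (
    ComparableAnnotation,
    ExonModel,
    FilterConfig,
    InvalidInputError,
    OrthologPair,
    PairAnnotation,
    PairwiseAlignment,
)
from .windows import build_annotation

BASES = np.array(list("ACGT"))
MIN_EXON_LEN = 30


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic dataset.

    Defaults model a rodent-scale comparison: ~10% substitution
    divergence, rare short indels, 3 replicate libraries per species,
    lognormal coverage noise of sigma 0.2 on the log scale, and per-gene
    species log2 fold changes drawn from {-2, 0, +2}.
    """

    n_genes: int = 300
    ancestor_length_range: tuple[int, int] = (500, 3000)
    n_exons_range: tuple[int, int] = (1, 6)
    substitution_rate: float = 0.10
    indel_rate: float = 0.005
    indel_length_geometric_p: float = 0.5
    n_replicates: int = 3
    depth_mean: float = 50.0
    noise_sigma_log: float = 0.2
    profile_sigma_log: float = 1.0
    fraction_discordant: float = 1.0 / 3.0
    log2fc_choices: tuple[float, ...] = (-2.0, 0.0, 2.0)
    bias_window_fraction: float = 0.05
    bias_factor: float = 5.0
    mean_fragments: float = 100.0
    abundance_sigma_log: float = 0.5
    fragment_length: int = 100
    species_a: str = "spalax"
    species_b: str = "rat"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "indel_rate", "fraction_discordant",
                     "bias_window_fraction", "indel_length_geometric_p"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidInputError(f"{name} must be in [0, 1], got {v}")
        if self.ancestor_length_range[0] < 2 * MIN_EXON_LEN:
            raise InvalidInputError("ancestor length must allow at least one exon")
        if self.n_genes < 0 or self.n_replicates < 1:
            raise InvalidInputError("n_genes >= 0 and n_replicates >= 1 required")


@dataclass
class GeneTruth:
    pair_id: str
    gene_a: str
    gene_b: str
    concordant: bool
    true_log2fc: float
    bias_windows: list[int] = field(default_factory=list)
    n_windows: int = 0
    mean_identity: float = float("nan")


def _gene_rng(config: SimConfig, gene_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), gene_index, stream])


def _evolve(ancestor: np.ndarray, rng: np.random.Generator, config: SimConfig):
    """Mutate one lineage: substitutions plus geometric-length indels.

    Returns (site characters, deleted mask, insertions before each site).
    """
    L = ancestor.size
    sites = ancestor.copy()
    sub_mask = rng.random(L) < config.substitution_rate
    for i in np.nonzero(sub_mask)[0]:
        choices = [b for b in "ACGT" if b != sites[i]]
        sites[i] = choices[rng.integers(0, 3)]
    deleted = np.zeros(L, dtype=bool)
    inserts = [""] * (L + 1)
    i = 0
    while i < L:
        if config.indel_rate > 0 and rng.random() < config.indel_rate:
            length = int(rng.geometric(config.indel_length_geometric_p))
            if rng.random() < 0.5:
                deleted[i : i + length] = True
                i += length
                continue
            inserts[i] += "".join(BASES[rng.integers(0, 4, size=length)])
        i += 1
    return sites, deleted, inserts


def _random_exon_model(
    gene_id: str, chrom: str, transcript_length: int, rng: np.random.Generator, config: SimConfig
) -> ExonModel:
    max_exons = max(1, transcript_length // MIN_EXON_LEN)
    lo, hi = config.n_exons_range
    n_exons = int(rng.integers(lo, min(hi, max_exons) + 1))
    extra = transcript_length - MIN_EXON_LEN * n_exons
    cuts = np.sort(rng.integers(0, extra + 1, size=n_exons - 1)) if n_exons > 1 else np.array([], int)
    parts = np.diff(np.concatenate([[0], cuts, [extra]])) + MIN_EXON_LEN
    pos = int(rng.integers(1000, 10000))
    exons = []
    for k, ln in enumerate(parts):
        exons.append((pos, pos + int(ln)))
        pos += int(ln)
        if k < len(parts) - 1:
            pos += int(rng.integers(100, 2001))  # intron
    strand = "+" if rng.random() < 0.5 else "-"
    return ExonModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=tuple(exons))


def simulate_ortholog_pair(
    config: SimConfig, rng: np.random.Generator, gene_index: int
) -> tuple[OrthologPair, PairwiseAlignment]:
    """One diverged ortholog pair plus its true column-level alignment."""
    lo, hi = config.ancestor_length_range
    L = int(rng.integers(lo, hi + 1))
    ancestor = BASES[rng.integers(0, 4, size=L)]
    sa, del_a, ins_a = _evolve(ancestor, rng, config)
    sb, del_b, ins_b = _evolve(ancestor, rng, config)
    row_a: list[str] = []
    row_b: list[str] = []
    for i in range(L + 1):
        for c in ins_a[i]:
            row_a.append(c)
            row_b.append("-")
        for c in ins_b[i]:
            row_a.append("-")
            row_b.append(c)
        if i < L:
            ca = "-" if del_a[i] else sa[i]
            cb = "-" if del_b[i] else sb[i]
            if ca == "-" and cb == "-":
                continue
            row_a.append(ca)
            row_b.append(cb)
    seq_a = "".join(row_a).replace("-", "")
    seq_b = "".join(row_b).replace("-", "")
    if len(seq_a) < MIN_EXON_LEN or len(seq_b) < MIN_EXON_LEN:
        raise InvalidInputError(f"gene {gene_index}: deletions consumed the transcript")
    pid = f"pair{gene_index:04d}"
    gene_a = f"{config.species_a}_g{gene_index:04d}"
    gene_b = f"{config.species_b}_g{gene_index:04d}"
    pair = OrthologPair(
        pair_id=pid,
        species_a=config.species_a,
        gene_a=gene_a,
        sequence_a=seq_a,
        exon_model_a=_random_exon_model(
            gene_a, f"{config.species_a}_chr{gene_index:04d}", len(seq_a), rng, config
        ),
        species_b=config.species_b,
        gene_b=gene_b,
        sequence_b=seq_b,
        exon_model_b=_random_exon_model(
            gene_b, f"{config.species_b}_chr{gene_index:04d}", len(seq_b), rng, config
        ),
    )
    return pair, PairwiseAlignment(pair_id=pid, row_a="".join(row_a), row_b="".join(row_b))


def simulate_coverage(
    pann: PairAnnotation,
    truth: GeneTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> dict[tuple[str, int], list[tuple[str, int, int, float]]]:
    """Replicate depth intervals over one gene's comparable windows.

    Concordant genes share a latent lognormal window-weight profile across
    species (species a scaled by 2^log2fc); discordant genes draw
    independent profiles. Bias windows get a one-species multiplicative
    distortion. Returns (species, replicate) -> bedGraph-style intervals,
    and records chosen bias windows in ``truth``.
    """
    wins = sorted(pann.windows, key=lambda w: w.window_index)
    n_w = len(wins)
    w_latent = rng.lognormal(0.0, config.profile_sigma_log, size=n_w)
    if truth.concordant:
        weights_a = w_latent * 2.0 ** truth.true_log2fc
        weights_b = w_latent
        bias_mask = rng.random(n_w) < config.bias_window_fraction
    else:
        weights_a = rng.lognormal(0.0, config.profile_sigma_log, size=n_w)
        weights_b = w_latent
        bias_mask = np.zeros(n_w, dtype=bool)
    truth.bias_windows = [wins[i].window_index for i in np.nonzero(bias_mask)[0]]
    out: dict[tuple[str, int], list[tuple[str, int, int, float]]] = {}
    for species, weights, attr in (
        (config.species_a, weights_a, "genomic_a"),
        (config.species_b, weights_b, "genomic_b"),
    ):
        for rep in range(config.n_replicates):
            intervals = []
            noise = rng.lognormal(0.0, config.noise_sigma_log, size=n_w)
            for i, w in enumerate(wins):
                depth = config.depth_mean * weights[i] * noise[i]
                if species == config.species_a and bias_mask[i]:
                    depth *= config.bias_factor
                gw = getattr(w, attr)
                for s, e in gw.segments:
                    intervals.append((gw.chrom, s, e, depth))
            out[(species, rep)] = intervals
    return out


def simulate_fragments(
    pann: PairAnnotation,
    truth: GeneTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> dict[tuple[str, int], list[tuple[str, int, int]]]:
    """Poisson fragment sets over one gene's comparable windows.

    Per-gene base abundance is lognormal around ``mean_fragments``;
    species a is scaled by 2^log2fc. Each fragment starts uniformly
    within the comparable bases and is clipped to its segment.
    """
    base = float(rng.lognormal(np.log(config.mean_fragments), config.abundance_sigma_log))
    lam = {
        config.species_a: base * 2.0 ** truth.true_log2fc,
        config.species_b: base,
    }
    wins = sorted(pann.windows, key=lambda w: w.window_index)
    out: dict[tuple[str, int], list[tuple[str, int, int]]] = {}
    for species, attr in ((config.species_a, "genomic_a"), (config.species_b, "genomic_b")):
        segments = [seg for w in wins for seg in getattr(w, attr).segments]
        chrom = getattr(wins[0], attr).chrom if wins else ""
        seg_lens = np.array([e - s for s, e in segments], dtype=np.int64)
        cum = np.concatenate([[0], np.cumsum(seg_lens)])
        total = int(cum[-1])
        for rep in range(config.n_replicates):
            n_frag = int(rng.poisson(lam[species])) if total > 0 else 0
            frags = []
            for _ in range(n_frag):
                u = int(rng.integers(0, total))
                k = int(np.searchsorted(cum, u, side="right")) - 1
                s, e = segments[k]
                start = s + (u - int(cum[k]))
                frags.append((chrom, start, min(start + config.fragment_length, e)))
            out[(species, rep)] = frags
    return out


def make_fixture_dataset(
    config: SimConfig, outdir: str | os.PathLike, filter_config: FilterConfig | None = None
) -> tuple[ComparableAnnotation, pd.DataFrame]:
    """Write a complete, internally consistent fixture directory.

    Produces transcript FASTAs, true-alignment FASTAs, exon-model GTFs,
    the ortholog pairs TSV, per-replicate bedGraph and fragment BED files,
    coverage/fragment sample sheets, the windows TSV of the pre-filter
    annotation, and truth.tsv. Returns the annotation and truth table.
    """
    filter_config = filter_config or FilterConfig()
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    aln_dir = os.path.join(outdir, "aln")
    os.makedirs(aln_dir, exist_ok=True)

    pairs: list[OrthologPair] = []
    alignments: dict[str, PairwiseAlignment] = {}
    truths: dict[str, GeneTruth] = {}
    for g in range(config.n_genes):
        rng = _gene_rng(config, g, 0)
        pair, aln = simulate_ortholog_pair(config, rng, g)
        concordant = not (rng.random() < config.fraction_discordant)
        lfc = float(config.log2fc_choices[rng.integers(0, len(config.log2fc_choices))])
        pairs.append(pair)
        alignments[pair.pair_id] = aln
        truths[pair.pair_id] = GeneTruth(
            pair_id=pair.pair_id, gene_a=pair.gene_a, gene_b=pair.gene_b,
            concordant=concordant, true_log2fc=lfc if concordant else 0.0,
        )

    if pairs:
        annotation, _excluded = build_annotation(pairs, alignments, filter_config)
    else:
        annotation = ComparableAnnotation(config.species_a, config.species_b)

    for pair in pairs:
        pid = pair.pair_id
        if pid in annotation.pairs:
            pann = annotation.pairs[pid]
            truths[pid].n_windows = pann.n_windows
            truths[pid].mean_identity = float(
                np.mean([w.identity for w in pann.windows])
            )

    # Per-sample interval accumulators.
    cov: dict[tuple[str, int], list] = {
        (sp, r): []
        for sp in (config.species_a, config.species_b)
        for r in range(config.n_replicates)
    }
    frg: dict[tuple[str, int], list] = {k: [] for k in cov}
    for g, pair in enumerate(pairs):
        pid = pair.pair_id
        if pid not in annotation.pairs:
            continue
        pann = annotation.pairs[pid]
        gene_cov = simulate_coverage(pann, truths[pid], config, _gene_rng(config, g, 1))
        for key, intervals in gene_cov.items():
            cov[key].extend(intervals)
        gene_frg = simulate_fragments(pann, truths[pid], config, _gene_rng(config, g, 2))
        for key, frags in gene_frg.items():
            frg[key].extend(frags)

    owio.write_fasta(
        os.path.join(outdir, f"transcripts_{config.species_a}.fasta"),
        [(p.gene_a, p.sequence_a) for p in pairs],
    )
    owio.write_fasta(
        os.path.join(outdir, f"transcripts_{config.species_b}.fasta"),
        [(p.gene_b, p.sequence_b) for p in pairs],
    )
    for pair in pairs:
        owio.write_fasta(
            os.path.join(aln_dir, f"{pair.pair_id}.fasta"),
            [(pair.gene_a, alignments[pair.pair_id].row_a),
             (pair.gene_b, alignments[pair.pair_id].row_b)],
        )
    with open(os.path.join(outdir, "pairs.tsv"), "w") as fh:
        for pair in pairs:
            fh.write(f"{pair.gene_a}\t{pair.gene_b}\n")
    for which, species in (("a", config.species_a), ("b", config.species_b)):
        with open(os.path.join(outdir, f"exons_{species}.gtf"), "w") as fh:
            for pair in pairs:
                model = pair.exon_model_a if which == "a" else pair.exon_model_b
                for s, e in model.exons:
                    fh.write(
                        f"{model.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{model.strand}\t.\t"
                        f'gene_id "{model.gene_id}"; transcript_id "{model.gene_id}.t1";\n'
                    )
    cov_rows, frg_rows = [], []
    for (species, rep), intervals in sorted(cov.items()):
        sample = f"{species}_rep{rep}"
        path = f"cov_{sample}.bedGraph"
        owio.write_bedgraph(os.path.join(outdir, path), sorted(intervals))
        cov_rows.append((sample, species, path))
    for (species, rep), frags in sorted(frg.items()):
        sample = f"{species}_rep{rep}"
        path = f"frags_{sample}.bed"
        with open(os.path.join(outdir, path), "w") as fh:
            for chrom, s, e in sorted(frags):
                fh.write(f"{chrom}\t{s}\t{e}\n")
        frg_rows.append((sample, species, path))
    pd.DataFrame(cov_rows, columns=["sample_id", "species", "path"]).to_csv(
        os.path.join(outdir, "samples_coverage.tsv"), sep="\t", index=False
    )
    pd.DataFrame(frg_rows, columns=["sample_id", "species", "path"]).to_csv(
        os.path.join(outdir, "samples_fragments.tsv"), sep="\t", index=False
    )
    owio.write_windows_tsv(annotation, os.path.join(outdir, "windows.tsv"))
    truth_df = pd.DataFrame(
        [
            (t.pair_id, t.gene_a, t.gene_b, int(t.concordant),
             owio.fmt_float(t.true_log2fc), t.n_windows,
             ";".join(str(j) for j in t.bias_windows),
             owio.fmt_float(t.mean_identity) if t.mean_identity == t.mean_identity else "NA")
            for t in truths.values()
        ],
        columns=["pair_id", "gene_a", "gene_b", "concordant", "true_log2fc",
                 "n_windows", "bias_windows", "mean_identity"],
    )
    truth_df.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    return annotation, truth_df


def scaled_config(seed: int, **overrides) -> SimConfig:
    """Convenience: default study conditions with a seed and overrides."""
    return replace(SimConfig(seed=seed), **overrides)
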