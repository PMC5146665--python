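"""Fragment counting over comparable regions, TMM/CPM/FPKM, and DE calls.

Counting is union-mode: a fragment is assigned to a gene only if it
overlaps (>= 1 bp) retained windows of exactly that one gene; fragments
touching windows of two or more genes are discarded as ambiguous, and
fragments touching no window are unassigned. Because only comparable
regions are counted, cross-species counts refer to near-equal-length
annotations and can be normalized together with TMM.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .concordance import sign_test
from .models import (
    ComparableAnnotation,
    ConfigurationError,
    DegenerateDataError,
    InvalidInputError,
)


@dataclass
class CountMatrix:
    """Gene x sample fragment counts over comparable regions."""

    counts: pd.DataFrame              # index: pair_id, columns: sample_id, int
    sample_species: dict[str, str]
    comparable_length: pd.DataFrame   # index: pair_id, columns: species, bp
    tallies: pd.DataFrame             # per sample: assigned/ambiguous/unassigned


@dataclass
class NormFactors:
    """Per-sample library sizes and reference-relative TMM factors."""

    ref_sample: str
    library_size: pd.Series
    tmm_factor: pd.Series

    @property
    def effective_size(self) -> pd.Series:
        return self.library_size * self.tmm_factor


def _window_trees(annotation: ComparableAnnotation, species: str) -> dict[str, IntervalTree]:
    attr = "genomic_a" if species == annotation.species_a else "genomic_b"
    trees: dict[str, IntervalTree] = {}
    for pid, pann in annotation.pairs.items():
        for w in pann.windows:
            gw = getattr(w, attr)
            tree = trees.setdefault(gw.chrom, IntervalTree())
            for s, e in gw.segments:
                tree.addi(s, e, pid)
    return trees


def count_fragments(
    fragments_by_sample: dict[str, list[tuple[str, int, int]]],
    sample_species: dict[str, str],
    annotation: ComparableAnnotation,
) -> CountMatrix:
    """Union-mode fragment counting over the finalized annotation.

    ``fragments_by_sample``: sample_id -> list of (chrom, start, end)
    fragment intervals (paired mates pre-merged). Fragments on unknown
    chromosomes count as no-overlap with a warning.
    """
    pair_ids = sorted(annotation.pairs)
    species_seen = set(sample_species.values())
    unknown = species_seen - {annotation.species_a, annotation.species_b}
    if unknown:
        raise ConfigurationError(f"samples with unknown species {sorted(unknown)}")
    trees_cache = {
        sp: _window_trees(annotation, sp)
        for sp in (annotation.species_a, annotation.species_b)
        if sp in species_seen
    }
    counts = pd.DataFrame(0, index=pair_ids, columns=sorted(fragments_by_sample), dtype=int)
    tally_rows = []
    warned_chroms: set[str] = set()
    for sample_id in sorted(fragments_by_sample):
        trees = trees_cache[sample_species[sample_id]]
        assigned = ambiguous = unassigned = 0
        for chrom, start, end in fragments_by_sample[sample_id]:
            tree = trees.get(chrom)
            if tree is None:
                if chrom not in warned_chroms:
                    warnings.warn(f"chromosome {chrom!r} absent from annotation")
                    warned_chroms.add(chrom)
                unassigned += 1
                continue
            genes = {iv.data for iv in tree.overlap(start, end)}
            if len(genes) == 1:
                counts.loc[genes.pop(), sample_id] += 1
                assigned += 1
            elif len(genes) > 1:
                ambiguous += 1
            else:
                unassigned += 1
        tally_rows.append((sample_id, assigned, ambiguous, unassigned))
    lengths = pd.DataFrame(
        {
            annotation.species_a: [annotation.pairs[p].comparable_length("a") for p in pair_ids],
            annotation.species_b: [annotation.pairs[p].comparable_length("b") for p in pair_ids],
        },
        index=pair_ids,
    )
    tallies = pd.DataFrame(
        tally_rows, columns=["sample_id", "assigned", "ambiguous", "unassigned"]
    ).set_index("sample_id")
    return CountMatrix(
        counts=counts,
        sample_species=dict(sample_species),
        comparable_length=lengths,
        tallies=tallies,
    )


def _upper_quartile_reference(counts: pd.DataFrame) -> str:
    lib = counts.sum(axis=0)
    uq = pd.Series(
        {s: float(np.quantile(counts[s] / lib[s], 0.75)) for s in counts.columns}
    )
    return str((uq - uq.mean()).abs().idxmin())


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormFactors:
    """Trimmed mean of M-values normalization factors, reference-relative.

    For sample k against reference r, per-gene log ratios
    M_g = log2((y_gk/N_k)/(y_gr/N_r)) and average abundances
    A_g = 0.5 * log2((y_gk/N_k)(y_gr/N_r)) are computed over genes with
    nonzero counts in both samples, doubly trimmed by rank (trim_m each
    side on M, trim_a each side on A), and averaged with inverse
    approximate (delta-method binomial) variance weights; the factor is
    2 to that weighted mean. No gene-length term enters: both samples of
    a comparison count near-equal-length comparable regions.
    """
    if counts.shape[1] < 2:
        raise InvalidInputError("TMM needs at least 2 samples")
    if ref_sample is None:
        ref_sample = _upper_quartile_reference(counts)
    if ref_sample not in counts.columns:
        raise InvalidInputError(f"reference sample {ref_sample!r} not in matrix")
    lib = counts.sum(axis=0).astype(float)
    yr = counts[ref_sample].to_numpy(dtype=float)
    Nr = float(lib[ref_sample])
    factors = {}
    for sample in counts.columns:
        yk = counts[sample].to_numpy(dtype=float)
        Nk = float(lib[sample])
        both = (yk > 0) & (yr > 0)
        ykk, yrr = yk[both], yr[both]
        n = int(both.sum())
        if n == 0:
            warnings.warn(f"sample {sample}: no genes shared with reference; factor 1")
            factors[sample] = 1.0
            continue
        M = np.log2((ykk / Nk) / (yrr / Nr))
        A = 0.5 * np.log2((ykk / Nk) * (yrr / Nr))
        w = (Nk - ykk) / (Nk * ykk) + (Nr - yrr) / (Nr * yrr)
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rank_m = stats.rankdata(M)
        rank_a = stats.rankdata(A)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            warnings.warn(f"sample {sample}: all genes trimmed away; factor 1")
            factors[sample] = 1.0
            continue
        with np.errstate(divide="ignore"):
            inv_w = 1.0 / w[keep]
        finite = np.isfinite(inv_w)
        if not finite.any():
            factors[sample] = float(2.0 ** np.mean(M[keep]))
        else:
            factors[sample] = float(
                2.0 ** (np.sum(M[keep][finite] * inv_w[finite]) / np.sum(inv_w[finite]))
            )
    return NormFactors(
        ref_sample=ref_sample,
        library_size=lib,
        tmm_factor=pd.Series(factors)[counts.columns],
    )


def cpm(matrix: CountMatrix, factors: NormFactors) -> pd.DataFrame:
    """Counts per million effective library size."""
    eff = factors.effective_size
    if (eff <= 0).any():
        raise InvalidInputError("zero or negative effective library size")
    return matrix.counts.div(eff, axis=1) * 1e6


def fpkm(matrix: CountMatrix, factors: NormFactors) -> pd.DataFrame:
    """Fragments per kilobase of comparable region per million fragments.

    The per-gene length is the species' own comparable length (the two
    species differ by at most the gap allowance per window). FPKM is for
    display; cross-species DE should work from counts/CPM.
    """
    c = cpm(matrix, factors)
    out = {}
    for sample in c.columns:
        length = matrix.comparable_length[matrix.sample_species[sample]]
        out[sample] = c[sample] * 1e3 / length
    return pd.DataFrame(out)[c.columns]


def log2_fold_change(mean_a: float, mean_b: float, pseudocount: float = 0.5) -> float:
    """log2((mean_a + pc) / (mean_b + pc)); pc defaults to 0.5 CPM."""
    if pseudocount <= 0:
        raise InvalidInputError("pseudocount must be > 0")
    if mean_a < 0 or mean_b < 0:
        raise InvalidInputError("means must be >= 0")
    return float(np.log2((mean_a + pseudocount) / (mean_b + pseudocount)))


def de_table(
    matrix: CountMatrix,
    factors: NormFactors,
    species_a: str,
    species_b: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene mean CPM of each species and the species-a vs -b log2FC."""
    c = cpm(matrix, factors)
    samples_a = [s for s in c.columns if matrix.sample_species[s] == species_a]
    samples_b = [s for s in c.columns if matrix.sample_species[s] == species_b]
    if not samples_a or not samples_b:
        raise ConfigurationError("both species need at least one sample")
    mean_a = c[samples_a].mean(axis=1)
    mean_b = c[samples_b].mean(axis=1)
    lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    return pd.DataFrame({"mean_a": mean_a, "mean_b": mean_b, "log2fc": lfc})


def de_threshold_filter(
    records: pd.DataFrame, alpha: float = 0.05, log2fc_cutoff: float = 1.0
) -> pd.DataFrame:
    """Call up/down/ns at strict adjusted-p and fold-change cutoffs.

    ``records`` needs columns log2fc and adj_p; rows with missing adj_p
    are skipped (call NaN) with a warning.
    """
    if "adj_p" not in records.columns or "log2fc" not in records.columns:
        raise InvalidInputError("records need columns 'adj_p' and 'log2fc'")
    out = records.copy()
    missing = out["adj_p"].isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} records lack adj_p; skipped")
    call = pd.Series("ns", index=out.index)
    sig = ~missing & (out["adj_p"] < alpha)
    call[sig & (out["log2fc"] > log2fc_cutoff)] = "up"
    call[sig & (out["log2fc"] < -log2fc_cutoff)] = "down"
    call[missing] = np.nan
    out["call"] = call
    return out


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test (two-sided).

    Returns (t, Welch-Satterthwaite df, p). If both groups have zero
    variance: equal means give (0, n-2, 1); different means admit no
    finite statistic and raise DegenerateDataError (documented edge
    convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InvalidInputError("each group needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, float(x.size + y.size - 2), 1.0
        raise DegenerateDataError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def method_concordance(
    directions_1: list[str], directions_2: list[str]
) -> tuple[int, int, float]:
    """Sign-test agreement between two sets of DE direction calls.

    Returns (k agreeing, n, one-sided p that agreement this high arises
    when each call is a coin flip).
    """
    if len(directions_1) != len(directions_2):
        raise InvalidInputError("direction vectors differ in length")
    n = len(directions_1)
    if n == 0:
        raise InvalidInputError("no direction calls")
    k = sum(1 for d1, d2 in zip(directions_1, directions_2) if d1 == d2)
    return k, n, sign_test(k, n, "greater")
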