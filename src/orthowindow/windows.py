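"""Sub-alignment windowing, identity/gap filtering, and coordinate mapping.

Each pairwise transcript alignment is divided into fixed-length blocks of
consecutive columns (25 by default). Blocks that are well conserved —
identity strictly above 70% of the window length and strictly fewer than
3 gap columns — are kept and mapped through each species' exon model to
genomic segments. The paired per-window genomic footprints are the
"comparable regions" over which cross-species coverage and expression are
later compared.
"""
from __future__ import annotations

from .models import (
    GAP,
    AlignmentWindow,
    ComparableAnnotation,
    ComparableWindow,
    CoordinateError,
    ExonModel,
    FilterConfig,
    GenomicWindow,
    Interval,
    InvalidInputError,
    OrthologPair,
    PairAnnotation,
    PairwiseAlignment,
)


def window_stats(cols_a: str, cols_b: str) -> tuple[int, int, int, float]:
    """Match / mismatch / gap-column counts and identity of one window.

    A column is a gap column if either row holds the gap character. Base
    comparison is case-insensitive; N matches nothing. Identity is
    n_match over the full window length, so gap columns count against it.
    """
    n_match = n_mismatch = n_gap = 0
    for ca, cb in zip(cols_a.upper(), cols_b.upper()):
        if ca == GAP or cb == GAP:
            n_gap += 1
        elif ca == cb and ca != "N":
            n_match += 1
        else:
            n_mismatch += 1
    return n_match, n_mismatch, n_gap, n_match / len(cols_a)


def passes_window_filter(
    n_match: int, n_gap_cols: int, window_len: int, config: FilterConfig
) -> bool:
    """True iff identity > min_identity and gap columns < max_gap_cols (strict)."""
    identity = n_match / window_len
    return identity > config.min_identity and n_gap_cols < config.max_gap_cols


def window_to_transcript_coords(
    alignment: PairwiseAlignment, col_start: int, col_end: int
) -> tuple[Interval, Interval]:
    """Ungapped-sequence intervals covered by columns [col_start, col_end).

    For each row the interval is half-open in transcript coordinates; a row
    that is entirely gaps within the window yields an empty interval.
    """
    if not (0 <= col_start <= col_end <= alignment.n_columns):
        raise CoordinateError(
            f"columns [{col_start},{col_end}) outside alignment of "
            f"{alignment.n_columns} columns"
        )
    out = []
    for row in (alignment.row_a, alignment.row_b):
        before = col_start - row.count(GAP, 0, col_start)
        inside = (col_end - col_start) - row.count(GAP, col_start, col_end)
        out.append((before, before + inside))
    return out[0], out[1]


def window_alignment(
    alignment: PairwiseAlignment, window_len: int = 25
) -> list[AlignmentWindow]:
    """Tile the alignment into consecutive windows of ``window_len`` columns.

    Windows cover columns [0, w), [w, 2w), ...; a terminal partial window is
    dropped so every window has the same length and identities are
    comparable. Returns floor(n_columns / window_len) windows.
    """
    if window_len < 2:
        raise InvalidInputError("window_len must be >= 2")
    windows = []
    n_full = alignment.n_columns // window_len
    for j in range(n_full):
        c0, c1 = j * window_len, (j + 1) * window_len
        n_match, n_mismatch, n_gap, _ = window_stats(
            alignment.row_a[c0:c1], alignment.row_b[c0:c1]
        )
        tx_a, tx_b = window_to_transcript_coords(alignment, c0, c1)
        windows.append(
            AlignmentWindow(
                pair_id=alignment.pair_id,
                window_index=j,
                col_start=c0,
                col_end=c1,
                n_match=n_match,
                n_mismatch=n_mismatch,
                n_gap_cols=n_gap,
                tx_interval_a=tx_a,
                tx_interval_b=tx_b,
            )
        )
    return windows


def transcript_to_genomic(tx_interval: Interval, model: ExonModel) -> list[Interval]:
    """Map a transcript interval to ascending genomic segments.

    Transcript coordinates walk exons 5'->3': for strand '-' the first
    transcript base is the highest genomic coordinate of the last exon and
    positions run in reverse-complement orientation. An interval spanning
    an exon junction yields one segment per exon touched.
    """
    s, e = tx_interval
    T = model.transcript_length
    if not (0 <= s <= e <= T):
        raise CoordinateError(
            f"transcript interval [{s},{e}) outside [0,{T}) of gene {model.gene_id}"
        )
    if s == e:
        return []
    segments: list[Interval] = []
    exons = model.exons if model.strand == "+" else tuple(reversed(model.exons))
    tx_pos = 0
    for g0, g1 in exons:
        ex_len = g1 - g0
        lo = max(s, tx_pos)
        hi = min(e, tx_pos + ex_len)
        if lo < hi:
            if model.strand == "+":
                segments.append((g0 + (lo - tx_pos), g0 + (hi - tx_pos)))
            else:
                # tx offset k within this exon maps to genomic g1 - 1 - k
                segments.append((g1 - (hi - tx_pos), g1 - (lo - tx_pos)))
        tx_pos += ex_len
    segments.sort()
    return segments


def genomic_to_transcript(genomic_interval: Interval, model: ExonModel) -> Interval:
    """Inverse of :func:`transcript_to_genomic` for an interval inside one exon."""
    g0, g1 = genomic_interval
    tx_pos = 0
    exons = model.exons if model.strand == "+" else tuple(reversed(model.exons))
    for e0, e1 in exons:
        if e0 <= g0 and g1 <= e1:
            if model.strand == "+":
                return (tx_pos + (g0 - e0), tx_pos + (g1 - e0))
            return (tx_pos + (e1 - g1), tx_pos + (e1 - g0))
        tx_pos += e1 - e0
    raise CoordinateError(
        f"genomic interval [{g0},{g1}) not inside a single exon of {model.gene_id}"
    )


def build_comparable_windows(
    pair: OrthologPair,
    alignment: PairwiseAlignment,
    config: FilterConfig | None = None,
) -> list[ComparableWindow]:
    """Retained windows of one pair with genomic footprints in both species.

    Only windows passing the identity/gap filter are returned; window
    indices are identical across species and the per-window genomic length
    difference is bounded by the window's gap-column count.
    """
    config = config or FilterConfig()
    if alignment.ungapped(alignment.row_a).upper() != pair.sequence_a.upper():
        raise InvalidInputError(f"pair {pair.pair_id}: row_a does not match sequence_a")
    if alignment.ungapped(alignment.row_b).upper() != pair.sequence_b.upper():
        raise InvalidInputError(f"pair {pair.pair_id}: row_b does not match sequence_b")
    out = []
    for w in window_alignment(alignment, config.window_len):
        if not passes_window_filter(w.n_match, w.n_gap_cols, w.window_len, config):
            continue
        try:
            seg_a = transcript_to_genomic(w.tx_interval_a, pair.exon_model_a)
            seg_b = transcript_to_genomic(w.tx_interval_b, pair.exon_model_b)
        except CoordinateError as err:
            raise CoordinateError(f"pair {pair.pair_id}: {err}") from err
        out.append(
            ComparableWindow(
                window_index=w.window_index,
                identity=w.identity,
                n_gap_cols=w.n_gap_cols,
                genomic_a=GenomicWindow(
                    pair_id=pair.pair_id,
                    window_index=w.window_index,
                    species=pair.species_a,
                    gene_id=pair.gene_a,
                    chrom=pair.exon_model_a.chrom,
                    strand=pair.exon_model_a.strand,
                    segments=tuple(seg_a),
                ),
                genomic_b=GenomicWindow(
                    pair_id=pair.pair_id,
                    window_index=w.window_index,
                    species=pair.species_b,
                    gene_id=pair.gene_b,
                    chrom=pair.exon_model_b.chrom,
                    strand=pair.exon_model_b.strand,
                    segments=tuple(seg_b),
                ),
            )
        )
    return out


def build_annotation(
    pairs: list[OrthologPair],
    alignments: dict[str, PairwiseAlignment],
    config: FilterConfig | None = None,
) -> tuple[ComparableAnnotation, dict[str, str]]:
    """Assemble the comparable annotation over all pairs.

    Pairs retaining fewer than ``config.min_windows`` windows are excluded
    outright (a coverage correlation over so few points is meaningless).
    Returns the annotation and a map of excluded pair id -> reason.
    """
    config = config or FilterConfig()
    if not pairs:
        raise InvalidInputError("no ortholog pairs given")
    ann = ComparableAnnotation(species_a=pairs[0].species_a, species_b=pairs[0].species_b)
    excluded: dict[str, str] = {}
    for pair in pairs:
        if pair.pair_id not in alignments:
            excluded[pair.pair_id] = "no_alignment"
            continue
        windows = build_comparable_windows(pair, alignments[pair.pair_id], config)
        if len(windows) < config.min_windows:
            excluded[pair.pair_id] = f"too_few_windows({len(windows)})"
            continue
        ann.pairs[pair.pair_id] = PairAnnotation(
            pair_id=pair.pair_id, gene_a=pair.gene_a, gene_b=pair.gene_b, windows=windows
        )
    return ann, excluded
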