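"""Fragment counting, TMM/CPM/FPKM, fold changes, and validation stats."""
import math

import numpy as np
import pandas as pd
import pytest

from orthowindow.models import (
    ComparableAnnotation,
    ComparableWindow,
    DegenerateDataError,
    GenomicWindow,
    InvalidInputError,
    PairAnnotation,
)
from orthowindow.quantify import (
    CountMatrix,
    count_fragments,
    cpm,
    de_threshold_filter,
    fpkm,
    log2_fold_change,
    method_concordance,
    tmm_factors,
    welch_t,
)


def _window(segments, species, chrom, j, pid, gene):
    return GenomicWindow(
        pair_id=pid, window_index=j, species=species, gene_id=gene,
        chrom=chrom, strand="+", segments=tuple(segments),
    )


def _annotation_two_genes():
    """Two genes in species a on one chromosome; windows 100-200 and 190-290.

    Gene p2's first window overlaps gene p1's last (180-200 vs 190-215)
    so a fragment in the shared stretch is ambiguous.
    """
    ann = ComparableAnnotation(species_a="sa", species_b="sb")
    for pid, gene_a, gene_b, start_a, start_b in (
        ("p1", "ga1", "gb1", 100, 1000),
        ("p2", "ga2", "gb2", 190, 2000),
    ):
        wins = []
        for j in range(4):
            wins.append(
                ComparableWindow(
                    window_index=j, identity=1.0, n_gap_cols=0,
                    genomic_a=_window([(start_a + 25 * j, start_a + 25 * (j + 1))],
                                      "sa", "chrA", j, pid, gene_a),
                    genomic_b=_window([(start_b + 25 * j, start_b + 25 * (j + 1))],
                                      "sb", "chrB", j, pid, gene_b),
                )
            )
        ann.pairs[pid] = PairAnnotation(pair_id=pid, gene_a=gene_a, gene_b=gene_b, windows=wins)
    return ann


class TestCountFragments:
    def test_unique_overlap_counted_once(self):
        ann = _annotation_two_genes()
        frags = {"s1": [("chrA", 110, 160)]}  # inside p1 windows only
        m = count_fragments(frags, {"s1": "sa"}, ann)
        assert m.counts.loc["p1", "s1"] == 1
        assert m.counts.loc["p2", "s1"] == 0

    def test_ambiguous_fragment_discarded(self):
        ann = _annotation_two_genes()
        frags = {"s1": [("chrA", 185, 205)]}  # overlaps p1 and p2 windows
        m = count_fragments(frags, {"s1": "sa"}, ann)
        assert m.counts["s1"].sum() == 0
        assert m.tallies.loc["s1", "ambiguous"] == 1

    def test_fragment_outside_windows_not_counted(self):
        """A fragment in a non-comparable stretch of a retained gene is skipped."""
        ann = _annotation_two_genes()
        frags = {"s1": [("chrA", 0, 90)]}  # before any window of p1
        m = count_fragments(frags, {"s1": "sa"}, ann)
        assert m.counts["s1"].sum() == 0
        assert m.tallies.loc["s1", "unassigned"] == 1

    def test_conservation_tally(self, rng):
        ann = _annotation_two_genes()
        frags = {"s1": [("chrA", int(s), int(s) + 30) for s in rng.integers(0, 400, 200)]}
        m = count_fragments(frags, {"s1": "sa"}, ann)
        t = m.tallies.loc["s1"]
        assert t["assigned"] + t["ambiguous"] + t["unassigned"] == 200
        assert m.counts["s1"].sum() == t["assigned"]

    def test_unknown_chromosome_warns_unassigned(self):
        ann = _annotation_two_genes()
        with pytest.warns(UserWarning, match="absent"):
            m = count_fragments({"s1": [("chrZ", 0, 50)]}, {"s1": "sa"}, ann)
        assert m.tallies.loc["s1", "unassigned"] == 1

    def test_comparable_lengths_recorded(self):
        ann = _annotation_two_genes()
        m = count_fragments({"s1": []}, {"s1": "sa"}, ann)
        assert (m.comparable_length["sa"] == 100).all()
        assert (m.comparable_length["sb"] == 100).all()


def _matrix(counts: pd.DataFrame, lengths=None, species=None):
    samples = list(counts.columns)
    species = species or {s: "sa" for s in samples}
    lengths = lengths if lengths is not None else pd.DataFrame(
        {sp: 1000 for sp in set(species.values())}, index=counts.index
    )
    return CountMatrix(
        counts=counts, sample_species=species, comparable_length=lengths,
        tallies=pd.DataFrame(),
    )


class TestTMM:
    def test_identical_samples_factor_one(self):
        counts = pd.DataFrame({"s1": [10, 20, 30, 40], "s2": [10, 20, 30, 40]})
        nf = tmm_factors(counts, ref_sample="s1")
        assert nf.tmm_factor["s2"] == pytest.approx(1.0)

    def test_doubled_sample_factor_one(self):
        """Library-size division absorbs a uniform doubling: all M_g = 0."""
        counts = pd.DataFrame({"s1": [10, 20, 30, 40], "s2": [20, 40, 60, 80]})
        nf = tmm_factors(counts, ref_sample="s1")
        assert nf.tmm_factor["s2"] == pytest.approx(1.0)

    def test_six_gene_matrix_matches_stepwise_oracle(self):
        """Factor equals a spreadsheet-style evaluation done from scratch."""
        y_k = np.array([100.0, 205.0, 300.0, 455.0, 40.0, 1000.0])
        y_r = np.array([80.0, 190.0, 330.0, 400.0, 35.0, 2100.0])
        counts = pd.DataFrame({"ref": y_r, "k": y_k})
        Nk, Nr = y_k.sum(), y_r.sum()
        M = np.log2((y_k / Nk) / (y_r / Nr))
        A = 0.5 * np.log2((y_k / Nk) * (y_r / Nr))
        # rank trimming, n=6: keep M-ranks 2..5, A-ranks 1..6 (trim 30%/5%)
        order_m = np.argsort(np.argsort(M)) + 1
        order_a = np.argsort(np.argsort(A)) + 1
        keep = (order_m >= 2) & (order_m <= 5) & (order_a >= 1) & (order_a <= 6)
        w = (Nk - y_k) / (Nk * y_k) + (Nr - y_r) / (Nr * y_r)
        expected = 2 ** (np.sum(M[keep] / w[keep]) / np.sum(1 / w[keep]))
        nf = tmm_factors(counts, ref_sample="ref")
        assert nf.tmm_factor["k"] == pytest.approx(expected, rel=1e-12)
        assert nf.tmm_factor["ref"] == pytest.approx(1.0)

    def test_symmetry_swapping_reference(self, rng):
        counts = pd.DataFrame({
            "s1": rng.integers(10, 1000, size=50),
            "s2": rng.integers(10, 1000, size=50),
        })
        f12 = tmm_factors(counts, ref_sample="s1").tmm_factor["s2"]
        f21 = tmm_factors(counts, ref_sample="s2").tmm_factor["s1"]
        assert math.log2(f12) == pytest.approx(-math.log2(f21), abs=0.05)

    def test_zero_overlap_warns_factor_one(self):
        counts = pd.DataFrame({"s1": [10, 0, 5, 0], "s2": [0, 7, 0, 9]})
        with pytest.warns(UserWarning):
            nf = tmm_factors(counts, ref_sample="s1")
        assert nf.tmm_factor["s2"] == 1.0


def _unit_factors(samples, library_size=1e6):
    from orthowindow.quantify import NormFactors

    return NormFactors(
        ref_sample=samples[0],
        library_size=pd.Series({s: library_size for s in samples}),
        tmm_factor=pd.Series({s: 1.0 for s in samples}),
    )


class TestCpmFpkm:
    def test_cpm_unit_example(self):
        m = _matrix(pd.DataFrame({"s1": [5]}, index=["g1"]))
        assert cpm(m, _unit_factors(["s1"])).loc["g1", "s1"] == pytest.approx(5.0)

    def test_fpkm_unit_example(self):
        m = _matrix(
            pd.DataFrame({"s1": [100]}, index=["g1"]),
            lengths=pd.DataFrame({"sa": [1000]}, index=["g1"]),
        )
        assert fpkm(m, _unit_factors(["s1"])).loc["g1", "s1"] == pytest.approx(100.0)

    def test_cpm_scale_invariance_and_column_sum(self, rng):
        counts = pd.DataFrame({
            "s1": rng.integers(1, 500, size=20),
            "s2": rng.integers(1, 500, size=20),
        })
        lib = counts.sum(axis=0)
        nf = _unit_factors(["s1", "s2"])
        nf.library_size = lib.astype(float)
        c1 = cpm(_matrix(counts), nf)
        # with all factors 1, CPM columns sum to 1e6
        np.testing.assert_allclose(c1.sum(axis=0), 1e6)
        nf2 = _unit_factors(["s1", "s2"])
        nf2.library_size = 2.0 * lib
        np.testing.assert_allclose(cpm(_matrix(counts * 2), nf2).to_numpy(), c1.to_numpy())

    def test_zero_effective_size_error(self):
        m = _matrix(pd.DataFrame({"s1": [5]}, index=["g1"]))
        with pytest.raises(InvalidInputError):
            cpm(m, _unit_factors(["s1"], library_size=0.0))


class TestFoldChange:
    def test_equal_means_zero(self):
        assert log2_fold_change(7.0, 7.0) == 0.0

    def test_fourfold(self):
        assert log2_fold_change(4000.0, 1000.0, pseudocount=0.5) == pytest.approx(2.0, abs=0.01)

    def test_both_zero(self):
        assert log2_fold_change(0.0, 0.0) == 0.0


class TestThresholdFilter:
    def test_calls(self):
        records = pd.DataFrame({
            "log2fc": [1.5, 1.0, -3.0, -1.4, 2.0],
            "adj_p": [0.01, 0.04, 0.2, 0.01, np.nan],
        })
        with pytest.warns(UserWarning, match="lack adj_p"):
            out = de_threshold_filter(records, alpha=0.05, log2fc_cutoff=1.0)
        assert list(out["call"][:4]) == ["up", "ns", "ns", "down"]
        assert pd.isna(out["call"].iloc[4])

    def test_strict_boundaries(self):
        records = pd.DataFrame({"log2fc": [1.0, 1.01], "adj_p": [0.05, 0.05]})
        out = de_threshold_filter(records)
        assert list(out["call"]) == ["ns", "ns"]  # adj_p == alpha is not significant


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([4.0, 5.0, 6.0])
        t, df, p = welch_t(x, y)
        sx2, sy2 = x.var(ddof=1), y.var(ddof=1)
        se2 = sx2 / 3 + sy2 / 3
        t_hand = (x.mean() - y.mean()) / math.sqrt(se2)
        df_hand = se2**2 / ((sx2 / 3) ** 2 / 2 + (sy2 / 3) ** 2 / 2)
        from scipy import stats

        p_hand = 2 * stats.t.sf(abs(t_hand), df_hand)
        assert t == pytest.approx(t_hand)
        assert df == pytest.approx(df_hand)
        assert p == pytest.approx(p_hand)

    def test_zero_variance_unequal_means_degenerate(self):
        with pytest.raises(DegenerateDataError):
            welch_t(np.array([2.0, 2.0]), np.array([3.0, 3.0]))

    def test_small_groups_rejected(self):
        with pytest.raises(InvalidInputError):
            welch_t(np.array([1.0]), np.array([1.0, 2.0]))


class TestMethodConcordance:
    def test_six_of_seven(self):
        k, n, p = method_concordance(list("+++++--"), list("+++++-+"))
        assert (k, n) == (6, 7)
        assert p == 0.0625

    def test_seven_of_seven(self):
        k, n, p = method_concordance(list("+++++--"), list("+++++--"))
        assert p == pytest.approx(1 / 128)

    def test_zero_of_four(self):
        k, n, p = method_concordance(list("++++"), list("----"))
        assert p == pytest.approx(sum(math.comb(4, i) for i in range(0, 5)) / 16)
        assert p == 1.0

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            method_concordance(["+"], ["+", "-"])
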