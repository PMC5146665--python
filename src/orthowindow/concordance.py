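"""Interspecies coverage-concordance screening of orthologous genes.

A gene survives cross-species comparison only if its per-window coverage
profiles agree between the species. The screen has three layers:

1. Pearson correlation of the two replicate-averaged window profiles;
   genes with r below ``min_r`` (default 0.4) are candidates for
   exclusion.
2. Sign-test rescue: a poorly correlated gene whose coverage is
   consistently higher in one species (exact binomial sign test at
   ``sign_alpha``, default 0.001) reflects a genuine expression shift,
   not an annotation artifact, and is retained with all its windows.
3. Robust-line outlier screen: for retained (non-rescued) genes a Huber
   M-estimated line of profile_a on profile_b is fitted and windows with
   |scaled residual| above ``outlier_z`` MAD units are dropped from both
   species.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .models import (
    EXCLUDED_DEGENERATE,
    EXCLUDED_LOW_R,
    RETAIN,
    RETAIN_RESCUED,
    ComparableAnnotation,
    DegenerateDataError,
    FilterConfig,
    GeneConcordance,
    InvalidInputError,
)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float | None:
    """Sample Pearson correlation; None if either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise InvalidInputError("need at least 3 points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def sign_test(k: int, n: int, alternative: str = "two_sided") -> float:
    """Exact binomial sign test at success probability 1/2.

    two_sided is the doubled smaller tail, capped at 1.
    """
    if n < 1:
        raise InvalidInputError("sign test needs n >= 1")
    if not (0 <= k <= n):
        raise InvalidInputError(f"k={k} outside [0, {n}]")
    if alternative == "greater":
        return float(stats.binom.sf(k - 1, n, 0.5))
    if alternative == "less":
        return float(stats.binom.cdf(k, n, 0.5))
    if alternative == "two_sided":
        lower = stats.binom.cdf(k, n, 0.5)
        upper = stats.binom.sf(k - 1, n, 0.5)
        return float(min(1.0, 2.0 * min(lower, upper)))
    raise InvalidInputError(f"unknown alternative {alternative!r}")


def robust_line_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Huber M-estimated line of y on x with MAD-scaled residuals.

    Returns (slope, intercept, scaled_residuals) where scaled residuals
    are raw residuals divided by 1.4826 x MAD (consistent for the normal
    sigma). Raises DegenerateDataError if x has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise InvalidInputError("need at least 3 points for a line fit")
    if np.ptp(x) == 0:
        raise DegenerateDataError("x has zero variance; line fit is degenerate")
    X = sm.add_constant(x)
    model = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=50, tol=1e-8)
    resid = np.asarray(res.resid, dtype=float)
    scale = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    magnitude = max(1.0, float(np.max(np.abs(y))))
    if scale > 1e-10 * magnitude:
        scaled = resid / scale
    else:
        # majority of points fit exactly, so the MAD scale degenerates to 0:
        # residuals at numerical-noise level are not outliers, anything
        # genuinely off the line is
        scaled = np.zeros_like(resid)
        genuine = np.abs(resid) > 1e-8 * magnitude
        scaled[genuine] = np.sign(resid[genuine]) * np.inf
    return float(res.params[1]), float(res.params[0]), scaled


def flag_outliers(scaled_residuals: np.ndarray, outlier_z: float = 2.5) -> set[int]:
    """Indices with |scaled residual| strictly above the cutoff."""
    return {int(i) for i in np.nonzero(np.abs(scaled_residuals) > outlier_z)[0]}


def classify_gene(
    gene_id: str,
    profile_a: np.ndarray,
    profile_b: np.ndarray,
    config: FilterConfig | None = None,
    window_indices: list[int] | None = None,
) -> GeneConcordance:
    """Decide whether a gene's interspecies coverage is comparable.

    Retain if r >= min_r; rescue a low-r gene whose coverage is
    consistently one-sided (two-sided sign test, ties dropped); exclude
    otherwise. Retained (non-rescued) genes additionally lose robust-fit
    outlier windows; rescued genes keep all windows. A retained gene must
    still hold at least ``min_windows`` windows, else it is degenerate.
    """
    config = config or FilterConfig()
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError(f"gene {gene_id}: profile length mismatch")
    n = a.size
    if n < config.min_windows:
        raise InvalidInputError(
            f"gene {gene_id}: {n} windows < min_windows {config.min_windows}"
        )
    idx = list(window_indices) if window_indices is not None else list(range(n))
    if len(idx) != n:
        raise InvalidInputError(f"gene {gene_id}: window index list length mismatch")

    diffs = a - b
    sign_k = int(np.sum(diffs > 0))
    sign_n = int(np.sum(diffs != 0))
    sign_p = sign_test(sign_k, sign_n, "two_sided") if sign_n > 0 else 1.0
    r = pearson_r(a, b)

    base = dict(
        gene_id=gene_id, n_windows=n, pearson_r=r,
        sign_k=sign_k, sign_n=sign_n, sign_p=sign_p,
    )

    if r is not None and r >= config.min_r:
        try:
            slope, intercept, scaled = robust_line_fit(b, a)
        except DegenerateDataError:
            return GeneConcordance(**base, decision=EXCLUDED_DEGENERATE)
        out_pos = flag_outliers(scaled, config.outlier_z)
        outliers = frozenset(idx[i] for i in out_pos)
        retained = frozenset(j for j in idx if j not in outliers)
        if len(retained) < config.min_windows:
            return GeneConcordance(
                **base, slope=slope, intercept=intercept,
                outlier_windows=outliers, decision=EXCLUDED_DEGENERATE,
            )
        return GeneConcordance(
            **base, slope=slope, intercept=intercept,
            outlier_windows=outliers, decision=RETAIN, retained_windows=retained,
        )
    if sign_p < config.sign_alpha:
        # Consistently higher in one species: a real expression shift,
        # exempt from outlier removal.
        return GeneConcordance(
            **base, decision=RETAIN_RESCUED, retained_windows=frozenset(idx)
        )
    return GeneConcordance(**base, decision=EXCLUDED_LOW_R)


def classify_all(
    profiles: dict[str, tuple[np.ndarray, np.ndarray]],
    annotation: ComparableAnnotation,
    config: FilterConfig | None = None,
) -> dict[str, GeneConcordance]:
    """Run classify_gene over every annotated pair."""
    config = config or FilterConfig()
    out = {}
    for pid, pann in annotation.pairs.items():
        if pid not in profiles:
            raise InvalidInputError(f"pair {pid}: annotated but no coverage profile")
        a, b = profiles[pid]
        indices = [w.window_index for w in sorted(pann.windows, key=lambda w: w.window_index)]
        out[pid] = classify_gene(pid, a, b, config, window_indices=indices)
    return out


def finalize_annotation(
    annotation: ComparableAnnotation, concordances: dict[str, GeneConcordance]
) -> ComparableAnnotation:
    """Drop excluded genes and outlier windows, symmetrically in both species."""
    for pid in annotation.pairs:
        if pid not in concordances:
            raise InvalidInputError(f"pair {pid}: annotated but no concordance computed")
    retained = {
        pid: sorted(conc.retained_windows)
        for pid, conc in concordances.items()
        if conc.retained and pid in annotation.pairs
    }
    return annotation.subset(retained)


def concordance_report(concordances: dict[str, GeneConcordance]) -> pd.DataFrame:
    rows = []
    for pid in sorted(concordances):
        c = concordances[pid]
        rows.append(
            (pid, c.n_windows,
             np.nan if c.pearson_r is None else c.pearson_r,
             c.sign_k, c.sign_n, c.sign_p,
             np.nan if c.slope is None else c.slope,
             np.nan if c.intercept is None else c.intercept,
             len(c.outlier_windows), c.decision)
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "n_windows", "r", "sign_k", "sign_n", "sign_p",
                 "slope", "intercept", "n_outliers", "decision"],
    )


def concordance_summary(
    concordances: dict[str, GeneConcordance], n_bins: int = 20
) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Histogram of per-gene r over [-1, 1] plus decision tallies."""
    if not concordances:
        raise InvalidInputError("no concordances to summarize")
    rs = [c.pearson_r for c in concordances.values() if c.pearson_r is not None]
    counts, edges = np.histogram(rs, bins=n_bins, range=(-1.0, 1.0))
    tallies: dict[str, int] = {}
    for c in concordances.values():
        tallies[c.decision] = tallies.get(c.decision, 0) + 1
    return counts, edges, tallies
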