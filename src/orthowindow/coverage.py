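"""Per-sample depth aggregation over comparable windows.

Coverage concordance between species is judged on per-window mean depths.
Each sample's window depths are scaled to per-million total depth mass
(so the later sign test is well defined across library sizes — Pearson r
would be scale-invariant anyway) and replicates of a species are averaged
arithmetically into one profile per gene per species.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    ComparableAnnotation,
    ConfigurationError,
    FormatError,
    GenomicWindow,
    InvalidInputError,
)


@dataclass
class DepthTrack:
    """Sorted, non-overlapping per-chromosome depth runs of one sample."""

    sample_id: str
    species: str
    runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)
    total_depth_mass: float = 0.0

    @classmethod
    def from_intervals(
        cls, sample_id: str, species: str, intervals: list[tuple[str, int, int, float]]
    ) -> "DepthTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, depth in intervals:
            by_chrom.setdefault(chrom, []).append((start, end, depth))
        runs = {}
        mass = 0.0
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            prev_end = -1
            for s, e, _ in ivals:
                if s < prev_end:
                    raise FormatError(f"overlapping intervals on {chrom} at {s}")
                prev_end = e
            starts = np.array([s for s, _, _ in ivals], dtype=np.int64)
            ends = np.array([e for _, e, _ in ivals], dtype=np.int64)
            depths = np.array([d for _, _, d in ivals], dtype=float)
            runs[chrom] = (starts, ends, depths)
            mass += float(np.sum(depths * (ends - starts)))
        return cls(sample_id=sample_id, species=species, runs=runs, total_depth_mass=mass)

    def interval_depth_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base depth over [start, end); absent bases count 0."""
        if chrom not in self.runs:
            return 0.0
        starts, ends, depths = self.runs[chrom]
        # runs overlapping [start, end): first with end > start, last with start < end
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        return float(np.sum(depths[lo:hi] * np.maximum(ov, 0)))


def window_mean_depth(track: DepthTrack, window: GenomicWindow) -> float:
    """Mean per-base depth of one genomic window (all segments pooled)."""
    total = window.total_length
    if total <= 0:
        raise InvalidInputError(
            f"window {window.pair_id}/{window.window_index}: zero-length window"
        )
    depth_sum = sum(track.interval_depth_sum(window.chrom, s, e) for s, e in window.segments)
    return depth_sum / total


def coverage_table(annotation: ComparableAnnotation, tracks: list[DepthTrack]) -> pd.DataFrame:
    """Long-format per-window per-sample mean depths over the annotation.

    Columns: pair_id, window_index, sample_id, species, mean_depth,
    total_depth_mass (the sample's full-track depth mass, repeated).
    """
    rows = []
    for track in tracks:
        if track.species not in (annotation.species_a, annotation.species_b):
            raise ConfigurationError(
                f"sample {track.sample_id}: species {track.species!r} not in annotation "
                f"({annotation.species_a!r}/{annotation.species_b!r})"
            )
        attr = "genomic_a" if track.species == annotation.species_a else "genomic_b"
        for pid in sorted(annotation.pairs):
            for w in annotation.pairs[pid].windows:
                gw = getattr(w, attr)
                rows.append(
                    (pid, w.window_index, track.sample_id, track.species,
                     window_mean_depth(track, gw), track.total_depth_mass)
                )
    return pd.DataFrame(
        rows,
        columns=["pair_id", "window_index", "sample_id", "species",
                 "mean_depth", "total_depth_mass"],
    )


def build_species_profiles(
    annotation: ComparableAnnotation, tracks: list[DepthTrack]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Replicate-averaged normalized window-depth profiles per pair.

    Returns pair_id -> (profile_a, profile_b): equal-length vectors of
    window depths in window-index order, each sample scaled to per-million
    depth mass before averaging across that species' replicates. Samples
    with zero total depth mass are excluded with a warning; a species with
    no usable sample raises ConfigurationError.
    """
    usable = []
    for t in tracks:
        if t.total_depth_mass <= 0:
            warnings.warn(f"sample {t.sample_id}: zero total depth mass, excluded")
            continue
        usable.append(t)
    by_species: dict[str, list[DepthTrack]] = {}
    for t in usable:
        by_species.setdefault(t.species, []).append(t)
    for sp in (annotation.species_a, annotation.species_b):
        if not by_species.get(sp):
            raise ConfigurationError(f"species {sp!r} has no usable depth track")

    profiles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for pid in sorted(annotation.pairs):
        pann = annotation.pairs[pid]
        wins = sorted(pann.windows, key=lambda w: w.window_index)
        out = []
        for sp, attr in ((annotation.species_a, "genomic_a"), (annotation.species_b, "genomic_b")):
            reps = []
            for t in by_species[sp]:
                scale = 1e6 / t.total_depth_mass
                reps.append([window_mean_depth(t, getattr(w, attr)) * scale for w in wins])
            out.append(np.mean(np.asarray(reps, dtype=float), axis=0))
        profiles[pid] = (out[0], out[1])
    return profiles


def profiles_from_coverage_table(
    table: pd.DataFrame, species_a: str, species_b: str
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Rebuild per-pair profiles from a serialized coverage table."""
    df = table.copy()
    usable = df["total_depth_mass"] > 0
    dropped = df.loc[~usable, "sample_id"].unique()
    for s in dropped:
        warnings.warn(f"sample {s}: zero total depth mass, excluded")
    df = df[usable]
    df["norm"] = df["mean_depth"] * 1e6 / df["total_depth_mass"]
    for sp in (species_a, species_b):
        if not (df["species"] == sp).any():
            raise ConfigurationError(f"species {sp!r} has no usable depth track")
    mean = (
        df.groupby(["pair_id", "window_index", "species"])["norm"].mean().unstack("species")
    )
    profiles = {}
    for pid, sub in mean.groupby(level="pair_id"):
        sub = sub.sort_index(level="window_index")
        profiles[pid] = (
            sub[species_a].to_numpy(dtype=float),
            sub[species_b].to_numpy(dtype=float),
        )
    return profiles
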