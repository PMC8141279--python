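"""Interval arithmetic, shuffle-based permutation enrichment, signal profiles.

Implements the accessibility meta-analysis: merge two peak sets, count DML
falling within a distance window of any peak (bedtools-window semantics:
extend every peak by w on both sides, a point DML matches if it lands inside),
build a permutation null by re-placing the peaks uniformly across the genome
with their lengths preserved (bedtools-shuffle semantics), and report the
empirical p as the fraction of permutations whose overlap count strictly
exceeds the observed one — with 0/n reported as "<1/n".

All intervals are 0-based half-open; DML positions (1-based) become points
pos - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._streams import substream
from .genome import GenomeModel

__all__ = [
    "merge_peaks",
    "window_overlap_count",
    "shuffle_intervals",
    "permutation_overlap_test",
    "PermutationResult",
    "aggregate_signal",
    "compare_anchor_signal",
    "liftover_noop",
]


def _validate_intervals(df: pd.DataFrame) -> None:
    if len(df) and ((df["start"] < 0).any() or (df["start"] >= df["end"]).any()):
        bad = df[(df["start"] < 0) | (df["start"] >= df["end"])].iloc[0]
        raise ValueError(f"invalid interval {bad['chrom']}:{bad['start']}-{bad['end']}")


def merge_peaks(set_a: pd.DataFrame, set_b: pd.DataFrame | None = None) -> pd.DataFrame:
    """Union of peak sets with overlapping or book-ended intervals coalesced."""
    parts = [set_a] if set_b is None else [set_a, set_b]
    allp = pd.concat([p[["chrom", "start", "end"]] for p in parts], ignore_index=True)
    _validate_intervals(allp)
    if not len(allp):
        return allp
    allp = allp.sort_values(["chrom", "start", "end"], kind="mergesort")
    rows = []
    for chrom, grp in allp.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, int(e))
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _match_points(points_by_chrom: dict, peaks: pd.DataFrame, w: int) -> int:
    """Count points with >=1 peak within w bp, via merged extended intervals."""
    n = 0
    ext = peaks.assign(start=np.maximum(peaks["start"] - w, 0), end=peaks["end"] + w)
    merged = merge_peaks(ext)
    for chrom, grp in merged.groupby("chrom", sort=False):
        pts = points_by_chrom.get(chrom)
        if pts is None or not len(pts):
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        idx = np.searchsorted(starts, pts, side="right") - 1
        ok = idx >= 0
        n += int(np.count_nonzero(ok & (pts < ends[np.clip(idx, 0, len(ends) - 1)])))
    return n


def _points_by_chrom(dml_table: pd.DataFrame) -> dict:
    return {chrom: np.sort(grp["pos"].to_numpy() - 1)
            for chrom, grp in dml_table.groupby("chrom", sort=False)}


def window_overlap_count(dml_table: pd.DataFrame, peaks: pd.DataFrame, w: int) -> tuple[int, float]:
    """Count and fraction of DML with at least one peak within w bp."""
    if w < 0:
        raise ValueError("w must be >= 0")
    _validate_intervals(peaks[["chrom", "start", "end"]])
    total = len(dml_table)
    if total == 0:
        return 0, 0.0
    count = _match_points(_points_by_chrom(dml_table), peaks, w)
    return count, count / total


def shuffle_intervals(peaks: pd.DataFrame, genome: GenomeModel, seed_or_rng) -> pd.DataFrame:
    """Re-place each interval uniformly across the genome, keeping its length.

    Chromosome chosen with probability proportional to length; start uniform on
    the feasible range; shuffled intervals may overlap one another.
    """
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else substream(int(seed_or_rng), "shuffle")
    lengths = (peaks["end"] - peaks["start"]).to_numpy()
    chrom_names = list(genome.chrom_names)
    chrom_lens = np.array([genome.chrom_lengths[c] for c in chrom_names], dtype=np.int64)
    if len(lengths) and lengths.max() > chrom_lens.max():
        raise ValueError("a peak is longer than every chromosome")
    probs = chrom_lens / chrom_lens.sum()
    ci = rng.choice(len(chrom_names), size=len(lengths), p=probs)
    # re-draw placements that do not fit their chromosome
    for _ in range(100):
        bad = lengths > chrom_lens[ci]
        if not bad.any():
            break
        ci[bad] = rng.choice(len(chrom_names), size=int(bad.sum()), p=probs)
    starts = (rng.random(len(lengths)) * (chrom_lens[ci] - lengths + 1)).astype(np.int64)
    return pd.DataFrame({
        "chrom": [chrom_names[i] for i in ci],
        "start": starts,
        "end": starts + lengths,
    })


@dataclass
class PermutationResult:
    """Observed vs shuffled overlap at one window distance."""

    window: int
    observed: int
    observed_fraction: float
    n_permutations: int
    permuted_counts: np.ndarray = field(repr=False)
    empirical_p: float = 0.0
    reported_p: str = ""

    def to_dict(self) -> dict:
        return {
            "window": self.window,
            "observed": self.observed,
            "observed_fraction": self.observed_fraction,
            "n_permutations": self.n_permutations,
            "empirical_p": self.empirical_p,
            "reported_p": self.reported_p,
        }


def permutation_overlap_test(
    dml_table: pd.DataFrame,
    peaks: pd.DataFrame,
    genome: GenomeModel,
    windows,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[PermutationResult]:
    """Shuffle-null enrichment of DML near peaks over one or more window sizes.

    Empirical p = (# permutations with count strictly greater than observed) /
    n_perm; when that count is zero the p is stored as 0.0 and reported as
    "<1/n_perm".
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if np.isscalar(windows):
        windows = [int(windows)]
    windows = [int(w) for w in windows]
    pts = _points_by_chrom(dml_table)
    total = len(dml_table)
    observed = {w: _match_points(pts, peaks, w) for w in windows}
    perm_counts = {w: np.empty(n_perm, dtype=np.int64) for w in windows}
    rng = substream(seed, "permutation")
    for i in range(n_perm):
        shuffled = shuffle_intervals(peaks, genome, rng)
        for w in windows:
            perm_counts[w][i] = _match_points(pts, shuffled, w)
    results = []
    for w in windows:
        greater = int((perm_counts[w] > observed[w]).sum())
        p = greater / n_perm
        reported = f"<{1 / n_perm:g}" if greater == 0 else f"{p:g}"
        results.append(PermutationResult(
            window=w,
            observed=observed[w],
            observed_fraction=observed[w] / total if total else 0.0,
            n_permutations=n_perm,
            permuted_counts=perm_counts[w],
            empirical_p=p,
            reported_p=reported,
        ))
    return results


def aggregate_signal(
    track: pd.DataFrame,
    anchors: pd.DataFrame,
    flank: int = 2000,
    n_bins: int = 40,
    chrom_lengths: dict | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned signal profile in [pos-flank, pos+flank) around each anchor.

    Bin value = coverage-weighted mean of track values intersecting the bin;
    uncovered bases count as 0.  Windows truncated at chromosome edges are
    zero-padded and flagged.  Returns (matrix (n_anchors, n_bins), mean
    profile, truncated flags).
    """
    if flank < 1 or n_bins < 1 or (2 * flank) % n_bins != 0:
        raise ValueError("need flank >= 1 and n_bins dividing the window width")
    bin_w = 2 * flank // n_bins
    tr = {}
    for chrom, grp in track.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        tr[chrom] = (grp["start"].to_numpy(), grp["end"].to_numpy(), grp["value"].to_numpy())
    mat = np.zeros((len(anchors), n_bins))
    truncated = np.zeros(len(anchors), dtype=bool)
    for i, row in enumerate(anchors.itertuples(index=False)):
        point = int(row.pos) - 1
        win_start = point - flank
        starts, ends, values = tr.get(row.chrom, (np.array([]), np.array([]), np.array([])))
        if win_start < 0:
            truncated[i] = True
        if chrom_lengths is not None and point + flank > chrom_lengths.get(row.chrom, np.inf):
            truncated[i] = True
        for b in range(n_bins):
            lo = win_start + b * bin_w
            hi = lo + bin_w
            if hi <= 0 or not len(starts):
                continue
            j0 = np.searchsorted(ends, lo, side="right")
            j1 = np.searchsorted(starts, hi, side="left")
            if j1 <= j0:
                continue
            ov = np.minimum(ends[j0:j1], hi) - np.maximum(starts[j0:j1], lo)
            mat[i, b] = float((values[j0:j1] * np.maximum(ov, 0)).sum()) / bin_w
    return mat, mat.mean(axis=0), truncated


def compare_anchor_signal(profiles_a: np.ndarray, profiles_b: np.ndarray) -> dict:
    """Equal-variance two-sample two-tailed t test on per-anchor window means."""
    a = np.asarray(profiles_a, dtype=float)
    b = np.asarray(profiles_b, dtype=float)
    if a.ndim == 2:
        a = a.mean(axis=1)
    if b.ndim == 2:
        b = b.mean(axis=1)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 anchors per condition")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "t": float(t),
        "pvalue": float(p),
        "per_anchor_means": (a, b),
    }


def liftover_noop(intervals: pd.DataFrame) -> pd.DataFrame:
    """Coordinate-system hook; the synthetic genome lives in one assembly, so
    this is the identity."""
    return intervals.copy()
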