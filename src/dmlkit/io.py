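"""Reading, writing and filtering per-sample CpG count data.

The on-disk dialect is the Bismark-style cytosine report: tab-separated
``chrom  pos(1-based)  strand  count_methylated  count_unmethylated  [context]``.
Coverage filtering implements the rule used throughout the analysis: a CpG is
kept only when the coverage summed over each group's replicates reaches the
threshold (default 10 reads) in *both* groups; a stricter per-sample mode is
available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Methylome",
    "FilteredMatrix",
    "read_cytosine_report",
    "write_cytosine_report",
    "coverage_filter",
    "conversion_efficiency",
    "global_methylation_summary",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
]

GROUPS = ("CD8", "DN")

_REPORT_COLS = ["chrom", "pos", "strand", "n_meth", "n_total"]


@dataclass
class Methylome:
    """Per-sample CpG methylated / total counts at 1-based positions."""

    sample_id: str
    group: str
    records: pd.DataFrame  # columns chrom, pos, strand, n_meth, n_total

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in _REPORT_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"methylome records missing columns {missing}")
        df = df.astype({"chrom": str, "pos": np.int64, "strand": str,
                        "n_meth": np.int64, "n_total": np.int64})
        if len(df):
            if (df["n_meth"] < 0).any() or (df["n_meth"] > df["n_total"]).any():
                raise ValueError("counts must satisfy 0 <= n_meth <= n_total")
            if df.duplicated(["chrom", "pos", "strand"]).any():
                raise ValueError("duplicate (chrom, pos, strand) in methylome")
        self.records = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Methylome):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.group == other.group
            and self.records[_REPORT_COLS].equals(other.records[_REPORT_COLS])
        )


@dataclass
class FilteredMatrix:
    """Coverage-filtered count matrix: one row per retained CpG, one column pair
    (meth, total) per sample, with a group label per sample."""

    keys: pd.DataFrame  # columns chrom, pos, strand
    meth: np.ndarray  # (n_cpg, n_samples) int
    total: np.ndarray  # (n_cpg, n_samples) int
    sample_ids: list[str]
    groups: list[str]  # per-sample group label
    min_cov: int = 10
    per_sample: bool = False
    n_dropped: int = field(default=0, compare=False)

    @property
    def n_cpgs(self) -> int:
        return len(self.keys)

    def group_mask(self, group: str) -> np.ndarray:
        return np.asarray([g == group for g in self.groups])

    def group_counts(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        """(meth, total) submatrices for one group's samples."""
        m = self.group_mask(group)
        return self.meth[:, m], self.total[:, m]


def read_cytosine_report(path, sample_id: str | None = None, group: str = "CD8") -> Methylome:
    """Parse a cytosine report; malformed lines raise with their line number."""
    chroms, poss, strands, meths, totals = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}: line {lineno}: expected >=5 tab-separated fields")
            chrom, pos_s, strand, m_s, u_s = parts[:5]
            try:
                pos, m, u = int(pos_s), int(m_s), int(u_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer field") from exc
            if pos <= 0:
                raise ValueError(f"{path}: line {lineno}: position must be >= 1")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: strand must be + or -")
            if m < 0 or u < 0:
                raise ValueError(f"{path}: line {lineno}: negative count")
            chroms.append(chrom)
            poss.append(pos)
            strands.append(strand)
            meths.append(m)
            totals.append(m + u)
    df = pd.DataFrame(
        {"chrom": chroms, "pos": np.asarray(poss, dtype=np.int64), "strand": strands,
         "n_meth": np.asarray(meths, dtype=np.int64), "n_total": np.asarray(totals, dtype=np.int64)}
    )
    sid = sample_id if sample_id is not None else str(path)
    return Methylome(sid, group, df)


def write_cytosine_report(methylome: Methylome, path) -> None:
    """Write a cytosine report, sorted chrom-lexicographic then by position."""
    df = methylome.records.sort_values(["chrom", "pos"], kind="mergesort")
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            unmeth = row.n_total - row.n_meth
            fh.write(f"{row.chrom}\t{row.pos}\t{row.strand}\t{row.n_meth}\t{unmeth}\tCG\n")


def coverage_filter(
    methylomes: list[Methylome], min_cov: int = 10, per_sample: bool = False
) -> FilteredMatrix:
    """Keep CpGs whose coverage reaches ``min_cov`` in each group.

    Pooled mode (default) sums coverage over a group's replicates; per-sample
    mode requires every individual replicate to reach the threshold.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    for m in methylomes:
        if m.group not in GROUPS:
            raise ValueError(f"unknown group label {m.group!r} for sample {m.sample_id}")
    for g in GROUPS:
        if not any(m.group == g for m in methylomes):
            raise ValueError(f"no samples in group {g}")

    frames = []
    for m in methylomes:
        df = m.records.set_index(["chrom", "pos", "strand"])[["n_meth", "n_total"]]
        df.columns = pd.MultiIndex.from_product([[m.sample_id], df.columns])
        frames.append(df)
    wide = pd.concat(frames, axis=1).fillna(0).astype(np.int64)
    wide = wide.sort_index()

    sample_ids = [m.sample_id for m in methylomes]
    groups = [m.group for m in methylomes]
    meth = np.column_stack([wide[(s, "n_meth")].to_numpy() for s in sample_ids])
    total = np.column_stack([wide[(s, "n_total")].to_numpy() for s in sample_ids])

    keep = np.ones(len(wide), dtype=bool)
    for g in GROUPS:
        cols = np.asarray([gg == g for gg in groups])
        if per_sample:
            keep &= (total[:, cols] >= min_cov).all(axis=1)
        else:
            keep &= total[:, cols].sum(axis=1) >= min_cov

    keys = wide.index.to_frame(index=False)[["chrom", "pos", "strand"]]
    n_dropped = int((~keep).sum())
    logger.info("coverage_filter: retained %d CpGs, dropped %d (min_cov=%d, %s)",
                int(keep.sum()), n_dropped, min_cov, "per-sample" if per_sample else "group-pooled")
    return FilteredMatrix(
        keys=keys.loc[keep].reset_index(drop=True),
        meth=meth[keep],
        total=total[keep],
        sample_ids=sample_ids,
        groups=groups,
        min_cov=min_cov,
        per_sample=per_sample,
        n_dropped=n_dropped,
    )


def conversion_efficiency(spikein: pd.DataFrame, threshold: float = 0.99) -> pd.DataFrame:
    """Pooled converted fraction per sample from spike-in control counts.

    ``spikein`` needs columns ``converted`` and ``total`` and optionally
    ``sample``; returns one row per sample with the efficiency and a pass flag
    against ``threshold``.
    """
    if "sample" not in spikein.columns:
        spikein = spikein.assign(sample="pooled")
    if not len(spikein):
        raise ValueError("empty spike-in table")
    out = []
    for sample, grp in spikein.groupby("sample", sort=True):
        tot = int(grp["total"].sum())
        if tot == 0:
            raise ValueError(f"zero total spike-in depth for sample {sample}")
        eff = float(grp["converted"].sum()) / tot
        out.append({"sample": sample, "efficiency": eff, "passed": eff >= threshold})
        logger.info("conversion efficiency %s: %.4f (%s)", sample, eff,
                    "pass" if eff >= threshold else "FAIL")
    return pd.DataFrame(out)


def global_methylation_summary(matrix: FilteredMatrix) -> dict:
    """Per-sample mean methylation (unweighted over CpGs), group means and the
    CD8 − DN difference — the violin-plot style global summary."""
    if matrix.n_cpgs == 0:
        raise ValueError("empty matrix")
    with np.errstate(invalid="ignore"):
        frac = np.where(matrix.total > 0, matrix.meth / np.maximum(matrix.total, 1), np.nan)
    sample_means = {
        s: float(np.nanmean(frac[:, j])) for j, s in enumerate(matrix.sample_ids)
    }
    group_means = {
        g: float(np.mean([sample_means[s] for s, gg in zip(matrix.sample_ids, matrix.groups) if gg == g]))
        for g in GROUPS
    }
    return {
        "sample_means": sample_means,
        "group_means": group_means,
        "difference": group_means["CD8"] - group_means["DN"],
    }


# --- simple BED / bedGraph plumbing (0-based, half-open) ---

def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score", "strand"],
                     usecols=range(6), engine="python")
    return df.dropna(subset=["chrom", "start", "end"]).astype({"start": np.int64, "end": np.int64})


def write_bed(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", "+")):
        if col not in out.columns:
            out[col] = default
    out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "value"]).astype(
        {"start": np.int64, "end": np.int64, "value": float})


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)
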