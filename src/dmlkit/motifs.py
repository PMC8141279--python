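"""PWM scanning, motif enrichment around demethylated loci, motif profiles.

Windows around hypomethylated DML are scanned on both strands with log-odds
position weight matrices; per PWM, the fraction of foreground windows with at
least one hit is compared with background windows by a one-sided binomial
test.  Background windows are CpG-anchored and GC-matched in quintile bins,
which deliberately preserves the restriction-site composition of
enzyme-digest libraries (the CCGG/TCGA "motifs" surface as positive controls
rather than being masked away).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from ._streams import substream
from .genome import GenomeModel, extract_window, gc_fraction

logger = logging.getLogger(__name__)

__all__ = [
    "PWM",
    "MotifHit",
    "load_meme",
    "bundled_pwms",
    "scan_pwm",
    "scan_windows",
    "motif_enrichment",
    "sample_background_windows",
    "extract_windows",
    "motif_centered_profiles",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = np.array([3, 2, 1, 0])


@dataclass
class PWM:
    """Position probability matrix over A,C,G,T with log-odds scoring.

    Scores are sum over positions of log2((p + pc)/(1 + 4 pc) / background);
    a window position is a hit when the score reaches ``threshold`` times the
    maximum attainable score.
    """

    name: str
    matrix: np.ndarray  # (length, 4) probabilities
    pseudocount: float = 0.01
    background: np.ndarray | None = None
    threshold: float = 0.8

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (length, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold fraction must lie in (0, 1]")
        if self.background is None:
            self.background = np.full(4, 0.25)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        adj = (self.matrix + self.pseudocount) / (1.0 + 4.0 * self.pseudocount)
        return np.log2(adj / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    @classmethod
    def from_consensus(cls, name: str, consensus: str, sharpness: float = 0.97, **kw) -> "PWM":
        mat = np.full((len(consensus), 4), (1 - sharpness) / 3)
        for i, b in enumerate(consensus.upper()):
            mat[i, _BASE_INDEX[b]] = sharpness
        return cls(name, mat, **kw)


@dataclass
class MotifHit:
    chrom: str
    start: int  # 0-based
    end: int
    strand: str
    pwm_name: str
    score: float


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def scan_pwm(windows: list[tuple[str, int, str]], pwm: PWM) -> list[MotifHit]:
    """Scan sequence windows (chrom, start0, seq) on both strands.

    Every offset on either strand whose log-odds score reaches
    threshold * max_score is reported; windows shorter than the motif are
    skipped and logged.
    """
    hits: list[MotifHit] = []
    lo = pwm.log_odds
    k = pwm.length
    cutoff = pwm.threshold * pwm.max_score
    for chrom, start0, seq in windows:
        enc = _encode(seq)
        n = len(enc) - k + 1
        if n <= 0:
            logger.info("scan_pwm: window %s:%d shorter than motif %s", chrom, start0, pwm.name)
            continue
        idx = np.lib.stride_tricks.sliding_window_view(enc, k)  # (n, k)
        valid = (idx >= 0).all(axis=1)
        safe = np.clip(idx, 0, 3)
        fwd = lo[np.arange(k), safe].sum(axis=1)
        # reverse complement: complement bases, reverse positions
        rc = lo[::-1][:, ::-1]
        rev = rc[np.arange(k), safe].sum(axis=1)
        for off in np.flatnonzero(valid & (fwd >= cutoff)):
            hits.append(MotifHit(chrom, start0 + int(off), start0 + int(off) + k, "+",
                                 pwm.name, float(fwd[off])))
        for off in np.flatnonzero(valid & (rev >= cutoff)):
            hits.append(MotifHit(chrom, start0 + int(off), start0 + int(off) + k, "-",
                                 pwm.name, float(rev[off])))
    return hits


def scan_windows(windows, pwm_set: list[PWM]) -> dict[str, np.ndarray]:
    """Per PWM, boolean vector of which windows contain >=1 hit."""
    out = {}
    for pwm in pwm_set:
        has = np.zeros(len(windows), dtype=bool)
        for i, win in enumerate(windows):
            if scan_pwm([win], pwm):
                has[i] = True
        out[pwm.name] = has
    return out


def motif_enrichment(
    fg_windows: list[tuple[str, int, str]],
    bg_windows: list[tuple[str, int, str]],
    pwm_set: list[PWM],
) -> pd.DataFrame:
    """One-sided binomial enrichment of each PWM in foreground vs background.

    A window "contains" a motif when it has >=1 hit.  The foreground hit count
    is tested against the background hit fraction as the null probability;
    when the background fraction is 0 but the foreground has hits, a
    continuity-corrected background fraction is used (and logged).
    """
    if not fg_windows or not bg_windows:
        raise ValueError("foreground and background window sets must be non-empty")
    rows = []
    fg_flags = scan_windows(fg_windows, pwm_set)
    bg_flags = scan_windows(bg_windows, pwm_set)
    for pwm in pwm_set:
        k_fg = int(fg_flags[pwm.name].sum())
        k_bg = int(bg_flags[pwm.name].sum())
        n_fg, n_bg = len(fg_windows), len(bg_windows)
        p0 = k_bg / n_bg
        if p0 == 0.0 and k_fg > 0:
            p0 = 0.5 / (n_bg + 1)
            logger.info("motif_enrichment: %s absent from background, continuity-corrected", pwm.name)
        if p0 == 0.0:
            p = 1.0
        else:
            p = stats.binomtest(k_fg, n_fg, min(p0, 1.0), alternative="greater").pvalue
        rows.append((pwm.name, k_fg / n_fg, k_bg / n_bg, float(p)))
    out = pd.DataFrame(rows, columns=["pwm", "fg_fraction", "bg_fraction", "pvalue"])
    out = out.sort_values(["pvalue", "pwm"], kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def extract_windows(genome: GenomeModel, anchors: pd.DataFrame, flank: int = 200):
    """Sequence windows ±flank around 1-based anchor points."""
    wins = []
    for row in anchors.itertuples(index=False):
        start, _end, seq = extract_window(genome, row.chrom, int(row.pos), flank)
        wins.append((row.chrom, start, seq))
    return wins


def sample_background_windows(
    genome: GenomeModel,
    fg_anchors: pd.DataFrame,
    flank: int = 200,
    multiple: int = 2,
    seed: int = 0,
):
    """CpG-anchored background windows, GC-matched to foreground in quintiles.

    Candidates are CpG positions at least 2*flank away from any foreground
    anchor; they are sampled to match the foreground GC-content quintile
    proportions, 'multiple' times the foreground count (capped by candidate
    availability).
    """
    rng = substream(seed, "background")
    fg_by_chrom = {c: grp["pos"].to_numpy() for c, grp in fg_anchors.groupby("chrom", sort=False)}
    candidates = []
    for chrom in genome.chrom_names:
        taken = np.sort(fg_by_chrom.get(chrom, np.array([])))
        for pos in genome.cpg_positions[chrom]:
            if len(taken):
                j = np.searchsorted(taken, pos)
                near = min(
                    abs(int(pos) - int(taken[j - 1])) if j > 0 else np.inf,
                    abs(int(taken[j]) - int(pos)) if j < len(taken) else np.inf,
                )
                if near < 2 * flank:
                    continue
            candidates.append((chrom, int(pos)))
    if not candidates:
        raise ValueError("no background candidates away from foreground windows")
    cand = pd.DataFrame(candidates, columns=["chrom", "pos"])
    cand_wins = extract_windows(genome, cand, flank)
    fg_wins = extract_windows(genome, fg_anchors, flank)
    fg_gc = np.array([gc_fraction(w[2]) for w in fg_wins])
    cand_gc = np.array([gc_fraction(w[2]) for w in cand_wins])
    edges = np.quantile(fg_gc, [0.2, 0.4, 0.6, 0.8])
    fg_bin = np.digitize(fg_gc, edges)
    cand_bin = np.digitize(cand_gc, edges)
    n_target = multiple * len(fg_wins)
    picked = []
    for b in range(5):
        want = int(round(n_target * (fg_bin == b).mean()))
        pool = np.flatnonzero(cand_bin == b)
        if not len(pool):
            continue
        take = rng.choice(pool, size=min(want, len(pool)), replace=False)
        picked.extend(int(i) for i in take)
    if not picked:  # degenerate GC structure; fall back to uniform sampling
        picked = list(rng.choice(len(cand_wins), size=min(n_target, len(cand_wins)), replace=False))
    return [cand_wins[i] for i in sorted(picked)]


def motif_centered_profiles(
    hits: list[MotifHit],
    matrix,
    tracks: dict[str, pd.DataFrame],
    flank: int = 200,
) -> pd.DataFrame:
    """Mean methylation per group and mean accessibility per condition around
    motif hits (±flank of each hit midpoint)."""
    from .intervals import aggregate_signal

    if not hits:
        raise ValueError("no motif hits")
    rows = []
    by_name: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_name.setdefault(h.pwm_name, []).append(h)
    keys = matrix.keys
    pos_by_chrom = {}
    for chrom, grp in keys.reset_index().groupby("chrom", sort=False):
        pos_by_chrom[chrom] = (grp["pos"].to_numpy(), grp["index"].to_numpy())
    for name, hs in sorted(by_name.items()):
        mids = pd.DataFrame({"chrom": [h.chrom for h in hs],
                             "pos": [(h.start + h.end) // 2 + 1 for h in hs]})
        idx: list[int] = []
        for row in mids.itertuples(index=False):
            pos_arr, orig = pos_by_chrom.get(row.chrom, (np.array([]), np.array([])))
            if not len(pos_arr):
                continue
            lo = np.searchsorted(pos_arr, row.pos - flank)
            hi = np.searchsorted(pos_arr, row.pos + flank, side="right")
            idx.extend(int(i) for i in orig[lo:hi])
        rec: dict = {"pwm": name, "n_hits": len(hs), "n_cpgs_in_windows": len(idx)}
        if idx:
            for g in ("CD8", "DN"):
                meth, total = matrix.group_counts(g)
                rec[f"meth_{g}"] = float(meth[idx].sum() / max(total[idx].sum(), 1))
        else:
            logger.info("motif_centered_profiles: no CpGs near %s hits", name)
            rec["meth_CD8"] = rec["meth_DN"] = float("nan")
        for cond, track in tracks.items():
            _, mean_profile, _ = aggregate_signal(track, mids, flank=flank,
                                                  n_bins=max(2, (2 * flank) // 50))
            rec[f"signal_{cond}"] = float(mean_profile.mean())
        rows.append(rec)
    return pd.DataFrame(rows)


def load_meme(path_or_file) -> list[PWM]:
    """Parse a MEME minimal-format motif file into PWMs."""
    if hasattr(path_or_file, "read"):
        text = path_or_file.read()
    else:
        with open(path_or_file) as fh:
            text = fh.read()
    pwms = []
    name = None
    rows: list[list[float]] = []
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("MOTIF"):
            if name is not None and rows:
                pwms.append(PWM(name, np.asarray(rows)))
            name = line.split()[1]
            rows = []
        elif name is not None and line:
            parts = line.split()
            if len(parts) == 4:
                try:
                    rows.append([float(x) for x in parts])
                except ValueError:
                    pass
    if name is not None and rows:
        pwms.append(PWM(name, np.asarray(rows)))
    return pwms


def bundled_pwms() -> list[PWM]:
    """The small shipped PWM library: AP-1, T-box/T-BET, EGR2 plus the MspI and
    TaqI restriction-site positive controls."""
    ref = resources.files("dmlkit").joinpath("data/motifs.meme")
    with ref.open() as fh:
        return load_meme(fh)
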