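"""Beta-binomial Wald test for differential CpG methylation.

Two groups of replicate bisulfite count data are compared per CpG.  Counts are
modelled as beta-binomial: the methylated count X_gr of replicate r in group g
has mean N_gr * mu_g and variance N_gr * mu_g * (1 - mu_g) * (1 + (N_gr - 1) * phi),
where phi is the extra-binomial (replicate-to-replicate) dispersion.  Per-CpG
dispersions are estimated by method of moments and shrunk toward the genome-wide
mean on the log scale (empirical-Bayes log-normal prior).  The Wald statistic

    t = (mu_DN - mu_CD8) / sqrt(Var_CD8 + Var_DN)

is referred to the standard normal; Benjamini-Hochberg correction gives an FDR
per CpG, and a locus is called differentially methylated when FDR < 0.05 and
|delta| > 0.20 (both strict), the thresholds used for the headline DML set.

The model-object interface::

    model = BetaBinomialDML(matrix)        # a FilteredMatrix
    res = model.fit()                      # DMLResults
    res.table                              # per-CpG statistics
    res.summary()

`DMLResults` also exposes volcano export, per-chromosome significance profiles
and a volcano plot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import FilteredMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DispersionEstimate",
    "BetaBinomialDML",
    "DMLResults",
    "estimate_dispersions",
    "wald_test",
    "bh_fdr",
    "call_dml",
    "chromosome_significance_profile",
    "volcano_table",
]

# weakly informative prior used when no CpG yields a finite positive dispersion
FALLBACK_PRIOR = (float(np.log(0.01)), 1.0)
_P_FLOOR = 1e-300


@dataclass
class DispersionEstimate:
    """Raw and shrunk per-CpG beta-binomial dispersions."""

    phi_raw: np.ndarray  # method-of-moments, NaN where undefined
    phi_shrunk: np.ndarray
    m0: float  # prior mean of log phi
    r0_sq: float  # prior variance of log phi


def _group_moments(meth: np.ndarray, total: np.ndarray):
    """Pooled mean, replicate variance of proportions and binomial terms per CpG
    for one group.  Rows with <2 covered replicates get NaN variance."""
    with np.errstate(invalid="ignore", divide="ignore"):
        covered = total > 0
        n_cov = covered.sum(axis=1)
        tot_sum = total.sum(axis=1)
        mu = np.where(tot_sum > 0, meth.sum(axis=1) / np.maximum(tot_sum, 1), np.nan)
        prop = np.where(covered, meth / np.maximum(total, 1), np.nan)
        dev_sq = np.where(covered, (prop - mu[:, None]) ** 2, 0.0)
        var = np.where(n_cov >= 2, dev_sq.sum(axis=1) / np.maximum(n_cov - 1, 1), np.nan)
        inv_n = np.where(covered, 1.0 / np.maximum(total, 1), 0.0)
        mean_inv_n = np.where(n_cov > 0, inv_n.sum(axis=1) / np.maximum(n_cov, 1), np.nan)
    return mu, var, mean_inv_n, n_cov


def estimate_dispersions(matrix: FilteredMatrix) -> DispersionEstimate:
    """Method-of-moments dispersion per CpG with log-normal shrinkage.

    For each group g the sample variance of replicate proportions around the
    pooled group mean has expectation
    mu_g(1-mu_g) * mean_r[1/N_gr + phi (N_gr-1)/N_gr]; solving for phi and
    pooling numerator and denominator over both groups (weights n_g - 1) gives
    the raw phi-hat, clamped at 0.  Shrinkage: with prior (m0, r0^2) estimated
    from finite positive phi-hats and a per-CpG sampling variance
    s_i^2 = 2/(n_eff - 1), the posterior log dispersion is
    w * log(phi-hat) + (1-w) * m0 with w = r0^2/(r0^2 + s_i^2).
    """
    if matrix.n_cpgs < 1:
        raise ValueError("matrix has no CpGs")
    num = np.zeros(matrix.n_cpgs)
    den = np.zeros(matrix.n_cpgs)
    any_valid = np.zeros(matrix.n_cpgs, dtype=bool)
    n_eff = np.zeros(matrix.n_cpgs)
    for g in ("CD8", "DN"):
        meth, total = matrix.group_counts(g)
        mu, var, mean_inv_n, n_cov = _group_moments(meth, total)
        n_eff += n_cov
        mumu = mu * (1.0 - mu)
        covered = total > 0
        frac_nm1 = np.where(covered, 1.0 - 1.0 / np.maximum(total, 1), 0.0)
        mean_c = np.where(n_cov > 0, frac_nm1.sum(axis=1) / np.maximum(n_cov, 1), np.nan)
        valid = (n_cov >= 2) & np.isfinite(var) & (mumu > 0) & np.isfinite(mean_c) & (mean_c > 0)
        w = np.where(valid, n_cov - 1, 0.0)
        num += np.where(valid, w * (var - mumu * mean_inv_n), 0.0)
        den += np.where(valid, w * mumu * mean_c, 0.0)
        any_valid |= valid
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_raw = np.where(any_valid & (den > 0), num / np.where(den > 0, den, 1.0), np.nan)
    phi_raw = np.where(np.isfinite(phi_raw), np.maximum(phi_raw, 0.0), np.nan)

    finite_pos = np.isfinite(phi_raw) & (phi_raw > 0)
    if finite_pos.sum() >= 2:
        log_phi = np.log(phi_raw[finite_pos])
        m0 = float(np.mean(log_phi))
        r0_sq = float(np.var(log_phi, ddof=1))
    elif finite_pos.sum() == 1:
        m0 = float(np.log(phi_raw[finite_pos][0]))
        r0_sq = FALLBACK_PRIOR[1]
    else:
        m0, r0_sq = FALLBACK_PRIOR

    s_sq = 2.0 / np.maximum(n_eff - 1, 1)
    w = r0_sq / (r0_sq + s_sq) if r0_sq > 0 else np.zeros_like(s_sq)
    with np.errstate(divide="ignore"):
        log_raw = np.where(finite_pos, np.log(np.where(finite_pos, phi_raw, 1.0)), m0)
    phi_shrunk = np.exp(np.where(finite_pos, w * log_raw + (1 - w) * m0, m0))
    return DispersionEstimate(phi_raw=phi_raw, phi_shrunk=phi_shrunk, m0=m0, r0_sq=r0_sq)


def _group_var(meth: np.ndarray, total: np.ndarray, phi: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Wald variance of the pooled group proportion under beta-binomial counts."""
    tot_sum = total.sum(axis=1).astype(float)
    inflation = (total * (1.0 + (total - 1.0) * phi[:, None])).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return mu * (1.0 - mu) * inflation / np.maximum(tot_sum, 1.0) ** 2


def wald_test(matrix: FilteredMatrix, dispersions: DispersionEstimate | None = None) -> pd.DataFrame:
    """Per-CpG group means, difference, Wald statistic and two-sided normal p.

    When both group means are degenerate (0 or 1) the variance is recomputed
    with the continuity-corrected mean (sum X + 0.5)/(sum N + 1) so the
    statistic stays finite while keeping its sign.
    """
    if dispersions is None:
        dispersions = estimate_dispersions(matrix)
    phi = dispersions.phi_shrunk
    meth_a, total_a = matrix.group_counts("CD8")
    meth_b, total_b = matrix.group_counts("DN")
    sum_xa, sum_na = meth_a.sum(axis=1), total_a.sum(axis=1)
    sum_xb, sum_nb = meth_b.sum(axis=1), total_b.sum(axis=1)
    mu_a = sum_xa / np.maximum(sum_na, 1)
    mu_b = sum_xb / np.maximum(sum_nb, 1)
    delta = mu_b - mu_a

    var_a = _group_var(meth_a, total_a, phi, mu_a)
    var_b = _group_var(meth_b, total_b, phi, mu_b)
    var = var_a + var_b

    degenerate = var <= 0
    if degenerate.any():
        mu_a_c = (sum_xa + 0.5) / (sum_na + 1.0)
        mu_b_c = (sum_xb + 0.5) / (sum_nb + 1.0)
        var_c = _group_var(meth_a, total_a, phi, mu_a_c) + _group_var(meth_b, total_b, phi, mu_b_c)
        var = np.where(degenerate, var_c, var)

    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(delta == 0.0, 0.0, delta / np.sqrt(var))
    p = np.clip(2.0 * stats.norm.sf(np.abs(t)), _P_FLOOR, 1.0)

    out = matrix.keys.copy()
    out["mu_cd8"] = mu_a
    out["mu_dn"] = mu_b
    out["delta"] = delta
    out["stat"] = t
    out["pvalue"] = p
    return out


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dml(
    test_results: pd.DataFrame, fdr_threshold: float = 0.05, min_delta: float = 0.20
) -> tuple[pd.DataFrame, dict]:
    """Flag significant DML (FDR < threshold AND |delta| > min_delta, strict)
    and summarise the direction split."""
    for name, val in (("fdr_threshold", fdr_threshold), ("min_delta", min_delta)):
        if not 0 < val < 1:
            raise ValueError(f"{name} must lie in (0, 1)")
    table = test_results.copy()
    if "fdr" not in table.columns:
        table["fdr"] = bh_fdr(table["pvalue"].to_numpy())
    table["direction"] = np.where(table["delta"] < 0, "hypo", np.where(table["delta"] > 0, "hyper", "none"))
    table["significant"] = (table["fdr"] < fdr_threshold) & (table["delta"].abs() > min_delta)
    sig = table[table["significant"]]
    n_hypo = int((sig["direction"] == "hypo").sum())
    n_hyper = int((sig["direction"] == "hyper").sum())
    n_sig = n_hypo + n_hyper
    summary = {
        "n_tested": int(len(table)),
        "n_significant": n_sig,
        "n_hypo": n_hypo,
        "n_hyper": n_hyper,
        "hypo_fraction": (n_hypo / n_sig) if n_sig else float("nan"),
    }
    logger.info("call_dml: %d/%d significant (%d hypo, %d hyper)", n_sig, len(table), n_hypo, n_hyper)
    return table, summary


def chromosome_significance_profile(
    test_results: pd.DataFrame, window_bp: int
) -> pd.DataFrame:
    """Tile each chromosome and report the minimum p per window (bedGraph rows
    chrom/start/end/value with value = -log10 min p); empty windows omitted."""
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    rows = []
    for chrom, grp in test_results.groupby("chrom", sort=True):
        pos0 = grp["pos"].to_numpy() - 1
        win = pos0 // window_bp
        frame = pd.DataFrame({"win": win, "p": grp["pvalue"].to_numpy()})
        agg = frame.groupby("win")["p"].min()
        for w, p in agg.items():
            rows.append((chrom, int(w) * window_bp, (int(w) + 1) * window_bp, float(-np.log10(p))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def volcano_table(test_results: pd.DataFrame) -> pd.DataFrame:
    """Project (delta, -log10 FDR) pairs for volcano plotting."""
    fdr = test_results["fdr"] if "fdr" in test_results.columns else pd.Series(
        bh_fdr(test_results["pvalue"].to_numpy()))
    return pd.DataFrame({
        "delta": test_results["delta"].to_numpy(),
        "neg_log10_fdr": -np.log10(np.asarray(fdr, dtype=float)),
    })


class BetaBinomialDML:
    """Two-group beta-binomial differential-methylation model.

    Parameters
    ----------
    matrix : FilteredMatrix
        Coverage-filtered count matrix with group labels CD8 and DN.
    """

    def __init__(self, matrix: FilteredMatrix):
        if matrix.n_cpgs < 1:
            raise ValueError("matrix has no CpGs")
        self.matrix = matrix

    @classmethod
    def from_methylomes(cls, methylomes, min_cov: int = 10, per_sample: bool = False):
        from .io import coverage_filter

        return cls(coverage_filter(methylomes, min_cov=min_cov, per_sample=per_sample))

    def fit(self, fdr_threshold: float = 0.05, min_delta: float = 0.20) -> "DMLResults":
        disp = estimate_dispersions(self.matrix)
        table = wald_test(self.matrix, disp)
        table["fdr"] = bh_fdr(table["pvalue"].to_numpy())
        table, summary = call_dml(table, fdr_threshold, min_delta)
        return DMLResults(self, disp, table, summary, fdr_threshold, min_delta)


class DMLResults:
    """Fitted per-CpG statistics with calling thresholds applied."""

    def __init__(self, model, dispersions, table, direction_summary, fdr_threshold, min_delta):
        self.model = model
        self.dispersions = dispersions
        self.table = table
        self.direction_summary = direction_summary
        self.fdr_threshold = fdr_threshold
        self.min_delta = min_delta

    @property
    def dml(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def recall(self, fdr_threshold: float, min_delta: float) -> "DMLResults":
        """Re-apply calling thresholds without refitting."""
        table, summary = call_dml(self.table.drop(columns=["direction", "significant"]),
                                  fdr_threshold, min_delta)
        return DMLResults(self.model, self.dispersions, table, summary, fdr_threshold, min_delta)

    def volcano_table(self) -> pd.DataFrame:
        return volcano_table(self.table)

    def significance_profile(self, window_bp: int) -> pd.DataFrame:
        return chromosome_significance_profile(self.table, window_bp)

    def plot_volcano(self, ax=None):
        import matplotlib.pyplot as plt

        vt = self.volcano_table()
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(vt["delta"], vt["neg_log10_fdr"], s=4,
                   c=np.where(self.table["significant"], "crimson", "grey"))
        ax.set_xlabel("methylation difference (DN - CD8)")
        ax.set_ylabel("-log10 FDR")
        return ax

    def summary(self) -> str:
        s = self.direction_summary
        lines = [
            "Beta-binomial Wald differential methylation",
            "=" * 46,
            f"CpGs tested            {s['n_tested']:>12d}",
            f"significant DML        {s['n_significant']:>12d}"
            f"  (FDR<{self.fdr_threshold:g}, |delta|>{self.min_delta:g})",
            f"  hypomethylated in DN {s['n_hypo']:>12d}",
            f"  hypermethylated in DN{s['n_hyper']:>12d}",
        ]
        if s["n_significant"]:
            lines.append(f"  hypo fraction        {s['hypo_fraction']:>12.3f}")
        lines.append(f"dispersion prior       m0={self.dispersions.m0:.3f}, "
                     f"r0^2={self.dispersions.r0_sq:.3f}")
        return "\n".join(lines)
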