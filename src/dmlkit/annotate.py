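"""Nearest-TSS annotation of DML and integration with expression changes.

A DML is assigned to the gene whose transcription start site is closest on the
same chromosome by absolute base-pair distance (strand-ignored point distance;
ties go to the lexicographically smallest gene id).  The annotated table is
then joined with a gene-level differential-expression table to count genes that
are both upregulated and demethylated, to summarise the quadrants of the
(Δmethylation, Δexpression) plane, and to rank genes by their burden of
demethylated DML.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["nearest_tss", "integrate_expression", "rank_genes_by_dml"]


def nearest_tss(
    dml_table: pd.DataFrame,
    tss_table: pd.DataFrame,
    max_distance: int | None = None,
) -> pd.DataFrame:
    """Annotate each DML with its nearest gene TSS and signed distance.

    Signed distance is ``pos - tss`` (positive when the DML lies downstream of
    the TSS coordinate, orientation-naive).  DML on chromosomes with no TSS are
    returned with a missing gene id.  ``max_distance``, when given, blanks
    assignments farther than the cap.
    """
    if not len(tss_table):
        raise ValueError("empty TSS table")
    if tss_table["gene_id"].duplicated().any():
        raise ValueError("gene ids must be unique")

    out = dml_table.copy().reset_index(drop=True)
    gene = np.full(len(out), None, dtype=object)
    dist = np.full(len(out), np.nan)

    for chrom, idx in out.groupby("chrom", sort=False).groups.items():
        sub = tss_table[tss_table["chrom"] == chrom]
        if not len(sub):
            logger.info("nearest_tss: %d DML on %s have no TSS", len(idx), chrom)
            continue
        # sort by (tss, gene_id) so equidistant ties resolve to the smallest id
        sub = sub.sort_values(["tss", "gene_id"], kind="mergesort")
        tss = sub["tss"].to_numpy()
        ids = sub["gene_id"].to_numpy()
        pos = out.loc[idx, "pos"].to_numpy()
        right = np.searchsorted(tss, pos, side="left")
        left = np.clip(right - 1, 0, len(tss) - 1)
        right = np.clip(right, 0, len(tss) - 1)
        d_left = np.abs(pos - tss[left])
        d_right = np.abs(pos - tss[right])
        # tie at equal distance: prefer the smaller gene id; compare each side's
        # smallest id at its coordinate (run-first entry)
        ids_left = ids[np.searchsorted(tss, tss[left], side="left")]
        ids_right = ids[np.searchsorted(tss, tss[right], side="left")]
        pick_left = (d_left < d_right) | ((d_left == d_right) & (ids_left <= ids_right))
        chosen = np.where(pick_left, left, right)
        # collapse equal-coordinate TSS runs to their first (smallest-id) entry
        chosen = np.searchsorted(tss, tss[chosen], side="left")
        gene[idx] = ids[chosen]
        dist[idx] = pos - tss[chosen]

    if max_distance is not None:
        far = np.abs(dist) > max_distance
        gene[far] = None
        dist[far] = np.nan
    out["gene_id"] = gene
    out["tss_distance"] = dist
    return out


def integrate_expression(
    annotated_dml: pd.DataFrame, expression: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Join annotated DML with expression changes and summarise the overlap.

    Returns the joined per-DML table plus a summary dict with: the number of
    upregulated genes mapped to at least one hypo DML; the number of DML
    mapping to significantly changed genes and how many of those are hypo; and
    quadrant counts of the (Δmethylation, Δexpression) plane.
    """
    if not len(expression):
        raise ValueError("empty expression table")
    ann = annotated_dml.dropna(subset=["gene_id"])
    joined = ann.merge(expression, on="gene_id", how="inner")

    if "direction" in joined.columns:
        is_hypo = joined["direction"] == "hypo"
    else:
        is_hypo = joined["delta"] < 0

    up_genes = set(expression.loc[expression["upregulated"], "gene_id"])
    genes_up_and_demeth = sorted(set(joined.loc[is_hypo, "gene_id"]) & up_genes)

    sig_genes = joined["upregulated"].astype(bool)
    n_dml_sig_genes = int(sig_genes.sum())
    n_dml_sig_genes_hypo = int((sig_genes & is_hypo).sum())

    dmeth = joined["delta"].to_numpy() if "delta" in joined.columns else np.where(is_hypo, -1.0, 1.0)
    dexpr = joined["log_fc"].to_numpy()
    quadrants = {
        "hypo_up": int(((dmeth < 0) & (dexpr > 0)).sum()),
        "hypo_down": int(((dmeth < 0) & (dexpr < 0)).sum()),
        "hyper_up": int(((dmeth > 0) & (dexpr > 0)).sum()),
        "hyper_down": int(((dmeth > 0) & (dexpr < 0)).sum()),
    }
    summary = {
        "n_genes_up_and_demethylated": len(genes_up_and_demeth),
        "genes_up_and_demethylated": genes_up_and_demeth,
        "n_dml_at_significant_genes": n_dml_sig_genes,
        "n_hypo_dml_at_significant_genes": n_dml_sig_genes_hypo,
        "quadrants": quadrants,
    }
    logger.info("integrate_expression: %d genes both upregulated and demethylated; "
                "%d/%d DML at significant genes are hypo",
                len(genes_up_and_demeth), n_dml_sig_genes_hypo, n_dml_sig_genes)
    return joined, summary


def rank_genes_by_dml(joined_table: pd.DataFrame) -> pd.DataFrame:
    """Rank genes by the number of hypo DML mapping to each (ties by gene id)."""
    if "direction" in joined_table.columns:
        hypo = joined_table[joined_table["direction"] == "hypo"]
    else:
        hypo = joined_table[joined_table["delta"] < 0]
    counts = hypo.groupby("gene_id").size().reset_index(name="n_hypo_dml")
    counts = counts.sort_values(["n_hypo_dml", "gene_id"],
                                ascending=[False, True], kind="mergesort")
    counts["rank"] = np.arange(1, len(counts) + 1)
    return counts.reset_index(drop=True)
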