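"""Gene-level CRISPR scores, Kolmogorov-Smirnov significance and hit calling.

The CRISPR score (CS) of a gene is the median of the log2 fold changes of
all its sgRNAs pooled across the two timepoint replicates.  Significance
comes from a two-sided two-sample Kolmogorov-Smirnov test of the gene's
pooled guide logFC values against the pooled logFC values of every other
guide in the screen, followed by Benjamini-Hochberg adjustment over the
genes that pass the minimum-guide filter.

Hit classes:

* ``strong_enriched``     — FDR below threshold and CS above the CS threshold
* ``enriched``            — FDR below threshold and CS in (0, threshold]
* ``depleted_significant``— FDR below threshold and CS <= 0
* ``not_significant``     — FDR at or above threshold
* ``filtered``            — fewer pooled guide values than ``min_guides``
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp
from statsmodels.stats.multitest import multipletests

from .io import LibraryDesign, ScreenFormatError
from .sgrna import P_FLOOR

__all__ = [
    "AnalysisConfig",
    "aggregate_gene_scores",
    "gene_ks_pvalue",
    "bh_adjust",
    "filter_and_call",
    "rank_significant",
    "score_genes",
    "volcano_table",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds of the hit-calling funnel.

    min_guides
        Genes with fewer pooled guide logFC values are filtered out and
        excluded from the multiple-testing family.
    fdr_threshold, cs_threshold
        A gene is a strong enrichment hit when FDR < ``fdr_threshold`` and
        CS > ``cs_threshold`` (a log2 quantity).
    exact_n_limit
        Exact small-sample KS p-values are used up to this many pooled
        guide values; the asymptotic Kolmogorov distribution beyond.
    """

    min_guides: int = 3
    fdr_threshold: float = 0.05
    cs_threshold: float = 1.5
    exact_n_limit: int = 10

    def __post_init__(self):
        errors = []
        if self.min_guides < 1:
            errors.append("min_guides must be >= 1")
        if self.fdr_threshold <= 0 or self.cs_threshold <= 0:
            errors.append("thresholds must be positive")
        if errors:
            raise ScreenFormatError(errors)


def aggregate_gene_scores(sgrna_results: pd.DataFrame, lib: LibraryDesign) -> pd.DataFrame:
    """Pool guide logFC values per gene across replicates; CS = median.

    Returns a table indexed by gene with columns ``n_guides``,
    ``crispr_score`` and ``logfcs`` (the pooled value array, kept for the
    KS test).  Genes of the library with no surviving guide value appear
    with ``n_guides`` 0 and NaN CS (they will be marked filtered).
    """
    if sgrna_results.empty:
        raise ScreenFormatError(["no sgRNA results to aggregate"])
    df = sgrna_results.copy()
    if "gene" not in df.columns or (df["gene"] == "").any():
        df["gene"] = [lib.entries.get(g, "") for g in df["guide"]]
    grouped = df.groupby("gene", sort=True)["logfc"].agg(list)
    genes = sorted(lib.genes)
    rows = []
    for gene in genes:
        vals = np.asarray(grouped.get(gene, []), dtype=float)
        rows.append(
            {
                "gene": gene,
                "n_guides": len(vals),
                "crispr_score": float(np.median(vals)) if len(vals) else np.nan,
                "logfcs": vals,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def gene_ks_pvalue(
    gene_logfcs: np.ndarray, background_logfcs: np.ndarray, exact_n_limit: int = 10
) -> float:
    """Two-sided two-sample KS p-value of a gene's guide scores vs background.

    Exact (full conditional null over label assignments) when the gene
    contributes at most ``exact_n_limit`` values, asymptotic otherwise.
    """
    gene_logfcs = np.asarray(gene_logfcs, dtype=float)
    background_logfcs = np.asarray(background_logfcs, dtype=float)
    if background_logfcs.size == 0:
        raise ScreenFormatError(["empty background for KS test"])
    method = "exact" if gene_logfcs.size <= exact_n_limit else "asymp"
    p = ks_2samp(gene_logfcs, background_logfcs, alternative="two-sided", method=method).pvalue
    return float(np.clip(p, P_FLOOR, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p <= 0) | (p > 1)).any():
        raise ScreenFormatError(["p-values must lie in (0, 1]"])
    return multipletests(p, method="fdr_bh")[1]


def filter_and_call(gene_table: pd.DataFrame, cfg: AnalysisConfig) -> pd.DataFrame:
    """Apply the guide filter, BH adjustment and hit classification.

    Genes below ``min_guides`` are marked ``filtered`` and excluded from
    the BH family; they carry no p-value, FDR or rank.
    """
    out = gene_table.copy()
    tested = out["n_guides"] >= cfg.min_guides
    out["fdr"] = np.nan
    out.loc[tested, "fdr"] = bh_adjust(out.loc[tested, "p_value"].to_numpy())
    out.loc[~tested, "p_value"] = np.nan

    hit = np.full(len(out), "not_significant", dtype=object)
    sig = tested & (out["fdr"] < cfg.fdr_threshold)
    cs = out["crispr_score"]
    hit[(sig & (cs > cfg.cs_threshold)).to_numpy()] = "strong_enriched"
    hit[(sig & (cs > 0) & (cs <= cfg.cs_threshold)).to_numpy()] = "enriched"
    hit[(sig & (cs <= 0)).to_numpy()] = "depleted_significant"
    hit[(~tested).to_numpy()] = "filtered"
    out["hit_class"] = hit
    return out


def rank_significant(gene_table: pd.DataFrame, cfg: AnalysisConfig) -> pd.DataFrame:
    """Rank FDR-significant genes by CS (1 = largest).

    Ties break by smaller p-value, then lexicographic gene symbol.
    Non-significant genes carry no rank.
    """
    out = gene_table.copy()
    sig = out["fdr"] < cfg.fdr_threshold
    ranked = (
        out[sig]
        .reset_index()
        .sort_values(
            ["crispr_score", "p_value", "gene"], ascending=[False, True, True]
        )["gene"]
        .tolist()
    )
    out["rank"] = np.nan
    for i, gene in enumerate(ranked, start=1):
        out.loc[gene, "rank"] = i
    out["rank"] = out["rank"].astype("Int64")
    return out


def score_genes(
    sgrna_results: pd.DataFrame, lib: LibraryDesign, cfg: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Full gene-level analysis: CS, KS p, BH FDR, hit class, rank.

    ``sgrna_results`` is the concatenated per-replicate guide table (columns
    guide, gene, replicate, logfc).  Returns a gene-indexed table with
    columns n_guides, crispr_score, p_value, fdr, rank, hit_class.
    """
    cfg = cfg or AnalysisConfig()
    table = aggregate_gene_scores(sgrna_results, lib)
    all_vals = np.concatenate([v for v in table["logfcs"] if len(v)])
    # background per gene = every other guide's pooled logFC values
    offsets = np.concatenate([[0], np.cumsum(table["n_guides"].to_numpy())])
    pvals = np.full(len(table), np.nan)
    for i, (n, vals) in enumerate(zip(table["n_guides"], table["logfcs"])):
        if n < cfg.min_guides:
            continue
        background = np.delete(all_vals, slice(offsets[i], offsets[i + 1]))
        pvals[i] = gene_ks_pvalue(vals, background, cfg.exact_n_limit)
    table = table.drop(columns=["logfcs"])
    table["p_value"] = pvals
    table = filter_and_call(table, cfg)
    table = rank_significant(table, cfg)
    return table[["n_guides", "crispr_score", "p_value", "fdr", "rank", "hit_class"]]


def volcano_table(gene_table: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot coordinates: gene, crispr_score, -log10(FDR)."""
    out = gene_table.reset_index()[["gene", "crispr_score", "fdr"]].copy()
    out["neg_log10_fdr"] = -np.log10(out["fdr"])
    return out[["gene", "crispr_score", "neg_log10_fdr"]]
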