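"""Model/Results interface over the screen-analysis pipeline.

:class:`PooledScreenModel` holds the data (counts, library, sample
sheet) and the analysis configuration; :meth:`PooledScreenModel.fit`
runs normalization, the per-replicate per-sgRNA negative-binomial tests
and the gene-level scoring, and returns a :class:`PooledScreenResults`
carrying the estimates, diagnostics and a text summary.

Example
-------
>>> from poolscreen import PooledScreenModel, SimConfig
>>> model = PooledScreenModel.from_simulation(SimConfig(seed=7))
>>> res = model.fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import compare as _compare
from . import enrich as _enrich
from .genescore import AnalysisConfig, score_genes, volcano_table
from .io import (
    CountMatrix,
    GeneSetCollection,
    LibraryDesign,
    SampleSheet,
    ScreenFormatError,
    read_count_table,
    read_library_map,
    read_sample_sheet,
    validate_screen,
    write_gene_results,
)
from .norm import NormFactors, tmm_factors
from .sgrna import ReplicateDesign, replicates_from_sheet, run_replicate
from .simulate import SimConfig, SimTruth, simulate_screen

__all__ = ["PooledScreenModel", "PooledScreenResults"]


class PooledScreenModel:
    """Two-group pooled CRISPR screen model.

    Parameters
    ----------
    counts, library, samples
        The raw observables: guide x sample integer counts, the guide ->
        gene map, and the per-sample arm/concentration/timepoint sheet.
    config
        Hit-calling thresholds; defaults follow the published analysis
        (>= 3 guides, FDR < 0.05, CS > 1.5).
    prior_df
        Shrinkage strength (pseudo-observations) pulling per-guide NB
        dispersions toward the replicate's common dispersion.
    """

    def __init__(
        self,
        counts: CountMatrix,
        library: LibraryDesign,
        samples: SampleSheet,
        config: AnalysisConfig | None = None,
        prior_df: float = 10.0,
    ):
        self.counts = counts
        self.library = library
        self.samples = samples
        self.config = config or AnalysisConfig()
        self.prior_df = prior_df
        self.truth: SimTruth | None = None
        report = validate_screen(counts, library, samples, self.config.min_guides)
        if not report.ok:
            raise ScreenFormatError(list(report.errors))
        self.validation = report

    @classmethod
    def from_tables(
        cls,
        counts_path,
        library_path,
        samples_path,
        config: AnalysisConfig | None = None,
        **kwargs,
    ) -> "PooledScreenModel":
        """Build the model from the on-disk TSV artifacts."""
        return cls(
            read_count_table(counts_path),
            read_library_map(library_path),
            read_sample_sheet(samples_path),
            config,
            **kwargs,
        )

    @classmethod
    def from_simulation(
        cls, sim_config: SimConfig, config: AnalysisConfig | None = None, **kwargs
    ) -> "PooledScreenModel":
        """Simulate a screen and build the model on it; truth is attached."""
        counts, sheet, lib, truth = simulate_screen(sim_config)
        model = cls(counts, lib, sheet, config, **kwargs)
        model.truth = truth
        return model

    @property
    def replicates(self) -> list[ReplicateDesign]:
        return replicates_from_sheet(self.samples)

    def fit(self) -> "PooledScreenResults":
        """Run the full analysis and return the results object."""
        sgrna_tables = []
        norm_factors: dict[str, NormFactors] = {}
        for rep in self.replicates:
            sub = self.counts.subset_samples(list(rep.member_ids))
            keep = sub.counts.sum(axis=1) > 0
            kept = CountMatrix(
                tuple(g for g, k in zip(sub.guide_ids, keep) if k),
                sub.sample_ids,
                sub.counts[keep],
            )
            norm_factors[rep.replicate_id] = tmm_factors(kept)
            sgrna_tables.append(
                run_replicate(self.counts, self.library, self.samples, rep, self.prior_df)
            )
        sgrna_table = pd.concat(sgrna_tables, ignore_index=True)
        gene_table = score_genes(sgrna_table, self.library, self.config)
        return PooledScreenResults(
            model=self,
            gene_table=gene_table,
            sgrna_table=sgrna_table,
            norm_factors=norm_factors,
        )


@dataclass
class PooledScreenResults:
    """Fitted screen analysis: gene table, guide table, diagnostics."""

    model: PooledScreenModel
    gene_table: pd.DataFrame  # gene-indexed: n_guides, crispr_score, p_value, fdr, rank, hit_class
    sgrna_table: pd.DataFrame  # guide, gene, replicate, logfc, lrt_stat, p_value
    norm_factors: dict[str, NormFactors] = field(default_factory=dict)

    # -- derived views -----------------------------------------------------

    @property
    def hits(self) -> pd.DataFrame:
        """Strong enrichment hits (FDR and CS thresholds both passed)."""
        return self.gene_table[self.gene_table["hit_class"] == "strong_enriched"]

    @property
    def significant(self) -> pd.DataFrame:
        cfg = self.model.config
        return self.gene_table[self.gene_table["fdr"] < cfg.fdr_threshold]

    def funnel(self) -> dict[str, int]:
        """Gene counts surviving each stage of the hit-calling funnel."""
        gt = self.gene_table
        cfg = self.model.config
        sig = gt["fdr"] < cfg.fdr_threshold
        return {
            "genes_total": len(gt),
            "genes_tested": int((gt["hit_class"] != "filtered").sum()),
            "genes_filtered": int((gt["hit_class"] == "filtered").sum()),
            "fdr_significant": int(sig.sum()),
            "enriched_cs_gt0": int((sig & (gt["crispr_score"] > 0)).sum()),
            "strong_enriched": int((gt["hit_class"] == "strong_enriched").sum()),
        }

    def volcano_table(self) -> pd.DataFrame:
        """Gene, CRISPR score and -log10(FDR), the volcano-plot axes."""
        return volcano_table(self.gene_table)

    def compare_ranks(
        self, other: "PooledScreenResults | pd.DataFrame", genes: Sequence[str] | None = None
    ) -> pd.DataFrame:
        """Rank comparison against another scored screen."""
        other_table = other.gene_table if isinstance(other, PooledScreenResults) else other
        return _compare.compare_ranks(self.gene_table, other_table, genes)

    def enrich(self, collection: GeneSetCollection) -> pd.DataFrame:
        """Over-representation of the strong hits among gene sets.

        Universe = genes passing the guide filter (the tested population).
        """
        universe = set(self.gene_table.index[self.gene_table["hit_class"] != "filtered"])
        hits = set(self.hits.index)
        return _enrich.hypergeometric_enrichment(hits, collection, universe)

    def plot_volcano(self, ax=None):
        """Volcano plot (CS vs -log10 FDR); needs matplotlib installed."""
        import matplotlib.pyplot as plt

        vt = self.volcano_table().dropna()
        if ax is None:
            _, ax = plt.subplots()
        strong = self.gene_table.loc[vt["gene"], "hit_class"].to_numpy() == "strong_enriched"
        ax.scatter(vt["crispr_score"], vt["neg_log10_fdr"], s=6, c="0.6", label="other")
        ax.scatter(
            vt["crispr_score"][strong], vt["neg_log10_fdr"][strong], s=10, c="crimson",
            label="strong enriched",
        )
        ax.axhline(-np.log10(self.model.config.fdr_threshold), ls="--", c="k", lw=0.8)
        ax.set_xlabel("CRISPR score (median log2 FC)")
        ax.set_ylabel("-log10 FDR")
        ax.legend(frameon=False)
        return ax

    def save(self, path) -> None:
        """Write the gene-results TSV."""
        write_gene_results(self.gene_table.reset_index(), path)

    def summary(self) -> str:
        """Text summary: design, dispersions, funnel and top-ranked genes."""
        cfg = self.model.config
        fun = self.funnel()
        lines = [
            "Pooled CRISPR screen analysis",
            "=" * 64,
            f"samples: {self.model.counts.n_samples} "
            f"({len(self.model.samples.control_ids)} control, "
            f"{len(self.model.samples.treated_ids)} treated)",
            f"replicates (timepoints): {len(self.model.replicates)}",
            f"guides: {self.model.counts.n_guides}; genes: {len(self.model.library.genes)}",
            f"thresholds: min_guides={cfg.min_guides}, FDR<{cfg.fdr_threshold}, "
            f"CS>{cfg.cs_threshold}",
            "-" * 64,
            "hit-calling funnel:",
        ]
        lines += [f"  {k:>18s}: {v}" for k, v in fun.items()]
        top = (
            self.gene_table.dropna(subset=["rank"]).sort_values("rank").head(10).reset_index()
        )
        if not top.empty:
            lines += ["-" * 64, "top ranked genes (by CRISPR score among FDR-significant):"]
            lines.append(f"  {'rank':>4} {'gene':<12} {'CS':>8} {'FDR':>10} {'n_guides':>8}")
            for r in top.itertuples():
                lines.append(
                    f"  {int(r.rank):>4} {r.gene:<12} {r.crispr_score:>8.3f} "
                    f"{r.fdr:>10.2e} {int(r.n_guides):>8}"
                )
        return "\n".join(lines)
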