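"""Cross-screen rank comparison.

Joins gene ranks between two analysed screens (e.g. the drug-selected
screen against the untreated essentialome screen) so that drug-specific
enrichment can be told apart from general fitness effects: a gene ranked
high only under selection is a drug-specific hit.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

__all__ = ["compare_ranks"]


def compare_ranks(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Outer-join gene ranks of two scored screens.

    Parameters
    ----------
    results_a, results_b
        Gene tables produced by :func:`poolscreen.genescore.score_genes`
        (gene-indexed, with ``rank`` and ``hit_class`` columns).
    genes
        Optional restriction to a gene subset (e.g. a pathway's members).

    Returns a table with columns gene, rank_a, rank_b, significant_a,
    significant_b and delta_rank (= rank_b - rank_a, defined only where
    both ranks are present; absent ranks are never imputed).
    """
    def _side(df: pd.DataFrame, suffix: str) -> pd.DataFrame:
        out = df[["rank", "hit_class"]].copy()
        out[f"significant_{suffix}"] = out["rank"].notna()
        return out.rename(columns={"rank": f"rank_{suffix}"}).drop(columns="hit_class")

    joined = _side(results_a, "a").join(_side(results_b, "b"), how="outer")
    for col in ("significant_a", "significant_b"):
        joined[col] = joined[col].astype("boolean").fillna(False).astype(bool)
    joined["delta_rank"] = joined["rank_b"] - joined["rank_a"]
    if genes is not None:
        joined = joined.loc[[g for g in genes if g in joined.index]]
    joined.index.name = "gene"
    return joined[["rank_a", "rank_b", "significant_a", "significant_b", "delta_rank"]]
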